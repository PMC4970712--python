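# Methods

`funnelpath` analyzes substrate translocation through membrane-transporter
channels: it profiles the funnel (pore) radius along the translocation axis,
classifies alternating-access conformational states from that profile,
detects typed ligand–protein interactions frame by frame, and condenses
trajectories into position-resolved interaction probabilities and RMSD/RMSF
statistics. All physical quantities are in Å and ns.

## Translocation axis

The 1-D transport coordinate z is defined by an `AxisFrame` (origin + unit
axis). Two constructions are supported:

* **inertia** — the principal axis of the coordinate inertia tensor. For a
  membrane transporter the long molecular axis is normal to the membrane
  plane, which corresponds to the *smallest* moment of inertia; that is the
  default, with the alternative exposed (`moment="largest"`). The axis sign
  is chosen so a user-supplied reference selection (or laboratory +z) maps
  to positive z, the extracellular/outward side by the package convention.
* **anchors** — the origin is the midpoint between the centroids of two
  anchor selections (e.g. the Cα atoms of the two gating tryptophans that
  bracket the binding site, which then spans roughly z = −5..+5), with a
  fixed or inertia-derived direction.

In trajectories the axis may be recomputed per frame (inertia mode) or held
fixed; both are exposed because neither choice is canonical for a
fluctuating protein. Whole-profile tests verify that z-values are invariant
under rigid motions applied jointly to the structure and the axis
definition (≤ 1e-6 Å).

## Funnel-radius profile

At each plane normal to the axis the profiler maximizes the clearance

    f(c) = min_i ( ‖c − x_i‖ − r_i )

over in-plane centers c, where x_i, r_i are atom centers and vdW radii —
the largest sphere centered in the plane that touches no atom. Radii
default to the HOLE "simple" set (C 1.85, N 1.75, O 1.65, S 2.00, H 1.00,
P 2.10 Å), overridable per element with a configurable fallback.

The maximizer is an annealed random search: `n_iter` proposals (default
2000) spent in `n_stages` batches whose Gaussian step size decays
geometrically from `step_hi` = 1.0 Å to `step_lo` = 0.01 Å; the first batch
samples uniformly over the whole search disk so eccentric pores and side
pockets are not missed, and the walker moves only on improvement. Within a
frame, planes are processed in z-order and each search warm-starts from the
previous plane's optimum. Results are clamped to [0, `r_max`] (default
12 Å); a plane whose clearance reaches `r_max` — e.g. through a gap to bulk
solvent — is flagged `capped`. The search is deterministic given the seed
(each frame/plane derives its own generator from `(seed, frame, plane)`).

Two numerical choices matter:

* **Search domain.** The center search is confined to the wall's local
  in-plane footprint: the lateral radius of atoms within ±1.5 Å (about one
  vdW diameter) of the plane, falling back to the global footprint when no
  atoms are that close. Without this bound, any finite wall admits
  unbounded clearance just outside its rim, and a thin-walled constriction
  shows a spurious "pore" in the empty shell between the neck's exterior
  and the flared wall above it. The exhaustive reference search shares the
  same domain, so the two routes answer the same question.
* **Clearance evaluation.** Atoms are grouped by radius value and queried
  through one KD-tree per class, keeping the per-proposal cost logarithmic
  in wall size. The brute-force reference (`grid_max_sphere_at_plane`,
  default 0.02 Å resolution) instead evaluates dense pairwise distances
  row by row; the two implementations share no search code.

Profiles are computed on a z-grid (defaults −15..+15 Å, dz = 0.5 Å) for a
frame selection that defaults to the final 0.1 ns of the trajectory (or the
last 100 frames when file times are uninformative), then averaged; the
reported uncertainty is the across-frame standard deviation divided by
√n_frames.

## State classification

A side of the transporter is **open** when the minimum mean radius over its
vestibule region (outward-facing +5..+15 Å, inward-facing −15..−5 Å)
reaches `r_open`, **semi-open** in [`r_semi`, `r_open`), and **closed**
below `r_semi`. Defaults are `r_open` = 2.0 Å (an arginine-passable bore)
and `r_semi` = 1.2 Å (a water-scale constriction); both are configuration
knobs because no canonical numeric cutoffs exist for these states. An
optional third threshold `r_quasi` splits the partially open band into
quasi-open and semi-open, mirroring the quasi-/semi-open vocabulary used
for inward-facing intermediates; it is off by default and no numeric
equivalence with any published assignment is claimed. The two side grades
compose into the label: both open → `bilaterally_open`, both closed →
`occluded`, one open → `OF_open`/`IF_open`, otherwise the wider side names
a semi-/quasi-open label (exact ties fall to `occluded`).

## Interaction detectors

Five geometric detectors run per frame between annotated ligand and
protein groups; all cutoffs are inclusive and configurable:

| type | criterion | defaults |
| --- | --- | --- |
| HB | donor–acceptor heavy-atom distance; optionally D–H···A angle | ≤ 3.5 Å; ≥ 120° |
| HB_H2O | one water O within the H-bond distance of a polar heavy atom on each side, same frame | ≤ 3.5 Å each |
| ionic | minimum N/O pair distance between charged groups | ≤ 4.0 Å |
| cation-π | charge center to ring centroid; angle from ring normal (sign folded) | ≤ 6.0 Å; ≤ 45° |
| π-π | centroid distance; interplanar angle (parallel stacking only) | ≤ 5.5 Å; ≤ 30° |

These thresholds are common practice for contact analysis; the taxonomy is
reproduced exactly, the numeric values transparently. Hydrogen-bond
geometry defaults to the heavy-atom criterion so structures without
explicit hydrogens are handled; the angular criterion activates with
`hb_use_hydrogens`. Ring planes come from a least-squares (SVD) fit;
degenerate rings are skipped with a warning. The cation charge center is
the group's designated atom (CZ for guanidinium, NZ for ammonium) else the
member centroid. Tryptophan contributes its 5- and 6-membered rings as two
groups, either of which may satisfy a ring contact. Multiple bridging
waters of one pair in one frame are kept as separate records but collapse
to a single pair-level event in probability profiles. T-shaped π stacking
and energy-based scoring are out of scope.

`scan_trajectory` applies every detector between ligand groups and the
protein residues that approach the ligand within 8 Å in at least one frame,
records the ligand's mass-weighted center-of-mass z per frame, and labels
each record backbone/side-chain by the ligand-side group.

## Slice statistics

The axis is divided into half-open 1-Å slices [k, k+1). For each
interaction key (type, ligand part, partner residue with the chain
stripped, so symmetry-related monomers pool):

    P(key, slice) = #frames(interaction present ∧ COM ∈ slice)
                    / #frames(COM ∈ slice)

Frames pool across trajectories by default ("pooled-frames" semantics); an
alternative that averages per-trajectory probabilities is available, since
pooling order is a genuine modeling choice when trajectories differ in
length. Keys whose peak probability over slices reaches the occurrence
threshold (default 20%, inclusive) are kept. Empty slices are masked as
undefined, never 0/0. Frames whose COM leaves the grid go to an overflow
bucket so occupancy is conserved.

## RMSD, RMSF and restraint traces

* **Ligand RMSD** — each frame and the reference are translated so the
  protein center of mass sits at the origin (translation-only
  registration; a rotational-fit variant is behind a flag) and the RMSD is
  taken over the ligand carbon atoms. This convention tracks the
  substrate's drift inside the transporter frame.
* **Occurrence histogram** — pooled RMSD values are binned ([low, high),
  counts N_O conserve the frame total); the per-bin standard error is the
  standard deviation of block-wise counts over contiguous equal blocks
  (remainder to the last block, each scaled to full-trajectory units)
  divided by √n_blocks. Block counts default to 3, with 6 and 18 used for
  longer analysis stages.
* **Protein RMSD** — optimal rigid superposition (Kabsch, SVD with
  reflection guard) onto the reference over backbone heavy atoms; atoms
  whose reference coordinates are missing (NaN) are excluded from both the
  fit and the RMSD, as unresolved crystal residues would be. Tests
  cross-check against an independent quaternion-based superposition.
* **RMSF** — frames are superposed onto the first frame over the
  selection; RMSF_i = √⟨‖x_i − ⟨x_i⟩‖²⟩, with optional per-residue
  averaging.
* **Restraint trace** — for targeted runs, the per-frame best-fit RMSD to
  the target and U(t) = (k/2N)·(RMSD(t) − RMSD*(t))² with RMSD*(t)
  decaying linearly from an anchor (default: the trace's initial value) to
  zero over T_total. The functional form is the standard targeted-MD
  convention, reconstructed here rather than taken from any particular
  engine's implementation.

## Synthetic data and what it does (not) show

The generator builds channels from rings of pseudo-atoms realizing a radius
function ρ(z) (cylinder, cone, hourglass, or Gaussian-constricted states),
with a closed-form expected maximal-sphere radius — min over rings of
√(ρ_k² + Δz²) − r_a — for assertions. Walls whose neighboring atom centers
are ≥ 2 atom radii apart are flagged leaky. State fixtures pinch a 6 Å
channel to ρ = 2 Å at z ≈ −8 (OF open), +8 (IF open), both (occluded), or
nowhere (bilaterally open).

Scripted translocations move an arginine-like pseudo-ligand (backbone +
guanidinium-like cationic head + a small synthetic aromatic ring, so every
detector type has a ligand-side partner — real arginine has no ring) down
the axis of a wide cylinder. The z-path is scripted exactly (default: 20
frames dwelling at each of 15 slice centers, 300 frames); lateral wobble is
an Ornstein–Uhlenbeck process (σ = 0.3 Å, correlation 5 frames), seeded and
reproducible. One probe residue per scheduled event is posed in contact
geometry (margins ≥ 0.3 Å / ≥ 5° inside its cutoff) on scheduled frames and
parked far outside all cutoffs otherwise; each probe carries exactly one
functional annotation so no unscheduled detector can fire. The ground-truth
sidecar (COM z per frame, boolean event matrix, implied P*) is therefore
exact, and the pipeline is required to recover it with **no tolerance**.

What passing these tests shows: the geometry, bookkeeping and statistics
are implemented correctly. What they do not show: agreement with any
particular force field, water model, or published detector parameter set;
the synthetic channels have no thermal physics, their walls are thin
shells, and probe poses are kinematic. Results on real trajectories depend
on the chosen cutoffs exactly as they would in any fingerprinting tool.

One subtlety found while validating: under independent per-atom coordinate
noise the maximal-sphere radius — a minimum over hundreds of noisy
constraints — contracts by an extreme-value bias (~0.25 Å at 0.1 Å
per-component noise), which is a property of the statistic, not a search
error; the profiler regression therefore jitters wall rings rigidly, and
search correctness is established separately against the exhaustive grid
reference on clean and random channels.

## Problem sizes

Default analysis sizes were chosen so the full test suite and the
acceptance script each complete in minutes on one core: profiles average
≤ 100 frames over 61 planes; oracle comparisons use 20 random channels of
≤ 200 atoms at 3 planes each; the bundled translocation preset has 300
frames and ~1150 atoms. All sizes scale up through configuration.

## Pipeline and determinism

`run_pipeline` executes load → profile → classify → contacts → slices →
RMSD, writing TSV/JSON outputs, the serialized config, and a MANIFEST that
names the failing stage on error. Every numeric output is a pure function
of the config and seed; fixed-precision formatting makes reruns
byte-identical, which the acceptance checks assert. The ligand-RMSD stage
of the synthetic preset uses the final frame as its reference pose, since
no crystal reference exists for generated data.
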