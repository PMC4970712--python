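"""Funnel (pore) radius profiling by maximal-sphere search.

At each plane normal to the translocation axis, the profiler finds the
largest sphere, centered in that plane, that touches no atom: it
maximizes f(c) = min_i (‖c − x_i‖ − r_i) over in-plane centers c, where
x_i and r_i are atom positions and vdW radii.  The search is an annealed
random walk seeded from the previous plane's optimum (warm start), which
is the classic strategy for pore-radius programs; a brute-force in-plane
grid search is provided as an independent reference for validation.

Radii are clamped to [0, r_max]; a plane where the search escapes past
r_max (e.g. through a gap to bulk solvent) is flagged ``capped``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axis import AxisFrame, build_axis
from .models import ConfigError, EmptyInputError, Trajectory

__all__ = [
    "SearchParams",
    "PlaneResult",
    "FunnelProfile",
    "ClearanceField",
    "max_sphere_at_plane",
    "grid_max_sphere_at_plane",
    "funnel_profile",
]


@dataclass(frozen=True)
class SearchParams:
    """Knobs of the stochastic in-plane search.

    ``n_iter`` proposals are spent per plane in ``n_stages`` batches whose
    Gaussian step size anneals geometrically from ``step_hi`` to
    ``step_lo`` (Å); the walker moves to the best proposal of a batch
    only when it improves.  Deterministic given ``seed``.
    """

    n_iter: int = 2000
    step_hi: float = 1.0
    step_lo: float = 0.01
    r_max: float = 12.0
    n_stages: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.n_stages < 1:
            raise ConfigError("n_iter and n_stages must be positive")
        if self.step_hi <= 0 or self.step_lo <= 0 or self.step_lo > self.step_hi:
            raise ConfigError("need 0 < step_lo <= step_hi")
        if self.r_max <= 0:
            raise ConfigError("r_max must be positive")


@dataclass
class PlaneResult:
    """Maximal-sphere result at one plane."""

    z: float
    radius: float
    center: np.ndarray
    capped: bool
    n_evals: int

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


@dataclass
class FunnelProfile:
    """Per-z mean radius ± standard error over trajectory frames."""

    z_grid: np.ndarray
    mean_radius: np.ndarray
    se_radius: np.ndarray
    per_frame: np.ndarray  # (n_frames, n_z)
    capped_fraction: np.ndarray
    params: SearchParams = field(default_factory=SearchParams)

    @property
    def n_frames(self) -> int:
        return self.per_frame.shape[0]

    def min_radius_in(self, z_lo: float, z_hi: float) -> float:
        mask = (self.z_grid >= z_lo) & (self.z_grid <= z_hi)
        if not mask.any():
            raise ConfigError(f"region [{z_lo}, {z_hi}] outside profile z-grid")
        return float(np.min(self.mean_radius[mask]))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "z": self.z_grid,
                "mean_radius": self.mean_radius,
                "se_radius": self.se_radius,
                "capped_fraction": self.capped_fraction,
            }
        )

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_json(self, path: str, extra: dict | None = None) -> None:
        import json

        payload = {
            "z": [round(float(v), 6) for v in self.z_grid],
            "mean_radius": [round(float(v), 6) for v in self.mean_radius],
            "se_radius": [round(float(v), 6) for v in self.se_radius],
            "capped_fraction": [round(float(v), 6) for v in self.capped_fraction],
            "n_frames": int(self.n_frames),
            "params": {
                "n_iter": self.params.n_iter,
                "step_hi": self.params.step_hi,
                "step_lo": self.params.step_lo,
                "r_max": self.params.r_max,
                "seed": self.params.seed,
            },
        }
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


class ClearanceField:
    """Fast evaluator of f(p) = min_i(‖p − x_i‖ − r_i) over all atoms.

    Atoms are grouped by radius value and queried through one KD-tree per
    class, which keeps the stochastic search cheap on large walls.
    """

    def __init__(self, positions: np.ndarray, radii: np.ndarray) -> None:
        from scipy.spatial import cKDTree

        positions = np.asarray(positions, dtype=float)
        radii = np.asarray(radii, dtype=float)
        if positions.shape[0] == 0:
            raise EmptyInputError("no atoms for pore profiling")
        self._classes = []
        for r in np.unique(np.round(radii, 9)):
            mask = np.round(radii, 9) == r
            self._classes.append((float(r), cKDTree(positions[mask])))

    def min_clearance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(points.shape[0], np.inf)
        for r, tree in self._classes:
            d, _ = tree.query(points)
            np.minimum(out, d - r, out=out)
        return out


def _lateral_bound(
    positions: np.ndarray, axis: AxisFrame, z: float, window: float = 1.5
) -> float:
    """Radius of the wall's local in-plane footprint at the plane z.

    Only atoms within ``window`` Å (about a van der Waals diameter) of
    the plane define the footprint: a center beyond the wall material
    near the plane sits outside the pore, not inside it.  When no atoms
    are that close, the global footprint is used.  Both the stochastic
    search and the grid reference share this domain.
    """
    positions = np.asarray(positions, dtype=float)
    lat = np.linalg.norm(axis.plane_coords(positions), axis=1)
    near = np.abs(axis.z(positions) - z) <= window
    return float(lat[near].max() if near.any() else lat.max())


def _plane_atoms(
    positions: np.ndarray,
    radii: np.ndarray,
    axis: AxisFrame,
    z: float,
    r_max: float,
):
    """Project atoms that can constrain the sphere below r_max into the plane."""
    zs = axis.z(positions)
    dz = zs - z
    keep = (np.abs(dz) - radii) < r_max
    if not np.any(keep):
        return None
    xy = axis.plane_coords(positions[keep])
    return xy, dz[keep], radii[keep]


def _clearance(c2d: np.ndarray, xy: np.ndarray, dz: np.ndarray, radii: np.ndarray):
    """f(c) = min_i(dist − r_i) for a batch of in-plane centers (k, 2)."""
    d_lat2 = ((c2d[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    dist = np.sqrt(d_lat2 + dz[None, :] ** 2)
    return (dist - radii[None, :]).min(axis=1)


def max_sphere_at_plane(
    positions: np.ndarray,
    radii: np.ndarray,
    axis: AxisFrame,
    z: float,
    params: SearchParams | None = None,
    start: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    field: ClearanceField | None = None,
) -> PlaneResult:
    """Annealed random search for the maximal sphere centered in the plane at z.

    ``start`` is a 2-vector of in-plane coordinates (warm start from the
    neighboring plane); default is the axis point.  A prebuilt
    ``ClearanceField`` may be passed to amortize tree construction over
    the planes of one frame.  Identical seeds and inputs give identical
    results.
    """
    params = params or SearchParams()
    if field is None:
        field = ClearanceField(positions, radii)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    e1, e2 = axis.plane_basis()
    p0 = axis.point_at(z)
    # the search domain is the wall's lateral footprint: centers beyond the
    # outermost atom ring would "find" unbounded clearance around a finite wall
    bound = _lateral_bound(positions, axis, z)

    def world(c2d: np.ndarray) -> np.ndarray:
        return p0 + np.outer(c2d[:, 0], e1) + np.outer(c2d[:, 1], e2)

    best_c = np.zeros(2) if start is None else np.asarray(start, dtype=float).copy()
    if np.linalg.norm(best_c) > bound:
        best_c = np.zeros(2)
    best_f = float(field.min_clearance(world(best_c[None, :]))[0])
    n_evals = 1

    per_stage = max(1, params.n_iter // params.n_stages)
    steps = np.geomspace(params.step_hi, params.step_lo, params.n_stages)
    for si, step in enumerate(steps):
        if si == 0:
            # global stage: uniform over the search disk, so off-axis
            # optima (side pockets, eccentric pores) are not missed
            u = rng.uniform(0.0, 1.0, size=per_stage)
            th = rng.uniform(0.0, 2 * np.pi, size=per_stage)
            proposals = bound * np.sqrt(u)[:, None] * np.stack(
                [np.cos(th), np.sin(th)], axis=1
            )
        else:
            proposals = best_c + step * rng.normal(size=(per_stage, 2))
        ok = np.linalg.norm(proposals, axis=1) <= bound
        if not ok.any():
            continue
        proposals = proposals[ok]
        f_vals = field.min_clearance(world(proposals))
        n_evals += proposals.shape[0]
        k = int(np.argmax(f_vals))
        if f_vals[k] > best_f:
            best_f = float(f_vals[k])
            best_c = proposals[k]
        if best_f >= params.r_max:
            break

    capped = best_f >= params.r_max
    radius = float(np.clip(best_f, 0.0, params.r_max))
    center = p0 + best_c[0] * e1 + best_c[1] * e2
    return PlaneResult(z=z, radius=radius, center=center, capped=capped, n_evals=n_evals)


def grid_max_sphere_at_plane(
    positions: np.ndarray,
    radii: np.ndarray,
    axis: AxisFrame,
    z: float,
    r_max: float = 12.0,
    resolution: float = 0.02,
    half_width: float | None = None,
) -> PlaneResult:
    """Exhaustive in-plane grid search; the brute-force reference profiler.

    Evaluates the clearance on a square grid of spacing ``resolution``
    centered on the axis.  Independent of the stochastic search path; its
    cost grows quadratically with ``half_width``/``resolution``.
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if positions.shape[0] == 0:
        raise EmptyInputError("no atoms for pore profiling")
    filtered = _plane_atoms(positions, radii, axis, z, r_max)
    p0 = axis.point_at(z)
    if filtered is None:
        return PlaneResult(z=z, radius=r_max, center=p0, capped=True, n_evals=0)
    xy, dz, r = filtered
    if half_width is None:
        half_width = _lateral_bound(positions, axis, z)
    ticks = np.arange(-half_width, half_width + resolution / 2, resolution)
    best_f, best_c = -np.inf, np.zeros(2)
    n_evals = 0
    for x in ticks:  # row-wise to bound memory
        ok = ticks ** 2 + x ** 2 <= half_width ** 2
        if not ok.any():
            continue
        row = np.stack([np.full(ok.sum(), x), ticks[ok]], axis=1)
        f_vals = _clearance(row, xy, dz, r)
        n_evals += row.shape[0]
        k = int(np.argmax(f_vals))
        if f_vals[k] > best_f:
            best_f = float(f_vals[k])
            best_c = row[k]
    e1, e2 = axis.plane_basis()
    capped = best_f >= r_max
    radius = float(np.clip(best_f, 0.0, r_max))
    center = p0 + best_c[0] * e1 + best_c[1] * e2
    return PlaneResult(z=z, radius=radius, center=center, capped=capped, n_evals=n_evals)


def funnel_profile(
    traj: Trajectory,
    axis: AxisFrame | None = None,
    z_min: float = -15.0,
    z_max: float = 15.0,
    dz: float = 0.5,
    frames: str | list | None = "last:0.1ns",
    params: SearchParams | None = None,
    axis_mode: str = "fixed",
    exclude: str | None = "ligand",
) -> FunnelProfile:
    """Funnel-radius profile averaged over trajectory frames.

    The radius is computed on a z-grid from ``z_min`` to ``z_max`` with
    spacing ``dz`` for each selected frame (default: the frames of the
    last 0.1 ns, or the last 100 frames when times are uninformative),
    then averaged; the standard error is the across-frame standard
    deviation divided by √n_frames.  Within a frame the plane searches
    are chained as warm starts.

    ``axis_mode``: "fixed" profiles every frame in the supplied
    AxisFrame; "inertia" recomputes the inertia axis per frame.
    ``exclude`` drops the ligand (or nothing, if None) from the wall atoms.
    """
    if z_min >= z_max:
        raise ConfigError("z_min must be smaller than z_max")
    params = params or SearchParams()
    if frames == "last:0.1ns" and not traj.has_times:
        frames = f"last:{min(traj.n_frames, 100)}"
    frame_idx = traj.select_frames(frames)
    if not frame_idx:
        raise EmptyInputError("frame selection is empty")

    model = traj.model
    radii = model.radii
    keep = np.ones(model.n_atoms, dtype=bool)
    if exclude == "ligand" and model.ligand_selection:
        keep[model.selection_indices("ligand")] = False
    keep &= radii > 0
    if not keep.any():
        raise EmptyInputError("no atoms with positive radii to profile")

    z_grid = np.arange(z_min, z_max + dz / 2, dz)
    per_frame = np.empty((len(frame_idx), len(z_grid)))
    capped = np.zeros((len(frame_idx), len(z_grid)), dtype=bool)

    for fi, frame_no in enumerate(frame_idx):
        coords = traj.frames[frame_no]
        if axis_mode == "inertia":
            frame_axis = build_axis(coords[keep], mode="inertia")
        elif axis_mode == "fixed":
            if axis is None:
                raise ConfigError("axis_mode='fixed' requires an AxisFrame")
            frame_axis = axis
        else:
            raise ConfigError(f"unknown axis_mode {axis_mode!r}")
        start = None
        frame_field = ClearanceField(coords[keep], radii[keep])
        for zi, z in enumerate(z_grid):
            rng = np.random.default_rng([params.seed, frame_no, zi])
            res = max_sphere_at_plane(
                coords[keep], radii[keep], frame_axis, float(z),
                params=params, start=start, rng=rng, field=frame_field,
            )
            per_frame[fi, zi] = res.radius
            capped[fi, zi] = res.capped
            start = frame_axis.plane_coords(res.center)

    mean = per_frame.mean(axis=0)
    n = per_frame.shape[0]
    se = per_frame.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return FunnelProfile(
        z_grid=z_grid,
        mean_radius=mean,
        se_radius=se,
        per_frame=per_frame,
        capped_fraction=capped.mean(axis=0),
        params=params,
    )
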