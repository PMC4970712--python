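"""Translocation-axis frames.

The transporter funnel is profiled along a 1-D coordinate z.  The axis is
either the principal inertia axis of the protein (the long axis of a
membrane-spanning transporter, normal to the membrane plane) or a fixed
laboratory axis re-originated between two anchor selections — the
convention in which the substrate binding site sits between the Cα atoms
of two gating tryptophans and spans roughly z = −5..+5 Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ConfigError, StructureModel

__all__ = ["AxisFrame", "build_axis"]


@dataclass(frozen=True)
class AxisFrame:
    """An origin and a unit axis defining z(p) = (p − origin)·axis."""

    origin: np.ndarray
    axis: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            raise ConfigError("axis vector has zero length")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axis", axis / norm)

    def z(self, points: np.ndarray) -> np.ndarray | float:
        points = np.asarray(points, dtype=float)
        return (points - self.origin) @ self.axis

    def point_at(self, z: float) -> np.ndarray:
        return self.origin + z * self.axis

    def plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """A deterministic orthonormal basis of the plane normal to the axis."""
        u = self.axis
        seed = np.zeros(3)
        seed[int(np.argmin(np.abs(u)))] = 1.0
        e1 = seed - (seed @ u) * u
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        return e1, e2

    def plane_coords(self, points: np.ndarray) -> np.ndarray:
        e1, e2 = self.plane_basis()
        d = np.asarray(points, dtype=float) - self.origin
        return np.stack([d @ e1, d @ e2], axis=-1)


def _principal_axis(points: np.ndarray, moment: str) -> np.ndarray:
    centered = points - points.mean(axis=0)
    # Inertia tensor of unit masses; eigenvectors sorted by moment.
    x2 = (centered ** 2).sum(axis=1)
    inertia = np.eye(3) * x2.sum() - centered.T @ centered
    evals, evecs = np.linalg.eigh(inertia)
    if moment == "smallest":
        return evecs[:, 0]
    if moment == "largest":
        return evecs[:, 2]
    raise ConfigError(f"moment must be 'smallest' or 'largest', got {moment!r}")


def build_axis(
    model: StructureModel | np.ndarray,
    mode: str = "inertia",
    anchors: tuple | None = None,
    positions: np.ndarray | None = None,
    moment: str = "smallest",
    fixed_axis: np.ndarray | None = None,
    sign_selection: np.ndarray | None = None,
) -> AxisFrame:
    """Construct the translocation AxisFrame.

    mode="inertia": axis is a principal axis of the coordinate inertia
    tensor (default: smallest moment, i.e. the long axis of an elongated
    channel), origin at the centroid.  mode="anchors": origin is the
    midpoint of the two anchor-selection centroids; the axis is
    ``fixed_axis`` if given, else the inertia axis re-originated.

    The axis sign is chosen so that ``sign_selection`` (atom indices; else
    the first anchor selection; else laboratory +z) points to positive z.
    """
    if isinstance(model, StructureModel):
        pos = model.positions if positions is None else np.asarray(positions, dtype=float)
    else:
        pos = np.asarray(model, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ConfigError("positions must be an (n, 3) array")

    if mode == "inertia":
        if pos.shape[0] < 3:
            raise ConfigError("inertia axis needs at least 3 atoms")
        line = _principal_axis(pos, "smallest")
        spread = pos - pos.mean(axis=0)
        resid = spread - np.outer(spread @ line, line)
        if np.allclose(resid, 0.0, atol=1e-9):
            raise ConfigError("collinear atoms give a degenerate inertia axis")
        axis = _principal_axis(pos, moment)
        origin = pos.mean(axis=0)
    elif mode == "anchors":
        if anchors is None or len(anchors) != 2:
            raise ConfigError("anchors mode needs two atom-index selections")
        sel_a = np.asarray(anchors[0], dtype=int)
        sel_b = np.asarray(anchors[1], dtype=int)
        if sel_a.size == 0 or sel_b.size == 0:
            raise ConfigError("anchor selections must be nonempty")
        cen_a = pos[sel_a].mean(axis=0)
        cen_b = pos[sel_b].mean(axis=0)
        origin = 0.5 * (cen_a + cen_b)
        if fixed_axis is not None:
            axis = np.asarray(fixed_axis, dtype=float)
            axis = axis / np.linalg.norm(axis)
        else:
            axis = _principal_axis(pos, moment)
        if sign_selection is None:
            sign_selection = sel_a
    else:
        raise ConfigError(f"unknown axis mode {mode!r}")

    frame = AxisFrame(origin=origin, axis=axis)
    if sign_selection is not None:
        ref = pos[np.asarray(sign_selection, dtype=int)].mean(axis=0)
        if frame.z(ref) < 0:
            frame = AxisFrame(origin=origin, axis=-frame.axis)
    elif frame.axis @ np.array([0.0, 0.0, 1.0]) < 0:
        frame = AxisFrame(origin=origin, axis=-frame.axis)
    return frame
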