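"""Water-accessible channel profiling: maximal inscribed sphere per slice.

The channel is scanned along its axis (default +z, the membrane normal). At
each axial sample the largest sphere centred in that plane that avoids every
heavy atom's van der Waals surface is found by multi-start local
optimization of the clearance function

    f(c) = min_a ( |c - a| - r_vdw(a) )

over in-plane centres ``c``, seeded from the previous slice's optimum plus
jittered starts. Twice the minimum radius over the profile is the minimal
channel diameter, the quantity that distinguishes functionally open from
closed states; a region-restricted minimum (e.g. over the extracellular
z-interval) is reported alongside. Hydrogens are ignored (hard-sphere
model); radii are clamped at ``r_max`` and slices whose optimum escapes the
structure are flagged unbounded and excluded from minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import (
    AnalysisParameters,
    ConnexinAnnotation,
    GJDockError,
    Structure,
    Trajectory,
)


@dataclass
class PoreProfile:
    """Radius-vs-axial-position profile of one frame."""

    axis: np.ndarray
    z: np.ndarray
    radius: np.ndarray
    center_xy: np.ndarray  # (n, 2) in-plane optimum per sample
    unbounded: np.ndarray  # bool per sample
    frame_index: int = 0
    window: tuple[float, float] | None = None

    @property
    def min_radius_overall(self) -> float:
        ok = ~self.unbounded
        return float(self.radius[ok].min()) if ok.any() else float("nan")

    @property
    def min_diameter_overall(self) -> float:
        return 2.0 * self.min_radius_overall

    @property
    def min_diameter_in_window(self) -> float:
        if self.window is None:
            return float("nan")
        lo, hi = self.window
        ok = ~self.unbounded & (self.z >= lo) & (self.z <= hi)
        return 2.0 * float(self.radius[ok].min()) if ok.any() else float("nan")

    @property
    def z_at_min(self) -> float:
        ok = ~self.unbounded
        if not ok.any():
            return float("nan")
        zs = self.z[ok]
        return float(zs[np.argmin(self.radius[ok])])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "z": self.z,
            "radius": self.radius,
            "center_x": self.center_xy[:, 0],
            "center_y": self.center_xy[:, 1],
            "unbounded": self.unbounded,
        })


def _axis_rotation(axis: Sequence[float]) -> np.ndarray:
    """Rotation matrix mapping ``axis`` onto +z."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    s = np.linalg.norm(v)
    c = float(a @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def pore_profile(
    frame: Structure,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    z_range: tuple[float, float] | None = None,
    step: float = 0.5,
    seed: int = 0,
    params: AnalysisParameters | None = None,
    r_max: float = 15.0,
    window: tuple[float, float] | None = None,
    n_jitter_starts: int = 8,
    frame_index: int = 0,
) -> PoreProfile:
    """Inscribed-sphere radius profile of one frame along the channel axis.

    ``z_range`` defaults to the heavy-atom z extent; sampling is every
    ``step`` Å. The optimization is deterministic for a fixed ``seed``.
    """
    if step <= 0:
        raise GJDockError("step must be > 0")
    if len(frame) == 0:
        raise GJDockError("empty structure")
    params = params or AnalysisParameters()
    heavy = frame.heavy_mask
    coords = frame.coords[heavy]
    if len(coords) == 0:
        raise GJDockError("structure has no heavy atoms")
    rot = _axis_rotation(axis)
    if not np.allclose(rot, np.eye(3)):
        coords = coords @ rot.T
    radii = params.vdw_radii_for(frame.elements[heavy])
    max_vdw = float(radii.max())
    if z_range is None:
        z_range = (float(coords[:, 2].min()), float(coords[:, 2].max()))
    lo, hi = z_range
    if hi < lo:
        raise GJDockError(f"invalid z_range {z_range}")
    zs = np.arange(lo, hi + step / 2, step)
    rng = np.random.default_rng(seed)

    out_r = np.zeros(len(zs))
    out_c = np.zeros((len(zs), 2))
    out_unbounded = np.zeros(len(zs), dtype=bool)
    prev_center: np.ndarray | None = None
    slab_reach = r_max + max_vdw
    for k, z in enumerate(zs):
        near = np.abs(coords[:, 2] - z) <= slab_reach
        if not near.any():
            out_r[k] = r_max
            out_c[k] = prev_center if prev_center is not None else (0.0, 0.0)
            out_unbounded[k] = True
            continue
        pts = coords[near]
        rad = radii[near]

        def clearance(c2: np.ndarray) -> float:
            d = np.sqrt((pts[:, 0] - c2[0])**2 + (pts[:, 1] - c2[1])**2
                        + (pts[:, 2] - z)**2)
            return float(np.min(d - rad))

        base = prev_center if prev_center is not None else pts[:, :2].mean(axis=0)
        starts = [np.asarray(base, dtype=float)]
        starts += [base + rng.normal(scale=1.0, size=2)
                   for _ in range(n_jitter_starts)]
        best_r, best_c = -np.inf, starts[0]
        for s0 in starts:
            res = minimize(lambda c: -clearance(c), s0, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6,
                                    "maxiter": 400})
            if -res.fun > best_r:
                best_r, best_c = -res.fun, res.x
        r = max(best_r, 0.0)
        if r >= r_max:
            r = r_max
            out_unbounded[k] = True
        out_r[k] = r
        out_c[k] = best_c
        prev_center = best_c
    return PoreProfile(
        axis=np.asarray(axis, dtype=float),
        z=zs,
        radius=out_r,
        center_xy=out_c,
        unbounded=out_unbounded,
        frame_index=frame_index,
        window=window,
    )


def extracellular_window(
    frame: Structure,
    annotation: ConnexinAnnotation | None = None,
) -> tuple[float, float]:
    """z-interval spanned by the EL1/EL2 residues of a frame."""
    annotation = annotation or ConnexinAnnotation()
    mask = annotation.extracellular_mask(frame.res_nums) & frame.heavy_mask
    if not mask.any():
        raise GJDockError("no extracellular residues present for window")
    z = frame.coords[mask, 2]
    return float(z.min()), float(z.max())


def min_diameter_series(
    trajectory: Trajectory,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    z_range: tuple[float, float] | None = None,
    window: tuple[float, float] | str | None = None,
    step: float = 0.5,
    seed: int = 0,
    params: AnalysisParameters | None = None,
    r_max: float = 15.0,
    annotation: ConnexinAnnotation | None = None,
) -> tuple[pd.DataFrame, list[PoreProfile]]:
    """Per-frame overall and window-restricted minimal channel diameters.

    ``window`` may be an explicit z-interval, the string ``"extracellular"``
    (recomputed per frame from the EL1/EL2 residue extent), or ``None``.

    Returns a table (frame, time_ps, min_diam_A, min_diam_window_A,
    z_at_min) and the per-frame profiles.
    """
    rows = []
    profiles = []
    for fi in range(trajectory.n_frames):
        frame = trajectory.frame(fi)
        win: tuple[float, float] | None
        if window == "extracellular":
            win = extracellular_window(frame, annotation)
        else:
            win = window  # type: ignore[assignment]
        prof = pore_profile(frame, axis=axis, z_range=z_range, step=step,
                            seed=seed + fi, params=params, r_max=r_max,
                            window=win, frame_index=fi)
        profiles.append(prof)
        rows.append({
            "frame": fi,
            "time_ps": fi * trajectory.frame_interval_ps,
            "min_diam_A": prof.min_diameter_overall,
            "min_diam_window_A": prof.min_diameter_in_window,
            "z_at_min": prof.z_at_min,
        })
    return pd.DataFrame(rows), profiles
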