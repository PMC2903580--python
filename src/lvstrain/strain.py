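"""Green-Lagrange strain computation, RCL transform and post-filtering.

Strain is reported in the local Radial / Circumferential / Longitudinal
(RCL) frame of the left ventricle. The frame is built from the long-axis
model on the reference (end-diastolic) positions and is reused for all
time frames, so temporal strain curves always refer to the same material
directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LongAxisModel",
    "RCLFrame",
    "StrainField",
    "green_lagrange",
    "e33_correction",
    "rcl_frame",
    "rcl_frames_at",
    "transform_to_rcl",
    "transform_to_rcl_batch",
    "strain_outlier_filter",
    "strain_postsmooth",
    "regional_peaks",
    "RCL_INDEX",
]

#: mapping from RCL component name to (row, col) of the strain tensor in
#: the (r, c, l) basis
RCL_INDEX = {
    "E_RR": (0, 0),
    "E_CC": (1, 1),
    "E_LL": (2, 2),
    "E_RC": (0, 1),
    "E_RL": (0, 2),
    "E_LC": (1, 2),
}


@dataclass(frozen=True)
class LongAxisModel:
    """Long axis of the LV from apex to base."""

    apex: np.ndarray
    base: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "apex", np.asarray(self.apex, dtype=float))
        object.__setattr__(self, "base", np.asarray(self.base, dtype=float))
        if np.allclose(self.apex, self.base):
            raise ValueError("apex and base must differ")

    @property
    def direction(self) -> np.ndarray:
        d = self.base - self.apex
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.base - self.apex))

    def axial_fraction(self, points: np.ndarray) -> np.ndarray:
        """Fractional position along the axis, 0 at apex, 1 at base."""
        rel = np.asarray(points, dtype=float) - self.apex
        return (rel @ self.direction) / self.length

    def perpendicular(self, points: np.ndarray) -> np.ndarray:
        """Component of (point - apex) perpendicular to the axis."""
        rel = np.atleast_2d(np.asarray(points, dtype=float) - self.apex)
        along = (rel @ self.direction)[:, None] * self.direction
        perp = rel - along
        return perp.reshape(np.shape(points))


@dataclass(frozen=True)
class RCLFrame:
    """Orthonormal radial/circumferential/longitudinal triad at a point."""

    r_hat: np.ndarray
    c_hat: np.ndarray
    l_hat: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        """Basis matrix Q with columns (r_hat, c_hat, l_hat)."""
        return np.stack([self.r_hat, self.c_hat, self.l_hat], axis=-1)


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = (F^T F - I) / 2 (batched over leading axes)."""
    F = np.asarray(F, dtype=float)
    return 0.5 * (np.einsum("...ki,...kj->...ij", F, F) - np.eye(3))


def e33_correction(F: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Out-of-plane normal strain from in-plane principal stretches.

    The in-plane 2x2 blocks of the frame-aligned ``F`` and ``G`` give the
    in-plane principal stretches (square roots of the eigenvalues of the
    2x2 right Cauchy-Green tensor; their product equals ``|det F_2x2|``).
    Incompressibility fixes the out-of-plane stretch as the reciprocal
    product for the forward map and the direct product for the inverse
    map; the corrected strain is the average of the two estimates

        E33 = 1/2 [ (lam3F^2 - 1)/2 + (lam3G^2 - 1)/2 ],
        lam3F = 1/(lam1F lam2F),  lam3G = lam1G lam2G.

    Returns NaN where an in-plane block is singular (voided point).
    """
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    detF2 = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    detG2 = G[..., 0, 0] * G[..., 1, 1] - G[..., 0, 1] * G[..., 1, 0]
    lam12_F = np.abs(detF2)  # lam1F * lam2F
    lam12_G = np.abs(detG2)
    with np.errstate(divide="ignore"):
        lam3F_sq = 1.0 / lam12_F**2
    lam3G_sq = lam12_G**2
    e33 = 0.5 * (0.5 * (lam3F_sq - 1.0) + 0.5 * (lam3G_sq - 1.0))
    return np.where(lam12_F > 0, e33, np.nan)


def rcl_frame(
    point: np.ndarray,
    long_axis: LongAxisModel,
    wall_normal_hint: np.ndarray | None = None,
) -> RCLFrame:
    """RCL triad at one reference point.

    ``l_hat`` is the long-axis direction; ``r_hat`` the unit in-plane
    component of the vector from the axis to the point (replaced by the
    projected ``wall_normal_hint`` when supplied, sign-aligned with the
    geometric radial); ``c_hat = l_hat x r_hat``.
    """
    Q = rcl_frames_at(np.asarray(point, float)[None, :], long_axis,
                      wall_normal_hint=wall_normal_hint)[0]
    return RCLFrame(r_hat=Q[:, 0], c_hat=Q[:, 1], l_hat=Q[:, 2])


def rcl_frames_at(
    points: np.ndarray,
    long_axis: LongAxisModel,
    wall_normal_hint: np.ndarray | None = None,
    axis_tol: float = 1e-9,
) -> np.ndarray:
    """Batched RCL basis matrices, shape (P, 3, 3), columns (r, c, l)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    l_hat = long_axis.direction
    perp = long_axis.perpendicular(pts)
    d = np.linalg.norm(perp, axis=-1)
    if np.any(d <= axis_tol):
        raise ValueError("RCL frame ill-defined for points on the long axis")
    r_hat = perp / d[:, None]
    if wall_normal_hint is not None:
        hint = np.asarray(wall_normal_hint, dtype=float)
        hint = hint - (hint @ l_hat) * l_hat
        hn = np.linalg.norm(hint)
        if hn > axis_tol:
            hint = hint / hn
            sign = np.sign(r_hat @ hint)
            sign[sign == 0] = 1.0
            r_hat = sign[:, None] * hint
    c_hat = np.cross(np.broadcast_to(l_hat, r_hat.shape), r_hat)
    return np.stack([r_hat, c_hat, np.broadcast_to(l_hat, r_hat.shape)], axis=-1)


def transform_to_rcl(E_cart: np.ndarray, frame: RCLFrame | np.ndarray) -> np.ndarray:
    """Congruence transform of a strain tensor into the RCL basis."""
    Q = frame.matrix if isinstance(frame, RCLFrame) else np.asarray(frame, float)
    return Q.T @ np.asarray(E_cart, dtype=float) @ Q


def transform_to_rcl_batch(E_cart: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Batched congruence transform, E_rcl = Q^T E Q per point."""
    return np.einsum("...ki,...kl,...lj->...ij", Q, E_cart, Q)


@dataclass
class StrainField:
    """Per-pixel Green-Lagrange strain on one slice at one time frame.

    ``E_cart``/``E_rcl`` are (nr, nc, 3, 3) grids, NaN outside the mask.
    ``component_void`` is a per-component void mask keyed by RCL name.
    """

    E_cart: np.ndarray
    E_rcl: np.ndarray
    mask: np.ndarray
    spacing: float
    t_ms: float
    ref_positions: np.ndarray | None = None
    component_void: dict[str, np.ndarray] = dc_field(default_factory=dict)
    quality: dict[str, np.ndarray] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.component_void:
            self.component_void = {
                name: np.zeros(self.mask.shape, dtype=bool) for name in RCL_INDEX
            }

    @property
    def voided(self) -> np.ndarray:
        """Points with at least one voided component."""
        out = np.zeros(self.mask.shape, dtype=bool)
        for v in self.component_void.values():
            out |= v
        return out

    def component(self, name: str) -> np.ndarray:
        i, j = RCL_INDEX[name]
        return self.E_rcl[..., i, j]

    def masked_component(self, name: str, exclude_void: bool = True) -> np.ndarray:
        vals = self.component(name)
        keep = self.mask & ~(self.component_void[name] if exclude_void else False)
        return vals[keep]

    def copy(self) -> "StrainField":
        return StrainField(
            E_cart=self.E_cart.copy(),
            E_rcl=self.E_rcl.copy(),
            mask=self.mask.copy(),
            spacing=self.spacing,
            t_ms=self.t_ms,
            ref_positions=None if self.ref_positions is None else self.ref_positions.copy(),
            component_void={k: v.copy() for k, v in self.component_void.items()},
            quality={k: v.copy() for k, v in self.quality.items()},
        )


def strain_outlier_filter(
    field: StrainField,
    sd_mult: float = 2.0,
    abs_cap: float = 1.0,
    min_points: int = 10,
) -> StrainField:
    """Void non-physiological and outlying strain values per component.

    Values with ``|E| > abs_cap`` are eliminated first; the mean and SD of
    each component over the remaining masked points then void values more
    than ``sd_mult`` standard deviations from the mean. Statistics are
    slice-wide, per component, per time frame.
    """
    n_valid = int(field.mask.sum())
    if n_valid < min_points:
        raise ValueError(f"need at least {min_points} valid points, got {n_valid}")
    out = field.copy()
    any_left = False
    for name, (i, j) in RCL_INDEX.items():
        vals = out.E_rcl[..., i, j]
        void = out.component_void[name].copy()
        cap = field.mask & ~void & (np.abs(np.nan_to_num(vals, nan=np.inf)) > abs_cap)
        void |= cap
        keep = field.mask & ~void & np.isfinite(vals)
        if keep.sum() >= 2:
            mu, sd = float(np.mean(vals[keep])), float(np.std(vals[keep]))
            if sd > 0:
                void |= keep & (np.abs(vals - mu) > sd_mult * sd)
        out.component_void[name] = void
        if (field.mask & ~void).any():
            any_left = True
    if not any_left:
        raise ValueError("all points voided by the outlier filter")
    return out


def _plus_median(vals: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Five-pixel plus-shaped median restricted to valid pixels.

    Pixels with fewer than 3 valid members in the plus neighborhood pass
    through unchanged.
    """
    nr, nc = vals.shape
    padded = np.full((nr + 2, nc + 2), np.nan)
    padded[1:-1, 1:-1] = np.where(valid, vals, np.nan)
    stack = np.stack(
        [
            padded[1:-1, 1:-1],
            padded[:-2, 1:-1],
            padded[2:, 1:-1],
            padded[1:-1, :-2],
            padded[1:-1, 2:],
        ]
    )
    counts = np.sum(np.isfinite(stack), axis=0)
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stack, axis=0)
    out = vals.copy()
    apply = valid & (counts >= 3)
    out[apply] = med[apply]
    return out


def _window_mean(vals: np.ndarray, valid: np.ndarray, half: int) -> np.ndarray:
    """Mask-aware moving average over a (2*half+1)^2 window."""
    filled = np.where(valid, vals, 0.0)
    w = np.ones((2 * half + 1, 2 * half + 1))
    from scipy.signal import convolve2d

    num = convolve2d(filled, w, mode="same")
    den = convolve2d(valid.astype(float), w, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def strain_postsmooth(field: StrainField, window_cm: float = 1.0) -> StrainField:
    """Median + moving-average post-filter of the RCL strain maps.

    Each component is passed through the five-pixel plus median and then a
    mask-aware moving average over a square window covering ``window_cm``
    (rounded to the nearest odd pixel count). The average also fills voided
    points from valid neighbors; voids with no valid neighbor in the window
    remain NaN and are flagged.
    """
    out = field.copy()
    # smallest odd pixel count covering the window
    half = max(1, int(np.ceil((10.0 * window_cm / field.spacing - 1) / 2)))
    unfilled = np.zeros(field.mask.shape, dtype=bool)
    for name, (i, j) in RCL_INDEX.items():
        vals = out.E_rcl[..., i, j]
        valid = field.mask & ~out.component_void[name] & np.isfinite(vals)
        med = _plus_median(vals, valid)
        avg = _window_mean(med, valid, half)
        newvals = np.where(field.mask, avg, np.nan)
        out.E_rcl[..., i, j] = newvals
        out.E_rcl[..., j, i] = newvals
        filled = field.mask & np.isfinite(newvals)
        out.component_void[name] = field.mask & ~filled
        unfilled |= field.mask & ~filled
    out.quality["unfilled_void"] = unfilled
    return out


def regional_peaks(
    fields: Sequence[StrainField],
    long_axis: LongAxisModel,
    wall_labels: np.ndarray,
    levels: dict[str, float] | None = None,
    band_halfwidth: float = 0.10,
    window_ms: tuple[float, float] = (330.0, 450.0),
    components: Sequence[str] = tuple(RCL_INDEX),
) -> pd.DataFrame:
    """Peak regional-mean strains in the systolic window.

    Regions are the product of longitudinal levels (default apical /
    equatorial / basal at 30 / 55 / 80 % of the apex-to-base distance)
    with the wall labels (e.g. "septal" / "lateral"). The peak of a
    regional mean is the value of largest magnitude attained within
    ``window_ms``.
    """
    if levels is None:
        levels = {"apical": 0.30, "equatorial": 0.55, "basal": 0.80}
    wall_labels = np.asarray(wall_labels)
    rows = []
    times = np.array([f.t_ms for f in fields])
    in_window = (times >= window_ms[0]) & (times <= window_ms[1])
    if not in_window.any():
        raise ValueError("no time frames inside the peak window")
    ref = fields[0].ref_positions
    if ref is None:
        raise ValueError("strain fields need ref_positions for regional averaging")
    frac = long_axis.axial_fraction(ref.reshape(-1, 3)).reshape(ref.shape[:2])
    for wall in np.unique(wall_labels[wall_labels != ""]):
        for level_name, level_frac in levels.items():
            region = (
                fields[0].mask
                & (wall_labels == wall)
                & (np.abs(frac - level_frac) <= band_halfwidth)
            )
            if not region.any():
                raise ValueError(f"empty region {wall}/{level_name}")
            for comp in components:
                means = []
                for f in fields:
                    vals = f.component(comp)
                    keep = region & ~f.component_void[comp] & np.isfinite(vals)
                    means.append(np.mean(vals[keep]) if keep.any() else np.nan)
                means = np.asarray(means)
                sel = np.where(in_window & np.isfinite(means))[0]
                if sel.size == 0:
                    peak_val, peak_t = np.nan, np.nan
                else:
                    k = sel[np.argmax(np.abs(means[sel]))]
                    peak_val, peak_t = means[k], times[k]
                rows.append(
                    {
                        "wall": str(wall),
                        "level": level_name,
                        "component": comp,
                        "peak": peak_val,
                        "peak_time_ms": peak_t,
                    }
                )
    return pd.DataFrame(rows)
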