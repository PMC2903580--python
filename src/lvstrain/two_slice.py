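"""Conventional two-slice deformation-gradient estimation and agreement.

With two parallel slices the reference points span all three dimensions,
so the full F follows from one unconstrained least squares per point --
no incompressibility, no inverse-map combination. This is the reference
method the single-slice estimator is compared against; its known biases
(chord-vs-arc underestimation across the wall curvature) are left
uncorrected, as properties of the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .defgrad import DefGradField, _neighbor_indices, neighborhood_size
from .fields import DisplacementField
from .strain import LongAxisModel

__all__ = ["SlicePair", "two_slice_defgrad", "estimate_two_slice", "bland_altman"]


@dataclass
class SlicePair:
    """Two parallel displacement slices with identical in-plane grids."""

    slice_a: DisplacementField
    slice_b: DisplacementField
    separation: float  # center-to-center distance, mm

    def __post_init__(self) -> None:
        na, nb = self.slice_a.slice_normal, self.slice_b.slice_normal
        angle = np.arccos(np.clip(np.abs(na @ nb), -1, 1))
        if angle > 1e-6:
            raise ValueError("slice normals are not parallel")
        if self.slice_a.grid_shape != self.slice_b.grid_shape:
            raise ValueError("slices must share the in-plane grid")


def two_slice_defgrad(
    pair: SlicePair,
    center_idx: tuple[int, int],
    area_mm2: float,
    t_index: int = 0,
    min_points_per_slice: int = 5,
) -> np.ndarray:
    """Unconstrained least-squares F at one point from both slices.

    The neighborhood is the same in-plane square area on each slice; the
    center lies on ``slice_a``. Raises if either slice contributes no
    points (the system would be singular through-plane).
    """
    from .defgrad import collect_neighborhood

    nb_a = collect_neighborhood(pair.slice_a, center_idx, area_mm2, t_index,
                                min_points=min_points_per_slice)
    nb_b = collect_neighborhood(pair.slice_b, center_idx, area_mm2, t_index,
                                min_points=min_points_per_slice)
    center = nb_a.center
    center_u = pair.slice_a.displacements[t_index][center_idx]
    # re-express slice_b pairs relative to the slice_a center
    Xb = nb_b.dX + nb_b.center
    xb = nb_b.dx + nb_b.center + pair.slice_b.displacements[t_index][center_idx]
    dX = np.vstack([nb_a.dX, Xb - center])
    dx = np.vstack([nb_a.dx, xb - (center + center_u)])
    if len(nb_a.dX) == 0 or len(nb_b.dX) == 0:
        raise ValueError("neighborhood must span both slices")
    M = dX.T @ dX
    if np.linalg.matrix_rank(M) < 3:
        raise np.linalg.LinAlgError("one-slice-only neighborhood: singular system")
    return np.linalg.solve(M, dX.T @ dx).T


def estimate_two_slice(
    pair: SlicePair,
    t_index: int = 0,
    area_mm2: float = 25.0,
    long_axis: LongAxisModel | None = None,
    min_points: int = 10,
) -> DefGradField:
    """Vectorized two-slice F at every masked point of ``slice_a``.

    Frames follow the same convention as the single-slice estimator so
    that the two tensor fields are directly comparable.
    """
    fa, fb = pair.slice_a, pair.slice_b
    n_pts = neighborhood_size(area_mm2, fa.spacing)
    ca, na_idx, ok_a = _neighbor_indices(fa.mask, n_pts, min_points)
    # slice_b neighborhoods looked up around the same in-plane indices
    mask_b = fb.mask
    keep = ok_a & mask_b[ca[:, 0], ca[:, 1]]
    cb, nb_idx, ok_b = _neighbor_indices(mask_b, n_pts, min_points)
    okb_grid = np.zeros(mask_b.shape, dtype=bool)
    okb_grid[cb[ok_b, 0], cb[ok_b, 1]] = True
    keep &= okb_grid[ca[:, 0], ca[:, 1]]
    centers = ca[keep]
    neigh_a = na_idx[keep]
    lut = -np.ones(mask_b.shape, dtype=int)
    lut[cb[:, 0], cb[:, 1]] = np.arange(len(cb))
    neigh_b = nb_idx[lut[centers[:, 0], centers[:, 1]]]
    P = len(centers)
    if P == 0:
        raise ValueError("no points usable on both slices")

    X = fa.ref_positions[centers[:, 0], centers[:, 1]]
    U = fa.displacements[t_index][centers[:, 0], centers[:, 1]]

    def pairs(field, neigh):
        Xn = field.ref_positions[neigh[..., 0], neigh[..., 1]]
        Un = field.displacements[t_index][neigh[..., 0], neigh[..., 1]]
        dX = Xn - X[:, None]
        dx = dX + (Un - U[:, None])
        return dX, dx

    dXa, dxa = pairs(fa, neigh_a)
    dXb, dxb = pairs(fb, neigh_b)
    dX = np.concatenate([dXa, dXb], axis=1)
    dx = np.concatenate([dxa, dxb], axis=1)

    # frame: same convention as the single-slice estimator (slice normal
    # as third axis, radial hint as first)
    n_vec = np.broadcast_to(fa.slice_normal, (P, 3)).copy()
    if long_axis is not None:
        hint = long_axis.perpendicular(X)
    else:
        hint = np.broadcast_to(np.array([1.0, 0.0, 0.0]), (P, 3)).copy()
    e1 = hint - np.einsum("pi,pi->p", hint, n_vec)[:, None] * n_vec
    norm = np.linalg.norm(e1, axis=-1, keepdims=True)
    e1 = np.where(norm > 1e-12, e1 / np.maximum(norm, 1e-30), [1.0, 0.0, 0.0])
    e2 = np.cross(n_vec, e1)
    B = np.stack([e1, e2, n_vec], axis=-1)

    dX_f = np.einsum("pni,pij->pnj", dX, B)
    dx_f = np.einsum("pni,pij->pnj", dx, B)
    M = np.einsum("pni,pnj->pij", dX_f, dX_f)
    b = np.einsum("pni,pnj->pij", dx_f, dX_f)
    F = np.swapaxes(np.linalg.solve(M, np.swapaxes(b, -1, -2)), -1, -2)

    return DefGradField(
        indices=centers,
        positions=X,
        F=F,
        G=np.linalg.inv(F),
        frames=B,
        grid_shape=fa.mask.shape,
        flags={"voided": np.zeros(P, dtype=bool),
               "incompressibility_applied": np.zeros(P, dtype=bool)},
        metadata={"method": "two_slice", "area_mm2": area_mm2,
                  "separation_mm": pair.separation,
                  "t_ms": float(fa.times[t_index])},
    )


def bland_altman(map_a: np.ndarray, map_b: np.ndarray) -> dict[str, float]:
    """Bland-Altman agreement statistics for two co-registered scalar maps.

    NaNs in either map are excluded; at least 10 common points required.
    """
    a = np.asarray(map_a, float).ravel()
    b = np.asarray(map_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have the same shape")
    common = np.isfinite(a) & np.isfinite(b)
    if common.sum() < 10:
        raise ValueError("fewer than 10 common points between the maps")
    diff = a[common] - b[common]
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    return {
        "n": int(common.sum()),
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "lower_limit": mean_diff - 1.96 * sd_diff,
        "upper_limit": mean_diff + 1.96 * sd_diff,
        "rms_diff": float(np.sqrt(np.mean(diff**2))),
    }
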