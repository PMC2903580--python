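"""Deformation-gradient estimation from a single slice of 3D displacement.

A slice of 3D Lagrangian displacement constrains the in-plane columns of
the deformation gradient F well, but the out-of-plane (third) column is
nearly singular: the reference points have essentially no spread along the
slice normal. The estimator therefore

1. solves a local least-squares problem for F (reference -> deformed) and
   for its inverse-map counterpart G (deformed -> reference) in a local
   frame whose third axis is the surface normal, so the singularity is
   confined to the third column of F;
2. pre-estimates the torsional couplings F13/F23 from the out-of-plane
   motion (long-axis slices, where the out-of-plane direction is nearly
   circumferential and LV rotation is nearly independent of azimuth);
3. recovers F33 from the in-plane block of G via incompressibility
   (det G = 1 makes F33 the in-plane adjugate of G);
4. optionally replaces F13/F23 using the orthogonality of the columns of
   F to the rows of G, keeping whichever candidate yields the smaller
   |E13| + |E23| (out-of-plane errors are biased upward, so the smaller
   shear-strain sum is the better-conditioned estimate);
5. enforces det F = 1 by rescaling the third column.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import DisplacementField
from .strain import LongAxisModel

__all__ = [
    "NeighborhoodPairs",
    "LocalFrame",
    "DefGradField",
    "neighborhood_size",
    "collect_neighborhood",
    "local_frame",
    "ls_estimate",
    "torsion_preestimate",
    "f33_from_g",
    "f13_f23_from_orthogonality",
    "enforce_incompressibility",
    "select_third_column",
    "estimate_single_slice",
]

DEFAULT_MIN_POINTS = 10
DEFAULT_DAMPING = 1e-12
#: eigenvalue fraction of the trace below which a scatter direction of a
#: neighborhood is considered uninformative (single-slice singularity)
NULL_REL_TOL = 1e-2


@dataclass
class NeighborhoodPairs:
    """Reference/deformed distance-vector pairs around one center point."""

    center: np.ndarray  # (3,) reference position
    dX: np.ndarray  # (N, 3) reference distance vectors
    dx: np.ndarray  # (N, 3) deformed distance vectors
    area_mm2: float
    indices: np.ndarray | None = None  # (N, 2) grid indices

    @property
    def n_points(self) -> int:
        return len(self.dX)


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal frame with in-plane e1, e2 and normal n."""

    e1: np.ndarray
    e2: np.ndarray
    n: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        """Basis matrix B with columns (e1, e2, n)."""
        return np.stack([self.e1, self.e2, self.n], axis=-1)


@dataclass
class DefGradField:
    """Estimated F and G tensors at the masked points of one slice.

    Tensors are expressed in the per-point local frame whose basis matrix
    (columns e1, e2, n) is stored in ``frames``.
    """

    indices: np.ndarray  # (P, 2) grid indices of processed points
    positions: np.ndarray  # (P, 3) reference positions
    F: np.ndarray  # (P, 3, 3)
    G: np.ndarray  # (P, 3, 3)
    frames: np.ndarray  # (P, 3, 3)
    grid_shape: tuple[int, int]
    flags: dict[str, np.ndarray] = dc_field(default_factory=dict)
    metadata: dict = dc_field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.indices)

    def grid_map(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter per-point values back onto the image grid."""
        out = np.full(self.grid_shape + values.shape[1:], fill, dtype=float)
        out[self.indices[:, 0], self.indices[:, 1]] = values
        return out


# ---------------------------------------------------------------------------
# neighborhoods


def neighborhood_size(area_mm2: float, spacing: float) -> int:
    """Number of grid points representing the requested smoothing area."""
    return max(1, int(round(area_mm2 / spacing**2)))


def _sorted_offsets(n_needed: int) -> np.ndarray:
    """Grid offsets sorted by (distance^2, di, dj), enough for n_needed."""
    r = int(np.ceil(4 * np.sqrt(n_needed))) + 2
    di, dj = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = di**2 + dj**2
    order = np.lexsort((dj.ravel(), di.ravel(), d2.ravel()))
    return np.stack([di.ravel()[order], dj.ravel()[order]], axis=1)


def _neighbor_indices(
    mask: np.ndarray, n_points: int, min_points: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """N-nearest in-mask neighbor lookup for every masked point.

    Returns (centers (P,2), neighbors (P,N,2), ok (P,) bool). Points whose
    neighborhood cannot reach ``min_points`` are marked not-ok.
    """
    offsets = _sorted_offsets(n_points)
    nr, nc = mask.shape
    centers = np.argwhere(mask)
    neigh = np.zeros((len(centers), n_points, 2), dtype=int)
    ok = np.zeros(len(centers), dtype=bool)
    for p, (i, j) in enumerate(centers):
        found = 0
        for di, dj in offsets:
            ii, jj = i + di, j + dj
            if 0 <= ii < nr and 0 <= jj < nc and mask[ii, jj]:
                neigh[p, found] = (ii, jj)
                found += 1
                if found == n_points:
                    break
        if found >= min_points:
            ok[p] = True
            if found < n_points:  # degrade gracefully: repeat the center
                neigh[p, found:] = (i, j)
    return centers, neigh, ok


def collect_neighborhood(
    field: DisplacementField,
    center_idx: tuple[int, int],
    area_mm2: float,
    t_index: int = 0,
    min_points: int = DEFAULT_MIN_POINTS,
) -> NeighborhoodPairs:
    """Distance-vector pairs over the smoothing area around one point.

    The neighborhood is the N nearest in-mask grid points (center
    included), N = round(area / spacing^2), so the point count represents
    the requested smoothing area exactly on a full grid (25 points for
    25 mm^2 at 1 mm spacing).
    """
    i, j = center_idx
    if not field.mask[i, j]:
        raise ValueError(f"center {center_idx} is outside the mask")
    n_points = neighborhood_size(area_mm2, field.spacing)
    offsets = _sorted_offsets(n_points)
    nr, nc = field.mask.shape
    sel = []
    for di, dj in offsets:
        ii, jj = i + di, j + dj
        if 0 <= ii < nr and 0 <= jj < nc and field.mask[ii, jj]:
            sel.append((ii, jj))
            if len(sel) == n_points:
                break
    if len(sel) < min_points:
        raise ValueError(
            f"only {len(sel)} in-mask points near {center_idx}; "
            f"need at least {min_points}"
        )
    sel = np.asarray(sel)
    X = field.ref_positions[sel[:, 0], sel[:, 1]]
    U = field.displacements[t_index][sel[:, 0], sel[:, 1]]
    Xc = field.ref_positions[i, j]
    Uc = field.displacements[t_index][i, j]
    dX = X - Xc
    dx = dX + (U - Uc)
    return NeighborhoodPairs(
        center=Xc, dX=dX, dx=dx, area_mm2=area_mm2, indices=sel
    )


# ---------------------------------------------------------------------------
# local frame


def local_frame(
    nb: NeighborhoodPairs,
    slice_normal: np.ndarray,
    inplane_hint: np.ndarray | None = None,
) -> LocalFrame:
    """Surface-aligned frame: n = direction of least scatter of the
    reference positions, sign-aligned with the slice normal."""
    M = nb.dX.T @ nb.dX
    w, V = np.linalg.eigh(M)
    if w[1] <= 1e-10 * max(np.trace(M), 1e-30):
        raise ValueError("degenerate neighborhood: reference points collinear")
    n = V[:, 0]
    if n @ np.asarray(slice_normal, float) < 0:
        n = -n
    if inplane_hint is not None:
        h = np.asarray(inplane_hint, float)
        h = h - (h @ n) * n
        hn = np.linalg.norm(h)
        e1 = h / hn if hn > 1e-12 else V[:, 2]
    else:
        e1 = V[:, 2]
    e1 = e1 - (e1 @ n) * n
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return LocalFrame(e1=e1, e2=e2, n=n)


# ---------------------------------------------------------------------------
# least squares


def _damped_rowwise_ls(
    M: np.ndarray,
    b: np.ndarray,
    prior: np.ndarray,
    damping: float,
    null_rel_tol: float = NULL_REL_TOL,
) -> np.ndarray:
    """Row-wise least squares with the singular axis taken from the prior.

    ``M`` is the (..., 3, 3) normal matrix of the distance vectors and
    ``b`` the (..., 3, 3) right-hand sides (rows indexed by output
    component). A single-slice neighborhood leaves ``M`` (near-)rank-2:
    for the forward fit the reference points are coplanar, and for the
    inverse fit the deformed points still lie on one smooth surface, so
    along the smallest-scatter eigendirection the apparent signal is
    only surface bowing, which a linear fit converts into large
    systematic errors. Eigendirections whose eigenvalue falls below
    ``null_rel_tol`` times the trace are therefore treated as carrying
    no information: the solution component along them is taken from
    ``prior``, while the informative components are the exact
    least-squares solution (Tikhonov floor ``damping`` times the trace).
    Full-rank systems (e.g. pairs spanning two slices) are untouched.
    """
    pinv, proj_null = _spectral_ops(M, damping, null_rel_tol)
    T = np.einsum("...ik,...kj->...ij", b, pinv)
    T += np.einsum("...ik,...kj->...ij", prior, proj_null)
    return T


def _spectral_ops(
    M: np.ndarray,
    damping: float,
    null_rel_tol: float,
    force_null_smallest: bool = False,
):
    """(pseudo-inverse, null-space projector) of a normal matrix.

    Eigendirections with eigenvalue below ``null_rel_tol`` times the
    trace are treated as uninformative: the pseudo-inverse ignores them
    and the projector routes them to the prior.
    ``force_null_smallest`` additionally marks the smallest
    eigendirection unconditionally -- the single-slice estimator uses
    this because its through-surface direction is singular by
    construction, and displacement noise must not masquerade as
    through-surface signal.
    """
    tr = np.trace(M, axis1=-2, axis2=-1)
    w, V = np.linalg.eigh(M)
    null = w < np.maximum(null_rel_tol * tr, 1e-300)[..., None]
    if force_null_smallest:
        null = null.copy()
        null[..., 0] = True
    with np.errstate(divide="ignore"):
        inv_w = np.where(null, 0.0, 1.0 / np.maximum(w, damping * tr[..., None]))
    pinv = np.einsum("...ik,...k,...jk->...ij", V, inv_w, V)
    proj_null = np.einsum("...ik,...k,...jk->...ij", V, null.astype(float), V)
    return pinv, proj_null


def ls_estimate(
    nb: NeighborhoodPairs,
    frame: LocalFrame,
    direction: str = "forward",
    prior: np.ndarray | None = None,
    damping: float = DEFAULT_DAMPING,
) -> np.ndarray:
    """Least-squares tensor over one neighborhood, in the local frame.

    ``forward`` minimizes sum ||dx - F dX||^2; ``inverse`` swaps the roles
    of dX and dx and yields G. The normal equations carry a Tikhonov term
    of relative weight ``damping`` on the out-of-plane column, which
    resolves the documented single-slice singularity by falling back to
    ``prior`` (identity by default) exactly where the data carry no
    information.
    """
    B = frame.matrix
    a = nb.dX @ B
    b_vecs = nb.dx @ B
    if direction == "inverse":
        a, b_vecs = b_vecs, a
    elif direction != "forward":
        raise ValueError("direction must be 'forward' or 'inverse'")
    M = a.T @ a
    rhs = b_vecs.T @ a
    if prior is None:
        prior = np.eye(3)
    return _damped_rowwise_ls(M, rhs, np.asarray(prior, float), damping)


# ---------------------------------------------------------------------------
# torsion pre-estimation


def torsion_preestimate(
    field: DisplacementField,
    long_axis: LongAxisModel,
    center_idx: tuple[int, int],
    t_index: int,
    frame: LocalFrame,
    nb: NeighborhoodPairs | None = None,
    min_axis_distance_px: float = 2.0,
) -> tuple[float, float]:
    """Torsional couplings (F13, F23) from the out-of-plane motion.

    The rotation signal is the out-of-plane displacement smoothed over
    the neighborhood as the mean of the per-neighbor ratios
    (out-of-plane displacement) / (perpendicular distance to the long
    axis). For a rotation by the local torsion angle beta this ratio
    equals sin(beta) exactly (a point at distance d moves d sin(beta)
    out of plane while keeping its distance), so the couplings are
    ``-(u_out/d)`` = ``-sin(beta)`` times the projection of the
    in-plane radial unit vector on (e1, e2). Points closer than
    ``min_axis_distance_px`` pixels to the axis return (nan, nan).
    """
    i, j = center_idx
    Xc = field.ref_positions[i, j]
    perp = long_axis.perpendicular(Xc)
    d = float(np.linalg.norm(perp))
    d_min = min_axis_distance_px * field.spacing
    if d < d_min:
        return (float("nan"), float("nan"))
    v = perp / d
    if nb is not None and nb.indices is not None:
        Xn = field.ref_positions[nb.indices[:, 0], nb.indices[:, 1]]
        Un = field.displacements[t_index][nb.indices[:, 0], nb.indices[:, 1]]
        perp_n = long_axis.perpendicular(Xn)
        dn = np.linalg.norm(perp_n, axis=-1)
        # same-side neighbors only: the rotation flips sign across the axis
        keep = (dn >= d_min) & (perp_n @ v > 0)
        sin_beta = float(np.mean((Un[keep] @ frame.n) / dn[keep]))
    else:
        sin_beta = float(field.displacements[t_index][i, j] @ frame.n) / d
    s = -sin_beta
    return (s * float(v @ frame.e1), s * float(v @ frame.e2))


# ---------------------------------------------------------------------------
# incompressibility-based third-column recovery


def f33_from_g(G: np.ndarray) -> float | np.ndarray:
    """F33 from the in-plane block of G under det(G) = 1.

    With det(G) = 1, the (3,3) entry of G^-1 is the in-plane adjugate
    G11 G22 - G12 G21, which uses only well-conditioned elements of G.
    """
    G = np.asarray(G, float)
    out = G[..., 0, 0] * G[..., 1, 1] - G[..., 0, 1] * G[..., 1, 0]
    return float(out) if out.ndim == 0 else out


def f13_f23_from_orthogonality(G: np.ndarray, F33: float | np.ndarray):
    """(F13, F23) from rows 1-2 of G F = I applied to the third column.

    Solves [[G11, G12], [G21, G22]] [F13, F23]^T = -F33 [G13, G23]^T.
    Raises for a singular in-plane block (scalar input); batched input
    returns NaN there.
    """
    G = np.asarray(G, float)
    F33 = np.asarray(F33, float)
    det2 = G[..., 0, 0] * G[..., 1, 1] - G[..., 0, 1] * G[..., 1, 0]
    e = -F33 * G[..., 0, 2]
    f = -F33 * G[..., 1, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        f13 = (G[..., 1, 1] * e - G[..., 0, 1] * f) / det2
        f23 = (G[..., 0, 0] * f - G[..., 1, 0] * e) / det2
    if np.ndim(det2) == 0:
        if det2 == 0:
            raise ValueError("singular in-plane block of G")
        return (float(f13), float(f23))
    bad = det2 == 0
    f13 = np.where(bad, np.nan, f13)
    f23 = np.where(bad, np.nan, f23)
    return f13, f23


def enforce_incompressibility(F: np.ndarray) -> np.ndarray:
    """Rescale the third column so det(F) = 1; in-plane columns untouched.

    The single-slice singularity lives in the third column of the
    frame-aligned F, so volume preservation is imposed there only.
    Raises for non-positive determinants (scalar input).
    """
    F = np.array(F, dtype=float, copy=True)
    det = np.linalg.det(F)
    if F.ndim == 2:
        if det <= 0:
            raise ValueError(f"non-physical deformation: det(F) = {det:.3g}")
        F[:, 2] /= det
        return F
    bad = det <= 0
    safe = np.where(bad, 1.0, det)
    F[..., :, 2] /= safe[..., None]
    F[bad] = np.nan
    return F


def _shear_strain_sum(col1: np.ndarray, col2: np.ndarray, col3: np.ndarray):
    """|E13| + |E23| for a tensor with the given columns."""
    e13 = 0.5 * np.einsum("...i,...i->...", col1, col3)
    e23 = 0.5 * np.einsum("...i,...i->...", col2, col3)
    return np.abs(e13) + np.abs(e23)


def select_third_column(
    F: np.ndarray, G: np.ndarray, f33: float | np.ndarray | None = None
):
    """Choose the F-based or G-based third column of F.

    The G-based candidate replaces (F13, F23) by the orthogonality
    solution; it is adopted only when its |E13| + |E23| is strictly
    smaller than that of the F-based candidate (ties keep F, since
    out-of-plane errors are biased toward larger absolute values).

    Returns (F_final, source) with source "F" or "G" (arrays for batched
    input).
    """
    F = np.array(F, dtype=float, copy=True)
    G = np.asarray(G, float)
    if f33 is None:
        f33 = f33_from_g(G)
    f33 = np.asarray(f33, float)
    scalar = F.ndim == 2
    Fb = F[None] if scalar else F
    Gb = G[None] if scalar else G
    f33b = np.atleast_1d(f33)

    col1, col2 = Fb[..., :, 0], Fb[..., :, 1]
    colF = Fb[..., :, 2].copy()
    colF[..., 2] = f33b
    f13g, f23g = f13_f23_from_orthogonality(Gb, f33b)
    colG = np.stack([f13g, f23g, f33b], axis=-1)
    # a singular in-plane block keeps the prior (F-based) estimates
    colG = np.where(np.isfinite(colG), colG, colF)

    sF = _shear_strain_sum(col1, col2, colF)
    sG = _shear_strain_sum(col1, col2, colG)
    use_g = sG < sF
    out = Fb.copy()
    out[..., :, 2] = np.where(use_g[..., None], colG, colF)
    if scalar:
        return out[0], ("G" if bool(use_g[0]) else "F")
    return out, np.where(use_g, "G", "F")


# ---------------------------------------------------------------------------
# full single-slice pipeline (vectorized)


def estimate_single_slice(
    field: DisplacementField,
    t_index: int = 0,
    area_mm2: float = 25.0,
    long_axis: LongAxisModel | None = None,
    use_torsion: bool = True,
    min_points: int = DEFAULT_MIN_POINTS,
    damping: float = DEFAULT_DAMPING,
    enforce_det: bool = True,
    max_refine: int = 20,
    refine_tol: float = 1e-13,
    neighborhoods: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> DefGradField:
    """Estimate F and G at every masked point of a single slice.

    Vectorized equivalent of applying :func:`collect_neighborhood`,
    :func:`local_frame`, :func:`ls_estimate`, :func:`torsion_preestimate`,
    :func:`f33_from_g`, :func:`select_third_column` and
    :func:`enforce_incompressibility` point by point.

    ``neighborhoods`` may carry a precomputed ``(centers, neigh, ok)``
    triple (from repeated runs on the same mask) to skip the lookup.
    """
    n_points = neighborhood_size(area_mm2, field.spacing)
    if neighborhoods is None:
        neighborhoods = _neighbor_indices(field.mask, n_points, min_points)
    centers, neigh, ok = neighborhoods
    centers, neigh = centers[ok], neigh[ok]
    P, N = neigh.shape[:2]
    if P == 0:
        raise ValueError("no usable points: mask too small for the area")

    X = field.ref_positions[centers[:, 0], centers[:, 1]]
    U = field.displacements[t_index][centers[:, 0], centers[:, 1]]
    Xn = field.ref_positions[neigh[..., 0], neigh[..., 1]]
    Un = field.displacements[t_index][neigh[..., 0], neigh[..., 1]]
    dX = Xn - X[:, None]
    dx = dX + (Un - U[:, None])

    # local frames: least-scatter direction of the reference neighborhoods
    M0 = np.einsum("pni,pnj->pij", dX, dX)
    w, V = np.linalg.eigh(M0)
    n_vec = V[..., 0]
    flip = (n_vec @ field.slice_normal) < 0
    n_vec[flip] *= -1
    if long_axis is not None:
        hint = long_axis.perpendicular(X)
        hint_norm = np.linalg.norm(hint, axis=-1, keepdims=True)
        hint = np.where(hint_norm > 1e-12, hint / np.maximum(hint_norm, 1e-30), V[..., 2])
    else:
        hint = V[..., 2]
    e1 = hint - np.einsum("pi,pi->p", hint, n_vec)[:, None] * n_vec
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    e2 = np.cross(n_vec, e1)
    B = np.stack([e1, e2, n_vec], axis=-1)  # (P, 3, 3), columns of the frame

    dX_f = np.einsum("pni,pij->pnj", dX, B)
    dx_f = np.einsum("pni,pij->pnj", dx, B)

    # torsion pre-estimates (long-axis slices)
    pre13 = np.zeros(P)
    pre23 = np.zeros(P)
    near_axis = np.zeros(P, dtype=bool)
    if use_torsion and long_axis is not None:
        perp = long_axis.perpendicular(X)
        d = np.linalg.norm(perp, axis=-1)
        d_min = 2.0 * field.spacing
        near_axis = d < d_min
        d_safe = np.maximum(d, 1e-30)
        v = perp / d_safe[:, None]
        perp_n = long_axis.perpendicular(Xn.reshape(-1, 3)).reshape(P, N, 3)
        dn = np.linalg.norm(perp_n, axis=-1)
        keep = (dn >= d_min) & (np.einsum("pni,pi->pn", perp_n, v) > 0)
        u_out_ratio = np.einsum("pni,pi->pn", Un, n_vec) / np.maximum(dn, 1e-30)
        cnt = np.maximum(keep.sum(axis=1), 1)
        sin_beta = np.where(
            near_axis, 0.0, np.sum(u_out_ratio * keep, axis=1) / cnt
        )
        s = -sin_beta
        pre13 = s * np.einsum("pi,pi->p", v, e1)
        pre23 = s * np.einsum("pi,pi->p", v, e2)
        pre13[near_axis] = 0.0
        pre23[near_axis] = 0.0

    prior_F = np.broadcast_to(np.eye(3), (P, 3, 3)).copy()
    prior_F[:, 0, 2] = pre13
    prior_F[:, 1, 2] = pre23

    MF = np.einsum("pni,pnj->pij", dX_f, dX_f)
    bF = np.einsum("pni,pnj->pij", dx_f, dX_f)
    pinvF, projF = _spectral_ops(MF, damping, NULL_REL_TOL,
                                 force_null_smallest=True)
    F0 = np.einsum("pik,pkj->pij", bF, pinvF) + np.einsum(
        "pik,pkj->pij", prior_F, projF
    )

    # the inverse-map fit falls back, along its own singular direction, to
    # the inverse of the current forward estimate; alternating the two
    # fits with the incompressibility/orthogonality recovery of the third
    # column converges to a self-consistent (F, G) pair
    MG = np.einsum("pni,pnj->pij", dx_f, dx_f)
    bG = np.einsum("pni,pnj->pij", dX_f, dx_f)
    pinvG, projG = _spectral_ops(MG, damping, NULL_REL_TOL,
                                 force_null_smallest=True)
    bG_pinv = np.einsum("pik,pkj->pij", bG, pinvG)

    eye = np.eye(3)
    voided = np.zeros(P, dtype=bool)
    F_final = F0
    G = None
    source = np.full(P, "F", dtype=object)
    for _ in range(max_refine if enforce_det else 1):
        detF = np.linalg.det(F_final)
        okF = detF > 1e-12
        prior_G = np.linalg.inv(np.where(okF[:, None, None], F_final, eye))
        G = bG_pinv + np.einsum("pik,pkj->pij", prior_G, projG)
        if enforce_det:
            detG = np.linalg.det(G)
            voided = voided | (detG <= 0)
            G = enforce_incompressibility(
                np.where(voided[:, None, None], eye, G)
            )
        G_safe = np.where(voided[:, None, None], eye, G)
        f33 = f33_from_g(G_safe)
        F_new, source = select_third_column(F0, G_safe, f33)
        if enforce_det:
            bad = ~(np.linalg.det(F_new) > 0)
            voided = voided | bad
            F_new = enforce_incompressibility(
                np.where(bad[:, None, None], eye, F_new)
            )
        delta = np.nanmax(np.abs(F_new - F_final)) if enforce_det else 0.0
        F_final = F_new
        if delta < refine_tol:
            break
    F_final = np.where(voided[:, None, None], np.nan, F_final)
    G = np.where(voided[:, None, None], np.nan, G)

    return DefGradField(
        indices=centers,
        positions=X,
        F=F_final,
        G=G,
        frames=B,
        grid_shape=field.mask.shape,
        flags={
            "third_column_source": np.asarray(source),
            "incompressibility_applied": np.full(P, enforce_det),
            "near_axis": near_axis,
            "voided": voided,
        },
        metadata={
            "area_mm2": area_mm2,
            "n_neighbors": N,
            "t_ms": float(field.times[t_index]),
            "damping": damping,
        },
    )
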