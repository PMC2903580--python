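"""Analytical incompressible left-ventricle motion phantom.

The phantom emulates a contracting, twisting LV wall (apex excluded) in a
cylindrical frame whose ``Z`` axis is the long axis of the ventricle. The
total deformation is the composition of an in-plane (radial/longitudinal)
contraction and an axial rotation,

    F_total = F_rotation . F_inplane,

and the in-plane map is itself a composition of three exactly
area-preserving maps of the (R^2, Z) half-plane, so that
``det F_total = 1`` holds to machine precision everywhere, for every
parameter choice:

1. a longitudinal shear ``Z -> Z + g(R)`` with
   ``g(R) = 2 f(t) [gamma (R - L/5) + (delta/k) sin k(R - L/5)]`` --
   the linear part mimics the longitudinal descent of the base, the
   oscillatory part imprints fast transmural changes on dz/dR so that the
   radial-longitudinal shear varies on a sub-neighborhood scale;
2. a conical rescale ``(R^2, Z) -> (R^2/h, h Z)`` with
   ``h(t) = 1 - s_L f(t)/f_max`` (longitudinal shortening, s_L = 0.2);
3. a radial squeeze ``R^2 -> R^2 + c(t)`` with
   ``c(t) = -c_0 f(t)/f_max`` (transmurally graded circumferential
   contraction, strongest at the endocardium).

The axial rotation angle is linear in ``Z`` and independent of the radius,
``beta(Z, t) = theta (1 - Z/L) tau(t)``, reaching the full base-to-apex
twist ``theta`` at peak torsion. Torsion leads contraction by ``t0``:
``tau(t) = sin^2(pi (t + t0)/T)`` while ``f(t) = f_max sin^2(pi t/T)``.
Because ``beta`` does not depend on ``R``, the analytic
radial-circumferential shear strain E_RC is identically zero.

The wall geometry tapers linearly: the epicardial radius is ``R0`` at the
base (Z = L) and ``R0/2`` at the apical cap (Z = 0); wall thickness is
``R0/4`` everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np

from .fields import DisplacementField

__all__ = [
    "PhantomSpec",
    "AnalyticPhantom",
    "geometry_profile",
    "build_phantom",
    "sample_slice",
    "long_axis_plane",
    "add_noise",
    "analytic_strain_summary",
]

#: strain component order used in summaries
RCL_COMPONENTS = ("E_RR", "E_CC", "E_LL", "E_RL", "E_LC", "E_RC")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the analytical LV motion phantom.

    All lengths in mm, times in ms, angles in degrees.
    """

    r0: float = 30.0  # epicardial radius at the base (Z = L)
    l_len: float = 60.0  # simulated LV length
    wall_thickness: float | None = None  # default r0 / 4
    f_max: float = 0.4  # peak contraction level
    twist_deg: float = 15.0  # base-to-apex rotation at peak torsion
    t0_ms: float = 100.0  # torsion lead time
    period_ms: float = 780.0  # period of the contraction waveform
    grid_spacing: float = 1.0  # sampling step for slices
    time_points: tuple[float, ...] = (390.0,)
    seed: int = 0
    # shape parameters of the in-plane map (see module docstring)
    long_shortening: float = 0.2  # longitudinal shortening at peak
    squeeze_mm2: float = 35.0  # radial squeeze c0, mm^2
    shear_slope: float = 0.31  # gamma
    shear_wobble: float = 0.56  # delta
    shear_wavenumber: float = 0.55  # k, rad/mm

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.l_len <= 0:
            raise ValueError("r0 and l_len must be positive")
        if not (0 <= self.f_max < 1):
            raise ValueError("f_max must lie in [0, 1)")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.thickness >= self.r0:
            raise ValueError("wall thickness must be smaller than r0")
        # the squeeze must keep the map real down to the apical endocardium
        r1_apex_sq = (self.r0 / 2.0 - self.thickness) ** 2
        if self.squeeze_mm2 >= r1_apex_sq:
            raise ValueError(
                "squeeze_mm2 too large: the apical endocardium would collapse"
            )

    @property
    def thickness(self) -> float:
        return self.r0 / 4.0 if self.wall_thickness is None else self.wall_thickness

    @property
    def twist_rad(self) -> float:
        return np.deg2rad(self.twist_deg)

    def contraction(self, t: float | np.ndarray) -> float | np.ndarray:
        """Contraction waveform f(t) = f_max sin^2(pi t / T)."""
        return self.f_max * np.sin(np.pi * np.asarray(t) / self.period_ms) ** 2

    def torsion_level(self, t: float | np.ndarray) -> float | np.ndarray:
        """Normalized torsion waveform tau(t) = sin^2(pi (t + t0)/T)."""
        return np.sin(np.pi * (np.asarray(t) + self.t0_ms) / self.period_ms) ** 2

    @property
    def peak_contraction_time(self) -> float:
        return self.period_ms / 2.0

    @property
    def peak_torsion_time(self) -> float:
        return self.period_ms / 2.0 - self.t0_ms


@dataclass
class AnalyticPhantom:
    """Closed-form displacement, deformation gradient and strain of the LV."""

    spec: PhantomSpec
    displacement_fn: Callable[[np.ndarray, float], np.ndarray] = dc_field(init=False)
    defgrad_fn: Callable[[np.ndarray, float], np.ndarray] = dc_field(init=False)
    strain_fn: Callable[[np.ndarray, float], np.ndarray] = dc_field(init=False)
    inside_fn: Callable[[np.ndarray], np.ndarray] = dc_field(init=False)

    def __post_init__(self) -> None:
        self.displacement_fn = lambda X, t: _displacement(self.spec, X, t)
        self.defgrad_fn = lambda X, t: _defgrad(self.spec, X, t)
        self.strain_fn = lambda X, t: _strain(self.spec, X, t)
        self.inside_fn = lambda X: _inside(self.spec, X)


def geometry_profile(spec: PhantomSpec, Z: float | np.ndarray):
    """Endocardial and epicardial radius (R1, R2) at height ``Z``.

    The epicardial radius tapers linearly from R0/2 at the apical cap
    (Z = 0) to R0 at the base (Z = L); the wall thickness is constant.
    """
    Z = np.asarray(Z, dtype=float)
    if np.any(Z < 0) or np.any(Z > spec.l_len):
        raise ValueError(f"Z outside the simulated domain [0, {spec.l_len}] mm")
    r2 = 0.5 * spec.r0 * (1.0 + Z / spec.l_len)
    r1 = r2 - spec.thickness
    return r1, r2


def build_phantom(spec: PhantomSpec) -> AnalyticPhantom:
    """Assemble the closed-form phantom for a validated spec."""
    return AnalyticPhantom(spec=spec)


# ---------------------------------------------------------------------------
# closed-form kinematics


def _inplane_params(spec: PhantomSpec, t: float):
    """Time-dependent parameters (f, h, c) of the in-plane map."""
    f = float(spec.contraction(t))
    level = f / spec.f_max if spec.f_max > 0 else 0.0
    h = 1.0 - spec.long_shortening * level
    c = -spec.squeeze_mm2 * level
    return f, h, c


def _shear(spec: PhantomSpec, R: np.ndarray, f: float):
    """Longitudinal shear profile g(R) and its derivative g'(R)."""
    x = R - spec.l_len / 5.0
    k = spec.shear_wavenumber
    g = 2.0 * f * (spec.shear_slope * x + spec.shear_wobble / k * np.sin(k * x))
    gp = 2.0 * f * (spec.shear_slope + spec.shear_wobble * np.cos(k * x))
    return g, gp


def _beta(spec: PhantomSpec, Z: np.ndarray, t: float):
    """Axial rotation angle beta(Z, t), rad, and its Z-derivative."""
    tau = float(spec.torsion_level(t))
    beta = spec.twist_rad * (1.0 - Z / spec.l_len) * tau
    beta_z = -spec.twist_rad * tau / spec.l_len
    return beta, beta_z


def _cyl(X: np.ndarray):
    X = np.asarray(X, dtype=float)
    R = np.hypot(X[..., 0], X[..., 1])
    phi = np.arctan2(X[..., 1], X[..., 0])
    return R, phi, X[..., 2]


def _deformed(spec: PhantomSpec, X: np.ndarray, t: float) -> np.ndarray:
    R, phi, Z = _cyl(X)
    f, h, c = _inplane_params(spec, t)
    g, _ = _shear(spec, R, f)
    with np.errstate(invalid="ignore"):
        rho = np.sqrt((R**2 + c) / h)
    zeta = h * (Z + g)
    beta, _ = _beta(spec, Z, t)
    ang = phi + beta
    out = np.empty(np.shape(R) + (3,))
    out[..., 0] = rho * np.cos(ang)
    out[..., 1] = rho * np.sin(ang)
    out[..., 2] = zeta
    return out


def _displacement(spec: PhantomSpec, X: np.ndarray, t: float) -> np.ndarray:
    return _deformed(spec, X, t) - np.asarray(X, dtype=float)


def _defgrad(spec: PhantomSpec, X: np.ndarray, t: float) -> np.ndarray:
    """Analytic deformation gradient in global Cartesian coordinates.

    Returns an array of shape ``X.shape[:-1] + (3, 3)``.
    """
    R, phi, Z = _cyl(X)
    f, h, c = _inplane_params(spec, t)
    _, gp = _shear(spec, R, f)
    beta, beta_z = _beta(spec, Z, t)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.sqrt((R**2 + c) / h)
        rho_r = R / (h * rho)  # d rho / d R
        rho_over_R = rho / R
    zeta_r = h * gp

    cP, sP = np.cos(phi), np.sin(phi)
    cb, sb = np.cos(phi + beta), np.sin(phi + beta)

    F = np.empty(np.shape(R) + (3, 3))
    F[..., 0, 0] = rho_r * cP * cb + rho_over_R * sb * sP
    F[..., 0, 1] = rho_r * sP * cb - rho_over_R * sb * cP
    F[..., 0, 2] = -rho * sb * beta_z
    F[..., 1, 0] = rho_r * cP * sb - rho_over_R * cb * sP
    F[..., 1, 1] = rho_r * sP * sb + rho_over_R * cb * cP
    F[..., 1, 2] = rho * cb * beta_z
    F[..., 2, 0] = zeta_r * cP
    F[..., 2, 1] = zeta_r * sP
    F[..., 2, 2] = h
    return F


def _strain(spec: PhantomSpec, X: np.ndarray, t: float) -> np.ndarray:
    F = _defgrad(spec, X, t)
    eye = np.eye(3)
    return 0.5 * (np.einsum("...ki,...kj->...ij", F, F) - eye)


def _inside(spec: PhantomSpec, X: np.ndarray) -> np.ndarray:
    """Myocardium membership; the apical cap Z = 0 is excluded (open cap)."""
    R, _, Z = _cyl(X)
    ok = (Z > 0) & (Z <= spec.l_len)
    r2 = 0.5 * spec.r0 * (1.0 + np.clip(Z, 0, spec.l_len) / spec.l_len)
    r1 = r2 - spec.thickness
    return ok & (R >= r1) & (R <= r2)


# ---------------------------------------------------------------------------
# sampling onto image slices


def long_axis_plane():
    """Origin and axes of the default long-axis plane (contains the axis)."""
    return np.zeros(3), (np.array([1.0, 0, 0]), np.array([0, 0, 1.0]))


def sample_slice(
    phantom: AnalyticPhantom,
    plane_origin: Sequence[float] | None = None,
    plane_axes: tuple[Sequence[float], Sequence[float]] | None = None,
    spacing: float | None = None,
    times: Sequence[float] | None = None,
) -> DisplacementField:
    """Sample the phantom displacement on a regular grid of one plane.

    The grid extent is chosen to cover the projection of the phantom
    bounding box onto the plane. The mask is the phantom's myocardium
    membership; displacements outside the mask are NaN.
    """
    spec = phantom.spec
    if plane_origin is None or plane_axes is None:
        plane_origin, plane_axes = long_axis_plane()
    origin = np.asarray(plane_origin, dtype=float)
    a1 = np.asarray(plane_axes[0], dtype=float)
    a2 = np.asarray(plane_axes[1], dtype=float)
    if not (
        np.isclose(np.linalg.norm(a1), 1, atol=1e-9)
        and np.isclose(np.linalg.norm(a2), 1, atol=1e-9)
        and np.isclose(a1 @ a2, 0, atol=1e-9)
    ):
        raise ValueError("plane_axes must be orthonormal")
    spacing = spec.grid_spacing if spacing is None else float(spacing)
    times = np.asarray(spec.time_points if times is None else times, dtype=float)

    # project phantom bounding-box corners onto the plane axes
    r0, L = spec.r0, spec.l_len
    corners = np.array(
        [(sx * r0, sy * r0, z) for sx in (-1, 1) for sy in (-1, 1) for z in (0, L)]
    )
    rel = corners - origin
    u_rng = rel @ a1
    v_rng = rel @ a2
    u = np.arange(np.floor(u_rng.min()), np.ceil(u_rng.max()) + spacing / 2, spacing)
    v = np.arange(np.floor(v_rng.min()), np.ceil(v_rng.max()) + spacing / 2, spacing)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pos = origin + uu[..., None] * a1 + vv[..., None] * a2

    mask = phantom.inside_fn(pos)
    if not mask.any():
        warnings.warn("slice does not intersect the myocardial wall", stacklevel=2)

    disp = np.full((len(times), *mask.shape, 3), np.nan)
    for it, t in enumerate(times):
        disp[it][mask] = phantom.displacement_fn(pos[mask], float(t))

    normal = np.cross(a1, a2)
    return DisplacementField(
        ref_positions=pos,
        displacements=disp,
        mask=mask,
        spacing=spacing,
        slice_normal=normal,
        times=times,
        metadata={
            "phantom": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(spec).items()
            },
            "composition_order": "F_total = F_rotation . F_inplane",
            "plane_origin": origin.tolist(),
            "plane_axes": [a1.tolist(), a2.tolist()],
        },
    )


def add_noise(
    field: DisplacementField, sigma_rel: float, seed: int | None = None
) -> DisplacementField:
    """Add i.i.d. Gaussian noise to every displacement component.

    The noise SD is ``sigma_rel`` times the maximum displacement magnitude
    over the whole masked motion (all points and times). One master seed
    spawns an independent substream per time frame.
    """
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be non-negative")
    out = field.copy()
    if sigma_rel == 0:
        return out
    mags = np.linalg.norm(field.displacements[:, field.mask, :], axis=-1)
    u_max = float(np.max(mags)) if mags.size else 0.0
    sd = sigma_rel * u_max
    streams = np.random.SeedSequence(seed).spawn(field.n_times)
    for it in range(field.n_times):
        rng = np.random.default_rng(streams[it])
        noise = rng.normal(0.0, sd, size=field.displacements[it].shape)
        out.displacements[it][field.mask] += noise[field.mask]
    out.metadata = dict(out.metadata, noise_sigma_rel=sigma_rel, noise_seed=seed)
    return out


def analytic_strain_summary(
    phantom: AnalyticPhantom, field: DisplacementField, t: float
) -> dict[str, float]:
    """RMS magnitude of each analytic RCL strain component over the mask.

    The magnitude convention matches the error tables: root-mean-square of
    the analytic component over all masked points of the slice.
    """
    from .strain import rcl_frames_at, LongAxisModel, transform_to_rcl_batch

    if not field.mask.any():
        raise ValueError("empty mask")
    pos = field.masked_positions()
    E = phantom.strain_fn(pos, float(t))
    axis = LongAxisModel(
        apex=np.zeros(3), base=np.array([0.0, 0.0, phantom.spec.l_len])
    )
    Q = rcl_frames_at(pos, axis)
    E_rcl = transform_to_rcl_batch(E, Q)
    idx = {"E_RR": (0, 0), "E_CC": (1, 1), "E_LL": (2, 2),
           "E_RL": (0, 2), "E_LC": (1, 2), "E_RC": (0, 1)}
    return {
        name: float(np.sqrt(np.mean(E_rcl[:, i, j] ** 2))) for name, (i, j) in idx.items()
    }
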