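"""Phase-to-displacement conversion and displacement smoothing.

Displacement-encoded MRI stores motion as per-pixel phase; one cycle of
phase corresponds to 1/k_e cm of displacement along the encoding
direction. Before spatial differentiation the displacement is smoothed
with the smallest symmetric 2D median filter (the five-pixel plus) and,
in time, by projection on a truncated Fourier basis: the significant
temporal frequencies of heart motion lie below five times the heart
rate, so a fifth-order basis is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fields import DisplacementField

__all__ = [
    "PhaseField",
    "phase_to_displacement",
    "unwrap_phase",
    "median_filter_plus",
    "temporal_fourier_smooth",
    "magnitude_template",
]


@dataclass
class PhaseField:
    """Wrapped phase grids per encoding direction and time.

    ``phase`` has shape (nt, nr, nc, ndir) with values in (-pi, pi];
    ``ke`` gives the encoding sensitivity per direction in cycles/cm.
    """

    phase: np.ndarray
    ke: np.ndarray  # (ndir,) cycles/cm
    mask: np.ndarray  # (nr, nc) bool
    spacing: float = 1.0
    slice_normal: np.ndarray | None = None
    times: np.ndarray | None = None
    ref_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.ke = np.atleast_1d(np.asarray(self.ke, dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.phase.ndim != 4:
            raise ValueError("phase must have shape (nt, nr, nc, ndir)")
        if np.nanmax(np.abs(self.phase[:, self.mask, :]), initial=0.0) > np.pi + 1e-9:
            raise ValueError("phase must lie in (-pi, pi]")
        if self.times is None:
            self.times = np.arange(self.phase.shape[0], dtype=float)


def phase_to_displacement(pf: PhaseField) -> DisplacementField:
    """Displacement in mm from phase: u = phase / (2 pi k_e), k_e in cycles/cm."""
    if pf.ke.shape[0] != pf.phase.shape[-1]:
        raise ValueError("one k_e per encoding direction is required")
    if np.any(~(pf.ke > 0)):
        raise ValueError("k_e must be positive for every direction")
    u_cm = pf.phase / (2.0 * np.pi * pf.ke)
    nt, nr, nc, ndir = pf.phase.shape
    if ndir > 3:
        raise ValueError("at most three encoding directions are supported")
    disp = np.zeros((nt, nr, nc, 3))
    disp[..., :ndir] = 10.0 * u_cm  # cm -> mm; unencoded directions stay 0
    if pf.ref_positions is None:
        ii, jj = np.mgrid[0:nr, 0:nc]
        ref = np.stack(
            [ii * pf.spacing, jj * pf.spacing, np.zeros_like(ii, dtype=float)],
            axis=-1,
        )
    else:
        ref = pf.ref_positions
    normal = pf.slice_normal if pf.slice_normal is not None else np.array([0.0, 0, 1])
    return DisplacementField(
        ref_positions=ref,
        displacements=disp,
        mask=pf.mask,
        spacing=pf.spacing,
        slice_normal=normal,
        times=pf.times,
        metadata={"ke_cycles_per_cm": pf.ke.tolist()},
    )


def _unwrap_single(phase: np.ndarray, mask: np.ndarray, seed: tuple[int, int]):
    """Region-growing unwrap of one 2D wrapped-phase image.

    Grows from the seed pixel; each accepted neighbor receives the
    integer multiple of 2 pi that minimizes its jump to the
    already-unwrapped neighbor (any jump above pi signals a wrap).
    """
    from collections import deque

    out = phase.astype(float).copy()
    visited = np.zeros_like(mask, dtype=bool)
    q = deque([seed])
    visited[seed] = True
    nr, nc = mask.shape
    while q:
        i, j = q.popleft()
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ii, jj = i + di, j + dj
            if 0 <= ii < nr and 0 <= jj < nc and mask[ii, jj] and not visited[ii, jj]:
                k = np.round((out[i, j] - out[ii, jj]) / (2 * np.pi))
                out[ii, jj] += 2 * np.pi * k
                visited[ii, jj] = True
                q.append((ii, jj))
    return out, visited


def _coherence_seed(phase: np.ndarray, mask: np.ndarray) -> tuple[int, int]:
    """Masked pixel with the lowest mean frame-to-frame phase jump."""
    if phase.shape[0] < 2:
        jumps = np.zeros(mask.shape)
    else:
        d = np.abs(np.diff(phase, axis=0))
        d = np.minimum(d, 2 * np.pi - d)  # wrapped difference
        jumps = d.mean(axis=0)
    jumps = np.where(mask, jumps, np.inf)
    return tuple(np.unravel_index(np.argmin(jumps), mask.shape))


def unwrap_phase(pf: PhaseField) -> PhaseField:
    """Unwrap every direction and time frame by region growing.

    The seed is the masked pixel of maximum temporal phase coherence.
    Disconnected mask components are unwrapped independently (each keeps
    its own global 2 pi k offset) and recorded in ``components_flagged``.
    """
    if not pf.mask.any():
        raise ValueError("empty mask")
    out = pf.phase.copy()
    n_components = 0
    for idir in range(pf.phase.shape[-1]):
        seed = _coherence_seed(pf.phase[..., idir], pf.mask)
        for it in range(pf.phase.shape[0]):
            remaining = pf.mask.copy()
            s = seed
            comp = 0
            while remaining.any():
                if not remaining[s]:
                    s = tuple(np.argwhere(remaining)[0])
                unwrapped, visited = _unwrap_single(out[it, ..., idir], remaining, s)
                out[it, ..., idir] = np.where(visited, unwrapped, out[it, ..., idir])
                remaining &= ~visited
                comp += 1
            n_components = max(n_components, comp)
    result = PhaseField.__new__(PhaseField)
    result.phase = out
    result.ke = pf.ke
    result.mask = pf.mask
    result.spacing = pf.spacing
    result.slice_normal = pf.slice_normal
    result.times = pf.times
    result.ref_positions = pf.ref_positions
    result.components_flagged = n_components > 1
    return result


def median_filter_plus(field: DisplacementField) -> DisplacementField:
    """Five-pixel plus-shaped median of each displacement component.

    The median is restricted to in-mask pixels; pixels with fewer than 3
    in-mask members in the plus neighborhood pass through unchanged.
    """
    from .strain import _plus_median

    out = field.copy()
    for it in range(field.n_times):
        for comp in range(3):
            vals = field.displacements[it, ..., comp]
            out.displacements[it, ..., comp] = np.where(
                field.mask, _plus_median(vals, field.mask), vals
            )
    return out


def temporal_fourier_smooth(
    series: np.ndarray,
    times: np.ndarray,
    order: int = 5,
    heart_period: float | None = None,
) -> np.ndarray:
    """Least-squares projection on a truncated temporal Fourier basis.

    ``series`` may have any shape with time as the FIRST axis. The basis
    is a constant plus sin/cos pairs at harmonics 1..order of the heart
    rate. The heart period defaults to the covered span plus one frame
    interval.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    nt = len(times)
    if series.shape[0] != nt:
        raise ValueError("time axis of series must match times")
    if nt < 2 * order + 1:
        raise ValueError(
            f"need at least {2 * order + 1} samples for order {order}; got {nt}"
        )
    if heart_period is None:
        dt = np.median(np.diff(times)) if nt > 1 else 1.0
        heart_period = (times[-1] - times[0]) + dt
    w = 2.0 * np.pi / heart_period
    cols = [np.ones(nt)]
    for k in range(1, order + 1):
        cols.append(np.cos(k * w * times))
        cols.append(np.sin(k * w * times))
    A = np.stack(cols, axis=1)
    flat = series.reshape(nt, -1)
    coef, *_ = np.linalg.lstsq(A, flat, rcond=None)
    return (A @ coef).reshape(series.shape)


def smooth_displacement_time(
    field: DisplacementField, order: int = 5, heart_period: float | None = None
) -> DisplacementField:
    """Apply the temporal Fourier filter to every masked pixel."""
    out = field.copy()
    vals = field.displacements[:, field.mask, :]
    out.displacements[:, field.mask, :] = temporal_fourier_smooth(
        vals, field.times, order=order, heart_period=heart_period
    )
    return out


def magnitude_template(
    field: DisplacementField, frames: Sequence[int]
) -> np.ndarray:
    """Mean displacement-magnitude image over the given frames.

    Averaging a few frames near maximum displacement yields a robust
    anatomical template for manual masking.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("frame list must not be empty")
    mags = np.linalg.norm(field.displacements[frames], axis=-1)
    return np.nanmean(mags, axis=0)
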