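"""Error metrics against the analytic ground truth.

The tables report, per tensor or strain component: the variation
magnitude (RMS of the analytic component minus its identity-tensor
value), the RMS estimation error, and their ratio (relative RMS). A
relative RMS is undefined (NA) when the analytic component is
identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["ErrorReport", "rms_metrics", "F_ELEMENTS", "STRAIN_ELEMENTS"]

#: deformation-gradient element names in reading order
F_ELEMENTS = tuple(f"F{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3))
#: RCL strain component names in the tables' order
STRAIN_ELEMENTS = ("E_RL", "E_LC", "E_RC", "E_RR", "E_LL", "E_CC")


@dataclass
class ErrorReport:
    """Per-component RMS error report with experiment metadata."""

    table: pd.DataFrame  # columns: component, variation_magnitude,
    #          rms_error, relative_rms
    metadata: dict[str, Any] = dc_field(default_factory=dict)

    def rms_error(self, component: str) -> float:
        return float(
            self.table.set_index("component").loc[component, "rms_error"]
        )

    def variation(self, component: str) -> float:
        return float(
            self.table.set_index("component").loc[component, "variation_magnitude"]
        )

    def relative_rms(self, component: str) -> float:
        """Relative RMS error (fraction, not percent); NaN means NA."""
        return float(
            self.table.set_index("component").loc[component, "relative_rms"]
        )

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["relative_rms"] = out["relative_rms"].map(
            lambda v: "NA" if not np.isfinite(v) else f"{v:.12g}"
        )
        out.to_csv(path, sep="\t", index=False)


def rms_metrics(
    estimated: dict[str, np.ndarray],
    analytic: dict[str, np.ndarray],
    identity_value: dict[str, float] | None = None,
    metadata: dict[str, Any] | None = None,
    zero_tol: float = 1e-12,
) -> ErrorReport:
    """Per-component RMS error, variation magnitude and relative RMS.

    ``estimated`` and ``analytic`` map component names to co-registered
    per-point value arrays (NaNs are dropped pairwise). The variation
    magnitude is the RMS of the analytic values minus ``identity_value``
    (0 by default; 1 for the diagonal of a deformation gradient).
    """
    identity_value = identity_value or {}
    rows = []
    for name, est in estimated.items():
        if name not in analytic:
            raise KeyError(f"analytic values missing for component {name}")
        est = np.asarray(est, float).ravel()
        tru = np.asarray(analytic[name], float).ravel()
        if est.shape != tru.shape:
            raise ValueError(f"component {name}: shape mismatch")
        keep = np.isfinite(est) & np.isfinite(tru)
        if not keep.any():
            raise ValueError(f"component {name}: no valid points")
        err = est[keep] - tru[keep]
        rms_err = float(np.sqrt(np.mean(err**2)))
        offset = identity_value.get(name, 0.0)
        var = float(np.sqrt(np.mean((tru[keep] - offset) ** 2)))
        rel = rms_err / var if var > zero_tol else np.nan
        rows.append(
            {
                "component": name,
                "variation_magnitude": var,
                "rms_error": rms_err,
                "relative_rms": rel,
            }
        )
    return ErrorReport(table=pd.DataFrame(rows), metadata=metadata or {})
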