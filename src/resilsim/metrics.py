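"""Prediction accuracy, standardized bias, heritability, aggregation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import TraitParams

__all__ = [
    "ReplicateMetrics",
    "accuracy",
    "standardized_bias",
    "heritability_at_x",
    "aggregate",
]


@dataclass
class ReplicateMetrics:
    """Accuracy/bias of one replicate's evaluation on the assessed cohort."""

    accuracy_a0: float = np.nan
    accuracy_ar: float = np.nan
    bias_a0: float = np.nan
    bias_ar: float = np.nan
    converged: bool = True
    subset: str = ""


def accuracy(ebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between estimated and true breeding values."""
    ebv = np.asarray(ebv, dtype=np.float64)
    tbv = np.asarray(tbv, dtype=np.float64)
    if ebv.shape[0] < 3:
        raise ValueError("need at least 3 animals")
    if np.std(ebv) == 0 or np.std(tbv) == 0:
        raise ValueError("zero variance in EBV or TBV")
    return float(np.corrcoef(ebv, tbv)[0, 1])


def standardized_bias(ebv: np.ndarray, tbv: np.ndarray,
                      printed_form: bool = False) -> float:
    """Standardized dispersion bias from the TBV-on-EBV regression slope b.

    Default (sign-consistent) convention: b_tilde = 1/b - 1 for b < 1
    (over-dispersed, i.e. over-estimated EBVs, positive) and 1 - b for b >= 1
    (under-estimated, negative); zero iff b = 1 and magnitudes symmetric
    under b <-> 1/b.  ``printed_form`` switches to the alternative mapping
    (1/b - 1 for b >= 1, b - 1 for b < 1), which is non-positive in both
    branches.
    """
    ebv = np.asarray(ebv, dtype=np.float64)
    tbv = np.asarray(tbv, dtype=np.float64)
    ec = ebv - ebv.mean()
    ss = float(ec @ ec)
    if ss == 0:
        raise ValueError("zero EBV variance: slope undefined")
    b = float(ec @ (tbv - tbv.mean())) / ss
    if b <= 0:
        raise ValueError("non-positive TBV-on-EBV slope: bias undefined")
    if printed_form:
        return 1.0 / b - 1.0 if b >= 1 else b - 1.0
    return 1.0 / b - 1.0 if b < 1 else 1.0 - b


def heritability_at_x(params: TraitParams, x: float,
                      printed_form: bool = False) -> float:
    """Heritability of performance at challenge level x.

    h2(x) = (va0 + x^2 var + 2x cov) / (va0 + x^2 var + 2x cov + ve0 + x^2 ver).
    ``printed_form`` replaces the final x^2 * var_er denominator term with
    x^2 * var_e0 (an alternative parameterization in which the residual slope
    variance never enters).
    """
    g = params.var_a0 + x * x * params.var_ar + 2.0 * x * params.cov_a
    e = params.var_e0 + x * x * (params.var_e0 if printed_form
                                 else params.var_er)
    denom = g + e
    if denom == 0:
        raise ValueError("zero phenotypic variance at this challenge level")
    return g / denom


def aggregate(replicates: list[ReplicateMetrics]) -> pd.DataFrame:
    """Converged-only means with normal 95% CIs plus the failure rate.

    Accuracy/bias averages use only replicates whose REML converged to
    feasible components; the failure rate counts all replicates.
    """
    if not replicates:
        raise ValueError("no replicates to aggregate")
    n_total = len(replicates)
    ok = [r for r in replicates if r.converged]
    rows = [{"metric": "failure_rate",
             "mean": 1.0 - len(ok) / n_total,
             "ci_low": np.nan, "ci_high": np.nan,
             "n_converged": len(ok), "n_total": n_total}]
    if not ok:
        raise ValueError("zero converged replicates")
    for name in ("accuracy_a0", "accuracy_ar", "bias_a0", "bias_ar"):
        vals = np.array([getattr(r, name) for r in ok], dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        m = vals.mean()
        half = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size) \
            if vals.size > 1 else 0.0
        rows.append({"metric": name, "mean": m, "ci_low": m - half,
                     "ci_high": m + half, "n_converged": vals.size,
                     "n_total": n_total})
    return pd.DataFrame(rows)
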