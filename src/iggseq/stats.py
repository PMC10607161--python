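"""Paired patient-control statistics and flow-derived quantities.

The study design pairs each patient with a healthy control from the same
household, so comparisons are paired throughout: a two-tailed paired t-test
on (optionally log-transformed) values, with Pearson correlation for
continuous associations.  No multiple-testing correction is applied by
default; a Benjamini-Hochberg helper is provided for callers who want one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateTestError, ValidationError


@dataclass
class PairedComparison:
    """Outcome of one paired patient-vs-control test."""

    measure: str
    patient_values: np.ndarray
    control_values: np.ndarray
    t_statistic: float
    p_value: float
    transform_applied: bool
    n_pairs: int


def paired_t_test(
    patient_values,
    control_values,
    auto_log: bool = False,
    measure: str = "",
    alpha_normality: float = 0.05,
) -> PairedComparison:
    """Two-tailed paired t-test of patients against their matched controls.

    With ``auto_log`` enabled and all values strictly positive, a
    Shapiro-Wilk test on the paired differences decides (at
    ``alpha_normality``) whether to log-transform both vectors first; the
    decision is recorded in ``transform_applied``.

    Identical vectors give t = 0, p = 1 (no signal).  Constant non-zero
    differences make the statistic undefined and raise
    :class:`DegenerateTestError`.
    """
    x = np.asarray(patient_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("patient and control vectors must be 1-D, equal length")
    n = len(x)
    if n < 2:
        raise ValidationError("need at least two pairs")
    transform = False
    if auto_log and (x > 0).all() and (y > 0).all():
        diffs = x - y
        if np.ptp(diffs) > 0 and n >= 3:  # Shapiro-Wilk needs >= 3 points
            shapiro_p = sps.shapiro(diffs).pvalue
            if shapiro_p < alpha_normality:
                transform = True
                x, y = np.log(x), np.log(y)
    diffs = x - y
    if np.allclose(diffs, 0):
        return PairedComparison(measure, x, y, 0.0, 1.0, transform, n)
    if np.ptp(diffs) == 0:
        raise DegenerateTestError(
            f"constant non-zero paired differences ({diffs[0]}): t is undefined"
        )
    t, p = sps.ttest_rel(x, y)
    return PairedComparison(measure, x, y, float(t), float(p), transform, n)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-based p-value on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ValidationError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def isotype_normalise(measured_pct: float, isotype_pct: float) -> float:
    """Subtract isotype-control background from a measured bound percentage.

    Non-specific staining measured with an isotype control is removed; the
    result is floored at 0 (with a warning) when background exceeds signal.
    """
    for name, v in (("measured_pct", measured_pct), ("isotype_pct", isotype_pct)):
        if not 0 <= v <= 100:
            raise ValidationError(f"{name} must lie in [0, 100], got {v}")
    corrected = measured_pct - isotype_pct
    if corrected < 0:
        warnings.warn(
            f"isotype background ({isotype_pct}%) exceeds measured signal "
            f"({measured_pct}%); clipping to 0",
            stacklevel=2,
        )
        return 0.0
    return corrected


def absolute_bound_load(bound_pct: float, microbial_load: float) -> float:
    """Convert a bound-cell percentage to cells/gram using total load."""
    if not 0 <= bound_pct <= 100:
        raise ValidationError("bound_pct must lie in [0, 100]")
    if microbial_load <= 0:
        raise ValidationError("microbial_load must be positive")
    return microbial_load * bound_pct / 100.0


def adjust_pvalues(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg (or any statsmodels-supported) p-value adjustment."""
    return multipletests(np.asarray(p_values, dtype=float), method=method)[1]
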