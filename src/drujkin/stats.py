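"""Statistical comparison of registration error across scan conditions.

Accuracy (the median error of a condition) and precision (its spread) are
compared pairwise between adjacent condition levels, mirroring how imaging
protocols are evaluated:

* normality — Shapiro–Wilk on each sample (the small Z-coverage samples,
  n = 9, are treated as non-parametric without testing);
* precision — Ansari–Bradley scale test after median-centering both samples
  (SNR / Z-coverage families), or a two-tailed Welch t-test (motion family);
* accuracy — Kruskal–Wallis when the precision comparison found equal
  spread, otherwise Mood's median test;
* trend — ordinary least-squares regression of per-condition accuracy
  (median) and precision (IQR) on angular velocity for the motion sweep.

All decisions at α = 0.05, raw p-values (no multiplicity correction):
p-values for translation and rotation responses are reported side by side.
All tests are scipy.stats under the hood except where a convention needed
pinning: Mood's median test counts values equal to the grand median in the
"at or below" cell and uses the chi-square statistic without continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .kinematics import ErrorSummary

__all__ = [
    "ALPHA",
    "StatResult",
    "RegressionResult",
    "shapiro_wilk",
    "precision_test",
    "accuracy_test",
    "moods_median_test",
    "velocity_regression",
    "run_comparison_table",
]

ALPHA = 0.05


class DegenerateSampleError(ValueError):
    """All values identical; the test statistic is undefined."""


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test at level ``alpha``."""

    test: str
    pair: Tuple[str, str]
    statistic: float
    p_value: float
    alpha: float = ALPHA
    response: str | None = None  # "translation" | "rotation" where relevant

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float


def shapiro_wilk(sample: Sequence[float], label: str = "") -> StatResult:
    """Shapiro–Wilk normality test; requires n >= 3."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    w, p = sps.shapiro(x)
    return StatResult(test="shapiro-wilk", pair=(label, ""), statistic=float(w),
                      p_value=float(p))


def precision_test(
    a: Sequence[float],
    b: Sequence[float],
    family: Literal["snr_zcov", "motion"],
    pair: Tuple[str, str] = ("a", "b"),
    response: str | None = None,
) -> StatResult:
    """Compare the spread of two error samples.

    ``snr_zcov`` — both samples are median-centered (the Ansari–Bradley test
    misleads when medians differ), then Ansari–Bradley.  ``motion`` — a
    two-tailed Welch t-test on the raw magnitudes.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if family == "snr_zcov":
        xc = x - np.median(x)
        yc = y - np.median(y)
        stat, p = sps.ansari(xc, yc)
        name = "ansari-bradley"
    elif family == "motion":
        stat, p = sps.ttest_ind(x, y, equal_var=False)
        name = "welch-t"
    else:
        raise ValueError(f"unknown family {family!r}")
    return StatResult(test=name, pair=pair, statistic=float(stat),
                      p_value=float(p), response=response)


def moods_median_test(
    a: Sequence[float], b: Sequence[float]
) -> Tuple[float, float, np.ndarray]:
    """Mood's median test for two samples.

    2×2 chi-square (no continuity correction) of counts above vs at-or-below
    the grand median; ties with the grand median count in the "at or below"
    cell.  Returns (statistic, p, contingency table).
    """
    stat, p, _, table = sps.median_test(
        np.asarray(a, float), np.asarray(b, float), ties="below", correction=False
    )
    return float(stat), float(p), table


def accuracy_test(
    a: Sequence[float],
    b: Sequence[float],
    equal_variance: bool,
    pair: Tuple[str, str] = ("a", "b"),
    response: str | None = None,
) -> StatResult:
    """Compare the medians of two error samples.

    Kruskal–Wallis when the precision test found equal spread, Mood's median
    test otherwise.  ``equal_variance`` is the verdict of
    :func:`precision_test` at α.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise DegenerateSampleError("all values identical across both samples")
    if equal_variance:
        stat, p = sps.kruskal(x, y)
        if np.isnan(p):  # H ≈ 0 for samples with identical ranks
            stat, p = max(float(stat), 0.0), 1.0
        name = "kruskal-wallis"
    else:
        stat, p, _ = moods_median_test(x, y)
        name = "moods-median"
    return StatResult(test=name, pair=pair, statistic=float(stat),
                      p_value=float(p), response=response)


def velocity_regression(
    omegas: Sequence[float], summaries: Sequence[ErrorSummary]
) -> Dict[str, RegressionResult]:
    """OLS of accuracy (median) and precision (IQR) on angular velocity.

    Returns regressions keyed ``"accuracy"`` and ``"precision"`` for one
    response (run separately for translation and rotation).
    """
    if len(omegas) < 3:
        raise ValueError("regression requires at least 3 conditions")
    if len(omegas) != len(summaries):
        raise ValueError("one summary per angular velocity required")
    w = np.asarray(omegas, dtype=float)
    out: Dict[str, RegressionResult] = {}
    for key, y in (
        ("accuracy", np.array([s.median for s in summaries])),
        ("precision", np.array([s.iqr for s in summaries])),
    ):
        if np.allclose(y, y[0]):
            # degenerate response: zero slope, no correlation
            out[key] = RegressionResult(0.0, float(y[0]), 0.0, 1.0)
            continue
        res = sps.linregress(w, y)
        out[key] = RegressionResult(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r=float(res.rvalue),
            p_value=float(res.pvalue),
        )
    return out


def run_comparison_table(
    summaries: Dict[str, Tuple[ErrorSummary, ErrorSummary]],
    design: Literal["snr", "zcoverage", "motion"],
) -> List[StatResult]:
    """Adjacent-pair precision and accuracy tests for a whole experiment.

    ``summaries`` maps condition label → (translation summary, rotation
    summary) and must be ordered by condition level.  For each adjacent pair
    and each response, the precision test runs first and its verdict selects
    the accuracy test, yielding 4 StatResults per pair (p_t and p_r for each
    of precision and accuracy).
    """
    if design not in ("snr", "zcoverage", "motion"):
        raise ValueError(f"unknown design {design!r}")
    labels = list(summaries)
    if len(labels) < 2:
        raise ValueError("need at least 2 conditions to compare")
    family = "motion" if design == "motion" else "snr_zcov"
    results: List[StatResult] = []
    for lab_a, lab_b in zip(labels[:-1], labels[1:]):
        for idx, response in ((0, "translation"), (1, "rotation")):
            x = summaries[lab_a][idx].values
            y = summaries[lab_b][idx].values
            prec = precision_test(x, y, family, pair=(lab_a, lab_b), response=response)
            acc = accuracy_test(
                x, y, equal_variance=not prec.significant,
                pair=(lab_a, lab_b), response=response,
            )
            results.extend([prec, acc])
    return results
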