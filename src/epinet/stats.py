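"""Cohort-level statistics: group tests, correlations, ROC prognosis.

The battery mirrors a surgical-outcome analysis: two-sample t-tests
between seizure-free and not-seizure-free groups, Spearman rank
correlations between network connectivity and neuropsychological scores
with Bonferroni control, post-minus-pre difference scores, demographic
summaries, and an ROC analysis treating network intraconnectivity as a
prognostic score for seizure freedom (higher score => predicts seizure
free), with AUC, a DeLong 95% CI and three operating thresholds
(Youden-optimal, sensitivity-maximising, specificity-maximising).

Missing data are handled by pairwise deletion; every result carries its
effective n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import NEUROPSYCH_TESTS

__all__ = [
    "TestResult",
    "RocResult",
    "two_sample_ttest",
    "spearman_with_bonferroni",
    "difference_scores",
    "roc_analysis",
    "demographics_summary",
    "round_half_away",
]

_TINY = float(np.finfo(float).tiny)


@dataclass
class TestResult:
    """A single hypothesis-test outcome."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    estimate: float
    adjusted_p: Optional[float] = None
    name: str = ""
    computable: bool = True

    def __post_init__(self) -> None:
        if self.computable:
            if not (0.0 <= self.p_value <= 1.0):
                raise ValueError(f"p_value {self.p_value} outside [0, 1]")
            if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-15:
                raise ValueError("adjusted_p must be >= p_value")

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> bool:
        p = self.adjusted_p if (adjusted and self.adjusted_p is not None) else self.p_value
        return self.computable and p < alpha


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def two_sample_ttest(a, b, equal_var: bool = True, name: str = "") -> TestResult:
    """Two-sided two-sample t-test (pooled-variance Student by default;
    ``equal_var=False`` switches to Welch).

    Degenerate separation (zero variance in both groups, different means)
    yields the smallest representable positive p rather than an error.
    """
    a, b = _clean(a), _clean(b)
    for label, g in (("first", a), ("second", b)):
        if len(g) < 2:
            raise ValueError(f"{label} group has {len(g)} non-missing values; need >= 2")
    n1, n2 = len(a), len(b)
    estimate = float(a.mean() - b.mean())
    if equal_var:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        v1, v2 = a.var(ddof=1) / n1, b.var(ddof=1) / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)) if (v1 + v2) > 0 else n1 + n2 - 2
    if se == 0.0:
        if estimate == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(estimate) * np.inf), _TINY
    else:
        t = estimate / se
        p = float(2.0 * sps.t.sf(abs(t), df))
        p = max(p, _TINY)
    return TestResult(statistic=float(t), p_value=p, n1=n1, n2=n2,
                      estimate=estimate, name=name)


def spearman_with_bonferroni(
    table: pd.DataFrame,
    x: str,
    y_columns: list[str],
    family_size: Optional[int] = None,
) -> list[TestResult]:
    """Spearman rho of ``x`` against each column in ``y_columns`` with
    Bonferroni-adjusted p-values (``adjusted_p = min(1, m * p)``).

    ``family_size`` defaults to ``len(y_columns)`` and must be supplied
    explicitly when the run tests a wider family.  Pairs with fewer than
    3 complete cases come back flagged not-computable rather than being
    dropped.
    """
    if family_size is None:
        family_size = len(y_columns)
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    results = []
    xv = pd.to_numeric(table[x], errors="coerce")
    for col in y_columns:
        yv = pd.to_numeric(table[col], errors="coerce")
        ok = xv.notna() & yv.notna()
        n = int(ok.sum())
        if n < 3:
            results.append(TestResult(
                statistic=np.nan, p_value=np.nan, n1=n, n2=n,
                estimate=np.nan, adjusted_p=np.nan, name=col, computable=False,
            ))
            continue
        rho, p = sps.spearmanr(xv[ok], yv[ok])
        p = float(min(max(p, _TINY), 1.0))
        results.append(TestResult(
            statistic=float(rho), p_value=p, n1=n, n2=n, estimate=float(rho),
            adjusted_p=float(min(1.0, family_size * p)), name=col,
        ))
    return results


def difference_scores(table: pd.DataFrame, test_name: str) -> pd.Series:
    """Post-operative minus pre-operative score per patient (negative =
    decline); missing whenever either side is missing."""
    if test_name not in NEUROPSYCH_TESTS:
        raise KeyError(
            f"unknown test {test_name!r}; known tests: {', '.join(NEUROPSYCH_TESTS)}"
        )
    pre, post = f"{test_name}_pre", f"{test_name}_post"
    for col in (pre, post):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not present in table")
    return pd.to_numeric(table[post], errors="coerce") - pd.to_numeric(
        table[pre], errors="coerce"
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    """Empirical ROC of a prognostic score against a binary outcome."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci95: tuple[float, float]
    selected: dict
    n_positive: int
    n_negative: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.sensitivity) > 1e-12):
            raise ValueError("sensitivity must be non-increasing as the threshold rises")
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.auc <= hi + 1e-12):
            raise ValueError("auc must lie within its confidence interval")

    def curve_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _auc_delong(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Concordance AUC (ties count 1/2) and its DeLong variance."""
    m, n = len(pos), len(neg)
    ranks_all = _midrank(np.concatenate([pos, neg]))
    auc = (ranks_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (ranks_all[:m] - _midrank(pos)) / n          # placements of positives
    v01 = 1.0 - (ranks_all[m:] - _midrank(neg)) / m    # placements of negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_analysis(
    scores,
    labels,
    ci_method: str = "delong",
    n_bootstrap: int = 2000,
    rng_seed: int = 0,
) -> RocResult:
    """Empirical ROC with the convention "score >= threshold => predicted
    positive" (positive = seizure free).

    AUC is the concordance probability with ties counted 1/2 (equal to
    the trapezoidal area under the empirical curve).  The 95% CI uses
    DeLong's variance by default (``ci_method='bootstrap'`` for a seeded
    percentile bootstrap), truncated to [0, 1].  Selected thresholds:
    the Youden-J maximiser (ties broken toward higher specificity), the
    sensitivity maximiser subject to specificity > 0, and the
    specificity maximiser subject to sensitivity > 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    ok = np.isfinite(scores)
    scores, labels = scores[ok], labels[ok]
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present for ROC analysis")

    thresholds = np.unique(scores)  # ascending; each is an attainable cut
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])

    auc, var = _auc_delong(pos, neg)
    if ci_method == "delong":
        half = 1.959963984540054 * np.sqrt(var)
        lo, hi = auc - half, auc + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(rng_seed)
        draws = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            bp = pos[rng.integers(len(pos), size=len(pos))]
            bn = neg[rng.integers(len(neg), size=len(neg))]
            draws[i], _ = _auc_delong(bp, bn)
        lo, hi = np.percentile(draws, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = float(max(0.0, lo)), float(min(1.0, hi))
    lo, hi = min(lo, auc), max(hi, auc)

    j = sens + spec - 1.0
    best_j = j.max()
    youden_idx = np.flatnonzero(j >= best_j - 1e-12)
    # ties in J broken toward higher specificity (higher threshold)
    youden_idx = youden_idx[np.argmax(spec[youden_idx])]

    sens_ok = spec > 0
    max_sens_idx = None
    if sens_ok.any():
        cand = np.flatnonzero(sens_ok)
        max_sens_idx = cand[np.argmax(sens[cand])]
    spec_ok = sens > 0
    max_spec_idx = None
    if spec_ok.any():
        cand = np.flatnonzero(spec_ok)
        max_spec_idx = cand[np.argmax(spec[cand])]

    selected = {
        "youden": float(thresholds[youden_idx]),
        "max_sensitivity": float(thresholds[max_sens_idx]) if max_sens_idx is not None else None,
        "max_specificity": float(thresholds[max_spec_idx]) if max_spec_idx is not None else None,
    }
    # report curve with thresholds ascending; sensitivity is then non-increasing
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci95=(lo, hi),
        selected=selected,
        n_positive=len(pos),
        n_negative=len(neg),
    )


# ---------------------------------------------------------------------------
# Demographics


def round_half_away(x: float) -> int:
    """Round half away from zero (the convention used for printed
    percentages: 12/19 -> 63%, 7/19 -> 37%)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def _count_pct(series: pd.Series) -> dict:
    total = int(series.notna().sum())
    out = {}
    for value, count in series.value_counts(dropna=True).items():
        out[str(value)] = {
            "count": int(count),
            "percent": round_half_away(100.0 * count / total) if total else None,
        }
    return out


def demographics_summary(table: pd.DataFrame) -> dict:
    """Counts, integer percentages and age statistics for a cohort table.

    Missing columns are reported as absent rather than raising.
    """
    out: dict = {"n_patients": int(len(table))}
    if "gender" in table.columns:
        out["gender"] = _count_pct(table["gender"])
    if "seizure_free" in table.columns:
        sf = table["seizure_free"].map(
            lambda v: "Yes" if v in (True, "Yes", "yes", 1) else "No"
        )
        out["seizure_free"] = _count_pct(sf)
    if "surgery_side" in table.columns:
        out["surgery_side"] = _count_pct(table["surgery_side"])
    if "surgery_type" in table.columns:
        out["surgery_type"] = _count_pct(table["surgery_type"])
    if "age" in table.columns:
        age = pd.to_numeric(table["age"], errors="coerce").dropna()
        out["age"] = {
            "min": float(age.min()),
            "max": float(age.max()),
            "mean": float(age.mean()),
        }
    return out
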