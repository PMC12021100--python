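"""Group comparisons of clinical/demographic variables ("table one").

Test-selection rules: continuous variables use Student's t (normal) or the
Mann-Whitney U test (non-normal); discrete variables use the Pearson
chi-square test when every expected cell count is at least five, otherwise
Fisher's exact test.  Chi-square on 2x2 tables applies the Yates continuity
correction; larger tables do not.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .layers import SampleTable


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (self.counts < 0).any() or not np.all(self.counts == np.round(self.counts)):
            raise ValueError("counts must be nonnegative integers")
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(self.counts.shape[1])]


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    df: float | None = None
    effect: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p}")


def chisq_test(table: ContingencyTable) -> TestResult:
    """Pearson chi-square; Yates continuity correction on 2x2 tables only."""
    counts = table.counts
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        raise ValueError("zero row/column margin in contingency table")
    is_2x2 = counts.shape == (2, 2)
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=is_2x2)
    total = counts.sum()
    props = {f"{table.col_labels[j]}": (counts[:, j] / counts[:, j].sum()).round(4).tolist()
             for j in range(counts.shape[1])}
    return TestResult("chi-square" + (" (Yates)" if is_2x2 else ""), float(stat), float(p),
                      df=float(dof), effect={"n": float(total), "proportions": props})


def expected_counts(table: ContingencyTable) -> np.ndarray:
    c = table.counts
    return np.outer(c.sum(axis=1), c.sum(axis=0)) / c.sum()


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables with the
    same margins that are no more probable than the observed one.
    """
    if table.counts.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    odds, p = stats.fisher_exact(table.counts.astype(int), alternative="two-sided")
    return TestResult("fisher-exact", float(odds), float(p))


def mann_whitney(x, y) -> TestResult:
    """Mann-Whitney U; exact p when both samples are small (n <= 8), else a
    tie-corrected normal approximation with +-0.5 continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    eff = {"median_x": float(np.median(x)), "median_y": float(np.median(y)),
           "iqr_x": [float(q) for q in np.percentile(x, [25, 75])],
           "iqr_y": [float(q) for q in np.percentile(y, [25, 75])]}
    return TestResult(f"mann-whitney ({method})", float(res.statistic),
                      float(min(1.0, res.pvalue)), effect=eff)


def student_t(x, y) -> TestResult:
    """Pooled-variance two-sample t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = (np.var(x, ddof=1) * (len(x) - 1) + np.var(y, ddof=1) * (len(y) - 1)) / \
          (len(x) + len(y) - 2)
    if sp2 == 0:
        if np.mean(x) == np.mean(y):
            return TestResult("student-t", 0.0, 1.0, df=float(len(x) + len(y) - 2))
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(x, y, equal_var=True)
    eff = {"mean_x": float(np.mean(x)), "mean_y": float(np.mean(y))}
    return TestResult("student-t", float(res.statistic), float(res.pvalue),
                      df=float(len(x) + len(y) - 2), effect=eff)


def build_table_one(samples: SampleTable, labels, test_map: dict[str, str]) -> pd.DataFrame:
    """Per-variable group comparison following the test-selection rules.

    ``test_map`` assigns each covariate one of ``continuous-normal``,
    ``continuous-nonnormal`` or ``categorical``.  Categorical variables use
    chi-square unless any expected cell count is below five, in which case a
    2x2 table falls back to Fisher's exact test (larger sparse tables keep
    chi-square with a warning flag).
    """
    if samples.covariates is None:
        raise ValueError("sample table has no covariates")
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) != 2:
        raise ValueError("table-one comparisons require exactly two groups")
    rows = []
    for var, kind in test_map.items():
        if var not in samples.covariates.columns:
            raise KeyError(f"variable {var!r} missing from sample table")
        col = samples.covariates[var]
        note = ""
        if kind == "categorical":
            levels = sorted(col.astype(str).unique())
            counts = np.array([[int(((col.astype(str) == lv) & (labels == g)).sum())
                                for g in groups] for lv in levels])
            if len(levels) < 2 or counts.sum(axis=1).min() == 0:
                rows.append({"variable": var, "test": "skipped (constant)", "statistic": np.nan,
                             "p": 1.0, "summary": "", "note": "constant covariate"})
                continue
            table = ContingencyTable(counts, levels, [str(g) for g in groups])
            if (expected_counts(table) < 5).any():
                if counts.shape == (2, 2):
                    res = fisher_exact(table)
                else:
                    res = chisq_test(table)
                    note = "expected count < 5; chi-square retained (no 2x2 Fisher fallback)"
            else:
                res = chisq_test(table)
            summ = "; ".join(f"{lv}: " + "/".join(str(int(c)) for c in counts[i])
                             for i, lv in enumerate(levels))
        else:
            x = col[labels == groups[0]].astype(float).to_numpy()
            y = col[labels == groups[1]].astype(float).to_numpy()
            if np.var(np.concatenate([x, y])) == 0:
                rows.append({"variable": var, "test": "skipped (constant)", "statistic": np.nan,
                             "p": 1.0, "summary": "", "note": "constant covariate"})
                continue
            res = student_t(x, y) if kind == "continuous-normal" else mann_whitney(x, y)
            summ = (f"{np.median(x):.3g} ({np.percentile(x, 25):.3g}-{np.percentile(x, 75):.3g})"
                    f" vs {np.median(y):.3g} "
                    f"({np.percentile(y, 25):.3g}-{np.percentile(y, 75):.3g})")
        rows.append({"variable": var, "test": res.test, "statistic": res.statistic,
                     "p": res.p, "summary": summ, "note": note})
    return pd.DataFrame(rows).set_index("variable")
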