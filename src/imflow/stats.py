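"""Inferential layer: Student's t-test, one-way ANOVA, concordance report.

The statistical unit is the per-image mean intensity for microscopy (the
sample size is the number of images per group, typically 10-20) and the
per-tube mean for flow cytometry (3-6 tubes per group).  Pooling the raw
per-cell values instead would treat thousands of correlated cells as
independent replicates and grossly inflate significance; a pooled mode is
available for sensitivity analysis only.

Tests are the classical equal-variance two-sample t (two-sided) and the
one-way F; p < alpha (default 0.05) is called significant.  No
multiple-testing correction is applied by default; Bonferroni is exposed
as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .histograms import METRICS


@dataclass
class TestResult:
    test: str  # "student_t" | "anova_oneway"
    statistic: float
    df: tuple[float, ...]
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _check_group(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ValueError(f"{name} needs n >= 2 replicates, got {values.size}")
    return values


def student_t(
    group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05
) -> TestResult:
    """Two-sided equal-variance (Student's) two-sample t-test.

    Degenerate case: zero pooled variance with equal means gives t = 0,
    p = 1 by convention; zero pooled variance with unequal means has no
    finite statistic and raises.
    """
    a = _check_group(group_a, "group_a")
    b = _check_group(group_b, "group_b")
    df = a.size + b.size - 2
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / df
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return TestResult("student_t", 0.0, (float(df),), 1.0, alpha)
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(
        "student_t", float(res.statistic), (float(df),), float(res.pvalue), alpha
    )


def anova_oneway(groups: list[np.ndarray], alpha: float = 0.05) -> TestResult:
    """One-way fixed-effects ANOVA, F = MS_between / MS_within.

    With two groups the F statistic equals t**2 and the p-value matches
    ``student_t`` exactly.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [_check_group(g, f"group {i}") for i, g in enumerate(groups)]
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df = (float(k - 1), float(n_total - k))
    within = sum(float((a.size - 1) * a.var(ddof=1)) for a in arrays)
    if within == 0.0:
        means = {float(a.mean()) for a in arrays}
        if len(means) == 1:
            return TestResult("anova_oneway", 0.0, df, 1.0, alpha)
        raise ValueError("zero within-group variance with unequal means")
    res = sps.f_oneway(*arrays)
    return TestResult(
        "anova_oneway", float(res.statistic), df, float(res.pvalue), alpha
    )


def compare_groups(
    replicate_means: dict[str, np.ndarray], alpha: float = 0.05
) -> TestResult:
    """Pick the published rule: t-test for 2 groups, one-way ANOVA for 3+."""
    if len(replicate_means) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = list(replicate_means.values())
    if len(arrays) == 2:
        return student_t(arrays[0], arrays[1], alpha)
    return anova_oneway(arrays, alpha)


def per_image_means(cell_table: pd.DataFrame) -> pd.Series:
    """Mean 8-bit cell intensity per image: the imaging replicate values."""
    return cell_table.groupby("image_id")["mean_intensity_8bit"].mean()


def per_tube_means(event_table: pd.DataFrame) -> pd.Series:
    """Mean event intensity per tube (source_id): the flow replicate values."""
    return event_table.groupby("source_id")["intensity_8bit"].mean()


def tests_to_frame(tests: dict[str, TestResult]) -> pd.DataFrame:
    rows = []
    for modality, res in tests.items():
        rows.append(
            {
                "modality": modality,
                "test": res.test,
                "statistic": res.statistic,
                "df1": res.df[0],
                "df2": res.df[1] if len(res.df) > 1 else np.nan,
                "p_value": res.p_value,
                "alpha": res.alpha,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def build_concordance(
    rel_changes_imaging: pd.DataFrame,
    rel_changes_flow: pd.DataFrame,
    tests_imaging: TestResult | None = None,
    tests_flow: TestResult | None = None,
) -> pd.DataFrame:
    """Join the two modalities' relative-change tables metric by metric.

    For every (metric, group) key, reports both relative changes, whether
    their signs agree (zero agrees with anything) and the magnitude ratio
    |flow| / |imaging|.  Mismatched keys raise, naming the offenders.
    """
    key = ["metric", "group"]
    left = rel_changes_imaging.set_index(key)["rel_change_pct"]
    right = rel_changes_flow.set_index(key)["rel_change_pct"]
    missing = set(left.index).symmetric_difference(right.index)
    if missing:
        raise KeyError(f"metric/group keys missing from one modality: {sorted(missing)}")
    rows = []
    for idx in left.index:
        gi, gf = float(left[idx]), float(right[idx])
        sign_agree = gi == 0.0 or gf == 0.0 or (gi > 0) == (gf > 0)
        magnitude_ratio = abs(gf) / abs(gi) if gi != 0.0 else np.nan
        rows.append(
            {
                "metric": idx[0],
                "group": idx[1],
                "rel_change_imaging_pct": gi,
                "rel_change_flow_pct": gf,
                "sign_agree": sign_agree,
                "magnitude_ratio": magnitude_ratio,
            }
        )
    report = pd.DataFrame(rows)
    # stable metric ordering for reproducible CSV output
    order = {m: i for i, m in enumerate(METRICS)}
    report = report.sort_values(
        by=["metric", "group"], key=lambda s: s.map(order) if s.name == "metric" else s
    ).reset_index(drop=True)
    if tests_imaging is not None:
        report.attrs["p_imaging"] = tests_imaging.p_value
    if tests_flow is not None:
        report.attrs["p_flow"] = tests_flow.p_value
    return report
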