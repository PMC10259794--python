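"""Statistical comparisons used in the focus-kinetics analysis.

One-way ANOVA with Tukey's HSD post hoc (focus area and intensity across
treatments), the two-sample t-test for independent samples (focus area in
two time intervals), and a t-test comparing two fitted slope coefficients of
``y = a t + b`` (focus frequency and intensity kinetics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinetics import LinearFit

ALPHA = 0.05


class StatsError(ValueError):
    pass


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p_value: float
    groups: tuple[str, ...] = ()
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "test": self.name, "statistic": self.statistic, "df": self.df,
            "p_value": self.p_value, "groups": list(self.groups),
            "alpha": self.alpha, "significant": self.significant, **self.extra,
        }


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA across groups plus Tukey HSD pairwise comparisons.

    Returns the omnibus result and a tidy pairwise table with Tukey-adjusted
    p-values.  Data identical across all groups yield ``F = 0, p = 1``.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise StatsError("need >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(a) < 2 for a in arrays):
        raise StatsError("every group needs n >= 2")

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all observations identical: no effect, no error
        n_total = len(pooled)
        omnibus = TestResult("one-way ANOVA", 0.0, float(len(labels) - 1), 1.0,
                             tuple(labels), extra={"df_within": n_total - len(labels)})
        pairwise = pd.DataFrame([
            {"group_a": a, "group_b": b, "mean_diff": 0.0, "p_adj": 1.0}
            for i, a in enumerate(labels) for b in labels[i + 1:]])
        return omnibus, pairwise

    means = [a.mean() for a in arrays]
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(means) != 0:
        # zero within-group variance with distinct means: infinitely strong
        f_stat, p = np.inf, 0.0
    else:
        f_stat, p = sps.f_oneway(*arrays)
        if np.ptp(means) == 0:
            f_stat = float(f_stat)  # numerically ~0
    df_between = len(labels) - 1
    df_within = sum(len(a) for a in arrays) - len(labels)
    omnibus = TestResult("one-way ANOVA", float(f_stat), float(df_between),
                         float(p), tuple(labels), extra={"df_within": df_within})

    tukey = sps.tukey_hsd(*arrays)
    rows = []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            rows.append({
                "group_a": a, "group_b": labels[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(tukey.pvalue[i, j]),
            })
    return omnibus, pd.DataFrame(rows)


def ttest_independent(sample_a, sample_b, equal_var: bool = True,
                      labels: tuple[str, str] = ("a", "b")) -> TestResult:
    """Two-sided t-test for the means of two independent samples.

    The classical equal-variance test by default (Welch via
    ``equal_var=False``).  Identical samples give ``t = 0, p = 1``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs n >= 2")
    if np.ptp(np.concatenate([a, b])) == 0:
        df = len(a) + len(b) - 2 if equal_var else float(len(a) + len(b) - 2)
        return TestResult("independent t-test", 0.0, float(df), 1.0, labels)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult("independent t-test", float(res.statistic),
                      float(res.df), float(res.pvalue), labels)


def compare_slopes(fit1: LinearFit, fit2: LinearFit,
                   labels: tuple[str, str] = ("fit1", "fit2")) -> TestResult:
    """t-test on the difference of two fitted slope coefficients.

    ``t = (a1 - a2) / sqrt(SE1^2 + SE2^2)`` with Welch-Satterthwaite degrees
    of freedom built from the two slope variances and fit dofs; the p-value
    is two-sided.
    """
    v1, v2 = fit1.slope_se**2, fit2.slope_se**2
    if v1 + v2 <= 0:
        raise StatsError("zero combined slope standard error")
    if fit1.dof < 1 or fit2.dof < 1:
        raise StatsError("both fits need dof >= 1")
    t = (fit1.slope - fit2.slope) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / fit1.dof + v2**2 / fit2.dof)
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("slope comparison t-test", float(t), float(df), float(p), labels)
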