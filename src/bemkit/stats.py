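"""Shared statistical machinery: Welch t, BH FDR, two-way ANOVA.

Every hypothesis test used elsewhere in the package routes through this
module so that conventions (two-sided p, Satterthwaite df, step-up FDR,
type-II sums of squares for possibly unbalanced 2x2 designs) are set in
one place.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "welch_t",
    "welch_t_rows",
    "bh_fdr",
    "TwoWayDesign",
    "AnovaResult",
    "two_way_anova",
]


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch unequal-variance t-test.

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom and a
    two-sided p-value.  When both samples have zero variance and equal
    means the comparison is vacuous and ``(0.0, df, 1.0)`` is returned.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires n >= 2 in each sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            warnings.warn("zero variance in both samples with equal means; p=1 by convention")
            return 0.0, df, 1.0
        return math.inf, df, 0.0
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_t_rows(mat_a: np.ndarray, mat_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-row Welch t over two genes x replicates matrices.

    Returns ``(t, p)`` arrays.  Rows where both groups are constant and
    equal get p = 1; constant-but-different rows get p = 0.
    """
    res = scipy.stats.ttest_ind(mat_a, mat_b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(mat_a.mean(axis=1), mat_b.mean(axis=1))
        p = np.where(degenerate & same, 1.0, p)
        p = np.where(degenerate & ~same, 0.0, p)
        t = np.where(degenerate, 0.0, t)
    return t, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TwoWayDesign:
    """Observations of a 2x2 factorial (e.g. radiation x drug) design.

    ``factor_a`` and ``factor_b`` are per-observation labels; cells may be
    unbalanced (the source study reports 9-12 animals per group).
    """

    response: np.ndarray
    factor_a: np.ndarray
    factor_b: np.ndarray

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        self.factor_a = np.asarray(self.factor_a)
        self.factor_b = np.asarray(self.factor_b)
        n = self.response.size
        if self.factor_a.size != n or self.factor_b.size != n:
            raise ValueError("response and factor labels must have equal length")
        cells = set(zip(self.factor_a.tolist(), self.factor_b.tolist()))
        if len(cells) < 2:
            raise ValueError("need at least two non-empty design cells")

    @property
    def n_cells(self) -> int:
        return len(set(zip(self.factor_a.tolist(), self.factor_b.tolist())))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"y": self.response, "a": self.factor_a.astype(str), "b": self.factor_b.astype(str)}
        )


@dataclass
class AnovaResult:
    """F statistics and p-values for the two main effects and interaction."""

    f_a: float
    p_a: float
    f_b: float
    p_b: float
    f_interaction: float
    p_interaction: float
    df_a: int
    df_b: int
    df_interaction: int
    df_error: int
    pairwise: pd.DataFrame | None = field(default=None)

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["a", "b", "a:b", "error"],
                "df": [self.df_a, self.df_b, self.df_interaction, self.df_error],
                "F": [self.f_a, self.f_b, self.f_interaction, np.nan],
                "p": [self.p_a, self.p_b, self.p_interaction, np.nan],
            }
        )


def two_way_anova(
    design: TwoWayDesign,
    posthoc: str = "none",
    control_cell: tuple[str, str] | None = None,
) -> AnovaResult:
    """Two-way ANOVA with interaction, type-II sums of squares.

    Type-II decomposition is used so unbalanced cell counts (the study
    design) are handled; with balanced cells it coincides with the
    classical decomposition.  ``posthoc`` is one of ``none``, ``tukey``
    (all pairwise cell comparisons, Tukey HSD) or ``dunnett`` (each cell
    against ``control_cell``).  Error df is N - 4 for the full-rank 2x2
    with interaction.
    """
    df = design.to_frame()
    cells = df.groupby(["a", "b"], observed=True).size()
    if posthoc != "none" and (len(cells) < 4 or (cells < 1).any()):
        raise ValueError("post-hoc comparisons require all four cells non-empty")
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    table = anova_lm(model, typ=2)
    res = AnovaResult(
        f_a=float(table.loc["C(a)", "F"]),
        p_a=float(table.loc["C(a)", "PR(>F)"]),
        f_b=float(table.loc["C(b)", "F"]),
        p_b=float(table.loc["C(b)", "PR(>F)"]),
        f_interaction=float(table.loc["C(a):C(b)", "F"]),
        p_interaction=float(table.loc["C(a):C(b)", "PR(>F)"]),
        df_a=int(table.loc["C(a)", "df"]),
        df_b=int(table.loc["C(b)", "df"]),
        df_interaction=int(table.loc["C(a):C(b)", "df"]),
        df_error=int(table.loc["Residual", "df"]),
    )
    if posthoc == "tukey":
        labels = df["a"] + "+" + df["b"]
        hsd = pairwise_tukeyhsd(df["y"].to_numpy(), labels.to_numpy())
        res.pairwise = pd.DataFrame(
            hsd.summary().data[1:], columns=hsd.summary().data[0]
        )
    elif posthoc == "dunnett":
        if control_cell is None:
            raise ValueError("dunnett post-hoc requires control_cell=(a_level, b_level)")
        ctrl_label = f"{control_cell[0]}+{control_cell[1]}"
        labels = (df["a"] + "+" + df["b"]).to_numpy()
        ctrl = df["y"].to_numpy()[labels == ctrl_label]
        if ctrl.size == 0:
            raise ValueError(f"control cell {ctrl_label} is empty")
        others = sorted(set(labels) - {ctrl_label})
        samples = [df["y"].to_numpy()[labels == lab] for lab in others]
        dn = scipy.stats.dunnett(*samples, control=ctrl)
        res.pairwise = pd.DataFrame(
            {"group": others, "control": ctrl_label, "statistic": dn.statistic, "p_adj": dn.pvalue}
        )
    elif posthoc != "none":
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return res
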