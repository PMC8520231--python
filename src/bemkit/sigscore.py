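"""Signature derivation and trend-concordance identity scoring.

This is the analytical centre of the package.  Given a reference contrast
between two cell populations (monocyte vs microglia, or embryonic vs
adult microglia), genes passing fold-change and significance thresholds
in either direction form a directional *signature set*.  Each study group
is then scored by how many signature genes it expresses "in the same
trend" as each reference population: a signature gene counts as
concordant with population A when it is elevated relative to a baseline
beyond the unspecified window and significant at the stated FDR, and it
sits in A's up-gene list.  The similarity score of a group to a
population is the concordant-gene count as an integer percentage of the
full defined signature list.

Pearson-correlation similarity matrices and one-minus-Pearson
hierarchical clustering over the signature genes complete the picture of
whether a group clusters with microglia, monocytes, or neither.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance
import scipy.stats

from .containers import CountMatrix
from .stats import bh_fdr, welch_t_rows

__all__ = [
    "SignatureThresholds",
    "SignatureSet",
    "TrendWindow",
    "TrendCallTable",
    "SimilarityScore",
    "DendrogramSpec",
    "filter_expressed",
    "derive_signatures",
    "classify_trends",
    "similarity_scores",
    "similarity_matrix",
    "cluster_profiles",
    "round_half_away",
]

POOLED_MEAN = "pooled_mean"

CONCORDANT_A = "concordant_a"
CONCORDANT_B = "concordant_b"
UNSPECIFIED = "unspecified"
NOT_EXPRESSED = "not_expressed"


@dataclass
class SignatureThresholds:
    """Cutoffs for calling a gene a directional signature gene.

    A gene qualifies when its fold-change A/B exceeds ``fc_up`` (up in A)
    or falls below ``fc_down`` (up in B) and it is significant.  Both a
    raw-p cutoff and an FDR cutoff are available because published
    signature lists of this kind quote either; set one to ``None`` to
    disable it.  ``min_avg_count`` is the expression floor applied before
    any testing.
    """

    fc_up: float = 1.5
    fc_down: float = 1.0 / 1.5
    alpha: float | None = 0.05
    fdr_q: float | None = 0.01
    min_avg_count: float = 10.0

    def __post_init__(self):
        if not self.fc_down < 1.0 < self.fc_up:
            raise ValueError("need fc_down < 1 < fc_up")
        for name, v in (("alpha", self.alpha), ("fdr_q", self.fdr_q)):
            if v is not None and not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class SignatureSet:
    """Directional gene lists from a reference contrast.

    ``listed_total`` is the size of the full defined list, which may
    exceed ``|up_in_a| + |up_in_b|`` when the published list contains
    genes not re-derivable from the matrix at hand; similarity scores are
    divided by this total, not by the expressed subset.
    """

    name_a: str
    name_b: str
    up_in_a: list[str]
    up_in_b: list[str]
    listed_total: int
    thresholds: SignatureThresholds = field(default_factory=SignatureThresholds)

    def __post_init__(self):
        if set(self.up_in_a) & set(self.up_in_b):
            raise ValueError("up_in_a and up_in_b must be disjoint")
        if len(self.up_in_a) + len(self.up_in_b) > self.listed_total:
            raise ValueError("listed_total smaller than the derived lists")

    @property
    def all_genes(self) -> list[str]:
        return list(self.up_in_a) + list(self.up_in_b)

    def direction_of(self, gene: str) -> str:
        if gene in set(self.up_in_a):
            return "a"
        if gene in set(self.up_in_b):
            return "b"
        raise KeyError(gene)

    def swapped(self) -> "SignatureSet":
        """Relabel populations A<->B (used by the symmetry property)."""
        return SignatureSet(
            self.name_b, self.name_a, list(self.up_in_b), list(self.up_in_a),
            self.listed_total, self.thresholds,
        )


@dataclass
class TrendWindow:
    """Fold-change band and FDR above which a gene stays unspecified.

    Genes with group-vs-baseline fold-change inside the closed interval
    [lower, upper], or with FDR above ``fdr_q``, are unspecified.
    """

    lower: float = 0.6667
    upper: float = 1.500
    fdr_q: float = 0.01

    def __post_init__(self):
        if not self.lower < 1.0 < self.upper:
            raise ValueError("need lower < 1 < upper")


@dataclass
class TrendCallTable:
    """Per (signature gene, study group) concordance calls.

    ``calls`` is genes x groups with values concordant_a / concordant_b /
    unspecified / not_expressed; every listed signature gene gets exactly
    one call per group.
    """

    calls: pd.DataFrame
    signatures: SignatureSet
    baseline: str
    fold_changes: pd.DataFrame
    fdr: pd.DataFrame

    def counts(self, group: str) -> dict[str, int]:
        vc = self.calls[group].value_counts()
        return {k: int(vc.get(k, 0)) for k in (CONCORDANT_A, CONCORDANT_B, UNSPECIFIED, NOT_EXPRESSED)}


@dataclass
class SimilarityScore:
    """Integer-percent similarity of one study group to each population."""

    group: str
    score_a: int
    score_b: int
    score_unspecified: int
    n_a: int
    n_b: int
    denominator: int


@dataclass
class DendrogramSpec:
    """Agglomerative merge order under distance = 1 - Pearson correlation."""

    labels: list[str]
    linkage_matrix: np.ndarray
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in sch.leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            kids = ",".join(walk(c, node.dist) for c in (node.left, node.right))
            return f"({kids}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def filter_expressed(counts: CountMatrix, min_avg_count: float = 10.0) -> CountMatrix:
    """Keep genes whose mean over all samples is strictly above the floor."""
    if counts.values.empty:
        raise ValueError("empty count matrix")
    keep = counts.values.mean(axis=1) > min_avg_count
    if not keep.any():
        warnings.warn("expression filter removed every gene")
    return CountMatrix(counts.values.loc[keep], counts.sample_groups.copy())


def _two_group_tests(reference: CountMatrix, pop_a: str, pop_b: str):
    a = reference.group_values(pop_a).to_numpy()
    b = reference.group_values(pop_b).to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("insufficient replication: need >= 2 replicates per population")
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = a.mean(axis=1) / b.mean(axis=1)
    _, p = welch_t_rows(a, b)
    return fc, p


def _multi_stage_tests(reference: CountMatrix, stages: list[str]):
    """Per-gene one-way ANOVA across stages + Sidak-adjusted first-vs-last test.

    The fold-change is taken between the first (population A, e.g.
    embryonic) and last (population B, e.g. adult) stage.  A gene is
    significant when the stage ANOVA rejects and the Sidak-adjusted
    pairwise first-vs-last comparison rejects as well.
    """
    mats = [reference.group_values(s).to_numpy() for s in stages]
    if any(m.shape[1] < 2 for m in mats):
        raise ValueError("insufficient replication: need >= 2 replicates per stage")
    f, p_anova = scipy.stats.f_oneway(*mats, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mats[0].mean(axis=1) / mats[-1].mean(axis=1)
    _, p_pair = welch_t_rows(mats[0], mats[-1])
    m = len(stages) * (len(stages) - 1) // 2  # Sidak family: all stage pairs
    p_sidak = 1.0 - (1.0 - p_pair) ** m
    p = np.maximum(np.nan_to_num(p_anova, nan=1.0), p_sidak)
    return fc, p


def derive_signatures(
    reference: CountMatrix,
    thresholds: SignatureThresholds | None = None,
    mode: str = "two_group",
    extra_listed: int = 0,
) -> SignatureSet:
    """Derive directional signature gene lists from a reference contrast.

    ``two_group`` mode contrasts exactly two populations with per-gene
    Welch t-tests; ``multi_stage`` mode handles development-staged
    references with a per-gene one-way ANOVA plus Sidak-adjusted
    first-vs-last comparison.  Genes with FC(A/B) above ``fc_up`` and
    significant go to ``up_in_a``; below ``fc_down`` to ``up_in_b``.
    ``extra_listed`` inflates ``listed_total`` for caller-supplied listed
    genes that are not re-derivable here.
    """
    thresholds = thresholds or SignatureThresholds()
    groups = reference.groups
    if mode == "two_group":
        if len(groups) != 2:
            raise ValueError(f"two_group mode requires exactly 2 populations, got {len(groups)}")
        name_a, name_b = groups
        fc, p = _two_group_tests(reference, name_a, name_b)
    elif mode == "multi_stage":
        if len(groups) < 2:
            raise ValueError("multi_stage mode requires >= 2 populations")
        name_a, name_b = groups[0], groups[-1]
        fc, p = _multi_stage_tests(reference, groups)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    sig = np.ones(len(fc), dtype=bool)
    if thresholds.alpha is not None:
        sig &= p < thresholds.alpha
    if thresholds.fdr_q is not None:
        sig &= bh_fdr(p) < thresholds.fdr_q
    genes = reference.gene_ids
    up_a = list(genes[sig & (fc > thresholds.fc_up)])
    up_b = list(genes[sig & (fc < thresholds.fc_down)])
    return SignatureSet(
        name_a, name_b, up_a, up_b,
        listed_total=len(up_a) + len(up_b) + extra_listed,
        thresholds=thresholds,
    )


def classify_trends(
    study: CountMatrix,
    signatures: SignatureSet,
    window: TrendWindow | None = None,
    baseline: str = POOLED_MEAN,
) -> TrendCallTable:
    """Call each signature gene concordant_a / concordant_b / unspecified per group.

    The fold-change of a group is taken against ``baseline``: either the
    pooled mean over all study samples (default) or a named group's mean.
    Per-gene significance is a Welch t-test of the group's samples against
    the baseline samples (all remaining samples under the pooled default),
    BH-adjusted across the signature genes within the contrast.  Concordance with a population requires the gene to
    belong to that population's up-list, FC strictly above the window and
    FDR at or below the window's q; everything else is unspecified.
    Signature genes absent from the (pre-filtered) study matrix are
    recorded as not_expressed.
    """
    window = window or TrendWindow()
    groups = study.groups
    if baseline != POOLED_MEAN and baseline not in groups:
        raise ValueError(f"baseline group {baseline!r} not in study groups {groups}")

    listed = signatures.all_genes
    present = [g for g in listed if g in study.gene_ids]
    absent = [g for g in listed if g not in study.gene_ids]
    sub = study.values.loc[present]

    calls = pd.DataFrame(NOT_EXPRESSED, index=pd.Index(listed, name="gene_id"), columns=groups)
    fcs = pd.DataFrame(np.nan, index=calls.index, columns=groups)
    fdrs = pd.DataFrame(np.nan, index=calls.index, columns=groups)
    dir_a = calls.index.isin(set(signatures.up_in_a))

    for grp in groups:
        grp_cols = study.samples_of(grp)
        grp_mat = sub[grp_cols].to_numpy()
        if baseline == POOLED_MEAN:
            base_mean = sub.to_numpy().mean(axis=1)
            test_cols = [s for s in study.sample_ids if s not in grp_cols]
        else:
            base_mean = sub[study.samples_of(baseline)].to_numpy().mean(axis=1)
            test_cols = [s for s in study.samples_of(baseline) if s not in grp_cols]
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = grp_mat.mean(axis=1) / base_mean
        if not test_cols:
            # the baseline group scored against itself: FC is identically 1
            p = np.ones(len(present))
        else:
            _, p = welch_t_rows(grp_mat, sub[test_cols].to_numpy())
        q = bh_fdr(p)

        zero_base = base_mean == 0
        if zero_base.any():
            warnings.warn(
                f"{int(zero_base.sum())} signature gene(s) with zero baseline mean in "
                f"group {grp!r} flagged unspecified"
            )
        beyond = np.where(np.isfinite(fc), fc > window.upper, False) & ~zero_base
        significant = q <= window.fdr_q
        call = np.full(len(present), UNSPECIFIED, dtype=object)
        idx_a = dir_a[calls.index.get_indexer(present)]
        call[beyond & significant & idx_a] = CONCORDANT_A
        call[beyond & significant & ~idx_a] = CONCORDANT_B
        calls.loc[present, grp] = call
        fcs.loc[present, grp] = fc
        fdrs.loc[present, grp] = q

    if absent:
        calls.loc[absent, :] = NOT_EXPRESSED
    return TrendCallTable(calls, signatures, baseline, fcs, fdrs)


def similarity_scores(
    calls: TrendCallTable, denominator_mode: str = "listed_total"
) -> list[SimilarityScore]:
    """Integer-percent similarity of every study group to populations A and B.

    ``score_x = round(100 * n_x / denominator)`` with the full defined
    signature list as the default denominator; ``expressed_only`` divides
    by the expressed subset instead.
    """
    if denominator_mode == "listed_total":
        denom = calls.signatures.listed_total
    elif denominator_mode == "expressed_only":
        denom = int((calls.calls.iloc[:, 0] != NOT_EXPRESSED).sum())
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if denom == 0:
        raise ValueError("zero denominator")
    out = []
    for grp in calls.calls.columns:
        c = calls.counts(grp)
        out.append(
            SimilarityScore(
                group=grp,
                score_a=round_half_away(100.0 * c[CONCORDANT_A] / denom),
                score_b=round_half_away(100.0 * c[CONCORDANT_B] / denom),
                score_unspecified=round_half_away(100.0 * c[UNSPECIFIED] / denom),
                n_a=c[CONCORDANT_A],
                n_b=c[CONCORDANT_B],
                denominator=denom,
            )
        )
    return out


def similarity_matrix(profiles: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Pearson-correlation matrix of expression profiles over signature genes.

    ``profiles`` is genes x profiles (study group means and reference
    population means side by side).  Correlations are computed on
    log2(count + 1) unless ``log_transform`` is disabled.  Zero-variance
    profiles get NaN correlations with a warning.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 profiles")
    if profiles.shape[0] < 3:
        raise ValueError("need >= 3 shared genes")
    x = np.log2(profiles + 1.0) if log_transform else profiles.astype(float)
    sd = x.std(axis=0, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"zero-variance profiles, correlations undefined: {dead}")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = x.corr(method="pearson")
    for lbl in corr.index:
        if lbl not in dead:
            corr.loc[lbl, lbl] = 1.0
    return corr


def cluster_profiles(
    profiles: pd.DataFrame,
    method: str = "average",
    log_transform: bool = True,
    precomputed_corr: pd.DataFrame | None = None,
) -> DendrogramSpec:
    """Hierarchical clustering under distance = 1 - Pearson correlation.

    Leaves are ordered lexicographically before linkage so merge order is
    deterministic under ties.  ``method`` is ``average`` (default) or
    ``complete``.
    """
    if method not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {method!r}")
    corr = precomputed_corr if precomputed_corr is not None else similarity_matrix(
        profiles, log_transform=log_transform
    )
    if corr.isna().any().any():
        bad = corr.index[corr.isna().any(axis=1)].tolist()
        raise ValueError(f"undefined correlations for profiles: {bad}")
    labels = sorted(corr.index)
    corr = corr.loc[labels, labels]
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = scipy.spatial.distance.squareform(np.clip(dist, 0.0, None), checks=False)
    z = sch.linkage(condensed, method=method)
    return DendrogramSpec(labels=list(labels), linkage_matrix=z, method=method)
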