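"""Differential-expression set logic and overrepresentation testing.

The radiation-specific gene set of the study is defined by contrast
algebra over a 2x2 design: genes differentially expressed between
irradiated and sham microglia on control diet, but *not* differentially
expressed in the same contrast under CSF-1R-inhibitor treatment (i.e.
after depletion and repopulation).  A flat hypergeometric
overrepresentation test stands in for web-based GO enrichment tools; no
ontology hierarchy propagation is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import CountMatrix
from .sigscore import SignatureThresholds
from .stats import bh_fdr, welch_t_rows

__all__ = [
    "ContrastResult",
    "AnnotationMap",
    "de_contrast",
    "radiation_only_set",
    "overrepresentation_test",
]


@dataclass
class ContrastResult:
    """Per-gene fold-change, p, FDR and DE flags for one group contrast."""

    table: pd.DataFrame  # index gene_id; columns fold_change, p, fdr, de, direction
    group_x: str
    group_y: str

    @property
    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["de"]])

    def de_by_direction(self, direction: str) -> set[str]:
        mask = self.table["de"] & (self.table["direction"] == direction)
        return set(self.table.index[mask])


@dataclass
class AnnotationMap:
    """Flat term -> gene-set annotation (GO-style, no hierarchy)."""

    term_genes: dict[str, set[str]]
    term_names: dict[str, str] | None = None

    def __post_init__(self):
        empty = [t for t, g in self.term_genes.items() if not g]
        if empty:
            raise ValueError(f"empty term sets: {empty}")


def de_contrast(
    counts: CountMatrix,
    group_x: str,
    group_y: str,
    thresholds: SignatureThresholds | None = None,
) -> ContrastResult:
    """Welch t-test + BH FDR contrast of two study groups.

    The DE flag requires the fold-change X/Y outside [fc_down, fc_up] and
    significance per the thresholds (raw p and/or FDR, whichever are set).
    """
    thresholds = thresholds or SignatureThresholds()
    for g in (group_x, group_y):
        if g not in counts.groups:
            raise ValueError(f"group {g!r} not present in count matrix")
    x = counts.group_values(group_x).to_numpy()
    y = counts.group_values(group_y).to_numpy()
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = x.mean(axis=1) / y.mean(axis=1)
    _, p = welch_t_rows(x, y)
    q = bh_fdr(p)
    sig = np.ones(len(p), dtype=bool)
    if thresholds.alpha is not None:
        sig &= p < thresholds.alpha
    if thresholds.fdr_q is not None:
        sig &= q < thresholds.fdr_q
    up = fc > thresholds.fc_up
    down = fc < thresholds.fc_down
    direction = np.where(up, "up", np.where(down, "down", "none"))
    table = pd.DataFrame(
        {"fold_change": fc, "p": p, "fdr": q, "de": sig & (up | down), "direction": direction},
        index=counts.gene_ids,
    )
    return ContrastResult(table, group_x, group_y)


def radiation_only_set(
    de_control: ContrastResult, de_treated: ContrastResult
) -> dict[str, set[str]]:
    """Genes DE in the control-diet contrast but not under treatment.

    Returns ``{"up": ..., "down": ..., "total": ...}`` where direction is
    taken from the control-diet contrast.  "Not changed" under treatment
    is read as not passing the DE flag there (no equivalence test).
    """
    if set(de_control.table.index) != set(de_treated.table.index):
        raise ValueError("contrasts cover different gene universes")
    treated_de = de_treated.de_genes
    up = de_control.de_by_direction("up") - treated_de
    down = de_control.de_by_direction("down") - treated_de
    return {"up": up, "down": down, "total": up | down}


def overrepresentation_test(
    gene_set: set[str],
    universe: set[str],
    annotation: AnnotationMap,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of annotation terms in a gene set.

    Per term with m annotated genes in a universe of M, drawing N genes
    and observing k overlaps, p = P[X >= k] for X ~ Hypergeom(M, m, N);
    fold enrichment is observed/expected.  BH FDR is applied across
    terms; rows are sorted by FDR then descending fold enrichment, and
    the ``enriched`` column marks FDR <= fdr_q.
    """
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of universe")
    if not gene_set:
        warnings.warn("empty gene set; no enrichment computed")
        return pd.DataFrame(
            columns=["term", "name", "overlap", "term_size", "expected", "fold_enrichment", "p", "fdr", "enriched"]
        )
    M, N = len(universe), len(gene_set)
    rows = []
    for term, genes in annotation.term_genes.items():
        in_univ = genes & universe
        if not in_univ:
            continue
        m = len(in_univ)
        k = len(in_univ & gene_set)
        expected = m * N / M
        p = float(scipy.stats.hypergeom.sf(k - 1, M, m, N)) if k > 0 else 1.0
        name = (annotation.term_names or {}).get(term, term)
        rows.append((term, name, k, m, expected, k / expected if expected else 0.0, p))
    out = pd.DataFrame(
        rows, columns=["term", "name", "overlap", "term_size", "expected", "fold_enrichment", "p"]
    )
    out["fdr"] = bh_fdr(out["p"]) if len(out) else []
    out["enriched"] = out["fdr"] <= fdr_q
    return out.sort_values(
        ["fdr", "fold_enrichment"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
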