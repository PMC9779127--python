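"""Immune-related ceRNA pair screening and network assembly.

The competing-endogenous-RNA hypothesis predicts that a lncRNA and an mRNA
which share miRNA response elements sequester the same miRNAs, so their
expression rises and falls together. The screen therefore admits a
lncRNA-mRNA pair iff

1. the two genes share at least one miRNA in the interaction table, and
2. their expression is positively correlated above a Pearson threshold
   (default r > 0.8; an optional high-stringency tier at |r| > 0.91).

Immune relevance enters through the mRNA side: immune-related mRNAs are the
differentially expressed mRNAs found in an ImmPort-style immune gene list,
and lncRNAs acquire immune relevance by co-expression with them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CeRNANetwork, ExpressionMatrix, GeneCatalog, InteractionTable

logger = logging.getLogger(__name__)

STANDARD_R_THRESHOLD = 0.8
HIGH_STRINGENCY_R = 0.91


@dataclass(frozen=True)
class CorrelationRecord:
    """Pearson co-expression of one candidate lncRNA-mRNA gene pair."""

    lncrna: str
    mrna: str
    r: float
    p_corr: float
    degenerate: bool = False  # a member had zero variance; r is undefined


@dataclass(frozen=True)
class CeRNAPair:
    """An admitted ceRNA pair: shared miRNAs plus positive co-expression."""

    lncrna: str
    mrna: str
    shared_mirnas: frozenset[str]
    r: float
    p_corr: float
    tier: str = "standard"  # or "high_stringency"


def immune_intersect(
    deg_genes: Sequence[str], catalog: GeneCatalog
) -> tuple[list[str], list[str]]:
    """Split a DEG list into immune-related mRNAs and candidate lncRNAs.

    Immune-related mRNAs are DEGs with mRNA biotype present in the immune
    list; every DEG lncRNA is a candidate (the immune flag applies only to
    mRNAs — lncRNAs acquire immune relevance downstream by co-expression).
    Genes absent from the catalog are logged and dropped.
    """
    if not deg_genes:
        logger.warning("empty DEG list: no immune mRNAs or candidate lncRNAs")
        return [], []
    uncovered = [g for g in deg_genes if g not in catalog]
    if uncovered:
        logger.warning(
            "%d DEGs absent from catalog (dropped): %s",
            len(uncovered), uncovered[:10],
        )
    covered = [g for g in deg_genes if g in catalog]
    immune_mrnas = [
        g for g in covered if catalog.biotype(g) == "mRNA" and catalog.is_immune(g)
    ]
    candidate_lncrnas = [g for g in covered if catalog.biotype(g) == "lncRNA"]
    return immune_mrnas, candidate_lncrnas


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r from the t distribution with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(t)] = 0.0  # |r| = 1 exactly
    return p


def pairwise_correlation(
    expr: ExpressionMatrix,
    set_a: Sequence[str],
    set_b: Sequence[str],
    group: str | None = None,
) -> list[CorrelationRecord]:
    """Pearson correlation of every (a, b) gene pair across samples.

    By default samples from both groups are pooled; pass ``group`` to
    restrict to one group. Zero-variance genes yield records with r = 0
    flagged degenerate (excluded from ceRNA admission downstream).
    """
    missing = [g for g in list(set_a) + list(set_b) if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    log2 = expr.log2_values()
    if group is not None:
        log2 = log2[expr.samples_in_group(group)]
    n = log2.shape[1]
    a_vals = log2.loc[list(set_a)].to_numpy()
    b_vals = log2.loc[list(set_b)].to_numpy()
    a_sd = a_vals.std(axis=1)
    b_sd = b_vals.std(axis=1)
    ac = a_vals - a_vals.mean(axis=1, keepdims=True)
    bc = b_vals - b_vals.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rmat = (ac @ bc.T) / n / np.outer(a_sd, b_sd)
    pmat = _pearson_p(np.nan_to_num(rmat), n)
    records: list[CorrelationRecord] = []
    for i, ga in enumerate(set_a):
        for j, gb in enumerate(set_b):
            if ga == gb:
                continue
            degenerate = a_sd[i] == 0.0 or b_sd[j] == 0.0
            if degenerate:
                records.append(CorrelationRecord(ga, gb, 0.0, 1.0, True))
            else:
                records.append(
                    CorrelationRecord(
                        ga, gb, float(np.clip(rmat[i, j], -1, 1)), float(pmat[i, j])
                    )
                )
    return records


def build_cerna_pairs(
    correlations: Iterable[CorrelationRecord],
    interactions: InteractionTable,
    r_threshold: float = STANDARD_R_THRESHOLD,
    corr_alpha: float | None = None,
) -> list[CeRNAPair]:
    """Admit ceRNA pairs: shared miRNA(s) plus r strictly above threshold.

    Positivity is binding — anti-correlated pairs are never admitted, no
    matter how large |r|. ``corr_alpha`` optionally also requires the
    correlation p-value below alpha. Output is sorted by r descending, ties
    broken lexicographically by (lncRNA, mRNA).
    """
    if not (0.0 < r_threshold < 1.0):
        raise ValueError(f"r_threshold must be in (0, 1), got {r_threshold}")
    mir_index = interactions.gene_index()
    pairs: list[CeRNAPair] = []
    for rec in correlations:
        if rec.degenerate or rec.r <= r_threshold:
            continue
        if corr_alpha is not None and rec.p_corr >= corr_alpha:
            continue
        shared = mir_index.get(rec.lncrna, set()) & mir_index.get(rec.mrna, set())
        if not shared:
            continue
        pairs.append(
            CeRNAPair(
                lncrna=rec.lncrna,
                mrna=rec.mrna,
                shared_mirnas=frozenset(shared),
                r=rec.r,
                p_corr=rec.p_corr,
            )
        )
    pairs.sort(key=lambda p: (-p.r, p.lncrna, p.mrna))
    return pairs


def stringency_filter(
    pairs: Sequence[CeRNAPair], cutoff: float = HIGH_STRINGENCY_R
) -> list[CeRNAPair]:
    """Retain pairs with |r| strictly above the high-stringency cutoff."""
    kept = [
        replace(p, tier="high_stringency") for p in pairs if abs(p.r) > cutoff
    ]
    logger.info("stringency filter |r| > %s: %d of %d pairs kept",
                cutoff, len(kept), len(list(pairs)))
    return kept


def assemble_network(pairs: Sequence[CeRNAPair]) -> CeRNANetwork:
    """Build the tripartite lncRNA-miRNA-mRNA network of admitted pairs."""
    net = CeRNANetwork()
    for p in pairs:
        net.node_types[p.lncrna] = "lncRNA"
        net.node_types[p.mrna] = "mRNA"
        for m in p.shared_mirnas:
            net.node_types[m] = "miRNA"
            net.edges.add((p.lncrna, m))
            net.edges.add((p.mrna, m))
    logger.info(
        "ceRNA network: %d lncRNAs, %d mRNAs, %d miRNAs, %d edges",
        len(net.nodes_of_type("lncRNA")), len(net.nodes_of_type("mRNA")),
        len(net.nodes_of_type("miRNA")), len(net.edges),
    )
    return net


def pairs_to_frame(pairs: Sequence[CeRNAPair]) -> pd.DataFrame:
    """Tabular view of admitted pairs (shared miRNAs semicolon-joined)."""
    return pd.DataFrame(
        {
            "lncrna": [p.lncrna for p in pairs],
            "mrna": [p.mrna for p in pairs],
            "r": [p.r for p in pairs],
            "p_corr": [p.p_corr for p in pairs],
            "shared_mirnas": [";".join(sorted(p.shared_mirnas)) for p in pairs],
            "tier": [p.tier for p in pairs],
        }
    )


def correlations_to_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna": [r.lncrna for r in records],
            "mrna": [r.mrna for r in records],
            "r": [r.r for r in records],
            "p_corr": [r.p_corr for r in records],
            "degenerate": [r.degenerate for r in records],
        }
    )
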