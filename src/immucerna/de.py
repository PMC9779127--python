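"""Two-group differential-expression screening and PCA quality control.

The screen follows the common microarray recipe: Welch's unequal-variance t
test (or Kruskal-Wallis as a rank-based alternative) on log2 expression,
log2 fold change as the difference of group means, and the classic
fold-change / p-value double cutoff (default p < 0.05, |log2FC| > 1, strict
inequalities). Benjamini-Hochberg adjusted p-values are always computed;
whether the call uses raw or adjusted p is a switch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEMethod = Literal["welch_t", "kruskal"]


@dataclass
class DEGTable:
    """Per-gene differential-expression results.

    ``table`` is indexed by gene with columns ``log2fc``, ``p``, ``p_adj``
    and ``direction`` (``up`` / ``down`` / ``none``). log2fc is
    case - control on the log2 scale.
    """

    table: pd.DataFrame
    alpha: float = 0.05
    lfc_cutoff: float = 1.0
    use_adjusted: bool = False

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def up_genes(self) -> list[str]:
        sub = self.table[self.table["direction"] == "up"]
        return list(sub.sort_values("p").index)

    def down_genes(self) -> list[str]:
        sub = self.table[self.table["direction"] == "down"]
        return list(sub.sort_values("p").index)

    def deg_genes(self) -> list[str]:
        """All called DEGs (up then down), each sorted by p ascending."""
        return self.up_genes() + self.down_genes()

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def _directions(
    log2fc: np.ndarray, pvals: np.ndarray, alpha: float, lfc_cutoff: float
) -> np.ndarray:
    out = np.full(log2fc.shape, "none", dtype=object)
    sig = pvals < alpha
    out[sig & (log2fc > lfc_cutoff)] = "up"
    out[sig & (log2fc < -lfc_cutoff)] = "down"
    return out


def differential_expression(
    expr: ExpressionMatrix,
    method: DEMethod = "welch_t",
    alpha: float = 0.05,
    lfc_cutoff: float = 1.0,
    use_adjusted: bool = False,
) -> DEGTable:
    """Screen every gene for case-vs-control differential expression.

    Linear-scale input is log2(x+1)-transformed first. Genes that are
    constant within both groups get p = 1 (with a warning), never an error.
    """
    if expr.groups is None:
        raise ValueError("differential expression needs group labels")
    log2 = expr.log2_values()
    a = log2[expr.samples_in_group("case")].to_numpy()
    b = log2[expr.samples_in_group("control")].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes raise harmless runtime warnings
        if method == "welch_t":
            _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
        elif method == "kruskal":
            def _kw(row_a: np.ndarray, row_b: np.ndarray) -> float:
                try:
                    return float(stats.kruskal(row_a, row_b).pvalue)
                except ValueError:  # all values identical
                    return np.nan
            pvals = np.array([_kw(ra, rb) for ra, rb in zip(a, b)])
        else:
            raise ValueError(f"unknown method {method!r}; use 'welch_t' or 'kruskal'")
    pvals = np.asarray(pvals, dtype=float)
    if degenerate.any():
        logger.warning(
            "%d genes constant in both groups; p set to 1", int(degenerate.sum())
        )
    pvals[degenerate | ~np.isfinite(pvals)] = 1.0
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")

    call_p = p_adj if use_adjusted else pvals
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": p_adj,
            "direction": _directions(log2fc, call_p, alpha, lfc_cutoff),
        },
        index=log2.index,
    )
    return DEGTable(table=table, alpha=alpha, lfc_cutoff=lfc_cutoff,
                    use_adjusted=use_adjusted)


def classify_degs(
    deg: DEGTable,
    alpha: float = 0.05,
    lfc_cutoff: float = 1.0,
    use_adjusted: bool = False,
) -> tuple[list[str], list[str]]:
    """Re-call up/down gene lists from a DEGTable at given strict cutoffs.

    Returns (up, down), each sorted by p ascending; the two lists are
    disjoint by construction (a gene has one signed fold change).
    """
    if alpha <= 0 or lfc_cutoff <= 0:
        raise ValueError("alpha and lfc_cutoff must be positive")
    t = deg.table
    call_p = t["p_adj"] if use_adjusted else t["p"]
    sig = t[call_p < alpha].sort_values("p")
    up = list(sig.index[sig["log2fc"] > lfc_cutoff])
    down = list(sig.index[sig["log2fc"] < -lfc_cutoff])
    return up, down


def pca_coordinates(
    expr: ExpressionMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto principal components of gene expression.

    Returns (coordinates, explained_variance_ratios); coordinates are a
    samples x components frame, components ordered by decreasing explained
    variance.
    """
    if expr.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > expr.n_samples:
        raise ValueError(
            f"n_components={n_components} exceeds {expr.n_samples} samples"
        )
    x = expr.log2_values().to_numpy().T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    frame = pd.DataFrame(
        coords,
        index=expr.sample_ids,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return frame, pca.explained_variance_ratio_
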