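"""Cross-cohort confirmation of admitted ceRNA pairs.

A pair discovered in a training cohort is confirmed in an independent
two-group validation cohort when (a) both members are significantly
differentially expressed in the expected direction (default: up in cases,
as biomarker pairs of this kind typically are) and (b) the members remain
significantly positively correlated. This is deliberately the strictest
reading of dataset-level validation: every component of the discovery claim
must reproduce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cerna import CeRNAPair, pairwise_correlation
from .de import DEMethod, differential_expression
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairValidationRecord:
    pair: CeRNAPair
    lnc_p: float
    mrna_p: float
    lnc_dir: str
    mrna_dir: str
    r_valid: float
    p_r_valid: float
    verdict: str  # "validated" | "failed"
    reason: str = ""


def validate_pairs(
    pairs: list[CeRNAPair],
    expr_valid: ExpressionMatrix,
    alpha: float = 0.05,
    test: DEMethod = "welch_t",
    direction: str = "up",
) -> list[PairValidationRecord]:
    """Confirm each admitted pair in an independent validation matrix.

    ``direction="up"`` (default) requires both members up-regulated in
    cases; ``direction="any"`` requires only that both members move the
    same way with significance. In all modes a significant positive
    validation correlation is required. Pairs with a member absent from the
    validation matrix fail with reason ``"absent"``.
    """
    if expr_valid.groups is None or set(expr_valid.groups) != {"control", "case"}:
        raise ValueError("validation matrix must contain both groups")
    if direction not in ("up", "any"):
        raise ValueError(f"direction must be 'up' or 'any', got {direction!r}")
    deg = differential_expression(expr_valid, method=test)
    t = deg.table
    records: list[PairValidationRecord] = []
    for pair in pairs:
        present = pair.lncrna in t.index and pair.mrna in t.index
        if not present:
            records.append(
                PairValidationRecord(
                    pair, np.nan, np.nan, "none", "none", np.nan, np.nan,
                    "failed", "absent",
                )
            )
            continue
        lnc_p = float(t.at[pair.lncrna, "p"])
        mrna_p = float(t.at[pair.mrna, "p"])
        lnc_fc = float(t.at[pair.lncrna, "log2fc"])
        mrna_fc = float(t.at[pair.mrna, "log2fc"])
        lnc_dir = "up" if lnc_fc > 0 else "down"
        mrna_dir = "up" if mrna_fc > 0 else "down"
        rec = pairwise_correlation(expr_valid, [pair.lncrna], [pair.mrna])[0]
        both_sig = lnc_p < alpha and mrna_p < alpha
        if direction == "up":
            dir_ok = lnc_dir == "up" and mrna_dir == "up"
        else:
            dir_ok = lnc_dir == mrna_dir
        corr_ok = (not rec.degenerate) and rec.r > 0 and rec.p_corr < alpha
        ok = both_sig and dir_ok and corr_ok
        reason = "" if ok else (
            "expression" if not (both_sig and dir_ok) else "correlation"
        )
        records.append(
            PairValidationRecord(
                pair, lnc_p, mrna_p, lnc_dir, mrna_dir,
                rec.r, rec.p_corr, "validated" if ok else "failed", reason,
            )
        )
    n_ok = sum(r.verdict == "validated" for r in records)
    logger.info("validated %d of %d pairs", n_ok, len(records))
    return records


def correlation_report(
    pairs: list[CeRNAPair],
    expr_train: ExpressionMatrix,
    expr_valid: ExpressionMatrix,
) -> pd.DataFrame:
    """Per-pair Pearson r (and p) in the training and validation cohorts.

    Pairs with a member missing from a matrix get NaN for that cohort and a
    ``missing`` flag, so the table is directly plottable as a train-vs-valid
    scatter.
    """
    rows = []
    for pair in pairs:
        row: dict = {"lncrna": pair.lncrna, "mrna": pair.mrna}
        for label, expr in (("train", expr_train), ("valid", expr_valid)):
            if pair.lncrna in expr.values.index and pair.mrna in expr.values.index:
                rec = pairwise_correlation(expr, [pair.lncrna], [pair.mrna])[0]
                row[f"r_{label}"] = rec.r
                row[f"p_{label}"] = rec.p_corr
                row[f"missing_{label}"] = False
            else:
                row[f"r_{label}"] = np.nan
                row[f"p_{label}"] = np.nan
                row[f"missing_{label}"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def validation_to_frame(records: list[PairValidationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna": [r.pair.lncrna for r in records],
            "mrna": [r.pair.mrna for r in records],
            "lnc_p": [r.lnc_p for r in records],
            "mrna_p": [r.mrna_p for r in records],
            "lnc_dir": [r.lnc_dir for r in records],
            "mrna_dir": [r.mrna_dir for r in records],
            "r_valid": [r.r_valid for r in records],
            "p_r_valid": [r.p_r_valid for r in records],
            "verdict": [r.verdict for r in records],
            "reason": [r.reason for r in records],
        }
    )
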