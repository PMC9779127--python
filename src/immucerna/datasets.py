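"""Small bundled data tables.

The package ships one real table: the high-stringency (|r| > 0.91)
lncRNA-mRNA co-expression pairs published for a PAH (pulmonary arterial
hypertension) lung-tissue cohort of 11 controls and 15 patients. It is the
worked-example input for the stringency tier and network-assembly stages.
Negative signs appear as the typographic minus (U+2212) exactly as printed
and are normalized on read.
"""

from __future__ import annotations

import io as _io
from importlib import resources

import pandas as pd


def load_published_pah_pairs() -> pd.DataFrame:
    """Published |r| > 0.91 lncRNA-mRNA pairs from a PAH case/control cohort.

    Returns a DataFrame with columns ``lncrna``, ``mrna``, ``r`` (signed
    Pearson correlation, as printed).
    """
    text = (
        resources.files("immucerna.data")
        .joinpath("pah_high_stringency_pairs.tsv")
        .read_text(encoding="utf-8")
        .replace("−", "-")
    )
    df = pd.read_csv(_io.StringIO(text), sep="\t")
    df["r"] = df["r"].astype(float)
    return df
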