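"""Screen an RNA-seq abundance table for qPCR candidates.

Two filters on per-condition FPKM values:

* reference-gene candidates — abundant in both conditions and with a
  between-condition fold change close to 1;
* gene-of-interest candidates — detectably expressed and enriched in the
  second condition (here, isolated egg cortices).

The fold thresholds are explicit proxies for a replicate-level
differential-expression call whose inputs (read-level replicates) this
table does not carry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from io import StringIO

__all__ = [
    "FpkmTable",
    "load_fpkm_table",
    "screen_reference_candidates",
    "screen_goi_candidates",
    "sea_urchin_fpkm",
]

#: Published egg/cortex FPKM values of the sea-urchin candidate panel
#: (three abundant reference candidates plus the cortically enriched
#: gene of interest).
_SEA_URCHIN_FPKM_CSV = """\
transcript,fpkm_egg,fpkm_cortex
Cycb,18086.99,15769.9
Daglb-2,2,9
Ebr1,7476.33,6490.31
Smtnl1,4183.87,3781.28
"""


@dataclass(frozen=True)
class FpkmTable:
    """Transcript abundance in two conditions (columns: transcript,
    fpkm_<condition_a>, fpkm_<condition_b>); FPKM must be >= 0."""

    data: pd.DataFrame
    condition_a: str = "egg"
    condition_b: str = "cortex"

    def __post_init__(self):
        cols = {"transcript", self.col_a, self.col_b}
        missing = cols - set(self.data.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        vals = self.data[[self.col_a, self.col_b]]
        if (vals < 0).any().any() or vals.isna().any().any():
            raise ValueError("FPKM values must be finite and >= 0")

    @property
    def col_a(self) -> str:
        return f"fpkm_{self.condition_a}"

    @property
    def col_b(self) -> str:
        return f"fpkm_{self.condition_b}"


def load_fpkm_table(
    path: str | Path, condition_a: str = "egg", condition_b: str = "cortex"
) -> FpkmTable:
    """Read a CSV/TSV with columns transcript, fpkm_<a>, fpkm_<b>."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return FpkmTable(pd.read_csv(path, sep=sep), condition_a, condition_b)


def sea_urchin_fpkm() -> FpkmTable:
    """The built-in egg/cortex FPKM panel used in the worked examples."""
    return FpkmTable(pd.read_csv(StringIO(_SEA_URCHIN_FPKM_CSV)))


def screen_reference_candidates(
    table: FpkmTable, min_fpkm: float = 1000.0, max_fold: float = 1.5
) -> pd.DataFrame:
    """Abundant transcripts with near-equal expression in both conditions.

    Keeps transcripts with min(FPKM_a, FPKM_b) >= ``min_fpkm`` and
    max(a/b, b/a) <= ``max_fold``; the abundance floor guarantees fold
    changes are well defined without pseudocounts.  Sorted by descending
    abundance (the smaller of the two FPKM values).
    """
    if min_fpkm <= 0 or max_fold < 1:
        raise ValueError("min_fpkm must be > 0 and max_fold >= 1")
    df = table.data.copy()
    a, b = df[table.col_a], df[table.col_b]
    df["min_fpkm"] = pd.concat([a, b], axis=1).min(axis=1)
    keep = df["min_fpkm"] >= min_fpkm
    df = df[keep].copy()
    ratio = df[table.col_a] / df[table.col_b]
    df["fold"] = pd.concat([ratio, 1 / ratio], axis=1).max(axis=1)
    df = df[df["fold"] <= max_fold]
    return df.sort_values("min_fpkm", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def screen_goi_candidates(
    table: FpkmTable, min_fpkm: float = 0.5, min_fold: float = 2.0
) -> pd.DataFrame:
    """Transcripts enriched in condition B (cortex) over condition A (egg).

    Keeps transcripts with both FPKM values > ``min_fpkm`` and
    FPKM_b / FPKM_a >= ``min_fold``; sorted by descending fold.
    """
    if min_fpkm <= 0 or min_fold <= 0:
        raise ValueError("thresholds must be positive")
    df = table.data.copy()
    keep = (df[table.col_a] > min_fpkm) & (df[table.col_b] > min_fpkm)
    df = df[keep].copy()
    df["fold"] = df[table.col_b] / df[table.col_a]
    df = df[df["fold"] >= min_fold]
    return df.sort_values("fold", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
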