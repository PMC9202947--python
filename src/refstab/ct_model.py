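"""Quantification-cycle (Ct) tables: data model, I/O, replicate collapsing, QC.

A :class:`CtTable` records gene x sample x technical-replicate quantification
cycles from an RT-qPCR run.  Each sample carries two annotations: an
experimental *group* (by default ``egg`` / ``cortex``, but any two labels
work) and a *template kind* (``total`` RNA or ``polyA`` mRNA).  Every
downstream estimator consumes per-sample mean Ct of exactly one template
kind, so the table offers :func:`collapse_technical_replicates` and
template restriction as first-class operations.

Missing cells (a gene undetected in a sample) are rejected at load time:
the stability estimators assume a complete gene x sample matrix, and
imputation would silently change their meaning.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "QcReport",
    "CtFormatError",
    "CtValueError",
    "load_ct_table",
    "write_ct_table",
    "load_ct_xlsx",
    "collapse_technical_replicates",
    "summarize_ct",
]

LONG_COLUMNS = ["gene", "sample", "group", "template", "replicate", "ct"]

#: Practical Ct range of a 40-cycle qPCR run; values outside are suspicious
#: but only non-positive / non-finite values are hard errors.
CT_PRACTICAL_RANGE = (5.0, 40.0)

#: Technical-replicate spread (max - min, cycles) above which a cell is
#: flagged by QC.  Flags warn; they never exclude data.
DEFAULT_MAX_SPREAD = 0.5


class CtFormatError(ValueError):
    """A Ct file does not have the expected columns / layout."""


class CtValueError(ValueError):
    """A Ct value is non-numeric, non-positive or non-finite."""


def _ordered_unique(values: Sequence) -> list:
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


@dataclass(frozen=True)
class CtTable:
    """Long-format Ct data with validated annotations.

    ``data`` has columns ``gene, sample, group, template, replicate, ct``;
    order of first appearance defines gene/sample ordering everywhere.
    """

    data: pd.DataFrame = field(repr=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CtTable":
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise CtFormatError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, LONG_COLUMNS].copy()
        for col in ("gene", "sample", "group", "template"):
            df[col] = df[col].astype(str).str.strip()
        df["group"] = df["group"].str.lower()
        df["template"] = df["template"].str.lower()
        ct = pd.to_numeric(df["ct"], errors="coerce")
        bad = ~np.isfinite(ct) | (ct <= 0)
        if bad.any():
            rows = df.index[bad].tolist()
            raise CtValueError(
                f"non-numeric or non-positive ct value(s) at row(s) {rows}: "
                f"{df.loc[bad, 'ct'].tolist()}"
            )
        df["ct"] = ct.astype(float)
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
        # one sample id must map to one (group, template)
        amb = df.groupby("sample")[["group", "template"]].nunique()
        conflicted = amb[(amb > 1).any(axis=1)].index.tolist()
        if conflicted:
            raise CtFormatError(
                f"sample(s) {conflicted} carry conflicting group/template labels"
            )
        dup = df.duplicated(["gene", "sample", "template", "replicate"])
        if dup.any():
            raise CtFormatError(
                f"duplicated gene/sample/replicate row(s) at {df.index[dup].tolist()}"
            )
        return cls(df.reset_index(drop=True))

    # -- basic views -----------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return _ordered_unique(self.data["gene"])

    @property
    def samples(self) -> list[str]:
        return _ordered_unique(self.data["sample"])

    @property
    def template_kinds(self) -> list[str]:
        return _ordered_unique(self.data["template"])

    @property
    def groups(self) -> pd.Series:
        """Sample -> group label."""
        return (
            self.data.drop_duplicates("sample").set_index("sample")["group"]
        ).loc[self.samples]

    @property
    def n_values(self) -> int:
        return len(self.data)

    def is_collapsed(self) -> bool:
        return not self.data.duplicated(["gene", "sample"]).any()

    def restrict(self, template: str) -> "CtTable":
        """Return the sub-table of one template kind."""
        template = template.strip().lower()
        sub = self.data[self.data["template"] == template]
        if sub.empty:
            raise CtValueError(
                f"no rows with template kind {template!r}; "
                f"present: {self.template_kinds}"
            )
        return CtTable(sub.reset_index(drop=True))

    def matrix(self) -> pd.DataFrame:
        """Gene x sample matrix of per-cell mean Ct (single template kind)."""
        if len(self.template_kinds) != 1:
            raise CtValueError(
                "table mixes template kinds "
                f"{self.template_kinds}; restrict() to one first"
            )
        m = self.data.pivot_table(
            index="gene", columns="sample", values="ct", aggfunc="mean"
        )
        if m.isna().any().any():
            holes = [
                (g, s) for g in m.index for s in m.columns if pd.isna(m.at[g, s])
            ]
            raise CtValueError(f"missing gene x sample cell(s): {holes}")
        return m.loc[self.genes, self.samples]


@dataclass(frozen=True)
class QcReport:
    """Technical-replicate QC: per-cell spread flags and per-gene summaries.

    ``cells`` columns: gene, sample, group, template, n_replicates, mean_ct,
    spread, passed.  ``gene_summary`` columns: gene, mean_ct, min_ct, max_ct,
    range (over per-sample means).  ``max_spread`` is the flag threshold in
    cycles; a cell passes iff spread < max_spread.
    """

    cells: pd.DataFrame
    gene_summary: pd.DataFrame
    max_spread: float

    @property
    def n_flagged(self) -> int:
        return int((~self.cells["passed"]).sum())

    def to_csv(self, path: str | Path) -> None:
        self.cells.to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "max_spread": self.max_spread,
            "n_flagged": self.n_flagged,
            "cells": self.cells.to_dict(orient="records"),
            "gene_summary": self.gene_summary.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_ct_table(
    path: str | Path,
    layout: str = "long",
    sample_info: Mapping[str, tuple[str, str]] | None = None,
) -> CtTable:
    """Read a Ct table from CSV.

    ``layout='long'`` expects columns gene, sample, group, template,
    replicate, ct.  ``layout='wide'`` expects one row per gene x replicate
    (columns ``gene`` and ``replicate`` first) and one column per sample;
    sample annotations come either from headers of the form
    ``sample:group:template`` or from ``sample_info`` mapping
    sample id -> (group, template).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "long":
        return CtTable.from_frame(pd.read_csv(path))
    if layout != "wide":
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path)
    for col in ("gene", "replicate"):
        if col not in df.columns:
            raise CtFormatError(f"missing required column(s): {col}")
    records = []
    for col in df.columns:
        if col in ("gene", "replicate"):
            continue
        if ":" in col:
            try:
                sample, group, template = col.split(":")
            except ValueError as exc:
                raise CtFormatError(
                    f"wide header {col!r} is not 'sample:group:template'"
                ) from exc
        elif sample_info and col in sample_info:
            sample, (group, template) = col, sample_info[col]
        else:
            raise CtFormatError(
                f"wide column {col!r} lacks annotations; use "
                "'sample:group:template' headers or pass sample_info"
            )
        for _, row in df.iterrows():
            records.append(
                {
                    "gene": row["gene"],
                    "sample": sample,
                    "group": group,
                    "template": template,
                    "replicate": row["replicate"],
                    "ct": row[col],
                }
            )
    return CtTable.from_frame(pd.DataFrame(records))


def write_ct_table(table: CtTable, path: str | Path) -> None:
    """Write the long CSV form (inverse of ``load_ct_table(layout='long')``)."""
    table.data.to_csv(path, index=False)


_XLSX_HEADER_RE = re.compile(
    r"^(?P<group>[A-Za-z]+)[\s_-]*(?P<num>\d+)[\s_-]*(?:r(?:ep)?)?[\s_-]*(?P<rep>\d+)$"
)


def load_ct_xlsx(
    path: str | Path,
    mapping: Mapping | str | Path | None = None,
) -> CtTable:
    """Read a raw-Ct workbook: one sheet per template kind, genes in rows,
    one column per sample x technical replicate.

    Column headers like ``Egg1_r2`` / ``cortex 2 3`` are auto-detected
    (group word, sample number, replicate number).  For any other dialect,
    pass ``mapping``: a dict (or path to a JSON file) of the form::

        {"sheets": {"<sheet name>": {
            "template": "total",
            "columns": {"<header>": {"sample": ..., "group": ..., "replicate": ...}}
        }}}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(mapping, (str, Path)):
        mapping = json.loads(Path(mapping).read_text())
    sheets = pd.read_excel(path, sheet_name=None, index_col=0)
    records = []
    for sheet_name, frame in sheets.items():
        sheet_map = (mapping or {}).get("sheets", {}).get(sheet_name, {})
        template = sheet_map.get("template", sheet_name.strip().lower())
        col_map = sheet_map.get("columns", {})
        for col in frame.columns:
            header = str(col).strip()
            if header in col_map:
                info = col_map[header]
                sample, group, rep = info["sample"], info["group"], info["replicate"]
            else:
                m = _XLSX_HEADER_RE.match(header)
                if not m:
                    raise CtFormatError(
                        f"cannot interpret column {header!r} on sheet "
                        f"{sheet_name!r}; supply a mapping file"
                    )
                group = m.group("group").lower()
                sample = f"{group}{m.group('num')}"
                rep = int(m.group("rep"))
            for gene, value in frame[col].items():
                records.append(
                    {
                        "gene": gene,
                        "sample": sample,
                        "group": group,
                        "template": template,
                        "replicate": rep,
                        "ct": value,
                    }
                )
    return CtTable.from_frame(pd.DataFrame(records))


# ---------------------------------------------------------------------------
# Replicate collapsing and summaries
# ---------------------------------------------------------------------------

def collapse_technical_replicates(
    table: CtTable, max_spread: float = DEFAULT_MAX_SPREAD
) -> tuple[CtTable, QcReport]:
    """Average technical replicates per gene x sample and QC their spread.

    Each cell is replaced by the arithmetic mean of its replicates on the
    Ct scale.  Cells whose replicate spread (max - min) is >= ``max_spread``
    cycles are flagged in the report but retained.  Idempotent: collapsing
    a collapsed table changes nothing (every spread is then 0).
    """
    if max_spread <= 0:
        raise ValueError("max_spread must be positive")
    g = table.data.groupby(["gene", "sample", "group", "template"], sort=False)
    cells = g["ct"].agg(
        n_replicates="size", mean_ct="mean", spread=lambda x: x.max() - x.min()
    ).reset_index()
    cells["passed"] = cells["spread"] < max_spread
    collapsed = cells.rename(columns={"mean_ct": "ct"})[
        ["gene", "sample", "group", "template", "ct"]
    ].copy()
    collapsed["replicate"] = 1
    out = CtTable.from_frame(collapsed)
    per_sample = cells.groupby("gene", sort=False)["mean_ct"]
    gene_summary = per_sample.agg(
        mean_ct="mean", min_ct="min", max_ct="max"
    ).reset_index()
    gene_summary["range"] = gene_summary["max_ct"] - gene_summary["min_ct"]
    return out, QcReport(cells=cells, gene_summary=gene_summary, max_spread=max_spread)


def summarize_ct(table: CtTable) -> pd.DataFrame:
    """Per-gene Ct level summary over per-sample means, one template kind.

    Returns a frame (gene, mean_ct, min_ct, max_ct, range) ordered by
    ascending mean Ct, i.e. most-abundant transcript first.
    """
    m = table.matrix()
    if m.shape[1] < 2:
        raise CtValueError("at least 2 samples required (range undefined)")
    out = pd.DataFrame(
        {
            "gene": m.index,
            "mean_ct": m.mean(axis=1).to_numpy(),
            "min_ct": m.min(axis=1).to_numpy(),
            "max_ct": m.max(axis=1).to_numpy(),
        }
    )
    out["range"] = out["max_ct"] - out["min_ct"]
    return out.sort_values("mean_ct", kind="mergesort").reset_index(drop=True)
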