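"""Aggregate per-method stability rankings into one matrix and a consensus.

The consensus ordering uses the geometric mean of per-method ranks, an
explicit formalization chosen by this package (stability programs publish
rankings, not a combination rule).  geNorm cannot separate its final pair,
so both pair members take rank 1.5 and occupy a merged 1-2 position in the
rendered matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .stability import StabilityResult

__all__ = ["RankTable", "aggregate_rankings"]


@dataclass(frozen=True)
class RankTable:
    """Method x gene numeric ranks, consensus scores and ordering.

    ``ranks``: DataFrame indexed by gene, one column per method, holding the
    1-based rank (1.5 for both members of a merged pair).  ``consensus``:
    geometric mean of ranks per gene.  ``ordering``: genes by ascending
    consensus, ties broken alphabetically.
    """

    ranks: pd.DataFrame
    consensus: pd.Series
    ordering: tuple[str, ...]
    pairs: dict[str, tuple[str, str]]

    def to_matrix(self) -> pd.DataFrame:
        """Method x rank-position view (pair at a merged '1-2' position)."""
        positions: dict[str, dict[str, str]] = {}
        k = len(self.ranks.index)
        for method in self.ranks.columns:
            row: dict[str, str] = {}
            col = self.ranks[method]
            if method in self.pairs:
                a, b = self.pairs[method]
                row["1-2"] = f"{a}/{b}"
                rest = col[~col.index.isin((a, b))].sort_values(kind="mergesort")
                for pos, gene in zip(range(3, k + 1), rest.index):
                    row[str(pos)] = gene
            else:
                ordered = col.sort_values(kind="mergesort")
                for pos, gene in zip(range(1, k + 1), ordered.index):
                    row[str(pos)] = gene
            positions[method] = row
        mat = pd.DataFrame(positions).T
        order = sorted(mat.columns, key=lambda c: 1.5 if c == "1-2" else float(c))
        return mat.loc[:, order]

    def to_markdown(self) -> str:
        mat = self.to_matrix()
        lines = ["| method | " + " | ".join(mat.columns) + " |"]
        lines.append("|" + "---|" * (len(mat.columns) + 1))
        for method, row in mat.iterrows():
            lines.append(
                f"| {method} | " + " | ".join(str(x) for x in row.fillna("")) + " |"
            )
        lines.append("")
        lines.append(
            "consensus (geometric mean of ranks): "
            + ", ".join(f"{g}={self.consensus[g]:.3g}" for g in self.ordering)
        )
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "ranks": self.ranks.to_dict(),
            "consensus": {g: float(v) for g, v in self.consensus.items()},
            "ordering": list(self.ordering),
            "pairs": {m: list(p) for m, p in self.pairs.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def aggregate_rankings(results: Sequence[StabilityResult]) -> RankTable:
    """Combine stability results over the same gene set into a RankTable.

    A result whose metadata carries a ``best_pair`` occupying ranks 1-2
    (geNorm) contributes rank 1.5 for both pair members.
    """
    if not results:
        raise ValueError("need at least one StabilityResult")
    gene_set = sorted(results[0].scores.index)
    for r in results[1:]:
        if sorted(r.scores.index) != gene_set:
            raise ValueError(
                f"inconsistent gene sets: {gene_set} vs {sorted(r.scores.index)}"
            )
    genes = list(results[0].scores.index)
    ranks = pd.DataFrame(index=genes, dtype=float)
    pairs: dict[str, tuple[str, str]] = {}
    for r in results:
        col = pd.Series(
            {g: float(r.ranking.index(g) + 1) for g in genes}, dtype=float
        )
        pair = r.metadata.get("best_pair")
        if r.method == "genorm" and pair:
            a, b = pair
            col[a] = col[b] = 1.5
            pairs[r.method] = (a, b)
        ranks[r.method] = col
    consensus = pd.Series(
        np.exp(np.log(ranks.to_numpy(dtype=float)).mean(axis=1)), index=genes
    )
    ordering = tuple(sorted(genes, key=lambda g: (consensus[g], g)))
    return RankTable(ranks=ranks, consensus=consensus, ordering=ordering, pairs=pairs)
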