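"""Relative quantification by the comparative-Ct (2^-ddCt) method.

For a gene of interest normalized to one or more reference genes:

    dCt_s  = Ct_goi,s - mean(Ct of the normalizers in sample s)
    ddCt_s = dCt_s - mean of dCt over the calibrator group's samples
    fold_s = 2 ** -ddCt_s

Averaging normalizer Ct arithmetically equals taking the geometric mean of
their relative quantities, the multi-reference convention geNorm
recommends.  Group fold changes are 2^-(group mean ddCt); the calibrator
group therefore has fold 1 by construction.  Groups are compared with an
unpaired two-tailed t-test on dCt (the log-scale quantity), pooled
variance by default, Welch optional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_model import CtTable

__all__ = ["RelExprResult", "ddct", "compare_groups"]


@dataclass(frozen=True)
class RelExprResult:
    """Per-sample and per-group relative expression of one gene of interest.

    ``per_sample`` columns: sample, group, delta_ct, ddct, fold.
    ``group_stats`` columns: group, n, mean_delta_ct, sd_delta_ct,
    mean_ddct, fold, fold_lo, fold_hi (fold_lo/hi are 2^-(mean +- SD),
    dispersion propagated from the dCt standard deviation).
    """

    goi: str
    refs: tuple[str, ...]
    calibrator: str
    per_sample: pd.DataFrame
    group_stats: pd.DataFrame
    base: float = 2.0

    def fold_of(self, group: str) -> float:
        row = self.group_stats.set_index("group")
        return float(row.loc[group, "fold"])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "goi": self.goi,
            "refs": list(self.refs),
            "calibrator": self.calibrator,
            "base": self.base,
            "per_sample": self.per_sample.to_dict(orient="records"),
            "group_stats": self.group_stats.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def ddct(
    table: CtTable,
    goi: str,
    refs: str | Sequence[str],
    calibrator: str,
    base: float = 2.0,
    efficiencies: dict[str, float] | None = None,
) -> RelExprResult:
    """Comparative-Ct fold changes of ``goi`` against reference gene(s).

    ``efficiencies`` switches on Pfaffl-style efficiency correction: each
    gene's Ct is rescaled by log2(1 + E/100) before differencing, so a
    cycle of a 92%-efficient reaction counts less than a cycle of a
    100%-efficient one.  Off by default (plain base-2 ddCt).
    """
    if isinstance(refs, str):
        refs = (refs,)
    refs = tuple(refs)
    if not refs:
        raise ValueError("need at least one reference gene")
    if goi in refs:
        raise ValueError(f"gene of interest {goi!r} listed among references")
    m = table.matrix()
    for g in (goi, *refs):
        if g not in m.index:
            raise ValueError(f"gene {g!r} not in table")
    groups = table.groups.loc[m.columns]
    calibrator = calibrator.strip().lower()
    if calibrator not in set(groups):
        raise ValueError(
            f"calibrator group {calibrator!r} absent; groups: {sorted(set(groups))}"
        )

    if efficiencies is None:
        scale = {g: 1.0 for g in (goi, *refs)}
    else:
        missing = [g for g in (goi, *refs) if g not in efficiencies]
        if missing:
            raise ValueError(f"no efficiency supplied for gene(s) {missing}")
        scale = {
            g: np.log2(1.0 + efficiencies[g] / 100.0) for g in (goi, *refs)
        }
    goi_ct = m.loc[goi] * scale[goi]
    ref_ct = pd.concat(
        [m.loc[r] * scale[r] for r in refs], axis=1
    ).mean(axis=1)
    delta = goi_ct - ref_ct
    cal_mean = delta[groups == calibrator].mean()
    dd = delta - cal_mean
    per_sample = pd.DataFrame(
        {
            "sample": m.columns,
            "group": groups.values,
            "delta_ct": delta.values,
            "ddct": dd.values,
            "fold": np.power(base, -dd.values),
        }
    )
    rows = []
    for lab, sub in per_sample.groupby("group", sort=False):
        mean_dd = sub["ddct"].mean()
        sd = sub["delta_ct"].std(ddof=1) if len(sub) > 1 else 0.0
        rows.append(
            {
                "group": lab,
                "n": len(sub),
                "mean_delta_ct": sub["delta_ct"].mean(),
                "sd_delta_ct": sd,
                "mean_ddct": mean_dd,
                "fold": base ** (-mean_dd),
                "fold_lo": base ** (-(mean_dd + sd)),
                "fold_hi": base ** (-(mean_dd - sd)),
            }
        )
    return RelExprResult(
        goi=goi,
        refs=refs,
        calibrator=calibrator,
        per_sample=per_sample,
        group_stats=pd.DataFrame(rows),
        base=base,
    )


def compare_groups(
    result: RelExprResult, equal_var: bool = True
) -> dict[str, float]:
    """Two-tailed unpaired t-test on per-sample dCt between the two groups.

    Pooled-variance by default (``equal_var=False`` gives Welch's test).
    Returns {'t', 'df', 'p', 'group_a', 'group_b'}; the sign of t follows
    group_a - group_b in order of appearance.
    """
    per = result.per_sample
    labels = list(dict.fromkeys(per["group"]))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    a = per.loc[per["group"] == labels[0], "delta_ct"].to_numpy()
    b = per.loc[per["group"] == labels[1], "delta_ct"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = len(a) + len(b) - 2
    else:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
    return {
        "t": float(res.statistic),
        "df": float(df),
        "p": float(res.pvalue),
        "group_a": labels[0],
        "group_b": labels[1],
    }
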