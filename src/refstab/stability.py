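"""Reference-gene expression-stability estimators for two-group qPCR designs.

Implements the five rankings practitioners combine when validating
housekeeping genes:

* ``bestkeeper`` — dispersion of raw Ct per gene (SD, plus CV% of Ct);
* ``cv_method``  — coefficient of variation of linear relative quantities;
* ``delta_ct_method`` — mean SD of pairwise Ct differences;
* ``genorm``     — mean pairwise variation M with stepwise elimination,
  plus the V_{n/n+1} criterion for how many reference genes to use;
* ``normfinder`` — model-based decomposition into intergroup difference
  and intragroup variance.

All estimators consume a :class:`~refstab.ct_model.CtTable` restricted to a
single template kind; technical replicates are averaged to one mean Ct per
gene x sample first.  Relative quantities are

    Q_{g,s} = B_g ** (min_s Ct_{g,s} - Ct_{g,s})

with base B_g = 2 (perfect doubling) unless per-gene amplification
efficiencies are supplied, in which case B_g = 1 + E_g/100.

Every score is "ascending is better": the most stable gene has the
smallest score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ct_model import CtTable

__all__ = [
    "StabilityResult",
    "PairwiseVariationCurve",
    "bestkeeper",
    "cv_method",
    "delta_ct_method",
    "genorm",
    "genorm_pairwise_variation",
    "normfinder",
    "METHODS",
]

#: geNorm's published M cut-off below which a gene is a good reference.
GENORM_M_THRESHOLD = 0.5
#: geNorm's published V_{n/n+1} cut-off for the number of reference genes.
GENORM_V_THRESHOLD = 0.15
#: BestKeeper's published acceptance bound on the Ct standard deviation.
BESTKEEPER_SD_LIMIT = 1.0


@dataclass(frozen=True)
class StabilityResult:
    """Per-gene stability scores of one method, lower = more stable.

    ``ranking`` is the ascending-score permutation of the gene set
    (ties broken alphabetically; geNorm's final pair occupies ranks 1-2).
    ``extras`` holds method-specific per-gene columns (e.g. BestKeeper CV%
    and acceptance flags); ``metadata`` holds method-level results (e.g.
    geNorm elimination order, NormFinder best pair).
    """

    method: str
    scores: pd.Series
    ranking: tuple[str, ...]
    extras: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"gene": self.scores.index, "score": self.scores.values})
        out["rank"] = [self.ranking.index(g) + 1 for g in out["gene"]]
        if self.extras is not None:
            out = out.merge(
                self.extras.reset_index().rename(columns={"index": "gene"}),
                on="gene",
                how="left",
            )
        return out.sort_values("rank", kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class PairwiseVariationCurve:
    """geNorm V_{n/n+1} values and the implied number of reference genes.

    ``v`` maps n (2 .. k-1) to V_{n/n+1}; the recommendation is the
    smallest n whose V falls below ``threshold`` (0.15 by default), or k —
    all candidates — when none does.
    """

    v: dict[int, float]
    threshold: float
    recommended_n: int
    ranking: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": list(self.v),
                "v_n_n+1": list(self.v.values()),
                "below_threshold": [x < self.threshold for x in self.v.values()],
            }
        )


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _mean_matrix(table: CtTable, min_samples: int = 2) -> pd.DataFrame:
    m = table.matrix()
    if m.shape[1] < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {m.shape[1]}")
    return m


def _bases(
    genes: Sequence[str], efficiencies: Mapping[str, float] | None, base: float
) -> pd.Series:
    """Per-gene quantity base: 1 + E/100 when efficiencies given, else `base`."""
    if efficiencies is None:
        return pd.Series(base, index=list(genes), dtype=float)
    missing = [g for g in genes if g not in efficiencies]
    if missing:
        raise ValueError(f"no efficiency supplied for gene(s) {missing}")
    return pd.Series({g: 1.0 + efficiencies[g] / 100.0 for g in genes})


def log2_quantities(
    m: pd.DataFrame,
    efficiencies: Mapping[str, float] | None = None,
    base: float = 2.0,
) -> pd.DataFrame:
    """log2 of relative quantities: (min Ct - Ct) * log2(B_g), per gene row."""
    b = _bases(m.index, efficiencies, base)
    centered = m.min(axis=1).to_numpy()[:, None] - m.to_numpy()
    return pd.DataFrame(
        centered * np.log2(b.to_numpy())[:, None], index=m.index, columns=m.columns
    )


def _rank(scores: pd.Series) -> tuple[str, ...]:
    """Ascending-score order, ties broken alphabetically."""
    return tuple(sorted(scores.index, key=lambda g: (scores[g], g)))


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper(table: CtTable, variant: str = "sd") -> StabilityResult:
    """Dispersion of raw per-sample mean Ct; SD <= 1 cycle is acceptable.

    ``variant='sd'`` (default) scores each gene by the sample standard
    deviation (n-1 denominator) of its Ct values; ``variant='mad_geo'``
    uses the original BestKeeper spreadsheet's dispersion, the mean
    absolute deviation of Ct around the geometric mean Ct.  Both report
    CV% = 100 * score / arithmetic-mean Ct.
    """
    m = _mean_matrix(table)
    if variant == "sd":
        score = m.std(axis=1, ddof=1)
    elif variant == "mad_geo":
        geo = np.exp(np.log(m).mean(axis=1))
        score = (m.sub(geo, axis=0)).abs().mean(axis=1)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    cv = 100.0 * score / m.mean(axis=1)
    extras = pd.DataFrame(
        {"cv_pct": cv, "accepted": score <= BESTKEEPER_SD_LIMIT}
    )
    return StabilityResult(
        method="bestkeeper",
        scores=score,
        ranking=_rank(score),
        extras=extras,
        metadata={"variant": variant, "sd_limit": BESTKEEPER_SD_LIMIT},
    )


# ---------------------------------------------------------------------------
# CV of relative quantities
# ---------------------------------------------------------------------------

def cv_method(
    table: CtTable,
    efficiencies: Mapping[str, float] | None = None,
    base: float = 2.0,
) -> StabilityResult:
    """Coefficient of variation of linear relative quantities, in percent.

    Q_s = B ** (Ctmin - Ct_s) puts the most-abundant sample at Q = 1;
    the score is 100 * SD(Q) / mean(Q) per gene.
    """
    m = _mean_matrix(table)
    b = _bases(m.index, efficiencies, base)
    q = np.power(
        b.to_numpy()[:, None], m.min(axis=1).to_numpy()[:, None] - m.to_numpy()
    )
    q = pd.DataFrame(q, index=m.index, columns=m.columns)
    score = 100.0 * q.std(axis=1, ddof=1) / q.mean(axis=1)
    return StabilityResult(method="cv", scores=score, ranking=_rank(score))


# ---------------------------------------------------------------------------
# comparative delta-Ct
# ---------------------------------------------------------------------------

def delta_ct_method(table: CtTable) -> StabilityResult:
    """Mean SD of pairwise Ct differences.

    For every gene pair (i, j) the per-sample difference Ct_i - Ct_j has a
    sample SD; a gene's score is the average of those SDs over all pairs it
    belongs to.  Genes that co-vary with the panel get low scores.
    """
    m = _mean_matrix(table)
    genes = list(m.index)
    if len(genes) < 3:
        raise ValueError("delta-Ct method needs >= 3 genes")
    pair_sd: dict[frozenset, float] = {}
    for i, j in combinations(genes, 2):
        pair_sd[frozenset((i, j))] = float((m.loc[i] - m.loc[j]).std(ddof=1))
    score = pd.Series(
        {
            g: float(np.mean([sd for pair, sd in pair_sd.items() if g in pair]))
            for g in genes
        }
    ).loc[genes]
    meta = {"pair_sd": {tuple(sorted(p)): sd for p, sd in pair_sd.items()}}
    return StabilityResult(
        method="delta_ct", scores=score, ranking=_rank(score), metadata=meta
    )


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def _genorm_m(logq: pd.DataFrame) -> pd.Series:
    """Mean pairwise variation M_j = mean_k SD_s(log2 Q_j - log2 Q_k)."""
    genes = list(logq.index)
    a = logq.to_numpy()
    m = np.zeros(len(genes))
    for idx, _ in enumerate(genes):
        diffs = a[idx][None, :] - a  # each other gene vs this one
        sds = np.std(np.delete(diffs, idx, axis=0), axis=1, ddof=1)
        m[idx] = sds.mean()
    return pd.Series(m, index=genes)


def genorm(
    table: CtTable,
    efficiencies: Mapping[str, float] | None = None,
    base: float = 2.0,
    m_threshold: float = GENORM_M_THRESHOLD,
) -> StabilityResult:
    """Stepwise geNorm: eliminate the highest-M gene until a pair remains.

    A gene's score is its M value in the round it was eliminated (for the
    two survivors, their mutual pairwise variation).  The ranking places
    the final pair — unresolvable by the method — at positions 1-2 in
    alphabetical order, then the other genes in reverse elimination order.
    Ties at the maximal M are broken by removing the lexicographically
    later gene id.  Genes with M above ``m_threshold`` (0.5) are flagged
    as unsuitable references.
    """
    m = _mean_matrix(table)
    if m.shape[0] < 3:
        raise ValueError("geNorm needs >= 3 genes")
    logq = log2_quantities(m, efficiencies, base)
    surviving = list(logq.index)
    eliminated: list[str] = []
    m_at_elimination: dict[str, float] = {}
    rounds: list[dict[str, float]] = []
    while len(surviving) > 2:
        mv = _genorm_m(logq.loc[surviving])
        rounds.append(mv.to_dict())
        worst = max(surviving, key=lambda g: (mv[g], g))
        m_at_elimination[worst] = float(mv[worst])
        eliminated.append(worst)
        surviving.remove(worst)
    final_mv = _genorm_m(logq.loc[surviving])
    rounds.append(final_mv.to_dict())
    pair = tuple(sorted(surviving))
    pair_m = float(final_mv.iloc[0])  # mutual V: identical for both survivors
    for g in pair:
        m_at_elimination[g] = pair_m
    scores = pd.Series(m_at_elimination).loc[list(logq.index)]
    ranking = tuple(list(pair) + list(reversed(eliminated)))
    extras = pd.DataFrame({"suitable": scores <= m_threshold})
    return StabilityResult(
        method="genorm",
        scores=scores,
        ranking=ranking,
        extras=extras,
        metadata={
            "elimination_order": tuple(eliminated),
            "rounds": rounds,
            "best_pair": pair,
            "best_pair_m": pair_m,
            "m_threshold": m_threshold,
        },
    )


def genorm_pairwise_variation(
    table: CtTable,
    ranking: Sequence[str] | StabilityResult | None = None,
    threshold: float = GENORM_V_THRESHOLD,
    efficiencies: Mapping[str, float] | None = None,
    base: float = 2.0,
) -> PairwiseVariationCurve:
    """V_{n/n+1} between normalization factors of the n and n+1 best genes.

    NF_n,s is the geometric mean of the relative quantities of the n
    top-ranked genes in sample s; V_{n/n+1} = SD_s log2(NF_n,s / NF_{n+1,s}).
    The smallest n with V below the 0.15 threshold is the recommended
    number of reference genes (k if none qualifies).  Uses the geNorm
    ranking, computed on the fly when not supplied.
    """
    m = _mean_matrix(table)
    if m.shape[0] < 3:
        raise ValueError("pairwise variation needs >= 3 genes")
    if ranking is None:
        ranking = genorm(table, efficiencies=efficiencies, base=base).ranking
    elif isinstance(ranking, StabilityResult):
        ranking = ranking.ranking
    ranking = list(ranking)
    if sorted(ranking) != sorted(m.index):
        raise ValueError("ranking is not a permutation of the table's genes")
    logq = log2_quantities(m, efficiencies, base).loc[ranking]
    k = len(ranking)
    v: dict[int, float] = {}
    for n in range(2, k):
        nf_n = logq.iloc[:n].mean(axis=0)  # log2 of geometric-mean NF
        nf_n1 = logq.iloc[: n + 1].mean(axis=0)
        v[n] = float((nf_n - nf_n1).std(ddof=1))
    below = [n for n, x in v.items() if x < threshold]
    recommended = min(below) if below else k
    return PairwiseVariationCurve(
        v=v, threshold=threshold, recommended_n=recommended, ranking=tuple(ranking)
    )


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def normfinder(
    table: CtTable,
    efficiencies: Mapping[str, float] | None = None,
    base: float = 2.0,
) -> StabilityResult:
    """Model-based stability combining intergroup shift and intragroup noise.

    On log2 expression y = log2(Q), the model per group g is
    y_{igj} = alpha_{ig} + beta_{gj} + eps_{igj} with gene effects alpha,
    sample effects beta and gene-specific noise eps ~ N(0, sigma^2_{ig}).

    Per group, intragroup variances come from double-centred residuals
    z = y - gene mean - sample mean + group mean via the small-sample
    correction

        sigma2_hat_ig = k/(k-2) * (s2_ig - s2bar_g / (k-1)),  truncated at 0,

    where s2_ig = sum_j z^2 / (n_g - 1) and k is the number of genes.  The
    intergroup difference d_ig (gene-centred group mean minus gene-centred
    grand mean; sums to zero over genes within a group) is shrunk toward 0
    with an empirical-Bayes factor gamma^2/(gamma^2 + var(d_hat)), and the
    stability value is

        rho_ig = |d_tilde_ig| + sqrt(var(d_hat_ig) * gamma^2/(gamma^2 + var(d_hat_ig)))

    averaged over the two groups.  In the degenerate case gamma^2 = 0 (the
    spread of d_hat across genes does not exceed its sampling variance)
    shrinkage would tie every gene at 0; the model then carries no
    intergroup information and the stability value falls back to
    sqrt(var(d_hat_ig)), ranking genes by intragroup variance alone.
    The best two-gene combination minimises the same quantity computed for
    the pair average (d averaged, variance quartered).
    """
    m = _mean_matrix(table)
    genes = list(m.index)
    k = len(genes)
    if k < 3:
        raise ValueError("NormFinder needs >= 3 genes")
    groups = table.groups.loc[m.columns]
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"NormFinder needs exactly 2 groups, got {labels}")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has < 2 samples")
    y = log2_quantities(m, efficiencies, base)

    grand_gene_mean = y.mean(axis=1)  # per gene, over all samples
    grand_center = grand_gene_mean - grand_gene_mean.mean()

    d = pd.DataFrame(index=genes, columns=labels, dtype=float)
    sigma2 = pd.DataFrame(index=genes, columns=labels, dtype=float)
    var_d = pd.DataFrame(index=genes, columns=labels, dtype=float)
    n_by_group: dict[str, int] = {}
    for lab in labels:
        sub = y.loc[:, groups[groups == lab].index]
        n_g = sub.shape[1]
        n_by_group[lab] = n_g
        gene_mean = sub.mean(axis=1)
        # intergroup difference, centred over genes within the group and
        # relative to the gene's grand-mean deviation
        d[lab] = (gene_mean - gene_mean.mean()) - grand_center
        # double-centred residuals within the group
        z = sub.sub(gene_mean, axis=0).sub(sub.mean(axis=0), axis=1) + sub.to_numpy().mean()
        s2 = (z**2).sum(axis=1) / (n_g - 1)
        corrected = (k / (k - 2)) * (s2 - s2.mean() / (k - 1))
        sigma2[lab] = corrected.clip(lower=0.0)
        var_d[lab] = sigma2[lab] / n_g

    # empirical-Bayes spread of true intergroup differences across genes
    gamma2 = float(
        (d.to_numpy() ** 2).sum() / (len(labels) * (k - 1))
        - var_d.to_numpy().mean()
    )
    gamma2 = max(gamma2, 0.0)
    if gamma2 > 0:
        shrink = gamma2 / (gamma2 + var_d)
        d_tilde = d * shrink
        rho_per_group = d_tilde.abs() + np.sqrt(var_d * shrink)
    else:
        shrink = var_d * 0.0
        d_tilde = d * 0.0
        rho_per_group = np.sqrt(var_d)
    rho = rho_per_group.mean(axis=1)

    # best two-gene combination: same criterion on the pair average
    pair_scores: dict[tuple[str, str], float] = {}
    for i, j in combinations(genes, 2):
        d_pair = (d.loc[i] + d.loc[j]) / 2.0
        var_pair = (var_d.loc[i] + var_d.loc[j]) / 4.0
        if gamma2 > 0:
            sh = gamma2 / (gamma2 + var_pair)
            score = float(((d_pair * sh).abs() + np.sqrt(var_pair * sh)).mean())
        else:
            score = float(np.sqrt(var_pair).mean())
        pair_scores[(i, j)] = score
    best_pair = min(pair_scores, key=lambda p: (pair_scores[p], p))

    extras = pd.DataFrame(
        {
            f"d_{lab}": d[lab] for lab in labels
        }
        | {f"sigma2_{lab}": sigma2[lab] for lab in labels}
    )
    return StabilityResult(
        method="normfinder",
        scores=rho.loc[genes],
        ranking=_rank(rho),
        extras=extras,
        metadata={
            "groups": tuple(labels),
            "n_by_group": n_by_group,
            "gamma2": gamma2,
            "best_pair": tuple(sorted(best_pair)),
            "best_pair_score": pair_scores[best_pair],
            "intergroup_d": d.to_dict(),
            "intragroup_var": sigma2.to_dict(),
        },
    )


#: Registry used by the CLI and the ranking aggregator.
METHODS = {
    "bestkeeper": bestkeeper,
    "cv": cv_method,
    "delta_ct": delta_ct_method,
    "genorm": genorm,
    "normfinder": normfinder,
}
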