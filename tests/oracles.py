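"""Naive, loop-based reference implementations of the stability estimators.

These deliberately avoid numpy/pandas vectorisation and the package's own
code paths: plain dict/list arithmetic with the ``statistics`` module, so
they can serve as independent oracles for the optimized implementations.
Matrices are dicts gene -> list of per-sample mean Ct; ``groups`` is a
list of group labels aligned with the sample axis.
"""

from __future__ import annotations

import math
import statistics


def sd(xs):
    return statistics.stdev(xs)  # n-1 denominator


def mean(xs):
    return sum(xs) / len(xs)


def log2q(mat, base=2.0):
    out = {}
    for g, v in mat.items():
        m = min(v)
        out[g] = [(m - x) * math.log2(base) for x in v]
    return out


def bestkeeper_sd(mat):
    return {g: sd(v) for g, v in mat.items()}


def cv_of_quantities(mat, base=2.0):
    out = {}
    for g, v in mat.items():
        q = [base ** (min(v) - x) for x in v]
        out[g] = 100.0 * sd(q) / mean(q)
    return out


def delta_ct_scores(mat):
    genes = list(mat)
    out = {}
    for g in genes:
        sds = [
            sd([a - b for a, b in zip(mat[g], mat[h])]) for h in genes if h != g
        ]
        out[g] = mean(sds)
    return out


def genorm_m(mat, base=2.0):
    lq = log2q(mat, base)
    genes = list(mat)
    out = {}
    for g in genes:
        vs = [
            sd([a - b for a, b in zip(lq[g], lq[h])]) for h in genes if h != g
        ]
        out[g] = mean(vs)
    return out


def genorm_elimination(mat, base=2.0):
    """Stepwise removal of the highest-M gene (ties: later gene id)."""
    surviving = list(mat)
    order = []
    m_at_drop = {}
    while len(surviving) > 2:
        mv = genorm_m({g: mat[g] for g in surviving}, base)
        worst = max(surviving, key=lambda g: (mv[g], g))
        m_at_drop[worst] = mv[worst]
        order.append(worst)
        surviving.remove(worst)
    final = genorm_m({g: mat[g] for g in surviving}, base)
    pair = tuple(sorted(surviving))
    for g in pair:
        m_at_drop[g] = final[g]
    return order, pair, m_at_drop


def pairwise_variation(mat, ranking, base=2.0):
    lq = log2q(mat, base)
    n_samples = len(next(iter(mat.values())))
    k = len(ranking)
    out = {}
    for n in range(2, k):
        diffs = []
        for s in range(n_samples):
            nf_n = mean([lq[g][s] for g in ranking[:n]])
            nf_n1 = mean([lq[g][s] for g in ranking[: n + 1]])
            diffs.append(nf_n - nf_n1)
        out[n] = sd(diffs)
    return out


def normfinder_rho(mat, groups, base=2.0):
    """Loop-based NormFinder: variance correction, shrinkage, stability."""
    lq = log2q(mat, base)
    genes = list(mat)
    k = len(genes)
    labels = list(dict.fromkeys(groups))
    idx = {lab: [i for i, g in enumerate(groups) if g == lab] for lab in labels}

    grand = {g: mean(lq[g]) for g in genes}
    grand_center = {g: grand[g] - mean(list(grand.values())) for g in genes}

    d = {}
    var_d = {}
    for lab in labels:
        cols = idx[lab]
        n_g = len(cols)
        gmean = {g: mean([lq[g][i] for i in cols]) for g in genes}
        gmean_avg = mean(list(gmean.values()))
        smean = {
            i: mean([lq[g][i] for g in genes]) for i in cols
        }
        total = mean([lq[g][i] for g in genes for i in cols])
        s2 = {}
        for g in genes:
            z = [lq[g][i] - gmean[g] - smean[i] + total for i in cols]
            s2[g] = sum(x * x for x in z) / (n_g - 1)
        s2bar = mean(list(s2.values()))
        for g in genes:
            sig2 = max(0.0, (k / (k - 2)) * (s2[g] - s2bar / (k - 1)))
            var_d[(g, lab)] = sig2 / n_g
            d[(g, lab)] = (gmean[g] - gmean_avg) - grand_center[g]

    gamma2 = sum(v * v for v in d.values()) / (len(labels) * (k - 1)) - mean(
        list(var_d.values())
    )
    gamma2 = max(gamma2, 0.0)
    rho = {}
    for g in genes:
        parts = []
        for lab in labels:
            vd = var_d[(g, lab)]
            if gamma2 > 0:
                sh = gamma2 / (gamma2 + vd)
                parts.append(abs(d[(g, lab)] * sh) + math.sqrt(vd * sh))
            else:
                parts.append(math.sqrt(vd))
        rho[g] = mean(parts)
    return rho
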