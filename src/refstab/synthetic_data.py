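"""Seeded generators for Ct tables, dilution series and FPKM tables.

The Ct generator draws from the additive error model the estimators
assume, on the Ct (log-quantity) scale:

    Ct_{g,s,r} = mu_g + delta_g * [s in group B] + L_s + b_{g,s} + tau_{g,s,r}

with a shared per-sample loading shift L_s ~ N(0, sigma_load^2) (cancels
in every ratio-based statistic), biological noise b ~ N(0, sigma_bio_g^2)
and technical noise tau ~ N(0, sigma_tech^2).  A designed group effect
delta_g (cycles) corresponds to a quantity fold of 2^-delta_g in group B.
Each simulation returns the table together with its ground truth.

The ``sea-urchin-7gene`` preset mirrors a 7-candidate egg/cortex design:
3 + 3 samples in technical triplicate, baseline Ct means spanning ~15.6
(an rRNA, most abundant) to ~28 (a glycolytic enzyme, least abundant),
one deliberately quiet gene (the designed most-stable reference), one
noisy rRNA with a +1-cycle cortex shift (designed least stable), and a
2-fold cortex-enriched gene of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ct_model import CtTable
from .efficiency import DilutionSeries
from .candidate_screen import FpkmTable

__all__ = [
    "GeneParams",
    "SimulationConfig",
    "GroundTruth",
    "simulate_ct_experiment",
    "simulate_dilution_series",
    "simulate_fpkm_table",
    "sea_urchin_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class GeneParams:
    """Per-gene truth: baseline mean Ct, group shift (cycles; positive =
    higher Ct, i.e. *less* transcript, in group B) and biological SD."""

    mu: float
    sigma_bio: float
    delta: float = 0.0
    role: str = "reference"  # or "goi"

    def __post_init__(self):
        if self.sigma_bio < 0:
            raise ValueError("sigma_bio must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    genes: dict[str, GeneParams]
    groups: tuple[str, str] = ("egg", "cortex")
    samples_per_group: int = 3
    technical_replicates: int = 3
    sigma_load: float = 0.2
    sigma_tech: float = 0.15
    template: str = "total"
    seed: int = 0

    def __post_init__(self):
        if not self.genes:
            raise ValueError("config has no genes")
        if self.samples_per_group < 1 or self.technical_replicates < 1:
            raise ValueError("samples_per_group and technical_replicates must be >= 1")
        if self.sigma_load < 0 or self.sigma_tech < 0:
            raise ValueError("noise SDs must be >= 0")
        if len(set(self.groups)) != 2:
            raise ValueError("need two distinct group labels")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator put in: quantity folds (group B vs A) and the
    designed most-stable gene (zero shift, smallest biological SD)."""

    fold: dict[str, float]
    most_stable: str
    least_stable: str
    config: SimulationConfig


def _truth(config: SimulationConfig) -> GroundTruth:
    refs = {n: p for n, p in config.genes.items() if p.role == "reference"}
    stable = min(
        (n for n, p in refs.items() if p.delta == 0),
        key=lambda n: (refs[n].sigma_bio, n),
    )
    least = max(
        refs, key=lambda n: (refs[n].sigma_bio + abs(refs[n].delta), n)
    )
    return GroundTruth(
        fold={n: 2.0 ** -p.delta for n, p in config.genes.items()},
        most_stable=stable,
        least_stable=least,
        config=config,
    )


def simulate_ct_experiment(
    config: SimulationConfig,
) -> tuple[CtTable, GroundTruth]:
    """Draw one seeded Ct experiment from the additive error model."""
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    n_per = config.samples_per_group
    reps = config.technical_replicates
    samples = [
        (f"{grp}{i + 1}", grp, gi)
        for gi, grp in enumerate(config.groups)
        for i in range(n_per)
    ]
    load = rng.normal(0.0, config.sigma_load, size=len(samples))
    records = []
    for g in genes:
        p = config.genes[g]
        for si, (sample, grp, gi) in enumerate(samples):
            bio = rng.normal(0.0, p.sigma_bio)
            mean_ct = p.mu + p.delta * (gi == 1) + load[si] + bio
            tech = rng.normal(0.0, config.sigma_tech, size=reps)
            for r in range(reps):
                records.append(
                    {
                        "gene": g,
                        "sample": sample,
                        "group": grp,
                        "template": config.template,
                        "replicate": r + 1,
                        "ct": mean_ct + tech[r],
                    }
                )
    return CtTable.from_frame(pd.DataFrame(records)), _truth(config)


def simulate_dilution_series(
    efficiency: float = 100.0,
    intercept: float = 20.0,
    n_points: int = 5,
    fold_step: float = 4.0,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    gene: str = "sim",
) -> tuple[DilutionSeries, float]:
    """Serial dilution consistent with a chosen true efficiency (%).

    Ct(d) = intercept - log2(d) / log2(1 + E/100) + N(0, noise_sd^2);
    dilutions run 1, 1/fold_step, 1/fold_step^2, ...  Returns the series
    and the true efficiency.
    """
    if not (0 < efficiency <= 150):
        raise ValueError("efficiency must be in (0, 150] percent")
    if n_points < 3 or fold_step <= 1 or replicates < 1 or noise_sd < 0:
        raise ValueError("invalid dilution-series parameters")
    rng = np.random.default_rng(seed)
    base = 1.0 + efficiency / 100.0
    points = []
    for i in range(n_points):
        d = fold_step ** -i
        ct = intercept - np.log2(d) / np.log2(base)
        reps = tuple(float(ct + rng.normal(0, noise_sd)) for _ in range(replicates))
        points.append((d, reps))
    return DilutionSeries(gene=gene, points=tuple(points)), efficiency


def simulate_fpkm_table(
    n_transcripts: int = 100,
    mean_log10_fpkm: float = 2.0,
    sd_log10_fpkm: float = 1.0,
    enriched_fraction: float = 0.1,
    enrichment_fold: float = 5.0,
    noise_sd_log10: float = 0.0,
    seed: int = 0,
) -> tuple[FpkmTable, set[str]]:
    """Log-normal abundances with a designated cortex-enriched subset.

    Returns the table and the set of enriched transcript ids (the truth
    for screen-recovery checks).
    """
    if n_transcripts < 1 or not (0 <= enriched_fraction <= 1):
        raise ValueError("invalid FPKM simulation parameters")
    if enrichment_fold <= 1 or sd_log10_fpkm < 0 or noise_sd_log10 < 0:
        raise ValueError("invalid FPKM simulation parameters")
    rng = np.random.default_rng(seed)
    ids = [f"tx{i:04d}" for i in range(n_transcripts)]
    base = 10 ** rng.normal(mean_log10_fpkm, sd_log10_fpkm, size=n_transcripts)
    n_enriched = int(round(enriched_fraction * n_transcripts))
    enriched = set(rng.choice(ids, size=n_enriched, replace=False).tolist())
    fold = np.array([enrichment_fold if t in enriched else 1.0 for t in ids])
    noise_a = 10 ** rng.normal(0, noise_sd_log10, size=n_transcripts)
    noise_b = 10 ** rng.normal(0, noise_sd_log10, size=n_transcripts)
    df = pd.DataFrame(
        {
            "transcript": ids,
            "fpkm_egg": base * noise_a,
            "fpkm_cortex": base * fold * noise_b,
        }
    )
    return FpkmTable(df), enriched


def sea_urchin_preset(seed: int = 0) -> SimulationConfig:
    """The ``sea-urchin-7gene`` preset: 7 reference candidates + 1 GOI.

    Baseline Ct means follow the observed abundance ordering of the
    egg/cortex panel (rRNA most abundant at ~15.6 cycles, GAPDH least at
    ~28).  Instability of the non-designed genes is carried mainly by
    egg-vs-cortex shifts (the dominant real effect when comparing whole
    eggs with isolated cortices, where transcript composition differs
    strongly) plus moderate biological noise; the shifts alternate in
    sign, sum to zero and are mutually well separated, so that exactly
    one gene — Ubb, zero shift and the smallest noise SD — is the
    designed most-stable reference, identifiable by every estimator at
    the small real-world sample size (3 + 3).  The rRNA combines the
    largest shift with the largest noise and is the designed least
    stable (its observed Ct range spans ~5 cycles, like real total-RNA
    rRNA data).  Ebr1 doubles as a mildly shifted, low-noise partner so
    that a best *pair* exists for pair-based methods.  The GOI (Daglb-2)
    is 2-fold enriched in cortices (delta = -1 cycle).
    """
    genes = {
        "28S": GeneParams(mu=15.6, sigma_bio=0.6, delta=3.5),
        "Ubb": GeneParams(mu=15.9, sigma_bio=0.03),
        "Cycb": GeneParams(mu=19.0, sigma_bio=0.42, delta=-2.2),
        "Ebr1": GeneParams(mu=20.3, sigma_bio=0.10, delta=-0.6),
        "Smtnl1": GeneParams(mu=21.5, sigma_bio=0.42, delta=0.7),
        "Hmg1": GeneParams(mu=24.0, sigma_bio=0.42, delta=2.1),
        "GAPDH": GeneParams(mu=28.0, sigma_bio=0.42, delta=-3.5),
        "Daglb-2": GeneParams(mu=26.0, sigma_bio=0.3, delta=-1.0, role="goi"),
    }
    return SimulationConfig(genes=genes, sigma_load=0.05, seed=seed)


PRESETS = {"sea-urchin-7gene": sea_urchin_preset}
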