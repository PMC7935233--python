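"""Synthetic genotype-phenotype cohorts with the structure the method assumes.

Genotypes are drawn per SNP from Hardy-Weinberg proportions (p^2, 2pq, q^2)
at a minor-allele frequency, coded 1 (major homozygote), 2 (heterozygote),
3 (minor homozygote).  The integer outcome ΔSSE is Gaussian baseline noise
plus small additive planted-allele effects on the -1/0/+1 orientation scale
(the same scale the recoding step estimates), rounded to an integer event
count.  The noise scale echoes the event-count variability of a two-week
diary period (run-in counts with mean ~3.6, SD ~2.6).

Ground truth (which SNPs were planted and in which direction) is returned so
recovery by the derivation pipeline can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seeds import stream_rng
from .genotype_io import GenotypeMatrix, OutcomeData

#: categories: 1 = major homozygote, 2 = heterozygote, 3 = minor homozygote
_ORIENT = {1: -1.0, 2: 0.0, 3: +1.0}


@dataclass(frozen=True)
class Scenario:
    """Cohort-generation parameters.

    ``maf`` is either a single minor-allele frequency in (0, 0.5] applied to
    every SNP or a ``(low, high)`` range from which each SNP's frequency is
    drawn uniformly.  ``effect_size`` is the additive shift of ΔSSE per +1
    step of the true orientation (outcome units).
    """

    n_subjects: int = 129
    n_snps: int = 285
    n_planted: int = 0
    maf: float | tuple[float, float] = (0.1, 0.5)
    effect_size: float = 0.0
    baseline_mean: float = 0.5
    baseline_sd: float = 2.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_planted <= self.n_snps:
            raise ValueError("n_planted must lie in [0, n_snps]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")

    @property
    def maf_range(self) -> tuple[float, float]:
        if isinstance(self.maf, (int, float)):
            return (float(self.maf), float(self.maf))
        lo, hi = self.maf
        return (float(lo), float(hi))

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_snps": self.n_snps,
            "n_planted": self.n_planted,
            "maf": list(self.maf) if isinstance(self.maf, tuple) else self.maf,
            "effect_size": self.effect_size,
            "baseline_mean": self.baseline_mean,
            "baseline_sd": self.baseline_sd,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Scenario":
        payload = dict(payload)
        if isinstance(payload.get("maf"), list):
            payload["maf"] = tuple(payload["maf"])
        return cls(**payload)


#: preset study conditions: a cohort of 129 subjects typed on a 285-SNP
#: candidate panel, with 20 planted alleles of strong (0.8), moderate (0.4)
#: or absent effect against baseline noise of SD 2.5.
_PRESETS = {
    "strong": dict(n_subjects=129, n_snps=285, n_planted=20,
                   effect_size=0.8, baseline_sd=2.5, seed=20),
    "moderate": dict(n_subjects=129, n_snps=285, n_planted=20,
                     effect_size=0.4, baseline_sd=2.5, seed=21),
    "null": dict(n_subjects=129, n_snps=285, n_planted=0,
                 effect_size=0.0, baseline_sd=2.5, seed=22),
}


def make_scenario(name: str, **overrides) -> Scenario:
    """Fixed presets: "strong", "moderate", "null" (documented seeds)."""
    try:
        params = dict(_PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(_PRESETS)}") from None
    params.update(overrides)
    return Scenario(**params)


def generate_genotype_matrix(s: Scenario) -> GenotypeMatrix:
    """Draw a subjects x SNPs category matrix under Hardy-Weinberg equilibrium."""
    rng = stream_rng(s.seed, "genotypes")
    lo, hi = s.maf_range
    q = rng.uniform(lo, hi, size=s.n_snps) if lo < hi else np.full(s.n_snps, lo)
    p = 1.0 - q
    probs = np.column_stack([p * p, 2 * p * q, q * q])  # categories 1, 2, 3
    u = rng.random((s.n_subjects, s.n_snps))
    cum1 = probs[:, 0]
    cum2 = probs[:, 0] + probs[:, 1]
    cats = np.where(u < cum1, 1.0, np.where(u < cum2, 2.0, 3.0))
    if s.missing_rate > 0:
        drop = rng.random((s.n_subjects, s.n_snps)) < s.missing_rate
        cats = np.where(drop, np.nan, cats)
    subjects = [f"S{i + 1:04d}" for i in range(s.n_subjects)]
    snps = [f"rs{j + 1:05d}" for j in range(s.n_snps)]
    return GenotypeMatrix(pd.DataFrame(cats, index=subjects, columns=snps))


def generate_outcomes(
    g: GenotypeMatrix, s: Scenario
) -> tuple[OutcomeData, pd.DataFrame]:
    """Integer ΔSSE = round(baseline noise + planted additive effects).

    The first ``n_planted`` SNPs carry an effect of ``effect_size`` per +1
    step of a random true orientation (+1: minor allele raises the outcome,
    -1: lowers it).  Returns the outcomes and a ground-truth frame with
    columns ``snp_id`` and ``direction``.
    """
    rng = stream_rng(s.seed, "outcomes")
    planted = list(g.snp_ids[: s.n_planted])
    directions = rng.choice([-1, 1], size=len(planted))
    signal = np.zeros(g.n_subjects)
    for snp, direction in zip(planted, directions):
        col = g.data[snp].to_numpy(dtype=float)
        orient = np.zeros_like(col)
        for cat, val in _ORIENT.items():
            orient[col == cat] = val * direction
        orient[np.isnan(col)] = 0.0
        signal += s.effect_size * orient
    noise = rng.normal(s.baseline_mean, s.baseline_sd, size=g.n_subjects)
    delta = np.round(noise + signal).astype(int)
    outcome = OutcomeData(delta_sse=pd.Series(delta, index=g.data.index))
    truth = pd.DataFrame({"snp_id": planted, "direction": directions.astype(int)})
    return outcome, truth


def generate_cohort(s: Scenario) -> tuple[GenotypeMatrix, OutcomeData, pd.DataFrame]:
    """Genotypes + outcomes + ground truth in one call."""
    g = generate_genotype_matrix(s)
    outcome, truth = generate_outcomes(g, s)
    return g, outcome, truth


def with_seed(s: Scenario, seed: int) -> Scenario:
    """Same scenario, different seed (for repeated-run experiments)."""
    return replace(s, seed=int(seed))
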