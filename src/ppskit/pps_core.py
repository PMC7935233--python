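"""Survival-of-the-fittest allele selection and the summed prediction score.

The method derives, from a small cohort, a Phenotype Prediction Score (PPS):
a per-subject sum of -1/0/+1 allele scores over the SNPs whose association
with the dichotomised outcome proved *stable* under repeated random
half-splitting of the derivation sample.  The stages, in order:

1.  subjects are paired by outcome and split into a first derivation set and
    an intermediary set (outcome-matched, e.g. 65/64 at n = 129);
2.  on the first derivation set, mean raw ΔSSE per genotype category orients
    each SNP: lowest-mean category -> -1, highest -> +1, middle -> 0
    (the recoded variable ``A``);
3.  alleles whose Pearson correlation with the dichotomised outcome ΔSSE_D
    falls below 0.1 on the first derivation set are dropped;
4.  ``A`` is split into a negative-risk indicator ``A1`` (values -1/0) and a
    positive-risk indicator ``A2`` (0/+1); on a random half of the first
    derivation set the better-correlating sign is chosen per SNP;
5.  stability filtering: the sample is randomly halved, correlations with
    ΔSSE_D computed in both halves, and any allele below 0 in either half is
    dropped; reshuffle and repeat (twice on the first derivation set);
6.  half of the intermediary set joins the derivation set (97/32 at n = 129)
    and two further stability rounds run on this final derivation set;
7.  the surviving alleles' scores are summed per subject — the companion
    demarcation formula — and evaluated on the held-out validation set.

Orientation means use raw ΔSSE; every correlation filter uses ΔSSE_D.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import stream_rng
from .config import RunConfig
from .errors import ScoringError, SizeError
from .genotype_io import (
    GenotypeMatrix,
    OutcomeData,
    drop_snps_with_missing,
    exclude_low_count_snps,
)
from .sampling import (
    SplitAssignment,
    finalize_derivation_validation,
    matched_binary_assignment,
    random_half_split,
)

logger = logging.getLogger(__name__)

NEGATIVE_RISK = "A1"
POSITIVE_RISK = "A2"


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; NaN when undefined.

    Pairs with a missing value in either vector are removed first.  The
    result is NaN when fewer than 3 complete pairs remain or either vector
    has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SizeError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float((xc @ yc) / denom)


def columnwise_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``X`` with ``y``, pairwise-complete.

    Vectorised over columns; NaN where fewer than 3 complete pairs remain or
    where either marginal is constant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    if X.shape[0] != y.shape[0]:
        raise SizeError(f"length mismatch: {X.shape[0]} rows vs {y.shape[0]} outcomes")
    mask = ~(np.isnan(X) | np.isnan(y))
    n = mask.sum(axis=0).astype(float)
    Xf = np.where(mask, X, 0.0)
    Yf = np.where(mask, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = Xf.sum(axis=0)
        sy = Yf.sum(axis=0)
        sxx = (Xf * Xf).sum(axis=0)
        syy = (Yf * Yf).sum(axis=0)
        sxy = (Xf * Yf).sum(axis=0)
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        # clamp tiny negative round-off before the sqrt
        denom = np.sqrt(np.maximum(vx, 0.0) * np.maximum(vy, 0.0))
        r = cov / denom
    r[(n < 3) | (denom <= 0.0) | ~np.isfinite(r)] = np.nan
    return r


# ---------------------------------------------------------------------------
# recoding
# ---------------------------------------------------------------------------


def compute_allele_means(
    g: GenotypeMatrix, outcome: OutcomeData, subset: Sequence
) -> dict:
    """Mean raw ΔSSE per observed genotype category, per SNP, over ``subset``.

    Categories unobserved in the subset are absent from the mapping; a SNP
    whose mapping has fewer than two categories cannot be recoded and is
    flagged for exclusion downstream.
    """
    subset = list(subset)
    if not subset:
        raise SizeError("subset of subjects is empty")
    sub = g.data.loc[subset]
    delta = outcome.delta_sse.loc[subset].to_numpy(dtype=float)
    values = sub.to_numpy(dtype=float)
    means: dict = {}
    for j, snp in enumerate(sub.columns):
        col = values[:, j]
        per_cat: dict[int, float] = {}
        for cat in (1, 2, 3):
            sel = col == cat
            if sel.any():
                per_cat[cat] = float(delta[sel].mean())
        means[snp] = per_cat
    return means


def derive_recoding(means: Mapping[int, float]) -> dict[int, int]:
    """Orient a SNP's categories by their outcome means.

    Lowest mean -> -1, highest -> +1, a middle category -> 0.  Ties are
    broken by the lower category code taking the lower rank, so the map is a
    deterministic function of the means.
    """
    if len(means) < 2:
        raise SizeError(
            f"recoding needs at least 2 observed categories, got {len(means)}"
        )
    ranked = sorted(means, key=lambda cat: (means[cat], cat))
    recode = {cat: 0 for cat in ranked}
    recode[ranked[0]] = -1
    recode[ranked[-1]] = +1
    return recode


def apply_recoding(
    g: GenotypeMatrix, maps: Mapping[str, Mapping[int, int]]
) -> pd.DataFrame:
    """Replace genotype categories by their -1/0/+1 scores (the ``A`` matrix).

    Missing stays missing; a category present in the data but absent from the
    SNP's map (unseen during derivation) becomes missing and is logged.
    """
    missing_maps = [s for s in g.snp_ids if s not in maps]
    if missing_maps:
        raise KeyError(f"no recode map for SNPs: {missing_maps}")
    out = np.full(g.data.shape, np.nan)
    values = g.data.to_numpy(dtype=float)
    for j, snp in enumerate(g.snp_ids):
        recode = maps[snp]
        col = values[:, j]
        for cat in (1, 2, 3):
            sel = col == cat
            if not sel.any():
                continue
            if cat in recode:
                out[sel, j] = recode[cat]
            else:
                logger.info(
                    "SNP %s: category %d unseen in derivation, %d cell(s) treated as missing",
                    snp, cat, int(sel.sum()),
                )
    return pd.DataFrame(out, index=g.data.index, columns=g.data.columns)


def split_signed_indicators(A: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split ``A`` into the negative-risk (A1) and positive-risk (A2) parts.

    A1 keeps the -1 cells (others 0), A2 keeps the +1 cells; missing
    propagates, and A1 + A2 reconstructs A elementwise.
    """
    arr = A.to_numpy(dtype=float)
    a1 = np.where(np.isnan(arr), np.nan, np.where(arr == -1, -1.0, 0.0))
    a2 = np.where(np.isnan(arr), np.nan, np.where(arr == +1, +1.0, 0.0))
    return (
        pd.DataFrame(a1, index=A.index, columns=A.columns),
        pd.DataFrame(a2, index=A.index, columns=A.columns),
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def initial_correlation_filter(
    A: pd.DataFrame,
    outcome: OutcomeData,
    subset: Sequence,
    threshold: float = 0.1,
) -> list:
    """Keep SNPs whose recoded allele correlates with ΔSSE_D at >= threshold.

    Undefined correlations (constant columns) fail the filter.  An empty
    survivor set is allowed (logged), not an error.
    """
    subset = list(subset)
    r = columnwise_pearson(
        A.loc[subset].to_numpy(), outcome.delta_sse_d.loc[subset].to_numpy()
    )
    keep = [snp for snp, ri in zip(A.columns, r) if not np.isnan(ri) and ri >= threshold]
    if not keep:
        logger.warning("initial correlation filter removed every SNP")
    return keep


def select_signed_variant(a1_col, a2_col, outcome_d, subset=None) -> str | None:
    """Pick the better-correlating sign (A1 vs A2) for one SNP.

    Signed correlations with ΔSSE_D are compared; if one is undefined the
    other wins; if both are undefined the SNP is excluded (None); an exact
    tie goes to the positive-risk variant A2.
    """
    if subset is not None:
        a1_col = pd.Series(a1_col).loc[list(subset)]
        a2_col = pd.Series(a2_col).loc[list(subset)]
        outcome_d = pd.Series(outcome_d).loc[list(subset)]
    r1 = pearson_r(np.asarray(a1_col, dtype=float), np.asarray(outcome_d, dtype=float))
    r2 = pearson_r(np.asarray(a2_col, dtype=float), np.asarray(outcome_d, dtype=float))
    if np.isnan(r1) and np.isnan(r2):
        return None
    if np.isnan(r2) or (not np.isnan(r1) and r1 > r2):
        return NEGATIVE_RISK
    return POSITIVE_RISK


def select_signs(
    A1: pd.DataFrame,
    A2: pd.DataFrame,
    outcome: OutcomeData,
    subset_1x: Sequence,
) -> dict[str, str]:
    """Vectorised sign selection over all SNPs on the chosen half-set."""
    subset = list(subset_1x)
    y = outcome.delta_sse_d.loc[subset].to_numpy()
    r1 = columnwise_pearson(A1.loc[subset].to_numpy(), y)
    r2 = columnwise_pearson(A2.loc[subset].to_numpy(), y)
    chosen: dict[str, str] = {}
    for snp, a, b in zip(A1.columns, r1, r2):
        if np.isnan(a) and np.isnan(b):
            logger.info("SNP %s: both signed variants undefined on set 1x, excluded", snp)
            continue
        if np.isnan(b) or (not np.isnan(a) and a > b):
            chosen[snp] = NEGATIVE_RISK
        else:
            chosen[snp] = POSITIVE_RISK
    return chosen


def stability_filter_round(
    cols: pd.DataFrame,
    outcome: OutcomeData,
    sample_ids: Sequence,
    rng_or_seed,
    threshold: float = 0.0,
) -> list:
    """One survival round: random halves, drop alleles below threshold in either.

    A SNP survives iff its correlation with ΔSSE_D is defined and
    >= ``threshold`` in *both* random halves (r = 0 survives the default
    threshold: only strictly negative correlations are 'lower than 0').
    """
    sample_ids = list(sample_ids)
    if len(sample_ids) < 4:
        raise SizeError(f"stability round needs >= 4 subjects, got {len(sample_ids)}")
    half_a, half_b = random_half_split(sample_ids, rng_or_seed)
    survivors = list(cols.columns)
    for half in (half_a, half_b):
        y = outcome.delta_sse_d.loc[half].to_numpy()
        r = columnwise_pearson(cols.loc[half, survivors].to_numpy(), y)
        survivors = [
            snp for snp, ri in zip(survivors, r) if not np.isnan(ri) and ri >= threshold
        ]
    return survivors


def run_stability_filters(
    cols: pd.DataFrame,
    outcome: OutcomeData,
    sample_ids: Sequence,
    n_rounds: int,
    master_seed: int,
    stream: str = "stability_pre",
    threshold: float = 0.0,
    stage_counts: list | None = None,
) -> list:
    """Apply ``n_rounds`` reshuffled stability rounds, intersecting survivors."""
    survivors = list(cols.columns)
    for i in range(n_rounds):
        if not survivors:
            break
        rng = stream_rng(master_seed, stream, i)
        survivors = stability_filter_round(
            cols.loc[:, survivors], outcome, sample_ids, rng, threshold
        )
        if stage_counts is not None:
            stage_counts.append((f"{stream}_round{i + 1}", len(survivors)))
    return survivors


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Survivor:
    """One surviving allele: its SNP, chosen sign, and restricted score map."""

    snp_id: str
    sign: str  # "A1" (negative risk) or "A2" (positive risk)
    score_map: Mapping[int, int]  # genotype category -> {-1,0} or {0,+1}


@dataclass
class PPSModel:
    """The companion demarcation formula: summed scores of surviving alleles.

    ``cutpoint`` (optional) is the responder threshold chosen on the
    derivation set; ``provenance`` records seeds, thresholds and per-stage
    survivor counts so a run can be audited and reproduced.
    """

    survivors: list[Survivor] = field(default_factory=list)
    cutpoint: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.snp_id for s in self.survivors]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate survivor SNP ids")
        if not self.survivors:
            warnings.warn("model has no surviving SNPs; every subject scores 0", stacklevel=2)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.survivors]

    def to_json(self) -> str:
        payload = {
            "survivors": [
                {
                    "snp_id": s.snp_id,
                    "sign": s.sign,
                    "map": {str(k): int(v) for k, v in sorted(s.score_map.items())},
                }
                for s in self.survivors
            ],
            "cutpoint": self.cutpoint,
            "provenance": self.provenance,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PPSModel":
        payload = json.loads(text)
        survivors = [
            Survivor(
                snp_id=s["snp_id"],
                sign=s["sign"],
                score_map={int(k): int(v) for k, v in s["map"].items()},
            )
            for s in payload["survivors"]
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cls(
                survivors=survivors,
                cutpoint=payload.get("cutpoint"),
                provenance=payload.get("provenance", {}),
            )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "PPSModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_pps_model(
    survivor_ids: Sequence[str],
    recode_maps: Mapping[str, Mapping[int, int]],
    chosen_signs: Mapping[str, str],
    provenance: dict | None = None,
) -> PPSModel:
    """Assemble the model from surviving SNPs, their maps and chosen signs.

    The stored map is restricted to the chosen sign: a negative-risk survivor
    keeps only the -1 category (others score 0), a positive-risk survivor
    keeps only the +1 category.
    """
    survivors = []
    for snp in survivor_ids:
        full = recode_maps[snp]
        sign = chosen_signs[snp]
        kept = -1 if sign == NEGATIVE_RISK else +1
        restricted = {cat: (score if score == kept else 0) for cat, score in full.items()}
        survivors.append(Survivor(snp_id=snp, sign=sign, score_map=restricted))
    return PPSModel(survivors=survivors, provenance=provenance or {})


def score_subjects(model: PPSModel, g: GenotypeMatrix) -> pd.Series:
    """Per-subject PPS: sum of mapped scores over the surviving SNPs.

    Missing genotypes and categories outside a survivor's map contribute 0,
    so |PPS| is bounded by the number of survivors.
    """
    absent = [s for s in model.snp_ids if s not in g.data.columns]
    if absent:
        raise ScoringError(f"survivor SNPs absent from genotype matrix: {absent}")
    total = np.zeros(g.n_subjects)
    for s in model.survivors:
        col = g.data[s.snp_id].to_numpy(dtype=float)
        for cat, score in s.score_map.items():
            if score:
                total += np.where(col == cat, float(score), 0.0)
    return pd.Series(total.astype(int), index=g.data.index, name="pps")


# ---------------------------------------------------------------------------
# end-to-end derivation
# ---------------------------------------------------------------------------


def derive_pps(
    g: GenotypeMatrix,
    outcome: OutcomeData,
    config: RunConfig | None = None,
    seed: int | None = None,
):
    """Run the full derivation and return (model, split assignment, report).

    ``seed`` overrides ``config.master_seed`` when given.  Stage-by-stage
    survivor counts are recorded in the model's provenance.
    """
    from .evaluation import evaluate_model  # local import: avoid cycle

    config = config or RunConfig()
    master_seed = config.master_seed if seed is None else int(seed)
    outcome = outcome.align_to(g)
    stage_counts: list[tuple[str, int]] = [("input", g.n_snps)]

    if config.missing_policy == "drop_snps":
        g = drop_snps_with_missing(g)
        stage_counts.append(("complete_cases", g.n_snps))
    g = exclude_low_count_snps(g, min_obs=config.min_obs)
    stage_counts.append(("low_count_filter", g.n_snps))

    assign = matched_binary_assignment(outcome, master_seed, match_on=config.match_on)
    d1 = assign.derivation1_ids

    means = compute_allele_means(g, outcome, d1)
    recode_maps = {snp: derive_recoding(m) for snp, m in means.items() if len(m) >= 2}
    g = g.select_snps(list(recode_maps))
    stage_counts.append(("recodable", g.n_snps))

    A = apply_recoding(g, recode_maps)
    survivors = initial_correlation_filter(A, outcome, d1, threshold=config.r_threshold)
    stage_counts.append(("initial_r_filter", len(survivors)))

    A1, A2 = split_signed_indicators(A.loc[:, survivors])
    set1x, _set1y = random_half_split(d1, stream_rng(master_seed, "sign_split"))
    chosen_signs = select_signs(A1, A2, outcome, set1x)
    survivors = [s for s in survivors if s in chosen_signs]
    stage_counts.append(("sign_selection", len(survivors)))

    chosen_cols = pd.DataFrame(
        {s: (A1[s] if chosen_signs[s] == NEGATIVE_RISK else A2[s]) for s in survivors},
        index=A.index,
    )

    survivors = run_stability_filters(
        chosen_cols.loc[:, survivors], outcome, d1,
        n_rounds=config.rounds_pre, master_seed=master_seed,
        stream="stability_pre", threshold=config.stability_threshold,
        stage_counts=stage_counts,
    )

    assign = finalize_derivation_validation(assign, master_seed)
    derivation_ids = assign.derivation_ids

    survivors = run_stability_filters(
        chosen_cols.loc[:, survivors], outcome, derivation_ids,
        n_rounds=config.rounds_post, master_seed=master_seed,
        stream="stability_post", threshold=config.stability_threshold,
        stage_counts=stage_counts,
    )

    provenance = {
        "master_seed": master_seed,
        "thresholds": {
            "min_obs": config.min_obs,
            "r_threshold": config.r_threshold,
            "stability_threshold": config.stability_threshold,
        },
        "rounds": {"pre": config.rounds_pre, "post": config.rounds_post},
        "stage_counts": [[name, n] for name, n in stage_counts],
    }
    model = build_pps_model(survivors, recode_maps, chosen_signs, provenance)

    report = evaluate_model(model, g, outcome, assign, config=config)
    model.cutpoint = report.cutpoint
    return model, assign, report
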