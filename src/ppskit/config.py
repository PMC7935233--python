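"""Run configuration: algorithm thresholds, evaluation choices, seeding."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Tunable knobs of the derivation pipeline, with method defaults.

    min_obs
        minimum observations of every observed genotype category (SNPs below
        it are excluded before derivation).
    r_threshold
        initial Pearson-correlation filter on the recoded alleles vs the
        dichotomised outcome; alleles with r below it are excluded.
    stability_threshold
        per-half survival bound in the stability rounds (alleles whose
        correlation drops below it in either random half are excluded).
    rounds_pre / rounds_post
        stability rounds run on the first derivation set and on the final
        derivation set respectively (2 + 2 by default: four rounds in total).
    missing_policy
        "drop_snps" (exclude SNPs with any missing call, the default) or
        "pairwise" (keep them; correlations use pairwise-complete cells).
    match_on
        matching variable for the initial paired assignment: "delta_sse"
        (default) or "sse_pri".
    ci_method
        AUC confidence interval: "hanley" (Hanley–McNeil, default) or "delong".
    cutpoint_method
        responder/non-responder threshold rule; "youden" is the only built-in.
    """

    min_obs: int = 3
    r_threshold: float = 0.1
    stability_threshold: float = 0.0
    rounds_pre: int = 2
    rounds_post: int = 2
    missing_policy: str = "drop_snps"
    match_on: str = "delta_sse"
    ci_method: str = "hanley"
    cutpoint_method: str = "youden"
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r_threshold", "stability_threshold"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")
        if self.rounds_pre < 0 or self.rounds_post < 0:
            raise ValueError("round counts must be >= 0")
        if self.missing_policy not in ("drop_snps", "pairwise"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        self.master_seed = int(self.master_seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in payload.items() if k in known})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
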