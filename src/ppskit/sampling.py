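"""Subject-set construction: matched assignment, half-splits, finalisation.

The derivation/validation structure is built in two steps.  First, subjects
sorted by outcome are paired off and, within each pair, one member is randomly
assigned to the *first derivation set* and one to the *intermediary set* —
matching the outcome distribution of the two groups by construction (65/64 at
n = 129).  Later, half of the intermediary set (randomly chosen) joins the
derivation set and the other half becomes the held-out validation set
(97/32 at n = 129).  In between, the stability filters repeatedly cut whatever
sample they operate on into random halves.

All assignments are deterministic functions of (input, seed); odd sizes always
favour the first-named set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seeds import stream_rng
from .errors import SizeError, StateError
from .genotype_io import OutcomeData

DERIVATION1 = "derivation1"
INTERMEDIARY = "intermediary"
DERIVATION = "derivation"
VALIDATION = "validation"


@dataclass(frozen=True)
class SplitAssignment:
    """Per-subject membership labels across the two-step split structure.

    ``first_part`` maps each subject to derivation1/intermediary; ``final``
    (present after :func:`finalize_derivation_validation`) maps each subject
    to derivation/validation.
    """

    first_part: pd.Series
    final: pd.Series | None = None

    @property
    def derivation1_ids(self) -> list:
        return list(self.first_part.index[self.first_part == DERIVATION1])

    @property
    def intermediary_ids(self) -> list:
        return list(self.first_part.index[self.first_part == INTERMEDIARY])

    @property
    def derivation_ids(self) -> list:
        self._require_final()
        return list(self.final.index[self.final == DERIVATION])

    @property
    def validation_ids(self) -> list:
        self._require_final()
        return list(self.final.index[self.final == VALIDATION])

    def _require_final(self) -> None:
        if self.final is None:
            raise StateError("final derivation/validation labels not assigned yet")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"first_part": self.first_part})
        if self.final is not None:
            df["final"] = self.final
        df.index.name = "subject_id"
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path)


def matched_binary_assignment(
    outcome: OutcomeData, seed: int, match_on: str = "delta_sse"
) -> SplitAssignment:
    """Outcome-matched pseudo-random 2-group assignment.

    Subjects are ordered by the matching variable (ties broken by subject id),
    consecutive pairs are formed, and a seeded coin decides which member of
    each pair goes to derivation1; an odd leftover subject joins derivation1.
    Group sizes are therefore ceil(n/2) and floor(n/2), and the two groups'
    outcome distributions differ only by within-pair substitutions.

    ``match_on`` is ``"delta_sse"`` (default: the variable subjects are
    ordered by) or ``"sse_pri"`` (match on run-in event counts instead).
    """
    if match_on == "delta_sse":
        values = outcome.delta_sse
    elif match_on == "sse_pri":
        if outcome.sse_pri is None:
            raise StateError("match_on='sse_pri' requires run-in counts")
        values = outcome.sse_pri
    else:
        raise ValueError(f"unknown match_on {match_on!r}")
    n = len(values)
    if n < 2:
        raise SizeError(f"need at least 2 subjects to assign, got {n}")

    order = sorted(values.index, key=lambda sid: (values[sid], str(sid)))
    rng = stream_rng(seed, "assignment")
    labels = pd.Series(index=values.index, dtype=object)
    for k in range(0, n - 1, 2):
        a, b = order[k], order[k + 1]
        if rng.integers(2) == 0:
            labels[a], labels[b] = DERIVATION1, INTERMEDIARY
        else:
            labels[a], labels[b] = INTERMEDIARY, DERIVATION1
    if n % 2:
        labels[order[-1]] = DERIVATION1
    return SplitAssignment(first_part=labels)


def random_half_split(ids, rng_or_seed) -> tuple[list, list]:
    """Uniform seeded partition into halves of size ceil(n/2) / floor(n/2).

    Accepts either an integer seed (a fresh generic sub-stream is used) or a
    ``numpy.random.Generator`` for callers managing their own streams.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise SizeError(f"need at least 2 ids to split, got {n}")
    if isinstance(rng_or_seed, np.random.Generator):
        rng = rng_or_seed
    else:
        rng = stream_rng(int(rng_or_seed), "generic")
    perm = rng.permutation(n)
    cut = (n + 1) // 2
    set1x = [ids[i] for i in perm[:cut]]
    set1y = [ids[i] for i in perm[cut:]]
    return set1x, set1y


def finalize_derivation_validation(assign: SplitAssignment, seed: int) -> SplitAssignment:
    """Halve the intermediary set: one half joins derivation, one is held out.

    The larger half (odd sizes) joins the derivation set, reproducing the
    97/32 structure from 65/64.
    """
    if assign.first_part is None or assign.first_part.isna().any():
        raise StateError("first_part labels are incomplete")
    intermediary = assign.intermediary_ids
    rng = stream_rng(seed, "finalize")
    if len(intermediary) < 2:
        # degenerate cohort: the lone intermediary subject joins derivation
        to_derivation, to_validation = list(intermediary), []
    else:
        to_derivation, to_validation = random_half_split(intermediary, rng)
    final = pd.Series(index=assign.first_part.index, dtype=object)
    final[assign.derivation1_ids] = DERIVATION
    final[to_derivation] = DERIVATION
    final[to_validation] = VALIDATION
    return replace(assign, final=final)
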