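"""Paired diagnostic algorithm for aganglionic vs. ganglionic bowel.

Two relative criteria distinguish the aganglionic segment within a pair of
specimens from the same patient:

  I.  the aganglionic segment has the *thinner* muscularis interna;
  II. the aganglionic segment has the *lower* muscularis interna /
      muscularis externa mean-thickness ratio.

The comparison is strictly pairwise — no absolute cut-off values are used,
because reliable cut-offs have not been validated.  When the two criteria
disagree, a resolution policy decides: ``ratio_priority`` trusts criterion
II (the default), ``mi_priority`` trusts criterion I, and ``abstain``
declines to predict.  Cohort evaluation additionally reports the
"either-criterion" count: a pair counts as correct when at least one
criterion points at the truly aganglionic segment, which is the
retrospective accuracy notion used when criteria are validated against
known labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "POLICIES",
    "FeaturePair",
    "PairClassification",
    "LabeledPair",
    "EvaluationReport",
    "classify_pair",
    "evaluate_algorithm",
]

POLICIES = ("ratio_priority", "mi_priority", "abstain")


@dataclass(frozen=True)
class FeaturePair:
    """The two discriminative features of one bowel segment."""

    mi_thickness: float  # muscularis interna mean thickness, mm
    mi_me_ratio: float  # muscularis interna / externa mean-thickness ratio

    def __post_init__(self) -> None:
        if not (self.mi_thickness > 0 and self.mi_me_ratio > 0):
            raise ValueError("features must be positive")


@dataclass(frozen=True)
class PairClassification:
    """Outcome of classifying one specimen pair."""

    predicted_aganglionic: str | None  # segment id, or None when indeterminate
    criterion_I_vote: str | None  # segment id, or None on exact tie
    criterion_II_vote: str | None
    concordant: bool
    policy: str


def _vote(value_a: float, value_b: float, id_a: str, id_b: str) -> str | None:
    """The segment with the smaller feature value; None on exact equality."""
    if value_a < value_b:
        return id_a
    if value_b < value_a:
        return id_b
    return None


def classify_pair(
    a: FeaturePair,
    b: FeaturePair,
    policy: str = "ratio_priority",
    ids: tuple[str, str] = ("a", "b"),
) -> PairClassification:
    """Predict which of two same-patient segments is aganglionic.

    Criterion I votes for the segment with the smaller muscularis interna
    thickness, criterion II for the segment with the smaller interna/externa
    ratio.  Concordant votes decide directly; discordant votes are resolved
    by ``policy``; a criterion whose feature values are exactly equal casts
    a tie (no vote).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    id_a, id_b = ids
    v1 = _vote(a.mi_thickness, b.mi_thickness, id_a, id_b)
    v2 = _vote(a.mi_me_ratio, b.mi_me_ratio, id_a, id_b)

    if v1 == v2:  # includes the double tie (both None -> indeterminate)
        predicted = v1
        concordant = v1 is not None
    elif v1 is None or v2 is None:
        predicted = v2 if v1 is None else v1  # the only criterion that voted
        concordant = False
    else:  # genuine disagreement
        concordant = False
        if policy == "ratio_priority":
            predicted = v2
        elif policy == "mi_priority":
            predicted = v1
        else:  # abstain
            predicted = None
    return PairClassification(predicted, v1, v2, concordant, policy)


@dataclass(frozen=True)
class LabeledPair:
    """One patient's two segments with the ground-truth aganglionic id."""

    patient_id: str
    segments: tuple[tuple[str, FeaturePair], tuple[str, FeaturePair]]
    true_aganglionic: str

    def __post_init__(self) -> None:
        ids = {sid for sid, _ in self.segments}
        if self.true_aganglionic not in ids:
            raise ValueError(
                f"true label {self.true_aganglionic!r} is not one of the segment ids"
            )


@dataclass(frozen=True)
class EvaluationReport:
    """Cohort-level counts for the diagnostic algorithm."""

    n: int
    criterion_I_correct: int
    criterion_II_correct: int
    either_correct: int  # at least one criterion votes the true segment
    policy_correct: dict[str, int]  # per resolution policy

    @property
    def either_accuracy(self) -> float:
        return self.either_correct / self.n

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "criterion_I_correct": self.criterion_I_correct,
            "criterion_II_correct": self.criterion_II_correct,
            "either_correct": self.either_correct,
            "either_accuracy": self.either_accuracy,
            "policy_correct": dict(self.policy_correct),
        }


def evaluate_algorithm(
    cohort: Iterable[LabeledPair],
    policy: str = "ratio_priority",
) -> tuple[list[PairClassification], EvaluationReport]:
    """Classify every labeled pair and tally the cohort counts.

    Reports per-criterion correct counts, the either-criterion count, and
    the count of correct predictions under each resolution policy.  The
    returned classifications use ``policy``.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort is empty")

    results: list[PairClassification] = []
    c1 = c2 = either = 0
    per_policy = {p: 0 for p in POLICIES}
    for pair in cohort:
        (id_a, fa), (id_b, fb) = pair.segments
        truth = pair.true_aganglionic
        res = classify_pair(fa, fb, policy=policy, ids=(id_a, id_b))
        results.append(res)
        hit1 = res.criterion_I_vote == truth
        hit2 = res.criterion_II_vote == truth
        c1 += hit1
        c2 += hit2
        either += hit1 or hit2
        for p in POLICIES:
            pred = classify_pair(fa, fb, policy=p, ids=(id_a, id_b)).predicted_aganglionic
            per_policy[p] += pred == truth

    report = EvaluationReport(
        n=len(cohort),
        criterion_I_correct=c1,
        criterion_II_correct=c2,
        either_correct=either,
        policy_correct=per_policy,
    )
    return results, report
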