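"""PreMA calls from external outcome distributions and the MENdel workflow.

Probability-based repair predictors (inDelphi- or Lindel-style) emit, for a
cut site, a list of outcomes with probabilities.  The PreMA rule for such a
predictor is: the single most likely outcome has probability >= 0.50 *and*
is an MMEJ deletion (junction microhomology >= 3 nt).  The single-majority
insertion rule is analogous: the top outcome is a 1 bp insertion at
probability >= 0.50.

MENdel combines the two orthogonal callers on a 60 bp window centered at a
SpCas9 break: microhomology ranking supplies the PreMA deletion call (and
whether its deletion is out of frame), an insertion predictor — consumed
through a pluggable adapter — supplies the single-majority 1 bp insertion
call, and the site is predicted to yield a homogeneous frameshift when
either an out-of-frame PreMA or a majority 1 bp insertion is called.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import pandas as pd

from . import repair_truth
from .mh_engine import (
    DEFAULT_DIST_THRESHOLD,
    DEFAULT_SCORE_THRESHOLD,
    enumerate_mh_patterns,
    menthu_rank,
)

__all__ = [
    "Outcome",
    "OutcomeDistribution",
    "MendelCall",
    "AdapterFormatError",
    "MENDEL_WINDOW",
    "prema_from_distribution",
    "sm_insertion_from_distribution",
    "mendel_predict",
    "constant_insertion_adapter",
    "null_insertion_adapter",
    "load_distribution",
]

MENDEL_WINDOW = 60            # nt of context; break after position 30
PROB_TOLERANCE = 1e-6

InsertionAdapter = Callable[[str], "OutcomeDistribution"]


class AdapterFormatError(ValueError):
    """Raised when an adapter's top outcome cannot be reconciled."""


@dataclass(frozen=True)
class Outcome:
    """One predicted repair outcome: an indel descriptor or a raw sequence."""

    probability: float
    kind: str | None = None       # "deletion" | "insertion" | None (sequence)
    length: int | None = None
    position: int | None = None   # 0-based in the predictor's input window
    inserted_seq: str | None = None
    sequence: str | None = None   # full predicted repaired sequence


@dataclass
class OutcomeDistribution:
    """Per-outcome probabilities from one predictor at one cut site."""

    cut_index: int
    outcomes: list[Outcome]
    source: str = ""

    def normalized(self) -> "OutcomeDistribution":
        """Renormalize probabilities and sort outcomes by descending mass.

        Adapter outputs may be rounded; totals within ``PROB_TOLERANCE``
        of 1 are accepted silently, anything else is rescaled (a zero
        total is an error).  Ties sort deterministically by descriptor.
        """
        if not self.outcomes:
            raise AdapterFormatError("empty outcome distribution")
        total = sum(o.probability for o in self.outcomes)
        if total <= 0:
            raise AdapterFormatError("outcome probabilities sum to zero")
        scale = 1.0 if abs(total - 1.0) <= PROB_TOLERANCE else 1.0 / total
        scaled = [
            Outcome(o.probability * scale, o.kind, o.length, o.position,
                    o.inserted_seq, o.sequence)
            for o in self.outcomes
        ]
        scaled.sort(
            key=lambda o: (-o.probability, o.kind or "", o.length or 0,
                           o.position or 0, o.inserted_seq or "",
                           o.sequence or "")
        )
        return OutcomeDistribution(self.cut_index, scaled, self.source)


@dataclass(frozen=True)
class MendelCall:
    prema_deletion: bool
    deletion_frameshift: bool
    sm_insertion: bool

    @property
    def frameshift_call(self) -> bool:
        return (self.prema_deletion and self.deletion_frameshift) \
            or self.sm_insertion


def _resolve_indel(
    top: Outcome, wt_context: str, cut_index: int
) -> repair_truth.IndelCall:
    """Turn a top outcome into a concrete leftmost indel call on the WT."""
    if top.sequence is not None and top.kind is None:
        call = repair_truth.align_simple_indel(wt_context, top.sequence)
        if call is None:
            raise AdapterFormatError(
                "top predicted sequence is not a single simple indel "
                "of the wild-type context"
            )
        return call
    if top.kind == "deletion":
        if top.length is None or top.position is None:
            raise AdapterFormatError("deletion outcome lacks length/position")
        return repair_truth.IndelCall("deletion", top.length, top.position)
    if top.kind == "insertion":
        if top.length is None:
            raise AdapterFormatError("insertion outcome lacks a length")
        return repair_truth.IndelCall(
            "insertion", top.length, top.position if top.position is not None
            else cut_index, top.inserted_seq,
        )
    raise AdapterFormatError(f"unintelligible outcome kind {top.kind!r}")


def prema_from_distribution(
    dist: OutcomeDistribution,
    wt_context: str,
    cut_index: int,
    p_threshold: float = 0.50,
) -> bool:
    """PreMA rule for a probability predictor (inclusive threshold)."""
    top = dist.normalized().outcomes[0]
    if top.probability < p_threshold:
        return False
    call = _resolve_indel(top, wt_context, cut_index)
    if call.kind != "deletion":
        return False
    k = repair_truth.junction_microhomology(wt_context, call.left, call.length)
    return k >= repair_truth.MIN_JUNCTION_MH


def sm_insertion_from_distribution(
    dist: OutcomeDistribution,
    p_threshold: float = 0.50,
    wt_context: str | None = None,
) -> bool:
    """Single-majority 1 bp insertion rule (inclusive threshold).

    Sequence-style outcomes (no indel descriptor) need ``wt_context`` to
    be reconciled; descriptor-style outcomes do not.
    """
    top = dist.normalized().outcomes[0]
    if top.probability < p_threshold:
        return False
    if top.kind is None and top.sequence is not None:
        if wt_context is None:
            raise AdapterFormatError(
                "sequence-style outcome requires wt_context to reconcile"
            )
        call = repair_truth.align_simple_indel(wt_context, top.sequence)
        if call is None:
            raise AdapterFormatError(
                "top predicted sequence is not a single simple indel "
                "of the wild-type context"
            )
        return call.kind == "insertion" and call.length == 1
    return top.kind == "insertion" and top.length == 1


def mendel_predict(
    context60: str,
    insertion_adapter: InsertionAdapter,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    dist_threshold: int = DEFAULT_DIST_THRESHOLD,
    p_threshold: float = 0.50,
) -> MendelCall:
    """MENdel call on a 60 nt window with the break after position 30."""
    if len(context60) != MENDEL_WINDOW:
        raise ValueError(
            f"MENdel requires a {MENDEL_WINDOW} nt window, "
            f"got {len(context60)} nt"
        )
    cut = MENDEL_WINDOW // 2
    result = menthu_rank(
        enumerate_mh_patterns(context60, cut),
        cut, score_threshold, dist_threshold,
    )
    try:
        dist = insertion_adapter(context60)
    except Exception as exc:
        raise RuntimeError(
            f"insertion adapter failed on window {context60!r}"
        ) from exc
    return MendelCall(
        prema_deletion=result.is_prema,
        deletion_frameshift=result.top_frameshift,
        sm_insertion=sm_insertion_from_distribution(
            dist, p_threshold, wt_context=context60
        ),
    )


def constant_insertion_adapter(
    p_insertion: float, inserted_base: str = "A"
) -> InsertionAdapter:
    """Deterministic mock adapter: fixed 1 bp insertion probability.

    The remaining probability mass is assigned to a generic long deletion
    outcome so the distribution always normalizes.
    """

    def adapter(context: str) -> OutcomeDistribution:
        cut = len(context) // 2
        outcomes = [
            Outcome(p_insertion, "insertion", 1, cut, inserted_base),
            Outcome(1.0 - p_insertion, "deletion", 2, cut - 1),
        ]
        return OutcomeDistribution(cut, outcomes, source="mock")

    return adapter


#: adapter that never predicts an insertion (probability 0)
null_insertion_adapter: InsertionAdapter = constant_insertion_adapter(0.0)


def load_distribution(path, cut_index: int | None = None) -> OutcomeDistribution:
    """Read an adapter output file (TSV or JSON) into a distribution.

    TSV columns: outcome_kind, indel_len, position, inserted_seq,
    probability.  JSON mirrors the same fields in a list under
    ``outcomes`` with an optional top-level ``cut_index``.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        cut = payload.get("cut_index", cut_index or 0)
        outcomes = [
            Outcome(
                probability=float(o["probability"]),
                kind=o.get("outcome_kind"),
                length=o.get("indel_len"),
                position=o.get("position"),
                inserted_seq=o.get("inserted_seq"),
                sequence=o.get("sequence"),
            )
            for o in payload["outcomes"]
        ]
        return OutcomeDistribution(cut, outcomes, source=path).normalized()
    df = pd.read_csv(path, sep="\t")
    outcomes = []
    for _, row in df.iterrows():
        outcomes.append(
            Outcome(
                probability=float(row["probability"]),
                kind=None if pd.isna(row.get("outcome_kind")) else
                str(row["outcome_kind"]),
                length=None if pd.isna(row.get("indel_len")) else
                int(row["indel_len"]),
                position=None if pd.isna(row.get("position")) else
                int(row["position"]),
                inserted_seq=None if pd.isna(row.get("inserted_seq")) else
                str(row["inserted_seq"]),
            )
        )
    return OutcomeDistribution(cut_index or 0, outcomes, source=path).normalized()
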