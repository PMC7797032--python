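"""Microhomology enumeration and scoring around a double-strand break.

Microhomology-mediated end joining (MMEJ) anneals a pair of short exact
repeats (arms) flanking a DNA double-strand break (DSB) and deletes one arm
copy plus everything between the two copies.  For a sequence context and a
cut position this module enumerates every candidate arm pair, scores each
resulting deletion with the Bae-style pattern score

    pi = 100 * round(exp(-delta / 20), 3) * (lam + gc_count)

where ``lam`` is the arm length, ``delta = lam + dist`` the deleted length
(``dist`` bases lie strictly between the arms), and G/C arm bases weigh 2
versus 1 for A/T.  The competition between the top two patterns,
``menthu_score = pi_max / pi_max-1``, together with the spacing ``dist`` of
the top pattern, drives the PreMA call: a site predicted to yield a
*predominant MMEJ allele* (a single repair genotype in >= 50% of the pool).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MicrohomologyPattern",
    "MenthuResult",
    "InvalidSequenceError",
    "InconsistentPatternError",
    "DIST_PRESETS",
    "apply_deletion",
    "pattern_score",
    "enumerate_mh_patterns",
    "menthu_rank",
    "classify_prema",
]

_ALPHABET = frozenset("ACGT")

#: distance-threshold presets, MENTHU@3 .. MENTHU@6; @5 is the published default
DIST_PRESETS = (3, 4, 5, 6)

DEFAULT_SCORE_THRESHOLD = 1.50
DEFAULT_DIST_THRESHOLD = 5


class InvalidSequenceError(ValueError):
    """Raised for sequences containing characters outside A/C/G/T."""


class InconsistentPatternError(ValueError):
    """Raised for a microhomology pattern whose geometry is impossible."""


def check_sequence(seq: str, name: str = "sequence") -> None:
    """Reject empty sequences and any character outside uppercase ACGT.

    Ambiguity codes (including N) are rejected: arm matching and GC
    weighting are undefined for them.
    """
    if not isinstance(seq, str) or not seq:
        raise InvalidSequenceError(f"{name} must be a nonempty string")
    bad = set(seq) - _ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"{name} contains invalid characters {sorted(bad)!r}; "
            "only uppercase A/C/G/T are accepted"
        )


@dataclass(frozen=True)
class MicrohomologyPattern:
    """One microhomology arm pair and the deletion it produces.

    Coordinates are 0-based on the wild-type context; the deletion removes
    the half-open interval ``[left_start, left_start + del_len)`` (the left
    arm copy plus the spacer), retaining the right copy at the junction.
    """

    arm_seq: str
    left_start: int
    right_start: int
    lam: int          # arm length, nt
    dist: int         # bases strictly between the two arm copies
    del_len: int      # lam + dist
    gc_count: int
    score: float      # Bae-style pattern score pi
    product: str      # context with the deletion applied

    @property
    def frameshift(self) -> bool:
        return self.del_len % 3 != 0


@dataclass
class MenthuResult:
    """Ranked microhomology patterns and the PreMA call for one cut site."""

    cut_index: int
    patterns: list[MicrohomologyPattern]
    menthu_score: float | None   # pi_max / pi_max-1; +inf if single pattern
    top_dist: int | None
    is_prema: bool
    top_frameshift: bool

    @property
    def top(self) -> MicrohomologyPattern | None:
        return self.patterns[0] if self.patterns else None


def apply_deletion(context: str, left: int, del_len: int) -> str:
    """Remove the half-open interval ``[left, left + del_len)``."""
    if left < 0 or del_len < 0 or left + del_len > len(context):
        raise ValueError(
            f"deletion [{left}, {left + del_len}) out of bounds for "
            f"length-{len(context)} sequence"
        )
    return context[:left] + context[left + del_len:]


def pattern_score(p: MicrohomologyPattern) -> float:
    """Bae-style pattern score pi for one microhomology deletion.

    The exponential length factor is rounded to 3 decimals *before*
    multiplication, reproducing the original published arithmetic.
    """
    return _score(p.arm_seq, p.del_len)


def _score(arm_seq: str, del_len: int) -> float:
    lam = len(arm_seq)
    if lam < 1:
        raise InconsistentPatternError("arm must be at least 1 nt")
    if del_len < lam:
        raise InconsistentPatternError(
            f"deletion length {del_len} shorter than arm length {lam}"
        )
    gc = sum(1 for b in arm_seq if b in "GC")
    return 100.0 * round(math.exp(-del_len / 20.0), 3) * (lam + gc)


def enumerate_mh_patterns(
    context: str, cut_index: int, min_arm: int = 3
) -> list[MicrohomologyPattern]:
    """Enumerate deduplicated microhomology deletion patterns at a cut.

    Every exact-repeat arm pair with arm length >= ``min_arm`` is reported
    when the left copy lies entirely 5' of the break and the right copy
    entirely 3' (copies may abut the break), so that collapsing the pair
    deletes a region straddling the break.  Pairs producing an identical
    deletion product (nested or shifted repeats) are deduplicated, keeping
    the representative with maximal arm length (leftmost on ties).

    Parameters
    ----------
    context:
        Uppercase ACGT wild-type window.
    cut_index:
        0-based break position: the number of bases 5' of the break;
        must satisfy ``0 < cut_index < len(context)``.
    min_arm:
        Minimum arm length (>= 2); the MMEJ definition uses 3.
    """
    check_sequence(context, "context")
    n = len(context)
    if not 0 < cut_index < n:
        raise ValueError(
            f"cut_index {cut_index} outside (0, {n}) for this context"
        )
    if min_arm < 2:
        raise ValueError(f"min_arm must be >= 2, got {min_arm}")

    best: dict[str, MicrohomologyPattern] = {}
    for i in range(0, cut_index - min_arm + 1):
        r0 = max(i + min_arm, cut_index)
        for r in range(r0, n - min_arm + 1):
            lam_cap = min(cut_index - i, n - r, r - i)
            if lam_cap < min_arm:
                continue
            lam = 0
            while lam < lam_cap and context[i + lam] == context[r + lam]:
                lam += 1
            if lam < min_arm:
                continue
            del_len = r - i
            product = context[:i] + context[r:]
            prev = best.get(product)
            if prev is not None and (prev.lam, -prev.left_start) >= (lam, -i):
                continue
            arm = context[i: i + lam]
            best[product] = MicrohomologyPattern(
                arm_seq=arm,
                left_start=i,
                right_start=r,
                lam=lam,
                dist=del_len - lam,
                del_len=del_len,
                gc_count=sum(1 for b in arm if b in "GC"),
                score=_score(arm, del_len),
                product=product,
            )
    return sorted(best.values(), key=lambda p: (p.left_start, p.right_start))


def menthu_rank(
    patterns: list[MicrohomologyPattern],
    cut_index: int,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    dist_threshold: int = DEFAULT_DIST_THRESHOLD,
) -> MenthuResult:
    """Rank patterns by descending score and derive the site-level call.

    Ties in score break toward smaller arm spacing, then leftmost arm.
    With a single pattern the score ratio is +inf (no competitor); with no
    pattern the score is undefined (None) and the site cannot be a PreMA.
    """
    ranked = sorted(
        patterns, key=lambda p: (-p.score, p.dist, p.left_start)
    )
    if not ranked:
        return MenthuResult(cut_index, [], None, None, False, False)
    if len(ranked) == 1:
        score: float = math.inf
    else:
        score = ranked[0].score / ranked[1].score
    result = MenthuResult(
        cut_index=cut_index,
        patterns=ranked,
        menthu_score=score,
        top_dist=ranked[0].dist,
        is_prema=False,
        top_frameshift=ranked[0].frameshift,
    )
    result.is_prema = classify_prema(result, score_threshold, dist_threshold)
    return result


def classify_prema(
    result: MenthuResult,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    dist_threshold: int = DEFAULT_DIST_THRESHOLD,
) -> bool:
    """PreMA call: score ratio >= threshold AND top spacing <= threshold.

    Both comparisons are inclusive.  ``dist_threshold`` values 3/4/5/6
    correspond to the MENTHU@3/@4/@5/@6 presets.
    """
    if score_threshold <= 0 or dist_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if result.menthu_score is None or result.top_dist is None:
        return False
    return (
        result.menthu_score >= score_threshold
        and result.top_dist <= dist_threshold
    )
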