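"""Ground-truth labeling of repair-read pools.

A repair event is a wild-type sequence, a cut position, and a pool of
repaired reads with counts (replicates already combined).  Events are
consolidated by sequence and rank-ordered by read count; the most frequent
read is aligned to the wild type and kept only when the alignment is a
single, simple indel with no mismatches.  Included events are classified
into four categories — MMEJ deletion (junction microhomology >= 3 nt),
non-MMEJ deletion, 1 bp insertion, >1 bp insertion — and labeled:

* ``is_prema``: top read is an MMEJ deletion at >= 50% of the pool;
* ``is_sm_insertion``: top read is a 1 bp insertion at >= 50%;
* ``is_sm_frameshift``: either of the above with an out-of-frame length
  (any 1 bp insertion is out of frame).

Both 50% comparisons are inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .mh_engine import _ALPHABET, apply_deletion, check_sequence

__all__ = [
    "Category",
    "IndelCall",
    "RepairEvent",
    "TruthLabel",
    "SchemaError",
    "MAJORITY_THRESHOLD",
    "MIN_JUNCTION_MH",
    "align_simple_indel",
    "junction_microhomology",
    "consolidate_reads",
    "load_events",
    "label_event",
]

logger = logging.getLogger(__name__)

MAJORITY_THRESHOLD = 0.50   # inclusive: "at least 50% of the pool"
MIN_JUNCTION_MH = 3         # nt of junction homology defining MMEJ

EVENT_COLUMNS = ("event_id", "wt", "cut_index", "read_seq", "count")


class SchemaError(ValueError):
    """Raised when an events table is missing required columns."""


class Category(str, Enum):
    MMEJ_DEL = "MMEJ_del"
    NONMMEJ_DEL = "nonMMEJ_del"
    INS_1BP = "ins_1bp"
    INS_MULTI = "ins_multi"


@dataclass(frozen=True)
class IndelCall:
    """A single simple indel explaining a read, leftmost-canonicalized."""

    kind: str                      # "deletion" | "insertion"
    length: int
    left: int                      # deletion start / insertion point in WT
    inserted_seq: str | None = None
    category: Category | None = None
    mh_len: int | None = None      # junction microhomology (deletions)


@dataclass
class RepairEvent:
    event_id: str
    wt: str
    cut_index: int
    reads: list[tuple[str, int]]   # consolidated, sorted desc count
    total_reads: int
    top_read: str
    top_freq: float
    genomic: bool = True


@dataclass(frozen=True)
class TruthLabel:
    included: bool
    category: Category | None
    is_prema: bool
    is_sm_insertion: bool
    is_sm_frameshift: bool


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[len(a) - 1 - i] == b[len(b) - 1 - i]:
        i += 1
    return i


def align_simple_indel(wt: str, read: str) -> IndelCall | None:
    """Explain ``read`` as WT plus one contiguous indel, or return None.

    Equivalent to a global alignment heavily penalizing mismatches
    (match 1, mismatch -50, gap open 10 / extend 4) followed by the
    acceptance filter "exactly one contiguous gap in one sequence, zero
    mismatches": such an alignment exists iff the longest common prefix
    and suffix of the two sequences cover the shorter one.  Ambiguous
    placements (the gap sliding within a repeat) are canonicalized to the
    leftmost position.  Identical sequences carry no indel and return
    None (the event is excluded from analysis).
    """
    check_sequence(wt, "wt")
    check_sequence(read, "read")
    d = len(read) - len(wt)
    if d == 0:
        return None  # identical, or substitutions only: not a simple indel
    p = _lcp(wt, read)
    s = _lcs(wt, read)
    short = min(len(wt), len(read))
    if p + s < short:
        return None  # needs mismatches or multiple gaps
    if d < 0:  # deletion of -d bases from WT
        left = max(0, len(read) - s)
        return IndelCall(kind="deletion", length=-d, left=left)
    left = max(0, len(wt) - s)
    return IndelCall(
        kind="insertion", length=d, left=left,
        inserted_seq=read[left: left + d],
    )


def junction_microhomology(wt: str, left: int, del_len: int) -> int:
    """Max exact homology between the deleted segment and a retained flank.

    Over every placement of the same deletion product, the deleted
    segment is compared against the immediately downstream retained flank
    (prefix match) and the immediately upstream retained flank (suffix
    match); the maximum match length is returned.  The result is
    placement-invariant by construction; a deletion is MMEJ when the
    value reaches ``MIN_JUNCTION_MH``.
    """
    if left < 0 or del_len < 1 or left + del_len > len(wt):
        raise ValueError(
            f"deletion [{left}, {left + del_len}) out of bounds for "
            f"length-{len(wt)} wt"
        )
    # all placements producing the same product form a contiguous run
    lo = left
    while lo > 0 and wt[lo - 1] == wt[lo - 1 + del_len]:
        lo -= 1
    hi = left
    while hi + del_len < len(wt) and wt[hi] == wt[hi + del_len]:
        hi += 1
    k = 0
    for pos in range(lo, hi + 1):
        deleted = wt[pos: pos + del_len]
        k = max(k, _lcp(deleted, wt[pos + del_len:]))
        k = max(k, _lcs(deleted, wt[:pos]))
    return k


def _classify(wt: str, call: IndelCall) -> IndelCall:
    """Fill category and junction-homology fields of a bare call."""
    if call.kind == "insertion":
        cat = Category.INS_1BP if call.length == 1 else Category.INS_MULTI
        return IndelCall(call.kind, call.length, call.left,
                         call.inserted_seq, cat, None)
    k = junction_microhomology(wt, call.left, call.length)
    cat = Category.MMEJ_DEL if k >= MIN_JUNCTION_MH else Category.NONMMEJ_DEL
    return IndelCall(call.kind, call.length, call.left, None, cat, k)


def reconstruct_read(wt: str, call: IndelCall) -> str:
    """Apply an indel call to the wild type (used to verify calls)."""
    if call.kind == "deletion":
        return apply_deletion(wt, call.left, call.length)
    return wt[: call.left] + (call.inserted_seq or "") + wt[call.left:]


def consolidate_reads(reads: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Sum counts of identical sequences; sort by count desc, then sequence."""
    pooled: dict[str, int] = {}
    for seq, count in reads:
        pooled[seq] = pooled.get(seq, 0) + int(count)
    return sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))


def make_event(
    event_id: str,
    wt: str,
    cut_index: int,
    reads: list[tuple[str, int]],
    genomic: bool = True,
) -> RepairEvent:
    consolidated = consolidate_reads(reads)
    total = sum(c for _, c in consolidated)
    top_read, top_count = consolidated[0]
    return RepairEvent(
        event_id=event_id,
        wt=wt,
        cut_index=cut_index,
        reads=consolidated,
        total_reads=total,
        top_read=top_read,
        top_freq=top_count / total,
        genomic=genomic,
    )


def load_events(path) -> list[RepairEvent]:
    """Read the canonical repair-event TSV and build consolidated events.

    Required columns: event_id, wt, cut_index, read_seq, count.  An
    optional boolean ``genomic`` column marks reads from genome-targeting
    guides; events flagged non-genomic are dropped (input curation).
    Malformed rows (non-ACGT sequences, non-positive counts) are rejected
    individually with a logged warning carrying their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"events table missing column(s): {missing}")
    if df.empty:
        warnings.warn(f"events table {path} contains no rows", stacklevel=2)
        return []

    groups: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after the header
        try:
            wt, read = str(row["wt"]), str(row["read_seq"])
            if set(wt) - _ALPHABET or set(read) - _ALPHABET:
                raise ValueError("non-ACGT sequence")
            cut = int(row["cut_index"])
            count = int(row["count"])
            if count < 1:
                raise ValueError("count must be >= 1")
        except (ValueError, TypeError) as exc:
            logger.warning("rejecting line %d of %s: %s", line_no, path, exc)
            continue
        genomic = True
        if "genomic" in df.columns:
            genomic = str(row["genomic"]).strip().lower() not in (
                "0", "false", "no", "f",
            )
        g = groups.setdefault(
            str(row["event_id"]),
            {"wt": wt, "cut": cut, "reads": [], "genomic": genomic},
        )
        g["reads"].append((read, count))

    events = []
    for event_id, g in groups.items():
        if not g["genomic"]:
            logger.info("dropping non-genomic event %s", event_id)
            continue
        events.append(
            make_event(event_id, g["wt"], g["cut"], g["reads"], g["genomic"])
        )
    return events


def label_event(event: RepairEvent) -> TruthLabel:
    """Apply the simple-indel filter and majority rules to one event."""
    call = align_simple_indel(event.wt, event.top_read)
    if call is None:
        return TruthLabel(False, None, False, False, False)
    call = _classify(event.wt, call)
    majority = event.top_freq >= MAJORITY_THRESHOLD
    is_prema = call.category is Category.MMEJ_DEL and majority
    is_sm_ins = call.category is Category.INS_1BP and majority
    is_sm_fs = (is_prema and call.length % 3 != 0) or is_sm_ins
    return TruthLabel(True, call.category, is_prema, is_sm_ins, is_sm_fs)
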