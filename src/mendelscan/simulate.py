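"""Synthetic wild-type sequences and repair-read pools with known truth.

Every stage of the pipeline is testable offline against fixtures whose
labels are known analytically:

* :func:`plant_mh_sequence` builds a wild-type window containing exactly
  one microhomology arm pair straddling the cut.  Fully random backgrounds
  almost always harbor extra cross-break 3-mer repeats, so backgrounds are
  drawn from complementary two-letter alphabets ({A,C} 5' of the break,
  {G,T} 3' of it), which suppresses accidental cross-break repeats;
  uniqueness is then *verified* by running the enumerator inside a bounded
  rejection loop, so the returned pattern is provably the only one.
* :func:`simulate_repair_pool` draws multinomial read counts over the
  planted MMEJ product, sampled non-MMEJ deletions (junction homology < 3
  enforced), and cut-site insertions, and returns the event together with
  the truth label implied by the realized counts.
* :func:`write_corpus` emits a labeled on-disk corpus in the canonical
  TSV schema, with a configurable fraction of PreMA-positive events and a
  top-read category mix emulating large Cas9 editing datasets (~54%
  non-MMEJ deletions, ~31% MMEJ deletions, ~14% 1 bp insertions, ~0.2%
  longer insertions).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mh_engine import MicrohomologyPattern, enumerate_mh_patterns, menthu_rank
from .repair_truth import (
    Category,
    MAJORITY_THRESHOLD,
    MIN_JUNCTION_MH,
    RepairEvent,
    TruthLabel,
    junction_microhomology,
    make_event,
)

__all__ = [
    "SimProfile",
    "plant_mh_sequence",
    "simulate_repair_pool",
    "write_corpus",
    "rule_labeled_corpus",
]

#: default top-read category mix (non-MMEJ del, MMEJ del, 1 bp ins, >1 bp ins)
DEFAULT_CATEGORY_MIX = (0.54, 0.31, 0.14, 0.002)

#: default fraction of all events that are PreMA-positive
DEFAULT_PREMA_PREVALENCE = 0.104

#: fraction of 1 bp-insertion-topped events that reach the majority bar
SM_INSERTION_RATE = 0.225

_LEFT_ALPHABET = np.array(list("AC"))
_RIGHT_ALPHABET = np.array(list("GT"))
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimProfile:
    """Read-pool composition for one simulated repair event."""

    n_reads: int = 1000
    frac_mmej_top: float = 0.6    # mass on the planted MMEJ product
    frac_nhej_del: float = 0.3    # spread over random non-MMEJ deletions
    frac_ins1: float = 0.1        # insertions at the cut
    seed: int = 0
    n_nhej_products: int = 3
    ins_bases: tuple[str, ...] = ("A",)
    ins_len: int = 1              # >1 models the rare longer insertions

    def __post_init__(self):
        total = self.frac_mmej_top + self.frac_nhej_del + self.frac_ins1
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile fractions sum to {total}, not 1")
        if min(self.frac_mmej_top, self.frac_nhej_del, self.frac_ins1) < 0:
            raise ValueError("profile fractions must be nonnegative")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if len(set(self.ins_bases)) != len(self.ins_bases):
            raise ValueError("ins_bases must be distinct")


def plant_mh_sequence(
    total_len: int,
    lam: int,
    dist: int,
    gc_arm: float,
    seed: int,
    max_attempts: int = 10_000,
) -> tuple[str, int, MicrohomologyPattern]:
    """Random background with exactly one cut-spanning arm pair.

    Returns ``(sequence, cut_index, pattern)`` where the enumerator finds
    the planted pattern — arm length ``lam``, spacing ``dist``, arm GC
    fraction ~``gc_arm`` — and nothing else.  The break sits at the window
    midpoint (``cut_index == total_len // 2``), so planted windows serve
    directly as centered prediction contexts.  Deterministic per seed.
    """
    if lam < MIN_JUNCTION_MH:
        raise ValueError(f"lam must be >= {MIN_JUNCTION_MH}")
    if dist < 0:
        raise ValueError("dist must be >= 0")
    if total_len < 2 * lam + dist + 40:
        raise ValueError(
            f"total_len {total_len} too short for lam={lam}, dist={dist} "
            "(needs 2*lam + dist + 40)"
        )
    rng = np.random.default_rng(seed)
    # pads chosen so the break sits at the window midpoint (cut == n//2),
    # making planted windows directly usable as centered contexts
    cut = total_len // 2
    i = cut - lam - dist // 2         # left arm start
    r = i + lam + dist                # right arm start
    left_pad = i
    right_pad = total_len - r - lam

    n_gc = int(round(gc_arm * lam))
    for attempt in range(max_attempts):
        gc_pos = rng.choice(lam, size=n_gc, replace=False)
        arm = np.where(
            np.isin(np.arange(lam), gc_pos),
            rng.choice(list("GC"), size=lam),
            rng.choice(list("AT"), size=lam),
        )
        arm_s = "".join(arm)
        seq = "".join(
            [
                "".join(rng.choice(_LEFT_ALPHABET, size=left_pad)),
                arm_s,
                "".join(rng.choice(_LEFT_ALPHABET, size=cut - i - lam)),
                "".join(rng.choice(_RIGHT_ALPHABET, size=r - cut)),
                arm_s,
                "".join(rng.choice(_RIGHT_ALPHABET, size=right_pad)),
            ]
        )
        pats = enumerate_mh_patterns(seq, cut)
        if (
            len(pats) == 1
            and pats[0].left_start == i
            and pats[0].lam == lam
            and pats[0].dist == dist
        ):
            return seq, cut, pats[0]
    raise RuntimeError(
        f"could not plant a unique pattern in {max_attempts} attempts "
        f"(total_len={total_len}, lam={lam}, dist={dist}, gc_arm={gc_arm})"
    )


def _sample_nhej_deletions(
    wt: str, cut: int, mmej_product: str | None, k: int,
    rng: np.random.Generator, max_attempts: int = 5000,
) -> list[tuple[str, int]]:
    """Distinct cut-straddling deletions with junction homology < 3."""
    products: list[tuple[str, int]] = []
    seen = {wt}
    if mmej_product is not None:
        seen.add(mmej_product)
    attempts = 0
    while len(products) < k and attempts < max_attempts:
        attempts += 1
        left = int(rng.integers(max(0, cut - 12), cut))
        min_len = cut - left + 1          # must straddle the break
        length = int(rng.integers(min_len, min_len + 10))
        if left + length > len(wt):
            continue
        if junction_microhomology(wt, left, length) >= MIN_JUNCTION_MH:
            continue
        product = wt[:left] + wt[left + length:]
        if product in seen:
            continue
        seen.add(product)
        products.append((product, length))
    if len(products) < k:
        raise RuntimeError(
            f"could not sample {k} distinct non-MMEJ deletions at cut {cut}"
        )
    return products


def simulate_repair_pool(
    wt: str,
    cut_index: int,
    profile: SimProfile,
    planted: MicrohomologyPattern | None = None,
    event_id: str = "sim",
) -> tuple[RepairEvent, TruthLabel]:
    """Multinomial read pool plus the truth label its counts imply.

    The label is derived from the realized counts and the known category
    of each simulated product, independently of the alignment-based
    labeling pipeline — `label_event` on the returned event must agree.
    """
    rng = np.random.default_rng(profile.seed)
    products: list[str] = []
    probs: list[float] = []
    info: dict[str, tuple[Category, int]] = {}

    mmej_product = None
    if profile.frac_mmej_top > 0:
        if planted is None:
            pats = enumerate_mh_patterns(wt, cut_index)
            if not pats:
                raise ValueError(
                    "wt has no cut-spanning microhomology but "
                    "frac_mmej_top > 0"
                )
            planted = menthu_rank(pats, cut_index).top
        mmej_product = planted.product
        products.append(mmej_product)
        probs.append(profile.frac_mmej_top)
        info[mmej_product] = (Category.MMEJ_DEL, planted.del_len)

    if profile.frac_nhej_del > 0:
        dels = _sample_nhej_deletions(
            wt, cut_index, mmej_product, profile.n_nhej_products, rng
        )
        for product, length in dels:
            products.append(product)
            probs.append(profile.frac_nhej_del / len(dels))
            info[product] = (Category.NONMMEJ_DEL, length)

    if profile.frac_ins1 > 0:
        cat = Category.INS_1BP if profile.ins_len == 1 else Category.INS_MULTI
        for base in profile.ins_bases:
            product = (
                wt[:cut_index] + base * profile.ins_len + wt[cut_index:]
            )
            products.append(product)
            probs.append(profile.frac_ins1 / len(profile.ins_bases))
            info[product] = (cat, profile.ins_len)

    counts = rng.multinomial(profile.n_reads, np.asarray(probs))
    reads = [(p, int(c)) for p, c in zip(products, counts) if c > 0]
    event = make_event(event_id, wt, cut_index, reads)

    category, length = info[event.top_read]
    majority = event.top_freq >= MAJORITY_THRESHOLD
    is_prema = category is Category.MMEJ_DEL and majority
    is_sm_ins = category is Category.INS_1BP and majority
    is_sm_fs = (is_prema and length % 3 != 0) or is_sm_ins
    label = TruthLabel(True, category, is_prema, is_sm_ins, is_sm_fs)
    return event, label


def _event_profile(
    event_type: str, rng: np.random.Generator, seed: int
) -> SimProfile:
    """Read-pool composition for one corpus event type."""
    if event_type == "prema":
        f = float(rng.uniform(0.55, 0.80))
        return SimProfile(1000, f, (1 - f) * 0.8, (1 - f) * 0.2, seed)
    if event_type == "mmej_minor":
        f = float(rng.uniform(0.30, 0.45))
        return SimProfile(1000, f, 1 - f - 0.05, 0.05, seed)
    if event_type == "nhej_top":
        if rng.random() < 0.5:   # single-majority non-MMEJ deletion
            return SimProfile(1000, 0.10, 0.60, 0.30, seed,
                              n_nhej_products=1)
        return SimProfile(1000, 0.10, 0.80, 0.10, seed, n_nhej_products=2)
    if event_type == "ins1_major":
        return SimProfile(1000, 0.15, 0.30, 0.55, seed)
    if event_type == "ins1_minor":
        return SimProfile(1000, 0.20, 0.40, 0.40, seed)
    if event_type == "ins_multi":
        return SimProfile(1000, 0.15, 0.40, 0.45, seed, ins_len=2)
    raise ValueError(event_type)


def generate_corpus(
    n_events: int,
    prema_prevalence: float = DEFAULT_PREMA_PREVALENCE,
    seed: int = 0,
) -> list[tuple[RepairEvent, TruthLabel]]:
    """In-memory labeled corpus of simulated repair events."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    mix = np.asarray(DEFAULT_CATEGORY_MIX) / sum(DEFAULT_CATEGORY_MIX)
    if not 0 <= prema_prevalence <= mix[1]:
        raise ValueError(
            f"prema_prevalence must lie in [0, {mix[1]:.3f}] under the "
            "default category mix"
        )
    type_probs = {
        "nhej_top": mix[0],
        "prema": prema_prevalence,
        "mmej_minor": mix[1] - prema_prevalence,
        "ins1_major": mix[2] * SM_INSERTION_RATE,
        "ins1_minor": mix[2] * (1 - SM_INSERTION_RATE),
        "ins_multi": mix[3],
    }
    names = list(type_probs)
    probs = np.asarray([type_probs[n] for n in names])
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    corpus = []
    for idx in range(n_events):
        event_type = str(rng.choice(names, p=probs))
        lam = int(rng.choice([3, 4, 5, 6], p=[0.4, 0.3, 0.2, 0.1]))
        dist = int(rng.choice(9, p=np.array(
            [3, 4, 4, 3, 2, 2, 1, 1, 1]) / 21))
        gc_arm = float(rng.uniform(0.25, 0.75))
        plant_seed = int(rng.integers(0, 2**31 - 1))
        pool_seed = int(rng.integers(0, 2**31 - 1))
        wt, cut, pattern = plant_mh_sequence(60, lam, dist, gc_arm, plant_seed)
        profile = _event_profile(event_type, rng, pool_seed)
        event, label = simulate_repair_pool(
            wt, cut, profile, pattern, event_id=f"ev{idx:05d}"
        )
        corpus.append((event, label))
    return corpus


def write_corpus(
    n_events: int,
    prema_prevalence: float = DEFAULT_PREMA_PREVALENCE,
    seed: int = 0,
    out_dir: str = ".",
) -> tuple[str, str]:
    """Write a labeled corpus as ``events.tsv`` + ``truth.tsv``.

    ``events.tsv`` follows the canonical schema (event_id, wt, cut_index,
    read_seq, count); ``truth.tsv`` carries the generator's labels.  Same
    seed, byte-identical files.
    """
    corpus = generate_corpus(n_events, prema_prevalence, seed)
    os.makedirs(out_dir, exist_ok=True)
    events_path = os.path.join(out_dir, "events.tsv")
    truth_path = os.path.join(out_dir, "truth.tsv")

    event_rows, truth_rows = [], []
    for event, label in corpus:
        for read, count in event.reads:
            event_rows.append(
                (event.event_id, event.wt, event.cut_index, read, count)
            )
        truth_rows.append(
            (
                event.event_id, True, label.category.value,
                round(event.top_freq, 6), label.is_prema,
                label.is_sm_insertion, label.is_sm_frameshift,
            )
        )
    pd.DataFrame(
        event_rows, columns=["event_id", "wt", "cut_index", "read_seq", "count"]
    ).to_csv(events_path, sep="\t", index=False)
    pd.DataFrame(
        truth_rows,
        columns=["event_id", "included", "category", "top_freq",
                 "is_prema", "is_sm_insertion", "is_sm_frameshift"],
    ).to_csv(truth_path, sep="\t", index=False)
    return events_path, truth_path


def rule_labeled_corpus(
    n: int,
    seed: int = 0,
    score_threshold: float = 1.50,
    dist_threshold: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-feature benchmark whose labels ARE the threshold rule.

    Random 60-mers are scanned at their midpoint; each site contributes a
    feature row (competition score, top spacing) and the label
    ``score >= score_threshold AND dist <= dist_threshold``.  Sites with
    no microhomology at all are skipped (they carry no features).
    """
    rng = np.random.default_rng(seed)
    X, y = [], []
    while len(X) < n:
        seq = "".join(rng.choice(_BASES, size=60))
        pats = enumerate_mh_patterns(seq, 30)
        if not pats:
            continue
        res = menthu_rank(pats, 30)
        X.append((res.menthu_score, res.top_dist))
        y.append(
            res.menthu_score >= score_threshold
            and res.top_dist <= dist_threshold
        )
    return np.asarray(X, dtype=float), np.asarray(y, dtype=bool)
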