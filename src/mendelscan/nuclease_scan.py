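"""PAM scanning: locate nuclease target sites and their cut positions.

SpCas9 requires an NGG protospacer-adjacent motif and cuts (blunt) 3 bp
5' of the PAM.  Cas12a (Cpf1) requires a 5' TTTV PAM (V = A/C/G) and cuts
distal to it; the staggered cut is represented here by a single nominal
blunt break a configurable number of nucleotides 3' of the 4-nt PAM
(default 18, the midpoint of the 18/23 stagger).

All coordinates are 0-based on the plus strand; ``cut_index`` counts the
bases 5' of the break, so the break sits between ``cut_index - 1`` and
``cut_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .mh_engine import check_sequence

__all__ = [
    "Nuclease",
    "GuideSite",
    "CAS12A_DEFAULT_OFFSET",
    "reverse_complement",
    "find_guide_sites",
    "extract_context",
]

CAS12A_DEFAULT_OFFSET = 18

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class Nuclease(str, Enum):
    SPCAS9 = "spcas9"
    CAS12A = "cas12a"


@dataclass(frozen=True)
class GuideSite:
    nuclease: Nuclease
    pam_start: int     # 0-based plus-strand index of the PAM's first base
    strand: str        # '+' or '-'
    cut_index: int     # 0-based plus-strand break position
    context: str | None = None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_guide_sites(
    seq: str,
    nuclease: Nuclease | str,
    both_strands: bool = True,
    cas12a_offset: int = CAS12A_DEFAULT_OFFSET,
) -> list[GuideSite]:
    """All PAM occurrences whose implied cut falls strictly inside ``seq``.

    Minus-strand sites are reported in plus-strand coordinates:
    ``pam_start`` is the plus-strand index of the leftmost base of the
    PAM's footprint, and ``cut_index`` the plus-strand break position
    (SpCas9 minus-strand PAM ``CCN`` at q cuts at ``q + 6``; Cas12a
    minus-strand PAM footprint at q cuts at ``q - cas12a_offset``).
    Results are sorted by ``cut_index``.
    """
    check_sequence(seq, "seq")
    nuclease = Nuclease(nuclease)
    n = len(seq)
    sites: list[GuideSite] = []

    if nuclease is Nuclease.SPCAS9:
        for p in range(n - 2):
            if seq[p + 1] == "G" and seq[p + 2] == "G":
                cut = p - 3
                if 0 < cut < n:
                    sites.append(GuideSite(nuclease, p, "+", cut))
        if both_strands:
            for q in range(n - 2):
                if seq[q] == "C" and seq[q + 1] == "C":
                    cut = q + 6
                    if 0 < cut < n:
                        sites.append(GuideSite(nuclease, q, "-", cut))
    elif nuclease is Nuclease.CAS12A:
        for p in range(n - 3):
            if seq[p: p + 3] == "TTT" and seq[p + 3] in "ACG":
                cut = p + 4 + cas12a_offset
                if 0 < cut < n:
                    sites.append(GuideSite(nuclease, p, "+", cut))
        if both_strands:
            for q in range(n - 3):
                if seq[q] in "TGC" and seq[q + 1: q + 4] == "AAA":
                    cut = q - cas12a_offset
                    if 0 < cut < n:
                        sites.append(GuideSite(nuclease, q, "-", cut))
    else:  # pragma: no cover - Nuclease() already rejects unknown values
        raise ValueError(f"unsupported nuclease {nuclease!r}")

    return sorted(sites, key=lambda s: (s.cut_index, s.strand, s.pam_start))


def extract_context(seq: str, cut_index: int, width: int) -> str | None:
    """Fixed-width window centered at the break, or None if out of bounds.

    ``width`` must be even; presets are 52 (microhomology scan) and 60
    (insertion-predictor input).  The break sits after window position
    ``width // 2 - 1``, i.e. at window cut index ``width // 2``.
    """
    if width % 2 != 0:
        raise ValueError(f"window width must be even, got {width}")
    half = width // 2
    if cut_index - half < 0 or cut_index + half > len(seq):
        return None
    return seq[cut_index - half: cut_index + half]


def with_context(site: GuideSite, seq: str, width: int) -> GuideSite | None:
    """Attach a centered context window to a site; None if unavailable."""
    ctx = extract_context(seq, site.cut_index, width)
    if ctx is None:
        return None
    return replace(site, context=ctx)
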