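"""Screening early coding sequence for homogeneous frameshift target sites.

For knockout design the interesting breaks sit early in the coding
sequence: the screen covers cut positions within the first 30% of the CDS,
or the first 182 bp (150 bp of screen plus 32 bp of upstream prediction
context) for short genes, whichever is larger.  Each targetable site is
evaluated for a PreMA (and, when an insertion adapter is supplied, a full
MENdel frameshift call); sites too close to a sequence end for a full
prediction window are skipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mendel import MENDEL_WINDOW, MendelCall, mendel_predict
from .mh_engine import (
    DEFAULT_DIST_THRESHOLD,
    DEFAULT_SCORE_THRESHOLD,
    MenthuResult,
    enumerate_mh_patterns,
    menthu_rank,
)
from .nuclease_scan import GuideSite, Nuclease, extract_context, find_guide_sites

__all__ = [
    "SiteCall",
    "GeneScreenReport",
    "MIN_SCREEN_SPAN",
    "EDGE_MARGIN",
    "screened_span",
    "screen_gene",
]

MIN_SCREEN_SPAN = 182     # bp: 150 screened + 32 upstream context
SCREEN_FRACTION = 0.30    # fraction of the CDS screened for longer genes
EDGE_MARGIN = 30          # nt of flanking sequence required on each side
MENTHU_WINDOW = 52


@dataclass(frozen=True)
class SiteCall:
    site: GuideSite
    menthu: MenthuResult
    mendel: MendelCall | None

    @property
    def frameshift_call(self) -> bool:
        """MENdel frameshift when available, else out-of-frame PreMA."""
        if self.mendel is not None:
            return self.mendel.frameshift_call
        return self.menthu.is_prema and self.menthu.top_frameshift


@dataclass
class GeneScreenReport:
    gene_id: str
    cds_len: int
    screenable: bool
    screened_span: int
    sites: list[SiteCall] = field(default_factory=list)
    n_context_deficient: int = 0
    has_early_frameshift_site: bool = False

    @property
    def prema_site_fraction(self) -> float | None:
        """Fraction of evaluated sites called PreMA (None with no sites)."""
        if not self.sites:
            return None
        n_prema = sum(1 for s in self.sites if s.menthu.is_prema)
        return n_prema / len(self.sites)


def screened_span(cds_len: int) -> int:
    """Cut positions below this bound are screened: max(30% of CDS, 182)."""
    return max(int(round(SCREEN_FRACTION * cds_len)), MIN_SCREEN_SPAN)


def screen_gene(
    cds: str,
    gene_id: str,
    nucleases=(Nuclease.SPCAS9,),
    insertion_adapter=None,
    both_strands: bool = True,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    dist_threshold: int = DEFAULT_DIST_THRESHOLD,
) -> GeneScreenReport:
    """Evaluate every early targetable site of one coding sequence.

    A CDS shorter than the minimum screenable span is reported as
    unscreenable rather than raising.  Context windows may extend past
    the screened span into downstream sequence.
    """
    span = screened_span(len(cds))
    report = GeneScreenReport(
        gene_id=gene_id,
        cds_len=len(cds),
        screenable=len(cds) >= MIN_SCREEN_SPAN,
        screened_span=span,
    )
    if not report.screenable:
        return report

    for nuclease in nucleases:
        for site in find_guide_sites(cds, nuclease, both_strands):
            if site.cut_index >= span:
                continue
            if (site.cut_index < EDGE_MARGIN
                    or site.cut_index > len(cds) - EDGE_MARGIN):
                report.n_context_deficient += 1
                continue
            window = extract_context(cds, site.cut_index, MENTHU_WINDOW)
            menthu = menthu_rank(
                enumerate_mh_patterns(window, MENTHU_WINDOW // 2),
                MENTHU_WINDOW // 2, score_threshold, dist_threshold,
            )
            mendel = None
            if insertion_adapter is not None:
                win60 = extract_context(cds, site.cut_index, MENDEL_WINDOW)
                mendel = mendel_predict(
                    win60, insertion_adapter,
                    score_threshold, dist_threshold,
                )
            report.sites.append(SiteCall(site, menthu, mendel))

    report.has_early_frameshift_site = any(
        s.frameshift_call for s in report.sites
    )
    return report
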