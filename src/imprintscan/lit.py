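"""LTR-initiated transcription units (LITs) and igDMR enrichment.

A LIT is a transcript whose transcription start site (TSS) falls inside a
long terminal repeat (LTR) of an endogenous retrovirus (classification
``Up``), or just outside a repeat edge (``UpEdge``).  Candidate igDMRs are
associated with LITs when they are embedded in the transcribed span or lie
immediately downstream of it, and the over-representation of LIT-associated
regions among igDMRs relative to all CpG islands is tested with a
one-degree-of-freedom chi-square goodness of fit.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, UsageError
from .methylome import MethylomeTrack, Region

__all__ = [
    "TranscriptModel",
    "RepeatElement",
    "LITCall",
    "LITAssociation",
    "EnrichmentResult",
    "MethDomain",
    "classify_transcript_initiation",
    "segment_hypermethylated_domains",
    "associate_lit_with_region",
    "lit_enrichment_test",
]


@dataclass(frozen=True)
class TranscriptModel:
    """Spliced transcript; exons are sorted, non-overlapping, 0-based
    half-open.  The TSS is the 5'-most transcribed base respecting strand."""

    chrom: str
    strand: str
    exons: tuple
    name: str = ""

    def __post_init__(self):
        if not self.exons:
            raise DataError(f"transcript {self.name!r} has no exons")
        if self.strand not in ("+", "-"):
            raise DataError(f"transcript {self.name!r}: bad strand {self.strand!r}")
        exons = tuple(tuple(e) for e in sorted(self.exons))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise DataError(f"transcript {self.name!r}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def span(self) -> tuple:
        """Exon-or-intron span (start of first exon, end of last), half-open."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def three_prime_end(self) -> int:
        return self.exons[-1][1] - 1 if self.strand == "+" else self.exons[0][0]


@dataclass(frozen=True)
class RepeatElement:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    family: str = ""
    class_label: str = "LTR"
    divergence: float | None = None  # RepeatMasker milliDiv when available

    def __post_init__(self):
        if not self.start < self.end:
            raise DataError(f"repeat {self.family!r}: start {self.start} !< end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LITCall:
    transcript: TranscriptModel
    tss_class: str                       # Up | UpEdge | none
    repeat: RepeatElement | None = None
    note: str = ""

    def __post_init__(self):
        if (self.repeat is not None) != (self.tss_class in ("Up", "UpEdge")):
            raise DataError("initiating repeat must be present iff tss_class is Up/UpEdge")


@dataclass
class LITAssociation:
    region: Region
    lit: LITCall | None
    relation: str            # embedded | downstream_within_window | none
    configuration: str       # sense | antisense | unknown


@dataclass
class EnrichmentResult:
    k_fore: int
    n_fore: int
    k_back: int
    n_back: int
    chi2: float
    p: float
    method: str = "chi2_gof"


@dataclass(frozen=True)
class MethDomain:
    chrom: str
    start: int
    end: int
    mean: float
    n_cpgs: int


# ---------------------------------------------------------------------------


def _repeat_sort_key(tss: int, strand: str):
    """Tie-break key: distance from TSS to the repeat's 5' boundary
    (relative to the transcript strand), then longest repeat, then coords."""

    def key(rep: RepeatElement):
        five_prime = rep.start if strand == "+" else rep.end - 1
        return (abs(tss - five_prime), -rep.length, rep.start, rep.end, rep.family)

    return key


def classify_transcript_initiation(
    transcript: TranscriptModel,
    repeats,
    edge_window: int = 100,
) -> LITCall:
    """Classify a transcript's initiation relative to repeat elements.

    ``Up``: TSS inside a repeat.  ``UpEdge``: TSS within ``edge_window`` bp
    outside a repeat lying on the transcript's upstream side (the repeat
    edge nearest the TSS is 1 bp away when they are adjacent).  Ties among
    overlapping repeats are broken by distance from the TSS to the repeat
    5' boundary, then by repeat length.
    """
    tss = transcript.tss
    same_chrom = [r for r in repeats if r.chrom == transcript.chrom]
    inside = [r for r in same_chrom if r.start <= tss < r.end]
    if inside:
        rep = min(inside, key=_repeat_sort_key(tss, transcript.strand))
        return LITCall(transcript, "Up", rep, note=f"TSS in {rep.family}")
    edge = []
    for r in same_chrom:
        if transcript.strand == "+":
            dist = tss - (r.end - 1)  # repeat upstream = left of TSS
        else:
            dist = r.start - tss      # repeat upstream = right of TSS
        if 1 <= dist <= edge_window:
            edge.append((dist, r))
    if edge:
        dist, rep = min(edge, key=lambda t: (t[0], -t[1].length, t[1].start, t[1].family))
        return LITCall(transcript, "UpEdge", rep,
                       note=f"TSS {dist} bp past {rep.family} edge")
    return LITCall(transcript, "none", None)


def segment_hypermethylated_domains(
    track: MethylomeTrack,
    min_meth: float = 0.7,
    max_gap_cpgs: int = 3,
    min_cpgs: int = 10,
) -> list:
    """Maximal runs of hypermethylated CpGs.

    A domain is a maximal run of CpGs starting and ending at sites with
    methylation fraction >= ``min_meth`` and containing at most
    ``max_gap_cpgs`` consecutive below-threshold sites internally.  Runs
    with fewer than ``min_cpgs`` sites (above- and below-threshold counted)
    are discarded.  Domain coordinates span the first C to the G of the
    last CpG (half-open).
    """
    domains = []
    df = track.df.dropna(subset=["fraction"])
    for chrom, sub in df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        frac = sub["fraction"].to_numpy()
        hyper = frac >= min_meth
        i = 0
        n = len(pos)
        while i < n:
            if not hyper[i]:
                i += 1
                continue
            # extend: j = last above-threshold site reachable with gaps <= max_gap
            j = i
            k = i + 1
            gap = 0
            while k < n:
                if hyper[k]:
                    j = k
                    gap = 0
                else:
                    gap += 1
                    if gap > max_gap_cpgs:
                        break
                k += 1
            count = j - i + 1
            if count >= min_cpgs:
                m = frac[i:j + 1]
                domains.append(MethDomain(chrom, int(pos[i]), int(pos[j]) + 2,
                                          float(m.mean()), count))
            i = j + 1
    return domains


def associate_lit_with_region(
    region: Region,
    lits,
    downstream_window: int = 2000,
) -> LITAssociation:
    """Associate a region with the best-supported LIT.

    ``embedded``: the region overlaps the transcript's exon-or-intron span.
    ``downstream_within_window``: the region begins within
    ``downstream_window`` bp past the transcript's 3' end on its strand.
    Embedded relations take precedence; ties are broken by overlap (then
    proximity), deterministically.  Configuration is ``sense`` when the
    transcript strand equals the region's gene strand, ``unknown`` when the
    region carries no gene strand or no LIT is found.
    """
    embedded = []
    downstream = []
    for lit in lits:
        if lit.tss_class not in ("Up", "UpEdge"):
            continue
        t = lit.transcript
        if t.chrom != region.chrom:
            continue
        s, e = t.span
        overlap = min(e, region.end) - max(s, region.start)
        if overlap > 0:
            embedded.append((-overlap, s, t.name, lit))
            continue
        if t.strand == "+":
            gap = region.start - e
        else:
            gap = s - region.end
        if 0 <= gap <= downstream_window:
            downstream.append((gap, s, t.name, lit))
    if embedded:
        lit = min(embedded)[-1]
        relation = "embedded"
    elif downstream:
        lit = min(downstream)[-1]
        relation = "downstream_within_window"
    else:
        return LITAssociation(region, None, "none", "unknown")
    if region.gene_strand in ("+", "-"):
        configuration = "sense" if lit.transcript.strand == region.gene_strand else "antisense"
    else:
        configuration = "unknown"
    return LITAssociation(region, lit, relation, configuration)


def lit_enrichment_test(
    k_fore: int,
    n_fore: int,
    k_back: int,
    n_back: int,
    method: str = "chi2_gof",
) -> EnrichmentResult:
    """Enrichment of LIT association among igDMRs versus background CGIs.

    The default is a one-degree-of-freedom chi-square goodness of fit of
    the observed foreground split ``(k_fore, n_fore - k_fore)`` against the
    expectation derived from the background proportion ``k_back / n_back``,
    without continuity correction, upper-tail p.  ``method="binomial"``
    computes the exact binomial upper tail instead.
    """
    if method not in ("chi2_gof", "binomial"):
        raise UsageError(f"unknown enrichment method {method!r}")
    if n_fore <= 0:
        raise UsageError("n_fore must be positive")
    if n_back <= 0:
        raise UsageError("n_back must be positive")
    for k, n, lbl in ((k_fore, n_fore, "foreground"), (k_back, n_back, "background")):
        if not 0 <= k <= n:
            raise UsageError(f"invalid {lbl} counts: {k}/{n}")
    p0 = k_back / n_back
    if k_back == 0:
        if k_fore > 0:
            # foreground hits with an empty background: off the chi-square scale
            return EnrichmentResult(k_fore, n_fore, k_back, n_back,
                                    float("inf"), 0.0, method)
        return EnrichmentResult(k_fore, n_fore, k_back, n_back, 0.0, 1.0, method)
    if method == "binomial":
        p = float(stats.binom.sf(k_fore - 1, n_fore, p0))
        chi2 = float("nan")
    else:
        observed = np.array([k_fore, n_fore - k_fore], dtype=float)
        expected = np.array([n_fore * p0, n_fore * (1.0 - p0)])
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(k_fore, n_fore, k_back, n_back, chi2, max(p, 0.0), method)
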