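"""Bimodal, allelic and imprinted methylation calls.

The evidence hierarchy runs: *bimodal* (reads at an overall ~50% level
split into nearly fully methylated and nearly unmethylated strands) ->
*allelic* (methylation class co-segregates with a SNP allele) ->
*imprinted* (the methylated allele has known parental origin, established
through trio genotypes).  Each step strictly requires the previous one, so
removing SNP or pedigree information can only move a call down the
hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .amplicon import AmpliconAlignment, AmpliconRef, ReadMethProfile
from .errors import MendelianInconsistencyError, UsageError

__all__ = [
    "BimodalityThresholds",
    "BimodalityVerdict",
    "AllelicResult",
    "AllelicCall",
    "classify_bimodality",
    "assign_allele",
    "allelic_methylation_test",
    "parental_origin",
    "imprinting_call",
]

FINAL_CALLS = (
    "maternal_methylated",
    "paternal_methylated",
    "allelic_origin_unknown",
    "bimodal_only",
    "none",
    "undetermined",
)


@dataclass(frozen=True)
class BimodalityThresholds:
    """Read-class cutoffs.  A read is *hyper* when its mean methylation
    exceeds ``read_hyper``, *hypo* below ``read_hypo``, else intermediate.
    Bimodality additionally requires both extreme classes to each hold at
    least ``min_class_fraction`` of reads, the intermediate class at most
    ``max_intermediate_fraction``, and the overall mean of read means to
    sit in ``overall_mean_window`` (the ~50% aggregate level)."""

    read_hyper: float = 0.7
    read_hypo: float = 0.3
    min_class_fraction: float = 0.25
    max_intermediate_fraction: float = 0.2
    overall_mean_window: tuple = (0.35, 0.65)
    min_reads: int = 10

    def __post_init__(self):
        if not self.read_hypo < self.read_hyper:
            raise UsageError("read_hypo must be < read_hyper")

    def classify_read(self, mean: float) -> str:
        if np.isnan(mean):
            return "undefined"
        if mean > self.read_hyper:
            return "hyper"
        if mean < self.read_hypo:
            return "hypo"
        return "intermediate"


@dataclass
class BimodalityVerdict:
    verdict: str               # bimodal | not_bimodal | undetermined
    n_hyper: int
    n_hypo: int
    n_intermediate: int
    overall_mean: float

    @property
    def n_classified(self) -> int:
        return self.n_hyper + self.n_hypo + self.n_intermediate


def classify_bimodality(
    profiles,
    thresholds: BimodalityThresholds = BimodalityThresholds(),
) -> BimodalityVerdict:
    """Classify reads and test for a bimodal methylation pattern."""
    means = [p.mean for p in profiles if not np.isnan(p.mean)]
    classes = [thresholds.classify_read(m) for m in means]
    n_hyper = classes.count("hyper")
    n_hypo = classes.count("hypo")
    n_int = classes.count("intermediate")
    n = len(classes)
    overall = float(np.mean(means)) if means else float("nan")
    if n < thresholds.min_reads:
        return BimodalityVerdict("undetermined", n_hyper, n_hypo, n_int, overall)
    lo, hi = thresholds.overall_mean_window
    bimodal = (
        n_hyper / n >= thresholds.min_class_fraction
        and n_hypo / n >= thresholds.min_class_fraction
        and n_int / n <= thresholds.max_intermediate_fraction
        and lo <= overall <= hi
    )
    return BimodalityVerdict("bimodal" if bimodal else "not_bimodal",
                             n_hyper, n_hypo, n_int, overall)


def assign_allele(alignment: AmpliconAlignment, ref: AmpliconRef) -> str:
    """Assign a read to the reference or alternate SNP allele.

    Matching is bisulfite-aware: on the top strand a genomic C allele reads
    as C or (converted) T.  A C/T SNP on the top strand -- or G/A on the
    bottom -- is therefore intrinsically confounded with conversion and
    always returns ``ambiguous``, as does an uncovered SNP or a base
    compatible with both or neither allele.
    """
    if ref.snp is None:
        raise UsageError(f"{ref.name}: no SNP defined")
    pos, ref_a, alt_a = ref.snp
    strand = alignment.strand
    confounded = {"C", "T"} if strand == "top" else {"G", "A"}
    if {ref_a, alt_a} == confounded:
        return "ambiguous"
    base = alignment.read_base_at(pos)
    if base is None:
        return "ambiguous"

    def matches(allele: str) -> bool:
        if base == allele:
            return True
        if strand == "top":
            return allele == "C" and base == "T"
        return allele == "G" and base == "A"

    m_ref, m_alt = matches(ref_a), matches(alt_a)
    if m_ref and not m_alt:
        return "ref"
    if m_alt and not m_ref:
        return "alt"
    return "ambiguous"


@dataclass
class AllelicResult:
    """Allele x methylation-class association for one region."""

    status: str                  # allelic | not_allelic | undetermined
    table: np.ndarray | None     # rows ref/alt x cols hyper/hypo
    concordance: float
    p: float
    methylated_allele: str | None   # 'ref' | 'alt' when allelic


def allelic_methylation_test(
    profiles,
    thresholds: BimodalityThresholds = BimodalityThresholds(),
    alpha: float = 0.05,
    min_concordance: float = 0.9,
    min_reads_per_allele: int = 5,
) -> AllelicResult:
    """Test whether methylation class co-segregates with the SNP allele.

    Only hyper/hypo reads with an unambiguous allele enter the 2x2 table
    (intermediate strands are excluded, since the allelic definition
    concerns fully hyper- or hypomethylated strands).  Concordance is the
    larger, over the two possible pairings, of the fraction of reads
    consistent with exactly one allele being methylated; significance is a
    two-sided Fisher exact test on the table.
    """
    table = np.zeros((2, 2), dtype=int)   # rows: ref, alt; cols: hyper, hypo
    for p in profiles:
        if p.allele not in ("ref", "alt"):
            continue
        cls = thresholds.classify_read(p.mean)
        if cls not in ("hyper", "hypo"):
            continue
        table[0 if p.allele == "ref" else 1, 0 if cls == "hyper" else 1] += 1
    if table[0].sum() < min_reads_per_allele or table[1].sum() < min_reads_per_allele:
        return AllelicResult("undetermined", table, float("nan"), float("nan"), None)
    total = table.sum()
    ref_meth = (table[0, 0] + table[1, 1]) / total   # ref methylated, alt not
    alt_meth = (table[0, 1] + table[1, 0]) / total
    if ref_meth >= alt_meth:
        concordance, methylated = ref_meth, "ref"
    else:
        concordance, methylated = alt_meth, "alt"
    _, p = stats.fisher_exact(table, alternative="two-sided")
    allelic = concordance >= min_concordance and p < alpha
    return AllelicResult(
        "allelic" if allelic else "not_allelic",
        table, float(concordance), float(p),
        methylated if allelic else None,
    )


def parental_origin(offspring, maternal, paternal) -> dict | None:
    """Derive the parental origin of the offspring's alleles from a trio.

    Genotypes are unordered allele pairs (e.g. ``("A", "G")``).  Returns a
    map ``{allele: "maternal" | "paternal"}`` when the offspring is
    heterozygous and the parental genotypes admit a unique assignment
    (e.g. mother AA x father GG), otherwise ``None`` (uninformative).  An
    offspring allele absent from both parents raises
    :class:`MendelianInconsistencyError`.
    """
    off = tuple(offspring)
    mo, fa = set(maternal), set(paternal)
    for allele in off:
        if allele not in mo and allele not in fa:
            raise MendelianInconsistencyError(
                f"offspring allele {allele!r} absent from both parents"
            )
    if off[0] == off[1]:
        return None
    a, b = off
    assignments = []
    if a in mo and b in fa:
        assignments.append({a: "maternal", b: "paternal"})
    if b in mo and a in fa:
        assignments.append({b: "maternal", a: "paternal"})
    if len(assignments) == 1:
        return assignments[0]
    return None


@dataclass
class AllelicCall:
    """Final per-region call with its supporting evidence."""

    final: str
    bimodality: BimodalityVerdict
    allelic: AllelicResult | None
    origin: dict | None


def imprinting_call(
    bimodality: BimodalityVerdict,
    allelic: AllelicResult | None,
    origin: dict | None,
    snp_alleles: tuple | None = None,
) -> AllelicCall:
    """Combine the evidence hierarchy into a final call.

    ``snp_alleles`` gives the bases of the (ref, alt) alleles so that the
    methylated allele can be looked up in the parental-origin map.  The
    lattice: imprinted (with direction) iff allelic and origin informative;
    allelic without origin -> ``allelic_origin_unknown``; bimodal without
    SNP support -> ``bimodal_only``; not bimodal -> ``none``; too few reads
    -> ``undetermined``.
    """
    if bimodality.verdict == "undetermined":
        final = "undetermined"
    elif bimodality.verdict == "not_bimodal":
        final = "none"
    elif allelic is None or allelic.status == "undetermined":
        final = "bimodal_only"
    elif allelic.status == "not_allelic":
        final = "bimodal_only"
    else:
        base = None
        if snp_alleles is not None and allelic.methylated_allele is not None:
            base = snp_alleles[0] if allelic.methylated_allele == "ref" else snp_alleles[1]
        side = origin.get(base) if (origin and base is not None) else None
        if side == "maternal":
            final = "maternal_methylated"
        elif side == "paternal":
            final = "paternal_methylated"
        else:
            final = "allelic_origin_unknown"
    return AllelicCall(final, bimodality, allelic, origin)
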