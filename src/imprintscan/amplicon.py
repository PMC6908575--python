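"""Targeted bisulfite amplicon analysis.

Bisulfite treatment converts unmethylated cytosine to uracil (read as T)
while methylated cytosines resist conversion.  Reads from the converted top
strand therefore differ from the genomic reference by C->T at every
unmethylated C; a bisulfite-aware aligner must score such substitutions as
matches and exclude them from the mismatch count.  This module aligns
amplicon reads to an unconverted reference, applies read selection and
conversion QC, and calls methylation per read and per CpG, in the style of
clone-based tools for targeted bisulfite sequencing.

Scoring defaults: match +1, bisulfite-consistent substitution +1 (not a
mismatch), mismatch -1, gap open -2, gap extend -1.  These are exposed in
:class:`AlignScores` because the original web tools do not publish their
internals; the load-bearing contract is the bisulfite-consistency rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _align
from .errors import DataError, ReadRejectedError, UsageError

__all__ = [
    "AmpliconRef",
    "AlignScores",
    "AmpliconAlignment",
    "ReadMethProfile",
    "AmpliconRead",
    "read_fastq",
    "bisulfite_align",
    "select_reads",
    "call_read_profile",
    "per_cpg_levels",
    "conversion_qc",
    "QCReport",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq.upper()], dtype=np.int8)


def find_cpgs(sequence: str) -> tuple:
    """0-based positions of the C of every CpG on the forward strand."""
    seq = sequence.upper()
    return tuple(i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")


@dataclass(frozen=True)
class AmpliconRef:
    """Unconverted genomic top-strand reference for one amplicon.

    ``snp`` is an optional ``(position, ref_allele, alt_allele)`` triple;
    it must not fall within a CpG dinucleotide, because a methylation state
    would then be confounded with the genotype.  ``mismatch_allowance``
    overrides the global allowance for this locus (used in the source study
    for one repetitive amplicon).
    """

    name: str
    sequence: str
    snp: tuple | None = None
    mismatch_allowance: int | None = None
    cpg_positions: tuple = ()

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        cpgs = find_cpgs(seq)
        if self.cpg_positions:
            for p in self.cpg_positions:
                if not (p + 1 < len(seq) and seq[p] == "C" and seq[p + 1] == "G"):
                    raise DataError(f"{self.name}: position {p} is not a CpG")
        else:
            object.__setattr__(self, "cpg_positions", cpgs)
        if self.snp is not None:
            pos, ref_a, alt_a = self.snp
            if ref_a == alt_a:
                raise DataError(f"{self.name}: SNP alleles identical ({ref_a})")
            in_cpg = {c for c in self.cpg_positions} | {c + 1 for c in self.cpg_positions}
            if pos in in_cpg:
                raise DataError(f"{self.name}: SNP at {pos} falls within a CpG")


@dataclass(frozen=True)
class AlignScores:
    match: int = 1
    mismatch: int = -1
    gap_open: int = 2      # cost of the first gap base (positive)
    gap_extend: int = 1    # cost of each further gap base (positive)
    free_ref_ends: bool = True


def _submat(strand: str, scores: AlignScores) -> np.ndarray:
    """5x5 substitution matrix (A,C,G,T,N) with bisulfite consistency.

    Top strand: reference C read as T is consistent (converted,
    unmethylated C).  Bottom strand: reference G read as A.
    """
    mat = np.full((5, 5), scores.mismatch, dtype=np.int64)
    for b in range(4):
        mat[b, b] = scores.match
    mat[4, :] = scores.mismatch
    mat[:, 4] = scores.mismatch
    if strand == "top":
        mat[_CODE["T"], _CODE["C"]] = scores.match   # read T vs ref C
    elif strand == "bottom":
        mat[_CODE["A"], _CODE["G"]] = scores.match   # read A vs ref G
    else:
        raise UsageError(f"strand must be 'top' or 'bottom', got {strand!r}")
    return mat


def _is_consistent(read_base: str, ref_base: str, strand: str) -> bool:
    if read_base == ref_base:
        return True
    if strand == "top":
        return ref_base == "C" and read_base == "T"
    return ref_base == "G" and read_base == "A"


@dataclass
class AmpliconAlignment:
    """Alignment of one read to one amplicon reference.

    ``pairs`` lists ``(ref_pos, read_pos)`` columns; ``None`` marks a gap.
    ``mismatches`` counts substitutions that are not bisulfite-consistent.
    """

    read_id: str
    read_seq: str
    ref_name: str
    strand: str
    score: int
    pairs: list
    mismatches: int

    def read_base_at(self, ref_pos: int) -> str | None:
        for rp, qp in self.pairs:
            if rp == ref_pos:
                return self.read_seq[qp] if qp is not None else None
        return None


def bisulfite_align(
    read_seq: str,
    ref: AmpliconRef,
    strand: str = "top",
    scores: AlignScores = AlignScores(),
    read_id: str = "",
) -> AmpliconAlignment:
    """Globally align a bisulfite read to an unconverted reference.

    Affine-gap dynamic programming with bisulfite-consistent substitutions
    scored as matches; deterministic tie-breaking (leftmost placement).
    Reads longer than twice the reference are rejected.
    """
    if not read_seq:
        raise ReadRejectedError(f"{read_id or 'read'}: empty sequence")
    if len(read_seq) > 2 * len(ref.sequence):
        raise ReadRejectedError(
            f"{read_id or 'read'}: length {len(read_seq)} exceeds 2x reference "
            f"({len(ref.sequence)})"
        )
    read_seq = read_seq.upper()
    submat = _submat(strand, scores)
    score, pairs = _align.align(
        _encode(read_seq), _encode(ref.sequence), submat,
        scores.gap_open, scores.gap_extend, scores.free_ref_ends,
    )
    mismatches = 0
    for rp, qp in pairs:
        if rp is None or qp is None:
            continue
        if not _is_consistent(read_seq[qp], ref.sequence[rp], strand):
            mismatches += 1
    return AmpliconAlignment(read_id, read_seq, ref.name, strand, score, pairs, mismatches)


# ---------------------------------------------------------------------------
# Reads and selection


@dataclass(frozen=True)
class AmpliconRead:
    id: str
    sequence: str
    is_read1: bool = True


def read_fastq(path) -> list:
    """Load reads; orientation taken from an ``/1`` / ``/2`` id suffix or an
    Illumina ``1:N:...`` description token (absent metadata means R1)."""
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        is_r1 = True
        if rec.id.endswith("/2"):
            is_r1 = False
        elif rec.id.endswith("/1"):
            is_r1 = True
        else:
            desc = rec.description.split()
            if len(desc) > 1 and desc[1].startswith("2:"):
                is_r1 = False
        reads.append(AmpliconRead(rec.id, str(rec.seq), is_r1))
    return reads


@dataclass
class SelectedRead:
    read: AmpliconRead
    alignment: AmpliconAlignment | None
    ref_name: str | None
    kept: bool
    reason: str = ""


def select_reads(
    reads,
    refs=None,
    max_reads: int = 400,
    orientation: str = "forward_only",
    max_mismatches: int = 10,
    strand: str = "top",
    scores: AlignScores = AlignScores(),
) -> list:
    """Select and (optionally) map amplicon reads.

    Keeps the first ``max_reads`` forward (R1) reads in file order -- the
    "top N" rule of the source protocol.  When ``refs`` (one or more
    :class:`AmpliconRef`) are given, each kept read is aligned to every
    reference; reads exceeding the mismatch allowance (the per-locus
    override when the reference defines one) are dropped, as are reads
    without a unique best-scoring reference.  Returns
    :class:`SelectedRead` records; ``kept`` marks survivors.
    """
    if orientation not in ("forward_only", "all"):
        raise UsageError(f"unknown orientation {orientation!r}")
    pool = [r for r in reads if r.is_read1] if orientation == "forward_only" else list(reads)
    pool = pool[:max_reads]
    out = []
    for read in pool:
        if refs is None:
            out.append(SelectedRead(read, None, None, True))
            continue
        alns = []
        for ref in refs:
            try:
                alns.append((ref, bisulfite_align(read.sequence, ref, strand, scores, read.id)))
            except ReadRejectedError as exc:
                alns.append((ref, exc))
        ok = [(ref, a) for ref, a in alns if isinstance(a, AmpliconAlignment)]
        if not ok:
            out.append(SelectedRead(read, None, None, False, "rejected by aligner"))
            continue
        best = max(a.score for _, a in ok)
        top = [(ref, a) for ref, a in ok if a.score == best]
        if len(top) > 1:
            out.append(SelectedRead(read, None, None, False, "ambiguous best reference"))
            continue
        ref, aln = top[0]
        allowance = ref.mismatch_allowance if ref.mismatch_allowance is not None else max_mismatches
        if aln.mismatches > allowance:
            out.append(SelectedRead(read, aln, ref.name, False,
                                    f"{aln.mismatches} mismatches > allowance {allowance}"))
        else:
            out.append(SelectedRead(read, aln, ref.name, True))
    return out


# ---------------------------------------------------------------------------
# Methylation calling


@dataclass
class ReadMethProfile:
    """Per-CpG methylation states of one read.

    ``states`` maps CpG reference position -> ``methylated`` (read C at a
    reference CpG C), ``unmethylated`` (read T) or ``missing``.  The
    conversion rate is estimated from non-CpG reference cytosines, which
    should all read T after complete conversion.
    """

    read_id: str
    states: dict
    mean: float                 # NaN when no CpG called
    n_cpgs_called: int
    n_unconverted_noncpg: int
    n_converted_noncpg: int
    allele: str | None = None

    @property
    def conversion_rate(self) -> float:
        tot = self.n_converted_noncpg + self.n_unconverted_noncpg
        return self.n_converted_noncpg / tot if tot else float("nan")


def call_read_profile(alignment: AmpliconAlignment, ref: AmpliconRef) -> ReadMethProfile:
    """Call per-CpG methylation and conversion metrics for one read."""
    strand = alignment.strand
    seq = ref.sequence
    base_at = {rp: (alignment.read_seq[qp] if qp is not None else None)
               for rp, qp in alignment.pairs if rp is not None}
    if strand == "top":
        meth_call = {"C": "methylated", "T": "unmethylated"}
        noncpg_positions = [i for i, b in enumerate(seq)
                            if b == "C" and i not in ref.cpg_positions]
        retained, converted = "C", "T"
        cpg_read_pos = list(ref.cpg_positions)
    else:
        # bottom strand reads G (methylated) / A (converted) at the G of a CpG
        meth_call = {"G": "methylated", "A": "unmethylated"}
        noncpg_positions = [i for i, b in enumerate(seq)
                            if b == "G" and i - 1 not in ref.cpg_positions]
        retained, converted = "G", "A"
        cpg_read_pos = [c + 1 for c in ref.cpg_positions]
    states = {}
    for cpg, pos in zip(ref.cpg_positions, cpg_read_pos):
        base = base_at.get(pos)
        states[cpg] = meth_call.get(base, "missing") if base else "missing"
    called = [s for s in states.values() if s != "missing"]
    n_called = len(called)
    mean = (sum(s == "methylated" for s in called) / n_called) if n_called else float("nan")
    n_unconv = n_conv = 0
    for pos in noncpg_positions:
        base = base_at.get(pos)
        if base == retained:
            n_unconv += 1
        elif base == converted:
            n_conv += 1
    return ReadMethProfile(alignment.read_id, states, mean, n_called, n_unconv, n_conv)


def per_cpg_levels(profiles) -> pd.DataFrame:
    """Aggregate read profiles to a per-CpG methylation table.

    One row per CpG reference position with methylated / unmethylated read
    counts and the methylation fraction (missing states excluded).
    """
    if not profiles:
        raise UsageError("per_cpg_levels requires at least one profile")
    counts: dict = {}
    for p in profiles:
        for pos, state in p.states.items():
            if state == "missing":
                continue
            m, u = counts.get(pos, (0, 0))
            if state == "methylated":
                counts[pos] = (m + 1, u)
            else:
                counts[pos] = (m, u + 1)
    all_pos = sorted({pos for p in profiles for pos in p.states})
    rows = []
    for pos in all_pos:
        m, u = counts.get(pos, (0, 0))
        frac = m / (m + u) if (m + u) else float("nan")
        rows.append({"cpg_pos": pos, "n_meth": m, "n_unmeth": u, "fraction": frac})
    return pd.DataFrame(rows)


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    n_dropped_conversion: int
    n_undefined_conversion: int
    global_conversion: float    # NaN when not estimable
    control_conversion: float | None = None


def conversion_qc(
    profiles,
    min_conversion: float = 0.9,
    control_profiles=None,
) -> tuple:
    """Filter reads by bisulfite conversion rate.

    Reads with conversion below ``min_conversion`` are dropped; reads with
    no non-CpG cytosine (conversion undefined) are retained and counted as
    flagged.  ``control_profiles`` (e.g. reads mapped to an unmethylated
    lambda spike-in) yield an independent global conversion estimate.
    Returns ``(QCReport, kept_profiles)``.
    """
    profiles = list(profiles)
    kept, dropped, undefined = [], 0, 0
    tot_conv = tot_all = 0
    for p in profiles:
        tot_conv += p.n_converted_noncpg
        tot_all += p.n_converted_noncpg + p.n_unconverted_noncpg
        rate = p.conversion_rate
        if np.isnan(rate):
            undefined += 1
            kept.append(p)
        elif rate < min_conversion:
            dropped += 1
        else:
            kept.append(p)
    global_conv = tot_conv / tot_all if tot_all else float("nan")
    control_conv = None
    if control_profiles is not None:
        c = sum(p.n_converted_noncpg for p in control_profiles)
        t = c + sum(p.n_unconverted_noncpg for p in control_profiles)
        control_conv = c / t if t else float("nan")
    report = QCReport(len(profiles), len(kept), dropped, undefined,
                      global_conv, control_conv)
    return report, kept
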