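"""Synthetic data with known truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* a panel of per-CpG methylomes (oocyte, sperm, blastocyst, placenta,
  somatic) over candidate CpG-island regions, a planted fraction of which
  are igDMRs -- oocyte-hypermethylated, sperm-hypomethylated, retained in
  blastocyst, intermediate in placenta/somatic -- with beta-binomial count
  noise;
* a genome annotation in which a subset of planted igDMRs is LIT-driven:
  spanned by a transcript whose 5' end lies inside an LTR-labelled repeat;
* bisulfite amplicon reads carrying one of two SNP-tagged alleles with
  distinct per-CpG methylation probabilities, incomplete conversion and
  sequencing error;
* trio genotypes with known parental origin.

Every simulated record is traceable to a truth label, so sensitivity and
specificity of each downstream operation can be scored without external
files.  All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .lit import RepeatElement, TranscriptModel
from .methylome import MethylomeTrack, Region
from .amplicon import AmpliconRead, AmpliconRef

__all__ = [
    "SimulationConfig",
    "AmpliconSimConfig",
    "AnnotationBundle",
    "AmpliconTruth",
    "TrioResult",
    "simulate_annotation",
    "simulate_methylomes",
    "simulate_amplicon_reads",
    "simulate_trio",
    "write_annotation",
    "write_amplicon_files",
]

# tissue -> (igDMR truth mean, background truth mean); the igDMR profile
# satisfies the screen thresholds with margin, the background violates the
# oocyte criterion.  Values sit on a 0.05 grid so that counts are exact in
# the noise-free limit at the default coverage of 20.
DEFAULT_TISSUE_MEANS = {
    "oocyte": (0.90, 0.10),
    "sperm": (0.05, 0.05),
    "blastocyst": (0.45, 0.10),
    "placenta": (0.50, 0.10),
    "liver": (0.50, 0.10),
}


def _check_proportion(name, value):
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name}={value} outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the annotation + methylome bundle."""

    seed: int = 0
    n_regions: int = 200
    fraction_igdmr: float = 0.2
    fraction_lit_driven: float = 0.3
    tissue_truth_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    beta_concentration: float = 50.0
    cpg_spacing: int = 50
    cpgs_per_region: int = 20
    coverage_per_cpg: int = 20
    region_spacing: int = 10_000
    chrom: str = "chrSim"

    def __post_init__(self):
        _check_proportion("fraction_igdmr", self.fraction_igdmr)
        _check_proportion("fraction_lit_driven", self.fraction_lit_driven)
        for tissue, (mi, mb) in self.tissue_truth_means.items():
            _check_proportion(f"tissue_truth_means[{tissue}][igdmr]", mi)
            _check_proportion(f"tissue_truth_means[{tissue}][background]", mb)
        if self.beta_concentration <= 0:
            raise ConfigError("beta_concentration must be positive (inf = noise-free)")
        if self.n_regions < 0 or self.coverage_per_cpg <= 0:
            raise ConfigError("counts must be positive")

    def noise_free(self) -> "SimulationConfig":
        from dataclasses import replace

        return replace(self, beta_concentration=math.inf)


@dataclass
class AnnotationBundle:
    regions: list
    repeats: list
    transcripts: list
    truth: pd.DataFrame            # name, is_igdmr, is_lit_driven
    config: SimulationConfig


def simulate_annotation(config: SimulationConfig) -> AnnotationBundle:
    """Lay out candidate regions, repeats and transcripts on one chromosome.

    Each region is a CpG-island-like grid of ``cpgs_per_region`` CpGs.  A
    LIT-driven igDMR gets an upstream LTR repeat and a two-exon transcript
    whose TSS falls inside the repeat and whose span covers the region;
    non-LIT igDMRs get a transcript initiating outside any repeat (a
    single-copy oocyte promoter); background regions are untranscribed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_regions
    n_igdmr = round(n * config.fraction_igdmr)
    igdmr_idx = np.sort(rng.choice(n, size=n_igdmr, replace=False))
    n_lit = round(n_igdmr * config.fraction_lit_driven)
    lit_idx = set(np.sort(rng.choice(igdmr_idx, size=n_lit, replace=False))) if n_igdmr else set()
    igdmr_set = set(igdmr_idx.tolist())

    span = (config.cpgs_per_region - 1) * config.cpg_spacing + 2
    regions, repeats, transcripts, rows = [], [], [], []
    for i in range(n):
        start = 5000 + i * config.region_spacing
        region = Region(config.chrom, start, start + span, name=f"region_{i:05d}",
                        gene_strand="+")
        regions.append(region)
        is_igdmr = i in igdmr_set
        is_lit = i in lit_idx
        if is_lit:
            rep = RepeatElement(config.chrom, start - 3000, start - 2400,
                                strand="+", family="LTRsim", class_label="LTR")
            repeats.append(rep)
            transcripts.append(TranscriptModel(
                config.chrom, "+",
                exons=((rep.start + 100, rep.start + 300),
                       (start - 200, start + span + 500)),
                name=f"tx_{i:05d}",
            ))
        elif is_igdmr:
            # transcribed, but from a single-copy (non-repeat) promoter
            transcripts.append(TranscriptModel(
                config.chrom, "+",
                exons=((start - 1500, start - 1300),
                       (start - 200, start + span + 500)),
                name=f"tx_{i:05d}",
            ))
        rows.append({"name": region.name, "is_igdmr": is_igdmr, "is_lit_driven": is_lit})
    truth = pd.DataFrame(rows)
    return AnnotationBundle(regions, repeats, transcripts, truth, config)


def simulate_methylomes(bundle: AnnotationBundle, config: SimulationConfig | None = None) -> dict:
    """Draw per-CpG counts for every tissue of the panel.

    Per CpG the methylation probability is beta-distributed around the
    tissue truth mean with concentration ``beta_concentration`` and counts
    are binomial at ``coverage_per_cpg``.  An infinite concentration is the
    noise-free limit: counts are the deterministic rounding of coverage x
    truth mean (exact whenever the product is integral, as with the
    defaults).
    """
    config = config or bundle.config
    rng = np.random.default_rng(config.seed + 1)
    truth = bundle.truth.set_index("name")["is_igdmr"]
    cov = config.coverage_per_cpg
    noise_free = math.isinf(config.beta_concentration)
    tracks = {}
    for tissue, (mean_ig, mean_bg) in config.tissue_truth_means.items():
        rows = []
        for region in bundle.regions:
            mean = mean_ig if truth[region.name] else mean_bg
            pos = np.arange(config.cpgs_per_region) * config.cpg_spacing + region.start
            if noise_free:
                m = np.full(pos.shape, int(round(mean * cov)))
            else:
                c = config.beta_concentration
                p = rng.beta(max(mean * c, 1e-12), max((1 - mean) * c, 1e-12), size=pos.shape)
                m = rng.binomial(cov, p)
            for x, mm in zip(pos, m):
                rows.append((region.chrom, int(x), int(mm), cov - int(mm)))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "count_meth", "count_unmeth"])
        tracks[tissue] = MethylomeTrack(tissue, df)
    return tracks


# ---------------------------------------------------------------------------
# Amplicon reads


@dataclass(frozen=True)
class AmpliconSimConfig:
    """Study conditions for one simulated bisulfite amplicon.

    Defaults mirror a typical targeted assay: a ~200-bp amplicon with 10
    CpGs, a maternal allele methylated at 0.9 per CpG and a paternal
    allele at 0.05, 1% conversion failure, 0.2% sequencing error, 400
    forward reads.  The maternal allele carries ``snp_alleles[0]``.
    """

    ref_length: int = 200
    n_cpgs: int = 10
    snp_position: int = 95
    snp_alleles: tuple = ("A", "G")
    p_meth_maternal: float = 0.9
    p_meth_paternal: float = 0.05
    conversion_failure_rate: float = 0.01
    seq_error_rate: float = 0.002
    n_reads: int = 400
    seed: int = 0
    strand: str = "top"
    # bimodal region WITHOUT allelic association: each read is drawn from
    # the hyper (p_meth_maternal) or hypo (p_meth_paternal) template with
    # probability 1/2 independently of its allele -- both alleles then have
    # the same methylation distribution (the null of the allelic test)
    allele_independent_bimodal: bool = False

    def __post_init__(self):
        for name in ("p_meth_maternal", "p_meth_paternal",
                     "conversion_failure_rate", "seq_error_rate"):
            _check_proportion(name, getattr(self, name))
        if len(set(self.snp_alleles)) != 2:
            raise ConfigError("snp_alleles must be two distinct bases")
        if self.strand not in ("top", "bottom"):
            raise ConfigError(f"strand must be top or bottom, got {self.strand!r}")
        if self.n_reads < 0 or self.ref_length < 20 or self.n_cpgs < 1:
            raise ConfigError("invalid amplicon geometry")


@dataclass
class AmpliconTruth:
    """Per-read truth: allele and per-CpG methylation states."""

    per_read: pd.DataFrame         # read_id, allele, meth_states (0/1 string)
    cpg_positions: tuple
    config: AmpliconSimConfig


def _build_amplicon_reference(config: AmpliconSimConfig, rng) -> AmpliconRef:
    """Random amplicon with evenly spaced CpGs, scattered non-CpG Cs for
    conversion QC, and the SNP (reference allele) at its position."""
    L = config.ref_length
    seq = list(rng.choice(list("AGT"), size=L))     # no C yet: no stray CpGs
    # sprinkle non-CpG cytosines (about 10%), avoiding a following G
    for i in range(0, L - 1, 9):
        if seq[i + 1] != "G":
            seq[i] = "C"
    # evenly spaced CpGs in the central portion
    cpg_gap = max((L - 40) // config.n_cpgs, 2)
    cpgs = []
    pos = 20
    while len(cpgs) < config.n_cpgs and pos < L - 2:
        if abs(pos - config.snp_position) > 2:
            seq[pos], seq[pos + 1] = "C", "G"
            cpgs.append(pos)
        pos += cpg_gap
    if len(cpgs) < config.n_cpgs:
        raise ConfigError("reference too short for the requested number of CpGs")
    snp_pos = config.snp_position
    ref_a, alt_a = config.snp_alleles
    seq[snp_pos] = ref_a
    # SNP must not create or sit in a CpG
    if snp_pos + 1 < L and seq[snp_pos + 1] == "G" and ref_a == "C":
        seq[snp_pos + 1] = "A"
    if snp_pos >= 1 and seq[snp_pos - 1] == "C" and ref_a == "G":
        seq[snp_pos - 1] = "A"
    # scrub any stray CpG outside the planted set so the non-CpG conversion
    # model holds exactly
    planted = set(cpgs)
    for i in range(L - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in planted:
            seq[i] = "A"
    return AmpliconRef("amplicon_sim", "".join(seq), snp=(snp_pos, ref_a, alt_a),
                       cpg_positions=tuple(cpgs))


_OTHER = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def simulate_amplicon_reads(config: AmpliconSimConfig):
    """Simulate SNP-tagged bisulfite amplicon reads.

    Returns ``(reads, ref, truth)``.  Each read carries one allele at the
    SNP (maternal = reference allele); each CpG is methylated with the
    allele's probability; unmethylated CpG Cs and all non-CpG Cs convert
    C->T with probability ``1 - conversion_failure_rate``; uniform base
    errors are applied last.  Reads are forward (R1), full amplicon length.
    """
    rng = np.random.default_rng(config.seed)
    ref = _build_amplicon_reference(config, rng)
    ref_a, alt_a = config.snp_alleles
    snp_pos = ref.snp[0]
    cpgs = ref.cpg_positions
    reads, rows = [], []
    for r in range(config.n_reads):
        maternal = bool(rng.random() < 0.5)
        if config.allele_independent_bimodal:
            hyper = bool(rng.random() < 0.5)
            p_meth = config.p_meth_maternal if hyper else config.p_meth_paternal
        else:
            p_meth = config.p_meth_maternal if maternal else config.p_meth_paternal
        seq = list(ref.sequence)
        seq[snp_pos] = ref_a if maternal else alt_a
        meth = rng.random(len(cpgs)) < p_meth
        for c, is_meth in zip(cpgs, meth):
            if not is_meth and rng.random() >= config.conversion_failure_rate:
                seq[c] = "T"
        for i, b in enumerate(seq):
            if b == "C" and i not in cpgs:
                if rng.random() >= config.conversion_failure_rate:
                    seq[i] = "T"
        if config.seq_error_rate > 0:
            errs = np.nonzero(rng.random(len(seq)) < config.seq_error_rate)[0]
            for i in errs:
                seq[i] = _OTHER[seq[i]][rng.integers(3)]
        read_id = f"simread_{r:05d}/1"
        reads.append(AmpliconRead(read_id, "".join(seq), is_read1=True))
        rows.append({
            "read_id": read_id,
            "allele": "maternal" if maternal else "paternal",
            "meth_states": "".join("1" if m else "0" for m in meth),
        })
    truth = AmpliconTruth(pd.DataFrame(rows, columns=["read_id", "allele", "meth_states"]),
                          cpgs, config)
    return reads, ref, truth


# ---------------------------------------------------------------------------
# Trios


@dataclass
class TrioResult:
    mother: tuple
    father: tuple
    offspring: tuple
    origin: dict | None       # allele -> maternal/paternal (None: uninformative)
    informative: bool


def simulate_trio(snp_alleles, seed: int, informative: bool = True,
                  maternal_allele: str | None = None) -> TrioResult:
    """Simulate a mother/father/offspring genotype triple at one SNP.

    Informative trios have opposite-homozygous parents; which parent
    carries which allele is randomized unless ``maternal_allele`` pins it
    (used when the trio must be consistent with a jointly simulated
    amplicon, whose maternal reads carry the reference allele).
    Uninformative trios have two heterozygous parents.  The true origin
    map is returned alongside.
    """
    a, b = snp_alleles
    if a == b:
        raise ConfigError("snp_alleles must be distinct")
    if maternal_allele is not None and maternal_allele not in (a, b):
        raise ConfigError(f"maternal_allele {maternal_allele!r} not one of the SNP alleles")
    rng = np.random.default_rng(seed)
    if informative:
        first = maternal_allele == a if maternal_allele is not None else rng.random() < 0.5
        if first:
            mother, father = (a, a), (b, b)
            origin = {a: "maternal", b: "paternal"}
        else:
            mother, father = (b, b), (a, a)
            origin = {b: "maternal", a: "paternal"}
        offspring = (a, b)
        return TrioResult(mother, father, offspring, origin, True)
    return TrioResult((a, b), (a, b), (a, b), None, False)


# ---------------------------------------------------------------------------
# File output (plain-text formats)


def write_annotation(bundle: AnnotationBundle, outdir) -> dict:
    """Write the bundle as BED / BED12 / TSV / JSON; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "regions": os.path.join(outdir, "regions.bed"),
        "repeats": os.path.join(outdir, "repeats.bed"),
        "transcripts": os.path.join(outdir, "transcripts.bed12"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "config": os.path.join(outdir, "config.json"),
    }
    with open(paths["regions"], "w") as fh:
        for r in bundle.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.gene_strand or '.'}\n")
    with open(paths["repeats"], "w") as fh:
        for rep in bundle.repeats:
            fh.write(f"{rep.chrom}\t{rep.start}\t{rep.end}\t{rep.family}\t0\t{rep.strand}\n")
    with open(paths["transcripts"], "w") as fh:
        for t in bundle.transcripts:
            s, e = t.span
            sizes = ",".join(str(b - a) for a, b in t.exons) + ","
            starts = ",".join(str(a - s) for a, _ in t.exons) + ","
            fh.write(f"{t.chrom}\t{s}\t{e}\t{t.name}\t0\t{t.strand}\t{s}\t{e}\t0\t"
                     f"{len(t.exons)}\t{sizes}\t{starts}\n")
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg = asdict(bundle.config)
    cfg["beta_concentration"] = (
        "inf" if math.isinf(cfg["beta_concentration"]) else cfg["beta_concentration"]
    )
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def write_amplicon_files(reads, ref: AmpliconRef, truth: AmpliconTruth, outdir) -> dict:
    """Write reference FASTA, reads FASTQ and the per-read truth TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reference": os.path.join(outdir, "amplicon.fasta"),
        "reads": os.path.join(outdir, "reads.fastq"),
        "truth": os.path.join(outdir, "read_truth.tsv"),
    }
    with open(paths["reference"], "w") as fh:
        snp = ref.snp
        fh.write(f">{ref.name} snp_pos_1based={snp[0] + 1} alleles={snp[1]}/{snp[2]}\n")
        for i in range(0, len(ref.sequence), 60):
            fh.write(ref.sequence[i:i + 60] + "\n")
    with open(paths["reads"], "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")
    truth.per_read.to_csv(paths["truth"], sep="\t", index=False)
    return paths
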