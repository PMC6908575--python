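"""End-to-end composition of the two analyses.

``run_igdmr_lit_screen`` chains the igDMR screen, conservation
classification, LIT calling, region-LIT association and the enrichment
test.  ``run_amplicon_imprinting`` chains read selection, bisulfite
alignment, per-read and per-CpG calling, conversion QC, bimodality,
allele assignment, the allelic test, parental origin and the final
imprinting call.  Both are deterministic given their inputs and write
plain-text intermediates when an output directory is provided.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .allelic import (
    BimodalityThresholds,
    allelic_methylation_test,
    assign_allele,
    classify_bimodality,
    imprinting_call,
    parental_origin,
)
from .amplicon import (
    AlignScores,
    AmpliconRef,
    call_read_profile,
    conversion_qc,
    per_cpg_levels,
    select_reads,
)
from .errors import UsageError
from .lit import (
    associate_lit_with_region,
    classify_transcript_initiation,
    lit_enrichment_test,
)
from .methylome import ScreenThresholds, calls_to_frame, classify_conservation, screen_igdmrs

logger = logging.getLogger(__name__)

__all__ = ["ScreenReport", "ImprintingReport", "run_igdmr_lit_screen", "run_amplicon_imprinting"]


def _config_hash(obj) -> str:
    def default(o):
        try:
            from dataclasses import asdict, is_dataclass

            if is_dataclass(o):
                return asdict(o)
        except TypeError:
            pass
        return repr(o)

    blob = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ScreenReport:
    calls: list
    associations: list
    enrichment: object
    conservation: dict | None
    provenance: dict

    def calls_frame(self) -> pd.DataFrame:
        return calls_to_frame(self.calls)


def run_igdmr_lit_screen(
    regions,
    tracks: dict,
    transcripts,
    repeats,
    thresholds: ScreenThresholds = ScreenThresholds(),
    edge_window: int = 100,
    downstream_window: int = 2000,
    enrichment_scope: str = "embedded_or_downstream",
    calls_other_species=None,
    synteny_map=None,
    outdir=None,
) -> ScreenReport:
    """Screen candidate regions, associate LITs and test enrichment.

    The enrichment foreground is the set of screen candidates; its hits
    are candidates associated with a LIT (embedded or downstream by
    default, ``enrichment_scope="embedded_only"`` to restrict).  The
    background is the full candidate-region list (the CGI universe).
    Empty region lists yield an empty report with a warning rather than an
    error.
    """
    t0 = time.time()
    regions = list(regions)
    if not regions:
        logger.warning("empty region list: empty report")
        return ScreenReport([], [], None, None,
                            {"version": __version__, "n_regions": 0})
    calls = screen_igdmrs(regions, tracks, thresholds)
    lits = [classify_transcript_initiation(t, repeats, edge_window) for t in transcripts]
    lits = [l for l in lits if l.tss_class in ("Up", "UpEdge")]
    associations = [associate_lit_with_region(r, lits, downstream_window) for r in regions]
    assoc_by_name = {a.region.name: a for a in associations}

    def is_hit(assoc) -> bool:
        if assoc.relation == "embedded":
            return True
        return (enrichment_scope == "embedded_or_downstream"
                and assoc.relation == "downstream_within_window")

    candidates = [c for c in calls if c.candidate]
    n_fore = len(candidates)
    k_fore = sum(is_hit(assoc_by_name[c.region.name]) for c in candidates)
    n_back = len(regions)
    k_back = sum(is_hit(a) for a in associations)
    enrichment = lit_enrichment_test(k_fore, n_fore, k_back, n_back) if n_fore else None
    conservation = None
    if calls_other_species is not None and synteny_map is not None:
        conservation = classify_conservation(calls, calls_other_species, synteny_map)
    provenance = {
        "version": __version__,
        "config_hash": _config_hash({
            "thresholds": thresholds, "edge_window": edge_window,
            "downstream_window": downstream_window, "enrichment_scope": enrichment_scope,
        }),
        "n_regions": len(regions),
        "n_candidates": n_fore,
        "elapsed_s": round(time.time() - t0, 3),
    }
    report = ScreenReport(calls, associations, enrichment, conservation, provenance)
    if outdir is not None:
        _write_screen_report(report, outdir)
    return report


def _write_screen_report(report: ScreenReport, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    report.calls_frame().to_csv(os.path.join(outdir, "igdmr_calls.tsv"), sep="\t", index=False)
    rows = [{
        "region": a.region.name,
        "lit": a.lit.transcript.name if a.lit else "",
        "tss_class": a.lit.tss_class if a.lit else "",
        "relation": a.relation,
        "configuration": a.configuration,
    } for a in report.associations]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "lit_associations.tsv"),
                              sep="\t", index=False)
    payload = {"provenance": report.provenance}
    if report.enrichment is not None:
        e = report.enrichment
        payload["enrichment"] = {
            "k_fore": e.k_fore, "n_fore": e.n_fore,
            "k_back": e.k_back, "n_back": e.n_back,
            "chi2": e.chi2, "p": e.p, "method": e.method,
        }
    if report.conservation is not None:
        payload["conservation"] = report.conservation
    with open(os.path.join(outdir, "screen_report.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class ImprintingReport:
    ref_name: str
    final_call: str
    bimodality: object
    allelic: object
    origin: dict | None
    per_cpg: pd.DataFrame | None
    qc: object | None
    n_reads_used: int
    profiles: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def run_amplicon_imprinting(
    ref: AmpliconRef,
    reads,
    trio=None,
    strand: str = "top",
    max_reads: int = 400,
    max_mismatches: int = 10,
    min_conversion: float = 0.9,
    bimodality: BimodalityThresholds = BimodalityThresholds(),
    alpha: float = 0.05,
    min_concordance: float = 0.9,
    min_reads_per_allele: int = 5,
    scores: AlignScores = AlignScores(),
) -> ImprintingReport:
    """Run the targeted-bisulfite imprinting analysis for one amplicon.

    ``trio`` is an optional object with ``mother``, ``father`` and
    ``offspring`` genotype attributes (e.g. a simulated trio); without it
    -- or without a SNP on the reference -- the call can reach at most
    ``bimodal_only``.  Zero reads yield an ``undetermined`` report.
    """
    reads = list(reads)
    selected = select_reads(reads, refs=[ref], max_reads=max_reads,
                            max_mismatches=max_mismatches, strand=strand, scores=scores)
    kept = [s for s in selected if s.kept]
    profiles = [call_read_profile(s.alignment, ref) for s in kept]
    qc, profiles = conversion_qc(profiles, min_conversion=min_conversion)
    aln_by_id = {s.alignment.read_id: s.alignment for s in kept}
    if ref.snp is not None:
        for p in profiles:
            allele = assign_allele(aln_by_id[p.read_id], ref)
            p.allele = allele if allele in ("ref", "alt") else None
    table = per_cpg_levels(profiles) if profiles else None
    verdict = classify_bimodality(profiles, bimodality)
    allelic = None
    if ref.snp is not None and verdict.verdict == "bimodal":
        allelic = allelic_methylation_test(profiles, bimodality, alpha,
                                           min_concordance, min_reads_per_allele)
    origin = None
    if trio is not None and ref.snp is not None:
        origin = parental_origin(trio.offspring, trio.mother, trio.father)
    snp_alleles = (ref.snp[1], ref.snp[2]) if ref.snp is not None else None
    call = imprinting_call(verdict, allelic, origin, snp_alleles)
    provenance = {
        "version": __version__,
        "config_hash": _config_hash({
            "max_reads": max_reads, "max_mismatches": max_mismatches,
            "min_conversion": min_conversion, "alpha": alpha,
            "min_concordance": min_concordance,
        }),
        "n_input_reads": len(reads),
    }
    return ImprintingReport(ref.name, call.final, verdict, allelic, origin,
                            table, qc, len(profiles), profiles, provenance)
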