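"""Cross-species LTR retrotransposon analysis.

Orthologous LTR insertions are scored present/absent across species; under
a single-gain (Dollo-style) assumption the family's colonization point is
the most recent common ancestor of the species carrying it.  Sequence
divergence of individual elements from their family consensus -- a proxy
for insertion age -- is computed from a global pairwise alignment, with an
element-length filter matching the published analysis of MT2A elements
(>450 bp against a 533-bp consensus).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd
from Bio import Align

from .errors import DataError, UsageError

__all__ = [
    "DivergenceParams",
    "load_tree",
    "load_presence_matrix",
    "percent_divergence",
    "filter_elements",
    "colonization_node",
    "node_label",
    "conservation_report",
]

PRESENCE_STATES = ("present", "absent", "no_data")


@dataclass(frozen=True)
class DivergenceParams:
    """Alignment scores and filters for element-vs-consensus divergence.

    The stiff gap-opening penalty keeps clusters of substitutions from
    being absorbed into spurious indel pairs, which would bias divergence
    low; real structural indels are still recovered.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5
    min_element_length: int = 450
    gap_policy: str = "events"   # 'events' or 'ignore_gaps'

    def __post_init__(self):
        if self.min_element_length <= 0:
            raise UsageError("min_element_length must be positive")
        if self.gap_policy not in ("events", "ignore_gaps"):
            raise UsageError(f"unknown gap policy {self.gap_policy!r}")


def load_tree(source: str) -> dendropy.Tree:
    """Load a rooted species tree from a newick string or file path."""
    import os

    kwargs = dict(schema="newick", preserve_underscores=True)
    if os.path.exists(source):
        tree = dendropy.Tree.get(path=source, **kwargs)
    else:
        tree = dendropy.Tree.get(data=source, **kwargs)
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise DataError("species tree has duplicate leaf names")
    return tree


def load_presence_matrix(path) -> pd.DataFrame:
    """Read a locus x species presence/absence TSV.

    First column = locus id; cells must be ``present``/``absent``/``no_data``
    (``1``/``0``/``NA`` accepted as aliases).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    alias = {"1": "present", "0": "absent", "NA": "no_data", "": "no_data"}
    df = df.fillna("no_data").map(lambda v: alias.get(str(v).strip(), str(v).strip()))
    bad = set(df.values.ravel()) - set(PRESENCE_STATES)
    if bad:
        raise DataError(f"invalid presence states: {sorted(bad)}")
    return df


def _aligner(params: DivergenceParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def percent_divergence(
    element: str,
    consensus: str,
    params: DivergenceParams = DivergenceParams(),
) -> float:
    """Percent divergence of an element from its family consensus.

    A global alignment is computed with the configured scores; divergence
    is ``100 * (mismatches + indel_events) / (ungapped_columns +
    indel_events)`` under the default policy, where each contiguous indel
    counts as a single event regardless of length (so columns inside a gap
    do not inflate the denominator).  ``gap_policy='ignore_gaps'`` drops
    indels from both numerator and denominator.
    """
    if not element or not consensus:
        raise UsageError("percent_divergence requires two non-empty sequences")
    element, consensus = element.upper(), consensus.upper()
    aln = _aligner(params).align(element, consensus)[0]
    blocks_e, blocks_c = aln.aligned
    matches = mismatches = 0
    for (es, ee), (cs, ce) in zip(blocks_e, blocks_c):
        for a, b in zip(element[es:ee], consensus[cs:ce]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
    # indel events: jumps between consecutive aligned blocks plus terminal gaps
    events = 0
    prev_e = prev_c = 0
    for (es, ee), (cs, ce) in zip(blocks_e, blocks_c):
        if es > prev_e:
            events += 1
        if cs > prev_c:
            events += 1
        prev_e, prev_c = ee, ce
    if prev_e < len(element):
        events += 1
    if prev_c < len(consensus):
        events += 1
    if params.gap_policy == "events":
        denom = matches + mismatches + events
        num = mismatches + events
    else:
        denom = matches + mismatches
        num = mismatches
    return 100.0 * num / denom if denom else 0.0


def filter_elements(elements, params: DivergenceParams = DivergenceParams()) -> list:
    """Keep elements strictly longer than ``min_element_length`` bp."""
    return [e for e in elements if e.length > params.min_element_length]


def colonization_node(tree: dendropy.Tree, present_species) -> dendropy.Node:
    """Impute the integration point of an LTR family on the species tree.

    Under a single-gain assumption the family entered the genome in the
    most recent common ancestor of all species in which it is present;
    species without data are simply ignored.  A single present species
    maps to its own leaf.
    """
    present = sorted(set(present_species))
    if not present:
        raise UsageError("presence set is empty")
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = set(present) - leaves
    if unknown:
        raise UsageError(f"species not in tree: {sorted(unknown)}")
    if len(present) == 1:
        return tree.find_node_with_taxon_label(present[0])
    return tree.mrca(taxon_labels=present)


def node_label(node: dendropy.Node) -> str:
    """Readable label for a tree node: its own label/taxon when present,
    else the sorted set of leaves it subtends."""
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return "mrca(" + ",".join(leaves) + ")"


def conservation_report(
    presence: pd.DataFrame,
    tree: dendropy.Tree,
    meth_status: pd.DataFrame | None = None,
    activity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Relate LTR presence, transcriptional activity and methylation status.

    ``presence`` is a locus x species frame of presence states; the
    optional ``meth_status`` and ``activity`` frames share its shape.  The
    result has one row per locus x species plus per-locus ``lineage``
    (colonization-node label) and a caveat flag set when the presence
    pattern is phylogenetically discontiguous (some species under the
    imputed node are scored absent), which would require independent gains
    or losses under the single-gain model.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = set(presence.columns) - leaves
    if unknown:
        raise DataError(f"presence matrix columns not in tree: {sorted(unknown)}")
    rows = []
    for locus in presence.index:
        states = presence.loc[locus]
        present = [sp for sp in presence.columns if states[sp] == "present"]
        if present:
            node = colonization_node(tree, present)
            lineage = node_label(node)
            under = {l.taxon.label for l in node.leaf_iter()} & set(presence.columns)
            absent_under = [sp for sp in under if states[sp] == "absent"]
            caveat = "discontiguous_presence" if absent_under else ""
        else:
            lineage, caveat = "none", ""
        for sp in presence.columns:
            row = {
                "locus": locus,
                "species": sp,
                "presence": states[sp],
                "lineage": lineage,
                "caveat": caveat,
            }
            if activity is not None:
                row["activity"] = activity.loc[locus, sp] if sp in activity.columns else "no_data"
            if meth_status is not None:
                row["meth_status"] = (
                    meth_status.loc[locus, sp] if sp in meth_status.columns else "no_data"
                )
            rows.append(row)
    return pd.DataFrame(rows)
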