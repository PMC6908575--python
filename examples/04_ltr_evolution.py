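"""LTR family evolution: colonization nodes and consensus divergence.

Imputes when LTR families entered the genome from their presence/absence
across a primate/rodent species tree, and measures how far individual
elements have diverged from a family consensus.
"""

import numpy as np
import pandas as pd

from imprintscan import (
    DivergenceParams,
    RepeatElement,
    colonization_node,
    conservation_report,
    filter_elements,
    load_tree,
    percent_divergence,
)
from imprintscan.evolution import node_label

tree = load_tree("(((human,chimp),macaque),(mouse,rat));")

presence = pd.DataFrame(
    {"human": ["present", "present", "absent"],
     "chimp": ["present", "present", "absent"],
     "macaque": ["absent", "present", "absent"],
     "mouse": ["absent", "absent", "present"],
     "rat": ["absent", "absent", "present"]},
    index=["LTR12C_at_ST8SIA1", "MSTA_at_RHOBTB3", "MT2A_at_Slc38a4"],
)
for locus in presence.index:
    present = [s for s in presence.columns if presence.loc[locus, s] == "present"]
    print(f"{locus:>20}: colonized at {node_label(colonization_node(tree, present))}")

report = conservation_report(presence, tree)
print(f"\nreport rows: {len(report)} (locus x species)")

# Divergence of simulated family members from a consensus; older copies
# accumulate more substitutions.
rng = np.random.default_rng(0)
consensus = "".join(rng.choice(list("ACGT"), size=533))   # MT2A-like length
for rate in (0.02, 0.08, 0.15):
    element = list(consensus)
    for i in rng.choice(533, size=int(rate * 533), replace=False):
        element[i] = rng.choice([b for b in "ACGT" if b != element[i]])
    d = percent_divergence("".join(element), consensus)
    print(f"simulated substitution rate {rate:.2f} -> divergence {d:.1f}%")

elements = [RepeatElement("chr1", 0, L, family="MT2A") for L in (300, 450, 451, 533)]
kept = filter_elements(elements, DivergenceParams())
print(f"length filter >450 bp keeps {[e.length for e in kept]}")
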