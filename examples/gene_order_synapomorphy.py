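"""Gene-order comparison and clade-diagnostic adjacencies.

Gene order is a slowly-evolving genome-level character.  This example
extracts the signed circular orders of the F and M genomes, measures their
breakpoint distance, and then asks which gene adjacencies are shared by all
female-type genomes of one subfamily but absent everywhere else — the
gene-order synapomorphy idea.
"""

from mitodui.data import solenaia_fixture_pair
from mitodui.gene_order import (GeneOrder, breakpoint_distance,
                                extract_order, synapomorphic_adjacencies)
from mitodui.simulate import (GONIDEINAE_F_PCG_RRNA_ORDER,
                              UNIONOID_PCG_RRNA_ORDER)

f, m = solenaia_fixture_pair()
of, om = extract_order(f), extract_order(m)
print("F order:", of)
print("M order:", om)
print(f"breakpoint distance (PCG+rRNA scope): "
      f"{breakpoint_distance(of, om)} — the relative positions of nad2 and "
      f"nad3 are exchanged, which breaks three gene junctions.")

# four Gonideinae female-type genomes against four other unionoid F genomes
gonideinae = ["Solenaia_F", "Unio_japanensis_F", "Hyriopsis_cumingii_F",
              "Hyriopsis_schlegelii_F"]
others = ["Lampsilis_F", "Cristaria_F", "Pyganodon_F", "Quadrula_F"]
orders = ([GeneOrder(i, GONIDEINAE_F_PCG_RRNA_ORDER) for i in gonideinae] +
          [GeneOrder(i, UNIONOID_PCG_RRNA_ORDER) for i in others])
diag = synapomorphic_adjacencies(orders, gonideinae)
print("\nadjacencies found in every Gonideinae F genome and nowhere else:")
for (a, sa), (b, sb) in sorted(diag):
    print(f"  {a}({'+' if sa > 0 else '-'}) -> {b}({'+' if sb > 0 else '-'})")
print("all diagnostic junctions fall in the cox2..rrnS segment: the "
      "female-lineage arrangement of that segment marks the clade.")
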