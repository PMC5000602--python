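"""Tandem and segmental duplicate detection on a planned genome layout.

Builds a genome with one six-gene tandem array (paralogs above the 40%
similarity rule, separated by up to four intervening genes) and a
five-gene block copied in order to another chromosome, then recovers
both duplication classes.
"""

from tcskit import find_segmental, find_tandem
from tcskit.synthetic import simulate_duplication_layout

loci, proteins, truth = simulate_duplication_layout(array_sizes=[6], block_size=5, seed=19)

family = [l for l in loci if l.gene_id.startswith(("ARR", "BLK"))]
tandem = find_tandem(family, proteins, sim_min=40.0, max_intervening=4)
blocks, segmental = find_segmental(loci, truth.anchor_pairs, min_chain=3)

print(f"tandem pairs    : {sorted(p.key() for p in tandem)}")
print(f"planned         : {sorted(map(tuple, truth.tandem_pairs))}")
print(f"synteny blocks  : {len(blocks)} (anchors: {len(blocks[0].anchors)})")
print(f"segmental pairs : {sorted(p.key() for p in segmental)}")
# Tandem pairs are same-chromosome neighbours passing both the similarity
# and intervening-gene rules; segmental pairs fall inside the collinear
# anchor chain linking the duplicated block to its copy.
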