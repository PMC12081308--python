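"""Developmental-stage labelling by kNN transfer and consolidation.

Simulates a 2D reference embedding with one Gaussian cluster per
embryonic stage (E5-E7), labels neighborhood centroids by their three
nearest reference points, propagates the labels to cells through
neighborhood membership, and consolidates each cell's label multiset:
a >50% majority wins, an exact two-way 50/50 split becomes a composite
like "E6/E7", and cells in no neighborhood stay "unassigned".
"""

from collections import Counter

from trophoflux import sc
from trophoflux.synthio import SimConfig
from trophoflux.synthio.reference import gen_reference_embedding

emb = gen_reference_embedding(SimConfig(seed=1))

nhood_labels = sc.nhood_stage_knn(emb.ref_points, emb.ref_labels, emb.query_points, k=3)
nhood_acc = sum(a == b for a, b in zip(nhood_labels, emb.query_truth)) / len(nhood_labels)
print(f"neighborhood labelling accuracy vs truth: {nhood_acc:.0%}")

multisets = [[nhood_labels[i] for i in m] for m in emb.memberships]
final = sc.consolidate_labels(multisets, stage_order=("E5", "E6", "E7"))
print("final per-cell labels:", dict(Counter(final)))
cell_acc = sum(f == t for f, t in zip(final, emb.cell_truth)) / len(final)
print(f"cells with a single correct stage label: {cell_acc:.0%}")
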