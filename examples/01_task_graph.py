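"""Build the directed task graph and inspect its triplet structure.

The task embeds 10 images in a directed graph with 12 edges and two hub
nodes.  Learning trials cue an edge (predecessor, current) and ask for the
context-valid successor; distractors are sampled at controlled graph
distances from the cue.
"""

import numpy as np

from graphreplay.task_graph import (build_task_graph, enumerate_triplets,
                                    select_distractors)

g = build_task_graph()
print(f"nodes: {g.node_ids}")
print(f"hubs (in/out degree 2): {sorted(g.hubs)}")
print(f"edges ({len(g.edges)}): {g.edges}")

print("\ntriplets (predecessor -> current -> successor):")
for pred, cur, suc in enumerate_triplets(g):
    print(f"  {pred} -> {cur} -> {suc}")

rng = np.random.default_rng(0)
trip = enumerate_triplets(g)[0]
close, distal = select_distractors(g, trip, rng)
print(f"\nfor triplet {trip}: close distractor {close} "
      f"(distance {g.distance[trip[1], close]} from cue), "
      f"distal distractor {distal} (distance {g.distance[trip[1], distal]})")
print("\nDistances are directed shortest paths; the distance matrix drives "
      "both distractor placement and the reactivation-by-distance analysis.")
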