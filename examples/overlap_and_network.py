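"""Cross-organ overlap statistics and the combined interactome graph.

Builds the graph with database (solid) edges between called interactors
and dashed MS-only edges from the bait to interactors with no database
path to it, then decomposes the combined interactome into organ-unique
and shared parts.
"""

import warnings

from pulldown import SynthConfig, assign_categories, build_graph, interactomes_by_tissue, overlap_stats, score_runs, simulate_all

warnings.filterwarnings("ignore")

cfg = SynthConfig(seed=1)
universe, truth, runs, _ = simulate_all(cfg)
evidence = assign_categories(score_runs(runs), universe.edges, bait_id=cfg.bait_id)
interactomes = interactomes_by_tissue(evidence)

g = build_graph(interactomes, universe.edges, bait_id=cfg.bait_id)
styles = {}
for _, _, d in g.edges(data=True):
    styles[d["style"]] = styles.get(d["style"], 0) + 1
print(f"combined graph: {g.number_of_nodes()} nodes; edges by style: {styles}")

s = overlap_stats(interactomes)
for organ in cfg.organs:
    print(
        f"{organ}: {s.sizes[organ]} interactors, "
        f"{s.unique_counts[organ]} unique ({100 * s.unique_fractions[organ]:.1f}%)"
    )
print(f"combined: {s.combined_size} proteins, {s.multi_organ_count} found in >= 2 organs")
print(f"shared(testis -> thymus): {100 * s.pairwise_shared_fractions[('testis', 'thymus')]:.1f}%")
# Conservation holds exactly: organ-unique counts plus the multi-organ
# count add up to the combined interactome size.
assert sum(s.unique_counts.values()) + s.multi_organ_count == s.combined_size
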