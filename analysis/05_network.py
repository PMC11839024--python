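#!/usr/bin/env python
"""Integrate XL and BN evidence into the endosome-centered network.

Builds the merged graph on a denser synthetic world, applies the
endosome-centering and nuclear filters, extracts the core component,
computes stats (mean shortest path, power-law R²), detects
edge-betweenness communities, runs 100 degree-preserving rewiring
permutations for complex-coherence enrichment, and enumerates 3-cliques
with cross-link support. Writes results under results/network/.
"""

import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd

from endonet import network, synthetic

SEED = 1
OUT = Path("results/network")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    world = synthetic.make_world(seed=SEED, n_proteins=1000, n_complexes=30)
    rng = np.random.default_rng(SEED)

    # XL edges: within-complex pairs (planted contacts), a sparse backbone
    xl_pairs, bn_pairs = [], []
    for cx in world.complexes:
        combos = list(itertools.combinations(cx.members, 2))
        for a, b in combos:
            (xl_pairs if rng.random() < 0.6 else bn_pairs).append((a, b))
    # bridge complexes so a core component forms
    for c1, c2 in zip(world.complexes[:-1], world.complexes[1:]):
        xl_pairs.append((c1.members[0], c2.members[0]))

    xl = pd.DataFrame(xl_pairs, columns=["accession_a", "accession_b"])
    xl["xl_count"] = rng.integers(1, 5, len(xl))
    bn = pd.DataFrame(bn_pairs, columns=["accession_a", "accession_b"])
    bn["bn_replicates_passing"] = 2

    g = network.build_network(xl, bn)
    nuclear = {p for p, c in world.labels.items() if c == "nucleus"}
    g_endo = network.endosome_center_filter(g, world.endosomal, nuclear)
    core = network.core_component(g_endo)
    stats = network.network_stats(g_endo)

    communities = network.detect_communities(core)
    nulls = network.rewire_null(core, n_permutations=100, seed=SEED,
                                swaps_per_edge=2)
    coherence = network.complex_coherence(
        core, {c.complex_id: c.members for c in world.complexes}, nulls
    )
    cliques = network.enumerate_3cliques(g_endo)
    comp_conn = network.compartment_connectivity(
        g_endo, {p: [c] for p, c in world.labels.items()}
    )

    pd.DataFrame(cliques, columns=["a", "b", "c"]).to_csv(
        OUT / "cliques.tsv", sep="\t", index=False
    )
    partition = pd.DataFrame(
        [(i, n) for i, part in enumerate(communities) for n in sorted(part)],
        columns=["community", "accession"],
    )
    partition.to_csv(OUT / "communities.tsv", sep="\t", index=False)
    summary = {
        "stats": {k: v for k, v in stats.items() if k != "degree_histogram"},
        "core_nodes": core.number_of_nodes(),
        "core_edges": core.number_of_edges(),
        "n_communities": len(communities),
        "n_3cliques": len(cliques),
        "coherence": {
            "mean_within": coherence["mean_within"],
            "mean_between": coherence["mean_between"],
            "neighbor_fraction": coherence["neighbor_fraction_observed"],
            "empirical_p": coherence.get("empirical_p"),
        },
        "compartment_connectivity": comp_conn,
    }
    with open(OUT / "network_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"network {stats['n_nodes']} nodes / {stats['n_edges']} edges; "
          f"core {core.number_of_nodes()}/{core.number_of_edges()}; "
          f"{len(communities)} communities; {len(cliques)} 3-cliques; "
          f"within-complex mean distance "
          f"{coherence['mean_within']:.2f} vs between "
          f"{coherence['mean_between']:.2f} (p={coherence['empirical_p']:.3f})")


if __name__ == "__main__":
    main()
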