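"""Integrated interaction network: construction, filtering, statistics,
communities, rewiring nulls, complex coherence, and triangle enumeration.

Cross-link (XL) and co-fractionation (BN) protein-pair evidence are merged
into an undirected simple graph. The organelle-centered view keeps the
reference endosomal proteins, their direct interactors, and second-order
interactors connected to at least one direct interactor by cross-link or
two direct interactors by BN; exclusively nuclear nodes are removed as
dubious connectivity. Degree-preserving rewiring (double edge swaps)
provides the null for complex-coherence enrichment.
"""

from __future__ import annotations

import itertools
import random
import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from endonet.rng import substream

DEFAULT_BLOCKLIST = frozenset({"EEA1", "UBC"})
N_PERMUTATIONS = 100

COMPARTMENT_PRECEDENCE = ("endosome", "lysosome", "golgi", "mito", "nucleus",
                          "other")


def build_network(
    xl_edges: pd.DataFrame | None,
    bn_edges: pd.DataFrame | None,
    blocklist: Iterable[str] = DEFAULT_BLOCKLIST,
    node_attrs: pd.DataFrame | None = None,
) -> nx.Graph:
    """Merge XL and BN evidence into one undirected simple graph.

    ``xl_edges`` carries accession_a/accession_b/xl_count; ``bn_edges``
    carries accession_a/accession_b/bn_replicates_passing (optionally
    secat_p, previously_reported). Parallel evidence merges onto a single
    edge holding both fields. Blocklisted nodes (BN marker proteins, the
    purification handle, ubiquitin, keratins by default) are removed with
    their edges.
    """
    g = nx.Graph()
    if xl_edges is not None:
        for rec in xl_edges.itertuples(index=False):
            if rec.accession_a == rec.accession_b:
                continue
            g.add_edge(rec.accession_a, rec.accession_b,
                       xl_count=int(getattr(rec, "xl_count", 1)),
                       bn_replicates_passing=0)
    if bn_edges is not None:
        for rec in bn_edges.itertuples(index=False):
            if rec.accession_a == rec.accession_b:
                continue
            a, b = rec.accession_a, rec.accession_b
            nrep = int(getattr(rec, "bn_replicates_passing", 1))
            if g.has_edge(a, b):
                g[a][b]["bn_replicates_passing"] = max(
                    g[a][b].get("bn_replicates_passing", 0), nrep
                )
            else:
                g.add_edge(a, b, xl_count=0, bn_replicates_passing=nrep)
            for opt in ("secat_p", "previously_reported"):
                if hasattr(rec, opt):
                    g[a][b][opt] = getattr(rec, opt)
    block = set(blocklist or ())
    g.remove_nodes_from([n for n in list(g) if n in block
                         or str(n).startswith("KRT")])
    if node_attrs is not None:
        for acc, row in node_attrs.iterrows():
            if acc in g:
                g.nodes[acc].update(row.to_dict())
    return g


def endosome_center_filter(
    graph: nx.Graph,
    endosomal: Iterable[str],
    nuclear: Iterable[str] = (),
    bn_rule: str = "two-edges",
) -> nx.Graph:
    """Center the network on the reference organelle proteome.

    Retains the endosomal proteins, their direct interactors, and
    second-order interactors connected to ≥ 1 direct interactor by a
    cross-link-supported edge and/or ≥ 2 direct interactors by BN-only
    edges (``bn_rule='two-edges'``; the single-edge two-replicate reading
    is available as ``bn_rule='two-replicates'``). Exclusively nuclear
    nodes are removed first, then edges are induced.
    """
    endo = set(endosomal)
    if not endo:
        raise ValueError("endosomal set must be non-empty")
    g = graph.copy()
    g.remove_nodes_from([n for n in list(g) if n in set(nuclear) and n not in endo])
    direct = {n for e in endo & set(g) for n in g.neighbors(e)} - endo
    keep = (endo & set(g)) | direct
    for n in set(g) - keep:
        xl_hits = 0
        bn_hits = 0
        bn_reps_best = 0
        for nbr in g.neighbors(n):
            if nbr not in direct:
                continue
            data = g[n][nbr]
            if data.get("xl_count", 0) >= 1:
                xl_hits += 1
            elif data.get("bn_replicates_passing", 0) >= 1:
                bn_hits += 1
                bn_reps_best = max(bn_reps_best, data["bn_replicates_passing"])
        if xl_hits >= 1:
            keep.add(n)
        elif bn_rule == "two-edges" and bn_hits >= 2:
            keep.add(n)
        elif bn_rule == "two-replicates" and bn_reps_best >= 2:
            keep.add(n)
    return g.subgraph(keep).copy()


def core_component(graph: nx.Graph) -> nx.Graph:
    """Largest connected component; ties broken by edge count, then by the
    lexicographically smallest member — deterministic."""
    if graph.number_of_nodes() == 0:
        return graph.copy()
    comps = [graph.subgraph(c) for c in nx.connected_components(graph)]
    best = max(
        comps,
        key=lambda c: (c.number_of_nodes(), c.number_of_edges(),
                       [-ord(ch) for ch in min(map(str, c.nodes))]),
    )
    return best.copy()


def powerlaw_r2(graph: nx.Graph, mle: bool = False) -> float:
    """R² of the least-squares line on log degree vs log frequency.

    Degrees ≥ 1 only; zero-frequency bins dropped. With ``mle=True`` the
    continuous-approximation maximum-likelihood exponent is fitted instead
    and R² of the implied line is returned.
    """
    degrees = np.array([d for _, d in graph.degree() if d >= 1])
    if degrees.size == 0:
        return float("nan")
    vals, counts = np.unique(degrees, return_counts=True)
    if len(vals) < 3:
        return float("nan")
    x = np.log10(vals.astype(float))
    y = np.log10(counts / counts.sum())
    if mle:
        kmin = vals.min()
        alpha = 1.0 + degrees.size / np.sum(np.log(degrees / (kmin - 0.5)))
        slope = -alpha
        intercept = y.mean() - slope * x.mean()
    else:
        slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def mean_shortest_path(graph: nx.Graph) -> float:
    """Mean BFS shortest-path length over connected node pairs only."""
    total = 0
    count = 0
    for source, dists in nx.all_pairs_shortest_path_length(graph):
        for target, d in dists.items():
            if target != source:
                total += d
                count += 1
    return total / count if count else float("nan")


def network_stats(graph: nx.Graph) -> dict:
    """Headline statistics of the graph (see NetworkStats fields)."""
    if graph.number_of_nodes() < 2:
        return {"n_nodes": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(), "degenerate": True}
    degrees = [d for _, d in graph.degree()]
    vals, counts = np.unique(degrees, return_counts=True)
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_components": nx.number_connected_components(graph),
        "mean_shortest_path": mean_shortest_path(graph),
        "powerlaw_r2": powerlaw_r2(graph),
        "degree_histogram": {int(v): int(c) for v, c in zip(vals, counts)},
        "degenerate": False,
    }


# ---------------------------------------------------------------------------
# Communities


def _most_valuable_edge(g: nx.Graph):
    """Max edge betweenness; ties resolved by lowest lexicographic edge."""
    bet = nx.edge_betweenness_centrality(g)
    top = max(bet.values())
    tied = [e for e, v in bet.items() if v >= top - 1e-12]
    return min(tied, key=lambda e: tuple(sorted(map(str, e))))


def detect_communities(graph: nx.Graph) -> list[set]:
    """Girvan–Newman edge-betweenness hierarchy cut at maximum modularity.

    Disconnected inputs are partitioned per component. The single-community
    partition is included as a candidate, so a clique stays one community.
    """
    parts: list[set] = []
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp).copy()
        if sub.number_of_edges() == 0:
            parts.append(set(comp))
            continue
        best = [set(sub.nodes)]
        best_q = nx.community.modularity(sub, best)
        for partition in nx.community.girvan_newman(
            sub, most_valuable_edge=_most_valuable_edge
        ):
            q = nx.community.modularity(sub, partition)
            if q > best_q + 1e-12:
                best_q = q
                best = [set(c) for c in partition]
        parts.extend(best)
    return parts


# ---------------------------------------------------------------------------
# Rewiring null


def rewire_null(
    graph: nx.Graph, n_permutations: int = N_PERMUTATIONS, seed: int = 0,
    swaps_per_edge: int = 10,
) -> list[nx.Graph]:
    """Degree-preserving randomized copies via double edge swaps.

    Every output conserves the input degree sequence exactly; self-loops
    and multi-edges are never created. Graphs with no valid swap (fewer
    than 2 edges, stars) are returned unchanged with a warning.
    """
    rng = substream(seed, "rewire")
    out = []
    m = graph.number_of_edges()
    for i in range(n_permutations):
        h = graph.copy()
        if m < 2:
            if i == 0:
                warnings.warn("graph admits no rewiring; returning copies")
            out.append(h)
            continue
        py_rng = random.Random(int(rng.integers(0, 2**31 - 1)))
        try:
            nx.double_edge_swap(
                h, nswap=swaps_per_edge * m, max_tries=100 * swaps_per_edge * m,
                seed=py_rng,
            )
        except (nx.NetworkXError, nx.NetworkXAlgorithmError):
            # dense or constrained graphs (stars, cliques) admit few or no
            # swaps; the partial result still conserves the degree sequence
            if i == 0:
                warnings.warn("rewiring saturated; returning partial swaps")
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# Complex coherence


def complex_coherence(
    graph: nx.Graph,
    complex_map: Mapping[str, Sequence[str]],
    null_graphs: Sequence[nx.Graph] | None = None,
) -> dict:
    """Path-distance and direct-contact coherence of annotated complexes.

    Returns shortest-path distance distributions for within-complex vs
    between-complex pairs (over annotated nodes present in the graph), the
    per-protein fraction of direct neighbors sharing a complex, and — when
    rewired nulls are supplied — an empirical enrichment p-value,
    p = (1 + #{nulls with mean fraction ≥ observed}) / (n_nulls + 1),
    bounded below by 1/(n_nulls + 1). Complexes with a single present
    member are skipped.
    """
    membership: dict[str, set[str]] = {}
    for cid, members in complex_map.items():
        present = [m for m in members if m in graph]
        if len(present) < 2:
            continue
        for m in present:
            membership.setdefault(m, set()).add(cid)
    annotated = sorted(membership)
    within, between = [], []
    for a, b in itertools.combinations(annotated, 2):
        try:
            d = nx.shortest_path_length(graph, a, b)
        except nx.NetworkXNoPath:
            continue
        if membership[a] & membership[b]:
            within.append(d)
        else:
            between.append(d)

    def mean_neighbor_fraction(g: nx.Graph) -> float:
        fracs = []
        for n in annotated:
            if n not in g:
                continue
            nbrs = list(g.neighbors(n))
            if not nbrs:
                continue
            same = sum(
                1 for x in nbrs if membership.get(x, set()) & membership[n]
            )
            fracs.append(same / len(nbrs))
        return float(np.mean(fracs)) if fracs else float("nan")

    observed = mean_neighbor_fraction(graph)
    result = {
        "within_distances": within,
        "between_distances": between,
        "mean_within": float(np.mean(within)) if within else None,
        "mean_between": float(np.mean(between)) if between else None,
        "neighbor_fraction_observed": observed,
    }
    if null_graphs:
        null_vals = [mean_neighbor_fraction(h) for h in null_graphs]
        ge = sum(1 for v in null_vals if not np.isnan(v) and v >= observed)
        result["neighbor_fraction_null"] = null_vals
        result["empirical_p"] = (1 + ge) / (len(null_graphs) + 1)
    return result


# ---------------------------------------------------------------------------
# Triangles


def enumerate_3cliques(graph: nx.Graph, require_xl: bool = True
                       ) -> list[tuple[str, str, str]]:
    """All node triples whose three edges exist, with ≥ 1 cross-link-
    supported edge when ``require_xl``; canonical sorted order, no
    duplicates."""
    nodes = sorted(graph.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    out = []
    for a in nodes:
        nbrs_a = [n for n in graph.neighbors(a) if index[n] > index[a]]
        nbrs_a.sort(key=str)
        for j, b in enumerate(nbrs_a):
            for c in nbrs_a[j + 1:]:
                if not graph.has_edge(b, c):
                    continue
                if require_xl:
                    has_xl = any(
                        graph[u][v].get("xl_count", 0) >= 1
                        for u, v in ((a, b), (a, c), (b, c))
                    )
                    if not has_xl:
                        continue
                out.append((a, b, c))
    return out


# ---------------------------------------------------------------------------
# Compartment connectivity


def _primary_compartment(comps: Iterable[str]) -> str:
    comps = set(comps)
    for c in COMPARTMENT_PRECEDENCE:
        if c in comps:
            return c
    return "other"


def compartment_connectivity(
    graph: nx.Graph, compartments: Mapping[str, Iterable[str]]
) -> dict:
    """Cross-tabulate edges incident to endosomal nodes by partner class.

    Multi-compartment nodes resolve by precedence endosome > lysosome >
    golgi > mito > nucleus > other (endosome-centric, no double counting).
    Reports the fraction of endosomal interactions whose partner is
    endosomal, lysosomal, or Golgi.
    """
    prim = {
        n: _primary_compartment(compartments.get(n, ("other",)))
        for n in graph
    }
    partner_counts: dict[str, int] = {}
    n_endo_edges = 0
    for a, b in graph.edges:
        ca, cb = prim[a], prim[b]
        if ca != "endosome" and cb != "endosome":
            continue
        n_endo_edges += 1
        partner = cb if ca == "endosome" else ca
        if ca == "endosome" and cb == "endosome":
            partner = "endosome"
        partner_counts[partner] = partner_counts.get(partner, 0) + 1
    frac = (
        sum(partner_counts.get(c, 0) for c in ("endosome", "lysosome", "golgi"))
        / n_endo_edges
        if n_endo_edges
        else None
    )
    return {
        "n_endosomal_edges": n_endo_edges,
        "partner_counts": partner_counts,
        "fraction_endo_lyso_golgi": frac,
    }
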