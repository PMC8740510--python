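"""Benchmark utilities: recovery of planted structure by the network stage.

These functions generate a synthetic dataset at the default study
conditions, run the co-occurrence pipeline on it, and score the result
against the generator's ground truth.  They back both the test suite and
the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import network as net_mod
from .synthetic import GeneratorParams, generate_dataset, truth_edge_set

__all__ = ["network_recovery", "habitat_structure"]


def network_recovery(seed: int, params: GeneratorParams = None,
                     min_prevalence: float = 0.5,
                     min_mean_rel_abund: float = 0.0001) -> dict:
    """Edge sensitivity, false-positive rate and hub keystoneness rank.

    The combined (96-sample) network is scored against the planted truth:
    sensitivity over truth edges whose OTUs survive the node filter,
    false-positive rate over all remaining candidate pairs, and the
    competition rank (1 + number of strictly higher scores) of the planted
    hub by keystoneness.
    """
    table, design, env, truth = generate_dataset(params, seed=seed)
    filtered = net_mod.filter_network_otus(table, min_prevalence,
                                           min_mean_rel_abund)
    network = net_mod.build_network(filtered)
    kept = set(filtered.otu_ids)
    truth_edges = truth_edge_set(truth)
    truth_present = {e for e in truth_edges if all(o in kept for o in e)}
    detected = network.edge_set()
    tp = len(detected & truth_present)
    fp = len(detected - truth_edges)
    n_pairs = len(kept) * (len(kept) - 1) // 2
    topology = net_mod.keystoneness(net_mod.compute_topology(network))
    scores = {t.otu_id: t.keystoneness for t in topology}
    hub = truth.hub_ids[0] if truth.hub_ids else None
    if hub is not None and hub in scores:
        hub_rank = 1 + sum(1 for v in scores.values() if v > scores[hub])
    else:
        hub_rank = np.inf
    return {
        "sensitivity": tp / len(truth_present) if truth_present else np.nan,
        "false_positive_rate": fp / (n_pairs - len(truth_present)),
        "hub_rank": hub_rank,
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
    }


def habitat_structure(seed: int, params: GeneratorParams = None,
                      min_prevalence: float = 0.5,
                      min_mean_rel_abund: float = 0.0001) -> dict:
    """Habitat purity of the combined network and Jaccard overlaps.

    A node's habitat is the one where its observed mean relative abundance
    is larger; an edge is cross-habitat when its endpoints disagree.
    """
    table, design, env, truth = generate_dataset(params, seed=seed)
    habitats = design.frame["habitat"].to_numpy()
    x = table.relative_abundance()
    mean_by_hab = {h: x[habitats == h].mean(axis=0) for h in ("water", "sediment")}
    node_habitat = {
        otu: ("water" if mean_by_hab["water"][j] > mean_by_hab["sediment"][j]
              else "sediment")
        for j, otu in enumerate(table.otu_ids)}

    networks = {}
    for subset in ("total", "water", "sediment"):
        sub = table if subset == "total" else table.select_samples(
            [s for s, h in design.frame["habitat"].items() if h == subset])
        filtered = net_mod.filter_network_otus(sub, min_prevalence,
                                               min_mean_rel_abund)
        networks[subset] = net_mod.build_network(filtered)

    total = networks["total"]
    cross = sum(1 for e in total.edge_set()
                if len({node_habitat[o] for o in e}) == 2)
    nodes = {k: v.nodes for k, v in networks.items()}
    return {
        "cross_habitat_edge_fraction": cross / max(1, total.n_edges),
        "jaccard_water_sediment": net_mod.jaccard_index(nodes["water"],
                                                        nodes["sediment"]),
        "jaccard_water_total": net_mod.jaccard_index(nodes["water"],
                                                     nodes["total"]),
        "jaccard_sediment_total": net_mod.jaccard_index(nodes["sediment"],
                                                        nodes["total"]),
        "n_nodes": {k: v.n_nodes for k, v in networks.items()},
        "n_edges": {k: v.n_edges for k, v in networks.items()},
    }
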