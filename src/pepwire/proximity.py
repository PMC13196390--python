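"""Pathway-proximity screen: rank nodes by causal connectivity to a target set.

For every non-target node the screen counts the distinct simple directed
paths (node sequences, length 1..``max_len``) that end at the first target
member reached, records the shortest such path length, and standardizes the
shortest distances into a Z score over all nodes that reach the target set.
Candidate regulators are the druggable nodes closer than average (Z < 0),
ranked by descending path count.

Edge signs are deliberately ignored here: the screen asks for connectivity
with either direction of effect; signed reasoning lives in the mechanisms
module.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import ValidationError
from .network import CausalNetwork

PROXIMITY_COLUMNS = ("node_id", "path_count", "shortest_distance", "z_score",
                     "druggable", "selected")


def count_causal_paths(network: CausalNetwork, node: str,
                       target_set: Iterable[str], max_len: int) -> int:
    """Exact count of simple directed paths from ``node`` to the target set.

    Paths are node sequences of 1..``max_len`` edges that stop at the first
    target member reached (no pass-through counting); parallel edges do not
    multiply the count.
    """
    if node not in network:
        raise ValidationError(f"node {node!r} is not in the network")
    targets = frozenset(target_set)
    if max_len < 1:
        raise ValidationError("max_len must be >= 1")
    graph = network.graph

    def walk(current: str, remaining: int, visited: frozenset[str]) -> int:
        count = 0
        for successor in sorted(set(graph.successors(current))):
            if successor in visited:
                continue
            if successor in targets:
                count += 1
            elif remaining > 1:
                count += walk(successor, remaining - 1, visited | {successor})
        return count

    return walk(node, max_len, frozenset({node}))


def shortest_distance_to_targets(network: CausalNetwork, node: str,
                                 target_set: frozenset[str],
                                 max_len: int) -> float:
    """Minimal directed path length from ``node`` into the target set, capped
    at ``max_len``; ``inf`` when no such path exists."""
    graph = network.graph
    frontier = {node}
    seen = {node}
    for depth in range(1, max_len + 1):
        nxt = set()
        for u in frontier:
            for v in graph.successors(u):
                if v in target_set:
                    return float(depth)
                if v not in seen:
                    seen.add(v)
                    nxt.add(v)
        frontier = nxt
        if not frontier:
            break
    return math.inf


def proximity_table(network: CausalNetwork, target_set: Iterable[str],
                    cfg: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """One proximity score per non-target node.

    Z scores standardize the finite shortest distances (sample sd; all zero
    when the distances are constant).  Rows are ordered by descending path
    count, ties broken lexicographically by node id.
    """
    cfg = cfg or AnalysisConfig()
    targets = frozenset(target_set)
    if not targets:
        raise ValidationError("proximity_table needs a non-empty target set")
    for t in targets:
        if t not in network:
            raise ValidationError(f"target {t!r} is not in the network")
    max_len = cfg.proximity_max_path_len
    rows = []
    for node in network.nodes:
        if node in targets:
            continue
        count = count_causal_paths(network, node, targets, max_len)
        dist = shortest_distance_to_targets(network, node, targets, max_len)
        rows.append({"node_id": node, "path_count": count,
                     "shortest_distance": dist,
                     "druggable": network.is_druggable(node)})
    table = pd.DataFrame(rows, columns=["node_id", "path_count",
                                        "shortest_distance", "druggable"])
    finite = np.isfinite(table["shortest_distance"].to_numpy())
    z = np.zeros(len(table))
    if finite.sum() > 1:
        d = table.loc[finite, "shortest_distance"].to_numpy()
        sd = d.std(ddof=1)
        if sd > 0:
            z[finite] = (d - d.mean()) / sd
    z[~finite] = np.nan
    table["z_score"] = z
    table["selected"] = (table["z_score"] < 0) & table["druggable"]
    table = table.sort_values(["path_count", "node_id"],
                              ascending=[False, True],
                              ignore_index=True)
    return table[list(PROXIMITY_COLUMNS)]


def select_candidate_kinases(scores: pd.DataFrame,
                             druggable_set: Optional[Iterable[str]] = None) -> list[str]:
    """Druggable nodes closer than average (Z < 0), ordered by descending
    path count then node id.  ``druggable_set`` overrides the table's own
    druggability column when given."""
    table = scores.copy()
    if druggable_set is not None:
        druggable = frozenset(druggable_set)
        table["druggable"] = table["node_id"].isin(druggable)
    chosen = table[(table["z_score"] < 0) & table["druggable"]]
    chosen = chosen.sort_values(["path_count", "node_id"],
                                ascending=[False, True])
    return chosen["node_id"].tolist()
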