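"""Signed causal interaction network and its annotation tables.

The network is a directed multigraph of signaling entities with signed, typed
edges; phosphorylation edges may carry a residue-level site on their target.
Kinase family nodes (e.g., an SFK family entity) list their member kinases in
a ``family_members`` node attribute and can be expanded wherever a concrete
kinase is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError

EDGE_TYPES = ("phosphorylation", "transcriptional", "stability", "other")
FUNCTIONAL_EFFECTS = (
    "activates_protein",
    "inhibits_protein",
    "stabilizes_protein",
    "destabilizes_protein",
)
ACTIVITY_EFFECTS = ("activates_protein", "inhibits_protein")
STABILITY_EFFECTS = ("stabilizes_protein", "destabilizes_protein")


@dataclass(frozen=True)
class CausalEdge:
    """One signed causal relation: ``source`` up-/down-regulates ``target``.

    ``sign`` is +1 (activation / up-regulation) or -1 (inhibition /
    down-regulation).  For phosphorylation edges ``site`` is the (residue,
    1-based position) on the target protein.
    """

    source: str
    target: str
    sign: int
    edge_type: str = "other"
    site: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValidationError(
                f"edge {self.source}->{self.target}: sign must be +1 or -1, "
                f"got {self.sign!r}")
        if self.edge_type not in EDGE_TYPES:
            raise ValidationError(
                f"edge {self.source}->{self.target}: unknown edge type "
                f"{self.edge_type!r}")


@dataclass(frozen=True)
class SiteAnnotation:
    """Functional annotation of one phosphosite.

    ``functional_effect`` describes what phosphorylation of the site does to
    the protein (activity or stability); it may be ``None`` for pure substrate
    sites whose only role is linking a peptide to its upstream kinases.
    """

    protein_id: str
    residue: str
    position: int
    functional_effect: Optional[str]
    upstream_kinases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError("site positions are 1-based")
        if self.functional_effect is not None \
                and self.functional_effect not in FUNCTIONAL_EFFECTS:
            raise ValidationError(
                f"unknown functional effect {self.functional_effect!r}")

    @property
    def site(self) -> tuple[str, str, int]:
        return (self.protein_id, self.residue, self.position)

    @property
    def label(self) -> str:
        return f"{self.protein_id}_{self.residue}{self.position}"


class SiteIndex:
    """Lookups over a collection of site annotations."""

    def __init__(self, sites: Iterable[SiteAnnotation]) -> None:
        self.by_site: dict[tuple[str, str, int], SiteAnnotation] = {}
        self.by_protein: dict[str, list[SiteAnnotation]] = {}
        for ann in sites:
            if ann.site in self.by_site:
                raise ValidationError(f"duplicate site annotation {ann.site}")
            self.by_site[ann.site] = ann
            self.by_protein.setdefault(ann.protein_id, []).append(ann)

    def get(self, site: tuple[str, str, int]) -> Optional[SiteAnnotation]:
        return self.by_site.get(site)

    def stability_sites(self, protein_id: str) -> list[SiteAnnotation]:
        return [s for s in self.by_protein.get(protein_id, [])
                if s.functional_effect in STABILITY_EFFECTS]

    def activity_sites(self, protein_id: str) -> list[SiteAnnotation]:
        return [s for s in self.by_protein.get(protein_id, [])
                if s.functional_effect in ACTIVITY_EFFECTS]


class CausalNetwork:
    """Signed, typed, directed multigraph of signaling entities.

    Node attributes: ``is_kinase``, ``is_tf``, ``is_druggable`` (booleans) and
    ``family_members`` (tuple of member node ids, empty for plain nodes).
    """

    def __init__(self, graph: Optional[nx.MultiDiGraph] = None) -> None:
        self.graph = graph if graph is not None else nx.MultiDiGraph()

    @classmethod
    def from_parts(cls, nodes: Mapping[str, Mapping], edges: Iterable[CausalEdge],
                   validate: bool = True) -> "CausalNetwork":
        net = cls()
        for node_id, attrs in nodes.items():
            net.add_node(node_id, **attrs)
        for edge in edges:
            net.add_edge(edge, validate_endpoints=False)
        if validate:
            net.validate()
        return net

    def add_node(self, node_id: str, *, is_kinase: bool = False, is_tf: bool = False,
                 is_druggable: bool = False,
                 family_members: Sequence[str] = ()) -> None:
        self.graph.add_node(node_id, is_kinase=bool(is_kinase), is_tf=bool(is_tf),
                            is_druggable=bool(is_druggable),
                            family_members=tuple(family_members))

    def add_edge(self, edge: CausalEdge, validate_endpoints: bool = True) -> None:
        if validate_endpoints:
            for endpoint in (edge.source, edge.target):
                if endpoint not in self.graph:
                    raise ValidationError(
                        f"edge {edge.source}->{edge.target}: endpoint "
                        f"{endpoint!r} is not a network node")
        self.graph.add_edge(edge.source, edge.target, sign=edge.sign,
                            edge_type=edge.edge_type, site=edge.site)

    # -- accessors ---------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph

    def edges(self) -> list[CausalEdge]:
        return [CausalEdge(u, v, d["sign"], d["edge_type"], d.get("site"))
                for u, v, d in self.graph.edges(data=True)]

    def node_attr(self, node_id: str, attr: str):
        if node_id not in self.graph:
            raise ValidationError(f"unknown node {node_id!r}")
        return self.graph.nodes[node_id].get(attr)

    def is_kinase(self, node_id: str) -> bool:
        return bool(self.node_attr(node_id, "is_kinase"))

    def is_tf(self, node_id: str) -> bool:
        return bool(self.node_attr(node_id, "is_tf"))

    def is_druggable(self, node_id: str) -> bool:
        return bool(self.node_attr(node_id, "is_druggable"))

    def family_members(self, node_id: str) -> tuple[str, ...]:
        return tuple(self.node_attr(node_id, "family_members") or ())

    def tf_nodes(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.is_tf(n))

    def druggable_nodes(self) -> frozenset[str]:
        return frozenset(n for n in self.graph.nodes if self.is_druggable(n))

    def expand_members(self, node_id: str) -> frozenset[str]:
        """A node together with its family members (member expansion)."""
        return frozenset((node_id, *self.family_members(node_id)))

    def edge_signs(self, source: str, target: str) -> frozenset[int]:
        """Signs of all parallel edges between a node pair."""
        data = self.graph.get_edge_data(source, target) or {}
        return frozenset(d["sign"] for d in data.values())

    def phospho_edge_signs(self, source: str, target: str,
                           site: Optional[tuple[str, int]] = None) -> frozenset[int]:
        """Signs of phosphorylation edges source->target, optionally matching
        a (residue, position) site."""
        data = self.graph.get_edge_data(source, target) or {}
        signs = set()
        for d in data.values():
            if d["edge_type"] != "phosphorylation":
                continue
            if site is not None and d.get("site") is not None and tuple(d["site"]) != tuple(site):
                continue
            signs.add(d["sign"])
        return frozenset(signs)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if d["sign"] not in (1, -1):
                raise ValidationError(f"edge {u}->{v}: sign must be +1/-1")
            if d["edge_type"] == "transcriptional" and not self.is_tf(u):
                raise ValidationError(
                    f"transcriptional edge {u}->{v} does not originate from a TF node")
            if d["edge_type"] == "phosphorylation" and not self.is_kinase(u):
                raise ValidationError(
                    f"phosphorylation edge {u}->{v} does not originate from a kinase node")
        for node in self.graph.nodes:
            for member in self.family_members(node):
                if member not in self.graph:
                    raise ValidationError(
                        f"family member {member!r} of {node!r} is not a network node")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalNetwork):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        for n in self.graph.nodes:
            if dict(self.graph.nodes[n]) != dict(other.graph.nodes[n]):
                return False
        return sorted(map(repr, self.edges())) == sorted(map(repr, other.edges()))


#: treatment label -> set of inhibited kinase node ids
InhibitorMap = dict[str, frozenset[str]]


def validate_inhibitor_map(inhibitor_map: Mapping[str, frozenset[str]],
                           network: CausalNetwork,
                           treatments: Sequence[str]) -> None:
    for treatment in treatments:
        if treatment not in inhibitor_map:
            raise ValidationError(
                f"inhibitor map does not cover treatment {treatment!r}")
    for treatment, kinases in inhibitor_map.items():
        if not kinases:
            raise ValidationError(f"treatment {treatment!r} inhibits no kinase")
        for kinase in kinases:
            if kinase not in network:
                raise ValidationError(
                    f"inhibited kinase {kinase!r} ({treatment}) is not a network node")


TF_TARGET_COLUMNS = ("tf_id", "target_id", "sign")


def validate_tf_targets(table: pd.DataFrame, network: Optional[CausalNetwork] = None) -> pd.DataFrame:
    """Validate a TF->target table (columns tf_id, target_id, sign)."""
    missing = [c for c in TF_TARGET_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"TF-target table lacks columns {missing}")
    if not table.empty:
        bad = table[~table["sign"].isin([1, -1])]
        if not bad.empty:
            raise ValidationError(
                f"TF-target table has signs outside +/-1 for {bad['tf_id'].tolist()[:5]}")
        dup = table.duplicated(subset=["tf_id", "target_id"])
        if dup.any():
            pairs = table.loc[dup, ["tf_id", "target_id"]].values.tolist()
            raise ValidationError(f"duplicate TF-target pairs: {pairs[:5]}")
        if network is not None:
            non_tf = sorted(set(table["tf_id"]) - {n for n in table["tf_id"] if n in network and network.is_tf(n)})
            if non_tf:
                raise ValidationError(f"tf_id values are not TF nodes: {non_tf[:5]}")
    return table
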