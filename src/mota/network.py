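"""Differential network container.

Nodes are (omic, feature) pairs; edges are typed ``intra`` (differential
partial correlation within the centric block) or ``inter`` (differential
canonical similarity between the centric block and an ancillary block) and
carry the per-group correlation values and their difference.
"""

from __future__ import annotations

import networkx as nx

__all__ = ["DifferentialNetwork"]

_SEP = "::"


class DifferentialNetwork:
    """Typed wrapper around an undirected :class:`networkx.Graph`.

    Node keys are ``(omic, feature_id)`` tuples.  Node attributes: ``omic``,
    ``feature``, and for scored centric nodes ``p_value``, ``z`` and
    ``mota_score``.  Edge attributes: ``kind`` ("intra"/"inter"),
    ``corr_group1``, ``corr_group2``, ``delta``.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction -----------------------------------------------------
    def add_node(self, omic: str, feature: str, **attrs) -> None:
        self.graph.add_node((omic, feature), omic=omic, feature=feature, **attrs)

    def add_edge(
        self,
        u: tuple[str, str],
        v: tuple[str, str],
        kind: str,
        corr_group1: float,
        corr_group2: float,
    ) -> None:
        if kind not in ("intra", "inter"):
            raise ValueError(f"edge kind must be intra or inter, got {kind!r}")
        for node in (u, v):
            if node not in self.graph:
                self.add_node(*node)
        self.graph.add_edge(
            u,
            v,
            kind=kind,
            corr_group1=float(corr_group1),
            corr_group2=float(corr_group2),
            delta=float(corr_group1) - float(corr_group2),
        )

    def set_node_attrs(self, omic: str, feature: str, **attrs) -> None:
        self.graph.nodes[(omic, feature)].update(attrs)

    # -- queries ----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors_by_block(self, omic: str, feature: str) -> dict[str, list[str]]:
        """Neighbors of a node grouped by the omic block they belong to."""
        out: dict[str, list[str]] = {}
        node = (omic, feature)
        if node not in self.graph:
            return out
        for nb_omic, nb_feature in self.graph.neighbors(node):
            out.setdefault(nb_omic, []).append(nb_feature)
        for lst in out.values():
            lst.sort()
        return out

    # -- (de)stringification for GraphML ---------------------------------
    def to_string_graph(self) -> nx.Graph:
        """Copy with string node ids ``omic::feature`` (GraphML-safe)."""
        return nx.relabel_nodes(self.graph, lambda n: f"{n[0]}{_SEP}{n[1]}", copy=True)

    @classmethod
    def from_string_graph(cls, g: nx.Graph) -> "DifferentialNetwork":
        net = cls()
        for node, attrs in g.nodes(data=True):
            omic, feature = str(node).split(_SEP, 1)
            net.graph.add_node((omic, feature), **{**attrs, "omic": omic, "feature": feature})
        for u, v, attrs in g.edges(data=True):
            uo, uf = str(u).split(_SEP, 1)
            vo, vf = str(v).split(_SEP, 1)
            net.graph.add_edge((uo, uf), (vo, vf), **attrs)
        return net
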