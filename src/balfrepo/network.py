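"""Regulatory network over DE proteins: betweenness hubs and the idealized vector.

The literature-informed regulatory graph is restricted to the
differentially expressed protein entities. Node importance is measured
by unweighted betweenness centrality

    Cb(n) = sum over s != t != n of sigma_st(n) / sigma_st

(sigma_st = number of shortest s-t paths, sigma_st(n) = those passing
through n; endpoints excluded), computed with Brandes' algorithm and
then expressed as a fraction of the maximum. *Hub* proteins are those
reaching at least 25% of the maximum (the primary rule); a secondary
gap rule that cuts at a super-linear drop in the sorted profile is
available.

The *idealized intervention vector* M assigns +1 to hubs depressed in
disease (they should be promoted), -1 to hubs elevated in disease
(they should be inhibited), and 0 elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import DOWN, UP, DifferentialTable


@dataclass
class RegulatoryGraph:
    """Simple signed regulatory graph restricted to the DE entity set.

    Parallel edges are collapsed (reference counts summed, net sign
    kept) and self-loops removed. ``skipped_edges`` lists edges whose
    endpoints were outside the DE entity set.
    """

    graph: nx.Graph
    de_directions: dict[str, str] = field(default_factory=dict)
    skipped_edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def isolated(self) -> list[str]:
        return sorted(nx.isolates(self.graph))

    @property
    def n_isolated(self) -> int:
        return len(list(nx.isolates(self.graph)))

    def connectivity_report(self) -> dict:
        comps = sorted(nx.connected_components(self.graph), key=len, reverse=True)
        largest = comps[0] if comps else set()
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "n_isolated": self.n_isolated,
            "largest_component_size": len(largest),
            "n_components_nontrivial": sum(1 for c in comps if len(c) > 1),
        }


def build_graph(
    edges: pd.DataFrame,
    de_table: DifferentialTable | dict[str, str],
    directed: bool = False,
) -> RegulatoryGraph:
    """Build the regulatory graph over the significant DE entities.

    ``edges`` needs columns source, target, sign (+1/-1), refs. Edges
    touching entities outside the DE set are skipped (and reported);
    every DE entity becomes a node even if it ends up isolated —
    isolation itself is a finding.
    """
    if isinstance(de_table, DifferentialTable):
        directions = de_table.directions()
    else:
        directions = dict(de_table)
    entity_set = set(directions)

    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(sorted(entity_set))
    skipped: list[tuple[str, str]] = []
    for row in edges.itertuples(index=False):
        u, v = str(row.source), str(row.target)
        if u not in entity_set or v not in entity_set:
            skipped.append((u, v))
            continue
        if u == v:
            continue
        sign = int(getattr(row, "sign", 1))
        refs = int(getattr(row, "refs", 1))
        if g.has_edge(u, v):
            g[u][v]["refs"] += refs
            g[u][v]["sign"] = int(np.sign(g[u][v]["sign"] + sign)) or g[u][v]["sign"]
        else:
            g.add_edge(u, v, sign=sign, refs=refs)
    if skipped:
        warnings.warn(
            f"{len(skipped)} edge(s) referencing non-DE entities skipped",
            stacklevel=2,
        )
    return RegulatoryGraph(g, de_directions=directions, skipped_edges=skipped)


@dataclass
class CentralityTable:
    """Per-node betweenness, normalized to the network maximum.

    ``table`` columns: Cb (raw), Cb_norm (Cb / max Cb; all zero when
    the graph has no intermediary at all), is_hub, desired_effect
    ('promote' for hubs down in disease, 'inhibit' for hubs up, 'none'
    otherwise).
    """

    table: pd.DataFrame
    hub_threshold: float | None = None
    hub_rule: str = "fraction_of_max"

    @property
    def hubs(self) -> list[str]:
        return sorted(self.table.index[self.table["is_hub"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("entity").to_csv(path, sep="\t")


def betweenness(rg: RegulatoryGraph | nx.Graph) -> CentralityTable:
    """Raw and max-normalized betweenness for every node (Brandes).

    Unweighted; reference counts are reporting metadata, not weights.
    Unreachable pairs contribute nothing; isolated nodes score 0.
    """
    g = rg.graph if isinstance(rg, RegulatoryGraph) else rg
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    cb = nx.betweenness_centrality(g, normalized=False)
    nodes = sorted(g.nodes)
    raw = np.array([cb[n] for n in nodes], dtype=float)
    cmax = raw.max()
    norm = raw / cmax if cmax > 0 else np.zeros_like(raw)
    table = pd.DataFrame(
        {"Cb": raw, "Cb_norm": norm, "is_hub": False, "desired_effect": "none"},
        index=nodes,
    )
    return CentralityTable(table)


def select_hubs(
    ct: CentralityTable,
    threshold: float = 0.25,
    rule: str = "fraction_of_max",
    de_directions: dict[str, str] | None = None,
) -> CentralityTable:
    """Flag hub nodes in place and annotate their desired effect.

    ``rule='fraction_of_max'`` (primary): hubs are nodes with
    Cb_norm >= threshold. ``rule='gap'`` (secondary): sort Cb_norm
    descending and cut at the deepest drop exceeding the linear
    baseline (range / (n-1)); nodes above the cut are hubs.
    """
    table = ct.table
    norm = table["Cb_norm"]
    if float(norm.max()) == 0.0:
        warnings.warn("all-zero centrality: no hubs selectable", stacklevel=2)
        table["is_hub"] = False
        return CentralityTable(table, hub_threshold=threshold, hub_rule=rule)

    if rule == "fraction_of_max":
        table["is_hub"] = norm >= threshold
    elif rule == "gap":
        v = norm.sort_values(ascending=False).to_numpy()
        ids = norm.sort_values(ascending=False).index
        n = len(v)
        if n == 1:
            cut = 1
        else:
            baseline = (v[0] - v[-1]) / (n - 1)
            drops = v[:-1] - v[1:]
            big = np.flatnonzero(drops > baseline)
            cut = int(big[np.argmax(drops[big])]) + 1 if len(big) else 1
        hubs = set(ids[:cut])
        table["is_hub"] = [i in hubs for i in table.index]
    else:
        raise ValueError(f"unknown hub rule: {rule}")

    if de_directions:
        effects = []
        for node, is_hub in zip(table.index, table["is_hub"]):
            if not is_hub:
                effects.append("none")
            else:
                d = de_directions.get(node)
                effects.append(
                    "promote" if d == DOWN else "inhibit" if d == UP else "none"
                )
        table["desired_effect"] = effects
    return CentralityTable(table, hub_threshold=threshold, hub_rule=rule)


@dataclass
class IdealizedVector:
    """Signed target profile M over all network entities.

    +1 at hubs down in disease (promote), -1 at hubs up in disease
    (inhibit), 0 elsewhere.
    """

    values: pd.Series  # int8 in {-1, 0, +1}, index = entity order

    @property
    def entities(self) -> list[str]:
        return list(self.values.index)

    @property
    def hubs(self) -> list[str]:
        return sorted(self.values.index[self.values != 0])

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            pd.Series(self.values, dtype=int).to_json(indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "IdealizedVector":
        import json

        d = json.loads(Path(path).read_text())
        return cls(pd.Series(d, dtype=np.int8))


def idealized_vector(
    hubs: list[str],
    de_directions: dict[str, str],
    entity_order: list[str],
) -> IdealizedVector:
    """Build M: promote (+1) hubs depressed in disease, inhibit (-1) elevated ones."""
    values = pd.Series(0, index=list(entity_order), dtype=np.int8)
    for h in hubs:
        if h not in values.index:
            raise ValueError(f"hub {h!r} not among network entities")
        d = de_directions.get(h)
        if d == DOWN:
            values[h] = 1
        elif d == UP:
            values[h] = -1
        else:
            raise ValueError(f"hub {h!r} has no differential direction")
    return IdealizedVector(values)
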