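"""Temporal ordering of driver events from within-patient clonality.

When two frequent somatic events co-occur in one patient with one clonal and
the other subclonal, the clonal event was acquired earlier and a directed
temporal edge is drawn from it to the subclonal one.  A patient with ``c``
clonal and ``s`` subclonal frequent events therefore contributes exactly
``c*s`` edges.  Pairs connected by at least five edges are tested for a
dominant direction (two-sided binomial sign test at p=0.5), and each event
is classified early / intermediary / late from the enrichment of its
outgoing vs incoming edges (binomial test, BH-FDR across events).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import fdr_adjust

__all__ = [
    "TemporalGraph",
    "build_graph",
    "test_pair",
    "pair_table",
    "classify_timing",
    "rank_by_ccf",
    "significant_direction_subgraph",
    "to_dot",
]

MIN_PAIR_EDGES = 5


@dataclass
class TemporalGraph:
    """Directed multigraph of clonal-to-subclonal driver pairs."""

    nodes: list[str]
    pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    n_samples: int = 0

    def n_edges(self, x: str, y: str) -> int:
        return self.pair_counts.get((x, y), 0)

    def out_degree(self, x: str) -> int:
        return sum(c for (a, _), c in self.pair_counts.items() if a == x)

    def in_degree(self, y: str) -> int:
        return sum(c for (_, b), c in self.pair_counts.items() if b == y)

    @property
    def total_edges(self) -> int:
        return sum(self.pair_counts.values())

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for (a, b), c in self.pair_counts.items():
            g.add_edge(a, b, weight=c)
        return g


def build_graph(calls: pd.DataFrame, n_samples: int | None = None) -> TemporalGraph:
    """Build the temporal graph from per-sample clonality calls.

    ``calls`` needs columns sample_id, event_id, clonality, restricted to the
    frequency-filtered events, with at most one call per (sample, event).
    """
    dup = calls.groupby(["sample_id", "event_id"]).size()
    if (dup > 1).any():
        s, e = dup[dup > 1].index[0]
        raise ValueError(f"duplicate call for sample {s}, event {e}; resolve before graph building")
    nodes = sorted(calls["event_id"].unique())
    counts: dict[tuple[str, str], int] = {}
    for _, grp in calls.groupby("sample_id"):
        clonal = grp.loc[grp["clonality"] == "clonal", "event_id"].tolist()
        subclonal = grp.loc[grp["clonality"] == "subclonal", "event_id"].tolist()
        for x in clonal:
            for y in subclonal:
                if x != y:
                    counts[(x, y)] = counts.get((x, y), 0) + 1
    n = n_samples if n_samples is not None else calls["sample_id"].nunique()
    return TemporalGraph(nodes=nodes, pair_counts=counts, n_samples=n)


def test_pair(n_xy: int, n_yx: int, min_edges: int = MIN_PAIR_EDGES, alpha: float = 0.05):
    """Directionality test for one driver pair.

    Returns (direction, p): direction is "untested" below ``min_edges`` total
    edges, the majority orientation when the two-sided binomial sign test is
    significant at ``alpha``, and None otherwise.
    """
    total = n_xy + n_yx
    if total < min_edges:
        return "untested", float("nan")
    p = stats.binomtest(n_xy, total, 0.5, alternative="two-sided").pvalue
    if p < alpha and n_xy != n_yx:
        return ("x_before_y" if n_xy > n_yx else "y_before_x"), float(p)
    return None, float(p)


def pair_table(graph: TemporalGraph, min_edges: int = MIN_PAIR_EDGES, alpha: float = 0.05) -> pd.DataFrame:
    """One row per unordered pair with edges in either direction."""
    seen = set()
    rows = []
    for (x, y) in graph.pair_counts:
        key = tuple(sorted((x, y)))
        if key in seen:
            continue
        seen.add(key)
        a, b = key
        n_ab, n_ba = graph.n_edges(a, b), graph.n_edges(b, a)
        direction, p = test_pair(n_ab, n_ba, min_edges=min_edges, alpha=alpha)
        rows.append((a, b, n_ab, n_ba, direction, p))
    return pd.DataFrame(
        rows, columns=["event_x", "event_y", "n_xy", "n_yx", "direction", "p_value"]
    ).sort_values(["event_x", "event_y"]).reset_index(drop=True)


def classify_timing(graph: TemporalGraph, alpha: float = 0.05) -> pd.DataFrame:
    """Early / intermediary / late labels per event from edge-degree enrichment.

    Two-sided binomial test of out-degree vs in-degree at p=0.5 per node,
    BH-FDR across nodes; early when out significantly exceeds in, late for
    the converse, intermediary otherwise (including isolated nodes).
    """
    rows = []
    for node in graph.nodes:
        out_e, in_e = graph.out_degree(node), graph.in_degree(node)
        total = out_e + in_e
        p = stats.binomtest(out_e, total, 0.5).pvalue if total > 0 else np.nan
        rows.append((node, out_e, in_e, p))
    df = pd.DataFrame(rows, columns=["event_id", "out_edges", "in_edges", "p_value"])
    mask = df["p_value"].notna()
    df["fdr"] = np.nan
    df.loc[mask, "fdr"] = fdr_adjust(df.loc[mask, "p_value"].to_numpy())
    labels = []
    for _, r in df.iterrows():
        if np.isnan(r["p_value"]) or r["fdr"] >= alpha:
            labels.append("intermediary")
        elif r["out_edges"] > r["in_edges"]:
            labels.append("early")
        elif r["in_edges"] > r["out_edges"]:
            labels.append("late")
        else:
            labels.append("intermediary")
    df["timing"] = labels
    return df


def rank_by_ccf(
    calls: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Events ordered by descending median CCF with bootstrap percentile CIs."""
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    rows = []
    for event, grp in calls.groupby("event_id"):
        vals = grp["ccf"].to_numpy(dtype=float)
        med = float(np.median(vals))
        idx = rng.integers(0, len(vals), size=(n_bootstrap, len(vals)))
        boot_meds = np.median(vals[idx], axis=1)
        rows.append((event, len(vals), med, float(np.percentile(boot_meds, lo_q)), float(np.percentile(boot_meds, hi_q))))
    df = pd.DataFrame(rows, columns=["event_id", "n", "median_ccf", "ci_low", "ci_high"])
    return df.sort_values("median_ccf", ascending=False, kind="mergesort").reset_index(drop=True)


def significant_direction_subgraph(
    graph: TemporalGraph, min_edges: int = MIN_PAIR_EDGES, alpha: float = 0.05
) -> tuple[nx.DiGraph, list[list[str]]]:
    """Directed graph of significant pair orientations, plus any cycles found.

    Contradictory edges can produce cycles in real data; cycles are reported,
    never suppressed.
    """
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    pt = pair_table(graph, min_edges=min_edges, alpha=alpha)
    for _, r in pt.iterrows():
        if r["direction"] == "x_before_y":
            g.add_edge(r["event_x"], r["event_y"], n=r["n_xy"])
        elif r["direction"] == "y_before_x":
            g.add_edge(r["event_y"], r["event_x"], n=r["n_yx"])
    cycles = [list(c) for c in nx.simple_cycles(g)]
    return g, cycles


def to_dot(graph: TemporalGraph, min_edges: int = MIN_PAIR_EDGES, alpha: float = 0.05) -> str:
    """Graphviz DOT export of the significant-direction subgraph."""
    g, _ = significant_direction_subgraph(graph, min_edges=min_edges, alpha=alpha)
    lines = ["digraph temporal {"]
    for node in sorted(g.nodes):
        lines.append(f'    "{node}";')
    for a, b, data in sorted(g.edges(data=True)):
        lines.append(f'    "{a}" -> "{b}" [label="{data.get("n", "")}"];')
    lines.append("}")
    return "\n".join(lines)
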