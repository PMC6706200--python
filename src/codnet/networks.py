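"""Weighted movement networks over receiver arrays and node connectivity metrics.

A movement network has one node per receiver station (isolated stations are
kept so the node count — and hence the triad-census denominator — is fixed)
and one weighted edge per ordered (directed) or unordered (undirected)
receiver pair, weighted by the number of movements in the time window.

Node *strength* (sum of incident edge weights: cumulative incomings and
outgoings per receiver) and *degree* (number of distinct neighbours) are
computed on undirected networks, and summed across receivers to give one
weekly connectivity value per fish.
"""

from __future__ import annotations

import itertools

import networkx as nx
import pandas as pd


def build_network(
    movements: pd.DataFrame,
    *,
    nodes,
    window: tuple | None = None,
    directed: bool = True,
    subject: str | None = None,
) -> nx.Graph:
    """Build a weighted movement network for one subject and time window.

    Parameters
    ----------
    movements
        Movement frame (see :mod:`codnet.preprocess`).
    nodes
        Full receiver id list; all appear as nodes even when isolated.
    window
        Optional (start, end] is not used — the convention is [start, end):
        movements with ``start <= departure < end`` are counted.  ``None``
        keeps everything.
    directed
        Directed networks count ordered pairs; undirected networks pool both
        directions onto one edge.
    subject
        Restrict to one transmitter; ``None`` aggregates all fish.

    Edge weights are movement counts; self-loops cannot occur because
    movements connect distinct receivers by construction.
    """
    mov = movements
    if subject is not None:
        mov = mov.loc[mov["transmitter_id"] == subject]
    if window is not None:
        start, end = window
        mov = mov.loc[(mov["departure"] >= start) & (mov["departure"] < end)]

    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(nodes)
    g.graph.update(window=window, subject=subject if subject is not None else "aggregate")
    if len(mov):
        if (mov["from_receiver"] == mov["to_receiver"]).any():
            raise ValueError("self-movement in input")
        counts = mov.groupby(["from_receiver", "to_receiver"]).size()
        for (u, v), w in counts.items():
            if g.has_edge(u, v):
                g[u][v]["weight"] += int(w)
            else:
                g.add_edge(u, v, weight=int(w))
    return g


def _require_undirected(network: nx.Graph, op: str) -> None:
    if network.is_directed():
        raise ValueError(f"{op} is defined on undirected movement networks")


def node_strength(network: nx.Graph) -> dict:
    """Weighted connectivity per receiver: sum of incident edge weights."""
    _require_undirected(network, "node_strength")
    return {v: int(s) for v, s in network.degree(weight="weight")}


def degree(network: nx.Graph) -> dict:
    """Unweighted connectivity per receiver: number of distinct neighbours."""
    _require_undirected(network, "degree")
    return {v: int(d) for v, d in network.degree()}


def weekly_metric_series(
    movements: pd.DataFrame,
    start,
    n_weeks: int,
    subjects,
    *,
    nodes,
) -> pd.DataFrame:
    """Per-subject weekly summed node strength and degree.

    Weeks are exactly 7 x 24 h from ``start``.  For every subject and week
    the subject's undirected network is built and both metrics are summed
    over all receivers (each edge therefore contributes twice — once per
    endpoint).  Weeks without movements yield 0/0 rows and are kept: the
    excess zeros are exactly what the zero-inflated count model downstream
    is for.
    """
    if n_weeks <= 0:
        raise ValueError("n_weeks must be positive")
    start = pd.Timestamp(start)
    rows = []
    for subject in subjects:
        for w in range(n_weeks):
            w0 = start + pd.Timedelta(days=7 * w)
            w1 = w0 + pd.Timedelta(days=7)
            net = build_network(
                movements, nodes=nodes, window=(w0, w1), directed=False, subject=subject
            )
            rows.append(
                {
                    "subject": subject,
                    "week": w,
                    "week_start": w0,
                    "strength": sum(node_strength(net).values()),
                    "degree": sum(degree(net).values()),
                }
            )
    return pd.DataFrame(rows)


def aggregate_seasonal(
    movements: pd.DataFrame,
    windows,
    *,
    nodes,
    tz: str | None = None,
) -> dict[str, nx.DiGraph]:
    """One pooled directed network per season window.

    ``windows`` is a sequence of :class:`codnet.preprocess.SeasonWindow`;
    a movement belongs to the season containing its departure date.
    """
    from .preprocess import DAY_TZ, local_dates

    tz = tz or DAY_TZ
    out = {}
    dates = local_dates(movements["departure"], tz) if len(movements) else pd.Series(dtype=object)
    for w in windows:
        if len(movements):
            mask = (dates >= w.start) & (dates <= w.end)
            mov = movements.loc[mask.to_numpy()]
        else:
            mov = movements
        out[w.label] = build_network(mov, nodes=nodes, directed=True)
        out[w.label].graph["window"] = (w.start, w.end)
        out[w.label].graph["season"] = w.label
    return out


def total_weight(network: nx.Graph) -> int:
    return int(sum(d["weight"] for _, _, d in network.edges(data=True)))


def write_graphml(network: nx.Graph, path) -> None:
    g = network.copy()
    # GraphML cannot serialise tuples/None graph attributes
    for k, v in list(g.graph.items()):
        if v is None or isinstance(v, tuple):
            g.graph[k] = str(v)
    nx.write_graphml(g, path)


def write_edgelist_csv(network: nx.Graph, path) -> None:
    rows = [
        {"from": u, "to": v, "weight": d["weight"]} for u, v, d in network.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["from", "to", "weight"]).to_csv(path, index=False)


def edge_pairs(network: nx.Graph):
    """Iterate (u, v, weight) in a stable order (for deterministic output)."""
    return sorted(
        ((u, v, d["weight"]) for u, v, d in network.edges(data=True)),
        key=lambda t: (str(t[0]), str(t[1])),
    )


def all_node_pairs(nodes):
    return itertools.combinations(sorted(nodes), 2)
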