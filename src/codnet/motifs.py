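"""Directed triad census (16 isomorphism classes) and monthly motif series.

Every unordered triple of receivers in a directed movement network induces a
3-node sub-digraph, which falls into one of 16 isomorphism classes — the
classic M-A-N scheme that labels each class by its count of Mutual,
Asymmetric and Null dyads plus an orientation letter (Down / Up / Cyclic /
Transitive).  Class 1 (003) is the null triad: three receivers with no
movement between any of them.  An n-node network always has exactly
C(n, 3) triads, so an 11-receiver array yields 165 per census, and the
null-class count measures how much of the array is *unused*.

The census here classifies each triple through a 64-entry decision table
over the six possible ordered edges; the table itself is derived at import
time by brute-force isomorphism against canonical exemplars, so the fast
path and the class definitions cannot drift apart.  Edge weights are
binarised (an ordered pair is present when at least one movement occurred).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

#: Class labels in the standard (Davis–Leinhardt / igraph triad_census) order;
#: class index i (1-based) is MAN_LABELS[i-1].
MAN_LABELS = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)

#: Canonical exemplar edge sets on nodes {0, 1, 2}, one per class.
_EXEMPLARS = {
    "003": (),
    "012": ((0, 1),),
    "102": ((0, 1), (1, 0)),
    "021D": ((1, 0), (1, 2)),              # one source feeding two sinks
    "021U": ((0, 1), (2, 1)),              # two sources into one sink
    "021C": ((0, 1), (1, 2)),              # directed path
    "111D": ((0, 1), (1, 0), (2, 1)),
    "111U": ((0, 1), (1, 0), (1, 2)),
    "030T": ((0, 1), (2, 1), (0, 2)),      # transitive triangle
    "030C": ((0, 1), (1, 2), (2, 0)),      # cyclic triangle
    "201": ((0, 1), (1, 0), (1, 2), (2, 1)),
    "120D": ((1, 0), (1, 2), (0, 2), (2, 0)),
    "120U": ((0, 1), (2, 1), (0, 2), (2, 0)),
    "120C": ((0, 1), (1, 2), (0, 2), (2, 0)),
    "210": ((0, 1), (1, 2), (2, 1), (0, 2), (2, 0)),
    "300": ((0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)),
}

# Ordered-edge slots for the bitmask encoding of a labeled 3-node digraph.
_EDGE_SLOTS = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))


def _mask(edges) -> int:
    m = 0
    for e in edges:
        m |= 1 << _EDGE_SLOTS.index(e)
    return m


def _canonical(mask: int) -> int:
    """Smallest bitmask among the 6 node relabelings of a 3-node digraph."""
    edges = [_EDGE_SLOTS[i] for i in range(6) if mask >> i & 1]
    best = None
    for perm in itertools.permutations(range(3)):
        m = _mask((perm[u], perm[v]) for u, v in edges)
        best = m if best is None else min(best, m)
    return best


def _build_lut() -> np.ndarray:
    canon_to_class = {}
    for idx, label in enumerate(MAN_LABELS, start=1):
        canon_to_class[_canonical(_mask(_EXEMPLARS[label]))] = idx
    lut = np.zeros(64, dtype=np.int64)
    for mask in range(64):
        lut[mask] = canon_to_class[_canonical(mask)]
    return lut


#: mask (6-bit labeled-edge pattern) -> class index 1..16
_TRIAD_LUT = _build_lut()


def classify_triad(edges, nodes=None) -> int:
    """Isomorphism class (1–16) of the digraph induced on three nodes.

    ``edges`` is an iterable of ordered pairs among exactly three distinct
    node labels; ``nodes`` fixes the label set when some node is isolated.
    Weights are irrelevant — a pair is present or absent.  The result is
    invariant under node relabeling.  Self-loops are rejected.
    """
    edges = list(edges)
    labels = set(nodes) if nodes is not None else set()
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        labels.add(u)
        labels.add(v)
    if len(labels) != 3:
        raise ValueError(f"expected exactly 3 nodes, got {sorted(map(str, labels))!r}")
    order = {lab: i for i, lab in enumerate(sorted(labels, key=str))}
    return int(_TRIAD_LUT[_mask((order[u], order[v]) for u, v in set(edges))])


def triad_census(network) -> np.ndarray:
    """Census of all C(n, 3) triads of a directed network.

    Returns a length-16 integer array in :data:`MAN_LABELS` order.  Isolated
    nodes participate (they generate null and near-null triads), so the
    counts always sum to C(n, 3).
    """
    if not network.is_directed():
        raise ValueError("triad census requires a directed network")
    nodes = sorted(network.nodes, key=str)
    succ = {v: set(network.successors(v)) for v in nodes}
    counts = np.zeros(16, dtype=np.int64)
    for a, b, c in itertools.combinations(nodes, 3):
        mask = (
            (b in succ[a])
            | (a in succ[b]) << 1
            | (c in succ[a]) << 2
            | (a in succ[c]) << 3
            | (c in succ[b]) << 4
            | (b in succ[c]) << 5
        )
        counts[_TRIAD_LUT[mask] - 1] += 1
    return counts


def census_series(counts: np.ndarray) -> pd.Series:
    """Census as a Series indexed by MAN code (paper-style 1–16 order)."""
    return pd.Series(counts, index=list(MAN_LABELS), name="count")


def monthly_motif_series(
    movements: pd.DataFrame,
    subjects,
    months,
    sst_by_month: pd.Series | dict,
    *,
    nodes,
    tz: str | None = None,
) -> pd.DataFrame:
    """Per-subject monthly triad censuses with the month's mean SST attached.

    For each subject x calendar month, the subject's directed movement
    network for that month is built (movement month = local departure date's
    month) and censused.  Months without movements yield the null census
    (all C(n,3) triads in class 003) — those rows carry the signal that the
    fish stopped moving.  Output columns: subject, month (pandas Period),
    sst, then one column per MAN code.
    """
    from .networks import build_network
    from .preprocess import DAY_TZ, local_dates

    tz = tz or DAY_TZ
    months = [pd.Period(m, freq="M") for m in months]
    if len(movements):
        mdates = pd.PeriodIndex(
            pd.DatetimeIndex(local_dates(movements["departure"], tz)), freq="M"
        )
    rows = []
    for subject in subjects:
        for month in months:
            mov = movements
            if len(movements):
                mov = movements.loc[
                    (movements["transmitter_id"].to_numpy() == subject)
                    & np.asarray(mdates == month)
                ]
            net = build_network(mov, nodes=nodes, directed=True, subject=subject)
            counts = triad_census(net)
            row = {"subject": subject, "month": month, "sst": float(sst_by_month[month])}
            row.update({lab: int(c) for lab, c in zip(MAN_LABELS, counts)})
            rows.append(row)
    return pd.DataFrame(rows)


def motif_temperature_model(series: pd.DataFrame, man_class: str):
    """Negative-binomial mixed model of one motif class's count against SST.

    Fits ``count ~ SST`` with a log link and a per-fish random intercept on
    the monthly census series.  A class that never occurs (or never varies)
    is reported as non-estimable rather than raising.
    Returns a :class:`codnet.stats.MixedModelFit`.
    """
    from .stats import MixedModelFit, fit_nb_glmm

    if man_class not in MAN_LABELS:
        raise KeyError(f"unknown triad class {man_class!r}; use one of {MAN_LABELS}")
    y = series[man_class].to_numpy()
    if y.max() == y.min():
        return MixedModelFit.non_estimable(
            reason=f"class {man_class} is constant ({y.min()}) across all subject-months",
            n_obs=len(y),
            n_subjects=series["subject"].nunique(),
        )
    return fit_nb_glmm(
        y, series[["sst"]].rename(columns={"sst": "SST"}), series["subject"].to_numpy()
    )
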