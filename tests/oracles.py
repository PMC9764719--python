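"""Independent brute-force oracles used by the test suite only.

These deliberately re-derive quantities by enumeration or tabulation, staying
independent of the library code paths they validate.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd


# --- d-separation by exhaustive path enumeration -------------------------

def _all_undirected_paths(g: nx.DiGraph, s, t):
    """All simple paths between s and t in the skeleton, as node sequences."""
    ug = g.to_undirected()
    return nx.all_simple_paths(ug, s, t)


def path_blocked(g: nx.DiGraph, path: list, z: set) -> bool:
    """Standard blocking rules applied to one path."""
    z_closure = set(z)
    for n in z:
        z_closure |= nx.ancestors(g, n)
    for i in range(1, len(path) - 1):
        prev, node, nxt = path[i - 1], path[i], path[i + 1]
        into_left = g.has_edge(prev, node)
        into_right = g.has_edge(nxt, node)
        is_collider = into_left and into_right
        if is_collider:
            if node not in z_closure:  # collider closed unless it (or a
                return True            # descendant) is conditioned on
        else:
            if node in z:
                return True
    return False


def d_separated_enum(g: nx.DiGraph, xs, ys, zs) -> bool:
    """d-separation decided by enumerating every path and applying the rules."""
    zs = set(zs)
    for s in xs:
        for t in ys:
            for path in _all_undirected_paths(g, s, t):
                if not path_blocked(g, path, zs):
                    return False
    return True


def all_dags(n: int):
    """Every labelled DAG on nodes 0..n-1 with edges respecting the node order.

    Every DAG is isomorphic to one with edges i->j only for i<j, and for
    d-separation queries over all labelled node subsets this family is
    exhaustive up to relabelling.
    """
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for mask in range(2 ** len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        for k, (i, j) in enumerate(pairs):
            if mask >> k & 1:
                g.add_edge(i, j)
        yield g


def random_dag(rng: np.random.Generator, n: int, p: float = 0.35) -> nx.DiGraph:
    order = rng.permutation(n)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(int(order[i]), int(order[j]))
    return g


def all_disjoint_queries(nodes):
    """All (x, y, Z) with singleton x,y and every conditioning subset."""
    nodes = list(nodes)
    for x, y in combinations(nodes, 2):
        rest = [n for n in nodes if n not in (x, y)]
        for r in range(len(rest) + 1):
            for z in combinations(rest, r):
                yield {x}, {y}, set(z)


# --- person-day bookkeeping ----------------------------------------------

def persondays_per_patient_loop(records: pd.DataFrame, max_days: int = 14) -> int:
    """Row count of the person-day expansion by a plain per-patient loop."""
    total = 0
    for _, r in records.iterrows():
        present = max(int(r["discharge_day"]) - int(r["admission_day"]), 1)
        if bool(r["died"]):
            followed = int(r["death_day"]) - int(r["admission_day"]) + 1
        else:
            followed = present
        total += min(followed, max_days)
    return total


def census_by_day_loop(records: pd.DataFrame, year_length: int) -> np.ndarray:
    """Daily census by looping patients and marking presence day by day."""
    census = np.zeros(year_length, dtype=int)
    for _, r in records.iterrows():
        a, d = int(r["admission_day"]), int(r["discharge_day"])
        last = max(d - 1, a)
        for day in range(max(a, 1), min(last, year_length) + 1):
            census[day - 1] += 1
    return census


# --- sequence-probability tabulation for stabilized weights ---------------

def sequence_weight_tabulation(df: pd.DataFrame) -> pd.Series:
    """Stabilized weights for a 2-day fully discrete system by tabulation.

    ``df`` has one row per patient-day with columns ``patient_id``, ``t``
    (1 or 2), ``a`` (exposure) and ``l`` (discrete confounder).  The weight of
    a patient's day-t row is

        P(a_1..a_t | a-history) / P(a_1..a_t | a- and l-history)

    where each factor is a product of empirical conditional frequencies over
    the full cross-tabulation of histories.
    """
    wide = df.pivot(index="patient_id", columns="t")
    a1 = wide[("a", 1)].astype(int)
    a2 = wide[("a", 2)].astype(int)
    l1 = wide[("l", 1)].astype(int)
    l2 = wide[("l", 2)].astype(int)

    def freq(num_mask, den_mask):
        return num_mask.sum() / den_mask.sum()

    n = len(wide)
    p_num_1 = pd.Series(index=wide.index, dtype=float)
    p_den_1 = pd.Series(index=wide.index, dtype=float)
    p_num_2 = pd.Series(index=wide.index, dtype=float)
    p_den_2 = pd.Series(index=wide.index, dtype=float)
    for pid in wide.index:
        m_a1 = a1 == a1[pid]
        p_num_1[pid] = freq(m_a1, pd.Series(True, index=wide.index))
        m_l1 = l1 == l1[pid]
        p_den_1[pid] = freq(m_a1 & m_l1, m_l1)
        hist_num = m_a1
        p_num_2[pid] = freq(hist_num & (a2 == a2[pid]), hist_num)
        hist_den = m_a1 & m_l1 & (l2 == l2[pid])
        p_den_2[pid] = freq(hist_den & (a2 == a2[pid]), hist_den)

    sw1 = p_num_1 / p_den_1
    sw2 = sw1 * p_num_2 / p_den_2
    out = {}
    for pid in wide.index:
        out[(pid, 1)] = sw1[pid]
        out[(pid, 2)] = sw2[pid]
    return pd.Series(out)
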