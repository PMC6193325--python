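import itertools
from collections import deque

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from herbnet.io import Compound, Herb, Role

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_compound(cid, name, herbs, OB=50.0, DL=0.5, MW=300.0, nHdon=2, nHacc=4, AlogP=2.0):
    return Compound(
        id=cid, name=name, MW=MW, nHdon=nHdon, nHacc=nHacc,
        AlogP=AlogP, OB=OB, DL=DL, herbs=set(herbs),
    )


@pytest.fixture
def toy_herbs():
    return {
        Herb("HB_J", Role.JUN),
        Herb("HB_C", Role.CHEN),
        Herb("HB_Z", Role.ZUO_SHI),
    }


@pytest.fixture
def formulary_file(tmp_path):
    """Write a small formulary TSV and return its path."""

    def _write(rows, columns=None):
        columns = columns or [
            "herb", "role", "compound_id", "name",
            "MW", "nHdon", "nHacc", "AlogP", "OB", "DL",
        ]
        path = tmp_path / "formulary.tsv"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return path

    return _write


# ---------------------------------------------------------------------------
# independent oracles (never call the implementation under test)


def brute_force_betweenness(edges, nodes):
    """Normalized betweenness by explicit enumeration of all shortest paths."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    n = len(nodes)
    score = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
        if t not in dist:
            continue
        paths = []
        stack = [[t]]
        while stack:
            path = stack.pop()
            head = path[-1]
            if head == s:
                paths.append(path)
                continue
            for w in adj[head]:
                if w in dist and dist[w] == dist[head] - 1:
                    stack.append(path + [w])
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: (score[v] / norm if norm > 0 else 0.0) for v in nodes}


def enumeration_hypergeom_sf(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all n-subsets of an N-universe."""
    universe = range(N)
    in_term = set(range(K))
    hits = total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if sum(1 for x in subset if x in in_term) >= k:
            hits += 1
    return hits / total


def anova_sums_of_squares(groups):
    """One-way ANOVA F statistic from explicit sums of squares."""
    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ssb / df_b) / (ssw / df_w)
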