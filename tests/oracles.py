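"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the literal definitions (exhaustive
enumeration, closed forms, 1-D search) and deliberately shares no code with
the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import optimize, stats


def plugin_mi(counts) -> float:
    """Closed-form plug-in MI (nats) of a joint count table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    total = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            c = counts[i, j]
            if c == 0:
                continue
            pij = c / n
            pi = counts[i, :].sum() / n
            pj = counts[:, j].sum() / n
            total += pij * np.log(pij / (pi * pj))
    return total


def dpi_brute_force(edges: dict, tolerance: float = 0.0) -> dict:
    """Exhaustive triangle enumeration with simultaneous removal.

    ``edges`` maps frozenset({a, b}) -> mi.
    """
    nodes = sorted({n for e in edges for n in e})
    doomed = set()
    for a, b, c in combinations(nodes, 3):
        ab, bc, ac = frozenset((a, b)), frozenset((b, c)), frozenset((a, c))
        if ab in edges and bc in edges and ac in edges:
            trio = [(edges[ab], ab), (edges[bc], bc), (edges[ac], ac)]
            trio.sort(key=lambda t: t[0])
            weakest_mi, weakest = trio[0]
            if weakest_mi < (1.0 - tolerance) * trio[1][0]:
                doomed.add(weakest)
    return {e: mi for e, mi in edges.items() if e not in doomed}


def running_sum_scan(weights: np.ndarray, absvals: np.ndarray) -> float:
    """All-k scan of the foreground-minus-background deviation."""
    n = len(weights)
    total = float((weights * absvals).sum())
    n_zero = int((weights == 0).sum())
    assert n_zero > 0
    if total == 0:
        return 0.0
    best = 0.0
    best_abs = -1.0
    fg_raw = 0.0
    zeros = 0
    for k in range(n):
        fg_raw += weights[k] * absvals[k]
        if weights[k] == 0:
            zeros += 1
        d = fg_raw / total - zeros / n_zero
        if abs(d) > best_abs:
            best_abs = abs(d)
            best = d
    return best


def fisher_upper_tail(table) -> float:
    """One-sided (enrichment) Fisher p by hypergeometric enumeration."""
    a, b, c, d = np.asarray(table).ravel()
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    p = 0.0
    for k in range(a, min(r1, c1) + 1):
        p += stats.hypergeom.pmf(k, n, r1, c1)
    return float(p)


def cox_loglik_efron(beta: float, x, time, event) -> float:
    """Literal Efron partial log-likelihood for a single covariate."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        tied = (time == t) & (event == 1)
        d = int(tied.sum())
        risk = time >= t
        s0 = np.exp(beta * x[risk]).sum()
        s0d = np.exp(beta * x[tied]).sum()
        ll += beta * x[tied].sum()
        for l in range(d):
            ll -= np.log(s0 - (l / d) * s0d)
    return ll


def cox_beta_brute_force(x, time, event, lo=-10.0, hi=10.0) -> float:
    """1-D maximiser of the written-out partial likelihood."""
    res = optimize.minimize_scalar(
        lambda b: -cox_loglik_efron(b, x, time, event),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x)


def stouffer_literal(zs, ns, mode="n") -> float:
    w = [float(n) if mode == "n" else float(n) ** 0.5 for n in ns]
    num = sum(wi * zi for wi, zi in zip(w, zs))
    den = sum(wi**2 for wi in w) ** 0.5
    return num / den


def bh_literal(ps) -> np.ndarray:
    """Step-up BH from the definition, with monotonicity enforcement."""
    ps = np.asarray(ps, float)
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * m / rank)
        adj[i] = running
    return adj


def logrank_hand(time, event, group) -> float:
    """Two-group log-rank chi-square from the observed-minus-expected sums."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    group = np.asarray(group)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)


def complete_linkage_brute(points: np.ndarray) -> list[tuple]:
    """O(n^3) agglomeration with complete linkage and Euclidean distance.

    Returns the merge sequence [(members_a, members_b, dist), ...] with
    clusters as frozensets of original row indices.
    """
    clusters = {i: frozenset([i]) for i in range(len(points))}
    merges = []

    def dist(ca, cb):
        return max(
            np.linalg.norm(points[i] - points[j]) for i in ca for j in cb
        )

    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            d = dist(clusters[a], clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges
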