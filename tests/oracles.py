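"""Independent brute-force oracles used to cross-check the library.

These deliberately re-derive each quantity from first principles —
explicit power iteration, term-by-term moment arithmetic, naive ranking —
and never call the code paths they verify.
"""

import math

import numpy as np


def pagerank_power_iteration(web, damping=0.85, weighted=True, tol=1e-14):
    """PageRank by explicit power iteration on the predator -> prey graph.

    Out-edge weights are row-normalised; nodes without out-edges spread
    their mass uniformly over the whole network.
    """
    ids = list(web.ids)
    n = len(ids)
    pos = {s: k for k, s in enumerate(ids)}
    W = np.zeros((n, n))
    for link in web.links:
        if link.consumption > 0:
            W[pos[link.predator], pos[link.prey]] += (
                link.consumption if weighted else 1.0
            )
    row_sums = W.sum(axis=1)
    P = np.zeros_like(W)
    nonzero = row_sums > 0
    P[nonzero] = W[nonzero] / row_sums[nonzero, None]
    x = np.full(n, 1.0 / n)
    for _ in range(100000):
        dangling_mass = x[~nonzero].sum()
        x_new = damping * (x @ P + dangling_mass / n) + (1 - damping) / n
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return dict(zip(ids, x))


def beta_eff_by_hand(web):
    """Term-by-term evaluation of the resilience state from raw flows."""
    ids = list(web.ids)
    s_in = {i: 0.0 for i in ids}
    s_out = {i: 0.0 for i in ids}
    for link in web.links:
        if link.consumption > 0:
            s_in[link.predator] += link.consumption
            s_out[link.prey] += link.consumption
    a = np.array([s_in[i] for i in ids])
    b = np.array([s_out[i] for i in ids])
    mean_s = a.mean()
    mean_prod = (a * b).mean()
    sig_in = math.sqrt(((a - a.mean()) ** 2).mean())
    sig_out = math.sqrt(((b - b.mean()) ** 2).mean())
    if sig_in * sig_out == 0:
        return mean_s
    S = (mean_prod - a.mean() * b.mean()) / (sig_in * sig_out)
    H = sig_in * sig_out / mean_s
    return mean_s + S * H


def competition_ranks(values):
    """Naive 1224 ranking, largest first."""
    return [1 + sum(other > v for other in values) for v in values]


def hub_set_by_hand(web, damping=0.85, percentile=0.05):
    """Recompute the hub designation from scratch: naive metric counts,
    naive ranks, min, sort, 5% cutoff with boundary ties included."""
    ids = list(web.ids)
    prey = {i: set() for i in ids}
    pred = {i: set() for i in ids}
    for link in web.links:
        if link.consumption > 0:
            prey[link.predator].add(link.prey)
            pred[link.prey].add(link.predator)
    deg = [len(prey[i]) + len(pred[i]) for i in ids]
    out = [len(pred[i]) for i in ids]
    pr_map = pagerank_power_iteration(web, damping=damping)
    pr = [pr_map[i] for i in ids]
    hub = [
        min(rd, ro, rp)
        for rd, ro, rp in zip(
            competition_ranks(deg), competition_ranks(out), competition_ranks(pr)
        )
    ]
    n_target = max(1, math.ceil(percentile * len(ids)))
    cutoff = sorted(hub)[n_target - 1]
    return {i for i, h in zip(ids, hub) if h <= cutoff}
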