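"""Independent reference implementations used as test oracles.

Deliberately naive: plain-Python loops and textbook formulas, sharing no
code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup(pvals):
    """Benjamini-Hochberg step-up adjustment, hand-coded."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = min(val, 1.0)
        prev = adj[i]
    return adj


def correlation_eig_pca(matrix):
    """Loadings as eigenvectors of the probe-probe correlation matrix."""
    X = np.asarray(matrix, float)
    R = np.corrcoef(X)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order]


def plain_corr(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def brute_force_patterns(study, params):
    """Exhaustive re-implementation of the pattern-extraction steps.

    Returns a list of sorted member-id lists, in creation order.
    """
    meta = study.metadata
    samples = list(study.sample_ids)
    rows = {p: [float(v) for v in study.values.loc[p, samples]] for p in study.probe_ids}
    cells = [f"{meta.loc[s, 'treatment']}|{meta.loc[s, 'time_hr']}" for s in samples]

    def snr(vals):
        groups = {}
        for v, c in zip(vals, cells):
            groups.setdefault(c, []).append(v)
        means = [sum(g) / len(g) for g in groups.values()]
        ss = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups.values())
        dof = sum(len(g) - 1 for g in groups.values())
        sd = math.sqrt(ss / dof)
        sig = max(means) - min(means)
        if sd == 0:
            return 0.0 if sig == 0 else params.snr_cap
        return sig / sd

    def mag(vals):
        best = 0.0
        for t in sorted({meta.loc[s, "time_hr"] for s in samples}):
            veh = [v for v, s in zip(vals, samples)
                   if meta.loc[s, "role"] == "vehicle" and meta.loc[s, "time_hr"] == t]
            veh_ids = {s for s in samples
                       if meta.loc[s, "role"] == "vehicle" and meta.loc[s, "time_hr"] == t}
            vm = sum(veh) / len(veh)
            for tr in sorted({meta.loc[s, "treatment"] for s in samples
                              if meta.loc[s, "time_hr"] == t}):
                ids = {s for s in samples
                       if meta.loc[s, "treatment"] == tr and meta.loc[s, "time_hr"] == t}
                if ids == veh_ids:
                    continue
                gvals = [v for v, s in zip(vals, samples) if s in ids]
                best = max(best, abs(sum(gvals) / len(gvals) - vm))
        return best

    eligible = [p for p in study.probe_ids
                if snr(rows[p]) >= params.snr_min and mag(rows[p]) >= params.mag_min]
    assigned: set = set()
    patterns = []
    while True:
        best_probe, best_count, best_nb = None, -1, None
        for p in sorted(eligible):
            if p in assigned:
                continue
            nb = [q for q in eligible if q not in assigned
                  and plain_corr(rows[p], rows[q]) >= params.r_min]
            if len(nb) > best_count:
                best_probe, best_count, best_nb = p, len(nb), nb
        if best_count < params.min_cluster:
            break
        members = set(best_nb)
        profile = [sum(rows[m][j] for m in members) / len(members)
                   for j in range(len(samples))]
        for q in sorted(eligible):
            if q in assigned or q in members:
                continue
            if plain_corr(profile, rows[q]) >= params.r_min:
                members.add(q)
        assigned |= members
        patterns.append(sorted(members))
        if all(p in assigned for p in eligible):
            break
    return patterns


def montecarlo_tukey_p(q_obs, k, group_sizes, reps, rng):
    """Null distribution of the Tukey-Kramer statistic by simulation.

    Groups are drawn from one standard normal; the statistic is the max
    over pairs of |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)) ... for
    the adjusted p of a single observed pair the relevant null is the
    maximum pairwise statistic, which is what the studentized-range
    adjustment integrates.
    """
    sizes = list(group_sizes)
    draws = [rng.standard_normal((reps, n)) for n in sizes]
    means = np.column_stack([d.mean(axis=1) for d in draws])
    ss = sum(((d - d.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for d in draws)
    df = sum(n - 1 for n in sizes)
    mse = ss / df
    qmax = np.zeros(reps)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            qmax = np.maximum(qmax, np.abs(means[:, i] - means[:, j]) / se)
    return float((qmax >= q_obs).mean())
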