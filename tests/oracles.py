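"""Independent brute-force oracles for the four stability statistics.

Deliberately written with plain Python loops and the statistics module,
not shared with the package implementation, so tests comparing the two
routes are meaningful.
"""

import math
import statistics

from scipy.stats import pearsonr


def sd(xs):
    return statistics.stdev(xs)  # sample SD, n-1


def genorm_m_values(q_rows):
    """M value per gene from all pairwise log2-ratio SDs (one round)."""
    k = len(q_rows)
    ms = []
    for j in range(k):
        vs = []
        for l in range(k):
            if l == j:
                continue
            ratios = [
                math.log2(a / b) for a, b in zip(q_rows[j], q_rows[l])
            ]
            vs.append(sd(ratios))
        ms.append(sum(vs) / len(vs))
    return ms


def genorm_full(q_rows, gene_ids):
    """Stepwise exclusion, recomputing every pairwise SD each round.

    Returns (stability per gene id, elimination order). Ties broken by
    dropping the later gene id, mirroring the documented convention.
    """
    active = list(range(len(gene_ids)))
    stability = {}
    order = []
    while len(active) > 2:
        ms = genorm_m_values([q_rows[i] for i in active])
        for local, gi in enumerate(active):
            stability[gene_ids[gi]] = ms[local]
        worst = max(ms)
        tied = [i for i, m in enumerate(ms) if m == worst]
        drop_local = max(tied, key=lambda i: gene_ids[active[i]])
        order.append(gene_ids[active[drop_local]])
        active.pop(drop_local)
    order.extend(sorted(gene_ids[i] for i in active))
    return stability, order


def normfinder_values(cq_rows):
    """Ungrouped stability: SD of deviation from per-sample panel mean."""
    k = len(cq_rows)
    n = len(cq_rows[0])
    col_means = [sum(cq_rows[g][s] for g in range(k)) / k for s in range(n)]
    out = []
    for g in range(k):
        z = [cq_rows[g][s] - col_means[s] for s in range(n)]
        out.append(sd(z))
    return out


def bestkeeper_values(cq_rows):
    """(sd_mad, geo_mean, r_vs_index) per gene, loop computed."""
    k = len(cq_rows)
    n = len(cq_rows[0])
    geo = [
        math.exp(sum(math.log(x) for x in row) / n) for row in cq_rows
    ]
    sd_mad = [
        sum(abs(x - g) for x in row) / n for row, g in zip(cq_rows, geo)
    ]
    index = [
        math.exp(sum(math.log(cq_rows[g][s]) for g in range(k)) / k)
        for s in range(n)
    ]
    rs = [pearsonr(row, index)[0] for row in cq_rows]
    return sd_mad, geo, rs


def delta_ct_values(cq_rows):
    """Mean pairwise SD of per-sample Cq differences."""
    k = len(cq_rows)
    out = []
    for j in range(k):
        sds = []
        for l in range(k):
            if l == j:
                continue
            diffs = [a - b for a, b in zip(cq_rows[j], cq_rows[l])]
            sds.append(sd(diffs))
        out.append(sum(sds) / len(sds))
    return out


def mann_whitney_exact_p(a, b):
    """Two-sided exact p by full enumeration of group assignments."""
    from itertools import combinations

    pooled = list(a) + list(b)
    na = len(a)

    def u_of(sample_a, sample_b):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x in sample_a
            for y in sample_b
        )

    observed = u_of(a, b)
    nb = len(b)
    mean_u = na * nb / 2
    obs_dev = abs(observed - mean_u)
    total = 0
    extreme = 0
    idx = range(len(pooled))
    for chosen in combinations(idx, na):
        sa = [pooled[i] for i in chosen]
        sb = [pooled[i] for i in idx if i not in chosen]
        total += 1
        if abs(u_of(sa, sb) - mean_u) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total
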