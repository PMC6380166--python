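"""Four-algorithm RT-qPCR reference-gene stability suite with rank aggregation.

Implements the four stability statistics commonly combined for
reference-gene selection, plus their geometric-mean-of-ranks
("comprehensive") aggregation:

* **geNorm** — a gene's M value is the mean, over all other candidates,
  of the sample standard deviation of the pairwise log2 expression
  ratio; genes are excluded iteratively from the highest M.
* **NormFinder** (ungrouped) — the SD across samples of a gene's Cq
  after centring each sample on the panel mean (deviation from the
  panel consensus on the log scale).
* **BestKeeper** — descriptive dispersion of raw Cq (mean absolute
  deviation from the geometric mean) plus correlation with the
  BestKeeper index (per-sample geometric mean of all candidates' Cq).
* **comparative ΔCt** — the mean, over all other genes, of the SD of
  the per-sample Cq difference.

Lower is more stable for every statistic. geNorm, NormFinder and ΔCt
are invariant to per-gene additive Cq shifts (multiplicative expression
rescaling); BestKeeper, operating on raw Cq, is not.

Stress subsets follow the factorial design: ``temperature`` = {C, HT,
LT}, ``salinity`` = {C, HS, LS}, ``combined`` = all treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CqMatrix, RefstabError, SUBSET_TREATMENTS

METHODS = ("genorm", "normfinder", "bestkeeper", "delta_ct")


@dataclass
class MethodResult:
    """Per-gene stability values and ranks for one method (1 = most stable)."""

    method: str
    gene_ids: list[str]
    stability_value: np.ndarray
    rank: np.ndarray

    def __post_init__(self) -> None:
        self.stability_value = np.asarray(self.stability_value, dtype=float)
        self.rank = np.asarray(self.rank, dtype=float)
        if not (
            len(self.gene_ids) == self.stability_value.size == self.rank.size
        ):
            raise RefstabError("MethodResult arrays misaligned")

    def as_series(self) -> pd.Series:
        return pd.Series(self.stability_value, index=self.gene_ids, name=self.method)


@dataclass
class StabilityReport:
    """Per-method results plus the comprehensive geometric-mean ranking."""

    gene_ids: list[str]
    methods: dict[str, MethodResult]
    comprehensive_score: np.ndarray
    comprehensive_rank: np.ndarray
    subset_label: str = "combined"
    pairwise_variation: np.ndarray | None = None
    bestkeeper_table: pd.DataFrame | None = None
    genorm_trajectory: list[str] = field(default_factory=list)

    def ranking(self) -> list[str]:
        """Gene ids from most to least stable by comprehensive rank."""
        order = np.argsort(self.comprehensive_rank, kind="stable")
        return [self.gene_ids[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.gene_ids})
        for name in METHODS:
            if name in self.methods:
                df[name] = self.methods[name].stability_value
                df[f"{name}_rank"] = self.methods[name].rank
        df["comprehensive_score"] = self.comprehensive_score
        df["comprehensive_rank"] = self.comprehensive_rank
        df["subset"] = self.subset_label
        return df.sort_values("comprehensive_rank", kind="mergesort").reset_index(
            drop=True
        )


@dataclass
class RelativeQuantityMatrix:
    """Gene x sample relative quantities Q = E^(minCq - Cq), each row max 1."""

    gene_ids: list[str]
    design: list
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q <= 0):
            raise RefstabError("relative quantities must be > 0")


def cq_to_quantity(cq: CqMatrix) -> RelativeQuantityMatrix:
    """Transform Cq to relative quantities with per-gene efficiency.

    ``Q[g,s] = E_g ** (min_s' Cq[g,s'] - Cq[g,s])``; the most abundant
    sample of each gene gets exactly 1.
    """
    eff = cq.efficiency_array()
    if np.any(eff <= 1):
        bad = [g for g, e in zip(cq.gene_ids, eff) if e <= 1]
        raise RefstabError(f"efficiency must be > 1 for quantity transform: {bad}")
    delta = cq.values.min(axis=1, keepdims=True) - cq.values
    q = eff[:, None] ** delta
    return RelativeQuantityMatrix(list(cq.gene_ids), list(cq.design), q)


def _pairwise_logratio_sd(log2q: np.ndarray) -> np.ndarray:
    """Matrix V[j,k] = sample SD over samples of log2(Q_j/Q_k)."""
    k = log2q.shape[0]
    v = np.zeros((k, k))
    for j in range(k):
        diffs = log2q[j] - log2q  # (k, n)
        v[j] = diffs.std(axis=1, ddof=1)
    return v


def genorm(q: RelativeQuantityMatrix) -> tuple[MethodResult, list[str]]:
    """geNorm M values via stepwise exclusion.

    Returns the method result and the exclusion trajectory (gene ids in
    elimination order, least stable first, ending with the final pair in
    id order). Each gene's reported M is its value in the round of its
    elimination; the final two genes keep their M from the last round in
    which three or more genes were active (a 2-gene M is degenerate) and
    share the averaged top rank 1.5. Ties in the elimination step are
    broken by removing the lexicographically later gene id.
    """
    k, n = q.q.shape
    if k < 3:
        raise RefstabError("genorm requires >= 3 genes")
    if n < 2:
        raise RefstabError("genorm requires >= 2 samples")
    log2q = np.log2(q.q)
    active = list(range(k))
    stability = np.empty(k)
    rank = np.empty(k)
    trajectory: list[str] = []
    next_rank = float(k)
    while len(active) > 2:
        sub = log2q[active]
        v = _pairwise_logratio_sd(sub)
        m = v.sum(axis=1) / (len(active) - 1)
        # every active gene keeps this round's M until eliminated; the
        # final pair retains it from the last >=3-gene round
        for local, gi in enumerate(active):
            stability[gi] = m[local]
        worst_m = m.max()
        tied = [i for i, mi in enumerate(m) if mi == worst_m]
        # deterministic tie-break: drop the later gene id
        worst_local = max(tied, key=lambda i: q.gene_ids[active[i]])
        gi = active[worst_local]
        rank[gi] = next_rank
        trajectory.append(q.gene_ids[gi])
        next_rank -= 1.0
        active.remove(gi)
    for gi in active:
        rank[gi] = 1.5
    trajectory.extend(sorted(q.gene_ids[gi] for gi in active))
    return (
        MethodResult("genorm", list(q.gene_ids), stability, rank),
        trajectory,
    )


def genorm_pairwise_variation(
    q: RelativeQuantityMatrix, ranking: list[str]
) -> np.ndarray:
    """geNorm pairwise variations V(n, n+1), n = 2..k-1.

    ``NF_n[s]`` is the geometric mean of the n most stable genes'
    quantities at sample s; ``V(n, n+1)`` is the sample SD over s of
    ``log2(NF_n / NF_{n+1})``. Low V means adding the (n+1)-th gene
    barely changes the normalization factor.
    """
    k = q.q.shape[0]
    if sorted(ranking) != sorted(q.gene_ids):
        raise RefstabError("ranking must be a permutation of the gene ids")
    if k < 3:
        raise RefstabError("pairwise variation requires >= 3 genes")
    idx = [q.gene_ids.index(g) for g in ranking]
    log2q = np.log2(q.q)[idx]
    vs = []
    for n in range(2, k):
        nf_n = log2q[:n].mean(axis=0)  # log2 of geometric mean
        nf_n1 = log2q[: n + 1].mean(axis=0)
        vs.append(float((nf_n - nf_n1).std(ddof=1)))
    return np.array(vs)


def normfinder(cq: CqMatrix) -> MethodResult:
    """Ungrouped NormFinder-style stability on the cycle (log) scale.

    A gene's stability is the sample SD of its deviation from the
    per-sample panel mean Cq; genes that track the panel consensus get
    low values.
    """
    k, n = cq.shape
    if k < 3:
        raise RefstabError("normfinder requires >= 3 genes")
    if n < 3:
        raise RefstabError("normfinder requires >= 3 samples")
    z = cq.values - cq.values.mean(axis=0, keepdims=True)
    stability = z.std(axis=1, ddof=1)
    rank = sps.rankdata(stability, method="average")
    return MethodResult("normfinder", list(cq.gene_ids), stability, rank)


def bestkeeper(cq: CqMatrix) -> tuple[MethodResult, pd.DataFrame]:
    """BestKeeper descriptives, index correlation, and SD-based ranking.

    Per gene over samples: geometric and arithmetic mean Cq, min, max,
    SD (mean absolute deviation from the geometric mean), CV% = 100 *
    SD / geometric mean, Pearson r (two-sided p) against the BestKeeper
    index — the per-sample geometric mean Cq of all candidates — and an
    ``unstable`` flag at SD > 1 cycle. Ranks ascend in SD.
    """
    k, n = cq.shape
    if k < 2:
        raise RefstabError("bestkeeper requires >= 2 genes")
    x = cq.values
    geo = np.exp(np.log(x).mean(axis=1))
    sd = np.abs(x - geo[:, None]).mean(axis=1)
    index = np.exp(np.log(x).mean(axis=0))  # per-sample geometric mean
    r = np.empty(k)
    p = np.empty(k)
    for gi in range(k):
        if np.ptp(x[gi]) == 0 or np.ptp(index) == 0:
            r[gi], p[gi] = np.nan, np.nan
        else:
            r[gi], p[gi] = sps.pearsonr(x[gi], index)
    table = pd.DataFrame(
        {
            "gene_id": cq.gene_ids,
            "geo_mean_cq": geo,
            "arith_mean_cq": x.mean(axis=1),
            "min_cq": x.min(axis=1),
            "max_cq": x.max(axis=1),
            "sd_cq": sd,
            "cv_pct": 100.0 * sd / geo,
            "r_vs_index": r,
            "p_vs_index": p,
            "unstable": sd > 1.0,
        }
    )
    rank = sps.rankdata(sd, method="average")
    return MethodResult("bestkeeper", list(cq.gene_ids), sd, rank), table


def delta_ct(cq: CqMatrix) -> MethodResult:
    """Comparative ΔCt stability: mean pairwise SD of Cq differences."""
    k, n = cq.shape
    if k < 2:
        raise RefstabError("delta_ct requires >= 2 genes")
    v = _pairwise_logratio_sd(cq.values)  # SD of Cq_j - Cq_k per pair
    stability = v.sum(axis=1) / (k - 1)
    rank = sps.rankdata(stability, method="average")
    return MethodResult("delta_ct", list(cq.gene_ids), stability, rank)


def aggregate_ranks(
    results: list[MethodResult], subset_label: str = "combined"
) -> StabilityReport:
    """Comprehensive ranking: geometric mean of the per-method ranks.

    All results must cover the same gene set; the score depends only on
    ranks, so it is invariant to monotone transforms of any method's
    stability values. Score ties receive average comprehensive ranks.
    """
    if not results:
        raise RefstabError("no method results to aggregate")
    gene_ids = list(results[0].gene_ids)
    for res in results[1:]:
        if sorted(res.gene_ids) != sorted(gene_ids):
            raise RefstabError("method results cover different gene sets")
    ranks = np.vstack(
        [
            np.asarray(res.rank)[[res.gene_ids.index(g) for g in gene_ids]]
            for res in results
        ]
    )
    score = np.exp(np.log(ranks).mean(axis=0))
    comp_rank = sps.rankdata(score, method="average")
    return StabilityReport(
        gene_ids=gene_ids,
        methods={res.method: res for res in results},
        comprehensive_score=score,
        comprehensive_rank=comp_rank,
        subset_label=subset_label,
    )


def stability_by_subset(cq: CqMatrix, subset: str = "combined") -> StabilityReport:
    """Run all four methods plus aggregation on a stress subset.

    ``temperature`` keeps treatments {C, HT, LT}, ``salinity`` {C, HS,
    LS}, ``combined`` all samples.
    """
    if subset not in SUBSET_TREATMENTS:
        raise RefstabError(
            f"unknown subset {subset!r}; expected one of {sorted(SUBSET_TREATMENTS)}"
        )
    sub = cq.subset_samples(SUBSET_TREATMENTS[subset])
    if sub.shape[1] < 3:
        raise RefstabError(f"subset {subset!r} has fewer than 3 samples")
    q = cq_to_quantity(sub)
    gn, trajectory = genorm(q)
    nf = normfinder(sub)
    bk, bk_table = bestkeeper(sub)
    dc = delta_ct(sub)
    report = aggregate_ranks([gn, nf, bk, dc], subset_label=subset)
    ranking = [g for g in trajectory[::-1]]
    report.pairwise_variation = genorm_pairwise_variation(q, ranking)
    report.bestkeeper_table = bk_table
    report.genorm_trajectory = trajectory
    return report
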