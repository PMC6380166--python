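"""Gene-architecture trend analysis for expression level and stability.

Relates per-gene expression summaries (mean FPKM or CV) to six
architecture variables (GC content, transcript length, exon count, CDS
length, transcript count, gene length): Pearson correlations, ordered
binning of genes into equal-as-possible groups (42 in the motivating
design), and Mann–Whitney U tests between group pairs. The headline
pattern this detects is compactness of highly expressed genes — the
top-expression group having the shortest transcripts and CDS.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import RefstabError

STRUCTURE_VARIABLES = (
    "gc_content",
    "transcript_length",
    "exon_count",
    "cds_length",
    "transcript_count",
    "gene_length",
)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment r with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise RefstabError("pearson_correlation needs equal-length vectors, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise RefstabError("pearson_correlation undefined at zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class OrderedGrouping:
    """Contiguous ordered grouping of genes by a ranking key.

    Group 1 holds the largest key values; sizes differ by at most one.
    """

    assignments: pd.Series  # gene_id -> group index 1..G
    key: str
    n_groups: int

    def group_members(self, group: int) -> list[str]:
        return list(self.assignments.index[self.assignments == group])

    def sizes(self) -> list[int]:
        return [int((self.assignments == g).sum()) for g in range(1, self.n_groups + 1)]


def bin_by_order(
    values: pd.Series, n_groups: int, key: str = "value"
) -> OrderedGrouping:
    """Split genes into ``n_groups`` contiguous groups by descending value.

    With ``n = q * G + r`` genes, the first ``r`` groups get ``q + 1``
    genes and the rest ``q``. Ties are broken by gene id for
    reproducibility.
    """
    if n_groups <= 0:
        raise RefstabError("n_groups must be positive")
    if n_groups > len(values):
        raise RefstabError("more groups than genes")
    order = (
        values.rename("v")
        .rename_axis("gene_id")
        .reset_index()
        .sort_values(["v", "gene_id"], ascending=[False, True], kind="mergesort")
    )
    n = len(order)
    q, r = divmod(n, n_groups)
    sizes = [q + 1] * r + [q] * (n_groups - r)
    groups = np.repeat(np.arange(1, n_groups + 1), sizes)
    assignments = pd.Series(groups, index=order["gene_id"].to_numpy(), name="group")
    assignments.index.name = "gene_id"
    return OrderedGrouping(assignments=assignments, key=key, n_groups=n_groups)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann–Whitney U (of the first sample) with a two-sided p.

    Exact p by enumeration when min(n) <= 8 and there are no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise RefstabError("mann_whitney_u needs nonempty samples")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def group_trend_report(
    grouping: OrderedGrouping,
    structure: pd.DataFrame,
    variables: Sequence[str] = STRUCTURE_VARIABLES,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Mann–Whitney tests per structure variable, plus a summary.

    The summary flags variables where group 1 (largest key values)
    differs from every other group in one consistent direction — e.g.
    the highest-expression group having systematically shorter
    transcripts. ``flagged`` requires a consistent median direction
    against all other groups and at least half of the group-1
    comparisons significant at ``alpha``.
    """
    if structure["gene_id"].duplicated().any():
        raise RefstabError("duplicate gene ids in structure table")
    struct = structure.set_index("gene_id")
    missing = set(grouping.assignments.index) - set(struct.index)
    if missing:
        raise RefstabError(f"structure table missing genes: {sorted(missing)[:5]} ...")
    members = {
        g: grouping.group_members(g) for g in range(1, grouping.n_groups + 1)
    }
    for g, ids in members.items():
        if not ids:
            raise RefstabError(f"group {g} is empty")

    rows = []
    for var in variables:
        series = struct[var]
        vals = {g: series.loc[ids].to_numpy(dtype=float) for g, ids in members.items()}
        for ga, gb in combinations(range(1, grouping.n_groups + 1), 2):
            u, p = mann_whitney_u(vals[ga], vals[gb])
            rows.append(
                {"variable": var, "group_a": ga, "group_b": gb, "u": u, "p": p}
            )
    pairwise = pd.DataFrame(rows, columns=["variable", "group_a", "group_b", "u", "p"])

    summary_rows = []
    for var in variables:
        series = struct[var]
        g1 = series.loc[members[1]].to_numpy(dtype=float)
        rest_ids = [
            gid for g in range(2, grouping.n_groups + 1) for gid in members[g]
        ]
        rest = series.loc[rest_ids].to_numpy(dtype=float) if rest_ids else np.array([])
        sub = pairwise[(pairwise["variable"] == var) & (pairwise["group_a"] == 1)]
        signs = []
        n_sig = 0
        for _, row in sub.iterrows():
            other = series.loc[members[int(row["group_b"])]].to_numpy(dtype=float)
            diff = np.median(g1) - np.median(other)
            if diff != 0:
                signs.append(np.sign(diff))
            if row["p"] < alpha:
                n_sig += 1
        consistent = len(set(signs)) <= 1 and bool(signs)
        frac_sig = n_sig / len(sub) if len(sub) else 0.0
        summary_rows.append(
            {
                "variable": var,
                "group1_median": float(np.median(g1)),
                "rest_median": float(np.median(rest)) if rest.size else float("nan"),
                "direction": (
                    "lower"
                    if rest.size and np.median(g1) < np.median(rest)
                    else "higher"
                    if rest.size and np.median(g1) > np.median(rest)
                    else "equal"
                ),
                "frac_significant_vs_group1": frac_sig,
                "flagged": bool(consistent and frac_sig >= 0.5),
            }
        )
    summary = pd.DataFrame(summary_rows)
    return pairwise, summary
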