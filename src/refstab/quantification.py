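"""Standard-curve efficiency and ΔΔCq relative quantification.

Amplification efficiency is estimated from a serial-dilution standard
curve as ``E = 10 ** (-1/slope)`` where the slope comes from ordinary
least squares of Cq on log10 template input (a perfect doubling gives
slope -3.3219 cycles per decade).

Target-gene expression is quantified against a reference gene with the
ΔΔCq scheme: per replicate ``ΔCq = Cq_target - Cq_reference``; per
treated replicate ``ΔΔCq = ΔCq - mean(ΔCq of the time-matched control
replicates)``; ``fold = base ** (-ΔΔCq)`` averaged over replicates with
the control cell fixed at 1. A positive mean ΔΔCq therefore means
down-regulation, a negative one up-regulation. Significance per
treatment x time cell is a two-sided Welch t-test of treated vs control
ΔCq replicates (replicate n is small and variance homogeneity is
unverifiable, so the unequal-variance test is the default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CqMatrix, RefstabError, SampleDesign


@dataclass
class StandardCurve:
    """OLS fit of a dilution series and the efficiency it implies."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    points: list[tuple[float, float]]
    valid: bool

    @property
    def efficiency_pct(self) -> float:
        """Efficiency expressed as percent of perfect doubling increment."""
        return 100.0 * (self.efficiency - 1.0)


@dataclass
class FoldChangeResult:
    """ΔΔCq outcome for one treatment x time cell against one reference."""

    treatment: str
    time_h: int
    reference: str
    ddcq: float
    fold_change: float
    direction: str  # up / down / unchanged
    p_value: float
    significant: bool


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit Cq on log10 input and derive E = 10^(-1/slope).

    Requires >= 3 distinct dilution points. A non-negative slope cannot
    come from a valid dilution series; the curve is returned with
    ``valid=False``, ``efficiency=nan`` and a warning.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len({x for x, _ in pts}) < 3:
        raise RefstabError("standard curve needs >= 3 distinct dilution points")
    xs = np.array([x for x, _ in pts])
    ys = np.array([y for _, y in pts])
    fit = sps.linregress(xs, ys)
    slope = float(fit.slope)
    if slope >= 0:
        warnings.warn(
            "standard-curve slope is non-negative; efficiency is invalid",
            RuntimeWarning,
            stacklevel=2,
        )
        eff, valid = float("nan"), False
    else:
        eff, valid = 10.0 ** (-1.0 / slope), True
    return StandardCurve(
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=eff,
        points=pts,
        valid=valid,
    )


def fold_significance(
    treated_dcq: Sequence[float],
    control_dcq: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Two-sided Welch t-test on ΔCq replicates; flag at p < alpha."""
    a = np.asarray(treated_dcq, dtype=float)
    b = np.asarray(control_dcq, dtype=float)
    if a.size < 2 or b.size < 2:
        raise RefstabError("fold_significance needs >= 2 replicates per side")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if math.isclose(a.mean(), b.mean()) else 0.0
    else:
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    return p, bool(p < alpha)


def _cells(design: Sequence[SampleDesign]) -> list[tuple[str, int]]:
    seen: list[tuple[str, int]] = []
    for d in design:
        cell = (d.treatment, d.time_h)
        if cell not in seen:
            seen.append(cell)
    return seen


def delta_delta_cq(
    cq: CqMatrix,
    target: str,
    reference: str,
    control_treatment: str = "C",
    base: float = 2.0,
    alpha: float = 0.05,
    efficiency_corrected: bool = False,
) -> list[FoldChangeResult]:
    """ΔΔCq fold changes of ``target`` vs ``reference`` per cell.

    With ``efficiency_corrected=True`` the per-gene measured
    efficiencies replace the common ``base`` (Pfaffl-style
    ``E_t^(-ΔCq_t) / E_r^(-ΔCq_r)`` against the time-matched control
    means). Control cells report ΔΔCq 0 and fold 1 by construction.
    """
    t_row = cq.row(target)
    r_row = cq.row(reference)
    dcq = t_row - r_row
    cell_idx: dict[tuple[str, int], list[int]] = {}
    for i, d in enumerate(cq.design):
        cell_idx.setdefault((d.treatment, d.time_h), []).append(i)

    results: list[FoldChangeResult] = []
    for treatment, time_h in _cells(cq.design):
        ctrl = cell_idx.get((control_treatment, time_h))
        if ctrl is None or len(ctrl) < 2:
            raise RefstabError(
                f"missing/underpowered control cell ({control_treatment}, {time_h} h)"
            )
        if treatment == control_treatment:
            results.append(
                FoldChangeResult(
                    treatment, time_h, reference, 0.0, 1.0, "unchanged", 1.0, False
                )
            )
            continue
        idx = cell_idx[(treatment, time_h)]
        if len(idx) < 2:
            raise RefstabError(
                f"cell ({treatment}, {time_h} h) has fewer than 2 replicates"
            )
        ddcq_reps = dcq[idx] - dcq[ctrl].mean()
        if efficiency_corrected:
            et = cq.efficiency[target]
            er = cq.efficiency[reference]
            dd_t = t_row[idx] - t_row[ctrl].mean()
            dd_r = r_row[idx] - r_row[ctrl].mean()
            folds = et ** (-dd_t) / er ** (-dd_r)
        else:
            folds = base ** (-ddcq_reps)
        mean_ddcq = float(ddcq_reps.mean())
        p, sig = fold_significance(dcq[idx], dcq[ctrl], alpha=alpha)
        if math.isclose(mean_ddcq, 0.0, abs_tol=1e-12):
            direction = "unchanged"
        elif mean_ddcq < 0:
            direction = "up"
        else:
            direction = "down"
        results.append(
            FoldChangeResult(
                treatment,
                time_h,
                reference,
                mean_ddcq,
                float(folds.mean()),
                direction,
                p,
                sig,
            )
        )
    return results


def fold_change_frame(results: Sequence[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "treatment": [r.treatment for r in results],
            "time_h": [r.time_h for r in results],
            "reference": [r.reference for r in results],
            "ddcq": [r.ddcq for r in results],
            "fold_change": [r.fold_change for r in results],
            "direction": [r.direction for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


def normalizer_comparison(
    cq: CqMatrix,
    target: str,
    references: Sequence[str],
    control_treatment: str = "C",
    base: float = 2.0,
    alpha: float = 0.05,
    efficiency_corrected: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Side-by-side ΔΔCq tables for several candidate normalizers.

    Returns the stacked fold-change table and a disagreement summary
    listing every non-control cell where the chosen reference changes
    the called direction or the significance flag — the practical cost
    of normalizing with an unstable gene.
    """
    references = list(references)
    missing = [g for g in references if g not in cq.gene_ids]
    if missing:
        raise RefstabError(f"references not in Cq table: {missing}")
    tables = [
        fold_change_frame(
            delta_delta_cq(
                cq,
                target,
                ref,
                control_treatment=control_treatment,
                base=base,
                alpha=alpha,
                efficiency_corrected=efficiency_corrected,
            )
        )
        for ref in references
    ]
    combined = pd.concat(tables, ignore_index=True)
    rows = []
    noncontrol = combined[combined["treatment"] != control_treatment]
    for (treatment, time_h), grp in noncontrol.groupby(["treatment", "time_h"]):
        directions = grp["direction"].unique()
        sigs = grp["significant"].unique()
        if len(directions) > 1 or len(sigs) > 1:
            rows.append(
                {
                    "treatment": treatment,
                    "time_h": time_h,
                    "directions": ",".join(
                        f"{r}:{d}" for r, d in zip(grp["reference"], grp["direction"])
                    ),
                    "significance": ",".join(
                        f"{r}:{s}" for r, s in zip(grp["reference"], grp["significant"])
                    ),
                    "direction_conflict": len(directions) > 1,
                    "significance_conflict": len(sigs) > 1,
                }
            )
    disagreements = pd.DataFrame(
        rows,
        columns=[
            "treatment",
            "time_h",
            "directions",
            "significance",
            "direction_conflict",
            "significance_conflict",
        ],
    )
    return combined, disagreements
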