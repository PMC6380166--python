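"""Synthetic data generator for the factorial stress-expression design.

Emulates the study conditions every downstream stage is tested against:
a 5 treatment x 3 time x 3 replicate sampling design, FPKM expression
with gene-wise log-normal biological noise and multiplicative treatment
effects, RT-qPCR Cq values linear in log expression with gene-wise
amplification efficiencies, a BioMart-style gene-structure table, and
standard-curve dilution series.

Noise model
-----------
Expression for gene *g* in sample *s* is drawn log-normally around
``baseline_fpkm * effect`` with log-scale spread
``sigma = sqrt(ln(1 + cv^2))`` so the distributional CV equals
``noise_cv`` exactly and values stay positive. Cq noise is additive
Gaussian on the cycle scale, independent per well. Random streams are
split per gene from the master seed, so adding a gene never perturbs the
values of the others.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_EFFICIENCY,
    N_REPLICATES,
    RefstabError,
    TIMES_H,
    TREATMENTS,
    CqMatrix,
    ExpressionMatrix,
    GeneSpec,
    SampleDesign,
)

DEFAULT_INTERCEPT = 35.0  # Cq of one relative template unit at E cycles/fold

# Stream labels so expression / Cq / structure draws never collide.
_STREAM_EXPR = 0
_STREAM_CQ = 1
_STREAM_STRUCT = 2
_STREAM_DILUTION = 3


def generate_design(
    treatments: Sequence[str] = TREATMENTS,
    times: Sequence[int] = TIMES_H,
    replicates: int = N_REPLICATES,
) -> list[SampleDesign]:
    """Full factorial sample design, treatment-major then time then replicate.

    The default arguments reproduce the 5 x 3 x 3 = 45-sample layout.
    """
    treatments = list(treatments)
    times = list(times)
    if not treatments or not times or replicates < 1:
        raise RefstabError("treatments, times and replicates must be nonempty/positive")
    design = []
    for t in treatments:
        for h in times:
            for r in range(1, replicates + 1):
                design.append(
                    SampleDesign(
                        sample_id=f"{t}_{h}h_r{r}", treatment=t, time_h=h, replicate=r
                    )
                )
    return design


def _gene_rng(seed: int, stream: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream, gene_index])


def simulate_expression(
    specs: Sequence[GeneSpec],
    design: Sequence[SampleDesign],
    seed: int,
) -> ExpressionMatrix:
    """Draw an FPKM matrix from gene specs over a design.

    Gene *g*, sample *s* is log-normal with mean
    ``baseline_fpkm[g] * effect_map[g][(treatment, time)]`` (effect 1
    where absent) and CV ``noise_cv[g]``. Deterministic for a given seed;
    a gene's draws depend only on the seed and its position in ``specs``.
    """
    specs = list(specs)
    if not specs:
        raise RefstabError("specs must be nonempty")
    design = list(design)
    n = len(design)
    values = np.empty((len(specs), n))
    for gi, spec in enumerate(specs):
        means = np.array(
            [
                spec.baseline_fpkm * spec.effect_map.get((d.treatment, d.time_h), 1.0)
                for d in design
            ]
        )
        if spec.noise_cv == 0:
            values[gi] = means
            continue
        sigma = math.sqrt(math.log1p(spec.noise_cv**2))
        mu = np.log(means) - 0.5 * sigma**2
        rng = _gene_rng(seed, _STREAM_EXPR, gi)
        values[gi] = np.exp(rng.normal(mu, sigma))
    return ExpressionMatrix([s.gene_id for s in specs], design, values)


def cq_from_expression(
    expr: ExpressionMatrix,
    specs: Sequence[GeneSpec],
    intercept: float = DEFAULT_INTERCEPT,
    cq_noise_sd: float = 0.0,
    seed: int = 0,
) -> CqMatrix:
    """Invert the standard-curve relation to produce a Cq matrix.

    ``Cq[g,s] = intercept - log(expr[g,s]) / log(E_g) + N(0, cq_noise_sd)``,
    so doubling the template lowers Cq by one cycle at E = 2.
    """
    if cq_noise_sd < 0:
        raise RefstabError("cq_noise_sd must be >= 0")
    eff = {s.gene_id: s.efficiency for s in specs}
    missing = sorted(set(expr.gene_ids) - set(eff))
    if missing:
        raise RefstabError(f"no GeneSpec (efficiency) for genes: {missing}")
    cq = np.empty_like(expr.values)
    for gi, gene in enumerate(expr.gene_ids):
        row = expr.values[gi]
        zero = np.flatnonzero(row <= 0)
        if zero.size:
            sid = expr.sample_ids[zero[0]]
            raise RefstabError(
                f"expression is zero for gene {gene!r}, sample {sid!r}; "
                "Cq is undefined"
            )
        cq[gi] = intercept - np.log(row) / math.log(eff[gene])
        if cq_noise_sd > 0:
            rng = _gene_rng(seed, _STREAM_CQ, gi)
            cq[gi] += rng.normal(0.0, cq_noise_sd, size=row.size)
    return CqMatrix(expr.gene_ids, expr.design, cq, eff)


def simulate_structure_table(
    gene_ids: Sequence[str],
    seed: int,
    mean_expression: Sequence[float] | None = None,
    length_association: float = 0.0,
) -> pd.DataFrame:
    """BioMart-style gene-structure table with a tunable expression-length link.

    Columns: ``gene_id, gc_content, transcript_length, exon_count,
    cds_length, transcript_count, gene_length``. When
    ``length_association`` is negative, genes with higher
    ``mean_expression`` receive systematically shorter transcript, CDS
    and gene lengths (correlation of that magnitude on the log scale);
    at 0 structure is independent of expression.
    """
    gene_ids = list(gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        raise RefstabError("gene ids must be unique")
    if not -1.0 <= length_association <= 1.0:
        raise RefstabError("length_association must be in [-1, 1]")
    n = len(gene_ids)
    rng = np.random.default_rng([int(seed), _STREAM_STRUCT])
    if mean_expression is None:
        z = np.zeros(n)
    else:
        expr = np.asarray(mean_expression, dtype=float)
        if expr.shape != (n,):
            raise RefstabError("mean_expression must match gene_ids length")
        logx = np.log10(expr)
        sd = logx.std()
        z = (logx - logx.mean()) / sd if sd > 0 else np.zeros(n)

    a = length_association
    latent = a * z + math.sqrt(max(0.0, 1 - a * a)) * rng.standard_normal(n)
    # log-normal transcript lengths around ~1.5 kb, sd ~0.45 on ln scale
    transcript_length = np.rint(np.exp(math.log(1500.0) + 0.45 * latent)).astype(int)
    transcript_length = np.maximum(transcript_length, 150)
    cds_fraction = rng.beta(8, 3, size=n)  # typically 60-85% coding
    cds_length = np.maximum((transcript_length * cds_fraction).astype(int), 90)
    intron_factor = 1.0 + rng.gamma(shape=1.5, scale=1.2, size=n)
    gene_length = np.rint(transcript_length * intron_factor).astype(int)
    exon_count = 1 + rng.poisson(np.clip(transcript_length / 400.0, 0.5, 30.0))
    transcript_count = 1 + rng.poisson(0.4, size=n)
    gc_content = rng.beta(30, 45, size=n)  # ~0.40 +/- 0.06, bounded in (0,1)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gc_content": gc_content,
            "transcript_length": transcript_length,
            "exon_count": exon_count,
            "cds_length": cds_length,
            "transcript_count": transcript_count,
            "gene_length": gene_length,
        }
    )


def simulate_dilution_series(
    efficiency: float = DEFAULT_EFFICIENCY,
    intercept: float = DEFAULT_INTERCEPT,
    n_points: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """10-fold serial-dilution standard curve: (log10 input, Cq) points.

    Cq follows the line ``intercept + slope * log10(input)`` with
    ``slope = -ln(10)/ln(E)`` (−3.3219 cycles per decade at E = 2), plus
    optional Gaussian cycle noise.
    """
    if efficiency <= 1:
        raise RefstabError("efficiency must be > 1")
    if n_points < 2:
        raise RefstabError("need at least 2 dilution points")
    slope = -math.log(10.0) / math.log(efficiency)
    xs = -np.arange(n_points, dtype=float)  # 0, -1, -2, ... decades
    cq = intercept + slope * xs
    if noise_sd > 0:
        rng = np.random.default_rng([int(seed), _STREAM_DILUTION])
        cq = cq + rng.normal(0.0, noise_sd, size=n_points)
    return list(zip(xs.tolist(), cq.tolist()))


def default_scenario() -> list[GeneSpec]:
    """The default 14-gene ground-truth panel.

    Mirrors the RT-qPCR candidate panel size: 3 designated stable genes
    (noise CV 3%), 8 stress-responsive genes with 2-4-fold effects in
    specific treatment x time cells, and 3 noisy genes (noise CV 50%).
    Baselines span the moderate-to-high FPKM range typical of candidate
    reference genes (~16-1400 FPKM); efficiencies sit in the measured
    1.94-2.07 band.
    """
    specs: list[GeneSpec] = [
        GeneSpec("STB1", 436.0, "stable", 0.03, {}, 1.98),
        GeneSpec("STB2", 204.0, "stable", 0.03, {}, 2.02),
        GeneSpec("STB3", 70.0, "stable", 0.03, {}, 2.00),
    ]
    responsive = [
        ("RSP1", 122.0, {("HT", 24): 4.0, ("HT", 48): 2.5}, 2.06),
        ("RSP2", 56.0, {("LT", 24): 0.4, ("LT", 48): 0.35}, 2.07),
        ("RSP3", 159.0, {("HS", 1): 2.0, ("HS", 24): 3.0}, 1.98),
        ("RSP4", 95.0, {("LS", 24): 0.5, ("LS", 48): 0.4}, 2.01),
        ("RSP5", 141.0, {("HT", 1): 2.0, ("LT", 1): 2.0}, 1.97),
        ("RSP6", 470.0, {("HS", 48): 2.5, ("LS", 48): 2.5}, 1.99),
        ("RSP7", 25.0, {("HT", 48): 3.0, ("HS", 48): 0.5}, 1.94),
        ("RSP8", 16.0, {("LT", 24): 2.0, ("LS", 1): 2.0}, 1.99),
    ]
    for gid, base, eff_map, e in responsive:
        specs.append(GeneSpec(gid, base, "responsive", 0.10, eff_map, e))
    specs += [
        GeneSpec("NSY1", 504.0, "noisy", 0.5, {}, 2.00),
        GeneSpec("NSY2", 1420.0, "noisy", 0.5, {}, 1.98),
        GeneSpec("NSY3", 41.0, "noisy", 0.5, {}, 2.11),
    ]
    return specs
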