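"""Core data containers for the reference-gene selection pipeline.

The experimental design emulated throughout the package is a factorial
stress-exposure study on the invasive ascidian *Ciona savignyi*: five
treatments (control ``C``, high/low temperature ``HT``/``LT``, high/low
salinity ``HS``/``LS``) sampled at 1, 24 and 48 h with three biological
replicates, i.e. 45 samples. Expression is carried either as FPKM
(RNA-Seq) in an :class:`ExpressionMatrix` or as quantification cycles
(RT-qPCR) in a :class:`CqMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TREATMENTS: tuple[str, ...] = ("C", "HT", "LT", "HS", "LS")
TIMES_H: tuple[int, ...] = (1, 24, 48)
N_REPLICATES: int = 3

#: Treatment subsets used for stress-specific stability analysis.
SUBSET_TREATMENTS: dict[str, tuple[str, ...]] = {
    "temperature": ("C", "HT", "LT"),
    "salinity": ("C", "HS", "LS"),
    "combined": TREATMENTS,
}

DEFAULT_EFFICIENCY: float = 2.0  # perfect doubling per PCR cycle


class RefstabError(ValueError):
    """Base class for domain errors raised by this package."""


class ParseError(RefstabError):
    """Raised when an input table cannot be parsed or validated."""


@dataclass(frozen=True)
class SampleDesign:
    """One sample's annotation in the factorial stress design."""

    sample_id: str
    treatment: str
    time_h: int
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise RefstabError(
                f"replicate must be >= 1, got {self.replicate} for {self.sample_id}"
            )


def validate_design(design: Sequence[SampleDesign]) -> None:
    """Check sample-id uniqueness; raise :class:`RefstabError` otherwise."""
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise RefstabError(f"duplicate sample ids in design: {dup}")


def design_frame(design: Sequence[SampleDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in design],
            "treatment": [d.treatment for d in design],
            "time_h": [d.time_h for d in design],
            "replicate": [d.replicate for d in design],
        }
    )


@dataclass
class GeneSpec:
    """Ground-truth parameters of one simulated gene.

    Parameters
    ----------
    baseline_fpkm
        Mean FPKM in the control condition; must be positive.
    stability_class
        ``stable`` (no treatment effect, low noise), ``responsive``
        (multiplicative treatment effects) or ``noisy`` (high biological
        variance).
    noise_cv
        Target coefficient of variation of the log-normal biological
        noise, as a fraction (0.10 = 10%).
    effect_map
        ``(treatment, time_h) -> fold`` multiplicative effects; empty for
        stable genes.
    efficiency
        PCR amplification efficiency E (fold product per cycle); 2.0 is
        perfect doubling.
    """

    gene_id: str
    baseline_fpkm: float
    stability_class: str = "stable"
    noise_cv: float = 0.0
    effect_map: dict[tuple[str, int], float] = field(default_factory=dict)
    efficiency: float = DEFAULT_EFFICIENCY

    def __post_init__(self) -> None:
        if self.baseline_fpkm <= 0:
            raise RefstabError(f"{self.gene_id}: baseline_fpkm must be > 0")
        if self.noise_cv < 0:
            raise RefstabError(f"{self.gene_id}: noise_cv must be >= 0")
        if self.efficiency <= 1:
            raise RefstabError(f"{self.gene_id}: efficiency must be > 1")
        if self.stability_class not in ("stable", "responsive", "noisy"):
            raise RefstabError(
                f"{self.gene_id}: unknown stability_class {self.stability_class!r}"
            )
        if self.stability_class == "stable":
            if self.effect_map:
                raise RefstabError(f"{self.gene_id}: stable genes have no effects")
            if self.noise_cv > 0.16:
                raise RefstabError(
                    f"{self.gene_id}: stable genes require noise_cv <= 0.16"
                )

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "baseline_fpkm": self.baseline_fpkm,
            "stability_class": self.stability_class,
            "noise_cv": self.noise_cv,
            "effect_map": {f"{t}:{h}": v for (t, h), v in self.effect_map.items()},
            "efficiency": self.efficiency,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneSpec":
        eff_map = {}
        for key, v in dict(d.get("effect_map", {})).items():
            t, h = key.split(":")
            eff_map[(t, int(h))] = float(v)
        return cls(
            gene_id=d["gene_id"],
            baseline_fpkm=float(d["baseline_fpkm"]),
            stability_class=d.get("stability_class", "stable"),
            noise_cv=float(d.get("noise_cv", 0.0)),
            effect_map=eff_map,
            efficiency=float(d.get("efficiency", DEFAULT_EFFICIENCY)),
        )


class _GeneSampleGrid:
    """Shared validation for gene x sample matrices."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        design: Sequence[SampleDesign],
        values: np.ndarray,
    ) -> None:
        gene_ids = list(gene_ids)
        design = list(design)
        values = np.asarray(values, dtype=float)
        if len(set(gene_ids)) != len(gene_ids):
            raise RefstabError("duplicate gene ids")
        validate_design(design)
        if values.shape != (len(gene_ids), len(design)):
            raise RefstabError(
                f"value grid shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(design)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise RefstabError("matrix contains missing or non-finite cells")
        self.gene_ids = gene_ids
        self.design = design
        self.values = values

    @property
    def sample_ids(self) -> list[str]:
        return [d.sample_id for d in self.design]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise RefstabError(f"gene {gene_id!r} not in matrix") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )


class ExpressionMatrix(_GeneSampleGrid):
    """Gene x sample FPKM matrix bound to a sample design.

    All values must be finite and non-negative.
    """

    def __init__(self, gene_ids, design, values) -> None:
        super().__init__(gene_ids, design, values)
        if np.any(self.values < 0):
            raise RefstabError("FPKM values must be >= 0")

    def subset_genes(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = list(keep)
        idx = [self.gene_index(g) for g in keep]
        return ExpressionMatrix(keep, self.design, self.values[idx])


class CqMatrix(_GeneSampleGrid):
    """Gene x sample quantification-cycle matrix with per-gene efficiency.

    Cq values must be finite and positive; every gene carries an
    amplification efficiency E (fold per cycle, default 2.0).
    """

    def __init__(self, gene_ids, design, cq, efficiency=None) -> None:
        super().__init__(gene_ids, design, cq)
        if np.any(self.values <= 0):
            raise RefstabError("Cq values must be > 0")
        eff = dict(efficiency or {})
        unknown = sorted(set(eff) - set(self.gene_ids))
        if unknown:
            raise RefstabError(f"efficiency given for unknown genes: {unknown}")
        self.efficiency = {
            g: float(eff.get(g, DEFAULT_EFFICIENCY)) for g in self.gene_ids
        }
        bad = [g for g, e in self.efficiency.items() if not e > 0]
        if bad:
            raise RefstabError(f"non-positive efficiency for genes: {bad}")

    @property
    def cq(self) -> np.ndarray:
        return self.values

    def efficiency_array(self) -> np.ndarray:
        return np.array([self.efficiency[g] for g in self.gene_ids])

    def subset_genes(self, keep: Iterable[str]) -> "CqMatrix":
        keep = list(keep)
        idx = [self.gene_index(g) for g in keep]
        return CqMatrix(
            keep, self.design, self.values[idx],
            {g: self.efficiency[g] for g in keep},
        )

    def subset_samples(self, treatments: Iterable[str]) -> "CqMatrix":
        keep = set(treatments)
        cols = [i for i, d in enumerate(self.design) if d.treatment in keep]
        if not cols:
            raise RefstabError(f"no samples with treatment in {sorted(keep)}")
        design = [self.design[i] for i in cols]
        return CqMatrix(self.gene_ids, design, self.values[:, cols], self.efficiency)
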