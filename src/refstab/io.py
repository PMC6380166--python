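"""Readers, writers, run configuration and packaged reference tables.

The canonical on-disk dialect is TSV (UTF-8, ``.`` decimal): gene x
sample matrices with ``gene_id`` as the first column, a design table
(``sample_id, treatment, time_h, replicate``), an efficiency table
(``gene, efficiency``), a BioMart-style structure table, and a
standard-curve table (``log10_input, cq``). CSV is accepted on read via
``sep=','``. Every file the package writes is re-parseable by these
readers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CqMatrix,
    ExpressionMatrix,
    GeneSpec,
    ParseError,
    SampleDesign,
    design_frame,
)
from .structure import STRUCTURE_VARIABLES

logger = logging.getLogger("refstab")


# ---------------------------------------------------------------- config


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study conventions."""

    min_fpkm: float = 1.0
    cv_threshold_pct: float = 20.0
    shortlist_threshold_pct: float = 16.0
    subset: str = "combined"
    fold_base: float = 2.0
    alpha: float = 0.05
    n_groups: int = 42
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_threshold_pct <= 0 or self.shortlist_threshold_pct <= 0:
            raise ParseError("CV thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ParseError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat ``key = value`` text config mirroring the CLI flags."""
        kwargs: dict = {}
        casts = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in cls.__dataclass_fields__:  # type: ignore[attr-defined]
                raise ParseError(f"{path}:{ln}: unknown config key {key!r}")
            typ = casts[key]
            if typ in ("int", int):
                kwargs[key] = int(val)
            elif typ in ("float", float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


# ---------------------------------------------------------------- helpers


def _read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc


def _numeric(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[converted.isna() & out[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"{path}: non-numeric value {out.loc[bad[0], col]!r} in column "
                f"{col!r} at line {bad[0] + 2}"
            )
        if converted.isna().any():
            raise ParseError(f"{path}: missing value in column {col!r}")
        out[col] = converted
    return out


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------- design


def read_design(path: str | Path, sep: str = "\t") -> list[SampleDesign]:
    df = _read_table(path, sep)
    _require_columns(df, ["sample_id", "treatment", "time_h", "replicate"], path)
    df = _numeric(df, ["time_h", "replicate"], path)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample ids {dup}")
    return [
        SampleDesign(
            sample_id=row.sample_id,
            treatment=row.treatment,
            time_h=int(row.time_h),
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def write_design_tsv(design: Sequence[SampleDesign], path: str | Path) -> None:
    design_frame(design).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- matrices


def _read_matrix(path: str | Path, sep: str) -> tuple[list[str], list[str], np.ndarray]:
    # pandas silently renames duplicate columns, so check the raw header
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    raw_samples = header[1:]
    if len(set(raw_samples)) != len(raw_samples):
        dup = sorted({s for s in raw_samples if raw_samples.count(s) > 1})
        raise ParseError(f"{path}: duplicated sample column {dup}")
    df = _read_table(path, sep)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected gene_id column plus sample columns")
    gene_col = df.columns[0]
    sample_ids = list(df.columns[1:])
    if df[gene_col].duplicated().any():
        dup = df.loc[df[gene_col].duplicated(), gene_col].tolist()
        raise ParseError(f"{path}: duplicate gene ids {dup}")
    df = _numeric(df, sample_ids, path)
    return df[gene_col].tolist(), sample_ids, df[sample_ids].to_numpy(dtype=float)


def _align_design(
    sample_ids: list[str], design: Sequence[SampleDesign] | None, path
) -> tuple[list[SampleDesign], list[int]]:
    if design is None:
        # no metadata: treat each column as its own unreplicated sample
        return (
            [SampleDesign(s, "C", 1, i + 1) for i, s in enumerate(sample_ids)],
            list(range(len(sample_ids))),
        )
    by_id = {d.sample_id: d for d in design}
    missing = sorted(set(sample_ids) - set(by_id))
    if missing:
        raise ParseError(f"{path}: samples absent from design: {missing}")
    extra = sorted(set(by_id) - set(sample_ids))
    if extra:
        raise ParseError(f"{path}: design samples missing from matrix: {extra}")
    order = [d.sample_id for d in design]
    return list(design), [sample_ids.index(s) for s in order]


def read_expression_tsv(
    path: str | Path,
    design: Sequence[SampleDesign] | None = None,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a gene x sample FPKM matrix, reordered to the design."""
    genes, sample_ids, values = _read_matrix(path, sep)
    dsn, order = _align_design(sample_ids, design, path)
    return ExpressionMatrix(genes, dsn, values[:, order])


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t")


def read_efficiency(path: str | Path, sep: str = "\t") -> dict[str, float]:
    df = _read_table(path, sep)
    _require_columns(df, ["gene", "efficiency"], path)
    df = _numeric(df, ["efficiency"], path)
    if df["gene"].duplicated().any():
        raise ParseError(f"{path}: duplicate genes in efficiency table")
    return dict(zip(df["gene"], df["efficiency"].astype(float)))


def write_efficiency_tsv(efficiency: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(efficiency), "efficiency": list(efficiency.values())}
    ).to_csv(path, sep="\t", index=False)


def read_cq_table(
    path: str | Path,
    design: Sequence[SampleDesign] | None = None,
    efficiency: dict[str, float] | None = None,
    layout: str = "wide",
    sep: str = "\t",
) -> CqMatrix:
    """Read a Cq table in wide (genes x samples) or long (gene, sample, cq) layout."""
    if layout == "wide":
        genes, sample_ids, values = _read_matrix(path, sep)
    elif layout == "long":
        df = _read_table(path, sep)
        _require_columns(df, ["gene", "sample", "cq"], path)
        df = _numeric(df, ["cq"], path)
        if df.duplicated(["gene", "sample"]).any():
            raise ParseError(f"{path}: duplicate (gene, sample) rows")
        wide = df.pivot(index="gene", columns="sample", values="cq")
        if wide.isna().any().any():
            gene = wide.index[wide.isna().any(axis=1)][0]
            raise ParseError(f"{path}: incomplete long table (gene {gene!r})")
        genes = wide.index.tolist()
        sample_ids = wide.columns.tolist()
        values = wide.to_numpy(dtype=float)
    else:
        raise ParseError(f"unknown Cq layout {layout!r}")
    dsn, order = _align_design(sample_ids, design, path)
    return CqMatrix(genes, dsn, values[:, order], efficiency)


def write_cq_tsv(cq: CqMatrix, path: str | Path) -> None:
    cq.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------- structure


def read_structure(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a BioMart-style gene-structure table.

    Rows with missing values in any of the six structure variables are
    dropped (a count is logged); ``cds_length <= transcript_length <=
    gene_length`` violations are flagged in a ``length_consistent``
    column rather than rejected, tolerating annotation quirks.
    """
    df = _read_table(path, sep)
    _require_columns(df, ["gene_id", *STRUCTURE_VARIABLES], path)
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids in structure table")
    for col in STRUCTURE_VARIABLES:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    complete = df.dropna(subset=list(STRUCTURE_VARIABLES))
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("read_structure: dropped %d incomplete rows", n_dropped)
    complete = complete.reset_index(drop=True)
    bad_gc = ~complete["gc_content"].between(0, 1, inclusive="neither")
    if bad_gc.any():
        raise ParseError(f"{path}: gc_content outside (0, 1)")
    complete["length_consistent"] = (
        complete["cds_length"] <= complete["transcript_length"]
    ) & (complete["transcript_length"] <= complete["gene_length"])
    return complete


def read_standard_curve(path: str | Path, sep: str = "\t") -> list[tuple[float, float]]:
    df = _read_table(path, sep)
    _require_columns(df, ["log10_input", "cq"], path)
    df = _numeric(df, ["log10_input", "cq"], path)
    return list(zip(df["log10_input"].astype(float), df["cq"].astype(float)))


# ---------------------------------------------------------------- specs


def write_gene_specs_json(specs: Sequence[GeneSpec], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([s.to_dict() for s in specs], indent=2) + "\n"
    )


def read_gene_specs_json(path: str | Path) -> list[GeneSpec]:
    return [GeneSpec.from_dict(d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------- fixtures


def load_table1() -> pd.DataFrame:
    """Packaged 17-gene RNA-Seq screening summary (mean FPKM, CV%)."""
    with resources.files("refstab.data").joinpath(
        "table1_candidate_genes.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table2() -> pd.DataFrame:
    """Packaged 14-gene RT-qPCR panel summary (E, mean Cq, SD, CV%)."""
    with resources.files("refstab.data").joinpath(
        "table2_qpcr_parameters.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
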