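"""Readers, writers and configuration for the pipeline's text formats.

Tab-separated values are the canonical tabular format (ICP-MS and
phenotyping exports are tabular); count matrices are additionally readable
and writable as MatrixMarket triplets with sibling gene/sample id files;
images travel as paired RGB + mask PNGs. Configuration is YAML with every
default echoed back for provenance, and unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .ionome import ELEMENTS, HARVESTS, IonomeSample, TISSUES_5, TREATMENTS
from .phenotyping import ImageRecord

PathLike = Union[str, Path]

_META_COLS = ["species", "treatment", "harvest", "tissue", "replicate", "dry_weight"]


class TableValidationError(ValueError):
    """A table failed validation; the message cites the offending rows."""


# ---------------------------------------------------------------------------
# ionome tables (wide and long dialects)
# ---------------------------------------------------------------------------


def _validate_ionome(df: pd.DataFrame) -> pd.DataFrame:
    bad_dw = df.index[df["dry_weight"] <= 0].tolist()
    if bad_dw:
        raise TableValidationError(f"non-positive dry weight in rows {bad_dw}")
    bad_tissue = df.index[~df["tissue"].isin(TISSUES_5)].tolist()
    if bad_tissue:
        names = df.loc[bad_tissue, "tissue"].unique().tolist()
        raise TableValidationError(
            f"unknown tissues {names} in rows {bad_tissue}"
        )
    bad_trt = df.index[~df["treatment"].isin(TREATMENTS)].tolist()
    if bad_trt:
        raise TableValidationError(f"unknown treatment in rows {bad_trt}")
    bad_hv = df.index[~df["harvest"].isin(HARVESTS)].tolist()
    if bad_hv:
        raise TableValidationError(f"unknown harvest in rows {bad_hv}")
    elements = [c for c in df.columns if c in ELEMENTS]
    for el in elements:
        neg = df.index[df[el] < 0].tolist()
        if neg:
            raise TableValidationError(
                f"negative {el} concentration in rows {neg}"
            )
    return df


def read_ionome_table(path: PathLike, dialect: str = "auto") -> pd.DataFrame:
    """Read a tidy ionome TSV in the wide or long dialect.

    Wide: one row per sample with one ppm column per element. Long: one row
    per sample x element with ``element`` and ``concentration`` columns.
    Returns the canonical wide DataFrame; validation errors cite row
    numbers (0-based data rows).
    """
    df = pd.read_csv(path, sep="\t")
    if dialect == "auto":
        dialect = "long" if {"element", "concentration"}.issubset(df.columns) else "wide"
    if dialect == "long":
        required = _META_COLS + ["element", "concentration"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableValidationError(f"missing columns: {missing}")
        bad = df.index[~df["element"].isin(ELEMENTS)].tolist()
        if bad:
            raise TableValidationError(f"unknown element in rows {bad}")
        wide = df.pivot_table(
            index=_META_COLS, columns="element", values="concentration",
            aggfunc="first",
        ).reset_index()
        wide.columns.name = None
        # keep the canonical element ordering
        cols = _META_COLS + [e for e in ELEMENTS if e in wide.columns]
        df = wide[cols]
    elif dialect == "wide":
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise TableValidationError(f"missing columns: {missing}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _validate_ionome(df)


def write_ionome_table(
    df: pd.DataFrame, path: PathLike, dialect: str = "wide"
) -> None:
    """Write an ionome table in the wide (default) or long dialect."""
    if dialect == "wide":
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "long":
        elements = [c for c in df.columns if c in ELEMENTS]
        long = df.melt(
            id_vars=_META_COLS, value_vars=elements,
            var_name="element", value_name="concentration",
        )
        long.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def ionome_samples(df: pd.DataFrame) -> list[IonomeSample]:
    """Convert a wide ionome table to :class:`IonomeSample` objects."""
    elements = [c for c in df.columns if c in ELEMENTS]
    return [
        IonomeSample(
            species=row["species"], treatment=row["treatment"],
            harvest=row["harvest"], tissue=row["tissue"],
            replicate=int(row["replicate"]), dry_weight=float(row["dry_weight"]),
            concentrations={e: float(row[e]) for e in elements},
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# count matrices (TSV or MatrixMarket)
# ---------------------------------------------------------------------------


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        raise TableValidationError("count matrix is empty")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate gene ids: {dup[:5]}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate sample ids: {dup[:5]}")
    arr = df.to_numpy()
    if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
        raise TableValidationError("counts must be non-negative integers")
    return df.astype(np.int64)


def read_count_matrix(path: PathLike) -> pd.DataFrame:
    """Read a gene x sample integer count matrix.

    ``.mtx`` files are MatrixMarket triplets with sibling
    ``<stem>.genes.txt`` and ``<stem>.samples.txt`` id files; anything else
    is a TSV with gene ids in the first column and sample ids as header.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(path).toarray()
        genes = Path(path.with_suffix("")).with_suffix(".genes.txt")
        samples = Path(path.with_suffix("")).with_suffix(".samples.txt")
        gene_ids = genes.read_text().split()
        sample_ids = samples.read_text().split()
        if mat.shape != (len(gene_ids), len(sample_ids)):
            raise TableValidationError(
                f"matrix shape {mat.shape} does not match id files "
                f"({len(gene_ids)} genes, {len(sample_ids)} samples)"
            )
        df = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene"),
                          columns=sample_ids)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "gene"
    return _validate_counts(df)


def write_count_matrix(df: pd.DataFrame, path: PathLike) -> None:
    """Write a count matrix as TSV or (``.mtx``) MatrixMarket + id files."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(df.to_numpy()))
        Path(path.with_suffix("")).with_suffix(".genes.txt").write_text(
            "\n".join(map(str, df.index)) + "\n"
        )
        Path(path.with_suffix("")).with_suffix(".samples.txt").write_text(
            "\n".join(map(str, df.columns)) + "\n"
        )
    else:
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def read_image(
    rgb_path: PathLike, mask_path: PathLike, pixel_scale: float = 1.0
) -> ImageRecord:
    """Load an RGB PNG and its binary mask PNG into an :class:`ImageRecord`."""
    from PIL import Image

    rgb = np.asarray(Image.open(rgb_path).convert("RGB"))
    mask = np.asarray(Image.open(mask_path).convert("L")) > 127
    return ImageRecord(rgb=rgb, mask=mask, pixel_scale=pixel_scale)


def write_image(record: ImageRecord, rgb_path: PathLike, mask_path: PathLike) -> None:
    from PIL import Image

    Image.fromarray(record.rgb.astype(np.uint8)).save(rgb_path)
    Image.fromarray((record.mask * 255).astype(np.uint8)).save(mask_path)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with its documented default.

    Defaults mirror the analysis conventions: alpha 0.05 throughout, Welch
    test on NU combinations, TMM trims 30% (M) / 5% (A), CPM >= 1 in >= 2
    samples filter, 0.75 dominance threshold for element patterns.
    """

    out_dir: str = "ionoflux_out"
    seed: int = 0
    alpha: float = 0.05
    nu_test: str = "welch"
    trim_m: float = 0.30
    trim_a: float = 0.05
    cpm_threshold: float = 1.0
    min_samples: int = 2
    dominance: float = 0.75
    species: str = "rapeseed"
    n_replicates: int = 5
    noise_cv: float = 0.05
    n_genes: int = 2000
    n_samples_per_group: int = 5
    de_fraction: float = 0.1
    planted_log2fc: float = 2.0
    count_dispersion: float = 0.1
    ionome_table: Optional[str] = None   # read instead of simulating if set
    count_matrix: Optional[str] = None   # idem
    sample_sheet: Optional[str] = None
    annotation_table: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TableValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: PathLike) -> None:
        """Echo the full configuration (all defaults included)."""
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )
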