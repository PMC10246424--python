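"""Readers/writers for the external formats the pipeline touches.

Conventions (fixed, not sniffed): expression TSVs carry genes as rows and
samples as columns; missing clinical values are written as ``NA``; MAF files
are tab-separated with at least ``Hugo_Symbol``, ``Tumor_Sample_Barcode``
and ``Variant_Classification`` columns.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger("myelodiv")

__all__ = [
    "ExpressionMatrix",
    "CellLabeling",
    "ClinicalTable",
    "MutationTable",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_maf",
    "write_maf",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "load_config",
    "MAF_VARIANT_CLASSES",
    "NON_SYNONYMOUS_CLASSES",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Dense genes x samples (or genes x cells) expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite entries")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])


@dataclass
class CellLabeling:
    """cell_id -> subgroup label assignment."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}
        if len(self.vocabulary) < 2:
            raise ValueError("cell labeling must cover at least 2 subgroups")

    @property
    def vocabulary(self) -> list[str]:
        """Subgroup vocabulary in first-appearance order."""
        seen: dict[str, None] = {}
        for v in self.labels.values():
            seen.setdefault(v, None)
        return list(seen)

    def cells_of(self, subgroup: str) -> list[str]:
        return [c for c, g in self.labels.items() if g == subgroup]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.labels) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"labelled cells absent from matrix: {sorted(missing)[:5]}")


@dataclass
class ClinicalTable:
    """Per-sample survival endpoint, optional binary response, covariates."""

    df: pd.DataFrame

    REQUIRED = ("sample_id", "time", "event")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample IDs in clinical table: {dup}")
        df["time"] = df["time"].astype(float)
        if (df["time"] < 0).any():
            raise ValueError("clinical time must be nonnegative")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event column must be binary 0/1")
        df["event"] = df["event"].astype(int)
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].astype(str).tolist()

    @property
    def covariate_columns(self) -> list[str]:
        skip = set(self.REQUIRED) | {"response"}
        return [c for c in self.df.columns if c not in skip]


# canonical MAF variant classification vocabulary
MAF_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "RNA",
        "IGR",
        "Targeted_Region",
    }
)

# default non-synonymous filter used for prevalence and TMB
NON_SYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


@dataclass
class MutationTable:
    """MAF-style somatic mutation records (one row per variant call)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("sample_id", "gene", "variant_classification"):
            if col not in df.columns:
                raise ValueError(f"mutation table missing column {col!r}")
        if "protein_position" not in df.columns:
            df["protein_position"] = pd.array([pd.NA] * len(df), dtype="Int64")
        if len(df) and (
            (df["sample_id"].astype(str) == "").any() or (df["gene"].astype(str) == "").any()
        ):
            raise ValueError("sample and gene identifiers must be nonempty")
        df["known_class"] = df["variant_classification"].isin(MAF_VARIANT_CLASSES)
        n_unknown = int((~df["known_class"]).sum())
        if n_unknown:
            warnings.warn(
                f"{n_unknown} mutation rows carry a non-standard variant classification; "
                "retained but flagged",
                stacklevel=2,
            )
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].astype(str).unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene"].astype(str).unique())

    def non_synonymous(self) -> "MutationTable":
        return MutationTable(
            self.df[self.df["variant_classification"].isin(NON_SYNONYMOUS_CLASSES)]
        )


@dataclass
class GeneSetCollection:
    """GMT-semantics mapping: set name -> gene-ID list."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = [str(g) for g in genes]

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    dup: list[str] = []
    for x in ids:
        if x in seen:
            dup.append(x)
        seen.add(x)
    if dup:
        raise ValueError(f"duplicate {kind} IDs: {sorted(set(dup))}")


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix.

    ``tsv``: dense genes x samples table with a header row of sample IDs and
    gene IDs in the first column. ``mtx-triplet``: ``path`` is a directory
    holding ``matrix.mtx`` (genes x cells triplets), ``features.tsv`` and
    ``barcodes.tsv``.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return ExpressionMatrix.from_frame(df)
    if format == "mtx-triplet":
        mat = spio.mmread(path / "matrix.mtx")
        genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        return ExpressionMatrix(genes, cells, dense)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(
    em: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        em.to_frame().to_csv(path, sep="\t", index_label="gene_id")
        return
    if format == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(em.values))
        pd.Series(em.gene_ids).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
        pd.Series(em.sample_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
        return
    raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# MAF I/O
# ---------------------------------------------------------------------------

_MAF_COLS = {
    "Hugo_Symbol": "gene",
    "Tumor_Sample_Barcode": "sample_id",
    "Variant_Classification": "variant_classification",
}


def read_maf(path: str | Path) -> MutationTable:
    """Read a MAF-style TSV. Gene symbols are preserved verbatim (no case folding)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _MAF_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file missing mandatory column(s): {missing}")
    out = df.rename(columns=_MAF_COLS)
    if "Protein_position" in out.columns:
        out["protein_position"] = pd.to_numeric(
            out["Protein_position"], errors="coerce"
        ).astype("Int64")
    keep = ["sample_id", "gene", "variant_classification"]
    if "protein_position" in out.columns:
        keep.append("protein_position")
    return MutationTable(out[keep])


def write_maf(mt: MutationTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "Hugo_Symbol": mt.df["gene"],
            "Tumor_Sample_Barcode": mt.df["sample_id"],
            "Variant_Classification": mt.df["variant_classification"],
            "Protein_position": mt.df["protein_position"],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# clinical I/O
# ---------------------------------------------------------------------------


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str})
    return ClinicalTable(df)


def write_clinical(ct: ClinicalTable, path: str | Path) -> None:
    ct.df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
            desc[parts[0]] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            desc = gsc.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------


def _coerce(value, annotation, path: str):
    """Validate a YAML scalar/sequence against a dataclass field annotation."""
    origin = getattr(annotation, "__origin__", None)
    if origin in (tuple, list):
        if not isinstance(value, (list, tuple)):
            raise TypeError(f"config key {path!r}: expected a sequence, got {type(value).__name__}")
        args = getattr(annotation, "__args__", (float,))
        inner = args[0]
        return tuple(_coerce(v, inner, f"{path}[{i}]") for i, v in enumerate(value))
    if annotation is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise TypeError(f"config key {path!r}: expected int, got {type(value).__name__}")
        return value
    if annotation is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise TypeError(f"config key {path!r}: expected number, got {type(value).__name__}")
        return float(value)
    if annotation is str:
        if not isinstance(value, str):
            raise TypeError(f"config key {path!r}: expected string, got {type(value).__name__}")
        return value
    if annotation is bool:
        if not isinstance(value, bool):
            raise TypeError(f"config key {path!r}: expected bool, got {type(value).__name__}")
        return value
    return value


def load_config(path: str | Path | None, schema=None):
    """Load a YAML config into a dataclass ``schema``, materializing defaults.

    Unknown keys are rejected and type violations are reported with the
    offending key path. An empty (or absent) file yields all defaults. The
    effective configuration is echoed to the module logger.
    """
    if schema is None:
        from .synthetic_cohort import SimulationConfig

        schema = SimulationConfig
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise TypeError("config file must contain a mapping at the top level")
        raw = dict(loaded)

    fields = {f.name: f for f in dataclasses.fields(schema)}
    unknown = sorted(set(raw) - set(fields))
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    kwargs = {}
    hints = _resolve_hints(schema)
    for name, value in raw.items():
        kwargs[name] = _coerce(value, hints[name], name)
    cfg = schema(**kwargs)
    buf = io.StringIO()
    for f in dataclasses.fields(schema):
        buf.write(f"{f.name}={getattr(cfg, f.name)!r} ")
    logger.info("effective config: %s", buf.getvalue().strip())
    return cfg


def _resolve_hints(schema) -> dict:
    import typing

    return typing.get_type_hints(schema)
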