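"""Readers, writers and unit conversions for the formats the pipeline consumes.

Expression matrices travel as :class:`ExpressionMatrix` (genes x samples with an
explicit linear/log2 scale tag); clinical tables, somatic mutation records and
gene-set collections have thin typed wrappers around pandas objects so that
invariants (unique ids, finite values, valid event codes) are checked once at
the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Scale tags for expression values.
LINEAR = "linear"
LOG2 = "log2"

#: MAF controlled vocabulary for Variant_Classification.
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
        "IGR",
        "RNA",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Targeted_Region",
    }
)

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with an explicit scale tag.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id, columns are sample ids.
    scale:
        ``"linear"`` (non-negative abundances such as FPKM/TPM) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if self.scale == LINEAR and (values < 0).any():
            raise ValueError("linear-scale expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        if self.scale == LOG2:
            return self
        return ExpressionMatrix(np.log2(self.data + pseudocount), scale=LOG2)

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == LINEAR:
            return self
        return ExpressionMatrix(2.0**self.data, scale=LINEAR)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present], scale=self.scale)


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus optional covariates.

    ``os_time`` is time to event or censoring (unit carried in ``time_unit``,
    never converted implicitly); ``os_event`` is 1 for death, 0 for censored.
    """

    data: pd.DataFrame
    time_unit: str = "days"

    def __post_init__(self) -> None:
        for col in ("os_time", "os_event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if (self.data["os_time"] < 0).any():
            raise ValueError("os_time must be non-negative")
        if not self.data["os_event"].isin([0, 1]).all():
            raise ValueError("os_event must be coded 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class MutationTable:
    """Long-form (sample, gene, variant classification) somatic records.

    Exact duplicate triples are allowed: a gene hit twice in one sample is a
    multi-hit, which the oncoprint summary collapses downstream.
    """

    records: pd.DataFrame  # columns: sample_id, gene, variant_classification

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "variant_classification"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"mutation table missing columns: {sorted(missing)}")
        bad = set(self.records["variant_classification"]) - MAF_VARIANT_CLASSES
        if bad:
            raise ValueError(f"unknown variant classifications: {sorted(bad)[:5]}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> ordered unique member list."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                self.sets[name] = list(dict.fromkeys(members))

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene rows, keeping the row with the highest mean.

    The standard microarray convention when several probes map to one symbol.
    """
    if not df.index.duplicated().any():
        return df
    means = df.mean(axis=1)
    order = np.argsort(-means.to_numpy(), kind="stable")
    df = df.iloc[order]
    df = df[~df.index.duplicated(keep="first")]
    return df.sort_index()


def read_expression_matrix(path: str | Path, scale_hint: str = LINEAR) -> ExpressionMatrix:
    """Read a TSV or GCT expression file into an :class:`ExpressionMatrix`.

    First column gene ids, header row sample ids. GCT files (``#1.2`` header,
    dims line, Name/Description columns) are detected from the leading line.
    Duplicate gene rows are collapsed by keeping the highest-mean row.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#1.2"):
            fh.readline()  # dims line
            header = fh.readline()
        else:
            header = first
    samples = header.rstrip("\n").split("\t")[1:]
    if first.startswith("#1.2") and samples and samples[0].lower() == "description":
        samples = samples[1:]
    dups = [s for s in set(samples) if samples.count(s) > 1]
    if dups:
        raise ParseError(f"duplicate sample ids in {path.name}: {sorted(dups)[:5]}")
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(f"non-numeric value at gene {row!r}, sample {col!r}")
    df = df.astype(float)
    df = _collapse_duplicate_genes(df)
    if scale_hint == LINEAR and df.to_numpy().max(initial=0.0) < 30:
        logger.warning(
            "max expression value < 30: data may already be log2-scaled; "
            "pass scale_hint='log2' if so"
        )
    return ExpressionMatrix(df, scale=scale_hint)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene")


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert linear FPKM values to TPM: each sample rescaled to sum 1e6."""
    if m.scale != LINEAR:
        raise ValueError("fpkm_to_tpm requires linear-scale input")
    sums = m.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero expression column(s): {list(zero.index)[:5]}")
    return ExpressionMatrix(m.data.div(sums, axis=1) * 1e6, scale=LINEAR)


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

DEFAULT_EVENT_CODES: Mapping[str, int] = {
    "0": 0,
    "1": 1,
    "alive": 0,
    "dead": 1,
    "living": 0,
    "deceased": 1,
    "censored": 0,
    "event": 1,
}


def read_clinical(
    path: str | Path,
    sample_col: str = "sample_id",
    time_col: str = "os_time",
    event_col: str = "os_event",
    time_unit: str = "days",
    event_codes: Mapping[str, int] | None = None,
) -> ClinicalTable:
    """Read a clinical TSV; os_event strings are mapped through ``event_codes``
    (case-insensitive; defaults accept 0/1, Alive/Dead, Living/Deceased)."""
    codes = {k.lower(): v for k, v in (event_codes or DEFAULT_EVENT_CODES).items()}
    df = pd.read_csv(path, sep="\t", dtype={sample_col: str})
    missing = {sample_col, time_col, event_col} - set(df.columns)
    if missing:
        raise ParseError(f"clinical file missing columns: {sorted(missing)}")
    df = df.set_index(sample_col)
    df.index.name = "sample_id"

    def _map_event(v) -> int:
        key = str(v).strip().lower()
        if key not in codes:
            raise ParseError(f"unmappable os_event value {v!r}")
        return codes[key]

    df["os_event"] = df[event_col].map(_map_event)
    df["os_time"] = pd.to_numeric(df[time_col])
    return ClinicalTable(df, time_unit=time_unit)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


def read_maf(path: str | Path) -> MutationTable:
    """Read a tab-separated MAF, keeping only the columns used downstream."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(MAF_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"MAF missing mandatory columns: {sorted(missing)}")
    extra = set(df.columns) - set(MAF_REQUIRED_COLUMNS)
    if extra:
        logger.info("ignoring %d extra MAF columns", len(extra))
    out = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"],
            "gene": df["Hugo_Symbol"],
            "variant_classification": df["Variant_Classification"],
        }
    )
    return MutationTable(out)


def write_maf(table: MutationTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "Hugo_Symbol": table.records["gene"],
            "Tumor_Sample_Barcode": table.records["sample_id"],
            "Variant_Classification": table.records["variant_classification"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"GMT line {lineno}: need name, description, >=1 member")
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")
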