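"""Cohort data model: abundance tables, phenotype tables, enterotype labels.

An :class:`AbundanceTable` holds a samples x taxa matrix of sequencing
counts or relative abundances (each row a composition summing to 1).  A
:class:`PhenotypeTable` holds per-sample fecal butyrate (mg/g fresh feces),
log10 gene copies per gram of the two terminal butyrate-synthesis genes —
butyrate kinase (Buk) and butyryl-CoA:acetate-CoA transferase (But) — and
optional physicochemical covariates (water %, pH, organic matter, total N,
total P).

On-disk formats are wide TSV (tab-delimited, ``#`` comment lines ignored,
first column = row ids) and, for abundances, dense BIOM-JSON v1.0 (rows =
taxa, columns = samples, per the BIOM convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COUNTS = "counts"
RELATIVE = "relative"

#: canonical phenotype column names
BUTYRATE = "butyrate_mg_per_g"
BUK = "buk_log10_copies"
BUT = "but_log10_copies"
PHENOTYPE_COLUMNS = (BUTYRATE, BUK, BUT)

_REL_TOL = 1e-9


class TableError(ValueError):
    """Raised when a table violates an invariant of the data model."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise TableError(f"duplicate {what} ids: {dups}")


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with a unit tag.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with one column per taxon.
    unit:
        ``"counts"`` or ``"relative"``.  Relative rows must sum to 1
        within 1e-9.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in (COUNTS, RELATIVE):
            raise TableError(f"unknown unit {self.unit!r}")
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "taxon")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise TableError("abundance table contains missing or non-finite cells")
        if values.size and values.min() < 0:
            bad = self.data.index[np.where(values < 0)[0][0]]
            raise TableError(f"negative abundance in sample {bad!r}")
        if self.unit == RELATIVE:
            sums = values.sum(axis=1)
            off = np.abs(sums - 1.0)
            if values.size and off.max() > _REL_TOL:
                bad = self.data.index[int(off.argmax())]
                raise TableError(
                    f"relative table row {bad!r} sums to {sums[int(off.argmax())]:.12g}, not 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]


@dataclass
class PhenotypeTable:
    """Per-sample butyrate, gene-copy and covariate measurements."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise TableError(f"phenotype table missing columns: {missing}")
        if (self.data[BUTYRATE].dropna() < 0).any():
            raise TableError("negative butyrate concentration")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in PHENOTYPE_COLUMNS]


@dataclass
class EnterotypeLabels:
    """Integer enterotype assignment, 1..K, per sample."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        _check_unique(self.sample_ids, "sample")
        if len(self.sample_ids) != len(self.labels):
            raise TableError("sample_ids and labels length mismatch")
        if len(self.labels) and (self.labels.min() < 1):
            raise TableError("enterotype labels must be in 1..K")

    @property
    def k(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=pd.Index(self.sample_ids, name="sample_id"), name="ET")


@dataclass
class AlignmentReport:
    """What an inner join of abundance and phenotype samples dropped."""

    n_common: int
    dropped_abundance: list[str] = field(default_factory=list)
    dropped_phenotype: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers


def _detect_unit(values: np.ndarray) -> str:
    if np.allclose(values, np.round(values), atol=1e-9):
        return COUNTS
    sums = values.sum(axis=1)
    if np.abs(sums - 1.0).max() <= 1e-6:
        return RELATIVE
    raise TableError(
        "cannot infer unit: values are neither all integral (counts) "
        "nor row-normalized (relative)"
    )


def read_abundance_table(
    path: str | Path,
    format: str = "tsv_wide",
    orientation: str = "samples_rows",
) -> AbundanceTable:
    """Read and validate an abundance table.

    The unit is auto-detected: an all-integral body is counts; rows summing
    to ~1 are relative abundances; anything else is an error.
    """
    path = Path(path)
    if format == "tsv_wide":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    elif format == "biom_json":
        df = _read_biom_dense(path)
        orientation = "samples_rows"  # BIOM conversion already transposes
    else:
        raise TableError(f"unknown format {format!r}")
    if orientation == "taxa_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise TableError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise TableError(f"non-numeric abundance body in {path}: {exc}") from exc
    unit = _detect_unit(values)
    if unit == RELATIVE:
        sums = values.sum(axis=1)
        if np.abs(sums - 1.0).max() > _REL_TOL:
            df = df.div(sums, axis=0)
    return AbundanceTable(df, unit)


def write_abundance_table(
    table: AbundanceTable, path: str | Path, format: str = "tsv_wide"
) -> None:
    path = Path(path)
    if format == "tsv_wide":
        table.data.rename_axis("sample_id").to_csv(path, sep="\t")
    elif format == "biom_json":
        _write_biom_dense(table, path)
    else:
        raise TableError(f"unknown format {format!r}")


def _read_biom_dense(path: Path) -> pd.DataFrame:
    """Minimal reader for dense BIOM-JSON v1.0 (rows=taxa, columns=samples)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise TableError("only dense BIOM-JSON v1.0 is supported")
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.asarray(doc["data"], dtype=float)
    if mat.shape != (len(taxa), len(samples)):
        raise TableError("BIOM shape does not match rows/columns")
    return pd.DataFrame(mat.T, index=samples, columns=taxa)


def _write_biom_dense(table: AbundanceTable, path: Path) -> None:
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "enterotyper",
        "date": datetime.now(timezone.utc).isoformat(),
        "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "matrix_type": "dense",
        "matrix_element_type": "int" if table.unit == COUNTS else "float",
        "shape": [table.n_taxa, table.n_samples],
        "data": table.values.T.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    table.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_labels(path: str | Path) -> EnterotypeLabels:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return EnterotypeLabels([str(s) for s in df.index], df.iloc[:, 0].to_numpy(dtype=int))


def write_labels(labels: EnterotypeLabels, path: str | Path) -> None:
    labels.to_series().rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# transformations


def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert to relative abundances by dividing each row by its sum.

    Idempotent: rows already summing to 1 within 1e-12 are left untouched,
    so normalizing twice is bit-identical to normalizing once.
    """
    values = table.values
    sums = values.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = table.data.index[int(np.where(zero)[0][0])]
        raise TableError(f"cannot normalize all-zero sample row {bad!r}")
    out = values.copy()
    needs = np.abs(sums - 1.0) > 1e-12
    out[needs] = values[needs] / sums[needs, None]
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return AbundanceTable(df, RELATIVE)


def filter_low_abundance(
    table: AbundanceTable,
    min_mean_rel: float = 0.0,
    min_prevalence: float = 0.0,
) -> tuple[AbundanceTable, list[str]]:
    """Drop rare taxa before clustering; rows are re-normalized.

    A taxon is kept when its mean relative abundance is at least
    ``min_mean_rel`` OR its prevalence (fraction of samples in which it is
    present) is at least ``min_prevalence``.  The defaults (0, 0) keep
    everything — the original enterotype methodology sometimes removes
    ultra-rare genera, so the filter is offered, but off by default.

    Returns the filtered table together with the list of removed taxa.
    """
    if table.unit != RELATIVE:
        raise TableError("filter_low_abundance expects a relative table; normalize first")
    values = table.values
    mean_rel = values.mean(axis=0)
    keep = mean_rel >= min_mean_rel
    if min_prevalence > 0:  # prevalence rescue only when actually requested
        keep |= (values > 0).mean(axis=0) >= min_prevalence
    if not keep.any():
        raise TableError("filter would remove all taxa")
    removed = [t for t, k in zip(table.taxon_ids, keep) if not k]
    if not removed:
        return table, []
    df = table.data.loc[:, keep]
    sums = df.to_numpy(dtype=float).sum(axis=1)
    if (sums <= 0).any():
        bad = df.index[int(np.argmin(sums))]
        raise TableError(f"filter left sample {bad!r} with zero total abundance")
    return AbundanceTable(df.div(sums, axis=0), RELATIVE), removed


def align_tables(
    abundance: AbundanceTable, phenotype: PhenotypeTable
) -> tuple[AbundanceTable, PhenotypeTable, AlignmentReport]:
    """Inner-join abundance and phenotype tables on sample id.

    Samples present in only one table are dropped and reported; the
    surviving tables share an identical sample order.
    """
    a_ids = pd.Index(abundance.sample_ids)
    p_ids = pd.Index(phenotype.sample_ids)
    common = a_ids.intersection(p_ids)
    report = AlignmentReport(
        n_common=len(common),
        dropped_abundance=a_ids.difference(p_ids).tolist(),
        dropped_phenotype=p_ids.difference(a_ids).tolist(),
    )
    if len(common) == 0:
        raise TableError("no common samples between abundance and phenotype tables")
    ordered = [s for s in abundance.sample_ids if s in set(common)]
    a = AbundanceTable(abundance.data.loc[ordered], abundance.unit)
    p = PhenotypeTable(phenotype.data.loc[ordered])
    return a, p, report
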