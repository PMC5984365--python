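"""Shared data model and table I/O.

The pipeline operates on two aligned structures: a taxon-by-sample integer
count matrix (:class:`CountMatrix`) carrying genus/species taxonomy labels,
and a per-sample covariate table (:class:`SampleFrame`) holding the group
label (PHIV = perinatally HIV-infected, PHEU = perinatally HIV-exposed but
uninfected), demographic covariates, oral-disease outcomes and total
sequencing reads.

Count tables are TSV (first column ``taxon_id``, optional ``genus`` and
``species`` columns, then one column per sample) or BIOM 1.0-style JSON.
Metadata tables are TSV with binary covariates coded 0/1.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("PHIV", "PHEU")

#: Metadata columns every included sample must provide.
REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "group",
    "age",
    "sex",
    "race_white",
    "ethnicity_hispanic",
    "dental_visit_past_year",
    "antibiotic_past_3mo",
    "periodontitis",
    "caries",
    "total_reads",
)

BINARY_COLUMNS = (
    "sex",
    "race_white",
    "ethnicity_hispanic",
    "dental_visit_past_year",
    "antibiotic_past_3mo",
    "periodontitis",
    "caries",
)

#: Columns of a count-table TSV that are not sample counts.
_TAXONOMY_COLUMNS = ("genus", "species")


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed data violate a data-model invariant."""


@dataclass
class CountMatrix:
    """Taxon × sample non-negative integer counts with taxonomy labels.

    Parameters
    ----------
    counts
        DataFrame with taxon ids as index, sample ids as columns, integer
        cells.
    taxonomy
        DataFrame indexed like ``counts`` with string columns ``genus`` and
        ``species``; ``species`` may be empty for genus-only reads, and
        phylotype labels (e.g. ``"HOT 272"``) are permitted.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if c.isna().any().any():
            raise ValidationError("count matrix contains missing cells")
        if not all(np.issubdtype(dt, np.integer) for dt in c.dtypes):
            raise ValidationError("count matrix cells must be integers")
        if (c.to_numpy() < 0).any():
            raise ValidationError("count matrix cells must be >= 0")
        if not self.taxonomy.index.equals(c.index):
            raise ValidationError("taxonomy index does not match count index")
        for col in _TAXONOMY_COLUMNS:
            if col not in self.taxonomy.columns:
                raise ValidationError(f"taxonomy missing column {col!r}")

    # -- convenience ------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def select_taxa(self, taxon_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(taxon_ids)],
                           self.taxonomy.loc[list(taxon_ids)])

    def select_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.taxonomy.copy())


@dataclass
class SampleFrame:
    """Per-sample covariates, group label, outcomes, total reads."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        bad_group = set(df["group"].unique()) - set(GROUPS)
        if bad_group:
            raise ValidationError(
                f"group values outside {GROUPS}: {sorted(bad_group)}")
        core = [c for c in REQUIRED_METADATA_COLUMNS if c != "sample_id"]
        if df[core].isna().any().any():
            cols = df[core].columns[df[core].isna().any()].tolist()
            raise ValidationError(f"missing values in required columns: {cols}")
        for col in BINARY_COLUMNS:
            vals = set(pd.unique(df[col]))
            if not vals <= {0, 1}:
                raise ValidationError(f"column {col!r} must be 0/1, got {vals}")
        if (df["total_reads"] <= 0).any():
            raise ValidationError("total_reads must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def group_indicator(self, group1: str = "PHIV") -> np.ndarray:
        """0/1 array, 1 for ``group1`` (PHIV by default)."""
        return (self.data["group"] == group1).to_numpy(dtype=int)

    def select_samples(self, sample_ids) -> "SampleFrame":
        keep = self.data["sample_id"].isin(set(sample_ids))
        return SampleFrame(self.data.loc[keep].reset_index(drop=True))


@dataclass
class RelAbundMatrix:
    """Per-sample proportions on the same axes as a CountMatrix."""

    values: pd.DataFrame
    taxonomy: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        colsums = self.values.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = colsums[~np.isclose(colsums, 1.0, atol=1e-9)].index.tolist()
            raise ValidationError(f"columns do not sum to 1: {bad}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts(path, dialect: str = "tsv", expected_samples=None) -> CountMatrix:
    """Read a count table.

    ``dialect`` is ``"tsv"`` (taxa rows × sample columns) or ``"biom-json"``
    (BIOM 1.0 JSON, dense or sparse). When ``expected_samples`` is given and
    the table appears transposed (row labels match the expected sample ids
    while column labels do not), it is auto-transposed with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        cm = _read_counts_tsv(path)
    elif dialect == "biom-json":
        cm = _read_counts_biom_json(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if expected_samples is not None:
        expected = set(expected_samples)
        cols = set(cm.counts.columns)
        rows = set(cm.counts.index)
        if not (cols & expected) and (rows & expected):
            warnings.warn("count table appears transposed; auto-transposing")
            counts = cm.counts.T
            counts.index.name = "taxon_id"
            tax = _default_taxonomy(counts.index)
            cm = CountMatrix(counts, tax)
    logger.info("read counts: %d taxa x %d samples", cm.n_taxa, cm.n_samples)
    return cm


def _read_counts_tsv(path: Path) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty count table") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a taxon_id column plus sample columns")
    first = df.columns[0]
    df = df.rename(columns={first: "taxon_id"})
    if df["taxon_id"].duplicated().any():
        dup = df.loc[df["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise ValidationError(f"{path}: duplicate taxon ids {dup}")
    df = df.set_index("taxon_id")
    tax_cols = [c for c in _TAXONOMY_COLUMNS if c in df.columns]
    taxonomy = df[tax_cols].fillna("") if tax_cols else pd.DataFrame(index=df.index)
    counts_raw = df.drop(columns=tax_cols)
    counts = pd.DataFrame(index=df.index)
    for col in counts_raw.columns:
        try:
            counts[col] = counts_raw[col].astype(np.int64)
        except (ValueError, TypeError):
            bad = counts_raw[col][~counts_raw[col].str.fullmatch(r"-?\d+", na=False)]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-integer cell at row {row!r}, column {col!r}")
    taxonomy = _complete_taxonomy(taxonomy)
    counts.index.name = "taxon_id"
    return CountMatrix(counts, taxonomy)


def _read_counts_biom_json(path: Path) -> CountMatrix:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON") from exc
    try:
        taxon_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mtype = doc.get("matrix_type", "dense")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a BIOM-JSON table ({exc})") from exc
    arr = np.zeros(shape, dtype=np.int64)
    if mtype == "dense":
        arr[:] = np.asarray(data)
    elif mtype == "sparse":
        for i, j, v in data:
            arr[int(i), int(j)] = v
    else:
        raise FormatError(f"{path}: unknown matrix_type {mtype!r}")
    counts = pd.DataFrame(arr, index=pd.Index(taxon_ids, name="taxon_id"),
                          columns=sample_ids)
    tax = pd.DataFrame(index=counts.index)
    genus, species = [], []
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        genus.append(meta.get("genus", ""))
        species.append(meta.get("species", ""))
    tax["genus"] = genus
    tax["species"] = species
    return CountMatrix(counts, _complete_taxonomy(tax))


def _default_taxonomy(index: pd.Index) -> pd.DataFrame:
    return pd.DataFrame({"genus": "", "species": ""}, index=index)


def _complete_taxonomy(tax: pd.DataFrame) -> pd.DataFrame:
    out = tax.copy()
    for col in _TAXONOMY_COLUMNS:
        if col not in out.columns:
            out[col] = ""
        out[col] = out[col].astype(str).replace("nan", "")
    return out[list(_TAXONOMY_COLUMNS)]


def write_counts(cm: CountMatrix, path) -> None:
    """Write a CountMatrix as TSV (round-trips through :func:`read_counts`)."""
    out = pd.concat([cm.taxonomy, cm.counts], axis=1)
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleFrame:
    """Read a metadata TSV into a validated SampleFrame.

    Unknown columns are preserved (and ignored downstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty metadata table") from exc
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    for col in BINARY_COLUMNS + ("total_reads",):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    df["age"] = df["age"].astype(float)
    return SampleFrame(df.reset_index(drop=True))


def write_metadata(sf: SampleFrame, path) -> None:
    sf.data.to_csv(path, sep="\t", index=False)


def align(cm: CountMatrix, sf: SampleFrame, check_totals: bool = False):
    """Restrict both structures to shared samples, in SampleFrame order.

    With ``check_totals=True``, asserts metadata ``total_reads`` equals the
    count-matrix column sums (the invariant when totals were derived from
    the matrix).
    """
    shared = [s for s in sf.sample_ids if s in set(cm.samples)]
    if not shared:
        raise ValidationError("no shared samples between counts and metadata")
    cm2 = cm.select_samples(shared)
    sf2 = sf.select_samples(shared)
    if check_totals:
        totals = cm2.sample_totals().to_numpy()
        meta = sf2.data["total_reads"].to_numpy()
        if not np.array_equal(totals, meta):
            raise ValidationError(
                "total_reads in metadata do not equal count column sums")
    return cm2, sf2


def relative_abundance(cm: CountMatrix) -> RelAbundMatrix:
    """Per-sample simple proportions: count / sample total."""
    totals = cm.sample_totals()
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValidationError(f"zero-total samples: {zero}")
    return RelAbundMatrix(cm.counts / totals, cm.taxonomy)
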