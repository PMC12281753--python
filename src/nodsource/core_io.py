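"""Data model, readers/writers and validators for the pipeline's tables.

Four tables drive every downstream stage:

* a **count table** of non-negative integer ASV abundances (ASVs x samples),
  read from plain TSV or from the JSON dialect of BIOM 1.0 tables;
* **sample metadata** keying each sample to its compartment (bulk soil,
  rhizosphere, root, nodule), fertilization treatment (P0, BC, BCplus, TSP),
  field block (1..3) and within-plot replicate;
* a **taxonomy table** mapping each ASV to a ranked lineage (SILVA-style
  strings or explicit rank columns), with unassigned ranks stored as the
  explicit sentinel ``"unassigned"``;
* an optional **phenotype table** of per-plot plant measurements.

A mock-community checker compares a positive-control sample against an
expected list of taxa at genus level.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPARTMENTS = ("bulk_soil", "rhizosphere", "root", "nodule")
TREATMENTS = ("P0", "BC", "BCplus", "TSP")
#: compartments with within-plot replicate extractions
REPLICATED_COMPARTMENTS = ("root", "nodule")
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "unassigned"
MAX_REPLICATES = 3

_METADATA_COLUMNS = ("sample_id", "compartment", "treatment", "block", "replicate")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dup}")


@dataclass
class CountTable:
    """ASV x sample matrix of non-negative integer read counts.

    ``data`` is indexed by ASV id with sample ids as columns.  Construction
    validates id uniqueness and non-negativity; all-zero samples are allowed
    (they arise transiently during filtering) but trigger a warning.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("CountTable expects a pandas DataFrame")
        _check_unique(self.data.index, "ASV ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            frac, _ = np.modf(values.astype(float))
            bad = np.argwhere(frac != 0)
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count at ASV {self.data.index[i]!r}, "
                    f"sample {self.data.columns[j]!r}: {values[i, j]!r}"
                )
            self.data = self.data.astype(np.int64)
            values = self.data.to_numpy()
        if values.size and values.min() < 0:
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at ASV {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}: {values[i, j]}"
            )
        if values.size:
            empty = self.data.columns[values.sum(axis=0) == 0].tolist()
            if empty:
                warnings.warn(f"samples with no reads: {empty}", stacklevel=3)

    @property
    def asv_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_asvs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def total_reads(self) -> int:
        return int(self.data.to_numpy().sum())

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def presence(self) -> pd.DataFrame:
        """Boolean presence matrix (count > 0)."""
        return self.data > 0

    def drop_samples(self, sample_ids) -> "CountTable":
        keep = [s for s in self.data.columns if s not in set(sample_ids)]
        return CountTable(self.data[keep].copy())

    def drop_empty_asvs(self) -> "CountTable":
        keep = self.data.sum(axis=1) > 0
        return CountTable(self.data.loc[keep].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class SampleMetadata:
    """Design labels for every sample: compartment, treatment, block, replicate."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _METADATA_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        _check_unique(df.index, "sample ids in metadata")
        bad_comp = sorted(set(df["compartment"]) - set(COMPARTMENTS))
        if bad_comp:
            raise ValidationError(
                f"unknown compartment values {bad_comp}; allowed: {list(COMPARTMENTS)}"
            )
        bad_trt = sorted(set(df["treatment"]) - set(TREATMENTS))
        if bad_trt:
            raise ValidationError(
                f"unknown treatment values {bad_trt}; allowed: {list(TREATMENTS)}"
            )
        for col in ("block", "replicate"):
            vals = pd.to_numeric(df[col], errors="raise").astype(int)
            self.data[col] = vals
        if (self.data["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be >= 1")
        key = df[["compartment", "treatment", "block", "replicate"]].apply(tuple, axis=1)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(f"duplicate design cell {dup}")
        rep = df[df["compartment"].isin(REPLICATED_COMPARTMENTS)]
        sizes = rep.groupby(["compartment", "treatment", "block"]).size()
        over = sizes[sizes > MAX_REPLICATES]
        if not over.empty:
            grp = over.index[0]
            raise ValidationError(
                f"plot {grp} has {over.iloc[0]} replicates; root/nodule plots "
                f"allow at most {MAX_REPLICATES}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def samples_for(self, compartment=None, treatment=None, block=None) -> list[str]:
        df = self.data
        mask = pd.Series(True, index=df.index)
        if compartment is not None:
            mask &= df["compartment"] == compartment
        if treatment is not None:
            mask &= df["treatment"] == treatment
        if block is not None:
            mask &= df["block"] == block
        return df.index[mask].tolist()

    def plots(self) -> list[tuple[str, int]]:
        """All (treatment, block) plots present, in treatment order."""
        pairs = sorted(
            set(zip(self.data["treatment"], self.data["block"])),
            key=lambda p: (TREATMENTS.index(p[0]), p[1]),
        )
        return pairs

    def check_covers(self, counts: CountTable, ignore=()) -> None:
        """Require a metadata record for every sample in ``counts``."""
        missing = [
            s for s in counts.sample_ids if s not in self.data.index and s not in set(ignore)
        ]
        if missing:
            raise ValidationError(f"samples present in counts but absent from metadata: {missing}")


_LINEAGE_PREFIX = re.compile(r"^[a-z]__\s*")


@dataclass
class TaxonomyTable:
    """Per-ASV ranked lineage; any rank may be the ``"unassigned"`` sentinel."""

    data: pd.DataFrame  # indexed by asv_id, columns == RANKS

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "ASV ids in taxonomy")
        for rank in RANKS:
            if rank not in self.data.columns:
                self.data[rank] = UNASSIGNED
        self.data = self.data[list(RANKS)].fillna(UNASSIGNED)
        self.data = self.data.replace("", UNASSIGNED)

    @classmethod
    def from_lineage_strings(cls, lineages: pd.Series) -> "TaxonomyTable":
        """Build from SILVA-style ``d__Bacteria; p__...`` or plain ``;``-joined strings."""
        rows = {}
        for asv, lin in lineages.items():
            parts = [(_LINEAGE_PREFIX.sub("", p.strip()) or UNASSIGNED) for p in str(lin).split(";")]
            parts = (parts + [UNASSIGNED] * len(RANKS))[: len(RANKS)]
            rows[asv] = parts
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
        return cls(df)

    @property
    def asv_ids(self) -> list[str]:
        return self.data.index.tolist()

    def family_of(self, asv_ids) -> pd.Series:
        fams = self.data["family"].reindex(asv_ids).fillna(UNASSIGNED)
        return fams

    def lineage_contains(self, needle: str) -> pd.Series:
        """Boolean per ASV: any rank matching ``needle`` (case-insensitive)."""
        needle = needle.lower()
        mat = self.data.apply(lambda col: col.astype(str).str.lower().str.contains(needle))
        return mat.any(axis=1)


@dataclass
class PhenotypeTable:
    """Per-plot plant measurements (nodule counts, mycorrhization %, biomass, ...)."""

    data: pd.DataFrame  # columns: treatment, block, then numeric variables

    def __post_init__(self) -> None:
        for col in ("treatment", "block"):
            if col not in self.data.columns:
                raise ValidationError(f"phenotype table missing column {col!r}")
        key = self.data[["treatment", "block"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValidationError(f"duplicate plot row {key[key.duplicated()].iloc[0]}")
        num = self.data.drop(columns=["treatment", "block"])
        arr = num.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("phenotype values must be finite")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("treatment", "block")]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file") from exc
    if df.shape[1] == 0 and df.shape[0] == 0:
        raise ValidationError(f"{path}: no data rows")
    return df


def read_count_table(path, format: str = "tsv", samples_as_rows: bool = False) -> CountTable:
    """Read an ASV count table from TSV or BIOM-1.0-style JSON.

    TSV files are ASVs-as-rows by default (first column ASV id, header row of
    sample ids); ``samples_as_rows=True`` transposes.  The BIOM reader accepts
    the JSON dialect (format 1.0) with dense or sparse ``matrix_type``.
    """
    if format == "tsv":
        df = _read_tsv(path)
        if samples_as_rows:
            df = df.T
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return CountTable(df)
    if format == "biom_json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        shape = tuple(doc.get("shape", (len(rows), len(cols))))
        mat = np.zeros(shape, dtype=np.int64)
        if doc.get("matrix_type", "sparse") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            mat[:, :] = np.asarray(doc["data"])
        return CountTable(pd.DataFrame(mat, index=rows, columns=cols))
    raise ValueError(f"unknown count-table format {format!r}")


def write_count_table(table: CountTable, path, header_lines=()) -> None:
    """Write a count table as TSV; optional ``#``-prefixed provenance header."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.data.to_csv(fh, sep="\t", index_label="asv_id")


def read_metadata(path) -> SampleMetadata:
    df = _read_tsv(path)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return SampleMetadata(df)


def read_taxonomy(path) -> TaxonomyTable:
    df = _read_tsv(path)
    df.index = df.index.astype(str)
    lineage_col = next((c for c in df.columns if c.lower() in ("lineage", "taxon", "taxonomy")), None)
    if lineage_col is not None:
        return TaxonomyTable.from_lineage_strings(df[lineage_col])
    return TaxonomyTable(df)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# mock community
# ---------------------------------------------------------------------------


@dataclass
class MockReport:
    """Detection report for a sequenced mock (positive-control) community."""

    expected: list[str]
    detected: list[str]
    missing: list[str]
    never_observed: list[str] = field(default_factory=list)
    relative_abundance: dict = field(default_factory=dict)

    @property
    def n_expected(self) -> int:
        return len(self.expected)

    @property
    def n_detected(self) -> int:
        return len(self.detected)

    @property
    def summary(self) -> str:
        return f"{self.n_detected}/{self.n_expected} detected"


def _genus_token(name: str) -> str:
    return name.strip().split()[0].lower()


def validate_mock_community(
    counts: CountTable,
    taxonomy: TaxonomyTable,
    expected: list[str],
    mock_sample_id: str,
) -> MockReport:
    """Check which expected mock taxa were recovered in the control sample.

    Matching is case-insensitive at genus level: an expected name (species or
    genus) is detected when an ASV carrying that genus has reads in the mock
    sample.  Genera absent from the taxonomy vocabulary entirely are flagged
    ``never_observed`` in addition to missing.
    """
    if not expected:
        raise ValidationError("expected taxon list is empty")
    if mock_sample_id not in counts.data.columns:
        raise ValidationError(f"mock sample {mock_sample_id!r} not found in count table")
    col = counts.data[mock_sample_id]
    present_asvs = col.index[col > 0]
    genera_present = set(
        taxonomy.data["genus"].reindex(present_asvs).dropna().str.lower()
    ) - {UNASSIGNED}
    vocabulary = set(taxonomy.data["genus"].str.lower()) - {UNASSIGNED}
    mock_total = col.sum()

    detected, missing, never = [], [], []
    rel = {}
    for name in expected:
        genus = _genus_token(name)
        if genus in genera_present:
            detected.append(name)
            asvs = taxonomy.data.index[taxonomy.data["genus"].str.lower() == genus]
            reads = col.reindex(asvs).fillna(0).sum()
            rel[name] = float(reads / mock_total) if mock_total else 0.0
        else:
            missing.append(name)
            if genus not in vocabulary:
                never.append(name)
    return MockReport(
        expected=list(expected),
        detected=detected,
        missing=missing,
        never_observed=never,
        relative_abundance=rel,
    )
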