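"""Per-block source attribution of nodule ASVs.

The core computation: within each field plot (treatment x block), the ASVs
detected in the plot's nodules are classified by the *exact* subset of outer
compartments -- bulk soil, rhizosphere, roots -- in which they are also
detected.  An ASV found in none of the three is "Unknown" (a candidate
seed-transmitted or otherwise unsampled source).  Category percentages are
computed per block and averaged per treatment, which is the quantity the
chord diagrams display.

The full 2^3 category lattice is reported, including BulkSoil+Roots; a
``collapse_bulk_roots`` switch folds that logically-possible-but-rare cell
into BulkSoil+Rhizosphere+Roots for parity with displays that omit it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nodsource.core_io import (
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)

SOURCE_COMPARTMENTS = ("bulk_soil", "rhizosphere", "root")
_LABELS = {"bulk_soil": "BulkSoil", "rhizosphere": "Rhizosphere", "root": "Roots"}

#: canonical category order: singletons, pairs, the triple, then Unknown
CATEGORY_ORDER = (
    "BulkSoil",
    "Rhizosphere",
    "Roots",
    "BulkSoil+Rhizosphere",
    "Rhizosphere+Roots",
    "BulkSoil+Roots",
    "BulkSoil+Rhizosphere+Roots",
    "Unknown",
)


def category_from_membership(members) -> str:
    """Map a subset of source compartments to its category name."""
    members = set(members)
    unknown_keys = members - set(SOURCE_COMPARTMENTS)
    if unknown_keys:
        raise ValidationError(f"unknown source compartments: {sorted(unknown_keys)}")
    if not members:
        return "Unknown"
    return "+".join(_LABELS[c] for c in SOURCE_COMPARTMENTS if c in members)


@dataclass
class AttributionResult:
    """Per-block and treatment-mean source-category percentages.

    ``per_block`` has one row per (treatment, block, category) over the full
    lattice, with the number of nodule ASVs in the category, the percentage
    of the block's nodule ASVs, and the percentage of the block's nodule
    reads.  ``treatment_means`` averages the per-block percentages over the
    blocks present for each treatment.  ``classifications`` retains the raw
    per-ASV category assignment of every block for family summaries.
    """

    per_block: pd.DataFrame
    treatment_means: pd.DataFrame
    classifications: dict = field(default_factory=dict)  # (treatment, block) -> {asv: category}
    weights: str = "asv_count"
    categories: tuple = CATEGORY_ORDER

    def mean_percent(self, treatment: str, category: str) -> float:
        df = self.treatment_means
        row = df[(df["treatment"] == treatment) & (df["category"] == category)]
        return float(row["mean_percent"].iloc[0]) if len(row) else 0.0


def block_source_sets(
    counts: CountTable, meta: SampleMetadata, treatment: str, block: int
) -> dict:
    """Presence sets per compartment for one plot (union over its samples).

    Consumes a table already passed through the replicate-presence filter, so
    the sets reflect that filter.  Raises when the plot lacks a compartment
    entirely; an all-zero compartment yields an empty set with a warning.
    """
    sets = {}
    for comp in ("bulk_soil", "rhizosphere", "root", "nodule"):
        samples = [
            s
            for s in meta.samples_for(compartment=comp, treatment=treatment, block=block)
            if s in counts.data.columns
        ]
        if not samples:
            raise ValidationError(
                f"plot ({treatment}, block {block}) has no {comp} samples"
            )
        present = (counts.data[samples] > 0).any(axis=1)
        ids = set(present.index[present])
        if not ids:
            warnings.warn(
                f"plot ({treatment}, block {block}): compartment {comp} has no ASVs",
                stacklevel=2,
            )
        sets[comp] = ids
    return sets


def classify_sink_asvs(sink_set, sources: dict, collapse_bulk_roots: bool = False) -> dict:
    """Assign each sink ASV the category of the exact source subset holding it.

    ``sources`` must be keyed exactly by bulk_soil / rhizosphere / root.
    Every sink ASV receives exactly one category (asserted).
    """
    if set(sources) != set(SOURCE_COMPARTMENTS):
        raise ValidationError(
            f"sources must be keyed by {SOURCE_COMPARTMENTS}, got {sorted(sources)}"
        )
    out = {}
    for asv in sink_set:
        members = {c for c in SOURCE_COMPARTMENTS if asv in sources[c]}
        cat = category_from_membership(members)
        if collapse_bulk_roots and cat == "BulkSoil+Roots":
            cat = "BulkSoil+Rhizosphere+Roots"
        out[asv] = cat
    assert set(out) == set(sink_set), "classification must cover every sink ASV"
    return out


def attribution_percentages(
    counts: CountTable,
    meta: SampleMetadata,
    weights: str = "asv_count",
    collapse_bulk_roots: bool = False,
) -> AttributionResult:
    """Classify every plot's nodule ASVs and compute category percentages.

    Per block, ``percent`` = 100 x (ASVs in category) / (nodule ASVs in the
    block); ``read_percent`` weights each category by the block's nodule
    reads carried by its ASVs.  Treatment-level values are arithmetic means
    over the treatment's blocks; a block with an empty nodule roster is
    excluded from the mean with a warning.  ``weights`` selects which of the
    two percentages downstream consumers treat as primary.
    """
    if weights not in ("asv_count", "reads"):
        raise ValueError("weights must be 'asv_count' or 'reads'")
    categories = list(CATEGORY_ORDER)
    if collapse_bulk_roots:
        categories = [c for c in categories if c != "BulkSoil+Roots"]
    rows = []
    classifications = {}
    for treatment, block in meta.plots():
        sources = block_source_sets(counts, meta, treatment, block)
        sink = sources.pop("nodule")
        if not sink:
            warnings.warn(
                f"plot ({treatment}, block {block}) has an empty nodule set; "
                "excluded from treatment means",
                stacklevel=2,
            )
            continue
        classified = classify_sink_asvs(sink, sources, collapse_bulk_roots)
        classifications[(treatment, block)] = classified
        nod_samples = meta.samples_for(compartment="nodule", treatment=treatment, block=block)
        nod_samples = [s for s in nod_samples if s in counts.data.columns]
        nod_reads = counts.data.loc[sorted(sink), nod_samples].sum(axis=1)
        total_reads = float(nod_reads.sum())
        by_cat: dict[str, list] = {c: [] for c in categories}
        for asv, cat in classified.items():
            by_cat[cat].append(asv)
        for cat in categories:
            ids = by_cat[cat]
            reads = float(nod_reads.reindex(ids).sum()) if ids else 0.0
            rows.append(
                {
                    "treatment": treatment,
                    "block": block,
                    "category": cat,
                    "n_asvs": len(ids),
                    "percent": 100.0 * len(ids) / len(sink),
                    "read_percent": 100.0 * reads / total_reads if total_reads else 0.0,
                }
            )
    per_block = pd.DataFrame(rows)
    if per_block.empty:
        raise ValidationError("no plot produced a non-empty nodule roster")

    # invariants: percentages sum to 100 and counts to the roster size per block
    for (trt, blk), sub in per_block.groupby(["treatment", "block"]):
        assert abs(sub["percent"].sum() - 100.0) < 1e-9
        assert sub["n_asvs"].sum() == len(classifications[(trt, blk)])

    means = (
        per_block.groupby(["treatment", "category"], sort=False)[["percent", "read_percent"]]
        .mean()
        .rename(columns={"percent": "mean_percent", "read_percent": "mean_read_percent"})
        .reset_index()
    )
    n_blocks = per_block.groupby(["treatment", "category"], sort=False).size().to_numpy()
    means["n_blocks"] = n_blocks
    return AttributionResult(per_block, means, classifications, weights, tuple(categories))


def recruited_family_summary(
    result: AttributionResult, taxonomy: TaxonomyTable
) -> pd.DataFrame:
    """Family tallies per (treatment, category) with cross-treatment uniqueness.

    For each treatment, ASVs of a category are pooled over the treatment's
    blocks (distinct ids); families are counted by distinct ASVs.  A family is
    flagged ``unique`` within a category when only one treatment recruits it
    there.
    """
    pooled: dict[tuple[str, str], set] = {}
    for (treatment, _block), classified in result.classifications.items():
        for asv, cat in classified.items():
            pooled.setdefault((treatment, cat), set()).add(asv)
    rows = []
    for (treatment, cat), ids in sorted(pooled.items()):
        fams = taxonomy.family_of(sorted(ids))
        for family, n in fams.value_counts().items():
            rows.append(
                {"treatment": treatment, "category": cat, "family": family, "n_asvs": int(n)}
            )
    df = pd.DataFrame(rows, columns=["treatment", "category", "family", "n_asvs"])
    if df.empty:
        df["unique"] = pd.Series(dtype=bool)
        return df
    counts_per = df.groupby(["category", "family"])["treatment"].transform("nunique")
    df["unique"] = counts_per == 1
    return df


def chord_matrix(result: AttributionResult) -> pd.DataFrame:
    """Long-format source -> sink flow table of treatment-mean percentages.

    Every (treatment, category) pair of the lattice is emitted, zeros
    included, so the full set of possible flows is always visible; percents
    sum to 100 within each treatment.
    """
    treatments = list(pd.unique(result.treatment_means["treatment"]))
    rows = []
    for trt in treatments:
        for cat in result.categories:
            rows.append(
                {
                    "treatment": trt,
                    "source": cat,
                    "percent": result.mean_percent(trt, cat),
                }
            )
    df = pd.DataFrame(rows)
    sums = df.groupby("treatment")["percent"].sum()
    assert np.allclose(sums.to_numpy(), 100.0), "chord flows must sum to 100 per treatment"
    return df
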