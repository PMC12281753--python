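"""Organelle removal, replicate-presence filtering and CSS normalization.

The order of operations mirrors the analysis the pipeline implements:
chloroplast/mitochondrial ASVs are removed first, then endophytic
compartments (root, nodule) are filtered so that an ASV only counts as
present in a plot when it appears in at least ``min_reps`` of the plot's
replicate extractions, and finally counts are depth-corrected by
cumulative sum scaling (CSS).

CSS divides each sample by the cumulative sum of its counts up to a chosen
quantile of the sample's *positive* counts: for sample :math:`j` with
quantile level :math:`l`,

.. math:: s_j = \\sum_{i:\\, c_{ij} \\le q_j(l)} c_{ij}, \\qquad
          v_{ij} = \\frac{c_{ij}}{s_j}\\, N

where :math:`q_j(l)` is the ``l``-quantile (linear interpolation) of the
positive counts of sample :math:`j` and :math:`N` is a common output scale.
Counts equal to the quantile are included in the cumulative sum.  The
quantile level is fixed (default 0.5) rather than searched adaptively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nodsource.core_io import (
    REPLICATED_COMPARTMENTS,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)

_ORGANELLE_MARKERS = ("chloroplast", "mitochondri")


@dataclass
class OrganelleLog:
    """What :func:`remove_organelles` dropped and what it could not assess."""

    removed_asvs: list[str]
    reads_removed: pd.Series  # per sample
    uncovered_asvs: list[str]  # ASVs without taxonomy, retained

    def to_frame(self) -> pd.DataFrame:
        df = self.reads_removed.rename("reads_removed").to_frame()
        df.index.name = "sample_id"
        return df


@dataclass
class NormalizedTable:
    """CSS-normalized abundances with the per-sample scaling factors used."""

    data: pd.DataFrame  # ASVs x samples, float
    scaling_factors: pd.Series  # s_j per sample, > 0
    quantile_level: float
    output_scale: float

    @property
    def asv_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()


def remove_organelles(
    counts: CountTable, taxonomy: TaxonomyTable
) -> tuple[CountTable, OrganelleLog]:
    """Drop ASVs whose lineage names a chloroplast or mitochondrion at any rank.

    Matching is case-insensitive substring search over all ranks.  ASVs not
    covered by the taxonomy are retained and listed in the log.  Returns the
    filtered table and an :class:`OrganelleLog` with per-sample read tallies
    of what was removed (input totals = output totals + removed totals).
    """
    covered = [a for a in counts.asv_ids if a in taxonomy.data.index]
    uncovered = [a for a in counts.asv_ids if a not in taxonomy.data.index]
    hit = taxonomy.data.loc[covered].apply(
        lambda col: col.astype(str).str.lower().str.contains("|".join(_ORGANELLE_MARKERS)),
    ).any(axis=1)
    removed = hit.index[hit].tolist()
    kept = [a for a in counts.asv_ids if a not in set(removed)]
    reads_removed = counts.data.loc[removed].sum(axis=0)
    out = CountTable(counts.data.loc[kept].copy())
    if not kept:
        warnings.warn("organelle removal left an empty count table", stacklevel=2)
    return out, OrganelleLog(removed, reads_removed, uncovered)


def replicate_presence_filter(
    counts: CountTable,
    meta: SampleMetadata,
    min_reps: int = 2,
    compartments=REPLICATED_COMPARTMENTS,
) -> CountTable:
    """Per-plot presence filter for compartments with replicate extractions.

    Within each (compartment, treatment, block) plot group, an ASV's counts
    are zeroed across the group's samples unless the ASV has count > 0 in at
    least ``min_reps`` of the replicates.  Bulk-soil and rhizosphere samples
    pass through unchanged.  ASVs left all-zero across the whole table are
    dropped.  Idempotent; the output ASV set is a subset of the input's.
    """
    data = counts.data.copy()
    df = meta.data
    grouped = df[df["compartment"].isin(compartments)].groupby(
        ["compartment", "treatment", "block"], observed=True
    )
    for key, sub in grouped:
        samples = [s for s in sub.index if s in data.columns]
        if not samples:
            continue
        if min_reps > len(samples):
            raise ValidationError(
                f"min_reps={min_reps} exceeds the {len(samples)} replicates of plot {key}"
            )
        presence = (data[samples] > 0).sum(axis=1)
        fail = presence < min_reps
        data.loc[fail, samples] = 0
    data = data.loc[data.sum(axis=1) > 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # filtering can empty individual samples
        return CountTable(data)


def _css_factor(column: np.ndarray, quantile_level: float) -> float:
    positive = column[column > 0]
    if positive.size == 0:
        raise ValidationError("sample has no positive counts")
    q = np.quantile(positive, quantile_level)  # linear interpolation
    return float(column[column <= q].sum())


def css_normalize(
    counts: CountTable, quantile_level: float = 0.5, output_scale: float = 1000.0
) -> NormalizedTable:
    """Cumulative-sum-scaling normalization of a count table.

    Raises :class:`ValidationError` naming the sample if any sample is
    all-zero.  Zero counts map to zero values; within a sample the rank order
    of counts is preserved; multiplying a sample by a constant leaves its
    normalized vector unchanged (scale equivariance of :math:`s_j`).
    """
    if not 0 < quantile_level < 1:
        raise ValueError("quantile_level must lie in (0, 1)")
    if output_scale <= 0:
        raise ValueError("output_scale must be positive")
    factors = {}
    for sample in counts.sample_ids:
        col = counts.data[sample].to_numpy()
        try:
            factors[sample] = _css_factor(col, quantile_level)
        except ValidationError as exc:
            raise ValidationError(f"sample {sample!r}: {exc}") from exc
    s = pd.Series(factors, name="scaling_factor")
    values = counts.data.astype(float).div(s, axis=1) * output_scale
    return NormalizedTable(values, s, quantile_level, output_scale)
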