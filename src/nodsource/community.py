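"""Community structure: richness, Bray-Curtis, NMDS, PERMANOVA, Venn partitions.

PERMANOVA follows the distance-based partitioning of Anderson (2001) /
McArdle & Anderson (2001): with Gower-centred matrix
:math:`G = -\\tfrac12 J D^{(2)} J` (where :math:`D^{(2)}` holds squared
dissimilarities and :math:`J = I - \\mathbf{1}\\mathbf{1}'/n`), the total sum
of squares is :math:`\\operatorname{tr}(G) = \\tfrac1n \\sum_{i<j} d_{ij}^2`
and the sum of squares of a model term is the increment in
:math:`\\operatorname{tr}(H G)` when the term's columns join the design
(sequential, Type-I, in the order terms are listed -- the ``adonis``
convention).  Significance comes from free permutation of sample labels with
the :math:`(b+1)/(m+1)` p-value estimator, or exhaustive enumeration of all
:math:`n!` relabellings for tiny designs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from nodsource.core_io import (
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    UNASSIGNED,
    ValidationError,
)
from nodsource.preprocess import NormalizedTable


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample ids")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValidationError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    """NMDS embedding: coordinates plus Kruskal stress-1 of the best run."""

    sample_ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


@dataclass
class PermanovaResult:
    """Per-term Df / SumOfSqs / R2 / F / p plus Residual and Total rows."""

    table: pd.DataFrame
    n_perm: int | str
    seed: int | None

    def __post_init__(self) -> None:
        terms = [t for t in self.table.index if t not in ("Residual", "Total")]
        r2 = self.table.loc[terms + ["Residual"], "R2"].sum()
        assert abs(r2 - 1.0) < 1e-9, "R2 components must sum to 1"
        df_sum = self.table.loc[terms + ["Residual"], "Df"].sum()
        assert df_sum == self.table.loc["Total", "Df"], "Df must sum to n - 1"


@dataclass
class VennPartition:
    """Disjoint assignment of ASVs to subsets of groups, with read shares."""

    groups: list[str]
    cells: dict  # tuple(group labels) -> set of ASV ids
    read_share: dict  # same keys -> fraction of total reads

    def __post_init__(self) -> None:
        all_ids: set = set()
        total = 0
        for key, ids in self.cells.items():
            assert not (all_ids & ids), f"Venn cells overlap at {key}"
            all_ids |= ids
            total += len(ids)
        assert total == len(all_ids)
        for share in self.read_share.values():
            assert -1e-12 <= share <= 1 + 1e-12

    def cell(self, *groups) -> set:
        return self.cells.get(tuple(groups), set())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cell": "&".join(key), "n_asvs": len(ids), "read_share": self.read_share[key]}
            for key, ids in sorted(self.cells.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {"cell": "&".join(key), "asv_id": asv}
            for key, ids in sorted(self.cells.items(), key=lambda kv: (len(kv[0]), kv[0]))
            for asv in sorted(ids)
        ]
        return pd.DataFrame(rows, columns=["cell", "asv_id"])


# ---------------------------------------------------------------------------
# richness and distances
# ---------------------------------------------------------------------------


def observed_richness(
    counts: CountTable | NormalizedTable,
    meta: SampleMetadata | None = None,
    group_by: list[str] | None = None,
) -> pd.Series:
    """Number of ASVs with count > 0, per sample or per pooled group union.

    With ``group_by`` (e.g. ``["compartment", "treatment", "block"]``) the
    samples of each group are pooled and distinct ASVs counted once.
    """
    presence = counts.data > 0
    if group_by is None:
        return presence.sum(axis=0).rename("observed_asvs")
    if meta is None:
        raise ValueError("group_by requires sample metadata")
    out = {}
    for key, sub in meta.data.groupby(group_by, observed=True):
        samples = [s for s in sub.index if s in presence.columns]
        if samples:
            out[key] = int(presence[samples].any(axis=1).sum())
    ser = pd.Series(out, name="observed_asvs")
    ser.index.names = group_by
    return ser


def bray_curtis(values: CountTable | NormalizedTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarities d_ij = sum|x-y| / sum(x+y) between samples.

    A pair of all-zero samples is assigned distance 0 with a warning.
    """
    x = values.data.to_numpy(dtype=float).T  # samples x ASVs
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    if (x < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative values")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair(s): distance set to 0", stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(list(values.data.columns), d)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress1(d: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 with monotone (isotonic) disparities."""
    dist_hat = pdist(coords)
    dissim = squareform(d, checks=False)
    order = np.argsort(dissim, kind="stable")
    disp = np.empty_like(dist_hat)
    disp[order] = IsotonicRegression().fit_transform(dissim[order], dist_hat[order])
    denom = float((dist_hat**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist_hat - disp) ** 2).sum() / denom))


def nmds_embed(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1 by SMACOF majorization.

    Runs ``n_restarts`` random initializations plus one warm start from
    classical (metric) scaling and keeps the lowest-stress configuration.
    """
    n = d.n
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of samples ({n})")
    if np.allclose(d.d, 0):
        return OrdinationResult(d.sample_ids, np.zeros((n, k)), 0.0, n_restarts, seed)
    rng = np.random.default_rng(seed)
    candidates = []
    warm = _classical_mds(d.d, k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords, _ = smacof(
            d.d, metric=False, n_components=k, init=warm, n_init=1,
            max_iter=max_iter, eps=1e-9, normalized_stress=True,
        )
    candidates.append(coords)
    if n_restarts > 0:
        state = int(rng.integers(0, 2**31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, _ = smacof(
                d.d, metric=False, n_components=k, n_init=n_restarts,
                max_iter=max_iter, eps=1e-9, random_state=state,
                normalized_stress=True,
            )
        candidates.append(coords)
    scored = [(_stress1(d.d, c), c) for c in candidates]
    stress, best = min(scored, key=lambda sc: sc[0])
    return OrdinationResult(d.sample_ids, best, stress, n_restarts, seed)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _term_dummies(meta_df: pd.DataFrame, term: str) -> np.ndarray:
    factors = term.split(":")
    for f in factors:
        if f not in meta_df.columns:
            raise ValidationError(f"term {f!r} not found in metadata")
        if meta_df[f].nunique() < 2:
            raise ValidationError(f"term {f!r} has a single level")
    combined = meta_df[factors[0]].astype(str)
    for f in factors[1:]:
        combined = combined + ":" + meta_df[f].astype(str)
    return pd.get_dummies(combined).to_numpy(dtype=float)


def permanova(
    d: DistanceMatrix,
    meta: SampleMetadata | pd.DataFrame,
    terms: list[str],
    n_perm: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``terms`` are factor names from the metadata, in fitting order; an
    interaction is written ``"a:b"``.  Sums of squares are sequential
    (Type-I).  ``n_perm="exhaustive"`` enumerates all n! relabellings
    (n <= 9); otherwise ``n_perm`` random permutations are drawn and
    p = (b + 1) / (n_perm + 1).
    """
    meta_df = meta.data if isinstance(meta, SampleMetadata) else meta
    missing = [s for s in d.sample_ids if s not in meta_df.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    meta_df = meta_df.loc[d.sample_ids]
    n = d.n

    dmat2 = d.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ dmat2 @ j
    ss_total = float(np.trace(g))

    # orthonormal bases of the cumulative design after each term
    bases: list[np.ndarray] = []
    dfs: list[int] = []
    x = np.ones((n, 1))
    rank_prev = 1
    for term in terms:
        x = np.hstack([x, _term_dummies(meta_df, term)])
        q, r = np.linalg.qr(x)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        qk = q[:, keep]
        rank = qk.shape[1]
        dfs.append(rank - rank_prev)
        rank_prev = rank
        bases.append(qk)
    df_res = (n - 1) - sum(dfs)
    if df_res <= 0:
        raise ValidationError("model saturates the design; no residual degrees of freedom")

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tr_prev = 0.0
        ss = np.empty(len(terms))
        for i, qk in enumerate(bases):
            tr = float(np.trace(qk.T @ gmat @ qk))
            ss[i] = tr - tr_prev
            tr_prev = tr
        ss_res = float(np.trace(gmat)) - tr_prev
        f = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, f

    ss_terms, f_obs = term_stats(g)
    ss_res = ss_total - ss_terms.sum()

    if n_perm == "exhaustive":
        if n > 9:
            raise ValidationError("exhaustive enumeration limited to n <= 9 samples")
        count = np.zeros(len(terms))
        m = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            _, f_star = term_stats(g[np.ix_(p, p)])
            count += f_star >= f_obs - 1e-12
            m += 1
        pvals = count / m
        n_perm_used: int | str = "exhaustive"
    else:
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(terms))
        for _ in range(int(n_perm)):
            p = rng.permutation(n)
            _, f_star = term_stats(g[np.ix_(p, p)])
            exceed += f_star >= f_obs - 1e-12
        pvals = (exceed + 1) / (int(n_perm) + 1)
        n_perm_used = int(n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "Df": dfs[i],
                "SumOfSqs": ss_terms[i],
                "R2": ss_terms[i] / ss_total,
                "F": f_obs[i],
                "p": pvals[i],
            }
        )
    table = pd.DataFrame(rows, index=terms)
    table.loc["Residual"] = [df_res, ss_res, ss_res / ss_total, np.nan, np.nan]
    table.loc["Total"] = [n - 1, ss_total, 1.0, np.nan, np.nan]
    table["Df"] = table["Df"].astype(int)
    return PermanovaResult(table, n_perm_used, seed)


# ---------------------------------------------------------------------------
# Venn partition and family aggregation
# ---------------------------------------------------------------------------


def venn_partition(
    counts: CountTable | NormalizedTable,
    meta: SampleMetadata,
    group_factor: str = "treatment",
    within: str | None = None,
) -> VennPartition:
    """Partition ASVs by the exact subset of groups in which they occur.

    Group presence pools a group's samples (count > 0 in any of them).  With
    ``within`` set, only samples of that compartment participate and read
    shares are fractions of that compartment's total reads.
    """
    meta_df = meta.data
    if within is not None:
        meta_df = meta_df[meta_df["compartment"] == within]
    meta_df = meta_df.loc[[s for s in meta_df.index if s in counts.data.columns]]
    levels = [g for g in _ordered_levels(meta_df[group_factor])]
    if len(levels) < 2:
        raise ValidationError(f"venn_partition needs >= 2 groups, got {levels}")
    data = counts.data[meta_df.index.tolist()]
    presence = {}
    for g in levels:
        samples = meta_df.index[meta_df[group_factor] == g].tolist()
        presence[g] = (data[samples] > 0).any(axis=1)
    pres = pd.DataFrame(presence)
    pres = pres[pres.any(axis=1)]
    total_reads = float(data.to_numpy().sum())
    cells: dict = {}
    shares: dict = {}
    masks = pres.apply(lambda row: tuple(g for g in levels if row[g]), axis=1)
    for key in (k for r in range(1, len(levels) + 1) for k in itertools.combinations(levels, r)):
        ids = set(masks.index[masks == key])
        if not ids:
            continue
        cells[key] = ids
        reads = float(data.loc[sorted(ids)].to_numpy().sum())
        shares[key] = reads / total_reads if total_reads else 0.0
    return VennPartition(levels, cells, shares)


def _ordered_levels(series: pd.Series) -> list:
    from nodsource.core_io import TREATMENTS

    levels = list(pd.unique(series))
    if set(levels) <= set(TREATMENTS):
        return [t for t in TREATMENTS if t in levels]
    return sorted(levels)


def family_aggregate(
    values: CountTable | NormalizedTable,
    taxonomy: TaxonomyTable,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Sum abundances of ASVs sharing a family; unassigned pooled together.

    ``top_n`` keeps the N families with the highest mean relative abundance
    across samples.
    """
    fams = taxonomy.data["family"].reindex(values.data.index).fillna(UNASSIGNED)
    agg = values.data.groupby(fams.to_numpy()).sum()
    agg.index.name = "family"
    agg = agg.loc[agg.sum(axis=1) > 0]
    if top_n is not None:
        totals = agg.sum(axis=0)
        totals[totals == 0] = 1.0
        mean_rel = (agg / totals).mean(axis=1)
        keep = mean_rel.sort_values(ascending=False, kind="stable").index[:top_n]
        agg = agg.loc[[f for f in agg.index if f in set(keep)]]
    return agg
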