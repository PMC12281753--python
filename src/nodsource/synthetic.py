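"""Synthetic community generator with known per-ASV provenance labels.

The generator emulates the field design the pipeline targets: four
fertilization treatments x three blocks, one bulk-soil and one rhizosphere
sample per plot, and three replicate extractions each for roots and nodules.
Community membership follows a stepwise path: bulk soil samples the regional
taxon pool, the rhizosphere is a Bernoulli-thinned subset of bulk (plus a
small colonist fraction absent from bulk), roots a thinned subset of the
rhizosphere (plus root colonists), and taxa absent from all three form the
plot's seed pool.  Each plot's nodule roster is drawn so that the expected
fraction of nodule ASVs in each source category equals a configurable vector
``pi`` over the 2^3 category lattice plus Unknown; Unknown members come from
the seed pool (taxa present *only* in nodules, standing in for seed
transmission).  When a category's realized membership class is smaller than
its draw, additional taxa are drafted from the seed pool and their plot
membership set to exactly that category, so truth labels always match
realized memberships; the generator errors only when the seed pool itself
cannot cover the demand.

Counts are Dirichlet-multinomial: per sample, relative abundances are drawn
from a Dirichlet centred on the roster's (log-normal) regional abundances
with mean per-taxon concentration ``dirichlet_alpha``, then reads are
multinomial at the configured depth.  Replicates share the plot roster but
resample both steps, so replicate-to-replicate dropout is realistic and the
two-of-three presence filter is non-trivially exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nodsource.core_io import (
    RANKS,
    TREATMENTS,
    UNASSIGNED,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)
from nodsource.source_tracking import (
    CATEGORY_ORDER,
    SOURCE_COMPARTMENTS,
    classify_sink_asvs,
)

#: default nodule source-category proportions; the pattern mirrors replicated
#: field observations: seed-borne/unknown taxa dominate, roots are the main
#: known source, bulk soil alone contributes nothing.
DEFAULT_PI = {
    "BulkSoil": 0.0,
    "Rhizosphere": 0.04,
    "Roots": 0.25,
    "BulkSoil+Rhizosphere": 0.0,
    "Rhizosphere+Roots": 0.08,
    "BulkSoil+Roots": 0.0,
    "BulkSoil+Rhizosphere+Roots": 0.21,
    "Unknown": 0.42,
}

FAMILY_VOCABULARY = (
    "Rhizobiaceae", "Pseudomonadaceae", "Beijerinckiaceae", "Flavobacteriaceae",
    "Sphingomonadaceae", "Micrococcaceae", "Gaiellaceae", "Oxalobacteraceae",
    "Ktedonobacteraceae", "Rhodanobacteraceae", "Caulobacteraceae",
    "Steroidobacteraceae", "Blastocatellaceae", "Acidobacteriaceae",
    "Chthoniobacteraceae", "Alcaligenaceae", "Streptomycetaceae", "Bacillaceae",
    "Burkholderiaceae", "Xanthomonadaceae", "Nocardioidaceae", "Chitinophagaceae",
    "Comamonadaceae", "Paenibacillaceae",
)

_MOCK_GENERA = (
    "Pseudomonas", "Escherichia", "Salmonella", "Lactobacillus",
    "Enterococcus", "Staphylococcus", "Listeria", "Bacillus",
)

_CATEGORY_MEMBERS = {
    "BulkSoil": ("bulk_soil",),
    "Rhizosphere": ("rhizosphere",),
    "Roots": ("root",),
    "BulkSoil+Rhizosphere": ("bulk_soil", "rhizosphere"),
    "Rhizosphere+Roots": ("rhizosphere", "root"),
    "BulkSoil+Roots": ("bulk_soil", "root"),
    "BulkSoil+Rhizosphere+Roots": ("bulk_soil", "rhizosphere", "root"),
    "Unknown": (),
}


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Retention probabilities describe the stepwise habitat filtering
    (bulk occupancy of the regional pool, bulk -> rhizosphere, rhizosphere ->
    root); the epsilon rates admit colonists that skip a step, so every
    membership class of the lattice is realizable.  ``dirichlet_alpha`` is the
    mean per-taxon Dirichlet concentration (smaller = more overdispersion and
    replicate dropout).
    """

    n_taxa: int = 800
    treatments: tuple = TREATMENTS
    n_blocks: int = 3
    n_replicates: int = 3  # root and nodule extractions per plot
    depth: int = 50_000
    p_bulk: float = 0.75
    p_rhizo: float = 0.6  # bulk -> rhizosphere retention
    p_root: float = 0.35  # rhizosphere -> root retention
    eps_rhizo: float = 0.08  # rhizosphere colonists absent from bulk
    eps_root: float = 0.3  # root colonists absent from the rhizosphere
    n_nodule_asvs: int = 80
    pi: dict = field(default_factory=lambda: dict(DEFAULT_PI))
    dirichlet_alpha: float = 2.0
    abund_sigma: float = 1.0
    organelle_fraction: float = 0.0
    mock_sample: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = set(self.pi) - set(CATEGORY_ORDER)
        if missing:
            raise ValidationError(f"unknown categories in pi: {sorted(missing)}")
        self.pi = {c: float(self.pi.get(c, 0.0)) for c in CATEGORY_ORDER}
        total = sum(self.pi.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"pi must sum to 1 (got {total})")
        if min(self.pi.values()) < 0:
            raise ValidationError("pi entries must be non-negative")
        for name in ("p_rhizo", "p_root"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if not 0 < self.p_bulk <= 1:
            raise ValidationError("p_bulk must lie in (0, 1]")
        if self.depth < 100:
            raise ValidationError("depth must be >= 100")
        if self.dirichlet_alpha <= 0:
            raise ValidationError("dirichlet_alpha must be positive")
        if not 0 <= self.organelle_fraction < 1:
            raise ValidationError("organelle_fraction must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset: labels, rosters and pi."""

    pi: dict
    per_plot: dict  # (treatment, block) -> {"categories": {...}, "sources": {...}}
    mock_sample_id: str | None = None
    seed: int | None = None

    def categories(self, treatment: str, block: int) -> dict:
        return self.per_plot[(treatment, block)]["categories"]

    def sources(self, treatment: str, block: int) -> dict:
        return self.per_plot[(treatment, block)]["sources"]

    def true_treatment_means(self) -> pd.DataFrame:
        """Realized category fractions per treatment (mean over blocks), in %."""
        rows = []
        for (trt, blk), plot in self.per_plot.items():
            cats = pd.Series(plot["categories"])
            frac = cats.value_counts(normalize=True)
            for cat in CATEGORY_ORDER:
                rows.append(
                    {"treatment": trt, "block": blk, "category": cat,
                     "percent": 100.0 * float(frac.get(cat, 0.0))}
                )
        df = pd.DataFrame(rows)
        return (
            df.groupby(["treatment", "category"], sort=False)["percent"]
            .mean()
            .rename("mean_percent")
            .reset_index()
        )

    def to_json(self, path) -> None:
        doc = {
            "pi": self.pi,
            "mock_sample_id": self.mock_sample_id,
            "seed": self.seed,
            "plots": [
                {
                    "treatment": trt,
                    "block": blk,
                    "categories": plot["categories"],
                    "sources": {c: sorted(ids) for c, ids in plot["sources"].items()},
                }
                for (trt, blk), plot in self.per_plot.items()
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = json.load(fh)
        per_plot = {
            (p["treatment"], int(p["block"])): {
                "categories": p["categories"],
                "sources": {c: set(ids) for c, ids in p["sources"].items()},
            }
            for p in doc["plots"]
        }
        return cls(doc["pi"], per_plot, doc.get("mock_sample_id"), doc.get("seed"))


def _dm_counts(rng: np.random.Generator, props: np.ndarray, depth: int, alpha_mean: float):
    alpha = alpha_mean * len(props) * props
    theta = rng.dirichlet(np.clip(alpha, 1e-8, None))
    theta = theta / theta.sum()
    return rng.multinomial(depth, theta)


def generate_dataset(
    config: SimConfig,
) -> tuple[CountTable, SampleMetadata, TaxonomyTable, SyntheticTruth]:
    """Generate (counts, metadata, taxonomy, truth) for one synthetic study.

    Deterministic given ``config.seed``.  Raises :class:`ValidationError`
    when ``pi`` demands more taxa of a category than the plot's seed pool can
    supply (e.g. a large Unknown fraction with an exhausted seed pool).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_taxa
    asv_ids = np.array([f"ASV{i + 1:05d}" for i in range(n)])
    abund = rng.lognormal(mean=0.0, sigma=cfg.abund_sigma, size=n)

    # taxonomy: family labels from a fixed vocabulary (realistic names only)
    fam_idx = rng.integers(0, len(FAMILY_VOCABULARY), size=n)
    tax_rows = []
    for i, asv in enumerate(asv_ids):
        fam = FAMILY_VOCABULARY[fam_idx[i]]
        tax_rows.append(
            ["Bacteria", UNASSIGNED, UNASSIGNED, UNASSIGNED, fam, f"{fam[:-4]}", UNASSIGNED]
        )
    taxonomy_df = pd.DataFrame(tax_rows, index=asv_ids, columns=list(RANKS))

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    per_plot: dict = {}

    cat_probs = np.array([cfg.pi[c] for c in CATEGORY_ORDER])

    for trt in cfg.treatments:
        for blk in range(1, cfg.n_blocks + 1):
            in_bulk = rng.random(n) < cfg.p_bulk
            in_rhizo = np.where(
                in_bulk, rng.random(n) < cfg.p_rhizo, rng.random(n) < cfg.eps_rhizo
            )
            in_root = np.where(
                in_rhizo, rng.random(n) < cfg.p_root, rng.random(n) < cfg.eps_root
            )
            membership = {
                "bulk_soil": set(asv_ids[in_bulk]),
                "rhizosphere": set(asv_ids[in_rhizo]),
                "root": set(asv_ids[in_root]),
            }
            seed_pool = set(asv_ids) - membership["bulk_soil"] - membership["rhizosphere"] - membership["root"]

            # exact-membership class of every taxon
            klass: dict[str, list] = {c: [] for c in CATEGORY_ORDER}
            for asv in asv_ids:
                members = frozenset(c for c in SOURCE_COMPARTMENTS if asv in membership[c])
                if members:
                    cat = "+".join(
                        {"bulk_soil": "BulkSoil", "rhizosphere": "Rhizosphere", "root": "Roots"}[c]
                        for c in SOURCE_COMPARTMENTS
                        if c in members
                    )
                    klass[cat].append(asv)

            need = rng.multinomial(cfg.n_nodule_asvs, cat_probs)
            roster: dict[str, str] = {}
            drafted: dict[str, list] = {}
            seed_list = sorted(seed_pool)
            for cat, n_need in zip(CATEGORY_ORDER, need):
                if n_need == 0 or cat == "Unknown":
                    continue
                pool = klass[cat]
                take = min(len(pool), int(n_need))
                chosen = list(rng.choice(pool, size=take, replace=False)) if take else []
                short = int(n_need) - take
                if short:
                    if short > len(seed_list):
                        raise ValidationError(
                            f"plot ({trt}, block {blk}): pi demands {n_need} "
                            f"{cat} taxa but only {len(pool)} exist and the seed "
                            f"pool cannot cover the shortfall"
                        )
                    extra = list(rng.choice(seed_list, size=short, replace=False))
                    seed_list = [a for a in seed_list if a not in set(extra)]
                    for comp in _CATEGORY_MEMBERS[cat]:
                        membership[comp].update(extra)
                    chosen.extend(extra)
                    drafted.setdefault(cat, []).extend(extra)
                for asv in chosen:
                    roster[asv] = cat
            n_unknown = int(need[CATEGORY_ORDER.index("Unknown")])
            if n_unknown:
                if n_unknown > len(seed_list):
                    raise ValidationError(
                        f"plot ({trt}, block {blk}): pi demands {n_unknown} Unknown "
                        f"taxa but the seed pool holds only {len(seed_list)}"
                    )
                for asv in rng.choice(seed_list, size=n_unknown, replace=False):
                    roster[asv] = "Unknown"

            # truth labels must match realized memberships by construction
            check = classify_sink_asvs(set(roster), membership)
            assert check == roster, "generator produced inconsistent truth labels"

            per_plot[(trt, blk)] = {
                "categories": dict(roster),
                "sources": {c: set(membership[c]) for c in SOURCE_COMPARTMENTS},
            }

            def sample_counts(member_ids: set) -> np.ndarray:
                idx = np.array(sorted(np.flatnonzero(np.isin(asv_ids, sorted(member_ids)))))
                col = np.zeros(n, dtype=np.int64)
                if idx.size == 0:
                    return col
                props = abund[idx] / abund[idx].sum()
                col[idx] = _dm_counts(rng, props, cfg.depth, cfg.dirichlet_alpha)
                return col

            for comp, reps in (
                ("bulk_soil", 1),
                ("rhizosphere", 1),
                ("root", cfg.n_replicates),
                ("nodule", cfg.n_replicates),
            ):
                members = set(roster) if comp == "nodule" else membership[comp]
                for rep in range(1, reps + 1):
                    sid = f"{trt}_b{blk}_{comp}_r{rep}"
                    columns[sid] = sample_counts(members)
                    meta_rows.append(
                        {"sample_id": sid, "compartment": comp, "treatment": trt,
                         "block": blk, "replicate": rep}
                    )

    counts_df = pd.DataFrame(columns, index=asv_ids)

    mock_sample_id = None
    if cfg.mock_sample:
        mock_sample_id = "MOCK1"
        mock_ids = [f"MOCKASV{i + 1}" for i in range(len(_MOCK_GENERA))]
        mock_counts = rng.multinomial(cfg.depth, np.full(len(mock_ids), 1 / len(mock_ids)))
        extra = pd.DataFrame(0, index=mock_ids, columns=counts_df.columns, dtype=np.int64)
        counts_df = pd.concat([counts_df, extra])
        counts_df[mock_sample_id] = 0
        counts_df.loc[mock_ids, mock_sample_id] = mock_counts
        mock_tax = pd.DataFrame(
            [["Bacteria"] + [UNASSIGNED] * 4 + [g, UNASSIGNED] for g in _MOCK_GENERA],
            index=mock_ids,
            columns=list(RANKS),
        )
        taxonomy_df = pd.concat([taxonomy_df, mock_tax])

    counts_df = counts_df.loc[counts_df.sum(axis=1) > 0]
    counts = CountTable(counts_df)
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    taxonomy = TaxonomyTable(taxonomy_df.loc[taxonomy_df.index.intersection(counts.data.index, sort=False)])
    truth = SyntheticTruth(dict(cfg.pi), per_plot, mock_sample_id, cfg.seed)

    if cfg.organelle_fraction > 0:
        counts, org_tax = spike_organelles(counts, meta, cfg.organelle_fraction)
        taxonomy = TaxonomyTable(pd.concat([taxonomy.data, org_tax]))
    return counts, meta, taxonomy, truth


def spike_organelles(
    counts: CountTable,
    meta: SampleMetadata,
    fraction: float,
    compartments=("root", "nodule"),
) -> tuple[CountTable, pd.DataFrame]:
    """Add chloroplast/mitochondrial reads to plant-associated samples.

    Each root/nodule sample gains ``round(fraction * its total)`` organelle
    reads split over one chloroplast and one mitochondrial ASV, so organelle
    removal restores the original totals exactly.  ``fraction = 0`` is the
    identity.  Returns the spiked table and the organelle taxonomy rows.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("fraction must lie in [0, 1)")
    if fraction == 0:
        return CountTable(counts.data.copy()), pd.DataFrame(columns=list(RANKS))
    data = counts.data.copy()
    chloro = pd.Series(0, index=data.columns, dtype=np.int64)
    mito = pd.Series(0, index=data.columns, dtype=np.int64)
    targets = meta.data.index[meta.data["compartment"].isin(compartments)]
    for sid in (s for s in targets if s in data.columns):
        added = int(round(fraction * data[sid].sum()))
        chloro[sid] = added - added // 2
        mito[sid] = added // 2
    data.loc["ORGANELLE_CHLORO"] = chloro
    data.loc["ORGANELLE_MITO"] = mito
    tax = pd.DataFrame(
        [
            ["Bacteria", "Cyanobacteria", UNASSIGNED, "Chloroplast", UNASSIGNED, UNASSIGNED, UNASSIGNED],
            ["Bacteria", "Proteobacteria", UNASSIGNED, UNASSIGNED, "Mitochondria", UNASSIGNED, UNASSIGNED],
        ],
        index=["ORGANELLE_CHLORO", "ORGANELLE_MITO"],
        columns=list(RANKS),
    )
    return CountTable(data), tax
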