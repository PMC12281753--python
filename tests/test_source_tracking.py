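import itertools

import numpy as np
import pandas as pd
import pytest

from nodsource.core_io import ValidationError
from nodsource.source_tracking import (
    CATEGORY_ORDER,
    attribution_percentages,
    block_source_sets,
    category_from_membership,
    chord_matrix,
    classify_sink_asvs,
    recruited_family_summary,
)
from nodsource.preprocess import replicate_presence_filter
from tests.conftest import make_counts, make_meta, make_taxonomy

SOURCES = ("bulk_soil", "rhizosphere", "root")


def classify_oracle(sink, sources):
    """Brute-force: check all 2^3 membership subsets per ASV."""
    out = {}
    for asv in sink:
        for subset in itertools.chain.from_iterable(
            itertools.combinations(SOURCES, r) for r in range(4)
        ):
            if all(asv in sources[c] for c in subset) and all(
                asv not in sources[c] for c in SOURCES if c not in subset
            ):
                out[asv] = category_from_membership(subset)
    return out


class TestClassify:
    def test_enumerated_example(self):
        sources = {
            "bulk_soil": {"A", "B", "C"},
            "rhizosphere": {"B", "C", "D"},
            "root": {"C", "D", "E"},
        }
        got = classify_sink_asvs({"C", "D", "E", "F"}, sources)
        assert got == {
            "C": "BulkSoil+Rhizosphere+Roots",
            "D": "Rhizosphere+Roots",
            "E": "Roots",
            "F": "Unknown",
        }

    def test_sink_subset_of_roots(self):
        sources = {"bulk_soil": set(), "rhizosphere": set(), "root": {"A", "B"}}
        got = classify_sink_asvs({"A", "B"}, sources)
        assert set(got.values()) == {"Roots"}

    def test_empty_sink(self):
        sources = {c: {"A"} for c in SOURCES}
        assert classify_sink_asvs(set(), sources) == {}

    def test_wrong_source_keys_rejected(self):
        with pytest.raises(ValidationError):
            classify_sink_asvs({"A"}, {"bulk_soil": set(), "leaf": set(), "root": set()})

    def test_collapse_bulk_roots_option(self):
        sources = {"bulk_soil": {"A"}, "rhizosphere": set(), "root": {"A"}}
        assert classify_sink_asvs({"A"}, sources)["A"] == "BulkSoil+Roots"
        assert (
            classify_sink_asvs({"A"}, sources, collapse_bulk_roots=True)["A"]
            == "BulkSoil+Rhizosphere+Roots"
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bitmask_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"T{i}" for i in range(int(rng.integers(5, 51)))]
        sources = {
            c: set(rng.choice(universe, size=rng.integers(0, len(universe)), replace=False))
            for c in SOURCES
        }
        sink = set(rng.choice(universe, size=rng.integers(1, len(universe)), replace=False))
        got = classify_sink_asvs(sink, sources)
        assert got == classify_oracle(sink, sources)
        assert set(got) == sink  # partition: every sink ASV classified once

    @pytest.mark.parametrize("seed", range(10))
    def test_monotonicity_adding_sources_never_creates_unknown(self, seed):
        rng = np.random.default_rng(100 + seed)
        universe = [f"T{i}" for i in range(30)]
        sources = {
            c: set(rng.choice(universe, size=10, replace=False)) for c in SOURCES
        }
        sink = set(rng.choice(universe, size=15, replace=False))
        before = classify_sink_asvs(sink, sources)
        extra = str(rng.choice(sorted(sink)))
        comp = str(rng.choice(SOURCES))
        grown = {c: set(v) for c, v in sources.items()}
        grown[comp].add(extra)
        after = classify_sink_asvs(sink, grown)
        for asv in sink:
            if before[asv] == after[asv]:
                continue
            assert asv == extra
            assert after[asv] != "Unknown"
            # the new category must include the grown compartment's label
            assert category_from_membership({comp}).strip("+") in after[asv]


class TestBlockSourceSets:
    def test_sets_reflect_replicate_filter(self, plot_meta):
        samples = plot_meta.data.index.tolist()
        mat = pd.DataFrame(0, index=["A", "C"], columns=samples)
        # roots block 1: A in 2 of 3 reps, C in 1 of 3
        mat.loc["A", ["rt1_1", "rt1_2"]] = [1, 2]
        mat.loc["C", "rt1_2"] = 4
        # keep every sample non-empty via nodule/bulk reads
        mat.loc["A", [s for s in samples if not s.startswith("rt")]] = 1
        mat.loc["A", "rt1_3"] = 0
        mat.loc["C", ["rt2_1", "rt2_2"]] = 1
        ct = make_counts(mat.to_numpy(), asv_ids=["A", "C"], sample_ids=samples)
        filtered = replicate_presence_filter(ct, plot_meta)
        sets = block_source_sets(filtered, plot_meta, "P0", 1)
        assert sets["root"] == {"A"}

    def test_missing_compartment_named(self):
        meta = make_meta([("n1", "nodule", "P0", 1, 1)])
        ct = make_counts([[1]], sample_ids=["n1"])
        with pytest.raises(ValidationError, match="bulk_soil"):
            block_source_sets(ct, meta, "P0", 1)

    def test_union_has_set_semantics(self, plot_meta):
        samples = plot_meta.data.index.tolist()
        mat = pd.DataFrame(1, index=["A"], columns=samples)
        ct = make_counts(mat.to_numpy(), asv_ids=["A"], sample_ids=samples)
        sets = block_source_sets(ct, plot_meta, "P0", 1)
        assert sets["root"] == {"A"}  # appears once despite 3 replicates


def single_plot_attribution(category_of: dict):
    """Build a one-plot dataset whose nodule ASVs classify as requested."""
    rows = [("bs", "bulk_soil", "P0", 1, 1), ("rz", "rhizosphere", "P0", 1, 1)]
    rows += [(f"rt{r}", "root", "P0", 1, r) for r in (1, 2, 3)]
    rows += [(f"nd{r}", "nodule", "P0", 1, r) for r in (1, 2, 3)]
    meta = make_meta(rows)
    samples = [r[0] for r in rows]
    members = {
        "BulkSoil": ("bs",),
        "Rhizosphere": ("rz",),
        "Roots": ("rt1", "rt2", "rt3"),
        "BulkSoil+Rhizosphere": ("bs", "rz"),
        "Rhizosphere+Roots": ("rz", "rt1", "rt2"),
        "BulkSoil+Roots": ("bs", "rt1", "rt2"),
        "BulkSoil+Rhizosphere+Roots": ("bs", "rz", "rt1", "rt2"),
        "Unknown": (),
    }
    mat = pd.DataFrame(0, index=list(category_of), columns=samples)
    for asv, cat in category_of.items():
        mat.loc[asv, ["nd1", "nd2", "nd3"]] = 1
        for s in members[cat]:
            mat.loc[asv, s] = 1
    # keep bulk/rhizo samples non-empty
    mat.loc["filler"] = 0
    mat.loc["filler", ["bs", "rz", "rt1", "rt2", "rt3"]] = 1
    ct = make_counts(mat.to_numpy(), asv_ids=list(mat.index), sample_ids=samples)
    return ct, meta


class TestAttribution:
    def test_one_asv_per_category(self):
        cats = {
            "a1": "BulkSoil+Rhizosphere+Roots",
            "a2": "Rhizosphere+Roots",
            "a3": "Roots",
            "a4": "Unknown",
        }
        ct, meta = single_plot_attribution(cats)
        res = attribution_percentages(ct, meta)
        blk = res.per_block.set_index("category")
        for cat in cats.values():
            assert blk.loc[cat, "percent"] == pytest.approx(25.0)
        for cat in set(CATEGORY_ORDER) - set(cats.values()):
            assert blk.loc[cat, "percent"] == 0.0
        assert blk["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        assert blk["n_asvs"].sum() == 4

    def test_identical_blocks_mean_equals_block(self):
        rows = []
        for blk in (1, 2, 3):
            rows += [(f"bs{blk}", "bulk_soil", "P0", blk, 1), (f"rz{blk}", "rhizosphere", "P0", blk, 1)]
            rows += [(f"rt{blk}_{r}", "root", "P0", blk, r) for r in (1, 2, 3)]
            rows += [(f"nd{blk}_{r}", "nodule", "P0", blk, r) for r in (1, 2, 3)]
        meta = make_meta(rows)
        samples = [r[0] for r in rows]
        mat = pd.DataFrame(0, index=["A", "B"], columns=samples)
        for blk in (1, 2, 3):
            mat.loc["A", [f"nd{blk}_{r}" for r in (1, 2, 3)]] = 2  # Unknown
            mat.loc["B", [f"nd{blk}_1", f"rt{blk}_1", f"rt{blk}_2"]] = 3  # Roots
            mat.loc["B", [f"bs{blk}", f"rz{blk}"]] = 0
            mat.loc["A", [f"bs{blk}", f"rz{blk}"]] = 0
        mat.loc["filler"] = 1
        ct = make_counts(mat.to_numpy(), asv_ids=list(mat.index), sample_ids=samples)
        res = attribution_percentages(ct, meta)
        means = res.treatment_means.set_index("category")["mean_percent"]
        blk1 = res.per_block[res.per_block["block"] == 1].set_index("category")["percent"]
        for cat in CATEGORY_ORDER:
            assert means[cat] == pytest.approx(blk1[cat])

    def test_treatment_mean_is_arithmetic(self):
        per_block = pd.DataFrame(
            [
                {"treatment": "P0", "block": b, "category": "Roots", "n_asvs": 1,
                 "percent": p, "read_percent": p}
                for b, p in zip((1, 2, 3), (40.0, 20.0, 30.0))
            ]
        )
        mean = per_block.groupby("treatment")["percent"].mean()
        assert mean["P0"] == pytest.approx(30.0)


class TestFamilySummaryAndChord:
    def test_unique_family_flags(self):
        cats = {"a1": "Rhizosphere", "a2": "Rhizosphere", "a3": "Roots"}
        ct, meta = single_plot_attribution(cats)
        res = attribution_percentages(ct, meta)
        tax = make_taxonomy({"a1": "X", "a2": "X", "a3": "Y", "filler": "Z"})
        fam = recruited_family_summary(res, tax)
        x_row = fam[(fam["family"] == "X") & (fam["category"] == "Rhizosphere")]
        assert x_row["n_asvs"].iloc[0] == 2
        assert bool(x_row["unique"].iloc[0])

    def test_family_in_two_treatments_not_unique(self):
        # same category populated for two treatments -> not unique
        pooled = pd.DataFrame(
            [
                {"treatment": t, "block": 1, "category": "Roots", "n_asvs": 1,
                 "percent": 100.0, "read_percent": 100.0}
                for t in ("P0", "BC")
            ]
        )
        from nodsource.source_tracking import AttributionResult

        res = AttributionResult(
            per_block=pooled,
            treatment_means=pooled.rename(columns={"percent": "mean_percent"}),
            classifications={("P0", 1): {"x": "Roots"}, ("BC", 1): {"y": "Roots"}},
        )
        tax = make_taxonomy({"x": "F", "y": "F"})
        fam = recruited_family_summary(res, tax)
        assert not fam["unique"].any()

    @pytest.mark.parametrize("seed", range(5))
    def test_uniqueness_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        from nodsource.source_tracking import AttributionResult

        classifications = {}
        fams = {}
        for t in ("P0", "BC", "BCplus"):
            for b in (1, 2):
                d = {}
                for i in range(rng.integers(1, 8)):
                    asv = f"{t}{b}a{i}"
                    d[asv] = str(rng.choice(["Roots", "Unknown", "Rhizosphere"]))
                    fams[asv] = str(rng.choice(["F1", "F2", "F3"]))
                classifications[(t, b)] = d
        dummy = pd.DataFrame(
            [{"treatment": "P0", "block": 1, "category": "Roots", "n_asvs": 1,
              "percent": 100.0, "read_percent": 100.0}]
        )
        res = AttributionResult(dummy, dummy.rename(columns={"percent": "mean_percent"}),
                                classifications)
        tax = make_taxonomy(fams)
        out = recruited_family_summary(res, tax)
        for _, row in out.iterrows():
            treatments_with = {
                t
                for (t, _b), cls in classifications.items()
                for asv, cat in cls.items()
                if cat == row["category"] and fams[asv] == row["family"]
            }
            assert row["unique"] == (len(treatments_with) == 1)

    def test_chord_round_trip_and_explicit_zeros(self):
        cats = {"a1": "Roots", "a2": "Unknown", "a3": "Unknown"}
        ct, meta = single_plot_attribution(cats)
        res = attribution_percentages(ct, meta)
        chord = chord_matrix(res)
        assert set(chord["source"]) == set(CATEGORY_ORDER)  # zeros explicit
        assert chord.groupby("treatment")["percent"].sum().iloc[0] == pytest.approx(100.0)
        # regrouping reproduces the treatment means exactly
        for _, row in chord.iterrows():
            assert row["percent"] == res.mean_percent(row["treatment"], row["source"])
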