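import itertools

import numpy as np
import pandas as pd
import pytest

import dslst
from dslst import (
    CountTable,
    LayerSets,
    SampleMetadata,
    ValidationError,
    detect_enriched,
    layer_sets,
    partition_profile,
    pooled_contribution,
    profile_partition,
    seasonal_overlap,
    summarize_partition,
)
from dslst.partition import CATEGORIES


def make_profile(counts: np.ndarray, layers=("SURF", "DCM", "MS", "DSL", "MD"),
                 profile="P1"):
    """Single-profile community with one sample per layer."""
    n_asvs = counts.shape[0]
    sample_ids = [f"{profile}_{l}" for l in layers]
    table = CountTable([f"A{i}" for i in range(n_asvs)], sample_ids, counts)
    depth = {"SURF": 5.0, "DCM": 80.0, "MS": 300.0, "DSL": 520.0, "MD": 700.0}
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "station": "ST1",
                "season": "spring",
                "layer": list(layers),
                "profile_id": profile,
                "depth_m": [depth[l] for l in layers],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return table, meta


class TestLayerSets:
    def test_dsl_only_asv(self):
        counts = np.array([[0, 0, 0, 3, 0], [1, 1, 1, 1, 1]])
        table, meta = make_profile(counts)
        sets = layer_sets(table, meta, "P1")
        assert "A0" in sets.dsl
        assert "A0" not in sets.epi | sets.ms | sets.md

    def test_surf_and_md_asv(self):
        counts = np.array([[2, 0, 0, 0, 4], [1, 1, 1, 1, 1]])
        table, meta = make_profile(counts)
        sets = layer_sets(table, meta, "P1")
        assert "A0" in sets.epi and "A0" in sets.md
        assert "A0" not in sets.ms and "A0" not in sets.dsl

    def test_epi_union_of_surf_dcm(self):
        counts = np.array([[2, 0, 0, 1, 0], [0, 3, 0, 1, 0], [1, 1, 1, 1, 1]])
        table, meta = make_profile(counts)
        sets = layer_sets(table, meta, "P1")
        assert {"A0", "A1", "A2"} <= sets.epi

    def test_random_occupancy_set_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            counts = rng.integers(0, 2, size=(15, 5))
            counts[0] = 1  # no all-zero sample
            table, meta = make_profile(counts)
            sets = layer_sets(table, meta, "P1")
            for layer, got in (("MS", sets.ms), ("DSL", sets.dsl), ("MD", sets.md)):
                col = ["SURF", "DCM", "MS", "DSL", "MD"].index(layer)
                expected = {f"A{i}" for i in range(15) if counts[i, col] > 0}
                assert got == expected
            epi_expected = {
                f"A{i}" for i in range(15) if counts[i, 0] > 0 or counts[i, 1] > 0
            }
            assert sets.epi == epi_expected

    def test_no_dsl_sample_error(self):
        counts = np.array([[1, 1, 1, 1]])
        table, meta = make_profile(counts, layers=("SURF", "DCM", "MS", "MD"))
        with pytest.raises(ValidationError, match="DSL"):
            layer_sets(table, meta, "P1")

    def test_missing_ms_md_empty_sets(self):
        counts = np.array([[1, 1, 1]])
        table, meta = make_profile(counts, layers=("SURF", "DCM", "DSL"))
        sets = layer_sets(table, meta, "P1")
        assert sets.ms == frozenset() and sets.md == frozenset()


TRUTH_TABLE = {
    # (in EPI, in MS, in MD) -> category of a DSL ASV
    (False, False, False): "unique_DSL",
    (False, False, True): "MD_only_shared",
    (False, True, False): "MS_only_shared",
    (False, True, True): "all_meso_shared",
    (True, False, False): "EPI_shared",
    (True, False, True): "EPI_shared",
    (True, True, False): "EPI_shared",
    (True, True, True): "EPI_shared",
}


class TestPartitionProfile:
    def test_truth_table_exhaustive(self):
        for pattern, expected in TRUTH_TABLE.items():
            in_epi, in_ms, in_md = pattern
            sets = LayerSets(
                profile_id="P1",
                epi=frozenset({"X"} if in_epi else set()),
                ms=frozenset({"X"} if in_ms else set()),
                dsl=frozenset({"X"}),
                md=frozenset({"X"} if in_md else set()),
            )
            assert partition_profile(sets) == {"X": expected}, pattern

    def test_epi_precedence(self):
        sets = LayerSets("P1", epi=frozenset({"X"}), ms=frozenset({"X"}),
                         dsl=frozenset({"X"}), md=frozenset())
        assert partition_profile(sets)["X"] == "EPI_shared"

    def test_disjoint_exhaustive(self):
        rng = np.random.default_rng(30)
        for _ in range(30):
            occupancy = rng.integers(0, 2, size=(20, 4)).astype(bool)  # EPI MS DSL MD
            ids = [f"A{i}" for i in range(20)]
            sets = LayerSets(
                "P1",
                epi=frozenset(a for a, o in zip(ids, occupancy[:, 0]) if o),
                ms=frozenset(a for a, o in zip(ids, occupancy[:, 1]) if o),
                dsl=frozenset(a for a, o in zip(ids, occupancy[:, 2]) if o),
                md=frozenset(a for a, o in zip(ids, occupancy[:, 3]) if o),
            )
            assignments = partition_profile(sets)
            assert set(assignments) == set(sets.dsl)
            for asv, cat in assignments.items():
                pattern = (asv in sets.epi, asv in sets.ms, asv in sets.md)
                assert cat == TRUTH_TABLE[pattern]

    def test_ms_addition_monotonicity(self):
        # adding an MS occurrence moves an ASV only toward MS-containing
        # categories, never to EPI_shared
        for in_epi, in_md in itertools.product([False, True], repeat=2):
            before = LayerSets(
                "P1",
                epi=frozenset({"X"} if in_epi else set()),
                ms=frozenset(),
                dsl=frozenset({"X"}),
                md=frozenset({"X"} if in_md else set()),
            )
            after = LayerSets(
                "P1", epi=before.epi, ms=frozenset({"X"}), dsl=before.dsl,
                md=before.md,
            )
            cat_before = partition_profile(before)["X"]
            cat_after = partition_profile(after)["X"]
            if cat_before == "EPI_shared":
                assert cat_after == "EPI_shared"
            else:
                assert cat_after in ("MS_only_shared", "all_meso_shared")


class TestProfilePartition:
    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(31)
        counts = rng.integers(0, 3, size=(30, 5))
        counts[:, 3] += 1  # everything present at DSL
        table, meta = make_profile(counts)
        result = profile_partition(table, meta, "P1")
        assert sum(result.percentages.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(result.counts.values()) == result.n_dsl

    def test_abundance_shares(self):
        counts = np.array(
            [
                [0, 0, 0, 30, 0],  # unique, 30% of DSL reads
                [5, 0, 0, 50, 0],  # EPI_shared
                [0, 0, 4, 20, 4],  # all_meso_shared
            ]
        )
        table, meta = make_profile(counts)
        result = profile_partition(table, meta, "P1")
        assert result.abundance["unique_DSL"] == pytest.approx(0.3)
        assert result.abundance["EPI_shared"] == pytest.approx(0.5)
        assert result.abundance["all_meso_shared"] == pytest.approx(0.2)

    def test_enriched_restricted_to_meso_shared(self):
        counts = np.array([[5, 0, 0, 50, 0], [0, 0, 4, 20, 4]])
        table, meta = make_profile(counts)
        result = profile_partition(
            table, meta, "P1", enriched={"A0", "A1"}  # A0 is EPI_shared
        )
        assert result.enriched == frozenset({"A1"})


class TestDetectEnriched:
    def _multi_profile(self, dsl_mult=1.0, n_profiles=5, seed=0, n_bg=8):
        rng = np.random.default_rng(seed)
        rows, sample_ids, layers_col = [], [], []
        layers = ("MS", "DSL", "MD")
        base = rng.uniform(50, 150, size=n_bg + 1)
        for p in range(n_profiles):
            for layer in layers:
                sample_ids.append(f"P{p}_{layer}")
                layers_col.append(layer)
        counts = np.zeros((n_bg + 1, len(sample_ids)), dtype=int)
        for j, (sid, layer) in enumerate(zip(sample_ids, layers_col)):
            mult = dsl_mult if layer == "DSL" else 1.0
            lam = base.copy()
            lam[0] *= mult
            counts[:, j] = rng.poisson(lam)
        counts[1] += 1  # keep samples non-empty
        table = CountTable([f"A{i}" for i in range(n_bg + 1)], sample_ids, counts)
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "station": "ST1", "season": "spring", "layer": layers_col,
                    "profile_id": [s.split("_")[0] for s in sample_ids],
                    "depth_m": [
                        {"MS": 300.0, "DSL": 520.0, "MD": 700.0}[l]
                        for l in layers_col
                    ],
                },
                index=pd.Index(sample_ids, name="sample_id"),
            )
        )
        return table, meta

    def test_identical_abundance_not_enriched(self):
        table, meta = self._multi_profile(dsl_mult=1.0, seed=1)
        # make A0 literally constant across samples
        table.counts[0, :] = 100
        enriched = detect_enriched(table, meta, ["A0"])
        assert enriched == set()

    def test_planted_tenfold_detected(self):
        hits = 0
        for seed in range(20):
            table, meta = self._multi_profile(dsl_mult=10.0, seed=seed)
            hits += "A0" in detect_enriched(table, meta, ["A0"])
        assert hits >= 19  # >= 95% detection

    def test_direction_requirement(self):
        table, meta = self._multi_profile(dsl_mult=0.1, seed=3)  # depleted at DSL
        assert "A0" not in detect_enriched(table, meta, ["A0"])

    def test_insufficient_replicates_skipped(self):
        table, meta = self._multi_profile(dsl_mult=10.0, n_profiles=1, seed=4)
        assert detect_enriched(table, meta, ["A0"]) == set()

    def test_null_false_positive_rate(self):
        # no planted enrichment: enriched fraction stays at/below the
        # alpha-driven expectation (direction + Tukey make it conservative)
        flags, total = 0, 0
        for seed in range(30):
            table, meta = self._multi_profile(dsl_mult=1.0, seed=100 + seed)
            candidates = [f"A{i}" for i in range(table.shape[0])]
            flags += len(detect_enriched(table, meta, candidates))
            total += len(candidates)
        assert flags / total <= 0.05

    def test_bh_adjustment_subset(self):
        table, meta = self._multi_profile(dsl_mult=10.0, seed=5)
        raw = detect_enriched(table, meta, ["A0"])
        adj = detect_enriched(table, meta, ["A0"], adjust="bh")
        assert adj <= raw


class TestSummarizePartition:
    def test_single_profile_identity(self):
        rng = np.random.default_rng(40)
        counts = rng.integers(0, 3, size=(25, 5))
        counts[:, 3] += 1
        table, meta = make_profile(counts)
        result = profile_partition(table, meta, "P1")
        summary = summarize_partition([result])
        for c in CATEGORIES:
            assert summary.mean_pct[c] == pytest.approx(result.percentages[c])
        assert summary.se_n_dsl == 0.0

    def test_means_sum_to_100(self):
        rng = np.random.default_rng(41)
        results = []
        for p in range(4):
            counts = rng.integers(0, 3, size=(25, 5))
            counts[:, 3] += 1
            table, meta = make_profile(counts, profile=f"P{p}")
            results.append(profile_partition(table, meta, f"P{p}"))
        summary = summarize_partition(results)
        assert sum(summary.mean_pct.values()) == pytest.approx(100.0, abs=1e-9)
        assert summary.n_profiles == 4

    def test_empty_error(self):
        with pytest.raises(ValidationError):
            summarize_partition([])


class TestPooledContribution:
    def test_no_exclusive_asvs(self):
        counts = np.ones((5, 5), dtype=int)
        table, meta = make_profile(counts)
        pc = pooled_contribution(table, meta)
        assert pc.unique_fraction == 0.0
        assert pc.unique_abundance_share == 0.0

    def test_all_dsl_exclusive(self):
        counts = np.array(
            [
                [0, 0, 0, 5, 0],
                [0, 0, 0, 7, 0],
                [1, 1, 3, 0, 3],
            ]
        )
        table, meta = make_profile(counts)
        pc = pooled_contribution(table, meta)
        assert pc.n_pooled_unique == 2
        assert pc.unique_fraction == pytest.approx(2 / 3)

    def test_random_occupancy_set_oracle(self):
        rng = np.random.default_rng(50)
        for _ in range(20):
            counts = rng.integers(0, 2, size=(20, 5))
            counts[0] = 1
            table, meta = make_profile(counts)
            pc = pooled_contribution(table, meta)
            ms, dsl, md = counts[:, 2] > 0, counts[:, 3] > 0, counts[:, 4] > 0
            meso_all = int((ms | dsl | md).sum())
            unique = int((dsl & ~ms & ~md).sum())
            assert pc.n_meso_asvs == meso_all
            assert pc.n_pooled_unique == unique
            assert pc.unique_fraction == pytest.approx(unique / meso_all)

    def test_enriched_inclusion(self):
        counts = np.array([[0, 0, 0, 5, 0], [0, 0, 3, 9, 3], [1, 1, 3, 1, 3]])
        table, meta = make_profile(counts)
        pc = pooled_contribution(table, meta, enriched={"A1"})
        assert pc.with_enriched_fraction == pytest.approx(2 / 3)
        assert pc.with_enriched_abundance_share > pc.unique_abundance_share

    def test_missing_layer_error(self):
        counts = np.ones((3, 3), dtype=int)
        table, meta = make_profile(counts, layers=("SURF", "DCM", "DSL"))
        with pytest.raises(ValidationError):
            pooled_contribution(table, meta)


def make_seasonal(counts_by_season: dict[str, np.ndarray], layer="DSL"):
    """Per-season single-sample tables for one layer."""
    seasons = list(counts_by_season)
    n_asvs = next(iter(counts_by_season.values())).shape[0]
    sample_ids = [f"{s}_1" for s in seasons]
    counts = np.column_stack([counts_by_season[s] for s in seasons])
    table = CountTable([f"A{i}" for i in range(n_asvs)], sample_ids, counts)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "station": "ST1", "season": seasons, "layer": layer,
                "profile_id": [f"P_{s}" for s in seasons], "depth_m": 520.0,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return table, meta


class TestSeasonalOverlap:
    def test_identical_patterns_full_core(self):
        v = np.array([3, 0, 5])
        table, meta = make_seasonal({"winter": v, "spring": v, "summer": v})
        overlap = seasonal_overlap(table, meta)
        core = frozenset({"winter", "spring", "summer"})
        assert overlap.asv_fraction[core] == pytest.approx(1.0)
        assert overlap.abundance_fraction[core] == pytest.approx(1.0)

    def test_disjoint_seasons_empty_core(self):
        table, meta = make_seasonal(
            {
                "winter": np.array([5, 0, 0]),
                "spring": np.array([0, 5, 0]),
                "summer": np.array([0, 0, 5]),
            }
        )
        overlap = seasonal_overlap(table, meta)
        core = frozenset({"winter", "spring", "summer"})
        assert core not in overlap.regions
        assert sum(overlap.asv_fraction.values()) == pytest.approx(1.0)

    def test_random_occupancy_oracle(self):
        rng = np.random.default_rng(60)
        for _ in range(20):
            data = {s: rng.integers(0, 2, size=12) for s in ("winter", "spring", "summer")}
            if all(v.sum() == 0 for v in data.values()):
                continue
            for s in data:
                if data[s].sum() == 0:
                    data[s][0] = 1
            table, meta = make_seasonal(data)
            overlap = seasonal_overlap(table, meta)
            for i in range(12):
                member = frozenset(s for s in data if data[s][i] > 0)
                if member:
                    assert f"A{i}" in overlap.regions[member]
            assert sum(overlap.asv_fraction.values()) == pytest.approx(1.0)
            assert sum(overlap.abundance_fraction.values()) == pytest.approx(1.0)

    def test_fractions_partition(self, default_community):
        table, _, metadata, _ = default_community
        overlap = seasonal_overlap(table, metadata, layer="DSL")
        assert sum(overlap.asv_fraction.values()) == pytest.approx(1.0)
        assert sum(overlap.abundance_fraction.values()) == pytest.approx(1.0)
        total = sum(len(m) for m in overlap.regions.values())
        assert total == len(set().union(*overlap.regions.values()))

    def test_layer_absent_error(self, default_community):
        table, _, metadata, _ = default_community
        dsl_only = metadata.samples_where(layer="DSL")
        sub = table.select_samples(dsl_only)
        with pytest.raises(ValidationError):
            seasonal_overlap(sub, metadata.subset(dsl_only), layer="MS")
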