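"""Strict-inequality boundaries, pipeline order, conservation and rarefaction."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_matrix
from mycocurate.curator import (
    CurationConfig,
    curate,
    drop_low_depth,
    drop_positive_controls,
    filter_librarywise,
    filter_samplewise,
    flag_mould,
    mould_score,
    rarefy,
    resolve_replicates,
)
from mycocurate.io_formats import Lineage

CFG = CurationConfig(rng_seed=0)


class TestSamplewiseFilter:
    def test_strict_boundary_at_one_per_mille(self):
        """Sample total 10,000: a 9-read cell (0.09%) is zeroed, a 10-read
        cell (exactly 0.1%) is kept — the rule is strictly less-than."""
        m = small_matrix({"s1": {"a": 9, "b": 10, "c": 9981}})
        out = filter_samplewise(m, CFG)
        assert out.counts.at["s1", "a"] == 0
        assert out.counts.at["s1", "b"] == 10
        assert out.counts.at["s1", "c"] == 9981

    def test_even_composition_untouched(self):
        m = small_matrix({"s1": {f"f{i}": 200 for i in range(5)}})
        out = filter_samplewise(m, CFG)
        pd.testing.assert_frame_equal(out.counts, m.counts)

    def test_zero_matrix_unchanged(self):
        m = small_matrix({"s1": {"a": 0, "b": 0}})
        out = filter_samplewise(m, CFG)
        assert out.counts.to_numpy().sum() == 0

    def test_thresholds_single_pass_then_idempotent(self):
        # after the first pass, remaining fractions only grow: a second
        # application removes nothing
        m = small_matrix({"s1": {"a": 5, "b": 10, "c": 9985}})
        once = filter_samplewise(m, CFG)
        twice = filter_samplewise(once, CFG)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestLibrarywiseFilter:
    def test_strict_boundary_at_half_percent(self):
        """ASV library total 10,000: a 49-read occurrence (0.49%) is zeroed,
        a 50-read occurrence (exactly 0.5%) is kept."""
        m = small_matrix(
            {
                "s1": {"a": 49, "b": 50},
                "s2": {"a": 9951, "b": 9950},
            }
        )
        out = filter_librarywise(m, CFG)
        assert out.counts.at["s1", "a"] == 0
        assert out.counts.at["s1", "b"] == 50
        assert out.counts.at["s2", "a"] == 9951

    def test_single_sample_asv_always_kept(self):
        m = small_matrix({"s1": {"a": 3}, "s2": {"a": 0}})
        out = filter_librarywise(m, CFG)
        assert out.counts.at["s1", "a"] == 3

    def test_libraries_isolated(self):
        # same counts, different libraries: each library total is its own
        m = small_matrix(
            {"s1": {"a": 40}, "s2": {"a": 9960}},
            library={"s1": "L1", "s2": "L2"},
        )
        out = filter_librarywise(m, CFG)
        # within L1, the ASV holds 100% of its library total
        assert out.counts.at["s1", "a"] == 40

    def test_bled_cells_removed_source_kept(self, sim_cfg, refdb, communities):
        """On the simulated fixture, every bled occurrence sits below both
        thresholds and is removed, while true source cells survive."""
        cm, _asvs, truth = communities
        out = filter_librarywise(filter_samplewise(cm, CFG), CFG)
        removed = 0
        for (sample, asv), info in truth.bled_cells.items():
            assert out.counts.at[sample, asv] == 0
            removed += 1
        assert removed > 100
        # dominant source cells survive both filters
        sources = {info["source"] for info in truth.bled_cells.values()}
        survivors = [
            (s, a)
            for (s, a), info in truth.bled_cells.items()
            if out.counts.at[info["source"], a] > 0
        ]
        assert len(survivors) == len(truth.bled_cells)


class TestControlsAndReplicates:
    def test_controls_dropped_after_filtering(self):
        m = small_matrix(
            {f"s{i}": {"a": 6000} for i in range(24)},
            role={"s0": "positive_control", "s1": "positive_control"},
        )
        out = drop_positive_controls(m)
        assert len(out.counts) == 22

    def test_controls_shape_library_denominators(self):
        """A dummy control's reads push a specimen occurrence below the 0.5%
        library-wise threshold; without the control it survives."""
        with_ctrl = small_matrix(
            {"s1": {"a": 49}, "ctrl": {"a": 9951}},
            role={"ctrl": "positive_control"},
        )
        out = drop_positive_controls(filter_librarywise(with_ctrl, CFG))
        assert out.counts.at["s1", "a"] == 0
        without = small_matrix({"s1": {"a": 49}})
        assert filter_librarywise(without, CFG).counts.at["s1", "a"] == 49

    def test_replicate_lowest_richness_to_abundance_kept(self):
        m = small_matrix(
            {
                "r1": {f"f{i}": 100 for i in range(100)},        # 100/10,000
                "r2": {f"g{i}": 10000 // 150 for i in range(150)},
            },
            plot={"r1": "p", "r2": "p"},
        )
        out = resolve_replicates(m)
        assert list(out.counts.index) == ["r1"]

    def test_replicate_tie_prefers_higher_depth(self):
        # equal ratios 10/8000 vs ... construct exact tie: richness/reads equal
        m = small_matrix(
            {
                "r1": {f"f{i}": 1000 for i in range(8)},   # 8 / 8,000
                "r2": {f"g{i}": 1000 for i in range(10)},  # 10 / 10,000
            },
            plot={"r1": "p", "r2": "p"},
        )
        out = resolve_replicates(m)
        assert list(out.counts.index) == ["r2"]

    def test_single_sample_plots_untouched(self):
        m = small_matrix({"s1": {"a": 10}, "s2": {"a": 20}})
        assert len(resolve_replicates(m).counts) == 2


class TestDepthAndRarefaction:
    def test_depth_boundary_strict(self):
        m = small_matrix(
            {"s1": {"a": 4999}, "s2": {"a": 5000}, "s3": {"a": 12000}}
        )
        out = drop_low_depth(m, CFG)
        assert list(out.counts.index) == ["s2", "s3"]

    def test_rarefy_identity_at_exact_depth_and_determinism(self, rng):
        counts = {f"f{i}": 500 for i in range(10)}
        m = small_matrix({"s1": counts, "s2": {"a": 2000, "b": 3000, "c": 3000}})
        cfg = CurationConfig(rng_seed=42)
        out1 = rarefy(m, cfg)
        out2 = rarefy(m, cfg)
        pd.testing.assert_frame_equal(out1.counts, out2.counts)
        # s1 totals exactly 5000 -> untouched
        pd.testing.assert_series_equal(out1.counts.loc["s1"], m.counts.loc["s1"])
        assert out1.counts.loc["s2"].sum() == 5000

    def test_rarefied_richness_never_exceeds_original(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 400, size=(6, 30)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"f{j}" for j in range(30)],
        )
        counts.iloc[:, 0] += 6000  # keep totals above depth
        m = small_matrix(counts.T.to_dict())
        out = rarefy(m, CurationConfig(rng_seed=1))
        assert (out.richness() <= m.richness()).all()
        assert (out.sample_totals() == 5000).all()

    def test_rarefy_requires_sufficient_depth(self):
        m = small_matrix({"s1": {"a": 100}})
        with pytest.raises(ValueError, match="drop_low_depth"):
            rarefy(m, CFG)


class TestMould:
    def taxonomy(self):
        mould = Lineage.from_names(
            ["Fungi", "Ascomycota", "Sordariomycetes", "Hypocreales",
             "Hypocreaceae", "Trichoderma", "Trichoderma_sp01"]
        )
        clean = Lineage.from_names(
            ["Fungi", "Basidiomycota", "Agaricomycetes", "Agaricales",
             "Amanitaceae", "Amanita", "Amanita_sp01"]
        )
        return {"t": mould, "x": clean}

    def test_no_mould_all_zero(self):
        m = small_matrix({"s1": {"x": 100}, "s2": {"x": 50}})
        scores = mould_score(m, self.taxonomy(), CFG)
        assert (scores == 0).all()
        flags, _ = flag_mould(scores, CFG)
        assert not flags.any()

    def test_single_contaminated_sample_flagged(self):
        counts = {f"s{i}": {"x": 1000, "t": 1} for i in range(50)}
        counts["bad"] = {"x": 0, "t": 1000}  # 100% Trichoderma
        m = small_matrix(counts)
        scores = mould_score(m, self.taxonomy(), CFG)
        flags, threshold = flag_mould(scores, CFG)
        assert flags["bad"]
        assert flags.sum() == 1
        assert threshold < 1.0

    def test_equal_scores_degenerate_no_flags(self):
        m = small_matrix({f"s{i}": {"x": 50, "t": 50} for i in range(5)})
        scores = mould_score(m, self.taxonomy(), CFG)
        flags, threshold = flag_mould(scores, CFG)
        assert threshold == pytest.approx(0.5)
        assert not flags.any()  # strict >


class TestCurateEndToEnd:
    def test_conservation_and_order(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 800, size=(12, 25)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"f{j}" for j in range(25)],
        )
        m = small_matrix(
            counts.T.to_dict(),
            role={"s0": "positive_control"},
            plot={"s1": "p", "s2": "p"},
        )
        out, report = curate(m, CFG)
        # only removal, never creation
        common = out.counts.index
        assert (out.counts.loc[common] <= m.counts.loc[common]).all().all()
        # fixed stage order recorded in the report
        assert list(report.steps) == [
            "samplewise_filter",
            "librarywise_filter",
            "drop_positive_controls",
            "resolve_replicates",
            "drop_low_depth",
        ]
        # the report accounts for all removed reads
        removed = sum(s.reads_removed for s in report.steps.values())
        assert removed == m.counts.to_numpy().sum() - out.counts.to_numpy().sum()
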