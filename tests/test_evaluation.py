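import numpy as np
import pandas as pd
import pytest

from negaprocess import (
    ValidationError,
    classify_peaks,
    compare_methods,
    count_events,
    roc_points,
    sweep_thresholds,
    total_error,
)
from negaprocess.evaluation import (
    EvaluationCount,
    expected_alleles,
    prepare_positive,
)
from negaprocess.filtering import screen_locus_positions
from negaprocess.thresholds import ThresholdSet

from conftest import make_table


def peaks_at(kit, marker_name, allele_labels, height=100.0, sample_id="p"):
    """Rows at the bin centers of the given alleles of one marker."""
    m = kit.marker_by_name(marker_name)
    return [
        {
            "sample_id": sample_id,
            "dye": m.dye,
            "size_bp": m.bins[a],
            "height_rfu": height,
        }
        for a in allele_labels
    ]


@pytest.fixture
def small_genotype(kit):
    # two dye-B markers: one heterozygous, one homozygous
    return {"M_B1": frozenset({"7", "11"}), "M_B2": frozenset({"9"})}


class TestClassifyPeaks:
    def _labelled(self, kit, genotype, rows):
        table, _ = screen_locus_positions(make_table(rows), kit)
        return classify_peaks(table, genotype, kit)

    def test_both_alleles_present(self, kit, small_genotype):
        rows = peaks_at(kit, "M_B1", ["7", "11"])
        labelled = self._labelled(kit, small_genotype, rows)
        assert list(labelled["label"]) == ["allelic", "allelic"]

    def test_stutter_position_is_non_allelic(self, kit, small_genotype):
        rows = peaks_at(kit, "M_B1", ["7", "10", "11"])  # 10 is not expected
        labelled = self._labelled(kit, small_genotype, rows)
        assert sorted(labelled["label"]) == ["allelic", "allelic", "non_allelic"]

    def test_marker_absent_from_genotype_raises(self, kit, small_genotype):
        rows = peaks_at(kit, "M_G1", ["7"])
        with pytest.raises(ValidationError, match="M_G1"):
            self._labelled(kit, small_genotype, rows)

    def test_matches_brute_force_matcher(self, kit, genotype):
        rng = np.random.default_rng(17)
        rows = []
        for _ in range(100):
            m = kit.markers[rng.integers(len(kit.markers))]
            size = rng.uniform(m.size_min, m.size_max)
            rows.append(
                {"sample_id": "p", "dye": m.dye, "size_bp": size, "height_rfu": 50.0}
            )
        table, _ = screen_locus_positions(make_table(rows), kit)
        labelled = classify_peaks(table, genotype, kit)
        # brute force: scan every expected allele bin of the row's marker
        for row in labelled.itertuples(index=False):
            marker = kit.marker_by_name(row.marker)
            hit = any(
                abs(row.size_bp - marker.bins[a]) <= 0.5
                for a in genotype[row.marker]
                if a in marker.bins
            )
            assert (row.label == "allelic") == hit


class TestCountEvents:
    def test_perfect_profile(self, kit, small_genotype):
        rows = peaks_at(kit, "M_B1", ["7", "11"]) + peaks_at(kit, "M_B2", ["9"])
        table, _ = screen_locus_positions(make_table(rows), kit)
        labelled = classify_peaks(table, small_genotype, kit)
        count = count_events(labelled, small_genotype, kit, dye="B")
        assert count.n_expected_alleles == 3  # homozygote counts once
        assert count.n_dropouts == 0
        assert count.n_non_allelic == 0
        assert count.tpr == 1.0 and count.fpr == 0.0 and count.total_error == 0.0

    def test_empty_profile_all_dropout(self, kit, small_genotype):
        labelled = classify_peaks(
            screen_locus_positions(make_table([]), kit)[0], small_genotype, kit
        )
        count = count_events(labelled, small_genotype, kit, dye="B")
        assert count.n_dropouts == count.n_expected_alleles == 3
        assert count.tpr == 0.0
        assert count.total_error == 1.0

    def test_counts_match_manual_tally(self, kit, genotype):
        # five markers of dye B: alleles partially present plus two artifacts
        rows = (
            peaks_at(kit, "M_B1", ["7"])          # 1 of 2 alleles
            + peaks_at(kit, "M_B2", ["7", "11"])  # both alleles
            + peaks_at(kit, "M_B3", ["8"])        # not expected -> non-allelic
            + peaks_at(kit, "M_B4", ["7", "8"])   # 7 expected, 8 not
        )
        table, _ = screen_locus_positions(make_table(rows), kit)
        labelled = classify_peaks(table, genotype, kit)
        count = count_events(labelled, genotype, kit, dye="B")
        # expected: M_B1 {7,11}, M_B2 {7,11}, M_B3 {9}, M_B4 {7,11} -> 7 alleles
        assert count.n_expected_alleles == 7
        assert count.n_true_alleles_detected == 4
        assert count.n_dropouts == 3
        assert count.n_non_allelic == 2
        assert count.n_dropouts + count.n_true_alleles_detected == count.n_expected_alleles


class TestSweep:
    def test_tall_peaks_never_drop(self, kit, small_genotype):
        rows = peaks_at(kit, "M_B1", ["7", "11"], height=500.0) + peaks_at(
            kit, "M_B2", ["9"], height=500.0
        )
        curve = sweep_thresholds([make_table(rows)], small_genotype, kit)
        b = curve.for_dye("B")
        assert (b["mean_dropouts"] == 0).all()

    def test_dropout_steps_at_true_allele_heights(self, kit, small_genotype):
        heights = {"7": 40.0, "11": 90.0}
        rows = [
            dict(r, height_rfu=heights[a])
            for a, r in zip(["7", "11"], peaks_at(kit, "M_B1", ["7", "11"]))
        ]
        curve = sweep_thresholds([make_table(rows)], small_genotype, kit, range(1, 201))
        b = curve.for_dye("B").set_index("at_rfu")["mean_dropouts"]
        # M_B2 allele is absent throughout -> floor of 1 dropout
        assert b.loc[40] == 1.0
        assert b.loc[41] == 2.0  # the 40-RFU peak drops out just above its height
        assert b.loc[90] == 2.0
        assert b.loc[91] == 3.0

    def test_curves_flatten_at_missing_allele_count(self, kit, genotype):
        rows = peaks_at(kit, "M_B1", ["7"], height=60.0)
        curve = sweep_thresholds([make_table(rows)], genotype, kit)
        b = curve.for_dye("B").set_index("at_rfu")["mean_dropouts"]
        n_expected = len(expected_alleles(genotype, kit, "B"))
        assert b.loc[200] == n_expected  # everything above 60 RFU is gone
        assert b.loc[1] == n_expected - 1

    def test_monotone_invariants(self, kit, genotype, config):
        from negaprocess import simulate_positive

        tables = [
            simulate_positive(config, kit, genotype, 31.25, 29, seed)
            for seed in range(3)
        ]
        curve = sweep_thresholds(tables, genotype, kit)
        assert curve.is_monotone()


def _count(method, tpr, fpr, condition=(31.25, 27, None)):
    return EvaluationCount(
        method=method,
        condition=condition,
        n_expected_alleles=10,
        n_dropouts=round(10 * (1 - tpr)),
        n_true_alleles_detected=round(10 * tpr),
        n_non_allelic=round(10 * fpr),
        tpr=tpr,
        fpr=fpr,
        total_error=(1 - tpr) + fpr,
    )


class TestRocAndTotalError:
    def test_ideal_point_selected(self):
        res = roc_points([_count("good", 1.0, 0.0), _count("bad", 0.5, 0.5)])
        assert res.best_method == "good"

    def test_hand_computed_distances(self):
        res = roc_points([_count("a", 0.6, 0.0), _count("b", 0.9, 0.2)])
        dist = dict(zip(res.points["method"], res.points["distance"]))
        assert dist["a"] == pytest.approx(0.4)
        assert dist["b"] == pytest.approx(0.2236, abs=1e-4)
        assert res.best_method == "b"

    def test_tie_breaks_toward_lower_fpr(self):
        # both points at distance 0.5 from (0, 1)
        res = roc_points([_count("high_fpr", 1.0, 0.5), _count("low_fpr", 0.5, 0.0)])
        assert res.best_method == "low_fpr"

    def test_mixed_conditions_rejected(self):
        with pytest.raises(ValidationError):
            roc_points(
                [_count("a", 1.0, 0.0), _count("b", 1.0, 0.0, (15.625, 27, None))]
            )

    @pytest.mark.parametrize(
        "tpr,fpr,expected",
        [(1.0, 0.0, 0.0), (0.0, 0.0, 1.0), (0.8, 0.3, 0.5)],
    )
    def test_total_error_arithmetic(self, tpr, fpr, expected):
        assert total_error(_count("m", tpr, fpr)) == pytest.approx(expected)


@pytest.fixture(scope="module")
def study_slice(kit, genotype, config):
    from negaprocess import simulate_positive

    tables = []
    for tpl in (31.25, 7.8125):
        for seed in range(3):
            tables.append(
                simulate_positive(config, kit, genotype, tpl, 27, seed + int(tpl * 16))
            )
    return tables


class TestCompareMethods:
    def test_thresholds_below_all_peaks_equal_minimum_at_analysis(
        self, kit, genotype, config
    ):
        # 1 ng input, artifacts and noise off: every allelic peak towers over
        # both threshold sets, so the counts coincide with the 1-RFU analysis
        from negaprocess import simulate_positive

        table = simulate_positive(
            config, kit, genotype, 1000.0, 27, 5,
            disable_artifacts=True, with_noise=False,
        )
        assert table.records["height_rfu"].min() > 175.0
        low = ThresholdSet("low", {d: 175.0 for d in kit.analysis_dyes})
        unit = ThresholdSet("unit", {d: 1.0 for d in kit.analysis_dyes})
        counts = compare_methods([low, unit], [table], genotype, kit)
        by_method = {c.method: c for c in counts}
        assert by_method["low"].n_dropouts == by_method["unit"].n_dropouts == 0
        assert by_method["low"].n_non_allelic == by_method["unit"].n_non_allelic

    def test_lowest_threshold_maximizes_non_allelic(self, kit, genotype, study_slice):
        sets = [
            ThresholdSet("AT2", {d: 8.0 for d in kit.analysis_dyes}),
            ThresholdSet("AT1", {d: 18.0 for d in kit.analysis_dyes}),
            ThresholdSet("AT5", {d: 30.0 for d in kit.analysis_dyes}),
        ]
        counts = compare_methods(sets, study_slice, genotype, kit)
        frame = pd.DataFrame(
            [(c.method, c.condition, c.n_non_allelic, c.n_dropouts) for c in counts],
            columns=["method", "condition", "na", "do"],
        )
        for _, grp in frame.groupby("condition"):
            by = grp.set_index("method")
            assert by.loc["AT2", "na"] == by["na"].max()
            # raising thresholds never decreases dropouts
            assert by.loc["AT2", "do"] <= by.loc["AT1", "do"] <= by.loc["AT5", "do"]

    def test_rates_bounded(self, kit, genotype, study_slice):
        sets = [ThresholdSet("m", {d: 15.0 for d in kit.analysis_dyes})]
        for c in compare_methods(sets, study_slice, genotype, kit):
            assert 0.0 <= c.tpr <= 1.0
            assert 0.0 <= c.fpr <= 1.0
            assert 0.0 <= c.total_error <= 2.0


class TestPreparePositive:
    def test_pullup_removed_before_labelling(self, kit, small_genotype):
        allele_rows = peaks_at(kit, "M_B1", ["7", "11"], height=1000.0)
        b1 = kit.marker_by_name("M_B1")
        # a 2%-height peak in dye G at the exact size of the tall B allele:
        # it lies inside marker M_G1 (so the locus screen keeps it) but in no
        # G bin, and only pull-up removal can drop it
        g1 = kit.marker_by_name("M_G1")
        pullup_row = {
            "sample_id": "p",
            "dye": "G",
            "size_bp": b1.bins["7"],
            "height_rfu": 20.0,
        }
        assert g1.contains(b1.bins["7"])  # staggered layouts still overlap
        genotype = dict(small_genotype, M_G1=frozenset({"7", "11"}))
        labelled = prepare_positive(
            make_table(allele_rows + [pullup_row]), genotype, kit
        )
        assert len(labelled[labelled["dye"] == "G"]) == 0
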