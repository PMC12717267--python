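import numpy as np
import pandas as pd
import pytest

from aerodiv.compositional import impute_zeros, plr_abundances
from aerodiv.synthetic import STATION, spike_false_positives
from aerodiv.taxon_filter import (
    FEATURE_STATISTICS,
    LabelSet,
    build_features,
    classify_genera,
    curate_labels,
    read_kraken_report,
    select_stringency,
    train_filter,
)
from aerodiv.catchment import destination_point

from conftest import make_count_matrix


def toy_summaries(genera, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "total_reads": rng.integers(100, 1000, len(genera)),
            "clade_reads": rng.integers(100, 1000, len(genera)),
            "direct_reads": rng.integers(50, 500, len(genera)),
            "total_minimizers": rng.integers(200, 2000, len(genera)),
            "distinct_minimizers": rng.integers(50, 200, len(genera)),
            "mean_confidence": rng.uniform(0.1, 0.9, len(genera)),
            "lineage_seq_bytes": rng.uniform(1e6, 1e9, len(genera)),
            "genome_size_proxy": rng.uniform(1e6, 1e9, len(genera)),
            "kingdom": rng.choice(["Fungi", "Metazoa"], len(genera)),
        },
        index=genera,
    )


class TestSelectStringency:
    def grid(self, rows):
        return pd.DataFrame(
            rows, columns=["confidence", "min_hit_groups", "frac_classified", "frac_regional"]
        )

    def test_single_row(self):
        g = self.grid([(0.1, 10, 0.5, 0.8)])
        assert select_stringency(g) == (0.1, 10)

    def test_flat_regional_ties_to_least_stringent(self):
        g = self.grid([(0.0, 1, 0.9, 0.5), (0.1, 10, 0.8, 0.5), (0.2, 20, 0.7, 0.5)])
        assert select_stringency(g) == (0.0, 1)

    def test_knee_selected_under_constraint(self):
        # regional fraction rises then saturates; classified fraction falls;
        # the knee is the highest regional point still keeping >= 50% of
        # the max classified fraction
        g = self.grid(
            [
                (0.0, 1, 1.00, 0.40),
                (0.05, 5, 0.80, 0.55),
                (0.1, 10, 0.60, 0.70),
                (0.2, 20, 0.40, 0.72),
                (0.3, 40, 0.20, 0.73),
            ]
        )
        assert select_stringency(g) == (0.1, 10)

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            select_stringency(self.grid([]))


class TestCurateLabels:
    def occ(self, rows):
        return pd.DataFrame(
            rows, columns=["taxon", "decimalLatitude", "decimalLongitude", "year"]
        )

    def records_at(self, taxon, dist_km, n, year=1990):
        lat, lon = destination_point(STATION[0], STATION[1], 90.0, dist_km)
        return [(taxon, float(lat), float(lon), year)] * n

    def test_five_near_records_positive(self):
        labels = curate_labels(self.occ(self.records_at("aa", 10, 5)), STATION)
        assert labels.labels["aa"] == "positive"

    def test_three_near_with_family_conflict_unlabeled(self):
        occ = self.occ(self.records_at("bb", 10, 3))
        labels = curate_labels(
            occ,
            STATION,
            genus_family=pd.Series({"bb": "famX"}),
            unsequenced_european_families={"famX"},
        )
        assert "bb" not in labels.labels.index

    def test_nothing_within_5000km_negative(self):
        occ = self.occ(self.records_at("cc", 7000, 2))
        labels = curate_labels(occ, STATION)
        assert labels.labels["cc"] == "negative"

    def test_missing_coordinates_skipped_with_count(self):
        occ = self.occ(self.records_at("dd", 10, 4) + [("dd", np.nan, np.nan, 1990)])
        with pytest.warns(UserWarning, match="skipped 1"):
            labels = curate_labels(occ, STATION)
        assert labels.n_skipped_records == 1
        assert labels.labels["dd"] == "positive"

    def test_order_independent(self):
        rows = (
            self.records_at("aa", 10, 5)
            + self.records_at("cc", 7000, 2)
            + self.records_at("ee", 100, 1)
        )
        l1 = curate_labels(self.occ(rows), STATION)
        l2 = curate_labels(self.occ(rows[::-1]), STATION)
        pd.testing.assert_series_equal(l1.labels, l2.labels)


class TestBuildFeatures:
    def make_inputs(self, counts):
        cm = make_count_matrix(counts)
        comp = impute_zeros(cm)
        plr = plr_abundances(comp)
        return cm, toy_summaries(list(cm.genera)), plr

    def test_thirty_one_statistics_present(self):
        cm, summ, plr = self.make_inputs(np.random.default_rng(0).integers(0, 9, (5, 12)) + np.eye(5, 12, dtype=int))
        feats = build_features(cm, summ, plr)
        assert len(FEATURE_STATISTICS) == 31
        assert all(c in feats.table.columns for c in FEATURE_STATISTICS)

    def test_always_detected_genus_extremes(self):
        counts = np.ones((3, 10), dtype=int)
        counts[0] = 100
        counts[1, ::2] = 0
        cm, summ, plr = self.make_inputs(counts)
        feats = build_features(cm, summ, plr)
        assert feats.table.loc["g0", "zero_week_fraction"] == 0.0
        assert feats.table.loc["g0", "n_detected_weeks"] == 10
        assert feats.table.loc["g0", "longest_detection_run"] == 10

    def test_identical_inputs_identical_rows(self):
        counts = np.vstack([np.arange(1, 11)] * 2 + [np.ones(10, dtype=int)])
        cm, summ, plr = self.make_inputs(counts)
        summ.iloc[1] = summ.iloc[0]
        feats = build_features(cm, summ, plr)
        stat_cols = list(FEATURE_STATISTICS)
        # identical counts + identical summaries -> identical statistic rows
        # (PLR rows also match because the two genera have equal proportions)
        pd.testing.assert_series_equal(
            feats.table.loc["g0", stat_cols],
            feats.table.loc["g1", stat_cols],
            check_names=False,
        )

    def test_minimizer_ratio_hand_computed(self):
        counts = np.array([[4, 5], [6, 7], [8, 9]])
        cm = make_count_matrix(counts)
        summ = toy_summaries(list(cm.genera))
        summ["total_minimizers"] = [100, 200, 400]
        summ["distinct_minimizers"] = [50, 40, 100]
        plr = plr_abundances(impute_zeros(cm))
        feats = build_features(cm, summ, plr)
        np.testing.assert_allclose(
            feats.table["distinct_minimizer_ratio"], [0.5, 0.2, 0.25]
        )

    def test_missing_summary_names_genera(self):
        cm, summ, plr = self.make_inputs(np.ones((4, 6), dtype=int))
        with pytest.raises(ValueError, match="g3"):
            build_features(cm, summ.drop(index="g3"), plr)


@pytest.fixture(scope="module")
def separable_model():
    rng = np.random.default_rng(1)
    n = 120
    genera = [f"g{i}" for i in range(n)]
    y = np.array(["positive"] * 60 + ["negative"] * 60)
    table = pd.DataFrame(
        {
            "f1": np.where(y == "positive", 1.0, -1.0) + rng.normal(0, 0.05, n),
            "f2": rng.normal(0, 1, n),
        },
        index=genera,
    )
    from aerodiv.taxon_filter import FeatureTable

    feats = FeatureTable(table=table, statistic_names=("f1", "f2"))
    labels = LabelSet(
        labels=pd.Series(y, index=genera),
        provenance=pd.Series("toy", index=genera),
    )
    model = train_filter(feats, labels, seed=0, grid={"max_depth": [2]}, n_estimators=20)
    return feats, model


class TestTrainAndClassify:
    def test_separable_perfect_holdout(self, separable_model):
        _, model = separable_model
        assert model.holdout_precision == 1.0
        assert model.holdout_recall == 1.0

    def test_threshold_boundary_inclusive(self, separable_model):
        feats, model = separable_model
        calls = classify_genera(model, feats)
        at = calls["probability"] >= model.threshold
        assert (calls["retained"] == at).all()

    def test_threshold_monotonicity(self, separable_model):
        feats, model = separable_model
        calls = classify_genera(model, feats)
        n_low = int((calls["probability"] >= 0.5).sum())
        n_high = int((calls["probability"] >= 0.9).sum())
        assert n_high <= int(calls["retained"].sum()) <= n_low

    def test_schema_mismatch_names_columns(self, separable_model):
        feats, model = separable_model
        from aerodiv.taxon_filter import FeatureTable

        bad = FeatureTable(
            table=feats.table.rename(columns={"f2": "f9"}), statistic_names=("f1", "f9")
        )
        with pytest.raises(ValueError, match="f9"):
            classify_genera(model, bad)

    def test_holdout_not_in_training(self, separable_model):
        feats, model = separable_model
        # retrain flagging leakage: holdout genera unique and disjoint from CV
        assert len(set(model.holdout_genera)) == len(model.holdout_genera)
        assert len(model.holdout_genera) == round(0.13 * len(feats.table))

    def test_single_class_rejected(self, separable_model):
        feats, _ = separable_model
        labels = LabelSet(
            labels=pd.Series("positive", index=feats.table.index),
            provenance=pd.Series("toy", index=feats.table.index),
        )
        with pytest.raises(ValueError, match="both classes"):
            train_filter(feats, labels)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        genera = [f"g{i}" for i in range(80)]
        y = np.array(["positive", "negative"] * 40)
        from aerodiv.taxon_filter import FeatureTable

        table = pd.DataFrame(
            {"f1": np.where(y == "positive", 1, -1) + rng.normal(0, 0.3, 80)},
            index=genera,
        )
        feats = FeatureTable(table=table, statistic_names=("f1",))
        labels = LabelSet(
            labels=pd.Series(y, index=genera), provenance=pd.Series("t", index=genera)
        )
        m1 = train_filter(feats, labels, seed=5, grid={"max_depth": [2]}, n_estimators=20)
        m2 = train_filter(feats, labels, seed=5, grid={"max_depth": [2]}, n_estimators=20)
        assert m1.holdout_precision == m2.holdout_precision
        assert m1.holdout_genera == m2.holdout_genera


def test_read_kraken_report(tmp_path):
    text = (
        "10.5\t1000\t800\t5000\t2500\tG\t9606\tHomo\n"
        "1.2\t100\t50\t400\t100\tG1\t10090\tMus\n"
        "50.0\t9000\t0\t90000\t60000\tD\t2\tBacteria\n"
    )
    p = tmp_path / "report.txt"
    p.write_text(text)
    df = read_kraken_report(p)
    assert list(df.index) == ["Homo", "Mus"]
    assert df.loc["Homo", "distinct_minimizers"] == 2500
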