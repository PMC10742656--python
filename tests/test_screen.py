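"""Two-level differential screen, dark-biomarker taxonomy and reports."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mqtrans.screen import (
    ScreenPolicy,
    classify_dark_biomarkers,
    count_detour_features,
    pca_coordinates,
    pn_ratio,
    rank_features_by_p,
    read_report,
    screen_dataset,
    two_sample_ttest,
    write_report,
)

from conftest import build_annotated, make_screen_result


def pooled_t_oracle(case, control):
    """Closed-form pooled-variance two-sample t, written out longhand."""
    case, control = np.asarray(case, float), np.asarray(control, float)
    n1, n2 = len(case), len(control)
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    t = (case.mean() - control.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


class TestTwoSampleTTest:
    def test_identical_groups(self):
        t, p = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups(self, rng):
        case = np.zeros(4) + 1e-9 * rng.standard_normal(4)
        control = np.ones(4) + 1e-9 * rng.standard_normal(4)
        _, p = two_sample_ttest(case, control)
        assert p < 1e-6

    def test_matches_pooled_closed_form(self):
        case = [2.1, 2.9, 3.2, 2.6]
        control = [1.1, 1.4, 0.9, 1.6]
        t, p = two_sample_ttest(case, control, equal_variance=True)
        t0, p0 = pooled_t_oracle(case, control)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_welch_variant_matches_scipy(self, rng):
        case, control = rng.normal(0, 1, 9), rng.normal(0.5, 3, 14)
        t, p = two_sample_ttest(case, control, equal_variance=False)
        ref = stats.ttest_ind(case, control, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_equal_groups_give_p_one(self, caplog):
        with caplog.at_level("WARNING"):
            t, p = two_sample_ttest([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_distinct_groups_give_p_zero(self):
        _, p = two_sample_ttest([0.0, 0.0], [1.0, 1.0])
        assert p == 0.0

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            two_sample_ttest([1.0], [1.0, 2.0])


class TestPnRatio:
    def test_arithmetic(self):
        assert pn_ratio([1.0, 1.4], [0.9, 1.1]) == pytest.approx(1.2)

    def test_identical_groups(self):
        assert pn_ratio([2.0, 4.0], [2.0, 4.0]) == pytest.approx(1.0)

    def test_swap_gives_reciprocal(self, rng):
        a, b = rng.uniform(0.5, 2.0, 10), rng.uniform(0.5, 2.0, 10)
        assert pn_ratio(a, b) == pytest.approx(1.0 / pn_ratio(b, a))

    def test_zero_control_mean_is_nan(self, caplog):
        with caplog.at_level("WARNING"):
            assert np.isnan(pn_ratio([1.0, 2.0], [-1.0, 1.0]))


def screened_dataset(policy=None, n=12, seed=7):
    """A small labeled cohort screened with hand-shaped target behaviors.

    G000: dark (mq separated, original exchangeable)
    G001: detour only (both levels separated)
    G002: null (nothing separated)
    G003: gate failure (pure-noise target)
    """
    rng = np.random.default_rng(seed)
    labels = ["case"] * n + ["control"] * n
    tf = rng.uniform(size=(3, 2 * n))
    w = np.array([1.0, 0.8, 1.2])
    g0 = w @ tf + 0.05 * rng.standard_normal(2 * n)
    g1 = w @ tf + 0.05 * rng.standard_normal(2 * n) + np.r_[np.full(n, 0.6), np.zeros(n)]
    g2 = w @ tf + 0.05 * rng.standard_normal(2 * n)
    g3 = rng.uniform(size=2 * n)
    data = build_annotated(tf, np.vstack([g0, g1, g2, g3]), labels=labels)

    train_tf = rng.uniform(size=(3, 50))
    train_targets = np.vstack([w @ train_tf + 0.05 * rng.standard_normal(50) for _ in range(4)])
    train_targets[3] = rng.uniform(size=50)
    train = build_annotated(train_tf, train_targets, labels=["control"] * 50)
    from mqtrans.regression import TranscriptionRegulationModel

    res = TranscriptionRegulationModel(train).fit()
    mq = res.mqtrans(data)
    # plant the dark signal: inflate case residuals of G000 at the mq level
    mq.loc["G000_at", mq.columns[:n]] += 0.5
    pcc = res.pcc(data)
    return screen_dataset("B", data, mq, pcc, policy or ScreenPolicy()), data, mq, pcc


class TestScreenDataset:
    def test_flag_logic(self):
        result, *_ = screened_dataset()
        t = result.table
        assert bool(t.loc["G000_at", "is_dark"])
        assert t.loc["G000_at", "p_original"] > 0.05 and t.loc["G000_at", "p_mqtrans"] < 0.05
        assert bool(t.loc["G001_at", "is_detour"]) and not t.loc["G001_at", "is_dark"]
        assert not t.loc["G003_at", "evaluable"] and not t.loc["G003_at", "is_detour"]

    def test_label_mismatch_rejected(self):
        result, data, mq, pcc = screened_dataset()
        with pytest.raises(ValueError, match="different samples"):
            screen_dataset("B", data, mq.iloc[:, :-1], pcc)

    def test_label_swap_symmetry(self):
        """Exchanging case/control leaves p-values unchanged and inverts P/N."""
        result, data, mq, pcc = screened_dataset()
        swapped = data.labels.map({"case": "control", "control": "case"})
        data_sw = build_annotated(
            data.tf_values().to_numpy(), data.target_values().to_numpy(), labels=list(swapped)
        )
        result_sw = screen_dataset("B", data_sw, mq, pcc)
        assert np.allclose(result.table["p_original"], result_sw.table["p_original"])
        assert np.allclose(result.table["p_mqtrans"], result_sw.table["p_mqtrans"])
        assert np.allclose(
            result.table["pn_original"], 1.0 / result_sw.table["pn_original"]
        )


class TestCountAndRank:
    def test_counting(self):
        r = make_screen_result("B", {
            "A": {"p_mqtrans": 0.01}, "B": {"p_mqtrans": 0.04}, "C": {"p_mqtrans": 0.06},
        })
        assert count_detour_features(r, 0.05) == 2

    def test_near_one_alpha_counts_all_evaluable(self):
        r = make_screen_result("B", {
            "A": {"p_mqtrans": 0.2}, "B": {"p_mqtrans": 0.9}, "C": {"pcc": 0.1, "p_mqtrans": 0.0},
        })
        assert count_detour_features(r, 1 - 1e-12) == 2  # C fails the gate

    def test_monotone_in_alpha(self, rng):
        r = make_screen_result("B", {f"F{i}": {"p_mqtrans": float(p)} for i, p in
                                     enumerate(rng.uniform(size=30))})
        counts = [count_detour_features(r, a) for a in np.linspace(0.01, 0.99, 9)]
        assert counts == sorted(counts)

    def test_rank_order_and_tie_break(self):
        r = make_screen_result("B", {
            "A": {"p_original": 0.3}, "B": {"p_original": 0.01}, "C": {"p_original": 0.3},
        })
        ranked = rank_features_by_p(r, "original")
        assert list(ranked.index) == ["B", "A", "C"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_all_ties_fall_back_to_feature_id(self):
        r = make_screen_result("B", {f: {"p_mqtrans": 0.5} for f in ["Z", "A", "M"]})
        assert list(rank_features_by_p(r, "mqtrans").index) == ["A", "M", "Z"]


class TestClassification:
    def test_table_taxonomy(self):
        datasets = ["B", "C", "D"]
        rows = {
            "strong_at": {"p_mqtrans": 0.001, "p_original": 0.742},
            "weak_at": {"p_mqtrans": 0.5, "p_original": 0.2},
            "none_at": {"p_mqtrans": 0.5, "p_original": 0.2},
        }
        results = []
        for ds in datasets:
            r = dict(rows)
            if ds == "B":
                r["weak_at"] = {"p_mqtrans": 0.001, "p_original": 0.954}
                r["none_at"] = {"p_mqtrans": 0.001, "p_original": 0.2}
            results.append(make_screen_result(ds, r))
        calls = classify_dark_biomarkers(results)
        assert calls.loc["strong_at", "call"] == "strong"
        assert calls.loc["weak_at", "call"] == "weak"     # dark only in B, p_orig 0.954 > 0.5
        assert calls.loc["none_at", "call"] == "none"     # dark only in B but below the floor
        assert list(calls.index[:1]) == ["strong_at"]     # strong sorted first

    def test_strong_requires_dark_everywhere(self):
        results = [
            make_screen_result("B", {"F": {"p_mqtrans": 0.001, "p_original": 0.9}}),
            make_screen_result("C", {"F": {"p_mqtrans": 0.5, "p_original": 0.9}}),
        ]
        calls = classify_dark_biomarkers(results)
        assert calls.loc["F", "call"] == "weak"

    def test_adding_a_dataset_only_shrinks_the_strong_set(self):
        base = {"F": {"p_mqtrans": 0.001, "p_original": 0.9},
                "G": {"p_mqtrans": 0.001, "p_original": 0.6}}
        two = [make_screen_result(d, base) for d in ("B", "C")]
        three = two + [make_screen_result("D", {
            "F": {"p_mqtrans": 0.001, "p_original": 0.9},
            "G": {"p_mqtrans": 0.9, "p_original": 0.6},
        })]
        strong2 = set(classify_dark_biomarkers(two).query("call == 'strong'").index)
        strong3 = set(classify_dark_biomarkers(three).query("call == 'strong'").index)
        assert strong3 <= strong2

    def test_fuzzed_patterns_keep_the_taxonomy_consistent(self, rng):
        """Random flag patterns: strong iff dark everywhere; strong/weak disjoint."""
        for _ in range(200):
            n_ds = rng.integers(1, 4)
            results = []
            for d in range(n_ds):
                rows = {}
                for f in ["F1", "F2", "F3"]:
                    rows[f] = {
                        "p_mqtrans": float(rng.uniform()),
                        "p_original": float(rng.uniform()),
                        "pcc": float(rng.uniform(-1, 1)),
                    }
                results.append(make_screen_result(f"D{d}", rows))
            calls = classify_dark_biomarkers(results)
            dark_cols = [c for c in calls.columns if c.startswith("dark_")]
            n_dark = calls[dark_cols].sum(axis=1)
            assert ((calls["call"] == "strong") == (n_dark == n_ds)).all()
            assert not ((calls["call"] == "strong") & (calls["call"] == "weak")).any()
            assert (calls.loc[calls["call"] == "weak", dark_cols].sum(axis=1) > 0).all()


class TestReports:
    def two_calls(self):
        results = [
            make_screen_result("B", {
                "strong_at": {"p_mqtrans": 0.001, "p_original": 0.742, "gene_symbol": "GBP5"},
                "weak_at": {"p_mqtrans": 0.001, "p_original": 0.954, "gene_symbol": "MX2"},
            }),
            make_screen_result("C", {
                "strong_at": {"p_mqtrans": 0.001, "p_original": 0.64, "gene_symbol": "GBP5"},
                "weak_at": {"p_mqtrans": 0.9, "p_original": 0.2, "gene_symbol": "MX2"},
            }),
        ]
        return classify_dark_biomarkers(results), results

    def test_summary_roundtrip(self, tmp_path):
        calls, results = self.two_calls()
        path = tmp_path / "summary.tsv"
        write_report(calls, results, path, tmp_path / "stats.tsv")
        back = read_report(path)
        assert list(back["Type"]) == ["Strong", "Weak"]
        assert list(back["Feature"]) == ["strong_at", "weak_at"]
        assert list(back["Gene"]) == ["GBP5", "MX2"]
        assert list(back["db_B"]) == [1, 1] and list(back["db_C"]) == [1, 0]
        stats_table = pd.read_csv(tmp_path / "stats.tsv", sep="\t")
        assert len(stats_table) == 4  # 2 features x 2 datasets

    def test_empty_calls_give_header_only(self, tmp_path):
        calls, results = self.two_calls()
        empty = calls[calls["call"] == "nothing"]
        write_report(empty, results, tmp_path / "summary.tsv")
        lines = (tmp_path / "summary.tsv").read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("Type\tFeature\tGene")

    def test_pca_coordinates_shape(self, rng):
        values = pd.DataFrame(rng.uniform(size=(13, 30)))
        coords = pca_coordinates(values)
        assert coords.shape == (30, 2)
        assert list(coords.columns) == ["PC1", "PC2"]


class TestPolicyValidation:
    @pytest.mark.parametrize("kwargs", [
        {"alpha_detour": 0.0}, {"alpha_detour": 0.6, "weak_original_floor": 0.5},
        {"alpha_original": 0.0}, {"pcc_threshold": 1.0},
    ])
    def test_invalid_policies_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScreenPolicy(**kwargs)
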