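"""QC statistics, fragment selection, retention filtering and
differential abundance, against hand calculations and reference
implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from diawin.extract import QUANT_COLUMNS, QuantMatrix, channel_label
from diawin.simulate import make_catalog, simulate_two_group_matrix
from diawin.stats import (
    StatParams,
    bh_adjust,
    channel_stats,
    differential,
    filter_for_diff,
    linearity,
    median_center,
    pearson_r2,
    qc_summary,
    representative_readout,
    rsd,
    rsd_category,
    select_best_fragment,
)


def matrix_from_rows(rows):
    return QuantMatrix(pd.DataFrame(rows, columns=QUANT_COLUMNS))


def simple_matrix(values_by_channel, samples, entry_id="E", sumcomp="PC 34:1",
                  polarity="positive"):
    rows = []
    for channel, vals in values_by_channel.items():
        for s, v in zip(samples, vals):
            rows.append({"entry_id": entry_id, "sum_composition": sumcomp,
                         "adduct": "[M+H]+", "polarity": polarity,
                         "channel": channel, "sample": s,
                         "area": v, "filled": False})
    return matrix_from_rows(rows)


class TestRsd:
    def test_constant_values_have_zero_rsd(self):
        assert rsd([5.0, 5.0, 5.0]) == 0.0

    def test_hand_calculation_with_sample_sd(self):
        # sd([90,100,110], ddof=1) = 10, mean = 100
        assert rsd([90.0, 100.0, 110.0]) == pytest.approx(10.0)

    def test_single_value_is_non_quantifiable(self):
        assert rsd([100.0]) is None
        assert rsd_category(None) == "non_quantifiable"

    def test_categories(self):
        assert rsd_category(5.0) == "<20"
        assert rsd_category(25.0) == "20-30"
        assert rsd_category(45.0) == ">30"


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels_on_1000_random_vectors(self):
        """Dual route: own step-up BH vs statsmodels fdr_bh, 1e-12."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestPearsonR2:
    def test_proportional_series_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r2(x, 2 * x) == pytest.approx(1.0)

    def test_constant_side_is_undefined(self):
        assert np.isnan(pearson_r2([1, 2, 3], [5, 5, 5]))

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        y = 3 * x + rng.normal(size=50)
        r, _ = sps.pearsonr(x, y)
        assert pearson_r2(x, y) == pytest.approx(r * r, abs=1e-12)


class TestQcSummary:
    def test_identical_qc_values_all_tight(self):
        samples = [f"qc_{i}" for i in range(6)]
        m = simple_matrix({"MS1": [100.0] * 6, "500.0000": [40.0] * 6}, samples)
        cs, summary = qc_summary(m, samples)
        assert set(cs.rsd_category) == {"<20"}
        assert summary.set_index("level").loc["MS1", "median_rsd_all"] == 0.0

    def test_generating_cvs_recovered(self):
        """Per-channel log-normal noise at CV 8% (MS1) / 18% (MS2) shows
        up as median RSDs within 3 points of the generating values."""
        catalog = make_catalog(150, seed=9)
        m, _, samples = simulate_two_group_matrix(
            catalog, 5, {}, ms1_cv=0.08, ms2_cv=0.18, n_qc=6, seed=9)
        _, summary = qc_summary(m, samples["QC"])
        med = summary.set_index("level")["median_rsd_all"]
        assert abs(med["MS1"] - 8.0) <= 3.0
        assert abs(med["MS2"] - 18.0) <= 3.0

    def test_single_qc_observation_is_non_quantifiable(self):
        samples = ["qc_0", "qc_1"]
        m = simple_matrix({"MS1": [100.0, np.nan]}, samples)
        cs, summary = qc_summary(m, samples)
        assert cs.iloc[0].rsd_category == "non_quantifiable"

    def test_category_counts_conserve_totals(self):
        catalog = make_catalog(60, seed=33)
        m, _, samples = simulate_two_group_matrix(
            catalog, 3, {}, ms1_cv=0.15, ms2_cv=0.35, n_qc=6, seed=33)
        _, summary = qc_summary(m, samples["QC"])
        for _, row in summary.iterrows():
            assert (row.n_rsd_lt20 + row.n_rsd_20_30 + row.n_rsd_gt30
                    + row.n_non_quantifiable) == row.n_total


class TestSelectBestFragment:
    samples = [f"s{i}" for i in range(6)]

    def test_single_fragment_returns_itself(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        m = simple_matrix({"MS1": x, "500.0000": 2 * x}, self.samples)
        assert select_best_fragment(m, "E", self.samples) == "500.0000"

    def test_higher_r2_wins(self):
        rng = np.random.default_rng(4)
        x = np.linspace(1, 6, 6)
        good = 2 * x + rng.normal(0, 0.01, 6)
        bad = 2 * x + rng.normal(0, 2.0, 6)
        m = simple_matrix({"MS1": x, "500.0000": good, "600.0000": bad}, self.samples)
        assert select_best_fragment(m, "E", self.samples) == "500.0000"

    def test_r2_tie_broken_by_lower_qc_rsd(self):
        x = np.linspace(1, 6, 6)
        m = simple_matrix({"MS1": x, "500.0000": 2 * x, "600.0000": 3 * x},
                          self.samples)
        qc = ["q0", "q1", "q2"]
        qc_rows = []
        for channel, vals in {"500.0000": [10, 14, 18], "600.0000": [10, 10.5, 11],
                              "MS1": [5, 5, 5]}.items():
            for s, v in zip(qc, vals):
                qc_rows.append({"entry_id": "E", "sum_composition": "PC 34:1",
                                "adduct": "[M+H]+", "polarity": "positive",
                                "channel": channel, "sample": s, "area": float(v),
                                "filled": False})
        m2 = QuantMatrix(pd.concat([m.df, pd.DataFrame(qc_rows)], ignore_index=True))
        assert select_best_fragment(m2, "E", self.samples, qc_samples=qc) == "600.0000"


class TestLinearity:
    volumes = {"d0": 0.25, "d1": 0.5, "d2": 1.0, "d3": 2.0, "d4": 4.0, "d5": 8.0}

    def test_proportional_series_is_one(self):
        samples = list(self.volumes)
        vols = np.array(list(self.volumes.values()))
        m = simple_matrix({"MS1": 100 * vols}, samples)
        lin = linearity(m, self.volumes)
        assert lin.iloc[0].r2_linearity == pytest.approx(1.0)

    def test_saturated_top_volume_excluded(self):
        """A plateau at 8 uL does not perturb R2 because only volumes up
        to 4 uL enter the fit — and exactly 5 of the 6 points are used."""
        samples = list(self.volumes)
        vols = np.array(list(self.volumes.values()))
        areas = 100 * vols
        areas[-1] = areas[-2] * 1.05  # hard saturation at 8 uL
        m = simple_matrix({"MS1": areas}, samples)
        lin = linearity(m, self.volumes)
        assert lin.iloc[0].r2_linearity == pytest.approx(1.0)
        assert lin.iloc[0].n_volumes_used == 5


class TestFilterForDiff:
    qc = [f"qc_{i}" for i in range(6)]
    study = [f"s{i}" for i in range(10)]

    def _matrix(self, ms1_qc, frag_qc, ms1_study, frag_study, entry="E"):
        rows = []
        for channel, qc_vals, st_vals in (("MS1", ms1_qc, ms1_study),
                                          ("500.0000", frag_qc, frag_study)):
            for s, v in zip(self.qc, qc_vals):
                rows.append({"entry_id": entry, "sum_composition": "PC 34:1",
                             "adduct": "[M+H]+", "polarity": "positive",
                             "channel": channel, "sample": s, "area": v,
                             "filled": False})
            for s, v in zip(self.study, st_vals):
                rows.append({"entry_id": entry, "sum_composition": "PC 34:1",
                             "adduct": "[M+H]+", "polarity": "positive",
                             "channel": channel, "sample": s, "area": v,
                             "filled": False})
        return matrix_from_rows(rows)

    def test_entry_failing_only_r2_criterion_dropped(self):
        rng = np.random.default_rng(12)
        x = np.linspace(100, 1000, 10)
        m = self._matrix([100] * 6, [50] * 6, x, rng.permutation(x))
        assert len(filter_for_diff(m, self.qc, self.study)) == 0

    def test_good_entry_retained_with_qualifying_fragment(self):
        x = np.linspace(100, 1000, 10)
        m = self._matrix([100, 101, 99, 100, 102, 98], [50, 51, 49, 50, 52, 48],
                         x, 0.5 * x)
        out = filter_for_diff(m, self.qc, self.study)
        assert len(out) == 1
        assert out.iloc[0].qualifying_fragments == "500.0000"

    def test_boundary_rsd_is_strict(self):
        """MS1 QC RSD of 29.9% passes the strict < 30% gate; 30.1%
        fails. The alternating-pair construction hits the target RSD
        exactly (mean 100, sample sd d*sqrt(6/5) over 6 points)."""
        x = np.linspace(100, 1000, 10)

        def qc_with_rsd(target):
            d = target / np.sqrt(6 / 5)
            return [100.0 - d, 100.0 + d] * 3

        ok = self._matrix(qc_with_rsd(29.9), [50, 51, 49, 50, 52, 48], x, 0.5 * x)
        bad = self._matrix(qc_with_rsd(30.1), [50, 51, 49, 50, 52, 48], x, 0.5 * x)
        assert rsd(ok.values("E", "MS1", self.qc)) == pytest.approx(29.9)
        assert rsd(bad.values("E", "MS1", self.qc)) == pytest.approx(30.1)
        assert len(filter_for_diff(ok, self.qc, self.study)) == 1
        assert len(filter_for_diff(bad, self.qc, self.study)) == 0

    def test_noisy_fragments_dropped_in_simulation(self):
        """Entries whose MS2 noise is blown up to CV 60% drop out of the
        retained set; clean entries with real inter-sample variation
        stay."""
        rng = np.random.default_rng(7)
        catalog = make_catalog(40, seed=7)
        changes = {sp.sum_composition: float(rng.uniform(2, 4)) for sp in catalog}
        m, _, samples = simulate_two_group_matrix(
            catalog, 5, changes, ms1_cv=0.08, ms2_cv=0.10, n_qc=6, seed=7)
        noisy_entries = {sp.to_library_entry().entry_id for sp in catalog[:8]}
        df = m.df.copy()
        sel = df.entry_id.isin(noisy_entries) & (df.channel != "MS1")
        df.loc[sel, "area"] *= rng.lognormal(0, 0.55, int(sel.sum()))
        m2 = QuantMatrix(df)
        out = filter_for_diff(m2, samples["QC"], samples["WT"] + samples["KO"])
        retained = set(out.entry_id)
        assert len(retained & noisy_entries) <= 2
        assert len(retained) >= 25

    def test_loosening_thresholds_monotone(self):
        catalog = make_catalog(30, seed=19)
        changes = {sp.sum_composition: 3.0 for sp in catalog[:15]}
        m, _, samples = simulate_two_group_matrix(
            catalog, 5, changes, ms1_cv=0.15, ms2_cv=0.25, n_qc=6, seed=19)
        tight = filter_for_diff(m, samples["QC"], samples["WT"] + samples["KO"],
                                StatParams(rsd_pass=25.0, r2_ms1_min=0.9))
        loose = filter_for_diff(m, samples["QC"], samples["WT"] + samples["KO"],
                                StatParams(rsd_pass=35.0, r2_ms1_min=0.7))
        assert set(tight.entry_id) <= set(loose.entry_id)


class TestRepresentativeReadout:
    def test_lowest_rsd_channel_wins_across_polarities(self):
        qc = ["q0", "q1", "q2"]
        rows = []
        # positive MS1: RSD ~5%; negative fragment: RSD ~1%
        spec = [("Epos", "positive", "MS1", [100, 105, 95]),
                ("Epos", "positive", "600.0000", [50, 70, 40]),
                ("Eneg", "negative", "MS1", [200, 260, 150]),
                ("Eneg", "negative", "500.0000", [80, 80.5, 79.8])]
        for entry, pol, channel, vals in spec:
            for s, v in zip(qc, vals):
                rows.append({"entry_id": entry, "sum_composition": "PC 34:1",
                             "adduct": "[M+H]+", "polarity": pol,
                             "channel": channel, "sample": s, "area": float(v),
                             "filled": False})
        m = matrix_from_rows(rows)
        retained = pd.DataFrame([
            {"entry_id": "Epos", "sum_composition": "PC 34:1", "polarity": "positive",
             "ms1_rsd_qc": 5.0, "qualifying_fragments": "600.0000"},
            {"entry_id": "Eneg", "sum_composition": "PC 34:1", "polarity": "negative",
             "ms1_rsd_qc": 25.0, "qualifying_fragments": "500.0000"},
        ])
        reps = representative_readout(m, retained, qc)
        assert len(reps) == 1
        assert reps.iloc[0].channel == "500.0000"
        assert reps.iloc[0].polarity == "negative"


class TestDifferential:
    def _run(self, matrix, samples, reps=None):
        if reps is None:
            reps = pd.DataFrame([{"entry_id": e, "sum_composition": e,
                                  "channel": "MS1", "polarity": "positive"}
                                 for e in matrix.entry_ids])
        groups = {"WT": samples["WT"], "KO": samples["KO"]}
        return differential(matrix, reps, groups)

    def test_identical_groups_not_significant(self):
        samples = {"WT": [f"w{i}" for i in range(5)], "KO": [f"k{i}" for i in range(5)]}
        m = simple_matrix({"MS1": [100.0] * 10}, samples["WT"] + samples["KO"])
        out = self._run(m, samples)
        assert out.iloc[0].log2_fc == 0.0
        assert not out.iloc[0].significant
        assert out.iloc[0].zero_variance_flag

    def test_welch_matches_scipy_on_regular_data(self):
        rng = np.random.default_rng(14)
        samples = {"WT": [f"w{i}" for i in range(5)], "KO": [f"k{i}" for i in range(5)]}
        a = rng.lognormal(10, 0.3, 5)
        b = rng.lognormal(11, 0.5, 5)
        m = simple_matrix({"MS1": np.concatenate([a, b])},
                          samples["WT"] + samples["KO"])
        out = self._run(m, samples)
        _, p_ref = sps.ttest_ind(np.log2(b), np.log2(a), equal_var=False)
        assert out.iloc[0].p_value == pytest.approx(p_ref, abs=1e-12)

    def test_power_and_error_rate_at_desk_scale(self):
        """150 null + 50 truly 2.5x lipids at CV 10%, n = 5 + 5: the
        filter + representative + Welch-BH chain finds >= 45 of 50 true
        changes and flags <= 5% of nulls, per seed."""
        detected, false_pos = [], []
        for seed in range(3):
            catalog = make_catalog(200, seed=300 + seed)
            changed = {sp.sum_composition: 2.5 for sp in catalog[:50]}
            m, truth, samples = simulate_two_group_matrix(
                catalog, 5, changed, ms1_cv=0.10, ms2_cv=0.10, n_qc=6, seed=seed)
            retained = filter_for_diff(m, samples["QC"],
                                       samples["WT"] + samples["KO"])
            reps = representative_readout(m, retained, samples["QC"])
            out = differential(m, reps, {"WT": samples["WT"], "KO": samples["KO"]})
            sig = set(out[out.significant].sum_composition)
            true_set = set(truth[truth.is_changed].sum_composition)
            detected.append(len(sig & true_set))
            false_pos.append(len(sig - true_set))
        assert all(d >= 45 for d in detected)
        assert all(fp <= 0.05 * 150 for fp in false_pos)

    def test_type_one_error_under_global_null(self):
        """All-null matrices tested directly (no retention filter, MS1
        readout): average fraction of significant q-values stays near
        the nominal level."""
        rates = []
        for seed in range(10):
            catalog = make_catalog(100, seed=500 + seed)
            m, _, samples = simulate_two_group_matrix(
                catalog, 5, {}, ms1_cv=0.10, ms2_cv=0.10, n_qc=2, seed=seed)
            reps = pd.DataFrame([
                {"entry_id": e, "sum_composition": e, "channel": "MS1",
                 "polarity": "positive"}
                for e in m.entry_ids])
            out = differential(m, reps, {"WT": samples["WT"], "KO": samples["KO"]},
                               StatParams(fc_threshold=1.0 + 1e-9))
            rates.append((out.q_value < 0.05).mean())
        assert np.mean(rates) <= 0.07

    def test_fold_change_parameter_recovery(self):
        """Programmed 3x fold changes come back as median log2FC within
        0.1 of log2(3) at CV 10%, n = 5."""
        catalog = make_catalog(80, seed=77)
        changed = {sp.sum_composition: 3.0 for sp in catalog[:40]}
        m, truth, samples = simulate_two_group_matrix(
            catalog, 5, changed, ms1_cv=0.10, ms2_cv=0.10, n_qc=6, seed=77)
        reps = pd.DataFrame([
            {"entry_id": sp.to_library_entry().entry_id,
             "sum_composition": sp.sum_composition, "channel": "MS1",
             "polarity": "positive"}
            for sp in catalog[:40]])
        out = differential(m, reps, {"WT": samples["WT"], "KO": samples["KO"]})
        assert abs(out.log2_fc.median() - np.log2(3.0)) <= 0.1


class TestMedianCenter:
    def test_constant_row_is_all_zero(self):
        samples = [f"s{i}" for i in range(5)]
        m = simple_matrix({"MS1": [100.0] * 5}, samples)
        out = median_center(m)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_doubled_sample_shows_plus_one(self):
        samples = [f"s{i}" for i in range(5)]
        m = simple_matrix({"MS1": [100, 100, 100, 100, 200]}, samples)
        out = median_center(m)
        assert out.iloc[0, 4] == pytest.approx(1.0)

    def test_row_medians_exactly_zero_on_random_input(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(7)]
        rows = []
        for k in range(20):
            for s in samples:
                rows.append({"entry_id": f"E{k}", "sum_composition": f"PC {k}:0",
                             "adduct": "[M+H]+", "polarity": "positive",
                             "channel": "MS1", "sample": s,
                             "area": float(rng.lognormal(10, 1)), "filled": False})
        out = median_center(matrix_from_rows(rows))
        assert np.allclose(out.median(axis=1).to_numpy(), 0.0, atol=1e-12)
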