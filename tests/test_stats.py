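"""Mixed models: exactness on noiseless data, coding, group comparisons."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sylseq.chron_sim import default_presets, simulate_isis, speaker_means
from sylseq.stats import (
    bonferroni_alpha, compare_groups, fit_interaction_model, fit_length_model,
    fit_practice_model,
)
from sylseq.stimuli import build_schedule


@pytest.fixture(scope="module")
def noiseless_tables():
    presets = default_presets()
    sched = build_schedule(5)
    out = {}
    for name in ("healthy", "hypokinetic"):
        quiet = replace(presets[name], speaker_sd_isi=0.0, resid_sd_isi=0.0)
        df = simulate_isis(quiet, sched, 1)
        out[name] = {
            "length": speaker_means(df, "length", "isi_ms"),
            "run": speaker_means(df, "run", "isi_ms"),
        }
    return out


class TestBonferroni:
    @pytest.mark.parametrize("k, alpha", [(2, 0.025), (1, 0.05)])
    def test_adjusted_threshold(self, k, alpha):
        assert bonferroni_alpha(k) == pytest.approx(alpha)

    def test_three_tests_rounds_to_0167(self):
        assert round(bonferroni_alpha(3), 4) == 0.0167

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0)


class TestNoiselessExactness:
    def test_length_slopes_equal_generative(self, noiseless_tables):
        fit_h = fit_length_model(noiseless_tables["healthy"]["length"], "isi")
        fit_k = fit_length_model(noiseless_tables["hypokinetic"]["length"], "isi")
        assert fit_h.slope == pytest.approx(4.9, rel=1e-8)
        assert fit_h.intercept == pytest.approx(230.0, rel=1e-8)
        assert fit_k.slope == pytest.approx(12.0, rel=1e-8)

    def test_practice_slopes_equal_generative(self, noiseless_tables):
        fit_h = fit_practice_model(noiseless_tables["healthy"]["run"], "isi")
        fit_k = fit_practice_model(noiseless_tables["hypokinetic"]["run"], "isi")
        assert fit_h.slope == pytest.approx(-3.2, rel=1e-8)
        assert fit_k.slope == pytest.approx(-3.5, rel=1e-8)

    def test_interaction_equals_slope_difference(self, noiseless_tables):
        both = pd.concat([noiseless_tables["healthy"]["length"],
                          noiseless_tables["hypokinetic"]["length"]])
        fit = fit_interaction_model(both, "length")
        assert fit.interaction == pytest.approx(12.0 - 4.9, rel=1e-8)

    def test_identical_groups_null_interaction(self, noiseless_tables):
        a = noiseless_tables["healthy"]["length"].copy()
        b = a.copy()
        b["group"] = "twin"
        b["speaker"] = b["speaker"] + "-twin"
        rng = np.random.default_rng(0)
        noisy = pd.concat([a, b]).reset_index(drop=True)
        noisy["value"] = noisy["value"] + rng.normal(0, 1.0, len(noisy))
        fit = fit_interaction_model(noisy, "length")
        assert abs(fit.interaction) < 1.5
        assert fit.p_interaction > 0.05


class TestModelStructure:
    def test_parallel_speakers_share_slope_with_positive_variance(self):
        x = np.arange(2, 6)
        rows = []
        for spk, off in (("a", 10.0), ("b", 40.0)):
            for xi in x:
                rows.append({"speaker": spk, "length": xi, "value": off + 2.0 * xi})
        fit = fit_length_model(pd.DataFrame(rows), "isi")
        assert fit.slope == pytest.approx(2.0, rel=1e-6)
        assert fit.random_intercept_var > 0 or fit.method == "ols-fallback"

    def test_shift_equivariance_of_intercept_only(self):
        rng = np.random.default_rng(1)
        rows = [{"speaker": f"s{s}", "length": n,
                 "value": 200 + 5 * n + rng.normal(0, 3)}
                for s in range(6) for n in range(2, 6)]
        df = pd.DataFrame(rows)
        fit0 = fit_length_model(df, "isi")
        shifted = df.assign(value=df["value"] + 100.0)
        fit1 = fit_length_model(shifted, "isi")
        assert fit1.slope == pytest.approx(fit0.slope, rel=1e-6)
        assert fit1.intercept == pytest.approx(fit0.intercept + 100.0, rel=1e-6)

    def test_isi_model_drops_length_one(self):
        rows = [{"speaker": f"s{s}", "length": n, "value": 200.0 + 5 * n}
                for s in range(3) for n in range(1, 6)]
        fit = fit_length_model(pd.DataFrame(rows), "isi")
        assert "length - 2" in fit.predictor_coding
        assert fit.df_resid == 3 * 4 - 2

    def test_arcsine_and_percent_slopes_agree_in_sign(self, schedule):
        from sylseq.chron_sim import simulate_errors, speaker_error_rates
        presets = default_presets()
        df = simulate_errors(presets["hypokinetic"], schedule, 21)
        pct = fit_length_model(speaker_error_rates(df, "length"), "pctErr")
        arc = speaker_error_rates(df, "length", percent=False)
        arc["value"] = np.arcsin(np.sqrt(arc["value"]))
        asn = fit_length_model(arc, "arcsineErr")
        assert np.sign(pct.slope) == np.sign(asn.slope) == 1.0


class TestCompareGroups:
    def test_identical_groups_zero_difference(self):
        df = pd.DataFrame([{"speaker": f"{g}{i}", "group": g, "value": 250.0}
                           for g in ("a", "b") for i in range(5)])
        gc = compare_groups(df)
        assert gc.post_hoc[0][1] == pytest.approx(0.0)

    def test_generative_offsets_recovered(self):
        rng = np.random.default_rng(2)
        rows = []
        for g, mu, n in (("healthy", 230, 14), ("hypokinetic", 306, 8),
                         ("ataxic", 318, 5)):
            for i in range(n):
                rows.append({"speaker": f"{g}{i}", "group": g,
                             "value": rng.normal(mu, 2.0)})
        gc = compare_groups(pd.DataFrame(rows))
        diffs = {pair: d for pair, d, _ in gc.post_hoc}
        assert abs(diffs["healthy-hypokinetic"]) == pytest.approx(76, abs=4)
        assert abs(diffs["ataxic-healthy"]) == pytest.approx(88, abs=4)
        assert gc.bonferroni_alpha == pytest.approx(0.05 / 3)

    def test_levene_violation_switches_to_kruskal(self):
        rng = np.random.default_rng(3)
        rows = [{"speaker": f"a{i}", "group": "a", "value": rng.normal(0, 0.1)}
                for i in range(12)]
        rows += [{"speaker": f"b{i}", "group": "b", "value": rng.normal(0, 40.0)}
                 for i in range(12)]
        gc = compare_groups(pd.DataFrame(rows))
        assert gc.levene_p < 0.05 and gc.used_test == "kruskal"

    def test_small_group_rejected(self):
        df = pd.DataFrame([{"speaker": "a1", "group": "a", "value": 1.0},
                           {"speaker": "b1", "group": "b", "value": 2.0},
                           {"speaker": "b2", "group": "b", "value": 3.0}])
        with pytest.raises(ValueError, match="speakers"):
            compare_groups(df)
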