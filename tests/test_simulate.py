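import numpy as np
import pandas as pd
import pytest

import meripchip as mc
from meripchip.differential import direction_counts


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_design, noisy):
        ip1, sup1, truth1, cfg = noisy
        ip2, sup2, truth2 = mc.simulate_experiment(small_design, cfg)
        assert ip1 == ip2
        assert sup1 == sup2
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_different_seed_differs(self, small_design, noisy):
        _, _, _, cfg = noisy
        cfg2 = mc.SimConfig(**{**cfg.__dict__, "seed": cfg.seed + 1})
        ip2, _, _ = mc.simulate_experiment(small_design, cfg2)
        assert not noisy[0].values.equals(ip2.values)

    def test_enlarging_design_preserves_earlier_rows(self):
        """The abundance noise stream is row-stable: adding transcripts
        appends draws without perturbing existing ones."""
        cfg = mc.SimConfig(noise_sd=0.25, seed=5)
        d50 = mc.default_design(n_mrna=50, n_spike_pos=2, n_spike_neg=2)
        d80 = mc.default_design(n_mrna=80, n_spike_pos=2, n_spike_neg=2)
        ip50, _, _ = mc.simulate_experiment(d50, cfg)
        ip80, _, _ = mc.simulate_experiment(d80, cfg)
        first = ip50.values.iloc[:50]
        pd.testing.assert_frame_equal(first, ip80.values.loc[first.index])


class TestNoiseFreeRecovery:
    def test_planted_ratios_recovered_exactly(self, small_design, noisefree):
        ip, sup, truth, _ = noisefree
        q = mc.quantify(ip, sup, small_design)
        meth = mc.call_differential(q.m6a_quantity, q.groups, kind="methylation")
        expr = mc.call_differential(q.expression, q.groups, kind="expression")
        np.testing.assert_allclose(
            meth["fold_change"], truth["true_meth_ratio"], rtol=0, atol=1e-9
        )
        np.testing.assert_allclose(
            expr["fold_change"], truth["true_expr_ratio"], rtol=0, atol=1e-9
        )

    def test_percentage_recovers_planted_fraction(self, small_design, noisefree):
        ip, sup, truth, _ = noisefree
        q = mc.quantify(ip, sup, small_design)
        case = [s for s in q.m6a_pct.columns if s.startswith("chol")]
        ctrl = [s for s in q.m6a_pct.columns if s.startswith("skin")]
        np.testing.assert_allclose(
            q.m6a_pct[case],
            np.tile(truth["true_m6a_pct_case"].to_numpy()[:, None], (1, len(case))),
            atol=1e-6,
        )
        np.testing.assert_allclose(
            q.m6a_pct[ctrl],
            np.tile(truth["true_m6a_pct_control"].to_numpy()[:, None], (1, len(ctrl))),
            atol=1e-6,
        )

    def test_channels_reconstruct_total_abundance(self, small_design):
        """With no planted effects and no noise, IP + Sup equals the
        baseline copy number exactly."""
        cfg = mc.SimConfig(n_transcripts=200, noise_sd=0.0, seed=0)
        ip, sup, _ = mc.simulate_experiment(small_design, cfg)
        mrna = list(small_design.mrna["probe_id"])
        total = ip.values.loc[mrna] + sup.values.loc[mrna]
        np.testing.assert_allclose(total, 2.0**cfg.baseline_log2, rtol=1e-12)


class TestNullBehaviour:
    def test_null_false_call_rate_below_alpha(self):
        """Without planted effects, FC>=3 & p<0.05 calls are rare."""
        design = mc.default_design(n_mrna=400, n_spike_pos=4, n_spike_neg=4)
        rates = []
        for seed in range(10):
            cfg = mc.SimConfig(n_transcripts=400, noise_sd=0.25, seed=seed)
            ip, sup, _ = mc.simulate_experiment(design, cfg)
            q = mc.quantify(ip, sup, design)
            meth = mc.call_differential(q.m6a_quantity, q.groups)
            rates.append(float((meth["direction"] != "none").mean()))
        assert max(rates) <= 0.05


class TestScaleFactors:
    def test_per_sample_channel_scaling_cancels_in_quantification(self, small_design):
        base = dict(n_transcripts=200, n_hyper=20, noise_sd=0.2, seed=4)
        cfg_flat = mc.SimConfig(**base)
        cfg_scaled = mc.SimConfig(**base, scale_log2_min=-1.5, scale_log2_max=1.5)
        q_flat = mc.quantify(*mc.simulate_experiment(small_design, cfg_flat)[:2],
                             small_design)
        q_scaled = mc.quantify(*mc.simulate_experiment(small_design, cfg_scaled)[:2],
                               small_design)
        np.testing.assert_allclose(
            q_flat.m6a_quantity, q_scaled.m6a_quantity, atol=1e-9
        )
        np.testing.assert_allclose(q_flat.m6a_pct, q_scaled.m6a_pct, atol=1e-9)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_transcripts": 10, "n_hyper": 8, "n_hypo": 8},
            {"n_transcripts": 10, "n_hyper": 3, "n_hypo": 3, "n_up": 3, "n_down": 3},
            {"noise_sd": -0.1},
            {"true_meth_fc": 0.0},
            {"meth_fraction_baseline": 1.0},
            {"n_per_group": 0},
            {"scale_log2_min": 1.0, "scale_log2_max": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, small_design, kwargs):
        cfg = mc.SimConfig(**kwargs)
        with pytest.raises(mc.ValidationError):
            mc.simulate_experiment(small_design, cfg)

    def test_mismatched_transcript_count_rejected(self, small_design):
        cfg = mc.SimConfig(n_transcripts=123)
        with pytest.raises(mc.ValidationError, match="match"):
            mc.simulate_experiment(small_design, cfg)


class TestSimulatedQpcr:
    def test_deterministic(self, noisy):
        _, _, truth, cfg = noisy
        targets = list(truth.index[:2])
        t1 = mc.simulate_qpcr(truth, targets, cfg)
        t2 = mc.simulate_qpcr(truth, targets, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_control_rows_once_per_sample_replicate_role(self, noisy):
        _, _, truth, cfg = noisy
        table = mc.simulate_qpcr(truth, [truth.index[0]], cfg)
        controls = table[table["target_id"].isin(["CTA850", "CTA650"])]
        key = ["sample_id", "target_id", "role", "replicate"]
        assert not controls.duplicated(subset=key).any()
        per_sample = controls.groupby("sample_id")["target_id"].nunique()
        assert (per_sample == 2).all()

    def test_zero_noise_percent_input_recovers_fraction(self, small_design):
        """f = 0.5, input fraction 1.0 -> %input = 50 by construction."""
        cfg = mc.SimConfig(n_transcripts=200, noise_sd=0.0, seed=1)
        _, _, truth = mc.simulate_experiment(small_design, cfg)
        table = mc.simulate_qpcr(
            truth, [truth.index[0]], cfg, input_fraction=1.0
        )
        row = table[(table["target_id"] == truth.index[0])]
        ip_ct = row[row["role"] == "IP"]["ct"].iloc[0]
        in_ct = row[row["role"] == "input"]["ct"].iloc[0]
        assert mc.percent_input(ip_ct, in_ct, 1.0) == pytest.approx(50.0)

    def test_unknown_transcript_rejected(self, noisy):
        _, _, truth, cfg = noisy
        with pytest.raises(mc.ValidationError, match="NOPE"):
            mc.simulate_qpcr(truth, ["NOPE"], cfg)

    def test_group_difference_recovers_planted_direction(self, small_design):
        """Across 10 seeds the qPCR comparison recovers the planted
        hyper/hypo signs for a clear majority."""
        agree = 0
        for seed in range(10):
            cfg = mc.SimConfig(
                n_transcripts=200, n_hyper=20, n_hypo=20, noise_sd=0.25, seed=seed
            )
            _, _, truth = mc.simulate_experiment(small_design, cfg)
            hyper_t = truth.index[0]
            hypo_t = truth.index[25]
            table = mc.simulate_qpcr(truth, [hyper_t, hypo_t], cfg)
            norm = mc.control_normalize(table)
            up = mc.group_compare(norm, hyper_t)
            down = mc.group_compare(norm, hypo_t)
            if up.direction == "higher" and down.direction == "lower":
                agree += 1
        assert agree > 5
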