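import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import meripchip as mc
from meripchip.containers import IntensityMatrix
from meripchip.quantify import (
    expression_level,
    m6a_percentage,
    normalize_channel,
    transcript_level,
)


def tiny_design():
    df = pd.DataFrame(
        {
            "probe_id": ["p1", "p2", "sp1", "sp2", "sn1", "sn2"],
            "transcript_id": ["t1", "t2", "c850a", "c850b", "c650a", "c650b"],
            "gene_symbol": ["G1", "G2", "CTA850", "CTA850", "CTA650", "CTA650"],
            "probe_class": ["mRNA", "mRNA", "spike_pos", "spike_pos",
                            "spike_neg", "spike_neg"],
        }
    )
    return mc.ArrayDesign(df, design_name="tiny")


def ip_matrix(values: dict) -> IntensityMatrix:
    df = pd.DataFrame(values, index=["chol_1", "skin_1"]).T
    return IntensityMatrix(df, {"chol_1": "cholesteatoma", "skin_1": "skin"}, "IP")


class TestNormalizeChannel:
    def test_probe_equal_to_spikes_normalizes_to_zero(self):
        raw = ip_matrix({"p1": [1024, 1024], "p2": [1024, 1024],
                         "sp1": [1024, 1024], "sp2": [1024, 1024]})
        norm = normalize_channel(raw, tiny_design())
        assert norm.scale == "normalized"
        assert norm.values.loc["p1", "chol_1"] == pytest.approx(0.0)

    def test_double_the_spikes_gives_one(self):
        raw = ip_matrix({"p1": [2048, 2048], "sp1": [1024, 1024],
                         "sp2": [1024, 1024]})
        norm = normalize_channel(raw, tiny_design())
        assert norm.values.loc["p1", "chol_1"] == pytest.approx(1.0)

    def test_sample_wide_rescaling_cancels(self):
        raw = ip_matrix({"p1": [512, 512], "p2": [4096, 4096],
                         "sp1": [1024, 1024], "sp2": [2048, 2048]})
        norm1 = normalize_channel(raw, tiny_design())
        scaled = raw.values.copy()
        scaled["chol_1"] *= 7.0
        norm2 = normalize_channel(
            IntensityMatrix(scaled, raw.groups, "IP"), tiny_design()
        )
        pd.testing.assert_frame_equal(norm1.values, norm2.values)

    @given(factor=st.floats(min_value=0.1, max_value=10.0,
                            allow_nan=False, allow_infinity=False))
    def test_rescaling_invariance_random_factor(self, factor):
        raw = ip_matrix({"p1": [512, 300], "p2": [4096, 900],
                         "sp1": [1024, 777], "sp2": [2048, 888]})
        norm1 = normalize_channel(raw, tiny_design())
        scaled = raw.values * factor
        norm2 = normalize_channel(
            IntensityMatrix(scaled, raw.groups, "IP"), tiny_design()
        )
        np.testing.assert_allclose(norm1.values, norm2.values, atol=1e-9)

    def test_spike_rows_retained(self):
        raw = ip_matrix({"p1": [1024, 1024], "sp1": [1024, 1024],
                         "sp2": [1024, 1024]})
        norm = normalize_channel(raw, tiny_design())
        assert "sp1" in norm.values.index

    def test_missing_spikes_rejected(self):
        raw = ip_matrix({"p1": [1024, 1024]})
        with pytest.raises(mc.ValidationError, match="spike"):
            normalize_channel(raw, tiny_design())

    def test_negative_intensity_rejected(self):
        with pytest.raises(mc.FormatError, match="nonnegative"):
            ip_matrix({"p1": [-1, 5], "sp1": [1, 1]})

    def test_zero_intensity_floored_not_minus_inf(self):
        raw = ip_matrix({"p1": [0, 0], "sp1": [1024, 1024], "sp2": [1024, 1024]})
        norm = normalize_channel(raw, tiny_design())
        assert np.isfinite(norm.values.to_numpy()).all()
        assert norm.values.loc["p1", "chol_1"] == pytest.approx(-10.0)

    def test_normalizing_twice_rejected(self):
        raw = ip_matrix({"p1": [1024, 1024], "sp1": [1024, 1024],
                         "sp2": [1024, 1024]})
        norm = normalize_channel(raw, tiny_design())
        with pytest.raises(mc.ValidationError, match="raw"):
            normalize_channel(norm, tiny_design())


class TestTranscriptLevel:
    def test_spike_rows_absent_and_columns_preserved(self):
        raw = ip_matrix({"p1": [1024, 512], "p2": [2048, 256],
                         "sp1": [1024, 1024], "sp2": [1024, 1024]})
        out = transcript_level(normalize_channel(raw, tiny_design()), tiny_design())
        assert list(out.index) == ["t1", "t2"]
        assert list(out.columns) == ["chol_1", "skin_1"]

    def test_multi_probe_transcripts_average_linearly(self):
        design = tiny_design()
        probes = design.probes.copy()
        probes.loc[probes["probe_id"] == "p2", "transcript_id"] = "t1"
        design = mc.ArrayDesign(probes, design_name="multi")
        raw = ip_matrix({"p1": [1024, 1024], "p2": [4096, 4096],
                         "sp1": [1024, 1024], "sp2": [1024, 1024]})
        out = transcript_level(normalize_channel(raw, design), design)
        # linear mean of 1x and 4x the spike level is 2.5x -> log2(2.5)
        assert out.loc["t1", "chol_1"] == pytest.approx(np.log2(2.5))


class TestPercentageAndExpression:
    def make(self, ip_val, sup_val):
        idx = pd.Index(["t1"], name="transcript_id")
        cols = ["s1"]
        ip = pd.DataFrame([[ip_val]], index=idx, columns=cols)
        sup = pd.DataFrame([[sup_val]], index=idx, columns=cols)
        return ip, sup

    def test_equal_channels_give_fifty_percent(self):
        ip, sup = self.make(3.7, 3.7)
        assert m6a_percentage(ip, sup).iloc[0, 0] == pytest.approx(50.0)

    def test_three_to_one_odds_give_seventy_five(self):
        ip, sup = self.make(np.log2(3.0), 0.0)
        assert m6a_percentage(ip, sup).iloc[0, 0] == pytest.approx(75.0)

    @given(delta=st.floats(min_value=-40, max_value=40, allow_nan=False),
           shift=st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_percentage_depends_only_on_difference(self, delta, shift):
        ip1, sup1 = self.make(delta, 0.0)
        ip2, sup2 = self.make(delta + shift, shift)
        assert m6a_percentage(ip1, sup1).iloc[0, 0] == pytest.approx(
            m6a_percentage(ip2, sup2).iloc[0, 0], abs=1e-9
        )

    def test_percentage_monotone_in_difference_with_limits(self):
        deltas = np.linspace(-30, 30, 41)
        pcts = [
            m6a_percentage(*self.make(d, 0.0)).iloc[0, 0] for d in deltas
        ]
        assert all(a < b for a, b in zip(pcts, pcts[1:]))
        assert pcts[0] == pytest.approx(0.0, abs=1e-6)
        assert pcts[-1] == pytest.approx(100.0, abs=1e-6)

    def test_expression_of_equal_zero_channels_is_one(self):
        ip, sup = self.make(0.0, 0.0)
        assert expression_level(ip, sup).iloc[0, 0] == pytest.approx(1.0)

    def test_expression_single_addend_limit(self):
        ip, sup = self.make(10.0, -60.0)
        assert expression_level(ip, sup).iloc[0, 0] == pytest.approx(10.0)

    @given(ip_val=st.floats(min_value=-50, max_value=50, allow_nan=False),
           sup_val=st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_expression_bounds_each_channel(self, ip_val, sup_val):
        ip, sup = self.make(ip_val, sup_val)
        expr = expression_level(ip, sup).iloc[0, 0]
        assert expr >= max(ip_val, sup_val)

    def test_misaligned_inputs_rejected(self):
        ip, _ = self.make(1.0, 1.0)
        sup = ip.rename(index={"t1": "t2"})
        with pytest.raises(mc.AlignmentError):
            m6a_percentage(ip, sup)
        with pytest.raises(mc.AlignmentError):
            expression_level(ip, sup)


class TestQuantifyEndToEnd:
    def test_random_per_sample_rescaling_leaves_quantities_unchanged(
        self, small_design, noisy
    ):
        """Spike-anchored normalization is invariant to channel-wide
        per-sample scale factors (dye efficiency)."""
        ip, sup, _, _ = noisy
        q1 = mc.quantify(ip, sup, small_design)
        rng = np.random.default_rng(42)
        ip_scaled = ip.values * rng.uniform(0.1, 10.0, size=len(ip.samples))
        sup_scaled = sup.values * rng.uniform(0.1, 10.0, size=len(sup.samples))
        q2 = mc.quantify(
            IntensityMatrix(ip_scaled, ip.groups, "IP"),
            IntensityMatrix(sup_scaled, sup.groups, "Sup"),
            small_design,
        )
        np.testing.assert_allclose(q1.m6a_quantity, q2.m6a_quantity, atol=1e-9)
        np.testing.assert_allclose(q1.m6a_pct, q2.m6a_pct, atol=1e-9)
        np.testing.assert_allclose(q1.expression, q2.expression, atol=1e-9)

    def test_channel_tags_enforced(self, small_design, noisy):
        ip, sup, _, _ = noisy
        with pytest.raises(mc.ValidationError):
            mc.quantify(sup, ip, small_design)
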