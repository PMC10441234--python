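import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import meripchip as mc
from meripchip.qpcr import (
    compare_all_targets,
    control_normalize,
    group_compare,
    percent_input,
    star_code,
    summarize_percent_input,
)


class TestPercentInput:
    def test_no_dilution_equal_cts_give_hundred(self):
        assert percent_input(20.0, 20.0, input_fraction=1.0) == pytest.approx(100.0)

    def test_ten_percent_input_gives_ten(self):
        assert percent_input(20.0, 20.0, input_fraction=0.1) == pytest.approx(10.0)

    def test_one_extra_ip_cycle_halves_enrichment(self):
        base = percent_input(20.0, 20.0, input_fraction=1.0)
        later = percent_input(21.0, 20.0, input_fraction=1.0)
        assert later == pytest.approx(base / 2.0)

    @given(shift=st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_invariant_to_common_ct_shift(self, shift):
        a = percent_input(22.0, 18.0, 0.1)
        b = percent_input(22.0 + shift, 18.0 + shift, 0.1)
        assert a == pytest.approx(b, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(mc.ValidationError):
            percent_input(20.0, 20.0, input_fraction=0.0)
        with pytest.raises(mc.ValidationError):
            percent_input(-1.0, 20.0, input_fraction=0.5)


class TestStarCode:
    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.5, ""), (0.05, ""), (0.049, "*"), (0.009, "**"),
            (0.0005, "***"), (5e-5, "****"), (0.0, "****"), (1.0, ""),
        ],
    )
    def test_threshold_function(self, p, stars):
        assert star_code(p) == stars

    @given(p=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_pure_function_of_p(self, p):
        stars = star_code(p)
        assert stars == star_code(p)
        assert stars in ("", "*", "**", "***", "****")
        # stars never increase with p
        assert len(star_code(min(1.0, p + 0.01))) <= len(stars)


def ct_table(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "target_id", "role", "replicate", "ct"]
    )


def sample_block(sample, group, targets):
    """One sample's rows: target -> (ct_ip, ct_input), 2 replicates."""
    rows = []
    for target, (ct_ip, ct_in) in targets.items():
        for rep in (1, 2):
            rows.append((sample, group, target, "IP", rep, ct_ip))
            rows.append((sample, group, target, "input", rep, ct_in))
    return rows


class TestControlNormalize:
    def test_target_matching_positive_control_has_unit_enrichment(self):
        table = ct_table(
            sample_block("s1", "skin", {
                "T": (21.0, 20.0), "CTA850": (21.0, 20.0), "CTA650": (27.0, 20.0),
            })
        )
        norm = control_normalize(table, input_fraction=1.0)
        t = norm[norm["target_id"] == "T"].iloc[0]
        assert t["rel_enrichment"] == pytest.approx(1.0)
        assert bool(t["sample_qc_pass"]) is True

    def test_replicates_average_percent_input_not_ct(self):
        # replicate %input values 100 and 25 -> mean 62.5
        rows = []
        for rep, ct_ip in ((1, 20.0), (2, 22.0)):
            rows.append(("s1", "skin", "T", "IP", rep, ct_ip))
            rows.append(("s1", "skin", "T", "input", rep, 20.0))
        summary = summarize_percent_input(ct_table(rows), input_fraction=1.0)
        assert summary["pct_input"].iloc[0] == pytest.approx(62.5)

    def test_missing_control_names_sample(self):
        table = ct_table(
            sample_block("s9", "skin", {"T": (21.0, 20.0), "CTA850": (21.0, 20.0)})
        )
        with pytest.raises(mc.ValidationError, match="s9"):
            control_normalize(table)

    def test_unpaired_replicates_rejected(self):
        rows = [("s1", "skin", "T", "IP", 1, 20.0)]
        with pytest.raises(mc.ValidationError):
            summarize_percent_input(ct_table(rows))

    def test_failed_spike_qc_flags_sample_and_excludes_it(self):
        targets_ok = {
            "T": (21.0, 20.0), "CTA850": (21.0, 20.0), "CTA650": (27.0, 20.0),
        }
        # negative control as strong as positive -> capture failed
        targets_bad = {
            "T": (21.0, 20.0), "CTA850": (21.0, 20.0), "CTA650": (21.0, 20.0),
        }
        rows = []
        for i in range(1, 4):
            rows += sample_block(f"skin_{i}", "skin", targets_ok)
            rows += sample_block(f"chol_{i}", "cholesteatoma", targets_ok)
        rows += sample_block("chol_4", "cholesteatoma", targets_bad)
        norm = control_normalize(ct_table(rows), input_fraction=1.0)
        flagged = norm[norm["sample_id"] == "chol_4"]
        assert not flagged["sample_qc_pass"].any()
        comp = group_compare(norm, "T")
        assert comp.n_group2 == 3  # chol_4 excluded
        comp_all = group_compare(norm, "T", exclude_flagged=False)
        assert comp_all.n_group2 == 4


class TestGroupCompare:
    def balanced_table(self, case_ip_ct):
        rows = []
        for i in range(1, 4):
            rows += sample_block(f"skin_{i}", "skin", {
                "T": (21.0 + 0.01 * i, 20.0),
                "CTA850": (21.0, 20.0), "CTA650": (29.0, 20.0),
            })
            rows += sample_block(f"chol_{i}", "cholesteatoma", {
                "T": (case_ip_ct + 0.01 * i, 20.0),
                "CTA850": (21.0, 20.0), "CTA650": (29.0, 20.0),
            })
        return control_normalize(ct_table(rows), input_fraction=1.0)

    def test_identical_groups_give_p_one_no_stars(self):
        norm = self.balanced_table(case_ip_ct=21.0)
        comp = group_compare(norm, "T")
        assert comp.p_value == pytest.approx(1.0)
        assert comp.stars == ""
        assert comp.direction == "equal"

    def test_lower_case_ct_means_higher_enrichment_with_stars(self):
        norm = self.balanced_table(case_ip_ct=19.0)  # 4x more captured
        comp = group_compare(norm, "T")
        assert comp.direction == "higher"
        assert comp.p_value < 0.001
        assert comp.stars in ("***", "****")

    def test_insufficient_samples_rejected(self):
        rows = sample_block("skin_1", "skin", {
            "T": (21.0, 20.0), "CTA850": (21.0, 20.0), "CTA650": (29.0, 20.0),
        })
        norm = control_normalize(ct_table(rows), input_fraction=1.0)
        with pytest.raises(mc.ValidationError, match="per group"):
            group_compare(norm, "T")

    def test_unknown_target_rejected(self):
        norm = self.balanced_table(case_ip_ct=21.0)
        with pytest.raises(mc.ValidationError, match="MISSING"):
            group_compare(norm, "MISSING")

    def test_compare_all_targets_skips_controls(self):
        norm = self.balanced_table(case_ip_ct=19.0)
        table = compare_all_targets(norm)
        assert list(table["target_id"]) == ["T"]
        assert set(table.columns) >= {"p_value", "stars", "direction"}
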