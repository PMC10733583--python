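"""Regulation-classification rules and their evidence trail."""

import numpy as np
import pandas as pd
import pytest

from tnftime.classify import (
    ClassifyThresholds,
    check_direction_consistency,
    check_sequential,
    classify_regulation,
    merge_sex_calls,
)

TIMES = [0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0, 72.0]


def flags(**at):
    """Build a flag row like flags(h2='up', h4='up') over the 11-point grid."""
    out = ["none"] * len(TIMES)
    for key, val in at.items():
        t = float(key[1:].replace("_", "."))
        out[TIMES.index(t)] = val
    return out


class TestSequentialRule:
    def test_adjacent_degs_pass(self):
        ok, run = check_sequential(flags(h12="up", h24="up"))
        assert ok and run == 2

    def test_non_adjacent_degs_fail(self):
        ok, run = check_sequential(flags(h2="up", h8="up"))
        assert not ok and run == 1

    def test_all_timepoints_run_eleven(self):
        ok, run = check_sequential(["up"] * 11)
        assert ok and run == 11

    def test_runs_must_share_sign(self):
        ok, _ = check_sequential(flags(h2="up", h4="down"))
        assert not ok


class TestDirectionRule:
    def test_same_direction_consistent(self):
        assert check_direction_consistency(flags(h2="up", h4="up"))

    def test_mixed_directions_inconsistent(self):
        assert not check_direction_consistency(flags(h2="up", h48="down"))

    def test_no_flags_vacuously_consistent(self):
        assert check_direction_consistency(flags())


def _evidence_frame(
    cv_control, cv_treated, deg_flags, lfc_row, peak_t0, expressed=True, gene="g"
):
    cv = pd.DataFrame(
        {"cv_control": [cv_control], "cv_treated": [cv_treated]}, index=[gene]
    )
    deg = pd.DataFrame([deg_flags], index=[gene], columns=TIMES)
    lfc = pd.DataFrame([lfc_row], index=[gene], columns=TIMES)
    peak = pd.Series([peak_t0], index=[gene])
    mask = pd.Series([expressed], index=[gene])
    return cv, deg, lfc, peak, mask


class TestClassifyRegulation:
    def test_induced_stable_control_is_upregulated(self):
        # control flat (cv 0), treated 10 -> 100 sustained: peak vs t0 ~ 3.3
        lfc = [0, 0, 1.5, 3.0, 3.0, 2.5, 2.0, 2.0, 1.5, 1.5, 1.0]
        args = _evidence_frame(
            0.0, 0.8, flags(h2="up", h4="up", h6="up"), lfc, peak_t0=3.32
        )
        out = classify_regulation(*args)
        assert out.loc["g", "label"] == "upregulated"
        assert out.loc["g", "longest_deg_run"] == 3

    def test_drifting_control_excluded(self):
        # control rises 10 -> 100 (cv >= 0.3), DEGs late and negative
        lfc = [0, 0, 0, 0, 0, 0, -1.5, -2.0, -2.0, -2.0, -2.0]
        args = _evidence_frame(
            0.9, 0.05, flags(h12="down", h24="down", h36="down"), lfc, peak_t0=0.1
        )
        out = classify_regulation(*args)
        assert out.loc["g", "label"] == "excluded_control_variable"

    def test_sustained_suppression_is_downregulated(self):
        # control flat at 50, treated falls to ~6: |peak lfc| vs control ~ 3
        lfc = [0, 0, 0, -1.0, -2.0, -2.5, -3.0, -3.0, -3.0, -3.0, -3.0]
        args = _evidence_frame(
            0.05, 0.7,
            flags(h12="down", h24="down", h36="down", h48="down", h72="down"),
            lfc, peak_t0=0.0,
        )
        out = classify_regulation(*args)
        assert out.loc["g", "label"] == "downregulated"
        assert out.loc["g", "peak_abs_log2fc_vs_control"] == pytest.approx(3.0)

    def test_low_expression_short_circuits(self):
        lfc = [0] * 10 + [3.0]
        args = _evidence_frame(
            0.0, 0.8, flags(h48="up", h72="up"), lfc, peak_t0=3.0, expressed=False
        )
        assert classify_regulation(*args).loc["g", "label"] == "excluded_low_expression"

    def test_no_deg_anywhere_is_not_regulated(self):
        args = _evidence_frame(0.0, 0.8, flags(), [0.0] * 11, peak_t0=2.0)
        assert classify_regulation(*args).loc["g", "label"] == "not_regulated"

    def test_mixed_direction_excluded(self):
        lfc = [0, 1.5, 1.5, 0, 0, 0, 0, 0, 0, -1.5, -1.5]
        args = _evidence_frame(
            0.0, 0.8, flags(h1="up", h2="up", h48="down", h72="down"), lfc, peak_t0=2.0
        )
        assert (
            classify_regulation(*args).loc["g", "label"]
            == "excluded_inconsistent_direction"
        )

    def test_isolated_degs_excluded_as_not_sequential(self):
        lfc = [0, 0, 1.5, 0, 0, 1.5, 0, 0, 0, 0, 0]
        args = _evidence_frame(0.0, 0.8, flags(h2="up", h8="up"), lfc, peak_t0=2.0)
        assert (
            classify_regulation(*args).loc["g", "label"] == "excluded_not_sequential"
        )

    def test_weak_peak_fold_change_excluded(self):
        lfc = [0, 0, 1.1, 1.1, 0, 0, 0, 0, 0, 0, 0]
        args = _evidence_frame(0.0, 0.5, flags(h2="up", h4="up"), lfc, peak_t0=0.6)
        assert classify_regulation(*args).loc["g", "label"] == "excluded_low_peak_fc"

    def test_undefined_cv_fails_stability_criterion(self):
        lfc = [0, 0, 1.5, 1.5, 0, 0, 0, 0, 0, 0, 0]
        args = _evidence_frame(np.nan, 0.8, flags(h2="up", h4="up"), lfc, peak_t0=2.0)
        assert (
            classify_regulation(*args).loc["g", "label"]
            == "excluded_control_variable"
        )

    def test_cv_boundaries_are_strict(self):
        lfc = [0, 0, 1.5, 1.5, 0, 0, 0, 0, 0, 0, 0]
        base = dict(deg_flags=flags(h2="up", h4="up"), lfc_row=lfc, peak_t0=2.0)
        # cv_control 0.29 passes (<0.3), 0.30 fails
        ok = classify_regulation(*_evidence_frame(0.29, 0.8, **base))
        assert ok.loc["g", "label"] == "upregulated"
        edge = classify_regulation(*_evidence_frame(0.30, 0.8, **base))
        assert edge.loc["g", "label"] == "excluded_control_variable"
        # cv_treated must be strictly > 0.3
        flat = classify_regulation(*_evidence_frame(0.0, 0.30, **base))
        assert flat.loc["g", "label"] == "excluded_control_variable"

    def test_labels_partition_all_genes(self, small_sim):
        # synthetic end-to-end: every gene gets exactly one label
        from tnftime.diffexpr import de_analysis
        from tnftime.preprocess import cv_profile, filter_low_expression, tpm
        from tnftime.classify import peak_log2fc_vs_t0

        ds = small_sim.dataset.sex_subset("F")
        de = de_analysis(ds.counts, ds.samples)
        tpm_vals = tpm(ds.counts, ds.genes["length_bp"])
        out = classify_regulation(
            cv_profile(tpm_vals, ds.samples),
            de.deg,
            de.log2fc,
            peak_log2fc_vs_t0(tpm_vals, ds.samples),
            filter_low_expression(tpm_vals, ds.samples),
        )
        assert len(out) == len(ds.counts)
        from tnftime.classify import LABELS

        assert out["label"].isin(LABELS).all()

    def test_gene_order_invariance(self):
        lfc_a = [0, 0, 1.5, 3.0, 3.0, 2.5, 2.0, 2.0, 1.5, 1.5, 1.0]
        cv = pd.DataFrame(
            {"cv_control": [0.0, 0.9], "cv_treated": [0.8, 0.05]}, index=["a", "b"]
        )
        deg = pd.DataFrame(
            [flags(h2="up", h4="up"), flags(h12="down", h24="down")],
            index=["a", "b"],
            columns=TIMES,
        )
        lfc = pd.DataFrame([lfc_a, [0.0] * 11], index=["a", "b"], columns=TIMES)
        peak = pd.Series([3.0, 0.1], index=["a", "b"])
        mask = pd.Series([True, True], index=["a", "b"])
        fwd = classify_regulation(cv, deg, lfc, peak, mask)
        rev = classify_regulation(
            cv.iloc[::-1], deg.iloc[::-1], lfc.iloc[::-1], peak.iloc[::-1],
            mask.iloc[::-1],
        )
        assert fwd.loc["a", "label"] == rev.loc["a", "label"]
        assert fwd.loc["b", "label"] == rev.loc["b", "label"]


class TestMergeSexCalls:
    def _calls(self, f_label, m_label):
        f = pd.DataFrame({"label": [f_label]}, index=["g"])
        m = pd.DataFrame({"label": [m_label]}, index=["g"])
        return {"F": f, "M": m}

    @pytest.mark.parametrize(
        "f,m,expected",
        [
            ("upregulated", "upregulated", "both"),
            ("upregulated", "not_regulated", "female_only"),
            ("not_regulated", "downregulated", "male_only"),
            ("not_regulated", "not_regulated", "neither"),
        ],
    )
    def test_set_algebra(self, f, m, expected):
        out = merge_sex_calls(self._calls(f, m))
        assert out.loc["g", "merged_class"] == expected

    def test_opposite_directions_flag_conflict(self):
        out = merge_sex_calls(self._calls("upregulated", "downregulated"))
        assert bool(out.loc["g", "conflict"])

    def test_universe_mismatch_errors(self):
        f = pd.DataFrame({"label": ["upregulated"]}, index=["g1"])
        m = pd.DataFrame({"label": ["upregulated"]}, index=["g2"])
        with pytest.raises(ValueError, match="universes"):
            merge_sex_calls({"F": f, "M": m})
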