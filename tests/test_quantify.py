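"""Censoring, ΔCt inhibition handling, detection verdicts and copies/L."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ednaqpcr import (
    QuantificationContext,
    censor_cutoff,
    classify_inhibition,
    copies_per_liter,
    delta_ct,
    detect_danish,
    quantify_norwegian,
    summarize_site,
)

LOD = 5.0
LOQ = 10.0


def _ct_for(copies, curve):
    return curve.intercept + curve.slope * math.log10(copies)


# --- Ct cut-off censoring ---------------------------------------------------

def test_censor_keeps_signals_below_cutoff(make_well):
    out = censor_cutoff([make_well(40.7)], cutoff=41.0)
    assert out[0].ct == 40.7


def test_censor_boundary_is_inclusive_and_audited(make_well):
    out = censor_cutoff([make_well(41.0), make_well(44.2)], cutoff=41.0)
    assert all(r.ct is None for r in out)
    assert [r.censored_ct for r in out] == [41.0, 44.2]


def test_censor_leaves_non_detects_unchanged(make_well):
    wells = [make_well(None), make_well(None)]
    assert censor_cutoff(wells, 41.0) == wells


# --- ΔCt --------------------------------------------------------------------

def test_delta_ct_theoretical_tenfold_gap():
    assert delta_ct([33.0, 33.0], [36.32, 36.32]) == pytest.approx(3.32)
    assert delta_ct([33.0], [33.0]) == 0.0


def test_delta_ct_ignores_non_detects_within_a_dilution():
    assert delta_ct([33.0, None], [36.32, None]) == pytest.approx(3.32)


def test_delta_ct_unassessable_when_one_side_all_negative():
    with pytest.raises(ValueError, match="not assessable"):
        delta_ct([33.0], [None, None])


@pytest.mark.parametrize("dct, label", [
    (3.32, "none"),
    (2.82, "none"),   # boundaries inclusive
    (3.82, "none"),
    (2.81, "inhibited"),
    (3.83, "dilution_out_of_range"),
])
def test_classify_inhibition_window(dct, label, norwegian_ctx):
    assert classify_inhibition(dct, norwegian_ctx) == label


_CTX = QuantificationContext(V_e=200.0, V_r=2.0, V_w=5.0, scheme="norwegian")


@given(st.floats(min_value=-10.0, max_value=15.0, allow_nan=False))
def test_classify_inhibition_partitions_the_line(dct):
    label = classify_inhibition(dct, _CTX)
    assert label in ("none", "inhibited", "dilution_out_of_range")
    expected = ("inhibited" if dct < 2.82
                else "dilution_out_of_range" if dct > 3.82 else "none")
    assert label == expected


# --- copies per litre -------------------------------------------------------

def test_copies_per_liter_published_limits(norwegian_ctx):
    assert copies_per_liter(5.0, norwegian_ctx) == pytest.approx(100.0)
    assert copies_per_liter(10.0, norwegian_ctx) == pytest.approx(200.0)
    assert copies_per_liter(0.0, norwegian_ctx) == 0.0
    identity = QuantificationContext(V_e=2.0, V_r=2.0, V_w=1.0)
    assert copies_per_liter(7.3, identity) == pytest.approx(7.3)


@given(st.floats(min_value=0.0, max_value=1e6),
       st.floats(min_value=20.0, max_value=1e4),
       st.floats(min_value=0.5, max_value=10.0),
       st.floats(min_value=0.1, max_value=50.0),
       st.floats(min_value=1.5, max_value=4.0))
def test_copies_per_liter_scaling_laws(cr, ve, vr, vw, k):
    """Linear in C_r and V_e; inverse in V_r and V_w."""
    ctx = QuantificationContext(V_e=ve, V_r=vr, V_w=vw)
    base = copies_per_liter(cr, ctx)
    assert copies_per_liter(k * cr, ctx) == pytest.approx(k * base, rel=1e-9)
    ctx2 = QuantificationContext(V_e=k * ve, V_r=vr, V_w=vw)
    assert copies_per_liter(cr, ctx2) == pytest.approx(k * base, rel=1e-9)
    ctx3 = QuantificationContext(V_e=ve, V_r=vr, V_w=k * vw)
    assert copies_per_liter(cr, ctx3) == pytest.approx(base / k, rel=1e-9)


# --- single-dilution (danish) verdicts --------------------------------------

def test_danish_single_positive_is_not_detected(danish_ctx, published_curve, make_well):
    reps = [make_well(38.0)] + [make_well(None)] * 3
    res = detect_danish(reps, published_curve, LOD, LOQ, danish_ctx)
    assert res.status == "not_detected"
    assert res.positive_replicates == "1/4"
    assert res.render() == "0"


def test_danish_two_positives_below_loq(danish_ctx, published_curve, make_well):
    ct = _ct_for(7.0, published_curve)  # between LOD 5 and LOQ 10
    reps = [make_well(ct), make_well(ct + 0.1), make_well(None), make_well(None)]
    res = detect_danish(reps, published_curve, LOD, LOQ, danish_ctx)
    assert res.status == "detected_below_LOQ"
    assert res.render() == "<LOQ"


def test_danish_full_detection_above_loq_quantifies(danish_ctx, published_curve, make_well):
    ct = _ct_for(50.0, published_curve)
    reps = [make_well(ct)] * 4
    res = detect_danish(reps, published_curve, LOD, LOQ, danish_ctx)
    assert res.status == "quantified"
    assert res.positive_replicates == "4/4"
    # 50 copies/reaction * (200/5) / 1 L = 2000 copies/L, no spread
    assert res.copies_per_L == pytest.approx(2000.0, rel=1e-6)
    assert res.sd_copies_per_L == pytest.approx(0.0, abs=1e-6)


def test_danish_non_detects_enter_mean_as_zero(danish_ctx, published_curve, make_well):
    ct = _ct_for(50.0, published_curve)
    reps = [make_well(ct), make_well(ct), make_well(ct), make_well(None)]
    res = detect_danish(reps, published_curve, LOD, LOQ, danish_ctx)
    assert res.status == "quantified"
    assert res.copies_per_L == pytest.approx(2000.0 * 3 / 4, rel=1e-6)
    assert res.sd_copies_per_L > 0


def test_danish_replicate_count_mismatch(danish_ctx, published_curve, make_well):
    with pytest.raises(ValueError, match="expected 4"):
        detect_danish([make_well(30.0)], published_curve, LOD, LOQ, danish_ctx)


def test_danish_cutoff_censoring_applies(danish_ctx, published_curve, make_well):
    reps = [make_well(41.5), make_well(43.0), make_well(None), make_well(None)]
    res = detect_danish(reps, published_curve, LOD, LOQ, danish_ctx)
    assert res.status == "not_detected"
    assert res.positive_replicates == "0/4"


# --- dilution-pair (norwegian) verdicts -------------------------------------

def _pair(make_well, und_copies, dil_copies, curve, und_shift=0.0):
    """2 undiluted + 2 diluted wells from per-reaction copy loads."""
    wells = []
    for c in und_copies:
        ct = None if c is None else _ct_for(c, curve) + und_shift
        wells.append(make_well(ct, dilution=1))
    for c in dil_copies:
        ct = None if c is None else _ct_for(c, curve)
        wells.append(make_well(ct, dilution=10))
    return wells


def test_norwegian_single_positive_is_not_detected(norwegian_ctx, published_curve, make_well):
    reps = _pair(make_well, (7.0, None), (None, None), published_curve)
    res = quantify_norwegian(reps, published_curve, LOQ, norwegian_ctx)
    assert res.status == "not_detected"
    assert res.positive_replicates == "1/4"
    assert res.render() == "0"


def test_norwegian_full_detection_below_loq(norwegian_ctx, published_curve, make_well):
    reps = _pair(make_well, (8.0, 8.0), (0.8, 0.8), published_curve)
    res = quantify_norwegian(reps, published_curve, LOQ, norwegian_ctx)
    assert res.status == "detected_below_LOQ"
    assert res.positive_replicates == "4/4"
    assert res.render() == "<LOQ"


def test_norwegian_two_positives_below_loq(norwegian_ctx, published_curve, make_well):
    reps = _pair(make_well, (7.0, 7.0), (None, None), published_curve)
    res = quantify_norwegian(reps, published_curve, LOQ, norwegian_ctx)
    assert res.status == "detected_below_LOQ"
    assert res.positive_replicates == "2/4"


def test_norwegian_clean_sample_quantifies_from_all_replicates(
        norwegian_ctx, published_curve, make_well):
    reps = _pair(make_well, (500.0, 500.0), (50.0, 50.0), published_curve)
    res = quantify_norwegian(reps, published_curve, LOQ, norwegian_ctx)
    assert res.status == "quantified"
    assert res.inhibition_flag == "none"
    # all four estimates are 500 copies/reaction on the extract scale
    assert res.copies_per_L == pytest.approx(copies_per_liter(500.0, norwegian_ctx))
    assert res.sd_copies_per_L == pytest.approx(0.0, abs=1e-6)


def test_norwegian_inhibited_sample_uses_diluted_wells_only(
        norwegian_ctx, published_curve, make_well):
    # +2 cycles on undiluted wells: ΔCt = 3.427 - 2 = 1.427 -> inhibited
    reps = _pair(make_well, (500.0, 500.0), (50.0, 50.0), published_curve, und_shift=2.0)
    res = quantify_norwegian(reps, published_curve, LOQ, norwegian_ctx)
    assert res.inhibition_flag == "inhibited"
    assert res.status == "quantified"
    assert res.copies_per_L == pytest.approx(copies_per_liter(500.0, norwegian_ctx))


def test_norwegian_out_of_range_dilution_uses_undiluted_wells_only(
        norwegian_ctx, published_curve, make_well):
    # a failed 100x-ish dilution: ΔCt = 2 * 3.427 > 3.82 -> out of range
    reps = _pair(make_well, (500.0, 500.0), (5.0, 5.0), published_curve)
    res = quantify_norwegian(reps, published_curve, LOQ, norwegian_ctx)
    assert res.inhibition_flag == "dilution_out_of_range"
    assert res.status == "quantified"
    assert res.copies_per_L == pytest.approx(copies_per_liter(500.0, norwegian_ctx))


def test_norwegian_branch_consistency_noiseless(norwegian_ctx, published_curve, make_well):
    """With no inhibition and noiseless Cts, the pooled mean equals both
    single-branch estimates."""
    reps = _pair(make_well, (200.0, 200.0), (20.0, 20.0), published_curve)
    pooled = quantify_norwegian(reps, published_curve, LOQ, norwegian_ctx)
    dil_only = quantify_norwegian(
        _pair(make_well, (200.0, 200.0), (20.0, 20.0), published_curve, und_shift=2.0),
        published_curve, LOQ, norwegian_ctx)
    und_only = quantify_norwegian(
        _pair(make_well, (200.0, 200.0), (2.0, 2.0), published_curve),
        published_curve, LOQ, norwegian_ctx)
    assert pooled.copies_per_L == pytest.approx(dil_only.copies_per_L)
    assert pooled.copies_per_L == pytest.approx(und_only.copies_per_L)


def test_norwegian_missing_dilution_pairing_is_an_error(
        norwegian_ctx, published_curve, make_well):
    with pytest.raises(ValueError, match="undiluted and diluted"):
        quantify_norwegian([make_well(30.0, dilution=1)] * 4,
                           published_curve, LOQ, norwegian_ctx)


# --- site summaries ---------------------------------------------------------

def test_summarize_site_mixed_filters(danish_ctx, published_curve, make_well):
    ct = _ct_for(50.0, published_curve)
    quantified = detect_danish([make_well(ct)] * 4, published_curve,
                               LOD, LOQ, danish_ctx)
    below = detect_danish(
        [make_well(_ct_for(7.0, published_curve))] * 2 + [make_well(None)] * 2,
        published_curve, LOD, LOQ, danish_ctx)
    none = detect_danish([make_well(None)] * 4, published_curve, LOD, LOQ, danish_ctx)
    summary = summarize_site([quantified, below, none], site_id="L1")
    assert summary.n_filters == 3 and summary.n_quantified == 1
    # mean over {2000, 0}; the <LOQ filter is flagged, not imputed
    assert summary.mean_copies_per_L == pytest.approx(1000.0, rel=1e-6)
    assert summary.below_loq_filters == ("S1",)
    assert summary.level_grade == 4


def test_summarize_site_all_not_detected(danish_ctx, published_curve, make_well):
    res = detect_danish([make_well(None)] * 4, published_curve, LOD, LOQ, danish_ctx)
    summary = summarize_site([res, res, res])
    assert summary.mean_copies_per_L == 0.0
    assert summary.level_grade == 0
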