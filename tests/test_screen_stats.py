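"""Density estimation, GC normalization and screen-design formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tillingkit.screen_stats import (
    MISSENSE,
    NONSENSE,
    SILENT,
    DensityUndefinedError,
    PopulationConstants,
    ScreenAssay,
    backcross_load,
    bp_per_mutation,
    class_composition_report,
    density_estimate,
    exon_budget,
    expected_mutations,
    format_density,
    mutations_per_plant,
    normalize_bp_per_mutation,
    p_at_least_one_nonsense,
    round_half_up,
    saturation_fraction,
    summarize_assays,
)


def make_assay(length=1007, gc=47, mutations=21, screened=768, population=6912):
    return ScreenAssay("g", 0.3, length, gc, mutations, screened, population)


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(10105.5) == 10106
    assert round_half_up(50.5) == 51
    assert round_half_up(2.4) == 2


def test_bp_per_mutation_and_rendering():
    bp = bp_per_mutation(make_assay())
    assert bp == pytest.approx(1007 * 768 / 21)
    assert format_density(bp) == "1/37"
    bp2 = bp_per_mutation(make_assay(1072, 45, 149, 4608))
    assert format_density(bp2) == "1/33"


def test_zero_mutations_raises_density_undefined():
    with pytest.raises(DensityUndefinedError):
        bp_per_mutation(make_assay(mutations=0))


def test_normalization_scales_with_gc_ratio():
    bp = 1007 * 768 / 21
    norm = normalize_bp_per_mutation(bp, 47, 35)
    assert norm == pytest.approx(bp * 47 / 35)
    assert format_density(norm) == "1/49"
    assert normalize_bp_per_mutation(1234.0, 40, 40) == pytest.approx(1234.0)
    with pytest.raises(ValueError):
        normalize_bp_per_mutation(1000.0, 0, 35)


def test_per_plant_load_extrapolation():
    assert mutations_per_plant(36827.4) == 13577
    assert mutations_per_plant(49453.0) == 10111
    assert mutations_per_plant(5.0e8) == 1


def test_density_estimate_uses_rounded_raw_load_for_display_norm():
    est = density_estimate(make_assay())
    assert est.mutations_per_plant_raw == 13577
    # 13577 * 35/47 = 10110.53 -> 10111 (the published display convention)
    assert est.mutations_per_plant_norm == 10111


def test_expected_mutations_column_values():
    bp = 1007 * 768 / 21
    assert round_half_up(expected_mutations(6912, 1000, bp)) == 188
    bp_exon = normalize_bp_per_mutation(bp, 47, 41)
    assert round_half_up(expected_mutations(6912, 1000, bp_exon)) == 164
    assert expected_mutations(0, 1000, bp) == 0.0


def test_stop_codon_probability_closed_form_and_binomial_oracle():
    assert p_at_least_one_nonsense(10, 0.5) == pytest.approx(1 - 0.5**10)
    assert p_at_least_one_nonsense(0) == 0.0
    # integer-E case must equal 1 - P(zero successes) of a Binomial oracle
    from scipy.stats import binom

    for e in (1, 5, 68):
        assert p_at_least_one_nonsense(e, 5 / 96) == pytest.approx(
            1 - binom.pmf(0, e, 5 / 96)
        )


def test_saturation_naive_and_collision_corrected():
    loads = [(9693, 6912), (7717, 2304)]
    naive = saturation_fraction(loads)
    assert naive == pytest.approx(84_777_984 / 175_000_000)
    corrected = saturation_fraction(loads, collision_corrected=True)
    assert corrected == pytest.approx(1 - math.exp(-naive))
    assert corrected < naive
    assert saturation_fraction([]) == 0.0


def test_exon_budget_partition():
    exonic, aa, non = exon_budget(10_000)
    assert exonic == pytest.approx(1100.0)
    assert aa == pytest.approx(1100 * 63 / 96)
    assert non == pytest.approx(1100 * 5 / 96)
    assert exon_budget(0) == (0.0, 0.0, 0.0)


def test_backcross_halving():
    assert backcross_load(10_000, 10) == pytest.approx(9.765625)
    assert backcross_load(617, 0) == 617
    assert backcross_load(617, 1) == pytest.approx(308.5)


def test_summarize_single_assay_matches_its_estimate(constants):
    a = make_assay()
    table = summarize_assays([a], constants)
    row = table[~table["is_average"].astype(bool)].iloc[0]
    est = density_estimate(a, constants)
    assert row["load_per_plant"] == est.mutations_per_plant_raw
    avg = table[table["is_average"].astype(bool)].iloc[0]
    assert avg["load_per_plant"] == est.mutations_per_plant_raw


def test_summarize_handles_zero_mutation_rows(constants):
    table = summarize_assays([make_assay(), make_assay(mutations=0)], constants)
    flagged = table[(table["gene"] == "g") & (table["mutations"] == 0)]
    assert flagged["load_per_plant"].isna().all()


def test_class_composition_report_expected_counts():
    rep = class_composition_report({SILENT: 90, MISSENSE: 167, NONSENSE: 5})
    assert rep.total == 262
    assert rep.expected[SILENT] == pytest.approx(262 * 33 / 96)
    assert rep.expected[MISSENSE] == pytest.approx(262 * 58 / 96)
    assert rep.expected[NONSENSE] == pytest.approx(262 * 5 / 96)
    # the spectrum's own counts are their own expectation
    rep2 = class_composition_report({SILENT: 33, MISSENSE: 58, NONSENSE: 5})
    for cls, n in rep2.observed.items():
        assert rep2.expected[cls] == pytest.approx(n)
    with pytest.raises(ValueError):
        class_composition_report({})


@given(
    bp=st.floats(min_value=1e2, max_value=1e7),
    a=st.floats(min_value=1.0, max_value=99.0),
    b=st.floats(min_value=1.0, max_value=99.0),
)
@settings(derandomize=True, max_examples=100)
def test_normalization_inverse_property(bp, a, b):
    there = normalize_bp_per_mutation(bp, a, b)
    back = normalize_bp_per_mutation(there, b, a)
    assert back == pytest.approx(bp, rel=1e-12)


@given(
    length=st.integers(min_value=100, max_value=5000),
    gc=st.integers(min_value=20, max_value=70),
    mutations=st.integers(min_value=1, max_value=500),
    screened=st.integers(min_value=8, max_value=8000),
    k=st.integers(min_value=2, max_value=10),
)
@settings(derandomize=True, max_examples=100)
def test_density_scale_invariance(length, gc, mutations, screened, k):
    """Doubling detections and screened plants together leaves density fixed."""
    a = ScreenAssay("g", 0.3, length, gc, mutations, screened, screened)
    b = ScreenAssay("g", 0.3, length, gc, k * mutations, k * screened, k * screened)
    assert bp_per_mutation(a) == pytest.approx(bp_per_mutation(b))


@given(
    e1=st.floats(min_value=0, max_value=200),
    e2=st.floats(min_value=0, max_value=200),
    f=st.floats(min_value=1e-6, max_value=0.5),
)
@settings(derandomize=True, max_examples=100)
def test_stop_probability_monotone_in_expected_mutations(e1, e2, f):
    lo, hi = sorted((e1, e2))
    assert p_at_least_one_nonsense(lo, f) <= p_at_least_one_nonsense(hi, f)


@given(
    loads=st.lists(
        st.tuples(
            st.floats(min_value=1, max_value=2e4),
            st.integers(min_value=1, max_value=10_000),
        ),
        min_size=1,
        max_size=5,
    )
)
@settings(derandomize=True, max_examples=100)
def test_saturation_naive_dominates_collision_corrected(loads):
    naive = saturation_fraction(loads)
    corrected = saturation_fraction(loads, collision_corrected=True)
    assert corrected <= naive
    assert corrected == pytest.approx(1 - np.exp(-naive))


def test_invalid_assays_rejected():
    with pytest.raises(ValueError):
        ScreenAssay("g", 0.3, 1000, 0, 10, 100, 100)  # gc out of range
    with pytest.raises(ValueError):
        ScreenAssay("g", 0.3, 1000, 47, 10, 200, 100)  # screened > population
    with pytest.raises(ValueError):
        PopulationConstants(exon_fraction=1.5)
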