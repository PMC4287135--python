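"""Fold-index profiles, CH/CDF distances, quadrants, per-domain means."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import cdf_distance_oracle
from disevo.disorder import (
    CdfBoundary,
    calibrate_cdf_boundary,
    cdf_distance,
    ch_point,
    classify_quadrant,
    disorder_profile,
    domain_mean_disorder,
    group_domain_disorder,
    DisorderProfile,
)
from disevo.errors import ParameterError, ValidationError
from disevo.records import AA20, DomainAnnotation, ProteinRecord


def test_poly_glutamate_is_disordered():
    rec = ProteinRecord("polyE", "E" * 101)
    prof = disorder_profile(rec, window=51)
    assert np.all(prof.scores > 0.5)


def test_poly_isoleucine_is_ordered():
    rec = ProteinRecord("polyI", "I" * 101)
    prof = disorder_profile(rec, window=51)
    assert np.all(prof.scores < 0.5)


def test_single_glycine_matches_direct_formula():
    # window 1: F = 2.785 * ((-0.4 + 4.5)/9) - 0 - 1.151; score = 0.5 - F
    h = (-0.4 + 4.5) / 9.0
    expected = min(1.0, max(0.0, 0.5 - (2.785 * h - 1.151)))
    prof = disorder_profile(ProteinRecord("g", "G"), window=1)
    assert prof.scores[0] == pytest.approx(expected, abs=1e-12)


def test_even_window_rejected():
    with pytest.raises(ParameterError):
        disorder_profile(ProteinRecord("p", "MKV"), window=4)


def test_profile_invariants_on_random_sequences(rng, random_protein_factory):
    for k in range(5):
        rec = random_protein_factory(rng, 200, rec_id=f"p{k}")
        prof = disorder_profile(rec)
        assert len(prof) == len(rec)
        assert np.all((prof.scores >= 0) & (prof.scores <= 1))


def test_ch_point_poly_lysine():
    r, h, dch = ch_point(ProteinRecord("k", "KKKK"))
    assert r == pytest.approx(1.0)
    assert h == pytest.approx((-3.9 + 4.5) / 9.0)
    assert dch == pytest.approx(1.0 - (2.785 * h - 1.151))
    assert dch > 0


def test_ch_point_poly_isoleucine():
    r, h, dch = ch_point(ProteinRecord("i", "IIII"))
    assert (r, h) == (0.0, 1.0)
    assert dch == pytest.approx(-1.634)


def test_balanced_charge_gives_zero_net():
    r, _, _ = ch_point(ProteinRecord("z", "KRDEKRDEMMM"))
    assert r == 0.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text(alphabet=AA20 + "X", min_size=2, max_size=60), st.randoms())
def test_dch_is_permutation_invariant(seq, pyrandom):
    shuffled = list(seq)
    pyrandom.shuffle(shuffled)
    a = ch_point(ProteinRecord("a", seq))
    b = ch_point(ProteinRecord("b", "".join(shuffled)))
    assert a == pytest.approx(b)


def _flat_boundary(value=0.5):
    return CdfBoundary(values=(value,) * 7)


def test_cdf_distance_all_ordered_scores():
    prof = DisorderProfile("p", np.zeros(10), window=1)
    assert cdf_distance(prof, _flat_boundary(0.5)) > 0


def test_cdf_distance_all_disordered_scores():
    prof = DisorderProfile("p", np.ones(10), window=1)
    assert cdf_distance(prof, _flat_boundary(0.5)) < 0


def test_cdf_distance_matches_step_function_oracle():
    scores = [0.2, 0.4, 0.6, 0.8]
    prof = DisorderProfile("p", np.array(scores), window=1)
    boundary = _flat_boundary(0.5)
    expected = cdf_distance_oracle(scores, boundary.thresholds, boundary.values)
    assert cdf_distance(prof, boundary) == pytest.approx(expected)
    # and the hand value: CDF at 0.1..0.7 = (0,1,1,2,2,3,3)/4
    assert expected == pytest.approx(sum([0, 1, 1, 2, 2, 3, 3]) / 4 / 7 - 0.5)


def test_cdf_boundary_needs_seven_points():
    with pytest.raises(ParameterError):
        CdfBoundary(thresholds=(0.1, 0.2), values=(0.5, 0.5))


def test_calibration_symmetric_classes_gives_mean_zero_distance():
    profs = [
        DisorderProfile(f"p{i}", np.linspace(0, 1, 20), window=1) for i in range(3)
    ]
    boundary = calibrate_cdf_boundary(profs, profs)
    dists = [cdf_distance(p, boundary) for p in profs]
    assert np.mean(dists) == pytest.approx(0.0, abs=1e-12)


def test_calibration_single_profile_per_class_is_midpoint():
    a = DisorderProfile("a", np.full(10, 0.05), window=1)
    b = DisorderProfile("b", np.full(10, 0.95), window=1)
    boundary = calibrate_cdf_boundary([a], [b])
    # a's CDF is 1 at every threshold, b's is 0 -> midpoint 0.5 everywhere
    assert np.allclose(boundary.values, 0.5)


def test_calibration_rejects_empty_class():
    a = DisorderProfile("a", np.full(10, 0.1), window=1)
    with pytest.raises(ParameterError):
        calibrate_cdf_boundary([], [a])


@pytest.mark.parametrize(
    "dch,dcdf,expected",
    [
        (0.0, 0.0, "Q1"),
        (0.5, 0.5, "Q1"),
        (-0.2, 0.3, "Q2"),
        (-0.2, 0.0, "Q2"),
        (-0.1, -0.1, "Q3"),
        (0.1, -0.4, "Q4"),
        (0.0, -0.4, "Q4"),
    ],
)
def test_quadrant_sign_rule(dch, dcdf, expected):
    assert classify_quadrant(dch, dcdf) == expected


def test_quadrant_rule_exhaustive_over_sign_combinations():
    for dch, dcdf in itertools.product([-1.0, -0.3, 0.0, 0.3, 1.0], repeat=2):
        q = classify_quadrant(dch, dcdf)
        assert (q == "Q1") == (dch >= 0 and dcdf >= 0)
        assert (q == "Q2") == (dch < 0 and dcdf >= 0)
        assert (q == "Q3") == (dch < 0 and dcdf < 0)
        assert (q == "Q4") == (dch >= 0 and dcdf < 0)


def test_domain_mean_disorder_basic():
    prof = DisorderProfile("p", np.array([0.0, 1.0]), window=1)
    whole = DomainAnnotation("p", "all", 1, 2)
    assert domain_mean_disorder(prof, whole) == pytest.approx(0.5)
    single = DomainAnnotation("p", "one", 2, 2)
    assert domain_mean_disorder(prof, single) == pytest.approx(1.0)


def test_domain_mean_disorder_constant_region():
    prof = DisorderProfile("p", np.full(30, 0.7), window=1)
    assert domain_mean_disorder(prof, DomainAnnotation("p", "d", 5, 20)) == pytest.approx(0.7)


def test_domain_mean_disorder_out_of_bounds():
    prof = DisorderProfile("p", np.full(10, 0.7), window=1)
    with pytest.raises(ValidationError):
        domain_mean_disorder(prof, DomainAnnotation("p", "d", 5, 20))


def _group_fixture():
    r1 = ProteinRecord("p1", "M" * 10, species="s1", group="g1")
    r2 = ProteinRecord("p2", "M" * 10, species="s2", group="g2")
    profiles = {
        "p1": DisorderProfile("p1", np.full(10, 0.2), window=1),
        "p2": DisorderProfile("p2", np.full(10, 0.9), window=1),
    }
    regions = {
        "p1": [DomainAnnotation("p1", "D", 1, 5)],
        "p2": [DomainAnnotation("p2", "D", 1, 5), DomainAnnotation("p2", "E", 6, 10)],
    }
    return [r1, r2], profiles, regions


def test_group_table_one_protein_per_group():
    records, profiles, regions = _group_fixture()
    table = group_domain_disorder(records, profiles, regions)
    d_g1 = table[(table.group == "g1") & (table.domain == "D")].iloc[0]
    assert d_g1.mean_disorder == pytest.approx(0.2)
    assert d_g1.n == 1


def test_group_table_missing_domain_is_flagged_not_zero():
    records, profiles, regions = _group_fixture()
    table = group_domain_disorder(records, profiles, regions)
    e_g1 = table[(table.group == "g1") & (table.domain == "E")].iloc[0]
    assert np.isnan(e_g1.mean_disorder)
    assert e_g1.n == 0
    e_g2 = table[(table.group == "g2") & (table.domain == "E")].iloc[0]
    assert e_g2.mean_disorder == pytest.approx(0.9)
    assert e_g2.n == 1


def test_group_table_invariant_to_protein_order():
    records, profiles, regions = _group_fixture()
    t1 = group_domain_disorder(records, profiles, regions)
    t2 = group_domain_disorder(records[::-1], profiles, regions)
    merged = t1.merge(t2, on=["group", "domain"], suffixes=("_a", "_b"))
    assert np.allclose(
        merged.mean_disorder_a, merged.mean_disorder_b, equal_nan=True
    )
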