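"""Domain projection and the group-vs-group substitution-rate statistic."""

import numpy as np
import pytest

from oracles import any_match_rate_oracle, pairwise_rate_oracle
from disevo.domain_evolution import (
    RegionProjection,
    project_domains,
    rate_profile,
    substitution_rate,
    whole_alignment_region,
)
from disevo.errors import ValidationError
from disevo.phylo import AlignedFamily
from disevo.records import DomainAnnotation


def test_projection_identity_on_gapless_alignment():
    fam = AlignedFamily(("r", "s"), ("MKVLI", "MKVLM"))
    dom = DomainAnnotation("r", "D", 2, 4)
    (proj,) = project_domains(fam, "r", [dom])
    assert (proj.col_start, proj.col_end) == (1, 4)  # same interval, 0-based


def test_projection_shifts_past_reference_gaps():
    fam = AlignedFamily(("r", "s"), ("A-CD", "AXCD"))
    dom = DomainAnnotation("r", "D", 2, 3)  # residues "CD"
    (proj,) = project_domains(fam, "r", [dom])
    assert (proj.col_start, proj.col_end) == (2, 4)  # 1-based columns 3-4


def test_projection_round_trips_to_reference_substring(rng):
    letters = list("ACDEF")
    for _ in range(10):
        seq = "".join(rng.choice(letters, size=20))
        # random gapping of the reference row
        row = "".join(
            c + ("-" * int(rng.integers(0, 3))) for c in seq
        )
        other = "".join(rng.choice(letters + ["-"], size=len(row)))
        other = other if other.replace("-", "") else "A" * len(row)
        fam = AlignedFamily(("r", "s"), (row, other))
        start = int(rng.integers(1, 15))
        end = int(rng.integers(start, 20))
        dom = DomainAnnotation("r", "D", start, end)
        (proj,) = project_domains(fam, "r", [dom])
        window = fam.row("r")[proj.col_start : proj.col_end]
        assert window.replace("-", "") == seq[start - 1 : end]


def test_projection_missing_reference_errors():
    fam = AlignedFamily(("a",), ("MK",))
    with pytest.raises(ValidationError):
        project_domains(fam, "zz", [DomainAnnotation("zz", "D", 1, 2)])


def test_projection_out_of_bounds_domain_errors():
    fam = AlignedFamily(("a",), ("MK",))
    with pytest.raises(ValidationError):
        project_domains(fam, "a", [DomainAnnotation("a", "D", 1, 5)])


def _fam(rows1, rows2):
    ids1 = tuple(f"a{i}" for i in range(len(rows1)))
    ids2 = tuple(f"b{i}" for i in range(len(rows2)))
    fam = AlignedFamily(ids1 + ids2, tuple(rows1) + tuple(rows2))
    return fam, list(ids1), list(ids2)


def test_worked_example_rate_is_one_third():
    fam, g1, g2 = _fam(["ACD", "ACE"], ["ACD", "GCD"])
    res = substitution_rate(fam, whole_alignment_region(fam), g1, g2)
    assert res.per_site_counts == (2, 0, 2)
    assert res.rate == pytest.approx(1 / 3)


def test_identical_group_content_gives_zero_rate():
    fam, g1, g2 = _fam(["MKV", "MKV"], ["MKV", "MKV"])
    res = substitution_rate(fam, whole_alignment_region(fam), g1, g2)
    assert res.rate == 0.0


def test_disjoint_alphabets_give_rate_one():
    fam, g1, g2 = _fam(["AAAA", "AAAA"], ["GGGG", "GGGG"])
    res = substitution_rate(fam, whole_alignment_region(fam), g1, g2)
    assert res.rate == 1.0


def test_rate_is_symmetric_in_groups(rng):
    rows = ["".join(rng.choice(list("ACD-X"), size=12)) for _ in range(6)]
    fam, g1, g2 = _fam(rows[:3], rows[3:])
    region = whole_alignment_region(fam)
    r12 = substitution_rate(fam, region, g1, g2)
    r21 = substitution_rate(fam, region, g2, g1)
    assert r12.rate == pytest.approx(r21.rate)


def test_overlapping_groups_rejected():
    fam, g1, g2 = _fam(["MKV"], ["MKL"])
    with pytest.raises(ValidationError):
        substitution_rate(fam, whole_alignment_region(fam), g1, g1)


@pytest.mark.parametrize("gap_policy", ["mismatch", "exclude"])
def test_pairwise_rate_equals_double_loop_oracle(gap_policy, rng):
    letters = list("ACDEG-X")
    for _ in range(25):
        m, n = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        width = int(rng.integers(3, 20))
        rows1 = ["".join(rng.choice(letters, size=width)) for _ in range(m)]
        rows2 = ["".join(rng.choice(letters, size=width)) for _ in range(n)]
        fam, g1, g2 = _fam(rows1, rows2)
        res = substitution_rate(
            fam, whole_alignment_region(fam), g1, g2, gap_policy=gap_policy
        )
        s_oracle, rate_oracle = pairwise_rate_oracle(rows1, rows2, gap_policy)
        assert list(res.per_site_counts) == s_oracle
        assert res.rate == pytest.approx(rate_oracle)
        assert 0.0 <= res.rate <= 1.0


@pytest.mark.parametrize("gap_policy", ["mismatch", "exclude"])
def test_any_match_rate_equals_literal_oracle(gap_policy, rng):
    letters = list("ACDEG-X")
    for _ in range(25):
        m, n = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        width = int(rng.integers(3, 15))
        rows1 = ["".join(rng.choice(letters, size=width)) for _ in range(m)]
        rows2 = ["".join(rng.choice(letters, size=width)) for _ in range(n)]
        fam, g1, g2 = _fam(rows1, rows2)
        res = substitution_rate(
            fam, whole_alignment_region(fam), g1, g2,
            mode="any-match", gap_policy=gap_policy,
        )
        s_oracle, rate_oracle = any_match_rate_oracle(rows1, rows2, gap_policy)
        assert list(res.per_site_counts) == s_oracle
        assert res.rate == pytest.approx(rate_oracle)


def test_x_counts_as_mismatch_even_against_x():
    fam, g1, g2 = _fam(["X"], ["X"])
    res = substitution_rate(fam, whole_alignment_region(fam), g1, g2)
    assert res.rate == 1.0


def test_gap_gap_matches_under_mismatch_policy():
    fam, g1, g2 = _fam(["A-"], ["A-"])
    res = substitution_rate(fam, whole_alignment_region(fam), g1, g2)
    assert res.rate == 0.0


def test_rate_profile_single_cell_matches_direct_call():
    fam, g1, g2 = _fam(["ACD", "ACE"], ["ACD", "GCD"])
    groups = {rid: ("G1" if rid.startswith("a") else "G2") for rid in fam.ids}
    table = rate_profile(
        fam, [whole_alignment_region(fam)], groups, [("G1", "G2")]
    )
    assert len(table) == 1
    assert table.iloc[0].rate == pytest.approx(1 / 3)
    assert (table.iloc[0].M, table.iloc[0].N, table.iloc[0].L) == (2, 2, 3)


def test_rate_profile_missing_group_is_flagged():
    fam, g1, g2 = _fam(["ACD"], ["ACE"])
    groups = {rid: "G1" for rid in fam.ids}
    table = rate_profile(
        fam, [whole_alignment_region(fam)], groups, [("G1", "G2")]
    )
    assert bool(table.iloc[0].missing)
    assert np.isnan(table.iloc[0].rate)


def test_rate_profile_invariant_to_row_order_within_groups():
    fam1, g1, g2 = _fam(["ACD", "AFD"], ["GCE", "GKE"])
    fam2 = AlignedFamily(
        (fam1.ids[1], fam1.ids[0], fam1.ids[3], fam1.ids[2]),
        (fam1.rows[1], fam1.rows[0], fam1.rows[3], fam1.rows[2]),
    )
    groups = {rid: ("G1" if rid.startswith("a") else "G2") for rid in fam1.ids}
    t1 = rate_profile(fam1, [whole_alignment_region(fam1)], groups, [("G1", "G2")])
    t2 = rate_profile(fam2, [whole_alignment_region(fam2)], groups, [("G1", "G2")])
    assert t1.iloc[0].rate == pytest.approx(t2.iloc[0].rate)
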