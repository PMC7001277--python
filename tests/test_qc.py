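"""Heterozygote recoding, filtering boundaries, deduplication and PIC."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wheatdiv import (MISSING, DartMatrix, deduplicate_profiles, filter_maf,
                      filter_missing, minor_allele_frequency, pic,
                      pic_from_freq, pic_summary, recode_heterozygous,
                      run_standard_filter)
from wheatdiv.qc import duplicate_groups
from wheatdiv.simulate import SimulationConfig, simulate_structured_genotypes

from conftest import make_snp, two_pop_config

M = MISSING


# ---------------------------------------------------------------------------
# recoding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("column,expected,action", [
    ([0, 2, 0, 2], [0, 1, 0, 1], "to_alt"),        # only 0 and 2 observed
    ([1, 2, 2, 1], [1, 0, 0, 1], "to_ref"),        # only 1 and 2 observed
    ([0, 1, 2, 0], [0, 1, M, 0], "to_missing"),    # all three observed
    ([2, 2, M], [M, M, M], "to_missing"),          # degenerate all-het column
    ([0, 1, 0, M], [0, 1, 0, M], "none"),          # nothing to repair
])
def test_recode_rules(column, expected, action):
    matrix = make_snp([column])
    out, report = recode_heterozygous(matrix)
    assert out.calls[:, 0].tolist() == expected
    assert report.recode_actions["M1"] == action


def test_recode_rejects_dart():
    d = DartMatrix(["a1", "a2"], ["m1"], np.array([[0], [1]]))
    with pytest.raises(TypeError):
        recode_heterozygous(d)


@given(st.integers(3, 6).flatmap(lambda n: st.lists(
    st.lists(st.sampled_from([0, 1, 2, M]), min_size=n, max_size=n),
    min_size=1, max_size=6)))
def test_recode_removes_all_hets_and_is_idempotent(columns):
    matrix = make_snp(columns)
    once, _ = recode_heterozygous(matrix)
    assert not (once.calls == 2).any()
    twice, rep = recode_heterozygous(once)
    assert twice.equals(once)
    assert all(a == "none" for a in rep.recode_actions.values())


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def test_dedup_keeps_least_missing():
    # B matches A wherever both scored but carries one missing cell
    matrix = make_snp([[0, 1, 0, 0], [0, 1, 0, M]])
    out, report = deduplicate_profiles(matrix)
    assert out.marker_ids == ["M1"]
    assert report.removed_by("deduplicate") == ["M2"]


def test_dedup_identity_when_all_distinct():
    matrix = make_snp([[0, 1, 0], [1, 1, 0], [0, 0, 1]])
    out, report = deduplicate_profiles(matrix)
    assert out.equals(matrix)
    assert report.removed_by("deduplicate") == []


def test_dedup_three_way_group_bruteforce():
    """Three mutually compatible columns, missing counts (2,1,0): only the
    complete one survives — confirmed by brute force over keep choices."""
    cols = [[0, 1, M, M, 1], [0, 1, 0, M, 1], [0, 1, 0, 1, 1]]
    matrix = make_snp(cols)
    out, _ = deduplicate_profiles(matrix)
    assert out.marker_ids == ["M3"]
    # brute-force: among all single-survivor choices the kept one minimizes
    # the missing count
    miss = [sum(1 for v in c if v == M) for c in cols]
    assert miss[2] == min(miss)


def test_dedup_rejects_unrecoded_matrix():
    with pytest.raises(ValueError, match="recoded"):
        deduplicate_profiles(make_snp([[0, 2, 1]]))


def _compatible(a, b):
    shared = [(x, y) for x, y in zip(a, b) if x != M and y != M]
    return bool(shared) and all(x == y for x, y in shared)


@given(st.lists(st.lists(st.sampled_from([0, 1, M]), min_size=4, max_size=4),
                min_size=1, max_size=7))
def test_dedup_no_surviving_pair_compatible_with_kept_seed(columns):
    """Survivors are exactly the greedy group seeds' best members: no survivor
    is compatible with an earlier survivor's seed (O(L^2) re-check)."""
    matrix = make_snp(columns)
    groups = duplicate_groups(matrix)
    seeds = [g[0] for g in groups]
    # every non-seed member is compatible with its seed; seeds are pairwise
    # built by first-fit, so a later seed is incompatible with all earlier ones
    for g in groups:
        for j in g[1:]:
            assert _compatible(columns[g[0]], columns[j])
    for a, b in itertools.combinations(seeds, 2):
        assert not _compatible(columns[a], columns[b])


# ---------------------------------------------------------------------------
# missing / MAF boundaries
# ---------------------------------------------------------------------------

def test_missing_filter_boundaries():
    """More than 10% missing removed; exactly 10% kept (strict inequality)."""
    col_15 = [M] * 3 + [0] * 17   # 15% missing
    col_10 = [M] * 2 + [1] * 18   # exactly 10%
    col_0 = [0, 1] * 10
    matrix = make_snp([col_15, col_10, col_0])
    out, report = filter_missing(matrix)
    assert out.marker_ids == ["M2", "M3"]
    assert report.removed_by("missing_filter") == ["M1"]


def test_missing_filter_identity_without_missing():
    matrix = make_snp([[0, 1, 0], [1, 1, 0]])
    out, _ = filter_missing(matrix)
    assert out.equals(matrix)


@pytest.mark.parametrize("column,expected", [
    ([0, 0, 0, 1], 0.25),
    ([1, 1, 1, 1], 0.0),
    ([0, 1, M, 1], 1 / 3),  # pairwise deletion: p = 2/3, MAF = 1/3
])
def test_minor_allele_frequency(column, expected):
    assert minor_allele_frequency(np.array(column)) == pytest.approx(expected)


def test_maf_all_missing_is_undefined_and_removed():
    assert np.isnan(minor_allele_frequency(np.array([M, M])))
    matrix = make_snp([[M, M, M], [0, 1, 1]])
    out, _ = filter_maf(matrix)
    assert out.marker_ids == ["M2"]


def test_maf_filter_boundaries():
    """MAF < 0.05 removed; exactly 0.05 kept (strict inequality)."""
    col_004 = [1] * 4 + [0] * 96   # MAF 0.04
    col_005 = [1] * 5 + [0] * 95   # MAF 0.05
    col_050 = [0, 1] * 50
    matrix = make_snp([col_004, col_005, col_050])
    out, report = filter_maf(matrix)
    assert out.marker_ids == ["M2", "M3"]
    assert report.removed_by("maf_filter") == ["M1"]


# ---------------------------------------------------------------------------
# full filter pipeline
# ---------------------------------------------------------------------------

def test_standard_filter_is_idempotent():
    cfg = two_pop_config(seed=5, n_markers=300, missing_rate=0.05,
                         het_artifact_rate=0.1, duplicate_fraction=0.1)
    matrix, _, _, _ = simulate_structured_genotypes(cfg)
    once, _ = run_standard_filter(matrix)
    twice, rep = run_standard_filter(once)
    assert twice.equals(once)
    assert all(s.n_before == s.n_after for s in rep.steps)


def test_standard_filter_counts_weakly_decreasing():
    cfg = two_pop_config(seed=6, n_markers=300, missing_rate=0.08,
                         het_artifact_rate=0.1, duplicate_fraction=0.1)
    matrix, _, _, _ = simulate_structured_genotypes(cfg)
    out, report = run_standard_filter(matrix)
    counts = [report.steps[0].n_before] + [s.n_after for s in report.steps]
    assert counts == sorted(counts, reverse=True)
    assert out.n_markers == counts[-1]
    removed_sets = [set(s.removed_ids) for s in report.steps]
    for a, b in itertools.combinations(removed_sets, 2):
        assert not (a & b)


def test_skip_dedup_keeps_duplicates():
    matrix = make_snp([[0, 1] * 5, [0, 1] * 4 + [0, M], [1, 0] * 5])
    out, _ = run_standard_filter(matrix, skip_dedup=True, min_maf=0.0)
    assert "M2" in out.marker_ids
    out2, _ = run_standard_filter(matrix, min_maf=0.0)
    assert "M2" not in out2.marker_ids


def test_surviving_markers_meet_all_thresholds(two_pop_fixture):
    matrix = two_pop_fixture[0]
    out, _ = run_standard_filter(matrix)
    frac = out.missing_per_marker() / out.n_accessions
    assert (frac <= 0.10).all()
    mafs = np.array([minor_allele_frequency(out.calls[:, j])
                     for j in range(out.n_markers)])
    assert (mafs >= 0.05).all()


# ---------------------------------------------------------------------------
# PIC
# ---------------------------------------------------------------------------

def test_pic_closed_forms():
    assert pic_from_freq(0.5) == pytest.approx(0.375)
    assert pic_from_freq(1.0) == 0.0
    assert pic_from_freq(0.0) == 0.0
    # direct evaluation of the Botstein expression at p = 0.2
    assert pic_from_freq(0.2) == pytest.approx(1 - 0.68 - 0.0512)


@given(st.floats(0.0, 1.0))
def test_pic_symmetric_and_bounded(p):
    assert pic_from_freq(p) == pytest.approx(pic_from_freq(1 - p), abs=1e-12)
    assert -1e-12 <= pic_from_freq(p) <= 0.375 + 1e-12


def test_pic_from_column_with_missing():
    col = np.array([0, 1, M, 1])  # p = 2/3
    assert pic(col) == pytest.approx(pic_from_freq(2 / 3))
    with pytest.raises(ValueError):
        pic(np.array([0, 2, 1]))


def test_pic_summary_fraction_and_analytic_values():
    matrix = make_snp([[0, 1] * 10, [1] * 19 + [0]])  # PIC 0.375 and ~0.0864
    s = pic_summary(matrix)
    assert s.fraction_gt_0_2 == pytest.approx(0.5)
    assert s.per_marker["M1"] == pytest.approx(0.375)
    assert s.per_marker["M2"] == pytest.approx(pic_from_freq(0.05))
    assert s.mean == pytest.approx((0.375 + pic_from_freq(0.05)) / 2)
    matrix_mono = make_snp([[1, 1, 1], [0, 0, 0]])
    assert pic_summary(matrix_mono).mean == 0.0
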