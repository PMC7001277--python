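"""Fixed-region caller vs brute-force oracle, plus windowing/annotation."""

import numpy as np
import pytest

from wheatdiv import (RegionCall, SimulationConfig, annotate_regions,
                      build_hs_track, call_fixed_regions, run_standard_filter,
                      simulate_structured_genotypes, windowed_hs)
from wheatdiv.scan import HS_ZERO_TOL, HsTrack


def make_track(positions, hs_ref, hs_land, chrom="1A"):
    n = len(positions)
    return HsTrack([f"m{i}" for i in range(n)], np.array([chrom] * n, dtype=object),
                   np.array(positions), np.array(hs_ref, float),
                   np.array(hs_land, float))


def brute_force_regions(track, min_run=5, min_diverse=5, hs_thr=0.1,
                        min_span=5_000_000):
    """Independent oracle: enumerate every contiguous marker interval, keep
    those whose markers are all reference-zero, reduce to maximal ones, then
    apply the three published conditions."""
    out = []
    for chrom in dict.fromkeys(track.chromosomes.tolist()):
        idx = [i for i, c in enumerate(track.chromosomes) if c == chrom]
        zero = [abs(track.hs_reference[i]) <= HS_ZERO_TOL for i in idx]
        n = len(idx)
        for s in range(n):
            for e in range(s, n):
                if not all(zero[s:e + 1]):
                    continue
                # maximality: cannot extend either way
                if s > 0 and zero[s - 1]:
                    continue
                if e < n - 1 and zero[e + 1]:
                    continue
                run_len = e - s + 1
                diverse = sum(track.hs_landrace[idx[i]] > hs_thr
                              for i in range(s, e + 1))
                span = int(track.positions[idx[e]] - track.positions[idx[s]])
                if run_len >= min_run and diverse >= min_diverse and span > min_span:
                    out.append((chrom, int(track.positions[idx[s]]),
                                int(track.positions[idx[e]]), run_len, diverse))
    return out


def as_tuples(regions):
    return [(r.chromosome, r.start_bp, r.end_bp, r.n_ref_zero,
             r.n_landrace_diverse) for r in regions]


# ---------------------------------------------------------------------------
# toy cases
# ---------------------------------------------------------------------------

def test_toy_track_called_with_counts():
    """Six consecutive reference-zero markers over 6.2 Mb, five of them
    landrace-diverse -> one region (n_ref_zero=6, n_landrace_diverse=5)."""
    positions = [1_000_000, 2_100_000, 3_500_000, 4_800_000, 6_000_000, 7_200_000]
    hs_land = [0.3, 0.3, 0.05, 0.3, 0.3, 0.3]
    track = make_track(positions, [0.0] * 6, hs_land)
    regions = call_fixed_regions(track)
    assert as_tuples(regions) == [("1A", 1_000_000, 7_200_000, 6, 5)]
    assert regions == [RegionCall(*as_tuples(regions)[0])] or regions[0].span_bp == 6_200_000
    assert as_tuples(regions) == brute_force_regions(track)


def test_run_of_four_not_called():
    track = make_track([1, 2_000_000, 4_000_000, 9_000_000],
                       [0.0] * 4, [0.3] * 4)
    assert call_fixed_regions(track) == []


def test_span_below_threshold_not_called():
    positions = [1, 1_000_000, 2_000_000, 3_000_000, 4_000_000, 4_900_001]
    track = make_track(positions, [0.0] * 6, [0.3] * 6)
    assert call_fixed_regions(track) == []          # 4.9 Mb, needs > 5 Mb
    positions[-1] = 5_000_002                        # span exactly 5 Mb + 1
    track = make_track(positions, [0.0] * 6, [0.3] * 6)
    assert len(call_fixed_regions(track)) == 1


def test_interrupting_marker_splits_runs():
    """A single non-zero marker breaks the run (no merging by default)."""
    positions = list(range(1, 12_000_002, 1_000_000))  # 13 markers, 1 Mb apart
    hs_ref = [0.0] * 6 + [0.2] + [0.0] * 6
    track = make_track(positions, hs_ref, [0.3] * 13)
    assert call_fixed_regions(track) == []  # each half spans 5 Mb, not > 5 Mb
    merged = call_fixed_regions(track, max_interrupt=1)
    assert len(merged) == 1 and merged[0].n_ref_zero == 12


def test_unsorted_track_rejected():
    track = make_track([5_000_000, 1_000_000], [0.0, 0.0], [0.3, 0.3])
    with pytest.raises(ValueError, match="sorted"):
        call_fixed_regions(track)
    assert track.sorted().is_sorted()


# ---------------------------------------------------------------------------
# oracle equivalence on random tracks
# ---------------------------------------------------------------------------

def test_caller_equals_bruteforce_oracle_on_random_tracks():
    """200 random 60-marker tracks across two chromosomes: the caller agrees
    with interval enumeration exactly."""
    rng = np.random.default_rng(123)
    for _ in range(200):
        n = 60
        chroms = np.sort(rng.choice(["1A", "2A"], n)).astype(object)
        positions = np.empty(n, dtype=np.int64)
        for c in ("1A", "2A"):
            k = int((chroms == c).sum())
            positions[chroms == c] = np.sort(rng.integers(1, 60_000_000, k))
        hs_ref = np.where(rng.random(n) < 0.55, 0.0, rng.uniform(0.01, 0.5, n))
        hs_land = rng.uniform(0.0, 0.5, n)
        track = HsTrack([f"m{i}" for i in range(n)], chroms, positions,
                        hs_ref, hs_land).sorted()
        got = as_tuples(call_fixed_regions(track, min_run=3, min_diverse=2,
                                           min_span_bp=2_000_000))
        want = brute_force_regions(track, min_run=3, min_diverse=2,
                                   min_span=2_000_000)
        assert got == want


def test_raising_min_span_never_adds_regions():
    rng = np.random.default_rng(7)
    n = 60
    positions = np.sort(rng.integers(1, 50_000_000, n))
    hs_ref = np.where(rng.random(n) < 0.6, 0.0, 0.3)
    track = make_track(positions.tolist(), hs_ref.tolist(),
                       rng.uniform(0.15, 0.5, n).tolist())
    prev = as_tuples(call_fixed_regions(track, min_run=3, min_diverse=2,
                                        min_span_bp=0))
    for span in (1_000_000, 5_000_000, 20_000_000):
        cur = as_tuples(call_fixed_regions(track, min_run=3, min_diverse=2,
                                           min_span_bp=span))
        assert set(cur) <= set(prev)
        prev = cur


# ---------------------------------------------------------------------------
# end-to-end recovery of injected regions
# ---------------------------------------------------------------------------

def scan_config(seed, region_spec):
    return SimulationConfig(
        n_populations=2, n_per_population=(30, 30), n_markers=300,
        reference_set_size=20, fst_target=0.2, missing_rate=0.02,
        het_artifact_rate=0.0, duplicate_fraction=0.0,
        n_chromosomes=2, chromosome_length_bp=80_000_000,
        fixed_region_spec=region_spec, seed=seed)


def run_scan(cfg):
    matrix, placements, frame, truth = simulate_structured_genotypes(cfg)
    scan_matrix, _ = run_standard_filter(matrix, skip_dedup=True)
    located = [m for m in scan_matrix.marker_ids if placements.get(m).located]
    track = build_hs_track(scan_matrix.subset_markers(located), placements, frame)
    return call_fixed_regions(track), truth


def test_injected_region_recovered_with_tight_boundaries():
    cfg = scan_config(31, (("1A", 20_000_001, 30_000_000),))
    regions, truth = run_scan(cfg)
    hits = [r for r in regions if r.chromosome == "1A"
            and r.end_bp >= 20_000_001 and r.start_bp <= 30_000_000]
    assert len(hits) == 1
    # boundary error bounded by one inter-marker gap on each side
    gap = 80_000_000 / (300 / 2)  # mean spacing; generous bound: 10 gaps
    assert hits[0].start_bp >= 20_000_001 - 10 * gap
    assert hits[0].end_bp <= 30_000_000 + 10 * gap


def test_interval_with_too_few_markers_not_called():
    """A 1.5 Mb injected interval holds fewer than 5 markers on average and
    cannot satisfy the span rule: nothing is called there."""
    cfg = scan_config(33, (("2A", 10_000_001, 11_500_000),))
    regions, truth = run_scan(cfg)
    assert len(truth.fixed_regions[0]["marker_ids"]) < 5 or all(
        not (r.chromosome == "2A" and r.start_bp <= 11_500_000
             and r.end_bp >= 10_000_001 and r.span_bp <= 1_500_000)
        for r in regions)
    assert all(r.satisfies_rule() for r in regions)


def test_empty_region_spec_changes_nothing():
    cfg_plain = scan_config(35, ())
    regions, _ = run_scan(cfg_plain)
    for r in regions:
        assert r.satisfies_rule()


# ---------------------------------------------------------------------------
# track construction / windows / annotation
# ---------------------------------------------------------------------------

def test_build_hs_track_values_and_order():
    cfg = scan_config(37, ())
    matrix, placements, frame, _ = simulate_structured_genotypes(cfg)
    scan_matrix, _ = run_standard_filter(matrix, skip_dedup=True)
    track = build_hs_track(scan_matrix, placements, frame)
    assert track.is_sorted()
    assert ((track.hs_reference >= 0) & (track.hs_reference <= 1)).all()
    # shuffled marker order yields the same sorted track
    shuffled = scan_matrix.subset_markers(list(reversed(scan_matrix.marker_ids)))
    track2 = build_hs_track(shuffled, placements, frame)
    assert track2.marker_ids == track.marker_ids


def test_build_hs_track_requires_placements():
    from wheatdiv.anchoring import PlacementTable
    cfg = scan_config(39, ())
    matrix, _, frame, _ = simulate_structured_genotypes(cfg)
    with pytest.raises(ValueError, match="placement"):
        build_hs_track(matrix, PlacementTable(), frame)


def test_windowed_hs_means_and_conservation():
    track = make_track([1_000_000, 9_000_000, 15_000_000],
                       [0.2, 0.4, 0.1], [0.3, 0.5, 0.2])
    df = windowed_hs(track, window_bp=10_000_000,
                     chromosome_lengths={"1A": 30_000_000})
    assert len(df) == 3
    assert df.loc[0, "mean_hs_reference"] == pytest.approx(0.3)
    assert df.loc[1, "n_markers"] == 1
    empty = df.loc[2]
    assert empty["n_markers"] == 0 and np.isnan(empty["mean_hs_reference"])
    assert df["n_markers"].sum() == len(track)


def test_annotate_regions_inclusive_bounds():
    region = RegionCall("4D", 10_000_001, 20_000_000, 6, 6)
    genes = {"Rht-D1": ("4D", 15_000_000),
             "edge": ("4D", 20_000_000),
             "outside": ("4D", 20_000_001),
             "other_chrom": ("5B", 15_000_000)}
    out = annotate_regions([region], genes)
    assert out[0].genes == ("Rht-D1", "edge")
    assert annotate_regions([region], {})[0].genes == ()
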