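"""Genome-wide Hs profiling and the fixed-region caller.

The scan contrasts modern reference varieties against landraces along each
chromosome.  Its input marker set deliberately skips the duplicate-profile
filter (nearby markers sharing a profile are informative here) and keeps only
markers with a known genomic location.

A region is called *fixed* when a maximal run of consecutive markers (in
genomic sort order on one chromosome) satisfies all three conditions:

* at least ``min_run`` markers with reference-set Hs equal to 0 (exact zero
  within 1e-12 — a monomorphic locus yields exactly 0 in the estimator),
* at least ``min_diverse`` of the run's own markers with landrace Hs
  strictly above ``hs_diverse_threshold``,
* the first-to-last marker span strictly greater than ``min_span_bp``.

Runs are not merged across interrupting non-zero markers by default; a
``max_interrupt`` option exists for sensitivity analysis only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anchoring import PlacementTable
from .diversity import gene_diversity, locus_frequencies
from .io_formats import PopulationFrame, RegionCall, ROLE_LANDRACE, ROLE_REFERENCE

log = logging.getLogger(__name__)

HS_ZERO_TOL = 1e-12
DEFAULT_MIN_RUN = 5
DEFAULT_MIN_DIVERSE = 5
DEFAULT_HS_DIVERSE_THRESHOLD = 0.1
DEFAULT_MIN_SPAN_BP = 5_000_000


@dataclass(eq=False)
class HsTrack:
    """Per-marker Hs in reference varieties and landraces, genome-sorted."""

    marker_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    hs_reference: np.ndarray
    hs_landrace: np.ndarray

    def __post_init__(self):
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.hs_reference = np.asarray(self.hs_reference, dtype=float)
        self.hs_landrace = np.asarray(self.hs_landrace, dtype=float)
        lengths = {len(self.marker_ids), self.chromosomes.size,
                   self.positions.size, self.hs_reference.size, self.hs_landrace.size}
        if len(lengths) != 1:
            raise ValueError("track arrays must have one common length")
        for name, arr in (("hs_reference", self.hs_reference),
                          ("hs_landrace", self.hs_landrace)):
            if ((arr < -HS_ZERO_TOL) | (arr > 1.0 + 1e-9)).any():
                raise ValueError(f"{name} values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def _keys(self):
        return list(zip(self.chromosomes.tolist(), self.positions.tolist(),
                        self.marker_ids))

    def is_sorted(self) -> bool:
        keys = self._keys()
        return keys == sorted(keys)

    def sorted(self) -> "HsTrack":
        order = sorted(range(len(self)), key=lambda i: (self.chromosomes[i],
                                                        int(self.positions[i]),
                                                        self.marker_ids[i]))
        return HsTrack(
            [self.marker_ids[i] for i in order],
            self.chromosomes[order], self.positions[order],
            self.hs_reference[order], self.hs_landrace[order],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids,
            "chromosome": self.chromosomes,
            "position_bp": self.positions,
            "hs_reference": self.hs_reference,
            "hs_landrace": self.hs_landrace,
        })


def build_hs_track(matrix, placements: PlacementTable,
                   frame: PopulationFrame) -> HsTrack:
    """Per-locus Hs within each role, over the scan-specific marker set.

    Every marker in ``matrix`` must be located; markers where either role has
    fewer than two scored lines are dropped (logged), since their Hs is
    undefined.
    """
    for mid in matrix.marker_ids:
        if not placements.get(mid).located:
            raise ValueError(f"marker {mid!r} reached the scan without a placement")
    freqs = locus_frequencies(matrix, frame, group_by="role")
    div = gene_diversity(freqs)
    try:
        i_ref = freqs.groups.index(ROLE_REFERENCE)
        i_land = freqs.groups.index(ROLE_LANDRACE)
    except ValueError as exc:
        raise ValueError("frame must contain both landrace and reference accessions") from exc
    hs_ref = div.hs_per_locus[i_ref]
    hs_land = div.hs_per_locus[i_land]
    usable = ~np.isnan(hs_ref) & ~np.isnan(hs_land)
    if (~usable).any():
        log.info("build_hs_track: dropped %d markers with undefined Hs in a role",
                 int((~usable).sum()))
    ids = [m for m, u in zip(matrix.marker_ids, usable) if u]
    chroms = [placements.get(m).chromosome for m in ids]
    positions = [placements.get(m).position_bp for m in ids]
    track = HsTrack(ids, np.asarray(chroms, dtype=object),
                    np.asarray(positions), hs_ref[usable], hs_land[usable])
    return track.sorted()


def _maximal_zero_runs(zero: np.ndarray, max_interrupt: int = 0) -> list[tuple[int, int]]:
    """Maximal index runs of True, optionally bridging short False gaps."""
    runs: list[tuple[int, int]] = []
    i, n = 0, zero.size
    while i < n:
        if not zero[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and zero[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1
    if max_interrupt > 0 and runs:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe - 1 <= max_interrupt:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged
    return runs


def call_fixed_regions(track: HsTrack,
                       min_run: int = DEFAULT_MIN_RUN,
                       min_diverse: int = DEFAULT_MIN_DIVERSE,
                       hs_diverse_threshold: float = DEFAULT_HS_DIVERSE_THRESHOLD,
                       min_span_bp: int = DEFAULT_MIN_SPAN_BP,
                       max_interrupt: int = 0) -> list[RegionCall]:
    """Call reference-fixed, landrace-diverse regions on a sorted track."""
    if not track.is_sorted():
        raise ValueError("track must be sorted by (chromosome, position) before scanning")
    regions: list[RegionCall] = []
    for chrom in pd.unique(track.chromosomes):
        sel = np.flatnonzero(track.chromosomes == chrom)
        hs_ref = track.hs_reference[sel]
        hs_land = track.hs_landrace[sel]
        pos = track.positions[sel]
        zero = np.abs(hs_ref) <= HS_ZERO_TOL
        for s, e in _maximal_zero_runs(zero, max_interrupt):
            n_zero = int(zero[s:e + 1].sum())
            if n_zero < min_run:
                continue
            n_diverse = int((hs_land[s:e + 1] > hs_diverse_threshold).sum())
            span = int(pos[e] - pos[s])
            if n_diverse >= min_diverse and span > min_span_bp:
                regions.append(RegionCall(
                    chromosome=str(chrom), start_bp=int(pos[s]), end_bp=int(pos[e]),
                    n_ref_zero=n_zero, n_landrace_diverse=n_diverse,
                ))
    return regions


def windowed_hs(track: HsTrack, window_bp: int = 10_000_000,
                chromosome_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Mean Hs per role in non-overlapping windows tiled from position 1.

    Empty windows are emitted with a missing mean and a zero marker count.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    lengths = chromosome_lengths or {}
    for chrom in pd.unique(track.chromosomes):
        sel = np.flatnonzero(track.chromosomes == chrom)
        pos = track.positions[sel]
        win = (pos - 1) // window_bp
        if chrom in lengths:
            n_win = int(np.ceil(lengths[chrom] / window_bp))
        else:
            n_win = int(win.max()) + 1 if win.size else 0
        for w in range(n_win):
            in_w = win == w
            n = int(in_w.sum())
            rows.append({
                "chromosome": chrom,
                "window_start_bp": w * window_bp + 1,
                "window_end_bp": (w + 1) * window_bp,
                "n_markers": n,
                "mean_hs_reference": float(track.hs_reference[sel][in_w].mean()) if n else np.nan,
                "mean_hs_landrace": float(track.hs_landrace[sel][in_w].mean()) if n else np.nan,
            })
    return pd.DataFrame(rows, columns=["chromosome", "window_start_bp", "window_end_bp",
                                       "n_markers", "mean_hs_reference",
                                       "mean_hs_landrace"])


def annotate_regions(regions: list[RegionCall],
                     gene_table: dict[str, tuple[str, int]]) -> list[RegionCall]:
    """Attach gene names whose position lies inside a region (inclusive)."""
    out = []
    for r in regions:
        genes = tuple(sorted(
            name for name, (chrom, pos) in gene_table.items()
            if chrom == r.chromosome and r.start_bp <= pos <= r.end_bp
        ))
        out.append(RegionCall(r.chromosome, r.start_bp, r.end_bp,
                              r.n_ref_zero, r.n_landrace_diverse, genes=genes))
    return out
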