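"""Placement of marker tags on a reference genome from BLAST tabular hits.

A marker is *located* when it has at least one hit passing the thresholds
(E-value strictly below ``e_max`` and identity strictly above
``min_identity``).  Among passing hits the best is chosen by lowest E-value,
then highest bitscore, then highest identity; a best-score tie across
different chromosomes leaves the marker unplaced, because an arbitrary choice
would corrupt the downstream genome scan.  The placement position is the
alignment start on the subject's forward strand, ``min(s_start, s_end)``, so
that strand does not affect windowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BlastHit, FormatError

DEFAULT_E_MAX = 5e-10
DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_WINDOW_BP = 10_000_000


@dataclass(frozen=True)
class Placement:
    chromosome: str | None
    position_bp: int | None
    located: bool

    @staticmethod
    def unplaced() -> "Placement":
        return Placement(None, None, False)


@dataclass(eq=False)
class PlacementTable:
    """Marker id -> genomic placement; unlocated markers carry ``located=False``."""

    placements: dict[str, Placement] = field(default_factory=dict)
    chromosome_lengths: dict[str, int] | None = None

    def __post_init__(self):
        if self.chromosome_lengths:
            for mid, p in self.placements.items():
                if p.located and p.position_bp > self.chromosome_lengths.get(p.chromosome, np.inf):
                    raise ValueError(
                        f"marker {mid!r} placed at {p.chromosome}:{p.position_bp} beyond "
                        f"chromosome length {self.chromosome_lengths[p.chromosome]}"
                    )

    def __len__(self) -> int:
        return len(self.placements)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.placements

    def get(self, marker_id: str) -> Placement:
        return self.placements.get(marker_id, Placement.unplaced())

    def located_ids(self) -> list[str]:
        return [m for m, p in self.placements.items() if p.located]

    def set(self, marker_id: str, chromosome: str, position_bp: int) -> None:
        self.placements[marker_id] = Placement(chromosome, int(position_bp), True)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"marker_id": m, "chromosome": p.chromosome if p.located else ".",
             "position_bp": p.position_bp if p.located else -1, "located": p.located}
            for m, p in self.placements.items()
        ]
        return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp", "located"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "PlacementTable":
        df = pd.read_csv(path, sep="\t")
        needed = {"marker_id", "chromosome", "position_bp", "located"}
        if not needed.issubset(df.columns):
            raise FormatError(f"{path}: placement table needs columns {sorted(needed)}")
        table = cls()
        for rec in df.itertuples(index=False):
            if bool(rec.located):
                table.set(str(rec.marker_id), str(rec.chromosome), int(rec.position_bp))
            else:
                table.placements[str(rec.marker_id)] = Placement.unplaced()
        return table


def place_markers(hits: list[BlastHit], e_max: float = DEFAULT_E_MAX,
                  min_identity: float = DEFAULT_MIN_IDENTITY,
                  marker_ids=None) -> PlacementTable:
    """Filter hits and choose one placement per marker.

    Both thresholds are strict inequalities (E-value ``<`` e_max, identity
    ``>`` min_identity).  ``marker_ids``, when given, lists every marker that
    was searched so that markers without any hit appear as unplaced.
    """
    passing: dict[str, list[BlastHit]] = {}
    for h in hits:
        if h.evalue < e_max and h.identity > min_identity:
            passing.setdefault(h.query_id, []).append(h)

    table = PlacementTable()
    all_ids = list(marker_ids) if marker_ids is not None else list(passing)
    for mid in all_ids:
        cand = passing.get(mid)
        if not cand:
            table.placements[mid] = Placement.unplaced()
            continue
        # best by (lowest evalue, highest bitscore, highest identity);
        # remaining ties resolved by position for order-invariance
        def score(h: BlastHit):
            return (h.evalue, -h.bitscore, -h.identity)
        best = min(cand, key=lambda h: (score(h), h.subject_id, min(h.s_start, h.s_end)))
        tied = [h for h in cand if score(h) == score(best)]
        if len({h.subject_id for h in tied}) > 1:
            # equally good hits on different chromosomes: ambiguous, leave out
            table.placements[mid] = Placement.unplaced()
        else:
            pos = min(min(h.s_start, h.s_end) for h in tied)
            table.set(mid, best.subject_id, pos)
    if marker_ids is None:
        # keep deterministic ordering even when derived from hit order
        table.placements = dict(sorted(table.placements.items()))
    return table


def subgenome_of(chromosome: str) -> str:
    """Trailing letter of a wheat-style chromosome name ('2A' or 'chr2A' -> 'A')."""
    for ch in reversed(chromosome):
        if ch.isalpha():
            return ch.upper()
    return "?"


@dataclass(eq=False)
class ChromosomeSummary:
    """Located-marker accounting in the layout of a per-chromosome table."""

    per_chromosome: dict[str, int]
    per_subgenome: dict[str, int]
    located: int
    not_located: int

    @property
    def total(self) -> int:
        return self.located + self.not_located

    def to_frame(self) -> pd.DataFrame:
        rows = [{"chromosome": c, "n_markers": n}
                for c, n in sorted(self.per_chromosome.items())]
        return pd.DataFrame(rows, columns=["chromosome", "n_markers"])


def chromosome_summary(placements: PlacementTable, marker_ids=None) -> ChromosomeSummary:
    """Count located markers per chromosome and subgenome.

    ``marker_ids`` restricts (and completes) the accounting: markers absent
    from the table count as not located, so located + not_located always
    equals the number of input markers.
    """
    ids = list(marker_ids) if marker_ids is not None else list(placements.placements)
    per_chrom: dict[str, int] = {}
    per_genome: dict[str, int] = {}
    located = 0
    for mid in ids:
        p = placements.get(mid)
        if p.located:
            located += 1
            per_chrom[p.chromosome] = per_chrom.get(p.chromosome, 0) + 1
            g = subgenome_of(p.chromosome)
            per_genome[g] = per_genome.get(g, 0) + 1
    return ChromosomeSummary(per_chrom, per_genome, located, len(ids) - located)


def density_profile(placements: PlacementTable, window_bp: int = DEFAULT_WINDOW_BP,
                    chromosome_lengths: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Marker counts in non-overlapping windows tiled from position 1.

    Windows are half-open in 1-based terms: window ``w`` covers positions
    ``[w*window_bp + 1, (w+1)*window_bp]``, so a marker exactly at
    ``window_bp + 1`` falls in the second window.  The last short window is
    retained.  Counts over one chromosome sum to its located markers.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    by_chrom: dict[str, list[int]] = {}
    for mid, p in placements.placements.items():
        if p.located:
            by_chrom.setdefault(p.chromosome, []).append(p.position_bp)
    lengths = chromosome_lengths or placements.chromosome_lengths or {}
    out: dict[str, np.ndarray] = {}
    for chrom, positions in by_chrom.items():
        pos = np.asarray(positions, dtype=np.int64)
        win = (pos - 1) // window_bp
        if chrom in lengths:
            n_win = int(np.ceil(lengths[chrom] / window_bp))
        else:
            n_win = int(win.max()) + 1
        counts = np.bincount(win, minlength=n_win)
        out[chrom] = counts
    for chrom, length in lengths.items():
        if chrom not in out:
            out[chrom] = np.zeros(int(np.ceil(length / window_bp)), dtype=np.int64)
    return out
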