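"""Heterozygote recoding, marker filtering and informativeness (PIC).

The accessions are fully inbred lines, so true heterozygote calls are not
expected: a SNP column containing 2s is assumed to carry homoeolog
cross-mapping artifacts and is repaired per column from the set of observed
non-missing values:

* only 0 and 2 observed  -> every 2 becomes 1 (the missing homozygote class),
* only 1 and 2 observed  -> every 2 becomes 0,
* 0, 1 and 2 observed    -> every 2 becomes missing (ambiguous),
* only 2 observed        -> the whole column becomes missing (nothing anchors
  the correction; degenerate case not covered by the three rules above).

Filtering then proceeds in a fixed order: duplicate-profile removal (optional),
missing-data filter (markers with MORE than ``max_missing`` removed, boundary
kept) and MAF filter (markers with MAF strictly below ``min_maf`` removed,
boundary kept).  Both boundary behaviors follow the strict wording of the
protocol this implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, DartMatrix, SnpMatrix

DEFAULT_MAX_MISSING = 0.10
DEFAULT_MIN_MAF = 0.05

RECODE_TO_ALT = "to_alt"
RECODE_TO_REF = "to_ref"
RECODE_TO_MISSING = "to_missing"
RECODE_NONE = "none"


@dataclass
class StepReport:
    name: str
    n_before: int
    n_after: int
    removed_ids: list = field(default_factory=list)


@dataclass
class QcReport:
    """Chained accounting of every QC step applied to a matrix."""

    steps: list = field(default_factory=list)
    recode_actions: dict = field(default_factory=dict)

    def add_step(self, step: StepReport) -> None:
        if self.steps and step.n_before != self.steps[-1].n_after:
            raise ValueError(
                f"step {step.name!r} starts from {step.n_before} markers but the "
                f"previous step left {self.steps[-1].n_after}"
            )
        if step.n_after > step.n_before:
            raise ValueError(f"step {step.name!r} increased the marker count")
        self.steps.append(step)

    def _after(self, name: str) -> int | None:
        for s in self.steps:
            if s.name == name:
                return s.n_after
        return None

    @property
    def n_input(self) -> int | None:
        return self.steps[0].n_before if self.steps else None

    @property
    def n_after_dedup(self) -> int | None:
        return self._after("deduplicate")

    @property
    def n_after_missing(self) -> int | None:
        return self._after("missing_filter")

    @property
    def n_after_maf(self) -> int | None:
        return self._after("maf_filter")

    def removed_by(self, name: str) -> list:
        for s in self.steps:
            if s.name == name:
                return list(s.removed_ids)
        return []

    def to_dict(self) -> dict:
        return {
            "steps": [
                {"name": s.name, "n_before": s.n_before, "n_after": s.n_after,
                 "removed_ids": list(s.removed_ids)}
                for s in self.steps
            ],
            "recode_actions": dict(self.recode_actions),
        }


def _merge_reports(*reports: QcReport) -> QcReport:
    out = QcReport()
    for r in reports:
        for s in r.steps:
            out.add_step(s)
        out.recode_actions.update(r.recode_actions)
    return out


# ---------------------------------------------------------------------------
# recoding
# ---------------------------------------------------------------------------

def recode_heterozygous(matrix: SnpMatrix) -> tuple[SnpMatrix, QcReport]:
    """Repair spurious heterozygote calls per marker; output contains no 2s."""
    if isinstance(matrix, DartMatrix) or not isinstance(matrix, SnpMatrix):
        raise TypeError("recode_heterozygous expects a SnpMatrix")
    out = matrix.copy()
    report = QcReport()
    report.add_step(StepReport("recode", matrix.n_markers, matrix.n_markers))
    for j, mid in enumerate(out.marker_ids):
        col = out.calls[:, j]
        observed = set(np.unique(col[col != MISSING]).tolist())
        if 2 not in observed:
            report.recode_actions[mid] = RECODE_NONE
            continue
        hets = col == 2
        if observed == {0, 2}:
            col[hets] = 1
            report.recode_actions[mid] = RECODE_TO_ALT
        elif observed == {1, 2}:
            col[hets] = 0
            report.recode_actions[mid] = RECODE_TO_REF
        else:  # {0,1,2} or the degenerate {2}
            col[hets] = MISSING
            report.recode_actions[mid] = RECODE_TO_MISSING
    return out, report


# ---------------------------------------------------------------------------
# duplicate profiles
# ---------------------------------------------------------------------------

def _compatibility(calls: np.ndarray) -> np.ndarray:
    """Boolean L x L grid: markers agree wherever both are scored AND share at
    least one scored accession.  Dense matmul formulation, O(L^2) memory."""
    a1 = (calls == 1).astype(np.float32)
    a0 = (calls == 0).astype(np.float32)
    scored = (calls != MISSING).astype(np.float32)
    cross = a1.T @ a0  # cross[j, k]: accessions where j==1 and k==0
    conflict = cross + cross.T
    shared = scored.T @ scored
    return (conflict < 0.5) & (shared > 0.5)


def duplicate_groups(matrix) -> list[list[int]]:
    """Group marker columns by shared allelic profile.

    Two markers are duplicates when their calls agree at every accession where
    both are scored and they share at least one scored accession.  The
    relation is not transitive, so grouping is greedy in input-column order:
    each column joins the first group whose *seed* column it is compatible
    with, otherwise it seeds a new group.  Returns column-index groups in seed
    order (singletons included).
    """
    calls = matrix.calls
    if isinstance(matrix, SnpMatrix) and (calls == 2).any():
        raise ValueError("deduplicate expects a recoded matrix (no heterozygote codes)")
    compat = _compatibility(calls)
    reps: list[int] = []
    groups: list[list[int]] = []
    reps_arr = np.empty(matrix.n_markers, dtype=np.intp)
    for j in range(matrix.n_markers):
        if reps:
            row = compat[j, reps_arr[:len(reps)]]
            hit = np.flatnonzero(row)
            if hit.size:
                groups[int(hit[0])].append(j)
                continue
        reps_arr[len(reps)] = j
        reps.append(j)
        groups.append([j])
    return groups


def deduplicate_profiles(matrix) -> tuple[SnpMatrix | DartMatrix, QcReport]:
    """Keep, within each duplicate group, the member with the least missing
    data (ties broken toward the first marker in input order)."""
    groups = duplicate_groups(matrix)
    miss = matrix.missing_per_marker()
    keep_idx = []
    removed = []
    for g in groups:
        best = min(g, key=lambda j: (miss[j], j))
        keep_idx.append(best)
        removed.extend(matrix.marker_ids[j] for j in g if j != best)
    keep_idx.sort()
    out = matrix.subset_markers(keep_idx)
    report = QcReport()
    report.add_step(StepReport("deduplicate", matrix.n_markers, out.n_markers, removed))
    return out, report


# ---------------------------------------------------------------------------
# missing / MAF filters
# ---------------------------------------------------------------------------

def filter_missing(matrix, max_missing: float = DEFAULT_MAX_MISSING):
    """Remove markers whose missing fraction strictly exceeds ``max_missing``."""
    frac = matrix.missing_per_marker() / matrix.n_accessions
    keep = frac <= max_missing
    removed = [m for m, k in zip(matrix.marker_ids, keep) if not k]
    out = matrix.subset_markers(list(keep))
    report = QcReport()
    report.add_step(StepReport("missing_filter", matrix.n_markers, out.n_markers, removed))
    return out, report


def minor_allele_frequency(column: np.ndarray) -> float:
    """MAF of one 0/1 column, each inbred line counting as one allele
    observation; missing calls are dropped (pairwise deletion).  An
    all-missing column returns NaN (undefined, flagged for removal)."""
    column = np.asarray(column)
    scored = column[column != MISSING]
    if np.isin(scored, [0, 1], invert=True).any():
        raise ValueError("minor_allele_frequency expects calls in {0, 1, missing}")
    if scored.size == 0:
        return float("nan")
    p = float(scored.mean())
    return min(p, 1.0 - p)


def filter_maf(matrix, min_maf: float = DEFAULT_MIN_MAF):
    """Remove markers with MAF strictly below ``min_maf`` (boundary kept);
    all-missing markers (undefined MAF) are removed too."""
    mafs = np.array([minor_allele_frequency(matrix.calls[:, j])
                     for j in range(matrix.n_markers)])
    keep = mafs >= min_maf  # NaN compares False -> removed
    removed = [m for m, k in zip(matrix.marker_ids, keep) if not k]
    out = matrix.subset_markers(list(keep))
    report = QcReport()
    report.add_step(StepReport("maf_filter", matrix.n_markers, out.n_markers, removed))
    return out, report


def run_standard_filter(matrix, skip_dedup: bool = False,
                        max_missing: float = DEFAULT_MAX_MISSING,
                        min_maf: float = DEFAULT_MIN_MAF):
    """Full pipeline: (recode if SNP) -> dedup (unless skipped) -> missing
    filter -> MAF filter.  Returns the filtered matrix and the chained report.

    ``skip_dedup=True`` reproduces the genome-scan marker set, where duplicate
    profiles are deliberately retained.
    """
    reports = []
    if isinstance(matrix, SnpMatrix) and not isinstance(matrix, DartMatrix):
        matrix, r = recode_heterozygous(matrix)
        reports.append(r)
    if not skip_dedup:
        matrix, r = deduplicate_profiles(matrix)
        reports.append(r)
    matrix, r = filter_missing(matrix, max_missing)
    reports.append(r)
    matrix, r = filter_maf(matrix, min_maf)
    reports.append(r)
    return matrix, _merge_reports(*reports)


# ---------------------------------------------------------------------------
# PIC
# ---------------------------------------------------------------------------

def pic_from_freq(p: float) -> float:
    """Botstein PIC for a biallelic locus: 1 - (p^2 + q^2) - 2 p^2 q^2."""
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def pic(column: np.ndarray, marker_type: str = "snp",
        dominant_correction: bool = False) -> float:
    """PIC of one marker column over {0,1,missing}.

    For inbred lines the presence frequency of a dominant (DArT) band is
    itself an allele-frequency estimate, so by default no Hardy–Weinberg
    back-correction is applied.  ``dominant_correction=True`` instead
    estimates the null-allele frequency as sqrt(freq of absence), the classic
    dominant-marker treatment for outbred material.
    """
    column = np.asarray(column)
    if (column == 2).any():
        raise ValueError("pic expects a recoded column (no heterozygote codes)")
    scored = column[column != MISSING]
    if scored.size == 0:
        return float("nan")
    p = float(scored.mean())
    if dominant_correction and marker_type.lower() == "dart":
        q = float(np.sqrt(1.0 - p))  # band-absence -> null-allele frequency
        p = 1.0 - q
    return pic_from_freq(p)


@dataclass
class PicSummary:
    per_marker: dict
    mean: float
    fraction_gt_0_2: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray


def pic_summary(matrix, marker_type: str = "snp", bins: int = 20,
                dominant_correction: bool = False) -> PicSummary:
    """Per-marker PIC with mean, fraction strictly above 0.2, and histogram."""
    values = {m: pic(matrix.calls[:, j], marker_type, dominant_correction)
              for j, m in enumerate(matrix.marker_ids)}
    arr = np.array([v for v in values.values() if not np.isnan(v)])
    counts, edges = np.histogram(arr, bins=bins, range=(0.0, 0.375))
    return PicSummary(
        per_marker=values,
        mean=float(arr.mean()) if arr.size else 0.0,
        fraction_gt_0_2=float((arr > 0.2).mean()) if arr.size else 0.0,
        histogram_counts=counts,
        histogram_edges=edges,
    )
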