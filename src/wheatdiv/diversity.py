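"""Gene diversity, differentiation and fixation statistics for inbred lines.

Every accession is a fully inbred line, so each line contributes a single
allele observation per locus (haploid treatment, observed heterozygosity 0).
With per-population allele frequency ``p`` estimated from ``n`` scored lines:

* within-population gene diversity (Nei), unbiased form::

      Hs = n/(n-1) * (1 - p^2 - q^2)

* total diversity uses the unweighted mean frequency across populations with
  the same small-sample factor evaluated at the harmonic mean sample size
  ``ñ``::

      Ht = ñ/(ñ-1) * (1 - p̄^2 - q̄^2)

  Applying the identical correction to within and total diversity keeps
  Ht >= mean(Hs) locus by locus (Jensen) and makes the differentiation
  statistics vanish exactly when all populations share the same frequencies.

* Jost differentiation per locus, with k populations scored::

      D = (Ht - Hs̄)/(1 - Hs̄) * k/(k-1)

  The overall estimate is a ratio of loci-averaged Ht and Hs̄ (ratio of
  averages, the "overall" convention of hierarchical-statistics packages),
  with per-locus values also exposed.

* pairwise Weir–Cockerham θ uses the variance components with observed
  heterozygosity fixed at zero, combined across loci as a ratio of sums;
  loci monomorphic across a pair contribute nothing.

An alternative diploid coding (each line scored as a homozygous diploid
genotype, 2n alleles) is available behind ``coding="diploid"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io_formats import MISSING, PopulationFrame

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-locus frequencies
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class LocusFrequencies:
    """Allele frequency ``p`` and scored sample size ``n`` per group and locus.

    ``p`` is NaN wherever a group has no scored call at that locus.
    """

    groups: list[str]
    p: np.ndarray  # (G, L)
    n: np.ndarray  # (G, L) ints
    marker_ids: list[str]

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.p.shape != self.n.shape or self.p.shape[0] != len(self.groups):
            raise ValueError("frequency/sample-size grids do not match group list")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.p, initial=0.0) < -1e-12 or np.nanmax(self.p, initial=0.0) > 1 + 1e-12:
                raise ValueError("allele frequencies outside [0, 1]")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_loci(self) -> int:
        return self.p.shape[1]


def locus_frequencies(matrix, frame: PopulationFrame,
                      group_by: str = "population") -> LocusFrequencies:
    """Per-group allele frequencies with pairwise deletion of missing calls.

    The matrix must be post-QC (calls in {0, 1, missing}); accessions absent
    from ``frame`` are ignored, groups empty at a locus get ``p = NaN, n = 0``.
    """
    if (matrix.calls == 2).any():
        raise ValueError("locus_frequencies expects a recoded matrix (no 2s)")
    acc_pos = {a: i for i, a in enumerate(matrix.accession_ids)}
    indices = frame.group_indices(group_by)
    groups = list(indices)
    G, L = len(groups), matrix.n_markers
    p = np.full((G, L), np.nan)
    n = np.zeros((G, L), dtype=int)
    for g, label in enumerate(groups):
        rows = [acc_pos[frame.accession_ids[i]] for i in indices[label]
                if frame.accession_ids[i] in acc_pos]
        if not rows:
            continue
        sub = matrix.calls[np.asarray(rows, dtype=int), :]
        scored = sub != MISSING
        cnt = scored.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(cnt > 0, (sub == 1).sum(axis=0) / np.maximum(cnt, 1), np.nan)
        p[g], n[g] = freq, cnt
    return LocusFrequencies(groups, p, n, list(matrix.marker_ids))


# ---------------------------------------------------------------------------
# gene diversity
# ---------------------------------------------------------------------------

def _allele_counts(n: np.ndarray, coding: str) -> np.ndarray:
    if coding == "haploid":
        return n.astype(float)
    if coding == "diploid":
        return 2.0 * n
    raise ValueError(f"coding must be 'haploid' or 'diploid', got {coding!r}")


@dataclass(eq=False)
class GeneDiversity:
    """Per-locus and aggregated Nei gene diversity."""

    groups: list[str]
    hs_per_locus: np.ndarray      # (G, L); NaN where fewer than 2 scored calls
    ht_per_locus: np.ndarray      # (L,);  NaN where fewer than 1 scored group
    hs_mean_per_locus: np.ndarray  # (L,) mean over scored groups
    hs_per_group: dict
    ht_overall: float


def gene_diversity(freqs: LocusFrequencies, coding: str = "haploid") -> GeneDiversity:
    """Unbiased Hs per group and Ht from unweighted mean frequencies.

    Loci where a group has fewer than 2 allele observations are skipped for
    that group (logged), not zero-filled.
    """
    counts = _allele_counts(freqs.n, coding)
    usable = counts >= 2
    n_skipped = int(((counts > 0) & ~usable).sum())
    if n_skipped:
        log.info("gene_diversity: skipped %d group-locus cells with <2 observations",
                 n_skipped)
    p = freqs.p
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = 1.0 - p ** 2 - (1.0 - p) ** 2
        hs = np.where(usable, counts / (counts - 1.0) * raw, np.nan)

        # total diversity over groups scored at each locus
        scored_group = usable & ~np.isnan(p)
        k = scored_group.sum(axis=0).astype(float)
        p_masked = np.where(scored_group, p, np.nan)
        pbar = np.nanmean(p_masked, axis=0)
        inv_n = np.where(scored_group, 1.0 / np.maximum(counts, 1), np.nan)
        n_harm = k / np.nansum(inv_n, axis=0)
        ht_raw = 1.0 - pbar ** 2 - (1.0 - pbar) ** 2
        ht = np.where(k >= 1, n_harm / (n_harm - 1.0) * ht_raw, np.nan)
        hs_mean = np.nanmean(np.where(scored_group, hs, np.nan), axis=0)

    hs_per_group = {}
    for g, label in enumerate(freqs.groups):
        vals = hs[g][~np.isnan(hs[g])]
        hs_per_group[label] = float(vals.mean()) if vals.size else float("nan")
    ht_vals = ht[~np.isnan(ht)]
    return GeneDiversity(
        groups=list(freqs.groups),
        hs_per_locus=hs, ht_per_locus=ht, hs_mean_per_locus=hs_mean,
        hs_per_group=hs_per_group,
        ht_overall=float(ht_vals.mean()) if ht_vals.size else float("nan"),
    )


# ---------------------------------------------------------------------------
# Jost differentiation
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class DestResult:
    overall: float
    per_locus: np.ndarray
    n_loci_used: int


def jost_dest(freqs: LocusFrequencies, coding: str = "haploid") -> DestResult:
    """Jost differentiation from loci-averaged Ht and mean Hs.

    Per-locus values use the number of populations scored at that locus; the
    overall value is the ratio of the across-locus averages scaled by
    K/(K-1) with K the number of groups in ``freqs``.
    """
    div = gene_diversity(freqs, coding=coding)
    counts = _allele_counts(freqs.n, coding)
    k = ((counts >= 2) & ~np.isnan(freqs.p)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(
            (k >= 2) & (div.hs_mean_per_locus < 1.0),
            (div.ht_per_locus - div.hs_mean_per_locus)
            / (1.0 - div.hs_mean_per_locus) * k / np.maximum(k - 1.0, 1e-300),
            np.nan,
        )
    usable = (k >= 2) & ~np.isnan(div.ht_per_locus) & ~np.isnan(div.hs_mean_per_locus)
    K = freqs.n_groups
    if usable.sum() == 0 or K < 2:
        return DestResult(float("nan"), per_locus, 0)
    ht_bar = float(div.ht_per_locus[usable].mean())
    hs_bar = float(div.hs_mean_per_locus[usable].mean())
    overall = (ht_bar - hs_bar) / (1.0 - hs_bar) * K / (K - 1.0)
    return DestResult(overall, per_locus, int(usable.sum()))


# ---------------------------------------------------------------------------
# Weir–Cockerham theta
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class FstMatrix:
    """Population x population multi-locus θ, symmetric with zero diagonal.

    Small negative estimates are reported as computed; ``clamped_frame``
    renders the non-negative version for summary tables.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("FstMatrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("FstMatrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("FstMatrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def clamped_frame(self) -> pd.DataFrame:
        return pd.DataFrame(np.clip(self.values, 0.0, None),
                            index=self.labels, columns=self.labels)

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def _theta_pair(p1, n1, p2, n2) -> float:
    """Multi-locus Weir–Cockerham θ for two samples of haploid observations.

    Variance components with observed heterozygosity 0; ratio of sums over
    loci where both samples have >=2 observations and the pooled sample is
    polymorphic.
    """
    p1, n1 = np.asarray(p1, float), np.asarray(n1, float)
    p2, n2 = np.asarray(p2, float), np.asarray(n2, float)
    valid = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
    p1, n1, p2, n2 = p1[valid], n1[valid], p2[valid], n2[valid]
    ntot = n1 + n2
    pw = (n1 * p1 + n2 * p2) / ntot
    poly = (pw > 0.0) & (pw < 1.0)
    p1, n1, p2, n2, pw, ntot = p1[poly], n1[poly], p2[poly], n2[poly], pw[poly], ntot[poly]
    if p1.size == 0:
        return float("nan")
    r = 2.0
    nbar = ntot / r
    nc = (ntot - (n1 ** 2 + n2 ** 2) / ntot) / (r - 1.0)
    s2 = (n1 * (p1 - pw) ** 2 + n2 * (p2 - pw) ** 2) / ((r - 1.0) * nbar)
    inner = pw * (1.0 - pw) - (r - 1.0) / r * s2
    a = nbar / nc * (s2 - inner / (nbar - 1.0))
    b = nbar / (nbar - 1.0) * inner
    denom = float(np.sum(a + b))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(a) / denom)


def pairwise_fst(matrix, frame: PopulationFrame, group_by: str = "population",
                 coding: str = "haploid") -> FstMatrix:
    """Pairwise multi-locus θ between every pair of groups."""
    freqs = locus_frequencies(matrix, frame, group_by)
    counts = _allele_counts(freqs.n, coding)
    G = freqs.n_groups
    values = np.zeros((G, G))
    for i, j in combinations(range(G), 2):
        theta = _theta_pair(freqs.p[i], counts[i], freqs.p[j], counts[j])
        values[i, j] = values[j, i] = theta
    return FstMatrix(list(freqs.groups), values)


# ---------------------------------------------------------------------------
# monomorphic accounting
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class MonomorphicResult:
    count: int
    monomorphic_ids: list
    all_missing_ids: list  # counted as monomorphic but flagged separately


def count_monomorphic(matrix, accession_ids) -> MonomorphicResult:
    """Markers whose non-missing calls are all identical within a subset.

    All-missing markers are counted as monomorphic and flagged.
    """
    sub = matrix.subset_accessions(list(accession_ids))
    mono, all_missing = [], []
    for j, mid in enumerate(sub.marker_ids):
        col = sub.calls[:, j]
        scored = col[col != MISSING]
        if scored.size == 0:
            all_missing.append(mid)
            mono.append(mid)
        elif np.all(scored == scored[0]):
            mono.append(mid)
    return MonomorphicResult(len(mono), mono, all_missing)


# ---------------------------------------------------------------------------
# assembled table
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class DiversityTable:
    """Per-population Hs, overall Ht and Dest for one grouping."""

    group_by: str
    hs_per_population: dict
    ht_overall: float
    dest: float
    hs_per_locus: np.ndarray
    ht_per_locus: np.ndarray
    dest_per_locus: np.ndarray
    groups: list[str]
    marker_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"group": g, "Hs": self.hs_per_population[g]} for g in self.groups]
        return pd.DataFrame(rows, columns=["group", "Hs"])


def diversity_table(matrix, frame: PopulationFrame, group_by: str = "population",
                    coding: str = "haploid") -> DiversityTable:
    """Convenience wrapper: frequencies -> Hs/Ht -> Dest in one call."""
    freqs = locus_frequencies(matrix, frame, group_by)
    div = gene_diversity(freqs, coding=coding)
    dest = jost_dest(freqs, coding=coding)
    return DiversityTable(
        group_by=group_by,
        hs_per_population=div.hs_per_group,
        ht_overall=div.ht_overall,
        dest=dest.overall,
        hs_per_locus=div.hs_per_locus,
        ht_per_locus=div.ht_per_locus,
        dest_per_locus=dest.per_locus,
        groups=list(freqs.groups),
        marker_ids=list(freqs.marker_ids),
    )
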