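"""Synthetic genotype collections with the structure the pipeline assumes.

The generator emulates a genebank collection of fully inbred lines drawn from
several differentiated populations, genotyped on a GBS platform:

* Per-marker ancestral allele frequencies are drawn from a configurable law,
  and each population's frequency follows the Balding–Nichols model
  ``Beta(p0(1-F)/F, (1-p0)(1-F)/F)``, whose variance around the ancestral
  frequency is ``p0(1-p0)F``.
* Accessions are inbred, so each line contributes a single haploid draw
  (call 0 or 1); heterozygote codes (2) exist only as injected homoeolog
  artifacts, mirroring how cross-subgenome tag mapping corrupts SNP calls in
  polyploid wheat.
* Optional injections add missing data, duplicated marker profiles with extra
  missing cells, and genomic intervals fixed in the reference varieties but
  kept polymorphic in the landraces — the signal the fixed-region scan is
  built to recover.

All randomness flows from a single seed through named
:class:`numpy.random.SeedSequence` children, one per sub-generator, so e.g.
membership sampling is unaffected by how many markers are drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anchoring import Placement, PlacementTable
from .io_formats import (MISSING, PopulationFrame, ROLE_LANDRACE,
                         ROLE_REFERENCE, SnpMatrix)

_STREAMS = ("ancestral", "population_freqs", "genotypes", "placements",
            "memberships", "missing", "regions", "artifacts", "duplicates")

#: default population sizes emulating a durum-type landrace collection:
#: seven admixture groups, the largest holding a third of the lines and two
#: small ones standing in for the minority subspecies pools
_DEFAULT_POP_SIZES = (25, 12, 37, 18, 14, 65, 20)


def default_chromosome_names(n: int) -> list[str]:
    """Wheat-style names: 1A..7A, 1B..7B, 1D..7D; generic beyond 21."""
    if n <= 21:
        return [f"{i % 7 + 1}{'ABD'[i // 7]}" for i in range(n)]
    return [f"chr{i + 1}" for i in range(n)]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic collection.

    Defaults emulate the durum-wheat-like setting: 191 landraces in seven
    populations plus 23 modern reference varieties, scored at 10,000 SNP
    markers over 14 chromosomes of 600 Mb, with moderate differentiation
    (F = 0.3), 5% missing data, homoeolog heterozygote artifacts on 5% of
    markers and 10% duplicated marker profiles.
    """

    n_populations: int = 7
    n_per_population: tuple = _DEFAULT_POP_SIZES
    n_markers: int = 10_000
    fst_target: float = 0.3
    ancestral_freq_law: tuple = ("uniform", 0.1, 0.9)
    missing_rate: float = 0.05
    het_artifact_rate: float = 0.05
    duplicate_fraction: float = 0.10
    n_chromosomes: int = 14
    chromosome_length_bp: int = 600_000_000
    fixed_region_spec: tuple = ()
    reference_set_size: int = 23
    subspecies_of_population: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if len(self.n_per_population) != self.n_populations:
            raise ValueError("n_per_population length must equal n_populations")
        if not (0.0 < self.fst_target < 1.0):
            raise ValueError(f"fst_target must lie in (0, 1), got {self.fst_target}")
        for name in ("missing_rate", "het_artifact_rate", "duplicate_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        names = set(self.chromosome_names())
        for chrom, start, end in self.fixed_region_spec:
            if chrom not in names:
                raise ValueError(f"fixed region on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= self.chromosome_length_bp):
                raise ValueError(
                    f"fixed region {chrom}:{start}-{end} outside chromosome bounds"
                )

    def chromosome_names(self) -> list[str]:
        return default_chromosome_names(self.n_chromosomes)

    @property
    def n_landraces(self) -> int:
        return int(sum(self.n_per_population))

    @property
    def n_accessions(self) -> int:
        return self.n_landraces + self.reference_set_size


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated collection."""

    marker_ids: list[str]
    accession_ids: list[str]
    ancestral_freqs: np.ndarray
    population_freqs: np.ndarray  # (K, L) landrace pools
    reference_freqs: np.ndarray   # (L,) modern-variety pool
    generating_population: list   # per accession; None for references
    duplicate_groups: list = field(default_factory=list)
    fixed_regions: list = field(default_factory=list)
    artifact_cells: list = field(default_factory=list)   # (accession, marker, original)
    artifact_scenarios: dict = field(default_factory=dict)
    n_missing_injected: int = 0

    def check_dimensions(self, matrix: SnpMatrix) -> None:
        """Truth arrays must agree with the emitted matrix (base markers only:
        injected duplicates are tracked through ``duplicate_groups``)."""
        dup_ids = {d for g in self.duplicate_groups for d in g[1:]}
        base = [m for m in matrix.marker_ids if m not in dup_ids]
        if base != self.marker_ids:
            raise ValueError("truth marker ids do not match matrix base markers")
        if matrix.accession_ids != self.accession_ids:
            raise ValueError("truth accession ids do not match matrix")
        if self.population_freqs.shape[1] != len(self.marker_ids):
            raise ValueError("population_freqs width does not match markers")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _draw_ancestral(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        lo, hi = float(law[1]), float(law[2])
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"uniform ancestral law bounds invalid: {law}")
        p0 = rng.uniform(lo, hi, size)
    elif kind == "beta":
        p0 = rng.beta(float(law[1]), float(law[2]), size)
    else:
        raise ValueError(f"unknown ancestral_freq_law {law!r}")
    return np.clip(p0, 1e-6, 1.0 - 1e-6)


def balding_nichols_freqs(rng: np.random.Generator, p0: np.ndarray,
                          fst: float, n_pools: int) -> np.ndarray:
    """Draw ``n_pools`` population frequency vectors around ``p0``."""
    alpha = p0 * (1.0 - fst) / fst
    beta = (1.0 - p0) * (1.0 - fst) / fst
    return rng.beta(alpha[None, :], beta[None, :], size=(n_pools, p0.size))


def simulate_structured_genotypes(config: SimulationConfig):
    """Generate a full synthetic collection.

    Returns ``(matrix, placements, frame, truth)`` where ``matrix`` is a
    :class:`SnpMatrix` over {0,1,2,missing} (2s only when artifacts are on),
    ``placements`` locates every marker, ``frame`` assigns roles and
    populations, and ``truth`` records everything injected.
    Deterministic for a fixed config (seed included).
    """
    rngs = _streams(config.seed)
    K, L = config.n_populations, config.n_markers

    p0 = _draw_ancestral(rngs["ancestral"], config.ancestral_freq_law, L)
    pools = balding_nichols_freqs(rngs["population_freqs"], p0,
                                  config.fst_target, K + 1)
    pop_freqs, ref_freqs = pools[:K], pools[K]

    # accession bookkeeping: landraces grouped by population, then references
    accession_ids: list[str] = []
    roles: list[str] = []
    gen_pop: list = []
    row_freq_idx: list[int] = []
    for k, n_k in enumerate(config.n_per_population):
        for i in range(n_k):
            accession_ids.append(f"LR{k + 1:02d}_{i + 1:03d}")
            roles.append(ROLE_LANDRACE)
            gen_pop.append(f"Pop{k + 1}")
            row_freq_idx.append(k)
    for i in range(config.reference_set_size):
        accession_ids.append(f"REF_{i + 1:03d}")
        roles.append(ROLE_REFERENCE)
        gen_pop.append(None)
        row_freq_idx.append(K)

    freq_rows = pools[np.asarray(row_freq_idx, dtype=int)]
    u = rngs["genotypes"].random((len(accession_ids), L))
    calls = (u < freq_rows).astype(np.int16)

    marker_ids = [f"M{j + 1:06d}" for j in range(L)]
    matrix = SnpMatrix(accession_ids, marker_ids, calls)

    # uniform placements; every marker located
    chrom_names = config.chromosome_names()
    chrom_idx = rngs["placements"].integers(0, config.n_chromosomes, L)
    positions = rngs["placements"].integers(1, config.chromosome_length_bp + 1, L)
    placements = PlacementTable(
        chromosome_lengths={c: config.chromosome_length_bp for c in chrom_names})
    for j, mid in enumerate(marker_ids):
        placements.set(mid, chrom_names[chrom_idx[j]], int(positions[j]))

    # memberships: concentrated Dirichlet around the generating population
    memberships = np.full((len(accession_ids), K), np.nan)
    mrng = rngs["memberships"]
    for i, pop in enumerate(gen_pop):
        if pop is None:
            continue
        alpha = np.full(K, 0.3)
        alpha[int(pop[3:]) - 1] = 15.0
        memberships[i] = mrng.dirichlet(alpha)
    subspecies = None
    if config.subspecies_of_population is not None:
        sub_of = list(config.subspecies_of_population)
        subspecies = [sub_of[int(p[3:]) - 1] if p is not None else None for p in gen_pop]
    frame = PopulationFrame.from_memberships(accession_ids, roles, memberships,
                                             subspecies=subspecies)

    truth = SimulationTruth(
        marker_ids=list(marker_ids), accession_ids=list(accession_ids),
        ancestral_freqs=p0, population_freqs=pop_freqs, reference_freqs=ref_freqs,
        generating_population=gen_pop,
    )

    if config.fixed_region_spec:
        matrix = inject_fixed_regions(matrix, placements, frame,
                                      config.fixed_region_spec, truth, rngs["regions"])
    if config.missing_rate > 0:
        mask = rngs["missing"].random(matrix.calls.shape) < config.missing_rate
        matrix = matrix.copy()
        matrix.calls[mask] = MISSING
        truth.n_missing_injected = int(mask.sum())
    if config.het_artifact_rate > 0:
        matrix = inject_het_artifacts(matrix, config.het_artifact_rate, truth,
                                      rngs["artifacts"])
    if config.duplicate_fraction > 0:
        matrix = inject_duplicates(matrix, config.duplicate_fraction, truth,
                                   rngs["duplicates"], placements=placements)

    truth.check_dimensions(matrix)
    return matrix, placements, frame, truth


# ---------------------------------------------------------------------------
# injectors
# ---------------------------------------------------------------------------

_SCENARIOS = ("only_0_and_2", "only_1_and_2", "mixed_0_1_2")


def inject_het_artifacts(matrix: SnpMatrix, rate: float, truth: SimulationTruth,
                         rng: np.random.Generator) -> SnpMatrix:
    """Turn calls into spurious heterozygotes on a sampled fraction of markers.

    Three scenarios mirror what homoeologous cross-mapping produces:
    every alternative-homozygote call becomes 2 (column reads only 0 and 2),
    every reference-homozygote call becomes 2 (only 1 and 2), or a random
    subset becomes 2 while both homozygote classes survive (0, 1 and 2 mixed).
    ``truth`` records every altered cell and the scenario per marker.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    if (matrix.calls == 2).any():
        raise ValueError("input matrix already contains heterozygote codes")
    if rate == 0.0:
        return matrix
    out = matrix.copy()
    chosen = np.flatnonzero(rng.random(out.n_markers) < rate)
    for j in chosen:
        col = out.calls[:, j]
        scenario = _SCENARIOS[int(rng.integers(3))]
        if scenario == "only_0_and_2":
            targets = np.flatnonzero(col == 1)
        elif scenario == "only_1_and_2":
            targets = np.flatnonzero(col == 0)
        else:
            zeros = np.flatnonzero(col == 0)
            ones = np.flatnonzero(col == 1)
            if zeros.size == 0 or ones.size == 0:
                continue  # cannot realize a three-state column here
            keep = {int(rng.choice(zeros)), int(rng.choice(ones))}
            cand = np.array([i for i in np.flatnonzero(col != MISSING) if i not in keep])
            flip = cand[rng.random(cand.size) < 0.5]
            if flip.size == 0 and cand.size:
                flip = cand[[int(rng.integers(cand.size))]]
            targets = flip
        if targets.size == 0:
            continue
        mid = out.marker_ids[j]
        for i in targets:
            truth.artifact_cells.append((out.accession_ids[i], mid, int(col[i])))
        col[targets] = 2
        truth.artifact_scenarios[mid] = scenario
    return out


def inject_duplicates(matrix: SnpMatrix, fraction: float, truth: SimulationTruth,
                      rng: np.random.Generator,
                      placements: PlacementTable | None = None) -> SnpMatrix:
    """Append duplicated marker columns carrying extra missing cells.

    The duplicate keeps the source profile wherever both are scored, so the
    deduplication filter should always discard the copy (it has strictly more
    missing data).  ``truth.duplicate_groups`` stores ``[source, copy]`` pairs.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    n_dup = int(round(fraction * matrix.n_markers))
    if n_dup == 0:
        return matrix
    sources = rng.choice(matrix.n_markers, size=n_dup, replace=False)
    new_cols, new_ids = [], []
    for j in sources:
        col = matrix.calls[:, j].copy()
        scored = np.flatnonzero(col != MISSING)
        n_extra = int(rng.integers(1, 4))
        if scored.size:
            drop = rng.choice(scored, size=min(n_extra, scored.size), replace=False)
            col[drop] = MISSING
        src = matrix.marker_ids[j]
        dup_id = f"{src}__dup"
        new_ids.append(dup_id)
        new_cols.append(col)
        truth.duplicate_groups.append([src, dup_id])
        if placements is not None:
            p = placements.get(src)
            if p.located:
                length = np.inf
                if placements.chromosome_lengths:
                    length = placements.chromosome_lengths.get(p.chromosome, np.inf)
                pos = int(min(p.position_bp + int(rng.integers(1, 50_000)), length))
                placements.set(dup_id, p.chromosome, pos)
    calls = np.concatenate([matrix.calls, np.column_stack(new_cols)], axis=1)
    return SnpMatrix(matrix.accession_ids, matrix.marker_ids + new_ids, calls)


def inject_fixed_regions(matrix: SnpMatrix, placements: PlacementTable,
                         frame: PopulationFrame, region_spec, truth: SimulationTruth,
                         rng: np.random.Generator) -> SnpMatrix:
    """Force reference varieties monomorphic inside the given intervals while
    resampling landrace calls to an intermediate frequency in [0.2, 0.8]."""
    if not region_spec:
        return matrix
    out = matrix.copy()
    acc_pos = {a: i for i, a in enumerate(out.accession_ids)}
    ref_rows = np.array([acc_pos[a] for a in frame.reference_ids], dtype=int)
    land_rows = np.array([acc_pos[a] for a in frame.landrace_ids], dtype=int)
    for chrom, start, end in region_spec:
        hit_ids = [m for m in out.marker_ids
                   if (p := placements.get(m)).located
                   and p.chromosome == chrom and start <= p.position_bp <= end]
        for mid in hit_ids:
            j = out.marker_ids.index(mid)
            col = out.calls[:, j]
            scored_ref = ref_rows[col[ref_rows] != MISSING]
            col[scored_ref] = 0
            scored_land = land_rows[col[land_rows] != MISSING]
            if scored_land.size == 0:
                continue
            for _ in range(100):
                f = rng.uniform(0.25, 0.75)
                draws = (rng.random(scored_land.size) < f).astype(np.int16)
                realized = draws.mean()
                if 0.2 <= realized <= 0.8:
                    break
            col[scored_land] = draws
        truth.fixed_regions.append(
            {"chromosome": chrom, "start_bp": int(start), "end_bp": int(end),
             "marker_ids": hit_ids})
    return out
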