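"""Readers and writers for the delimited formats the pipeline exchanges.

Call-matrix files follow the DArT-report convention: one row per marker, one
column per accession, with a header row of accession identifiers.  In memory
every matrix is accession-per-row so that columns are loci, which is what all
per-locus statistics expect; the transposition happens in the reader/writer
pair and nowhere else.

Missing calls are represented by the sentinel :data:`MISSING` (``-1``), never
by a value that could be confused with a legal call.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import ClassVar

import numpy as np
import pandas as pd

#: Internal sentinel for a missing call.  Never a legal call value.
MISSING = -1

#: Default token representing a missing call in delimited files.
DEFAULT_MISSING_TOKEN = "-"

_IUPAC = frozenset("ACGTURYSWKMBDHVN")


class FormatError(ValueError):
    """Structural problem in an input file (bad header, wrong column count)."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# call matrices
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class _CallMatrix:
    """Accession x marker integer call grid with identifier bookkeeping."""

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    #: legal non-missing call values; overridden by subclasses
    ALPHABET: ClassVar[frozenset] = frozenset()

    def __post_init__(self):
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        _check_unique(self.accession_ids, "accession")
        _check_unique(self.marker_ids, "marker")
        self.calls = np.ascontiguousarray(np.asarray(self.calls, dtype=np.int16))
        expected = (len(self.accession_ids), len(self.marker_ids))
        if self.calls.shape != expected:
            raise FormatError(
                f"call grid shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        legal = np.array(sorted(self.ALPHABET) + [MISSING], dtype=np.int16)
        bad = ~np.isin(self.calls, legal)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"illegal call {int(self.calls[r, c])} at accession "
                f"{self.accession_ids[r]!r}, marker {self.marker_ids[c]!r}; "
                f"allowed values are {sorted(self.ALPHABET)} or missing"
            )

    # -- basic properties ---------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_missing(self) -> int:
        return int((self.calls == MISSING).sum())

    def missing_per_marker(self) -> np.ndarray:
        return (self.calls == MISSING).sum(axis=0)

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_ids.index(marker_id)]

    def accession_index(self, accession_id: str) -> int:
        return self.accession_ids.index(accession_id)

    # -- subsetting ---------------------------------------------------------

    def subset_markers(self, keep) -> "_CallMatrix":
        """Return a new matrix restricted to ``keep`` (ids, indices or bool mask)."""
        keep = list(keep)
        if len(keep) and isinstance(keep[0], (bool, np.bool_)):
            idx = np.flatnonzero(np.asarray(keep, dtype=bool))
        elif len(keep) and isinstance(keep[0], str):
            pos = {m: i for i, m in enumerate(self.marker_ids)}
            idx = np.array([pos[m] for m in keep], dtype=int)
        else:
            idx = np.asarray(keep, dtype=int)
        return type(self)(
            self.accession_ids,
            [self.marker_ids[i] for i in idx],
            self.calls[:, idx],
        )

    def subset_accessions(self, accession_ids) -> "_CallMatrix":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        idx = np.array([pos[a] for a in accession_ids], dtype=int)
        return type(self)(list(accession_ids), self.marker_ids, self.calls[idx, :])

    def copy(self) -> "_CallMatrix":
        return type(self)(list(self.accession_ids), list(self.marker_ids), self.calls.copy())

    def equals(self, other) -> bool:
        return (
            type(self) is type(other)
            and self.accession_ids == other.accession_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
        )


class SnpMatrix(_CallMatrix):
    """SNP calls: 0 = reference homozygote, 1 = alternative homozygote,
    2 = heterozygote, :data:`MISSING` = no call."""

    ALPHABET = frozenset({0, 1, 2})


class DartMatrix(_CallMatrix):
    """Dominant presence/absence calls: 1 = band present, 0 = absent."""

    ALPHABET = frozenset({0, 1})


@dataclass(frozen=True)
class MarkerInfo:
    """Descriptive metadata for one marker tag."""

    marker_id: str
    marker_type: str  # "SNP" or "DArT"
    tag_sequence: str | None = None

    def __post_init__(self):
        if self.marker_type not in ("SNP", "DArT"):
            raise ValueError(f"marker_type must be 'SNP' or 'DArT', got {self.marker_type!r}")
        if self.tag_sequence is not None:
            bad = set(self.tag_sequence.upper()) - _IUPAC
            if bad:
                raise ValueError(
                    f"tag_sequence for {self.marker_id!r} contains non-IUPAC symbols: {sorted(bad)}"
                )


_MATRIX_TYPES = {"snp": SnpMatrix, "dart": DartMatrix}


def _infer_delimiter(line: str, path) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    raise FormatError(f"{path}: could not infer delimiter from header line")


def read_call_matrix(path, marker_type: str = "snp", *,
                     missing_token: str = DEFAULT_MISSING_TOKEN,
                     delimiter: str | None = None):
    """Read a marker-per-row call matrix file.

    Parameters
    ----------
    path
        Delimited text file.  First row: anything, then accession ids.
        Subsequent rows: marker id, then one call per accession.
    marker_type
        ``"snp"`` (calls 0/1/2) or ``"dart"`` (calls 0/1).
    missing_token
        Cell content denoting a missing call; empty cells also count.
    delimiter
        Field separator; inferred from the header when omitted.

    Returns
    -------
    SnpMatrix or DartMatrix with accessions as rows (the file is transposed).
    """
    try:
        cls = _MATRIX_TYPES[marker_type.lower()]
    except KeyError:
        raise ValueError(f"marker_type must be 'snp' or 'dart', got {marker_type!r}")

    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        delim = delimiter or _infer_delimiter(first, path)
        header = next(csv.reader([first], delimiter=delim))
        accession_ids = [h.strip() for h in header[1:]]
        marker_ids: list[str] = []
        rows: list[list[int]] = []
        legal = {str(v) for v in cls.ALPHABET}
        for lineno, rec in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not rec or all(not c.strip() for c in rec):
                continue
            if len(rec) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(rec)}"
                )
            mid = rec[0].strip()
            row = []
            for aid, cell in zip(accession_ids, rec[1:]):
                cell = cell.strip()
                if cell == missing_token or cell == "":
                    row.append(MISSING)
                elif cell in legal:
                    row.append(int(cell))
                else:
                    raise ValueError(
                        f"{path}:{lineno}: invalid call {cell!r} for marker {mid!r}, "
                        f"accession {aid!r} (allowed: {sorted(legal)} or {missing_token!r})"
                    )
            marker_ids.append(mid)
            rows.append(row)

    grid = np.asarray(rows, dtype=np.int16).reshape(len(marker_ids), len(accession_ids))
    return cls(accession_ids, marker_ids, grid.T)


def write_call_matrix(matrix, path, *, missing_token: str = DEFAULT_MISSING_TOKEN,
                      delimiter: str | None = None) -> None:
    """Write a matrix in the marker-per-row layout :func:`read_call_matrix` reads."""
    if delimiter is None:
        delimiter = "\t" if str(path).endswith(".tsv") else ","
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["marker_id", *matrix.accession_ids])
        for j, mid in enumerate(matrix.marker_ids):
            col = matrix.calls[:, j]
            w.writerow([mid] + [missing_token if v == MISSING else str(int(v)) for v in col])


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlastHit:
    """One line of 12-column tabular (outfmt-6 style) BLAST output."""

    query_id: str
    subject_id: str
    identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")
        for name in ("q_start", "q_end", "s_start", "s_end"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 (1-based coordinates)")


def read_blast_tabular(path) -> list[BlastHit]:
    """Parse 12-column tab-separated BLAST hits, preserving file order."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                hits.append(BlastHit(
                    query_id=parts[0], subject_id=parts[1],
                    identity=float(parts[2]), align_len=int(parts[3]),
                    mismatches=int(parts[4]), gap_opens=int(parts[5]),
                    q_start=int(parts[6]), q_end=int(parts[7]),
                    s_start=int(parts[8]), s_end=int(parts[9]),
                    evalue=float(parts[10]), bitscore=float(parts[11]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# population frame
# ---------------------------------------------------------------------------

MEMBERSHIP_TOL = 1e-6

ROLE_LANDRACE = "landrace"
ROLE_REFERENCE = "reference"
REFERENCE_POPULATION = "Reference"


@dataclass(eq=False)
class PopulationFrame:
    """Accession roles, population assignments and admixture memberships.

    ``memberships`` rows for reference accessions may be NaN: modern varieties
    are not part of the landrace admixture model, they simply carry the
    population label :data:`REFERENCE_POPULATION`.
    """

    accession_ids: list[str]
    roles: list[str]
    populations: list[str]
    memberships: np.ndarray | None = None
    population_labels: list[str] | None = None
    subspecies: list | None = None

    def __post_init__(self):
        self.accession_ids = [str(a) for a in self.accession_ids]
        _check_unique(self.accession_ids, "accession")
        n = len(self.accession_ids)
        if len(self.roles) != n or len(self.populations) != n:
            raise FormatError("roles/populations length does not match accession_ids")
        bad_roles = set(self.roles) - {ROLE_LANDRACE, ROLE_REFERENCE}
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        if self.memberships is not None:
            self.memberships = np.asarray(self.memberships, dtype=float)
            if self.memberships.shape[0] != n:
                raise FormatError("memberships row count does not match accessions")
            for i, role in enumerate(self.roles):
                row = self.memberships[i]
                if role == ROLE_REFERENCE and np.isnan(row).all():
                    continue
                s = float(np.nansum(row))
                if abs(s - 1.0) > MEMBERSHIP_TOL:
                    raise ValueError(
                        f"memberships for accession {self.accession_ids[i]!r} "
                        f"sum to {s!r}, expected 1 within {MEMBERSHIP_TOL}"
                    )
        if self.subspecies is not None and len(self.subspecies) != n:
            raise FormatError("subspecies length does not match accessions")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_memberships(cls, accession_ids, roles, memberships,
                         population_labels=None, subspecies=None) -> "PopulationFrame":
        """Assign each landrace to the population of maximal membership.

        Ties are broken toward the lowest population index so that repeated
        runs are deterministic.
        """
        memberships = np.asarray(memberships, dtype=float)
        k = memberships.shape[1]
        labels = list(population_labels) if population_labels else [f"Pop{i + 1}" for i in range(k)]
        if len(labels) != k:
            raise ValueError("population_labels length does not match membership columns")
        populations = []
        for i, role in enumerate(roles):
            if role == ROLE_REFERENCE:
                populations.append(REFERENCE_POPULATION)
            else:
                row = memberships[i]
                # argmax returns the first (lowest-index) maximum: the tie rule
                populations.append(labels[int(np.argmax(row))])
        return cls(list(accession_ids), list(roles), populations,
                   memberships=memberships, population_labels=labels,
                   subspecies=list(subspecies) if subspecies is not None else None)

    # -- accessors ----------------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def landrace_ids(self) -> list[str]:
        return [a for a, r in zip(self.accession_ids, self.roles) if r == ROLE_LANDRACE]

    @property
    def reference_ids(self) -> list[str]:
        return [a for a, r in zip(self.accession_ids, self.roles) if r == ROLE_REFERENCE]

    def group_labels(self, group_by: str) -> list:
        if group_by == "population":
            return list(self.populations)
        if group_by == "role":
            return list(self.roles)
        if group_by == "subspecies":
            if self.subspecies is None:
                raise ValueError("this frame carries no subspecies annotation")
            return list(self.subspecies)
        raise ValueError(f"group_by must be population/role/subspecies, got {group_by!r}")

    def group_indices(self, group_by: str) -> dict:
        """Map group label -> integer row indices, skipping None labels."""
        out: dict = {}
        for i, lab in enumerate(self.group_labels(group_by)):
            if lab is None:
                continue
            out.setdefault(lab, []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def subset(self, accession_ids) -> "PopulationFrame":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        idx = [pos[a] for a in accession_ids]
        return PopulationFrame(
            [self.accession_ids[i] for i in idx],
            [self.roles[i] for i in idx],
            [self.populations[i] for i in idx],
            memberships=self.memberships[idx] if self.memberships is not None else None,
            population_labels=self.population_labels,
            subspecies=[self.subspecies[i] for i in idx] if self.subspecies is not None else None,
        )

    def landraces_only(self) -> "PopulationFrame":
        return self.subset(self.landrace_ids)


_Q_COL = re.compile(r"^Q(\d+)$")


def read_population_frame(path) -> PopulationFrame:
    """Read an accession metadata table.

    Expected columns: ``accession_id``, ``role``, then either membership
    columns ``Q1..QK`` (population derived by argmax) or a pre-assigned
    ``population`` column.  An optional ``subspecies`` column is carried along.
    """
    df = pd.read_csv(path)
    for col in ("accession_id", "role"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    qcols = sorted((c for c in df.columns if _Q_COL.match(c)),
                   key=lambda c: int(_Q_COL.match(c).group(1)))
    subspecies = df["subspecies"].where(df["subspecies"].notna(), None).tolist() \
        if "subspecies" in df.columns else None
    ids = df["accession_id"].astype(str).tolist()
    roles = df["role"].astype(str).tolist()
    if qcols:
        memberships = df[qcols].to_numpy(dtype=float)
        return PopulationFrame.from_memberships(ids, roles, memberships, subspecies=subspecies)
    if "population" not in df.columns:
        raise FormatError(f"{path}: need membership columns Q1..QK or a 'population' column")
    return PopulationFrame(ids, roles, df["population"].astype(str).tolist(),
                           subspecies=subspecies)


def write_population_frame(frame: PopulationFrame, path) -> None:
    data = {"accession_id": frame.accession_ids, "role": frame.roles,
            "population": frame.populations}
    if frame.subspecies is not None:
        data["subspecies"] = frame.subspecies
    if frame.memberships is not None:
        for j in range(frame.memberships.shape[1]):
            data[f"Q{j + 1}"] = frame.memberships[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# region calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionCall:
    """A genomic interval monomorphic in reference varieties but diverse in
    landraces.  Coordinates are 1-based inclusive (reference-genome
    convention); conversion to BED happens only in :func:`write_regions`."""

    chromosome: str
    start_bp: int
    end_bp: int
    n_ref_zero: int
    n_landrace_diverse: int
    genes: tuple = ()

    def __post_init__(self):
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start_bp}-{self.end_bp}"
            )
        if self.n_ref_zero < 0 or self.n_landrace_diverse < 0:
            raise ValueError("supporting marker counts must be non-negative")

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp

    def satisfies_rule(self, min_run: int = 5, min_diverse: int = 5,
                       min_span_bp: int = 5_000_000) -> bool:
        """Check the published fixed-region rule (all inequalities as stated:
        run and diverse counts 'at least', span strictly 'more than')."""
        return (self.n_ref_zero >= min_run
                and self.n_landrace_diverse >= min_diverse
                and self.span_bp > min_span_bp)


_REGION_HEADER = (
    "# fixed-region calls\n"
    "# columns: chrom, bed_start, bed_end, name, n_ref_zero, n_landrace_diverse, span_bp, genes\n"
    "# coordinates: BED 0-based half-open; internally 1-based inclusive\n"
    "#   start_bp = bed_start + 1 ; end_bp = bed_end\n"
)


def write_regions(regions, path) -> None:
    """Write regions as BED (0-based half-open) with supporting counts.

    Input must already be sorted by (chromosome, start); the writer refuses to
    reorder silently.
    """
    keys = [(r.chromosome, r.start_bp) for r in regions]
    if keys != sorted(keys):
        raise ValueError("regions must be sorted by (chromosome, start_bp) before writing")
    with open(path, "w") as fh:
        fh.write(_REGION_HEADER)
        for i, r in enumerate(regions, start=1):
            genes = ",".join(r.genes) if r.genes else "."
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\tregion_{i}"
                     f"\t{r.n_ref_zero}\t{r.n_landrace_diverse}\t{r.span_bp}\t{genes}\n")


def read_regions(path) -> list:
    """Round-trip reader for :func:`write_regions` output."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 8:
                raise FormatError(f"{path}:{lineno}: expected 8 columns, got {len(parts)}")
            genes = () if parts[7] == "." else tuple(parts[7].split(","))
            out.append(RegionCall(
                chromosome=parts[0], start_bp=int(parts[1]) + 1, end_bp=int(parts[2]),
                n_ref_zero=int(parts[4]), n_landrace_diverse=int(parts[5]), genes=genes,
            ))
    return out
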