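"""End-to-end orchestration: qc -> anchor -> diversity -> pcoa -> scan.

The pipeline is a pure function of (inputs, config): all randomness lives in
the synthetic-data generator, so repeated runs with the same inputs produce
byte-identical numeric tables.  Each stage logs its marker accounting so the
filtering history is reconstructible from the logs alone, and the manifest
records input checksums plus every threshold used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anchoring, diversity, ordination, qc, scan as scan_mod
from .io_formats import (read_blast_tabular, read_call_matrix,
                         read_population_frame, write_call_matrix, write_regions)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Inputs and thresholds for one full run."""

    snp_matrix: str
    populations: str
    out_dir: str
    blast_hits: str | None = None
    placements: str | None = None
    marker_type: str = "snp"
    missing_token: str = "-"
    max_missing: float = 0.10
    min_maf: float = 0.05
    e_max: float = 5e-10
    min_identity: float = 90.0
    window_bp: int = 10_000_000
    min_run: int = 5
    min_diverse: int = 5
    hs_diverse_threshold: float = 0.1
    min_span_bp: int = 5_000_000
    group_by: str = "population"
    n_axes: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.max_missing <= 1.0):
            raise ValueError("max_missing must lie in [0, 1]")
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in [0, 0.5]")
        if self.min_identity < 0 or self.min_identity > 100:
            raise ValueError("min_identity must lie in [0, 100]")
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate_paths(self) -> None:
        for name in ("snp_matrix", "populations", "blast_hits", "placements"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: input {name}={p!r} does not exist")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the manifest of produced artifacts."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(key: str, filename: str) -> Path:
        path = out_dir / filename
        artifacts[key] = str(path)
        return path

    # ---- load inputs ------------------------------------------------------
    matrix = _stage("load_matrix", read_call_matrix, config.snp_matrix,
                    config.marker_type, missing_token=config.missing_token)
    frame = _stage("load_populations", read_population_frame, config.populations)
    missing_acc = set(matrix.accession_ids) - set(frame.accession_ids)
    if missing_acc:
        raise PipelineError(
            f"stage 'load_populations' failed: accessions missing from "
            f"{config.populations!r}: {sorted(missing_acc)[:5]}"
        )
    log.info("inputs: %d accessions x %d markers", matrix.n_accessions, matrix.n_markers)

    # ---- qc ---------------------------------------------------------------
    filtered, report = _stage("qc", qc.run_standard_filter, matrix,
                              max_missing=config.max_missing, min_maf=config.min_maf)
    log.info("qc: %d -> %d markers", matrix.n_markers, filtered.n_markers)
    with open(emit("qc_report", "qc_report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    write_call_matrix(filtered, emit("filtered_matrix", "filtered_matrix.csv"))

    # ---- anchoring --------------------------------------------------------
    placements = None
    if config.placements:
        placements = _stage("anchor", anchoring.PlacementTable.read_tsv, config.placements)
    elif config.blast_hits:
        hits = _stage("anchor", read_blast_tabular, config.blast_hits)
        placements = _stage("anchor", anchoring.place_markers, hits,
                            e_max=config.e_max, min_identity=config.min_identity,
                            marker_ids=matrix.marker_ids)
    if placements is not None:
        placements.write_tsv(emit("placements", "placements.tsv"))
        summary = anchoring.chromosome_summary(placements, matrix.marker_ids)
        log.info("anchor: %d located / %d not located", summary.located, summary.not_located)

    # ---- diversity (landrace populations only) ----------------------------
    land_ids = [a for a in filtered.accession_ids if a in set(frame.landrace_ids)]
    land_matrix = filtered.subset_accessions(land_ids)
    land_frame = frame.subset(land_ids)
    table = _stage("diversity", diversity.diversity_table, land_matrix, land_frame,
                   group_by=config.group_by)
    fst = _stage("diversity", diversity.pairwise_fst, land_matrix, land_frame,
                 group_by=config.group_by)
    div_df = table.to_frame()
    div_df.loc[len(div_df)] = ["__Ht_overall__", table.ht_overall]
    div_df.loc[len(div_df)] = ["__Dest__", table.dest]
    div_df.to_csv(emit("diversity_table", "diversity_table.csv"), index=False)
    fst.to_frame().to_csv(emit("fst_matrix", "fst_matrix.csv"))

    # ---- pcoa (whole collection) ------------------------------------------
    dists = _stage("pcoa", ordination.genetic_distance, filtered)
    result = _stage("pcoa", ordination.pcoa, dists, config.n_axes,
                    filtered.accession_ids)
    coords = pd.DataFrame(result.coordinates,
                          index=filtered.accession_ids,
                          columns=[f"PCo{i + 1}" for i in range(result.coordinates.shape[1])])
    coords.insert(0, "population",
                  [frame.populations[frame.accession_ids.index(a)]
                   for a in filtered.accession_ids])
    path = emit("pcoa_coordinates", "pcoa_coordinates.csv")
    with open(path, "w") as fh:
        fh.write("# variance_explained: "
                 + ",".join(f"{v:.6f}" for v in result.variance_explained) + "\n")
        coords.to_csv(fh)

    # ---- fixed-region scan ------------------------------------------------
    if placements is not None:
        scan_matrix, scan_report = _stage("scan", qc.run_standard_filter, matrix,
                                          skip_dedup=True,
                                          max_missing=config.max_missing,
                                          min_maf=config.min_maf)
        located = [m for m in scan_matrix.marker_ids if placements.get(m).located]
        scan_matrix = scan_matrix.subset_markers(located)
        log.info("scan marker set: %d located markers (dedup skipped)",
                 scan_matrix.n_markers)
        track = _stage("scan", scan_mod.build_hs_track, scan_matrix, placements, frame)
        regions = _stage("scan", scan_mod.call_fixed_regions, track,
                         min_run=config.min_run, min_diverse=config.min_diverse,
                         hs_diverse_threshold=config.hs_diverse_threshold,
                         min_span_bp=config.min_span_bp)
        write_regions(regions, emit("regions", "regions.bed"))
        scan_mod.windowed_hs(track, config.window_bp).to_csv(
            emit("windowed_hs", "windowed_hs.csv"), index=False)
        log.info("scan: %d fixed regions called", len(regions))

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "inputs": {name: {"path": p, "sha256": _sha256(p)}
                   for name, p in (("snp_matrix", config.snp_matrix),
                                   ("populations", config.populations),
                                   ("blast_hits", config.blast_hits),
                                   ("placements", config.placements))
                   if p is not None},
        "thresholds": {k: v for k, v in asdict(config).items()
                       if k not in ("snp_matrix", "populations", "blast_hits",
                                    "placements", "out_dir")},
        "artifacts": artifacts,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    manifest["manifest_path"] = str(out_dir / "manifest.json")
    return manifest
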