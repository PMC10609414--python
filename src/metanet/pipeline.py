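"""End-to-end pipeline orchestration with a single config and run manifest.

Stages run in order: spectra -> molecular network -> library search ->
annotation -> target prediction -> compound--target network. A stage whose
inputs are absent is skipped and logged. All outputs are written atomically
(temp file + rename) into the output directory, and a JSON manifest records
the effective config and per-stage record counts, so a rerun with identical
config and inputs reproduces the stage outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import shutil
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from metanet import __version__
from metanet.ctnet import (
    build_network,
    export_bipartite,
    import_ppi_table,
    rank_compounds,
    read_disease_list,
)
from metanet.masscalc import (
    build_annotation_table,
    write_annotation_table,
)
from metanet.networking import (
    FAMILY_MAX,
    FRAGMENT_TOL,
    LIBRARY_MIN_MATCHED,
    LIBRARY_SCORE_MIN,
    MIN_MATCHED,
    PRECURSOR_TOL,
    SCORE_MIN,
    TOP_K,
    build_molecular_network,
    export_network,
    library_search,
    pairwise_edges,
)
from metanet.spectra import filter_acquisition, read_mgf, read_mzml, write_mgf
from metanet.targets import (
    DEFAULT_CUTOFF,
    DEFAULT_MAX_TABS,
    DEFAULT_N_BITS,
    DEFAULT_RADIUS,
    FingerprintBitSet,
    fingerprint,
    fingerprint_references,
    global_target_frequencies,
    parse_reference_table,
    predict_targets,
    write_prediction_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths and thresholds of a pipeline run.

    Threshold defaults are the standard molecular-networking and
    target-prediction settings used throughout the package; every field can
    be overridden from a YAML config file or a CLI flag.
    """

    # inputs (any may be None -> the dependent stage is skipped)
    spectra_path: str | None = None
    library_path: str | None = None
    formulas_path: str | None = None
    reference_path: str | None = None
    disease_path: str | None = None
    ppi_path: str | None = None
    query_fingerprints_path: str | None = None
    out_dir: str = "metanet_out"
    # acquisition filter
    mz_min: float = 100.0
    mz_max: float = 1000.0
    min_intensity: float = 5000.0
    # molecular network
    fragment_tol: float = FRAGMENT_TOL
    precursor_tol: float = PRECURSOR_TOL
    score_min: float = SCORE_MIN
    min_matched: int = MIN_MATCHED
    top_k: int = TOP_K
    family_max: int = FAMILY_MAX
    # library matching
    library_score_min: float = LIBRARY_SCORE_MIN
    library_min_matched: int = LIBRARY_MIN_MATCHED
    # target prediction
    cutoff: float = DEFAULT_CUTOFF
    radius: int = DEFAULT_RADIUS
    n_bits: int = DEFAULT_N_BITS
    organism: str = "Homo sapiens"
    max_tabs: int = DEFAULT_MAX_TABS
    fingerprint_backend: str = "rdkit"
    # synthetic generation only
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat: dict[str, Any] = {}
        for key, value in data.items():
            if isinstance(value, dict):
                flat.update(value)  # nested sections are flattened
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of human-readable issues; empty iff the config is valid."""
    issues: list[str] = []
    for name in ("score_min", "library_score_min", "cutoff"):
        v = getattr(cfg, name)
        if not 0.0 <= v <= 1.0:
            issues.append(f"{name} must be in [0,1], got {v}")
    for name in ("fragment_tol", "precursor_tol"):
        if getattr(cfg, name) <= 0:
            issues.append(f"{name} must be > 0")
    for name in ("min_matched", "library_min_matched", "top_k", "family_max", "radius", "n_bits"):
        if getattr(cfg, name) < 1:
            issues.append(f"{name} must be >= 1")
    if not cfg.mz_min < cfg.mz_max:
        issues.append("mz_min must be < mz_max")
    if cfg.min_intensity < 0:
        issues.append("min_intensity must be >= 0")
    if cfg.fingerprint_backend not in ("rdkit", "hex"):
        issues.append(f"fingerprint_backend must be 'rdkit' or 'hex', got {cfg.fingerprint_backend!r}")
    if cfg.reference_path and not cfg.query_fingerprints_path and not cfg.library_path:
        issues.append("target prediction needs query_fingerprints_path (or library hits to derive queries)")
    for name in ("spectra_path", "library_path", "formulas_path", "reference_path", "disease_path", "ppi_path", "query_fingerprints_path"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            issues.append(f"{name} does not exist: {p}")
    return issues


@dataclass
class RunManifest:
    """Per-stage record counts plus the effective config, for reproducibility."""

    config: dict[str, Any] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    stages_run: list[str] = field(default_factory=list)
    stages_skipped: list[str] = field(default_factory=list)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _atomic_write(producer, final_path: Path) -> Path:
    """Run ``producer(tmp_path)`` then atomically rename onto ``final_path``."""
    final_path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=final_path.parent, prefix=".tmp_")
    os.close(fd)
    try:
        producer(Path(tmp))
        os.replace(tmp, final_path)
    except Exception:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return final_path


def _read_query_fingerprints(path: str | Path, cfg: RunConfig) -> dict[str, FingerprintBitSet]:
    """Read query metabolites: TSV of (id, SMILES) or (id, hex bit string)."""
    out: dict[str, FingerprintBitSet] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("id\t"):
                continue
            mid, payload = line.split("\t")[:2]
            if cfg.fingerprint_backend == "hex":
                out[mid] = FingerprintBitSet.from_hex(payload, radius=cfg.radius)
            else:
                out[mid] = fingerprint(payload, radius=cfg.radius, n_bits=cfg.n_bits)
    return out


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute all stages whose inputs are present; returns the manifest.

    Raises on invalid config or stage failure; the manifest written so far
    is flushed to ``<out_dir>/manifest.json`` either way.
    """
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict(), started=_now())
    try:
        _run_stages(cfg, out_dir, manifest)
    finally:
        manifest.finished = _now()
        _atomic_write(
            lambda p: p.write_text(manifest.to_json() + "\n"), out_dir / "manifest.json"
        )
    return manifest


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())


def _run_stages(cfg: RunConfig, out_dir: Path, manifest: RunManifest) -> None:
    coll = None
    if cfg.spectra_path:
        t0 = time.monotonic()
        path = Path(cfg.spectra_path)
        reader = read_mzml if path.suffix.lower() == ".mzml" else read_mgf
        coll = reader(path)
        manifest.counts["spectra_in"] = len(coll)
        coll = filter_acquisition(coll, cfg.mz_min, cfg.mz_max, cfg.min_intensity)
        manifest.counts["spectra_after_filter"] = len(coll)
        _atomic_write(lambda p: write_mgf(coll, p), out_dir / "spectra.filtered.mgf")
        manifest.stages_run.append("spectra")
        logger.info("spectra: %d -> %d after acquisition filter (%.1fs)",
                    manifest.counts["spectra_in"], len(coll), time.monotonic() - t0)
    else:
        manifest.stages_skipped.append("spectra")

    net = None
    if coll is not None and len(coll) >= 2:
        t0 = time.monotonic()
        edges_all = pairwise_edges(coll, cfg.fragment_tol, cfg.score_min, cfg.min_matched)
        manifest.counts["edges_after_score_filter"] = len(edges_all)
        from metanet.networking import cap_family_size, mutual_top_k_filter

        edges_topk = mutual_top_k_filter(edges_all, cfg.top_k)
        manifest.counts["edges_after_top_k"] = len(edges_topk)
        net = cap_family_size(
            edges_topk,
            cfg.family_max,
            node_ids=[s.spectrum_id for s in coll],
            params={
                "fragment_tol": cfg.fragment_tol,
                "score_min": cfg.score_min,
                "min_matched": cfg.min_matched,
                "top_k": cfg.top_k,
                "family_max": cfg.family_max,
            },
        )
        manifest.counts["edges_after_capping"] = len(net.edges)
        manifest.counts["molecular_families"] = len(set(net.family_of.values()))
        manifest.stages_run.append("network")
        logger.info("network: %d nodes, %d edges (%.1fs)", len(net.node_ids), len(net.edges), time.monotonic() - t0)
    else:
        manifest.stages_skipped.append("network")

    hits = []
    if coll is not None and cfg.library_path:
        library = read_mgf(cfg.library_path)
        hits = library_search(
            coll,
            library,
            cfg.precursor_tol,
            cfg.fragment_tol,
            cfg.library_score_min,
            cfg.library_min_matched,
        )
        manifest.counts["library_hits"] = len(hits)
        manifest.stages_run.append("library")
    else:
        manifest.stages_skipped.append("library")

    if net is not None:
        export_network(net, hits, out_dir / "network")

    if hits and cfg.formulas_path:
        formulas = _read_formulas(cfg.formulas_path)
        rts = {s.spectrum_id: s.retention_time for s in coll if s.retention_time is not None}
        records = build_annotation_table(hits, formulas, retention_times=rts)
        manifest.counts["annotations"] = len(records)
        _atomic_write(lambda p: write_annotation_table(records, p), out_dir / "annotations.tsv")
        manifest.stages_run.append("annotation")
    else:
        manifest.stages_skipped.append("annotation")

    results = []
    if cfg.reference_path and cfg.query_fingerprints_path:
        records, stats = parse_reference_table(
            cfg.reference_path, cfg.organism, cfg.max_tabs
        )
        manifest.counts["reference_unique_smiles"] = stats.unique_smiles
        manifest.counts["reference_overlong_dropped"] = stats.overlong_dropped
        manifest.counts["reference_organism_dropped"] = stats.organism_dropped
        ref_fps, excluded = fingerprint_references(
            records, cfg.radius, cfg.n_bits, backend=cfg.fingerprint_backend
        )
        manifest.counts["reference_unconvertible"] = excluded
        queries = _read_query_fingerprints(cfg.query_fingerprints_path, cfg)
        gfreq = global_target_frequencies(records)
        for mid, qfp in queries.items():
            results.append(predict_targets(mid, qfp, ref_fps, cfg.cutoff, gfreq))
        manifest.counts["metabolites_predicted"] = len(results)
        union_targets = set().union(*(r.all_targets for r in results)) if results else set()
        inter = None
        for r in results:
            inter = r.all_targets if inter is None else (inter & r.all_targets)
        manifest.counts["predicted_targets_union"] = len(union_targets)
        manifest.counts["predicted_targets_intersection"] = len(inter or set())
        _atomic_write(lambda p: write_prediction_table(results, p), out_dir / "predictions.tsv")
        manifest.stages_run.append("prediction")
    else:
        manifest.stages_skipped.append("prediction")

    if results and cfg.disease_path:
        disease = read_disease_list(cfg.disease_path)
        ct = build_network(results, disease)
        ranking = rank_compounds(ct)
        ppi = import_ppi_table(cfg.ppi_path) if cfg.ppi_path else None
        export_bipartite(ct, ranking, out_dir / "compound_target", ppi_edges=ppi)
        manifest.counts["ct_compounds"] = len(ct.compound_nodes)
        manifest.counts["ct_targets"] = len(ct.target_nodes)
        manifest.counts["ct_edges"] = len(ct.edges)
        manifest.stages_run.append("ct_network")
    else:
        manifest.stages_skipped.append("ct_network")


def _read_formulas(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV: compound name, molecular formula."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2 and parts[1].strip():
                out[parts[0].strip()] = parts[1].strip()
    return out
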