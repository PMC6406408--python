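"""Run orchestration: configuration loading, manifest, output directory.

Exit statuses distinguish a *gate failure* (a reported scientific outcome:
too few inactivated samples or a bad inactivated/control ratio) from an
actual error, so batch drivers sweeping many gene-dataset pairs can tally
failure causes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .io import PipelineConfig
from .model import GeneLossSignatureModel

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_GATES_FAILED = 3

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a validated config from an optional YAML file plus overrides.

    Override values (command-line flags) win over file values; unknown keys
    in either source are rejected.
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        unknown = set(loaded) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        values.update(loaded)
    overrides = {k: v for k, v in overrides.items() if v is not None}
    unknown = set(overrides) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config option(s) {sorted(unknown)}")
    values.update(overrides)
    if "target_gene" not in values:
        raise ValueError("target_gene is required")
    return PipelineConfig(**values)


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, counts_path, seg_path,
                 mutations_path, loci_path, outdir,
                 inactivation_list_path=None, loci_coords: str = "one-based",
                 compute_mda: bool = True) -> int:
    """Execute the full workflow on local files; returns an exit status.

    Always writes the partition TSV and a run manifest (including on gate
    failure, when downstream stages are skipped); on success also the DE,
    RF and comparison TSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"counts": counts_path, "seg": seg_path, "loci": loci_path}
    if mutations_path:
        inputs["mutations"] = mutations_path
    if inactivation_list_path:
        inputs["inactivation_list"] = inactivation_list_path
    manifest: dict = {
        "tool_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": {k: {"path": str(v), "sha256": _checksum(v)}
                   for k, v in inputs.items()},
        "outputs": {},
        "status": "error",
        "failure_stage": None,
    }
    manifest_path = outdir / "manifest.json"
    stage = "read-inputs"
    try:
        model = GeneLossSignatureModel.from_files(
            counts_path, seg_path, mutations_path, loci_path, config,
            inactivation_list_path=inactivation_list_path,
            loci_coords=loci_coords)
        stage = "fit"
        results = model.fit(compute_mda=compute_mda)
        paths = results.save(outdir)
        manifest["outputs"] = {k: str(p) for k, p in paths.items()}
        manifest["run_summary"] = _jsonable(results.run_summary())
        gate = results.partition.gate_report
        for assignment, count in (("inactivated", gate.n_inactivated),
                                  ("control", gate.n_control)):
            logger.info("%s samples: %d", assignment, count)
        reasons: dict = {}
        for r in results.partition.excluded.values():
            reasons[r] = reasons.get(r, 0) + 1
        for reason, count in sorted(reasons.items()):
            logger.info("excluded (%s): %d", reason, count)
        manifest["excluded_counts"] = reasons
        if not results.gates_passed:
            manifest["status"] = "gates-failed"
            logger.warning("gates failed (%s); downstream analysis skipped",
                           ", ".join(gate.reasons))
            return EXIT_GATES_FAILED
        manifest["status"] = "ok"
        return EXIT_OK
    except Exception as exc:
        manifest["failure_stage"] = stage
        manifest["error"] = str(exc)
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if hasattr(v, "item"):
            v = v.item()
        out[k] = v
    return out
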