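"""File-level orchestration: discover -> score -> combine -> validate, plus simulate.

Each run function reads the on-disk formats defined in :mod:`targetindex.io`,
composes the library stages, writes its artifacts and a deterministic run
manifest (sha256 of every input and output, plus the effective parameters
and seed). Rerunning a command on identical inputs reproduces every output
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import io as tio
from .discovery import TargetIndexDefinition, build_index, correlate_all_probes, select_extremes
from .scoring import combine_indices, read_scores, score_index, write_scores
from .simulate import CovariateConfig, SimConfig, generate_covariates, generate_multi_cohort
from .validation import validate_index

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, command: str, params: dict,
                    inputs: list[Path], outputs: list[Path]) -> Path:
    manifest = {
        "command": command,
        "parameters": params,
        "inputs": {str(p): _sha256(p) for p in sorted(inputs)},
        "outputs": {str(p): _sha256(p) for p in sorted(outputs)},
    }
    path = out_dir / f"{command}_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def run_discover(
    expr_paths: list[str | Path],
    target_probe: str,
    out_path: str | Path,
    fraction: float = 0.01,
    include_target: bool = True,
    format: str = "tabular",
) -> TargetIndexDefinition:
    """Discover a consensus signed index across discovery cohorts."""
    if not (0.0 < fraction < 0.5):
        raise ValueError(f"fraction must be in (0, 0.5), got {fraction}")
    expr_paths = [Path(p) for p in expr_paths]
    per_cohort = []
    for p in expr_paths:
        m = tio.read_expression(p, format=format)
        ct = correlate_all_probes(m, target_probe)
        per_cohort.append(select_extremes(ct, fraction))
    idx = build_index(per_cohort, target_probe, include_target=include_target)
    out_path = Path(out_path)
    idx.to_json(out_path)
    _write_manifest(
        out_path.parent, "discover",
        {"target_probe": target_probe, "fraction": fraction,
         "include_target": include_target, "n_cohorts": len(expr_paths)},
        expr_paths, [out_path],
    )
    logger.info("index: |P|=%d |N|=%d -> %s", len(idx.positive_set), len(idx.negative_set), out_path)
    return idx


def run_score(
    expr_path: str | Path,
    index_path: str | Path,
    out_path: str | Path,
    format: str = "tabular",
    min_coverage: float = 0.5,
):
    """Standardize a cohort and score one index on it."""
    expr_path, index_path, out_path = Path(expr_path), Path(index_path), Path(out_path)
    m = tio.read_expression(expr_path, format=format)
    zm, _ = tio.standardize(m)
    idx = TargetIndexDefinition.from_json(index_path)
    scores = score_index(zm, idx, min_coverage=min_coverage)
    write_scores(scores, out_path)
    _write_manifest(out_path.parent, "score", {"min_coverage": min_coverage},
                    [expr_path, index_path], [out_path])
    return scores


def run_validate(
    expr_path: str | Path,
    clinical_path: str | Path,
    index_paths: list[str | Path],
    out_path: str | Path,
    combine: bool = False,
    combination_rule: str = "sum",
    variance_rule: str = "auto",
    covariates: list[str] | None = None,
    multivariate: bool = False,
    format: str = "tabular",
):
    """Standardize, score one or more indices, optionally combine, validate."""
    expr_path, clinical_path = Path(expr_path), Path(clinical_path)
    index_paths = [Path(p) for p in index_paths]
    out_path = Path(out_path)
    m = tio.read_expression(expr_path, format=format)
    zm, _ = tio.standardize(m)
    clin = tio.read_clinical(clinical_path)
    parts = [score_index(zm, TargetIndexDefinition.from_json(p)) for p in index_paths]
    if combine and len(parts) > 1:
        scores = combine_indices(parts, rule=combination_rule)
    elif len(parts) == 1:
        scores = parts[0]
    else:
        raise ValueError("multiple indices given without --combine")
    report = validate_index(scores, clin, variance_rule=variance_rule,
                            covariates=covariates, multivariate=multivariate)
    report.to_json(out_path)
    _write_manifest(
        out_path.parent, "validate",
        {"combine": combine, "combination_rule": combination_rule,
         "variance_rule": variance_rule, "covariates": covariates or [],
         "multivariate": multivariate},
        [expr_path, clinical_path, *index_paths], [out_path],
    )
    return report


def run_simulate(
    out_dir: str | Path,
    config_path: str | Path | None = None,
    with_covariates: bool = True,
    **overrides,
) -> SimConfig:
    """Generate cohorts to disk with a ground-truth JSON sidecar each."""
    params: dict = {}
    if config_path is not None:
        params.update(yaml.safe_load(Path(config_path).read_text()) or {})
    params.update(overrides)
    for key in ("loading_range", "baseline_mean_range"):
        if key in params:
            params[key] = tuple(params[key])
    cfg = SimConfig(**params)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohorts, truths = generate_multi_cohort(cfg)
    outputs = []
    for (expr, clin), truth in zip(cohorts, truths):
        if with_covariates:
            clin = generate_covariates(cfg, truth, clin, CovariateConfig())
        e = out_dir / f"{expr.cohort_id}_expression.tsv"
        c = out_dir / f"{expr.cohort_id}_clinical.csv"
        g = out_dir / f"{expr.cohort_id}_truth.json"
        tio.write_expression(expr, e)
        tio.write_clinical(clin, c)
        truth.to_json(g)
        outputs += [e, c, g]
    cfg_dict = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()}
    _write_manifest(out_dir, "simulate", cfg_dict, [], outputs)
    return cfg
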