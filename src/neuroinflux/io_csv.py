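"""Reading, validating and writing the four study inputs and result files.

All tabular data travel as comma-delimited UTF-8 CSV with one header row and
region labels in the first column (headerless numeric matrices are also
accepted for connectivity). The study configuration is a YAML key-value
document. Results are CSV tables plus a JSON metadata sidecar; every writer
has a reader that reproduces the values to full stored precision.

File naming convention: ``<cohort_tag>_<subject_tag>_<artifact>.csv``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import (
    Connectome,
    FunctionalVector,
    PathologyMap,
    StudyConfig,
    ValidationReport,
)
from .estimation import SubjectData
from .surrogate import FitResult

__all__ = [
    "read_connectivity",
    "read_regional_table",
    "read_study_config",
    "validate_inputs",
    "align_inputs",
    "write_connectivity",
    "write_regional_table",
    "write_study_config",
    "write_subject_inputs",
    "read_subject_inputs",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

_CONFIG_KEYS = tuple(StudyConfig.__dataclass_fields__)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_connectivity(path) -> Connectome:
    """Read a square nonnegative connectivity matrix.

    Accepts either a labelled CSV (header row + region labels in the first
    column) or a plain numeric matrix without labels (regions are then named
    positionally). Self-connections are zeroed with a logged warning.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = [t.strip() for t in first.strip().split(",") if t.strip() != ""]
    labelled = not all(_is_number(t) for t in tokens)
    if labelled:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        labels = [str(x) for x in df.index]
    else:
        df = pd.read_csv(path, header=None, float_precision="round_trip")
        labels = [f"R{i + 1}" for i in range(df.shape[0])]
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path.name}: connectivity must be square, got "
            f"{df.shape[0]} rows x {df.shape[1]} columns"
        )
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path.name}: non-numeric or non-finite entry at row "
            f"{labels[i]!r}, column {j + 1}"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path.name}: negative weight {values[i, j]} at row "
            f"{labels[i]!r}, column {labels[j]!r}"
        )
    if np.any(np.diag(values) != 0):
        logger.warning(
            "%s: %d nonzero self-connection(s) set to zero",
            path.name, int(np.count_nonzero(np.diag(values))),
        )
        np.fill_diagonal(values, 0.0)
    return Connectome(labels, values)


def read_regional_table(path, kind: str):
    """Read a pathology map (``kind='pathology'``) or functional indicator
    vector (``kind='functional'``); first column holds region labels."""
    if kind not in ("pathology", "functional"):
        raise ValueError("kind must be 'pathology' or 'functional'")
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    labels = [str(x) for x in df.index]
    dupes = sorted({x for x in labels if labels.count(x) > 1})
    if dupes:
        raise ValueError(f"{path.name}: duplicate region label(s) {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        col = numeric.columns[numeric.isna().any()][0]
        row = numeric.index[numeric[col].isna()][0]
        raise ValueError(
            f"{path.name}: non-numeric cell at region {row!r}, column {col!r}"
        )
    if kind == "pathology":
        return PathologyMap(labels, [str(c) for c in df.columns],
                            numeric.to_numpy(dtype=float))
    if numeric.shape[1] != 1:
        raise ValueError(
            f"{path.name}: functional table must have exactly one value "
            f"column, got {numeric.shape[1]}"
        )
    colname = str(df.columns[0]).lower()
    indicator = "fALFF" if "falff" in colname else ("ALFF" if "alff" in colname else "fALFF")
    return FunctionalVector(labels, numeric.to_numpy(dtype=float).ravel(), indicator)


def read_study_config(path) -> StudyConfig:
    """Read a YAML study configuration; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path.name}: expected a key-value document")
    unknown = sorted(set(doc) - set(_CONFIG_KEYS))
    if unknown:
        raise ValueError(
            f"{path.name}: unknown key(s) {unknown}; valid keys: "
            f"{sorted(_CONFIG_KEYS)}"
        )
    if "free_params" in doc and isinstance(doc["free_params"], dict):
        doc["free_params"] = [
            (name, lo, hi) for name, (lo, hi) in doc["free_params"].items()
        ]
    config = StudyConfig(**doc)
    problems = config.validate()
    if problems:
        msgs = "; ".join(m for _, m in problems)
        raise ValueError(f"{path.name}: {msgs}")
    return config


def align_inputs(
    connectome: Connectome,
    pathology: PathologyMap,
    functional: FunctionalVector,
):
    """Reorder the pathology and functional tables to the connectome's region
    order (by label when all three are labelled consistently)."""
    ref = connectome.region_labels
    if set(pathology.region_labels) == set(ref) and set(functional.region_labels) == set(ref):
        p_idx = [pathology.region_labels.index(r) for r in ref]
        f_idx = [functional.region_labels.index(r) for r in ref]
        pathology = PathologyMap(ref, pathology.factor_labels,
                                 pathology.burdens[p_idx])
        functional = FunctionalVector(ref, functional.values[f_idx],
                                      functional.indicator_kind)
    else:
        logger.warning(
            "region labels do not match across inputs; aligning by position"
        )
    return connectome, pathology, functional


def validate_inputs(
    connectome: Connectome,
    pathology: PathologyMap,
    functional: FunctionalVector,
    config: StudyConfig,
) -> ValidationReport:
    """Cross-check the four loaded inputs; all failures are accumulated into
    one report rather than raising on the first."""
    report = ValidationReport()
    n = connectome.n_regions
    if pathology.n_regions != n:
        report.errors.append((
            "regions.count",
            f"region count mismatch: connectome has {n}, pathology has "
            f"{pathology.n_regions}",
        ))
    if functional.n_regions != n:
        report.errors.append((
            "regions.count",
            f"region count mismatch: connectome has {n}, functional has "
            f"{functional.n_regions}",
        ))
    for name, other in (("pathology", pathology.region_labels),
                        ("functional", functional.region_labels)):
        if len(other) == n and set(other) != set(connectome.region_labels):
            report.errors.append((
                "regions.labels",
                f"{name} region labels differ from the connectome's",
            ))
        elif len(other) == n and other != connectome.region_labels:
            report.warnings.append((
                "regions.order",
                f"{name} region order differs from the connectome's "
                "(will be aligned by label)",
            ))
    if not np.allclose(connectome.weights, connectome.weights.T):
        report.warnings.append(
            ("connectome.symmetry", "connectivity matrix is not symmetric")
        )
    if np.any(connectome.weights.sum(axis=1) == 0):
        idx = int(np.argmax(connectome.weights.sum(axis=1) == 0))
        report.warnings.append((
            "connectome.isolated",
            f"region {connectome.region_labels[idx]!r} has no connections",
        ))
    report.errors.extend(config.validate(factor_labels=pathology.factor_labels))
    if config.n_volumes < 8:
        report.errors.append((
            "config.n_volumes",
            f"at least 8 volumes are needed for the spectral indicator, "
            f"got {config.n_volumes}",
        ))
    return report


# --------------------------------------------------------------------------
# writers


def write_connectivity(connectome: Connectome, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(connectome.weights, index=connectome.region_labels,
                      columns=connectome.region_labels)
    df.index.name = "region"
    df.to_csv(path)
    return path


def write_regional_table(obj, path) -> Path:
    path = Path(path)
    if isinstance(obj, PathologyMap):
        df = pd.DataFrame(obj.burdens, index=obj.region_labels,
                          columns=obj.factor_labels)
    elif isinstance(obj, FunctionalVector):
        df = pd.DataFrame({obj.indicator_kind: obj.values},
                          index=obj.region_labels)
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as a regional table")
    df.index.name = "region"
    df.to_csv(path)
    return path


def write_study_config(config: StudyConfig, path) -> Path:
    path = Path(path)
    doc = asdict(config)
    doc["free_params"] = [list(t) for t in doc["free_params"]]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def _prefix(config: StudyConfig) -> str:
    return f"{config.cohort_tag}_{config.subject_tag}"


def write_subject_inputs(subject: SubjectData, out_dir) -> dict[str, Path]:
    """Write a subject's four input files using the naming convention."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = _prefix(subject.config)
    return {
        "connectivity": write_connectivity(
            subject.connectome, out / f"{prefix}_connectivity.csv"),
        "pathology": write_regional_table(
            subject.pathology, out / f"{prefix}_pathology.csv"),
        "functional": write_regional_table(
            subject.functional, out / f"{prefix}_functional.csv"),
        "config": write_study_config(
            subject.config, out / f"{prefix}_config.yaml"),
    }


def read_subject_inputs(
    connectivity_path, pathology_path, functional_path, config_path
) -> SubjectData:
    """Load, align and assemble the four inputs (without validating; call
    :func:`validate_inputs` for the pre-run check)."""
    connectome = read_connectivity(connectivity_path)
    pathology = read_regional_table(pathology_path, "pathology")
    functional = read_regional_table(functional_path, "functional")
    config = read_study_config(config_path)
    connectome, pathology, functional = align_inputs(
        connectome, pathology, functional
    )
    return SubjectData(connectome, pathology, functional, config)


def write_results(fit_result: FitResult, out_dir) -> dict[str, Path]:
    """Write the full outcome of a subject fit.

    Emits the best-parameter table, reconstructed excitability, simulated
    vs observed indicators, the cost trajectory and a JSON metadata sidecar.
    Every file is re-readable via :func:`read_results` at full precision.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    config = fit_result.config_echo or {}
    prefix = f"{config.get('cohort_tag', 'run')}_{config.get('subject_tag', 'subject')}"
    paths: dict[str, Path] = {}

    params = pd.DataFrame(
        {"parameter": fit_result.param_names, "value": fit_result.best_theta}
    )
    paths["parameters"] = out / f"{prefix}_parameters.csv"
    params.to_csv(paths["parameters"], index=False)

    if fit_result.excitability is not None:
        exc_df = pd.DataFrame(
            {"excitability": fit_result.excitability},
            index=fit_result.region_labels,
        )
        exc_df.index.name = "region"
        paths["excitability"] = out / f"{prefix}_excitability.csv"
        exc_df.to_csv(paths["excitability"])

    if fit_result.indicator_sim is not None:
        ind = pd.DataFrame(
            {"observed": fit_result.indicator_obs,
             "simulated": fit_result.indicator_sim},
            index=fit_result.region_labels,
        )
        ind.index.name = "region"
        paths["indicators"] = out / f"{prefix}_indicators.csv"
        ind.to_csv(paths["indicators"])

    hist = pd.DataFrame(
        [
            {"eval_index": r.eval_index, "cost": r.cost,
             **{name: r.theta[i] for i, name in enumerate(fit_result.param_names)}}
            for r in fit_result.records
        ]
    )
    paths["history"] = out / f"{prefix}_history.csv"
    hist.to_csv(paths["history"], index=False)

    meta = {
        "package_version": __version__,
        "seed": fit_result.seed,
        "best_cost": fit_result.best_cost,
        "n_evaluations": fit_result.n_evaluations,
        "converged": fit_result.converged,
        "param_names": fit_result.param_names,
        "config": config,
    }
    paths["metadata"] = out / f"{prefix}_metadata.json"
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2)
    return paths


def read_results(out_dir, prefix: str) -> dict:
    """Read back everything :func:`write_results` wrote for ``prefix``."""
    out = Path(out_dir)
    results: dict = {}
    params = pd.read_csv(out / f"{prefix}_parameters.csv", float_precision="round_trip")
    results["parameters"] = dict(zip(params["parameter"], params["value"]))
    exc_path = out / f"{prefix}_excitability.csv"
    if exc_path.exists():
        results["excitability"] = pd.read_csv(exc_path, index_col=0, float_precision="round_trip")
    ind_path = out / f"{prefix}_indicators.csv"
    if ind_path.exists():
        results["indicators"] = pd.read_csv(ind_path, index_col=0, float_precision="round_trip")
    results["history"] = pd.read_csv(out / f"{prefix}_history.csv", float_precision="round_trip")
    with open(out / f"{prefix}_metadata.json") as fh:
        results["metadata"] = json.load(fh)
    return results
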