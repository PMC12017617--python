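"""Surrogate (radial-basis-function) global optimization with checkpointing.

The optimizer targets expensive black-box objectives: it seeds the search
with a Latin-hypercube design, fits a cubic RBF interpolant with a linear
polynomial tail to all evaluated points, and proposes each next point by
scoring a seeded candidate cloud with a weighted mix of predicted objective
value and distance to previously evaluated points. The exploit weight cycles
through ``{0.3, 0.5, 0.8, 0.95}`` so the search alternates between global
coverage and local refinement.

Every evaluation can be checkpointed to a JSON document; resuming from a
checkpoint reproduces the uninterrupted run's evaluation sequence exactly
(the generator state is stored, and the initial design is derived from the
run seed, not from the evolving generator).
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.optimize import minimize as _local_minimize
from scipy.stats import qmc

from .influence import ParameterSpec

__all__ = [
    "EvaluationRecord",
    "FitResult",
    "CheckpointError",
    "latin_hypercube",
    "fit_rbf_surrogate",
    "propose_candidate",
    "surrogate_optimize",
    "resume_optimization",
]

logger = logging.getLogger(__name__)

_WEIGHT_CYCLE = (0.3, 0.5, 0.8, 0.95)
_CHECKPOINT_FORMAT = "neuroinflux-checkpoint-1"
#: scales (as fractions of each bound width) of the Gaussian perturbation
#: blocks around the incumbent in the candidate cloud
_PERTURB_SCALES = (0.25, 0.05, 0.01, 0.002, 0.0004)
_N_PERTURB = 100   # candidates per perturbation scale
_N_UNIFORM = 200   # uniform candidates
_CONVERGENCE_TOL = 1e-8


class CheckpointError(RuntimeError):
    """Raised for unreadable, corrupted or incompatible checkpoints."""


@dataclass
class EvaluationRecord:
    theta: np.ndarray
    cost: float
    eval_index: int


@dataclass
class FitResult:
    """Outcome of a surrogate-optimization run.

    ``history`` lists the cost of every evaluation in order; ``best_cost`` is
    its minimum. The regional fields are filled by the subject-level fitting
    layer and stay ``None`` for generic objectives.
    """

    param_names: list[str]
    best_theta: np.ndarray
    best_cost: float
    history: list[float]
    records: list[EvaluationRecord]
    n_evaluations: int
    converged: bool
    seed: int
    excitability: np.ndarray | None = None
    indicator_sim: np.ndarray | None = None
    indicator_obs: np.ndarray | None = None
    region_labels: list[str] | None = None
    config_echo: dict | None = None

    @property
    def incumbent(self) -> np.ndarray:
        """Running minimum of the cost history."""
        return np.minimum.accumulate(np.asarray(self.history))


def latin_hypercube(n_points: int, spec: ParameterSpec, seed) -> np.ndarray:
    """Seeded Latin-hypercube design within the spec's box.

    Each non-degenerate dimension is stratified: exactly one point falls in
    each of the ``n_points`` equal-width slabs. Degenerate dimensions
    (lower == upper) are held fixed at their single value.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    sampler = qmc.LatinHypercube(d=spec.dims, seed=seed)
    u = sampler.random(n_points)
    return spec.lowers + u * (spec.uppers - spec.lowers)


def fit_rbf_surrogate(points: np.ndarray, values: np.ndarray):
    """Cubic RBF interpolant with a linear polynomial tail.

    Duplicate points are dropped (keeping the first occurrence, with a
    warning); a tiny smoothing ridge guards conditioning against clusters of
    near-duplicates. Requires at least ``dims + 1`` distinct points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if points.shape[0] != len(values):
        raise ValueError("points and values disagree in length")
    _, keep = np.unique(points, axis=0, return_index=True)
    if len(keep) < len(values):
        warnings.warn(
            f"dropping {len(values) - len(keep)} duplicate sample point(s) "
            "before surrogate fit",
            stacklevel=2,
        )
        keep = np.sort(keep)
        points, values = points[keep], values[keep]
    if points.shape[0] < points.shape[1] + 1:
        raise ValueError(
            f"need at least dims+1={points.shape[1] + 1} distinct points, "
            f"got {points.shape[0]}"
        )
    return RBFInterpolator(
        points, values, kernel="cubic", degree=1, smoothing=1e-12
    )


def _candidate_cloud(
    incumbent: np.ndarray,
    lowers: np.ndarray,
    uppers: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    width = uppers - lowers
    blocks = []
    normals = rng.standard_normal((len(_PERTURB_SCALES) * _N_PERTURB, len(incumbent)))
    for b, scale in enumerate(_PERTURB_SCALES):
        pert = incumbent + normals[b * _N_PERTURB:(b + 1) * _N_PERTURB] * (scale * width)
        blocks.append(pert)
    blocks.append(lowers + rng.random((_N_UNIFORM, len(incumbent))) * width)
    cloud = np.vstack(blocks)
    return np.clip(cloud, lowers, uppers)


def _score_candidates(
    surrogate_values: np.ndarray,
    min_dists: np.ndarray,
    explore_weight: float,
    box_diagonal: float,
) -> np.ndarray:
    """Weighted mix of scaled predicted value and scaled negative distance.

    Values are min-max scaled (their units are arbitrary); distances are
    scaled by the box diagonal so the exploration bonus shrinks naturally as
    the evaluated set fills the box, letting exploitation dominate late on.
    """

    def minmax(x):
        lo, hi = x.min(), x.max()
        return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)

    d_scaled = min_dists / box_diagonal if box_diagonal > 0 else min_dists
    return explore_weight * minmax(surrogate_values) - (1.0 - explore_weight) * d_scaled


def propose_candidate(
    surrogate,
    evaluated_points: np.ndarray,
    spec: ParameterSpec,
    explore_weight: float,
    seed,
) -> np.ndarray:
    """Pick the next evaluation point from a seeded candidate cloud.

    Candidates are Gaussian perturbations of the incumbent best (at several
    scales) plus uniform points, all clipped to the bounds. Each candidate is
    scored ``w * scaled_surrogate - (1 - w) * scaled_nearest_distance`` and
    the minimizer is returned; ``explore_weight`` 0 therefore yields the
    candidate farthest from the evaluated set, 1 the lowest predicted value.
    Already-evaluated points are never returned.
    """
    if not (0.0 <= explore_weight <= 1.0):
        raise ValueError("explore_weight must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = np.atleast_2d(np.asarray(evaluated_points, dtype=float))
    incumbent = pts[int(np.argmin(surrogate(pts)))]
    cloud = _candidate_cloud(incumbent, spec.lowers, spec.uppers, rng)
    # deterministic exploitation candidate: local minimum of the surrogate
    # reached from the incumbent (keeps the cloud's stochastic order intact)
    try:
        loc = _local_minimize(
            lambda x: float(surrogate(x[None, :])), incumbent,
            method="L-BFGS-B", bounds=list(zip(spec.lowers, spec.uppers)),
        )
        if np.all(np.isfinite(loc.x)):
            cloud = np.vstack([cloud, np.clip(loc.x, spec.lowers, spec.uppers)])
    except Exception:  # surrogate minimization is best-effort only
        logger.debug("surrogate local minimization failed", exc_info=True)
    dists = np.linalg.norm(cloud[:, None, :] - pts[None, :, :], axis=2)
    min_dists = dists.min(axis=1)
    fresh = min_dists > 0
    if not fresh.any():  # degenerate box: everything already evaluated
        return cloud[0]
    cloud, min_dists = cloud[fresh], min_dists[fresh]
    diag = float(np.linalg.norm(spec.uppers - spec.lowers))
    score = _score_candidates(np.asarray(surrogate(cloud), dtype=float),
                              min_dists, explore_weight, diag)
    return cloud[int(np.argmin(score))]


def default_initial_design_size(dims: int) -> int:
    return max(2 * dims + 2, 8)


# --------------------------------------------------------------------------
# run state and checkpointing


@dataclass
class _RunState:
    spec: ParameterSpec
    seed: int
    n_init: int
    rng: np.random.Generator
    records: list[EvaluationRecord] = field(default_factory=list)
    config_echo: dict | None = None

    @classmethod
    def fresh(cls, spec, seed, n_init, config_echo=None) -> "_RunState":
        ss = np.random.SeedSequence(seed)
        _, ss_rng = ss.spawn(2)  # first child reserved for the LHS design
        return cls(spec=spec, seed=int(seed), n_init=n_init,
                   rng=np.random.default_rng(ss_rng), config_echo=config_echo)

    def design_seed(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(2)[0])

    def to_json(self) -> dict:
        return {
            "format": _CHECKPOINT_FORMAT,
            "seed": self.seed,
            "n_init": self.n_init,
            "spec": {
                "names": self.spec.names,
                "lowers": self.spec.lowers.tolist(),
                "uppers": self.spec.uppers.tolist(),
            },
            "records": [
                {"eval_index": r.eval_index, "theta": r.theta.tolist(), "cost": r.cost}
                for r in self.records
            ],
            "rng_state": self.rng.bit_generator.state,
            "config_echo": self.config_echo,
        }

    @classmethod
    def from_json(cls, doc: dict) -> "_RunState":
        try:
            if doc["format"] != _CHECKPOINT_FORMAT:
                raise CheckpointError(f"unknown checkpoint format {doc['format']!r}")
            spec = ParameterSpec(doc["spec"]["names"], doc["spec"]["lowers"],
                                 doc["spec"]["uppers"])
            records = [
                EvaluationRecord(theta=np.array(r["theta"], dtype=float),
                                 cost=float(r["cost"]),
                                 eval_index=int(r["eval_index"]))
                for r in doc["records"]
            ]
            rng = np.random.default_rng(0)
            rng.bit_generator.state = doc["rng_state"]
            state = cls(spec=spec, seed=int(doc["seed"]), n_init=int(doc["n_init"]),
                        rng=rng, records=records, config_echo=doc.get("config_echo"))
        except (KeyError, TypeError, ValueError) as exc:
            raise CheckpointError(f"corrupted checkpoint: {exc}") from exc
        idx = [r.eval_index for r in state.records]
        if idx != list(range(len(idx))):
            raise CheckpointError("checkpoint evaluation indices are not contiguous")
        return state

    def save(self, path) -> None:
        tmp = f"{path}.tmp"
        with open(tmp, "w") as fh:
            json.dump(self.to_json(), fh)
        os.replace(tmp, path)

    @classmethod
    def load(cls, path) -> "_RunState":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
        return cls.from_json(doc)


def _result_from_state(state: _RunState) -> FitResult:
    history = [r.cost for r in state.records]
    best = int(np.argmin(history))
    n = len(history)
    incumbent = np.minimum.accumulate(history)
    tail_start = int(np.floor(0.75 * n))
    converged = bool(
        n >= 4 and incumbent[tail_start] - incumbent[-1] <= _CONVERGENCE_TOL
    )
    return FitResult(
        param_names=list(state.spec.names),
        best_theta=state.records[best].theta.copy(),
        best_cost=float(history[best]),
        history=history,
        records=list(state.records),
        n_evaluations=n,
        converged=converged,
        seed=state.seed,
        config_echo=state.config_echo,
    )


def _run(objective, state: _RunState, total_evaluations: int,
         checkpoint_path=None, log_fn=None) -> FitResult:
    spec = state.spec
    free = spec.uppers > spec.lowers
    design = latin_hypercube(state.n_init, spec, seed=state.design_seed())

    if not free.any():
        # zero-volume box: a single admissible point
        if not state.records:
            theta = spec.lowers.copy()
            state.records.append(EvaluationRecord(theta, float(objective(theta)), 0))
            if checkpoint_path:
                state.save(checkpoint_path)
        return _result_from_state(state)

    while len(state.records) < total_evaluations:
        k = len(state.records)
        if k < state.n_init:
            theta = design[k].copy()
        else:
            pts = np.array([r.theta for r in state.records])
            vals = np.array([r.cost for r in state.records])
            rbf = fit_rbf_surrogate(pts[:, free], vals)
            surrogate = lambda X: rbf(np.atleast_2d(X)[:, free])  # noqa: E731
            weight = _WEIGHT_CYCLE[(k - state.n_init) % len(_WEIGHT_CYCLE)]
            theta = propose_candidate(surrogate, pts, spec, weight, state.rng)
        cost = float(objective(theta))
        state.records.append(EvaluationRecord(theta, cost, k))
        if checkpoint_path:
            state.save(checkpoint_path)
        if log_fn is not None:
            inc = min(r.cost for r in state.records)
            log_fn(k, cost, inc)
    return _result_from_state(state)


def surrogate_optimize(
    objective,
    spec: ParameterSpec,
    max_evaluations: int,
    seed: int = 0,
    checkpoint_path=None,
    config_echo: dict | None = None,
    log_fn=None,
) -> FitResult:
    """Minimize ``objective`` over the spec's box with at most
    ``max_evaluations`` evaluations.

    The run starts from a Latin-hypercube design of
    ``max(2 * dims + 2, 8)`` points (capped at the budget), then iterates
    surrogate fit / candidate proposal / evaluation. When
    ``checkpoint_path`` is given, a resumable JSON checkpoint is rewritten
    after every evaluation.
    """
    if max_evaluations < 1:
        raise ValueError("max_evaluations must be >= 1")
    n_init = min(default_initial_design_size(spec.dims), max_evaluations)
    state = _RunState.fresh(spec, seed, n_init, config_echo=config_echo)
    return _run(objective, state, max_evaluations, checkpoint_path, log_fn)


def resume_optimization(
    checkpoint_path,
    objective,
    additional_evaluations: int,
    spec: ParameterSpec | None = None,
    log_fn=None,
) -> FitResult:
    """Continue an interrupted run from its checkpoint.

    A run of N evaluations split as N1 + resume(N - N1) reproduces the
    uninterrupted run's evaluation history bit-identically. When ``spec`` is
    given it is cross-checked against the checkpoint and a mismatch refused.
    Resuming with ``additional_evaluations=0`` returns the current result
    unchanged.
    """
    if additional_evaluations < 0:
        raise ValueError("additional_evaluations must be >= 0")
    state = _RunState.load(checkpoint_path)
    if spec is not None:
        same = (
            spec.names == state.spec.names
            and np.array_equal(spec.lowers, state.spec.lowers)
            and np.array_equal(spec.uppers, state.spec.uppers)
        )
        if not same:
            raise CheckpointError(
                "checkpoint was created for a different parameter spec "
                f"({state.spec.names} with bounds "
                f"{list(zip(state.spec.lowers, state.spec.uppers))})"
            )
    if not state.records:
        raise CheckpointError("checkpoint contains no evaluations")
    total = len(state.records) + additional_evaluations
    return _run(objective, state, total, checkpoint_path, log_fn)
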