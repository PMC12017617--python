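"""Subject-level estimation of pathological influence coefficients.

The objective maps a free-parameter vector to model overrides, simulates the
coupled neural populations with pathology-modulated excitability, converts
activity to BOLD, computes the per-region spectral indicator (fALFF or ALFF)
and returns its mean squared difference from the subject's observed regional
indicator. One noise realization per subject — drawn from the study seed —
is shared across all evaluations (common random numbers), so the
optimization landscape is deterministic and the generating parameters of a
noise-free synthetic subject score exactly zero.

:class:`PathologyInfluenceModel` wraps the pipeline as a scikit-learn style
regressor: ``X`` is the regions x factors burden matrix, ``y`` the observed
regional indicator, and the fitted attributes expose the influence
coefficients and reconstructed excitability.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import Connectome, FunctionalVector, PathologyMap, StudyConfig
from .forward import (
    HemoParams,
    IntegrationError,
    NeuralModelParams,
    bold_forward,
    simulate_neural,
)
from .indicators import Band, alff_columns, falff_columns
from .influence import (
    InfluenceParams,
    ParameterSpec,
    apply_influence,
    map_free_vector,
)
from .surrogate import FitResult, resume_optimization, surrogate_optimize

__all__ = [
    "SubjectData",
    "PENALTY_COST",
    "DEFAULT_ALPHA_BOUNDS",
    "DEFAULT_COUPLING_BOUNDS",
    "default_free_params",
    "default_assignment",
    "subject_noise",
    "simulate_indicator",
    "build_objective",
    "fit_subject",
    "resume_subject",
    "PathologyInfluenceModel",
]

logger = logging.getLogger(__name__)

#: Finite cost returned (and logged) when a simulation diverges, so a single
#: pathological parameter combination cannot abort a whole fit.
PENALTY_COST = 1e6

#: Default optimization interval per influence coefficient. The interval is
#: deliberately narrow and nonnegative: burdens are taken to raise the
#: excitatory drive (the hyperexcitability regime), and narrow intervals keep
#: every region's drive inside the dynamical regime the baseline was chosen
#: for, which also keeps the fitting landscape well behaved.
DEFAULT_ALPHA_BOUNDS = (0.0, 0.2)
#: Default interval for the global coupling scalar (connectome normalized to
#: unit maximum row sum).
DEFAULT_COUPLING_BOUNDS = (0.0, 1.0)


@dataclass
class SubjectData:
    """The four aligned inputs describing one subject."""

    connectome: Connectome
    pathology: PathologyMap
    functional: FunctionalVector
    config: StudyConfig


def default_free_params(factor_labels) -> list[tuple[str, float, float]]:
    """One influence coefficient per factor plus the global coupling."""
    free = [(f"alpha_{f}", *DEFAULT_ALPHA_BOUNDS) for f in factor_labels]
    free.append(("G_coupling", *DEFAULT_COUPLING_BOUNDS))
    return free


def default_assignment(
    factor_labels, neural: NeuralModelParams
) -> dict[str, float]:
    """Complete named parameter assignment at model defaults (alphas zero)."""
    assignment = {f"alpha_{f}": 0.0 for f in factor_labels}
    assignment["baseline"] = neural.P_baseline
    assignment["G_coupling"] = neural.G_coupling
    assignment["noise_sd"] = neural.noise_sd
    return assignment


def subject_noise(config: StudyConfig, n_regions: int) -> np.ndarray:
    """The subject's standard-normal state-noise realization.

    Drawn once from ``config.seed`` and reused by every objective evaluation
    and by the synthetic-data generator, guaranteeing that simulating at the
    generating parameters reproduces the observation bit-for-bit.
    """
    n_steps = int(round(config.duration / config.dt))
    rng = np.random.default_rng(config.seed)
    return rng.standard_normal((n_steps, 2 * n_regions))


def _influence_from_assignment(
    assignment: dict[str, float], factor_labels
) -> InfluenceParams:
    alphas = np.array([assignment[f"alpha_{f}"] for f in factor_labels])
    return InfluenceParams(baseline=assignment["baseline"], alphas=alphas)


def simulate_indicator(
    connectome: Connectome,
    pathology: PathologyMap,
    assignment: dict[str, float],
    config: StudyConfig,
    neural: NeuralModelParams | None = None,
    hemo: HemoParams | None = None,
    noise: np.ndarray | None = None,
    return_bold: bool = False,
):
    """Forward-simulate one subject and return the regional indicator vector.

    This single code path serves both the fitting objective and the
    synthetic-data generator.
    """
    neural = neural or NeuralModelParams()
    hemo = hemo or HemoParams()
    params = neural.with_overrides(assignment)
    influence = _influence_from_assignment(assignment, pathology.factor_labels)
    excitability = apply_influence(influence, pathology)
    trace = simulate_neural(
        params, connectome, excitability, config.duration, config.dt,
        seed=config.seed, noise=noise,
    )
    bold = bold_forward(trace, hemo, config.TR, config.n_volumes, config.burn_in)
    band = Band(config.band_low, config.band_high)
    if config.indicator_kind == "fALFF":
        vec = falff_columns(bold.signals, config.TR, band)
    else:
        vec = alff_columns(bold.signals, config.TR, band)
    if return_bold:
        return vec, bold
    return vec


def _cost(sim: np.ndarray, obs: np.ndarray, metric: str) -> float:
    if metric == "corr":
        if np.std(sim) == 0 or np.std(obs) == 0:
            return 2.0  # maximal correlation distance for degenerate vectors
        return float(1.0 - np.corrcoef(sim, obs)[0, 1])
    return float(np.mean((sim - obs) ** 2))


def build_objective(
    subject: SubjectData,
    neural: NeuralModelParams | None = None,
    hemo: HemoParams | None = None,
    spec: ParameterSpec | None = None,
):
    """Return ``(objective, spec, defaults)`` for a subject.

    The objective is deterministic in theta (fixed per-subject noise) and
    returns :data:`PENALTY_COST` instead of raising when a simulation
    diverges.
    """
    neural = neural or NeuralModelParams()
    hemo = hemo or HemoParams()
    if spec is None:
        free = subject.config.free_params or default_free_params(
            subject.pathology.factor_labels
        )
        spec = ParameterSpec.from_config_list(free)
    defaults = default_assignment(subject.pathology.factor_labels, neural)
    observed = subject.functional.values
    noise = (
        subject_noise(subject.config, subject.connectome.n_regions)
        if subject.config.noise_sd > 0 or "noise_sd" in spec.names
        else None
    )

    def objective(theta: np.ndarray) -> float:
        assignment = map_free_vector(theta, spec, defaults)
        try:
            sim = simulate_indicator(
                subject.connectome, subject.pathology, assignment,
                subject.config, neural, hemo, noise=noise,
            )
        except IntegrationError as exc:
            logger.warning("simulation diverged at theta=%s: %s", theta, exc)
            return PENALTY_COST
        return _cost(sim, observed, subject.config.cost_metric)

    return objective, spec, defaults


def _finalize(
    result: FitResult,
    subject: SubjectData,
    neural: NeuralModelParams,
    hemo: HemoParams,
    spec: ParameterSpec,
    defaults: dict[str, float],
) -> FitResult:
    assignment = map_free_vector(result.best_theta, spec, defaults)
    influence = _influence_from_assignment(assignment, subject.pathology.factor_labels)
    excitability = apply_influence(influence, subject.pathology)
    noise = (
        subject_noise(subject.config, subject.connectome.n_regions)
        if subject.config.noise_sd > 0
        else None
    )
    sim = simulate_indicator(
        subject.connectome, subject.pathology, assignment, subject.config,
        neural, hemo, noise=noise,
    )
    return replace(
        result,
        excitability=excitability,
        indicator_sim=sim,
        indicator_obs=subject.functional.values.copy(),
        region_labels=list(subject.connectome.region_labels),
        config_echo=asdict(subject.config),
    )


def fit_subject(
    subject: SubjectData,
    neural: NeuralModelParams | None = None,
    hemo: HemoParams | None = None,
    max_evaluations: int | None = None,
    seed: int | None = None,
    checkpoint_path=None,
    log_fn=None,
) -> FitResult:
    """Estimate a subject's influence coefficients by surrogate optimization.

    ``seed`` controls the optimizer's sampling; the simulation noise inside
    the objective is governed by ``subject.config.seed`` and is unaffected.
    """
    neural = neural or NeuralModelParams()
    hemo = hemo or HemoParams()
    objective, spec, defaults = build_objective(subject, neural, hemo)
    result = surrogate_optimize(
        objective,
        spec,
        max_evaluations=max_evaluations or subject.config.max_evaluations,
        seed=subject.config.seed if seed is None else seed,
        checkpoint_path=checkpoint_path,
        config_echo=asdict(subject.config),
        log_fn=log_fn,
    )
    return _finalize(result, subject, neural, hemo, spec, defaults)


def resume_subject(
    checkpoint_path,
    subject: SubjectData,
    additional_evaluations: int,
    neural: NeuralModelParams | None = None,
    hemo: HemoParams | None = None,
    log_fn=None,
) -> FitResult:
    """Continue an interrupted subject fit from its checkpoint."""
    neural = neural or NeuralModelParams()
    hemo = hemo or HemoParams()
    objective, spec, defaults = build_objective(subject, neural, hemo)
    result = resume_optimization(
        checkpoint_path, objective, additional_evaluations, spec=spec,
        log_fn=log_fn,
    )
    return _finalize(result, subject, neural, hemo, spec, defaults)


class PathologyInfluenceModel(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator of pathological influences on excitability.

    Parameters
    ----------
    connectome : Connectome or (n_regions, n_regions) array
        Anatomical connectivity of the subject's parcellation.
    config : StudyConfig, optional
        Acquisition and simulation settings; defaults describe a TR 2 s,
        150-volume resting-state protocol.
    factor_labels : sequence of str, optional
        Names of the pathology factors (columns of ``X``); defaults to
        ``f0, f1, ...``.
    free_params : list of (name, lower, upper), optional
        Overrides the free-parameter set; default is one ``alpha_<factor>``
        per factor plus ``G_coupling``.
    neural_params, hemo_params : optional
        Override the population-model and hemodynamic defaults.
    max_evaluations, seed, checkpoint_path : optional
        Optimizer budget, seed and checkpoint location.

    Attributes
    ----------
    coef_ : ndarray of shape (n_factors,)
        Fitted influence coefficients (alphas), zero for factors whose
        coefficient was not free.
    excitability_ : ndarray of shape (n_regions,)
        Reconstructed regional excitatory drive at the fitted parameters.
    result_ : FitResult
        Full optimization outcome (history, records, convergence flag).

    Examples
    --------
    >>> model = PathologyInfluenceModel(connectome, config=config)
    >>> model.fit(burdens, observed_falff)      # doctest: +SKIP
    >>> model.coef_                             # doctest: +SKIP
    """

    def __init__(
        self,
        connectome=None,
        config=None,
        factor_labels=None,
        free_params=None,
        neural_params=None,
        hemo_params=None,
        max_evaluations=None,
        seed=None,
        checkpoint_path=None,
    ):
        self.connectome = connectome
        self.config = config
        self.factor_labels = factor_labels
        self.free_params = free_params
        self.neural_params = neural_params
        self.hemo_params = hemo_params
        self.max_evaluations = max_evaluations
        self.seed = seed
        self.checkpoint_path = checkpoint_path

    def _subject(self, X, y=None) -> SubjectData:
        X = check_array(X, ensure_2d=True, dtype=float)
        if self.connectome is None:
            raise ValueError("a connectome is required; pass it to the constructor")
        conn = self.connectome
        if not isinstance(conn, Connectome):
            conn = np.asarray(conn, dtype=float)
            labels = [f"R{i + 1}" for i in range(conn.shape[0])]
            conn = Connectome(labels, conn)
        if X.shape[0] != conn.n_regions:
            raise ValueError(
                f"X has {X.shape[0]} regions but connectome has {conn.n_regions}"
            )
        factors = (
            list(self.factor_labels)
            if self.factor_labels is not None
            else [f"f{i}" for i in range(X.shape[1])]
        )
        config = self.config or StudyConfig()
        if self.free_params is not None:
            config = config.copy(free_params=list(self.free_params))
        if self.max_evaluations is not None:
            config = config.copy(max_evaluations=int(self.max_evaluations))
        pathology = PathologyMap(conn.region_labels, factors, X)
        if y is None:
            y = np.zeros(conn.n_regions)
            kind = "ALFF"  # placeholder vector for predict-only paths
        else:
            y = np.asarray(y, dtype=float).ravel()
            if len(y) != conn.n_regions:
                raise ValueError("y length does not match the number of regions")
            kind = config.indicator_kind
        functional = FunctionalVector(conn.region_labels, y, kind)
        return SubjectData(conn, pathology, functional, config)

    def fit(self, X, y):
        """Fit influence coefficients to an observed regional indicator.

        Parameters
        ----------
        X : array of shape (n_regions, n_factors)
            Regional pathological burdens.
        y : array of shape (n_regions,)
            Observed regional indicator (fALFF by default).
        """
        subject = self._subject(X, y)
        self.n_features_in_ = subject.pathology.n_factors
        result = fit_subject(
            subject,
            neural=self.neural_params,
            hemo=self.hemo_params,
            seed=self.seed,
            checkpoint_path=self.checkpoint_path,
        )
        assignment = map_free_vector(
            result.best_theta,
            ParameterSpec(result.param_names,
                          *_bounds_from(result, subject)),
            default_assignment(subject.pathology.factor_labels,
                               self.neural_params or NeuralModelParams()),
        )
        self.result_ = result
        self.assignment_ = assignment
        self.coef_ = np.array(
            [assignment[f"alpha_{f}"] for f in subject.pathology.factor_labels]
        )
        self.intercept_ = assignment["baseline"]
        self.coupling_ = assignment["G_coupling"]
        self.best_theta_ = result.best_theta
        self.best_cost_ = result.best_cost
        self.history_ = list(result.history)
        self.excitability_ = result.excitability
        self.indicator_sim_ = result.indicator_sim
        self.n_evaluations_ = result.n_evaluations
        self.converged_ = result.converged
        self._fit_subject_data = subject
        return self

    def predict(self, X):
        """Simulated regional indicator for burdens ``X`` at the fitted
        parameters (deterministic given the study seed)."""
        check_is_fitted(self, "assignment_")
        subject = self._subject(X)
        missing = [
            f for f in subject.pathology.factor_labels
            if f"alpha_{f}" not in self.assignment_
        ]
        if missing:
            raise ValueError(f"no fitted coefficient for factor(s) {missing}")
        config = self._fit_subject_data.config
        noise = (
            subject_noise(config, subject.connectome.n_regions)
            if config.noise_sd > 0
            else None
        )
        return simulate_indicator(
            subject.connectome, subject.pathology, self.assignment_, config,
            self.neural_params, self.hemo_params, noise=noise,
        )


def _bounds_from(result: FitResult, subject: SubjectData):
    free = subject.config.free_params or default_free_params(
        subject.pathology.factor_labels
    )
    by_name = {n: (lo, hi) for n, lo, hi in free}
    lowers = [by_name[n][0] for n in result.param_names]
    uppers = [by_name[n][1] for n in result.param_names]
    return lowers, uppers
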