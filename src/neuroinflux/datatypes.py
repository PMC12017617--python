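"""Core in-memory containers shared across the package.

All regional structures (connectome, pathology map, functional vector) carry
an ordered list of region labels; after loading through :mod:`neuroinflux.io_csv`
they share a single label ordering, so downstream code indexes by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Connectome",
    "PathologyMap",
    "FunctionalVector",
    "StudyConfig",
    "ValidationReport",
    "RECOGNIZED_PARAM_NAMES",
]

#: Free-parameter names the model recognizes besides per-factor influence
#: coefficients (which are spelled ``alpha_<factor>``).
RECOGNIZED_PARAM_NAMES = ("baseline", "G_coupling", "noise_sd")


def _as_float_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    return arr


@dataclass
class Connectome:
    """Anatomical connectivity between brain regions.

    ``weights[i, j]`` is the connection strength from region ``j`` to region
    ``i`` (symmetric for diffusion-MRI-derived matrices, but symmetry is not
    required). Units are arbitrary (streamline counts, densities, ...); the
    forward model rescales the matrix before use.
    """

    region_labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.region_labels = [str(r) for r in self.region_labels]
        self.weights = _as_float_matrix(self.weights, "connectome weights")
        n = len(self.region_labels)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"connectome must be square with one row per region label: "
                f"got shape {self.weights.shape} for {n} labels"
            )
        if not np.all(np.isfinite(self.weights)):
            i, j = np.argwhere(~np.isfinite(self.weights))[0]
            raise ValueError(f"non-finite connectome entry at ({i}, {j})")
        if np.any(self.weights < 0):
            i, j = np.argwhere(self.weights < 0)[0]
            raise ValueError(
                f"negative connectome weight at row {self.region_labels[i]!r}, "
                f"column {self.region_labels[j]!r}"
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def normalized(self) -> np.ndarray:
        """Weights divided by the maximum row sum (so the global coupling
        scalar G has a bounded, interpretable effect)."""
        s = self.weights.sum(axis=1).max()
        if s <= 0:
            return self.weights.copy()
        return self.weights / s


@dataclass
class PathologyMap:
    """Regional burdens of one or more pathological factors (e.g. amyloid-beta
    and tau SUVR-like values), regions x factors."""

    region_labels: list[str]
    factor_labels: list[str]
    burdens: np.ndarray

    def __post_init__(self) -> None:
        self.region_labels = [str(r) for r in self.region_labels]
        self.factor_labels = [str(f) for f in self.factor_labels]
        self.burdens = _as_float_matrix(self.burdens, "pathology burdens")
        if len(self.factor_labels) < 1:
            raise ValueError("pathology map needs at least one factor")
        expected = (len(self.region_labels), len(self.factor_labels))
        if self.burdens.shape != expected:
            raise ValueError(
                f"burdens shape {self.burdens.shape} does not match "
                f"{expected} (regions x factors)"
            )
        if not np.all(np.isfinite(self.burdens)):
            raise ValueError("pathology burdens contain non-finite values")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_factors(self) -> int:
        return len(self.factor_labels)


@dataclass
class FunctionalVector:
    """Observed regional functional indicator (fALFF or ALFF)."""

    region_labels: list[str]
    values: np.ndarray
    indicator_kind: str = "fALFF"

    def __post_init__(self) -> None:
        self.region_labels = [str(r) for r in self.region_labels]
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.indicator_kind not in ("fALFF", "ALFF"):
            raise ValueError(
                f"indicator_kind must be 'fALFF' or 'ALFF', got {self.indicator_kind!r}"
            )
        if len(self.values) != len(self.region_labels):
            raise ValueError("functional vector length does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("functional indicator contains non-finite values")
        if self.indicator_kind == "fALFF" and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            bad = np.argwhere((self.values < 0) | (self.values > 1)).ravel()[0]
            raise ValueError(
                f"fALFF value {self.values[bad]} for region "
                f"{self.region_labels[bad]!r} outside [0, 1]"
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


@dataclass
class StudyConfig:
    """Acquisition parameters, simulation settings and optimization constraints.

    Parameters
    ----------
    TR : float
        fMRI repetition time in seconds; sets the Nyquist limit 1/(2 TR).
    n_volumes : int
        Number of fMRI volumes to simulate and use for the indicator.
    band_low, band_high : float
        Frequency band (Hz) for ALFF/fALFF; default 0.01-0.08 Hz, the
        standard low-frequency fluctuation band.
    dt : float
        Integration step in seconds for the neural and hemodynamic equations.
    burn_in : float
        Initial simulated seconds discarded before BOLD sampling.
    noise_sd : float
        Standard deviation of the additive state noise driving the neural
        populations (per sqrt-second).
    free_params : list of (name, lower, upper)
        Parameters the optimizer may vary; names are ``alpha_<factor>``,
        ``baseline``, ``G_coupling`` or ``noise_sd``.
    max_evaluations : int
        Objective-evaluation budget for the surrogate optimizer.
    seed : int
        Seed for the subject's simulation noise (shared across objective
        evaluations, so the optimization landscape is deterministic).
    cost_metric : str
        ``"mse"`` (default) or ``"corr"`` (one minus Pearson correlation).
    """

    TR: float = 2.0
    n_volumes: int = 150
    band_low: float = 0.01
    band_high: float = 0.08
    dt: float = 0.002
    burn_in: float = 30.0
    noise_sd: float = 0.01
    free_params: list[tuple[str, float, float]] = field(default_factory=list)
    max_evaluations: int = 150
    seed: int = 0
    cost_metric: str = "mse"
    indicator_kind: str = "fALFF"
    cohort_tag: str = "cohort"
    subject_tag: str = "subject"

    def __post_init__(self) -> None:
        self.free_params = [
            (str(n), float(lo), float(hi)) for n, lo, hi in self.free_params
        ]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.TR)

    @property
    def duration(self) -> float:
        """Total simulated seconds: burn-in plus the sampled acquisition."""
        return self.burn_in + self.n_volumes * self.TR

    def validate(self, factor_labels: Sequence[str] | None = None) -> list[tuple[str, str]]:
        """Return a list of ``(code, message)`` problems; empty when valid."""
        errors: list[tuple[str, str]] = []
        if self.TR <= 0:
            errors.append(("config.TR", f"TR must be > 0 s, got {self.TR}"))
        if self.n_volumes < 1:
            errors.append(("config.n_volumes", f"n_volumes must be >= 1, got {self.n_volumes}"))
        if self.dt <= 0:
            errors.append(("config.dt", f"dt must be > 0 s, got {self.dt}"))
        if self.burn_in < 0:
            errors.append(("config.burn_in", f"burn_in must be >= 0 s, got {self.burn_in}"))
        if self.noise_sd < 0:
            errors.append(("config.noise_sd", f"noise_sd must be >= 0, got {self.noise_sd}"))
        if self.max_evaluations < 1:
            errors.append(("config.max_evaluations",
                           f"max_evaluations must be >= 1, got {self.max_evaluations}"))
        if self.TR > 0:
            if not (0 < self.band_low < self.band_high):
                errors.append(("config.band",
                               f"need 0 < band_low < band_high, got "
                               f"[{self.band_low}, {self.band_high}]"))
            elif self.band_high >= self.nyquist:
                errors.append(("config.band",
                               f"band_high {self.band_high} Hz >= Nyquist "
                               f"{self.nyquist} Hz for TR={self.TR} s"))
        if self.cost_metric not in ("mse", "corr"):
            errors.append(("config.cost_metric",
                           f"cost_metric must be 'mse' or 'corr', got {self.cost_metric!r}"))
        if self.indicator_kind not in ("fALFF", "ALFF"):
            errors.append(("config.indicator_kind",
                           f"indicator_kind must be 'fALFF' or 'ALFF', "
                           f"got {self.indicator_kind!r}"))
        seen: set[str] = set()
        for name, lo, hi in self.free_params:
            if name in seen:
                errors.append(("config.free_params", f"duplicate free parameter {name!r}"))
            seen.add(name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                errors.append(("config.free_params", f"non-finite bounds for {name!r}"))
            elif lo > hi:
                errors.append(("config.free_params",
                               f"lower bound {lo} > upper bound {hi} for {name!r}"))
            if not _param_name_ok(name, factor_labels):
                valid = list(RECOGNIZED_PARAM_NAMES) + ["alpha_<factor>"]
                errors.append(("config.free_params",
                               f"unrecognized free parameter {name!r}; valid: {valid}"))
        return errors

    def copy(self, **changes) -> "StudyConfig":
        return replace(self, **changes)


def _param_name_ok(name: str, factor_labels: Sequence[str] | None) -> bool:
    if name in RECOGNIZED_PARAM_NAMES:
        return True
    if name.startswith("alpha_"):
        if factor_labels is None:
            return True  # factor set unknown at config-parse time
        return name[len("alpha_"):] in factor_labels
    return False


@dataclass
class ValidationReport:
    """Accumulated outcome of the pre-run input checks."""

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = []
        for code, msg in self.errors:
            lines.append(f"ERROR   [{code}] {msg}")
        for code, msg in self.warnings:
            lines.append(f"WARNING [{code}] {msg}")
        if not lines:
            lines = ["all checks passed"]
        return "\n".join(lines)
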