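"""Linear pathological-influence law and free-parameter plumbing.

The model assumes regional burdens of each pathological factor shift a
neuronal excitability parameter linearly and additively:

    a_i = baseline + sum_f alpha_f * q_{i,f}

where ``q_{i,f}`` is the burden of factor ``f`` in region ``i`` and the
``alpha_f`` are subject-level influence coefficients shared across regions.
The modulated parameter is the external drive to each region's excitatory
population (see :mod:`neuroinflux.forward`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import PathologyMap, RECOGNIZED_PARAM_NAMES

__all__ = [
    "InfluenceParams",
    "ParameterSpec",
    "apply_influence",
    "map_free_vector",
    "pack_free_vector",
]


@dataclass
class InfluenceParams:
    """Baseline excitability plus one influence coefficient per factor.

    ``alphas`` is ordered like the factor labels of the pathology map it is
    applied to; units are excitability units per burden unit.
    """

    baseline: float
    alphas: np.ndarray

    def __post_init__(self) -> None:
        self.baseline = float(self.baseline)
        self.alphas = np.atleast_1d(np.asarray(self.alphas, dtype=float))
        if not np.isfinite(self.baseline) or not np.all(np.isfinite(self.alphas)):
            raise ValueError("influence parameters must be finite")


@dataclass
class ParameterSpec:
    """Ordered free-parameter names with box bounds."""

    names: list[str]
    lowers: np.ndarray
    uppers: np.ndarray

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        self.lowers = np.asarray(self.lowers, dtype=float).ravel()
        self.uppers = np.asarray(self.uppers, dtype=float).ravel()
        if len(set(self.names)) != len(self.names):
            raise ValueError("free-parameter names must be unique")
        if not (len(self.names) == len(self.lowers) == len(self.uppers)):
            raise ValueError("names and bound vectors must have equal length")
        if not (np.all(np.isfinite(self.lowers)) and np.all(np.isfinite(self.uppers))):
            raise ValueError("bounds must be finite")
        if np.any(self.lowers > self.uppers):
            bad = self.names[int(np.argmax(self.lowers > self.uppers))]
            raise ValueError(f"lower bound exceeds upper bound for {bad!r}")
        for name in self.names:
            if name not in RECOGNIZED_PARAM_NAMES and not name.startswith("alpha_"):
                raise ValueError(
                    f"unrecognized free parameter {name!r}; expected one of "
                    f"{list(RECOGNIZED_PARAM_NAMES)} or 'alpha_<factor>'"
                )

    @property
    def dims(self) -> int:
        return len(self.names)

    @classmethod
    def from_config_list(cls, free_params) -> "ParameterSpec":
        names = [n for n, _, _ in free_params]
        lowers = [lo for _, lo, _ in free_params]
        uppers = [hi for _, _, hi in free_params]
        return cls(names, lowers, uppers)


def apply_influence(params: InfluenceParams, pathology: PathologyMap) -> np.ndarray:
    """Regional excitability vector ``a_i = baseline + sum_f alpha_f q_{i,f}``."""
    if len(params.alphas) != pathology.n_factors:
        raise ValueError(
            f"{len(params.alphas)} influence coefficients for "
            f"{pathology.n_factors} pathology factors"
        )
    return params.baseline + pathology.burdens @ params.alphas


def map_free_vector(
    theta: np.ndarray, spec: ParameterSpec, defaults: dict[str, float]
) -> dict[str, float]:
    """Translate an optimizer vector into a complete named assignment.

    Returns ``defaults`` overridden at ``spec.names``; the inverse,
    :func:`pack_free_vector`, recovers ``theta`` exactly.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if len(theta) != spec.dims:
        raise ValueError(f"theta has {len(theta)} components for {spec.dims} free parameters")
    for i, name in enumerate(spec.names):
        if not (spec.lowers[i] <= theta[i] <= spec.uppers[i]):
            raise ValueError(
                f"{name} out of bounds: {theta[i]} not in "
                f"[{spec.lowers[i]}, {spec.uppers[i]}]"
            )
    assignment = dict(defaults)
    for name, value in zip(spec.names, theta):
        assignment[name] = float(value)
    return assignment


def pack_free_vector(assignment: dict[str, float], spec: ParameterSpec) -> np.ndarray:
    """Extract the free components of a named assignment, in spec order."""
    return np.array([assignment[name] for name in spec.names], dtype=float)
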