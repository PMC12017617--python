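"""Connectome-coupled excitatory-inhibitory dynamics and the hemodynamic
forward model.

Each region holds a two-population Wilson-Cowan unit. With ``E_i``, ``I_i``
the mean excitatory/inhibitory activities (dimensionless rates in [0, 1]):

    tau_E dE_i/dt = -E_i + S(c_EE E_i - c_IE I_i + G sum_j C_ij E_j + a_i;
                             gain_E, thresh_E)
    tau_I dI_i/dt = -I_i + S(c_EI E_i - c_II I_i + Q; gain_I, thresh_I)

where ``S`` is a logistic sigmoid, ``C`` the row-sum-normalized connectome and
``a_i`` the pathology-modulated excitatory drive from
:mod:`neuroinflux.influence`. Integration is Euler-Maruyama with additive
Gaussian state noise; states are clipped to [0, 1], the range of the
saturating sigmoid.

Excitatory activity drives a balloon-windkessel model per region
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q), whose
output is a percent-signal-like BOLD trace sampled every TR after a burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.special import expit

from .datatypes import Connectome

__all__ = [
    "NeuralModelParams",
    "HemoParams",
    "NeuralTrace",
    "BoldMatrix",
    "IntegrationError",
    "sigmoid",
    "neural_drift",
    "simulate_neural",
    "bold_forward",
    "trace_to_csv",
]


class IntegrationError(RuntimeError):
    """Raised when the forward integration leaves its valid state space."""


@dataclass
class NeuralModelParams:
    """Wilson-Cowan unit parameters with canonical couplings.

    The intra-regional couplings (c_EE=16, c_IE=12, c_EI=15, c_II=3) and
    sigmoid shapes are the classic values for which the isolated unit shows a
    limit cycle over a window of excitatory drive (onset near drive ~0.95
    with these numbers). ``P_baseline`` defaults to the noise-driven regime
    just below that window, so positive pathological influences push regions
    toward the oscillatory instability — the hyperexcitability picture — and
    the stochastic fluctuations that generate the BOLD signal vary smoothly
    with the drive.
    """

    tau_E: float = 0.01
    tau_I: float = 0.01
    c_EE: float = 16.0
    c_IE: float = 12.0
    c_EI: float = 15.0
    c_II: float = 3.0
    gain_E: float = 1.3
    thresh_E: float = 4.0
    gain_I: float = 2.0
    thresh_I: float = 3.7
    G_coupling: float = 0.5
    P_baseline: float = 0.2
    Q_input: float = 0.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("time constants must be positive")
        if self.gain_E <= 0 or self.gain_I <= 0:
            raise ValueError("sigmoid gains must be positive")
        if self.G_coupling < 0:
            raise ValueError("G_coupling must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_overrides(self, overrides: dict[str, float]) -> "NeuralModelParams":
        known = {k: v for k, v in overrides.items() if hasattr(self, k)}
        return replace(self, **known)


@dataclass
class HemoParams:
    """Balloon-windkessel hemodynamic parameters (standard values)."""

    kappa: float = 0.65   # vasodilatory signal decay, 1/s
    gamma: float = 0.41   # flow-dependent elimination, 1/s
    tau_h: float = 0.98   # hemodynamic transit time, s
    alpha_h: float = 0.32  # Grubb vessel stiffness exponent
    rho: float = 0.34     # resting oxygen extraction fraction
    V0: float = 0.02      # resting venous blood volume fraction

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau_h", "alpha_h", "rho", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_h", "rho", "V0"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class NeuralTrace:
    """Time-resolved population activity on a uniform grid of step ``dt``."""

    times: np.ndarray
    E: np.ndarray  # time x regions
    I: np.ndarray  # time x regions
    dt: float


@dataclass
class BoldMatrix:
    """Simulated fMRI signals, volumes x regions, sampled every TR."""

    TR: float
    signals: np.ndarray


def sigmoid(x, gain: float, threshold: float):
    """Logistic activation ``1 / (1 + exp(-gain (x - threshold)))``."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    return expit(gain * (np.asarray(x, dtype=float) - threshold))


def _connectome_matrix(connectome) -> np.ndarray:
    """Row-sum-normalized coupling matrix from a Connectome or raw array."""
    if isinstance(connectome, Connectome):
        return connectome.normalized()
    w = np.asarray(connectome, dtype=float)
    s = w.sum(axis=1).max()
    return w / s if s > 0 else w.copy()


def neural_drift(E, I, params: NeuralModelParams, connectome, excitability):
    """Deterministic drift (dE/dt, dI/dt) of the coupled system.

    ``connectome`` is taken as already normalized when passed as an array via
    :func:`_connectome_matrix`; a :class:`Connectome` is normalized here.
    """
    E = np.asarray(E, dtype=float)
    I = np.asarray(I, dtype=float)
    a = np.asarray(excitability, dtype=float)
    C = _connectome_matrix(connectome)
    if not (E.shape == I.shape == a.shape == (C.shape[0],)):
        raise ValueError("E, I, excitability and connectome dimensions disagree")
    inp_E = params.c_EE * E - params.c_IE * I + params.G_coupling * (C @ E) + a
    inp_I = params.c_EI * E - params.c_II * I + params.Q_input
    dE = (-E + sigmoid(inp_E, params.gain_E, params.thresh_E)) / params.tau_E
    dI = (-I + sigmoid(inp_I, params.gain_I, params.thresh_I)) / params.tau_I
    return dE, dI


@njit(cache=True, fastmath=True)
def _integrate_wc(C, a, E0, I0, n_steps, dt, tau_E, tau_I, c_EE, c_IE, c_EI,
                  c_II, gain_E, thresh_E, gain_I, thresh_I, G, Q, noise_sd,
                  noise):  # pragma: no cover - exercised via simulate_neural
    n = C.shape[0]
    E = np.empty((n_steps + 1, n))
    I = np.empty((n_steps + 1, n))
    E[0] = E0
    I[0] = I0
    sq = noise_sd * np.sqrt(dt)
    for t in range(n_steps):
        for i in range(n):
            coup = 0.0
            for j in range(n):
                coup += C[i, j] * E[t, j]
            xe = c_EE * E[t, i] - c_IE * I[t, i] + G * coup + a[i]
            xi = c_EI * E[t, i] - c_II * I[t, i] + Q
            se = 1.0 / (1.0 + np.exp(-gain_E * (xe - thresh_E)))
            si = 1.0 / (1.0 + np.exp(-gain_I * (xi - thresh_I)))
            e = E[t, i] + dt * (-E[t, i] + se) / tau_E
            v = I[t, i] + dt * (-I[t, i] + si) / tau_I
            if noise_sd > 0.0:
                e += sq * noise[t, 2 * i]
                v += sq * noise[t, 2 * i + 1]
            # saturating dynamics: clip to the sigmoid's range
            E[t + 1, i] = min(1.0, max(0.0, e))
            I[t + 1, i] = min(1.0, max(0.0, v))
    return E, I


def simulate_neural(
    params: NeuralModelParams,
    connectome,
    excitability,
    duration: float,
    dt: float,
    seed: int | None = 0,
    initial_state: tuple[float, float] = (0.1, 0.1),
    noise: np.ndarray | None = None,
) -> NeuralTrace:
    """Integrate the stochastic network with Euler-Maruyama at step ``dt``.

    Additive Gaussian state noise has per-step standard deviation
    ``noise_sd * sqrt(dt)``. A fixed ``seed`` makes the trace bit-reproducible;
    alternatively a pre-drawn standard-normal ``noise`` array of shape
    ``(n_steps, 2 * n_regions)`` may be supplied (columns alternate E, I per
    region), which the subject-fitting objective uses to share one noise
    realization across evaluations.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    C = _connectome_matrix(connectome)
    a = np.asarray(excitability, dtype=float).ravel()
    n = C.shape[0]
    if len(a) != n:
        raise ValueError(f"excitability length {len(a)} != {n} regions")
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise ValueError("duration shorter than one integration step")
    if params.noise_sd > 0:
        if noise is None:
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal((n_steps, 2 * n))
        elif noise.shape[0] < n_steps or noise.shape[1] != 2 * n:
            raise ValueError(
                f"noise array shape {noise.shape} too small for "
                f"({n_steps}, {2 * n})"
            )
    else:
        noise = np.zeros((1, 2 * n))
    E0 = np.full(n, float(initial_state[0]))
    I0 = np.full(n, float(initial_state[1]))
    E, I = _integrate_wc(
        C, a, E0, I0, n_steps, dt, params.tau_E, params.tau_I, params.c_EE,
        params.c_IE, params.c_EI, params.c_II, params.gain_E, params.thresh_E,
        params.gain_I, params.thresh_I, params.G_coupling, params.Q_input,
        params.noise_sd, np.ascontiguousarray(noise[:n_steps], dtype=float),
    )
    if not (np.all(np.isfinite(E)) and np.all(np.isfinite(I))):
        t_bad = int(np.argwhere(~np.isfinite(E).all(axis=1) | ~np.isfinite(I).all(axis=1))[0])
        raise IntegrationError(f"non-finite neural state at t = {t_bad * dt:.4f} s")
    times = np.arange(n_steps + 1) * dt
    return NeuralTrace(times=times, E=E, I=I, dt=dt)


@njit(cache=True, fastmath=True)
def _integrate_balloon(E, dt, kappa, gamma, tau_h, alpha_h, rho, V0,
                       sample_idx):  # pragma: no cover - via bold_forward
    n_steps, n = E.shape
    inv_alpha = 1.0 / alpha_h
    k1 = 7.0 * rho
    k2 = 2.0
    k3 = 2.0 * rho - 0.2
    bold = np.empty((sample_idx.shape[0], n))
    ok = True
    for i in range(n):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        k = 0
        for t in range(n_steps):
            if k < sample_idx.shape[0] and t == sample_idx[k]:
                bold[k, i] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v)
                                   + k3 * (1.0 - v))
                k += 1
            fv = v ** inv_alpha
            ds = E[t, i] - kappa * s - gamma * (f - 1.0)
            df = s
            dv = (f - fv) / tau_h
            dq = (f * (1.0 - (1.0 - rho) ** (1.0 / f)) / rho - fv * q / v) / tau_h
            s += dt * ds
            f += dt * df
            v += dt * dv
            q += dt * dq
            if f <= 0.0 or v <= 0.0:
                ok = False
                return bold, ok, t
    return bold, ok, -1


def bold_forward(
    trace: NeuralTrace,
    hemo: HemoParams,
    TR: float,
    n_volumes: int,
    burn_in: float = 0.0,
) -> BoldMatrix:
    """Convert excitatory activity to BOLD via the balloon-windkessel system.

    Per region: ds/dt = E - kappa s - gamma (f - 1); df/dt = s;
    tau_h dv/dt = f - v^(1/alpha_h);
    tau_h dq/dt = f (1 - (1 - rho)^(1/f))/rho - v^(1/alpha_h) q / v;
    BOLD = V0 (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)) with k1 = 7 rho,
    k2 = 2, k3 = 2 rho - 0.2. Integrated on the neural grid; sampled at the
    grid point nearest each multiple of TR after discarding ``burn_in``.
    """
    if TR <= 0 or n_volumes < 1:
        raise ValueError("TR must be > 0 and n_volumes >= 1")
    dt = trace.dt
    n_steps = trace.E.shape[0]
    sample_idx = np.array(
        [int(round((burn_in + k * TR) / dt)) for k in range(n_volumes)], dtype=np.int64
    )
    if sample_idx[-1] >= n_steps:
        need = burn_in + (n_volumes - 1) * TR
        raise ValueError(
            f"trace covers {(n_steps - 1) * dt:.3f} s but sampling requires "
            f"{need:.3f} s"
        )
    bold, ok, t_bad = _integrate_balloon(
        np.ascontiguousarray(trace.E, dtype=float), dt, hemo.kappa, hemo.gamma,
        hemo.tau_h, hemo.alpha_h, hemo.rho, hemo.V0, sample_idx,
    )
    if not ok:
        raise IntegrationError(
            f"hemodynamic state left its domain (f or v <= 0) at t = {t_bad * dt:.4f} s"
        )
    if not np.all(np.isfinite(bold)):
        raise IntegrationError("non-finite BOLD sample")
    return BoldMatrix(TR=TR, signals=bold)


def trace_to_csv(trace: NeuralTrace, path, region_labels=None):
    """Dump a neural trace (times plus per-region E and I columns) to CSV,
    mainly for debugging; traces at the default 2 ms step are large."""
    import pandas as pd

    n = trace.E.shape[1]
    labels = list(region_labels) if region_labels else [f"R{i + 1}" for i in range(n)]
    data = {"time": trace.times}
    for i, lab in enumerate(labels):
        data[f"E_{lab}"] = trace.E[:, i]
    for i, lab in enumerate(labels):
        data[f"I_{lab}"] = trace.I[:, i]
    pd.DataFrame(data).to_csv(path, index=False)
    return path
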