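"""Synthetic subjects and cohorts with known ground truth.

The generator emulates the four study inputs — a structural connectome, a
regional pathology map, an observed functional indicator and a study
configuration — where the observed indicator is produced by the package's
own forward model at known influence parameters. For noise-free
observations the generating parameters therefore achieve objective cost
exactly zero, making parameter recovery well posed up to identifiability.

Defaults describe the benchmark conditions: 20 regions, two pathological
factors with gamma-distributed burdens (shape 2, scale 0.5, i.e. unit mean,
right-skewed like tracer-uptake maps), a 30 % dense symmetric connectome and
a 150-volume TR 2 s acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .datatypes import Connectome, FunctionalVector, PathologyMap, StudyConfig
from .estimation import (
    SubjectData,
    default_assignment,
    default_free_params,
    simulate_indicator,
    subject_noise,
)
from .forward import HemoParams, NeuralModelParams
from .influence import InfluenceParams, apply_influence

__all__ = [
    "SyntheticSubject",
    "gen_connectome",
    "gen_pathology",
    "gen_subject",
    "gen_benchmark_cohort",
    "sample_truth",
]

DEFAULT_FACTORS = ("abeta", "tau")


@dataclass
class SyntheticSubject:
    """A complete synthetic subject with stored ground truth."""

    connectome: Connectome
    pathology: PathologyMap
    functional: FunctionalVector
    config: StudyConfig
    truth: dict[str, float]
    true_excitability: np.ndarray
    seed: int

    def as_subject_data(self) -> SubjectData:
        return SubjectData(self.connectome, self.pathology, self.functional,
                          self.config)


def _region_labels(n: int) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(n)]


def gen_connectome(
    n_regions: int,
    density: float = 0.3,
    weight_scale: float = 1.0,
    seed=0,
) -> Connectome:
    """Random symmetric nonnegative connectome with ~``density`` of the
    off-diagonal pairs connected; bridge edges are added if the graph is
    disconnected."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    w = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    present = rng.random(len(iu[0])) < density
    weights = rng.uniform(0.5, 1.5, len(iu[0])) * weight_scale
    w[iu] = np.where(present, weights, 0.0)
    w = w + w.T
    # bridge disconnected components so activity can propagate everywhere
    n_comp, labels = connected_components(w > 0, directed=False)
    while n_comp > 1:
        a = int(np.flatnonzero(labels == 0)[0])
        b = int(np.flatnonzero(labels != 0)[0])
        w[a, b] = w[b, a] = weight_scale
        n_comp, labels = connected_components(w > 0, directed=False)
    return Connectome(_region_labels(n_regions), w)


def gen_pathology(
    n_regions: int,
    factor_labels=DEFAULT_FACTORS,
    seed=0,
    shape: float = 2.0,
    scale: float = 0.5,
) -> PathologyMap:
    """Right-skewed nonnegative burdens, i.i.d. gamma per region and factor."""
    factor_labels = list(factor_labels)
    if not factor_labels:
        raise ValueError("need at least one pathology factor")
    rng = np.random.default_rng(seed)
    burdens = rng.gamma(shape, scale, size=(n_regions, len(factor_labels)))
    return PathologyMap(_region_labels(n_regions), factor_labels, burdens)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def sample_truth(
    factor_labels,
    rng: np.random.Generator,
    free_params=None,
) -> dict[str, float]:
    """Draw ground-truth free-parameter values from the middle 60 % of each
    optimization interval (so truths never sit on a bound)."""
    free = free_params or default_free_params(factor_labels)
    truth = {}
    for name, lo, hi in free:
        width = hi - lo
        truth[name] = float(rng.uniform(lo + 0.2 * width, hi - 0.2 * width))
    return truth


def gen_subject(
    n_regions: int = 20,
    truth: dict[str, float] | None = None,
    config: StudyConfig | None = None,
    obs_noise_sd: float = 0.0,
    seed=0,
    factor_labels=DEFAULT_FACTORS,
    density: float = 0.3,
    neural: NeuralModelParams | None = None,
    hemo: HemoParams | None = None,
) -> SyntheticSubject:
    """Generate one synthetic subject.

    ``truth`` maps free-parameter names to their generating values; omitted
    entries fall back to the model defaults. ``obs_noise_sd`` adds Gaussian
    observation noise to the indicator (then clipped to [0, 1] for fALFF);
    the default 0 keeps the generating parameters an exact global optimum.
    """
    factor_labels = list(factor_labels)
    neural = neural or NeuralModelParams()
    hemo = hemo or HemoParams()
    ss = np.random.SeedSequence(seed)
    ss_conn, ss_path, ss_sim, ss_obs, ss_truth = ss.spawn(5)
    connectome = gen_connectome(n_regions, density=density, seed=ss_conn)
    pathology = gen_pathology(n_regions, factor_labels, seed=ss_path)
    if truth is None:
        truth = sample_truth(factor_labels, np.random.default_rng(ss_truth))
    config = config or StudyConfig()
    config = config.copy(
        seed=_child_seed(ss_sim),
        free_params=config.free_params or default_free_params(factor_labels),
    )
    assignment = default_assignment(factor_labels, neural)
    assignment.update(truth)
    noise = (
        subject_noise(config, n_regions)
        if assignment["noise_sd"] > 0
        else None
    )
    observed = simulate_indicator(
        connectome, pathology, assignment, config, neural, hemo, noise=noise
    )
    if obs_noise_sd > 0:
        rng_obs = np.random.default_rng(ss_obs)
        observed = observed + rng_obs.normal(0.0, obs_noise_sd, size=n_regions)
        if config.indicator_kind == "fALFF":
            observed = np.clip(observed, 0.0, 1.0)
    influence = InfluenceParams(
        baseline=assignment["baseline"],
        alphas=[assignment[f"alpha_{f}"] for f in factor_labels],
    )
    true_excitability = apply_influence(influence, pathology)
    functional = FunctionalVector(
        connectome.region_labels, observed, config.indicator_kind
    )
    truth_full = {k: assignment[k] for k in sorted(assignment)}
    return SyntheticSubject(
        connectome=connectome,
        pathology=pathology,
        functional=functional,
        config=config,
        truth=truth_full,
        true_excitability=true_excitability,
        seed=int(seed) if np.isscalar(seed) else 0,
    )


def gen_benchmark_cohort(
    n_subjects: int = 10,
    n_regions: int = 20,
    factor_labels=DEFAULT_FACTORS,
    config: StudyConfig | None = None,
    truth_sampler=None,
    obs_noise_sd: float = 0.0,
    seed=0,
    out_dir=None,
):
    """Generate an independent cohort with subject-specific ground truths.

    Returns ``(subjects, truth_table)``; when ``out_dir`` is given the four
    input files per subject plus one cohort truth CSV are written in the
    formats :mod:`neuroinflux.io_csv` reads.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    factor_labels = list(factor_labels)
    base_config = config or StudyConfig(cohort_tag="synthbench")
    ss = np.random.SeedSequence(seed)
    subject_seeds = [_child_seed(child) for child in ss.spawn(n_subjects)]
    truth_rng = np.random.default_rng(ss.spawn(n_subjects + 1)[-1])
    sampler = truth_sampler or (
        lambda rng: sample_truth(factor_labels, rng,
                                 base_config.free_params or None)
    )
    subjects: list[SyntheticSubject] = []
    rows = []
    for k in range(n_subjects):
        tag = f"sub{k + 1:02d}"
        truth = sampler(truth_rng)
        subj = gen_subject(
            n_regions=n_regions,
            truth=truth,
            config=base_config.copy(subject_tag=tag),
            obs_noise_sd=obs_noise_sd,
            seed=subject_seeds[k],
            factor_labels=factor_labels,
        )
        subjects.append(subj)
        rows.append({"subject": tag, **subj.truth})
    truth_table = pd.DataFrame(rows).set_index("subject")
    if out_dir is not None:
        from . import io_csv  # deferred: io_csv imports these containers

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for subj in subjects:
            io_csv.write_subject_inputs(subj.as_subject_data(), out)
        truth_table.to_csv(out / f"{base_config.cohort_tag}_truth.csv")
    return subjects, truth_table
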