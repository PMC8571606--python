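"""Multigenotype frequency dynamics for serially propagated strain communities.

A community of ``N`` haploid strains is tracked by genotype frequencies.  One
strain is the *focal* strain; every other strain ``i`` carries a per-generation
selection coefficient ``s_i`` measured against the focal strain, so its fitness
relative to the focal strain is ``w_i = 1 - s_i`` (the focal strain itself has
``w = 1``).  Per generation each frequency is multiplied by its relative
fitness and renormalised by the population mean fitness::

    x_i(t+1) = x_i(t) * w_i / sum_k x_k(t) * w_k

Deterministic forecasts (:func:`predict_trajectory`), stochastic
serial-transfer simulations with a multinomial bottleneck
(:func:`simulate_bottleneck_regime`) and outcome classification
(:func:`classify_outcome`) all operate on this representation.

Two distinct generation conventions coexist in this package and are kept in
separate functions on purpose: regrowth after a D-fold dilution corresponds to
``log2(D)`` doublings (:func:`generations_per_transfer`), while
competitive-fitness assays count generations as ``ln(X_f/X_i)``
(:func:`strainfate.fitness.generations_elapsed`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Community",
    "FrequencyState",
    "FrequencyTrajectory",
    "OutcomeCall",
    "CoverageWarning",
    "initial_frequencies",
    "step_frequencies",
    "predict_trajectory",
    "simulate_bottleneck_regime",
    "generations_per_transfer",
    "classify_outcome",
    "compare_prediction_to_observation",
    "DEFAULT_HORIZON",
    "DEFAULT_DILUTION",
    "DEFAULT_CENSUS",
]

#: Forecast horizon in generations used throughout (long-term propagation scale).
DEFAULT_HORIZON = 400

#: Serial-transfer dilution factor of the propagation regime.
DEFAULT_DILUTION = 500

#: Founder census after diluting a saturated 200 ul culture 1:500
#: (od_to_cells(1.0, 0.2) / 500 ~= 1.19e4 cells).
DEFAULT_CENSUS = 11880

_SUM_TOL = 1e-12


class CoverageWarning(UserWarning):
    """Raised when a trajectory has too few points to classify reliably."""


@dataclass(frozen=True)
class Community:
    """A strain community defined relative to one focal strain.

    Parameters
    ----------
    strain_names
        All strain labels, focal included.
    focal
        Label of the focal strain; must appear in ``strain_names``.
    selection_vs_focal
        Mapping ``strain -> s`` for every non-focal strain.  ``s > 0`` means
        the focal strain outcompetes that strain (the rival's relative
        fitness is ``w = 1 - s``).
    initial_focal_frequency
        Frequency of the focal strain at time zero, strictly inside (0, 1).
    """

    strain_names: tuple[str, ...]
    focal: str
    selection_vs_focal: dict[str, float]
    initial_focal_frequency: float = 0.5

    def __post_init__(self) -> None:
        if len(self.strain_names) < 2:
            raise ValueError("a community needs at least two strains")
        if len(set(self.strain_names)) != len(self.strain_names):
            raise ValueError("duplicate strain names")
        if self.focal not in self.strain_names:
            raise ValueError(f"focal strain {self.focal!r} not in strain_names")
        others = [n for n in self.strain_names if n != self.focal]
        missing = set(others) - set(self.selection_vs_focal)
        if missing:
            raise ValueError(f"no selection coefficient for: {sorted(missing)}")
        if not 0.0 < self.initial_focal_frequency < 1.0:
            raise ValueError("initial_focal_frequency must be in (0, 1)")
        for name, s in self.selection_vs_focal.items():
            if 1.0 - s <= 0.0:
                raise ValueError(
                    f"strain {name!r}: s={s} gives non-positive relative fitness"
                )

    @property
    def n_strains(self) -> int:
        return len(self.strain_names)

    @property
    def focal_index(self) -> int:
        return self.strain_names.index(self.focal)

    def fitness_vector(self) -> np.ndarray:
        """Relative fitness ``w_i = 1 - s_i`` per strain; 1.0 for the focal."""
        w = np.ones(self.n_strains)
        for i, name in enumerate(self.strain_names):
            if name != self.focal:
                w[i] = 1.0 - self.selection_vs_focal[name]
        return w


@dataclass(frozen=True)
class FrequencyState:
    """Genotype frequencies at one moment, indexed like the community."""

    frequencies: np.ndarray
    generation: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if np.any(freqs < 0):
            raise ValueError("negative frequency")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {freqs.sum()}, not 1")


@dataclass
class FrequencyTrajectory:
    """A time-ordered list of frequency states plus strain labels."""

    states: list[FrequencyState]
    strain_names: tuple[str, ...]
    focal: str
    kind: Literal["predicted", "simulated", "observed"] = "predicted"

    def __post_init__(self) -> None:
        gens = [s.generation for s in self.states]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("generations must be strictly increasing")

    @property
    def generations(self) -> np.ndarray:
        return np.array([s.generation for s in self.states])

    @property
    def focal_frequencies(self) -> np.ndarray:
        idx = self.strain_names.index(self.focal)
        return np.array([s.frequencies[idx] for s in self.states])

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class OutcomeCall:
    """Fixation/extinction/persistence verdict for a focal-strain trajectory."""

    outcome: Literal["fixed", "extinct", "persisting"]
    at_generation: float | None = None

    def __post_init__(self) -> None:
        if (self.outcome == "persisting") != (self.at_generation is None):
            raise ValueError("at_generation present iff outcome is not persisting")


def initial_frequencies(community: Community) -> FrequencyState:
    """Equal-split initial state: the focal strain gets its configured
    frequency and the remainder is shared evenly among the other strains,
    ``x_i(t0) = (1 - x_f(t0)) / (N - 1)``.
    """
    n = community.n_strains
    xf = community.initial_focal_frequency
    freqs = np.full(n, (1.0 - xf) / (n - 1))
    freqs[community.focal_index] = xf
    # exact unit sum regardless of rounding in the equal split
    freqs /= freqs.sum()
    return FrequencyState(freqs, generation=0.0)


def step_frequencies(state: FrequencyState, community: Community) -> FrequencyState:
    """Advance one generation of deterministic selection.

    Each frequency is weighted by the strain's fitness relative to the focal
    strain and renormalised by the mean fitness; the focal strain's frequency
    therefore changes only through the denominator.
    """
    w = community.fitness_vector()
    weighted = state.frequencies * w
    mean_fitness = weighted.sum()
    if mean_fitness <= 0:
        raise ValueError("non-positive mean fitness")
    return FrequencyState(weighted / mean_fitness, state.generation + 1.0)


def predict_trajectory(
    community: Community,
    horizon: int = DEFAULT_HORIZON,
    record_every: int = 1,
) -> FrequencyTrajectory:
    """Deterministic frequency forecast over ``horizon`` generations.

    Iterates :func:`step_frequencies` from :func:`initial_frequencies`,
    recording the state at ``t = 0`` and every ``record_every`` generations.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    state = initial_frequencies(community)
    states = [state]
    for t in range(1, horizon + 1):
        state = step_frequencies(state, community)
        if t % record_every == 0 or t == horizon:
            states.append(state)
    return FrequencyTrajectory(states, community.strain_names, community.focal, "predicted")


def _select(freqs: np.ndarray, w: np.ndarray, generations: float) -> np.ndarray:
    """Deterministic selection over a possibly fractional number of
    generations: multiply by ``w**g`` and renormalise (equivalent to ``g``
    single-generation steps when ``g`` is an integer)."""
    weighted = freqs * np.power(w, generations)
    return weighted / weighted.sum()


def simulate_bottleneck_regime(
    community: Community,
    n_transfers: int,
    census_at_transfer: int = DEFAULT_CENSUS,
    growth_generations_per_transfer: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> FrequencyTrajectory:
    """Serial-transfer simulation: deterministic growth, multinomial bottleneck.

    Each cycle applies ``growth_generations_per_transfer`` generations of
    deterministic selection (default ``log2(500)``, the regrowth implied by a
    1:500 dilution) and then samples ``census_at_transfer`` founder cells
    multinomially from the current frequencies.  A strain drawn at zero
    founders is extinct and stays extinct.  Frequencies after each bottleneck
    are founder counts divided by the census, so they sum to one exactly.
    """
    if census_at_transfer < 1:
        raise ValueError("census_at_transfer must be >= 1")
    if n_transfers < 0:
        raise ValueError("n_transfers must be >= 0")
    if growth_generations_per_transfer is None:
        growth_generations_per_transfer = generations_per_transfer(DEFAULT_DILUTION)
    if growth_generations_per_transfer <= 0:
        raise ValueError("growth_generations_per_transfer must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    w = community.fitness_vector()
    state = initial_frequencies(community)
    states = [state]
    t = 0.0
    freqs = state.frequencies
    for _ in range(n_transfers):
        t += growth_generations_per_transfer
        freqs = _select(freqs, w, growth_generations_per_transfer)
        counts = rng.multinomial(census_at_transfer, freqs)
        freqs = counts / census_at_transfer
        states.append(FrequencyState(freqs, t))
    return FrequencyTrajectory(states, community.strain_names, community.focal, "simulated")


def generations_per_transfer(dilution: float) -> float:
    """Cell doublings needed to regrow to pre-dilution density after a
    ``dilution``-fold serial transfer, ``log2(dilution)``.

    For the 1:500 regime this is ~8.97, i.e. around 9 generations per
    transfer.  Note the base-2 convention: this counts doublings, unlike the
    natural-log generation count of the competition assays.
    """
    if dilution <= 1:
        raise ValueError("dilution must be > 1")
    return math.log2(dilution)


def classify_outcome(
    trajectory: FrequencyTrajectory,
    fixation_threshold: float = 0.99,
    extinction_threshold: float = 0.01,
    consecutive_points: int = 3,
) -> OutcomeCall:
    """Classify a focal-strain trajectory as fixed, extinct or persisting.

    ``fixed``: focal frequency above ``fixation_threshold`` at
    ``consecutive_points`` or more successive recorded points (default: >99%
    at >=3 points).  ``extinct`` is the mirror rule below
    ``extinction_threshold``.  ``at_generation`` is the first point of the
    earliest qualifying run.  Trajectories with fewer recorded points than
    ``consecutive_points`` are ``persisting`` with a :class:`CoverageWarning`.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    if consecutive_points < 1:
        raise ValueError("consecutive_points must be >= 1")
    if len(trajectory) < consecutive_points:
        warnings.warn(
            f"only {len(trajectory)} recorded points; need {consecutive_points} "
            "to call an outcome",
            CoverageWarning,
            stacklevel=2,
        )
        return OutcomeCall("persisting")

    focal = trajectory.focal_frequencies
    gens = trajectory.generations

    def first_run(mask: np.ndarray) -> float | None:
        run = 0
        for i, hit in enumerate(mask):
            run = run + 1 if hit else 0
            if run >= consecutive_points:
                return float(gens[i - consecutive_points + 1])
        return None

    fixed_at = first_run(focal > fixation_threshold)
    extinct_at = first_run(focal < extinction_threshold)
    if fixed_at is not None and (extinct_at is None or fixed_at <= extinct_at):
        return OutcomeCall("fixed", fixed_at)
    if extinct_at is not None:
        return OutcomeCall("extinct", extinct_at)
    return OutcomeCall("persisting")


@dataclass
class TrajectoryComparison:
    """Residuals of an observed trajectory against a prediction."""

    generations: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray
    mean_absolute_error: float
    lag_sign: int

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": self.generations,
                "observed": self.observed,
                "predicted": self.predicted,
                "residual": self.residuals,
            }
        )


def compare_prediction_to_observation(
    predicted: FrequencyTrajectory,
    observed: FrequencyTrajectory,
) -> TrajectoryComparison:
    """Interpolate a prediction onto observed timepoints and compute residuals.

    ``residual = observed - predicted`` per timepoint.  ``lag_sign`` is +1
    when the observation is lagging the prediction (moving toward loss or
    fixation more slowly than predicted), -1 when it leads, 0 when neither;
    it is the sign of the summed residuals oriented by the predicted trend.
    """
    pg, og = predicted.generations, observed.generations
    if og.min() < pg.min() - 1e-9 or og.max() > pg.max() + 1e-9:
        raise ValueError(
            "observed timepoints fall outside the predicted horizon "
            f"([{og.min()}, {og.max()}] vs [{pg.min()}, {pg.max()}])"
        )
    interp = np.interp(og, pg, predicted.focal_frequencies)
    obs = observed.focal_frequencies
    residuals = obs - interp
    mae = float(np.mean(np.abs(residuals)))
    # predicted trend: falling -> lag means observed sits above the prediction
    trend = predicted.focal_frequencies[-1] - predicted.focal_frequencies[0]
    oriented = residuals.sum() * (-1.0 if trend > 0 else 1.0)
    lag_sign = 0 if abs(oriented) < 1e-12 else (1 if oriented > 0 else -1)
    return TrajectoryComparison(og, obs, interp, residuals, mae, lag_sign)
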