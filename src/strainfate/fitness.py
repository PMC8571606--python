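"""Competitive-fitness estimation from paired fluorescent/non-fluorescent counts.

A pairwise competition mixes a fluorescent reference strain 1:1 with a
non-fluorescent rival, lets the culture grow for 48 h, and counts both
subpopulations by flow cytometry at the start and the end.  With ``X`` the
fluorescent (reference) cell number and ``R`` the fluorescent/non-fluorescent
ratio, the per-generation selection coefficient of the reference strain is::

    t   = ln(X_final / X_initial)        # reference-strain generations
    S/g = ln(R_final / R_initial) / t

Positive ``S/g`` means the fluorescent strain has the advantage.  Note the
natural-log generation convention here, distinct from the base-2 doublings of
:func:`strainfate.dynamics.generations_per_transfer`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CompetitionCounts",
    "FitnessEstimate",
    "ShrinkingPopulationWarning",
    "ZeroCountWarning",
    "generations_elapsed",
    "fitness_per_generation",
    "aggregate_replicates",
    "community_fitness_change",
]


class ShrinkingPopulationWarning(UserWarning):
    """The reference strain declined during the assay (t <= 0)."""


class ZeroCountWarning(UserWarning):
    """A zero count was replaced by a pseudocount before ratio formation."""


@dataclass(frozen=True)
class CompetitionCounts:
    """Cytometer counts for one competition replicate at start and end."""

    assay_id: str
    fluor_initial: float
    fluor_final: float
    nonfluor_initial: float
    nonfluor_final: float

    def __post_init__(self) -> None:
        for name in ("fluor_initial", "fluor_final", "nonfluor_initial", "nonfluor_final"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fluor_initial <= 0 or self.nonfluor_initial <= 0:
            raise ValueError("initial counts must be > 0")

    def swapped(self) -> "CompetitionCounts":
        """Counts with the fluorescent/non-fluorescent labels exchanged."""
        return CompetitionCounts(
            self.assay_id,
            self.nonfluor_initial,
            self.nonfluor_final,
            self.fluor_initial,
            self.fluor_final,
        )


@dataclass(frozen=True)
class FitnessEstimate:
    """A selection-coefficient estimate, single-replicate or aggregated.

    ``mean`` and ``two_sem`` describe the replicate distribution; for a
    single replicate ``mean`` equals ``s_per_generation`` and ``two_sem`` is
    NaN.  ``valid`` is False when the generation count was non-positive.
    """

    assay_id: str
    s_per_generation: float
    generations: float
    n_replicates: int = 1
    mean: float = math.nan
    two_sem: float = math.nan
    sd: float = math.nan
    valid: bool = True

    def __post_init__(self) -> None:
        if not math.isnan(self.two_sem) and self.two_sem < 0:
            raise ValueError("two_sem must be >= 0")


def generations_elapsed(counts: CompetitionCounts) -> float:
    """Reference-strain generations over the assay, ``ln(X_f / X_i)``.

    A declining reference strain yields a negative value and a
    :class:`ShrinkingPopulationWarning`; downstream estimates built on it are
    marked invalid rather than silently returned.
    """
    if counts.fluor_initial <= 0:
        raise ValueError("undefined generations: zero initial reference count")
    if counts.fluor_final <= 0:
        raise ValueError("undefined generations: zero final reference count")
    t = math.log(counts.fluor_final / counts.fluor_initial)
    if t < 0:
        warnings.warn(
            f"{counts.assay_id}: reference strain shrank (t={t:.3g})",
            ShrinkingPopulationWarning,
            stacklevel=2,
        )
    return t


def fitness_per_generation(
    counts: CompetitionCounts, pseudocount: float = 1.0
) -> FitnessEstimate:
    """Per-generation selection coefficient ``S/g = ln(R_f/R_i) / t``.

    ``R`` is the fluorescent/non-fluorescent ratio at each timepoint.  Any
    zero count is replaced by ``pseudocount`` (with a
    :class:`ZeroCountWarning`) so the statistic stays finite; assays where the
    reference strain failed to grow (``t <= 0``) return an estimate flagged
    ``valid=False``.
    """
    xf, xi = counts.fluor_final, counts.fluor_initial
    nf, ni = counts.nonfluor_final, counts.nonfluor_initial
    patched = [k for k, v in (("fluor_final", xf), ("nonfluor_final", nf)) if v == 0]
    if patched:
        warnings.warn(
            f"{counts.assay_id}: zero count(s) {patched} replaced by "
            f"pseudocount {pseudocount}",
            ZeroCountWarning,
            stacklevel=2,
        )
        xf = xf or pseudocount
        nf = nf or pseudocount
    t = math.log(xf / xi)
    if t < 0:
        warnings.warn(
            f"{counts.assay_id}: reference strain shrank (t={t:.3g})",
            ShrinkingPopulationWarning,
            stacklevel=2,
        )
    ri = xi / ni
    rf = xf / nf
    if t <= 0:
        return FitnessEstimate(counts.assay_id, math.nan, t, valid=False)
    s = math.log(rf / ri) / t
    return FitnessEstimate(counts.assay_id, s, t, mean=s)


def aggregate_replicates(estimates: Sequence[FitnessEstimate]) -> FitnessEstimate:
    """Mean and 2*SEM of ``S/g`` across valid replicate estimates.

    The dispersion convention is twice the standard error of the mean
    (sample SD / sqrt(n)); the SD itself is also stored.
    """
    valid = [e for e in estimates if e.valid]
    if len(valid) < 2:
        raise ValueError(f"need >= 2 valid estimates, got {len(valid)}")
    values = np.array([e.s_per_generation for e in valid])
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    two_sem = 2.0 * sd / math.sqrt(len(values))
    return FitnessEstimate(
        assay_id=valid[0].assay_id,
        s_per_generation=mean,
        generations=float(np.mean([e.generations for e in valid])),
        n_replicates=len(values),
        mean=mean,
        two_sem=two_sem,
        sd=sd,
    )


def community_fitness_change(
    ancestral: FitnessEstimate,
    evolved: FitnessEstimate,
    correction: FitnessEstimate | None = None,
    correction_required: bool = False,
) -> float:
    """Fitness change of a community over evolution, vs a common reference.

    Both inputs are selection coefficients of the *reference* strain competed
    against the community (ancestral vs evolved).  The community's change is
    the negated difference::

        delta = -(evolved.mean - ancestral.mean)

    so a reference strain that fares worse against the evolved community
    (more negative ``evolved.mean``) reports a positive community gain.  When
    the evolved population had to be competed against a different reference
    strain, ``correction`` (the selection coefficient between the two
    references) is added to ``evolved.mean`` first to put both assays on the
    same scale; pass ``correction_required=True`` to make its absence an
    error for that case.
    """
    if not (ancestral.valid and evolved.valid):
        raise ValueError("both estimates must be valid")
    if correction_required and correction is None:
        raise ValueError(
            "correction estimate required: evolved population was competed "
            "against a different reference strain"
        )
    evolved_mean = evolved.mean
    if correction is not None:
        if not correction.valid:
            raise ValueError("correction estimate must be valid")
        evolved_mean = evolved_mean + correction.mean
    return -(evolved_mean - ancestral.mean)
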