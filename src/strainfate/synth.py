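"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: logistic OD600
growth curves with plate-reader noise, two-genotype competition counts under
constant per-generation selection, multi-strain frequency trajectories with
multinomial bottleneck sampling, and samtools-mpileup text with planted SNPs,
sequencing errors and strand-bias decoys.  All generators are deterministic
for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    Community,
    FrequencyState,
    FrequencyTrajectory,
    generations_per_transfer,
    initial_frequencies,
    predict_trajectory,
    simulate_bottleneck_regime,
)
from .fitness import CompetitionCounts
from .growth import GrowthCurve

__all__ = [
    "GroundTruth",
    "gen_growth_curve",
    "gen_competition_counts",
    "gen_trajectory",
    "gen_pileup",
    "write_growth_curves_csv",
    "write_competition_counts_csv",
    "read_competition_counts_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_pileup",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth: the values a generator hid inside its output."""

    rng_seed: int
    true_growth_rate: float | None = None
    true_selection: tuple[float, ...] = ()
    true_variant_positions: tuple[tuple[str, int, str, str], ...] = ()

    def __post_init__(self) -> None:
        for s in self.true_selection:
            if not -1.0 < s < 1.0:
                raise ValueError(f"selection coefficient {s} outside (-1, 1)")
        by_contig: dict[str, int] = {}
        for contig, pos, _, _ in self.true_variant_positions:
            if pos <= by_contig.get(contig, 0):
                raise ValueError("variant positions must be strictly increasing per contig")
            by_contig[contig] = pos


def gen_growth_curve(
    rate: float,
    carrying_capacity: float = 1.0,
    initial_od: float = 0.003,
    interval_min: float = 20.0,
    duration_h: float = 48.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    well_id: str = "A1",
) -> GrowthCurve:
    """Logistic OD600 curve with optional additive Gaussian reader noise.

    The noiseless trajectory is the logistic solution
    ``OD(t) = K*OD0*e^(rt) / (K + OD0*(e^(rt) - 1))``; noise is i.i.d.
    Gaussian, truncated at zero so readings stay non-negative.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if initial_od <= 0:
        raise ValueError("initial_od must be > 0")
    if carrying_capacity <= initial_od:
        raise ValueError("carrying_capacity must exceed initial_od")
    if interval_min <= 0 or duration_h <= 0:
        raise ValueError("interval and duration must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    n = int(round(duration_h * 60.0 / interval_min)) + 1
    times = np.arange(n) * interval_min / 60.0
    growth = np.exp(rate * times)
    od = carrying_capacity * initial_od * growth / (
        carrying_capacity + initial_od * (growth - 1.0)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = np.maximum(od + rng.normal(0.0, noise_sd, size=n), 0.0)
    return GrowthCurve(well_id, times, od)


def gen_competition_counts(
    s: float,
    initial_total: float = 1e5,
    initial_focal_fraction: float = 0.5,
    fold_expansion: float = 500.0,
    sampling: Literal["noiseless", "multinomial"] = "noiseless",
    events: int = 10_000,
    seed: int = 0,
    assay_id: str = "assay",
) -> CompetitionCounts:
    """Two-genotype competition counts with known selection coefficient.

    The fluorescent (focal) strain expands ``fold_expansion``-fold, i.e. for
    ``t = ln(fold_expansion)`` generations in the assay's natural-log
    convention.  The rival's final abundance is set so that the
    ``S/g = ln(R_f/R_i)/t`` estimator applied to the noiseless counts returns
    exactly ``s`` — the generator is the estimator's algebraic inverse.

    With ``sampling="multinomial"``, ``events`` cytometer events are drawn
    from the true frequencies at each timepoint and rescaled to the true
    population totals, so frequency noise is added while the absolute scale
    (and hence the generation count) is preserved.
    """
    if not 0.0 < initial_focal_fraction < 1.0:
        raise ValueError("initial_focal_fraction must be in (0, 1)")
    if fold_expansion <= 1.0:
        raise ValueError("fold_expansion must be > 1")
    if not -1.0 < s < 1.0:
        raise ValueError("s must be in (-1, 1)")

    t = math.log(fold_expansion)
    fluor_i = initial_total * initial_focal_fraction
    nonfluor_i = initial_total * (1.0 - initial_focal_fraction)
    fluor_f = fluor_i * fold_expansion
    # R_f = R_i * e^(s t)  =>  rival_final = rival_initial * fold * e^(-s t)
    nonfluor_f = nonfluor_i * fold_expansion * math.exp(-s * t)

    if sampling == "noiseless":
        return CompetitionCounts(assay_id, fluor_i, fluor_f, nonfluor_i, nonfluor_f)
    if sampling != "multinomial":
        raise ValueError(f"unknown sampling mode {sampling!r}")
    if events <= 0:
        raise ValueError("events must be > 0 for multinomial sampling")

    rng = np.random.default_rng(seed)

    def sample(fluor: float, nonfluor: float) -> tuple[float, float]:
        total = fluor + nonfluor
        k = rng.binomial(events, fluor / total)
        return k / events * total, (events - k) / events * total

    fluor_i_obs, nonfluor_i_obs = sample(fluor_i, nonfluor_i)
    fluor_f_obs, nonfluor_f_obs = sample(fluor_f, nonfluor_f)
    if fluor_i_obs == 0 or nonfluor_i_obs == 0:
        # initial counts must stay positive; one event's worth is the floor
        floor_i = (fluor_i + nonfluor_i) / events
        fluor_i_obs = fluor_i_obs or floor_i
        nonfluor_i_obs = nonfluor_i_obs or floor_i
    return CompetitionCounts(
        assay_id, fluor_i_obs, fluor_f_obs, nonfluor_i_obs, nonfluor_f_obs
    )


def gen_trajectory(
    community: Community,
    n_transfers: int,
    census_at_transfer: int = 10_000,
    drift: bool = True,
    observation_times: Sequence[float] | None = None,
    seed: int = 0,
) -> FrequencyTrajectory:
    """Focal-strain frequency trajectory observed at sparse timepoints.

    Runs the community-dynamics engine (deterministic when ``drift=False``,
    serial-transfer bottleneck simulation otherwise) and samples the focal
    frequency at ``observation_times`` (generations) by linear interpolation
    between recorded states, mimicking sporadic measurement.
    """
    gpt = generations_per_transfer(500)
    horizon = n_transfers * gpt
    if observation_times is None:
        observation_times = np.arange(0.0, horizon + 1e-9, gpt)
    obs = np.asarray(list(observation_times), dtype=float)
    if len(obs) == 0:
        raise ValueError("observation_times must be non-empty")
    if obs.min() < 0 or obs.max() > horizon + 1e-9:
        raise ValueError("observation_times outside [0, n_transfers * generations/transfer]")

    if drift:
        base = simulate_bottleneck_regime(
            community, n_transfers, census_at_transfer, gpt, seed=seed
        )
    else:
        base = predict_trajectory(community, horizon=max(1, math.ceil(horizon)))
    gens = base.generations
    states = []
    for t in np.unique(obs):
        freqs = np.array(
            [
                np.interp(t, gens, [st.frequencies[i] for st in base.states])
                for i in range(community.n_strains)
            ]
        )
        freqs = np.clip(freqs, 0.0, None)
        freqs /= freqs.sum()
        states.append(FrequencyState(freqs, float(t)))
    return FrequencyTrajectory(states, community.strain_names, community.focal, "observed")


def gen_pileup(
    genome_length: int,
    variant_positions: Sequence[int] = (),
    depth: int = 10,
    error_rate: float = 0.0,
    strand_bias_at: Sequence[int] = (),
    seed: int = 0,
    contig: str = "chrI",
    alt_fraction: float = 0.9,
    base_quality: int = 40,
    mapping_quality: int = 60,
) -> tuple[list[str], GroundTruth]:
    """Samtools-mpileup text with planted SNPs and known truth.

    Emits one 7-column record per position (chrom, 1-based pos, ref, depth,
    read bases, base qualities, mapping qualities).  Reference matches are
    ``.``/``,`` with case encoding strand; read strands alternate so both
    strands are always present.  Planted variants are supported by
    ``alt_fraction`` of the reads split across both strands — except
    positions listed in ``strand_bias_at``, whose supporting reads all sit on
    the forward strand (a strand-bias artifact the caller must reject).
    Non-variant positions acquire random single-read errors at
    ``error_rate``.

    Returns the text lines and the :class:`GroundTruth` carrying the planted
    ``(contig, position, ref, alt)`` tuples (biased decoys included).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    positions = sorted(set(variant_positions) | set(strand_bias_at))
    if positions and (positions[0] < 1 or positions[-1] > genome_length):
        raise ValueError("variant position outside [1, genome_length]")
    biased = set(strand_bias_at)

    rng = np.random.default_rng(seed)
    ref_seq = rng.choice(list(_BASES), size=genome_length)
    bq_char = chr(33 + base_quality)
    mq_char = chr(33 + mapping_quality)
    n_alt = max(1, round(alt_fraction * depth))

    lines: list[str] = []
    truth: list[tuple[str, int, str, str]] = []
    variant_set = set(positions)
    for pos in range(1, genome_length + 1):
        ref = str(ref_seq[pos - 1])
        # read strands alternate: even read index forward, odd reverse
        if pos in variant_set:
            alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
            truth.append((contig, pos, ref, alt))
            bases = []
            for read in range(depth):
                supports = read < n_alt
                if pos in biased:
                    forward = True if supports else (read % 2 == 0)
                else:
                    forward = read % 2 == 0
                if supports:
                    bases.append(alt.upper() if forward else alt.lower())
                else:
                    bases.append("." if forward else ",")
        else:
            bases = []
            for read in range(depth):
                forward = read % 2 == 0
                if error_rate > 0 and rng.random() < error_rate:
                    err = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
                    bases.append(err.upper() if forward else err.lower())
                else:
                    bases.append("." if forward else ",")
        lines.append(
            "\t".join(
                (
                    contig,
                    str(pos),
                    ref,
                    str(depth),
                    "".join(bases),
                    bq_char * depth,
                    mq_char * depth,
                )
            )
        )
    return lines, GroundTruth(
        rng_seed=seed, true_variant_positions=tuple(truth)
    )


# ---------------------------------------------------------------------------
# writers / readers for the plain-text exchange formats


def write_growth_curves_csv(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    """Long-format CSV: well, time_min, od600."""
    rows = [
        {"well": c.well_id, "time_min": t * 60.0, "od600": od}
        for c in curves
        for t, od in zip(c.times, c.od)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_competition_counts_csv(
    counts: Iterable[CompetitionCounts], path: str | Path
) -> None:
    """CSV: assay_id, replicate, timepoint, fluorescent_count, nonfluorescent_count."""
    rows = []
    for rep, c in enumerate(counts):
        rows.append(
            dict(assay_id=c.assay_id, replicate=rep, timepoint="initial",
                 fluorescent_count=c.fluor_initial, nonfluorescent_count=c.nonfluor_initial)
        )
        rows.append(
            dict(assay_id=c.assay_id, replicate=rep, timepoint="final",
                 fluorescent_count=c.fluor_final, nonfluorescent_count=c.nonfluor_final)
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_competition_counts_csv(path: str | Path) -> list[CompetitionCounts]:
    df = pd.read_csv(path)
    required = {"assay_id", "replicate", "timepoint", "fluorescent_count", "nonfluorescent_count"}
    if not required <= set(df.columns):
        raise ValueError(f"competition CSV must have columns {sorted(required)}")
    out = []
    for (assay, _rep), grp in df.groupby(["assay_id", "replicate"], sort=False):
        by_tp = grp.set_index("timepoint")
        try:
            ini = by_tp.loc["initial"]
            fin = by_tp.loc["final"]
        except KeyError as exc:
            raise ValueError(f"assay {assay!r}: missing timepoint {exc}") from exc
        out.append(
            CompetitionCounts(
                str(assay),
                float(ini["fluorescent_count"]),
                float(fin["fluorescent_count"]),
                float(ini["nonfluorescent_count"]),
                float(fin["nonfluorescent_count"]),
            )
        )
    return out


def write_trajectory_csv(
    trajectories: Iterable[FrequencyTrajectory], path: str | Path
) -> None:
    """CSV: replicate, generation, focal_frequency."""
    rows = [
        {"replicate": rep, "generation": g, "focal_frequency": x}
        for rep, traj in enumerate(trajectories)
        for g, x in zip(traj.generations, traj.focal_frequencies)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> list[FrequencyTrajectory]:
    """Read focal-frequency trajectories; strains are summarized as
    focal vs rest because the CSV stores only the focal frequency."""
    df = pd.read_csv(path)
    required = {"replicate", "generation", "focal_frequency"}
    if not required <= set(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    out = []
    for _rep, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("generation")
        states = [
            FrequencyState(np.array([x, 1.0 - x]), float(g))
            for g, x in zip(grp["generation"], grp["focal_frequency"])
        ]
        out.append(FrequencyTrajectory(states, ("focal", "rest"), "focal", "observed"))
    return out


def write_pileup(lines: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(lines) + "\n")
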