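"""Synthetic crossing experiments with the statistical structure the
analysis assumes.

Emulated designs: F2 cohorts drawn from a selfed interspecies
F1 under seed-stage viability selection, per-plant backcross seed counts
with binomial abortion at genotype-determined rates, seed-scoring noise,
F1-selfing seed sets, and RIL panels built by single-seed descent with
selection.  All randomness flows from the single seed in the configuration
(one ``numpy.random.Generator`` stream), so every simulator is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np

from .genetics import (
    ConfigurationError,
    Genotype,
    IncompatibilityModel,
    f1_hybrid,
    pure_selfer,
)
from .crosses import FullyLethalCrossError, self_cross, zygote_distribution
from .inference import PlantRecord
from .prediction import f1_self_abortion_rate, pollen_lethal_fraction

__all__ = [
    "SimulationConfig",
    "simulate_f2_cohort",
    "simulate_backcross_panel",
    "simulate_f1_selfing",
    "simulate_ril_panel",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated crossing experiment.

    Parameters
    ----------
    model:
        The incompatibility model genotypes are drawn under.
    n_plants:
        Number of plants in the panel (default 250, the F2 panel size).
    seeds_per_plant:
        Fixed seed count per plant; when None, counts are drawn from a
        Poisson with mean ``seeds_per_plant_mean`` truncated at 1.
    seeds_per_plant_mean:
        Mean of the truncated Poisson (default 25, a plausible per-plant
        scoring scale for this crucifer).
    epsilon:
        Probability that a seed's aborted/normal call is flipped when
        scoring (default 0.01, below the 2% binarization threshold so
        intra-class noise does not flip binary calls).
    seed:
        The single integer seed governing all draws.
    conditioned:
        Sample F2 genotypes from the survivor distribution (True, the
        default: genotyped plants survived the seed-abortion episode) or
        from the unconditioned zygote distribution.
    overdispersion:
        Optional beta-binomial intra-plant correlation rho in (0, 1); when
        set, each plant's realised abortion probability is drawn from a
        Beta with mean at the genotype rate.  Off by default.
    """

    model: IncompatibilityModel = IncompatibilityModel(1, 3)
    n_plants: int = 250
    seeds_per_plant: Optional[int] = None
    seeds_per_plant_mean: float = 25.0
    epsilon: float = 0.01
    seed: int = 0
    conditioned: bool = True
    overdispersion: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ConfigurationError(
                f"n_plants must be >= 1, got {self.n_plants}"
            )
        if not 0.0 <= self.epsilon < 0.5:
            raise ConfigurationError(
                f"scoring-noise epsilon must lie in [0, 0.5), "
                f"got {self.epsilon}"
            )
        if self.seeds_per_plant is not None and self.seeds_per_plant < 1:
            raise ConfigurationError("seeds_per_plant must be >= 1")
        if self.seeds_per_plant is None and self.seeds_per_plant_mean <= 0:
            raise ConfigurationError("seeds_per_plant_mean must be > 0")
        if self.overdispersion is not None and not (
            0.0 < self.overdispersion < 1.0
        ):
            raise ConfigurationError("overdispersion rho must lie in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _flip(rate: float, epsilon: float) -> float:
    """Rate seen through symmetric per-seed mis-scoring."""
    return rate * (1.0 - epsilon) + (1.0 - rate) * epsilon


def _draw_seed_counts(
    config: SimulationConfig, size: int, rng: np.random.Generator
) -> np.ndarray:
    if config.seeds_per_plant is not None:
        return np.full(size, config.seeds_per_plant, dtype=int)
    counts = rng.poisson(config.seeds_per_plant_mean, size=size)
    # truncate at 1: redraw zeros (rare for the default mean)
    while True:
        zeros = counts == 0
        if not zeros.any():
            return counts
        counts[zeros] = rng.poisson(config.seeds_per_plant_mean, int(zeros.sum()))


def _sample_from_rational(
    distribution, size: int, rng: np.random.Generator
) -> list:
    """Inverse-CDF draws from an exact rational distribution."""
    items = sorted(distribution.items(), key=lambda kv: str(kv[0]))
    cum = np.cumsum([float(p) for _, p in items])
    cum[-1] = 1.0
    idx = np.searchsorted(cum, rng.random(size), side="right")
    return [items[i][0] for i in idx]


def simulate_f2_cohort(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[Genotype]:
    """Draw an F2 cohort from the selfed interspecies F1.

    Genotypes come from the exact survivor distribution of the selfed F1
    (or the unconditioned zygote distribution when
    ``config.conditioned`` is False) by inverse-CDF sampling; no rejection
    loop is needed.
    """
    if rng is None:
        rng = config.rng()
    f1 = f1_hybrid(config.model)
    if config.conditioned:
        outcome = self_cross(f1, config.model)
        if outcome.is_fully_lethal:
            raise FullyLethalCrossError("selfed F1 left no viable seeds")
        dist = outcome.survivors
    else:
        dist = zygote_distribution(f1, f1, config.model)
    return _sample_from_rational(dist, config.n_plants, rng)


def simulate_backcross_panel(
    cohort: Sequence[Genotype],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    tester: Optional[Genotype] = None,
) -> list[PlantRecord]:
    """Score each cohort plant as a pollen donor on the tester.

    For each plant, the number of seeds scored is drawn from the
    seeds-per-plant distribution and the number aborted is Binomial at the
    genotype's pollen lethal fraction flipped through the scoring noise
    ``epsilon``.
    """
    if rng is None:
        rng = config.rng()
    if tester is None:
        tester = pure_selfer(config.model)
    n_seeds = _draw_seed_counts(config, len(cohort), rng)
    rates = np.array(
        [
            _flip(
                float(pollen_lethal_fraction(g, tester, config.model)),
                config.epsilon,
            )
            for g in cohort
        ]
    )
    if config.overdispersion is not None:
        rho = config.overdispersion
        scale = (1.0 - rho) / rho
        # Beta draws keep the mean at the genotype rate; degenerate rates
        # 0 and 1 stay fixed points only when epsilon is also 0.
        safe = np.clip(rates, 1e-12, 1.0 - 1e-12)
        rates = rng.beta(safe * scale, (1.0 - safe) * scale)
    n_aborted = rng.binomial(n_seeds, rates)
    return [
        PlantRecord(f"plant_{i + 1:04d}", int(n), int(k))
        for i, (n, k) in enumerate(zip(n_seeds, n_aborted))
    ]


def simulate_f1_selfing(
    config: SimulationConfig,
    n_mother_plants: int = 7,
    seeds_per_mother: Union[int, Sequence[int], None] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[PlantRecord]:
    """Simulate seed sets of selfed interspecies F1 mothers.

    Each seed independently dies with probability
    :func:`bdmseed.prediction.f1_self_abortion_rate` flipped through the
    scoring noise.  ``seeds_per_mother`` may be a fixed count, a per-mother
    sequence, or None to draw from the seeds-per-plant distribution.
    """
    if rng is None:
        rng = config.rng()
    if n_mother_plants < 1:
        raise ConfigurationError("n_mother_plants must be >= 1")
    if seeds_per_mother is None:
        counts = _draw_seed_counts(config, n_mother_plants, rng)
    elif isinstance(seeds_per_mother, int):
        counts = np.full(n_mother_plants, seeds_per_mother, dtype=int)
    else:
        counts = np.asarray(list(seeds_per_mother), dtype=int)
        if len(counts) != n_mother_plants:
            raise ConfigurationError(
                "seeds_per_mother sequence length must equal n_mother_plants"
            )
    if (counts < 1).any():
        raise ConfigurationError("every mother must contribute >= 1 seed")
    rate = _flip(float(f1_self_abortion_rate(config.model)), config.epsilon)
    aborted = rng.binomial(counts, rate)
    return [
        PlantRecord(f"mother_{i + 1:02d}", int(n), int(k))
        for i, (n, k) in enumerate(zip(counts, aborted))
    ]


def simulate_ril_panel(
    config: SimulationConfig,
    n_generations: int,
    n_lines: int,
    rng: Optional[np.random.Generator] = None,
    selection: bool = True,
) -> list[Genotype]:
    """Sample RIL terminal genotypes by single-seed descent.

    Each line starts at the F1 and advances by drawing one surviving seed
    per generation from the exact survivor distribution of its self-cross
    (viability selection applied each generation unless ``selection`` is
    False).  Pair with :func:`simulate_backcross_panel` to emulate a RIL
    phenotyping cross.
    """
    if rng is None:
        rng = config.rng()
    if n_generations < 1:
        raise ConfigurationError("n_generations must be >= 1")
    if n_lines < 1:
        raise ConfigurationError("n_lines must be >= 1")
    model = config.model
    # Lines are exchangeable, so they are advanced in genotype groups: one
    # multinomial draw per distinct genotype has the same joint law as
    # independent per-line draws and keeps large panels fast.
    counts: dict[Genotype, int] = {f1_hybrid(model): n_lines}
    for _ in range(n_generations):
        nxt: dict[Genotype, int] = {}
        for genotype, n in sorted(
            counts.items(), key=lambda kv: str(kv[0].maternal) + str(kv[0].paternal)
        ):
            if selection:
                outcome = self_cross(genotype, model)
                if outcome.is_fully_lethal:
                    raise FullyLethalCrossError(
                        "self-cross of a surviving line has no viable seeds"
                    )
                dist = outcome.survivors
            else:
                dist = zygote_distribution(genotype, genotype, model)
            items = sorted(dist.items(), key=lambda kv: str(kv[0].maternal))
            probs = np.array([float(p) for _, p in items])
            probs /= probs.sum()
            drawn = rng.multinomial(n, probs)
            for (child, _), k in zip(items, drawn):
                if k:
                    nxt[child] = nxt.get(child, 0) + int(k)
        counts = nxt
    lines: list[Genotype] = []
    for genotype, n in counts.items():
        lines.extend([genotype] * n)
    return lines
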