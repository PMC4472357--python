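"""Exact cross outcomes with seed-stage viability selection, and
single-seed-descent propagation of recombinant inbred lines (RILs).

All distributions here are expectations over an effectively infinite seed
pool, held as exact rationals; finite-sample noise is the job of
:mod:`bdmseed.simulate`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Mapping

from .genetics import (
    ConfigurationError,
    Fate,
    Genotype,
    IncompatibilityModel,
    enumerate_gametes,
    f1_hybrid,
    genotype_fate,
    pure_outcrosser,
    pure_selfer,
    seed_fate,
)

__all__ = [
    "CrossOutcome",
    "GenerationState",
    "RILPanel",
    "FullyLethalCrossError",
    "cross",
    "self_cross",
    "zygote_distribution",
    "advance_ssd",
    "ril_panel_distribution",
    "can_trigger_abortion",
]


class FullyLethalCrossError(RuntimeError):
    """Raised when offspring are requested from a cross with no survivors."""


@dataclass(frozen=True)
class CrossOutcome:
    """Result of one cross under seed-stage viability selection.

    ``survivors`` maps ordered offspring genotypes to their exact frequency
    *among viable seeds* (renormalised); ``abortion_rate`` is the lethal
    probability mass before conditioning.  When ``abortion_rate == 1`` the
    survivor map is empty and :attr:`is_fully_lethal` is set so callers
    cannot silently draw offspring.
    """

    survivors: Mapping[Genotype, Fraction]
    abortion_rate: Fraction

    def __post_init__(self) -> None:
        if not 0 <= self.abortion_rate <= 1:
            raise ConfigurationError(
                f"abortion rate {self.abortion_rate} outside [0, 1]"
            )
        total = sum(self.survivors.values(), Fraction(0))
        if self.abortion_rate == 1:
            if self.survivors:
                raise ConfigurationError(
                    "fully lethal cross must have an empty survivor map"
                )
        elif total != 1:
            raise ConfigurationError(
                f"survivor frequencies sum to {total}, expected 1"
            )

    @property
    def is_fully_lethal(self) -> bool:
        return self.abortion_rate == 1


@dataclass(frozen=True)
class GenerationState:
    """Distribution of line genotypes at a given selfing generation."""

    frequencies: Mapping[Genotype, Fraction]
    generation: int = 0

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values(), Fraction(0))
        if total != 1:
            raise ConfigurationError(
                f"generation-state frequencies sum to {total}, expected 1"
            )


@dataclass(frozen=True)
class RILPanel:
    """Exact genotype distribution of a RIL panel plus its purging summary.

    ``abortion_triggering_fraction`` is the probability mass of lines whose
    genotype would cause a nonzero seed-abortion rate when used as a pollen
    donor on the selfer tester (the panel's phenotyping cross).
    """

    state: GenerationState
    abortion_triggering_fraction: Fraction

    @property
    def zero_abortion_fraction(self) -> Fraction:
        return 1 - self.abortion_triggering_fraction


@lru_cache(maxsize=None)
def _cross_cached(
    maternal: Genotype, paternal: Genotype, model: IncompatibilityModel
) -> CrossOutcome:
    eggs = enumerate_gametes(maternal, model)
    pollen = enumerate_gametes(paternal, model)
    lethal = Fraction(0)
    survivors: dict[Genotype, Fraction] = defaultdict(Fraction)
    for egg, p_egg in eggs.items():
        for sperm, p_sperm in pollen.items():
            prob = p_egg * p_sperm
            if seed_fate(egg, sperm, model) is Fate.LETHAL:
                lethal += prob
            else:
                survivors[Genotype.from_haplotypes(egg, sperm)] += prob
    if lethal == 1:
        return CrossOutcome({}, Fraction(1))
    viable = 1 - lethal
    return CrossOutcome(
        {g: p / viable for g, p in survivors.items()}, lethal
    )


def cross(
    maternal: Genotype, paternal: Genotype, model: IncompatibilityModel
) -> CrossOutcome:
    """Exact offspring distribution of ``maternal`` x ``paternal``.

    Enumerates the product of the two Mendelian gamete distributions,
    accumulates the lethal mass as ``abortion_rate`` and renormalises the
    viable ordered genotypes by ``1 - abortion_rate``.
    """
    return _cross_cached(maternal, paternal, model)


def self_cross(genotype: Genotype, model: IncompatibilityModel) -> CrossOutcome:
    """Self-pollination: ``cross(g, g, model)``."""
    return cross(genotype, genotype, model)


@lru_cache(maxsize=None)
def zygote_distribution(
    maternal: Genotype, paternal: Genotype, model: IncompatibilityModel
) -> Mapping[Genotype, Fraction]:
    """Unconditioned zygote distribution (viability selection switched off).

    Includes lethal genotype classes at their Mendelian frequencies; a
    zygote's fate can still be read off with
    :func:`bdmseed.genetics.genotype_fate`.
    """
    eggs = enumerate_gametes(maternal, model)
    pollen = enumerate_gametes(paternal, model)
    out: dict[Genotype, Fraction] = defaultdict(Fraction)
    for egg, p_egg in eggs.items():
        for sperm, p_sperm in pollen.items():
            out[Genotype.from_haplotypes(egg, sperm)] += p_egg * p_sperm
    return dict(out)


def advance_ssd(
    state: GenerationState,
    model: IncompatibilityModel,
    selection: bool = True,
) -> GenerationState:
    """Advance a single-seed-descent population by one selfing generation.

    Each line's next state is the survivor distribution of its self-cross
    (viability selection applied every generation unless ``selection`` is
    False); the population state is the mixture weighted by the current line
    frequencies.  Selfing a surviving plant always leaves viable mass under
    this model, so a fully lethal self-cross indicates a corrupted state.
    """
    nxt: dict[Genotype, Fraction] = defaultdict(Fraction)
    for genotype, freq in state.frequencies.items():
        if selection:
            outcome = self_cross(genotype, model)
            if outcome.is_fully_lethal:
                raise FullyLethalCrossError(
                    f"self-cross of a surviving line has no viable seeds: "
                    f"{genotype.to_string(model)}"
                )
            offspring = outcome.survivors
        else:
            offspring = zygote_distribution(genotype, genotype, model)
        for child, p in offspring.items():
            nxt[child] += freq * p
    return GenerationState(dict(nxt), state.generation + 1)


def can_trigger_abortion(
    genotype: Genotype, model: IncompatibilityModel
) -> bool:
    """Would this plant, as pollen donor on the selfer tester, abort any seeds?

    The selfer tester is homozygous for the incompatible maternal allele, so
    every one of its maternal gametes completes the maternal half of the
    lethal conjunction; the donor triggers abortion iff it can transmit the
    incompatible allele at every paternal locus, i.e. carries at least one
    incompatible copy at each paternal locus.
    """
    m = model.n_maternal_loci
    return all(
        genotype.maternal[i] or genotype.paternal[i]
        for i in range(m, model.n_loci)
    )


def ril_panel_distribution(
    model: IncompatibilityModel,
    n_generations: int,
    selection: bool = True,
) -> RILPanel:
    """Exact RIL-panel genotype distribution after single-seed descent.

    Starts from the F1 of outcrosser seed parent x selfer pollen donor and
    applies ``n_generations`` rounds of :func:`advance_ssd`.  Also reports
    the fraction of lines that would trigger >0 abortion as pollen donors on
    the selfer tester — the quantity that shrinks as incompatibility alleles
    are purged.
    """
    if n_generations < 0:
        raise ConfigurationError("n_generations must be >= 0")
    state = GenerationState({f1_hybrid(model): Fraction(1)}, 0)
    for _ in range(n_generations):
        state = advance_ssd(state, model, selection=selection)
    triggering = sum(
        (
            freq
            for genotype, freq in state.frequencies.items()
            if can_trigger_abortion(genotype, model)
        ),
        Fraction(0),
    )
    return RILPanel(state, triggering)
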