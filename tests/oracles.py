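"""Independent brute-force oracles for the exact genetic machinery.

Everything here re-derives expectations from first principles — explicit
enumeration of per-locus allele picks — without touching the package's
gamete-distribution, cross or class-distribution code paths, so tests can
confront the implementation with a genuinely independent computation.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product

from bdmseed.genetics import Genotype, IncompatibilityModel


def brute_force_cross(
    maternal: Genotype, paternal: Genotype, model: IncompatibilityModel
):
    """Enumerate all 4**L equally weighted ordered gamete-pair origins.

    Each parent transmits, per locus, either its maternally or paternally
    inherited allele (2**L picks per parent).  Returns
    ``(lethal_mass, survivors)`` where survivors maps
    ``(egg_tuple, sperm_tuple)`` to renormalised frequency.
    """
    L = model.n_loci
    m = model.n_maternal_loci
    weight = Fraction(1, 4**L)
    lethal = Fraction(0)
    survivors: dict[tuple, Fraction] = {}
    for egg_pick in product((0, 1), repeat=L):
        egg = tuple(
            maternal.maternal[i] if c == 0 else maternal.paternal[i]
            for i, c in enumerate(egg_pick)
        )
        for sperm_pick in product((0, 1), repeat=L):
            sperm = tuple(
                paternal.maternal[i] if c == 0 else paternal.paternal[i]
                for i, c in enumerate(sperm_pick)
            )
            if all(egg[:m]) and all(sperm[m:]):
                lethal += weight
            else:
                key = (egg, sperm)
                survivors[key] = survivors.get(key, Fraction(0)) + weight
    if lethal < 1:
        viable = 1 - lethal
        survivors = {k: v / viable for k, v in survivors.items()}
    return lethal, survivors


def brute_force_pollen_fraction(
    donor_egg: tuple, donor_sperm: tuple, model: IncompatibilityModel
) -> Fraction:
    """Fraction of the donor's 2**L gamete picks carrying the full paternal
    incompatible complement (the abortion rate on the homozygous selfer
    tester, whose maternal gametes always complete the maternal half)."""
    L = model.n_loci
    m = model.n_maternal_loci
    hits = 0
    for pick in product((0, 1), repeat=L):
        gamete = tuple(
            donor_egg[i] if c == 0 else donor_sperm[i]
            for i, c in enumerate(pick)
        )
        if all(gamete[m:]):
            hits += 1
    return Fraction(hits, 2**L)


def brute_force_f2_classes(
    model: IncompatibilityModel, conditioned: bool = True
) -> dict[Fraction, Fraction]:
    """F2 abortion-rate class distribution by exhaustive enumeration.

    The F1 is heterozygous everywhere (maternally inherited haplotype from
    the outcrosser, paternally from the selfer).  Enumerates all ordered F2
    gamete-pair origins, optionally removes lethal ones and renormalises,
    then classifies every (surviving) genotype by its pollen fraction.
    """
    m = model.n_maternal_loci
    L = model.n_loci
    outcrosser_gamete = tuple(i >= m for i in range(L))
    selfer_gamete = tuple(i < m for i in range(L))
    f1 = Genotype(outcrosser_gamete, selfer_gamete)
    lethal, survivors = brute_force_cross(f1, f1, model)
    if not conditioned:
        weight = Fraction(1, 4**L)
        survivors = {}
        for egg_pick in product((0, 1), repeat=L):
            egg = tuple(
                f1.maternal[i] if c == 0 else f1.paternal[i]
                for i, c in enumerate(egg_pick)
            )
            for sperm_pick in product((0, 1), repeat=L):
                sperm = tuple(
                    f1.maternal[i] if c == 0 else f1.paternal[i]
                    for i, c in enumerate(sperm_pick)
                )
                key = (egg, sperm)
                survivors[key] = survivors.get(key, Fraction(0)) + weight
    classes: dict[Fraction, Fraction] = {}
    for (egg, sperm), freq in survivors.items():
        rate = brute_force_pollen_fraction(egg, sperm, model)
        classes[rate] = classes.get(rate, Fraction(0)) + freq
    return classes


def markov_ssd(
    model: IncompatibilityModel,
    n_generations: int,
    selection: bool = True,
) -> dict[tuple, Fraction]:
    """Single-seed-descent genotype chain driven by the brute-force cross.

    State: mapping (egg_tuple, sperm_tuple) -> probability.  Transitions use
    :func:`brute_force_cross` (with or without viability selection) so the
    chain never calls the package's cross engine.
    """
    m = model.n_maternal_loci
    L = model.n_loci
    outcrosser_gamete = tuple(i >= m for i in range(L))
    selfer_gamete = tuple(i < m for i in range(L))
    state = {(outcrosser_gamete, selfer_gamete): Fraction(1)}
    for _ in range(n_generations):
        nxt: dict[tuple, Fraction] = {}
        for (egg, sperm), freq in state.items():
            genotype = Genotype(egg, sperm)
            lethal, survivors = brute_force_cross(genotype, genotype, model)
            if not selection:
                weight = Fraction(1, 4**L)
                survivors = {}
                for egg_pick in product((0, 1), repeat=L):
                    e = tuple(
                        egg[i] if c == 0 else sperm[i]
                        for i, c in enumerate(egg_pick)
                    )
                    for sperm_pick in product((0, 1), repeat=L):
                        s = tuple(
                            egg[i] if c == 0 else sperm[i]
                            for i, c in enumerate(sperm_pick)
                        )
                        survivors[(e, s)] = survivors.get(
                            (e, s), Fraction(0)
                        ) + weight
            for key, p in survivors.items():
                nxt[key] = nxt.get(key, Fraction(0)) + freq * p
        state = nxt
    return state


def markov_triggering_fraction(
    model: IncompatibilityModel, n_generations: int, selection: bool = True
) -> Fraction:
    """Mass of SSD lines able to transmit the full paternal complement."""
    state = markov_ssd(model, n_generations, selection)
    return sum(
        (
            freq
            for (egg, sperm), freq in state.items()
            if brute_force_pollen_fraction(egg, sperm, model) > 0
        ),
        Fraction(0),
    )


def wilson_interval(k: int, n: int, z: float = 1.959963984540054):
    """Closed-form Wilson score interval, written out from the formula."""
    phat = k / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * ((phat * (1 - phat) / n + z**2 / (4 * n**2)) ** 0.5) / denom
    return centre - half, centre + half
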