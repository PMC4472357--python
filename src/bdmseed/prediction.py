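"""Predicted seed-abortion rates and the theoretical F2 class distribution.

The headline quantities of the model:

* the *pollen lethal fraction* — the probability that a random pollen grain
  of a donor plant, united with a maternal gamete of a tester, forms a
  lethal seed; on the selfer tester this is the donor's predicted
  seed-abortion rate and takes only the exact class values
  ``prod over paternal loci of {0, 1/2, 1}``;
* the theoretical distribution of F2 plants over those abortion-rate
  classes, computed on the survivor-conditioned F2 panel (the plants that
  can be grown and backcrossed are necessarily survivors of the F2
  seed-abortion episode); the unconditioned variant is exposed for
  comparison;
* the expected abortion rate of selfed F1 seeds, ``(1/2)**(m+p)``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Mapping, Optional

import pandas as pd

from .genetics import (
    Fate,
    Genotype,
    IncompatibilityModel,
    enumerate_gametes,
    f1_hybrid,
    pure_selfer,
    seed_fate,
)
from .crosses import self_cross, zygote_distribution

__all__ = [
    "AbortionClassDistribution",
    "pollen_lethal_fraction",
    "f2_class_distribution",
    "f1_self_abortion_rate",
]


@dataclass(frozen=True)
class AbortionClassDistribution:
    """Distribution of plants over exact abortion-rate classes.

    ``frequencies`` maps each exact-rational abortion-rate class to the
    exact-rational frequency of plants in that class; frequencies sum to 1.
    For one maternal and three paternal loci the realizable classes are
    {0, 1/8, 1/4, 1/2, 1}; for two paternal loci, {0, 1/4, 1/2, 1}.
    """

    frequencies: Mapping[Fraction, Fraction]
    model: IncompatibilityModel
    conditioned: bool = True

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values(), Fraction(0))
        if total != 1:
            raise ValueError(f"class frequencies sum to {total}, expected 1")

    @property
    def classes(self) -> tuple[Fraction, ...]:
        """Realized abortion-rate classes in ascending order."""
        return tuple(sorted(self.frequencies))

    def __getitem__(self, rate: Fraction) -> Fraction:
        return self.frequencies.get(Fraction(rate), Fraction(0))

    def to_frame(self) -> pd.DataFrame:
        """Tabular rendering: one row per class, exact and float columns."""
        rows = [
            {
                "class_rate_fraction": str(rate),
                "class_rate_percent": float(rate) * 100.0,
                "frequency_fraction": str(freq),
                "frequency_float": float(freq),
            }
            for rate, freq in sorted(self.frequencies.items())
        ]
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Bar plot of class frequencies (percent abortion on the x axis)."""
        import matplotlib.pyplot as plt  # optional dependency

        if ax is None:
            _, ax = plt.subplots()
        rates = [float(r) * 100 for r in self.classes]
        freqs = [float(self.frequencies[r]) for r in self.classes]
        ax.bar(range(len(rates)), freqs, tick_label=[f"{r:g}%" for r in rates])
        ax.set_xlabel("seed abortion rate class")
        ax.set_ylabel("frequency of plants")
        ax.set_title(self.model.describe())
        return ax


@lru_cache(maxsize=None)
def pollen_lethal_fraction(
    donor: Genotype,
    tester_maternal: Genotype,
    model: IncompatibilityModel,
) -> Fraction:
    """Predicted seed-abortion rate of ``donor`` pollen on ``tester_maternal``.

    Sums P(maternal gamete) x P(pollen haplotype) over all lethal pairs,
    using the tester's gamete distribution for the maternal side.  For a
    tester homozygous for the maternal incompatible allele this reduces to
    the fraction of donor pollen carrying the full paternal incompatible
    complement.
    """
    eggs = enumerate_gametes(tester_maternal, model)
    pollen = enumerate_gametes(donor, model)
    return sum(
        (
            p_egg * p_sperm
            for egg, p_egg in eggs.items()
            for sperm, p_sperm in pollen.items()
            if seed_fate(egg, sperm, model) is Fate.LETHAL
        ),
        Fraction(0),
    )


def f1_self_abortion_rate(model: IncompatibilityModel) -> Fraction:
    """Expected abortion rate among seeds of a selfed interspecies F1.

    The F1 is heterozygous at every locus, so the lethal gamete pair occurs
    with probability ``(1/2)**(m+p)`` — 1/16 for one maternal and three
    paternal loci, 1/8 for two paternal loci.
    """
    f1 = f1_hybrid(model)
    return self_cross(f1, model).abortion_rate


def f2_class_distribution(
    model: IncompatibilityModel,
    conditioned: bool = True,
    tester: Optional[Genotype] = None,
) -> AbortionClassDistribution:
    """Theoretical distribution of F2 plants over abortion-rate classes.

    Builds the F1 (outcrosser seed parent x selfer pollen donor), selfs it,
    and classifies each F2 genotype by its pollen lethal fraction on the
    tester (default: the pure selfer, matching the backcross design).

    With ``conditioned=True`` (default) the F2 genotype distribution is the
    *survivor* distribution of the selfed F1: the dead class — seeds
    inheriting the incompatible maternal allele together with the full
    paternal complement — never grows into a plant that could be
    backcrossed.  Conditioning changes the answer (e.g. the 100% class is
    1/120 conditioned vs 1/64 unconditioned for three paternal loci).
    """
    f1 = f1_hybrid(model)
    if conditioned:
        f2 = self_cross(f1, model).survivors
    else:
        f2 = zygote_distribution(f1, f1, model)
    if tester is None:
        tester = pure_selfer(model)
    classes: dict[Fraction, Fraction] = defaultdict(Fraction)
    for genotype, freq in f2.items():
        classes[pollen_lethal_fraction(genotype, tester, model)] += freq
    return AbortionClassDistribution(dict(classes), model, conditioned)
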