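"""Allele-origin coding, Mendelian gamete enumeration and the lethality rule.

The hybrid seed barrier modelled here is a parent-of-origin-aware
Bateson-Dobzhansky-Muller (BDM) incompatibility between a selfing species
(the seed parent side, carrying the incompatible *maternal* allele, written
``R``) and an outcrossing species (contributing the incompatible *paternal*
alleles, written ``A``, ``B``, ``C``, ...).  A seed dies exactly when

* its maternal gamete carries the incompatible selfer-origin allele at
  **every** maternal-incompatibility locus, and
* its paternal gamete carries the incompatible outcrosser-origin allele at
  **every** paternal-incompatibility locus.

Parent of origin matters: swapping the two gametes can change the fate, which
is what makes the barrier non-reciprocal.  All loci are unlinked and all
probabilities are exact :class:`fractions.Fraction` rationals.

Genotype strings use the ``Rr|AaBbCc`` dialect: maternal-locus block, pipe,
paternal-locus block; within each locus the maternally inherited allele is
written first and the incompatible allele is uppercase.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Mapping

__all__ = [
    "ConfigurationError",
    "GenotypeParseError",
    "Fate",
    "IncompatibilityModel",
    "Haplotype",
    "Genotype",
    "GameteDistribution",
    "enumerate_gametes",
    "seed_fate",
    "genotype_fate",
    "pure_selfer",
    "pure_outcrosser",
    "f1_hybrid",
]

_MATERNAL_ALPHABET = "RSTUVWXYZ"
_PATERNAL_ALPHABET = "ABCDEFGHIJ"


class ConfigurationError(ValueError):
    """Invalid model parameters or a model/genotype mismatch."""


class GenotypeParseError(ConfigurationError):
    """A genotype string does not follow the ``Rr|AaBbCc`` dialect."""


class Fate(enum.Enum):
    """Fate of a single seed (embryo) formed by a gamete pair."""

    VIABLE = "viable"
    LETHAL = "lethal"


@dataclass(frozen=True)
class IncompatibilityModel:
    """A fixed-conjunction BDM lethality model.

    Parameters
    ----------
    n_maternal_loci:
        Number of maternal-incompatibility loci (labelled ``R``, ``S``, ...).
        The incompatible allele at these loci is the selfer-origin allele.
    n_paternal_loci:
        Number of paternal-incompatibility loci (labelled ``A``, ``B``, ...).
        The incompatible allele at these loci is the outcrosser-origin allele.

    All loci are unlinked; the lethality rule is the fixed conjunction over
    all loci implemented by :func:`seed_fate` and is not configurable.
    """

    n_maternal_loci: int = 1
    n_paternal_loci: int = 3

    def __post_init__(self) -> None:
        if self.n_maternal_loci < 1:
            raise ConfigurationError(
                f"need at least one maternal-incompatibility locus, "
                f"got {self.n_maternal_loci}"
            )
        if self.n_paternal_loci < 1:
            raise ConfigurationError(
                f"need at least one paternal-incompatibility locus, "
                f"got {self.n_paternal_loci}"
            )
        if self.n_maternal_loci > len(_MATERNAL_ALPHABET):
            raise ConfigurationError("too many maternal loci to label")
        if self.n_paternal_loci > len(_PATERNAL_ALPHABET):
            raise ConfigurationError("too many paternal loci to label")

    @property
    def n_loci(self) -> int:
        return self.n_maternal_loci + self.n_paternal_loci

    @property
    def maternal_labels(self) -> tuple[str, ...]:
        return tuple(_MATERNAL_ALPHABET[: self.n_maternal_loci])

    @property
    def paternal_labels(self) -> tuple[str, ...]:
        return tuple(_PATERNAL_ALPHABET[: self.n_paternal_loci])

    @property
    def locus_labels(self) -> tuple[str, ...]:
        """Ordered locus labels, maternal loci first."""
        return self.maternal_labels + self.paternal_labels

    def is_maternal_locus(self, index: int) -> bool:
        return index < self.n_maternal_loci

    def describe(self) -> str:
        return (
            f"{self.n_maternal_loci} maternal x "
            f"{self.n_paternal_loci} paternal loci"
        )


@dataclass(frozen=True)
class Haplotype:
    """A single gamete's allele-origin vector.

    ``carries[i]`` is True when the gamete carries the *incompatible* allele
    at locus ``i`` (selfer-origin at maternal loci, outcrosser-origin at
    paternal loci).
    """

    carries: tuple[bool, ...]

    def __len__(self) -> int:
        return len(self.carries)

    def to_string(self, model: IncompatibilityModel) -> str:
        _check_length(len(self), model)
        return "".join(
            label if c else label.lower()
            for label, c in zip(model.locus_labels, self.carries)
        )


@dataclass(frozen=True)
class Genotype:
    """An ordered diploid genotype tracking parent of origin.

    ``maternal[i]`` / ``paternal[i]`` record whether the allele inherited
    from the seed parent / pollen parent at locus ``i`` is the incompatible
    one.  Ordered genotypes are kept throughout because downstream lethality
    is parent-of-origin aware.
    """

    maternal: tuple[bool, ...]
    paternal: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.maternal) != len(self.paternal):
            raise ConfigurationError(
                "maternal and paternal allele vectors differ in length"
            )

    def __len__(self) -> int:
        return len(self.maternal)

    @property
    def maternal_haplotype(self) -> Haplotype:
        return Haplotype(self.maternal)

    @property
    def paternal_haplotype(self) -> Haplotype:
        return Haplotype(self.paternal)

    def is_heterozygous(self, index: int) -> bool:
        return self.maternal[index] != self.paternal[index]

    @property
    def n_heterozygous(self) -> int:
        return sum(m != p for m, p in zip(self.maternal, self.paternal))

    def unordered(self) -> tuple[frozenset[bool] | tuple[bool, ...], ...]:
        """Order-insensitive view: per-locus sorted allele pairs."""
        return tuple(
            tuple(sorted((m, p))) for m, p in zip(self.maternal, self.paternal)
        )

    @classmethod
    def from_haplotypes(cls, maternal: Haplotype, paternal: Haplotype) -> "Genotype":
        return cls(maternal.carries, paternal.carries)

    def to_string(self, model: IncompatibilityModel) -> str:
        _check_length(len(self), model)
        parts = []
        for i, label in enumerate(model.locus_labels):
            a = label if self.maternal[i] else label.lower()
            b = label if self.paternal[i] else label.lower()
            parts.append(a + b)
        m = model.n_maternal_loci
        return "".join(parts[:m]) + "|" + "".join(parts[m:])

    @classmethod
    def from_string(cls, text: str, model: IncompatibilityModel) -> "Genotype":
        """Parse the ``Rr|AaBbCc`` dialect; whitespace is ignored."""
        compact = re.sub(r"\s+", "", text)
        blocks = compact.split("|")
        if len(blocks) != 2:
            raise GenotypeParseError(
                f"expected exactly one '|' separator in genotype {text!r}"
            )
        merged = blocks[0] + blocks[1]
        if len(blocks[0]) != 2 * model.n_maternal_loci or len(
            merged
        ) != 2 * model.n_loci:
            raise GenotypeParseError(
                f"genotype {text!r} does not match {model.describe()}"
            )
        maternal: list[bool] = []
        paternal: list[bool] = []
        for i, label in enumerate(model.locus_labels):
            pair = merged[2 * i : 2 * i + 2]
            for char, dest in zip(pair, (maternal, paternal)):
                if char.upper() != label:
                    raise GenotypeParseError(
                        f"unexpected allele token {char!r} at locus {label} "
                        f"in genotype {text!r}"
                    )
                dest.append(char.isupper())
        return cls(tuple(maternal), tuple(paternal))


@dataclass(frozen=True)
class GameteDistribution:
    """Exact Mendelian transmission distribution of one parent's gametes."""

    probabilities: Mapping[Haplotype, Fraction]

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values(), Fraction(0))
        if total != 1:
            raise ConfigurationError(
                f"gamete probabilities sum to {total}, expected 1"
            )

    def items(self) -> Iterator[tuple[Haplotype, Fraction]]:
        return iter(self.probabilities.items())

    def __getitem__(self, haplotype: Haplotype) -> Fraction:
        return self.probabilities.get(haplotype, Fraction(0))

    def __len__(self) -> int:
        return len(self.probabilities)


def _check_length(length: int, model: IncompatibilityModel) -> None:
    if length != model.n_loci:
        raise ConfigurationError(
            f"length {length} does not match model with {model.n_loci} loci"
        )


def enumerate_gametes(
    genotype: Genotype, model: IncompatibilityModel
) -> GameteDistribution:
    """Enumerate all gametes of ``genotype`` with exact Mendelian probabilities.

    Each heterozygous locus transmits either allele with probability 1/2;
    homozygous loci transmit their single allele with probability 1.  The
    support therefore has size ``2**n_heterozygous`` and probabilities sum
    to exactly 1.
    """
    _check_length(len(genotype), model)
    half = Fraction(1, 2)
    partial: dict[tuple[bool, ...], Fraction] = {(): Fraction(1)}
    for m_allele, p_allele in zip(genotype.maternal, genotype.paternal):
        if m_allele == p_allele:
            options = ((m_allele, Fraction(1)),)
        else:
            options = ((m_allele, half), (p_allele, half))
        partial = {
            prefix + (allele,): prob * q
            for prefix, prob in partial.items()
            for allele, q in options
        }
    return GameteDistribution(
        {Haplotype(carries): prob for carries, prob in partial.items()}
    )


def seed_fate(
    maternal_gamete: Haplotype,
    paternal_gamete: Haplotype,
    model: IncompatibilityModel,
) -> Fate:
    """Fate of the seed formed by a (maternal, paternal) gamete pair.

    Lethal iff the maternal gamete carries the incompatible allele at every
    maternal locus AND the paternal gamete carries the incompatible allele at
    every paternal locus.  Swapping the gametes can change the fate.
    """
    _check_length(len(maternal_gamete), model)
    _check_length(len(paternal_gamete), model)
    m = model.n_maternal_loci
    maternal_hit = all(maternal_gamete.carries[:m])
    paternal_hit = all(paternal_gamete.carries[m:])
    return Fate.LETHAL if maternal_hit and paternal_hit else Fate.VIABLE


def genotype_fate(genotype: Genotype, model: IncompatibilityModel) -> Fate:
    """Fate of a zygote, read off its own parent-of-origin allele vectors."""
    return seed_fate(
        genotype.maternal_haplotype, genotype.paternal_haplotype, model
    )


def pure_selfer(model: IncompatibilityModel) -> Genotype:
    """Homozygous selfer-species genotype, e.g. ``RR|aabbcc``."""
    carries = tuple(
        model.is_maternal_locus(i) for i in range(model.n_loci)
    )
    return Genotype(carries, carries)


def pure_outcrosser(model: IncompatibilityModel) -> Genotype:
    """Homozygous outcrosser-species genotype, e.g. ``rr|AABBCC``."""
    carries = tuple(
        not model.is_maternal_locus(i) for i in range(model.n_loci)
    )
    return Genotype(carries, carries)


def f1_hybrid(model: IncompatibilityModel) -> Genotype:
    """The viable F1 of outcrosser seed parent x selfer pollen donor.

    Heterozygous at every locus: the maternally inherited haplotype is an
    outcrosser gamete, the paternally inherited haplotype a selfer gamete
    (renders as ``rR|AaBbCc`` for the one-maternal x three-paternal model).
    """
    return Genotype(
        pure_outcrosser(model).maternal, pure_selfer(model).paternal
    )
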