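"""Confronting observed per-plant seed-abortion counts with candidate models.

Pipeline: assign each plant to its most likely abortion-rate class by
binomial maximum likelihood (a small mis-scoring rate ``epsilon`` keeps the
boundary classes 0 and 1 at nonzero likelihood), tally class counts, and
test them against a model's theoretical class distribution with a Pearson
chi-square after pooling small expected classes.  Candidate locus-number
models are ranked by goodness-of-fit p-value, with p > alpha flagged as
"not rejected" — the criterion used to conclude for three paternal loci.

Also provides the >2% binarization of per-plant abortion rates used to
prepare a binary trait for QTL mapping, and Wilson score intervals for
abortion proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import ConfigurationError, IncompatibilityModel
from .prediction import AbortionClassDistribution, f2_class_distribution

__all__ = [
    "PlantRecord",
    "GofResult",
    "PooledBin",
    "ModelComparison",
    "DataFormatError",
    "StatisticalProcedureError",
    "assign_class",
    "assign_classes",
    "expected_counts",
    "chisq_gof",
    "compare_models",
    "binarize_abortion",
    "log_rate_histogram",
    "binomial_ci",
    "read_plant_table",
    "write_plant_table",
]


class DataFormatError(ValueError):
    """A plant table violates the expected delimited-text format."""


class StatisticalProcedureError(RuntimeError):
    """A statistical procedure is undefined for the given data."""


@dataclass(frozen=True)
class PlantRecord:
    """Seed phenotype of one plant: seeds scored and seeds aborted."""

    plant_id: str
    n_seeds: int
    n_aborted: int

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise DataFormatError(
                f"plant {self.plant_id!r}: n_seeds must be >= 1, "
                f"got {self.n_seeds}"
            )
        if not 0 <= self.n_aborted <= self.n_seeds:
            raise DataFormatError(
                f"plant {self.plant_id!r}: n_aborted {self.n_aborted} outside "
                f"[0, {self.n_seeds}]"
            )

    @property
    def observed_rate(self) -> float:
        return self.n_aborted / self.n_seeds


@dataclass(frozen=True)
class PooledBin:
    """One chi-square cell after pooling: member classes, observed, expected."""

    classes: tuple[Fraction, ...]
    observed: int
    expected: float


@dataclass(frozen=True)
class GofResult:
    """Chi-square confrontation of observed class counts with one model."""

    model: IncompatibilityModel
    observed: Mapping[Fraction, int]
    expected: Mapping[Fraction, float]
    pooled: tuple[PooledBin, ...]
    statistic: float
    df: int
    pvalue: float

    @property
    def n_plants(self) -> int:
        return sum(self.observed.values())

    def rejected(self, alpha: float = 0.05) -> bool:
        return self.pvalue <= alpha

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "classes": "+".join(str(c) for c in b.classes),
                "observed": b.observed,
                "expected": b.expected,
            }
            for b in self.pooled
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ModelComparison:
    """Ranked goodness-of-fit results for competing locus-number models."""

    results: tuple[GofResult, ...]  # sorted by p-value, best first
    alpha: float = 0.05

    @property
    def selected(self) -> GofResult:
        return self.results[0]

    @property
    def non_rejected(self) -> tuple[GofResult, ...]:
        return tuple(r for r in self.results if r.pvalue > self.alpha)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": r.model.describe(),
                "chi_square": r.statistic,
                "df": r.df,
                "p_value": r.pvalue,
                "rejected_at_alpha": r.rejected(self.alpha),
                "selected": r is self.selected,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def _effective_rates(
    classes: Sequence[Fraction], epsilon: float
) -> np.ndarray:
    """Class rates after flipping each seed call with probability epsilon."""
    c = np.array([float(x) for x in classes])
    return c * (1.0 - epsilon) + (1.0 - c) * epsilon


def _validate_epsilon(epsilon: float) -> None:
    if not 0.0 <= epsilon < 0.5:
        raise ConfigurationError(
            f"scoring-noise epsilon must lie in [0, 0.5), got {epsilon}"
        )


def assign_classes(
    n_aborted: np.ndarray,
    n_seeds: np.ndarray,
    classes: Sequence[Fraction],
    epsilon: float = 0.01,
) -> np.ndarray:
    """Vectorised maximum-likelihood class assignment.

    Returns the index into the ascending-sorted ``classes`` for each record;
    exact likelihood ties break toward the smaller class.
    """
    _validate_epsilon(epsilon)
    if len(classes) == 0:
        raise ConfigurationError("need at least one abortion-rate class")
    ordered = sorted(Fraction(c) for c in classes)
    if list(ordered) != [Fraction(c) for c in classes]:
        raise ConfigurationError("classes must be given in ascending order")
    rates = _effective_rates(ordered, epsilon)
    k = np.asarray(n_aborted)[:, None]
    n = np.asarray(n_seeds)[:, None]
    loglik = stats.binom.logpmf(k, n, rates[None, :])
    # argmax takes the first maximum, i.e. the smaller class on ties
    return np.argmax(loglik, axis=1)


def assign_class(
    record: PlantRecord,
    classes: Sequence[Fraction],
    epsilon: float = 0.01,
) -> Fraction:
    """Most likely abortion-rate class for one plant.

    The likelihood of class ``c`` is Binomial(n_seeds, c') at the observed
    n_aborted, where ``c' = c(1-eps) + (1-c)eps`` absorbs seed mis-scoring so
    that the boundary classes 0 and 1 retain nonzero likelihood.
    """
    ordered = sorted(Fraction(c) for c in classes)
    idx = assign_classes(
        np.array([record.n_aborted]), np.array([record.n_seeds]),
        ordered, epsilon,
    )[0]
    return ordered[idx]


def expected_counts(
    dist: AbortionClassDistribution, n_plants: int
) -> dict[Fraction, Fraction]:
    """Expected plants per class: ``n_plants`` x class frequency, exact."""
    if n_plants < 1:
        raise ConfigurationError(f"n_plants must be >= 1, got {n_plants}")
    return {c: n_plants * f for c, f in sorted(dist.frequencies.items())}


def chisq_gof(
    observed_class_counts: Mapping[Fraction, int],
    dist: AbortionClassDistribution,
    n_plants: Optional[int] = None,
    pooling_min: float = 5.0,
) -> GofResult:
    """Pearson chi-square of observed class counts against a model.

    Classes are pooled with their neighbour in ascending rate order until
    every pooled expected count is >= ``pooling_min`` (small-expected-count
    practice; the pooling map is reported so results stay auditable).
    Degrees of freedom = pooled classes - 1; the p-value is the chi-square
    upper tail.
    """
    observed = {
        Fraction(c): int(observed_class_counts.get(c, 0)) for c in dist.classes
    }
    extra = set(observed_class_counts) - set(dist.classes)
    if extra:
        raise ConfigurationError(
            f"observed counts include classes not in the model: {sorted(extra)}"
        )
    total = sum(observed.values())
    if n_plants is None:
        n_plants = total
    if total != n_plants:
        raise ConfigurationError(
            f"observed counts sum to {total}, expected n_plants={n_plants}"
        )
    exact_expected = expected_counts(dist, n_plants)
    expected = {c: float(e) for c, e in exact_expected.items()}

    bins: list[list] = []  # [classes, obs, exp]
    for c in dist.classes:
        if bins and bins[-1][2] < pooling_min:
            bins[-1][0].append(c)
            bins[-1][1] += observed[c]
            bins[-1][2] += expected[c]
        else:
            bins.append([[c], observed[c], expected[c]])
    if len(bins) > 1 and bins[-1][2] < pooling_min:
        last = bins.pop()
        bins[-1][0].extend(last[0])
        bins[-1][1] += last[1]
        bins[-1][2] += last[2]
    if len(bins) < 2:
        raise StatisticalProcedureError(
            "fewer than 2 classes remain after pooling; "
            "goodness of fit is undefined"
        )
    pooled = tuple(
        PooledBin(tuple(cs), obs, exp) for cs, obs, exp in bins
    )
    statistic = float(
        sum((b.observed - b.expected) ** 2 / b.expected for b in pooled)
    )
    df = len(pooled) - 1
    pvalue = float(stats.chi2.sf(statistic, df))
    return GofResult(
        model=dist.model,
        observed=observed,
        expected=expected,
        pooled=pooled,
        statistic=statistic,
        df=df,
        pvalue=pvalue,
    )


def compare_models(
    records: Sequence[PlantRecord],
    candidate_models: Sequence[IncompatibilityModel],
    epsilon: float = 0.01,
    pooling_min: float = 5.0,
    alpha: float = 0.05,
) -> ModelComparison:
    """Rank candidate locus-number models by goodness of fit.

    For each candidate, plants are assigned to that candidate's own class
    set and the counts are tested against its theoretical F2 class
    distribution.  The selected model is the one with the highest p-value;
    candidates with p > ``alpha`` are additionally flagged as not rejected.
    """
    if len(candidate_models) < 2:
        raise ConfigurationError(
            "model comparison needs at least two candidate models"
        )
    if not records:
        raise DataFormatError("no plant records supplied")
    k = np.array([r.n_aborted for r in records])
    n = np.array([r.n_seeds for r in records])
    results = []
    for model in candidate_models:
        dist = f2_class_distribution(model)
        classes = dist.classes
        idx = assign_classes(k, n, classes, epsilon)
        counts = {
            c: int(np.sum(idx == i)) for i, c in enumerate(classes)
        }
        results.append(chisq_gof(counts, dist, len(records), pooling_min))
    results.sort(key=lambda r: r.pvalue, reverse=True)
    return ModelComparison(tuple(results), alpha)


def binarize_abortion(
    records: Sequence[PlantRecord], threshold: float = 0.02
) -> np.ndarray:
    """Binary trait vector: 1 for plants with abortion rate > ``threshold``.

    The inequality is strict, so a rate exactly at the threshold codes 0.
    Monotone in the rate and independent of n_seeds given the rate.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(
            f"threshold must lie in (0, 1), got {threshold}"
        )
    return np.array(
        [1 if r.observed_rate > threshold else 0 for r in records], dtype=int
    )


def log_rate_histogram(
    records: Sequence[PlantRecord],
    n_bins: int = 20,
    floor: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of log10 abortion rates, used to justify a binarization cut.

    Zero rates are mapped into the lowest (floor) bin; ``floor`` defaults to
    one decade below the smallest positive observed rate.
    """
    rates = np.array([r.observed_rate for r in records], dtype=float)
    positive = rates[rates > 0]
    if floor is None:
        floor = float(positive.min()) / 10.0 if positive.size else 1e-4
    clipped = np.maximum(rates, floor)
    counts, edges = np.histogram(np.log10(clipped), bins=n_bins)
    return counts, edges


def binomial_ci(
    n_aborted: int, n_seeds: int, level: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for an abortion proportion.

    Wilson rather than Wald for sane behaviour at proportions near 0 or 1
    (the lower bound of 0/n is exactly 0, the upper bound of n/n exactly 1).
    """
    PlantRecord("ci", n_seeds, n_aborted)  # reuse the count invariants
    ci = stats.binomtest(n_aborted, n_seeds).proportion_ci(
        confidence_level=level, method="wilson"
    )
    return float(ci.low), float(ci.high)


_REQUIRED_COLUMNS = ("plant_id", "n_seeds", "n_aborted")


def read_plant_table(path) -> list[PlantRecord]:
    """Read a per-plant seed table (TSV with header, '#' comment lines)."""
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # malformed delimited text
        raise DataFormatError(f"cannot parse plant table {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(
            f"plant table {path} is missing columns: {missing}"
        )
    if frame.empty:
        raise DataFormatError(f"plant table {path} contains no plants")
    records = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            records.append(
                PlantRecord(
                    plant_id=str(row.plant_id),
                    n_seeds=int(row.n_seeds),
                    n_aborted=int(row.n_aborted),
                )
            )
        except (TypeError, ValueError) as exc:
            raise DataFormatError(
                f"plant table {path}, row {row_number}: {exc}"
            ) from exc
    return records


def write_plant_table(
    records: Iterable[PlantRecord], path, header_lines: Sequence[str] = ()
) -> None:
    """Write PlantRecords as TSV, with optional '#' provenance lines."""
    frame = pd.DataFrame(
        [
            {
                "plant_id": r.plant_id,
                "n_seeds": r.n_seeds,
                "n_aborted": r.n_aborted,
            }
            for r in records
        ]
    )
    with open(path, "w") as handle:
        for line in header_lines:
            handle.write(f"# {line}\n")
        frame.to_csv(handle, sep="\t", index=False)
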