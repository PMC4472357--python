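"""Provenance-stamped delimited-text output.

Every file written by the command-line workflow is tab-separated text with
a header row, preceded by '#' comment lines carrying the package version,
the echoed run configuration, the random seed and checksums of any inputs.
"""

from __future__ import annotations

import hashlib
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .crosses import CrossOutcome, GenerationState
from .genetics import Genotype, IncompatibilityModel

__all__ = [
    "provenance_header",
    "sha256_of",
    "write_frame",
    "cross_outcome_frame",
    "generation_state_frame",
]


def sha256_of(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def provenance_header(
    command: str,
    config: Mapping[str, object],
    seed: Optional[int] = None,
    inputs: Sequence[Path] = (),
) -> list[str]:
    lines = [f"bdmseed v{__version__}", f"command: {command}"]
    for key, value in config.items():
        lines.append(f"config: {key} = {value}")
    if seed is not None:
        lines.append(f"seed: {seed}")
    for path in inputs:
        lines.append(f"input: {path} sha256={sha256_of(path)}")
    return lines


def write_frame(
    frame: pd.DataFrame, path, header_lines: Sequence[str] = ()
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        for line in header_lines:
            handle.write(f"# {line}\n")
        frame.to_csv(handle, sep="\t", index=False)


def _rational_rows(
    dist: Mapping[Genotype, Fraction], model: IncompatibilityModel
) -> list[dict]:
    return [
        {
            "genotype": g.to_string(model),
            "frequency_numerator": f.numerator,
            "frequency_denominator": f.denominator,
            "frequency_float": float(f),
        }
        for g, f in sorted(
            dist.items(), key=lambda kv: kv[0].to_string(model)
        )
    ]


def cross_outcome_frame(
    outcome: CrossOutcome, model: IncompatibilityModel
) -> pd.DataFrame:
    """Survivor table of a cross; the abortion rate rides in a summary row."""
    rows = _rational_rows(outcome.survivors, model)
    rows.append(
        {
            "genotype": "__aborted__",
            "frequency_numerator": outcome.abortion_rate.numerator,
            "frequency_denominator": outcome.abortion_rate.denominator,
            "frequency_float": float(outcome.abortion_rate),
        }
    )
    return pd.DataFrame(rows)


def generation_state_frame(
    state: GenerationState, model: IncompatibilityModel
) -> pd.DataFrame:
    frame = pd.DataFrame(_rational_rows(state.frequencies, model))
    frame.insert(0, "generation", state.generation)
    return frame
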