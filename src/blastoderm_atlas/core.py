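"""Core containers and errors shared across the pipeline.

The central in-memory object is :class:`EmbryoProfile`: one embryo's
per-nucleus records in normalized embryo coordinates.  Positions along the
antero-posterior (A-P) axis are expressed in percent egg length (% EL,
0 = anterior pole); positions along the dorso-ventral axis in percent embryo
height.  Fluorescence intensities are in arbitrary units (a.u.).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

#: canonical staging sequence: cleavage cycles C10-C13, then the eight
#: time classes subdividing C14A (the pre-gastrulation part of cycle 14).
TIME_CLASSES = ("C10", "C11", "C12", "C13", "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8")
C14A_CLASSES = ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8")

#: columns every per-nucleus table must carry, in order; per-channel
#: intensity columns ("I_<gene>") follow.
NUCLEUS_BASE_COLUMNS = ("nucleus_id", "x", "y")


class ConfigurationError(ValueError):
    """An invalid gene/species/time-class combination or pipeline setting."""


class DegenerateInputError(ValueError):
    """Input that the operation cannot meaningfully process (e.g. empty)."""


class ParseError(ValueError):
    """Malformed delimited-text input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def time_class_index(tc: str) -> int:
    """Integer index of a C14A time class (T1 -> 1 ... T8 -> 8)."""
    if tc not in C14A_CLASSES:
        raise ConfigurationError(f"not a C14A time class: {tc!r}")
    return int(tc[1:])


def cycle_of_class(tc: str) -> str:
    """Cleavage cycle a staging class belongs to (T1-T8 are all C14A)."""
    if tc in C14A_CLASSES:
        return "C14A"
    if tc in TIME_CLASSES:
        return tc
    raise ConfigurationError(f"unknown staging class: {tc!r}")


@dataclass
class EmbryoProfile:
    """Per-nucleus records of one embryo plus staging/orientation metadata.

    ``data`` holds one row per nucleus with columns ``nucleus_id``, ``x``
    (% EL), ``y`` (% height) and one ``I_<gene>`` intensity column per
    imaged channel.
    """

    embryo_id: str
    data: pd.DataFrame
    cycle: str | None = None
    time_class: str | None = None
    orientation_known: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in NUCLEUS_BASE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"profile data lacks columns {missing}")

    @property
    def channels(self) -> list[str]:
        return [c[2:] for c in self.data.columns if c.startswith("I_")]

    @property
    def n_nuclei(self) -> int:
        return len(self.data)

    def intensity(self, channel: str) -> pd.Series:
        col = f"I_{channel}"
        if col not in self.data.columns:
            raise ConfigurationError(f"channel {channel!r} not present in profile")
        return self.data[col]

    def with_data(self, data: pd.DataFrame, **meta_updates) -> "EmbryoProfile":
        """Copy of this profile with replaced nucleus table and updated meta."""
        new = replace(self, data=data.reset_index(drop=True))
        new.meta = {**self.meta, **meta_updates}
        return new
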