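"""Core domain containers for staged phonological lexica.

A *staged lexicon* is the cumulative second-language vocabulary at each of six
age-of-acquisition (AoA) stages (mapped from CEFR proficiency levels A1-C2).
Each word form carries its orthography, a segment-level phonemic transcription,
the stage at which it enters the lexicon, its lexical frequency, and the
neighborhood density of the same form in the first-language reference lexicon
(the saturation benchmark).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

N_STAGES = 6

Transcription = tuple[str, ...]


class LexiconError(ValueError):
    """Raised for invalid or inconsistent lexicon input."""


def log_frequency(freq_raw: float) -> float:
    """Base-10 log transform ``log10(x + 1)`` of a raw frequency rate.

    The +1 offset accommodates zero-frequency forms; the result is >= 0.
    """
    if freq_raw < 0:
        raise LexiconError(f"negative frequency rate: {freq_raw!r}")
    return math.log10(freq_raw + 1.0)


def phoneme_count(phon: Transcription) -> int:
    """Number of segment tokens in a transcription (phonological length)."""
    if len(phon) == 0:
        raise LexiconError("empty transcription")
    return len(phon)


@dataclass(frozen=True)
class LexiconEntry:
    """One phonological word form.

    ``phon`` is a tuple of single segment tokens; multi-character symbols must
    already be recoded to unique single tokens upstream.  ``l1_density`` is the
    form's neighbor count in the full first-language lexicon and serves as the
    100%-saturation benchmark.
    """

    orth: str
    phon: Transcription
    aoa: int
    freq_raw: float
    l1_density: int
    freq_log: float = field(default=-1.0)
    length: int = field(default=-1)

    def __post_init__(self) -> None:
        if not 1 <= self.aoa <= N_STAGES:
            raise LexiconError(f"aoa must be in 1..{N_STAGES}, got {self.aoa}")
        if self.freq_raw < 0:
            raise LexiconError(f"negative freq_raw for {self.orth!r}")
        if self.l1_density < 0:
            raise LexiconError(f"negative l1_density for {self.orth!r}")
        if self.freq_log < 0:
            object.__setattr__(self, "freq_log", log_frequency(self.freq_raw))
        if self.length < 0:
            object.__setattr__(self, "length", phoneme_count(self.phon))
        if self.length != len(self.phon):
            raise LexiconError(
                f"length {self.length} != segment count {len(self.phon)} for {self.orth!r}"
            )


@dataclass
class StagedLexicon:
    """Cumulative staged vocabulary keyed by phonological form.

    Stage sets are cumulative: a form is a member from its AoA stage onward.
    Each phonological form appears with exactly one AoA (homophones must be
    merged before construction).
    """

    entries: dict[Transcription, LexiconEntry]

    def __post_init__(self) -> None:
        for phon, e in self.entries.items():
            if phon != e.phon:
                raise LexiconError(f"entry keyed by {phon!r} but phon is {e.phon!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries.values())

    def __contains__(self, phon: Transcription) -> bool:
        return tuple(phon) in self.entries

    def entry(self, phon: Transcription) -> LexiconEntry:
        return self.entries[tuple(phon)]

    def stage_vocabulary(self, stage: int) -> set[Transcription]:
        """All forms known at ``stage`` (cumulative membership)."""
        _check_stage(stage)
        return {p for p, e in self.entries.items() if e.aoa <= stage}

    def new_at_stage(self, stage: int) -> set[Transcription]:
        """Forms uniquely acquired at ``stage``."""
        _check_stage(stage)
        return {p for p, e in self.entries.items() if e.aoa == stage}

    def stage_sizes(self) -> dict[int, int]:
        sizes = {s: 0 for s in range(1, N_STAGES + 1)}
        for e in self:
            for s in range(e.aoa, N_STAGES + 1):
                sizes[s] += 1
        return sizes


def _check_stage(stage: int) -> None:
    if not 1 <= stage <= N_STAGES:
        raise LexiconError(f"stage must be in 1..{N_STAGES}, got {stage}")
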