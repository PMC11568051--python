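"""Reading, cleaning and writing staged word lists.

Input schema: UTF-8 TSV/CSV with header columns ``orth, stage, freq, phon,
l1_density`` — one row per word, one file (or one stage label) per AoA stage.
Cleaning applies the study's rules: homophones (rows sharing one phonemic
form) are merged with the arithmetic mean of their frequency rates and the
earliest member stage; frequencies are log-transformed as ``log10(x+1)``;
rows whose transcription contains symbols outside the declared segment
inventory are dropped and counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    LexiconEntry,
    LexiconError,
    StagedLexicon,
    Transcription,
    log_frequency,
    phoneme_count,
)

REQUIRED_COLUMNS = ("orth", "stage", "freq", "phon", "l1_density")


@dataclass
class IOConfig:
    """Declares the segment inventory and parsing options.

    ``inventory`` is the set of valid single-token segment symbols; multi-
    character phones (affricates, long vowels, rhotic vowels ...) must be
    recoded upstream to unique single tokens.  If ``segment_delimiter`` is
    None, transcriptions are tokenized one character per segment.
    """

    inventory: frozenset[str]
    segment_delimiter: str | None = None
    sep: str = "\t"

    def tokenize(self, phon: str) -> Transcription:
        if self.segment_delimiter is None:
            toks = tuple(phon)
        else:
            toks = tuple(t for t in phon.split(self.segment_delimiter) if t)
        if not toks:
            raise LexiconError(f"empty transcription: {phon!r}")
        unknown = [t for t in toks if t not in self.inventory]
        if unknown:
            raise LexiconError(f"unknown segment(s) {unknown!r} in {phon!r}")
        return toks

    def format(self, phon: Transcription) -> str:
        delim = self.segment_delimiter or ""
        return delim.join(phon)


@dataclass
class DropReport:
    """Accounting of rows removed during ingestion."""

    n_rows: int = 0
    n_dropped: int = 0
    dropped: list[dict] = field(default_factory=list)
    n_merged_homophones: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows_read": self.n_rows,
                "rows_dropped": self.n_dropped,
                "homophone_rows_merged": self.n_merged_homophones,
                "dropped_rows": self.dropped,
            },
            indent=2,
        )


@dataclass(frozen=True)
class RawRow:
    orth: str
    phon: Transcription
    aoa: int
    freq_raw: float
    l1_density: int


def merge_homophones(rows: Sequence[RawRow]) -> RawRow:
    """Collapse rows sharing one phonemic form into a single entry.

    The merged frequency rate is the arithmetic mean of the members'; the AoA
    is the earliest member stage (a form is known once any spelling of it is
    learned).  Orthographies are joined with "/" in first-seen order.
    """
    if not rows:
        raise LexiconError("merge_homophones requires at least one row")
    phons = {r.phon for r in rows}
    if len(phons) != 1:
        raise LexiconError(f"rows do not share one phon: {sorted(phons)!r}")
    if len(rows) == 1:
        return rows[0]
    orths: list[str] = []
    for r in rows:
        if r.orth not in orths:
            orths.append(r.orth)
    return RawRow(
        orth="/".join(orths),
        phon=rows[0].phon,
        aoa=min(r.aoa for r in rows),
        freq_raw=sum(r.freq_raw for r in rows) / len(rows),
        l1_density=max(r.l1_density for r in rows),
    )


def _read_table(path: Path, config: IOConfig) -> pd.DataFrame:
    df = pd.read_csv(path, sep=config.sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LexiconError(f"{path}: missing required column(s) {missing}")
    return df


def read_word_lists(
    paths: Iterable[str | Path], config: IOConfig
) -> tuple[StagedLexicon, DropReport]:
    """Ingest per-stage word lists into a validated :class:`StagedLexicon`.

    Rows with untokenizable transcriptions are dropped and counted in the
    returned :class:`DropReport`.  Duplicate phonemic forms across rows are
    merged as homophones; a duplicate appearing with a *later* stage in a
    different file is treated the same way (earliest stage wins), but two rows
    with identical phon and identical orth at different stages indicate an
    upstream error and raise.
    """
    report = DropReport()
    by_phon: dict[Transcription, list[RawRow]] = {}
    for path in paths:
        df = _read_table(Path(path), config)
        for _, rec in df.iterrows():
            report.n_rows += 1
            try:
                phon = config.tokenize(rec["phon"])
                row = RawRow(
                    orth=str(rec["orth"]),
                    phon=phon,
                    aoa=int(rec["stage"]),
                    freq_raw=float(rec["freq"]),
                    l1_density=int(rec["l1_density"]),
                )
                if not 1 <= row.aoa <= 6:
                    raise LexiconError(f"stage out of range: {row.aoa}")
                if row.freq_raw < 0 or row.l1_density < 0:
                    raise LexiconError("negative freq or l1_density")
            except (LexiconError, ValueError) as exc:
                report.n_dropped += 1
                report.dropped.append({"orth": str(rec["orth"]), "reason": str(exc)})
                continue
            by_phon.setdefault(phon, []).append(row)

    entries: dict[Transcription, LexiconEntry] = {}
    for phon, rows in by_phon.items():
        seen = {(r.orth, r.aoa) for r in rows}
        orth_stages: dict[str, set[int]] = {}
        for o, s in seen:
            orth_stages.setdefault(o, set()).add(s)
        conflicted = {o: s for o, s in orth_stages.items() if len(s) > 1}
        if conflicted:
            raise LexiconError(
                f"form {config.format(phon)!r}: same orthography listed at "
                f"multiple stages {conflicted} (unmerged duplicates upstream)"
            )
        if len(rows) > 1:
            report.n_merged_homophones += len(rows)
        merged = merge_homophones(rows)
        entries[phon] = LexiconEntry(
            orth=merged.orth,
            phon=phon,
            aoa=merged.aoa,
            freq_raw=merged.freq_raw,
            l1_density=merged.l1_density,
        )
    return StagedLexicon(entries), report


def lexicon_to_frame(lexicon: StagedLexicon, config: IOConfig) -> pd.DataFrame:
    """Normalized tabular view, sorted by (stage, phon) for stable output."""
    rows = [
        {
            "orth": e.orth,
            "stage": e.aoa,
            "freq": repr(e.freq_raw),
            "phon": config.format(e.phon),
            "l1_density": e.l1_density,
            "freq_log": repr(e.freq_log),
            "length": e.length,
        }
        for e in lexicon
    ]
    df = pd.DataFrame(
        rows,
        columns=["orth", "stage", "freq", "phon", "l1_density", "freq_log", "length"],
    )
    return df.sort_values(["stage", "phon"], kind="mergesort").reset_index(drop=True)


def write_word_lists(lexicon: StagedLexicon, path: str | Path, config: IOConfig) -> None:
    """Write the normalized lexicon as a single TSV (round-trips bit-stably)."""
    df = lexicon_to_frame(lexicon, config)
    df.to_csv(path, sep=config.sep, index=False)


def round_display(x: float, ndigits: int = 1) -> float:
    """Display rounding at 1 decimal, round-half-to-even (banker's)."""
    return round(x, ndigits)
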