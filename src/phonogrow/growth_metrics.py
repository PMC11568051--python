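"""Per-word growth trajectories and the study's three dependent variables.

A word entering the lexicon at AoA stage ``a`` undergoes ``7 - a`` growth
spurts: spurt 1 comprises the neighbors already present at its entry stage,
and spurt ``j > 1`` the neighbors gained between stages ``a+j-2`` and
``a+j-1``.  From a trajectory we derive:

* **proportional degree gain** — a spurt's neighbor gain as a percentage of
  the word's final (stage-6) degree;
* **saturation** — the cumulative neighbor count as a percentage of the
  word's neighborhood density in the first-language reference lexicon;
* **average weighted degree of new neighbors** — the phonetic-similarity
  weight per neighbor.  The default ("cumulative") convention divides the
  cumulative weighted degree by the cumulative neighbor count after the
  spurt, so a no-growth spurt carries the previous per-neighbor average
  forward over the whole neighborhood; the "new" convention divides the
  weight added during a growth spurt by the number of neighbors added.

Growth-pattern labels (initial / continuous / delayed / other) summarize the
timing of a word's growth relative to its entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .network_build import PhonNetwork
from .types import N_STAGES, Transcription


class GrowthError(ValueError):
    pass


@dataclass(frozen=True)
class Spurt:
    neighbors_added: int
    cumulative_degree: int
    added_weight: int
    cumulative_weight: int


@dataclass(frozen=True)
class GrowthTrajectory:
    """Spurt-by-spurt record of one word's neighborhood growth."""

    phon: Transcription
    aoa: int
    spurts: tuple[Spurt, ...]

    @property
    def n_spurts(self) -> int:
        return len(self.spurts)

    @property
    def final_degree(self) -> int:
        return self.spurts[-1].cumulative_degree

    @property
    def gains(self) -> tuple[int, ...]:
        return tuple(s.neighbors_added for s in self.spurts)


class GrowthPattern(str, Enum):
    INITIAL = "initial"
    CONTINUOUS = "continuous"
    DELAYED = "delayed"
    OTHER = "other"


def compute_trajectory(
    phon: Transcription, networks: Mapping[int, PhonNetwork]
) -> GrowthTrajectory:
    """Track a word's degree and weighted degree from its entry to stage 6."""
    phon = tuple(phon)
    aoa = None
    for s in range(1, N_STAGES + 1):
        if phon in networks[s].graph:
            aoa = s
            break
    if aoa is None:
        raise GrowthError(f"form {''.join(phon)!r} absent from all stage networks")
    spurts: list[Spurt] = []
    prev_deg = prev_w = 0
    for s in range(aoa, N_STAGES + 1):
        deg = networks[s].degree(phon)
        w = networks[s].weighted_degree(phon)
        spurts.append(
            Spurt(
                neighbors_added=deg - prev_deg,
                cumulative_degree=deg,
                added_weight=w - prev_w,
                cumulative_weight=w,
            )
        )
        prev_deg, prev_w = deg, w
    return GrowthTrajectory(phon=phon, aoa=aoa, spurts=tuple(spurts))


def compute_all_trajectories(networks: Mapping[int, PhonNetwork]) -> list[GrowthTrajectory]:
    forms = sorted(networks[N_STAGES].graph.nodes)
    return [compute_trajectory(p, networks) for p in forms]


def _check_spurt(traj: GrowthTrajectory, spurt: int) -> None:
    if not 1 <= spurt <= traj.n_spurts:
        raise GrowthError(
            f"spurt {spurt} invalid for AoA {traj.aoa} (1..{traj.n_spurts})"
        )


def proportional_degree_gain(traj: GrowthTrajectory, spurt: int) -> float:
    """A spurt's neighbor gain as a percentage of the word's final degree."""
    _check_spurt(traj, spurt)
    if traj.final_degree == 0:
        raise GrowthError(
            f"form {''.join(traj.phon)!r} never grew; excluded from the gain analysis"
        )
    return traj.spurts[spurt - 1].neighbors_added / traj.final_degree * 100.0


def saturation(traj: GrowthTrajectory, l1_density: int, through_spurt: int) -> float:
    """Cumulative neighbor count as a percentage of the L1 density benchmark."""
    _check_spurt(traj, through_spurt)
    if l1_density <= 0:
        raise GrowthError(
            f"form {''.join(traj.phon)!r} has no L1 neighbors; "
            "excluded from the saturation analysis"
        )
    return traj.spurts[through_spurt - 1].cumulative_degree / l1_density * 100.0


def avg_weighted_degree_new(
    traj: GrowthTrajectory, spurt: int, mode: str = "cumulative"
) -> float:
    """Average phonetic-similarity weight per neighbor at a spurt.

    mode="cumulative" (default): cumulative weight / cumulative degree after
    the spurt — a no-growth spurt therefore repeats the previous neighborhood
    average.  mode="new": weight added / neighbors added during a growth
    spurt, carrying the previous value forward through no-growth spurts.
    Both conventions return 0 while the neighborhood is empty.
    """
    _check_spurt(traj, spurt)
    sp = traj.spurts[spurt - 1]
    if sp.cumulative_degree == 0:
        return 0.0
    if mode == "cumulative":
        return sp.cumulative_weight / sp.cumulative_degree
    if mode == "new":
        for j in range(spurt - 1, -1, -1):
            s = traj.spurts[j]
            if s.neighbors_added > 0:
                return s.added_weight / s.neighbors_added
        return 0.0
    raise ValueError(f"unknown mode {mode!r}")


def classify_growth_pattern(traj: GrowthTrajectory) -> GrowthPattern:
    """Label the timing of a word's growth relative to its lexicon entry.

    initial — growth only at the entry spurt; continuous — growth at every
    spurt; delayed — no growth for the first one or two post-entry spurts,
    then growth at every remaining spurt; other — any remaining profile.
    Requires at least three spurts (early-acquired words only).
    """
    if traj.n_spurts < 3:
        raise GrowthError(
            f"AoA {traj.aoa} leaves only {traj.n_spurts} spurts; "
            "pattern classification needs at least 3"
        )
    g = traj.gains
    if all(x > 0 for x in g):
        return GrowthPattern.CONTINUOUS
    if g[0] > 0 and all(x == 0 for x in g[1:]):
        return GrowthPattern.INITIAL
    if g[1] == 0:
        if all(x > 0 for x in g[2:]):
            return GrowthPattern.DELAYED
        if traj.n_spurts >= 4 and g[2] == 0 and all(x > 0 for x in g[3:]):
            return GrowthPattern.DELAYED
    return GrowthPattern.OTHER


def sv_transform(y: float, n: int) -> float:
    """Smithson-Verkuilen squeeze ``(y*(n-1)+0.5)/n`` mapping [0,1] into (0,1)."""
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"proportion out of [0, 1]: {y!r}")
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    return (y * (n - 1) + 0.5) / n


def build_model_table(
    trajectories: Sequence[GrowthTrajectory],
    l1_densities: Mapping[Transcription, int],
    freq_log: Mapping[Transcription, float],
    lengths: Mapping[Transcription, int],
    wd_mode: str = "cumulative",
) -> pd.DataFrame:
    """Model-ready rows: one per (growing word) x spurt.

    Columns: word, aoa, spurt, prop_degree_gain and prop_saturation_gain
    (Smithson-Verkuilen transformed with n = table row count), the integer
    count DV avg_wd_int, plus freq_log and length covariates.  Words that
    never grow contribute no rows; saturation DVs are NA for words without an
    L1 benchmark or with gains exceeding it.
    """
    rows: list[dict] = []
    for traj in trajectories:
        if traj.final_degree == 0:
            continue
        word = "".join(traj.phon)
        l1 = l1_densities.get(traj.phon, 0)
        prev_cum = 0
        for j in range(1, traj.n_spurts + 1):
            sp = traj.spurts[j - 1]
            degree_gain = sp.neighbors_added / traj.final_degree
            if l1 > 0:
                sat_gain = (sp.cumulative_degree - prev_cum) / l1
                if not 0.0 <= sat_gain <= 1.0:
                    sat_gain = float("nan")
            else:
                sat_gain = float("nan")
            avg_wd = avg_weighted_degree_new(traj, j, mode=wd_mode)
            rows.append(
                {
                    "word": word,
                    "aoa": traj.aoa,
                    "spurt": j,
                    "degree_gain_raw": degree_gain,
                    "saturation_gain_raw": sat_gain,
                    "avg_wd": avg_wd,
                    "avg_wd_int": int(round(avg_wd)),
                    "freq_log": freq_log.get(traj.phon, 0.0),
                    "length": lengths.get(traj.phon, len(traj.phon)),
                }
            )
            prev_cum = sp.cumulative_degree
    df = pd.DataFrame(
        rows,
        columns=[
            "word", "aoa", "spurt", "degree_gain_raw", "saturation_gain_raw",
            "avg_wd", "avg_wd_int", "freq_log", "length",
        ],
    )
    n = len(df)
    if n:
        df["prop_degree_gain"] = df["degree_gain_raw"].map(lambda y: sv_transform(y, n))
        df["prop_saturation_gain"] = df["saturation_gain_raw"].map(
            lambda y: sv_transform(y, n) if y == y else float("nan")
        )
    else:
        df["prop_degree_gain"] = []
        df["prop_saturation_gain"] = []
    df.attrs["sv_n"] = n
    df.attrs["wd_mode"] = wd_mode
    return df
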