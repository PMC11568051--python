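"""Synthetic staged lexica with the statistical structure the analysis assumes.

The generator emulates the data-generating situation of a second-language
vocabulary growing inside a fixed first-language lexicon:

* An **L1 form pool** of CV / CVC / CVCC strings over a small segment
  inventory.  Shared rimes make one-segment neighborhoods arise naturally;
  a word's degree inside the pool is its L1 neighborhood density, so the
  staged L2 lexicon (a subset of the pool) can never exceed 100% saturation.

* **Staged acquisition.**  Stage 1 seeds the lexicon; each later stage
  samples words from the remaining pool.  Sampling weights combine a static
  acquisition bias — shorter and denser forms earlier, the profile reported
  for real learner vocabularies — with an *obsolescence* (node-aging)
  multiplier: a candidate adjacent to recently acquired words keeps its full
  weight, while a candidate whose lexicon neighbors have aged is suppressed
  by a factor that decays as exp(-alpha * age), scaled by the neighbors'
  degrees (the preferential-attachment exponent).  At ``aging_alpha = 0`` the
  multiplier is identically 1, so with the static biases switched off the
  arrival stages of words are exchangeable and expected per-spurt gains are
  equal — the no-obsolescence null.  Larger alpha concentrates a word's
  growth into its entry spurt.

* **Zipf frequencies.**  Raw frequency rates follow a Zipf law over the
  acquisition order with lognormal noise, so early-acquired words are on
  average more frequent.

The generator records its own ground truth (per-word spurt schedule, growth
pattern labels, L1 densities), emits the same TSV schema ``lexicon_io``
reads, and is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import growth_metrics
from .lexicon_io import IOConfig, write_word_lists
from .phonetics import default_feature_table, find_neighbors
from .types import N_STAGES, LexiconEntry, StagedLexicon, Transcription

_CONSONANTS = ("p", "t", "k", "b", "d", "g", "m", "n", "s", "z", "l", "r", "f", "v", "h", "w")
_VOWELS = ("a", "e", "i", "o", "u")


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the staged-lexicon generator.

    ``words_per_stage`` defaults to the unique-words-per-stage profile of the
    learner vocabulary the analysis targets, scaled by ~1/10 to keep the
    default pipeline fast.  ``aging_alpha`` is the obsolescence strength
    (0 = none); ``pa_exponent`` the degree exponent inside the aging term;
    ``length_bias`` and ``density_bias`` the static early-acquisition biases
    for short and neighbor-rich forms; ``l1_inflation`` the pool size as a
    multiple of the total L2 vocabulary.
    """

    n_consonants: int = 10
    n_vowels: int = 5
    words_per_stage: tuple[int, ...] = (60, 90, 134, 166, 95, 94)
    min_len: int = 2
    max_len: int = 4
    zipf_exponent: float = 1.0
    zipf_scale: float = 2000.0
    freq_noise_sd: float = 0.2
    aging_alpha: float = 1.5
    pa_exponent: float = 1.0
    pa_strength: float = 5.0
    length_bias: float = 0.6
    density_bias: float = 0.5
    l1_inflation: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.words_per_stage) != N_STAGES:
            raise GeneratorError("words_per_stage must have six entries")
        if any(n <= 0 for n in self.words_per_stage):
            raise GeneratorError("words_per_stage entries must be positive")
        if self.aging_alpha < 0 or self.l1_inflation < 1:
            raise GeneratorError("aging_alpha must be >= 0 and l1_inflation >= 1")
        if not (1 <= self.n_consonants <= len(_CONSONANTS) and 1 <= self.n_vowels <= len(_VOWELS)):
            raise GeneratorError("inventory size out of range")


@dataclass
class SyntheticLexicon:
    """A staged lexicon plus the ground truth that generated it."""

    lexicon: StagedLexicon
    config: GeneratorConfig
    pool_size: int
    ground_truth: dict[str, dict] = field(default_factory=dict)

    def io_config(self) -> IOConfig:
        return synthetic_io_config()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_word_lists(self.lexicon, out / "lexicon.tsv", self.io_config())
        meta = {
            "config": asdict(self.config),
            "pool_size": self.pool_size,
            "ground_truth": self.ground_truth,
        }
        (out / "ground_truth.json").write_text(json.dumps(meta, indent=1))


def synthetic_io_config() -> IOConfig:
    """IO config whose inventory matches the shipped feature table."""
    return IOConfig(inventory=default_feature_table().inventory)


def _enumerate_forms(cons: tuple[str, ...], vows: tuple[str, ...], min_len: int, max_len: int):
    """CV(C(C)) forms with optional onset; shared rimes give natural neighbors."""
    forms: list[Transcription] = []
    onsets: list[tuple[str, ...]] = [()] + [(c,) for c in cons]
    rimes: list[tuple[str, ...]] = []
    for v in vows:
        rimes.append((v,))
        for c1 in cons:
            rimes.append((v, c1))
            for c2 in cons:
                rimes.append((v, c1, c2))
    for on in onsets:
        for rime in rimes:
            f = on + rime
            if min_len <= len(f) <= max_len:
                forms.append(f)
    return sorted(set(forms))


def generate(config: GeneratorConfig) -> SyntheticLexicon:
    """Draw a staged lexicon (plus ground truth) from the generator model."""
    rng = np.random.default_rng(config.seed)
    cons = _CONSONANTS[: config.n_consonants]
    vows = _VOWELS[: config.n_vowels]
    all_forms = _enumerate_forms(cons, vows, config.min_len, config.max_len)
    n_total = sum(config.words_per_stage)
    pool_size = min(len(all_forms), math.ceil(config.l1_inflation * n_total))
    if pool_size < n_total:
        raise GeneratorError(
            f"requested {n_total} words but only {len(all_forms)} forms exist"
        )
    pool_idx = rng.choice(len(all_forms), size=pool_size, replace=False)
    pool = [all_forms[i] for i in sorted(pool_idx)]
    index = {f: i for i, f in enumerate(pool)}

    adj: list[list[int]] = [[] for _ in pool]
    for a, b in find_neighbors(pool):
        adj[index[a]].append(index[b])
        adj[index[b]].append(index[a])
    l1_density = np.array([len(nb) for nb in adj])

    aoa = np.zeros(pool_size, dtype=int)  # 0 = not acquired
    deg_lex = np.zeros(pool_size, dtype=int)
    order: list[int] = []
    lengths = np.array([len(f) for f in pool], dtype=float)
    alpha, gamma, c_pa = config.aging_alpha, config.pa_exponent, config.pa_strength

    # Words are drawn one at a time.  A candidate's attachment score A sums,
    # over its already-acquired neighbors u, (deg(u)+1)^gamma times the
    # *centered* aging factor exp(-alpha*age(u)) - kappa, where kappa is the
    # mean aging factor over the possible node ages 0..5.  Same-stage
    # neighbors (age 0) therefore boost a candidate above the hermit
    # baseline -- acquisition comes in phonologically similar bursts -- while
    # aged neighborhoods suppress it.  At alpha = 0 every centered factor
    # vanishes and arrivals are exchangeable (the no-obsolescence null).
    # Degrees are frozen at their stage-entry values within a stage.
    kappa = float(np.mean(np.exp(-alpha * np.arange(N_STAGES))))
    for s in range(1, N_STAGES + 1):
        n_s = config.words_per_stage[s - 1]
        if n_s > int((aoa == 0).sum()):
            raise GeneratorError(f"pool exhausted at stage {s}")
        lam = config.length_bias * (N_STAGES - s) / (N_STAGES - 1)
        base = np.exp(-lam * lengths) * (l1_density + 1.0) ** config.density_bias
        acquired = np.flatnonzero(aoa > 0)
        A = np.zeros(pool_size)
        if alpha > 0:
            for u, fade in zip(acquired, np.exp(-alpha * (s - aoa[acquired])) - kappa):
                t = (deg_lex[u] + 1.0) ** gamma * fade
                for w in adj[u]:
                    if aoa[w] == 0:
                        A[w] += t
        fresh = (1.0 - kappa) if alpha > 0 else 0.0
        for _ in range(n_s):
            remaining = np.flatnonzero(aoa == 0)
            wts = base[remaining] * np.maximum(0.05, 1.0 + c_pa * A[remaining])
            w = int(rng.choice(remaining, p=wts / wts.sum()))
            aoa[w] = s
            order.append(w)
            deg_lex[w] = sum(1 for u in adj[w] if aoa[u])
            boost = (deg_lex[w] + 1.0) ** gamma * fresh
            for u in adj[w]:
                if aoa[u]:
                    deg_lex[u] += 1
                else:
                    A[u] += boost

    # Zipf frequencies over acquisition order with lognormal noise
    freq = {}
    for r, w in enumerate(order, start=1):
        noise = math.exp(rng.normal(0.0, config.freq_noise_sd))
        freq[w] = config.zipf_scale / (r ** config.zipf_exponent) * noise

    entries: dict[Transcription, LexiconEntry] = {}
    for w in order:
        phon = pool[w]
        entries[phon] = LexiconEntry(
            orth="".join(phon),
            phon=phon,
            aoa=int(aoa[w]),
            freq_raw=round(float(freq[w]), 4),
            l1_density=int(l1_density[w]),
        )
    lexicon = StagedLexicon(entries)

    ground_truth: dict[str, dict] = {}
    for w in order:
        a = int(aoa[w])
        gains = []
        for j in range(1, N_STAGES - a + 2):
            stage = a + j - 1
            if j == 1:
                g = sum(1 for u in adj[w] if 0 < aoa[u] <= stage)
            else:
                g = sum(1 for u in adj[w] if aoa[u] == stage)
            gains.append(g)
        label = None
        if len(gains) >= 3 and sum(gains) > 0:
            traj = trajectory_from_gains(pool[w], a, gains)
            label = growth_metrics.classify_growth_pattern(traj).value
        ground_truth["".join(pool[w])] = {
            "aoa": a,
            "gains": gains,
            "l1_density": int(l1_density[w]),
            "pattern": label,
        }
    return SyntheticLexicon(
        lexicon=lexicon, config=config, pool_size=pool_size, ground_truth=ground_truth
    )


def trajectory_from_gains(
    phon: Transcription, aoa: int, gains: list[int]
) -> growth_metrics.GrowthTrajectory:
    """Build a (weightless) trajectory from a per-spurt gain schedule."""
    spurts = []
    cum = 0
    for g in gains:
        cum += g
        spurts.append(
            growth_metrics.Spurt(
                neighbors_added=g, cumulative_degree=cum, added_weight=0, cumulative_weight=0
            )
        )
    return growth_metrics.GrowthTrajectory(phon=tuple(phon), aoa=aoa, spurts=tuple(spurts))


# ---------------------------------------------------------------------------
# Hand-crafted worked-example fixture
# ---------------------------------------------------------------------------

# Stage assignments of the miniature lexicon.  Three designated words carry
# the worked trajectories: "bad" (degree gains 8,3,2,1,1,1 -> final 16),
# "eni" (gains 2,0,2,0,1,0 against an L1 density of 15), and "bi"
# (7 neighbors of summed weight 352, expanding to 12 of summed weight 704).
_FIXTURE_STAGES: Mapping[str, int] = {
    # designated words
    "bad": 1, "eni": 1, "bi": 1,
    # neighbors of "bad"
    "pad": 1, "mad": 1, "sad": 1, "had": 1, "bed": 1, "bod": 1, "bat": 1, "ban": 1,
    "bag": 2, "bud": 2, "lad": 2,
    "fad": 3, "gad": 3,
    "tad": 4,
    "brad": 5,
    "rad": 6,
    # neighbors of "eni"
    "ani": 1, "enu": 1,
    "en": 3, "deni": 3,
    "enig": 5,
    # neighbors of "bi"
    "pi": 1, "mi": 1, "si": 1, "di": 1, "ti": 1, "be": 1, "vi": 1,
    "bin": 3, "bit": 3, "bis": 3, "bil": 3, "bu": 3,
}

_FIXTURE_L1 = {"bad": 20, "eni": 15, "bi": 14}

# Integer phonetic-similarity weights for the "bi" neighborhood; every other
# edge of the fixture defaults to 60.  The entry-stage seven sum to 352 and
# the five spurt-3 additions to another 352 (cumulative 704).
_BI_WEIGHTS = {
    "pi": 51, "mi": 51, "si": 50, "di": 50, "ti": 50, "be": 50, "vi": 50,
    "bin": 71, "bit": 71, "bis": 70, "bil": 70, "bu": 70,
}
_FIXTURE_DEFAULT_WEIGHT = 60


def fixture_weight_fn(a: Transcription, b: Transcription) -> int:
    """Edge-weight override reproducing the worked weighted-degree numbers."""
    pair = {"".join(a), "".join(b)}
    if "bi" in pair:
        (other,) = pair - {"bi"}
        return _BI_WEIGHTS.get(other, _FIXTURE_DEFAULT_WEIGHT)
    return _FIXTURE_DEFAULT_WEIGHT


def make_worked_example_fixture() -> StagedLexicon:
    """Miniature synthetic lexicon reproducing the worked growth examples.

    The neighbor structure is real (segment edit distance over the listed
    transcriptions); pair it with :func:`fixture_weight_fn` when building
    networks so the "bi" neighborhood carries the prescribed edge weights.
    """
    entries: dict[Transcription, LexiconEntry] = {}
    for i, (orth, stage) in enumerate(sorted(_FIXTURE_STAGES.items())):
        phon = tuple(orth)
        entries[phon] = LexiconEntry(
            orth=orth,
            phon=phon,
            aoa=stage,
            freq_raw=float(100 - 2 * i),
            l1_density=_FIXTURE_L1.get(orth, 30),
        )
    return StagedLexicon(entries)
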