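"""Segment-level edit distance and feature-weighted phonetic similarity.

Two primitives drive the network construction:

* **Neighbor detection** — two word forms are phonological neighbors when
  their transcriptions are at Levenshtein distance exactly 1 on the *segment*
  level (one substitution, deletion, or addition).  Transcriptions are token
  sequences; multi-character phone symbols must already be recoded to single
  tokens so that segment-level and character-level distance coincide.

* **Phonetic distance** — a dynamic-programming alignment in the style of
  Kondrak's ALINE algorithm.  Segment pairs are scored by weighted phonetic
  features (place, manner, voicing, nasality, vowel height/backness,
  rounding, length, ...), with skips and 1:2 expansions (e.g. a diphthong
  aligned against a monophthong).  The raw similarity is normalized to a
  distance in [0, 1]: 0 for segmentally identical forms (homophones), larger
  values for phonetically more distant pairs.  The distance is then reverse
  rescaled to an integer similarity in [0, 100] used as the network edge
  weight.

The normalization divides the alignment score by the larger of the two
self-alignment scores.  ALINE's raw score grows with word length, and the
larger self-score is the tightest symmetric upper bound available, keeping
the distance in [0, 1] without depending on which argument is longer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

from .types import StagedLexicon, Transcription

# ---------------------------------------------------------------------------
# Levenshtein distance and one-segment neighbor detection
# ---------------------------------------------------------------------------


def edit_distance(a: Transcription, b: Transcription) -> int:
    """Segment-level Levenshtein distance (substitution/deletion/addition)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("edit_distance requires non-empty transcriptions")
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, sa in enumerate(a, start=1):
        cur = [i]
        for j, sb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (sa != sb)))
        prev = cur
    return prev[-1]


def is_one_segment_neighbor(a: Transcription, b: Transcription) -> bool:
    """True iff ``a`` and ``b`` are at segment edit distance exactly 1.

    Specialized O(len) check: equal-length forms must differ in exactly one
    position; forms whose lengths differ by one must be related by a single
    deletion.  Provably equivalent to ``edit_distance(a, b) == 1``.
    """
    la, lb = len(a), len(b)
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) == 1
    if abs(la - lb) != 1:
        return False
    if la < lb:
        a, b = b, a
        la, lb = lb, la
    # a is longer by one: skip the first mismatch and require the rest equal
    i = 0
    while i < lb and a[i] == b[i]:
        i += 1
    return a[i + 1 :] == b[i:]


def find_neighbors(
    lexicon: StagedLexicon | Iterable[Transcription], stage: int | None = None
) -> set[tuple[Transcription, Transcription]]:
    """All unordered pairs of forms at edit distance exactly 1.

    With a :class:`StagedLexicon` and a stage, the cumulative stage vocabulary
    is used; a bare iterable of transcriptions is also accepted.  Candidate
    pairs are pruned by length (only ``|len(a) - len(b)| <= 1`` pairs can be
    neighbors), which is output-equivalent to the full quadratic scan.
    """
    if isinstance(lexicon, StagedLexicon):
        if stage is None:
            raise ValueError("stage is required with a StagedLexicon")
        forms = sorted(lexicon.stage_vocabulary(stage))
    else:
        forms = sorted(set(lexicon))
    by_len: dict[int, list[Transcription]] = {}
    for f in forms:
        by_len.setdefault(len(f), []).append(f)
    pairs: set[tuple[Transcription, Transcription]] = set()
    for length, group in by_len.items():
        for i, f in enumerate(group):
            for g in group[i + 1 :]:
                if is_one_segment_neighbor(f, g):
                    pairs.add((f, g))
            for g in by_len.get(length + 1, ()):
                if is_one_segment_neighbor(f, g):
                    pairs.add(tuple(sorted((f, g))))  # type: ignore[arg-type]
    return pairs


# ---------------------------------------------------------------------------
# ALINE-style feature-weighted alignment
# ---------------------------------------------------------------------------

_PLACE = {
    "bilabial": 1.0,
    "labiodental": 0.95,
    "dental": 0.9,
    "alveolar": 0.85,
    "retroflex": 0.8,
    "palato-alveolar": 0.75,
    "palatal": 0.7,
    "velar": 0.6,
    "uvular": 0.5,
    "pharyngeal": 0.3,
    "glottal": 0.1,
    # vowel placeholders derived from backness
    "vowel-front": 0.7,
    "vowel-central": 0.65,
    "vowel-back": 0.6,
}
_MANNER = {
    "stop": 1.0,
    "affricate": 0.9,
    "fricative": 0.8,
    "approximant": 0.6,
    "high-vowel": 0.4,
    "mid-vowel": 0.2,
    "low-vowel": 0.0,
}
_BACK = {"front": 1.0, "central": 0.5, "back": 0.0}

# Feature sets used for the pairwise difference: consonant pairs are compared
# on articulator features, any pair involving a vowel on vocalic features.
R_CONSONANT = ("place", "manner", "syllabic", "voice", "nasal", "retroflex", "lateral", "aspirated")
R_VOWEL = ("place", "syllabic", "nasal", "retroflex", "high", "back", "round", "long")


class UnknownSegmentError(KeyError):
    def __init__(self, segment: str):
        super().__init__(segment)
        self.segment = segment

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"segment {self.segment!r} has no feature vector in the feature table"


@dataclass(frozen=True)
class FeatureTable:
    """Numeric feature vectors, salience weights and alignment penalties.

    ``vectors`` maps each segment to a dict of numeric feature values in
    [0, 1]; ``salience`` weights each feature's contribution to the pairwise
    difference; ``c_skip``/``c_sub``/``c_exp`` are the alignment operation
    ceilings and ``c_vwl`` the vowel substitution penalty.
    """

    vectors: Mapping[str, Mapping[str, float]]
    salience: Mapping[str, float]
    c_skip: float = -10.0
    c_sub: float = 35.0
    c_exp: float = 45.0
    c_vwl: float = 10.0
    version: str = "0"

    def __post_init__(self) -> None:
        bad = [f for f, w in self.salience.items() if w < 0]
        if bad:
            raise ValueError(f"negative salience weight(s) for {bad}")

    @property
    def inventory(self) -> frozenset[str]:
        return frozenset(self.vectors)

    def vector(self, seg: str) -> Mapping[str, float]:
        try:
            return self.vectors[seg]
        except KeyError:
            raise UnknownSegmentError(seg) from None

    def is_vowel(self, seg: str) -> bool:
        return self.vector(seg)["syllabic"] == 1.0

    def v_penalty(self, seg: str) -> float:
        return self.c_vwl if self.is_vowel(seg) else 0.0

    def delta(self, p: str, q: str) -> float:
        """Weighted feature difference between two segments."""
        vp, vq = self.vector(p), self.vector(q)
        feats = R_CONSONANT if vp["syllabic"] == 0.0 and vq["syllabic"] == 0.0 else R_VOWEL
        return sum(abs(vp[f] - vq[f]) * self.salience[f] for f in feats)

    def sigma_sub(self, p: str, q: str) -> float:
        return self.c_sub - self.delta(p, q) - self.v_penalty(p) - self.v_penalty(q)

    def sigma_skip(self, p: str) -> float:
        # c_skip is a penalty (negative): leaving a segment unmatched must
        # never outscore matching it against an identical segment.
        return self.c_skip

    def sigma_exp(self, p: str, q1: str, q2: str) -> float:
        return (
            self.c_exp
            - self.delta(p, q1)
            - self.delta(p, q2)
            - self.v_penalty(p)
            - max(self.v_penalty(q1), self.v_penalty(q2))
        )

    def self_score(self, a: Transcription) -> float:
        """Score of aligning a form with itself (all identity substitutions)."""
        return sum(self.c_sub - 2.0 * self.v_penalty(p) for p in a)


def _numeric_vector(seg: str, spec: Mapping) -> dict[str, float]:
    """Translate a categorical segment description into numeric features."""
    if spec["type"] == "consonant":
        return {
            "syllabic": 0.0,
            "place": _PLACE[spec["place"]],
            "manner": _MANNER[spec["manner"]],
            "voice": float(spec.get("voice", 0)),
            "nasal": float(spec.get("nasal", 0)),
            "lateral": float(spec.get("lateral", 0)),
            "aspirated": float(spec.get("aspirated", 0)),
            "retroflex": float(spec.get("retroflex", 0)),
            "high": 0.0,
            "back": 0.5,
            "round": 0.0,
            "long": float(spec.get("long", 0)),
        }
    height = float(spec["height"])  # 1 high ... 0 low
    backness = spec["backness"]
    manner = "high-vowel" if height >= 0.75 else ("low-vowel" if height <= 0.25 else "mid-vowel")
    return {
        "syllabic": 1.0,
        "place": _PLACE[f"vowel-{backness}"],
        "manner": _MANNER[manner],
        "voice": 1.0,
        "nasal": float(spec.get("nasal", 0)),
        "lateral": 0.0,
        "aspirated": 0.0,
        "retroflex": float(spec.get("retroflex", 0)),
        "high": height,
        "back": _BACK[backness],
        "round": float(spec.get("round", 0)),
        "long": float(spec.get("long", 0)),
    }


def load_feature_table(path: str | None = None) -> FeatureTable:
    """Load a feature table from JSON (default: the table shipped in-package)."""
    if path is None:
        text = resources.files("phonogrow.data").joinpath("feature_table.json").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = json.loads(text)
    vectors = {seg: _numeric_vector(seg, spec) for seg, spec in raw["segments"].items()}
    params = raw.get("parameters", {})
    return FeatureTable(
        vectors=vectors,
        salience=raw["salience"],
        c_skip=params.get("c_skip", 10.0),
        c_sub=params.get("c_sub", 35.0),
        c_exp=params.get("c_exp", 45.0),
        c_vwl=params.get("c_vwl", 10.0),
        version=str(raw.get("version", "0")),
    )


@lru_cache(maxsize=1)
def default_feature_table() -> FeatureTable:
    return load_feature_table(None)


def aline_score(a: Transcription, b: Transcription, ft: FeatureTable) -> float:
    """Raw global alignment similarity (substitutions, skips, expansions)."""
    la, lb = len(a), len(b)
    NEG = -math.inf
    S = [[NEG] * (lb + 1) for _ in range(la + 1)]
    S[0][0] = 0.0
    for i in range(la + 1):
        for j in range(lb + 1):
            base = S[i][j]
            if base == NEG:
                continue
            if i < la:
                v = base + ft.sigma_skip(a[i])
                if v > S[i + 1][j]:
                    S[i + 1][j] = v
            if j < lb:
                v = base + ft.sigma_skip(b[j])
                if v > S[i][j + 1]:
                    S[i][j + 1] = v
            if i < la and j < lb:
                v = base + ft.sigma_sub(a[i], b[j])
                if v > S[i + 1][j + 1]:
                    S[i + 1][j + 1] = v
            if i < la and j + 1 < lb:
                v = base + ft.sigma_exp(a[i], b[j], b[j + 1])
                if v > S[i + 1][j + 2]:
                    S[i + 1][j + 2] = v
            if i + 1 < la and j < lb:
                v = base + ft.sigma_exp(b[j], a[i], a[i + 1])
                if v > S[i + 2][j + 1]:
                    S[i + 2][j + 1] = v
    return S[la][lb]


def aline_distance(a: Transcription, b: Transcription, ft: FeatureTable | None = None) -> float:
    """Feature-weighted phonetic distance in [0, 1]; 0 iff segmentally identical."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("aline_distance requires non-empty transcriptions")
    if ft is None:
        ft = default_feature_table()
    a, b = tuple(a), tuple(b)
    if a == b:
        return 0.0
    norm = max(ft.self_score(a), ft.self_score(b))
    if norm <= 0:
        raise ValueError("degenerate feature table: non-positive self score")
    d = 1.0 - aline_score(a, b, ft) / norm
    return min(1.0, max(0.0, d))


def rescale_similarity(d: float) -> int:
    """Reverse rescale a distance in [0,1] to an integer similarity in [0,100].

    100 is perfect phonetic similarity (homophones), 0 maximal distance.
    Round-half-up after multiplying by 100.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"distance out of [0, 1]: {d!r}")
    return int(math.floor((1.0 - d) * 100.0 + 0.5))


def similarity_int(a: Transcription, b: Transcription, ft: FeatureTable | None = None) -> int:
    """Integer edge weight: rescaled phonetic similarity between two forms."""
    return rescale_similarity(aline_distance(a, b, ft))
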