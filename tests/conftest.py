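"""Shared fixtures: worked-example lexicon, stage networks, small synthetic run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import phonogrow as pg
import phonogrow.stats_models as psm


@pytest.fixture(scope="session")
def worked_lexicon():
    return pg.make_worked_example_fixture()


@pytest.fixture(scope="session")
def worked_networks(worked_lexicon):
    return pg.build_all_networks(worked_lexicon, weight_fn=pg.fixture_weight_fn)


@pytest.fixture(scope="session")
def small_synthetic():
    """One deterministic synthetic lexicon small enough for fast tests."""
    cfg = pg.GeneratorConfig(seed=11, words_per_stage=(40, 55, 70, 80, 55, 50))
    return pg.generate(cfg)


@pytest.fixture(scope="session")
def small_networks(small_synthetic):
    return pg.build_all_networks(small_synthetic.lexicon)


def make_lexicon(stages: dict[str, int], l1: dict[str, int] | None = None) -> pg.StagedLexicon:
    """Build a StagedLexicon from {orth/phon-string: stage} (chars = segments)."""
    l1 = l1 or {}
    entries = {}
    for i, (word, stage) in enumerate(sorted(stages.items())):
        phon = tuple(word)
        entries[phon] = pg.LexiconEntry(
            orth=word, phon=phon, aoa=stage, freq_raw=float(10 + i), l1_density=l1.get(word, 25)
        )
    return pg.StagedLexicon(entries)


def simulate_proportional_table(
    n: int, beta: dict[str, float], rng: np.random.Generator, m_trials: int = 20
) -> pd.DataFrame:
    """Model table whose proportional DV follows a known binomial-logit law."""
    spurt = rng.integers(1, 7, n)
    aoa = rng.integers(1, 6, n)
    freq = rng.normal(1.0, 0.5, n)
    length = rng.integers(2, 8, n).astype(float)
    df = pd.DataFrame(dict(spurt=spurt, aoa=aoa, freq_log=freq, length=length))
    X = psm._design(df)
    eta = sum(v * X[k].to_numpy() for k, v in beta.items())
    p = 1.0 / (1.0 + np.exp(-eta))
    y = rng.binomial(m_trials, p) / m_trials
    df["prop_degree_gain"] = np.clip(y, 0.5 / m_trials / 2, 1 - 0.5 / m_trials / 2)
    df["prop_saturation_gain"] = df["prop_degree_gain"]
    return df


def simulate_zinb_table(
    n: int,
    beta_count: dict[str, float],
    beta_zero: dict[str, float],
    alpha: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Model table whose count DV follows a known zero-inflated NB2 law."""
    spurt = rng.integers(1, 7, n)
    aoa = rng.integers(1, 6, n)
    freq = rng.normal(1.0, 0.5, n)
    length = rng.integers(2, 8, n).astype(float)
    df = pd.DataFrame(dict(spurt=spurt, aoa=aoa, freq_log=freq, length=length))
    X = psm._design(df)
    mu = np.exp(sum(v * X[k].to_numpy() for k, v in beta_count.items()))
    pi = 1.0 / (1.0 + np.exp(-sum(v * X[k].to_numpy() for k, v in beta_zero.items())))
    y = rng.poisson(rng.gamma(1.0 / alpha, mu * alpha))
    y[rng.random(n) < pi] = 0
    df["avg_wd_int"] = y
    return df
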