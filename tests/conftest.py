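"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from fshd_nipd.core import GenotypeTable, Locus
from fshd_nipd.simulate import SimConfig


@pytest.fixture
def locus() -> Locus:
    return Locus("chr4", 190_060_000, 190_100_000)


@pytest.fixture
def small_config(locus) -> SimConfig:
    """Reduced panel for fast unit tests (study-scale tests build their own)."""
    return SimConfig(
        locus=locus,
        n_target_snps=80,
        n_background_snps=120,
        rng_seed=7,
    )


def make_genotype_table(rows) -> GenotypeTable:
    """rows: (chrom, pos, ref, alt, gf, gm, fa, mo) with GT strings or dosages."""
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "grandfather", "grandmother", "father", "mother"],
    )
    return GenotypeTable(df)


# ------------------------------------------------------------- HMM oracles

def enumerate_all_paths(log_e: np.ndarray, gaps: np.ndarray, c: float, prior) -> dict:
    """Exhaustive two-state HMM reference: sums/maxima over all 2^n paths.

    Independent of the package's recursions: scores every path explicitly.
    Returns the total log-likelihood, per-site posteriors of state 0, the
    best path score and one best path.
    """
    n = log_e.shape[0]
    paths = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(np.int8)
    log_prior = np.log(np.asarray(prior, dtype=float))
    scores = log_prior[paths[:, 0]] + log_e[np.arange(n), paths].sum(axis=1)
    if n > 1:
        r = 0.5 * (1.0 - np.exp(-2.0 * c * np.asarray(gaps, dtype=float)))
        switched = paths[:, 1:] != paths[:, :-1]
        with np.errstate(divide="ignore"):
            scores = scores + np.where(switched, np.log(r), np.log1p(-r)).sum(axis=1)
    total = logsumexp(scores)
    post0 = np.array(
        [np.exp(logsumexp(scores[paths[:, i] == 0]) - total) for i in range(n)]
    )
    best = int(np.argmax(scores))
    return {
        "loglik": float(total),
        "posterior_state0": post0,
        "viterbi_score": float(scores[best]),
        "viterbi_path": paths[best],
    }


def random_observation_sequence(rng: np.random.Generator, n_max: int = 12):
    """A random, well-formed observation sequence for oracle comparisons."""
    from fshd_nipd.hmm import ObservationSequence

    n = int(rng.integers(1, n_max + 1))
    pos = np.sort(rng.choice(np.arange(1, 5_000_000), size=n, replace=False))
    depth = rng.integers(0, 60, size=n)
    b_count = rng.binomial(depth, rng.uniform(0, 0.3, size=n))
    return ObservationSequence(
        chrom="chr4",
        pos=pos,
        b_is_alt=rng.random(n) < 0.5,
        hap0_carries_b=rng.random(n) < 0.5,
        depth=depth,
        b_count=b_count,
    )
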