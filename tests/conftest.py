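"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from replinet import synthetic as syn

NEG_INF = float("-inf")


def gotoh_score(
    target: str,
    query: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -0.5,
) -> float:
    """Independent affine-gap global alignment score (pure-Python Gotoh DP).

    A gap of length L scores ``gap_open + gap_extend * (L - 1)``. Used as
    an oracle on small instances; deliberately unoptimized.
    """
    n, m = len(target), len(query)
    # M: last column aligned; X: gap in query (target consumed); Y: gap in target
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if target[i - 1] == query[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                X[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
            )
    return max(M[n][m], X[n][m], Y[n][m])


@pytest.fixture(scope="session")
def refs() -> syn.ReferenceSet:
    return syn.generate_references(seed=11)


@pytest.fixture(scope="session")
def five_rates():
    return syn.five_species_rates()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
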