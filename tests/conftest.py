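"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-derivations of the definitions
(brute-force repeat enumeration, brute-force single-indel placement) used
to validate the optimized implementations; they must stay independent of
the package's internals.
"""

from __future__ import annotations

import numpy as np
import pytest

# canonical worked sequence: arms GCAT at 2 and 8, cut in the TT spacer
FIXTURE_WT = "AAGCATTTGCATCC"
FIXTURE_CUT = 7


def brute_force_patterns(context: str, cut: int, min_arm: int = 3):
    """O(n^3) enumeration of deduplicated cut-spanning repeat pairs.

    Returns a set of (lam, left, right, product) keeping, per distinct
    deletion product, the pair with maximal arm length (leftmost on ties).
    """
    n = len(context)
    best: dict[str, tuple[int, int, int]] = {}
    for lam in range(min_arm, n):
        for i in range(0, cut - lam + 1):
            for r in range(max(i + lam, cut), n - lam + 1):
                if context[i: i + lam] != context[r: r + lam]:
                    continue
                product = context[:i] + context[r:]
                prev = best.get(product)
                if prev is None or (lam, -i) > (prev[0], -prev[1]):
                    best[product] = (lam, i, r)
    return {(v[0], v[1], v[2], k) for k, v in best.items()}


def brute_force_simple_indel(wt: str, read: str):
    """All (kind, left, length) single-indel explanations of a read."""
    out = []
    d = len(read) - len(wt)
    if d < 0:
        for i in range(len(read) + 1):
            if wt[:i] + wt[i - d:] == read:
                out.append(("deletion", i, -d))
    elif d > 0:
        for i in range(len(wt) + 1):
            if wt[:i] + read[i: i + d] + wt[i:] == read:
                out.append(("insertion", i, d))
    return out


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def fixture_wt():
    return FIXTURE_WT
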