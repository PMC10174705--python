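"""Evolutionary descriptors vs independent brute-force oracles.

The oracles below re-derive each descriptor with explicit Python loops
over the defining sums, independently of the vectorized implementation.
"""

import numpy as np
import pytest

from acrscreen.io import AA_ORDER, PSSM
from acrscreen.pssm_features import (
    RPSSM_GROUPS,
    dpc_pssm,
    evolutionary_features,
    pssm_ac,
    pssm_composition,
    rpssm,
)

from conftest import random_pssm


# ---------------------------------------------------------------------------
# Brute-force oracles (loop-based, no shared code with the implementation)
# ---------------------------------------------------------------------------

def oracle_composition(pssm: PSSM) -> np.ndarray:
    L = len(pssm.sequence)
    out = np.zeros((20, 20))
    for a_idx, a in enumerate(AA_ORDER):
        for j in range(20):
            s = 0.0
            for k in range(L):
                if pssm.sequence[k] == a:
                    s += pssm.scores[k, j]
            out[a_idx, j] = s / L
    return out.ravel()


def oracle_dpc(pssm: PSSM) -> np.ndarray:
    L = len(pssm.sequence)
    out = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            s = 0.0
            for k in range(L - 1):
                s += pssm.scores[k, i] * pssm.scores[k + 1, j]
            out[i, j] = s / (L - 1)
    return out.ravel()


def oracle_ac(pssm: PSSM, G: int) -> np.ndarray:
    L = len(pssm.sequence)
    out = np.zeros((20, G))
    for j in range(20):
        mean_j = sum(pssm.scores[k, j] for k in range(L)) / L
        for g in range(1, G + 1):
            s = 0.0
            for k in range(L - g):
                s += (pssm.scores[k, j] - mean_j) * (
                    pssm.scores[k + g, j] - mean_j
                )
            out[j, g - 1] = s / (L - g)
    return out.ravel()


def oracle_rpssm(pssm: PSSM) -> np.ndarray:
    L = len(pssm.sequence)
    cols = {a: i for i, a in enumerate(AA_ORDER)}
    p = np.zeros((L, 10))
    for i in range(L):
        for s_idx, group in enumerate(RPSSM_GROUPS):
            p[i, s_idx] = np.mean([pssm.scores[i, cols[a]] for a in group])
    pairs = np.zeros((10, 10))
    for s in range(10):
        for t in range(10):
            acc = 0.0
            for i in range(L - 1):
                acc += (p[i, s] - p[i + 1, t]) ** 2 / 2.0
            pairs[s, t] = acc / (L - 1)
    variances = np.zeros(10)
    for s in range(10):
        mean_s = sum(p[i, s] for i in range(L)) / L
        variances[s] = sum((p[i, s] - mean_s) ** 2 for i in range(L)) / L
    return np.concatenate([pairs.ravel(), variances])


# ---------------------------------------------------------------------------
# Oracle agreement on random PSSMs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "transform,oracle",
    [
        (pssm_composition, oracle_composition),
        (dpc_pssm, oracle_dpc),
        (lambda p: pssm_ac(p, 10), lambda p: oracle_ac(p, 10)),
        (rpssm, oracle_rpssm),
    ],
    ids=["composition", "dpc", "ac", "rpssm"],
)
def test_transform_matches_bruteforce_oracle(transform, oracle):
    """Each descriptor equals its loop oracle on 30 random PSSMs."""
    rng = np.random.default_rng(42)
    for _ in range(30):
        pssm = random_pssm(rng, int(rng.integers(11, 41)))
        got = transform(pssm)
        want = oracle(pssm)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)


# ---------------------------------------------------------------------------
# Trivial algebraic cases
# ---------------------------------------------------------------------------

def _const_pssm(L: int, value: float) -> PSSM:
    seq = (AA_ORDER * 3)[:L]
    return PSSM(sequence=seq, scores=np.full((L, 20), value))


def test_zero_pssm_gives_zero_composition_and_dpc():
    z = _const_pssm(5, 0.0)
    assert not pssm_composition(z).any()
    assert not dpc_pssm(z).any()


def test_single_position_composition_block():
    v = np.arange(20, dtype=float).reshape(1, 20)
    p = PSSM(sequence="A", scores=v)
    c = pssm_composition(p).reshape(20, 20)
    np.testing.assert_array_equal(c[AA_ORDER.index("A")], v[0])
    others = np.delete(c, AA_ORDER.index("A"), axis=0)
    assert not others.any()


def test_all_ones_dpc_is_all_ones():
    p = _const_pssm(4, 1.0)
    np.testing.assert_allclose(dpc_pssm(p), np.ones(400))


def test_constant_columns_kill_ac_and_rpssm():
    p = _const_pssm(30, 3.0)
    assert np.allclose(pssm_ac(p, 10), 0.0)
    assert np.allclose(rpssm(p), 0.0)


def test_ac_length_boundary():
    rng = np.random.default_rng(0)
    assert pssm_ac(random_pssm(rng, 11), 10).shape == (200,)
    with pytest.raises(ValueError, match="length"):
        pssm_ac(random_pssm(rng, 10), 10)


def test_dpc_short_sequence_error():
    p = PSSM(sequence="A", scores=np.zeros((1, 20)))
    with pytest.raises(ValueError, match="L<2"):
        dpc_pssm(p)


# ---------------------------------------------------------------------------
# Structural and algebraic invariants
# ---------------------------------------------------------------------------

def test_concatenation_order_and_dimensions():
    rng = np.random.default_rng(1)
    p = random_pssm(rng, 25)
    ef = evolutionary_features(p)
    assert ef.dimension == 1110
    np.testing.assert_array_equal(ef.concatenated[:400], ef.composition)
    np.testing.assert_array_equal(ef.concatenated[400:800], ef.dpc)
    np.testing.assert_array_equal(ef.concatenated[800:1000], ef.ac)
    np.testing.assert_array_equal(ef.concatenated[1000:], ef.rpssm)
    assert np.isfinite(ef.concatenated).all()
    assert evolutionary_features(p, lag_bound=5).dimension == 1010


def test_column_shift_invariance_pattern():
    """AC is centered (shift-invariant per column); composition and DPC
    are not."""
    rng = np.random.default_rng(2)
    p = random_pssm(rng, 30)
    shifted = PSSM(sequence=p.sequence, scores=p.scores + 5.0)
    np.testing.assert_allclose(
        pssm_ac(p, 10), pssm_ac(shifted, 10), atol=1e-9
    )
    assert not np.allclose(pssm_composition(p), pssm_composition(shifted))
    assert not np.allclose(dpc_pssm(p), dpc_pssm(shifted))


def test_scaling_degrees():
    """Scaling scores by c scales composition by c and the quadratic
    descriptors by c^2."""
    rng = np.random.default_rng(3)
    p = random_pssm(rng, 30)
    c = 3.0
    scaled = PSSM(sequence=p.sequence, scores=c * p.scores)
    np.testing.assert_allclose(
        pssm_composition(scaled), c * pssm_composition(p), rtol=1e-9
    )
    np.testing.assert_allclose(dpc_pssm(scaled), c**2 * dpc_pssm(p), rtol=1e-9)
    np.testing.assert_allclose(
        pssm_ac(scaled, 10), c**2 * pssm_ac(p, 10), rtol=1e-9
    )
    np.testing.assert_allclose(rpssm(scaled), c**2 * rpssm(p), rtol=1e-9)


def test_sigmoid_option_bounds_composition():
    rng = np.random.default_rng(4)
    p = random_pssm(rng, 20)
    comp = pssm_composition(p, sigmoid=True).reshape(20, 20)
    # each block row is a 1/L-weighted sum of sigmoids: within [0, 1]
    assert comp.min() >= 0.0
    assert comp.max() <= 1.0
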