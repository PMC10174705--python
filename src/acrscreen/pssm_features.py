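"""Fixed-size evolutionary descriptors of a variable-length PSSM.

Four standard transforms summarize an L x 20 position-specific scoring
matrix S (columns in the order A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,V,W,Y)
into fixed-length vectors:

PSSM-composition (400)
    Per residue type ``a`` and column ``j``:
    ``(1/L) * sum_{k: seq_k = a} S[k, j]`` — the length-normalized column
    profile of each residue type. Rows whose sequence letter is
    nonstandard contribute to no block.

DPC-PSSM (400)
    Dipeptide-style adjacent-position products:
    ``(1/(L-1)) * sum_k S[k, i] * S[k+1, j]``.

PSSM-AC (20 x G, default G=10 -> 200)
    Per-column lagged auto-covariance after centering each column at its
    mean: ``(1/(L-g)) * sum_k (S[k,j]-m_j)(S[k+g,j]-m_j)`` for lags
    ``g = 1..G``; captures local sequence-order effects.

RPSSM (110)
    The 20 columns are first averaged into 10 physicochemical groups
    ({F,Y,W}, {M,L}, {I,V}, {A,T,S}, {N,H}, {Q,E,D}, {R,K}, {C}, {G},
    {P}), giving an L x 10 reduced matrix p. The descriptor concatenates
    100 adjacent-row pair terms
    ``(1/(L-1)) * sum_i (p[i,s]-p[i+1,t])^2 / 2`` and 10 per-column
    variances ``(1/L) * sum_i (p[i,s]-mean_s)^2``.

All four accept raw log-odds scores by default; ``sigmoid=True`` squashes
every score through 1/(1+exp(-x)) first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AA_ORDER, PSSM

#: Reduced 10-group alphabet used by RPSSM, in fixed order.
RPSSM_GROUPS: tuple[tuple[str, ...], ...] = (
    ("F", "Y", "W"),
    ("M", "L"),
    ("I", "V"),
    ("A", "T", "S"),
    ("N", "H"),
    ("Q", "E", "D"),
    ("R", "K"),
    ("C",),
    ("G",),
    ("P",),
)

_AA_INDEX = {ch: i for i, ch in enumerate(AA_ORDER)}
_GROUP_COLS = [
    np.array([_AA_INDEX[a] for a in group]) for group in RPSSM_GROUPS
]


@dataclass
class EvolutionaryFeatures:
    """The four PSSM descriptors and their fixed-order concatenation."""

    composition: np.ndarray  # 400
    dpc: np.ndarray  # 400
    ac: np.ndarray  # 20 * G
    rpssm: np.ndarray  # 110

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate(
            [self.composition, self.dpc, self.ac, self.rpssm]
        )

    @property
    def dimension(self) -> int:
        return self.concatenated.shape[0]


def _scores(pssm: PSSM, sigmoid: bool) -> np.ndarray:
    s = np.asarray(pssm.scores, dtype=float)
    if sigmoid:
        s = 1.0 / (1.0 + np.exp(-s))
    return s


def pssm_composition(pssm: PSSM, sigmoid: bool = False) -> np.ndarray:
    """400-vector: length-normalized per-residue-type column sums.

    Flattened residue-type-major: entry ``20*a + j`` is the (a, j) block.
    """
    s = _scores(pssm, sigmoid)
    length = s.shape[0]
    out = np.zeros((20, 20))
    for k, ch in enumerate(pssm.sequence):
        a = _AA_INDEX.get(ch)
        if a is not None:
            out[a] += s[k]
    return (out / length).ravel()


def dpc_pssm(pssm: PSSM, sigmoid: bool = False) -> np.ndarray:
    """400-vector of adjacent-position column products, flattened (i, j)."""
    s = _scores(pssm, sigmoid)
    length = s.shape[0]
    if length < 2:
        raise ValueError("DPC-PSSM undefined for L<2")
    return (s[:-1].T @ s[1:]).ravel() / (length - 1)


def pssm_ac(pssm: PSSM, lag_bound: int = 10, sigmoid: bool = False) -> np.ndarray:
    """(20*G)-vector of per-column auto-covariances, flattened column-major.

    Entry ``G*j + (g-1)`` is column j at lag g. Requires L > G.
    """
    if lag_bound < 1:
        raise ValueError("lag bound must be >= 1")
    s = _scores(pssm, sigmoid)
    length = s.shape[0]
    if length <= lag_bound:
        raise ValueError(
            f"PSSM-AC with lag bound {lag_bound} requires length > "
            f"{lag_bound}, got {length}"
        )
    centered = s - s.mean(axis=0)
    out = np.empty((20, lag_bound))
    for g in range(1, lag_bound + 1):
        out[:, g - 1] = (centered[:-g] * centered[g:]).sum(axis=0) / (
            length - g
        )
    return out.ravel()


def rpssm(pssm: PSSM, sigmoid: bool = False) -> np.ndarray:
    """110-vector: 100 reduced-alphabet pair terms then 10 column variances."""
    s = _scores(pssm, sigmoid)
    length = s.shape[0]
    if length < 2:
        raise ValueError("RPSSM undefined for L<2")
    reduced = np.column_stack([s[:, cols].mean(axis=1) for cols in _GROUP_COLS])
    head, tail = reduced[:-1], reduced[1:]
    # pairs[s, t] = mean over i of (p[i,s] - p[i+1,t])^2 / 2
    diffs = head[:, :, None] - tail[:, None, :]
    pairs = (diffs**2).sum(axis=0) / (2.0 * (length - 1))
    variances = ((reduced - reduced.mean(axis=0)) ** 2).sum(axis=0) / length
    return np.concatenate([pairs.ravel(), variances])


def evolutionary_features(
    pssm: PSSM, lag_bound: int = 10, sigmoid: bool = False
) -> EvolutionaryFeatures:
    """Compute all four descriptors; default total dimension 1110.

    Concatenation order is fixed: [composition | dpc | ac | rpssm].
    """
    return EvolutionaryFeatures(
        composition=pssm_composition(pssm, sigmoid),
        dpc=dpc_pssm(pssm, sigmoid),
        ac=pssm_ac(pssm, lag_bound, sigmoid),
        rpssm=rpssm(pssm, sigmoid),
    )


def evolutionary_dimension(lag_bound: int = 10) -> int:
    """Total descriptor length for a given auto-covariance lag bound."""
    return 400 + 400 + 20 * lag_bound + 110
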