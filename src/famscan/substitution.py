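"""Amino-acid alphabet and the JTT empirical substitution model.

The package uses a single canonical amino-acid ordering (the classic
A R N D C Q E G H I L K M F P S T W Y V order used by most phylogenetics
software) everywhere: profile-HMM emission vectors, background frequency
tables, and rate matrices all index residues in this order.

The Jones-Taylor-Thornton (JTT) model is specified by a symmetric
exchangeability matrix (stored below as the strict lower triangle, 190
values) and a vector of equilibrium amino-acid frequencies.  The same
frequency vector doubles as the package's canonical background
distribution for profile-HMM null models: it is an empirical average over
a large protein database and is the conventional choice when no
alignment-specific background is requested.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20

# JTT pairwise exchangeabilities, strict lower triangle, row-major:
# row i (i = 1..19) holds s(i, j) for j < i in AMINO_ACIDS order.
_JTT_LOWER = np.array([
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475,
    9, 11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74,
    101, 64, 126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10,
    15, 503, 232, 8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15,
    59, 38, 4, 46, 31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115,
    209, 62, 323, 26, 597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20,
    119, 26, 12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14,
    5, 24, 201, 33, 55, 8, 47, 16, 56, 45, 33, 40, 115, 73, 46, 8, 573,
    11, 229, 21, 479, 89, 10, 40, 245, 9, 32, 961, 14, 388, 248, 102, 59,
    25, 52, 24, 180, 65, 4, 21, 47, 103, 10, 8, 14, 43, 16, 29, 226, 24,
    18, 323, 17, 92, 12, 53, 536, 62, 285, 118, 6, 10, 23, 477, 35, 63,
    38, 12, 21, 112, 71, 25, 16,
], dtype=float)

JTT_FREQS = np.array([
    0.07674792325, 0.05169094831, 0.04264495736, 0.05154394846,
    0.01980298020, 0.04075195925, 0.06182993817, 0.07315192685,
    0.02294397706, 0.05376094624, 0.09190390810, 0.05867594132,
    0.02382597617, 0.04012595987, 0.05090094910, 0.06876493124,
    0.05856494144, 0.01426098574, 0.03210196790, 0.06600493400,
])
JTT_FREQS = JTT_FREQS / JTT_FREQS.sum()

#: Canonical background amino-acid frequencies used by profile-HMM null
#: models unless the caller supplies their own.
BACKGROUND_FREQS = JTT_FREQS.copy()


def jtt_exchangeabilities() -> np.ndarray:
    """Return the symmetric 20x20 JTT exchangeability matrix (zero diagonal)."""
    s = np.zeros((N_AA, N_AA))
    idx = 0
    for i in range(1, N_AA):
        for j in range(i):
            s[i, j] = s[j, i] = _JTT_LOWER[idx]
            idx += 1
    return s


def rate_matrix(exchangeabilities: np.ndarray | None = None,
                freqs: np.ndarray | None = None) -> np.ndarray:
    """Build a reversible rate matrix Q from exchangeabilities and frequencies.

    Q_ij = s_ij * pi_j for i != j, diagonal set so rows sum to zero, and the
    whole matrix rescaled so the expected substitution rate at equilibrium,
    -sum_i pi_i Q_ii, equals one.  Branch lengths used with this Q are then
    expected substitutions per site.
    """
    s = jtt_exchangeabilities() if exchangeabilities is None else exchangeabilities
    pi = JTT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -np.dot(pi, np.diag(q))
    return q / mu


def encode_protein(seq: str, unknown_ok: bool = True) -> np.ndarray:
    """Encode an amino-acid string as integer indices; unknown/X become -1."""
    out = np.empty(len(seq), dtype=np.int64)
    for i, a in enumerate(seq.upper()):
        code = AA_INDEX.get(a, -1)
        if code < 0 and not unknown_ok and a != "X":
            raise ValueError(f"unknown amino acid {a!r} at position {i}")
        out[i] = code
    return out
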