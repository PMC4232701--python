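"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and recursion
shortcuts: paths are enumerated explicitly, parsimony is solved by
exhaustive labeling, and codons are looked up one at a time.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# independent codon table (transcribed, not imported from the package)
_BASES = "TCAG"
_AA_ORDER = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
CODON_TABLE = {a + b + c: _AA_ORDER[16 * i + 4 * j + k]
               for i, a in enumerate(_BASES)
               for j, b in enumerate(_BASES)
               for k, c in enumerate(_BASES)}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def codon_translate(nuc: str) -> str:
    """Per-codon lookup translation (frame +1, N-containing codons -> X)."""
    out = []
    for i in range(0, len(nuc) - len(nuc) % 3, 3):
        codon = nuc[i:i + 3].upper()
        out.append(CODON_TABLE[codon] if "N" not in codon else "X")
    return "".join(out)


def enum_forward_viterbi(hmm, codes: list[int]) -> tuple[float, float]:
    """Exhaustive path enumeration of the local profile-HMM model.

    Returns (ln forward odds, ln best-path odds) by recursing over every
    legal state path with any entry/exit match state and any placement of
    the aligned core in the target.
    """
    M, L = hmm.M, len(codes)
    em = hmm.match_emit / hmm.background[None, :]
    ei = hmm.insert_emit / hmm.background
    entry = 2.0 / (M * (M + 1))
    total = 0.0
    best = 0.0

    def rec(kind: str, k: int, t: int, prob: float) -> None:
        nonlocal total, best
        if kind == "M":
            total += prob * entry
            best = max(best, prob * entry)
            if k < M - 1:
                if t < L:
                    rec("M", k + 1, t + 1, prob * hmm.t_m[k, 0] * em[k + 1, codes[t]])
                    rec("I", k, t + 1, prob * hmm.t_m[k, 1] * ei[codes[t]])
                rec("D", k + 1, t, prob * hmm.t_m[k, 2])
        elif kind == "I":
            if t < L:
                rec("M", k + 1, t + 1, prob * hmm.t_i[k, 0] * em[k + 1, codes[t]])
                rec("I", k, t + 1, prob * hmm.t_i[k, 1] * ei[codes[t]])
        else:  # D
            if k < M - 1:
                if t < L:
                    rec("M", k + 1, t + 1, prob * hmm.t_d[k, 0] * em[k + 1, codes[t]])
                rec("D", k + 1, t, prob * hmm.t_d[k, 1])

    for i in range(M):
        for t0 in range(L):
            rec("M", i, t0 + 1, em[i, codes[t0]])
    return math.log(total), math.log(best)


def brute_force_parsimony(tree, tip_states: dict[str, int]) -> int:
    """Minimum number of state changes over all internal 0/1 labelings."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        states = dict(zip((id(n) for n in internal), assignment))
        for leaf in tree.leaf_node_iter():
            states[id(leaf)] = tip_states[leaf.taxon.label]
        changes = sum(1 for n in tree.preorder_node_iter()
                      if n.parent_node is not None
                      and states[id(n)] != states[id(n.parent_node)])
        best = changes if best is None else min(best, changes)
    return best


def random_profile(rng: np.random.Generator, M: int, background: np.ndarray):
    """A random but valid profile HMM for oracle comparisons."""
    from famscan.profilehmm import ProfileHMM
    return ProfileHMM(
        name=f"rand{M}", subfamily="s", region="r", M=M,
        match_emit=rng.dirichlet(np.ones(20) * 0.5, size=M),
        insert_emit=background.copy(),
        t_m=rng.dirichlet(np.ones(3), size=M),
        t_i=rng.dirichlet(np.ones(2), size=M),
        t_d=rng.dirichlet(np.ones(2), size=M),
        background=background.copy())
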