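"""Profile hidden Markov models: construction, scoring, calibration, logos.

This module is a self-contained replacement for the build/search half of a
profile-HMM toolchain.  A profile is built from a labeled multiple
alignment (match columns by occupancy, background-proportional
pseudocounts, optional position-based sequence weighting), scored against
target peptides with local-alignment forward and Viterbi dynamic
programming, and calibrated against random background sequences so that
bit scores convert to E-values through a fitted Gumbel distribution.

Local-alignment architecture
----------------------------
The model is unihit and local on both ends.  An alignment fragment enters
at any match state i and exits at any match state j >= i; every (i, j)
fragment choice carries the same prior mass 2 / (M (M + 1)), i.e. uniform
over the M (M + 1) / 2 possible fragments.  Within the fragment, paths
move through match, insert, and delete states under the profile's
transition probabilities.  Target residues outside the aligned core are
emitted by the background model, so they contribute zero log-odds; the
forward sum over all placements of the core in the target is the score.
Scores are computed in natural-log space and reported in bits
(log2 odds versus the background model).

This architecture is deliberately simpler than HMMER3's (no Dirichlet
mixture priors, no multihit model, no parametric length model); its
correctness is defined by exact path enumeration, which the test suite
performs on small instances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .seqkit import MsAlignment
from .substitution import AMINO_ACIDS, AA_INDEX, BACKGROUND_FREQS, N_AA, encode_protein

LN2 = math.log(2.0)
EULER_GAMMA = 0.5772156649015329

DEFAULT_SYMFRAC = 0.5
DEFAULT_TAU = 5.0
DEFAULT_N_CAL = 200
DEFAULT_INDEL_THRESHOLD = 0.10

SCHEMA_VERSION = "famscan-hmm-1"


@dataclass
class Gumbel:
    """Gumbel (extreme-value) null distribution of bit scores."""

    mu: float
    lambda_g: float
    n_cal: int
    len_cal: int
    seed: int


@dataclass
class HitScore:
    """Score of one profile against one target sequence."""

    bit_score: float
    evalue: float | None
    raw_forward: float  # natural-log forward odds
    query: str
    target: str


@dataclass
class LogoPosition:
    position: int
    relative_entropy: float  # bits
    letters: list[tuple[str, float]]  # (residue, height), descending
    indel: bool


@dataclass
class ProfileHMM:
    """A calibratable profile HMM for one (subfamily, region) pair.

    match_emit is (M, 20); insert_emit and background are (20,);
    t_m / t_i / t_d hold per-state outgoing transition distributions
    (M, 3) over (M->M, M->I, M->D), (M, 2) over (I->M, I->I) and (M, 2)
    over (D->M, D->D); row k describes transitions from state k+1 toward
    state k+2 (the final row is unused by the dynamic programming).
    """

    name: str
    subfamily: str
    region: str
    M: int
    match_emit: np.ndarray
    insert_emit: np.ndarray
    t_m: np.ndarray
    t_i: np.ndarray
    t_d: np.ndarray
    background: np.ndarray
    calibration: Gumbel | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.match_emit = np.asarray(self.match_emit, dtype=float)
        self.insert_emit = np.asarray(self.insert_emit, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.t_m = np.asarray(self.t_m, dtype=float)
        self.t_i = np.asarray(self.t_i, dtype=float)
        self.t_d = np.asarray(self.t_d, dtype=float)
        if self.M < 1 or self.match_emit.shape != (self.M, N_AA):
            raise ValueError("match_emit must have shape (M, 20) with M >= 1")
        for name, arr, width in (("match_emit", self.match_emit, None),
                                 ("t_m", self.t_m, 3), ("t_i", self.t_i, 2),
                                 ("t_d", self.t_d, 2)):
            if width is not None and arr.shape != (self.M, width):
                raise ValueError(f"{name} must have shape (M, {width})")
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(arr.sum(axis=-1), 1.0, atol=1e-12):
                raise ValueError(f"{name} rows must sum to 1")
        for name, vec in (("insert_emit", self.insert_emit),
                          ("background", self.background)):
            if vec.shape != (N_AA,) or np.any(vec < 0):
                raise ValueError(f"{name} must be a nonnegative length-20 vector")
            if not math.isclose(vec.sum(), 1.0, abs_tol=1e-12):
                raise ValueError(f"{name} must sum to 1")
        self._cache = {}

    # -- cached log-space parameterization ---------------------------------

    def _log_params(self) -> dict:
        cache = self._cache.get("log_params")
        if cache is not None:
            return cache
        with np.errstate(divide="ignore"):
            lbg = np.log(self.background)
            lem = np.log(self.match_emit) - lbg[None, :]
            lei = np.log(self.insert_emit) - lbg
            lt_m = np.log(self.t_m)
            lt_i = np.log(self.t_i)
            lt_d = np.log(self.t_d)
        # column 20 = unknown residue ('X'): odds ratio 1
        lem_ext = np.concatenate([lem, np.zeros((self.M, 1))], axis=1)
        lei_ext = np.concatenate([lei, [0.0]])
        entry = math.log(2.0 / (self.M * (self.M + 1)))
        # floor log-probabilities so zero-probability transitions stay
        # representable in the vectorized delete-chain cumulation
        floor = -1e8
        cache = dict(lem_ext=lem_ext, lei_ext=lei_ext, entry=entry,
                     ltmm=np.maximum(lt_m[:, 0], floor),
                     ltmi=np.maximum(lt_m[:, 1], floor),
                     ltmd=np.maximum(lt_m[:, 2], floor),
                     ltim=np.maximum(lt_i[:, 0], floor),
                     ltii=np.maximum(lt_i[:, 1], floor),
                     ltdm=np.maximum(lt_d[:, 0], floor),
                     ltdd=np.maximum(lt_d[:, 1], floor))
        # ctdd[k] = sum_{i<k} ln t(D_i -> D_{i+1}); used by the delete chain
        cache["ctdd"] = np.concatenate([[0.0], np.cumsum(cache["ltdd"][:-1])])
        self._cache["log_params"] = cache
        return cache


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def assign_match_columns(aln: MsAlignment, symfrac: float = DEFAULT_SYMFRAC) -> np.ndarray:
    """Mark column k as a match column iff its non-gap fraction >= symfrac."""
    if not 0 < symfrac <= 1:
        raise ValueError("symfrac must be in (0, 1]")
    nrows = aln.nrows
    mask = np.zeros(aln.ncols, dtype=bool)
    for k in range(aln.ncols):
        occ = sum(1 for c in aln.column(k) if c != "-")
        mask[k] = occ / nrows >= symfrac
    if not mask.any():
        raise ValueError("no consensus columns: every column fails symfrac")
    return mask


def henikoff_weights(aln: MsAlignment, mask: np.ndarray) -> np.ndarray:
    """Position-based sequence weights computed on match columns only.

    Each match column distributes one unit of weight: a row holding residue
    a in a column with r distinct residues, a appearing s times, receives
    1/(r*s).  Weights are normalized to mean one.
    """
    n = aln.nrows
    w = np.zeros(n)
    for k in np.nonzero(mask)[0]:
        col = aln.column(k)
        residues = [c for c in col if c != "-"]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for i, c in enumerate(col):
            if c != "-":
                w[i] += 1.0 / (r * counts[c])
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


def build_profile(aln: MsAlignment, *, name: str = "", subfamily: str = "",
                  region: str = "", symfrac: float = DEFAULT_SYMFRAC,
                  tau: float = DEFAULT_TAU, weighting: str = "position",
                  background: np.ndarray | None = None) -> ProfileHMM:
    """Estimate a profile HMM from a gapped alignment.

    Match emissions are pseudocount-smoothed weighted counts,
    e_k(a) = (c_k(a) + tau q(a)) / (C_k + tau); insert states emit the
    background; transitions are Laplace-smoothed counts of the
    match/insert/delete path each row implies over the match-column mask.
    """
    if weighting not in ("position", "uniform"):
        raise ValueError("weighting must be 'position' or 'uniform'")
    q = BACKGROUND_FREQS if background is None else np.asarray(background, float)
    mask = assign_match_columns(aln, symfrac)
    match_cols = np.nonzero(mask)[0]
    M = len(match_cols)
    if weighting == "position":
        w = henikoff_weights(aln, mask)
    else:
        w = np.ones(aln.nrows)

    counts = np.zeros((M, N_AA))
    # transition counts from state k (0-based) to k+1
    c_m = np.zeros((M, 3))  # MM, MI, MD
    c_i = np.zeros((M, 2))  # IM, II
    c_d = np.zeros((M, 2))  # DM, DD
    for (row_i, (_, seq)) in enumerate(aln.rows):
        wi = w[row_i]
        # emission counts
        for k, col in enumerate(match_cols):
            a = seq[col]
            idx = AA_INDEX.get(a)
            if idx is not None:
                counts[k, idx] += wi
        # implied state path between consecutive match columns
        for k in range(M - 1):
            c0, c1 = match_cols[k], match_cols[k + 1]
            s0 = "M" if seq[c0] != "-" else "D"
            s1 = "M" if seq[c1] != "-" else "D"
            n_ins = sum(1 for j in range(c0 + 1, c1) if seq[j] != "-")
            if n_ins == 0:
                if s0 == "M" and s1 == "M":
                    c_m[k, 0] += wi
                elif s0 == "M":
                    c_m[k, 2] += wi
                elif s1 == "M":
                    c_d[k, 0] += wi
                else:
                    c_d[k, 1] += wi
            else:
                # inserts between match columns; D->I / I->D are not part of
                # the architecture, so a flanking delete keeps its direct
                # delete transition and the insert run attaches to match ends
                if s0 == "M":
                    c_m[k, 1] += wi
                else:
                    c_d[k, 1 if s1 == "D" else 0] += wi
                c_i[k, 1] += wi * (n_ins - 1)
                if s1 == "M":
                    c_i[k, 0] += wi

    totals = counts.sum(axis=1)
    match_emit = (counts + tau * q[None, :]) / (totals + tau)[:, None]
    t_m = (c_m + 1.0) / (c_m + 1.0).sum(axis=1, keepdims=True)
    t_i = (c_i + 1.0) / (c_i + 1.0).sum(axis=1, keepdims=True)
    t_d = (c_d + 1.0) / (c_d + 1.0).sum(axis=1, keepdims=True)
    return ProfileHMM(name=name or f"{subfamily}:{region}", subfamily=subfamily,
                      region=region, M=M, match_emit=match_emit,
                      insert_emit=q.copy(), t_m=t_m, t_i=t_i, t_d=t_d,
                      background=q.copy())


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _encode_batch(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pad encoded sequences into a (N, Lmax) matrix; unknowns/padding -> 20."""
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    lmax = int(lengths.max()) if len(seqs) else 0
    codes = np.full((len(seqs), lmax), 20, dtype=np.int64)
    for i, s in enumerate(seqs):
        codes[i, :len(s)] = np.where(s < 0, 20, s)
    return codes, lengths


def forward_batch_raw(hmm: ProfileHMM, encoded: list[np.ndarray],
                      chunk: int = 128) -> np.ndarray:
    """Natural-log forward odds for a batch of encoded target sequences.

    Sequences are processed in length-sorted chunks so that padding to the
    chunk maximum wastes little work on mixed-length batches.
    """
    if any(len(s) == 0 for s in encoded):
        raise ValueError("empty target sequence")
    if len(encoded) > chunk:
        order = np.argsort([len(s) for s in encoded], kind="stable")
        out = np.empty(len(encoded))
        for start in range(0, len(order), chunk):
            sel = order[start:start + chunk]
            out[sel] = _forward_chunk_raw(hmm, [encoded[i] for i in sel])
        return out
    return _forward_chunk_raw(hmm, encoded)


def _forward_chunk_raw(hmm: ProfileHMM, encoded: list[np.ndarray]) -> np.ndarray:
    p = hmm._log_params()
    codes, lengths = _encode_batch(encoded)
    n, lmax = codes.shape
    m = hmm.M
    neg_inf = -np.inf
    vm = np.full((n, m), neg_inf)
    vi = np.full((n, m), neg_inf)
    vd = np.full((n, m), neg_inf)
    end_acc = np.full(n, neg_inf)
    ltmm, ltim, ltdm = p["ltmm"][:m - 1], p["ltim"][:m - 1], p["ltdm"][:m - 1]
    ltmi, ltii = p["ltmi"], p["ltii"]
    ltmd, ctdd = p["ltmd"], p["ctdd"]
    lem_t = p["lem_ext"].T  # (21, M)
    lei = p["lei_ext"]
    entry = p["entry"]
    for t in range(lmax):
        c = codes[:, t]
        emit = lem_t[c]  # (N, M)
        # match
        new_vm = np.full((n, m), entry)
        if m > 1:
            acc = np.logaddexp(vm[:, :-1] + ltmm[None, :],
                               vi[:, :-1] + ltim[None, :])
            acc = np.logaddexp(acc, vd[:, :-1] + ltdm[None, :])
            new_vm[:, 1:] = np.logaddexp(acc, entry)
        new_vm += emit
        # insert (emits residue t, state index unchanged)
        new_vi = lei[c][:, None] + np.logaddexp(vm + ltmi[None, :], vi + ltii[None, :])
        # delete (no emission; chain along k at the same t):
        # D_k = ctdd[k] + logcumsumexp_j<k (M_j + t(M_j->D) - ctdd[j+1]),
        # computed by row-max-scaled cumulative sums in linear space
        new_vd = np.full((n, m), neg_inf)
        if m > 1:
            a = new_vm[:, :-1] + ltmd[:-1][None, :] - ctdd[1:][None, :]
            hi2 = a.max(axis=1, keepdims=True)
            with np.errstate(divide="ignore"):
                cum = np.log(np.cumsum(np.exp(a - hi2), axis=1))
            new_vd[:, 1:] = cum + hi2 + ctdd[1:][None, :]
        # exit from any match state after emitting residue t
        hi = new_vm.max(axis=1)
        contrib = hi + np.log(np.exp(new_vm - hi[:, None]).sum(axis=1))
        active = t < lengths
        end_acc = np.where(active, np.logaddexp(end_acc, contrib), end_acc)
        vm, vi, vd = new_vm, new_vi, new_vd
    return end_acc


def forward_raw(hmm: ProfileHMM, seq: str) -> float:
    """Natural-log forward odds of one target peptide."""
    return float(forward_batch_raw(hmm, [encode_protein(seq)])[0])


def forward_bits(hmm: ProfileHMM, seq: str, *, target_id: str = "") -> HitScore:
    """Forward log-odds score in bits (uncalibrated: no E-value attached)."""
    raw = forward_raw(hmm, seq)
    return HitScore(bit_score=raw / LN2, evalue=None, raw_forward=raw,
                    query=hmm.name, target=target_id)


@dataclass
class ViterbiResult:
    path: list[tuple[str, int]]  # (state in {M,I,D}, 1-based state index)
    viterbi_bits: float
    target_start: int  # 0-based index of first match-emitted residue
    target_end: int    # 0-based half-open end of last match-emitted residue


def viterbi(hmm: ProfileHMM, seq: str) -> ViterbiResult:
    """Best single alignment path and its score under the same local model."""
    enc = encode_protein(seq)
    if len(enc) == 0:
        raise ValueError("empty target sequence")
    p = hmm._log_params()
    m, L = hmm.M, len(enc)
    codes = np.where(enc < 0, 20, enc)
    neg_inf = -np.inf
    vm = np.full((L + 1, m), neg_inf)
    vi = np.full((L + 1, m), neg_inf)
    vd = np.full((L + 1, m), neg_inf)
    bm = np.zeros((L + 1, m), dtype=np.int8)  # 0 entry, 1 M, 2 I, 3 D
    bi = np.zeros((L + 1, m), dtype=np.int8)
    bd = np.zeros((L + 1, m), dtype=np.int8)
    lem_t = p["lem_ext"].T
    lei = p["lei_ext"]
    entry = p["entry"]
    ltmm, ltim, ltdm = p["ltmm"][:m - 1], p["ltim"][:m - 1], p["ltdm"][:m - 1]
    ltmd, ctdd = p["ltmd"], p["ctdd"]
    kidx = np.arange(m - 1)
    for t in range(1, L + 1):
        c = codes[t - 1]
        emit = lem_t[c]
        vm[t, 0] = entry + emit[0]
        bm[t, 0] = 0
        if m > 1:
            cand = np.stack([np.full(m - 1, entry),
                             vm[t - 1, :-1] + ltmm,
                             vi[t - 1, :-1] + ltim,
                             vd[t - 1, :-1] + ltdm])
            who = cand.argmax(axis=0)
            vm[t, 1:] = cand[who, kidx] + emit[1:]
            bm[t, 1:] = who
        a = vm[t - 1] + p["ltmi"]
        b = vi[t - 1] + p["ltii"]
        vi[t] = np.maximum(a, b) + lei[c]
        bi[t] = np.where(a >= b, 1, 2)
        if m > 1:
            # max-plus delete chain with prefix argmax for backpointers
            arr = vm[t, :-1] + ltmd[:-1] - ctdd[1:]
            run = np.maximum.accumulate(arr)
            arg = np.maximum.accumulate(np.where(arr >= run, kidx, -1))
            vd[t, 1:] = run + ctdd[1:]
            bd[t, 1:] = np.where(arg == kidx, 1, 3)
    # best exit over (t, k) from match states
    flat = int(np.argmax(vm[1:]))
    t_best, k_best = divmod(flat, m)
    t_best += 1
    score = vm[t_best, k_best]
    # traceback
    path: list[tuple[str, int]] = []
    state, t, k = "M", t_best, k_best
    first_emit = t_best - 1
    while True:
        path.append((state, k + 1))
        if state == "M":
            who = bm[t, k]
            first_emit = t - 1
            if who == 0:
                break
            t, k = t - 1, k - 1
            state = {1: "M", 2: "I", 3: "D"}[int(who)]
        elif state == "I":
            who = bi[t, k]
            t = t - 1
            state = {1: "M", 2: "I"}[int(who)]
        else:  # D
            who = bd[t, k]
            k = k - 1
            state = {1: "M", 3: "D"}[int(who)]
    path.reverse()
    return ViterbiResult(path=path, viterbi_bits=float(score / LN2),
                         target_start=first_emit, target_end=t_best)


# ---------------------------------------------------------------------------
# calibration and E-values
# ---------------------------------------------------------------------------

def fit_gumbel_moments(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: lambda = pi / (sd sqrt(6)),
    mu = mean - EulerGamma / lambda.  Raises on zero score variance."""
    scores = np.asarray(scores, dtype=float)
    sd = float(np.std(scores, ddof=1))
    mean = float(np.mean(scores))
    if not math.isfinite(sd) or sd <= 1e-9 * (1.0 + abs(mean)):
        raise ValueError("degenerate calibration: zero score variance")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = mean - EULER_GAMMA / lam
    return mu, lam


def calibrate(hmm: ProfileHMM, n_cal: int = DEFAULT_N_CAL,
              len_cal: int | None = None, seed: int = 0) -> Gumbel:
    """Fit a Gumbel null distribution of bit scores by the method of moments.

    Scores n_cal i.i.d. background sequences of length len_cal (default
    2M) and fits location/scale from the sample moments.  The fit is
    stored on the profile.
    """
    if n_cal < 100:
        raise ValueError("n_cal must be >= 100")
    if len_cal is None:
        len_cal = 2 * hmm.M
    rng = np.random.default_rng(seed)
    codes = rng.choice(N_AA, size=(n_cal, len_cal), p=hmm.background)
    bits = forward_batch_raw(hmm, list(codes)) / LN2
    mu, lam = fit_gumbel_moments(bits)
    gumbel = Gumbel(mu=mu, lambda_g=lam, n_cal=n_cal, len_cal=len_cal, seed=seed)
    hmm.calibration = gumbel
    return gumbel


def evalue(hmm: ProfileHMM, bit_score: float, n_targets: int) -> float:
    """E = n_targets * P(S' >= S) under the calibrated Gumbel null."""
    if hmm.calibration is None:
        raise ValueError(f"profile {hmm.name!r} is not calibrated")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    g = hmm.calibration
    p_ge = -math.expm1(-math.exp(-g.lambda_g * (bit_score - g.mu)))
    return n_targets * p_ge


# ---------------------------------------------------------------------------
# logos
# ---------------------------------------------------------------------------

def logo(hmm: ProfileHMM,
         indel_threshold: float = DEFAULT_INDEL_THRESHOLD) -> list[LogoPosition]:
    """Per-position relative entropy (bits), letter heights, and indel flags.

    R_k = sum_a e_k(a) log2(e_k(a) / q(a)); each residue's letter height is
    e_k(a) * R_k; a position is flagged as an indel site when its
    match->delete or match->insert probability exceeds the threshold.
    """
    out = []
    q = hmm.background
    for k in range(hmm.M):
        e = hmm.match_emit[k]
        nz = e > 0
        r_k = float(np.sum(e[nz] * np.log2(e[nz] / q[nz])))
        letters = sorted(((AMINO_ACIDS[a], float(e[a] * r_k)) for a in range(N_AA)),
                         key=lambda x: -x[1])
        indel = bool(hmm.t_m[k, 1] > indel_threshold or hmm.t_m[k, 2] > indel_threshold)
        out.append(LogoPosition(position=k, relative_entropy=r_k,
                                letters=letters, indel=indel))
    return out


def write_logo_tsv(path: str, positions: list[LogoPosition], top_n: int = 3) -> None:
    with open(path, "w") as fh:
        fh.write("position\trelative_entropy\ttop_letters\tindel\n")
        for rec in positions:
            tops = ",".join(f"{a}:{h:.4f}" for a, h in rec.letters[:top_n])
            fh.write(f"{rec.position}\t{rec.relative_entropy:.6f}\t{tops}\t"
                     f"{int(rec.indel)}\n")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def to_dict(hmm: ProfileHMM) -> dict:
    d = {
        "schema": SCHEMA_VERSION,
        "name": hmm.name,
        "subfamily": hmm.subfamily,
        "region": hmm.region,
        "M": hmm.M,
        "alphabet": AMINO_ACIDS,
        "match_emit": hmm.match_emit.tolist(),
        "insert_emit": hmm.insert_emit.tolist(),
        "t_m": hmm.t_m.tolist(),
        "t_i": hmm.t_i.tolist(),
        "t_d": hmm.t_d.tolist(),
        "background": hmm.background.tolist(),
    }
    if hmm.calibration is not None:
        g = hmm.calibration
        d["calibration"] = {"mu": g.mu, "lambda_g": g.lambda_g, "n_cal": g.n_cal,
                            "len_cal": g.len_cal, "seed": g.seed}
    return d


def from_dict(d: dict) -> ProfileHMM:
    if d.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"unsupported profile schema: {d.get('schema')!r}")
    hmm = ProfileHMM(name=d["name"], subfamily=d["subfamily"], region=d["region"],
                     M=d["M"], match_emit=np.array(d["match_emit"]),
                     insert_emit=np.array(d["insert_emit"]),
                     t_m=np.array(d["t_m"]), t_i=np.array(d["t_i"]),
                     t_d=np.array(d["t_d"]), background=np.array(d["background"]))
    cal = d.get("calibration")
    if cal is not None:
        hmm.calibration = Gumbel(**cal)
    return hmm


def save_profile(hmm: ProfileHMM, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(to_dict(hmm), fh)


def load_profile(path: str) -> ProfileHMM:
    with open(path) as fh:
        return from_dict(json.load(fh))
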