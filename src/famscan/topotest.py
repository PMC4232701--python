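"""SH and AU constrained-topology tests from per-site log-likelihoods.

Both tests operate on a site-likelihood table (sites x topologies) by
resampling estimated log-likelihoods (RELL): bootstrap replicates re-draw
site indices and sum the stored per-site values, avoiding re-optimization.

The Shimodaira-Hasegawa test centers each topology's replicate totals on
its own replicate mean and compares the observed log-likelihood deficit
of each topology to the resampled distribution of the worst-case deficit,
which makes it conservative.

The approximately unbiased (AU) test runs bootstraps at several scales r
(replicate size n' = r n), records the proportion BP(r) of replicates in
which each topology is best, fits the signed distance d and boundary
curvature c of the normal model Phi^{-1}(1 - BP(r)) = d sqrt(r) +
c / sqrt(r) by weighted least squares, and reports p = 1 - Phi(d - c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.401, 0.1), 10))
DEFAULT_B = 1000


@dataclass
class TopoTestResult:
    """Per-topology totals, deltas, SH and AU p-values, and AU diagnostics."""

    names: list[str]
    loglik: np.ndarray            # total lnL per topology
    delta: np.ndarray             # lnL deficit to the best topology
    sh_p: np.ndarray | None = None
    au_p: np.ndarray | None = None
    au_d: np.ndarray | None = None
    au_c: np.ndarray | None = None
    bp: dict[float, np.ndarray] = field(default_factory=dict)
    degenerate: np.ndarray | None = None
    B: int = 0
    seed: int = 0

    def best_index(self) -> int:
        return int(np.argmin(self.delta))


def _check_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("site-likelihood table must be 2-D (sites x topologies)")
    if table.shape[0] < 2:
        raise ValueError("need at least 2 sites to resample")
    return table


def rell_resample(table: np.ndarray, B: int, scale: float = 1.0,
                  seed: int = 0, weights: np.ndarray | None = None) -> np.ndarray:
    """B RELL replicates at one scale: resampled total lnL per topology.

    Each replicate draws n' = round(scale * n) site indices with
    replacement (optionally with site-pattern weights) and sums the stored
    per-site log-likelihoods column-wise.  Deterministic given the seed.
    """
    table = _check_table(table)
    if B < 100:
        raise ValueError("B must be >= 100")
    n = table.shape[0]
    n_prime = int(round(scale * n))
    if n_prime < 1:
        raise ValueError(f"scale {scale} gives an empty replicate")
    rng = np.random.default_rng(seed)
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        p = w / w.sum()
    out = np.empty((B, table.shape[1]))
    chunk = max(1, min(B, 1 + 4_000_000 // max(1, n_prime)))
    for start in range(0, B, chunk):
        stop = min(B, start + chunk)
        idx = rng.choice(n, size=(stop - start, n_prime), p=p)
        out[start:stop] = table[idx].sum(axis=1)
    return out


def sh_test(table: np.ndarray, B: int = DEFAULT_B, seed: int = 0) -> np.ndarray:
    """Shimodaira-Hasegawa p-value per topology.

    Replicate totals are centered by their per-topology replicate means;
    the replicate statistic for topology i is max_j centered_j - centered_i
    and p_i is the fraction of replicates at or above the observed deficit.
    """
    table = _check_table(table)
    if table.shape[1] < 2:
        raise ValueError("need at least 2 topologies")
    totals = table.sum(axis=0)
    delta = totals.max() - totals
    reps = rell_resample(table, B, 1.0, seed)
    centered = reps - reps.mean(axis=0, keepdims=True)
    stat = centered.max(axis=1, keepdims=True) - centered  # (B, T)
    return (stat >= delta[None, :]).mean(axis=0)


def _bp_proportions(reps: np.ndarray) -> np.ndarray:
    """Proportion of replicates in which each topology attains the maximum,
    with ties split equally among the tied topologies."""
    best = reps.max(axis=1, keepdims=True)
    is_best = reps == best
    share = is_best / is_best.sum(axis=1, keepdims=True)
    return share.mean(axis=0)


def fit_au_curve(bp: np.ndarray, scales: tuple[float, ...], B: int,
                 fit_curvature: bool = True) -> tuple[float, float, float, bool]:
    """Fit (d, c) to bootstrap proportions across scales; return (d, c, p, degenerate).

    Solves the weighted least squares Phi^{-1}(1 - BP(r)) = d sqrt(r) +
    c / sqrt(r) (weights from the binomial delta method) and returns
    p = 1 - Phi(d - c).  With fit_curvature=False the curvature term is
    dropped; at a single scale r = 1 this reduces exactly to the normal
    approximation p = BP.  BP values are clamped to [1/(2B), 1 - 1/(2B)];
    a curve that is 0 or 1 everywhere is degenerate and p is the clamp
    limit.
    """
    bp_raw = np.asarray(bp, dtype=float)
    rs = np.asarray(scales, dtype=float)
    clamp_lo, clamp_hi = 1.0 / (2 * B), 1.0 - 1.0 / (2 * B)
    cols = [np.sqrt(rs)] + ([1.0 / np.sqrt(rs)] if fit_curvature else [])
    design = np.stack(cols, axis=1)
    degenerate = bool(np.all(bp_raw <= 0.0) or np.all(bp_raw >= 1.0))
    bp_c = np.clip(bp_raw, clamp_lo, clamp_hi)
    z = norm.ppf(1.0 - bp_c)
    if degenerate:
        coef = np.linalg.lstsq(design, z, rcond=None)[0]
        p = clamp_lo if np.all(bp_raw <= 0.0) else clamp_hi
    else:
        var = bp_c * (1.0 - bp_c) / (B * norm.pdf(z) ** 2)
        w = 1.0 / var
        wd = design * w[:, None]
        coef = np.linalg.solve(design.T @ wd, wd.T @ z)
        d = float(coef[0])
        c = float(coef[1]) if fit_curvature else 0.0
        p = float(1.0 - norm.cdf(d - c))
    d = float(coef[0])
    c = float(coef[1]) if fit_curvature else 0.0
    return d, c, p, degenerate


def au_test(table: np.ndarray, scales: tuple[float, ...] = DEFAULT_SCALES,
            B: int = DEFAULT_B, seed: int = 0) -> TopoTestResult:
    """Approximately unbiased test by multiscale RELL bootstrap.

    For each scale r, BP_i(r) is the share of replicates where topology i
    is best.  z(r) = Phi^{-1}(1 - BP(r)) is regressed on (sqrt(r),
    1/sqrt(r)) with binomial delta-method weights; p_i = 1 - Phi(d - c).
    BP values are clamped to [1/(2B), 1 - 1/(2B)] before the transform;
    topologies with BP identically 0 or 1 at every scale are flagged
    degenerate and get the corresponding clamp-limit p.
    """
    table = _check_table(table)
    scales = tuple(scales)
    if len(set(scales)) < 2:
        raise ValueError("need >= 2 distinct scales")
    if not (min(scales) < 1.0 and max(scales) > 1.0):
        raise ValueError("scales must span values below and above 1")
    n_topo = table.shape[1]
    totals = table.sum(axis=0)
    delta = totals.max() - totals
    bp_by_scale: dict[float, np.ndarray] = {}
    for si, r in enumerate(scales):
        reps = rell_resample(table, B, r, seed + si)
        bp_by_scale[float(r)] = _bp_proportions(reps)
    d_arr = np.zeros(n_topo)
    c_arr = np.zeros(n_topo)
    p_arr = np.zeros(n_topo)
    degenerate = np.zeros(n_topo, dtype=bool)
    for i in range(n_topo):
        bp_raw = np.array([bp_by_scale[float(r)][i] for r in scales])
        d_arr[i], c_arr[i], p_arr[i], degenerate[i] = fit_au_curve(
            bp_raw, scales, B)
    return TopoTestResult(names=[f"topology{i}" for i in range(n_topo)],
                          loglik=totals, delta=delta, au_p=p_arr, au_d=d_arr,
                          au_c=c_arr, bp=bp_by_scale, degenerate=degenerate,
                          B=B, seed=seed)


def topology_tests(table: np.ndarray, names: list[str] | None = None,
                   scales: tuple[float, ...] = DEFAULT_SCALES,
                   B: int = DEFAULT_B, seed: int = 0) -> TopoTestResult:
    """Run both SH and AU tests on one site-likelihood table."""
    res = au_test(table, scales=scales, B=B, seed=seed)
    res.sh_p = sh_test(table, B=B, seed=seed + 10_000)
    if names is not None:
        if len(names) != table.shape[1]:
            raise ValueError("names length must match topology count")
        res.names = list(names)
    return res


def write_result_tsv(path: str, res: TopoTestResult) -> None:
    with open(path, "w") as fh:
        fh.write("topology\tlnL\tdelta\tSH_p\tAU_p\td\tc\tdegenerate\n")
        for i, name in enumerate(res.names):
            sh = f"{res.sh_p[i]:.4f}" if res.sh_p is not None else ""
            au = f"{res.au_p[i]:.4f}" if res.au_p is not None else ""
            d = f"{res.au_d[i]:.4f}" if res.au_d is not None else ""
            c = f"{res.au_c[i]:.4f}" if res.au_c is not None else ""
            deg = int(res.degenerate[i]) if res.degenerate is not None else 0
            fh.write(f"{name}\t{res.loglik[i]:.4f}\t{res.delta[i]:.4f}\t"
                     f"{sh}\t{au}\t{d}\t{c}\t{deg}\n")
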