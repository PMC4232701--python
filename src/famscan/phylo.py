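"""Protein likelihood on fixed topologies: JTT + discrete gamma + invariant sites.

Per-site log-likelihoods are computed by Felsenstein pruning under the
JTT amino-acid model with gamma-distributed rate variation (discretized
into equal-probability categories using category means) and a proportion
of invariant sites.  Branch lengths and the rate parameters can be
optimized by coordinate ascent on a fixed topology.  Candidate topologies
come from the user; helpers test and filter monophyly constraints on
unrooted trees.  Trees are dendropy objects throughout; Newick I/O goes
through dendropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .seqkit import MsAlignment
from .substitution import AA_INDEX, JTT_FREQS, N_AA, jtt_exchangeabilities, rate_matrix

DEFAULT_N_CATEGORIES = 4
_BL_BOUNDS = (1e-8, 20.0)
_ALPHA_BOUNDS = (0.02, 100.0)
_PINV_BOUNDS = (0.0, 0.99)


def discrete_gamma_rates(alpha: float, ncat: int = DEFAULT_N_CATEGORIES) -> np.ndarray:
    """Category rates: means of ncat equal-probability bins of Gamma(alpha, alpha).

    The probability-weighted mean of the returned rates is exactly one.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if ncat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=alpha, scale=1.0 / alpha)
    cuts = np.concatenate([[0.0], edges * alpha, [np.inf]])
    # mean of Gamma(alpha, rate=alpha) over a bin, via the shape alpha+1 identity
    upper = gammainc(alpha + 1, cuts[1:])
    lower = gammainc(alpha + 1, cuts[:-1])
    rates = ncat * (upper - lower)
    return rates / (rates.mean())


@dataclass
class SubstModel:
    """JTT-family substitution model with +G and +I rate variation."""

    exchangeabilities: np.ndarray = field(default_factory=jtt_exchangeabilities)
    freqs: np.ndarray = field(default_factory=lambda: JTT_FREQS.copy())
    alpha: float = 1.0
    n_categories: int = DEFAULT_N_CATEGORIES
    p_inv: float = 0.0
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not math.isclose(self.freqs.sum(), 1.0, abs_tol=1e-10):
            raise ValueError("frequencies must sum to 1")
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        self._eig = None

    def _eigendecomposition(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._eig is None:
            q = rate_matrix(self.exchangeabilities, self.freqs)
            sqrt_pi = np.sqrt(self.freqs)
            sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
            sym = (sym + sym.T) / 2
            w, u = np.linalg.eigh(sym)
            self._eig = (w, u, sqrt_pi)
        return self._eig

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)

    def copy(self) -> "SubstModel":
        return SubstModel(exchangeabilities=self.exchangeabilities,
                          freqs=self.freqs.copy(), alpha=self.alpha,
                          n_categories=self.n_categories, p_inv=self.p_inv)


def empirical_freqs(aln: MsAlignment, smooth: float = 1.0) -> np.ndarray:
    """Amino-acid frequencies counted from an alignment with add-one smoothing."""
    counts = np.full(N_AA, smooth)
    for _, seq in aln.rows:
        for c in seq:
            idx = AA_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def transition_matrix(model: SubstModel, t: float, rate: float = 1.0) -> np.ndarray:
    """P(r t) = exp(Q r t / (1 - p_inv)) via symmetric eigendecomposition.

    Under +I the variable-site rate matrix is rescaled by 1/(1 - p_inv) so
    the expected overall substitution rate (invariant sites included)
    stays one and branch lengths remain comparable across p_inv values.
    """
    if t < 0 or rate < 0:
        raise ValueError("t and rate must be >= 0")
    w, u, sqrt_pi = model._eigendecomposition()
    scale = rate * t / (1.0 - model.p_inv)
    p = (u * np.exp(w * scale)[None, :]) @ u.T
    p = p * (sqrt_pi[None, :] / sqrt_pi[:, None])
    return np.clip(p, 0.0, None)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _encode_alignment(aln: MsAlignment) -> dict[str, np.ndarray]:
    out = {}
    for name, seq in aln.rows:
        out[name] = np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    return out


def site_loglik(tree: dendropy.Tree, aln: MsAlignment,
                model: SubstModel) -> np.ndarray:
    """Per-site natural-log likelihoods by Felsenstein pruning.

    Gaps and unknown residues are missing data (conditional likelihood one
    in every state).  Per site, L = p_inv * I(site constant) * pi(residue)
    + (1 - p_inv) * mean over gamma categories of the pruned likelihood.
    """
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    aln_taxa = set(aln.ids)
    if taxa != aln_taxa:
        raise ValueError(f"taxon mismatch: tree={sorted(taxa - aln_taxa)} "
                         f"alignment={sorted(aln_taxa - taxa)}")
    codes = _encode_alignment(aln)
    nsites = aln.ncols
    rates = model.category_rates()
    ncat = len(rates)
    pi = model.freqs

    # leaf partials shared across categories
    def leaf_partial(code: np.ndarray) -> np.ndarray:
        part = np.zeros((nsites, N_AA))
        known = code >= 0
        part[known, code[known]] = 1.0
        part[~known, :] = 1.0
        return part

    partials: dict[int, np.ndarray] = {}  # node id -> (ncat, nsites, 20)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lp = leaf_partial(codes[node.taxon.label])
            partials[id(node)] = np.broadcast_to(lp, (ncat, nsites, N_AA))
        else:
            acc = np.ones((ncat, nsites, N_AA))
            for child in node.child_nodes():
                t = child.edge.length if child.edge.length is not None else 0.0
                child_part = partials.pop(id(child))
                down = np.empty((ncat, nsites, N_AA))
                for ci, r in enumerate(rates):
                    p = transition_matrix(model, t, r)
                    down[ci] = child_part[ci] @ p.T
                acc *= down
            partials[id(node)] = acc
    root_part = partials[id(tree.seed_node)]
    var_site = (root_part @ pi).mean(axis=0)  # (nsites,)

    # invariant-site component: sites where all non-missing residues agree
    inv = np.zeros(nsites)
    if model.p_inv > 0:
        for s in range(nsites):
            obs = {codes[name][s] for name in codes if codes[name][s] >= 0}
            if len(obs) == 0:
                inv[s] = 1.0
            elif len(obs) == 1:
                inv[s] = pi[obs.pop()]
    lik = (1.0 - model.p_inv) * var_site + model.p_inv * inv
    if np.any(lik <= 0) or not np.all(np.isfinite(lik)):
        bad = int(np.argmin(lik))
        raise ValueError(f"non-finite site likelihood at site {bad}")
    return np.log(lik)


def total_loglik(tree: dendropy.Tree, aln: MsAlignment, model: SubstModel) -> float:
    return float(site_loglik(tree, aln, model).sum())


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    tree: dendropy.Tree
    model: SubstModel
    loglik: float
    n_sweeps: int
    converged: bool


def optimize(tree: dendropy.Tree, aln: MsAlignment, model: SubstModel, *,
             free_branch_lengths: bool = True, free_alpha: bool = False,
             free_p_inv: bool = False, tol: float = 1e-6,
             max_sweeps: int = 20) -> FitResult:
    """Coordinate-ascent fit of branch lengths, alpha and p_inv on a fixed tree.

    Each sweep optimizes every free scalar with bounded Brent search; the
    total log-likelihood is non-decreasing across sweeps and iteration
    stops when a sweep improves it by less than tol.
    """
    tree = tree.clone(depth=1)
    model = model.copy()
    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    for e in edges:
        if e.length is None or e.length <= 0:
            e.length = 0.01
    current = total_loglik(tree, aln, model)
    sweeps = 0
    converged = False
    while sweeps < max_sweeps:
        sweeps += 1
        before = current
        if free_branch_lengths:
            for e in edges:
                def neg(t: float, edge=e) -> float:
                    edge.length = t
                    return -total_loglik(tree, aln, model)
                res = minimize_scalar(neg, bounds=_BL_BOUNDS, method="bounded",
                                      options={"xatol": tol})
                cand = -res.fun
                if cand >= current:
                    e.length, current = float(res.x), cand
                else:
                    neg(e.length)  # restore
        if free_alpha:
            def neg_a(a: float) -> float:
                model.alpha = a
                return -total_loglik(tree, aln, model)
            res = minimize_scalar(neg_a, bounds=_ALPHA_BOUNDS, method="bounded",
                                  options={"xatol": tol})
            if -res.fun >= current:
                model.alpha, current = float(res.x), -res.fun
            else:
                model.alpha = model.alpha
        if free_p_inv:
            def neg_p(p: float) -> float:
                model.p_inv = p
                return -total_loglik(tree, aln, model)
            res = minimize_scalar(neg_p, bounds=_PINV_BOUNDS, method="bounded",
                                  options={"xatol": tol})
            if -res.fun >= current:
                model.p_inv, current = float(res.x), -res.fun
        if current - before < tol:
            converged = True
            break
    return FitResult(tree=tree, model=model, loglik=current, n_sweeps=sweeps,
                     converged=converged)


# ---------------------------------------------------------------------------
# monophyly constraints
# ---------------------------------------------------------------------------

def _leafsets(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf set below each edge of the (arbitrarily rooted) unrooted tree."""
    sets = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        sets.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    return sets


def check_monophyly(tree: dendropy.Tree, taxon_set: set[str]) -> bool:
    """True iff (taxon_set | complement) is a bipartition edge of the unrooted tree.

    On an unrooted tree a set and its complement are the same bipartition,
    so the complement of a monophyletic set is monophyletic too.
    """
    all_taxa = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = set(taxon_set) - all_taxa
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    ts = frozenset(taxon_set)
    if not 0 < len(ts) < len(all_taxa):
        raise ValueError("taxon_set must be a proper non-empty subset of the leaves")
    comp = frozenset(all_taxa - ts)
    leafsets = _leafsets(tree)
    return ts in leafsets or comp in leafsets


def filter_topologies(trees: list[dendropy.Tree], taxon_set: set[str],
                      mode: str = "positive") -> list[dendropy.Tree]:
    """Keep trees where the set is (positive) or is not (negative) monophyletic."""
    if not trees:
        raise ValueError("empty tree list")
    if mode not in ("positive", "negative"):
        raise ValueError("mode must be 'positive' or 'negative'")
    keep = [t for t in trees
            if check_monophyly(t, taxon_set) == (mode == "positive")]
    if not keep:
        import warnings
        warnings.warn(f"no topology satisfies the {mode} constraint on {sorted(taxon_set)}")
    return keep


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_trees(path: str) -> list[dendropy.Tree]:
    tl = dendropy.TreeList.get(path=path, schema="newick",
                               preserve_underscores=True)
    return list(tl)


def read_tree(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick", preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", unquoted_underscores=True)


def write_site_loglik_tsv(path: str, table: np.ndarray, names: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("site\t" + "\t".join(names) + "\n")
        for s in range(table.shape[0]):
            fh.write(str(s) + "\t" + "\t".join(f"{v:.10f}" for v in table[s]) + "\n")


def read_site_loglik_tsv(path: str) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = header[1:]
        rows = [[float(v) for v in line.rstrip("\n").split("\t")[1:]]
                for line in fh if line.strip()]
    return np.array(rows), names
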