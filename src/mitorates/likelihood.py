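"""Maximum-likelihood branch lengths on a fixed topology.

Implements Felsenstein's pruning algorithm for amino-acid data under a
reversible substitution model with discrete-gamma across-site rate
heterogeneity, coordinate-wise branch-length optimization, and model
selection by log-likelihood.

Gap ``-`` and missing ``X`` symbols contribute a partial likelihood of 1 for
every state (fully undetermined characters).  Site patterns are compressed
before any likelihood work.  Partial likelihoods are rescaled per site when
they drop below a floor, with the log scale carried separately, so arbitrarily
large trees do not underflow.

Branch-length identifiability at the root: under a reversible model the two
branches incident to a bifurcating root are only jointly identifiable through
their sum.  The optimizer therefore treats that sum as a single parameter and
splits it between the two edges in fixed proportion to their starting values
(by default proportional to the chronogram durations).  Downstream root-to-tip
sums are unaffected by the split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignment import GAP_CODE, ProteinAlignment
from .models import N_STATES, SubstitutionModel
from .trees import Phylogeny, PhyloTree

__all__ = [
    "discretize_gamma",
    "log_likelihood",
    "optimize_branch_lengths",
    "select_model",
]

MIN_BRANCH = 1e-8
MAX_BRANCH = 20.0
ALPHA_BOUNDS = (0.02, 50.0)
_SCALE_FLOOR = 1e-240
_LOG_FLOOR = 1e-310


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Discrete-gamma category rates (mean-1 gamma, equal-probability bins).

    Each category's rate is the mean of the gamma(alpha, 1/alpha) density over
    its quantile interval, so the category mean is exactly 1.
    """
    if not alpha > 0:
        raise ValueError("gamma shape alpha must be > 0")
    if k < 1:
        raise ValueError("number of categories must be >= 1")
    if k == 1:
        return np.array([1.0])
    # interval boundaries in the unscaled (rate=alpha) parameterisation
    q = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], alpha * q, [np.inf]])
    rates = k * np.diff(gammainc(alpha + 1.0, bounds))
    rates /= rates.mean()  # exact renormalisation against quadrature round-off
    if np.any(np.diff(rates) <= 0):
        raise RuntimeError("discrete-gamma rates are not strictly increasing")
    return rates


# --------------------------------------------------------------------------
# pruning engine
# --------------------------------------------------------------------------


def _compress_patterns(msa: ProteinAlignment, tip_labels: list[str]):
    sub = msa.subset(tip_labels)
    cols = np.ascontiguousarray(sub.data.T)  # (n_sites, n_tips)
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns.T.copy(), counts.astype(float)  # (n_tips, n_pat), weights


class _PruningEngine:
    """Partial-likelihood bookkeeping for one (tree, model, alignment)."""

    def __init__(self, tree: Phylogeny, msa: ProteinAlignment,
                 model: SubstitutionModel):
        missing = set(tree.tip_labels) - set(msa.labels)
        if missing:
            raise ValueError(f"species in tree but not alignment: {sorted(missing)}")
        self.tree = tree
        self.model = model
        self.rates = discretize_gamma(model.alpha, model.n_categories)
        self.k = model.n_categories
        tip_ids = tree.tip_ids
        self.tip_row = {t: r for r, t in enumerate(tip_ids)}
        codes, self.weights = _compress_patterns(
            msa, [tree.labels[t] for t in tip_ids]
        )
        self.n_pat = codes.shape[1]
        # tip conditionals: one-hot for residues, all-ones for gap/missing
        self.tipD: dict[int, np.ndarray] = {}
        for t in tip_ids:
            row = codes[self.tip_row[t]]
            D = np.zeros((1, self.n_pat, N_STATES))
            det = row < GAP_CODE
            D[0, det, row[det]] = 1.0
            D[0, ~det, :] = 1.0
            self.tipD[t] = D
        n = tree.n_nodes
        self.D: list[np.ndarray | None] = [None] * n   # (k, n_pat, 20)
        self.S: list[np.ndarray | None] = [None] * n   # (k, n_pat) log scale
        self.M: list[np.ndarray | None] = [None] * n   # message to parent
        for t in tip_ids:
            self.D[t] = self.tipD[t]
            self.S[t] = np.zeros((1, self.n_pat))

    def set_model(self, model: SubstitutionModel) -> None:
        self.model = model
        self.rates = discretize_gamma(model.alpha, model.n_categories)
        self.k = model.n_categories

    # ------------------------------------------------------------- low level
    def _edge_P(self, t: float) -> np.ndarray:
        return self.model.transition_matrices(t, self.rates)

    @staticmethod
    def _rescale(A: np.ndarray, S: np.ndarray) -> None:
        m = A.max(axis=-1)
        bad = m < _SCALE_FLOOR
        if np.any(bad):
            f = np.where(bad & (m > 0), m, 1.0)
            A /= f[..., None]
            S += np.log(f)

    def _message(self, v: int, lengths: np.ndarray) -> np.ndarray:
        """M[v][c] = D[v] @ P_c(t_v).T — child conditional seen from parent."""
        P = self._edge_P(lengths[v])
        return np.matmul(self.D[v], P.transpose(0, 2, 1))

    def _update_internal(self, v: int, lengths: np.ndarray) -> None:
        """Recompute D[v] from the children's messages (assumed current)."""
        D = np.ones((self.k, self.n_pat, N_STATES))
        S = np.zeros((self.k, self.n_pat))
        for u in self.tree.children[v]:
            D *= self.M[u]
            S += self.S[u][0] if self.S[u].shape[0] == 1 else self.S[u]
        self._rescale(D, S)
        self.D[v] = D
        self.S[v] = S

    def full_postorder(self, lengths: np.ndarray) -> None:
        for v in self.tree.postorder():
            if self.tree.children[v]:
                for u in self.tree.children[v]:
                    self.M[u] = self._message(u, lengths)
                self._update_internal(v, lengths)
            # tips: D fixed; M computed lazily by parents above

    def root_loglik(self) -> float:
        r = self.tree.root
        L = self.D[r] @ self.model.frequencies  # (k, n_pat)
        ll = np.log(np.maximum(L, _LOG_FLOOR)) + self.S[r]
        m = ll.max(axis=0)
        site_ll = m + np.log(np.exp(ll - m).mean(axis=0))
        return float(site_ll @ self.weights)

    def loglik(self, lengths: np.ndarray) -> float:
        self.full_postorder(lengths)
        return self.root_loglik()

    def edge_loglik(self, G, SG, D, SD, t: float) -> float:
        """Log-likelihood as a function of one edge length, ends fixed."""
        return self.edge_loglik_fn(G, SG, D, SD)(t)

    def edge_loglik_fn(self, G, SG, D, SD):
        """Fast closure t -> log-likelihood for one edge, ends fixed.

        Projects both endpoint partials into the model's eigenbasis once, so
        each evaluation is only an exp-weighted inner product:
        L_pc = sum_j (G' * D')[c,p,j] * exp(lambda_j * r_c * t).
        """
        md = self.model
        C = np.matmul(G, md._left) * np.matmul(D, md._right.T)  # (k, n_pat, 20)
        if C.shape[0] == 1 and self.k > 1:
            C = np.broadcast_to(C, (self.k, self.n_pat, N_STATES))
        S = SG + SD
        lam = md._lam
        rates = self.rates
        weights = self.weights

        def f(t: float) -> float:
            E = np.exp(np.multiply.outer(rates * t, lam))  # (k, 20)
            L = np.matmul(C, E[:, :, None])[:, :, 0]       # (k, n_pat)
            ll = np.log(np.maximum(L, _LOG_FLOOR)) + S
            m = ll.max(axis=0)
            site_ll = m + np.log(np.exp(ll - m).mean(axis=0))
            return float(site_ll @ weights)

        return f


def log_likelihood(
    msa: ProteinAlignment, tree: Phylogeny, model: SubstitutionModel
) -> float:
    """Felsenstein-pruning log-likelihood of ``msa`` on ``tree``.

    Branch lengths are taken from ``tree`` (expected substitutions/site);
    site likelihoods are averaged over the model's discrete-gamma categories.
    """
    lengths = np.asarray(tree.lengths, float)
    if np.any(~np.isfinite(lengths)) or np.any(lengths < 0):
        raise ValueError("branch lengths must be finite and non-negative")
    eng = _PruningEngine(tree, msa, model)
    return eng.loglik(lengths)


# --------------------------------------------------------------------------
# branch-length optimization
# --------------------------------------------------------------------------


def _initial_rate_guess(msa: ProteinAlignment, topology: Phylogeny) -> float:
    """Crude substitutions-per-MY scale from corrected p-distances of
    consecutive tip pairs; only used to seed the optimizer."""
    tips = topology.tip_ids
    depths = topology.depths()
    labels = topology.labels
    anc: dict[int, list[int]] = {}
    for t in tips:
        v, path = t, []
        while v >= 0:
            path.append(v)
            v = int(topology.parent[v])
        anc[t] = path
    ests = []
    for a, b in zip(tips[:-1], tips[1:]):
        sa = msa.data[msa.labels.index(labels[a])]
        sb = msa.data[msa.labels.index(labels[b])]
        det = (sa < GAP_CODE) & (sb < GAP_CODE)
        if det.sum() < 10:
            continue
        p = float(np.mean(sa[det] != sb[det]))
        p = min(p, 0.93)
        d = -(19.0 / 20.0) * np.log(1.0 - (20.0 / 19.0) * p)
        set_a = set(anc[a])
        lca = next(v for v in anc[b] if v in set_a)
        dur = depths[a] + depths[b] - 2.0 * depths[lca]
        if dur > 0 and d > 0:
            ests.append(d / dur)
    return float(np.median(ests)) if ests else 1e-3


def _brent_max(f, lo: float, hi: float, xatol: float = 1e-7) -> tuple[float, float]:
    res = minimize_scalar(
        lambda x: -f(x), bounds=(lo, hi), method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x), float(-res.fun)


def optimize_branch_lengths(
    msa: ProteinAlignment,
    topology: Phylogeny,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_rounds: int = 20,
    optimize_alpha: bool = False,
    initial_lengths: np.ndarray | None = None,
) -> PhyloTree:
    """Coordinate-wise ML branch lengths on the fixed rooted topology.

    Each branch is optimized in turn by bounded scalar (Brent) search on
    [1e-8, 20] substitutions/site, sweeping the tree depth-first with exact
    incremental updates of the inside/outside partial likelihoods, cycling
    until the round-over-round log-likelihood gain falls below ``tol`` or
    ``max_rounds`` is reached.  ``optimize_alpha`` interleaves a scalar search
    of the gamma shape on [0.02, 50] between branch rounds.  The returned tree
    shares the topology's node indexing and carries the final log-likelihood
    (and model, with the fitted alpha, as ``.model``).
    """
    eng = _PruningEngine(topology, msa, model)
    tree = eng.tree
    if initial_lengths is not None:
        lengths = np.clip(np.asarray(initial_lengths, float), MIN_BRANCH, MAX_BRANCH)
    else:
        r0 = _initial_rate_guess(msa, topology)
        lengths = np.clip(topology.lengths * r0, MIN_BRANCH, MAX_BRANCH)
    lengths[tree.root] = 0.0

    root_children = tree.children[tree.root]
    binary_root = len(root_children) == 2
    if binary_root:
        a, b = root_children
        tot = lengths[a] + lengths[b]
        split = (0.5 if tot <= 0 else float(lengths[a] / tot))

    E: list[np.ndarray | None] = [None] * tree.n_nodes
    SE: list[np.ndarray | None] = [None] * tree.n_nodes

    def optimize_edge(v: int, G, SG) -> None:
        f = eng.edge_loglik_fn(G, SG, eng.D[v], _S(v))
        t_new, ll_new = _brent_max(f, MIN_BRANCH, MAX_BRANCH)
        if ll_new >= f(lengths[v]):
            lengths[v] = t_new

    def _S(v: int) -> np.ndarray:
        S = eng.S[v]
        return S if S.shape[0] > 1 else np.broadcast_to(S, (eng.k, eng.n_pat))

    def sweep(u: int) -> None:
        kids = tree.children[u]
        for i, v in enumerate(kids):
            # outside partial at u excluding v's subtree
            G = np.ones((eng.k, eng.n_pat, N_STATES)) * (
                E[u] if E[u].shape[0] > 1 else E[u][0]
            )
            SG = SE[u].copy()
            for s in kids:
                if s is not v:
                    G *= eng.M[s]
                    SG += _S(s)
            eng._rescale(G, SG)
            if not (u == tree.root and binary_root):
                optimize_edge(v, G, SG)
            eng.M[v] = eng._message(v, lengths)
            P = eng._edge_P(lengths[v])
            Ev = np.empty_like(G)
            for c in range(eng.k):
                Ev[c] = G[c] @ P[c]
            SEv = SG.copy()
            eng._rescale(Ev, SEv)
            E[v], SE[v] = Ev, SEv
            if tree.children[v]:
                sweep(v)
                eng._update_internal(v, lengths)
                eng.M[v] = eng._message(v, lengths)

    def root_sum_step() -> None:
        a, b = root_children
        pi = eng.model.frequencies
        Da, Db = eng.D[a], eng.D[b]
        Ga = (Da if Da.shape[0] > 1 else np.broadcast_to(Da, (eng.k, eng.n_pat,
                                                              N_STATES))) * pi
        f = eng.edge_loglik_fn(Ga, _S(a), Db, _S(b))
        s_cur = lengths[a] + lengths[b]
        s_new, ll_new = _brent_max(f, 2 * MIN_BRANCH, 2 * MAX_BRANCH)
        if ll_new >= f(s_cur):
            s_cur = s_new
        lengths[a] = split * s_cur
        lengths[b] = (1.0 - split) * s_cur
        eng.M[a] = eng._message(a, lengths)
        eng.M[b] = eng._message(b, lengths)

    cur_model = model
    eng.full_postorder(lengths)
    ll = eng.root_loglik()
    if not np.isfinite(ll):
        raise RuntimeError(
            "non-finite log-likelihood at the starting branch lengths"
        )
    for _ in range(max_rounds):
        if binary_root:
            root_sum_step()
            eng._update_internal(tree.root, lengths)
        E[tree.root] = eng.model.frequencies[None, None, :] * np.ones(
            (1, eng.n_pat, 1)
        )
        SE[tree.root] = np.zeros((eng.k, eng.n_pat))
        sweep(tree.root)
        eng._update_internal(tree.root, lengths)
        if optimize_alpha:
            def f_alpha(log_a: float) -> float:
                eng.set_model(cur_model.with_alpha(float(np.exp(log_a))))
                return eng.loglik(lengths)

            la, _ = _brent_max(
                f_alpha, np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1]),
                xatol=0.02,
            )
            cur_model = cur_model.with_alpha(float(np.exp(la)))
            eng.set_model(cur_model)
        eng.full_postorder(lengths)
        ll_new = eng.root_loglik()
        if not np.isfinite(ll_new):
            raise RuntimeError("branch-length optimization produced a "
                               "non-finite log-likelihood")
        if ll_new - ll < tol:
            ll = max(ll, ll_new)
            break
        ll = ll_new
    out = tree.with_lengths(lengths, cls=PhyloTree)
    out.log_likelihood = ll
    out.model = cur_model
    return out


def select_model(
    msa: ProteinAlignment,
    topology: Phylogeny,
    candidates: list[SubstitutionModel],
    use_empirical_frequencies: bool = True,
    tol: float = 1e-6,
    max_rounds: int = 20,
) -> tuple[SubstitutionModel, pd.DataFrame, PhyloTree]:
    """Fit every candidate model (branch lengths + gamma shape) and pick the
    one with the highest log-likelihood; ties broken by candidate order.

    With ``use_empirical_frequencies`` the equilibrium frequencies of each
    candidate are replaced by those observed in the alignment (with a 0.5
    pseudocount), the usual "+F" convention.

    Returns ``(best_model, table, best_tree)`` where ``table`` has one row per
    candidate with its final log-likelihood and fitted alpha.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    rows = []
    fits: list[tuple[SubstitutionModel, PhyloTree]] = []
    for cand in candidates:
        m = cand
        if use_empirical_frequencies:
            m = cand.with_frequencies(msa.residue_frequencies(pseudocount=0.5))
        fit = optimize_branch_lengths(
            msa, topology, m, tol=tol, max_rounds=max_rounds, optimize_alpha=True
        )
        fits.append((fit.model, fit))
        rows.append(
            {"model": cand.name, "log_likelihood": fit.log_likelihood,
             "alpha": fit.model.alpha}
        )
    table = pd.DataFrame(rows)
    best_i = int(table["log_likelihood"].round(12).idxmax())
    # idxmax returns the first index at the max, honouring candidate order
    best_model, best_tree = fits[best_i]
    return best_model, table, best_tree
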