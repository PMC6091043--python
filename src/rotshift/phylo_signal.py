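"""Phylogenetic-signal statistics and the phylogenetic regression.

Implements the signal measures used for the decay-mode / host
characters:

* Fritz–Purvis D for a binary trait (scaled sum of sister-clade
  differences; ~1 under random tip shuffles, ~0 under thresholded
  Brownian motion),
* Pagel's lambda for a continuous trait (multiplier on off-diagonal
  phylogenetic covariances),
* a phylogenetic correlogram (Moran's I across a sequence of
  Gaussian-kernel distance classes, with a bootstrap envelope),
* the Maddison–Slatkin style parsimony randomization for a discrete
  multistate trait (Fitch score vs tip-shuffled null),
* a phylogenetic linear model with a lambda error structure
  (GLS with covariance lambda-transformed, fitted by ML).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats

from . import phylo_core

__all__ = [
    "DResult",
    "LambdaResult",
    "CorrelogramResult",
    "ParsimonyCResult",
    "RegressionResult",
    "fitch_score",
    "parsimony_randomization",
    "estimate_d",
    "fit_lambda",
    "phylo_correlogram",
    "phylo_lm",
]


# ---------------------------------------------------------------------------
# tree flattening shared by D and the Brownian null


class _BinaryLevels:
    """Index arrays for vectorized passes over a rooted binary tree."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        index = {nd: i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root = index[tree.seed_node]
        self.tip_index: dict[str, int] = {}
        level = np.zeros(self.n_nodes, dtype=int)
        left, right = [], []
        node_of_pair = []
        for nd in nodes:
            i = index[nd]
            ch = nd.child_nodes()
            if not ch:
                self.tip_index[nd.taxon.label] = i
                continue
            if len(ch) != 2:
                raise ValueError("binary tree required; resolve polytomies first")
            level[i] = 1 + max(level[index[c]] for c in ch)
            left.append(index[ch[0]])
            right.append(index[ch[1]])
            node_of_pair.append(i)
        left = np.array(left, dtype=int)
        right = np.array(right, dtype=int)
        node_of_pair = np.array(node_of_pair, dtype=int)
        pair_level = level[node_of_pair]
        self.pair_batches = [
            (node_of_pair[pair_level == lv], left[pair_level == lv], right[pair_level == lv])
            for lv in range(1, int(level.max()) + 1)
        ]
        # preorder edge batches for Brownian simulation
        self.edge_child, self.edge_parent, self.edge_len = [], [], []
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                self.edge_child.append(index[nd])
                self.edge_parent.append(index[nd.parent_node])
                self.edge_len.append(nd.edge.length or 0.0)
        self.edge_child = np.array(self.edge_child, dtype=int)
        self.edge_parent = np.array(self.edge_parent, dtype=int)
        self.edge_len = np.array(self.edge_len, dtype=float)
        self.tip_rows = np.array(sorted(self.tip_index.values()), dtype=int)

    def sister_difference_sums(self, tip_values: np.ndarray) -> np.ndarray:
        """d = sum over nodes |v(left) - v(right)|, nodal values by
        equal-weight down-pass averaging; vectorized over replicate columns."""
        vals = np.zeros((self.n_nodes, tip_values.shape[1]))
        vals[self.tip_rows] = tip_values
        d = np.zeros(tip_values.shape[1])
        for node, left, right in self.pair_batches:
            diff = vals[left] - vals[right]
            d += np.abs(diff).sum(axis=0)
            vals[node] = 0.5 * (vals[left] + vals[right])
        return d

    def simulate_bm_tips(self, n_rep: int, rng: np.random.Generator) -> np.ndarray:
        """Unit-rate Brownian tip values, shape (n_tips, n_rep)."""
        vals = np.zeros((self.n_nodes, n_rep))
        eps = rng.standard_normal((len(self.edge_child), n_rep))
        eps *= np.sqrt(self.edge_len)[:, None]
        # preorder order guarantees parents are filled before children
        for e in range(len(self.edge_child)):
            vals[self.edge_child[e]] = vals[self.edge_parent[e]] + eps[e]
        return vals[self.tip_rows]


def _as_binary_tree(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    if any(len(nd.child_nodes()) > 2 for nd in tree.preorder_internal_node_iter()):
        return phylo_core.resolve_polytomies_random(tree, seed=seed)
    return tree


# ---------------------------------------------------------------------------
# Fitch parsimony and randomization


def fitch_score(tree: dendropy.Tree, states: dict) -> int:
    """Minimum number of state changes under Fitch parsimony.

    Requires a binary tree; states may be any hashable discrete values.
    """
    score = 0
    sets: dict = {}
    for nd in tree.postorder_node_iter():
        ch = nd.child_nodes()
        if not ch:
            label = nd.taxon.label
            if label not in states:
                raise KeyError(f"tip {label!r} has no state")
            sets[nd] = frozenset([states[label]])
            continue
        if len(ch) != 2:
            raise ValueError("binary tree required; resolve polytomies first")
        a, b = sets.pop(ch[0]), sets.pop(ch[1])
        inter = a & b
        if inter:
            sets[nd] = inter
        else:
            sets[nd] = a | b
            score += 1
    return score


@dataclass
class ParsimonyCResult:
    score_obs: int
    null_scores: np.ndarray
    p: float
    p_uncorrected: float
    n_rand: int


def parsimony_randomization(
    tree: dendropy.Tree, states: dict, n_rand: int = 1000, seed: int = 42
) -> ParsimonyCResult:
    """Compare the observed Fitch score to tip-shuffled null scores.

    A score below the whole null distribution indicates the trait is
    more conserved on the tree than expected at random. ``p`` uses the
    (1 + #{null <= obs}) / (1 + n_rand) correction.
    """
    tree = _as_binary_tree(tree, seed)
    labels = phylo_core.tip_labels(tree)
    values = [states[lb] for lb in labels]
    obs = fitch_score(tree, dict(zip(labels, values)))
    rng = np.random.default_rng(seed)
    null = np.empty(n_rand, dtype=int)
    vals = np.array(values, dtype=object)
    for r in range(n_rand):
        shuffled = vals[rng.permutation(len(vals))]
        null[r] = fitch_score(tree, dict(zip(labels, shuffled)))
    n_le = int((null <= obs).sum())
    return ParsimonyCResult(
        score_obs=obs,
        null_scores=null,
        p=(1 + n_le) / (1 + n_rand),
        p_uncorrected=n_le / n_rand,
        n_rand=n_rand,
    )


# ---------------------------------------------------------------------------
# Fritz–Purvis D


@dataclass
class DResult:
    d_obs: float
    d_random_mean: float
    d_brownian_mean: float
    D: float
    p_random: float
    p_brownian: float
    n_perm: int


def estimate_d(
    tree: dendropy.Tree, binary_trait: dict, n_sim: int = 1000, seed: int = 42
) -> DResult:
    """Fritz–Purvis D for a binary trait.

    ``d_obs`` is the sum of absolute sister-clade differences of nodal
    values obtained by equal-weight down-pass averaging. It is scaled
    between the mean of a tip-shuffling null (D = 1) and a
    threshold-Brownian null matched to the observed prevalence (D = 0):
    ``D = (d_obs - mean d_B) / (mean d_R - mean d_B)``.

    ``p_random`` is the fraction of shuffle replicates with d <= d_obs
    (small when the trait is clumped); ``p_brownian`` the fraction of
    Brownian replicates with d >= d_obs.
    """
    tree, values = phylo_core.align_trait(tree, binary_trait, on_missing="error")
    uniq = sorted(set(values))
    if len(uniq) != 2:
        raise ValueError(f"trait must be strictly binary, saw values {uniq}")
    tree = _as_binary_tree(tree, seed)
    labels = phylo_core.tip_labels(tree)
    y = np.array([float(binary_trait[lb] == uniq[1]) for lb in labels])
    n = len(y)
    prevalence = y.mean()

    levels = _BinaryLevels(tree)
    # map: row positions in levels.tip_rows for our label order
    pos = {row: i for i, row in enumerate(levels.tip_rows)}
    y_rows = np.empty_like(y)
    for lb, v in zip(labels, y):
        y_rows[pos[levels.tip_index[lb]]] = v

    d_obs = float(levels.sister_difference_sums(y_rows[:, None])[0])

    rng = np.random.default_rng(seed)
    shuffles = np.empty((n, n_sim))
    for r in range(n_sim):
        shuffles[:, r] = y_rows[rng.permutation(n)]
    d_rand = levels.sister_difference_sums(shuffles)

    # prevalence matching by order statistic: each replicate is split into
    # groups of exactly k and n-k tips. The split size uses the minority
    # count — equivalent in distribution (Brownian motion is
    # sign-symmetric) and it makes D exactly invariant to relabeling 0<->1,
    # since the sister-difference sum only sees the partition.
    k_eff = min(int(round(y.sum())), n - int(round(y.sum())))
    bm = levels.simulate_bm_tips(n_sim, rng)
    ranks = np.argsort(np.argsort(bm, axis=0), axis=0)
    bm_bin = (ranks >= n - k_eff).astype(float)
    d_brown = levels.sister_difference_sums(bm_bin)

    mean_r, mean_b = float(d_rand.mean()), float(d_brown.mean())
    if np.isclose(mean_r, mean_b):
        raise ValueError("degenerate nulls: random and Brownian means coincide")
    return DResult(
        d_obs=d_obs,
        d_random_mean=mean_r,
        d_brownian_mean=mean_b,
        D=(d_obs - mean_b) / (mean_r - mean_b),
        p_random=float((d_rand <= d_obs).mean()),
        p_brownian=float((d_brown >= d_obs).mean()),
        n_perm=n_sim,
    )


# ---------------------------------------------------------------------------
# Pagel's lambda


def _lambda_vcv(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls_profile_lnL(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Profile ML: beta and sigma2 maximized analytically given V."""
    n = len(y)
    cf = scipy.linalg.cho_factor(V, lower=True)
    Vinv_X = scipy.linalg.cho_solve(cf, X)
    Vinv_y = scipy.linalg.cho_solve(cf, y)
    XtVX = X.T @ Vinv_X
    beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
    r = y - X @ beta
    Vinv_r = scipy.linalg.cho_solve(cf, r)
    sigma2 = float(r @ Vinv_r) / n
    logdet = 2 * np.sum(np.log(np.diag(cf[0])))
    lnL = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return lnL, beta, sigma2, XtVX


@dataclass
class LambdaResult:
    lambda_hat: float
    lnL: float
    lnL0: float
    lnL1: float
    sigma2: float
    mu: float


def fit_lambda(tree: dendropy.Tree, trait: dict) -> LambdaResult:
    """ML estimate of Pagel's lambda in [0, 1] for a continuous trait.

    The trait is modeled as Gaussian with mean mu and covariance
    sigma2 * V(lambda), where V(lambda) keeps the diagonal of the
    phylogenetic covariance matrix and scales off-diagonals by lambda;
    mu and sigma2 are profiled out analytically.
    """
    tree, values = phylo_core.align_trait(tree, trait, on_missing="error")
    y = np.asarray(values, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("trait is constant; lambda undefined")
    _, C = phylo_core.vcv(tree)
    X = np.ones((len(y), 1))

    def neg(lam: float) -> float:
        try:
            lnL, *_ = _gls_profile_lnL(y, X, _lambda_vcv(C, lam))
        except np.linalg.LinAlgError:
            return 1e12
        return -lnL

    res = scipy.optimize.minimize_scalar(
        neg, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
    )
    candidates = [(0.0, -neg(0.0)), (1.0, -neg(1.0)), (float(res.x), -float(res.fun))]
    lam_hat, lnL_hat = max(candidates, key=lambda t: t[1])
    _, beta, sigma2, _ = _gls_profile_lnL(y, X, _lambda_vcv(C, lam_hat))
    return LambdaResult(
        lambda_hat=lam_hat,
        lnL=lnL_hat,
        lnL0=candidates[0][1],
        lnL1=candidates[1][1],
        sigma2=sigma2,
        mu=float(beta[0]),
    )


# ---------------------------------------------------------------------------
# phylogenetic correlogram


@dataclass
class CorrelogramResult:
    lags: np.ndarray
    moran_i: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_points: int
    n_boot: int


def _moran_i(z: np.ndarray, W: np.ndarray) -> float:
    zc = z - z.mean()
    denom = float(zc @ zc)
    if denom == 0:
        return np.nan
    # rows of W sum to 1, so the n/S0 factor is 1
    return float(zc @ (W @ zc)) / denom


def _kernel_weights(D: np.ndarray, mu: float, sd: float) -> np.ndarray:
    W = np.exp(-0.5 * ((D - mu) / sd) ** 2)
    W[D == 0] = 0.0  # no self-weight (and no weight between identical tips)
    rows = W.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return W / rows


def phylo_correlogram(
    tree: dendropy.Tree,
    trait: dict,
    n_points: int = 100,
    n_boot: int = 100,
    seed: int = 42,
) -> CorrelogramResult:
    """Moran's I across Gaussian distance classes ("lag-norm" weights).

    The tree is rescaled to height 1 internally. For each lag mean
    mu_m the weight matrix is a row-normalized normal density of the
    patristic distances centered at mu_m (kernel sd = 2 * max distance
    / n_points). The envelope is the central 95% of Moran's I over
    bootstrap resamples of the tips.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    tree = phylo_core.rescale_height(tree, 1.0)
    tree, values = phylo_core.align_trait(tree, trait, on_missing="error")
    z = np.asarray(values, dtype=float)
    if np.ptp(z) == 0:
        raise ValueError("trait is constant; autocorrelation undefined")
    _, D = phylo_core.patristic_distances(tree)
    dmax = D.max()
    lags = np.linspace(dmax / n_points, dmax, n_points)
    sd = 2 * dmax / n_points

    moran = np.array([_moran_i(z, _kernel_weights(D, mu, sd)) for mu in lags])

    rng = np.random.default_rng(seed)
    n = len(z)
    boot = np.empty((n_boot, n_points))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Db = D[np.ix_(idx, idx)]
        zb = z[idx]
        for m, mu in enumerate(lags):
            boot[b, m] = _moran_i(zb, _kernel_weights(Db, mu, sd))
    lo, hi = np.nanpercentile(boot, [2.5, 97.5], axis=0)
    return CorrelogramResult(
        lags=lags, moran_i=moran, ci_lower=lo, ci_upper=hi,
        n_points=n_points, n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# phylogenetic linear model (lambda error structure)


@dataclass
class RegressionResult:
    coefficients: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    lambda_hat: float
    sigma2: float
    lnL: float
    names: list


def phylo_lm(
    tree: dendropy.Tree,
    response: dict,
    predictor: dict,
    lambda_fixed: float | None = None,
) -> RegressionResult:
    """GLS regression of a continuous response on one predictor with a
    lambda-transformed phylogenetic error covariance, fitted by ML.

    Used for testing whether (log10) host range differs between decay
    modes: response = log10 host count, predictor = decay-mode
    indicator. ``lambda_fixed=0`` reduces to ordinary least squares.
    """
    common = set(response) & set(predictor) & set(phylo_core.tip_labels(tree))
    if not common:
        raise ValueError("no tips shared by tree, response and predictor")
    tree = phylo_core.prune_to_taxa(tree, common)
    labels = phylo_core.tip_labels(tree)
    y = np.array([float(response[lb]) for lb in labels])
    x = np.array([float(predictor[lb]) for lb in labels])
    X = np.column_stack([np.ones_like(x), x])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant predictor?)")
    _, C = phylo_core.vcv(tree)

    def neg(lam: float) -> float:
        try:
            lnL, *_ = _gls_profile_lnL(y, X, _lambda_vcv(C, lam))
        except np.linalg.LinAlgError:
            return 1e12
        return -lnL

    if lambda_fixed is not None:
        lam_hat = float(lambda_fixed)
    else:
        res = scipy.optimize.minimize_scalar(
            neg, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
        )
        cand = [(0.0, neg(0.0)), (1.0, neg(1.0)), (float(res.x), float(res.fun))]
        lam_hat = min(cand, key=lambda t: t[1])[0]
    lnL, beta, sigma2, XtVX = _gls_profile_lnL(y, X, _lambda_vcv(C, lam_hat))
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    zval = beta / se
    pval = 2 * scipy.stats.norm.sf(np.abs(zval))
    return RegressionResult(
        coefficients=beta, se=se, zvalues=zval, pvalues=pval,
        lambda_hat=lam_hat, sigma2=sigma2, lnL=lnL,
        names=["intercept", "predictor"],
    )
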