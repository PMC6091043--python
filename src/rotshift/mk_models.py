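"""Constrained six-state Markov (Mk) models of decay-mode/host evolution.

The character is the fixed six-state coding (odd = white rot, even =
brown rot; see :mod:`rotshift.host_coding`). Evolution along the tree
is a continuous-time Markov chain with a 6x6 rate matrix Q whose
structure encodes biological hypotheses:

``uncorrelated``
    every single-step transition allowed (30 free cells under ARD);
``correlated_hosts``
    host switches must pass through the generalist state within a decay
    mode, and decay-mode switches preserve the host state (direct
    specialist-to-specialist cells set to zero; 14 cells);
``correlated_hosts_norev``
    additionally forbids brown-rot to white-rot reversals, motivated by
    the irreversible loss of ligninolytic class II peroxidases (11 cells).

Each structure is fitted with equal rates (ER, one shared rate) or all
rates different (ARD), by maximum likelihood via Felsenstein's pruning
algorithm, and compared by AIC / Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .host_coding import STATE_NAMES

__all__ = [
    "N_STATES",
    "MODEL_NAMES",
    "QSpec",
    "RootPrior",
    "MkFit",
    "ModelComparison",
    "build_qspec",
    "build_q",
    "transition_prob",
    "transition_probs",
    "TreeLikelihood",
    "tree_likelihood",
    "fit_mk",
    "aic",
    "compare_models",
    "report_rates",
]

N_STATES = 6
MODEL_NAMES = ("uncorrelated", "correlated_hosts", "correlated_hosts_norev")
RATE_SCHEMES = ("ER", "ARD")

# 0-based state indices: white = {0, 2, 4}, brown = {1, 3, 5};
# host: angiosperm specialist {0, 1}, gymnosperm specialist {2, 3},
# generalist {4, 5}.
_WHITE = (0, 2, 4)
_BROWN = (1, 3, 5)
_GENERALIST = (4, 5)


@dataclass(frozen=True)
class QSpec:
    """Structure of a constrained rate matrix.

    ``mask[i, j]`` marks allowed off-diagonal transitions (0-based
    states); ``param_index[i, j]`` maps each allowed cell to a free
    parameter id (all cells share id 0 under ER). ``k`` is the number
    of free rates.
    """

    model_name: str
    rate_scheme: str
    mask: np.ndarray
    param_index: np.ndarray

    @property
    def k(self) -> int:
        return int(self.param_index.max()) + 1

    @property
    def n_allowed(self) -> int:
        return int(self.mask.sum())

    def allowed_cells(self) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.mask)]


def _model_mask(model_name: str) -> np.ndarray:
    mask = np.zeros((N_STATES, N_STATES), dtype=bool)
    if model_name == "uncorrelated":
        mask[:] = True
    elif model_name in ("correlated_hosts", "correlated_hosts_norev"):
        # host moves via the generalist state, within a decay mode
        for spec, gen in [(0, 4), (2, 4), (1, 5), (3, 5)]:
            mask[spec, gen] = mask[gen, spec] = True
        # decay-mode switches that preserve the host state
        for w, b in zip(_WHITE, _BROWN):
            mask[w, b] = mask[b, w] = True
        if model_name == "correlated_hosts_norev":
            for w, b in zip(_WHITE, _BROWN):
                mask[b, w] = False  # no brown -> white reversals
    else:
        raise ValueError(f"unknown model {model_name!r}; known: {MODEL_NAMES}")
    np.fill_diagonal(mask, False)
    return mask


def build_qspec(model_name: str, rate_scheme: str) -> QSpec:
    """Build the transition mask and parameterization for a model variant."""
    if rate_scheme not in RATE_SCHEMES:
        raise ValueError(f"rate_scheme must be one of {RATE_SCHEMES}")
    mask = _model_mask(model_name)
    param_index = np.full((N_STATES, N_STATES), -1, dtype=int)
    if rate_scheme == "ER":
        param_index[mask] = 0
    else:
        param_index[mask] = np.arange(int(mask.sum()))
    return QSpec(model_name, rate_scheme, mask, param_index)


def build_q(qspec: QSpec, theta: np.ndarray) -> np.ndarray:
    """Fill the rate matrix from free parameters; rows sum to zero."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (qspec.k,):
        raise ValueError(f"theta must have length k={qspec.k}, got {theta.shape}")
    if np.any(theta < 0):
        raise ValueError("rates must be non-negative")
    Q = np.zeros((N_STATES, N_STATES))
    Q[qspec.mask] = theta[qspec.param_index[qspec.mask]]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass(frozen=True)
class RootPrior:
    """Fixed probability vector over the six states at the root."""

    pi: np.ndarray
    kind: str = "custom"

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (N_STATES,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-9:
            raise ValueError("root prior must be a length-6 probability vector")
        object.__setattr__(self, "pi", pi)

    @classmethod
    def flat(cls) -> "RootPrior":
        """Equal weight 1/6 on each of the six states."""
        return cls(np.full(N_STATES, 1 / N_STATES), "flat")

    @classmethod
    def white_rot_equal(cls) -> "RootPrior":
        """Zero weight on brown-rot states, 1/3 on each white-rot state."""
        pi = np.zeros(N_STATES)
        pi[list(_WHITE)] = 1 / 3
        return cls(pi, "white_rot_equal")

    @classmethod
    def from_name(cls, name: str) -> "RootPrior":
        name = name.replace("-", "_")
        if name in ("flat", "equal"):
            return cls.flat()
        if name == "white_rot_equal":
            return cls.white_rot_equal()
        raise ValueError(f"unknown root prior {name!r}")


# ---------------------------------------------------------------------------
# transition probabilities

_EIG_COND_MAX = 1e8


def transition_probs(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) for a vector of branch lengths, shape (len(ts), 6, 6).

    Eigendecomposition of Q (done once) serves all branch lengths; when
    the eigenvector matrix is ill-conditioned (non-generic constrained
    Q), falls back to scaling-and-squaring on each length.
    """
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise ValueError("branch lengths must be non-negative")
    try:
        w, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        cond = np.linalg.cond(U)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < _EIG_COND_MAX:
        E = np.exp(np.multiply.outer(ts, w))  # (m, 6)
        P = np.einsum("ij,mj,jk->mik", U, E, Uinv)
        P = P.real if np.iscomplexobj(P) else P
    else:
        P = scipy.linalg.expm(Q[None, :, :] * ts[:, None, None])
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def transition_prob(Q: np.ndarray, t: float) -> np.ndarray:
    """Single transition-probability matrix P(t) = exp(Qt)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return transition_probs(Q, np.array([t]))[0]


# ---------------------------------------------------------------------------
# pruning likelihood


class TreeLikelihood:
    """Felsenstein pruning likelihood on a fixed (tree, tip states) pair.

    Precomputes a level-ordered edge schedule so that repeated
    evaluations (as in ML optimization) reduce to a handful of batched
    matrix operations per tree level. Tip states are 1-based integers
    or iterables of 1-based integers (ambiguity sets).
    """

    def __init__(self, tree: dendropy.Tree, states: dict, n_states: int = N_STATES):
        self.n_states = n_states
        nodes = list(tree.postorder_node_iter())
        index = {nd: i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root_index = index[tree.seed_node]

        tip_partials = np.ones((self.n_nodes, n_states))
        level = np.zeros(self.n_nodes, dtype=int)
        is_tip = np.zeros(self.n_nodes, dtype=bool)
        for nd in nodes:
            i = index[nd]
            if nd.is_leaf():
                label = nd.taxon.label
                if label not in states:
                    raise KeyError(f"tip {label!r} has no assigned state")
                val = states[label]
                seen = [val] if np.isscalar(val) else list(val)
                part = np.zeros(n_states)
                for s in seen:
                    s = int(s)
                    if not (1 <= s <= n_states):
                        raise ValueError(f"state {s} out of 1..{n_states} for {label!r}")
                    part[s - 1] = 1.0
                tip_partials[i] = part
                is_tip[i] = True
            else:
                level[i] = 1 + max(level[index[ch]] for ch in nd.child_nodes())
        extra = set(states) - {nd.taxon.label for nd in nodes if nd.is_leaf()}
        if extra:
            raise KeyError(f"states given for taxa absent from tree: {sorted(extra)[:5]}")

        child_idx, parent_idx, lengths = [], [], []
        for nd in nodes:
            if nd.parent_node is not None:
                child_idx.append(index[nd])
                parent_idx.append(index[nd.parent_node])
                lengths.append(nd.edge.length or 0.0)
        child_idx = np.array(child_idx, dtype=int)
        parent_idx = np.array(parent_idx, dtype=int)
        self.lengths = np.array(lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise ValueError("negative branch length")

        # schedule edges by the level of their child node
        child_level = level[child_idx]
        self._edge_batches = []
        for lvl in range(int(level.max()) + 1):
            sel = np.nonzero(child_level == lvl)[0]
            if sel.size:
                self._edge_batches.append((sel, child_idx[sel], parent_idx[sel]))
        self._internal_by_level = [
            np.nonzero((level == lvl) & ~is_tip)[0]
            for lvl in range(1, int(level.max()) + 1)
        ]
        self._tip_partials = tip_partials
        self._is_tip = is_tip

    def log_likelihood(self, Q: np.ndarray, prior: RootPrior) -> float:
        """ln L = log sum_i pi_i L_i(root), with per-node rescaling."""
        P = transition_probs(Q, self.lengths)
        partials = self._tip_partials.copy()
        logscale = 0.0
        n_batches = len(self._edge_batches)
        for b, (sel, child, parent) in enumerate(self._edge_batches):
            msgs = np.einsum("eij,ej->ei", P[sel], partials[child])
            np.multiply.at(partials, parent, msgs)
            if b < len(self._internal_by_level):
                done = self._internal_by_level[b]
                mx = partials[done].max(axis=1)
                if np.any(mx <= 0):
                    return -np.inf
                partials[done] /= mx[:, None]
                logscale += float(np.log(mx).sum())
        root_l = float(prior.pi @ partials[self.root_index])
        if root_l <= 0:
            return -np.inf
        return float(np.log(root_l) + logscale)


def tree_likelihood(
    tree: dendropy.Tree, states: dict, Q: np.ndarray, prior: RootPrior
) -> float:
    """One-shot pruning log-likelihood (see :class:`TreeLikelihood`)."""
    return TreeLikelihood(tree, states).log_likelihood(Q, prior)


# ---------------------------------------------------------------------------
# fitting and model selection


@dataclass
class MkFit:
    qspec: QSpec
    theta_hat: np.ndarray
    lnL: float
    k: int
    aic: float
    converged: bool
    n_restarts_used: int
    prior: RootPrior
    lower_bound: float = 1e-9

    def to_dict(self) -> dict:
        return {
            "model": self.qspec.model_name,
            "scheme": self.qspec.rate_scheme,
            "root": self.prior.kind,
            "k": self.k,
            "lnL": self.lnL,
            "aic": self.aic,
            "converged": self.converged,
            "rates": report_rates(self).to_dict(orient="records"),
        }


def aic(lnL: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 lnL."""
    return 2 * k - 2 * lnL


def fit_mk(
    tree: dendropy.Tree,
    states: dict,
    qspec: QSpec,
    prior: RootPrior | None = None,
    n_restarts: int = 10,
    seed: int = 42,
    bounds: tuple[float, float] = (1e-9, 100.0),
    rescale_to_unit_height: bool = True,
) -> MkFit:
    """Maximum-likelihood rates for one model structure.

    Optimization runs on log-rates with bounds per unit branch length;
    the tree is internally rescaled to unit height (rates reported on
    the original branch-length scale) to stabilize fits on trees in
    absolute-time units. ``n_restarts`` optimizations start from
    log-uniform draws; the best is kept.
    """
    from .phylo_core import tree_height

    if prior is None:
        prior = RootPrior.flat()
    h = tree_height(tree) if rescale_to_unit_height else 1.0
    if h <= 0:
        raise ValueError("tree has zero height")
    lik = TreeLikelihood(tree, states)
    lengths = lik.lengths.copy()
    lik.lengths = lengths / h  # rates fitted per unit of scaled length

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    k = qspec.k

    def neg_lnL(x: np.ndarray) -> float:
        Q = build_q(qspec, np.exp(x))
        val = lik.log_likelihood(Q, prior)
        return 1e12 if not np.isfinite(val) else -val

    rng = np.random.default_rng(seed)
    # a Fitch-flavored scale guess: about one event per tree on average
    starts = [np.full(k, np.log(1.0))]
    starts += [rng.uniform(np.log(1e-2), np.log(20.0), size=k) for _ in range(n_restarts - 1)]

    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        res = scipy.optimize.minimize(
            neg_lnL, x0, method="L-BFGS-B", bounds=[(lo, hi)] * k,
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    converged = bool(best is not None and best.success and best.fun < 1e11)
    theta_scaled = np.exp(best.x)
    lnL = -float(best.fun)
    return MkFit(
        qspec=qspec,
        theta_hat=theta_scaled / h,
        lnL=lnL,
        k=k,
        aic=aic(lnL, k),
        converged=converged,
        n_restarts_used=n_used,
        prior=prior,
        lower_bound=bounds[0] / h,
    )


@dataclass
class ModelComparison:
    fits: list
    delta_aic: np.ndarray
    weights: np.ndarray

    def table(self, labels: list[str] | None = None) -> pd.DataFrame:
        if labels is None:
            labels = [
                f"{f.qspec.model_name}, {f.qspec.rate_scheme}, root = {f.prior.kind}"
                for f in self.fits
            ]
        return pd.DataFrame(
            {
                "model": labels,
                "k": [f.k for f in self.fits],
                "neg_lnL": [-f.lnL for f in self.fits],
                "AIC": [f.aic for f in self.fits],
                "delta_AIC": self.delta_aic,
                "w": self.weights,
            }
        )


def compare_models(fits: list) -> ModelComparison:
    """Delta-AIC and Akaike weights, w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)."""
    if not fits:
        raise ValueError("need at least one fit")
    aics = np.array([f.aic for f in fits], dtype=float)
    delta = aics - aics.min()
    raw = np.exp(-delta / 2)
    return ModelComparison(fits=list(fits), delta_aic=delta, weights=raw / raw.sum())


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights from raw AIC (or delta-AIC) values."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    raw = np.exp(-delta / 2)
    return raw / raw.sum()


def report_rates(fit: MkFit, zero_tol_factor: float = 1.5) -> pd.DataFrame:
    """Per-transition rate table for the fitted model.

    One row per allowed transition, labeled with the six-state names.
    Estimates pinned at the optimizer's lower bound are reported as 0.
    """
    qspec = fit.qspec
    rows = []
    zero_cut = fit.lower_bound * zero_tol_factor
    for (i, j) in qspec.allowed_cells():
        rate = float(fit.theta_hat[qspec.param_index[i, j]])
        rows.append(
            {
                "from_state": i + 1,
                "to_state": j + 1,
                "from": STATE_NAMES[i + 1],
                "to": STATE_NAMES[j + 1],
                "estimate": 0.0 if rate <= zero_cut else rate,
            }
        )
    return pd.DataFrame(rows)
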