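"""Synthetic trees, characters and host-count tables with known truth.

Every downstream module is testable without external data: a
birth–death tree stands in for the empirical chronogram, a six-state
CTMC simulated along it provides tip states with a full event log, and
host-association / decay-mode tables are generated so that re-coding
them recovers the true states exactly.

Default conditions mirror the empirical study design: 1157 tips, a
root age of 282 (time units, interpreted as MY), and a generating
model of the ``correlated_hosts_norev`` structure with all rates
different and a white-rot root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import phylo_core
from .host_coding import (
    SCHEME_90_10,
    CodingScheme,
    DecayMode,
    DecayModeRecord,
    HostState,
    genus_of,
    state_components,
)
from .mk_models import N_STATES, QSpec, RootPrior, build_q, build_qspec

__all__ = [
    "SimConfig",
    "SimBundle",
    "EventLog",
    "DEFAULT_NOREV_RATES",
    "default_norev_q",
    "simulate_tree",
    "simulate_discrete",
    "simulate_bm",
    "simulate_lambda",
    "simulate_threshold_binary",
    "simulate_host_counts",
    "make_fixture",
]


# ---------------------------------------------------------------------------
# trees


def _birth_death_tree(
    n_tips: int, birth: float, death: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Forward birth–death simulation stopped at ``n_tips`` extant lineages.

    Starts from a crown split (two lineages), conditions on survival by
    restarting on total extinction, prunes extinct lineages, and — to
    avoid the zero-length cherry a naive stop-at-the-nth-birth gives —
    extends the extant branches by the waiting time to the next event.
    """
    while True:
        tree = dendropy.Tree()
        root = tree.seed_node
        t = 0.0
        extant: list[tuple[dendropy.Node, float]] = []  # (node, branch start)
        for _ in range(2):
            ch = root.new_child()
            extant.append((ch, 0.0))
        failed = False
        while len(extant) < n_tips:
            k = len(extant)
            t += rng.exponential(1.0 / (k * (birth + death)))
            idx = int(rng.integers(k))
            node, start = extant.pop(idx)
            node.edge.length = t - start
            if rng.random() < birth / (birth + death):
                for _ in range(2):
                    extant.append((node.new_child(), t))
            else:
                if not extant:
                    failed = True
                    break
        if failed:
            continue
        # final extension: stop just before the next event
        t += rng.exponential(1.0 / (len(extant) * (birth + death)))
        survivors = {id(node) for node, _ in extant}
        for node, start in extant:
            node.edge.length = t - start
        # prune extinct lineages, merging lengths through unifurcations
        while True:
            dead = [lf for lf in tree.leaf_node_iter() if id(lf) not in survivors]
            if not dead:
                break
            for lf in dead:
                lf.parent_node.remove_child(lf)
        tree.suppress_unifurcations()
        return tree


def simulate_tree(
    n_tips: int,
    birth: float = 1.0,
    death: float = 0.0,
    seed: int = 42,
    genus_size_mean: float = 3.0,
) -> dendropy.Tree:
    """Ultrametric birth–death tree with ``n_tips`` extant tips.

    Tips are labeled ``Genus<i>_sp<j>`` in blocks of consecutive
    leaves (block sizes geometric with the given mean), giving the
    genus structure that the coding utilities expect. Reproducible per
    seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    tree = _birth_death_tree(n_tips, birth, death, np.random.default_rng(seed))
    # relabel tips with a genus block structure
    nrng = np.random.default_rng(seed)
    p = 1.0 / genus_size_mean
    genus, left = 0, 0
    for i, leaf in enumerate(tree.leaf_node_iter()):
        if left == 0:
            left = int(nrng.geometric(p))
            genus += 1
        label = f"Genus{genus}_sp{i + 1}"
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(label)
        else:
            leaf.taxon.label = label
        left -= 1
    return tree


# ---------------------------------------------------------------------------
# discrete character simulation


@dataclass
class EventLog:
    """Record of every simulated transition plus state occupancy."""

    events: list = field(default_factory=list)  # (edge_id, time, from, to) 1-based
    dwell_time: np.ndarray = field(default_factory=lambda: np.zeros(N_STATES))
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_STATES, N_STATES), dtype=int)
    )

    def rate_estimates(self) -> np.ndarray:
        """Naive rate estimates: transition counts / source-state dwell time."""
        with np.errstate(divide="ignore", invalid="ignore"):
            R = self.counts / self.dwell_time[:, None]
        return np.where(np.isfinite(R), R, np.nan)


def simulate_discrete(
    tree: dendropy.Tree,
    Q: np.ndarray,
    root: int | RootPrior | np.ndarray,
    seed: int = 42,
) -> tuple[dict, EventLog]:
    """Exact CTMC simulation of a discrete character along the tree.

    ``root`` is a 1-based state, a :class:`RootPrior`, or a probability
    vector. Returns tip states (1-based) and the full event log with
    per-state dwell times.
    """
    rng = np.random.default_rng(seed)
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    if isinstance(root, RootPrior):
        root_state = int(rng.choice(n, p=root.pi))
    elif np.ndim(root) == 0:
        root_state = int(root) - 1
        if not 0 <= root_state < n:
            raise ValueError(f"root state must be 1..{n}")
    else:
        pi = np.asarray(root, dtype=float)
        root_state = int(rng.choice(n, p=pi / pi.sum()))

    log = EventLog()
    node_state = {tree.seed_node: root_state}
    tips: dict[str, int] = {}
    for edge_id, nd in enumerate(tree.preorder_node_iter()):
        if nd.parent_node is None:
            continue
        s = node_state[nd.parent_node]
        t_remaining = nd.edge.length or 0.0
        t_pos = 0.0
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                log.dwell_time[s] += t_remaining
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= t_remaining:
                log.dwell_time[s] += t_remaining
                break
            log.dwell_time[s] += wait
            t_pos += wait
            t_remaining -= wait
            probs = Q[s].copy()
            probs[s] = 0.0
            s_new = int(rng.choice(n, p=probs / probs.sum()))
            log.events.append((edge_id, t_pos, s + 1, s_new + 1))
            log.counts[s, s_new] += 1
            s = s_new
        node_state[nd] = s
        if nd.is_leaf():
            tips[nd.taxon.label] = s + 1
    return tips, log


# ---------------------------------------------------------------------------
# continuous characters


def _bm_tips(tree: dendropy.Tree, sigma2: float, rng: np.random.Generator) -> dict:
    vals = {tree.seed_node: 0.0}
    out = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            t = nd.edge.length or 0.0
            vals[nd] = vals[nd.parent_node] + rng.standard_normal() * np.sqrt(sigma2 * t)
        if nd.is_leaf():
            out[nd.taxon.label] = vals[nd]
    return out


def simulate_bm(tree: dendropy.Tree, sigma2: float = 1.0, seed: int = 42) -> dict:
    """Brownian motion tip values (independent Gaussian branch increments)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    return _bm_tips(tree, sigma2, np.random.default_rng(seed))


def simulate_lambda(
    tree: dendropy.Tree, lam: float, sigma2: float = 1.0, seed: int = 42
) -> dict:
    """Gaussian tip values under the lambda-transformed covariance."""
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")
    labels, C = phylo_core.vcv(tree)
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(labels)))
    y = np.sqrt(sigma2) * (L @ rng.standard_normal(len(labels)))
    return dict(zip(labels, y))


def simulate_threshold_binary(
    tree: dendropy.Tree, prevalence: float, seed: int = 42
) -> dict:
    """Binary trait from thresholded Brownian motion at a target prevalence."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    bm = simulate_bm(tree, 1.0, seed)
    labels = list(bm)
    vals = np.array([bm[lb] for lb in labels])
    cut = np.quantile(vals, 1 - prevalence)
    return {lb: int(v >= cut) for lb, v in zip(labels, vals)}


# ---------------------------------------------------------------------------
# host-count tables


def _draw_total_hosts(law: tuple, rng: np.random.Generator) -> int:
    """Zero-truncated draw of a species' total woody-host count."""
    family, params = law
    while True:
        if family == "ztnb":
            t = int(rng.negative_binomial(params["n"], params["p"]))
        elif family == "poisson":
            t = int(rng.poisson(params["mean"]))
        elif family == "fixed":
            t = int(params["value"])
        else:
            raise ValueError(f"unknown total-host law {family!r}")
        if t >= 1:
            return t


#: long-tailed default: mean ~8 woody hosts, overdispersed
DEFAULT_HOST_LAW = ("ztnb", {"n": 0.8, "p": 0.8 / 8.8})


def simulate_host_counts(
    true_states: dict,
    total_host_law: tuple = DEFAULT_HOST_LAW,
    purity: float = 0.95,
    seed: int = 42,
    scheme: CodingScheme = SCHEME_90_10,
    max_retries: int = 1000,
) -> tuple[pd.DataFrame, list[DecayModeRecord]]:
    """Host-association and decay-mode tables consistent with true states.

    For each species the total woody-host count is drawn from
    ``total_host_law`` and split between gymnosperms and angiosperms so
    the realized gymnosperm association re-codes to the species' true
    host state under ``scheme`` (specialists at least as extreme as
    ``purity``; generalists strictly between the thresholds). The decay
    mode is read off the state parity. Decay records are genus-level
    where a genus is uniform, species-level otherwise.
    """
    if not (scheme.upper_threshold <= purity <= 1.0):
        raise ValueError("purity must be >= the scheme's upper threshold")
    rng = np.random.default_rng(seed)
    rows = []
    modes: dict[str, DecayMode] = {}
    for species in true_states:
        state = int(true_states[species])
        mode, host = state_components(state)
        modes[species] = mode
        for attempt in range(max_retries):
            total = _draw_total_hosts(total_host_law, rng)
            n_gym = _split_counts(total, host, purity, scheme, rng)
            if n_gym is not None:
                break
        else:
            raise RuntimeError(f"could not satisfy purity for {species}")
        rows.append(
            {"species": species, "n_angiosperm": total - n_gym, "n_gymnosperm": n_gym}
        )
    hosts = pd.DataFrame(rows, columns=["species", "n_angiosperm", "n_gymnosperm"])

    decay: list[DecayModeRecord] = []
    by_genus: dict[str, list[str]] = {}
    for sp in true_states:
        by_genus.setdefault(genus_of(sp), []).append(sp)
    for genus, members in by_genus.items():
        member_modes = {modes[sp] for sp in members}
        if len(member_modes) == 1:
            decay.append(DecayModeRecord(genus, member_modes.pop(), "genus"))
        else:
            decay.extend(DecayModeRecord(sp, modes[sp], "species") for sp in members)
    return hosts, decay


def _split_counts(
    total: int,
    host: HostState,
    purity: float,
    scheme: CodingScheme,
    rng: np.random.Generator,
) -> int | None:
    """Gymnosperm count placing g in the coding region; None if infeasible."""
    lo, hi = scheme.lower_threshold, scheme.upper_threshold
    if host is HostState.gymnosperm_specialist:
        n_min = max(int(np.ceil(purity * total)), int(np.ceil(hi * total)))
        if n_min > total:
            n_min = total
        n = int(rng.integers(n_min, total + 1))
        return n if n / total >= hi else None
    if host is HostState.angiosperm_specialist:
        n_max = min(int(np.floor((1 - purity) * total)), int(np.floor(lo * total)))
        n = int(rng.integers(0, n_max + 1)) if n_max >= 0 else 0
        return n if n / total <= lo else None
    # generalist: strictly between the thresholds
    lo_int = int(np.floor(lo * total)) + 1
    hi_int = int(np.ceil(hi * total)) - 1
    candidates = [n for n in range(lo_int, hi_int + 1) if lo < n / total < hi]
    if not candidates:
        return None
    return int(rng.choice(candidates))


# ---------------------------------------------------------------------------
# fixtures

# generating rates for the norev/ARD structure, per unit tree height;
# deliberately well separated so each transition is informative
DEFAULT_NOREV_RATES = {
    (1, 5): 3.0, (5, 1): 4.0,   # white: angiosperm specialist <-> generalist
    (3, 5): 1.0, (5, 3): 0.6,   # white: gymnosperm specialist <-> generalist
    (2, 6): 1.5, (6, 2): 2.0,   # brown: angiosperm specialist <-> generalist
    (4, 6): 2.5, (6, 4): 1.2,   # brown: gymnosperm specialist <-> generalist
    (1, 2): 0.4, (3, 4): 0.8, (5, 6): 0.5,  # white -> brown switches
}


def default_norev_q(height: float = 1.0) -> tuple[QSpec, np.ndarray]:
    """Default generating (QSpec, Q) for a tree of the given height."""
    qspec = build_qspec("correlated_hosts_norev", "ARD")
    theta = np.zeros(qspec.k)
    for (i, j), rate in DEFAULT_NOREV_RATES.items():
        theta[qspec.param_index[i - 1, j - 1]] = rate / height
    return qspec, build_q(qspec, theta)


@dataclass
class SimConfig:
    """Conditions for a full synthetic bundle."""

    n_tips: int = 1157
    birth_rate: float = 1.0
    death_rate: float = 0.0
    tree_height: float = 282.0
    model_name: str = "correlated_hosts_norev"
    rates: dict = field(default_factory=lambda: dict(DEFAULT_NOREV_RATES))
    root: str = "white_rot_equal"
    scheme: CodingScheme = SCHEME_90_10
    purity: float = 0.95
    total_host_law: tuple = DEFAULT_HOST_LAW
    seed: int = 42


@dataclass
class SimBundle:
    tree: dendropy.Tree
    true_states: dict
    host_table: pd.DataFrame
    decay_table: list
    event_log: EventLog
    qspec: QSpec
    q_true: np.ndarray
    config: SimConfig


def make_fixture(config: SimConfig | None = None, out_dir=None) -> SimBundle:
    """Simulate a full bundle (tree, states, host/decay tables).

    With ``out_dir`` set, writes ``tree.nwk``, ``hosts.csv``,
    ``decay.csv`` and ``truth.csv``. Deterministic per ``config.seed``;
    sub-seeds for the tree, character and host-count stages are split
    from it.
    """
    if config is None:
        config = SimConfig()
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(config.seed).spawn(3)]
    tree = simulate_tree(
        config.n_tips, config.birth_rate, config.death_rate, seed=seeds[0]
    )
    tree = phylo_core.rescale_height(tree, config.tree_height)

    qspec = build_qspec(config.model_name, "ARD")
    theta = np.zeros(qspec.k)
    for (i, j), rate in config.rates.items():
        if qspec.param_index[i - 1, j - 1] < 0:
            raise ValueError(f"rate for disallowed transition {i}->{j}")
        theta[qspec.param_index[i - 1, j - 1]] = rate / config.tree_height
    Q = build_q(qspec, theta)
    prior = RootPrior.from_name(config.root)
    states, log = simulate_discrete(tree, Q, prior, seed=seeds[1])
    hosts, decay = simulate_host_counts(
        states,
        total_host_law=config.total_host_law,
        purity=config.purity,
        seed=seeds[2],
        scheme=config.scheme,
    )
    bundle = SimBundle(tree, states, hosts, decay, log, qspec, Q, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        phylo_core.write_newick(tree, out / "tree.nwk")
        hosts.to_csv(out / "hosts.csv", index=False)
        pd.DataFrame(
            [{"taxon": r.taxon, "mode": r.mode.value, "level": r.source_level}
             for r in decay]
        ).to_csv(out / "decay.csv", index=False)
        pd.DataFrame(
            {"species": list(states), "state": [states[s] for s in states]}
        ).to_csv(out / "truth.csv", index=False)
    return bundle
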