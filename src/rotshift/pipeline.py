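"""End-to-end orchestration: code -> fit -> compare -> signal.

Runs the full comparative analysis from a tree plus host/decay tables:
six-state coding, ML fits of the candidate Mk models, an AIC model
table, per-transition rate tables, phylogenetic-signal statistics, and
the two robustness loops (alternative trees, one-genus subsets).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import host_coding, mk_models, phylo_core, phylo_signal

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "MODEL_SET_TABLE1", "run_full"]

#: the standard candidate set: three structures x {ER, ARD} with a flat
#: root, plus the norev/ARD variant with a white-rot-only root
MODEL_SET_TABLE1 = [
    ("uncorrelated", "ER", "flat"),
    ("uncorrelated", "ARD", "flat"),
    ("correlated_hosts", "ER", "flat"),
    ("correlated_hosts", "ARD", "flat"),
    ("correlated_hosts_norev", "ER", "flat"),
    ("correlated_hosts_norev", "ARD", "flat"),
    ("correlated_hosts_norev", "ARD", "white_rot_equal"),
]


@dataclass
class AnalysisConfig:
    tree: str
    hosts: str
    decay: str
    alt_trees: str | None = None  # nexus tree set
    scheme: str = "90-10"
    models: list = field(default_factory=lambda: list(MODEL_SET_TABLE1))
    n_restarts: int = 5
    seed: int = 42
    n_alt_trees: int = 0
    n_subsets: int = 0
    signal: bool = True
    n_signal_sim: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _fit_model_set(tree, states, models, n_restarts, seed):
    fits = []
    for i, (model, scheme, root) in enumerate(models):
        qspec = mk_models.build_qspec(model, scheme)
        prior = mk_models.RootPrior.from_name(root)
        logger.info("fitting %s/%s root=%s", model, scheme, root)
        fits.append(
            mk_models.fit_mk(
                tree, states, qspec, prior, n_restarts=n_restarts, seed=seed + i
            )
        )
    return fits


def _rounded_table(comparison: mk_models.ModelComparison) -> pd.DataFrame:
    tab = comparison.table()
    for col in ("neg_lnL", "AIC", "delta_AIC", "w"):
        tab[col] = tab[col].round(2)
    return tab


def run_full(config: AnalysisConfig, out_dir=None) -> dict:
    """Run the full analysis; returns a report bundle (dict of results).

    With ``out_dir`` set, writes ``coded_states.csv``,
    ``model_table.csv``, ``rates_<model>.csv``, ``signal/*.json`` and
    ``robustness/*.csv``.
    """
    tree = phylo_core.read_newick(config.tree)
    hosts = host_coding.read_hosts_csv(config.hosts)
    decay = host_coding.read_decay_csv(config.decay)
    scheme = host_coding.get_scheme(config.scheme)
    coded = host_coding.code_table(hosts, decay, scheme)
    if coded.empty:
        raise ValueError("no codable species (check host/decay tables)")

    states = dict(zip(coded["species"], coded["state"]))
    tree_fit = phylo_core.prune_to_taxa(tree, set(states))
    kept = set(phylo_core.tip_labels(tree_fit))
    states = {sp: st for sp, st in states.items() if sp in kept}
    logger.info("coded %d species, %d on the tree", len(coded), len(states))

    fits = _fit_model_set(tree_fit, states, config.models, config.n_restarts, config.seed)
    if not all(f.converged for f in fits):
        bad = [m for m, f in zip(config.models, fits) if not f.converged]
        raise RuntimeError(f"non-converged fits: {bad}")
    comparison = mk_models.compare_models(fits)
    best = fits[int(np.argmin([f.aic for f in fits]))]
    report: dict = {
        "coded_states": coded,
        "fits": fits,
        "comparison": comparison,
        "model_table": _rounded_table(comparison),
        "best": best,
        "rates": {
            f"{f.qspec.model_name}_{f.qspec.rate_scheme}_{f.prior.kind}":
                mk_models.report_rates(f)
            for f in fits
        },
    }

    if config.signal:
        decay_trait = {r.species: r.mode for r in coded.itertuples(index=False)}
        gym_trait = {r.species: r.gym_assoc for r in coded.itertuples(index=False)}
        totals = hosts.set_index("species")[["n_angiosperm", "n_gymnosperm"]].sum(axis=1)
        log_range = {
            sp: float(np.log10(totals[sp])) for sp in decay_trait if totals[sp] >= 1
        }
        is_brown = {sp: float(m == "brown") for sp, m in decay_trait.items()}
        report["signal"] = {
            "host_range_lm": phylo_signal.phylo_lm(tree_fit, log_range, is_brown)
            if len(set(is_brown.values())) == 2 else None,
            "D_decay_mode": phylo_signal.estimate_d(
                tree_fit, decay_trait, n_sim=config.n_signal_sim, seed=config.seed
            ),
            "lambda_gym_assoc": phylo_signal.fit_lambda(tree_fit, gym_trait),
            "parsimony_six_state": phylo_signal.parsimony_randomization(
                tree_fit, states, n_rand=config.n_signal_sim, seed=config.seed
            ),
        }

    if config.n_alt_trees > 0:
        if not config.alt_trees:
            raise ValueError("n_alt_trees > 0 requires an alt_trees nexus path")
        alt = phylo_core.read_nexus_trees(config.alt_trees)[: config.n_alt_trees]
        report["robustness_trees"] = _refit_over(
            alt, states, best, config, label="tree"
        )
    if config.n_subsets > 0:
        chars = host_coding.characters_from_frame(coded)
        subsets = []
        for rep in range(config.n_subsets):
            sub = host_coding.one_genus_subset(chars, seed=config.seed + rep)
            sub_states = {c.species: c.state for c in sub if c.species in kept}
            subsets.append(sub_states)
        report["robustness_subsets"] = _refit_subsets(
            tree_fit, subsets, best, config
        )

    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _refit_over(trees, states, best, config, label):
    rows = []
    for i, t in enumerate(trees):
        t2 = phylo_core.prune_to_taxa(t, set(states))
        sub_states = {s: v for s, v in states.items()
                      if s in set(phylo_core.tip_labels(t2))}
        fit = mk_models.fit_mk(
            t2, sub_states, best.qspec, best.prior,
            n_restarts=max(2, config.n_restarts // 2), seed=config.seed + i,
        )
        for r in mk_models.report_rates(fit).itertuples(index=False):
            rows.append({label: i, "from": r.from_state, "to": r.to_state,
                         "estimate": r.estimate})
    return _summarize_rates(pd.DataFrame(rows))


def _refit_subsets(tree, subsets, best, config):
    rows = []
    for i, sub_states in enumerate(subsets):
        t2 = phylo_core.prune_to_taxa(tree, set(sub_states))
        keep = set(phylo_core.tip_labels(t2))
        fit = mk_models.fit_mk(
            t2, {s: v for s, v in sub_states.items() if s in keep},
            best.qspec, best.prior,
            n_restarts=max(2, config.n_restarts // 2), seed=config.seed + i,
        )
        for r in mk_models.report_rates(fit).itertuples(index=False):
            rows.append({"subset": i, "from": r.from_state, "to": r.to_state,
                         "estimate": r.estimate})
    return _summarize_rates(pd.DataFrame(rows))


def _summarize_rates(long: pd.DataFrame) -> dict:
    """Per-transition quantiles of rate estimates across replicates."""
    summary = (
        long.groupby(["from", "to"])["estimate"]
        .quantile([0.025, 0.25, 0.5, 0.75, 0.975])
        .unstack()
        .reset_index()
    )
    return {"replicates": long, "quantiles": summary}


def _write_report(report: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report["coded_states"].to_csv(out / "coded_states.csv", index=False)
    report["model_table"].to_csv(out / "model_table.csv", index=False)
    for name, rates in report["rates"].items():
        rates.to_csv(out / f"rates_{name}.csv", index=False)
    if "signal" in report:
        sig_dir = out / "signal"
        sig_dir.mkdir(exist_ok=True)
        d = report["signal"]["D_decay_mode"]
        lam = report["signal"]["lambda_gym_assoc"]
        pc = report["signal"]["parsimony_six_state"]
        lm = report["signal"].get("host_range_lm")
        payload = {
            "D": {"D": d.D, "d_obs": d.d_obs, "p_random": d.p_random,
                  "p_brownian": d.p_brownian},
            "lambda": {"lambda_hat": lam.lambda_hat, "lnL": lam.lnL},
            "parsimony": {"score_obs": pc.score_obs, "p": pc.p},
        }
        if lm is not None:
            payload["host_range_lm"] = {
                "coefficients": dict(zip(lm.names, lm.coefficients.tolist())),
                "pvalues": dict(zip(lm.names, lm.pvalues.tolist())),
                "lambda_hat": lm.lambda_hat,
            }
        with open(sig_dir / "signal.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    for key, sub in (("robustness_trees", "trees"), ("robustness_subsets", "subsets")):
        if key in report:
            rb = out / "robustness"
            rb.mkdir(exist_ok=True)
            report[key]["replicates"].to_csv(rb / f"{sub}_replicates.csv", index=False)
            report[key]["quantiles"].to_csv(rb / f"{sub}_quantiles.csv", index=False)
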