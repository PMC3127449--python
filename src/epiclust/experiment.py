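"""The replicated paired experiment: does clustering leave a signal?

Each replicate samples a base network ``Y_i``, rewires it to a
high-clustering arm ``Y_i^hi`` (coefficient +5) and a low-clustering arm
``Y_i^lo`` (coefficient -5) while preserving every node's degree, runs a
conditioned SEIR epidemic on each arm from a shared index node, extracts
both transmission trees and reduces them to one summary row per arm.
Comparing the per-arm summary distributions asks whether clustering level
is detectable from epidemic data when the degree sequence is held fixed.

Seeding: the master seed spawns one independent substream per replicate, so
replicates are reproducible individually and results do not depend on
execution order.  Replicates whose conditioning fails are reported in the
table with ``failed=True``, never silently resampled.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .networks import (
    BernoulliParams,
    PowerLawParams,
    global_clustering,
    largest_component,
    sample_bernoulli,
    sample_power_law,
)
from .rewire import RewireConfig, rewire_network
from .seir import EpidemicParams, PairingError, paired_epidemics
from .summaries import summarize_curve, summarize_tree
from .transtree import build_tree, write_newick

__all__ = [
    "ExperimentConfig",
    "STATISTICS",
    "run_replicate",
    "run_experiment",
    "compare_distributions",
]

#: summary columns compared between the high- and low-clustering arms
STATISTICS = [
    "clustering",
    "final_size",
    "epidemic_length",
    "peak_prevalence",
    "peak_time",
    "mean_internal_branch",
    "mean_external_branch",
    "mean_secondary",
    "cherry_ratio",
    "prop_giant_infected",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of the paired experiment.

    Defaults are the study conditions: Bernoulli N=500, p=7/N; power-law
    N=600, alpha=1.8; gwesp decay 0.2 with coefficients +5/-5 and burn-in
    5e5 proposals; SEIR beta=0.1, unit-shape gamma periods with scale 3
    days, outbreaks of at least 20; 500 replicates.
    """

    model: str = "bernoulli"
    n_nodes: int = 500
    edge_prob: float = 0.014
    exponent: float = 1.8
    max_degree: int | None = None
    decay: float = 0.2
    theta_hi: float = 5.0
    theta_lo: float = -5.0
    burnin: int = 500_000
    epidemic: EpidemicParams = field(default_factory=EpidemicParams)
    n_replicates: int = 500
    seed: int = 0
    max_attempts: int = 200
    index_redraws: int = 20

    def __post_init__(self) -> None:
        if self.model not in ("bernoulli", "powerlaw"):
            raise ValueError(f"model must be 'bernoulli' or 'powerlaw', got {self.model}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epidemic"] = asdict(self.epidemic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "epidemic" in d and isinstance(d["epidemic"], dict):
            d["epidemic"] = EpidemicParams(**d["epidemic"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sample_base_network(config: ExperimentConfig, rng: np.random.Generator):
    if config.model == "bernoulli":
        return sample_bernoulli(BernoulliParams(config.n_nodes, config.edge_prob), rng)
    return sample_power_law(
        PowerLawParams(config.n_nodes, config.exponent, config.max_degree), rng
    )


_NAN_STATS = {
    "final_size": math.nan,
    "epidemic_length": math.nan,
    "peak_prevalence": math.nan,
    "peak_time": math.nan,
    "mean_internal_branch": math.nan,
    "mean_external_branch": math.nan,
    "mean_secondary": math.nan,
    "cherry_ratio": math.nan,
    "n_cherries": math.nan,
    "prop_giant_infected": math.nan,
    "index_node": math.nan,
}


def run_replicate(
    i: int,
    config: ExperimentConfig,
    seed_seq: np.random.SeedSequence,
    return_trees: bool = False,
):
    """Run one paired replicate; return two summary rows (hi and lo arm).

    With ``return_trees=True`` returns ``(rows, {"hi": tree, "lo": tree})``;
    the trees are ``None`` on a failed replicate.
    """
    ss_net, ss_hi, ss_lo, ss_epi = seed_seq.spawn(4)
    base = _sample_base_network(config, np.random.default_rng(ss_net))
    arms = {
        "hi": rewire_network(
            base,
            RewireConfig(config.theta_hi, config.decay, config.burnin),
            rng=np.random.default_rng(ss_hi),
        ),
        "lo": rewire_network(
            base,
            RewireConfig(config.theta_lo, config.decay, config.burnin),
            rng=np.random.default_rng(ss_lo),
        ),
    }
    rng_epi = np.random.default_rng(ss_epi)
    rows = []
    trees: dict[str, object | None] = {"hi": None, "lo": None}
    try:
        log_hi, log_lo = paired_epidemics(
            arms["hi"],
            arms["lo"],
            config.epidemic,
            rng_epi,
            max_attempts=config.max_attempts,
            index_redraws=config.index_redraws,
        )
        logs = {"hi": log_hi, "lo": log_lo}
        failed = False
    except PairingError:
        logs = {"hi": None, "lo": None}
        failed = True
    for arm, net in arms.items():
        giant = largest_component(net)
        row = {
            "replicate": i,
            "arm": arm,
            "failed": failed,
            "clustering": global_clustering(net),
            "n_edges": net.number_of_edges(),
            "giant_size": giant.number_of_nodes(),
        }
        if failed:
            row.update(_NAN_STATS)
        else:
            log = logs[arm]
            tree = build_tree(log)
            trees[arm] = tree
            curve = summarize_curve(log)
            tree_summary = summarize_tree(tree)
            row.update(
                index_node=log.index_node,
                final_size=curve.final_size,
                epidemic_length=curve.epidemic_length,
                peak_prevalence=curve.peak_prevalence,
                peak_time=curve.peak_time,
                mean_internal_branch=tree_summary.mean_internal_branch,
                mean_external_branch=tree_summary.mean_external_branch,
                mean_secondary=tree_summary.mean_secondary,
                cherry_ratio=tree_summary.cherry_ratio,
                n_cherries=tree_summary.n_cherries,
                prop_giant_infected=curve.final_size / giant.number_of_nodes(),
            )
        rows.append(row)
    if return_trees:
        return rows, trees
    return rows


def run_experiment(
    config: ExperimentConfig,
    outdir=None,
    save_trees: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """Run all replicates; return the paired summary table.

    When *outdir* is given, writes ``summaries_hi.csv``, ``summaries_lo.csv``,
    ``comparison.csv``, a config echo, the per-individual secondary- and
    descendant-count distributions in long format (``distributions.csv``),
    and (optionally) per-replicate Newick transmission trees.
    """
    master = np.random.SeedSequence(config.seed)
    substreams = master.spawn(config.n_replicates)
    rows = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        if save_trees:
            (out / "trees").mkdir(exist_ok=True)
    iterator = range(config.n_replicates)
    if progress:
        import tqdm  # optional nicety; not a package dependency

        iterator = tqdm.tqdm(iterator, desc="replicates")
    long_rows = []
    for i in iterator:
        replicate_rows, trees = run_replicate(
            i, config, substreams[i], return_trees=True
        )
        rows.extend(replicate_rows)
        for arm, tree in trees.items():
            if tree is None:
                continue
            if out is not None and save_trees:
                write_newick(tree, out / "trees" / f"rep{i:04d}_{arm}.nwk")
            if out is not None:
                summary = summarize_tree(tree)
                for u in summary.secondary_counts:
                    long_rows.append(
                        {
                            "replicate": i,
                            "arm": arm,
                            "individual": u,
                            "secondary_infections": summary.secondary_counts[u],
                            "infective_descendants": summary.descendant_counts[u],
                        }
                    )
    table = pd.DataFrame(rows)
    if out is not None:
        for arm in ("hi", "lo"):
            table[table["arm"] == arm].to_csv(
                out / f"summaries_{arm}.csv", index=False
            )
        compare_distributions(table).to_csv(out / "comparison.csv", index=False)
        pd.DataFrame(long_rows).to_csv(out / "distributions.csv", index=False)
    return table


def _range_overlap(lo1, hi1, lo2, hi2) -> float:
    union = max(hi1, hi2) - min(lo1, lo2)
    if union == 0.0:  # all four points coincide
        return 1.0
    intersection = max(0.0, min(hi1, hi2) - max(lo1, lo2))
    return intersection / union


def compare_distributions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-statistic arm comparison: means, ranges and range overlap.

    The overlap coefficient is ``|range intersection| / |range union|`` in
    [0, 1]; undefined entries (``NaN``, e.g. failed replicates or
    single-individual trees) are dropped per statistic before comparing.
    """
    ok = table[~table["failed"]]
    hi = ok[ok["arm"] == "hi"]
    lo = ok[ok["arm"] == "lo"]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need at least two successful replicates per arm")
    records = []
    for stat in STATISTICS:
        if stat not in table.columns:
            continue
        x = hi[stat].dropna()
        y = lo[stat].dropna()
        if x.empty or y.empty:
            continue
        records.append(
            {
                "statistic": stat,
                "hi_mean": x.mean(),
                "hi_min": x.min(),
                "hi_max": x.max(),
                "lo_mean": y.mean(),
                "lo_min": y.min(),
                "lo_max": y.max(),
                "range_overlap": _range_overlap(x.min(), x.max(), y.min(), y.max()),
            }
        )
    return pd.DataFrame.from_records(records)
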