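"""End-to-end experiment orchestration.

One call (or the ``run-all`` CLI subcommand) takes a cohort -- loaded
from a directory of matrices or generated synthetically -- through the
full procedure: consensus ladder, metastability profiles, DBC
selection, distance-dependent and consistency reference networks, and
the structural/dynamical comparison report.  Every stage writes its
outputs under the run directory and a manifest records every parameter
and derived seed, so re-running with the same config reproduces all
numeric outputs bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .connectome import (
    BinaryConnectome, Cohort, WeightedConnectome, binarize, density,
    read_connectome, read_node_table, write_matrix, write_node_table,
)
from .consensus import (
    build_ladder, consistency_consensus, distance_dependent_consensus,
    edge_prevalence, euclidean_distance_matrix, min_subject_count,
    prevalence_histogram,
)
from .dbc import select_dbc
from .kuramoto import CouplingGrid, SimulationConfig, metastability_profile
from .metrics import edge_lengths, global_metrics, nodal_metrics
from .stats import bonferroni, dynamical_anova, global_zscore, mean_ks
from .synthetic import CohortGenSpec, generate_cohort, manhattan_distance, nearest_member

__all__ = ["RunConfig", "run_pipeline", "load_cohort_dir", "write_cohort_dir"]

log = logging.getLogger("dynconsensus")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Exactly one of ``cohort_dir`` (directory of subject matrices plus a
    node TSV) or ``synthetic`` (generator parameters) supplies the
    cohort.  ``reference_thresholds`` are extra uniform-consensus
    networks carried into the comparison (they must sit on the ladder,
    i.e. be multiples of 100/n).  ``target_density`` of the consistency
    network defaults to the DBC's own density.
    """

    out_dir: str = "runs/run"
    cohort_dir: str | None = None
    synthetic: CohortGenSpec | None = None
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    grid: CouplingGrid = field(default_factory=CouplingGrid.default)
    n_bins: int = 41
    target_density: float | None = None
    cv_include_zeros: bool = True
    alpha: float = 0.01
    reference_thresholds: tuple = (62.5,)
    modularity_repeats: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort_dir is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of cohort_dir or synthetic")


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    """Counter-derived per-stage seeds, each below 2**31."""
    ss = np.random.SeedSequence(master)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_cohort_dir(path: Path, ground_truth, cohort, core_edges, spec) -> None:
    path.mkdir(parents=True, exist_ok=True)
    write_node_table(cohort.nodes, path / "nodes.tsv")
    write_matrix(ground_truth.adjacency, path / "ground_truth.txt")
    for k, m in enumerate(cohort):
        mat = m.adjacency if isinstance(m, BinaryConnectome) else m.weights
        write_matrix(mat, path / f"subject_{k:03d}.txt")
    pd.DataFrame(sorted(core_edges), columns=["i", "j"]).to_csv(
        path / "core_edges.tsv", sep="\t", index=False
    )
    spec_dict = {k: v for k, v in asdict(spec).items() if k != "seed_network"}
    (path / "cohortgen.json").write_text(json.dumps(spec_dict, indent=2))


def load_cohort_dir(path) -> Cohort:
    """Load ``subject_*.txt`` matrices plus ``nodes.tsv`` from a directory."""
    path = Path(path)
    node_path = path / "nodes.tsv"
    files = sorted(path.glob("subject_*.txt"))
    if not files:
        raise FileNotFoundError(f"no subject_*.txt matrices under {path}")
    members = [read_connectome(f, node_path) for f in files]
    return Cohort(members=members, nodes=members[0].nodes)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; return the run directory.

    Raises at the first failing stage; outputs of completed stages are
    left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.rng_seed)
    t0 = time.time()

    def stage(name):
        log.info("[%7.1fs] stage: %s", time.time() - t0, name)

    # --- stage 0: cohort ---------------------------------------------------
    stage("cohort")
    ground_truth = None
    if config.synthetic is not None:
        spec = config.synthetic
        spec.rng_seed = seeds[0] if spec.rng_seed == 0 else spec.rng_seed
        ground_truth, raw_cohort, core_edges = generate_cohort(spec)
        write_cohort_dir(out / "cohort", ground_truth, raw_cohort, core_edges, spec)
        weighted_cohort = None
        cohort = raw_cohort
    else:
        loaded = load_cohort_dir(config.cohort_dir)
        weighted_cohort = loaded
        cohort = Cohort(members=[binarize(m) for m in loaded], nodes=loaded.nodes)

    n = len(cohort)
    ladder_thresholds = {round(k * 100.0 / n, 9) for k in range(1, n + 1)}
    for t in config.reference_thresholds:
        if round(t, 9) not in ladder_thresholds:
            raise ValueError(
                f"reference threshold {t}% is not a multiple of 100/{n}"
            )

    # --- stage 1: ladder and prevalence ------------------------------------
    stage("ladder")
    ladder = build_ladder(cohort)
    prev = edge_prevalence(cohort)
    hist = prevalence_histogram(prev, n)
    (out / "groups").mkdir(exist_ok=True)
    pd.DataFrame(
        {"prevalence_count": np.arange(n + 1), "fraction_of_pairs": hist}
    ).to_csv(out / "groups" / "edge_prevalence_histogram.tsv", sep="\t", index=False)
    for t in ladder:
        write_matrix(ladder[t].adjacency, out / "groups" / f"consensus_{t:g}.txt")

    # --- stage 2: profiles and DBC selection --------------------------------
    stage("profiles+dbc")
    sim = SimulationConfig(
        total_time=config.sim.total_time,
        transient_time=config.sim.transient_time,
        dt=config.sim.dt,
        mean_frequency=config.sim.mean_frequency,
        frequency_sd=config.sim.frequency_sd,
        n_realisations=config.sim.n_realisations,
        rng_seed=seeds[1] if config.sim.rng_seed == 0 else config.sim.rng_seed,
    )
    subject_profiles = [
        metastability_profile(m, config.grid, sim) for m in cohort
    ]
    selection = select_dbc(ladder, subject_profiles, config.grid, sim)
    dbc = selection.dbc_network
    pd.DataFrame(
        {
            "threshold_pct": list(selection.mse),
            "mse": list(selection.mse.values()),
        }
    ).to_csv(out / "mse.tsv", sep="\t", index=False)
    write_matrix(dbc.adjacency, out / "dbc.txt")
    prof_df = pd.DataFrame(
        {"K": config.grid.values,
         "subject_mean": selection.subject_mean_profile,
         "subject_sd": selection.subject_sd_profile,
         "dbc": selection.ladder_profiles[selection.dbc_threshold].values}
    )
    prof_df.to_csv(out / "profiles.tsv", sep="\t", index=False)

    summary = {
        "dbc_threshold_pct": selection.dbc_threshold,
        "dbc_min_subject_count": min_subject_count(selection.dbc_threshold, n),
        "dbc_density": density(dbc),
        "min_mse": selection.min_mse,
        "n_subjects": n,
        "n_nodes": cohort.nodes.n_nodes,
        "seeds": seeds,
    }
    if ground_truth is not None:
        (best_idx, best_dist), table = nearest_member(
            dbc, [ground_truth] + list(cohort)
        )
        summary["dbc_to_ground_truth_manhattan"] = manhattan_distance(dbc, ground_truth)
        summary["nearest_is_ground_truth"] = best_idx == 0
        summary["nearest_distance"] = best_dist
    (out / "dbc_summary.json").write_text(json.dumps(_jsonable(summary), indent=2))

    # --- stage 3: reference group networks ----------------------------------
    stage("reference builders")
    dist_mat = euclidean_distance_matrix(cohort.nodes)
    ddc = distance_dependent_consensus(cohort, dist_mat, n_bins=config.n_bins)
    write_matrix(ddc.adjacency, out / "groups" / "distance_dependent.txt")

    target = config.target_density if config.target_density is not None else density(dbc)
    if weighted_cohort is None:
        # no streamline weights available: use the binary adjacencies as
        # weights, for which CV ranking reduces to prevalence ranking
        weighted_cohort = Cohort(
            members=[
                WeightedConnectome(weights=m.adjacency.astype(float), nodes=m.nodes)
                for m in cohort
            ],
            nodes=cohort.nodes,
        )
    cons = consistency_consensus(
        weighted_cohort, target, cv_include_zeros=config.cv_include_zeros
    )
    write_matrix(cons.adjacency, out / "groups" / "consistency.txt")

    group_nets = {"dbc": dbc}
    for t in config.reference_thresholds:
        group_nets[f"consensus_{t:g}"] = ladder[
            min(ladder, key=lambda x: abs(x - t))
        ]
    group_nets["distance_dependent"] = ddc
    group_nets["consistency"] = cons

    # --- stage 4: comparison report -----------------------------------------
    stage("comparison")
    report = {"groups": list(group_nets), "alpha": config.alpha}

    group_profiles = []
    for name, net in group_nets.items():
        if name == "dbc":
            group_profiles.append(selection.ladder_profiles[selection.dbc_threshold])
        elif name.startswith("consensus_"):
            t = min(ladder, key=lambda x: abs(x - float(name.split("_")[1])))
            group_profiles.append(selection.ladder_profiles[t])
        else:
            group_profiles.append(metastability_profile(net, config.grid, sim))
    report["dynamical"] = _jsonable(
        {
            k: v
            for k, v in dynamical_anova(
                list(group_nets.values()),
                subject_profiles,
                config.grid,
                sim,
                group_profiles=group_profiles,
                alpha=config.alpha,
            ).items()
            if k != "distances"
        }
    )

    subj_nodal = [nodal_metrics(m) for m in cohort]
    nodal_rows = []
    for name, net in group_nets.items():
        gm = nodal_metrics(net)
        for metric in ("degree", "clustering", "betweenness", "eigenvector"):
            mks, sks = mean_ks(
                gm.as_dict()[metric], [s.as_dict()[metric] for s in subj_nodal]
            )
            nodal_rows.append(
                {"group": name, "metric": metric, "mean_ks": mks, "sd_ks": sks}
            )
    pd.DataFrame(nodal_rows).to_csv(out / "nodal_ks.tsv", sep="\t", index=False)
    report["nodal_ks"] = _jsonable(nodal_rows)

    subj_global = [
        global_metrics(m, config.modularity_repeats, rng_seed=seeds[2])
        for m in cohort
    ]
    global_rows = []
    for name, net in group_nets.items():
        gg = global_metrics(net, config.modularity_repeats, rng_seed=seeds[2])
        for metric, val in gg.as_dict().items():
            z = global_zscore(val, [s.as_dict()[metric] for s in subj_global])
            global_rows.append(
                {"group": name, "metric": metric, "value": val, "zscore": z}
            )
    pd.DataFrame(global_rows).to_csv(out / "global_z.tsv", sep="\t", index=False)
    report["global_z"] = _jsonable(global_rows)

    subj_lengths = [edge_lengths(m, dist_mat) for m in cohort]
    pooled = np.concatenate(subj_lengths)
    length_rows = []
    from scipy.stats import ks_2samp

    for name, net in group_nets.items():
        gl = edge_lengths(net, dist_mat)
        mks, sks = mean_ks(gl, subj_lengths)
        length_rows.append(
            {
                "group": name,
                "mean_ks": mks,
                "sd_ks": sks,
                "pooled_ks": float(ks_2samp(gl, pooled).statistic),
            }
        )
    pd.DataFrame(length_rows).to_csv(out / "edge_length_ks.tsv", sep="\t", index=False)
    report["edge_length_ks"] = _jsonable(length_rows)

    (out / "comparison.json").write_text(json.dumps(_jsonable(report), indent=2))

    # --- manifest ------------------------------------------------------------
    manifest = {
        "package_version": _pkg_version,
        "rng_seed": config.rng_seed,
        "stage_seeds": seeds,
        "sim": asdict(sim),
        "grid": config.grid.values.tolist(),
        "n_bins": config.n_bins,
        "target_density": target,
        "cv_include_zeros": config.cv_include_zeros,
        "alpha": config.alpha,
        "reference_thresholds": list(config.reference_thresholds),
        "modularity_repeats": config.modularity_repeats,
        "paired_seeds": True,
        "n_subjects": n,
        "n_nodes": cohort.nodes.n_nodes,
        "dbc_threshold_pct": selection.dbc_threshold,
    }
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    stage("done")
    return out
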