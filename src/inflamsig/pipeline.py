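"""End-to-end orchestration: simulate -> regress -> domains -> cluster ->
sam -> network -> kinetics, driven by one config and one master seed.

Every stage consumes and produces plain TSV files in the output directory,
so any stage can be re-run standalone with identical results.  Per-stage
randomness is derived from the master seed by stable hashing of the stage
name, so adding a stage never perturbs earlier stages' streams.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from ._rng import derive_seed
from .clustering import gap_statistic, hierarchical_cluster, hypergeom_enrichment
from .datasets import CohortDataset, znormalize_within_cohort
from .domains import assign_domains, domain_overlap, shared_effect_table
from .kinetics import group_comparisons, trajectory_summary
from .network import (
    build_network,
    category_enrichment,
    classify_roles,
    detect_communities,
    node_centralities,
    robustness_test,
    spearman_matrix,
    topology_over_time,
)
from .regression import PermutationRegression
from .sam import PairedSAM, paired_differences

__all__ = ["default_config", "load_config", "run_pipeline", "STAGES"]

STAGES = ["simulate", "regress", "domains", "cluster", "sam", "network", "kinetics"]

_FLOAT_FMT = "%.10g"


def default_config() -> dict:
    """Pipeline defaults; stage parameters follow the study's stated values."""
    return {
        "seed": 0,
        "simulate": {
            "noise_sd": 1.0,
            "loading": 0.8,
            "improve_delta": 1.5,
            "pulse_amplitude": 1.0,
            "vl0": 1.0e6,
            "decay_rate": 2.0,
        },
        "regression": {"n_perm": 1000, "fdr": 0.2, "scheme": "covariate"},
        "cluster": {"kmax": 8, "B": 100, "metric": "euclidean", "method": "average"},
        "sam": {"n_perm": 1000, "fdr": 0.01},
        "network": {
            "threshold": 0.5,
            "n_perm": 10000,
            "timepoints": ["pre", "wk4", "post"],
            "top_fraction": 0.2,
            "resolution": 1.0,
            "n_restarts": 10,
        },
        "kinetics": {"stimulus": "IFNa", "param": "pSTAT1"},
    }


def load_config(path: str | Path | None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
    return path


# --------------------------------------------------------------------- #
# Stages


def stage_simulate(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    p = cfg["simulate"]
    subjects = sim.generate_subjects(seed=derive_seed(seed, "subjects"))
    panel = sim.generate_panel()
    effects = sim.default_effects(panel)
    comm = sim.default_community_spec(panel, loading=p["loading"])
    cross = sim.simulate_measurements(
        subjects,
        panel,
        effects,
        community_spec=comm,
        noise_sd=p["noise_sd"],
        seed=derive_seed(seed, "cross"),
    )
    spec = sim.LongitudinalSpec(
        vl0=p["vl0"],
        decay_rate=p["decay_rate"],
        pulse_amplitude=p["pulse_amplitude"],
        improve_delta=p["improve_delta"],
        improve_features=sim.default_improve_features(panel),
    )
    longi = sim.simulate_longitudinal_hcv(
        subjects,
        panel,
        spec=spec,
        community_spec=comm,
        noise_sd=p["noise_sd"],
        seed=derive_seed(seed, "longitudinal"),
    )
    files = list(cross.to_tsv(outdir).values())
    files += list(longi.to_tsv(outdir / "longitudinal").values())
    truth = pd.DataFrame(
        [
            {"feature_id": e.feature_id, "driver": e.driver, "beta": e.beta}
            for e in effects
        ]
    )
    improve = pd.DataFrame({"feature_id": spec.improve_features})
    files.append(_write(truth, outdir / "truth.tsv"))
    files.append(_write(improve, outdir / "truth_improve.tsv"))
    return files


def stage_regress(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    p = cfg["regression"]
    ds = CohortDataset.from_tsv(outdir)
    model = PermutationRegression(ds, scheme=p["scheme"])
    res = model.fit(
        n_perm=p["n_perm"],
        seed=derive_seed(seed, "regress"),
        fdr_threshold=p["fdr"],
    )
    res.to_tsv(outdir / "regression_results.tsv")
    return [outdir / "regression_results.tsv"]


def stage_domains(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    ds = CohortDataset.from_tsv(outdir)
    results = pd.read_csv(outdir / "regression_results.tsv", sep="\t")
    domains = assign_domains(ds.features)
    dom_of = dict(zip(domains["feature_id"], domains["domain"]))
    sig_domains = {}
    for driver, cohort in (("age", "aging"), ("hiv", "hiv"), ("hcv", "hcv")):
        sel = results[
            (results["cohort"] == cohort)
            & (results["covariate"] == driver)
            & results["significant"]
        ]
        sig_domains[cohort] = {dom_of[f] for f in sel["feature_id"]}
    overlap = domain_overlap(sig_domains)
    shared = set(overlap.regions["all_three"])
    shared_fx = shared_effect_table(results, domains, shared)
    files = [
        _write(domains, outdir / "domains.tsv"),
        _write(overlap.to_frame(), outdir / "overlap.tsv"),
        _write(shared_fx, outdir / "shared_effects.tsv"),
    ]
    return files


def stage_cluster(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    p = cfg["cluster"]
    ds = CohortDataset.from_tsv(outdir)
    hcv = ds.subset_samples((ds.subjects["cohort"] == "hcv").to_numpy())
    base_ids = hcv.features.loc[
        hcv.features["modality"] == "baseline_signaling", "feature_id"
    ]
    hcv = znormalize_within_cohort(hcv)
    X = hcv.measurements[base_ids].to_numpy()
    kmax = min(p["kmax"], len(X) - 1)
    curve = gap_statistic(
        X,
        kmax=kmax,
        B=p["B"],
        seed=derive_seed(seed, "gap"),
        metric=p["metric"],
        method=p["method"],
    )
    tree = hierarchical_cluster(X, metric=p["metric"], method=p["method"])
    labels = tree.labels_at_k(max(curve.chosen_k, 2))
    clusters = pd.DataFrame(
        {"sample_id": hcv.subjects["sample_id"], "cluster": labels}
    )
    enrich = hypergeom_enrichment(hcv.subjects["group"].to_numpy(), labels)
    return [
        _write(clusters, outdir / "clusters.tsv"),
        _write(curve.to_frame(), outdir / "gap.tsv"),
        _write(enrich, outdir / "cluster_enrichment.tsv"),
    ]


def stage_sam(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    p = cfg["sam"]
    longi = CohortDataset.from_tsv(outdir / "longitudinal")
    paired = paired_differences(longi, pre="pre", post="post")
    res = PairedSAM(paired).fit(
        n_perm=p["n_perm"],
        seed=derive_seed(seed, "sam"),
        fdr_threshold=p["fdr"],
    )
    return [
        _write(res.frame, outdir / "sam_results.tsv"),
        _write(res.fdr_table, outdir / "sam_fdr.tsv"),
    ]


def stage_network(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    p = cfg["network"]
    longi = CohortDataset.from_tsv(outdir / "longitudinal")
    base = longi.features[longi.features["modality"] == "baseline_signaling"]
    node_attrs = base.set_index("feature_id")[
        ["cell_type", "signaling_param", "pathway"]
    ]
    files: list[Path] = []
    networks, corrs, node_rows = {}, {}, []
    for tp in p["timepoints"]:
        at_tp = longi.at_timepoint(tp).measurements[base["feature_id"]]
        corr = spearman_matrix(at_tp)
        net = build_network(
            corr, threshold=p["threshold"], timepoint=tp, node_attrs=node_attrs
        )
        node_centralities(net)
        classify_roles(net, fraction=p["top_fraction"])
        comm_table = detect_communities(
            net,
            resolution=p["resolution"],
            n_restarts=p["n_restarts"],
            seed=derive_seed(seed, "louvain", tp),
        )
        corrs[tp] = corr
        networks[tp] = net
        gpath = outdir / f"network_{tp}.graphml"
        net.to_graphml(gpath)
        files.append(gpath)
        files.append(
            _write(
                comm_table.attrs["composition"], outdir / f"communities_{tp}.tsv"
            )
        )
        tbl = net.nodes_table
        tbl.insert(0, "timepoint", tp)
        node_rows.append(tbl)
        hubs = {
            v for v in net.graph.nodes if net.graph.nodes[v]["role"].startswith("H")
        }
        if hubs:
            enr = category_enrichment(
                net, dict(zip(base["feature_id"], base["signaling_param"])), hubs
            )
            enr.insert(0, "timepoint", tp)
            enr.insert(1, "subset", "hubs")
            files.append(_write(enr, outdir / f"hub_enrichment_{tp}.tsv"))
    files.append(_write(pd.concat(node_rows), outdir / "network_nodes.tsv"))
    report = robustness_test(
        corrs, n_perm=p["n_perm"], seed=derive_seed(seed, "robustness")
    )
    files.append(_write(report.frame, outdir / "robustness.tsv"))
    summary, tests = topology_over_time(networks)
    files.append(_write(summary, outdir / "topology_summary.tsv"))
    files.append(_write(tests, outdir / "topology_tests.tsv"))
    return files


def stage_kinetics(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    p = cfg["kinetics"]
    longi = CohortDataset.from_tsv(outdir / "longitudinal")
    feats = longi.features
    resp_ids = feats[
        (feats["modality"] == "stim_response")
        & (feats["stimulus"] == p["stimulus"])
        & (feats["signaling_param"] == p["param"])
    ]
    long_rows = []
    for _, f in resp_ids.iterrows():
        vals = longi.measurements[f["feature_id"]]
        for sid, v in vals.items():
            srow = longi.subjects[longi.subjects["sample_id"] == sid].iloc[0]
            long_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": srow["subject_id"],
                    "timepoint": srow["timepoint"],
                    "cell_type": f["cell_type"],
                    "stimulus": p["stimulus"],
                    "signaling_param": p["param"],
                    "response": float(v),
                }
            )
    responses = pd.DataFrame(long_rows)
    traj = trajectory_summary(responses)
    paired = {}
    for cell, grp in responses.groupby("cell_type"):
        pre = grp[grp["timepoint"] == "pre"].sort_values("subject_id")["response"]
        post = grp[grp["timepoint"] == "post"].sort_values("subject_id")["response"]
        paired[f"{cell}: pre vs post"] = (pre.to_numpy(), post.to_numpy())
    tests = group_comparisons(paired=paired)
    return [
        _write(responses, outdir / "responses.tsv"),
        _write(traj, outdir / "trajectories.tsv"),
        _write(tests, outdir / "group_tests.tsv"),
    ]


_STAGE_FN = {
    "simulate": stage_simulate,
    "regress": stage_regress,
    "domains": stage_domains,
    "cluster": stage_cluster,
    "sam": stage_sam,
    "network": stage_network,
    "kinetics": stage_kinetics,
}


def run_pipeline(
    cfg: dict | None = None,
    outdir: str | Path = "results",
    seed: int | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Run the configured stages in order and write a run manifest.

    Returns the manifest dict.  ``seed`` overrides the config's seed.
    """
    cfg = copy.deepcopy(cfg) if cfg is not None else default_config()
    if seed is not None:
        cfg["seed"] = int(seed)
    master = int(cfg.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": master,
        "stages": {},
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        try:
            files = _STAGE_FN[stage](cfg, outdir, master)
        except FileNotFoundError as err:
            raise RuntimeError(f"stage {stage!r} failed: missing input ({err})")
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        manifest["stages"][stage] = {
            "outputs": [str(f.relative_to(outdir)) for f in files],
            "seconds": round(time.perf_counter() - t0, 3),
        }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
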