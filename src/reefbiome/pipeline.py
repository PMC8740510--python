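"""End-to-end orchestration: seeded stages, artifacts, and a run report.

Each stage reads its inputs from the output directory (or the configured
input paths), writes plain-text artifacts, and is individually reproducible:
all randomness flows from the root seed through named per-stage substreams.
The run report (``run_report.json``) is deterministic; wall-clock timings go
to ``run.log`` so that re-running an identical config diffs empty on every
numeric output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import alpha as alpha_mod
from . import beta as beta_mod
from . import envassoc, network as net_mod, synthetic
from .tables import (DistanceMatrix, SampleFrame, ValidationError,
                     export_network, read_design, read_edge_tsv, read_env,
                     read_otu_table, write_design, write_env, write_newick,
                     write_otu_table)

__all__ = ["default_config", "load_config", "stage_seed", "run_pipeline",
           "STAGES"]

DEFAULT_THRESHOLDS = {
    "network_r": 0.8,
    "network_p": 0.001,
    "min_prevalence": 0.5,
    "network_min_abund": 0.0001,   # preset "broad"; 0.005 mirrors the 0.5% wording
    "abundant_min_abund": 0.005,
    "keystone_top_n": 10,
    "keystone_min_abund": 0.001,
}


def default_config(seed: int = 1, output_dir: str = "reefbiome_out") -> dict:
    return {
        "seed": seed,
        "output_dir": output_dir,
        "simulate": {},  # GeneratorParams overrides; remove to use input paths
        "inputs": None,  # {otu_table, format, design, env_water, env_sediment}
        "subsets": ["total", "water", "sediment"],
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "n_permutations": 999,
    }


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    merged = default_config()
    merged.update(cfg or {})
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update((cfg or {}).get("thresholds") or {})
    merged["thresholds"] = thr
    if merged.get("seed") is None:
        raise ValidationError("config must set a seed")
    if not (0 < thr["network_r"] <= 1):
        raise ValidationError("network_r must be in (0, 1]")
    if not (0 < thr["network_p"] <= 1):
        raise ValidationError("network_p must be in (0, 1]")
    if not (0 <= thr["min_prevalence"] < 1):
        raise ValidationError("min_prevalence must be in [0, 1)")
    for key in ("network_min_abund", "abundant_min_abund", "keystone_min_abund"):
        if not (0 <= thr[key] < 1):
            raise ValidationError(f"{key} must be in [0, 1)")
    if merged["n_permutations"] < 1:
        raise ValidationError("n_permutations must be >= 1")
    bad = set(merged["subsets"]) - {"total", "water", "sediment"}
    if bad:
        raise ValidationError(f"unknown subsets: {sorted(bad)}")
    return merged


def stage_seed(root_seed: int, stage: str) -> int:
    """Named deterministic substream seed, kept below 2**31."""
    return (int(root_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(outdir: Path, name: str, producer: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise ValidationError(
            f"missing artifact {name!r}; run the {producer!r} stage first")
    return p


def _load_core(cfg, outdir: Path):
    table = read_otu_table(_require(outdir, "otu_table.tsv", "simulate"), "tsv")
    design = read_design(_require(outdir, "design.tsv", "simulate"))
    return table, design


def _subset_table(table, design, subset):
    if subset == "total":
        return table
    frame = design.aligned_to(table.sample_ids)
    keep = [s for s, h in frame["habitat"].items() if h == subset]
    return table.select_samples(keep)


# ---------------------------------------------------------------------------
# Stages


def run_simulate(cfg, outdir: Path):
    sim = cfg.get("simulate")
    if sim is None and cfg.get("inputs"):
        inputs = cfg["inputs"]
        table = read_otu_table(inputs["otu_table"], inputs.get("format", "tsv"))
        design = read_design(inputs["design"])
        write_otu_table(table, outdir / "otu_table.tsv", "tsv")
        write_design(design, outdir / "design.tsv")
        for h in ("water", "sediment"):
            key = f"env_{h}"
            if inputs.get(key):
                write_env(read_env(inputs[key]), outdir / f"env_{h}.tsv")
        return
    params = synthetic.GeneratorParams(**(sim or {}))
    seed = stage_seed(cfg["seed"], "simulate")
    table, design, env, truth = synthetic.generate_dataset(params, seed=seed)
    write_otu_table(table, outdir / "otu_table.tsv", "tsv")
    write_design(design, outdir / "design.tsv")
    for h, e in env.items():
        write_env(e, outdir / f"env_{h}.tsv")
    synthetic.write_truth(truth, outdir / "truth.tsv", outdir / "truth.json")
    with open(outdir / "generator_params.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(params) | {"stage_seed": seed}, fh, indent=1)


def run_alpha(cfg, outdir: Path):
    table, design = _load_core(cfg, outdir)
    frame = design.aligned_to(table.sample_ids)
    records = alpha_mod.alpha_table(table)
    merged = records.join(frame[["habitat", "season", "area"]])
    merged.to_csv(outdir / "alpha_per_sample.tsv", sep="\t")
    indices = ["observed_otus", "shannon", "simpson", "ace", "chao1", "coverage"]
    summary = merged.groupby(["season", "habitat"], sort=False)[indices].mean()
    summary = summary.reindex(
        pd.MultiIndex.from_product(
            [[s for s in ("spring", "summer", "autumn", "winter")
              if s in set(frame["season"])],
             [h for h in ("water", "sediment") if h in set(frame["habitat"])]],
            names=["season", "habitat"]))
    summary.to_csv(outdir / "alpha_summary.tsv", sep="\t", float_format="%.6g")
    rows = []
    for idx in indices:
        for habitat, sub in merged.groupby("habitat", sort=False):
            try:
                h_stat, p = alpha_mod.kruskal_wallis(
                    sub[idx].to_numpy(), sub["season"].to_numpy())
                letters = alpha_mod.group_letters(
                    sub[idx].to_numpy(), sub["season"].to_numpy())
            except ValueError:
                continue
            rows.append({"index": idx, "habitat": habitat,
                         "kw_H": h_stat, "kw_p": p,
                         **{f"letter_{s}": letters.get(s, "")
                            for s in ("spring", "summer", "autumn", "winter")}})
        if merged["habitat"].nunique() == 2:
            h_stat, p = alpha_mod.kruskal_wallis(
                merged[idx].to_numpy(), merged["habitat"].to_numpy())
            rows.append({"index": idx, "habitat": "water-vs-sediment",
                         "kw_H": h_stat, "kw_p": p})
    pd.DataFrame(rows).to_csv(outdir / "alpha_tests.tsv", sep="\t", index=False,
                              float_format="%.6g")


_TERMS = {
    "total": ["habitat", "season", "area", "habitat x season",
              "habitat x area", "season x area", "habitat x season x area"],
    "water": ["season", "area", "season x area"],
    "sediment": ["season", "area", "season x area"],
}
_ANOSIM_FACTORS = {
    "total": ["habitat", "season", "area"],
    "water": ["season", "area"],
    "sediment": ["season", "area"],
}


def run_beta(cfg, outdir: Path):
    table, design = _load_core(cfg, outdir)
    n_perm = cfg["n_permutations"]
    for subset in cfg["subsets"]:
        sub = _subset_table(table, design, subset)
        dm = beta_mod.bray_curtis(sub)
        pd.DataFrame(dm.d, index=dm.sample_ids, columns=dm.sample_ids).to_csv(
            outdir / f"bray_curtis_{subset}.tsv", sep="\t", float_format="%.10g")
        ord_res = beta_mod.pcoa(dm, n_axes=2)
        coords = pd.DataFrame(ord_res.coordinates, index=ord_res.sample_ids,
                              columns=[f"PCo{i+1}"
                                       for i in range(ord_res.coordinates.shape[1])])
        coords.to_csv(outdir / f"pcoa_{subset}.tsv", sep="\t",
                      float_format="%.10g")
        frame = design.aligned_to(dm.sample_ids)
        perm = beta_mod.permanova(
            dm, design, _TERMS[subset], n_perm=n_perm,
            seed=stage_seed(cfg["seed"], f"permanova:{subset}"))
        perm.to_frame().to_csv(outdir / f"permanova_{subset}.tsv", sep="\t",
                               float_format="%.6g")
        rows = []
        for factor in _ANOSIM_FACTORS[subset]:
            res = beta_mod.anosim(
                dm, frame[factor].to_numpy(), n_perm=n_perm,
                seed=stage_seed(cfg["seed"], f"anosim:{subset}:{factor}"))
            rows.append({"factor": factor, "R": res.r, "P": res.p})
        pd.DataFrame(rows).to_csv(outdir / f"anosim_{subset}.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        tree = beta_mod.hierarchical_cluster(dm)
        write_newick(tree, outdir / f"upgma_{subset}.nwk")


def run_envcorr(cfg, outdir: Path):
    table, design = _load_core(cfg, outdir)
    thr = cfg["thresholds"]
    n_perm = cfg["n_permutations"]
    for habitat in ("water", "sediment"):
        if habitat not in cfg["subsets"] and "total" not in cfg["subsets"]:
            continue
        env_path = outdir / f"env_{habitat}.tsv"
        if not env_path.exists():
            continue
        env = read_env(env_path)
        sub = _subset_table(table, design, habitat)
        sub = sub.select_samples([s for s in sub.sample_ids
                                  if s in set(env.sample_ids)])
        abundant = envassoc.abundant_otus(sub, thr["abundant_min_abund"])
        if abundant.n_otus:
            grid = envassoc.spearman_grid(abundant, env)
            rho, p = grid.to_frames()
            stars = pd.DataFrame(grid.stars(), index=grid.otu_ids,
                                 columns=grid.factor_names)
            wide = pd.concat({"rho": rho, "p": p, "stars": stars}, axis=1)
            wide.to_csv(outdir / f"spearman_grid_{habitat}.tsv", sep="\t",
                        float_format="%.6g")
        dm = beta_mod.bray_curtis(sub).reorder(env.sample_ids)
        rows = []
        total_d = envassoc.env_distance(env)
        res = envassoc.mantel(dm, total_d, n_perm=n_perm,
                              seed=stage_seed(cfg["seed"], f"mantel:{habitat}:Total"))
        rows.append({"factor": "Total", "r": res.r, "P": res.p,
                     "partial_r": np.nan, "partial_P": np.nan})
        for fac in env.factor_names:
            d_f = envassoc.env_distance(env, [fac])
            res = envassoc.mantel(
                dm, d_f, n_perm=n_perm,
                seed=stage_seed(cfg["seed"], f"mantel:{habitat}:{fac}"))
            others = [f for f in env.factor_names if f != fac]
            try:
                pres = envassoc.partial_mantel(
                    dm, d_f, envassoc.env_distance(env, others), n_perm=n_perm,
                    seed=stage_seed(cfg["seed"], f"pmantel:{habitat}:{fac}"))
                pr, pp = pres.r, pres.p
            except ValueError:
                pr, pp = np.nan, np.nan
            rows.append({"factor": fac, "r": res.r, "P": res.p,
                         "partial_r": pr, "partial_P": pp})
        pd.DataFrame(rows).to_csv(outdir / f"mantel_{habitat}.tsv", sep="\t",
                                  index=False, float_format="%.6g")


def run_network(cfg, outdir: Path):
    table, design = _load_core(cfg, outdir)
    thr = cfg["thresholds"]
    summaries = {}
    for subset in cfg["subsets"]:
        sub = _subset_table(table, design, subset)
        filtered = net_mod.filter_network_otus(
            sub, thr["min_prevalence"], thr["network_min_abund"])
        net = net_mod.build_network(filtered, thr["network_r"], thr["network_p"])
        export_network(net, outdir / f"network_{subset}.edges.tsv", "edge-tsv")
        export_network(net, outdir / f"network_{subset}.sif", "sif")
        export_network(net, outdir / f"network_{subset}.graphml", "graphml")
        summaries[subset] = net_mod.network_summary(net)
    meta = {"thresholds": thr, "summaries": summaries,
            "note": "keystone selection order: abundance floor first, then top_n"}
    with open(outdir / "network_summary.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, default=str)


def run_keystone(cfg, outdir: Path):
    thr = cfg["thresholds"]
    nodes = {}
    for subset in cfg["subsets"]:
        edge_path = _require(outdir, f"network_{subset}.edges.tsv", "network")
        g = read_edge_tsv(edge_path)
        attr_path = Path(str(edge_path) + ".nodes.tsv")
        attrs = pd.read_csv(attr_path, sep="\t", index_col=0) \
            if attr_path.exists() else pd.DataFrame()
        for node in g.nodes():
            if node in attrs.index:
                g.nodes[node]["mean_rel_abund"] = float(
                    attrs.loc[node, "mean_rel_abund"])
                g.nodes[node]["phylum"] = str(attrs.loc[node, "phylum"])
        net = net_mod.CooccurrenceNetwork(
            graph=g, r_threshold=thr["network_r"], p_threshold=thr["network_p"])
        topo = net_mod.keystoneness(net_mod.compute_topology(net))
        net_mod.topology_frame(topo).to_csv(
            outdir / f"topology_{subset}.tsv", sep="\t", float_format="%.10g")
        for t in topo:  # re-export with full node attributes for Cytoscape
            g.nodes[t.otu_id].update(
                degree=t.degree, betweenness=t.betweenness,
                closeness=t.closeness, keystoneness=t.keystoneness)
        export_network(net, outdir / f"network_{subset}.graphml", "graphml")
        keys = net_mod.identify_keystones(
            net, topo, thr["keystone_top_n"], thr["keystone_min_abund"])
        pd.DataFrame([dataclasses.asdict(k) for k in keys]).to_csv(
            outdir / f"keystones_{subset}.tsv", sep="\t", index=False,
            float_format="%.10g")
        nodes[subset] = set(g.nodes())
    subsets = list(cfg["subsets"])
    jac = pd.DataFrame(
        [[net_mod.jaccard_index(nodes[a], nodes[b]) for b in subsets]
         for a in subsets], index=subsets, columns=subsets)
    jac.to_csv(outdir / "network_jaccard.tsv", sep="\t", float_format="%.6g")


STAGES = {
    "simulate": run_simulate,
    "alpha": run_alpha,
    "beta": run_beta,
    "envcorr": run_envcorr,
    "network": run_network,
    "keystone": run_keystone,
}


def run_pipeline(cfg: dict, outdir=None) -> dict:
    """Run every stage in order; write run.log and a deterministic report."""
    cfg = validate_config(cfg)
    outdir = Path(outdir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []
    failed = None
    for name, stage in STAGES.items():
        t0 = time.perf_counter()
        try:
            stage(cfg, outdir)
        except Exception as e:
            failed = (name, str(e))
            (outdir / "FAILED").write_text(f"stage {name}: {e}\n")
            log_lines.append(f"stage={name} status=failed error={e}")
            break
        dt = time.perf_counter() - t0
        log_lines.append(f"stage={name} status=ok wall_s={dt:.3f}")
    artifacts = sorted(p.name for p in outdir.iterdir()
                       if p.is_file() and p.name not in ("run.log",
                                                         "run_report.json"))
    checksums = {name: _sha256(outdir / name) for name in artifacts}
    for name in artifacts:
        log_lines.append(f"artifact={name} sha256={checksums[name]}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    report = {
        # output_dir is where the run landed, not a parameter of it
        "config": {k: v for k, v in cfg.items() if k != "output_dir"},
        "seed": cfg["seed"],
        "versions": {"reefbiome": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "stages": [name for name in STAGES],
        "failed_stage": failed[0] if failed else None,
        "artifacts": checksums,
    }
    with open(outdir / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    if failed:
        raise RuntimeError(f"pipeline failed at stage {failed[0]}: {failed[1]}")
    return report
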