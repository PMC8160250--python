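"""End-to-end pipeline driver.

Runs the configured stages — simulate (or read) expression, confound
adjustment, per-tissue network construction, community detection, multiplex
analysis, embedding persistence, tissue prediction, gene-set enrichment, and
community-conditional p-value statistics — and writes a provenance manifest
(package version, parameters, seeds, content hashes of every output) so a
rerun with the same configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import coexatlas
from coexatlas import adjust as adjust_mod
from coexatlas import coexpression, communities, enrichment, multiplex
from coexatlas import persistence as persistence_mod
from coexatlas import prediction as prediction_mod
from coexatlas import twas as twas_mod
from coexatlas.io import ExpressionMatrix, build_master_matrix, read_expression, \
    read_gmt, write_expression
from coexatlas.simulate import Confounder, PlantedBlock, SimConfig, \
    generate_expression, generate_pvalues

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config_from_dict(cfg: dict, seed: int) -> SimConfig:
    blocks = []
    for blk in cfg.get("blocks", []):
        genes = tuple(blk["genes"])
        loadings = blk.get("loadings", 0.95)
        if np.isscalar(loadings):
            loadings = tuple(float(loadings) for _ in genes)
        else:
            loadings = tuple(float(b) for b in loadings)
        blocks.append(PlantedBlock(genes=genes, loadings=loadings,
                                   tissues=tuple(blk["tissues"])))
    confs = [Confounder(name=c["name"], effects=tuple(c["effects"]),
                        distribution=c.get("distribution", "normal"))
             for c in cfg.get("confounders", [])]
    return SimConfig(
        n_tissues=cfg["n_tissues"],
        samples_per_tissue=cfg["samples_per_tissue"],
        n_genes=cfg["n_genes"],
        planted_blocks=blocks,
        tissue_effect_sd=cfg.get("tissue_effect_sd", 1.0),
        noise_sd=cfg.get("noise_sd", 0.31),
        confounders=confs,
        seed=cfg.get("seed", seed),
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the provenance manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config.get("out_dir", "coexatlas_out"))
    seed = int(config.get("seed", 0))

    # validate inputs before any stage runs
    if "simulate" not in config and "expression" not in config:
        raise ValueError("config must provide either 'simulate' or "
                         "'expression' inputs")
    for p in config.get("expression", []):
        if not Path(p).exists():
            raise FileNotFoundError(f"expression input not found: {p}")
    gmt_path = config.get("enrich", {}).get("gmt")
    if gmt_path and not Path(gmt_path).exists():
        raise FileNotFoundError(f"gene-set collection not found: {gmt_path}")

    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "coexatlas",
        "version": coexatlas.__version__,
        "config": config,
        "seed": seed,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    # ---- expression ------------------------------------------------------
    if "simulate" in config:
        sim = _sim_config_from_dict(config["simulate"], seed)
        matrices, truth = generate_expression(sim)
        (out / "expression").mkdir(exist_ok=True)
        for m in matrices:
            p = out / "expression" / f"{m.tissue}.tsv"
            write_expression(m, p)
            record("simulate", p)
        meta = pd.DataFrame({
            "sample": [s for m in matrices for s in m.samples],
            "tissue": [m.tissue for m in matrices for _ in m.samples],
        })
        meta_path = out / "expression" / "metadata.tsv"
        meta.to_csv(meta_path, sep="\t", index=False)
        record("simulate", meta_path)
        gt_path = out / "expression" / "ground_truth.json"
        gt_path.write_text(json.dumps({
            "partitions": truth.partitions,
            "block_tissues": [list(t) for t in truth.block_tissues],
        }, indent=1, sort_keys=True))
        record("simulate", gt_path)
        manifest["stages"]["simulate"] = {
            "n_tissues": sim.n_tissues, "n_genes": sim.n_genes,
            "samples_per_tissue": list(sim.samples_per_tissue),
            "seed": sim.seed,
        }
    else:
        matrices = [read_expression(p) for p in config["expression"]]
        manifest["stages"]["read"] = {
            "tissues": [m.tissue for m in matrices],
            "n_genes": [m.n_genes for m in matrices],
        }

    # ---- confound adjustment --------------------------------------------
    adj_cfg = config.get("adjust", {})
    if adj_cfg.get("enabled", False):
        adjusted = []
        counts = {}
        for m in matrices:
            res = adjust_mod.sva_adjust(m, n_perm=adj_cfg.get("n_perm", 20),
                                        alpha=adj_cfg.get("alpha", 0.05),
                                        seed=seed)
            counts[m.tissue] = len(res.regressed) - 1
            adjusted.append(ExpressionMatrix(values=res.values, genes=res.genes,
                                             samples=res.samples,
                                             tissue=res.tissue))
        matrices = adjusted
        manifest["stages"]["adjust"] = {"n_factors": counts,
                                        "alpha": adj_cfg.get("alpha", 0.05)}

    # ---- networks + communities -----------------------------------------
    cutoff = config.get("coexpress", {}).get("cutoff", 0.8)
    gamma = config.get("communities", {}).get("gamma", 1.0)
    min_size = config.get("communities", {}).get("min_size", 4)
    (out / "networks").mkdir(exist_ok=True)
    networks, atlases = [], []
    for m in matrices:
        net = coexpression.build_network(m, cutoff=cutoff)
        part = communities.louvain_sign(net.A, gamma=gamma, seed=seed,
                                        genes=net.genes)
        atlas = communities.filter_communities(part, min_size=min_size,
                                               tissue=m.tissue)
        networks.append(net)
        atlases.append(atlas)
        p = out / "networks" / f"{m.tissue}_edges.tsv"
        net.edge_list().to_csv(p, sep="\t", index=False, float_format="%.10g")
        record("coexpress", p)
    atlas_json = {a.tissue: [{"community_id": cid, "genes": genes}
                             for cid, genes in sorted(a.communities.items())]
                  for a in atlases}
    p = out / "atlas.json"
    p.write_text(json.dumps({"schema": 1, "min_size": min_size,
                             "atlases": atlas_json}, indent=1, sort_keys=True))
    record("communities", p)
    long = pd.concat([a.to_records() for a in atlases], ignore_index=True)
    p = out / "atlas.tsv"
    long.to_csv(p, sep="\t", index=False)
    record("communities", p)
    manifest["stages"]["communities"] = {
        "cutoff": cutoff, "gamma": gamma, "min_size": min_size, "seed": seed,
        "n_communities": {a.tissue: a.n_communities for a in atlases},
        "n_edges": {n.tissue: int(np.count_nonzero(np.triu(n.A, 1)))
                    for n in networks},
    }

    # ---- multiplex -------------------------------------------------------
    archs = config.get("multiplex", {}).get("architectures", {})
    if archs:
        (out / "multiplex").mkdir(exist_ok=True)
        arch_info = {}
        for name, layer_spec in archs.items():
            layers = ([a.tissue for a in atlases] if layer_spec == "all"
                      else list(layer_spec))
            mpx = multiplex.build_multiplex(atlases, layers, name=name)
            gmi = multiplex.global_multiplexity(mpx)
            pi_k = multiplex.gmi_distribution(gmi)
            groups = multiplex.maximal_groups(gmi)
            p = out / "multiplex" / f"{name}_gmi.tsv"
            gmi.to_edge_list().to_csv(p, sep="\t", index=False)
            record("multiplex", p)
            p = out / "multiplex" / f"{name}_pi_k.tsv"
            pi_k.rename_axis("k").to_frame().to_csv(p, sep="\t",
                                                    float_format="%.10g")
            record("multiplex", p)
            p = out / "multiplex" / f"{name}_groups.json"
            p.write_text(json.dumps(groups, indent=1))
            record("multiplex", p)
            arch_info[name] = {"L": mpx.n_layers,
                               "max_gmi": int(gmi.values.max())
                               if gmi.values.size else 0,
                               "n_groups": len(groups)}
        manifest["stages"]["multiplex"] = arch_info

    # ---- master matrix, persistence, prediction -------------------------
    master = build_master_matrix(matrices)
    pers_cfg = config.get("persistence", {})
    if pers_cfg.get("enabled", True) and len(set(master.tissue_labels)) >= 2:
        ens = persistence_mod.bootstrap_manifolds(
            master, B=pers_cfg.get("B", 20), frac=pers_cfg.get("frac", 0.8),
            backend=pers_cfg.get("backend", "umap"), seed=seed,
            **pers_cfg.get("params", {}))
        dbar, var = persistence_mod.summarize_distances(ens)
        (out / "persistence").mkdir(exist_ok=True)
        for tag, mat in (("dbar", dbar), ("sigma2", var), ("V0", ens.V0)):
            p = out / "persistence" / f"{tag}.tsv"
            pd.DataFrame(mat, index=ens.tissues, columns=ens.tissues).to_csv(
                p, sep="\t", float_format="%.10g")
            record("persistence", p)
        rk = persistence_mod.structure_correlation(ens)
        p = out / "persistence" / "r_k.tsv"
        pd.Series(rk, name="r_k").rename_axis("k").to_frame().to_csv(
            p, sep="\t", float_format="%.10g")
        record("persistence", p)
        cons_rows = []
        if ens.L >= 5:
            for i in range(ens.L):
                for j in range(i + 1, ens.L):
                    r = persistence_mod.conservation_coefficient(
                        dbar, i, j, tissues=ens.tissues)
                    cons_rows.append((r.tissues[0], r.tissues[1], r.C,
                                      r.statistic, r.p_value))
            p = out / "persistence" / "conservation.tsv"
            pd.DataFrame(cons_rows, columns=["tissue_i", "tissue_j", "C",
                                             "statistic", "p"]).to_csv(
                p, sep="\t", index=False, float_format="%.10g")
            record("persistence", p)
        manifest["stages"]["persistence"] = {
            "B": ens.B, "frac": ens.frac, "backend": ens.backend,
            "seed": seed, "n_pairs_tested": len(cons_rows)}

    if config.get("predict", {}).get("enabled", True) and \
            len(set(master.tissue_labels)) >= 2:
        report = prediction_mod.prediction_report(master, atlases, seed=seed)
        p = out / "prediction.tsv"
        report.to_csv(p, sep="\t", index=False, float_format="%.10g")
        record("predict", p)
        manifest["stages"]["predict"] = {
            "n_pairs": len(report),
            "n_predictive": int(report["can_predict"].sum()), "seed": seed}

    # ---- enrichment ------------------------------------------------------
    if gmt_path:
        collection = read_gmt(gmt_path)
        background = {g for m in matrices for g in m.genes}
        frames = []
        for a in atlases:
            df = enrichment.enrich_atlas(a, collection, background)
            df.insert(0, "tissue", a.tissue)
            frames.append(df)
        result = pd.concat(frames, ignore_index=True)
        p = out / "enrichment.tsv"
        result.to_csv(p, sep="\t", index=False, float_format="%.10g")
        record("enrich", p)
        manifest["stages"]["enrich"] = {
            "n_sets": len(collection),
            "n_enriched": int(result["enriched"].sum())}

    # ---- community-conditional p-value statistics ------------------------
    twas_cfg = config.get("twas", {})
    if twas_cfg:
        community_genes = {g for a in atlases for g in a.genes()}
        n_genes = int(twas_cfg.get("n_genes", 10000))
        all_genes = [f"G{i:05d}" for i in range(n_genes)]
        mask = np.array([g in community_genes for g in all_genes])
        table = generate_pvalues(n_genes, twas_cfg.get("pi1", 0.3), mask,
                                 twas_cfg.get("effect", 3.0), seed=seed,
                                 enrichment_ratio=twas_cfg.get(
                                     "enrichment_ratio", 3.0))
        qq = twas_mod.conditional_qq(table)
        (out / "twas").mkdir(exist_ok=True)
        p = out / "twas" / "qq.tsv"
        qq.to_csv(p, sep="\t", index=False, float_format="%.10g")
        record("twas", p)
        pi1 = {}
        for name, m in (("community", mask), ("complement", ~mask)):
            try:
                est = twas_mod.estimate_pi1(table.loc[m, "p"])
                pi1[name] = None if np.isnan(est) else est
            except ValueError:  # stratum too small for a stable estimate
                pi1[name] = None
        p = out / "twas" / "pi1.json"
        p.write_text(json.dumps(pi1, indent=1, sort_keys=True))
        record("twas", p)
        manifest["stages"]["twas"] = {"n_genes": n_genes, "seed": seed,
                                      "pi1": pi1}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
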