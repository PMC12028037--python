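"""End-to-end pipeline: simulate/load -> diversity -> networks -> cohesion &
robustness -> environmental drivers -> PLS path models, one run directory per
configuration.

Each stage writes plain TSV/JSON/GraphML files into the run directory and the
manifest records the normalized configuration (including every default that
was filled in), the seeds, and a checksum per output file, so a rerun of the
same config is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohesion as coh
from . import diversity as dv
from . import drivers as drv
from . import io_tables as io
from . import network as netmod
from . import plspm as pm
from . import synthetic as syn
from .config import RunConfig

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "paper_shaped_model", "plspm_manifest_table"]

_SOIL_VARS = ["ORP", "pH", "temperature", "salinity", "clay", "silt", "sand"]
_NUTRIENT_VARS = ["TOC", "TC", "TIC", "TS", "TN", "TP", "PO4", "SO4", "NO2_N", "NO3_N", "NH4_N"]


def paper_shaped_model(env: io.EnvMatrix, scheme: str = "centroid") -> pm.PathModel:
    """Seven-latent structural model: soil properties, nutrients and
    geographic distance act on alpha and beta diversity, and all five act on
    community complexity (cohesion) and stability (robustness)."""
    soil = [v for v in _SOIL_VARS if v in env.variable_names]
    nutrients = [v for v in _NUTRIENT_VARS if v in env.variable_names]
    latents = ("soil_properties", "nutrients", "geographic_distance",
               "alpha_diversity", "beta_diversity", "complexity", "stability")
    L = len(latents)
    pmx = np.zeros((L, L))
    for target in (3, 4):          # alpha, beta <- soil, nutrients, distance
        pmx[target, [0, 1, 2]] = 1
    for target in (5, 6):          # complexity, stability <- all five
        pmx[target, [0, 1, 2, 3, 4]] = 1
    blocks = {
        "soil_properties": soil,
        "nutrients": nutrients,
        "geographic_distance": ["mean_geodesic_km"],
        "alpha_diversity": ["shannon"],
        "beta_diversity": ["PCo1", "PCo2"],
        "complexity": ["total_cohesion"],
        "stability": ["stability"],
    }
    return pm.PathModel(latents, pmx, blocks, scheme=scheme)


def plspm_manifest_table(env: io.EnvMatrix, geo: dv.DistanceMatrix,
                         shannon: pd.Series, ordination: dv.OrdinationResult,
                         cohesion_df: pd.DataFrame, stability: pd.Series) -> pd.DataFrame:
    """Assemble the per-sample manifest table feeding the structural model."""
    ids = list(geo.ids)
    n = len(ids)
    mean_geo = geo.values.sum(axis=1) / (n - 1) / 1000.0  # km
    df = env.to_frame().loc[ids].copy()
    df["mean_geodesic_km"] = mean_geo
    df["shannon"] = shannon.loc[ids]
    df["PCo1"] = ordination.coordinates[:, 0]
    df["PCo2"] = ordination.coordinates[:, 1] if ordination.coordinates.shape[1] > 1 else 0.0
    df["total_cohesion"] = cohesion_df.loc[ids, "total_cohesion"]
    df["stability"] = stability.loc[ids]
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.12g")


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> Path:
    """Execute every stage for every sample group; returns the run directory."""
    cfg = config.raw
    out = Path(output_dir if output_dir is not None else cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "inputs"
    try:
        # ------------------------------------------------------------ inputs
        inputs = cfg["inputs"]
        if inputs["simulate"] is not None:
            sim_seed = int(inputs["simulate"]["seed"])
            ft, meta, env = syn.simulate_study(seed=sim_seed)
        else:
            ft = io.read_feature_table(inputs["feature_table"], orientation=inputs["orientation"])
            meta = io.read_metadata(inputs["metadata"])
            env = io.read_env_matrix(inputs["env"]) if inputs["env"] else None
        meta = meta.aligned_to(ft.sample_ids)
        if env is not None:
            env = env.aligned_to(ft.sample_ids).with_ratios()
        io.write_feature_table(ft, out / "feature_table.tsv")
        io.write_metadata(meta, out / "metadata.tsv")
        if env is not None:
            io.write_env_matrix(env, out / "env.tsv")

        grouping = cfg["grouping"]
        groups = meta.column(grouping).astype(str)
        group_labels = sorted(set(groups))

        # --------------------------------------------------------- diversity
        stage = "diversity"
        dcfg = cfg["diversity"]
        rel = io.to_relative_abundance(ft)
        shannon = pd.Series(dv.shannon_per_sample(ft), name="shannon")
        _write_tsv(shannon.to_frame(), out / "shannon.tsv")
        bc = dv.bray_curtis(rel)
        _write_tsv(pd.DataFrame(bc.values, index=bc.ids, columns=bc.ids), out / "bray_curtis.tsv")
        ord_all = dv.pcoa(bc, k=2)
        ord_df = pd.DataFrame(ord_all.coordinates, index=ord_all.ids,
                              columns=[f"PCo{i+1}" for i in range(ord_all.coordinates.shape[1])])
        _write_tsv(ord_df, out / "pcoa_coordinates.tsv")
        geo = dv.geodesic_distance_matrix(meta)
        _write_tsv(pd.DataFrame(geo.values, index=geo.ids, columns=geo.ids), out / "geodesic.tsv")
        tests = {}
        for label, gvec in (("site", meta.column("site").astype(str)), (grouping, groups)):
            r, p = dv.anosim(bc, gvec, n_perm=dcfg["n_perm"], seed=dcfg["seed"])
            tests[f"anosim_{label}"] = {"R": r, "p": p, "n_perm": dcfg["n_perm"], "seed": dcfg["seed"]}
        if env is not None:
            env_z = (env.values - env.values.mean(axis=0)) / env.values.std(axis=0)
            env_d = dv.DistanceMatrix(env.sample_ids, _euclidean(env_z))
            r, p = dv.mantel(bc, env_d, method="spearman", n_perm=dcfg["n_perm"], seed=dcfg["seed"])
            tests["mantel_env"] = {"r": r, "p": p, "n_perm": dcfg["n_perm"], "seed": dcfg["seed"]}
        r, p = dv.mantel(bc, geo, method="spearman", n_perm=dcfg["n_perm"], seed=dcfg["seed"])
        tests["mantel_geographic"] = {"r": r, "p": p, "n_perm": dcfg["n_perm"], "seed": dcfg["seed"]}
        _write_json({"pcoa_pct_explained": ord_all.pct_explained.tolist(), **tests},
                    out / "diversity_tests.json")

        # ---------------------------------------- per-group network & stability
        ncfg, rcfg, scfg = cfg["network"], cfg["robustness"], cfg["stability"]
        flt = cfg["filter"]
        cohesion_frames, stability_series = [], []
        topo_all = {}
        for g in group_labels:
            stage = f"network[{g}]"
            sample_ids = [s for s, gv in zip(ft.sample_ids, groups) if gv == g]
            ft_g = io.filter_taxa(ft.select_samples(sample_ids),
                                  min_prevalence=flt["min_prevalence"],
                                  min_mean_abundance=flt["min_mean_abundance"])
            rel_g = io.to_relative_abundance(ft_g)
            # Spearman on the count table: rank-based, so sequencing depth only
            # enters weakly, and compositional closure does not cancel the
            # shared variation of dominant co-varying taxa
            rho, pmat = netmod.spearman_matrix(ft_g)
            net = netmod.build_network(rho, pmat, ft_g, rho_min=ncfg["rho_min"],
                                       alpha=ncfg["alpha"], correction=ncfg["correction"])
            report = netmod.topology_report(net, resolution=ncfg["resolution"], seed=ncfg["seed"])
            topo_all[g] = report.to_dict()
            io.export_network(net, out / f"network_{g}.graphml", format="graphml")
            io.export_network(net, out / f"edges_{g}.tsv", format="edgelist")
            _write_json(report.to_dict(), out / f"topology_{g}.json")

            stage = f"stability[{g}]"
            ccfg = cfg["cohesion"]
            retained = coh.retained_correlation_matrix(rel_g, rho, pmat,
                                                      corr_source=ccfg["corr_source"],
                                                      net=net, alpha=ncfg["alpha"])
            if ccfg["null_model_correction"]:
                retained = coh.null_corrected_matrix(ft_g, retained,
                                                     n_null=ccfg["n_null"],
                                                     seed=rcfg["seed"])
            conn_pos, conn_neg = coh.connectedness(retained)
            cdf = coh.cohesion_table(coh.cohesion(rel_g, conn_pos, conn_neg))
            cohesion_frames.append(cdf)
            strength = _node_strength(ft_g, net)
            rob = {}
            if net.n_edges > 0:
                rnd = coh.robustness(net, strength, protocol="random_fraction",
                                     parameter=rcfg["random_fraction"],
                                     n_iterations=rcfg["n_iterations"], seed=rcfg["seed"])
                tgt = coh.robustness(net, strength, protocol="targeted_hubs",
                                     parameter=min(rcfg["hub_count"], net.n_nodes),
                                     modules=net.modules, seed=rcfg["seed"])
                rob = {"random": rnd.to_dict(), "targeted": tgt.to_dict()}
            _write_json(rob, out / f"robustness_{g}.json")
            stab = coh.per_sample_stability(rel_g, net, parameter=rcfg["random_fraction"],
                                            n_iterations=scfg["n_iterations"], seed=scfg["seed"],
                                            counts=ft_g)
            stability_series.append(stab)
        cohesion_df = pd.concat(cohesion_frames).loc[list(ft.sample_ids)]
        _write_tsv(cohesion_df, out / "cohesion.tsv")
        stability = pd.concat(stability_series).loc[list(ft.sample_ids)]
        stability.index.name = "sample_id"
        _write_tsv(stability.to_frame(), out / "stability.tsv")
        _write_json(topo_all, out / "topology.json")

        # ----------------------------------------------------------- drivers
        responses_all = {}
        if env is not None:
            stage = "drivers"
            for g in group_labels:
                sample_ids = [s for s, gv in zip(ft.sample_ids, groups) if gv == g]
                responses = pd.DataFrame({
                    "shannon": shannon.loc[sample_ids],
                    "positive_cohesion": cohesion_df.loc[sample_ids, "positive_cohesion"],
                    "negative_cohesion": cohesion_df.loc[sample_ids, "negative_cohesion"],
                    "total_cohesion": cohesion_df.loc[sample_ids, "total_cohesion"],
                    "stability": stability.loc[sample_ids],
                })
                responses = responses.loc[:, responses.std() > 0]
                responses_all[g] = responses
                table = drv.driver_correlations(env.aligned_to(sample_ids), responses,
                                                correction=cfg["drivers"]["correction"])
                _write_tsv(table.frame, out / f"drivers_{g}.tsv", index=False)

        # ------------------------------------------------------------ plspm
        if env is not None:
            pcfg = cfg["plspm"]
            for g in group_labels:
                stage = f"plspm[{g}]"
                sample_ids = [s for s, gv in zip(ft.sample_ids, groups) if gv == g]
                meta_g = meta.aligned_to(sample_ids)
                bc_g = dv.bray_curtis(rel.select_samples(sample_ids))
                ord_g = dv.pcoa(bc_g, k=2)
                geo_g = dv.geodesic_distance_matrix(meta_g)
                table = plspm_manifest_table(env.aligned_to(sample_ids), geo_g,
                                             shannon, ord_g, cohesion_df, stability)
                model = paper_shaped_model(env, scheme=pcfg["scheme"])
                model = _drop_degenerate_manifests(model, table)
                res = pm.fit_plspm(table, model, max_iter=pcfg["max_iter"], tol=pcfg["tol"])
                boot = None
                if pcfg["n_boot"]:
                    boot = pm.bootstrap_paths(table, model, n_boot=pcfg["n_boot"],
                                              seed=pcfg["seed"], max_iter=pcfg["max_iter"],
                                              tol=pcfg["tol"])
                _write_tsv(res.effects, out / f"plspm_effects_{g}.tsv", index=False)
                doc = {
                    "latents": list(model.latent_names),
                    "path_coefficients": {
                        f"{model.latent_names[j]}->{model.latent_names[i]}": float(res.path_coefficients[i, j])
                        for i in range(model.n_latents) for j in model.predecessors(i)
                    },
                    "r_squared": res.r_squared,
                    "gof": res.gof,
                    "n_iterations_used": res.n_iterations_used,
                }
                if boot is not None:
                    doc["bootstrap"] = boot.to_dict(orient="records")
                _write_json(doc, out / f"plspm_{g}.json")

        # ---------------------------------------------------------- manifest
        stage = "manifest"
        outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
        manifest = {
            "config": cfg,
            "filled_defaults": list(config.filled_defaults),
            "config_hash": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
            "outputs": {name: _sha256(out / name) for name in outputs},
        }
        _write_json(manifest, out / "manifest.json")
    except Exception:
        (out / "FAILED_STAGE").write_text(stage + "\n")
        log.exception("pipeline failed at stage %s", stage)
        raise
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return out


def _euclidean(x: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform
    return squareform(pdist(x, metric="euclidean"))


def _node_strength(ft_g, net) -> np.ndarray:
    """Pearson association matrix restricted to the network's nodes.

    Computed on the same abundance table the network was inferred from:
    correlating row-normalized abundances instead would let compositional
    closure flip the associations of dominant co-varying taxa."""
    strength_full = netmod.pearson_matrix(ft_g)
    idx = [ft_g.taxon_ids.index(t) for t in net.node_ids]
    return strength_full[np.ix_(idx, idx)]


def _drop_degenerate_manifests(model: pm.PathModel, table: pd.DataFrame) -> pm.PathModel:
    """Remove zero-variance manifests (keeping each block nonempty)."""
    blocks = {}
    for lat, manifests in model.blocks.items():
        kept = tuple(mv for mv in manifests if table[mv].std() > 0)
        if not kept:
            raise ValueError(f"every manifest of latent {lat!r} is constant")
        blocks[lat] = kept
    return pm.PathModel(model.latent_names, model.path_matrix, blocks, scheme=model.scheme)
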