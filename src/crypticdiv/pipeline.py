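"""Config-driven orchestration of the full analysis workflow.

Runs the stages in dependency order — landmark geometry -> shape
statistics and cluster detection; sequences -> mtDNA statistics and
clustering; genotypes -> microsatellite statistics and clustering;
partitions -> cross-dataset concordance; optional ABC — and writes a
machine-readable JSON results tree plus CSV tables.

A config is a plain dict (or YAML file via :func:`load_config`) with
optional keys per stage; a synthetic bundle can be generated in place of
file inputs with the ``synthetic`` block.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import (cluster_concord, divergence_abc, morpho_geometry,
               morpho_stats, popgen_msat, popgen_mtdna, synthetic_data)

logger = logging.getLogger("crypticdiv")

DEFAULTS = {
    "n_perm": 1000,
    "n_boot": 1000,
    "seed": 0,
    "k_max": 9,
}


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path) -> dict:
    import yaml
    with open(path) as fh:
        return yaml.safe_load(fh)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        from dataclasses import asdict
        return _jsonify(asdict(obj))
    return obj


def _landmark_stage(cfg, results, rng, shared_sizes=None):
    """GPA (+ symmetric component) -> allometry residuals -> shape stats."""
    name = cfg.get("name", "shape")
    if "synthetic" in cfg:
        spec = synthetic_data.SynthSpec(**cfg["synthetic"])
        ds = synthetic_data.gen_landmarks(spec)
    else:
        ds = morpho_geometry.read_landmarks(
            cfg["path"], cfg.get("format", "tps"),
            cfg["roles"], curves=cfg.get("curves"),
            pairing=cfg.get("pairing"), midline=cfg.get("midline"),
            group_labels=cfg.get("group_labels"))
    if ds.missing_mask.any():
        ds = morpho_geometry.estimate_missing_by_reflection(ds)
    if cfg.get("symmetric_component"):
        aligned = morpho_geometry.symmetric_component(ds)
    else:
        aligned = morpho_geometry.gpa_with_sliding(ds)
    sizes = shared_sizes if shared_sizes is not None else None
    if sizes is not None:
        resid = morpho_geometry.allometry_correct(
            aligned, "external_size_vector", external_sizes=sizes)
    else:
        resid = morpho_geometry.allometry_correct(aligned)
    labels = np.asarray(aligned.group_labels)
    n_perm = cfg.get("n_perm", DEFAULTS["n_perm"])
    n_boot = cfg.get("n_boot", DEFAULTS["n_boot"])
    seed = int(rng.integers(2 ** 31 - 1))
    out = {"n": aligned.proc_coords.shape[0],
           "converged": aligned.converged}
    out["mean_test"] = _jsonify(morpho_stats.procrustes_distance_test(
        resid, labels, n_perm=n_perm, seed=seed))
    out["loo_cv"] = _jsonify(morpho_stats.loo_cv_classification(resid, labels))
    groups = np.unique(labels)
    out["integration_sve"] = {
        str(g): float(morpho_stats.integration_sve(
            resid.residuals[labels == g], n_boot=n_boot, seed=seed).sve)
        for g in groups}
    disp = {}
    for est in ("multivariate_variance", "mean_pairwise_dist",
                "mean_dist_centroid"):
        res = morpho_stats.disparity_rarefied(
            resid, labels, est, n_boot=n_boot, seed=seed)
        disp[est] = {g: {"mean": r.mean, "sd": r.sd}
                     for g, r in res.items()}
        a, b = [res[str(g)].boot_distribution for g in groups]
        disp[est]["btail_p"] = morpho_stats.btail_test(a, b)
    out["disparity"] = disp
    red = cluster_concord.broken_stick_reduce(resid.residuals, mode="pca")
    part = cluster_concord.gmm_cluster(
        red, k_max=cfg.get("k_max", DEFAULTS["k_max"]),
        seed=seed, ids=resid.specimen_ids, source=name)
    out["clusters"] = {"k": part.k}
    return out, resid, part


def run_pipeline(cfg: dict, out_dir=None) -> dict:
    """Execute the configured stages and return the results tree.

    Raises :class:`StageError` naming the failed stage; partial results
    accumulated before the failure are attached to the exception.
    """
    cfg = dict(cfg or {})
    seed = cfg.get("seed", DEFAULTS["seed"])
    rng = np.random.default_rng(seed)
    results = {"seed": seed}
    partitions = {}
    out_dir = Path(out_dir) if out_dir else None
    handler = None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log")
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    logger.info("pipeline start (seed %s)", seed)

    residuals = {}
    stage = None
    try:
        body_sizes = None
        for block_key in ("body", "jaw"):
            block = cfg.get(block_key)
            if not block:
                continue
            stage = f"morphometrics:{block_key}"
            logger.info("stage %s", stage)
            block = dict(block, name=block_key)
            shared = body_sizes if block_key == "jaw" and \
                block.get("use_body_size") else None
            out, resid, part = _landmark_stage(block, results, rng,
                                               shared_sizes=shared)
            results[block_key] = out
            residuals[block_key] = resid
            partitions[block_key] = part
            if block_key == "body":
                body_sizes = resid.sizes

        if "body" in residuals and "jaw" in residuals:
            stage = "covariation"
            logger.info("stage %s", "covariation")
            block = cfg.get("covariation", {})
            rv = morpho_stats.rv_and_tests(
                residuals["body"], residuals["jaw"],
                labels=np.asarray(residuals["body"].group_labels),
                rarefied_n=block.get("rarefied_n"),
                n_perm=block.get("n_perm", DEFAULTS["n_perm"]),
                seed=int(rng.integers(2 ** 31 - 1)))
            results["covariation"] = {"rv": rv.rv, "p_value": rv.p_value,
                                      "diff_p": rv.diff_p}

        if cfg.get("mtdna"):
            stage = "mtdna"
            logger.info("stage %s", "mtdna")
            block = cfg["mtdna"]
            if "synthetic" in block:
                spec = synthetic_data.SynthSpec(**block["synthetic"])
                aln = synthetic_data.gen_sequences(spec)
            else:
                aln = popgen_mtdna.read_fasta_alignment(
                    block["path"], block.get("popmap"))
            n_perm = block.get("n_perm", DEFAULTS["n_perm"])
            sub_seed = int(rng.integers(2 ** 31 - 1))
            res = {}
            for pop in dict.fromkeys(aln.pop_labels):
                sub = aln.subset(pop)
                st = popgen_mtdna.seq_stats(sub)
                entry = {"n": st.n, "S": st.S, "pi": st.pi,
                         "k_obs": st.k_obs}
                if st.S > 0 and st.pi > 0:
                    fs, pfs = popgen_mtdna.fu_fs(st, n_sims=n_perm,
                                                 seed=sub_seed)
                    r2, pr2 = popgen_mtdna.r2_test(st, n_sims=n_perm,
                                                   seed=sub_seed)
                    entry.update(fs=fs, fs_p=pfs, r2=r2, r2_p=pr2)
                res[pop] = entry
            fst = popgen_mtdna.phi_st_permutation(aln, n_perm=n_perm,
                                                  seed=sub_seed)
            res["phi_st"] = {"value": fst.phi_st, "p_value": fst.p_value}
            net = popgen_mtdna.median_joining_network(aln)
            res["network"] = {"n_haplotypes": len(net.haplotypes)
                              - len(net.median_nodes),
                              "n_medians": len(net.median_nodes),
                              "total_cost": net.total_cost()}
            if out_dir:
                net.write_edgelist_csv(out_dir / "haplonet_edges.csv")
            dm = popgen_mtdna.tamura_nei_matrix(aln)
            dm = np.nan_to_num(dm, nan=0.0)
            red = cluster_concord.broken_stick_reduce(dm, mode="pcoa")
            part = cluster_concord.gmm_cluster(
                red, k_max=block.get("k_max", DEFAULTS["k_max"]),
                seed=sub_seed, ids=aln.ids, source="mtdna")
            partitions["mtdna"] = part
            res["clusters"] = {"k": part.k}
            results["mtdna"] = res

        if cfg.get("msat"):
            stage = "msat"
            logger.info("stage %s", "msat")
            block = cfg["msat"]
            if "synthetic" in block:
                spec = synthetic_data.SynthSpec(**block["synthetic"])
                gt = synthetic_data.gen_microsats(spec)
            else:
                gt = popgen_msat.read_genepop(block["path"])
            n_perm = block.get("n_perm", DEFAULTS["n_perm"])
            sub_seed = int(rng.integers(2 ** 31 - 1))
            fst = popgen_msat.wc_fst_permutation(gt, n_perm=n_perm,
                                                 seed=sub_seed)
            res = {"fst": {"theta": fst.theta, "p_value": fst.p_value}}
            pcoa = popgen_msat.codominant_distance_pcoa(gt)
            res["pcoa_percent_variance"] = pcoa["percent_variance"][:2].tolist()
            red = cluster_concord.broken_stick_reduce(
                np.sqrt(popgen_msat.codominant_distance_matrix(gt)),
                mode="pcoa")
            part = cluster_concord.gmm_cluster(
                red, k_max=block.get("k_max", DEFAULTS["k_max"]),
                seed=sub_seed, ids=gt.ids, source="msat")
            partitions["msat"] = part
            res["clusters"] = {"k": part.k}
            if block.get("assignment"):
                asg = popgen_msat.frequency_assignment(
                    gt, n_sim=block.get("n_sim", 10000),
                    seed=sub_seed)
                correct = np.mean([a == p for a, p in
                                   zip(asg.assigned, gt.pop_labels)])
                res["assignment_self_rate"] = float(correct)
            results["msat"] = res

        if len(partitions) >= 2:
            stage = "concordance"
            logger.info("stage %s", "concordance")
            conc = cluster_concord.concordance_matrix(
                partitions, n_perm=cfg.get("n_perm", DEFAULTS["n_perm"]),
                seed=int(rng.integers(2 ** 31 - 1)))
            results["concordance"] = {
                f"{a}|{b}": {"ari": r.ari, "p_value": r.p_value,
                             "n_common": r.n_common}
                for (a, b), r in conc.items()}

        if cfg.get("abc"):
            stage = "abc"
            logger.info("stage %s", "abc")
            block = cfg["abc"]
            model = divergence_abc.ABCModel(
                theta_max=block.get("theta_max", 20.0),
                tau_max=block.get("tau_max", 5.0),
                m_max=block.get("m_max", 0.0),
                L=block.get("L", 711),
                sample_sizes=tuple(map(tuple, block.get(
                    "sample_sizes", ((20, 20), (20, 20))))))
            observed = np.asarray(block["observed"], dtype=float)
            abc = divergence_abc.abc_psi(
                observed, model, n_sims=block.get("n_sims", 10000),
                tolerance_frac=block.get("tolerance_frac", 0.01),
                seed=int(rng.integers(2 ** 31 - 1)))
            results["abc"] = {"posterior_psi": abc.posterior_psi,
                              "omega_mean": float(abc.omega.mean())}
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        logger.error("stage %s failed: %s", stage, exc)
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()
        err = StageError(stage, exc)
        err.partial_results = results
        raise err from exc

    if out_dir:
        import csv
        with open(out_dir / "results.json", "w") as fh:
            json.dump(_jsonify(results), fh, indent=2)
        for name, part in partitions.items():
            with open(out_dir / f"partition_{name}.csv", "w",
                      newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["id", "label"])
                for sid, lab in zip(part.ids, part.labels):
                    w.writerow([sid, lab])
        # disparity table (one row per trait x group, mean +/- sd)
        rows = []
        for block in ("body", "jaw"):
            disp = results.get(block, {}).get("disparity")
            if not disp:
                continue
            groups = [g for g in next(iter(disp.values())) if g != "btail_p"]
            for g in groups:
                row = {"trait": block, "group": g}
                for est, vals in disp.items():
                    row[f"{est}_mean"] = vals[g]["mean"]
                    row[f"{est}_sd"] = vals[g]["sd"]
                rows.append(row)
        if rows:
            with open(out_dir / "disparity.csv", "w", newline="") as fh:
                w = csv.DictWriter(fh, fieldnames=list(rows[0]))
                w.writeheader()
                w.writerows(rows)
        # pairwise concordance matrix
        if "concordance" in results:
            names = sorted({n for key in results["concordance"]
                            for n in key.split("|")})
            with open(out_dir / "concordance.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["dataset"] + names)
                for a in names:
                    row = [a]
                    for b in names:
                        if a == b:
                            row.append(1.0)
                        else:
                            key = f"{a}|{b}" if f"{a}|{b}" in \
                                results["concordance"] else f"{b}|{a}"
                            row.append(results["concordance"][key]["ari"])
                    w.writerow(row)
    logger.info("pipeline done")
    if handler is not None:
        logger.removeHandler(handler)
        handler.close()
    return results
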