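"""Stage-wise pipeline: simulate -> msn -> topology -> normative ->
deviations -> fuse -> cluster -> decode -> transfer -> report.

The pipeline is file-based and resumable: every stage reads its inputs
from, and writes its outputs to, a workspace directory; a stage is
skipped when its recorded input checksums and the config hash are
unchanged and its outputs exist.  Deleting an intermediate therefore
recomputes exactly the downstream stages.  A master seed deterministically
derives per-stage seeds, and two runs of an identical config produce
byte-identical artifacts and manifests (timings are kept out of the
manifest, in ``timings.json``).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from msnbiotype import __version__
from msnbiotype.io import (
    read_json,
    read_matrix_archive,
    read_tsv,
    sha256_file,
    write_json,
    write_matrix_archive,
    write_tsv,
)
from msnbiotype.synthetic import (
    AnnotationMap,
    CohortSpec,
    NodeGeometry,
    generate_annotation_maps,
    generate_cohort,
)
from msnbiotype.msn import build_msn
from msnbiotype.topology import (
    METRIC_NAMES,
    consensus_partition,
    threshold_network,
    topology_profile,
)
from msnbiotype.normative import (
    DeviationTensor,
    NormativeConfig,
    NormativeModel,
    check_site_effects,
    compute_deviation_tensor,
    deviation_z,
    fit_normative_battery,
    transfer_recalibrate,
)
from msnbiotype import deviations as devmod
from msnbiotype import fusion as fusmod
from msnbiotype import hydra as hydmod
from msnbiotype import decode as decmod
from msnbiotype import cohort_stats as statmod

log = logging.getLogger("msnbiotype.pipeline")

__all__ = ["DEFAULT_CONFIG", "RunConfig", "run", "load_config", "STAGES"]

STAGES = (
    "simulate",
    "msn",
    "topology",
    "normative",
    "deviations",
    "fuse",
    "cluster",
    "decode",
    "transfer",
    "report",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n_controls": 300,
        "n_cases": 200,
        "n_sites": 4,
        "n_regions": 60,
        "n_samples_per_region": 200,
        "age_range": [6.0, 18.0],
        "male_fraction": 0.7,
        "k_true": 3,
        "effect_size": 3.0,
    },
    "validation": {"n_controls": 100, "n_cases": 150, "n_sites": 2},
    "annotations": {"n_receptor_maps": 19, "n_term_maps": 25, "smoothness": 0.5},
    "msn": {"n_bins": 128, "floor": 1e-10, "method": "histogram"},
    "topology": {"sparsity": 0.3, "gamma": 1.0, "n_reps": 20},
    "normative": {"n_knots": 5, "degree": 3, "warp": "sinh-arcsinh", "min_train": 50},
    "deviations": {"n_perm": 1000, "direction": "either", "within_site": True},
    "fusion": {"n_components": None, "variance_floor": 0.8, "n_restarts": 20, "max_components": 12},
    "hydra": {
        "k_grid": [2, 3, 4],
        "n_folds": 10,
        "n_restarts": 5,
        "C": 1.0,
        "n_splits": 5,
    },
    "decode": {"n_surrogates": 1000, "n_boot": 500, "method": "spearman"},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, seed: int | None = None) -> dict:
    """Merge a YAML/JSON config file over the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


class RunConfig:
    """Configuration + workspace layout for one pipeline run."""

    def __init__(self, cfg: dict, workspace: str | Path, stages: tuple[str, ...] = STAGES):
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.cfg = cfg
        self.workspace = Path(workspace)
        self.stages = tuple(s for s in STAGES if s in stages)
        self.seed = int(cfg["seed"])

    def path(self, rel: str) -> Path:
        p = self.workspace / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        return p


# ---------------------------------------------------------------------------
# stage helpers


def _cohort_spec(cfg: dict, seed: int, validation: bool = False) -> CohortSpec:
    c = cfg["cohort"]
    kw = dict(
        n_sites=c["n_sites"],
        n_regions=c["n_regions"],
        n_samples_per_region=c["n_samples_per_region"],
        age_range=tuple(c["age_range"]),
        male_fraction=c["male_fraction"],
        k_true=c["k_true"],
        effect_size=c["effect_size"],
    )
    if validation:
        v = cfg["validation"]
        kw.update(n_controls=v["n_controls"], n_cases=v["n_cases"], n_sites=v["n_sites"])
        return CohortSpec(seed=seed + 1, biology_seed=seed, **kw)
    return CohortSpec(n_controls=c["n_controls"], n_cases=c["n_cases"], seed=seed, biology_seed=seed, **kw)


def _write_cohort(rc: RunConfig, prefix: str, cohort, samples, truth) -> None:
    write_tsv(rc.path(f"{prefix}cohort.tsv"), cohort)
    write_matrix_archive(rc.path(f"{prefix}samples.zip"), samples)
    write_json(
        rc.path(f"{prefix}ground_truth.json"),
        {
            "biotype_nodes": {str(k): v for k, v in truth.biotype_nodes.items()},
            "case_biotypes": truth.case_biotypes,
            "module_of_region": truth.module_of_region,
            "symptom_means": truth.symptom_means,
        },
    )


def _load_geometry(rc: RunConfig) -> NodeGeometry:
    g = read_json(rc.path("geometry.json"))
    return NodeGeometry(
        coords=np.asarray(g["coords"]), true_module=np.asarray(g["true_module"])
    )


def _load_deviations(rc: RunConfig, prefix: str = "") -> tuple[DeviationTensor, pd.DataFrame]:
    cohort = read_tsv(rc.path(f"{prefix}cohort.tsv"))
    dev = read_tsv(rc.path(f"{prefix}deviations.tsv"))
    R = dev["node"].max() + 1
    z = (
        dev.pivot_table(index="subject_id", columns=["metric", "node"], values="z")
        .reindex(cohort["subject_id"])
        .to_numpy()
        .reshape(len(cohort), len(METRIC_NAMES), R)
        .transpose(0, 2, 1)
    )
    # pivot orders metrics alphabetically; realign to METRIC_NAMES order
    metrics_sorted = sorted(METRIC_NAMES)
    order = [metrics_sorted.index(m) for m in METRIC_NAMES]
    z = z[:, :, order]
    devs = DeviationTensor(z=z, metric_names=METRIC_NAMES, subject_ids=cohort["subject_id"].tolist())
    return devs, cohort


def _deviations_long(devs: DeviationTensor) -> pd.DataFrame:
    n, R, M = devs.z.shape
    recs = []
    for m, name in enumerate(devs.metric_names):
        df = pd.DataFrame(devs.z[:, :, m], columns=range(R))
        df["subject_id"] = devs.subject_ids
        long = df.melt(id_vars="subject_id", var_name="node", value_name="z")
        long["metric"] = name
        recs.append(long)
    out = pd.concat(recs, ignore_index=True)[["subject_id", "node", "metric", "z"]]
    return out.sort_values(["metric", "node", "subject_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(rc: RunConfig) -> None:
    seed = stage_seed(rc.seed, "simulate")
    spec = _cohort_spec(rc.cfg, seed)
    cohort, samples, geometry, truth = generate_cohort(spec)
    _write_cohort(rc, "", cohort, samples, truth)
    write_json(
        rc.path("geometry.json"),
        {"coords": geometry.coords, "true_module": geometry.true_module},
    )
    ann_cfg = rc.cfg["annotations"]
    receptors = generate_annotation_maps(
        geometry,
        ann_cfg["n_receptor_maps"],
        smoothness=ann_cfg["smoothness"],
        seed=seed + 11,
        names=[f"receptor-{i:02d}" for i in range(ann_cfg["n_receptor_maps"])],
    )
    terms = generate_annotation_maps(
        geometry,
        ann_cfg["n_term_maps"],
        smoothness=ann_cfg["smoothness"],
        seed=seed + 13,
        names=[f"term-{i:02d}" for i in range(ann_cfg["n_term_maps"])],
    )
    for fname, maps in (("annotations.tsv", receptors), ("term_maps.tsv", terms)):
        df = pd.DataFrame({"region_index": np.arange(geometry.n_regions)})
        for m in maps:
            df[m.name] = m.values
        write_tsv(rc.path(fname), df)

    vspec = _cohort_spec(rc.cfg, seed, validation=True)
    vcohort, vsamples, _, vtruth = generate_cohort(vspec)
    _write_cohort(rc, "validation/", vcohort, vsamples, vtruth)


def _build_msns(rc: RunConfig, prefix: str) -> None:
    cfg = rc.cfg["msn"]
    samples = read_matrix_archive(rc.path(f"{prefix}samples.zip"))
    out = {}
    for sid, mat in samples.items():
        regions = {r: mat[r] for r in range(mat.shape[0])}
        out[sid] = build_msn(
            regions, sid, n_bins=cfg["n_bins"], floor=cfg["floor"], method=cfg["method"]
        ).matrix
    write_matrix_archive(rc.path(f"{prefix}msn.zip"), out)


def _stage_msn(rc: RunConfig) -> None:
    _build_msns(rc, "")
    _build_msns(rc, "validation/")


def _topology_table(rc: RunConfig, prefix: str, partition: np.ndarray) -> None:
    sparsity = rc.cfg["topology"]["sparsity"]
    msns = read_matrix_archive(rc.path(f"{prefix}msn.zip"))
    cohort = read_tsv(rc.path(f"{prefix}cohort.tsv"))
    recs = []
    for sid in cohort["subject_id"]:
        prof = topology_profile(msns[sid], partition, sid, sparsity=sparsity)
        for m, name in enumerate(METRIC_NAMES):
            for node in range(prof.metrics.shape[0]):
                recs.append((sid, node, name, prof.metrics[node, m]))
    write_tsv(
        rc.path(f"{prefix}topology.tsv"),
        pd.DataFrame(recs, columns=["subject_id", "region_index", "metric", "value"]),
    )


def _stage_topology(rc: RunConfig) -> None:
    cfg = rc.cfg["topology"]
    seed = stage_seed(rc.seed, "topology")
    msns = read_matrix_archive(rc.path("msn.zip"))
    cohort = read_tsv(rc.path("cohort.tsv"))
    ctrl_ids = cohort.loc[cohort["group"] == "control", "subject_id"]
    adjs = [threshold_network(msns[sid], cfg["sparsity"]) for sid in ctrl_ids]
    partition = consensus_partition(adjs, gamma=cfg["gamma"], n_reps=cfg["n_reps"], seed=seed)
    write_json(rc.path("partition.json"), {"labels": partition})
    _topology_table(rc, "", partition)
    _topology_table(rc, "validation/", partition)


def _topology_tensor(rc: RunConfig, prefix: str) -> tuple[np.ndarray, pd.DataFrame]:
    topo = read_tsv(rc.path(f"{prefix}topology.tsv"))
    cohort = read_tsv(rc.path(f"{prefix}cohort.tsv"))
    R = topo["region_index"].max() + 1
    Y = np.empty((len(cohort), R, len(METRIC_NAMES)))
    for m, name in enumerate(METRIC_NAMES):
        sub = topo[topo["metric"] == name].pivot(
            index="subject_id", columns="region_index", values="value"
        )
        Y[:, :, m] = sub.reindex(cohort["subject_id"]).to_numpy()
    return Y, cohort


def _stage_normative(rc: RunConfig) -> None:
    ncfg = rc.cfg["normative"]
    config = NormativeConfig(
        n_knots=ncfg["n_knots"],
        degree=ncfg["degree"],
        warp=ncfg["warp"],
        min_train=ncfg["min_train"],
    )
    Y, cohort = _topology_tensor(rc, "")
    ctrl = (cohort["group"] == "control").to_numpy()
    age = cohort["age"].to_numpy()
    sex = cohort["sex"].to_numpy()
    models = fit_normative_battery(Y[ctrl], age[ctrl], sex[ctrl], METRIC_NAMES, config)
    write_json(
        rc.path("normative_models.json"),
        [[m.to_dict() for m in row] for row in models],
    )
    devs = compute_deviation_tensor(
        models, Y, age, sex, METRIC_NAMES, cohort["subject_id"].tolist()
    )
    write_tsv(rc.path("deviations.tsv"), _deviations_long(devs))
    z_feat, _ = devs.flatten_features()
    acc = check_site_effects(
        z_feat[ctrl], cohort.loc[ctrl, "site"].to_numpy(), seed=stage_seed(rc.seed, "normative")
    )
    n_sites = cohort["site"].nunique()
    write_json(
        rc.path("site_check.json"),
        {"balanced_accuracy": acc, "chance": 1.0 / n_sites, "n_sites": n_sites},
    )


def _stage_deviations(rc: RunConfig) -> None:
    dcfg = rc.cfg["deviations"]
    seed = stage_seed(rc.seed, "deviations")
    devs, cohort = _load_deviations(rc)
    geometry = _load_geometry(rc)
    case = (cohort["group"] == "case").to_numpy()
    within = cohort["site"].to_numpy() if dcfg["within_site"] else None
    for m, name in enumerate(METRIC_NAMES):
        table = devmod.case_control_difference_analysis(
            devs,
            case,
            geometry,
            m,
            direction=dcfg["direction"],
            n_perm=dcfg["n_perm"],
            seed=seed + m,
            within=within,
        )
        write_tsv(rc.path(f"diffmap_{name}.tsv"), table)
    write_tsv(rc.path("burden.tsv"), devmod.extreme_burden_compare(devs, case, dcfg["direction"]))


def _stage_fuse(rc: RunConfig) -> None:
    fcfg = rc.cfg["fusion"]
    seed = stage_seed(rc.seed, "fuse")
    devs, cohort = _load_deviations(rc)
    X_list = [devs.z[:, :, m] for m in range(len(METRIC_NAMES))]
    n_comp = fcfg["n_components"]
    if n_comp is None:
        n_comp = fusmod.select_component_count(
            X_list, fcfg["variance_floor"], max_components=fcfg["max_components"]
        )
    result = fusmod.mcca_jica(
        X_list, n_comp, list(METRIC_NAMES), seed=seed, n_restarts=fcfg["n_restarts"]
    )
    case = (cohort["group"] == "case").to_numpy()
    table = fusmod.component_group_test(result.A, case, list(METRIC_NAMES))
    write_tsv(rc.path("fusion_group_test.tsv"), table)
    write_json(
        rc.path("fusion.json"),
        {
            "n_components": int(n_comp),
            "explained_variance": result.explained_variance,
            "canonical_ssq": result.canonical_ssq,
            "negentropy": result.negentropy,
            "low_nongaussianity": result.low_nongaussianity,
            "joint_components": sorted(
                table.loc[table["joint_significant"], "component"].unique().tolist()
            ),
        },
    )
    write_matrix_archive(
        rc.path("fusion_matrices.zip"),
        {
            **{f"D_{n}": D for n, D in zip(METRIC_NAMES, result.D)},
            **{f"C_{n}": C for n, C in zip(METRIC_NAMES, result.C)},
            **{f"S_{n}": S for n, S in zip(METRIC_NAMES, result.S)},
            **{f"A_{n}": A for n, A in zip(METRIC_NAMES, result.A)},
            "W": result.W,
        },
    )


def _stage_cluster(rc: RunConfig) -> None:
    hcfg = rc.cfg["hydra"]
    seed = stage_seed(rc.seed, "cluster")
    devs, cohort = _load_deviations(rc)
    X, feature_names = devs.flatten_features()
    case = (cohort["group"] == "case").to_numpy()
    k_table, chosen_k = hydmod.cv_select_k(
        X,
        case,
        k_grid=tuple(hcfg["k_grid"]),
        n_folds=hcfg["n_folds"],
        seed=seed,
        n_restarts=hcfg["n_restarts"],
        C=hcfg["C"],
    )
    write_tsv(rc.path("k_selection.tsv"), k_table)
    model = hydmod.fit_hydra(
        X,
        case,
        chosen_k,
        n_restarts=max(hcfg["n_restarts"], 10),
        seed=seed + 1,
        C=hcfg["C"],
        feature_names=feature_names,
    )
    model.ari_cv = float(k_table.loc[k_table["k"] == chosen_k, "ari"].iloc[0])
    write_json(rc.path("hydra_model.json"), model.to_dict())
    assign = pd.DataFrame(
        {
            "subject_id": cohort.loc[case, "subject_id"].to_numpy(),
            "biotype": model.case_labels + 1,
        }
    )
    write_tsv(rc.path("biotype_assignments.tsv"), assign)
    write_tsv(
        rc.path("split_half.tsv"),
        hydmod.split_half_validate(
            X, case, tuple(hcfg["k_grid"]), n_splits=hcfg["n_splits"], seed=seed + 2,
            n_restarts=hcfg["n_restarts"], C=hcfg["C"],
        ),
    )

    # clinical profiles across biotypes
    bio = model.case_labels + 1
    clinical = {}
    for score in ("inattention", "hyperactivity"):
        vals = cohort.loc[case, score].to_numpy()
        clinical[score] = {
            "kruskal_wallis": statmod.kruskal_wallis(vals, bio),
            "posthoc": statmod.posthoc_pairwise(vals, bio).to_dict(orient="records"),
            "group_means": {str(k): float(vals[bio == k].mean()) for k in np.unique(bio)},
        }
    write_json(rc.path("clinical_stats.json"), clinical)

    # biotype-wise extreme-deviation frequency differences per node
    case_idx = np.where(case)[0]
    sub = DeviationTensor(
        z=devs.z[case_idx], metric_names=devs.metric_names,
        subject_ids=[devs.subject_ids[i] for i in case_idx],
    )
    for name in METRIC_NAMES:
        write_tsv(
            rc.path(f"biotype_chisq_{name}.tsv"),
            devmod.biotype_node_chisq(sub, bio, name, rc.cfg["deviations"]["direction"]),
        )


def _stage_decode(rc: RunConfig) -> None:
    dcfg = rc.cfg["decode"]
    seed = stage_seed(rc.seed, "decode")
    devs, cohort = _load_deviations(rc)
    geometry = _load_geometry(rc)
    assign = read_tsv(rc.path("biotype_assignments.tsv"))
    ann_df = read_tsv(rc.path("annotations.tsv"))
    term_df = read_tsv(rc.path("term_maps.tsv"))
    annotations = [
        AnnotationMap(name=c, values=ann_df[c].to_numpy())
        for c in ann_df.columns
        if c != "region_index"
    ]
    term_names = [c for c in term_df.columns if c != "region_index"]
    term_maps = term_df[term_names].to_numpy()

    cohort = cohort.merge(assign, on="subject_id", how="left")
    ctrl = (cohort["group"] == "control").to_numpy()
    summary = {}
    for k in sorted(assign["biotype"].unique()):
        members = (cohort["biotype"] == k).to_numpy()
        diff_maps = []
        for m, name in enumerate(METRIC_NAMES):
            bmap = devmod.overlap_map(devs, members, m, rc.cfg["deviations"]["direction"])
            cmap = devmod.overlap_map(devs, ctrl, m, rc.cfg["deviations"]["direction"])
            diff_maps.append(devmod.difference_map(bmap, cmap))
        fused = decmod.fuse_maps(diff_maps)
        ann_table = decmod.annotation_correlation(
            fused,
            annotations,
            geometry,
            n_surrogates=dcfg["n_surrogates"],
            seed=seed + 10 * k,
            method=dcfg["method"],
        )
        write_tsv(rc.path(f"decode_annotations_biotype{k}.tsv"), ann_table)
        pls = decmod.pls_decode(
            fused,
            term_maps,
            term_names,
            geometry,
            n_boot=dcfg["n_boot"],
            n_surrogates=dcfg["n_surrogates"],
            seed=seed + 10 * k + 1,
        )
        write_tsv(rc.path(f"decode_pls_biotype{k}.tsv"), pls.component_weights)
        summary[str(k)] = {
            "n_significant_annotations": int(ann_table["significant_fdr"].sum()),
            "pls_explained_variance": pls.explained_variance,
            "pls_p_spin": pls.p_spin,
        }
    write_json(rc.path("decode_summary.json"), summary)


def _stage_transfer(rc: RunConfig) -> None:
    seed = stage_seed(rc.seed, "transfer")
    models = [
        [NormativeModel.from_dict(d) for d in row]
        for row in read_json(rc.path("normative_models.json"))
    ]
    Y, vcohort = _topology_tensor(rc, "validation/")
    age = vcohort["age"].to_numpy()
    sex = vcohort["sex"].to_numpy()
    ctrl = (vcohort["group"] == "control").to_numpy()
    sites = vcohort["site"].to_numpy()
    R, M = Y.shape[1], Y.shape[2]
    z = np.empty_like(Y)
    for s in np.unique(sites):
        s_mask = sites == s
        adapt = s_mask & ctrl
        for r in range(R):
            for m in range(M):
                recal = transfer_recalibrate(
                    models[r][m], Y[adapt, r, m], age[adapt], sex[adapt], site=str(s)
                )
                z[s_mask, r, m] = deviation_z(recal, Y[s_mask, r, m], age[s_mask], sex[s_mask])
    devs = DeviationTensor(
        z=z, metric_names=METRIC_NAMES, subject_ids=vcohort["subject_id"].tolist()
    )
    write_tsv(rc.path("validation/deviations.tsv"), _deviations_long(devs))

    model = hydmod.HydraModel.from_dict(read_json(rc.path("hydra_model.json")))
    X, names = devs.flatten_features()
    if names != model.feature_names:
        raise ValueError("validation features do not match the pretrained model")
    case = (vcohort["group"] == "case").to_numpy()
    scores = hydmod.expression_scores(model, X[case], feature_names=names)
    assign = scores.assignment + 1
    write_tsv(
        rc.path("validation/biotype_assignments.tsv"),
        pd.DataFrame(
            {"subject_id": vcohort.loc[case, "subject_id"].to_numpy(), "biotype": assign}
        ),
    )

    # agreement with a freshly trained model on the validation cohort
    fresh = hydmod.fit_hydra(
        X, case, model.k, n_restarts=10, seed=seed, C=model.regularization
    )
    from sklearn.metrics import adjusted_rand_score

    ari_fresh = adjusted_rand_score(fresh.case_labels, assign)

    # per-biotype mean deviation-vector correlation between cohorts
    disc_devs, disc_cohort = _load_deviations(rc)
    disc_assign = read_tsv(rc.path("biotype_assignments.tsv"))
    disc = disc_cohort.merge(disc_assign, on="subject_id", how="left")
    Xd, _ = disc_devs.flatten_features()
    correlations = {}
    for k in range(1, model.k + 1):
        a = Xd[(disc["biotype"] == k).to_numpy()].mean(axis=0)
        b = X[case][assign == k].mean(axis=0) if np.any(assign == k) else None
        correlations[str(k)] = (
            None if b is None else float(np.corrcoef(a, b)[0, 1])
        )

    clinical = {}
    for score in ("inattention", "hyperactivity"):
        vals = vcohort.loc[case, score].to_numpy()
        clinical[score] = statmod.kruskal_wallis(vals, assign)

    write_json(
        rc.path("transfer_report.json"),
        {
            "biotype_sizes": {str(k): int(np.sum(assign == k)) for k in range(1, model.k + 1)},
            "ari_vs_fresh_model": float(ari_fresh),
            "biotype_feature_correlations": correlations,
            "clinical": clinical,
        },
    )


def _stage_report(rc: RunConfig) -> None:
    lines = ["# Pipeline report", ""]
    cohort = read_tsv(rc.path("cohort.tsv"))
    lines += [
        "## Cohort",
        "",
        f"- {int((cohort['group'] == 'control').sum())} controls, "
        f"{int((cohort['group'] == 'case').sum())} cases over "
        f"{cohort['site'].nunique()} sites",
        f"- age {cohort['age'].min():.1f}-{cohort['age'].max():.1f} years, "
        f"{100 * cohort['sex'].mean():.0f}% male",
        "",
    ]
    site = read_json(rc.path("site_check.json"))
    lines += [
        "## Normative deviations",
        "",
        f"- site-prediction balanced accuracy {site['balanced_accuracy']:.3f} "
        f"(chance {site['chance']:.3f})",
        "",
        "### Extreme-deviation burden (case vs control)",
        "",
        read_tsv(rc.path("burden.tsv")).to_markdown(index=False),
        "",
    ]
    for name in METRIC_NAMES:
        d = read_tsv(rc.path(f"diffmap_{name}.tsv"))
        top = d.reindex(d["difference_pct"].abs().sort_values(ascending=False).index).head(5)
        lines += [
            f"### Top case-control difference nodes — {name}",
            "",
            top.to_markdown(index=False),
            "",
        ]
    fus = read_json(rc.path("fusion.json"))
    lines += [
        "## Fusion (mCCA+jICA)",
        "",
        f"- {fus['n_components']} components; explained variance "
        + ", ".join(f"{v:.1%}" for v in fus["explained_variance"])
        + f"; joint group-differentiating components: {fus['joint_components']}",
        "",
    ]
    ksel = read_tsv(rc.path("k_selection.tsv"))
    clin = read_json(rc.path("clinical_stats.json"))
    lines += ["## Biotypes", "", ksel.to_markdown(index=False), ""]
    for score, entry in clin.items():
        kw = entry["kruskal_wallis"]
        lines += [
            f"- {score}: H = {kw['H']:.2f}, eta^2 = {kw['eta_squared']:.3f}, p = {kw['p']:.3g}; "
            f"biotype means "
            + ", ".join(f"{k}: {v:.2f}" for k, v in entry["group_means"].items()),
        ]
    lines += [""]
    dec = read_json(rc.path("decode_summary.json"))
    lines += ["## Decoding", ""]
    for k, entry in dec.items():
        lines += [
            f"- biotype {k}: {entry['n_significant_annotations']} spin-FDR-significant "
            f"annotation correlations; PLS explained variance "
            f"{entry['pls_explained_variance']:.1%} (spin p = {entry['pls_p_spin']:.3g})",
        ]
    tr = read_json(rc.path("transfer_report.json"))
    lines += [
        "",
        "## Transfer validation",
        "",
        f"- biotype sizes {tr['biotype_sizes']}",
        f"- ARI vs freshly trained model {tr['ari_vs_fresh_model']:.3f}",
        f"- per-biotype feature-vector correlations {tr['biotype_feature_correlations']}",
        "",
    ]
    rc.path("report.md").write_text("\n".join(lines))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "msn": _stage_msn,
    "topology": _stage_topology,
    "normative": _stage_normative,
    "deviations": _stage_deviations,
    "fuse": _stage_fuse,
    "cluster": _stage_cluster,
    "decode": _stage_decode,
    "transfer": _stage_transfer,
    "report": _stage_report,
}

# stage -> (input artifacts, output artifacts), workspace-relative
STAGE_IO: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "simulate": (
        (),
        (
            "cohort.tsv",
            "samples.zip",
            "geometry.json",
            "ground_truth.json",
            "annotations.tsv",
            "term_maps.tsv",
            "validation/cohort.tsv",
            "validation/samples.zip",
            "validation/ground_truth.json",
        ),
    ),
    "msn": (("samples.zip", "validation/samples.zip"), ("msn.zip", "validation/msn.zip")),
    "topology": (
        ("msn.zip", "validation/msn.zip", "cohort.tsv", "validation/cohort.tsv"),
        ("partition.json", "topology.tsv", "validation/topology.tsv"),
    ),
    "normative": (
        ("topology.tsv", "cohort.tsv"),
        ("normative_models.json", "deviations.tsv", "site_check.json"),
    ),
    "deviations": (
        ("deviations.tsv", "cohort.tsv", "geometry.json"),
        tuple(f"diffmap_{n}.tsv" for n in METRIC_NAMES) + ("burden.tsv",),
    ),
    "fuse": (
        ("deviations.tsv", "cohort.tsv"),
        ("fusion.json", "fusion_group_test.tsv", "fusion_matrices.zip"),
    ),
    "cluster": (
        ("deviations.tsv", "cohort.tsv"),
        (
            "k_selection.tsv",
            "hydra_model.json",
            "biotype_assignments.tsv",
            "split_half.tsv",
            "clinical_stats.json",
        )
        + tuple(f"biotype_chisq_{n}.tsv" for n in METRIC_NAMES),
    ),
    "decode": (
        (
            "deviations.tsv",
            "cohort.tsv",
            "geometry.json",
            "biotype_assignments.tsv",
            "annotations.tsv",
            "term_maps.tsv",
        ),
        ("decode_summary.json",),
    ),
    "transfer": (
        (
            "normative_models.json",
            "hydra_model.json",
            "validation/topology.tsv",
            "validation/cohort.tsv",
            "deviations.tsv",
            "biotype_assignments.tsv",
        ),
        (
            "validation/deviations.tsv",
            "validation/biotype_assignments.tsv",
            "transfer_report.json",
        ),
    ),
    "report": (
        (
            "cohort.tsv",
            "site_check.json",
            "burden.tsv",
            "fusion.json",
            "k_selection.tsv",
            "clinical_stats.json",
            "decode_summary.json",
            "transfer_report.json",
        ),
        ("report.md",),
    ),
}


def _versions() -> dict:
    import networkx
    import scipy
    import sklearn

    return {
        "msnbiotype": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Stages whose inputs and config are unchanged and whose outputs exist
    are skipped.  The manifest (config hash, per-stage input/output
    checksums, versions) is written to ``manifest.json``; wall-clock
    timings go to ``timings.json`` so the manifest stays reproducible.
    """
    ws = config.workspace
    ws.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.cfg)
    manifest_path = ws / "manifest.json"
    manifest = read_json(manifest_path) if manifest_path.exists() else {}
    if manifest.get("config_hash") != chash:
        manifest = {}
    manifest.setdefault("config_hash", chash)
    manifest.setdefault("versions", _versions())
    manifest.setdefault("stages", {})
    timings: dict[str, float] = {}

    for stage in config.stages:
        inputs, outputs = STAGE_IO[stage]
        for rel in inputs:
            if not (ws / rel).exists():
                raise FileNotFoundError(
                    f"stage {stage!r}: missing input {rel} (run its producer first)"
                )
        in_hashes = {rel: sha256_file(ws / rel) for rel in inputs}
        prev = manifest["stages"].get(stage)
        if (
            prev is not None
            and prev["inputs"] == in_hashes
            and all((ws / rel).exists() for rel in outputs)
            and prev["outputs"] == {rel: sha256_file(ws / rel) for rel in outputs}
        ):
            log.info("stage %s: up to date, skipping", stage)
            continue
        log.info("stage %s: running", stage)
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed in workspace {ws}: {err}") from err
        timings[stage] = round(time.perf_counter() - t0, 3)
        out_hashes = {rel: sha256_file(ws / rel) for rel in outputs}
        manifest["stages"][stage] = {"inputs": in_hashes, "outputs": out_hashes}
        write_json(manifest_path, manifest)

    write_json(manifest_path, manifest)
    old_timings = read_json(ws / "timings.json") if (ws / "timings.json").exists() else {}
    old_timings.update(timings)
    write_json(ws / "timings.json", old_timings)
    return manifest
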