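"""End-to-end orchestration of the synthetic multi-omic analysis.

Stages run in dependency order on files under one output directory:

    simulate -> de -> enrich -> deconv -> nmr -> classify -> measures -> correlate

Each stage reads the files earlier stages wrote, so any stage can be re-run
in isolation, and a missing dependency surfaces as an actionable error. A
manifest (parameters, seed, SHA-256 checksums of every output) makes a run
reproducible: the same config and seed give identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlation, de, deconv, enrichment, io, measures, nmr, rdcv, synthetic

log = logging.getLogger("renofao")

STAGES = ("simulate", "de", "enrich", "deconv", "nmr", "classify", "measures", "correlate")


@dataclass
class PipelineConfig:
    outdir: str = "renofao_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # DEG thresholds
    fc: float = de.DEFAULT_FC
    alpha: float = de.DEFAULT_ALPHA
    # NMR processing
    baseline_window: int = 1000
    baseline_quantile: float = 0.1
    baseline_step: int = 500
    min_snr: float = 5.0
    group_tolerance: float = nmr.DEFAULT_GROUP_TOLERANCE
    silhouette_threshold: float = nmr.SILHOUETTE_THRESHOLD
    # classifier (scaled-down defaults for the synthetic end-to-end run)
    n_outer: int = 5
    n_rep: int = 10
    var_ratio: float = 0.85
    n_trees: int = 100
    # correlation network
    min_abs_r: float = correlation.MIN_ABS_R
    k_clusters: int = 2
    # generator
    synthetic_config: synthetic.SyntheticStudyConfig | None = None

    def generator(self) -> synthetic.SyntheticStudyConfig:
        if self.synthetic_config is not None:
            return self.synthetic_config
        return synthetic.SyntheticStudyConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _require(path: Path, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {needed_by!r} needs {path.name}, which no earlier stage produced; "
            f"enable the stage that writes it or provide the file"
        )
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    gen = cfg.generator()
    written = []
    for model in ("ZDF", "ZDSD"):
        cm, truth = synthetic.generate_count_study(gen, model)
        io.write_counts(cm, out / f"counts_{model}.tsv", out / f"metadata_{model}.tsv")
        truth.to_json(out / f"truth_counts_{model}.json")
        written += [out / f"counts_{model}.tsv", out / f"metadata_{model}.tsv",
                    out / f"truth_counts_{model}.json"]
    atlas, atruth = synthetic.generate_atlas(gen)
    io.write_atlas(atlas, out / "atlas.tsv")
    atruth.to_json(out / "truth_atlas.json")
    net, ntruth = synthetic.generate_drug_networks(gen)
    io.write_network(net, out / "drug_networks.tsv")
    ntruth.to_json(out / "truth_networks.json")
    # animal-matched urinary cohort for the ZDSD arm
    zdsd_meta = pd.read_csv(out / "metadata_ZDSD.tsv", sep="\t", index_col=0)
    sizes = zdsd_meta["group"].value_counts().to_dict()
    ordered_sizes = {g: sizes[g] for g in synthetic.GROUPS}
    ids = [sid for g in synthetic.GROUPS for sid in zdsd_meta.index[zdsd_meta["group"] == g]]
    spectra, struth = synthetic.generate_nmr_cohort(gen, group_sizes=ordered_sizes,
                                                    sample_ids=ids)
    io.write_spectra(spectra, out / "spectra.csv", out / "spectra_metadata.tsv")
    struth.to_json(out / "truth_nmr.json")
    ids_by_group = {g: [s for s in ids if zdsd_meta.loc[s, "group"] == g]
                    for g in synthetic.GROUPS}
    gen.morphometry.n_per_group = {g: len(v) for g, v in ids_by_group.items()}
    morph, mtruth = synthetic.generate_morphometry(gen, animal_ids=ids_by_group)
    morph.to_csv(out / "morphometry.tsv", sep="\t", index=False)
    mtruth.to_json(out / "truth_morphometry.json")
    written += [out / "atlas.tsv", out / "truth_atlas.json", out / "drug_networks.tsv",
                out / "truth_networks.json", out / "spectra.csv",
                out / "spectra_metadata.tsv", out / "truth_nmr.json",
                out / "morphometry.tsv", out / "truth_morphometry.json"]
    return written


def stage_de(cfg: PipelineConfig, out: Path) -> list[Path]:
    written = []
    degsets = {}
    for model in ("ZDF", "ZDSD"):
        cm = io.read_counts(_require(out / f"counts_{model}.tsv", "de"),
                            _require(out / f"metadata_{model}.tsv", "de"))
        sf = de.estimate_size_factors(cm)
        disp = de.estimate_dispersion(cm, sf)
        for contrast in (("DMT", "SHAM"), ("SHAM", "healthy")):
            res = de.wald_test(cm, contrast, sf, disp)
            label = f"{model}_{contrast[0]}_vs_{contrast[1]}"
            res.to_csv(out / f"de_{label}.tsv", sep="\t")
            degs = de.call_degs(res, cfg.fc, cfg.alpha)
            io.write_degset(degs, out / f"degs_{label}.json")
            degsets[label] = degs
            written += [out / f"de_{label}.tsv", out / f"degs_{label}.json"]
        rlog = de.rlog_like_transform(cm, sf)
        rlog.to_csv(out / f"rlog_{model}.tsv", sep="\t")
        written.append(out / f"rlog_{model}.tsv")
    conc = de.concordant_degs(degsets["ZDF_DMT_vs_SHAM"], degsets["ZDSD_DMT_vs_SHAM"])
    io.write_degset(conc, out / "degs_concordant.json")
    summary = {}
    for model in ("ZDF", "ZDSD"):
        n, pct = de.corrected_fraction(degsets[f"{model}_SHAM_vs_healthy"],
                                       degsets[f"{model}_DMT_vs_SHAM"])
        summary[model] = {
            "n_disease": len(degsets[f"{model}_SHAM_vs_healthy"]),
            "n_treatment": len(degsets[f"{model}_DMT_vs_SHAM"]),
            "n_corrected": n, "pct_corrected": pct,
        }
    summary["n_concordant"] = len(conc)
    io.write_json(summary, out / "de_summary.json")
    return written + [out / "degs_concordant.json", out / "de_summary.json"]


def stage_enrich(cfg: PipelineConfig, out: Path) -> list[Path]:
    gen = cfg.generator()
    conc = io.read_degset(_require(out / "degs_concordant.json", "enrich"))
    universe = set(gen.gene_ids)
    rng = np.random.default_rng(gen.seed + 17)
    collection = enrichment.GeneSetCollection(
        sets={
            "FAO_pathway": set(gen.fao_module.genes),
            "fibrosis_pathway": set(gen.fibrosis_module.genes),
            "random_A": set(rng.choice(sorted(universe), 60, replace=False)),
            "random_B": set(rng.choice(sorted(universe), 60, replace=False)),
        },
        universe=universe,
    )
    up = {g for g, d in conc.directions.items() if d == "up"}
    down = {g for g, d in conc.directions.items() if d == "down"}
    queries = {k: v for k, v in {"up": up, "down": down}.items() if v}
    table = enrichment.compare_clusters(queries, collection)
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    net = io.read_network(_require(out / "drug_networks.tsv", "enrich"))
    zdsd = io.read_degset(_require(out / "degs_ZDSD_DMT_vs_SHAM.json", "enrich"))
    calls = {}
    for isotype in deconv.PPAR_ISOTYPES:
        call = enrichment.regulator_activation_score(net.signs[isotype], zdsd, isotype)
        calls[isotype] = {"n": call.n_overlap, "z": call.z, "state": call.state}
    io.write_json(calls, out / "regulator_calls.json")
    return [out / "enrichment.tsv", out / "regulator_calls.json"]


def stage_deconv(cfg: PipelineConfig, out: Path) -> list[Path]:
    atlas = io.read_atlas(_require(out / "atlas.tsv", "deconv"))
    net = io.read_network(_require(out / "drug_networks.tsv", "deconv"))
    conc = io.read_degset(_require(out / "degs_concordant.json", "deconv"))
    loc = deconv.localize_features(conc.genes, atlas)
    loc.to_csv(out / "localization.tsv", sep="\t")
    drug_net = deconv.DrugTargetNetwork(
        {e: net.targets[e] for e in deconv.DRUGS})
    ppar_net = deconv.DrugTargetNetwork(
        {e: net.targets[e] for e in deconv.PPAR_ISOTYPES})
    strat = {
        "fenofibrate": deconv.stratify_by_responsiveness(conc, drug_net, atlas, "fenofibrate"),
        "PPARA": deconv.stratify_by_responsiveness(conc, ppar_net, atlas, "PPARA"),
    }
    io.write_json(strat, out / "stratification.json")
    venn = deconv.multiway_overlap(
        {d: net.targets[d] & conc.genes for d in deconv.DRUGS
         if net.targets[d] & conc.genes}
    ) if any(net.targets[d] & conc.genes for d in deconv.DRUGS) else pd.DataFrame()
    venn.to_csv(out / "venn.tsv", sep="\t", index=False)
    return [out / "localization.tsv", out / "stratification.json", out / "venn.tsv"]


def stage_nmr(cfg: PipelineConfig, out: Path) -> list[Path]:
    spectra = io.read_spectra(_require(out / "spectra.csv", "nmr"),
                              _require(out / "spectra_metadata.tsv", "nmr"))
    result = nmr.process_cohort(
        spectra,
        window=cfg.baseline_window, quantile=cfg.baseline_quantile,
        step=cfg.baseline_step, min_snr=cfg.min_snr,
        tolerance=cfg.group_tolerance,
        silhouette_threshold=cfg.silhouette_threshold,
    )
    result["members"].to_csv(out / "peak_members.tsv", sep="\t", index=False)
    result["matrix"].to_csv(out / "intensity_matrix.csv")
    result["normalized"].to_csv(out / "intensity_matrix_pqn.csv")
    result["factors"].to_csv(out / "pqn_factors.tsv", sep="\t")
    return [out / "peak_members.tsv", out / "intensity_matrix.csv",
            out / "intensity_matrix_pqn.csv", out / "pqn_factors.tsv"]


def stage_classify(cfg: PipelineConfig, out: Path) -> list[Path]:
    matrix = pd.read_csv(
        _require(out / "intensity_matrix_pqn.csv", "classify"), index_col=0)
    meta = pd.read_csv(out / "spectra_metadata.tsv", sep="\t").set_index("sample_id")
    groups = meta.loc[matrix.index, "group"]
    keep = groups.isin(["DMT", "SHAM"])
    X = matrix.loc[keep]
    y = groups[keep]
    config = rdcv.RDCVConfig(n_outer=cfg.n_outer, n_rep=cfg.n_rep,
                             var_ratio=cfg.var_ratio, n_trees=cfg.n_trees,
                             seed=cfg.seed)
    result = rdcv.fit_rdcv(X, y, config)
    rdcv.rank_variables(result, "max").to_csv(out / "rdcv_ranking.tsv", sep="\t", index=False)
    result.probabilities.to_csv(out / "rdcv_probabilities.tsv", sep="\t")
    cm = rdcv.confusion_metrics(result.y.to_numpy(),
                                result.predicted["max"].to_numpy())
    io.write_json(
        {
            "classes": result.classes,
            "n_min": result.n_min, "n_mid": result.n_mid, "n_max": result.n_max,
            "selected_max": result.selected["max"],
            "misclassifications": result.misclassifications,
            "auc": result.auc,
            "confusion_max": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                              "sensitivity": cm.sensitivity,
                              "specificity": cm.specificity},
            "error_curve": {int(k): float(v) for k, v in result.error_curve.items()},
        },
        out / "rdcv_result.json",
    )
    return [out / "rdcv_ranking.tsv", out / "rdcv_probabilities.tsv",
            out / "rdcv_result.json"]


def stage_measures(cfg: PipelineConfig, out: Path) -> list[Path]:
    morph = pd.read_csv(_require(out / "morphometry.tsv", "measures"), sep="\t")
    morph["glomerular_volume"] = measures.glomerular_volume(morph["glomerular_area"])
    morph["pfpd"] = measures.pfpd_from_pfpf(morph["pfpf"])
    morph["mito_roundness"] = measures.roundness(morph["mito_area"], morph["mito_major"])
    morph.to_csv(out / "morphometry_derived.tsv", sep="\t", index=False)
    return [out / "morphometry_derived.tsv"]


def stage_correlate(cfg: PipelineConfig, out: Path) -> list[Path]:
    gen = cfg.generator()
    morph = pd.read_csv(_require(out / "morphometry_derived.tsv", "correlate"),
                        sep="\t").set_index("animal_id")
    rlog = pd.read_csv(_require(out / "rlog_ZDSD.tsv", "correlate"),
                       sep="\t", index_col=0)
    pqn = pd.read_csv(_require(out / "intensity_matrix_pqn.csv", "correlate"),
                      index_col=0)
    pqn.columns = pqn.columns.astype(float)

    animals = [a for a in morph.index if a in rlog.columns and a in pqn.index]
    struct = morph.loc[
        animals, ["glomerular_volume", "gbm_thickness", "pfpd", "mito_roundness"]]
    fao_genes = list(gen.fao_module.genes[:5])
    trans = rlog.loc[fao_genes, animals].T.add_prefix("fao_")
    met_cols = {}
    for fam in ("nicotinamide", "tca", "clearance"):
        for p in gen.nmr_specs.family_ppm[fam]:
            near = min(pqn.columns, key=lambda c: abs(c - p))
            if abs(near - p) <= 4 * cfg.group_tolerance:
                met_cols[f"{fam}_{p:.2f}"] = near
    mets = pd.DataFrame({name: pqn.loc[animals, col] for name, col in met_cols.items()},
                        index=animals)

    table = pd.concat([struct, trans, mets], axis=1)
    types = pd.Series(
        {**{c: "structure" for c in struct.columns},
         **{c: "transcript" for c in trans.columns},
         **{c: "metabolite" for c in mets.columns}}
    )
    ft = correlation.FeatureTable(table, types)
    corr = correlation.pearson_matrix(ft)
    g = correlation.threshold_network(corr, cfg.min_abs_r, types)
    layout = correlation.mds_cluster(corr, cfg.k_clusters)
    edges, nodes = correlation.network_tables(g, layout)
    corr.to_csv(out / "correlation_matrix.tsv", sep="\t")
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    nodes.to_csv(out / "network_nodes.tsv", sep="\t")
    return [out / "correlation_matrix.tsv", out / "network_edges.tsv",
            out / "network_nodes.tsv"]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "de": stage_de,
    "enrich": stage_enrich,
    "deconv": stage_deconv,
    "nmr": stage_nmr,
    "classify": stage_classify,
    "measures": stage_measures,
    "correlate": stage_correlate,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the manifest."""
    unknown = set(cfg.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items()
            if k not in ("synthetic_config",) and not isinstance(v, dict)
        },
        "stages": {},
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        log.info("running stage %s", stage)
        files = _STAGE_FUNCS[stage](cfg, out)
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in files}
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(cfg: PipelineConfig) -> dict:
    """Schema-check declared input files; report errors without raising."""
    out = Path(cfg.outdir)
    errors: list[str] = []
    warnings_: list[str] = []
    counts_info = {}
    for model in ("ZDF", "ZDSD"):
        cpath, mpath = out / f"counts_{model}.tsv", out / f"metadata_{model}.tsv"
        if not cpath.exists():
            continue
        df = pd.read_csv(cpath, sep="\t", index_col=0)
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            errors.append(f"{cpath.name}: duplicate gene id {dup!r}")
        if (df.to_numpy() < 0).any():
            errors.append(f"{cpath.name}: negative counts")
        if mpath.exists():
            meta = pd.read_csv(mpath, sep="\t", index_col=0)
            missing = set(df.columns) - set(meta.index)
            if missing:
                errors.append(f"{mpath.name}: samples without metadata {sorted(missing)}")
        counts_info[model] = {"genes": df.shape[0], "samples": df.shape[1]}
    spath = out / "spectra.csv"
    if spath.exists():
        wide = pd.read_csv(spath)
        ppm = wide.iloc[:, 0].to_numpy()
        d = np.diff(ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            errors.append("spectra.csv: ppm axis not strictly monotone")
        counts_info["spectra"] = {"points": len(ppm), "samples": wide.shape[1] - 1}
    apath = out / "atlas.tsv"
    if apath.exists():
        df = pd.read_csv(apath, sep="\t", index_col=0)
        missing_ct = [c for c in deconv.CELL_TYPES if c not in df.columns]
        if missing_ct:
            errors.append(f"atlas.tsv: missing cell types {missing_ct}")
    return {"errors": errors, "warnings": warnings_, "counts": counts_info}
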