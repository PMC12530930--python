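"""End-to-end orchestration: simulate -> process -> fingerprint ->
chemometrics -> classify -> stats, with artifact CSVs and a reproducible
run report.

A single global seed fans out to each stochastic stage through a
counter-based ``SeedSequence`` scheme, so disabling one stage never
perturbs another stage's random stream.  Every headline number in the
report is recomputable from the stored artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import classification as cls
from . import fingerprint as fp
from . import io as spio
from . import processing as proc
from . import stats as spstats
from .containers import Chromatogram, PeakTable
from .exceptions import MissingStageInputError
from .simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_external_samples,
    simulate_qc_replicates,
    simulate_soil_properties,
)

logger = logging.getLogger("soilprint")

STAGES = ("simulate", "process", "fingerprint", "chemometrics", "classify",
          "stats")

_STAGE_SEED_KEY = {name: i for i, name in enumerate(
    ("simulate", "external", "qc", "soil", "permutation"))}


def stage_seed(global_seed: int, stage: str) -> int:
    """Counter-based per-stage seed derived from the global seed."""
    key = _STAGE_SEED_KEY[stage]
    ss = np.random.SeedSequence(global_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All knobs of an end-to-end run; keys mirror the YAML config."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = STAGES
    window_min: tuple[float, float] = proc.DEFAULT_WINDOW_MIN
    snr_min: float = 10.0
    min_width_points: int = 5
    baseline_method: str = "asls"
    n_anchors: int = 5
    anchor_coarse_tol_min: float = 0.2
    match_tol_min: float = fp.DEFAULT_MATCH_TOL_MIN
    presence: float = 1.0
    similarity_metrics: tuple[str, ...] = ("pearson", "cosine")
    normalize_total_area: bool = False
    pls_components: int | None = None
    cv_folds: int = 7
    n_permutations: int = 200
    vip_cut: float = 1.0
    p_cut: float = 0.05
    lda_regularization: tuple = ("shrinkage", 0.01)
    cv_scheme: tuple = ("loo",)
    hca_linkage: str = "ward"
    alpha: float = 0.05
    external_groups: tuple[str, ...] = ("MT I", "MT I", "MT I", "QT")
    n_qc_replicates: int = 5
    seed: int = 0
    outdir: str = "soilprint_run"
    figures: bool = False

    def __post_init__(self):
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        # global seed drives the simulation unless one was set explicitly
        if self.simulation.seed == 0 and self.seed != 0:
            self.simulation.seed = stage_seed(self.seed, "simulate")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        for key in ("stages", "window_min", "similarity_metrics",
                    "lda_regularization", "cv_scheme", "external_groups"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d


# --------------------------------------------------------------------------
# discriminant-function rendering

def render_discriminant_functions(model: cls.LDAModel, decimals: int = 3
                                  ) -> str:
    """One ``Yk = c1*X.. +/- ... +/- intercept`` line per class, in the
    conventional printed layout (signed terms, trailing intercept)."""
    lines = []
    for k, label in enumerate(model.classes):
        terms = []
        for j, (coef, feat) in enumerate(
                zip(model.coefficients[k], model.feature_ids)):
            if j == 0:
                terms.append(f"{coef:.{decimals}f}{feat}")
            else:
                terms.append(f"{coef:+.{decimals}f}{feat}")
        terms.append(f"{model.intercepts[k]:+.{decimals}f}")
        lines.append(f"Y{k + 1}=" + "".join(terms) + f"  ({label})")
    return "\n".join(lines)


def parse_discriminant_functions(text: str) -> dict[int, tuple[dict, float]]:
    """Inverse of :func:`render_discriminant_functions`: per function index,
    a (feature -> coefficient) mapping and the intercept."""
    out = {}
    for line in text.strip().splitlines():
        m = re.match(r"\s*Y(\d+)\s*=\s*(.*)", line)
        if not m:
            continue
        idx = int(m.group(1))
        body = m.group(2).split("  (")[0]
        coeffs = {}
        intercept = 0.0
        for num, feat in re.findall(r"([+-]?\d+(?:\.\d+)?)(X\d+)?", body):
            if not num:
                continue
            if feat:
                coeffs[feat] = float(num)
            else:
                intercept = float(num)
        out[idx] = (coeffs, intercept)
    return out


# --------------------------------------------------------------------------
# stage helpers (usable directly from Python)

def process_chromatograms(chroms: list[Chromatogram], config: RunConfig
                          ) -> list[PeakTable]:
    """Baseline-correct and integrate every chromatogram."""
    tables = []
    for c in chroms:
        corrected = proc.correct_baseline(c, method=config.baseline_method)
        tables.append(proc.detect_peaks(
            corrected, window_min=config.window_min, snr_min=config.snr_min,
            min_width_points=config.min_width_points))
    return tables


def build_fingerprint(tables: list[PeakTable], config: RunConfig):
    """Align, match and reduce peak tables to the common-peak matrix,
    reference fingerprint and similarity report."""
    aligned = fp.align_tables(tables, k=config.n_anchors,
                              coarse_tol_min=config.anchor_coarse_tol_min)
    candidate = fp.match_peaks(aligned, config.match_tol_min)
    matrix = fp.common_peaks(candidate, presence=config.presence)
    reference = fp.reference_fingerprint(matrix)
    sim = fp.similarity_report(matrix, reference,
                               metrics=config.similarity_metrics,
                               normalize_total_area=config.normalize_total_area)
    return aligned, matrix, reference, sim


def extract_feature_vector(table: PeakTable, consensus_rts: np.ndarray,
                           tol_min: float,
                           fallback: np.ndarray | None = None) -> np.ndarray:
    """Areas of the peaks nearest each consensus RT (within tolerance).

    A consensus position with no matching peak falls back to the supplied
    per-peak fallback (typically the reference mean), with a warning.
    """
    apexes = table.apex_rts
    areas = table.areas
    out = np.empty(len(consensus_rts))
    missing = []
    for i, rt in enumerate(consensus_rts):
        j = int(np.argmin(np.abs(apexes - rt)))
        if abs(apexes[j] - rt) <= tol_min:
            out[i] = areas[j]
        else:
            missing.append(i)
            out[i] = np.nan
    if missing:
        if fallback is None:
            raise MissingStageInputError(
                f"sample {table.sample_id}: no peak near consensus position(s) "
                f"{missing} and no fallback given")
        warnings.warn(
            f"sample {table.sample_id}: filling {len(missing)} missing common "
            "peak(s) from the reference fingerprint", stacklevel=2)
        out[missing] = np.asarray(fallback)[missing]
    return out


def _hash_file(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# the pipeline

def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    All intermediate artifacts are written as CSV under ``config.outdir``;
    the report is saved both as sorted-key JSON and as readable text.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    report: dict = {"config": config.to_dict(), "artifacts": {},
                    "headline": {}}

    def record(name: str, path: Path):
        report["artifacts"][name] = {"path": str(path),
                                     "md5": _hash_file(path)}

    enabled = config.stages
    for stage in enabled:
        logger.info("stage %s: start", stage)
        _STAGE_FUNCS[stage](config, state, report, outdir, record)
        logger.info("stage %s: done", stage)

    report_json = json.dumps(report, sort_keys=True, indent=2, default=str)
    (outdir / "report.json").write_text(report_json)
    (outdir / "report.txt").write_text(_render_report_text(report))
    return report


def _stage_simulate(config, state, report, outdir, record):
    chroms, truth = simulate_cohort(config.simulation)
    ext_chroms, ext_truth = simulate_external_samples(
        config.simulation, groups=config.external_groups)
    qc = simulate_qc_replicates(config.simulation,
                                n_replicates=config.n_qc_replicates)
    soil = simulate_soil_properties(
        seed=stage_seed(config.seed, "soil"),
        sample_ids=truth.sample_ids)
    state.update(chroms=chroms, truth=truth, ext_chroms=ext_chroms,
                 ext_truth=ext_truth, qc=qc, soil=soil)
    spio.write_ground_truth_csv(truth, outdir / "ground_truth.csv")
    record("ground_truth", outdir / "ground_truth.csv")
    soil.to_csv(outdir / "soil_properties.csv", index=False)
    record("soil_properties", outdir / "soil_properties.csv")
    for c in chroms[:1]:  # store one example trace; the rest are re-derivable
        spio.write_chromatogram_csv(c, outdir / "chromatogram_S1.csv")
        record("chromatogram_S1", outdir / "chromatogram_S1.csv")
    report["headline"]["n_samples"] = len(chroms)


def _stage_process(config, state, report, outdir, record):
    if "chroms" not in state:
        raise MissingStageInputError(
            "process stage needs chromatograms; enable 'simulate' or load them"
        )
    state["tables"] = process_chromatograms(state["chroms"], config)
    state["ext_tables"] = process_chromatograms(state["ext_chroms"], config) \
        if "ext_chroms" in state else []
    qc_tables = process_chromatograms(state.get("qc", []), config)
    spio.write_peak_tables_csv(state["tables"], outdir / "peak_tables.csv")
    record("peak_tables", outdir / "peak_tables.csv")
    if qc_tables:
        prec = proc.precision_report(qc_tables, scope="intraday",
                                     tol_min=config.match_tol_min)
        prec.table.to_csv(outdir / "precision_report.csv", index=False)
        record("precision_report", outdir / "precision_report.csv")
        report["headline"]["qc_max_rt_rsd_pct"] = prec.max_rt_rsd
        report["headline"]["qc_max_area_rsd_pct"] = prec.max_area_rsd
    counts = [len(t) for t in state["tables"]]
    report["headline"]["median_peaks_per_sample"] = float(np.median(counts))


def _stage_fingerprint(config, state, report, outdir, record):
    if "tables" not in state:
        raise MissingStageInputError(
            "fingerprint stage needs peak tables; enable 'process' or supply "
            "a peak-table CSV")
    aligned, matrix, reference, sim = build_fingerprint(state["tables"], config)
    state.update(aligned=aligned, matrix=matrix, reference=reference, sim=sim)
    spio.write_matrix_csv(matrix, outdir / "common_peak_matrix.csv")
    record("common_peak_matrix", outdir / "common_peak_matrix.csv")
    spio.write_fingerprint_csv(reference, outdir / "reference_fingerprint.csv")
    record("reference_fingerprint", outdir / "reference_fingerprint.csv")
    sim.to_csv(outdir / "similarity_report.csv")
    record("similarity_report", outdir / "similarity_report.csv")
    metric = config.similarity_metrics[0]
    report["headline"]["n_common_peaks"] = len(matrix.peak_ids)
    report["headline"]["similarity_min"] = float(sim[metric].min())
    report["headline"]["similarity_max"] = float(sim[metric].max())


def _stage_chemometrics(config, state, report, outdir, record):
    if "matrix" not in state:
        raise MissingStageInputError(
            "chemometrics stage needs the common-peak matrix; enable "
            "'fingerprint' or supply a matrix CSV")
    matrix: fp.CommonPeakMatrix = state["matrix"]
    X = matrix.areas.to_numpy(float)
    labels = matrix.labels()
    pca = chem.run_pca(X)
    model = chem.fit_plsda(X, labels, A=config.pls_components,
                           cv_folds=config.cv_folds)
    perm = chem.permutation_test(
        X, labels, n_perm=config.n_permutations, A=model.n_components,
        cv_folds=config.cv_folds,
        seed=stage_seed(config.seed, "permutation"))
    vip = chem.vip_scores(model)
    pvals = chem.peak_anova_pvalues(matrix)
    selection = chem.select_markers(matrix.peak_ids, vip, pvals,
                                    vip_cut=config.vip_cut, p_cut=config.p_cut)
    state.update(pca=pca, plsda=model, perm=perm, selection=selection)
    selection.table.to_csv(outdir / "vip_table.csv", index=False)
    record("vip_table", outdir / "vip_table.csv")
    perm_df = pd.DataFrame({"correlation": perm.correlations,
                            "r2y": perm.r2y, "q2": perm.q2})
    perm_df.to_csv(outdir / "permutation_table.csv", index=False)
    record("permutation_table", outdir / "permutation_table.csv")
    if config.figures:
        from . import plots
        plots.plot_scores(pca.scores, matrix.labels(),
                          outdir / "pca_scores.png", "PCA scores",
                          pca.explained_pct)
        record("pca_scores", outdir / "pca_scores.png")
        plots.plot_scores(model.scores, matrix.labels(),
                          outdir / "plsda_scores.png", "PLS-DA scores")
        record("plsda_scores", outdir / "plsda_scores.png")
    report["headline"].update(
        pc1_pct=float(pca.explained_pct[0]),
        pc2_pct=float(pca.explained_pct[1]),
        r2y=model.r2y, q2=model.q2,
        permutation_r2_intercept=perm.r2_intercept,
        permutation_q2_intercept=perm.q2_intercept,
        marker_ids=selection.selected_ids,
        n_markers=len(selection.selected_ids),
    )


def _stage_classify(config, state, report, outdir, record):
    for need in ("matrix", "selection"):
        if need not in state:
            raise MissingStageInputError(
                "classify stage needs the common-peak matrix and marker "
                "selection; enable 'fingerprint' and 'chemometrics'")
    matrix: fp.CommonPeakMatrix = state["matrix"]
    marker_ids = state["selection"].selected_ids
    X = matrix.areas[marker_ids].to_numpy(float)
    labels = matrix.labels()
    model = cls.fit_lda(X, labels, regularization=config.lda_regularization,
                        feature_ids=marker_ids)
    yhat, _ = cls.classify(model, X)
    cm_train = cls.ConfusionMatrix.from_predictions(labels, yhat,
                                                    model.classes, "training")
    cm_cv = cls.cross_validate(X, labels, scheme=config.cv_scheme,
                               regularization=config.lda_regularization)
    # hierarchical clustering of the cohort on marker features
    hca_res = cls.hca(X, method=config.hca_linkage, k=len(model.classes),
                      sample_ids=matrix.sample_ids)
    ari = cls.adjusted_rand_index(hca_res.assignments, labels)
    # external samples: warp onto the cohort RT register, extract features
    ext_results = []
    if state.get("ext_tables"):
        reference = state["reference"]
        anchors = fp.select_anchors(state["tables"], k=config.n_anchors,
                                    coarse_tol_min=config.anchor_coarse_tol_min)
        idx = [matrix.peak_ids.index(m) for m in marker_ids]
        reg_rts = state["tables"][0].apex_rts
        for t in state["ext_tables"]:
            amap = fp.alignment_maps([t], anchors,
                                     registration_rts=reg_rts)[t.sample_id]
            warped = fp.correct_retention(t, amap)
            vec = extract_feature_vector(
                warped, matrix.consensus_rts, config.match_tol_min,
                fallback=reference.mean_areas)
            pred, _ = cls.classify(model, vec[idx])
            ext_results.append((t.sample_id, t.group, pred))
    state.update(lda=model, cm_train=cm_train, cm_cv=cm_cv, hca=hca_res,
                 ext_results=ext_results)
    text = render_discriminant_functions(model)
    (outdir / "discriminant_functions.txt").write_text(text + "\n")
    record("discriminant_functions", outdir / "discriminant_functions.txt")
    coeff_rows = [
        {"class": c, "feature": f, "coefficient": model.coefficients[k, j]}
        for k, c in enumerate(model.classes)
        for j, f in enumerate(model.feature_ids)
    ] + [{"class": c, "feature": "(intercept)",
          "coefficient": model.intercepts[k]}
         for k, c in enumerate(model.classes)]
    pd.DataFrame(coeff_rows).to_csv(outdir / "discriminant_functions.csv",
                                    index=False)
    record("discriminant_functions_csv", outdir / "discriminant_functions.csv")
    for name, cm in (("training", cm_train), ("cross_validation", cm_cv)):
        df = pd.DataFrame(cm.counts, index=cm.classes, columns=cm.classes)
        df["total"] = cm.counts.sum(axis=1)
        df["accuracy_pct"] = cls.accuracy(cm, "per_class")
        df.to_csv(outdir / f"confusion_{name}.csv")
        record(f"confusion_{name}", outdir / f"confusion_{name}.csv")
    (outdir / "hca_tree.txt").write_text(hca_res.tree_text() + "\n")
    record("hca_tree", outdir / "hca_tree.txt")
    if config.figures:
        from . import plots
        plots.plot_dendrogram(hca_res.linkage_matrix, matrix.sample_ids,
                              outdir / "hca_dendrogram.png",
                              "HCA (ward, euclidean)")
        record("hca_dendrogram", outdir / "hca_dendrogram.png")
    n_ext_correct = sum(1 for _, true, pred in ext_results if true == pred)
    report["headline"].update(
        training_accuracy_pct=cls.accuracy(cm_train),
        loo_accuracy_pct=cls.accuracy(cm_cv),
        training_confusion=cm_train.counts.tolist(),
        cv_confusion=cm_cv.counts.tolist(),
        hca_ari=ari,
        external_assignments=[
            {"sample": s, "true": t, "predicted": p} for s, t, p in ext_results
        ],
        external_correct=n_ext_correct,
    )


def _stage_stats(config, state, report, outdir, record):
    if "soil" not in state:
        raise MissingStageInputError(
            "stats stage needs the soil table; enable 'simulate' or load one")
    soil = state["soil"]
    duncan = spstats.anova_duncan_report(soil, alpha=config.alpha)
    duncan.to_csv(outdir / "soil_anova_duncan.csv")
    record("soil_anova_duncan", outdir / "soil_anova_duncan.csv")
    if "matrix" in state and "selection" in state:
        markers = state["selection"].selected_ids
        corr = spstats.pearson_matrix(state["matrix"].areas[markers], soil)
        corr.r.to_csv(outdir / "marker_soil_correlation_r.csv")
        corr.p.to_csv(outdir / "marker_soil_correlation_p.csv")
        record("marker_soil_correlation_r",
               outdir / "marker_soil_correlation_r.csv")
        record("marker_soil_correlation_p",
               outdir / "marker_soil_correlation_p.csv")
        report["headline"]["n_significant_soil_correlations"] = int(
            (corr.p < config.alpha).sum().sum())


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "process": _stage_process,
    "fingerprint": _stage_fingerprint,
    "chemometrics": _stage_chemometrics,
    "classify": _stage_classify,
    "stats": _stage_stats,
}


def _render_report_text(report: dict) -> str:
    lines = ["soilprint run report", "=" * 20]
    for key in sorted(report["headline"]):
        lines.append(f"{key}: {report['headline'][key]}")
    lines.append("")
    lines.append("artifacts:")
    for name in sorted(report["artifacts"]):
        art = report["artifacts"][name]
        lines.append(f"  {name}: {art['path']} (md5 {art['md5']})")
    return "\n".join(lines) + "\n"
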