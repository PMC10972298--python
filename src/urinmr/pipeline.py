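"""End-to-end orchestration: simulate/ingest -> process -> analyze -> correlate -> report.

Each stage reads and writes the documented plain-text artifacts inside
a run directory, so stages can be re-run individually and a completed
run is reproducible bit-for-bit from its manifest (seed + config).
Stage randomness draws from per-stage streams derived from the global
seed and the stage name, so no stage shares a stream with another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, datasets, io, opls, pathways, preprocess, spectral, univariate, viavc
from .clinical import correlation_families, records_to_frame
from .io import FLOAT_FMT
from .simulate import ClinicalLink, CohortConfig, default_library, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    # data source: synthetic by default, or paths to spectra + tables
    simulate: dict[str, Any] = field(default_factory=dict)
    spectra_dir: str | None = None
    metadata_csv: str | None = None
    clinical_csv: str | None = None
    n_library_metabolites: int = 40
    # stage parameters
    tsp_window: tuple[float, float] = (-0.2, 0.2)
    alignment: dict[str, Any] = field(default_factory=dict)
    binning: dict[str, Any] = field(
        default_factory=lambda: {"min_bin_width": 0.02, "noise_floor": 0.02,
                                 "smoothing_points": 5}
    )
    excluded_regions: list[tuple[float, float]] = field(
        default_factory=lambda: list(spectral.DEFAULT_EXCLUDED_REGIONS)
    )
    preprocess: dict[str, Any] = field(default_factory=dict)
    univariate_alpha: float = 0.05
    viavc: dict[str, Any] = field(default_factory=dict)
    opls: dict[str, Any] = field(
        default_factory=lambda: {"n_orth": "auto", "cv_folds": 10,
                                 "n_permutations": 1999, "n_boot": 2000}
    )
    clinical_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage stream: global seed combined with the stage name."""
        return int(
            np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
            .generate_state(1)[0] % (2**31)
        )


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format=FLOAT_FMT, **kw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages

def simulate_stage(config: PipelineConfig, outdir: Path) -> None:
    """Generate the synthetic cohort and write spectra + tables + truth."""
    outdir.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(config.simulate)
    if "clinical_link" in sim_kwargs and isinstance(sim_kwargs["clinical_link"], dict):
        sim_kwargs["clinical_link"] = ClinicalLink(**sim_kwargs["clinical_link"])
    cohort_config = CohortConfig(seed=config.stage_seed("simulate"), **sim_kwargs)
    library = default_library(config.n_library_metabolites,
                              seed=config.stage_seed("library"))
    cohort = simulate_cohort(cohort_config, library)
    spectra_dir = outdir / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    for sid, spectrum in cohort.spectra.items():
        io.write_spectrum(spectrum, spectra_dir / f"{sid}.txt")
    _write_csv(cohort.metadata, outdir / "metadata.csv")
    io.write_clinical_table(cohort.clinical, outdir / "clinical.csv")
    cohort.truth.to_json(outdir / "truth.json")
    logger.info("simulated %d spectra for %d subjects",
                len(cohort.spectra), cohort_config.n_subjects)


def process_stage(config: PipelineConfig, outdir: Path) -> None:
    """Reference, align, bin, exclude, integrate; write matrices + manifest."""
    spectra_dir = Path(config.spectra_dir) if config.spectra_dir else outdir / "spectra"
    paths = sorted(spectra_dir.glob("*.txt"))
    if not paths:
        raise FileNotFoundError(f"no spectra found in {spectra_dir}")
    spectra = {p.stem: io.read_spectrum(p) for p in paths}
    referenced = {
        sid: spectral.reference_to_tsp(s, config.tsp_window) for sid, s in spectra.items()
    }
    # common grid spanning the intersection of all referenced axes
    hi = min(s.ppm[0] for s in referenced.values())
    lo = max(s.ppm[-1] for s in referenced.values())
    points = len(next(iter(referenced.values())))
    grid = np.linspace(hi, lo, points)
    on_grid = {sid: spectral.interpolate_to_grid(s, grid) for sid, s in referenced.items()}

    ids = list(on_grid)
    specs = list(on_grid.values())
    ref_idx = spectral.select_reference_spectrum(specs)
    aligned = spectral.align_rspa(specs, ref_idx, spectral.AlignmentParams(**config.alignment))
    mean_spec = spectral.mean_spectrum(aligned)
    noise_floor = config.binning.get("noise_floor", 0.0)
    if noise_floor and noise_floor < 1:  # interpreted as a fraction of the max intensity
        noise_floor = noise_floor * float(mean_spec.intensity.max())
    bins = spectral.dynamic_adaptive_bins(
        mean_spec,
        min_bin_width=config.binning.get("min_bin_width", 0.008),
        noise_floor=noise_floor,
        smoothing_points=config.binning.get("smoothing_points", 5),
    )
    bins = spectral.exclude_regions(bins, config.excluded_regions)
    matrix = spectral.integrate_bins(dict(zip(ids, aligned)), bins)
    matrix.bins = datasets.label_bins(matrix.bins)
    io.write_bin_manifest(matrix.bins, outdir / "bin_manifest.csv")
    io.write_feature_matrix(matrix, outdir / "feature_matrix.csv")
    logger.info("process: %d spectra -> %d bins (%d excluded)",
                len(ids), len(matrix.bins), int(matrix.bins["excluded"].sum()))


def _load_matrix_and_metadata(config: PipelineConfig, outdir: Path):
    matrix = io.read_feature_matrix(outdir / "feature_matrix.csv")
    manifest = io.read_bin_manifest(outdir / "bin_manifest.csv")
    active = manifest[~manifest["excluded"]].reset_index(drop=True)
    matrix = io.FeatureMatrix(
        values=matrix.values.set_axis(active.index, axis=1), bins=active
    )
    meta_path = Path(config.metadata_csv) if config.metadata_csv else outdir / "metadata.csv"
    metadata = pd.read_csv(meta_path, index_col="sample_id")
    return matrix, metadata


def analyze_stage(config: PipelineConfig, outdir: Path) -> None:
    """Preprocess + univariate + VIAVC + OPLS-DA/ROC on the feature matrix."""
    matrix, metadata = _load_matrix_and_metadata(config, outdir)
    normalized = preprocess.normalize_total(matrix)
    _write_csv(normalized.values, outdir / "normalized_matrix.csv", index_label="sample_id")
    pp_conf = preprocess.PreprocessConfig(**config.preprocess)
    processed = preprocess.preprocess_chain(matrix, metadata, pp_conf)
    _write_csv(processed.values, outdir / "processed_matrix.csv", index_label="sample_id")

    uni = univariate.run_univariate(processed, metadata, config.univariate_alpha)
    _write_csv(uni, outdir / "univariate.csv", index_label="bin_id")

    meta = metadata.reindex(processed.values.index)
    y = np.where(meta["phase"] == "chronic", 1.0, -1.0)
    groups = meta["subject_id"].to_numpy()
    vconf = viavc.ViavcConfig(seed=config.stage_seed("viavc"), **config.viavc)
    result = viavc.viavc_iterate(processed.values, y, groups, vconf)
    result.to_json(outdir / "viavc_result.json")
    best_ids = [int(b) for b in result.best_subset]
    best_manifest = processed.bins.loc[best_ids]
    _write_csv(
        best_manifest.assign(
            p_holm=[result.p_holm[str(b)] for b in best_ids],
            rank=np.arange(1, len(best_ids) + 1),
        ),
        outdir / "best_subset.csv", index_label="bin_id",
    )

    X_panel = processed.values[best_ids].to_numpy()
    oconf = config.opls
    seed = config.stage_seed("opls")
    model = opls.fit_opls_da(X_panel, y, n_orth=oconf.get("n_orth", "auto"),
                             cv_folds=oconf.get("cv_folds", 10), groups=groups, seed=seed)
    _, p_q2 = opls.permutation_test(
        X_panel, y, groups, statistic="Q2", n_orth=model.n_orth,
        n_perm=oconf.get("n_permutations", 1999), folds=oconf.get("cv_folds", 10), seed=seed)
    r2y_obs, p_r2y = opls.permutation_test(
        X_panel, y, groups, statistic="R2Y", n_orth=model.n_orth,
        n_perm=oconf.get("n_permutations", 1999), seed=seed)
    t_pred, t_orth = model.transform(X_panel)
    _write_csv(
        pd.DataFrame({"sample_id": processed.values.index, "phase": meta["phase"].to_numpy(),
                      "t_predictive": t_pred, "t_orthogonal_1": t_orth}).set_index("sample_id"),
        outdir / "opls_scores.csv",
    )
    cv_scores = opls.cross_validated_scores(X_panel, y, groups, n_orth=model.n_orth,
                                            folds=oconf.get("cv_folds", 10), seed=seed)
    roc = opls.roc_from_scores(cv_scores, y, n_boot=oconf.get("n_boot", 2000), seed=seed)
    _write_csv(pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}),
               outdir / "roc_points.csv", index=False)
    summary = {
        "r2y": model.r2y, "q2": model.q2, "n_orth": model.n_orth,
        "perm_p_r2y": p_r2y, "perm_p_q2": p_q2,
        "roc_auc": roc.auc, "roc_ci95": list(roc.ci95), "accuracy": roc.accuracy,
        "best_subset_bins": best_ids,
        "best_subset_labels": [best_manifest.loc[b, "label"] for b in best_ids],
        "best_subset_cv_auc": result.best_subset_cv_auc,
    }
    with (outdir / "opls_summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)

    # pathway over-representation on the significant metabolites
    labels = set(best_manifest["label"].dropna())
    labels |= set(uni.loc[uni["p_raw"] < config.univariate_alpha, "label"].dropna())
    library = datasets.load_pathway_library()
    ora = pathways.run_pathway_analysis(labels, library)
    _write_csv(ora, outdir / "pathway_results.csv", index=False)


def correlate_stage(config: PipelineConfig, outdir: Path) -> None:
    """Spearman correlation families between panel bins and clinical scores."""
    clin_path = Path(config.clinical_csv) if config.clinical_csv else outdir / "clinical.csv"
    records = io.read_clinical_table(clin_path)
    normalized = pd.read_csv(outdir / "normalized_matrix.csv", index_col="sample_id")
    metadata = pd.read_csv(
        Path(config.metadata_csv) if config.metadata_csv else outdir / "metadata.csv",
        index_col="sample_id",
    )
    best = pd.read_csv(outdir / "best_subset.csv", index_col="bin_id")
    panel_cols = [str(b) for b in best.index]
    panel_names = {
        str(b): (best.loc[b, "label"] if isinstance(best.loc[b, "label"], str)
                 else f"bin_{best.loc[b, 'center']:.3f}")
        for b in best.index
    }
    meta = metadata.reindex(normalized.index)
    subjects = sorted(meta["subject_id"].unique())
    acute_rows, pct_rows = [], []
    for s in subjects:
        sel = meta[meta["subject_id"] == s]
        a_id = sel.index[sel["phase"] == "acute"][0]
        c_id = sel.index[sel["phase"] == "chronic"][0]
        a = normalized.loc[a_id, panel_cols].to_numpy(dtype=float)
        c = normalized.loc[c_id, panel_cols].to_numpy(dtype=float)
        acute_rows.append(a)
        pct_rows.append((c - a) / ((c + a) / 2.0) * 100.0)
    acute = pd.DataFrame(acute_rows, index=subjects, columns=panel_cols)
    pct = pd.DataFrame(pct_rows, index=subjects, columns=panel_cols)
    acute.columns = [panel_names[c] for c in acute.columns]
    pct.columns = list(acute.columns)
    corr = correlation_families(acute, pct, records, alpha=config.clinical_alpha)
    _write_csv(corr, outdir / "correlations.csv", index=False)


def report_stage(config: PipelineConfig, outdir: Path) -> None:
    """Assemble a markdown report + run manifest from the stage outputs."""
    parts = [f"# urinmr run report\n\nseed: {config.seed}\n"]
    uni = pd.read_csv(outdir / "univariate.csv")
    sig = uni.sort_values("p_raw").head(15)
    parts.append("## Univariate results (top 15 by raw p)\n\n```\n" +
                 sig.to_string(index=False) + "\n```")
    with (outdir / "opls_summary.json").open() as fh:
        summary = json.load(fh)
    parts.append(
        "\n\n## OPLS-DA / ROC\n\n"
        + "\n".join(f"- {k}: {v}" for k, v in sorted(summary.items()))
    )
    ora = pd.read_csv(outdir / "pathway_results.csv")
    parts.append("\n\n## Pathway over-representation\n\n```\n" +
                 ora.to_string(index=False) + "\n```")
    corr = pd.read_csv(outdir / "correlations.csv")
    corr_sig = corr.sort_values("p").head(15)
    parts.append("\n\n## Clinical correlations (top 15 by p)\n\n```\n" +
                 corr_sig.to_string(index=False) + "\n```")
    (outdir / "report.md").write_text("\n".join(parts) + "\n")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


STAGES = ["simulate", "process", "analyze", "correlate", "report"]


def run_all(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage in order inside ``outdir``; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage == "simulate" and config.spectra_dir is not None:
            continue  # real data supplied; nothing to simulate
        func = globals()[f"{stage}_stage"]
        try:
            func(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed (inputs under {outdir})") from exc
    return outdir
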