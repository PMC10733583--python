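"""End-to-end pipeline driver with a machine-readable run report.

Stage order: normalization -> time-series DE (per sex, then merged) ->
regulation classification -> coexpression network -> enrichment ->
sex comparisons. All outputs are TSV with explicit headers; the run
report (JSON) carries per-stage gene counts, the fully serialized
configuration, a config hash and wall time, so that a report plus the
inputs suffices to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifyThresholds, classify_regulation, merge_sex_calls, peak_log2fc_vs_t0
from .datasets import CountDataset, read_dataset
from .diffexpr import de_analysis
from .enrich import hypergeom_enrich, read_gmt
from .network import detect_modules, filter_network_genes
from .preprocess import (
    classical_mds,
    cv_profile,
    estimate_size_factors,
    filter_low_expression,
    normalize_counts,
    tpm,
)
from .sexdiff import baseline_sex_de, sex_specific_regulation_check

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Paths, thresholds and switches for a full run."""

    counts: str = ""
    samples: str = ""
    genes: str = ""
    gmt: str = ""
    outdir: str = "tnftime_out"
    alpha: float = 0.05
    lfc: float = 1.0
    pseudocount: float = 0.5
    cv_stable: float = 0.3
    cv_variable: float = 0.3
    peak_lfc: float = 0.7
    min_tpm: float = 1.0
    min_total_counts: int = 10
    net_min_counts: int = 10
    net_min_cv: float = 0.2
    beta: float | None = None  # None = auto-select, fallback 12
    min_module_size: int = 30
    kme_threshold: float = 0.80
    sex_lfc: float = 1.0
    sex_null_lfc: float = 0.1375
    sex_split: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "alpha", "lfc", "cv_stable", "cv_variable", "peak_lfc", "min_tpm",
            "kme_threshold", "sex_lfc", "sex_null_lfc", "pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage counts and provenance for one pipeline run."""

    version: str
    config: dict
    config_hash: str
    stages: dict = field(default_factory=dict)
    wall_time_s: float = 0.0

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def run_pipeline(
    config: PipelineConfig, dataset: CountDataset | None = None
) -> RunReport:
    """Execute all stages and write outputs under ``config.outdir``."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        version=__version__, config=asdict(config), config_hash=config.config_hash()
    )

    if dataset is None:
        dataset = read_dataset(config.counts, config.samples, config.genes)
    logger.info("loaded %d genes x %d samples", *dataset.counts.shape)
    report.stages["input"] = {
        "n_genes": int(dataset.counts.shape[0]),
        "n_samples": int(dataset.counts.shape[1]),
    }

    sexes = dataset.sexes
    if config.sex_split and len(sexes) < 2:
        raise ValueError(
            f"sex_split requested but sample sheet has a single sex: {sexes}"
        )
    groups = {s: dataset.sex_subset(s) for s in sexes} if config.sex_split else {
        "all": dataset
    }

    # ---- normalization & QC (whole dataset) -----------------------------
    size_factors = estimate_size_factors(dataset.counts)
    size_factors.to_frame().to_csv(
        outdir / "size_factors.tsv", sep="\t", index_label="sample_id"
    )
    tpm_all = tpm(dataset.counts, dataset.genes["length_bp"])
    _write_tsv(tpm_all, outdir / "tpm.tsv")
    norm_all = normalize_counts(dataset.counts, size_factors)
    log_norm = np.log2(norm_all + 1.0)
    mds = classical_mds(log_norm.T, dims=2)
    mds.to_csv(outdir / "mds.tsv", sep="\t", index_label="sample_id")
    report.stages["normalization"] = {
        "size_factor_range": [float(size_factors.min()), float(size_factors.max())]
    }

    # ---- per-group DE + classification ----------------------------------
    thresholds = ClassifyThresholds(
        cv_stable=config.cv_stable,
        cv_variable=config.cv_variable,
        peak_lfc=config.peak_lfc,
    )
    calls = {}
    de_counts = {}
    for group, sub in groups.items():
        de = de_analysis(
            sub.counts,
            sub.samples,
            alpha=config.alpha,
            lfc_threshold=config.lfc,
            pseudocount=config.pseudocount,
            min_total_counts=config.min_total_counts,
        )
        _write_tsv(de.to_frame(), outdir / f"de_{group}.tsv")
        sub_tpm = tpm(sub.counts, sub.genes["length_bp"])
        expressed = filter_low_expression(sub_tpm, sub.samples, min_tpm=config.min_tpm)
        cv = cv_profile(sub_tpm, sub.samples)
        peak0 = peak_log2fc_vs_t0(sub_tpm, sub.samples, pseudocount=config.pseudocount)
        call = classify_regulation(
            cv, de.deg, de.log2fc, peak0, expressed, thresholds=thresholds
        )
        _write_tsv(call, outdir / f"classification_{group}.tsv")
        calls[group] = call
        de_counts[group] = {
            "n_tested": int(de.table["converged"].sum()),
            "n_deg_any_time": int((de.deg.to_numpy() != "none").any(axis=1).sum()),
            "labels": call["label"].value_counts().to_dict(),
        }
    report.stages["differential_expression"] = de_counts

    if config.sex_split and set(calls) == {"F", "M"}:
        merged = merge_sex_calls(calls)
        _write_tsv(merged, outdir / "classification_merged.tsv")
        report.stages["merged_classification"] = (
            merged["merged_class"].value_counts().to_dict()
        )
        regulated_any = merged.index[merged["merged_class"] != "neither"]
    else:
        only = next(iter(calls.values()))
        regulated_any = only.index[
            only["label"].isin(["upregulated", "downregulated"])
        ]

    # ---- coexpression network -------------------------------------------
    # CV filter on linear normalized counts; correlations on the log2 scale
    net_mask = filter_network_genes(
        dataset.counts,
        norm_all,
        min_total_counts=config.net_min_counts,
        min_cv=config.net_min_cv,
    )
    net_expr = log_norm.loc[net_mask[net_mask].index]
    modules = detect_modules(
        net_expr,
        beta=config.beta,
        min_module_size=config.min_module_size,
        kme_threshold=config.kme_threshold,
    )
    assign = pd.DataFrame({"module": modules.labels})
    if len(modules.kme.columns):
        own = modules.labels.replace(0, np.nan)
        kme_own = pd.Series(np.nan, index=assign.index)
        for mod in modules.kme.columns:
            members = modules.labels.index[modules.labels == mod]
            kme_own.loc[members] = modules.kme.loc[members, mod]
        assign["kme_own"] = kme_own
        assign["featured"] = modules.featured
    _write_tsv(assign, outdir / "modules.tsv")
    if len(modules.eigengenes):
        _write_tsv(modules.eigengenes, outdir / "eigengenes.tsv", index_label="module")
        hubs = pd.DataFrame(
            sorted(modules.hubs.items()), columns=["module", "hub_gene"]
        ).set_index("module")
        hubs.to_csv(outdir / "hub_genes.tsv", sep="\t")
    report.stages["network"] = {
        "n_network_genes": int(net_mask.sum()),
        "n_modules": int(len(modules.eigengenes)),
        "n_unassigned": int((modules.labels == 0).sum()),
    }

    # ---- enrichment ------------------------------------------------------
    if config.gmt:
        sets = read_gmt(config.gmt)
        universe_tpm = tpm_all
        universe = set(
            filter_low_expression(
                universe_tpm, dataset.samples, min_tpm=config.min_tpm
            ).pipe(lambda s: s[s].index)
        )
        query = [g for g in regulated_any if g in universe]
        enr = hypergeom_enrich(query, sets, universe)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report.stages["enrichment"] = {
            "n_terms_tested": int(len(enr)),
            "n_significant_fdr05": int((enr["fdr"] < 0.05).sum()) if len(enr) else 0,
        }

    # ---- sex comparisons -------------------------------------------------
    if config.sex_split and len(sexes) == 2:
        base = baseline_sex_de(
            dataset,
            alpha=config.alpha,
            lfc_threshold=config.sex_lfc,
            pseudocount=config.pseudocount,
            min_total_counts=config.min_total_counts,
        )
        base_tab = base.log2fc.add_prefix("log2fc_F_vs_M_")
        base_tab["de_all_timepoints"] = base.de_all_timepoints
        _write_tsv(base_tab, outdir / "sex_baseline_de.tsv")
        concord = sex_specific_regulation_check(
            dataset,
            lfc_threshold=config.sex_lfc,
            null_lfc=config.sex_null_lfc,
            pseudocount=config.pseudocount,
        )
        _write_tsv(concord, outdir / "sex_specific_regulation.tsv")
        report.stages["sexdiff"] = {
            "n_baseline_sex_de": int(base.de_all_timepoints.sum()),
            "n_sex_specific_regulated": int(concord["sex_specific"].sum()),
        }

    report.wall_time_s = round(time.time() - t_start, 3)
    report.write(outdir / "run_report.json")
    return report
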