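"""End-to-end orchestration: read -> filter -> test -> call -> annotate -> report.

``RunConfig`` gathers every stage's settings plus input/output paths and
a seed, round-trips through YAML unchanged, and ``run_pipeline`` executes
the design-appropriate sequence:

* pooled design: per-site two-group binomial Wald test;
* paired design: per-site family-intercept GLMM, then dispersion (lambda)
  HPD filtering.

Both then apply the Bonferroni + minimum-difference DMC rule, annotate
called sites against the GFF3 gene models, and emit deterministic TSV
outputs plus a machine-readable JSON run summary (site counts per stage,
thresholds, DMC count).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import filters, glmm, pooled, profiles
from .cgmap import assemble_matrix, read_cgmap, read_sample_sheet

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_NUMERICAL_ERROR = 4


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, exit_code: int = EXIT_DATA_ERROR):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class RunConfig:
    sample_sheet: str = ""
    cgmap_dir: str = ""  # expects <sample_id>.cgmap[.gz] per sheet row
    gff3: str = ""
    outdir: str = "results"
    design: str = "pooled"  # or "paired"
    seed: int = 0
    alpha: float = 0.05
    min_abs_diff: float = 0.10
    hpd_mass: float = 0.95
    filter: filters.FilterConfig = field(default_factory=filters.FilterConfig)
    glmm: glmm.GlmmConfig = field(default_factory=glmm.GlmmConfig)
    windows: ann.WindowConfig = field(default_factory=ann.WindowConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("filter", filters.FilterConfig),
            ("glmm", glmm.GlmmConfig),
            ("windows", ann.WindowConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                if key == "glmm" and "log_sigma_bounds" in sub_d:
                    sub_d["log_sigma_bounds"] = tuple(sub_d["log_sigma_bounds"])
                d[key] = sub(**sub_d)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _load_matrix(config: RunConfig):
    meta = read_sample_sheet(config.sample_sheet)
    cgdir = Path(config.cgmap_dir)
    streams = {}
    for m in meta:
        path = cgdir / f"{m.sample_id}.cgmap"
        if not path.exists():
            path = cgdir / f"{m.sample_id}.cgmap.gz"
        if not path.exists():
            raise PipelineError("read", f"no CGmap file for sample {m.sample_id}")
        streams[m.sample_id] = read_cgmap(path)
    return assemble_matrix(streams, meta)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run summary dict."""
    if config.design not in ("pooled", "paired"):
        raise PipelineError("config", f"unknown design {config.design!r}",
                            EXIT_CONFIG_ERROR)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    log.info("run config: %s", json.dumps(config.to_dict(), default=str))

    try:
        matrix = _load_matrix(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc

    fcfg = config.filter
    if config.design == "paired":
        fcfg = dataclasses.replace(fcfg, presence_mode="family_presence")
    else:
        fcfg = dataclasses.replace(fcfg, presence_mode="pool_intersection")
    try:
        filtered, report = filters.apply_filters(matrix, fcfg, matrix.meta)
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    report.to_tsv(outdir / "filter_report.tsv")
    n_tests = filtered.n_sites

    hpd = (float("nan"), float("nan"))
    try:
        if config.design == "pooled":
            results = pooled.pooled_site_tests(filtered)
        else:
            results, hpd = glmm.family_site_tests(
                filtered, filtered.meta, config.glmm, config.hpd_mass
            )
    except Exception as exc:
        raise PipelineError("test", str(exc), EXIT_NUMERICAL_ERROR) from exc
    if results.empty:
        raise PipelineError("test", "no testable sites after filtering")
    results.to_csv(outdir / "site_tests.tsv", sep="\t", index=False,
                   float_format="%.10g")

    call_cfg = pooled.CallConfig(config.alpha, max(n_tests, 1), config.min_abs_diff)
    dmcs = pooled.call_dmcs(results, call_cfg)
    threshold = pooled.bonferroni_neglog10(call_cfg.n_tests, call_cfg.alpha)

    annotation = pd.DataFrame()
    if config.gff3:
        try:
            models = ann.read_gff(config.gff3)
            windows = ann.build_feature_windows(models, config.windows)
            annotation = ann.annotate_sites(
                dmcs[["chrom", "pos"]] if len(dmcs) else pd.DataFrame(
                    columns=["chrom", "pos"]
                ),
                windows,
            )
        except Exception as exc:
            raise PipelineError("annotate", str(exc)) from exc
    if len(dmcs):
        dmcs = dmcs.merge(annotation, on=["chrom", "pos"], how="left") if len(
            annotation
        ) else dmcs
    dmcs.to_csv(outdir / "dmcs.tsv", sep="\t", index=False, float_format="%.10g")
    if len(dmcs):
        pooled.results_to_bed(dmcs, outdir / "dmcs.bed")

    try:
        prof = profiles.profile_matrix(filtered)
        if prof.shape[0] >= 2 and prof.shape[1] >= 2:
            profiles.manhattan_table(results).to_csv(
                outdir / "manhattan.tsv", sep="\t", index=False, float_format="%.6g")
            profiles.qq_table(results).to_csv(
                outdir / "qq.tsv", sep="\t", index=False, float_format="%.6g")
            profiles.volcano_table(results).to_csv(
                outdir / "volcano.tsv", sep="\t", index=False, float_format="%.6g")
            if prof.std(axis=1).min() > 0:
                dist = profiles.correlation_distance(prof)
                tree = profiles.ward_cluster(dist)
                (outdir / "dendrogram.newick").write_text(tree.to_newick() + "\n")
                scores, _, frac = profiles.pca(prof)
                scores.to_csv(outdir / "pca_scores.tsv", sep="\t",
                              float_format="%.6g")
                pd.Series(frac, index=scores.columns, name="variance_fraction").to_csv(
                    outdir / "pca_variance.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc

    summary = {
        "design": config.design,
        "stage_site_counts": dict(report.stages),
        "n_tests": int(n_tests),
        "bonferroni_neglog10_threshold": threshold,
        "min_abs_diff": config.min_abs_diff,
        "lambda_hpd": [float(hpd[0]), float(hpd[1])],
        "n_dmcs": int(len(dmcs)),
        "seed": config.seed,
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
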