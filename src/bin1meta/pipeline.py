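"""End-to-end analysis pipeline: roster -> effects -> pooling -> diagnostics.

``run_pipeline`` performs, for each requested genetic model: subgroup
heterogeneity + pooling, leave-one-out sensitivity, Begg/Egger bias tests
and funnel coordinates; plus the between-ancestry MAF/OR comparison.  The
result bundle is deterministic given the inputs and configuration, and can
be written out as CSV tables plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .effect_models import build_effects
from .errors import PipelineError
from .group_comparison import ComparisonResult, compare_groups
from .meta_engine import SubgroupAnalysis, pool_random_dl, subgroup_meta
from .robustness_bias import (
    BiasTestResult,
    begg_test,
    egger_test,
    funnel_data,
    leave_one_out,
    leave_one_out_table,
)
from .study_io import StudyTable, load_bundled_roster, read_study_table, write_results_table

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything a pipeline run depends on, in one serialisable object."""

    input_path: str | None = None  # None -> bundled roster
    models: tuple[str, ...] = ("additive",)
    maf_scope: str = "combined"  # combined | control
    harmonize: bool = True  # align reported ORs to the C-vs-T direction
    policy: str = "genotype_first"
    correction: float = 0.5
    het_p_threshold: float = 0.05
    i2_threshold: float = 50.0
    bias_alpha: float = 0.01
    force_random: bool = False  # pin random effects in every stratum
    output_dir: str | None = None
    seed: int | None = None  # simulate mode only

    def __post_init__(self):
        if not self.models:
            raise PipelineError("at least one genetic model must be requested")
        if not 0 < self.het_p_threshold < 1 or not 0 < self.bias_alpha < 1:
            raise PipelineError("thresholds must be probabilities in (0,1)")
        if not 0 <= self.i2_threshold <= 100:
            raise PipelineError("I^2 threshold must lie in [0,100]")


@dataclass
class ModelResults:
    """All outputs for one genetic model."""

    model: str
    subgroups: SubgroupAnalysis
    sensitivity: pd.DataFrame
    begg: BiasTestResult
    egger: BiasTestResult
    funnel_points: pd.DataFrame
    funnel_bounds: pd.DataFrame


@dataclass
class ResultBundle:
    config: AnalysisConfig
    roster: StudyTable
    by_model: dict[str, ModelResults]
    comparisons: dict[str, ComparisonResult]
    log_messages: list[str] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "package": "bin1meta",
            "version": __version__,
            "config": asdict(self.config),
            "n_studies": len(self.roster),
            "source": self.roster.source,
            "groups": {g: len(self.roster.subset(g)) for g in self.roster.groups},
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for model, res in self.by_model.items():
            res.subgroups.table().rename_axis("quantity").reset_index().pipe(
                write_results_table, outdir / f"meta_{model}.csv"
            )
            write_results_table(res.sensitivity, outdir / f"sensitivity_{model}.csv")
            write_results_table(res.funnel_points, outdir / f"funnel_points_{model}.csv")
            write_results_table(res.funnel_bounds, outdir / f"funnel_bounds_{model}.csv")
            bias = pd.DataFrame(
                [
                    {"method": b.method, "statistic": b.statistic, "t_or_z": b.t_or_z,
                     "p": b.p, "significant": b.p < self.config.bias_alpha}
                    for b in (res.begg, res.egger)
                ]
            )
            write_results_table(bias, outdir / f"bias_{model}.csv")
        comp = pd.DataFrame([asdict(c) for c in self.comparisons.values()])
        write_results_table(comp, outdir / "group_comparison.csv")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))


def run_pipeline(config: AnalysisConfig, roster: StudyTable | None = None) -> ResultBundle:
    """Run the full analysis described by ``config``.

    ``roster`` overrides ``config.input_path`` when given (useful for
    simulated tables already in memory).
    """
    if roster is None:
        roster = read_study_table(config.input_path) if config.input_path else load_bundled_roster()
    messages: list[str] = []
    by_model: dict[str, ModelResults] = {}
    for model in config.models:
        if model in ("dominant", "recessive") and not any(r.has_genotypes for r in roster):
            raise PipelineError(
                f"model {model!r} needs genotype columns "
                "(cc_case, ct_case, tt_case, cc_control, ct_control, tt_control)"
            )
        subgroups = subgroup_meta(
            roster, model=model, policy=config.policy, maf_scope=config.maf_scope,
            harmonize=config.harmonize, p_threshold=config.het_p_threshold,
            i2_threshold=config.i2_threshold, force_random=config.force_random,
        )
        messages.append(
            f"{model}: overall pooled with {subgroups.overall.model} "
            f"(Q p={subgroups.overall.het.p:.3g}, I^2={subgroups.overall.het.i_squared:.1f}%)"
        )
        for g, k in subgroups.skipped.items():
            messages.append(f"{model}: group {g!r} skipped with only {k} usable studies")
        effects = build_effects(
            roster, model=model, policy=config.policy, maf_scope=config.maf_scope,
            harmonize=config.harmonize, correction=config.correction,
        )
        sensitivity = leave_one_out_table(leave_one_out(effects))
        begg = begg_test(effects)
        egger = egger_test(effects)
        pooled_re = pool_random_dl(effects)
        points, bounds = funnel_data(effects, pooled_re)
        by_model[model] = ModelResults(
            model=model, subgroups=subgroups, sensitivity=sensitivity,
            begg=begg, egger=egger, funnel_points=points, funnel_bounds=bounds,
        )
    groups = roster.groups
    comparisons = compare_groups(roster, *groups[:2]) if len(groups) >= 2 else {}
    for msg in messages:
        log.info(msg)
    bundle = ResultBundle(
        config=config, roster=roster, by_model=by_model,
        comparisons=comparisons, log_messages=messages,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
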