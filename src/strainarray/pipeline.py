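"""End-to-end orchestration of the probe-level analysis.

Stage order: load -> background correct -> quantile normalize -> median-
polish summarize -> detection calls -> expression filter -> IQR filter ->
SFP screen/remove -> control-probe-set exclusion -> linear models ->
contrasts -> BH adjustment -> fold changes -> range-overlap filter ->
enrichment.  Every run emits a count ledger (the cascade of probe-set
counts through the filters) and, when an output directory is given, all
intermediate tables plus a log.  Runs are fully deterministic given the
configuration: the only stochastic stage (SFP permutation nulls) is
seeded.

Quality-control probe sets (``AFFX-`` prefix; e.g. the GFP/CFP features
of a transgenic strain) are excluded after the expression filters and
before SFP screening, so all ledger counts are control-free; a flag
restores the post-hoc ordering in which controls ride through the models
and are dropped only from the final lists.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, preprocess, sfp as sfp_mod
from .io import (
    AnnotationTable,
    ExpressionMatrix,
    ProbeLevelDataset,
    load_annotation_table,
    load_probe_level_dataset,
    write_result_table,
)

__all__ = [
    "PipelineConfig",
    "CountLedger",
    "PipelineResult",
    "PipelineStageError",
    "run_pipeline",
]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    tau: float = 0.015
    p_present: float = 0.04
    p_absent: float = 0.04
    absent_percentile: float = 0.99
    min_iqr: float = 0.5
    sfp_alpha: float = 0.01
    sfp_permutations: int = 1000
    fdr: float = 0.05
    fold_change_threshold: float = 2.0
    max_overlap: int = 1
    seed: int = 17
    controls_post_hoc: bool = False

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("p_present", 0.0, 1.0),
            ("p_absent", 0.0, 1.0),
            ("absent_percentile", 0.0, 1.0),
            ("sfp_alpha", 0.0, 1.0),
            ("fdr", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.sfp_permutations < 1:
            raise ValueError("sfp_permutations must be >= 1")
        if self.fold_change_threshold < 1:
            raise ValueError("fold_change_threshold must be >= 1")
        if self.max_overlap < 0:
            raise ValueError("max_overlap must be >= 0")


@dataclass
class CountLedger:
    """Probe-set counts through the filter/test cascade."""

    n_probesets_total: int = 0
    n_expressed: int = 0
    n_sfp_flagged: int = 0
    n_analyzed: int = 0
    n_de_strain: int = 0
    n_de_strain_2fold: int = 0
    n_de_dom_initial: int = 0
    n_de_dom_final: int = 0
    n_de_dom_2fold: int = 0
    n_de_sex: int = 0

    def validate(self) -> None:
        assert self.n_analyzed == self.n_expressed - self.n_sfp_flagged
        assert self.n_de_dom_final <= self.n_de_dom_initial
        assert self.n_de_strain_2fold <= self.n_de_strain
        assert self.n_de_dom_2fold <= self.n_de_dom_final

    def to_dict(self) -> dict[str, int]:
        return asdict(self)


@dataclass
class PipelineResult:
    ledger: CountLedger
    expression: ExpressionMatrix  # full summarized matrix
    filtered_expression: ExpressionMatrix  # after expression + IQR filters
    calls: preprocess.DetectionCalls
    expression_threshold: float
    sfp_report: sfp_mod.SFPReport
    de_strain: pd.DataFrame
    de_domestication: pd.DataFrame
    de_sex: pd.DataFrame
    strain_fold_changes: pd.DataFrame
    dom_fold_changes: pd.DataFrame
    dom_final_probesets: list[str]
    enrichment: pd.DataFrame | None
    log: list[str] = field(default_factory=list)


def run_pipeline(
    dataset: ProbeLevelDataset,
    config: PipelineConfig = PipelineConfig(),
    annotation: AnnotationTable | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis on an in-memory dataset.

    Any stage failure is re-raised as :class:`PipelineStageError` naming
    the stage.
    """
    from contextlib import contextmanager

    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    @contextmanager
    def stage(name: str):
        try:
            yield
        except PipelineStageError:
            raise
        except Exception as err:
            raise PipelineStageError(name, err) from err

    ledger = CountLedger(n_probesets_total=dataset.n_probesets)
    note(f"loaded {dataset.n_probesets} probe sets x {len(dataset.samples)} samples")

    # --- preprocessing ----------------------------------------------------
    with stage("rma"):
        expr, log2_probes = preprocess.rma(dataset)
    with stage("detection_calls"):
        calls = preprocess.detection_calls(
            dataset,
            tau=config.tau,
            p_present=config.p_present,
            p_absent=config.p_absent,
        )
    filtered, threshold = preprocess.expression_threshold_filter(
        expr, calls, percentile=config.absent_percentile
    )
    note(
        f"expression filter: threshold {threshold:.4g}, "
        f"{len(filtered.probeset_ids)} probe sets retained"
    )
    filtered = preprocess.iqr_filter(filtered, min_iqr=config.min_iqr)
    note(f"IQR filter: {len(filtered.probeset_ids)} probe sets retained")

    controls = dataset.control_flags()
    control_ids = set(controls.index[controls])
    if not config.controls_post_hoc:
        keep = [p for p in filtered.probeset_ids if p not in control_ids]
        n_ctl = len(filtered.probeset_ids) - len(keep)
        if n_ctl:
            note(f"excluded {n_ctl} control probe sets")
        filtered = ExpressionMatrix(filtered.values.loc[keep])
    ledger.n_expressed = len(filtered.probeset_ids)

    # --- SFP screen -------------------------------------------------------
    in_filtered = dataset.probe_map["probeset_id"].isin(
        set(filtered.probeset_ids)
    ).to_numpy()
    probe_map_f = dataset.probe_map.loc[in_filtered].reset_index(drop=True)
    with stage("sfp_screen"):
        residuals = sfp_mod.compute_probe_residuals(
            log2_probes[in_filtered], filtered, probe_map_f
        )
        strains = np.array([s.strain for s in dataset.samples])
        probe_stats = sfp_mod.sam_multiclass(
            residuals,
            strains,
            n_permutations=config.sfp_permutations,
            seed=config.seed,
        )
        report = sfp_mod.flag_sfp_probesets(
            probe_stats, probe_map_f, alpha=config.sfp_alpha
        )
    flagged = report.flagged_probesets()
    ledger.n_sfp_flagged = len(flagged)
    analyzed = ExpressionMatrix(
        filtered.values.loc[[p for p in filtered.probeset_ids if p not in flagged]]
    )
    if config.controls_post_hoc:
        keep = [p for p in analyzed.probeset_ids if p not in control_ids]
        analyzed = ExpressionMatrix(analyzed.values.loc[keep])
    ledger.n_analyzed = len(analyzed.probeset_ids)
    note(
        f"SFP screen: {ledger.n_sfp_flagged} probe sets flagged, "
        f"{ledger.n_analyzed} analyzed"
    )

    # --- differential expression -----------------------------------------
    wild = tuple(
        sorted({s.strain for s in dataset.samples if s.domestication == "wild"})
    )
    with stage("differential_expression"):
        design_strain = diffexpr.make_design(dataset.samples, model="strain")
        fits = diffexpr.fit_gene_linear_models(analyzed, design_strain)
        mfit = diffexpr.moderate_variances(fits)
        de_strain = diffexpr.test_contrasts(
            mfit, "among_strain", wild_strains=wild, fdr=config.fdr
        )
        de_dom = diffexpr.test_contrasts(
            mfit, "wild_vs_domesticated", wild_strains=wild, fdr=config.fdr
        )
        design_factorial = diffexpr.make_design(dataset.samples, model="strain_sex")
        fits_fact = diffexpr.fit_gene_linear_models(analyzed, design_factorial)
        mfit_fact = diffexpr.moderate_variances(fits_fact)
        de_sex = diffexpr.test_contrasts(
            mfit_fact, "sex", wild_strains=wild, fdr=config.fdr
        )

    strain_groups = {
        st: [s.sample_id for s in dataset.samples if s.strain == st]
        for st in design_strain.strains
    }
    strain_fc = diffexpr.fold_changes(analyzed, strain_groups)
    wild_ids = [s.sample_id for s in dataset.samples if s.domestication == "wild"]
    dom_ids = [
        s.sample_id for s in dataset.samples if s.domestication == "domesticated"
    ]
    dom_fc = diffexpr.fold_changes(
        analyzed, {"domesticated": dom_ids, "wild": wild_ids}
    )

    sig_strain = set(de_strain.loc[de_strain["significant"], "probeset_id"])
    sig_dom = list(de_dom.loc[de_dom["significant"], "probeset_id"])
    dom_final = diffexpr.range_overlap_filter(
        analyzed, wild_ids, dom_ids, sig_dom, max_overlap=config.max_overlap
    )
    fc_by_id_strain = strain_fc.set_index("probeset_id")["fold_change"]
    fc_by_id_dom = dom_fc.set_index("probeset_id")["fold_change"]
    ledger.n_de_strain = len(sig_strain)
    ledger.n_de_strain_2fold = int(
        (fc_by_id_strain.loc[sorted(sig_strain)] >= config.fold_change_threshold).sum()
    )
    ledger.n_de_dom_initial = len(sig_dom)
    ledger.n_de_dom_final = len(dom_final)
    ledger.n_de_dom_2fold = int(
        (fc_by_id_dom.loc[dom_final] >= config.fold_change_threshold).sum()
    )
    ledger.n_de_sex = int(de_sex["significant"].sum())
    ledger.validate()
    note(
        f"DE: {ledger.n_de_strain} among-strain ({ledger.n_de_strain_2fold} >= "
        f"{config.fold_change_threshold}-fold), {ledger.n_de_dom_initial} -> "
        f"{ledger.n_de_dom_final} domestication ({ledger.n_de_dom_2fold} >= "
        f"{config.fold_change_threshold}-fold), {ledger.n_de_sex} sex"
    )

    # --- enrichment -------------------------------------------------------
    enrich_table = None
    if annotation is not None:
        background = list(filtered.probeset_ids)
        gene_list = sorted(sig_strain)
        enrich_table = enrichment.run_enrichment(
            gene_list, background, annotation, alpha=0.05
        )
        note(
            f"enrichment: {int(enrich_table['overrepresented'].sum()) if len(enrich_table) else 0} "
            "categories overrepresented"
        )

    result = PipelineResult(
        ledger=ledger,
        expression=expr,
        filtered_expression=filtered,
        calls=calls,
        expression_threshold=threshold,
        sfp_report=report,
        de_strain=de_strain,
        de_domestication=de_dom,
        de_sex=de_sex,
        strain_fold_changes=strain_fc,
        dom_fold_changes=dom_fc,
        dom_final_probesets=dom_final,
        enrichment=enrich_table,
        log=log,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), config)
    return result


def run_pipeline_from_paths(
    pm_path: str | Path,
    mm_path: str | Path,
    samples_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
    annotation_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    dataset = load_probe_level_dataset(pm_path, mm_path, samples_path)
    annotation = (
        load_annotation_table(annotation_path) if annotation_path else None
    )
    return run_pipeline(dataset, config, annotation=annotation, out_dir=out_dir)


def _write_outputs(
    result: PipelineResult, out: Path, config: PipelineConfig
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    expr_df = result.filtered_expression.values.reset_index()
    expr_df.to_csv(out / "expr.tsv", sep="\t", index=False, float_format="%.12g")
    result.calls.call.reset_index().to_csv(out / "calls.tsv", sep="\t", index=False)
    write_result_table(
        result.sfp_report.probes.sort_values(["q", "probe_id"], kind="mergesort"),
        out / "sfp.tsv",
        id_column="probe_id",
        p_column="q",
    )
    write_result_table(result.de_strain, out / "de_strain.tsv", id_column="probeset_id")
    write_result_table(
        result.de_domestication, out / "de_domestication.tsv", id_column="probeset_id"
    )
    write_result_table(result.de_sex, out / "de_sex.tsv", id_column="probeset_id")
    if result.enrichment is not None:
        write_result_table(
            result.enrichment, out / "enrich.tsv", id_column="category_id",
            p_column="ease_p",
        )
    payload = {"config": asdict(config), "ledger": result.ledger.to_dict()}
    (out / "ledger.json").write_text(json.dumps(payload, indent=2) + "\n")
    (out / "log.txt").write_text("\n".join(result.log) + "\n")
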