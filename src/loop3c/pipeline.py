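"""End-to-end run orchestration.

``run_pipeline`` wires the stages together from a validated
:class:`~loop3c.config.RunConfig`: digest the locus, check digestion QC,
build the bait-anchored interaction profile, fit the distance-decay
background, compute fold enrichments and call loops; then, when the
corresponding inputs are configured, the expression, ChIP, and ddPCR
quantifications.  Every stage logs its inputs and parameters, all result
tables are written as TSV/BED next to a JSON summary, and the effective
configuration is echoed into the output directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import chip as chip_mod
from . import ddpcr as ddpcr_mod
from . import io as io_mod
from . import locus as locus_mod
from . import qpcr, threec
from .config import RunConfig
from .errors import Loop3cError

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    summary: dict
    locus: locus_mod.LocusModel | None = None
    profile: threec.InteractionProfile | None = None
    background: threec.BackgroundModel | None = None
    loop_calls: list[threec.LoopCall] = field(default_factory=list)
    qc_report: qpcr.DigestionQCReport | None = None
    expression: list[qpcr.ExpressionResult] = field(default_factory=list)
    chip: list[chip_mod.ChipResult] = field(default_factory=list)
    ddpcr: list[ddpcr_mod.NormalizedRatio] = field(default_factory=list)


def _setup_logging(outdir: Path, level: str) -> None:
    root = logging.getLogger("loop3c")
    for h in [h for h in root.handlers if isinstance(h, logging.FileHandler)]:
        root.removeHandler(h)
        h.close()
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root.addHandler(handler)
    root.setLevel(level.upper())


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all configured stages; see the module docstring."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)
    config.write_yaml(outdir / "effective_config.yaml")
    logger.info("run starting; seed=%d; output=%s", config.seed, outdir)

    summary: dict = {"stages": [], "seed": config.seed}
    result = RunResult(summary=summary)

    # --- locus -----------------------------------------------------------
    fasta = config.inputs.locus_fasta
    if not fasta:
        raise Loop3cError("no locus FASTA configured")
    _, sequence = locus_mod.read_locus_fasta(fasta)
    locus = locus_mod.build_locus_model(
        sequence,
        config.locus.tss_position,
        config.locus.gene_strand,
        motif=config.locus.motif,
        cut_offset=config.locus.cut_offset,
    )
    result.locus = locus
    locus_mod.write_fragments_bed(locus, outdir / "fragments.bed")
    locus_mod.write_fragments_tsv(locus, outdir / "fragments.tsv")
    summary["stages"].append("digest")
    summary["n_fragments"] = len(locus.fragments)
    summary["bait_fragment_id"] = locus.bait_fragment_id
    logger.info(
        "digest: %d fragments, bait fragment %d",
        len(locus.fragments),
        locus.bait_fragment_id,
    )

    # --- digestion QC ----------------------------------------------------
    if config.inputs.digestion_qc:
        qc_df = io_mod.read_digestion_qc_csv(config.inputs.digestion_qc)
        effs = {
            str(r["site"]): qpcr.digestion_efficiency(
                r["cq_site_digested"],
                r["cq_ctrl_digested"],
                r["cq_site_undigested"],
                r["cq_ctrl_undigested"],
            )
            for _, r in qc_df.iterrows()
        }
        report = qpcr.qc_digestion(effs, config.threec.digestion_threshold_percent)
        result.qc_report = report
        io_mod.write_tsv(
            pd.DataFrame(
                {
                    "site": list(report.efficiencies),
                    "efficiency_percent": list(report.efficiencies.values()),
                    "passed": [s not in report.failing_sites for s in report.efficiencies],
                }
            ),
            outdir / "digestion_qc.tsv",
        )
        summary["stages"].append("digestion_qc")
        summary["digestion_qc_passed"] = report.passed
        if not report.passed:
            msg = f"digestion QC failed at sites: {list(report.failing_sites)}"
            if config.threec.require_digestion_qc:
                raise Loop3cError(msg)
            logger.warning("%s (continuing: warn-only mode)", msg)

    # --- 3C profile and loop calls --------------------------------------
    if config.inputs.plate_3c:
        plate = io_mod.read_plate_csv(config.inputs.plate_3c)
        anchor_map = io_mod.read_anchor_map(config.inputs.anchor_map)
        library_id = config.threec.library_id or str(plate["sample"].iloc[0])
        profile = threec.build_profile(
            plate,
            locus,
            library_id,
            anchor_map,
            normalizer_assay=config.threec.normalizer_assay,
        )
        background = threec.fit_background(
            profile,
            iterative=config.threec.iterative_background,
            z_threshold=config.threec.background_z_threshold,
        )
        enrichments = threec.fold_enrichments(
            profile, background, proximal_window_kb=config.threec.proximal_window_kb
        )
        calls = threec.call_loops(
            enrichments,
            min_fold_background=config.threec.min_fold_background,
            min_fold_proximal=config.threec.min_fold_proximal,
        )
        result.profile, result.background, result.loop_calls = profile, background, calls

        io_mod.write_tsv(threec.profile_table(profile), outdir / "profile.tsv")
        io_mod.write_tsv(threec.loop_calls_table(calls), outdir / "loop_calls.tsv")
        peaks = [c for c in calls if c.is_peak]
        with open(outdir / "loops.bed", "w") as fh:
            for c in peaks:
                frag = locus.fragment(c.fragment_id)
                fh.write(
                    f"{frag.interval.chrom}\t{frag.interval.start}\t{frag.interval.end}"
                    f"\tloop_{c.tss_distance_kb:+.1f}kb\t0\t{locus.gene_strand}\n"
                )
        threec.plot_profile(profile, background, calls, str(outdir / "profile.png"))
        summary["stages"].append("threec")
        summary["background"] = {
            "log_a": background.log_a,
            "b": background.b,
            "flat": background.flat,
            "excluded_fragments": list(background.excluded_fragments),
            "fit_rmse": background.fit_rmse,
        }
        summary["n_loop_calls"] = len(peaks)
        summary["loop_calls"] = [
            {
                "fragment_id": c.fragment_id,
                "tss_distance_kb": c.tss_distance_kb,
                "fold_over_background": c.fold_over_background,
                "fold_over_proximal": c.fold_over_proximal,
            }
            for c in peaks
        ]
        logger.info("3C: %d loop call(s) at %s kb", len(peaks),
                    [round(c.tss_distance_kb, 1) for c in peaks])

    # --- expression ------------------------------------------------------
    if config.inputs.expression_plate:
        plate = io_mod.read_plate_csv(config.inputs.expression_plate)
        p = config.expression
        test_samples = p.test_samples or sorted(
            set(plate["sample"]) - {p.calibrator_sample}
        )
        results = qpcr.expression_results(
            plate,
            p.target_assay,
            p.reference_assays,
            test_samples,
            p.calibrator_sample,
            star_thresholds=tuple(p.star_thresholds),
        )
        result.expression = results
        io_mod.write_tsv(qpcr.expression_results_table(results), outdir / "expression.tsv")
        summary["stages"].append("expression")
        summary["expression"] = [
            {
                "sample": r.sample,
                "reference_gene": r.reference_gene,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "stars": r.stars,
            }
            for r in results
        ]

    # --- ChIP ------------------------------------------------------------
    if config.inputs.chip_wells:
        wells = io_mod.read_chip_csv(config.inputs.chip_wells)
        results = chip_mod.chip_results(
            wells,
            antibody=config.chip.antibody,
            star_thresholds=tuple(config.chip.star_thresholds),
        )
        result.chip = results
        io_mod.write_tsv(chip_mod.chip_results_table(results), outdir / "chip.tsv")
        summary["stages"].append("chip")
        summary["chip"] = [
            {
                "cell_line": r.cell_line,
                "region": r.region,
                "fold_over_igg": r.fold_over_igg,
                "p_value": r.p_value,
                "stars": r.stars,
            }
            for r in results
        ]

    # --- ddPCR -----------------------------------------------------------
    if config.inputs.ddpcr_wells:
        wells = io_mod.read_ddpcr_csv(config.inputs.ddpcr_wells)
        p = config.ddpcr
        test_samples = p.test_samples or sorted(
            set(wells["sample"]) - {p.calibrator_sample}
        )
        ratios = [
            ddpcr_mod.normalized_ratio(
                wells, p.target_assay, p.reference_assay, s, p.calibrator_sample
            )
            for s in test_samples
        ]
        result.ddpcr = ratios
        io_mod.write_tsv(ddpcr_mod.ddpcr_results_table(wells), outdir / "ddpcr_wells.tsv")
        io_mod.write_tsv(
            pd.DataFrame(
                {
                    "test_sample": [r.test_sample for r in ratios],
                    "calibrator_sample": [r.calibrator_sample for r in ratios],
                    "fold": [r.fold for r in ratios],
                    "ci_low": [r.ci_low for r in ratios],
                    "ci_high": [r.ci_high for r in ratios],
                }
            ),
            outdir / "ddpcr_ratios.tsv",
        )
        summary["stages"].append("ddpcr")
        summary["ddpcr"] = [
            {"sample": r.test_sample, "fold": r.fold} for r in ratios
        ]

    io_mod.write_json(summary, outdir / "summary.json")
    logger.info("run complete: stages %s", summary["stages"])
    return result
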