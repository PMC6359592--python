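"""Seeded synthetic-data generator for the whole pipeline.

A :class:`Scenario` fully parameterizes one virtual experiment: locus
geometry (a ~200-kb region with planted HindIII sites and a TSS), a
power-law contact-decay curve with optional loops injected at named
anchors, expression fold changes per reference gene, ChIP enrichments over
IgG, ddPCR concentration ratios, and per-assay Cq noise.  The scenario's
ground truth is exactly what the analysis modules should recover, which
makes every downstream operation testable with no external data.

The generative model, per assay family:

* locus — random ACGT sequence with the restriction motif planted so that
  one fragment midpoint coincides with each anchor; accidental motif
  occurrences are rejection-edited away, so the digest ground truth is the
  planted cut list.
* 3C — true relative frequency ``a * |d|**-b`` times the loop fold at
  looping anchors; junction Cq = normalizer Cq - log2(rel) + Gaussian
  noise per replicate; the normalizer Cq is drawn once per plate.
  Digestion-QC wells are emitted from the digestion-efficiency truth.
* expression — target Cq shifted down by log2(fold); when the fold differs
  between reference genes, the non-anchor reference absorbs the
  difference.  A per-sample loading shift (which cancels in ddCt) adds
  realism.
* ChIP — IP well Cq derived from the true percent input; the input well is
  shared per (region, experiment) between antibody and IgG.
* ddPCR — droplet positives drawn binomially with p = 1 - exp(-lambda).

Identical scenario + seed gives byte-identical outputs; each assay family
draws from its own independent, seed-derived stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidScenarioError
from .locus import LocusModel, build_locus_model, find_motif_positions, locate_fragment
from .threec import DEFAULT_NORMALIZER_ASSAY

# independent rng streams per assay family
_STREAM_LOCUS, _STREAM_3C, _STREAM_EXPR, _STREAM_CHIP, _STREAM_DDPCR = range(5)

# plate-level Cq baselines (arbitrary but fixed; all downstream statistics
# are invariant to them)
TARGET_BASE_CQ = 26.0
REFERENCE_BASE_CQ = {"GAPDH": 18.0, "PBGD": 24.0}
DEFAULT_REFERENCE_BASE_CQ = 22.0
QC_BASE_CQ = 24.0
CHIP_INPUT_BASE_CQ = 24.0
SAMPLE_SHIFT_SD = 0.3
CHIP_INPUT_SHIFT_SD = 0.4

TARGET_ASSAY = "PTBP3"


def _require_keys(d: Mapping, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise InvalidScenarioError(f"unknown key(s) in {context}: {sorted(unknown)}")


@dataclass(frozen=True)
class LocusSpec:
    length_bp: int = 210_000
    tss_position: int = 85_000
    gene_strand: str = "+"
    motif: str = "AAGCTT"
    anchor_fragment_bp: int = 1500
    bait_fragment_bp: int = 2000
    extra_cut_sites: int = 8


@dataclass(frozen=True)
class DecaySpec:
    a: float = 6.8**0.5
    b: float = 0.5


@dataclass(frozen=True)
class LoopSpec:
    anchor_kb: float
    fold: float


@dataclass(frozen=True)
class DigestionSpec:
    efficiency: float = 0.92
    cq_noise_sd: float = 0.15


@dataclass(frozen=True)
class ExpressionSpec:
    calibrator: str = "fibroblast"
    #: sample -> {reference gene -> true fold vs calibrator}
    samples: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class ChipSpec:
    cell_line: str = "PC3M"
    experiments: int = 2
    input_fraction: float = 0.01
    baseline_percent_input: float = 0.05
    #: region -> true fold over IgG
    folds: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class DdpcrSpec:
    calibrator: str = "fibroblast"
    #: sample -> true reference-normalized ratio vs calibrator
    samples: dict[str, float] = field(default_factory=dict)
    reference_lambda: float = 0.5
    target_base_lambda: float = 0.2
    wells_per_sample: int = 2
    total_droplets: int = 15_000
    droplet_volume_nl: float = 0.85


@dataclass(frozen=True)
class Scenario:
    """Complete parameterization of one synthetic experiment."""

    name: str = "scenario"
    seed: int = 0
    locus: LocusSpec = field(default_factory=LocusSpec)
    anchors_kb: tuple[float, ...] = (-79.7, -63.2, -30.7, -6.8, 48.4, 71.3, 119.3)
    decay: DecaySpec = field(default_factory=DecaySpec)
    loops: tuple[LoopSpec, ...] = ()
    replicates: int = 3
    normalizer_cq: float = 25.0
    cq_noise_sd_3c: float = 0.15
    cq_noise_sd_expression: float = 0.12
    cq_noise_sd_chip: float = 0.15
    digestion: DigestionSpec = field(default_factory=DigestionSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    chip: ChipSpec = field(default_factory=ChipSpec)
    ddpcr: DdpcrSpec = field(default_factory=DdpcrSpec)

    def __post_init__(self) -> None:
        anchor_set = set(self.anchors_kb)
        for loop in self.loops:
            if loop.anchor_kb not in anchor_set:
                raise InvalidScenarioError(
                    f"loop at {loop.anchor_kb} kb references no anchor"
                )
            if loop.fold <= 0:
                raise InvalidScenarioError("loop folds must be > 0")
        if self.replicates < 1:
            raise InvalidScenarioError("replicates must be >= 1")
        if not 0 < self.digestion.efficiency < 1:
            raise InvalidScenarioError("digestion efficiency must be in (0, 1)")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        _require_keys(
            d,
            {
                "name", "seed", "locus", "anchors_kb", "decay", "loops",
                "replicates", "normalizer_cq", "cq_noise_sd_3c",
                "cq_noise_sd_expression", "cq_noise_sd_chip", "digestion",
                "expression", "chip", "ddpcr",
            },
            "scenario",
        )
        locus_d = dict(d.get("locus", {}))
        _require_keys(locus_d, set(LocusSpec.__dataclass_fields__), "locus")
        decay_d = dict(d.get("decay", {}))
        _require_keys(decay_d, set(DecaySpec.__dataclass_fields__), "decay")
        dig_d = dict(d.get("digestion", {}))
        _require_keys(dig_d, set(DigestionSpec.__dataclass_fields__), "digestion")
        expr_d = dict(d.get("expression", {}))
        _require_keys(expr_d, set(ExpressionSpec.__dataclass_fields__), "expression")
        chip_d = dict(d.get("chip", {}))
        _require_keys(chip_d, set(ChipSpec.__dataclass_fields__), "chip")
        ddpcr_d = dict(d.get("ddpcr", {}))
        _require_keys(ddpcr_d, set(DdpcrSpec.__dataclass_fields__), "ddpcr")
        loops = tuple(
            LoopSpec(**{"anchor_kb": float(l["anchor_kb"]), "fold": float(l["fold"])})
            for l in d.get("loops", [])
        )
        expr_samples = {
            str(s): {str(g): float(f) for g, f in genes.items()}
            for s, genes in dict(expr_d.pop("samples", {}) or {}).items()
        }
        chip_folds = {
            str(r): float(f) for r, f in dict(chip_d.pop("folds", {}) or {}).items()
        }
        ddpcr_samples = {
            str(s): float(f) for s, f in dict(ddpcr_d.pop("samples", {}) or {}).items()
        }
        return cls(
            name=str(d.get("name", "scenario")),
            seed=int(d.get("seed", 0)),
            locus=LocusSpec(**locus_d),
            anchors_kb=tuple(float(a) for a in d.get("anchors_kb", cls.anchors_kb)),
            decay=DecaySpec(**decay_d),
            loops=loops,
            replicates=int(d.get("replicates", 3)),
            normalizer_cq=float(d.get("normalizer_cq", 25.0)),
            cq_noise_sd_3c=float(d.get("cq_noise_sd_3c", 0.15)),
            cq_noise_sd_expression=float(d.get("cq_noise_sd_expression", 0.12)),
            cq_noise_sd_chip=float(d.get("cq_noise_sd_chip", 0.15)),
            digestion=DigestionSpec(**dig_d),
            expression=ExpressionSpec(samples=expr_samples, **expr_d),
            chip=ChipSpec(folds=chip_folds, **chip_d),
            ddpcr=DdpcrSpec(samples=ddpcr_samples, **ddpcr_d),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise InvalidScenarioError(f"{path}: scenario YAML must be a mapping")
        return cls.from_dict(data)

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=int(seed))

    # -- derived quantities ------------------------------------------------

    def loop_fold_at(self, anchor_kb: float) -> float:
        for loop in self.loops:
            if abs(loop.anchor_kb - anchor_kb) < 1e-9:
                return loop.fold
        return 1.0

    def true_rel_frequency(self, anchor_kb: float) -> float:
        d = abs(anchor_kb)
        return self.decay.a * d**-self.decay.b * self.loop_fold_at(anchor_kb)

    def rng(self, stream: int, seed: int | None = None) -> np.random.Generator:
        return np.random.default_rng(
            [int(self.seed if seed is None else seed), stream]
        )


def available_presets() -> list[str]:
    pkg = resources.files("loop3c") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> Scenario:
    """Load a bundled scenario preset (pc3m, pc3, fibroblast, null)."""
    pkg = resources.files("loop3c") / "presets" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise InvalidScenarioError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    data = yaml.safe_load(text)
    return Scenario.from_dict(data)


# ---------------------------------------------------------------------------
# locus construction


@dataclass
class SimulatedLocus:
    sequence: str
    locus: LocusModel
    cut_positions: list[int]
    anchor_map: pd.DataFrame  # assay, anchor_kb, position, fragment_id

    def assay_for_anchor(self, anchor_kb: float) -> str:
        row = self.anchor_map[np.isclose(self.anchor_map["anchor_kb"], anchor_kb)]
        if row.empty:
            raise InvalidScenarioError(f"no anchor at {anchor_kb} kb")
        return str(row["assay"].iloc[0])

    def fragment_for_anchor(self, anchor_kb: float) -> int:
        row = self.anchor_map[np.isclose(self.anchor_map["anchor_kb"], anchor_kb)]
        if row.empty:
            raise InvalidScenarioError(f"no anchor at {anchor_kb} kb")
        return int(row["fragment_id"].iloc[0])


def _junction_assay_name(anchor_kb: float) -> str:
    return f"junction_{anchor_kb:+.1f}kb"


def _planted_cuts(scenario: Scenario) -> list[int]:
    sp = scenario.locus
    tss = sp.tss_position
    half_anchor = sp.anchor_fragment_bp // 2
    half_bait = sp.bait_fragment_bp // 2
    cuts = {tss - half_bait, tss + half_bait}
    for a in scenario.anchors_kb:
        center = tss + round(a * 1000)
        lo, hi = center - half_anchor, center + half_anchor
        if lo <= 0 or hi >= sp.length_bp:
            raise InvalidScenarioError(
                f"anchor at {a} kb falls outside the {sp.length_bp}-bp locus"
            )
        cuts.add(lo)
        cuts.add(hi)
    ordered = sorted(cuts)
    if ordered[0] <= 0 or ordered[-1] >= sp.length_bp:
        raise InvalidScenarioError(
            "planted cut sites fall outside the locus; enlarge the locus or "
            "shrink the bait/anchor fragments"
        )
    min_gap = 2 * len(sp.motif)
    for c1, c2 in zip(ordered, ordered[1:]):
        if c2 - c1 < min_gap:
            raise InvalidScenarioError(
                f"planted cut sites {c1} and {c2} are closer than {min_gap} bp; "
                "anchors too close together"
            )
    return ordered


def make_locus(scenario: Scenario, *, seed: int | None = None) -> SimulatedLocus:
    """Build the synthetic locus sequence and its ground-truth fragment map.

    The restriction motif appears exactly at the planted cut positions:
    one fragment is centered on each anchor (midpoint within half a
    fragment of the stated kb position), one on the TSS (the bait), and a
    few extra cut sites fall in between to vary fragment sizes the way a
    real HindIII map does.
    """
    sp = scenario.locus
    rng = scenario.rng(_STREAM_LOCUS, seed)
    cuts = _planted_cuts(scenario)

    # extra cuts, kept clear of planted fragments so anchor midpoints stay put
    extra: list[int] = []
    attempts = 0
    while len(extra) < sp.extra_cut_sites and attempts < 1000:
        attempts += 1
        pos = int(rng.integers(1000, sp.length_bp - 1000))
        if all(abs(pos - c) >= 2000 for c in [*cuts, *extra]):
            extra.append(pos)
    cuts = sorted([*cuts, *extra])

    motif = sp.motif.upper()
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=sp.length_bp)
    # plant the motif at every cut
    motif_arr = np.array(list(motif))
    planted_spans = [(c, c + len(motif)) for c in cuts]
    for c in cuts:
        seq[c : c + len(motif)] = motif_arr

    # edit away accidental occurrences (N never matches, so editing to a
    # different base suffices); repeat until only planted motifs remain
    planted_set = set(cuts)
    for _ in range(50):
        text = "".join(seq)
        accidental = [p for p in find_motif_positions(text, motif) if p not in planted_set]
        if not accidental:
            break
        for occ in accidental:
            for offset in range(len(motif)):
                idx = occ + offset
                if not any(lo <= idx < hi for lo, hi in planted_spans):
                    current = seq[idx]
                    choices = [b for b in "ACGT" if b != current]
                    seq[idx] = choices[int(rng.integers(len(choices)))]
                    break
    else:  # pragma: no cover - construction failure
        raise InvalidScenarioError("could not purge accidental motif occurrences")

    sequence = "".join(seq)
    assert find_motif_positions(sequence, motif) == cuts

    locus = build_locus_model(
        sequence,
        sp.tss_position,
        sp.gene_strand,
        motif=motif,
        chrom=f"{scenario.name}_locus",
    )
    rows = []
    for a in scenario.anchors_kb:
        pos = sp.tss_position + round(a * 1000)
        rows.append(
            {
                "assay": _junction_assay_name(a),
                "anchor_kb": a,
                "position": pos,
                "fragment_id": locate_fragment(locus, pos),
            }
        )
    return SimulatedLocus(
        sequence=sequence,
        locus=locus,
        cut_positions=cuts,
        anchor_map=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# plate simulators


@dataclass
class Plates3C:
    plate: pd.DataFrame      # sample, assay, replicate, cq
    qc: pd.DataFrame         # library, site, 4 paired Cq columns
    truth: pd.DataFrame      # assay, anchor_kb, fragment_id, rel_true, loop_fold
    library_id: str


def simulate_3c_plates(
    scenario: Scenario,
    simlocus: SimulatedLocus,
    *,
    seed: int | None = None,
) -> Plates3C:
    """TaqMan junction plate + SYBR digestion-QC plate for one 3C library."""
    rng = scenario.rng(_STREAM_3C, seed)
    sd = scenario.cq_noise_sd_3c
    library_id = f"{scenario.name}_3c"

    rows = []
    truth_rows = []
    # normalizer Cq: one draw per plate
    norm_cq = scenario.normalizer_cq + rng.normal(0.0, sd)
    rows.append(
        {
            "sample": library_id,
            "assay": DEFAULT_NORMALIZER_ASSAY,
            "replicate": 1,
            "cq": norm_cq,
        }
    )
    for a in scenario.anchors_kb:
        rel = scenario.true_rel_frequency(a)
        assay = _junction_assay_name(a)
        for rep in range(1, scenario.replicates + 1):
            cq = scenario.normalizer_cq - math.log2(rel) + rng.normal(0.0, sd)
            rows.append(
                {"sample": library_id, "assay": assay, "replicate": rep, "cq": cq}
            )
        truth_rows.append(
            {
                "assay": assay,
                "anchor_kb": a,
                "fragment_id": simlocus.fragment_for_anchor(a),
                "rel_true": rel,
                "loop_fold": scenario.loop_fold_at(a),
            }
        )

    # digestion QC: per anchored site, paired digested/undigested wells for
    # a site-spanning and a control amplicon
    qc_rows = []
    dig = scenario.digestion
    true_ddcq = -math.log2(1.0 - dig.efficiency)
    for a in scenario.anchors_kb:
        qc_rows.append(
            {
                "library": library_id,
                "site": _junction_assay_name(a),
                "cq_site_digested": QC_BASE_CQ + true_ddcq + rng.normal(0.0, dig.cq_noise_sd),
                "cq_ctrl_digested": QC_BASE_CQ + rng.normal(0.0, dig.cq_noise_sd),
                "cq_site_undigested": QC_BASE_CQ + rng.normal(0.0, dig.cq_noise_sd),
                "cq_ctrl_undigested": QC_BASE_CQ + rng.normal(0.0, dig.cq_noise_sd),
            }
        )

    return Plates3C(
        plate=pd.DataFrame(rows),
        qc=pd.DataFrame(qc_rows),
        truth=pd.DataFrame(truth_rows),
        library_id=library_id,
    )


def simulate_expression_plates(
    scenario: Scenario, *, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression Cq plate (target + reference genes) and its truth table.

    The first reference gene of each sample's fold map anchors the target
    Cq shift; other references absorb the between-gene fold difference, so
    ddCt against each gene recovers that gene's stated fold.
    """
    rng = scenario.rng(_STREAM_EXPR, seed)
    sd = scenario.cq_noise_sd_expression
    spec = scenario.expression
    all_refs: list[str] = []
    for genes in spec.samples.values():
        for g in genes:
            if g not in all_refs:
                all_refs.append(g)
    if not all_refs:
        all_refs = ["GAPDH", "PBGD"]

    samples = {spec.calibrator: {g: 1.0 for g in all_refs}}
    samples.update(spec.samples)

    rows = []
    truth_rows = []
    for sample, folds in samples.items():
        shift = rng.normal(0.0, SAMPLE_SHIFT_SD)
        anchor_ref = next(iter(folds))
        f_anchor = folds[anchor_ref]
        for rep in range(1, scenario.replicates + 1):
            rows.append(
                {
                    "sample": sample,
                    "assay": TARGET_ASSAY,
                    "replicate": rep,
                    "cq": TARGET_BASE_CQ + shift - math.log2(f_anchor) + rng.normal(0.0, sd),
                }
            )
        for ref in all_refs:
            f_ref = folds.get(ref, 1.0)
            base = REFERENCE_BASE_CQ.get(ref, DEFAULT_REFERENCE_BASE_CQ)
            delta = math.log2(f_ref / f_anchor)
            for rep in range(1, scenario.replicates + 1):
                rows.append(
                    {
                        "sample": sample,
                        "assay": ref,
                        "replicate": rep,
                        "cq": base + shift + delta + rng.normal(0.0, sd),
                    }
                )
            if sample != spec.calibrator:
                truth_rows.append(
                    {"sample": sample, "reference_gene": ref, "true_fold": f_ref}
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_chip_plates(
    scenario: Scenario, *, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ChIP-qPCR well table and truth for the scenario's cell line."""
    rng = scenario.rng(_STREAM_CHIP, seed)
    sp = scenario.chip
    sd = scenario.cq_noise_sd_chip
    adj = math.log2(1.0 / sp.input_fraction)
    rows = []
    truth_rows = []
    for region, fold in sp.folds.items():
        pct_igg = sp.baseline_percent_input
        pct_ab = pct_igg * fold
        for exp in range(1, sp.experiments + 1):
            input_base = CHIP_INPUT_BASE_CQ + rng.normal(0.0, CHIP_INPUT_SHIFT_SD)
            common = {
                "cell_line": sp.cell_line,
                "region": region,
                "experiment": exp,
                "input_fraction": sp.input_fraction,
            }
            rows.append(
                {**common, "antibody": "input", "cq": input_base + rng.normal(0.0, sd)}
            )
            for antibody, pct in (("H3K27ac", pct_ab), ("IgG", pct_igg)):
                cq_ip = (input_base - adj) - math.log2(pct / 100.0) + rng.normal(0.0, sd)
                rows.append({**common, "antibody": antibody, "cq": cq_ip})
        truth_rows.append(
            {
                "cell_line": sp.cell_line,
                "region": region,
                "true_fold_over_igg": fold,
                "baseline_percent_input": pct_igg,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_ddpcr_wells(
    scenario: Scenario, *, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Droplet-count wells (target + reference assays) and truth ratios."""
    rng = scenario.rng(_STREAM_DDPCR, seed)
    sp = scenario.ddpcr
    samples = {sp.calibrator: 1.0, **sp.samples}
    rows = []
    truth_rows = []
    for sample, ratio in samples.items():
        lam_by_assay = {
            TARGET_ASSAY: sp.target_base_lambda * ratio,
            "PBGD": sp.reference_lambda,
        }
        for assay, lam in lam_by_assay.items():
            p = 1.0 - math.exp(-lam)
            for _ in range(sp.wells_per_sample):
                rows.append(
                    {
                        "sample": sample,
                        "assay": assay,
                        "positives": int(rng.binomial(sp.total_droplets, p)),
                        "total": sp.total_droplets,
                        "droplet_volume_nl": sp.droplet_volume_nl,
                    }
                )
        if sample != sp.calibrator:
            truth_rows.append({"sample": sample, "true_ratio": ratio})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# bundle writer


def write_scenario_bundle(scenario: Scenario, outdir: str | Path):
    """Materialize every input the pipeline consumes for one scenario.

    Writes the locus FASTA, ground-truth tables, the 3C/expression/ChIP
    plates, the ddPCR wells, the assay-to-fragment anchor map, and a
    ready-to-run ``run_config.yaml`` pointing at all of them.  Returns the
    :class:`~loop3c.config.RunConfig`.
    """
    from . import io as io_mod
    from .config import RunConfig

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simlocus = make_locus(scenario)
    plates3c = simulate_3c_plates(scenario, simlocus)
    expr_plate, expr_truth = simulate_expression_plates(scenario)
    chip_wells, chip_truth = simulate_chip_plates(scenario)
    ddpcr_wells, ddpcr_truth = simulate_ddpcr_wells(scenario)

    io_mod.write_fasta(f"{scenario.name}_locus", simlocus.sequence, outdir / "locus.fasta")
    io_mod.write_tsv(
        pd.DataFrame({"cut_position": simlocus.cut_positions}),
        outdir / "truth_cut_positions.tsv",
    )
    io_mod.write_tsv(simlocus.anchor_map, outdir / "anchor_map.tsv")
    plates3c.plate.to_csv(outdir / "plate_3c.csv", index=False)
    plates3c.qc.to_csv(outdir / "digestion_qc.csv", index=False)
    io_mod.write_tsv(plates3c.truth, outdir / "truth_3c.tsv")
    expr_plate.to_csv(outdir / "expression_plate.csv", index=False)
    io_mod.write_tsv(expr_truth, outdir / "truth_expression.tsv")
    chip_wells.to_csv(outdir / "chip_wells.csv", index=False)
    io_mod.write_tsv(chip_truth, outdir / "truth_chip.tsv")
    ddpcr_wells.to_csv(outdir / "ddpcr_wells.csv", index=False)
    io_mod.write_tsv(ddpcr_truth, outdir / "truth_ddpcr.tsv")

    config = RunConfig.from_dict(
        {
            "inputs": {
                "locus_fasta": str(outdir / "locus.fasta"),
                "plate_3c": str(outdir / "plate_3c.csv"),
                "digestion_qc": str(outdir / "digestion_qc.csv"),
                "anchor_map": str(outdir / "anchor_map.tsv"),
                "expression_plate": str(outdir / "expression_plate.csv"),
                "chip_wells": str(outdir / "chip_wells.csv"),
                "ddpcr_wells": str(outdir / "ddpcr_wells.csv"),
            },
            "locus": {
                "motif": scenario.locus.motif,
                "tss_position": scenario.locus.tss_position,
                "gene_strand": scenario.locus.gene_strand,
            },
            "threec": {"library_id": plates3c.library_id},
            "expression": {"calibrator_sample": scenario.expression.calibrator},
            "ddpcr": {"calibrator_sample": scenario.ddpcr.calibrator},
            "output_dir": str(outdir / "results"),
            "seed": scenario.seed,
        }
    )
    config.write_yaml(outdir / "run_config.yaml")
    return config
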