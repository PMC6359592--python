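"""Core Cq arithmetic.

Everything downstream of the thermocycler starts from the quantification
cycle (Cq): the cycle at which fluorescence crosses threshold.  One cycle
is one doubling at perfect efficiency, so relative template quantity is
``(1 + E) ** (-Cq)`` with amplification efficiency ``E`` in (0, 1].

This module provides:

* relative quantities and the restriction-digestion efficiency QC used to
  accept or reject a 3C library (every assayed site must exceed a cutoff,
  85% by default);
* the ddCt (delta-delta-Ct) relative-expression statistic against a
  calibrator sample, with a Welch t-test on per-replicate delta-Cq values,
  a t-interval back-transformed to the fold scale, and significance stars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientReplicatesError, InvalidInputError

DEFAULT_STAR_THRESHOLDS = (0.05, 0.01, 0.001)

#: Two-tier scheme sometimes used for ChIP panels: * below 0.05, ** below 0.001.
TWO_TIER_STAR_THRESHOLDS = (0.05, 0.001)


@dataclass(frozen=True)
class CqRecord:
    """One qPCR well."""

    sample: str
    assay: str
    replicate: int
    cq: float
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.cq) or self.cq <= 0:
            raise InvalidInputError(f"cq must be finite and positive, got {self.cq}")
        if not 0 < self.efficiency <= 1:
            raise InvalidInputError(
                f"efficiency must be in (0, 1], got {self.efficiency}"
            )


@dataclass(frozen=True)
class ExpressionResult:
    """Relative expression of one sample vs the calibrator."""

    sample: str
    reference_gene: str
    fold_change: float
    ci_low: float
    ci_high: float
    p_value: float
    stars: str
    delta_delta_cq: float
    n_test: int
    n_calibrator: int


@dataclass(frozen=True)
class DigestionQCReport:
    """Per-library digestion QC outcome."""

    efficiencies: dict[str, float]
    threshold_percent: float
    passed: bool
    failing_sites: tuple[str, ...]


def relative_quantity(cq: float, efficiency: float = 1.0) -> float:
    """Template quantity in arbitrary units: ``(1 + E) ** (-cq)``.

    Monotone decreasing in Cq; at E = 1 each cycle halves the quantity.
    """
    if not math.isfinite(cq):
        raise InvalidInputError(f"cq must be finite, got {cq}")
    if not 0 < efficiency <= 1:
        raise InvalidInputError(f"efficiency must be in (0, 1], got {efficiency}")
    return float((1.0 + efficiency) ** (-cq))


def digestion_efficiency(
    cq_site_digested: float,
    cq_ctrl_digested: float,
    cq_site_undigested: float,
    cq_ctrl_undigested: float,
) -> float:
    """Percent of templates cut at a restriction site.

    The site assay spans the cut site (signal lost on digestion); the
    control assay does not.  The ratio-of-ratios on the Cq scale,

        ddCq = (Cq_site,dig - Cq_ctrl,dig) - (Cq_site,undig - Cq_ctrl,undig),

    measures the fraction of molecules surviving digestion, giving
    ``percent = 100 - 100 / 2**ddCq``.  Values are <= 100 by construction;
    negative values can occur with noisy plates and are a QC anomaly.
    """
    for name, v in (
        ("cq_site_digested", cq_site_digested),
        ("cq_ctrl_digested", cq_ctrl_digested),
        ("cq_site_undigested", cq_site_undigested),
        ("cq_ctrl_undigested", cq_ctrl_undigested),
    ):
        if not math.isfinite(v):
            raise InvalidInputError(f"{name} must be finite, got {v}")
    ddcq = (cq_site_digested - cq_ctrl_digested) - (
        cq_site_undigested - cq_ctrl_undigested
    )
    return 100.0 - 100.0 / 2.0**ddcq


def qc_digestion(
    efficiencies: Mapping[str, float],
    threshold_percent: float = 85.0,
) -> DigestionQCReport:
    """Library-level digestion QC: every site must exceed the threshold."""
    if not efficiencies:
        raise InvalidInputError("no site efficiencies provided")
    failing = tuple(
        site for site, eff in efficiencies.items() if not eff > threshold_percent
    )
    return DigestionQCReport(
        efficiencies=dict(efficiencies),
        threshold_percent=threshold_percent,
        passed=not failing,
        failing_sites=failing,
    )


def significance_stars(
    p_value: float,
    thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS,
) -> str:
    """Map a p-value to a star string: one star per threshold it beats.

    With the default three-tier scheme (0.05, 0.01, 0.001): ``***`` below
    0.001, ``**`` below 0.01, ``*`` below 0.05, else ``ns``.
    """
    if not 0 <= p_value <= 1:
        raise InvalidInputError(f"p_value must be in [0, 1], got {p_value}")
    n = sum(p_value < t for t in sorted(thresholds, reverse=True))
    return "*" * n if n else "ns"


def _to_frame(records: Iterable[CqRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "efficiency" not in df.columns:
            df["efficiency"] = 1.0
        df["efficiency"] = df["efficiency"].fillna(1.0)
        return df
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "assay": r.assay,
                "replicate": r.replicate,
                "cq": r.cq,
                "efficiency": r.efficiency,
            }
            for r in records
        ]
    )


def _sample_cqs(df: pd.DataFrame, sample: str, assay: str) -> np.ndarray:
    sub = df[(df["sample"] == sample) & (df["assay"] == assay)]
    if sub.empty:
        raise InvalidInputError(f"no wells for sample {sample!r}, assay {assay!r}")
    if len(sub) < 2:
        raise InsufficientReplicatesError(
            f"sample {sample!r}, assay {assay!r}: {len(sub)} replicate(s), need >= 2"
        )
    return sub.sort_values("replicate")["cq"].to_numpy(dtype=float)


def delta_delta_ct(
    records: Iterable[CqRecord] | pd.DataFrame,
    target_assay: str,
    reference_assay: str,
    test_sample: str,
    calibrator_sample: str,
    *,
    star_thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS,
    confidence: float = 0.95,
) -> ExpressionResult:
    """Relative expression of ``test_sample`` vs ``calibrator_sample``.

    Per sample, dCq = mean Cq_target - mean Cq_reference; the fold change is
    ``2 ** -(dCq_test - dCq_cal)`` at perfect efficiency, and the
    efficiency-corrected ratio ``(1+E_t)**dCq_t / (1+E_r)**dCq_r`` (with
    dCq = calibrator - test per assay) otherwise — the two coincide at
    E = 1.  Inference is on per-replicate dCq values: Welch's two-sided
    t-test between samples, and a t-interval on the ddCq difference
    back-transformed to the fold scale.
    """
    df = _to_frame(records)
    cq_t_test = _sample_cqs(df, test_sample, target_assay)
    cq_r_test = _sample_cqs(df, test_sample, reference_assay)
    cq_t_cal = _sample_cqs(df, calibrator_sample, target_assay)
    cq_r_cal = _sample_cqs(df, calibrator_sample, reference_assay)

    eff_t = float(df[df["assay"] == target_assay]["efficiency"].mean())
    eff_r = float(df[df["assay"] == reference_assay]["efficiency"].mean())
    log2_amp_t = math.log2(1.0 + eff_t)
    log2_amp_r = math.log2(1.0 + eff_r)

    # Per-replicate log2 expression (target relative to reference).  With
    # E = 1 this is just -dCq; in general the amplification factors scale
    # the two assays' Cq axes differently.
    def _log2_expr(cq_t: np.ndarray, cq_r: np.ndarray) -> np.ndarray:
        k = min(len(cq_t), len(cq_r))
        return -cq_t[:k] * log2_amp_t + cq_r[:k] * log2_amp_r

    expr_test = _log2_expr(cq_t_test, cq_r_test)
    expr_cal = _log2_expr(cq_t_cal, cq_r_cal)

    log2_fold = float(expr_test.mean() - expr_cal.mean())
    fold = 2.0**log2_fold
    # ddCq on the conventional scale (meaningful when both assays share E)
    ddcq = float(
        (cq_t_test.mean() - cq_r_test.mean()) - (cq_t_cal.mean() - cq_r_cal.mean())
    )

    t_res = stats.ttest_ind(expr_test, expr_cal, equal_var=False)
    p_value = float(t_res.pvalue)

    se = math.sqrt(
        expr_test.var(ddof=1) / len(expr_test) + expr_cal.var(ddof=1) / len(expr_cal)
    )
    if se > 0:
        dof = float(t_res.df)
        t_crit = float(stats.t.ppf(0.5 + confidence / 2.0, dof))
        ci_low = 2.0 ** (log2_fold - t_crit * se)
        ci_high = 2.0 ** (log2_fold + t_crit * se)
    else:
        ci_low = ci_high = fold
        p_value = 1.0 if log2_fold == 0 else 0.0

    return ExpressionResult(
        sample=test_sample,
        reference_gene=reference_assay,
        fold_change=fold,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        stars=significance_stars(p_value, star_thresholds),
        delta_delta_cq=ddcq,
        n_test=len(expr_test),
        n_calibrator=len(expr_cal),
    )


def expression_results(
    records: pd.DataFrame,
    target_assay: str,
    reference_assays: Sequence[str],
    test_samples: Sequence[str],
    calibrator_sample: str,
    *,
    star_thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS,
    combine_references: bool = False,
) -> list[ExpressionResult]:
    """ddCt for every (test sample, reference gene) combination.

    Reference genes are analyzed separately by default, one result per
    gene, mirroring how dual-normalized panels are usually reported.  With
    ``combine_references=True`` a single result per sample is produced
    against the geometric mean of the reference genes (arithmetic mean of
    their Cq values per replicate).
    """
    df = _to_frame(records)
    if combine_references:
        refs = df[df["assay"].isin(list(reference_assays))]
        combined = (
            refs.groupby(["sample", "replicate"], as_index=False)["cq"]
            .mean()
            .assign(assay="+".join(reference_assays), efficiency=1.0)
        )
        df = pd.concat([df[df["assay"] == target_assay], combined], ignore_index=True)
        reference_assays = ["+".join(reference_assays)]
    results = []
    for sample in test_samples:
        for ref in reference_assays:
            results.append(
                delta_delta_ct(
                    df,
                    target_assay,
                    ref,
                    sample,
                    calibrator_sample,
                    star_thresholds=star_thresholds,
                )
            )
    return results


def expression_results_table(results: Sequence[ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample for r in results],
            "reference_gene": [r.reference_gene for r in results],
            "fold_change": [r.fold_change for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
            "stars": [r.stars for r in results],
            "delta_delta_cq": [r.delta_delta_cq for r in results],
        }
    )
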