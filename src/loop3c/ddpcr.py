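"""Droplet digital PCR: Poisson concentrations and normalized ratios.

A ddPCR reaction is partitioned into ~0.85-nl droplets; after endpoint
PCR each droplet reads positive or negative.  With target molecules
distributed Poisson across droplets, the mean copies per droplet is

    lambda = -ln(1 - p),        p = positives / total,

and the concentration is lambda divided by the droplet volume.  The
standard error of lambda follows from the binomial variance of p by the
delta method: ``SE = sqrt(p / ((1 - p) * total))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateReferenceError,
    InvalidInputError,
    SaturationError,
)

DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Below this many positive or negative droplets the Poisson estimate is
#: unreliable and the well is flagged.
LOW_COUNT_FLAG = 10


@dataclass(frozen=True)
class DropletWell:
    sample: str
    assay: str
    positives: int
    total: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise InvalidInputError(f"total droplets must be > 0, got {self.total}")
        if self.positives < 0 or self.positives > self.total:
            raise InvalidInputError(
                f"positives must be in [0, total], got {self.positives}/{self.total}"
            )
        if self.droplet_volume_nl <= 0:
            raise InvalidInputError("droplet volume must be positive")


@dataclass(frozen=True)
class DdpcrResult:
    sample: str
    assay: str
    lam: float
    conc_copies_per_ul: float
    ci_low: float
    ci_high: float
    se_conc: float
    flagged_low_counts: bool


def poisson_concentration(
    well: DropletWell, *, ci_method: str = "normal", confidence: float = 0.95
) -> DdpcrResult:
    """Poisson-corrected concentration for one well.

    ``ci_method='normal'`` uses the delta-method normal interval on lambda;
    ``'clopper-pearson'`` transforms an exact binomial interval on p, which
    behaves better at very low counts.  Saturated wells (all droplets
    positive) are rejected: lambda is unbounded there.
    """
    if well.positives == well.total:
        raise SaturationError(
            f"all {well.total} droplets positive: concentration unbounded"
        )
    p = well.positives / well.total
    lam = -math.log1p(-p)
    vol_ul = well.droplet_volume_nl * 1e-3
    conc = lam / vol_ul
    se_lam = math.sqrt(p / ((1.0 - p) * well.total))

    if ci_method == "normal":
        z = float(stats.norm.ppf(0.5 + confidence / 2.0))
        lam_lo = max(lam - z * se_lam, 0.0)
        lam_hi = lam + z * se_lam
    elif ci_method == "clopper-pearson":
        alpha = 1.0 - confidence
        if well.positives == 0:
            p_lo = 0.0
        else:
            p_lo = float(stats.beta.ppf(alpha / 2, well.positives, well.total - well.positives + 1))
        p_hi = float(stats.beta.ppf(1 - alpha / 2, well.positives + 1, well.total - well.positives))
        lam_lo = -math.log1p(-p_lo)
        lam_hi = -math.log1p(-min(p_hi, 1.0 - 1e-12))
    else:
        raise InvalidInputError(f"unknown ci_method {ci_method!r}")

    flagged = well.positives < LOW_COUNT_FLAG or (well.total - well.positives) < LOW_COUNT_FLAG
    return DdpcrResult(
        sample=well.sample,
        assay=well.assay,
        lam=lam,
        conc_copies_per_ul=conc,
        ci_low=lam_lo / vol_ul,
        ci_high=lam_hi / vol_ul,
        se_conc=se_lam / vol_ul,
        flagged_low_counts=flagged,
    )


def _mean_concentration(wells: Sequence[DropletWell]) -> tuple[float, float]:
    """Duplicate wells averaged on the concentration scale: (mean, SE of mean)."""
    results = [poisson_concentration(w) for w in wells]
    concs = np.array([r.conc_copies_per_ul for r in results])
    ses = np.array([r.se_conc for r in results])
    return float(concs.mean()), float(np.sqrt((ses**2).sum()) / len(ses))


@dataclass(frozen=True)
class NormalizedRatio:
    test_sample: str
    calibrator_sample: str
    fold: float
    ci_low: float
    ci_high: float


def normalized_ratio(
    wells: pd.DataFrame,
    target_assay: str,
    reference_assay: str,
    test_sample: str,
    calibrator_sample: str,
    *,
    confidence: float = 0.95,
) -> NormalizedRatio:
    """Reference-normalized expression ratio between two samples.

    ``fold = (target/reference)_test / (target/reference)_calibrator``,
    with duplicate wells averaged on the concentration scale and a
    confidence interval from first-order error propagation on the log
    scale (the four concentration estimates are independent).
    """
    required = {"sample", "assay", "positives", "total"}
    missing = required - set(wells.columns)
    if missing:
        raise InvalidInputError(f"ddPCR wells missing columns: {sorted(missing)}")

    def _wells(sample: str, assay: str) -> list[DropletWell]:
        sub = wells[(wells["sample"] == sample) & (wells["assay"] == assay)]
        if sub.empty:
            raise InvalidInputError(f"no wells for sample {sample!r}, assay {assay!r}")
        vol_col = (
            sub["droplet_volume_nl"]
            if "droplet_volume_nl" in sub.columns
            else pd.Series(DEFAULT_DROPLET_VOLUME_NL, index=sub.index)
        )
        return [
            DropletWell(
                sample=sample,
                assay=assay,
                positives=int(r.positives),
                total=int(r.total),
                droplet_volume_nl=float(v) if pd.notna(v) else DEFAULT_DROPLET_VOLUME_NL,
            )
            for (_, r), v in zip(sub.iterrows(), vol_col)
        ]

    parts = {}
    for sample in (test_sample, calibrator_sample):
        for assay in (target_assay, reference_assay):
            conc, se = _mean_concentration(_wells(sample, assay))
            if assay == reference_assay and conc <= 0:
                raise DegenerateReferenceError(
                    f"reference concentration is zero for sample {sample!r}"
                )
            parts[(sample, assay)] = (conc, se)

    t_test, r_test = parts[(test_sample, target_assay)], parts[(test_sample, reference_assay)]
    t_cal, r_cal = parts[(calibrator_sample, target_assay)], parts[(calibrator_sample, reference_assay)]
    fold = (t_test[0] / r_test[0]) / (t_cal[0] / r_cal[0])
    # relative variances add on the log scale
    var_log = sum(
        (se / conc) ** 2 for conc, se in (t_test, r_test, t_cal, r_cal) if conc > 0
    )
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    half = z * math.sqrt(var_log)
    return NormalizedRatio(
        test_sample=test_sample,
        calibrator_sample=calibrator_sample,
        fold=float(fold),
        ci_low=float(fold * math.exp(-half)),
        ci_high=float(fold * math.exp(half)),
    )


def ddpcr_results_table(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-well Poisson concentrations as a flat table."""
    rows = []
    for _, r in wells.iterrows():
        well = DropletWell(
            sample=str(r["sample"]),
            assay=str(r["assay"]),
            positives=int(r["positives"]),
            total=int(r["total"]),
            droplet_volume_nl=float(r.get("droplet_volume_nl", DEFAULT_DROPLET_VOLUME_NL)),
        )
        res = poisson_concentration(well)
        rows.append(
            {
                "sample": res.sample,
                "assay": res.assay,
                "lambda": res.lam,
                "conc_copies_per_ul": res.conc_copies_per_ul,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "flagged_low_counts": res.flagged_low_counts,
            }
        )
    return pd.DataFrame(rows)
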