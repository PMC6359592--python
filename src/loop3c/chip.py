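"""ChIP-qPCR enrichment: percent input and fold over IgG.

ChIP signal at a region is expressed as percent of the pre-IP input
chromatin.  Because only a fraction of chromatin is saved as input, the
input Cq is first adjusted down by ``log2(1 / input_fraction)`` (6.64
cycles for a 1% input), then

    percent = 100 * 2 ** (adjusted_input_Cq - IP_Cq).

Specific enrichment is the ratio of the antibody's percent input to the
matched IgG control's.  Experiments are combined as a geometric mean of
folds, with a Welch t-test on log2 percent input (antibody vs IgG) across
experiments — fold ratios are close to log-normal, so the log scale is
where replicate spread is symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateControlError, InvalidInputError
from .qpcr import DEFAULT_STAR_THRESHOLDS, significance_stars

ANTIBODY_LABELS = {"H3K27ac", "IgG", "input"}


@dataclass(frozen=True)
class ChipResult:
    region: str
    cell_line: str
    percent_input_ab: float
    percent_input_igg: float
    fold_over_igg: float
    p_value: float
    stars: str
    n_experiments: int


def percent_input(cq_ip: float, cq_input: float, input_fraction: float = 0.01) -> float:
    """ChIP recovery as percent of total input chromatin."""
    if not 0 < input_fraction <= 1:
        raise InvalidInputError(
            f"input_fraction must be in (0, 1], got {input_fraction}"
        )
    adjusted_input_cq = cq_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted_input_cq - cq_ip)


def fold_over_igg(
    percents_ab: Sequence[float],
    percents_igg: Sequence[float],
    *,
    star_thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS,
) -> tuple[float, float, str]:
    """Specific enrichment over the IgG background across experiments.

    Returns (fold, p_value, stars).  Fold is the geometric mean of
    per-experiment percent-input ratios; the p-value is a two-sided Welch
    t-test on log2 percent input, antibody vs IgG.
    """
    ab = np.asarray(list(percents_ab), dtype=float)
    igg = np.asarray(list(percents_igg), dtype=float)
    if ab.size == 0 or igg.size == 0:
        raise InvalidInputError("need at least one experiment per antibody")
    if (igg <= 0).any():
        raise DegenerateControlError("IgG percent input must be positive")
    if (ab <= 0).any():
        raise InvalidInputError("antibody percent input must be positive")
    log2_ab = np.log2(ab)
    log2_igg = np.log2(igg)
    fold = float(2.0 ** (log2_ab.mean() - log2_igg.mean()))
    if ab.size > 1 and igg.size > 1:
        p = float(stats.ttest_ind(log2_ab, log2_igg, equal_var=False).pvalue)
        if math.isnan(p):  # zero variance in both groups
            p = 1.0 if fold == 1.0 else 0.0
    else:
        p = float("nan")
    stars = significance_stars(p, star_thresholds) if math.isfinite(p) else "ns"
    return fold, p, stars


def chip_results(
    wells: pd.DataFrame,
    *,
    antibody: str = "H3K27ac",
    star_thresholds: Sequence[float] = DEFAULT_STAR_THRESHOLDS,
) -> list[ChipResult]:
    """Per (cell line, region) enrichment from a ChIP well table.

    ``wells`` columns: cell_line, region, antibody (one of the specific
    antibody, ``IgG``, ``input``), experiment, cq, input_fraction.  The
    input well is shared per (region, experiment) between the antibody and
    IgG pull-downs.
    """
    required = {"cell_line", "region", "antibody", "experiment", "cq", "input_fraction"}
    missing = required - set(wells.columns)
    if missing:
        raise InvalidInputError(f"ChIP wells missing columns: {sorted(missing)}")
    results = []
    for (cell_line, region), grp in wells.groupby(["cell_line", "region"], sort=True):
        pct_ab, pct_igg = [], []
        for exp, sub in grp.groupby("experiment"):
            inp = sub[sub["antibody"] == "input"]
            if inp.empty:
                raise InvalidInputError(
                    f"{cell_line}/{region} experiment {exp}: no input well"
                )
            cq_input = float(inp["cq"].mean())
            frac = float(inp["input_fraction"].iloc[0])
            for ab_label, bucket in ((antibody, pct_ab), ("IgG", pct_igg)):
                ip = sub[sub["antibody"] == ab_label]
                if ip.empty:
                    raise InvalidInputError(
                        f"{cell_line}/{region} experiment {exp}: no {ab_label} well"
                    )
                bucket.append(percent_input(float(ip["cq"].mean()), cq_input, frac))
        fold, p, stars = fold_over_igg(pct_ab, pct_igg, star_thresholds=star_thresholds)
        results.append(
            ChipResult(
                region=str(region),
                cell_line=str(cell_line),
                percent_input_ab=float(np.exp(np.mean(np.log(pct_ab)))),
                percent_input_igg=float(np.exp(np.mean(np.log(pct_igg)))),
                fold_over_igg=fold,
                p_value=p,
                stars=stars,
                n_experiments=len(pct_ab),
            )
        )
    return results


def chip_results_table(results: Sequence[ChipResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_line": [r.cell_line for r in results],
            "region": [r.region for r in results],
            "percent_input_ab": [r.percent_input_ab for r in results],
            "percent_input_igg": [r.percent_input_igg for r in results],
            "fold_over_igg": [r.fold_over_igg for r in results],
            "p_value": [r.p_value for r in results],
            "stars": [r.stars for r in results],
            "n_experiments": [r.n_experiments for r in results],
        }
    )
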