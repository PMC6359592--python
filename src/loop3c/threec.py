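"""Bait-anchored 3C-qPCR interaction profiles and loop calling.

The 3C readout for a fragment is the abundance of its ligation junction
with the bait (promoter) fragment, measured by TaqMan qPCR and expressed
relative to a control junction inside a conformationally invariant locus
(an ERCC3-style normalizer).  Contact frequency falls off with genomic
distance along the fiber; loops appear as fragments whose relative
frequency stands above that distance-decay background.

The pipeline is:

1. :func:`interaction_frequency` — Cq pairs to relative ligation frequency,
   ``rel = 2 ** (Cq_normalizer - Cq_junction)``;
2. :func:`build_profile` — one point per assayed fragment, ordered by
   signed TSS distance, bait excluded;
3. :func:`fit_background` — power-law decay ``rel = a * |d| ** -b`` fitted
   by least squares in log-log space, with iterative exclusion of loop
   candidates so that true loops do not inflate their own background;
4. :func:`fold_enrichments` / :func:`call_loops` — fold over the fitted
   background and over a promoter-proximal reference fragment; a fragment
   is a loop when both folds clear their thresholds (defaults 3x and 1.5x).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateProximalError,
    InsufficientDataError,
    InvalidInputError,
    InvalidStandardsError,
    MissingNormalizerError,
    UnmappedAssayError,
)
from .locus import LocusModel, locate_fragment

logger = logging.getLogger(__name__)

DEFAULT_NORMALIZER_ASSAY = "ERCC3_junction"
DEFAULT_PROXIMAL_WINDOW_KB = 4.0
DEFAULT_MIN_FOLD_BACKGROUND = 3.0
DEFAULT_MIN_FOLD_PROXIMAL = 1.5


@dataclass(frozen=True)
class InteractionPoint:
    """Relative ligation frequency of one fragment with the bait."""

    fragment_id: int
    tss_distance_kb: float
    rel_frequency: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.rel_frequency < 0 or self.sd < 0 or self.n < 1:
            raise InvalidInputError("rel_frequency and sd must be >= 0, n >= 1")


@dataclass
class InteractionProfile:
    """Bait-anchored profile for one 3C library, ordered by TSS distance."""

    points: list[InteractionPoint]
    bait_fragment_id: int
    normalizer_assay: str = DEFAULT_NORMALIZER_ASSAY
    library_id: str = ""

    def __post_init__(self) -> None:
        dists = [p.tss_distance_kb for p in self.points]
        if any(d2 <= d1 for d1, d2 in zip(dists, dists[1:])):
            raise InvalidInputError("profile points must be strictly ordered by distance")
        if any(p.fragment_id == self.bait_fragment_id for p in self.points):
            raise InvalidInputError("bait fragment must not appear among profile points")

    def point(self, fragment_id: int) -> InteractionPoint:
        for p in self.points:
            if p.fragment_id == fragment_id:
                return p
        raise InvalidInputError(f"no profile point for fragment {fragment_id}")


@dataclass
class BackgroundModel:
    """Power-law distance decay: ``rel = exp(log_a) * |d_kb| ** -b``.

    ``flat`` marks the degenerate fallback (no positive decay supported by
    the data): the background is then the constant ``exp(log_a)``.
    """

    log_a: float
    b: float
    excluded_fragments: tuple[int, ...] = ()
    fit_rmse: float = 0.0
    flat: bool = False

    def predict(self, distance_kb: float) -> float:
        if self.flat:
            return math.exp(self.log_a)
        d = abs(distance_kb)
        if d <= 0:
            raise InvalidInputError("background undefined at zero distance")
        return math.exp(self.log_a - self.b * math.log(d))


@dataclass(frozen=True)
class LoopCall:
    """Fold statistics for one fragment; ``is_peak`` set by the caller."""

    fragment_id: int
    tss_distance_kb: float
    fold_over_background: float
    fold_over_proximal: float
    proximal_fragment_id: int
    is_peak: bool = False


def interaction_frequency(
    cq_junction: Sequence[float],
    cq_normalizer: Sequence[float],
    *,
    fragment_id: int = -1,
    tss_distance_kb: float = 0.0,
    calibration: float = 1.0,
) -> InteractionPoint:
    """Relative ligation frequency from junction and normalizer Cq wells.

    Per junction replicate, ``rel = 2 ** (mean Cq_normalizer - Cq_junction)``
    times an optional per-assay calibration factor (random-ligation / BAC
    control; default 1).  The point carries the replicate mean, sd, and n.
    """
    junc = np.asarray(list(cq_junction), dtype=float)
    norm = np.asarray(list(cq_normalizer), dtype=float)
    if norm.size == 0:
        raise MissingNormalizerError("no normalizer wells provided")
    if junc.size == 0:
        raise InvalidInputError("no junction wells provided")
    if calibration <= 0:
        raise InvalidInputError(f"calibration must be > 0, got {calibration}")
    rel = calibration * 2.0 ** (norm.mean() - junc)
    sd = float(rel.std(ddof=1)) if rel.size > 1 else 0.0
    return InteractionPoint(
        fragment_id=fragment_id,
        tss_distance_kb=tss_distance_kb,
        rel_frequency=float(rel.mean()),
        sd=sd,
        n=int(rel.size),
    )


def resolve_anchor_map(
    anchor_map: pd.DataFrame, locus: LocusModel
) -> dict[str, int]:
    """Assay name -> fragment id, from a table with either a ``fragment_id``
    or a ``position`` column."""
    if "assay" not in anchor_map.columns:
        raise InvalidInputError("anchor map must have an 'assay' column")
    mapping: dict[str, int] = {}
    for _, row in anchor_map.iterrows():
        assay = str(row["assay"])
        if "fragment_id" in anchor_map.columns and not pd.isna(row.get("fragment_id")):
            mapping[assay] = int(row["fragment_id"])
        elif "position" in anchor_map.columns and not pd.isna(row.get("position")):
            mapping[assay] = locate_fragment(locus, int(row["position"]))
        else:
            raise InvalidInputError(
                f"anchor map row for assay {assay!r} has neither fragment_id nor position"
            )
    return mapping


def build_profile(
    plate: pd.DataFrame,
    locus: LocusModel,
    library_id: str,
    anchor_map: pd.DataFrame | Mapping[str, int],
    *,
    normalizer_assay: str = DEFAULT_NORMALIZER_ASSAY,
    calibrations: Mapping[str, float] | None = None,
) -> InteractionProfile:
    """One interaction point per anchored fragment, sorted by TSS distance.

    ``plate`` holds one library's junction and normalizer wells (columns
    sample, assay, replicate, cq).  Every junction assay must map to a
    fragment through the anchor map; the bait fragment itself is excluded
    from the profile.
    """
    if plate.empty:
        raise InvalidInputError("empty 3C plate")
    sub = plate[plate["sample"] == library_id]
    if sub.empty:
        raise InvalidInputError(f"no wells for library {library_id!r}")
    norm_cq = sub[sub["assay"] == normalizer_assay]["cq"].to_numpy(dtype=float)
    if norm_cq.size == 0:
        raise MissingNormalizerError(
            f"library {library_id!r}: no wells for normalizer assay {normalizer_assay!r}"
        )
    if isinstance(anchor_map, pd.DataFrame):
        mapping = resolve_anchor_map(anchor_map, locus)
    else:
        mapping = dict(anchor_map)
    calibrations = dict(calibrations or {})

    points = []
    for assay, wells in sub[sub["assay"] != normalizer_assay].groupby("assay"):
        if assay not in mapping:
            raise UnmappedAssayError(
                f"assay {assay!r} has no fragment mapping in the anchor map"
            )
        frag_id = mapping[assay]
        if frag_id == locus.bait_fragment_id:
            logger.info("assay %s maps to the bait fragment; excluded from profile", assay)
            continue
        frag = locus.fragment(frag_id)
        points.append(
            interaction_frequency(
                wells["cq"].to_numpy(dtype=float),
                norm_cq,
                fragment_id=frag_id,
                tss_distance_kb=float(frag.tss_distance_kb),
                calibration=calibrations.get(str(assay), 1.0),
            )
        )
    points.sort(key=lambda p: p.tss_distance_kb)
    return InteractionProfile(
        points=points,
        bait_fragment_id=locus.bait_fragment_id,
        normalizer_assay=normalizer_assay,
        library_id=library_id,
    )


def _point_log_sem(p: InteractionPoint) -> float:
    """Approximate natural-log standard error of a point's mean rel."""
    if p.rel_frequency <= 0 or p.sd <= 0:
        return 0.0
    return p.sd / (p.rel_frequency * math.sqrt(p.n))


def fit_background(
    profile: InteractionProfile,
    *,
    iterative: bool = True,
    max_rounds: int = 3,
    z_threshold: float = 2.0,
) -> BackgroundModel:
    """Least-squares power-law fit of the distance-decay background.

    Fits ``log rel = log_a - b log|d|`` over the profile.  When
    ``iterative`` (the default), candidate loops are excluded before the
    final fit: after each round, points whose residual exceeds
    ``z_threshold`` robust standard deviations *above* the fit are dropped
    and the model refitted (at most ``max_rounds`` rounds).  The residual
    scale is the MAD-based sd, floored at the replicate-noise level, so a
    couple of strong loops among a handful of anchors cannot mask
    themselves by inflating an ordinary residual variance.  Only positive
    outliers are excluded: loops are enrichments, and a low point is not a
    loop candidate.

    If the fitted decay exponent comes out non-positive, the model falls
    back to a flat background at the robust (median) level with a warning.
    """
    usable = [p for p in profile.points if p.rel_frequency > 0 and abs(p.tss_distance_kb) > 0]
    if len({round(abs(p.tss_distance_kb), 9) for p in usable}) < 4:
        raise InsufficientDataError(
            f"need >= 4 points with distinct |distance|, got {len(usable)}"
        )
    x = np.array([math.log(abs(p.tss_distance_kb)) for p in usable])
    y = np.array([math.log(p.rel_frequency) for p in usable])
    frag_ids = np.array([p.fragment_id for p in usable])
    sems = [s for s in (_point_log_sem(p) for p in usable) if s > 0]
    noise_floor = float(np.median(sems)) if sems else 0.0

    included = np.ones(len(usable), dtype=bool)
    slope = intercept = 0.0
    rounds = max_rounds if iterative else 1
    for _ in range(rounds):
        if included.sum() < 4:
            break
        slope, intercept = np.polyfit(x[included], y[included], 1)
        resid = y - (intercept + slope * x)
        r_in = resid[included]
        mad = float(np.median(np.abs(r_in - np.median(r_in))))
        sigma = max(1.4826 * mad, noise_floor, 1e-12)
        if not iterative:
            break
        newly = included & (resid > z_threshold * sigma)
        if not newly.any():
            break
        included &= ~newly

    slope, intercept = np.polyfit(x[included], y[included], 1)
    resid_in = y[included] - (intercept + slope * x[included])
    rmse = float(np.sqrt(np.mean(resid_in**2)))
    b = -float(slope)
    if b <= 0:
        logger.warning(
            "fitted decay exponent b = %.3g is not positive; "
            "falling back to a flat background at the median level",
            b,
        )
        return BackgroundModel(
            log_a=float(np.median(y[included])),
            b=0.0,
            excluded_fragments=tuple(int(i) for i in frag_ids[~included]),
            fit_rmse=rmse,
            flat=True,
        )
    return BackgroundModel(
        log_a=float(intercept),
        b=b,
        excluded_fragments=tuple(int(i) for i in frag_ids[~included]),
        fit_rmse=rmse,
    )


def fold_enrichments(
    profile: InteractionProfile,
    background: BackgroundModel,
    *,
    proximal_window_kb: float = DEFAULT_PROXIMAL_WINDOW_KB,
) -> list[LoopCall]:
    """Fold over background and over the promoter-proximal reference.

    The proximal reference is the fragment with the smallest |distance|
    within ``proximal_window_kb`` of the TSS; when no fragment falls inside
    the window, the nearest assayed fragment is used and a note is logged.
    """
    if not profile.points:
        raise InvalidInputError("empty profile")
    in_window = [p for p in profile.points if abs(p.tss_distance_kb) < proximal_window_kb]
    if in_window:
        proximal = min(in_window, key=lambda p: abs(p.tss_distance_kb))
    else:
        proximal = min(profile.points, key=lambda p: abs(p.tss_distance_kb))
        logger.info(
            "no fragment within %.1f kb of the TSS; using nearest fragment %d (%.1f kb) "
            "as the proximal reference",
            proximal_window_kb,
            proximal.fragment_id,
            proximal.tss_distance_kb,
        )
    if proximal.rel_frequency <= 0:
        raise DegenerateProximalError(
            f"proximal fragment {proximal.fragment_id} has zero relative frequency"
        )
    calls = []
    for p in profile.points:
        bg = background.predict(p.tss_distance_kb)
        calls.append(
            LoopCall(
                fragment_id=p.fragment_id,
                tss_distance_kb=p.tss_distance_kb,
                fold_over_background=p.rel_frequency / bg,
                fold_over_proximal=p.rel_frequency / proximal.rel_frequency,
                proximal_fragment_id=proximal.fragment_id,
                is_peak=False,
            )
        )
    return calls


def call_loops(
    enrichments: Sequence[LoopCall],
    *,
    min_fold_background: float = DEFAULT_MIN_FOLD_BACKGROUND,
    min_fold_proximal: float = DEFAULT_MIN_FOLD_PROXIMAL,
) -> list[LoopCall]:
    """Flag fragments whose folds clear both thresholds as loops."""
    if not enrichments:
        raise InvalidInputError("no enrichments to call")
    return [
        replace(
            c,
            is_peak=(
                c.fold_over_background >= min_fold_background
                and c.fold_over_proximal >= min_fold_proximal
            ),
        )
        for c in enrichments
    ]


@dataclass(frozen=True)
class ConcentrationEstimate:
    ng: float
    extrapolated: bool


def library_concentration(
    cq_library: float,
    standard_points: Sequence[tuple[float, float]],
) -> ConcentrationEstimate:
    """3C library concentration against a genomic-DNA standard curve.

    ``standard_points`` are (known ng, Cq) pairs; a line of Cq against
    log10(ng) is fitted and the unknown interpolated.  Estimates outside
    the standards' Cq range are flagged as extrapolated.
    """
    if len(standard_points) < 2:
        raise InvalidStandardsError("need >= 2 standard points")
    ngs = np.array([s[0] for s in standard_points], dtype=float)
    cqs = np.array([s[1] for s in standard_points], dtype=float)
    if (ngs <= 0).any():
        raise InvalidStandardsError("standard concentrations must be positive")
    if len(set(ngs)) < 2:
        raise InvalidStandardsError("standard concentrations are all equal")
    slope, intercept = np.polyfit(np.log10(ngs), cqs, 1)
    if slope == 0:
        raise InvalidStandardsError("degenerate standard curve (zero slope)")
    log_ng = (cq_library - intercept) / slope
    extrapolated = not (cqs.min() <= cq_library <= cqs.max())
    return ConcentrationEstimate(ng=float(10.0**log_ng), extrapolated=extrapolated)


def combine_profiles(profiles: Sequence[InteractionProfile]) -> InteractionProfile:
    """Average independent libraries on the log scale, per fragment.

    Each library is already normalized to its own control junction, so the
    geometric mean across libraries is the natural combination.  Only
    fragments present in every library are kept.
    """
    if not profiles:
        raise InvalidInputError("no profiles to combine")
    if len(profiles) == 1:
        return profiles[0]
    by_frag: dict[int, list[InteractionPoint]] = {}
    for prof in profiles:
        for p in prof.points:
            by_frag.setdefault(p.fragment_id, []).append(p)
    n_lib = len(profiles)
    points = []
    for frag_id, pts in by_frag.items():
        if len(pts) != n_lib:
            logger.info("fragment %d missing from some libraries; dropped", frag_id)
            continue
        logs = np.array([math.log(p.rel_frequency) for p in pts if p.rel_frequency > 0])
        if logs.size != n_lib:
            continue
        rel = float(np.exp(logs.mean()))
        sd = float(rel * logs.std(ddof=1)) if n_lib > 1 else 0.0
        points.append(
            InteractionPoint(
                fragment_id=frag_id,
                tss_distance_kb=pts[0].tss_distance_kb,
                rel_frequency=rel,
                sd=sd,
                n=sum(p.n for p in pts),
            )
        )
    points.sort(key=lambda p: p.tss_distance_kb)
    return InteractionProfile(
        points=points,
        bait_fragment_id=profiles[0].bait_fragment_id,
        normalizer_assay=profiles[0].normalizer_assay,
        library_id="+".join(p.library_id for p in profiles),
    )


def profile_table(profile: InteractionProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fragment_id": [p.fragment_id for p in profile.points],
            "tss_distance_kb": [p.tss_distance_kb for p in profile.points],
            "rel_frequency": [p.rel_frequency for p in profile.points],
            "sd": [p.sd for p in profile.points],
            "n": [p.n for p in profile.points],
        }
    )


def loop_calls_table(calls: Sequence[LoopCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fragment_id": [c.fragment_id for c in calls],
            "tss_distance_kb": [c.tss_distance_kb for c in calls],
            "fold_over_background": [c.fold_over_background for c in calls],
            "fold_over_proximal": [c.fold_over_proximal for c in calls],
            "proximal_fragment_id": [c.proximal_fragment_id for c in calls],
            "is_peak": [c.is_peak for c in calls],
        }
    )


def plot_profile(
    profile: InteractionProfile,
    background: BackgroundModel | None = None,
    calls: Sequence[LoopCall] | None = None,
    path: str | None = None,
):
    """Interaction-frequency profile figure (distance vs relative frequency)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    d = [p.tss_distance_kb for p in profile.points]
    r = [p.rel_frequency for p in profile.points]
    e = [p.sd for p in profile.points]
    ax.errorbar(d, r, yerr=e, fmt="o-", color="black", capsize=3, label="3C signal")
    if background is not None:
        grid = np.linspace(min(d), max(d), 400)
        grid = grid[np.abs(grid) > 0.5]
        ax.plot(grid, [background.predict(g) for g in grid], "--", color="gray",
                label="distance-decay background")
    if calls:
        peaks = [c for c in calls if c.is_peak]
        if peaks:
            pd_ = [c.tss_distance_kb for c in peaks]
            pr = [profile.point(c.fragment_id).rel_frequency for c in peaks]
            ax.plot(pd_, pr, "r^", markersize=10, label="loop call")
    ax.axvline(0, color="red", lw=0.8)
    ax.set_xlabel("position relative to TSS (kb)")
    ax.set_ylabel("interaction frequency (rel. to control junction)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
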