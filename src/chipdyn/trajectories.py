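"""Clone-trajectory modeling: weighted log-linear fits of VAF over age.

Each driver mutation's longitudinal series is modeled as

    log10(VAF) = C + β · age

by weighted least squares, each observation weighted by the square root of its
read depth, with zero VAFs floored at 1e-4 (a conservative detection limit).
Fits are classified by the sign of β and the two-sided p-value of β = 0:
growing (β > 0, P < 0.5), shrinking (β ≤ 0, P < 0.5), static (P ≥ 0.5).
Under the exponential model a growing clone's VAF doubles every log10(2)/β
years.

Eligibility mirrors the upstream study design: subjects sequenced at ≥3
timepoints with at least one driver above 1% VAF somewhere; observations with
alternate count < 2 or depth < 200 excluded (an undetected driver at a
well-covered timepoint contributes VAF 0); clones starting above 10% VAF
excluded from trajectory analysis, where exponential growth may not hold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TrajectoryObservation",
    "Trajectory",
    "TrajectoryFit",
    "DominantClone",
    "assemble_trajectories",
    "fit_trajectory",
    "classify_trajectory",
    "classify_two_timepoint",
    "doubling_period",
    "exclude_high_start",
    "select_dominant",
    "competition_report",
    "compare_gene_groups",
    "gene_growth_odds",
    "trajectory_table",
]

logger = logging.getLogger(__name__)

MAJOR_CHIP_GENES = frozenset({"DNMT3A", "TET2", "ASXL1"})


@dataclass(frozen=True)
class TrajectoryObservation:
    age: float
    vaf: float
    depth: int
    alt_count: int


@dataclass
class Trajectory:
    """One driver mutation's retained longitudinal observations."""

    subject_id: str
    gene: str
    variant_id: str
    protein_change: str = ""
    observations: list[TrajectoryObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ages = [o.age for o in self.observations]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("observation ages must be strictly increasing")

    @property
    def ages(self) -> np.ndarray:
        return np.array([o.age for o in self.observations])

    @property
    def vafs(self) -> np.ndarray:
        return np.array([o.vaf for o in self.observations])

    @property
    def depths(self) -> np.ndarray:
        return np.array([o.depth for o in self.observations])

    @property
    def starting_vaf(self) -> float:
        """VAF of the first retained observation (zeros count as 0)."""
        return self.observations[0].vaf

    @property
    def peak_vaf(self) -> float:
        return float(self.vafs.max())

    def nonzero(self) -> list[TrajectoryObservation]:
        return [o for o in self.observations if o.vaf > 0]


@dataclass
class TrajectoryFit:
    C: float  # intercept: log10 VAF at age 0
    beta: float  # per-year slope of log10 VAF
    p_value: float  # two-sided test of beta = 0 (NaN when 0 residual df)
    n_obs: int
    label: str | None = None  # growing / shrinking / static / None

    @property
    def doubling_period(self) -> float | None:
        return doubling_period(self.beta) if self.beta > 0 else None


@dataclass
class DominantClone:
    subject_id: str
    trajectory: Trajectory
    fit: TrajectoryFit | None
    delta_log10_vaf: float  # log10(last non-zero VAF) − log10(first non-zero VAF)


def assemble_trajectories(
    drivers: pd.DataFrame,
    manifest: pd.DataFrame,
    min_timepoints: int = 3,
    min_tracking_vaf: float = 0.01,
    min_depth: int = 200,
    min_alt: int = 2,
) -> list[Trajectory]:
    """Build eligible longitudinal series from a driver table and manifest.

    ``drivers`` needs one row per (subject_id, timepoint, variant_id) with
    gene, depth, alt_count (protein_change optional) covering every assayed
    timepoint of each driver site; ``manifest`` supplies subject ages.
    Retention per observation: depth ≥ ``min_depth`` and alt_count ≥
    ``min_alt`` keeps the measured VAF; depth ≥ ``min_depth`` with fewer
    alternate reads records VAF 0 (absence at adequate depth is informative);
    lower depth drops the timepoint as unassayed.  Subjects need
    ≥ ``min_timepoints`` sequenced visits and at least one driver observation
    above ``min_tracking_vaf``.
    """
    ages = manifest.set_index(["subject_id", "timepoint"])["age"]
    n_tp = manifest.groupby("subject_id")["timepoint"].nunique()

    trajectories: list[Trajectory] = []
    for (sid, vid), grp in drivers.groupby(["subject_id", "variant_id"], sort=True):
        if n_tp.get(sid, 0) < min_timepoints:
            continue
        obs: list[TrajectoryObservation] = []
        for row in grp.itertuples():
            try:
                age = float(ages.loc[(sid, row.timepoint)])
            except KeyError:
                logger.warning(
                    "subject %s timepoint %s missing from manifest; observation dropped",
                    sid, row.timepoint,
                )
                continue
            depth, alt = int(row.depth), int(row.alt_count)
            if depth < min_depth:
                continue
            vaf = alt / depth if alt >= min_alt else 0.0
            alt_kept = alt if alt >= min_alt else 0
            obs.append(TrajectoryObservation(age=age, vaf=vaf, depth=depth,
                                             alt_count=alt_kept))
        if not obs:
            continue
        obs.sort(key=lambda o: o.age)
        trajectories.append(
            Trajectory(
                subject_id=sid,
                gene=str(grp["gene"].iloc[0]),
                variant_id=vid,
                protein_change=str(grp["protein_change"].iloc[0])
                if "protein_change" in grp else "",
                observations=obs,
            )
        )

    # subject-level tracking rule: at least one driver above the tracking VAF
    tracked = {
        t.subject_id
        for t in trajectories
        if (t.vafs > min_tracking_vaf).any()
    }
    return [t for t in trajectories if t.subject_id in tracked]


def fit_trajectory(traj: Trajectory, vaf_floor: float = 1e-4) -> TrajectoryFit:
    """Weighted least-squares fit of log10(VAF) on age.

    Zero VAFs are floored at ``vaf_floor``; weights are sqrt(read depth).
    The p-value is the two-sided t-test of β = 0 on n−2 degrees of freedom;
    an exactly collinear (zero-residual) fit reports P = 0, and a
    two-observation fit has no residual degrees of freedom, so P is NaN.
    """
    obs = traj.observations
    if len(obs) < 2:
        raise ValueError("need at least 2 observations to fit a trajectory")
    ages = traj.ages
    if len(np.unique(ages)) < 2:
        raise ValueError("need at least 2 distinct ages")
    if vaf_floor <= 0:
        raise ValueError("vaf_floor must be positive")

    y = np.log10(np.maximum(traj.vafs, vaf_floor))
    w = np.sqrt(traj.depths.astype(float))
    X = sm.add_constant(ages)
    res = sm.WLS(y, X, weights=w).fit()
    C, beta = float(res.params[0]), float(res.params[1])

    n = len(obs)
    # perfect fit: weighted residual SS indistinguishable from 0
    wrss = float(np.sum(w * (y - res.fittedvalues) ** 2))
    scale = max(float(np.sum(w * y**2)), 1.0)
    if n == 2:
        p = float("nan")
    elif wrss <= 1e-20 * scale:
        p = 0.0
    else:
        p = float(res.pvalues[1])
    return TrajectoryFit(C=C, beta=beta, p_value=p, n_obs=n)


def classify_trajectory(fit: TrajectoryFit, p_threshold: float = 0.5) -> str | None:
    """Growing (β>0, P<thr), shrinking (β≤0, P<thr), or static (P≥thr).

    The default threshold 0.5 is the trajectory rule used throughout this
    pipeline (a deliberately permissive cut; see the methods note).  A fit
    without a defined P (2 observations) gets no label.
    """
    if math.isnan(fit.p_value):
        return None
    if fit.p_value >= p_threshold:
        return "static"
    return "growing" if fit.beta > 0 else "shrinking"


def classify_two_timepoint(delta_log10_vaf: float) -> str:
    """Growing vs non-growing call for subjects with only two timepoints."""
    return "growing" if delta_log10_vaf > 0 else "non-growing"


def doubling_period(beta: float) -> float:
    """Years per VAF doubling under exponential growth: log10(2)/β (β > 0)."""
    if beta <= 0:
        raise ValueError(f"doubling period is defined only for beta > 0 (got {beta})")
    return math.log10(2.0) / beta


def exclude_high_start(
    trajectories: Iterable[Trajectory], max_start_vaf: float = 0.10
) -> list[Trajectory]:
    """Drop clones whose first retained VAF exceeds ``max_start_vaf`` (strict >)."""
    return [t for t in trajectories if t.starting_vaf <= max_start_vaf]


def select_dominant(
    trajectories: Sequence[Trajectory],
    fits: Sequence[TrajectoryFit] | None = None,
) -> DominantClone | None:
    """The subject's predominant clone: highest VAF at any timepoint.

    Ties on peak VAF break toward the larger final VAF, then lexicographic
    variant id.  Returns None when no trajectory has ≥2 non-zero VAFs.
    """
    candidates = [
        (t, fits[i] if fits is not None else None)
        for i, t in enumerate(trajectories)
        if len(t.nonzero()) >= 2
    ]
    if not candidates:
        return None
    subject_ids = {t.subject_id for t, _ in candidates}
    if len(subject_ids) != 1:
        raise ValueError("select_dominant expects trajectories of a single subject")

    def rank(item):
        t, _ = item
        return (t.peak_vaf, t.vafs[-1], t.variant_id)

    traj, fit = max(candidates, key=rank)
    nz = traj.nonzero()
    delta = math.log10(nz[-1].vaf) - math.log10(nz[0].vaf)
    return DominantClone(
        subject_id=traj.subject_id, trajectory=traj, fit=fit, delta_log10_vaf=delta
    )


def competition_report(
    trajectories: Sequence[Trajectory],
    fits: Sequence[TrajectoryFit],
    chip_vaf: float = 0.02,
) -> pd.DataFrame:
    """Co-occurring labeled clones per subject, flagging likely competition.

    For subjects with ≥2 labeled trajectories, a non-growing clone that still
    reaches the CHIP threshold (peak VAF ≥ ``chip_vaf``) while a growing clone
    co-occurs in the same subject is flagged as a competition candidate —
    its stalling plausibly reflects displacement by the fitter clone.
    """
    if len(trajectories) != len(fits):
        raise ValueError("trajectories and fits must align")
    rows = []
    by_subject: dict[str, list[tuple[Trajectory, TrajectoryFit]]] = {}
    for t, f in zip(trajectories, fits):
        by_subject.setdefault(t.subject_id, []).append((t, f))
    for sid, items in sorted(by_subject.items()):
        labeled = [(t, f) for t, f in items if f.label is not None]
        if len(labeled) < 2:
            continue
        has_growing = any(f.label == "growing" for _, f in labeled)
        for t, f in labeled:
            rows.append(
                {
                    "subject_id": sid,
                    "variant_id": t.variant_id,
                    "gene": t.gene,
                    "label": f.label,
                    "peak_vaf": t.peak_vaf,
                    "competition_candidate": bool(
                        has_growing
                        and f.label in ("shrinking", "static")
                        and t.peak_vaf >= chip_vaf
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "variant_id", "gene", "label", "peak_vaf",
            "competition_candidate",
        ],
    )


def compare_gene_groups(
    fits_by_gene: pd.DataFrame,
    major_genes: frozenset[str] | set[str] = MAJOR_CHIP_GENES,
    value: str = "beta",
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """Mann-Whitney U between major-gene and other-gene growth rates.

    ``fits_by_gene`` needs columns gene and the chosen ``value`` ("beta" or
    "doubling_period").  Returns (U for the major-gene group, two-sided p).
    The exact null distribution is enumerated when the combined sample is
    ≤ ``exact_max_n`` without ties; otherwise the normal approximation with
    tie correction is used.
    """
    major = fits_by_gene[fits_by_gene["gene"].isin(major_genes)][value].to_numpy()
    other = fits_by_gene[~fits_by_gene["gene"].isin(major_genes)][value].to_numpy()
    if len(major) == 0 or len(other) == 0:
        raise ValueError("both gene groups must be non-empty")
    values = np.concatenate([major, other])
    no_ties = len(np.unique(values)) == len(values)
    method = "exact" if (len(values) <= exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(major, other, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def gene_growth_odds(
    labeled: pd.DataFrame,
    gene: str,
    growing_label: str = "growing",
    method: str = "fisher",
) -> tuple[float, float, bool]:
    """Odds ratio that clones of ``gene`` are on growing trajectories.

    Default ``method="fisher"``: 2×2 table (gene vs other) × (growing vs not),
    OR = ad/bc with the Haldane–Anscombe 0.5 correction applied to all cells
    when any is zero (flagged in the third return value), p from Fisher's
    exact test on the uncorrected table.  ``method="logistic"`` instead fits a
    logistic regression of growing on gene membership and returns the
    exponentiated coefficient with its Wald p.  ``labeled`` needs columns gene
    and label.
    """
    if labeled["gene"].nunique() < 2:
        raise ValueError("need trajectories from at least two genes")
    if method == "logistic":
        import statsmodels.api as _sm

        y = (labeled["label"] == growing_label).astype(float).to_numpy()
        X = _sm.add_constant((labeled["gene"] == gene).astype(float).to_numpy())
        res = _sm.Logit(y, X).fit(disp=0)
        return float(np.exp(res.params[1])), float(res.pvalues[1]), False
    if method != "fisher":
        raise ValueError(f"unknown method {method!r}")
    is_gene = labeled["gene"] == gene
    is_growing = labeled["label"] == growing_label
    a = int((is_gene & is_growing).sum())
    b = int((is_gene & ~is_growing).sum())
    c = int((~is_gene & is_growing).sum())
    d = int((~is_gene & ~is_growing).sum())
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a_, b_, c_, d_ = (x + 0.5 for x in (a, b, c, d))
    else:
        a_, b_, c_, d_ = a, b, c, d
    return float(a_ * d_ / (b_ * c_)), float(p), corrected


def trajectory_table(
    trajectories: Sequence[Trajectory],
    fits: Sequence[TrajectoryFit],
    dominant: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Flat per-mutation summary: subject, gene, variant, fit, label, doubling."""
    rows = []
    for t, f in zip(trajectories, fits):
        rows.append(
            {
                "subject_id": t.subject_id,
                "gene": t.gene,
                "variant_id": t.variant_id,
                "n_obs": f.n_obs,
                "C": f.C,
                "beta": f.beta,
                "p_value": f.p_value,
                "label": f.label,
                "doubling_period": f.doubling_period,
                "starting_vaf": t.starting_vaf,
                "peak_vaf": t.peak_vaf,
                "dominant": bool(
                    dominant is not None and dominant.get(t.subject_id) == t.variant_id
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "gene", "variant_id", "n_obs", "C", "beta",
                 "p_value", "label", "doubling_period", "starting_vaf",
                 "peak_vaf", "dominant"],
    )
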