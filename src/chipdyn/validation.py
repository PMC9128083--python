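"""Assay-validation mathematics: expected mixture VAFs, pooled error rate,
replicate reliability (ICC), and observed-vs-expected / cross-platform
concordance.

These quantities characterize a deep targeted sequencing assay from a defined
multi-cell-line gDNA mixture sequenced in replicate: how closely measured
allele fractions track the fractions implied by the mixing proportions, how
reproducible a variant's VAF is across replicates, and how often a base is
misread at positions with no true variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MixtureSpec

__all__ = [
    "expected_mixture_vaf",
    "estimate_error_rate",
    "ErrorRateEstimate",
    "icc",
    "IccResult",
    "concordance",
    "ConcordanceResult",
    "platform_comparison",
    "PlatformComparison",
]


def expected_mixture_vaf(
    mixture: MixtureSpec, variant: str | Mapping[str, int]
) -> float:
    """Expected VAF of a variant in a defined mixture: Σᵢ pᵢ·dᵢ/2.

    ``variant`` is either a variant id present in ``mixture.dosages`` or a
    mapping line id → genotype dosage (0/1/2).  The minimum nonzero value over
    dosage configurations is (smallest proportion)/2 — a single heterozygous
    copy in the rarest line — and the maximum, all lines homozygous, is 1.
    """
    mixture.validate()
    dosages = mixture.dosages[variant] if isinstance(variant, str) else variant
    total = 0.0
    for line, proportion in mixture.lines.items():
        d = dosages.get(line, 0)
        if d not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1 or 2 (got {d!r} for line {line})")
        total += proportion * d / 2.0
    return total


@dataclass
class ErrorRateEstimate:
    rate: float  # pooled non-reference fraction
    n_sites: int
    total_reads: int
    total_nonref: int
    per_site: pd.DataFrame  # site, depth, nonref_count, rate

    @property
    def one_in_n_bp(self) -> float:
        """The rate expressed as '1 in N bp'."""
        return np.inf if self.rate == 0 else 1.0 / self.rate


def estimate_error_rate(invariant_sites: pd.DataFrame) -> ErrorRateEstimate:
    """Pooled per-base error rate from counts at invariant sites.

    ``invariant_sites`` needs columns depth and nonref_count (an optional
    site column is carried through).  The estimate is total non-reference
    reads over total reads — pooled, not a mean of per-site rates, so it is
    invariant to how reads are partitioned across sites.
    """
    if invariant_sites.empty:
        raise ValueError("need at least one invariant site")
    depths = invariant_sites["depth"].to_numpy()
    nonref = invariant_sites["nonref_count"].to_numpy()
    total = int(depths.sum())
    if total <= 0:
        raise ValueError("total depth across invariant sites is zero")
    if (nonref > depths).any() or (nonref < 0).any():
        raise ValueError("nonref_count must lie in [0, depth]")
    per_site = invariant_sites.copy()
    per_site["rate"] = per_site["nonref_count"] / per_site["depth"]
    return ErrorRateEstimate(
        rate=float(nonref.sum() / total),
        n_sites=len(invariant_sites),
        total_reads=total,
        total_nonref=int(nonref.sum()),
        per_site=per_site,
    )


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_between: float
    ms_within: float
    n_sites: int
    k: float  # (mean) replicates per site


def icc(matrix: pd.DataFrame | np.ndarray, confidence: float = 0.95) -> IccResult:
    """One-way random-effects intraclass correlation, ICC(1).

    Rows are variant sites, columns replicate VAF measurements; NaNs are
    allowed and excluded per cell.  ICC(1) = (MS_B − MS_W) / (MS_B + (k−1)·MS_W)
    with k the mean replicate count per site; the confidence interval follows
    the F-distribution bounds on MS_B/MS_W.  Negative estimates are reported
    as computed.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a sites x replicates matrix with >=2 of each")
    counts = np.sum(~np.isnan(arr), axis=1)
    if (counts < 1).any():
        raise ValueError("every site needs at least one replicate measurement")
    n_total = int(counts.sum())
    a = arr.shape[0]
    site_means = np.nanmean(arr, axis=1)
    grand = float(np.nansum(arr) / n_total)
    ss_between = float(np.sum(counts * (site_means - grand) ** 2))
    ss_within = float(np.nansum((arr - site_means[:, None]) ** 2))
    df_between = a - 1
    df_within = n_total - a
    if df_within < 1:
        raise ValueError("need at least one within-site degree of freedom")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    k = float(np.mean(counts))
    denom = ms_between + (k - 1) * ms_within
    if denom == 0:
        raise ValueError("zero total variance: ICC undefined")
    est = (ms_between - ms_within) / denom

    if ms_within == 0:
        lo = hi = est
    else:
        alpha = 1.0 - confidence
        f_obs = ms_between / ms_within
        f_low = f_obs / stats.f.ppf(1 - alpha / 2, df_between, df_within)
        f_high = f_obs * stats.f.ppf(1 - alpha / 2, df_within, df_between)
        lo = (f_low - 1) / (f_low + k - 1)
        hi = (f_high - 1) / (f_high + k - 1)
    return IccResult(
        icc=float(est), ci_low=float(lo), ci_high=float(hi),
        ms_between=ms_between, ms_within=ms_within, n_sites=a, k=k,
    )


@dataclass
class ConcordanceResult:
    r_overall: float
    r_low: float  # expected VAF <= split
    r_high: float  # expected VAF > split
    split_at: float
    n: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def concordance(
    vaf_observed: Sequence[float],
    vaf_expected: Sequence[float],
    split_at: float = 0.02,
    log_scale: bool = False,
) -> ConcordanceResult:
    """Observed-vs-expected Pearson correlation, overall and stratified.

    Strata are defined on the *expected* VAF vector at ``split_at`` (≤ vs >).
    Correlations are computed on untransformed VAFs by default; ``log_scale``
    applies log10 to both vectors first.
    """
    x = np.asarray(vaf_observed, dtype=float)
    y = np.asarray(vaf_expected, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if log_scale:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log scale requires strictly positive VAFs")
        x, y = np.log10(x), np.log10(y)
        split = np.log10(split_at)
    else:
        split = split_at
    low = y <= split
    return ConcordanceResult(
        r_overall=_pearson(x, y),
        r_low=_pearson(x[low], y[low]),
        r_high=_pearson(x[~low], y[~low]),
        split_at=split_at,
        n=len(x),
    )


@dataclass
class PlatformComparison:
    sensitivity: float
    n_reference: int
    n_shared: int
    r_shared: float  # VAF correlation on variants >= threshold in both


def platform_comparison(
    panel: pd.DataFrame,
    reference: pd.DataFrame,
    vaf_threshold: float = 0.02,
) -> PlatformComparison:
    """Detection sensitivity and VAF concordance vs a reference call set.

    Both tables are keyed by (subject_id, variant_id) with a vaf column.
    Sensitivity = shared / reference count; the correlation uses variants with
    VAF ≥ ``vaf_threshold`` on both platforms.
    """
    if reference.empty:
        raise ValueError("reference call set is empty")
    key = ["subject_id", "variant_id"]
    merged = reference.merge(panel, on=key, suffixes=("_ref", "_panel"))
    n_ref = len(reference.drop_duplicates(key))
    n_shared = len(merged.drop_duplicates(key))
    both_big = merged[
        (merged["vaf_ref"] >= vaf_threshold) & (merged["vaf_panel"] >= vaf_threshold)
    ]
    r = _pearson(both_big["vaf_panel"].to_numpy(), both_big["vaf_ref"].to_numpy())
    return PlatformComparison(
        sensitivity=n_shared / n_ref, n_reference=n_ref, n_shared=n_shared, r_shared=r
    )
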