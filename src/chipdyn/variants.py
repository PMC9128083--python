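"""Raw reads → deduplicated counts → candidate somatic calls → filtered calls.

Implements the post-alignment half of a deep targeted somatic pipeline:

* UMI deduplication with majority-vote consensus per (probe, UMI) group;
* a stand-in somatic caller — a one-sided exact binomial test of the alternate
  count against the per-base error rate;
* the per-call depth / alternate-support / VAF thresholds and the cross-sample
  recurrent-artifact filter.

Thresholds default to the pipeline's canonical values (minimum coverage 40,
≥5 alternate reads, VAF ≥ 0.1%, artifact window 1–10% VAF in ≥5% of samples)
and are inclusive at the stated boundary.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .simulate import RawReadRecord

__all__ = [
    "SiteObservation",
    "CandidateCall",
    "DedupStats",
    "dedup_umis",
    "call_variants",
    "apply_call_filters",
    "filter_recurrent_artifacts",
]

logger = logging.getLogger(__name__)

UMI_LENGTH = 9


@dataclass
class SiteObservation:
    """Deduplicated read counts for one variant site in one sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
            )

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class CandidateCall:
    """A site observation with its caller p-value and filter flags."""

    obs: SiteObservation
    p_value: float
    is_candidate: bool
    low_coverage: bool = False
    low_alt_support: bool = False
    low_vaf: bool = False
    recurrent_artifact: bool = False

    @property
    def is_pass(self) -> bool:
        return not (
            self.low_coverage
            or self.low_alt_support
            or self.low_vaf
            or self.recurrent_artifact
        )

    @property
    def filter_string(self) -> str:
        flags = []
        if self.low_coverage:
            flags.append("LOW_COV")
        if self.low_alt_support:
            flags.append("LOW_ALT")
        if self.low_vaf:
            flags.append("LOW_VAF")
        if self.recurrent_artifact:
            flags.append("RECURRENT_ARTIFACT")
        return ";".join(flags) if flags else "PASS"


@dataclass
class DedupStats:
    n_reads: int = 0
    n_malformed: int = 0
    n_groups: int = 0
    n_tied_dropped: int = 0
    n_molecules: int = 0


def dedup_umis(
    reads: Iterable[RawReadRecord],
) -> tuple[list[SiteObservation], DedupStats]:
    """Collapse UMI-tagged reads into unique-molecule counts per site.

    Reads sharing (probe_id, UMI) are one source molecule; its allele is the
    majority vote over copies, and groups with an exact tie are dropped —
    conservative, deterministic, and order-independent.  Reads with a UMI that
    is not exactly 9 characters are rejected record-by-record and counted.
    """
    stats_ = DedupStats()
    # (probe, umi) -> allele counter; also remember the site each probe covers
    groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    sites: dict[tuple[str, str], tuple[str, int, str, str]] = {}
    for rec in reads:
        stats_.n_reads += 1
        if len(rec.umi) != UMI_LENGTH:
            stats_.n_malformed += 1
            continue
        key = (rec.probe_id, rec.umi)
        groups[key][rec.observed_allele] += 1
        sites[key] = (rec.chrom, rec.pos, rec.ref, rec.alt)
    if stats_.n_malformed:
        logger.warning("dedup_umis: rejected %d reads with malformed UMIs",
                       stats_.n_malformed)

    stats_.n_groups = len(groups)
    per_site: dict[tuple[str, int, str, str], list[int]] = defaultdict(lambda: [0, 0])
    for key, counter in groups.items():
        ranked = counter.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            stats_.n_tied_dropped += 1
            continue
        consensus = ranked[0][0]
        site = sites[key]
        per_site[site][0] += 1  # depth: one molecule
        if consensus == site[3]:  # alt allele
            per_site[site][1] += 1
        stats_.n_molecules += 1

    observations = [
        SiteObservation(chrom=c, pos=p, ref=r, alt=a, depth=d, alt_count=ac)
        for (c, p, r, a), (d, ac) in sorted(per_site.items())
    ]
    return observations, stats_


def call_variants(
    obs: SiteObservation, error_rate: float, alpha: float = 1e-6
) -> CandidateCall:
    """Stand-in somatic caller: one-sided exact binomial test vs. error rate.

    Tests whether ``alt_count`` exceeds what Binomial(depth, error_rate) would
    produce; the observation is a candidate variant iff p < ``alpha``.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError(f"error_rate must be in (0,1), got {error_rate}")
    if obs.depth <= 0:
        raise ValueError("depth must be positive")
    if obs.alt_count == 0:
        p = 1.0
    else:
        p = float(
            stats.binomtest(obs.alt_count, obs.depth, error_rate,
                            alternative="greater").pvalue
        )
    return CandidateCall(obs=obs, p_value=p, is_candidate=p < alpha)


def apply_call_filters(
    call: CandidateCall,
    min_depth: int = 40,
    min_alt: int = 5,
    min_vaf: float = 0.001,
) -> CandidateCall:
    """Set the three per-call threshold flags (inclusive at the boundary)."""
    call.low_coverage = call.obs.depth < min_depth
    call.low_alt_support = call.obs.alt_count < min_alt
    call.low_vaf = call.obs.vaf < min_vaf
    return call


def filter_recurrent_artifacts(
    calls: pd.DataFrame,
    sample_fraction: float = 0.05,
    vaf_window: tuple[float, float] = (0.01, 0.10),
    n_total_samples: int | None = None,
    group_col: str = "sample_id",
) -> pd.DataFrame:
    """Flag variants recurring at intermediate VAF across many samples.

    For each distinct variant, count samples where its VAF lies in the closed
    ``vaf_window``; if that count divided by the total number of samples is at
    least ``sample_fraction``, flag the variant as a recurrent artifact in
    *every* sample.  ``calls`` needs columns ``group_col``, ``variant_id``,
    ``vaf``; a ``recurrent_artifact`` bool column is added (a copy is
    returned).  ``group_col`` may be switched to ``subject_id`` to count
    subjects instead of samples.
    """
    if calls.empty:
        out = calls.copy()
        out["recurrent_artifact"] = pd.Series(dtype=bool)
        return out
    lo, hi = vaf_window
    total = n_total_samples if n_total_samples is not None else calls[group_col].nunique()
    if total < 1:
        raise ValueError("need at least one sample")
    in_window = calls[(calls["vaf"] >= lo) & (calls["vaf"] <= hi)]
    n_by_variant = in_window.groupby("variant_id")[group_col].nunique()
    flagged = set(n_by_variant[n_by_variant / total >= sample_fraction].index)
    if flagged:
        logger.info("recurrent-artifact filter: flagged %d variants", len(flagged))
    out = calls.copy()
    out["recurrent_artifact"] = out["variant_id"].isin(flagged)
    return out
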