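"""Synthetic longitudinal CHIP cohorts, read-count noise, UMI read records, and
defined cell-line mixtures.

The simulator emulates a deep targeted-sequencing study of clonal hematopoiesis
(CHIP): post-menopausal subjects sampled at a baseline visit plus up to five
follow-up visits spanning ~16 years, each carrying zero or more mutant
hematopoietic clones whose variant allele fraction (VAF) grows or shrinks
exponentially (linearly on the log10 scale).  Read counts at each variant site
are binomial draws at assay-scale depths with a small per-base substitution
error, and raw reads can be expanded into UMI-tagged duplicates for exercising
the deduplication stage.

All randomness flows from a single integer seed through
:class:`numpy.random.Generator`; identical configurations give bit-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthRateDistribution",
    "CohortSimConfig",
    "TrueClone",
    "MixtureSpec",
    "RawReadRecord",
    "CohortData",
    "simulate_cohort",
    "simulate_site_reads",
    "simulate_umi_reads",
    "simulate_mixture",
    "simulate_invariant_sites",
    "five_line_mixture",
    "random_mixture_dosages",
    "DEFAULT_GENE_FREQUENCIES",
    "FIVE_LINE_PROPORTIONS",
    "FIVE_LINE_IDS",
]


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


# Relative frequency of each panel gene among CHIP driver mutations,
# normalized from reported population proportions for the 15 panel genes.
DEFAULT_GENE_FREQUENCIES: dict[str, float] = {
    "DNMT3A": 45.97,
    "TET2": 19.13,
    "ASXL1": 7.41,
    "PPM1D": 4.01,
    "SF3B1": 2.46,
    "ZBTB33": 2.22,
    "TP53": 1.97,
    "SRSF2": 1.88,
    "ZNF318": 1.80,
    "JAK2": 1.65,
    "GNB1": 0.97,
    "CBL": 0.62,
    "IDH2": 0.30,
    "U2AF1": 0.23,
    "IDH1": 0.09,
}
_total = sum(DEFAULT_GENE_FREQUENCIES.values())
DEFAULT_GENE_FREQUENCIES = {g: v / _total for g, v in DEFAULT_GENE_FREQUENCIES.items()}

# Synthetic-but-plausible loci (GRCh37-scale coordinates) used to place
# simulated variants; one anchor per panel gene.
GENE_LOCI: dict[str, tuple[str, int]] = {
    "DNMT3A": ("2", 25_457_000),
    "TET2": ("4", 106_155_000),
    "ASXL1": ("20", 31_015_000),
    "PPM1D": ("17", 58_700_000),
    "SF3B1": ("2", 198_266_000),
    "ZBTB33": ("X", 119_384_000),
    "TP53": ("17", 7_574_000),
    "SRSF2": ("17", 74_732_000),
    "ZNF318": ("6", 43_319_000),
    "JAK2": ("9", 5_073_770),
    "GNB1": ("1", 1_737_000),
    "CBL": ("11", 119_148_000),
    "IDH2": ("15", 90_631_000),
    "U2AF1": ("21", 44_524_000),
    "IDH1": ("2", 209_113_000),
}

_HOTSPOT_CHANGES = {
    "JAK2": "V617F",
    "SRSF2": "P95H",
    "IDH1": "R132H",
    "IDH2": "R140Q",
}

_BASES = np.array(list("ACGT"))

# WHI-style visit schedule: baseline, annual visits 1/3/6/9, and a long-term
# follow-up visit ~15.4 y after enrollment.
_VISIT_LABELS = ("BL", "AV1", "AV3", "AV6", "AV9", "LLS")
_VISIT_OFFSETS = (0.0, 1.0, 3.0, 6.0, 9.0)  # LLS offset drawn per subject

_SMOKING_LEVELS = ("never", "former", "current")
_SMOKING_PROBS = (0.52, 0.41, 0.07)
_RACE_LEVELS = ("white", "black", "hispanic", "asian", "other")
_RACE_PROBS = (0.72, 0.14, 0.08, 0.04, 0.02)


@dataclass
class GrowthRateDistribution:
    """Mixture distribution for per-year log10-VAF slopes (β).

    A point mass at zero (truly static clones) plus a Gaussian component that
    produces both growing and shrinking clones.  The defaults are illustrative:
    no published estimate of the population of clone growth rates is assumed.
    """

    p_zero: float = 0.25
    mean: float = 0.02
    sd: float = 0.04

    def validate(self) -> None:
        if not 0.0 <= self.p_zero <= 1.0:
            raise ConfigurationError(f"p_zero must be in [0,1], got {self.p_zero}")
        if self.sd < 0:
            raise ConfigurationError(f"sd must be >= 0, got {self.sd}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        beta = rng.normal(self.mean, self.sd, size=size)
        beta[rng.random(size) < self.p_zero] = 0.0
        return beta


@dataclass
class CohortSimConfig:
    """All parameters of the longitudinal cohort simulator.

    ``depth_lognorm_median``/``depth_lognorm_sigma`` parameterize a lognormal
    read-depth distribution; the defaults reproduce the assay's scale (median
    ~2803, mean ~4480 reads per site).  ``error_rate`` is the total per-base
    substitution probability (0.045% by default), spread uniformly over the
    three non-reference bases.
    """

    n_subjects: int = 40
    timepoints_per_subject: int | Sequence[int] | None = None  # None: draw 1-6
    baseline_age_range: tuple[float, float] = (50.0, 78.0)
    clone_rate: float = 1.2  # expected clones per subject (Poisson)
    gene_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_FREQUENCIES)
    )
    growth_rate_distribution: GrowthRateDistribution = field(
        default_factory=GrowthRateDistribution
    )
    initial_vaf_range: tuple[float, float] = (0.002, 0.08)  # log-uniform
    depth_lognorm_median: float = 2803.0
    depth_lognorm_sigma: float = 0.97
    error_rate: float = 0.00045
    umi_duplication_rate: float = 2.0
    vaf_ceiling: float = 0.5  # heterozygous ceiling
    n_invariant_sites: int = 20  # error-only background sites per sample
    bmi_effect_log10_vaf: float = 0.0  # optional linear BMI effect on baseline log10 VAF
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        freq_sum = float(sum(self.gene_frequencies.values()))
        if abs(freq_sum - 1.0) > 1e-9:
            raise ConfigurationError(
                f"gene frequencies must sum to 1 (got {freq_sum!r})"
            )
        if any(p < 0 or p > 1 for p in self.gene_frequencies.values()):
            raise ConfigurationError("gene frequencies must be probabilities")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ConfigurationError("error_rate must be a probability")
        if self.clone_rate < 0:
            raise ConfigurationError("clone_rate must be >= 0")
        if self.umi_duplication_rate < 1:
            raise ConfigurationError("umi_duplication_rate must be >= 1")
        lo, hi = self.initial_vaf_range
        if not (0 < lo <= hi <= self.vaf_ceiling):
            raise ConfigurationError("initial_vaf_range must lie in (0, vaf_ceiling]")
        if self.depth_lognorm_median <= 0:
            raise ConfigurationError("depth_lognorm_median must be > 0")
        if isinstance(self.timepoints_per_subject, int):
            if not 1 <= self.timepoints_per_subject <= 6:
                raise ConfigurationError("timepoints_per_subject must be 1..6")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_frequencies"] = dict(self.gene_frequencies)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSimConfig":
        d = dict(d)
        if "growth_rate_distribution" in d and isinstance(
            d["growth_rate_distribution"], Mapping
        ):
            d["growth_rate_distribution"] = GrowthRateDistribution(
                **d["growth_rate_distribution"]
            )
        for key in ("baseline_age_range", "initial_vaf_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrueClone:
    """Ground-truth clone: exponential VAF trajectory on the log10 scale."""

    subject_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    beta_true: float  # per-year slope of log10(VAF)
    vaf_baseline: float
    age_baseline: float
    protein_change: str = ""
    functional_class: str = "missense"
    vaf_ceiling: float = 0.5

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def vaf_at(self, age: float) -> float:
        """Noiseless VAF at a given age: vaf_b * 10^(β (age − age_b)), capped."""
        v = self.vaf_baseline * 10.0 ** (self.beta_true * (age - self.age_baseline))
        return min(v, self.vaf_ceiling)


@dataclass
class MixtureSpec:
    """A defined mixture of cell lines with known genotype dosages.

    ``lines`` maps line id -> mixing proportion (must sum to 1);
    ``dosages`` maps variant id -> {line id: dosage in {0,1,2}}.
    """

    lines: dict[str, float]
    dosages: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        total = float(sum(self.lines.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"mixture proportions must sum to 1 (got {total!r})")
        if any(p < 0 for p in self.lines.values()):
            raise ConfigurationError("mixture proportions must be non-negative")
        for vid, per_line in self.dosages.items():
            for line, d in per_line.items():
                if line not in self.lines:
                    raise ConfigurationError(f"{vid}: unknown line {line!r}")
                if d not in (0, 1, 2):
                    raise ConfigurationError(f"{vid}: dosage must be 0, 1 or 2 (got {d})")


@dataclass(frozen=True)
class RawReadRecord:
    """One raw (pre-dedup) read at a variant site, tagged with its 9-mer UMI."""

    probe_id: str
    umi: str
    chrom: str
    pos: int
    ref: str
    alt: str
    observed_allele: str


# Mixing proportions of the five-cell-line positive-control gDNA mixture.
# The dominant line is the complement of the four spiked-in lines (78.75%,
# printed as 78.8% after rounding); proportions must sum to exactly 1.
FIVE_LINE_IDS = ("GM06994", "GM12878", "GM20847", "GM12877", "GM18507")
FIVE_LINE_PROPORTIONS = (0.7875, 0.16, 0.04, 0.01, 0.0025)


def five_line_mixture(dosages: Mapping[str, Mapping[str, int]] | None = None) -> MixtureSpec:
    """The five-line control mixture (78.8 / 16 / 4 / 1 / 0.25%)."""
    spec = MixtureSpec(
        lines=dict(zip(FIVE_LINE_IDS, FIVE_LINE_PROPORTIONS)),
        dosages={k: dict(v) for k, v in (dosages or {}).items()},
    )
    spec.validate()
    return spec


def random_mixture_dosages(
    n_variants: int, seed: int | np.random.Generator = 0
) -> dict[str, dict[str, int]]:
    """Random per-line genotype dosages for ``n_variants`` sites.

    Every site carries at least one non-reference dosage, and the two extreme
    configurations — heterozygous only in the rarest line (the assay's lowest
    expected VAF) and homozygous in every line (expected VAF 1) — are always
    included so the simulated panel spans the full dynamic range.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_variants < 2:
        raise ConfigurationError("need at least 2 variants to span the VAF range")
    dosages: dict[str, dict[str, int]] = {
        "var0001": {line: (1 if line == FIVE_LINE_IDS[-1] else 0) for line in FIVE_LINE_IDS},
        "var0002": {line: 2 for line in FIVE_LINE_IDS},
    }
    i = 3
    while len(dosages) < n_variants:
        d = rng.integers(0, 3, size=len(FIVE_LINE_IDS))
        if d.sum() == 0:
            continue
        dosages[f"var{i:04d}"] = dict(zip(FIVE_LINE_IDS, (int(x) for x in d)))
        i += 1
    return dosages


def _effective_alt_probability(true_vaf: float, error_rate: float) -> float:
    """P(read reports the specific alternate base).

    True alternate molecules are misread away with probability ``error_rate``;
    reference molecules are misread *to* this alternate with probability
    ``error_rate``/3 (errors uniform over the three non-reference bases).
    """
    return true_vaf * (1.0 - error_rate) + (1.0 - true_vaf) * error_rate / 3.0


def simulate_site_reads(
    true_vaf: float,
    depth: int,
    error_rate: float,
    seed: int | np.random.Generator = 0,
) -> tuple[int, int]:
    """Draw an alternate-read count at one site: Binomial(depth, p_eff)."""
    if not 0.0 <= true_vaf <= 1.0:
        raise ConfigurationError(f"true_vaf must be in [0,1], got {true_vaf}")
    if depth <= 0:
        raise ConfigurationError(f"depth must be positive, got {depth}")
    if not 0.0 <= error_rate <= 1.0:
        raise ConfigurationError(f"error_rate must be a probability, got {error_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = _effective_alt_probability(true_vaf, error_rate)
    alt = int(rng.binomial(depth, p))
    return alt, int(depth)


def simulate_invariant_sites(
    n_sites: int,
    depth: int | Sequence[int],
    error_rate: float,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Total non-reference read counts at sites with no true variant.

    Unlike :func:`simulate_site_reads`, which counts one specific alternate
    base (rate ``error_rate``/3 at an invariant site), this draws the *total*
    non-reference count at rate ``error_rate`` — the quantity pooled by the
    error-rate estimator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depths = np.broadcast_to(np.asarray(depth, dtype=int), (n_sites,)).copy()
    if (depths <= 0).any():
        raise ConfigurationError("depths must be positive")
    nonref = rng.binomial(depths, error_rate)
    return pd.DataFrame(
        {"site": [f"inv{i:05d}" for i in range(n_sites)], "depth": depths, "nonref_count": nonref}
    )


@dataclass
class CohortData:
    """Everything :func:`simulate_cohort` produces."""

    truth: list[TrueClone]
    manifest: pd.DataFrame  # one row per (subject, timepoint)
    observations: dict[tuple[str, str], pd.DataFrame]  # (subject, timepoint) -> table
    annotations: pd.DataFrame  # variant_id -> gene / functional class / pop AF


def _draw_visits(rng: np.random.Generator, n_timepoints: int) -> tuple[list[str], list[float]]:
    """Pick visit labels/offsets: baseline always, then later visits in order."""
    lls_offset = float(rng.uniform(14.0, 19.0))
    labels = list(_VISIT_LABELS)
    offsets = list(_VISIT_OFFSETS) + [lls_offset]
    if n_timepoints >= 6:
        return labels, offsets
    # keep baseline, sample the rest preserving chronological order
    extra = np.sort(rng.choice(np.arange(1, 6), size=n_timepoints - 1, replace=False))
    idx = [0] + [int(i) for i in extra]
    return [labels[i] for i in idx], [offsets[i] for i in idx]


def _novel_position(rng: np.random.Generator, gene: str, used: set) -> tuple[str, int, str, str]:
    chrom, start = GENE_LOCI[gene]
    while True:
        pos = int(start + rng.integers(0, 5000))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        key = (chrom, pos, str(ref), str(alt))
        if key not in used:
            used.add(key)
            return chrom, pos, str(ref), str(alt)


def simulate_cohort(config: CohortSimConfig) -> CohortData:
    """Simulate a full longitudinal cohort under ``config``.

    Returns ground-truth clones, a sample manifest (ages + covariates), one
    observation table per (subject, timepoint) containing clone sites (binomial
    alt counts at the clone's age-specific VAF) plus error-only invariant
    background sites, and a functional-annotation table for the clone variants.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = list(config.gene_frequencies.keys())
    gene_p = np.array([config.gene_frequencies[g] for g in genes], dtype=float)
    gene_p = gene_p / gene_p.sum()

    truth: list[TrueClone] = []
    manifest_rows: list[dict] = []
    observations: dict[tuple[str, str], pd.DataFrame] = {}
    used_positions: set = set()
    ann_rows: list[dict] = []

    lo, hi = config.initial_vaf_range
    log_lo, log_hi = np.log10(lo), np.log10(hi)

    for i in range(config.n_subjects):
        sid = f"S{i + 1:04d}"
        if config.timepoints_per_subject is None:
            n_tp = int(rng.integers(1, 7))
        elif isinstance(config.timepoints_per_subject, int):
            n_tp = config.timepoints_per_subject
        else:
            n_tp = int(config.timepoints_per_subject[i])
            if not 1 <= n_tp <= 6:
                raise ConfigurationError(f"timepoints for subject {i} must be 1..6")
        labels, offsets = _draw_visits(rng, n_tp)
        age0 = float(rng.uniform(*config.baseline_age_range))
        enroll_year = int(rng.integers(1993, 1999))
        bmi = float(np.clip(rng.normal(28.0, 5.0), 17.0, 50.0))
        smoking = str(rng.choice(_SMOKING_LEVELS, p=_SMOKING_PROBS))
        race = str(rng.choice(_RACE_LEVELS, p=_RACE_PROBS))

        n_clones = int(rng.poisson(config.clone_rate))
        betas = config.growth_rate_distribution.sample(rng, n_clones)
        subject_clones: list[TrueClone] = []
        for c in range(n_clones):
            gene = str(rng.choice(genes, p=gene_p))
            chrom, pos, ref, alt = _novel_position(rng, gene, used_positions)
            log_v0 = rng.uniform(log_lo, log_hi)
            log_v0 += config.bmi_effect_log10_vaf * (bmi - 28.0)
            v0 = float(np.clip(10.0 ** log_v0, 1e-6, config.vaf_ceiling))
            if gene in _HOTSPOT_CHANGES:
                change, fclass = _HOTSPOT_CHANGES[gene], "missense"
            elif gene in ("ZBTB33", "ZNF318") or rng.random() < 0.6:
                aa = int(rng.integers(1, 900))
                change, fclass = f"M{aa}V", "missense"
            else:
                aa = int(rng.integers(1, 900))
                change, fclass = f"Q{aa}*", "nonsense"
            clone = TrueClone(
                subject_id=sid, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
                beta_true=float(betas[c]), vaf_baseline=v0, age_baseline=age0,
                protein_change=change, functional_class=fclass,
                vaf_ceiling=config.vaf_ceiling,
            )
            subject_clones.append(clone)
            truth.append(clone)
            ann_rows.append(
                {
                    "variant_id": clone.variant_id,
                    "gene": gene,
                    "functional_class": fclass,
                    "protein_change": change,
                    "pop_af": 0.0,
                }
            )

        for label, off in zip(labels, offsets):
            age = age0 + off
            manifest_rows.append(
                {
                    "subject_id": sid,
                    "timepoint": label,
                    "age": round(age, 3),
                    "draw_year": enroll_year + off,
                    "bmi": round(bmi, 2),
                    "smoking": smoking,
                    "race_ethnicity": race,
                }
            )
            rows = []
            for clone in subject_clones:
                depth = max(
                    1,
                    int(
                        round(
                            rng.lognormal(
                                np.log(config.depth_lognorm_median),
                                config.depth_lognorm_sigma,
                            )
                        )
                    ),
                )
                v = clone.vaf_at(age)
                alt_count, depth = simulate_site_reads(v, depth, config.error_rate, rng)
                rows.append(
                    {
                        "chrom": clone.chrom,
                        "pos": clone.pos,
                        "ref": clone.ref,
                        "alt": clone.alt,
                        "gene": clone.gene,
                        "depth": depth,
                        "alt_count": alt_count,
                    }
                )
            inv = simulate_invariant_sites(
                config.n_invariant_sites,
                np.maximum(
                    1,
                    np.round(
                        rng.lognormal(
                            np.log(config.depth_lognorm_median),
                            config.depth_lognorm_sigma,
                            size=config.n_invariant_sites,
                        )
                    ).astype(int),
                ),
                config.error_rate,
                rng,
            ) if config.n_invariant_sites else None
            obs = pd.DataFrame(
                rows,
                columns=["chrom", "pos", "ref", "alt", "gene", "depth", "alt_count"],
            )
            if len(obs):
                obs["vaf"] = obs["alt_count"] / obs["depth"]
            else:
                obs["vaf"] = pd.Series(dtype=float)
            obs.attrs["invariant_sites"] = inv
            observations[(sid, label)] = obs

    manifest = pd.DataFrame(manifest_rows)
    annotations = pd.DataFrame(
        ann_rows,
        columns=["variant_id", "gene", "functional_class", "protein_change", "pop_af"],
    )
    return CohortData(truth=truth, manifest=manifest, observations=observations,
                      annotations=annotations)


def _fresh_umi(rng: np.random.Generator, used: set) -> str:
    while True:
        umi = "".join(rng.choice(_BASES, size=9))
        if umi not in used:
            used.add(umi)
            return umi


def simulate_umi_reads(
    observations: Sequence,
    umi_duplication_rate: float,
    seed: int | np.random.Generator = 0,
    copy_error_rate: float = 0.0,
) -> list[RawReadRecord]:
    """Expand per-site molecule counts into UMI-tagged raw read records.

    Each unique molecule gets a distinct 9-mer UMI within its probe and is
    emitted 1 + Poisson(rate − 1) times; duplicate copies repeat the molecule's
    allele except for an optional per-copy substitution error.  ``observations``
    is a sequence of objects/rows with chrom, pos, ref, alt, depth, alt_count.
    """
    if umi_duplication_rate < 1:
        raise ConfigurationError("umi_duplication_rate must be >= 1")
    if not 0.0 <= copy_error_rate <= 1.0:
        raise ConfigurationError("copy_error_rate must be a probability")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    records: list[RawReadRecord] = []
    for obs in observations:
        get = obs.get if hasattr(obs, "get") else lambda k, o=obs: getattr(o, k)
        chrom, pos = str(get("chrom")), int(get("pos"))
        ref, alt = str(get("ref")), str(get("alt"))
        depth, alt_count = int(get("depth")), int(get("alt_count"))
        probe_id = f"probe_{chrom}:{pos}"
        used_umis: set = set()
        alleles = [alt] * alt_count + [ref] * (depth - alt_count)
        for allele in alleles:
            umi = _fresh_umi(rng, used_umis)
            n_copies = 1 + int(rng.poisson(umi_duplication_rate - 1.0))
            for _ in range(n_copies):
                obs_allele = allele
                if copy_error_rate and rng.random() < copy_error_rate:
                    obs_allele = alt if allele == ref else ref
                records.append(
                    RawReadRecord(
                        probe_id=probe_id, umi=umi, chrom=chrom, pos=pos,
                        ref=ref, alt=alt, observed_allele=obs_allele,
                    )
                )
    return records


def simulate_mixture(
    mixture: MixtureSpec,
    depth: int = 2803,
    error_rate: float = 0.00045,
    n_replicates: int = 27,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate repeated sequencing of a defined cell-line mixture.

    Each variant's true VAF is its expected mixture VAF (proportion-weighted
    mean of dosage/2); counts are binomial as in :func:`simulate_site_reads`.
    Returns a long table: replicate, variant_id, expected_vaf, depth,
    alt_count, vaf.
    """
    from .validation import expected_mixture_vaf

    mixture.validate()
    if not mixture.dosages:
        raise ConfigurationError("mixture has no variant dosages")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    variant_ids = list(mixture.dosages.keys())
    expected = {vid: expected_mixture_vaf(mixture, vid) for vid in variant_ids}
    for rep in range(1, n_replicates + 1):
        for vid in variant_ids:
            alt, d = simulate_site_reads(expected[vid], depth, error_rate, rng)
            rows.append(
                {
                    "replicate": rep,
                    "variant_id": vid,
                    "expected_vaf": expected[vid],
                    "depth": d,
                    "alt_count": alt,
                    "vaf": alt / d,
                }
            )
    return pd.DataFrame(rows)
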