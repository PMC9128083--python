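"""CHIP driver annotation and per-subject CHIP status.

A configurable whitelist maps PASS somatic calls to CHIP driver mutations
using gene name, variant functional class, an optional explicit change list,
and a population-allele-frequency ceiling for germline exclusion.  Rule kinds:

* ``hotspot`` — only the explicitly listed protein changes qualify;
* ``truncating`` — frameshift / splice-site / nonsense anywhere in the gene;
* ``missense`` — any nonsynonymous change (used for genes where both
  truncating and missense variants are accepted, e.g. ZBTB33/ZNF318-style
  rules);
* ``listed_missense`` — missense changes restricted to an explicit list.

A gene may carry several rules; a call is a driver if any rule matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneRule",
    "DriverWhitelist",
    "VariantAnnotation",
    "DriverMutation",
    "ChipStatus",
    "annotate_driver",
    "chip_status",
    "chip_status_table",
    "prevalence_by_age",
    "default_whitelist",
]

logger = logging.getLogger(__name__)

RULE_KINDS = {"hotspot", "truncating", "missense", "listed_missense"}

TRUNCATING_CLASSES = {
    "nonsense", "stopgain", "frameshift", "frameshift_insertion",
    "frameshift_deletion", "splice_site", "splicing",
}
MISSENSE_CLASSES = {"missense", "nonsynonymous", "nonsynonymous_snv"}


@dataclass
class GeneRule:
    gene: str
    kinds: list[str]
    changes: list[str] = field(default_factory=list)
    af_ceiling: float = 0.001

    def __post_init__(self) -> None:
        unknown = set(self.kinds) - RULE_KINDS
        if unknown:
            raise ValueError(f"{self.gene}: unknown rule kinds {sorted(unknown)}")
        if ("hotspot" in self.kinds or "listed_missense" in self.kinds) and not self.changes:
            raise ValueError(f"{self.gene}: hotspot/listed_missense rules need a change list")


@dataclass
class DriverWhitelist:
    """Per-gene driver rules; each gene appears exactly once."""

    rules: dict[str, GeneRule]

    @classmethod
    def from_rules(cls, rules: list[GeneRule]) -> "DriverWhitelist":
        seen: dict[str, GeneRule] = {}
        for r in rules:
            if r.gene in seen:
                raise ValueError(f"gene {r.gene} appears more than once in whitelist")
            seen[r.gene] = r
        return cls(rules=seen)

    @classmethod
    def from_yaml(cls, path) -> "DriverWhitelist":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = [
            GeneRule(
                gene=gene,
                kinds=list(block.get("kinds", [])),
                changes=list(block.get("changes", []) or []),
                af_ceiling=float(block.get("af_ceiling", 0.001)),
            )
            for gene, block in raw["genes"].items()
        ]
        return cls.from_rules(rules)

    def to_yaml(self, path) -> None:
        doc = {
            "genes": {
                r.gene: {
                    "kinds": list(r.kinds),
                    "changes": list(r.changes),
                    "af_ceiling": r.af_ceiling,
                }
                for r in self.rules.values()
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def default_whitelist() -> DriverWhitelist:
    """The 15-gene panel whitelist with the documented rule kinds.

    Full-gene targets accept truncating variants (plus recurrent missense
    hotspots where established); ZBTB33 and ZNF318 accept truncating *or any*
    nonsynonymous change; the four hotspot-only targets accept just their
    listed changes.
    """
    full = lambda g, changes=(): GeneRule(  # noqa: E731
        g,
        kinds=["truncating"] + (["listed_missense"] if changes else []),
        changes=list(changes),
    )
    rules = [
        GeneRule("DNMT3A", kinds=["truncating", "missense"]),
        full("TET2"),
        full("ASXL1"),
        full("PPM1D"),
        full("CBL", ("C384Y", "R420Q")),
        full("SF3B1", ("K700E", "K666N")),
        full("TP53", ("R175H", "R248Q", "R273H")),
        full("U2AF1", ("S34F", "Q157P")),
        full("GNB1", ("K57E",)),
        GeneRule("ZBTB33", kinds=["truncating", "missense"]),
        GeneRule("ZNF318", kinds=["truncating", "missense"]),
        GeneRule("JAK2", kinds=["hotspot"], changes=["V617F"]),
        GeneRule("SRSF2", kinds=["hotspot"], changes=["P95H", "P95L", "P95R"]),
        GeneRule("IDH1", kinds=["hotspot"], changes=["R132H", "R132C"]),
        GeneRule("IDH2", kinds=["hotspot"], changes=["R140Q", "R172K"]),
    ]
    return DriverWhitelist.from_rules(rules)


@dataclass
class VariantAnnotation:
    """Externally supplied functional annotation for one variant."""

    variant_id: str
    gene: str
    functional_class: str
    protein_change: str = ""
    pop_af: float = 0.0


@dataclass
class DriverMutation:
    """A whitelist-matching driver mutation tracked across timepoints."""

    subject_id: str
    gene: str
    variant_id: str
    protein_change: str = ""
    # (timepoint label, age, depth, alt_count, vaf) per visit, age-sorted
    observations: list[tuple] = field(default_factory=list)


@dataclass
class ChipStatus:
    subject_id: str
    timepoint: str
    n_clones_2pct: int
    n_clones_10pct: int

    @property
    def chip_positive(self) -> bool:
        return self.n_clones_2pct >= 1


def annotate_driver(
    call,
    annotation: VariantAnnotation | None,
    whitelist: DriverWhitelist,
) -> bool:
    """True iff a PASS call is a CHIP driver under the whitelist.

    ``call`` may be a CandidateCall, SiteObservation, or any object with a
    ``variant_id``.  A missing annotation is treated (with a warning) as
    non-driver; a population allele frequency at or above the gene's ceiling
    excludes the variant as likely germline.
    """
    if annotation is None:
        vid = getattr(call, "variant_id", getattr(getattr(call, "obs", None), "variant_id", "?"))
        logger.warning("no annotation for PASS call %s; treating as non-driver", vid)
        return False
    rule = whitelist.rules.get(annotation.gene)
    if rule is None:
        return False
    if annotation.pop_af >= rule.af_ceiling:
        return False
    fclass = annotation.functional_class.lower()
    for kind in rule.kinds:
        if kind == "truncating" and fclass in TRUNCATING_CLASSES:
            return True
        if kind == "missense" and fclass in MISSENSE_CLASSES:
            return True
        if kind == "hotspot" and annotation.protein_change in rule.changes:
            return True
        if (
            kind == "listed_missense"
            and fclass in MISSENSE_CLASSES
            and annotation.protein_change in rule.changes
        ):
            return True
    return False


def chip_status(
    subject_id: str,
    timepoint: str,
    driver_vafs,
    chip_vaf: float = 0.02,
    large_clone_vaf: float = 0.10,
) -> ChipStatus:
    """CHIP status at one subject-timepoint from its driver VAFs (inclusive ≥)."""
    vafs = np.asarray(list(driver_vafs), dtype=float)
    return ChipStatus(
        subject_id=subject_id,
        timepoint=timepoint,
        n_clones_2pct=int((vafs >= chip_vaf).sum()),
        n_clones_10pct=int((vafs >= large_clone_vaf).sum()),
    )


def chip_status_table(
    drivers: pd.DataFrame,
    manifest: pd.DataFrame,
    chip_vaf: float = 0.02,
    large_clone_vaf: float = 0.10,
) -> pd.DataFrame:
    """Per-(subject, timepoint) CHIP status for all sequenced samples.

    ``drivers`` needs subject_id, timepoint, vaf; ``manifest`` supplies the
    full set of sequenced samples so driver-free samples appear with zero
    counts.  Emits both the per-timepoint counts and, via ``ever_chip``, the
    subject-level "driver at ≥2% at any timepoint" summary.
    """
    counts = (
        drivers.groupby(["subject_id", "timepoint"])["vaf"]
        .agg(
            n_clones_2pct=lambda v: int((v >= chip_vaf).sum()),
            n_clones_10pct=lambda v: int((v >= large_clone_vaf).sum()),
        )
        .reset_index()
    )
    out = manifest[["subject_id", "timepoint", "age"]].merge(
        counts, on=["subject_id", "timepoint"], how="left"
    )
    out[["n_clones_2pct", "n_clones_10pct"]] = (
        out[["n_clones_2pct", "n_clones_10pct"]].fillna(0).astype(int)
    )
    out["chip_positive"] = out["n_clones_2pct"] >= 1
    ever = out.groupby("subject_id")["chip_positive"].any().rename("ever_chip")
    out = out.merge(ever, on="subject_id")
    return out


def prevalence_by_age(
    statuses: pd.DataFrame,
    age_bins=(50, 60, 70, 80, 100),
) -> pd.DataFrame:
    """Fraction of subjects CHIP-positive per age bin at the first timepoint.

    ``statuses`` should hold one row per subject (its initial timepoint) with
    age, n_clones_2pct, n_clones_10pct.  Empty bins report NaN, not 0.
    """
    df = statuses.copy()
    df["age_bin"] = pd.cut(df["age"], bins=list(age_bins), right=False)
    rows = []
    for interval in df["age_bin"].cat.categories:
        sub = df[df["age_bin"] == interval]
        n = len(sub)
        rows.append(
            {
                "age_bin": str(interval),
                "n_subjects": n,
                "prevalence_2pct": (sub["n_clones_2pct"] >= 1).mean() if n else np.nan,
                "prevalence_10pct": (sub["n_clones_10pct"] >= 1).mean() if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
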