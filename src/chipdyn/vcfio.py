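"""VCF and TSV round-trip I/O for per-sample site observations.

VCFs are v4.2 with per-record INFO fields DP (deduplicated depth) and AD
(ref,alt read counts); coordinates are 1-based inclusive throughout.
Multi-allelic records are decomposed into biallelic observations on read.
A VCF lacking AD falls back to a ``<path>.counts.tsv`` sidecar keyed by
chrom/pos/ref/alt.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .variants import SiteObservation

__all__ = ["read_vcf", "write_vcf", "read_observation_tsv", "write_observation_tsv"]


class VcfParseError(ValueError):
    pass


_HEADER_LINES = [
    ('INFO', {'ID': 'DP', 'Number': '1', 'Type': 'Integer',
              'Description': 'Deduplicated read depth'}),
    ('INFO', {'ID': 'AD', 'Number': 'R', 'Type': 'Integer',
              'Description': 'Deduplicated read counts per allele (ref first)'}),
]


def write_vcf(path, observations: Iterable[SiteObservation]) -> None:
    """Write observations as a minimal uncompressed VCF v4.2."""
    obs = sorted(observations, key=lambda o: (o.chrom, o.pos, o.ref, o.alt))
    header = pysam.VariantHeader()
    for kind, d in _HEADER_LINES:
        header.add_meta(kind, items=list(d.items()))
    for chrom in dict.fromkeys(o.chrom for o in obs):
        header.contigs.add(chrom)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for o in obs:
            rec = vf.new_record(
                contig=o.chrom, start=o.pos - 1, stop=o.pos,
                alleles=(o.ref, o.alt),
            )
            rec.info["DP"] = o.depth
            rec.info["AD"] = (o.depth - o.alt_count, o.alt_count)
            vf.write(rec)


def read_vcf(path) -> list[SiteObservation]:
    """Read a VCF into biallelic SiteObservations (1-based positions).

    Multi-allelic records are decomposed, pairing each alternate allele with
    its AD entry.  When AD is absent everywhere, counts come from a
    ``<path>.counts.tsv`` sidecar (columns chrom, pos, ref, alt, depth,
    alt_count); a missing sidecar is a parse error.
    """
    sidecar = None
    out: list[SiteObservation] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as e:
        raise VcfParseError(f"{path}: cannot parse VCF header: {e}") from e
    with vf:
        has_dp = "DP" in vf.header.info
        has_ad = "AD" in vf.header.info
        for i, rec in enumerate(vf, start=1):
            if rec.alts is None:
                continue
            dp = rec.info.get("DP") if has_dp else None
            ad = rec.info.get("AD") if has_ad else None
            if ad is None:
                if sidecar is None:
                    sidecar = _load_sidecar(path, record_no=i)
                for alt in rec.alts:
                    key = (rec.chrom, rec.pos, rec.ref, alt)
                    if key not in sidecar.index:
                        raise VcfParseError(
                            f"{path} record {i}: no AD and no sidecar entry for {key}"
                        )
                    row = sidecar.loc[key]
                    out.append(SiteObservation(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=str(alt),
                        depth=int(row["depth"]), alt_count=int(row["alt_count"]),
                    ))
                continue
            if dp is None:
                dp = sum(int(x) for x in ad)
            if len(ad) != len(rec.alts) + 1:
                raise VcfParseError(
                    f"{path} record {i} ({rec.chrom}:{rec.pos}): "
                    f"AD has {len(ad)} entries for {len(rec.alts)} alts"
                )
            for alt, alt_count in zip(rec.alts, ad[1:]):
                out.append(SiteObservation(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=str(alt),
                    depth=int(dp), alt_count=int(alt_count),
                ))
    return out


def _load_sidecar(vcf_path, record_no: int) -> pd.DataFrame:
    sidecar_path = f"{vcf_path}.counts.tsv"
    if not os.path.exists(sidecar_path):
        raise VcfParseError(
            f"{vcf_path} record {record_no}: AD missing and no sidecar "
            f"{sidecar_path}"
        )
    df = pd.read_csv(sidecar_path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return df.set_index(["chrom", "pos", "ref", "alt"])


def write_observation_tsv(path, observations: Sequence[SiteObservation] | pd.DataFrame) -> None:
    if isinstance(observations, pd.DataFrame):
        df = observations
    else:
        df = pd.DataFrame(
            [
                {"chrom": o.chrom, "pos": o.pos, "ref": o.ref, "alt": o.alt,
                 "depth": o.depth, "alt_count": o.alt_count, "vaf": o.vaf}
                for o in observations
            ]
        )
    df.to_csv(path, sep="\t", index=False)


def read_observation_tsv(path) -> list[SiteObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return [
        SiteObservation(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
                        depth=int(r.depth), alt_count=int(r.alt_count))
        for r in df.itertuples()
    ]
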