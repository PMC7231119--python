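"""Variant-table IO, hard filtering, and per-sample tallies.

SNPs pass with FS < 60, MQ > 40, QD > 4 and a genotype-quality condition;
indels pass with FS <= 200 and QD >= 4 (inclusive, unlike the strict SNP
thresholds).  GQ is a per-sample field: a sample's genotype is masked where
its GQ fails the floor, and a site satisfies the GQ condition only if both
bulk samples keep a genotype — parents may drop out without killing the
site, because the SNP-index is computed from the bulks.

The canonical in-memory form is a flat pandas DataFrame (one row per
bi-allelic site, columns ``{sample}_gt/_gq/_ad_ref/_ad_alt`` per sample);
``VariantSite`` is the scalar view used by the per-site filter functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

SAMPLES = ("KF", "KM", "K21", "K5")
HET_GTS = {"0/1", "1/0", "0|1", "1|0"}
HOM_ALT_GTS = {"1/1", "1|1"}
HOM_REF_GTS = {"0/0", "0|0"}


@dataclass(frozen=True)
class SnpFilterParams:
    fs_max: float = 60.0    # FS <  fs_max  (strict)
    mq_min: float = 40.0    # MQ >  mq_min  (strict)
    qd_min: float = 4.0     # QD >  qd_min  (strict)
    gq_min: float = 20.0    # per-sample GQ > gq_min


@dataclass(frozen=True)
class IndelFilterParams:
    fs_max: float = 200.0   # FS <= fs_max  (inclusive)
    qd_min: float = 4.0     # QD >= qd_min  (inclusive)


@dataclass
class SampleCall:
    gt: str
    gq: float
    ad_ref: int
    ad_alt: int


@dataclass
class VariantSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    fs: float
    mq: float
    qd: float
    samples: dict[str, SampleCall]

    @property
    def vtype(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SampleTally:
    total: int
    het: int
    hom: int


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


# ---------------------------------------------------------------------------
# per-site filters
# ---------------------------------------------------------------------------

def filter_snp(
    site: VariantSite,
    params: SnpFilterParams = SnpFilterParams(),
    bulks: tuple[str, str] = ("K21", "K5"),
) -> tuple[bool, str | None]:
    """(passed, first-violated-rule-or-None) for a SNP site."""
    for key in ("fs", "mq", "qd"):
        if _missing(getattr(site, key)):
            return False, f"missing:{key}"
    if not site.fs < params.fs_max:
        return False, "FS"
    if not site.mq > params.mq_min:
        return False, "MQ"
    if not site.qd > params.qd_min:
        return False, "QD"
    for b in bulks:
        call = site.samples.get(b)
        if call is None or _missing(call.gq):
            return False, f"missing:GQ:{b}"
        if call.gt in ("./.", ".|.") or not call.gq > params.gq_min:
            return False, "GQ"
    return True, None


def filter_indel(
    site: VariantSite, params: IndelFilterParams = IndelFilterParams()
) -> tuple[bool, str | None]:
    """(passed, first-violated-rule-or-None) for an indel site."""
    for key in ("fs", "qd"):
        if _missing(getattr(site, key)):
            return False, f"missing:{key}"
    if not site.fs <= params.fs_max:
        return False, "FS"
    if not site.qd >= params.qd_min:
        return False, "QD"
    return True, None


# ---------------------------------------------------------------------------
# DataFrame <-> VariantSite and bulk filtering
# ---------------------------------------------------------------------------

def site_from_row(row, samples=SAMPLES) -> VariantSite:
    d = row._asdict() if hasattr(row, "_asdict") else dict(row)
    return VariantSite(
        chrom=d["chrom"], pos=int(d["pos"]), ref=d["ref"], alt=d["alt"],
        fs=d["fs"], mq=d["mq"], qd=d["qd"],
        samples={
            s: SampleCall(
                gt=d[f"{s}_gt"], gq=d[f"{s}_gq"],
                ad_ref=int(d[f"{s}_ad_ref"]), ad_alt=int(d[f"{s}_ad_alt"]),
            )
            for s in samples
            if f"{s}_gt" in d
        },
    )


def apply_filters(
    df: pd.DataFrame,
    snp_params: SnpFilterParams = SnpFilterParams(),
    indel_params: IndelFilterParams = IndelFilterParams(),
    bulks: tuple[str, str] = ("K21", "K5"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Filter a variant table; returns (passing rows, fail reason per row).

    The reason series is indexed like ``df`` with None for passing rows.
    """
    passed = np.zeros(len(df), dtype=bool)
    reasons: list[str | None] = []
    for i, row in enumerate(df.itertuples(index=False)):
        site = site_from_row(row)
        if site.vtype == "SNP":
            ok, why = filter_snp(site, snp_params, bulks)
        else:
            ok, why = filter_indel(site, indel_params)
        passed[i] = ok
        reasons.append(why)
    return df[passed].reset_index(drop=True), pd.Series(reasons, index=df.index)


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

def tally_sample(df: pd.DataFrame, sample: str) -> SampleTally:
    """Het / hom-alt / total counts for one sample (hom-ref and missing excluded)."""
    col = f"{sample}_gt"
    if col not in df.columns:
        raise KeyError(f"unknown sample {sample!r}")
    gt = df[col]
    het = int(gt.isin(HET_GTS).sum())
    hom = int(gt.isin(HOM_ALT_GTS).sum())
    return SampleTally(total=het + hom, het=het, hom=hom)


def union_variants(per_sample_sites: list) -> int:
    """Count distinct (chrom, pos, ref, alt) keys across per-sample site sets.

    Accepts DataFrames (with chrom/pos/ref/alt columns) or iterables of keys.
    """
    if not per_sample_sites:
        raise ValueError("need at least one sample set")
    keys: set = set()
    for sites in per_sample_sites:
        if isinstance(sites, pd.DataFrame):
            keys.update(map(tuple, sites[["chrom", "pos", "ref", "alt"]].itertuples(index=False)))
        else:
            keys.update(tuple(k) for k in sites)
    return len(keys)


def write_tally_report(df: pd.DataFrame, path: str | Path, samples=SAMPLES) -> None:
    """Per-sample SNP/indel het-hom table, one row per sample plus the union."""
    is_snp = (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)
    rows = []
    for s in samples:
        if f"{s}_gt" not in df.columns:
            continue
        for label, sub in (("SNP", df[is_snp]), ("indel", df[~is_snp])):
            t = tally_sample(sub, s)
            rows.append({"sample": s, "vtype": label,
                         "total": t.total, "het": t.het, "hom": t.hom})
    rows.append({"sample": "union", "vtype": "any",
                 "total": union_variants([df]), "het": "", "hom": ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF IO (minimal VCF 4.2: INFO FS/MQ/QD, FORMAT GT:AD:GQ)
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bulkseg
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled Fisher strand bias">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_vcf(df: pd.DataFrame, path: str | Path, samples=SAMPLES) -> None:
    samples = [s for s in samples if f"{s}_gt" in df.columns]
    lines = [_VCF_HEADER.rstrip("\n")]
    for chrom in pd.unique(df["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for row in df.itertuples(index=False):
        d = row._asdict()
        info = f"FS={d['fs']:.3f};MQ={d['mq']:.3f};QD={d['qd']:.3f}"
        fields = [d["chrom"], str(d["pos"]), ".", d["ref"], d["alt"], ".", "PASS", info, "GT:AD:GQ"]
        for s in samples:
            fields.append(
                f"{d[f'{s}_gt']}:{int(d[f'{s}_ad_ref'])},{int(d[f'{s}_ad_alt'])}:{int(d[f'{s}_gq'])}"
            )
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF with FS/MQ/QD INFO and GT:AD:GQ samples into the flat table.

    Multi-allelic records are split into one bi-allelic row per alt allele
    (AD recomputed as ref vs that alt; genotypes re-expressed against it).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        gq = rec.format("GQ")
        for ai, alt in enumerate(rec.ALT):
            row = {
                "chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": alt,
                "fs": rec.INFO.get("FS"), "mq": rec.INFO.get("MQ"), "qd": rec.INFO.get("QD"),
            }
            row["vtype"] = "SNP" if len(rec.REF) == 1 and len(alt) == 1 else "indel"
            for si, s in enumerate(samples):
                alleles = rec.genotypes[si][:-1]
                if any(a < 0 for a in alleles):
                    gt = "./."
                else:
                    mapped = ["1" if a == ai + 1 else "0" for a in alleles]
                    gt = "/".join(sorted(mapped))
                row[f"{s}_gt"] = gt
                row[f"{s}_gq"] = float(gq[si][0]) if gq is not None else np.nan
                row[f"{s}_ad_ref"] = int(ad[si][0]) if ad is not None else 0
                row[f"{s}_ad_alt"] = int(ad[si][ai + 1]) if ad is not None else 0
            rows.append(row)
    return pd.DataFrame(rows)
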