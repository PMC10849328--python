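"""VCF, sample-sheet and BED-mask I/O.

Writing emits minimal VCF v4.2 text with FORMAT ``GT:DP:AD:GQ`` and INFO
``MQ``/``MQ0F``; invariant sites are written with ALT "." and a single-valued
AD (ref reads only).  Reading goes through cyvcf2/htslib, so bgzipped input
works transparently; ``.gz`` output is bgzip-compressed via pysam so that
downstream htslib tools accept it.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from gamescan.types import (
    MISSING,
    SAMPLE_COLUMNS,
    VARIANT_COLUMNS,
    GenotypeCalls,
    validate_samples,
    validate_variants,
)

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_HEADER = """\
##fileformat=VCFv4.2
##source=gamescan
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQ0F,Number=1,Type=Float,Description="Fraction of MQ0 reads">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_vcf(
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    calls: GenotypeCalls,
    path: str | os.PathLike,
) -> None:
    """Write the cohort as VCF v4.2 (bgzipped when ``path`` ends in .gz)."""
    validate_samples(samples)
    validate_variants(variants)
    if calls.n_samples != len(samples) or calls.n_variants != len(variants):
        raise ValueError("calls shape does not match sample/variant tables")

    path = os.fspath(path)
    gz = path.endswith(".gz")
    text_path = path[:-3] + ".tmp.vcf" if gz else path

    contigs = list(dict.fromkeys(variants["chrom"]))
    with open(text_path, "w") as fh:
        fh.write(_HEADER)
        for c in contigs:
            length = int(variants.loc[variants["chrom"] == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={length + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples["sample_id"])
            + "\n"
        )
        dos = calls.dosage
        dp = calls.dp
        ad = calls.ad
        gq = calls.gq
        for j, rec in enumerate(variants.itertuples(index=False)):
            invariant = rec.alt == "."
            info = f"MQ={rec.mq:g};MQ0F={rec.mq0f:g}"
            fields = []
            for i in range(len(samples)):
                d = int(dos[i, j])
                if d == MISSING:
                    gt = "./."
                elif invariant:
                    gt = "0/0" if d == 0 else _GT_STRINGS[d]
                else:
                    gt = _GT_STRINGS[d]
                if invariant:
                    ad_str = str(int(ad[i, j, 0]))
                else:
                    ad_str = f"{int(ad[i, j, 0])},{int(ad[i, j, 1])}"
                fields.append(f"{gt}:{int(dp[i, j])}:{ad_str}:{int(gq[i, j])}")
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}\tGT:DP:AD:GQ\t"
                + "\t".join(fields)
                + "\n"
            )
    if gz:
        import pysam

        pysam.tabix_compress(text_path, path, force=True)
        os.remove(text_path)


def read_vcf(
    path: str | os.PathLike, sample_sheet: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeCalls]:
    """Read a VCF into (samples, variants, calls).

    If ``sample_sheet`` is given, its sample ids must all be present in the
    VCF and the output is restricted to (and ordered by) the sheet; group and
    population labels come from the sheet.  Otherwise every VCF sample is
    returned with group/population set to "unknown".

    Multiallelic records are kept as rows flagged ``is_multiallelic`` (first
    ALT only, extra-allele dosages treated as missing) so that site filters
    can count and drop them; indels are flagged likewise.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path), gts012=True)
    vcf_samples = list(vcf.samples)
    if sample_sheet is not None:
        validate_samples(sample_sheet)
        missing = set(sample_sheet["sample_id"]) - set(vcf_samples)
        if missing:
            raise ValueError(f"sheet samples absent from VCF: {sorted(missing)}")
        samples = sample_sheet.reset_index(drop=True)
    else:
        samples = pd.DataFrame(
            {
                "sample_id": vcf_samples,
                "group": "unknown",
                "population": "unknown",
            }
        )
    sel = np.array([vcf_samples.index(s) for s in samples["sample_id"]])

    var_rows = []
    dos_rows, dp_rows, ad_rows, gq_rows = [], [], [], []
    n_in_vcf = len(vcf_samples)
    for v in vcf:
        n_alt = len(v.ALT)
        invariant = n_alt == 0
        is_multi = n_alt > 2 or n_alt == 2  # >1 ALT allele
        is_indel = v.is_indel
        alt = "." if invariant else ",".join(v.ALT)
        var_rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": alt,
                "mq": _info_float(v, "MQ"),
                "mq0f": _info_float(v, "MQ0F"),
                "indel_distance": np.inf,
                "is_indel": bool(is_indel),
                "is_multiallelic": bool(n_alt > 1),
            }
        )
        # genotypes: list of [a1, a2, phased]; -1 encodes '.'
        gts = v.genotypes
        dos = np.empty(n_in_vcf, dtype=np.int8)
        for i, g in enumerate(gts):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                dos[i] = MISSING
            elif invariant:
                dos[i] = 0
            elif any(a > 1 for a in alleles):
                dos[i] = MISSING  # third allele: not representable biallelically
            else:
                dos[i] = sum(alleles)
        dos_rows.append(dos)

        dp = v.format("DP")
        dp_rows.append(
            np.zeros(n_in_vcf, dtype=np.int32)
            if dp is None
            else np.clip(dp[:, 0], 0, None).astype(np.int32)
        )
        ad = v.format("AD")
        if ad is None:
            ad_arr = np.zeros((n_in_vcf, 2), dtype=np.int32)
        else:
            ad_arr = np.clip(ad, 0, None).astype(np.int32)
            if ad_arr.shape[1] == 1:  # invariant site: ref reads only
                ad_arr = np.concatenate(
                    [ad_arr, np.zeros((n_in_vcf, 1), dtype=np.int32)], axis=1
                )
            ad_arr = ad_arr[:, :2]
        ad_rows.append(ad_arr)
        gqf = v.format("GQ")
        if gqf is None:
            gq_rows.append(np.zeros(n_in_vcf, dtype=np.int16))
        else:
            gq_rows.append(np.clip(gqf[:, 0], 0, None).astype(np.int16))

    variants = pd.DataFrame(var_rows, columns=VARIANT_COLUMNS)
    validate_variants(variants)
    dosage = np.stack(dos_rows, axis=1)[sel]
    dp_m = np.stack(dp_rows, axis=1)[sel]
    ad_m = np.stack(ad_rows, axis=1)[sel]
    gq_m = np.stack(gq_rows, axis=1)[sel]
    # masked calls may still carry DP in malformed files; clamp AD to DP
    ad_m = np.minimum(ad_m, dp_m[:, :, None])
    calls = GenotypeCalls(dosage=dosage, dp=dp_m, ad=ad_m, gq=gq_m)
    return samples, variants, calls


def _info_float(v, key: str) -> float:
    val = v.INFO.get(key)
    return float(val) if val is not None else np.nan


def write_sample_sheet(samples: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_samples(samples)
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Sample sheet TSV: sample_id <TAB> group <TAB> population, no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=SAMPLE_COLUMNS, dtype=str)
    validate_samples(df)
    return df


def read_bed_mask(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 3-column BED (0-based half-open) of retained regions.

    Intervals must be sorted and non-overlapping within each chromosome.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
        comment="#",
    )
    validate_mask(df)
    return df


def validate_mask(mask: pd.DataFrame) -> None:
    if np.any(mask["end"].to_numpy() <= mask["start"].to_numpy()):
        raise ValueError("mask contains empty or inverted intervals")
    for chrom, sub in mask.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if np.any(np.diff(s) < 0):
            raise ValueError(f"mask intervals unsorted on {chrom}")
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"mask intervals overlap on {chrom}")
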