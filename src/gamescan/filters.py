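"""Hard genotype, site and sample filters.

The rules are the standard bcftools-style hard filters for a medium-coverage
resequencing cohort.  Per-call rules only ever set a call MISSING (they are
order-independent and idempotent); per-site rules drop whole rows; per-sample
QC reports verdicts without silently dropping anyone — the contamination flag
in particular is advisory.

All exclusion thresholds are strict inequalities: a call with DP exactly 4 or
GQ exactly 30 is kept, a site with exactly 20% missingness is kept, a sample
with exactly 30% missing genotypes is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gamescan.types import MISSING, GenotypeCalls, is_autosome
from gamescan.vcfio import validate_mask

CALL_REASONS = ("DP_LOW", "GQ_LOW", "DP_HIGH", "AD_LOW", "AD_RATIO")
SITE_REASONS = (
    "INDEL",
    "MULTIALLELIC",
    "MQ",
    "MQ0F",
    "NEAR_INDEL",
    "MASKED",
    "MISSINGNESS",
)


@dataclass(frozen=True)
class FilterThresholds:
    """All hard-filter cutoffs, with the cohort defaults.

    ``dp_gq_rule`` selects how "DP < 4 GQ < 30" is read: "or" (either
    condition masks the call; the conservative bcftools-style reading, the
    default) or "and" (both required).
    """

    mq_min: float = 50.0
    mq0f_max: float = 0.1
    indel_dist_min_bp: int = 3  # keep sites strictly more than this from an indel
    dp_call_min: int = 4
    gq_min: int = 30
    het_ad_min: int = 2
    het_ad_ratio_low: float = 0.25
    het_ad_ratio_high: float = 0.75
    dp_max_factor: float = 1.65  # x per-sample mean autosomal depth
    site_missing_max: float = 0.20
    sample_missing_max: float = 0.30
    mito_contam_af: float = 0.20
    mito_contam_site_frac: float = 0.05
    maf_gwas: float = 0.05
    min_allele_count: int = 1
    dp_gq_rule: str = "or"

    def __post_init__(self) -> None:
        if not (0.0 <= self.het_ad_ratio_low <= self.het_ad_ratio_high <= 1.0):
            raise ValueError("AD-ratio band must satisfy 0 <= low <= high <= 1")
        if self.dp_max_factor <= 0:
            raise ValueError("dp_max_factor must be positive")
        if self.dp_gq_rule not in ("or", "and"):
            raise ValueError("dp_gq_rule must be 'or' or 'and'")


@dataclass
class FilterReport:
    """Reason-coded account of everything the filters removed."""

    call_reasons: dict[str, np.ndarray] = field(default_factory=dict)
    site_reasons: dict[str, np.ndarray] = field(default_factory=dict)
    sample_verdicts: pd.DataFrame | None = None

    def call_counts(self) -> pd.Series:
        return pd.Series(
            {k: int(v.sum()) for k, v in self.call_reasons.items()}, name="n_calls"
        )

    def site_counts(self) -> pd.Series:
        return pd.Series(
            {k: int(v.sum()) for k, v in self.site_reasons.items()}, name="n_sites"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": "call", "reason": k, "count": int(v.sum())}
            for k, v in self.call_reasons.items()
        ] + [
            {"level": "site", "reason": k, "count": int(v.sum())}
            for k, v in self.site_reasons.items()
        ]
        return pd.DataFrame(rows, columns=["level", "reason", "count"])


def mean_autosomal_depth(
    calls: GenotypeCalls, variants: pd.DataFrame
) -> np.ndarray:
    """Arithmetic mean DP over non-missing calls at autosomal sites, per sample.

    A property of sequencing rather than of site QC, so it is computed on the
    pre-filter calls.  A sample with zero called autosomal genotypes is an
    error (its depth is undefined and the high-depth rule could not run).
    """
    auto = variants["chrom"].map(is_autosome).to_numpy()
    if not auto.any():
        raise ValueError("no autosomal sites in variant table")
    called = (calls.dosage[:, auto] != MISSING)
    n_called = called.sum(axis=1)
    if np.any(n_called == 0):
        bad = np.where(n_called == 0)[0]
        raise ValueError(f"samples with zero called autosomal genotypes: {bad.tolist()}")
    dp = calls.dp[:, auto]
    return (dp * called).sum(axis=1) / n_called


def apply_genotype_filters(
    calls: GenotypeCalls,
    thresholds: FilterThresholds,
    mean_depths: np.ndarray,
) -> tuple[GenotypeCalls, FilterReport]:
    """Mask individual calls that fail the per-genotype hard filters.

    A call becomes MISSING when: DP < dp_call_min or GQ < gq_min (joined by
    ``dp_gq_rule``); DP >= dp_max_factor x the sample's mean autosomal depth;
    het with min(AD) < het_ad_min; or het with ref-read fraction outside
    [ratio_low, ratio_high].  Homozygous calls are never touched by the two
    AD rules.  Already-missing calls stay missing and accrue no reasons.
    """
    t = thresholds
    called = calls.dosage != MISSING
    het = calls.dosage == 1

    dp_low = calls.dp < t.dp_call_min
    gq_low = calls.gq < t.gq_min
    if t.dp_gq_rule == "or":
        dpgq = dp_low | gq_low
    else:
        dpgq = dp_low & gq_low
    dp_high = calls.dp >= t.dp_max_factor * mean_depths[:, None]

    ad = calls.ad
    ad_min = ad.min(axis=2)
    ad_sum = ad.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ad_sum > 0, ad[:, :, 0] / np.maximum(ad_sum, 1), np.nan)
    ad_low = het & (ad_min < t.het_ad_min)
    ratio_bad = het & (ad_sum > 0) & (
        (ratio < t.het_ad_ratio_low) | (ratio > t.het_ad_ratio_high)
    )

    report = FilterReport(
        call_reasons={
            "DP_LOW": called & dp_low & (dpgq if t.dp_gq_rule == "and" else True),
            "GQ_LOW": called & gq_low & (dpgq if t.dp_gq_rule == "and" else True),
            "DP_HIGH": called & dp_high,
            "AD_LOW": called & ad_low,
            "AD_RATIO": called & ratio_bad,
        }
    )
    # under the OR rule each failed condition is its own reason; under AND a
    # call is only removed (and counted) when both hold
    if t.dp_gq_rule == "and":
        report.call_reasons["DP_LOW"] = called & dpgq
        report.call_reasons["GQ_LOW"] = called & dpgq

    any_fail = called & (dpgq | dp_high | ad_low | ratio_bad)
    out = calls.copy()
    out.dosage[any_fail] = MISSING
    return out, report


def _in_mask(variants: pd.DataFrame, mask: pd.DataFrame) -> np.ndarray:
    """True where a 1-based VCF position falls inside the 0-based half-open
    BED mask.  This is the single place the two conventions meet: position
    ``pos`` is covered by interval (start, end] in 1-based terms, i.e.
    start < pos <= end."""
    validate_mask(mask)
    out = np.zeros(len(variants), dtype=bool)
    for chrom, sub in mask.groupby("chrom", sort=False):
        rows = variants["chrom"].to_numpy() == chrom
        if not rows.any():
            continue
        pos = variants.loc[rows, "pos"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # interval index whose start is the rightmost <= pos-1
        idx = np.searchsorted(starts, pos - 1, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] - 1 < ends[idx[ok]]
        out[rows] = ok
    return out


def apply_site_filters(
    variants: pd.DataFrame,
    masked_calls: GenotypeCalls,
    mask: pd.DataFrame | None,
    thresholds: FilterThresholds,
) -> tuple[np.ndarray, FilterReport]:
    """Return the boolean kept-site index after all per-site rules.

    Drops indels, multiallelic records, sites with MQ < mq_min or
    MQ0F > mq0f_max, sites within ``indel_dist_min_bp`` of an indel, sites
    outside the mapability mask, and sites whose post-genotype-filter
    missingness exceeds ``site_missing_max`` of samples.
    """
    t = thresholds
    n_samples = masked_calls.n_samples
    miss_frac = (masked_calls.dosage == MISSING).sum(axis=0) / n_samples

    mq = variants["mq"].to_numpy(dtype=float)
    mq0f = variants["mq0f"].to_numpy(dtype=float)
    reasons = {
        "INDEL": variants["is_indel"].to_numpy(dtype=bool),
        "MULTIALLELIC": variants["is_multiallelic"].to_numpy(dtype=bool),
        "MQ": np.nan_to_num(mq, nan=np.inf) < t.mq_min,
        "MQ0F": np.nan_to_num(mq0f, nan=0.0) > t.mq0f_max,
        "NEAR_INDEL": variants["indel_distance"].to_numpy(dtype=float)
        <= t.indel_dist_min_bp,
        "MASKED": ~_in_mask(variants, mask)
        if mask is not None
        else np.zeros(len(variants), dtype=bool),
        "MISSINGNESS": miss_frac > t.site_missing_max,
    }
    dropped = np.zeros(len(variants), dtype=bool)
    for r in SITE_REASONS:
        dropped |= reasons[r]
    report = FilterReport(site_reasons=reasons)
    return ~dropped, report


def sample_qc(
    masked_calls: GenotypeCalls,
    samples: pd.DataFrame,
    thresholds: FilterThresholds,
    mito_calls: GenotypeCalls | None = None,
) -> pd.DataFrame:
    """Per-sample QC verdicts after site and genotype filtering.

    HIGH_MISSING when the sample's missing fraction exceeds
    ``sample_missing_max``.  CONTAM_FLAG (advisory) when, across
    mitochondrial sites, the fraction of sites whose minor-read fraction
    exceeds ``mito_contam_af`` is above ``mito_contam_site_frac``: a diploid
    cannot be heterozygous for its mitochondria, so pervasive intermediate
    allele balance there indicates reads from a second individual.
    """
    t = thresholds
    n_var = masked_calls.n_variants
    miss_frac = (masked_calls.dosage == MISSING).sum(axis=1) / n_var
    high_missing = miss_frac > t.sample_missing_max

    contam_frac = np.zeros(masked_calls.n_samples)
    if mito_calls is not None and mito_calls.n_variants > 0:
        ad = mito_calls.ad
        dp_eff = ad.sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            minor = np.where(dp_eff > 0, ad.min(axis=2) / np.maximum(dp_eff, 1), 0.0)
        informative = dp_eff > 0
        n_inf = informative.sum(axis=1)
        flagged = ((minor > t.mito_contam_af) & informative).sum(axis=1)
        contam_frac = np.where(n_inf > 0, flagged / np.maximum(n_inf, 1), 0.0)
    contam = contam_frac > t.mito_contam_site_frac

    verdict = np.where(high_missing, "HIGH_MISSING", "KEPT")
    return pd.DataFrame(
        {
            "sample_id": samples["sample_id"].to_numpy(),
            "missing_frac": miss_frac,
            "verdict": verdict,
            "contam_frac": contam_frac,
            "contam_flag": contam,
        }
    )


def frequency_filters(
    masked_calls: GenotypeCalls,
    mode: str = "maf",
    thresholds: FilterThresholds | None = None,
    sample_index: np.ndarray | None = None,
) -> np.ndarray:
    """Kept-site index under the allele-frequency ("maf") or minor-allele-
    count ("mac") rule, computed over non-missing alleles of the included
    samples.  Thresholds are inclusive ("at a minimum of"); sites with zero
    called alleles are dropped.
    """
    t = thresholds or FilterThresholds()
    dos = masked_calls.dosage
    if sample_index is not None:
        dos = dos[sample_index]
    called = dos != MISSING
    n = 2 * called.sum(axis=0)
    a = np.where(called, dos, 0).sum(axis=0)
    minor = np.minimum(a, n - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(n > 0, minor / np.maximum(n, 1), np.nan)
    if mode == "maf":
        keep = (n > 0) & (maf >= t.maf_gwas)
    elif mode == "mac":
        keep = (n > 0) & (minor >= t.min_allele_count)
    else:
        raise ValueError("mode must be 'maf' or 'mac'")
    return keep
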