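"""Core in-memory containers shared by every stage of the pipeline.

Genotypes are held as a dense samples x variants dosage matrix (0/1/2 copies
of the ALT allele, ``MISSING`` = -1 for uncalled) together with the per-call
read evidence (DP, AD, GQ) the hard filters operate on.  Site and sample
metadata live in plain pandas DataFrames, the field's lingua franca for
tabular genomic annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sentinel dosage for an uncalled genotype.
MISSING: int = -1

#: Columns every variant table carries, in order.
VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "mq",
    "mq0f",
    "indel_distance",
    "is_indel",
    "is_multiallelic",
]

SAMPLE_COLUMNS = ["sample_id", "group", "population"]

GROUPS = ("gamecock", "nongame", "outgroup")


@dataclass
class GenotypeCalls:
    """Dense diploid genotype matrix with per-call read evidence.

    Attributes
    ----------
    dosage : int8 array, shape (n_samples, n_variants)
        ALT-allele dosage 0/1/2, or ``MISSING`` (-1).
    dp : int32 array, shape (n_samples, n_variants)
        Read depth at the call.
    ad : int32 array, shape (n_samples, n_variants, 2)
        (ref_reads, alt_reads); their sum never exceeds ``dp``.
    gq : int16 array, shape (n_samples, n_variants)
        Phred-scaled genotype quality.
    """

    dosage: np.ndarray
    dp: np.ndarray
    ad: np.ndarray
    gq: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if self.dp.shape != (n, m) or self.gq.shape != (n, m):
            raise ValueError("dp/gq shape mismatch with dosage")
        if self.ad.shape != (n, m, 2):
            raise ValueError("ad must have shape (n_samples, n_variants, 2)")
        if np.any(self.ad.sum(axis=2) > self.dp):
            raise ValueError("AD sum exceeds DP at some call")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def is_missing(self) -> np.ndarray:
        return self.dosage == MISSING

    def copy(self) -> "GenotypeCalls":
        return GenotypeCalls(
            self.dosage.copy(), self.dp.copy(), self.ad.copy(), self.gq.copy()
        )

    def take_variants(self, index: np.ndarray) -> "GenotypeCalls":
        """Subset to the given variant indices (order preserved)."""
        return GenotypeCalls(
            self.dosage[:, index], self.dp[:, index], self.ad[:, index, :], self.gq[:, index]
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeCalls":
        return GenotypeCalls(
            self.dosage[index, :], self.dp[index, :], self.ad[index, :, :], self.gq[index, :]
        )


def validate_variants(variants: pd.DataFrame) -> None:
    """Check the variant-table contract: required columns, sorted positions."""
    missing_cols = set(VARIANT_COLUMNS) - set(variants.columns)
    if missing_cols:
        raise ValueError(f"variant table missing columns: {sorted(missing_cols)}")
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")


def validate_samples(samples: pd.DataFrame) -> None:
    missing_cols = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing_cols:
        raise ValueError(f"sample table missing columns: {sorted(missing_cols)}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    bad = set(samples["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown groups: {sorted(bad)}")


def is_autosome(chrom: str) -> bool:
    """Heuristic autosome check: excludes sex chromosomes and mitochondria."""
    name = chrom.removeprefix("chr").upper()
    return name not in {"Z", "W", "X", "Y", "M", "MT"}
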