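"""Windowed selection statistics.

Hudson's FST (ratio-of-averages within windows, Bhatia-style), the
population branch statistic PBS built from pairwise FST via the
T = -ln(1 - FST) branch-length transform, observed heterozygosity tracked in
variant-count windows, and the pixy form of nucleotide diversity that uses
invariant sites and is robust to missing genotypes.

Windows are defined in numbers of variants (size, step); trailing partial
windows are emitted and flagged.  A window whose denominator is empty is
reported as NaN, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gamescan.types import MISSING, GenotypeCalls

WINDOW_COLUMNS = [
    "chrom",
    "start_idx",
    "end_idx",
    "start_bp",
    "end_bp",
    "n_variants",
    "partial",
    "value",
]


@dataclass(frozen=True)
class WindowSpec:
    """Variant-count window: ``size_variants`` wide, advancing by
    ``step_variants``."""

    size_variants: int
    step_variants: int

    def __post_init__(self) -> None:
        if self.size_variants < 1 or self.step_variants < 1:
            raise ValueError("window size and step must be >= 1")
        if self.step_variants > self.size_variants:
            raise ValueError("step must not exceed window size")


def iter_windows(
    n: int, spec: WindowSpec, include_trailing: bool = True
) -> list[tuple[int, int, bool]]:
    """(start, end_exclusive, is_partial) spans over ``n`` variants.

    Full windows start at 0, step, 2*step, ... while they fit; one trailing
    short window covers whatever the last full window leaves uncovered.
    """
    if n <= 0:
        return []
    out: list[tuple[int, int, bool]] = []
    start = 0
    while start + spec.size_variants <= n:
        out.append((start, start + spec.size_variants, False))
        start += spec.step_variants
    if include_trailing and (not out or out[-1][1] < n) and start < n:
        out.append((start, n, True))
    return out


def allele_counts(
    calls: GenotypeCalls, sample_index: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Missingness-aware per-variant allele counts (n called alleles, alt
    count) over the given samples."""
    dos = calls.dosage if sample_index is None else calls.dosage[sample_index]
    if dos.shape[0] == 0:
        raise ValueError("empty sample subset")
    called = dos != MISSING
    n = 2 * called.sum(axis=0)
    a = np.where(called, dos, 0).sum(axis=0)
    return n.astype(np.int64), a.astype(np.int64)


def hudson_fst_sites(
    counts1: tuple[np.ndarray, np.ndarray], counts2: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Hudson numerator N and denominator D, plus the validity mask.

    With sample frequencies p_i = a_i/n_i:
      N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
      D = p1(1-p2) + p2(1-p1)
    A site contributes only when both populations have >= 2 called alleles.
    """
    n1, a1 = counts1
    n2, a2 = counts2
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, a1 / np.maximum(n1, 1), np.nan)
        p2 = np.where(n2 > 0, a2 / np.maximum(n2, 1), np.nan)
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(valid, num, 0.0)
    den = np.where(valid, den, 0.0)
    return num, den, valid


def _window_frame(
    variants: pd.DataFrame, spans: list[tuple[int, int, bool]], values, extra=None
) -> pd.DataFrame:
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].to_numpy()
    rows = {
        "chrom": [chrom[s] for s, e, _ in spans],
        "start_idx": [s for s, e, _ in spans],
        "end_idx": [e - 1 for s, e, _ in spans],
        "start_bp": [int(pos[s]) for s, e, _ in spans],
        "end_bp": [int(pos[e - 1]) for s, e, _ in spans],
        "n_variants": [e - s for s, e, _ in spans],
        "partial": [p for _, _, p in spans],
        "value": values,
    }
    df = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def _window_ratio(num: np.ndarray, den: np.ndarray, spans) -> np.ndarray:
    """Ratio-of-sums per window; NaN where the summed denominator is zero."""
    cnum = np.concatenate([[0.0], np.cumsum(num)])
    cden = np.concatenate([[0.0], np.cumsum(den)])
    out = np.empty(len(spans))
    for i, (s, e, _) in enumerate(spans):
        d = cden[e] - cden[s]
        out[i] = (cnum[e] - cnum[s]) / d if d != 0 else np.nan
    return out


def hudson_fst_windows(
    variants: pd.DataFrame,
    counts1: tuple[np.ndarray, np.ndarray],
    counts2: tuple[np.ndarray, np.ndarray],
    window: WindowSpec,
    include_trailing: bool = True,
) -> pd.DataFrame:
    """Windowed Hudson FST as the ratio of summed numerators to summed
    denominators over contributing sites (ratio of averages)."""
    num, den, valid = hudson_fst_sites(counts1, counts2)
    spans = iter_windows(len(variants), window, include_trailing)
    values = _window_ratio(num, den, spans)
    cval = np.concatenate([[0], np.cumsum(valid)])
    used = [int(cval[e] - cval[s]) for s, e, _ in spans]
    df = _window_frame(variants, spans, values, extra={"n_used": used})
    return df


def pbs_from_fst(fst_focal_c1, fst_focal_c2, fst_c1_c2, eps: float = 1e-6):
    """PBS from the three pairwise FST values.

    T_xy = -ln(1 - FST_xy), FST clipped below 1 - eps (negative values pass
    through unclipped); PBS = (T_f,c1 + T_f,c2 - T_c1,c2) / 2.
    """
    def branch(f):
        return -np.log(1.0 - np.minimum(f, 1.0 - eps))

    return (branch(fst_focal_c1) + branch(fst_focal_c2) - branch(fst_c1_c2)) / 2.0


def pbs_windows(
    variants: pd.DataFrame,
    counts_focal: tuple[np.ndarray, np.ndarray],
    counts_c1: tuple[np.ndarray, np.ndarray],
    counts_c2: tuple[np.ndarray, np.ndarray],
    window: WindowSpec,
    include_trailing: bool = True,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Windowed population branch statistic for the focal population.

    Per window, with T_xy = -ln(1 - FST_xy) and FST clipped below 1 - eps
    (negative FST passes through the log unclipped):
      PBS = (T_f,c1 + T_f,c2 - T_c1,c2) / 2
    Elevated values mark focal-specific allele-frequency change.  Windows
    where any pairwise FST is undefined are NaN.
    """
    spans = iter_windows(len(variants), window, include_trailing)
    pair_values = {}
    for key, (ca, cb) in {
        "fst_focal_c1": (counts_focal, counts_c1),
        "fst_focal_c2": (counts_focal, counts_c2),
        "fst_c1_c2": (counts_c1, counts_c2),
    }.items():
        num, den, _ = hudson_fst_sites(ca, cb)
        pair_values[key] = _window_ratio(num, den, spans)

    def branch(f):
        return -np.log(1.0 - np.minimum(f, 1.0 - eps))

    t_f1 = branch(pair_values["fst_focal_c1"])
    t_f2 = branch(pair_values["fst_focal_c2"])
    t_12 = branch(pair_values["fst_c1_c2"])
    pbs = pbs_from_fst(
        pair_values["fst_focal_c1"], pair_values["fst_focal_c2"],
        pair_values["fst_c1_c2"], eps,
    )
    return _window_frame(
        variants,
        spans,
        pbs,
        extra={
            "fst_focal_c1": pair_values["fst_focal_c1"],
            "fst_focal_c2": pair_values["fst_focal_c2"],
            "fst_c1_c2": pair_values["fst_c1_c2"],
            "t_focal_c1": t_f1,
            "t_focal_c2": t_f2,
            "t_c1_c2": t_12,
        },
    )


def windowed_heterozygosity(
    calls: GenotypeCalls,
    sample_index: np.ndarray,
    variants: pd.DataFrame,
    window: WindowSpec,
    include_trailing: bool = True,
) -> pd.DataFrame:
    """Observed heterozygosity per window: heterozygous calls divided by
    non-missing calls over all samples x sites in the window."""
    dos = calls.dosage[sample_index]
    if dos.shape[0] == 0:
        raise ValueError("empty sample subset")
    het = (dos == 1).sum(axis=0).astype(float)
    called = (dos != MISSING).sum(axis=0).astype(float)
    spans = iter_windows(len(variants), window, include_trailing)
    values = _window_ratio(het, called, spans)
    return _window_frame(variants, spans, values)


def expected_heterozygosity_windows(
    calls: GenotypeCalls,
    sample_index: np.ndarray,
    variants: pd.DataFrame,
    window: WindowSpec,
    include_trailing: bool = True,
) -> pd.DataFrame:
    """Expected heterozygosity (2p(1-p) per site, averaged over called sites
    in the window) — the alternative definition, offered behind this
    function rather than a flag."""
    n, a = allele_counts(calls, sample_index)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, a / np.maximum(n, 1), np.nan)
    he = np.where(n > 0, 2 * p * (1 - p), 0.0)
    contributes = (n > 0).astype(float)
    spans = iter_windows(len(variants), window, include_trailing)
    values = _window_ratio(he, contributes, spans)
    return _window_frame(variants, spans, values)


@dataclass
class PiResult:
    """pixy-style nucleotide diversity over a region."""

    pi: float
    n_sites: int  # sites contributing comparisons (>= 2 called alleles)
    diffs: float  # summed pairwise differences
    comps: float  # summed pairwise comparisons


def pixy_pi(
    calls: GenotypeCalls,
    sample_index: np.ndarray,
    variants: pd.DataFrame,
    chrom: str | None = None,
    start_bp: int | None = None,
    end_bp: int | None = None,
) -> PiResult:
    """Nucleotide diversity as summed pairwise differences over summed
    pairwise comparisons (ratio of sums), including invariant sites.

    Per site with n called alleles of which a are ALT: diffs = a(n-a),
    comps = n(n-1)/2.  Invariant sites contribute diffs = 0 with their full
    comps, which is what makes the estimate a per-site rate; sites with
    fewer than two called alleles contribute nothing.
    """
    sel = np.ones(len(variants), dtype=bool)
    if chrom is not None:
        sel &= (variants["chrom"] == chrom).to_numpy()
    pos = variants["pos"].to_numpy()
    if start_bp is not None:
        sel &= pos >= start_bp
    if end_bp is not None:
        sel &= pos <= end_bp
    if not sel.any():
        raise ValueError("region contains no sites")
    sub = calls.take_variants(np.where(sel)[0])
    n, a = allele_counts(sub, sample_index)
    diffs = a * (n - a)
    comps = n * (n - 1) // 2
    usable = n >= 2
    total_comps = float(comps[usable].sum())
    total_diffs = float(diffs[usable].sum())
    if total_comps == 0:
        return PiResult(pi=np.nan, n_sites=0, diffs=0.0, comps=0.0)
    return PiResult(
        pi=total_diffs / total_comps,
        n_sites=int(usable.sum()),
        diffs=total_diffs,
        comps=total_comps,
    )
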