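"""Genetic-structure utilities: LD pruning, genotype PCA, and the
small-sample group-contrast statistics (Fisher's exact test, Mann-Whitney U).

Admixture-style ancestry decomposition is not fitted here; instead an
externally produced ancestry-proportion table (sample x component) can be
compared between groups with ``compare_ancestry``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from gamescan.types import MISSING, GenotypeCalls
from gamescan.assoc import ld_r2  # noqa: F401  (re-exported pairing of the pair/matrix forms)


@dataclass(frozen=True)
class PruneSpec:
    """PLINK-style --indep-pairwise parameters (bp window, bp step, r^2)."""

    window_bp: int = 50_000
    step_bp: int = 10_000
    r2_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step must not exceed window")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2 threshold must be in (0, 1]")


def _maf(dosage_col: np.ndarray) -> float:
    ok = dosage_col != MISSING
    n = 2 * int(ok.sum())
    if n == 0:
        return 0.0
    a = int(dosage_col[ok].sum())
    return min(a, n - a) / n


def pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """All-pairs composite genotypic r^2 over co-called samples.

    ``dosage`` is (n_samples, n_variants); returns an (n_variants,
    n_variants) matrix, NaN for pairs with < 2 co-called samples or a
    monomorphic member.  Agrees with ``ld_r2`` pair by pair.
    """
    x = dosage.T.astype(np.float64)  # variants x samples
    c = (x != MISSING).astype(np.float64)
    xc = np.where(x == MISSING, 0.0, x)
    x2c = xc * xc
    n = c @ c.T
    sx = xc @ c.T  # sum of x_i over samples co-called with j
    sxx = x2c @ c.T
    sxy = xc @ xc.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * sxy - sx * sx.T
        var_i = n * sxx - sx**2
        var_j = var_i.T
        r2 = cov**2 / (var_i * var_j)
    r2[(n < 2) | (var_i <= 0) | (var_j <= 0)] = np.nan
    return r2


def ld_prune(
    calls: GenotypeCalls, variants: pd.DataFrame, spec: PruneSpec = PruneSpec()
) -> np.ndarray:
    """Greedy LD pruning over a sliding base-pair span.

    Every pair of still-kept variants closer than ``window_bp`` is examined
    in position order; when r^2 exceeds the threshold the member with the
    lower MAF is dropped (tie: the later position).  The sweep visits each
    anchor variant once, so the postcondition — no surviving pair within
    ``window_bp`` of each other exceeds the threshold — holds by
    construction regardless of ``step_bp`` (kept in the dataclass for interface
    parity with the usual window/step parameterisation).  Returns the
    sorted kept variant indices.
    """
    pos = variants["pos"].to_numpy()
    chroms = variants["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        if np.any(np.diff(pos[chroms == chrom]) <= 0):
            raise ValueError(f"variants must be position-sorted on {chrom}")
    kept = np.ones(len(variants), dtype=bool)
    mafs = np.array([_maf(calls.dosage[:, j]) for j in range(len(variants))])

    for chrom in dict.fromkeys(chroms):
        on = np.where(chroms == chrom)[0]
        cpos = pos[on]
        for x in range(len(on)):
            i = on[x]
            if not kept[i]:
                continue
            hi = np.searchsorted(cpos, cpos[x] + spec.window_bp, side="left")
            partners = [on[y] for y in range(x + 1, hi) if kept[on[y]]]
            if not partners:
                continue
            r2m = pairwise_r2(calls.dosage[:, [i] + partners])[0, 1:]
            for r2, j in zip(r2m, partners):
                if not kept[i]:
                    break  # anchor dropped mid-scan
                if not kept[j]:
                    continue
                if np.isfinite(r2) and r2 > spec.r2_threshold:
                    if mafs[i] < mafs[j]:
                        kept[i] = False
                    else:  # ties drop the later (j) position
                        kept[j] = False
    return np.where(kept)[0]


@dataclass
class PCAResult:
    """Genotype PCA: per-sample coordinates and the eigenvalue spectrum."""

    coords: np.ndarray  # (n_samples, n_components)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    n_variants_used: int


def pca(
    calls: GenotypeCalls,
    variant_index: np.ndarray | None = None,
    n_components: int = 10,
) -> PCAResult:
    """PCA of the standardised genotype matrix.

    Missing dosages are imputed to the variant mean; each variant is centred
    by 2p and scaled by sqrt(2p(1-p)) (the usual allele-frequency
    standardisation), monomorphic variants are dropped, and the
    sample x sample covariance is eigendecomposed.  Coordinates are
    eigenvectors scaled by sqrt(eigenvalue), with each axis oriented so its
    largest-magnitude coordinate is positive.
    """
    dos = calls.dosage.astype(float)
    if variant_index is not None:
        dos = dos[:, variant_index]
    dos[dos == MISSING] = np.nan
    mean = np.nanmean(dos, axis=0)
    p_hat = mean / 2.0
    poly = (p_hat > 0) & (p_hat < 1) & np.isfinite(p_hat)
    if poly.sum() < n_components:
        raise ValueError(
            f"only {int(poly.sum())} polymorphic variants for {n_components} components"
        )
    x = dos[:, poly]
    mean = mean[poly]
    scale = np.sqrt(2.0 * p_hat[poly] * (1.0 - p_hat[poly]))
    x = np.where(np.isnan(x), mean, x)
    x = (x - mean) / scale
    m = x.shape[1]
    cov = (x @ x.T) / m
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    k = n_components
    coords = evecs[:, :k] * np.sqrt(evals[:k])[None, :]
    for c in range(k):
        if coords[np.argmax(np.abs(coords[:, c])), c] < 0:
            coords[:, c] = -coords[:, c]
    return PCAResult(coords=coords, eigenvalues=evals, n_variants_used=m)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table: the sum of
    hypergeometric probabilities no larger than that of the observed table.
    A zero margin makes every table equally (un)informative: p = 1, with a
    warning."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum()) - n_a * (n_a + 1) / 2.0


def mann_whitney_u(
    values_a, values_b, exact_product_limit: int = 400
) -> tuple[float, float]:
    """Mann-Whitney U with midranks for ties.

    Exact two-sided p by the full permutation distribution (dynamic
    programming over rank sums, valid under ties) when
    n_A * n_B <= ``exact_product_limit``; otherwise the tie-corrected normal
    approximation without continuity correction.  Returns (U_A, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = _u_from_ranks(ranks[:n_a], n_a)
    if np.ptp(pooled) == 0:
        return u, 1.0

    if n_a * n_b <= exact_product_limit:
        p = _exact_mwu_p(ranks, n_a)
        return u, p

    # tie-corrected normal approximation
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u, 1.0
    z = (u - mu) / np.sqrt(sigma2)
    return u, float(2.0 * stats.norm.sf(abs(z)))


def _exact_mwu_p(ranks: np.ndarray, n_a: int) -> float:
    """Exact two-sided p over all C(n, n_a) label allocations.

    Midranks are multiples of 1/2, so doubling makes them integers and the
    count of size-j subsets by rank sum follows a subset-sum DP; two-sided
    p sums the allocations at least as far from the U mean as observed.
    """
    r2 = np.round(ranks * 2).astype(np.int64)
    n = len(r2)
    total = int(r2.sum())
    # ways[j][s]: subsets of size j with doubled-rank sum s
    max_s = total
    ways = np.zeros((n_a + 1, max_s + 1), dtype=np.float64)
    ways[0, 0] = 1.0
    for r in r2:
        upper = min(n_a, n_a)  # size cap
        for j in range(upper - 1, -1, -1):
            row = ways[j]
            nz = np.nonzero(row)[0]
            if nz.size:
                ways[j + 1, nz + r] += row[nz]
    sums = np.nonzero(ways[n_a])[0]
    weights = ways[n_a][sums]
    # U is linear in the group-A rank sum
    u_vals = sums / 2.0 - n_a * (n_a + 1) / 2.0
    n_b = n - n_a
    mu = n_a * n_b / 2.0
    u_obs = _u_from_ranks(ranks[:n_a], n_a)
    dev = np.abs(u_vals - mu)
    obs_dev = abs(u_obs - mu)
    p = weights[dev >= obs_dev - 1e-9].sum() / weights.sum()
    return float(p)


def compare_ancestry(
    q_table: pd.DataFrame,
    samples: pd.DataFrame,
    component: str,
    group_a: str = "gamecock",
    group_b: str = "nongame",
) -> dict:
    """Contrast one ancestry component between two phenotype groups.

    ``q_table`` is a sample x component proportion table (index or
    'sample_id' column = sample id).  Returns the two group medians and the
    Mann-Whitney result, the standard way an admixture component is compared
    between cohorts.
    """
    q = q_table.set_index("sample_id") if "sample_id" in q_table.columns else q_table
    merged = samples.join(q, on="sample_id")
    if component not in merged.columns:
        raise ValueError(f"component {component!r} not in ancestry table")
    a = merged.loc[merged["group"] == group_a, component].dropna().to_numpy()
    b = merged.loc[merged["group"] == group_b, component].dropna().to_numpy()
    u, p = mann_whitney_u(a, b)
    return {
        "component": component,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "u": u,
        "p": p,
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
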