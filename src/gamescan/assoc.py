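"""Cluster-stratified case/control association.

The chain of operations that maps gamecock status while controlling for
population structure: identity-by-state distances -> complete-linkage
clustering into K strata -> Cochran-Mantel-Haenszel 1-df chi-square on
allele-count tables replicated across strata -> genomic-control correction
by the inflation factor lambda -> within-cluster permutation significance.

K itself is chosen by the data: the K with the smallest lambda wins, ties
going to the clustering that leaves more samples in informative strata
(strata containing both cases and controls are the only ones that contribute
to the CMH statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist

from gamescan.types import MISSING, GenotypeCalls

#: Median of the chi-squared distribution with 1 df.
CHI2_1DF_MEDIAN = 0.4549364231


def ibs_distance(calls: GenotypeCalls, sample_index: np.ndarray | None = None) -> np.ndarray:
    """Pairwise identity-by-state distance matrix.

    Per co-called site the IBS share is 1 - |dosage_i - dosage_j| / 2 (1 for
    identical genotypes, 1/2 for one shared allele, 0 for opposite
    homozygotes); the distance is one minus the mean share.  A pair with no
    co-called site has no defined distance and raises.
    """
    dos = calls.dosage if sample_index is None else calls.dosage[sample_index]
    n = dos.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    called = (dos != MISSING).astype(np.float64)
    # sum over co-called sites of |d_i - d_j| via dosage-class indicators
    g = [((dos == k) & (dos != MISSING)).astype(np.float64) for k in (0, 1, 2)]
    co = called @ called.T
    absdiff = (
        g[0] @ g[1].T
        + g[1] @ g[0].T
        + g[1] @ g[2].T
        + g[2] @ g[1].T
        + 2.0 * (g[0] @ g[2].T + g[2] @ g[0].T)
    )
    off = ~np.eye(n, dtype=bool)
    if np.any(co[off] == 0):
        i, j = np.argwhere((co == 0) & off)[0]
        raise ValueError(f"samples {i} and {j} share no co-called site")
    with np.errstate(invalid="ignore"):
        dist = absdiff / (2.0 * np.maximum(co, 1))
    np.fill_diagonal(dist, 0.0)
    return dist


def complete_linkage(dist: np.ndarray, k: int) -> np.ndarray:
    """Cut a complete-linkage agglomerative tree at K clusters.

    Returns cluster ids 1..K, relabelled by first appearance so the output
    is deterministic for a given distance matrix.
    """
    n = dist.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"K must be in [1, {n}]")
    if k == n:
        return np.arange(1, n + 1)
    z = linkage(squareform(dist, checks=False), method="complete")
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out = np.empty(n, dtype=np.int64)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[i] = relabel[c]
    return out


def informative_samples(assignment: np.ndarray, case_mask: np.ndarray) -> int:
    """Number of samples sitting in strata that contain both cases and
    controls — the samples that actually contribute to the CMH statistic."""
    total = 0
    for c in np.unique(assignment):
        members = assignment == c
        n_case = int((case_mask & members).sum())
        if 0 < n_case < int(members.sum()):
            total += int(members.sum())
    return total


def cmh_test(tables: np.ndarray) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel 1-df chi-square for K stacked 2x2 tables.

    ``tables`` has shape (K, 2, 2): rows case/control, columns alt/ref
    allele counts.  With a_k the case-alt cell, row margins n1k/n2k, column
    margins m1k/m2k and total T_k:

      chi2 = (sum_k (a_k - E_k))^2 / sum_k V_k,
      E_k = n1k m1k / T_k,   V_k = n1k n2k m1k m2k / (T_k^2 (T_k - 1))

    No continuity correction.  Strata with T_k <= 1 or a zero margin
    contribute nothing; if no stratum contributes the result is (nan, nan).
    """
    t = np.asarray(tables, dtype=np.float64)
    if t.ndim == 2:
        t = t[None]
    if t.shape[1:] != (2, 2):
        raise ValueError("tables must have shape (K, 2, 2)")
    a = t[:, 0, 0]
    n1 = t[:, 0].sum(axis=1)
    n2 = t[:, 1].sum(axis=1)
    m1 = t[:, :, 0].sum(axis=1)
    m2 = t[:, :, 1].sum(axis=1)
    tt = n1 + n2
    ok = (tt > 1) & (n1 > 0) & (n2 > 0) & (m1 > 0) & (m2 > 0)
    if not ok.any():
        return float("nan"), float("nan")
    e = n1[ok] * m1[ok] / tt[ok]
    v = n1[ok] * n2[ok] * m1[ok] * m2[ok] / (tt[ok] ** 2 * (tt[ok] - 1.0))
    num = float((a[ok] - e).sum()) ** 2
    den = float(v.sum())
    if den == 0:
        return float("nan"), float("nan")
    chi2 = num / den
    return chi2, float(chi2_dist.sf(chi2, 1))


def _stratum_arrays(dos: np.ndarray):
    """Per-variant called-allele and alt-allele counts usable for vectorised
    CMH: returns (called2, alt) with missing calls contributing zero."""
    called2 = 2.0 * (dos != MISSING)
    alt = np.where(dos != MISSING, dos, 0).astype(np.float64)
    return called2, alt


def cmh_from_calls(
    calls: GenotypeCalls,
    case_mask: np.ndarray,
    strata: np.ndarray,
    variant_index: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-variant CMH over allele-count tables built from the
    genotype matrix (2 alleles per called diploid genotype).

    Returns (chi2, p) arrays; variants where no stratum contributes are NaN.
    """
    dos = calls.dosage
    if variant_index is not None:
        dos = dos[:, variant_index]
    case_mask = np.asarray(case_mask, dtype=bool)
    num = np.zeros(dos.shape[1])
    den = np.zeros(dos.shape[1])
    for c in np.unique(strata):
        members = strata == c
        cases = members & case_mask
        controls = members & ~case_mask
        if not cases.any() or not controls.any():
            continue
        called2, alt = _stratum_arrays(dos[members])
        case_rows = case_mask[members]
        n1 = called2[case_rows].sum(axis=0)
        tt = called2.sum(axis=0)
        m1 = alt.sum(axis=0)
        a = alt[case_rows].sum(axis=0)
        ok = (tt > 1) & (n1 > 0) & (n1 < tt) & (m1 > 0) & (m1 < tt)
        e = np.where(ok, n1 * m1 / np.maximum(tt, 1), 0.0)
        v = np.where(
            ok,
            n1 * (tt - n1) * m1 * (tt - m1) / np.maximum(tt**2 * (tt - 1.0), 1.0),
            0.0,
        )
        num += np.where(ok, a - e, 0.0)
        den += v
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num**2 / np.maximum(den, 1e-300), np.nan)
    p = np.where(np.isfinite(chi2), chi2_dist.sf(np.nan_to_num(chi2), 1), np.nan)
    return chi2, p


def genomic_control(chi2: np.ndarray) -> tuple[float, np.ndarray]:
    """Genomic-control correction: lambda is the median chi-square over the
    chi-squared(1) median, floored at 1 (the correction never inflates
    significance); adjusted p-values come from chi2/lambda.
    """
    chi2 = np.asarray(chi2, dtype=float)
    finite = np.isfinite(chi2)
    if not finite.any():
        raise ValueError("no finite chi-square values")
    lam = max(1.0, float(np.median(chi2[finite])) / CHI2_1DF_MEDIAN)
    adj = chi2 / lam
    p_adj = np.where(np.isfinite(adj), chi2_dist.sf(np.nan_to_num(adj), 1), np.nan)
    return lam, p_adj


@dataclass
class SelectKResult:
    best_k: int
    table: pd.DataFrame  # columns: k, lam, informative_samples
    assignments: dict[int, np.ndarray]


def select_k(
    calls: GenotypeCalls,
    case_mask: np.ndarray,
    k_range,
    variant_index: np.ndarray | None = None,
    dist: np.ndarray | None = None,
    lambda_decimals: int = 2,
) -> SelectKResult:
    """Choose the number of IBS strata by genomic inflation.

    For each candidate K: cluster, run the CMH scan, compute lambda.  The
    winner minimises lambda; ties (lambda equal at ``lambda_decimals``
    places) go to the K keeping more samples in informative strata, then to
    the smaller K.  K values where lambda is undefined (no informative
    stratum, or no finite statistic) are excluded.
    """
    k_range = list(k_range)
    if len(k_range) < 2:
        raise ValueError("need at least two candidate K values")
    if dist is None:
        dist = ibs_distance(calls)
    rows = []
    assignments: dict[int, np.ndarray] = {}
    for k in k_range:
        assignment = complete_linkage(dist, k)
        assignments[k] = assignment
        info = informative_samples(assignment, case_mask)
        if info == 0:
            rows.append({"k": k, "lam": np.nan, "informative_samples": 0})
            continue
        chi2, _ = cmh_from_calls(calls, case_mask, assignment, variant_index)
        if not np.isfinite(chi2).any():
            rows.append({"k": k, "lam": np.nan, "informative_samples": info})
            continue
        lam, _ = genomic_control(chi2)
        rows.append({"k": k, "lam": lam, "informative_samples": info})
    table = pd.DataFrame(rows)
    best = choose_best_k(table, lambda_decimals)
    return SelectKResult(best_k=best, table=table, assignments=assignments)


def choose_best_k(table: pd.DataFrame, lambda_decimals: int = 2) -> int:
    """The K-selection rule on a (k, lam, informative_samples) table:
    smallest lambda wins; lambdas equal at ``lambda_decimals`` places are
    ties, broken by larger informative_samples, then by smaller K.
    Rows with undefined lambda are excluded."""
    defined = table.dropna(subset=["lam"])
    if defined.empty:
        raise ValueError("lambda undefined at every candidate K")
    key = defined.assign(lam_r=defined["lam"].round(lambda_decimals))
    key = key.sort_values(
        ["lam_r", "informative_samples", "k"], ascending=[True, False, True]
    )
    return int(key.iloc[0]["k"])


def permutation_p(
    calls: GenotypeCalls,
    case_mask: np.ndarray,
    strata: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    variant_index: np.ndarray | None = None,
    chunk: int = 2_000,
    max_t: bool = False,
    ties: str = "count",
) -> tuple[np.ndarray, np.ndarray]:
    """Within-cluster permutation p-values for the CMH scan.

    Phenotype labels are shuffled independently within each cluster,
    preserving per-cluster case counts, so the permutation null respects the
    stratification.  Add-one estimator:
    p = (1 + #{perm chi2 >= observed}) / (1 + n_perm), whose floor
    1/(n_perm+1) is just below the conventional 1e-4 threshold at
    n_perm = 10,000.  Returns (p, observed chi2).

    With ``max_t=False`` the comparison is pointwise (each variant against
    its own permutation distribution).  With ``max_t=True`` each variant is
    compared against the genome-wide maximum chi-square of every permutation
    (family-wise, PLINK mperm-style).  The pointwise p is exact per variant
    but, thresholded at 1e-4 across V variants, flags ~V/10001 null variants
    per scan by chance; only the family-wise form can leave an entire null
    genome unflagged, which is how a clean "nothing outside the peak"
    genome-wide readout arises.

    ``ties``: "count" (default) counts permutation statistics equal to the
    observed one as exceedances — the conventional, conservative estimator
    (valid: P(p <= a) <= a), noticeably super-uniform on discrete count data;
    "midp" gives ties half weight, which restores uniformity under the null
    and is the right choice for calibration diagnostics.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if ties not in ("count", "midp"):
        raise ValueError("ties must be 'count' or 'midp'")
    rng = np.random.default_rng(seed)
    dos = calls.dosage
    if variant_index is not None:
        dos = dos[:, variant_index]
    case_mask = np.asarray(case_mask, dtype=bool)
    n_var = dos.shape[1]

    # precompute per-stratum fixed quantities
    strata_data = []
    for c in np.unique(strata):
        members = np.where(strata == c)[0]
        n_case = int(case_mask[members].sum())
        if n_case == 0 or n_case == len(members):
            continue  # uninformative under every permutation
        called2, alt = _stratum_arrays(dos[members])
        tt = called2.sum(axis=0)
        m1 = alt.sum(axis=0)
        ok = (tt > 1) & (m1 > 0) & (m1 < tt)
        strata_data.append((members, n_case, called2, alt, tt, m1, ok))
    if not strata_data:
        raise ValueError("no informative stratum")

    def chi2_for(case_rows_by_stratum) -> np.ndarray:
        """case_rows_by_stratum: list of (n_reps, m_k) boolean matrices."""
        reps = case_rows_by_stratum[0].shape[0]
        num = np.zeros((reps, n_var))
        den = np.zeros((reps, n_var))
        for (members, n_case, called2, alt, tt, m1, ok), p_k in zip(
            strata_data, case_rows_by_stratum
        ):
            pk = p_k.astype(np.float64)
            n1 = pk @ called2
            a = pk @ alt
            okk = ok[None, :] & (n1 > 0) & (n1 < tt[None, :])
            e = np.where(okk, n1 * m1[None, :] / np.maximum(tt, 1)[None, :], 0.0)
            v = np.where(
                okk,
                n1
                * (tt[None, :] - n1)
                * m1[None, :]
                * (tt[None, :] - m1[None, :])
                / np.maximum(tt**2 * (tt - 1.0), 1.0)[None, :],
                0.0,
            )
            num += np.where(okk, a - e, 0.0)
            den += v
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, num**2 / np.maximum(den, 1e-300), np.nan)

    obs = chi2_for(
        [case_mask[members][None, :] for (members, *_rest) in strata_data]
    )[0]

    greater = np.zeros(n_var, dtype=np.int64)
    equal = np.zeros(n_var, dtype=np.int64)
    done = 0
    while done < n_perm:
        reps = min(chunk, n_perm - done)
        perm_rows = []
        for members, n_case, *_rest in strata_data:
            keys = rng.random((reps, len(members)))
            sel = np.argpartition(keys, n_case - 1, axis=1)[:, :n_case]
            pk = np.zeros((reps, len(members)), dtype=bool)
            np.put_along_axis(pk, sel, True, axis=1)
            perm_rows.append(pk)
        perm_chi2 = chi2_for(perm_rows)
        if max_t:
            perm_stat = np.nanmax(perm_chi2, axis=1)[:, None]
        else:
            perm_stat = perm_chi2
        with np.errstate(invalid="ignore"):
            greater += np.nansum(perm_stat > obs[None, :] + 1e-12, axis=0).astype(np.int64)
            equal += np.nansum(
                np.abs(perm_stat - obs[None, :]) <= 1e-12, axis=0
            ).astype(np.int64)
        done += reps
    tie_weight = 1.0 if ties == "count" else 0.5
    p = (1.0 + greater + tie_weight * equal) / (1.0 + n_perm)
    p = np.where(np.isfinite(obs), p, np.nan)
    return p, obs


def ld_r2(dosages_i: np.ndarray, dosages_j: np.ndarray) -> float:
    """Composite genotypic LD: squared Pearson correlation of the two dosage
    vectors over co-called samples.  NaN when fewer than two samples are
    co-called or either variant is monomorphic among them."""
    x = np.asarray(dosages_i, dtype=float)
    y = np.asarray(dosages_j, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def group_allele_frequencies(
    calls: GenotypeCalls, samples: pd.DataFrame, by: str = "group"
) -> pd.DataFrame:
    """ALT-allele frequency per variant per group, over non-missing alleles.

    NaN where a group has zero called alleles at a site.
    """
    out = {}
    for value, sub in samples.groupby(by, sort=False):
        idx = sub.index.to_numpy()
        dos = calls.dosage[idx]
        called = dos != MISSING
        n = 2 * called.sum(axis=0)
        a = np.where(called, dos, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[value] = np.where(n > 0, a / np.maximum(n, 1), np.nan)
    return pd.DataFrame(out)
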