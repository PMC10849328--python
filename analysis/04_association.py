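#!/usr/bin/env python
"""Cluster-stratified association scan on the filtered cohort.

On the MAF>=5% set: IBS distances -> complete-linkage clustering with K
chosen by genomic inflation (ties to the K keeping more samples in
informative strata) -> CMH test within clusters -> genomic control ->
10,000 within-cluster permutations, flagging variants whose family-wise
(max-T) permutation p falls below 1e-4.

Writes results/assoc/{lambda_by_k.tsv,assoc.tsv} and prints the top hit.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import gamescan as gs
from gamescan import filters as filt
from gamescan.assoc import cmh_from_calls, genomic_control, group_allele_frequencies, permutation_p, select_k

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20230902


def main() -> None:
    out = ROOT / "assoc"
    out.mkdir(parents=True, exist_ok=True)
    sheet = gs.read_sample_sheet(ROOT / "cohort" / "samples.tsv")
    samples, variants, calls = gs.read_vcf(ROOT / "filtered" / "filtered.vcf", sheet)

    poly = (variants["alt"] != ".").to_numpy()
    maf = np.where(filt.frequency_filters(calls, "maf") & poly)[0]
    av = variants.iloc[maf].reset_index(drop=True)
    ac = calls.take_variants(maf)
    case = (samples["group"] == "gamecock").to_numpy()

    sel = select_k(ac, case, range(1, 6))
    sel.table.to_csv(out / "lambda_by_k.tsv", sep="\t", index=False)
    print("lambda by K:")
    print(sel.table.round(3).to_string(index=False))
    print(f"chosen K = {sel.best_k}")

    strata = sel.assignments[sel.best_k]
    chi2, p_raw = cmh_from_calls(ac, case, strata)
    lam, p_gc = genomic_control(chi2)
    p_perm, _ = permutation_p(ac, case, strata, n_perm=10_000, seed=SEED, max_t=True)
    freqs = group_allele_frequencies(ac, samples)

    df = pd.DataFrame({
        "chrom": av["chrom"], "pos": av["pos"], "ref": av["ref"], "alt": av["alt"],
        "freq_case": freqs["gamecock"], "freq_control": freqs["nongame"],
        "chi2": chi2, "p_raw": p_raw, "lambda": lam, "p_gc": p_gc,
        "p_perm": p_perm, "significant": p_perm < 1e-4,
    })
    df.to_csv(out / "assoc.tsv", sep="\t", index=False)

    top = df.loc[df["p_gc"].idxmin()]
    sig = df[df["significant"]]
    print(f"genomic control lambda = {lam:.3f}")
    print(f"top hit: {top.chrom}:{top.pos:,} p_gc={top.p_gc:.3g} "
          f"freq {top.freq_case:.3f} (game) vs {top.freq_control:.3f} (nongame)")
    print(f"{len(sig)} variants pass the family-wise permutation threshold; "
          f"span {sig.pos.min():,}-{sig.pos.max():,} bp" if len(sig) else
          "no variant passes the permutation threshold")


if __name__ == "__main__":
    main()
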