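#!/usr/bin/env python
"""Windowed selection scans on the filtered cohort.

Computes, on the MAC>=1 variant set: the population branch statistic with
Japanese gamecocks as the focal population (Japanese and Ethiopian nongame
chickens as contrasts), Hudson FST between all gamecocks and all nongame
birds, observed-heterozygosity tracks per cohort, and pixy-style nucleotide
diversity (invariant-site aware) inside the swept block for each cohort.

Writes results/scans/*.tsv and prints where each statistic peaks relative
to the selected locus.
"""

from pathlib import Path

import numpy as np

import gamescan as gs
from gamescan import filters as filt
from gamescan.scans import WindowSpec, allele_counts, hudson_fst_windows, pbs_windows, pixy_pi, windowed_heterozygosity

ROOT = Path(__file__).resolve().parent.parent / "results"
LOCUS_BP = 1_000_000
BLOCK = (950_000, 1_050_000)


def subset(samples, population=None, group=None):
    sel = np.ones(len(samples), dtype=bool)
    if population:
        sel &= (samples["population"] == population).to_numpy()
    if group:
        sel &= (samples["group"] == group).to_numpy()
    return np.where(sel)[0]


def main() -> None:
    out = ROOT / "scans"
    out.mkdir(parents=True, exist_ok=True)
    sheet = gs.read_sample_sheet(ROOT / "cohort" / "samples.tsv")
    samples, variants, calls = gs.read_vcf(ROOT / "filtered" / "filtered.vcf", sheet)

    poly = (variants["alt"] != ".").to_numpy()
    mac = np.where(filt.frequency_filters(calls, "mac") & poly)[0]
    sv = variants.iloc[mac].reset_index(drop=True)
    sc = calls.take_variants(mac)
    w = WindowSpec(50, 10)

    pbs = pbs_windows(
        sv,
        allele_counts(sc, subset(samples, "japan", "gamecock")),
        allele_counts(sc, subset(samples, "japan", "nongame")),
        allele_counts(sc, subset(samples, "ethiopia", "nongame")),
        w,
    )
    pbs.to_csv(out / "pbs_windows.tsv", sep="\t", index=False)
    top = pbs.loc[pbs["value"].idxmax()]
    print(f"top PBS window: {top.start_bp:,}-{top.end_bp:,} bp "
          f"(PBS={top.value:.3f}); selected locus at {LOCUS_BP:,} bp "
          f"{'inside' if top.start_bp <= LOCUS_BP <= top.end_bp else 'OUTSIDE'}")

    game, nong = subset(samples, None, "gamecock"), subset(samples, None, "nongame")
    fst = hudson_fst_windows(sv, allele_counts(sc, game), allele_counts(sc, nong), w)
    fst.to_csv(out / "fst_windows.tsv", sep="\t", index=False)

    for label, idx in (("gamecock", game), ("nongame", nong)):
        het = windowed_heterozygosity(sc, idx, sv, w)
        het.to_csv(out / f"het_{label}.tsv", sep="\t", index=False)
        m = het.loc[het["value"].idxmin()]
        print(f"{label} heterozygosity minimum: {m.start_bp:,}-{m.end_bp:,} bp "
              f"(H_obs={m.value:.4f})")

    rows = []
    for label, idx in (("gamecock", game), ("nongame", nong)):
        r = pixy_pi(calls, idx, variants, "chrS", *BLOCK)
        rows.append((label, r.pi, r.n_sites))
        print(f"pi in block ({label}): {r.pi:.4f} over {r.n_sites} usable sites")
    if rows[1][1] > 0:
        print(f"block diversity reduction in gamecocks: "
              f"{100 * (1 - rows[0][1] / rows[1][1]):.1f}%")
    with open(out / "pi_block.tsv", "w") as fh:
        fh.write("group\tpi\tn_sites\n")
        for label, pi, n in rows:
            fh.write(f"{label}\t{pi:.6g}\t{n}\n")


if __name__ == "__main__":
    main()
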