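"""End-to-end orchestration: simulate/load -> filter -> scan -> assoc -> structure.

One root seed drives every stochastic stage; the manifest records the seed,
per-stage record counts and sha256 checksums of every output, so a rerun
with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from gamescan import assoc as assoc_mod
from gamescan import filters as filt
from gamescan import scans, structure
from gamescan.sim import SimConfig, default_config, simulate_cohort
from gamescan.vcfio import read_bed_mask, read_sample_sheet, read_vcf, write_sample_sheet, write_vcf

log = logging.getLogger("gamescan")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``sim`` is set (synthetic cohort) or ``vcf_path`` + ``sheet_path``
    point at real inputs; ``mask_path`` is optional in both cases.
    """

    outdir: str = "gamescan_run"
    sim: SimConfig | None = None
    vcf_path: str | None = None
    sheet_path: str | None = None
    mask_path: str | None = None
    thresholds: filt.FilterThresholds = field(default_factory=filt.FilterThresholds)
    pbs_window: scans.WindowSpec = field(default_factory=lambda: scans.WindowSpec(50, 10))
    het_window: scans.WindowSpec = field(default_factory=lambda: scans.WindowSpec(50, 10))
    pbs_focal: tuple[str, str] = ("japan", "gamecock")
    pbs_c1: tuple[str, str] = ("japan", "nongame")
    pbs_c2: tuple[str, str] = ("ethiopia", "nongame")
    pi_region: tuple[str, int, int] | None = None  # (chrom, start_bp, end_bp)
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_perm: int = 10_000
    n_components: int = 5
    prune: structure.PruneSpec = field(default_factory=structure.PruneSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.sim is None and (self.vcf_path is None or self.sheet_path is None):
            raise ValueError("either sim or vcf_path+sheet_path must be given")
        for p in (self.vcf_path, self.sheet_path, self.mask_path):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _subset(samples: pd.DataFrame, population: str | None, group: str | None) -> np.ndarray:
    sel = np.ones(len(samples), dtype=bool)
    if population is not None:
        sel &= (samples["population"] == population).to_numpy()
    if group is not None:
        sel &= (samples["group"] == group).to_numpy()
    return np.where(sel)[0]


def _write_tsv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to the outdir).

    Stages: cohort acquisition, hard filtering + sample QC, windowed
    selection scans (FST / PBS / heterozygosity / pi), cluster-stratified
    CMH association with genomic control and permutations, LD pruning + PCA.
    A stage failure propagates with the stage named.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": {}}
    t_run = time.time()

    def stage(name):
        log.info("stage %s", name)
        return time.time()

    def done(name, t0, **counts):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **counts}

    # --- cohort ------------------------------------------------------------
    t0 = stage("cohort")
    try:
        if cfg.sim is not None:
            sim = cfg.sim.with_seed(cfg.seed)
            samples, variants, calls = simulate_cohort(sim)
            write_vcf(samples, variants, calls, outdir / "cohort.vcf")
            write_sample_sheet(samples, outdir / "samples.tsv")
            manifest["inputs"] = {"simulated": True}
        else:
            sheet = read_sample_sheet(cfg.sheet_path)
            samples, variants, calls = read_vcf(cfg.vcf_path, sheet)
            manifest["inputs"] = {
                "vcf": cfg.vcf_path,
                "vcf_sha256": _sha256(Path(cfg.vcf_path)),
            }
        mask = read_bed_mask(cfg.mask_path) if cfg.mask_path else None
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc
    done("cohort", t0, n_samples=len(samples), n_sites=len(variants))

    # --- filtering ---------------------------------------------------------
    t0 = stage("filter")
    try:
        depths = filt.mean_autosomal_depth(calls, variants)
        gcalls, call_report = filt.apply_genotype_filters(calls, cfg.thresholds, depths)
        kept_sites, site_report = filt.apply_site_filters(
            variants, gcalls, mask, cfg.thresholds
        )
        site_idx = np.where(kept_sites)[0]
        fvariants = variants.iloc[site_idx].reset_index(drop=True)
        fcalls = gcalls.take_variants(site_idx)
        qc = filt.sample_qc(fcalls, samples, cfg.thresholds)
        keep_samples = np.where((qc["verdict"] == "KEPT").to_numpy())[0]
        samples = samples.iloc[keep_samples].reset_index(drop=True)
        fcalls = fcalls.take_samples(keep_samples)
        report = filt.FilterReport(
            call_reasons=call_report.call_reasons,
            site_reasons=site_report.site_reasons,
        )
        _write_tsv(report.to_frame(), outdir / "filter_report.tsv",
                   "counts of calls masked / sites dropped per reason code")
        _write_tsv(qc, outdir / "sample_qc.tsv",
                   "per-sample QC: missing fraction, verdict, mito contamination flag")
        is_variant_site = (fvariants["alt"] != ".").to_numpy()
        mac_keep = filt.frequency_filters(fcalls, "mac", cfg.thresholds) & is_variant_site
        maf_keep = filt.frequency_filters(fcalls, "maf", cfg.thresholds) & is_variant_site
    except Exception as exc:
        raise RuntimeError(f"stage 'filter' failed: {exc}") from exc
    done(
        "filter",
        t0,
        n_samples_kept=len(samples),
        n_sites_kept=len(fvariants),
        n_mac1=int(mac_keep.sum()),
        n_maf05=int(maf_keep.sum()),
    )

    # --- selection scans ---------------------------------------------------
    t0 = stage("scan")
    try:
        mac_idx = np.where(mac_keep)[0]
        svariants = fvariants.iloc[mac_idx].reset_index(drop=True)
        scalls = fcalls.take_variants(mac_idx)

        focal = _subset(samples, *cfg.pbs_focal)
        c1 = _subset(samples, *cfg.pbs_c1)
        c2 = _subset(samples, *cfg.pbs_c2)
        pbs = scans.pbs_windows(
            svariants,
            scans.allele_counts(scalls, focal),
            scans.allele_counts(scalls, c1),
            scans.allele_counts(scalls, c2),
            cfg.pbs_window,
        )
        _write_tsv(pbs, outdir / "pbs_windows.tsv",
                   "PBS per variant-count window; focal="
                   f"{cfg.pbs_focal} c1={cfg.pbs_c1} c2={cfg.pbs_c2}; bp 1-based inclusive")

        game = _subset(samples, None, "gamecock")
        nong = _subset(samples, None, "nongame")
        het_game = scans.windowed_heterozygosity(scalls, game, svariants, cfg.het_window)
        het_nong = scans.windowed_heterozygosity(scalls, nong, svariants, cfg.het_window)
        _write_tsv(het_game, outdir / "het_gamecock.tsv",
                   "observed heterozygosity per window, gamecocks")
        _write_tsv(het_nong, outdir / "het_nongame.tsv",
                   "observed heterozygosity per window, nongame chickens")

        fst = scans.hudson_fst_windows(
            svariants,
            scans.allele_counts(scalls, game),
            scans.allele_counts(scalls, nong),
            cfg.pbs_window,
        )
        _write_tsv(fst, outdir / "fst_game_vs_nongame.tsv",
                   "Hudson FST (ratio of averages) per window, gamecock vs nongame")

        pi_rows = []
        if cfg.pi_region is not None:
            chrom, lo, hi = cfg.pi_region
            for label, idx in (("gamecock", game), ("nongame", nong)):
                r = scans.pixy_pi(fcalls, idx, fvariants, chrom, lo, hi)
                pi_rows.append(
                    {"group": label, "pi": r.pi, "n_sites": r.n_sites,
                     "diffs": r.diffs, "comps": r.comps}
                )
            _write_tsv(pd.DataFrame(pi_rows), outdir / "pi_region.tsv",
                       f"pixy-style nucleotide diversity in {chrom}:{lo}-{hi}")
    except Exception as exc:
        raise RuntimeError(f"stage 'scan' failed: {exc}") from exc
    done("scan", t0, n_pbs_windows=len(pbs), n_het_windows=len(het_game))

    # --- association -------------------------------------------------------
    t0 = stage("assoc")
    try:
        maf_idx = np.where(maf_keep)[0]
        avariants = fvariants.iloc[maf_idx].reset_index(drop=True)
        case_mask = (samples["group"] == "gamecock").to_numpy()
        ctrl_mask = (samples["group"] == "nongame").to_numpy()
        in_assoc = np.where(case_mask | ctrl_mask)[0]
        acalls = fcalls.take_samples(in_assoc).take_variants(maf_idx)
        acase = case_mask[in_assoc]

        dist = assoc_mod.ibs_distance(acalls)
        sel = assoc_mod.select_k(acalls, acase, cfg.k_range, dist=dist)
        _write_tsv(sel.table, outdir / "lambda_by_k.tsv",
                   "genomic inflation lambda and informative sample count per K")
        strata = sel.assignments[sel.best_k]
        pd.DataFrame(
            {"sample_id": samples["sample_id"].to_numpy()[in_assoc], "cluster": strata}
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

        chi2, p_raw = assoc_mod.cmh_from_calls(acalls, acase, strata)
        lam, p_gc = assoc_mod.genomic_control(chi2)
        p_perm, _ = assoc_mod.permutation_p(
            acalls, acase, strata, n_perm=cfg.n_perm, seed=cfg.seed + 1
        )
        freqs = assoc_mod.group_allele_frequencies(
            acalls, samples.iloc[in_assoc].reset_index(drop=True)
        )
        assoc_df = pd.DataFrame(
            {
                "chrom": avariants["chrom"],
                "pos": avariants["pos"],
                "ref": avariants["ref"],
                "alt": avariants["alt"],
                "freq_case": freqs.get("gamecock"),
                "freq_control": freqs.get("nongame"),
                "chi2": chi2,
                "p_raw": p_raw,
                "lambda": lam,
                "p_gc": p_gc,
                "p_perm": p_perm,
                "significant": p_perm < 1e-4,
            }
        )
        _write_tsv(assoc_df, outdir / "assoc.tsv",
                   f"CMH association at K={sel.best_k}; genomic control lambda={lam:.4g}; "
                   f"significant = permutation p < 1e-4 ({cfg.n_perm} permutations)")
    except Exception as exc:
        raise RuntimeError(f"stage 'assoc' failed: {exc}") from exc
    done("assoc", t0, best_k=sel.best_k, lam=round(lam, 4),
         n_significant=int(assoc_df["significant"].sum()))

    # --- structure ---------------------------------------------------------
    t0 = stage("structure")
    try:
        kept = structure.ld_prune(scalls, svariants, cfg.prune)
        pca_res = structure.pca(scalls, kept, n_components=cfg.n_components)
        coords = pd.DataFrame(
            pca_res.coords,
            columns=[f"PC{i + 1}" for i in range(pca_res.coords.shape[1])],
        )
        coords.insert(0, "sample_id", samples["sample_id"].to_numpy())
        coords.insert(1, "group", samples["group"].to_numpy())
        _write_tsv(coords, outdir / "pca.tsv",
                   f"PCA coordinates on {pca_res.n_variants_used} LD-pruned variants")
        np.savetxt(outdir / "pruned_variants.txt", kept, fmt="%d")
    except Exception as exc:
        raise RuntimeError(f"stage 'structure' failed: {exc}") from exc
    done("structure", t0, n_pruned=len(kept))

    manifest["outputs"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["total_seconds"] = round(time.time() - t_run, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
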