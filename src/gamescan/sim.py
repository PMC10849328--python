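"""Balding-Nichols cohort simulator.

Generates a diploid biallelic cohort with the statistical structure the
downstream analyses assume: several genetic demes drifted from a common
ancestor (Balding-Nichols Beta model, one drift coefficient F per deme),
one selected locus whose "game" allele sits at high frequency in gamecocks
and low frequency in nongame birds regardless of deme, an optional block of
variants linked to that locus, and realistic per-call read evidence
(Poisson DP, binomial AD, a monotone depth->GQ map) with random missingness.

The simulator is a stand-in: the study it emulates analysed real birds and
gives no generative model.  Its defaults mirror the real cohort's shape —
48 gamecocks vs 62 nongame chickens split across demes, a selected locus at
89.5% frequency in gamecocks and 3.7% in nongame chickens, ~12x mean depth.

Rows of ``SimConfig.populations`` that share a population label share one
Balding-Nichols frequency draw: a deme may contain both gamecock and nongame
rows, which is what makes the phenotype confounded with — but not identical
to — genetic structure, as in the real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from gamescan.types import MISSING, VARIANT_COLUMNS, GenotypeCalls

#: chi-squared(1) median; used nowhere here but re-exported for convenience.
_GROUPS = ("gamecock", "nongame", "outgroup")


@dataclass(frozen=True)
class PopulationSpec:
    """One cohort row: a phenotype group drawn from a genetic deme.

    ``label`` names the deme (rows sharing a label share allele frequencies);
    ``group`` is the phenotype class; ``drift_f`` is the Balding-Nichols F.
    """

    label: str
    group: str
    n_samples: int
    drift_f: float

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0.0 <= self.drift_f < 1.0):
            raise ValueError("drift_f must be in [0, 1)")

    @property
    def name(self) -> str:
        return f"{self.label}:{self.group}"


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one synthetic cohort."""

    n_variants: int = 2000
    n_invariant_sites: int = 0
    chrom_length_bp: int = 2_000_000
    populations: tuple[PopulationSpec, ...] = ()
    ancestral_freq_beta: tuple[float, float] = (0.8, 0.8)
    #: (bp position, game-allele freq in gamecocks, freq in nongame birds);
    #: None disables the selected locus.
    selected_locus: tuple[int, float, float] | None = None
    #: total bp width of the linked block centred on the selected locus;
    #: 0 disables linkage.
    haplotype_block_bp: int = 0
    missing_rate: float = 0.02
    mean_depth: float = 12.0
    #: GQ = min(gq_cap, round(gq_per_depth * DP)) — a crude monotone map.
    #: The slope is set so that at ~12x mean depth only genuinely low-depth
    #: calls (DP <= 4) fall under the GQ < 30 filter.
    gq_per_depth: float = 6.0
    gq_cap: int = 99
    #: homozygote reads on the other allele: Binomial(DP, error_read_rate).
    error_read_rate: float = 0.005
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_invariant_sites < 0:
            raise ValueError("n_invariant_sites must be >= 0")
        if not self.populations:
            raise ValueError("at least one population row required")
        a, b = self.ancestral_freq_beta
        if a <= 0 or b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.selected_locus is not None:
            pos, f_game, f_nongame = self.selected_locus
            if not (1 <= pos <= self.chrom_length_bp):
                raise ValueError("selected locus position outside chromosome")
            for f in (f_game, f_nongame):
                if not (0.0 <= f <= 1.0):
                    raise ValueError("selected-locus frequencies must be in [0, 1]")
            groups = {p.group for p in self.populations}
            if "gamecock" not in groups or "nongame" not in groups:
                raise ValueError(
                    "a selected locus requires both gamecock and nongame samples"
                )
        total_sites = self.n_variants + self.n_invariant_sites
        if total_sites > self.chrom_length_bp:
            raise ValueError("more sites than base pairs")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def default_config(**overrides) -> SimConfig:
    """The default study-shaped cohort.

    Three demes mirroring the real cohort's composition: a Japanese deme with
    both gamecocks (n=14) and nongame birds (n=19), a worldwide deme with
    gamecocks (n=34) and nongame birds (n=9), and an Ethiopian nongame deme
    (n=34) — 48 gamecocks vs 62 nongame chickens in total.  The selected
    locus sits mid-chromosome at frequencies 0.895 (gamecocks) / 0.037
    (nongame) inside a 100 kb linked block.
    """
    cfg = SimConfig(
        n_variants=2000,
        chrom_length_bp=2_000_000,
        populations=(
            PopulationSpec("japan", "gamecock", 14, 0.08),
            PopulationSpec("japan", "nongame", 19, 0.08),
            PopulationSpec("world", "gamecock", 34, 0.10),
            PopulationSpec("world", "nongame", 9, 0.10),
            PopulationSpec("ethiopia", "nongame", 34, 0.12),
        ),
        selected_locus=(1_000_000, 0.895, 0.037),
        haplotype_block_bp=100_000,
        missing_rate=0.02,
        mean_depth=12.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimFrequencies:
    """Per-population allele frequencies plus the site coordinates."""

    positions: np.ndarray  # 1-based bp, strictly increasing (variants only)
    freqs: pd.DataFrame  # n_variants x population rows (columns = row names)
    selected_index: int | None  # row in positions/freqs of the selected locus
    ancestral: np.ndarray | None = None  # ancestral frequency per variant


def _locus_freq_for_group(cfg: SimConfig, group: str) -> float:
    _, f_game, f_nongame = cfg.selected_locus
    # outgroup birds were never bred for fighting; give them the nongame freq
    return f_game if group == "gamecock" else f_nongame


def _draw_positions(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, int | None]:
    """Variant positions: uniform without replacement, sorted, with the
    selected locus forced onto its configured coordinate."""
    n = cfg.n_variants
    pos = rng.choice(cfg.chrom_length_bp, size=n, replace=False) + 1
    pos.sort()
    sel_idx: int | None = None
    if cfg.selected_locus is not None:
        target = cfg.selected_locus[0]
        # replace the nearest drawn position with the exact locus coordinate
        nearest = int(np.argmin(np.abs(pos - target)))
        pos = np.delete(pos, nearest)
        pos = np.unique(np.append(pos, target))
        sel_idx = int(np.searchsorted(pos, target))
    return pos.astype(np.int64), sel_idx


def simulate_frequencies(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimFrequencies:
    """Draw per-deme allele frequencies under the Balding-Nichols model.

    The ancestral frequency p of each variant is Beta(a, b); each deme's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance
    F p(1-p).  F = 0 copies the ancestral frequency exactly.  At the selected
    locus the frequency is overridden per population row by phenotype group.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    positions, sel_idx = _draw_positions(cfg, rng)
    n = len(positions)
    a, b = cfg.ancestral_freq_beta
    ancestral = rng.beta(a, b, size=n)

    deme_freqs: dict[str, np.ndarray] = {}
    # one draw per deme, keyed by label; F taken from the first row of the deme
    for pop in cfg.populations:
        if pop.label in deme_freqs:
            continue
        f = pop.drift_f
        if f == 0.0:
            deme_freqs[pop.label] = ancestral.copy()
        else:
            scale = (1.0 - f) / f
            alpha = np.clip(ancestral * scale, 1e-12, None)
            beta = np.clip((1.0 - ancestral) * scale, 1e-12, None)
            deme_freqs[pop.label] = rng.beta(alpha, beta)

    table = {}
    for pop in cfg.populations:
        col = deme_freqs[pop.label].copy()
        if sel_idx is not None:
            col[sel_idx] = _locus_freq_for_group(cfg, pop.group)
        table[pop.name] = col
    freqs = pd.DataFrame(table)
    return SimFrequencies(
        positions=positions, freqs=freqs, selected_index=sel_idx, ancestral=ancestral
    )


def _block_weights(
    cfg: SimConfig, positions: np.ndarray, sel_idx: int
) -> np.ndarray:
    """Linkage weight per variant: 1 at the locus, decaying linearly to 0 at
    the block edge (half-width = haplotype_block_bp / 2)."""
    w = np.zeros(len(positions))
    if cfg.haplotype_block_bp <= 0:
        w[sel_idx] = 1.0
        return w
    half = cfg.haplotype_block_bp / 2.0
    dist = np.abs(positions - positions[sel_idx])
    inside = dist < half
    w[inside] = 1.0 - dist[inside] / half
    return w


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeCalls]:
    """Simulate a full cohort: sample sheet, variant table, genotype calls.

    Dosages are Binomial(2, deme frequency) per sample, except inside the
    linked block where each haplotype copies the selected-locus allele with
    probability equal to the linkage weight.  DP ~ Poisson(mean_depth); AD
    splits the reads Binomial(DP, 1/2) for hets while homozygotes put all
    reads on the carried allele apart from Binomial(DP, error_read_rate)
    error reads; GQ = min(cap, round(gq_per_depth * DP)); calls are masked
    MISSING independently at ``missing_rate``.  Output is a pure function of
    the config (same seed, same arrays).
    """
    rng = np.random.default_rng(cfg.seed)
    sf = simulate_frequencies(cfg, rng)
    positions, sel_idx = sf.positions, sf.selected_index
    n_var = len(positions)

    # --- sample sheet ------------------------------------------------------
    rows = []
    for pop in cfg.populations:
        tag = {"gamecock": "game", "nongame": "ngam", "outgroup": "outg"}[pop.group]
        for i in range(pop.n_samples):
            rows.append(
                {
                    "sample_id": f"{pop.label}_{tag}{i:03d}",
                    "group": pop.group,
                    "population": pop.label,
                }
            )
    samples = pd.DataFrame(rows)
    n_samp = len(samples)

    # --- dosages -----------------------------------------------------------
    # Inside the linked block the model is a soft sweep on one ancestral
    # "game" haplotype h*: every haplotype carrying the game (ALT) allele at
    # the locus copies h* at a linked variant with probability equal to the
    # linkage weight, so gamecocks — where the game allele is near fixation —
    # are close to monomorphic for h* across the block (low diversity, high
    # LD with the locus), while nongame birds mostly carry background
    # haplotypes.  This mirrors a selected haplotype of common origin.
    dosage = np.empty((n_samp, n_var), dtype=np.int8)
    row_of_sample = np.repeat(np.arange(len(cfg.populations)), [p.n_samples for p in cfg.populations])
    freq_mat = sf.freqs.to_numpy()  # n_var x n_pop_rows
    if sel_idx is not None:
        w = _block_weights(cfg, positions, sel_idx)
        swept_hap = rng.random(n_var) < sf.ancestral
        swept_hap[sel_idx] = True  # the game haplotype carries the game allele
    for r, pop in enumerate(cfg.populations):
        idx = np.where(row_of_sample == r)[0]
        p = freq_mat[:, r]
        if sel_idx is None:
            dosage[idx, :] = rng.binomial(2, p, size=(len(idx), n_var))
        else:
            p_loc = p[sel_idx]
            carries_game = rng.random((len(idx), 2)) < p_loc
            haps = rng.random((len(idx), 2, n_var)) < p[None, None, :]
            copy_mask = (
                (rng.random((len(idx), 2, n_var)) < w[None, None, :])
                & carries_game[:, :, None]
            )
            haps = np.where(copy_mask, swept_hap[None, None, :], haps)
            haps[:, :, sel_idx] = carries_game
            dosage[idx, :] = haps.sum(axis=1).astype(np.int8)

    # --- read evidence -----------------------------------------------------
    dp = rng.poisson(cfg.mean_depth, size=(n_samp, n_var)).astype(np.int32)
    alt_reads = np.empty_like(dp)
    het = dosage == 1
    hom_ref = dosage == 0
    hom_alt = dosage == 2
    alt_reads[het] = rng.binomial(dp[het], 0.5)
    alt_reads[hom_ref] = rng.binomial(dp[hom_ref], cfg.error_read_rate)
    err_on_ref = rng.binomial(dp[hom_alt], cfg.error_read_rate)
    alt_reads[hom_alt] = dp[hom_alt] - err_on_ref
    ad = np.stack([dp - alt_reads, alt_reads], axis=2).astype(np.int32)
    gq = np.minimum(cfg.gq_cap, np.round(cfg.gq_per_depth * dp)).astype(np.int16)

    if cfg.missing_rate > 0:
        miss = rng.random((n_samp, n_var)) < cfg.missing_rate
        dosage[miss] = MISSING
        dp[miss] = 0
        ad[miss] = 0
        gq[miss] = 0

    # --- variant table (invariant sites interleaved) -----------------------
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_var)]
    alt = np.array([bases[(bases != r)][rng.integers(0, 3)] for r in ref])
    variants = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "mq": np.round(np.clip(rng.normal(58.0, 1.5, size=n_var), 30.0, 60.0), 2),
            "mq0f": np.round(rng.beta(0.5, 200.0, size=n_var), 4),
            "indel_distance": np.inf,
            "is_indel": False,
            "is_multiallelic": False,
        }
    )

    if cfg.n_invariant_sites > 0:
        free = np.setdiff1d(
            rng.choice(cfg.chrom_length_bp, size=min(cfg.chrom_length_bp, 4 * cfg.n_invariant_sites + n_var), replace=False) + 1,
            positions,
        )
        inv_pos = np.sort(rng.choice(free, size=cfg.n_invariant_sites, replace=False))
        inv = pd.DataFrame(
            {
                "chrom": cfg.chrom,
                "pos": inv_pos,
                "ref": bases[rng.integers(0, 4, size=cfg.n_invariant_sites)],
                "alt": ".",
                "mq": 60.0,
                "mq0f": 0.0,
                "indel_distance": np.inf,
                "is_indel": False,
                "is_multiallelic": False,
            }
        )
        n_inv = cfg.n_invariant_sites
        inv_dos = np.zeros((n_samp, n_inv), dtype=np.int8)
        inv_dp = rng.poisson(cfg.mean_depth, size=(n_samp, n_inv)).astype(np.int32)
        inv_ad = np.stack([inv_dp, np.zeros_like(inv_dp)], axis=2).astype(np.int32)
        inv_gq = np.minimum(cfg.gq_cap, np.round(cfg.gq_per_depth * inv_dp)).astype(np.int16)
        if cfg.missing_rate > 0:
            miss = rng.random((n_samp, n_inv)) < cfg.missing_rate
            inv_dos[miss] = MISSING
            inv_dp[miss] = 0
            inv_ad[miss] = 0
            inv_gq[miss] = 0
        variants = pd.concat([variants, inv], ignore_index=True)
        order = np.argsort(variants["pos"].to_numpy(), kind="stable")
        variants = variants.iloc[order].reset_index(drop=True)
        dosage = np.concatenate([dosage, inv_dos], axis=1)[:, order]
        dp = np.concatenate([dp, inv_dp], axis=1)[:, order]
        ad = np.concatenate([ad, inv_ad], axis=1)[:, order, :]
        gq = np.concatenate([gq, inv_gq], axis=1)[:, order]

    variants = variants[VARIANT_COLUMNS]
    calls = GenotypeCalls(dosage=dosage, dp=dp, ad=ad, gq=gq)
    return samples, variants, calls


def selected_variant_index(cfg: SimConfig, variants: pd.DataFrame) -> int:
    """Index of the selected locus in a simulated variant table."""
    if cfg.selected_locus is None:
        raise ValueError("config has no selected locus")
    hits = np.where(variants["pos"].to_numpy() == cfg.selected_locus[0])[0]
    if len(hits) != 1:
        raise ValueError("selected locus not found in variant table")
    return int(hits[0])


def block_span(cfg: SimConfig) -> tuple[int, int]:
    """bp span (inclusive) of the linked block around the selected locus."""
    if cfg.selected_locus is None:
        raise ValueError("config has no selected locus")
    pos = cfg.selected_locus[0]
    half = cfg.haplotype_block_bp // 2
    return pos - half, pos + half
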