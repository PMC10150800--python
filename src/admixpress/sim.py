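"""Synthetic admixed cohorts with known truth.

Two symmetric source populations are drawn from a Balding-Nichols model
(shared base frequency per site, a single F parameter controlling their
differentiation); an admixed cohort is built as a haplotype mosaic whose
ancestry switches follow a two-state Markov process in genetic distance
(switch rate = admixture age in generations per Morgan, stationary western
probability alpha_west). Expression is linear in per-ancestry allele
copies plus a local-ancestry term and Gaussian noise; allele-specific read
counts are binomial around 0.5 + AI at Poisson depths. Every stage has its
own deterministic substream of the master seed, so a module's inputs can
be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ANCESTRY_COLUMNS, EAST, WEST, HaplotypeSet

# named substreams of the master seed; child rng k for component `name`
# is default_rng(SeedSequence(master_seed, spawn_key=(STREAMS[name],)))
STREAMS = {
    "frequencies": 0,
    "haplotypes_east": 1,
    "haplotypes_west": 2,
    "admixture": 3,
    "expression": 4,
    "ase": 5,
    "layout": 6,
}


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Deterministic per-component random stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(master_seed,
                                                        spawn_key=(STREAMS[name],)))


@dataclass
class SimConfig:
    """Study-condition parameters for one synthetic cohort."""

    n_anc_east: int = 500
    n_anc_west: int = 500
    n_admixed: int = 90
    n_sites: int = 2000
    n_genes: int = 40
    fst_sim: float = 0.2
    alpha_west: float = 0.5
    generations: float = 30.0
    map_length: float = 1.0           # Morgans
    chrom_length_bp: int = 100_000_000
    eqtl_effects: list[tuple] = field(default_factory=list)  # (gene_idx, site_idx, b_east, b_west)
    ancestry_effects: list[tuple] = field(default_factory=list)  # (gene_idx, gamma)
    noise_sd: float = 1.0
    ase_depth: float = 50.0
    ai_truth: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_anc_east", "n_anc_west", "n_admixed", "n_sites", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.alpha_west <= 1:
            raise ValueError("alpha_west must lie in [0, 1]")
        if not 0 <= self.fst_sim < 1:
            raise ValueError("fst_sim must lie in [0, 1)")
        if not 0 <= self.ai_truth <= 0.5:
            raise ValueError("ai_truth must lie in [0, 0.5]")


def simulate_ancestral_frequencies(n_sites: int, fst_sim: float, seed: int,
                                   base_freq_sampler=None) -> pd.DataFrame:
    """Balding-Nichols per-population frequencies around a shared base.

    With F > 0 each population's frequency at a site of base frequency p is
    Beta(p(1-F)/F, (1-p)(1-F)/F); F = 0 degenerates to the base frequency.
    Base frequencies default to Uniform(0.05, 0.95). Sites fixed in both
    populations are flagged ``monomorphic``.
    """
    if not 0 <= fst_sim < 1:
        raise ValueError(f"fst_sim must lie in [0, 1), got {fst_sim}")
    rng = substream(seed, "frequencies")
    if base_freq_sampler is None:
        base = rng.uniform(0.05, 0.95, size=n_sites)
    else:
        base = np.asarray(base_freq_sampler(rng, n_sites), dtype=float)
    if np.any((base < 0) | (base > 1)):
        raise ValueError("base frequencies must lie in [0, 1]")

    if fst_sim == 0:
        fe = base.copy()
        fw = base.copy()
    else:
        scale = (1 - fst_sim) / fst_sim
        a, b = base * scale, (1 - base) * scale
        interior = (base > 0) & (base < 1)
        fe = base.copy()
        fw = base.copy()
        fe[interior] = rng.beta(a[interior], b[interior])
        fw[interior] = rng.beta(a[interior], b[interior])
    table = pd.DataFrame({"base_freq": base, "freq_east": fe, "freq_west": fw})
    table["monomorphic"] = ((fe == 0) & (fw == 0)) | ((fe == 1) & (fw == 1))
    return table


def simulate_haplotypes(freqs, n_individuals: int, seed: int,
                        stream: str = "haplotypes_east",
                        positions=None, map_pos=None,
                        prefix: str = "S") -> HaplotypeSet:
    """Panel of 2n phased haplotypes with independent Bernoulli(freq) sites."""
    f = np.asarray(freqs, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = substream(seed, stream)
    hap = (rng.random((2 * n_individuals, f.size)) < f).astype(np.int8)
    if positions is None:
        positions = np.arange(f.size, dtype=np.int64)
    return HaplotypeSet(hap, positions, map_pos,
                        [f"{prefix}{i:04d}" for i in range(n_individuals)])


def _mosaic_segments(rng, map_length: float, generations: float,
                     alpha_west: float) -> list[tuple[float, float, str]]:
    """Ancestry segments of one haplotype over [0, map_length] Morgans.

    Switch points are a Poisson process of rate ``generations``; at each
    point (and at the origin) ancestry is drawn from the stationary law
    (alpha_west west). Adjacent same-ancestry draws merge into one segment.
    """
    labels = [WEST, EAST]
    cur = WEST if rng.random() < alpha_west else EAST
    segs = []
    pos = 0.0
    while pos < map_length:
        nxt = map_length if generations <= 0 else min(
            map_length, pos + rng.exponential(1.0 / generations))
        segs.append((pos, nxt, cur))
        pos = nxt
        cur = WEST if rng.random() < alpha_west else EAST
    # merge runs of identical ancestry
    merged = [list(segs[0])]
    for s in segs[1:]:
        if s[2] == merged[-1][2]:
            merged[-1][1] = s[1]
        else:
            merged.append(list(s))
    return [tuple(s) for s in merged]


def simulate_admixed(hap_east: HaplotypeSet, hap_west: HaplotypeSet,
                     alpha_west: float, generations: float, map_positions,
                     n_admixed: int, seed: int,
                     chrom: str = "chr1") -> tuple[HaplotypeSet, pd.DataFrame]:
    """Mosaic admixed cohort with its true local-ancestry track.

    Each admixed haplotype is a sequence of ancestry segments (Markov
    switching in genetic distance); within a segment, alleles are copied
    from one random haplotype of the labelled source panel. Returns the
    cohort and a BED-like truth table (bp coordinates, 0-based half-open).
    """
    if hap_east.n_haplotypes == 0 or hap_west.n_haplotypes == 0:
        raise ValueError("ancestral panels must be non-empty")
    if not 0 <= alpha_west <= 1:
        raise ValueError("alpha_west must lie in [0, 1]")
    mp = np.asarray(map_positions, dtype=float)
    if np.any(np.diff(mp) < 0):
        raise ValueError("map positions must be non-decreasing")
    rng = substream(seed, "admixture")
    map_length = float(mp[-1]) if len(mp) else 0.0
    bp = hap_east.positions
    # bp coordinate for a genetic position, for the truth BED
    grid_m = np.concatenate([[0.0], mp, [map_length]])
    grid_bp = np.concatenate([[0], bp, [bp[-1] + 1 if len(bp) else 1]])

    n_sites = hap_east.n_sites
    out = np.zeros((2 * n_admixed, n_sites), dtype=np.int8)
    panels = {EAST: hap_east.haplotypes, WEST: hap_west.haplotypes}
    track_rows = []
    samples = [f"ADM{i:04d}" for i in range(n_admixed)]
    for h in range(2 * n_admixed):
        sample, hap_idx = samples[h // 2], h % 2
        segs = _mosaic_segments(rng, map_length, generations, alpha_west)
        for (m0, m1, anc) in segs:
            in_seg = (mp >= m0) & (mp < m1) if m1 < map_length else (mp >= m0)
            if in_seg.any():
                donor = rng.integers(panels[anc].shape[0])
                out[h, in_seg] = panels[anc][donor, in_seg]
            b0 = int(np.interp(m0, grid_m, grid_bp))
            b1 = int(np.interp(m1, grid_m, grid_bp)) if m1 < map_length \
                else int(grid_bp[-1])
            if b1 > b0:
                track_rows.append((chrom, b0, b1, sample, hap_idx, anc))
    track = pd.DataFrame(track_rows, columns=ANCESTRY_COLUMNS)
    return HaplotypeSet(out, bp, mp, samples), track


def ancestry_at_sites(track: pd.DataFrame, haps: HaplotypeSet) -> np.ndarray:
    """Boolean matrix (haplotypes x sites): True where the haplotype is EAST."""
    n_h, n_s = haps.n_haplotypes, haps.n_sites
    east = np.zeros((n_h, n_s), dtype=bool)
    pos = haps.positions
    by_hap = {(s, h): g for (s, h), g in track.groupby(["sample", "haplotype"])}
    for h in range(n_h):
        sample, hap_idx = haps.samples[h // 2], h % 2
        seg = by_hap.get((sample, hap_idx))
        if seg is None:
            continue
        for row in seg.itertuples(index=False):
            if row.ancestry == EAST:
                east[h, (pos >= row.start) & (pos < row.end)] = True
    return east


def simulate_expression(haps: HaplotypeSet, east_mask: np.ndarray,
                        eqtl_effects: list[tuple], ancestry_effects: list[tuple],
                        n_genes: int, noise_sd: float, seed: int,
                        gene_anc_sites=None) -> pd.DataFrame:
    """Expression matrix with per-ancestry eQTL effects and ancestry effects.

    For effect (gene g, site s, b_east, b_west): each allele-1 copy
    contributes b of the ancestry of the haplotype carrying it. For
    ancestry effect (g, gamma): gamma * eastern dosage at the gene's
    reference site (``gene_anc_sites[g]``, default site 0). Returns genes x
    samples with gene ids G0000...
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    H = haps.haplotypes
    n_ind = haps.n_individuals
    rng = substream(seed, "expression")
    expr = rng.normal(0.0, noise_sd, size=(n_genes, n_ind)) if noise_sd > 0 \
        else np.zeros((n_genes, n_ind))
    for (g, s, b_east, b_west) in eqtl_effects:
        if not (0 <= g < n_genes and 0 <= s < haps.n_sites):
            raise ValueError(f"effect indices out of range: gene {g}, site {s}")
        carries = H[:, s] == 1
        east_copies = (carries & east_mask[:, s]).reshape(n_ind, 2).sum(axis=1)
        west_copies = (carries & ~east_mask[:, s]).reshape(n_ind, 2).sum(axis=1)
        expr[g] += b_east * east_copies + b_west * west_copies
    for (g, gamma) in ancestry_effects:
        s = 0 if gene_anc_sites is None else gene_anc_sites[g]
        east_dos = east_mask[:, s].reshape(n_ind, 2).sum(axis=1)
        expr[g] += gamma * east_dos
    return pd.DataFrame(expr, index=[f"G{i:04d}" for i in range(n_genes)],
                        columns=haps.samples)


def simulate_ase_counts(het_table: pd.DataFrame, ai_truth, ase_depth: float,
                        seed: int) -> pd.DataFrame:
    """Binomial ASE read counts at heterozygous sample-sites.

    ``het_table`` needs columns ``sample, site``; ``ai_truth`` is a scalar
    or per-row array in [0, 0.5], applied toward the reference allele
    (p_ref = 0.5 + ai). Depth ~ Poisson(ase_depth) truncated at >= 1.
    """
    ai = np.broadcast_to(np.asarray(ai_truth, dtype=float), (len(het_table),))
    if np.any((ai < 0) | (ai > 0.5)):
        raise ValueError("ai_truth must lie in [0, 0.5]")
    if ase_depth <= 0:
        raise ValueError("ase_depth must be > 0")
    rng = substream(seed, "ase")
    depth = rng.poisson(ase_depth, size=len(het_table))
    while np.any(depth == 0):  # truncate at >= 1
        redraw = depth == 0
        depth[redraw] = rng.poisson(ase_depth, size=int(redraw.sum()))
    ref = rng.binomial(depth, 0.5 + ai)
    out = het_table.copy().reset_index(drop=True)
    out["ref_count"] = ref
    out["alt_count"] = depth - ref
    return out


def random_layout(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site positions and non-overlapping gene intervals on one chromosome."""
    rng = substream(cfg.seed, "layout")
    pos = np.sort(rng.choice(cfg.chrom_length_bp, size=cfg.n_sites, replace=False))
    variants = pd.DataFrame({
        "id": [f"snp{i:05d}" for i in range(cfg.n_sites)],
        "chrom": "chr1", "pos": pos, "ref": "A", "alt": "G",
    })
    # genes tile the chromosome; span 50 kb each, evenly spaced starts
    starts = np.linspace(0, cfg.chrom_length_bp - 50_000, cfg.n_genes).astype(np.int64)
    genes = pd.DataFrame({
        "gene": [f"G{i:04d}" for i in range(cfg.n_genes)],
        "chrom": "chr1", "start": starts, "end": starts + 50_000,
    })
    return variants, genes


def nearest_site_to_gene(variants: pd.DataFrame, genes: pd.DataFrame,
                         gene_idx: int) -> int:
    """Index of the variant closest to a gene's midpoint (for placing
    cis-regulatory effects in simulated layouts)."""
    mid = (genes.loc[gene_idx, "start"] + genes.loc[gene_idx, "end"]) // 2
    return int(np.argmin(np.abs(variants["pos"].to_numpy() - mid)))


@dataclass
class Cohort:
    """One fully simulated study: panels, admixed cohort, truth and phenotypes."""

    config: SimConfig
    variants: pd.DataFrame
    genes: pd.DataFrame
    freqs: pd.DataFrame
    hap_east: HaplotypeSet
    hap_west: HaplotypeSet
    hap_admixed: HaplotypeSet
    ancestry_track: pd.DataFrame
    east_mask: np.ndarray
    expression: pd.DataFrame
    ancestral_alleles: pd.DataFrame


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """End-to-end generation of a synthetic two-way admixed study."""
    variants, genes = random_layout(cfg)
    freqs = simulate_ancestral_frequencies(cfg.n_sites, cfg.fst_sim, cfg.seed)
    map_pos = variants["pos"].to_numpy() / cfg.chrom_length_bp * cfg.map_length
    hap_e = simulate_haplotypes(freqs["freq_east"], cfg.n_anc_east, cfg.seed,
                                "haplotypes_east", variants["pos"].to_numpy(),
                                map_pos, prefix="EAS")
    hap_w = simulate_haplotypes(freqs["freq_west"], cfg.n_anc_west, cfg.seed,
                                "haplotypes_west", variants["pos"].to_numpy(),
                                map_pos, prefix="EUR")
    hap_adm, track = simulate_admixed(hap_e, hap_w, cfg.alpha_west,
                                      cfg.generations, map_pos, cfg.n_admixed,
                                      cfg.seed)
    east_mask = ancestry_at_sites(track, hap_adm)
    gene_anc_sites = {
        g: int(np.argmin(np.abs(variants["pos"].to_numpy()
                                - (genes.loc[g, "start"] + genes.loc[g, "end"]) // 2)))
        for g in range(cfg.n_genes)
    }
    expression = simulate_expression(hap_adm, east_mask, cfg.eqtl_effects,
                                     cfg.ancestry_effects, cfg.n_genes,
                                     cfg.noise_sd, cfg.seed, gene_anc_sites)
    # ancestral allele: REF ancestral for all sites (derived = ALT), a fixed
    # polarity the DAF stages re-polarize from
    anc = pd.DataFrame({"id": variants["id"], "ancestral": variants["ref"]})
    return Cohort(cfg, variants, genes, freqs, hap_e, hap_w, hap_adm, track,
                  east_mask, expression, anc)
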