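"""Weir-Cockerham F_ST, HDS/HDG classification and set enrichment.

Per-site differentiation between the two source populations is measured
with the Weir & Cockerham (1984) estimator theta-hat = a / (a + b + c),
where ``a`` is the among-population variance component, ``b`` the
among-individual-within-population component and ``c`` the
within-individual component. Sites with F_ST strictly above a threshold
(default 0.2) are called highly differentiated SNVs (HDS); genes whose
mean AND component-weighted F_ST over their sites both strictly exceed
the threshold are highly differentiated genes (HDG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FST_THRESHOLD = 0.2


@dataclass(frozen=True)
class SiteFst:
    """Variance components and estimate for one biallelic site.

    ``fst`` is ``None`` when a + b + c == 0 (site monomorphic in every
    population) — an explicit undefined marker, never a silent zero.
    """

    site_id: str
    a: float
    b: float
    c: float
    fst: float | None

    @property
    def defined(self) -> bool:
        return self.fst is not None


@dataclass(frozen=True)
class GeneFst:
    gene_id: str
    mean_fst: float | None
    weighted_fst: float | None
    n_sites: int

    @property
    def defined(self) -> bool:
        return self.mean_fst is not None


def _validate_counts(genotype_counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ValueError(
            "genotype counts must be (n_populations, 3): AA, Aa, aa per population"
        )
    if counts.shape[0] < 2:
        raise ValueError("need >= 2 populations")
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    if np.any(counts.sum(axis=1) < 1):
        raise ValueError("each population needs >= 1 genotyped diploid")
    return counts


def weir_cockerham_components(genotype_counts) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one biallelic site.

    ``genotype_counts`` is (n_populations, 3): counts of the three diploid
    genotypes (AA, Aa, aa) per population, missing genotypes already
    dropped. Follows the two-allele formulation with r populations of
    sizes n_i, reference-allele frequencies p_i and heterozygote
    proportions h_i.
    """
    counts = _validate_counts(genotype_counts)
    r = counts.shape[0]
    n = counts.sum(axis=1)  # diploids per population
    p = (2 * counts[:, 0] + counts[:, 1]) / (2 * n)
    h = counts[:, 1] / n

    nbar = n.mean()
    sum_n = n.sum()
    nc = (sum_n - (n**2).sum() / sum_n) / (r - 1)
    pbar = (n * p).sum() / sum_n
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / sum_n

    if nbar <= 1:
        raise ValueError("need average sample size > 1 diploid")

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def weir_cockerham_fst(genotype_counts, site_id: str = "") -> SiteFst:
    """Per-site Weir-Cockerham estimate; undefined for monomorphic sites."""
    a, b, c = weir_cockerham_components(genotype_counts)
    denom = a + b + c
    if denom == 0.0:
        return SiteFst(site_id, a, b, c, None)
    return SiteFst(site_id, a, b, c, a / denom)


def fst_from_haplotypes(hap_a, hap_b) -> pd.DataFrame:
    """Vectorised per-site components for two phased panels.

    ``hap_a`` / ``hap_b`` are 0/1 haplotype matrices (haplotypes x sites)
    with an even number of rows. Returns a DataFrame with columns
    ``a, b, c, fst`` (``fst`` NaN where undefined).
    """
    out = []
    for s in range(np.asarray(hap_a).shape[1]):
        counts = []
        for hap in (hap_a, hap_b):
            h = np.asarray(hap)
            g = h[0::2, s] + h[1::2, s]  # diploid genotype = alt-allele count
            counts.append([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()])
        a, b, c = weir_cockerham_components(np.array(counts))
        denom = a + b + c
        out.append((a, b, c, a / denom if denom != 0 else np.nan))
    return pd.DataFrame(out, columns=["a", "b", "c", "fst"])


def genomewide_fst(components: pd.DataFrame) -> float:
    """Multi-locus (ratio-of-sums) estimate: sum(a) / sum(a + b + c).

    This is the standard summary of overall differentiation between two
    panels and the quantity the simulator's F dial calibrates against; the
    per-site ratio a/(a+b+c) is a skewed quantity whose median sits well
    below the model F even at large sample sizes.
    """
    num = components["a"].sum()
    den = (components["a"] + components["b"] + components["c"]).sum()
    if den == 0:
        raise ValueError("all sites monomorphic: genome-wide F_ST undefined")
    return float(num / den)


def classify_hds(site: SiteFst, threshold: float = FST_THRESHOLD) -> bool:
    """HDS iff the estimate is defined and strictly > threshold."""
    if not site.defined:
        raise ValueError(f"site {site.site_id!r}: undefined F_ST cannot be classified")
    return site.fst > threshold


def gene_fst(site_fsts: list[SiteFst], gene_intervals: pd.DataFrame,
             site_positions: dict[str, tuple[str, int]]) -> list[GeneFst]:
    """Aggregate per-site components to genes.

    ``gene_intervals`` needs columns ``gene, chrom, start, end`` (0-based
    half-open); ``site_positions`` maps site id -> (chrom, pos). Sites with
    undefined components are skipped; a gene with zero defined sites gets an
    undefined GeneFst.
    """
    results = []
    for row in gene_intervals.itertuples(index=False):
        mem = [
            s for s in site_fsts
            if s.defined
            and site_positions[s.site_id][0] == row.chrom
            and row.start <= site_positions[s.site_id][1] < row.end
        ]
        if not mem:
            results.append(GeneFst(row.gene, None, None, 0))
            continue
        ests = np.array([s.fst for s in mem])
        num = sum(s.a for s in mem)
        den = sum(s.a + s.b + s.c for s in mem)
        results.append(
            GeneFst(row.gene, float(ests.mean()),
                    float(num / den) if den != 0 else None, len(mem))
        )
    return results


def classify_hdg(gene: GeneFst, threshold: float = FST_THRESHOLD) -> bool:
    """HDG iff mean AND weighted F_ST both strictly exceed the threshold."""
    if not gene.defined or gene.weighted_fst is None:
        raise ValueError(f"gene {gene.gene_id!r}: undefined F_ST cannot be classified")
    return gene.mean_fst > threshold and gene.weighted_fst > threshold


def fisher_enrichment(hits_in_set: int, hits_out_set: int,
                      misses_in_set: int, misses_out_set: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 membership table.

    Returns (odds ratio, p). OR = (a*d)/(b*c); inf when b*c == 0 with
    a*d > 0, 0 when a*d == 0 with b*c > 0, NaN when both are zero.
    """
    table = np.array([[hits_in_set, hits_out_set],
                      [misses_in_set, misses_out_set]])
    if np.any(table < 0):
        raise ValueError("table entries must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    res = stats.fisher_exact(table, alternative="two-sided")
    ad = hits_in_set * misses_out_set
    bc = hits_out_set * misses_in_set
    if bc == 0:
        odds = np.nan if ad == 0 else np.inf
    else:
        odds = ad / bc
    return float(odds), float(res.pvalue)
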