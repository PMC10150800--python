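"""Allele-specific expression: AI statistics, exact tests, origin contrasts,
the ±100 kb aseQTL scan, and driver classification.

Allelic imbalance (AI) at a heterozygous site is |ref fraction - 0.5|,
bounded by 0.5 (monoallelic). The signed variant is positive when the
derived allele is the overexpressed one. Significance is an exact binomial
test of the read counts against 0.5, BH-corrected across all tested
site-samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qtl import bh_fdr

MIN_DEPTH = 20
ASEQTL_WINDOW = 100_000

CIS_REGULATED = "CIS_REGULATED"
NMD = "NMD"
UNEXPLAINED = "UNEXPLAINED"

#: annotation terms treated as protein-truncating / loss-of-function
LOF_TERMS = frozenset({
    "stop_gained", "frameshift", "frameshift_variant", "splice_donor",
    "splice_acceptor", "splice_donor_variant", "splice_acceptor_variant",
    "start_lost", "stop_lost", "lof", "loss_of_function", "protein_truncating",
})


def allelic_imbalance(ref_count: int, alt_count: int) -> float:
    """AI = |ref/(ref+alt) - 0.5|; undefined (error) at zero depth."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_count + alt_count
    if total == 0:
        raise ValueError("zero total depth: AI undefined")
    return abs(ref_count / total - 0.5)


def binomial_ase_test(ref_count: int, alt_count: int, null_p: float = 0.5,
                      min_depth: int = MIN_DEPTH) -> float:
    """Exact two-sided binomial p (minimum-likelihood two-sided convention).

    Raises on depth below ``min_depth``; callers filter first and log.
    """
    total = ref_count + alt_count
    if total < min_depth:
        raise ValueError(f"depth {total} below min_depth {min_depth}")
    return float(stats.binomtest(ref_count, total, null_p).pvalue)


def call_ase(observations: pd.DataFrame, ancestral_is_ref=None,
             min_depth: int = MIN_DEPTH, alpha: float = 0.05) -> pd.DataFrame:
    """ASE calls for a table of (sample, site) read counts.

    ``observations`` needs columns ``sample, site, ref_count, alt_count``.
    ``ancestral_is_ref``, when given, maps site id -> bool (REF allele is
    ancestral) and enables the signed AI (+ derived allele overexpressed).
    Rows below ``min_depth`` are dropped. Significance = BH q < alpha over
    all tested rows.
    """
    obs = observations.copy()
    if (obs["ref_count"] < 0).any() or (obs["alt_count"] < 0).any():
        raise ValueError("negative read counts")
    depth = obs["ref_count"] + obs["alt_count"]
    obs = obs[depth >= min_depth].reset_index(drop=True)
    if obs.empty:
        return obs.assign(ai=[], signed_ai=[], p=[], q=[], significant=[],
                          overexpressed_allele=[])
    ref_frac = obs["ref_count"] / (obs["ref_count"] + obs["alt_count"])
    obs["ai"] = (ref_frac - 0.5).abs()
    obs["p"] = [
        binomial_ase_test(r, a, min_depth=min_depth)
        for r, a in zip(obs["ref_count"], obs["alt_count"])
    ]
    obs["q"] = bh_fdr(obs["p"].to_numpy())
    obs["significant"] = obs["q"] < alpha
    obs["overexpressed_allele"] = np.where(obs["ai"] == 0, "",
                                           np.where(ref_frac > 0.5, "ref", "alt"))
    if ancestral_is_ref is not None:
        anc_ref = obs["site"].map(ancestral_is_ref)
        derived_frac = np.where(anc_ref.astype(bool), 1 - ref_frac, ref_frac)
        obs["signed_ai"] = derived_frac - 0.5
    else:
        obs["signed_ai"] = np.nan
    return obs


def compare_origin_groups(signed_ai: np.ndarray, origins: np.ndarray,
                          alternative: str = "greater") -> pd.DataFrame:
    """One-sample one-tailed t of signed AI against 0 within each origin group.

    ``alternative='greater'`` tests derived-allele overexpression (the
    hypothesis for derived alleles of western origin). Groups with fewer
    than two values are excluded. Zero-variance groups get t = +/-inf with
    p 0 or 1 by the sign of the mean relative to the tested tail.
    """
    signed_ai = np.asarray(signed_ai, dtype=float)
    origins = np.asarray(origins)
    rows = []
    for grp in pd.unique(origins):
        vals = signed_ai[origins == grp]
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            continue
        if np.ptp(vals) == 0:
            mean = vals[0]
            t = np.inf * np.sign(mean) if mean != 0 else 0.0
            if mean == 0:
                p = 0.5
            elif (mean > 0) == (alternative == "greater"):
                p = 0.0
            else:
                p = 1.0
        else:
            res = stats.ttest_1samp(vals, 0.0, alternative=alternative)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append((grp, len(vals), float(np.mean(vals)), t, p))
    return pd.DataFrame(rows, columns=["origin", "n", "mean_signed_ai", "t", "p"])


def aseqtl_scan(ase_pos: int, ase_het_samples: list[str], ai_by_sample: dict,
                candidates: pd.DataFrame, genotypes: pd.DataFrame,
                window_bp: int = ASEQTL_WINDOW, alpha: float = 0.05,
                chrom=None) -> pd.DataFrame:
    """Scan candidate variants within ±window of an ASE site.

    Among individuals heterozygous at the ASE site, each candidate in
    [ase_pos - window, ase_pos + window) splits samples into candidate
    heterozygotes vs homozygotes; a two-sided Wilcoxon rank-sum on AI between
    the two groups tests whether candidate genotype drives the imbalance.

    ``candidates``: columns ``id, chrom, pos``; ``genotypes``: dosage rows
    indexed by variant id, columns = sample ids. Returns tested candidates
    with ``p`` and ``hit`` (p < alpha). Candidates monomorphic for
    heterozygosity among the eligible samples are skipped.
    """
    cand = candidates[(candidates["pos"] >= ase_pos - window_bp)
                      & (candidates["pos"] < ase_pos + window_bp)]
    if chrom is not None:
        cand = cand[cand["chrom"] == chrom]
    samples = [s for s in ase_het_samples if s in genotypes.columns]
    ai = np.array([ai_by_sample[s] for s in samples], dtype=float)
    rows = []
    for c in cand.itertuples(index=False):
        if c.id not in genotypes.index:
            continue
        dos = genotypes.loc[c.id, samples].to_numpy(dtype=float)
        is_het = dos == 1
        if is_het.all() or (~is_het).all():
            continue  # no genotype contrast among eligible individuals
        if len(ai[is_het]) < 1 or len(ai[~is_het]) < 1:
            continue
        stat, p = stats.mannwhitneyu(ai[is_het], ai[~is_het],
                                     alternative="two-sided")
        rows.append((c.id, c.pos, float(stat), float(p), p < alpha))
    return pd.DataFrame(rows, columns=["candidate", "pos", "u", "p", "hit"])


@dataclass(frozen=True)
class DriverCall:
    site: str
    driver_class: str
    n_aseqtl_hits: int


def classify_ase_driver(site: str, n_aseqtl_hits: int,
                        consequence: str | None) -> DriverCall:
    """Attribute an ASE site to a driver class.

    Cis regulation (>= 1 aseQTL hit) takes precedence over NMD
    (protein-truncating consequence); everything else is unexplained.
    Missing annotation is treated as no consequence.
    """
    if n_aseqtl_hits >= 1:
        return DriverCall(site, CIS_REGULATED, n_aseqtl_hits)
    term = (consequence or "").strip().lower()
    if term in LOF_TERMS:
        return DriverCall(site, NMD, 0)
    return DriverCall(site, UNEXPLAINED, 0)
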