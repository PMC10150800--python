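"""Local-ancestry dosage and its association with gene expression.

At any locus an admixed diploid carries 0, 1 or 2 haplotypes of eastern
ancestry. Genes whose expression correlates with eastern-ancestry dosage
are "ancestral-like" (eastern when the correlation is positive, western
when negative, i.e. positive with western dosage = 2 - eastern). The eQTAS
scan regresses a gene's expression on the ancestry dosage of every
candidate segment in a window around the gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EAST
from .qtl import bh_fdr

EQTAS_WINDOW = 1_000_000


def ancestry_dosage_at(tracks: pd.DataFrame, chrom, locus: int,
                       samples: list[str]) -> pd.Series:
    """Eastern-ancestry dosage (0/1/2) per sample at one position.

    ``tracks`` is the BED-like segment table (columns chrom, start, end,
    sample, haplotype, ancestry; 0-based half-open). For point queries a
    segment covers position m when start < m <= end (right-closed), except
    that a track's first segment also covers its own start; this keeps a
    breakpoint exactly at a locus midpoint attached to the segment ending
    there. Samples with an uncovered haplotype get NaN.
    """
    seg = tracks[tracks["chrom"] == chrom]
    out = {}
    for sample in samples:
        total = 0.0
        for hap in (0, 1):
            rows = seg[(seg["sample"] == sample) & (seg["haplotype"] == hap)]
            if rows.empty:
                total = np.nan
                break
            first_start = rows["start"].min()
            cover = rows[((rows["start"] < locus) & (locus <= rows["end"]))
                         | ((rows["start"] == first_start) & (locus == first_start))]
            if cover.empty:
                total = np.nan
                break
            total += float((cover.iloc[0]["ancestry"] == EAST))
        out[sample] = total
    return pd.Series(out, name="east_dosage")


def ancestry_dosage_matrix(tracks: pd.DataFrame, loci: pd.DataFrame,
                           samples: list[str]) -> pd.DataFrame:
    """Eastern dosage at many loci; rows = locus ids, columns = samples.

    ``loci`` needs columns ``id, chrom, pos``.
    """
    rows = {
        l.id: ancestry_dosage_at(tracks, l.chrom, l.pos, samples)
        for l in loci.itertuples(index=False)
    }
    return pd.DataFrame(rows).T.loc[[l for l in loci["id"]], samples]


def find_ancestral_like_genes(expression: pd.DataFrame, east_dosage: pd.DataFrame,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of expression with eastern-ancestry dosage per gene.

    ``expression``: genes x samples; ``east_dosage``: genes x samples
    (dosage at each gene's own locus). Genes with zero variance in either
    vector are excluded. Returns r, p, BH q, significance and direction
    (EASTERN for positive r, WESTERN for negative).
    """
    common = [s for s in expression.columns if s in east_dosage.columns]
    rows = []
    for gene in expression.index:
        if gene not in east_dosage.index:
            continue
        y = expression.loc[gene, common].to_numpy(dtype=float)
        d = east_dosage.loc[gene, common].to_numpy(dtype=float)
        keep = ~(np.isnan(y) | np.isnan(d))
        y, d = y[keep], d[keep]
        if len(y) < 3 or np.ptp(d) == 0 or np.ptp(y) == 0:
            continue
        r, p = stats.pearsonr(d, y)
        rows.append((gene, len(y), float(r), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "n", "r", "p"])
    if out.empty:
        return out.assign(q=[], significant=[], direction=[])
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    out["direction"] = np.where(out["r"] > 0, "EASTERN", "WESTERN")
    return out


def eqtas_scan(gene_expression, segment_dosages: pd.DataFrame,
               alpha: float = 0.05) -> pd.DataFrame:
    """OLS of one gene's expression on each candidate segment's east dosage.

    ``segment_dosages``: segments x samples, already restricted to the scan
    window around the gene. Constant-dosage segments are skipped. BH across
    the tested segments.
    """
    y = np.asarray(gene_expression, dtype=float)
    rows = []
    for seg_id, dosage in segment_dosages.iterrows():
        d = dosage.to_numpy(dtype=float)
        keep = ~(np.isnan(y) | np.isnan(d))
        if keep.sum() < 3 or np.ptp(d[keep]) == 0:
            continue
        res = stats.linregress(d[keep], y[keep])
        rows.append((seg_id, int(keep.sum()), float(res.slope), float(res.rvalue),
                     float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["segment", "n", "beta", "r", "p"])
    if out.empty:
        return out.assign(q=[], significant=[], direction=[])
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    out["direction"] = np.where(out["beta"] > 0, "EASTERN", "WESTERN")
    return out


def segments_in_window(tracks: pd.DataFrame, chrom, start: int, end: int,
                       window_bp: int = EQTAS_WINDOW) -> pd.DataFrame:
    """Candidate segment loci for the eQTAS scan around a gene.

    Candidates are the distinct segment breakpoint midpoints observed in the
    cohort within [start - window, end + window); each defines a locus at
    which ancestry dosage is evaluated.
    """
    lo, hi = start - window_bp, end + window_bp
    seg = tracks[(tracks["chrom"] == chrom)
                 & (tracks["end"] > lo) & (tracks["start"] < hi)]
    mids = np.unique(((seg["start"] + seg["end"]) // 2).to_numpy())
    mids = mids[(mids >= lo) & (mids < hi)]
    return pd.DataFrame({"id": [f"seg_{chrom}_{m}" for m in mids],
                         "chrom": chrom, "pos": mids})
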