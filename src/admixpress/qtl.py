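"""Cis-QTL mapping: candidate pairing, OLS association, FDR, effect classes.

Associations are ordinary least squares of a quantitative phenotype
(normalized expression, or any per-gene quantitative trait such as a
splicing ratio) on alternative-allele dosage plus optional covariates and
an intercept. Two-sided p-values come from the t distribution with
n - n_covariates - 2 degrees of freedom. Multiple testing is a single
pooled Benjamini-Hochberg pass over all tested pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ES_THRESHOLD = 5.0
DEFAULT_CIS_WINDOW = 1_000_000
P_FLOOR = 1e-300


@dataclass(frozen=True)
class QtlAssociation:
    variant_id: str
    gene_id: str
    beta: float
    se: float
    t_statistic: float
    p: float
    n_samples: int


def cis_pairs(variants: pd.DataFrame, genes: pd.DataFrame,
              window_bp: int = DEFAULT_CIS_WINDOW) -> pd.DataFrame:
    """Candidate (variant, gene) pairs within the cis window.

    ``variants`` needs ``id, chrom, pos`` (0-based); ``genes`` needs
    ``gene, chrom, start, end`` (0-based half-open). A pair is kept when the
    variant position lies in [start - window, end + window), half-open.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    out = []
    for g in genes.itertuples(index=False):
        lo = g.start - window_bp
        hi = g.end + window_bp
        hit = variants[(variants["chrom"] == g.chrom)
                       & (variants["pos"] >= lo) & (variants["pos"] < hi)]
        for vid in hit["id"]:
            out.append((vid, g.gene))
    return pd.DataFrame(out, columns=["variant", "gene"])


def associate(phenotype, dosage, covariates=None) -> QtlAssociation | None:
    """OLS of phenotype on dosage (+ covariates + intercept).

    Returns None when the dosage is constant after dropping missing samples
    (the pair is untestable). Missing dosage (NaN or negative) drops the
    sample for this pair.
    """
    y = np.asarray(phenotype, dtype=float)
    d = np.asarray(dosage, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(d) | (d < 0))
    y, d = y[keep], d[keep]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != keep.size:
            C = C.T
        C = C[keep]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), C])) < C.shape[1] + 1:
            raise ValueError("rank-deficient covariate matrix")
    else:
        C = np.empty((len(y), 0))
    n = len(y)
    n_cov = C.shape[1]
    df = n - n_cov - 2
    if df < 0 or n < n_cov + 2:
        raise ValueError(f"need n >= n_covariates + 2 samples, got n={n}")
    if np.ptp(d) == 0:
        return None

    X = np.column_stack([np.ones(n), d, C])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    if df == 0:
        return None
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
    beta = float(coef[1])
    if se == 0.0:
        # perfect fit: report the effect with the smallest reportable p
        t = np.inf if beta != 0 else 0.0
        p = P_FLOOR if beta != 0 else 1.0
    else:
        t = beta / se
        p = max(2 * stats.t.sf(abs(t), df), P_FLOOR)
    return QtlAssociation("", "", beta, se, float(t), float(p), n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_high_effect(beta: float, es_threshold: float = ES_THRESHOLD) -> bool:
    """High-effect QTL iff |beta| strictly exceeds the threshold."""
    if beta is None or np.isnan(beta):
        raise ValueError("undefined effect size")
    return abs(beta) > es_threshold


def lead_qtl(associations: pd.DataFrame) -> str:
    """Lead variant for one gene: min p, ties by position then variant id.

    ``associations`` needs columns ``variant, pos, p``.
    """
    if associations.empty:
        raise ValueError("no associations to pick a lead from")
    ranked = associations.sort_values(["p", "pos", "variant"], kind="mergesort")
    return str(ranked.iloc[0]["variant"])


def map_cis_qtl(expression: pd.DataFrame, dosages: pd.DataFrame,
                variants: pd.DataFrame, genes: pd.DataFrame,
                window_bp: int = DEFAULT_CIS_WINDOW,
                covariates=None) -> pd.DataFrame:
    """Run the full cis scan and pooled BH over all tested pairs.

    ``expression``: genes x samples; ``dosages``: variants x samples (rows
    indexed by variant id). Returns a tidy association table with q-values.
    """
    pairs = cis_pairs(variants, genes, window_bp)
    pos_by_variant = dict(zip(variants["id"], variants["pos"]))
    rows = []
    for pair in pairs.itertuples(index=False):
        if pair.gene not in expression.index or pair.variant not in dosages.index:
            continue
        res = associate(expression.loc[pair.gene].to_numpy(),
                        dosages.loc[pair.variant].to_numpy(), covariates)
        if res is None:  # constant dosage among usable samples
            continue
        rows.append((pair.variant, pair.gene, pos_by_variant[pair.variant],
                     res.beta, res.se, res.t_statistic, res.p, res.n_samples))
    table = pd.DataFrame(rows, columns=["variant", "gene", "pos", "beta", "se",
                                        "t", "p", "n"])
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return table
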