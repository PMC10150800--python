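"""Admixture-expectation derived-allele frequencies and the deviation statistic.

Under two-way admixture with western ancestry proportion alpha_w, the
expected derived-allele frequency (DAF) in the admixed group is the linear
mixture alpha_w * f_west + (1 - alpha_w) * f_east. The deviation
|expected - observed| flags sites whose post-admixture frequency moved away
from the neutral expectation; alleles are assigned an eastern or western
ancestral origin when the source-population DAFs differ by more than a
threshold (default 0.20).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EAST, WEST

UNASSIGNED = "UNASSIGNED"
ORIGIN_THRESHOLD = 0.20


def _check_freq(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def expected_daf(daf_east, daf_west, alpha_west: float):
    """Mixture expectation alpha_w * f_west + (1 - alpha_w) * f_east."""
    if not 0 <= alpha_west <= 1:
        raise ValueError("alpha_west must lie in [0, 1]")
    fe = _check_freq(daf_east, "daf_east")
    fw = _check_freq(daf_west, "daf_west")
    out = alpha_west * fw + (1 - alpha_west) * fe
    return float(out) if out.ndim == 0 else out


def daf_deviation(expected, observed):
    """|expected - observed| derived-allele frequency."""
    e = _check_freq(expected, "expected")
    o = _check_freq(observed, "observed")
    out = np.abs(e - o)
    return float(out) if out.ndim == 0 else out


def assign_origin(daf_east: float, daf_west: float,
                  threshold: float = ORIGIN_THRESHOLD) -> str:
    """Ancestral origin of the derived allele from the source-DAF contrast."""
    _check_freq(daf_east, "daf_east")
    _check_freq(daf_west, "daf_west")
    if daf_west - daf_east > threshold:
        return WEST
    if daf_east - daf_west > threshold:
        return EAST
    return UNASSIGNED


def polarize_frequency(alt_freq, ref_allele, alt_allele, ancestral_allele):
    """Derived-allele frequency given the ancestral allele.

    Returns NaN where the ancestral allele matches neither REF nor ALT
    (unpolarizable site).
    """
    alt_freq = np.asarray(alt_freq, dtype=float)
    ref = np.asarray(ref_allele)
    alt = np.asarray(alt_allele)
    anc = np.asarray(ancestral_allele)
    out = np.full(alt_freq.shape, np.nan)
    out[anc == ref] = alt_freq[anc == ref]          # derived = ALT
    out[anc == alt] = 1.0 - alt_freq[anc == alt]    # derived = REF
    return out


def daf_table(sites: pd.DataFrame, alpha_west: float,
              origin_threshold: float = ORIGIN_THRESHOLD) -> pd.DataFrame:
    """Per-site DAF records for a cohort.

    ``sites`` needs columns ``id, ref, alt, ancestral, freq_east, freq_west,
    freq_admixed`` where the frequencies refer to the ALT allele. Sites whose
    ancestral allele matches neither REF nor ALT are dropped (they cannot be
    polarized); the number dropped is available from the length difference.
    """
    daf_e = polarize_frequency(sites["freq_east"], sites["ref"], sites["alt"],
                               sites["ancestral"])
    daf_w = polarize_frequency(sites["freq_west"], sites["ref"], sites["alt"],
                               sites["ancestral"])
    daf_o = polarize_frequency(sites["freq_admixed"], sites["ref"], sites["alt"],
                               sites["ancestral"])
    keep = ~np.isnan(daf_e)
    exp = expected_daf(daf_e[keep], daf_w[keep], alpha_west)
    dev = daf_deviation(exp, daf_o[keep])
    origins = [assign_origin(e, w, origin_threshold)
               for e, w in zip(daf_e[keep], daf_w[keep])]
    return pd.DataFrame({
        "id": sites.loc[keep, "id"].to_numpy(),
        "daf_east": daf_e[keep],
        "daf_west": daf_w[keep],
        "daf_admixed_observed": daf_o[keep],
        "daf_expected": exp,
        "deviation": dev,
        "origin": origins,
    })
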