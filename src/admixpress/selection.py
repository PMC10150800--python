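"""EHH curves, iHH integration and the standardized iHS selection scan.

EHH at distance x from a core allele is the probability that two randomly
chosen carrier haplotypes are identical over the interval core..x,
estimated by pair counting: sum over distinct extended haplotypes h of
C(n_h, 2) / C(n, 2). iHH is the trapezoidal integral of EHH over genetic
distance out to the 0.05 crossing in each direction; the unstandardized
iHS is ln(iHH_ancestral / iHH_derived), standardized to z-scores within
derived-allele-frequency bins. |z| > 2 flags candidate hard sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EHH_CUTOFF = 0.05
SWEEP_Z = 2.0
N_DAF_BINS = 50
MAF_BOUNDS = (0.05, 0.95)


@dataclass
class EhhCurve:
    """EHH values at ordered genetic-distance offsets from the core.

    ``offsets[0] == 0`` (the core, EHH 1); offsets are non-negative
    distances in Morgans in one scan direction.
    """

    core_site: int
    core_allele: int
    offsets: np.ndarray
    ehh: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.ehh = np.asarray(self.ehh, dtype=float)
        if len(self.offsets) != len(self.ehh):
            raise ValueError("offsets and EHH values must align")
        if len(self.ehh) and not np.isclose(self.ehh[0], 1.0):
            raise ValueError("EHH at the core must be 1")


def _pair_homozygosity(group_ids: np.ndarray) -> float:
    n = len(group_ids)
    _, counts = np.unique(group_ids, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh(haplotypes, core_site: int, core_allele: int, direction: int,
        map_pos=None, stop_below: float | None = None) -> EhhCurve | None:
    """EHH decay curve in one direction (+1 right, -1 left) from the core.

    ``haplotypes`` is a 0/1 matrix (negative entries = missing, which break
    a haplotype's extension); ``map_pos`` gives genetic positions in
    Morgans (defaults to site index). ``stop_below`` truncates the curve one
    point past the first value under the threshold (enough for the
    interpolated iHH integral). Returns None with < 2 carriers of the core
    allele.
    """
    H = np.asarray(haplotypes)
    n_sites = H.shape[1]
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    mp = np.arange(n_sites, dtype=float) if map_pos is None else np.asarray(map_pos, dtype=float)
    carriers = H[H[:, core_site] == core_allele]
    n = carriers.shape[0]
    if n < 2:
        return None

    idx = (range(core_site + 1, n_sites) if direction == +1
           else range(core_site - 1, -1, -1))
    offsets = [0.0]
    values = [1.0]
    # iteratively refine haplotype groups by the next site's allele;
    # a missing allele gets a per-haplotype sentinel so it never matches
    groups = np.zeros(n, dtype=np.int64)
    for j in idx:
        alleles = carriers[:, j].astype(np.int64).copy()
        miss = alleles < 0
        alleles[miss] = -(np.arange(n)[miss] + 1)
        keys = groups * (2 * n + 4) + (alleles + n + 2)
        _, groups = np.unique(keys, return_inverse=True)
        offsets.append(abs(mp[j] - mp[core_site]))
        values.append(_pair_homozygosity(groups))
        if stop_below is not None and values[-1] < stop_below:
            break
    return EhhCurve(core_site, core_allele, np.array(offsets), np.array(values))


def ihh(curve: EhhCurve, cutoff: float = EHH_CUTOFF) -> tuple[float, bool]:
    """Trapezoidal integral of one directional EHH curve.

    Integration stops at the first offset where EHH < cutoff, linearly
    interpolated to the exact crossing. If the curve never reaches the
    cutoff the whole curve is integrated and the truncation flag is set.
    Returns (integral in Morgans, truncated).
    """
    x, y = curve.offsets, curve.ehh
    total = 0.0
    for i in range(1, len(x)):
        if y[i] >= cutoff:
            total += 0.5 * (y[i] + y[i - 1]) * (x[i] - x[i - 1])
            continue
        # linear interpolation to the cutoff crossing
        if y[i - 1] > cutoff:
            frac = (y[i - 1] - cutoff) / (y[i - 1] - y[i])
            xc = x[i - 1] + frac * (x[i] - x[i - 1])
            total += 0.5 * (y[i - 1] + cutoff) * (xc - x[i - 1])
        return float(total), False
    return float(total), True


def ihh_site(haplotypes, core_site: int, core_allele: int, map_pos=None,
             cutoff: float = EHH_CUTOFF) -> tuple[float, bool] | None:
    """Two-directional iHH: left + right integrals for one core allele."""
    parts = []
    truncated = False
    for direction in (-1, +1):
        curve = ehh(haplotypes, core_site, core_allele, direction, map_pos,
                    stop_below=cutoff)
        if curve is None:
            return None
        val, trunc = ihh(curve, cutoff)
        parts.append(val)
        truncated |= trunc
    return sum(parts), truncated


def ihs_unstandardized(ihh_ancestral: float, ihh_derived: float) -> float:
    """ln(iHH_a / iHH_d); undefined (error) when either integral is zero."""
    if ihh_ancestral <= 0 or ihh_derived <= 0:
        raise ValueError("iHH must be positive to form the log-ratio")
    return float(np.log(ihh_ancestral / ihh_derived))


def standardize_ihs(values, daf, n_bins: int = N_DAF_BINS,
                    maf_bounds: tuple[float, float] = MAF_BOUNDS) -> np.ndarray:
    """Z-standardize raw iHS within equal-width DAF bins.

    Sites with DAF outside ``maf_bounds`` get NaN (excluded, standard
    practice). Bins with fewer than two sites are merged with the next bin
    to the right (the last bin merges leftward).
    """
    values = np.asarray(values, dtype=float)
    daf = np.asarray(daf, dtype=float)
    z = np.full(values.shape, np.nan)
    usable = (daf >= maf_bounds[0]) & (daf <= maf_bounds[1]) & ~np.isnan(values)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_of = np.clip(np.digitize(daf, edges) - 1, 0, n_bins - 1)

    # merge small bins rightward so every effective bin has >= 2 sites
    merged = np.full(n_bins, -1, dtype=int)
    current: list[int] = []
    label = 0
    for b in range(n_bins):
        current.append(b)
        if np.sum(usable & np.isin(bin_of, current)) >= 2:
            merged[current] = label
            label += 1
            current = []
    if current:  # leftover small tail merges into the previous label
        merged[current] = max(label - 1, 0)

    eff = merged[bin_of]
    for lab in np.unique(eff[usable]):
        m = usable & (eff == lab)
        vals = values[m]
        sd = vals.std(ddof=0)
        if sd == 0 or len(vals) < 2:
            continue
        z[m] = (vals - vals.mean()) / sd
    return z


def flag_sweep(z: float, threshold: float = SWEEP_Z) -> bool:
    """Candidate hard sweep iff |z| strictly exceeds the threshold."""
    return bool(abs(z) > threshold)


def ihs_scan(haplotypes, derived_is_alt, map_pos=None,
             cutoff: float = EHH_CUTOFF, n_bins: int = N_DAF_BINS) -> pd.DataFrame:
    """Per-site iHS over a phased panel.

    ``derived_is_alt``: boolean per site — True when allele 1 is derived.
    Returns a table with daf, iHH for both alleles, raw and standardized
    iHS, sweep and truncation flags; undefined sites carry NaN.
    """
    H = np.asarray(haplotypes)
    n_sites = H.shape[1]
    derived_is_alt = np.asarray(derived_is_alt, dtype=bool)
    rows = []
    for s in range(n_sites):
        alt_freq = float((H[:, s] == 1).mean())
        daf_s = alt_freq if derived_is_alt[s] else 1 - alt_freq
        der_allele = 1 if derived_is_alt[s] else 0
        anc_allele = 1 - der_allele
        res_d = ihh_site(H, s, der_allele, map_pos, cutoff)
        res_a = ihh_site(H, s, anc_allele, map_pos, cutoff)
        if res_d is None or res_a is None or res_d[0] <= 0 or res_a[0] <= 0:
            rows.append((s, daf_s, np.nan, np.nan, np.nan, False))
            continue
        raw = ihs_unstandardized(res_a[0], res_d[0])
        rows.append((s, daf_s, res_a[0], res_d[0], raw, res_a[1] or res_d[1]))
    out = pd.DataFrame(rows, columns=["site", "daf", "ihh_ancestral",
                                      "ihh_derived", "ihs_raw", "truncated"])
    out["ihs_z"] = standardize_ihs(out["ihs_raw"].to_numpy(),
                                   out["daf"].to_numpy(), n_bins)
    out["sweep_flag"] = np.abs(out["ihs_z"]) > SWEEP_Z
    out.loc[out["ihs_z"].isna(), "sweep_flag"] = False
    return out
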