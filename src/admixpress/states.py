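"""Admixture-induced expression states: ideal vs enhanced vs relaxed.

After long-term two-way admixture, a gene's expression level — or a
variant's regulatory effect size — is expected to sit between the levels
of the two ancestral populations (the *ideal* state). Departures define
the admixed-group-specific states: *enhanced* when the admixed effect
magnitude exceeds both ancestral magnitudes, *relaxed* when it falls below
both. Effects are estimated per cohort on equal group sizes (default 40
individuals, randomly down-sampled) and compared with a two-sample
effect-heterogeneity z-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .qtl import associate

IDEAL = "IDEAL"
ENHANCED = "ENHANCED"
RELAXED = "RELAXED"
SPECIFIC_ABOVE = "SPECIFIC_ABOVE"
SPECIFIC_BELOW = "SPECIFIC_BELOW"

DOWNSAMPLE_N = 40


@dataclass(frozen=True)
class EffectTriple:
    pair_id: str
    b_east: float
    se_east: float
    b_west: float
    se_west: float
    b_adm: float
    se_adm: float
    n: int = DOWNSAMPLE_N


@dataclass(frozen=True)
class StateCall:
    pair_id: str
    state: str
    p_het_vs_east: float
    p_het_vs_west: float


def downsample_equal(groups: dict[str, list], n: int = DOWNSAMPLE_N,
                     seed: int = 0) -> dict[str, list]:
    """Uniform random subset of exactly n members per group, seeded."""
    rng = np.random.default_rng(seed)
    out = {}
    for name in groups:  # iteration order fixed by dict insertion order
        members = list(groups[name])
        if len(members) < n:
            raise ValueError(f"group {name!r} has {len(members)} < n={n} members")
        idx = rng.choice(len(members), size=n, replace=False)
        out[name] = [members[i] for i in sorted(idx)]
    return out


def heterogeneity_test(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Two-sample effect-heterogeneity z-test.

    z = (b1 - b2) / sqrt(se1^2 + se2^2), p two-sided from the standard
    normal. In the se -> 0 limit with b1 != b2, z diverges and p -> 0.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.hypot(se1, se2)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def classify_effect_state(triple: EffectTriple, alpha: float = 0.05) -> StateCall:
    """Classify one SNP-gene regulatory effect across the three cohorts.

    IDEAL when the admixed beta lies in the closed ancestral interval, or
    when neither heterogeneity test (admixed vs east, admixed vs west)
    rejects at alpha. Otherwise ENHANCED/RELAXED by the admixed effect
    magnitude relative to the ancestral magnitudes; a non-ideal sign-flip
    without a magnitude extremum is assigned by |b_adm| against the mean
    ancestral magnitude.
    """
    b_e, b_w, b_a = triple.b_east, triple.b_west, triple.b_adm
    for b in (b_e, b_w, b_a):
        if b is None or np.isnan(b):
            raise ValueError(f"pair {triple.pair_id!r}: undefined beta")
    _, p_e = heterogeneity_test(b_a, triple.se_adm, b_e, triple.se_east)
    _, p_w = heterogeneity_test(b_a, triple.se_adm, b_w, triple.se_west)

    if min(b_e, b_w) <= b_a <= max(b_e, b_w) or (p_e >= alpha and p_w >= alpha):
        return StateCall(triple.pair_id, IDEAL, p_e, p_w)
    mag_a, mag_e, mag_w = abs(b_a), abs(b_e), abs(b_w)
    if mag_a > max(mag_e, mag_w):
        return StateCall(triple.pair_id, ENHANCED, p_e, p_w)
    if mag_a < min(mag_e, mag_w):
        return StateCall(triple.pair_id, RELAXED, p_e, p_w)
    # sign flip without magnitude extremum: compare to mean ancestral magnitude
    state = ENHANCED if mag_a >= (mag_e + mag_w) / 2 else RELAXED
    return StateCall(triple.pair_id, state, p_e, p_w)


def classify_expression_state(mean_east: float, mean_west: float,
                              mean_adm: float) -> str:
    """Expression-level state from group means (closed ancestral interval)."""
    lo, hi = min(mean_east, mean_west), max(mean_east, mean_west)
    if lo <= mean_adm <= hi:
        return IDEAL
    return SPECIFIC_ABOVE if mean_adm > hi else SPECIFIC_BELOW


def estimate_effect_triple(pair_id: str, cohorts: dict[str, tuple],
                           n: int = DOWNSAMPLE_N, seed: int = 0) -> EffectTriple | None:
    """Fit per-cohort OLS effects on equal down-sampled groups.

    ``cohorts`` maps 'east'/'west'/'admixed' to (phenotype, dosage) arrays.
    Returns None when any cohort's dosage is constant in the subsample.
    """
    groups = {k: list(range(len(v[0]))) for k, v in cohorts.items()}
    subsets = downsample_equal(groups, n=n, seed=seed)
    fits = {}
    for name, (y, d) in cohorts.items():
        idx = subsets[name]
        res = associate(np.asarray(y, float)[idx], np.asarray(d, float)[idx])
        if res is None or res.se <= 0:
            return None
        fits[name] = res
    return EffectTriple(pair_id,
                        fits["east"].beta, fits["east"].se,
                        fits["west"].beta, fits["west"].se,
                        fits["admixed"].beta, fits["admixed"].se, n)
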