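"""Shared in-memory containers for the pipeline.

Coordinates are 0-based half-open everywhere inside the package; the VCF
boundary (1-based) is handled in :mod:`admixpress.io` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EAST = "EAST"
WEST = "WEST"

#: columns of a local-ancestry segment table (BED-like, 0-based half-open)
ANCESTRY_COLUMNS = ["chrom", "start", "end", "sample", "haplotype", "ancestry"]


@dataclass
class VariantTable:
    """Per-site metadata.

    ``sites`` is a DataFrame with at least columns ``id, chrom, pos, ref,
    alt`` (``pos`` 0-based); optional columns include ``ancestral`` (the
    ancestral allele), per-population frequencies and ``monomorphic`` flags.
    """

    sites: pd.DataFrame

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class HaplotypeSet:
    """Phased 0/1 haplotypes.

    ``haplotypes`` has shape (2 * n_individuals, n_sites); row ``2*i`` and
    ``2*i + 1`` are the two haplotypes of individual ``i``. ``positions``
    are 0-based base-pair coordinates and ``map_pos`` genetic positions in
    Morgans, both non-decreasing.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    map_pos: np.ndarray | None = None
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even (two per individual)")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.map_pos is not None:
            self.map_pos = np.asarray(self.map_pos, dtype=float)
        if not self.samples:
            self.samples = [f"S{i:04d}" for i in range(self.n_individuals)]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def dosages(self) -> np.ndarray:
        """Alternative-allele dosage matrix, shape (n_individuals, n_sites)."""
        h = self.haplotypes
        return (h[0::2] + h[1::2]).astype(np.int8)

    def allele_frequencies(self) -> np.ndarray:
        """Per-site frequency of allele 1 across all haplotypes."""
        return self.haplotypes.mean(axis=0)


def empty_ancestry_table() -> pd.DataFrame:
    return pd.DataFrame(columns=ANCESTRY_COLUMNS)
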