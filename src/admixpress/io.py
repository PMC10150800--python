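"""Readers and writers for the pipeline's file formats.

Dialects: phased VCF v4.2 ("|"-separated GT); expression TSV (first column
gene id, then sample columns); ASE TSV (chrom, pos, ref, alt, sample,
refCount, altCount); local-ancestry BED (0-based half-open: chrom, start,
end, sample, haplotype 0/1, ancestry EAST/WEST). Internal coordinates are
0-based half-open; the 1-based VCF convention is converted here and only
here. Result files carry '#' header comments (version, seed, thresholds)
which all readers skip.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .containers import ANCESTRY_COLUMNS, HaplotypeSet, VariantTable


def write_vcf(path, haps: HaplotypeSet, variants: pd.DataFrame) -> None:
    """Minimal phased VCF v4.2 for a haplotype panel (text, uncompressed)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=admixpress {__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(haps.samples) + "\n")
        H = haps.haplotypes
        for s, row in enumerate(variants.itertuples(index=False)):
            gts = "\t".join(f"{H[2 * i, s]}|{H[2 * i + 1, s]}"
                            for i in range(haps.n_individuals))
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotypes(vcf_path, sample_subset: list[str] | None = None,
                   require_phased: bool = False) -> tuple[HaplotypeSet, VariantTable]:
    """Load a biallelic VCF into haplotypes + variant metadata.

    Multi-allelic records are skipped (they must be split upstream).
    Unphased genotypes are accepted for dosage-only use; with
    ``require_phased`` they raise instead. 1-based VCF positions become
    0-based internally.
    """
    vcf = VCF(str(vcf_path))
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in vcf.samples]
        if missing:
            raise ValueError(f"samples not in VCF: {missing}")
        vcf.set_samples(sample_subset)
    samples = list(vcf.samples)
    hap_rows, meta = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        if require_phased and not all(g[2] for g in gts):
            raise ValueError(
                f"unphased genotype at {rec.CHROM}:{rec.POS} — phased input required")
        hap_rows.append([a for g in gts for a in (g[0], g[1])])
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM,
                     rec.POS - 1, rec.REF, rec.ALT[0]))
    sites = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    hap = np.array(hap_rows, dtype=np.int8).T if hap_rows \
        else np.zeros((2 * len(samples), 0), dtype=np.int8)
    return (HaplotypeSet(hap, sites["pos"].to_numpy(), samples=samples),
            VariantTable(sites))


def _header(seed=None, thresholds: dict | None = None) -> str:
    parts = [f"# admixpress {__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    for key, val in (thresholds or {}).items():
        parts.append(f"# {key}: {val}")
    return "\n".join(parts) + "\n"


def write_table(path, table: pd.DataFrame, seed=None,
                thresholds: dict | None = None, index: bool = False) -> None:
    """TSV with provenance header comments."""
    with open(path, "w") as fh:
        fh.write(_header(seed, thresholds))
        # repr() round-trips IEEE doubles exactly and keeps the decimal
        # point (so float columns stay float on re-read)
        table.to_csv(fh, sep="\t", index=index,
                     float_format=lambda v: repr(float(v)))


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip", **kwargs)


def write_expression(path, expression: pd.DataFrame, seed=None) -> None:
    """Expression TSV: first column gene id, then sample columns."""
    out = expression.copy()
    out.insert(0, "gene", out.index)
    write_table(path, out, seed=seed)


def read_expression(path) -> pd.DataFrame:
    table = read_table(path)
    if table["gene"].duplicated().any():
        dup = table.loc[table["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicated gene ids: {dup}")
    return table.set_index("gene").rename_axis(None)


def write_ase(path, ase: pd.DataFrame, seed=None) -> None:
    """ASE TSV with columns chrom, pos, ref, alt, sample, refCount, altCount."""
    cols = ["chrom", "pos", "ref", "alt", "sample", "refCount", "altCount"]
    write_table(path, ase[cols], seed=seed)


def read_ase(path) -> pd.DataFrame:
    table = read_table(path)
    if (table["refCount"] < 0).any() or (table["altCount"] < 0).any():
        raise ValueError("negative read counts in ASE table")
    return table


def write_ancestry_bed(path, track: pd.DataFrame, seed=None) -> None:
    write_table(path, track[ANCESTRY_COLUMNS], seed=seed)


def read_ancestry_bed(path) -> pd.DataFrame:
    track = read_table(path, names=ANCESTRY_COLUMNS, header=0)
    if (track["start"] >= track["end"]).any():
        bad = track[track["start"] >= track["end"]]
        raise ValueError(f"empty/inverted BED segments:\n{bad}")
    for (sample, hap), seg in track.groupby(["sample", "haplotype"]):
        seg = seg.sort_values("start")
        if (seg["start"].to_numpy()[1:] < seg["end"].to_numpy()[:-1]).any():
            raise ValueError(
                f"overlapping ancestry segments for sample {sample} haplotype {hap}")
    return track


def summarize_classification(numerator: int, denominator: int,
                             decimals: int = 2) -> dict:
    """Category summary with half-up rounded percentage.

    E.g. (39854, 921872) at 2 decimals -> 4.32; (1067, 8913) at 0 -> 12.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    exact = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    pct = exact.quantize(quantum, rounding=ROUND_HALF_UP)
    value = float(pct) if decimals > 0 else int(pct)
    return {"numerator": numerator, "denominator": denominator,
            "percentage": value}
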