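"""End-to-end pipeline over a simulated admixed cohort.

`run_pipeline` chains simulation -> differentiation -> admixture-frequency
deviation -> cis-QTL mapping -> ASE -> iHS -> ancestry-expression ->
state model, writing one TSV per stage, a JSON summary of the
classification counts, and a log of seeds and thresholds. Reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ancestry, ase, daf, fst, io, qtl, selection, sim, states


@dataclass
class RunConfig:
    """Declarative run configuration; unknown keys are rejected."""

    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    fst_threshold: float = 0.2
    origin_threshold: float = 0.2
    es_threshold: float = 5.0
    ihs_threshold: float = 2.0
    ase_min_depth: int = 20
    alpha: float = 0.05
    qtl_window_bp: int = 1_000_000
    aseqtl_window_bp: int = 100_000
    eqtas_window_bp: int = 1_000_000
    high_deviation: float = 0.1
    max_ase_sites: int = 60
    max_eqtas_genes: int = 5
    state_downsample_n: int = 40

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim_part = data.pop("sim", {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in fields(sim.SimConfig)}
        sim_unknown = set(sim_part) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
        return cls(sim=sim.SimConfig(**sim_part), **data)

    def thresholds(self) -> dict:
        return {"fst_threshold": self.fst_threshold,
                "origin_threshold": self.origin_threshold,
                "es_threshold": self.es_threshold,
                "ihs_threshold": self.ihs_threshold,
                "ase_min_depth": self.ase_min_depth,
                "alpha": self.alpha}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_differentiation(cohort, cfg, out, log):
    table = fst.fst_from_haplotypes(cohort.hap_east.haplotypes,
                                    cohort.hap_west.haplotypes)
    table.insert(0, "id", cohort.variants["id"].to_numpy())
    table["hds"] = (table["fst"] > cfg.fst_threshold).fillna(False)
    io.write_table(out / "site_fst.tsv", table, cfg.sim.seed, cfg.thresholds())

    site_fsts = [fst.SiteFst(r.id, r.a, r.b, r.c,
                             None if np.isnan(r.fst) else r.fst)
                 for r in table.itertuples(index=False)]
    pos = dict(zip(cohort.variants["id"],
                   zip(cohort.variants["chrom"], cohort.variants["pos"])))
    genes = fst.gene_fst(site_fsts, cohort.genes, pos)
    gene_table = pd.DataFrame(
        [(g.gene_id, g.mean_fst, g.weighted_fst, g.n_sites,
          g.defined and fst.classify_hdg(g, cfg.fst_threshold))
         for g in genes],
        columns=["gene", "mean_fst", "weighted_fst", "n_sites", "hdg"])
    io.write_table(out / "gene_fst.tsv", gene_table, cfg.sim.seed)
    log.append(f"differentiation: {int(table['hds'].sum())} HDS of "
               f"{len(table)} sites; {int(gene_table['hdg'].sum())} HDG")
    return table, gene_table


def _stage_daf(cohort, site_table, cfg, out, log):
    sites = cohort.variants.copy()
    sites["ancestral"] = cohort.ancestral_alleles["ancestral"].to_numpy()
    sites["freq_east"] = cohort.hap_east.allele_frequencies()
    sites["freq_west"] = cohort.hap_west.allele_frequencies()
    sites["freq_admixed"] = cohort.hap_admixed.allele_frequencies()
    table = daf.daf_table(sites, cfg.sim.alpha_west, cfg.origin_threshold)
    table["high_deviation"] = table["deviation"] > cfg.high_deviation
    io.write_table(out / "daf.tsv", table, cfg.sim.seed)
    log.append(f"daf: {int(table['high_deviation'].sum())} sites above the "
               f"{cfg.high_deviation} deviation tier")
    return table


def _stage_qtl(cohort, cfg, out, log):
    dosages = pd.DataFrame(cohort.hap_admixed.dosages().T,
                           index=cohort.variants["id"],
                           columns=cohort.hap_admixed.samples)
    table = qtl.map_cis_qtl(cohort.expression, dosages, cohort.variants,
                            cohort.genes, cfg.qtl_window_bp)
    if len(table):
        table["high_effect"] = table["beta"].abs() > cfg.es_threshold
        table["significant"] = table["q"] < cfg.alpha
    else:
        table["high_effect"] = []
        table["significant"] = []
    io.write_table(out / "qtl.tsv", table, cfg.sim.seed)
    log.append(f"qtl: {len(table)} tested pairs, "
               f"{int(table['significant'].sum())} significant, "
               f"{int(table['high_effect'].sum())} high-effect")
    return table, dosages


def _stage_ase(cohort, site_table, dosages, cfg, out, log):
    dos = dosages  # variants x samples
    hds_ids = site_table.loc[site_table["hds"], "id"].tolist()
    chosen = hds_ids[: cfg.max_ase_sites]
    het_rows = []
    for vid in chosen:
        het_samples = dos.columns[dos.loc[vid] == 1]
        for s in het_samples:
            het_rows.append((vid, s))
    het = pd.DataFrame(het_rows, columns=["site", "sample"])
    if het.empty:
        for name in ("ase_calls.tsv", "aseqtl.tsv", "ase_drivers.tsv"):
            io.write_table(out / name, pd.DataFrame(), cfg.sim.seed)
        log.append("ase: no heterozygous HDS site-samples")
        return pd.DataFrame(), pd.DataFrame()
    # half the chosen sites carry the injected imbalance, half are null
    imbalanced = {vid for i, vid in enumerate(chosen) if i % 2 == 0}
    ai = np.where(het["site"].isin(imbalanced), cfg.sim.ai_truth, 0.0)
    counts = sim.simulate_ase_counts(het, ai, cfg.sim.ase_depth, cfg.sim.seed)
    anc_is_ref = {vid: True for vid in chosen}  # simulated ancestral = REF
    calls = ase.call_ase(counts, anc_is_ref, cfg.ase_min_depth, cfg.alpha)
    io.write_table(out / "ase_calls.tsv", calls, cfg.sim.seed)

    hits_rows, driver_rows = [], []
    sig_sites = calls.loc[calls["significant"], "site"].unique()
    pos_by_id = dict(zip(cohort.variants["id"], cohort.variants["pos"]))
    for vid in sig_sites:
        het_s = calls.loc[calls["site"] == vid, "sample"].tolist()
        ai_by_s = dict(zip(calls.loc[calls["site"] == vid, "sample"],
                           calls.loc[calls["site"] == vid, "ai"]))
        hits = ase.aseqtl_scan(pos_by_id[vid], het_s, ai_by_s,
                               cohort.variants, dos,
                               cfg.aseqtl_window_bp, cfg.alpha)
        n_hits = int(hits["hit"].sum()) if len(hits) else 0
        hits.insert(0, "ase_site", vid)
        hits_rows.append(hits)
        driver = ase.classify_ase_driver(vid, n_hits, None)
        driver_rows.append((vid, driver.driver_class, n_hits))
    hits_rows = [h for h in hits_rows if len(h)]
    aseqtl_table = (pd.concat(hits_rows, ignore_index=True)
                    if hits_rows else pd.DataFrame())
    drivers = pd.DataFrame(driver_rows, columns=["site", "driver", "n_hits"])
    io.write_table(out / "aseqtl.tsv", aseqtl_table, cfg.sim.seed)
    io.write_table(out / "ase_drivers.tsv", drivers, cfg.sim.seed)
    log.append(f"ase: {len(calls)} tested site-samples, "
               f"{len(sig_sites)} significant ASE sites")
    return calls, drivers


def _stage_selection(cohort, site_table, cfg, out, log):
    hds_idx = np.flatnonzero(site_table["hds"].to_numpy())
    H = cohort.hap_admixed.haplotypes
    sub = H[:, hds_idx]
    mp = cohort.hap_admixed.map_pos[hds_idx]
    scan = selection.ihs_scan(sub, np.ones(len(hds_idx), dtype=bool), mp)
    scan["site"] = cohort.variants["id"].to_numpy()[hds_idx]
    io.write_table(out / "ihs.tsv", scan, cfg.sim.seed)
    n_def = int(scan["ihs_z"].notna().sum())
    log.append(f"selection: {int(scan['sweep_flag'].sum())} sweep flags "
               f"among {n_def} scored HDS")
    return scan


def _stage_ancestry(cohort, cfg, out, log):
    mids = (cohort.genes["start"] + cohort.genes["end"]) // 2
    loci = pd.DataFrame({"id": cohort.genes["gene"],
                         "chrom": cohort.genes["chrom"], "pos": mids})
    dosage = ancestry.ancestry_dosage_matrix(cohort.ancestry_track, loci,
                                             cohort.hap_admixed.samples)
    likeg = ancestry.find_ancestral_like_genes(cohort.expression, dosage,
                                               cfg.alpha)
    io.write_table(out / "ancestral_like_genes.tsv", likeg, cfg.sim.seed)

    eqtas_rows = []
    sig = likeg.loc[likeg["significant"], "gene"].tolist()[: cfg.max_eqtas_genes]
    for gene in sig:
        row = cohort.genes.set_index("gene").loc[gene]
        segs = ancestry.segments_in_window(cohort.ancestry_track, row["chrom"],
                                           int(row["start"]), int(row["end"]),
                                           cfg.eqtas_window_bp)
        seg_dos = ancestry.ancestry_dosage_matrix(cohort.ancestry_track, segs,
                                                  cohort.hap_admixed.samples)
        res = ancestry.eqtas_scan(cohort.expression.loc[gene].to_numpy(),
                                  seg_dos, cfg.alpha)
        res.insert(0, "gene", gene)
        eqtas_rows.append(res)
    eqtas = pd.concat(eqtas_rows, ignore_index=True) if eqtas_rows else pd.DataFrame()
    io.write_table(out / "eqtas.tsv", eqtas, cfg.sim.seed)
    log.append(f"ancestry: {int(likeg['significant'].sum()) if len(likeg) else 0} "
               f"ancestral-like genes")
    return likeg, eqtas


def _stage_states(cohort, cfg, out, log):
    n_sites = cohort.hap_east.n_sites
    east_all = np.ones((cohort.hap_east.n_haplotypes, n_sites), dtype=bool)
    west_all = np.zeros((cohort.hap_west.n_haplotypes, n_sites), dtype=bool)
    expr_e = sim.simulate_expression(cohort.hap_east, east_all,
                                     cfg.sim.eqtl_effects, [], cfg.sim.n_genes,
                                     cfg.sim.noise_sd, cfg.sim.seed + 1)
    expr_w = sim.simulate_expression(cohort.hap_west, west_all,
                                     cfg.sim.eqtl_effects, [], cfg.sim.n_genes,
                                     cfg.sim.noise_sd, cfg.sim.seed + 2)
    rows = []
    for k, (g, s, b_e, b_w) in enumerate(cfg.sim.eqtl_effects):
        gene = f"G{g:04d}"
        cohorts = {
            "east": (expr_e.loc[gene].to_numpy(),
                     cohort.hap_east.dosages()[:, s]),
            "west": (expr_w.loc[gene].to_numpy(),
                     cohort.hap_west.dosages()[:, s]),
            "admixed": (cohort.expression.loc[gene].to_numpy(),
                        cohort.hap_admixed.dosages()[:, s]),
        }
        try:
            triple = states.estimate_effect_triple(
                f"{cohort.variants['id'][s]}:{gene}", cohorts,
                n=cfg.state_downsample_n, seed=cfg.sim.seed + k)
        except ValueError:
            triple = None
        if triple is None:
            continue
        call = states.classify_effect_state(triple, cfg.alpha)
        rows.append((call.pair_id, triple.b_east, triple.b_west, triple.b_adm,
                     call.state, call.p_het_vs_east, call.p_het_vs_west))
    table = pd.DataFrame(rows, columns=["pair", "b_east", "b_west", "b_adm",
                                        "state", "p_vs_east", "p_vs_west"])
    io.write_table(out / "states.tsv", table, cfg.sim.seed)
    log.append(f"states: {len(table)} classified pairs")
    return table


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage on one simulated cohort; returns the summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"admixpress {__version__}",
                      f"seed: {config.sim.seed}",
                      f"thresholds: {config.thresholds()}"]
    stage = "simulate"
    try:
        cohort = sim.simulate_cohort(config.sim)
        log.append(f"simulate: {config.sim.n_sites} sites, "
                   f"{config.sim.n_admixed} admixed individuals")
        stage = "differentiation"
        site_table, gene_table = _stage_differentiation(cohort, config, out, log)
        stage = "admixture_frequency"
        daf_table = _stage_daf(cohort, site_table, config, out, log)
        stage = "qtl"
        qtl_table, dosages = _stage_qtl(cohort, config, out, log)
        stage = "ase"
        ase_calls, drivers = _stage_ase(cohort, site_table, dosages, config,
                                        out, log)
        stage = "selection"
        ihs_table = _stage_selection(cohort, site_table, config, out, log)
        stage = "ancestry_expression"
        likeg, eqtas = _stage_ancestry(cohort, config, out, log)
        stage = "state_model"
        state_table = _stage_states(cohort, config, out, log)
    except Exception as exc:  # abort with stage provenance
        raise StageError(stage, exc) from exc

    n_sites = len(site_table)
    n_hds = int(site_table["hds"].sum())
    hds_set = set(site_table.loc[site_table["hds"], "id"])
    sig_qtl_sites = set(qtl_table.loc[qtl_table["significant"], "variant"]) \
        if len(qtl_table) else set()
    summary = {
        "version": __version__,
        "seed": config.sim.seed,
        "counts": {
            "sites": n_sites,
            "hds": n_hds,
            "hdg": int(gene_table["hdg"].sum()),
            "tested_pairs": int(len(qtl_table)),
            "significant_qtl_pairs": int(qtl_table["significant"].sum())
            if len(qtl_table) else 0,
            "high_effect_pairs": int(qtl_table["high_effect"].sum())
            if len(qtl_table) else 0,
            "significant_ase_sites":
            int(ase_calls.loc[ase_calls["significant"], "site"].nunique())
            if len(ase_calls) else 0,
            "sweep_flags": int(ihs_table["sweep_flag"].sum()),
            "ancestral_like_genes": int(likeg["significant"].sum())
            if len(likeg) else 0,
            "high_deviation_sites": int(daf_table["high_deviation"].sum()),
        },
        "percentages": {},
        "state_counts": {} if state_table.empty else
        {k: int(v) for k, v in
         state_table["state"].value_counts().sort_index().items()},
    }
    if n_hds:
        summary["percentages"]["hds_eqtl"] = io.summarize_classification(
            len(hds_set & sig_qtl_sites), n_hds)
        summary["percentages"]["hds_sweep"] = io.summarize_classification(
            int(ihs_table["sweep_flag"].sum()), n_hds)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return summary
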