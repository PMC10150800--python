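"""Shared configuration for the numbered analysis drivers."""

from pathlib import Path

from admixpress import pipeline, sim

RESULTS = Path(__file__).resolve().parent.parent / "results"


def demo_config(seed: int = 7) -> pipeline.RunConfig:
    """The demonstration study: 2000 sites, 90 admixed individuals, F=0.2,
    equal ancestry, three planted cis effects and one ancestry effect."""
    base = sim.SimConfig(n_anc_east=60, n_anc_west=60, n_admixed=90,
                         n_sites=2000, n_genes=20, fst_sim=0.2,
                         alpha_west=0.5, generations=30.0, seed=seed)
    variants, genes = sim.random_layout(base)
    base.eqtl_effects = [
        (0, sim.nearest_site_to_gene(variants, genes, 0), 1.5, 0.5),
        (1, sim.nearest_site_to_gene(variants, genes, 1), 2.0, 2.0),
        (2, sim.nearest_site_to_gene(variants, genes, 2), 6.0, 6.0),
    ]
    base.ancestry_effects = [(3, 1.0)]
    return pipeline.RunConfig(sim=base)
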