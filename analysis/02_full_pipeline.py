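"""Run every analysis stage on the demonstration cohort.

Chains differentiation (HDS/HDG), admixture-frequency deviation, cis-QTL
mapping, ASE calling with the aseQTL scan, the iHS selection scan over
HDSs, ancestry-expression association and the expression state model.
Per-stage TSVs, summary JSON and the run log land in results/pipeline/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import demo_config, RESULTS

from admixpress import pipeline


def main() -> None:
    summary = pipeline.run_pipeline(demo_config(seed=7), RESULTS / "pipeline")
    counts = summary["counts"]
    print(f"{counts['hds']} HDS of {counts['sites']} sites; "
          f"{counts['hdg']} HDG")
    print(f"{counts['significant_qtl_pairs']} significant cis-QTL pairs of "
          f"{counts['tested_pairs']} tested "
          f"({counts['high_effect_pairs']} with |beta| > 5)")
    print(f"{counts['significant_ase_sites']} significant ASE sites; "
          f"{counts['sweep_flags']} sweep flags; "
          f"{counts['ancestral_like_genes']} ancestral-like genes")
    print("state calls:", json.dumps(summary["state_counts"]))
    print(f"tables under {RESULTS / 'pipeline'}")


if __name__ == "__main__":
    main()
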