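#!/usr/bin/env python
"""Generate the synthetic study the downstream analyses run on.

Emulates the real study's shape — a diabetes-like exposure GWAS (FinnGen
scale), an aplastic-anemia-like outcome GWAS (IEU scale), a 731-trait immune
mediator panel of which 54 carry real exposure effects, and a mediation
triangle with total effect 0.11 = direct 0.0983 + (-0.13 x -0.09). Full
summary-statistic tables go to scratch/ (they are bulky and regenerable);
results/ receives the truth manifest and the canonical test fixture suite.
"""

import json
from pathlib import Path

from mrpath.simulate import SimTruth, simulate_mediation_triangle, write_fixture_suite
from mrpath.summary_stats import write_gwas_table

STUDY_SEED = 20_250_822
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    truth = SimTruth(seed=STUDY_SEED, n_decoys=730, n_nonnull_decoys=53)
    bundle = simulate_mediation_triangle(truth)

    scratch = ROOT / "scratch" / "study"
    scratch.mkdir(parents=True, exist_ok=True)
    write_gwas_table(bundle.exposure, scratch / "exposure.tsv")
    write_gwas_table(bundle.outcome, scratch / "outcome.tsv")
    for mid, table in bundle.mediators.items():
        write_gwas_table(table, scratch / f"{mid}.tsv")
    bundle.ld.write(scratch / "ld_pairs.tsv", scratch / "ld_positions.tsv")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    manifest = {
        "seed": STUDY_SEED,
        "truth": truth.__dict__,
        "n_mediators": len(bundle.mediators),
        "n_nonnull_mediators": sum(1 for p in bundle.mediator_phis.values() if p != 0),
        "tables_dir": "scratch/study",
    }
    with open(results / "study_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    fixtures = write_fixture_suite(ROOT / "scratch" / "fixtures")
    print(f"simulated study: {len(bundle.mediators)} mediator traits, "
          f"{bundle.exposure.records.shape[0]} variants -> {scratch}")
    print(f"fixture suite: {len(fixtures['fixtures'])} fixtures -> scratch/fixtures")
    print(f"truth manifest -> {results / 'study_truth.json'}")


if __name__ == "__main__":
    main()
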