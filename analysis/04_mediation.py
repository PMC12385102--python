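#!/usr/bin/env python
"""Step 3: two-step mediation MR over the 731-trait mediator panel.

Screens every simulated immune-cell-like trait for an exposure effect
(triangulation rule, no multiplicity correction — an exploratory screen),
estimates each survivor's conditional effect on the outcome by multivariable
MR, and decomposes the total effect by the product of coefficients. The
generating triangle (phi -0.13, psi -0.09, total 0.11) implies a mediated
proportion of 10.64%; the run reports the panel-wide tallies and the
decomposition for every mediator passing both steps.
"""

from pathlib import Path

from mrpath.pipeline import PipelineConfig, run_mediation_study, run_uvmr_study
from mrpath.simulate import SimTruth, simulate_mediation_triangle

STUDY_SEED = 20_250_822
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    truth = SimTruth(seed=STUDY_SEED, n_decoys=730, n_nonnull_decoys=53)
    bundle = simulate_mediation_triangle(truth)
    config = PipelineConfig(seed=STUDY_SEED)

    total = run_uvmr_study(bundle.exposure, bundle.outcome, bundle.ld, config).ivw
    rep = run_mediation_study(
        bundle.exposure, bundle.outcome, bundle.mediators, bundle.ld, config,
        total_effect=total,
    )
    rep.write(results / "mediation")

    t = rep.tallies
    print(f"screened {t['mediators_in']} traits -> {t['screen_hits']} passed step 1 "
          f"(54 carry true effects); {t['decomposed']} passed step 2 and were decomposed")
    table = rep.table()
    print(table.to_string(index=False))
    if "mediator_target" in set(table["mediator"]):
        row = table.set_index("mediator").loc["mediator_target"]
        print(f"\ntarget mediator: mediated proportion "
              f"{row['proportion_pct']:.2f}% (truth 10.64%), p = {row['pvalue']:.2e}")


if __name__ == "__main__":
    main()
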