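"""Generate the synthetic two-sample study data.

Simulates GWAS summary statistics for a binary exposure, one metabolic
mediator and one disease outcome from the mediation structural model at
the study-scale truth (theta_XY = 0.10, theta_XM = 0.385, theta_MY =
0.19, cohorts of 300k), and writes the three summary-stats tables plus
the generating truth under results/simdata/.

Run from the repository root:  python analysis/01_simulate_cohorts.py [seed]
"""

import json
import sys
from pathlib import Path

import mrkit as mk

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = Path("results/simdata")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = mk.simulate_study(mk.SimConfig(), seed=SEED)
    for tbl in (bundle.exposure, bundle.mediator, bundle.outcome):
        mk.write_sumstats(tbl, OUT / f"{tbl.trait_label}.tsv")
    truth = bundle.truth
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "seed": SEED,
                "theta_XY": truth.config.theta_XY,
                "theta_XM": truth.config.theta_XM,
                "theta_MY": truth.config.theta_MY,
                "theta_total": truth.theta_total,
                "true_mediated_proportion": truth.true_mediated_proportion,
                "n_exposure_instruments": len(truth.exposure_instrument_ids),
                "n_mediator_instruments": len(truth.mediator_instrument_ids),
            },
            indent=2,
        )
    )
    print(
        f"wrote {len(bundle.exposure)}-variant tables for exposure/mediator/"
        f"outcome to {OUT}; true total effect "
        f"{truth.theta_total:.4f} (OR {2.718281828**truth.theta_total:.2f}), "
        f"true mediated proportion {100 * truth.true_mediated_proportion:.2f}%"
    )


if __name__ == "__main__":
    main()
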