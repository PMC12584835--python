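"""Two-step mediation analysis of the simulated study.

Runs the full design over the tables from 01_simulate_cohorts.py: total
effect (beta0), exposure -> mediator (beta1), mediator -> outcome
controlling for the exposure via multivariable MR (beta2), and the
delta-method decomposition indirect = beta1*beta2, mediated proportion =
indirect/beta0.  Compares the recovered proportion with the generating
truth recorded in truth.json and writes results/mediation_table.tsv.

Run from the repository root:  python analysis/03_mediation_decomposition.py [seed]
"""

import json
import sys
from pathlib import Path

import mrkit as mk

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
SIM = Path("results/simdata")
OUT = Path("results")


def main() -> None:
    exposure = mk.read_sumstats(SIM / "exposure.tsv", trait_label="exposure")
    mediator = mk.read_sumstats(SIM / "mediator.tsv", trait_label="mediator")
    outcome = mk.read_sumstats(SIM / "outcome.tsv", trait_label="outcome")
    truth = json.loads((SIM / "truth.json").read_text())

    res = mk.run_study(
        exposure, [mediator], [outcome], mk.AnalysisOptions(seed=SEED), out_dir=OUT
    )
    if not res.mediation:
        print("no mediation pathway passed the screening criteria")
        print("errors:", res.errors)
        return
    m = res.mediation[0]
    lo, hi = m.proportion_ci
    print(
        f"beta0 (total)    = {m.beta0:.4f} +/- {m.beta0_se:.4f}\n"
        f"beta1 (X -> M)   = {m.beta1:.4f} +/- {m.beta1_se:.4f}\n"
        f"beta2 (M -> Y|X) = {m.beta2:.4f} +/- {m.beta2_se:.4f}\n"
        f"indirect = beta1*beta2 = {m.indirect:.4f}; "
        f"direct = {m.direct:.4f} (direct + indirect = beta0 exactly)\n"
        f"mediated proportion = {100 * m.proportion:.2f}% "
        f"(95% CI {100 * lo:.2f}%, {100 * hi:.2f}%)\n"
        f"generative truth     = {100 * truth['true_mediated_proportion']:.2f}%"
    )


if __name__ == "__main__":
    main()
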