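"""Repeated-simulation calibration of the pipeline.

Three experiments, each re-simulating the study many times:

1. mediated-proportion recovery — does the two-step pipeline's mean
   proportion match the generative truth, and do the delta-method 95%
   CIs cover it about 95% of the time?
2. null calibration — type-I error of the IVW, Egger-slope and
   Egger-intercept tests under a valid-instrument null;
3. reverse-MR null — rejection rate of the reverse IVW test when no
   reverse effect exists.

Writes results/calibration.json.  Replicate counts are kept at desk
scale (hundreds); pass [reps] to change.

Run from the repository root:  python analysis/04_calibration_study.py [seed] [reps]
"""

import json
import sys
from pathlib import Path

import numpy as np

import mrkit as mk
from mrkit import HarmonizedSet

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
REPS = int(sys.argv[2]) if len(sys.argv) > 2 else 200
OUT = Path("results")


def mediation_recovery(reps: int, seed: int) -> dict:
    cfg = mk.SimConfig(n_null=1000)
    props, covered = [], 0
    truth = None
    for rep in range(reps):
        b = mk.simulate_study(cfg, seed=seed * 1_000_000 + rep)
        truth = b.truth.true_mediated_proportion
        res = mk.run_study(
            b.exposure,
            [b.mediator],
            [b.outcome],
            mk.AnalysisOptions(seed=rep, sensitivity_estimators=False),
        )
        m = res.mediation[0]
        props.append(m.proportion)
        lo, hi = m.proportion_ci
        covered += lo <= truth <= hi
    return {
        "true_proportion": truth,
        "mean_estimated_proportion": float(np.mean(props)),
        "sd": float(np.std(props, ddof=1)),
        "ci_coverage": covered / reps,
        "reps": reps,
    }


def null_calibration(reps: int, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    n = 50
    hits = {"ivw": 0, "egger_slope": 0, "egger_intercept": 0}
    for _ in range(reps):
        gamma = rng.uniform(0.03, 0.15, n) * rng.choice([-1, 1], n)
        sx = np.full(n, 0.004)
        sy = rng.uniform(0.008, 0.02, n)
        h = HarmonizedSet.from_arrays(
            gamma + rng.normal(0, sx), sx, rng.normal(0, sy), sy
        )
        est, egg = mk.ivw(h), mk.egger(h)
        hits["ivw"] += est.pval < 0.05
        hits["egger_slope"] += egg.pval < 0.05
        hits["egger_intercept"] += egg.egger_intercept_pval < 0.05
    return {k: v / reps for k, v in hits.items()} | {"reps": reps}


def reverse_null(reps: int, seed: int) -> dict:
    cfg = mk.SimConfig(
        n_instruments=0, n_mediator_instruments=0,
        n_outcome_instruments=50, n_null=500,
    )
    hits = 0
    for rep in range(reps):
        b = mk.simulate_study(cfg, seed=seed * 1_000_000 + 500_000 + rep)
        res = mk.reverse_mr(
            b.outcome, b.exposure,
            mk.AnalysisOptions(seed=rep, sensitivity_estimators=False, n_sim=200),
        )
        hits += res.estimable and res.estimates["ivw"].pval < 0.05
    return {"rejection_rate": hits / reps, "reps": reps}


def main() -> None:
    out = {
        "mediation_recovery": mediation_recovery(REPS, SEED),
        "null_calibration": null_calibration(max(REPS, 1000), SEED),
        "reverse_null": reverse_null(REPS, SEED),
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "calibration.json").write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
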