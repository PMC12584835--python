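"""Two-step MR mediation: total effect, step-1/step-2 effects, decomposition.

The study design estimates, per exposure-mediator-outcome pathway:

* beta0 — total effect of the exposure on the outcome (univariable IVW
  after MR-PRESSO outlier removal),
* beta1 — effect of the exposure on the mediator (univariable IVW),
* beta2 — direct effect of the mediator on the outcome controlling for
  the exposure (multivariable IVW),

then decomposes: indirect = beta1*beta2, direct = beta0 - indirect, and
mediated proportion = indirect/beta0, with first-order delta-method
confidence intervals.  beta1 and beta2 come from separate regressions on
non-overlapping samples, so their covariance is taken as zero; the
proportion CI propagates the uncertainty in beta0 as well (optional).

A reverse (bidirectional) analysis re-runs the univariable pipeline with
exposure and outcome roles swapped.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError
from .instruments import InstrumentSet, LDMatrix, SelectionConfig, select_instruments
from .mvmr import MVMREstimate, build_mvmr_input, mvmr_ivw
from .presso import PressoResult, presso_test
from .sumstats import HarmonizedSet, SumStatsTable, harmonize
from .uvmr import Z95, MREstimate, estimate_all



@dataclass
class AnalysisOptions:
    """Estimation settings shared across pipeline stages."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    effects_model: str = "multiplicative_random"
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int | None = None
    alpha: float = 0.05
    run_presso: bool = True
    ld: LDMatrix | None = None
    exclusion_list: list[str] | None = None
    propagate_total_uncertainty: bool = True
    bonferroni_mediators: bool = False
    # run the bootstrap-based sensitivity estimators (median/mode/Egger)
    # alongside IVW; disable for large calibration simulations where only
    # the IVW point estimates feed the decomposition
    sensitivity_estimators: bool = True

    def stage_seed(self, *tags: str) -> int:
        """Deterministic child seed for a named pipeline stage."""
        base = 0 if self.seed is None else int(self.seed)
        codes = [zlib.crc32(t.encode()) for t in tags]
        h = np.random.SeedSequence([base, *codes])
        return int(h.generate_state(1)[0] % 2**31)


@dataclass
class PathwayEstimate:
    """Univariable pipeline output for one exposure-outcome pair."""

    exposure: str
    outcome: str
    instruments: InstrumentSet
    harmonized: HarmonizedSet
    presso: PressoResult | None
    estimates: dict[str, MREstimate]
    removed_outliers: list[str]

    @property
    def ivw(self) -> MREstimate:
        return self.estimates["ivw"]


def _univariable_pipeline(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    opts: AnalysisOptions,
    stage: str,
) -> PathwayEstimate:
    inst = select_instruments(
        exposure.restrict(exposure.variant_ids),
        ld=opts.ld,
        cfg=opts.selection,
        exclusion_list=opts.exclusion_list,
    )
    h = harmonize(exposure.restrict(inst.variant_ids), outcome)
    if h.n_snp < 3:
        raise AnalysisError(
            f"{exposure.trait_label} -> {outcome.trait_label}: fewer than 3 "
            "instruments after harmonization"
        )
    presso = None
    removed: list[str] = []
    if opts.run_presso and h.n_snp >= 4:
        presso = presso_test(
            h,
            n_sim=opts.n_sim,
            outlier_alpha=opts.alpha,
            seed=opts.stage_seed(stage, "presso"),
        )
        if presso.outlier_ids:
            removed = list(presso.outlier_ids)
            h = h.drop_variants(removed)
    if opts.sensitivity_estimators:
        estimates = estimate_all(
            h,
            seed=opts.stage_seed(stage, "estimators"),
            n_boot=opts.n_boot,
            effects_model=opts.effects_model,
        )
    else:
        from .uvmr import ivw

        estimates = {"ivw": ivw(h, effects_model=opts.effects_model)}
    return PathwayEstimate(
        exposure=exposure.trait_label,
        outcome=outcome.trait_label,
        instruments=inst,
        harmonized=h,
        presso=presso,
        estimates=estimates,
        removed_outliers=removed,
    )


def total_effect(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    opts: AnalysisOptions | None = None,
) -> PathwayEstimate:
    """Total exposure -> outcome effect (beta0 = the IVW estimate).

    Pipeline: instrument selection -> harmonization -> MR-PRESSO outlier
    removal -> all four estimators on the pruned set.
    """
    opts = opts or AnalysisOptions()
    return _univariable_pipeline(exposure, outcome, opts, "total")


def step1_effect(
    exposure: SumStatsTable,
    mediator: SumStatsTable,
    opts: AnalysisOptions | None = None,
) -> PathwayEstimate:
    """Exposure -> mediator effect (beta1), same univariable pipeline."""
    opts = opts or AnalysisOptions()
    return _univariable_pipeline(exposure, mediator, opts, "step1")


def step2_effect(
    exposure: SumStatsTable,
    mediator: SumStatsTable,
    outcome: SumStatsTable,
    opts: AnalysisOptions | None = None,
) -> MVMREstimate:
    """Mediator -> outcome direct effect controlling for the exposure (beta2)."""
    opts = opts or AnalysisOptions()
    inp = build_mvmr_input(
        [exposure, mediator],
        outcome,
        ld=opts.ld,
        cfg=opts.selection,
        exclusion_list=opts.exclusion_list,
    )
    ests = mvmr_ivw(inp, effects_model=opts.effects_model)
    by_label = {e.exposure: e for e in ests}
    return by_label[mediator.trait_label]


FLAG_INCONSISTENT_SIGN = "inconsistent_sign"
FLAG_PROPORTION_OUT_OF_UNIT_INTERVAL = "proportion_out_of_unit_interval"


@dataclass
class MediationResult:
    """Decomposition of a total effect into mediated and direct parts."""

    exposure: str
    mediator: str
    outcome: str
    beta0: float
    beta0_se: float
    beta1: float
    beta1_se: float
    beta2: float
    beta2_se: float
    indirect: float
    indirect_se: float
    direct: float
    proportion: float
    proportion_se: float
    proportion_ci: tuple[float, float]
    flags: set[str]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["proportion_ci"] = list(self.proportion_ci)
        d["flags"] = sorted(self.flags)
        return d


def mediation_decompose(
    beta0: float,
    beta0_se: float,
    beta1: float,
    beta1_se: float,
    beta2: float,
    beta2_se: float,
    alpha: float = 0.05,
    propagate_total_uncertainty: bool = True,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Delta-method decomposition of the mediated effect.

    indirect = beta1*beta2 with Var = beta1^2 se2^2 + beta2^2 se1^2
    (first-order, independent estimates); direct = beta0 - indirect;
    proportion = indirect/beta0 with the ratio delta method
    Var = Var(indirect)/beta0^2 + indirect^2 Var(beta0)/beta0^4
    (the beta0 term is dropped when ``propagate_total_uncertainty`` is
    off).  Flags record a mediated effect opposite in sign to the total
    effect and proportions outside [0, 1].
    """
    if beta0 == 0:
        raise AnalysisError("mediated proportion undefined: total effect is zero")
    z = float(stats.norm.ppf(1 - alpha / 2))
    indirect = beta1 * beta2
    var_ind = beta1**2 * beta2_se**2 + beta2**2 * beta1_se**2
    ind_se = float(np.sqrt(var_ind))
    direct = beta0 - indirect
    proportion = indirect / beta0
    var_prop = var_ind / beta0**2
    if propagate_total_uncertainty:
        var_prop += indirect**2 * beta0_se**2 / beta0**4
    prop_se = float(np.sqrt(var_prop))
    flags: set[str] = set()
    if indirect != 0 and np.sign(indirect) != np.sign(beta0):
        flags.add(FLAG_INCONSISTENT_SIGN)
    if not 0 <= proportion <= 1:
        flags.add(FLAG_PROPORTION_OUT_OF_UNIT_INTERVAL)
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        beta0=beta0,
        beta0_se=beta0_se,
        beta1=beta1,
        beta1_se=beta1_se,
        beta2=beta2,
        beta2_se=beta2_se,
        indirect=indirect,
        indirect_se=ind_se,
        direct=direct,
        proportion=proportion,
        proportion_se=prop_se,
        proportion_ci=(proportion - z * prop_se, proportion + z * prop_se),
        flags=flags,
    )


@dataclass
class ReverseResult:
    """Reverse-direction MR outcome; may be not-estimable."""

    exposure: str
    outcome: str
    estimable: bool
    reason: str = ""
    estimates: dict[str, MREstimate] | None = None
    no_significant_association: bool | None = None


def reverse_mr(
    former_outcome: SumStatsTable,
    former_exposure: SumStatsTable,
    opts: AnalysisOptions | None = None,
) -> ReverseResult:
    """Run the univariable pipeline with exposure and outcome roles swapped.

    Too few genome-wide-significant instruments for the former outcome is
    reported as not-estimable rather than raised.
    """
    opts = opts or AnalysisOptions()
    try:
        res = _univariable_pipeline(former_outcome, former_exposure, opts, "reverse")
    except AnalysisError as exc:
        return ReverseResult(
            exposure=former_outcome.trait_label,
            outcome=former_exposure.trait_label,
            estimable=False,
            reason=str(exc),
        )
    none_sig = all(e.pval >= opts.alpha for e in res.estimates.values())
    return ReverseResult(
        exposure=former_outcome.trait_label,
        outcome=former_exposure.trait_label,
        estimable=True,
        estimates=res.estimates,
        no_significant_association=none_sig,
    )


@dataclass
class StudyResult:
    """Bundle of all tables produced by :func:`run_study`."""

    forward: dict[str, PathwayEstimate]
    reverse: dict[str, ReverseResult]
    step1: dict[str, PathwayEstimate | str]
    step2: dict[tuple[str, str], MVMREstimate | str]
    mediation: list[MediationResult]
    errors: dict[str, str]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _estimates_frame(rows: list[dict]) -> pd.DataFrame:
    cols = [
        "exposure",
        "outcome",
        "method",
        "n_snp",
        "beta",
        "se",
        "pval",
        "or_value",
        "or_low",
        "or_high",
        "q_stat",
        "q_pval",
        "egger_intercept",
        "egger_intercept_pval",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_study(
    exposure: SumStatsTable,
    mediators: list[SumStatsTable],
    outcomes: list[SumStatsTable],
    opts: AnalysisOptions | None = None,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Execute the full bidirectional two-step mediation design.

    For every outcome: total effect (with sensitivity estimators) and
    reverse MR.  For every mediator: step-1 effect, and — when the
    mediator passes the screening criteria (beta1 significant, beta2
    significant, mediated effect sign-consistent with the total effect)
    — step-2 MVMR and the delta-method decomposition.  Stage failures
    are recorded per pathway; completed pathways are still reported.
    When ``out_dir`` is given, writes ``estimates_forward.tsv``,
    ``estimates_reverse.tsv``, ``mediators_step1.tsv``,
    ``mediators_step2.tsv``, ``mediation_table.tsv``, ``run_log.txt``
    and a JSON bundle.
    """
    opts = opts or AnalysisOptions()
    result = StudyResult({}, {}, {}, {}, [], {})
    log = result.log

    fwd_rows, rev_rows, s1_rows, s2_rows, med_rows = [], [], [], [], []

    for outc in outcomes:
        key = outc.trait_label
        try:
            pe = total_effect(exposure, outc, opts)
            result.forward[key] = pe
            log.append(
                f"total {exposure.trait_label}->{key}: "
                f"{pe.instruments.attrition.as_dict()}, "
                f"presso removed {pe.removed_outliers}"
            )
            for m, e in pe.estimates.items():
                fwd_rows.append(
                    {"exposure": exposure.trait_label, "outcome": key, **e.to_dict()}
                )
        except AnalysisError as exc:
            result.errors[f"total:{key}"] = str(exc)
            log.append(f"total {exposure.trait_label}->{key} failed: {exc}")

        rev = reverse_mr(outc, exposure, opts)
        result.reverse[key] = rev
        if rev.estimable:
            for m, e in rev.estimates.items():
                rev_rows.append({"exposure": key, "outcome": exposure.trait_label, **e.to_dict()})
            log.append(
                f"reverse {key}->{exposure.trait_label}: "
                + (
                    "no significant association"
                    if rev.no_significant_association
                    else "significant association detected"
                )
            )
        else:
            log.append(f"reverse {key}->{exposure.trait_label} not estimable: {rev.reason}")

    n_candidates = max(1, len(mediators))
    screen_alpha = (
        opts.alpha / n_candidates if opts.bonferroni_mediators else opts.alpha
    )

    for med in mediators:
        mkey = med.trait_label
        try:
            s1 = step1_effect(exposure, med, opts)
            result.step1[mkey] = s1
            for m, e in s1.estimates.items():
                s1_rows.append(
                    {"exposure": exposure.trait_label, "outcome": mkey, **e.to_dict()}
                )
        except AnalysisError as exc:
            result.step1[mkey] = f"error: {exc}"
            result.errors[f"step1:{mkey}"] = str(exc)
            continue

        for outc in outcomes:
            okey = outc.trait_label
            if okey not in result.forward:
                continue
            beta0_est = result.forward[okey].ivw
            try:
                s2 = step2_effect(exposure, med, outc, opts)
                result.step2[(mkey, okey)] = s2
                s2_rows.append(
                    {
                        "mediator": mkey,
                        "outcome": okey,
                        "beta": s2.beta,
                        "se": s2.se,
                        "pval": s2.pval,
                        "or_value": s2.or_value,
                        "or_low": s2.or_low,
                        "or_high": s2.or_high,
                        "n_snp": s2.n_snp,
                    }
                )
            except AnalysisError as exc:
                result.step2[(mkey, okey)] = f"error: {exc}"
                result.errors[f"step2:{mkey}:{okey}"] = str(exc)
                continue

            b1 = s1.ivw
            passes = (
                b1.pval < screen_alpha
                and s2.pval < screen_alpha
                and np.sign(b1.beta * s2.beta) == np.sign(beta0_est.beta)
            )
            if not passes:
                log.append(f"mediator {mkey} ({okey}): screening criteria not met")
                continue
            mr = mediation_decompose(
                beta0_est.beta,
                beta0_est.se,
                b1.beta,
                b1.se,
                s2.beta,
                s2.se,
                alpha=opts.alpha,
                propagate_total_uncertainty=opts.propagate_total_uncertainty,
                exposure=exposure.trait_label,
                mediator=mkey,
                outcome=okey,
            )
            result.mediation.append(mr)
            med_rows.append(mr.to_dict())
            log.append(
                f"mediation {mkey} ({okey}): proportion "
                f"{100 * mr.proportion:.2f}%"
            )

    result.tables = {
        "estimates_forward": _estimates_frame(fwd_rows),
        "estimates_reverse": _estimates_frame(rev_rows),
        "mediators_step1": _estimates_frame(s1_rows),
        "mediators_step2": pd.DataFrame(s2_rows),
        "mediation_table": pd.DataFrame(med_rows),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in result.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
        bundle = {
            "mediation": [m.to_dict() for m in result.mediation],
            "errors": result.errors,
        }
        (out / "study.json").write_text(json.dumps(bundle, indent=2, default=str))
    return result
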