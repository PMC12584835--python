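"""Synthetic two-sample GWAS summary statistics from a known mediation model.

The generative structural model has one exposure X, one mediator M and
one outcome Y with causal coefficients

    theta_XM : X -> M        theta_MY : M -> Y        theta_XY : X -> Y (direct)

so the total X -> Y effect is theta_XY + theta_XM * theta_MY and the
true mediated proportion is theta_XM*theta_MY / theta_total.  Each
variant j carries an instrument effect gamma_j on X, an optional direct
(horizontally pleiotropic) effect alpha_j on Y, and an effect delta_j on
M; a block of mediator-specific instruments has delta_j != 0 with
gamma_j = 0, which is what makes the mediator identifiable in
multivariable MR.  The implied true marginal effects are

    b_X,j = gamma_j
    b_M,j = theta_XM * gamma_j + delta_j
    b_Y,j = theta_total * gamma_j + theta_MY * delta_j + alpha_j

Summary statistics are simulated directly at the summary level: each
cohort observes effect estimates drawn independently as
normal(true effect, se^2) with the unit-variance-trait approximation
se = 1/sqrt(2 n eaf (1-eaf)).  Three independent random streams model
the non-overlapping exposure, mediator and outcome cohorts of a
two-sample design.  Binary traits are represented on the log-odds scale
under the same normal sampling model.

Instrument strengths are controlled through the per-variant F statistic:
the target F for each instrument is drawn as f_floor + Exponential(mean
= f_mean - f_floor), and |gamma_j| is set to se_j * sqrt(F_j - 1) so the
expected observed F equals the drawn target.  The default floor keeps
planted instruments reliably genome-wide significant while the mean
matches a typical strong-instrument GWAS regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .instruments import LDMatrix
from .sumstats import CANONICAL_COLUMNS, SumStatsTable


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults encode the regime of the motivating application: a binary
    exposure (log-odds units) with ~100 independent genome-wide-
    significant instruments in cohorts of ~300k, a mediator with its own
    instruments, structural coefficients theta_XY = 0.10, theta_XM =
    0.385 (log 1.47) and theta_MY = 0.19 (log 1.21), hence a true
    mediated proportion of about 42%.
    """

    n_instruments: int = 100          # exposure instruments (gamma != 0)
    n_mediator_instruments: int = 100  # mediator-specific instruments (delta != 0)
    n_outcome_instruments: int = 0     # outcome-specific instruments (eta != 0)
    n_null: int | None = None          # defaults to 10x the signal count
    theta_XM: float = 0.385
    theta_MY: float = 0.19
    theta_XY: float = 0.10
    n_x: int = 300_000
    n_m: int = 300_000
    n_y: int = 300_000
    f_mean: float = 60.0
    f_floor: float = 35.0
    pi_pleio: float = 0.0
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.05
    # reverse-direction structural effect (outcome back onto the exposure)
    theta_YX: float = 0.0
    n_chrom: int = 22
    chrom_span_bp: int = 250_000_000
    clump_window_kb: int = 10_000
    ld_block_size: int = 1
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.pi_pleio <= 1:
            raise ConfigurationError("pi_pleio must lie in [0, 1]")
        if min(self.n_x, self.n_m, self.n_y) <= 0:
            raise ConfigurationError("cohort sizes must be positive")
        if self.f_mean <= self.f_floor:
            raise ConfigurationError("f_mean must exceed f_floor")
        if self.n_null is None:
            self.n_null = 10 * (self.n_instruments + self.n_mediator_instruments)


@dataclass
class SimTruth:
    """The generative parameters a simulation run must allow recovering."""

    config: SimConfig
    variant_id: list[str]
    chrom: list[str]
    pos: np.ndarray
    eaf: np.ndarray
    gamma: np.ndarray   # effect on exposure
    delta: np.ndarray   # effect on mediator (mediator instruments + pleiotropy)
    alpha: np.ndarray   # direct pleiotropic effect on outcome
    eta: np.ndarray     # outcome-specific instrument effect
    seed: int | None = None

    @property
    def theta_total(self) -> float:
        c = self.config
        return c.theta_XY + c.theta_XM * c.theta_MY

    @property
    def true_mediated_proportion(self) -> float:
        c = self.config
        return c.theta_XM * c.theta_MY / self.theta_total

    @property
    def exposure_instrument_ids(self) -> list[str]:
        return [v for v, g in zip(self.variant_id, self.gamma) if g != 0]

    @property
    def mediator_instrument_ids(self) -> list[str]:
        return [
            v
            for v, g, d in zip(self.variant_id, self.gamma, self.delta)
            if g == 0 and d != 0
        ]

    @property
    def outcome_instrument_ids(self) -> list[str]:
        return [v for v, e in zip(self.variant_id, self.eta) if e != 0]


@dataclass
class SimBundle:
    """One simulated two-sample study: tables, LD and the generating truth."""

    exposure: SumStatsTable
    mediator: SumStatsTable
    outcome: SumStatsTable
    ld: LDMatrix | None
    truth: SimTruth


def _se_marginal(n: int, eaf: np.ndarray) -> np.ndarray:
    """SE of a per-allele marginal effect for a unit-variance trait."""
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _draw_f_targets(
    n: int, f_mean: float, f_floor: float, rng: np.random.Generator
) -> np.ndarray:
    return f_floor + rng.exponential(f_mean - f_floor, size=n)


def simulate_truth(config: SimConfig | None = None, seed: int | None = None) -> SimTruth:
    """Draw the per-variant generative parameters.

    Planted signals are laid out mutually more than one clumping window
    apart (round-robin over chromosomes) so that selection recovers them
    exactly; null variants are interspersed freely.  Raises
    :class:`ConfigurationError` if the genome span cannot hold that many
    independent signals.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    n_sig = cfg.n_instruments + cfg.n_mediator_instruments + cfg.n_outcome_instruments
    n_total = n_sig + cfg.n_null

    window_bp = cfg.clump_window_kb * 1000
    per_chrom = cfg.chrom_span_bp // (window_bp + 1)
    if per_chrom < 1 or n_sig > per_chrom * cfg.n_chrom:
        raise ConfigurationError(
            f"cannot place {n_sig} mutually independent signals on "
            f"{cfg.n_chrom} chromosomes of {cfg.chrom_span_bp} bp with a "
            f"{cfg.clump_window_kb} kb window"
        )
    # signals round-robin across chromosomes, > window apart within each
    chrom = [str(1 + i % cfg.n_chrom) for i in range(n_sig)]
    pos = np.array(
        [1 + (i // cfg.n_chrom) * (window_bp + 1) for i in range(n_sig)], dtype=np.int64
    )
    # nulls placed anywhere
    null_chrom = [str(c) for c in rng.integers(1, cfg.n_chrom + 1, size=cfg.n_null)]
    null_pos = rng.integers(1, cfg.chrom_span_bp, size=cfg.n_null).astype(np.int64)

    eaf = rng.uniform(0.05, 0.5, size=n_total)
    gamma = np.zeros(n_total)
    delta = np.zeros(n_total)
    alpha = np.zeros(n_total)
    eta = np.zeros(n_total)

    se_x = _se_marginal(cfg.n_x, eaf)
    se_m = _se_marginal(cfg.n_m, eaf)
    se_y = _se_marginal(cfg.n_y, eaf)
    sign = rng.choice([-1.0, 1.0], size=n_total)

    ex = slice(0, cfg.n_instruments)
    med = slice(cfg.n_instruments, cfg.n_instruments + cfg.n_mediator_instruments)
    outc = slice(cfg.n_instruments + cfg.n_mediator_instruments, n_sig)
    f_x = _draw_f_targets(cfg.n_instruments, cfg.f_mean, cfg.f_floor, rng)
    gamma[ex] = sign[ex] * se_x[ex] * np.sqrt(f_x - 1.0)
    f_m = _draw_f_targets(cfg.n_mediator_instruments, cfg.f_mean, cfg.f_floor, rng)
    delta[med] = sign[med] * se_m[med] * np.sqrt(f_m - 1.0)
    if cfg.n_outcome_instruments:
        f_y = _draw_f_targets(cfg.n_outcome_instruments, cfg.f_mean, cfg.f_floor, rng)
        eta[outc] = sign[outc] * se_y[outc] * np.sqrt(f_y - 1.0)

    if cfg.pi_pleio > 0:
        pleio = rng.random(n_total) < cfg.pi_pleio
        # pleiotropy violates the exclusion restriction for exposure
        # instruments; mediator/outcome-specific signals stay clean
        pleio[med] = False
        pleio[outc] = False
        raw = rng.normal(cfg.mu_alpha, cfg.sigma_alpha, size=pleio.sum())
        # directional pleiotropy is defined relative to the
        # exposure-raising allele: orient it with gamma's sign so that a
        # positive mu_alpha biases the causal estimate upward
        orient = np.where(gamma[pleio] != 0, np.sign(gamma[pleio]), 1.0)
        alpha[pleio] = orient * raw

    variant_id = [f"rs{100000 + i}" for i in range(n_total)]
    return SimTruth(
        config=cfg,
        variant_id=variant_id,
        chrom=chrom + null_chrom,
        pos=np.concatenate([pos, null_pos]),
        eaf=eaf,
        gamma=gamma,
        delta=delta,
        alpha=alpha,
        eta=eta,
        seed=seed,
    )


def _table(
    label: str,
    truth: SimTruth,
    true_beta: np.ndarray,
    se: np.ndarray,
    n: int,
    rng: np.random.Generator,
    unit_note: str,
) -> SumStatsTable:
    from scipy import stats

    beta_obs = rng.normal(true_beta, se)
    z = beta_obs / se
    pval = 2 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame(
        {
            "variant_id": truth.variant_id,
            "chrom": truth.chrom,
            "pos": truth.pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": truth.eaf,
            "beta": beta_obs,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )[CANONICAL_COLUMNS]
    return SumStatsTable(label, df, unit_note)


def simulate_sumstats(truth: SimTruth, seed: int | None = None) -> SimBundle:
    """Simulate the exposure, mediator and outcome summary-statistic tables.

    Three independent child streams (spawned from ``seed``) play the
    role of the three non-overlapping cohorts, so estimation error is
    uncorrelated between tables, as in a genuine two-sample design.
    """
    cfg = truth.config
    rng_x, rng_m, rng_y = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)
    )
    b_x = truth.gamma + cfg.theta_YX * truth.eta
    b_m = cfg.theta_XM * truth.gamma + truth.delta
    b_y = (
        truth.theta_total * truth.gamma
        + cfg.theta_MY * truth.delta
        + truth.alpha
        + truth.eta
    )

    se_x = _se_marginal(cfg.n_x, truth.eaf)
    se_m = _se_marginal(cfg.n_m, truth.eaf)
    se_y = _se_marginal(cfg.n_y, truth.eaf)

    exposure = _table("exposure", truth, b_x, se_x, cfg.n_x, rng_x, "log-odds")
    mediator = _table("mediator", truth, b_m, se_m, cfg.n_m, rng_m, "log-odds")
    outcome = _table("outcome", truth, b_y, se_y, cfg.n_y, rng_y, "log-odds")

    ld = None
    if cfg.ld_block_size > 1 or cfg.ld_rho > 0:
        n_total = len(truth.variant_id)
        sizes = [cfg.ld_block_size] * (n_total // cfg.ld_block_size)
        rem = n_total - sum(sizes)
        if rem:
            sizes.append(rem)
        ld = make_ld_blocks(sizes, cfg.ld_rho, truth.variant_id)
    return SimBundle(exposure, mediator, outcome, ld, truth)


def simulate_study(
    config: SimConfig | None = None, seed: int | None = None
) -> SimBundle:
    """Convenience wrapper: draw a truth and simulate one study from it."""
    ss = np.random.SeedSequence(seed)
    s_truth, s_obs = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    truth = simulate_truth(config, seed=s_truth)
    return simulate_sumstats(truth, seed=s_obs)


def make_ld_blocks(
    block_sizes: list[int],
    rho: float,
    variant_ids: list[str] | None = None,
) -> LDMatrix:
    """Block-diagonal r^2 matrix with within-block decay rho^d.

    ``d`` is the rank distance between two variants inside a block; r^2
    is zero across blocks and 1 on the diagonal.
    """
    if not 0 <= rho < 1:
        raise ConfigurationError("rho must lie in [0, 1)")
    if any(b < 1 for b in block_sizes):
        raise ConfigurationError("block sizes must be >= 1")
    n = sum(block_sizes)
    r2 = np.zeros((n, n))
    start = 0
    for b in block_sizes:
        idx = np.arange(b)
        r2[start : start + b, start : start + b] = rho ** np.abs(
            idx[:, None] - idx[None, :]
        )
        start += b
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(n)]
    return LDMatrix(list(variant_ids), r2)
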