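"""Mating-class fertility contrasts and in-utero mortality estimation.

AI insemination records are grouped by sire genotype class (genotyped, so
known with certainty) and dam's-sire genotype class (the dam herself is not
genotyped). A dam whose sire is a carrier has probability 0.5 + c/2 of
carrying the mutation (1/2 from her sire plus c/2 from her ungenotyped dam);
a non-carrier-sired dam still has probability c/2. The expected fraction of
homozygous-mutant conceptuses in a class with a carrier sire is then
P_hom = P(dam carrier) / 4.

If a fraction m(t) of homozygous conceptuses has died by day t, the
pregnancy-failure rate of that class at day t exceeds the non-carrier x
non-carrier reference by P_hom * m(t) (additive risk — the arithmetic is a
difference of failure probabilities, not an odds ratio). The method-of-
moments mortality estimate is therefore

    m_hat(t) = excess(t) / P_hom,

with confidence intervals both by the delta method on the rate difference
and by a parametric bootstrap over class failure counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .synthetic_data import MATING_CLASSES, MatingSimConfig, simulate_matings
from ._seeds import child_seed

__all__ = [
    "STAGES",
    "MatingClassSummary",
    "ContrastResult",
    "LethalityEstimate",
    "RecoveryReport",
    "dam_carrier_probability",
    "expected_homozygote_fraction",
    "class_contrasts",
    "estimate_mortality",
    "mortality_from_excess",
    "recover_parameters",
]

STAGES = (56, 90, 270)
_REFERENCE = "NCxNC"


def dam_carrier_probability(dam_sire_is_carrier: bool, c: float) -> float:
    """Probability that a dam carries the mutation given her sire's class.

    Carrier-sired: 1/2 from the sire plus c/2 from the ungenotyped granddam;
    non-carrier-sired: c/2 from the granddam only.
    """
    if not 0.0 <= c <= 1.0:
        raise DataError(f"carrier frequency {c} outside [0, 1]")
    return 0.5 + c / 2.0 if dam_sire_is_carrier else c / 2.0


def expected_homozygote_fraction(mating_class: str, c: float) -> float:
    """Expected D/D conceptus fraction for a mating class.

    P_hom = P(dam carrier) * 1/4 when the sire is a genotyped carrier (both
    parents must transmit), and 0 when the sire is a genotyped non-carrier.
    """
    if mating_class not in MATING_CLASSES:
        raise DataError(f"unknown mating class {mating_class!r}")
    dam_sire_class, sire_class = mating_class.split("x")
    if sire_class != "C":
        return 0.0
    return dam_carrier_probability(dam_sire_class == "C", c) * 0.25


@dataclass(frozen=True)
class MatingClassSummary:
    label: str
    n: int
    failures: tuple[int, int, int]  # at 56 / 90 / 270 d

    @property
    def rates(self) -> tuple[float, float, float]:
        return tuple(f / self.n for f in self.failures)


@dataclass(eq=False)
class ContrastResult:
    """Per-class failure summaries and contrasts against NC x NC."""

    summaries: dict[str, MatingClassSummary]
    excess: pd.DataFrame  # index class, columns stages; rate - reference rate
    p_values: pd.DataFrame  # same shape; chi-square (df 1) or Fisher exact
    chi_square: pd.DataFrame  # the statistic (NaN where Fisher was used)


def _contrast_test(f1: int, n1: int, f0: int, n0: int) -> tuple[float, float]:
    """2x2 test of failure counts; chi-square without continuity correction,
    switching to Fisher's exact test when any cell is below 5."""
    table = np.array([[f1, n1 - f1], [f0, n0 - f0]])
    if table.min() < 5:
        res = stats.fisher_exact(table)
        return float("nan"), float(res.pvalue)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def class_contrasts(records: pd.DataFrame) -> ContrastResult:
    """Summarise failure rates per mating class and contrast against NC x NC."""
    if "mating_class" not in records.columns:
        records = records.assign(
            mating_class=records["dam_sire_class"] + "x" + records["sire_class"]
        )
    present = [c for c in MATING_CLASSES if (records["mating_class"] == c).any()]
    if _REFERENCE not in present:
        raise DataError("reference class NCxNC absent")
    if len(present) < 2:
        raise DataError("need >= 2 mating classes including NCxNC")
    summaries = {}
    for label in present:
        sub = records[records["mating_class"] == label]
        summaries[label] = MatingClassSummary(
            label=label,
            n=len(sub),
            failures=tuple(int(sub[f"fail{t}"].sum()) for t in STAGES),
        )
    ref = summaries[_REFERENCE]
    rows_e, rows_p, rows_c = {}, {}, {}
    for label in present:
        if label == _REFERENCE:
            continue
        s = summaries[label]
        rows_e[label] = [s.rates[i] - ref.rates[i] for i in range(3)]
        tests = [
            _contrast_test(s.failures[i], s.n, ref.failures[i], ref.n) for i in range(3)
        ]
        rows_c[label] = [t[0] for t in tests]
        rows_p[label] = [t[1] for t in tests]
    cols = [f"d{t}" for t in STAGES]
    return ContrastResult(
        summaries=summaries,
        excess=pd.DataFrame.from_dict(rows_e, orient="index", columns=cols),
        p_values=pd.DataFrame.from_dict(rows_p, orient="index", columns=cols),
        chi_square=pd.DataFrame.from_dict(rows_c, orient="index", columns=cols),
    )


def mortality_from_excess(excess: float, p_hom: float) -> float:
    """Method-of-moments cumulative mortality, clipped to [0, 1]."""
    if p_hom <= 0:
        raise DataError("P_hom must be > 0: class carries no expected homozygotes")
    return float(np.clip(excess / p_hom, 0.0, 1.0))


@dataclass(eq=False)
class LethalityEstimate:
    """Cumulative homozygote mortality per gestation stage, with CIs."""

    stages: tuple[int, ...]
    m_hat: np.ndarray
    ci_delta: np.ndarray  # (3, 2) lower/upper, delta method
    ci_boot: np.ndarray | None  # (3, 2) percentile bootstrap, None if skipped
    p_hom: float
    mating_class: str
    p_values: np.ndarray


def estimate_mortality(
    contrast: ContrastResult,
    carrier_freq: float,
    mating_class: str = "CxC",
    alpha: float = 0.05,
    n_boot: int = 200,
    isotonic: bool = False,
    seed: int = 0,
) -> LethalityEstimate:
    """Estimate cumulative homozygote mortality from one class contrast.

    m_hat(t) = excess(t) / P_hom. The delta-method CI propagates the
    binomial variance of both class rates through the rate difference; the
    bootstrap redraws class failure counts parametrically. ``isotonic``
    optionally enforces the (true) monotonicity of cumulative mortality on
    the point estimates.
    """
    p_hom = expected_homozygote_fraction(mating_class, carrier_freq)
    if p_hom <= 0:
        raise DataError(f"class {mating_class} carries no expected homozygotes")
    if mating_class not in contrast.summaries:
        raise DataError(f"class {mating_class} absent from contrast")
    s = contrast.summaries[mating_class]
    ref = contrast.summaries[_REFERENCE]
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    m_hat = np.empty(3)
    ci_delta = np.empty((3, 2))
    for i in range(3):
        p1, p0 = s.rates[i], ref.rates[i]
        diff = p1 - p0
        se = np.sqrt(p1 * (1 - p1) / s.n + p0 * (1 - p0) / ref.n)
        m_hat[i] = np.clip(diff / p_hom, 0.0, 1.0)
        ci_delta[i] = np.clip([(diff - z * se) / p_hom, (diff + z * se) / p_hom], 0.0, 1.0)
    ci_boot = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, 3))
        for i in range(3):
            f1 = rng.binomial(s.n, s.rates[i], size=n_boot) / s.n
            f0 = rng.binomial(ref.n, ref.rates[i], size=n_boot) / ref.n
            boot[:, i] = np.clip((f1 - f0) / p_hom, 0.0, 1.0)
        ci_boot = np.stack(
            [
                np.quantile(boot, alpha / 2.0, axis=0),
                np.quantile(boot, 1.0 - alpha / 2.0, axis=0),
            ],
            axis=1,
        )
    if isotonic:
        m_hat = np.maximum.accumulate(m_hat)
    return LethalityEstimate(
        stages=STAGES,
        m_hat=m_hat,
        ci_delta=ci_delta,
        ci_boot=ci_boot,
        p_hom=p_hom,
        mating_class=mating_class,
        p_values=contrast.p_values.loc[mating_class].to_numpy(),
    )


@dataclass(eq=False)
class RecoveryReport:
    """Simulate -> estimate recovery diagnostics for the mortality estimator."""

    truth: np.ndarray
    mean_m_hat: np.ndarray
    bias: np.ndarray
    rmse: np.ndarray
    ci_coverage: np.ndarray  # delta-method 95% CI coverage per stage
    n_reps: int


def recover_parameters(
    config: MatingSimConfig, n_reps: int = 50, seed: int = 0
) -> RecoveryReport:
    """Repeatedly simulate matings and re-estimate mortality from each draw."""
    if n_reps < 10:
        raise DataError("n_reps must be >= 10")
    truth = np.array(config.mortality, dtype=float)
    est = np.empty((n_reps, 3))
    covered = np.zeros((n_reps, 3), dtype=bool)
    for r in range(n_reps):
        cfg = MatingSimConfig(
            n_per_class=config.n_per_class,
            baseline=config.baseline,
            mortality=config.mortality,
            carrier_freq=config.carrier_freq,
            seed=child_seed(seed, f"recovery_{r}"),
        )
        records = simulate_matings(cfg)
        contrast = class_contrasts(records)
        fit = estimate_mortality(contrast, cfg.carrier_freq, n_boot=0)
        est[r] = fit.m_hat
        covered[r] = (fit.ci_delta[:, 0] <= truth) & (truth <= fit.ci_delta[:, 1])
    return RecoveryReport(
        truth=truth,
        mean_m_hat=est.mean(axis=0),
        bias=est.mean(axis=0) - truth,
        rmse=np.sqrt(((est - truth) ** 2).mean(axis=0)),
        ci_coverage=covered.mean(axis=0),
        n_reps=n_reps,
    )
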