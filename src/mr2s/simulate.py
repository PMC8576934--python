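"""Synthetic two-sample GWAS summary statistics with known ground truth.

Generates paired exposure/outcome tables under a linear structural model

    gamma_hat_j ~ N(gamma_j, se_gamma_j)
    Gamma_hat_j ~ N(beta_true * gamma_j + alpha_j, se_Gamma_j)

with per-SNP horizontal pleiotropy ``alpha_j`` that can be absent,
balanced (zero mean), directional (nonzero mean) or correlated with
instrument strength (violating the InSIDE condition).  Standard errors
follow the usual single-SNP approximation
``se = sqrt(var / (2 n eaf (1 - eaf)))``.

Every draw flows from one seed, so studies are bit-reproducible, and the
emitted tables use the package's standard summary-statistic schema so the
whole pipeline can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import estimators as est
from .exceptions import ValidationError
from .instruments import HarmonizedInstrument, KEPT
from .summary_io import GwasTable, SnpAssociation

PLEIOTROPY_MODES = ("none", "balanced", "directional", "correlated")

_P_FLOOR = 1e-300  # keep p-values inside (0,1] at extreme z-scores


@dataclass
class SimulationConfig:
    """Parameters of one simulated two-sample study.

    ``gamma_range`` and ``eaf_range`` are uniform laws for the true
    SNP-exposure effect magnitude and the effect-allele frequency; defaults
    mirror the magnitudes seen in published fatty-acid instruments
    (|beta| 0.005-0.12, EAF 0.05-0.93).  ``gamma_sign='positive'`` disables
    the random sign, which keeps directional pleiotropy directional after
    the orientation step used by slope-intercept estimators.
    """

    J: int = 26
    beta_true: float = 0.0
    gamma_range: tuple[float, float] = (0.005, 0.12)
    gamma_sign: str = "random"  # random | positive
    eaf_range: tuple[float, float] = (0.05, 0.93)
    n_exposure: int = 8866
    n_outcome: int = 100_000
    exposure_variance: float = 1.0
    outcome_variance: float = 1.0
    pleiotropy_mode: str = "none"
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    rho: float = 0.0
    fraction_invalid: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValidationError("J must be >= 1")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValidationError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if self.gamma_sign not in {"random", "positive"}:
            raise ValidationError("gamma_sign must be 'random' or 'positive'")
        if not 0.0 <= self.fraction_invalid <= 1.0:
            raise ValidationError("fraction_invalid must lie in [0,1]")
        if not abs(self.rho) <= 1.0:
            raise ValidationError("|rho| must be <= 1")
        if self.sigma_alpha < 0:
            raise ValidationError("sigma_alpha must be >= 0")
        for name in ("n_exposure", "n_outcome"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2")
        for name in ("exposure_variance", "outcome_variance"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind a simulated study."""

    beta_true: float
    gamma: np.ndarray
    alpha: np.ndarray
    invalid: np.ndarray
    seed: int


@dataclass
class SimulatedStudy:
    exposure_table: GwasTable
    outcome_table: GwasTable
    truth: SimulationTruth
    seed: int

    def instruments(self) -> list[HarmonizedInstrument]:
        """Harmonized instruments built directly from the paired tables."""
        out = []
        for x, y in zip(self.exposure_table.records, self.outcome_table.records):
            out.append(
                HarmonizedInstrument(
                    rsid=x.rsid,
                    gamma=x.beta,
                    se_gamma=x.se,
                    Gamma=y.beta,
                    se_Gamma=y.se,
                    eaf_exposure=x.eaf_or_nan,
                    eaf_outcome=y.eaf_or_nan,
                    action=KEPT,
                )
            )
        return out

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [r.rsid for r in self.exposure_table.records],
                "gamma_true": self.truth.gamma,
                "alpha_true": self.truth.alpha,
                "invalid": self.truth.invalid.astype(int),
                "beta_true": self.truth.beta_true,
            }
        )


def _single_snp_se(variance: float, n: int, eaf: np.ndarray) -> np.ndarray:
    return np.sqrt(variance / (2.0 * n * eaf * (1.0 - eaf)))


def _draw_alpha(cfg: SimulationConfig, gamma: np.ndarray, invalid: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    alpha = np.zeros(cfg.J)
    idx = np.nonzero(invalid)[0]
    if idx.size == 0 or cfg.pleiotropy_mode == "none":
        return alpha
    if cfg.pleiotropy_mode == "balanced":
        alpha[idx] = rng.normal(0.0, cfg.sigma_alpha, size=idx.size)
    elif cfg.pleiotropy_mode == "directional":
        alpha[idx] = rng.normal(cfg.mu_alpha, cfg.sigma_alpha, size=idx.size)
    else:  # correlated: couple alpha to instrument strength (InSIDE violated)
        g = gamma[idx]
        sd = float(np.std(g))
        zg = (g - float(np.mean(g))) / sd if sd > 0 else np.zeros(idx.size)
        eps = rng.standard_normal(idx.size)
        alpha[idx] = cfg.mu_alpha + cfg.sigma_alpha * (
            cfg.rho * zg + math.sqrt(1.0 - cfg.rho**2) * eps
        )
    return alpha


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, _P_FLOOR, 1.0)


def simulate_study(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimulatedStudy:
    """Draw one two-sample study under ``config``.

    The same config (and seed) always yields identical tables.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    eaf = rng.uniform(*cfg.eaf_range, size=cfg.J)
    magnitude = rng.uniform(*cfg.gamma_range, size=cfg.J)
    if cfg.gamma_sign == "random":
        sign = rng.choice([-1.0, 1.0], size=cfg.J)
    else:
        sign = np.ones(cfg.J)
    gamma = magnitude * sign

    n_invalid = int(round(cfg.fraction_invalid * cfg.J))
    invalid = np.zeros(cfg.J, dtype=bool)
    if n_invalid and cfg.pleiotropy_mode != "none":
        invalid[rng.choice(cfg.J, size=n_invalid, replace=False)] = True
    alpha = _draw_alpha(cfg, gamma, invalid, rng)

    se_gamma = _single_snp_se(cfg.exposure_variance, cfg.n_exposure, eaf)
    se_Gamma = _single_snp_se(cfg.outcome_variance, cfg.n_outcome, eaf)
    gamma_hat = rng.normal(gamma, se_gamma)
    Gamma_hat = rng.normal(cfg.beta_true * gamma + alpha, se_Gamma)

    rsids = [f"rs{j + 1:06d}" for j in range(cfg.J)]
    p_x = _pvalues(gamma_hat, se_gamma)
    p_y = _pvalues(Gamma_hat, se_Gamma)

    def _records(betas, ses, ps) -> list[SnpAssociation]:
        return [
            SnpAssociation(
                rsid=rsids[j],
                chromosome="1",
                position=(j + 1) * 1000,
                effect_allele="A",
                other_allele="G",
                eaf=float(eaf[j]),
                beta=float(betas[j]),
                se=float(ses[j]),
                pvalue=float(ps[j]),
            )
            for j in range(cfg.J)
        ]

    exposure = GwasTable(
        trait_name="sim_exposure",
        trait_type="continuous",
        sample_size=cfg.n_exposure,
        trait_variance=cfg.exposure_variance,
        records=_records(gamma_hat, se_gamma, p_x),
    )
    outcome = GwasTable(
        trait_name="sim_outcome",
        trait_type="binary",
        sample_size=cfg.n_outcome,
        records=_records(Gamma_hat, se_Gamma, p_y),
    )
    truth = SimulationTruth(
        beta_true=cfg.beta_true, gamma=gamma, alpha=alpha, invalid=invalid, seed=cfg.seed
    )
    return SimulatedStudy(exposure_table=exposure, outcome_table=outcome, truth=truth, seed=cfg.seed)


def evaluate_recovery(
    config: SimulationConfig,
    n_reps: int,
    methods: Sequence[str] = ("ivw", "egger", "weighted_median"),
    n_boot: int = 200,
    n_sim: int = 500,
) -> pd.DataFrame:
    """Estimator operating characteristics over repeated simulated studies.

    Returns one row per method with mean bias, empirical SE, mean estimated
    SE, 95% CI coverage and rejection rate at alpha = 0.05, plus the mean
    Egger intercept and MR-PRESSO outlier sensitivity/specificity where
    those methods are requested.  Deterministic given ``config.seed``.
    """
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2")
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n_reps)

    acc: dict[str, dict[str, list]] = {
        m: {"beta": [], "se": [], "cover": [], "reject": []} for m in methods
    }
    intercepts: list[float] = []
    sens: list[float] = []
    spec: list[float] = []
    beta_true = config.beta_true

    for child in children:
        rng = np.random.default_rng(child)
        study = simulate_study(config, rng=rng)
        insts = study.instruments()
        for m in methods:
            if m == "ivw":
                fit = est.ivw(insts)
            elif m == "egger":
                fit = est.mr_egger(insts)
            elif m == "weighted_median":
                fit = est.weighted_median(insts, n_boot=n_boot, seed=rng)
                # rng is advanced in place, keeping replicates independent
            elif m == "presso":
                report = est.mr_presso(
                    insts, n_sim=n_sim, seed=int(child.generate_state(1)[0])
                )
                flagged = set(report.outlier_rsids)
                truth_invalid = {
                    r.rsid
                    for r, bad in zip(study.exposure_table.records, study.truth.invalid)
                    if bad
                }
                valid = {r.rsid for r in study.exposure_table.records} - truth_invalid
                if truth_invalid:
                    sens.append(len(flagged & truth_invalid) / len(truth_invalid))
                if valid:
                    spec.append(1.0 - len(flagged & valid) / len(valid))
                fit = report.corrected_estimate or report.raw_estimate
            else:
                raise ValidationError(f"unknown method {m!r}")
            acc[m]["beta"].append(fit.beta)
            acc[m]["se"].append(fit.se)
            acc[m]["cover"].append(fit.ci_low <= beta_true <= fit.ci_high)
            acc[m]["reject"].append(fit.pvalue < 0.05)
            if m == "egger":
                intercepts.append(fit.intercept)

    rows = []
    for m in methods:
        betas = np.array(acc[m]["beta"])
        rows.append(
            {
                "method": m,
                "n_reps": n_reps,
                "mean_bias": float(np.mean(betas) - beta_true),
                "empirical_se": float(np.std(betas, ddof=1)),
                "mean_estimated_se": float(np.mean(acc[m]["se"])),
                "coverage_95": float(np.mean(acc[m]["cover"])),
                "rejection_rate_05": float(np.mean(acc[m]["reject"])),
                "egger_intercept_mean": float(np.mean(intercepts)) if m == "egger" else np.nan,
                "outlier_sensitivity": float(np.mean(sens)) if m == "presso" and sens else np.nan,
                "outlier_specificity": float(np.mean(spec)) if m == "presso" and spec else np.nan,
            }
        )
    return pd.DataFrame(rows)
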