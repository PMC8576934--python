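"""Two-sample Mendelian randomization estimators.

Implements the Wald ratio, inverse-variance weighted (IVW) regression
through the origin, Cochran's Q, MR-Egger regression with its intercept
test for directional pleiotropy, the weighted-median estimator with a
parametric-bootstrap SE, and the MR-PRESSO global/outlier/distortion
resampling procedure.

All estimators operate on :class:`~mr2s.instruments.HarmonizedInstrument`
sequences carrying (gamma, se_gamma, Gamma, se_Gamma) and are equivariant
under joint reorientation of (gamma, Gamma) for any subset of SNPs.
Stochastic procedures take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    CorrectionError,
    DegenerateInstrumentError,
    MethodGatingError,
    ValidationError,
)
from .instruments import HarmonizedInstrument

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile

IVW_FIXED = "ivw_fixed"
IVW_RANDOM = "ivw_random"
EGGER = "egger"
WEIGHTED_MEDIAN = "weighted_median"
PRESSO_RAW = "presso_raw"
PRESSO_CORRECTED = "presso_outlier_corrected"


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio and its (first-order delta-method) SE."""

    rsid: str
    beta_ratio: float
    se_ratio: float


@dataclass(frozen=True)
class MrEstimate:
    """One method's causal estimate.

    ``intercept*`` fields are populated only for MR-Egger; ``q_stat`` and
    ``q_pvalue`` only where a heterogeneity statistic is defined (J >= 2).
    """

    method: str
    n_snps: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    q_stat: float | None = None
    q_pvalue: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None

    def scaled(self, factor: float) -> "MrEstimate":
        """Rescale the estimate to ``factor`` exposure units.

        Betas, SEs and CI bounds scale linearly; p-values and heterogeneity
        statistics are invariant.  The Egger intercept lives on the outcome
        scale and is left untouched.
        """
        return replace(
            self,
            beta=self.beta * factor,
            se=self.se * factor,
            ci_low=self.ci_low * factor,
            ci_high=self.ci_high * factor,
        )


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    g = np.array([i.gamma for i in instruments], dtype=float)
    sg = np.array([i.se_gamma for i in instruments], dtype=float)
    G = np.array([i.Gamma for i in instruments], dtype=float)
    sG = np.array([i.se_Gamma for i in instruments], dtype=float)
    if np.isnan(g).any() or np.isnan(G).any():
        raise ValidationError("instruments with NaN effects passed to an estimator")
    return g, sg, G, sG


def _two_sided_normal_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> RatioEstimate:
    """Single-SNP causal estimate Gamma/gamma.

    The default SE is the first-order delta approximation
    ``se(Gamma)/|gamma|``; ``second_order=True`` adds the term propagating
    the uncertainty in gamma.
    """
    if inst.gamma == 0:
        raise DegenerateInstrumentError(f"{inst.rsid}: gamma is zero, Wald ratio undefined")
    beta = inst.Gamma / inst.gamma
    if second_order:
        se = math.sqrt(
            inst.se_Gamma**2 / inst.gamma**2
            + inst.Gamma**2 * inst.se_gamma**2 / inst.gamma**4
        )
    else:
        se = inst.se_Gamma / abs(inst.gamma)
    return RatioEstimate(rsid=inst.rsid, beta_ratio=beta, se_ratio=se)


def wald_ratios(
    instruments: Sequence[HarmonizedInstrument], second_order: bool = False
) -> list[RatioEstimate]:
    return [wald_ratio(i, second_order=second_order) for i in instruments]


def cochran_q(
    instruments: Sequence[HarmonizedInstrument], beta_ref: float
) -> tuple[float, float]:
    """Cochran's Q over the Wald ratios around ``beta_ref``.

    Q = sum_j w_j (beta_j - beta_ref)^2 with w_j = se_ratio_j^-2; p from
    chi-square with J - 1 degrees of freedom.
    """
    if len(instruments) < 2:
        raise MethodGatingError("Cochran's Q needs at least 2 instruments")
    ratios = wald_ratios(instruments)
    b = np.array([r.beta_ratio for r in ratios])
    w = np.array([r.se_ratio for r in ratios]) ** -2.0
    q = float(np.sum(w * (b - beta_ref) ** 2))
    pvalue = float(stats.chi2.sf(q, len(instruments) - 1))
    return q, pvalue


def ivw(instruments: Sequence[HarmonizedInstrument], model: str = "auto") -> MrEstimate:
    """Inverse-variance weighted estimate.

    Weighted regression of Gamma on gamma through the origin with weights
    se_Gamma^-2:

        beta = sum(w g G) / sum(w g^2),   se_fixed = sum(w g^2)^-1/2.

    ``model='random'`` inflates the SE multiplicatively by
    ``max(1, sqrt(Q/(J-1)))``; ``'auto'`` uses random effects when J >= 4
    and fixed effects otherwise.  With a single instrument the estimate
    equals the Wald ratio exactly.
    """
    if model not in {"fixed", "random", "auto"}:
        raise ValidationError(f"model must be fixed|random|auto, got {model!r}")
    J = len(instruments)
    if J < 1:
        raise MethodGatingError("IVW needs at least 1 instrument")
    g, _, G, sG = _arrays(instruments)
    if np.any(g == 0):
        raise DegenerateInstrumentError("IVW requires nonzero gamma for every instrument")
    w = sG**-2.0
    denom = float(np.sum(w * g * g))
    beta = float(np.sum(w * g * G)) / denom
    se_fixed = denom**-0.5

    q = q_pvalue = None
    if J >= 2:
        q, q_pvalue = cochran_q(instruments, beta)

    resolved = model
    if model == "auto":
        resolved = "random" if J >= 4 else "fixed"
    if resolved == "random" and J >= 2:
        se = se_fixed * max(1.0, math.sqrt(q / (J - 1)))
        method = IVW_RANDOM
    else:
        se = se_fixed
        method = IVW_FIXED
    pvalue = _two_sided_normal_p(beta / se)
    return MrEstimate(
        method=method,
        n_snps=J,
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        pvalue=pvalue,
        q_stat=q,
        q_pvalue=q_pvalue,
    )


def _orient_positive(g: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sign = np.where(g < 0, -1.0, 1.0)
    return g * sign, G * sign


def mr_egger(instruments: Sequence[HarmonizedInstrument]) -> MrEstimate:
    """MR-Egger weighted regression with an unconstrained intercept.

    Instruments are oriented so every gamma is non-negative (negating
    gamma and Gamma jointly), then Gamma = b0 + b*gamma is fit by weighted
    least squares with weights se_Gamma^-2.  SEs are inflated
    multiplicatively by ``max(1, sqrt(RSS/(J-2)))`` and both coefficients
    are tested against t with J - 2 degrees of freedom.  The intercept
    p-value is the directional-pleiotropy flag.
    """
    J = len(instruments)
    if J < 3:
        raise MethodGatingError("MR-Egger requires a minimum of 3 instruments")
    g, _, G, sG = _arrays(instruments)
    g, G = _orient_positive(g, G)
    w = sG**-2.0
    sw = np.sqrt(w)
    X = np.column_stack([np.ones(J), g]) * sw[:, None]
    y = G * sw
    xtx = X.T @ X
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = J - 2
    scale = max(1.0, math.sqrt(rss / df))
    cov = np.linalg.inv(xtx)
    se_b0 = math.sqrt(cov[0, 0]) * scale
    se_b1 = math.sqrt(cov[1, 1]) * scale
    b0, b1 = float(coef[0]), float(coef[1])
    t_crit = float(stats.t.ppf(0.975, df))
    p_b1 = float(min(1.0, 2.0 * stats.t.sf(abs(b1 / se_b1), df)))
    p_b0 = float(min(1.0, 2.0 * stats.t.sf(abs(b0 / se_b0), df)))
    return MrEstimate(
        method=EGGER,
        n_snps=J,
        beta=b1,
        se=se_b1,
        ci_low=b1 - t_crit * se_b1,
        ci_high=b1 + t_crit * se_b1,
        pvalue=p_b1,
        q_stat=rss,
        q_pvalue=float(stats.chi2.sf(rss, df)),
        intercept=b0,
        intercept_se=se_b0,
        intercept_pvalue=p_b0,
    )


def _weighted_median_sorted(b_sorted: np.ndarray, w_sorted: np.ndarray) -> float:
    """Weighted median by interpolation of the cumulative-midpoint grid."""
    wn = w_sorted / w_sorted.sum()
    s = np.cumsum(wn) - 0.5 * wn
    return float(np.interp(0.5, s, b_sorted))


def weighted_median_point(betas: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted median of ``betas`` under ``weights`` (need not sum to 1).

    Order statistics b_(1) <= ... <= b_(J) get cumulative midpoints
    S_j = sum_{i<=j} w_i - w_j/2 (weights normalized); the estimate is the
    linear interpolation of (S_j, b_(j)) at 0.5.
    """
    b = np.asarray(betas, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(b, kind="stable")
    return _weighted_median_sorted(b[order], w[order])


def _weighted_median_rows(b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median; ``b`` is (m, J), ``w`` is (J,) or (m, J)."""
    m, J = b.shape
    order = np.argsort(b, axis=1, kind="stable")
    bs = np.take_along_axis(b, order, axis=1)
    if w.ndim == 1:
        ws = np.broadcast_to(w, (m, J))
        ws = np.take_along_axis(ws, order, axis=1)
    else:
        ws = np.take_along_axis(w, order, axis=1)
    wn = ws / ws.sum(axis=1, keepdims=True)
    s = np.cumsum(wn, axis=1) - 0.5 * wn
    # vectorized np.interp(0.5, s_row, bs_row) with endpoint clamping
    idx = (s < 0.5).sum(axis=1)  # first index with s >= 0.5
    out = np.empty(m)
    at_low = idx == 0
    at_high = idx == J
    out[at_low] = bs[at_low, 0]
    out[at_high] = bs[at_high, -1]
    mid = ~(at_low | at_high)
    i = idx[mid]
    rows = np.nonzero(mid)[0]
    s_lo = s[rows, i - 1]
    s_hi = s[rows, i]
    b_lo = bs[rows, i - 1]
    b_hi = bs[rows, i]
    frac = np.where(s_hi > s_lo, (0.5 - s_lo) / np.where(s_hi > s_lo, s_hi - s_lo, 1.0), 0.0)
    out[rows] = b_lo + (b_hi - b_lo) * frac
    return out


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MrEstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    The point estimate is the weighted median of the Wald ratios with
    weights se_ratio^-2.  The SE is the standard deviation of the estimate
    over ``n_boot`` parametric resamples gamma* ~ N(gamma, se_gamma),
    Gamma* ~ N(Gamma, se_Gamma) (weights held fixed); the p-value is
    two-sided normal.
    """
    J = len(instruments)
    if J < 3:
        raise MethodGatingError("weighted median requires a minimum of 3 instruments")
    g, sg, G, sG = _arrays(instruments)
    if np.any(g == 0):
        raise DegenerateInstrumentError("weighted median requires nonzero gamma")
    ratios = G / g
    w = (sG / np.abs(g)) ** -2.0
    beta = weighted_median_point(ratios, w)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g_star = rng.normal(g, sg, size=(n_boot, J))
    G_star = rng.normal(G, sG, size=(n_boot, J))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios_star = G_star / g_star
    boot = _weighted_median_rows(ratios_star, w)
    se = float(np.std(boot, ddof=1))
    pvalue = _two_sided_normal_p(beta / se) if se > 0 else 0.0
    return MrEstimate(
        method=WEIGHTED_MEDIAN,
        n_snps=J,
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        pvalue=pvalue,
    )


@dataclass(frozen=True)
class PressoReport:
    """MR-PRESSO global, outlier and distortion results."""

    global_rss_observed: float
    global_pvalue: float
    outlier_pvalues: dict[str, float]
    outlier_rsids: tuple[str, ...]
    distortion_pvalue: float | None
    raw_estimate: MrEstimate
    corrected_estimate: MrEstimate | None
    n_simulations: int
    seed: int


def _loo_ivw_beta(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, one per left-out SNP.

    Works row-wise when given 2-D inputs of shape (m, J).
    """
    num = w * g * G
    den = w * g * g
    s_num = num.sum(axis=-1, keepdims=True)
    s_den = den.sum(axis=-1, keepdims=True)
    return (s_num - num) / (s_den - den)


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    signif_threshold: float = 0.05,
    seed: int = 0,
    ivw_model: str = "auto",
    distortion_boot: int = 500,
) -> PressoReport:
    """MR-PRESSO pleiotropy residual-sum and outlier procedure.

    Global test: the observed residual sum of squares is
    ``RSS = sum_j (Gamma_j - gamma_j * beta_(-j))^2`` with ``beta_(-j)``
    the leave-one-out fixed-effect IVW estimate.  Each of ``n_sim``
    replicates draws gamma*_j ~ N(gamma_j, se_gamma_j) and
    Gamma*_j ~ N(gamma_j * beta_(-j), se_Gamma_j), recomputes RSS* the same
    way, and the empirical p-value uses the add-one rule
    ``(1 + #{RSS* >= RSS}) / (n_sim + 1)`` so it is never zero.

    Outlier test: each SNP's observed squared residual is compared with its
    simulated distribution; empirical p-values are Bonferroni-adjusted over
    J and SNPs below ``signif_threshold`` are flagged.

    Correction: the corrected estimate is IVW on the unflagged SNPs; the
    distortion p-value compares the raw and corrected estimates via a
    parametric bootstrap of the difference.  Raises
    :class:`~mr2s.exceptions.CorrectionError` when every SNP is flagged.
    """
    J = len(instruments)
    if J < 3:
        raise MethodGatingError("MR-PRESSO requires a minimum of 3 instruments")
    if J == 3:
        logger.warning("MR-PRESSO with 3 instruments: leave-one-out estimates rest on 2 SNPs")
    g, sg, G, sG = _arrays(instruments)
    w = sG**-2.0

    loo = _loo_ivw_beta(g, G, w)
    resid = G - g * loo
    resid_sq = resid**2
    rss_obs = float(resid_sq.sum())

    rng = np.random.default_rng(seed)
    g_star = rng.normal(g, sg, size=(n_sim, J))
    G_star = rng.normal(g * loo, sG, size=(n_sim, J))
    loo_star = _loo_ivw_beta(g_star, G_star, w)
    resid_star_sq = (G_star - g_star * loo_star) ** 2
    rss_star = resid_star_sq.sum(axis=1)

    global_pvalue = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))

    per_snp_p = (1 + (resid_star_sq >= resid_sq).sum(axis=0)) / (n_sim + 1)
    adj = np.minimum(1.0, per_snp_p * J)
    outlier_pvalues = {inst.rsid: float(p) for inst, p in zip(instruments, adj)}
    flagged = [inst.rsid for inst, p in zip(instruments, adj) if p < signif_threshold]

    raw = ivw(instruments, model=ivw_model)
    raw = replace(raw, method=PRESSO_RAW)

    corrected = None
    distortion_pvalue = None
    if flagged:
        kept = [inst for inst in instruments if inst.rsid not in set(flagged)]
        if not kept:
            raise CorrectionError("every instrument was flagged as an outlier; nothing remains")
        corrected = replace(ivw(kept, model=ivw_model), method=PRESSO_CORRECTED)
        distortion_pvalue = _distortion_pvalue(
            instruments, set(flagged), raw.beta - corrected.beta, distortion_boot, rng, ivw_model
        )

    return PressoReport(
        global_rss_observed=rss_obs,
        global_pvalue=global_pvalue,
        outlier_pvalues=outlier_pvalues,
        outlier_rsids=tuple(flagged),
        distortion_pvalue=distortion_pvalue,
        raw_estimate=raw,
        corrected_estimate=corrected,
        n_simulations=n_sim,
        seed=seed if isinstance(seed, int) else -1,
    )


def _distortion_pvalue(
    instruments: Sequence[HarmonizedInstrument],
    flagged: set[str],
    d_obs: float,
    n_boot: int,
    rng: np.random.Generator,
    ivw_model: str,
) -> float:
    """Bootstrap test of raw-vs-corrected estimate difference.

    Draws parametric resamples of every instrument, recomputes the raw and
    corrected IVW estimates and their difference d*, and compares the
    spread of d* re-centred at the observed difference against |d_obs|.
    """
    g, sg, G, sG = _arrays(instruments)
    keep_mask = np.array([inst.rsid not in flagged for inst in instruments])
    w = sG**-2.0
    g_star = rng.normal(g, sg, size=(n_boot, len(instruments)))
    G_star = rng.normal(G, sG, size=(n_boot, len(instruments)))

    def _beta(mask: np.ndarray) -> np.ndarray:
        num = (w * g_star * G_star)[:, mask].sum(axis=1)
        den = (w * g_star**2)[:, mask].sum(axis=1)
        return num / den

    d_star = _beta(np.ones_like(keep_mask)) - _beta(keep_mask)
    return float((1 + np.sum(np.abs(d_star - d_obs) >= abs(d_obs))) / (n_boot + 1))
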