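"""Bi-directional two-sample Mendelian randomization per ancestry group.

Instruments are genome-wide significant exposure variants (falling back
to a suggestive threshold when fewer than ten survive clumping),
LD-clumped at r^2 = 0.001 within 10,000 kb, and harmonized so exposure
and outcome effects refer to the same allele. Five estimators of the
causal effect are provided — inverse-variance weighted (the primary
result), MR-Egger with its pleiotropy intercept test, the weighted
median, and the simple and weighted mode estimators — together with
Cochran heterogeneity and an iterative heterogeneity-driven outlier
removal with a full audit trail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import AssocRecord, LDMatrix, harmonize_to_reference

logger = logging.getLogger(__name__)

GENOME_WIDE = 5e-8
SUGGESTIVE = 5e-6


@dataclass
class Instrument:
    """Harmonized exposure/outcome effect pair for one variant."""

    snp: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float = math.nan
    p_exposure: float = math.nan


@dataclass
class MRResult:
    """One estimator's causal-effect estimate."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    q: float | None = None
    q_pvalue: float | None = None

    @property
    def ci(self) -> tuple[float, float]:
        return self.beta - 1.96 * self.se, self.beta + 1.96 * self.se


def _as_frame(instruments) -> pd.DataFrame:
    if isinstance(instruments, pd.DataFrame):
        return instruments
    return pd.DataFrame([{
        "SNP": i.snp, "BETA_EXP": i.beta_exposure, "SE_EXP": i.se_exposure,
        "BETA_OUT": i.beta_outcome, "SE_OUT": i.se_outcome,
        "EAF": i.eaf, "P_EXP": i.p_exposure,
    } for i in instruments])


# ---------------------------------------------------------------------------
# Instrument selection


def clump(
    variants: pd.DataFrame,
    ld: LDMatrix,
    *,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> list[str]:
    """Greedy LD clumping by ascending p-value.

    Repeatedly keeps the best remaining variant and discards all others
    with r^2 > 0.001 within the 10,000 kb window. Variants absent from
    the LD panel are treated as independent. Returns kept SNP ids in
    p-value order.
    """
    window = window_kb * 1_000
    order = variants.sort_values("P").reset_index(drop=True)
    kept: list[str] = []
    removed: set[str] = set()
    rows = list(order.itertuples(index=False))
    for row in rows:
        if row.SNP in removed:
            continue
        kept.append(row.SNP)
        for other in rows:
            if other.SNP == row.SNP or other.SNP in removed:
                continue
            if str(other.CHR) != str(row.CHR) or abs(other.BP - row.BP) > window:
                continue
            if row.SNP in ld and other.SNP in ld:
                if ld.r2_between(row.SNP, other.SNP) > r2_threshold:
                    removed.add(other.SNP)
    return kept


def select_instruments(
    exposure: pd.DataFrame,
    ld: LDMatrix,
    *,
    primary_threshold: float = GENOME_WIDE,
    fallback_threshold: float = SUGGESTIVE,
    min_primary: int = 10,
) -> list[str]:
    """Select independent exposure instruments.

    Clumps variants below 5e-8; when fewer than ten survive, reselects
    at the suggestive 5e-6 threshold. Fewer than three instruments even
    at the fallback is a hard error (the estimators are undefined).
    """
    primary = exposure[exposure["P"] < primary_threshold]
    kept = clump(primary, ld) if not primary.empty else []
    if len(kept) < min_primary:
        fallback = exposure[exposure["P"] < fallback_threshold]
        kept_fb = clump(fallback, ld) if not fallback.empty else []
        if len(kept_fb) > len(kept):
            logger.info("select_instruments: %d below %.0e; using suggestive "
                        "threshold (%d instruments)", len(kept), primary_threshold,
                        len(kept_fb))
            kept = kept_fb
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} instruments available; need >= 3")
    return kept


def harmonize_pair(
    exposure: AssocRecord,
    outcome: AssocRecord,
    *,
    palindromic_maf_limit: float = 0.42,
) -> Instrument | None:
    """Align an outcome record to the exposure effect allele.

    The outcome effect is sign-flipped (and its EAF complemented) when
    its alleles are swapped relative to the exposure. Palindromic
    variants whose minor-allele frequency exceeds 0.42 on either side
    are ambiguous and dropped; otherwise they are resolved by frequency.
    Returns ``None`` for irreconcilable pairs.
    """
    if exposure.variant.id != outcome.variant.id:
        raise ValueError("exposure and outcome records must describe the same variant")
    if exposure.variant.is_palindromic:
        if exposure.maf > palindromic_maf_limit or outcome.maf > palindromic_maf_limit:
            logger.info("dropping palindromic %s: MAF too close to 0.5",
                        exposure.variant.id)
            return None
    aligned = harmonize_to_reference(
        outcome, exposure.variant.allele1, exposure.variant.allele2,
        ref_eaf=exposure.eaf,
    )
    if aligned is None:
        logger.info("dropping %s: alleles irreconcilable", exposure.variant.id)
        return None
    return Instrument(
        snp=exposure.variant.id,
        beta_exposure=exposure.beta, se_exposure=exposure.se,
        beta_outcome=aligned.beta, se_outcome=aligned.se,
        eaf=exposure.eaf, p_exposure=exposure.pvalue,
    )


# ---------------------------------------------------------------------------
# Estimators


def ivw(instruments) -> MRResult:
    """Inverse-variance-weighted estimate: weighted regression of outcome
    on exposure effects through the origin, weights 1/se_out^2."""
    df = _as_frame(instruments)
    if len(df) < 2:
        raise ValueError("IVW requires at least 2 instruments")
    bx, by = df["BETA_EXP"].to_numpy(), df["BETA_OUT"].to_numpy()
    w = 1.0 / df["SE_OUT"].to_numpy() ** 2
    denom = np.sum(w * bx ** 2)
    beta = float(np.sum(w * bx * by) / denom)
    se = float(1.0 / math.sqrt(denom))
    z = beta / se
    q, q_p = _cochran_q(df, beta)
    return MRResult("IVW", beta, se, float(2 * stats.norm.sf(abs(z))), len(df),
                    q=q, q_pvalue=q_p)


def egger(instruments) -> MRResult:
    """MR-Egger: weighted regression with a free intercept.

    The slope is the pleiotropy-robust causal estimate under InSIDE;
    the intercept estimates directional pleiotropy and its test is
    reported. Instruments are oriented so all exposure effects are
    positive before fitting, as the intercept is only identified up to
    that orientation.
    """
    df = _as_frame(instruments)
    if len(df) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    sign = np.sign(df["BETA_EXP"].to_numpy())
    sign[sign == 0] = 1.0
    bx = df["BETA_EXP"].to_numpy() * sign
    by = df["BETA_OUT"].to_numpy() * sign
    w = 1.0 / df["SE_OUT"].to_numpy() ** 2
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (w[:, None] * x)
    coef = np.linalg.solve(xtwx, x.T @ (w * by))
    resid = by - x @ coef
    dof = len(df) - 2
    sigma2 = float(np.sum(w * resid ** 2) / dof)
    cov = np.linalg.inv(xtwx) * max(sigma2, 1.0)
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    t_slope = coef[1] / se_slope
    t_int = coef[0] / se_int
    q, q_p = _cochran_q(df, float(coef[1]))
    return MRResult(
        "Egger", float(coef[1]), se_slope,
        float(2 * stats.t.sf(abs(t_slope), dof)), len(df),
        egger_intercept=float(coef[0]),
        egger_intercept_p=float(2 * stats.t.sf(abs(t_int), dof)),
        q=q, q_pvalue=q_p,
    )


def _ratio_estimates(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument Wald ratios and their first-order standard errors.

    Instruments with a zero exposure effect are dropped (the ratio is
    undefined for them).
    """
    bx = df["BETA_EXP"].to_numpy()
    keep = bx != 0
    if not keep.all():
        logger.warning("dropping %d instruments with zero exposure effect",
                       int((~keep).sum()))
    bx = bx[keep]
    by = df["BETA_OUT"].to_numpy()[keep]
    se_out = df["SE_OUT"].to_numpy()[keep]
    return by / bx, se_out / np.abs(bx)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    b, w = ratios[order], weights[order]
    csum = np.cumsum(w) - 0.5 * w
    csum = csum / np.sum(w)
    below = np.searchsorted(csum, 0.5, side="right") - 1
    below = np.clip(below, 0, len(b) - 2)
    return float(b[below] + (b[below + 1] - b[below])
                 * (0.5 - csum[below]) / (csum[below + 1] - csum[below]))


def weighted_median(instruments, n_boot: int = 1000,
                    seed: int | np.random.Generator = 0) -> MRResult:
    """Weighted-median estimator: consistent when instruments carrying
    half the weight are valid. Standard error by parametric bootstrap."""
    df = _as_frame(instruments)
    if len(df) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    ratios, se_ratio = _ratio_estimates(df)
    weights = 1.0 / se_ratio ** 2
    beta = _weighted_median(ratios, weights)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(df)
    boot = np.empty(n_boot)
    bx = df["BETA_EXP"].to_numpy()
    by = df["BETA_OUT"].to_numpy()
    se_x = df["SE_EXP"].to_numpy()
    se_y = df["SE_OUT"].to_numpy()
    for b in range(n_boot):
        bx_b = bx + rng.normal(0.0, se_x)
        by_b = by + rng.normal(0.0, se_y)
        keep = bx_b != 0
        r_b = by_b[keep] / bx_b[keep]
        w_b = (bx_b[keep] / se_y[keep]) ** 2
        boot[b] = _weighted_median(r_b, w_b)
    se = float(np.std(boot, ddof=1))
    z = beta / se
    return MRResult("weighted_median", beta, se,
                    float(2 * stats.norm.sf(abs(z))), len(df))


def _mode_estimate(ratios: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    """Mode of the weighted kernel-smoothed ratio density (Hartwig).

    Kernel scale s = bandwidth * 0.9 * min(sd, mad/0.6745) * n^(-1/5);
    the density is evaluated on a fine grid over the ratio range.
    """
    n = ratios.size
    sd = np.std(ratios, ddof=1) if n > 1 else 1.0
    mad = np.median(np.abs(ratios - np.median(ratios))) / 0.6745
    scale = min(sd, mad) if mad > 0 else sd
    s = bandwidth * 0.9 * scale * n ** (-1 / 5)
    if s <= 0:
        return float(np.median(ratios))
    lo, hi = ratios.min() - 3 * s, ratios.max() + 3 * s
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(weights[None, :]
                  * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / s) ** 2),
                  axis=1)
    return float(grid[np.argmax(dens)])


def _mode_method(instruments, weighting: Literal["simple", "weighted"],
                 bandwidth: float, n_boot: int,
                 seed: int | np.random.Generator) -> MRResult:
    df = _as_frame(instruments)
    if len(df) < 3:
        raise ValueError("mode estimators require at least 3 instruments")
    ratios, se_ratio = _ratio_estimates(df)
    weights = (np.ones_like(ratios) if weighting == "simple"
               else 1.0 / se_ratio ** 2)
    beta = _mode_estimate(ratios, weights, bandwidth)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bx = df["BETA_EXP"].to_numpy()
    by = df["BETA_OUT"].to_numpy()
    se_x = df["SE_EXP"].to_numpy()
    se_y = df["SE_OUT"].to_numpy()
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + rng.normal(0.0, se_x)
        by_b = by + rng.normal(0.0, se_y)
        keep = bx_b != 0
        r_b = by_b[keep] / bx_b[keep]
        w_b = (np.ones(keep.sum()) if weighting == "simple"
               else (bx_b[keep] / se_y[keep]) ** 2)
        boot[b] = _mode_estimate(r_b, w_b, bandwidth)
    se = float(np.std(boot, ddof=1))
    z = beta / se
    name = "simple_mode" if weighting == "simple" else "weighted_mode"
    return MRResult(name, beta, se, float(2 * stats.norm.sf(abs(z))), len(df))


def simple_mode(instruments, bandwidth: float = 1.0, n_boot: int = 1000,
                seed: int | np.random.Generator = 0) -> MRResult:
    """Simple mode estimator (uniform kernel weights)."""
    return _mode_method(instruments, "simple", bandwidth, n_boot, seed)


def weighted_mode(instruments, bandwidth: float = 1.0, n_boot: int = 1000,
                  seed: int | np.random.Generator = 0) -> MRResult:
    """Weighted mode estimator (inverse-variance kernel weights)."""
    return _mode_method(instruments, "weighted", bandwidth, n_boot, seed)


def all_estimators(instruments, *, bandwidth: float = 1.0, n_boot: int = 1000,
                   seed: int | np.random.Generator = 0) -> list[MRResult]:
    """Run the five estimators on a harmonized instrument table."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        ivw(instruments),
        egger(instruments),
        weighted_median(instruments, n_boot=n_boot, seed=rng),
        simple_mode(instruments, bandwidth=bandwidth, n_boot=n_boot, seed=rng),
        weighted_mode(instruments, bandwidth=bandwidth, n_boot=n_boot, seed=rng),
    ]


# ---------------------------------------------------------------------------
# Heterogeneity and outliers


def _cochran_q(df: pd.DataFrame, estimate: float) -> tuple[float, float]:
    w = 1.0 / df["SE_OUT"].to_numpy() ** 2
    resid = df["BETA_OUT"].to_numpy() - estimate * df["BETA_EXP"].to_numpy()
    q = float(np.sum(w * resid ** 2))
    dof = len(df) - 1
    if dof <= 0:
        return q, math.nan
    return q, float(stats.chi2.sf(q, dof))


def heterogeneity_q(instruments, estimate: float | None = None) -> tuple[float, float]:
    """Cochran heterogeneity of the per-instrument ratio estimates.

    Q = sum_j w_j (beta_out_j - theta * beta_exp_j)^2 with
    w_j = 1/se_out_j^2, referred to chi-square with n-1 df. Uses the
    IVW estimate when none is supplied.
    """
    df = _as_frame(instruments)
    if estimate is None:
        estimate = ivw(df).beta
    return _cochran_q(df, estimate)


def remove_outliers(
    instruments,
    *,
    alpha: float = 0.05,
    min_remaining: int = 3,
) -> tuple[pd.DataFrame, list[dict]]:
    """Iterative heterogeneity-driven outlier removal with audit trail.

    While the global Cochran test rejects homogeneity at ``alpha`` and
    more than three instruments remain, the instrument contributing most
    to Q (at the current IVW estimate) is removed. Each removal is
    recorded with the Q decomposition at the time of removal. This is a
    deterministic heterogeneity-pruning procedure in the spirit of
    outlier-robust MR sensitivity analyses.
    """
    df = _as_frame(instruments).reset_index(drop=True)
    if len(df) < 4:
        raise ValueError("outlier removal requires at least 4 instruments")
    audit: list[dict] = []
    while len(df) > min_remaining:
        est = ivw(df).beta
        w = 1.0 / df["SE_OUT"].to_numpy() ** 2
        contrib = w * (df["BETA_OUT"].to_numpy() - est * df["BETA_EXP"].to_numpy()) ** 2
        q = float(contrib.sum())
        q_p = float(stats.chi2.sf(q, len(df) - 1))
        if q_p >= alpha:
            break
        worst = int(np.argmax(contrib))
        audit.append({
            "SNP": df.iloc[worst]["SNP"], "q_before": q, "q_pvalue_before": q_p,
            "contribution": float(contrib[worst]), "ivw_at_removal": est,
        })
        df = df.drop(df.index[worst]).reset_index(drop=True)
    return df, audit
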