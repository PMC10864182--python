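"""Synthetic multi-ancestry GWAS summary statistics with known truth.

Real depression GWAS cohorts are access-controlled, so every analysis in
this package is exercised against simulated summary statistics with
controlled ground truth: block-autoregressive LD, ancestry-specific
allele frequencies from a Balding-Nichols drift model, shared or
group-specific causal log-odds effects, and z-scores drawn from the
standard multivariate-normal summary-statistics model

    z ~ MVN(R @ lam, R),   lam_j = beta_j * sqrt(2 f_j (1 - f_j) * n_eff_half)

where R is the signed LD matrix, f_j the effect-allele frequency and
n_eff_half = 2 / (1/n_cases + 1/n_controls) the half effective sample
size of the emulated case-control study. Per-variant standard errors
follow the same score-information scale, se_j = 1 / sqrt(2 f_j (1-f_j)
* n_eff_half), so beta_j = z_j * se_j. Effects live directly on the
log-odds scale through this asymptotic approximation; no individual
genotypes are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDMatrix, Variant, effective_sample_size, z_to_p

__all__ = [
    "AncestryConfig", "CausalModel", "SimConfig",
    "make_variant_map", "simulate_ld_matrix", "balding_nichols_af",
    "simulate_zscores", "simulate_study", "generate_known_loci",
    "generate_mr_pair",
]


@dataclass
class AncestryConfig:
    """One emulated ancestry-group cohort.

    ``af`` holds per-variant effect-allele frequencies (clamped to
    [0.01, 0.99]); ``ld_blocks`` lists (block size, AR-1 correlation)
    pairs describing the group's LD structure.
    """

    label: str
    n_cases: int
    n_controls: int
    af: np.ndarray
    ld_blocks: list[tuple[int, float]]

    def __post_init__(self) -> None:
        self.af = np.clip(np.asarray(self.af, dtype=float), 0.01, 0.99)
        for size, rho in self.ld_blocks:
            if abs(rho) >= 1:
                raise ValueError(f"AR-1 correlation must satisfy |rho| < 1, got {rho}")

    @property
    def n_eff_half(self) -> float:
        return effective_sample_size(self.n_cases, self.n_controls)


@dataclass
class CausalModel:
    """Ground-truth causal configuration shared by the test harnesses."""

    causal_indices: np.ndarray
    beta_by_ancestry: dict[str, np.ndarray]
    shared: bool = True

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.beta_by_ancestry = {k: np.asarray(v, dtype=float)
                                 for k, v in self.beta_by_ancestry.items()}
        if self.shared:
            betas = list(self.beta_by_ancestry.values())
            for b in betas[1:]:
                if not np.array_equal(b, betas[0]):
                    raise ValueError("shared causal model requires identical effects per group")

    def beta_vector(self, label: str, n_variants: int) -> np.ndarray:
        """Dense per-variant effect vector for one ancestry group."""
        beta = np.zeros(n_variants)
        beta[self.causal_indices] = self.beta_by_ancestry[label]
        return beta


@dataclass
class SimConfig:
    """Reproducibility envelope: identical config implies identical output."""

    seed: int
    n_variants: int
    n_blocks: int
    spacing_bp: int = 5_000


def make_variant_map(n_variants: int, spacing_bp: int = 5_000, chrom: str = "1",
                     start: int = 1_000_000) -> list[Variant]:
    """Evenly spaced biallelic SNVs with alternating allele pairs."""
    pairs = [("A", "G"), ("C", "T")]
    return [Variant(f"rs{i + 1}", chrom, start + i * spacing_bp, *pairs[i % 2])
            for i in range(n_variants)]


def simulate_ld_matrix(
    block_sizes: Sequence[int],
    rhos: Sequence[float],
    variants: Sequence[Variant] | None = None,
    *,
    spacing_bp: int = 5_000,
    chrom: str = "1",
) -> LDMatrix:
    """Block-diagonal LD with AR-1 correlation within each block.

    Within a block, r_ij = rho^|i-j|; across blocks r = 0. AR-1 blocks
    are positive definite by construction for |rho| < 1.
    """
    if len(block_sizes) != len(rhos):
        raise ValueError("block_sizes and rhos must have equal length")
    for rho in rhos:
        if abs(rho) >= 1:
            raise ValueError(f"AR-1 correlation must satisfy |rho| < 1, got {rho}")
    n = int(np.sum(block_sizes))
    if variants is None:
        variants = make_variant_map(n, spacing_bp, chrom)
    if len(variants) != n:
        raise ValueError("variant list length must equal total block size")
    r = np.zeros((n, n))
    offset = 0
    for size, rho in zip(block_sizes, rhos):
        idx = np.arange(size)
        r[offset:offset + size, offset:offset + size] = rho ** np.abs(idx[:, None] - idx[None, :])
        offset += size
    return LDMatrix(list(variants), r, validate=False)


def balding_nichols_af(
    ancestral_af: np.ndarray,
    fst: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw group-specific allele frequencies around ancestral values.

    Uses the Balding-Nichols beta model: for ancestral frequency p and
    drift parameter F, the group frequency is Beta(p (1-F)/F,
    (1-p)(1-F)/F), clamped to [0.01, 0.99].
    """
    p = np.asarray(ancestral_af, dtype=float)
    if not 0 < fst < 1:
        raise ValueError(f"drift parameter must lie in (0, 1), got {fst}")
    a = (1.0 - fst) / fst
    return np.clip(rng.beta(p * a, (1.0 - p) * a), 0.01, 0.99)


def _block_slices(ld_blocks: Sequence[tuple[int, float]]):
    offset = 0
    for size, rho in ld_blocks:
        yield slice(offset, offset + size), rho
        offset += size


def simulate_zscores(
    ld: LDMatrix,
    beta: np.ndarray,
    af: np.ndarray,
    n_eff_half: float,
    rng: np.random.Generator,
    *,
    ld_blocks: Sequence[tuple[int, float]] | None = None,
) -> pd.DataFrame:
    """Draw one replicate of summary statistics for one study.

    The marginal (GWAS) noncentrality is mu = R @ lam with
    lam_j = beta_j * sqrt(2 f_j (1-f_j) n_eff_half); z is multivariate
    normal with mean mu and covariance R. Passing ``ld_blocks`` lets the
    sampler exploit the block structure (Cholesky per block) instead of
    factorizing the full matrix.

    Returns a DataFrame with columns Z, BETA, SE, P, EAF aligned to the
    panel's variant order.
    """
    n = len(ld)
    beta = np.asarray(beta, dtype=float)
    af = np.asarray(af, dtype=float)
    if beta.shape != (n,) or af.shape != (n,):
        raise ValueError("beta and af must match the LD panel dimension")
    info = 2.0 * af * (1.0 - af) * n_eff_half
    lam = beta * np.sqrt(info)
    noise = rng.standard_normal(n)
    if ld_blocks is not None:
        mu = np.empty(n)
        z = np.empty(n)
        for sl, rho in _block_slices(ld_blocks):
            r_block = ld.r[sl, sl]
            mu[sl] = r_block @ lam[sl]
            chol = np.linalg.cholesky(r_block)
            z[sl] = mu[sl] + chol @ noise[sl]
    else:
        mu = ld.r @ lam
        # eigen-based root tolerates the numerically semi-definite case
        vals, vecs = np.linalg.eigh(ld.r)
        root = vecs @ (np.sqrt(np.clip(vals, 0.0, None))[:, None] * vecs.T)
        z = mu + root @ noise
    se = 1.0 / np.sqrt(info)
    return pd.DataFrame({
        "Z": z, "BETA": z * se, "SE": se, "P": z_to_p(z), "EAF": af,
    })


def simulate_study(
    ld: LDMatrix,
    causal: CausalModel,
    ancestry: AncestryConfig,
    rng: np.random.Generator,
    *,
    missing_rate: float = 0.0,
    info_value: float = 1.0,
    n_studies: int = 2,
) -> pd.DataFrame:
    """Full canonical summary-statistics frame for one ancestry cohort.

    Wraps :func:`simulate_zscores` with the cohort's frequencies and
    sample sizes and attaches the bookkeeping columns (counts, info,
    contributing-study number). ``missing_rate`` masks a random subset
    of variants to emulate group-specific coverage gaps.
    """
    beta = causal.beta_vector(ancestry.label, len(ld))
    core = simulate_zscores(ld, beta, ancestry.af, ancestry.n_eff_half, rng,
                            ld_blocks=ancestry.ld_blocks or None)
    df = pd.DataFrame({
        "SNP": [v.id for v in ld.variants],
        "CHR": [v.chrom for v in ld.variants],
        "BP": [v.pos for v in ld.variants],
        "A1": [v.allele1 for v in ld.variants],
        "A2": [v.allele2 for v in ld.variants],
        "EAF": core["EAF"], "BETA": core["BETA"], "SE": core["SE"], "P": core["P"],
        "N_CAS": ancestry.n_cases, "N_CON": ancestry.n_controls,
        "INFO": info_value, "N_STUDIES": n_studies, "DIRECTION": ".",
    })
    if missing_rate > 0:
        keep = rng.random(len(df)) >= missing_rate
        df = df[keep].reset_index(drop=True)
    return df


def generate_known_loci(
    discovery: pd.DataFrame,
    ld_blocks: Sequence[tuple[int, float]],
    *,
    sig_threshold: float = 5e-8,
) -> pd.DataFrame:
    """Catalogue of discovery-significant loci from a simulated study.

    One candidate locus per LD block (blocks are independent by
    construction); the block's minimum-p variant is its lead and a
    catalogue row is emitted when the lead reaches the genome-wide
    threshold. Returns the known-loci TSV schema: SNP CHR BP A1 A2
    BETA_DISCOVERY EAF_DISCOVERY P_DISCOVERY SOURCE.
    """
    rows = []
    offset = 0
    for i, (size, _rho) in enumerate(ld_blocks):
        block = discovery.iloc[offset:offset + size]
        offset += size
        if block.empty:
            continue
        lead = block.loc[block["P"].idxmin()]
        if lead["P"] < sig_threshold:
            rows.append({
                "SNP": lead["SNP"], "CHR": lead["CHR"], "BP": int(lead["BP"]),
                "A1": lead["A1"], "A2": lead["A2"],
                "BETA_DISCOVERY": lead["BETA"], "EAF_DISCOVERY": lead["EAF"],
                "P_DISCOVERY": lead["P"], "SOURCE": f"sim_block_{i}",
            })
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2",
                                       "BETA_DISCOVERY", "EAF_DISCOVERY",
                                       "P_DISCOVERY", "SOURCE"])


def generate_mr_pair(
    n_instruments: int,
    theta: float,
    pleiotropy: Literal["none", "directional", "outlier"] = "none",
    seed: int | np.random.Generator = 0,
    *,
    alpha: float = 0.05,
    se_exposure: float = 0.01,
    se_outcome: float = 0.02,
    outlier_shift: float = 10.0,
) -> pd.DataFrame:
    """Synthetic harmonized exposure/outcome instrument table.

    True exposure effects are drawn as |N(0, 0.1^2)| + 0.05 (oriented to
    the exposure-increasing allele, as instrument selection does); the
    outcome effect of instrument j is theta * bx_j + alpha_j plus noise.
    The pleiotropy model sets alpha_j to zero everywhere ("none"), to a
    constant ``alpha`` ("directional"), or shifts a single instrument's
    outcome effect by ``outlier_shift`` outcome standard errors
    ("outlier"). Observed effects add N(0, se^2) estimation noise.

    Returns a frame with columns SNP, BETA_EXP, SE_EXP, BETA_OUT,
    SE_OUT, EAF, P_EXP and the ground-truth columns TRUE_BX, ALPHA.
    """
    if n_instruments < 3:
        raise ValueError("at least 3 instruments are required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bx_true = np.abs(rng.normal(0.0, 0.1, n_instruments)) + 0.05
    alpha_j = np.zeros(n_instruments)
    if pleiotropy == "directional":
        alpha_j[:] = alpha
    elif pleiotropy == "outlier":
        alpha_j[rng.integers(n_instruments)] = outlier_shift * se_outcome
    elif pleiotropy != "none":
        raise ValueError(f"unknown pleiotropy model {pleiotropy!r}")
    bx_hat = bx_true + rng.normal(0.0, se_exposure, n_instruments)
    by_hat = theta * bx_true + alpha_j + rng.normal(0.0, se_outcome, n_instruments)
    eaf = rng.uniform(0.05, 0.95, n_instruments)
    z_exp = bx_hat / se_exposure
    return pd.DataFrame({
        "SNP": [f"iv{i + 1}" for i in range(n_instruments)],
        "BETA_EXP": bx_hat, "SE_EXP": se_exposure,
        "BETA_OUT": by_hat, "SE_OUT": se_outcome,
        "EAF": eaf, "P_EXP": z_to_p(z_exp),
        "TRUE_BX": bx_true, "ALPHA": alpha_j,
    })
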