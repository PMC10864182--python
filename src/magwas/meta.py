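"""Inverse-variance-weighted fixed-effects meta-analysis and locus calling.

Implements METAL-style IVW pooling with Cochran heterogeneity, the
genomic inflation factor and its sample-size rescaling lambda_1000,
LD-score-regression intercept correction of test statistics (the
intercept itself is a supplied input, never estimated here), physical
locus definition around independent lead variants, and the novelty rule
against a catalogue of previously reported associations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDMatrix, StudyMeta, Variant, z_to_p

logger = logging.getLogger(__name__)

GENOME_WIDE_SIG = 5e-8
#: Median of the 1-df chi-square distribution.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class MetaResult:
    """Pooled association summary for one variant."""

    beta: float
    se: float
    z: float
    pvalue: float
    q: float
    i2: float
    n_studies: int
    direction: str

    @property
    def chi2(self) -> float:
        return self.z ** 2


@dataclass
class InflationStats:
    """Genomic-control summary for one meta-analysis."""

    lambda_gc: float
    lambda_1000: float
    ldsc_intercept: float | None = None
    corrected: bool = False


@dataclass
class Locus:
    """A genomic interval around one or more merged lead variants."""

    lead: Variant
    lead_pvalue: float
    start: int
    end: int
    member_leads: list[Variant] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.lead.chrom


def ivw_meta(betas: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Fixed-effects inverse-variance-weighted pooling of one variant.

    Weights are 1/se^2. Returns the pooled effect, its standard error
    1/sqrt(sum of weights), the z-statistic with a two-sided normal
    p-value, Cochran's Q over the contributing studies and
    I^2 = max(0, (Q - (k-1)) / Q).

    Studies with non-positive standard errors are excluded with a
    warning; at least one valid study is required.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    valid = ses > 0
    if not valid.all():
        logger.warning("ivw_meta: excluding %d studies with non-positive se", (~valid).sum())
        betas, ses = betas[valid], ses[valid]
    if betas.size == 0:
        raise ValueError("no valid studies to pool")
    w = 1.0 / ses ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = beta / se
    q = float(np.sum(w * (betas - beta) ** 2))
    k = betas.size
    i2 = max(0.0, (q - (k - 1)) / q) if k > 1 and q > 0 else 0.0
    direction = "".join("+" if b > 0 else "-" if b < 0 else "?" for b in betas)
    return MetaResult(beta=beta, se=se, z=z, pvalue=float(z_to_p(z)), q=q, i2=i2,
                      n_studies=k, direction=direction)


def meta_analyze_frames(frames: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Meta-analyse canonical summary-statistics frames across studies.

    ``frames`` maps study identifier to a canonical-column DataFrame;
    records are matched on SNP identifier (the caller harmonizes effect
    alleles beforehand, e.g. with
    :func:`magwas.sumstats.harmonize_to_reference`). Returns a canonical
    frame with pooled BETA/SE/P, N_STUDIES, a METAL-style DIRECTION
    string following the (sorted) study order, and Q/I2 columns.
    """
    study_ids = sorted(frames)
    pieces = []
    for sid in study_ids:
        df = frames[sid][["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE",
                          "N_CAS", "N_CON"]].copy()
        df["study"] = sid
        pieces.append(df)
    stacked = pd.concat(pieces, ignore_index=True)
    stacked = stacked[stacked["SE"] > 0]

    w = 1.0 / stacked["SE"] ** 2
    stacked["_w"] = w
    stacked["_wb"] = w * stacked["BETA"]
    stacked["_weaf"] = w * stacked["EAF"]

    g = stacked.groupby("SNP", sort=False)
    agg = g.agg(
        CHR=("CHR", "first"), BP=("BP", "first"),
        A1=("A1", "first"), A2=("A2", "first"),
        sw=("_w", "sum"), swb=("_wb", "sum"), sweaf=("_weaf", "sum"),
        N_CAS=("N_CAS", "sum"), N_CON=("N_CON", "sum"),
        N_STUDIES=("study", "size"),
    )
    beta = agg["swb"] / agg["sw"]
    se = 1.0 / np.sqrt(agg["sw"])
    z = beta / se

    # Cochran Q per variant
    stacked = stacked.merge(beta.rename("_pooled"), left_on="SNP", right_index=True)
    stacked["_qterm"] = stacked["_w"] * (stacked["BETA"] - stacked["_pooled"]) ** 2
    q = stacked.groupby("SNP", sort=False)["_qterm"].sum().reindex(agg.index)
    k = agg["N_STUDIES"]
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where((k > 1) & (q > 0), np.maximum(0.0, (q - (k - 1)) / q), 0.0)

    sign = stacked.assign(_s=np.sign(stacked["BETA"]))
    dir_map = {sid: sign[sign["study"] == sid].set_index("SNP")["_s"] for sid in study_ids}

    def _direction(snp: str) -> str:
        out = []
        for sid in study_ids:
            s = dir_map[sid].get(snp)
            out.append("?" if s is None else "+" if s > 0 else "-" if s < 0 else "?")
        return "".join(out)

    result = pd.DataFrame({
        "SNP": agg.index, "CHR": agg["CHR"].values, "BP": agg["BP"].values,
        "A1": agg["A1"].values, "A2": agg["A2"].values,
        "EAF": (agg["sweaf"] / agg["sw"]).values,
        "BETA": beta.values, "SE": se.values,
        "P": z_to_p(z.values),
        "N_CAS": agg["N_CAS"].values, "N_CON": agg["N_CON"].values,
        "INFO": np.nan,
        "N_STUDIES": agg["N_STUDIES"].values,
        "DIRECTION": [_direction(s) for s in agg.index],
        "Q": q.values, "I2": i2,
    })
    return result.reset_index(drop=True)


def min_study_filter(meta: pd.DataFrame, min_studies: int = 2) -> pd.DataFrame:
    """Retain variants present in at least ``min_studies`` studies."""
    return meta[meta["N_STUDIES"] >= min_studies].reset_index(drop=True)


def study_inclusion_filter(
    studies: Sequence[StudyMeta],
    sensitivity: bool = False,
    *,
    min_ratio: float = 0.25,
) -> list[StudyMeta]:
    """Study-level inclusion rule.

    In the default mode all studies are included. In sensitivity mode,
    studies with an extreme case-control ratio (n_cases/n_controls
    strictly below 0.25) or flagged as adolescent cohorts are excluded.
    """
    if not sensitivity:
        return list(studies)
    kept = [s for s in studies
            if s.case_control_ratio >= min_ratio and not s.adolescent_cohort]
    logger.info("study_inclusion_filter: excluded %d of %d studies",
                len(studies) - len(kept), len(studies))
    return kept


def genomic_lambda(pvalues: Sequence[float]) -> float:
    """Genomic inflation factor: median association chi-square over its
    null expectation (the 1-df chi-square median, 0.4549...)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("genomic_lambda requires at least one p-value")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def lambda_1000(lam: float, n_cases: float, n_controls: float) -> float:
    """Rescale lambda to a study of 1,000 cases and 1,000 controls.

    lambda_1000 = 1 + (lambda - 1) * (1/n_cases + 1/n_controls) * 500.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 1.0 + (lam - 1.0) * (1.0 / n_cases + 1.0 / n_controls) * 500.0


def apply_intercept_correction(meta: pd.DataFrame, intercept: float) -> pd.DataFrame:
    """Deflate test statistics by a supplied LDSC intercept.

    Divides each variant's chi-square by the intercept — equivalently
    scales the standard error by sqrt(intercept) — and recomputes the
    p-value; effect estimates are unchanged. The intercept is an input
    estimated elsewhere (LDSC regression is out of scope here).
    """
    if intercept <= 0:
        raise ValueError(f"intercept must be positive, got {intercept}")
    out = meta.copy()
    out["SE"] = out["SE"] * math.sqrt(intercept)
    z = out["BETA"] / out["SE"]
    out["P"] = z_to_p(z.to_numpy())
    return out


def define_loci(
    leads: Sequence[tuple[Variant, float]],
    *,
    flank: int = 250_000,
    merge_distance: int = 500_000,
) -> list[Locus]:
    """Aggregate independent lead variants into physical loci.

    Each locus spans its lead +/- ``flank`` bp. Leads on the same
    chromosome separated by less than ``merge_distance`` are merged
    transitively into a single locus whose lead is the minimum-p member;
    the merged interval spans from the leftmost member lead - flank to
    the rightmost member lead + flank. Loci are returned sorted by
    chromosome then position.
    """
    by_chrom: dict[str, list[tuple[Variant, float]]] = {}
    for v, p in leads:
        by_chrom.setdefault(v.chrom, []).append((v, p))

    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom], key=lambda t: t[0].pos)
        cluster: list[tuple[Variant, float]] = []
        for entry in entries:
            if cluster and entry[0].pos - cluster[-1][0].pos >= merge_distance:
                loci.append(_make_locus(cluster, flank))
                cluster = []
            cluster.append(entry)
        if cluster:
            loci.append(_make_locus(cluster, flank))
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


def _make_locus(cluster: list[tuple[Variant, float]], flank: int) -> Locus:
    lead, lead_p = min(cluster, key=lambda t: t[1])
    positions = [v.pos for v, _ in cluster]
    return Locus(
        lead=lead, lead_pvalue=lead_p,
        start=max(1, min(positions) - flank), end=max(positions) + flank,
        member_leads=[v for v, _ in cluster],
    )


def classify_novel(
    lead: Variant,
    catalogue: Iterable[Variant],
    ld: LDMatrix | None = None,
    *,
    r2_threshold: float = 0.1,
    distance_threshold: int = 250_000,
) -> bool:
    """Novelty rule against previously reported variants.

    A lead is novel iff, for every catalogue variant, the pairwise LD
    satisfies r^2 < 0.1 AND the physical distance exceeds 250 kb
    (variants on other chromosomes trivially satisfy both). When the LD
    panel does not cover both variants the r^2 clause falls back to
    distance only, with a logged warning.
    """
    for known in catalogue:
        same_chrom = known.chrom == lead.chrom
        distance_close = same_chrom and abs(known.pos - lead.pos) <= distance_threshold
        if distance_close:
            return False
        if same_chrom:
            if ld is not None and lead.id in ld and known.id in ld:
                if ld.r2_between(lead.id, known.id) >= r2_threshold:
                    return False
            elif ld is not None:
                logger.warning("classify_novel: %s or %s absent from LD panel; "
                               "using distance-only rule", lead.id, known.id)
    return True
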