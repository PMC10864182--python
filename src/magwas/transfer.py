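"""Power-adjusted transferability (PAT) of discovery loci across ancestries.

Given a catalogue of loci discovered in one ancestry group (typically
European), this module asks whether each locus shows evidence of
association in a target ancestry group, after accounting for the
statistical power the target study has to see it:

1. each discovery locus is expanded into a proxy credible set — the
   lead plus all variants with r^2 >= 0.8 within 50 kb whose discovery
   p-value is below 100x the lead's;
2. a locus is "transferable" when at least one set member passes a
   size-penalized significance threshold 10^(log10(0.05) - Pf*(N-1))
   in the target data with a direction of effect consistent with
   discovery. The penalization factor Pf is an empirically estimated
   slope correcting for the larger number of effectively independent
   proxies in target ancestries with weaker LD;
3. per-locus replication power is computed from the discovery effect and
   the target allele frequency and sample size; the PAT ratio divides
   the observed number of transferable loci by the power-expected
   number, with a percentile-bootstrap confidence interval;
4. well-powered loci with no signal anywhere nearby are called
   "nontransferable".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDMatrix, Variant

logger = logging.getLogger(__name__)

#: Penalization factors estimated from an uncorrelated-trait GWAS
#: (breast cancer) regressed on credible-set size, per target group.
PF_CONSTANTS = {"AFR": 0.008341, "EAS": 0.007378, "SAS": 0.006847, "HIS": 0.003147}

CHI2_95 = float(stats.chi2.ppf(0.95, 1))  # 3.8415


@dataclass(frozen=True)
class KnownLocus:
    """A previously reported lead signal from a discovery GWAS."""

    lead: Variant
    beta_discovery: float
    eaf_discovery: float
    p_discovery: float


@dataclass
class CredibleSetT:
    """Lead variant plus correlated discovery proxies used for transfer.

    Members satisfy r^2 >= 0.8 with the lead, lie within 50 kb, and have
    discovery p < 100x the lead p. Parallel arrays carry each member's
    discovery effect sign and p-value.
    """

    lead: Variant
    members: list[Variant]
    beta_discovery: np.ndarray
    p_discovery: np.ndarray

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class PenalizationFit:
    """Per-group penalized-threshold slope with its fit diagnostics."""

    p_f: float
    intercept: float
    stderr: float
    n_loci: int


@dataclass
class TransferRecord:
    """Per-locus transferability assessment in one target group."""

    lead_id: str
    n_members: int
    power: float
    min_target_p: float
    transferable: bool
    nontransferable: bool
    assessable: bool = True


@dataclass
class PATResult:
    """Observed vs power-expected transferable loci in a target group."""

    observed: int
    expected: float
    ratio: float
    ci_low: float
    ci_high: float
    records: list[TransferRecord] = field(default_factory=list)


def read_known_loci(path) -> list[KnownLocus]:
    """Read a known-loci catalogue TSV (SNP CHR BP A1 A2 BETA_DISCOVERY
    EAF_DISCOVERY P_DISCOVERY SOURCE)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    return [
        KnownLocus(
            lead=Variant(str(r.SNP), str(r.CHR), int(r.BP), str(r.A1), str(r.A2)),
            beta_discovery=float(r.BETA_DISCOVERY),
            eaf_discovery=float(r.EAF_DISCOVERY),
            p_discovery=float(r.P_DISCOVERY),
        )
        for r in df.itertuples(index=False)
    ]


def known_loci_from_frame(catalogue: pd.DataFrame) -> list[KnownLocus]:
    """Convert a known-loci catalogue DataFrame into locus records."""
    return [
        KnownLocus(
            lead=Variant(str(r.SNP), str(r.CHR), int(r.BP), str(r.A1), str(r.A2)),
            beta_discovery=float(r.BETA_DISCOVERY),
            eaf_discovery=float(r.EAF_DISCOVERY),
            p_discovery=float(r.P_DISCOVERY),
        )
        for r in catalogue.itertuples(index=False)
    ]


def build_transfer_credible_set(
    locus: KnownLocus,
    discovery: pd.DataFrame,
    ld: LDMatrix,
    *,
    r2_threshold: float = 0.8,
    window: int = 50_000,
    p_multiplier: float = 100.0,
) -> CredibleSetT:
    """Expand a discovery lead into its correlated proxy set.

    Members are panel variants with r^2 >= 0.8 to the lead, within the
    50 kb window, whose discovery p-value is below 100x the lead's. The
    lead is always a member. A lead absent from the LD panel yields a
    singleton set with a warning.
    """
    lead = locus.lead
    disc = discovery.set_index("SNP") if discovery.index.name != "SNP" else discovery
    if lead.id not in ld:
        logger.warning("lead %s absent from discovery LD panel; credible set = {lead}", lead.id)
        return CredibleSetT(lead, [lead], np.array([locus.beta_discovery]),
                            np.array([locus.p_discovery]))
    li = ld.index_of(lead.id)
    members: list[Variant] = [lead]
    betas = [locus.beta_discovery]
    ps = [locus.p_discovery]
    p_cut = p_multiplier * locus.p_discovery
    candidates = np.nonzero(
        (ld.chroms == lead.chrom)
        & (np.abs(ld.positions - lead.pos) <= window)
        & (ld.r[li] ** 2 >= r2_threshold)
    )[0]
    for j in candidates:
        v = ld.variants[j]
        if j == li:
            continue
        if v.id not in disc.index:
            continue
        row = disc.loc[v.id]
        if float(row["P"]) < p_cut:
            members.append(v)
            betas.append(float(row["BETA"]))
            ps.append(float(row["P"]))
    return CredibleSetT(lead, members, np.asarray(betas), np.asarray(ps))


def estimate_penalization_factor(
    credible_sets: Sequence[CredibleSetT],
    null_target: pd.DataFrame,
) -> PenalizationFit:
    """Estimate the penalization slope Pf from null-trait loci.

    For loci of a trait uncorrelated with the target outcome, regresses
    -log10(minimum target p-value among credible-set members) on the
    credible-set size N by ordinary least squares. The fitted slope is
    Pf: it measures how much the best member p-value inflates per extra
    proxy variant purely through multiple testing under the target
    group's LD. Requires at least 10 loci.
    """
    if len(credible_sets) < 10:
        raise ValueError("penalization fit requires at least 10 null loci")
    tgt = null_target.set_index("SNP") if null_target.index.name != "SNP" else null_target
    sizes, neglogp = [], []
    for cs in credible_sets:
        present = [m.id for m in cs.members if m.id in tgt.index]
        if not present:
            continue
        pmin = float(tgt.loc[present, "P"].min())
        sizes.append(cs.n)
        neglogp.append(-math.log10(pmin))
    if len(sizes) < 10:
        raise ValueError("fewer than 10 null loci with target data; fit unstable")
    fit = stats.linregress(sizes, neglogp)
    return PenalizationFit(p_f=float(fit.slope), intercept=float(fit.intercept),
                           stderr=float(fit.stderr), n_loci=len(sizes))


def transfer_threshold(n_members: int, p_f: float) -> float:
    """Size-penalized significance threshold 10^(log10(0.05) - Pf(N-1)).

    Equals 0.05 exactly for a singleton set and decreases geometrically
    in the number of credible-set proxies.
    """
    if n_members < 1:
        raise ValueError("credible set must contain at least the lead")
    return 10.0 ** (math.log10(0.05) - p_f * (n_members - 1))


def call_transferable(
    cs: CredibleSetT,
    target: pd.DataFrame,
    p_f: float,
) -> tuple[bool, float]:
    """Transferability call for one locus in one target group.

    True iff at least one credible-set member is associated in the
    target data below the penalized threshold with the same direction of
    effect as in discovery. Target records must be harmonized to the
    discovery effect alleles. Returns ``(flag, min member target p)``;
    a locus with no member present in the target data is unassessable
    (flag False, p NaN).
    """
    tgt = target.set_index("SNP") if target.index.name != "SNP" else target
    threshold = transfer_threshold(cs.n, p_f)
    min_p = math.inf
    hit = False
    any_present = False
    for member, disc_beta in zip(cs.members, cs.beta_discovery):
        if member.id not in tgt.index:
            continue
        any_present = True
        row = tgt.loc[member.id]
        p = float(row["P"])
        min_p = min(min_p, p)
        if p < threshold and np.sign(float(row["BETA"])) == np.sign(disc_beta):
            hit = True
    if not any_present:
        logger.info("locus %s unassessable: no credible-set member in target data", cs.lead.id)
        return False, math.nan
    return hit, min_p


def locus_power(
    beta_discovery: float,
    eaf_target: float,
    n_cases: float,
    n_controls: float,
    *,
    alpha: float = 0.05,
) -> float:
    """Replication power for an additive log-odds effect at level alpha.

    The expected standard error of the target estimate follows the
    logistic-score asymptotics se = 1/sqrt(2 f (1-f) N phi (1-phi)) with
    N the total sample and phi the case fraction; power is the upper
    tail of the noncentral 1-df chi-square with noncentrality
    (beta/se)^2 beyond the central chi-square critical value.
    """
    if not 0.0 < eaf_target < 1.0:
        logger.warning("degenerate target frequency %.3g; power set to 0", eaf_target)
        return 0.0
    n_total = n_cases + n_controls
    phi = n_cases / n_total
    var = 2.0 * eaf_target * (1.0 - eaf_target) * n_total * phi * (1.0 - phi)
    ncp = beta_discovery ** 2 * var
    crit = stats.chi2.ppf(1.0 - alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp))


def call_nontransferable(
    cs: CredibleSetT,
    target: pd.DataFrame,
    member_powers: Sequence[float],
    *,
    window: int = 50_000,
    power_threshold: float = 0.8,
    member_p_floor: float = 0.05,
    neighbor_p_floor: float = 1e-3,
) -> bool:
    """Nontransferability call: well powered yet signal-free.

    True iff the set contains a member with power > 0.8, no member has
    target p < 0.05, and no variant within 50 kb of the lead has target
    p < 1e-3.
    """
    if max(member_powers, default=0.0) <= power_threshold:
        return False
    tgt = target.set_index("SNP") if target.index.name != "SNP" else target
    member_ps = [float(tgt.loc[m.id, "P"]) for m in cs.members if m.id in tgt.index]
    if not member_ps or min(member_ps) < member_p_floor:
        return False
    lead = cs.lead
    near = target[(target["CHR"].astype(str) == lead.chrom)
                  & (np.abs(target["BP"] - lead.pos) <= window)]
    if not near.empty and float(near["P"].min()) < neighbor_p_floor:
        return False
    return True


def pat_ratio(
    records: Sequence[TransferRecord],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PATResult:
    """PAT ratio with a percentile-bootstrap confidence interval.

    Observed is the number of transferable loci; expected is the sum of
    per-locus replication powers. Unassessable loci (no member in the
    target data) contribute to neither sum. The 95% CI resamples loci
    with replacement, keeping each locus's (flag, power) pair intact.
    """
    usable = [r for r in records if r.assessable]
    powers = np.array([r.power for r in usable])
    flags = np.array([r.transferable for r in usable], dtype=float)
    expected = float(powers.sum())
    observed = int(flags.sum())
    if expected == 0:
        raise ValueError("expected count is zero; PAT ratio undefined")
    ratio = observed / expected
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(usable)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_obs = flags[idx].sum(axis=1)
    boot_exp = powers[idx].sum(axis=1)
    valid = boot_exp > 0
    boot_ratio = boot_obs[valid] / boot_exp[valid]
    ci_low, ci_high = np.percentile(boot_ratio, [2.5, 97.5])
    return PATResult(observed=observed, expected=expected, ratio=ratio,
                     ci_low=float(ci_low), ci_high=float(ci_high),
                     records=list(records))


def assess_transferability(
    catalogue: Sequence[KnownLocus],
    discovery: pd.DataFrame,
    target: pd.DataFrame,
    discovery_ld: LDMatrix,
    p_f: float,
    n_cases: float,
    n_controls: float,
    *,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PATResult:
    """End-to-end PAT assessment of a locus catalogue in one target group.

    Builds each locus's credible set from the discovery data, computes
    per-member replication power from the discovery effect and the
    target allele frequency and sample size, makes the transferable and
    nontransferable calls, and aggregates into the PAT ratio.
    """
    tgt = target.set_index("SNP", drop=False)
    records: list[TransferRecord] = []
    for locus in catalogue:
        cs = build_transfer_credible_set(locus, discovery, discovery_ld)
        member_powers = []
        for member, b in zip(cs.members, cs.beta_discovery):
            if member.id in tgt.index:
                f = float(tgt.loc[member.id, "EAF"])
                member_powers.append(locus_power(b, f, n_cases, n_controls))
            else:
                member_powers.append(0.0)
        flag, min_p = call_transferable(cs, target, p_f)
        assessable = not math.isnan(min_p)
        power = max(member_powers) if assessable else 0.0
        nontrans = (call_nontransferable(cs, target, member_powers)
                    if assessable and not flag else False)
        records.append(TransferRecord(
            lead_id=locus.lead.id, n_members=cs.n, power=power,
            min_target_p=min_p, transferable=flag, nontransferable=nontrans,
            assessable=assessable,
        ))
    return pat_ratio(records, n_boot=n_boot, seed=seed)
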