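"""Core data model and I/O for GWAS summary statistics.

Defines the variant/association record types shared by all analysis
modules, readers and writers for the canonical tab-separated summary
statistics format, allele harmonization, variant-level quality-control
filters, and the score-test -> log-odds effect-scale conversions needed
to pool mixed-model score statistics with logistic-regression results.

Canonical summary-statistics columns (tab-delimited, header required,
"." for missing)::

    SNP CHR BP A1 A2 EAF BETA SE P N_CAS N_CON INFO N_STUDIES DIRECTION

A1 is the effect allele; BETA is the log-odds effect per A1 allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical column order of the summary-statistics TSV dialect.
CANONICAL_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P",
    "N_CAS", "N_CON", "INFO", "N_STUDIES", "DIRECTION",
]

#: Columns a row must carry to yield a usable association record.
MANDATORY_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P"]

_NUCLEOTIDES = {"A", "C", "G", "T"}
_PALINDROMIC_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Variant:
    """A genomic variant keyed by identifier, position and allele pair.

    ``allele1`` is the effect allele. Indel alleles are recoded to the
    single letters "I" (longer allele) and "D" (shorter allele) by
    :func:`recode_indels`; SNV alleles are single nucleotides.
    """

    id: str
    chrom: str
    pos: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.allele1 == self.allele2:
            raise ValueError(f"alleles must differ, got {self.allele1}/{self.allele2}")

    @property
    def is_indel(self) -> bool:
        return len(self.allele1) != len(self.allele2) or {self.allele1, self.allele2} & {"I", "D"} != set()

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous SNVs (A/T or C/G)."""
        return frozenset({self.allele1, self.allele2}) in _PALINDROMIC_PAIRS


@dataclass
class AssocRecord:
    """One variant's association summary in one study or meta-analysis."""

    variant: Variant
    eaf: float
    beta: float
    se: float
    pvalue: float
    n_cases: float = math.nan
    n_controls: float = math.nan
    info: float = math.nan
    n_studies: int = 1
    direction: str | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"standard error must be positive, got {self.se}")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"EAF must lie in [0, 1], got {self.eaf}")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class ScoreStat:
    """Score-test summary from a mixed-model association analysis.

    ``case_fraction`` is the proportion of cases in the analysed sample,
    needed to map the score-scale effect onto the log-odds scale.
    """

    score: float
    variance: float
    case_fraction: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"score variance must be positive, got {self.variance}")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError(f"case fraction must lie in (0, 1), got {self.case_fraction}")


@dataclass(frozen=True)
class StudyMeta:
    """Study-level metadata used by inclusion filters."""

    study_id: str
    ancestry_group: str
    outcome_definition: str = "broad"
    n_cases: int = 0
    n_controls: int = 0
    adolescent_cohort: bool = False

    @property
    def case_control_ratio(self) -> float:
        return self.n_cases / self.n_controls


ANCESTRY_GROUPS = ("AFR", "EAS", "SAS", "HIS", "EUR")


class LDMatrix:
    """Variant-indexed symmetric matrix of signed LD correlations.

    Parameters
    ----------
    variants
        Ordered variant list matching the rows/columns of ``r``.
    r
        Square matrix of signed correlations, unit diagonal.
    validate
        Check symmetry, unit diagonal, |r| <= 1 and positive
        semi-definiteness (minimum eigenvalue >= -1e-8).
    """

    def __init__(self, variants: Sequence[Variant], r: np.ndarray, *, validate: bool = True):
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("LD matrix must be square")
        if len(variants) != r.shape[0]:
            raise ValueError("variant list length must match matrix dimension")
        if validate:
            if not np.allclose(r, r.T, atol=1e-8):
                raise ValueError("LD matrix must be symmetric")
            if not np.allclose(np.diag(r), 1.0, atol=1e-8):
                raise ValueError("LD matrix must have unit diagonal")
            if np.any(np.abs(r) > 1.0 + 1e-8):
                raise ValueError("LD correlations must satisfy |r| <= 1")
            if np.linalg.eigvalsh(r).min() < -1e-8:
                raise ValueError("LD matrix must be positive semi-definite")
        self.variants = list(variants)
        self.r = r
        self._index = {v.id: i for i, v in enumerate(self.variants)}
        self.positions = np.array([v.pos for v in self.variants], dtype=np.int64)
        self.chroms = np.array([v.chrom for v in self.variants], dtype=object)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index_of(self, variant_id: str) -> int:
        return self._index[variant_id]

    def r_between(self, id_a: str, id_b: str) -> float:
        """Signed correlation between two variants in the panel."""
        return float(self.r[self._index[id_a], self._index[id_b]])

    def r2_between(self, id_a: str, id_b: str) -> float:
        return self.r_between(id_a, id_b) ** 2

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix([self.variants[i] for i in idx], self.r[np.ix_(idx, idx)], validate=False)


# ---------------------------------------------------------------------------
# File I/O


def _records_to_frame(records: Iterable[AssocRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        v = rec.variant
        rows.append({
            "SNP": v.id, "CHR": v.chrom, "BP": v.pos, "A1": v.allele1, "A2": v.allele2,
            "EAF": rec.eaf, "BETA": rec.beta, "SE": rec.se, "P": rec.pvalue,
            "N_CAS": rec.n_cases, "N_CON": rec.n_controls, "INFO": rec.info,
            "N_STUDIES": rec.n_studies,
            "DIRECTION": rec.direction if rec.direction is not None else ".",
        })
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def _frame_to_records(df: pd.DataFrame) -> tuple[list[AssocRecord], int]:
    records: list[AssocRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        vals = row._asdict()
        mandatory = [vals[c] for c in MANDATORY_COLUMNS]
        if any(pd.isna(x) for x in mandatory):
            n_dropped += 1
            continue
        try:
            variant = Variant(str(vals["SNP"]), str(vals["CHR"]), int(vals["BP"]),
                              str(vals["A1"]), str(vals["A2"]))
            rec = AssocRecord(
                variant=variant,
                eaf=float(vals["EAF"]), beta=float(vals["BETA"]),
                se=float(vals["SE"]), pvalue=float(vals["P"]),
                n_cases=float(vals.get("N_CAS", math.nan)),
                n_controls=float(vals.get("N_CON", math.nan)),
                info=float(vals.get("INFO", math.nan)),
                n_studies=int(vals["N_STUDIES"]) if not pd.isna(vals.get("N_STUDIES")) else 1,
                direction=None if pd.isna(vals.get("DIRECTION")) or vals.get("DIRECTION") == "." else str(vals["DIRECTION"]),
            )
        except (ValueError, TypeError):
            n_dropped += 1
            continue
        records.append(rec)
    return records, n_dropped


def read_sumstats_frame(path: str | Path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a summary-statistics TSV into a canonical-column DataFrame.

    ``dialect`` maps canonical column names to the file's column names
    (e.g. ``{"SNP": "rsid", "P": "pval"}``); unmapped canonical columns
    are looked up by their own name. Missing optional columns are filled
    with NaN; a missing mandatory column is a hard error naming it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str}, na_values=["."])
    if dialect:
        rename = {src: canon for canon, src in dialect.items() if src in df.columns}
        df = df.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} absent from {path}")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["CHR"] = df["CHR"].astype(str)
    return df[CANONICAL_COLUMNS]


def read_sumstats(path: str | Path, dialect: Mapping[str, str] | None = None) -> list[AssocRecord]:
    """Read summary statistics as :class:`AssocRecord` objects.

    Rows missing any mandatory field are dropped; the dropped count is
    logged at INFO level.
    """
    df = read_sumstats_frame(path, dialect)
    records, n_dropped = _frame_to_records(df)
    if n_dropped:
        logger.info("read_sumstats: dropped %d rows with missing mandatory fields from %s",
                    n_dropped, path)
    return records


def write_sumstats(records: Iterable[AssocRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write records (or a canonical-column DataFrame) as canonical TSV."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[CANONICAL_COLUMNS]
    else:
        df = _records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_ld_matrix(variants_path: str | Path, matrix_path: str | Path) -> LDMatrix:
    """Read an LD panel from a variant-list TSV plus a dense matrix file.

    The variant list carries the canonical SNP/CHR/BP/A1/A2 columns; the
    matrix file is whitespace-delimited signed r, row order matching the
    variant list.
    """
    vdf = pd.read_csv(variants_path, sep="\t", dtype={"CHR": str})
    variants = [Variant(str(r.SNP), str(r.CHR), int(r.BP), str(r.A1), str(r.A2))
                for r in vdf.itertuples(index=False)]
    r = np.loadtxt(matrix_path)
    if r.ndim == 0:
        r = r.reshape(1, 1)
    return LDMatrix(variants, r)


def write_ld_matrix(ld: LDMatrix, variants_path: str | Path, matrix_path: str | Path) -> None:
    vdf = pd.DataFrame({
        "SNP": [v.id for v in ld.variants],
        "CHR": [v.chrom for v in ld.variants],
        "BP": [v.pos for v in ld.variants],
        "A1": [v.allele1 for v in ld.variants],
        "A2": [v.allele2 for v in ld.variants],
    })
    vdf.to_csv(variants_path, sep="\t", index=False)
    np.savetxt(matrix_path, ld.r, fmt="%.8g")


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` text configuration file.

    Blank lines and lines starting with ``#`` are ignored. Values are
    returned as strings; callers coerce types.
    """
    config: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, _, value = line.partition("=")
        config[key.strip()] = value.strip()
    return config


# ---------------------------------------------------------------------------
# Harmonization and recoding


def recode_indels(records: Sequence[AssocRecord]) -> list[AssocRecord]:
    """Recode indel alleles to I/D and drop ambiguous indel positions.

    For each insertion/deletion the longer allele becomes "I" and the
    shorter "D". Positions carrying two or more distinct indel allele
    patterns are unresolvable after recoding, so all indel records at
    such positions are removed. Records whose alleles are multi-base but
    equal-length cannot be oriented and are dropped with a warning.
    SNVs pass through untouched.
    """
    patterns: dict[tuple[str, int], set[frozenset[str]]] = {}
    for rec in records:
        v = rec.variant
        if len(v.allele1) != len(v.allele2):
            patterns.setdefault((v.chrom, v.pos), set()).add(frozenset({v.allele1, v.allele2}))

    out: list[AssocRecord] = []
    for rec in records:
        v = rec.variant
        if len(v.allele1) == len(v.allele2):
            if len(v.allele1) > 1:
                logger.warning("dropping %s: equal-length multi-base alleles %s/%s are ambiguous",
                               v.id, v.allele1, v.allele2)
                continue
            out.append(rec)
            continue
        if len(patterns[(v.chrom, v.pos)]) > 1:
            continue  # >=2 distinct indel patterns at this position
        a1, a2 = ("I", "D") if len(v.allele1) > len(v.allele2) else ("D", "I")
        out.append(replace(rec, variant=Variant(v.id, v.chrom, v.pos, a1, a2)))
    return out


def harmonize_to_reference(
    record: AssocRecord,
    ref_effect_allele: str,
    ref_other_allele: str,
    ref_eaf: float | None = None,
) -> AssocRecord | None:
    """Orient a record to a reference effect/other allele pair.

    If the record's alleles are swapped relative to the reference the
    effect sign is flipped and the EAF complemented. Strand flips of
    non-palindromic SNVs are resolved by complementing. Palindromic SNVs
    (A/T, C/G) are orientable only by frequency: when both the record
    and reference EAF are available and both < 0.42 or both > 0.58 the
    alleles are matched by frequency; otherwise the record is excluded.
    Returns ``None`` for any record that cannot be reconciled.
    """
    v = record.variant
    ref = (ref_effect_allele, ref_other_allele)

    if v.is_palindromic:
        if ref_eaf is None or frozenset(ref) != frozenset({v.allele1, v.allele2}):
            if frozenset(ref) != frozenset({v.allele1, v.allele2}):
                logger.info("excluding %s: alleles incompatible with reference", v.id)
            else:
                logger.info("excluding palindromic %s: no reference EAF", v.id)
            return None
        if record.eaf < 0.42 and ref_eaf < 0.42:
            same_allele = True
        elif record.eaf > 0.58 and ref_eaf > 0.58:
            same_allele = True
        elif (record.eaf < 0.42 and ref_eaf > 0.58) or (record.eaf > 0.58 and ref_eaf < 0.42):
            same_allele = False
        else:
            logger.info("excluding palindromic %s: EAF %.3f uninformative", v.id, record.eaf)
            return None
        # frequency rank is the sole authority for palindromic variants:
        # matching minor/major status identifies the same physical allele
        # regardless of which strand either file reports
        if same_allele:
            return replace(record, variant=Variant(v.id, v.chrom, v.pos, ref[0], ref[1]))
        return replace(
            record,
            variant=Variant(v.id, v.chrom, v.pos, ref[0], ref[1]),
            beta=-record.beta,
            eaf=1.0 - record.eaf,
        )

    pair = (v.allele1, v.allele2)
    if pair == ref:
        return record
    if pair == (ref[1], ref[0]):
        return replace(
            record,
            variant=Variant(v.id, v.chrom, v.pos, ref[0], ref[1]),
            beta=-record.beta,
            eaf=1.0 - record.eaf,
        )
    # try a strand flip for SNVs
    if v.allele1 in _COMPLEMENT and v.allele2 in _COMPLEMENT:
        flipped = (_COMPLEMENT[v.allele1], _COMPLEMENT[v.allele2])
        if flipped == ref:
            return replace(record, variant=Variant(v.id, v.chrom, v.pos, ref[0], ref[1]))
        if flipped == (ref[1], ref[0]):
            return replace(
                record,
                variant=Variant(v.id, v.chrom, v.pos, ref[0], ref[1]),
                beta=-record.beta,
                eaf=1.0 - record.eaf,
            )
    logger.info("excluding %s: alleles %s/%s incompatible with reference %s/%s",
                v.id, v.allele1, v.allele2, ref[0], ref[1])
    return None


# ---------------------------------------------------------------------------
# QC filters and effect-scale conversions


def effective_allele_count(eaf: float, n_total: float, info: float) -> float:
    """Effective allele count 2 * MAF * (1 - MAF) * N * R^2."""
    maf = min(eaf, 1.0 - eaf)
    return 2.0 * maf * (1.0 - maf) * n_total * info


def qc_filter(
    records: Sequence[AssocRecord],
    n_total: float,
    small_study: bool = False,
    *,
    info_threshold: float = 0.7,
    eac_threshold: float = 50.0,
    small_study_maf: float = 0.05,
) -> list[AssocRecord]:
    """Variant-level QC: imputation accuracy and effective allele count.

    Keeps records with ``info >= 0.7`` and effective allele count
    ``2 * MAF * (1-MAF) * N * R^2 >= 50``. For small studies a minimum
    minor allele frequency of 0.05 is additionally required. Counts
    removed per criterion are logged.
    """
    kept: list[AssocRecord] = []
    n_info = n_eac = n_maf = 0
    for rec in records:
        if not (rec.info >= info_threshold):
            n_info += 1
            continue
        if effective_allele_count(rec.eaf, n_total, rec.info) < eac_threshold:
            n_eac += 1
            continue
        if small_study and rec.maf < small_study_maf:
            n_maf += 1
            continue
        kept.append(rec)
    logger.info("qc_filter: removed %d (info), %d (EAC), %d (small-study MAF); kept %d",
                n_info, n_eac, n_maf, len(kept))
    return kept


def score_to_beta(s: ScoreStat) -> tuple[float, float]:
    """Convert a score statistic to a linear-scale effect and s.e.m.

    beta = score / variance, se = sqrt(variance) / variance.
    """
    beta = s.score / s.variance
    se = math.sqrt(s.variance) / s.variance
    return beta, se


def logor_scale(beta: float, se: float, case_fraction: float) -> tuple[float, float]:
    """Rescale a score-scale effect to the approximate log-odds scale.

    Divides both the effect and its standard error by pi * (1 - pi),
    where pi is the case fraction; the z-statistic is unchanged.
    """
    if not 0.0 < case_fraction < 1.0:
        raise ValueError(f"case fraction must lie in (0, 1), got {case_fraction}")
    denom = case_fraction * (1.0 - case_fraction)
    return beta / denom, se / denom


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Half effective sample size 2 / (1/n_cases + 1/n_controls).

    The harmonic-style rescaling of a case-control design to the size of
    a balanced study; equals n_cases (= n_controls) when balanced.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 2.0 / (1.0 / n_cases + 1.0 / n_controls)


def z_to_p(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal p-value for a z-statistic."""
    return 2.0 * stats.norm.sf(np.abs(z))


def z_to_neglog10p(z: float | np.ndarray) -> float | np.ndarray:
    """-log10 of the two-sided normal p-value, safe against underflow.

    Computed from the log survival function so extreme statistics (for
    which the p-value underflows double precision) remain finite.
    """
    return -(stats.norm.logsf(np.abs(z)) + math.log(2.0)) / math.log(10.0)
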