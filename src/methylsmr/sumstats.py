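"""Reading, validation and allele harmonization of GWAS / cis-QTL summary
statistics, and an LD reference backed by a genotype dosage matrix.

Two tabular dialects are supported out of the box:

* GWAS: the whitespace-delimited ``.ma`` layout
  (``SNP A1 A2 freq b se p n``), optionally extended with ``chr``/``bp``
  columns when downstream steps need variant coordinates.
* cis-QTL: a tab-delimited long format, one row per (probe, SNP) pair
  (``probe probe_chr probe_bp gene SNP chr bp A1 A2 freq b se p``).

All effect sizes are interpreted per copy of the effect allele (A1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default half-width of the cis window around a probe, in bp
DEFAULT_CIS_WINDOW = 500_000

#: default tolerance band around eaf = 0.5 inside which palindromic
#: (A/T, C/G) SNPs are considered unresolvable by frequency
DEFAULT_FREQ_TOL = 0.2


class SummaryStatsError(ValueError):
    """Raised for unrecoverable problems in a summary-statistics file."""


@dataclass
class VariantAssoc:
    """One SNP's association record in one study.

    ``beta`` is the additive per-effect-allele regression coefficient,
    ``se`` its standard error and ``p`` the reported two-sided p-value.
    ``chrom``/``pos`` and ``eaf``/``n`` may be missing (``None``) depending
    on the source dialect.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    eaf: float | None = None
    n: float | None = None
    chrom: str | None = None
    pos: int | None = None
    p_inconsistent: bool = False

    @property
    def z(self) -> float:
        return self.beta / self.se

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.effect_allele not in VALID_ALLELES:
            problems.append(f"bad effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            problems.append(f"bad other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            problems.append("identical alleles")
        if not (self.se > 0) or not math.isfinite(self.se):
            problems.append(f"se={self.se} not > 0")
        if not (0 < self.p <= 1):
            problems.append(f"p={self.p} outside (0,1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            problems.append(f"eaf={self.eaf} outside [0,1]")
        if not math.isfinite(self.beta):
            problems.append(f"beta={self.beta} not finite")
        return problems

    def check_p_consistency(self, factor: float = 10.0) -> bool:
        """True when the stored p is within ``factor``x of the two-sided
        normal p recomputed from beta/se.

        Meta-analysed p-values legitimately drift from the Wald p, so an
        inconsistency flags rather than excludes the record.
        """
        p_wald = wald_p(self.beta, self.se)
        lo = max(p_wald / factor, 0.0)
        hi = min(p_wald * factor, 1.0)
        return lo <= self.p <= hi


def wald_p(beta: float, se: float) -> float:
    """Two-sided normal p-value for beta/se, floored to stay in (0, 1]."""
    z = abs(beta / se)
    # sf underflows to 0 around |z| ~ 39; keep p in the open interval
    return max(2.0 * stats.norm.sf(z), 5e-324)


@dataclass
class ProbeCisSet:
    """All cis SNP association records for one methylation/expression probe."""

    probe_id: str
    probe_chrom: str
    probe_pos: int
    records: list[VariantAssoc] = field(default_factory=list)
    gene_annotation: str | None = None

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise SummaryStatsError(
                f"duplicate SNP ids for probe {self.probe_id}: {dup}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def get(self, snp_id: str) -> VariantAssoc | None:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        return None

    def subset(self, snp_ids: Iterable[str]) -> "ProbeCisSet":
        keep = set(snp_ids)
        return ProbeCisSet(
            probe_id=self.probe_id,
            probe_chrom=self.probe_chrom,
            probe_pos=self.probe_pos,
            gene_annotation=self.gene_annotation,
            records=[r for r in self.records if r.snp_id in keep],
        )


class RecordList(list):
    """A list of records that also carries read diagnostics."""

    def __init__(self, records=(), n_skipped: int = 0, n_flagged: int = 0,
                 n_out_of_window: int = 0):
        super().__init__(records)
        self.n_skipped = n_skipped
        self.n_flagged = n_flagged
        self.n_out_of_window = n_out_of_window


# ---------------------------------------------------------------------------
# dialects

GWAS_MA_DIALECT: Mapping[str, str] = {
    "snp_id": "SNP", "effect_allele": "A1", "other_allele": "A2",
    "eaf": "freq", "beta": "b", "se": "se", "p": "p", "n": "n",
    # optional coordinate columns (present in the extended dialect)
    "chrom": "chr", "pos": "bp",
}

QTL_LONG_DIALECT: Mapping[str, str] = {
    "probe_id": "probe", "probe_chrom": "probe_chr", "probe_pos": "probe_bp",
    "gene": "gene", "snp_id": "SNP", "chrom": "chr", "pos": "bp",
    "effect_allele": "A1", "other_allele": "A2", "eaf": "freq",
    "beta": "b", "se": "se", "p": "p",
}

_GWAS_MANDATORY = ("snp_id", "effect_allele", "other_allele", "beta", "se", "p")
_QTL_MANDATORY = _GWAS_MANDATORY + ("probe_id", "probe_chrom", "probe_pos",
                                    "chrom", "pos")


def _require_columns(df: pd.DataFrame, dialect: Mapping[str, str],
                     mandatory: Sequence[str], path) -> None:
    missing = [dialect[k] for k in mandatory
               if dialect.get(k) not in df.columns]
    if missing:
        raise SummaryStatsError(
            f"{path}: missing mandatory column(s) {missing}"
        )


def _row_to_assoc(row, dialect: Mapping[str, str], want_coords: bool
                  ) -> VariantAssoc:
    def opt(key, cast):
        col = dialect.get(key)
        if col is None or col not in row or pd.isna(row[col]):
            return None
        return cast(row[col])

    return VariantAssoc(
        snp_id=str(row[dialect["snp_id"]]),
        effect_allele=str(row[dialect["effect_allele"]]).upper(),
        other_allele=str(row[dialect["other_allele"]]).upper(),
        eaf=opt("eaf", float),
        beta=float(row[dialect["beta"]]),
        se=float(row[dialect["se"]]),
        p=float(row[dialect["p"]]),
        n=opt("n", float),
        chrom=(str(row[dialect["chrom"]]) if want_coords and
               dialect.get("chrom") in row and not pd.isna(row[dialect["chrom"]])
               else None),
        pos=opt("pos", lambda v: int(float(v))) if want_coords else None,
    )


def read_gwas(path, dialect: Mapping[str, str] | None = None) -> RecordList:
    """Read a GWAS summary table in the ``.ma`` dialect.

    Rows failing validation are skipped (counted in ``.n_skipped``); rows
    whose stored p disagrees with the Wald p recomputed from beta/se by more
    than 10x are retained but flagged (``p_inconsistent=True``, counted in
    ``.n_flagged``). A missing mandatory column is a hard error.
    """
    dialect = dict(GWAS_MA_DIALECT if dialect is None else dialect)
    df = pd.read_csv(path, sep=r"\s+")
    _require_columns(df, dialect, _GWAS_MANDATORY, path)
    out = RecordList()
    for _, row in df.iterrows():
        try:
            rec = _row_to_assoc(row, dialect, want_coords=True)
        except (ValueError, TypeError) as exc:
            out.n_skipped += 1
            logger.warning("%s: unparsable row skipped (%s)", path, exc)
            continue
        problems = rec.validate()
        if problems:
            out.n_skipped += 1
            logger.warning("%s: %s skipped: %s", path, rec.snp_id,
                           "; ".join(problems))
            continue
        if not rec.check_p_consistency():
            rec.p_inconsistent = True
            out.n_flagged += 1
            logger.warning("%s: %s p=%.3g inconsistent with |beta/se|=%.3g",
                           path, rec.snp_id, rec.p, abs(rec.z))
        out.append(rec)
    return out


def read_qtl(path, dialect: Mapping[str, str] | None = None,
             cis_window: int = DEFAULT_CIS_WINDOW) -> list[ProbeCisSet]:
    """Read a long-format cis-QTL table, grouped by probe.

    SNPs farther than ``cis_window`` bp from the probe (or on another
    chromosome) are excluded and logged. A duplicated (probe, SNP) pair is a
    hard error.
    """
    dialect = dict(QTL_LONG_DIALECT if dialect is None else dialect)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, dialect, _QTL_MANDATORY, path)

    pcol, scol = dialect["probe_id"], dialect["snp_id"]
    dups = df[df.duplicated([pcol, scol], keep=False)]
    if len(dups):
        pair = dups.iloc[0]
        raise SummaryStatsError(
            f"{path}: duplicate row for probe {pair[pcol]!r} / "
            f"SNP {pair[scol]!r}"
        )

    probes: list[ProbeCisSet] = []
    for probe_id, grp in df.groupby(pcol, sort=True):
        first = grp.iloc[0]
        probe_chrom = str(first[dialect["probe_chrom"]])
        probe_pos = int(first[dialect["probe_pos"]])
        gene_col = dialect.get("gene")
        gene = (str(first[gene_col])
                if gene_col in grp.columns and not pd.isna(first[gene_col])
                else None)
        records = []
        for _, row in grp.iterrows():
            try:
                rec = _row_to_assoc(row, dialect, want_coords=True)
            except (ValueError, TypeError) as exc:
                logger.warning("%s: unparsable row skipped (%s)", path, exc)
                continue
            if rec.validate():
                logger.warning("%s: %s/%s skipped: %s", path, probe_id,
                               rec.snp_id, "; ".join(rec.validate()))
                continue
            if rec.chrom != probe_chrom or abs(rec.pos - probe_pos) > cis_window:
                logger.info("%s: %s excluded from probe %s: outside +/-%d bp "
                            "cis window", path, rec.snp_id, probe_id, cis_window)
                continue
            if not rec.check_p_consistency():
                rec.p_inconsistent = True
            records.append(rec)
        probes.append(ProbeCisSet(probe_id=str(probe_id),
                                  probe_chrom=probe_chrom,
                                  probe_pos=probe_pos,
                                  gene_annotation=gene,
                                  records=records))
    return probes


def write_gwas(records: Iterable[VariantAssoc], path) -> None:
    """Write records back out in the extended ``.ma`` dialect."""
    rows = []
    for r in records:
        rows.append({
            "SNP": r.snp_id, "A1": r.effect_allele, "A2": r.other_allele,
            "freq": r.eaf, "b": r.beta, "se": r.se, "p": r.p, "n": r.n,
            "chr": r.chrom, "bp": r.pos,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_qtl(probes: Iterable[ProbeCisSet], path) -> None:
    rows = []
    for probe in probes:
        for r in probe.records:
            rows.append({
                "probe": probe.probe_id, "probe_chr": probe.probe_chrom,
                "probe_bp": probe.probe_pos, "gene": probe.gene_annotation,
                "SNP": r.snp_id, "chr": r.chrom, "bp": r.pos,
                "A1": r.effect_allele, "A2": r.other_allele,
                "freq": r.eaf, "b": r.beta, "se": r.se, "p": r.p,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# allele harmonization

@dataclass
class HarmonizedPair:
    """Outcome of aligning record ``b`` onto record ``a``'s allele frame.

    When ``ok`` is False, ``reason`` is one of ``"allele_mismatch"`` or
    ``"ambiguous_palindrome"`` and ``b`` is None.
    """

    ok: bool
    a: VariantAssoc
    b: VariantAssoc | None
    reason: str | None = None
    flipped: bool = False


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT[ea] == oa


def _flip(rec: VariantAssoc) -> VariantAssoc:
    return replace(rec,
                   effect_allele=rec.other_allele,
                   other_allele=rec.effect_allele,
                   beta=-rec.beta,
                   eaf=None if rec.eaf is None else 1.0 - rec.eaf)


def harmonize(a: VariantAssoc, b: VariantAssoc,
              freq_tol: float = DEFAULT_FREQ_TOL) -> HarmonizedPair:
    """Align ``b`` onto ``a``'s effect-allele orientation.

    Straightforward cases: matching allele pairs are kept; swapped pairs have
    beta negated and eaf complemented; non-palindromic strand flips are
    resolved by complementing. Palindromic (A/T, C/G) pairs are resolved by
    allele frequency only when both eafs sit outside
    ``[0.5 - freq_tol, 0.5 + freq_tol]``; otherwise the pair is excluded with
    reason ``"ambiguous_palindrome"``. Irreconcilable allele sets are
    excluded with reason ``"allele_mismatch"``.
    """
    if a.snp_id != b.snp_id:
        raise ValueError(f"snp_id mismatch: {a.snp_id} vs {b.snp_id}")
    ea, oa = a.effect_allele, a.other_allele

    if _is_palindromic(ea, oa):
        if {b.effect_allele, b.other_allele} != {ea, oa}:
            return HarmonizedPair(False, a, None, "allele_mismatch")
        if a.eaf is None or b.eaf is None:
            return HarmonizedPair(False, a, None, "ambiguous_palindrome")
        lo, hi = 0.5 - freq_tol, 0.5 + freq_tol
        if lo <= a.eaf <= hi or lo <= b.eaf <= hi:
            return HarmonizedPair(False, a, None, "ambiguous_palindrome")
        b_oriented = b if b.effect_allele == ea else _flip(b)
        # after orientation the minor/major side must agree; a disagreement
        # means the two studies counted complementary strands
        if (a.eaf - 0.5) * (b_oriented.eaf - 0.5) < 0:
            b_oriented = _flip(b_oriented)
        return HarmonizedPair(True, a, b_oriented,
                              flipped=b_oriented.beta != b.beta)

    pairs = {
        (b.effect_allele, b.other_allele): False,
        (b.other_allele, b.effect_allele): True,
        (COMPLEMENT[b.effect_allele], COMPLEMENT[b.other_allele]): False,
        (COMPLEMENT[b.other_allele], COMPLEMENT[b.effect_allele]): True,
    }
    key = (ea, oa)
    if key not in pairs:
        return HarmonizedPair(False, a, None, "allele_mismatch")
    if pairs[key]:
        return HarmonizedPair(True, a, replace(_flip(b), effect_allele=ea,
                                               other_allele=oa), flipped=True)
    return HarmonizedPair(True, a, replace(b, effect_allele=ea,
                                           other_allele=oa), flipped=False)


# ---------------------------------------------------------------------------
# LD reference

class LDReference:
    """Pairwise allelic correlations computed from a dosage matrix.

    Dosages count copies of each SNP's *effect allele* (0..2, missing as
    NaN); correlations are Pearson correlations over individuals with
    complete data for both SNPs, on the orientation recorded in
    ``effect_alleles``.
    """

    def __init__(self, snp_ids: Sequence[str], dosages: np.ndarray,
                 effect_alleles: Sequence[str] | None = None,
                 other_alleles: Sequence[str] | None = None):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2 or dosages.shape[1] != len(snp_ids):
            raise ValueError("dosage matrix shape does not match snp_ids")
        self.snp_ids = list(snp_ids)
        self.index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self.index) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids in LD reference")
        self.dosages = dosages
        self.effect_alleles = (list(effect_alleles) if effect_alleles
                               else [None] * len(self.snp_ids))
        self.other_alleles = (list(other_alleles) if other_alleles
                              else [None] * len(self.snp_ids))

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.index

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def orientation(self, snp_id: str, effect_allele: str) -> int:
        """+1 if the reference counts ``effect_allele`` (directly or on the
        opposite strand), -1 if it counts the other allele, for use when a
        correlation must be expressed on a study's allele frame."""
        i = self.index[snp_id]
        ref_ea = self.effect_alleles[i]
        if ref_ea is None:
            return 1
        if effect_allele in (ref_ea, COMPLEMENT[ref_ea]):
            return 1
        return -1

    def corr(self, snp_i: str, snp_j: str) -> float:
        """Pearson correlation of dosages over complete-data individuals."""
        i, j = self.index[snp_i], self.index[snp_j]
        x, y = self.dosages[:, i], self.dosages[:, j]
        mask = ~(np.isnan(x) | np.isnan(y))
        x, y = x[mask], y[mask]
        if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            bad = snp_i if (x.size < 2 or np.ptp(x) == 0) else snp_j
            raise ValueError(f"monomorphic: {bad}")
        xc, yc = x - x.mean(), y - y.mean()
        r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
        return min(1.0, max(-1.0, r))

    def corr_matrix(self, snp_ids: Sequence[str],
                    orientations: Sequence[int] | None = None) -> np.ndarray:
        """Full correlation matrix for ``snp_ids``; ``orientations`` (+/-1
        per SNP) re-expresses it on a study's effect-allele frame."""
        k = len(snp_ids)
        cols = [self.index[s] for s in snp_ids]
        sub = self.dosages[:, cols]
        if not np.isnan(sub).any():
            sd = sub.std(axis=0)
            if np.any(sd == 0):
                bad = snp_ids[int(np.argmax(sd == 0))]
                raise ValueError(f"monomorphic: {bad}")
            r = np.corrcoef(sub, rowvar=False)
        else:
            r = np.empty((k, k))
            for i in range(k):
                r[i, i] = 1.0
                for j in range(i + 1, k):
                    r[i, j] = r[j, i] = self.corr(snp_ids[i], snp_ids[j])
        if orientations is not None:
            s = np.asarray(orientations, dtype=float)
            r = r * np.outer(s, s)
        np.fill_diagonal(r, 1.0)
        return np.clip(r, -1.0, 1.0)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dosage_file(cls, path) -> "LDReference":
        """Read a tab-delimited dosage matrix.

        First column is the individual id; remaining header cells are SNP
        ids, optionally annotated ``id:EA:OA`` to record which allele the
        dosage counts.
        """
        df = pd.read_csv(path, sep="\t")
        header = list(df.columns[1:])
        ids, eas, oas = [], [], []
        for cell in header:
            parts = cell.split(":")
            if len(parts) == 3:
                ids.append(parts[0])
                eas.append(parts[1].upper())
                oas.append(parts[2].upper())
            else:
                ids.append(cell)
                eas.append(None)
                oas.append(None)
        dos = df.iloc[:, 1:].to_numpy(dtype=float)
        if np.nanmin(dos) < 0 or np.nanmax(dos) > 2:
            raise SummaryStatsError(f"{path}: dosages outside [0, 2]")
        return cls(ids, dos, eas, oas)

    @classmethod
    def from_vcf(cls, path) -> "LDReference":
        """Read dosages from a VCF: the DS FORMAT field when present,
        otherwise the ALT-allele count from GT. The ALT allele is the
        counted (effect) allele."""
        from cyvcf2 import VCF

        ids, eas, oas, cols = [], [], [], []
        vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 missing
        for var in vcf:
            if len(var.ALT) != 1:
                logger.info("%s: skipping multi-allelic %s", path, var.ID)
                continue
            try:
                ds_field = var.format("DS")
            except KeyError:
                ds_field = None
            if ds_field is not None:
                ds = np.asarray(ds_field, dtype=float).reshape(-1)
            else:
                gt = np.asarray(var.gt_types, dtype=float)
                # cyvcf2 gt_types: 0=hom-ref 1=het 2=hom-alt 3=missing
                ds = np.where(gt == 3, np.nan, np.where(gt == 2, 2.0, gt))
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            eas.append(var.ALT[0].upper())
            oas.append(var.REF.upper())
            cols.append(ds)
        return cls(ids, np.column_stack(cols), eas, oas)

    def write_dosage_file(self, path, float_format: str = "%.4g") -> None:
        header = ["IID"]
        for sid, ea, oa in zip(self.snp_ids, self.effect_alleles,
                               self.other_alleles):
            header.append(f"{sid}:{ea}:{oa}" if ea and oa else sid)
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for i in range(self.n_individuals):
                cells = [f"ind{i + 1}"]
                for v in self.dosages[i]:
                    cells.append("" if np.isnan(v) else float_format % v)
                fh.write("\t".join(cells) + "\n")


def ld_correlation(ref: LDReference, snp_i: str, snp_j: str) -> float:
    """Pairwise dosage correlation between two SNPs in the reference."""
    return ref.corr(snp_i, snp_j)
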