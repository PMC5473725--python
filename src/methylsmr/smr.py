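"""Single-instrument summary-data Mendelian randomization (SMR).

The SMR test asks whether a molecular trait (methylation at a CpG site, or
a transcript) and a complex trait share a genetic signal, using only
summary statistics. With the instrument SNP's QTL z-score z2 = b_qtl/se_qtl
and GWAS z-score z1 = b_gwas/se_gwas, the test statistic is

    T_SMR = z1^2 * z2^2 / (z1^2 + z2^2)   ~  chi-square, 1 df,

the effect estimate is the Wald ratio b_SMR = b_gwas / b_qtl, and its
standard error is defined through the statistic, se_SMR = |b_SMR| /
sqrt(T_SMR). T_SMR is harmonic in the two arms, so the test can never be
more significant than its weaker arm: T_SMR <= min(z1^2, z2^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from scipy import stats

from .sumstats import ProbeCisSet, VariantAssoc


class DegenerateInstrumentError(ValueError):
    """Raised when the instrument's QTL effect is exactly zero."""


class SMRStats(NamedTuple):
    b_smr: float
    se_smr: float
    t_smr: float
    p_smr: float
    chi2_smr: float


@dataclass
class SMRRecord:
    """One probe-trait SMR result.

    ``t_smr`` is the signed ratio b_SMR/se_SMR (the heatmap statistic);
    ``t_smr**2`` equals ``chi2_smr``. ``classification`` is assigned by the
    pipeline once family-wise thresholds are known.
    """

    probe_id: str
    trait_id: str
    instrument_snp: str | None
    b_qtl: float | None = None
    se_qtl: float | None = None
    b_gwas: float | None = None
    se_gwas: float | None = None
    b_smr: float | None = None
    se_smr: float | None = None
    t_smr: float | None = None
    p_smr: float | None = None
    chi2_smr: float | None = None
    heidi_p: float | None = None
    n_heidi_snps: int = 0
    heidi_status: str | None = None
    classification: str = "untested"
    reason: str | None = None
    probe_chrom: str | None = None
    probe_pos: int | None = None
    gene_annotation: str | None = None

    @property
    def tested(self) -> bool:
        return self.p_smr is not None


def smr_test(b_gwas: float, se_gwas: float,
             b_qtl: float, se_qtl: float) -> SMRStats:
    """Compute the SMR ratio estimate and chi-square test.

    The p-value always comes from the 1-df chi-square survival function of
    T_SMR (never a normal approximation of b_SMR/se_SMR), so extreme tails
    are stable. ``b_qtl = 0`` raises DegenerateInstrumentError.
    """
    if not (se_gwas > 0 and se_qtl > 0):
        raise ValueError("standard errors must be positive")
    if b_qtl == 0:
        raise DegenerateInstrumentError("degenerate_instrument")
    z1 = b_gwas / se_gwas
    z2 = b_qtl / se_qtl
    denom = z1 * z1 + z2 * z2
    chi2_smr = (z1 * z1) * (z2 * z2) / denom if denom > 0 else 0.0
    b_smr = b_gwas / b_qtl
    if chi2_smr > 0:
        se_smr = abs(b_smr) / math.sqrt(chi2_smr)
        t_smr = math.copysign(math.sqrt(chi2_smr), b_smr)
    else:
        se_smr = math.inf
        t_smr = 0.0
    p_smr = float(stats.chi2.sf(chi2_smr, df=1))
    p_smr = max(p_smr, 5e-324)
    return SMRStats(b_smr, se_smr, t_smr, p_smr, chi2_smr)


def select_instrument(probe: ProbeCisSet, qtl_p_threshold: float
                      ) -> tuple[VariantAssoc | None, str | None]:
    """Pick the instrument SNP for a probe.

    ``probe`` must already be restricted to SNPs shared with (and harmonized
    to) the GWAS. Returns the shared SNP with the smallest QTL p-value iff
    that p-value is below ``qtl_p_threshold``; ties break by larger |z|,
    then smaller genomic position, then SNP id. Returns ``(None, reason)``
    when the probe is untestable.
    """
    if not probe.records:
        return None, "no_shared_snps"
    best = min(probe.records,
               key=lambda r: (r.p, -abs(r.z), r.pos if r.pos is not None
                              else math.inf, r.snp_id))
    if best.p >= qtl_p_threshold:
        return None, "no_significant_qtl"
    return best, None
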