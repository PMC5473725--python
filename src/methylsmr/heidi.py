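"""HEIDI: heterogeneity in dependent instruments.

A significant SMR test can reflect either pleiotropy (one causal variant
driving both the QTL and the GWAS signal) or linkage (two distinct causal
variants in LD). Under pleiotropy the Wald ratio b_xy = b_gwas/b_qtl is the
same whichever cis SNP is used as the instrument, so the deviations

    d_i = b_xy(SNP i) - b_xy(top SNP)

of alternative instruments from the top instrument are all zero in
expectation. HEIDI tests that joint null. The d_i are correlated because
the instruments are in LD and share the top-SNP term; their covariance is
obtained by the first-order delta method, propagating the sampling
uncertainty of every QTL and GWAS coefficient including the top SNP's
(dropping the top-SNP QTL term also drops a negative covariance component
and makes the test measurably conservative when instruments are in strong
LD). The statistic sum_i (d_i/se(d_i))^2 is, under the
null, a weighted sum of independent 1-df chi-squares whose weights are the
eigenvalues of the correlation matrix of the standardized d vector; its
tail probability is evaluated by Imhof's characteristic-function inversion,
with a fixed-seed Monte-Carlo fallback when the quadrature misbehaves.

Two distinct causal variants in perfect LD are indistinguishable from
pleiotropy: the d_i are then identically zero in expectation too, and HEIDI
retains only its nominal rejection rate. Power grows as the LD between the
two causal variants weakens.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate

from .sumstats import LDReference, ProbeCisSet, VariantAssoc

#: defaults for alternative-instrument selection
R2_MIN = 0.05
R2_MAX = 0.9
MAX_SNPS = 20
MIN_SNPS = 3
#: QTL p-value below which a cis SNP qualifies as an alternative
#: instrument (|z| > 3.16)
P_INCLUDE = 1.57e-3

#: LD submatrices with a condition number above this are pruned
COND_MAX = 1e8

_MC_SEED = 987654321
_MC_DRAWS = 1_000_000


@dataclass
class HEIDIResult:
    probe_id: str
    trait_id: str
    top_snp: str
    snps_used: list[str] = field(default_factory=list)
    d_stats: np.ndarray | None = None
    stat: float | None = None
    p_heidi: float | None = None
    status: str = "ok"          # ok | too_few_snps | ld_unavailable
    tail_method: str | None = None  # imhof | montecarlo | exact_zero


@dataclass
class HEIDISelection:
    snps: list[str]
    status: str  # ok | too_few_snps


def heidi_select_snps(probe: ProbeCisSet, top_snp: str, ld: LDReference,
                      r2_min: float = R2_MIN, r2_max: float = R2_MAX,
                      max_snps: int = MAX_SNPS, min_snps: int = MIN_SNPS,
                      p_include: float = P_INCLUDE) -> HEIDISelection:
    """Choose alternative instruments for the HEIDI test.

    Eligible SNPs (excluding the top SNP) must be in the LD reference, have
    QTL p below ``p_include`` and r^2 to the top SNP within
    ``[r2_min, r2_max]``; they are ranked by QTL significance and truncated
    to ``max_snps``. Fewer than ``min_snps`` qualifying SNPs yields status
    ``too_few_snps``.
    """
    if top_snp not in ld or probe.get(top_snp) is None:
        raise ValueError(f"top SNP {top_snp} not available for probe "
                         f"{probe.probe_id}")
    candidates = []
    for rec in probe.records:
        if rec.snp_id == top_snp or rec.snp_id not in ld:
            continue
        if rec.p >= p_include:
            continue
        try:
            r2 = ld.corr(top_snp, rec.snp_id) ** 2
        except ValueError:
            continue
        if not (r2_min <= r2 <= r2_max):
            continue
        candidates.append(rec)
    candidates.sort(key=lambda r: (r.p, -abs(r.z),
                                   r.pos if r.pos is not None else math.inf,
                                   r.snp_id))
    snps = [r.snp_id for r in candidates[:max_snps]]
    status = "ok" if len(snps) >= min_snps else "too_few_snps"
    return HEIDISelection(snps, status)


def _prune_ld(snp_ids: list[str], probe: ProbeCisSet, r: np.ndarray,
              min_snps: int) -> tuple[list[str], np.ndarray]:
    """Drop the most collinear alternative SNPs (deterministically) until the
    LD submatrix condition number is acceptable. snp_ids[0] is the top SNP
    and is never dropped."""
    ids = list(snp_ids)
    while len(ids) - 1 >= min_snps:
        cond = np.linalg.cond(r)
        if cond <= COND_MAX:
            return ids, r
        # most collinear alternative: largest max |r| to any other SNP;
        # ties break by larger QTL p then id
        absr = np.abs(r - np.eye(len(ids)))
        scores = []
        for i in range(1, len(ids)):
            rec = probe.get(ids[i])
            scores.append((absr[i].max(), rec.p if rec else 1.0, ids[i], i))
        scores.sort(reverse=True)
        drop = scores[0][3]
        keep = [j for j in range(len(ids)) if j != drop]
        ids = [ids[j] for j in keep]
        r = r[np.ix_(keep, keep)]
    if np.linalg.cond(r) <= COND_MAX:
        return ids, r
    return ids, r  # caller checks condition again


def wchi2_sf(q: float, weights: Sequence[float]) -> tuple[float, str]:
    """Upper tail P(sum_k w_k X_k > q), X_k iid 1-df chi-squares.

    Evaluated by Imhof's (1961) numerical inversion of the characteristic
    function; falls back to fixed-seed Monte Carlo (10^6 draws) when the
    quadrature result is unusable. Returns (p, method).
    """
    lam = np.asarray(weights, dtype=float)
    lam = lam[lam > 1e-12 * max(lam.max(), 1.0)]
    if lam.size == 0 or q <= 0:
        return 1.0, "exact_zero"

    def integrand(x: float) -> float:
        # Imhof integrand mapped from u in (0, inf) to x in (0, 1)
        u = x / (1.0 - x)
        lu = lam * u
        theta = 0.5 * np.sum(np.arctan(lu)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p(lu * lu)))
        return math.sin(theta) / (u * rho) / (1.0 - x) ** 2

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(integrand, 0.0, 1.0, limit=5000,
                                      epsabs=1e-11, epsrel=1e-11)
        p = 0.5 + val / math.pi
    except Exception:  # pragma: no cover - quad failure is rare
        p, err = math.nan, math.inf
    if not math.isfinite(p) or err > 3e-5 or p < -1e-5 or p > 1 + 1e-5:
        rng = np.random.default_rng(_MC_SEED)
        exceed = 0
        chunk = 100_000
        for _ in range(_MC_DRAWS // chunk):
            g = rng.standard_normal((lam.size, chunk))
            exceed += int(np.count_nonzero(lam @ (g * g) > q))
        p = exceed / _MC_DRAWS
        return min(max(p, 5e-324), 1.0), "montecarlo"
    return min(max(p, 5e-324), 1.0), "imhof"


def heidi_test(probe: ProbeCisSet, gwas: Mapping[str, VariantAssoc],
               top_snp: str, snps_used: Sequence[str], ld: LDReference,
               trait_id: str = "trait", min_snps: int = MIN_SNPS
               ) -> HEIDIResult:
    """Run the HEIDI heterogeneity test.

    ``probe`` holds the QTL statistics and ``gwas`` the GWAS statistics for
    the same SNPs, already harmonized onto a common effect-allele frame.
    ``snps_used`` are the alternative instruments from
    :func:`heidi_select_snps`.
    """
    res = HEIDIResult(probe_id=probe.probe_id, trait_id=trait_id,
                      top_snp=top_snp, snps_used=list(snps_used))
    if len(res.snps_used) < min_snps:
        res.status = "too_few_snps"
        return res

    ids = [top_snp] + res.snps_used
    orient = []
    for s in ids:
        rec = probe.get(s)
        if rec is None or s not in gwas or s not in ld:
            res.status = "ld_unavailable"
            return res
        orient.append(ld.orientation(s, rec.effect_allele))
    try:
        r = ld.corr_matrix(ids, orientations=orient)
    except ValueError:
        res.status = "ld_unavailable"
        return res

    ids, r = _prune_ld(ids, probe, r, min_snps)
    if np.linalg.cond(r) > COND_MAX or len(ids) - 1 < min_snps:
        res.status = "ld_unavailable"
        return res
    res.snps_used = ids[1:]

    bq = np.array([probe.get(s).beta for s in ids])
    sq = np.array([probe.get(s).se for s in ids])
    bg = np.array([gwas[s].beta for s in ids])
    sg = np.array([gwas[s].se for s in ids])
    if np.any(bq == 0):
        res.status = "ld_unavailable"
        return res

    bxy = bg / bq
    d = bxy[1:] - bxy[0]

    # C = cov(b_xy_i, b_xy_j): GWAS sampling part plus QTL sampling part
    # (first-order delta method); QTL and GWAS samples are independent.
    gwas_part = r * np.outer(sg / bq, sg / bq)
    qtl_part = r * np.outer(bxy * sq / bq, bxy * sq / bq)
    c = gwas_part + qtl_part

    k = len(ids) - 1
    v = (c[1:, 1:] - c[1:, [0]] - c[[0], 1:] + c[0, 0])
    var_d = np.diag(v).copy()
    if np.any(var_d <= 0):
        res.status = "ld_unavailable"
        return res
    sd = np.sqrt(var_d)
    z_d = d / sd
    r_d = v / np.outer(sd, sd)
    np.fill_diagonal(r_d, 1.0)

    res.d_stats = d
    res.stat = float(z_d @ z_d)
    eig = np.linalg.eigvalsh((r_d + r_d.T) / 2.0)
    eig = np.clip(eig, 0.0, None)
    if eig.max() <= 0:
        res.status = "ld_unavailable"
        return res
    p, method = wchi2_sf(res.stat, eig)
    res.p_heidi = p
    res.tail_method = method
    res.status = "ok"
    return res


def classify(smr_p: float, heidi_p: float | None,
             smr_threshold: float, heidi_threshold: float = 0.05) -> str:
    """Assign the pleiotropy/linkage call for one probe-trait pair.

    ``pleiotropic``: SMR-significant with non-significant heterogeneity
    (HEIDI p > threshold); ``linkage``: SMR-significant with significant
    heterogeneity; ``not_significant``: SMR p at or above its threshold;
    ``untested``: SMR-significant but HEIDI unavailable.
    """
    if not (0 < smr_p <= 1):
        raise ValueError(f"invalid smr_p={smr_p}")
    if smr_p >= smr_threshold:
        return "not_significant"
    if heidi_p is None:
        return "untested"
    return "pleiotropic" if heidi_p > heidi_threshold else "linkage"
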