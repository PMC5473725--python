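"""Discovery orchestration and downstream analyses.

Runs SMR + HEIDI across traits and probes, applies family-wise correction
(Bonferroni over the probes actually tested in a dataset, which is what
reproduces the distinct per-dataset thresholds a multi-dataset study
reports), and provides the downstream comparisons: replication against a
second study, sign concordance between datasets or tissues, mQTL/eQTL
gene-level overlap, novel-locus flagging, multi-trait sites, and the
trait-by-probe t-statistic matrix with hierarchical clustering.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.special import gammaln, logsumexp

from .config import AnalysisConfig
from .heidi import classify, heidi_select_snps, heidi_test
from .smr import SMRRecord, select_instrument, smr_test
from .sumstats import LDReference, ProbeCisSet, VariantAssoc, harmonize

logger = logging.getLogger(__name__)

LOG10_MIN_P = -320.0  # reporting floor for log10 p-values


def bonferroni_threshold(n_tests: int, alpha_fw: float = 0.05) -> float:
    """Family-wise p-value threshold alpha_fw / n_tests (unrounded).

    With alpha 0.05 this reproduces the printed arithmetic of a
    multi-dataset study: 35,263 methylation sites -> 1.42e-6; 5,966
    expression probes -> 8.38e-6; 9,265 sites -> 5.40e-6 (3 s.f.).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha_fw < 1):
        raise ValueError("alpha_fw must be in (0,1)")
    return alpha_fw / n_tests


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (for reporting only)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


# ---------------------------------------------------------------------------
# discovery

@dataclass
class DiscoveryResult:
    records: list[SMRRecord]
    manifest: dict
    smr_threshold: float
    n_probes_tested: int
    config: AnalysisConfig

    def to_frame(self) -> pd.DataFrame:
        cols = ["trait_id", "probe_id", "probe_chrom", "probe_pos",
                "gene_annotation", "instrument_snp", "b_qtl", "se_qtl",
                "b_gwas", "se_gwas", "b_smr", "se_smr", "t_smr", "p_smr",
                "heidi_p", "n_heidi_snps", "heidi_status", "classification",
                "reason"]
        return pd.DataFrame([{c: getattr(r, c) for c in cols}
                             for r in self.records])

    def by_key(self) -> dict[tuple[str, str], SMRRecord]:
        return {(r.trait_id, r.probe_id): r for r in self.records}


def _chrom_key(chrom: str | None) -> tuple[int, str]:
    if chrom is None:
        return (10**9, "")
    m = re.fullmatch(r"(?:chr)?(\d+)", str(chrom))
    return (int(m.group(1)), "") if m else (10**8, str(chrom))


def harmonize_probe_with_gwas(probe: ProbeCisSet,
                              gwas_index: Mapping[str, VariantAssoc],
                              freq_tol: float
                              ) -> tuple[ProbeCisSet, dict[str, VariantAssoc]]:
    """Intersect a probe's cis SNPs with a GWAS and put both studies on the
    QTL effect-allele frame. Returns the restricted probe set and a map of
    SNP id to the harmonized GWAS record."""
    kept, gmap = [], {}
    for rec in probe.records:
        grec = gwas_index.get(rec.snp_id)
        if grec is None:
            continue
        h = harmonize(rec, grec, freq_tol=freq_tol)
        if not h.ok:
            logger.debug("probe %s SNP %s excluded: %s", probe.probe_id,
                         rec.snp_id, h.reason)
            continue
        kept.append(rec)
        gmap[rec.snp_id] = h.b
    restricted = ProbeCisSet(probe.probe_id, probe.probe_chrom,
                             probe.probe_pos, records=kept,
                             gene_annotation=probe.gene_annotation)
    return restricted, gmap


def analyze_probe(probe: ProbeCisSet, gwas_index: Mapping[str, VariantAssoc],
                  ld: LDReference, config: AnalysisConfig, trait_id: str,
                  run_heidi: bool = True) -> SMRRecord:
    """SMR (and optionally HEIDI) for one probe-trait pair.

    Classification is left ``untested``; the caller assigns it once the
    family-wise threshold over all tested probes is known.
    """
    shared, gmap = harmonize_probe_with_gwas(probe, gwas_index,
                                             config.freq_tol)
    rec = SMRRecord(probe_id=probe.probe_id, trait_id=trait_id,
                    instrument_snp=None, probe_chrom=probe.probe_chrom,
                    probe_pos=probe.probe_pos,
                    gene_annotation=probe.gene_annotation)
    instrument, reason = select_instrument(shared, config.qtl_p_threshold)
    if instrument is None:
        rec.reason = reason
        return rec
    g = gmap[instrument.snp_id]
    s = smr_test(g.beta, g.se, instrument.beta, instrument.se)
    rec.instrument_snp = instrument.snp_id
    rec.b_qtl, rec.se_qtl = instrument.beta, instrument.se
    rec.b_gwas, rec.se_gwas = g.beta, g.se
    rec.b_smr, rec.se_smr = s.b_smr, s.se_smr
    rec.t_smr, rec.p_smr, rec.chi2_smr = s.t_smr, s.p_smr, s.chi2_smr
    if run_heidi:
        sel = heidi_select_snps(shared, instrument.snp_id, ld,
                                r2_min=config.heidi_r2_min,
                                r2_max=config.heidi_r2_max,
                                max_snps=config.heidi_max_snps,
                                min_snps=config.heidi_min_snps,
                                p_include=config.heidi_p_include)
        if sel.status != "ok":
            rec.heidi_status = sel.status
        else:
            hres = heidi_test(shared, gmap, instrument.snp_id, sel.snps, ld,
                              trait_id=trait_id,
                              min_snps=config.heidi_min_snps)
            rec.heidi_status = hres.status
            rec.heidi_p = hres.p_heidi
            rec.n_heidi_snps = len(hres.snps_used)
    return rec


def run_discovery(gwas_by_trait: Mapping[str, Sequence[VariantAssoc]],
                  probes: Sequence[ProbeCisSet], ld: LDReference,
                  config: AnalysisConfig | None = None) -> DiscoveryResult:
    """Run SMR + HEIDI for every trait and testable probe.

    The SMR significance threshold is ``alpha_fw`` Bonferroni-corrected for
    the number of distinct probes that actually entered SMR in this dataset
    (across traits, not per trait). HEIDI runs only for SMR-significant
    pairs, which are then classified pleiotropic/linkage; everything else is
    ``not_significant`` or ``untested``.
    """
    config = config or AnalysisConfig()
    indices = {t: {r.snp_id: r for r in recs}
               for t, recs in gwas_by_trait.items()}

    records: list[SMRRecord] = []
    probe_by_id = {p.probe_id: p for p in probes}
    for trait_id in sorted(indices):
        gidx = indices[trait_id]
        for probe in probes:
            records.append(analyze_probe(probe, gidx, ld, config, trait_id,
                                         run_heidi=False))

    tested_probes = {r.probe_id for r in records if r.tested}
    n_tested = len(tested_probes)
    threshold = bonferroni_threshold(max(n_tested, 1), config.alpha_fw)

    # second pass: HEIDI + classification for SMR-significant pairs
    for rec in records:
        if not rec.tested:
            rec.classification = "untested"
            continue
        if rec.p_smr >= threshold:
            rec.classification = "not_significant"
            continue
        probe = probe_by_id[rec.probe_id]
        shared, gmap = harmonize_probe_with_gwas(
            probe, indices[rec.trait_id], config.freq_tol)
        sel = heidi_select_snps(shared, rec.instrument_snp, ld,
                                r2_min=config.heidi_r2_min,
                                r2_max=config.heidi_r2_max,
                                max_snps=config.heidi_max_snps,
                                min_snps=config.heidi_min_snps,
                                p_include=config.heidi_p_include)
        if sel.status != "ok":
            rec.heidi_status = sel.status
        else:
            hres = heidi_test(shared, gmap, rec.instrument_snp, sel.snps, ld,
                              trait_id=rec.trait_id,
                              min_snps=config.heidi_min_snps)
            rec.heidi_status = hres.status
            rec.heidi_p = hres.p_heidi
            rec.n_heidi_snps = len(hres.snps_used)
        rec.classification = classify(rec.p_smr, rec.heidi_p, threshold,
                                      config.heidi_threshold)

    records.sort(key=lambda r: (r.trait_id, _chrom_key(r.probe_chrom),
                                r.probe_pos or 0, r.probe_id))

    manifest: dict = {"n_probes_tested": n_tested,
                      "smr_threshold": threshold,
                      "alpha_fw": config.alpha_fw,
                      "traits": {}}
    for trait_id in sorted(indices):
        sub = [r for r in records if r.trait_id == trait_id]
        manifest["traits"][trait_id] = {
            "n_probes": len(sub),
            "n_tested": sum(r.tested for r in sub),
            "n_significant": sum(r.tested and r.p_smr < threshold
                                 for r in sub),
            "n_pleiotropic": sum(r.classification == "pleiotropic"
                                 for r in sub),
            "n_linkage": sum(r.classification == "linkage" for r in sub),
        }
    return DiscoveryResult(records=records, manifest=manifest,
                           smr_threshold=threshold,
                           n_probes_tested=n_tested, config=config)


# ---------------------------------------------------------------------------
# sign concordance

@dataclass
class ConcordanceReport:
    n_tested: int
    n_same_sign: int
    proportion: float
    sign_test_p: float
    log10_sign_test_p: float


def exact_sign_test(n_same: int, n_total: int) -> tuple[float, float]:
    """Two-sided exact binomial test against p0 = 1/2, in log space.

    Returns ``(p, log10_p)``; ``p`` underflows to 0 below ~1e-308 but
    ``log10_p`` stays exact to the precision of the log-space sum, so
    magnitudes like 1e-172 (or smaller) remain comparable.
    """
    if not 0 <= n_same <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_same <= n_total, n_total >= 1")
    k = max(n_same, n_total - n_same)
    i = np.arange(k, n_total + 1)
    log_terms = (gammaln(n_total + 1) - gammaln(i + 1)
                 - gammaln(n_total - i + 1)) - n_total * math.log(2.0)
    log_tail = float(logsumexp(log_terms))
    log_p = min(math.log(2.0) + log_tail, 0.0)
    return math.exp(log_p), log_p / math.log(10.0)


def sign_concordance(a: Iterable[SMRRecord], b: Iterable[SMRRecord]
                     ) -> ConcordanceReport:
    """Direction-of-effect agreement of SMR estimates between two runs.

    Pairs are matched on (trait, probe); pairs with a missing or exactly
    zero b_SMR on either side are excluded from the denominator.
    """
    amap = {(r.trait_id, r.probe_id): r for r in a}
    bmap = {(r.trait_id, r.probe_id): r for r in b}
    shared = sorted(set(amap) & set(bmap))
    if not shared:
        raise ValueError("no shared (trait, probe) keys")
    n_tested = n_same = 0
    for key in shared:
        ba, bb = amap[key].b_smr, bmap[key].b_smr
        if ba is None or bb is None or ba == 0 or bb == 0:
            continue
        n_tested += 1
        if (ba > 0) == (bb > 0):
            n_same += 1
    if n_tested == 0:
        raise ValueError("no comparable pairs with non-zero b_smr")
    p, log10p = exact_sign_test(n_same, n_tested)
    return ConcordanceReport(n_tested=n_tested, n_same_sign=n_same,
                             proportion=n_same / n_tested,
                             sign_test_p=p, log10_sign_test_p=log10p)


# ---------------------------------------------------------------------------
# replication

@dataclass
class ReplicationStatus:
    trait_id: str
    probe_id: str
    status: str  # replicated | not_replicated | untested
    replication_p_smr: float | None = None
    replication_heidi_p: float | None = None


def replicate(discovery: DiscoveryResult, replication: DiscoveryResult,
              config: AnalysisConfig | None = None) -> list[ReplicationStatus]:
    """Check each discovery pleiotropic association in a replication run.

    Replicated means SMR p below the replication dataset's own Bonferroni
    threshold (alpha over probes tested in replication) and HEIDI p above
    the heterogeneity threshold there too.
    """
    config = config or discovery.config
    rmap = replication.by_key()
    thr = replication.smr_threshold
    out = []
    for rec in discovery.records:
        if rec.classification != "pleiotropic":
            continue
        rrec = rmap.get((rec.trait_id, rec.probe_id))
        if rrec is None or not rrec.tested:
            out.append(ReplicationStatus(rec.trait_id, rec.probe_id,
                                         "untested"))
            continue
        ok = (rrec.p_smr < thr and rrec.heidi_p is not None
              and rrec.heidi_p > config.heidi_threshold)
        out.append(ReplicationStatus(
            rec.trait_id, rec.probe_id,
            "replicated" if ok else "not_replicated",
            replication_p_smr=rrec.p_smr,
            replication_heidi_p=rrec.heidi_p))
    return out


# ---------------------------------------------------------------------------
# gene-level mQTL/eQTL overlap

def gene_overlap(mqtl: DiscoveryResult, eqtl: DiscoveryResult,
                 config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Collapse probe-level results to gene-trait level and align the
    methylation and expression runs.

    A gene-trait pair is pleiotropic in a run when at least one of its
    probes is. ``sign_consistent`` records whether all tested probes of the
    gene agree in the direction of b_SMR.
    """
    def collapse(result: DiscoveryResult) -> pd.DataFrame:
        rows = []
        for r in result.records:
            if r.gene_annotation is None:
                continue
            rows.append({"gene": r.gene_annotation, "trait_id": r.trait_id,
                         "tested": r.tested,
                         "pleiotropic": r.classification == "pleiotropic",
                         "b_smr": r.b_smr})
        df = pd.DataFrame(rows)
        if df.empty:
            return pd.DataFrame(columns=["gene", "trait_id", "tested",
                                         "pleiotropic", "n_probes",
                                         "sign_consistent"])
        grouped = df.groupby(["gene", "trait_id"]).agg(
            tested=("tested", "any"),
            pleiotropic=("pleiotropic", "any"),
            n_probes=("tested", "size"),
            sign_consistent=("b_smr", lambda s: (
                s.dropna().gt(0).nunique() <= 1)),
        ).reset_index()
        return grouped

    m = collapse(mqtl).rename(columns={
        "tested": "mqtl_tested", "pleiotropic": "mqtl_pleiotropic",
        "n_probes": "mqtl_n_probes", "sign_consistent": "mqtl_sign_consistent"})
    e = collapse(eqtl).rename(columns={
        "tested": "eqtl_tested", "pleiotropic": "eqtl_pleiotropic",
        "n_probes": "eqtl_n_probes", "sign_consistent": "eqtl_sign_consistent"})
    merged = m.merge(e, on=["gene", "trait_id"], how="left")
    merged["eqtl_tested"] = merged["eqtl_tested"].eq(True)
    merged["eqtl_pleiotropic"] = merged["eqtl_pleiotropic"].eq(True)
    merged["tested_in_both"] = merged["mqtl_tested"] & merged["eqtl_tested"]
    merged["pleiotropic_in_both"] = (merged["mqtl_pleiotropic"]
                                     & merged["eqtl_pleiotropic"])
    return merged.sort_values(["gene", "trait_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# novel loci / multi-trait sites

def flag_novel_locus(record: SMRRecord, gwas: Sequence[VariantAssoc],
                     config: AnalysisConfig | None = None) -> bool:
    """True when no genome-wide-significant GWAS SNP lies within the
    novelty window of the probe position (window boundary inclusive)."""
    config = config or AnalysisConfig()
    if record.probe_pos is None or record.probe_chrom is None:
        raise ValueError("probe position required for novelty flagging")
    for snp in gwas:
        if snp.chrom is None or snp.pos is None:
            continue
        if (snp.chrom == record.probe_chrom
                and abs(snp.pos - record.probe_pos) <= config.novel_locus_window
                and snp.p < config.gwas_sig_threshold):
            return False
    return True


def multi_trait_sites(records: Iterable[SMRRecord]) -> pd.DataFrame:
    """Probes with pleiotropic associations for two or more traits."""
    by_probe: dict[str, list[str]] = {}
    for r in records:
        if r.classification == "pleiotropic":
            by_probe.setdefault(r.probe_id, []).append(r.trait_id)
    rows = [{"probe_id": p, "n_traits": len(ts), "traits": ",".join(sorted(ts))}
            for p, ts in sorted(by_probe.items()) if len(ts) >= 2]
    return pd.DataFrame(rows, columns=["probe_id", "n_traits", "traits"])


# ---------------------------------------------------------------------------
# trait-by-probe matrix and clustering

@dataclass
class TraitProbeMatrix:
    values: pd.DataFrame            # probes x traits, t_smr, NaN = missing
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None


def masked_euclidean_pdist(x: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances with pairwise-complete masking.

    Distances over the shared non-missing coordinates are rescaled by
    sqrt(p/m) (p total, m shared coordinates) so sparsity does not shrink
    them; pairs with no shared coordinate get 1.1x the largest finite
    distance.
    """
    n, p = x.shape
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(x[i]) & np.isfinite(x[j])
            m = int(mask.sum())
            if m == 0:
                out[k] = np.nan
            else:
                diff = x[i, mask] - x[j, mask]
                out[k] = math.sqrt(float(diff @ diff) * p / m)
            k += 1
    if np.isnan(out).any():
        finite = out[np.isfinite(out)]
        fill = 1.1 * finite.max() if finite.size else 1.0
        out = np.where(np.isnan(out), fill, out)
    return out


def trait_probe_matrix(result: DiscoveryResult | Iterable[SMRRecord],
                       seed_probes: Sequence[str],
                       min_tested_sites: int | None = None
                       ) -> TraitProbeMatrix:
    """Build the probes-by-traits matrix of t_SMR statistics and order both
    axes by average-linkage hierarchical clustering (Euclidean distance with
    pairwise-complete masking; missing cells are never imputed)."""
    if isinstance(result, DiscoveryResult):
        records = result.records
        if min_tested_sites is None:
            min_tested_sites = result.config.min_tested_sites
    else:
        records = list(result)
        if min_tested_sites is None:
            min_tested_sites = 1

    tested_per_trait: dict[str, int] = {}
    for r in records:
        if r.tested:
            tested_per_trait[r.trait_id] = tested_per_trait.get(r.trait_id,
                                                                0) + 1
    traits = sorted(t for t, n in tested_per_trait.items()
                    if n >= min_tested_sites)
    seed = [p for p in seed_probes]
    cells: dict[tuple[str, str], float] = {}
    for r in records:
        if r.tested and r.trait_id in traits:
            cells[(r.probe_id, r.trait_id)] = r.t_smr
    rows = [p for p in seed if any((p, t) in cells for t in traits)]
    dropped = [p for p in seed if p not in rows]
    if dropped:
        logger.info("trait_probe_matrix: dropped all-missing probes %s",
                    dropped)
    mat = pd.DataFrame(np.nan, index=rows, columns=traits, dtype=float)
    for (p, t), v in cells.items():
        if p in mat.index:
            mat.loc[p, t] = v
    keep_cols = [c for c in mat.columns if mat[c].notna().any()]
    if len(keep_cols) < len(mat.columns):
        logger.info("trait_probe_matrix: dropped all-missing traits %s",
                    sorted(set(mat.columns) - set(keep_cols)))
        mat = mat[keep_cols]

    tpm = TraitProbeMatrix(values=mat)
    if mat.shape[0] >= 2:
        z = hierarchy.linkage(masked_euclidean_pdist(mat.to_numpy()),
                              method="average")
        tpm.row_linkage = z
        tpm.row_order = [mat.index[i] for i in hierarchy.leaves_list(z)]
    else:
        tpm.row_order = list(mat.index)
    if mat.shape[1] >= 2:
        z = hierarchy.linkage(masked_euclidean_pdist(mat.to_numpy().T),
                              method="average")
        tpm.col_linkage = z
        tpm.col_order = [mat.columns[i] for i in hierarchy.leaves_list(z)]
    else:
        tpm.col_order = list(mat.columns)
    return tpm


def pleiotropic_bed(records: Iterable[SMRRecord]) -> pd.DataFrame:
    """BED (0-based half-open) intervals of pleiotropic probe positions."""
    rows = []
    for r in records:
        if r.classification == "pleiotropic" and r.probe_pos is not None:
            rows.append({"chrom": r.probe_chrom, "start": r.probe_pos - 1,
                         "end": r.probe_pos,
                         "name": f"{r.probe_id}|{r.trait_id}"})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
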