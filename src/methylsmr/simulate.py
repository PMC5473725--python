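"""Synthetic genotypes, molecular traits, phenotypes and two-study summary
statistics under the causal scenarios the SMR/HEIDI analysis assumes.

Three generative scenarios are available per cis locus:

* ``pleiotropy`` — one causal SNP drives methylation (m = b_zx * g + e) and,
  through mediation, the phenotype in an independent GWAS sample
  (y = b_xy * m + e, with m regenerated from the same causal SNP);
* ``linkage`` — two distinct causal SNPs in LD at a target correlation
  ``causal_r``: one drives methylation, the other drives the phenotype
  directly (y = b_zy * g2 + e);
* ``null`` — the QTL exists but the phenotype is pure noise.

Genotypes come from a latent-Gaussian threshold model: haplotype alleles
are indicators Z < Phi^-1(maf) of a first-order autoregressive latent
Gaussian (adjacent latent correlation ``ld_rho``), and dosages are sums of
two independent haplotypes. Thresholding attenuates correlation, so the
latent correlation of the two causal SNPs in the linkage scenario is tuned
numerically (tetrachoric inversion) to realize ``causal_r`` on the dosage
scale. This gives direct control over LD, which the HEIDI power properties
require. QTL and GWAS samples are always disjoint, as summary-data MR
assumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .sumstats import (LDReference, ProbeCisSet, RecordList, VariantAssoc,
                       wald_p, write_gwas, write_qtl)

logger = logging.getLogger(__name__)

MAF_MIN, MAF_MAX = 0.05, 0.5

#: non-palindromic allele pairs drawn for simulated SNPs (array-style QC
#: usually removes ambiguous A/T and C/G sites)
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SimScenario:
    """Generative description of one cis locus and its study pair.

    Effect sizes are on the dosage scale; methylation is M-value-like
    (unbounded). ``b_xy`` is the mediated methylation-to-phenotype effect
    (pleiotropy), ``b_zy`` the direct SNP effect at the second causal
    variant (linkage), and ``b_direct`` an optional horizontal-pleiotropy
    path (direct SNP-to-phenotype effect alongside mediation).
    """

    kind: str = "pleiotropy"        # pleiotropy | linkage | null
    n_snps: int = 20
    maf: np.ndarray | None = None   # drawn U[MAF_MIN, MAF_MAX] when None
    ld_rho: float = 0.95            # latent AR(1) adjacent correlation
    b_zx: float = 0.6               # causal SNP -> methylation
    b_xy: float = 0.3               # methylation -> phenotype (mediation)
    b_zy: float = 0.3               # second causal SNP -> phenotype
    causal_r: float = 0.5           # target dosage LD of the causal pair
    b_direct: float = 0.0           # horizontal pleiotropy path
    n_qtl: int = 639
    n_gwas: int = 20_000
    sd_m: float = 1.0
    sd_y: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("pleiotropy", "linkage", "null"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.n_snps < 2:
            raise ValueError("need at least 2 SNPs per locus")

    @property
    def causal_index(self) -> int:
        return self.n_snps // 2

    @property
    def causal_index_2(self) -> int:
        return self.causal_index + 1


@dataclass
class GenotypeSample:
    """Dosage matrix for one study sample, with SNP metadata."""

    sample_ids: list[str]
    dosages: np.ndarray                 # individuals x SNPs
    snp_ids: list[str]
    chrom: str
    positions: list[int]
    effect_alleles: list[str]
    other_alleles: list[str]

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    def to_ld_reference(self) -> LDReference:
        return LDReference(self.snp_ids, self.dosages,
                           self.effect_alleles, self.other_alleles)


# ---------------------------------------------------------------------------
# latent-Gaussian haplotype model

def _bvn_cdf(t1: float, t2: float, rho: float) -> float:
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov,
                                           allow_singular=True).cdf([t1, t2]))


def dosage_corr_from_latent(rho: float, maf_i: float, maf_j: float) -> float:
    """Predicted dosage-scale Pearson correlation between two SNPs whose
    latent Gaussians correlate at ``rho`` (tetrachoric forward map)."""
    t1, t2 = stats.norm.ppf(maf_i), stats.norm.ppf(maf_j)
    p11 = _bvn_cdf(t1, t2, rho)
    num = p11 - maf_i * maf_j
    den = math.sqrt(maf_i * (1 - maf_i) * maf_j * (1 - maf_j))
    return num / den


def latent_rho_for_dosage_r(target_r: float, maf_i: float, maf_j: float
                            ) -> float:
    """Invert the tetrachoric map: the latent correlation realizing
    ``target_r`` on the dosage scale (clipped to the achievable range)."""
    if abs(target_r) < 1e-12:
        return 0.0
    lo, hi = -0.9999, 0.9999
    f = lambda rho: dosage_corr_from_latent(rho, maf_i, maf_j) - target_r
    fmax = f(hi)
    if fmax < 0:  # target beyond what thresholding allows; saturate
        return hi
    if f(lo) > 0:
        return lo
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


def _latent_corr_matrix(scenario: SimScenario, maf: np.ndarray) -> np.ndarray:
    m = scenario.n_snps
    adj = np.full(m - 1, scenario.ld_rho, dtype=float)
    if scenario.kind == "linkage":
        c = scenario.causal_index
        if scenario.causal_r >= 0.999:
            adj[c] = 0.9999
        else:
            adj[c] = latent_rho_for_dosage_r(scenario.causal_r,
                                             maf[c], maf[c + 1])
    # Markov chain: corr(i, j) = product of adjacent correlations
    sigma = np.eye(m)
    for i in range(m):
        acc = 1.0
        for j in range(i + 1, m):
            acc *= adj[j - 1]
            sigma[i, j] = sigma[j, i] = acc
    return sigma


def _draw_maf(scenario: SimScenario, rng: np.random.Generator) -> np.ndarray:
    if scenario.maf is not None:
        maf = np.asarray(scenario.maf, dtype=float)
        if maf.shape != (scenario.n_snps,):
            raise ValueError("maf vector length != n_snps")
    else:
        maf = rng.uniform(MAF_MIN, MAF_MAX, size=scenario.n_snps)
        # keep causal SNPs common so the instrument carries real signal
        c = scenario.causal_index
        maf[c] = rng.uniform(0.2, MAF_MAX)
        maf[c + 1] = maf[c] if scenario.kind == "linkage" else maf[c + 1]
    if np.any(maf < MAF_MIN) or np.any(maf > MAF_MAX):
        raise ValueError(f"maf outside [{MAF_MIN}, {MAF_MAX}]")
    return maf


def simulate_genotypes(scenario: SimScenario, n_individuals: int,
                       rng: np.random.Generator,
                       maf: np.ndarray | None = None,
                       id_prefix: str = "ind", chrom: str = "1",
                       base_pos: int = 10_000_000, pos_step: int = 5_000,
                       snp_prefix: str = "snp",
                       allele_pairs: Sequence[tuple[str, str]] | None = None,
                       ) -> GenotypeSample:
    """Draw a dosage matrix from the latent-Gaussian AR(1) haplotype model.

    Haplotype alleles are thresholded latent Gaussians; dosages are sums of
    two independent haplotypes, so column means are ~2*maf and adjacent-SNP
    correlation follows the tetrachoric map of ``ld_rho``.
    """
    maf = _draw_maf(scenario, rng) if maf is None else np.asarray(maf, float)
    if np.any(maf < MAF_MIN) or np.any(maf > MAF_MAX):
        raise ValueError(f"maf outside [{MAF_MIN}, {MAF_MAX}]")
    m = scenario.n_snps
    sigma = _latent_corr_matrix(scenario, maf)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(m))
    z = rng.standard_normal((2 * n_individuals, m)) @ chol.T
    hap = (z < stats.norm.ppf(maf)).astype(float)
    dos = hap[:n_individuals] + hap[n_individuals:]
    if scenario.kind == "linkage" and scenario.causal_r >= 0.999:
        dos[:, scenario.causal_index_2] = dos[:, scenario.causal_index]
    if allele_pairs is None:
        allele_pairs = [_ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
                        for _ in range(m)]
    return GenotypeSample(
        sample_ids=[f"{id_prefix}{i + 1}" for i in range(n_individuals)],
        dosages=dos,
        snp_ids=[f"{snp_prefix}{j + 1:03d}" for j in range(m)],
        chrom=chrom,
        positions=[base_pos + j * pos_step for j in range(m)],
        effect_alleles=[a for a, _ in allele_pairs],
        other_alleles=[b for _, b in allele_pairs],
    )


def simulate_traits(qtl_sample: GenotypeSample, gwas_sample: GenotypeSample,
                    scenario: SimScenario, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Generate the methylation vector (QTL sample) and phenotype vector
    (GWAS sample) under the scenario. The two samples must be disjoint."""
    if set(qtl_sample.sample_ids) & set(gwas_sample.sample_ids):
        raise ValueError("sample_overlap")
    c1, c2 = scenario.causal_index, scenario.causal_index_2
    m = (scenario.b_zx * qtl_sample.dosages[:, c1]
         + rng.normal(0.0, scenario.sd_m, qtl_sample.n))
    if scenario.kind == "pleiotropy":
        m_star = (scenario.b_zx * gwas_sample.dosages[:, c1]
                  + rng.normal(0.0, scenario.sd_m, gwas_sample.n))
        y = (scenario.b_xy * m_star
             + scenario.b_direct * gwas_sample.dosages[:, c1]
             + rng.normal(0.0, scenario.sd_y, gwas_sample.n))
    elif scenario.kind == "linkage":
        y = (scenario.b_zy * gwas_sample.dosages[:, c2]
             + rng.normal(0.0, scenario.sd_y, gwas_sample.n))
    else:
        y = rng.normal(0.0, scenario.sd_y, gwas_sample.n)
    return m, y


def summary_stats(genotypes: GenotypeSample, trait: np.ndarray,
                  n_label: float | None = None) -> RecordList:
    """Per-SNP simple-linear-regression summary statistics.

    Returns one VariantAssoc per polymorphic SNP (beta, SE, two-sided
    normal p floored at the smallest positive float); monomorphic SNPs are
    omitted and logged.
    """
    y = np.asarray(trait, dtype=float)
    g = genotypes.dosages
    if y.shape[0] != g.shape[0]:
        raise ValueError("trait vector not aligned to genotype rows")
    n = y.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    out = RecordList()
    syy = float(yc @ yc)
    sxy = gc.T @ yc
    for j, sid in enumerate(genotypes.snp_ids):
        if sxx[j] <= 0:
            logger.info("summary_stats: %s monomorphic, omitted", sid)
            continue
        beta = sxy[j] / sxx[j]
        rss = max(syy - beta * sxy[j], 0.0)
        se = math.sqrt(max(rss / (n - 2), 1e-300) / sxx[j])
        out.append(VariantAssoc(
            snp_id=sid,
            chrom=genotypes.chrom,
            pos=genotypes.positions[j],
            effect_allele=genotypes.effect_alleles[j],
            other_allele=genotypes.other_alleles[j],
            eaf=float(g[:, j].mean() / 2.0),
            beta=float(beta),
            se=float(se),
            p=wald_p(beta, se),
            n=float(n if n_label is None else n_label),
        ))
    return out


# ---------------------------------------------------------------------------
# one-locus study: the unit the calibration experiments replicate

@dataclass
class LocusStudy:
    """Summary statistics for one simulated locus in one study pair."""

    scenario: SimScenario
    qtl: ProbeCisSet
    gwas: RecordList
    ld: LDReference
    maf: np.ndarray


def simulate_locus_study(scenario: SimScenario,
                         rng: np.random.Generator | None = None,
                         probe_id: str = "cg0000001",
                         gene: str | None = "GENE1",
                         chrom: str = "1", base_pos: int = 10_000_000,
                         ) -> LocusStudy:
    """Simulate QTL and GWAS summary statistics for a single cis locus.

    The LD reference is the QTL sample's genotypes (in-sample LD), as a
    QTL-cohort reference panel would provide.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    maf = _draw_maf(scenario, rng)
    qtl_geno = simulate_genotypes(scenario, scenario.n_qtl, rng, maf=maf,
                                  id_prefix="q", chrom=chrom,
                                  base_pos=base_pos)
    gwas_geno = simulate_genotypes(scenario, scenario.n_gwas, rng, maf=maf,
                                   id_prefix="g", chrom=chrom,
                                   base_pos=base_pos)
    # both samples carry the same SNP panel/orientation
    gwas_geno.effect_alleles = list(qtl_geno.effect_alleles)
    gwas_geno.other_alleles = list(qtl_geno.other_alleles)
    meth, pheno = simulate_traits(qtl_geno, gwas_geno, scenario, rng)
    qtl_stats = summary_stats(qtl_geno, meth)
    gwas_stats = summary_stats(gwas_geno, pheno)
    probe = ProbeCisSet(
        probe_id=probe_id, probe_chrom=chrom,
        probe_pos=qtl_geno.positions[scenario.causal_index],
        gene_annotation=gene, records=list(qtl_stats),
    )
    return LocusStudy(scenario=scenario, qtl=probe, gwas=gwas_stats,
                      ld=qtl_geno.to_ld_reference(), maf=maf)


# ---------------------------------------------------------------------------
# benchmark fixture: a complete miniature two-tissue study

@dataclass
class BenchmarkConfig:
    """Layout of the miniature study written by :func:`make_benchmark`.

    Defaults mirror the structure of a two-cohort blood mQTL design: a
    phase-1-sized discovery tissue (n=639), a phase-2-sized second tissue
    (n=665) sharing the causal variant for most probes, and well-powered
    GWAS samples. Probes cycle through the pleiotropy/linkage/null
    scenarios and, for non-null probes, through the traits.
    """

    n_traits: int = 3
    n_probes: int = 60
    n_snps_per_locus: int = 20
    n_qtl: int = 639
    n_qtl2: int = 665
    n_gwas: int = 20_000
    n_eqtl: int = 5_311
    b_zx: float = 0.6
    b_xy: float = 0.3
    b_zy: float = 0.3
    b_zx_expr: float = 0.3
    causal_r: float = 0.5
    ld_rho: float = 0.95
    shared_causal_fraction: float = 0.9
    second_probe_every: int = 5     # every k-th locus hosts two CpGs
    dual_target_every: int = 3      # every k-th pleiotropy locus hits 2 traits
    include_second_tissue: bool = True
    include_expression: bool = False
    seed: int = 0


@dataclass
class Benchmark:
    config: BenchmarkConfig
    gwas: dict[str, RecordList]
    qtl: list[ProbeCisSet]
    qtl2: list[ProbeCisSet] | None
    eqtl: list[ProbeCisSet] | None
    ld: LDReference
    truth: pd.DataFrame


def _locus_scenario(cfg: BenchmarkConfig, kind: str) -> SimScenario:
    return SimScenario(kind=kind, n_snps=cfg.n_snps_per_locus,
                       ld_rho=cfg.ld_rho, b_zx=cfg.b_zx, b_xy=cfg.b_xy,
                       b_zy=cfg.b_zy, causal_r=cfg.causal_r,
                       n_qtl=cfg.n_qtl, n_gwas=cfg.n_gwas)


def make_benchmark(config: BenchmarkConfig | None = None,
                   seed: int | None = None) -> Benchmark:
    """Build a complete miniature study in memory.

    Loci are independent; each trait's GWAS is assembled from per-locus
    summary statistics. A truth table records the generative label of every
    probe-trait pair. Fixed seed implies a byte-identical fixture set (see
    :func:`write_benchmark`).
    """
    cfg = config or BenchmarkConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    kinds = ["pleiotropy", "linkage", "null"]
    traits = [f"trait{t + 1}" for t in range(cfg.n_traits)]

    gwas: dict[str, RecordList] = {t: RecordList() for t in traits}
    qtl: list[ProbeCisSet] = []
    qtl2: list[ProbeCisSet] = []
    eqtl: list[ProbeCisSet] = []
    truth_rows = []
    ld_ids: list[str] = []
    ld_cols: list[np.ndarray] = []
    ld_eas: list[str] = []
    ld_oas: list[str] = []

    next_gwas_id = 0
    n_pleio_seen = 0
    for locus in range(cfg.n_probes):
        kind = kinds[locus % 3]
        # trait assignment cycles independently of the scenario kind so no
        # trait is confounded with one scenario
        target = traits[(locus // 3) % cfg.n_traits]
        targets = {target}
        if kind == "pleiotropy":
            n_pleio_seen += 1
            if (cfg.dual_target_every and cfg.n_traits > 1
                    and n_pleio_seen % cfg.dual_target_every == 0):
                targets.add(traits[((locus // 3) + 1) % cfg.n_traits])
        chrom = str(locus % 22 + 1)
        base_pos = 10_000_000 + (locus // 22) * 3_000_000
        scen = _locus_scenario(cfg, kind)
        maf = _draw_maf(scen, rng)
        c1 = scen.causal_index

        qtl_geno = simulate_genotypes(scen, cfg.n_qtl, rng, maf=maf,
                                      id_prefix=f"q{locus}_", chrom=chrom,
                                      base_pos=base_pos,
                                      snp_prefix=f"rs{locus:03d}_")
        pair = list(zip(qtl_geno.effect_alleles, qtl_geno.other_alleles))
        gene = f"G{locus:03d}"
        probe_ids = [f"cg{locus:07d}"]
        if cfg.second_probe_every and (locus + 1) % cfg.second_probe_every == 0:
            probe_ids.append(f"cg{locus:07d}b")

        # tissue 1 methylation: one vector per probe at this locus
        for pid in probe_ids:
            meth = (cfg.b_zx * qtl_geno.dosages[:, c1]
                    + rng.normal(0.0, scen.sd_m, cfg.n_qtl))
            recs = summary_stats(qtl_geno, meth)
            qtl.append(ProbeCisSet(pid, chrom, qtl_geno.positions[c1],
                                   records=list(recs), gene_annotation=gene))

        # tissue 2: same causal SNP for most loci, a different cis SNP
        # (weaker LD with the top tissue-1 SNP) otherwise
        if cfg.include_second_tissue:
            shared = rng.random() < cfg.shared_causal_fraction
            c_t2 = c1 if shared else max(c1 - 3, 0)
            scen2 = replace(scen, n_qtl=cfg.n_qtl2)
            qtl2_geno = simulate_genotypes(scen2, cfg.n_qtl2, rng, maf=maf,
                                           id_prefix=f"r{locus}_", chrom=chrom,
                                           base_pos=base_pos,
                                           snp_prefix=f"rs{locus:03d}_",
                                           allele_pairs=pair)
            for pid in probe_ids:
                meth2 = (cfg.b_zx * qtl2_geno.dosages[:, c_t2]
                         + rng.normal(0.0, scen.sd_m, cfg.n_qtl2))
                recs2 = summary_stats(qtl2_geno, meth2)
                qtl2.append(ProbeCisSet(pid, chrom, qtl_geno.positions[c1],
                                        records=list(recs2),
                                        gene_annotation=gene))
        else:
            shared = True

        # expression: same causal SNP, ILMN-style probe on the same gene
        if cfg.include_expression:
            scen_e = replace(scen, n_qtl=cfg.n_eqtl)
            e_geno = simulate_genotypes(scen_e, cfg.n_eqtl, rng, maf=maf,
                                        id_prefix=f"e{locus}_", chrom=chrom,
                                        base_pos=base_pos,
                                        snp_prefix=f"rs{locus:03d}_",
                                        allele_pairs=pair)
            expr = (cfg.b_zx_expr * e_geno.dosages[:, c1]
                    + rng.normal(0.0, scen.sd_m, cfg.n_eqtl))
            recs_e = summary_stats(e_geno, expr)
            eqtl.append(ProbeCisSet(f"ILMN_{locus:06d}", chrom,
                                    qtl_geno.positions[c1],
                                    records=list(recs_e),
                                    gene_annotation=gene))

        # one GWAS sample per trait at this locus (loci are independent)
        for trait in traits:
            gwas_geno = simulate_genotypes(scen, cfg.n_gwas, rng, maf=maf,
                                           id_prefix=f"g{next_gwas_id}_",
                                           chrom=chrom, base_pos=base_pos,
                                           snp_prefix=f"rs{locus:03d}_",
                                           allele_pairs=pair)
            next_gwas_id += 1
            eff_kind = kind if trait in targets else "null"
            scen_t = replace(scen, kind="null") if eff_kind == "null" else scen
            _, pheno = simulate_traits(qtl_geno, gwas_geno, scen_t, rng)
            gwas[trait].extend(summary_stats(gwas_geno, pheno))
            for pid in probe_ids:
                truth_rows.append({
                    "probe_id": pid, "trait_id": trait, "gene": gene,
                    "kind": eff_kind,
                    "is_pleiotropic": eff_kind == "pleiotropy",
                    "shared_causal": bool(shared),
                })

        ld_ids.extend(qtl_geno.snp_ids)
        ld_cols.append(qtl_geno.dosages)
        ld_eas.extend(qtl_geno.effect_alleles)
        ld_oas.extend(qtl_geno.other_alleles)

    ld = LDReference(ld_ids, np.hstack(ld_cols), ld_eas, ld_oas)
    truth = pd.DataFrame(truth_rows)
    return Benchmark(config=cfg, gwas=gwas, qtl=qtl,
                     qtl2=qtl2 if cfg.include_second_tissue else None,
                     eqtl=eqtl if cfg.include_expression else None,
                     ld=ld, truth=truth)


def write_benchmark(bench: Benchmark, out_dir) -> dict[str, Path]:
    """Write the benchmark fixture set to disk (all plain text)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for trait, recs in bench.gwas.items():
        p = out / f"gwas_{trait}.ma"
        write_gwas(recs, p)
        paths[f"gwas_{trait}"] = p
    write_qtl(bench.qtl, out / "mqtl_tissue1.tsv")
    paths["mqtl_tissue1"] = out / "mqtl_tissue1.tsv"
    if bench.qtl2 is not None:
        write_qtl(bench.qtl2, out / "mqtl_tissue2.tsv")
        paths["mqtl_tissue2"] = out / "mqtl_tissue2.tsv"
    if bench.eqtl is not None:
        write_qtl(bench.eqtl, out / "eqtl.tsv")
        paths["eqtl"] = out / "eqtl.tsv"
    bench.ld.write_dosage_file(out / "ld_reference.tsv")
    paths["ld_reference"] = out / "ld_reference.tsv"
    bench.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out / "truth.tsv"
    with open(out / "benchmark_config.yaml", "w") as fh:
        yaml.safe_dump(vars(bench.config), fh, sort_keys=True)
    paths["config"] = out / "benchmark_config.yaml"
    return paths
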