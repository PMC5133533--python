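"""Synthetic family cohorts with the statistical structure the tests assume.

The generator emulates a family-based sequencing study: multi-generation
pedigrees, rare-variant genotypes produced by Mendelian gene-dropping
from founder haplotypes, functional categories drawn at genome-typical
frequencies, and quantitative phenotypes from the additive polygenic
mixed model

    Y = gamma_0 + Z gamma + G beta + delta + eps,
    delta ~ N(0, sigma2_g * 2*Phi),  eps ~ N(0, sigma2_e * I).

Under the null (beta = 0) genotypes are independent of phenotypes by
construction, which drives the empirical type-I-error experiment:
50 windows of rare variants crossed with 200 phenotype replicates,
each replicate refitting the null model and testing every window with
all six methods.

Linkage disequilibrium is not modelled (sites are independent); an
optional block-correlation mode is available for robustness checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import assoc
from .nullmodel import fit_null
from .pedigree import Individual, Pedigree, kinship, relatedness_covariance

__all__ = [
    "SimulationConfig", "SimulatedCohort", "Type1Result", "PowerResult",
    "simulate_pedigree", "simulate_genotypes", "simulate_covariates",
    "simulate_cohort", "write_cohort", "type1_experiment", "power_experiment",
]

# genome-wide functional-category frequencies (categories 1..6) typical of
# whole-genome RegulomeDB annotation
DEFAULT_CATEGORY_PROBS = (0.0026, 0.0271, 0.0212, 0.0756, 0.3076, 0.5659)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults give 40 three-generation families (11 members each: two
    grandparents, three of their children, two married-in spouses and
    four grandchildren), 50 windows of 19 rare variants, unit polygenic
    and residual variances, and blood-pressure-flavoured covariate
    effects.
    """

    n_families: int = 40
    n_windows: int = 50
    variants_per_window: int = 19
    maf_low: Optional[float] = None   # default 1/(2n), the rarest observable
    maf_high: float = 0.05
    category_probs: tuple = DEFAULT_CATEGORY_PROBS
    sigma2_g: float = 1.0
    sigma2_e: float = 1.0
    intercept: float = 120.0
    covariate_effects: dict = field(default_factory=lambda: {
        "age": 0.3, "sex": 2.0, "smoking": 1.5, "medication": -2.0})
    effect_model: str = "null"   # null | doubleton | category1 | mixed
    effect_size: float = 0.0
    causal_window: Optional[int] = None
    n_replicates: int = 200
    alpha: float = 0.05
    window_length: int = 4000
    step: int = 2000
    window_spacing: int = 10000
    chromosome: str = "15"
    ld_block_rho: float = 0.0    # >0 turns on within-window latent correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variants_per_window < 1:
            raise ValueError("variants_per_window must be >= 1")
        if self.n_windows < 1 or self.n_families < 1:
            raise ValueError("n_windows and n_families must be >= 1")
        if not math.isclose(sum(self.category_probs), 1.0, abs_tol=1e-9):
            raise ValueError("category probabilities must sum to 1")
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be nonnegative")
        if self.effect_model not in ("null", "doubleton", "category1", "mixed"):
            raise ValueError(f"unknown effect model {self.effect_model!r}")


def type1_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study conditions for the type-I-error evaluation.

    Matches the evaluation design the tests are calibrated against:
    a related cohort of approximately 790 individuals (72 of the
    three-generation 11-member families), 50 null windows of rare
    variants, and 200 simulated phenotype replicates.
    """
    base = dict(n_families=72, n_windows=50, n_replicates=200,
                effect_model="null", seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Deterministic three-generation pedigree fixture.

    Each family: founder couple GP1 x GP2 with children C1-C3; C1 and C2
    marry unrelated founders SP1/SP2 and each couple has two children.
    All matings are between non-relatives, so the cohort is non-inbred.
    """
    inds: list[Individual] = []
    for f in range(cfg.n_families):
        fam = f"FAM{f+1}"
        gp1, gp2 = f"{fam}_GP1", f"{fam}_GP2"
        inds.append(Individual(fam, gp1, None, None, 1))
        inds.append(Individual(fam, gp2, None, None, 2))
        for c in range(3):
            inds.append(Individual(fam, f"{fam}_C{c+1}", gp1, gp2, 1 + c % 2))
        for s in range(2):
            spouse = f"{fam}_SP{s+1}"
            inds.append(Individual(fam, spouse, None, None, 2 - s % 2))
            parent = f"{fam}_C{s+1}"
            father, mother = (parent, spouse) if s % 2 == 0 else (spouse, parent)
            for g in range(2):
                inds.append(Individual(fam, f"{fam}_GC{2*s+g+1}",
                                       father, mother, 1 + g % 2))
    return Pedigree(inds)


def simulate_genotypes(ped: Pedigree, mafs: np.ndarray,
                       rng: np.random.Generator,
                       ld_block_rho: float = 0.0) -> np.ndarray:
    """Gene-drop genotypes for every pedigree member at independent sites.

    Founders receive two haplotypes with per-site alternate-allele
    probability ``mafs``; non-founders inherit one uniformly chosen
    haplotype from each parent.  Returns an n x m allele-count matrix in
    pedigree row order.  ``ld_block_rho`` > 0 correlates founder
    haplotypes within the block through a shared Gaussian factor.
    """
    mafs = np.asarray(mafs, dtype=float)
    m = mafs.size
    order = ped.topological()
    haps: dict[str, np.ndarray] = {}
    for ind in order:
        if ind.father_id is None and ind.mother_id is None:
            if ld_block_rho > 0.0:
                z = rng.standard_normal((2, 1))
                e = rng.standard_normal((2, m))
                latent = math.sqrt(ld_block_rho) * z + math.sqrt(1 - ld_block_rho) * e
                from scipy.stats import norm
                h = latent < norm.ppf(mafs)[None, :]
            else:
                h = rng.random((2, m)) < mafs
            haps[ind.individual_id] = h.astype(np.int8)
        else:
            rows = []
            for parent in (ind.father_id, ind.mother_id):
                if parent is None:
                    rows.append((rng.random(m) < mafs).astype(np.int8))
                else:
                    pick = rng.integers(0, 2, size=m)
                    rows.append(haps[parent][pick, np.arange(m)])
            haps[ind.individual_id] = np.stack(rows)
    return np.stack([haps[i].sum(axis=0) for i in ped.ids]).astype(float)


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age, sex, smoking and medication-use covariates for n individuals."""
    return pd.DataFrame({
        "age": rng.normal(50.0, 10.0, size=n).round(1),
        "sex": rng.integers(0, 2, size=n),
        "smoking": (rng.random(n) < 0.3).astype(int),
        "medication": (rng.random(n) < 0.2).astype(int),
    })


@dataclass
class SimulatedCohort:
    pedigree: Pedigree
    kinship2: np.ndarray              # 2*Phi over pedigree.ids
    chrom: str
    positions: np.ndarray             # all variants, sorted
    window_slices: list[slice]        # variant index ranges per window
    G: np.ndarray                     # n x m_total allele counts
    categories: np.ndarray            # integer categories 1..6 per variant
    covariates: pd.DataFrame
    beta: np.ndarray                  # per-variant phenotype effect
    config: SimulationConfig

    @property
    def ids(self) -> list[str]:
        return self.pedigree.ids

    def phenotypes(self, rng: np.random.Generator,
                   n_replicates: int = 1) -> np.ndarray:
        """Draw phenotype replicates from the generative mixed model.

        Returns an (n_replicates, n) array; the fixed part (covariates,
        genetic effects) is shared, polygenic and residual noise redrawn.
        """
        cfg = self.config
        n = len(self.ids)
        Z = self.covariates[["age", "sex", "smoking", "medication"]].to_numpy(float)
        gamma = np.array([cfg.covariate_effects[k]
                          for k in ("age", "sex", "smoking", "medication")])
        mean = cfg.intercept + Z @ gamma + self.G @ self.beta
        d, U = np.linalg.eigh(self.kinship2)
        L = U * np.sqrt(np.clip(d, 0.0, None))
        delta = rng.standard_normal((n_replicates, n)) @ L.T * math.sqrt(cfg.sigma2_g)
        eps = rng.standard_normal((n_replicates, n)) * math.sqrt(cfg.sigma2_e)
        return mean[None, :] + delta + eps


def _drop_doubleton(ped: Pedigree, rng: np.random.Generator,
                    max_tries: int = 2000) -> np.ndarray:
    """Gene-drop a single site until exactly two minor alleles survive."""
    n_founders = sum(1 for i in ped.individuals
                     if i.father_id is None and i.mother_id is None)
    maf = np.array([1.0 / (2.0 * n_founders)])
    for _ in range(max_tries):
        g = simulate_genotypes(ped, maf, rng)[:, 0]
        if g.sum() == 2.0 and g.max() == 1.0:
            return g
    raise RuntimeError("failed to simulate a doubleton site")


def simulate_cohort(cfg: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> SimulatedCohort:
    """Generate pedigree, genotypes, categories, covariates and effects."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg)
    kin2 = relatedness_covariance(kinship(ped))
    n = len(ped.ids)

    maf_low = cfg.maf_low if cfg.maf_low is not None else 1.0 / (2.0 * n)
    m_total = cfg.n_windows * cfg.variants_per_window
    positions = []
    slices = []
    for w in range(cfg.n_windows):
        base = 1 + w * cfg.window_spacing
        pos = np.sort(rng.choice(np.arange(base, base + cfg.window_length),
                                 size=cfg.variants_per_window, replace=False))
        slices.append(slice(w * cfg.variants_per_window,
                            (w + 1) * cfg.variants_per_window))
        positions.append(pos)
    positions = np.concatenate(positions)

    mafs = rng.uniform(maf_low, cfg.maf_high, size=m_total)
    if cfg.ld_block_rho > 0.0:
        blocks = [simulate_genotypes(ped, mafs[s], rng, cfg.ld_block_rho)
                  for s in slices]
        G = np.concatenate(blocks, axis=1)
    else:
        G = simulate_genotypes(ped, mafs, rng)
    categories = 1 + rng.choice(6, size=m_total, p=np.asarray(cfg.category_probs))

    beta = np.zeros(m_total)
    causal_w = cfg.causal_window if cfg.causal_window is not None else cfg.n_windows // 2
    if cfg.effect_model == "doubleton":
        # plant a strong-effect category-1 doubleton inside the causal window
        g_extra = _drop_doubleton(ped, rng)
        sl = slices[causal_w]
        base = 1 + causal_w * cfg.window_spacing
        taken = set(positions[sl])
        free = [p for p in range(base, base + cfg.window_length) if p not in taken]
        new_pos = int(rng.choice(free))
        insert_at = sl.start + int(np.searchsorted(positions[sl], new_pos))
        positions = np.insert(positions, insert_at, new_pos)
        G = np.insert(G, insert_at, g_extra, axis=1)
        categories = np.insert(categories, insert_at, 1)
        beta = np.insert(beta, insert_at, cfg.effect_size)
        slices = [slice(s.start if s.start < insert_at else s.start + 1,
                        s.stop if s.stop <= insert_at else s.stop + 1)
                  for s in slices]
    elif cfg.effect_model in ("category1", "mixed"):
        sl = slices[causal_w]
        idx = np.flatnonzero(categories[sl] == 1) + sl.start
        if idx.size == 0:  # guarantee at least one annotated causal variant
            idx = np.array([sl.start])
            categories[sl.start] = 1
        signs = np.ones(idx.size)
        if cfg.effect_model == "mixed":
            signs[1::2] = -1.0
        beta[idx] = cfg.effect_size * signs

    covariates = simulate_covariates(n, rng)
    return SimulatedCohort(ped, kin2, cfg.chromosome, positions, slices, G,
                           categories, covariates, beta, cfg)


# ---------------------------------------------------------------------------
# File emission (VCF / PED / TSV) for the end-to-end pipeline
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir,
                 rng: Optional[np.random.Generator] = None) -> dict:
    """Write PED, VCF, phenotype TSV and annotation TSV; returns the paths.

    One phenotype realisation is drawn for the file (the in-memory
    experiments redraw replicates instead).  Annotation strings include
    RegulomeDB sub-category letters and occasional PolyPhen2-only
    records so the fallback path is exercised on round-trips.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)

    ped_path = outdir / "cohort.ped"
    with open(ped_path, "w") as fh:
        for ind in cohort.pedigree.individuals:
            fh.write(f"{ind.family_id}\t{ind.individual_id}\t"
                     f"{ind.father_id or '0'}\t{ind.mother_id or '0'}\t{ind.sex}\n")

    vcf_path = outdir / "cohort.vcf"
    ids = cohort.ids
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cohort.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, pos in enumerate(cohort.positions):
            calls = "\t".join(gt_map[int(g)] for g in cohort.G[:, j])
            fh.write(f"{cohort.chrom}\t{int(pos)}\t.\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")

    pheno_path = outdir / "phenotypes.tsv"
    y = cohort.phenotypes(rng, n_replicates=1)[0]
    df = cohort.covariates.copy()
    df.insert(0, "id", ids)
    df.insert(1, "sbp", np.round(y, 3))
    df.to_csv(pheno_path, sep="\t", index=False)

    anno_path = outdir / "annotations.tsv"
    sub = "abcdef"
    rows = []
    for j, pos in enumerate(cohort.positions):
        cat = int(cohort.categories[j])
        use_polyphen = cat in (1, 3, 5) and rng.random() < 0.1
        if use_polyphen:
            reg, pp = "", {1: "probably damaging", 3: "possibly damaging",
                           5: "benign"}[cat]
        else:
            letter = sub[rng.integers(0, 3)] if cat <= 2 else ""
            reg, pp = f"{cat}{letter}", ""
        rows.append((cohort.chrom, int(pos), "A", "G", reg, pp))
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                "regdb_category", "polyphen2"]
                 ).to_csv(anno_path, sep="\t", index=False)

    return {"ped": ped_path, "vcf": vcf_path, "phenotypes": pheno_path,
            "annotations": anno_path}


# ---------------------------------------------------------------------------
# Type-I error and power experiments
# ---------------------------------------------------------------------------

@dataclass
class Type1Result:
    rates: dict                 # method -> empirical rejection rate
    conf_int99: dict            # method -> (lo, hi) 99% binomial band at 0.05
    n_tests: int
    alpha: float
    p_values: np.ndarray        # replicates x windows x methods


def _experiment(cfg: SimulationConfig, rng: np.random.Generator
                ) -> tuple[np.ndarray, list[int]]:
    """Shared engine: p-value array (replicates x windows x methods)."""
    cohort = simulate_cohort(cfg, rng)
    d, U = np.linalg.eigh(cohort.kinship2)
    d = np.clip(d, 0.0, None)
    Z = cohort.covariates[["age", "sex", "smoking", "medication"]].to_numpy(float)
    X = np.column_stack([np.ones(len(cohort.ids)), Z])

    wins = []
    win_ids: list[int] = []
    for w, sl in enumerate(cohort.window_slices):
        gw = assoc.filter_rare(cohort.G[:, sl], maf_threshold=cfg.maf_high)
        if gw is None:
            continue
        cats = cohort.categories[sl][gw.kept]
        label = f"{cohort.chrom}:w{w}"
        wins.append((gw, cats, label))
        win_ids.append(w)

    n_methods = len(assoc.ALL_METHODS)
    pvals = np.full((cfg.n_replicates, len(wins), n_methods), np.nan)
    Y = cohort.phenotypes(rng, n_replicates=cfg.n_replicates)
    rotated = None
    for r in range(cfg.n_replicates):
        fit = fit_null(Y[r], X, eig=(d, U))
        if rotated is None:
            rotated = [fit.rotate(gw.G) for gw, _, _ in wins]
        for k, (gw, cats, label) in enumerate(wins):
            GPy, GPG = fit.quadratics(gw.G, Gt=rotated[k])
            resid = fit.resid_proj
            for t, method in enumerate(assoc.SKAT_METHODS):
                wsq = assoc.variance_weights(method, gw.mafs, cats)
                stat = assoc.skat_statistic(gw, wsq, resid)
                p, _flag = assoc.skat_pvalue(stat, gw, wsq, fit, GPG=GPG)
                pvals[r, k, t] = p
            for t, method in enumerate(assoc.BURDEN_METHODS):
                w_b = assoc.burden_weights(method, gw.mafs, cats)
                res = assoc.burden_test(gw, w_b, fit, label, method,
                                        quad=(GPy, GPG))
                pvals[r, k, len(assoc.SKAT_METHODS) + t] = res.p_value
    return pvals, win_ids


def type1_experiment(cfg: SimulationConfig,
                     rng: Optional[np.random.Generator] = None) -> Type1Result:
    """Empirical type-I error of all six tests on a null family cohort.

    Every (window, replicate) pair contributes one test per method; the
    rate is the fraction rejected at ``cfg.alpha``.  The 99% binomial
    band treats the window x replicate tests as independent, which they
    are up to the replicate-shared phenotype draw.
    """
    if cfg.effect_model != "null" or cfg.effect_size != 0.0:
        raise ValueError("type-I experiment requires the null effect model")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pvals, win_ids = _experiment(cfg, rng)
    n_tests = cfg.n_replicates * len(win_ids)
    from scipy.stats import norm
    half = norm.ppf(0.995) * math.sqrt(cfg.alpha * (1 - cfg.alpha) / n_tests)
    rates, bands = {}, {}
    for t, method in enumerate(assoc.ALL_METHODS):
        rates[method] = float(np.mean(pvals[:, :, t] < cfg.alpha))
        bands[method] = (cfg.alpha - half, cfg.alpha + half)
    return Type1Result(rates, bands, n_tests, cfg.alpha, pvals)


@dataclass
class PowerResult:
    power: dict
    n_tests: int
    alpha: float


def power_experiment(cfg: SimulationConfig,
                     rng: Optional[np.random.Generator] = None) -> PowerResult:
    """Empirical power on the causal window when ``effect_size`` != 0."""
    if cfg.effect_model == "null":
        raise ValueError("power experiment requires a non-null effect model")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    causal = cfg.causal_window if cfg.causal_window is not None else cfg.n_windows // 2
    pvals, win_ids = _experiment(cfg, rng)
    if causal not in win_ids:
        raise RuntimeError("causal window was filtered out entirely")
    k = win_ids.index(causal)
    power = {m: float(np.mean(pvals[:, k, t] < cfg.alpha))
             for t, m in enumerate(assoc.ALL_METHODS)}
    return PowerResult(power, cfg.n_replicates, cfg.alpha)
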