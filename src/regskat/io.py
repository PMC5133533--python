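"""Interchange-format readers/writers and the end-to-end genome scan.

The scan pipeline wires the modules together: read genotypes, pedigree,
phenotypes and annotations; compute kinship on the full pedigree and
subset it to the analyzed individuals; fit the null mixed model once;
tile sliding windows; run all six tests per window; and emit a results
TSV plus a machine-readable JSON run report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import assoc
from .annotate import categories_from_table, read_annotation, _strip_chr
from .nullmodel import fit_null, read_phenotypes
from .pedigree import kinship, read_pedigree, relatedness_covariance
from .windows import WindowingConfig, tile_windows

logger = logging.getLogger("regskat")

__all__ = ["RunConfig", "read_genotypes", "scan", "write_results"]

RESULT_COLUMNS = ["chrom", "window_start", "window_end", "window_label",
                  "m_used", "method", "statistic", "p", "neg_log10_p", "flag"]


@dataclass
class RunConfig:
    vcf: str
    ped: str
    phenotypes: str
    annotations: str
    out_dir: str
    trait: str = "sbp"
    covariates: Sequence[str] = ("age", "sex", "smoking", "medication")
    id_column: str = "id"
    window_length: int = 4000
    step: int = 2000
    maf_threshold: float = 0.05
    fwer: float = 0.05
    chromosomes: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold <= 0.5:
            raise ValueError("MAF threshold must be in (0, 0.5]")
        for path in (self.vcf, self.ped, self.phenotypes, self.annotations):
            if not Path(path).exists():
                raise FileNotFoundError(path)


def read_genotypes(vcf_path, sample_ids: Optional[Sequence[str]] = None
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a VCF into variant metadata and an allele-count matrix.

    Returns ``(variants, G)`` where ``variants`` has columns
    chrom/pos/ref/alt (one row per alternate allele — multi-allelic
    records are split) and ``G`` is n_samples x n_variants with NaN for
    missing calls.  Chromosome names are normalised without the ``chr``
    prefix.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    if sample_ids is not None:
        missing = sorted(set(sample_ids) - set(vcf.samples))
        if missing:
            raise ValueError(f"samples absent from VCF: {missing[:10]}")
        vcf.set_samples(list(sample_ids))
    samples = list(vcf.samples)

    rows = []
    columns = []
    for variant in vcf:
        gts = np.array(variant.genotypes, dtype=object)
        a1 = np.array([g[0] for g in gts], dtype=int)
        a2 = np.array([g[1] for g in gts], dtype=int)
        miss = (a1 < 0) | (a2 < 0)
        for alt_index, alt in enumerate(variant.ALT, start=1):
            counts = (a1 == alt_index).astype(float) + (a2 == alt_index)
            counts[miss] = np.nan
            rows.append((_strip_chr(variant.CHROM), variant.POS,
                         variant.REF, alt))
            columns.append(counts)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    G = (np.column_stack(columns) if columns
         else np.empty((len(samples), 0)))
    if sample_ids is not None and samples != list(sample_ids):
        order = [samples.index(s) for s in sample_ids]
        G = G[order]
    return variants, G


def write_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=RESULT_COLUMNS)


def scan(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Run the sliding-window association scan end to end.

    Returns the results table and the run report; both are also written
    under ``config.out_dir`` (``results.tsv``, ``run_report.json``,
    ``skipped_windows.tsv``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ped = read_pedigree(config.ped)
    pheno = read_phenotypes(config.phenotypes, config.trait,
                            config.covariates, config.id_column)

    # individuals analysed: present in phenotype table AND genotype file
    from cyvcf2 import VCF
    vcf_samples = set(VCF(str(config.vcf)).samples)
    analyzed = [i for i in pheno.ids if i in vcf_samples]
    if not analyzed:
        raise RuntimeError("no individuals shared between phenotype table and VCF")
    keep = [pheno.ids.index(i) for i in analyzed]
    y = pheno.y[keep]
    Z = pheno.covariates[keep]

    orphans = [i for i in analyzed if i not in set(ped.ids)]
    if orphans:
        logger.warning("%d phenotyped individuals absent from the pedigree; "
                       "treated as unrelated founders", len(orphans))
        ped = ped.add_founders(orphans)
    kin = kinship(ped).subset(analyzed)
    K2 = relatedness_covariance(kin)

    variants, G = read_genotypes(config.vcf, analyzed)
    if config.chromosomes is not None:
        wanted = {_strip_chr(str(c)) for c in config.chromosomes}
        mask = variants["chrom"].isin(wanted).to_numpy()
        variants, G = variants[mask].reset_index(drop=True), G[:, mask]
    if len(variants) == 0:
        logger.warning("no variants to analyse; emitting empty results")
        empty = pd.DataFrame(columns=RESULT_COLUMNS)
        write_results(empty, out_dir / "results.tsv")
        report = {"n_analyzed": len(analyzed), "n_variants": 0,
                  "windows_tested": 0, "windows_skipped": 0}
        (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
        return empty, report

    anno = read_annotation(config.annotations)
    merged = variants.merge(anno, on=["chrom", "pos", "ref", "alt"], how="left")
    merged["regdb_category"] = merged["regdb_category"].fillna("")
    merged["polyphen2"] = merged["polyphen2"].fillna("")
    categories = np.array([c.value for c in categories_from_table(merged)])

    wcfg = WindowingConfig(config.window_length, config.step)
    wins = tile_windows(merged["chrom"].to_numpy(),
                        merged["pos"].to_numpy(), wcfg)

    X = np.column_stack([np.ones(len(y)), Z])
    fit = fit_null(y, X, K2)

    results: list[assoc.TestResult] = []
    meta: list[tuple] = []
    skipped: list[tuple] = []
    for w in wins:
        idx = np.array(w.variant_indices)
        gw = assoc.filter_rare(G[:, idx], config.maf_threshold)
        if gw is None:
            skipped.append((w.chromosome, w.start, w.end, w.label,
                            "no_rare_variants"))
            continue
        cats = categories[idx[gw.kept]]
        for res in assoc.run_window(gw, fit, cats, w.label):
            results.append(res)
            meta.append((w.chromosome, w.start, w.end))

    df = pd.DataFrame({
        "chrom": [m[0] for m in meta],
        "window_start": [m[1] for m in meta],
        "window_end": [m[2] for m in meta],
        "window_label": [r.window_label for r in results],
        "m_used": [r.m_used for r in results],
        "method": [r.method for r in results],
        "statistic": [r.statistic for r in results],
        "p": [r.p_value for r in results],
        "flag": [r.flag for r in results],
    })
    df["neg_log10_p"] = -np.log10(df["p"])
    df = df[RESULT_COLUMNS]

    n_tested = df["window_label"].nunique()
    alpha, neglog = (assoc.bonferroni_threshold(n_tested, config.fwer)
                     if n_tested else (config.fwer, float("nan")))
    sig_counts = {m: int(((df["method"] == m) & (df["p"] < alpha)).sum())
                  for m in assoc.ALL_METHODS}
    report = {
        "n_analyzed": len(analyzed),
        "n_dropped_missing_phenotype": pheno.n_dropped_missing,
        "n_variants": int(len(variants)),
        "windows_tested": int(n_tested),
        "windows_skipped": len(skipped),
        "bonferroni_alpha": alpha,
        "bonferroni_neg_log10": neglog,
        "null_model": {"sigma2_g": fit.sigma2_g, "sigma2_e": fit.sigma2_e,
                       "gamma_hat": fit.gamma_hat.tolist()},
        "significant_windows": sig_counts,
    }
    write_results(df, out_dir / "results.tsv")
    pd.DataFrame(skipped, columns=["chrom", "start", "end", "label", "reason"]
                 ).to_csv(out_dir / "skipped_windows.tsv", sep="\t", index=False)
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
    return df, report
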