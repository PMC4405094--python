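"""Chromosome partitioning and regional heritability scanning.

For each genomic unit (a chromosome or a sliding SNP window) two nested
animal models are compared by REML likelihood-ratio test:

    full:    y = Xb + Z c_unit + Z ra_rest + (other random terms) + e
    reduced: y = Xb +            Z ra_rest + (other random terms) + e

where c_unit is structured by a GRM built from the unit's SNPs and
ra_rest by a GRM from all remaining autosomal SNPs.  With shared allele
frequencies the two GRMs decompose the whole-genome GRM exactly, so the
complement matrix is derived by linearity rather than recomputed.

Chromosome results carry nominal P values (no multiple-testing
adjustment); the regional scan's threshold is alpha divided by half the
number of converged region models, reflecting the 50% window overlap.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .grm import GRM, RegionDefinition, adjust_grm, compute_grm, define_regions
from .io import GenotypeSet
from .varcomp import (
    build_model,
    fit_variance_components,
    likelihood_ratio_test,
    variance_ratios,
)

__all__ = [
    "chromosome_partition",
    "regional_scan",
    "length_regression",
    "whole_genome_fit",
]

log = logging.getLogger(__name__)


def _paired_grms(
    genotypes: GenotypeSet, subset: np.ndarray, adjust: str = "off"
) -> tuple[GRM, GRM]:
    """(unit GRM, complement GRM) with shared full-sample frequencies.

    Monomorphic SNPs are excluded up front so the pair decomposes the
    whole-genome GRM exactly: m_tot A_tot = m_u A_u + m_c A_c.
    """
    p_all = genotypes.allele_frequencies()
    poly = (p_all > 0) & (p_all < 1)
    subset = np.asarray(subset)
    in_unit = np.zeros(genotypes.n_snps, dtype=bool)
    in_unit[subset] = True
    unit_idx = np.flatnonzero(in_unit & poly)
    comp_idx = np.flatnonzero(~in_unit & poly)
    if unit_idx.size == 0 or comp_idx.size == 0:
        raise ValueError("unit or complement SNP set is empty after filtering")
    g_unit = compute_grm(genotypes, unit_idx, p_all[unit_idx])
    g_comp = compute_grm(genotypes, comp_idx, p_all[comp_idx])
    if adjust != "off":
        g_unit = adjust_grm(g_unit, adjust)
        g_comp = adjust_grm(g_comp, adjust)
    return g_unit, g_comp


def whole_genome_fit(
    genotypes: GenotypeSet,
    pheno: pd.DataFrame,
    trait: str,
    groups: list[str] | None = None,
    permanent_env: bool = False,
    fixed=("sex", "age"),
    **fit_kw,
):
    """All-autosome animal model: genomic V_A and h2."""
    grm = compute_grm(genotypes)
    spec = build_model(
        pheno, trait, grms={"a": grm}, groups=groups,
        permanent_env=permanent_env, fixed=list(fixed),
    )
    fit = fit_variance_components(spec, **fit_kw)
    return fit, spec, grm


def _fit_unit(
    genotypes, pheno, trait, subset, unit_label,
    groups, permanent_env, fixed, adjust, fit_kw,
) -> dict:
    g_unit, g_comp = _paired_grms(genotypes, subset, adjust)
    spec_full = build_model(
        pheno, trait, grms={"c": g_unit, "ra": g_comp}, groups=groups,
        permanent_env=permanent_env, fixed=list(fixed),
    )
    fit_full = fit_variance_components(spec_full, **fit_kw)
    fit_red = fit_variance_components(spec_full.drop_term("c"), **fit_kw)
    row = {
        "unit": unit_label,
        "converged": fit_full.converged and fit_red.converged,
        "v_unit": np.nan,
        "v_unit_se": np.nan,
        "h2_unit": np.nan,
        "h2_unit_se": np.nan,
        "lrt": np.nan,
        "p": np.nan,
    }
    if row["converged"]:
        lrt, p = likelihood_ratio_test(fit_full, fit_red)
        ratio, ratio_se = variance_ratios(fit_full, "c")["c"]
        row.update(
            v_unit=fit_full.components["c"],
            v_unit_se=fit_full.se["c"],
            h2_unit=ratio,
            h2_unit_se=ratio_se,
            lrt=lrt,
            p=p,
        )
    else:
        log.warning("unit %s: model did not converge", unit_label)
    return {"row": row, "fit_full": fit_full, "fit_reduced": fit_red}


def chromosome_partition(
    genotypes: GenotypeSet,
    pheno: pd.DataFrame,
    trait: str,
    groups: list[str] | None = None,
    permanent_env: bool = False,
    fixed=("sex", "age"),
    adjust: str = "off",
    alpha: float = 0.05,
    **fit_kw,
) -> dict:
    """Partition phenotypic variance across chromosomes.

    Returns a table with one row per chromosome (variance, h2, LRT against
    chi-square(1), nominal P — deliberately unadjusted), a sum row over
    converged chromosomes, and the whole-genome fit.
    """
    chroms = list(pd.unique(genotypes.snp_map["chrom"]))
    rows, fits = [], {}
    for chrom in chroms:
        subset = np.flatnonzero((genotypes.snp_map["chrom"] == chrom).to_numpy())
        res = _fit_unit(
            genotypes, pheno, trait, subset, chrom,
            groups, permanent_env, fixed, adjust, fit_kw,
        )
        rows.append(res["row"])
        fits[chrom] = res
    table = pd.DataFrame(rows)
    table["significant"] = table["p"] < alpha
    ok = table["converged"]
    sum_row = {
        "unit": "sum",
        "v_unit": table.loc[ok, "v_unit"].sum(),
        "h2_unit": table.loc[ok, "h2_unit"].sum(),
        "n_converged": int(ok.sum()),
        "n_attempted": len(table),
    }
    wg_fit, wg_spec, _ = whole_genome_fit(
        genotypes, pheno, trait, groups, permanent_env, fixed, **fit_kw
    )
    return {"table": table, "sum": sum_row, "whole_genome": wg_fit, "fits": fits}


def regional_scan(
    genotypes: GenotypeSet,
    pheno: pd.DataFrame,
    trait: str,
    regions: list[RegionDefinition] | None = None,
    groups: list[str] | None = None,
    permanent_env: bool = False,
    fixed=("sex", "age"),
    adjust: str = "off",
    alpha: float = 0.05,
    window: int = 150,
    step: int = 75,
    min_snps: int = 113,
    **fit_kw,
) -> dict:
    """Regional heritability scan over sliding SNP windows.

    The significance threshold is alpha / (n_converged / 2): windows
    overlap by half, so the effective number of independent regions is
    taken as half the converged model count.
    """
    if regions is None:
        regions = define_regions(genotypes.snp_map, window, step, min_snps)
    if not regions:
        raise ValueError("no testable regions on this SNP map")
    rows = []
    for reg in regions:
        res = _fit_unit(
            genotypes, pheno, trait, reg.global_indices, reg.index,
            groups, permanent_env, fixed, adjust, fit_kw,
        )
        row = res["row"]
        row.update(
            chrom=reg.chrom,
            bp_start=reg.bp_start,
            bp_end=reg.bp_end,
            n_snps=reg.n_snps,
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    n_conv = int(table["converged"].sum())
    if n_conv == 0:
        raise ValueError("no testable regions: no region model converged")
    threshold = alpha / (n_conv / 2.0)
    table["significant"] = table["p"] < threshold
    return {
        "table": table,
        "threshold": threshold,
        "n_converged": n_conv,
        "n_attempted": len(table),
    }


def length_regression(
    table: pd.DataFrame,
    lengths: pd.Series | dict,
    value: str = "h2_unit",
):
    """OLS of per-chromosome variance explained on physical length (Mb).

    Returns (slope, intercept, r2, p) with a two-sided slope test; needs
    at least three converged chromosomes and non-constant lengths.
    """
    sub = table[table["converged"]] if "converged" in table else table
    if len(sub) < 3:
        raise ValueError("need >= 3 converged chromosomes for the regression")
    x = np.array([float(pd.Series(lengths)[u]) for u in sub["unit"]])
    y = sub[value].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError("chromosome lengths are constant; regression undefined")
    if np.var(y) == 0:
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)
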