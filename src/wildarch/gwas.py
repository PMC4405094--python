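"""Two-stage (GRAMMAR) genome-wide association scan.

Stage one fits the full animal model (whole-genome GRM plus any
non-genetic random terms) by REML; stage two regresses the model
residuals — averaged per individual when repeated measures exist — on
each SNP's minor-allele dosage with a fast score test, n * r^2 against
chi-square(1).  Residual-based scans are conservative in
family-structured data (the genomic inflation factor lambda drops below
1), so top SNPs are refitted inside the mixed model as a dosage
covariate to obtain unbiased effects, and the SNP variance is reported
as V_SNP = 2 p q a^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeSet
from .varcomp import ModelSpec, VarianceFit, fit_variance_components

__all__ = [
    "grammar_residuals",
    "score_scan",
    "inflation_factor",
    "bonferroni_threshold",
    "refit_snp_effect",
    "snp_variance_ratios",
    "SnpEffect",
]

log = logging.getLogger(__name__)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


@dataclass
class SnpEffect:
    """Mixed-model refit of one SNP."""

    snp_id: str
    a: float  # additive effect per minor-allele copy, trait units
    se: float
    p_wald: float
    p_major: float
    q_minor: float
    v_snp: float  # 2 p q a^2
    v_p: float
    v_a: float
    h2_snp: float  # V_SNP / V_P
    share_va: float  # V_SNP / V_A
    fit: VarianceFit | None = None


def grammar_residuals(fit: VarianceFit) -> pd.Series:
    """Per-individual mean residual from a converged animal-model fit.

    The residual subtracts fixed-effect predictions and the BLUPs of every
    random term (e-hat = s2_e * P y); repeated measures are averaged so
    each individual contributes one value.
    """
    if not fit.converged:
        raise ValueError("GRAMMAR residuals require a converged mixed-model fit")
    s = pd.Series(fit.resid_blup, index=pd.Index(fit.obs_ids, name="id"))
    return s.groupby(level="id").mean()


def score_scan(residuals: pd.Series, genotypes: GenotypeSet) -> pd.DataFrame:
    """Score test of mean residuals against every SNP.

    Per SNP the statistic is n * r^2 with r the Pearson correlation of
    residual and dosage over non-missing pairs, referred to chi-square(1);
    the reported effect is the OLS slope of residual on minor-allele
    dosage.  Monomorphic SNPs yield NA rows.
    """
    common = [i for i in genotypes.sample_ids if i in residuals.index]
    if not common:
        raise ValueError("no genotyped individuals with residuals")
    pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
    X = genotypes.dosages[[pos[i] for i in common]]
    r_vec = residuals.loc[common].to_numpy()

    obs = ~np.isnan(X)
    n = obs.sum(axis=0).astype(float)
    # orient dosage to count the CURRENT minor allele
    with np.errstate(invalid="ignore"):
        freq1 = np.nansum(X, axis=0) / (2 * n)
    flip = freq1 > 0.5
    Xm = np.where(flip, 2 - X, X)

    Xz = np.where(obs, Xm, 0.0)
    rz = np.where(obs, r_vec[:, None], 0.0)
    sx = Xz.sum(axis=0)
    sy = rz.sum(axis=0)
    sxx = (Xz * Xz).sum(axis=0)
    syy = (rz * rz).sum(axis=0)
    sxy = (Xz * rz).sum(axis=0)
    cov = sxy - sx * sy / n
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov**2 / (vx * vy)
        slope = cov / vx
    mono = vx <= 0
    if mono.any():
        log.info("%d monomorphic SNPs: association undefined", int(mono.sum()))
    chi2 = np.where(mono, np.nan, n * r2)
    p = stats.chi2.sf(chi2, 1)

    sm = genotypes.snp_map
    minor = np.where(flip, sm["a2"], sm["a1"])
    major = np.where(flip, sm["a1"], sm["a2"])
    return pd.DataFrame(
        {
            "snp_id": sm["snp_id"].to_numpy(),
            "chrom": sm["chrom"].to_numpy(),
            "bp": sm["bp"].to_numpy(),
            "major_allele": major,
            "minor_allele": minor,
            "n_obs": n.astype(int),
            "effect": np.where(mono, np.nan, slope),
            "chi2": chi2,
            "p": np.where(mono, np.nan, p),
        }
    )


def inflation_factor(statistics: np.ndarray) -> float:
    """Genomic inflation lambda: median observed chi2 over the chi2(1) median.

    Diagnostic only — the scan's P values are not rescaled by default,
    matching the conservative residual-scan convention.
    """
    s = np.asarray(statistics, dtype=float)
    s = s[np.isfinite(s)]
    if s.size == 0:
        raise ValueError("no finite statistics supplied")
    if s.size < 100:
        log.warning("inflation factor from only %d statistics", s.size)
    return float(np.median(s) / CHI2_1_MEDIAN)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def snp_variance_ratios(v_snp: float, v_a: float, h2: float) -> tuple[float, float]:
    """(share of V_A, h2_SNP) for a SNP variance under a genomic h2.

    share = V_SNP / V_A; h2_SNP = V_SNP / V_P with V_P = V_A / h2, i.e.
    V_SNP * h2 / V_A.
    """
    if v_a <= 0 or not 0 < h2 <= 1:
        raise ValueError("need V_A > 0 and h2 in (0, 1]")
    return v_snp / v_a, v_snp * h2 / v_a


def refit_snp_effect(
    spec: ModelSpec,
    genotypes: GenotypeSet,
    snp_id: str,
    genetic_term: str = "a",
    allele_freq: float | None = None,
    **fit_kw,
) -> SnpEffect:
    """Refit the animal model with the SNP's minor-allele dosage as covariate.

    ``a`` is the covariate coefficient (trait units per minor-allele
    copy) with its Wald P; V_SNP = 2 p q a^2 with q the minor-allele
    frequency in the full genotyped sample (or ``allele_freq`` if given);
    h2_SNP = V_SNP / V_P and the share of additive variance is
    V_SNP / s2(genetic_term).  Individuals with a missing call at the SNP
    are mean-imputed for the covariate.
    """
    j = np.flatnonzero(genotypes.snp_map["snp_id"].to_numpy() == snp_id)
    if j.size != 1:
        raise ValueError(f"SNP {snp_id!r} not found (or duplicated)")
    col = genotypes.dosages[:, j[0]]
    pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
    missing = [i for i in spec.obs_ids if i not in pos]
    if missing:
        raise ValueError(f"genotypes lack ids: {missing[:5]}")
    x = col[[pos[i] for i in spec.obs_ids]]

    full_freq = float(np.nanmean(col) / 2.0) if allele_freq is None else allele_freq
    if not 0 < full_freq < 1:
        raise ValueError(f"SNP {snp_id!r} is monomorphic in the genotyped sample")
    q = min(full_freq, 1 - full_freq)
    if full_freq > 0.5:  # dosage counts allele1; recode to minor-allele copies
        x = 2 - x
    x = np.where(np.isnan(x), 2 * q, x)
    if np.nanstd(x) == 0:
        raise ValueError(f"SNP {snp_id!r} is monomorphic in the fitted sample")

    X = np.column_stack([spec.X, x])
    aug = ModelSpec(spec.y, X, spec.terms, spec.obs_ids, spec.fixed_names + ["snp"])
    fit = fit_variance_components(aug, **fit_kw)
    if not fit.converged:
        raise ValueError("joint SNP refit did not converge")
    a = float(fit.beta[-1])
    se = float(np.sqrt(fit.beta_cov[-1, -1]))
    p_wald = float(2 * stats.norm.sf(abs(a) / se)) if se > 0 else np.nan
    v_snp = 2 * (1 - q) * q * a * a
    v_p = fit.total_variance
    v_a = fit.components.get(genetic_term, np.nan)
    return SnpEffect(
        snp_id=snp_id,
        a=a,
        se=se,
        p_wald=p_wald,
        p_major=1 - q,
        q_minor=q,
        v_snp=v_snp,
        v_p=v_p,
        v_a=v_a,
        h2_snp=v_snp / v_p if v_p > 0 else np.nan,
        share_va=v_snp / v_a if v_a > 0 else np.nan,
        fit=fit,
    )


def top_snp(scan: pd.DataFrame) -> pd.Series:
    """Most associated SNP; ties broken by smaller bp then lexicographic id."""
    ranked = scan.dropna(subset=["chi2"]).sort_values(
        ["chi2", "bp", "snp_id"], ascending=[False, True, True], kind="mergesort"
    )
    if ranked.empty:
        raise ValueError("scan has no testable SNPs")
    return ranked.iloc[0]
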