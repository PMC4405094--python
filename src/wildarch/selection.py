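"""Fitness measures, selection coefficients and gene-drop drift nulls.

Four fitness measures are derived from pedigree plus census records:

* AS — annual survival, a binary flag per individual-year (survival past
  the census date of that year);
* AR — annual recruits, offspring born that year that survived their
  first year;
* LBS — lifetime breeding success, total offspring, restricted to a
  birth-cohort window so censoring does not bias it;
* LR — lifetime recruits.

Per-genotype relative fitness is w = mean fitness / max genotype mean,
the selection coefficient s = 1 - w (so the fittest genotype has s = 0),
with percentile bootstrap confidence intervals over individuals.  Under
heterozygote advantage the equilibrium minor-allele frequency is
q = s1 / (s1 + s2) with s1, s2 the homozygote selection coefficients.

Observed allele-frequency trends are tested against a gene-drop null:
founders keep their observed genotypes, every descendant's genotype is
re-sampled by Mendelian transmission through the fixed pedigree, and
yearly frequencies are recomputed over the same individuals, giving the
distribution of trend slopes that drift alone can generate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "derive_fitness",
    "selection_coefficients",
    "equilibrium_frequency",
    "allele_trend_test",
    "genotype_fitness_glm",
    "SelectionEstimate",
]

log = logging.getLogger(__name__)

GENOTYPE_LABELS = ("major_hom", "het", "minor_hom")


def derive_fitness(
    pedigree: pd.DataFrame,
    census: pd.DataFrame,
    cohort_window: tuple[int, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Fitness tables from a pedigree and per-year census survival flags.

    ``census`` needs columns (id, year, survived); an individual-year row
    means the individual was in the study population that year.  Returns
    ``annual`` (id, year, AS, AR) and ``lifetime`` (id, sex, LBS, LR,
    in_cohort); LBS is restricted to ``cohort_window`` birth years when
    given (others get NA).
    """
    ped = pedigree.copy()
    by = ped.set_index("id")["birth_year"]
    for col in ("sire", "dam"):
        sub = ped.dropna(subset=[col])
        bad = sub[by.loc[sub[col]].to_numpy() >= sub["birth_year"].to_numpy()]
        if len(bad):
            raise ValueError(
                f"offspring born in or before {col}'s birth year: {list(bad['id'])[:5]}"
            )

    surv = census.set_index(["id", "year"])["survived"]
    # a recruit survived past the census date of its birth year
    recruited = {
        r.id: bool(surv.get((r.id, r.birth_year), False)) for r in ped.itertuples()
    }

    offspring = ped.dropna(subset=["sire", "dam"])
    ar: dict[tuple, int] = {}
    lbs = dict.fromkeys(ped["id"], 0)
    lr = dict.fromkeys(ped["id"], 0)
    for r in offspring.itertuples():
        rec = int(recruited[r.id])
        for parent in (r.sire, r.dam):
            lbs[parent] += 1
            lr[parent] += rec
            key = (parent, r.birth_year)
            ar[key] = ar.get(key, 0) + rec

    annual = census[["id", "year"]].copy()
    annual["AS"] = census["survived"].astype(int).to_numpy()
    annual["AR"] = [ar.get((i, y), 0) for i, y in zip(annual["id"], annual["year"])]

    lifetime = pd.DataFrame(
        {
            "id": ped["id"],
            "sex": ped["sex"],
            "LBS": [lbs[i] for i in ped["id"]],
            "LR": [lr[i] for i in ped["id"]],
        }
    )
    if cohort_window is not None:
        lo, hi = cohort_window
        out = ~ped["birth_year"].between(lo, hi)
        lifetime["in_cohort"] = ~out.to_numpy()
        lifetime.loc[out.to_numpy(), "LBS"] = pd.NA
    else:
        lifetime["in_cohort"] = True
    bad = lifetime.dropna(subset=["LBS"])
    if (bad["LBS"] < bad["LR"]).any():
        raise AssertionError("internal error: LBS < LR")
    return {"annual": annual, "lifetime": lifetime}


@dataclass
class SelectionEstimate:
    """Per-genotype fitness summary at one SNP."""

    table: pd.DataFrame  # genotype, n, mean_fitness, w, s, s_lo, s_hi
    fittest: str
    heterozygote_advantage: bool
    boot_s: np.ndarray  # (n_boot, 3) bootstrap draws of s per genotype


def selection_coefficients(
    fitness: np.ndarray,
    dosage: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    min_class: int = 5,
) -> SelectionEstimate:
    """Relative fitness and selection coefficients per genotype.

    ``dosage`` counts minor-allele copies (0/1/2); pairs with missing
    fitness or genotype are dropped.  Genotype classes smaller than
    ``min_class`` are flagged with a warning (their estimates are noisy).
    Bootstrap resamples individuals; CIs are percentile.
    """
    fitness = np.asarray(fitness, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    keep = np.isfinite(fitness) & np.isfinite(dosage)
    fitness, dosage = fitness[keep], dosage[keep]
    classes = [dosage == g for g in (0, 1, 2)]
    n_per = np.array([c.sum() for c in classes])
    if (n_per == 0).any():
        missing = [GENOTYPE_LABELS[i] for i in np.flatnonzero(n_per == 0)]
        raise ValueError(f"no individuals in genotype class(es): {missing}")
    small = n_per < min_class
    if small.any():
        log.warning(
            "genotype classes with < %d individuals: %s",
            min_class,
            [GENOTYPE_LABELS[i] for i in np.flatnonzero(small)],
        )
    means = np.array([fitness[c].mean() for c in classes])
    if means.max() <= 0:
        raise ValueError("all genotype classes have zero mean fitness")
    w = means / means.max()
    s = 1.0 - w

    rng = np.random.default_rng(seed)
    n = len(fitness)
    boot = np.full((n_boot, 3), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        f, d = fitness[idx], dosage[idx]
        m = np.array([f[d == g].mean() if (d == g).any() else np.nan for g in (0, 1, 2)])
        if np.nanmax(m) > 0:
            boot[b] = 1.0 - m / np.nanmax(m)
    lo = np.nanpercentile(boot, 2.5, axis=0)
    hi = np.nanpercentile(boot, 97.5, axis=0)

    table = pd.DataFrame(
        {
            "genotype": GENOTYPE_LABELS,
            "n": n_per,
            "mean_fitness": means,
            "w": w,
            "s": s,
            "s_lo": lo,
            "s_hi": hi,
        }
    )
    fittest = GENOTYPE_LABELS[int(np.argmax(means))]
    return SelectionEstimate(
        table=table,
        fittest=fittest,
        heterozygote_advantage=(fittest == "het"),
        boot_s=boot,
    )


def equilibrium_frequency(
    s1: float, s2: float, boot_s: np.ndarray | None = None
) -> tuple[float, tuple[float, float] | None]:
    """Equilibrium minor-allele frequency q = s1 / (s1 + s2) under
    heterozygote advantage.

    ``s1`` is the major-homozygote and ``s2`` the minor-homozygote
    selection coefficient; both must be non-negative (heterozygote
    fittest) and not both zero.  If bootstrap draws of (s_major, s_het,
    s_minor) are supplied, a percentile CI is propagated.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError(
            "equilibrium frequency requires the heterozygote to be fittest "
            "(s1, s2 >= 0)"
        )
    if s1 == 0 and s2 == 0:
        raise ValueError("s1 = s2 = 0: equilibrium frequency undefined")
    q = s1 / (s1 + s2)
    ci = None
    if boot_s is not None:
        b1, b2 = boot_s[:, 0], boot_s[:, 2]
        ok = np.isfinite(b1) & np.isfinite(b2) & ((b1 + b2) > 0)
        if ok.sum() >= 10:
            draws = b1[ok] / (b1[ok] + b2[ok])
            ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    return float(q), ci


def _yearly_frequencies(
    dosage_by_id: pd.Series, membership: dict[int, list[str]]
) -> pd.Series:
    out = {}
    for year, ids in membership.items():
        d = dosage_by_id.reindex(ids).dropna()
        if len(d):
            out[year] = float(d.mean() / 2.0)
    return pd.Series(out).sort_index()


def allele_trend_test(
    pedigree: pd.DataFrame,
    dosage_by_id: pd.Series,
    membership: dict[int, list[str]] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> dict:
    """Observed allele-frequency trend vs a gene-drop drift null.

    ``dosage_by_id`` maps individual id to minor-allele dosage (NaN for
    ungenotyped); ``membership`` maps year to the ids counted in that
    year's frequency (default: everyone alive by birth/death year).
    Founders keep their observed genotypes (missing founders draw from
    the observed founder frequency); descendants are re-dropped by
    Mendelian sampling; the same yearly membership is reused.  One-tailed
    P is taken in the direction of the observed slope; both tails are
    reported.  Deterministic given ``seed``.
    """
    ped = pedigree.reset_index(drop=True)
    if membership is None:
        if "death_year" not in ped.columns:
            raise ValueError("membership or a death_year column is required")
        membership = {
            int(y): list(
                ped.loc[
                    (ped["birth_year"] <= y) & (ped["death_year"] >= y), "id"
                ]
            )
            for y in range(int(ped["birth_year"].min()), int(ped["death_year"].max()) + 1)
        }
    obs_freq = _yearly_frequencies(dosage_by_id, membership)
    if len(obs_freq) < 3:
        raise ValueError("need at least 3 years of frequency data")
    reg = stats.linregress(obs_freq.index.to_numpy(float), obs_freq.to_numpy())
    b_obs, r2, p_reg = float(reg.slope), float(reg.rvalue**2), float(reg.pvalue)

    rng = np.random.default_rng(seed)
    order = ped.sort_values("birth_year").index.to_numpy()
    idx = {iid: i for i, iid in enumerate(ped["id"])}
    n = len(ped)
    obs_dos = dosage_by_id.reindex(ped["id"]).to_numpy(dtype=float)
    founders = ped["sire"].isna() | ped["dam"].isna()
    founder_obs = obs_dos[founders.to_numpy()]
    founder_p = (
        np.nanmean(founder_obs) / 2.0 if np.isfinite(founder_obs).any() else np.nan
    )

    G = np.empty((n, n_reps))
    for i in order:
        if founders.iloc[i]:
            g = obs_dos[i]
            if np.isfinite(g):
                G[i] = g
            else:
                G[i] = rng.binomial(2, founder_p, n_reps)
        else:
            gs = G[idx[ped.at[i, "sire"]]]
            gd = G[idx[ped.at[i, "dam"]]]
            # one allele per parent; ints, not bools (bool + bool is OR)
            G[i] = (rng.random(n_reps) < gs / 2.0).astype(np.int8) + (
                rng.random(n_reps) < gd / 2.0
            ).astype(np.int8)

    years = obs_freq.index.to_numpy(float)
    sim_freq = np.empty((len(years), n_reps))
    genotyped = np.isfinite(obs_dos)
    for t, y in enumerate(obs_freq.index):
        rows = [idx[i] for i in membership[int(y)] if genotyped[idx[i]]]
        sim_freq[t] = G[rows].mean(axis=0) / 2.0
    yc = years - years.mean()
    slopes = yc @ (sim_freq - sim_freq.mean(axis=0)) / (yc @ yc)

    p_up = float(np.mean(slopes >= b_obs))
    p_down = float(np.mean(slopes <= b_obs))
    return {
        "slope": b_obs,
        "r2": r2,
        "p_regression": p_reg,
        "p_genedrop": p_up if b_obs >= 0 else p_down,
        "p_genedrop_up": p_up,
        "p_genedrop_down": p_down,
        "sim_slopes": slopes,
        "yearly_freq": obs_freq,
    }


def genotype_fitness_glm(
    data: pd.DataFrame,
    measure: str,
    covariates: list[str] = (),
):
    """Frequentist genotype-contrast GLM for a fitness measure.

    A validation-only stand-in (Poisson for counts, binomial for AS) with
    genotype as a three-level factor plus fixed covariates; random terms
    of the full hierarchical treatment are collapsed to fixed year and
    maternal covariates, so estimates are not equivalent to a mixed or
    hierarchical Bayesian analysis.
    """
    import statsmodels.formula.api as smf

    fam_mod = "Binomial" if measure == "AS" else "Poisson"
    import statsmodels.api as sm

    family = getattr(sm.families, fam_mod)()
    rhs = " + ".join(["C(genotype)"] + list(covariates)) or "1"
    model = smf.glm(f"{measure} ~ {rhs}", data=data, family=family)
    return model.fit()
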