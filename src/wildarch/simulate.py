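"""Forward simulation of a SNP-typed pedigreed population.

Generates the statistical structure the downstream analyses assume: a
multi-year pedigree with overlapping generations, phased founder
haplotypes built as mosaics of a small ancestral haplotype pool (so LD
decays with physical distance), Mendelian transmission with Poisson
crossovers on a uniform 1 cM/Mb map, a polygenic trait whose
per-chromosome variance is proportional to chromosome length plus
optional planted QTLs, fitness records (annual survival and
recruitment), and an admixture scenario in which a donor breed's
haplotypes entered the focal population a configurable number of
generations ago.

LD arises mechanistically: founders share ancestral haplotype blocks and
descendants inherit recombinant mosaics of them, so identity by descent
— not a parametric correlation model — drives relatedness downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeSet, PhasedPanel

__all__ = [
    "QtlSpec",
    "SimConfig",
    "SimPopulation",
    "simulate_population",
    "simulate_trait_and_phenotypes",
    "simulate_fitness_records",
    "simulate_breed_panel",
    "default_chromosomes",
]


@dataclass
class QtlSpec:
    """A planted quantitative-trait locus.

    ``additive_effect`` is in trait units per copy of the minor allele;
    ``fitness_mode`` is one of ``neutral``, ``additive``, ``overdominant``;
    ``fitness_effect`` multiplies survival probability and fecundity weight
    (per minor-allele copy in additive mode, for heterozygotes in
    overdominant mode).  ``donor_only`` restricts the minor allele to
    donor-derived haplotypes in an admixture scenario.
    """

    chromosome: int
    target_maf: float = 0.05
    additive_effect: float = 0.0
    dominance_effect: float = 0.0
    fitness_mode: str = "neutral"
    fitness_effect: float = 0.0
    donor_only: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.target_maf <= 0.5:
            raise ValueError(f"target_maf must be in (0, 0.5], got {self.target_maf}")
        if self.fitness_mode not in ("neutral", "additive", "overdominant"):
            raise ValueError(f"unknown fitness_mode {self.fitness_mode!r}")

    def multiplier(self, dosage: np.ndarray) -> np.ndarray:
        """Relative fitness per individual given minor-allele dosage."""
        if self.fitness_mode == "neutral" or self.fitness_effect == 0.0:
            return np.ones_like(dosage, dtype=float)
        if self.fitness_mode == "additive":
            return np.clip(1.0 + self.fitness_effect * dosage, 0.01, None)
        return np.where(dosage == 1, 1.0 + self.fitness_effect, 1.0).clip(0.01)


def default_chromosomes(n: int = 5, snps: int = 400, length_mb: float = 80.0):
    """A small genome: n equal chromosomes of ``snps`` SNPs each."""
    return [(snps, length_mb)] * n


@dataclass
class SimConfig:
    """Study-design knobs for the simulated population.

    Defaults emulate a scaled-down version of the long-term sheep study:
    repeated adult measures (about 2.8 per measured individual, mirroring
    roughly 2550 measures on 900 sheep), birth-year / year-of-measurement /
    permanent-environment random effects, a polygenic heritability of 0.4
    on a unit phenotypic scale, and a folded MAF spectrum on (0.05, 0.5).
    Variance shares must sum to 1; planted QTL variance rides on top.
    """

    n_founders: int = 100
    n_years: int = 15
    chromosomes: list = field(default_factory=default_chromosomes)
    maf_range: tuple = (0.05, 0.5)
    recomb_rate: float = 0.01  # expected crossovers per Mb per meiosis (1 cM/Mb)
    qtl_specs: list = field(default_factory=list)
    polygenic_h2: float = 0.4
    random_effect_variances: dict = field(
        default_factory=lambda: {
            "birth_year": 0.05,
            "year_of_measurement": 0.05,
            "permanent_environment": 0.1,
            "residual": 0.4,
        }
    )
    repeat_rate: float = 2.8
    admixture: tuple = (0, 0.0)  # (donor_generations, donor_proportion)
    seed: int = 0
    # demography / mechanism details
    survival_rate: float = 0.72
    n_ancestral: int = 12
    ancestral_switch_per_mb: float = 0.2
    sex_effect: float = 1.0
    age_effect: float = 0.15
    missing_rate: float = 0.0
    complete_turnover: bool = False  # non-overlapping generations if True

    def __post_init__(self) -> None:
        if self.n_founders < 4:
            raise ValueError("n_founders: need at least 4 founders")
        if self.n_years < 1:
            raise ValueError("n_years: must be >= 1")
        for snp_count, length in self.chromosomes:
            if snp_count < 1:
                raise ValueError("chromosomes: snp_count per chromosome must be >= 1")
            if length <= 0:
                raise ValueError("chromosomes: length_Mb must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(
                f"maf_range: must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}"
            )
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate: must be non-negative")
        if not 0.0 <= self.polygenic_h2 <= 1.0:
            raise ValueError("polygenic_h2: must be in [0, 1]")
        total = self.polygenic_h2 + sum(self.random_effect_variances.values())
        if total > 1.0 + 1e-8:
            raise ValueError(
                f"random_effect_variances: variance shares sum to {total:.3f} > 1"
            )
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                "random_effect_variances: polygenic_h2 + noise shares must sum "
                f"to 1 on the phenotypic scale, got {total:.3f}"
            )
        g, p = self.admixture
        if not 0.0 <= p <= 1.0:
            raise ValueError("admixture: donor_proportion must be in [0, 1]")
        if g < 0:
            raise ValueError("admixture: donor_generations must be >= 0")
        if any(q.donor_only for q in self.qtl_specs) and p == 0.0:
            raise ValueError(
                "qtl_specs: a donor-only QTL allele requires donor_proportion > 0"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate: must be in [0, 1)")
        if self.repeat_rate < 1:
            raise ValueError("repeat_rate: mean measures per individual must be >= 1")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# founder haplotypes


def _build_snp_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c, (m, length) in enumerate(config.chromosomes, start=1):
        # sorted distinct uniform positions without materialising the range
        bp = np.sort(rng.integers(1, int(length * 1e6) - m, size=m)) + np.arange(m)
        for j, pos in enumerate(bp):
            rows.append((f"c{c}s{j + 1}", str(c), int(pos), "A", "G"))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "bp", "a1", "a2"])


def _ancestral_pool(
    config: SimConfig, snp_map: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """K ancestral haplotypes with target frequencies drawn from maf_range.

    Allele assignments are autocorrelated along each chromosome so nearby
    SNPs tend to segregate on the same ancestral backgrounds.
    """
    K = config.n_ancestral
    lo, hi = config.maf_range
    pool = np.zeros((K, len(snp_map)), dtype=np.int8)
    for _, sub in snp_map.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        bp = sub["bp"].to_numpy()
        p = rng.uniform(lo, hi, size=len(idx))
        counts = np.clip(np.round(K * p).astype(int), 1, K - 1)
        current = np.zeros(K, dtype=np.int8)
        current[rng.choice(K, size=counts[0], replace=False)] = 1
        pool[:, idx[0]] = current
        for t in range(1, len(idx)):
            d_mb = (bp[t] - bp[t - 1]) / 1e6
            r = 1.0 - np.exp(-config.ancestral_switch_per_mb * d_mb)
            current = current.copy()
            refresh = rng.random(K) < r
            current[refresh] = rng.random(int(refresh.sum())) < p[t]
            diff = counts[t] - int(current.sum())
            if diff > 0:
                zeros = np.flatnonzero(current == 0)
                current[rng.choice(zeros, size=diff, replace=False)] = 1
            elif diff < 0:
                ones = np.flatnonzero(current == 1)
                current[rng.choice(ones, size=-diff, replace=False)] = 0
            pool[:, idx[t]] = current
    return pool


def _mosaic_haplotypes(
    n_hap: int,
    pool: np.ndarray,
    snp_map: pd.DataFrame,
    switch_per_mb: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw haplotypes as block mosaics of an ancestral pool."""
    K = pool.shape[0]
    haps = np.zeros((n_hap, len(snp_map)), dtype=np.int8)
    for _, sub in snp_map.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        bp = sub["bp"].to_numpy()
        switch_p = 1.0 - np.exp(-switch_per_mb * np.diff(bp) / 1e6)
        # ancestor index path per haplotype, vectorized over haplotypes
        switches = rng.random((n_hap, len(idx) - 1)) < switch_p
        draws = rng.integers(0, K, size=(n_hap, len(idx)))
        anc = np.empty((n_hap, len(idx)), dtype=np.int64)
        anc[:, 0] = draws[:, 0]
        for t in range(1, len(idx)):
            anc[:, t] = np.where(switches[:, t - 1], draws[:, t], anc[:, t - 1])
        haps[:, idx] = pool[anc, idx]
    return haps


def _clamp_founder_freqs(
    haps: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> None:
    """Flip alleles on random haplotypes so realized founder minor-allele
    frequencies land inside maf_range."""
    n_hap = haps.shape[0]
    lo, hi = config.maf_range
    lo_c = int(np.ceil(lo * n_hap))
    hi_c = int(np.floor(hi * n_hap))
    counts = haps.sum(axis=0)
    for j in range(haps.shape[1]):
        c = int(counts[j])
        minor_is_one = c <= n_hap - c
        mc = c if minor_is_one else n_hap - c
        target = min(max(mc, lo_c), hi_c)
        diff = target - mc
        if diff == 0:
            continue
        minor_val = 1 if minor_is_one else 0
        if diff > 0:
            cand = np.flatnonzero(haps[:, j] != minor_val)
            haps[cand[rng.choice(len(cand), size=diff, replace=False)], j] = minor_val
        else:
            cand = np.flatnonzero(haps[:, j] == minor_val)
            haps[cand[rng.choice(len(cand), size=-diff, replace=False)], j] = 1 - minor_val


def _set_founder_freq(
    haps: np.ndarray, j: int, target_count: int, rng: np.random.Generator
) -> None:
    """Force the '1'-allele count at SNP j to target_count exactly."""
    c = int(haps[:, j].sum())
    diff = target_count - c
    if diff > 0:
        cand = np.flatnonzero(haps[:, j] == 0)
        haps[cand[rng.choice(len(cand), size=diff, replace=False)], j] = 1
    elif diff < 0:
        cand = np.flatnonzero(haps[:, j] == 1)
        haps[cand[rng.choice(len(cand), size=-diff, replace=False)], j] = 0


# ---------------------------------------------------------------------------
# meiosis


def _snp_map_arrays(snp_map: pd.DataFrame, chromosomes) -> tuple:
    slices, lengths = [], []
    start = 0
    for (m, length_mb) in chromosomes:
        slices.append((start, start + m))
        lengths.append(int(length_mb * 1e6))
        start += m
    return slices, lengths, snp_map["bp"].to_numpy()


def _gamete_mask(arrays, recomb_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Which of the two parental haplotypes each SNP is copied from.

    Per chromosome: Poisson(recomb_rate * length_Mb) crossovers at uniform
    bp positions, no interference, random starting strand.
    """
    chrom_slices, chrom_lengths_bp, bp = arrays
    use_a = np.empty(len(bp), dtype=bool)
    for (start, stop), length_bp in zip(chrom_slices, chrom_lengths_bp):
        n_x = rng.poisson(recomb_rate * length_bp / 1e6)
        state = bool(rng.integers(2))
        if n_x == 0:
            use_a[start:stop] = state
            continue
        cuts = np.sort(rng.integers(1, length_bp, size=n_x))
        n_before = np.searchsorted(cuts, bp[start:stop], side="right")
        use_a[start:stop] = (n_before % 2 == 0) == state
    return use_a


# ---------------------------------------------------------------------------
# population container


@dataclass
class SimPopulation:
    """All state produced by :func:`simulate_population`."""

    pedigree: pd.DataFrame  # id, sire, dam, sex, birth_year, death_year
    haplotypes: np.ndarray  # (2n, m) int8, rows 2i/2i+1 for individual i
    ancestry: np.ndarray | None  # donor-origin flags, same shape; None if no admixture
    snp_map: pd.DataFrame
    survival: pd.DataFrame  # id, year, survived (one row per study year alive)
    qtl_indices: list  # SNP column per QtlSpec
    config: SimConfig
    donor_pool: np.ndarray | None = None
    base_pool: np.ndarray | None = None

    @property
    def ids(self) -> list[str]:
        return list(self.pedigree["id"])

    def dosages(self) -> np.ndarray:
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(float)

    def genotype_set(self, rng: np.random.Generator | None = None) -> GenotypeSet:
        dos = self.dosages()
        if self.config.missing_rate > 0:
            rng = rng or np.random.default_rng(self.config.seed + 7)
            mask = rng.random(dos.shape) < self.config.missing_rate
            dos = dos.copy()
            dos[mask] = np.nan
        return GenotypeSet(dos, self.snp_map.copy(), self.ids)

    def phased_panel(self, label: str = "focal") -> PhasedPanel:
        return PhasedPanel(
            self.haplotypes.copy(), self.snp_map.copy(), self.ids, [label] * len(self.ids)
        )

    def qtl_dosage(self, k: int = 0) -> np.ndarray:
        j = self.qtl_indices[k]
        return (self.haplotypes[0::2, j] + self.haplotypes[1::2, j]).astype(float)

    def alive_in_year(self, year: int) -> np.ndarray:
        ped = self.pedigree
        return ((ped["birth_year"] <= year) & (ped["death_year"] >= year)).to_numpy()


# ---------------------------------------------------------------------------
# main simulation


def simulate_population(config: SimConfig) -> SimPopulation:
    """Simulate founders, yearly survival/reproduction, and transmission.

    Deterministic given ``config.seed``.  If ``config.admixture`` sets a
    positive donor proportion, donor immigrants join the breeding pool
    ``donor_generations`` years before the end and genome-wide donor
    ancestry is tracked per SNP, transmitted with the same crossovers as
    the alleles.
    """
    rng = np.random.default_rng(config.seed)
    snp_map = _build_snp_map(config, rng)
    arrays = _snp_map_arrays(snp_map, config.chromosomes)
    m = len(snp_map)

    base_pool = _ancestral_pool(config, snp_map, rng)
    donor_gens, donor_prop = config.admixture
    track_ancestry = donor_prop > 0
    donor_pool = None
    donor_only_cols: list[int] = []

    founder_haps = _mosaic_haplotypes(
        2 * config.n_founders, base_pool, snp_map, config.ancestral_switch_per_mb, rng
    )
    _clamp_founder_freqs(founder_haps, config, rng)

    # plant QTLs at the nearest-to-target-MAF SNP on the requested chromosome
    qtl_indices: list[int] = []
    freqs = founder_haps.mean(axis=0)
    folded = np.minimum(freqs, 1 - freqs)
    for spec in config.qtl_specs:
        on_chrom = np.flatnonzero((snp_map["chrom"] == str(spec.chromosome)).to_numpy())
        if len(on_chrom) == 0:
            raise ValueError(f"qtl_specs: no SNPs on chromosome {spec.chromosome}")
        if len(on_chrom) > 20:  # keep flanking SNPs available around the QTL
            on_chrom = on_chrom[5:-5]
        j = int(on_chrom[np.argmin(np.abs(folded[on_chrom] - spec.target_maf))])
        qtl_indices.append(j)
        n_hap = founder_haps.shape[0]
        if spec.donor_only:
            _set_founder_freq(founder_haps, j, 0, rng)
            donor_only_cols.append(j)
        else:
            _set_founder_freq(
                founder_haps, j, max(1, int(round(spec.target_maf * n_hap))), rng
            )

    if track_ancestry:
        # donor breed: same ancestral pool plus private variation; a
        # donor-only allele sits on ONE donor ancestral background so every
        # carrier descends from a single young haplotype
        donor_pool = base_pool.copy()
        refresh = rng.random(donor_pool.shape) < 0.25
        donor_pool[refresh] = (rng.random(int(refresh.sum())) < 0.3).astype(np.int8)
        for spec, j in zip(config.qtl_specs, qtl_indices):
            if spec.donor_only:
                donor_pool[:, j] = 0
                donor_pool[rng.integers(donor_pool.shape[0]), j] = 1

    # preallocated growth arrays
    cap = config.n_founders * (3 + config.n_years)
    haps = np.zeros((2 * cap, m), dtype=np.int8)
    anc = np.zeros((2 * cap, m), dtype=np.int8) if track_ancestry else None
    haps[: 2 * config.n_founders] = founder_haps

    ids = [f"I{i + 1:05d}" for i in range(config.n_founders)]
    sire: list = [None] * config.n_founders
    dam: list = [None] * config.n_founders
    sex = list(np.array(["F", "M"])[rng.permutation(config.n_founders) % 2])
    birth = np.zeros(cap, dtype=int)
    death = np.full(cap, config.n_years, dtype=int)
    alive = np.zeros(cap, dtype=bool)
    alive[: config.n_founders] = True
    n_ind = config.n_founders
    survival_rows: list = []

    adm_year = max(1, config.n_years - donor_gens) if track_ancestry else None

    def qtl_multiplier(upto: int) -> np.ndarray:
        mult = np.ones(upto)
        for spec, j in zip(config.qtl_specs, qtl_indices):
            dos = (haps[0: 2 * upto: 2, j] + haps[1: 2 * upto: 2, j]).astype(float)
            mult *= spec.multiplier(dos)
        return mult

    for year in range(1, config.n_years + 1):
        if adm_year is not None and year == adm_year:
            n_alive = int(alive[:n_ind].sum())
            n_imm = max(2, int(round(donor_prop / max(1e-9, 1 - donor_prop) * n_alive)))
            imm = _draw_donor_haplotypes(
                2 * n_imm, donor_pool, snp_map, config, donor_only_cols, rng
            )
            haps[2 * n_ind: 2 * (n_ind + n_imm)] = imm
            anc[2 * n_ind: 2 * (n_ind + n_imm)] = 1
            for k in range(n_imm):
                ids.append(f"I{n_ind + k + 1:05d}")
                sire.append(None)
                dam.append(None)
                sex.append("F" if k % 2 else "M")
            birth[n_ind: n_ind + n_imm] = year - 1
            alive[n_ind: n_ind + n_imm] = True
            n_ind += n_imm

        mult = qtl_multiplier(n_ind)
        sex_arr = np.array(sex)
        can_breed = alive[:n_ind] & (birth[:n_ind] < year)
        dams = np.flatnonzero(can_breed & (sex_arr == "F"))
        sires = np.flatnonzero(can_breed & (sex_arr == "M"))

        if config.complete_turnover:
            n_births = config.n_founders
        else:
            surv_p = np.clip(config.survival_rate * mult, 0.0, 1.0)
            n_births = int(round((alive[:n_ind] * (1 - surv_p)).sum()))
        if len(dams) == 0 or len(sires) == 0:
            n_births = 0
        n_births = min(n_births, 2 * len(dams), cap - n_ind)

        if n_births:
            dam_pick = rng.choice(dams, size=n_births, p=mult[dams] / mult[dams].sum())
            sire_pick = rng.choice(sires, size=n_births, p=mult[sires] / mult[sires].sum())
            for b in range(n_births):
                di, si = int(dam_pick[b]), int(sire_pick[b])
                i = n_ind
                mask_d = _gamete_mask(arrays, config.recomb_rate, rng)
                mask_s = _gamete_mask(arrays, config.recomb_rate, rng)
                haps[2 * i] = np.where(mask_d, haps[2 * di], haps[2 * di + 1])
                haps[2 * i + 1] = np.where(mask_s, haps[2 * si], haps[2 * si + 1])
                if track_ancestry:
                    anc[2 * i] = np.where(mask_d, anc[2 * di], anc[2 * di + 1])
                    anc[2 * i + 1] = np.where(mask_s, anc[2 * si], anc[2 * si + 1])
                ids.append(f"I{i + 1:05d}")
                sire.append(ids[si])
                dam.append(ids[di])
                sex.append("F" if rng.random() < 0.5 else "M")
                birth[i] = year
                alive[i] = True
                n_ind += 1

        # survival past the end of the year
        mult = qtl_multiplier(n_ind)
        if config.complete_turnover:
            surv_p = np.where(birth[:n_ind] == year, 1.0, 0.0)
        else:
            surv_p = np.clip(config.survival_rate * mult, 0.0, 1.0)
        survived = rng.random(n_ind) < surv_p
        if year == config.n_years:
            # final census: everyone alive at the start of the last year
            # is observed; survival flags still recorded
            pass
        for i in np.flatnonzero(alive[:n_ind]):
            survival_rows.append([ids[i], year, bool(survived[i])])
        dies = alive[:n_ind] & ~survived
        death[:n_ind][dies] = year
        alive[:n_ind] &= survived
        if alive[:n_ind].sum() < 4 and year < config.n_years:
            dead_now = np.flatnonzero(dies)
            revive = rng.choice(dead_now, size=min(4, len(dead_now)), replace=False)
            alive[revive] = True
            death[revive] = config.n_years

    ped = pd.DataFrame(
        {
            "id": ids,
            "sire": sire,
            "dam": dam,
            "sex": sex,
            "birth_year": birth[:n_ind],
            "death_year": death[:n_ind],
        }
    )
    surv = pd.DataFrame(survival_rows, columns=["id", "year", "survived"])
    return SimPopulation(
        ped,
        haps[: 2 * n_ind],
        anc[: 2 * n_ind] if track_ancestry else None,
        snp_map,
        surv,
        qtl_indices,
        config,
        donor_pool,
        base_pool,
    )


def _draw_donor_haplotypes(
    n_hap, donor_pool, snp_map, config, donor_only_cols, rng
) -> np.ndarray:
    haps = _mosaic_haplotypes(
        n_hap, donor_pool, snp_map, config.ancestral_switch_per_mb, rng
    )
    # the donor-only allele segregates at moderate frequency in the donor
    # breed (the introgressed haplotype is common there); its carriers copy
    # the single carrier ancestral background across the whole chromosome
    for j in donor_only_cols:
        carrier = int(np.flatnonzero(donor_pool[:, j] == 1)[0])
        chrom = snp_map.loc[j, "chrom"]
        on_chrom = np.flatnonzero((snp_map["chrom"] == chrom).to_numpy())
        n_carriers = max(2, int(round(0.3 * n_hap)))
        rows = rng.choice(n_hap, size=n_carriers, replace=False)
        haps[np.ix_(rows, on_chrom)] = donor_pool[carrier, on_chrom]
    return haps


# ---------------------------------------------------------------------------
# phenotypes


def simulate_trait_and_phenotypes(
    pop: SimPopulation, config: SimConfig | None = None
) -> pd.DataFrame:
    """Phenotype table with repeated measures.

    Breeding value = planted QTL effects + a polygenic score whose
    per-chromosome variance is proportional to chromosome length and whose
    realized total variance equals ``polygenic_h2`` (unit phenotypic
    scale).  Adds birth-year, year-of-measurement, permanent-environment
    and residual deviations plus sex and age fixed effects.  Ground truth
    is attached in ``.attrs["truth"]``.
    """
    config = config or pop.config
    rng = np.random.default_rng(config.seed + 1)
    ped = pop.pedigree
    n = len(ped)
    dos = pop.dosages()

    lengths = np.array([l for _, l in config.chromosomes], dtype=float)
    shares = lengths / lengths.sum()
    slices = _snp_map_arrays(pop.snp_map, config.chromosomes)[0]
    bv = np.zeros(n)
    if config.polygenic_h2 > 0:
        for sl, v_target in zip(slices, config.polygenic_h2 * shares):
            X = dos[:, sl[0]: sl[1]]
            p = X.mean(axis=0) / 2.0
            poly = (p > 0) & (p < 1)
            # standardized-SNP effect model: effect variance scales with
            # 1/(2pq), the spectrum assumed by frequency-weighted GRMs
            Z = (X[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
            beta = rng.normal(size=int(poly.sum()))
            g = Z @ beta
            sd = g.std()
            if sd > 0:
                bv += g * np.sqrt(v_target) / sd
        # relatedness correlates per-chromosome scores; rescale the total so
        # the realized polygenic variance hits the configured share exactly
        sd_tot = bv.std()
        if sd_tot > 0:
            bv *= np.sqrt(config.polygenic_h2) / sd_tot
    for spec, j in zip(config.qtl_specs, pop.qtl_indices):
        x = dos[:, j]
        if x.mean() / 2 > 0.5:  # orient the effect on the minor allele
            x = 2 - x
        bv += spec.additive_effect * x + spec.dominance_effect * (x == 1)

    v = config.random_effect_variances
    years = np.arange(0, config.n_years + 1)
    by_eff = dict(zip(years, rng.normal(0, np.sqrt(v.get("birth_year", 0)), len(years))))
    yr_eff = dict(
        zip(years, rng.normal(0, np.sqrt(v.get("year_of_measurement", 0)), len(years)))
    )
    pe_eff = rng.normal(0, np.sqrt(v.get("permanent_environment", 0)), n)
    sd_res = np.sqrt(v.get("residual", 0))

    # measurement years: adult (age >= 1) years alive, sampled so the mean
    # number of repeats approximates repeat_rate; at least one measure
    birth = ped["birth_year"].to_numpy()
    deathv = ped["death_year"].to_numpy()
    avail = [list(range(int(birth[i]) + 1, int(deathv[i]) + 1)) for i in range(n)]
    lens = [len(a) for a in avail if a]
    mean_avail = float(np.mean(lens)) if lens else 1.0
    p_measure = min(1.0, config.repeat_rate / max(mean_avail, 1e-9))
    rows = []
    sexes = ped["sex"].to_numpy()
    id_arr = ped["id"].to_numpy()
    for i in range(n):
        if not avail[i]:
            continue
        chosen = [y for y in avail[i] if rng.random() < p_measure] or [avail[i][0]]
        for y in chosen:
            age = y - birth[i]
            val = (
                10.0
                + (config.sex_effect if sexes[i] == "M" else 0.0)
                + config.age_effect * min(age, 6)
                + bv[i]
                + by_eff[birth[i]]
                + yr_eff[y]
                + pe_eff[i]
                + rng.normal(0, sd_res)
            )
            rows.append([id_arr[i], val, sexes[i], int(age), int(y), int(birth[i])])
    df = pd.DataFrame(rows, columns=["id", "trait", "sex", "age", "year", "birth_year"])
    df.attrs["truth"] = {
        "breeding_value": dict(zip(id_arr, bv)),
        "polygenic_h2": config.polygenic_h2,
        "pe": dict(zip(id_arr, pe_eff)),
    }
    return df


# ---------------------------------------------------------------------------
# fitness records


def simulate_fitness_records(
    pop: SimPopulation, config: SimConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Raw fitness tables realized by the demography.

    Returns ``survival`` (id, year, survived — one row per study year), an
    ``offspring`` table (id, sire, dam, birth_year, recruited) and the
    generator's own per-individual ``truth`` table (LBS, LR) for
    round-trip checks.  Selection acted during the forward simulation via
    the QTL fitness modes, so genotype differences are already embodied in
    these records.
    """
    config = config or pop.config
    ped = pop.pedigree
    surv = pop.survival.copy()
    surv_by = surv.set_index(["id", "year"])["survived"]
    recruited = {
        r.id: bool(surv_by.get((r.id, r.birth_year), False))
        for r in ped.itertuples()
    }
    offspring = ped.dropna(subset=["sire", "dam"])[
        ["id", "sire", "dam", "birth_year"]
    ].copy()
    offspring["recruited"] = offspring["id"].map(recruited)

    lbs = dict.fromkeys(ped["id"], 0)
    lr = dict.fromkeys(ped["id"], 0)
    for r in offspring.itertuples():
        for parent in (r.sire, r.dam):
            lbs[parent] += 1
            lr[parent] += int(r.recruited)
    truth = pd.DataFrame(
        {
            "id": list(ped["id"]),
            "sex": list(ped["sex"]),
            "LBS": [lbs[i] for i in ped["id"]],
            "LR": [lr[i] for i in ped["id"]],
        }
    )
    return {"survival": surv, "offspring": offspring, "truth": truth}


# ---------------------------------------------------------------------------
# breed panels


def simulate_breed_panel(
    pop: SimPopulation,
    config: SimConfig | None = None,
    n_outgroups: int = 2,
    panel_size: int = 25,
    outgroup_divergence: float = 5.0,
) -> PhasedPanel:
    """Phased panels for the focal population, the donor breed and outgroups.

    The focal panel holds final-year individuals (admixture already in
    their genomes); the donor panel is drawn from the donor breed's
    haplotype distribution; outgroup breeds derive from the same ancestral
    pool but with ``outgroup_divergence``-fold shorter shared blocks, so
    they carry the same old haplotypes broken into shorter tracts.
    """
    config = config or pop.config
    if pop.donor_pool is None:
        raise ValueError("population was simulated without admixture; no donor breed")
    rng = np.random.default_rng(config.seed + 5)

    alive = pop.alive_in_year(config.n_years)
    focal_idx = np.flatnonzero(alive)
    if len(focal_idx) > panel_size * 2:
        focal_idx = np.sort(rng.choice(focal_idx, size=panel_size * 2, replace=False))
    rows = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in focal_idx]))
    hap_blocks = [pop.haplotypes[rows]]
    ids = [pop.pedigree.at[i, "id"] for i in focal_idx]
    labels = ["focal"] * len(focal_idx)

    donor_only_cols = [
        j for spec, j in zip(config.qtl_specs, pop.qtl_indices) if spec.donor_only
    ]
    donor = _draw_donor_haplotypes(
        2 * panel_size, pop.donor_pool, pop.snp_map, config, donor_only_cols, rng
    )
    hap_blocks.append(donor)
    ids += [f"D{k + 1:04d}" for k in range(panel_size)]
    labels += ["donor"] * panel_size

    mixed_pool = np.vstack([pop.base_pool, pop.donor_pool])
    for g in range(n_outgroups):
        out = _mosaic_haplotypes(
            2 * panel_size,
            mixed_pool,
            pop.snp_map,
            config.ancestral_switch_per_mb * outgroup_divergence,
            rng,
        )
        hap_blocks.append(out)
        ids += [f"O{g + 1}{k + 1:03d}" for k in range(panel_size)]
        labels += [f"outgroup_{g + 1}"] * panel_size

    return PhasedPanel(np.vstack(hap_blocks), pop.snp_map.copy(), ids, labels)
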