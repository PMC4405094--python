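"""The forward simulator: Mendelian transmission, LD, trait calibration,
fitness modes and the admixture scenario."""

import numpy as np
import pandas as pd
import pytest

import wildarch.simulate as sim
from wildarch.simulate import QtlSpec, SimConfig


def _trio_rows(pop):
    idx = {iid: i for i, iid in enumerate(pop.pedigree["id"])}
    for r in pop.pedigree.dropna(subset=["sire"]).itertuples():
        yield idx[r.id], idx[r.sire], idx[r.dam]


class TestTransmission:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_founders=30, n_years=5, chromosomes=[(40, 20.0)], seed=3)
        a, b = sim.simulate_population(cfg), sim.simulate_population(cfg)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.pedigree.equals(b.pedigree)
        assert a.snp_map.equals(b.snp_map)

    def test_no_recombination_copies_whole_parental_chromosome(self):
        cfg = SimConfig(
            n_founders=20, n_years=4, chromosomes=[(50, 30.0)], recomb_rate=0.0, seed=4
        )
        pop = sim.simulate_population(cfg)
        H = pop.haplotypes
        for i, si, di in _trio_rows(pop):
            assert np.array_equal(H[2 * i], H[2 * di]) or np.array_equal(
                H[2 * i], H[2 * di + 1]
            )
            assert np.array_equal(H[2 * i + 1], H[2 * si]) or np.array_equal(
                H[2 * i + 1], H[2 * si + 1]
            )

    def test_offspring_consistent_with_parental_haplotypes(self, small_pop):
        H = small_pop.haplotypes
        for i, si, di in _trio_rows(small_pop):
            assert np.all((H[2 * i] == H[2 * di]) | (H[2 * i] == H[2 * di + 1]))
            assert np.all(
                (H[2 * i + 1] == H[2 * si]) | (H[2 * i + 1] == H[2 * si + 1])
            )

    def test_heterozygous_transmission_is_fair(self):
        """Pooled transmission ratio at a planted locus is 1/2 (Mendelian law)."""
        tot = n1 = 0
        for seed in range(12):
            cfg = SimConfig(
                n_founders=80, n_years=8, chromosomes=[(40, 30.0)], seed=seed,
                qtl_specs=[QtlSpec(1, target_maf=0.3)],
            )
            pop = sim.simulate_population(cfg)
            H, j = pop.haplotypes, pop.qtl_indices[0]
            for i, si, di in _trio_rows(pop):
                for child_hap, p in ((2 * i, di), (2 * i + 1, si)):
                    if H[2 * p, j] != H[2 * p + 1, j]:
                        tot += 1
                        n1 += int(H[child_hap, j] == 1)
        # binomial(1/2) with ~thousands of trials: 4 sigma band
        assert abs(n1 / tot - 0.5) < 2.0 / np.sqrt(tot)

    def test_founder_minor_allele_frequencies_inside_range(self, small_pop):
        ped = small_pop.pedigree
        founders = (ped["sire"].isna() & (ped["birth_year"] == 0)).to_numpy()
        rows = np.repeat(founders, 2)
        f = small_pop.haplotypes[rows].mean(axis=0)
        maf = np.minimum(f, 1 - f)
        lo, hi = small_pop.config.maf_range
        assert maf.min() >= lo - 1e-12 and maf.max() <= hi + 1e-12

    def test_adjacent_ld_decays_with_distance(self):
        cfg = SimConfig(
            n_founders=150, n_years=8, chromosomes=[(250, 80.0)] * 2, seed=17
        )
        pop = sim.simulate_population(cfg)
        X = pop.dosages()
        sm = pop.snp_map
        r2s, dists = [], []
        for chrom, sub in sm.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            for a, b in zip(idx[:-1], idx[1:]):
                # brute-force r^2 by definition
                r = np.corrcoef(X[:, a], X[:, b])[0, 1]
                r2s.append(r * r)
                dists.append(sm.at[b, "bp"] - sm.at[a, "bp"])
        r2s, dists = np.array(r2s), np.array(dists)
        qs = np.quantile(dists, [0.25, 0.5, 0.75])
        bins = np.digitize(dists, qs)
        means = [r2s[bins == k].mean() for k in range(4)]
        assert means[0] > means[-1]  # near pairs in stronger LD than far pairs
        assert np.corrcoef(np.arange(4), means)[0, 1] < 0


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw, field",
        [
            ({"n_founders": 2}, "n_founders"),
            ({"maf_range": (0.0, 0.5)}, "maf_range"),
            ({"recomb_rate": -1.0}, "recomb_rate"),
            ({"polygenic_h2": 1.2}, "polygenic_h2"),
            ({"admixture": (2, 1.5)}, "admixture"),
            ({"chromosomes": [(0, 10.0)]}, "chromosomes"),
            (
                {"random_effect_variances": {"residual": 0.9}},
                "random_effect_variances",
            ),
        ],
    )
    def test_invalid_fields_named_in_error(self, kw, field):
        with pytest.raises(ValueError, match=field):
            SimConfig(**kw)

    def test_donor_only_qtl_requires_admixture(self):
        with pytest.raises(ValueError, match="donor"):
            SimConfig(qtl_specs=[QtlSpec(1, donor_only=True)], admixture=(5, 0.0))


class TestPhenotypes:
    def test_pure_residual_variance(self):
        cfg = SimConfig(
            n_founders=200, n_years=8, chromosomes=[(50, 30.0)], seed=5,
            polygenic_h2=0.0, random_effect_variances={"residual": 1.0},
            repeat_rate=1.0, sex_effect=0.0, age_effect=0.0,
        )
        pop = sim.simulate_population(cfg)
        ph = sim.simulate_trait_and_phenotypes(pop)
        assert ph["trait"].var() == pytest.approx(1.0, abs=0.15)

    def test_realized_heritability_matches_target(self):
        """var(BV)/var(phenotype) averages the configured 0.4 over replicates."""
        ratios = []
        for seed in range(6):
            cfg = SimConfig(
                n_founders=120, n_years=8, chromosomes=[(80, 40.0)] * 3, seed=seed,
                polygenic_h2=0.4, random_effect_variances={"residual": 0.6},
                repeat_rate=1.0, sex_effect=0.0, age_effect=0.0,
            )
            pop = sim.simulate_population(cfg)
            ph = sim.simulate_trait_and_phenotypes(pop).drop_duplicates("id")
            bv = pd.Series(ph.attrs["truth"]["breeding_value"])
            ratios.append(bv.loc[ph["id"]].var() / ph["trait"].var())
        assert np.mean(ratios) == pytest.approx(0.4, abs=0.05)

    def test_planted_qtl_variance_is_2pq_a2(self):
        a = 0.8
        cfg = SimConfig(
            n_founders=250, n_years=8, chromosomes=[(60, 40.0)], seed=6,
            qtl_specs=[QtlSpec(1, target_maf=0.2, additive_effect=a)],
            polygenic_h2=0.0, random_effect_variances={"residual": 1.0},
        )
        pop = sim.simulate_population(cfg)
        ph = sim.simulate_trait_and_phenotypes(pop)
        bv = pd.Series(ph.attrs["truth"]["breeding_value"])
        x = pd.Series(pop.qtl_dosage(0), index=pop.pedigree["id"])
        q = x.mean() / 2
        q = min(q, 1 - q)
        expected = 2 * q * (1 - q) * a * a
        assert bv.var() == pytest.approx(expected, rel=0.15)

    def test_repeat_rate_realized(self, small_pop):
        ph = sim.simulate_trait_and_phenotypes(small_pop)
        mean_rep = len(ph) / ph["id"].nunique()
        assert mean_rep == pytest.approx(small_pop.config.repeat_rate, abs=0.5)


class TestFitness:
    def _lifetime_by_genotype(self, cfg):
        pop = sim.simulate_population(cfg)
        tabs = sim.simulate_fitness_records(pop)
        truth = tabs["truth"].set_index("id")
        dos = pd.Series(pop.qtl_dosage(0), index=pop.pedigree["id"])
        return pop, truth.join(dos.rename("g"))

    def test_neutral_mode_no_genotype_differences(self):
        cfg = SimConfig(
            n_founders=300, n_years=12, chromosomes=[(40, 30.0)], seed=7,
            qtl_specs=[QtlSpec(1, target_maf=0.3, fitness_mode="neutral")],
        )
        _, df = self._lifetime_by_genotype(cfg)
        means = df.groupby("g")["LR"].mean()
        assert abs(means.loc[0.0] - means.loc[2.0]) < 0.6

    def test_overdominance_heterozygote_most_recruits(self):
        cfg = SimConfig(
            n_founders=300, n_years=14, chromosomes=[(40, 30.0)], seed=8,
            qtl_specs=[
                QtlSpec(1, target_maf=0.3, fitness_mode="overdominant", fitness_effect=0.3)
            ],
        )
        _, df = self._lifetime_by_genotype(cfg)
        means = df.groupby("g")["LR"].mean()
        assert means.loc[1.0] > means.loc[0.0]
        assert means.loc[1.0] > means.loc[2.0]

    def test_deleterious_allele_declines(self):
        declines = 0
        for seed in range(5):
            cfg = SimConfig(
                n_founders=250, n_years=14, chromosomes=[(40, 30.0)], seed=100 + seed,
                qtl_specs=[
                    QtlSpec(1, target_maf=0.3, fitness_mode="additive", fitness_effect=-0.3)
                ],
            )
            pop = sim.simulate_population(cfg)
            dos = pop.qtl_dosage(0)
            ped = pop.pedigree
            early = dos[(ped["birth_year"] <= 1).to_numpy()].mean()
            late = dos[(ped["birth_year"] >= cfg.n_years - 3).to_numpy()].mean()
            declines += int(late < early)
        assert declines >= 4

    def test_derived_equals_generator_truth(self, small_pop):
        from wildarch.selection import derive_fitness

        tabs = sim.simulate_fitness_records(small_pop)
        derived = derive_fitness(small_pop.pedigree, tabs["survival"])
        m = derived["lifetime"].merge(tabs["truth"], on="id", suffixes=("_d", "_t"))
        assert (m["LBS_d"] == m["LBS_t"]).all()
        assert (m["LR_d"] == m["LR_t"]).all()


class TestBreedPanel:
    def test_no_admixture_population_has_no_donor_breed(self, small_pop):
        with pytest.raises(ValueError, match="admixture"):
            sim.simulate_breed_panel(small_pop)

    def test_recent_admixture_spans_whole_chromosomes(self):
        cfg = SimConfig(
            n_founders=60, n_years=6, chromosomes=[(60, 30.0)], seed=9,
            admixture=(0, 0.2),
        )
        pop = sim.simulate_population(cfg)
        donor_rows = pop.ancestry.any(axis=1)
        # every haplotype with any donor material is donor end to end
        assert np.all(pop.ancestry[donor_rows] == 1)

    def test_donor_only_allele_rides_on_donor_haplotypes(self):
        cfg = SimConfig(
            n_founders=120, n_years=12, chromosomes=[(120, 50.0)], seed=10,
            admixture=(6, 0.25), qtl_specs=[QtlSpec(1, target_maf=0.1, donor_only=True)],
        )
        pop = sim.simulate_population(cfg)
        j = pop.qtl_indices[0]
        carriers = pop.haplotypes[:, j] == 1
        assert carriers.sum() > 0
        assert np.all(pop.ancestry[carriers, j] == 1)

    def test_panel_labels_present(self):
        cfg = SimConfig(
            n_founders=80, n_years=8, chromosomes=[(80, 40.0)], seed=12,
            admixture=(4, 0.2),
        )
        pop = sim.simulate_population(cfg)
        panel = sim.simulate_breed_panel(pop, n_outgroups=2, panel_size=10)
        labels = set(panel.labels)
        assert {"focal", "donor", "outgroup_1", "outgroup_2"} <= labels

    def test_donor_segment_length_matches_exponential_expectation(self):
        """Mean donor tract length ~ 100 / ((1 - p) g) cM after g complete
        generations, the exponential break-point expectation."""
        g, p = 10, 0.2
        means = []
        for seed in range(4):
            cfg = SimConfig(
                n_founders=120, n_years=g + 2, chromosomes=[(400, 100.0)],
                seed=400 + seed, admixture=(g, p), complete_turnover=True,
            )
            pop = sim.simulate_population(cfg)
            alive = np.repeat(pop.alive_in_year(cfg.n_years), 2)
            bp = pop.snp_map["bp"].to_numpy()
            lens = []
            for h in pop.ancestry[alive]:
                d = np.diff(np.concatenate([[0], h, [0]]))
                for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1) - 1):
                    lens.append((bp[e] - bp[s]) / 1e6)
            if lens:
                means.append(np.mean(lens))
        expected = 100.0 / ((1 - p) * g)  # cM == Mb at 1 cM/Mb
        assert np.mean(means) == pytest.approx(expected, rel=0.30)
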