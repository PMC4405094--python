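"""End-to-end orchestration: simulate -> partition -> GWAS -> selection -> HS.

A run is driven by a structured config (dict or YAML file) with per-stage
toggles and parameters; every stage writes its outputs under the run
directory and registers them in a manifest with content hashes, so a
rerun with the same config and seeds reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas as gwas_mod
from . import io as gio
from . import scan as scan_mod
from . import selection as sel_mod
from . import simulate as sim_mod
from .grm import compute_grm
from .haplo import extract_core_haplotypes, hs_lengths
from .varcomp import build_model, fit_variance_components

__all__ = ["run_pipeline", "default_config", "load_config"]


def default_config() -> dict:
    return {
        "outdir": "wildarch_run",
        "seed": 0,
        "stages": {
            "simulate": True,
            "partition": True,
            "regions": False,
            "gwas": True,
            "selection": True,
            "haplo": False,
        },
        "simulate": {
            "n_founders": 100,
            "n_years": 12,
            "chromosomes": [[200, 80.0], [150, 60.0], [100, 40.0], [60, 25.0]],
            "qtl": [],
            "admixture": [0, 0.0],
        },
        "scan": {"window": 150, "step": 75, "min_snps": 113, "alpha": 0.05},
        "selection": {"n_boot": 500, "n_reps": 1000},
    }


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: dict):
        self.outdir = outdir
        self.data = {"config": config, "stages": {}, "outputs": {}}

    def add(self, stage: str, path: Path, note: str = ""):
        self.data["outputs"][str(path.relative_to(self.outdir))] = {
            "sha256": _sha256(path),
            "stage": stage,
            "note": note,
        }

    def stage_done(self, stage: str, seconds: float, **info):
        self.data["stages"][stage] = {"seconds": round(seconds, 3), **info}

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True, default=str))
        return path


def run_pipeline(config: dict) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    outdir = Path(config.get("outdir", "wildarch_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    man = _Manifest(outdir, config)
    stages = config.get("stages", {})
    seed = int(config.get("seed", 0))
    state: dict = {}

    if stages.get("simulate"):
        t0 = time.time()
        sc = config.get("simulate", {})
        qtl = [sim_mod.QtlSpec(**q) for q in sc.get("qtl", [])]
        g, p = sc.get("admixture", [0, 0.0])
        simcfg = sim_mod.SimConfig(
            n_founders=int(sc.get("n_founders", 100)),
            n_years=int(sc.get("n_years", 12)),
            chromosomes=[tuple(c) for c in sc.get("chromosomes", [[200, 60.0]] * 4)],
            qtl_specs=qtl,
            admixture=(int(g), float(p)),
            seed=seed,
        )
        pop = sim_mod.simulate_population(simcfg)
        pheno = sim_mod.simulate_trait_and_phenotypes(pop)
        gs = pop.genotype_set()
        gio.write_plink(gs, outdir / "genotypes")
        pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
        ped_out = pop.pedigree.fillna("0")
        ped_out.to_csv(outdir / "pedigree.tsv", sep="\t", index=False)
        fit_tabs = sim_mod.simulate_fitness_records(pop)
        fit_tabs["survival"].to_csv(outdir / "census.tsv", sep="\t", index=False)
        for ext in (".bed", ".bim", ".fam"):
            man.add("simulate", outdir / f"genotypes{ext}")
        for f in ("phenotypes.tsv", "pedigree.tsv", "census.tsv"):
            man.add("simulate", outdir / f)
        state.update(pop=pop, pheno=pheno, genotypes=gs, fitness=fit_tabs)
        man.stage_done("simulate", time.time() - t0, seed=seed, n_ind=len(pop.pedigree))

    if stages.get("partition"):
        t0 = time.time()
        pop, pheno, gs = state["pop"], state["pheno"], state["genotypes"]
        res = scan_mod.chromosome_partition(gs, pheno.drop_duplicates("id"), "trait")
        res["table"].to_csv(outdir / "chromosome_partition.tsv", sep="\t", index=False)
        man.add("partition", outdir / "chromosome_partition.tsv")
        lengths = {str(i + 1): l for i, (_, l) in enumerate(pop.config.chromosomes)}
        try:
            slope, _, r2, p = scan_mod.length_regression(res["table"], lengths)
            lenreg = {"slope": slope, "r2": r2, "p": p}
        except ValueError as exc:
            lenreg = {"skipped": str(exc)}
        state["partition"] = res
        man.stage_done(
            "partition",
            time.time() - t0,
            wg_h2=round(
                res["whole_genome"].components.get("a", 0.0)
                / res["whole_genome"].total_variance,
                4,
            ),
            length_regression=lenreg,
        )

    if stages.get("regions"):
        t0 = time.time()
        gs, pheno = state["genotypes"], state["pheno"]
        sc = config.get("scan", {})
        res = scan_mod.regional_scan(
            gs,
            pheno.drop_duplicates("id"),
            "trait",
            window=int(sc.get("window", 150)),
            step=int(sc.get("step", 75)),
            min_snps=int(sc.get("min_snps", 113)),
            alpha=float(sc.get("alpha", 0.05)),
        )
        res["table"].to_csv(outdir / "regional_scan.tsv", sep="\t", index=False)
        man.add("regions", outdir / "regional_scan.tsv")
        state["regions"] = res
        man.stage_done(
            "regions", time.time() - t0,
            threshold=res["threshold"], n_converged=res["n_converged"],
        )

    if stages.get("gwas"):
        t0 = time.time()
        gs, pheno = state["genotypes"], state["pheno"]
        grm = compute_grm(gs)
        spec = build_model(pheno.drop_duplicates("id"), "trait", grms={"a": grm})
        fit = fit_variance_components(spec)
        resid = gwas_mod.grammar_residuals(fit)
        scan_df = gwas_mod.score_scan(resid, gs)
        scan_df.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
        man.add("gwas", outdir / "gwas.tsv")
        lam = gwas_mod.inflation_factor(scan_df["chi2"].to_numpy())
        thr = gwas_mod.bonferroni_threshold(int(scan_df["p"].notna().sum()))
        state.update(gwas=scan_df, gwas_fit=fit, gwas_spec=spec)
        man.stage_done(
            "gwas", time.time() - t0, **{"lambda": round(lam, 3), "threshold": thr}
        )

    if stages.get("selection"):
        t0 = time.time()
        pop = state["pop"]
        fit_tabs = state.get("fitness") or sim_mod.simulate_fitness_records(pop)
        derived = sel_mod.derive_fitness(pop.pedigree, fit_tabs["survival"])
        derived["lifetime"].to_csv(outdir / "fitness_lifetime.tsv", sep="\t", index=False)
        man.add("selection", outdir / "fitness_lifetime.tsv")
        info = {}
        if pop.qtl_indices:
            selcfg = config.get("selection", {})
            dos = pd.Series(pop.qtl_dosage(0), index=pop.pedigree["id"])
            lt = derived["lifetime"].set_index("id")
            est = sel_mod.selection_coefficients(
                lt["LR"].to_numpy(dtype=float),
                dos.reindex(lt.index).to_numpy(),
                n_boot=int(selcfg.get("n_boot", 500)),
                seed=seed + 13,
            )
            est.table.to_csv(outdir / "selection_LR.tsv", sep="\t", index=False)
            man.add("selection", outdir / "selection_LR.tsv")
            trend = sel_mod.allele_trend_test(
                pop.pedigree, dos, n_reps=int(selcfg.get("n_reps", 1000)),
                seed=seed + 17,
            )
            info = {
                "fittest": est.fittest,
                "trend_slope": round(trend["slope"], 5),
                "p_genedrop": trend["p_genedrop"],
            }
        state["selection"] = derived
        man.stage_done("selection", time.time() - t0, **info)

    if stages.get("haplo"):
        t0 = time.time()
        pop = state["pop"]
        panel = sim_mod.simulate_breed_panel(pop)
        focal = panel.samples_with_label("focal")
        refs = panel  # references include every non-focal breed
        donor_qtls = [
            (spec, j) for spec, j in zip(pop.config.qtl_specs, pop.qtl_indices)
            if spec.donor_only
        ]
        rows = []
        if donor_qtls:
            _, j = donor_qtls[0]
            snp_id = pop.snp_map.at[j, "snp_id"]
            cores = extract_core_haplotypes(focal, snp_id, min_count=3)
            breeds = [b for b in sorted(set(panel.labels)) if b != "focal"]
            for core in cores:
                for r in hs_lengths(focal, refs, core, breeds=breeds):
                    rows.append(
                        {
                            "core": r.core,
                            "focal_allele": core.focal_allele,
                            "breed": r.breed,
                            "n_pairs": r.n_pairs,
                            "mean_bp": r.mean_bp,
                            "sd_bp": r.sd_bp,
                        }
                    )
        hs_df = pd.DataFrame(rows)
        hs_df.to_csv(outdir / "haplotype_sharing.tsv", sep="\t", index=False)
        man.add("haplo", outdir / "haplotype_sharing.tsv")
        state["haplo"] = hs_df
        man.stage_done("haplo", time.time() - t0, n_cores=len(rows))

    path = man.write()
    man.data["manifest_path"] = str(path)
    return man.data
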