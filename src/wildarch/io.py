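"""Readers/writers for the standard formats the pipeline touches.

Covers PLINK bed/bim/fam (v1.0, SNP-major), phased VCF, GCTA binary GRM
triplets and the delimited phenotype / pedigree / fitness tables.  All
coordinates are 1-based and inclusive, matching bim/VCF conventions.

Missing dosages are held internally as NaN — a sentinel distinct from the
valid codes 0/1/2.  GRM construction and the association scan mean-impute
per SNP; variance-component models never see a missing value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeSet",
    "PhasedPanel",
    "GRM",
    "read_plink",
    "write_plink",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_grm_gcta",
    "write_grm_gcta",
    "read_pedigree",
    "read_phenotypes",
    "read_fitness",
]

MISSING = np.nan

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 2-bit codes (SNP-major, v1.0): 00=hom A1, 01=missing, 10=het, 11=hom A2.
# We count A1 copies, so hom A1 -> 2, het -> 1, hom A2 -> 0.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class GenotypeSet:
    """Individuals x SNPs dosage matrix plus SNP map and sample ids.

    ``dosages[i, j]`` counts copies of allele1 (A1) carried by sample *i*
    at SNP *j*; NaN marks a missing call.  ``snp_map`` has columns
    ``snp_id, chrom, bp, a1, a2`` sorted by (chrom, bp) in file order.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"dosage rows ({n}) != number of sample ids ({len(self.sample_ids)})"
            )
        if len(self.snp_map) != m:
            raise ValueError(
                f"dosage columns ({m}) != number of mapped SNPs ({len(self.snp_map)})"
            )
        if (self.snp_map["bp"] <= 0).any():
            raise ValueError("bp positions must be positive (1-based)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of allele1 per SNP, ignoring missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_snps(self, index: np.ndarray) -> "GenotypeSet":
        index = np.asarray(index)
        return GenotypeSet(
            self.dosages[:, index],
            self.snp_map.iloc[index].reset_index(drop=True),
            list(self.sample_ids),
        )


@dataclass
class PhasedPanel:
    """Phased haplotypes over a SNP subset with a population label per sample.

    ``haplotypes`` has shape (2 * n_samples, n_snps); rows 2i and 2i+1 are
    the two haplotypes of sample i, coded as copies of allele1 (0/1).
    """

    haplotypes: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list[str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("expected two haplotypes per sample")
        if self.haplotypes.shape[1] != len(self.snp_map):
            raise ValueError("haplotype columns != number of mapped SNPs")
        if not self.labels:
            self.labels = ["focal"] * len(self.sample_ids)
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one population label per sample required")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def dosages(self) -> np.ndarray:
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(float)

    def samples_with_label(self, label: str) -> "PhasedPanel":
        keep = [i for i, l in enumerate(self.labels) if l == label]
        rows = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in keep])) if keep else []
        return PhasedPanel(
            self.haplotypes[list(rows)],
            self.snp_map,
            [self.sample_ids[i] for i in keep],
            [label] * len(keep),
        )

    def subset_snps(self, index: np.ndarray) -> "PhasedPanel":
        index = np.asarray(index)
        return PhasedPanel(
            self.haplotypes[:, index],
            self.snp_map.iloc[index].reset_index(drop=True),
            list(self.sample_ids),
            list(self.labels),
        )


@dataclass
class GRM:
    """Genomic relatedness matrix with provenance.

    ``n_snps`` records how many markers built the matrix (needed for the
    sampling-error shrinkage); ``freq_source`` tags where the allele
    frequencies came from (``"sample"`` or an external file path).
    """

    values: np.ndarray
    sample_ids: list[str]
    n_snps: int
    freq_source: str = "sample"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match sample id count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GRM contains non-finite entries")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam


def write_plink(gs: GenotypeSet, prefix: str | Path) -> None:
    """Write a GenotypeSet as PLINK bed (v1.0 SNP-major) + bim + fam."""
    prefix = Path(prefix)
    n = gs.n_samples
    # bim: chrom, snp id, cM (0), bp, allele1, allele2
    bim = pd.DataFrame(
        {
            "chrom": gs.snp_map["chrom"],
            "snp_id": gs.snp_map["snp_id"],
            "cm": 0,
            "bp": gs.snp_map["bp"],
            "a1": gs.snp_map["a1"],
            "a2": gs.snp_map["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": gs.sample_ids,
            "iid": gs.sample_ids,
            "sire": 0,
            "dam": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)

    # 2-bit pack, one SNP per row block of ceil(n/4) bytes
    dos = gs.dosages
    codes = np.full(dos.shape, 1, dtype=np.uint8)  # 01 = missing
    codes[dos == 2] = 0b00
    codes[dos == 1] = 0b10
    codes[dos == 0] = 0b11
    n_bytes = (n + 3) // 4
    padded = np.zeros((dos.shape[1], n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix: str | Path) -> GenotypeSet:
    """Read PLINK bed/bim/fam; dosage counts A1 copies; missing -> NaN."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    sample_ids = list(fam[1])
    n, m = len(sample_ids), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes "
            f"{raw[:3].hex()} (expected SNP-major PLINK v1.0)"
        )
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    n_bytes = (n + 3) // 4
    if body.size != m * n_bytes:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: expected {m * n_bytes} data bytes "
            f"for {n} samples x {m} SNPs, found {body.size}"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    snp_map = bim[["snp_id", "chrom", "bp", "a1", "a2"]].copy()
    return GenotypeSet(dosages, snp_map, sample_ids)


# ---------------------------------------------------------------------------
# Phased VCF


def write_phased_vcf(panel: PhasedPanel, path: str | Path) -> None:
    """Write a phased panel as VCF 4.2 with '|'-separated GT."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(panel.snp_map["chrom"]):
            sub = panel.snp_map[panel.snp_map["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['bp'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        hap = panel.haplotypes
        for j, row in panel.snp_map.reset_index(drop=True).iterrows():
            # REF = allele2, ALT = allele1; GT "1" means one copy of allele1
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{row['chrom']}\t{int(row['bp'])}\t{row['snp_id']}\t"
                f"{row['a2']}\t{row['a1']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
    labels: dict[str, str] | None = None,
) -> PhasedPanel:
    """Read phased GT from a VCF into a PhasedPanel.

    ``region`` is (chrom, start_bp, end_bp), 1-based inclusive.  Unphased
    genotypes ('/'-separated with both alleles called) raise with the
    offending record ids listed.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows, haps, bad = [], [], []
    for var in vcf:
        if region is not None:
            chrom, start, end = region
            if str(var.CHROM) != str(chrom) or not (start <= var.POS <= end):
                continue
        gts = np.array(var.genotypes)  # (n, 3): a, b, phased flag
        called = (gts[:, 0] >= 0) & (gts[:, 1] >= 0)
        if np.any(called & (gts[:, 2] == 0)):
            bad.append(var.ID or f"{var.CHROM}:{var.POS}")
            continue
        rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "bp": int(var.POS),
                "a1": var.ALT[0] if var.ALT else ".",
                "a2": var.REF,
            }
        )
        haps.append(gts[:, :2].reshape(-1))
    if bad:
        raise ValueError(f"unphased GT records in {path}: {', '.join(bad[:10])}")
    if not rows:
        warnings.warn(f"no records found in {path} for region {region}")
        return PhasedPanel(
            np.zeros((2 * len(sample_ids), 0), dtype=np.int8),
            pd.DataFrame(columns=["snp_id", "chrom", "bp", "a1", "a2"]),
            sample_ids,
            [labels.get(s, "focal") for s in sample_ids] if labels else None,
        )
    hap = np.stack(haps, axis=1).astype(np.int8)
    lab = [labels.get(s, "focal") for s in sample_ids] if labels else None
    return PhasedPanel(hap, pd.DataFrame(rows), sample_ids, lab)


# ---------------------------------------------------------------------------
# GCTA binary GRM triplet


def write_grm_gcta(grm: GRM, prefix: str | Path) -> None:
    """Write the GCTA triplet: .grm.bin (lower-triangle float32 row by row),
    .grm.N.bin (per-pair SNP counts, float32) and .grm.id."""
    prefix = Path(prefix)
    n = len(grm.sample_ids)
    tri = np.concatenate([grm.values[i, : i + 1] for i in range(n)])
    tri.astype("<f4").tofile(f"{prefix}.grm.bin")
    np.full(tri.shape, grm.n_snps, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm_gcta(prefix: str | Path) -> GRM:
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None, dtype=str)
    sample_ids = list(ids[1])
    n = len(sample_ids)
    expected = n * (n + 1) // 2
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if tri.size != expected:
        raise ValueError(
            f"{prefix}.grm.bin: expected {expected} lower-triangle entries "
            f"for {n} ids, found {tri.size}"
        )
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if counts.size not in (1, expected):
        raise ValueError(
            f"{prefix}.grm.N.bin: expected 1 or {expected} entries, found {counts.size}"
        )
    mat = np.zeros((n, n))
    idx = np.tril_indices(n)
    mat[idx] = tri
    mat = mat + mat.T - np.diag(np.diag(mat))
    return GRM(mat, sample_ids, int(round(float(np.max(counts)))), "file")


# ---------------------------------------------------------------------------
# Delimited tables

_SEX_LEVELS = {"F", "M"}


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a pedigree TSV (id, sire, dam, sex, birth_year); validates that
    every cited parent exists, sexes are F/M, and parents precede offspring."""
    ped = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str})
    return validate_pedigree(ped)


def validate_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    required = {"id", "sire", "dam", "sex", "birth_year"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree missing columns: {sorted(missing)}")
    ped = ped.copy()
    for col in ("sire", "dam"):
        ped[col] = ped[col].where(~ped[col].isin(["0", "NA", ""]), other=pd.NA)
    known = set(ped["id"])
    for col in ("sire", "dam"):
        cited = set(ped[col].dropna())
        unknown = cited - known
        if unknown:
            raise ValueError(f"pedigree cites absent {col} ids: {sorted(unknown)[:5]}")
    bad_sex = set(ped["sex"]) - _SEX_LEVELS
    if bad_sex:
        raise ValueError(f"unknown sex levels: {sorted(bad_sex)}")
    by = ped.set_index("id")["birth_year"]
    for col in ("sire", "dam"):
        sub = ped.dropna(subset=[col])
        late = sub[by.loc[sub[col]].to_numpy() >= sub["birth_year"].to_numpy()]
        if len(late):
            raise ValueError(
                f"{col} born in or after offspring's birth year for ids "
                f"{list(late['id'])[:5]}"
            )
    return ped


def read_phenotypes(path: str | Path, trait: str | None = None) -> pd.DataFrame:
    """Read a phenotype TSV with repeated measures allowed.

    Validates sex levels and non-negative ages; any trait column named must
    be numeric.  Records a ``n_repeats`` attribute in ``df.attrs``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "sex" in df.columns:
        bad = set(df["sex"].dropna()) - _SEX_LEVELS
        if bad:
            raise ValueError(f"unknown sex levels: {sorted(bad)}")
    if "age" in df.columns and (df["age"].dropna() < 0).any():
        raise ValueError("negative ages in phenotype table")
    if trait is not None:
        if trait not in df.columns:
            raise ValueError(f"trait column {trait!r} absent")
        if not pd.api.types.is_numeric_dtype(df[trait]):
            raise ValueError(f"non-numeric values in trait column {trait!r}")
    df.attrs["n_repeats"] = df.groupby("id").size().to_dict()
    return df


def read_fitness(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    for col in ("AR", "LR", "LBS"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValueError(f"negative values in fitness column {col}")
    return df
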