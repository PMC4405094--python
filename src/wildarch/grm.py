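"""Genomic relatedness matrices and sliding-window region definitions.

The GRM estimator is the standard allele-frequency-weighted form used by
GCTA: for individuals j, k and SNPs i with allele-1 frequency p_i,

    A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    A_jj = 1 + (1/m) * sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2)
                              / (2 p_i (1 - p_i))

Missing dosages are mean-imputed to 2 p_i.  Frequencies default to the
full genotyped sample and may be supplied externally (the source is
recorded in the GRM tag).  An optional reliability shrinkage of the
off-diagonals stands in for sampling-error adjustment when m is small;
it is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GRM, GenotypeSet

__all__ = ["GRM", "RegionDefinition", "compute_grm", "adjust_grm", "define_regions"]

log = logging.getLogger(__name__)


@dataclass
class RegionDefinition:
    """A retained sliding window of SNPs on one chromosome.

    SNP ordinals are 1-based and inclusive within the chromosome; bp
    endpoints are both inclusive.
    """

    index: int
    chrom: str
    first_ordinal: int
    last_ordinal: int
    snp_ids: list[str]
    bp_start: int
    bp_end: int
    global_indices: np.ndarray  # columns into the full dosage matrix

    @property
    def n_snps(self) -> int:
        return self.last_ordinal - self.first_ordinal + 1


def compute_grm(
    genotypes: GenotypeSet,
    snp_subset: np.ndarray | None = None,
    allele_freqs: np.ndarray | None = None,
) -> GRM:
    """Allele-frequency-weighted GRM over a SNP subset.

    ``snp_subset`` holds column indices (default: all SNPs).
    ``allele_freqs`` are external allele-1 frequencies *for the subset
    columns*, all strictly inside (0, 1); by default frequencies come
    from the sample itself and monomorphic SNPs are dropped with a
    warning.
    """
    if snp_subset is None:
        snp_subset = np.arange(genotypes.n_snps)
    snp_subset = np.asarray(snp_subset)
    if snp_subset.size == 0:
        raise ValueError("snp_subset is empty")
    X = genotypes.dosages[:, snp_subset].copy()

    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(X, axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        if not poly.all():
            log.warning("excluding %d monomorphic SNPs from GRM", (~poly).sum())
            X, p = X[:, poly], p[poly]
            if X.shape[1] == 0:
                raise ValueError("no polymorphic SNPs left in subset")
        freq_source = "sample"
    else:
        p = np.asarray(allele_freqs, dtype=float)
        if p.shape[0] != X.shape[1]:
            raise ValueError("allele_freqs length does not match snp_subset")
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("external allele frequencies must lie strictly in (0, 1)")
        freq_source = "external"

    m = X.shape[1]
    miss = np.isnan(X)
    if miss.any():
        X[miss] = np.broadcast_to(2 * p, X.shape)[miss]

    w = 2 * p * (1 - p)
    Z = (X - 2 * p) / np.sqrt(w)
    A = (Z @ Z.T) / m
    diag = 1.0 + np.sum((X * X - (1 + 2 * p) * X + 2 * p * p) / w, axis=1) / m
    np.fill_diagonal(A, diag)
    return GRM(A, list(genotypes.sample_ids), m, freq_source)


def adjust_grm(grm: GRM, mode: str = "off", c: float = 1.0) -> GRM:
    """Reliability shrinkage of GRM off-diagonals for finite marker counts.

    The sampling variance of a pairwise estimate built from m markers is
    roughly c/m; shrinking off-diagonals by
    beta = var_true / (var_true + c/m), with var_true the observed
    off-diagonal variance minus c/m, pulls noisy estimates toward 0.  The
    diagonal is left untouched.  ``mode='off'`` returns the input
    unchanged.
    """
    if mode == "off":
        return grm
    if mode != "shrink":
        raise ValueError(f"unknown adjustment mode {mode!r}")
    A = grm.values.copy()
    n = A.shape[0]
    off = A[np.triu_indices(n, k=1)]
    noise = c / grm.n_snps
    var_true = off.var() - noise
    if var_true < 0:
        log.warning("estimated true relatedness variance negative; shrinking to 0")
        var_true = 0.0
    beta = var_true / (var_true + noise) if (var_true + noise) > 0 else 0.0
    diag = np.diag(A).copy()
    A *= beta
    np.fill_diagonal(A, diag)
    return GRM(A, list(grm.sample_ids), grm.n_snps, grm.freq_source + "+shrink")


def define_regions(
    snp_map: pd.DataFrame,
    window: int = 150,
    step: int = 75,
    min_snps: int = 113,
) -> list[RegionDefinition]:
    """Sliding windows of ``window`` adjacent SNPs started ``step`` apart.

    Per chromosome, windows begin at ordinals 1, 1+step, 1+2*step, ...;
    each spans min(window, SNPs remaining); windows with fewer than
    ``min_snps`` SNPs are dropped.  Region indices run in genome order
    over retained windows.
    """
    regions: list[RegionDefinition] = []
    index = 1
    offset = 0
    for chrom, sub in snp_map.groupby("chrom", sort=False):
        m = len(sub)
        if m < min_snps:
            log.info("chromosome %s has %d SNPs (< %d): no regions", chrom, m, min_snps)
            offset += m
            continue
        ids = sub["snp_id"].to_numpy()
        bps = sub["bp"].to_numpy()
        for start in range(1, m + 1, step):
            stop = min(start + window - 1, m)
            count = stop - start + 1
            if count < min_snps:
                continue
            regions.append(
                RegionDefinition(
                    index=index,
                    chrom=str(chrom),
                    first_ordinal=start,
                    last_ordinal=stop,
                    snp_ids=list(ids[start - 1: stop]),
                    bp_start=int(bps[start - 1]),
                    bp_end=int(bps[stop - 1]),
                    global_indices=offset + np.arange(start - 1, stop),
                )
            )
            index += 1
        offset += m
    return regions


def regions_table(regions: list[RegionDefinition]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [r.index for r in regions],
            "chrom": [r.chrom for r in regions],
            "first_ordinal": [r.first_ordinal for r in regions],
            "last_ordinal": [r.last_ordinal for r in regions],
            "bp_start": [r.bp_start for r in regions],
            "bp_end": [r.bp_end for r in regions],
            "n_snps": [r.n_snps for r in regions],
        }
    )
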