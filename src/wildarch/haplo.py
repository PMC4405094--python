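"""LD, core haplotypes and haplotype-sharing lengths across breed panels.

A *core haplotype* is the allele string over the focal SNP plus its
three upstream and two downstream neighbours in map order (six SNPs
including the focal one).  For every pair of chromosomes — one from the
focal population, one from a reference breed — that carry the same core,
sharing is scanned outward SNP-by-SNP from the core's edges; the HS
length is the bp distance between the last matching SNPs on either side
(so an immediate mismatch on both flanks yields the core's own bp span,
and an unbroken match truncates at the window's terminal SNPs).  Long
shared flanks with one breed in particular are the signature of a
haplotype that entered the focal population by admixture from that
breed's ancestors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PhasedPanel

__all__ = [
    "ld_r2_matrix",
    "enumerate_haplotypes",
    "extract_core_haplotypes",
    "hs_lengths",
    "CoreHaplotype",
    "HsResult",
]

log = logging.getLogger(__name__)


def ld_r2_matrix(data, snp_indices: np.ndarray | None = None) -> np.ndarray:
    """Pairwise allelic correlation r^2.

    On a PhasedPanel r^2 is the squared Pearson correlation of allele
    indicators over haplotypes (the allelic correlation); on a dosage
    matrix it is computed on dosages.  Monomorphic SNPs get NaN rows and
    columns; the diagonal is 1 where defined.
    """
    if isinstance(data, PhasedPanel):
        M = data.haplotypes.astype(float)
    else:
        M = np.asarray(data, dtype=float)
    if snp_indices is not None:
        M = M[:, np.asarray(snp_indices)]
    if M.shape[1] < 2:
        raise ValueError("need at least 2 SNPs for an LD matrix")
    sd = M.std(axis=0)
    mono = sd == 0
    if mono.any():
        log.info("%d monomorphic SNPs in LD window", int(mono.sum()))
    Mc = (M - M.mean(axis=0)) / np.where(mono, np.nan, sd)
    r = (Mc.T @ Mc) / M.shape[0]
    r2 = r**2
    np.fill_diagonal(r2, np.where(mono, np.nan, 1.0))
    return r2


def enumerate_haplotypes(
    panel: PhasedPanel, region: np.ndarray, min_count: int = 5
) -> pd.DataFrame:
    """Distinct haplotype strings over a SNP index region, rare ones dropped.

    Counts run over all chromosomes; the result is sorted by descending
    count and keeps haplotypes with count >= ``min_count``.  Pre-filter
    counts always sum to the number of chromosomes.
    """
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("empty region")
    H = panel.haplotypes[:, region]
    strings = ["".join(map(str, row)) for row in H]
    counts = pd.Series(strings).value_counts()
    kept = counts[counts >= min_count]
    if kept.empty:
        log.warning(
            "no haplotype reaches the retention count %d (max observed %d)",
            min_count,
            int(counts.max()),
        )
    return pd.DataFrame(
        {"haplotype": kept.index, "count": kept.to_numpy()}
    ).reset_index(drop=True)


@dataclass
class CoreHaplotype:
    """A retained core around a focal SNP: focal + 3 upstream + 2 downstream."""

    focal_snp: str
    member_snps: list[str]
    member_indices: np.ndarray  # columns in the panel's SNP map, map order
    alleles: str
    count: int
    bp_start: int
    bp_end: int
    focal_allele: int  # allele carried at the focal SNP

    @property
    def bp_span(self) -> int:
        return self.bp_end - self.bp_start


def _core_window(snp_map: pd.DataFrame, focal_snp: str, upstream: int, downstream: int):
    hits = np.flatnonzero(snp_map["snp_id"].to_numpy() == focal_snp)
    if hits.size != 1:
        raise ValueError(f"focal SNP {focal_snp!r} not found (or duplicated)")
    j = int(hits[0])
    chrom = snp_map.at[j, "chrom"]
    on_chrom = np.flatnonzero((snp_map["chrom"] == chrom).to_numpy())
    k = int(np.flatnonzero(on_chrom == j)[0])
    if k < upstream or k + downstream >= len(on_chrom):
        raise ValueError(
            f"focal SNP {focal_snp!r} too close to the chromosome end: "
            f"{k} SNPs upstream, {len(on_chrom) - k - 1} downstream available "
            f"(need {upstream}/{downstream})"
        )
    return j, on_chrom, on_chrom[k - upstream: k + downstream + 1]


def extract_core_haplotypes(
    panel: PhasedPanel,
    focal_snp: str,
    upstream: int = 3,
    downstream: int = 2,
    min_count: int = 5,
) -> list[CoreHaplotype]:
    """Distinct core haplotypes around a focal SNP with count >= min_count.

    The six-SNP core includes the focal SNP itself; each core is labelled
    with its focal-SNP allele so carrier cores (e.g. the rare trait
    allele) are identifiable.  Sorted by descending count.
    """
    j, _, member = _core_window(panel.snp_map, focal_snp, upstream, downstream)
    haps = enumerate_haplotypes(panel, member, min_count=min_count)
    focal_pos = int(np.flatnonzero(member == j)[0])
    bps = panel.snp_map["bp"].to_numpy()
    ids = panel.snp_map["snp_id"].to_numpy()
    out = []
    for r in haps.itertuples():
        out.append(
            CoreHaplotype(
                focal_snp=focal_snp,
                member_snps=list(ids[member]),
                member_indices=member,
                alleles=r.haplotype,
                count=int(r.count),
                bp_start=int(bps[member[0]]),
                bp_end=int(bps[member[-1]]),
                focal_allele=int(r.haplotype[focal_pos]),
            )
        )
    return out


@dataclass
class HsResult:
    """Mean haplotype-sharing length between focal carriers and one breed."""

    core: str
    breed: str
    n_pairs: int
    mean_bp: float | None
    sd_bp: float | None


def _carrier_rows(panel: PhasedPanel, core: CoreHaplotype) -> np.ndarray:
    H = panel.haplotypes[:, core.member_indices]
    target = np.array([int(c) for c in core.alleles], dtype=H.dtype)
    return np.flatnonzero((H == target).all(axis=1))


def hs_lengths(
    focal: PhasedPanel,
    reference: PhasedPanel,
    core: CoreHaplotype,
    window: np.ndarray | None = None,
    window_mb: float = 5.0,
    breeds: list[str] | None = None,
) -> list[HsResult]:
    """Haplotype-sharing lengths between focal carriers and each breed.

    Both panels must be phased over the same SNP map.  ``window`` gives
    SNP column indices bounding the scan (default: all SNPs of the core's
    chromosome within ``window_mb`` Mb of the focal SNP).  For each
    (focal carrier chromosome, reference carrier chromosome) pair the
    shared tract is the bp distance between the last matching SNPs found
    scanning outward from the core's edges; with no mismatch inside the
    window the tract truncates at the window's terminal SNPs, so
    HS >= the core's bp span always.
    """
    if not focal.snp_map["snp_id"].equals(reference.snp_map["snp_id"]):
        raise ValueError("focal and reference panels must share a SNP map")
    sm = focal.snp_map
    if window is None:
        j = core.member_indices[0]
        chrom = sm.at[int(j), "chrom"]
        focal_bp = sm.loc[
            sm["snp_id"] == core.focal_snp, "bp"
        ].iloc[0]
        window = np.flatnonzero(
            (
                (sm["chrom"] == chrom)
                & (sm["bp"] >= focal_bp - window_mb * 1e6)
                & (sm["bp"] <= focal_bp + window_mb * 1e6)
            ).to_numpy()
        )
    window = np.asarray(window)
    bps = sm["bp"].to_numpy()

    in_window = np.isin(core.member_indices, window)
    if not in_window.all():
        raise ValueError("core SNPs must lie inside the scan window")
    left_cols = window[window < core.member_indices[0]]  # outside-core, upstream
    right_cols = window[window > core.member_indices[-1]]

    focal_rows = _carrier_rows(focal, core)
    if focal_rows.size == 0:
        raise ValueError("no focal chromosomes carry this core haplotype")

    results = []
    for breed in breeds or sorted(set(reference.labels)):
        sub = reference.samples_with_label(breed)
        ref_rows = _carrier_rows(sub, core)
        if ref_rows.size == 0:
            results.append(HsResult(core.alleles, breed, 0, None, None))
            continue
        F = focal.haplotypes[np.ix_(focal_rows, window)]
        R = sub.haplotypes[np.ix_(ref_rows, window)]
        # pairwise mismatch tensor restricted to flanks, vectorized
        lengths = _pairwise_hs(
            F, R, window, left_cols, right_cols, core, bps
        )
        results.append(
            HsResult(
                core.alleles,
                breed,
                int(lengths.size),
                float(lengths.mean()),
                float(lengths.std()),
            )
        )
    return results


def _pairwise_hs(F, R, window, left_cols, right_cols, core, bps) -> np.ndarray:
    """bp length of unbroken sharing for every (focal, reference) pair."""
    nf, nr = F.shape[0], R.shape[0]
    col_of = {c: k for k, c in enumerate(window)}
    li = np.array([col_of[c] for c in left_cols], dtype=int)
    ri = np.array([col_of[c] for c in right_cols], dtype=int)

    # upstream: scan right-to-left from the core edge; last matching SNP
    # before the first mismatch
    up_bp = np.full((nf, nr), core.bp_start, dtype=np.int64)
    if li.size:
        mism = F[:, None, li] != R[None, :, li]  # (nf, nr, L) ordered left->right
        rev = mism[:, :, ::-1]  # core-outward order
        first = np.argmax(rev, axis=2)
        any_mism = rev.any(axis=2)
        # index (in outward order) of the last matching SNP
        last_match = np.where(any_mism, first - 1, li.size - 1)
        has_match = last_match >= 0
        outward_bps = bps[left_cols][::-1]
        up_bp = np.where(has_match, outward_bps[np.clip(last_match, 0, None)], core.bp_start)
    down_bp = np.full((nf, nr), core.bp_end, dtype=np.int64)
    if ri.size:
        mism = F[:, None, ri] != R[None, :, ri]
        first = np.argmax(mism, axis=2)
        any_mism = mism.any(axis=2)
        last_match = np.where(any_mism, first - 1, ri.size - 1)
        has_match = last_match >= 0
        outward_bps = bps[right_cols]
        down_bp = np.where(
            has_match, outward_bps[np.clip(last_match, 0, None)], core.bp_end
        )
    return (down_bp - up_bp).ravel()
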