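"""Site- and genotype-level hard-filter cascade for MHC and TLR profiles.

Each stage is a pure site predicate: it removes sites and never alters
genotypes, so the cascade is order-stable. All threshold comparisons are
strict ("less than" / "greater than"): a site with QUAL exactly 80 or MQ
exactly 40 passes, mean depth exactly at the threshold passes, and mean
allelic-balance difference exactly 0.9 passes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats_io import GeneRegion, Genotype, GenotypeMatrix

logger = logging.getLogger("mhcdepth")


@dataclass(frozen=True)
class FilterProfile:
    """Hard-filter thresholds for one gene family profile.

    The MHC profile applies quality, mapping-quality, rank-sum and
    allelic-balance rules; the TLR profile applies only quality and
    mapping quality.
    """

    name: str
    min_qual: float = 80.0
    min_mq: float = 40.0
    mq_rank_sum_bounds: tuple[float, float] | None = None
    read_pos_rank_sum_bounds: tuple[float, float] | None = None
    allelic_balance_max_diff: float | None = None

    def __post_init__(self) -> None:
        if self.min_qual <= 0 or self.min_mq <= 0:
            raise ValueError("thresholds must be strictly positive")
        for b in (self.mq_rank_sum_bounds, self.read_pos_rank_sum_bounds):
            if b is not None and abs(b[0] + b[1]) > 1e-12:
                raise ValueError("rank-sum bounds must be symmetric")

    @classmethod
    def mhc(cls) -> "FilterProfile":
        return cls(
            name="MHC",
            mq_rank_sum_bounds=(-12.5, 12.5),
            read_pos_rank_sum_bounds=(-8.0, 8.0),
            allelic_balance_max_diff=0.9,
        )

    @classmethod
    def tlr(cls) -> "FilterProfile":
        return cls(name="TLR")


def select_biallelic_exonic(
    matrix: GenotypeMatrix, regions: Sequence[GeneRegion]
) -> tuple[GenotypeMatrix, dict]:
    """Retain only biallelic SNVs whose position falls inside an exon."""
    if not regions:
        raise ValueError("regions must be non-empty")
    by_chrom: dict[str, list[GeneRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    keep = np.zeros(matrix.n_sites, dtype=bool)
    n_multi = n_nonexonic = 0
    for i, s in enumerate(matrix.sites):
        if not s.is_biallelic_snv:
            n_multi += 1
            continue
        if any(g.contains(s.pos) for g in by_chrom.get(s.chrom, [])):
            keep[i] = True
        else:
            n_nonexonic += 1
    out = matrix.subset_sites(keep)
    if out.n_sites == 0:
        warnings.warn("no biallelic exonic sites remain")
    report = {
        "input_sites": matrix.n_sites,
        "removed_non_biallelic": n_multi,
        "removed_non_exonic": n_nonexonic,
        "retained": out.n_sites,
    }
    logger.info("select_biallelic_exonic: %s", report)
    return out, report


def apply_hard_filters(
    matrix: GenotypeMatrix, profile: FilterProfile
) -> tuple[GenotypeMatrix, dict]:
    """Remove sites failing QUAL/MQ (and, for the MHC profile, rank-sum)
    thresholds. Absent rank-sum annotations pass."""
    keep = np.ones(matrix.n_sites, dtype=bool)
    tallies = {"qual": 0, "mq": 0, "mq_rank_sum": 0, "read_pos_rank_sum": 0}
    for i, s in enumerate(matrix.sites):
        fail = False
        if not np.isnan(s.qual) and s.qual < profile.min_qual:
            tallies["qual"] += 1
            fail = True
        if not np.isnan(s.mq) and s.mq < profile.min_mq:
            tallies["mq"] += 1
            fail = True
        if profile.mq_rank_sum_bounds is not None and s.mq_rank_sum is not None:
            lo, hi = profile.mq_rank_sum_bounds
            if s.mq_rank_sum < lo or s.mq_rank_sum > hi:
                tallies["mq_rank_sum"] += 1
                fail = True
        if (
            profile.read_pos_rank_sum_bounds is not None
            and s.read_pos_rank_sum is not None
        ):
            lo, hi = profile.read_pos_rank_sum_bounds
            if s.read_pos_rank_sum < lo or s.read_pos_rank_sum > hi:
                tallies["read_pos_rank_sum"] += 1
                fail = True
        keep[i] = not fail
    out = matrix.subset_sites(keep)
    report = {
        "profile": profile.name,
        "input_sites": matrix.n_sites,
        "failed": tallies,
        "retained": out.n_sites,
    }
    logger.info("apply_hard_filters: %s", report)
    return out, report


def depth_threshold(target_depth: float) -> float:
    """Mean-depth exclusion threshold: one third of the target depth,
    capped at 10 (a 15x target gives 5; a 60x target gives 10)."""
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    return min(target_depth / 3.0, 10.0)


def apply_depth_filter(
    matrix: GenotypeMatrix, target_depth: float
) -> tuple[GenotypeMatrix, dict]:
    """Remove sites whose mean per-genotype depth is below
    ``min(target_depth / 3, 10)`` (strict)."""
    t = depth_threshold(target_depth)
    if matrix.depth is None:
        raise ValueError("matrix has no per-genotype depths")
    mean_depth = matrix.depth.mean(axis=1) if matrix.n_sites else np.zeros(0)
    keep = ~(mean_depth < t)
    out = matrix.subset_sites(keep)
    report = {
        "target_depth": target_depth,
        "threshold": t,
        "input_sites": matrix.n_sites,
        "retained": out.n_sites,
    }
    logger.info("apply_depth_filter: %s", report)
    return out, report


def allelic_balance_diff(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-site mean over heterozygous genotypes of
    ``|ref_reads - alt_reads| / (ref_reads + alt_reads)``; NaN when a site
    has no heterozygous call with reads."""
    if matrix.allele_depths is None:
        raise ValueError("matrix has no allele depths")
    ad = matrix.allele_depths.astype(float)
    het = matrix.calls == Genotype.HET
    total = ad[..., 0] + ad[..., 1]
    valid = het & (ad[..., 0] >= 0) & (total > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.abs(ad[..., 0] - ad[..., 1]) / total
    diff = np.where(valid, diff, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return np.nanmean(diff, axis=1)


def apply_allelic_balance_filter(
    matrix: GenotypeMatrix, max_diff: float = 0.9, mode: str = "diff_mean"
) -> tuple[GenotypeMatrix, dict]:
    """Remove sites whose allelic balance is too skewed.

    ``mode="diff_mean"`` (default): remove a site when the mean normalized
    read-count difference over its heterozygous genotypes is strictly
    greater than ``max_diff``. Sites with no heterozygous genotype pass
    vacuously. ``mode="band"``: remove when the mean heterozygous ALT
    fraction lies outside ``[(1-max_diff)/2, (1+max_diff)/2]``.
    """
    if mode not in ("diff_mean", "band"):
        raise ValueError("mode must be 'diff_mean' or 'band'")
    if mode == "diff_mean":
        diff = allelic_balance_diff(matrix)
        keep = ~(diff > max_diff)  # NaN (no hets) passes
    else:
        ad = matrix.allele_depths.astype(float)
        het = matrix.calls == Genotype.HET
        total = ad[..., 0] + ad[..., 1]
        valid = het & (ad[..., 0] >= 0) & (total > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(valid, ad[..., 1] / total, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_frac = np.nanmean(frac, axis=1)
        lo, hi = (1 - max_diff) / 2, (1 + max_diff) / 2
        keep = ~((mean_frac < lo) | (mean_frac > hi))
    out = matrix.subset_sites(keep)
    report = {
        "mode": mode,
        "max_diff": max_diff,
        "input_sites": matrix.n_sites,
        "retained": out.n_sites,
    }
    logger.info("apply_allelic_balance_filter: %s", report)
    return out, report


def run_filter_cascade(
    matrix: GenotypeMatrix,
    regions: Sequence[GeneRegion],
    profile: FilterProfile,
    target_depth: float,
) -> tuple[GenotypeMatrix, dict]:
    """Biallelic/exonic selection, hard filters, depth filter and (for
    profiles that define it) the allelic-balance filter, in order."""
    m, r1 = select_biallelic_exonic(matrix, regions)
    m, r2 = apply_hard_filters(m, profile)
    m, r3 = apply_depth_filter(m, target_depth)
    reports = {"biallelic_exonic": r1, "hard_filters": r2, "depth": r3}
    if profile.allelic_balance_max_diff is not None:
        m, r4 = apply_allelic_balance_filter(m, profile.allelic_balance_max_diff)
        reports["allelic_balance"] = r4
    return m, reports
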