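"""Genotype concordance between a high-depth reference call set (target
enrichment) and a test call set (down-sampled WGS).

Every (site, individual) pair of genotype states is assigned one of 16
letters A..P laid out row-major on a 4x4 grid: rows are the WGS state and
columns the target-enrichment state, both in the order (HOM_REF, HET,
HOM_ALT, MISSING). The diagonal letters A, F, K, P are matching states
('A' = both homozygous reference), the WGS-missing row is M, N, O and the
enrichment-missing column is D, H, L; the remaining six letters are
genuine genotype disagreements.

Four metrics partition the pair total: concordance (A+F+K+P), missing WGS
calls (M+N+O), missing target-enrichment calls (D+H+L) and non-concordance
(B+C+E+G+I+J), each divided by the total count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .formats_io import Genotype, GenotypeMatrix

LETTERS = "ABCDEFGHIJKLMNOP"

#: default 16-entry mapping (wgs_state, te_state) -> letter; overridable
#: by passing an explicit mapping to :func:`classify_genotype_pair`.
DEFAULT_GRID: dict[tuple[Genotype, Genotype], str] = {
    (Genotype(w), Genotype(t)): LETTERS[4 * w + t]
    for w in range(4)
    for t in range(4)
}

CONCORDANT = frozenset("AFKP")
MISSING_WGS = frozenset("MNO")
MISSING_TE = frozenset("DHL")
NON_CONCORDANT = frozenset("BCEGIJ")


@dataclass
class ConcordanceTable:
    """Counts of the 16 genotype-pair categories and the derived metrics."""

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in LETTERS})

    def __post_init__(self) -> None:
        full = {c: 0 for c in LETTERS}
        for k, v in self.counts.items():
            if k not in full:
                raise ValueError(f"unknown category {k!r}")
            if v < 0:
                raise ValueError("counts must be non-negative")
            full[k] = int(v)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def metrics(self, strict: bool = False) -> dict[str, float]:
        """The four printed ratios. With ``strict=True`` both-missing pairs
        (P) are excluded from both numerator and denominator, deflating the
        concordance metric; the default follows the printed equations."""
        return concordance_metrics(self, strict=strict)


def classify_genotype_pair(
    gt_te: Genotype | int,
    gt_wgs: Genotype | int,
    grid: dict[tuple[Genotype, Genotype], str] | None = None,
) -> str:
    """Letter A..P for one (target-enrichment, WGS) genotype state pair."""
    te, wgs = Genotype(gt_te), Genotype(gt_wgs)
    return (grid or DEFAULT_GRID)[(wgs, te)]


def align_sites(
    matrix_te: GenotypeMatrix, matrix_wgs: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict both call sets to the shared (chrom, pos, ref, alt) sites
    and the shared individuals, in a common order."""
    shared_inds = [i for i in matrix_te.individuals if i in set(matrix_wgs.individuals)]
    if not shared_inds:
        raise ValueError("no shared individuals between call sets")

    keys_te = matrix_te.site_keys()
    keys_wgs = matrix_wgs.site_keys()
    shared = [k for k in keys_te if k in set(keys_wgs)]
    if not shared:
        warnings.warn("no shared variant sites between call sets")
    order = {k: i for i, k in enumerate(shared)}

    def restrict(m: GenotypeMatrix, keys: list) -> GenotypeMatrix:
        keep = np.array([k in order for k in keys], dtype=bool)
        sub = m.subset_sites(keep)
        idx = np.argsort([order[k] for k in sub.site_keys()], kind="stable")
        sub = sub.subset_sites(np.ones(sub.n_sites, bool))  # copy
        sub.sites = [sub.sites[i] for i in idx]
        sub.calls = sub.calls[idx]
        if sub.depth is not None:
            sub.depth = sub.depth[idx]
        if sub.allele_depths is not None:
            sub.allele_depths = sub.allele_depths[idx]
        return sub.subset_individuals(shared_inds)

    return restrict(matrix_te, keys_te), restrict(matrix_wgs, keys_wgs)


def count_pairs(
    matrix_te: GenotypeMatrix, matrix_wgs: GenotypeMatrix
) -> ConcordanceTable:
    """Tally the 16 categories over aligned call sets (same sites and
    individuals, same order)."""
    if matrix_te.site_keys() != matrix_wgs.site_keys():
        raise ValueError("call sets are not aligned on sites; use align_sites")
    if matrix_te.individuals != matrix_wgs.individuals:
        raise ValueError("call sets are not aligned on individuals")
    idx = 4 * matrix_wgs.calls.astype(int) + matrix_te.calls.astype(int)
    binc = np.bincount(idx.ravel(), minlength=16)
    return ConcordanceTable({LETTERS[i]: int(binc[i]) for i in range(16)})


def concordance_metrics(table: ConcordanceTable, strict: bool = False) -> dict[str, float]:
    """Concordance, missing-WGS, missing-target-enrichment and
    non-concordance fractions; the four sum to 1."""
    counts = dict(table.counts)
    if strict:
        counts["P"] = 0
    total = sum(counts.values())
    if total == 0:
        raise ValueError("concordance metrics undefined for an empty table")

    def frac(letters) -> float:
        return sum(counts[c] for c in letters) / total

    return {
        "concordance": frac(CONCORDANT),
        "missing_wgs": frac(MISSING_WGS),
        "missing_te": frac(MISSING_TE),
        "non_concordance": frac(NON_CONCORDANT),
    }


def compare_call_sets(
    matrix_te: GenotypeMatrix, matrix_wgs: GenotypeMatrix, strict: bool = False
) -> dict:
    """Align, tally and summarize two call sets in one step."""
    te, wgs = align_sites(matrix_te, matrix_wgs)
    table = count_pairs(te, wgs)
    out = {
        "n_shared_sites": te.n_sites,
        "n_individuals": te.n_individuals,
        "counts": dict(table.counts),
    }
    if table.total:
        out["metrics"] = table.metrics(strict=strict)
    return out
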