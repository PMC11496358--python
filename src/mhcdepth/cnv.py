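"""Read-depth copy-number estimation normalized against single-copy genes.

Reads spanning a gene are converted to reads per kilobase (RPK); the RPK
of each target gene is divided by the mean RPK of the single-copy
reference genes (the TLR panel) and multiplied by two, giving an allelic
copy number (ACN) in which 2 means a diploid single-copy gene. Individuals
with ACN in the closed band [1.5, 2.5] are called single copy; ACN outside
the band flags copy-number variation (deletion below, duplication above).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import CoverageSummary, GeneRegion

SINGLE_COPY_BAND = (1.5, 2.5)


@dataclass(frozen=True)
class CopyNumberCall:
    gene_id: str
    individual: str
    rpk: float
    acn: float
    copy_class: int
    single_copy: bool


def rpk(read_count: int, gene_length_bp: int) -> float:
    """Reads per kilobase: ``read_count / (gene_length_bp / 1000)``."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if read_count < 0:
        raise ValueError("read count must be non-negative")
    return read_count / (gene_length_bp / 1000.0)


def allelic_copy_number(rpk_gene: float, rpk_reference_genes: Sequence[float]) -> float:
    """``2 * rpk_gene / mean(reference RPKs)``; 2 = diploid single copy."""
    refs = np.asarray(list(rpk_reference_genes), dtype=float)
    if refs.size == 0:
        raise ValueError("need at least one reference gene")
    mean_ref = refs.mean()
    if mean_ref <= 0:
        raise ValueError("all reference RPK values are zero: individual uncallable")
    return 2.0 * rpk_gene / mean_ref


def classify_copy_number(acn: float) -> tuple[int, bool]:
    """Copy class 0-6 with bin edges at n +/- 0.5 and the printed
    single-copy band closed at both ends.

    Bins are closed-left/open-right ([1.5, 2.5) -> 2, [2.5, 3.5) -> 3, ...)
    except that ACN exactly 2.5 resolves to the single-copy class 2, the
    inclusive reading of the printed 1.5-2.5 band. Classes clamp to 6.
    """
    if acn < 0:
        raise ValueError("allelic copy number must be non-negative")
    lo, hi = SINGLE_COPY_BAND
    single = lo <= acn <= hi
    cls = 2 if single else min(6, int(np.floor(acn + 0.5)))
    return cls, single


def acn_table(
    coverage: CoverageSummary,
    regions: Sequence[GeneRegion],
    reference: str = "mean",
) -> pd.DataFrame:
    """Tidy long-format copy-number table (gene, individual, rpk, acn,
    copy_class, single_copy) for every gene in ``regions``.

    Normalization uses the ``single_copy_reference`` genes of ``regions``;
    ``reference`` selects mean (the default) or median aggregation across
    them. Individuals whose reference RPKs are all zero are dropped with a
    warning.
    """
    if reference not in ("mean", "median"):
        raise ValueError("reference must be 'mean' or 'median'")
    ref_genes = [r.gene_id for r in regions if r.single_copy_reference]
    if not ref_genes:
        raise ValueError("no single-copy reference genes in regions")
    df = coverage.df.copy()
    df["rpk"] = df.read_count / (df.gene_length_bp / 1000.0)
    ref = df[df.gene_id.isin(ref_genes)].groupby("individual")["rpk"]
    ref_stat = ref.mean() if reference == "mean" else ref.median()

    rows = []
    gene_ids = [r.gene_id for r in regions]
    for _, row in df[df.gene_id.isin(gene_ids)].iterrows():
        denom = ref_stat.get(row.individual, 0.0)
        if denom <= 0:
            continue
        acn = 2.0 * row.rpk / denom
        cls, single = classify_copy_number(acn)
        rows.append((row.gene_id, row.individual, row.rpk, acn, cls, single))
    dropped = set(df.individual) - {r[1] for r in rows}
    if dropped:
        warnings.warn(
            f"{len(dropped)} individual(s) uncallable (zero reference coverage)"
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "individual", "rpk", "acn", "copy_class", "single_copy"]
    )


def leave_one_out_reference_acn(
    coverage: CoverageSummary, regions: Sequence[GeneRegion]
) -> pd.DataFrame:
    """Self-test of the estimator: each single-copy reference gene's ACN
    normalized by the remaining references. Values should sit in the
    single-copy band."""
    ref_genes = [r.gene_id for r in regions if r.single_copy_reference]
    if len(ref_genes) < 2:
        raise ValueError("need at least two reference genes")
    df = coverage.df[coverage.df.gene_id.isin(ref_genes)].copy()
    df["rpk"] = df.read_count / (df.gene_length_bp / 1000.0)
    wide = df.pivot(index="individual", columns="gene_id", values="rpk")
    rows = []
    for g in ref_genes:
        others = wide.drop(columns=g).mean(axis=1)
        acn = 2.0 * wide[g] / others
        for ind, v in acn.items():
            rows.append((g, ind, float(v)))
    return pd.DataFrame(rows, columns=["gene_id", "individual", "acn"])


def call_cnv_genes(
    acn: pd.DataFrame,
    band: tuple[float, float] = SINGLE_COPY_BAND,
    min_fraction: float = 0.0,
) -> set[str]:
    """Genes with copy-number variation: any individual (or at least
    ``min_fraction`` of individuals) with ACN outside the single-copy band."""
    if acn.individual.nunique() < 2:
        raise ValueError("need at least two individuals to call CNV genes")
    lo, hi = band
    out: set[str] = set()
    for gene, sub in acn.groupby("gene_id"):
        outside = ((sub.acn < lo) | (sub.acn > hi)).mean()
        if (outside > 0 and min_fraction == 0.0) or outside >= min_fraction > 0:
            out.add(str(gene))
    return out
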