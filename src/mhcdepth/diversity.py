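"""Allele assignment from phased haplotypes and per-gene diversity
statistics: nucleotide diversity, Nei allelic (haplotype) diversity, SNP
effect classification and Weir-Cockerham F_ST.

Allele labels follow the convention of phasing-based surveys: unique
sequences become alleles H1, H2, ... ordered by descending count (ties
broken by sequence lexicographic order). Alleles at sample frequency below
0.005 are dropped before diversity statistics are computed, mirroring the
rare-allele rule of the survey design (at 900 phased sequences the largest
excluded count is 4).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .formats_io import GeneRegion, Genotype, GenotypeMatrix, HaplotypeSet

RARE_ALLELE_MIN_FREQ = 0.005


@dataclass
class AlleleTable:
    """Alleles of one gene with per-region counts.

    ``alleles`` maps label -> sequence in label order (H1 first);
    ``counts`` is a label x region integer table.
    """

    gene_id: str
    alleles: dict[str, str]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.alleles):
            raise ValueError("counts index must match allele labels")
        if (self.counts.values < 0).any():
            raise ValueError("negative allele counts")

    @property
    def n_sequences(self) -> int:
        return int(self.counts.values.sum())

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def frequencies(self) -> pd.DataFrame:
        """Per-region allele frequencies (columns sum to 1)."""
        col = self.counts.sum(axis=0)
        return self.counts / col.replace(0, np.nan)


@dataclass(frozen=True)
class GeneDiversityStats:
    gene_id: str
    n: int
    n_snps: int
    n_snps_nonsynonymous: int
    pi: float
    n_alleles: int
    allelic_diversity: float

    def __post_init__(self) -> None:
        if not (0 <= self.pi <= 1 and 0 <= self.allelic_diversity <= 1):
            raise ValueError("diversity statistics must lie in [0, 1]")
        if self.n_snps_nonsynonymous > self.n_snps:
            raise ValueError("non-synonymous SNPs exceed total SNPs")


def assign_alleles(
    haplotypes: HaplotypeSet,
    region_labels: Mapping[str, str] | None = None,
) -> AlleleTable:
    """Collapse phased sequences into labelled alleles with per-region counts.

    Unresolved sequences (ambiguity codes) must be removed beforehand;
    their presence is a precondition violation.
    """
    if haplotypes.unresolved():
        raise ValueError(
            f"{haplotypes.gene_id}: unresolved sequences present; "
            "drop_unresolved() before allele assignment"
        )
    if not haplotypes.entries:
        raise ValueError(f"{haplotypes.gene_id}: empty haplotype set")

    region_of = dict(region_labels or {})
    counts: dict[str, dict[str, int]] = {}
    for ind, _hap, seq in haplotypes.entries:
        reg = region_of.get(ind, "all")
        counts.setdefault(seq, {})
        counts[seq][reg] = counts[seq].get(reg, 0) + 1

    totals = {seq: sum(c.values()) for seq, c in counts.items()}
    ordered = sorted(counts, key=lambda s: (-totals[s], s))
    labels = [f"H{i + 1}" for i in range(len(ordered))]
    regions = sorted({r for c in counts.values() for r in c})
    table = pd.DataFrame(
        [[counts[seq].get(r, 0) for r in regions] for seq in ordered],
        index=labels,
        columns=regions,
        dtype=int,
    )
    return AlleleTable(
        gene_id=haplotypes.gene_id,
        alleles=dict(zip(labels, ordered)),
        counts=table,
    )


def filter_rare_alleles(
    table: AlleleTable, min_freq: float = RARE_ALLELE_MIN_FREQ
) -> AlleleTable:
    """Drop alleles whose sample frequency is strictly below ``min_freq``
    (at n=900 this removes counts of four or fewer). Surviving labels keep
    their original names and order."""
    n = table.n_sequences
    if n == 0:
        raise ValueError("empty allele table")
    totals = table.total_counts()
    keep = [lab for lab in table.alleles if totals[lab] / n >= min_freq]
    if not keep:
        raise ValueError("all alleles fall below the frequency threshold")
    return AlleleTable(
        gene_id=table.gene_id,
        alleles={lab: table.alleles[lab] for lab in keep},
        counts=table.counts.loc[keep],
    )


def _seq_matrix(sequences: Sequence[str]) -> np.ndarray:
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequence length mismatch: {sorted(lengths)}")
    return np.frombuffer(
        "".join(sequences).upper().encode(), dtype=np.uint8
    ).reshape(len(sequences), -1)


def nucleotide_diversity(haplotypes: HaplotypeSet | Sequence[str]) -> float:
    """Mean over all unordered sequence pairs of the per-site difference
    fraction (Hamming distance / length)."""
    seqs = haplotypes.sequences() if isinstance(haplotypes, HaplotypeSet) else list(haplotypes)
    n = len(seqs)
    if n < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    mat = _seq_matrix(seqs)
    L = mat.shape[1]
    # per-site pair differences from base counts: (n^2 - sum c_b^2) / 2
    diffs = 0.0
    for b in np.unique(mat):
        diffs -= np.sum((mat == b).sum(axis=0).astype(float) ** 2)
    diffs = (diffs + L * n * n) / 2.0
    n_pairs = n * (n - 1) / 2.0
    return float(diffs / (n_pairs * L))


def allelic_diversity(counts: Sequence[int] | pd.Series) -> float:
    """Nei haplotype diversity ``h = n/(n-1) * (1 - sum p_i^2)``."""
    c = np.asarray(list(counts), dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise ValueError("allelic diversity needs at least two sequences")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def classify_snp_effect(site, region: GeneRegion, reference_seq: str) -> str:
    """Synonymous / nonsynonymous status of one exonic SNV.

    ``site`` needs ``pos`` (1-based genomic), ``ref`` and ``alt``;
    ``reference_seq`` is the plus-strand concatenation of the gene's exons.
    Positions in a partial codon (codon phase unknown or codon truncated at
    the exon boundary) come back ``"indeterminate"``.
    """
    offset = region.exonic_offset(site.pos)
    frame = (region.frame_offsets or (0,))[0]
    return classify_site_effects(
        reference_seq, [(offset, site.ref, site.alt)], region.strand, frame
    )[0]


def classify_site_effects(
    reference_seq: str,
    sites: Sequence[tuple[int, str, str]],
    strand: str = "+",
    frame_offset: int = 0,
) -> list[str]:
    """Classify substitutions as synonymous / nonsynonymous / indeterminate.

    ``reference_seq`` is the plus-strand concatenation of the gene's exons;
    each site is ``(offset, ref_base, alt_base)`` in that coordinate system.
    For minus-strand genes the coding sequence is the reverse complement
    and substituted bases are complemented before translation.
    ``frame_offset`` (0-2) is the codon phase at the coding-strand start.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    L = len(reference_seq)
    cds = str(Seq(reference_seq).reverse_complement()) if strand == "-" else reference_seq
    out = []
    for offset, ref_base, alt_base in sites:
        if not 0 <= offset < L:
            raise ValueError(f"offset {offset} outside sequence")
        if reference_seq[offset].upper() != ref_base.upper():
            raise ValueError(
                f"reference mismatch at offset {offset}: "
                f"{reference_seq[offset]} != {ref_base}"
            )
        if strand == "+":
            cds_off = offset
            sub = alt_base.upper()
        else:
            cds_off = L - 1 - offset
            sub = str(Seq(alt_base.upper()).complement())
        rel = cds_off - frame_offset
        if rel < 0:
            out.append("indeterminate")
            continue
        codon_start = frame_offset + 3 * (rel // 3)
        if codon_start + 3 > len(cds):
            out.append("indeterminate")
            continue
        codon = cds[codon_start : codon_start + 3]
        pos_in_codon = cds_off - codon_start
        alt_codon = codon[:pos_in_codon] + sub + codon[pos_in_codon + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        out.append("synonymous" if aa_ref == aa_alt else "nonsynonymous")
    return out


def weir_cockerham_fst(
    matrix: GenotypeMatrix, region_labels: Sequence[str] | None = None
) -> tuple[pd.DataFrame, float]:
    """Weir & Cockerham (1984) variance components per biallelic site and
    the mean weighted estimate ``sum(a) / sum(a + b + c)``.

    Monomorphic sites contribute zero components and drop from the sums.
    Returns the per-site component table and the overall estimate.
    """
    labels = list(region_labels or matrix.region_labels or [])
    if len(labels) != matrix.n_individuals:
        raise ValueError("region labels missing or wrong length")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least two regions")
    idx = {g: np.array([i for i, l in enumerate(labels) if l == g]) for g in groups}

    rows = []
    for i, site in enumerate(matrix.sites):
        calls = matrix.calls[i]
        n_i, p_i, h_i = [], [], []
        for g in groups:
            sub = calls[idx[g]]
            called = sub != Genotype.MISSING
            n = int(called.sum())
            if n == 0:
                continue
            het = int((sub == Genotype.HET).sum())
            alt = int((sub == Genotype.HOM_ALT).sum())
            n_i.append(n)
            p_i.append((2 * alt + het) / (2 * n))
            h_i.append(het / n)
        r = len(n_i)
        if r < 2:
            continue
        n_i = np.array(n_i, float)
        p_i = np.array(p_i)
        h_i = np.array(h_i)
        n_bar = n_i.mean()
        if n_bar <= 1:
            continue
        n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
        if n_c <= 0:
            continue
        p_bar = (n_i * p_i).sum() / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (r * n_bar)
        pq = p_bar * (1 - p_bar)
        a = (n_bar / n_c) * (
            s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        if a + b + c == 0:
            continue  # monomorphic
        rows.append((site.chrom, site.pos, site.ref, site.alt, a, b, c,
                     a / (a + b + c)))
    per_site = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "a", "b", "c", "fst"]
    )
    if per_site.empty:
        return per_site, float("nan")
    overall = per_site.a.sum() / (per_site.a + per_site.b + per_site.c).sum()
    return per_site, float(overall)


def pairwise_fst(
    matrix: GenotypeMatrix, region_labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean weighted F_ST between every pair of regions (symmetric table
    with NaN diagonal), the layout of a between-cluster differentiation
    table."""
    labels = list(region_labels or matrix.region_labels or [])
    groups = sorted(set(labels))
    out = pd.DataFrame(np.nan, index=groups, columns=groups)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            ids = [
                ind
                for ind, l in zip(matrix.individuals, labels)
                if l in (g1, g2)
            ]
            sub = matrix.subset_individuals(ids)
            sub_labels = [l for l in labels if l in (g1, g2)]
            _, fst = weir_cockerham_fst(sub, sub_labels)
            out.loc[g1, g2] = out.loc[g2, g1] = fst
    return out


def gene_diversity_stats(
    haplotypes: HaplotypeSet,
    region: GeneRegion | None = None,
    region_labels: Mapping[str, str] | None = None,
    min_freq: float = RARE_ALLELE_MIN_FREQ,
) -> GeneDiversityStats:
    """Table-1-style summary for one gene: drop unresolved sequences,
    assign and rare-filter alleles, then compute N, SNP counts (with
    synonymous / nonsynonymous classification when ``region`` provides
    strand and frame), pi and allelic diversity."""
    hs = haplotypes.drop_unresolved()
    table = filter_rare_alleles(assign_alleles(hs, region_labels), min_freq)
    totals = table.total_counts()
    seqs = []
    for lab, seq in table.alleles.items():
        seqs.extend([seq] * int(totals[lab]))

    allele_seqs = list(table.alleles.values())
    mat = _seq_matrix(allele_seqs)
    segregating = [
        j for j in range(mat.shape[1]) if len(np.unique(mat[:, j])) > 1
    ]
    n_ns = 0
    if segregating:
        strand = region.strand if region else "+"
        frame = (region.frame_offsets or (0,))[0] if region else 0
        consensus = "".join(
            chr(np.bincount(mat[:, j]).argmax()) for j in range(mat.shape[1])
        )
        site_specs = []
        for j in segregating:
            bases = [chr(b) for b in np.unique(mat[:, j])]
            ref = consensus[j]
            alt = next(b for b in bases if b != ref)
            site_specs.append((j, ref, alt))
        effects = classify_site_effects(consensus, site_specs, strand, frame)
        n_ns = sum(e == "nonsynonymous" for e in effects)

    return GeneDiversityStats(
        gene_id=haplotypes.gene_id,
        n=table.n_sequences,
        n_snps=len(segregating),
        n_snps_nonsynonymous=n_ns,
        pi=nucleotide_diversity(seqs) if len(seqs) >= 2 else 0.0,
        n_alleles=table.n_alleles,
        allelic_diversity=allelic_diversity(totals) if len(seqs) >= 2 else 0.0,
    )


_AGG_COLS = ["n_snps", "n_snps_nonsynonymous", "n_alleles", "pi", "allelic_diversity"]


def aggregate_gene_table(stats: pd.DataFrame | Sequence[GeneDiversityStats]) -> dict:
    """Column summaries (sum, mean to 2 decimals, min, max) overall and by
    MHC class for a per-gene diversity table.

    Accepts a DataFrame with a ``mhc_class`` column ('I'/'II') or a list of
    :class:`GeneDiversityStats` (then only the overall block is produced).
    """
    if not isinstance(stats, pd.DataFrame):
        if not stats:
            raise ValueError("empty stats")
        stats = pd.DataFrame([s.__dict__ for s in stats])
    if stats.empty:
        raise ValueError("empty stats")

    def block(df: pd.DataFrame) -> dict:
        out: dict[str, dict[str, float]] = {"n_genes": len(df)}
        for col in _AGG_COLS:
            if col not in df.columns:
                continue
            vals = df[col]
            summary = {
                "sum": float(vals.sum()),
                "mean": round(float(vals.mean()), 2),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
            if vals.dtype.kind in "iu":
                summary["sum"] = int(vals.sum())
                summary["min"] = int(vals.min())
                summary["max"] = int(vals.max())
            out[col] = summary
        return out

    result = {"overall": block(stats)}
    if "mhc_class" in stats.columns:
        for cls, sub in stats.groupby("mhc_class"):
            result[f"class_{cls}"] = block(sub)
    return result


def load_koala_gene_table() -> pd.DataFrame:
    """The published per-gene diversity table for the 24 polymorphic koala
    MHC genes (survey of 438 wild koalas), shipped as package data."""
    ref = importlib.resources.files("mhcdepth") / "data" / "koala_mhc_diversity.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
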