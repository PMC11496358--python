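"""Domain types and readers/writers for the formats the pipeline touches.

Coordinate conventions
----------------------
Gene/exon intervals are 0-based half-open (BED convention). VCF positions
are 1-based. A variant at VCF position ``p`` falls in exon ``(s, e)`` iff
``s <= p - 1 < e``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("mhcdepth")


class Genotype(IntEnum):
    """Diploid genotype state of one individual at one biallelic site."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3


class GeneFamily(str, Enum):
    MHC_I = "MHC_I"
    MHC_II_A = "MHC_II_A"
    MHC_II_B = "MHC_II_B"
    TLR = "TLR"

    @property
    def is_class_i(self) -> bool:
        return self is GeneFamily.MHC_I

    @property
    def is_class_ii(self) -> bool:
        return self in (GeneFamily.MHC_II_A, GeneFamily.MHC_II_B)


@dataclass(frozen=True)
class GeneRegion:
    """A named gene with its exon intervals and family annotation.

    Exons are 0-based half-open on ``chrom``, sorted, non-overlapping.
    ``frame_offsets`` gives the codon phase (0-2) at the start of each exon,
    in transcription order (5'->3' of the coding strand).
    """

    gene_id: str
    chrom: str
    exons: tuple[tuple[int, int], ...]
    family: GeneFamily
    single_copy_reference: bool = False
    strand: str = "+"
    frame_offsets: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = -1
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if self.length < 3:
            raise ValueError(f"{self.gene_id}: total exon length < 3")
        fo = (
            tuple(0 for _ in exons)
            if self.frame_offsets is None
            else tuple(int(f) for f in self.frame_offsets)
        )
        if len(fo) != len(exons) or any(f not in (0, 1, 2) for f in fo):
            raise ValueError(f"{self.gene_id}: bad frame_offsets {fo}")
        object.__setattr__(self, "frame_offsets", fo)

    @property
    def length(self) -> int:
        """Total exonic length in bp."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def contains(self, pos_1based: int) -> bool:
        """True if the 1-based (VCF) position falls inside an exon."""
        p = pos_1based - 1
        return any(s <= p < e for s, e in self.exons)

    def genomic_pos(self, offset: int) -> int:
        """1-based genomic position of an offset into the concatenated exons
        (plus-strand orientation). Inverse of :meth:`exonic_offset`."""
        if offset < 0:
            raise ValueError("negative exonic offset")
        for s, e in self.exons:
            if offset < e - s:
                return s + offset + 1
            offset -= e - s
        raise ValueError(f"offset beyond exonic length of {self.gene_id}")

    def exonic_offset(self, pos_1based: int) -> int:
        """Offset of a 1-based position within the concatenated exons
        (plus-strand orientation)."""
        p = pos_1based - 1
        off = 0
        for s, e in self.exons:
            if s <= p < e:
                return off + (p - s)
            off += e - s
        raise ValueError(f"position {pos_1based} not exonic in {self.gene_id}")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic variant site with the annotations the filters use."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: float = float("nan")
    mq: float = float("nan")
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None
    gene_id: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_biallelic_snv(self) -> bool:
        return (
            "," not in self.alt
            and len(self.ref) == 1
            and len(self.alt) == 1
            and self.alt in "ACGT"
        )


@dataclass
class GenotypeMatrix:
    """Sites x individuals genotype calls with depths and allele depths.

    ``calls`` holds :class:`Genotype` codes (int8). ``depth`` is total read
    depth per call; ``allele_depths[..., 0]`` / ``[..., 1]`` are ref / alt
    read counts and sum to ``depth`` wherever present (-1 marks absent).
    """

    sites: list[SiteRecord]
    individuals: list[str]
    calls: np.ndarray
    depth: np.ndarray | None = None
    allele_depths: np.ndarray | None = None
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        n_s, n_i = len(self.sites), len(self.individuals)
        self.calls = np.asarray(self.calls, dtype=np.int8).reshape(n_s, n_i)
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int64).reshape(n_s, n_i)
        if self.allele_depths is not None:
            self.allele_depths = np.asarray(self.allele_depths, dtype=np.int64).reshape(
                n_s, n_i, 2
            )
        if self.region_labels is not None and len(self.region_labels) != n_i:
            raise ValueError("region_labels length != number of individuals")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def site_keys(self) -> list[tuple[str, int, str, str]]:
        return [s.key for s in self.sites]

    def subset_sites(self, keep: Sequence[bool] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=bool)
        return GenotypeMatrix(
            sites=[s for s, k in zip(self.sites, keep) if k],
            individuals=list(self.individuals),
            calls=self.calls[keep],
            depth=None if self.depth is None else self.depth[keep],
            allele_depths=None
            if self.allele_depths is None
            else self.allele_depths[keep],
            region_labels=None
            if self.region_labels is None
            else list(self.region_labels),
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in ids]
        return GenotypeMatrix(
            sites=list(self.sites),
            individuals=[self.individuals[i] for i in idx],
            calls=self.calls[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            allele_depths=None
            if self.allele_depths is None
            else self.allele_depths[:, idx],
            region_labels=None
            if self.region_labels is None
            else [self.region_labels[i] for i in idx],
        )


@dataclass
class CoverageSummary:
    """Per (gene, individual) read counts, mirroring ``samtools coverage``."""

    df: pd.DataFrame  # columns: gene_id, individual, read_count, bases_covered, gene_length_bp

    REQUIRED = ("gene_id", "individual", "read_count", "bases_covered", "gene_length_bp")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ValueError(f"coverage table missing columns: {sorted(missing)}")
        if (self.df["read_count"] < 0).any() or (self.df["bases_covered"] < 0).any():
            raise ValueError("negative counts in coverage table")
        if (self.df["bases_covered"] > self.df["gene_length_bp"]).any():
            raise ValueError("bases_covered exceeds gene_length_bp")
        if self.df.duplicated(["gene_id", "individual"]).any():
            raise ValueError("duplicate (gene_id, individual) rows in coverage table")

    def read_count(self, gene_id: str, individual: str) -> int:
        row = self.df[(self.df.gene_id == gene_id) & (self.df.individual == individual)]
        if row.empty:
            raise KeyError((gene_id, individual))
        return int(row.read_count.iloc[0])


@dataclass
class HaplotypeSet:
    """Phased per-gene sequences: up to two haplotypes per individual.

    A haplotype is *unresolved* when it contains any non-ACGT character.
    Individuals missing a mate haplotype are flagged incomplete.
    """

    gene_id: str
    entries: list[tuple[str, int, str]]  # (individual, hap_index in {1,2}, sequence)

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, _, seq in self.entries}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.gene_id}: haplotype length mismatch {sorted(lengths)}"
            )
        seen: set[tuple[str, int]] = set()
        for ind, hap, _ in self.entries:
            if (ind, hap) in seen:
                raise ValueError(f"{self.gene_id}: duplicate haplotype {ind}/{hap}")
            seen.add((ind, hap))

    @property
    def sequence_length(self) -> int:
        return len(self.entries[0][2]) if self.entries else 0

    def unresolved(self) -> list[tuple[str, int]]:
        return [
            (ind, hap)
            for ind, hap, seq in self.entries
            if set(seq.upper()) - set("ACGT")
        ]

    def incomplete_individuals(self) -> list[str]:
        haps: dict[str, set[int]] = {}
        for ind, hap, _ in self.entries:
            haps.setdefault(ind, set()).add(hap)
        return sorted(ind for ind, hs in haps.items() if hs != {1, 2})

    def drop_unresolved(self) -> "HaplotypeSet":
        bad = set(self.unresolved())
        return HaplotypeSet(
            self.gene_id,
            [(i, h, s) for i, h, s in self.entries if (i, h) not in bad],
        )

    def sequences(self) -> list[str]:
        return [seq for _, _, seq in self.entries]


# ---------------------------------------------------------------------------
# Readers / writers


class VcfParseError(ValueError):
    pass


_GT_MAP = {
    (0, 0): Genotype.HOM_REF,
    (0, 1): Genotype.HET,
    (1, 0): Genotype.HET,
    (1, 1): Genotype.HOM_ALT,
}


def read_vcf(path: str | Path, regions: Sequence[GeneRegion]) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Only biallelic SNVs whose position lies inside an exon of one of
    ``regions`` are retained; records on contigs absent from ``regions``
    are skipped with a warning.
    """
    from cyvcf2 import VCF

    known_chroms = {r.chrom for r in regions}
    by_chrom: dict[str, list[GeneRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    individuals = list(vcf.samples)
    sites: list[SiteRecord] = []
    calls_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    ad_rows: list[np.ndarray] = []
    unknown_contigs: set[str] = set()

    for var in vcf:
        if var.CHROM not in known_chroms:
            if var.CHROM not in unknown_contigs:
                unknown_contigs.add(var.CHROM)
                warnings.warn(f"skipping records on unknown contig {var.CHROM}")
            continue
        if len(var.ALT) != 1:
            continue  # multi-allelic excluded by construction
        gene = next(
            (r for r in by_chrom[var.CHROM] if r.contains(var.POS)), None
        )
        if gene is None:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
            continue

        info = var.INFO
        site = SiteRecord(
            chrom=var.CHROM,
            pos=var.POS,
            ref=ref,
            alt=alt,
            qual=float(var.QUAL) if var.QUAL is not None else float("nan"),
            mq=float(info.get("MQ", float("nan"))),
            mq_rank_sum=_opt_float(info.get("MQRankSum")),
            read_pos_rank_sum=_opt_float(info.get("ReadPosRankSum")),
            gene_id=gene.gene_id,
        )
        n = len(individuals)
        row = np.full(n, Genotype.MISSING, dtype=np.int8)
        for j, g in enumerate(var.genotypes):
            a, b = g[0], g[1] if len(g) > 2 else -1
            state = _GT_MAP.get((a, b))
            if state is not None:
                row[j] = state
        dp = var.format("DP")
        if dp is None:
            drow = np.zeros(n, dtype=np.int64)
        else:
            drow = np.clip(dp.reshape(-1).astype(np.int64), 0, None)
        ad = var.format("AD")
        if ad is None:
            arow = np.full((n, 2), -1, dtype=np.int64)
        else:
            arow = np.clip(ad.astype(np.int64)[:, :2], -1, None)
        sites.append(site)
        calls_rows.append(row)
        depth_rows.append(drow)
        ad_rows.append(arow)

    n = len(individuals)
    return GenotypeMatrix(
        sites=sites,
        individuals=individuals,
        calls=np.array(calls_rows, dtype=np.int8).reshape(len(sites), n),
        depth=np.array(depth_rows, dtype=np.int64).reshape(len(sites), n),
        allele_depths=np.array(ad_rows, dtype=np.int64).reshape(len(sites), n, 2),
    )


def _opt_float(x) -> float | None:
    if x is None:
        return None
    try:
        return float(x)
    except (TypeError, ValueError):
        return None


_GT_STR = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 preserving genotypes, depths and the site
    annotations the filter cascade reads."""
    path = Path(path)
    contigs = sorted({s.chrom for s in matrix.sites})
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mhcdepth\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">\n')
        fh.write('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        for i, s in enumerate(matrix.sites):
            info = []
            if not np.isnan(s.mq):
                info.append(f"MQ={s.mq:g}")
            if s.mq_rank_sum is not None:
                info.append(f"MQRankSum={s.mq_rank_sum:g}")
            if s.read_pos_rank_sum is not None:
                info.append(f"ReadPosRankSum={s.read_pos_rank_sum:g}")
            if s.gene_id:
                info.append(f"GENE={s.gene_id}")
            qual = "." if np.isnan(s.qual) else f"{s.qual:g}"
            cols = [s.chrom, str(s.pos), ".", s.ref, s.alt, qual, "PASS",
                    ";".join(info) or ".", "GT:DP:AD"]
            for j in range(matrix.n_individuals):
                gt = _GT_STR[Genotype(matrix.calls[i, j])]
                dp = 0 if matrix.depth is None else int(matrix.depth[i, j])
                if matrix.allele_depths is None or matrix.allele_depths[i, j, 0] < 0:
                    ad = ".,."
                else:
                    ad = f"{matrix.allele_depths[i, j, 0]},{matrix.allele_depths[i, j, 1]}"
                cols.append(f"{gt}:{dp}:{ad}")
            fh.write("\t".join(cols) + "\n")


def read_coverage_table(path: str | Path) -> CoverageSummary:
    """Read a TSV with columns gene_id, individual, read_count,
    bases_covered, gene_length_bp."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        warnings.warn(f"coverage table {path} is empty")
        df = pd.DataFrame(columns=list(CoverageSummary.REQUIRED))
    return CoverageSummary(df)


def write_coverage_table(cov: CoverageSummary, path: str | Path) -> None:
    cov.df.to_csv(path, sep="\t", index=False)


def read_haplotypes(path_fasta: str | Path) -> dict[str, HaplotypeSet]:
    """Read phased haplotype FASTA with headers ``{individual}__{gene}__{1|2}``.

    Returns one :class:`HaplotypeSet` per gene. Sequences with ambiguity
    codes are kept but flagged by :meth:`HaplotypeSet.unresolved`.
    """
    per_gene: dict[str, list[tuple[str, int, str]]] = {}
    for rec in SeqIO.parse(str(path_fasta), "fasta"):
        parts = rec.id.split("__")
        if len(parts) != 3 or parts[2] not in ("1", "2"):
            raise ValueError(
                f"bad haplotype header {rec.id!r}; expected individual__gene__1|2"
            )
        ind, gene, hap = parts[0], parts[1], int(parts[2])
        per_gene.setdefault(gene, []).append((ind, hap, str(rec.seq).upper()))
    return {g: HaplotypeSet(g, entries) for g, entries in per_gene.items()}


def write_haplotypes(sets: Iterable[HaplotypeSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for hs in sets:
            for ind, hap, seq in hs.entries:
                fh.write(f">{ind}__{hs.gene_id}__{hap}\n{seq}\n")


_REGION_COLS = [
    "chrom", "start", "end", "gene_id", "family",
    "single_copy_reference", "strand", "frame_offset",
]


def read_regions(path: str | Path) -> list[GeneRegion]:
    """Read a BED-like TSV of exons (one row per exon, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_REGION_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    out: list[GeneRegion] = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        sub = sub.sort_values("start")
        out.append(
            GeneRegion(
                gene_id=str(gene_id),
                chrom=str(sub.chrom.iloc[0]),
                exons=tuple(zip(sub.start.astype(int), sub.end.astype(int))),
                family=GeneFamily(sub.family.iloc[0]),
                single_copy_reference=bool(sub.single_copy_reference.iloc[0]),
                strand=str(sub.strand.iloc[0]),
                frame_offsets=tuple(sub.frame_offset.astype(int)),
            )
        )
    return out


def write_regions(regions: Sequence[GeneRegion], path: str | Path) -> None:
    rows = []
    for r in regions:
        fo = r.frame_offsets or tuple(0 for _ in r.exons)
        for (s, e), f in zip(r.exons, fo):
            rows.append((r.chrom, s, e, r.gene_id, r.family.value,
                         r.single_copy_reference, r.strand, f))
    pd.DataFrame(rows, columns=_REGION_COLS).to_csv(path, sep="\t", index=False)
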