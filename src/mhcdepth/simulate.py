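"""Synthetic diploid populations for exercising the depth/diversity pipeline.

The generator emulates the statistical structure the downstream analyses
assume: region-structured allele frequencies at a panel of exonic immune
genes, copy-number genotypes (0-6 allelic copies) at CNV-prone genes,
single-copy reference genes held at two copies, and depth-dependent
genotype missingness and error across a ladder of target sequencing
depths. It does not attempt coalescent realism or read-level simulation.

Model sketch
------------
* Each gene gets an ancestral exonic sequence built from sense codons and a
  Poisson number of segregating sites; alleles are mutation patterns over
  those sites, so synonymous/non-synonymous status emerges from the code.
* Regional allele frequencies are softmax-transformed log-abundances:
  a shared per-allele baseline plus, when ``distance_decay`` is on, a
  per-allele cline term that grows linearly along the sampling transect,
  both scaled by the differentiation parameter ``d`` in [0, 1). ``d = 0``
  collapses every region onto one frequency vector (F_ST = 0); larger
  ``d`` increases both differentiation and isolation by distance. With
  ``distance_decay=False`` regional deviations are i.i.d. instead, giving
  structure without a geographic gradient.
* Per-site read depth is Poisson(target depth x copies/2); a genotype is
  callable only with >= ``min_reads_to_call`` reads, and a heterozygote
  whose reads all landed on one allele is miscalled homozygous, giving the
  miscall probability 2 x 0.5^depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    CoverageSummary,
    GeneFamily,
    GeneRegion,
    Genotype,
    GenotypeMatrix,
    HaplotypeSet,
    SiteRecord,
    write_coverage_table,
    write_haplotypes,
    write_regions,
    write_vcf,
)

DEPTH_LADDER = (0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0)

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimGene:
    """Per-gene simulation settings.

    ``copy_number_probs`` maps allelic copy number (0-6) to probability;
    ``None`` means the gene is always present in single copy (two allelic
    copies). A list of such maps gives one distribution per region.
    """

    region: GeneRegion
    n_alleles: int = 8
    mutation_rate: float = 0.01  # expected segregating sites per exonic bp
    copy_number_probs: Mapping[int, float] | Sequence[Mapping[int, float]] | None = None

    def probs_for_region(self, r: int, n_regions: int) -> dict[int, float] | None:
        p = self.copy_number_probs
        if p is None:
            return None
        if isinstance(p, Mapping):
            return dict(p)
        if len(p) != n_regions:
            raise ValueError(
                f"{self.region.gene_id}: per-region copy-number probs length "
                f"{len(p)} != n_regions {n_regions}"
            )
        return dict(p[r])


@dataclass
class SimConfig:
    genes: list[SimGene]
    n_regions: int = 7
    n_individuals_per_region: int = 30
    differentiation: float = 0.15  # regional drift / cline strength in [0, 1)
    distance_decay: bool = True
    target_depths: tuple[float, ...] = DEPTH_LADDER
    read_length_bp: int = 150
    min_reads_to_call: int = 2
    error_rate: float = 0.005
    enrichment_depth: float = 264.0
    frac_bad_sites: float = 0.05  # sites drawn with failing QUAL/MQ/rank-sums
    frac_unresolved: float = 0.05  # per gene x individual phase failures
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_individuals_per_region < 1:
            raise ValueError("need at least one region and one individual")
        if not self.genes:
            raise ValueError("need at least one gene")
        if not 0 <= self.differentiation < 1:
            raise ValueError("differentiation must be in [0, 1)")
        for g in self.genes:
            for r in range(self.n_regions):
                p = g.probs_for_region(r, self.n_regions)
                if p is None:
                    continue
                if abs(sum(p.values()) - 1.0) > 1e-9:
                    raise ValueError(
                        f"{g.region.gene_id}: copy-number probabilities must sum to 1"
                    )
                if any(k < 0 or k > 6 for k in p):
                    raise ValueError("copy-number classes must be 0-6")

    @property
    def region_names(self) -> list[str]:
        return [f"R{r + 1}" for r in range(self.n_regions)]


@dataclass
class GeneTruth:
    """Ground truth for one gene: allele pool, frequencies, copies, phases."""

    gene: SimGene
    ancestral: str  # concatenated exons, plus-strand orientation
    patterns: np.ndarray  # alleles x sites bool: allele carries the alt base
    site_offsets: np.ndarray  # offsets into concatenated exons
    sites: list[SiteRecord]
    freqs: np.ndarray  # regions x alleles, rows sum to 1
    copy_number: np.ndarray  # per individual, 0-6
    haplotypes: list[np.ndarray]  # per individual, allele indices (len = copies)

    def allele_sequence(self, allele: int) -> str:
        seq = list(self.ancestral)
        for k in np.flatnonzero(self.patterns[allele]):
            seq[self.site_offsets[k]] = self.sites[k].alt
        return "".join(seq)

    @property
    def n_alleles(self) -> int:
        return self.patterns.shape[0]


@dataclass
class TruthSet:
    """Complete ground truth for a simulated survey."""

    config: SimConfig
    individuals: list[str]
    region_labels: list[str]
    coords: np.ndarray  # individuals x 2: (lat, lon) degrees
    genes: dict[str, GeneTruth]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def regions(self) -> list[GeneRegion]:
        return [gt.gene.region for gt in self.genes.values()]

    def true_genotypes(self) -> GenotypeMatrix:
        """Error-free genotype matrix over all truth sites.

        Individuals with one allelic copy are homozygous for their single
        haplotype; individuals with zero copies are MISSING; individuals
        with more than two copies are genotyped from two of their copies
        (the diploid genotyper's view of a duplicated locus).
        """
        sites: list[SiteRecord] = []
        rows: list[np.ndarray] = []
        for gt in self.genes.values():
            calls = _true_calls(gt, self.n_individuals)
            sites.extend(gt.sites)
            rows.append(calls)
        calls = np.vstack(rows) if rows else np.zeros((0, self.n_individuals), np.int8)
        return GenotypeMatrix(
            sites=sites,
            individuals=list(self.individuals),
            calls=calls,
            region_labels=list(self.region_labels),
        )

    def haplotype_sets(
        self, frac_unresolved: float | None = None, seed: int | None = None
    ) -> dict[str, HaplotypeSet]:
        """Phased FASTA-style haplotypes, two per individual where possible.

        A fraction of gene x individual pairs gets an 'N' injected into both
        haplotypes, emulating statistical-phasing failures; those sequences
        are flagged unresolved downstream and drop out of allele counts.
        """
        cfg = self.config
        frac = cfg.frac_unresolved if frac_unresolved is None else frac_unresolved
        rng = np.random.default_rng(cfg.rng_seed + 977 if seed is None else seed)
        out: dict[str, HaplotypeSet] = {}
        for gid, gt in self.genes.items():
            entries: list[tuple[str, int, str]] = []
            seqs = [gt.allele_sequence(a) for a in range(gt.n_alleles)]
            for j, ind in enumerate(self.individuals):
                haps = gt.haplotypes[j]
                if len(haps) == 0:
                    continue
                pair = haps[:2] if len(haps) >= 2 else haps
                fail = rng.random() < frac
                pos = int(rng.integers(0, len(gt.ancestral))) if fail else -1
                for h, allele in enumerate(pair, start=1):
                    s = seqs[allele]
                    if fail:
                        s = s[:pos] + "N" + s[pos + 1 :]
                    entries.append((ind, h, s))
            out[gid] = HaplotypeSet(gid, entries)
        return out


# ---------------------------------------------------------------------------
# generation


def simulate_truth(config: SimConfig) -> TruthSet:
    """Draw a complete ground-truth population from ``config``.

    Deterministic given ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_reg = config.n_regions
    n_per = config.n_individuals_per_region
    region_names = config.region_names

    individuals, region_labels = [], []
    for r, name in enumerate(region_names):
        for i in range(n_per):
            individuals.append(f"{name}_{i + 1:03d}")
            region_labels.append(name)
    n_ind = len(individuals)

    # sampling transect roughly along a coastline: south-west to north-east
    centers = np.column_stack(
        [
            np.linspace(-38.0, -20.0, n_reg),
            np.linspace(141.0, 153.0, n_reg),
        ]
    )
    coords = np.vstack(
        [
            centers[r] + rng.normal(0.0, 0.2, size=2)
            for r in range(n_reg)
            for _ in range(n_per)
        ]
    )
    region_idx = np.repeat(np.arange(n_reg), n_per)

    genes: dict[str, GeneTruth] = {}
    for sg in config.genes:
        genes[sg.region.gene_id] = _simulate_gene(sg, config, region_idx, rng)

    return TruthSet(
        config=config,
        individuals=individuals,
        region_labels=region_labels,
        coords=coords,
        genes=genes,
    )


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def _simulate_gene(
    sg: SimGene, config: SimConfig, region_idx: np.ndarray, rng: np.random.Generator
) -> GeneTruth:
    region = sg.region
    L = region.length
    n_codons = L // 3
    ancestral = "".join(
        rng.choice(_SENSE_CODONS) for _ in range(n_codons)
    ) + "".join(rng.choice(list("ACGT")) for _ in range(L - 3 * n_codons))

    n_sites = max(1, rng.poisson(sg.mutation_rate * L)) if sg.n_alleles > 1 else 0
    n_sites = min(n_sites, L)
    offsets = np.sort(rng.choice(L, size=n_sites, replace=False))
    alts = []
    for off in offsets:
        ref = ancestral[off]
        alts.append(rng.choice([b for b in "ACGT" if b != ref]))

    # allele pool: ancestral plus derived mutation patterns over the sites
    pats = {tuple([False] * n_sites)}
    tries = 0
    while len(pats) < sg.n_alleles and tries < 50 * sg.n_alleles:
        pats.add(tuple(rng.random(n_sites) < 0.35))
        tries += 1
    patterns = np.array(sorted(pats), dtype=bool).reshape(len(pats), n_sites)
    K = patterns.shape[0]

    sites = [
        SiteRecord(
            chrom=region.chrom,
            pos=region.genomic_pos(int(off)),
            ref=ancestral[off],
            alt=alt,
            gene_id=region.gene_id,
        )
        for off, alt in zip(offsets, alts)
    ]

    # region-structured allele frequencies: softmax of per-allele baseline
    # log-abundances plus (with distance_decay) a cline term growing along
    # the sampling transect, scaled by the differentiation parameter
    d = config.differentiation
    R = config.n_regions
    base = rng.normal(0.0, 1.5, K)
    freqs = np.empty((R, K))
    if d == 0.0:
        freqs[:] = _softmax(base)
    else:
        cline = rng.normal(0.0, 6.0 * d, K)
        for r in range(R):
            w = r / (R - 1) if R > 1 else 0.0
            if config.distance_decay:
                x = base + cline * w + rng.normal(0.0, 0.75 * d, K)
            else:
                x = base + rng.normal(0.0, 3.0 * d, K)
            freqs[r] = _softmax(x)
    freqs /= freqs.sum(axis=1, keepdims=True)

    n_ind = len(region_idx)
    copy_number = np.full(n_ind, 2, dtype=np.int64)
    if sg.copy_number_probs is not None and not region.single_copy_reference:
        for r in range(config.n_regions):
            probs = sg.probs_for_region(r, config.n_regions)
            ks = np.array(sorted(probs))
            ps = np.array([probs[k] for k in ks], dtype=float)
            mask = region_idx == r
            copy_number[mask] = rng.choice(ks, size=mask.sum(), p=ps / ps.sum())

    haplotypes = [
        rng.choice(K, size=int(copy_number[j]), p=freqs[region_idx[j]])
        for j in range(n_ind)
    ]

    return GeneTruth(
        gene=sg,
        ancestral=ancestral,
        patterns=patterns,
        site_offsets=offsets.astype(int),
        sites=sites,
        freqs=freqs,
        copy_number=copy_number,
        haplotypes=haplotypes,
    )


def _true_calls(gt: GeneTruth, n_ind: int) -> np.ndarray:
    """Truth genotype codes (sites x individuals) for one gene."""
    S = len(gt.sites)
    calls = np.full((S, n_ind), Genotype.MISSING, dtype=np.int8)
    for j in range(n_ind):
        haps = gt.haplotypes[j]
        if len(haps) == 0:
            continue
        a1 = gt.patterns[haps[0]]
        a2 = gt.patterns[haps[1]] if len(haps) >= 2 else a1
        calls[:, j] = a1.astype(np.int8) + a2.astype(np.int8)
    return calls


# ---------------------------------------------------------------------------
# observation models


def simulate_coverage(truth: TruthSet, depth: float, seed: int = 0) -> CoverageSummary:
    """Per-gene read counts at a target depth.

    ``read_count ~ Poisson(depth * (copies / 2) * gene_length / read_length)``;
    single-copy reference genes always carry two allelic copies.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    rl = truth.config.read_length_bp
    rows = []
    for gid, gt in truth.genes.items():
        L = gt.gene.region.length
        lam = depth * (gt.copy_number / 2.0) * L / rl
        counts = rng.poisson(lam)
        frac = 1.0 - np.exp(-counts * rl / L)
        covered = np.minimum(L, np.round(L * frac)).astype(int)
        for j, ind in enumerate(truth.individuals):
            rows.append((gid, ind, int(counts[j]), int(covered[j]), L))
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "individual", "read_count", "bases_covered", "gene_length_bp"],
    )
    return CoverageSummary(df)


def simulate_calls(
    truth: TruthSet, depth: float, platform: str = "wgs", seed: int = 0
) -> GenotypeMatrix:
    """Simulate a joint-genotyped call set at a target depth.

    Per-site per-individual depth is Poisson(depth x copies/2); genotypes
    with fewer than ``min_reads_to_call`` reads are MISSING. True
    heterozygotes are called heterozygous iff both alleles were read, so
    the het->hom miscall probability is 2 x 0.5^depth. For homozygotes an
    errant read (per-read error rate) must occur at least twice to flip the
    call. Sites at which no individual carries a called ALT allele are not
    discovered and drop from the output, so low depths yield fewer sites.
    Site annotations (QUAL, MQ, rank-sums) are drawn so that a configurable
    fraction of sites fails the hard-filter cascade.
    """
    if platform not in ("wgs", "enrichment"):
        raise ValueError("platform must be 'wgs' or 'enrichment'")
    if depth <= 0:
        raise ValueError("depth must be positive")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    n_ind = truth.n_individuals
    e = cfg.error_rate

    all_sites: list[SiteRecord] = []
    all_calls, all_depth, all_ad = [], [], []
    for gid, gt in truth.genes.items():
        S = len(gt.sites)
        if S == 0:
            continue
        true_gt = _true_calls(gt, n_ind)  # S x n_ind
        scale = gt.copy_number / 2.0
        d = rng.poisson(depth * scale[None, :], size=(S, n_ind))

        p_alt = np.select(
            [true_gt == Genotype.HET, true_gt == Genotype.HOM_ALT],
            [0.5, 1.0 - e],
            default=e,
        )
        nalt = rng.binomial(d, p_alt)
        nref = d - nalt

        call = np.full((S, n_ind), Genotype.MISSING, dtype=np.int8)
        callable_ = (d >= cfg.min_reads_to_call) & (true_gt != Genotype.MISSING)

        het_truth = true_gt == Genotype.HET
        call = np.where(
            callable_ & het_truth & (nalt > 0) & (nref > 0), Genotype.HET, call
        )
        call = np.where(
            callable_ & het_truth & (nalt == d), Genotype.HOM_ALT, call
        )
        call = np.where(
            callable_ & het_truth & (nalt == 0), Genotype.HOM_REF, call
        )

        hom_truth = ~het_truth & (true_gt != Genotype.MISSING)
        minor = np.minimum(nalt, nref)
        # errant reads flip a homozygote only when they are both repeated
        # and a plausible allele fraction for a heterozygote
        hom_as_het = callable_ & hom_truth & (minor >= 2) & (minor >= 0.2 * d)
        call = np.where(
            callable_ & hom_truth & ~hom_as_het,
            np.where(nalt > nref, Genotype.HOM_ALT, Genotype.HOM_REF),
            call,
        )
        call = np.where(hom_as_het, Genotype.HET, call)

        all_sites.extend(gt.sites)
        all_calls.append(call)
        all_depth.append(d)
        all_ad.append(np.stack([nref, nalt], axis=-1))

    calls = np.vstack(all_calls)
    depths = np.vstack(all_depth)
    ads = np.vstack(all_ad)

    discovered = ((calls == Genotype.HET) | (calls == Genotype.HOM_ALT)).any(axis=1)

    # site annotations for the filter stages
    S = len(all_sites)
    qual = np.maximum(100.0, rng.normal(500.0, 150.0, S))
    mq = np.clip(rng.normal(59.5, 0.8, S), 45.0, 60.0)
    mqrs = np.clip(rng.normal(0.0, 2.0, S), -9.0, 9.0)
    rprs = np.clip(rng.normal(0.0, 1.5, S), -6.0, 6.0)
    bad = rng.random(S) < cfg.frac_bad_sites
    mode = rng.integers(0, 4, S)
    sign = np.where(rng.random(S) < 0.5, -1.0, 1.0)
    qual = np.where(bad & (mode == 0), rng.uniform(10.0, 79.9, S), qual)
    mq = np.where(bad & (mode == 1), rng.uniform(10.0, 39.9, S), mq)
    mqrs = np.where(bad & (mode == 2), sign * rng.uniform(12.6, 18.0, S), mqrs)
    rprs = np.where(bad & (mode == 3), sign * rng.uniform(8.1, 12.0, S), rprs)

    sites = [
        SiteRecord(
            chrom=s.chrom,
            pos=s.pos,
            ref=s.ref,
            alt=s.alt,
            qual=float(qual[i]),
            mq=float(mq[i]),
            mq_rank_sum=float(mqrs[i]),
            read_pos_rank_sum=float(rprs[i]),
            gene_id=s.gene_id,
        )
        for i, s in enumerate(all_sites)
    ]
    matrix = GenotypeMatrix(
        sites=sites,
        individuals=list(truth.individuals),
        calls=calls,
        depth=depths,
        allele_depths=ads,
        region_labels=list(truth.region_labels),
    )
    return matrix.subset_sites(discovered)


# ---------------------------------------------------------------------------
# default study panel


def default_gene_panel() -> list[SimGene]:
    """A reduced koala-like panel: CNV-prone and single-copy MHC class I and
    class II genes plus eight single-copy TLR reference genes."""
    genes: list[SimGene] = []
    pos = 10_000

    def region(gene_id: str, family: GeneFamily, length: int, single_copy: bool):
        nonlocal pos
        half = length // 2
        r = GeneRegion(
            gene_id=gene_id,
            chrom="scaf_1",
            exons=((pos, pos + half), (pos + half + 500, pos + half + 500 + (length - half))),
            family=family,
            single_copy_reference=single_copy,
            strand="+",
            frame_offsets=(0, half % 3),
        )
        pos += length + 5_000
        return r

    dup = {1: 0.1, 2: 0.55, 3: 0.2, 4: 0.1, 5: 0.03, 6: 0.02}
    deletion = {0: 0.1, 1: 0.2, 2: 0.7}

    genes.append(SimGene(region("UA", GeneFamily.MHC_I, 1098, False), 20, 0.02, dup))
    genes.append(SimGene(region("UB", GeneFamily.MHC_I, 1098, False), 8, 0.008, deletion))
    genes.append(SimGene(region("UC", GeneFamily.MHC_I, 1098, False), 5, 0.004))
    genes.append(SimGene(region("UH", GeneFamily.MHC_I, 1098, False), 12, 0.02, dup))
    genes.append(SimGene(region("DAA", GeneFamily.MHC_II_A, 780, False), 5, 0.006))
    genes.append(SimGene(region("DBA2", GeneFamily.MHC_II_A, 780, False), 8, 0.012, deletion))
    genes.append(SimGene(region("DAB2", GeneFamily.MHC_II_B, 810, False), 12, 0.012, dup))
    genes.append(SimGene(region("DMB", GeneFamily.MHC_II_B, 810, False), 5, 0.005))
    for t in range(1, 9):
        genes.append(
            SimGene(region(f"TLR{t}", GeneFamily.TLR, 2250, True), 3, 0.0015)
        )
    return genes


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study conditions: 7 regions, 30 individuals each, the
    default gene panel and the 0.5-30x depth ladder."""
    kwargs = dict(
        genes=default_gene_panel(),
        n_regions=7,
        n_individuals_per_region=30,
        rng_seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# persistence


def write_truth(truth: TruthSet, out_dir: str | Path, depth: float = 30.0) -> dict:
    """Write a simulated dataset (VCF, coverage TSV, haplotype FASTA, region
    table, geography TSV, truth JSON) and return the path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.config

    paths = {
        "regions": out / "regions.tsv",
        "vcf": out / f"calls_{depth:g}x.vcf",
        "coverage": out / f"coverage_{depth:g}x.tsv",
        "haplotypes": out / "haplotypes.fasta",
        "geography": out / "geography.tsv",
        "truth": out / "truth.json",
    }
    write_regions(truth.regions(), paths["regions"])
    write_vcf(simulate_calls(truth, depth, seed=cfg.rng_seed + 1), paths["vcf"])
    write_coverage_table(
        simulate_coverage(truth, depth, seed=cfg.rng_seed + 2), paths["coverage"]
    )
    write_haplotypes(truth.haplotype_sets().values(), paths["haplotypes"])
    pd.DataFrame(
        {
            "individual": truth.individuals,
            "region": truth.region_labels,
            "lat": truth.coords[:, 0],
            "lon": truth.coords[:, 1],
        }
    ).to_csv(paths["geography"], sep="\t", index=False)

    truth_json = {
        "seed": cfg.rng_seed,
        "individuals": truth.individuals,
        "region_labels": truth.region_labels,
        "copy_number": {
            gid: gt.copy_number.tolist() for gid, gt in truth.genes.items()
        },
        "n_alleles": {gid: int(gt.n_alleles) for gid, gt in truth.genes.items()},
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1))
    return {k: str(v) for k, v in paths.items()}
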