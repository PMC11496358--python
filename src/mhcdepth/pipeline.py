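"""End-to-end orchestration: simulate -> filter -> concordance / CNV /
diversity / structure / supertype, with a reproducible run manifest.

Two entry points mirror the two study designs:

* :func:`run_depth_comparison` pairs a high-depth target-enrichment call
  set with WGS call sets simulated across a depth ladder and reports
  genotype concordance and copy-number detectability per depth.
* :func:`run_diversity_survey` runs the 30x survey: per-gene diversity
  statistics, pairwise Weir-Cockerham F_ST between regions, PCoA
  ordinations, a Mantel isolation-by-distance test and class I supertype
  clustering.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cnv import acn_table, call_cnv_genes
from .concordance import compare_call_sets
from .diversity import (
    aggregate_gene_table,
    assign_alleles,
    filter_rare_alleles,
    gene_diversity_stats,
    pairwise_fst,
)
from .filters import FilterProfile, run_filter_cascade
from .formats_io import GeneFamily, GeneRegion, Genotype, GenotypeMatrix
from .simulate import SimConfig, TruthSet, simulate_calls, simulate_coverage, simulate_truth
from .structure import dosage_matrix, genetic_distance, haversine_distance, mantel, pcoa
from .supertype import (
    KSelection,
    dapc,
    extract_pbr,
    find_k,
    translate_alleles,
    z_encode,
)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def _config_hash(config: SimConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def _split_matrix(matrix: GenotypeMatrix, regions: list[GeneRegion]):
    """(MHC sites, TLR sites) submatrices by gene family."""
    tlr_genes = {r.gene_id for r in regions if r.family is GeneFamily.TLR}
    is_tlr = np.array([s.gene_id in tlr_genes for s in matrix.sites], bool)
    return matrix.subset_sites(~is_tlr), matrix.subset_sites(is_tlr)


def _filtered(matrix: GenotypeMatrix, regions: list[GeneRegion], target_depth: float):
    """Family-specific filter cascades, recombined into one matrix."""
    mhc_regions = [r for r in regions if r.family is not GeneFamily.TLR]
    tlr_regions = [r for r in regions if r.family is GeneFamily.TLR]
    mhc, tlr = _split_matrix(matrix, regions)
    out = []
    if mhc_regions and mhc.n_sites:
        m, _ = run_filter_cascade(mhc, mhc_regions, FilterProfile.mhc(), target_depth)
        out.append(m)
    if tlr_regions and tlr.n_sites:
        t, _ = run_filter_cascade(tlr, tlr_regions, FilterProfile.tlr(), target_depth)
        out.append(t)
    if len(out) == 1:
        return out[0]
    merged = GenotypeMatrix(
        sites=out[0].sites + out[1].sites,
        individuals=list(out[0].individuals),
        calls=np.vstack([out[0].calls, out[1].calls]),
        depth=np.vstack([out[0].depth, out[1].depth]),
        allele_depths=np.vstack([out[0].allele_depths, out[1].allele_depths]),
        region_labels=out[0].region_labels,
    )
    return merged


def run_depth_comparison(
    config: SimConfig,
    depths: tuple[float, ...] | None = None,
    apply_filters: bool = True,
    manifest: RunManifest | None = None,
) -> dict:
    """Concordance and CNV detectability across the depth ladder.

    Returns ``{"concordance": DataFrame, "cnv": DataFrame, "truth": TruthSet}``
    with one concordance row per depth and one CNV row per depth x gene.
    """
    depths = tuple(depths or config.target_depths)
    truth = simulate_truth(config)
    regions = truth.regions()
    seed = config.rng_seed
    manifest = manifest or RunManifest(_config_hash(config), seed)

    te = simulate_calls(truth, config.enrichment_depth, "enrichment", seed=seed + 101)
    if apply_filters:
        te = _filtered(te, regions, config.enrichment_depth)

    conc_rows, cnv_rows = [], []
    for di, depth in enumerate(depths):
        wgs = simulate_calls(truth, depth, "wgs", seed=seed + 1000 + di)
        if apply_filters:
            wgs = _filtered(wgs, regions, depth)
        rep = compare_call_sets(te, wgs)
        row = {"depth": depth, "n_shared_sites": rep["n_shared_sites"]}
        row.update(rep.get("metrics", {}))
        conc_rows.append(row)

        cov = simulate_coverage(truth, depth, seed=seed + 2000 + di)
        acn = acn_table(cov, regions)
        for gid, gt in truth.genes.items():
            if gt.gene.region.single_copy_reference:
                continue
            sub = acn[acn.gene_id == gid].set_index("individual")
            tc = pd.Series(gt.copy_number, index=truth.individuals)
            joined = sub.join(tc.rename("true_copies"), how="inner")
            if joined.empty:
                continue
            correct = (joined.copy_class == joined.true_copies).mean()
            dels = joined[joined.true_copies == 0]
            cnv_rows.append(
                {
                    "depth": depth,
                    "gene_id": gid,
                    "n": len(joined),
                    "copy_class_accuracy": float(correct),
                    "n_true_deletions": len(dels),
                    "deletions_detected": float((dels.copy_class == 0).mean())
                    if len(dels)
                    else np.nan,
                }
            )
    conc = pd.DataFrame(conc_rows)
    cnv = pd.DataFrame(cnv_rows)
    manifest.record("depth_comparison", depths=list(depths), rows=len(conc))
    return {"concordance": conc, "cnv": cnv, "truth": truth, "manifest": manifest}


DEFAULT_PBR_POSITIONS = tuple(range(3, 360, 12))


def run_diversity_survey(
    config: SimConfig,
    depth: float = 30.0,
    pbr_positions: tuple[int, ...] = DEFAULT_PBR_POSITIONS,
    supertype_params: Mapping | None = None,
    manifest: RunManifest | None = None,
) -> dict:
    """The range-wide survey on one simulated dataset.

    Returns per-gene diversity statistics with aggregates, the pairwise
    F_ST table, PCoA coordinates for SNP / allele / supertype encodings
    (split into single-copy and CNV gene sets for SNPs), the Mantel
    isolation-by-distance test and the supertype model summary.
    """
    truth = simulate_truth(config)
    regions = truth.regions()
    seed = config.rng_seed
    manifest = manifest or RunManifest(_config_hash(config), seed)
    region_of = dict(zip(truth.individuals, truth.region_labels))

    # --- per-gene diversity from phased haplotypes
    hapsets = truth.haplotype_sets()
    stats_rows = []
    allele_tables = {}
    for gid, gt in truth.genes.items():
        if gt.gene.region.single_copy_reference:
            continue
        hs = hapsets[gid].drop_unresolved()
        if len(hs.entries) < 2:
            continue
        try:
            table = filter_rare_alleles(assign_alleles(hs, region_of))
        except ValueError:
            continue
        allele_tables[gid] = table
        s = gene_diversity_stats(hapsets[gid], gt.gene.region, region_of)
        row = s.__dict__ | {
            "mhc_class": "I" if gt.gene.region.family.is_class_i else "II"
        }
        stats_rows.append(row)
    gene_stats = pd.DataFrame(stats_rows)
    aggregates = aggregate_gene_table(gene_stats) if not gene_stats.empty else {}

    # --- filtered 30x call set for SNP-level analyses
    calls = simulate_calls(truth, depth, "wgs", seed=seed + 31)
    calls = _filtered(calls, regions, depth)
    mhc_calls, _ = _split_matrix(calls, regions)
    fst = pairwise_fst(mhc_calls) if mhc_calls.n_sites else pd.DataFrame()

    # --- ordinations
    cnv_genes = {
        gid
        for gid, gt in truth.genes.items()
        if gt.gene.copy_number_probs is not None
        and not gt.gene.region.single_copy_reference
    }
    coords = {}
    for mode, site_filter in (
        ("snp_single_copy", lambda s: s.gene_id not in cnv_genes),
        ("snp_cnv", lambda s: s.gene_id in cnv_genes),
    ):
        keep = np.array([site_filter(s) for s in mhc_calls.sites], bool)
        sub = mhc_calls.subset_sites(keep)
        if sub.n_sites < 2:
            continue
        dm = genetic_distance(dosage_matrix(sub))
        xy, _ = pcoa(dm, k=2)
        coords[mode] = pd.DataFrame(
            xy, index=sub.individuals, columns=["PC1", "PC2"]
        ).assign(region=[region_of[i] for i in sub.individuals])

    # allele-count encoding across genes
    allele_feats = _allele_encoding(truth, hapsets, allele_tables)
    if allele_feats is not None and allele_feats.shape[1] >= 2:
        dm = genetic_distance(allele_feats)
        xy, _ = pcoa(dm, k=2)
        coords["allele"] = pd.DataFrame(
            xy, index=allele_feats.index, columns=["PC1", "PC2"]
        ).assign(region=[region_of[i] for i in allele_feats.index])

    # --- Mantel isolation by distance: population-level genetic distance
    # (region-mean SNP dosages) against great-circle distance between
    # region centroids
    mantel_res = None
    if mhc_calls.n_sites >= 2 and len(set(truth.region_labels)) >= 4:
        dos = dosage_matrix(mhc_calls)
        reg = pd.Series(truth.region_labels, index=truth.individuals)
        pop = dos.groupby(reg).mean()
        centers = (
            pd.DataFrame(truth.coords, index=truth.individuals)
            .groupby(reg)
            .mean()
            .loc[pop.index]
            .to_numpy()
        )
        mantel_res = mantel(
            genetic_distance(pop),
            haversine_distance(centers, list(pop.index)),
            n_perm=999,
            seed=seed + 7,
        )

    # --- class I supertypes
    st_params = dict(n_pca=30, max_k=12, n_replicates=20, n_starts=20, seed=seed + 5)
    st_params.update(supertype_params or {})
    supertypes = class_i_supertypes(truth, allele_tables, pbr_positions, **st_params)
    if supertypes is not None and "profiles" in supertypes:
        prof = supertypes["profiles"]
        if prof.shape[0] > 2 and prof.shape[1] >= 2:
            dm = genetic_distance(prof)
            xy, _ = pcoa(dm, k=2)
            coords["supertype"] = pd.DataFrame(
                xy, index=prof.index, columns=["PC1", "PC2"]
            ).assign(region=[region_of[i] for i in prof.index])

    manifest.record(
        "diversity_survey",
        depth=depth,
        n_genes=len(gene_stats),
        n_snp_sites=int(mhc_calls.n_sites),
    )
    return {
        "truth": truth,
        "gene_stats": gene_stats,
        "aggregates": aggregates,
        "fst": fst,
        "pcoa": coords,
        "mantel": mantel_res,
        "supertypes": supertypes,
        "manifest": manifest,
    }


def _allele_encoding(truth: TruthSet, hapsets, allele_tables) -> pd.DataFrame | None:
    """Individuals x (gene, allele) count features from resolved phases."""
    cols, data = [], {}
    for gid, table in allele_tables.items():
        seq_to_label = {seq: lab for lab, seq in table.alleles.items()}
        per_ind: dict[str, dict[str, int]] = {}
        for ind, _h, seq in hapsets[gid].drop_unresolved().entries:
            lab = seq_to_label.get(seq)
            if lab is None:
                continue  # rare allele filtered out
            per_ind.setdefault(ind, {}).setdefault(lab, 0)
            per_ind[ind][lab] += 1
        for lab in table.alleles:
            col = f"{gid}:{lab}"
            cols.append(col)
            data[col] = {
                ind: per_ind.get(ind, {}).get(lab, np.nan) for ind in truth.individuals
            }
    if not cols:
        return None
    df = pd.DataFrame(data, index=truth.individuals)
    # individuals with no resolved phase anywhere cannot be encoded
    return df.dropna(how="all")


def class_i_supertypes(
    truth: TruthSet,
    allele_tables: Mapping[str, "object"],
    pbr_positions: tuple[int, ...],
    n_pca: int = 30,
    max_k: int = 12,
    n_replicates: int = 20,
    n_starts: int = 20,
    seed: int = 0,
) -> dict | None:
    """Pooled clustering of class I alleles into supertypes.

    Alleles from every class I gene are pooled into one z-descriptor
    matrix (one clustering across genes), k chosen by modal BIC, DAPC
    fitted, and per-individual supertype profiles tallied.
    """
    class_i = {
        gid: t
        for gid, t in allele_tables.items()
        if truth.genes[gid].gene.region.family.is_class_i
    }
    if not class_i:
        return None
    proteins: dict[str, str] = {}
    for gid, table in class_i.items():
        region = truth.genes[gid].gene.region
        frame = (region.frame_offsets or (0,))[0]
        prots = translate_alleles(table.alleles, region.strand, frame)
        for lab, p in prots.items():
            proteins[f"{gid}:{lab}"] = p
    min_len = min(len(p) for p in proteins.values())
    positions = [p for p in pbr_positions if 1 <= p <= min_len]
    if len(positions) < 2 or len(proteins) < 3:
        return None
    residues = extract_pbr(proteins, positions)
    z = z_encode(residues)
    sel = find_k(
        z,
        n_pca=n_pca,
        max_k=min(max_k, z.n - 1),
        n_replicates=n_replicates,
        n_starts=n_starts,
        seed=seed,
    )
    model = dapc(z, sel.cluster_labels, n_pca=15)

    # per-individual profiles from resolved haplotypes; alleles that were
    # excluded from the model (stop codons in the PBR) are skipped
    modelled = set(model.labels)
    hapsets = truth.haplotype_sets()
    individual_alleles: dict[str, list[str]] = {i: [] for i in truth.individuals}
    for gid, table in class_i.items():
        seq_to_label = {seq: lab for lab, seq in table.alleles.items()}
        for ind, _h, seq in hapsets[gid].drop_unresolved().entries:
            lab = seq_to_label.get(seq)
            if lab is not None and f"{gid}:{lab}" in modelled:
                individual_alleles[ind].append(f"{gid}:{lab}")
    individual_alleles = {i: a for i, a in individual_alleles.items() if a}

    from .supertype import assign_supertypes

    allele_st, profiles, gene_map = assign_supertypes(model, individual_alleles)
    return {
        "k": sel.k,
        "selection": sel,
        "model": model,
        "allele_supertypes": allele_st,
        "profiles": profiles,
        "gene_supertypes": {g: sorted(s) for g, s in gene_map.items()},
    }


def write_survey_outputs(results: dict, out_dir: str | Path) -> dict:
    """Write the survey's tidy TSV/JSON outputs and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if isinstance(results.get("gene_stats"), pd.DataFrame) and not results["gene_stats"].empty:
        p = out / "gene_stats.tsv"
        results["gene_stats"].to_csv(p, sep="\t", index=False)
        paths["gene_stats"] = str(p)
    if isinstance(results.get("fst"), pd.DataFrame) and not results["fst"].empty:
        p = out / "fst.tsv"
        results["fst"].to_csv(p, sep="\t")
        paths["fst"] = str(p)
    for mode, df in (results.get("pcoa") or {}).items():
        p = out / f"pcoa_{mode}.tsv"
        df.to_csv(p, sep="\t")
        paths[f"pcoa_{mode}"] = str(p)
    if results.get("mantel"):
        p = out / "mantel.json"
        p.write_text(json.dumps(results["mantel"], indent=1))
        paths["mantel"] = str(p)
    if results.get("aggregates"):
        p = out / "aggregates.json"
        p.write_text(json.dumps(results["aggregates"], indent=1))
        paths["aggregates"] = str(p)
    st = results.get("supertypes")
    if st:
        p = out / "supertypes.tsv"
        pd.Series(st["allele_supertypes"]).rename("supertype").to_csv(p, sep="\t")
        paths["supertypes"] = str(p)
    manifest = results.get("manifest")
    if manifest is not None:
        for name, p in paths.items():
            manifest.record("output", name=name, path=p)
        manifest.write(out / "manifest.json")
        paths["manifest"] = str(out / "manifest.json")
    return paths
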