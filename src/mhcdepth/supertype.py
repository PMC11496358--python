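"""Supertype clustering of MHC class I alleles.

Alleles are reduced to the residues of the peptide-binding region (PBR),
each residue is replaced by the five Sandberg et al. (1998) physiochemical
z-descriptors (hydrophobicity, steric bulk, polarity and two
electronic-property scales), and the resulting numeric matrix is
clustered: k is selected by the modal argmin of the Bayesian information
criterion over repeated k-means runs, then discriminant analysis of
principal components (DAPC: PCA followed by LDA on the cluster labels)
yields posterior supertype memberships. The a-score (observed minus
permutation-expected reassignment success) guides how many PCs to retain.
"""

from __future__ import annotations

import importlib.resources
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from sklearn.decomposition import PCA
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def load_zscales() -> pd.DataFrame:
    """The 20x5 z-descriptor table (rows: one-letter amino acids)."""
    ref = importlib.resources.files("mhcdepth") / "data" / "zscales_sandberg1998.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", index_col="aa")


def translate_alleles(
    alleles: Mapping[str, str], strand: str = "+", frame_offset: int = 0
) -> dict[str, str]:
    """Translate nucleotide allele sequences (plus-strand exon
    concatenation) to protein, honouring strand and codon phase."""
    out = {}
    for label, nt in alleles.items():
        seq = Seq(nt)
        if strand == "-":
            seq = seq.reverse_complement()
        seq = seq[frame_offset:]
        seq = seq[: 3 * (len(seq) // 3)]
        out[label] = str(seq.translate())
    return out


def extract_pbr(
    allele_protein_seqs: Mapping[str, str], pbr_positions: Sequence[int]
) -> pd.DataFrame:
    """Residue matrix (alleles x PBR positions; positions are 1-based in
    the aligned protein). Alleles with a stop codon inside the PBR are
    excluded with a warning."""
    positions = list(pbr_positions)
    if not positions:
        raise ValueError("empty PBR position list")
    rows, labels, dropped = [], [], []
    for label, prot in allele_protein_seqs.items():
        if any(p < 1 or p > len(prot) for p in positions):
            raise ValueError(
                f"PBR position out of range for allele {label} (length {len(prot)})"
            )
        residues = [prot[p - 1] for p in positions]
        if "*" in residues:
            dropped.append(label)
            continue
        labels.append(label)
        rows.append(residues)
    if dropped:
        warnings.warn(f"excluded {len(dropped)} allele(s) with stop codons in PBR")
    return pd.DataFrame(rows, index=labels, columns=[f"p{p}" for p in positions])


@dataclass
class ZEncoding:
    """Alleles x (positions x 5) z-descriptor matrix."""

    labels: list[str]
    matrix: np.ndarray
    pbr_positions: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.labels), 5 * len(self.pbr_positions)):
            raise ValueError("z-encoding shape mismatch")
        if np.isnan(self.matrix).any():
            raise ValueError("z-encoding contains missing values")

    @property
    def n(self) -> int:
        return len(self.labels)


def z_encode(residues: pd.DataFrame) -> ZEncoding:
    """Replace each PBR residue by its (z1..z5) descriptor vector."""
    z = load_zscales()
    rows = []
    for label, row in residues.iterrows():
        vec = []
        for col, aa in row.items():
            if aa not in z.index:
                raise ValueError(
                    f"non-standard residue {aa!r} in allele {label} at {col}"
                )
            vec.extend(z.loc[aa].tolist())
        rows.append(vec)
    return ZEncoding(
        labels=[str(i) for i in residues.index],
        matrix=np.array(rows, dtype=float),
        pbr_positions=[str(c) for c in residues.columns],
    )


def _pca_reduce(X: np.ndarray, n_pca: int) -> np.ndarray:
    n_pca = max(1, min(n_pca, X.shape[0] - 1, X.shape[1]))
    return PCA(n_components=n_pca, svd_solver="full").fit_transform(
        X - X.mean(axis=0)
    )


def _kmeans_bic(X: np.ndarray, k: int, n_starts: int, max_iter: int, rs: int) -> tuple[float, np.ndarray]:
    n = X.shape[0]
    if k == 1:
        wss = float(((X - X.mean(axis=0)) ** 2).sum())
        labels = np.zeros(n, dtype=int)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate points shrink k
            km = KMeans(
                n_clusters=k, n_init=n_starts, max_iter=max_iter, random_state=rs
            ).fit(X)
        wss = float(km.inertia_)
        labels = km.labels_
    wss = max(wss, 1e-12)
    bic = n * np.log(wss / n) + k * np.log(n)
    return bic, labels


@dataclass
class KSelection:
    k: int
    bic_trace: pd.DataFrame  # replicates x k values
    argmin_counts: dict[int, int]
    cluster_labels: np.ndarray  # labels from a k-means run at the modal k


def find_k(
    z: ZEncoding,
    n_pca: int = 30,
    max_k: int = 30,
    n_replicates: int = 1000,
    n_starts: int = 500,
    max_iter: int = 300,
    seed: int = 0,
) -> KSelection:
    """Select the number of supertypes by modal argmin-BIC over repeated
    k-means runs on the PCA-reduced z-encoding.

    ``BIC(k) = n ln(WSS_k / n) + k ln(n)``; each replicate reruns k-means
    (``n_starts`` restarts per k) and records its argmin; the returned k is
    the most common argmin across replicates.
    """
    if z.n < 2:
        raise ValueError("need at least two alleles")
    if max_k >= z.n:
        warnings.warn(f"max_k {max_k} >= n alleles {z.n}; reducing")
        max_k = z.n - 1
    X = _pca_reduce(z.matrix, n_pca)
    # alleles identical at every PBR position collapse to one point;
    # k cannot exceed the number of distinct points
    n_distinct = np.unique(X.round(9), axis=0).shape[0]
    max_k = max(1, min(max_k, n_distinct))
    rng = np.random.default_rng(seed)
    ks = list(range(1, max_k + 1))
    traces = np.empty((n_replicates, len(ks)))
    argmins = []
    for rep in range(n_replicates):
        rs = int(rng.integers(0, 2**31 - 1))
        for j, k in enumerate(ks):
            traces[rep, j], _ = _kmeans_bic(X, k, n_starts, max_iter, rs + j)
        argmins.append(ks[int(np.argmin(traces[rep]))])
    counts = Counter(argmins)
    best_k = counts.most_common(1)[0][0]
    _, labels = _kmeans_bic(X, best_k, n_starts, max_iter, int(rng.integers(0, 2**31 - 1)))
    return KSelection(
        k=best_k,
        bic_trace=pd.DataFrame(traces, columns=ks),
        argmin_counts=dict(counts),
        cluster_labels=labels,
    )


@dataclass
class SupertypeModel:
    """Fitted DAPC model: cluster assignment, retained PCs, discriminant
    functions and posterior memberships (rows sum to 1)."""

    labels: list[str]
    k: int
    n_pca: int
    clusters: np.ndarray
    posteriors: pd.DataFrame
    discriminants: np.ndarray | None = None
    _pca: PCA | None = field(default=None, repr=False)
    _lda: LinearDiscriminantAnalysis | None = field(default=None, repr=False)

    def assignment(self) -> dict[str, int]:
        return {lab: int(c) for lab, c in zip(self.labels, self.clusters)}


def dapc(z: ZEncoding, clusters: Sequence[int], n_pca: int = 15) -> SupertypeModel:
    """Discriminant analysis of principal components.

    PCA-reduce to ``n_pca`` dimensions, then LDA on the cluster labels,
    retaining all k-1 discriminant functions; posterior memberships come
    from the discriminant-space Gaussian model.
    """
    clusters = np.asarray(clusters, dtype=int)
    if len(clusters) != z.n:
        raise ValueError("cluster labels length mismatch")
    if n_pca < 1:
        raise ValueError("n_pca must be >= 1")
    k = len(np.unique(clusters))
    if k == 1:
        post = pd.DataFrame(np.ones((z.n, 1)), index=z.labels, columns=[0])
        return SupertypeModel(
            labels=list(z.labels), k=1, n_pca=0, clusters=clusters, posteriors=post
        )
    n_pca = min(n_pca, z.n - 1, z.matrix.shape[1])
    pca = PCA(n_components=n_pca, svd_solver="full").fit(z.matrix)
    scores = pca.transform(z.matrix)
    n_disc = min(k - 1, n_pca)
    lda = LinearDiscriminantAnalysis(n_components=n_disc)
    try:
        lda.fit(scores, clusters)
    except (IndexError, np.linalg.LinAlgError):
        # zero within-class scatter (clusters of identical points) makes the
        # problem singular; a deterministic sub-resolution jitter regularizes
        # it without moving any decision boundary
        scale = float(np.abs(scores).max()) or 1.0
        jitter = np.random.default_rng(0).normal(0.0, 1e-8 * scale, scores.shape)
        scores = scores + jitter
        lda = LinearDiscriminantAnalysis(n_components=n_disc)
        lda.fit(scores, clusters)
    post = pd.DataFrame(
        lda.predict_proba(scores), index=z.labels, columns=lda.classes_
    )
    pred = np.array([lda.classes_[i] for i in np.argmax(post.values, axis=1)])
    return SupertypeModel(
        labels=list(z.labels),
        k=k,
        n_pca=n_pca,
        clusters=pred,
        posteriors=post,
        discriminants=lda.transform(scores),
        _pca=pca,
        _lda=lda,
    )


def _reassignment_rate(z: ZEncoding, clusters: np.ndarray, n_pca: int) -> float:
    """Mean over clusters of the proportion of members DAPC reassigns to
    their own cluster."""
    model = dapc(z, clusters, n_pca=n_pca)
    rates = []
    for c in np.unique(clusters):
        mask = clusters == c
        rates.append(float((model.clusters[mask] == c).mean()))
    return float(np.mean(rates))


def optim_a_score(
    z: ZEncoding,
    clusters: Sequence[int],
    pc_candidates: Sequence[int] | None = None,
    n_sim: int = 10,
    seed: int = 0,
) -> dict:
    """Optimal number of retained PCs by the a-score.

    For each candidate PC count: a-score = observed mean per-cluster
    correct-reassignment proportion minus the mean of the same quantity
    under ``n_sim`` random label permutations. Returns the argmax and the
    per-candidate scores.
    """
    clusters = np.asarray(clusters, dtype=int)
    k = len(np.unique(clusters))
    if k < 2:
        raise ValueError("a-score needs at least two clusters")
    max_pc = min(z.n - 1, z.matrix.shape[1])
    if pc_candidates is None:
        pc_candidates = list(range(1, max_pc + 1))
    rng = np.random.default_rng(seed)
    scores = {}
    for npc in pc_candidates:
        if npc < 1 or npc > max_pc:
            continue
        obs = _reassignment_rate(z, clusters, npc)
        null = [
            _reassignment_rate(z, rng.permutation(clusters), npc)
            for _ in range(n_sim)
        ]
        scores[int(npc)] = obs - float(np.mean(null))
    best = max(scores, key=scores.get)
    return {"n_pca": best, "a_scores": scores}


def assign_supertypes(
    model: SupertypeModel,
    individual_alleles: Mapping[str, Sequence[str]],
) -> tuple[dict[str, int], pd.DataFrame, dict[str, set[int]]]:
    """Supertype labels per allele and supertype profiles per individual.

    ``individual_alleles`` maps individual -> allele keys (``gene:label``)
    across genes. Returns (per-allele supertype, individuals x supertypes
    count table, gene -> supertype set).
    """
    allele_st = model.assignment()
    supertypes = sorted(set(allele_st.values()))
    rows = []
    for ind, alleles in individual_alleles.items():
        counts = Counter()
        for a in alleles:
            if a not in allele_st:
                raise KeyError(f"allele {a!r} missing from supertype model")
            counts[allele_st[a]] += 1
        rows.append([counts.get(s, 0) for s in supertypes])
    profiles = pd.DataFrame(
        rows, index=list(individual_alleles), columns=supertypes, dtype=int
    )
    gene_map: dict[str, set[int]] = {}
    for key, st in allele_st.items():
        gene = key.split(":", 1)[0] if ":" in key else key
        gene_map.setdefault(gene, set()).add(st)
    return allele_st, profiles, gene_map
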