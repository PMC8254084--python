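"""Expression-pattern clustering with Pearson correlation distance.

Three clustering views of the same per-gene time-course profiles:

* the conventional baseline — k-means over all pan-DEGs with d = 1 - r and
  the number of clusters chosen by mean silhouette over K = 5..10;
* GO-centric clustering — agglomerative clustering of the genes of one
  enriched term, cut into subclusters (default two) whose two largest
  groups are contrasted downstream for promoter motifs;
* sample-level clustering — a dendrogram of libraries used to check that
  replicates of each time point form a clade.

Profiles are replicate-averaged log2-CPM vectors, z-scored per gene, so
Pearson correlation reduces to a dot product and correlation-distance
k-means becomes spherical k-means on the z-rows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode
from sklearn.metrics import silhouette_samples

from .matrix import CountMatrix
from .de import effective_lib_sizes
from .ontology import AnnotationMap, GODag, classic_fisher


@dataclass
class ExpressionProfile:
    """Per-gene z-scored mean log2-CPM across time points."""

    values: pd.DataFrame  # genes x timepoints, rows mean 0 / sd 1 (or all-zero)
    constant_genes: set[str]  # rows that were flat before z-scoring

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def subset(self, genes) -> "ExpressionProfile":
        genes = list(genes)
        missing = set(genes) - set(self.values.index)
        if missing:
            raise KeyError(f"genes absent from profiles: {sorted(missing)[:5]}")
        return ExpressionProfile(self.values.loc[genes], self.constant_genes & set(genes))


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> 1..K
    silhouette: pd.Series  # per-gene silhouette (NaN when K == 1)
    mean_silhouette: float
    objective: float  # sum of correlation distances to assigned centroid

    @property
    def k(self) -> int:
        return int(self.labels.max())

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass
class GOCentricResult:
    """Dendrogram of one enriched term's genes plus subcluster bookkeeping."""

    term: str
    genes: list[str]
    linkage_matrix: np.ndarray | None  # None for a single-leaf degenerate tree
    subclusters: pd.Series | None = None  # gene -> subcluster label
    top_two: list[int] = field(default_factory=list)
    subcluster_means: pd.DataFrame | None = None

    def to_newick(self) -> str:
        if self.linkage_matrix is None:
            return f"{self.genes[0]};"
        return linkage_to_newick(self.linkage_matrix, self.genes)


def _zscore_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row z-scores (ddof 0); constant rows become zero vectors (flagged)."""
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    const = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[const] = 1.0
    z = (mat - mu) / sd
    z[const] = 0.0
    return z, const


def correlation_distance(z: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - r for z-scored rows; constant rows get r = 0."""
    m = z.shape[1]
    d = 1.0 - (z @ z.T) / m
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def log2_cpm(cm: CountMatrix, factors: np.ndarray | None = None, prior: float = 1.0) -> pd.DataFrame:
    eff = effective_lib_sizes(cm, factors)
    cpm = cm.counts / eff * 1e6
    return pd.DataFrame(np.log2(cpm + prior), index=cm.gene_ids, columns=cm.samples)


def build_profiles(
    cm: CountMatrix,
    genes: list[str] | None = None,
    factors: np.ndarray | None = None,
    prior: float = 1.0,
) -> ExpressionProfile:
    """Replicate-averaged, per-gene z-scored log2-CPM time-course profiles."""
    sub = cm if genes is None else cm.subset_genes(genes)
    lc = log2_cpm(sub, factors if genes is None else None, prior)
    if genes is not None and factors is not None:
        # factors computed on the full matrix still apply to the subset
        eff = cm.lib_sizes * np.asarray(factors, dtype=float)
        lc = pd.DataFrame(
            np.log2(sub.counts / eff * 1e6 + prior), index=sub.gene_ids, columns=sub.samples
        )
    order = sub.timepoint_order
    means = np.column_stack(
        [lc.iloc[:, sub.samples_at(t)].mean(axis=1).to_numpy() for t in order]
    )
    z, const = _zscore_rows(means)
    values = pd.DataFrame(z, index=sub.gene_ids, columns=order)
    return ExpressionProfile(values, {g for g, c in zip(sub.gene_ids, const) if c})


def _assign(z: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = z.shape[1]
    sim = z @ centroids.T / m  # Pearson r against each centroid
    labels = np.argmax(sim, axis=1)
    dist = 1.0 - sim[np.arange(len(z)), labels]
    return labels, dist


def _recentre(z: np.ndarray, labels: np.ndarray, k: int, old: np.ndarray) -> np.ndarray:
    centroids = old.copy()
    for c in range(k):
        members = z[labels == c]
        if len(members) == 0:
            continue
        mean = members.mean(axis=0)
        sd = mean.std()
        if sd == 0:
            continue  # keep previous centroid rather than a degenerate one
        centroids[c] = (mean - mean.mean()) / sd
    return centroids


def kmeans_correlation(
    ep: ExpressionProfile,
    k: int,
    seed: int = 0,
    restarts: int = 25,
    max_iter: int = 100,
) -> ClusterAssignment:
    """K-means under d = 1 - Pearson r, best of ``restarts`` seeded starts.

    Centroids are member means re-standardised each iteration; an emptied
    cluster is reseeded with the point farthest from its centroid.  The
    result is deterministic for a given seed.
    """
    z = ep.values.to_numpy(float)
    n = len(z)
    if not 1 <= k <= n:
        raise ValueError("k must lie in [1, n_genes]")
    if len(np.unique(z, axis=0)) < k:
        raise ValueError("fewer distinct profiles than requested clusters")
    best_labels, best_obj = None, np.inf
    streams = np.random.SeedSequence(seed).spawn(max(restarts, 1))
    for ss in streams:
        rng = np.random.default_rng(ss)
        centroids = z[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1)
        for _ in range(max_iter):
            new_labels, dist = _assign(z, centroids)
            for c in range(k):  # refill emptied clusters
                if not np.any(new_labels == c):
                    far = int(np.argmax(dist))
                    new_labels[far] = c
                    dist[far] = 0.0
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centroids = _recentre(z, labels, k, centroids)
        labels, dist = _assign(z, centroids)
        obj = float(dist.sum())
        if obj < best_obj - 1e-12:
            best_obj, best_labels = obj, labels
    assert best_labels is not None
    # contiguous labels 1..K ordered by first appearance
    remap: dict[int, int] = {}
    final = np.empty(n, dtype=int)
    for i, lab in enumerate(best_labels):
        remap.setdefault(lab, len(remap) + 1)
        final[i] = remap[lab]
    labels_s = pd.Series(final, index=ep.values.index, name="cluster")
    if k >= 2:
        d = correlation_distance(z)
        sil = silhouette_samples(d, final, metric="precomputed")
        sil_s = pd.Series(sil, index=ep.values.index, name="silhouette")
        mean_sil = float(np.mean(sil))
    else:
        sil_s = pd.Series(np.nan, index=ep.values.index, name="silhouette")
        mean_sil = float("nan")
    return ClusterAssignment(labels_s, sil_s, mean_sil, best_obj)


def select_k(
    ep: ExpressionProfile,
    k_range: range | list[int] = range(5, 11),
    seed: int = 0,
    restarts: int = 25,
) -> tuple[int, pd.DataFrame, dict[int, ClusterAssignment]]:
    """Choose K by maximum mean silhouette over ``k_range`` (default 5..10)."""
    ks = [int(k) for k in k_range]
    n = len(ep.values)
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError("k_range must lie within [2, n_genes - 1]")
    fits: dict[int, ClusterAssignment] = {}
    rows = []
    for k in ks:
        fits[k] = kmeans_correlation(ep, k, seed=seed, restarts=restarts)
        rows.append({"k": k, "mean_silhouette": fits[k].mean_silhouette})
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["mean_silhouette"].idxmax(), "k"])
    return chosen, table, fits


def cluster_enrichment(
    ca: ClusterAssignment,
    universe: set[str],
    ann: AnnotationMap,
    dag: GODag,
    min_node_size: int = 10,
    namespace: str | None = "biological_process",
) -> dict[int, pd.DataFrame]:
    """Classic Fisher enrichment with each cluster as the study set.

    The universe is typically the clustered gene set itself, which asks
    "which functions characterise this expression pattern relative to all
    differential genes" and exposes the dilution effect.
    """
    out: dict[int, pd.DataFrame] = {}
    for label in sorted(ca.labels.unique()):
        study = set(ca.members(label)) & universe
        if not study:
            import warnings

            warnings.warn(f"cluster {label} empty after universe restriction; skipped")
            continue
        out[label] = classic_fisher(study, universe, ann, dag, min_node_size, namespace)
    return out


def hier_cluster(ep: ExpressionProfile, term: str = "", method: str = "average") -> GOCentricResult:
    """Agglomerative clustering of profiles under d = 1 - r."""
    genes = ep.genes
    if len(genes) == 0:
        raise ValueError("no genes to cluster")
    if len(genes) == 1:
        return GOCentricResult(term, genes, None)
    d = correlation_distance(ep.values.to_numpy(float))
    z = linkage(squareform(d, checks=False), method=method)
    return GOCentricResult(term, genes, z)


def cut_subclusters(gr: GOCentricResult, k: int = 2) -> GOCentricResult:
    """Cut the dendrogram into ``k`` groups; keep the two largest on top.

    Labels are renumbered 1..k by decreasing size; ties are broken by the
    height at which the subcluster finished forming (lower first), then by
    smallest leaf index.
    """
    n = len(gr.genes)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot cut {n} leaves into {k} subclusters")
    if gr.linkage_matrix is None or k == 1:
        labels = np.ones(n, dtype=int)
    else:
        labels = fcluster(gr.linkage_matrix, t=k, criterion="maxclust")
    heights = _formation_heights(gr.linkage_matrix, labels)
    order = sorted(
        np.unique(labels),
        key=lambda c: (-(labels == c).sum(), heights[c], int(np.argmax(labels == c))),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    relabelled = pd.Series(
        [remap[c] for c in labels], index=pd.Index(gr.genes, name="gene"), name="subcluster"
    )
    top_two = sorted(remap[c] for c in order[: min(2, len(order))])
    return GOCentricResult(gr.term, gr.genes, gr.linkage_matrix, relabelled, top_two)


def _formation_heights(z: np.ndarray | None, labels: np.ndarray) -> dict[int, float]:
    """Height of the last merge internal to each flat cluster (0 for singletons)."""
    heights = {int(c): 0.0 for c in np.unique(labels)}
    if z is None:
        return heights
    n = len(labels)
    node_members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    for i, (a, b, h, _) in enumerate(z):
        members = np.concatenate([node_members[int(a)], node_members[int(b)]])
        node_members.append(members)
        labs = np.unique(labels[members])
        if len(labs) == 1:
            heights[int(labs[0])] = max(heights[int(labs[0])], float(h))
    return heights


def subcluster_means(gr: GOCentricResult, ep: ExpressionProfile) -> pd.DataFrame:
    if gr.subclusters is None:
        raise ValueError("cut_subclusters must run first")
    prof = ep.values.loc[gr.genes]
    return prof.groupby(gr.subclusters).mean()


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    tree = TreeNode.from_linkage_matrix(z, labels)
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


@dataclass
class SampleDendrogram:
    samples: list[str]
    linkage_matrix: np.ndarray
    monophyly: dict[str, bool]  # timepoint -> replicates form a clade

    @property
    def all_monophyletic(self) -> bool:
        return all(self.monophyly.values())

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage_matrix, self.samples)


def sample_dendrogram(
    cm: CountMatrix, factors: np.ndarray | None = None, method: str = "average"
) -> SampleDendrogram:
    """Cluster libraries on 1 - Pearson r over log2-CPM; report replicate clades.

    A time point is "monophyletic" when some internal node of the sample
    tree contains exactly its replicate libraries.
    """
    if cm.n_samples < 2:
        raise ValueError("need at least two samples")
    lc = log2_cpm(cm, factors).to_numpy(float).T  # samples x genes
    z, _ = _zscore_rows(lc)
    d = correlation_distance(z)
    zl = linkage(squareform(d, checks=False), method=method)
    clades = _clades(zl, cm.n_samples)
    monophyly = {}
    for t in cm.timepoint_order:
        members = frozenset(cm.samples_at(t))
        monophyly[t] = len(members) == 1 or members in clades
    return SampleDendrogram(list(cm.samples), zl, monophyly)


def _clades(z: np.ndarray, n: int) -> set[frozenset[int]]:
    members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    out: set[frozenset[int]] = set()
    for a, b, _, _ in z:
        merged = members[int(a)] | members[int(b)]
        members.append(merged)
        out.add(merged)
    return out
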