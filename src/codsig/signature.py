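"""Derivation of the COD signature from a mixed-histology cohort.

The derivation stage mirrors the discovery analysis: genes varying across
the cohort (sample SD above a threshold, default 0.9) feed unsupervised
hierarchical clustering of samples into three groups, labelled N / INT /
COD from their histological composition; differential expression (Welch t,
unadjusted P below a threshold, default 0.001) restricted to diffuse-type
samples yields list A (N vs INT) and list B (INT vs COD); the Venn
partition of A and B gives only-A / A-and-B / only-B, and the only-B genes
— expression changes tied to progression into the core diffuse-type group
rather than to tumorigenesis — form the signature, each with a direction
sign from its INT/COD mean difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .errors import StageError, ValidationError
from .io import CohortAnnotation, ExpressionMatrix
from .stats import welch_t_matrix

__all__ = [
    "ClusterModel", "GeneListPartition", "Signature", "DerivationResult",
    "variance_filter", "hierarchical_cluster", "label_clusters",
    "differential_genes", "venn_partition", "derive_signature",
    "derive_signature_detailed",
]

DISTANCES = {"one_minus_pearson", "euclidean"}
LINKAGES = {"average", "complete", "ward"}


@dataclass
class ClusterModel:
    """A fitted sample dendrogram cut into k flat clusters."""

    distance: str
    linkage: str
    k: int
    sample_ids: list[str]
    labels: np.ndarray          # cluster index in 1..k per sample
    merge_tree: np.ndarray      # scipy linkage matrix, n-1 merges with heights

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValidationError("cluster indices must lie in 1..k")
        if len(self.merge_tree) != len(self.sample_ids) - 1:
            raise ValidationError("merge tree must have n-1 entries")

    def members(self, cluster: int) -> list[str]:
        return [s for s, lab in zip(self.sample_ids, self.labels)
                if lab == cluster]


@dataclass
class GeneListPartition:
    """Venn decomposition of two differential gene lists."""

    list_a: frozenset[str]
    list_b: frozenset[str]
    only_a: frozenset[str] = field(init=False)
    a_and_b: frozenset[str] = field(init=False)
    only_b: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.list_a = frozenset(self.list_a)
        self.list_b = frozenset(self.list_b)
        self.only_a = self.list_a - self.list_b
        self.a_and_b = self.list_a & self.list_b
        self.only_b = self.list_b - self.list_a

    def counts(self) -> dict[str, int]:
        return {
            "a": len(self.list_a), "b": len(self.list_b),
            "only_a": len(self.only_a), "a_and_b": len(self.a_and_b),
            "only_b": len(self.only_b),
        }


@dataclass
class Signature:
    """The only-B gene list with per-gene direction signs and provenance."""

    gene_ids: list[str]
    directions: list[int]
    sd_threshold: float
    p_threshold: float
    distance: str = "one_minus_pearson"
    linkage: str = "average"

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.directions):
            raise ValidationError("gene_ids and directions must align")
        if any(d not in (-1, 1) for d in self.directions):
            raise ValidationError("directions must be +1 or -1")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene in signature")

    @property
    def direction_map(self) -> dict[str, int]:
        return dict(zip(self.gene_ids, self.directions))

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.gene_ids),
            "directions": [int(d) for d in self.directions],
            "sd_threshold": float(self.sd_threshold),
            "p_threshold": float(self.p_threshold),
            "distance": self.distance,
            "linkage": self.linkage,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "Signature":
        return cls(**json.loads(Path(path).read_text()))


def variance_filter(expr: ExpressionMatrix, sd_threshold: float) -> list[str]:
    """Genes whose sample SD (ddof=1) strictly exceeds the threshold.

    Returns the qualifying gene ids in matrix order (treat as a set).
    """
    if sd_threshold < 0:
        raise ValidationError("sd_threshold must be nonnegative")
    if expr.n_samples < 2:
        raise ValidationError("variance filter needs at least 2 samples")
    sds = expr.values.std(axis=1, ddof=1)
    return [g for g, sd in zip(expr.gene_ids, sds) if sd > sd_threshold]


def _sample_distances(values: np.ndarray, sample_ids: Sequence[str],
                      distance: str) -> np.ndarray:
    """Condensed pairwise sample distances over the given genes x samples block."""
    if distance == "euclidean":
        return pdist(values.T, metric="euclidean")
    if distance != "one_minus_pearson":
        raise ValidationError(f"unknown distance {distance!r}")
    sds = values.std(axis=0)
    flat = [s for s, sd in zip(sample_ids, sds) if sd == 0]
    if flat:
        raise ValidationError(
            f"zero-variance sample(s) under correlation distance: {flat[:5]}"
        )
    corr = np.corrcoef(values.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def hierarchical_cluster(expr: ExpressionMatrix, genes: Sequence[str],
                         k: int, distance: str = "one_minus_pearson",
                         linkage: str = "average") -> ClusterModel:
    """Agglomerative clustering of samples on the given genes, cut into k groups."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValidationError("need at least 2 genes to cluster on")
    if not 1 <= k <= expr.n_samples:
        raise ValidationError(f"k={k} out of range for {expr.n_samples} samples")
    if distance not in DISTANCES:
        raise ValidationError(f"unknown distance {distance!r}")
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}")
    sub = expr.values[expr.gene_index(genes)]
    condensed = _sample_distances(sub, expr.sample_ids, distance)
    tree = scipy_linkage(condensed, method=linkage)
    labels = fcluster(tree, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        raise ValidationError(
            f"dendrogram cut produced {len(np.unique(labels))} groups instead of "
            f"{k} (tied merge heights)"
        )
    return ClusterModel(distance=distance, linkage=linkage, k=k,
                        sample_ids=list(expr.sample_ids), labels=labels,
                        merge_tree=tree)


def label_clusters(model: ClusterModel,
                   annotations: Sequence[CohortAnnotation]) -> dict[int, str]:
    """Assign N / INT / COD to the three clusters from histological makeup.

    N is the cluster with the highest fraction of normal samples, INT the
    remaining cluster with the highest intestinal fraction, COD the
    remainder.  A single-criterion tie is broken by the other fraction; a
    tie on both normal and intestinal fractions is refused (manual labels
    required).
    """
    if model.k != 3:
        raise ValidationError("label_clusters requires a 3-cluster model")
    hist = {a.sample_id: a.histology for a in annotations}
    missing = [s for s in model.sample_ids if s not in hist]
    if missing:
        raise ValidationError(f"no annotation for sample(s) {missing[:5]}")
    frac: dict[int, tuple[float, float]] = {}
    for c in (1, 2, 3):
        members = model.members(c)
        if not members:
            raise ValidationError(f"cluster {c} is empty")
        hs = [hist[s] for s in members]
        frac[c] = (
            sum(h == "normal" for h in hs) / len(hs),
            sum(h == "intestinal" for h in hs) / len(hs),
        )

    def pick(candidates: list[int], primary: int, secondary: int) -> int:
        best = max(frac[c][primary] for c in candidates)
        top = [c for c in candidates if frac[c][primary] == best]
        if len(top) == 1:
            return top[0]
        # tie on the primary criterion: prefer the lowest secondary fraction
        low = min(frac[c][secondary] for c in top)
        low_set = [c for c in top if frac[c][secondary] == low]
        if len(low_set) == 1:
            return low_set[0]
        raise ValidationError(
            "clusters tie on both normal and intestinal fractions; "
            "manual cluster labels are required"
        )

    n_cluster = pick([1, 2, 3], primary=0, secondary=1)
    rest = [c for c in (1, 2, 3) if c != n_cluster]
    best_int = max(frac[c][1] for c in rest)
    top_int = [c for c in rest if frac[c][1] == best_int]
    if len(top_int) == 1:
        int_cluster = top_int[0]
    else:
        low_norm = min(frac[c][0] for c in top_int)
        low_set = [c for c in top_int if frac[c][0] == low_norm]
        if len(low_set) != 1:
            raise ValidationError(
                "clusters tie on both normal and intestinal fractions; "
                "manual cluster labels are required"
            )
        int_cluster = low_set[0]
    cod_cluster = next(c for c in rest if c != int_cluster)
    return {n_cluster: "N", int_cluster: "INT", cod_cluster: "COD"}


def differential_genes(expr: ExpressionMatrix, group_a: Sequence[str],
                       group_b: Sequence[str], p_threshold: float) -> list[str]:
    """Genes with Welch-t p below the threshold between two sample groups.

    Unadjusted p-values, per the discovery screen's P < 0.001 convention.
    Returns gene ids in matrix order.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    if not 0.0 <= p_threshold <= 1.0:
        raise ValidationError("p_threshold must be in [0, 1]")
    a = expr.values[:, expr.sample_index(group_a)]
    b = expr.values[:, expr.sample_index(group_b)]
    _, _, p = welch_t_matrix(a, b)
    return [g for g, pv in zip(expr.gene_ids, p) if pv < p_threshold]


def venn_partition(list_a: Sequence[str], list_b: Sequence[str]
                   ) -> GeneListPartition:
    """Set algebra only: only-A = A\\B, A-and-B = A∩B, only-B = B\\A."""
    return GeneListPartition(frozenset(list_a), frozenset(list_b))


@dataclass
class DerivationResult:
    """Everything the derivation produces, for reporting and inspection."""

    signature: Signature
    cluster_model: ClusterModel
    cluster_names: dict[int, str]
    partition: GeneListPartition
    filtered_genes: list[str]
    diffuse_groups: dict[str, list[str]]


def derive_signature_detailed(expr: ExpressionMatrix,
                              annotations: Sequence[CohortAnnotation],
                              sd_threshold: float = 0.9,
                              p_threshold: float = 0.001,
                              distance: str = "one_minus_pearson",
                              linkage: str = "average") -> DerivationResult:
    """Run the full derivation; see the module docstring for the stages."""
    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False
        return _Ctx()

    with stage("variance_filter"):
        filtered = variance_filter(expr, sd_threshold)
        if len(filtered) < 2:
            raise ValidationError(
                f"only {len(filtered)} gene(s) pass SD > {sd_threshold}"
            )
    with stage("clustering"):
        model = hierarchical_cluster(expr, filtered, k=3,
                                     distance=distance, linkage=linkage)
    with stage("cluster_labeling"):
        names = label_clusters(model, annotations)
    with stage("differential_expression"):
        hist = {a.sample_id: a.histology for a in annotations}
        groups: dict[str, list[str]] = {"N": [], "INT": [], "COD": []}
        for s, lab in zip(model.sample_ids, model.labels):
            if hist.get(s) == "diffuse":
                groups[names[lab]].append(s)
        n_diffuse = sum(len(v) for v in groups.values())
        if n_diffuse == 0:
            raise ValidationError("cohort contains no diffuse-type samples")
        for name, members in groups.items():
            if len(members) < 2:
                raise ValidationError(
                    f"cluster {name} holds {len(members)} diffuse sample(s); "
                    "at least 2 are needed for the differential screen"
                )
        list_a = differential_genes(expr, groups["N"], groups["INT"], p_threshold)
        list_b = differential_genes(expr, groups["INT"], groups["COD"], p_threshold)
    with stage("venn_partition"):
        partition = venn_partition(list_a, list_b)
    with stage("signature_assembly"):
        only_b_ordered = [g for g in expr.gene_ids if g in partition.only_b]
        gi = expr.gene_index(only_b_ordered)
        mean_cod = expr.values[np.ix_(gi, expr.sample_index(groups["COD"]))].mean(axis=1)
        mean_int = expr.values[np.ix_(gi, expr.sample_index(groups["INT"]))].mean(axis=1)
        directions = [1 if dc >= di else -1 for dc, di in zip(mean_cod, mean_int)]
        sig = Signature(gene_ids=only_b_ordered, directions=directions,
                        sd_threshold=sd_threshold, p_threshold=p_threshold,
                        distance=distance, linkage=linkage)
    return DerivationResult(signature=sig, cluster_model=model,
                            cluster_names=names, partition=partition,
                            filtered_genes=filtered, diffuse_groups=groups)


def derive_signature(expr: ExpressionMatrix,
                     annotations: Sequence[CohortAnnotation],
                     sd_threshold: float = 0.9, p_threshold: float = 0.001,
                     distance: str = "one_minus_pearson",
                     linkage: str = "average") -> Signature:
    """Convenience wrapper returning only the signature."""
    return derive_signature_detailed(
        expr, annotations, sd_threshold, p_threshold, distance, linkage
    ).signature
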