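"""Community drift statistics: Bray-Curtis, UPGMA, richness trends.

Community structures are compared with the Bray-Curtis dissimilarity
BC(x, y) = 1 - 2 sum_i min(x_i, y_i) / (sum_i x_i + sum_i y_i), which is 0
for identical composition and 1 for disjoint communities. Drift is the
series BC(lake, site) over river sites ordered by distance, summarized by a
Pearson regression against distance (river sites only; the lake's forced
zero anchor is excluded). Whole-transect structure is clustered with UPGMA
(average linkage) into an ultrametric dendrogram.

Correlation statistics reported here are signed Pearson r with two-sided
p-values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConstantSeriesError, ValidationError
from .network import pearson_with_p
from .tables import CountTable, ProportionTable, TransectMetadata


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity between two non-negative abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bray_curtis needs two equal-length 1-D vectors")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("abundances must be non-negative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValidationError("bray_curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarity matrix in [0, 1] with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape does not match labels")
        if np.isnan(v).any():
            raise ValidationError("dissimilarity matrix contains NaN")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity diagonal must be 0")
        if (v < -1e-12).any() or (v > 1 + 1e-9).any():
            raise ValidationError("dissimilarities must lie in [0, 1]")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 0.0)
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def bray_curtis_matrix(props: ProportionTable, sites: list[str] | None = None) -> DissimilarityMatrix:
    """All-pairs Bray-Curtis over site-averaged proportion vectors."""
    sites = list(sites) if sites is not None else list(props.site_ids)
    mat = np.vstack([props.site_vector(s) for s in sites])
    return _pairwise_bc(sites, mat)


def bray_curtis_matrix_samples(table: CountTable) -> DissimilarityMatrix:
    """All-pairs Bray-Curtis over individual duplicate samples (counts)."""
    return _pairwise_bc(list(table.sample_ids), table.counts.astype(float))


def _pairwise_bc(labels: list[str], mat: np.ndarray) -> DissimilarityMatrix:
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(mat[i], mat[j])
    return DissimilarityMatrix(labels=labels, values=out)


@dataclass(frozen=True)
class DriftRegression:
    """Pearson regression of BC-to-source against river distance."""

    r: float
    p_value: float
    n: int
    degenerate: bool = False


def drift_to_source(
    props: ProportionTable, metadata: TransectMetadata
) -> tuple[pd.Series, DriftRegression]:
    """Bray-Curtis drift away from the lake community.

    Returns the series BC(lake, river site) indexed by distance_m in
    downstream order, and its Pearson regression over river sites. A
    constant series (e.g. river identical to the lake) is reported as
    r = NaN with ``degenerate=True`` rather than an error.
    """
    rivers = metadata.river_sites
    if len(rivers) < 3:
        raise ValidationError("drift regression needs >= 3 river sites")
    lake_vec = props.site_vector(metadata.lake_site)
    dist = metadata.site_distances()
    values = [bray_curtis(lake_vec, props.site_vector(s)) for s in rivers]
    series = pd.Series(values, index=dist.loc[rivers].to_numpy(), name="bray_curtis")
    series.index.name = "distance_m"
    try:
        res = pearson_with_p(series.index.to_numpy(float), series.to_numpy())
        reg = DriftRegression(r=res.r, p_value=res.p, n=res.n)
    except ConstantSeriesError:
        reg = DriftRegression(r=float("nan"), p_value=float("nan"), n=len(rivers), degenerate=True)
    return series, reg


class Dendrogram:
    """Rooted ultrametric tree from average-linkage clustering.

    Wraps a scipy linkage matrix. Node heights are half the merge
    dissimilarity, so the cophenetic distance between two leaves (the merge
    dissimilarity of their lowest common ancestor) equals their tip-to-tip
    path length in the exported newick.
    """

    def __init__(self, linkage: np.ndarray, labels: list[str]):
        self.linkage = np.asarray(linkage, dtype=float)
        self.labels = list(labels)

    def cophenetic_matrix(self) -> pd.DataFrame:
        dense = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(dense, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            height = node.dist / 2.0
            length = parent_height - height
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = render(node.left, height)
            right = render(node.right, height)
            return f"({left},{right}):{length:.10g}"

        root_h = tree.dist / 2.0
        inner = f"({render(tree.left, root_h)},{render(tree.right, root_h)})"
        return inner + ";"

    def leaves_under_root_clades(self) -> tuple[set[str], set[str]]:
        """Leaf label sets of the two children of the root."""
        tree = hierarchy.to_tree(self.linkage)
        left = {self.labels[i] for i in tree.left.pre_order(lambda n: n.id)}
        right = {self.labels[i] for i in tree.right.pre_order(lambda n: n.id)}
        return left, right

    def monophyletic(self, group: set[str]) -> bool:
        """True if some clade's leaf set equals ``group`` exactly."""
        tree = hierarchy.to_tree(self.linkage)
        found = False

        def visit(node):
            nonlocal found
            leaves = {self.labels[i] for i in node.pre_order(lambda n: n.id)}
            if leaves == group:
                found = True
            if not node.is_leaf():
                visit(node.left)
                visit(node.right)

        visit(tree)
        return found


def upgma(d: DissimilarityMatrix) -> Dendrogram:
    """Average-linkage agglomeration of a validated dissimilarity matrix.

    scipy's implementation merges the closest pair first with deterministic
    lowest-index tie-breaking, so the output is reproducible.
    """
    if len(d.labels) < 2:
        raise ValidationError("UPGMA needs >= 2 labels")
    linkage = hierarchy.linkage(d.condensed(), method="average")
    return Dendrogram(linkage, d.labels)


@dataclass(frozen=True)
class RichnessTrend:
    richness: pd.Series
    r: float
    p_value: float
    degenerate: bool = False


def richness_trend(props: ProportionTable, metadata: TransectMetadata) -> RichnessTrend:
    """Detected-OTU richness per river site and its distance regression."""
    rivers = metadata.river_sites
    det = props.detection_frame().loc[rivers]
    counts = det.sum(axis=1).astype(int)
    dist = metadata.site_distances().loc[rivers].to_numpy(float)
    counts.index = dist
    counts.index.name = "distance_m"
    counts.name = "richness"
    try:
        res = pearson_with_p(dist, counts.to_numpy(float))
        return RichnessTrend(richness=counts, r=res.r, p_value=res.p)
    except ConstantSeriesError:
        return RichnessTrend(
            richness=counts, r=float("nan"), p_value=float("nan"), degenerate=True
        )
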