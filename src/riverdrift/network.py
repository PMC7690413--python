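"""Pearson covariation structure among OTUs and environmental parameters.

Implements the correlation layer of the analysis: pairwise Pearson tests
with two-sided t-distributed p-values, distance-trend classes for every
variable at p < 0.05, a covariation graph whose edges are the correlations
with p below a threshold (0.01 by default), and a seeded force-directed
layout in which |r| acts as the edge weight.

No multiple-testing correction is applied by default (raw p thresholds);
Benjamini-Hochberg is available as an option and its effect is logged.
Correlations use river-site series only: tributaries never enter a distance
series, and the lake can be included via ``include_lake`` where a caller
wants the full main-stem series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantSeriesError, ValidationError
from .tables import ProportionTable, TransectMetadata

logger = logging.getLogger(__name__)

TREND_DECREASING = "decreasing"
TREND_NONE = "none"
TREND_INCREASING = "increasing"


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int


def pearson_with_p(x, y) -> PearsonResult:
    """Pearson r with a two-sided p from t = r sqrt(n-2)/sqrt(1-r^2).

    Raises :class:`ConstantSeriesError` (not a numerical error) when either
    series has zero variance, and requires n >= 3 so the t test has at least
    one degree of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_with_p needs two equal-length 1-D series")
    n = x.size
    if n < 3:
        raise ValidationError(f"pearson_with_p needs n >= 3, got n = {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("constant series has no defined correlation")
    r, p = stats.pearsonr(x, y)
    return PearsonResult(r=float(r), p=float(p), n=n)


def trend_classes(
    variables: pd.DataFrame, distances: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Classify each column of ``variables`` against ``distances``.

    Returns a frame indexed by variable with columns ``r``, ``p``, ``trend``
    (decreasing / none / increasing). Constant series are classified
    ``none`` with NaN statistics.
    """
    distances = np.asarray(distances, dtype=float)
    rows = []
    for name in variables.columns:
        series = variables[name].to_numpy(dtype=float)
        try:
            res = pearson_with_p(distances, series)
        except ConstantSeriesError:
            rows.append((name, np.nan, np.nan, TREND_NONE))
            continue
        if res.p < alpha:
            trend = TREND_DECREASING if res.r < 0 else TREND_INCREASING
        else:
            trend = TREND_NONE
        rows.append((name, res.r, res.p, trend))
    return pd.DataFrame(rows, columns=["variable", "r", "p", "trend"]).set_index("variable")


def _river_variables(
    props: ProportionTable,
    metadata: TransectMetadata,
    env: pd.DataFrame | None,
    include_lake: bool,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, str]]:
    sites = metadata.river_sites
    if include_lake:
        sites = [metadata.lake_site, *sites]
    dist = metadata.site_distances().loc[sites].to_numpy(dtype=float)
    otus = props.to_dataframe().loc[sites]
    kinds = {o: "otu" for o in otus.columns}
    blocks = [otus]
    if env is not None:
        env_block = env.loc[sites].astype(float)
        clash = set(env_block.columns) & set(otus.columns)
        if clash:
            raise ValidationError(f"environmental names clash with OTU ids: {sorted(clash)}")
        blocks.append(env_block)
        kinds.update({c: "env" for c in env_block.columns})
    return pd.concat(blocks, axis=1), dist, kinds


def distance_trends(
    props: ProportionTable,
    metadata: TransectMetadata,
    env: pd.DataFrame | None = None,
    alpha: float = 0.05,
    include_lake: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Distance-trend class for every OTU (and environmental parameter).

    Series are relative proportions (or parameter values) over river sites
    ordered by distance; p < ``alpha`` with a negative/positive r yields
    decreasing/increasing. ``fdr=True`` applies Benjamini-Hochberg to the
    p-values before thresholding (off by default).
    """
    if env is None:
        env = metadata.env
    variables, dist, kinds = _river_variables(props, metadata, env, include_lake)
    out = trend_classes(variables, dist, alpha=alpha)
    if fdr:
        ok = out["p"].notna()
        adj = stats.false_discovery_control(out.loc[ok, "p"].to_numpy())
        before = int((out.loc[ok, "p"] < alpha).sum())
        out.loc[ok, "p"] = adj
        out["trend"] = TREND_NONE
        sig = ok & (out["p"] < alpha)
        out.loc[sig & (out["r"] < 0), "trend"] = TREND_DECREASING
        out.loc[sig & (out["r"] > 0), "trend"] = TREND_INCREASING
        logger.info(
            "distance_trends: BH correction reduced significant calls %d -> %d",
            before,
            int(sig.sum()),
        )
    out["kind"] = [kinds[v] for v in out.index]
    return out


def build_network(
    props: ProportionTable,
    metadata: TransectMetadata,
    env: pd.DataFrame | None = None,
    alpha: float = 0.01,
    include_lake: bool = False,
    include_distance: bool = True,
    domains: dict[str, str] | None = None,
    fdr: bool = False,
) -> nx.Graph:
    """Covariation graph over dominant OTUs and environmental parameters.

    Nodes carry ``kind`` ('otu', 'env' or 'distance') and, for OTUs, an
    optional gene ``domain`` tag. An edge (u, v) exists iff the Pearson
    p-value over river-site series is below ``alpha``; edges carry ``r``,
    ``p``, ``sign`` and ``weight`` = |r| (used by the layout).
    """
    if env is None:
        env = metadata.env
    variables, dist, kinds = _river_variables(props, metadata, env, include_lake)
    if include_distance:
        variables = variables.copy()
        variables["distance_from_lake_m"] = dist
        kinds["distance_from_lake_m"] = "distance"
    names = list(variables.columns)
    graph = nx.Graph(alpha=alpha)
    for name in names:
        attrs = {"kind": kinds[name]}
        if domains and name in domains:
            attrs["domain"] = domains[name]
        graph.add_node(name, **attrs)
    results = []
    for i in range(len(names)):
        xi = variables.iloc[:, i].to_numpy(dtype=float)
        for j in range(i + 1, len(names)):
            try:
                res = pearson_with_p(xi, variables.iloc[:, j].to_numpy(dtype=float))
            except ConstantSeriesError:
                continue
            results.append((names[i], names[j], res.r, res.p))
    if not results:
        return graph
    pvals = np.array([p for *_ignored, p in results])
    if fdr:
        pvals = stats.false_discovery_control(pvals)
    for (u, v, r, _), p in zip(results, pvals):
        if p < alpha:
            graph.add_edge(u, v, r=r, p=float(p), sign=int(np.sign(r)), weight=abs(r))
    return graph


def fr_layout(graph: nx.Graph, seed: int = 0, iterations: int = 50) -> dict[str, np.ndarray]:
    """Seeded Fruchterman-Reingold layout with |r|-weighted attraction.

    Deterministic for a given seed; a single node is placed at the origin.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot lay out an empty graph")
    if graph.number_of_nodes() == 1:
        (node,) = graph.nodes
        return {node: np.zeros(2)}
    pos = nx.spring_layout(graph, seed=seed, iterations=iterations, weight="weight")
    return {n: np.asarray(p, dtype=float) for n, p in pos.items()}


def edges_frame(graph: nx.Graph) -> pd.DataFrame:
    """Edge list as a tidy frame (node_u, node_v, r, p, sign)."""
    rows = [
        (u, v, d["r"], d["p"], d["sign"]) for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_u", "node_v", "r", "p", "sign"])
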