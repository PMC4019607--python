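"""Anti-correlation gating of predicted miRNA->target pairs.

A predicted pair becomes a network edge only when the miRNA and target
trajectories over the shared timepoint grid are significantly
(anti-)correlated: standard product-moment r with a two-sided p from
t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.  Trajectories
are timepoint means; by default both series are log2-transformed before
correlating, since normalized expression is ratio-scaled.  The result
is a bipartite miRNA-gene graph exported as an edge-list TSV and
GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantSeriesError, GridMismatchError, ParameterError
from .expression import DifferentialCall
from .target_prediction import SITE_TYPES, TargetPrediction

log = logging.getLogger(__name__)


@dataclass
class LinkEdge:
    mirna_id: str
    gene_id: str
    r: float
    p: float
    n: int
    direction_consistent: bool
    n_sites: int
    best_site_type: str


def pearson_r_test(
    x: pd.Series, y: pd.Series, name_x: str = "x", name_y: str = "y"
) -> tuple[float, float, int]:
    """Pearson r with a two-sided t-test p over a shared timepoint grid.

    Requires >= 3 shared timepoints and non-constant series; |r| = 1 is
    reported with p = 0.
    """
    if not list(x.index) == list(y.index):
        raise GridMismatchError(
            f"timepoint grids differ: {list(x.index)} vs {list(y.index)}"
        )
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(xv)
    if n < 3:
        raise ParameterError(f"need >= 3 timepoints, got {n}")
    for name, v in ((name_x, xv), (name_y, yv)):
        if np.ptp(v) == 0:
            raise ConstantSeriesError(f"constant series for {name!r}")
    r, p = stats.pearsonr(xv, yv)
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        p = 0.0
    return float(r), float(p), n


def predict_links(
    mirna_trajs: pd.DataFrame,
    gene_trajs: pd.DataFrame,
    predictions: list[TargetPrediction],
    alpha: float = 0.05,
    mode: str = "negative",
    log2_transform: bool = True,
    calls: dict[str, DifferentialCall] | None = None,
) -> list[LinkEdge]:
    """Correlation-gated edges for retained target predictions.

    For every (miRNA, gene) prediction with both trajectories present,
    compute (r, p, n); in ``mode="negative"`` an edge is emitted iff
    r < 0 and p < alpha, in ``mode="any"`` iff p < alpha.  Pairs lacking
    a trajectory, and pairs whose trajectory is constant (correlation
    undefined), are skipped with a logged count.  Edges are sorted by
    ascending p, then (miRNA, gene).
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if mode not in ("negative", "any"):
        raise ParameterError(f"mode must be 'negative' or 'any', got {mode!r}")
    if not mirna_trajs.columns.equals(gene_trajs.columns):
        raise GridMismatchError(
            "miRNA and gene trajectory tables are on different timepoint grids"
        )
    mt = np.log2(mirna_trajs) if log2_transform else mirna_trajs
    gt = np.log2(gene_trajs) if log2_transform else gene_trajs

    edges = []
    skipped = 0
    for pred in predictions:
        if pred.mirna_id not in mt.index or pred.gene_id not in gt.index:
            skipped += 1
            continue
        x = mt.loc[pred.mirna_id]
        y = gt.loc[pred.gene_id]
        try:
            r, p, n = pearson_r_test(x, y, pred.mirna_id, pred.gene_id)
        except ConstantSeriesError:
            skipped += 1
            continue
        if p >= alpha:
            continue
        if mode == "negative" and r >= 0:
            continue
        gene_ratio = float(gene_trajs.loc[pred.gene_id].iloc[-1]) / float(
            gene_trajs.loc[pred.gene_id].iloc[0]
        )
        call = calls.get(pred.mirna_id) if calls else None
        direction_consistent = (
            (call is not None and call.direction == "down" and gene_ratio > 1)
            or (call is not None and call.direction == "up" and gene_ratio < 1)
            or r < 0
        )
        site_rank = {t: i for i, t in enumerate(SITE_TYPES)}
        best_site = min(pred.sites, key=lambda s: site_rank[s.site_type])
        edges.append(
            LinkEdge(
                mirna_id=pred.mirna_id,
                gene_id=pred.gene_id,
                r=r,
                p=p,
                n=n,
                direction_consistent=direction_consistent,
                n_sites=len(pred.sites),
                best_site_type=best_site.site_type,
            )
        )
    if skipped:
        log.info("skipped %d pairs lacking usable trajectories", skipped)
    edges.sort(key=lambda e: (e.p, e.mirna_id, e.gene_id))
    return edges


EDGE_COLUMNS = (
    "mirna",
    "gene",
    "r",
    "p",
    "n",
    "n_sites",
    "best_site_type",
    "direction_consistent",
)


def export_network(
    edges: list[LinkEdge], tsv_path: str | Path, graphml_path: str | Path
) -> None:
    """Write the bipartite edge list as TSV and GraphML, deterministically.

    Node attribute ``node_type`` distinguishes miRNAs from genes.  Empty
    edge lists still produce valid files with headers.
    """
    rows = [
        (
            e.mirna_id,
            e.gene_id,
            e.r,
            e.p,
            e.n,
            e.n_sites,
            e.best_site_type,
            e.direction_consistent,
        )
        for e in edges
    ]
    df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    with open(tsv_path, "w") as fh:
        fh.write("# miRNA-gene anti-correlation edges; r/p from Pearson test\n")
        df.to_csv(fh, sep="\t", index=False)

    graph = nx.Graph()
    for mirna in sorted({e.mirna_id for e in edges}):
        graph.add_node(mirna, node_type="mirna")
    for gene in sorted({e.gene_id for e in edges}):
        graph.add_node(gene, node_type="gene")
    for e in sorted(edges, key=lambda e: (e.mirna_id, e.gene_id)):
        graph.add_edge(
            e.mirna_id,
            e.gene_id,
            r=float(e.r),
            p=float(e.p),
            n_sites=int(e.n_sites),
            best_site_type=e.best_site_type,
            direction_consistent=bool(e.direction_consistent),
        )
    nx.write_graphml(graph, str(graphml_path))
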