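"""Assembly of the DMR - miRNA - mRNA regulatory network.

Candidate edges come from structure (a DMR overlapping a miRNA promoter;
a miRNA with a predicted or externally supplied target) gated by
differential status, and are retained only when the per-sample values of
the two endpoints correlate strongly enough: |r| >= r_min and
p <= p_max, with the Pearson p taken from the t transform
t = r * sqrt((n-2)/(1-r^2)).

Strict mode additionally requires the biologically directed pattern of a
promoter-methylation chain: anticorrelation on both edge kinds and
sign-consistent differential calls (hypomethylated promoter with an
upregulated miRNA repressing a downregulated target, or the mirror).
Permissive mode keeps any sign, reproducing mixed-direction networks.
Triplets are chains (DMR, miRNA, mRNA) sharing a retained miRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ParameterError, UndefinedCorrelationError
from .methylation import DMR
from .regulatory_map import TargetPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeRecord:
    """One scored candidate edge of the regulatory network."""

    kind: str  # 'meth_mirna' | 'mirna_mrna'
    source: str
    target: str
    r: float
    p_value: float
    retained: bool


@dataclass
class RegulatoryNetwork:
    """Typed nodes, retained edges and (DMR, miRNA, mRNA) triplets.

    ``graph`` holds only retained edges; every node in it participates in
    at least one retained edge.  ``edges`` records all scored candidates,
    retained or not.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    edges: list[EdgeRecord] = field(default_factory=list)
    strict: bool = True

    @property
    def retained_edges(self) -> list[EdgeRecord]:
        return [e for e in self.edges if e.retained]

    @property
    def triplets(self) -> list[tuple[str, str, str]]:
        """(dmr, mirna, mrna) chains through retained edges."""
        out = []
        for d, mi in self.graph.edges:
            if self.graph.edges[d, mi].get("kind") != "meth_mirna":
                continue
            for _, g in self.graph.out_edges(mi):
                if self.graph.edges[mi, g].get("kind") == "mirna_mrna":
                    out.append((d, mi, g))
        return sorted(out)


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p for paired vectors.

    Pearson p uses the exact t transform; Spearman ranks first (average
    ranks on ties).  Raises :class:`UndefinedCorrelationError` when either
    vector has zero variance, and :class:`ParameterError` for n < 3 or
    non-finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ParameterError(f"need >= 3 paired observations, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ParameterError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in correlation input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return float(res[0]), float(res[1])


def _edge_allowed_strict(kind: str, src_dir: str, dst_dir: str) -> bool:
    if kind == "meth_mirna":
        return (src_dir, dst_dir) in {("hypo", "up"), ("hyper", "down")}
    return (src_dir, dst_dir) in {("up", "down"), ("down", "up")}


def build_network(
    dmrs: Sequence[DMR],
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    promoter_pairs: Sequence[tuple[DMR, str]],
    target_pairs: Sequence[TargetPair],
    dmr_meth_levels: pd.DataFrame,
    mirna_norm: pd.DataFrame,
    mrna_norm: pd.DataFrame,
    r_min: float = 0.7,
    p_max: float = 0.05,
    strict: bool = True,
    method: str = "pearson",
) -> RegulatoryNetwork:
    """Score candidate edges and assemble the regulatory network.

    Parameters
    ----------
    dmrs
        Screened DMRs (already significant).
    de_mirna, de_mrna
        DE tables with a 'status' column ('up'/'down'/'ns').
    promoter_pairs
        (DMR, mirna_id) promoter-overlap candidates.
    target_pairs
        miRNA -> mRNA candidates (seed match or external).
    dmr_meth_levels
        Per-sample methylation level of each DMR, rows 'chrom:start-end'.
    mirna_norm, mrna_norm
        Normalized expression matrices sharing the sample columns.
    """
    samples = list(mirna_norm.columns)
    if list(mrna_norm.columns) != samples:
        raise AlignmentError("miRNA and mRNA matrices have different samples")
    if not set(samples) <= set(dmr_meth_levels.columns):
        raise AlignmentError("methylation level table misses expression samples")
    dmr_meth_levels = dmr_meth_levels[samples]

    net = RegulatoryNetwork(strict=strict)
    g = net.graph
    mirna_status = de_mirna["status"]
    mrna_status = de_mrna["status"]
    dmr_by_name = {f"{d.chrom}:{d.start}-{d.end}": d for d in dmrs}

    n_skipped = 0
    for d, mirna_id in promoter_pairs:
        name = f"{d.chrom}:{d.start}-{d.end}"
        if name not in dmr_by_name or mirna_id not in mirna_status.index:
            continue
        status = mirna_status.loc[mirna_id]
        if status == "ns":
            continue
        x = dmr_meth_levels.loc[name].to_numpy(dtype=float)
        y = mirna_norm.loc[mirna_id].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        try:
            r, p = correlate(x[keep], y[keep], method)
        except (UndefinedCorrelationError, ParameterError):
            n_skipped += 1
            continue
        retained = p <= p_max and abs(r) >= r_min
        if strict:
            retained = retained and r < 0 and _edge_allowed_strict(
                "meth_mirna", d.direction, str(status)
            )
        net.edges.append(EdgeRecord("meth_mirna", name, mirna_id, r, p, retained))
        if retained:
            g.add_node(name, kind="dmr", direction=d.direction)
            g.add_node(mirna_id, kind="mirna", direction=str(status))
            g.add_edge(name, mirna_id, kind="meth_mirna", r=r, p_value=p)

    for tp in target_pairs:
        if tp.mirna_id not in mirna_status.index or tp.mrna_id not in mrna_status.index:
            continue
        s_mi = mirna_status.loc[tp.mirna_id]
        s_g = mrna_status.loc[tp.mrna_id]
        if s_mi == "ns" or s_g == "ns":
            continue
        x = mirna_norm.loc[tp.mirna_id].to_numpy(dtype=float)
        y = mrna_norm.loc[tp.mrna_id].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        try:
            r, p = correlate(x[keep], y[keep], method)
        except (UndefinedCorrelationError, ParameterError):
            n_skipped += 1
            continue
        retained = p <= p_max and abs(r) >= r_min
        if strict:
            retained = retained and r < 0 and _edge_allowed_strict(
                "mirna_mrna", str(s_mi), str(s_g)
            )
        net.edges.append(
            EdgeRecord("mirna_mrna", tp.mirna_id, tp.mrna_id, r, p, retained)
        )
        if retained:
            g.add_node(tp.mirna_id, kind="mirna", direction=str(s_mi))
            g.add_node(tp.mrna_id, kind="mrna", direction=str(s_g))
            g.add_edge(tp.mirna_id, tp.mrna_id, kind="mirna_mrna", r=r, p_value=p)

    if n_skipped:
        logger.info("build_network: %d candidate edges skipped (undefined r)", n_skipped)
    logger.info(
        "build_network: %d candidates scored, %d retained, %d triplets",
        len(net.edges), len(net.retained_edges), len(net.triplets),
    )
    return net


def summarize_network(network: RegulatoryNetwork) -> dict:
    """Node counts per class and direction, edge counts per kind, triplets."""
    g = network.graph
    nodes = {
        "dmr": {"total": 0, "hyper": 0, "hypo": 0},
        "mirna": {"total": 0, "up": 0, "down": 0},
        "mrna": {"total": 0, "up": 0, "down": 0},
    }
    for _, attrs in g.nodes(data=True):
        kind, direction = attrs["kind"], attrs["direction"]
        nodes[kind]["total"] += 1
        nodes[kind][direction] += 1
    edges = {"meth_mirna": 0, "mirna_mrna": 0}
    for _, _, attrs in g.edges(data=True):
        edges[attrs["kind"]] += 1
    return {"nodes": nodes, "edges": edges, "n_triplets": len(network.triplets)}


def recovery_metrics(
    network: RegulatoryNetwork, truth, require_dmr_overlap: bool = True
) -> dict:
    """Precision/recall of planted-triplet recovery.

    A recovered (dmr, mirna, mrna) chain counts as true when its miRNA
    and mRNA match a planted triplet and (by default) its DMR interval
    overlaps the planted promoter interval.  Scoring is over unique
    (mirna, mrna) pairs.
    """
    planted = {(t.mirna_id, t.mrna_id): t for t in truth.triplets}
    recovered: dict[tuple[str, str], bool] = {}
    for d_name, mi, gene in network.triplets:
        key = (mi, gene)
        good = key in planted
        if good and require_dmr_overlap:
            t = planted[key]
            chrom, span = d_name.split(":")
            start, end = (int(v) for v in span.split("-"))
            good = (
                chrom == t.dmr_chrom and start < t.dmr_end and t.dmr_start < end
            )
        recovered[key] = recovered.get(key, False) or good
    n_rec = len(recovered)
    n_true_rec = sum(recovered.values())
    precision = n_true_rec / n_rec if n_rec else float("nan")
    recall = n_true_rec / len(planted) if planted else float("nan")
    return {
        "n_recovered": n_rec,
        "n_true_recovered": n_true_rec,
        "n_planted": len(planted),
        "precision": precision,
        "recall": recall,
    }


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_network(
    network: RegulatoryNetwork, directory: str | Path,
    formats: Sequence[str] = ("tsv", "graphml"),
) -> list[Path]:
    """Write nodes.tsv + edges.tsv and/or network.graphml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fmt in formats:
        if fmt == "tsv":
            nodes = pd.DataFrame(
                [
                    {"node": n, "kind": a["kind"], "direction": a["direction"]}
                    for n, a in network.graph.nodes(data=True)
                ],
                columns=["node", "kind", "direction"],
            )
            edges = pd.DataFrame(
                [
                    {"source": u, "target": v, "kind": a["kind"],
                     "r": a["r"], "p_value": a["p_value"]}
                    for u, v, a in network.graph.edges(data=True)
                ],
                columns=["source", "target", "kind", "r", "p_value"],
            )
            nodes.to_csv(directory / "nodes.tsv", sep="\t", index=False)
            edges.to_csv(directory / "edges.tsv", sep="\t", index=False)
            written += [directory / "nodes.tsv", directory / "edges.tsv"]
        elif fmt == "graphml":
            path = directory / "network.graphml"
            nx.write_graphml(network.graph, path)
            written.append(path)
        else:
            raise ParameterError(f"unknown export format {fmt!r}")
    return written


def read_graphml(path: str | Path, strict: bool = True) -> RegulatoryNetwork:
    """Re-load a network exported as GraphML (retained edges only)."""
    g = nx.read_graphml(str(path))
    net = RegulatoryNetwork(graph=nx.DiGraph(g), strict=strict)
    net.edges = [
        EdgeRecord(a["kind"], u, v, float(a["r"]), float(a["p_value"]), True)
        for u, v, a in net.graph.edges(data=True)
    ]
    return net
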