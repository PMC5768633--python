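"""lncRNA-mRNA co-expression network construction and cis/trans classification.

Gene-level FPKM profiles of differentially expressed lncRNA genes are
correlated against those of differentially expressed mRNA genes (Pearson, over
a chosen sample subset).  Pairs with r^2 >= 0.9 and correlation-test p < 0.01
become edges of a bipartite network; both positively and negatively correlated
pairs are retained.  An edge is a potential *cis* regulation when the two genes
sit on the same chromosome within 1000 kb (closest span boundaries, inclusive
window), otherwise *trans*.

Networks are exported as Cytoscape-readable SIF/GraphML plus node/edge TSVs
that round-trip losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exprio import ExpressionMatrix

log = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "lnc_gene",
    "mrna_gene",
    "r",
    "r_squared",
    "p",
    "sign",
    "locality",
    "distance_bp",
]


def correlate_pairs(
    gene_matrix: ExpressionMatrix,
    lnc_ids: set[str],
    mrna_ids: set[str],
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """All-pairs Pearson correlation between lncRNA and mRNA gene profiles.

    p values come from the t transform t = r * sqrt((n-2)/(1-r^2)) with
    df = n - 2 (two-sided).  Genes with zero variance over the selected
    samples produce no candidates (logged), rather than NaN correlations.
    """
    overlap = set(lnc_ids) & set(mrna_ids)
    if overlap:
        raise ValueError(f"id sets overlap: {sorted(overlap)[:5]}")
    if samples is None:
        samples = gene_matrix.sample_ids
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a correlation test")
    data = gene_matrix.data[list(samples)]
    lnc = sorted(set(lnc_ids) & set(data.index))
    mrna = sorted(set(mrna_ids) & set(data.index))
    X = data.loc[lnc].to_numpy(dtype=float)
    Y = data.loc[mrna].to_numpy(dtype=float)

    def _drop_constant(ids: list[str], M: np.ndarray) -> tuple[list[str], np.ndarray]:
        sd = M.std(axis=1)
        const = sd == 0
        for gid in np.asarray(ids)[const]:
            log.warning("gene %s has zero variance over the selected samples; skipped", gid)
        return [g for g, c in zip(ids, const) if not c], M[~const]

    lnc, X = _drop_constant(lnc, X)
    mrna, Y = _drop_constant(mrna, Y)
    if not lnc or not mrna:
        return pd.DataFrame(columns=["lnc_gene", "mrna_gene", "r", "r_squared", "p"])
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    R = (Xc @ Yc.T) / np.sqrt(
        np.outer((Xc**2).sum(axis=1), (Yc**2).sum(axis=1))
    )
    R = np.clip(R, -1.0, 1.0)
    n = len(samples)
    with np.errstate(divide="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, 0.0))
    P = 2.0 * stats.t.sf(np.abs(t), n - 2)
    P = np.where(R**2 >= 1.0, 0.0, P)
    ii, jj = np.meshgrid(range(len(lnc)), range(len(mrna)), indexing="ij")
    return pd.DataFrame(
        {
            "lnc_gene": np.asarray(lnc)[ii.ravel()],
            "mrna_gene": np.asarray(mrna)[jj.ravel()],
            "r": R.ravel(),
            "r_squared": R.ravel() ** 2,
            "p": P.ravel(),
        }
    )


def filter_edges(
    candidates: pd.DataFrame, r2_min: float = 0.9, p_max: float = 0.01
) -> pd.DataFrame:
    """Keep strongly correlated pairs: r^2 >= r2_min (inclusive) and p < p_max."""
    if not (0 <= r2_min <= 1 and 0 <= p_max <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    keep = (candidates["r_squared"] >= r2_min) & (candidates["p"] < p_max)
    edges = candidates.loc[keep].copy()
    edges["sign"] = np.where(edges["r"] >= 0, "positive", "negative")
    return edges.reset_index(drop=True)


def span_distance(
    span_a: tuple[str, int, int], span_b: tuple[str, int, int]
) -> int | None:
    """Gap in bp between closest boundaries of two gene spans; None across
    chromosomes, 0 when the spans overlap.  Coordinates 1-based inclusive."""
    chrom_a, start_a, end_a = span_a
    chrom_b, start_b, end_b = span_b
    if chrom_a != chrom_b:
        return None
    return max(0, max(start_a, start_b) - min(end_a, end_b))


def classify_cis_trans(
    edges: pd.DataFrame, spans: pd.DataFrame, window_bp: int = 1_000_000
) -> pd.DataFrame:
    """Label each edge cis or trans by genomic distance.

    Same chromosome with boundary gap <= window_bp (inclusive) -> cis; larger
    gaps or different chromosomes -> trans (distance undefined across
    chromosomes).  ``spans`` is the per-gene table from
    :func:`lhnet.exprio.gene_spans`.
    """
    needed = set(edges["lnc_gene"]) | set(edges["mrna_gene"])
    missing = needed - set(spans.index)
    if missing:
        raise ValueError(f"genes missing from annotation: {sorted(missing)[:10]}")
    out = edges.copy()
    localities, distances = [], []
    for row in out.itertuples(index=False):
        a = spans.loc[row.lnc_gene]
        b = spans.loc[row.mrna_gene]
        d = span_distance(
            (a["chromosome"], int(a["start"]), int(a["end"])),
            (b["chromosome"], int(b["start"]), int(b["end"])),
        )
        if d is None:
            localities.append("trans")
            distances.append(np.nan)
        else:
            localities.append("cis" if d <= window_bp else "trans")
            distances.append(float(d))
    out["locality"] = localities
    out["distance_bp"] = distances
    return out


def build_network(edges: pd.DataFrame, comparison: str = "") -> nx.Graph:
    """Assemble a deduplicated bipartite lncRNA-mRNA graph from an edge table."""
    g = nx.Graph(comparison=comparison)
    roles: dict[str, str] = {}
    for row in edges.itertuples(index=False):
        for node, role in ((row.lnc_gene, "lncRNA"), (row.mrna_gene, "mRNA")):
            if roles.get(node, role) != role:
                raise ValueError(f"gene {node!r} appears as both lncRNA and mRNA")
            roles[node] = role
        attrs = {
            k: getattr(row, k)
            for k in ("r", "r_squared", "p", "sign", "locality", "distance_bp")
            if hasattr(row, k)
        }
        g.add_node(row.lnc_gene, role="lncRNA")
        g.add_node(row.mrna_gene, role="mRNA")
        g.add_edge(row.lnc_gene, row.mrna_gene, **attrs)
    return g


def network_stats(g: nx.Graph, n_lnc_candidates: int | None = None) -> dict:
    """Summary counts; fraction of candidate lncRNAs that acquired >= 1 edge."""
    lnc = [n for n, d in g.nodes(data=True) if d.get("role") == "lncRNA"]
    mrna = [n for n, d in g.nodes(data=True) if d.get("role") == "mRNA"]
    connected = sum(1 for n in lnc if g.degree(n) > 0)
    total = n_lnc_candidates if n_lnc_candidates is not None else len(lnc)
    cis = sum(1 for *_, d in g.edges(data=True) if d.get("locality") == "cis")
    trans = sum(1 for *_, d in g.edges(data=True) if d.get("locality") == "trans")
    return {
        "n_lnc_nodes": len(lnc),
        "n_mrna_nodes": len(mrna),
        "n_edges": g.number_of_edges(),
        "n_cis": cis,
        "n_trans": trans,
        "frac_lnc_connected": (connected / total) if total else 0.0,
    }


def _edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, d in g.edges(data=True):
        lnc, mrna = (u, v) if g.nodes[u].get("role") == "lncRNA" else (v, u)
        rows.append(
            {
                "lnc_gene": lnc,
                "mrna_gene": mrna,
                **{k: d.get(k, np.nan) for k in ("r", "r_squared", "p", "sign", "locality", "distance_bp")},
            }
        )
    df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return df.sort_values(["lnc_gene", "mrna_gene"]).reset_index(drop=True)


def export_network(
    g: nx.Graph,
    out_dir: str | Path,
    prefix: str = "network",
    formats: tuple[str, ...] = ("sif", "graphml", "tsv"),
) -> dict[str, Path]:
    """Write the network in Cytoscape-readable formats.

    SIF lines read "lnc_gene coexp mrna_gene"; GraphML carries node roles and
    edge attributes; the node/edge TSV pair round-trips via
    :func:`import_network_tsv`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    edges = _edge_table(g)
    for fmt in formats:
        if fmt == "sif":
            path = out_dir / f"{prefix}.sif"
            with open(path, "w") as fh:
                for row in edges.itertuples(index=False):
                    fh.write(f"{row.lnc_gene}\tcoexp\t{row.mrna_gene}\n")
            written["sif"] = path
        elif fmt == "graphml":
            path = out_dir / f"{prefix}.graphml"
            gg = g.copy()
            for *_, d in gg.edges(data=True):  # GraphML cannot carry NaN floats portably
                if "distance_bp" in d and (d["distance_bp"] != d["distance_bp"]):
                    d["distance_bp"] = -1.0
            nx.write_graphml(gg, path)
            written["graphml"] = path
        elif fmt == "tsv":
            nodes = pd.DataFrame(
                [(n, d.get("role", "")) for n, d in sorted(g.nodes(data=True))],
                columns=["node", "role"],
            )
            npath = out_dir / f"{prefix}.nodes.tsv"
            epath = out_dir / f"{prefix}.edges.tsv"
            nodes.to_csv(npath, sep="\t", index=False)
            edges.to_csv(epath, sep="\t", index=False)
            written["nodes_tsv"] = npath
            written["edges_tsv"] = epath
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return written


def import_network_tsv(nodes_path: str | Path, edges_path: str | Path) -> nx.Graph:
    nodes = pd.read_csv(nodes_path, sep="\t")
    edges = pd.read_csv(edges_path, sep="\t")
    g = build_network(edges)
    for row in nodes.itertuples(index=False):  # keep isolated nodes, if any
        g.add_node(row.node, role=row.role)
    return g
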