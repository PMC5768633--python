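"""Offline functional enrichment (Fisher's exact test) and lncRNA-function networks.

Gene sets are supplied as flat GMT files (no ontology hierarchy); enrichment of
a query gene list against a background universe uses the one-sided (greater)
Fisher exact test on the 2x2 table (k, n-k, K-k, N-K-n+k), i.e. the
hypergeometric upper tail P(X >= k).  Pathway-level comparisons between two
query lists use a stricter cutoff (p < 0.01) and partition terms into
common / A-only / B-only.

For each lncRNA of a co-expression network, its co-expressed mRNA partner set
is enrichment-tested; significant terms with enough supporting partners become
edges of a bipartite lncRNA-bioprocess network.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset]]:
    """Parse a GMT file into {term_id: (term_name, member gene ids)}."""
    collection: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term_id, name, genes = parts[0], parts[1], parts[2:]
            members = frozenset(g.strip() for g in genes if g.strip())
            if not members:
                continue
            collection[term_id] = (name, members)
    return collection


def write_gmt(collection: dict[str, tuple[str, frozenset]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, (name, members) in collection.items():
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


def fisher_enrichment(
    query: set[str],
    background: set[str],
    collection: dict[str, tuple[str, frozenset]],
    alpha: float = 0.05,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of ``query`` within ``background``.

    Per term with at least ``min_term_size`` members in the background:
    k = query hits, n = query size, K = term size in background,
    N = background size; p = Fisher exact, alternative "greater".
    """
    query, background = set(query), set(background)
    stray = query - background
    if stray:
        raise ValueError(f"query genes not in background: {sorted(stray)[:10]}")
    if len(background) < 2:
        raise ValueError("background needs at least 2 genes")
    N, n = len(background), len(query)
    rows = []
    for term_id, (name, members) in collection.items():
        in_bg = members & background
        K = len(in_bg)
        if K < min_term_size:
            continue
        k = len(in_bg & query)
        table = [[k, n - k], [K - k, N - K - n + k]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "odds_ratio": float(odds),
                "p": float(p),
                "significant": p < alpha,
            }
        )
    return (
        pd.DataFrame(
            rows,
            columns=["term_id", "term_name", "k", "n", "K", "N", "odds_ratio", "p", "significant"],
        )
        .sort_values("p", kind="stable")
        .reset_index(drop=True)
    )


def pathway_overlap(
    enrich_a: pd.DataFrame, enrich_b: pd.DataFrame, alpha_strict: float = 0.01
) -> dict[str, frozenset]:
    """Partition terms by stringent significance (p < alpha_strict) in A and B."""
    terms_a, terms_b = set(enrich_a["term_id"]), set(enrich_b["term_id"])
    if terms_a != terms_b:
        raise ValueError("enrichment tables cover different term collections")
    sig_a = set(enrich_a.loc[enrich_a["p"] < alpha_strict, "term_id"])
    sig_b = set(enrich_b.loc[enrich_b["p"] < alpha_strict, "term_id"])
    return {
        "common": frozenset(sig_a & sig_b),
        "a_only": frozenset(sig_a - sig_b),
        "b_only": frozenset(sig_b - sig_a),
    }


def lncrna_function_network(
    network: nx.Graph,
    collection: dict[str, tuple[str, frozenset]],
    background: set[str],
    alpha: float = 0.05,
    min_support: int = 2,
    min_term_size: int = 3,
    directions: dict[str, str] | None = None,
) -> nx.Graph:
    """Bipartite lncRNA-bioprocess graph from a co-expression network.

    Each lncRNA's co-expressed mRNA partner set is enrichment-tested against
    ``background``; an edge (lncRNA, term) is created when the term reaches
    p < alpha with at least ``min_support`` supporting partner genes.  The
    optional ``directions`` mapping (gene -> "up"/"down", from the DE stage)
    is stored on lncRNA nodes.
    """
    fnet = nx.Graph()
    lnc_nodes = sorted(
        n for n, d in network.nodes(data=True) if d.get("role") == "lncRNA"
    )
    for lnc in lnc_nodes:
        partners = {p for p in network.neighbors(lnc)} & background
        if not partners:
            log.info("lncRNA %s has no in-background partners; omitted", lnc)
            continue
        res = fisher_enrichment(
            partners, background, collection, alpha=alpha, min_term_size=min_term_size
        )
        hits = res[(res["significant"]) & (res["k"] >= min_support)]
        if hits.empty:
            continue
        attrs = {"role": "lncRNA"}
        if directions and lnc in directions:
            attrs["direction"] = directions[lnc]
        fnet.add_node(lnc, **attrs)
        for row in hits.itertuples(index=False):
            fnet.add_node(row.term_id, role="bioprocess", term_name=row.term_name)
            fnet.add_edge(lnc, row.term_id, support=int(row.k), p=float(row.p))
    return fnet


def term_theme_summary(
    function_network: nx.Graph, theme_terms: set[str]
) -> dict[str, float | int | bool]:
    """Fraction of network lncRNAs linked to >= 1 theme term, and terms hit.

    An empty network is reported as zero with a ``degenerate`` flag rather
    than an undefined fraction.
    """
    lnc = [n for n, d in function_network.nodes(data=True) if d.get("role") == "lncRNA"]
    if not lnc:
        return {
            "n_linked": 0,
            "n_total": 0,
            "fraction": 0.0,
            "n_theme_terms_hit": 0,
            "degenerate": True,
        }
    linked = [
        n for n in lnc if any(t in theme_terms for t in function_network.neighbors(n))
    ]
    terms_hit = {
        t
        for t in theme_terms
        if t in function_network and function_network.degree(t) > 0
    }
    return {
        "n_linked": len(linked),
        "n_total": len(lnc),
        "fraction": len(linked) / len(lnc),
        "n_theme_terms_hit": len(terms_hit),
        "degenerate": False,
    }
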