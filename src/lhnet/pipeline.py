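"""End-to-end orchestration: QC -> DE -> co-expression -> enrichment -> report.

``run`` wires the stages over files named in a :class:`RunConfig`, writes every
stage artifact to disk before the next stage starts (so each report number can
be re-derived from the artifacts), and returns a structured run report.

``consistency_checks`` verifies the arithmetic identities that tie a set of
printed per-comparison counts together — sums of up/down tallies, totals
across comparisons, and rounded percentages.  ``PAPER_COUNTS`` carries the
published counts of the study this pipeline re-implements, usable as a worked
example input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexnet, diffexpr, enrich, exprio, qpcr

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expression: str = "expression.tsv"
    annotation: str = "annotation.tsv"
    annotation_format: str = "tsv"
    metadata: str = "samples.tsv"
    gene_sets: str = "gene_sets.gmt"
    qpcr_table: str | None = None
    theme_terms: str | None = None
    out_dir: str = "results"
    alpha_de: float = 0.05
    log_transform: bool = False
    r2_min: float = 0.9
    p_max: float = 0.01
    window_bp: int = 1_000_000
    alpha_go: float = 0.05
    alpha_pathway: float = 0.01
    qc_min_fpkm: float = 0.1
    qc_min_samples: int = 1
    correlation_scope: str = "comparison"  # or "all"
    min_term_size: int = 3
    min_support: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("alpha_de", 0, 1),
            ("r2_min", 0, 1),
            ("p_max", 0, 1),
            ("alpha_go", 0, 1),
            ("alpha_pathway", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if self.correlation_scope not in ("comparison", "all"):
            raise ValueError("correlation_scope must be 'comparison' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name travels with the error."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


SPECIFIC_SETS = {
    "LHvsCtrl": "lh_vs_ctrl_specific",
    "LHvsNLH": "lh_vs_nlh_specific",
}


@_stage("expression")
def stage_expression(config: RunConfig, out: Path):
    matrix = exprio.read_expression(config.expression)
    annotation = exprio.read_annotation(config.annotation, format=config.annotation_format)
    design = exprio.read_metadata(config.metadata)
    missing = set(matrix.sample_ids) - set(design.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    filtered, qc_report = exprio.qc_filter(
        matrix, min_fpkm=config.qc_min_fpkm, min_samples=config.qc_min_samples
    )
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc_report, fh, indent=2)
    log.info(
        "QC filter (FPKM >= %g in >= %d samples): %d -> %d features",
        config.qc_min_fpkm, config.qc_min_samples,
        qc_report["n_before"], qc_report["n_after"],
    )
    return filtered, annotation, design, qc_report


@_stage("diffexpr")
def stage_de(config: RunConfig, matrix, annotation, design, out: Path):
    de_tables, raw_sets = {}, {}
    for comp, pair in diffexpr.COMPARISONS.items():
        table = diffexpr.run_comparison(
            matrix, design, pair, alpha=config.alpha_de, log_transform=config.log_transform
        )
        table.to_csv(out / f"de_{comp}.tsv", sep="\t", index=False)
        de_tables[comp] = table
        raw_sets[comp] = set(table.loc[table["significant"], "feature_id"])
    sets = diffexpr.exclusion_filter(raw_sets)
    with open(out / "comparison_sets.json", "w") as fh:
        json.dump(
            {
                "raw": {k: sorted(v) for k, v in sets.raw.items()},
                "LHvsCtrl_specific": sorted(sets.lh_vs_ctrl_specific),
                "LHvsNLH_specific": sorted(sets.lh_vs_nlh_specific),
            },
            fh,
            indent=2,
        )
    venn = diffexpr.venn_counts(raw_sets)
    pd.DataFrame(
        [("+".join(k), v) for k, v in sorted(venn.items())], columns=["region", "count"]
    ).to_csv(out / "venn_counts.tsv", sep="\t", index=False)

    summaries = {}
    for comp, attr in SPECIFIC_SETS.items():
        specific = getattr(sets, attr)
        table = de_tables[comp]
        sub = table[table["feature_id"].isin(specific)][["feature_id", "direction"]]
        summary = diffexpr.biotype_summary(sub, annotation)
        summary.to_csv(out / f"biotype_summary_{comp}.tsv", sep="\t")
        summaries[comp] = summary
    return de_tables, sets, summaries, venn


@_stage("coexnet")
def stage_coexpression(config: RunConfig, matrix, annotation, design, de_tables, sets, out: Path):
    gene_matrix = exprio.gene_level_average(matrix, annotation)
    exprio.write_expression(gene_matrix, out / "gene_matrix.tsv")
    spans = exprio.gene_spans(annotation)
    t2g = annotation.set_index("transcript_id")["gene_id"]
    networks, net_stats = {}, {}
    for comp, attr in SPECIFIC_SETS.items():
        specific = getattr(sets, attr)
        genes = set(t2g.reindex(sorted(specific)).dropna())
        lnc_genes = {g for g in genes if spans.loc[g, "biotype"] in exprio.LNCRNA_BIOTYPES}
        mrna_genes = {g for g in genes if spans.loc[g, "biotype"] == "protein_coding"}
        if config.correlation_scope == "comparison":
            groups = diffexpr.COMPARISONS[comp]
            samples = [s for s in gene_matrix.sample_ids if design[s] in groups]
        else:
            samples = gene_matrix.sample_ids
        if lnc_genes and mrna_genes:
            candidates = coexnet.correlate_pairs(gene_matrix, lnc_genes, mrna_genes, samples)
            edges = coexnet.filter_edges(candidates, r2_min=config.r2_min, p_max=config.p_max)
            edges = coexnet.classify_cis_trans(edges, spans, window_bp=config.window_bp)
        else:
            edges = pd.DataFrame(columns=coexnet.EDGE_COLUMNS)
        g = coexnet.build_network(edges, comparison=comp)
        coexnet.export_network(g, out, prefix=f"network_{comp}")
        networks[comp] = g
        net_stats[comp] = coexnet.network_stats(g, n_lnc_candidates=len(lnc_genes))
        net_stats[comp]["n_lnc_candidates"] = len(lnc_genes)
        net_stats[comp]["n_mrna_candidates"] = len(mrna_genes)
    return gene_matrix, spans, networks, net_stats


@_stage("enrich")
def stage_enrichment(config: RunConfig, gene_matrix, spans, annotation, de_tables,
                     sets, networks, out: Path):
    collection = enrich.read_gmt(config.gene_sets)
    background = set(gene_matrix.data.index)
    t2g = annotation.set_index("transcript_id")["gene_id"]
    results, fnets, theme = {}, {}, {}
    theme_terms: set[str] = set()
    if config.theme_terms:
        theme_terms = {
            line.strip() for line in Path(config.theme_terms).read_text().splitlines() if line.strip()
        }
    for comp, attr in SPECIFIC_SETS.items():
        specific = getattr(sets, attr)
        genes = set(t2g.reindex(sorted(specific)).dropna())
        query = {g for g in genes if spans.loc[g, "biotype"] == "protein_coding"} & background
        res = enrich.fisher_enrichment(
            query, background, collection,
            alpha=config.alpha_go, min_term_size=config.min_term_size,
        )
        res.to_csv(out / f"enrichment_{comp}.tsv", sep="\t", index=False)
        results[comp] = res

        de_table = de_tables[comp]
        dir_by_gene = (
            de_table[de_table["feature_id"].isin(specific)]
            .assign(gene=lambda d: t2g.reindex(d["feature_id"]).values)
            .groupby("gene")["direction"]
            .agg(lambda s: s.mode().iloc[0])
            .to_dict()
        )
        fnet = enrich.lncrna_function_network(
            networks[comp], collection, background,
            alpha=config.alpha_go, min_support=config.min_support,
            min_term_size=config.min_term_size, directions=dir_by_gene,
        )
        _export_function_network(fnet, out, f"function_network_{comp}")
        fnets[comp] = fnet
        theme[comp] = enrich.term_theme_summary(fnet, theme_terms)
    overlap = enrich.pathway_overlap(
        results["LHvsCtrl"], results["LHvsNLH"], alpha_strict=config.alpha_pathway
    )
    with open(out / "pathway_overlap.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in overlap.items()}, fh, indent=2)
    return results, overlap, fnets, theme


def _export_function_network(fnet, out: Path, prefix: str) -> None:
    import networkx as nx

    nx.write_graphml(fnet, out / f"{prefix}.graphml")
    rows = [
        {"lncRNA": u if fnet.nodes[u].get("role") == "lncRNA" else v,
         "term": v if fnet.nodes[u].get("role") == "lncRNA" else u,
         "support": d.get("support"), "p": d.get("p")}
        for u, v, d in fnet.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["lncRNA", "term", "support", "p"]).sort_values(
        ["lncRNA", "term"]
    ).to_csv(out / f"{prefix}.edges.tsv", sep="\t", index=False)


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_echo.yaml")

    matrix, annotation, design, qc_report = stage_expression(config, out)
    de_tables, sets, summaries, venn = stage_de(config, matrix, annotation, design, out)
    gene_matrix, spans, networks, net_stats = stage_coexpression(
        config, matrix, annotation, design, de_tables, sets, out
    )
    enr, overlap, fnets, theme = stage_enrichment(
        config, gene_matrix, spans, annotation, de_tables, sets, networks, out
    )

    report: dict = {
        "qc": qc_report,
        "de": {
            comp: {
                "n_significant_raw": len(sets.raw[comp]),
            }
            for comp in diffexpr.COMPARISONS
        },
        "specific": {
            comp: {
                "n_specific": len(getattr(sets, attr)),
                "biotype_summary": summaries[comp].to_dict(orient="index"),
            }
            for comp, attr in SPECIFIC_SETS.items()
        },
        "network": net_stats,
        "enrichment": {
            comp: {"n_significant_terms": int(enr[comp]["significant"].sum())}
            for comp in SPECIFIC_SETS
        },
        "pathway_overlap": {k: len(v) for k, v in overlap.items()},
        "theme": theme,
        "config": asdict(config),
    }
    if config.qpcr_table:
        report["qpcr"] = _run_qpcr(config)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


@_stage("qpcr")
def _run_qpcr(config: RunConfig) -> dict:
    plate = qpcr.read_qpcr(config.qpcr_table)
    rel = qpcr.ddct(plate)
    stats = qpcr.validate(rel, ("LH", "Ctrl"))
    out = Path(config.out_dir)
    rel.to_csv(out / "qpcr_relative.tsv", sep="\t", index=False)
    stats.to_csv(out / "qpcr_validation.tsv", sep="\t", index=False)
    return {
        "n_genes": int(stats["gene"].nunique()),
        "n_significant": int(stats["significant"].sum()),
    }


# ---------------------------------------------------------------------------
# arithmetic consistency checks over printed counts

#: Published per-comparison counts of the learned-helplessness study this
#: pipeline re-implements (totals and tallies as printed), usable as a worked
#: example for :func:`consistency_checks`.
PAPER_COUNTS = {
    "lh_vs_ctrl_total": 3927,
    "lh_vs_nlh_total": 2419,
    "grand_total": 6346,
    "lh_vs_ctrl_down": 2550,
    "lh_vs_ctrl_up": 1337,
    "lh_vs_nlh_down": 1663,
    "lh_vs_nlh_up": 756,
    "lh_vs_ctrl_protein_coding": 2163,
    "lh_vs_nlh_protein_coding": 1396,
    "protein_coding_total": 3559,
    "lh_vs_ctrl_lnc_down": 169,
    "lh_vs_ctrl_lnc_up": 30,
    "lh_vs_ctrl_lnc_total": 199,
    "lh_vs_nlh_lnc_down": 121,
    "lh_vs_nlh_lnc_up": 21,
    "lh_vs_nlh_lnc_total": 142,
    "lnc_correlated_lh_vs_ctrl": 34,
    "lnc_correlated_pct": 17,
    "theme_linked": 33,
    "theme_total": 58,
    "theme_pct": 57,
}

_SUM_CHECKS = [
    ("total DE transcripts", ["lh_vs_ctrl_total", "lh_vs_nlh_total"], "grand_total"),
    ("LH vs Ctrl up+down", ["lh_vs_ctrl_down", "lh_vs_ctrl_up"], "lh_vs_ctrl_total"),
    ("LH vs NLH up+down", ["lh_vs_nlh_down", "lh_vs_nlh_up"], "lh_vs_nlh_total"),
    ("protein-coding mRNAs", ["lh_vs_ctrl_protein_coding", "lh_vs_nlh_protein_coding"], "protein_coding_total"),
    ("LH vs Ctrl lncRNAs", ["lh_vs_ctrl_lnc_down", "lh_vs_ctrl_lnc_up"], "lh_vs_ctrl_lnc_total"),
    ("LH vs NLH lncRNAs", ["lh_vs_nlh_lnc_down", "lh_vs_nlh_lnc_up"], "lh_vs_nlh_lnc_total"),
]

_PCT_CHECKS = [
    ("correlated lncRNA fraction", "lnc_correlated_lh_vs_ctrl", "lh_vs_ctrl_lnc_total", "lnc_correlated_pct"),
    ("synapse-linked lncRNA fraction", "theme_linked", "theme_total", "theme_pct"),
]


def consistency_checks(counts: dict[str, float]) -> pd.DataFrame:
    """Verify sum and rounded-percentage identities among printed counts.

    Checks whose inputs are missing from ``counts`` are skipped; a percentage
    with zero denominator is reported as 0 and flagged degenerate.
    """
    rows = []
    for name, parts, total in _SUM_CHECKS:
        if not all(k in counts for k in [*parts, total]):
            continue
        value = sum(counts[k] for k in parts)
        rows.append(
            {
                "check": name,
                "kind": "sum",
                "computed": float(value),
                "expected": float(counts[total]),
                "passed": value == counts[total],
                "degenerate": False,
            }
        )
    for name, numer, denom, pct in _PCT_CHECKS:
        if not all(k in counts for k in (numer, denom, pct)):
            continue
        if counts[denom] == 0:
            rows.append(
                {
                    "check": name, "kind": "percent", "computed": 0.0,
                    "expected": float(counts[pct]), "passed": counts[pct] == 0,
                    "degenerate": True,
                }
            )
            continue
        value = round(100.0 * counts[numer] / counts[denom])
        rows.append(
            {
                "check": name,
                "kind": "percent",
                "computed": float(value),
                "expected": float(counts[pct]),
                "passed": value == counts[pct],
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows, columns=["check", "kind", "computed", "expected", "passed", "degenerate"])
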