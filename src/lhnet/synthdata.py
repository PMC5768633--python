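"""Synthetic study generator with planted ground truth.

Every input of the analysis — behavioral shuttle-box table, FPKM expression
matrix with annotation and sample metadata, gene sets, and qPCR plates — can be
simulated with known truth so each downstream stage is testable without
external data.  All generators are pure functions of their configuration and
seed.

The expression model plants three kinds of structure on top of heavy-tailed
(log-normal) baseline abundances with additive Gaussian FPKM noise (clipped at
zero):

* group mean-shifts of 2^de_effect for differential expression — helplessness-
  specific (LH group), handling-related (all handled groups vs homecage) and
  resilience-related (NLH group) transcript classes;
* lncRNA-mRNA pairs coupled through a shared per-sample latent factor, scaled
  so the within-group population Pearson correlation equals ``pair_r``; pairs
  are placed at controlled genomic distances so both cis and trans labels occur
  in truth;
* two-cluster bivariate-Gaussian behavioral data bounded by the shuttle-box
  protocol (failures in [0, 30] over 30 trials, latencies in [0, 10] s).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrich, exprio, qpcr
from .exprio import ExpressionMatrix

LNC_SUBCLASSES = [
    "lincRNA",
    "antisense",
    "sense_intronic",
    "sense_overlapping",
    "bidirectional_promoter_lncRNA",
    "processed_transcript",
]
_OTHER_BIOTYPES = ["protein_coding", "novel", "pseudogene", "TEC", "miscRNA", "snoRNA", "scaRNA"]
_OTHER_WEIGHTS = [0.55, 0.30, 0.06, 0.06, 0.01, 0.01, 0.01]

_CHROMS = [f"chr{i}" for i in range(1, 20)]

COMPARISON_GROUPS = {
    "LHvsCtrl": ("LH", "Ctrl"),
    "LHvsNLH": ("LH", "NLH"),
    "CtrlvsHC": ("Ctrl", "HC"),
    "CtrlvsNLH": ("Ctrl", "NLH"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated study.

    ``de_effect`` is the planted log2 group shift (3.0 -> 8-fold);
    ``noise_sd`` the additive FPKM noise; ``pair_r`` the within-group
    population correlation of planted lncRNA-mRNA pairs.
    """

    n_per_group: int = 4
    n_transcripts: int = 2000
    frac_lncrna: float = 0.15
    de_effect: float = 3.0
    noise_sd: float = 0.5
    pair_r: float = 0.98
    seed: int = 0
    n_de_lh: int = 100
    n_de_handling: int = 60
    n_de_resilience: int = 60
    n_pairs: int = 10
    frac_down: float = 0.65
    pairs_are_de: bool = True
    pair_cv: float = 0.25
    baseline_meanlog: float = 1.0
    baseline_sdlog: float = 1.5

    def __post_init__(self) -> None:
        if self.n_per_group < 2 or self.n_transcripts < 1:
            raise ValueError("counts must be positive (n_per_group >= 2)")
        if not 0 < self.frac_lncrna < 1:
            raise ValueError("frac_lncrna must lie in (0, 1)")
        if not -1 < self.pair_r < 1:
            raise ValueError("pair_r must lie in (-1, 1)")
        if self.noise_sd < 0 or self.pair_cv <= 0:
            raise ValueError("noise_sd must be >= 0 and pair_cv > 0")
        if min(self.n_de_lh, self.n_de_handling, self.n_de_resilience, self.n_pairs) < 0:
            raise ValueError("planted counts must be >= 0")

    @property
    def n_planted(self) -> int:
        return 2 * self.n_pairs + self.n_de_lh + self.n_de_handling + self.n_de_resilience


def default_design(n_per_group: int = 4) -> pd.Series:
    """Sample -> group assignment for the four-group layout."""
    idx, vals = [], []
    for g in exprio.GROUPS:
        for i in range(n_per_group):
            idx.append(f"{g}_{i + 1}")
            vals.append(g)
    return pd.Series(vals, index=pd.Index(idx, name="sample_id"), name="group")


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(
    n_lh: int = 14,
    n_nlh: int = 17,
    n_ctrl: int = 10,
    cluster_means: tuple = ((25.0, 8.0), (5.0, 3.0)),
    cluster_sds: tuple = ((3.0, 1.0), (3.0, 1.0)),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-cluster shuttle-box behavior with Ctrl mice drawn from the
    resilient cluster.

    Failures are integer counts clipped to [0, 30]; latencies are clipped to
    the 10 s trial cap.  Returns (behavior table, truth table); truth records
    the planted LH/NLH class for stressed mice only (Ctrl is not clustered).
    """
    means = np.asarray(cluster_means, dtype=float)
    sds = np.asarray(cluster_sds, dtype=float)
    if not (np.isfinite(means).all() and np.isfinite(sds).all()):
        raise ValueError("cluster means/sds must be finite")
    if (sds < 0).any():
        raise ValueError("cluster sds must be non-negative")
    if min(n_lh, n_nlh, n_ctrl) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    plan = [("LH", n_lh, 0), ("NLH", n_nlh, 1), ("Ctrl", n_ctrl, 1)]
    i = 0
    for group, n, cluster in plan:
        for _ in range(n):
            i += 1
            f = rng.normal(means[cluster, 0], sds[cluster, 0])
            l = rng.normal(means[cluster, 1], sds[cluster, 1])
            failures = int(np.clip(round(f), 0, 30))
            latency = float(np.clip(l, 0.0, 10.0))
            mouse = f"m{i:03d}"
            rows.append((mouse, group, failures, latency))
            if group in ("LH", "NLH"):
                truth.append((mouse, group))
    behavior = pd.DataFrame(rows, columns=["mouse_id", "group", "failures", "latency_s"])
    truth_df = pd.DataFrame(truth, columns=["mouse_id", "true_class"])
    return behavior, truth_df


# ---------------------------------------------------------------------------
# expression


def _truncated_lognormal(rng, meanlog, sdlog, size, floor=1.0):
    # baselines for planted features: expressed transcripts (FPKM >= floor)
    out = rng.lognormal(meanlog, sdlog, size)
    bad = out < floor
    while bad.any():
        out[bad] = rng.lognormal(meanlog, sdlog, int(bad.sum()))
        bad = out < floor
    return out


def _comparison_direction(shifts: dict[str, float], comparison: str) -> str:
    test, ref = COMPARISON_GROUPS[comparison]
    d = shifts.get(test, 0.0) - shifts.get(ref, 0.0)
    return "null" if d == 0 else ("up" if d > 0 else "down")


def simulate_expression(
    cfg: SimulationConfig, design: pd.Series | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the FPKM matrix, annotation and per-transcript truth table.

    Truth columns: de_class in {pair, lh, handling, resilience, null}; the
    planted DE direction for each of the four comparisons; for pair members
    the partner gene, population correlation and planted cis/trans placement.
    """
    if design is None:
        design = default_design(cfg.n_per_group)
    missing_groups = set(exprio.GROUPS) - set(design.values)
    if missing_groups:
        raise ValueError(f"design lacks groups {sorted(missing_groups)}")
    if cfg.n_transcripts < cfg.n_planted:
        raise ValueError(
            f"n_transcripts={cfg.n_transcripts} below planted feature count {cfg.n_planted}"
        )
    rng = np.random.default_rng(cfg.seed)
    n_t, n_s = cfg.n_transcripts, len(design)
    samples = design.index.tolist()
    groups = design.values

    tids = [f"T{i + 1:06d}" for i in range(n_t)]

    # --- planted layout -----------------------------------------------------
    idx_pair_lnc = list(range(cfg.n_pairs))
    idx_pair_mrna = list(range(cfg.n_pairs, 2 * cfg.n_pairs))
    p0 = 2 * cfg.n_pairs
    idx_lh = list(range(p0, p0 + cfg.n_de_lh))
    idx_handling = list(range(p0 + cfg.n_de_lh, p0 + cfg.n_de_lh + cfg.n_de_handling))
    idx_resilience = list(
        range(p0 + cfg.n_de_lh + cfg.n_de_handling, cfg.n_planted)
    )
    idx_null = list(range(cfg.n_planted, n_t))
    de_class = np.array(["null"] * n_t, dtype=object)
    de_class[idx_pair_lnc + idx_pair_mrna] = "pair"
    de_class[idx_lh] = "lh"
    de_class[idx_handling] = "handling"
    de_class[idx_resilience] = "resilience"

    # per-transcript log2 shift per group
    shifts: list[dict[str, float]] = [dict() for _ in range(n_t)]
    sign = lambda: -1.0 if rng.random() < cfg.frac_down else 1.0
    for i in idx_lh:
        shifts[i]["LH"] = sign() * cfg.de_effect
    for i in idx_handling:
        s = sign() * cfg.de_effect
        for g in ("LH", "NLH", "Ctrl"):
            shifts[i][g] = s
    for i in idx_resilience:
        shifts[i]["NLH"] = sign() * cfg.de_effect
    if cfg.pairs_are_de:
        for a, b in zip(idx_pair_lnc, idx_pair_mrna):
            s = sign() * cfg.de_effect
            shifts[a]["LH"] = s
            shifts[b]["LH"] = s

    # --- baselines and values ----------------------------------------------
    mu = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, n_t)
    planted = np.flatnonzero(de_class != "null")
    mu[planted] = _truncated_lognormal(
        rng, cfg.baseline_meanlog, cfg.baseline_sdlog, len(planted)
    )

    shift_factor = np.ones((n_t, n_s))
    for i in range(n_t):
        if shifts[i]:
            for j, g in enumerate(groups):
                shift_factor[i, j] = 2.0 ** shifts[i].get(g, 0.0)

    values = mu[:, None] * shift_factor + rng.normal(0.0, cfg.noise_sd, (n_t, n_s))

    # pair members: multiplicative latent-factor coupling replaces the
    # additive-noise model so the population correlation is exactly pair_r
    rho = abs(cfg.pair_r)
    pair_sign = 1.0 if cfg.pair_r >= 0 else -1.0
    if cfg.noise_sd > 0:
        c = cfg.pair_cv * np.sqrt(rho)
        d = cfg.pair_cv * np.sqrt(1.0 - rho)
    else:
        c, d = cfg.pair_cv, 0.0
    for a, b in zip(idx_pair_lnc, idx_pair_mrna):
        f = rng.standard_normal(n_s)
        ea = rng.standard_normal(n_s)
        eb = rng.standard_normal(n_s)
        values[a] = mu[a] * (1.0 + c * f + d * ea) * shift_factor[a]
        values[b] = mu[b] * (1.0 + pair_sign * c * f + d * eb) * shift_factor[b]

    values = np.clip(values, 0.0, None)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(tids, name="transcript_id"), columns=samples),
        level="transcript",
    )

    # --- annotation ---------------------------------------------------------
    gene_ids = np.empty(n_t, dtype=object)
    chrom = np.empty(n_t, dtype=object)
    start = np.zeros(n_t, dtype=int)
    end = np.zeros(n_t, dtype=int)
    biotype = np.empty(n_t, dtype=object)
    pair_locality = np.array([""] * n_t, dtype=object)
    partner_gene = np.array([""] * n_t, dtype=object)

    next_gene = 1

    def _new_gene() -> str:
        nonlocal next_gene
        gid = f"G{next_gene:06d}"
        next_gene += 1
        return gid

    lengths = rng.integers(500, 50_001, n_t)
    for k, (a, b) in enumerate(zip(idx_pair_lnc, idx_pair_mrna)):
        gene_ids[a], gene_ids[b] = _new_gene(), _new_gene()
        partner_gene[a], partner_gene[b] = gene_ids[b], gene_ids[a]
        biotype[a] = LNC_SUBCLASSES[int(rng.integers(len(LNC_SUBCLASSES)))]
        biotype[b] = "protein_coding"
        if k % 2 == 0:  # cis placement: same chromosome, gap well inside 1 Mb
            ch = _CHROMS[k % len(_CHROMS)]
            chrom[a] = chrom[b] = ch
            start[a] = int(rng.integers(1_000_000, 50_000_000))
            end[a] = start[a] + int(lengths[a])
            gap = int(rng.integers(10_000, 800_001))
            start[b] = end[a] + gap
            end[b] = start[b] + int(lengths[b])
            pair_locality[a] = pair_locality[b] = "cis"
        else:  # trans placement: different chromosomes
            chrom[a] = _CHROMS[k % len(_CHROMS)]
            chrom[b] = _CHROMS[(k + 9) % len(_CHROMS)]
            for i in (a, b):
                start[i] = int(rng.integers(1_000_000, 100_000_000))
                end[i] = start[i] + int(lengths[i])
            pair_locality[a] = pair_locality[b] = "trans"

    def _random_biotype() -> str:
        if rng.random() < cfg.frac_lncrna:
            return LNC_SUBCLASSES[int(rng.integers(len(LNC_SUBCLASSES)))]
        return str(rng.choice(_OTHER_BIOTYPES, p=_OTHER_WEIGHTS))

    # ~10% of null transcripts are second isoforms of the preceding null gene,
    # exercising the gene-level averaging path; planted genes stay single-isoform
    prev_gene_pos: tuple[str, str, int, str] | None = None  # gid, chrom, start, biotype
    for i in idx_lh + idx_handling + idx_resilience + idx_null:
        second_isoform = (
            de_class[i] == "null"
            and prev_gene_pos is not None
            and rng.random() < 0.1
        )
        if second_isoform:
            gid, ch, st, bt = prev_gene_pos
            gene_ids[i] = gid
            chrom[i] = ch
            start[i] = st + int(rng.integers(0, 1000))
            end[i] = start[i] + int(lengths[i])
            biotype[i] = bt
        else:
            gid = _new_gene()
            gene_ids[i] = gid
            chrom[i] = _CHROMS[int(rng.integers(len(_CHROMS)))]
            start[i] = int(rng.integers(1_000_000, 150_000_000))
            end[i] = start[i] + int(lengths[i])
            biotype[i] = _random_biotype()
            if de_class[i] == "null":
                prev_gene_pos = (gid, str(chrom[i]), int(start[i]), str(biotype[i]))

    annotation = pd.DataFrame(
        {
            "transcript_id": tids,
            "gene_id": gene_ids,
            "chromosome": chrom,
            "start": start,
            "end": end,
            "strand": rng.choice(["+", "-"], n_t),
            "biotype": biotype,
        }
    )

    # --- truth --------------------------------------------------------------
    truth = pd.DataFrame(
        {
            "transcript_id": tids,
            "gene_id": gene_ids,
            "de_class": de_class,
            "partner_gene": partner_gene,
            "population_r": [
                cfg.pair_r if de_class[i] == "pair" else np.nan for i in range(n_t)
            ],
            "pair_locality": pair_locality,
        }
    )
    for comp in COMPARISON_GROUPS:
        truth[f"de_{comp}"] = [
            _comparison_direction(shifts[i], comp) for i in range(n_t)
        ]
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    true_fold: dict[str, float],
    n_per_group: int = 10,
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    target_group: str = "LH",
    control_group: str = "Ctrl",
    reference_gene: str = "GAPDH",
) -> pd.DataFrame:
    """Triplicate Ct plate with planted fold changes in the target group.

    The target-gene Ct drops by log2(fold) in the target group; a reference
    gene (fold 1) is emitted for every sample.  With ct_noise_sd = 0 the ddCt
    computation inverts the planting exactly; with noise, per-sample loading
    offsets shared by all genes of a sample are added too (they cancel under
    reference normalization).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    for g, f in true_fold.items():
        if not f > 0:
            raise ValueError(f"fold for {g!r} must be positive, got {f}")
    rng = np.random.default_rng(seed)
    genes = sorted(true_fold)
    base_ct = {g: float(rng.uniform(22, 28)) for g in genes}
    base_ct[reference_gene] = 20.0
    rows = []
    for group in (target_group, control_group):
        for i in range(n_per_group):
            sample = f"{group}_{i + 1}"
            offset = float(rng.normal(0.0, 0.3)) if ct_noise_sd > 0 else 0.0
            for gene in [reference_gene, *genes]:
                fold = true_fold.get(gene, 1.0) if group == target_group else 1.0
                ct = base_ct[gene] - np.log2(fold) + offset
                if ct_noise_sd > 0:
                    reps = np.round(ct + rng.normal(0.0, ct_noise_sd, 3), 4)
                else:
                    reps = np.full(3, ct)
                rows.append((sample, group, gene, *reps))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct1", "ct2", "ct3"])


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(
    annotation: pd.DataFrame,
    truth: pd.DataFrame,
    n_terms: int = 40,
    enriched_terms: int = 5,
    term_size_range: tuple[int, int] = (10, 40),
    enriched_frac: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, tuple[str, frozenset]], list[str]]:
    """Flat gene-set collection over the protein-coding gene universe.

    The first ``enriched_terms`` terms draw ``enriched_frac`` of their members
    from planted helplessness-DE protein-coding genes, so the enrichment stage
    has guaranteed positives.  Returns (collection, enriched term ids).
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    if n_terms < enriched_terms:
        raise ValueError("n_terms must be >= enriched_terms")
    rng = np.random.default_rng(seed)
    pc = annotation.loc[annotation["biotype"] == "protein_coding", "gene_id"].unique()
    de_pc = truth.loc[
        (truth["de_LHvsCtrl"] != "null")
        & truth["gene_id"].isin(pc)
        & (truth["de_class"].isin(["lh", "pair"])),
        "gene_id",
    ].unique()
    non_de = np.setdiff1d(pc, de_pc)
    collection: dict[str, tuple[str, frozenset]] = {}
    enriched_ids = []
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        term_id = f"BP:{t + 1:04d}"
        if t < enriched_terms and len(de_pc) > 0:
            n_de = min(len(de_pc), max(1, int(round(enriched_frac * size))))
            members = list(rng.choice(de_pc, n_de, replace=False))
            fill = min(len(non_de), size - n_de)
            members += list(rng.choice(non_de, fill, replace=False))
            name = f"synthetic enriched bioprocess {t + 1}"
            enriched_ids.append(term_id)
        else:
            members = list(rng.choice(pc, min(size, len(pc)), replace=False))
            name = f"synthetic background bioprocess {t + 1}"
        collection[term_id] = (name, frozenset(map(str, members)))
    return collection, enriched_ids


# ---------------------------------------------------------------------------
# whole-study convenience writer


def generate_study(
    cfg: SimulationConfig,
    out_dir: str | Path,
    qpcr_folds: dict[str, float] | None = None,
) -> dict[str, Path]:
    """Simulate every pipeline input and write it under ``out_dir``.

    Emits the expression TSV, annotation (GTF + TSV), sample metadata,
    behavior CSV, qPCR CSV, gene-set GMT and the truth tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = default_design(cfg.n_per_group)
    matrix, annotation, truth = simulate_expression(cfg, design)
    behavior, behavior_truth = simulate_behavior(seed=cfg.seed)
    if qpcr_folds is None:
        qpcr_folds = {"Nub1": 0.5, "Rab3a": 0.6, "Gm26859": 1.8, "Tcf4": 0.7}
    plate = simulate_qpcr(qpcr_folds, seed=cfg.seed)
    collection, enriched = simulate_gene_sets(annotation, truth, seed=cfg.seed)

    paths = {
        "expression": out / "expression.tsv",
        "annotation_tsv": out / "annotation.tsv",
        "annotation_gtf": out / "annotation.gtf",
        "metadata": out / "samples.tsv",
        "behavior": out / "behavior.csv",
        "qpcr": out / "qpcr.csv",
        "gene_sets": out / "gene_sets.gmt",
        "truth_expression": out / "truth_expression.tsv",
        "truth_behavior": out / "truth_behavior.tsv",
        "theme_terms": out / "theme_terms.txt",
    }
    exprio.write_expression(matrix, paths["expression"])
    exprio.write_annotation_tsv(annotation, paths["annotation_tsv"])
    exprio.write_annotation_gtf(annotation, paths["annotation_gtf"])
    exprio.write_metadata(design, paths["metadata"])
    behavior.to_csv(paths["behavior"], index=False)
    qpcr.write_qpcr(plate, paths["qpcr"])
    enrich.write_gmt(collection, paths["gene_sets"])
    truth.to_csv(paths["truth_expression"], sep="\t", index=False)
    behavior_truth.to_csv(paths["truth_behavior"], sep="\t", index=False)
    paths["theme_terms"].write_text("\n".join(enriched) + "\n")
    return paths
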