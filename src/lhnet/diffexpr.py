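"""Differential expression by Student's t-test and multi-comparison set logic.

Four group comparisons are made on the FPKM matrix: LH vs Ctrl, LH vs NLH,
Ctrl vs HC and Ctrl vs NLH.  Transcripts significant in Ctrl vs HC (handling /
context effects) or Ctrl vs NLH (resilience-related effects) are excluded from
the two LH comparisons, leaving helplessness-specific sets:

    LHvsCtrl_specific = LHvsCtrl \\ (CtrlvsHC u CtrlvsNLH)
    LHvsNLH_specific  = LHvsNLH  \\ (CtrlvsHC u CtrlvsNLH)

Testing is a pooled-variance two-sample t-test (df = n1 + n2 - 2) at p < alpha
with no fold-change cutoff and no multiple-testing correction; by default raw
FPKM enters the test, with an optional log2(FPKM+1) transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .exprio import LNCRNA_BIOTYPES, ExpressionMatrix

COMPARISONS = {
    "LHvsCtrl": ("LH", "Ctrl"),
    "LHvsNLH": ("LH", "NLH"),
    "CtrlvsHC": ("Ctrl", "HC"),
    "CtrlvsNLH": ("Ctrl", "NLH"),
}


def t_test(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float, str | None]:
    """Pooled-variance two-sample t-test.

    Returns (t, two-sided p, direction) where direction is "up"/"down" by the
    sign of mean(a) - mean(b), or None when the means are equal.  Zero pooled
    variance with equal means gives t=0, p=1; with unequal means the difference
    is infinitely many pooled standard errors, reported as p=0 (degenerate).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    diff = a.mean() - b.mean()
    direction = None if diff == 0 else ("up" if diff > 0 else "down")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled == 0.0:
        if diff == 0:
            return 0.0, 1.0, None
        return float(np.sign(diff)) * np.inf, 0.0, direction
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), direction


def run_comparison(
    matrix: ExpressionMatrix,
    design: pd.Series,
    comparison: tuple[str, str],
    alpha: float = 0.05,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-feature Student's t-test for one (test group, reference group) pair.

    Returns a DataFrame with one row per feature: means, t, p, direction and a
    significance flag at p < alpha.  Features with zero pooled variance and
    equal means are reported non-significant (t=0, p=1) to keep the pipeline
    total; zero variance with unequal means is flagged ``degenerate``.
    """
    test_g, ref_g = comparison
    for g in comparison:
        if g not in set(design.values):
            raise ValueError(f"unknown group {g!r} in comparison")
    cols_a = design.index[design == test_g]
    cols_b = design.index[design == ref_g]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    A = matrix.data[cols_a].to_numpy(dtype=float)
    B = matrix.data[cols_b].to_numpy(dtype=float)
    if log_transform:
        A, B = np.log2(A + 1.0), np.log2(B + 1.0)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    diff = mean_a - mean_b
    na, nb = A.shape[1], B.shape[1]
    pooled = ((na - 1) * A.var(axis=1, ddof=1) + (nb - 1) * B.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        t = diff / se
    df = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = pooled == 0.0
    t = np.where(degenerate & (diff == 0), 0.0, t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    t = np.where(degenerate & (diff > 0), np.inf, t)
    t = np.where(degenerate & (diff < 0), -np.inf, t)
    direction = np.where(diff > 0, "up", np.where(diff < 0, "down", "none"))
    out = pd.DataFrame(
        {
            "feature_id": matrix.data.index,
            "comparison": f"{test_g}vs{ref_g}",
            "mean_test": mean_a,
            "mean_ref": mean_b,
            "t": t,
            "p": p,
            "direction": direction,
            "significant": p < alpha,
            "degenerate": degenerate & (diff != 0),
        }
    ).reset_index(drop=True)
    return out


@dataclass
class ComparisonSets:
    """Raw significant sets per comparison plus exclusion-filtered specific sets."""

    raw: dict[str, frozenset]
    lh_vs_ctrl_specific: frozenset
    lh_vs_nlh_specific: frozenset


def exclusion_filter(raw_sets: dict[str, set | frozenset]) -> ComparisonSets:
    """Remove handling- and resilience-related transcripts from the LH sets."""
    required = set(COMPARISONS)
    missing = required - set(raw_sets)
    if missing:
        raise ValueError(f"missing comparisons: {sorted(missing)}")
    excluded = frozenset(raw_sets["CtrlvsHC"]) | frozenset(raw_sets["CtrlvsNLH"])
    return ComparisonSets(
        raw={k: frozenset(v) for k, v in raw_sets.items()},
        lh_vs_ctrl_specific=frozenset(raw_sets["LHvsCtrl"]) - excluded,
        lh_vs_nlh_specific=frozenset(raw_sets["LHvsNLH"]) - excluded,
    )


def biotype_summary(de_features: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Tally a DE feature set per biotype, split by direction.

    ``de_features`` needs columns feature_id and direction ("up"/"down").
    Rows are biotypes plus an aggregated ``lncRNA`` row summing the lncRNA
    subclasses and a ``Total`` row; columns n_down, n_up, n_total.
    """
    bt = annotation.set_index("transcript_id")["biotype"]
    missing = set(de_features["feature_id"]) - set(bt.index)
    if missing:
        raise ValueError(f"unannotated features: {sorted(missing)[:10]}")
    df = de_features.copy()
    df["biotype"] = bt.reindex(df["feature_id"].values).values
    rows = {}
    for biotype, grp in df.groupby("biotype"):
        n_down = int((grp["direction"] == "down").sum())
        n_up = int((grp["direction"] == "up").sum())
        rows[biotype] = (n_down, n_up, n_down + n_up)
    lnc = df[df["biotype"].isin(LNCRNA_BIOTYPES)]
    rows["lncRNA"] = (
        int((lnc["direction"] == "down").sum()),
        int((lnc["direction"] == "up").sum()),
        int(len(lnc)),
    )
    rows["Total"] = (
        int((df["direction"] == "down").sum()),
        int((df["direction"] == "up").sum()),
        int(len(df)),
    )
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_down", "n_up", "n_total"]
    )
    out.index.name = "biotype"
    return out


def venn_counts(sets: dict[str, set | frozenset]) -> dict[tuple[str, ...], int]:
    """Counts of every non-empty region of the inclusion-exclusion partition.

    Keys are tuples of the set names an element belongs to (region signature);
    at most 4 sets are supported.
    """
    if len(sets) > 4:
        raise ValueError("at most 4 sets supported")
    names = list(sets)
    counts: dict[tuple[str, ...], int] = {}
    universe = set().union(*sets.values()) if sets else set()
    for member in product([False, True], repeat=len(names)):
        if not any(member):
            continue
        region = universe
        for name, inside in zip(names, member):
            region = region & sets[name] if inside else region - sets[name]
        if region:
            counts[tuple(n for n, m in zip(names, member) if m)] = len(region)
    return counts
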