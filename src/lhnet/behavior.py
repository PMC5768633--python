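"""Behavioral phenotyping: k-means clustering and linear discriminant scoring.

Mice exposed to inescapable stress split into learned-helpless (LH) and
non-learned-helpless (NLH, stress-resilient) phenotypes.  The split is made in
the (escape failures, mean escape latency) plane by k-means with k=2, and a
Fisher linear discriminant fitted to the cluster labels yields one linear score
function per class:

    score_c(F, L) = intercept_c + coef_failure_c * F + coef_latency_c * L

A mouse is called LH when score_LH > score_NLH; ties go to NLH (helplessness is
not over-called).  ``PAPER_MODEL`` is a frozen published instance of such a
discriminant, usable without refitting.

Group comparisons (LH vs NLH vs Ctrl) use one-way ANOVA with Bonferroni
pairwise post hoc tests, on raw units (failure counts, seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

LH = "LH"
NLH = "NLH"

FEATURES = ["failures", "latency_s"]


@dataclass(frozen=True)
class ClassScore:
    intercept: float
    coef_failure: float
    coef_latency: float

    def __call__(self, failures: float, latency: float) -> float:
        return self.intercept + self.coef_failure * failures + self.coef_latency * latency


@dataclass(frozen=True)
class DiscriminantModel:
    """Two linear per-class score functions over (failures, latency)."""

    lh: ClassScore
    nlh: ClassScore

    def scores(self, failures: float, latency: float) -> tuple[float, float]:
        return self.lh(failures, latency), self.nlh(failures, latency)


#: Frozen published discriminant: LH = -24.75 + 0.23*F + 4.79*L,
#: NLH = -15.34 - 2.78*F + 10.31*L.
PAPER_MODEL = DiscriminantModel(
    lh=ClassScore(-24.75, 0.23, 4.79),
    nlh=ClassScore(-15.34, -2.78, 10.31),
)


@dataclass
class ClusterResult:
    labels: pd.Series  # mouse_id -> {LH, NLH}
    centroids: dict[str, np.ndarray]  # class -> (failures, latency)
    inertia: float


def cluster_mice(
    behavior: pd.DataFrame, n_restarts: int = 50, seed: int = 0
) -> ClusterResult:
    """Split mice into LH/NLH by k-means (k=2) on raw (failures, latency).

    Best of ``n_restarts`` random initialisations by inertia.  The cluster
    whose centroid has the larger failure coordinate is named LH.
    """
    X = behavior[FEATURES].to_numpy(dtype=float)
    if len(X) < 2 or len(np.unique(X, axis=0)) < 2:
        raise ValueError("need at least 2 mice with at least 2 distinct points")
    km = KMeans(
        n_clusters=2, n_init=n_restarts, init="random", random_state=seed
    ).fit(X)
    # higher mean-failure centroid is the helpless cluster
    lh_cluster = int(np.argmax(km.cluster_centers_[:, 0]))
    names = {lh_cluster: LH, 1 - lh_cluster: NLH}
    labels = pd.Series(
        [names[l] for l in km.labels_],
        index=behavior["mouse_id"].astype(str).values,
        name="label",
    )
    centroids = {names[i]: km.cluster_centers_[i].copy() for i in (0, 1)}
    return ClusterResult(labels=labels, centroids=centroids, inertia=float(km.inertia_))


def fit_discriminant(behavior: pd.DataFrame, labels: pd.Series) -> DiscriminantModel:
    """Fit a Fisher linear discriminant to labelled (failures, latency) data.

    Shared (pooled) within-class covariance, class priors proportional to
    class sizes.  Per class c the score is the usual LDA discriminant
    x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log pi_c, a linear function of the
    two behavioral readouts.
    """
    lab = labels.reindex(behavior["mouse_id"].astype(str).values)
    if lab.isna().any():
        raise ValueError("every mouse needs a label")
    X = behavior[FEATURES].to_numpy(dtype=float)
    present = set(lab)
    if present != {LH, NLH}:
        raise ValueError(f"need both classes LH and NLH, got {sorted(present)}")
    mus, priors, pooled = {}, {}, np.zeros((2, 2))
    n = len(X)
    for cls in (LH, NLH):
        Xc = X[(lab == cls).to_numpy()]
        if len(Xc) < 2:
            raise ValueError(f"class {cls} needs >= 2 members")
        mus[cls] = Xc.mean(axis=0)
        priors[cls] = len(Xc) / n
        pooled += (len(Xc) - 1) * np.cov(Xc, rowvar=False, ddof=1)
    pooled /= n - 2
    if np.linalg.cond(pooled) > 1e12:
        raise ValueError(
            "singular pooled within-class covariance; the two behavioral "
            "readouts are degenerate (collinear or constant within classes)"
        )
    prec = np.linalg.inv(pooled)

    def _score(cls: str) -> ClassScore:
        w = prec @ mus[cls]
        b = -0.5 * mus[cls] @ prec @ mus[cls] + math.log(priors[cls])
        return ClassScore(float(b), float(w[0]), float(w[1]))

    return DiscriminantModel(lh=_score(LH), nlh=_score(NLH))


def classify(
    model: DiscriminantModel, failures: float, latency: float
) -> tuple[str, float, float]:
    """Score one mouse under both class functions; argmax wins, ties -> NLH."""
    if not (math.isfinite(failures) and math.isfinite(latency)):
        raise ValueError("inputs must be finite")
    s_lh, s_nlh = model.scores(failures, latency)
    return (LH if s_lh > s_nlh else NLH), s_lh, s_nlh


def classify_table(model: DiscriminantModel, behavior: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for row in behavior.itertuples(index=False):
        cls, s_lh, s_nlh = classify(model, row.failures, row.latency_s)
        rows.append((str(row.mouse_id), cls, s_lh, s_nlh))
    return pd.DataFrame(rows, columns=["mouse_id", "label", "score_lh", "score_nlh"])


def save_model(model: DiscriminantModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tintercept\tcoef_failure\tcoef_latency\n")
        for name, sc in ((LH, model.lh), (NLH, model.nlh)):
            fh.write(f"{name}\t{sc.intercept!r}\t{sc.coef_failure!r}\t{sc.coef_latency!r}\n")


def load_model(path: str | Path) -> DiscriminantModel:
    df = pd.read_csv(path, sep="\t").set_index("class")
    def _sc(name: str) -> ClassScore:
        r = df.loc[name]
        return ClassScore(float(r["intercept"]), float(r["coef_failure"]), float(r["coef_latency"]))
    return DiscriminantModel(lh=_sc(LH), nlh=_sc(NLH))


def compare_groups(behavior: pd.DataFrame, labels: pd.Series) -> dict[str, dict]:
    """One-way ANOVA + Bonferroni pairwise post hoc per behavioral metric.

    ``labels`` maps mouse_id to group (may include Ctrl).  Returns, per metric,
    group means and SEMs, the ANOVA F and p, and Bonferroni-adjusted pairwise
    two-sided p values (raw p multiplied by the number of comparisons, capped
    at 1).
    """
    lab = labels.reindex(behavior["mouse_id"].astype(str).values)
    if lab.isna().any():
        raise ValueError("every mouse needs a group label")
    groups = sorted(lab.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out: dict[str, dict] = {}
    for metric in FEATURES:
        vals = {
            g: behavior.loc[(lab == g).to_numpy(), metric].to_numpy(dtype=float)
            for g in groups
        }
        for g, v in vals.items():
            if len(v) < 2:
                raise ValueError(f"group {g} has fewer than 2 members")
        grand = np.concatenate(list(vals.values()))
        between = sum(len(v) * (v.mean() - grand.mean()) ** 2 for v in vals.values())
        if between == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*vals.values())
        pairs = list(combinations(groups, 2))
        pairwise = {}
        for a, b in pairs:
            _, p_raw = stats.ttest_ind(vals[a], vals[b], equal_var=True)
            pairwise[(a, b)] = min(1.0, float(p_raw) * len(pairs))
        out[metric] = {
            "means": {g: float(v.mean()) for g, v in vals.items()},
            "sems": {g: float(stats.sem(v)) for g, v in vals.items()},
            "F": float(f_stat),
            "p": float(p),
            "pairwise_bonferroni": pairwise,
        }
    return out
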