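"""Relative qPCR quantification by the 2^-ddCt method.

Each sample's target-gene Ct (mean over up to three replicates) is normalised
to a reference housekeeping gene (dCt = Ct_target - Ct_reference), then to the
mean dCt of the control group (ddCt); relative expression is 2^-ddCt, reported
as a percentage of control.  Amplification efficiency is assumed to be exactly
2 per cycle.  Group validation uses a two-tailed unpaired pooled-variance
t-test on the percent-of-control values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import t_test

CT_COLUMNS = ["ct1", "ct2", "ct3"]


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read a qPCR plate CSV with columns sample, group, gene, ct1..ct3."""
    df = pd.read_csv(path)
    needed = {"sample", "group", "gene"}
    if not needed <= set(df.columns):
        raise ValueError(f"qPCR table must have columns {sorted(needed)} + ct replicates")
    cts = [c for c in CT_COLUMNS if c in df.columns]
    if not cts:
        raise ValueError("no ct replicate columns (ct1..ct3) found")
    vals = df[cts].to_numpy(dtype=float)
    if np.nanmin(vals) <= 0 or not np.isfinite(np.nanmax(vals)):
        raise ValueError("Ct values must be positive and finite")
    return df


def write_qpcr(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)


def ddct(
    plate: pd.DataFrame, reference_gene: str = "GAPDH", control_group: str = "Ctrl"
) -> pd.DataFrame:
    """Compute per-sample relative expression for every non-reference gene.

    The ddCt baseline is the *mean* dCt of the control-group samples (not a
    single calibrator sample), so control samples average to 100% of control.
    """
    cts = [c for c in CT_COLUMNS if c in plate.columns]
    df = plate.copy()
    df["mean_ct"] = df[cts].mean(axis=1)
    ref = df[df["gene"] == reference_gene].set_index("sample")["mean_ct"]
    if not (df["group"] == control_group).any():
        raise ValueError(f"control group {control_group!r} absent from plate")
    rows = []
    for gene, sub in df[df["gene"] != reference_gene].groupby("gene", sort=True):
        missing = set(sub["sample"]) - set(ref.index)
        if missing:
            raise ValueError(
                f"samples missing reference gene {reference_gene!r}: {sorted(missing)}"
            )
        sub = sub.copy()
        sub["delta_ct"] = sub["mean_ct"].to_numpy() - ref.reindex(sub["sample"]).to_numpy()
        ctrl = sub.loc[sub["group"] == control_group, "delta_ct"]
        if ctrl.empty:
            raise ValueError(f"gene {gene!r} has no control-group measurements")
        baseline = float(ctrl.mean())
        sub["ddct"] = sub["delta_ct"] - baseline
        sub["fold_change"] = np.power(2.0, -sub["ddct"])
        sub["percent_of_control"] = 100.0 * sub["fold_change"]
        rows.append(
            sub[["sample", "group", "gene", "mean_ct", "delta_ct", "ddct",
                 "fold_change", "percent_of_control"]]
        )
    return pd.concat(rows, ignore_index=True)


def validate(rel: pd.DataFrame, group_pair: tuple[str, str]) -> pd.DataFrame:
    """Two-tailed unpaired t-test on percent-of-control, per gene."""
    a, b = group_pair
    for g in group_pair:
        if not (rel["group"] == g).any():
            raise ValueError(f"group {g!r} absent from results")
    rows = []
    for gene, sub in rel.groupby("gene", sort=True):
        va = sub.loc[sub["group"] == a, "percent_of_control"].to_numpy()
        vb = sub.loc[sub["group"] == b, "percent_of_control"].to_numpy()
        t, p, direction = t_test(va, vb)
        rows.append(
            {
                "gene": gene,
                "comparison": f"{a}vs{b}",
                "mean_test": float(va.mean()),
                "mean_ref": float(vb.mean()),
                "t": t,
                "p": p,
                "direction": direction,
                "significant": p < 0.05,
            }
        )
    return pd.DataFrame(rows)
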