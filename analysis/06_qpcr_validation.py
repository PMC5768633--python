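"""qPCR validation by 2^-ddCt with GAPDH normalization.

Quantifies the simulated triplicate plate relative to the control group,
reports percent-of-control per gene, and validates group differences with the
two-tailed unpaired t-test.
"""

import argparse
from pathlib import Path

from lhnet import qpcr, synthdata


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data-dir", default="results/synthetic")
    ap.add_argument("--out-dir", default="results/qpcr")
    args = ap.parse_args()

    data = Path(args.data_dir)
    if not (data / "qpcr.csv").exists():
        synthdata.generate_study(synthdata.SimulationConfig(seed=args.seed), data)
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    plate = qpcr.read_qpcr(data / "qpcr.csv")
    rel = qpcr.ddct(plate, reference_gene="GAPDH", control_group="Ctrl")
    rel.to_csv(out / "qpcr_relative.tsv", sep="\t", index=False)
    stats = qpcr.validate(rel, ("LH", "Ctrl"))
    stats.to_csv(out / "qpcr_validation.tsv", sep="\t", index=False)

    lh_means = rel[rel["group"] == "LH"].groupby("gene")["percent_of_control"].mean()
    for row in stats.itertuples(index=False):
        star = "*" if row.significant else " "
        print(f"{row.gene:10s} LH = {lh_means[row.gene]:6.1f}% of control, "
              f"t = {row.t:6.2f}, p = {row.p:.4f} {star}")


if __name__ == "__main__":
    main()
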