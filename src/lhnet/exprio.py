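"""Expression-matrix, annotation and metadata I/O plus gene-level aggregation.

The pipeline starts from a transcript x sample FPKM matrix (TSV), a transcript
annotation (GTF or flat TSV) and a sample->group metadata table.  This module
reads and validates those files, applies the expression QC filter, and collapses
transcript-level values to gene level by unweighted averaging of all transcripts
of a gene.

Coordinates are stored 1-based inclusive, exactly as GTF supplies them; all
genomic-distance arithmetic downstream assumes this convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: lncRNA subclasses; anything here counts toward the combined "lncRNA" tally.
LNCRNA_BIOTYPES = frozenset(
    {
        "lincRNA",
        "antisense",
        "sense_intronic",
        "sense_overlapping",
        "bidirectional_promoter_lncRNA",
        "processed_transcript",
    }
)

#: Closed biotype vocabulary.  Unknown biotypes read from annotation fall back
#: to "novel" with a logged warning.
BIOTYPES = LNCRNA_BIOTYPES | frozenset(
    {"protein_coding", "novel", "pseudogene", "TEC", "miscRNA", "snoRNA", "scaRNA"}
)

GROUPS = ("LH", "NLH", "Ctrl", "HC")

ANNOTATION_COLUMNS = [
    "transcript_id",
    "gene_id",
    "chromosome",
    "start",
    "end",
    "strand",
    "biotype",
]


@dataclass
class ExpressionMatrix:
    """A feature x sample table of FPKM values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by feature id (transcript or gene), columns by sample id.
    level : {"transcript", "gene"}
        Aggregation level of the rows.
    """

    data: pd.DataFrame
    level: str = "transcript"

    def __post_init__(self) -> None:
        if self.level not in ("transcript", "gene"):
            raise ValueError(f"unknown expression level {self.level!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.data.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite FPKM at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative FPKM at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()


def read_expression(path: str | Path, level: str = "transcript") -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return ExpressionMatrix(df, level=level)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = f"{matrix.level}_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.Series:
    """Read sample metadata TSV (columns sample_id, group) as a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("metadata must have columns sample_id, group")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return df.set_index("sample_id")["group"]


def write_metadata(design: pd.Series, path: str | Path) -> None:
    design.rename("group").rename_axis("sample_id").to_frame().to_csv(path, sep="\t")


def _validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "transcript_id"].tolist()
        raise ValueError(f"start > end for transcripts {bad[:5]}")
    if df["gene_id"].isna().any() or (df["gene_id"] == "").any():
        bad = df.loc[df["gene_id"].isna() | (df["gene_id"] == ""), "transcript_id"]
        raise ValueError(f"transcripts missing gene_id: {bad.tolist()[:5]}")
    unknown = ~df["biotype"].isin(BIOTYPES)
    if unknown.any():
        for bt in df.loc[unknown, "biotype"].unique():
            log.warning("unknown biotype %r mapped to 'novel'", bt)
        df.loc[unknown, "biotype"] = "novel"
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise ValueError(f"duplicate transcript ids: {dups[:5]}")
    return df.reset_index(drop=True)


def read_annotation(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read transcript annotation from a flat TSV or an (Ensembl-dialect) GTF.

    Returns a DataFrame with columns transcript_id, gene_id, chromosome,
    start, end, strand, biotype — coordinates 1-based inclusive as in GTF.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        return _validate_annotation(df)
    if format == "gtf":
        import gffutils

        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
        rows = []
        for tr in db.features_of_type("transcript"):
            if "gene_id" not in tr.attributes:
                raise ValueError(f"transcript {tr.id!r} missing gene_id attribute")
            rows.append(
                {
                    "transcript_id": tr.attributes["transcript_id"][0],
                    "gene_id": tr.attributes["gene_id"][0],
                    "chromosome": tr.seqid,
                    "start": tr.start,
                    "end": tr.end,
                    "strand": tr.strand,
                    "biotype": tr.attributes.get("transcript_biotype", ["novel"])[0],
                }
            )
        if not rows:
            raise ValueError(f"no transcript features in {path}")
        return _validate_annotation(pd.DataFrame(rows))
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def write_annotation_gtf(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write transcript features as a minimal Ensembl-dialect GTF."""
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            attrs = (
                f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}"; '
                f'transcript_biotype "{row.biotype}";'
            )
            fh.write(
                f"{row.chromosome}\tlhnet\ttranscript\t{row.start}\t{row.end}\t."
                f"\t{row.strand}\t.\t{attrs}\n"
            )


def gene_spans(annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse transcript annotation to per-gene spans and biotypes.

    The gene span is the union [min start, max end] of its transcripts, which
    must all sit on one chromosome.  Gene biotype is the modal transcript
    biotype, ties broken toward protein_coding (then lexicographically).
    """

    rows = {}
    for gene_id, group in annotation.groupby("gene_id", sort=True):
        chroms = group["chromosome"].unique()
        if len(chroms) > 1:
            raise ValueError(f"gene {gene_id!r} spans chromosomes {list(chroms)}")
        counts = group["biotype"].value_counts()
        top = counts[counts == counts.max()].index
        biotype = "protein_coding" if "protein_coding" in top else sorted(top)[0]
        rows[gene_id] = {
            "chromosome": chroms[0],
            "start": int(group["start"].min()),
            "end": int(group["end"].max()),
            "biotype": biotype,
            "n_transcripts": len(group),
        }
    spans = pd.DataFrame.from_dict(rows, orient="index")
    spans.index.name = "gene_id"
    return spans


def qc_filter(
    matrix: ExpressionMatrix, min_fpkm: float = 0.1, min_samples: int = 1
) -> tuple[ExpressionMatrix, dict]:
    """Keep features with FPKM >= ``min_fpkm`` in at least ``min_samples`` samples.

    Returns the filtered matrix and a report dict with before/after counts.
    """
    if min_fpkm < 0 or min_samples < 0:
        raise ValueError("thresholds must be non-negative")
    n_samples = matrix.data.shape[1]
    if min_samples > n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {n_samples}"
        )
    keep = (matrix.data >= min_fpkm).sum(axis=1) >= min_samples
    filtered = ExpressionMatrix(matrix.data.loc[keep], level=matrix.level)
    report = {
        "n_before": int(matrix.data.shape[0]),
        "n_after": int(filtered.data.shape[0]),
        "min_fpkm": float(min_fpkm),
        "min_samples": int(min_samples),
    }
    return filtered, report


def gene_level_average(
    matrix: ExpressionMatrix, annotation: pd.DataFrame
) -> ExpressionMatrix:
    """Average FPKM of all transcripts of a gene, per sample.

    The unweighted arithmetic mean over a gene's transcripts is used; sample
    order is preserved and the result is a gene-level matrix.
    """
    if matrix.level != "transcript":
        raise ValueError("gene_level_average expects a transcript-level matrix")
    mapping = annotation.set_index("transcript_id")["gene_id"]
    missing = matrix.data.index.difference(mapping.index)
    if len(missing) > 0:
        raise ValueError(
            f"transcripts missing from annotation: {missing.tolist()[:10]}"
        )
    genes = mapping.reindex(matrix.data.index)
    out = matrix.data.groupby(genes.values).mean()
    out.index.name = "gene_id"
    return ExpressionMatrix(out, level="gene")
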