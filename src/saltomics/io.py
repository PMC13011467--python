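"""Readers and writers for the pipeline's plain-text formats.

Feature/sample/expression/annotation tables are CSV/TSV; fragments are
BED6 (0-based half-open); gene models are GFF3 (1-based inclusive). Each
writer's output round-trips through its reader. No timestamps are written
anywhere, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .exceptions import InvalidAnnotationError, InvalidInputError, InvalidRecordError
from .metabolomics import FeatureTable

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


# -- feature tables ---------------------------------------------------------

def write_feature_table(table: FeatureTable, features_csv, samples_csv) -> None:
    out = table.features.copy()
    out = pd.concat([out, table.signals], axis=1)
    out.to_csv(features_csv, index=True)
    table.samples.to_csv(samples_csv, index=True)


def read_feature_table(features_csv, samples_csv) -> FeatureTable:
    feats = pd.read_csv(features_csv, index_col="feature_id")
    samples = pd.read_csv(samples_csv, index_col="sample_id")
    meta_cols = [c for c in ("mz", "rt", "mode") if c in feats.columns]
    sample_cols = [c for c in feats.columns if c not in meta_cols]
    if set(sample_cols) != set(samples.index):
        raise InvalidInputError("feature table samples do not match sample metadata")
    return FeatureTable(
        features=feats[meta_cols],
        signals=feats[list(samples.index)],
        samples=samples,
    )


# -- expression tables ------------------------------------------------------

def write_expression_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True)


def read_expression_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def read_annotation_table(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"gene_id", "category", "conservation"}
    if not required <= set(ann.columns):
        raise InvalidInputError(f"annotation table needs columns {sorted(required)}")
    return ann


# -- BED6 -------------------------------------------------------------------

def write_bed6(df: pd.DataFrame, path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    if df.empty:
        return df
    if (df["start"] >= df["end"]).any():
        raise InvalidRecordError(f"{path}: BED interval with start >= end")
    return df


# -- GFF3 -------------------------------------------------------------------

def write_gff3(genes: pd.DataFrame, path, seqid: str = "chr") -> None:
    lines = ["##gff-version 3"]
    for row in genes.itertuples():
        attrs = f"ID={row.gene_id}"
        lines.append(
            "\t".join(
                [seqid, "saltomics", "gene", str(row.start), str(row.end), ".",
                 row.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise InvalidAnnotationError(f"{path}: malformed GFF3 line: {line!r}")
        m = re.search(r"ID=([^;]+)", parts[8])
        gene_id = m.group(1) if m else parts[8]
        start, end = int(parts[3]), int(parts[4])
        if end < start:
            raise InvalidAnnotationError(f"{path}: gene with end < start: {line!r}")
        rows.append(
            {"gene_id": gene_id, "start": start, "end": end, "strand": parts[6]}
        )
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand"])


# -- truth & manifest -------------------------------------------------------

def write_truth(truth, path) -> None:
    """Serialise a GroundTruth as a tidy TSV (kind, id, position, strand, conditions)."""
    rows = []
    for fid in sorted(truth.differential_feature_ids):
        rows.append({"kind": "differential_feature", "id": fid})
    for gid in sorted(truth.de_gene_ids):
        rows.append({"kind": "de_gene", "id": gid})
    for gid in sorted(truth.salt_up_gene_ids):
        rows.append({"kind": "salt_up_gene", "id": gid})
    for pos, strand, conds in truth.true_tss:
        rows.append(
            {"kind": "tss", "id": f"{strand}{pos}", "position": pos,
             "strand": strand, "conditions": "+".join(sorted(conds))}
        )
    pd.DataFrame(rows, columns=["kind", "id", "position", "strand", "conditions"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path):
    from .synthetic_data import GroundTruth

    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    tss = []
    for row in df[df["kind"] == "tss"].itertuples():
        tss.append(
            (int(row.position), row.strand, frozenset(str(row.conditions).split("+")))
        )
    return GroundTruth(
        differential_feature_ids=frozenset(df.loc[df["kind"] == "differential_feature", "id"]),
        de_gene_ids=frozenset(df.loc[df["kind"] == "de_gene", "id"]),
        salt_up_gene_ids=frozenset(df.loc[df["kind"] == "salt_up_gene", "id"]),
        true_tss=tuple(tss),
    )


def read_manifest(path) -> pd.DataFrame:
    """Fragment-file manifest: TSV with columns path, condition, replicate."""
    df = pd.read_csv(path, sep="\t")
    required = {"path", "condition", "replicate"}
    if not required <= set(df.columns):
        raise InvalidInputError(f"manifest needs columns {sorted(required)}")
    return df


# -- format validation ------------------------------------------------------

def validate_formats(paths: dict) -> list[str]:
    """Structural checks on a set of files; returns a list of problems.

    ``paths`` maps a format name in {bed6, gff3, features, samples,
    expression, annotation} to one path or a list of paths. Reporting
    only: never raises for content errors.
    """
    problems: list[str] = []

    def as_list(v):
        return v if isinstance(v, (list, tuple)) else [v]

    for path in as_list(paths.get("bed6", [])):
        try:
            df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
            bad = df[df["start"] >= df["end"]]
            for row in bad.itertuples():
                problems.append(f"{path}: BED start >= end at {row.start}-{row.end}")
            if not df["strand"].isin(["+", "-"]).all():
                problems.append(f"{path}: BED with unknown strand")
        except Exception as exc:  # pragma: no cover - defensive
            problems.append(f"{path}: unreadable BED6 ({exc})")
    for path in as_list(paths.get("gff3", [])):
        try:
            for line in Path(path).read_text().splitlines():
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    problems.append(f"{path}: GFF3 line with {len(parts)} fields")
                    continue
                if int(parts[4]) < int(parts[3]):
                    problems.append(f"{path}: GFF3 end < start ({parts[3]}-{parts[4]})")
        except Exception as exc:  # pragma: no cover - defensive
            problems.append(f"{path}: unreadable GFF3 ({exc})")
    for key, reader in (
        ("features", None),
        ("expression", read_expression_table),
        ("annotation", read_annotation_table),
    ):
        for path in as_list(paths.get(key, [])):
            try:
                if key == "features":
                    pd.read_csv(path, index_col="feature_id")
                else:
                    reader(path)
            except Exception as exc:
                problems.append(f"{path}: invalid {key} table ({exc})")
    return problems
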