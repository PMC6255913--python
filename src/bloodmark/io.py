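"""Readers and writers for the pipeline's external text formats.

All inputs are plain tab-delimited UTF-8 text with a '.' decimal point:

* expression matrices (first column = feature id, header row = sample ids),
* sample metadata tables (sample_id, group, age, gender, + extra columns),
* feature annotation tables (feature_id, gene_id, symbol),
* gene-set collections in standard GMT format.

Readers validate aggressively and report the offending line / identifier;
they never silently drop rows.  Writers round-trip losslessly (matrix
values via repr-precision floats, GMT members in sorted order).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, FeatureAnnotation, GeneSetCollection, SampleInfo

_META_COLUMNS = ("sample_id", "group", "age", "gender")


def read_expression_matrix(path: str | Path, dataset_label: str = "") -> ExpressionDataset:
    """Read a feature x sample TSV into an :class:`ExpressionDataset`.

    The first header field is ignored (corner label); remaining header
    fields are sample ids.  Raises ``ValueError`` naming the line number
    for ragged rows and the feature/sample position for non-numeric cells.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        feature_ids: list[str] = []
        rows: list[np.ndarray] = []
        ncol = len(sample_ids)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != ncol + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncol + 1} fields, found {len(fields)} (ragged row)"
                )
            fid = fields[0]
            try:
                vals = np.array(fields[1:], dtype=float)
            except ValueError:
                for j, cell in enumerate(fields[1:]):
                    try:
                        float(cell)
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric cell {cell!r} for feature "
                            f"{fid!r}, sample {sample_ids[j]!r}"
                        ) from None
                raise
            feature_ids.append(fid)
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    matrix = np.vstack(rows)
    return ExpressionDataset(matrix, feature_ids, sample_ids, dataset_label=dataset_label)


def write_expression_matrix(ds: ExpressionDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(ds.sample_ids) + "\n")
        for fid, row in zip(ds.feature_ids, ds.matrix):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_sample_info(path: str | Path) -> list[SampleInfo]:
    """Read a sample metadata TSV into :class:`SampleInfo` records.

    Requires columns sample_id, group, age, gender; any further columns are
    parsed as numeric extra covariates and kept by name.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra_cols = [c for c in df.columns if c not in _META_COLUMNS]
    records = []
    for i, row in df.iterrows():
        extras = {}
        for c in extra_cols:
            try:
                extras[c] = float(row[c])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {row[c]!r} in extra covariate column "
                    f"{c!r} for sample {row['sample_id']!r}"
                ) from None
        try:
            age = float(row["age"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-numeric age {row['age']!r} for sample {row['sample_id']!r}"
            ) from None
        records.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                age=age,
                gender=str(row["gender"]),
                extra_covariates=extras,
            )
        )
    return records


def write_sample_info(records: list[SampleInfo], path: str | Path) -> None:
    path = Path(path)
    extra_cols = sorted({k for r in records for k in r.extra_covariates})
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_META_COLUMNS + tuple(extra_cols)) + "\n")
        for r in records:
            fields = [r.sample_id, r.group, repr(float(r.age)), r.gender]
            fields += [repr(float(r.extra_covariates[c])) for c in extra_cols]
            fh.write("\t".join(fields) + "\n")


def read_annotation(path: str | Path) -> list[FeatureAnnotation]:
    """Read a feature_id / gene_id / symbol TSV; empty gene_id is preserved
    (unannotated features are filtered downstream, not here)."""
    path = Path(path)
    records: list[FeatureAnnotation] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "feature_id":
            raise ValueError(f"{path}: first column must be 'feature_id', found {header[0]!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            fields += [""] * (3 - len(fields))
            fid, gid, sym = fields[0], fields[1], fields[2]
            if fid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate feature_id {fid!r}")
            seen.add(fid)
            records.append(FeatureAnnotation(feature_id=fid, gene_id=gid, symbol=sym))
    return records


def write_annotation(records: list[FeatureAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("feature_id\tgene_id\tsymbol\n")
        for r in records:
            fh.write(f"{r.feature_id}\t{r.gene_id}\t{r.symbol}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (name, description, then member ids)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: gene set line needs name, description and at least "
                    f"one member"
                )
            name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen: set[str] = set()
            sets[name] = [m for m in members if not (m in seen or seen.add(m))]
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a GMT file with members in sorted order (round-trip policy)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write(name + "\t" + desc + "\t" + "\t".join(sorted(collection[name])) + "\n")


def write_run_metadata(meta: dict, path: str | Path) -> None:
    """Write a JSON run-metadata file (parameters, seed, versions)."""
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8")
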