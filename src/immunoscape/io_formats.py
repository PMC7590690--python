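"""Readers and writers for the pipeline's tab-separated dialects.

All tables are plain TSV with '.' decimals and no locale handling (GDAC-style).
Lines starting with '#' are treated as header comments; writers prepend one
recording the package version and any parameters passed.  Gene identifiers
are opaque symbols — no alias resolution is attempted.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from . import __version__
from .types import (
    CausalNetwork,
    ClinicalTable,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    VariantRecord,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_variants",
    "write_variants",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
]

PathLike = Union[str, Path]

_SIGN_TOKENS = {"1": 1, "+1": 1, "-1": -1, "activates": 1, "inhibits": -1}


def _comment(params: Optional[Mapping] = None) -> str:
    extra = "" if not params else " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# immunoscape v{__version__}{extra}\n"


def read_expression(path: PathLike, state: str) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (gene id in the first column).

    Raises :class:`FormatError` naming the offending row/column on duplicate
    identifiers or non-numeric cells.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                         float_precision="round_trip")
    except Exception as exc:  # malformed header / ragged rows
        raise FormatError(f"cannot parse expression table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"expression table {path} has no sample columns")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().sum() > df[col].isna().sum():
            bad = df.index[coerced.isna() & df[col].notna()][0]
            raise FormatError(
                f"non-numeric cell at gene {bad!r}, sample {col!r} in {path}"
            )
        df[col] = coerced
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicated gene rows in {path}: {dups[:10]}")
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df.astype(float), state)


def write_expression(matrix: ExpressionMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_comment({"state": matrix.state}))
        buf = io.StringIO()
        # repr-formatted floats survive the text round trip bit-for-bit
        matrix.values.to_csv(buf, sep="\t", index_label="gene_id",
                             float_format=lambda v: repr(float(v)))
        fh.write(buf.getvalue())


_VARIANT_COLS = {"sample": "sample_id", "gene": "gene_symbol",
                 "variant_classification": "variant_classification"}


def read_variants(path: PathLike) -> list[VariantRecord]:
    """Read a minimal MAF-like TSV (sample, gene, variant_classification
    [, protein_change]); unknown extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_VARIANT_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"variant table {path} missing columns: {sorted(missing)}")
    has_pc = "protein_change" in df.columns
    records = []
    for row in df.itertuples(index=False):
        pc = getattr(row, "protein_change", None) if has_pc else None
        if isinstance(pc, float):  # NaN
            pc = None
        records.append(
            VariantRecord(
                sample_id=row.sample,
                gene_symbol=row.gene,
                variant_classification=row.variant_classification,
                protein_change=pc,
            )
        )
    return records


def write_variants(records: Iterable[VariantRecord], path: PathLike,
                   params: Optional[Mapping] = None) -> None:
    df = pd.DataFrame(
        [
            {
                "sample": r.sample_id,
                "gene": r.gene_symbol,
                "variant_classification": r.variant_classification,
                "protein_change": r.protein_change if r.protein_change is not None else "",
            }
            for r in records
        ],
        columns=["sample", "gene", "variant_classification", "protein_change"],
    )
    with open(path, "w") as fh:
        fh.write(_comment(params))
        df.to_csv(fh, sep="\t", index=False)


def read_clinical(path: PathLike) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"clinical table {path} missing 'sample_id' column")
    df = df.set_index("sample_id")
    if "response" in df.columns:
        df["response"] = df["response"].replace("", pd.NA)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_comment())
        clinical.data.to_csv(fh, sep="\t", index_label="sample_id", na_rep="")


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Genes are deduplicated within a set; a line with fewer than three
    fields is a format error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno} in {path} has {len(fields)} fields (< 3)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"duplicate gene set name {name!r} in {path}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_network(path: PathLike,
                 annotation_path: Optional[PathLike] = None) -> CausalNetwork:
    """Read a signed edge TSV (regulator, target, sign).

    Sign tokens accepted: 1, +1, -1, activates, inhibits.  Duplicate
    (regulator, target) rows are collapsed to one edge when their signs
    agree; conflicting duplicates are an error.  An optional second TSV
    (regulator, pathway) supplies the pathway annotation.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"regulator", "target", "sign"} - set(df.columns)
    if missing:
        raise FormatError(f"network table {path} missing columns: {sorted(missing)}")
    signs = []
    for tok in df["sign"]:
        key = str(tok).strip().lower()
        if key not in _SIGN_TOKENS:
            raise FormatError(f"invalid sign token {tok!r} in {path}")
        signs.append(_SIGN_TOKENS[key])
    df = df.assign(sign=signs)
    conflict = df.groupby(["regulator", "target"])["sign"].nunique()
    bad = conflict[conflict > 1]
    if len(bad):
        raise FormatError(
            f"conflicting duplicate edges in {path}: {list(bad.index[:10])}"
        )
    df = df.drop_duplicates(subset=["regulator", "target"]).reset_index(drop=True)
    annotation: dict[str, set[str]] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", comment="#", dtype=str)
        missing = {"regulator", "pathway"} - set(ann.columns)
        if missing:
            raise FormatError(
                f"annotation table {annotation_path} missing columns: {sorted(missing)}"
            )
        for row in ann.itertuples(index=False):
            annotation.setdefault(row.regulator, set()).add(row.pathway)
    return CausalNetwork(df[["regulator", "target", "sign"]], annotation)


def write_network(network: CausalNetwork, path: PathLike,
                  annotation_path: Optional[PathLike] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment())
        network.edges.to_csv(fh, sep="\t", index=False)
    if annotation_path is not None and network.annotation:
        rows = [
            {"regulator": reg, "pathway": pw}
            for reg, pws in network.annotation.items()
            for pw in sorted(pws)
        ]
        with open(annotation_path, "w") as fh:
            fh.write(_comment())
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: PathLike,
                params: Optional[Mapping] = None, index: bool = False,
                index_label: Optional[str] = None) -> None:
    """Write an arbitrary result table with the standard header comment."""
    with open(path, "w") as fh:
        fh.write(_comment(params))
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)
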