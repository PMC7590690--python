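"""Core in-memory containers shared across the pipeline.

The pipeline moves five kinds of tables around: gene-by-sample expression
matrices (with an explicit normalization state), somatic variant records,
per-sample clinical annotation, named gene sets, and a signed
regulator->target causal network.  Each container validates its invariants
on construction so downstream statistics can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "VariantRecord",
    "ClinicalTable",
    "GeneSetCollection",
    "CausalNetwork",
    "EXPRESSION_STATES",
    "RESPONSE_LEVELS",
]

EXPRESSION_STATES = ("raw_counts", "normalized", "log2")
RESPONSE_LEVELS = ("PD", "SD", "PR", "CR")


class FormatError(ValueError):
    """A table violates the dialect this pipeline reads and writes."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix tagged with its normalization state.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the row index and sample
        identifiers as columns.
    state
        One of ``raw_counts``, ``normalized`` or ``log2``.  ``raw_counts``
        requires all values to be nonnegative.
    """

    values: pd.DataFrame
    state: str

    def __post_init__(self) -> None:
        if self.state not in EXPRESSION_STATES:
            raise ValueError(
                f"state must be one of {EXPRESSION_STATES}, got {self.state!r}"
            )
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "gene identifiers")
        _check_unique(self.values.columns, "sample identifiers")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        if self.state == "raw_counts" and (arr < 0).any():
            raise FormatError("raw_counts state requires nonnegative values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.state)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.state)


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant call on one sample."""

    sample_id: str
    gene_symbol: str
    variant_classification: str
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.variant_classification:
            raise FormatError(
                f"empty variant_classification for sample {self.sample_id!r}, "
                f"gene {self.gene_symbol!r}"
            )


@dataclass
class ClinicalTable:
    """Per-sample annotation: tumor type, optional treatment response.

    ``data`` is indexed by sample_id and must contain a ``tumor_type``
    column; a ``response`` column, when present, uses RECIST levels
    PD / SD / PR / CR (missing values allowed).  Extra columns pass
    through untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "tumor_type" not in self.data.columns:
            raise FormatError("clinical table requires a 'tumor_type' column")
        _check_unique(self.data.index, "sample identifiers")
        tt = self.data["tumor_type"]
        if tt.isna().any() or (tt.astype(str).str.len() == 0).any():
            bad = self.data.index[tt.isna() | (tt.astype(str).str.len() == 0)]
            raise FormatError(f"empty tumor_type for samples {list(bad[:10])}")
        if "response" in self.data.columns:
            resp = self.data["response"].dropna()
            bad = set(resp.unique()) - set(RESPONSE_LEVELS)
            if bad:
                raise FormatError(f"invalid response levels: {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def tumor_type(self) -> pd.Series:
        return self.data["tumor_type"]

    @property
    def response(self) -> Optional[pd.Series]:
        return self.data.get("response")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> ordered unique symbols."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            cleaned[name] = list(dict.fromkeys(genes))
        self.sets = cleaned

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class CausalNetwork:
    """Signed regulator -> target edges, optionally annotated with pathways.

    ``edges`` has columns regulator, target, sign (+1 activates the target,
    -1 inhibits it); duplicate (regulator, target) pairs are invalid.
    ``annotation`` maps a regulator to the set of named signaling pathways
    it belongs to, used to build the pathway-sharing network.
    """

    edges: pd.DataFrame
    annotation: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"regulator", "target", "sign"}
        missing = required - set(self.edges.columns)
        if missing:
            raise FormatError(f"network edges missing columns: {sorted(missing)}")
        signs = set(self.edges["sign"].unique())
        if not signs <= {1, -1}:
            raise FormatError(f"edge signs must be +1/-1, got {sorted(signs - {1, -1})}")
        dup = self.edges.duplicated(subset=["regulator", "target"])
        if dup.any():
            pairs = self.edges.loc[dup, ["regulator", "target"]].values.tolist()
            raise FormatError(f"duplicate regulator->target edges: {pairs[:10]}")
        self.edges = self.edges.reset_index(drop=True)

    def regulators(self) -> list[str]:
        return list(pd.unique(self.edges["regulator"]))

    def targets_of(self, regulator: str) -> pd.DataFrame:
        """Edge rows for one regulator (columns target, sign)."""
        sub = self.edges.loc[self.edges["regulator"] == regulator, ["target", "sign"]]
        return sub.reset_index(drop=True)
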