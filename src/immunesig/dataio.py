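"""Core containers and file formats shared by every pipeline stage.

Expression data travels as features × samples log2 matrices (TSV with a
header row of sample ids and the first column holding feature ids; GCT is
accepted on read by sniffing the ``#1.2`` header).  Gene sets use the GMT
dialect (name, description, members).  Clinical tables are TSV with a
``sample_id`` column, a survival ``time`` (unit declared per table), a
binary ``event`` indicator and optional stratification columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("immunesig")

__all__ = [
    "ExpressionMatrix",
    "FeatureAnnotation",
    "ClinicalTable",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_clinical",
    "write_clinical",
]


@dataclass
class ExpressionMatrix:
    """A features × samples matrix of log2 expression intensities.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features (probe sets or genes), columns are samples.
    dataset_name : str
        Label used in logs and multi-dataset bookkeeping.
    """

    data: pd.DataFrame
    dataset_name: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError(
                f"expression matrix must be at least 2×2, got {self.data.shape}"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at feature {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, features: Iterable[str]) -> "ExpressionMatrix":
        keep = [f for f in features if f in self.data.index]
        return ExpressionMatrix(self.data.loc[keep], self.dataset_name)


@dataclass
class FeatureAnnotation:
    """Feature → gene-symbol map plus term memberships.

    ``immune_terms`` flags the subset of ``term_to_features`` keys regarded
    as immunity-related; it drives cluster flagging and final signature
    qualification.
    """

    feature_to_gene: dict[str, str] = field(default_factory=dict)
    term_to_features: dict[str, frozenset] = field(default_factory=dict)
    term_labels: dict[str, str] = field(default_factory=dict)
    immune_terms: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.term_to_features = {
            t: frozenset(m) for t, m in self.term_to_features.items()
        }
        self.immune_terms = frozenset(self.immune_terms)
        missing = self.immune_terms - set(self.term_to_features)
        if missing:
            raise ValueError(
                f"immune terms not present in the term table: {sorted(missing)[:5]}"
            )

    def gene_of(self, feature: str) -> str | None:
        return self.feature_to_gene.get(feature)

    def annotated_features(self) -> frozenset:
        """Features that belong to at least one term."""
        out: set = set()
        for members in self.term_to_features.values():
            out |= members
        return frozenset(out)


@dataclass
class ClinicalTable:
    """Per-sample survival annotation: time, event and strata columns."""

    data: pd.DataFrame  # index: sample ids; columns: time, event, strata...
    time_unit: str = "years"

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id in clinical table: {dup!r}")
        if (self.data["time"] < 0).any():
            raise ValueError("negative survival time")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def strata_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]


# ---------------------------------------------------------------------------
# expression matrix IO


def read_expression(path: str | Path, dataset_name: str = "") -> ExpressionMatrix:
    """Read a TSV (or GCT) expression matrix; rows features, columns samples.

    Raises on duplicate identifiers (naming the duplicate) and on
    non-numeric cells (naming the coordinates); row and column order are
    preserved from the file.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skiprows: int = 0
    gct = first.startswith("#1.2")
    if gct:
        skiprows = 2  # version line + dimensions line
    df = pd.read_csv(path, sep="\t", skiprows=skiprows, index_col=0, dtype=str)
    if gct and df.columns[:1].str.lower().isin(["description"]).any():
        df = df.drop(columns=df.columns[0])
    idx = df.index.astype(str)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"{path.name}: duplicate feature id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path.name}: duplicate sample id {dup!r}")
    probe = df.apply(pd.to_numeric, errors="coerce")
    bad = probe.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path.name}: non-numeric cell at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {df.iloc[i, j]!r}"
        )
    numeric = df.astype(np.float64)  # exactly-rounded parse for round trips
    numeric.index = idx
    if not dataset_name:
        dataset_name = path.stem
    return ExpressionMatrix(numeric, dataset_name)


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    df = x.data.copy()
    df.index.name = "feature_id"
    # repr-round-trip float format keeps read(write(x)) bit-exact
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path: str | Path) -> dict[str, frozenset]:
    """Read a GMT file: one set per line (name, description, members...)."""
    out: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{Path(path).name}:{lineno}: GMT line needs at least "
                    f"3 fields, got {len(fields)}"
                )
            name = fields[0]
            out[name] = frozenset(fields[2:])
    return out


def write_gene_sets(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sets:
            members = sorted(set(sets[name]))
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# clinical tables


def read_clinical(path: str | Path, time_unit: str = "years") -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df, time_unit=time_unit)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    df = clin.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")
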