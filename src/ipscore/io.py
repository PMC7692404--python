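"""Reading, validation and writing of the external tabular formats.

Three inputs drive the pipeline:

* a normalized expression matrix (genes x samples, TSV) plus a sample
  annotation table labelling each sample ``normal`` or ``tumor``;
* a pathway edge list in the three-column functional-interaction export
  dialect (pathway name, gene A, gene B);
* a clinical table (sample_id, time_days, event).

Gene identifiers are opaque, case-sensitive strings; no aliasing is
attempted.  Missing expression values are an error, never imputed, because
imputation would silently change the edge correlations everything downstream
rests on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("ipscore")

VALID_GROUPS = ("normal", "tumor")


class ValidationError(ValueError):
    """Raised when an input file or in-memory table violates the format contract."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x samples, with a normal/tumor label per sample.

    Parameters
    ----------
    values
        DataFrame indexed by gene, columns are sample identifiers.
    sample_group
        Series mapping every sample to ``"normal"`` or ``"tumor"``.
    cohort_label
        Free-text cohort tag (e.g. a cancer-type code).
    log_transformed
        Provenance flag: negative values are permitted only when True.
    """

    values: pd.DataFrame
    sample_group: pd.Series
    cohort_label: str = ""
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.sample_group = pd.Series(self.sample_group, dtype=object)
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        missing = [s for s in cols if s not in self.sample_group.index]
        if missing:
            raise ValidationError(
                f"{len(missing)} sample(s) missing a group annotation, first: {missing[0]!r}"
            )
        bad_groups = set(self.sample_group.loc[list(cols)]) - set(VALID_GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown sample group label(s): {sorted(bad_groups)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {idx[r]!r}, sample {cols[c]!r}"
            )
        if not self.log_transformed and (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression at gene {idx[r]!r}, sample {cols[c]!r} "
                "(only allowed when log_transformed=True)"
            )

    # -- convenience views ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_group[s] == group]

    @property
    def normal_samples(self) -> list[str]:
        return self.samples_in_group("normal")

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples_in_group("tumor")


def read_expression(path: str | Path, annotation_path: str | Path,
                    cohort_label: str = "", log_transformed: bool = False) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id, header row of sample ids)
    together with its sample annotation TSV (columns ``sample_id``, ``group``).

    Samples present in the matrix but absent from the annotation are rejected.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise ValidationError(f"{path}: no genes parsed")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValidationError(f"{path}: header repeats sample id {dup!r}")
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene row {dup!r}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    blank = raw.isna()
    if blank.to_numpy().any():
        r, c = np.argwhere(blank.to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at gene {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if "sample_id" not in ann.columns or "group" not in ann.columns:
        raise ValidationError(f"{annotation_path}: need columns sample_id and group")
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{annotation_path}: duplicate sample_id {dup!r}")
    groups = ann.set_index("sample_id")["group"]
    return ExpressionMatrix(values.astype(float), groups,
                            cohort_label=cohort_label, log_transformed=log_transformed)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     annotation_path: str | Path | None = None) -> None:
    """Write the matrix (and optionally its annotation) back to TSV.

    Uses repr-faithful float formatting so a read/write round trip of finite
    decimal inputs is bit-identical.
    """
    df = matrix.values.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t")
    if annotation_path is not None:
        ann = pd.DataFrame({
            "sample_id": matrix.sample_ids,
            "group": [matrix.sample_group[s] for s in matrix.sample_ids],
        })
        ann.to_csv(annotation_path, sep="\t", index=False)


def filter_genes(matrix: ExpressionMatrix, zero_fraction_threshold: float = 0.75) -> ExpressionMatrix:
    """Drop genes whose fraction of exactly-zero values, over ALL samples of the
    cohort (normal and tumor jointly), exceeds ``zero_fraction_threshold``.

    The exclusion is strict (``> threshold``): a gene sitting exactly on the
    threshold is retained.  Gene order is preserved; the input is not modified.
    """
    if not 0 < zero_fraction_threshold <= 1:
        raise ValidationError("zero_fraction_threshold must be in (0, 1]")
    zero_frac = (matrix.values == 0).mean(axis=1)
    keep = zero_frac <= zero_fraction_threshold
    if not keep.any():
        raise ValidationError("gene filter removed every gene")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_genes: dropped %d of %d genes (zero fraction > %g)",
                    n_dropped, len(keep), zero_fraction_threshold)
    return ExpressionMatrix(matrix.values.loc[keep].copy(), matrix.sample_group,
                            cohort_label=matrix.cohort_label,
                            log_transformed=matrix.log_transformed)


# ---------------------------------------------------------------------------
# Pathway edge lists
# ---------------------------------------------------------------------------

@dataclass
class PathwayEdgeSet:
    """Named pathways as lists of undirected, deduplicated gene pairs.

    Each edge is stored as a lexicographically sorted tuple so that (A, B) and
    (B, A) collapse to one undirected pair.  ``dropped_edges`` records, per
    pathway, how many raw lines were discarded (unknown gene, self-loop, or
    duplicate) for logging.
    """

    pathways: dict[str, list[tuple[str, str]]]
    dropped_edges: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, edges in self.pathways.items():
            if not edges:
                raise ValidationError(f"pathway {name!r} has no edges")
            seen = set()
            for a, b in edges:
                if a == b:
                    raise ValidationError(f"pathway {name!r}: self-loop on {a!r}")
                key = (a, b) if a <= b else (b, a)
                if key in seen:
                    raise ValidationError(f"pathway {name!r}: duplicate edge {key}")
                seen.add(key)

    @property
    def pathway_names(self) -> list[str]:
        return list(self.pathways)

    def edge_count(self, pathway: str) -> int:
        return len(self.pathways[pathway])

    def genes(self) -> set[str]:
        return {g for edges in self.pathways.values() for e in edges for g in e}


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def read_pathways(path: str | Path, known_genes: Iterable[str]) -> PathwayEdgeSet:
    """Parse a three-column pathway edge list (pathway name, gene A, gene B).

    Edges with an endpoint outside ``known_genes`` (the post-filter gene
    universe) are dropped, as are self-loops and duplicate unordered pairs
    within a pathway.  Pathways left without edges are dropped entirely.
    """
    path = Path(path)
    known = set(known_genes)
    pathways: dict[str, list[tuple[str, str]]] = {}
    seen: dict[str, set[tuple[str, str]]] = {}
    dropped: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            name, a, b = (p.strip() for p in parts)
            dropped.setdefault(name, 0)
            if a == b or a not in known or b not in known:
                dropped[name] += 1
                continue
            key = _canon(a, b)
            bucket = seen.setdefault(name, set())
            if key in bucket:
                dropped[name] += 1
                continue
            bucket.add(key)
            pathways.setdefault(name, []).append(key)
    empty = [name for name in dropped if name not in pathways]
    for name in empty:
        logger.info("read_pathways: pathway %r dropped (no usable edges)", name)
    total_dropped = sum(dropped.values())
    if total_dropped:
        logger.info("read_pathways: dropped %d edge line(s) across %d pathway(s)",
                    total_dropped, sum(1 for v in dropped.values() if v))
    return PathwayEdgeSet(pathways, dropped_edges=dropped)


def write_pathways(edge_set: PathwayEdgeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, edges in edge_set.pathways.items():
            for a, b in edges:
                fh.write(f"{name}\t{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical frame: unique sample ids, time >= 0, event in {0, 1}."""
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValidationError(f"clinical table: duplicate sample_id {dup!r}")
    if (table["time_days"] < 0).any():
        bad = table.index[table["time_days"] < 0][0]
        raise ValidationError(f"clinical table: negative survival time for {bad!r}")
    if not table["event"].isin([0, 1]).all():
        bad = table.index[~table["event"].isin([0, 1])][0]
        raise ValidationError(f"clinical table: event outside {{0,1}} for {bad!r}")
    return table


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical TSV (columns sample_id, time_days, event).

    Rows with a missing time or event are dropped with a logged count; a
    negative time or an event outside {0, 1} is an error.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    need = {"sample_id", "time_days", "event"}
    if not need.issubset(raw.columns):
        raise ValidationError(f"{path}: need columns {sorted(need)}")
    raw["time_days"] = pd.to_numeric(raw["time_days"], errors="coerce")
    raw["event"] = pd.to_numeric(raw["event"], errors="coerce")
    complete = raw.dropna(subset=["time_days", "event"])
    n_dropped = len(raw) - len(complete)
    if n_dropped:
        logger.info("read_clinical: dropped %d row(s) with missing time/event", n_dropped)
    table = complete.set_index("sample_id")[["time_days", "event"]].copy()
    table["event"] = table["event"].astype(int) if table["event"].isin([0, 1]).all() else table["event"]
    return validate_clinical(table)


def write_clinical(table: pd.DataFrame, path: str | Path) -> None:
    out = table.reset_index()
    if out.columns[0] != "sample_id":
        out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(path, sep="\t", index=False)
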