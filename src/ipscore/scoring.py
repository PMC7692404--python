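"""The individual-level pathway score (iPS).

For one sample and one pathway with m retained edges,

    iPS = (1/m) * sum_i |PCC_{n+1,i} - PCC_{n,i}|

i.e. the mean absolute single-sample correlation perturbation over the
pathway's edges.  Tumor samples are scored against the full normal
reference.  A normal sample's own score is, by default, computed
leave-one-out: the reference is downdated to the other n-1 normals so the
sample does not deflate its own perturbation (a self-inclusive ``pooled``
mode is available behind a flag, and the choice is carried in the output
metadata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import ReferenceEdgeStats, build_reference
from .io import ExpressionMatrix, PathwayEdgeSet, ValidationError

logger = logging.getLogger("ipscore")

SCORING_MODES = ("leave_one_out", "pooled")
DEFAULT_MIN_EDGES = 3


@dataclass
class IPSMatrix:
    """Pathways x samples iPS values plus the metadata needed downstream.

    ``values`` has one row per pathway in the input edge set; pathways with
    fewer than ``min_edges`` defined edges are carried as all-NaN rows
    (explicitly unscored, never silently dropped).
    """

    values: pd.DataFrame
    m: pd.Series                    # retained (defined) edge count per pathway
    sample_group: pd.Series
    scoring_mode: str
    reference_n: int
    min_edges: int
    unscored_pathways: list[str] = field(default_factory=list)

    @property
    def pathway_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def scored_pathways(self) -> list[str]:
        return [p for p in self.values.index if p not in set(self.unscored_pathways)]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_group[s] == group]

    @property
    def normal_samples(self) -> list[str]:
        return self.samples_in_group("normal")

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples_in_group("tumor")

    def metadata(self) -> dict:
        """Sidecar metadata describing how the matrix was produced."""
        return {
            "scoring_mode": self.scoring_mode,
            "min_edges": self.min_edges,
            "reference_n": self.reference_n,
            "pathway_m": {p: int(self.m[p]) for p in self.values.index},
            "unscored_pathways": list(self.unscored_pathways),
            "sample_group": {s: self.sample_group[s] for s in self.values.columns},
        }


def _pathway_edge_indices(reference: ReferenceEdgeStats,
                          pathway_set: PathwayEdgeSet) -> dict[str, np.ndarray]:
    """Defined-edge index arrays per pathway, in reference edge numbering."""
    defined = reference.defined
    out: dict[str, np.ndarray] = {}
    for name, edges in pathway_set.pathways.items():
        idx = np.array([reference.edge_index(e) for e in edges], dtype=np.intp)
        out[name] = idx[defined[idx]]
    return out


def ips_for_sample(reference: ReferenceEdgeStats,
                   pathway_edges: list[tuple[str, str]],
                   sample, min_edges: int = 1) -> float:
    """iPS of one sample on one pathway (mean |dPCC| over its defined edges).

    Returns NaN when fewer than ``min_edges`` edges are defined in the
    reference.
    """
    idx = np.array([reference.edge_index(e) for e in pathway_edges], dtype=np.intp)
    idx = idx[reference.defined[idx]]
    if len(idx) < min_edges:
        return float("nan")
    delta = reference.delta_pcc(sample)
    return float(np.abs(delta[idx]).mean())


def ips_matrix(matrix: ExpressionMatrix, pathway_set: PathwayEdgeSet,
               scoring_mode: str = "leave_one_out",
               min_edges: int = DEFAULT_MIN_EDGES,
               reference: ReferenceEdgeStats | None = None) -> IPSMatrix:
    """Score every sample (tumor and normal) on every pathway.

    Tumor samples are scored against the full normal reference.  Normal
    samples are scored per ``scoring_mode``:

    * ``leave_one_out`` (default): the reference statistics are downdated to
      exclude the sample, so its dPCC is |PCC_n(all normals) - PCC_{n-1}|;
    * ``pooled``: the sample is scored against the full reference, itself
      included.
    """
    if scoring_mode not in SCORING_MODES:
        raise ValidationError(f"scoring_mode must be one of {SCORING_MODES}")
    all_edges = [e for edges in pathway_set.pathways.values() for e in edges]
    if reference is None:
        reference = build_reference(matrix, all_edges)
    pw_idx = _pathway_edge_indices(reference, pathway_set)
    m = pd.Series({p: len(idx) for p, idx in pw_idx.items()}, dtype=int)
    scored = [p for p in pathway_set.pathway_names if m[p] >= min_edges]
    unscored = [p for p in pathway_set.pathway_names if m[p] < min_edges]
    if unscored:
        logger.info("ips_matrix: %d pathway(s) unscored (< %d defined edges): %s",
                    len(unscored), min_edges, ", ".join(unscored[:5]))
    if not scored:
        raise ValidationError("no pathway has enough defined edges to score")

    sample_ids = matrix.sample_ids
    values = np.full((len(pathway_set.pathway_names), len(sample_ids)), np.nan)
    row_of = {p: i for i, p in enumerate(pathway_set.pathway_names)}
    gene_order = list(reference.genes)
    missing = [g for g in gene_order if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"expression matrix lacks edge gene {missing[0]!r}")
    expr = matrix.values.loc[gene_order].to_numpy(dtype=float)  # (G, S)

    normal_set = set(matrix.normal_samples)
    for j, sid in enumerate(sample_ids):
        v = expr[:, j]
        if sid in normal_set and scoring_mode == "leave_one_out":
            loo = reference.downdate(v)
            delta = reference.pcc - loo.pcc
            delta = np.where(np.isnan(loo.pcc), 0.0, delta)  # degenerate LOO edge: no evidence
        else:
            delta = reference.delta_pcc(v)
        abs_delta = np.abs(delta)
        for p in scored:
            idx = pw_idx[p]
            values[row_of[p], j] = abs_delta[idx].mean()

    df = pd.DataFrame(values, index=pathway_set.pathway_names, columns=sample_ids)
    if df.loc[scored].isna().any().any():
        raise ValidationError("internal error: missing iPS for a scored pathway")
    return IPSMatrix(values=df, m=m, sample_group=matrix.sample_group.loc[sample_ids].copy(),
                     scoring_mode=scoring_mode, reference_n=reference.n,
                     min_edges=min_edges, unscored_pathways=unscored)


def write_ips(ips: IPSMatrix, path, meta_path=None) -> None:
    """Write the iPS matrix as TSV (rows pathways, columns samples) and the
    sidecar metadata as JSON."""
    out = ips.values.copy()
    out.index.name = "pathway"
    out.to_csv(path, sep="\t")
    if meta_path is not None:
        import json
        with open(meta_path, "w") as fh:
            json.dump(ips.metadata(), fh, indent=2)


def read_ips(path, meta_path) -> IPSMatrix:
    """Reload an iPS matrix and its metadata written by :func:`write_ips`."""
    import json
    values = pd.read_csv(path, sep="\t", index_col=0)
    with open(meta_path) as fh:
        meta = json.load(fh)
    m = pd.Series(meta["pathway_m"], dtype=int)
    groups = pd.Series(meta["sample_group"], dtype=object)
    return IPSMatrix(values=values, m=m, sample_group=groups,
                     scoring_mode=meta["scoring_mode"],
                     reference_n=int(meta["reference_n"]),
                     min_edges=int(meta["min_edges"]),
                     unscored_pathways=list(meta["unscored_pathways"]))
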