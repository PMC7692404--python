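"""Reference edge correlations and single-sample correlation perturbation.

The reference network is the Pearson correlation (PCC_n) of every pathway
edge over the n normal samples of a cohort.  Adding one sample d to the
reference gives PCC_{n+1}; the difference

    dPCC = PCC_{n+1} - PCC_n

is the correlation perturbation that sample induces on the edge.  Because a
cohort has thousands of samples and a pathway collection can carry ~150k
edges, PCC_{n+1} is obtained from per-edge sufficient statistics with an
O(1) update per (edge, sample) rather than re-running Pearson from scratch.

The statistics are kept in centered form (per-gene means plus centered
second-moment sums, Welford-style), which is an equivalent sufficient set to
the raw power sums but avoids the catastrophic cancellation raw sums suffer
when the mean dominates the spread.  Equivalence to a from-scratch Pearson
computation to <= 1e-10 is enforced by property tests.

Edges whose reference variance vanishes in either gene are flagged undefined
and excluded globally (for every sample), so every sample's pathway score
averages over the same edge set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger("ipscore")

# Relative floor below which a centered second moment is treated as zero
# variance.  Rounding in the accumulation leaves residues ~ n * (eps * x)^2,
# far below this floor for any realistic value scale.
_VAR_REL_EPS = 1e-24
_VAR_ABS_EPS = 1e-300

MIN_REFERENCE_SAMPLES = 3
SMALL_REFERENCE_WARN = 20  # small normal cohorts may not be representative


def _zero_var(m2: np.ndarray, n: int, mean: np.ndarray) -> np.ndarray:
    """Mask of edges whose centered sum of squares is numerically zero."""
    return m2 <= np.maximum(_VAR_REL_EPS * n * mean * mean, _VAR_ABS_EPS)


@dataclass
class ReferenceEdgeStats:
    """Per-edge sufficient statistics over the reference (normal) samples.

    Attributes
    ----------
    genes : array of gene ids covering every edge endpoint.
    edges : list of (geneA, geneB) unordered pairs, one entry per unique edge.
    ix, iy : integer positions of each edge's endpoints in ``genes``.
    n : reference sample count.
    mean_x, mean_y : per-edge reference means of the two genes.
    mxx, myy, mxy : per-edge centered second-moment sums
        sum (x - mean_x)^2, sum (y - mean_y)^2, sum (x - mean_x)(y - mean_y).
    pcc : reference Pearson correlation per edge; NaN where undefined
        (zero variance in either gene).
    """

    genes: np.ndarray
    edges: list[tuple[str, str]]
    ix: np.ndarray
    iy: np.ndarray
    n: int
    mean_x: np.ndarray
    mean_y: np.ndarray
    mxx: np.ndarray
    myy: np.ndarray
    mxy: np.ndarray
    pcc: np.ndarray

    _gene_pos: dict[str, int] | None = None
    _edge_pos: dict[tuple[str, str], int] | None = None

    # -- lookup helpers ------------------------------------------------------
    @property
    def gene_pos(self) -> dict[str, int]:
        if self._gene_pos is None:
            self._gene_pos = {g: i for i, g in enumerate(self.genes)}
        return self._gene_pos

    @property
    def edge_pos(self) -> dict[tuple[str, str], int]:
        if self._edge_pos is None:
            self._edge_pos = {e: i for i, e in enumerate(self.edges)}
        return self._edge_pos

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of edges with a defined reference correlation."""
        return ~np.isnan(self.pcc)

    def edge_index(self, edge: tuple[str, str]) -> int:
        a, b = edge
        key = (a, b) if a <= b else (b, a)
        try:
            return self.edge_pos[key]
        except KeyError:
            raise KeyError(f"edge {edge} not in reference") from None

    def sample_vector(self, sample: Mapping[str, float] | pd.Series) -> np.ndarray:
        """Align a sample's expression to the reference gene order.

        Raises if the sample is missing any gene that appears in an edge.
        """
        if isinstance(sample, pd.Series):
            vec = sample.reindex(self.genes).to_numpy(dtype=float)
        else:
            vec = np.array([sample.get(g, np.nan) for g in self.genes], dtype=float)
        if np.isnan(vec).any():
            missing = self.genes[np.isnan(vec)][0]
            raise ValidationError(f"sample is missing expression for gene {missing!r}")
        return vec

    # -- the O(1)-per-edge update and downdate -------------------------------
    def augmented_pcc(self, sample: Mapping[str, float] | pd.Series | np.ndarray) -> np.ndarray:
        """PCC_{n+1} for every edge after adding one sample.

        Where the augmented set still has zero variance in either gene (all
        n+1 values coincide), the reference PCC_n is returned so the edge
        contributes dPCC = 0.
        """
        v = sample if isinstance(sample, np.ndarray) else self.sample_vector(sample)
        x, y = v[self.ix], v[self.iy]
        n1 = self.n + 1
        dx = x - self.mean_x
        dy = y - self.mean_y
        f = self.n / n1
        mxx = self.mxx + f * dx * dx
        myy = self.myy + f * dy * dy
        mxy = self.mxy + f * dx * dy
        mean_x1 = self.mean_x + dx / n1
        mean_y1 = self.mean_y + dy / n1
        bad = _zero_var(mxx, n1, mean_x1) | _zero_var(myy, n1, mean_y1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = mxy / np.sqrt(mxx * myy)
        r = np.clip(r, -1.0, 1.0)
        return np.where(bad, self.pcc, r)

    def delta_pcc(self, sample: Mapping[str, float] | pd.Series | np.ndarray) -> np.ndarray:
        """dPCC = PCC_{n+1} - PCC_n per edge (NaN on undefined edges)."""
        return self.augmented_pcc(sample) - self.pcc

    def downdate(self, sample: Mapping[str, float] | pd.Series | np.ndarray) -> "ReferenceEdgeStats":
        """Statistics of the reference with one of its samples removed.

        The inverse of the Welford update: used to score a normal sample
        against the other n-1 normals (leave-one-out) without rebuilding.
        """
        if self.n <= MIN_REFERENCE_SAMPLES - 1:
            raise ValidationError("cannot downdate below 2 reference samples")
        v = sample if isinstance(sample, np.ndarray) else self.sample_vector(sample)
        x, y = v[self.ix], v[self.iy]
        n0 = self.n - 1
        mean_x0 = (self.n * self.mean_x - x) / n0
        mean_y0 = (self.n * self.mean_y - y) / n0
        dx = x - mean_x0
        dy = y - mean_y0
        f = n0 / self.n
        mxx = np.maximum(self.mxx - f * dx * dx, 0.0)
        myy = np.maximum(self.myy - f * dy * dy, 0.0)
        mxy = self.mxy - f * dx * dy
        bad = _zero_var(mxx, n0, mean_x0) | _zero_var(myy, n0, mean_y0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.clip(mxy / np.sqrt(mxx * myy), -1.0, 1.0)
        r = np.where(bad, np.nan, r)
        r = np.where(np.isnan(self.pcc), np.nan, r)
        return ReferenceEdgeStats(
            genes=self.genes, edges=self.edges, ix=self.ix, iy=self.iy,
            n=n0, mean_x=mean_x0, mean_y=mean_y0,
            mxx=mxx, myy=myy, mxy=mxy, pcc=r,
        )


def build_reference(matrix: ExpressionMatrix | pd.DataFrame,
                    edges: Sequence[tuple[str, str]]) -> ReferenceEdgeStats:
    """Compute reference statistics and PCC_n for each unique edge over the
    normal samples.

    ``matrix`` is either an :class:`ExpressionMatrix` (its normal samples are
    used) or a plain genes x samples DataFrame already restricted to the
    reference cohort.  Requires at least 3 reference samples; fewer make the
    correlation undefined or degenerate.  Edges where either gene has zero
    variance across the reference are flagged undefined (``pcc`` = NaN) and
    stay excluded for every sample downstream.
    """
    if isinstance(matrix, ExpressionMatrix):
        ref = matrix.values[matrix.normal_samples]
    else:
        ref = matrix
    n = ref.shape[1]
    if n < MIN_REFERENCE_SAMPLES:
        raise ValidationError(
            f"need >= {MIN_REFERENCE_SAMPLES} reference (normal) samples, got {n}"
        )
    if n < SMALL_REFERENCE_WARN:
        logger.warning("reference has only %d normal samples; "
                       "null statistics may not be representative", n)
    # unique undirected edges, order of first appearance
    uniq: dict[tuple[str, str], int] = {}
    for a, b in edges:
        key = (a, b) if a <= b else (b, a)
        if key not in uniq:
            uniq[key] = len(uniq)
    edge_list = list(uniq)
    genes_needed = sorted({g for e in edge_list for g in e})
    missing = [g for g in genes_needed if g not in ref.index]
    if missing:
        raise ValidationError(f"edge gene {missing[0]!r} absent from expression matrix")
    genes = np.array(genes_needed, dtype=object)
    gene_pos = {g: i for i, g in enumerate(genes)}
    vals = ref.loc[list(genes)].to_numpy(dtype=float)  # (G, n)
    means = vals.mean(axis=1)
    centered = vals - means[:, None]
    ix = np.array([gene_pos[a] for a, _ in edge_list], dtype=np.intp)
    iy = np.array([gene_pos[b] for _, b in edge_list], dtype=np.intp)
    m2 = (centered * centered).sum(axis=1)  # per gene
    mxx = m2[ix]
    myy = m2[iy]
    mxy = (centered[ix] * centered[iy]).sum(axis=1)
    bad = _zero_var(mxx, n, means[ix]) | _zero_var(myy, n, means[iy])
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.clip(mxy / np.sqrt(mxx * myy), -1.0, 1.0)
    pcc = np.where(bad, np.nan, pcc)
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("build_reference: %d of %d edges undefined (zero reference variance)",
                    n_bad, len(edge_list))
    return ReferenceEdgeStats(
        genes=genes, edges=edge_list, ix=ix, iy=iy, n=n,
        mean_x=means[ix], mean_y=means[iy],
        mxx=mxx, myy=myy, mxy=mxy, pcc=pcc,
    )


# ---------------------------------------------------------------------------
# Per-edge conveniences (scalar API mirroring the vectorized methods)
# ---------------------------------------------------------------------------

def augmented_pcc(stats: ReferenceEdgeStats, sample: Mapping[str, float] | pd.Series,
                  edge: tuple[str, str]) -> float:
    """PCC_{n+1} of one edge after adding ``sample`` to the reference."""
    i = stats.edge_index(edge)
    if np.isnan(stats.pcc[i]):
        raise ValidationError(f"edge {edge} is undefined in the reference")
    a, b = stats.edges[i]
    try:
        xv, yv = float(sample[a]), float(sample[b])
    except KeyError as exc:
        raise ValidationError(f"sample is missing expression for gene {exc.args[0]!r}") from None
    v = np.zeros(len(stats.genes))
    v[stats.ix[i]] = xv
    v[stats.iy[i]] = yv
    return float(stats.augmented_pcc(v)[i])


def delta_pcc(stats: ReferenceEdgeStats, sample: Mapping[str, float] | pd.Series,
              edge: tuple[str, str]) -> float:
    """dPCC = PCC_{n+1} - PCC_n of one edge; always in [-2, 2]."""
    i = stats.edge_index(edge)
    return augmented_pcc(stats, sample, edge) - float(stats.pcc[i])


def naive_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """From-scratch Pearson correlation (oracle-friendly closed form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))
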