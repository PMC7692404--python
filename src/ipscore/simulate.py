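"""Synthetic cohorts with planted correlation perturbations and survival effects.

The generator builds everything the pipeline consumes — expression matrix,
pathway edge list, clinical table — plus a truth table naming the planted
effects, so every stage is testable end to end without external data.

Model
-----
Each pathway owns a disjoint block of genes.  A latent Gaussian field gives
every block compound-symmetric correlation rho in normal samples; expression
is the exponentiated field (log-normal), matching the nonnegativity and
right skew of normalized RNA-seq.  Exponentiation attenuates Pearson
correlation, so the truth table records the realized (post-transform)
within-block correlation of the normal samples, not the latent rho.

Tumor samples designated perturbation carriers on a perturbed pathway draw
that block either with independent genes (``decorrelate``) or with the
latent values of alternate genes negated (``sign_flip``), which flips the
correlation sign on every edge crossing the two halves of the block while
keeping the covariance valid (a full block of pairwise -rho is not positive
semi-definite for more than two genes).

Survival times are exponential with hazard
``baseline_hazard * hazard_ratio_strong ** carrier`` where carrier means the
tumor carries the perturbation on at least one survival pathway; carriers
are drawn independently per perturbed pathway.  Censoring replaces a random
``censoring_fraction`` of tumors' times with a uniform draw before their
event, independent of the covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, PathwayEdgeSet, ValidationError,
                 write_clinical, write_expression, write_pathways)

logger = logging.getLogger("ipscore")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults describe a mid-sized cohort: 50 tumor-adjacent normals and 100
    tumors, 10 disjoint 10-gene pathway blocks with latent within-block
    correlation 0.8, no planted perturbation.  ``latent_sigma`` (log-scale
    SD, default 0.5) keeps the realized log-normal correlation within a few
    hundredths of the latent rho; ``baseline_hazard`` is per day, default
    1/1000 (mean survival ~2.7 years), ``censoring_fraction`` default 0.2.
    """

    seed: int = 0
    n_normal: int = 50
    n_tumor: int = 100
    n_pathways: int = 10
    genes_per_pathway: int = 10
    rho: float = 0.8
    perturbed_pathway_ids: tuple[str, ...] = ()
    perturbation_mode: str = "decorrelate"
    fraction_tumors_perturbed: float = 0.5
    survival_pathway_ids: tuple[str, ...] = ()
    hazard_ratio_strong: float = 3.0
    baseline_hazard: float = 1e-3
    censoring_fraction: float = 0.2
    latent_sigma: float = 0.5
    log_mean: float = 2.0
    max_edges_per_pathway: int | None = None
    cohort_label: str = "SYNTH"

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_tumor, self.n_pathways, self.genes_per_pathway) <= 0:
            raise ValidationError("all cohort counts must be positive")
        if not -1 < self.rho < 1:
            raise ValidationError("rho must be in (-1, 1)")
        if self.perturbation_mode not in ("decorrelate", "sign_flip"):
            raise ValidationError("perturbation_mode must be decorrelate or sign_flip")
        if not 0 <= self.fraction_tumors_perturbed <= 1:
            raise ValidationError("fraction_tumors_perturbed must be in [0, 1]")
        if self.hazard_ratio_strong <= 0 or self.baseline_hazard <= 0:
            raise ValidationError("hazards must be positive")
        if not 0 <= self.censoring_fraction < 1:
            raise ValidationError("censoring_fraction must be in [0, 1)")
        known = set(self.pathway_names())
        for pid in tuple(self.perturbed_pathway_ids) + tuple(self.survival_pathway_ids):
            if pid not in known:
                raise ValidationError(f"unknown pathway id {pid!r}")
        if not set(self.survival_pathway_ids) <= set(self.perturbed_pathway_ids):
            raise ValidationError("survival pathways must be perturbed pathways")

    def pathway_names(self) -> list[str]:
        return [f"PW{i + 1:03d}" for i in range(self.n_pathways)]

    def gene_block(self, pathway_index: int) -> list[str]:
        g = self.genes_per_pathway
        start = pathway_index * g
        return [f"G{start + j + 1:05d}" for j in range(g)]


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    expression: ExpressionMatrix
    pathways: PathwayEdgeSet
    clinical: pd.DataFrame
    truth_samples: pd.DataFrame   # sample, pathway, is_perturbed (carriers only = True rows kept too)
    truth_pathways: pd.DataFrame  # pathway, is_perturbed, is_survival_pathway, realized_rho
    config: SimulationConfig = field(repr=False, default=None)


def _correlated_block(rng: np.random.Generator, n: int, g: int, rho: float) -> np.ndarray:
    """(n, g) latent draws with compound-symmetric correlation rho (rho >= 0)."""
    if rho < 0:
        raise ValidationError("within-block rho must be nonnegative; "
                              "negative edges come from sign_flip mode")
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, g))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort per ``config`` (single seeded RNG).

    Identical configs give identical outputs; no global random state is
    touched.
    """
    rng = np.random.default_rng(config.seed)
    g = config.genes_per_pathway
    pnames = config.pathway_names()
    n_n, n_t = config.n_normal, config.n_tumor
    normal_ids = [f"N{i + 1:04d}" for i in range(n_n)]
    tumor_ids = [f"T{i + 1:04d}" for i in range(n_t)]

    latent = np.empty((n_n + n_t, config.n_pathways * g))
    carrier: dict[str, np.ndarray] = {}
    perturbed = set(config.perturbed_pathway_ids)

    for pi, pname in enumerate(pnames):
        cols = slice(pi * g, (pi + 1) * g)
        latent[:n_n, cols] = _correlated_block(rng, n_n, g, config.rho)
        if pname in perturbed and config.fraction_tumors_perturbed > 0:
            n_carrier = int(round(config.fraction_tumors_perturbed * n_t))
            idx = rng.choice(n_t, size=n_carrier, replace=False)
            mask = np.zeros(n_t, dtype=bool)
            mask[idx] = True
        else:
            mask = np.zeros(n_t, dtype=bool)
        carrier[pname] = mask
        background = _correlated_block(rng, n_t, g, config.rho)
        if mask.any():
            if config.perturbation_mode == "decorrelate":
                replacement = rng.standard_normal((int(mask.sum()), g))
            else:  # sign_flip: negate alternate genes -> cross edges flip sign
                replacement = _correlated_block(rng, int(mask.sum()), g, config.rho)
                replacement[:, 1::2] *= -1.0
            background[mask] = replacement
        latent[n_n:, cols] = background

    values = np.exp(config.log_mean + config.latent_sigma * latent)  # log-normal, > 0
    all_ids = normal_ids + tumor_ids
    genes = [gname for pi in range(config.n_pathways) for gname in config.gene_block(pi)]
    expr = pd.DataFrame(values.T, index=genes, columns=all_ids)
    groups = pd.Series({**{s: "normal" for s in normal_ids},
                        **{s: "tumor" for s in tumor_ids}})
    matrix = ExpressionMatrix(expr, groups, cohort_label=config.cohort_label)

    # pathway edges: all within-block pairs, optionally capped
    pathways: dict[str, list[tuple[str, str]]] = {}
    for pi, pname in enumerate(pnames):
        pairs = list(combinations(config.gene_block(pi), 2))
        if config.max_edges_per_pathway is not None:
            pairs = pairs[:config.max_edges_per_pathway]
        pathways[pname] = pairs
    edge_set = PathwayEdgeSet(pathways)

    # realized within-block correlation of the emitted normal values
    realized = {}
    for pi, pname in enumerate(pnames):
        block = values[:n_n, pi * g:(pi + 1) * g]
        cc = np.corrcoef(block, rowvar=False)
        iu = np.triu_indices(g, k=1)
        realized[pname] = float(cc[iu].mean())

    # survival: hazard multiplied for carriers on any survival pathway
    surv_carrier = np.zeros(n_t, dtype=bool)
    for pname in config.survival_pathway_ids:
        surv_carrier |= carrier[pname]
    hazard = config.baseline_hazard * np.where(surv_carrier,
                                               config.hazard_ratio_strong, 1.0)
    times = rng.exponential(1.0 / hazard)
    events = np.ones(n_t, dtype=int)
    n_cens = int(np.floor(config.censoring_fraction * n_t))
    if n_cens:
        cens_idx = rng.choice(n_t, size=n_cens, replace=False)
        times[cens_idx] *= rng.uniform(0.0, 1.0, size=n_cens)
        events[cens_idx] = 0
    clinical = pd.DataFrame({"time_days": np.round(times, 3), "event": events},
                            index=pd.Index(tumor_ids, name="sample_id"))

    truth_samples = pd.DataFrame(
        [(t, pname, bool(carrier[pname][ti]))
         for pname in pnames if pname in perturbed
         for ti, t in enumerate(tumor_ids)],
        columns=["sample", "pathway", "is_perturbed"],
    )
    truth_pathways = pd.DataFrame({
        "pathway": pnames,
        "is_perturbed": [p in perturbed for p in pnames],
        "is_survival_pathway": [p in set(config.survival_pathway_ids) for p in pnames],
        "realized_rho": [realized[p] for p in pnames],
    })
    return SimulatedCohort(expression=matrix, pathways=edge_set, clinical=clinical,
                           truth_samples=truth_samples, truth_pathways=truth_pathways,
                           config=config)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort in the pipeline's external TSV formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "annotation": out / "annotation.tsv",
        "pathways": out / "pathways.tsv",
        "clinical": out / "clinical.tsv",
        "truth_samples": out / "truth_samples.tsv",
        "truth_pathways": out / "truth_pathways.tsv",
    }
    write_expression(cohort.expression, paths["expression"], paths["annotation"])
    write_pathways(cohort.pathways, paths["pathways"])
    write_clinical(cohort.clinical, paths["clinical"])
    cohort.truth_samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    cohort.truth_pathways.to_csv(paths["truth_pathways"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Canonical small fixtures
# ---------------------------------------------------------------------------

def planted_config(seed: int = 1) -> SimulationConfig:
    """The standard planted cohort: 2 of 10 pathways decorrelated in half the
    tumors, one of them with a 3x hazard for its carriers."""
    return SimulationConfig(
        seed=seed, n_normal=50, n_tumor=200, n_pathways=10, genes_per_pathway=10,
        rho=0.8, perturbed_pathway_ids=("PW001", "PW002"),
        perturbation_mode="decorrelate", fraction_tumors_perturbed=0.5,
        survival_pathway_ids=("PW001",), hazard_ratio_strong=3.0,
        censoring_fraction=0.2,
    )


def null_config(seed: int = 1, n_pathways: int = 100) -> SimulationConfig:
    """A no-perturbation cohort used for null calibration."""
    return SimulationConfig(
        seed=seed, n_normal=50, n_tumor=100, n_pathways=n_pathways,
        genes_per_pathway=6, rho=0.8,
    )


def write_fixture_suite(out_dir: str | Path, seed: int = 1) -> dict[str, Path]:
    """Emit the canonical small fixtures used across the test suite, in the
    exact external formats the readers expect.

    Produces a 3-pathway toy cohort and the planted-prognosis cohort, each in
    its own subdirectory, plus the hand-checkable two-gene reference fixture.
    Regeneration with the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    toy = simulate_cohort(SimulationConfig(
        seed=seed, n_normal=10, n_tumor=12, n_pathways=3, genes_per_pathway=4,
        rho=0.7, perturbed_pathway_ids=("PW001",), fraction_tumors_perturbed=0.5,
    ))
    for k, p in write_cohort(toy, out / "toy").items():
        written[f"toy_{k}"] = p

    planted = simulate_cohort(planted_config(seed))
    for k, p in write_cohort(planted, out / "planted").items():
        written[f"planted_{k}"] = p

    # hand-computed correlation fixture: x=(1,2,3) vs y=(1,3,2) has PCC 0.5
    hand = out / "hand_edge_expression.tsv"
    hand.write_text("gene\ts1\ts2\ts3\nGX\t1\t2\t3\nGY\t1\t3\t2\n")
    written["hand_edge_expression"] = hand
    ann = out / "hand_edge_annotation.tsv"
    ann.write_text("sample_id\tgroup\ns1\tnormal\ns2\tnormal\ns3\tnormal\n")
    written["hand_edge_annotation"] = ann
    return written
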