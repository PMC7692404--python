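"""Perturbed-strong / perturbed-weak classification and cohort summaries.

Per pathway, the normal samples' iPS values define a null with mean mu_p and
sample standard deviation sigma_p.  A tumor sample is labelled
``perturbed-strong`` on a pathway when its iPS lies more than k (default 2)
standard deviations from mu_p — strictly more: a sample sitting exactly on
the boundary is weak.  The rule is two-sided by default (distance from the
mean); a one-sided variant (iPS > mu_p + k*sigma_p) is available since iPS
is nonnegative and perturbation inflates it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError
from .scoring import IPSMatrix

logger = logging.getLogger("ipscore")

DEFAULT_K = 2.0
MIN_NORMALS_FOR_NULL = 3

LABEL_STRONG = "strong"
LABEL_WEAK = "weak"
LABEL_UNSCORED = "unscored"


def null_stats(ips: IPSMatrix) -> pd.DataFrame:
    """Per-pathway mean and sample (n-1 denominator) SD of the normal
    samples' iPS values.

    Pathways with fewer than 3 scored normal samples are left unscored (NaN
    mu/sigma).  Returns a frame indexed by pathway with columns ``mu``,
    ``sigma``, ``n_normal``.
    """
    normals = ips.normal_samples
    sub = ips.values[normals]
    n_scored = sub.notna().sum(axis=1)
    mu = sub.mean(axis=1)
    sigma = sub.std(axis=1, ddof=1)
    bad = n_scored < MIN_NORMALS_FOR_NULL
    mu[bad] = np.nan
    sigma[bad] = np.nan
    if bad.any():
        logger.info("null_stats: %d pathway(s) with < %d scored normals left unscored",
                    int(bad.sum()), MIN_NORMALS_FOR_NULL)
    return pd.DataFrame({"mu": mu, "sigma": sigma, "n_normal": n_scored})


@dataclass
class PerturbationCalls:
    """Strong/weak labels for tumor samples, pathways x tumor samples.

    ``labels`` holds ``strong`` / ``weak`` / ``unscored`` strings; ``ips``
    the underlying scores for export; ``null`` the per-pathway mu/sigma used.
    """

    labels: pd.DataFrame
    ips: pd.DataFrame
    null: pd.DataFrame
    k: float
    two_sided: bool = True

    @property
    def pathway_names(self) -> list[str]:
        return list(self.labels.index)

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.labels.columns)

    def strong_mask(self) -> pd.DataFrame:
        return self.labels == LABEL_STRONG

    def scored_mask(self) -> pd.DataFrame:
        return self.labels != LABEL_UNSCORED

    def strong_samples(self, pathway: str) -> list[str]:
        row = self.labels.loc[pathway]
        return list(row.index[row == LABEL_STRONG])

    def weak_samples(self, pathway: str) -> list[str]:
        row = self.labels.loc[pathway]
        return list(row.index[row == LABEL_WEAK])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: sample, pathway, ips, mu, sigma, label."""
        rows = []
        for p in self.labels.index:
            mu = self.null.at[p, "mu"]
            sigma = self.null.at[p, "sigma"]
            for s in self.labels.columns:
                rows.append((s, p, self.ips.at[p, s], mu, sigma, self.labels.at[p, s]))
        return pd.DataFrame(rows, columns=["sample", "pathway", "ips", "mu", "sigma", "label"])

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, k: float = DEFAULT_K,
                        two_sided: bool = True) -> "PerturbationCalls":
        labels = frame.pivot(index="pathway", columns="sample", values="label")
        ips = frame.pivot(index="pathway", columns="sample", values="ips")
        null = (frame.groupby("pathway")[["mu", "sigma"]].first())
        null["n_normal"] = np.nan
        return cls(labels=labels, ips=ips, null=null, k=k, two_sided=two_sided)


def classify(ips: IPSMatrix, null: pd.DataFrame | None = None,
             k: float = DEFAULT_K, two_sided: bool = True) -> PerturbationCalls:
    """Label every (tumor sample, pathway) pair strong or weak.

    strong  iff  |iPS - mu_p| > k * sigma_p        (two_sided, default)
    strong  iff   iPS > mu_p + k * sigma_p         (one-sided variant)

    Boundary equality resolves to weak.  Pathways without null statistics
    propagate as ``unscored``.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if null is None:
        null = null_stats(ips)
    tumors = ips.tumor_samples
    if not tumors:
        raise ValidationError("no tumor samples to classify")
    sub = ips.values[tumors]
    mu = null["mu"].reindex(sub.index)
    sigma = null["sigma"].reindex(sub.index)
    dev = sub.sub(mu, axis=0)
    if two_sided:
        dev = dev.abs()
    strong = dev.gt(sigma.mul(k), axis=0)
    scored = sub.notna() & mu.notna().to_numpy()[:, None] & sigma.notna().to_numpy()[:, None]
    labels = pd.DataFrame(LABEL_UNSCORED, index=sub.index, columns=sub.columns)
    labels = labels.mask(scored & strong, LABEL_STRONG).mask(scored & ~strong, LABEL_WEAK)
    return PerturbationCalls(labels=labels, ips=sub.copy(), null=null, k=k, two_sided=two_sided)


def fraction_strong_per_sample(calls: PerturbationCalls) -> pd.Series:
    """Percentage of scored pathways labelled strong, per tumor sample.

    Unscored pathways are excluded from the denominator; samples with zero
    scored pathways are dropped with a log line.
    """
    scored = calls.scored_mask().sum(axis=0)
    strong = calls.strong_mask().sum(axis=0)
    empty = scored == 0
    if empty.any():
        logger.info("fraction_strong_per_sample: %d sample(s) with no scored pathway dropped",
                    int(empty.sum()))
    frac = 100.0 * strong[~empty] / scored[~empty]
    frac.name = "pct_strong_pathways"
    return frac


def fraction_strong_per_pathway(calls: PerturbationCalls) -> pd.Series:
    """Percentage of scored tumor samples labelled strong, per pathway."""
    scored = calls.scored_mask().sum(axis=1)
    strong = calls.strong_mask().sum(axis=1)
    empty = scored == 0
    if empty.any():
        logger.info("fraction_strong_per_pathway: %d pathway(s) with no scored tumor dropped",
                    int(empty.sum()))
    frac = 100.0 * strong[~empty] / scored[~empty]
    frac.name = "pct_strong_tumors"
    return frac
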