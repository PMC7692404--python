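"""Two-step screen for prognosis-related pathways, plus gene connectivity.

Step 1 — differential pathways: per pathway, a two-sided Wilcoxon rank-sum
test compares the iPS values of perturbed-strong versus perturbed-weak tumor
samples; Benjamini–Hochberg FDR across all tested pathways keeps those with
q < 0.05.  (Because the two groups are themselves defined by an iPS
threshold, this stage is close to tautological; it is implemented verbatim
for fidelity and can be skipped with a flag.)

Step 2 — survival: among differential pathways, Kaplan–Meier curves and a
two-group log-rank test compare strong against weak samples.  A pathway is
prognosis-related when log-rank p < 0.005 AND the strong group has worse
prognosis, operationalized as a lower restricted mean survival time (RMST)
up to the largest observed time — RMST is well-defined under censoring where
median survival may not be.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .calls import PerturbationCalls
from .io import PathwayEdgeSet, ValidationError
from .scoring import IPSMatrix

logger = logging.getLogger("ipscore")

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_LOGRANK_THRESHOLD = 0.005
DEFAULT_MIN_GROUP = 10

DIRECTION_STRONG_WORSE = "strong_worse"
DIRECTION_STRONG_BETTER = "strong_better"
DIRECTION_INDETERMINATE = "indeterminate"

_EXACT_MAX_GROUP = 25  # exact rank-sum distribution up to this group size


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both groups have <= 25 observations and the
    pooled values are tie-free; otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(a) <= _EXACT_MAX_GROUP and len(b) <= _EXACT_MAX_GROUP:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def differential_pathways(ips: IPSMatrix, calls: PerturbationCalls,
                          min_group: int = DEFAULT_MIN_GROUP) -> pd.DataFrame:
    """Per-pathway Wilcoxon test of strong vs weak tumor iPS, with BH FDR.

    Pathways where either group has fewer than ``min_group`` tumor samples
    are excluded from testing (``tested`` = False, NaN p/q) and logged.
    Returns a frame indexed by pathway with columns n_strong, n_weak,
    wilcoxon_p, fdr_q, tested.
    """
    rows = {}
    for p in calls.pathway_names:
        strong = calls.strong_samples(p)
        weak = calls.weak_samples(p)
        rows[p] = {"n_strong": len(strong), "n_weak": len(weak),
                   "wilcoxon_p": np.nan, "fdr_q": np.nan,
                   "tested": len(strong) >= min_group and len(weak) >= min_group}
        if rows[p]["tested"]:
            sv = ips.values.loc[p, strong].to_numpy(dtype=float)
            wv = ips.values.loc[p, weak].to_numpy(dtype=float)
            rows[p]["wilcoxon_p"] = wilcoxon_rank_sum(sv, wv)
    out = pd.DataFrame.from_dict(rows, orient="index")
    tested = out.index[out["tested"]]
    skipped = len(out) - len(tested)
    if skipped:
        logger.info("differential_pathways: %d pathway(s) excluded (group < %d)",
                    skipped, min_group)
    if len(tested):
        out.loc[tested, "fdr_q"] = bh_fdr(out.loc[tested, "wilcoxon_p"].to_numpy())
    return out


def _km_fit(times: np.ndarray, events: np.ndarray, label: str) -> KaplanMeierFitter:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, label=label)
    return kmf


def _arm(calls: PerturbationCalls, clinical: pd.DataFrame, pathway: str,
         label: str) -> pd.DataFrame:
    samples = (calls.strong_samples(pathway) if label == "strong"
               else calls.weak_samples(pathway))
    present = [s for s in samples if s in clinical.index]
    return clinical.loc[present]


def survival_screen(calls: PerturbationCalls, clinical: pd.DataFrame,
                    differential: pd.DataFrame | Iterable[str] | None = None,
                    min_group: int = DEFAULT_MIN_GROUP,
                    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                    logrank_threshold: float = DEFAULT_LOGRANK_THRESHOLD,
                    skip_wilcoxon: bool = False) -> pd.DataFrame:
    """Kaplan–Meier log-rank screen of strong vs weak samples per pathway.

    ``differential`` is the output of :func:`differential_pathways` (or an
    explicit pathway collection).  Only pathways with fdr_q below
    ``fdr_threshold`` are screened unless ``skip_wilcoxon``.  Returns the
    final PrognosisResult frame: pathway-indexed with columns n_strong,
    n_weak, wilcoxon_p, fdr_q, logrank_p, direction, is_prognosis_related.
    """
    if isinstance(differential, pd.DataFrame):
        diff = differential
    else:
        diff = pd.DataFrame(index=pd.Index(list(differential) if differential is not None
                                           else calls.pathway_names))
        diff["wilcoxon_p"] = np.nan
        diff["fdr_q"] = np.nan
        diff["tested"] = True
        diff["n_strong"] = np.nan
        diff["n_weak"] = np.nan

    out = diff.copy()
    out["logrank_p"] = np.nan
    out["direction"] = DIRECTION_INDETERMINATE
    out["is_prognosis_related"] = False
    out.attrs["fdr_threshold"] = fdr_threshold
    out.attrs["logrank_threshold"] = logrank_threshold

    if skip_wilcoxon:
        screened = list(out.index)
    else:
        screened = list(out.index[(out["fdr_q"] < fdr_threshold).fillna(False)])
    for p in screened:
        strong = _arm(calls, clinical, p, "strong")
        weak = _arm(calls, clinical, p, "weak")
        if len(strong) < min_group or len(weak) < min_group:
            logger.info("survival_screen: pathway %r excluded "
                        "(<%d samples with clinical data in an arm)", p, min_group)
            continue
        res = logrank_test(strong["time_days"], weak["time_days"],
                           event_observed_A=strong["event"],
                           event_observed_B=weak["event"])
        out.at[p, "logrank_p"] = res.p_value
        horizon = float(max(strong["time_days"].max(), weak["time_days"].max()))
        kmf_s = _km_fit(strong["time_days"].to_numpy(), strong["event"].to_numpy(), "strong")
        kmf_w = _km_fit(weak["time_days"].to_numpy(), weak["event"].to_numpy(), "weak")
        rmst_s = float(restricted_mean_survival_time(kmf_s, t=horizon))
        rmst_w = float(restricted_mean_survival_time(kmf_w, t=horizon))
        if rmst_s < rmst_w:
            out.at[p, "direction"] = DIRECTION_STRONG_WORSE
        elif rmst_s > rmst_w:
            out.at[p, "direction"] = DIRECTION_STRONG_BETTER
        out.at[p, "is_prognosis_related"] = bool(
            out.at[p, "logrank_p"] < logrank_threshold
            and out.at[p, "direction"] == DIRECTION_STRONG_WORSE
            and (skip_wilcoxon or out.at[p, "fdr_q"] < fdr_threshold)
        )
    return out


def prognosis_screen(ips: IPSMatrix, calls: PerturbationCalls, clinical: pd.DataFrame,
                     min_group: int = DEFAULT_MIN_GROUP,
                     fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                     logrank_threshold: float = DEFAULT_LOGRANK_THRESHOLD,
                     skip_wilcoxon: bool = False) -> pd.DataFrame:
    """Run both screening stages and return the combined result frame."""
    diff = differential_pathways(ips, calls, min_group=min_group)
    return survival_screen(calls, clinical, diff, min_group=min_group,
                           fdr_threshold=fdr_threshold,
                           logrank_threshold=logrank_threshold,
                           skip_wilcoxon=skip_wilcoxon)


def km_curve(calls: PerturbationCalls, pathway: str,
             clinical: pd.DataFrame) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate per group for one pathway.

    Returns a long frame (group, time, survival) suitable for TSV export and
    external plotting; times include t=0 with survival 1.
    """
    frames = []
    for label in ("strong", "weak"):
        arm = _arm(calls, clinical, pathway, label)
        if arm.empty:
            raise ValidationError(f"pathway {pathway!r}: empty {label} group")
        kmf = _km_fit(arm["time_days"].to_numpy(), arm["event"].to_numpy(), label)
        sf = kmf.survival_function_
        frames.append(pd.DataFrame({
            "group": label,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        }))
    return pd.concat(frames, ignore_index=True)


def gene_degree(pathway_set: PathwayEdgeSet,
                pathway_names: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-gene incident edge counts within each named pathway.

    Returns a frame (pathway, gene, degree) sorted by descending degree
    within each pathway.  The degrees of one pathway sum to twice its edge
    count (handshake lemma).
    """
    names = list(pathway_names) if pathway_names is not None else pathway_set.pathway_names
    rows = []
    for name in names:
        if name not in pathway_set.pathways:
            raise ValidationError(f"unknown pathway {name!r}")
        deg: dict[str, int] = {}
        for a, b in pathway_set.pathways[name]:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        for g, d in sorted(deg.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append((name, g, d))
    return pd.DataFrame(rows, columns=["pathway", "gene", "degree"])
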