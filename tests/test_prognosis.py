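import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ipscore import (PathwayEdgeSet, ValidationError, bh_fdr,
                     differential_pathways, gene_degree, km_curve,
                     prognosis_screen, survival_screen, wilcoxon_rank_sum)
from ipscore.calls import LABEL_STRONG, LABEL_WEAK
from ipscore.prognosis import DIRECTION_INDETERMINATE, DIRECTION_STRONG_WORSE


def _logrank_oracle(t1, e1, t2, e2):
    """Independent two-group log-rank chi-square, straight from the
    hypergeometric-moment formula."""
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    group = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / var
    return 1 - sps.chi2.cdf(chi2, df=1)


def _calls_from_labels(label_map, ips_values=None):
    """Build a minimal PerturbationCalls from {pathway: {sample: label}}."""
    from ipscore import PerturbationCalls
    labels = pd.DataFrame(label_map).T
    ips = pd.DataFrame(ips_values).T if ips_values is not None \
        else pd.DataFrame(0.0, index=labels.index, columns=labels.columns)
    null = pd.DataFrame({"mu": 0.0, "sigma": 1.0, "n_normal": 3},
                        index=labels.index)
    return PerturbationCalls(labels=labels, ips=ips, null=null, k=2.0)


class TestWilcoxon:
    def test_exact_two_sided_p(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_matches_enumeration(self):
        # enumerate all 35 assignments of ranks 1..7 to a group of 3
        from itertools import combinations
        a, b = [1.0, 5.0, 7.0], [2.0, 3.0, 4.0, 6.0]
        obs = sum(sorted(a + b).index(v) + 1 for v in a)
        ranks = range(1, 8)
        sums = [sum(c) for c in combinations(ranks, 3)]
        mean = np.mean(sums)
        p_enum = np.mean([abs(s - mean) >= abs(obs - mean) for s in sums])
        assert wilcoxon_rank_sum(a, b) == pytest.approx(p_enum)


class TestBhFdr:
    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(q, [0.04, 0.04, 0.05, 0.05])

    def test_monotone_and_permutation_stable(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=20)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = rng.permutation(20)
        assert np.allclose(bh_fdr(p[perm]), q[perm])


class TestDifferentialPathways:
    def test_small_group_excluded(self, planted):
        _, ips, calls = planted
        diff = differential_pathways(ips, calls, min_group=10)
        small = diff.index[(diff["n_strong"] < 10) | (diff["n_weak"] < 10)]
        assert (~diff.loc[small, "tested"]).all()
        assert diff.loc[small, "wilcoxon_p"].isna().all()

    def test_perturbed_pathways_significant(self, planted):
        _, ips, calls = planted
        diff = differential_pathways(ips, calls)
        assert diff.at["PW001", "fdr_q"] < 0.05
        assert diff.at["PW002", "fdr_q"] < 0.05


class TestSurvivalScreen:
    def test_separated_arms_strong_worse_and_oracle_p(self):
        labels = {"P": {f"s{i}": LABEL_STRONG if i < 3 else LABEL_WEAK
                        for i in range(6)}}
        calls = _calls_from_labels(labels)
        clinical = pd.DataFrame(
            {"time_days": [10, 20, 30, 100, 200, 300], "event": [1] * 6},
            index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"))
        res = survival_screen(calls, clinical, ["P"], min_group=3,
                              skip_wilcoxon=True)
        assert res.at["P", "direction"] == DIRECTION_STRONG_WORSE
        oracle = _logrank_oracle(np.array([10, 20, 30]), np.ones(3),
                                 np.array([100, 200, 300]), np.ones(3))
        assert res.at["P", "logrank_p"] == pytest.approx(oracle, abs=1e-6)

    def test_identical_arms_indeterminate(self):
        labels = {"P": {f"s{i}": LABEL_STRONG if i < 3 else LABEL_WEAK
                        for i in range(6)}}
        calls = _calls_from_labels(labels)
        clinical = pd.DataFrame(
            {"time_days": [50, 60, 70, 50, 60, 70], "event": [1] * 6},
            index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"))
        res = survival_screen(calls, clinical, ["P"], min_group=3,
                              skip_wilcoxon=True)
        assert res.at["P", "logrank_p"] == pytest.approx(1.0)
        assert res.at["P", "direction"] == DIRECTION_INDETERMINATE
        assert not res.at["P", "is_prognosis_related"]

    def test_never_flags_strong_better(self):
        labels = {"P": {f"s{i}": LABEL_STRONG if i < 3 else LABEL_WEAK
                        for i in range(6)}}
        calls = _calls_from_labels(labels)
        clinical = pd.DataFrame(
            {"time_days": [100, 200, 300, 10, 20, 30], "event": [1] * 6},
            index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"))
        res = survival_screen(calls, clinical, ["P"], min_group=3,
                              skip_wilcoxon=True)
        assert not res.at["P", "is_prognosis_related"]

    def test_planted_cohort_flags_only_survival_pathway(self, planted):
        cohort, ips, calls = planted
        res = prognosis_screen(ips, calls, cohort.clinical)
        assert list(res.index[res["is_prognosis_related"]]) == ["PW001"]


class TestKmCurve:
    def test_product_limit_by_hand(self):
        labels = {"P": {"a": LABEL_STRONG, "b": LABEL_STRONG, "c": LABEL_STRONG,
                        "d": LABEL_WEAK}}
        calls = _calls_from_labels(labels)
        clinical = pd.DataFrame({"time_days": [1, 2, 3, 5], "event": [1, 1, 0, 1]},
                                index=pd.Index(["a", "b", "c", "d"], name="sample_id"))
        curve = km_curve(calls, "P", clinical)
        strong = curve[curve["group"] == "strong"].set_index("time")["survival"]
        assert strong[0.0] == pytest.approx(1.0)
        assert strong[1.0] == pytest.approx(2 / 3)
        assert strong[2.0] == pytest.approx(1 / 3)
        assert strong[3.0] == pytest.approx(1 / 3)

    def test_no_events_flat_curve(self):
        labels = {"P": {"a": LABEL_STRONG, "b": LABEL_STRONG, "c": LABEL_WEAK}}
        calls = _calls_from_labels(labels)
        clinical = pd.DataFrame({"time_days": [5, 8, 3], "event": [0, 0, 1]},
                                index=pd.Index(["a", "b", "c"], name="sample_id"))
        curve = km_curve(calls, "P", clinical)
        strong = curve[curve["group"] == "strong"]
        assert (strong["survival"] == 1.0).all()

    def test_single_step_when_all_events_coincide(self):
        labels = {"P": {"a": LABEL_STRONG, "b": LABEL_STRONG, "c": LABEL_WEAK}}
        calls = _calls_from_labels(labels)
        clinical = pd.DataFrame({"time_days": [4, 4, 9], "event": [1, 1, 1]},
                                index=pd.Index(["a", "b", "c"], name="sample_id"))
        curve = km_curve(calls, "P", clinical)
        strong = curve[curve["group"] == "strong"].set_index("time")["survival"]
        assert strong[4.0] == pytest.approx(0.0)
        assert len(strong) == 2  # t=0 and the single step

    def test_empty_group_is_error(self):
        labels = {"P": {"a": LABEL_STRONG, "b": LABEL_STRONG}}
        calls = _calls_from_labels(labels)
        clinical = pd.DataFrame({"time_days": [4, 9], "event": [1, 1]},
                                index=pd.Index(["a", "b"], name="sample_id"))
        with pytest.raises(ValidationError, match="weak"):
            km_curve(calls, "P", clinical)


class TestGeneDegree:
    def test_triangle(self):
        es = PathwayEdgeSet({"P": [("A", "B"), ("A", "C"), ("B", "C")]})
        table = gene_degree(es, ["P"])
        assert dict(zip(table["gene"], table["degree"])) == {"A": 2, "B": 2, "C": 2}

    def test_star(self):
        es = PathwayEdgeSet({"P": [("A", "B"), ("A", "C"), ("A", "D")]})
        table = gene_degree(es, ["P"])
        assert table.iloc[0]["gene"] == "A" and table.iloc[0]["degree"] == 3

    def test_handshake_lemma_random(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(12)]
        from itertools import combinations
        pairs = list(combinations(genes, 2))
        idx = rng.choice(len(pairs), size=20, replace=False)
        es = PathwayEdgeSet({"P": [pairs[i] for i in idx]})
        table = gene_degree(es)
        assert table["degree"].sum() == 2 * 20

    def test_unknown_pathway_is_error(self):
        es = PathwayEdgeSet({"P": [("A", "B")]})
        with pytest.raises(ValidationError, match="nope"):
            gene_degree(es, ["nope"])
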