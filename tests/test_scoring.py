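import numpy as np
import pandas as pd
import pytest

from ipscore import (ExpressionMatrix, PathwayEdgeSet, ValidationError,
                     build_reference, ips_for_sample, ips_matrix, naive_pearson,
                     read_ips, write_ips)


def _two_edge_setup():
    """Pathway of two edges: A-B carries |dPCC| = 1.2 for the crafted tumor
    (reference x=y=(1,2,3), tumor adds (4,0)); C-D stays perfectly correlated
    (colinear added point, dPCC = 0)."""
    values = pd.DataFrame(
        {"n1": [1.0, 1.0, 1.0, 2.0], "n2": [2.0, 2.0, 2.0, 4.0],
         "n3": [3.0, 3.0, 3.0, 6.0], "t1": [4.0, 0.0, 4.0, 8.0]},
        index=["A", "B", "C", "D"])
    groups = pd.Series({"n1": "normal", "n2": "normal", "n3": "normal", "t1": "tumor"})
    matrix = ExpressionMatrix(values, groups)
    edges = PathwayEdgeSet({"P": [("A", "B"), ("C", "D")]})
    return matrix, edges


class TestIpsForSample:
    def test_two_edge_mean(self):
        matrix, edges = _two_edge_setup()
        ref = build_reference(matrix, edges.pathways["P"])
        sample = matrix.values["t1"]
        ips = ips_for_sample(ref, edges.pathways["P"], ref.sample_vector(sample))
        assert ips == pytest.approx(0.6, abs=1e-10)

    def test_unperturbed_pathway_scores_zero(self):
        matrix, edges = _two_edge_setup()
        ref = build_reference(matrix, edges.pathways["P"])
        colinear = pd.Series({"A": 4.0, "B": 4.0, "C": 4.0, "D": 8.0})
        ips = ips_for_sample(ref, [("C", "D")], ref.sample_vector(colinear))
        assert ips == pytest.approx(0.0, abs=1e-10)

    def test_single_edge_pathway_is_abs_delta(self):
        matrix, edges = _two_edge_setup()
        ref = build_reference(matrix, edges.pathways["P"])
        sample = ref.sample_vector(matrix.values["t1"])
        ips = ips_for_sample(ref, [("A", "B")], sample, min_edges=1)
        assert ips == pytest.approx(1.2, abs=1e-10)

    def test_below_min_edges_gives_nan(self):
        matrix, edges = _two_edge_setup()
        ref = build_reference(matrix, edges.pathways["P"])
        sample = ref.sample_vector(matrix.values["t1"])
        assert np.isnan(ips_for_sample(ref, [("A", "B")], sample, min_edges=2))


class TestIpsMatrix:
    def test_shape_and_bounds(self, planted):
        cohort, ips, _ = planted
        n_pathways = len(cohort.pathways.pathway_names)
        n_samples = len(cohort.expression.sample_ids)
        assert ips.values.shape == (n_pathways, n_samples)
        vals = ips.values.to_numpy()
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 2.0

    def test_invariant_to_edge_ordering(self):
        matrix, _ = _two_edge_setup()
        fwd = PathwayEdgeSet({"P": [("A", "B"), ("C", "D")]})
        rev = PathwayEdgeSet({"P": [("C", "D"), ("A", "B")]})
        a = ips_matrix(matrix, fwd, min_edges=2, scoring_mode="pooled")
        b = ips_matrix(matrix, rev, min_edges=2, scoring_mode="pooled")
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_leave_one_out_matches_rebuild(self):
        rng = np.random.default_rng(21)
        n = 12
        values = pd.DataFrame(rng.lognormal(size=(4, n + 2)),
                              index=["A", "B", "C", "D"],
                              columns=[f"n{i}" for i in range(n)] + ["t0", "t1"])
        groups = pd.Series({c: ("normal" if c.startswith("n") else "tumor")
                            for c in values.columns})
        matrix = ExpressionMatrix(values, groups)
        edges = PathwayEdgeSet({"P": [("A", "B"), ("C", "D"), ("A", "C")]})
        ref = build_reference(matrix, edges.pathways["P"])
        for j in range(n):
            held = f"n{j}"
            loo = ref.downdate(ref.sample_vector(matrix.values[held]))
            others = [c for c in values.columns[:n] if c != held]
            for e, (ga, gb) in enumerate(edges.pathways["P"]):
                rebuilt = naive_pearson(values.loc[ga, others].to_numpy(),
                                        values.loc[gb, others].to_numpy())
                assert abs(loo.pcc[ref.edge_index((ga, gb))] - rebuilt) <= 1e-10

    def test_pooled_and_loo_differ_only_on_normals(self):
        rng = np.random.default_rng(8)
        cols = [f"n{i}" for i in range(6)] + ["t1"]
        values = pd.DataFrame(rng.lognormal(size=(4, 7)),
                              index=["A", "B", "C", "D"], columns=cols)
        groups = pd.Series({c: ("normal" if c.startswith("n") else "tumor")
                            for c in cols})
        matrix = ExpressionMatrix(values, groups)
        edges = PathwayEdgeSet({"P": [("A", "B"), ("C", "D")]})
        loo = ips_matrix(matrix, edges, scoring_mode="leave_one_out", min_edges=2)
        pooled = ips_matrix(matrix, edges, scoring_mode="pooled", min_edges=2)
        assert np.allclose(loo.values["t1"], pooled.values["t1"])
        normals = [c for c in cols if c.startswith("n")]
        assert not np.allclose(loo.values[normals], pooled.values[normals])

    def test_unscored_pathway_kept_as_nan_row(self):
        matrix, _ = _two_edge_setup()
        edges = PathwayEdgeSet({"P": [("A", "B"), ("C", "D")],
                                "Q": [("A", "C")]})
        ips = ips_matrix(matrix, edges, min_edges=2)
        assert "Q" in ips.values.index
        assert ips.values.loc["Q"].isna().all()
        assert ips.unscored_pathways == ["Q"]

    def test_tumor_ips_elevated_on_perturbed_pathway(self, planted):
        cohort, ips, _ = planted
        for p in ("PW001", "PW002"):
            med_t = ips.values.loc[p, ips.tumor_samples].median()
            med_n = ips.values.loc[p, ips.normal_samples].median()
            assert med_t > med_n

    def test_round_trip_through_tsv(self, tmp_path):
        matrix, edges = _two_edge_setup()
        ips = ips_matrix(matrix, edges, min_edges=2)
        write_ips(ips, tmp_path / "ips.tsv", tmp_path / "meta.json")
        back = read_ips(tmp_path / "ips.tsv", tmp_path / "meta.json")
        assert np.allclose(back.values.to_numpy(), ips.values.to_numpy())
        assert back.scoring_mode == ips.scoring_mode
        assert back.reference_n == ips.reference_n
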