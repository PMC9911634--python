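import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from ithsig import (
    ExpressionMatrix,
    ValidationError,
    marker_score,
    nmf_factorize,
    select_immune_factor,
    top_loading_genes,
)
from ithsig.nmf import NMFResult


def _expr(values, prefix="G"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"S{j}" for j in range(values.shape[1])],
        )
    )


class TestFactorize:
    def test_exact_rank2_matrix_reconstructed(self):
        rng = np.random.default_rng(42)
        W0, H0 = rng.uniform(size=(50, 2)), rng.uniform(size=(2, 20))
        V = W0 @ H0  # oracle: the construction itself
        expr = _expr(V)
        res = nmf_factorize(expr, k=2, restarts=3, max_iter=2000, tol=1e-9, seed=0)
        rel = np.linalg.norm(V - res.W.to_numpy() @ res.H.to_numpy()) / np.linalg.norm(V)
        assert rel < 0.02

    def test_loss_trajectory_non_increasing(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.uniform(0, 5, size=(30, 12)))
        res = nmf_factorize(expr, k=3, restarts=2, max_iter=150, seed=3)
        traj = np.array(res.loss_trajectory)
        assert np.all(np.diff(traj) <= 1e-9)

    def test_factors_nonnegative(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.uniform(0, 5, size=(25, 10)))
        res = nmf_factorize(expr, k=3, restarts=2, max_iter=100, seed=5)
        assert (res.W.to_numpy() >= 0).all() and (res.H.to_numpy() >= 0).all()

    def test_seed_determinism_bitwise(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.uniform(0, 5, size=(20, 8)))
        r1 = nmf_factorize(expr, k=2, restarts=3, max_iter=80, seed=9)
        r2 = nmf_factorize(expr, k=2, restarts=3, max_iter=80, seed=9)
        assert r1.W.equals(r2.W) and r1.H.equals(r2.H)
        r3 = nmf_factorize(expr, k=2, restarts=3, max_iter=80, seed=10)
        assert not r1.W.equals(r3.W)

    def test_agrees_with_sklearn_objective(self):
        # independent optimizer as cross-check: final losses should land close
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(4)
        V = rng.uniform(0, 5, size=(40, 15))
        res = nmf_factorize(_expr(V), k=3, restarts=3, max_iter=2000, tol=1e-8, seed=0)
        ours = res.loss_trajectory[-1]
        m = sklearn.NMF(3, init="nndsvda", max_iter=2000, tol=1e-8, random_state=0).fit(V)
        theirs = np.linalg.norm(V - m.transform(V) @ m.components_)
        assert ours <= theirs * 1.05

    def test_input_validation(self):
        expr = _expr(np.ones((5, 4)))
        with pytest.raises(ValidationError, match="k"):
            nmf_factorize(expr, k=4)
        neg = ExpressionMatrix(
            pd.DataFrame([[-1.0, 1.0]], index=["G0"], columns=["S0", "S1"]),
            allow_negative=True,
        )
        with pytest.raises(ValidationError, match="non-negative"):
            nmf_factorize(neg, k=1)

    def test_column_permutation_equivariance_with_matched_init(self):
        # multiplicative updates commute with sample permutation: permuting V's
        # columns together with the H init permutes H identically, W unchanged
        from ithsig.nmf import _mu_nmf

        rng = np.random.default_rng(6)
        V = rng.uniform(0, 5, size=(20, 10))
        W0 = rng.uniform(0, 1, size=(20, 2))
        H0 = rng.uniform(0, 1, size=(2, 10))
        perm = np.random.default_rng(7).permutation(10)
        W, H, _ = _mu_nmf(V, 2, rng, 100, 0.0, init=(W0, H0))
        Wp, Hp, _ = _mu_nmf(V[:, perm], 2, rng, 100, 0.0, init=(W0, H0[:, perm]))
        assert np.allclose(W, Wp, atol=1e-12)
        assert np.allclose(H[:, perm], Hp, atol=1e-12)


class TestMarkerScore:
    def test_single_marker_equals_its_zscore(self, toy_expr):
        s = marker_score(toy_expr, ["M2"])
        x = toy_expr.data.loc["M2"]
        expected = (x - x.mean()) / x.std(ddof=0)
        assert np.allclose(s.to_numpy(), expected.to_numpy())

    def test_identical_markers_collapse_to_common_zscore(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]],
            index=["A", "B"], columns=["S1", "S2", "S3"],
        )
        s = marker_score(ExpressionMatrix(df), ["A", "B"])
        z = (df.loc["A"] - 2.0) / df.loc["A"].std(ddof=0)
        assert np.allclose(s.to_numpy(), z.to_numpy())

    def test_three_marker_hand_oracle(self):
        # hand arithmetic (population sd):
        # M1=[1,2,3,4]: z = +-(1.5, 0.5)/1.1180339887
        # M2=[2,2,4,4]: z = [-1,-1,1,1];  M3=[0,4,0,4]: z = [-1,1,-1,1]
        df = pd.DataFrame(
            {
                "S1": [1.0, 2.0, 0.0],
                "S2": [2.0, 2.0, 4.0],
                "S3": [3.0, 4.0, 0.0],
                "S4": [4.0, 4.0, 4.0],
            },
            index=["M1", "M2", "M3"],
        )
        s = marker_score(ExpressionMatrix(df), ["M1", "M2", "M3"])
        expected = [-1.1138802622, -0.1490711985, 0.1490711985, 1.1138802622]
        assert np.allclose(s.to_numpy(), expected, atol=1e-9)

    def test_flat_marker_skipped_and_all_absent_rejected(self, toy_expr, caplog):
        with caplog.at_level("WARNING", logger="ithsig"):
            s = marker_score(toy_expr, ["M1", "FLAT"])
        x = toy_expr.data.loc["M1"]
        assert np.allclose(
            s.to_numpy(), ((x - x.mean()) / x.std(ddof=0)).to_numpy()
        )
        with pytest.raises(ValidationError):
            marker_score(toy_expr, ["NOPE"])


class TestImmuneFactorSelection:
    def _result(self, H):
        H = np.asarray(H, dtype=float)
        k, S = H.shape
        return NMFResult(
            W=pd.DataFrame(np.ones((3, k)), index=["G0", "G1", "G2"],
                           columns=[f"factor_{i}" for i in range(k)]),
            H=pd.DataFrame(H, index=[f"factor_{i}" for i in range(k)],
                           columns=[f"S{j}" for j in range(S)]),
            loss=(1.0,), chosen_restart=0, loss_trajectory=(1.0,),
            rank=k, seed=0,
        )

    def test_exact_match_row_selected(self):
        score = pd.Series([0.1, 0.5, 0.9, 0.2], index=[f"S{j}" for j in range(4)])
        H = [[1, 1, 1, 1.1], [0.3, 0.2, 0.1, 0.05], [0.1, 0.5, 0.9, 0.2]]
        sel = select_immune_factor(self._result(H), score)
        assert sel.factor_index == 2
        assert sel.correlation_per_factor[2] == pytest.approx(1.0)

    def test_zero_variance_row_never_selected(self):
        score = pd.Series([1.0, 2.0, 3.0], index=["S0", "S1", "S2"])
        H = [[5, 5, 5], [1, 2, 2.5]]
        sel = select_immune_factor(self._result(H), score)
        assert sel.factor_index == 1
        assert sel.correlation_per_factor[0] == -np.inf

    def test_recovers_planted_immune_program(self, mild_cohort):
        expr, annot, truth = mild_cohort
        res = nmf_factorize(expr, k=6, restarts=5, seed=11)
        markers = truth.genes_in_category("clonal_immune")[:10]
        sel = select_immune_factor(res, marker_score(expr, markers))
        h = res.H.iloc[sel.factor_index]
        # patient-level factor weight tracks the planted immune level
        pat = annot.data.set_index("sample_id")["patient_id"]
        h_pat = h.groupby(pat).mean().reindex(truth.patient_theta.index)
        r = st.pearsonr(h_pat.to_numpy(), truth.patient_theta.to_numpy())[0]
        assert r >= 0.7


class TestTopLoadingGenes:
    def test_full_request_returns_all(self, mild_cohort):
        expr, _, _ = mild_cohort
        res = nmf_factorize(
            ExpressionMatrix(expr.data.iloc[:50]), k=2, restarts=1, max_iter=50, seed=0
        )
        assert len(top_loading_genes(res, 0, 50)) == 50

    def test_dominant_gene_selected(self):
        W = pd.DataFrame(
            {"factor_0": [0.0, 10.0, 0.0]}, index=["GA", "GB", "GC"]
        )
        res = NMFResult(
            W=W, H=pd.DataFrame(np.ones((1, 2)), index=["factor_0"],
                                columns=["S0", "S1"]),
            loss=(1.0,), chosen_restart=0, loss_trajectory=(1.0,), rank=1, seed=0,
        )
        assert top_loading_genes(res, 0, 1).genes == ("GB",)

    def test_immune_gene_recall_on_simulation(self, mild_cohort):
        expr, _, truth = mild_cohort
        res = nmf_factorize(expr, k=6, restarts=5, seed=11)
        markers = truth.genes_in_category("clonal_immune")[:10]
        sel = select_immune_factor(res, marker_score(expr, markers))
        n_immune = 120  # planted clonal + subclonal immune genes
        top = top_loading_genes(res, sel.factor_index, n_immune)
        immune = set(truth.genes_in_category("clonal_immune")) | set(
            truth.genes_in_category("subclonal_immune")
        )
        recall = sum(1 for g in top.genes if g in immune) / n_immune
        assert recall >= 0.7
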