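"""Fragment scores, NNLS gene scores, gene pairs and the clone calculator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dubseq.counting import CountMatrix
from dubseq.io import ConfigurationError
from dubseq.library import ReferenceFragment
from dubseq.scoring import (
    CoverageMatrix,
    build_coverage_matrix,
    compute_fragment_scores,
    compute_gene_pair_scores,
    compute_gene_scores_mean,
    compute_gene_scores_nnls,
    estimate_clone_requirement,
    select_valid_barcodes,
)

from helpers import nnls_grid


def _matrix(count_dict, samples):
    frame = pd.DataFrame(count_dict, columns=samples).fillna(0).astype(int)
    totals = frame.sum(axis=0)
    return CountMatrix(frame, totals, totals.copy(), pd.Series(0, index=samples))


def _design(samples, t0_flags):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "set_id": ["set1"] * len(samples),
            "condition": ["T0" if f else "cond" for f in t0_flags],
            "is_time_zero": t0_flags,
            "replicate_group": ["g"] * len(samples),
        }
    )


def _scores(f_by_barcode, s=100, t=100):
    barcodes = list(f_by_barcode)
    return pd.DataFrame(
        {
            "s": [s] * len(barcodes),
            "t": [t] * len(barcodes),
            "f_raw": list(f_by_barcode.values()),
            "f": list(f_by_barcode.values()),
        },
        index=pd.Index(barcodes, name="barcode"),
    )


def _coverage(rows, genes):
    return CoverageMatrix(
        np.array(rows, dtype=np.int8), [f"F{i}" for i in range(len(rows))], genes
    )


class TestValidBarcodes:
    def test_threshold_10(self):
        m = _matrix({"T0_1": {"b1": 12, "b2": 3}}, ["T0_1"])
        d = _design(["T0_1"], [True])
        assert select_valid_barcodes(m, d, "set1") == {"b1"}

    def test_any_time_zero_sample_qualifies(self):
        m = _matrix({"T0_1": {"b2": 3}, "T0_2": {"b2": 10}}, ["T0_1", "T0_2"])
        d = _design(["T0_1", "T0_2"], [True, True])
        assert select_valid_barcodes(m, d, "set1") == {"b2"}

    def test_all_zero_counts(self):
        m = _matrix({"T0_1": {"b1": 0}}, ["T0_1"])
        d = _design(["T0_1"], [True])
        assert select_valid_barcodes(m, d, "set1") == set()

    def test_no_time_zero_sample_errors(self):
        m = _matrix({"s": {"b1": 5}}, ["s"])
        with pytest.raises(ConfigurationError):
            _design(["s"], [False]).pipe(
                lambda d: select_valid_barcodes(m, d, "set1")
            )


class TestFragmentScores:
    def _setup(self, counts):
        samples = ["T0_1", "T0_2", "cond"]
        m = _matrix(counts, samples)
        d = _design(samples, [True, True, False])
        return compute_fragment_scores(m, d, "cond")

    def test_equal_counts_give_zero_raw(self):
        out = self._setup({"T0_1": {"b": 15}, "T0_2": {"b": 0}, "cond": {"b": 15}})
        assert out.at["b", "f_raw"] == 0.0

    def test_closed_form_log_ratio(self):
        out = self._setup({"T0_1": {"b": 15}, "T0_2": {"b": 0}, "cond": {"b": 63}})
        assert out.at["b", "f_raw"] == pytest.approx(2.0)

    def test_t_is_summed_over_time_zero_samples(self):
        out = self._setup({"T0_1": {"b": 10}, "T0_2": {"b": 20}, "cond": {"b": 50}})
        assert out.at["b", "t"] == 30

    def test_invalid_barcodes_excluded(self):
        out = self._setup(
            {"T0_1": {"b": 15, "weak": 4}, "T0_2": {"b": 0, "weak": 3},
             "cond": {"b": 15, "weak": 100}}
        )
        assert "weak" not in out.index

    def test_median_centering(self):
        counts = {
            "T0_1": {f"b{i}": 50 for i in range(9)},
            "T0_2": {f"b{i}": 0 for i in range(9)},
            "cond": {f"b{i}": 10 * (i + 1) for i in range(9)},
        }
        out = self._setup(counts)
        assert abs(np.median(out["f"])) < 1e-12


class TestCoverage:
    GENES = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "contig": ["chr"] * 3,
            "start": [10, 90, 0],
            "end": [20, 110, 100],
        }
    )

    def test_containment_rules(self):
        frag = ReferenceFragment("U", "D", "chr", 0, 100)
        cov = build_coverage_matrix([frag], self.GENES)
        # inside; partial overlap; exactly equal
        assert cov.matrix.tolist() == [[1, 0, 1]]

    def test_out_of_bounds_gene_errors(self):
        frag = ReferenceFragment("U", "D", "chr", 0, 100)
        with pytest.raises(ValueError, match="bounds"):
            build_coverage_matrix([frag], self.GENES, {"chr": 105})


class TestMeanScores:
    def test_simple_means(self):
        cov = _coverage([[1], [1], [1]], ["g1"])
        out = compute_gene_scores_mean(_scores({"F0": 2, "F1": 2, "F2": 2}), cov)
        assert out["g1"] == pytest.approx(2.0)
        cov2 = _coverage([[1], [1]], ["g1"])
        out2 = compute_gene_scores_mean(_scores({"F0": 3, "F1": 0}), cov2)
        assert out2["g1"] == pytest.approx(1.5)

    def test_uncovered_gene_missing(self):
        cov = _coverage([[1, 0]], ["g1", "g2"])
        out = compute_gene_scores_mean(_scores({"F0": 2}), cov)
        assert "g2" not in out.index


class TestNnlsScores:
    def test_single_gene(self):
        cov = _coverage([[1], [1], [1]], ["g1"])
        out = compute_gene_scores_nnls(_scores({"F0": 2, "F1": 2, "F2": 2}), cov)
        assert out.at["g1", "score"] == pytest.approx(2.0)

    def test_causative_neighbor_pattern(self):
        # one causative gene drags a neutral neighbour's mean up; the
        # regression assigns the effect to the right gene
        cov = _coverage([[1, 0], [1, 1], [0, 1]], ["g1", "g2"])
        scores = _scores({"F0": 3, "F1": 3, "F2": 0})
        out = compute_gene_scores_nnls(scores, cov)
        assert out.at["g1", "score"] == pytest.approx(3.0, abs=1e-8)
        assert out.at["g2", "score"] == pytest.approx(0.0, abs=1e-8)
        assert out.at["g2", "score_mean"] == pytest.approx(1.5)
        grid = nnls_grid(cov.matrix, scores["f"].to_numpy())
        assert np.allclose(grid, [3.0, 0.0], atol=0.02)

    def test_all_nonpositive_scores_zero_positive_pass(self):
        cov = _coverage([[1, 0], [0, 1]], ["g1", "g2"])
        out = compute_gene_scores_nnls(_scores({"F0": -1, "F1": -2}), cov)
        assert (out["score_pos"] == 0).all()
        assert out.at["g2", "score"] == pytest.approx(-2.0)

    def test_signed_decomposition_invariants(self):
        cov = _coverage([[1, 1], [1, 0], [0, 1]], ["g1", "g2"])
        out = compute_gene_scores_nnls(_scores({"F0": 1.5, "F1": 2.0, "F2": -1.0}), cov)
        assert (out["score_pos"] >= 0).all() and (out["score_neg"] >= 0).all()
        assert np.allclose(out["score"], out["score_pos"] - out["score_neg"])

    def test_objective_no_worse_than_zero(self):
        rng = np.random.default_rng(5)
        A = (rng.random((8, 4)) < 0.5).astype(np.int8)
        A[:, A.sum(axis=0) == 0] = 1
        f = rng.normal(0, 2, size=8)
        cov = CoverageMatrix(A, [f"F{i}" for i in range(8)], list("abcd"))
        out = compute_gene_scores_nnls(_scores(dict(zip(cov.fragment_barcodes, f))), cov)
        resid = A @ out["score_pos"].to_numpy() - f
        assert resid @ resid <= f @ f + 1e-9

    def test_empty_input_gives_empty_result(self):
        cov = _coverage([[1]], ["g1"])
        out = compute_gene_scores_nnls(_scores({}), cov)
        assert out.empty

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_frag = int(rng.integers(2, 9))
        n_gene = int(rng.integers(1, 5))
        A = (rng.random((n_frag, n_gene)) < 0.6).astype(np.int8)
        for j in range(n_gene):  # ensure every gene is covered
            if A[:, j].sum() == 0:
                A[int(rng.integers(0, n_frag)), j] = 1
        f = np.round(rng.normal(0, 1.5, size=n_frag), 2)
        cov = CoverageMatrix(A, [f"F{i}" for i in range(n_frag)], [f"g{j}" for j in range(n_gene)])
        out = compute_gene_scores_nnls(_scores(dict(zip(cov.fragment_barcodes, f))), cov)
        pos = out["score_pos"].to_numpy()
        grid_pos = nnls_grid(A, f)
        # the optimum need not be unique (duplicated columns); the fitted
        # values and the objective are, so compare those
        obj = float(np.sum((A @ pos - f) ** 2))
        grid_obj = float(np.sum((A @ grid_pos - f) ** 2))
        assert obj <= grid_obj + 1e-6
        assert np.allclose(A @ pos, A @ grid_pos, atol=0.02)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equals_ols_when_unconstrained_solution_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        A = (rng.random((10, 3)) < 0.6).astype(float)
        A[:, A.sum(axis=0) == 0] = 1
        g_true = rng.uniform(1, 3, size=3)
        f = A @ g_true
        ols, *_ = np.linalg.lstsq(A, f, rcond=None)
        if (ols < 0).any():
            return
        cov = CoverageMatrix(A.astype(np.int8), [f"F{i}" for i in range(10)], list("abc"))
        out = compute_gene_scores_nnls(_scores(dict(zip(cov.fragment_barcodes, f))), cov)
        assert np.allclose(out["score_pos"].to_numpy(), ols, atol=1e-6)


class TestGenePairs:
    GENES = pd.DataFrame(
        {
            "gene_id": ["g1", "g2"],
            "contig": ["chr", "chr"],
            "start": [0, 200],
            "end": [100, 300],
        }
    )

    def _run(self, rows, f_values, n_reps=2):
        cov = _coverage(rows, ["g1", "g2"])
        scores = _scores(dict(zip(cov.fragment_barcodes, f_values)))
        by_exp = {f"rep{r}": scores for r in range(n_reps)}
        return compute_gene_pair_scores(by_exp, cov, self.GENES)

    def test_synergistic_pair_passes(self):
        out = self._run([[1, 0], [0, 1], [1, 1], [1, 1]], [0, 0, 4, 4])
        row = out.iloc[0]
        assert row["passes"]
        assert row["pair_score"] == pytest.approx(4.0, abs=0.02)
        assert row["supporting_fragments"] == 2

    def test_no_synergy_fails(self):
        out = self._run([[1, 0], [1, 1], [1, 1]], [4, 4, 4])
        assert not out.iloc[0]["passes"]

    def test_single_supporting_fragment_fails(self):
        out = self._run([[1, 0], [0, 1], [1, 1]], [0, 0, 4])
        row = out.iloc[0]
        assert row["supporting_fragments"] == 1 and not row["passes"]


class TestCloneEstimate:
    def test_half_genome_insert(self):
        est = estimate_clone_requirement(500, 1000, 0.99)
        assert est.n_clones == 7  # ln(0.01)/ln(0.5) = 6.64, rounded up

    def test_printed_formula_at_scale(self):
        est = estimate_clone_requirement(3000, 4_700_000, 0.99)
        assert 7210 <= est.n_clones <= 7215

    def test_monotone_in_coverage_prob(self):
        values = [
            estimate_clone_requirement(3000, 4_700_000, p).n_clones
            for p in (0.5, 0.9, 0.99, 0.999)
        ]
        assert values == sorted(values) and values[0] < values[-1]

    def test_domain_error(self):
        with pytest.raises(ValueError):
            estimate_clone_requirement(5000, 4000)
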