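"""Effect-calling filters, noise model, FDR and operon comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from dubseq.confidence import (
    FdrEstimate,
    call_high_confidence,
    call_reliable,
    consistency_test,
    estimate_fdr_by_shuffling,
    expected_false_positives,
    gene_noise_z,
    operon_position_comparison,
    replicate_consistency,
)
from dubseq.scoring import CoverageMatrix

from helpers import fisher_exact_enumeration


class TestNoise:
    def test_printed_formula_single_fragment(self):
        est = gene_noise_z([0.5], [63], [63])
        expected = math.sqrt(2.0 / 64.0) / math.log(2)
        assert est.fragment_noise[0] == pytest.approx(expected, abs=1e-4)
        assert est.gene_noise == pytest.approx(0.2551, abs=1e-3)

    def test_equal_noise_fragments_combine_as_inverse_sqrt2(self):
        one = gene_noise_z([1.0], [63], [63]).gene_noise
        two = gene_noise_z([1.0, 1.0], [63, 63], [63, 63]).gene_noise
        assert two == pytest.approx(one / math.sqrt(2))

    def test_deep_counts_shrink_noise(self):
        shallow = gene_noise_z([1.0], [20], [20])
        deep = gene_noise_z([1.0], [20000], [20000])
        assert deep.gene_noise < shallow.gene_noise / 10
        assert abs(deep.z) > abs(shallow.z)


class TestConsistency:
    def test_tight_fragments_pass(self):
        passed, p = consistency_test([3.0, 3.1, 2.9], np.zeros(100), 3.0)
        # closed form: mean 3, sd 0.1, n 3 -> t = 3/(0.1/sqrt(3)) = 51.96
        t = 3.0 / (0.1 / math.sqrt(3))
        assert t == pytest.approx(51.96, abs=0.01)
        assert passed and p < 1e-3

    def test_scattered_fragments_fail(self):
        passed, p = consistency_test([3.0, -2.0, 2.0, -1.0], np.zeros(100), 0.5)
        assert not passed and p > 0.5

    def test_reference_shifts_when_sign_matches(self):
        # all-fragment mean 2.9 with a positive gene score: testing against
        # 2.9 rather than 0 makes fragments at ~3 non-significant
        all_f = np.full(200, 2.9)
        passed_shifted, _ = consistency_test([3.0, 3.05, 2.95], all_f, 3.0)
        passed_zero, _ = consistency_test([3.0, 3.05, 2.95], -all_f, 3.0)
        assert not passed_shifted  # reference 2.9, mean 3.0: weak evidence
        assert passed_zero  # opposite-sign mean -> reference 0

    def test_single_fragment_top_percentile_rule(self):
        all_f = np.concatenate([np.linspace(-1, 1, 999), [5.0]])
        passed_hi, p = consistency_test([5.0], all_f, 5.0)
        passed_lo, _ = consistency_test([0.9], all_f, 0.9)
        assert passed_hi and math.isnan(p)
        assert not passed_lo

    def test_zero_variance_degenerate(self):
        passed, p = consistency_test([2.0, 2.0, 2.0], np.zeros(10), 2.0)
        assert passed and p == 0.0
        passed, p = consistency_test([0.0, 0.0], np.zeros(10), 0.0)
        assert not passed and p == 1.0


def _gene_frame(score, n_fragments, frag_ids):
    return pd.DataFrame(
        {
            "score": [score],
            "score_mean": [score],
            "n_fragments": [n_fragments],
            "fragment_ids": [tuple(frag_ids)],
        },
        index=pd.Index(["g1"], name="gene_id"),
    )


def _frag_frame(f_by_barcode, s=2000, t=2000):
    return pd.DataFrame(
        {
            "s": [s] * len(f_by_barcode),
            "t": [t] * len(f_by_barcode),
            "f_raw": list(f_by_barcode.values()),
            "f": list(f_by_barcode.values()),
        },
        index=pd.Index(list(f_by_barcode), name="barcode"),
    )


class TestCallReliable:
    def _call(self, score, f_values, s=2000, t=2000):
        frags = {f"F{i}": v for i, v in enumerate(f_values)}
        # embed in a sea of null fragments for the percentile/reference
        sea = {f"N{i}": 0.01 * ((-1) ** i) for i in range(200)}
        scores = _frag_frame({**frags, **sea}, s=s, t=t)
        genes = _gene_frame(score, len(frags), list(frags))
        return call_reliable(genes, scores, "exp1").iloc[0]

    def test_all_filters_pass(self):
        row = self._call(3.0, [3.0, 3.1, 2.9])
        assert row["reliable"]
        assert row["passes_magnitude"] and row["passes_consistency"] and row["passes_noise"]

    def test_magnitude_boundary(self):
        assert not self._call(1.9, [1.9, 1.95, 1.85])["reliable"]
        assert self._call(2.0, [2.0, 2.05, 1.95])["passes_magnitude"]

    def test_low_z_fails_noise_filter(self):
        # one shallow fragment: s=t=3 -> noise sqrt(2/4)/ln2 = 1.02, z = 2.9
        row = self._call(3.0, [3.0], s=3, t=3)
        assert not row["passes_noise"] and not row["reliable"]

    def test_reliable_is_conjunction(self):
        row = self._call(3.0, [3.0, -2.0, 2.0, -1.0])
        assert not row["passes_consistency"] and not row["reliable"]


class TestHighConfidence:
    def _calls(self, rows):
        frame = pd.DataFrame(rows)
        frame["score_mean"] = frame["score"]
        frame["p"] = 0.01
        frame["z"] = 10.0
        frame["passes_magnitude"] = True
        frame["passes_consistency"] = True
        frame["passes_noise"] = True
        return frame

    def test_multi_fragment_upgraded(self):
        calls = self._calls(
            [{"gene_id": "g1", "experiment_id": "e1", "score": 3.0,
              "n_fragments": 3, "reliable": True}]
        )
        out = call_high_confidence(calls, {"e1": "nickel"})
        assert out["high_confidence"].iloc[0]

    def test_single_fragment_without_support_not_upgraded(self):
        calls = self._calls(
            [{"gene_id": "g1", "experiment_id": "e1", "score": 3.0,
              "n_fragments": 1, "reliable": True}]
        )
        out = call_high_confidence(calls, {"e1": "nickel"})
        assert not out["high_confidence"].iloc[0]

    def test_single_fragment_with_replicate_support_upgraded(self):
        calls = self._calls(
            [
                {"gene_id": "g1", "experiment_id": "e1", "score": 3.0,
                 "n_fragments": 1, "reliable": True},
                {"gene_id": "g1", "experiment_id": "e2", "score": 2.4,
                 "n_fragments": 1, "reliable": False},
            ]
        )
        out = call_high_confidence(calls, {"e1": "nickel", "e2": "nickel"})
        assert out.loc[out["experiment_id"] == "e1", "high_confidence"].iloc[0]


class TestReplicateConsistency:
    def _calls(self, score_a, score_b):
        return pd.DataFrame(
            [
                {"gene_id": "g1", "experiment_id": "A", "score": score_a,
                 "reliable": True},
                {"gene_id": "g1", "experiment_id": "B", "score": score_b,
                 "reliable": False},
            ]
        )

    @pytest.mark.parametrize(
        "score_b,expected", [(1.6, 1.0), (-2.0, 0.0), (1.4, 0.0), (1.5, 1.0)]
    )
    def test_rule(self, score_b, expected):
        frac = replicate_consistency(self._calls(3.0, score_b), [("A", "B")])
        assert frac == pytest.approx(expected)

    def test_no_effects_gives_nan(self):
        calls = self._calls(3.0, 1.6)
        calls["reliable"] = False
        assert math.isnan(replicate_consistency(calls, [("A", "B")]))


class TestExpectedFalsePositives:
    def test_monotone_and_linear(self):
        assert expected_false_positives(0, 4) == 0.0
        assert expected_false_positives(100, 0) == pytest.approx(100.0)
        v1, v2 = expected_false_positives(100, 3), expected_false_positives(100, 4)
        assert v2 < v1
        assert expected_false_positives(200, 3) == pytest.approx(2 * v1)


def _null_setup(seed=0, n_frag=60, n_gene=6):
    rng = np.random.default_rng(seed)
    A = np.zeros((n_frag, n_gene), dtype=np.int8)
    for i in range(n_frag):
        j = i % n_gene
        A[i, j] = 1
        if rng.random() < 0.5 and j + 1 < n_gene:
            A[i, j + 1] = 1
    barcodes = [f"F{i}" for i in range(n_frag)]
    cov = CoverageMatrix(A, barcodes, [f"g{j}" for j in range(n_gene)])
    scores = {
        e: _frag_frame(dict(zip(barcodes, rng.normal(0, 0.05, n_frag))))
        for e in ("e1", "e2")
    }
    return scores, cov


class TestFdr:
    def test_worked_arithmetic(self):
        est = FdrEstimate(n_shuffles=10, shuffled_counts=[75] * 10,
                          actual_count=4051, seed=0)
        assert est.fdr == pytest.approx(75 / 4051)
        assert round(100 * est.fdr, 1) == 1.9

    def test_zero_shuffled_counts(self):
        est = FdrEstimate(10, [0] * 10, 100, 0)
        assert est.fdr == 0.0

    def test_no_actual_effects_not_applicable(self):
        est = FdrEstimate(10, [0] * 10, 0, 0)
        assert est.fdr is None

    def test_null_data_pipeline_runs_clean(self):
        scores, cov = _null_setup()
        est = estimate_fdr_by_shuffling(
            scores, cov, {"e1": "c", "e2": "c"}, n_shuffles=3, seed=1
        )
        assert est.actual_count == 0 and est.fdr is None
        assert all(c == 0 for c in est.shuffled_counts)

    def test_fdr_low_with_large_true_effects(self):
        from dubseq.scoring import build_coverage_matrix, compute_fragment_scores
        from dubseq.simulate import (
            SimConfig,
            make_design,
            simulate_fitness_counts,
            simulate_genome_and_genes,
            simulate_library,
        )

        base = SimConfig(seed=2)
        genome, genes = simulate_genome_and_genes(base)
        ids = genes["gene_id"].tolist()
        effects = {ids[6]: 3.0, ids[14]: 4.0, ids[22]: 3.0, ids[30]: 4.0,
                   ids[38]: 3.0}
        cfg = SimConfig(seed=2, effects=effects)
        truth = simulate_library(cfg, genome, genes)
        design = make_design()
        matrix = simulate_fitness_counts(truth, design)
        cov = build_coverage_matrix(truth.reference_fragments(), genes)
        scores = {
            s: compute_fragment_scores(matrix, design, s)
            for s in ("condA_r1", "condA_r2")
        }
        est = estimate_fdr_by_shuffling(
            scores, cov, {"condA_r1": "condA", "condA_r2": "condA"},
            n_shuffles=10, seed=5,
        )
        assert est.actual_count > 0
        assert est.fdr is not None and est.fdr <= 0.10

    def test_deterministic_under_seed(self):
        scores, cov = _null_setup(seed=3)
        a = estimate_fdr_by_shuffling(scores, cov, {"e1": "c", "e2": "c"},
                                      n_shuffles=3, seed=42)
        b = estimate_fdr_by_shuffling(scores, cov, {"e1": "c", "e2": "c"},
                                      n_shuffles=3, seed=42)
        assert a.shuffled_counts == b.shuffled_counts


class TestOperonComparison:
    def _inputs(self, n_first, first_hits, n_later, later_hits):
        genes, effect = [], {}
        rows = []
        for i in range(n_first):
            g = f"f{i}"
            rows.append({"gene_id": g, "position": "first"})
            effect[g] = i < first_hits
        for i in range(n_later):
            g = f"l{i}"
            rows.append({"gene_id": g, "position": "later"})
            effect[g] = i < later_hits
        return effect, pd.DataFrame(rows)

    def test_enrichment_table(self):
        effect, operons = self._inputs(100, 30, 100, 13)
        result = operon_position_comparison(effect, operons)
        assert result.table == ((30, 70), (13, 87))
        assert result.odds_ratio == pytest.approx(30 * 87 / (70 * 13), rel=1e-6)
        assert result.p_value == pytest.approx(
            fisher_exact_enumeration(result.table), rel=1e-6
        )

    def test_equal_proportions(self):
        effect, operons = self._inputs(50, 10, 50, 10)
        result = operon_position_comparison(effect, operons)
        assert result.odds_ratio == pytest.approx(1.0)
        assert result.p_value == pytest.approx(1.0)

    def test_empty_category_not_applicable(self):
        effect, operons = self._inputs(50, 10, 0, 0)
        assert not operon_position_comparison(effect, operons).applicable
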