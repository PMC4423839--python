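"""Differential screening, consensus selection, enrichment, drug join."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pdxfidelity.de_meta import (
    DifferentialResult,
    consensus_genes,
    count_interacting_drugs,
    differential_genes,
    enrich,
    leave_one_out,
    robustness_score,
)
from pdxfidelity.errors import ValidationError
from pdxfidelity.expression_io import AnnotationSet, ExpressionMatrix, GeneSetTerm
from pdxfidelity.fidelity import HUMAN_VS_XENO, XENO_VS_XENO, Pair


def _pair(patient, dataset, kind=HUMAN_VS_XENO, suffix="x"):
    return Pair(f"{patient}_F0", f"{patient}_F1{suffix}", kind, patient, dataset)


def _result(patient, dataset, genes, kind=HUMAN_VS_XENO):
    return DifferentialResult(_pair(patient, dataset, kind), frozenset(genes), frozenset())


class TestDifferentialGenes:
    def _matrix(self, a_values, b_values):
        genes = [f"g{i + 1}" for i in range(len(a_values))]
        return ExpressionMatrix(
            pd.DataFrame({"a": a_values, "b": b_values}, index=genes), scale="log2"
        )

    def test_boundary_inclusive_up(self):
        # a = 0 keeps the log2 difference exactly on the cutoff
        m = self._matrix([0.0], [math.log2(1.5)])
        r = differential_genes(m, Pair("a", "b", HUMAN_VS_XENO, "p", "d"))
        assert r.up_genes == {"g1"} and r.down_genes == frozenset()

    def test_small_change_neither(self):
        m = self._matrix([3.0], [3.3])
        r = differential_genes(m, Pair("a", "b", HUMAN_VS_XENO, "p", "d"))
        assert r.all_genes == frozenset()

    def test_five_gene_toy(self):
        deltas = [1.0, -1.0, 0.0, 0.6, -0.5]
        m = self._matrix([3.0] * 5, [3.0 + d for d in deltas])
        r = differential_genes(m, Pair("a", "b", HUMAN_VS_XENO, "p", "d"))
        assert r.up_genes == {"g1", "g4"}
        assert r.down_genes == {"g2"}

    def test_linear_scale_rejected(self):
        m = ExpressionMatrix(
            pd.DataFrame({"a": [3.0], "b": [9.0]}, index=["g1"]), scale="linear"
        )
        with pytest.raises(ValidationError, match="log"):
            differential_genes(m, Pair("a", "b", HUMAN_VS_XENO, "p", "d"))


class TestConsensus:
    def _toy_results(self):
        """10 patients over 5 datasets, one pair each; gene X hits
        patients 1–6 spanning datasets 1–3, gene Y only 2 datasets."""
        results = []
        for i in range(10):
            patient, dataset = f"p{i + 1}", f"d{i // 2 + 1}"
            genes = []
            if i < 6:
                genes.append("X")
            if i < 4:
                genes.append("Y")
            results.append(_result(patient, dataset, genes))
        return results

    def test_threshold_semantics(self):
        consensus = consensus_genes(self._toy_results())
        # X: 3 datasets, 6/10 patients → selected; Y: 2 datasets → rejected
        assert consensus.genes == ["X"]
        row = consensus.stats.iloc[0]
        assert row["n_datasets_hit"] == 3 and row["patient_fraction"] == 0.6

    def test_exactly_half_patients_rejected_strict(self):
        results = self._toy_results()
        # gene Z in 5 of 10 patients across 3 datasets: fraction == 0.5 fails
        for i in range(5):
            results[i] = DifferentialResult(
                results[i].pair, results[i].up_genes | {"Z"}, frozenset()
            )
        assert "Z" not in consensus_genes(results).genes

    def test_xeno_pairs_do_not_count(self):
        results = self._toy_results()
        results += [
            _result(f"p{i + 1}", f"d{i // 2 + 1}", ["W"], kind=XENO_VS_XENO)
            for i in range(10)
        ]
        assert "W" not in consensus_genes(results).genes

    def test_permutation_invariant(self):
        results = self._toy_results()
        shuffled = [results[i] for i in [7, 2, 9, 0, 4, 1, 8, 3, 6, 5]]
        a, b = consensus_genes(results), consensus_genes(shuffled)
        assert a.genes == b.genes
        assert a.stats.equals(b.stats)

    def test_requires_hx_pairs_and_dataset_coverage(self):
        with pytest.raises(ValidationError, match="human-vs-xeno"):
            consensus_genes([_result("p1", "d1", ["X"], kind=XENO_VS_XENO)])
        two_ds = [_result(f"p{i}", f"d{i % 2}", ["X"]) for i in range(4)]
        with pytest.raises(ValidationError, match="datasets"):
            consensus_genes(two_ds)

    def test_recovers_planted_program(self, cohort, cohort_de):
        """Frozen-seed recovery: ≥90% sensitivity, ≤5% false discoveries."""
        _, _, truth = cohort
        selected = set(consensus_genes(cohort_de).genes)
        planted = set(truth.engraftment_genes)
        sensitivity = len(selected & planted) / len(planted)
        fdr = len(selected - planted) / max(len(selected), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.05


class TestLeaveOneOut:
    def test_identical_datasets_stable(self):
        results = [
            _result(f"p{i + 1}_{d}", d, ["X"])
            for d in ("d1", "d2", "d3", "d4")
            for i in range(3)
        ]
        out = leave_one_out(results)
        assert all(genes == ["X"] for genes in out["per_drop"].values())
        assert out["intersection"] == ["X"]

    def test_gene_dominated_by_one_dataset_vanishes_on_its_drop(self):
        # Q rides on d1 (6 of its 9 patient hits); removing d1 drops it
        # below half of the remaining patients, removing any other
        # dataset does not
        results = [_result(f"p{i}", "d1", ["X", "Q"]) for i in range(6)]
        results += [_result("q0", "d2", ["X", "Q"])]
        results += [_result(f"q{i}", "d2", ["X"]) for i in (1, 2, 3)]
        results += [_result("r0", "d3", ["X", "Q"])]
        results += [_result(f"r{i}", "d3", ["X"]) for i in (1, 2)]
        results += [_result("s0", "d4", ["X", "Q"])]
        out = leave_one_out(results, min_datasets=3)
        assert "Q" not in out["per_drop"]["d1"]
        assert "Q" in out["per_drop"]["d4"]
        assert "X" in out["intersection"]
        assert "Q" not in out["intersection"]

    def test_planted_genes_survive_every_drop(self, cohort, cohort_de):
        _, _, truth = cohort
        out = leave_one_out(cohort_de)
        planted = set(truth.engraftment_genes)
        for dropped, genes in out["per_drop"].items():
            assert len(set(genes) & planted) / len(planted) >= 0.9
        assert len(set(out["intersection"]) & planted) / len(planted) >= 0.9


class TestEnrichment:
    def _catalogue(self, terms):
        ann = AnnotationSet()
        for tid, genes in terms.items():
            ann.add(GeneSetTerm(tid, tid.lower(), frozenset(genes)))
        return ann

    def test_hand_counted_upper_tail(self):
        # universe 10, term 4, query 5, overlap 4 → 6/252
        universe = [f"u{i}" for i in range(10)]
        term = universe[:4]
        query = universe[:4] + [universe[9]]
        table = enrich(query, universe, self._catalogue({"T": term}))
        assert table["p"].iloc[0] == pytest.approx(6 / 252, abs=1e-12)

    def test_disjoint_term_near_one_never_zero(self):
        universe = [f"u{i}" for i in range(10)]
        table = enrich(universe[5:], universe, self._catalogue({"T": universe[:3]}))
        assert 0.9 < table["p"].iloc[0] <= 1.0

    def test_matches_exhaustive_enumeration_small_universes(self):
        rng = np.random.default_rng(21)
        for trial in range(5):
            N = int(rng.integers(6, 13))
            universe = [f"u{i}" for i in range(N)]
            term = list(rng.choice(universe, size=int(rng.integers(2, N - 1)), replace=False))
            n_query = int(rng.integers(2, N - 1))
            query = list(rng.choice(universe, size=n_query, replace=False))
            observed = len(set(term) & set(query))
            hits = total = 0
            for draw in itertools.combinations(universe, n_query):
                total += 1
                hits += len(set(draw) & set(term)) >= observed
            table = enrich(query, universe, self._catalogue({"T": term}))
            assert table["p"].iloc[0] == pytest.approx(hits / total, abs=1e-12)

    def test_bh_step_up_by_hand(self):
        universe = [f"u{i}" for i in range(40)]
        catalogue = self._catalogue(
            {"A": universe[:8], "B": universe[8:20], "C": universe[20:30]}
        )
        query = universe[:6] + universe[8:12]
        table = enrich(query, universe, catalogue).sort_values("p").reset_index(drop=True)
        raw = table["p"].to_numpy()
        m = len(raw)
        expected = np.minimum.accumulate((raw * m / np.arange(1, m + 1))[::-1])[::-1]
        assert np.allclose(table["p_adj"].to_numpy(), np.minimum(expected, 1.0))
        # monotone along sorted raw p's and bounded by 1
        assert (np.diff(table["p_adj"]) >= -1e-15).all()
        assert (table["p_adj"] <= 1).all()
        assert (table["p_adj"] >= table["p"] - 1e-15).all()

    def test_printed_toy_bh_values(self):
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests([0.01, 0.02, 0.06], method="fdr_bh")[1]
        assert np.allclose(adjusted, [0.03, 0.03, 0.06])

    def test_empty_query_and_stray_genes_rejected(self):
        universe = ["a", "b", "c", "d"]
        catalogue = self._catalogue({"T": ["a", "b"]})
        with pytest.raises(ValidationError, match="empty"):
            enrich([], universe, catalogue)
        with pytest.raises(ValidationError, match="outside"):
            enrich(["z"], universe, catalogue)


class TestRobustness:
    def test_fraction_arithmetic(self):
        universe = [f"u{i}" for i in range(100)]
        term = universe[:10]
        ann = AnnotationSet()
        ann.add(GeneSetTerm("T", "t", frozenset(term)))
        results = []
        for i in range(10):
            # 8 pairs hit the whole term, 2 pairs a random non-overlap set
            genes = term if i < 8 else universe[50:60]
            results.append(_result(f"p{i}", "d1", genes))
        assert robustness_score("T", results, universe, ann) == pytest.approx(0.8)

    def test_never_significant_scores_zero(self):
        universe = [f"u{i}" for i in range(100)]
        ann = AnnotationSet()
        ann.add(GeneSetTerm("T", "t", frozenset(universe[:10])))
        results = [_result(f"p{i}", "d1", universe[50:55]) for i in range(5)]
        assert robustness_score("T", results, universe, ann) == 0.0

    def test_unknown_term_rejected(self):
        ann = AnnotationSet()
        ann.add(GeneSetTerm("T", "t", frozenset({"a"})))
        with pytest.raises(ValidationError, match="absent"):
            robustness_score("MISSING", [_result("p", "d", ["a"])], ["a", "b"], ann)

    def test_empty_pairs_excluded_from_denominator(self):
        universe = [f"u{i}" for i in range(50)]
        ann = AnnotationSet()
        ann.add(GeneSetTerm("T", "t", frozenset(universe[:5])))
        results = [
            _result("p1", "d1", universe[:5]),
            DifferentialResult(_pair("p2", "d1"), frozenset(), frozenset()),
        ]
        assert robustness_score("T", results, universe, ann) == pytest.approx(1.0)

    def test_planted_term_robust_decoys_not(self, cohort, cohort_de, cohort_gene_sets):
        """Frozen-seed analogue of the published per-pair robustness table."""
        from pdxfidelity.synthetic_data import PLANTED_TERM_ID

        matrix, _, _ = cohort
        planted = robustness_score(
            PLANTED_TERM_ID, cohort_de, matrix.gene_ids, cohort_gene_sets
        )
        decoys = [
            robustness_score(f"DECOY{i + 1:03d}", cohort_de, matrix.gene_ids, cohort_gene_sets)
            for i in range(5)
        ]
        assert planted >= 0.75
        assert max(decoys) <= 0.2


class TestDrugJoin:
    def test_counts_both_directions(self):
        per_gene, per_drug = count_interacting_drugs(
            ["A", "B"], {"A": frozenset({"d1", "d2"}), "C": frozenset({"d9"})}
        )
        assert per_gene == {"A": 2, "B": 0}
        assert per_drug == {"d1": 1, "d2": 1}

    def test_empty_map_all_zero(self):
        per_gene, per_drug = count_interacting_drugs(["A", "B"], {})
        assert per_gene == {"A": 0, "B": 0}
        assert per_drug == {}

    def test_drug_hitting_four_genes(self):
        genes = ["g1", "g2", "g3", "g4", "g5"]
        dmap = {g: frozenset({"alem"}) for g in genes[:4]}
        _, per_drug = count_interacting_drugs(genes, dmap)
        assert per_drug == {"alem": 4}
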