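"""Term grading, gene grouping, frequency features and logistic stages."""

import numpy as np
import pandas as pd
import pytest

from dnawords.association import (
    FitResult,
    TermAssociationModel,
    WordFrequencyTransformer,
    bootstrap_evaluate,
    evaluate_dataset,
    fit_term_model,
    grade_terms,
    group_genes,
    select_words_stage1,
    term_qualifies,
    word_frequency_matrix,
)
from dnawords.synthetic import toy_association_dataset


class TestGradeTerms:
    def test_two_edge_chain(self):
        h = grade_terms([("A", "root"), ("B", "A")], roots=["root"])
        assert h.levels == {"A": 1, "B": 2}
        assert h.descendants["A"] == frozenset({"B"})
        assert h.descendants["B"] == frozenset()

    def test_diamond_uses_minimum_parent_level(self):
        edges = [("A", "root"), ("B", "root"), ("C", "A"), ("C", "B"), ("D", "C")]
        h = grade_terms(edges, roots=["root"])
        assert h.levels["C"] == 2 and h.levels["D"] == 3

    def test_multi_parent_min_depth(self):
        # C is a direct child of the root through B, grandchild through A
        edges = [("A", "root"), ("B", "A"), ("C", "B"), ("C", "root")]
        h = grade_terms(edges, roots=["root"])
        assert h.levels["C"] == 1

    def test_empty_edges_one_root(self):
        h = grade_terms([], roots=["root"])
        assert h.levels == {}

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            grade_terms([("A", "root"), ("B", "A"), ("A", "B")], roots=["root"])

    def test_category_filter(self):
        edges = [("A", "mf"), ("B", "bp")]
        h = grade_terms(edges, roots=["mf", "bp"], category_root="mf")
        assert set(h.levels) == {"A"}


class TestGroupGenes:
    edges = [("t1", "root"), ("t2", "root"), ("t3", "root"), ("c1", "t1")]

    def _h(self):
        return grade_terms(self.edges, roots=["root"])

    def test_single_annotation_exclusive_elsewhere_control(self):
        ann = [("g1", "t1"), ("g2", "t2"), ("g3", "t3")]
        exc, share, ctl = group_genes("t1", self._h(), ann)
        assert exc == {"g1"} and share == frozenset() and ctl == {"g2", "g3"}
        exc2, _, ctl2 = group_genes("t2", self._h(), ann)
        assert exc2 == {"g2"} and ctl2 == {"g1", "g3"}

    def test_two_same_level_terms_share(self):
        ann = [("g1", "t1"), ("g1", "t2"), ("g2", "t3")]
        exc, share, ctl = group_genes("t1", self._h(), ann)
        assert share == {"g1"} and exc == frozenset() and ctl == {"g2"}

    def test_descendant_annotation_propagates_up(self):
        ann = [("g1", "c1"), ("g2", "t2")]
        exc, share, ctl = group_genes("t1", self._h(), ann)
        assert exc == {"g1"} and ctl == {"g2"}

    def test_partition_invariant(self):
        rng = np.random.default_rng(0)
        terms = ["t1", "t2", "t3", "c1"]
        ann = [
            (f"g{i}", terms[int(rng.integers(0, 4))])
            for i in range(200)
            for _ in range(int(rng.integers(1, 3)))
        ]
        universe = {g for g, _ in ann}
        for term in ("t1", "t2", "t3"):
            exc, share, ctl = group_genes(term, self._h(), ann)
            assert exc | share | ctl == universe
            assert not (exc & share) and not (exc & ctl) and not (share & ctl)

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            group_genes("nope", self._h(), [("g1", "t1")])

    def test_qualification_rule_strict(self):
        exc = frozenset(f"g{i}" for i in range(151))
        ctl = frozenset(f"h{i}" for i in range(151))
        assert term_qualifies(exc, ctl)
        assert not term_qualifies(frozenset(list(exc)[:150]), ctl)


class TestWordFrequencyMatrix:
    def test_subword_inside_superword_not_double_counted(self):
        vocab = ["information", "bioinformation"]
        genes = {"g": "xxbioinformationyyinformationzz"}
        f = word_frequency_matrix(genes, vocab)
        assert f.loc["g", "bioinformation"] == 1
        assert f.loc["g", "information"] == 1

    def test_word_absent_is_zero(self):
        f = word_frequency_matrix({"g": "AAAA"}, ["CG"])
        assert f.loc["g", "CG"] == 0

    def test_two_identical_variants_average(self):
        f1 = word_frequency_matrix({"g": "xxinformationyy"}, ["information"])
        f2 = word_frequency_matrix(
            {"g": ["xxinformationyy", "xxinformationyy"]}, ["information"]
        )
        assert f1.loc["g", "information"] == f2.loc["g", "information"] == 1

    def test_variant_average_fractional(self):
        f = word_frequency_matrix({"g": ["information", "xxxxxxxxxxx"]}, ["information"])
        assert f.loc["g", "information"] == 0.5

    def test_subtraction_floors_at_zero(self):
        # subword occurs twice inside the superword string but only one
        # superword copy is present standalone
        vocab = ["aba", "abaaba"]
        f = word_frequency_matrix({"g": "zzabaabazz"}, vocab)
        assert f.loc["g", "abaaba"] == 1
        assert f.loc["g", "aba"] == 0  # 2 raw - 1*2 nested = 0

    def test_frequency_length_conservation(self):
        """Adjusted counts x word length never exceed the sequence length."""
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        vocab = ["AC", "ACG", "ACGT", "GT", "T"]
        f = word_frequency_matrix({"g": seq}, vocab)
        total = sum(f.loc["g", w] * len(w) for w in vocab)
        assert total <= len(seq)


class TestStage1Selection:
    def _freq(self, fe_fc: dict[str, tuple[float, float]], n=50):
        cols = {}
        for w, (fe, fc) in fe_fc.items():
            cols[w] = [fe] * n + [fc] * n
        freq = pd.DataFrame(cols, index=[f"g{i}" for i in range(2 * n)])
        labels = pd.Series([1] * n + [0] * n, index=freq.index)
        return freq, labels

    def test_thresholds_applied_strictly(self):
        freq, labels = self._freq(
            {"yes": (0.7, 0.55), "border": (0.61, 0.51), "lowfe": (0.5, 0.1)}
        )
        assert select_words_stage1(freq, labels) == ["yes"]

    def test_cap_escalates_fd_threshold(self):
        fe_fc = {f"w{i:02d}": (1.0, 1.0 - (0.11 + 0.001 * i)) for i in range(60)}
        freq, labels = self._freq(fe_fc)
        unlimited = select_words_stage1(freq, labels)
        assert len(unlimited) == 60
        capped = select_words_stage1(freq, labels, cap=50)
        assert len(capped) < 50
        # fd in (0.11, 0.17): one escalation step to 0.12 keeps fd > 0.12
        assert all(1.0 - fe_fc[w][1] > 0.12 for w in capped)


class TestFitAndBootstrap:
    def test_almost_perfectly_predictive_word_survives(self):
        # two controls share the exclusive-group frequency, so the MLE is
        # finite (separation-adjacent, not separated)
        n = 40
        freq = pd.DataFrame(
            {"w": [3.0] * (n - 2) + [0.0, 0.0] + [3.0, 3.0] + [0.0] * (n - 2)},
            index=[f"g{i}" for i in range(2 * n)],
        )
        labels = pd.Series([1] * n + [0] * n, index=freq.index)
        fit = fit_term_model(freq, labels, ["w"])
        assert fit.converged and "w" in fit.terms
        p = fit.predict_proba(freq)
        assert (p[freq["w"] == 3.0] > 0.5).all()
        assert (p[freq["w"] == 0.0] < 0.5).all()

    def test_parameter_recovery_on_toy_data(self):
        words = ["ACGTTACG", "GGATCCAT", "TTGCAGTC"]
        ds = toy_association_dataset(500, 500, words, effect=1.0, seed=21)
        fit = fit_term_model(ds.freq, ds.labels, words)
        assert fit.converged
        for w in words:
            assert w in fit.terms
            assert fit.coefficients[w] == pytest.approx(1.0, abs=0.35)

    def test_null_keeps_about_p_keep_fraction(self):
        words = ["ACGTTACG", "GGATCCAT", "TTGCAGTC", "CATGGTAC", "AGCTTGCA"]
        kept = 0
        n_data = 40
        for s in range(n_data):
            ds = toy_association_dataset(80, 80, words, effect=0.0, seed=500 + s)
            fit = fit_term_model(ds.freq, ds.labels, words)
            kept += len(fit.terms)
        frac = kept / (n_data * len(words))
        assert 0.1 < frac < 0.3

    def test_interaction_terms_are_products_of_kept_words(self):
        words = ["ACGTTACG", "GGATCCAT", "TTGCAGTC"]
        ds = toy_association_dataset(300, 300, words, effect=1.0, seed=33)
        fit = fit_term_model(ds.freq, ds.labels, words, model_kind="with_interaction")
        mains = [t for t in fit.terms if "*" not in t]
        for t in fit.terms:
            if "*" in t:
                a, b = t.split("*")
                assert a in words and b in words

    def test_bootstrap_perfect_classifier_fixed_point(self):
        # a model predicting P~1 on exclusive and P~0 on control; every
        # bootstrap refit reproduces the separation, so all rates are exact
        n = 60
        genes = [f"g{i}" for i in range(2 * n)]
        freq = pd.DataFrame({"w": [4.0] * n + [0.0] * n}, index=genes)
        labels = pd.Series([1] * n + [0] * n, index=genes)
        fit = FitResult(
            model_kind="main_effects",
            terms=("w",),
            coefficients={"const": -10.0, "w": 5.0},
            p_values={},
            converged=True,
        )
        ev = bootstrap_evaluate(fit, freq, labels, n_boot=30, seed=0)
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0
        assert ev.agreement == 1.0
        assert ev.sensitivity_mad == 0.0 and ev.specificity_mad == 0.0
        assert ev.share_accuracy is None  # empty share group -> missing

    def test_bootstrap_constant_below_half_model(self):
        n = 30
        genes = [f"g{i}" for i in range(2 * n)]
        freq = pd.DataFrame({"w": [0.0] * 2 * n}, index=genes)
        labels = pd.Series([1] * n + [0] * n, index=genes)
        # constant model P = sigmoid(-0.1) < 0.5 everywhere
        fit = FitResult(
            model_kind="main_effects",
            terms=(),
            coefficients={"const": -0.1},
            p_values={},
            converged=True,
        )
        p = fit.predict_proba(freq)
        assert ((p < 0.5)).all()
        sens = float((p[labels == 1] > 0.5).mean())
        spec = float((p[labels == 0] < 0.5).mean())
        assert sens == 0.0 and spec == 1.0

    def test_evaluate_dataset_with_share_group(self):
        words = ["ACGTTACG"]
        ds = toy_association_dataset(120, 120, words, effect=1.5, seed=8, n_share=20)
        fit = fit_term_model(ds.model_freq, ds.labels.loc[ds.model_freq.index], words)
        ev = evaluate_dataset(fit, ds, n_boot=30, seed=2)
        for r in (ev.sensitivity, ev.specificity, ev.agreement, ev.share_accuracy):
            assert r is not None and 0.0 <= r <= 1.0
        assert ev.sensitivity > 0.6 and ev.specificity > 0.6


class TestEstimators:
    def test_transformer(self):
        tr = WordFrequencyTransformer(vocabulary=["information", "bioinformation"])
        f = tr.fit().transform({"g": "bioinformation"})
        assert f.loc["g", "bioinformation"] == 1
        assert f.loc["g", "information"] == 0

    def test_term_association_model_pipeline(self):
        words = ["ACGTTACG", "GGATCCAT"]
        ds = toy_association_dataset(200, 200, words, effect=1.2, seed=11)
        m = TermAssociationModel().fit(ds.freq, ds.labels)
        assert set(m.selected_words_) <= set(words)
        proba = m.predict_proba(ds.freq)
        assert proba.shape == (len(ds.freq), 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        acc = (m.predict(ds.freq) == ds.labels.to_numpy()).mean()
        assert acc > 0.7
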