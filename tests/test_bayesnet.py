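"""Discrete Bayesian-network classifier: CPTs, AIC, structure, prediction."""

import itertools
import math

import numpy as np
import pytest

from lorenzgini.bayesnet import (BayesNetModel, aic_score, fit_cpts,
                                 joint_probability, learn_structure,
                                 log_likelihood, n_free_parameters, predict,
                                 predict_codes)
from lorenzgini.data import DiscretizedMatrix


def make_disc(codes, labels, class_set, gene_ids=None):
    codes = np.asarray(codes)
    gene_ids = gene_ids or [f"g{i}" for i in range(codes.shape[0])]
    return DiscretizedMatrix(
        gene_ids, [f"s{j}" for j in range(codes.shape[1])], codes,
        labels, class_set,
        [int(c.max()) + 1 for c in codes],
        [np.arange(int(c.max()), dtype=float) + 0.5 for c in codes])


@pytest.fixture
def two_class_disc():
    # gene g0: 9 zeros and 1 one under class A, all ones under class B
    codes = np.array([[0] * 9 + [1] + [1] * 10])
    labels = ["A"] * 10 + ["B"] * 10
    return make_disc(codes, labels, ["A", "B"])


class TestFitCpts:
    def test_empirical_frequencies(self, two_class_disc):
        model = fit_cpts({"g0": []}, two_class_disc, smoothing=0.0)
        assert model.cpts["g0"][0, 0] == pytest.approx(0.9)  # P(0|A)
        assert model.cpts["g0"][1, 1] == pytest.approx(1.0)  # P(1|B)
        assert model.class_priors == pytest.approx([0.5, 0.5])

    def test_smoothing_formula(self, two_class_disc):
        model = fit_cpts({"g0": []}, two_class_disc, smoothing=0.5)
        assert model.cpts["g0"][0, 0] == pytest.approx(9.5 / 11)

    def test_unobserved_parent_combo_uniform(self):
        # parent gene only takes value 0 under class A, so (A, 1) is unseen
        codes = np.array([[0, 0, 1, 1], [0, 1, 0, 1]])
        labels = ["A", "A", "B", "B"]
        disc = make_disc(codes, labels, ["A", "B"])
        model = fit_cpts({"g1": ["g0"], "g0": []}, disc, smoothing=0.5)
        assert model.cpts["g1"][0, 1] == pytest.approx([0.5, 0.5])

    def test_missing_node_rejected(self, two_class_disc):
        with pytest.raises(ValueError, match="absent"):
            fit_cpts({"nope": []}, two_class_disc)

    def test_cpt_rows_are_distributions(self, two_class_disc):
        model = fit_cpts({"g0": []}, two_class_disc, smoothing=0.5)
        assert np.allclose(model.cpts["g0"].sum(axis=-1), 1.0)
        assert (model.cpts["g0"] > 0).all()


class TestScores:
    def test_parameter_count(self, two_class_disc):
        model = fit_cpts({"g0": []}, two_class_disc)
        # class prior (1) + gene: (2-1) values x 2 class combos
        assert n_free_parameters(model) == 3

    def test_extra_edge_increases_aic_when_probabilities_unchanged(self):
        # within each class the two genes form an exact product
        # distribution, so the extra edge leaves every fitted probability
        # unchanged and AIC rises by exactly the added parameter count
        cell = [(0, 0), (0, 1), (1, 0), (1, 1)]
        codes = np.array(list(zip(*(cell * 2))))
        labels = ["A"] * 4 + ["B"] * 4
        disc = make_disc(codes, labels, ["A", "B"])
        naive = fit_cpts({"g0": [], "g1": []}, disc, smoothing=0.0)
        extra = fit_cpts({"g0": [], "g1": ["g0"]}, disc, smoothing=0.0)
        assert n_free_parameters(extra) == n_free_parameters(naive) + 2
        assert log_likelihood(extra, disc) == pytest.approx(
            log_likelihood(naive, disc), abs=1e-12)
        assert aic_score(extra, disc) == pytest.approx(
            aic_score(naive, disc) + 2, abs=1e-12)

    def test_zero_probability_gives_minus_inf_not_error(self, two_class_disc):
        model = fit_cpts({"g0": []}, two_class_disc, smoothing=0.0)
        flipped = make_disc(np.array([[1] * 10 + [0] * 10]),
                            ["A"] * 10 + ["B"] * 10, ["A", "B"])
        assert log_likelihood(model, flipped) == -math.inf

    def test_aic_agrees_with_brute_force_enumeration(self):
        # exhaustive oracle over every DAG on three binary genes
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 2, size=(3, 60))
        labels = list(rng.choice(["A", "B"], 60))
        disc = make_disc(codes, labels, ["A", "B"])
        lab = np.array([0 if l == "A" else 1 for l in labels])

        def brute_aic(parents):
            # direct counting, no shared code with the implementation
            ll = 0.0
            n_par = 1  # class prior
            cc = np.bincount(lab, minlength=2)
            pri = cc / cc.sum()
            for s in range(60):
                ll += math.log(pri[lab[s]])
            for g, pars in parents.items():
                gi = int(g[1])
                pidx = [int(p[1]) for p in pars]
                combos = itertools.product([0, 1], repeat=1 + len(pidx))
                n_par += 1 * 2 * 2 ** len(pidx)
                for combo in combos:
                    sel = lab == combo[0]
                    for ax, p in zip(combo[1:], pidx):
                        sel &= codes[p] == ax
                    tot = sel.sum()
                    if tot == 0:
                        continue
                    for v in (0, 1):
                        cnt = (sel & (codes[gi] == v)).sum()
                        if cnt:
                            ll += cnt * math.log(cnt / tot)
            return -ll + n_par

        gene_sets = {
            "g0": [[], ["g1"], ["g2"], ["g1", "g2"]],
            "g1": [[], ["g2"]],
            "g2": [[]],
        }
        for p0 in gene_sets["g0"]:
            for p1 in gene_sets["g1"]:
                parents = {"g0": p0, "g1": p1, "g2": []}
                model = fit_cpts(parents, disc, smoothing=0.0)
                assert aic_score(model, disc) == pytest.approx(
                    brute_aic(parents), abs=1e-9)


class TestStructureLearning:
    def _simulate(self, rng, n, copy_noise=None):
        lab = rng.integers(0, 2, n)
        g0 = (lab + rng.integers(0, 2, n)) % 2
        if copy_noise is None:
            g1 = (lab + rng.integers(0, 2, n)) % 2  # independent given class
        else:
            flip = rng.random(n) < copy_noise
            g1 = np.where(flip, 1 - g0, g0)  # near-copy of g0
        labels = ["A" if l == 0 else "B" for l in lab]
        return make_disc(np.array([g0, g1]), labels, ["A", "B"])

    def test_conditionally_independent_genes_stay_unlinked(self):
        disc = self._simulate(np.random.default_rng(2), 2000)
        model = learn_structure(disc, max_parents=1)
        assert model.parents == {"g0": [], "g1": []}

    def test_copied_gene_gains_edge(self):
        disc = self._simulate(np.random.default_rng(3), 2000, copy_noise=0.01)
        model = learn_structure(disc, max_parents=1)
        assert model.parents["g1"] == ["g0"]

    def test_max_parents_zero_gives_naive_structure(self):
        disc = self._simulate(np.random.default_rng(4), 500, copy_noise=0.01)
        model = learn_structure(disc, max_parents=0)
        assert all(p == [] for p in model.parents.values())

    def test_never_cyclic_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            codes = rng.integers(0, 3, size=(4, 40))
            labels = list(rng.choice(["A", "B", "C"], 40))
            disc = make_disc(codes, labels, ["A", "B", "C"])
            model = learn_structure(disc, max_parents=2)
            # BayesNetModel construction runs the cycle check; also assert
            # edges only point from earlier-ordered genes
            order = {g: i for i, g in enumerate(model.gene_ids)}
            for g, pars in model.parents.items():
                assert all(order[p] < order[g] for p in pars)


class TestPrediction:
    def test_worked_reference_joint(self, worked_model):
        j = joint_probability(worked_model, [0] * 9, "normal")
        assert j == pytest.approx(0.4454e-8, rel=3e-4)

    def test_zero_prior_class_zero_joint(self, worked_model):
        j = joint_probability(worked_model, [0] * 9, "adenocarcinoma")
        assert j == 0.0

    def test_single_gene_joint_is_prior_times_cpt(self, two_class_disc):
        model = fit_cpts({"g0": []}, two_class_disc, smoothing=0.0)
        assert joint_probability(model, [0], "A") == pytest.approx(0.5 * 0.9)

    def test_out_of_range_value_names_gene(self, worked_model):
        with pytest.raises(ValueError, match="JAG1"):
            joint_probability(worked_model, [5] + [0] * 8, "normal")

    def test_predict_reference_instance(self, worked_model):
        cls, post = predict(worked_model, [0] * 9)
        assert cls == "squamous"
        assert post.sum() == pytest.approx(1.0)

    def test_tie_break_class_order(self):
        model = BayesNetModel(
            class_set=["A", "B"], gene_ids=["g0"], arities=[2],
            parents={"g0": []}, class_priors=np.array([0.5, 0.5]),
            cpts={"g0": np.array([[0.5, 0.5], [0.5, 0.5]])}, smoothing=0.0)
        cls, post = predict(model, [0])
        assert cls == "A" and post == pytest.approx([0.5, 0.5])

    def test_posterior_matches_full_joint_enumeration(self):
        # oracle: posterior from the product query equals summing the full
        # joint table over all configurations
        rng = np.random.default_rng(6)
        codes = rng.integers(0, 2, size=(4, 120))
        labels = list(rng.choice(["A", "B", "C"], 120))
        disc = make_disc(codes, labels, ["A", "B", "C"])
        model = learn_structure(disc, max_parents=2, smoothing=0.5)
        full = {}
        for cfg in itertools.product([0, 1], repeat=4):
            for c in model.class_set:
                full[cfg + (c,)] = joint_probability(model, list(cfg), c)
        total = sum(full.values())
        assert total == pytest.approx(1.0, abs=1e-10)
        for cfg in itertools.product([0, 1], repeat=4):
            _, post = predict(model, list(cfg))
            marg = sum(full[cfg + (c,)] for c in model.class_set)
            for j, c in enumerate(model.class_set):
                assert post[j] == pytest.approx(full[cfg + (c,)] / marg,
                                                abs=1e-10)

    def test_smoothed_posteriors_strictly_positive(self, two_class_disc):
        model = fit_cpts({"g0": []}, two_class_disc, smoothing=0.5)
        for v in (0, 1):
            _, post = predict(model, [v])
            assert (post > 0).all()

    def test_predict_codes_batch(self, two_class_disc):
        model = fit_cpts({"g0": []}, two_class_disc, smoothing=0.5)
        preds = predict_codes(model, np.array([[0, 1]]))
        assert preds == ["A", "B"]
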