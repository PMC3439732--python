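"""Unit and property tests for the hierarchical block model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import dirichlet_multinomial, multinomial

from hnbgwas.hnb import (
    HNBModel,
    Hyperparams,
    classify,
    collapse_weight,
    estimate_xi,
    fit_hnb,
    log_marginal_likelihood,
    predict_log_posterior,
)
from hnbgwas.ld import Block, BlockSchema
from hnbgwas.naive_bayes import fit_nb, predict_nb

from oracles import compositions, dirichlet_multinomial_by_quadrature

ML = Hyperparams(estimator="ml")


def singleton_schema(dataset, beta=3.0):
    """Every SNP its own 'block' of size one."""
    return BlockSchema(
        blocks=[
            Block(id=f"b{j}", chrom=str(dataset.chrom[j]), snp_ids=(s,))
            for j, s in enumerate(dataset.snp_ids)
        ],
        covariates=[],
        minor_alleles={s: "A" for s in dataset.snp_ids},
        r2_threshold=0.8,
    )


class TestCollapseWeight:
    @pytest.mark.parametrize(
        "nrep,alpha,expected",
        [(1, 7.3, 1.0), (3, 1.0, 0.5), (0, 2.0, 1.5), (9, 1.0, 0.2)],
    )
    def test_values(self, nrep, alpha, expected):
        assert collapse_weight(nrep, alpha) == pytest.approx(expected)

    def test_strictly_decreasing_in_nrep(self):
        taus = collapse_weight(np.arange(1, 200), 1.0)
        assert (np.diff(taus) < 0).all()
        assert collapse_weight(100, 1.0) < collapse_weight(10, 1.0)

    @pytest.mark.parametrize("nrep,alpha", [(-1, 1.0), (2, 0.0), (2, -3.0)])
    def test_domain_errors(self, nrep, alpha):
        with pytest.raises(ValueError):
            collapse_weight(nrep, alpha)


class TestEstimateXi:
    def test_single_example_tau_cancels(self):
        for alpha in (0.3, 1.0, 12.0):
            xi = estimate_xi([[2, 1, 1]], Hyperparams(alpha=alpha, estimator="ml"))
            assert xi == pytest.approx([0.5, 0.25, 0.25])

    def test_empty_counts_return_prior_mean(self):
        h = Hyperparams(beta=1.0, gamma=(1 / 3, 1 / 3, 1 / 3))
        xi = estimate_xi(np.zeros((0, 3)), h)
        assert xi == pytest.approx([1 / 3] * 3)

    def test_two_examples_weighted_by_tau(self):
        # tau = (0.5, 1.0) at alpha=1 -> xi = (1.5, 1, 0) / 2.5
        xi = estimate_xi([[3, 0, 0], [0, 1, 0]], Hyperparams(alpha=1.0, estimator="ml"))
        assert xi == pytest.approx([0.6, 0.4, 0.0])

    def test_scalar_reference_implementation(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 5, size=(20, 3))
        alpha = 2.5
        num = np.zeros(3)
        den = 0.0
        for row in counts:
            nrep = row.sum()
            if nrep == 0:
                continue
            tau = (1 + alpha) / (nrep + alpha)
            num += tau * row
            den += tau * nrep
        xi = estimate_xi(counts, Hyperparams(alpha=alpha, estimator="ml"))
        assert xi == pytest.approx(num / den)

    def test_all_missing_rows_contribute_nothing(self):
        base = [[2, 0, 1], [1, 1, 1]]
        with_zero = base + [[0, 0, 0]]
        for h in (ML, Hyperparams()):
            assert estimate_xi(base, h) == pytest.approx(estimate_xi(with_zero, h))

    def test_bayes_beta_zero_equals_ml(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            counts = rng.integers(0, 6, size=(rng.integers(1, 15), 3))
            if counts.sum() == 0:
                continue
            alpha = float(rng.uniform(0.1, 10))
            ml = estimate_xi(counts, Hyperparams(alpha=alpha, estimator="ml"))
            bz = estimate_xi(counts, Hyperparams(alpha=alpha, beta=0.0,
                                                 estimator="bayes"))
            np.testing.assert_array_equal(ml, bz)

    def test_ml_undefined_without_observations(self):
        with pytest.raises(ValueError, match="undefined"):
            estimate_xi(np.zeros((3, 3)), ML)

    def test_result_sums_to_one(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 4, size=(10, 5))
        for h in (ML, Hyperparams(beta=2.0)):
            assert estimate_xi(counts, h).sum() == pytest.approx(1.0)


class TestLogMarginalLikelihood:
    def test_uniform_dirichlet_two_states(self):
        # Dirichlet(1,1)-multinomial with n=2 is uniform over 3 outcomes
        lml = log_marginal_likelihood([1, 1], [0.5, 0.5], 2.0,
                                      include_count_coefficient=True)
        assert lml == pytest.approx(np.log(1 / 3))

    def test_single_draw_equals_dirichlet_mean(self):
        lml = log_marginal_likelihood([1, 0, 0], [1 / 3] * 3, 3.0,
                                      include_count_coefficient=True)
        assert lml == pytest.approx(np.log(1 / 3))

    def test_quadrature_oracle(self):
        val = log_marginal_likelihood([2, 1, 0], [0.5, 0.3, 0.2], 1.5,
                                      include_count_coefficient=True)
        oracle = dirichlet_multinomial_by_quadrature([2, 1, 0],
                                                     [0.5, 0.3, 0.2], 1.5)
        assert np.exp(val) == pytest.approx(oracle, rel=1e-8)

    def test_matches_scipy_dirichlet_multinomial(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            xi = rng.dirichlet([1, 1, 1])
            alpha = float(rng.uniform(0.2, 20))
            x = rng.integers(0, 7, size=3)
            mine = log_marginal_likelihood(x, xi, alpha,
                                           include_count_coefficient=True)
            ref = dirichlet_multinomial.logpmf(x, alpha * xi, int(x.sum()))
            assert mine == pytest.approx(ref, rel=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=6),
        st.floats(min_value=0.2, max_value=15),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_normalization_over_compositions(self, nrep, alpha, seed):
        xi = np.random.default_rng(seed).dirichlet([1.0, 1.0, 1.0])
        total = sum(
            np.exp(log_marginal_likelihood(np.array(x), xi, alpha,
                                           include_count_coefficient=True))
            for x in compositions(nrep, 3)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_pooling_limit_large_alpha(self):
        # alpha -> inf collapses the hierarchy to a plain multinomial
        rng = np.random.default_rng(2)
        for _ in range(20):
            xi = rng.dirichlet([2, 2, 2])
            x = rng.integers(0, 6, size=3)
            if x.sum() == 0:
                continue
            lml = log_marginal_likelihood(x, xi, 1e6,
                                          include_count_coefficient=True)
            ref = multinomial.logpmf(x, int(x.sum()), xi)
            assert lml == pytest.approx(ref, rel=1e-3)

    def test_zero_xi_observed_state_is_minus_inf(self):
        lml = log_marginal_likelihood([1, 1, 0], [0.5, 0.0, 0.5], 1.0)
        assert lml == -np.inf

    def test_zero_xi_unobserved_state_is_finite(self):
        lml = log_marginal_likelihood([2, 0, 1], [0.5, 0.0, 0.5], 1.0)
        assert np.isfinite(lml)

    def test_nrep_zero_returns_log_one(self):
        assert log_marginal_likelihood([0, 0, 0], [0.2, 0.3, 0.5], 4.0) == 0.0

    def test_count_coefficient_drops_class_constant_terms(self):
        x = np.array([2, 1, 3])
        diff = log_marginal_likelihood(x, [0.2, 0.3, 0.5], 2.0, True) - \
            log_marginal_likelihood(x, [0.2, 0.3, 0.5], 2.0, False)
        from scipy.special import gammaln
        assert diff == pytest.approx(
            gammaln(x.sum() + 1) - gammaln(x + 1).sum()
        )


class TestFitPredict:
    def test_balanced_prior(self, toy_factory):
        ds = toy_factory([[0, 1], [1, 2], [2, 0], [0, 0]], [2, 2, 1, 1])
        schema = BlockSchema(
            blocks=[Block("b1", "1", ("s1", "s2"))],
            covariates=[], minor_alleles={"s1": "A", "s2": "A"},
            r2_threshold=0.8,
        )
        model = fit_hnb(ds, schema)
        assert np.exp(model.log_prior) == pytest.approx([0.5, 0.5])

    def test_single_class_training_is_fit_as_given(self, toy_factory):
        ds = toy_factory([[0], [1]], [2, 2])
        schema = BlockSchema(blocks=[], covariates=["s1"],
                             minor_alleles={"s1": "A"}, r2_threshold=0.8)
        model = fit_hnb(ds, schema)  # single class is fitted
        assert model.classes == [2]

    def test_schema_with_unknown_snp_raises(self, toy_factory):
        ds = toy_factory([[0], [1]], [2, 1])
        schema = BlockSchema(blocks=[Block("b1", "1", ("nope", "s1"))],
                             covariates=[], minor_alleles={}, r2_threshold=0.8)
        with pytest.raises(KeyError, match="nope"):
            fit_hnb(ds, schema)

    def test_all_missing_individual_gets_prior(self, toy_factory):
        ds = toy_factory([[0, 1], [1, 2], [2, 0], [1, 1], [0, 0], [2, 2]],
                         [2, 2, 1, 1, 2, 1])
        schema = BlockSchema(
            blocks=[Block("b1", "1", ("s1", "s2"))], covariates=[],
            minor_alleles={"s1": "A", "s2": "A"}, r2_threshold=0.8,
        )
        model = fit_hnb(ds, schema)
        blank = toy_factory([[-1, -1]], [1])
        post = predict_log_posterior(model, blank)
        assert post[0] == pytest.approx(model.log_prior)

    def test_identical_populations_give_prior_back(self, toy_factory):
        ds = toy_factory([[0, 1], [1, 2], [0, 1], [1, 2]], [2, 2, 1, 1])
        schema = BlockSchema(
            blocks=[Block("b1", "1", ("s1", "s2"))], covariates=[],
            minor_alleles={"s1": "A", "s2": "A"}, r2_threshold=0.8,
        )
        model = fit_hnb(ds, schema)
        np.testing.assert_allclose(model.block_xi[0], model.block_xi[1])
        post = predict_log_posterior(model, ds)
        np.testing.assert_allclose(post, np.tile(model.log_prior, (4, 1)),
                                   atol=1e-12)

    def test_singleton_blocks_reduce_to_naive_bayes(self, sim_small):
        """With every block of size one and matched smoothing (beta = S,
        gamma uniform vs Laplace), HNB posteriors equal NB posteriors."""
        ds, _ = sim_small
        sub = ds.subset_snps(ds.snp_ids[:30])
        schema = singleton_schema(sub)
        schema.minor_alleles = {s: sub.counted_allele[j]
                               for j, s in enumerate(sub.snp_ids)}
        hyper = Hyperparams(alpha=1.7, beta=3.0, estimator="bayes")
        hnb_model = fit_hnb(sub, schema, hyper)
        nb_model = fit_nb(sub, sub.snp_ids, smoothing="laplace")
        np.testing.assert_allclose(
            predict_log_posterior(hnb_model, sub),
            predict_nb(nb_model, sub),
            atol=1e-12,
        )

    def test_predict_invariant_to_block_and_snp_order(self, sim_small):
        ds, truth = sim_small
        blocks = [b for b in truth["blocks"].values()][:4]
        minor = {s: ds.counted_allele[ds.snp_index([s])[0]]
                 for b in blocks for s in b}
        covs = [s for s in ds.snp_ids[:10] if s not in minor]
        minor.update({s: ds.counted_allele[ds.snp_index([s])[0]] for s in covs})

        def make(order_blocks, order_within, order_covs):
            bl = [Block(f"b{i}", "22", tuple(order_within(b)))
                  for i, b in enumerate(order_blocks(blocks))]
            return BlockSchema(blocks=bl, covariates=order_covs(covs),
                               minor_alleles=minor, r2_threshold=0.8)

        ident = lambda x: list(x)
        rev = lambda x: list(x)[::-1]
        m1 = fit_hnb(ds, make(ident, ident, ident))
        m2 = fit_hnb(ds, make(rev, rev, rev))
        np.testing.assert_allclose(
            predict_log_posterior(m1, ds), predict_log_posterior(m2, ds),
            atol=1e-10,
        )

    def test_parameter_recovery_on_simulated_block(self):
        """Fitted xi approaches the generating HWE frequencies, and the
        error shrinks as the per-class sample grows."""
        from hnbgwas.simulate import SimScenario, simulate_haplotypes

        maf = 0.2
        truth = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        errs = {}
        for n in (100, 1000):
            sc = SimScenario(n_snps=12, n_blocks=2, block_size_range=(5, 6),
                             maf_range=(maf, maf), causal_maf_range=(maf, maf),
                             n_causal=0, seed=99)
            reps = []
            for k in range(5):
                rng = np.random.default_rng(1000 + k)
                h, meta = simulate_haplotypes(sc, n_haplotypes=2 * n, rng=rng)
                g = h[0::2] + h[1::2]
                members = np.flatnonzero(meta["block_of"] == 0)
                counts = np.stack(
                    [(g[:, members] == s).sum(axis=1) for s in (0, 1, 2)], axis=1
                )
                xi = estimate_xi(counts, Hyperparams())
                reps.append(np.abs(xi - truth).max())
            errs[n] = np.mean(reps)
        assert errs[1000] < errs[100]
        assert errs[1000] < 0.02

    def test_classify_tie_break_and_majority(self, toy_factory):
        ds = toy_factory([[0, 1], [1, 2], [0, 1], [1, 2]], [2, 2, 1, 1])
        schema = BlockSchema(
            blocks=[Block("b1", "1", ("s1", "s2"))], covariates=[],
            minor_alleles={"s1": "A", "s2": "A"}, r2_threshold=0.8,
        )
        model = fit_hnb(ds, schema)  # identical classes -> all posteriors tied
        labels, post = classify(model, ds)
        assert (labels == model.classes[0]).all()
        np.testing.assert_allclose(post.sum(axis=1), 1.0)

    def test_model_json_round_trip(self, sim_small):
        ds, truth = sim_small
        blocks = list(truth["blocks"].values())[:2]
        minor = {s: ds.counted_allele[ds.snp_index([s])[0]]
                 for b in blocks for s in b}
        covs = [s for s in ds.snp_ids[:5] if s not in minor]
        minor.update({s: ds.counted_allele[ds.snp_index([s])[0]] for s in covs})
        schema = BlockSchema(
            blocks=[Block(f"b{i}", "22", tuple(b)) for i, b in enumerate(blocks)],
            covariates=covs, minor_alleles=minor, r2_threshold=0.8,
        )
        model = fit_hnb(ds, schema)
        back = HNBModel.from_json(model.to_json())
        np.testing.assert_allclose(
            predict_log_posterior(model, ds), predict_log_posterior(back, ds)
        )


class TestHyperparams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"alpha": -1.0},
            {"beta": -0.1},
            {"estimator": "map"},
            {"gamma": (0.5, 0.4)},
            {"gamma": (-0.1, 1.1, 0.0)},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            Hyperparams(**kwargs)
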