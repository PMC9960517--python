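"""PRS computation, min-max normalization, clumping and incremental R^2."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from iterprs import (
    CohortSpec,
    PRSModel,
    clump,
    compute_prs,
    ct_search,
    minmax_normalize,
    prs_r2,
    simulate_cohort,
    summary_stats,
)
from iterprs.assoc import SummaryStats
from iterprs.genio import MISSING


def model_from(ids, alleles, weights, mode="none"):
    return PRSModel(
        pd.DataFrame({"id": ids, "effect_allele": alleles, "weight": weights}),
        denominator_mode=mode,
    )


class TestComputePRS:
    @pytest.fixture
    def two_by_two(self, make_dataset):
        # sample1 dosages (2, 0), sample2 (1, 2); weights (0.5, -1.0)
        return make_dataset([[2, 0], [1, 2]])

    def test_hand_computed_mode_none(self, two_by_two):
        m = model_from(["v0", "v1"], ["A", "A"], [0.5, -1.0], "none")
        assert compute_prs(two_by_two, m).tolist() == [1.0, -1.5]

    def test_hand_computed_mode_allele_count(self, two_by_two):
        m = model_from(["v0", "v1"], ["A", "A"], [0.5, -1.0], "allele_count")
        assert compute_prs(two_by_two, m).tolist() == [0.25, -0.375]

    def test_hand_computed_mode_n_samples(self, two_by_two):
        m = model_from(["v0", "v1"], ["A", "A"], [0.5, -1.0], "n_samples_literal")
        assert compute_prs(two_by_two, m).tolist() == [0.5, -0.75]

    def test_modes_affine_equivalent(self, small_cohort):
        """All denominator modes are positive affine transforms of one
        another on complete data: identical after min-max normalization."""
        ds, truth = small_cohort
        ids = truth.causal_variant_ids
        ea = ds.variants.set_index("id").loc[ids, "allele1"]
        norm = {}
        for mode in ("none", "allele_count", "n_samples_literal"):
            m = model_from(ids, ea.tolist(), truth.true_betas, mode)
            norm[mode] = minmax_normalize(compute_prs(ds, m))
        assert np.allclose(norm["none"], norm["allele_count"], atol=1e-12)
        assert np.allclose(norm["none"], norm["n_samples_literal"], atol=1e-12)

    def test_zero_weights_zero_scores(self, two_by_two):
        m = model_from(["v0", "v1"], ["A", "A"], [0.0, 0.0], "none")
        assert (compute_prs(two_by_two, m) == 0).all()

    def test_linear_in_weights(self, make_dataset):
        rng = np.random.default_rng(11)
        ds = make_dataset(rng.integers(0, 3, size=(20, 6)))
        w1, w2 = rng.standard_normal(6), rng.standard_normal(6)
        ids = [f"v{j}" for j in range(6)]
        s1 = compute_prs(ds, model_from(ids, ["A"] * 6, w1, "none"))
        s2 = compute_prs(ds, model_from(ids, ["A"] * 6, w2, "none"))
        s12 = compute_prs(ds, model_from(ids, ["A"] * 6, w1 + w2, "none"))
        assert np.allclose(s12, s1 + s2, atol=1e-12)

    def test_other_allele_counts_complement(self, make_dataset):
        ds = make_dataset([[2], [0]])  # allele1 = A, allele2 = G
        m = model_from(["v0"], ["G"], [1.0], "none")
        assert compute_prs(ds, m).tolist() == [0.0, 2.0]

    def test_strand_image_allele_reconciled(self, make_dataset):
        ds = make_dataset([[2], [1]])  # A/G; effect allele given as T = complement(A)
        m = model_from(["v0"], ["T"], [1.0], "none")
        assert compute_prs(ds, m).tolist() == [2.0, 1.0]

    def test_duplicated_samples_invariant_allele_count(self, make_dataset):
        rng = np.random.default_rng(12)
        d = rng.integers(0, 3, size=(10, 4))
        ds = make_dataset(d)
        ds2 = make_dataset(np.vstack([d, d]))
        ids = [f"v{j}" for j in range(4)]
        m = model_from(ids, ["A"] * 4, rng.standard_normal(4), "allele_count")
        s1, s2 = compute_prs(ds, m), compute_prs(ds2, m)
        assert np.allclose(np.tile(s1, 2), s2)

    def test_no_overlap_is_error(self, two_by_two):
        m = model_from(["zzz"], ["A"], [1.0], "none")
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="matched"):
                compute_prs(two_by_two, m)


class TestMinMax:
    def test_basic(self):
        assert minmax_normalize(np.array([2.0, 4.0, 6.0])).tolist() == [0.0, 0.5, 1.0]

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(30)
        assert np.allclose(minmax_normalize(x), minmax_normalize(3.5 * x + 2.0))

    def test_order_preserved(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(50)
        from scipy.stats import spearmanr

        assert spearmanr(x, minmax_normalize(x)).statistic == pytest.approx(1.0)

    def test_constant_vector_warns_half(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(np.ones(5))
        assert (out == 0.5).all()


def _sumstats_frame(ids, ps, alleles=None):
    return pd.DataFrame(
        {
            "id": ids,
            "effect_allele": ["A"] * len(ids) if alleles is None else alleles,
            "beta": np.ones(len(ids)),
            "p": ps,
        }
    )


class TestClump:
    def test_duplicate_dosage_keeps_smaller_p(self, make_dataset):
        base = np.random.default_rng(1).integers(0, 3, size=(40, 1))
        ds = make_dataset(np.hstack([base, base]))
        kept = clump(_sumstats_frame(["v0", "v1"], [1e-4, 1e-8]), ds)
        assert kept == ["v1"]

    def test_different_chromosomes_all_kept(self, make_dataset):
        base = np.random.default_rng(2).integers(0, 3, size=(40, 1))
        ds = make_dataset(np.hstack([base, base]), chrom=["1", "2"])
        kept = clump(_sumstats_frame(["v0", "v1"], [1e-4, 1e-8]), ds)
        assert sorted(kept) == ["v0", "v1"]

    def test_outside_window_kept(self, make_dataset):
        base = np.random.default_rng(3).integers(0, 3, size=(40, 1))
        ds = make_dataset(np.hstack([base, base]), pos=[1000, 500_000])
        kept = clump(_sumstats_frame(["v0", "v1"], [1e-4, 1e-8]), ds, window_kb=250)
        assert sorted(kept) == ["v0", "v1"]

    def test_matches_brute_force_oracle(self):
        """20-variant LD fixture: greedy result equals a literal-rule
        brute-force implementation."""
        spec = CohortSpec(n_samples=300, n_snps=20, ld_rho=0.9, n_chroms=1, bp_spacing=50_000, seed=44)
        ds, _ = simulate_cohort(spec)
        rng = np.random.default_rng(7)
        ps = rng.uniform(1e-8, 1, size=20)
        table = _sumstats_frame(ds.variants["id"].tolist(), ps)
        kept = clump(table, ds, r2_max=0.1, window_kb=250)

        # oracle: literal rule, python loops
        d = ds.dosages.astype(float)
        order = table.sort_values(["p", "id"]).reset_index(drop=True)
        accepted = []
        vmeta = ds.variants.set_index("id")
        for row in order.itertuples(index=False):
            j = ds.variants["id"].tolist().index(row.id)
            ok = True
            for aid in accepted:
                ja = ds.variants["id"].tolist().index(aid)
                same_chrom = vmeta.loc[row.id, "chrom"] == vmeta.loc[aid, "chrom"]
                close = abs(int(vmeta.loc[row.id, "pos"]) - int(vmeta.loc[aid, "pos"])) <= 250_000
                if same_chrom and close:
                    r = np.corrcoef(d[:, j], d[:, ja])[0, 1]
                    if r**2 > 0.1:
                        ok = False
                        break
            if ok:
                accepted.append(row.id)
        assert kept == accepted


class TestPrsR2:
    def test_perfect_score_explains_everything(self):
        y = np.arange(30.0)
        fit = prs_r2(y.copy(), y)
        assert fit.prs_r2 == pytest.approx(1.0, abs=1e-10)

    def test_noise_score_explains_nothing(self):
        rng = np.random.default_rng(15)
        n = 2000
        fit = prs_r2(rng.standard_normal(n), rng.standard_normal(n))
        assert fit.prs_r2 < 3 / np.sqrt(n)

    def test_matches_two_regression_oracle(self):
        """Direct full-vs-reduced statsmodels computation agrees to 1e-10."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(16)
        n = 150
        C = rng.standard_normal((n, 3))
        s = rng.standard_normal(n) + 0.4 * C[:, 0]
        y = 0.8 * s + C @ [0.5, -0.2, 0.1] + rng.standard_normal(n)
        fit = prs_r2(s, y, C)
        full = sm.OLS(y, sm.add_constant(np.column_stack([C, s]))).fit()
        red = sm.OLS(y, sm.add_constant(C)).fit()
        assert fit.prs_r2 == pytest.approx(full.rsquared - red.rsquared, abs=1e-10)
        assert fit.beta_prs == pytest.approx(full.params[-1], abs=1e-10)
        assert fit.p_value == pytest.approx(full.pvalues[-1], rel=1e-8)

    def test_never_negative(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = 60
            C = rng.standard_normal((n, 2))
            assert prs_r2(rng.standard_normal(n), rng.standard_normal(n), C).prs_r2 >= 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="fewer samples"):
            prs_r2(np.ones(3), np.arange(3.0), np.ones((3, 2)))


class TestCTSearch:
    @pytest.fixture(scope="class")
    def causal_setup(self):
        spec = CohortSpec(n_samples=1200, n_snps=300, n_causal=1, heritability=0.25, seed=18)
        ds, truth = simulate_cohort(spec)
        ss = summary_stats(ds, covariates=("sex", "age", "status1", "status2"))
        return ds, truth, ss

    def test_single_causal_found(self, causal_setup):
        ds, truth, ss = causal_setup
        model, fit = ct_search(ss, ds)
        assert truth.causal_variant_ids[0] in set(model.entries["id"])
        # recovers nearly all of the realized (not nominal) genetic signal
        tab = ds.phenotable.loc[ds.sample_ids]
        C = tab[["sex", "age", "status1", "status2"]].to_numpy(float)
        realized = prs_r2(
            truth.genetic_values(ds), tab["phenotype"].to_numpy(), C
        ).prs_r2
        assert fit.prs_r2 > 0.8 * realized > 0

    def test_degenerate_grid_equals_direct_fit(self, causal_setup):
        ds, truth, ss = causal_setup
        model, fit = ct_search(ss, ds, thresholds=[0.01])
        scores = compute_prs(ds, model)
        tab = ds.phenotable.loc[ds.sample_ids]
        C = tab[["sex", "age", "status1", "status2"]].to_numpy(float)
        direct = prs_r2(scores, tab["phenotype"].to_numpy(), C, n_snps=model.n_snps)
        assert fit.prs_r2 == pytest.approx(direct.prs_r2, abs=1e-12)

    def test_self_consistency(self, causal_setup):
        """The reported best fit is reproducible from the returned model."""
        ds, truth, ss = causal_setup
        model, fit = ct_search(ss, ds)
        scores = compute_prs(ds, model)
        tab = ds.phenotable.loc[ds.sample_ids]
        C = tab[["sex", "age", "status1", "status2"]].to_numpy(float)
        again = prs_r2(scores, tab["phenotype"].to_numpy(), C, n_snps=model.n_snps)
        assert again.prs_r2 == pytest.approx(fit.prs_r2, abs=1e-12)

    def test_nothing_below_threshold_is_error(self, make_dataset):
        rng = np.random.default_rng(19)
        d = rng.integers(0, 3, size=(50, 3)).astype(np.int8)
        ds = make_dataset(d, pheno=rng.standard_normal(50))
        table = _sumstats_frame(["v0", "v1", "v2"], [0.5, 0.6, 0.9])
        ss = SummaryStats(pd.DataFrame(table.assign(se=1.0, n_used=50)), "external", (), 0, "phenotype")
        with pytest.raises(ValueError, match="threshold"):
            ct_search(ss, ds, thresholds=[1e-8], covariates=())


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(-5, 5), min_size=2, max_size=40, unique=True))
def test_minmax_bounds_property(values):
    out = minmax_normalize(np.array(values))
    assert out.min() == 0.0 and out.max() == 1.0
    assert np.all((out >= 0) & (out <= 1))
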