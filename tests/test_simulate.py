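import numpy as np
import pandas as pd
import pytest

import subtypesim as st
from subtypesim.errors import ValidationError
from subtypesim.simulate import _substream

from conftest import symmetric_pair


@pytest.fixture()
def parent(centroids):
    return st.ExpressionProfile("p0", centroids.profiles["Luminal B"])


class TestSimulateOne:
    def test_zero_sigma_reproduces_parent(self, parent):
        rng = np.random.default_rng(0)
        sim = st.simulate_one(parent, {g: 0.0 for g in parent.gene_ids}, rng)
        pd.testing.assert_series_equal(sim.values, parent.values, check_names=False)

    def test_moment_recovery_of_gene_gaussian(self):
        """Draws around mu=1.94 with sigma=0.085 recover both moments —
        the per-gene Gaussian sampling step at archetype scale."""
        genes = ["ACTR3B-like", "g2", "g3"]
        p = st.ExpressionProfile("s", pd.Series([1.94, 5.0, 2.0], index=genes))
        sigma = {"ACTR3B-like": 0.085, "g2": 0.0, "g3": 0.0}
        rng = np.random.default_rng(123)
        draws = np.array(
            [st.simulate_one(p, sigma, rng).values.iloc[0] for _ in range(10_000)]
        )
        assert draws.mean() == pytest.approx(1.94, abs=0.003)
        assert draws.std(ddof=1) == pytest.approx(0.085, rel=0.05)

    def test_fixed_stream_is_bit_identical(self, parent):
        sigma = {g: 0.1 for g in parent.gene_ids}
        a = st.simulate_one(parent, sigma, np.random.default_rng(99))
        b = st.simulate_one(parent, sigma, np.random.default_rng(99))
        assert np.array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_negative_sigma_rejected(self, parent):
        with pytest.raises(ValidationError):
            st.simulate_one(parent, {g: -0.1 for g in parent.gene_ids},
                            np.random.default_rng(0))

    def test_missing_gene_sigma_rejected(self, parent):
        with pytest.raises(ValidationError, match="undefined"):
            st.simulate_one(parent, {}, np.random.default_rng(0))


class TestRunReproducibility:
    def test_zero_sigma_gives_prop_one_exactly(self, parent, centroids):
        cfg = st.SimulationConfig(n_sims=500, master_seed=1)
        res = st.run_reproducibility(
            parent, "Luminal B", centroids, np.zeros(50), cfg
        )
        assert res.prop_identical == 1.0
        assert sum(res.counts_by_subtype.values()) == 500

    @pytest.mark.parametrize("sigma_scale", [0.05, 0.3, 1.0])
    def test_tally_conservation(self, parent, centroids, sigma_scale):
        cfg = st.SimulationConfig(n_sims=777, master_seed=3, chunk_size=250)
        res = st.run_reproducibility(
            parent, "Luminal B", centroids, np.full(50, sigma_scale), cfg
        )
        assert sum(res.counts_by_subtype.values()) == 777

    def test_deterministic_given_master_seed(self, parent, centroids):
        cfg = st.SimulationConfig(n_sims=2_000, master_seed=17)
        sigma = np.full(50, 0.5)
        a = st.run_reproducibility(parent, "Luminal B", centroids, sigma, cfg)
        b = st.run_reproducibility(parent, "Luminal B", centroids, sigma, cfg)
        assert a.counts_by_subtype == b.counts_by_subtype

    def test_vectorized_engine_matches_naive_scipy_loop(self, parent, centroids):
        """The batched rank/correlation engine agrees draw-for-draw with a
        naive loop classifying each simulated sample via scipy.spearmanr."""
        from scipy.stats import spearmanr

        cfg = st.SimulationConfig(n_sims=300, master_seed=5)
        sigma = np.full(50, 0.8)
        res = st.run_reproducibility(parent, "Luminal B", centroids, sigma, cfg)

        aligned = st.align_genes(parent, centroids)
        rng, _ = _substream(cfg.master_seed, parent.sample_id, "average")
        draws = (
            aligned.sample_values[:, None]
            + rng.standard_normal((50, 300)) * sigma[:, None]
        )
        names = aligned.subtype_names
        counts = dict.fromkeys(names, 0)
        for j in range(300):
            rhos = [
                float(spearmanr(draws[:, j], aligned.centroid_matrix[:, k]).statistic)
                for k in range(len(names))
            ]
            counts[names[int(np.argmax(rhos))]] += 1
        assert res.counts_by_subtype == counts

    def test_borderline_midpoint_splits_evenly(self):
        """At the exact 50/50 mixing point of two permutation-symmetric
        centroids, neither subtype should win much more than half the time."""
        cents, midpoint = symmetric_pair(n_genes=50, seed=8)
        cfg = st.SimulationConfig(n_sims=10_000, master_seed=21)
        res = st.run_reproducibility(
            midpoint, "A", cents, np.full(50, 0.5), cfg
        )
        top = max(res.counts_by_subtype.values()) / cfg.n_sims
        assert top <= 0.55

    def test_monotone_degradation_with_sigma_multiplier(self, centroids):
        """More measurement error can only make a borderline call less
        reproducible: prop_identical is non-increasing in a global sigma
        multiplier."""
        a, b = centroids.subtype_names[0], centroids.subtype_names[1]
        mix = 0.62 * centroids.profiles[a] + 0.38 * centroids.profiles[b]
        parent = st.ExpressionProfile("border", mix)
        subtype = st.classify_sample(parent, centroids).assigned_subtype
        base = np.full(50, 0.6)
        props = []
        for mult in (0.0, 0.5, 1.0, 2.0):
            cfg = st.SimulationConfig(n_sims=4_000, master_seed=31)
            res = st.run_reproducibility(parent, subtype, centroids, base * mult, cfg)
            props.append(res.prop_identical)
        assert props[0] == 1.0
        for lo, hi in zip(props[1:], props[:-1]):
            assert lo <= hi + 0.01  # Monte Carlo slack well below observed drops

    def test_prop_tends_to_one_as_sigma_vanishes(self, parent, centroids):
        cfg = st.SimulationConfig(n_sims=2_000, master_seed=41)
        res = st.run_reproducibility(
            parent, "Luminal B", centroids, np.full(50, 1e-4), cfg
        )
        assert res.prop_identical == 1.0


class TestRunCohort:
    @pytest.fixture()
    def cohort(self, spec, centroids):
        matrix, _ = st.make_cohort(spec, 4, 2, centroids=centroids)
        return matrix

    def test_results_independent_of_sample_order(self, cohort, centroids, sigma_model):
        cfg = st.SimulationConfig(n_sims=400, master_seed=7)
        fwd = st.run_cohort(cohort, centroids, sigma_model, cfg).results
        reversed_matrix = st.ExpressionMatrix(cohort.values.iloc[:, ::-1])
        rev = st.run_cohort(reversed_matrix, centroids, sigma_model, cfg).results
        fwd_by_id = {r.parent_sample_id: r for r in fwd}
        rev_by_id = {r.parent_sample_id: r for r in rev}
        assert fwd_by_id.keys() == rev_by_id.keys()
        for k in fwd_by_id:
            assert fwd_by_id[k].counts_by_subtype == rev_by_id[k].counts_by_subtype

    def test_three_scenarios_use_ordered_sigmas(self, cohort, centroids, sigma_model):
        cfg = st.SimulationConfig(n_sims=200, master_seed=9)
        run = st.run_cohort(
            cohort, centroids, sigma_model, cfg, scenarios=("best", "average", "worst")
        )
        one = [r for r in run.results if r.parent_sample_id == cohort.sample_ids[0]]
        assert [r.scenario for r in one] == ["best", "average", "worst"]
        profile = cohort.profile(cohort.sample_ids[0])
        subtype = st.classify_sample(profile, centroids).assigned_subtype
        vals = profile.values.to_numpy()
        means = [
            sigma_model.predict(vals, subtype, s).mean()
            for s in ("best", "average", "worst")
        ]
        assert means[0] <= means[1] <= means[2]

    def test_subtype_without_curve_is_skipped_and_recorded(self, spec, centroids, sigma_model):
        # Normal-like has no archetype in the fitted model
        p = st.make_archetype(centroids.profiles["Normal-like"], spec)
        matrix = st.ExpressionMatrix(p.values.to_frame(name=p.sample_id))
        cfg = st.SimulationConfig(n_sims=100, master_seed=2)
        run = st.run_cohort(matrix, centroids, sigma_model, cfg)
        assert run.results == []
        assert len(run.skipped) == 1 and run.skipped[0][0] == p.sample_id

    def test_results_tsv_round_trip(self, cohort, centroids, sigma_model, tmp_path):
        cfg = st.SimulationConfig(n_sims=300, master_seed=13)
        results = st.run_cohort(cohort, centroids, sigma_model, cfg).results
        path = tmp_path / "results.tsv"
        st.write_results_tsv(results, path)
        loaded = st.read_results_tsv(path)
        assert [r.counts_by_subtype for r in loaded] == [
            r.counts_by_subtype for r in results
        ]
        assert [r.prop_identical for r in loaded] == pytest.approx(
            [r.prop_identical for r in results]
        )
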