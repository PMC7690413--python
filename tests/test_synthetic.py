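import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import riverdrift as rd
from riverdrift.synthetic import BULK_OTU, OtuSpec, TransectDesign, Tributary


def tiny_design(otus, tributaries=(), depth=1000, seed=0, distances=(1000, 5000, 10000)):
    return TransectDesign(
        river_distances_m=distances,
        tributaries=tuple(tributaries),
        otus=tuple(otus),
        depth=depth,
        seed=seed,
    )


class TestExpectedProportions:
    def test_zero_decay_identical_everywhere(self):
        design = tiny_design(
            [
                OtuSpec("a", "lake_decaying", lake_proportion=0.2, decay_per_km=0.0),
                OtuSpec("b", "stable", lake_proportion=0.3),
            ]
        )
        mats = [rd.expected_proportions(design, i) for i in range(4)]
        for vec in mats[1:]:
            np.testing.assert_allclose(vec, mats[0], atol=1e-12)

    def test_exponential_decay_formula(self):
        # p0 = 0.2, lambda = 0.1/km, d = 10 km -> unnormalized 0.2 e^-1
        design = tiny_design(
            [OtuSpec("a", "lake_decaying", lake_proportion=0.2, decay_per_km=0.1)]
        )
        vec = rd.expected_proportions(design, 3)  # site at 10 km
        expected = 0.2 * math.exp(-1.0)
        assert vec[design.otu_ids.index("a")] == pytest.approx(expected, abs=1e-12)

    def test_confluence_mixing_halves_upstream_mass(self):
        design = tiny_design(
            [OtuSpec("a", "stable", lake_proportion=0.2)],
            tributaries=[Tributary("T", 2000.0, 0.5)],
        )
        before = rd.expected_proportions(design, 1)
        after = rd.expected_proportions(design, 2)
        i = design.otu_ids.index("a")
        assert before[i] == pytest.approx(0.2)
        assert after[i] == pytest.approx(0.1)

    def test_probability_vector_at_every_site(self, default_run):
        design = default_run["design"]
        for si in range(1 + design.n_river_sites + len(design.tributaries)):
            vec = rd.expected_proportions(design, si)
            assert vec.sum() == pytest.approx(1.0, abs=1e-12)
            assert (vec >= 0).all()

    def test_site_index_out_of_range(self):
        design = tiny_design([OtuSpec("a", "stable", lake_proportion=0.2)])
        with pytest.raises(rd.ValidationError, match="out of range"):
            rd.expected_proportions(design, 99)

    @given(lam1=st.floats(0.0, 2.0), lam2=st.floats(0.0, 2.0))
    def test_decay_monotone_in_rate(self, lam1, lam2):
        lo, hi = sorted([lam1, lam2])
        if hi - lo < 1e-6:
            return
        vecs = []
        for lam in (lo, hi):
            design = tiny_design(
                [OtuSpec("a", "lake_decaying", lake_proportion=0.2, decay_per_km=lam)]
            )
            vecs.append(rd.expected_proportions(design, 2)[0])  # d = 5 km > 0
        assert vecs[1] < vecs[0]


class TestSimulateCounts:
    def test_counts_sum_to_depth(self, default_run):
        table = default_run["table"]
        assert (table.counts.sum(axis=1) == default_run["design"].depth).all()

    def test_same_seed_byte_identical(self, tmp_path):
        design = rd.with_seed(rd.default_design(), 42)
        paths = []
        for k in range(2):
            table, meta, _ = rd.simulate_counts(design)
            p = tmp_path / f"t{k}.tsv"
            rd.write_count_table(table, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_differ(self):
        t1, *_ = rd.simulate_counts(rd.with_seed(rd.default_design(), 1))
        t2, *_ = rd.simulate_counts(rd.with_seed(rd.default_design(), 2))
        assert not np.array_equal(t1.counts, t2.counts)

    def test_realized_means_match_mean_model(self):
        """Monte-Carlo check: mean realized proportions within 3 SE of the model."""
        design = tiny_design(
            [
                OtuSpec("dec", "lake_decaying", lake_proportion=0.2, decay_per_km=0.3),
                OtuSpec("ris", "river_rising", rise_max=0.1, rise_midpoint_km=4.0,
                        rise_rate_per_km=2.0),
                OtuSpec("sta", "stable", lake_proportion=0.3),
                OtuSpec("see", "tributary_seeded", tributary="T", tributary_proportion=0.4),
            ],
            tributaries=[Tributary("T", 2000.0, 0.2)],
            depth=100_000,
        )
        reps = 200
        rng = np.random.default_rng(7)
        for si in range(1 + design.n_river_sites + len(design.tributaries)):
            p = rd.expected_proportions(design, si)
            draws = rng.multinomial(design.depth, p, size=reps) / design.depth
            se = np.sqrt(p * (1 - p) / (design.depth * reps))
            ok = np.abs(draws.mean(axis=0) - p) <= 3 * se + 1e-12
            assert ok.all()

    def test_env_gradients_have_expected_signs(self, default_run):
        meta = default_run["metadata"]
        sites = [meta.lake_site, *meta.river_sites]
        dist = meta.site_distances().loc[sites].to_numpy()
        env = meta.env.loc[sites]
        for col, sign in [
            ("temperature_c", -1), ("toc_mg_per_l", -1),
            ("turbidity_ntu", 1), ("total_nitrogen_mg_per_l", 1),
            ("no3_no2_mg_per_l", 1), ("conductivity_umhos_per_cm", 1),
            ("alkalinity_mg_per_l_caco3", 1),
        ]:
            r = np.corrcoef(dist, env[col].to_numpy())[0, 1]
            assert np.sign(r) == sign and abs(r) > 0.7, col

    def test_qpcr_totals_positive(self, default_run):
        assert (default_run["metadata"].qpcr["copies_per_ml"] > 0).all()


class TestGroundTruth:
    def test_labels_by_construction(self):
        design = tiny_design(
            [
                OtuSpec("sta", "stable", lake_proportion=0.3),
                # expected count crosses below 1 read between 5 and 10 km
                OtuSpec("dec", "lake_decaying", lake_proportion=0.1,
                        decay_per_km=math.log(0.1 * 1000) / 6.0),
                OtuSpec("see", "tributary_seeded", tributary="T", tributary_proportion=0.4),
            ],
            tributaries=[Tributary("T", 2000.0, 0.2)],
        )
        truth = rd.ground_truth_labels(design)
        assert truth.trajectory("sta") == "stable"
        assert truth.trajectory("dec") == "lost"
        assert truth.trajectory("see") == "emerging"
        assert truth.labels.loc["see", "origin"] == "tributaries_only"
        assert truth.labels.loc["sta", "origin"] == "lake_only"

    def test_rare_intermittent_is_unstable(self):
        design = tiny_design(
            [
                OtuSpec("sta", "stable", lake_proportion=0.3),
                OtuSpec("rar", "rare_intermittent", lake_proportion=0.01, occupancy=0.5),
            ]
        )
        truth = rd.ground_truth_labels(design)
        assert truth.trajectory("rar") == "unstable"

    def test_trend_signs_follow_archetypes(self, default_run):
        labels = default_run["truth"].labels
        assert (labels.loc[labels.archetype == "lake_decaying", "trend"] == "-").all()
        assert (labels.loc[labels.archetype == "river_rising", "trend"] == "+").all()
        assert labels.loc[BULK_OTU, "trend"] == "+"

    def test_labels_do_not_depend_on_seed(self):
        a = rd.ground_truth_labels(rd.with_seed(rd.default_design(), 1)).labels
        b = rd.ground_truth_labels(rd.with_seed(rd.default_design(), 999)).labels
        assert a.equals(b)


class TestDesignValidation:
    def test_overallocated_lake_rejected(self):
        with pytest.raises(rd.ValidationError, match="sum"):
            tiny_design(
                [
                    OtuSpec("a", "stable", lake_proportion=0.7),
                    OtuSpec("b", "stable", lake_proportion=0.5),
                ]
            )

    def test_flow_fraction_bounds(self):
        with pytest.raises(rd.ValidationError, match="flow fraction"):
            Tributary("T", 1000.0, 1.0)

    def test_unknown_tributary_rejected(self):
        with pytest.raises(rd.ValidationError, match="unknown tributaries"):
            tiny_design(
                [OtuSpec("a", "tributary_seeded", tributary="nope", tributary_proportion=0.1)]
            )
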