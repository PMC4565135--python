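import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cmapsig import (
    QuerySignature,
    combine_scores,
    connection_score,
    profile_p_value,
    run_diffexp,
    score_dataset,
)
from cmapsig.synthetic import (
    ReferenceSpec,
    StudyConfig,
    generate_reference_db,
    generate_study,
)


class TestGenerateStudy:
    def test_same_seed_is_byte_identical(self):
        a, _ = generate_study(seed=3, n_genes=100, n_deg=10,
                              n_datasets=2, pairs_per_dataset=(5, 6))
        b, _ = generate_study(seed=3, n_genes=100, n_deg=10,
                              n_datasets=2, pairs_per_dataset=(5, 6))
        for da, db_ in zip(a, b):
            pd.testing.assert_frame_equal(da.values, db_.values)
            assert da.pairs == db_.pairs

    def test_null_study_yields_few_significant_genes(self):
        datasets, _ = generate_study(
            seed=4, n_genes=1000, n_deg=0, effect_log2=0.0,
            n_datasets=2, pairs_per_dataset=(10, 10),
        )
        for ds in datasets:
            assert run_diffexp(ds).M <= 5

    def test_strong_planting_dominates_significant_list(self):
        datasets, truth = generate_study(
            seed=5, n_genes=1000, n_deg=40, effect_log2=2.0,
            presence_prob=1.0, flip_prob=0.0,
            n_datasets=1, pairs_per_dataset=(10,),
        )
        res = run_diffexp(datasets[0])
        recovered = set(res.significant_ids) & set(truth.deg_ids)
        assert len(recovered) >= 0.9 * len(truth.deg_ids)

    def test_truth_tables_shapes_and_flags(self):
        datasets, truth = generate_study(
            seed=6, n_genes=200, n_deg=20, n_datasets=3,
            pairs_per_dataset=(5, 5, 5), flip_prob=0.5,
        )
        assert len(truth.deg_ids) == 20
        assert truth.presence.shape == (20, 3)
        assert truth.flipped.shape == (20, 3)
        assert (truth.effects.abs() == 2.0).all()
        name = datasets[0].name
        realised = truth.effect_in(name)
        absent = ~truth.presence[name]
        assert (realised[absent] == 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(n_genes=10, n_deg=10)
        with pytest.raises(ValueError):
            StudyConfig(pairs_per_dataset=(5, 5))  # wrong length for 5 datasets
        with pytest.raises(ValueError):
            generate_study(StudyConfig(), seed=0, n_genes=50)  # config + overrides


class TestGenerateReferenceDb:
    def _signature(self, universe, m=10, seed=0):
        rng = np.random.default_rng(seed)
        genes = tuple(rng.choice(list(universe.genes), m, replace=False))
        signs = tuple(int(s) for s in rng.choice([-1, 1], m))
        return QuerySignature(genes, signs)

    def test_full_strength_inhibitor_scores_minus_one(self):
        datasets, _ = generate_study(seed=7, n_genes=100, n_deg=5,
                                     n_datasets=1, pairs_per_dataset=(5,))
        universe = datasets[0].universe
        sig = self._signature(universe)
        db, truth = generate_reference_db(
            universe,
            spec=ReferenceSpec(n_compounds=3, n_inhibitors=1, strength=1.0,
                               replicates_range=(1, 1)),
            signature=sig, seed=8,
        )
        idx = db.profiles_of(truth.inhibitor_ids[0])[0]
        assert connection_score(sig, db.profile(idx)) == pytest.approx(-1.0)

    def test_full_strength_mimic_scores_plus_one(self):
        datasets, _ = generate_study(seed=9, n_genes=80, n_deg=5,
                                     n_datasets=1, pairs_per_dataset=(5,))
        universe = datasets[0].universe
        sig = self._signature(universe, m=8)
        db, truth = generate_reference_db(
            universe,
            spec=ReferenceSpec(n_compounds=3, n_inhibitors=0, n_mimics=1,
                               strength=1.0, replicates_range=(1, 1)),
            signature=sig, seed=10,
        )
        idx = db.profiles_of(truth.mimic_ids[0])[0]
        assert connection_score(sig, db.profile(idx)) == pytest.approx(1.0)

    def test_null_compound_p_uniform_over_database_draws(self):
        # a fixed signature against fresh random null profiles: the
        # directional p mapped through the null CDF must be uniform
        datasets, _ = generate_study(seed=11, n_genes=60, n_deg=0,
                                     n_datasets=1, pairs_per_dataset=(5,))
        universe = datasets[0].universe
        sig = self._signature(universe, m=3, seed=12)
        u = []
        for k in range(300):
            db, _ = generate_reference_db(
                universe,
                spec=ReferenceSpec(n_compounds=1, n_inhibitors=0,
                                   replicates_range=(1, 1)),
                seed=100 + k,
            )
            profile = db.profile(0)
            p = profile_p_value(sig, profile, n_null=1000, seed=k, method="mc")
            c = connection_score(sig, profile)
            u.append(p if c < 0 else 1 - p)
        assert stats.kstest(np.array(u), "uniform").pvalue > 0.01

    def test_nc_counts_compounds_not_replicates(self):
        datasets, _ = generate_study(seed=13, n_genes=50, n_deg=0,
                                     n_datasets=1, pairs_per_dataset=(5,))
        db, _ = generate_reference_db(
            datasets[0].universe,
            spec=ReferenceSpec(n_compounds=7, n_inhibitors=0,
                               replicates_range=(2, 4)),
            seed=14,
        )
        assert db.Nc == 7
        assert db.n_profiles >= 14

    def test_partition_of_compound_ids(self):
        datasets, _ = generate_study(seed=15, n_genes=50, n_deg=5,
                                     n_datasets=1, pairs_per_dataset=(5,))
        universe = datasets[0].universe
        sig = self._signature(universe, m=5, seed=16)
        _, truth = generate_reference_db(
            universe,
            spec=ReferenceSpec(n_compounds=10, n_inhibitors=3, n_mimics=2),
            signature=sig, seed=17,
        )
        ids = truth.inhibitor_ids + truth.mimic_ids + truth.null_ids
        assert len(ids) == 10
        assert len(set(ids)) == 10

    def test_planting_without_signature_rejected(self):
        datasets, _ = generate_study(seed=18, n_genes=50, n_deg=0,
                                     n_datasets=1, pairs_per_dataset=(5,))
        with pytest.raises(ValueError, match="requires a signature"):
            generate_reference_db(
                datasets[0].universe,
                spec=ReferenceSpec(n_compounds=5, n_inhibitors=1),
                seed=19,
            )


class TestMultiDatasetRecovery:
    def test_combined_ranking_beats_each_single_dataset(self):
        # scaled-down version of the study design: the combined ranking
        # must place more planted genes near the top than any single cohort
        datasets, truth = generate_study(
            seed=20, n_genes=800, n_deg=40, effect_log2=2.0,
            presence_prob=0.8, flip_prob=0.05,
            n_datasets=3, pairs_per_dataset=(12, 10, 14),
        )
        results = [run_diffexp(d) for d in datasets]
        vectors = [score_dataset(r) for r in results]
        combined = combine_scores(vectors)
        top = 60
        combined_hits = len(
            set(combined.frame.head(top).index) & set(truth.deg_ids)
        )
        for vec in vectors:
            single_rank = vec.scores.abs().sort_values(ascending=False)
            single_top = set(single_rank.head(top).index[
                single_rank.head(top) > 0
            ])
            single_hits = len(single_top & set(truth.deg_ids))
            assert combined_hits >= single_hits
        assert combined_hits >= 0.75 * 40
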