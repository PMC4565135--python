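import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmapsig import (
    ConnectivityMap,
    QuerySignature,
    ReferenceDatabase,
    compound_connection,
    connection_score,
    profile_p_value,
    significant_connections,
)
from cmapsig.connectivity import max_possible_sum

from conftest import make_profile, random_profile

HAND_PROFILE = {"g1": 1, "g2": 4, "g3": -3, "g4": 2}


def naive_score(signature: QuerySignature, ranks: dict[str, int]) -> float:
    """Independent oracle: direct signed-rank sum over the signature genes."""
    N, m = len(ranks), signature.m
    raw = sum(s * ranks[g] for g, s in zip(signature.genes, signature.signs))
    return raw / sum(range(N, N - m, -1))


def enumerate_null(ranks: dict[str, int], m: int) -> list[float]:
    """Independent oracle: scores of every signed m-gene signature."""
    genes = list(ranks)
    out = []
    for subset in itertools.combinations(genes, m):
        for signs in itertools.product((1, -1), repeat=m):
            out.append(naive_score(QuerySignature(subset, signs), ranks))
    return out


class TestConnectionScore:
    def test_hand_enumeration_case(self):
        profile = make_profile(HAND_PROFILE)
        sig = QuerySignature(("g1", "g3"), (1, -1))
        # raw = 1 + 3 = 4, max = 4 + 3 = 7
        assert connection_score(sig, profile) == pytest.approx(4 / 7)

    def test_perfect_agreement_scores_one(self):
        rng = np.random.default_rng(2)
        profile = random_profile(12, rng)
        ranks = profile.signed_ranks
        top = ranks.abs().sort_values(ascending=False).index[:4]
        sig = QuerySignature(
            tuple(top), tuple(int(np.sign(ranks[g])) for g in top)
        )
        assert connection_score(sig, profile) == pytest.approx(1.0)
        assert connection_score(sig.flipped(), profile) == pytest.approx(-1.0)

    @given(seed=st.integers(0, 999))
    def test_antisymmetry_under_sign_flip(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(3, 20))
        m = int(rng.integers(1, min(N, 6)))
        profile = random_profile(N, rng)
        genes = tuple(rng.choice(list(profile.signed_ranks.index), m, replace=False))
        signs = tuple(int(s) for s in rng.choice([-1, 1], m))
        sig = QuerySignature(genes, signs)
        assert connection_score(sig.flipped(), profile) == pytest.approx(
            -connection_score(sig, profile)
        )

    def test_invariant_to_genes_outside_signature(self):
        sig = QuerySignature(("g1", "g3"), (1, -1))
        a = make_profile({"g1": 1, "g2": 4, "g3": -3, "g4": 2})
        b = make_profile({"g1": 1, "g2": 2, "g3": -3, "g4": 4})  # g2/g4 swapped
        assert connection_score(sig, a) == connection_score(sig, b)

    def test_missing_gene_is_an_error(self):
        profile = make_profile(HAND_PROFILE)
        with pytest.raises(KeyError, match="not in universe"):
            connection_score(QuerySignature(("nope",), (1,)), profile)

    def test_score_range(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            N = int(rng.integers(2, 15))
            profile = random_profile(N, rng)
            m = int(rng.integers(1, N + 1))
            genes = tuple(rng.choice(list(profile.signed_ranks.index), m, replace=False))
            signs = tuple(int(s) for s in rng.choice([-1, 1], m))
            assert abs(connection_score(QuerySignature(genes, signs), profile)) <= 1


class TestProfilePValue:
    def test_exhaustive_singleton_case(self):
        profile = make_profile(HAND_PROFILE)
        sig = QuerySignature(("g2",), (1,))
        # cscore = 1; only 1 of the 8 signed singletons reaches it
        assert profile_p_value(sig, profile, method="exhaustive") == pytest.approx(1 / 8)

    def test_zero_score_has_p_about_half(self):
        # g1 rank +1 with sign chosen so raw = +1, nearly the null median
        profile = make_profile(HAND_PROFILE)
        sig = QuerySignature(("g1",), (1,))
        p = profile_p_value(sig, profile, method="exhaustive")
        assert p == pytest.approx(0.5, abs=0.15)

    def test_monte_carlo_agrees_with_exhaustive(self):
        rng = np.random.default_rng(13)
        for case in range(20):
            profile = random_profile(6, rng)
            genes = tuple(rng.choice(list(profile.signed_ranks.index), 2, replace=False))
            signs = tuple(int(s) for s in rng.choice([-1, 1], 2))
            sig = QuerySignature(genes, signs)
            exact = profile_p_value(sig, profile, method="exhaustive")
            n_null = 4000
            mc = profile_p_value(sig, profile, n_null=n_null, seed=case, method="mc")
            se = np.sqrt(exact * (1 - exact) / n_null)
            assert abs(mc - exact) <= 3 * se + 2 / n_null

    def test_exhaustive_matches_independent_enumeration(self):
        rng = np.random.default_rng(19)
        profile = random_profile(6, rng)
        ranks = profile.signed_ranks.to_dict()
        null = np.array(enumerate_null(ranks, 2))
        genes = ("g0", "g4")
        for signs in itertools.product((1, -1), repeat=2):
            sig = QuerySignature(genes, signs)
            obs = naive_score(sig, ranks)
            expected = (
                (null >= obs).mean() if obs >= 0 else (null <= obs).mean()
            )
            assert profile_p_value(sig, profile, method="exhaustive") == pytest.approx(
                expected
            )

    def test_mc_mode_requires_enough_draws(self):
        profile = make_profile(HAND_PROFILE)
        with pytest.raises(ValueError, match="n_null"):
            profile_p_value(
                QuerySignature(("g1",), (1,)), profile, n_null=10, method="mc"
            )

    def test_random_signature_mean_score_is_zero(self):
        # under the signed null the expected cscore is 0
        rng = np.random.default_rng(23)
        profile = random_profile(30, rng)
        ranks = profile.signed_ranks.to_numpy()
        draws = 10_000
        idx = np.array([rng.choice(30, 3, replace=False) for _ in range(draws)])
        signs = rng.choice([-1, 1], size=(draws, 3))
        scores = (signs * ranks[idx]).sum(axis=1) / max_possible_sum(30, 3)
        se = scores.std(ddof=1) / np.sqrt(draws)
        assert abs(scores.mean()) <= 3 * se


def _database(rng, n_compounds=6, N=40, reps=2):
    profiles = []
    for c in range(n_compounds):
        for r in range(reps):
            profiles.append(
                random_profile(N, rng, compound=f"c{c}", replicate_id=f"c{c}_r{r}")
            )
    return ReferenceDatabase.from_profiles(profiles)


class TestCompoundConnection:
    def test_single_replicate_equals_profile_score(self):
        rng = np.random.default_rng(31)
        profile = random_profile(20, rng, compound="solo")
        db = ReferenceDatabase.from_profiles([profile])
        sig = QuerySignature(("g0", "g5", "g9"), (1, -1, 1))
        res = compound_connection(sig, db, "solo", n_null=1000, seed=1)
        assert res.cscore == pytest.approx(connection_score(sig, profile))
        assert res.replicate_count == 1

    def test_independent_replicates_shrink_null_variance(self):
        # replicates that agree on the observed signal but are otherwise
        # independent average away null variance, boosting |z|
        from cmapsig.io import GeneUniverse
        from cmapsig.synthetic import ReferenceSpec, generate_reference_db

        universe = GeneUniverse(tuple(f"g{i}" for i in range(40)))
        sig = QuerySignature(
            tuple(f"g{i}" for i in range(5)), (1, -1, 1, 1, -1)
        )
        zs = {}
        for k in (1, 3):
            db, truth = generate_reference_db(
                universe,
                spec=ReferenceSpec(n_compounds=1, n_inhibitors=1,
                                   strength=1.0, replicates_range=(k, k)),
                signature=sig, seed=37,
            )
            res = compound_connection(
                sig, db, truth.inhibitor_ids[0], n_null=2000, seed=3
            )
            assert res.cscore == pytest.approx(-1.0)
            assert res.replicate_count == k
            zs[k] = res.z_score
        assert abs(zs[3]) > abs(zs[1])

    def test_unknown_compound_is_an_error(self):
        rng = np.random.default_rng(41)
        db = _database(rng)
        sig = QuerySignature(("g0",), (1,))
        with pytest.raises(KeyError, match="not in reference database"):
            compound_connection(sig, db, "missing", n_null=1000, seed=0)

    def test_query_null_calibration(self):
        # p of random signatures against one compound, mapped through the
        # null CDF, should be uniform (KS at alpha = 0.01)
        rng = np.random.default_rng(43)
        db = _database(rng, n_compounds=1, N=60, reps=2)
        engine = ConnectivityMap(db)
        u = []
        for k in range(400):
            genes = tuple(rng.choice(list(db.universe.genes), 4, replace=False))
            signs = tuple(int(s) for s in rng.choice([-1, 1], 4))
            res = engine.query(
                QuerySignature(genes, signs), n_null=1000, seed=k,
                direction_filter=None,
            )
            row = res.frame.iloc[0]
            p = row["p_value"]
            u.append(p if row["cscore"] < 0 else 1 - p)
        from scipy import stats

        assert stats.kstest(np.array(u), "uniform").pvalue > 0.01


class TestSignificantConnections:
    def _results(self):
        return pd.DataFrame(
            {
                "replicate_count": [182, 3, 2],
                "cscore": [-0.144, 0.3, -0.2],
                "p_value": [5.0e-6, 5.0e-6, 0.5],
                "z_score": [-5.87, 4.0, -0.1],
                "direction": ["negative", "positive", "negative"],
            },
            index=pd.Index(["tsa", "mimic", "dud"], name="compound"),
        )

    def test_threshold_and_direction_rule(self):
        # Efp=1 over 1309 compounds: threshold 1/1309 ~ 7.64e-4
        out = significant_connections(self._results(), efp=1.0, nc=1309,
                                      direction_filter="negative")
        assert list(out.index) == ["tsa"]

    def test_positive_direction_keeps_mimics(self):
        out = significant_connections(self._results(), efp=1.0, nc=1309,
                                      direction_filter="positive")
        assert list(out.index) == ["mimic"]

    def test_no_filter_keeps_both_tails(self):
        out = significant_connections(self._results(), efp=1.0, nc=1309,
                                      direction_filter=None)
        assert set(out.index) == {"tsa", "mimic"}

    def test_empty_input_gives_empty_output(self):
        empty = self._results().iloc[:0]
        assert len(significant_connections(empty, efp=1.0, nc=1309)) == 0

    def test_invalid_efp(self):
        with pytest.raises(ValueError, match="Efp"):
            significant_connections(self._results(), efp=0.0, nc=10)


class TestReferenceDatabaseIO:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(47)
        db = _database(rng, n_compounds=3, N=10, reps=2)
        path = tmp_path / "ref.tsv"
        db.to_tsv(path)
        back = ReferenceDatabase.from_tsv(path)
        assert back.Nc == db.Nc
        assert back.universe.genes == db.universe.genes
        sig = QuerySignature(("g0", "g3"), (1, -1))
        a = ConnectivityMap(db).query(sig, n_null=1000, seed=5, direction_filter=None)
        b = ConnectivityMap(back).query(sig, n_null=1000, seed=5, direction_filter=None)
        pd.testing.assert_frame_equal(
            a.frame.sort_index(), b.frame.sort_index(), check_exact=False
        )

    def test_bad_magnitudes_rejected(self, toy_universe):
        ranks = np.array([[1, 2, 2, 4]])
        with pytest.raises(ValueError, match="permute"):
            ReferenceDatabase(ranks, ["c"], ["r"], toy_universe)
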