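"""Early-recognition metrics, alpha calibration, combination search, hits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoscreen.screening_eval import (
    RankedScreen,
    active_ranks,
    alpha_for_mass_fraction,
    bedroc,
    combination_search,
    enrichment_factor,
    merge_screening_ledger,
    rie,
    select_consensus_hits,
    weight_mass_fraction,
)


def screen_with_active_ranks(N, ranks):
    """Distinct descending scores with actives at the given 1-based ranks."""
    scores = np.arange(N, 0, -1, dtype=float)
    labels = np.zeros(N, dtype=int)
    labels[np.asarray(ranks) - 1] = 1
    return RankedScreen(scores, labels)


def brute_force_rie(ranks, N, alpha):
    """Direct exponential-sum evaluation, no shared code with the package."""
    n = len(ranks)
    num = sum(math.exp(-alpha * r / N) for r in ranks)
    denom = (n / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1)
    return num / denom


def brute_force_bedroc(ranks, N, alpha):
    ra = len(ranks) / N
    rie_v = brute_force_rie(ranks, N, alpha)
    rie_min = (1 - math.exp(alpha * ra)) / (ra * (1 - math.exp(alpha)))
    rie_max = (1 - math.exp(-alpha * ra)) / (ra * (1 - math.exp(-alpha)))
    return (rie_v - rie_min) / (rie_max - rie_min)


def brute_force_ef(ranks, N, chi):
    window = max(1, math.floor(chi * N))
    hits = sum(1 for r in ranks if r <= window)
    return hits / (chi * len(ranks))


class TestMetricOracles:
    CASES = [
        (10, (1, 5), 20.0),
        (10, (1, 2), 5.0),
        (15, (3, 7, 11), 12.5),
        (20, (1, 10, 20), 160.9),
        (8, (2,), 3.0),
    ]

    @pytest.mark.parametrize("N,ranks,alpha", CASES)
    def test_rie_and_bedroc_match_brute_force(self, N, ranks, alpha):
        s = screen_with_active_ranks(N, ranks)
        assert rie(s, alpha) == pytest.approx(brute_force_rie(ranks, N, alpha), abs=1e-9)
        assert bedroc(s, alpha) == pytest.approx(
            brute_force_bedroc(ranks, N, alpha), abs=1e-9
        )

    @pytest.mark.parametrize("N,ranks,chi", [(10, (1, 5), 0.2), (20, (3, 18), 0.1)])
    def test_ef_matches_window_count(self, N, ranks, chi):
        s = screen_with_active_ranks(N, ranks)
        assert enrichment_factor(s, chi) == pytest.approx(
            brute_force_ef(ranks, N, chi), abs=1e-9
        )

    def test_perfect_and_worst_rankings_attain_bounds(self):
        for alpha in (5.0, 20.0, 160.9):
            best = screen_with_active_ranks(50, range(1, 6))
            worst = screen_with_active_ranks(50, range(46, 51))
            assert bedroc(best, alpha) == pytest.approx(1.0, abs=1e-9)
            assert bedroc(worst, alpha) == pytest.approx(0.0, abs=1e-9)

    def test_all_actives_in_window_gives_inverse_chi(self):
        s = screen_with_active_ranks(100, (1, 2, 3))
        assert enrichment_factor(s, 0.1) == pytest.approx(10.0)

    def test_no_actives_in_window_gives_zero(self):
        s = screen_with_active_ranks(100, (90, 95))
        assert enrichment_factor(s, 0.05) == 0.0

    def test_printed_screen_composition(self):
        """14 of 86 actives in the top 45 of 4,535 gives EF = 16.28 at 1%."""
        ranks = list(range(1, 15)) + list(range(200, 272))
        s = screen_with_active_ranks(4535, ranks)
        assert enrichment_factor(s, 0.01) == pytest.approx(14 / (0.01 * 86), abs=1e-9)
        assert enrichment_factor(s, 0.01) == pytest.approx(16.28, abs=0.005)

    def test_degenerate_screens_rejected(self):
        with pytest.raises(ValueError):
            RankedScreen(np.ones(5), np.ones(5, int))
        with pytest.raises(ValueError):
            RankedScreen(np.ones(5), np.zeros(5, int))

    def test_random_ranking_ef_expectation_near_one(self, rng):
        N, n, chi = 200, 20, 0.1
        labels = np.zeros(N, int)
        labels[:n] = 1
        efs = []
        for _ in range(300):
            scores = rng.permutation(N).astype(float)
            efs.append(enrichment_factor(RankedScreen(scores, labels), chi))
        assert 0.85 <= np.mean(efs) <= 1.15


class TestMetricProperties:
    def test_bedroc_in_unit_interval_and_monotone_under_exchange(self, rng):
        for _ in range(20):
            N = int(rng.integers(10, 40))
            n = int(rng.integers(1, N // 2))
            labels = np.zeros(N, int)
            labels[rng.choice(N, n, replace=False)] = 1
            scores = np.arange(N, 0, -1, dtype=float)
            s = RankedScreen(scores, labels)
            b = bedroc(s, 20.0)
            assert 0.0 <= b <= 1.0
            # swap the worst-ranked active with a better-ranked inactive
            act = np.flatnonzero(labels == 1)
            inact = np.flatnonzero(labels == 0)
            worst_act = act.max()
            better_inact = inact[inact < worst_act]
            if len(better_inact):
                labels2 = labels.copy()
                labels2[worst_act], labels2[better_inact.max()] = 0, 1
                assert bedroc(RankedScreen(scores, labels2), 20.0) >= b - 1e-12

    def test_invariance_under_monotone_score_transform(self, rng):
        scores = rng.normal(size=60)
        scores += np.linspace(0, 1e-6, 60)  # ensure distinct
        labels = np.zeros(60, int)
        labels[rng.choice(60, 12, replace=False)] = 1
        s1 = RankedScreen(scores, labels)
        s2 = RankedScreen(np.exp(3 * scores), labels)
        assert bedroc(s1, 20.0) == pytest.approx(bedroc(s2, 20.0), abs=1e-12)
        assert enrichment_factor(s1, 0.1) == enrichment_factor(s2, 0.1)

    def test_tie_break_is_seeded_and_reproducible(self):
        scores = np.zeros(30)
        labels = np.zeros(30, int)
        labels[:6] = 1
        s = RankedScreen(scores, labels)
        assert np.array_equal(active_ranks(s, seed=5), active_ranks(s, seed=5))


class TestAlphaCalibration:
    @pytest.mark.parametrize(
        "chi,mass,expected",
        [
            (0.01, 0.8, 160.94),
            (0.5, 1 - math.exp(-1), 2.0),
            (0.05, 0.8, 32.19),
        ],
    )
    def test_hand_values(self, chi, mass, expected):
        assert alpha_for_mass_fraction(chi, mass) == pytest.approx(expected, abs=0.005)

    def test_boundary_arguments_rejected(self):
        for chi, mass in [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)]:
            with pytest.raises(ValueError):
                alpha_for_mass_fraction(chi, mass)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0.001, 0.999),
        st.floats(0.001, 0.999),
    )
    def test_mutual_inverse_with_weight_mass(self, chi, mass):
        alpha = alpha_for_mass_fraction(chi, mass)
        assert weight_mass_fraction(alpha, chi) == pytest.approx(mass, abs=1e-9)


class TestCombinationSearch:
    def _tables(self, rng, n=400, n_cells=4, good_family="E"):
        labels = np.zeros(n, int)
        labels[rng.choice(n, 40, replace=False)] = 1
        probs, domains = {}, {}
        for c in range(n_cells):
            cell = f"CL{c}"
            probs[cell], domains[cell] = {}, {}
            for fam in ("RF", "DTREE", "KNN", "E"):
                noise = 0.3 if fam == good_family else 3.0
                p = labels + rng.normal(0, noise, n)
                probs[cell][fam] = 1 / (1 + np.exp(-p))
                domains[cell][fam] = np.ones(n, bool)
        return probs, domains, labels

    def test_enumerates_all_family_power_combinations(self, rng):
        probs, domains, labels = self._tables(rng)
        results = combination_search(probs, domains, labels)
        assert len(results) == 4**4
        assert len({tuple(sorted(r.choice.items())) for r in results}) == 256

    def test_identical_probabilities_consensus_is_that_value(self, rng):
        probs, domains, _ = self._tables(rng)
        for cell in probs:
            for fam in probs[cell]:
                probs[cell][fam] = np.full(400, 0.37)
        results = combination_search(probs, domains, labels=None)
        for r in results[:5]:
            assert np.allclose(r.consensus_scores, 0.37)

    def test_better_calibrated_family_ranks_first(self, rng):
        probs, domains, labels = self._tables(rng, good_family="E")
        results = combination_search(probs, domains, labels)
        assert set(results[0].choice.values()) == {"E"}

    def test_out_of_domain_compounds_excluded(self, rng):
        probs, domains, labels = self._tables(rng)
        domains["CL0"]["RF"] = np.zeros(400, bool)
        domains["CL0"]["RF"][:200] = True
        results = combination_search(probs, domains, labels)
        rf0 = [r for r in results if r.choice["CL0"] == "RF"][0]
        assert rf0.n_in_domain == 200
        assert np.isnan(rf0.consensus_scores[200:]).all()

    def test_empty_domain_rejected(self, rng):
        probs, domains, labels = self._tables(rng)
        for fam in domains["CL1"]:
            domains["CL1"][fam] = np.zeros(400, bool)
        with pytest.raises(ValueError):
            combination_search(probs, domains, labels)


class TestConsensusHits:
    def test_disjoint_exceedance_sets_empty_intersection(self):
        a = {"k1": 0.9, "k2": 0.1, "k3": 0.2}
        b = {"k1": 0.1, "k2": 0.9, "k3": 0.2}
        rep = select_consensus_hits(a, b)
        assert all(len(h) == 0 for h in rep.hits.values())
        assert rep.exceedance_a[0.5] == 1 and rep.exceedance_b[0.5] == 1

    def test_all_below_threshold_empty(self):
        a = {"k1": 0.2, "k2": 0.3}
        b = {"k1": 0.9, "k2": 0.9}
        rep = select_consensus_hits(a, b)
        assert all(len(h) == 0 for h in rep.hits.values())

    def test_intersections_match_brute_force_set_arithmetic(self, rng):
        keys = [f"c{i}" for i in range(1000)]
        a = dict(zip(keys, rng.random(1000)))
        b = dict(zip(keys, rng.random(1000)))
        rep = select_consensus_hits(a, b, thresholds=(0.5, 0.55, 0.6))
        for t in (0.5, 0.55, 0.6):
            expected = {k for k in keys if a[k] > t} & {k for k in keys if b[k] > t}
            assert rep.hits[t] == expected

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            select_consensus_hits({"a": 1.0}, {"b": 1.0})


class TestLedgerMerge:
    def test_overlapping_keys_deduplicated_eval_wins(self):
        eva = pd.DataFrame(
            {"smiles": ["CCO", "CCN"], "inchikey": ["K1", "K2"], "label": [1, 0]}
        )
        dec = pd.DataFrame({"smiles": ["CCO", "CCC"], "inchikey": ["K1", "K3"]})
        merged = merge_screening_ledger(eva, dec)
        assert len(merged) == 3
        assert merged.set_index("inchikey").loc["K1", "label"] == 1

    def test_keys_computed_when_absent(self):
        eva = pd.DataFrame({"smiles": ["CCO"], "label": [1]})
        dec = pd.DataFrame({"smiles": ["OCC"]})  # same molecule, different notation
        merged = merge_screening_ledger(eva, dec)
        assert len(merged) == 1
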