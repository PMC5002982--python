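import numpy as np
import pingouin as pg
import pytest
from scipy.spatial.distance import pdist, squareform

from chromapop._angles import circ_dist
from chromapop.geometry import (
    RDM,
    compare_rsa_paired,
    hue_angle_rdm,
    neural_rdm,
    rsa_correlation,
    sammon_mds,
    zscore_rates,
)
from chromapop.synth import model_population_rates


class TestNeuralRdm:
    def test_diagonal_is_zero(self):
        rng = np.random.default_rng(1)
        rdm = neural_rdm(rng.normal(size=(6, 10)))
        assert np.allclose(np.diag(rdm.d), 0.0)
        assert np.allclose(rdm.d, rdm.d.T)

    def test_toy_anticorrelated_stimuli(self):
        # 3 neurons; s1 = (1,2,3), s2 = (3,2,1): rho = -1 so d = 2
        rates = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])  # neurons x stim
        rdm = neural_rdm(rates, normalize=False)
        assert rdm.d[0, 1] == pytest.approx(2.0)

    def test_zero_variance_stimulus_dropped(self):
        rates = np.array([[1.0, 2.0, 5.0],
                          [2.0, 4.0, 5.0],
                          [3.0, 1.0, 5.0]])
        rdm = neural_rdm(rates, labels=["a", "b", "c"], normalize=False)
        assert rdm.labels == ["a", "b"]
        assert rdm.d.shape == (2, 2)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        rates = rng.normal(size=(8, 12))
        scaled = rates * rng.uniform(0.5, 4, size=(8, 1)) + \
            rng.normal(size=(8, 1))
        d1 = neural_rdm(rates).d
        d2 = neural_rdm(scaled).d
        assert np.allclose(d1, d2, atol=1e-10)


class TestHueAngleRdm:
    def test_wrap_and_antipodal_entries(self):
        import pandas as pd
        tab = pd.DataFrame({
            "stimulus_id": ["a", "b", "c"],
            "luminance_class": "equi",
            "hue_angle_deg": [0.0, 350.0, 90.0],
        })
        rdm = hue_angle_rdm(tab)
        assert rdm.d[0, 1] == pytest.approx(10.0)
        tab2 = pd.DataFrame({
            "stimulus_id": ["a", "b"],
            "luminance_class": "equi",
            "hue_angle_deg": [90.0, 270.0],
        })
        assert hue_angle_rdm(tab2).d[0, 1] == pytest.approx(180.0)

    def test_matches_brute_force_on_full_set(self, equi):
        rdm = hue_angle_rdm(equi)
        ang = equi.hue_angle_deg.to_numpy()
        for i in range(0, 45, 7):
            for j in range(0, 45, 5):
                expected = min(abs(ang[i] - ang[j]),
                               360 - abs(ang[i] - ang[j]))
                assert rdm.d[i, j] == pytest.approx(expected)


class TestSammonMds:
    def test_exactly_embeddable_configuration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 2))
        d = squareform(pdist(pts))
        emb = sammon_mds(RDM(labels=list(range(15)), d=d, metric="x"),
                         k=2, n_restarts=3, seed=0)
        assert emb.stress < 1e-3

    def test_stress_non_increasing_in_k(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 5))
        d = squareform(pdist(pts))
        rdm = RDM(labels=list(range(12)), d=d, metric="x")
        stresses = [sammon_mds(rdm, k=k, n_restarts=3, seed=1).stress
                    for k in range(1, 6)]
        for a, b in zip(stresses, stresses[1:]):
            assert b <= a + 1e-9

    def test_recovers_circular_hue_order(self, equi):
        # narrow uniformly tuned population: the 2-D embedding must place
        # stimuli on a closed curve in hue order
        peaks = np.arange(0, 360, 6.0)
        rates = model_population_rates(peaks, 70.0, equi,
                                       use_saturation=False)
        rdm = neural_rdm(rates, labels=list(equi.stimulus_id))
        emb = sammon_mds(rdm, k=2, n_restarts=5, seed=2)
        xy = emb.coords - emb.coords.mean(axis=0)
        emb_ang = np.degrees(np.arctan2(xy[:, 1], xy[:, 0]))
        hue = equi.hue_angle_deg.to_numpy()
        r = abs(pg.circ_corrcc(np.radians(emb_ang), np.radians(hue))[0])
        assert r > 0.9

    def test_nonfinite_rdm_raises(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            sammon_mds(RDM(labels=list(range(4)), d=d, metric="x"), k=2)


class TestRsa:
    def test_self_correlation_is_one(self, equi):
        rdm = hue_angle_rdm(equi)
        r, p = rsa_correlation(rdm, rdm)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_shuffled_reference_centers_at_zero(self, equi):
        rng = np.random.default_rng(5)
        rdm = hue_angle_rdm(equi)
        rs = []
        for _ in range(100):
            perm = rng.permutation(45)
            shuffled = RDM(labels=rdm.labels,
                           d=rdm.d[np.ix_(perm, perm)], metric=rdm.metric)
            rs.append(rsa_correlation(rdm, shuffled)[0])
        assert abs(np.mean(rs)) < 0.05

    def test_narrow_uniform_population_tracks_hue_space(self, equi):
        peaks = np.arange(0, 360, 6.0)
        rates = model_population_rates(peaks, 70.0, equi,
                                       use_saturation=False)
        nrdm = neural_rdm(rates, labels=list(equi.stimulus_id))
        r, p = rsa_correlation(nrdm, hue_angle_rdm(equi))
        assert r > 0.7
        assert p < 0.001

    def test_too_few_common_stimuli_raises(self):
        a = RDM(labels=["x", "y"], d=np.zeros((2, 2)), metric="m")
        with pytest.raises(ValueError):
            rsa_correlation(a, a)

    def test_labels_intersected_before_correlation(self, equi):
        rates = np.random.default_rng(6).normal(size=(10, 45))
        nrdm = neural_rdm(rates, labels=list(equi.stimulus_id))
        trimmed = RDM(labels=nrdm.labels[:40], d=nrdm.d[:40, :40],
                      metric=nrdm.metric)
        r, _ = rsa_correlation(trimmed, hue_angle_rdm(equi))
        assert -1.0 <= r <= 1.0


class TestCompareRsaPaired:
    def test_identical_distributions_give_p_one(self):
        r = np.random.default_rng(7).uniform(0.2, 0.8, 50)
        assert compare_rsa_paired(r, r) == 1.0

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.7, 0.01, 50)
        b = rng.normal(0.3, 0.01, 50)
        assert compare_rsa_paired(a, b) < 1e-3

    def test_glob_like_more_hue_correlated_than_interglob_like(self, table, equi):
        # narrow, strongly modulated populations track hue space more
        # closely than broad weakly modulated ones once trial noise is in
        # play (width alone does not decide it: a noiseless cosine
        # population correlates near-perfectly with angular distance)
        from chromapop.synth import simulate_recorded_population
        href = hue_angle_rdm(equi)
        rs = {}
        for kind in ("glob", "interglob"):
            vals = []
            for seed in range(8):
                pop = simulate_recorded_population(kind, 60, table,
                                                   seed=seed, n_trials=3)
                idx = [pop.stimulus_ids.index(s) for s in equi.stimulus_id]
                vals.append(rsa_correlation(
                    neural_rdm(pop.rates[:, idx],
                               labels=list(equi.stimulus_id)), href)[0])
            rs[kind] = np.array(vals)
        assert rs["glob"].mean() > rs["interglob"].mean()
        assert compare_rsa_paired(rs["glob"], rs["interglob"]) < 0.05


def test_zscore_rows_have_unit_scale():
    rng = np.random.default_rng(10)
    z = zscore_rates(rng.normal(3, 7, size=(5, 30)))
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(z.std(axis=1), 1.0, atol=1e-12)
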