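import numpy as np
import pytest

from torves import (
    WeightedSamples,
    cluster_states,
    label_states,
    select_high_weight,
    state_fe_difference,
    state_free_energies,
    state_free_energy,
)
from torves.constants import beta as beta_of, kt
from torves.states import MetastableState, toroidal_distance

BETA = beta_of(300.0)
KT = kt(300.0)


def _ws(phi, psi, weights=None, mask=None):
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = phi.size
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    mask = np.ones(n, dtype=bool) if mask is None else mask
    bias = np.log(np.maximum(weights, 1e-300)) / BETA
    return WeightedSamples(np.arange(n, dtype=float), phi, psi, bias, weights, mask, BETA)


def _blob(rng, center, n, spread=0.05):
    return (
        center[0] + rng.normal(0, spread, n),
        center[1] + rng.normal(0, spread, n),
    )


class TestSelectHighWeight:
    def test_huge_cutoff_keeps_every_unmasked_sample(self):
        ws = _ws(np.zeros(10), np.zeros(10), weights=np.linspace(0.01, 1, 10))
        assert select_high_weight(ws, 1e6).size == 10

    def test_threshold_arithmetic_on_the_fe_scale(self):
        ws = _ws(np.zeros(3), np.zeros(3), weights=np.array([1.0, 0.5, 0.1]))
        kept = select_high_weight(ws, KT * np.log(2) + 1e-9)
        np.testing.assert_array_equal(kept, [0, 1])

    def test_tiny_cutoff_keeps_only_the_weight_maximum(self):
        ws = _ws(np.zeros(4), np.zeros(4), weights=np.array([0.2, 1.0, 0.5, 0.9]))
        np.testing.assert_array_equal(select_high_weight(ws, 1e-6), [1])

    def test_empty_sieve_raises_with_advice(self):
        # weights not rescaled to a max of 1 (constructed directly)
        ws = _ws(np.zeros(3), np.zeros(3), weights=np.array([1e-9, 1e-8, 1e-9]))
        with pytest.raises(ValueError, match="increase fe_cutoff"):
            select_high_weight(ws, 1.0)
        with pytest.raises(ValueError):
            select_high_weight(ws, -1.0)


class TestClustering:
    def test_four_tight_blobs_resolve_to_four_clusters(self):
        rng = np.random.default_rng(0)
        centers = [(0, 0), (np.pi, 0), (0, np.pi), (np.pi, np.pi)]
        phi, psi = [], []
        for c in centers:
            p, q = _blob(rng, c, 200)
            phi.append(p)
            psi.append(q)
        ws = _ws(np.concatenate(phi), np.concatenate(psi))
        states = cluster_states(ws, np.arange(800), toroidal_eps=0.5, min_members=10)
        assert len(states) == 4
        for c in centers:
            d = [toroidal_distance(s.centroid, c) for s in states]
            nearest = states[int(np.argmin(d))]
            assert min(d) < 0.1
            # memberships: every member of the matched cluster lies near c
            pts = np.column_stack([ws.phi[nearest.members], ws.psi[nearest.members]])
            assert np.all(toroidal_distance(pts, np.asarray(c)) < 0.5)

    def test_single_blob_is_one_cluster(self):
        rng = np.random.default_rng(1)
        phi, psi = _blob(rng, (1.0, -1.0), 100)
        states = cluster_states(_ws(phi, psi), np.arange(100), 0.5, 10)
        assert len(states) == 1

    def test_blob_straddling_the_seam_is_one_cluster_with_seam_centroid(self):
        rng = np.random.default_rng(2)
        phi = np.pi - 0.02 + rng.normal(0, 0.08, 300)  # wraps past +pi
        phi = np.mod(phi + np.pi, 2 * np.pi) - np.pi
        psi = rng.normal(0.5, 0.05, 300)
        states = cluster_states(_ws(phi, psi), np.arange(300), 0.5, 10)
        assert len(states) == 1
        assert abs(abs(states[0].centroid[0]) - np.pi) < 0.1

    def test_clustering_is_permutation_invariant(self):
        rng = np.random.default_rng(3)
        phi1, psi1 = _blob(rng, (0, 0), 150)
        phi2, psi2 = _blob(rng, (np.pi, np.pi), 150)
        phi = np.concatenate([phi1, phi2])
        psi = np.concatenate([psi1, psi2])
        perm = rng.permutation(300)
        a = cluster_states(_ws(phi, psi), np.arange(300), 0.5, 10)
        b = cluster_states(_ws(phi[perm], psi[perm]), np.arange(300), 0.5, 10)
        assert len(a) == len(b) == 2
        for sa, sb in zip(a, b):
            assert toroidal_distance(sa.centroid, sb.centroid) < 1e-9
            assert sa.member_count == sb.member_count


class TestLabeling:
    def test_centroid_on_reference_gets_its_label(self):
        s = MetastableState("unassigned", np.arange(5), (np.pi, np.pi))
        (labeled,) = label_states([s])
        assert labeled.label == "S_c"

    def test_labeling_is_invariant_to_cluster_order(self):
        states = [
            MetastableState("unassigned", np.arange(3), (0.1, 0.0)),
            MetastableState("unassigned", np.arange(3), (np.pi - 0.1, 0.0)),
            MetastableState("unassigned", np.arange(3), (0.0, np.pi + 0.2)),
        ]
        fwd = {s.centroid: s.label for s in label_states(states)}
        rev = {s.centroid: s.label for s in label_states(states[::-1])}
        assert fwd == rev
        assert set(fwd.values()) == {"S_m", "S_h", "S_v"}

    def test_conflicting_clusters_resolve_by_distance(self):
        near = MetastableState("unassigned", np.arange(3), (0.05, 0.0))
        far = MetastableState("unassigned", np.arange(3), (0.6, 0.0))
        labeled = label_states([near, far])
        assert labeled[0].label == "S_m"
        assert labeled[1].label != "S_m"
        assert labeled[1].label in {"S_v", "S_h", "S_c"}


class TestStateFreeEnergies:
    def test_single_state_holding_all_samples_is_zero(self):
        ws = _ws(np.zeros(100), np.zeros(100))
        s = MetastableState("S_m", np.arange(100), (0.0, 0.0))
        assert state_free_energy(ws, s) == pytest.approx(0.0, abs=1e-12)

    def test_equal_weight_split_gives_both_zero_after_shift(self):
        ws = _ws(np.zeros(100), np.zeros(100))
        a = MetastableState("S_m", np.arange(50), (0.0, 0.0))
        b = MetastableState("S_h", np.arange(50, 100), (np.pi, 0.0))
        fa, fb = [s.free_energy for s in state_free_energies(ws, [a, b])]
        assert fa == pytest.approx(0.0, abs=1e-12)
        assert fb == pytest.approx(0.0, abs=1e-12)

    def test_two_to_one_weight_ratio_gives_kt_ln2(self):
        weights = np.concatenate([np.ones(200), np.full(100, 1.0)])
        ws = _ws(np.zeros(300), np.zeros(300), weights=weights)
        big = MetastableState("S_m", np.arange(200), (0.0, 0.0))
        small = MetastableState("S_h", np.arange(200, 300), (np.pi, 0.0))
        states = state_free_energies(ws, [big, small])
        assert states[0].free_energy == pytest.approx(0.0, abs=1e-12)
        assert states[1].free_energy == pytest.approx(KT * np.log(2), abs=1e-9)

    def test_empty_state_raises(self):
        ws = _ws(np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            state_free_energy(ws, MetastableState("S_m", np.array([], dtype=int), (0, 0)))

    def test_weight_shares_sum_to_at_most_one(self):
        rng = np.random.default_rng(5)
        ws = _ws(rng.uniform(-np.pi, np.pi, 500), rng.uniform(-np.pi, np.pi, 500))
        a = MetastableState("S_m", np.arange(200), (0, 0))
        b = MetastableState("S_h", np.arange(200, 450), (np.pi, 0))
        shares = [
            ws.weights[s.members].sum() / ws.weights[ws.mask].sum() for s in (a, b)
        ]
        assert sum(shares) <= 1.0 + 1e-12
        full = MetastableState("S_m", np.arange(500), (0, 0))
        assert ws.weights[full.members].sum() / ws.weights[ws.mask].sum() == pytest.approx(1.0)


class TestStateDifferences:
    def _labeled(self, fes):
        return [
            MetastableState(lab, np.arange(3), (0.0, 0.0), f) for lab, f in fes.items()
        ]

    def test_identical_landscapes_have_zero_differences(self):
        a = self._labeled({"S_m": 0.0, "S_h": 3.0})
        d = state_fe_difference(a, self._labeled({"S_m": 0.0, "S_h": 3.0}))
        assert d == {"S_m": 0.0, "S_h": 0.0}

    def test_deepened_state_in_b_shows_positive_difference(self):
        a = self._labeled({"S_m": 5.0, "S_h": 0.0})
        b = self._labeled({"S_m": 0.0, "S_h": 0.0})
        assert state_fe_difference(a, b)["S_m"] == pytest.approx(5.0)

    def test_state_more_populated_in_a_is_negative(self):
        a = self._labeled({"S_c": 0.0, "S_h": 2.0})
        b = self._labeled({"S_c": 4.0, "S_h": 2.0})
        d = state_fe_difference(a, b)
        assert d["S_c"] < 0

    def test_missing_labels_are_absent_not_zero(self):
        a = self._labeled({"S_m": 0.0, "S_v": 1.0})
        b = self._labeled({"S_m": 0.0, "S_c": 1.0})
        d = state_fe_difference(a, b)
        assert set(d) == {"S_m"}
        with pytest.raises(ValueError):
            state_fe_difference(self._labeled({"S_v": 0.0}), self._labeled({"S_c": 0.0}))


def test_four_state_boltzmann_mixture_recovers_basin_free_energies():
    """Exact draws from a four-component Boltzmann mixture with known
    basin free energies are recovered by sieve -> cluster -> label -> FE."""
    rng = np.random.default_rng(8)
    centers = {"S_m": (0, 0), "S_h": (np.pi, 0), "S_v": (0, np.pi), "S_c": (np.pi, np.pi)}
    true_fe = {"S_m": 0.0, "S_h": 3.0, "S_v": 7.0, "S_c": 5.0}
    probs = np.array([np.exp(-BETA * true_fe[k]) for k in centers])
    probs /= probs.sum()
    n = 1_000_000
    counts = rng.multinomial(n, probs)
    phi, psi = [], []
    for (label, c), m in zip(centers.items(), counts):
        phi.append(c[0] + rng.vonmises(0, 50.0, m))
        psi.append(c[1] + rng.vonmises(0, 50.0, m))
    phi = np.mod(np.concatenate(phi) + np.pi, 2 * np.pi) - np.pi
    psi = np.mod(np.concatenate(psi) + np.pi, 2 * np.pi) - np.pi
    ws = _ws(phi, psi)
    idx = select_high_weight(ws, 1e6)
    clusters = cluster_states(ws, idx, toroidal_eps=0.5, min_members=10)
    labeled = state_free_energies(ws, label_states(clusters))
    assert len(labeled) == 4
    recovered = {s.label: s.free_energy for s in labeled}
    for lab, f in true_fe.items():
        assert recovered[lab] == pytest.approx(f, abs=0.3)
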