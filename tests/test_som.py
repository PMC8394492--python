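"""SOM training, BMU lookup and the E-matrix projection."""

import numpy as np
import pytest

from tsocclude import (
    SOMConfig,
    SubSignal,
    bmu,
    build_e_matrix,
    train_som,
    unit_members,
)
from tsocclude.som import load_som, save_som, subsignal_matrix


def make_subsignals(rng, count=30, length=12, prototypes=None):
    """Scored sub-signals drawn around optional prototype shapes."""
    if prototypes is None:
        prototypes = [rng.normal(size=length)]
    out = []
    for i in range(count):
        proto = prototypes[i % len(prototypes)]
        values = proto + 0.05 * rng.normal(size=length)
        out.append(
            SubSignal(values=values, series_index=i, signal_index=0,
                      window_index=i % 4, start=0, end=length,
                      score=float(rng.uniform(0.1, 1.0)))
        )
    return out


SMALL = SOMConfig(rows=4, cols=5, sigma=1.0, learning_rate=0.5, steps=400, seed=11)


class TestTraining:
    def test_reproducible_given_seed(self, rng):
        G = make_subsignals(rng)
        w1 = train_som(G, SMALL).weights
        w2 = train_som(G, SMALL).weights
        assert np.array_equal(w1, w2)

    def test_single_input_attracts_weights(self, rng):
        G = make_subsignals(rng, count=1)
        som = train_som(G, SMALL)
        dists = np.linalg.norm(som.weights - G[0].values, axis=-1)
        assert dists.min() < 0.05  # some unit converged onto the lone input

    def test_identical_inputs_share_bmu(self, rng):
        proto = rng.normal(size=10)
        G = [SubSignal(values=proto, series_index=i, signal_index=0, window_index=0,
                       start=0, end=10, score=0.5) for i in range(5)]
        som = train_som(G, SMALL)
        units = {bmu(som, s.values) for s in G}
        assert len(units) == 1

    def test_separated_clusters_map_to_disjoint_regions(self, rng):
        """Sine vs spike prototypes occupy different grid neighbourhoods."""
        t = np.linspace(0, 2 * np.pi, 16)
        sine = np.sin(t)
        spike = np.zeros(16)
        spike[8] = 3.0
        G = make_subsignals(rng, count=40, length=16, prototypes=[sine, spike])
        som = train_som(G, SOMConfig(rows=6, cols=6, sigma=1.5, learning_rate=0.5,
                                     steps=2000, seed=4))
        bmus = np.array([bmu(som, s.values) for s in G])
        sine_cells, spike_cells = bmus[0::2], bmus[1::2]
        assert not {tuple(c) for c in sine_cells} & {tuple(c) for c in spike_cells}
        # weak topographic sanity: intra-cluster spread < inter-cluster distance
        intra = max(np.ptp(sine_cells, axis=0).max(), np.ptp(spike_cells, axis=0).max())
        inter = np.linalg.norm(sine_cells.mean(axis=0) - spike_cells.mean(axis=0))
        assert inter > 0

    def test_heterogeneous_lengths_zero_padded(self, rng):
        G = make_subsignals(rng, count=4, length=10)
        short = SubSignal(values=np.ones(6), series_index=99, signal_index=0,
                          window_index=3, start=0, end=6, score=0.2, truncated=True)
        mat = subsignal_matrix(G + [short])
        assert mat.shape == (5, 10)
        assert np.array_equal(mat[-1], np.r_[np.ones(6), np.zeros(4)])


class TestBmu:
    def test_exact_weight_vector_maps_to_its_unit(self, rng):
        som = train_som(make_subsignals(rng), SMALL)
        assert bmu(som, som.weights[2, 3]) == (2, 3)

    def test_tie_broken_row_major(self):
        cfg = SOMConfig(rows=2, cols=2, sigma=1.0, learning_rate=0.5, steps=1, seed=0)
        weights = np.zeros((2, 2, 3))  # all units equidistant from any query
        from tsocclude.som import SOMGrid

        som = SOMGrid(weights=weights, config=cfg)
        assert bmu(som, np.ones(3)) == (0, 0)

    def test_matches_exhaustive_scan(self, rng):
        som = train_som(make_subsignals(rng, length=8), SMALL)
        for _ in range(100):
            query = rng.normal(size=8)
            dists = np.linalg.norm(som.weights - query, axis=-1)
            expected = np.unravel_index(np.argmin(dists), dists.shape)
            assert bmu(som, query) == tuple(int(c) for c in expected)

    def test_length_mismatch(self, rng):
        som = train_som(make_subsignals(rng, length=8), SMALL)
        with pytest.raises(Exception):
            bmu(som, np.zeros(9))


class TestEMatrix:
    def test_single_subsignal_accumulates_its_score(self, rng):
        G = make_subsignals(rng, count=1)
        som = train_som(G, SMALL)
        E = build_e_matrix(som, G)
        cell = bmu(som, G[0].values)
        assert E.values[cell] == pytest.approx(G[0].score)
        assert E.counts.sum() == 1
        assert np.count_nonzero(E.values) == 1

    def test_conservation_and_partition(self, rng):
        G = make_subsignals(rng, count=50)
        som = train_som(G, SMALL)
        E = build_e_matrix(som, G, normalize=False)
        assert (E.values * E.counts).sum() == pytest.approx(
            sum(s.score for s in G), rel=1e-12
        )
        assert E.counts.sum() == len(G)

    def test_member_lists_partition_g(self, rng):
        G = make_subsignals(rng, count=25)
        som = train_som(G, SMALL)
        total = 0
        for u in range(som.config.rows):
            for v in range(som.config.cols):
                total += len(unit_members(som, G, (u, v)))
        assert total == len(G)

    def test_normalization_range_and_degenerate_case(self, rng):
        G = make_subsignals(rng, count=40)
        som = train_som(G, SMALL)
        E = build_e_matrix(som, G, normalize=True)
        occupied = E.counts > 0
        assert E.values[occupied].min() >= 0 and E.values[occupied].max() == 1.0
        assert np.all(E.values[~occupied] == 0)
        # all-equal scores: every occupied cell normalizes to 1.0
        G_flat = [SubSignal(values=s.values, series_index=s.series_index,
                            signal_index=0, window_index=s.window_index,
                            start=s.start, end=s.end, score=0.7) for s in G]
        E_flat = build_e_matrix(som, G_flat, normalize=True)
        occ = E_flat.counts > 0
        assert np.all(E_flat.values[occ] == 1.0)

    def test_empty_set_warns_and_zeroes(self, rng):
        som = train_som(make_subsignals(rng), SMALL)
        with pytest.warns(UserWarning):
            E = build_e_matrix(som, [])
        assert E.counts.sum() == 0 and np.all(E.values == 0)


class TestPersistence:
    def test_hdf5_roundtrip(self, rng, tmp_path):
        som = train_som(make_subsignals(rng), SMALL)
        save_som(tmp_path / "som.h5", som)
        loaded = load_som(tmp_path / "som.h5")
        assert np.array_equal(loaded.weights, som.weights)
        assert loaded.config == som.config
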