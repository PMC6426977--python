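"""DS vectors: sub-window layout, grid binning, and feature-set assembly."""

import numpy as np
import pytest

from dstab import DSGrid, SurrogateSpec, bin_modes, make_ds_vectors, subwindow_starts
from dstab.io import InfeasibleError
from dstab.modes import ModeSet


def modeset_from(tau, f):
    tau = np.asarray(tau, dtype=float)
    f = np.asarray(f, dtype=float)
    rho = np.exp(tau * 1e-3)
    return ModeSet(rho=rho, phi=2 * np.pi * f * 1e-3, f=f, tau=tau)


def brute_force_bins(tau, f, grid):
    """Independent double-loop histogram used as the binning oracle."""
    counts = np.zeros(grid.dim, dtype=int)
    te, fe = grid.tau_edges, grid.log2f_edges
    for t, x in zip(tau, f):
        if x <= 0:
            continue
        lx = np.log2(x)
        if not (te[0] <= t <= te[-1]) or not (fe[0] <= lx <= fe[-1]):
            continue
        ti = min(int((t - te[0]) / (te[1] - te[0])), grid.n_tau_bins - 1)
        fi = min(int((lx - fe[0]) / (fe[1] - fe[0])), grid.n_f_bins - 1)
        counts[ti * grid.n_f_bins + fi] += 1
    return counts


class TestSubwindowStarts:
    def test_five_second_segment_tiles_exactly(self):
        starts = subwindow_starts(0.0, 5.0)
        np.testing.assert_allclose(starts, np.arange(10) * 0.5)

    def test_degenerate_segment_duplicates(self):
        starts = subwindow_starts(2.0, 0.5)
        np.testing.assert_allclose(starts, [2.0] * 10)

    def test_two_second_segment_spacing(self):
        starts = subwindow_starts(0.0, 2.0)
        np.testing.assert_allclose(np.diff(starts), [(2.0 - 0.5) / 9] * 9)

    def test_below_subwindow_length_infeasible(self):
        with pytest.raises(InfeasibleError):
            subwindow_starts(0.0, 0.4)


class TestBinning:
    def test_dimension_is_400(self):
        vec = bin_modes([modeset_from([-10.0], [32.0])])
        assert vec.counts.shape == (400,)
        assert DSGrid().dim == 400

    def test_empty_in_range_set_yields_zero_vector(self):
        vec = bin_modes([modeset_from([-300.0, 50.0], [1.0, 300.0])])
        assert vec.counts.sum() == 0
        assert vec.n_modes_total == 2
        assert vec.n_modes_in_range == 0

    def test_single_mode_lands_at_derived_index(self):
        # tau = -100 -> bin 10 (width 13.75); f = 16 Hz -> bin 6 (width 0.3 log2)
        vec = bin_modes([modeset_from([-100.0], [16.0])])
        assert vec.counts[20 * 10 + 6] == 1
        assert vec.counts.sum() == 1

    def test_count_conservation_at_full_occupancy(self, rng):
        sets = [
            modeset_from(rng.uniform(-249, 24, 128), rng.uniform(5, 255, 128))
            for _ in range(10)
        ]
        vec = bin_modes(sets)
        assert vec.counts.sum() == 1280
        assert vec.n_modes_total == 1280

    def test_top_edges_closed(self):
        vec = bin_modes([modeset_from([25.0, -250.0], [256.0, 4.0])])
        assert vec.counts.sum() == 2
        assert vec.counts[-1] == 1  # (tau=25, f=256) in the last cell
        assert vec.counts[0] == 1  # (tau=-250, f=4) in the first cell

    @pytest.mark.parametrize("n_modes", [10, 1000, 10000])
    def test_agrees_with_brute_force_oracle(self, rng, n_modes):
        grid = DSGrid()
        tau = rng.uniform(-300, 50, n_modes)
        f = rng.uniform(0.5, 400, n_modes)
        vec = bin_modes((tau, f), grid)
        np.testing.assert_array_equal(vec.counts, brute_force_bins(tau, f, grid))


class TestMakeDSVectors:
    def test_shapes_labels_and_counts(self, two_state):
        fset = make_ds_vectors(
            two_state.recording, two_state.intervals, 2.0, n_per_interval=5, seed=1
        )
        assert fset.vectors.shape == (10, 400)
        assert sorted(set(fset.labels)) == ["anesthetized", "awake"]
        assert np.sum(fset.labels == "awake") == 5
        # every vector pools 10 fits x 16 channels
        assert np.all(fset.vectors.sum(axis=1) <= 160)

    def test_deterministic_without_surrogate(self, two_state):
        kw = dict(window_s=2.0, n_per_interval=3, seed=5)
        a = make_ds_vectors(two_state.recording, two_state.intervals, **kw)
        b = make_ds_vectors(two_state.recording, two_state.intervals, **kw)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_stagger_seed_changes_vectors_not_shape(self, two_state):
        kw = dict(window_s=1.0, n_per_interval=3)
        a = make_ds_vectors(
            two_state.recording, two_state.intervals,
            surrogate=SurrogateSpec("stagger"), seed=1, **kw,
        )
        b = make_ds_vectors(
            two_state.recording, two_state.intervals,
            surrogate=SurrogateSpec("stagger"), seed=2, **kw,
        )
        assert a.vectors.shape == b.vectors.shape
        assert not np.array_equal(a.vectors, b.vectors)
        assert a.surrogate == "stagger"

    def test_stabilized_regime_shifts_mean_tau_down(self, two_state):
        """Anesthetized-interval vectors put their mass at lower tau rows."""
        fset = make_ds_vectors(
            two_state.recording, two_state.intervals, 2.0, n_per_interval=5, seed=2
        )
        grid = DSGrid()
        centers = (grid.tau_edges[:-1] + grid.tau_edges[1:]) / 2
        row_tau = np.repeat(centers, grid.n_f_bins)

        def mean_tau(rows):
            w = rows.sum(axis=0)
            return np.sum(w * row_tau) / w.sum()

        awake_tau = mean_tau(fset.vectors[fset.labels == "awake"])
        anes_tau = mean_tau(fset.vectors[fset.labels == "anesthetized"])
        assert anes_tau < awake_tau - 30.0
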