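"""Layout relaxation, columnarity, apoptosis, reconstruction, mirrors."""

import numpy as np
import pytest

from cortigen.errors import (
    InsufficientClustersError,
    InvalidParameterError,
    OverCullError,
)
from cortigen.field import FieldConfig, build_field, simulate
from cortigen.fixtures import FixtureSpec, make_fixture
from cortigen.morphogenesis import (
    LOCAL,
    PATCH,
    CellLayout,
    apoptotic_selection,
    cluster_centers,
    columnarity_index,
    force_equilibrium_layout,
    mirror_symmetry_score,
    reconstruct_symmetric_connections,
    reflect_points,
    surrogate_correlation,
    tiling_classification,
)


def two_pop_layout(positions, populations, chirality=None, domain=10.0):
    return CellLayout(
        positions=np.asarray(positions, dtype=float),
        population=np.asarray(populations),
        axon_scale={PATCH: 4.0, LOCAL: 0.5},
        domain=domain, chirality=chirality,
    )


# --------------------------------------------------------------------------
# columnarity
# --------------------------------------------------------------------------


class TestColumnarity:
    def test_uniform_random_layout_scores_low(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 10, size=(60, 2))
        assert columnarity_index(pts, domain=10.0, seed=1) < 0.2

    def test_tight_separated_clusters_score_high(self):
        rng = np.random.default_rng(3)
        centers = np.array([[2, 2], [2, 8], [8, 2], [8, 8]], dtype=float)
        pts = np.concatenate(
            [c + rng.normal(0, 0.08, (15, 2)) for c in centers])
        assert columnarity_index(pts, domain=10.0, seed=1) > 0.8

    def test_invariant_under_rotation_and_translation(self):
        rng = np.random.default_rng(5)
        pts = np.concatenate([
            c + rng.normal(0, 0.1, (12, 2))
            for c in ([1, 1], [4, 1], [1, 4], [4, 4])
        ])
        base = columnarity_index(pts, domain=6.0, seed=2)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ rot.T + [3.0, -2.0]
        assert columnarity_index(moved, domain=6.0, seed=2) == pytest.approx(
            base, abs=0.05)

    def test_needs_enough_cells(self):
        with pytest.raises(InvalidParameterError):
            columnarity_index(np.zeros((4, 2)) + [[0, 0]], domain=1.0)


# --------------------------------------------------------------------------
# force equilibrium
# --------------------------------------------------------------------------


class TestForceEquilibrium:
    def test_synchrony_only_forms_clusters_surrounded_by_patch_cells(self):
        layout = force_equilibrium_layout(
            40, 40, w_synchrony=1.0, w_wiring=0.0, seed=0, max_iter=1200)
        assert columnarity_index(layout, seed=1) > 0.8
        centers = cluster_centers(layout)
        def mean_center_dist(pts):
            return np.sqrt(
                ((pts[:, None] - centers[None]) ** 2).sum(-1)).min(1).mean()
        assert mean_center_dist(layout.positions[layout.is_patch]) > \
            mean_center_dist(layout.positions[layout.is_local])

    def test_wiring_only_is_diffuse(self):
        layout = force_equilibrium_layout(
            40, 40, w_synchrony=0.0, w_wiring=1.0, seed=0, max_iter=1200)
        assert columnarity_index(layout, seed=1) < 0.2
        assert layout.tiling_class == "diffuse"

    def test_both_weights_zero_rejected(self):
        with pytest.raises(InvalidParameterError):
            force_equilibrium_layout(8, 8, w_synchrony=0.0, w_wiring=0.0)

    def test_positions_stay_in_domain(self):
        layout = force_equilibrium_layout(10, 10, seed=2, max_iter=300,
                                          domain=5.0)
        assert layout.positions.min() >= 0
        assert layout.positions.max() <= 5.0


# --------------------------------------------------------------------------
# tiling classification
# --------------------------------------------------------------------------


class TestTiling:
    def test_exact_square_lattice(self):
        assert tiling_classification(
            make_fixture(FixtureSpec("square-lattice", 0))) == "square"

    def test_exact_hexagonal_lattice(self):
        assert tiling_classification(
            make_fixture(FixtureSpec("hex-lattice", 0))) == "hexagonal"

    def test_jittered_hexagonal_lattice_still_hexagonal(self):
        lay = make_fixture(FixtureSpec("hex-lattice", 0,
                                       params={"jitter": 0.05}))
        assert tiling_classification(lay) == "hexagonal"

    def test_too_few_centers_rejected(self):
        with pytest.raises(InsufficientClustersError):
            tiling_classification(np.array([[0.0, 0], [1, 0], [0, 1]]))


# --------------------------------------------------------------------------
# apoptotic selection
# --------------------------------------------------------------------------


class TestApoptosis:
    def test_zero_cull_is_identity(self):
        geo, gains = build_field(FieldConfig(n=12, seed=2))
        g2_geo, g2, kept = apoptotic_selection(
            geo, gains, 0.0, synchrony_scores=np.zeros(12))
        assert np.array_equal(kept, np.arange(12))
        assert g2_geo is geo

    def test_least_synchronous_cell_is_removed(self):
        geo, gains = build_field(FieldConfig(n=10, seed=2))
        scores = np.linspace(0.9, 0.2, 10)     # cell 9 least synchronous
        _, _, kept = apoptotic_selection(geo, gains, 0.1,
                                         synchrony_scores=scores)
        assert 9 not in kept and len(kept) == 9

    def test_survivor_synchrony_not_worse_on_simulated_field(self):
        rec = simulate(FieldConfig(n=24, seed=7), 2500, record_phi=False)
        x = rec.Q[rec.burn_in:]
        c = np.corrcoef((x - x.mean(0)).T)
        np.fill_diagonal(c, np.nan)
        pre_mean = np.nanmean(c)
        _, _, kept = apoptotic_selection(
            rec.geometry, rec.gains_final, 0.25, record=rec)
        post = c[np.ix_(kept, kept)]
        assert np.nanmean(post) >= pre_mean

    def test_gain_matrices_renumbered_consistently(self):
        geo, gains = build_field(FieldConfig(n=10, seed=2))
        scores = np.arange(10, dtype=float)
        geo2, g2, kept = apoptotic_selection(geo, gains, 0.2,
                                             synchrony_scores=scores)
        assert g2.g.shape == (8, 8)
        assert np.array_equal(g2.g, gains.g[np.ix_(kept, kept)])
        assert geo2.delay_matrix.shape == (8, 8)

    def test_over_cull_rejected(self):
        geo, gains = build_field(FieldConfig(n=4, seed=2))
        with pytest.raises(OverCullError):
            apoptotic_selection(geo, gains, 0.8,
                                synchrony_scores=np.zeros(4))


# --------------------------------------------------------------------------
# symmetric reconstruction
# --------------------------------------------------------------------------


class TestReconstruction:
    def test_adjacent_correlated_cells_get_one_symmetric_edge(self):
        lay = two_pop_layout([[0, 0], [0.5, 0]], [LOCAL, LOCAL])
        corr = np.array([[1.0, 0.95], [0.95, 1.0]])
        g = reconstruct_symmetric_connections(lay, correlation=corr)
        assert len(g.edges) == 1
        assert bool(g.symmetric[0])

    def test_correlated_pair_beyond_axonal_reach_not_connected(self):
        lay = two_pop_layout([[0, 0], [5.0, 0]], [LOCAL, LOCAL])
        corr = np.array([[1.0, 0.95], [0.95, 1.0]])
        with pytest.warns(UserWarning):
            g = reconstruct_symmetric_connections(lay, correlation=corr)
        assert len(g.edges) == 0

    def test_adjacency_equals_its_transpose(self):
        lay = make_fixture(FixtureSpec("clustered-layout", 4))
        g = reconstruct_symmetric_connections(lay)
        adj = g.adjacency()
        assert np.array_equal(adj, adj.T)

    def test_patch_edges_span_clusters_local_edges_stay_within(self):
        """Patch-skipping connectivity census on a clustered layout."""
        lay = make_fixture(FixtureSpec("clustered-layout", 4,
                                       params={"spacing": 5.0}))
        g = reconstruct_symmetric_connections(lay, threshold=0.25)
        centers = cluster_centers(lay)
        member = np.argmin(
            ((lay.positions[:, None] - centers[None]) ** 2).sum(-1), axis=1)
        is_local = lay.is_local
        cross_patch = same_local = cross_local = 0
        for (i, j) in g.edges:
            if is_local[i] and is_local[j]:
                if member[i] == member[j]:
                    same_local += 1
                else:
                    cross_local += 1
            elif not is_local[i] and not is_local[j]:
                if member[i] != member[j]:
                    cross_patch += 1
        assert same_local > 0          # local edges within columns
        assert cross_local == 0        # none between columns
        assert cross_patch > 0         # patch edges skip between columns

    def test_surrogate_correlation_decays_with_distance(self):
        lay = two_pop_layout([[0, 0], [1, 0], [4, 0]],
                             [LOCAL, LOCAL, LOCAL])
        c = surrogate_correlation(lay)
        assert c[0, 1] > c[0, 2]


# --------------------------------------------------------------------------
# mirror symmetry
# --------------------------------------------------------------------------


class TestMirrorSymmetry:
    def _reflected_construction(self, seed=2):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 4, size=(12, 2)) + [1.0, 0.0]
        chi = rng.choice([-1, 1], size=12)
        point = np.zeros(2)
        normal = np.array([1.0, 0.0])
        refl = reflect_points(pts, point, normal)
        lay = two_pop_layout(np.vstack([pts, refl]), [PATCH] * 24,
                             chirality=np.concatenate([chi, -chi]))
        return lay, (point, normal)

    def test_exact_reflection_scores_one(self):
        lay, axis = self._reflected_construction()
        rep = mirror_symmetry_score(lay, axis=axis, seed=0)
        assert rep.score == pytest.approx(1.0)

    def test_reflection_involution(self):
        lay, axis = self._reflected_construction()
        mirrored = CellLayout(
            positions=reflect_points(lay.positions, *axis),
            population=lay.population, axon_scale=lay.axon_scale,
            domain=lay.domain,
            chirality=-lay.chirality,
        )
        a = mirror_symmetry_score(lay, axis=axis, seed=0).score
        b = mirror_symmetry_score(mirrored, axis=axis, seed=0).score
        assert a == pytest.approx(b)

    def test_independent_random_sides_sit_in_the_permutation_null(self):
        rng = np.random.default_rng(9)
        left = rng.uniform(0, 4, (15, 2)) * [-1, 1]
        right = rng.uniform(0, 4, (15, 2))
        lay = two_pop_layout(np.vstack([left, right]), [PATCH] * 30)
        rep = mirror_symmetry_score(
            lay, axis=(np.zeros(2), np.array([1.0, 0.0])), seed=3)
        assert abs(rep.score - rep.null_mean) < 3 * rep.null_sd

    def test_square_patch_array_more_mirror_symmetric_than_hexagonal(self):
        sq = make_fixture(FixtureSpec("patch-array-square", 0))
        hx = make_fixture(FixtureSpec("patch-array-hex", 0))
        s_sq = mirror_symmetry_score(sq, axis="fit", seed=1).score
        s_hx = mirror_symmetry_score(hx, axis="fit", seed=1).score
        assert s_sq > s_hx
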