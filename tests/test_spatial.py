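"""Heat-map binning and Dixon nearest-neighbour segregation."""

import math

import numpy as np
import pandas as pd
import pytest

from ventrhythms.spatial import (
    LabelledPointSet,
    bin_points,
    expected_counts,
    nn_contingency,
    pooled_segregation,
    segregation_index,
)
from ventrhythms.synthetic_data import PatternSpec, generate_point_pattern


def pts(records, w=100, h=100, pixel_area=1.0):
    df = pd.DataFrame(records, columns=["frame_id", "taxon", "x", "y"])
    return LabelledPointSet(df, frame_width=w, frame_height=h,
                            pixel_area_cm2=pixel_area)


def hand_S(N_ab, n_a, n_b, N, conspecific):
    """Spec-stated Dixon log odds-ratio, written out independently."""
    obs_odds = N_ab / (n_a - N_ab)
    if conspecific:
        exp_odds = (n_a - 1) / (N - n_a)
    else:
        exp_odds = n_b / (N - 1 - n_b)
    return math.log(obs_odds / exp_odds)


class TestBinPoints:
    def test_single_point_single_bin(self):
        grid = bin_points(pts([(0, "A", 12.0, 30.0)]), bin_area_cm2=25.0)
        assert grid.counts["A"].sum() == 1
        assert (grid.counts["A"] > 0).sum() == 1

    def test_corner_points_land_in_quadrants(self):
        # 100x100 frame, 1 cm2 pixels, 2500 cm2 bins -> 50 px bins, 2x2 grid
        corners = [(0, "A", 0.0, 0.0), (0, "A", 99.0, 0.0),
                   (0, "A", 0.0, 99.0), (0, "A", 99.0, 99.0)]
        grid = bin_points(pts(corners), bin_area_cm2=2500.0)
        assert grid.counts["A"].shape == (2, 2)
        assert np.array_equal(grid.counts["A"], np.ones((2, 2), dtype=int))

    def test_edge_point_belongs_to_lower_index_bin(self):
        grid = bin_points(pts([(0, "A", 50.0, 10.0)]), bin_area_cm2=2500.0)
        assert grid.counts["A"][0, 1] == 1  # x=50 starts the second column

    def test_conservation_and_order_invariance(self, rng):
        records = [(0, "A", float(x), float(y))
                   for x, y in rng.uniform(0, 100, size=(1000, 2))]
        grid = bin_points(pts(records), bin_area_cm2=49.0)
        assert grid.counts["A"].sum() == 1000
        shuffled = list(records)
        rng.shuffle(shuffled)
        grid2 = bin_points(pts(shuffled), bin_area_cm2=49.0)
        assert np.array_equal(grid.counts["A"], grid2.counts["A"])

    def test_empty_point_set_gives_empty_grid(self):
        grid = bin_points(pts([]), bin_area_cm2=100.0)
        assert grid.counts == {}


class TestNNContingency:
    def test_two_points_are_mutual_neighbours(self):
        obs, ab = nn_contingency(pts([(0, "A", 1, 1), (0, "B", 5, 5)]).points)
        assert obs[0, 1] == 1 and obs[1, 0] == 1
        assert obs[0, 0] == 0 and obs[1, 1] == 0

    def test_collinear_hand_enumeration(self):
        frame = pts([(0, "A", 0, 0), (0, "A", 1, 0), (0, "B", 3, 0)]).points
        obs, ab = nn_contingency(frame)
        assert obs[0, 0] == 2  # both A choose the other A
        assert obs[1, 0] == 1  # B's neighbour is A at x=1
        assert obs[0, 1] == 0 and obs[1, 1] == 0

    def test_row_sums_equal_abundances(self, rng):
        records = [(0, rng.choice(["A", "B", "C"]), float(x), float(y))
                   for x, y in rng.uniform(0, 100, size=(60, 2))]
        obs, ab = nn_contingency(pts(records).points)
        assert np.array_equal(obs.sum(axis=1), ab)

    def test_duplicate_coordinates_allowed(self):
        frame = pts([(0, "A", 2, 2), (0, "B", 2, 2), (0, "B", 90, 90)]).points
        obs, _ = nn_contingency(frame)
        assert obs[0, 1] == 1  # zero distance is a valid nearest neighbour

    def test_tie_broken_by_lowest_record_index(self):
        frame = pts([(0, "A", 5, 5), (0, "B", 5, 4), (0, "C", 5, 6)]).points
        obs, _ = nn_contingency(frame)
        assert obs[0, 1] == 1 and obs[0, 2] == 0  # B recorded before C

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            nn_contingency(pts([(0, "A", 1, 1)]).points)


class TestExpectedCounts:
    def test_single_taxon_forced_conspecific(self):
        E = expected_counts([6])
        assert E[0, 0] == pytest.approx(6.0)

    def test_two_equal_taxa(self):
        E = expected_counts([3, 3])
        assert E[0, 0] == pytest.approx(1.2)
        assert E[0, 1] == pytest.approx(1.8)

    def test_conspecific_expectation_monotone_in_abundance(self):
        E = expected_counts([5, 50, 500])
        diag = np.diag(E)
        assert diag[0] < diag[1] < diag[2]

    def test_expectations_conserve_total(self, rng):
        n = rng.integers(1, 30, size=4)
        assert expected_counts(n).sum() == pytest.approx(n.sum())

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            expected_counts([1])


class TestSegregationIndex:
    def test_zero_at_expected_odds(self):
        # n=(2,1): conspecific expected odds (n_A-1)/(N-n_A) = 1; observing
        # N_AA=1 gives observed odds 1 and S exactly 0
        observed = np.array([[1, 1], [1, 0]])
        S, degen = segregation_index(observed, [2, 1])
        assert S[0, 0] == pytest.approx(0.0)
        assert not degen[0, 0]

    def test_sign_pattern_above_and_below_expectation(self):
        # 2 taxa of 10 in which conspecific neighbours dominate
        observed = np.array([[9, 1], [1, 9]])
        S, _ = segregation_index(observed, [10, 10])
        assert S[0, 0] > 0 and S[1, 1] > 0
        assert S[0, 1] < 0 and S[1, 0] < 0

    def test_collinear_example_matches_first_principles(self):
        # A at x=0,1,5 and B at x=3,10: NN(A0)=A1, NN(A1)=A0, NN(A2)=B0,
        # NN(B0)=A1 (tie with A2 broken by record index), NN(B1)=A2
        frame = pd.DataFrame(
            [(0, "A", 0, 0), (0, "A", 1, 0), (0, "A", 5, 0),
             (0, "B", 3, 0), (0, "B", 10, 0)],
            columns=["frame_id", "taxon", "x", "y"],
        )
        obs, ab = nn_contingency(frame)
        assert np.array_equal(obs, [[2, 1], [2, 0]])
        S, degen = segregation_index(obs, ab)
        assert S[0, 0] == pytest.approx(hand_S(2, 3, 3, 5, conspecific=True))
        assert S[0, 1] == pytest.approx(hand_S(1, 3, 2, 5, conspecific=False))
        # all of B's neighbours are A: both B odds are degenerate
        assert degen[1, 0] and degen[1, 1]

    def test_inconsistent_rows_rejected(self):
        with pytest.raises(ValueError):
            segregation_index(np.array([[1, 0], [0, 1]]), [2, 1])


class TestPooledSegregation:
    def segregated_pattern(self, n_frames=60):
        # three home ranges far apart, with enough spread that a few
        # heterospecific neighbours occur (complete segregation would
        # give infinite observed odds)
        return generate_point_pattern(PatternSpec(
            frame_width=900, frame_height=700,
            taxa=[("Buccinidae", 3, 1, 100.0),
                  ("Polynoidae", 6, 2, 100.0),
                  ("Pycnogonida", 9, 2, 100.0)],
            centers={
                "Buccinidae": [(150, 150)],
                "Polynoidae": [(450, 150), (450, 550)],
                "Pycnogonida": [(750, 350), (150, 550)],
            },
            n_frames=n_frames, seed=21,
        ))

    def test_single_frame_matches_direct_path(self):
        pattern = self.segregated_pattern(n_frames=1)
        pooled = pooled_segregation(pattern)
        obs, ab = nn_contingency(pattern.points, taxa=pooled.taxa)
        S_direct, _ = segregation_index(obs, ab)
        assert np.array_equal(pooled.observed, obs)
        both = ~np.isnan(pooled.S) & ~np.isnan(S_direct)
        assert np.allclose(pooled.S[both], S_direct[both])

    def test_two_identical_frames_double_the_counts(self):
        one = self.segregated_pattern(n_frames=1)
        df2 = pd.concat([one.points, one.points.assign(frame_id=1)])
        two = LabelledPointSet(df2, one.frame_width, one.frame_height)
        p1, p2 = pooled_segregation(one), pooled_segregation(two)
        assert np.array_equal(2 * p1.observed, p2.observed)
        assert np.allclose(2 * p1.expected, p2.expected)

    def test_segregated_taxa_reproduce_sign_structure(self):
        pooled = pooled_segregation(self.segregated_pattern())
        k = len(pooled.taxa)
        for i in range(k):
            for j in range(k):
                if i == j:
                    assert pooled.S[i, j] > 0
                else:
                    assert pooled.S[i, j] < 0

    def test_observed_exceeds_expected_on_diagonal(self):
        pooled = pooled_segregation(self.segregated_pattern())
        assert np.all(np.diag(pooled.observed) > np.diag(pooled.expected))

    def test_random_labelling_shrinks_S_toward_zero(self, rng):
        pattern = self.segregated_pattern(n_frames=20)
        observed_mean_abs = np.nanmean(np.abs(pooled_segregation(pattern).S))
        shuffled_means = []
        for _ in range(50):
            df = pattern.points.copy()
            df["taxon"] = rng.permutation(df["taxon"].to_numpy())
            shuffled = LabelledPointSet(df, pattern.frame_width,
                                        pattern.frame_height)
            shuffled_means.append(
                np.nanmean(np.abs(pooled_segregation(shuffled).S)))
        assert np.mean(shuffled_means) < observed_mean_abs

    def test_tiny_frames_skipped_with_warning(self, caplog):
        df = pd.DataFrame(
            [(0, "A", 1, 1), (0, "B", 9, 9), (1, "A", 3, 3)],
            columns=["frame_id", "taxon", "x", "y"],
        )
        pooled = pooled_segregation(LabelledPointSet(df, 20, 20))
        assert pooled.n_frames == 1
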