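"""Grid geometry, AHA segmentation, normalization and table I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polargcn as pg
from polargcn.polarmap import N_NODES, N_SEGMENTS, SEGMENT_TERRITORY


class TestNodeIndex:
    @pytest.mark.parametrize(
        "ring,sector,expected", [(0, 0, 0), (19, 22, 459), (1, 0, 23), (0, 22, 22)]
    )
    def test_layout(self, ring, sector, expected):
        assert pg.node_index(ring, sector) == expected

    def test_bijective(self):
        seen = {pg.node_index(r, s) for r in range(20) for s in range(23)}
        assert seen == set(range(N_NODES))

    @pytest.mark.parametrize("ring,sector", [(-1, 0), (20, 0), (0, 23), (0, -1)])
    def test_out_of_range(self, ring, sector):
        with pytest.raises(IndexError):
            pg.node_index(ring, sector)


class TestSegments:
    def test_apical_cap_is_segment_17(self, grid):
        for r in range(5):
            for s in range(23):
                assert grid.segment_of[pg.node_index(r, s)] == 17

    def test_partition_into_17_nonempty_segments(self, grid):
        ids, counts = np.unique(grid.segment_of, return_counts=True)
        assert list(ids) == list(range(1, 18))
        assert counts.min() >= 1

    def test_band_structure(self, grid):
        # apical band holds segments 13-16, mid 7-12, basal 1-6
        bands = {(5, 9): set(range(13, 17)), (10, 14): set(range(7, 13)), (15, 19): set(range(1, 7))}
        for (lo, hi), expect in bands.items():
            segs = {grid.segment_of[pg.node_index(r, s)] for r in range(lo, hi + 1) for s in range(23)}
            assert segs == expect

    def test_anterior_sector_hits_anterior_segments(self, grid):
        # sector 0 straddles angle 0 = anterior wall
        assert grid.segment_of[pg.node_index(17, 0)] == 1  # basal anterior
        assert grid.segment_of[pg.node_index(12, 0)] == 7  # mid anterior
        assert grid.segment_of[pg.node_index(7, 0)] == 13  # apical anterior

    def test_frozen_sample_of_assignments(self, grid):
        # spot values frozen from a one-off enumeration of the angular rule
        # sector 22 (center 352.2 deg = -7.8 deg) is back in the anterior span
        frozen = {(17, 1): 1, (17, 5): 2, (17, 11): 4, (17, 22): 1, (12, 8): 9, (7, 6): 14}
        for (r, s), seg in frozen.items():
            assert grid.segment_of[pg.node_index(r, s)] == seg


class TestTerritories:
    @pytest.mark.parametrize("seg,territory", [(17, "LAD"), (4, "RCA"), (5, "LCX"), (13, "LAD")])
    def test_assignment(self, seg, territory):
        assert pg.territory_of_segment(seg) == territory

    def test_partition_sizes(self):
        sizes = {t: len(pg.segments_of_territory(t)) for t in pg.TERRITORIES}
        assert sizes == {"LAD": 7, "RCA": 5, "LCX": 5}
        assert sum(sizes.values()) == N_SEGMENTS

    @pytest.mark.parametrize("seg", [0, 18, -3])
    def test_domain_error(self, seg):
        with pytest.raises(ValueError):
            pg.territory_of_segment(seg)

    def test_truth_aggregation_matches_or(self):
        flags = np.zeros(17, dtype=int)
        flags[[0, 8]] = 1  # segment 1 (LAD) and 9 (RCA)
        assert list(pg.territory_truth_from_segments(flags)) == [1, 1, 0]


class TestNormalize:
    def test_direct_division(self):
        pm = pg.PolarMap(values=np.linspace(0.5, 2.0, N_NODES))
        out = pg.normalize_map(pm)
        assert out.values.max() == 1.0
        np.testing.assert_allclose(out.values, pm.values / 2.0)

    def test_constant_map_becomes_ones(self):
        out = pg.normalize_map(pg.PolarMap(values=np.full(N_NODES, 3.7)))
        np.testing.assert_array_equal(out.values, 1.0)

    def test_idempotent_and_scale_invariant(self, rng):
        v = rng.random(N_NODES) + 0.01
        once = pg.normalize_map(pg.PolarMap(values=v))
        twice = pg.normalize_map(once)
        scaled = pg.normalize_map(pg.PolarMap(values=17.3 * v))
        np.testing.assert_array_equal(once.values, twice.values)
        np.testing.assert_allclose(once.values, scaled.values)

    def test_all_zero_map_rejected(self):
        with pytest.raises(pg.PolarMapError):
            pg.normalize_map(pg.PolarMap(values=np.zeros(N_NODES)))


class TestRaster:
    def test_corner_values_and_round_trip(self, rng):
        pm = pg.PolarMap(values=np.arange(N_NODES, dtype=float))
        raster = pg.reshape_to_raster(pm)
        assert raster.shape == (23, 20)
        assert raster[0, 0] == 0 and raster[22, 19] == 459
        v = rng.random(N_NODES)
        back = pg.reshape_to_raster(pg.PolarMap(values=v)).flatten(order="F")
        np.testing.assert_array_equal(back, v)


class TestTableIO:
    def _random_maps(self, rng, n=10):
        maps = []
        for i in range(n):
            truth = None if i % 3 == 0 else rng.integers(0, 2, size=17)
            maps.append(
                pg.PolarMap(
                    values=rng.random(N_NODES),
                    condition="stress" if i % 2 else "rest",
                    label=[None, "normal", "abnormal"][i % 3],
                    segment_truth=truth,
                    sample_id=f"s{i:03d}",
                )
            )
        return maps

    def test_round_trip(self, tmp_path, rng):
        maps = self._random_maps(rng)
        path = tmp_path / "maps.csv"
        pg.write_polarmap_table(maps, path)
        back = pg.read_polarmap_table(path)
        assert len(back) == len(maps)
        for a, b in zip(maps, back):
            np.testing.assert_allclose(a.values, b.values, rtol=0, atol=1e-12)
            assert (a.sample_id, a.condition, a.label) == (b.sample_id, b.condition, b.label)
            if a.segment_truth is None:
                assert b.segment_truth is None
            else:
                np.testing.assert_array_equal(a.segment_truth, b.segment_truth)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert pg.read_polarmap_table(path) == []

    def test_short_row_is_parse_error_with_line(self, tmp_path, rng):
        path = tmp_path / "bad.csv"
        pg.write_polarmap_table(self._random_maps(rng, 2), path)
        lines = path.read_text().splitlines()
        lines[2] = ",".join(lines[2].split(",")[:-1])  # drop one value: 459 left
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(pg.PolarMapError, match="line 3"):
            pg.read_polarmap_table(path)

    def test_negative_value_rejected(self, tmp_path, rng):
        maps = self._random_maps(rng, 1)
        path = tmp_path / "neg.csv"
        pg.write_polarmap_table(maps, path)
        text = path.read_text().replace(f"{maps[0].values[0]}", "-0.5", 1)
        path.write_text(text)
        with pytest.raises(pg.PolarMapError):
            pg.read_polarmap_table(path)

    def test_unknown_condition_rejected(self, tmp_path, rng):
        maps = self._random_maps(rng, 1)
        path = tmp_path / "cond.csv"
        pg.write_polarmap_table(maps, path)
        path.write_text(path.read_text().replace("rest", "supine"))
        with pytest.raises(pg.PolarMapError):
            pg.read_polarmap_table(path)


@settings(max_examples=25, deadline=None)
@given(scale=st.floats(min_value=0.01, max_value=100.0))
def test_normalize_scale_invariance_property(scale):
    rng = np.random.default_rng(7)
    v = rng.random(N_NODES) + 0.05
    a = pg.normalize_map(pg.PolarMap(values=v)).values
    b = pg.normalize_map(pg.PolarMap(values=scale * v)).values
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_grid_audit_frame(grid):
    df = grid.to_frame()
    assert len(df) == N_NODES
    assert set(df["territory"]) == set(pg.TERRITORIES)
    assert df["segment"].between(1, 17).all()
    # frame agrees with the canonical assignment maps
    for _, row in df.sample(20, random_state=0).iterrows():
        assert SEGMENT_TERRITORY[row["segment"]] == row["territory"]
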