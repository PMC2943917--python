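"""Raster carrier, file I/O, aggregation, extraction and bioclim derivation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from climsuit.grids import (
    BIOCLIM_NAMES,
    BioclimStack,
    Grid,
    GridFormatError,
    MonthlyClimate,
    PointSet,
    aggregate,
    derive_bioclim,
    extract,
    read_grid,
    write_grid,
)


def make_grid(values, origin=(0.0, 2.0), cell=1.0, nodata=-9999.0):
    return Grid(np.asarray(values, dtype=float), origin, cell, nodata=nodata)


def constant_climate(tmin=10.0, tmax=20.0, prec=50.0, shape=(3, 4)):
    origin = (0.0, shape[0] * 1.0)
    mk = lambda v: Grid(np.full(shape, float(v)), origin, 1.0)
    return MonthlyClimate(tmin=[mk(tmin)] * 12, tmax=[mk(tmax)] * 12,
                         prec=[mk(prec)] * 12)


class TestGridIO:
    @pytest.mark.parametrize("fmt,ext", [("esri_ascii", ".asc"), ("geotiff", ".tif")])
    def test_round_trip_identity(self, tmp_path, fmt, ext):
        g = make_grid([[1.25, -3.5, -9999.0], [0.0, 7.125, 42.0]],
                      origin=(10.0, 20.0), cell=2.5)
        path = tmp_path / f"layer{ext}"
        write_grid(g, path, fmt)
        back = read_grid(path, fmt)
        assert back == g

    def test_nodata_excluded_from_statistics(self, tmp_path):
        path = tmp_path / "g.asc"
        path.write_text(
            "ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n-9999 5\n")
        g = read_grid(path)
        assert g.valid_mask().sum() == 1
        assert g.values[g.valid_mask()].mean() == 5

    def test_hand_written_corner_coordinates(self, tmp_path):
        # 2x2 grid with known corners: xll=100, yll=200, cellsize=10
        path = tmp_path / "g.asc"
        path.write_text("ncols 2\nnrows 2\nxllcorner 100\nyllcorner 200\n"
                        "cellsize 10\nNODATA_value -9999\n1 2\n3 4\n")
        g = read_grid(path)
        # top-left origin is (100, 220); centers hand-computed
        centers = {(105.0, 215.0): 1, (115.0, 215.0): 2,
                   (105.0, 205.0): 3, (115.0, 205.0): 4}
        for (x, y), v in centers.items():
            r, c = g.cell_of(x, y)
            assert g.values[r, c] == v

    def test_malformed_header_names_field(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\nnrows two\nxllcorner 0\nyllcorner 0\n"
                        "cellsize 1\n1 2\n")
        with pytest.raises(GridFormatError, match="nrows"):
            read_grid(path)

    def test_one_by_one_grid(self, tmp_path):
        g = make_grid([[3.0]])
        write_grid(g, tmp_path / "tiny.asc")
        assert read_grid(tmp_path / "tiny.asc") == g


class TestAggregate:
    def test_factor_one_identity(self):
        g = make_grid([[1, 2], [3, 4]])
        assert aggregate(g, 1) == g

    def test_block_mean(self):
        g = make_grid([[1, 3], [5, 7]])
        out = aggregate(g, 2)
        assert out.shape == (1, 1)
        assert out.values[0, 0] == 4.0
        assert out.cell_size == 2.0

    def test_ragged_edges_average_available_cells(self):
        g = make_grid(np.arange(9).reshape(3, 3), origin=(0.0, 3.0))
        out = aggregate(g, 2)
        # hand enumeration: blocks [[0,1],[3,4]], [[2],[5]], [[6,7]], [[8]]
        expect = np.array([[2.0, 3.5], [6.5, 8.0]])
        np.testing.assert_allclose(out.values, expect)

    def test_nodata_blocks(self):
        g = make_grid([[-9999, -9999], [-9999, 8]])
        out = aggregate(g, 2)
        assert out.values[0, 0] == 8.0
        g2 = make_grid([[-9999, -9999], [-9999, -9999]])
        assert aggregate(g2, 2).values[0, 0] == -9999.0

    def test_mean_preserved_without_nodata(self, rng):
        g = make_grid(rng.random((6, 8)), origin=(0.0, 6.0))
        out = aggregate(g, 2)
        assert np.isclose(out.values.mean(), g.values.mean())

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            aggregate(make_grid([[1.0]]), 0)


class TestExtract:
    def make_stack(self, shape=(2, 2)):
        origin = (0.0, float(shape[0]))
        layers = {}
        for i, name in enumerate(BIOCLIM_NAMES):
            vals = np.arange(shape[0] * shape[1], dtype=float).reshape(shape) + 10 * i
            layers[name] = Grid(vals, origin, 1.0)
        # keep stack invariants irrelevant here: extraction only reads values
        return BioclimStack(layers)

    def test_cell_center_values(self):
        stack = self.make_stack()
        pts = PointSet(ids=["a"], x=[0.5], y=[1.5])
        tab = extract(stack, pts)
        assert tab.loc[0, "MTEMP"] == 0.0
        assert tab.loc[0, "PDQ"] == 90.0

    def test_half_open_membership_on_edges(self):
        stack = self.make_stack()
        # x on the shared vertical edge belongs to the right cell;
        # y on the shared horizontal edge belongs to the upper cell
        tab = extract(stack, PointSet(ids=["e"], x=[1.0], y=[1.0]))
        assert tab.loc[0, "MTEMP"] == 1.0  # row 0, col 1

    def test_epsilon_inside_edge(self):
        stack = self.make_stack()
        tab = extract(stack, PointSet(ids=["p"], x=[1.0 - 1e-9], y=[2.0]))
        assert tab.loc[0, "MTEMP"] == 0.0  # row 0, col 0

    def test_point_outside_names_id(self):
        stack = self.make_stack()
        with pytest.raises(ValueError, match="stray"):
            extract(stack, PointSet(ids=["stray"], x=[5.0], y=[0.5]))

    def test_nodata_cell_flagged_invalid(self):
        stack = self.make_stack()
        stack.layers["PREC"].values[0, 0] = -9999.0
        tab = extract(stack, PointSet(ids=["n"], x=[0.5], y=[1.5]))
        assert not tab.loc[0, "valid"]


class TestDeriveBioclim:
    def test_constant_climate_values(self):
        bc = derive_bioclim(constant_climate())
        expect = {"MTEMP": 15, "TEMPR": 10, "ISO": 1.0, "TEMPS": 0, "MTWM": 20,
                  "MTCM": 10, "PREC": 600, "PRECS": 0, "PWQ": 150, "PDQ": 150}
        for name, v in expect.items():
            np.testing.assert_allclose(bc.layers[name].values, v)

    def test_wet_month_quarters(self):
        mc = constant_climate()
        prec = [g.with_values(np.full(g.shape, 50.0)) for g in mc.prec]
        prec[5] = prec[5].with_values(np.full(prec[5].shape, 160.0))
        mc = MonthlyClimate(tmin=mc.tmin, tmax=mc.tmax, prec=prec)
        bc = derive_bioclim(mc)
        # enumerate the 12 wrap-around quarters by hand: max 50+50+160=260
        np.testing.assert_allclose(bc.layers["PWQ"].values, 260.0)
        np.testing.assert_allclose(bc.layers["PDQ"].values, 150.0)

    def test_layer_names_exact(self):
        bc = derive_bioclim(constant_climate())
        assert set(bc.layers) == set(BIOCLIM_NAMES)

    def test_zero_annual_range_iso_nodata(self):
        mc = constant_climate(tmin=15.0, tmax=15.0)
        bc = derive_bioclim(mc)
        assert not bc.layers["ISO"].valid_mask().any()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_ordering_invariants_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        shape = (3, 3)
        origin = (0.0, 3.0)
        base = r.uniform(-10, 30, size=(12,) + shape)
        diurnal = r.uniform(0.1, 15, size=(12,) + shape)
        prec = r.uniform(0, 300, size=(12,) + shape)
        mc = MonthlyClimate(
            tmin=[Grid(base[i], origin, 1.0) for i in range(12)],
            tmax=[Grid(base[i] + diurnal[i], origin, 1.0) for i in range(12)],
            prec=[Grid(prec[i], origin, 1.0) for i in range(12)])
        bc = derive_bioclim(mc)
        L = {n: bc.layers[n].values for n in BIOCLIM_NAMES}
        assert (L["MTWM"] >= L["MTEMP"] - 1e-9).all()
        assert (L["MTEMP"] >= L["MTCM"] - 1e-9).all()
        assert (L["PREC"] >= L["PWQ"] - 1e-9).all()
        assert (L["PWQ"] >= L["PDQ"] - 1e-9).all()
        assert (L["PDQ"] >= -1e-9).all()
        assert (L["TEMPS"] >= 0).all()
        iso = L["ISO"][bc.layers["ISO"].valid_mask()]
        assert ((iso > 0) & (iso <= 1 + 1e-12)).all()

    def test_month_rotation_invariance(self, rng):
        shape = (2, 2)
        origin = (0.0, 2.0)
        base = rng.uniform(-5, 25, size=(12,) + shape)
        diurnal = rng.uniform(1, 12, size=(12,) + shape)
        prec = rng.uniform(0, 200, size=(12,) + shape)

        def build(rot):
            idx = [(i + rot) % 12 for i in range(12)]
            return MonthlyClimate(
                tmin=[Grid(base[i], origin, 1.0) for i in idx],
                tmax=[Grid(base[i] + diurnal[i], origin, 1.0) for i in idx],
                prec=[Grid(prec[i], origin, 1.0) for i in idx])

        a, b = derive_bioclim(build(0)), derive_bioclim(build(5))
        for name in BIOCLIM_NAMES:
            np.testing.assert_allclose(a.layers[name].values,
                                       b.layers[name].values, atol=1e-9)
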