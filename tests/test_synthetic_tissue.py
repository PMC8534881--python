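"""Tissue generator tests: geometry, seeded fibrosis, conductivity rules."""

import itertools

import numpy as np
import pytest
from scipy import stats

from atriafib import synthetic_tissue as st
from atriafib.cell_models import CELL_PARAMS, KIND_CODE


class TestMakeSheet:
    def test_node_and_element_counts(self):
        grid = st.make_sheet(100, 100)
        assert grid.n_nodes == 10_000
        assert grid.n_elements == 9_801
        assert np.all(grid.element_conductivity == 0.26)

    def test_minimal_sheet_has_one_element(self):
        assert st.make_sheet(2, 2).n_elements == 1

    def test_split_layout_halves_columns(self):
        grid = st.make_sheet(100, 100, region_layout="split")
        la = (grid.node_region == st.REGION_CODE["left_atrium"]).sum()
        ra = (grid.node_region == st.REGION_CODE["right_atrium"]).sum()
        assert la == ra == 5_000

    @pytest.mark.parametrize("nx,ny", [(1, 5), (5, 1), (0, 0)])
    def test_degenerate_dimensions_rejected(self, nx, ny):
        with pytest.raises(ValueError):
            st.make_sheet(nx, ny)


class TestGenerateFibrosis:
    def test_exact_density_count(self):
        grid = st.make_sheet(100, 100)
        out = st.generate_fibrosis(grid, st.FibrosisConfig(
            kinds=("fibrocyte",), density=0.0625, seed=1))
        assert (out.node_kind == KIND_CODE["fibrocyte"]).sum() == 625
        assert out.fibrosis_manifest["n_fibrotic"] == 625

    def test_high_density_count(self):
        grid = st.make_sheet(100, 100)
        out = st.generate_fibrosis(grid, st.FibrosisConfig(
            kinds=("fibroblast",), density=0.25, seed=1))
        assert (out.node_kind != 0).sum() == 2_500

    def test_homogeneous_split_with_remainder(self):
        """9984 eligible at 6.25% gives 624 fibrotic nodes, 208 per kind."""
        grid = st.make_sheet(100, 100)
        mask = grid.default_eligible_mask()
        mask.ravel()[:16] = False       # 9984 eligible nodes
        out = st.generate_fibrosis(grid, st.FibrosisConfig(
            kinds=("fibroblast", "myofibroblast", "fibrocyte"),
            density=0.0625, eligible_mask=mask, seed=7))
        counts = out.fibrosis_manifest["per_kind_counts"]
        assert counts == {"fibroblast": 208, "myofibroblast": 208,
                          "fibrocyte": 208}

    def test_zero_density_is_identity(self):
        grid = st.make_sheet(20, 20)
        out = st.generate_fibrosis(grid, st.FibrosisConfig(
            kinds=("fibroblast",), density=0.0, seed=0))
        assert np.array_equal(out.node_kind, grid.node_kind)
        assert np.all(out.element_conductivity == 0.26)

    def test_too_few_nodes_for_kinds_rejected(self):
        grid = st.make_sheet(10, 10)
        with pytest.raises(ValueError):
            st.generate_fibrosis(grid, st.FibrosisConfig(
                kinds=("fibroblast", "myofibroblast", "fibrocyte"),
                density=0.02, seed=0))    # 2 nodes for 3 kinds

    def test_same_seed_reproduces_different_seeds_differ(self):
        grid = st.make_sheet(40, 40)
        cfg = st.FibrosisConfig(kinds=("fibrocyte",), density=0.25, seed=11)
        a = st.generate_fibrosis(grid, cfg)
        b = st.generate_fibrosis(grid, cfg)
        assert np.array_equal(a.node_kind, b.node_kind)
        c = st.generate_fibrosis(grid, st.FibrosisConfig(
            kinds=("fibrocyte",), density=0.25, seed=12))
        assert not np.array_equal(a.node_kind, c.node_kind)
        assert (c.node_kind != 0).sum() == (a.node_kind != 0).sum()

    def test_per_kind_counts_are_seed_independent(self):
        grid = st.make_sheet(31, 31)
        counts = []
        for seed in (0, 1, 2):
            out = st.generate_fibrosis(grid, st.FibrosisConfig(
                kinds=("fibroblast", "fibrocyte"), density=0.0625, seed=seed))
            counts.append(tuple(sorted(
                out.fibrosis_manifest["per_kind_counts"].items())))
        assert len(set(counts)) == 1

    def test_excluded_structures_never_relabeled(self):
        region = np.full((30, 30), "left_atrium", dtype=object)
        region[10:20, 10:20] = "excluded"
        grid = st.make_sheet(30, 30, region_layout=region)
        out = st.generate_fibrosis(grid, st.FibrosisConfig(
            kinds=("fibroblast",), density=0.5, seed=3))
        assert np.all(out.node_kind[10:20, 10:20] == 0)
        bad = grid.default_eligible_mask().copy()
        bad[:] = True                    # illegally includes excluded nodes
        with pytest.raises(ValueError):
            st.generate_fibrosis(grid, st.FibrosisConfig(
                kinds=("fibroblast",), density=0.1, eligible_mask=bad,
                seed=0))

    def test_realized_density_within_one_node(self):
        grid = st.make_sheet(37, 53)
        for density in (0.0625, 0.25, 0.111):
            out = st.generate_fibrosis(grid, st.FibrosisConfig(
                kinds=("myofibroblast",), density=density, seed=5))
            n = out.fibrosis_manifest["n_eligible"]
            realized = (out.node_kind != 0).sum() / n
            assert abs(realized - density) <= 1.0 / n

    def test_spatial_uniformity_chi_square(self):
        """Fibrotic counts over a 4x4 partition stay consistent with a
        uniform distribution (chi-square, alpha = 0.01, 100-seed average)."""
        grid = st.make_sheet(40, 40)
        stats_sum = 0.0
        n_seeds = 100
        for seed in range(n_seeds):
            out = st.generate_fibrosis(grid, st.FibrosisConfig(
                kinds=("fibrocyte",), density=0.25, seed=seed))
            fib = (out.node_kind != 0)
            counts = fib.reshape(4, 10, 4, 10).sum(axis=(1, 3)).ravel()
            expected = counts.sum() / 16.0
            stats_sum += ((counts - expected) ** 2 / expected).sum()
        critical = stats.chi2.ppf(0.99, df=15)
        assert stats_sum / n_seeds < critical


class TestElementConductivity:
    def _grid_with_kinds(self, kinds_2x2):
        grid = st.make_sheet(2, 2)
        grid.node_kind = np.array(kinds_2x2, dtype=np.int8)
        return st.assign_element_conductivity(grid)

    def test_pure_myocardium_keeps_baseline(self):
        g = self._grid_with_kinds([[0, 0], [0, 0]])
        assert g.element_conductivity[0, 0] == 0.26

    def test_single_fibrocyte_corner_assigns_its_conductivity(self):
        g = self._grid_with_kinds([[3, 0], [0, 0]])
        assert g.element_conductivity[0, 0] == 0.024

    def test_mixed_kinds_take_minimum(self):
        g = self._grid_with_kinds([[1, 3], [0, 0]])
        assert g.element_conductivity[0, 0] == 0.024

    def test_all_corner_combinations_follow_min_rule(self):
        """Exhaustive enumeration of the 4^4 corner-kind combinations against
        an independent minimum-conductivity computation."""
        cond = {0: 0.26, 1: 0.078, 2: 0.078, 3: 0.024}
        for combo in itertools.product(range(4), repeat=4):
            g = self._grid_with_kinds([[combo[0], combo[1]],
                                       [combo[2], combo[3]]])
            fibrotic = [cond[k] for k in combo if k != 0]
            expected = min(fibrotic) if fibrotic else 0.26
            assert g.element_conductivity[0, 0] == expected, combo


class TestElectrodes:
    def test_regular_coverage_at_offset(self):
        grid = st.make_sheet(100, 100)
        arr = st.place_electrodes(grid, layout=(5, 5))
        assert arr.n_electrodes == 25
        assert np.all(arr.positions[:, 2] == pytest.approx(0.02))

    def test_study_layout_emulation_50_electrodes(self):
        """28 LA-region + 22 RA-region electrodes."""
        grid = st.make_sheet(100, 100, region_layout="split")
        arr = st.place_electrodes(grid, layout=[(4, 7), (2, 11)])
        assert arr.n_electrodes == 50
        names = arr.region_names()
        assert names.count("left_atrium") == 28
        assert names.count("right_atrium") == 22

    def test_zero_offset_rejected(self):
        grid = st.make_sheet(10, 10)
        with pytest.raises(ValueError):
            st.place_electrodes(grid, offset=0.0)


class TestSlab:
    def test_slab_counts_and_hex_conductivity(self):
        slab = st.make_slab(10, 8, 3)
        assert slab.n_nodes == 240
        assert slab.hex_conductivity.shape == (2, 7, 9)
        assert np.all(slab.hex_conductivity == 0.26)

    def test_hex_rule_any_of_eight_corners(self):
        slab = st.make_slab(3, 3, 2)
        slab.layers[1].node_kind[2, 2] = KIND_CODE["fibrocyte"]
        st.assign_hex_conductivity(slab)
        assert slab.hex_conductivity[0, 1, 1] == 0.024
        assert slab.hex_conductivity[0, 0, 0] == 0.26

    def test_slab_fibrosis_reproducible_and_independent_layers(self):
        slab = st.make_slab(20, 20, 3)
        cfg = st.FibrosisConfig(kinds=("fibrocyte",), density=0.25, seed=4)
        a = st.generate_fibrosis_slab(slab, cfg)
        b = st.generate_fibrosis_slab(slab, cfg)
        assert np.array_equal(a.node_kind_stack(), b.node_kind_stack())
        kinds = a.node_kind_stack()
        assert not np.array_equal(kinds[0], kinds[1])
        for l in range(3):
            assert (kinds[l] != 0).sum() == 100


def test_vtk_roundtrip_header(tmp_path):
    grid = st.make_sheet(5, 4)
    path = tmp_path / "sheet.vtk"
    st.write_vtk(grid, path)
    lines = path.read_text().splitlines()
    assert lines[3] == "DATASET STRUCTURED_GRID"
    assert lines[4] == "DIMENSIONS 5 4 1"
    assert f"POINT_DATA {grid.n_nodes}" in lines
    assert f"CELL_DATA {grid.n_elements}" in lines


def test_electrode_csv(tmp_path):
    grid = st.make_sheet(10, 10)
    arr = st.place_electrodes(grid, layout=(2, 2))
    path = tmp_path / "elec.csv"
    st.electrodes_to_csv(arr, path)
    rows = path.read_text().splitlines()
    assert rows[0] == "id,x_mm,y_mm,z_mm,region"
    assert len(rows) == 1 + arr.n_electrodes
    assert rows[1].endswith("left_atrium")
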