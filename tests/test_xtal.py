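"""Crystallographic math core: structure factors, syntheses, phase errors."""

import numpy as np
import pytest

from phaseformer.xtal import (
    Atom,
    DomainMismatchError,
    EmptyStructureError,
    FragmentStructure,
    InvalidCellError,
    InvalidMapError,
    InvalidResolutionError,
    NonRealDensityError,
    ReflectionSet,
    UnitCell,
    VolumeGrid,
    build_grid,
    calc_structure_factors,
    density_from_sf,
    normalize_map,
    patterson_from_density,
    patterson_from_sf,
    phase_error,
    scattering_factor,
    sf_from_density,
)

from conftest import random_point_structure


def direct_sum_density(refs, dims):
    """Naive density synthesis: explicit loop over reflections and voxels."""
    hkl, f = refs.full_sphere()
    n1, n2, n3 = dims
    x, y, z = np.meshgrid(np.arange(n1) / n1, np.arange(n2) / n2,
                          np.arange(n3) / n3, indexing="ij")
    rho = np.zeros(dims, dtype=complex)
    for (h, k, l), fv in zip(hkl, f):
        amp, phi = np.abs(fv), np.angle(fv)
        rho += amp * np.exp(-2j * np.pi * (h * x + k * y + l * z) + 1j * phi)
    return rho.real / refs.cell.volume


def brute_force_sf(structure, hkl):
    """Independent direct summation (python loop, point scatterers)."""
    from phaseformer.xtal import ELECTRON_COUNTS
    out = []
    for h, k, l in hkl:
        total = 0j
        for atom in structure.atoms:
            x, y, z = atom.position / structure.cell.edges
            f = ELECTRON_COUNTS.get(atom.element, 1) * atom.occupancy
            total += f * np.exp(2j * np.pi * (h * x + k * y + l * z))
        out.append(total)
    return np.array(out)


class TestUnitCellAndGrid:
    def test_volume_is_edge_product(self):
        assert UnitCell(2.0, 3.0, 4.0).volume == pytest.approx(24.0)

    @pytest.mark.parametrize("edges", [(0, 1, 1), (-2, 3, 3), (1, 1, -1)])
    def test_nonpositive_edges_rejected(self, edges):
        with pytest.raises(InvalidCellError):
            UnitCell(*edges)

    def test_fifteenmer_cell_spacing_and_dims(self):
        # 41 x 30 x 24 A at d_min 1.5, oversampling 3.0 -> 0.5 A voxels
        spec = build_grid(UnitCell(41, 30, 24), 1.5, 3.0)
        assert spec.spacing == (0.5, 0.5, 0.5)
        assert spec.dims == (82, 60, 48)

    def test_exact_division_cell(self):
        spec = build_grid(UnitCell(10, 10, 10), 2.0, 2.0)
        assert spec.spacing == (1.0, 1.0, 1.0)
        assert spec.dims == (10, 10, 10)

    def test_dims_rounded_up_to_even_and_cover_cell(self):
        spec = build_grid(UnitCell(10.3, 7.1, 5.0), 2.0, 2.0)
        for n, edge in zip(spec.dims, (10.3, 7.1, 5.0)):
            assert n % 2 == 0
            assert n * 1.0 >= edge

    def test_invalid_resolution(self):
        with pytest.raises(InvalidResolutionError):
            build_grid(UnitCell(10, 10, 10), -1.0, 3.0)


class TestStructureFactors:
    def test_atom_at_origin_gives_unit_factors(self):
        st = FragmentStructure([Atom("X", [0, 0, 0])], [("GLY", (0, 1))],
                               UnitCell(10, 10, 10))
        refs = calc_structure_factors(st, 3.0)
        assert np.allclose(refs.f, 1.0 + 0j)

    def test_body_center_alternates_sign(self):
        st = FragmentStructure([Atom("X", [5.0, 5.0, 5.0])], [("GLY", (0, 1))],
                               UnitCell(10, 10, 10))
        refs = calc_structure_factors(st, 3.0)
        expected = (-1.0) ** refs.hkl.sum(axis=1)
        assert np.allclose(refs.f, expected, atol=1e-12)

    def test_two_atom_amplitudes_along_h(self):
        # atoms at fractional 0 and 1/4 on x: |F(h00)| = |1 + i^h|
        st = FragmentStructure(
            [Atom("X", [0, 0, 0]), Atom("X", [2.5, 0, 0])],
            [("GLY", (0, 2))], UnitCell(10, 10, 10))
        refs = calc_structure_factors(st, 2.0)
        lookup = {tuple(hkl): f for hkl, f in zip(map(tuple, refs.hkl), refs.f)}
        expected = [2.0, np.sqrt(2), 0.0, np.sqrt(2), 2.0]
        for h, amp in enumerate(expected):
            assert abs(lookup[(h, 0, 0)]) == pytest.approx(amp, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        st = random_point_structure(rng, n_atoms=4)
        refs = calc_structure_factors(st, 2.5)
        oracle = brute_force_sf(st, refs.hkl)
        assert np.allclose(refs.f, oracle, atol=1e-9)

    def test_friedel_property_exact(self, rng):
        st = random_point_structure(rng, n_atoms=6)
        refs = calc_structure_factors(st, 2.0)
        hkl, f = refs.full_sphere()
        lookup = {tuple(h): v for h, v in zip(map(tuple, hkl), f)}
        for h, v in lookup.items():
            assert lookup[tuple(-np.array(h))] == pytest.approx(np.conj(v))

    def test_empty_structure_rejected(self):
        st = FragmentStructure([], [], UnitCell(10, 10, 10))
        with pytest.raises(EmptyStructureError):
            calc_structure_factors(st, 2.0)

    def test_bad_resolution_rejected(self, rng):
        st = random_point_structure(rng)
        with pytest.raises(InvalidResolutionError):
            calc_structure_factors(st, 0.0)

    def test_gaussian_form_factors_match_gemmi_it92(self):
        import gemmi

        s = np.linspace(0.0, 1.2, 7)
        for el in ("C", "N", "O", "S"):
            ours = scattering_factor(el, s, "gaussian")
            theirs = [gemmi.Element(el).it92.calculate_sf((si / 2) ** 2)
                      for si in s]
            assert np.allclose(ours, theirs, atol=1e-5)
        # hydrogen parameterizations differ between tables; agree loosely
        ours_h = scattering_factor("H", s, "gaussian")
        theirs_h = [gemmi.Element("H").it92.calculate_sf((si / 2) ** 2)
                    for si in s]
        assert np.allclose(ours_h, theirs_h, atol=0.1)
        assert ours_h[0] == pytest.approx(1.0, abs=2e-3)  # electron count at s=0

    def test_gaussian_sf_match_gemmi_calculator(self):
        import gemmi

        cell = UnitCell(12.0, 10.0, 9.0)
        atoms = [Atom("C", [2.0, 3.0, 4.0]), Atom("N", [5.5, 6.0, 2.5]),
                 Atom("O", [8.0, 1.5, 7.0])]
        st = FragmentStructure(atoms, [("GLY", (0, 3))], cell)
        refs = calc_structure_factors(st, 2.0, scattering_model="gaussian")

        g = gemmi.Structure()
        g.cell = gemmi.UnitCell(cell.a, cell.b, cell.c, 90, 90, 90)
        g.spacegroup_hm = "P 1"
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(1, " ")
        for i, atom in enumerate(atoms):
            a = gemmi.Atom()
            a.name = f"{atom.element}{i}"
            a.element = gemmi.Element(atom.element)
            a.pos = gemmi.Position(*atom.position)
            a.occ = 1.0
            a.b_iso = 0.0
            res.add_atom(a)
        chain.add_residue(res)
        model.add_chain(chain)
        g.add_model(model)
        calc = gemmi.StructureFactorCalculatorX(g.cell)
        for hkl, ours in zip(refs.hkl[:40], refs.f[:40]):
            theirs = complex(calc.calculate_sf_from_model(g[0], tuple(hkl)))
            assert ours == pytest.approx(theirs, abs=5e-3 * max(1.0, abs(theirs)))


class TestDensitySynthesis:
    def test_f000_only_gives_uniform_map(self):
        cell = UnitCell(8.3, 8.3, 8.3)
        refs = calc_structure_factors(
            FragmentStructure([Atom("X", [1, 2, 3])], [("GLY", (0, 1))], cell), 2.5)
        f = np.where(np.all(refs.hkl == 0, axis=1), cell.volume + 0j, 0j)
        uniform = density_from_sf(ReflectionSet(cell, 2.5, refs.hkl, f),
                                  build_grid(cell, 2.5, 2.4))
        assert np.allclose(uniform.values, 1.0, atol=1e-12)

    def test_fft_matches_direct_summation(self, rng):
        for _ in range(3):
            st = random_point_structure(rng, n_atoms=5, cell=(8.3, 8.3, 8.3))
            refs = calc_structure_factors(st, 2.5)
            grid = build_grid(st.cell, 2.5, 2.4)
            assert grid.dims == (8, 8, 8)
            fft_map = density_from_sf(refs, grid)
            naive = direct_sum_density(refs, grid.dims)
            assert np.max(np.abs(fft_map.values - naive)) < 1e-9

    def test_band_limited_round_trip(self, rng):
        st = random_point_structure(rng, n_atoms=5)
        refs = calc_structure_factors(st, 2.0)
        grid = build_grid(st.cell, 2.0, 3.0)
        e = density_from_sf(refs, grid)
        refs2 = sf_from_density(e, 2.0)
        e2 = density_from_sf(refs2, grid)
        assert np.max(np.abs(e.values - e2.values)) < 1e-9

    def test_friedel_violation_raises(self):
        # an imaginary F(000) has no Friedel mate to cancel it: complex density
        cell = UnitCell(10, 10, 10)
        hkl = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        f = np.array([1j * cell.volume, 1.0 + 0j, 0j])
        with pytest.raises(NonRealDensityError):
            density_from_sf(ReflectionSet(cell, 5.0, hkl, f),
                            build_grid(cell, 5.0, 2.0))


class TestPatterson:
    def test_origin_peak_is_global_max(self, rng):
        st = random_point_structure(rng, n_atoms=1)
        refs = calc_structure_factors(st, 2.5)
        p = patterson_from_sf(refs, build_grid(st.cell, 2.5, 3.0))
        assert np.unravel_index(np.argmax(p.values), p.dims) == (0, 0, 0)

    def test_two_atom_interatomic_vector_peaks(self):
        # two unit deltas separated by 4 voxels: the autocorrelation has its
        # origin peak at exactly twice the +-delta satellite heights
        cell = UnitCell(12.0, 12.0, 12.0)
        values = np.zeros((12, 12, 12))
        values[0, 0, 0] = 1.0
        values[4, 0, 0] = 1.0
        e = VolumeGrid(values, cell, (1.0, 1.0, 1.0))
        p = patterson_from_density(e).values
        assert np.unravel_index(np.argmax(p), p.shape) == (0, 0, 0)
        assert p[4, 0, 0] == pytest.approx(p[-4, 0, 0], rel=1e-12)
        assert p[0, 0, 0] == pytest.approx(2 * p[4, 0, 0], rel=1e-9)
        # no other voxel carries significant weight
        mask = np.ones_like(p, dtype=bool)
        mask[0, 0, 0] = mask[4, 0, 0] = mask[-4, 0, 0] = False
        assert np.max(np.abs(p[mask])) < 1e-9 * p[0, 0, 0]

    def test_band_limited_two_atom_satellites(self):
        # with truncated data the +-delta peaks remain symmetric local maxima
        cell = UnitCell(12.0, 12.0, 12.0)
        st = FragmentStructure(
            [Atom("X", [0, 0, 0]), Atom("X", [3.0, 0, 0])],
            [("GLY", (0, 2))], cell)
        refs = calc_structure_factors(st, 3.0)
        p = patterson_from_sf(refs, build_grid(cell, 3.0, 4.0))
        n1 = p.dims[0]
        dvox = round(3.0 / cell.a * n1)
        assert p.values[dvox, 0, 0] == pytest.approx(p.values[-dvox, 0, 0],
                                                     rel=1e-9)
        assert p.values[0, 0, 0] > p.values[dvox, 0, 0] > 0

    def test_squared_amplitude_and_autocorrelation_routes_agree(self, rng):
        st = random_point_structure(rng, n_atoms=7)
        refs = calc_structure_factors(st, 2.0)
        grid = build_grid(st.cell, 2.0, 3.0)
        via_sf = patterson_from_sf(refs, grid)
        via_density = patterson_from_density(density_from_sf(refs, grid))
        scale = np.max(np.abs(via_sf.values))
        assert np.max(np.abs(via_sf.values - via_density.values)) / scale < 1e-6

    def test_zero_map_gives_zero_patterson(self):
        zero = VolumeGrid(np.zeros((8, 8, 8)), UnitCell(8, 8, 8), (1, 1, 1))
        assert np.all(patterson_from_density(zero).values == 0)

    def test_translation_invariance_of_autocorrelation(self, rng):
        e = VolumeGrid(rng.standard_normal((8, 8, 8)), UnitCell(8, 8, 8),
                       (1, 1, 1))
        p0 = patterson_from_density(e)
        shifted = e.copy_with(np.roll(e.values, (3, 1, 5), axis=(0, 1, 2)))
        p1 = patterson_from_density(shifted)
        assert np.max(np.abs(p0.values - p1.values)) < 1e-10

    def test_centrosymmetry_by_explicit_index_check(self, rng):
        e = VolumeGrid(rng.standard_normal((8, 8, 8)), UnitCell(8, 8, 8),
                       (1, 1, 1))
        p = patterson_from_density(e).values
        n1, n2, n3 = p.shape
        for i in range(n1):
            for j in range(n2):
                for k in range(n3):
                    assert p[i, j, k] == pytest.approx(
                        p[-i % n1, -j % n2, -k % n3], abs=1e-10)


class TestNormalizeMap:
    def _grid(self, values):
        return VolumeGrid(np.asarray(values, dtype=float).reshape(1, 1, -1),
                          UnitCell(5, 5, 5), (1, 1, 1))

    def test_divides_by_max_abs_preserving_zero(self):
        out = normalize_map(self._grid([-2.0, 0.0, 4.0]))
        assert np.allclose(out.values.ravel(), [-0.5, 0.0, 1.0])
        assert out.normalized

    def test_all_zero_unchanged(self):
        out = normalize_map(self._grid([0.0, 0.0, 0.0]))
        assert np.all(out.values == 0)
        assert out.normalized

    def test_idempotent_and_sign_preserving(self, rng):
        vals = rng.standard_normal(27)
        once = normalize_map(self._grid(vals))
        twice = normalize_map(once)
        assert np.array_equal(once.values, twice.values)
        assert np.array_equal(np.sign(once.values.ravel()), np.sign(vals))

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidMapError):
            normalize_map(self._grid([1.0, np.nan, 0.0]))


class TestPhaseError:
    def _refs_pair(self, rng, n_min=200, d_min=1.2):
        cell = UnitCell(14, 13, 12)
        st = random_point_structure(rng, n_atoms=5, cell=(14, 13, 12))
        truth = calc_structure_factors(st, d_min)
        assert len(truth) >= n_min
        return cell, truth

    def test_identical_sets_have_zero_error(self, rng):
        _, truth = self._refs_pair(rng)
        res = phase_error(truth, truth, n_shells=5)
        assert res.mean_deg == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.shell_mean_deg, 0.0)
        assert np.allclose(res.shell_frac_below_60, 1.0)

    def test_antiphase_gives_180(self, rng):
        cell, truth = self._refs_pair(rng)
        flipped = ReflectionSet(cell, truth.d_min, truth.hkl, -truth.f)
        res = phase_error(flipped, truth, n_shells=5)
        assert res.mean_deg == pytest.approx(180.0, abs=1e-9)

    def test_uniform_random_phases_average_90_degrees(self):
        cell = UnitCell(30, 28, 26)
        st = FragmentStructure([Atom("C", [3.0, 4.0, 5.0])], [("GLY", (0, 1))],
                               cell)
        truth = calc_structure_factors(st, 1.5)
        assert len(truth) >= 5000
        rng = np.random.default_rng(7)
        phases = rng.uniform(0, 2 * np.pi, size=len(truth))
        pred = ReflectionSet(cell, truth.d_min, truth.hkl,
                             truth.amplitudes * np.exp(1j * phases))
        res = phase_error(pred, truth, n_shells=10)
        assert res.mean_deg == pytest.approx(90.0, abs=2.0)

    def test_shells_partition_reflections_equally(self, rng):
        _, truth = self._refs_pair(rng)
        res = phase_error(truth, truth, n_shells=7)
        assert res.shell_count.sum() == len(truth) - 1  # F(000) excluded
        assert res.shell_count.max() - res.shell_count.min() <= 1
        # low-resolution shell first
        assert res.shell_d_max[0] >= res.shell_d_max[-1]

    def test_mismatched_domains_rejected(self, rng):
        cell, truth = self._refs_pair(rng)
        shrunk = ReflectionSet(cell, truth.d_min, truth.hkl[:-5], truth.f[:-5])
        with pytest.raises(DomainMismatchError):
            phase_error(shrunk, truth, n_shells=5)
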