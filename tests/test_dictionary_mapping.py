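"""Dictionary construction, polarity restoration and inner-product matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomap import bloch
from cardiomap.dictionary import Dictionary, DictionaryGrid, generate_dictionary
from cardiomap.mapping import (
    SENTINEL,
    match_maps,
    match_signals,
    match_voxel,
    restore_polarity,
)
from cardiomap.params import TissueParams


class TestGrid:
    def test_printed_ranges_give_291_by_122(self):
        grid = DictionaryGrid()
        assert len(grid.t1_values) == 291
        assert len(grid.t1rho_values) == 122
        assert grid.n_atoms == 35_502

    def test_values_strictly_increasing_and_positive(self):
        grid = DictionaryGrid()
        for v in (grid.t1_values, grid.t1rho_values):
            assert np.all(np.diff(v) > 0)
            assert np.all(v > 0)


class TestDictionary:
    def test_atoms_unit_norm(self, full_dictionary):
        norms = np.linalg.norm(full_dictionary.atoms, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_atom_consistent_with_direct_simulation(
        self, full_dictionary, seq, timing60
    ):
        idx = np.flatnonzero(
            (full_dictionary.atom_params[:, 0] == 700)
            & (full_dictionary.atom_params[:, 1] == 56)
        )[0]
        sig = bloch.simulate_signals(seq, timing60, TissueParams(0.7, 0.056))
        expected = sig.signals / np.linalg.norm(sig.signals)
        # agreement bounded by the steady-state fixed-point tolerance
        np.testing.assert_allclose(full_dictionary.atoms[idx], expected, atol=2e-5)

    def test_hdf5_round_trip(self, coarse_dictionary, tmp_path):
        path = tmp_path / "dict.h5"
        coarse_dictionary.save(path, config={"hr": 60})
        loaded = Dictionary.load(path)
        np.testing.assert_array_equal(loaded.atoms, coarse_dictionary.atoms)
        np.testing.assert_array_equal(
            loaded.atom_params, coarse_dictionary.atom_params
        )
        assert loaded.hr == coarse_dictionary.hr


class TestMatching:
    def test_noiseless_atom_self_match_is_exact(self, coarse_dictionary):
        rng = np.random.default_rng(0)
        idx = rng.choice(coarse_dictionary.n_atoms, 50, replace=False)
        scaled = 3.7 * coarse_dictionary.atoms[idx]
        t1, t1rho, ssd = match_signals(scaled, coarse_dictionary)
        np.testing.assert_array_equal(t1, coarse_dictionary.atom_params[idx, 0])
        np.testing.assert_array_equal(t1rho, coarse_dictionary.atom_params[idx, 1])
        assert np.all(ssd < 1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None)
    def test_match_invariant_to_positive_scaling(self, scale):
        # build a small dictionary inline: hypothesis cannot see fixtures'
        # session scope safely, so use a deterministic module-level cache
        d = _cached_dict()
        idx = 123 % d.n_atoms
        sig = d.atoms[idx] * scale
        t1, t1rho, _ = match_signals(sig[None], d)
        assert (t1[0], t1rho[0]) == tuple(d.atom_params[idx])

    def test_off_grid_tissue_matches_brute_force(
        self, full_dictionary, seq, timing60
    ):
        sig = bloch.simulate_signals(seq, timing60, TissueParams(0.702, 0.056))
        t1, t1rho, _ = match_signals(sig.signals[None], full_dictionary)
        # brute force over all atoms
        unit = sig.signals / np.linalg.norm(sig.signals)
        best = int(np.argmax(full_dictionary.atoms @ unit))
        assert t1[0] == full_dictionary.atom_params[best, 0]
        assert t1rho[0] == full_dictionary.atom_params[best, 1]
        assert abs(t1[0] - 702) <= 5.0

    def test_ssd_equals_two_minus_twice_inner_product(self, coarse_dictionary):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=(20, 4))
        _, _, ssd = match_signals(sig, coarse_dictionary)
        unit = sig / np.linalg.norm(sig, axis=1, keepdims=True)
        ip = unit @ coarse_dictionary.atoms.T
        np.testing.assert_allclose(ssd, 2 - 2 * ip.max(axis=1), atol=1e-12)

    def test_zero_voxel_gets_sentinel_not_nan(self, coarse_dictionary):
        sig = np.zeros((1, 4))
        t1, t1rho, ssd = match_signals(sig, coarse_dictionary)
        assert t1[0] == SENTINEL and t1rho[0] == SENTINEL
        assert not np.isnan(ssd[0])

    def test_match_maps_masks_and_geometry(self, coarse_dictionary):
        vol = np.zeros((4, 4, 4, 3))
        vol[:, 1, 1, 1] = coarse_dictionary.atoms[100]
        mask = np.zeros((4, 4, 3), dtype=bool)
        mask[1, 1, 1] = True
        maps = match_maps(vol, coarse_dictionary, mask=mask)
        assert maps.t1[1, 1, 1] == coarse_dictionary.atom_params[100, 0]
        assert maps.t1[0, 0, 0] == SENTINEL
        with pytest.raises(ValueError):
            match_maps(vol, coarse_dictionary, mask=np.ones((2, 2, 2), bool))

    def test_match_voxel_records_polarity(self, coarse_dictionary):
        res = match_voxel(coarse_dictionary.atoms[5], coarse_dictionary)
        assert res.ssd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(
            res.polarity, np.sign(coarse_dictionary.atoms[5])
        )


_DICT_CACHE = {}


def _cached_dict():
    if "d" not in _DICT_CACHE:
        from cardiomap.params import CardiacTiming, SequenceParams

        grid = DictionaryGrid(
            t1_values=np.arange(100, 1501, 50), t1rho_values=np.arange(10, 121, 5)
        )
        _DICT_CACHE["d"] = generate_dictionary(
            SequenceParams(), CardiacTiming.from_hr(60), grid
        )
    return _DICT_CACHE["d"]


class TestPolarity:
    def _volumes(self, signed, phase):
        water = np.abs(signed) * np.exp(1j * (phase + np.pi * (signed < 0)))
        return water

    def test_zero_phase_gives_positive_magnitude(self):
        rng = np.random.default_rng(0)
        mag = rng.uniform(0.1, 1.0, size=(4, 8, 8, 4))
        out = restore_polarity(mag.astype(complex), mag.astype(complex))
        np.testing.assert_allclose(out, mag, rtol=1e-12)

    def test_uniform_background_phase_recovered(self):
        """Signed image + constant 2 rad background: signs restored exactly."""
        rng = np.random.default_rng(1)
        shape = (16, 16, 6)
        signed = np.stack(
            [rng.uniform(0.2, 1.0, shape) * s for s in (-1.0, 1.0, 1.0, 1.0)]
        )
        phase = 2.0
        water = self._volumes(signed, phase)
        psip = np.abs(signed) * np.exp(1j * phase)  # non-inverted reference
        out = restore_polarity(water, psip, sigma=4.0, reference=1)
        np.testing.assert_allclose(np.sign(out), np.sign(signed))
        np.testing.assert_allclose(np.abs(out), np.abs(signed), rtol=1e-10)

    def test_ir_volume_negative_for_long_t1(self, seq, timing60):
        """At TI 245 ms a long-T1 tissue is still inverted in volume 1."""
        sig = bloch.simulate_signals(seq, timing60, TissueParams(1.5, 0.08))
        assert sig.signals[0] < 0
        shape = (8, 8, 4)
        signed = np.stack([np.full(shape, s) for s in sig.signals])
        water = self._volumes(signed, phase=1.0)
        psip = np.abs(signed) * np.exp(1j * 1.0)
        out = restore_polarity(water, psip, sigma=2.0, reference=1)
        assert np.all(out[0] < 0)

    def test_geometry_mismatch_raises(self):
        with pytest.raises(ValueError):
            restore_polarity(np.zeros((4, 4, 4, 2)), np.zeros((4, 4, 4, 3)))
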