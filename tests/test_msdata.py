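import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cannclass.msdata import (
    ClassAnnotation,
    MassSpectrum,
    bin_to_unit_mass,
    build_matrix,
    crop_spectrum,
    normalize_base_peak,
    read_annotations,
    read_msp,
    write_annotations,
    write_msp,
)


def spec(peaks, cid="c1"):
    return MassSpectrum(compound_id=cid, name=cid, peaks=tuple(peaks))


# ---------------------------------------------------------------------------
# MSP dialect
# ---------------------------------------------------------------------------

class TestReadMsp:
    def test_semicolon_pairs_sorted_by_mz(self, tmp_path):
        p = tmp_path / "lib.msp"
        p.write_text("Name: X\nNum Peaks: 2\n144 999; 116 250\n")
        (s,) = read_msp(p)
        assert s.name == "X"
        assert s.peaks == ((116.0, 250.0), (144.0, 999.0))

    def test_peak_count_mismatch_skips_record(self, tmp_path, caplog):
        p = tmp_path / "lib.msp"
        p.write_text(
            "Name: bad\nNum Peaks: 3\n144 999; 116 250\n\n"
            "Name: good\nNum Peaks: 1\n77 100\n"
        )
        with caplog.at_level("WARNING"):
            out = read_msp(p)
        assert [s.name for s in out] == ["good"]
        assert any("declares 3 peaks" in r.message for r in caplog.records)

    def test_extra_header_fields_ignored(self, tmp_path):
        p = tmp_path / "lib.msp"
        p.write_text(
            "Name: X\nFormula: C10H10\nComments: whatever\nNum Peaks: 2\n"
            "50 10\n60 20\n"
        )
        (s,) = read_msp(p)
        assert len(s.peaks) == 2

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.msp"
        p.write_text("\n\n")
        with pytest.raises(ValueError):
            read_msp(p)

    def test_round_trip_ten_records(self, tmp_path):
        rng = np.random.default_rng(42)
        originals = []
        for i in range(10):
            mz = np.sort(rng.choice(np.arange(40, 301), size=12, replace=False))
            inten = rng.uniform(1, 999, size=12)
            originals.append(spec(zip(mz.astype(float), inten), cid=f"cmp{i}"))
        f = tmp_path / "rt.msp"
        write_msp(originals, f)
        back = read_msp(f)
        assert len(back) == 10
        for a, b in zip(originals, back):
            assert a.name == b.name
            np.testing.assert_allclose(a.mz, b.mz, atol=1e-9)
            np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-9)

    def test_round_trip_against_matchms(self, tmp_path):
        """Independent read-back of our MSP output with matchms."""
        matchms = pytest.importorskip("matchms.importing")
        originals = [
            spec([(56.0, 10.0), (144.0, 999.0)], cid="JWH018LIKE"),
            spec([(109.0, 500.0), (252.0, 120.0)], cid="FUBLIKE"),
        ]
        f = tmp_path / "x.msp"
        write_msp(originals, f)
        loaded = list(matchms.load_from_msp(str(f)))
        assert len(loaded) == 2
        for ours, theirs in zip(originals, loaded):
            np.testing.assert_allclose(theirs.peaks.mz, ours.mz)
            np.testing.assert_allclose(theirs.peaks.intensities, ours.intensity)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

peaks_strategy = st.lists(
    st.tuples(
        st.floats(min_value=1.0, max_value=400.0, allow_nan=False),
        st.floats(min_value=0.1, max_value=1e4, allow_nan=False),
    ),
    min_size=1,
    max_size=30,
    unique_by=lambda t: round(t[0], 2),
)


class TestNormalize:
    def test_linear_rescale(self):
        s = normalize_base_peak(spec([(144, 500), (116, 250)]))
        assert dict(s.peaks) == {116.0: 50.0, 144.0: 100.0}

    def test_identity_when_already_scaled(self):
        s = spec([(116, 50.0), (144, 100.0)])
        assert normalize_base_peak(s).peaks == s.peaks

    @given(peaks_strategy)
    def test_intensity_ratios_preserved(self, peaks):
        s = normalize_base_peak(spec(peaks))
        orig = np.array([i for _, i in sorted(peaks)])
        new = s.intensity
        np.testing.assert_allclose(new / new.max(), orig / orig.max(), rtol=1e-12)


class TestCrop:
    def test_inclusive_bounds(self):
        s = crop_spectrum(spec([(39, 1), (40, 2), (300, 3), (301, 4)]))
        assert s.mz.tolist() == [40.0, 300.0]

    def test_identity_inside_range(self):
        s = spec([(50, 1), (200, 2)])
        assert crop_spectrum(s).peaks == s.peaks

    def test_all_cropped_returns_none(self):
        assert crop_spectrum(spec([(20, 5)])) is None

    @given(peaks_strategy)
    def test_idempotent(self, peaks):
        once = crop_spectrum(spec(peaks))
        if once is not None:
            assert crop_spectrum(once).peaks == once.peaks


class TestBinning:
    def test_single_peak_index(self):
        v = bin_to_unit_mass(spec([(144.0, 999)]), lo=40)
        assert v[104] == 999
        assert v.sum() == 999

    def test_rounding_collisions_summed(self):
        v = bin_to_unit_mass(spec([(144.4, 10), (143.6, 5)]))
        assert v[144 - 40] == 15

    def test_default_length_261(self):
        assert len(bin_to_unit_mass(spec([(100, 1)]))) == 261

    @given(peaks_strategy)
    def test_total_intensity_conserved(self, peaks):
        s = crop_spectrum(spec(peaks))
        if s is not None:
            assert np.isclose(bin_to_unit_mass(s).sum(), s.intensity.sum())


class TestBuildMatrix:
    def _ann(self, cid):
        return ClassAnnotation(compound_id=cid, is_cannabinoid=False)

    def test_shape_and_row_order(self):
        spectra = [spec([(100, 1)], f"c{i}") for i in range(3)]
        anns = [self._ann(f"c{i}") for i in range(3)]
        m = build_matrix(spectra, anns)
        assert m.X.shape == (3, 261)
        assert m.sample_ids == ["c0", "c1", "c2"]

    def test_missing_annotation_names_compound(self):
        spectra = [spec([(100, 1)], "c0"), spec([(100, 1)], "lost")]
        with pytest.raises(ValueError, match="lost"):
            build_matrix(spectra, [self._ann("c0")])

    def test_duplicate_id_rejected(self):
        spectra = [spec([(100, 1)], "dup"), spec([(110, 1)], "dup")]
        with pytest.raises(ValueError, match="dup"):
            build_matrix(spectra, [self._ann("dup")])

    def test_permutation_permutes_rows(self):
        rng = np.random.default_rng(1)
        spectra = [
            spec([(50 + 10 * i, 5), (90 + i, rng.uniform(1, 9))], f"c{i}")
            for i in range(6)
        ]
        anns = [self._ann(f"c{i}") for i in range(6)]
        m1 = build_matrix(spectra, anns)
        perm = [3, 0, 5, 1, 4, 2]
        m2 = build_matrix([spectra[i] for i in perm], anns)
        np.testing.assert_array_equal(m1.X[perm], m2.X)
        assert m2.sample_ids == [f"c{i}" for i in perm]

    def test_pipeline_deterministic(self):
        spectra = [spec([(144.3, 7.5), (144.6, 2.5), (60, 1)], "a")]
        anns = [self._ann("a")]
        x1 = build_matrix(spectra, anns).X
        x2 = build_matrix(spectra, anns).X
        assert (x1 == x2).all()


class TestAnnotations:
    def test_csv_round_trip(self, tmp_path):
        anns = [
            ClassAnnotation("jwh018", True, False, "indole", True, False, False),
            ClassAnnotation("thc", True, True),
            ClassAnnotation("fentanyl", False),
        ]
        f = tmp_path / "labels.csv"
        write_annotations(anns, f)
        assert read_annotations(f) == anns

    def test_subgroup_on_non_cannabinoid_rejected(self):
        with pytest.raises(ValueError):
            ClassAnnotation("x", False, core_group="indole")

    def test_core_on_classical_rejected(self):
        with pytest.raises(ValueError):
            ClassAnnotation("x", True, True, core_group="indole")
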