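"""Encoding, framing, magnitude spectra and spectrograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specgmm import seq_signal as sig
from specgmm.seq_signal import (
    GenomicSignal,
    LabeledSequence,
    encode_pp,
    frame_windows,
    magnitude_spectrum,
    next_power_of_two,
    read_fasta_with_labels,
    spectrogram,
)


def _seq(dna, sid="s1", label="x"):
    return LabeledSequence(id=sid, dna=dna, label=label)


class TestEncodePP:
    @pytest.mark.parametrize(
        "dna, expected",
        [
            ("AG", [-1, -1]),          # purines map to -1
            ("ACGT", [-1, 1, -1, 1]),  # pyrimidines map to +1
            ("ANA", [-1, -1]),         # N positions removed
            ("acgt", [-1, 1, -1, 1]),  # lowercase accepted
        ],
    )
    def test_mapping(self, dna, expected):
        out = encode_pp(_seq(dna))
        assert out.values.tolist() == expected

    def test_all_n_errors(self):
        with pytest.raises(ValueError, match="empty after N removal"):
            encode_pp(_seq("NNN"))

    def test_bad_character_named(self):
        with pytest.raises(ValueError, match="'X'"):
            encode_pp(_seq("AXG"))

    def test_alternative_encoders_share_interface(self):
        for name in ("real", "integer", "eiip"):
            out = sig.encode(_seq("ACGTN"), name)
            assert out.length == 4
        with pytest.raises(ValueError, match="unknown encoder"):
            sig.encode(_seq("ACGT"), "nope")


class TestFraming:
    @pytest.mark.parametrize(
        "length, winlen, winshift, expected_starts",
        [
            (351, 351, 99, [0]),
            (549, 351, 99, [0, 99, 198]),
            (100, 351, 99, [0]),  # short sequence keeps one whole frame
        ],
    )
    def test_window_starts(self, length, winlen, winshift, expected_starts):
        signal = GenomicSignal(id="s", values=np.ones(length))
        starts, frames = frame_windows(signal, winlen, winshift)
        assert starts.tolist() == expected_starts
        expected_len = winlen if length >= winlen else length
        assert all(f.shape[0] == expected_len for f in frames)

    @given(
        length=st.integers(min_value=2, max_value=500),
        winlen=st.integers(min_value=2, max_value=400),
        winshift=st.integers(min_value=1, max_value=120),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_frame_count_formula(self, length, winlen, winshift):
        signal = GenomicSignal(id="s", values=np.ones(length))
        starts, _ = frame_windows(signal, winlen, winshift)
        if length >= winlen:
            assert len(starts) == (length - winlen) // winshift + 1
        else:
            assert len(starts) == 1


def naive_dft_magnitudes(frame, order):
    """Brute-force DFT-sum oracle: |sum_n x[n] e^{-i 2 pi k n / N}| for k < N/2."""
    n = np.arange(len(frame))
    return np.array([
        abs(sum(frame * np.exp(-2j * np.pi * k * n / order)))
        for k in range(order // 2)
    ])


class TestMagnitudeSpectrum:
    @pytest.mark.parametrize("frame_len, order, dim", [(351, 512, 256), (63, 64, 32)])
    def test_dimension(self, frame_len, order, dim, rng):
        frame = rng.choice([-1.0, 1.0], size=frame_len)
        assert magnitude_spectrum(frame, order).shape == (dim,)

    def test_zero_frame(self):
        assert np.all(magnitude_spectrum(np.zeros(16), 16) == 0)

    def test_matches_bruteforce_dft(self, rng):
        frame = rng.choice([-1.0, 1.0], size=16)
        fast = magnitude_spectrum(frame, 16)
        slow = naive_dft_magnitudes(frame, 16)
        np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-12)

    def test_negation_invariance(self, rng):
        # complementing purines<->pyrimidines flips the signal sign only
        frame = rng.choice([-1.0, 1.0], size=63)
        np.testing.assert_allclose(
            magnitude_spectrum(frame, 64), magnitude_spectrum(-frame, 64)
        )

    def test_order_validation(self):
        with pytest.raises(ValueError, match="power of two"):
            magnitude_spectrum(np.ones(10), 12)
        with pytest.raises(ValueError, match=">= frame length"):
            magnitude_spectrum(np.ones(100), 64)


class TestSpectrogram:
    def test_shape_and_column_identity(self):
        values = np.resize([-1.0, -1.0, 1.0], 351 + 2 * 99)
        signal = GenomicSignal(id="s", values=values)
        matrix, starts = spectrogram(signal, 351, 99, 512)
        assert matrix.shape == (256, 3)
        np.testing.assert_allclose(
            matrix[:, 0], magnitude_spectrum(values[:351], 512)
        )

    def test_period3_peak_location(self):
        # period-3 square-ish wave concentrates energy near bin order/3
        values = np.resize([-1.0, 1.0, 1.0], 300)
        signal = GenomicSignal(id="s", values=values)
        matrix, _ = spectrogram(signal, 63, 9, 64)
        peak_bin = round(64 / 3)
        for col in matrix.T:
            assert abs(int(np.argmax(col[1:])) + 1 - peak_bin) <= 1

    def test_single_window_equals_spectrum(self, rng):
        values = rng.choice([-1.0, 1.0], size=50)
        signal = GenomicSignal(id="s", values=values)
        matrix, starts = spectrogram(signal, 63, 9, 64)
        assert matrix.shape == (32, 1)
        np.testing.assert_allclose(matrix[:, 0], magnitude_spectrum(values, 64))

    def test_tsv_and_png_export(self, tmp_path, rng):
        values = rng.choice([-1.0, 1.0], size=200)
        matrix, starts = spectrogram(GenomicSignal(id="s", values=values), 63, 9, 64)
        sig.save_spectrogram_tsv(matrix, starts, tmp_path / "m.tsv")
        sig.save_spectrogram_png(matrix, starts, tmp_path / "m.png")
        assert (tmp_path / "m.tsv").exists() and (tmp_path / "m.png").exists()
        import pandas as pd

        read_back = pd.read_csv(tmp_path / "m.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(read_back.to_numpy(), matrix)


class TestNextPowerOfTwo:
    @pytest.mark.parametrize("n, p", [(351, 512), (63, 64), (64, 64), (1, 1)])
    def test_values(self, n, p):
        assert next_power_of_two(n) == p


class TestFastaManifest:
    def test_round_trip(self, tiny_fixture):
        records = read_fasta_with_labels(tiny_fixture["fasta"], tiny_fixture["manifest"])
        assert len(records) == 16
        assert {r.label for r in records} == {"a", "b"}

    def test_missing_label_names_sequence(self, tmp_path):
        fasta = tmp_path / "f.fa"
        fasta.write_text(">seqX\nACGT\n")
        manifest = tmp_path / "m.tsv"
        manifest.write_text("sequence_id\tlabel\nother\ty\n")
        with pytest.raises(KeyError, match="seqX"):
            read_fasta_with_labels(fasta, manifest)

    def test_extra_manifest_rows_ignored(self, tmp_path, caplog):
        fasta = tmp_path / "f.fa"
        fasta.write_text(">s1\nACGT\n")
        manifest = tmp_path / "m.tsv"
        manifest.write_text("sequence_id\tlabel\ns1\tx\nghost\ty\n")
        records = read_fasta_with_labels(fasta, manifest)
        assert [r.id for r in records] == ["s1"]

    def test_empty_fasta_errors(self, tmp_path):
        fasta = tmp_path / "f.fa"
        fasta.write_text("")
        manifest = tmp_path / "m.tsv"
        manifest.write_text("sequence_id\tlabel\n")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta_with_labels(fasta, manifest)
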