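"""Sequence I/O, numeric DNA encoding, sliding-window framing and magnitude spectra.

DNA sequences are mapped to discrete +/-1 signals under the purine/pyrimidine
(PP) representation: purines (A, G) -> -1, pyrimidines (T, C) -> +1, with
unknown bases (N) removed.  A fixed-length window slides across the signal
and the magnitude of the discrete Fourier transform is taken per window,
keeping only the first half of the spectrum (0 to pi) since the input signal
is real.  The resulting D-dimensional spectra (D = fft_order / 2) are the
frame-level features consumed by the GMM stages, and stacked column-wise they
form a spectrogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledSequence",
    "GenomicSignal",
    "SpectralFrameSet",
    "read_fasta_with_labels",
    "encode_pp",
    "encode",
    "ENCODERS",
    "frame_windows",
    "magnitude_spectrum",
    "sequence_frame_set",
    "spectrogram",
    "next_power_of_two",
]


@dataclass(frozen=True)
class LabeledSequence:
    """A raw DNA sequence with its class label."""

    id: str
    dna: str
    label: str


@dataclass(frozen=True)
class GenomicSignal:
    """Numeric signal derived from a DNA string (N positions removed)."""

    id: str
    values: np.ndarray

    @property
    def length(self) -> int:
        return int(self.values.shape[0])


@dataclass
class SpectralFrameSet:
    """Ordered per-window magnitude spectra for one sequence.

    ``frames`` has shape (num_windows, D) with D = fft_order // 2;
    ``window_starts`` are 0-based offsets into the N-reduced signal.
    """

    id: str
    frames: np.ndarray
    window_starts: np.ndarray
    winlen: int
    winshift: int
    fft_order: int
    label: str | None = field(default=None)

    @property
    def dim(self) -> int:
        return self.fft_order // 2

    @property
    def num_windows(self) -> int:
        return int(self.frames.shape[0])


# ---------------------------------------------------------------------------
# I/O


def read_fasta_with_labels(fasta_path, manifest_path) -> list[LabeledSequence]:
    """Read a multi-record FASTA and join per-sequence labels from a TSV manifest.

    The manifest must have columns ``sequence_id`` and ``label``.  Every FASTA
    record id must appear in the manifest; manifest rows without a matching
    FASTA record are ignored with a warning.  Record order follows the FASTA.
    """
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    missing_cols = {"sequence_id", "label"} - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest missing column(s): {sorted(missing_cols)}")
    labels = dict(zip(manifest["sequence_id"], manifest["label"]))

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")

    out = []
    seen = set()
    for rec in records:
        if rec.id not in labels:
            raise KeyError(f"sequence {rec.id!r} has no label in the manifest")
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in FASTA")
        seen.add(rec.id)
        out.append(LabeledSequence(id=rec.id, dna=str(rec.seq), label=labels[rec.id]))

    extra = set(labels) - seen
    if extra:
        logger.warning(
            "%d manifest row(s) have no FASTA record and were ignored (e.g. %s)",
            len(extra), sorted(extra)[0],
        )
    return out


# ---------------------------------------------------------------------------
# Encoders

# PP: purines (A, G) -> -1, pyrimidines (T, C) -> +1.  N is dropped.
_PP_MAP = {"A": -1.0, "G": -1.0, "T": +1.0, "C": +1.0}

# Alternative single-value encodings kept behind the same interface; PP is the
# default and the only encoder used by the shipped presets.
_REAL_MAP = {"A": -1.5, "G": -0.5, "C": 0.5, "T": 1.5}
_INTEGER_MAP = {"T": 0.0, "C": 1.0, "A": 2.0, "G": 3.0}
_EIIP_MAP = {"A": 0.1260, "G": 0.0806, "C": 0.1340, "T": 0.1335}


def _encode_with_map(seq: LabeledSequence, mapping: dict[str, float]) -> GenomicSignal:
    vals = []
    for ch in seq.dna.upper():
        if ch == "N":
            continue
        try:
            vals.append(mapping[ch])
        except KeyError:
            raise ValueError(
                f"sequence {seq.id!r}: unsupported character {ch!r}"
            ) from None
    if not vals:
        raise ValueError(f"sequence {seq.id!r} is empty after N removal")
    return GenomicSignal(id=seq.id, values=np.asarray(vals, dtype=np.float64))


def encode_pp(seq: LabeledSequence) -> GenomicSignal:
    """Encode DNA under the purine/pyrimidine mapping: A,G -> -1; T,C -> +1.

    Lowercase input is accepted; N positions are removed so downstream window
    coordinates refer to the reduced signal.  Any other character is an error.
    """
    return _encode_with_map(seq, _PP_MAP)


ENCODERS = {
    "pp": lambda s: _encode_with_map(s, _PP_MAP),
    "real": lambda s: _encode_with_map(s, _REAL_MAP),
    "integer": lambda s: _encode_with_map(s, _INTEGER_MAP),
    "eiip": lambda s: _encode_with_map(s, _EIIP_MAP),
}


def encode(seq: LabeledSequence, encoder: str = "pp") -> GenomicSignal:
    """Encode with a named encoder (``pp`` default; ``real``/``integer``/``eiip``)."""
    try:
        fn = ENCODERS[encoder]
    except KeyError:
        raise ValueError(
            f"unknown encoder {encoder!r}; valid: {sorted(ENCODERS)}"
        ) from None
    return fn(seq)


# ---------------------------------------------------------------------------
# Framing and spectra


def frame_windows(signal: GenomicSignal, winlen: int, winshift: int):
    """Slice a signal into sliding windows.

    Returns ``(window_starts, frames)`` where frames is a list of 1-D arrays of
    exactly ``winlen`` samples each.  Window starts are 0, winshift, 2*winshift,
    ... while the full window fits.  A signal shorter than ``winlen`` yields a
    single frame holding the whole signal (zero-padding happens at FFT time).
    """
    if winlen < 2:
        raise ValueError(f"winlen must be >= 2, got {winlen}")
    if winshift < 1:
        raise ValueError(f"winshift must be >= 1, got {winshift}")
    x = signal.values
    L = x.shape[0]
    if L < winlen:
        return np.array([0], dtype=np.int64), [x.copy()]
    n = (L - winlen) // winshift + 1
    starts = np.arange(n, dtype=np.int64) * winshift
    frames = [x[s : s + winlen] for s in starts]
    return starts, frames


def next_power_of_two(n: int) -> int:
    """Smallest power of two >= n."""
    if n < 1:
        raise ValueError("n must be positive")
    return 1 << (int(n) - 1).bit_length()


def _check_fft_order(fft_order: int, frame_len: int) -> None:
    if fft_order < 1 or (fft_order & (fft_order - 1)) != 0:
        raise ValueError(f"fft_order must be a power of two, got {fft_order}")
    if fft_order < frame_len:
        raise ValueError(
            f"fft_order ({fft_order}) must be >= frame length ({frame_len})"
        )


def magnitude_spectrum(frame: np.ndarray, fft_order: int) -> np.ndarray:
    """Magnitude of DFT bins 0 .. fft_order/2 - 1 of a zero-padded frame.

    Only the first half of the spectrum (0 to pi) is kept, since the DFT of a
    real signal is conjugate-symmetric; the returned vector has D = fft_order/2
    non-negative entries (DC included, the bin at pi excluded).
    """
    frame = np.asarray(frame, dtype=np.float64)
    _check_fft_order(fft_order, frame.shape[0])
    spec = np.fft.rfft(frame, n=fft_order)
    return np.abs(spec[: fft_order // 2])


def sequence_frame_set(
    signal: GenomicSignal,
    winlen: int,
    winshift: int,
    fft_order: int,
    label: str | None = None,
) -> SpectralFrameSet:
    """Frame a signal and compute the magnitude spectrum of every window."""
    starts, frames = frame_windows(signal, winlen, winshift)
    spectra = np.stack([magnitude_spectrum(f, fft_order) for f in frames])
    return SpectralFrameSet(
        id=signal.id,
        frames=spectra,
        window_starts=starts,
        winlen=winlen,
        winshift=winshift,
        fft_order=fft_order,
        label=label,
    )


def spectrogram(signal: GenomicSignal, winlen: int, winshift: int, fft_order: int):
    """Spectrogram matrix: column j is the magnitude spectrum of window j.

    Returns ``(matrix, window_starts)`` with matrix shape (D, num_windows),
    D = fft_order // 2; rows are frequency bins 0..D-1 (0 to pi rad/sample).
    """
    fs = sequence_frame_set(signal, winlen, winshift, fft_order)
    return fs.frames.T.copy(), fs.window_starts


def save_spectrogram_tsv(matrix: np.ndarray, window_starts: np.ndarray, path) -> None:
    """Write a spectrogram as TSV: rows = frequency bins, columns = window starts."""
    df = pd.DataFrame(matrix, columns=[str(int(s)) for s in window_starts])
    df.index.name = "freq_bin"
    df.to_csv(path, sep="\t")


def save_spectrogram_png(
    matrix: np.ndarray, window_starts: np.ndarray, path, title: str | None = None
) -> None:
    """Render a spectrogram heatmap (frequency bin x window position) to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(matrix, aspect="auto", origin="lower", cmap="viridis")
    ax.set_xlabel("window index")
    ax.set_ylabel("frequency bin (0 to pi)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="|DFT|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
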