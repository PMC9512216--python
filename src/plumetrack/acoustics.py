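"""Long-term average spectrum (LTAS) computation and spectral comparison.

LTAS here is the Welch-style mean of Hanning-windowed 512-point power
spectra (hop 256), expressed in dB relative to the spectrum's own maximum
and floored at -110 dB, matching common speech-analysis tooling defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "LtasSpectrum",
    "compute_ltas",
    "average_spectra",
    "ltas_mse",
    "read_wav",
    "write_wav",
]


@dataclass
class LtasSpectrum:
    """Frequency-bin dB levels of a long-term average spectrum."""

    freqs_hz: np.ndarray  # nfft/2 + 1 bins at fs/nfft spacing
    levels_db: np.ndarray
    fs: float = 44100.0
    nfft: int = 512
    floor_db: float = -110.0

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        if self.freqs_hz.shape != self.levels_db.shape:
            raise ValueError("frequency and level arrays differ in length")
        if len(self.freqs_hz) != self.nfft // 2 + 1:
            raise ValueError(
                f"expected {self.nfft // 2 + 1} bins, got {len(self.freqs_hz)}"
            )
        if np.any(self.levels_db < self.floor_db - 1e-9):
            raise ValueError("levels below the dB floor")

    def same_grid(self, other: "LtasSpectrum") -> bool:
        return (
            self.fs == other.fs
            and self.nfft == other.nfft
            and np.allclose(self.freqs_hz, other.freqs_hz)
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"freq_hz": self.freqs_hz, "level_db": self.levels_db}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, fs: float = 44100.0, floor_db: float = -110.0):
        import pandas as pd

        df = pd.read_csv(path)
        nfft = 2 * (len(df) - 1)
        return cls(
            freqs_hz=df["freq_hz"].to_numpy(),
            levels_db=df["level_db"].to_numpy(),
            fs=fs,
            nfft=nfft,
            floor_db=floor_db,
        )


def compute_ltas(
    audio,
    fs: float = 44100.0,
    nfft: int = 512,
    hop: int = 256,
    floor_db: float = -110.0,
) -> LtasSpectrum:
    """Average Hanning-windowed power spectra of a mono recording.

    Per-frame power spectra are averaged in the power domain, peak-normalised
    and converted to dB, then clipped below at ``floor_db``.  Digital silence
    maps to a uniform floor.
    """
    x = np.asarray(audio, dtype=float)
    if x.ndim != 1:
        raise ValueError("audio must be mono (1-D)")
    if x.size < nfft:
        raise ValueError(f"audio shorter than one analysis frame ({nfft} samples)")
    if not 0 < hop <= nfft:
        raise ValueError("hop must lie in (0, nfft]")
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nfft,
        noverlap=nfft - hop,
        detrend=False,
        scaling="density",
        average="mean",
    )
    peak = psd.max()
    if peak <= 0:
        levels = np.full_like(psd, floor_db)
    else:
        with np.errstate(divide="ignore"):
            levels = 10.0 * np.log10(psd / peak)
        levels = np.maximum(levels, floor_db)
    return LtasSpectrum(
        freqs_hz=freqs, levels_db=levels, fs=fs, nfft=nfft, floor_db=floor_db
    )


def average_spectra(spectra) -> LtasSpectrum:
    """Per-bin arithmetic mean of dB levels across spectra on one grid."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise ValueError("spectra are on different fs/nfft grids")
    levels = np.mean([s.levels_db for s in spectra], axis=0)
    return LtasSpectrum(
        freqs_hz=first.freqs_hz.copy(),
        levels_db=levels,
        fs=first.fs,
        nfft=first.nfft,
        floor_db=min(s.floor_db for s in spectra),
    )


def ltas_mse(a: LtasSpectrum, b: LtasSpectrum) -> float:
    """Mean squared error between two spectra in dB^2."""
    if not a.same_grid(b):
        raise ValueError("spectra are on different fs/nfft grids")
    d = a.levels_db - b.levels_db
    return float(np.mean(d * d))


def read_wav(path, expected_fs: float | None = None) -> tuple[np.ndarray, float]:
    """Read a PCM WAV file as float samples in [-1, 1]; must be mono."""
    fs, data = wavfile.read(Path(path))
    if expected_fs is not None and fs != expected_fs:
        raise ValueError(f"sampling rate {fs} Hz does not match expected {expected_fs}")
    if data.ndim != 1:
        raise ValueError("expected a mono WAV file")
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(float) - 128.0) / 128.0
    else:
        x = data.astype(float)
    return x, float(fs)


def write_wav(path, audio, fs: float = 44100.0) -> None:
    """Write float samples in [-1, 1] as 16-bit PCM mono WAV."""
    x = np.clip(np.asarray(audio, dtype=float), -1.0, 1.0)
    wavfile.write(Path(path), int(fs), np.rint(x * 32767.0).astype(np.int16))
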