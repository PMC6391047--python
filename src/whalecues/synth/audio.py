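"""Parametric tonal-call audio with ground-truth annotations.

Calls are frequency-modulated sinusoids with a quadratic frequency contour
``f(t) = c0 + c1*t + c2*t**2`` (Hz), rendered by integrating the instantaneous
frequency, shaped with short cosine on/off ramps, and summed into white
Gaussian noise.  The generator returns both the waveform and a
:class:`SyntheticAudioTruth` listing every call's onset, offset, contour
coefficients and cluster label, so detector recall/precision can be measured
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "CallSpec",
    "SyntheticAudioTruth",
    "generate_audio",
    "write_wav",
    "read_wav",
    "write_annotations",
    "read_annotations",
]

#: half-cosine ramp applied to each call's ends, seconds
RAMP_S = 0.010


@dataclass(frozen=True)
class CallSpec:
    """One synthetic tonal call.

    Parameters
    ----------
    onset_s : float
        Call start, seconds from file start.
    duration_s : float
        Call length in seconds; must be positive.
    contour : tuple of float
        Polynomial coefficients ``(c0, c1, c2)`` of the frequency contour
        ``f(t) = c0 + c1*t + c2*t**2`` in Hz, with ``t`` in seconds measured
        from the call onset.
    amplitude : float
        Peak linear amplitude of the sinusoid.
    label : int
        Cluster identity of the call type (ground truth for clustering).
    """

    onset_s: float
    duration_s: float
    contour: tuple[float, float, float] = (1000.0, 0.0, 0.0)
    amplitude: float = 1.0
    label: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s

    def freq_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous frequency at time ``t`` (seconds from onset)."""
        c0, c1, c2 = self.contour
        return c0 + c1 * np.asarray(t) + c2 * np.asarray(t) ** 2

    def phase_at(self, t: np.ndarray) -> np.ndarray:
        """Integrated phase 2*pi*int_0^t f(u) du at times ``t`` from onset."""
        c0, c1, c2 = self.contour
        return 2.0 * np.pi * (c0 * t + c1 * t**2 / 2.0 + c2 * t**3 / 3.0)


@dataclass
class SyntheticAudioTruth:
    """Ground-truth annotation of a generated audio file."""

    calls: list[CallSpec]
    sample_rate: float
    total_s: float
    noise_sd: float = 0.0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "call_id": i,
                "onset_s": c.onset_s,
                "offset_s": c.offset_s,
                "c0": c.contour[0],
                "c1": c.contour[1],
                "c2": c.contour[2],
                "amplitude": c.amplitude,
                "label": c.label,
            }
            for i, c in enumerate(self.calls)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "call_id",
                "onset_s",
                "offset_s",
                "c0",
                "c1",
                "c2",
                "amplitude",
                "label",
            ],
        )


def _validate_specs(
    specs: list[CallSpec], sample_rate: float, total_s: float
) -> None:
    nyquist = sample_rate / 2.0
    for i, spec in enumerate(specs):
        if spec.offset_s > total_s + 1e-9:
            raise ValueError(
                f"call {i} ends at {spec.offset_s:.3f}s, beyond total_s={total_s}"
            )
        t = np.linspace(0.0, spec.duration_s, 101)
        f = spec.freq_at(t)
        if np.any(f <= 0):
            raise ValueError(f"call {i}: contour is non-positive within the call")
        if np.any(f >= nyquist):
            raise ValueError(
                f"call {i}: contour reaches {float(np.max(f)):.1f} Hz, at or above "
                f"the Nyquist frequency {nyquist:.1f} Hz"
            )


def generate_audio(
    specs: list[CallSpec],
    noise_sd: float = 0.0,
    sample_rate: float = 16_000.0,
    total_s: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, SyntheticAudioTruth]:
    """Render calls into white Gaussian noise.

    Returns ``(waveform, truth)`` where the waveform is ``float64`` of length
    ``round(total_s * sample_rate)``.  Rendering is deterministic for a fixed
    seed.  A call whose contour touches or exceeds Nyquist, or extends past
    ``total_s``, is rejected with a :class:`ValueError`.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    _validate_specs(specs, sample_rate, total_s)

    n = int(round(total_s * sample_rate))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    wave = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)

    for spec in specs:
        i0 = int(round(spec.onset_s * sample_rate))
        m = int(round(spec.duration_s * sample_rate))
        m = min(m, n - i0)
        t = np.arange(m) / sample_rate
        tone = spec.amplitude * np.sin(spec.phase_at(t))
        ramp_n = min(int(round(RAMP_S * sample_rate)), m // 2)
        if ramp_n > 0:
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
            env = np.ones(m)
            env[:ramp_n] = ramp
            env[m - ramp_n :] = ramp[::-1]
            tone *= env
        wave[i0 : i0 + m] += tone

    truth = SyntheticAudioTruth(
        calls=list(specs),
        sample_rate=sample_rate,
        total_s=total_s,
        noise_sd=noise_sd,
        seed=seed if isinstance(seed, int) else None,
    )
    return wave, truth


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: float, bits: int = 16) -> None:
    """Write a mono WAV file (16-bit PCM or 32-bit float)."""
    path = Path(path)
    if bits == 16:
        peak = float(np.max(np.abs(waveform))) or 1.0
        scaled = np.clip(waveform / max(peak, 1.0), -1.0, 1.0)
        wavfile.write(path, int(sample_rate), (scaled * 32767).astype(np.int16))
    elif bits == 32:
        wavfile.write(path, int(sample_rate), waveform.astype(np.float32))
    else:
        raise ValueError("bits must be 16 or 32")


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono WAV file; returns (float64 waveform, sample_rate)."""
    rate, data = wavfile.read(Path(path))
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return np.asarray(data, dtype=np.float64), float(rate)


def write_annotations(path: str | Path, truth: SyntheticAudioTruth) -> None:
    """Write truth annotations as CSV plus a JSON sidecar with generator config."""
    path = Path(path)
    truth.to_frame().to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "sample_rate": truth.sample_rate,
                "total_s": truth.total_s,
                "noise_sd": truth.noise_sd,
                "seed": truth.seed,
                "n_calls": len(truth.calls),
            },
            indent=2,
        )
    )


def read_annotations(path: str | Path) -> SyntheticAudioTruth:
    """Round-trip reader for :func:`write_annotations`."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    calls = [
        CallSpec(
            onset_s=row.onset_s,
            duration_s=row.offset_s - row.onset_s,
            contour=(row.c0, row.c1, row.c2),
            amplitude=row.amplitude,
            label=int(row.label),
        )
        for row in df.itertuples()
    ]
    seed = meta.get("seed")
    return SyntheticAudioTruth(
        calls=calls,
        sample_rate=meta["sample_rate"],
        total_s=meta["total_s"],
        noise_sd=meta["noise_sd"],
        seed=int(seed) if seed is not None else None,
    )
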