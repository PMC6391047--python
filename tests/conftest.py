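"""Shared fixtures: ground-truthed synthetic audio and trial tables."""

from __future__ import annotations

import numpy as np
import pytest

from whalecues.detection import DetectorConfig, Track
from whalecues.synth.audio import CallSpec, generate_audio

SAMPLE_RATE = 16_000.0

#: detector settings matched to the 16 kHz test fixtures
FIXTURE_DETECTOR = DetectorConfig(window=1024, hop=256)


def overlap_s(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def snr_to_noise_sd(snr_db: float, amplitude: float = 1.0) -> float:
    """White-noise SD giving the requested broadband SNR for a unit sinusoid."""
    return amplitude / (10.0 ** (snr_db / 20.0)) / np.sqrt(2.0)


def twenty_call_specs() -> tuple[list[CallSpec], float]:
    """20 chirps with distinct onsets; returns (specs, total_s)."""
    rng = np.random.default_rng(0)
    specs, t = [], 1.0
    for i in range(20):
        dur = float(rng.uniform(0.4, 1.0))
        specs.append(
            CallSpec(t, dur, (1000.0 + (200.0 * i) % 3000.0, 500.0, -300.0), 1.0, 0)
        )
        t += dur + 1.5
    return specs, t + 1.0


@pytest.fixture(scope="session")
def call_fixture():
    """20 synthetic chirps at 10 dB SNR with their ground truth."""
    specs, total_s = twenty_call_specs()
    wave, truth = generate_audio(
        specs, noise_sd=snr_to_noise_sd(10.0), sample_rate=SAMPLE_RATE,
        total_s=total_s, seed=1,
    )
    return wave, truth


def make_track(times: np.ndarray, contour_hz: np.ndarray) -> Track:
    hop = float(np.mean(np.diff(times)))
    return Track(
        pixels=[], times=np.asarray(times), contour_hz=np.asarray(contour_hz),
        onset_s=float(times[0] - hop / 2), offset_s=float(times[-1] + hop / 2),
    )
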