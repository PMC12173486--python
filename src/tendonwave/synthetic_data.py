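"""Synthetic inputs: gait force profiles and plane-wave validation maps.

Everything the analysis consumes can be generated here without downloads.
Synthetic spatiotemporal maps carry their ground-truth wave speed so no
test ever compares against an unlabelled constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tendonwave.loading import GaitProfile
from tendonwave.maps import SpatioTemporalMap

__all__ = ["SynthMapSpec", "synth_gait_profile", "synth_plane_wave_map"]


def synth_gait_profile(
    n: int = 100,
    peak_force: float = 3300.0,
    peak_location: float = 0.45,
    seed: int | None = None,
) -> GaitProfile:
    """Smooth single-peaked stance/push-off style total-force curve.

    A raised-cosine window warped so its maximum falls at ``peak_location``
    of the cycle (default 0.45, i.e. late stance).  Forces are zero at the
    cycle endpoints and non-negative throughout.  The curve is fully
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    if n < 2:
        raise ValueError("need at least 2 increments")
    if not (0.0 < peak_location < 1.0):
        raise ValueError("peak_location must lie in (0, 1)")
    x = np.linspace(0.0, 1.0, n)
    warped = np.where(
        x <= peak_location,
        0.5 * x / peak_location,
        0.5 + 0.5 * (x - peak_location) / (1.0 - peak_location),
    )
    forces = peak_force * 0.5 * (1.0 - np.cos(2.0 * np.pi * warped))
    return GaitProfile(forces=forces)


@dataclass(frozen=True)
class SynthMapSpec:
    """Specification of a synthetic plane-wave spatiotemporal map.

    ``snr_db`` is the ratio of signal RMS to noise RMS in decibels
    (``20*log10(rms_signal/rms_noise)``); ``None`` disables noise.
    ``reflection`` in [0, 1] scales a backward wave reflected off the far
    (proximal) end of the domain.
    """

    true_speed: float  # m/s
    dx: float = 1.0e-3  # m
    dt: float = 1.0e-5  # s
    n_positions: int = 64
    n_times: int = 100
    reflection: float = 0.0
    snr_db: float | None = None
    pulse_width: float = 250.0e-6  # s (half-sine half period)
    amplitude: float = 20.0e-6  # m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_speed <= 0:
            raise ValueError("true_speed must be positive")
        if not (0.0 <= self.reflection <= 1.0):
            raise ValueError("reflection must lie in [0, 1]")
        if self.dx <= 0 or self.dt <= 0 or self.pulse_width <= 0:
            raise ValueError("dx, dt and pulse_width must be positive")


def _half_sine_pulse(t: np.ndarray, width: float, amplitude: float) -> np.ndarray:
    inside = (t >= 0.0) & (t <= width)
    return np.where(inside, amplitude * np.sin(np.pi * np.clip(t, 0.0, width) / width), 0.0)


def synth_plane_wave_map(spec: SynthMapSpec) -> tuple[SpatioTemporalMap, dict]:
    """Non-dispersive plane-wave map with known ground truth.

    Forward wave ``u(x, t) = pulse(t - x/c)``; an optional backward wave
    reflected at the far end ``x = X`` enters as
    ``reflection * pulse(t - (2X - x)/c)``.  Seeded Gaussian noise is added
    at the requested SNR.  Returns ``(map, truth)`` where ``truth`` records
    the speed, reflection and realized noise level.
    """
    x = np.arange(spec.n_positions) * spec.dx
    t = np.arange(spec.n_times) * spec.dt
    tt = t[None, :]
    xx = x[:, None]
    c = spec.true_speed
    u = _half_sine_pulse(tt - xx / c, spec.pulse_width, spec.amplitude)
    if spec.reflection > 0.0:
        far = x[-1]
        u = u + spec.reflection * _half_sine_pulse(
            tt - (2.0 * far - xx) / c, spec.pulse_width, spec.amplitude
        )
    noise_rms = 0.0
    if spec.snr_db is not None:
        rng = np.random.default_rng(spec.seed)
        signal_rms = float(np.sqrt(np.mean(u**2)))
        noise_rms = signal_rms / (10.0 ** (spec.snr_db / 20.0))
        u = u + rng.normal(0.0, noise_rms, size=u.shape)
    truth = {
        "speed": c,
        "reflection": spec.reflection,
        "noise_rms": noise_rms,
        "snr_db": spec.snr_db,
    }
    smap = SpatioTemporalMap(
        u=u,
        dx=spec.dx,
        dt=spec.dt,
        meta={"synthetic": True, "true_speed": c, "seed": spec.seed},
    )
    return smap, truth
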