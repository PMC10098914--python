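"""Synthetic PPG + respiration generator with controllable respiratory modulations.

The generator emulates the three mechanisms by which breathing imprints
itself on a photoplethysmogram:

* RIIV -- additive baseline modulation at the respiratory frequency
  (venous-return / intra-thoracic-pressure effect),
* RIAV -- multiplicative modulation of pulse amplitude (stroke-volume
  effect),
* RIFV -- modulation of the instantaneous heart rate (respiratory sinus
  arrhythmia): f_h(t) = f_heart * (1 + a_rifv * sin(2 pi f_resp t)).

Beats are placed where the accumulated cardiac phase crosses integers; each
beat contributes an asymmetric two-lobe template (a sharp systolic Gaussian
followed by a broader, lower diastolic one).  White Gaussian noise is added
at a configurable SNR defined against the pulse train's RMS.  A matched
respiratory reference channel (a sinusoid at the respiratory frequency,
sampled at the physiological rate) accompanies every record, and a corrupted
variant with breath-interval jitter and trough-depth noise is available for
exercising the quality-control screen.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .signals import TimeSeries


def _truncnorm_scale_for_std(mean: float, floor: float, target_std: float) -> float:
    """Pre-truncation scale giving a left-truncated normal the target std."""
    lo, hi = target_std, 10.0 * target_std
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        sd = truncnorm.std((floor - mean) / mid, np.inf, loc=mean, scale=mid)
        if sd < target_std:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)

__all__ = ["SynthConfig", "SynthRecord", "generate_ppg", "generate_corrupted_respiration"]


@dataclass(frozen=True)
class SynthConfig:
    """Simulation conditions.

    Defaults mirror a typical camera-based acquisition: 25 Hz PPG (25 fps
    video), 1000 Hz respiratory reference, 72 beats/min heart rate,
    15 breaths/min respiration, all three modulations enabled at moderate
    physiological depths, and 10 dB additive noise.
    """

    duration: float = 60.0        # s
    fs_ppg: float = 25.0          # Hz
    fs_resp: float = 1000.0       # Hz
    f_resp: float = 0.25          # Hz (true RR = 15 breaths/min)
    f_heart: float = 1.2          # Hz (72 beats/min)
    a_riiv: float = 0.3           # baseline modulation depth (amplitude units)
    a_riav: float = 0.3           # fractional pulse-amplitude depth
    a_rifv: float = 0.05          # fractional heart-frequency depth (RSA)
    snr_db: float = 10.0          # inf -> noise-free
    phi_a: float = 0.0            # RIAV phase offset, rad
    phi_i: float = 0.0            # RIIV phase offset, rad
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f_resp < self.f_heart / 2):
            raise ValueError("need 0 < f_resp < f_heart / 2")
        for d in (self.a_riiv, self.a_riav, self.a_rifv):
            if not (0 <= d < 1):
                raise ValueError("modulation depths must lie in [0, 1)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class SynthRecord:
    ppg: TimeSeries
    respiration: TimeSeries
    true_rr: float        # breaths/min
    true_hr: float        # beats/min
    beat_times: np.ndarray


# Two-lobe beat template: sharp systolic peak + broad diastolic shoulder.
_SYS_WIDTH = 0.08   # s
_DIA_WIDTH = 0.25   # s
_DIA_HEIGHT = 0.4   # relative to systolic
_DIA_DELAY = 0.25   # s after the systolic peak


def _beat_template(dt: np.ndarray) -> np.ndarray:
    """Template value at offsets ``dt`` (s) from the systolic peak."""
    return (np.exp(-0.5 * (dt / _SYS_WIDTH) ** 2)
            + _DIA_HEIGHT * np.exp(-0.5 * ((dt - _DIA_DELAY) / _DIA_WIDTH) ** 2))


def _beat_times(cfg: SynthConfig) -> np.ndarray:
    """Beat instants: integer crossings of the accumulated cardiac phase.

    The instantaneous heart frequency is integrated analytically:
    Phi(t) = f_heart * (t - a_rifv/(2 pi f_resp) * (cos(2 pi f_resp t) - 1)).
    """
    def phase(t: np.ndarray) -> np.ndarray:
        return cfg.f_heart * (
            t - cfg.a_rifv / (2 * np.pi * cfg.f_resp)
            * (np.cos(2 * np.pi * cfg.f_resp * t) - 1.0)
        )

    # dense grid + linear inversion of the monotone phase
    tg = np.linspace(0.0, cfg.duration, int(cfg.duration * 1000) + 1)
    ph = phase(tg)
    n_beats = int(np.floor(ph[-1]))
    return np.interp(np.arange(1, n_beats + 1, dtype=float), ph, tg)


def generate_ppg(cfg: SynthConfig) -> SynthRecord:
    """Generate one PPG record plus its matched respiratory reference."""
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.duration, 1.0 / cfg.fs_ppg)
    beats = _beat_times(cfg)

    pulse = np.zeros_like(t)
    half_support = _DIA_DELAY + 4 * _DIA_WIDTH
    for tb in beats:
        amp = 1.0 + cfg.a_riav * np.sin(2 * np.pi * cfg.f_resp * tb + cfg.phi_a)
        lo = np.searchsorted(t, tb - half_support)
        hi = np.searchsorted(t, tb + half_support)
        pulse[lo:hi] += amp * _beat_template(t[lo:hi] - tb)

    baseline = cfg.a_riiv * np.sin(2 * np.pi * cfg.f_resp * t + cfg.phi_i)
    clean = pulse + baseline
    if np.isfinite(cfg.snr_db):
        prms = np.sqrt(np.mean(pulse**2))
        noise_rms = prms / 10 ** (cfg.snr_db / 20.0)
        clean = clean + rng.normal(0.0, noise_rms, size=t.size)

    t_resp = np.arange(0.0, cfg.duration, 1.0 / cfg.fs_resp)
    resp = np.sin(2 * np.pi * cfg.f_resp * t_resp)

    return SynthRecord(
        ppg=TimeSeries(clean, cfg.fs_ppg, label=f"synth_ppg_seed{cfg.seed}"),
        respiration=TimeSeries(resp, cfg.fs_resp, label=f"synth_resp_seed{cfg.seed}"),
        true_rr=60.0 * cfg.f_resp,
        true_hr=60.0 * cfg.f_heart,
        beat_times=beats,
    )


def generate_corrupted_respiration(
    cfg: SynthConfig,
    jitter_s: float = 0.0,
    trough_noise: float = 0.0,
) -> TimeSeries:
    """Respiratory waveform with irregular breath intervals and trough depths.

    Breath-cycle lengths have mean ``1/f_resp`` and standard deviation
    ``jitter_s`` exactly: they are drawn from a normal law left-truncated at
    the shortest cycle the screening band can resolve, with the
    pre-truncation scale solved so that truncation does not clip the
    requested dispersion away.  Cycles run from peak to peak, making the
    drawn intervals the peak-to-peak intervals the quality screen measures.

    Trough depths are perturbed with standard deviation ``trough_noise`` on
    the normalized [-1, 1] scale, encoded as per-cycle amplitude of a
    zero-mean cosine cycle: a zero-mean construction keeps the perturbation
    in the band-pass filter's passband (a perturbation of the cycle mean
    would be removed as baseline wander before the troughs are measured).
    The deepest trough sits at -1 and the tallest peak at +1, so the
    screen's re-normalization is close to the identity.

    With both knobs at zero the output is a regular breathing waveform that
    passes quality control.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    period = 1.0 / cfg.f_resp
    n_cycles = int(np.ceil(cfg.duration / period)) + 3
    if jitter_s > 0:
        # truncated normal with support above the shortest band-resolvable
        # cycle; the pre-truncation scale is solved so the drawn intervals
        # have standard deviation jitter_s exactly
        floor = max(0.1 * period, min(2.1, 0.9 * period))
        scale = _truncnorm_scale_for_std(period, floor, jitter_s)
        dist = truncnorm((floor - period) / scale, np.inf, loc=period, scale=scale)
        lengths = dist.rvs(size=n_cycles, random_state=rng)
    else:
        lengths = np.full(n_cycles, period)
    if trough_noise > 0:
        d = rng.normal(0.0, trough_noise, n_cycles)
        amp = np.maximum(1.0 + d - d.max(), 0.05)  # tallest cycle has amplitude 1
    else:
        amp = np.ones(n_cycles)

    starts = np.concatenate([[0.0], np.cumsum(lengths)])
    t = np.arange(0.0, cfg.duration, 1.0 / cfg.fs_resp)
    cyc = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_cycles - 1)
    phase = (t - starts[cyc]) / lengths[cyc]
    # peak (height amp) at each cycle start, trough (-amp) mid-cycle
    out = amp[cyc] * np.cos(2 * np.pi * phase)
    return TimeSeries(out, cfg.fs_resp, label=f"corrupted_resp_seed{cfg.seed}")
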