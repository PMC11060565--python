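"""Fourier-signature fitting target and waveform error metrics.

A single beat is summarized by the constant and first six harmonic pairs of
its sine-cosine Fourier series

    P(t) ~ a0/2 + sum_{n=1..6} a_n cos(2 pi n t/T) + b_n sin(2 pi n t/T)

packed as the 13-vector ``c = (a0, a1..a6, b1..b6)``.  The calibration
objective is the plain sum of squared differences between the simulated and
measured signatures; MAPE quantifies the final fit pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .simulation import PressureWaveform


@dataclass(frozen=True)
class FourierSignature:
    """Ordered coefficient vector (a0, a1..aN, b1..bN) of one beat."""

    c: np.ndarray
    T: float

    def __post_init__(self) -> None:
        c = np.asarray(self.c, float)
        object.__setattr__(self, "c", c)
        if c.ndim != 1 or c.size % 2 == 0:
            raise ValueError("signature must be (a0, a1..aN, b1..bN): odd length")
        if not np.all(np.isfinite(c)):
            raise ValueError("signature entries must be finite")

    @property
    def n_harmonics(self) -> int:
        return (self.c.size - 1) // 2

    def to_json(self) -> str:
        import json
        return json.dumps({"c": self.c.tolist(), "T": self.T})

    @classmethod
    def from_json(cls, s: str) -> "FourierSignature":
        import json
        d = json.loads(s)
        return cls(c=np.asarray(d["c"], float), T=float(d["T"]))

    def reconstruct(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the truncated series at times t."""
        n = self.n_harmonics
        w = 2.0 * np.pi / self.T
        out = np.full_like(np.asarray(t, float), 0.5 * self.c[0])
        for k in range(1, n + 1):
            out += self.c[k] * np.cos(k * w * t) + self.c[n + k] * np.sin(k * w * t)
        return out


def _resample_uniform(w: PressureWaveform, n: int) -> np.ndarray:
    """Monotone-cubic resampling of one beat onto n uniform points in [0, T)."""
    t = np.concatenate([w.t, [w.t[0] + w.T]])  # periodic closure
    p = np.concatenate([w.p, [w.p[0]]])
    interp = PchipInterpolator(t, p)
    tk = w.t[0] + np.arange(n) * (w.T / n)
    return np.asarray(interp(tk), float)


def fourier_signature(w: PressureWaveform, n_harmonics: int = 6,
                      n_resample: int = 128) -> FourierSignature:
    """Project one beat onto its first ``n_harmonics`` Fourier coefficients.

    Uniformly sampled beats are projected directly (the quadrature sums are
    then exact for band-limited signals); otherwise the beat is first
    resampled to ``n_resample`` uniform points by monotone cubic
    interpolation.  With the periodic closure P(T) = P(0), the trapezoid
    quadrature of the projection integrals reduces to the plain sums below.
    """
    if w.n < 2 * n_harmonics + 1:
        raise ValueError(
            f"need >= {2 * n_harmonics + 1} samples for {n_harmonics} harmonics")
    if w.is_uniform() and w.n >= 2 * n_harmonics + 2:
        p = w.p
    else:
        p = _resample_uniform(w, n_resample)
    N = p.size
    k = np.arange(N)
    c = np.empty(2 * n_harmonics + 1)
    c[0] = 2.0 * np.mean(p)
    for n in range(1, n_harmonics + 1):
        ang = 2.0 * np.pi * n * k / N
        c[n] = 2.0 * np.mean(p * np.cos(ang))
        c[n_harmonics + n] = 2.0 * np.mean(p * np.sin(ang))
    return FourierSignature(c=c, T=w.T)


def align_smooth(w: PressureWaveform, n_harmonics: int = 6,
                 n_resample: int = 128) -> PressureWaveform:
    """Foot-align a beat using its band-limited reconstruction.

    The diastolic minimum of a raw beat is flat, so measurement noise moves
    the literal ``argmin`` by many samples and rotates the beat's phase —
    which the harmonic signature is very sensitive to.  Locating the foot on
    the truncated Fourier reconstruction instead is robust: the smooth beat
    has a well-defined minimum.  Both the fitting target and the simulated
    beats go through this alignment before signature extraction.
    """
    from dataclasses import replace
    if not w.is_uniform():
        p = _resample_uniform(w, n_resample)
        t = w.t[0] + np.arange(n_resample) * (w.T / n_resample)
        w = PressureWaveform(t=t - t[0], p=p, T=w.T, sbp=w.sbp, dbp=w.dbp)
    sig = fourier_signature(w, n_harmonics)
    recon = sig.reconstruct(w.t)
    i = int(np.argmin(recon))
    return replace(w, p=np.roll(w.p, -i))


def signature_error(c_sim: FourierSignature, c_meas: FourierSignature) -> float:
    """Sum of squared coefficient differences over the 13 entries."""
    if c_sim.c.size != c_meas.c.size:
        raise ValueError("signatures have different harmonic counts")
    return float(np.sum((c_sim.c - c_meas.c) ** 2))


def mape(sim: PressureWaveform, meas: PressureWaveform) -> float:
    """Mean absolute percentage error of sim vs meas at the measured samples.

    The simulated beat is interpolated (periodically, monotone cubic) onto the
    measured time points; the result is in percent.
    """
    if np.any(np.abs(meas.p) < 1e-12):
        raise ValueError("measured pressure contains zeros")
    ts = np.concatenate([sim.t, [sim.t[0] + sim.T]])
    ps = np.concatenate([sim.p, [sim.p[0]]])
    interp = PchipInterpolator(ts, ps)
    tq = np.mod(meas.t - sim.t[0], sim.T) + sim.t[0]
    s = np.asarray(interp(tq), float)
    return float(np.mean(np.abs(s - meas.p) / np.abs(meas.p)) * 100.0)
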