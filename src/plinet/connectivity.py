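"""Phase lag index (PLI) connectivity.

The PLI between two channels is the absolute value of the time-averaged
sign of their wrapped instantaneous phase difference,

    PLI = | < sign(dphi) > |,        dphi in (-pi, pi],

with sign(0) = 0.  It is 0 when the phase-difference distribution is
symmetric around zero (including the zero-lag case, which is why the
statistic suppresses volume-conduction artefacts) and 1 when one channel
consistently leads the other.  Instantaneous phases come from the
analytic signal (Hilbert transform) of the band-filtered epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import BandSpec, EpochedBandData

#: Minimum number of phase samples required for a PLI estimate.
MIN_SAMPLES = 100


@dataclass
class PhaseSeries:
    """Instantaneous phases, epochs x channels x samples, radians in (-pi, pi]."""

    phases: np.ndarray
    band: BandSpec
    fs: float
    labels: tuple[str, ...]
    subject_id: str = ""


@dataclass
class ConnectivityMatrix:
    """Symmetric epoch-averaged PLI matrix with zero diagonal."""

    pli: np.ndarray
    band: str
    labels: tuple[str, ...]
    n_epochs_averaged: int = 1
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.pli = np.asarray(self.pli, dtype=float)
        n = len(self.labels)
        if self.pli.shape != (n, n):
            raise ValueError("PLI matrix shape does not match labels")


def instantaneous_phase(epoched: EpochedBandData, trim_s: float = 0.5) -> PhaseSeries:
    """Analytic-signal phase of each channel in each epoch.

    The analytic signal is computed per epoch in the frequency domain;
    *trim_s* seconds are discarded at each epoch edge to remove the
    Hilbert/filter edge transients before any phase statistics.
    """
    data = epoched.data
    ntrim = int(round(trim_s * epoched.fs))
    if data.shape[-1] - 2 * ntrim < 2:
        raise ValueError("epochs too short for the requested edge trim")
    flat = np.std(data, axis=-1) == 0
    if np.any(flat):
        ep, ch = np.argwhere(flat)[0]
        raise ValueError(
            f"zero-variance channel {epoched.labels[ch]!r} in epoch {ep}: "
            "phase is undefined"
        )
    analytic = hilbert(data, axis=-1)
    phases = np.angle(analytic)
    if ntrim:
        phases = phases[..., ntrim:-ntrim]
    return PhaseSeries(
        phases=phases,
        band=epoched.band,
        fs=epoched.fs,
        labels=epoched.labels,
        subject_id=epoched.subject_id,
    )


def wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Map phase differences to the principal interval (-pi, pi]."""
    out = np.mod(dphi + np.pi, 2 * np.pi) - np.pi
    # mod maps to [-pi, pi); fold the -pi edge to +pi for the half-open interval
    return np.where(out == -np.pi, np.pi, out)


def pli_pairwise(phases: np.ndarray) -> np.ndarray:
    """PLI matrix of a single channels x samples phase array."""
    phases = np.asarray(phases, dtype=float)
    n_ch, n_samp = phases.shape
    if n_ch < 2:
        raise ValueError("PLI needs at least 2 channels")
    if n_samp < MIN_SAMPLES:
        raise ValueError(f"PLI needs >= {MIN_SAMPLES} phase samples, got {n_samp}")
    out = np.zeros((n_ch, n_ch))
    for i in range(n_ch - 1):
        dphi = wrap_phase(phases[i, None, :] - phases[i + 1:, :])
        out[i, i + 1:] = np.abs(np.mean(np.sign(dphi), axis=-1))
    return out + out.T


def pli_matrix(ps: PhaseSeries) -> list[ConnectivityMatrix]:
    """One PLI matrix per epoch of *ps*."""
    return [
        ConnectivityMatrix(
            pli=pli_pairwise(epoch),
            band=ps.band.name,
            labels=ps.labels,
            n_epochs_averaged=1,
            subject_id=ps.subject_id,
        )
        for epoch in ps.phases
    ]


def average_over_epochs(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of per-epoch PLI matrices."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.labels != first.labels:
            raise ValueError("label mismatch between epoch matrices")
        if m.band != first.band:
            raise ValueError("band mismatch between epoch matrices")
    stacked = np.stack([m.pli for m in matrices])
    return ConnectivityMatrix(
        pli=stacked.mean(axis=0),
        band=first.band,
        labels=first.labels,
        n_epochs_averaged=int(sum(m.n_epochs_averaged for m in matrices)),
        subject_id=first.subject_id,
    )


def band_pli(epoched: EpochedBandData, trim_s: float = 0.5) -> ConnectivityMatrix:
    """Epoch-averaged PLI matrix of one band: phase -> per-epoch PLI -> mean."""
    ps = instantaneous_phase(epoched, trim_s=trim_s)
    return average_over_epochs(pli_matrix(ps))
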