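"""Synthetic local field potentials and spectral analysis.

Each spike is assumed to generate an exponentially decaying postsynaptic
potential.  Binned spike counts of every excitatory neuron are convolved
with a causal kernel ``exp(-t / tau)`` (tau = 24 ms, a typical mEPSP
time-scale for frontal-cortex pyramidal cells) and averaged across the
population:

    sLFP(t) = (1/N) * sum_n [S_n * exp(-t/tau)](t)

The default bin width of 8 ms gives a 125 Hz sampling rate, which supports
Welch spectra with 1 Hz resolution and coherence against down-sampled real
field recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import SpikeTrainSet, bin_population


@dataclass
class FieldSignal:
    """Sampled field-potential-like time series (arbitrary units)."""

    samples: np.ndarray
    fs: float
    kind: str = "sLFP"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class SpectralResult:
    freqs: np.ndarray
    psd: np.ndarray | None = None
    coherence: np.ndarray | None = None
    alpha: float | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.psd is not None:
            self.psd = np.asarray(self.psd, dtype=float)
            if np.any(self.psd < 0):
                raise ValueError("negative power")
        if self.coherence is not None:
            self.coherence = np.asarray(self.coherence, dtype=float)

    def band_fraction(self, f_lo: float, f_hi: float) -> float:
        """Fraction of total power in [f_lo, f_hi] (DC excluded)."""
        keep = self.freqs > 0
        band = keep & (self.freqs >= f_lo) & (self.freqs <= f_hi)
        total = self.psd[keep].sum()
        return float(self.psd[band].sum() / total) if total > 0 else 0.0


def exponential_kernel(bin_width: float, tau: float = 0.024) -> np.ndarray:
    """Causal decaying-exponential kernel, unit peak, truncated at 10 tau."""
    n = max(int(np.ceil(10 * tau / bin_width)), 1)
    t = bin_width * np.arange(n)
    return np.exp(-t / tau)


def build_slfp(
    spikes: SpikeTrainSet,
    bin_width: float = 0.008,
    tau: float = 0.024,
    excitatory_only: bool = True,
    window: tuple | None = None,
) -> FieldSignal:
    """Construct the synthetic LFP from (excitatory) spike trains."""
    if excitatory_only:
        ids = [n for n in spikes.neuron_ids if spikes.excitatory.get(n, True)]
        if not ids:
            raise ValueError("no excitatory neurons: sLFP undefined")
        spikes = spikes.subset(ids)
    traj = bin_population(spikes, bin_width=bin_width, window=window)
    kernel = exponential_kernel(bin_width, tau)
    T = traj.n_bins
    out = np.zeros(T)
    for k in range(traj.n_neurons):
        out += np.convolve(traj.counts[:, k].astype(float), kernel)[:T]
    out /= traj.n_neurons
    return FieldSignal(samples=out, fs=1.0 / bin_width, kind="sLFP")


def welch_psd(
    sig: FieldSignal,
    seg_len: float = 1.0,
    window: str = "hann",
    overlap: float = 0.0,
) -> SpectralResult:
    """Averaged periodogram over non-overlapping Hann segments.

    With 1 s segments the frequency resolution is 1 Hz.
    """
    nperseg = int(round(seg_len * sig.fs))
    if sig.samples.size < 2 * nperseg:
        raise ValueError("signal shorter than two Welch segments")
    f, p = sps.welch(
        sig.samples, fs=sig.fs, window=window,
        nperseg=nperseg, noverlap=int(round(overlap * nperseg)),
    )
    return SpectralResult(freqs=f, psd=p)


def msc_coherence(a: FieldSignal, b: FieldSignal, seg_len: float = 1.0) -> SpectralResult:
    """Magnitude-squared coherence with the same segmentation as the PSD."""
    if a.fs != b.fs:
        raise ValueError("sampling rates differ")
    if a.samples.size != b.samples.size:
        raise ValueError("signal lengths differ")
    nperseg = int(round(seg_len * a.fs))
    if a.samples.size < 2 * nperseg:
        raise ValueError("signals shorter than two segments")
    f, c = sps.coherence(a.samples, b.samples, fs=a.fs, window="hann",
                         nperseg=nperseg, noverlap=0)
    return SpectralResult(freqs=f, coherence=np.clip(c, 0.0, 1.0))


def spectral_slope(spec: SpectralResult, f_range: tuple) -> float:
    """Power-law decay exponent alpha of the spectrum: psd ~ f^-alpha.

    Ordinary least squares of log10(psd) on log10(f) over ``f_range``;
    returns the negated slope.
    """
    lo, hi = f_range
    keep = (spec.freqs >= lo) & (spec.freqs <= hi) & (spec.freqs > 0)
    if np.count_nonzero(keep) < 5:
        raise ValueError("need at least 5 frequency points in range")
    p = spec.psd[keep]
    if np.any(p <= 0):
        raise ValueError("nonpositive power in fit range")
    slope = np.polyfit(np.log10(spec.freqs[keep]), np.log10(p), 1)[0]
    return float(-slope)


def resample_average(
    channels: np.ndarray,
    fs: float,
    fs_target: float = 125.0,
) -> FieldSignal:
    """Average field-potential channels and resample to ``fs_target``.

    Generic handling for real multi-channel recordings; channels is
    (n_channels, n_samples) or 1-d.
    """
    x = np.atleast_2d(np.asarray(channels, dtype=float)).mean(axis=0)
    if fs != fs_target:
        from fractions import Fraction

        frac = Fraction(fs_target / fs).limit_denominator(10000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
    return FieldSignal(samples=x, fs=fs_target, kind="LFP")
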