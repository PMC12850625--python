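"""Synthetic signal models for multi-channel X-nuclear MRSI.

This module houses the domain types (spectral models, FIDs, multi-channel
voxel data, sensitivity vectors/maps, noise covariance, CSI datasets) and the
synthesis operations used throughout the package: Lorentzian spectra, the
spectrum <-> FID Fourier pair, quadrature-phase "true" coil sensitivities,
complex-Gaussian channel noise, cross-nucleus sensitivity surrogates, and
low-resolution CSI phantoms with Hamming-weighted, truncated k-space.

Conventions
-----------
* A spectrum of length ``n`` is stored with its frequency axis ascending,
  i.e. index ``n // 2`` carries frequency 0 (the carrier).  The chemical-shift
  (ppm) axis is stored explicitly; no left/right display convention is assumed.
* ``spectrum_to_fid`` is ``ifft(ifftshift(spectrum))`` and ``fid_to_spectrum``
  is ``fftshift(fft(fid))``; the two are exact inverses.
* Complex Gaussian noise of level ``sigma`` means independent real and
  imaginary components each of standard deviation ``sigma``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NUCLEUS_FREQ_7T_MHZ",
    "Provenance",
    "Resonance",
    "SpectralModel",
    "FidSignal",
    "MultiChannelFid",
    "SensitivityVector",
    "SensitivityMap",
    "NoiseCovariance",
    "CsiDataset",
    "default_model_31p",
    "default_model_23na",
    "make_spectrum",
    "spectrum_to_fid",
    "fid_to_spectrum",
    "ppm_axis",
    "true_sensitivity",
    "synth_voxel",
    "synth_cross_sensitivity",
    "central_window",
    "synth_csi_phantom",
    "synth_csi_pair",
]

#: Larmor frequencies at 7 T (MHz) for the supported nucleus labels.
NUCLEUS_FREQ_7T_MHZ: dict[str, float] = {
    "1H": 298.0,
    "31P": 120.6,
    "23Na": 78.9,
    "13C": 74.9,
    "19F": 280.3,
    "2H": 45.7,
    "17O": 40.4,
}


class Provenance(str, enum.Enum):
    """Where a sensitivity estimate came from.

    ``TRUE``   — noise-free ground truth (simulation only).
    ``SELF``   — estimated from the very data being combined (noise-correlated).
    ``OTHER``  — estimated from an independent acquisition of the same nucleus.
    ``CROSS``  — estimated from a different nucleus (e.g. sodium for phosphorus).
    """

    TRUE = "true"
    SELF = "self"
    OTHER = "other"
    CROSS = "cross"


def _rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Spectral model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Resonance:
    """A single Lorentzian line: chemical shift (ppm), real-part peak height
    at resonance (a.u.), full width at half maximum (Hz), and phase (rad)."""

    shift_ppm: float
    amplitude: float
    linewidth_hz: float
    phase_rad: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError(f"resonance {self.label or self.shift_ppm}: amplitude must be >= 0")
        if self.linewidth_hz <= 0:
            raise ValueError(f"resonance {self.label or self.shift_ppm}: linewidth must be > 0")


@dataclass(frozen=True)
class SpectralModel:
    """A multi-line spectral model plus its acquisition axis.

    The carrier (``carrier_ppm``) is the ppm value assigned to the center of
    the readout band; by default phosphocreatine (0 ppm) sits at band center.
    """

    resonances: tuple[Resonance, ...]
    n_points: int = 256
    bandwidth_hz: float = 5000.0
    carrier_ppm: float = 0.0
    f0_mhz: float = NUCLEUS_FREQ_7T_MHZ["31P"]

    def __post_init__(self):
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.f0_mhz <= 0:
            raise ValueError("f0_mhz must be > 0")
        half_span = self.bandwidth_hz / self.f0_mhz / 2.0
        for r in self.resonances:
            if abs(r.shift_ppm - self.carrier_ppm) > half_span:
                raise ValueError(
                    f"resonance {r.label or r.shift_ppm!r} at {r.shift_ppm} ppm lies outside "
                    f"the readout band [{self.carrier_ppm - half_span:.2f}, "
                    f"{self.carrier_ppm + half_span:.2f}] ppm"
                )

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.bandwidth_hz

    @property
    def ppm_axis(self) -> np.ndarray:
        return ppm_axis(self.n_points, self.dwell_s, self.f0_mhz, self.carrier_ppm)

    def peak_window(self, label: str, half_width_ppm: float = 1.0) -> tuple[float, float]:
        """Default ppm window around the labeled resonance."""
        for r in self.resonances:
            if r.label == label:
                return (r.shift_ppm - half_width_ppm, r.shift_ppm + half_width_ppm)
        raise KeyError(f"no resonance labeled {label!r}")

    def to_json(self) -> str:
        d = {
            "resonances": [
                {
                    "shift_ppm": r.shift_ppm,
                    "amplitude": r.amplitude,
                    "linewidth_hz": r.linewidth_hz,
                    "phase_rad": r.phase_rad,
                    "label": r.label,
                }
                for r in self.resonances
            ],
            "n_points": self.n_points,
            "bandwidth_hz": self.bandwidth_hz,
            "carrier_ppm": self.carrier_ppm,
            "f0_mhz": self.f0_mhz,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "SpectralModel":
        d = json.loads(s)
        res = tuple(Resonance(**r) for r in d.pop("resonances"))
        return cls(resonances=res, **d)


def default_model_31p(n_points: int = 256, bandwidth_hz: float = 5000.0) -> SpectralModel:
    """An illustrative in-vivo-like brain ³¹P model (PCr-referenced shifts).

    Shifts are standard literature values; amplitudes and linewidths are
    package defaults chosen to look like a realistic 7 T brain spectrum.
    They are not measured ground truth of any particular acquisition.
    """
    res = (
        Resonance(0.00, 1.00, 20.0, label="PCr"),
        Resonance(4.82, 0.35, 25.0, label="Pi"),
        Resonance(6.33, 0.25, 35.0, label="PME"),
        Resonance(2.76, 0.30, 35.0, label="PDE"),
        Resonance(-2.53, 0.55, 30.0, label="gATP"),
        Resonance(-7.52, 0.55, 30.0, label="aATP"),
        Resonance(-16.26, 0.45, 40.0, label="bATP"),
    )
    return SpectralModel(res, n_points=n_points, bandwidth_hz=bandwidth_hz)


def default_model_23na(n_points: int = 256, bandwidth_hz: float = 5000.0) -> SpectralModel:
    """A single-resonance sodium-like model (one line at the carrier)."""
    res = (Resonance(0.0, 1.0, 30.0, label="Na"),)
    return SpectralModel(
        res, n_points=n_points, bandwidth_hz=bandwidth_hz, f0_mhz=NUCLEUS_FREQ_7T_MHZ["23Na"]
    )


def ppm_axis(n_points: int, dwell_s: float, f0_mhz: float, carrier_ppm: float = 0.0) -> np.ndarray:
    """Ascending ppm axis matching the package's spectrum ordering."""
    freqs_hz = np.fft.fftshift(np.fft.fftfreq(n_points, d=dwell_s))
    return carrier_ppm + freqs_hz / f0_mhz


def make_spectrum(model: SpectralModel) -> np.ndarray:
    """Evaluate the complex model spectrum on its discrete frequency grid.

    Each resonance contributes a complex Lorentzian
    ``A e^{i phi} / (1 + 2i (f - f_r) / L)`` whose real part at zero phase is
    an absorption line of height ``A`` and FWHM ``L``.
    """
    ppm = model.ppm_axis
    f_hz = (ppm - model.carrier_ppm) * model.f0_mhz
    spec = np.zeros(model.n_points, dtype=complex)
    for r in model.resonances:
        f_r = (r.shift_ppm - model.carrier_ppm) * model.f0_mhz
        x = 2.0 * (f_hz - f_r) / r.linewidth_hz
        spec += r.amplitude * np.exp(1j * r.phase_rad) / (1.0 + 1j * x)
    return spec


# ---------------------------------------------------------------------------
# FID / spectrum Fourier pair
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FidSignal:
    """A single-voxel complex FID and its axis metadata."""

    samples: np.ndarray
    dwell_s: float
    f0_mhz: float = NUCLEUS_FREQ_7T_MHZ["31P"]
    carrier_ppm: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=complex))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("FID samples must be finite")
        if self.dwell_s <= 0:
            raise ValueError("dwell must be > 0")

    @property
    def n_points(self) -> int:
        return self.samples.size

    @property
    def ppm_axis(self) -> np.ndarray:
        return ppm_axis(self.n_points, self.dwell_s, self.f0_mhz, self.carrier_ppm)

    def spectrum(self) -> np.ndarray:
        return fid_to_spectrum(self.samples)


def spectrum_to_fid(
    spectrum: np.ndarray,
    dwell_s: float,
    f0_mhz: float = NUCLEUS_FREQ_7T_MHZ["31P"],
    carrier_ppm: float = 0.0,
) -> FidSignal:
    """Inverse Fourier transform a (frequency-ascending) spectrum into an FID."""
    spectrum = np.asarray(spectrum, dtype=complex)
    if not np.all(np.isfinite(spectrum)):
        raise ValueError("spectrum must be finite")
    samples = np.fft.ifft(np.fft.ifftshift(spectrum))
    return FidSignal(samples, dwell_s, f0_mhz=f0_mhz, carrier_ppm=carrier_ppm)


def fid_to_spectrum(fid: np.ndarray) -> np.ndarray:
    """Fourier transform an FID (array or ``FidSignal.samples``) into a spectrum."""
    fid = np.asarray(fid, dtype=complex)
    return np.fft.fftshift(np.fft.fft(fid, axis=-1), axes=-1)


# ---------------------------------------------------------------------------
# Multi-channel data and sensitivities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultiChannelFid:
    """One voxel's FID as seen by every receive channel: ``data[k, t]``."""

    data: np.ndarray
    dwell_s: float
    f0_mhz: float = NUCLEUS_FREQ_7T_MHZ["31P"]
    carrier_ppm: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.data, dtype=complex)
        if d.ndim != 2 or d.shape[0] < 1:
            raise ValueError("data must be (n_channels, n_fid) with n_channels >= 1")
        if not np.all(np.isfinite(d)):
            raise ValueError("multi-channel data must be finite")
        object.__setattr__(self, "data", d)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_fid(self) -> int:
        return self.data.shape[1]

    @property
    def ppm_axis(self) -> np.ndarray:
        return ppm_axis(self.n_fid, self.dwell_s, self.f0_mhz, self.carrier_ppm)


@dataclass(frozen=True)
class SensitivityVector:
    """Per-channel complex sensitivity for a single voxel."""

    values: np.ndarray
    provenance: Provenance = Provenance.TRUE
    source_snr: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=complex)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("sensitivity values must be a 1-D array of length >= 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "provenance", Provenance(self.provenance))

    @property
    def n_channels(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SensitivityMap:
    """Per-voxel per-channel complex sensitivities: ``values[x, y, z, k]``."""

    values: np.ndarray
    provenance: Provenance = Provenance.TRUE

    def __post_init__(self):
        v = np.asarray(self.values, dtype=complex)
        if v.ndim != 4:
            raise ValueError("sensitivity map must be (nx, ny, nz, n_channels)")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "provenance", Provenance(self.provenance))

    @property
    def n_channels(self) -> int:
        return self.values.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]


@dataclass(frozen=True)
class NoiseCovariance:
    """Hermitian positive-definite inter-channel noise covariance ``R``."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("noise covariance must be square")
        if not np.allclose(m, m.conj().T, rtol=1e-8, atol=1e-12 * max(1.0, np.abs(m).max())):
            raise ValueError("noise covariance must be Hermitian")
        m = 0.5 * (m + m.conj().T)
        eig = np.linalg.eigvalsh(m)
        if eig.min() <= 0:
            raise ValueError(
                "noise covariance must be positive definite; consider adding diagonal "
                "regularization (jitter) before construction"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def identity(cls, n_channels: int) -> "NoiseCovariance":
        return cls(np.eye(n_channels, dtype=complex))

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """R^{-1} rhs via Cholesky."""
        import scipy.linalg

        c, low = scipy.linalg.cho_factor(self.matrix)
        return scipy.linalg.cho_solve((c, low), rhs)


def true_sensitivity(n_channels: int) -> SensitivityVector:
    """Unit-magnitude quadrature-phase sensitivities b_k = e^{i k 2π/N}, k = 1..N."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    k = np.arange(1, n_channels + 1)
    return SensitivityVector(np.exp(1j * k * 2.0 * np.pi / n_channels), Provenance.TRUE)


def synth_voxel(
    fid: FidSignal,
    b: SensitivityVector,
    sigma: float,
    rng_seed=None,
) -> MultiChannelFid:
    """Synthesize one voxel of multi-channel data ``p = b s + n``.

    Noise is independent complex Gaussian per channel and per sample, with
    real and imaginary parts each of standard deviation ``sigma``; there is
    no inter-channel noise correlation.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = _rng(rng_seed)
    s = fid.samples
    data = np.outer(b.values, s)
    if sigma > 0:
        shape = (b.n_channels, s.size)
        data = data + sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    return MultiChannelFid(data, fid.dwell_s, f0_mhz=fid.f0_mhz, carrier_ppm=fid.carrier_ppm)


def synth_cross_sensitivity(
    b_true: SensitivityVector,
    sigma_cross: float,
    perturbation: float = 0.0,
    rng_seed=None,
) -> SensitivityVector:
    """Emulate a sensitivity estimated from an independent high-SNR nucleus.

    Returns ``b_true * (1 + delta) + eps`` where ``delta`` is a fixed complex
    per-channel systematic deviation of relative scale ``perturbation``
    (standing in for the wavelength offset between the two Larmor
    frequencies) and ``eps`` is independent complex Gaussian noise with
    per-component standard deviation ``sigma_cross``.  The noise is
    statistically independent of any data noise by construction.
    """
    if sigma_cross < 0 or perturbation < 0:
        raise ValueError("sigma_cross and perturbation must be >= 0")
    rng = _rng(rng_seed)
    n = b_true.n_channels
    values = b_true.values.copy()
    if perturbation > 0:
        delta = perturbation * (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
        values = values * (1.0 + delta)
    if sigma_cross > 0:
        values = values + sigma_cross * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    snr = None
    if sigma_cross > 0:
        snr = float(np.mean(np.abs(b_true.values)) / sigma_cross)
    return SensitivityVector(values, Provenance.CROSS, source_snr=snr)


# ---------------------------------------------------------------------------
# CSI datasets and phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CsiDataset:
    """A spatial grid of multi-channel FIDs plus acquisition metadata.

    ``data`` has shape ``(nx, ny, nz, n_channels, n_fid)``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    fov_mm: tuple[float, float, float]
    nucleus: str
    dwell_s: float
    noise_scan: np.ndarray | None = None
    f0_mhz: float | None = None
    carrier_ppm: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.data, dtype=complex)
        if d.ndim != 5:
            raise ValueError("CSI data must be (nx, ny, nz, n_channels, n_fid)")
        object.__setattr__(self, "data", d)
        if self.nucleus not in NUCLEUS_FREQ_7T_MHZ:
            raise ValueError(
                f"unknown nucleus {self.nucleus!r}; known: {sorted(NUCLEUS_FREQ_7T_MHZ)}"
            )
        if self.f0_mhz is None:
            object.__setattr__(self, "f0_mhz", NUCLEUS_FREQ_7T_MHZ[self.nucleus])
        vs = tuple(float(v) for v in self.voxel_size_mm)
        fov = tuple(float(v) for v in self.fov_mm)
        object.__setattr__(self, "voxel_size_mm", vs)
        object.__setattr__(self, "fov_mm", fov)
        for ax in range(3):
            expect = d.shape[ax] * vs[ax]
            if not np.isclose(fov[ax], expect, rtol=1e-6):
                raise ValueError(
                    f"fov[{ax}]={fov[ax]} inconsistent with grid {d.shape[ax]} x "
                    f"voxel {vs[ax]} mm"
                )
        if self.noise_scan is not None:
            ns = np.asarray(self.noise_scan, dtype=complex)
            if ns.ndim != 2 or ns.shape[1] != d.shape[3]:
                raise ValueError("noise scan must be (n_samples, n_channels)")
            object.__setattr__(self, "noise_scan", ns)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def n_fid(self) -> int:
        return self.data.shape[4]

    @property
    def ppm_axis(self) -> np.ndarray:
        return ppm_axis(self.n_fid, self.dwell_s, self.f0_mhz, self.carrier_ppm)

    def voxel(self, ix: int, iy: int, iz: int) -> MultiChannelFid:
        return MultiChannelFid(
            self.data[ix, iy, iz], self.dwell_s, f0_mhz=self.f0_mhz, carrier_ppm=self.carrier_ppm
        )


def central_window(n: int, fraction: float, kind: str = "boxcar") -> np.ndarray:
    """A k-space window retaining the central ``ceil(fraction * n)`` samples.

    The retained block is centered on the zero-frequency index ``n // 2`` of a
    frequency-shifted (fftshift) axis; with an even count the extra sample
    goes to the low-frequency side.  ``kind`` is ``boxcar`` or ``hamming``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    m = int(np.ceil(fraction * n))
    start = n // 2 - m // 2
    w = np.zeros(n)
    if kind == "boxcar":
        w[start : start + m] = 1.0
    elif kind == "hamming":
        w[start : start + m] = np.hamming(m)
    else:
        raise ValueError("window kind must be 'boxcar' or 'hamming'")
    return w


def _apply_k_window(data: np.ndarray, spatial_shape: tuple[int, ...], fraction: float, kind: str) -> np.ndarray:
    """Filter the leading spatial axes of ``data`` through a truncated k-space window."""
    nsp = len(spatial_shape)
    axes = tuple(range(nsp))
    k = np.fft.fftshift(np.fft.fftn(data, axes=axes), axes=axes)
    for ax, n in enumerate(spatial_shape):
        w = central_window(n, fraction, kind)
        shape = [1] * data.ndim
        shape[ax] = n
        k = k * w.reshape(shape)
    return np.fft.ifftn(np.fft.ifftshift(k, axes=axes), axes=axes)


def synth_csi_phantom(
    compartment_map: np.ndarray,
    models: Mapping[int, SpectralModel],
    b_maps: np.ndarray,
    *,
    k_weighting: str = "hamming",
    truncation_fraction: float = 0.95,
    sigma: float = 0.0,
    channel_phases: Sequence[float] | None = None,
    voxel_size_mm: tuple[float, float, float] = (20.0, 20.0, 20.0),
    nucleus: str = "31P",
    noise_scan_samples: int = 0,
    rng_seed=None,
) -> CsiDataset:
    """Synthesize a low-resolution CSI acquisition of a compartment phantom.

    Each voxel emits the FID of its compartment's spectral model, weighted by
    the per-channel sensitivity ``b_maps[..., k]``; the spatial signal is
    transported through a truncated (optionally Hamming-weighted) k-space to
    emulate the point-spread function of low-resolution CSI, then independent
    complex channel noise is added.  ``channel_phases`` injects per-channel
    global phase offsets e^{i psi_k} (receive-chain offsets) into the data.

    Compartment label 0 (or any label missing from ``models``) is signal-free.
    """
    cmap = np.asarray(compartment_map)
    if cmap.ndim > 3:
        raise ValueError("compartment map must be at most 3-D")
    spatial = cmap.shape + (1,) * (3 - cmap.ndim)
    cmap3 = cmap.reshape(spatial)
    b = np.asarray(b_maps, dtype=complex)
    if b.shape[:-1] != cmap.shape:
        raise ValueError(
            f"b_maps spatial shape {b.shape[:-1]} does not match compartment map {cmap.shape}"
        )
    nch = b.shape[-1]
    b3 = b.reshape(spatial + (nch,))

    some_model = next(iter(models.values())) if models else default_model_31p()
    n_fid = some_model.n_points
    dwell = some_model.dwell_s
    f0 = some_model.f0_mhz
    carrier = some_model.carrier_ppm

    fids: dict[int, np.ndarray] = {}
    for label, model in models.items():
        if (model.n_points, model.dwell_s) != (n_fid, dwell):
            raise ValueError("all compartment models must share n_points and bandwidth")
        fids[label] = spectrum_to_fid(make_spectrum(model), dwell, f0, carrier).samples

    # spatial signal per voxel per FID sample
    sig = np.zeros(spatial + (n_fid,), dtype=complex)
    for label, f in fids.items():
        sig[cmap3 == label] = f

    data = sig[..., None, :] * b3[..., :, None]  # (x, y, z, ch, t)
    if truncation_fraction < 1 or k_weighting != "boxcar":
        data = _apply_k_window(data, spatial, truncation_fraction, k_weighting)

    rng = _rng(rng_seed)
    if sigma > 0:
        data = data + sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    if channel_phases is not None:
        ph = np.exp(1j * np.asarray(channel_phases, dtype=float))
        if ph.size != nch:
            raise ValueError("channel_phases length must equal the channel count")
        data = data * ph[None, None, None, :, None]

    noise_scan = None
    if noise_scan_samples > 0:
        noise_scan = (sigma if sigma > 0 else 1.0) * (
            rng.standard_normal((noise_scan_samples, nch))
            + 1j * rng.standard_normal((noise_scan_samples, nch))
        )

    fov = tuple(s * v for s, v in zip(spatial, voxel_size_mm))
    return CsiDataset(
        data,
        voxel_size_mm=voxel_size_mm,
        fov_mm=fov,
        nucleus=nucleus,
        dwell_s=dwell,
        noise_scan=noise_scan,
        f0_mhz=f0,
        carrier_ppm=carrier,
    )


def synth_csi_pair(
    compartment_map: np.ndarray,
    models_target: Mapping[int, SpectralModel],
    models_sens: Mapping[int, SpectralModel],
    b_maps: np.ndarray,
    *,
    sigma_target: float,
    sens_snr_gain: float = 10.0,
    cross_perturbation: float = 0.0,
    channel_phases: Sequence[float] | None = None,
    k_weighting: str = "hamming",
    truncation_fraction: float = 0.95,
    voxel_size_mm: tuple[float, float, float] = (20.0, 20.0, 20.0),
    rng_seed=None,
) -> tuple[CsiDataset, CsiDataset]:
    """Synthesize a matched low-SNR ³¹P + high-SNR ²³Na-like CSI pair.

    Both nuclei share the acquisition grid and the coil sensitivities up to a
    per-channel systematic ``cross_perturbation`` (wavelength mismatch stand-in)
    and the per-channel receive-chain phase offsets ``channel_phases``, which
    are injected into the sensitivity-source (sodium-like) dataset.  The
    sodium-like noise level is ``sigma_target / sens_snr_gain``, emulating the
    order-of-magnitude concentration advantage of sodium.
    """
    rng = _rng(rng_seed)
    b = np.asarray(b_maps, dtype=complex)
    nch = b.shape[-1]
    target = synth_csi_phantom(
        compartment_map,
        models_target,
        b,
        k_weighting=k_weighting,
        truncation_fraction=truncation_fraction,
        sigma=sigma_target,
        voxel_size_mm=voxel_size_mm,
        nucleus="31P",
        noise_scan_samples=2048 if sigma_target > 0 else 0,
        rng_seed=rng,
    )
    b_sens = b
    if cross_perturbation > 0:
        delta = cross_perturbation * (
            rng.standard_normal(nch) + 1j * rng.standard_normal(nch)
        ) / np.sqrt(2)
        b_sens = b * (1.0 + delta)
    sens = synth_csi_phantom(
        compartment_map,
        models_sens,
        b_sens,
        k_weighting=k_weighting,
        truncation_fraction=truncation_fraction,
        sigma=sigma_target / sens_snr_gain if sigma_target > 0 else 0.0,
        channel_phases=channel_phases,
        voxel_size_mm=voxel_size_mm,
        nucleus="23Na",
        rng_seed=rng,
    )
    return target, sens


def scale_model(model: SpectralModel, factor: float) -> SpectralModel:
    """A copy of ``model`` with every resonance amplitude scaled by ``factor``."""
    res = tuple(replace(r, amplitude=r.amplitude * factor) for r in model.resonances)
    return replace(model, resonances=res)


def default_phantom_maps(
    grid_shape: tuple[int, int, int],
    n_channels: int,
    decay: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A default head-like 3-D phantom: compartments and smooth coil maps.

    Compartments along the first axis: a thin high-signal slab near one edge
    (label 1, muscle-like), a signal-free gap (label 0, CSF-like), and a large
    low-signal interior (label 2, brain-like).  Coil maps decay exponentially
    from anchor points spaced around the x-y perimeter (length scale
    ``max(grid) / decay``) and carry quadrature channel phases.
    """
    nx, ny, nz = grid_shape
    cmap = np.full(grid_shape, 2, dtype=int)
    cmap[: max(1, int(0.2 * nx))] = 1
    cmap[max(1, int(0.2 * nx)) : max(2, int(0.35 * nx))] = 0

    b = np.empty(grid_shape + (n_channels,), dtype=complex)
    xx, yy, zz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    scale = max(grid_shape) / decay
    for k in range(n_channels):
        ang = 2.0 * np.pi * k / n_channels
        ax = cx + (nx / 2.0) * np.cos(ang)
        ay = cy + (ny / 2.0) * np.sin(ang)
        d = np.sqrt((xx - ax) ** 2 + (yy - ay) ** 2 + (zz - cz) ** 2)
        b[..., k] = np.exp(-d / scale) * np.exp(1j * 2.0 * np.pi * (k + 1) / n_channels)
    return cmap, b
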