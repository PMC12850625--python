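"""Phased-array coil combination and spectral metrics.

Implements the SNR-optimal (Roemer) combination in its uniform-noise and
uniform-sensitivity normalizations, the phase-blind sum-of-squares, sensitivity
estimation from early FID points, noise-covariance estimation from a noise
scan, zero/first-order phase correction, and peak-SNR metrics.

The uniform-noise combination is

    P(t) = C * b^H R^{-1} p(t) / sqrt(b^H R^{-1} b)

with ``b`` the per-channel complex sensitivity, ``R`` the inter-channel noise
covariance and ``C`` a display constant.  Under this normalization the output
noise level is position-independent (C times the single-channel level for
white noise), which makes peak heights directly comparable across voxels.
The uniform-sensitivity variant divides by ``b^H R^{-1} b`` instead, flattening
the receive profile so that noise-free data reconstructs the true signal
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.optimize

from .sigmodel import (
    MultiChannelFid,
    NoiseCovariance,
    Provenance,
    SensitivityVector,
    fid_to_spectrum,
    ppm_axis,
    spectrum_to_fid,
)

__all__ = [
    "CombinedSpectrum",
    "SnrMetrics",
    "DEFAULT_NOISE_WINDOW_PPM",
    "DEFAULT_PEAK_WINDOWS_PPM",
    "estimate_sensitivity",
    "estimate_noise_covariance",
    "roemer_combine",
    "roemer_combine_uniform_sensitivity",
    "sum_of_squares",
    "phase_correct",
    "snr_metrics",
    "combine_dataset",
]

#: Spectral region used as the noise floor: 10-20 ppm, which is free of
#: phosphorus metabolite resonances.
DEFAULT_NOISE_WINDOW_PPM: tuple[float, float] = (10.0, 20.0)

#: Default +-1 ppm peak windows around PCr (0 ppm) and alpha-ATP (-7.52 ppm).
DEFAULT_PEAK_WINDOWS_PPM: dict[str, tuple[float, float]] = {
    "PCr": (-1.0, 1.0),
    "aATP": (-8.52, -6.52),
}


@dataclass(frozen=True)
class CombinedSpectrum:
    """A combined FID plus derived spectrum and bookkeeping.

    The spectrum is always the Fourier transform of ``fid`` under the
    package's fixed convention; phase corrections are stored back into the
    FID so the invariant holds after correction too.
    """

    fid: np.ndarray
    dwell_s: float
    f0_mhz: float
    carrier_ppm: float = 0.0
    weighting_provenance: Provenance = Provenance.TRUE
    scale_constant: float = 1.0
    phase0: float = 0.0
    phase1: float = 0.0
    missing: bool = False
    low_confidence: bool = False

    def __post_init__(self):
        object.__setattr__(self, "fid", np.asarray(self.fid, dtype=complex))

    @property
    def n_fid(self) -> int:
        return self.fid.size

    @property
    def spectrum(self) -> np.ndarray:
        return fid_to_spectrum(self.fid)

    @property
    def ppm_axis(self) -> np.ndarray:
        return ppm_axis(self.n_fid, self.dwell_s, self.f0_mhz, self.carrier_ppm)


@dataclass(frozen=True)
class SnrMetrics:
    """Noise level and per-peak SNR of a combined spectrum.

    ``snr`` entries are NaN (flagged missing) when the noise estimate is zero
    rather than infinite.
    """

    noise_std: float
    peak_height: dict[str, float]
    snr: dict[str, float]


def _window_mask(ppm: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = min(window), max(window)
    mask = (ppm >= lo) & (ppm <= hi)
    if not mask.any():
        raise ValueError(f"ppm window {window} contains no spectral points")
    return mask


def estimate_sensitivity(
    p: MultiChannelFid,
    point_range: tuple[int, int] = (2, 5),
    provenance: Provenance = Provenance.SELF,
) -> SensitivityVector:
    """Estimate per-channel sensitivity from early FID points.

    ``point_range`` is a 1-based inclusive index range; the default (2, 5)
    averages the second through fifth FID samples of each channel, skipping
    the first point (prone to filter transients).  Pass (1, 5) to average the
    first five points instead.
    """
    lo, hi = point_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid 1-based inclusive point range {point_range}")
    if hi > p.n_fid:
        raise ValueError(f"point range {point_range} exceeds FID length {p.n_fid}")
    values = p.data[:, lo - 1 : hi].mean(axis=1)
    return SensitivityVector(values, provenance)


def estimate_noise_covariance(
    noise_scan: np.ndarray,
    jitter_rel: float = 1e-10,
) -> NoiseCovariance:
    """Sample covariance of a noise-only scan of shape ``(n_samples, n_channels)``.

    ``R = (1/(N-1)) sum (n - nbar)(n - nbar)^H``.  If the sample covariance is
    numerically singular it is regularized by adding ``jitter_rel`` times the
    largest eigenvalue to the diagonal (documented jitter); an identically
    zero scan is an error.
    """
    ns = np.asarray(noise_scan, dtype=complex)
    if ns.ndim != 2:
        raise ValueError("noise scan must be (n_samples, n_channels)")
    n_samples, n_ch = ns.shape
    if n_samples <= n_ch:
        raise ValueError(f"need more noise samples ({n_samples}) than channels ({n_ch})")
    centered = ns - ns.mean(axis=0, keepdims=True)
    r = (centered.T @ centered.conj()) / (n_samples - 1)
    r = 0.5 * (r + r.conj().T)
    eig = np.linalg.eigvalsh(r)
    if eig.max() <= 0:
        raise ValueError("noise scan is identically zero: covariance is singular")
    if eig.min() <= jitter_rel * eig.max():
        r = r + (jitter_rel * eig.max()) * np.eye(n_ch)
    return NoiseCovariance(r)


def _weights(b: SensitivityVector, R: NoiseCovariance | None) -> tuple[np.ndarray, float]:
    """Return ``w = R^{-1} b`` and the real quadratic form ``b^H R^{-1} b``."""
    bv = b.values
    if R is None:
        w = bv.copy()
    else:
        if R.n_channels != b.n_channels:
            raise ValueError("sensitivity and noise covariance dimensions disagree")
        try:
            w = R.solve(bv)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by type
            raise ValueError(
                "noise covariance is not positive definite; regularize it first"
            ) from exc
    quad = float(np.real(bv.conj() @ w))
    return w, quad


def roemer_combine(
    p: MultiChannelFid,
    b: SensitivityVector,
    R: NoiseCovariance | None = None,
    scale: float = 1.0,
) -> CombinedSpectrum:
    """Uniform-noise SNR-optimal combination ``C b^H R^{-1} p / sqrt(b^H R^{-1} b)``."""
    if b.n_channels != p.n_channels:
        raise ValueError("sensitivity length must match channel count")
    w, quad = _weights(b, R)
    if quad <= 0:
        raise ValueError("b^H R^{-1} b is not positive: degenerate sensitivity")
    fid = scale * (w.conj() @ p.data) / np.sqrt(quad)
    return CombinedSpectrum(
        fid,
        p.dwell_s,
        p.f0_mhz,
        p.carrier_ppm,
        weighting_provenance=b.provenance,
        scale_constant=scale,
    )


def roemer_combine_uniform_sensitivity(
    p: MultiChannelFid,
    b: SensitivityVector,
    R: NoiseCovariance | None = None,
    norm_tolerance: float = 1e-6,
    norm_reference: float | None = None,
) -> CombinedSpectrum:
    """Unit-gain (sensitivity-flattened) combination ``b^H R^{-1} p / (b^H R^{-1} b)``.

    Voxels whose sensitivity norm falls below ``norm_tolerance`` times
    ``norm_reference`` (default 1) yield a flagged missing result (NaN FID)
    rather than noise-amplified output.
    """
    if b.n_channels != p.n_channels:
        raise ValueError("sensitivity length must match channel count")
    ref = 1.0 if norm_reference is None else norm_reference
    if np.linalg.norm(b.values) < norm_tolerance * ref:
        return CombinedSpectrum(
            np.full(p.n_fid, np.nan + 1j * np.nan),
            p.dwell_s,
            p.f0_mhz,
            p.carrier_ppm,
            weighting_provenance=b.provenance,
            missing=True,
        )
    w, quad = _weights(b, R)
    fid = (w.conj() @ p.data) / quad
    return CombinedSpectrum(
        fid,
        p.dwell_s,
        p.f0_mhz,
        p.carrier_ppm,
        weighting_provenance=b.provenance,
    )


def sum_of_squares(p: MultiChannelFid) -> np.ndarray:
    """Root-sum-of-squares magnitude combination (phase discarded)."""
    return np.sqrt(np.sum(np.abs(p.data) ** 2, axis=0))


# ---------------------------------------------------------------------------
# Phase correction
# ---------------------------------------------------------------------------


def _phase_objective(win_spec: np.ndarray, win_f: np.ndarray, phi0: float, phi1: float) -> float:
    return float(np.max(np.real(win_spec * np.exp(1j * (phi0 + phi1 * win_f)))))


def phase_correct(
    spec: CombinedSpectrum,
    mode: str = "both",
    reference_window: tuple[float, float] = (-1.0, 1.0),
    phi1_max: float | None = None,
    n_grid0: int = 72,
    n_grid1: int = 41,
    refine: bool = True,
    phi1_rel_improve: float = 1e-2,
) -> CombinedSpectrum:
    """Zero/first-order phase correction maximizing the real reference peak.

    Applies ``e^{i (phi0 + phi1 (f - f_ref))}`` with ``f_ref`` the frequency of
    the magnitude maximum inside ``reference_window`` (ppm).  ``mode`` selects
    which orders are optimized: ``zero``, ``first``, or ``both``.  The optimum
    is located by a coarse grid search followed by Nelder-Mead refinement.

    The reference-peak height is nearly (often exactly) degenerate in the
    first-order term: any ramp across the window can be absorbed by the
    zero-order term at the peak sample.  A first-order term is therefore
    accepted only when it improves the peak height by more than
    ``phi1_rel_improve`` relative to the best zero-order-only correction;
    otherwise ``phi1 = 0`` is kept.  Without this tie-break the optimizer
    would wander along the flat ridge and arbitrarily rotate spectral regions
    far from the reference peak.  On signal-poor input a valid correction is
    still returned, flagged ``low_confidence``.
    """
    if mode not in ("zero", "first", "both"):
        raise ValueError("mode must be 'zero', 'first', or 'both'")
    ppm = spec.ppm_axis
    mask = _window_mask(ppm, reference_window)
    s = spec.spectrum
    f_hz = (ppm - spec.carrier_ppm) * spec.f0_mhz
    win_spec = s[mask]
    win_f_abs = f_hz[mask]
    f_ref = win_f_abs[int(np.argmax(np.abs(win_spec)))]
    win_f = win_f_abs - f_ref

    bandwidth = 1.0 / spec.dwell_s
    if phi1_max is None:
        phi1_max = 4.0 * np.pi / bandwidth

    phi0_grid = np.linspace(0.0, 2.0 * np.pi, n_grid0, endpoint=False)
    phi1_grid = np.linspace(-phi1_max, phi1_max, n_grid1)

    def _grid_and_refine(p0_grid, p1_grid, free0: bool, free1: bool):
        e0 = np.exp(1j * p0_grid)[:, None, None]
        e1 = np.exp(1j * np.outer(p1_grid, win_f))[None, :, :]
        obj = np.max(np.real(win_spec[None, None, :] * e0 * e1), axis=-1)
        i0, i1 = np.unravel_index(int(np.argmax(obj)), obj.shape)
        p0, p1 = float(p0_grid[i0]), float(p1_grid[i1])
        best = float(obj[i0, i1])
        if refine and (free0 or free1):
            x0 = ([p0] if free0 else []) + ([p1] if free1 else [])

            def neg(x):
                xs = list(x)
                a = xs.pop(0) if free0 else p0
                b = xs.pop(0) if free1 else p1
                return -_phase_objective(win_spec, win_f, a, b)

            res = scipy.optimize.minimize(
                neg, x0, method="Nelder-Mead", options={"xatol": 1e-9, "fatol": 1e-13}
            )
            xs = list(res.x)
            if free0:
                p0 = float(xs.pop(0))
            if free1:
                p1 = float(np.clip(xs.pop(0), -phi1_max, phi1_max))
            best = _phase_objective(win_spec, win_f, p0, p1)
        return p0, p1, best

    if mode == "zero":
        phi0, phi1, _ = _grid_and_refine(phi0_grid, np.array([0.0]), True, False)
    elif mode == "first":
        _, _, base = _grid_and_refine(np.array([0.0]), np.array([0.0]), False, False)
        phi0, phi1, best = _grid_and_refine(np.array([0.0]), phi1_grid, False, True)
        if best <= base + phi1_rel_improve * abs(base):
            phi1 = 0.0
    else:
        phi0_z, _, base = _grid_and_refine(phi0_grid, np.array([0.0]), True, False)
        phi0, phi1, best = _grid_and_refine(phi0_grid, phi1_grid, True, True)
        if best <= base + phi1_rel_improve * abs(base):
            phi0, phi1 = phi0_z, 0.0
    phi0 = float(np.mod(phi0, 2.0 * np.pi))

    corrected = s * np.exp(1j * (phi0 + phi1 * (f_hz - f_ref)))
    new_fid = spectrum_to_fid(corrected, spec.dwell_s, spec.f0_mhz, spec.carrier_ppm).samples
    peak = np.max(np.abs(win_spec))
    floor = np.median(np.abs(s)) + np.finfo(float).tiny
    return replace(
        spec,
        fid=new_fid,
        phase0=phi0,
        phase1=phi1,
        low_confidence=bool(peak < 5.0 * floor),
    )


def snr_metrics(
    spec: CombinedSpectrum,
    noise_window: tuple[float, float] = DEFAULT_NOISE_WINDOW_PPM,
    peak_windows: dict[str, tuple[float, float]] | None = None,
) -> SnrMetrics:
    """Peak SNRs of the real spectrum against the noise-window floor.

    Noise is the standard deviation of the real part inside ``noise_window``
    (default 10-20 ppm); each peak's SNR is its maximum real value inside its
    window divided by that noise.  The noise window must be disjoint from
    every peak window.  A zero noise floor yields NaN SNRs (flagged missing).
    """
    if peak_windows is None:
        peak_windows = DEFAULT_PEAK_WINDOWS_PPM
    ppm = spec.ppm_axis
    nlo, nhi = min(noise_window), max(noise_window)
    for label, (plo, phi) in peak_windows.items():
        lo, hi = min(plo, phi), max(plo, phi)
        if hi > nlo and lo < nhi:
            raise ValueError(f"peak window {label!r} overlaps the noise window")
    nmask = _window_mask(ppm, noise_window)
    real = np.real(spec.spectrum)
    noise = float(np.std(real[nmask]))
    heights = {}
    snrs = {}
    for label, window in peak_windows.items():
        pmask = _window_mask(ppm, window)
        h = float(np.max(real[pmask]))
        heights[label] = h
        snrs[label] = h / noise if noise > 0 else float("nan")
    return SnrMetrics(noise_std=noise, peak_height=heights, snr=snrs)


# ---------------------------------------------------------------------------
# Dataset-level pipeline
# ---------------------------------------------------------------------------


def combine_dataset(
    csi,
    sens_source: str = "self",
    sens_csi=None,
    point_range: tuple[int, int] = (2, 5),
    R: NoiseCovariance | None = None,
    offsets=None,
    noise_window: tuple[float, float] = DEFAULT_NOISE_WINDOW_PPM,
    peak_windows: dict[str, tuple[float, float]] | None = None,
    norm_tolerance: float = 1e-6,
    phase_mode: str = "both",
):
    """Combine every voxel of a CSI dataset; return spectra and an SNR table.

    ``sens_source='self'`` estimates each voxel's sensitivity from its own
    early FID points; ``'cross'`` estimates it from the matching voxel of an
    independently acquired ``sens_csi`` (e.g. a sodium scan), optionally
    rotated by per-channel calibration ``offsets``.  The noise covariance
    defaults to an estimate from the dataset's noise scan when present, else
    the identity.  Voxels whose sensitivity norm is below ``norm_tolerance``
    times the volume maximum are flagged missing (NaN).

    Returns ``(spectra, table)``: a complex ``(nx, ny, nz, n_fid)`` array of
    phase-corrected combined spectra and a :class:`pandas.DataFrame` with one
    row per voxel (noise level, per-peak heights and SNRs, missing flag).
    """
    import pandas as pd

    if peak_windows is None:
        peak_windows = DEFAULT_PEAK_WINDOWS_PPM
    if sens_source not in ("self", "cross"):
        raise ValueError("sens_source must be 'self' or 'cross'")
    if sens_source == "cross":
        if sens_csi is None:
            raise ValueError("sens_source='cross' requires sens_csi")
        if sens_csi.grid_shape != csi.grid_shape or sens_csi.n_channels != csi.n_channels:
            raise ValueError("sensitivity dataset grid does not match the data grid")
    if R is None and csi.noise_scan is not None:
        R = estimate_noise_covariance(csi.noise_scan)

    phase = None
    if offsets is not None:
        phase = np.exp(1j * np.asarray(offsets, dtype=float))
        if phase.size != csi.n_channels:
            raise ValueError("offsets length must equal the channel count")

    nx, ny, nz = csi.grid_shape
    prov = Provenance.SELF if sens_source == "self" else Provenance.CROSS

    # first pass: sensitivity vectors and the volume-wide norm reference
    b_vals = np.empty((nx, ny, nz, csi.n_channels), dtype=complex)
    source = csi if sens_source == "self" else sens_csi
    lo, hi = point_range
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                b_vals[ix, iy, iz] = source.data[ix, iy, iz, :, lo - 1 : hi].mean(axis=1)
    if phase is not None:
        b_vals = b_vals * phase
    norm_ref = float(np.linalg.norm(b_vals, axis=-1).max())

    spectra = np.full((nx, ny, nz, csi.n_fid), np.nan + 1j * np.nan)
    rows = []
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                b = SensitivityVector(b_vals[ix, iy, iz], prov)
                if np.linalg.norm(b.values) < norm_tolerance * norm_ref:
                    rows.append(
                        {"ix": ix, "iy": iy, "iz": iz, "missing": True, "noise_std": np.nan}
                        | {f"snr_{k}": np.nan for k in peak_windows}
                    )
                    continue
                combined = roemer_combine(csi.voxel(ix, iy, iz), b, R)
                ref_window = next(iter(peak_windows.values()))
                corrected = phase_correct(combined, mode=phase_mode, reference_window=ref_window)
                spectra[ix, iy, iz] = corrected.spectrum
                m = snr_metrics(corrected, noise_window, peak_windows)
                rows.append(
                    {"ix": ix, "iy": iy, "iz": iz, "missing": False, "noise_std": m.noise_std}
                    | {f"snr_{k}": m.snr[k] for k in peak_windows}
                    | {f"height_{k}": m.peak_height[k] for k in peak_windows}
                )
    return spectra, pd.DataFrame(rows)
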