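"""SNR evaluation from simulated electromagnetic fields.

Given per-channel electric fields (per unit loop current) over a tissue
volume, the inter-channel thermal-noise covariance is the conductivity-
weighted field overlap

    R_ik = sum_voxels sigma(x) E_i(x) . E_k(x)* dV

(the conjugated dot product keeps R Hermitian).  Given per-channel receive
sensitivities (B1-minus maps), the voxel-wise SNR of the optimal linear
combination with weights R^{-1} b is

    SNR = const * |p^H R^{-1} b| / sqrt(b^H R^{-1} b)

where ``p`` is the received-signal vector (in simulation studies the target
nucleus' B1-minus stands in for it) and ``b`` the sensitivity used for the
combination.  With ``b = p`` this is the matched-filter optimum
``sqrt(p^H R^{-1} p)``; any other sensitivity reaches a fraction <= 1 of it
(Cauchy-Schwarz), which is what the ratio maps quantify.

All physical constants default to 1 so the module reports relative SNR; the
comparisons of interest are ratios, in which the constants cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sigmodel import NoiseCovariance

__all__ = [
    "FieldSet",
    "SnrEvalConstants",
    "noise_cov_from_fields",
    "snr_map",
    "snr_ratio_map",
]


@dataclass(frozen=True)
class FieldSet:
    """Per-channel complex fields on a voxel grid.

    ``e_fields``: (n_channels, nx, ny, nz, 3) complex V/m per unit loop
    current; ``b1_minus``: (n_channels, nx, ny, nz) complex receive
    sensitivity; ``conductivity``: (nx, ny, nz) S/m; ``voxel_volume_m3``
    the volume of one grid cell; ``frequency_hz`` the Larmor frequency the
    fields were simulated at.
    """

    e_fields: np.ndarray | None
    b1_minus: np.ndarray | None
    conductivity: np.ndarray | None
    voxel_volume_m3: float = 1.0
    frequency_hz: float = 0.0

    def __post_init__(self):
        grid = None
        if self.e_fields is not None:
            e = np.asarray(self.e_fields, dtype=complex)
            if e.ndim != 5 or e.shape[-1] != 3:
                raise ValueError("e_fields must be (n_channels, nx, ny, nz, 3)")
            object.__setattr__(self, "e_fields", e)
            grid = e.shape[1:4]
        if self.b1_minus is not None:
            b = np.asarray(self.b1_minus, dtype=complex)
            if b.ndim != 4:
                raise ValueError("b1_minus must be (n_channels, nx, ny, nz)")
            if grid is not None and b.shape[1:] != grid:
                raise ValueError("b1_minus grid does not match e_fields grid")
            object.__setattr__(self, "b1_minus", b)
            grid = b.shape[1:]
        if self.conductivity is not None:
            s = np.asarray(self.conductivity, dtype=float)
            if s.ndim != 3:
                raise ValueError("conductivity must be (nx, ny, nz)")
            if np.any(s < 0):
                raise ValueError("conductivity must be >= 0")
            if grid is not None and s.shape != grid:
                raise ValueError("conductivity grid does not match field grids")
            object.__setattr__(self, "conductivity", s)
        if self.voxel_volume_m3 <= 0:
            raise ValueError("voxel_volume_m3 must be > 0")

    @property
    def n_channels(self) -> int:
        if self.e_fields is not None:
            return self.e_fields.shape[0]
        if self.b1_minus is not None:
            return self.b1_minus.shape[0]
        raise ValueError("field set holds neither E fields nor B1- maps")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        if self.b1_minus is not None:
            return self.b1_minus.shape[1:]
        return self.e_fields.shape[1:4]


@dataclass(frozen=True)
class SnrEvalConstants:
    """Physical constants of the absolute-SNR prefactor omega M V / sqrt(4 k T df).

    All default to 1, in which case the evaluation is in relative-SNR mode.
    """

    omega: float = 1.0
    magnetization: float = 1.0
    voxel_volume: float = 1.0
    boltzmann: float = 1.0
    temperature: float = 1.0
    bandwidth: float = 1.0

    def __post_init__(self):
        for name in ("omega", "magnetization", "voxel_volume", "boltzmann", "temperature", "bandwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def prefactor(self) -> float:
        return (
            self.omega
            * self.magnetization
            * self.voxel_volume
            / np.sqrt(4.0 * self.boltzmann * self.temperature * self.bandwidth)
        )


def noise_cov_from_fields(fs: FieldSet) -> NoiseCovariance:
    """Thermal-noise covariance from conductivity-weighted E-field overlaps."""
    if fs.e_fields is None or fs.conductivity is None:
        raise ValueError("field set must carry E fields and a conductivity map")
    if not np.any(fs.conductivity > 0):
        raise ValueError("conductivity is zero everywhere: noise covariance is singular")
    r = np.einsum(
        "ixyzc,kxyzc,xyz->ik",
        fs.e_fields,
        fs.e_fields.conj(),
        fs.conductivity,
    ) * fs.voxel_volume_m3
    r = 0.5 * (r + r.conj().T)
    return NoiseCovariance(r)


def snr_map(
    fs_signal: FieldSet,
    fs_sens: FieldSet,
    R: NoiseCovariance,
    consts: SnrEvalConstants | None = None,
    norm_tolerance: float = 1e-12,
) -> np.ndarray:
    """Voxel-wise relative SNR of the combination weighted by ``fs_sens``.

    ``SNR(x) = const |p(x)^H R^{-1} b(x)| / sqrt(b(x)^H R^{-1} b(x))`` with
    ``p`` from ``fs_signal.b1_minus`` and ``b`` from ``fs_sens.b1_minus``.
    Voxels with vanishing ``b^H R^{-1} b`` are NaN (flagged missing).
    """
    if consts is None:
        consts = SnrEvalConstants()
    p = fs_signal.b1_minus
    b = fs_sens.b1_minus
    if p is None or b is None:
        raise ValueError("both field sets must carry B1- maps")
    if p.shape != b.shape:
        raise ValueError(f"signal grid {p.shape} does not match sensitivity grid {b.shape}")
    if R.n_channels != p.shape[0]:
        raise ValueError("noise covariance dimension does not match channel count")
    nch = p.shape[0]
    grid = p.shape[1:]
    pf = p.reshape(nch, -1)
    bf = b.reshape(nch, -1)
    w = R.solve(bf)  # R^{-1} b, per voxel column
    num = np.abs(np.sum(pf.conj() * w, axis=0))
    quad = np.real(np.sum(bf.conj() * w, axis=0))
    out = np.full(pf.shape[1], np.nan)
    ok = quad > norm_tolerance
    out[ok] = consts.prefactor * num[ok] / np.sqrt(quad[ok])
    return out.reshape(grid)


def snr_ratio_map(
    fs_signal: FieldSet,
    fs_sens_alt: FieldSet,
    fs_sens_ref: FieldSet,
    R: NoiseCovariance,
    consts: SnrEvalConstants | None = None,
) -> np.ndarray:
    """Voxel-wise SNR ratio of an alternative sensitivity over a reference.

    Physical constants cancel.  When the reference is the matched filter
    (``fs_sens_ref = fs_signal``) the ratio is bounded by 1 (Cauchy-Schwarz).
    Voxels where the reference SNR vanishes are NaN (flagged missing).
    """
    alt = snr_map(fs_signal, fs_sens_alt, R, consts)
    ref = snr_map(fs_signal, fs_sens_ref, R, consts)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = alt / ref
    ratio[~np.isfinite(ratio)] = np.nan
    return ratio
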