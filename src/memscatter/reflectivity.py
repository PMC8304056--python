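"""Specular reflectivity kernels: Parratt recursion, Abelès matrices, Born limit.

Both exact kernels propagate complex wave amplitudes through a stack of
homogeneous slabs between two semi-infinite media.  The vertical wavevector in
medium j is ``k_j = sqrt((Q/2)² − 4π(ρ_j − ρ_fronting))`` with the evanescent
branch taken as +iκ below the medium's critical edge.  Gaussian interfacial
roughness damps each interface reflectance by the Nevot–Croce factor
``exp(−2 k_j k_{j+1} σ²)``, the reflectometry analogue of a Debye–Waller
factor.  Parratt and Abelès are algebraically equivalent exact solutions and
are kept as two independent kernels so each can check the other.

The Born "master equation" expresses R at large Q as the Fresnel reflectivity
times the squared Fourier transform of dρ/dz normalized by the total contrast;
it fails below the critical edge (where it exceeds 1) and is provided for
intuition and as a high-Q cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .assembly import SlabStack
from .profiles import SLDProfile

__all__ = [
    "ReflectivityCurve",
    "fresnel_interface",
    "parratt_reflectivity",
    "abeles_reflectivity",
    "born_reflectivity",
    "smear_resolution",
    "apply_scale_background",
    "incoherent_mean",
    "locate_bragg_peaks",
    "q_grid",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class ReflectivityCurve:
    """Reflectivity vs momentum transfer: Q (Å⁻¹, ascending), R, optional dR/dQ."""

    Q: np.ndarray
    R: np.ndarray
    dR: np.ndarray | None = None
    dQ: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.Q.shape != self.R.shape:
            raise ValueError("Q and R must have the same shape")
        if np.any(self.Q <= 0) or np.any(np.diff(self.Q) <= 0):
            raise ValueError("Q must be positive and strictly ascending")
        if self.dR is not None:
            self.dR = np.asarray(self.dR, dtype=float)
        if self.dQ is not None:
            self.dQ = np.asarray(self.dQ, dtype=float)

    def copy(self) -> "ReflectivityCurve":
        return ReflectivityCurve(
            self.Q.copy(),
            self.R.copy(),
            None if self.dR is None else self.dR.copy(),
            None if self.dQ is None else self.dQ.copy(),
            dict(self.metadata),
        )


def q_grid(q_min: float = 0.005, q_max: float = 0.3, n: int = 500, log: bool = False) -> np.ndarray:
    """Convenience Q grid; never extends below 1e-4 Å⁻¹."""
    q_min = max(q_min, 1e-4)
    if log:
        return np.geomspace(q_min, q_max, n)
    return np.linspace(q_min, q_max, n)


def _kz(Q: np.ndarray, sld: complex, sld_fronting: complex) -> np.ndarray:
    """Vertical wavevector in a medium, referenced to the fronting medium.

    Complex sqrt takes the principal branch, giving the +iκ evanescent wave
    below the critical edge.
    """
    return np.sqrt((Q / 2.0) ** 2 - 4.0 * np.pi * (sld - sld_fronting) + 0j)


def fresnel_interface(Q, sld_front: complex, sld_back: complex):
    """Fresnel amplitude reflectance and transmittance of one sharp interface."""
    Q = np.asarray(Q, dtype=float)
    kf = _kz(Q, sld_front, sld_front)
    kb = _kz(Q, sld_back, sld_front)
    r = (kf - kb) / (kf + kb)
    t = 2.0 * kf / (kf + kb)
    return r, t


def _stack_kz(stack: SlabStack, Q: np.ndarray):
    slds, d, sigma = stack.arrays()
    k = np.empty((len(slds), len(Q)), dtype=complex)
    for j, rho in enumerate(slds):
        k[j] = _kz(Q, rho, slds[0])
    return k, d, sigma


def _warn_thin_rough(stack: SlabStack) -> None:
    for i, s in enumerate(stack.slabs):
        sig_above = s.roughness
        sig_below = (
            stack.slabs[i + 1].roughness
            if i + 1 < len(stack.slabs)
            else stack.backing_roughness
        )
        if max(sig_above, sig_below) > s.thickness / 3.0:
            warnings.warn(
                f"slab {i}: roughness {max(sig_above, sig_below):.2f} Å exceeds "
                f"thickness/3 ({s.thickness / 3.0:.2f} Å); the Nevot-Croce "
                "approximation assumes roughness much smaller than the layer",
                stacklevel=3,
            )


def parratt_reflectivity(stack: SlabStack, Q) -> ReflectivityCurve:
    """Exact reflectivity by the Parratt recursion (backing to fronting)."""
    Q = np.asarray(Q, dtype=float)
    _warn_thin_rough(stack)
    k, d, sigma = _stack_kz(stack, Q)
    n_int = k.shape[0] - 1
    # interface Fresnel coefficients with Nevot-Croce damping
    r_amp = np.zeros_like(Q, dtype=complex)
    for j in range(n_int - 1, -1, -1):
        r_j = (k[j] - k[j + 1]) / (k[j] + k[j + 1])
        if sigma[j] > 0:
            r_j = r_j * np.exp(-2.0 * k[j] * k[j + 1] * sigma[j] ** 2)
        if j == n_int - 1:
            r_amp = r_j
        else:
            phase = np.exp(2j * k[j + 1] * d[j])
            r_amp = (r_j + r_amp * phase) / (1.0 + r_j * r_amp * phase)
    R = np.abs(r_amp) ** 2
    return ReflectivityCurve(Q, R, metadata={"kernel": "parratt"})


def abeles_reflectivity(stack: SlabStack, Q) -> ReflectivityCurve:
    """Exact reflectivity by the Abelès optical transfer-matrix product."""
    Q = np.asarray(Q, dtype=float)
    _warn_thin_rough(stack)
    k, d, sigma = _stack_kz(stack, Q)
    n_int = k.shape[0] - 1
    nq = len(Q)
    M00 = np.ones(nq, dtype=complex)
    M01 = np.zeros(nq, dtype=complex)
    M10 = np.zeros(nq, dtype=complex)
    M11 = np.ones(nq, dtype=complex)
    for j in range(n_int):
        r_j = (k[j] - k[j + 1]) / (k[j] + k[j + 1])
        if sigma[j] > 0:
            r_j = r_j * np.exp(-2.0 * k[j] * k[j + 1] * sigma[j] ** 2)
        beta = k[j] * d[j - 1] if j > 0 else np.zeros(nq, dtype=complex)
        ep, em = np.exp(1j * beta), np.exp(-1j * beta)
        a00, a01 = ep, r_j * ep
        a10, a11 = r_j * em, em
        M00, M01, M10, M11 = (
            M00 * a00 + M01 * a10,
            M00 * a01 + M01 * a11,
            M10 * a00 + M11 * a10,
            M10 * a01 + M11 * a11,
        )
    r_amp = M10 / M00
    R = np.abs(r_amp) ** 2
    return ReflectivityCurve(Q, R, metadata={"kernel": "abeles"})


def born_reflectivity(profile: SLDProfile, Q) -> ReflectivityCurve:
    """Born-approximation reflectivity of a binned profile.

    R(Q) = R_Fresnel(Q) · |Σ_k Δρ_k e^{iQ z_k}|² / Δρ_total², summing the SLD
    steps at the bin edges (a sharp interface therefore reproduces the exact
    Fresnel curve).  Valid only well above the critical edge; the region
    Q < Qc is flagged in the metadata and the curve there is meaningless.
    """
    Q = np.asarray(Q, dtype=float)
    fronting = profile.fronting if profile.fronting is not None else float(profile.rho[0])
    backing = profile.backing if profile.backing is not None else float(profile.rho[-1])
    d_total = backing - fronting
    if d_total == 0.0:
        raise ValueError("zero total contrast: Born master equation undefined")
    # SLD steps at every bin edge, including the two semi-infinite junctions:
    # fronting->rho[0] at edge 0, rho[i]->rho[i+1] at the inner edges, and
    # rho[-1]->backing at the last edge; one step per edge.
    levels = np.concatenate([[fronting], profile.rho, [backing]])
    steps = np.diff(levels)
    positions = profile.bin_edges
    ft = (steps[None, :] * np.exp(1j * Q[:, None] * positions[None, :])).sum(axis=1)
    r_f, _ = fresnel_interface(Q, fronting, backing)
    R = np.abs(r_f) ** 2 * np.abs(ft) ** 2 / d_total**2
    qc = math.sqrt(16.0 * math.pi * d_total) if d_total > 0 else 0.0
    return ReflectivityCurve(
        Q, R, metadata={"kernel": "born", "invalid_below_q": qc}
    )


def smear_resolution(
    curve: ReflectivityCurve,
    dq_over_q: float,
    convention: str = "fwhm",
    n_kernel: int = 51,
    width_sigmas: float = 4.0,
) -> ReflectivityCurve:
    """Gaussian resolution convolution with Q-proportional width.

    ``dq_over_q`` is interpreted as the FWHM fraction (common reflectometry
    convention; pass ``convention='sigma'`` for a σ fraction).  Each output
    point is a normalized Gaussian quadrature over ±``width_sigmas``σ of the
    input curve interpolated linearly in Q and clamped at the ends.
    """
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be >= 0")
    if dq_over_q == 0:
        return curve.copy()
    if convention == "fwhm":
        sig_frac = dq_over_q * _FWHM_TO_SIGMA
    elif convention == "sigma":
        sig_frac = dq_over_q
    else:
        raise ValueError("convention must be 'fwhm' or 'sigma'")
    Q, R = curve.Q, curve.R
    u = np.linspace(-width_sigmas, width_sigmas, n_kernel)
    w = np.exp(-0.5 * u**2)
    w /= w.sum()
    samples = Q[:, None] * (1.0 + sig_frac * u[None, :])
    Rs = np.interp(samples, Q, R)  # clamps outside the measured range
    R_out = (Rs * w[None, :]).sum(axis=1)
    out = curve.copy()
    out.R = R_out
    out.dQ = dq_over_q * Q
    out.metadata = dict(curve.metadata, dq_over_q=dq_over_q, convention=convention)
    return out


def apply_scale_background(
    curve: ReflectivityCurve, scale: float, background: float
) -> ReflectivityCurve:
    """R' = scale · R + background (normalization error + Q-independent background)."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if background < 0:
        raise ValueError("background must be >= 0")
    out = curve.copy()
    out.R = scale * curve.R + background
    if curve.dR is not None:
        out.dR = scale * curve.dR
    out.metadata = dict(curve.metadata, scale=scale, background=background)
    return out


def incoherent_mean(curves: Sequence[ReflectivityCurve]) -> ReflectivityCurve:
    """Pointwise mean of intensities over uncorrelated structural realizations."""
    if not curves:
        raise ValueError("need at least one curve")
    ref = curves[0]
    for c in curves[1:]:
        if len(c.Q) != len(ref.Q) or not np.allclose(c.Q, ref.Q):
            raise ValueError("curves are on different Q grids")
    R = np.mean([c.R for c in curves], axis=0)
    return ReflectivityCurve(
        ref.Q.copy(), R, metadata={"n_realizations": len(curves)}
    )


def locate_bragg_peaks(
    curve: ReflectivityCurve,
    q_min: float,
    prominence: float = 0.3,
) -> list[tuple[float, float]]:
    """Local maxima of log10 R above ``q_min``, with parabolic Q refinement.

    Returns (Q_peak, d = 2π/Q_peak) pairs; ``prominence`` is in decades of R.
    An empty list means no peaks (e.g. a featureless Fresnel decay).
    """
    mask = curve.Q >= q_min
    Q = curve.Q[mask]
    logR = np.log10(np.clip(curve.R[mask], 1e-15, None))
    idx, _ = find_peaks(logR, prominence=prominence)
    out = []
    for i in idx:
        if 0 < i < len(Q) - 1:
            y0, y1, y2 = logR[i - 1], logR[i], logR[i + 1]
            denom = y0 - 2.0 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
            qp = Q[i] + shift * (Q[min(i + 1, len(Q) - 1)] - Q[i - 1]) / 2.0
        else:
            qp = Q[i]
        out.append((float(qp), 2.0 * math.pi / float(qp)))
    return out
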