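"""Variational mode decomposition with pinned center frequencies (MVMD).

Standard VMD decomposes a signal into K narrow-band modes u_k with center
frequencies w_k by ADMM on the variational problem

    min sum_k || d/dt [ analytic(u_k) e^{-j w_k t} ] ||^2   s.t.  sum_k u_k = x,

alternating (i) a Wiener-filter mode update in the frequency domain,

    u_k(v) <- ( x(v) - sum_{i != k} u_i(v) - lambda(v)/2 ) / (1 + 2a (v - w_k)^2),

(ii) a power-weighted-mean center update  w_k <- (int v |u_k|^2) / (int |u_k|^2),
and (iii) dual ascent  lambda <- lambda + tau (sum_k u_k - x).

The modification: a subset of the centers is *pinned* — their w_k are never
updated.  For the shock-advice channel construction, 10 modes are used with
six pinned centers {0, 2, 3.5, 5, 6.5, 8} Hz; the remaining four centers are
free and settle above 10 Hz on ECG-like inputs.  The sum of the five nonzero
pinned modes is the shockability-oriented (SH) signal, the sum of the free
modes the NSH signal, and the 0 Hz mode (residual DC/drift) is discarded.

All spectral work happens on the half spectrum of the mirror-extended signal;
because every update is linear in the rfft of a real signal, each mode's half
spectrum inverts to a real mode directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .records import ChannelStack, Segment

__all__ = ["MvmdParams", "ModeSet", "mvmd_decompose", "build_channels"]

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps

#: the pinned center frequencies of the shock-advice construction (Hz)
DEFAULT_FIXED_FREQS = (0.0, 2.0, 3.5, 5.0, 6.5, 8.0)


@dataclass
class MvmdParams:
    """Decomposition settings.

    alpha is the bandwidth penalty (dimensionless, on normalized frequency),
    tau the dual-ascent step (tau > 0 enforces exact reconstruction at
    convergence), tol the convergence tolerance on the summed relative mode
    change per iteration.
    """

    n_modes: int = 10
    fixed_freqs: tuple[float, ...] = DEFAULT_FIXED_FREQS
    alpha: float = 2000.0
    tau: float = 0.1
    tol: float = 1e-6
    max_iter: int = 500
    free_init_lo_hz: float = 10.0   # free centers start — and stay — above this floor

    def __post_init__(self) -> None:
        if self.n_modes < len(self.fixed_freqs):
            raise ValueError("n_modes must be >= number of fixed frequencies")
        if any(f >= 10.0 for f in self.fixed_freqs if f > 0):
            raise ValueError("nonzero pinned centers must lie below 10 Hz")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    @property
    def n_free(self) -> int:
        return self.n_modes - len(self.fixed_freqs)


@dataclass
class ModeSet:
    """K modes, their center frequencies (Hz), and the fixed/free mask."""

    modes: np.ndarray            # (K, n_samples)
    center_freqs: np.ndarray     # (K,) Hz
    fixed_mask: np.ndarray       # (K,) bool
    n_iters: int
    converged: bool
    fs: float

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


def _mirror_extend(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Reflect half the signal at each end (standard VMD boundary treatment)."""
    n = len(x)
    half = n // 2
    xm = np.concatenate([x[:half][::-1], x, x[half:][::-1]])
    return xm, half


def mvmd_decompose(x: np.ndarray, fs: float, params: MvmdParams | None = None) -> ModeSet:
    """Decompose a preprocessed ECG segment into modes with pinned centers.

    Non-convergence within ``max_iter`` returns the best iterate with a
    warning; an all-zero input returns all-zero modes.
    """
    if params is None:
        params = MvmdParams()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("expected a 1-D signal of at least 4 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples cannot be decomposed")

    K = params.n_modes
    n = len(x)
    xm, half = _mirror_extend(x)
    T = len(xm)
    nf = T // 2 + 1
    nu = np.arange(nf) / T                      # normalized frequency, cycles/sample
    X = np.fft.rfft(xm)

    fixed = np.zeros(K, dtype=bool)
    fixed[: len(params.fixed_freqs)] = True
    omega = np.empty(K)
    omega[: len(params.fixed_freqs)] = np.asarray(params.fixed_freqs) / fs
    if params.n_free > 0:
        lo, hi = params.free_init_lo_hz / fs, 0.8 * 0.5
        omega[len(params.fixed_freqs):] = lo + (hi - lo) * (
            np.arange(1, params.n_free + 1) / (params.n_free + 1)
        )

    u_hat = np.zeros((K, nf), dtype=complex)
    lam = np.zeros(nf, dtype=complex)
    sum_u = np.zeros(nf, dtype=complex)

    zero_input = np.abs(X).max() <= _EPS
    n_iter = 0
    converged = False
    omega_floor = params.free_init_lo_hz / fs
    if not zero_input:
        for n_iter in range(1, params.max_iter + 1):
            delta_sq = 0.0
            prev_sq = 0.0
            for k in range(K):
                sum_u -= u_hat[k]
                u_new = (X - sum_u - lam / 2) / (1 + 2 * params.alpha * (nu - omega[k]) ** 2)
                if not fixed[k]:
                    p = np.abs(u_new) ** 2
                    denom = p.sum()
                    if denom > _EPS:
                        # free centers track their mode's power centroid but are
                        # confined to the band above the pinned (sub-10 Hz) set
                        omega[k] = min(max((nu * p).sum() / denom, omega_floor), 0.5)
                prev_sq += np.vdot(u_hat[k], u_hat[k]).real
                delta = u_new - u_hat[k]
                delta_sq += np.vdot(delta, delta).real
                u_hat[k] = u_new
                sum_u += u_new
            lam += params.tau * (sum_u - X)
            if n_iter > 1 and delta_sq / (prev_sq + _EPS) < params.tol:
                converged = True
                break
        if not converged:
            logger.warning(
                "MVMD did not reach tol=%.1e within %d iterations (last change %.2e); "
                "returning best iterate", params.tol, params.max_iter,
                delta_sq / (prev_sq + _EPS),
            )
    else:
        converged = True

    modes = np.empty((K, n))
    for k in range(K):
        modes[k] = np.fft.irfft(u_hat[k], T)[half: half + n]
    return ModeSet(
        modes=modes,
        center_freqs=omega * fs,
        fixed_mask=fixed,
        n_iters=n_iter,
        converged=converged,
        fs=fs,
    )


def build_channels(
    pecg: np.ndarray,
    modes: ModeSet,
    label: int = 0,
    record_id: str = "",
) -> ChannelStack:
    """Assemble the 3-channel CNN input from a decomposition.

    SH channel = sum of nonzero pinned modes; NSH channel = sum of free
    modes; the 0 Hz pinned mode belongs to neither.
    """
    pecg = np.asarray(pecg, dtype=float)
    if modes.modes.shape[1] != len(pecg):
        raise ValueError("mode length does not match the pECG length")
    pinned_nonzero = modes.fixed_mask & (modes.center_freqs > 0)
    free = ~modes.fixed_mask
    if not pinned_nonzero.any() and not free.any():
        raise ValueError("mode set has neither nonzero pinned nor free modes")
    sh = modes.modes[pinned_nonzero].sum(axis=0)
    nsh = modes.modes[free].sum(axis=0) if free.any() else np.zeros_like(pecg)
    return ChannelStack(pecg=pecg, sh_signal=sh, nsh_signal=nsh,
                        label=label, record_id=record_id)


def channels_for_segment(segment: Segment, fs: float,
                         params: MvmdParams | None = None) -> ChannelStack:
    """Decompose an (already preprocessed) segment and build its channels."""
    ms = mvmd_decompose(segment.samples, fs, params)
    return build_channels(segment.samples, ms, label=segment.label,
                         record_id=segment.record_id)
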