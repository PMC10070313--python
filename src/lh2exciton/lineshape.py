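"""Spectral densities, cumulant lineshape functions and homogeneous spectra.

The exciton-phonon coupling of each pigment is encoded in a spectral density
J(w) = J_env(w) + J_vib(w): an overdamped Drude-Lorentz component for the
low-frequency protein/solvent bath and a sum of underdamped Brownian
oscillators for the high-frequency intramolecular modes of the
bacteriochlorophyll.  The second-order cumulant lineshape function

    g(t) = (1/pi) Int_0^inf dw J(w)/w^2
           [ coth(hbar w / 2 kT) (1 - cos wt) + i (sin wt - wt) ]

yields homogeneous absorption lineshapes in the exciton basis,

    A(w) ~ w Sum_k |mu_k|^2 Re Int_0^inf dt e^{i(w - w_k)t - g_k(t) - t/(2 tau_k)},

with the per-exciton lineshape function g_k(t) = Sum_i c_ki^4 g_i(t)
(exchange narrowing: delocalization over N sites reduces the dynamic
broadening by the participation factor Sum_i c^4) and optional lifetime
broadening tau_k from secular Redfield relaxation rates.  CD spectra replace
|mu_k|^2 by the signed rotational strength R_k.

Internal units: energies/frequencies in cm^-1, time in fs, temperature in K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exciton import ExcitonState

__all__ = [
    "SpectralDensity",
    "LineshapeFunction",
    "evaluate_spectral_density",
    "lineshape_g",
    "homogeneous_absorption",
    "homogeneous_cd",
    "redfield_lifetimes",
    "fwhm",
    "KB_CM",
    "TWO_PI_C",
]

#: Boltzmann constant in cm^-1 / K.
KB_CM = 0.6950348
#: 2*pi*c in cm/fs: multiplies (cm^-1 x fs) into a phase in radians.
TWO_PI_C = 2.0 * np.pi * 2.99792458e-5


@dataclass(frozen=True)
class SpectralDensity:
    """J(w) = J_env (Drude-Lorentz) + J_vib (underdamped Brownian oscillators).

    lambda_env: environment reorganization energy (cm^-1); omega_c: Drude
    cutoff frequency (cm^-1); modes: (lambda_j, omega_j, gamma_j) triples in
    cm^-1 for the intramolecular vibrations.
    """

    lambda_env: float = 0.0
    omega_c: float = 50.0
    modes: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.lambda_env < 0 or self.omega_c <= 0:
            raise ValueError("lambda_env must be >= 0 and omega_c > 0")
        for lam, w0, gam in self.modes:
            if lam < 0 or w0 <= 0 or gam <= 0:
                raise ValueError(
                    "each mode needs lambda >= 0, omega > 0, gamma > 0"
                )
        object.__setattr__(self, "modes", tuple(tuple(m) for m in self.modes))

    @property
    def total_reorganization(self) -> float:
        """lambda_env + sum of mode reorganization energies (cm^-1)."""
        return self.lambda_env + sum(m[0] for m in self.modes)

    @property
    def max_frequency(self) -> float:
        """Highest characteristic frequency: drives the Nyquist check."""
        freqs = [self.omega_c] + [w0 + gam for _, w0, gam in self.modes]
        return max(freqs)

    def __call__(self, omega: np.ndarray) -> np.ndarray:
        return evaluate_spectral_density(self, omega)


def evaluate_spectral_density(sd: SpectralDensity, omega: np.ndarray) -> np.ndarray:
    """Evaluate J(w) >= 0 on a grid of non-negative frequencies (cm^-1).

    Drude-Lorentz: 2 lambda w w_c / (w^2 + w_c^2), which peaks at w = w_c
    with value lambda.  Brownian oscillator:
    2 lambda_j w_j^2 gamma_j w / ((w^2 - w_j^2)^2 + gamma_j^2 w^2).
    Both satisfy (1/pi) Int J/w dw = lambda.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega grid must be non-negative")
    j = 2.0 * sd.lambda_env * w * sd.omega_c / (w**2 + sd.omega_c**2)
    for lam, w0, gam in sd.modes:
        j = j + 2.0 * lam * w0**2 * gam * w / ((w**2 - w0**2) ** 2 + gam**2 * w**2)
    return j


@dataclass
class LineshapeFunction:
    """Complex g(t) on a uniform time grid (fs), with its provenance."""

    t: np.ndarray
    g: np.ndarray
    temperature: float
    source: SpectralDensity

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def lineshape_g(
    sd: SpectralDensity,
    temperature: float,
    t: np.ndarray,
    n_omega: int = 3000,
    omega_max: float | None = None,
) -> LineshapeFunction:
    """Second-order cumulant lineshape function g(t) by frequency quadrature.

    The time grid must be uniform from 0 and fine enough to resolve the
    highest bath frequency (Nyquist); otherwise the g(t) sampled here would
    alias when Fourier transformed into a spectrum.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    t = np.asarray(t, dtype=float)
    if t.size < 2 or t[0] != 0.0 or np.ptp(np.diff(t)) > 1e-9:
        raise ValueError("t must be a uniform grid starting at 0 (fs)")
    dt = t[1] - t[0]
    dt_required = np.pi / (TWO_PI_C * sd.max_frequency)
    if dt > dt_required:
        raise ValueError(
            f"time step {dt:.3f} fs aliases the bath (max frequency "
            f"{sd.max_frequency:.0f} cm^-1); need dt <= {dt_required:.3f} fs"
        )

    if sd.total_reorganization == 0:
        g = np.zeros(t.size, dtype=complex)
        return LineshapeFunction(t=t, g=g, temperature=temperature, source=sd)

    if omega_max is None:
        # the Drude tail decays only as 1/omega^2, so it needs a long grid
        omega_max = max(6.0 * sd.max_frequency, 60.0 * sd.omega_c)
    w = np.linspace(omega_max / n_omega, omega_max, n_omega)
    j = evaluate_spectral_density(sd, w)
    kt = KB_CM * temperature
    coth = 1.0 / np.tanh(w / (2.0 * kt))
    pref = j / w**2

    theta = np.outer(t * TWO_PI_C, w)  # phase in radians, (Nt, Nw)
    dw = w[1] - w[0]
    weights = np.full(w.size, dw)
    weights[0] = weights[-1] = 0.5 * dw
    re = ((1.0 - np.cos(theta)) @ (pref * coth * weights)) / np.pi
    # the linear term -lambda*t of Im g is taken analytically: its quadrature
    # converges slowly (Drude tail), while the sin transform converges fast
    im = (np.sin(theta) @ (pref * weights)) / np.pi
    im -= sd.total_reorganization * t * TWO_PI_C
    return LineshapeFunction(t=t, g=re + 1j * im, temperature=temperature, source=sd)


def _site_g_matrix(
    states: Sequence[ExcitonState],
    g: LineshapeFunction | Sequence[LineshapeFunction],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state g_k(t) = sum_i c_ki^4 g_i(t); returns (t, g_k matrix)."""
    if isinstance(g, LineshapeFunction):
        t = g.t
        gk = np.array([s.site_participation for s in states])[:, None] * g.g[None, :]
    else:
        gs = list(g)
        if len(gs) != states[0].n_sites:
            raise ValueError("need one lineshape function per site")
        t = gs[0].t
        for gi in gs[1:]:
            if gi.t.shape != t.shape or np.max(np.abs(gi.t - t)) > 1e-9:
                raise ValueError("site lineshape functions must share the time grid")
        gmat = np.array([gi.g for gi in gs])  # (N_p, Nt)
        c4 = np.array([s.site_coefficients**4 for s in states])  # (Nk, N_p)
        gk = c4 @ gmat
    return t, gk


def _state_spectrum_matrix(
    states: Sequence[ExcitonState],
    g: LineshapeFunction | Sequence[LineshapeFunction],
    lifetimes: np.ndarray | None,
    omega: np.ndarray,
) -> np.ndarray:
    """Per-state normalized lineshapes I_k(w) via zero-padded FFT of the
    dephasing function, with trapezoidal end-correction, interpolated onto
    the requested frequency grid.

    The transform runs in a rotating frame at the mean state energy, so the
    Nyquist condition applies to detunings within the exciton band, not to
    the absolute transition energies.
    """
    t, gk = _site_g_matrix(states, g)
    dt = float(t[1] - t[0])
    if dt <= 0:
        raise ValueError("non-positive time step")
    omega = np.asarray(omega, dtype=float)
    energies = np.array([s.energy for s in states])
    n_fft = 1
    while n_fft < 8 * t.size:
        n_fft *= 2
    # snap the frame reference to the FFT bin grid so a state's sampled
    # lineshape is identical whichever set of states it is computed with
    bin_width = 2.0 * np.pi / (n_fft * dt * TWO_PI_C)
    omega_ref = bin_width * round(float(energies.mean()) / bin_width)
    nyquist = np.pi / (TWO_PI_C * dt)
    max_detuning = max(
        abs(omega.max() - omega_ref),
        abs(omega.min() - omega_ref),
        np.max(np.abs(energies - omega_ref)),
    )
    if max_detuning >= nyquist:
        required = np.pi / (TWO_PI_C * max_detuning)
        raise ValueError(
            f"time step {dt} fs aliases detunings up to {max_detuning:.0f} cm^-1; "
            f"need dt < {required:.2f} fs"
        )

    # detuning axis of the shifted FFT, ascending, centred on omega_ref
    w_fft = np.fft.fftshift(
        np.fft.fftfreq(n_fft, d=dt * TWO_PI_C / (2.0 * np.pi))
    )
    out = np.zeros((len(states), omega.size))
    t_rad = t * TWO_PI_C
    for k, s in enumerate(states):
        damp = np.exp(-gk[k] - 1j * (energies[k] - omega_ref) * t_rad)
        if lifetimes is not None and np.isfinite(lifetimes[k]):
            damp = damp * np.exp(-t / (2.0 * lifetimes[k]))
        f = damp.copy()
        f[0] *= 0.5
        f[-1] *= 0.5
        spec = (dt * TWO_PI_C) * n_fft * np.fft.ifft(f, n=n_fft)
        out[k] = np.interp(omega - omega_ref, w_fft, np.fft.fftshift(spec.real))
    return out


def _check_coverage(states: Sequence[ExcitonState], omega: np.ndarray) -> None:
    margin = 500.0  # ~5 FWHM of a typical B850 line
    weights = np.array(
        [
            max(s.dipole_strength or 0.0, abs(s.rotational_strength or 0.0))
            for s in states
        ]
    )
    cutoff = 0.01 * weights.max() if weights.size else 0.0
    bright = [s.energy for s, w in zip(states, weights) if w > cutoff]
    if bright and (
        min(bright) - margin < omega.min() or max(bright) + margin > omega.max()
    ):
        warnings.warn(
            "frequency grid may not cover all bright state energies +- 5 FWHM",
            stacklevel=3,
        )


def homogeneous_absorption(
    states: Sequence[ExcitonState],
    g: LineshapeFunction | Sequence[LineshapeFunction],
    omega: np.ndarray,
    lifetimes: np.ndarray | None = None,
) -> np.ndarray:
    """Homogeneous absorption spectrum A(w) on the given grid (cm^-1).

    A(w) ~ w Sum_k |mu_k|^2 I_k(w); states must carry dipole strengths.
    ``lifetimes`` are per-state tau_k in fs (inf or None disables lifetime
    broadening).
    """
    weights = np.array([s.dipole_strength for s in states], dtype=float)
    if np.any(np.isnan(weights)):
        raise ValueError("states must carry dipole strengths (run state_dipoles)")
    omega = np.asarray(omega, dtype=float)
    _check_coverage(states, omega)
    lines = _state_spectrum_matrix(states, g, lifetimes, omega)
    return omega * (weights @ lines)


def homogeneous_cd(
    states: Sequence[ExcitonState],
    g: LineshapeFunction | Sequence[LineshapeFunction],
    omega: np.ndarray,
    lifetimes: np.ndarray | None = None,
) -> np.ndarray:
    """Homogeneous CD spectrum: signed rotational strengths as line weights."""
    weights = np.array([s.rotational_strength for s in states], dtype=float)
    if np.any(np.isnan(weights)):
        raise ValueError("states must carry rotational strengths")
    omega = np.asarray(omega, dtype=float)
    if np.all(weights == 0):
        return np.zeros(omega.size)
    _check_coverage(states, omega)
    lines = _state_spectrum_matrix(states, g, lifetimes, omega)
    return omega * (weights @ lines)


def redfield_lifetimes(
    states: Sequence[ExcitonState],
    sd: SpectralDensity,
    temperature: float,
) -> np.ndarray:
    """Exciton lifetimes tau_k (fs) from secular Redfield population rates.

    Downhill rate k->l weighted by the spatial overlap sum_i c_ki^2 c_li^2
    and the bath correlation 2 J(|D|)(n(|D|)+1); uphill rates carry the
    detailed-balance factor n(|D|).
    """
    kt = KB_CM * temperature
    n_states = len(states)
    c2 = np.array([s.site_coefficients**2 for s in states])
    overlap = c2 @ c2.T
    energies = np.array([s.energy for s in states])
    rates = np.zeros(n_states)
    for k in range(n_states):
        total = 0.0
        for l in range(n_states):
            if l == k:
                continue
            delta = energies[k] - energies[l]
            if abs(delta) < 1e-9:
                continue
            jw = float(evaluate_spectral_density(sd, np.array([abs(delta)]))[0])
            n_occ = 1.0 / np.expm1(abs(delta) / kt)
            corr = 2.0 * jw * (n_occ + 1.0 if delta > 0 else n_occ)
            total += overlap[k, l] * corr
        rates[k] = total * TWO_PI_C  # cm^-1 -> rad/fs
    with np.errstate(divide="ignore"):
        return np.where(rates > 0, 1.0 / rates, np.inf)


def fwhm(omega: np.ndarray, intensity: np.ndarray) -> float:
    """Full width at half maximum of a single-peaked spectrum by linear
    interpolation of the half-maximum crossings."""
    y = np.asarray(intensity, dtype=float)
    x = np.asarray(omega, dtype=float)
    i_max = int(np.argmax(y))
    half = y[i_max] / 2.0
    left = np.nonzero(y[:i_max] < half)[0]
    right = np.nonzero(y[i_max:] < half)[0]
    if left.size == 0 or right.size == 0:
        raise ValueError("peak is not resolved within the grid")
    i0 = left[-1]
    x_left = np.interp(half, [y[i0], y[i0 + 1]], [x[i0], x[i0 + 1]])
    i1 = i_max + right[0]
    x_right = np.interp(half, [y[i1], y[i1 - 1]], [x[i1], x[i1 - 1]])
    return float(x_right - x_left)
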