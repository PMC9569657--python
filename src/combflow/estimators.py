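"""Time-series and scaling estimators.

Covers the relaxation-time fit of the end-to-end autocorrelation
C(t) = C0 exp(-t/tau_eq), the Weissenberg number Wi = gamma_dot * tau_eq, the
periodic tumbling fit f(t) = A cos(omega t + phi) + B of the backbone
orientation cosine, power-law exponent fits, and the intrinsic viscosity
assembled from the polymer's steady-state shear stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .box import ShearBox
from .errors import FitError
from .model import CombTopology, ModelParams, pairwise_terms


# ---------------------------------------------------------------------------
# Autocorrelation and relaxation time
# ---------------------------------------------------------------------------

def autocorrelation(series: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Normalized vector autocorrelation C(t) = <R(t).R(0)> / <R.R>.

    ``series`` has shape (T, 3) for a single vector or (T, n, 3) for n vectors
    (e.g. all arms); averaging runs over time origins and over vectors.
    C(0) = 1 by construction.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    T = x.shape[0]
    if T < 8:
        raise FitError("autocorrelation: series too short")
    if max_lag is None:
        max_lag = T // 2
    # FFT over time for each vector component
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    f = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft((f * np.conj(f)).real, n=nfft, axis=0)[:max_lag]
    acf = acf.sum(axis=(1, 2))  # sum components and vectors
    norm = T - np.arange(max_lag)  # number of origins per lag
    acf = acf / norm
    return acf / acf[0]


@dataclass
class RelaxationFit:
    """Exponential-decay fit of a normalized correlation function."""

    C0: float
    tau_eq: float
    stderr: float
    window: tuple[int, int]
    residual_rms: float


def fit_relaxation(
    t: np.ndarray, C: np.ndarray, floor: float = 0.05
) -> RelaxationFit:
    """Least-squares fit of C0 exp(-t/tau) on the window where C > ``floor``.

    The correlation must decay below 1/e inside the window, otherwise the
    series is flagged as non-decaying.
    """
    t = np.asarray(t, dtype=float)
    C = np.asarray(C, dtype=float)
    end = int(np.argmax(C <= floor)) if np.any(C <= floor) else len(C)
    w = slice(0, max(end, 3))
    if np.min(C[w]) > np.exp(-1.0):
        raise FitError("fit_relaxation: correlation does not decay below 1/e")
    # log-linear start values, then proper nonlinear least squares
    pos = C[w] > 0
    slope, intercept = np.polyfit(t[w][pos], np.log(C[w][pos]), 1)
    if slope >= 0:
        raise FitError("fit_relaxation: correlation is not decaying")
    p0 = (np.exp(intercept), -1.0 / slope)
    popt, pcov = optimize.curve_fit(
        lambda tt, c0, tau: c0 * np.exp(-tt / tau), t[w], C[w], p0=p0, maxfev=10000
    )
    resid = C[w] - popt[0] * np.exp(-t[w] / popt[1])
    return RelaxationFit(
        C0=float(popt[0]),
        tau_eq=float(popt[1]),
        stderr=float(np.sqrt(pcov[1, 1])),
        window=(0, int(w.stop)),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def weissenberg(gamma_dot: float, tau_eq: float) -> float:
    """Wi = gamma_dot * tau_eq."""
    if tau_eq <= 0:
        raise FitError("weissenberg: tau_eq must be positive")
    return float(gamma_dot * tau_eq)


# ---------------------------------------------------------------------------
# Tumbling
# ---------------------------------------------------------------------------

@dataclass
class TumblingFit:
    """Fit of f(t) = A cos(omega t + phi) + B to an orientation series."""

    A: float
    omega: float
    phi: float
    B: float
    residual_rms: float
    converged: bool

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega


def fit_tumbling(
    t: np.ndarray, cos_theta: np.ndarray, peak_snr: float = 6.0
) -> TumblingFit:
    """Nonlinear least squares for the periodic orientation fit.

    omega is initialized at the dominant discrete-Fourier peak of the
    mean-subtracted series (random restarts would not be reproducible) and
    constrained positive. If no spectral peak rises ``peak_snr`` times above
    the median spectral amplitude, the fit is flagged unconverged rather than
    raising.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(cos_theta, dtype=float)
    if len(t) < 8 or len(t) != len(y):
        raise FitError("fit_tumbling: need a matching series of >= 8 samples")
    dt = t[1] - t[0]
    yc = y - y.mean()
    spec = np.abs(np.fft.rfft(yc))
    freqs = np.fft.rfftfreq(len(y), d=dt)
    k = 1 + int(np.argmax(spec[1:]))
    noise = float(np.median(spec[1:])) + 1e-300
    bad = spec[k] < peak_snr * noise
    omega0 = 2.0 * np.pi * freqs[k]
    A0 = 2.0 * spec[k] / len(y)
    phi0 = float(np.angle(np.fft.rfft(yc)[k]))
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, A, om, ph, B: A * np.cos(om * tt + ph) + B,
            t,
            y,
            p0=(A0, omega0, phi0, y.mean()),
            bounds=([0.0, 1e-12, -2 * np.pi, -2.0], [np.inf, np.pi / dt, 2 * np.pi, 2.0]),
            maxfev=10000,
            xtol=1e-12,
        )
        A, omega, phi, B = (float(v) for v in popt)
        resid = y - (A * np.cos(omega * t + phi) + B)
        rms = float(np.sqrt(np.mean(resid**2)))
        conv = not bad and omega > 0
    except RuntimeError:
        A, omega, phi, B, rms, conv = A0, omega0, phi0, float(y.mean()), np.inf, False
    return TumblingFit(A=A, omega=omega, phi=phi, B=B, residual_rms=rms, converged=conv)


def tumbling_frequency(fits) -> tuple[float, float]:
    """Ensemble-averaged tumbling frequency over converged fits.

    Returns (mean omega, standard error); raises if no fit converged.
    """
    om = np.array([f.omega for f in fits if f.converged], dtype=float)
    if om.size == 0:
        raise FitError("tumbling_frequency: no converged fits")
    se = float(om.std(ddof=1) / np.sqrt(om.size)) if om.size > 1 else 0.0
    return float(om.mean()), se


def count_zero_crossings(cos_theta: np.ndarray) -> int:
    """Sign changes of cos(theta_back): two per full tumbling cycle.
    Cross-check for the fitted tumbling frequency."""
    y = np.asarray(cos_theta, dtype=float)
    s = np.sign(y[y != 0])
    return int(np.sum(s[1:] != s[:-1]))


# ---------------------------------------------------------------------------
# Power laws
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    prefactor: float
    exponent: float
    stderr: float


def powerlaw_fit(x, y) -> PowerLawFit:
    """Least-squares line in log-log space; the exponent is the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise FitError("powerlaw_fit: need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise FitError("powerlaw_fit: all data must be positive")
    res = stats.linregress(np.log(x), np.log(y))
    return PowerLawFit(
        prefactor=float(np.exp(res.intercept)),
        exponent=float(res.slope),
        stderr=float(res.stderr),
    )


# ---------------------------------------------------------------------------
# Intrinsic viscosity
# ---------------------------------------------------------------------------

def shear_virial_stress(
    positions: np.ndarray,
    topology: CombTopology,
    params: ModelParams,
    box: ShearBox | None,
    volume: float,
) -> float:
    """Kramers virial shear stress of the chain,
    sigma_xz = -(1/V) sum_pairs F_x r_z (F on i from j, r = r_i - r_j)."""
    if len(positions) < 2:
        return 0.0
    _, _, rij, fij = pairwise_terms(positions, topology, params, box)
    return float(-np.sum(fij[:, 0] * rij[:, 2]) / volume)


@dataclass
class ViscosityEstimate:
    """Intrinsic viscosity from steady-state dissipation.

    At steady state the rate of energy dissipation per unit volume that the
    polymer adds to the flow (flow-perturbation plus rotational-friction
    channels together) balances gamma_dot * sigma_xz with sigma_xz the
    polymer's virial shear stress; the two channels cannot be split at this
    level.
    """

    w_dot: float
    eta0: float
    concentration: float
    gamma_dot: float
    intrinsic_viscosity: float


def intrinsic_viscosity(
    sigma_xz_series,
    volume: float,
    n_beads: int,
    eta0: float,
    gamma_dot: float,
) -> ViscosityEstimate:
    """[eta] = (w1 + w2) / (eta0 gamma_dot^2 c) with the dissipation rate per
    unit volume w1 + w2 = gamma_dot * <sigma_xz> and the bead concentration
    c = N/V, giving [eta] in sigma^3 per bead."""
    if gamma_dot == 0:
        raise FitError("intrinsic_viscosity: undefined at gamma_dot = 0")
    sig = float(np.mean(np.asarray(sigma_xz_series, dtype=float)))
    w_dot = gamma_dot * sig
    c = n_beads / volume
    return ViscosityEstimate(
        w_dot=w_dot,
        eta0=eta0,
        concentration=c,
        gamma_dot=gamma_dot,
        intrinsic_viscosity=w_dot / (eta0 * gamma_dot**2 * c),
    )
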