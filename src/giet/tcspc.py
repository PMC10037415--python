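"""TCSPC decay modelling, bunching, and biexponential maximum-likelihood fits.

A measured decay histogram is modelled as two exponential decays convolved
with a Gaussian instrument response function (IRF) plus a constant
background, integrated bin-wise over a uniform time grid.  Fits maximize
the Poisson likelihood of the observed counts — correct for the low-count
tail bins where least squares is biased.  Photon streams are split into
consecutive bunches of a fixed photon count (the study design: bunches of
10^6 photons) and each bunch is fitted independently; the spread of the
per-bunch results is the measurement error estimate.

Lifetime labelling convention: ``tau_short`` is the bottom-leaflet
component (closer to the graphene, more strongly quenched) and
``tau_long`` the top-leaflet component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr
from scipy.stats import norm

__all__ = [
    "DecayHistogram",
    "IRFModel",
    "BiexpFit",
    "default_bin_edges",
    "emg_cdf",
    "decay_model",
    "fit_biexponential",
    "bunch_photons",
    "poisson_deviance",
]

#: default TCSPC window (ns) and bin width (ns): 50 ns with 16 ps bins
WINDOW_NS = 50.0
BIN_NS = 0.016


def default_bin_edges(window_ns: float = WINDOW_NS, bin_ns: float = BIN_NS) -> np.ndarray:
    n_bins = int(round(window_ns / bin_ns))
    return np.linspace(0.0, n_bins * bin_ns, n_bins + 1)


@dataclass(frozen=True)
class IRFModel:
    """Gaussian instrument response: rms width sigma (ns) and arrival shift (ns).

    ``sigma = 0`` is the idealized delta-IRF limit.
    """

    sigma_ns: float = 0.1
    shift_ns: float = 2.0

    def __post_init__(self):
        if self.sigma_ns < 0:
            raise ValueError("IRF sigma must be >= 0")


@dataclass(frozen=True)
class DecayHistogram:
    """Binned photon micro-times on a uniform grid.

    Counts are integers for measured data but may be fractional expected
    counts when validating the decay model against noise-free expectations.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        if edges.ndim != 1 or len(edges) < 2 or counts.shape != (len(edges) - 1,):
            raise ValueError("need bin_edges (n+1,) and counts (n,)")
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bin edges must be uniform and strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts.astype(float))

    @property
    def total_photons(self) -> int:
        return int(round(float(self.counts.sum())))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_times(cls, times_ns, bin_edges: np.ndarray | None = None) -> "DecayHistogram":
        edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, float)
        counts, _ = np.histogram(np.asarray(times_ns, dtype=float), bins=edges)
        return cls(edges, counts)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.bin_centers, self.counts])
        np.savetxt(path, arr, delimiter=",", header="time_ns,counts",
                   comments="", fmt=["%.6f", "%.8g"])

    @classmethod
    def from_csv(cls, path) -> "DecayHistogram":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        centers = data[:, 0]
        width = centers[1] - centers[0]
        edges = np.concatenate([centers - 0.5 * width, [centers[-1] + 0.5 * width]])
        return cls(edges, data[:, 1])


@dataclass(frozen=True)
class BiexpFit:
    """Biexponential fit result; lifetimes relabeled so tau_short <= tau_long."""

    tau_short_ns: float
    tau_long_ns: float
    amp_short: float
    amp_long: float
    background_per_bin: float
    loglik: float
    cov: np.ndarray | None
    converged: bool
    degenerate: bool = False


def emg_cdf(t, tau: float, sigma: float, shift: float = 0.0):
    """CDF of an exponential decay (lifetime tau) convolved with a Gaussian IRF.

    Exponentially-modified-Gaussian distribution function, evaluated in a
    numerically stable form via ``log_ndtr``; reduces to the truncated
    exponential CDF for ``sigma = 0``.
    """
    if tau <= 0:
        raise ValueError("lifetime must be > 0")
    x = np.asarray(t, dtype=float) - shift
    lam = 1.0 / tau
    if sigma == 0.0:
        return np.where(x > 0, -np.expm1(-lam * np.maximum(x, 0.0)), 0.0)
    u = x / sigma
    # Phi(u) - exp(lam^2 sigma^2/2 - lam x + log Phi(u - lam sigma))
    return norm.cdf(u) - np.exp(0.5 * (lam * sigma) ** 2 - lam * x
                                + log_ndtr(u - lam * sigma))


def decay_model(tau_short: float, tau_long: float, amp_short: float,
                amp_long: float, background_per_bin: float,
                irf: IRFModel, bin_edges: np.ndarray) -> np.ndarray:
    """Expected counts per bin of the IRF-convolved biexponential plus background.

    Amplitudes are expected total photon counts of each component over the
    whole real line; the in-window total is smaller only by window
    truncation.  Exact bin integrals (differences of the convolved CDF).
    """
    if tau_short <= 0 or tau_long <= 0:
        raise ValueError("lifetimes must be > 0")
    if amp_short < 0 or amp_long < 0 or background_per_bin < 0:
        raise ValueError("amplitudes and background must be >= 0")
    edges = np.asarray(bin_edges, dtype=float)
    mu = np.full(len(edges) - 1, float(background_per_bin))
    for amp, tau in ((amp_short, tau_short), (amp_long, tau_long)):
        if amp > 0:
            cdf = emg_cdf(edges, tau, irf.sigma_ns, irf.shift_ns)
            mu = mu + amp * np.diff(cdf)
    return mu


def poisson_deviance(counts: np.ndarray, mu: np.ndarray) -> float:
    """Poisson deviance 2*sum[mu - c + c*log(c/mu)] (c log c -> 0 at c = 0)."""
    c = np.asarray(counts, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(c > 0, c * np.log(c / mu), 0.0)
    return float(2.0 * np.sum(mu - c + term))


def _emg_cdf_terms(edges, tau, sigma, shift):
    """EMG CDF at the bin edges plus its derivative with respect to tau."""
    x = edges - shift
    lam = 1.0 / tau
    if sigma == 0.0:
        T = np.where(x > 0, np.exp(-lam * np.maximum(x, 0.0)), 0.0)
        cdf = np.where(x > 0, 1.0 - T, 0.0)
        dcdf_dlam = np.where(x > 0, x, 0.0) * T
    else:
        u = x / sigma
        T = np.exp(0.5 * (lam * sigma) ** 2 - lam * x + log_ndtr(u - lam * sigma))
        cdf = norm.cdf(u) - T
        # d/dlam of T is (lam*sigma^2 - x)*T - sigma*phi(u)
        dcdf_dlam = -((lam * sigma ** 2 - x) * T - sigma * norm.pdf(u))
    return cdf, dcdf_dlam * (-lam ** 2)  # chain rule: dlam/dtau = -1/tau^2


def _neg_loglik_grad(x, counts, irf, edges):
    """Poisson NLL (up to a counts-only constant) and its log-parameter gradient."""
    tau_s, tau_l, a_s, a_l, b = np.exp(x)
    cdf_s, dcdf_s = _emg_cdf_terms(edges, tau_s, irf.sigma_ns, irf.shift_ns)
    cdf_l, dcdf_l = _emg_cdf_terms(edges, tau_l, irf.sigma_ns, irf.shift_ns)
    mu = b + a_s * np.diff(cdf_s) + a_l * np.diff(cdf_l)
    mu = np.maximum(mu, 1e-300)
    resid = 1.0 - counts / mu
    grad = np.array([
        np.sum(resid * a_s * np.diff(dcdf_s)) * tau_s,
        np.sum(resid * a_l * np.diff(dcdf_l)) * tau_l,
        np.sum(resid * np.diff(cdf_s)) * a_s,
        np.sum(resid * np.diff(cdf_l)) * a_l,
        np.sum(resid) * b,
    ])
    return float(np.sum(mu - counts * np.log(mu))), grad


def _initial_guess(hist: DecayHistogram, irf: IRFModel):
    """Log-linear tail fit for the long component, early-time residual for the short."""
    t = hist.bin_centers
    c = hist.counts.astype(float)
    total = c.sum()
    # background from pre-rise bins when available, else from the last bins
    pre = t < irf.shift_ns - 5.0 * irf.sigma_ns - 0.05
    bg = c[pre].mean() if pre.sum() >= 10 else max(np.median(c[-max(len(c) // 50, 5):]), 0.1)
    bg = max(bg, 1e-3)
    peak = int(np.argmax(c))
    t0 = t[peak]
    signal = np.maximum(c - bg, 1e-12)
    # tail window: from a few ns past the peak to where counts sink into background
    tail = (t > t0 + 2.0) & (c > bg + 3.0 * np.sqrt(bg + 1.0))
    if tail.sum() >= 10:
        slope, _ = np.polyfit(t[tail], np.log(signal[tail]), 1, w=np.sqrt(c[tail]))
        tau_l = float(np.clip(-1.0 / slope if slope < 0 else 3.0, 0.2, 20.0))
    else:
        tau_l = 3.0
    tau_s = tau_l / 2.5
    amp = max(total - bg * len(c), 10.0)
    return np.log([tau_s, tau_l, 0.5 * amp, 0.5 * amp, bg])


def fit_biexponential(hist: DecayHistogram, irf: IRFModel,
                      init: np.ndarray | None = None) -> BiexpFit:
    """Poisson maximum-likelihood biexponential fit of one decay histogram.

    ``init`` optionally overrides the automatic initial guess with
    ``[tau_short, tau_long, amp_short, amp_long, background_per_bin]``.
    Output lifetimes are relabeled so that ``tau_short <= tau_long``; fits
    whose lifetimes collapse within 1% are flagged ``degenerate``
    (effectively mono-exponential).
    """
    if hist.total_photons < 10_000:
        warnings.warn(f"only {hist.total_photons} photons in histogram; "
                      "biexponential fits may be unstable", stacklevel=2)
    x0 = np.log(np.asarray(init, float)) if init is not None else _initial_guess(hist, irf)
    counts = hist.counts.astype(float)
    edges = hist.bin_edges
    bounds = [(np.log(1e-3), np.log(1e3))] * 2 + \
             [(np.log(1e-6), np.log(1e12))] * 2 + [(np.log(1e-9), np.log(1e9))]
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    res = minimize(_neg_loglik_grad, x0, args=(counts, irf, edges), jac=True,
                   method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-9})
    tau_s, tau_l, a_s, a_l, b = np.exp(res.x)
    if tau_s > tau_l:
        tau_s, tau_l = tau_l, tau_s
        a_s, a_l = a_l, a_s
    # covariance proxy: inverse Hessian of the NLL in log-parameter space
    cov = None
    if hasattr(res, "hess_inv"):
        try:
            cov = res.hess_inv.todense()
        except AttributeError:
            cov = np.asarray(res.hess_inv)
    degenerate = abs(tau_l - tau_s) < 0.01 * tau_l
    return BiexpFit(tau_short_ns=float(tau_s), tau_long_ns=float(tau_l),
                    amp_short=float(a_s), amp_long=float(a_l),
                    background_per_bin=float(b), loglik=-float(res.fun),
                    cov=cov, converged=bool(res.success), degenerate=degenerate)


def bunch_photons(times_ns, bunch_size: int,
                  bin_edges: np.ndarray | None = None) -> list[DecayHistogram]:
    """Split a photon micro-time stream into consecutive fixed-size bunches.

    Bunches are non-overlapping and keep arrival order; the trailing
    remainder of fewer than ``bunch_size`` photons is discarded.
    """
    if bunch_size < 1:
        raise ValueError("bunch_size must be >= 1")
    times = np.asarray(times_ns, dtype=float)
    n_bunches = len(times) // bunch_size
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, float)
    return [DecayHistogram.from_times(times[i * bunch_size:(i + 1) * bunch_size], edges)
            for i in range(n_bunches)]
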