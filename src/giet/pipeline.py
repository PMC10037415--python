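"""End-to-end analysis: per-bunch fits, thickness conversion, aggregation, trends.

One measurement is a list of per-bunch decay histograms.  Each bunch is
fitted with the biexponential model, the lifetime pair is converted into
leaflet heights and thickness by the iterative calibration inversion, and
the per-bunch thicknesses are aggregated into mean ± sample standard
deviation — the study's error model, where the bunch-to-bunch spread *is*
the measurement uncertainty.  Thickness-vs-cholesterol trends are
summarized with a descriptive least-squares parabola.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ThicknessInverter
from .errors import AnalysisError, LifetimeRangeError
from .optics import Emitter
from .tcspc import DecayHistogram, IRFModel, fit_biexponential

logger = logging.getLogger(__name__)

__all__ = [
    "BunchResult",
    "ThicknessEstimate",
    "TrendFit",
    "analyze_measurement",
    "trend_fit",
    "write_results",
    "read_results",
    "run_panel",
]


@dataclass(frozen=True)
class BunchResult:
    """Per-bunch fit and inversion outcome."""

    tau_short_ns: float
    tau_long_ns: float
    z_bottom_nm: float
    z_top_nm: float
    d_nm: float
    converged: bool
    note: str = ""


@dataclass(frozen=True)
class ThicknessEstimate:
    """Mean ± SD of per-bunch bilayer thickness for one measurement.

    ``sd_d_nm`` is the sample standard deviation (ddof=1) over converged
    bunches only; dropped bunches are counted in ``n_dropped``.
    """

    mean_d_nm: float
    sd_d_nm: float
    n_bunches: int
    per_bunch: tuple[BunchResult, ...]
    n_dropped: int = 0

    @property
    def mean_z_bottom_nm(self) -> float:
        vals = [b.z_bottom_nm for b in self.per_bunch if b.converged]
        return float(np.mean(vals))


def analyze_measurement(histograms: list[DecayHistogram], emitter: Emitter,
                        irf: IRFModel, inverter: ThicknessInverter) -> ThicknessEstimate:
    """Fit every bunch, invert lifetimes to heights, aggregate mean ± SD.

    Bunches whose fit fails, whose lifetimes leave the invertible branch
    of the calibration curves, or whose fixed-point iteration does not
    converge are excluded from the aggregate and counted as dropped
    (clamping them would bias the mean).
    """
    if not histograms:
        raise AnalysisError("no histograms to analyze")
    results: list[BunchResult] = []
    for i, hist in enumerate(histograms):
        fit = fit_biexponential(hist, irf)
        note = ""
        ok = fit.converged and not fit.degenerate
        z_b = z_t = d = np.nan
        if not fit.converged:
            note = "fit did not converge"
        elif fit.degenerate:
            note = "degenerate (mono-exponential) fit"
        else:
            try:
                est = inverter.estimate(fit.tau_short_ns, fit.tau_long_ns)
                z_b, z_t, d = est.z_bottom_nm, est.z_top_nm, est.d_nm
                if not est.converged:
                    ok, note = False, "thickness iteration did not converge"
            except (LifetimeRangeError, ValueError) as exc:
                ok, note = False, f"inversion out of range: {exc}"
        if note:
            logger.warning("bunch %d dropped: %s", i, note)
        else:
            logger.debug("bunch %d: tau=(%.4f, %.4f) ns -> d=%.3f nm",
                         i, fit.tau_short_ns, fit.tau_long_ns, d)
        results.append(BunchResult(fit.tau_short_ns, fit.tau_long_ns,
                                   z_b, z_t, d, ok, note))
    kept = [r.d_nm for r in results if r.converged]
    if not kept:
        notes = "; ".join(f"bunch {i}: {r.note}" for i, r in enumerate(results))
        raise AnalysisError(f"no bunch converged ({notes})")
    mean_d = float(np.mean(kept))
    sd_d = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
    return ThicknessEstimate(mean_d_nm=mean_d, sd_d_nm=sd_d,
                             n_bunches=len(kept), per_bunch=tuple(results),
                             n_dropped=len(results) - len(kept))


@dataclass(frozen=True)
class TrendFit:
    """Descriptive parabola d(x) = c0 + c1*x + c2*x^2 in cholesterol mol %.

    Purely a trend summary — no physical square law is implied.
    """

    c0: float
    c1: float
    c2: float
    residuals: np.ndarray


def trend_fit(points, weighted: bool = False) -> TrendFit:
    """Least-squares parabola through (chol mol %, mean d [, sd d]) points.

    Unweighted by default; ``weighted=True`` applies 1/sd^2 weights (the
    third element of each point).  Requires >= 3 distinct abscissae.
    """
    pts = [tuple(p) for p in points]
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if len(set(x.tolist())) < 3:
        raise ValueError("need at least 3 distinct cholesterol levels")
    w = None
    if weighted:
        sd = np.array([p[2] for p in pts], dtype=float)
        if np.any(sd <= 0):
            raise ValueError("weighted fit requires positive sd for every point")
        w = 1.0 / sd  # polyfit weights multiply residuals, so w = 1/sd gives 1/sd^2
    coeffs = np.polynomial.polynomial.polyfit(x, y, 2, w=w)
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    return TrendFit(c0=float(coeffs[0]), c1=float(coeffs[1]), c2=float(coeffs[2]),
                    residuals=resid)


_RESULT_COLUMNS = ["lipid", "chol_pct", "mean_d_nm", "sd_d_nm", "n_bunches"]


def write_results(estimates: dict[tuple[str, float], ThicknessEstimate], path) -> pd.DataFrame:
    """Write the thickness table, rows ordered by (lipid, cholesterol)."""
    rows = [
        {"lipid": lipid, "chol_pct": chol, "mean_d_nm": est.mean_d_nm,
         "sd_d_nm": est.sd_d_nm, "n_bunches": est.n_bunches}
        for (lipid, chol), est in sorted(estimates.items())
    ]
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def run_panel(designs, emitter: Emitter, irf: IRFModel,
              inverter: ThicknessInverter) -> dict[tuple[str, float], ThicknessEstimate]:
    """Simulate and analyze a list of scenarios; returns keyed estimates."""
    from .synthetic import simulate_measurement
    from .tcspc import bunch_photons

    out = {}
    for design in designs:
        times, truth = simulate_measurement(design, emitter, irf, inverter.spec)
        hists = bunch_photons(times, design.photons_per_bunch)
        out[(design.lipid_label, design.chol_mol_percent)] = analyze_measurement(
            hists, emitter, irf, inverter)
    return out
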