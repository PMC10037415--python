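"""Exception hierarchy for the giet package."""


class GietError(Exception):
    """Base class for all giet-specific errors."""


class DispersionRangeError(GietError, ValueError):
    """A wavelength fell outside the tabulated range of a dispersion/spectrum table."""

    def __init__(self, table_name: str, wavelength_nm: float, lo: float, hi: float):
        self.table_name = table_name
        self.wavelength_nm = wavelength_nm
        super().__init__(
            f"wavelength {wavelength_nm:g} nm outside range "
            f"[{lo:g}, {hi:g}] nm of table {table_name!r}"
        )


class QuadratureError(GietError, ArithmeticError):
    """The wavevector integral did not converge within the refinement limit."""

    def __init__(self, achieved_tol: float, requested_tol: float):
        self.achieved_tol = achieved_tol
        self.requested_tol = requested_tol
        super().__init__(
            f"wavevector quadrature reached relative tolerance {achieved_tol:.3e} "
            f"but {requested_tol:.3e} was requested"
        )


class LifetimeRangeError(GietError, ValueError):
    """A lifetime cannot be inverted on the monotone branch of a calibration curve."""


class AnalysisError(GietError, RuntimeError):
    """A pipeline stage produced no usable result (e.g. zero converged bunches)."""
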