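"""Internal-standard calibration and surrogate calibration.

Targeted analytes are quantified by isotope dilution: the response ratio
``R = analyte area / internal-standard area`` is regressed on the calibrant
concentration with a weighted straight line (1/x^2 by default, the standard
weighting for bioanalytical assays spanning four decades), and unknowns are
back-calculated through the inverse of that line.

Untargeted analytes have no own calibrants in routine runs. Their response is
instead pushed through the calibration curve of a structurally related
*surrogate* (A4 for C19 steroids, P4 for C21 steroids), giving an *apparent*
concentration in surrogate-equivalents. Because electrospray ionization
efficiency differs between compounds, the apparent concentration is biased by
a compound-specific constant; a zero-intercept regression of true on apparent
concentration over a matched calibration series yields that constant — the
*correction factor* — and multiplying apparent concentrations by it restores
absolute concentrations (0.329 for 11-ketoandrostenedione vs A4). The factor
is a valid multiplier because the curves stay linear over the whole range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigError, DataError, MissingInternalStandardError
from .panel import Panel

__all__ = [
    "compute_response",
    "CalibrationModel",
    "CalibrationResult",
    "fit_calibration",
    "back_calculate",
    "CorrectionFactorModel",
    "CorrectionFactor",
    "derive_correction_factor",
    "QuantResult",
    "quantify_targeted",
    "quantify_untargeted",
    "agreement_analysis",
    "quantify_samples",
]

BACKCALC_TOLERANCE = 15.0  # % allowed back-calculation bias per level
BACKCALC_TOLERANCE_LLOQ = 20.0  # % at the lowest level
MAX_FAILING_LEVEL_FRACTION = 0.25

_WEIGHTINGS = ("none", "1/x", "1/x^2")


def compute_response(area: float, is_area: float) -> float:
    """Internal-standard-normalized response ratio, area / IS area."""
    if is_area <= 0:
        raise MissingInternalStandardError(
            "internal-standard area is zero or negative; response undefined"
        )
    if area < 0:
        raise DataError("peak area must be non-negative")
    return area / is_area


def _weights(conc: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(conc)
    if weighting == "1/x":
        return 1.0 / conc
    if weighting == "1/x^2":
        return 1.0 / conc**2
    raise ConfigError(f"weighting must be one of {_WEIGHTINGS}, got {weighting!r}")


@dataclass
class CalibrationResult:
    """Fitted calibration line with per-level back-calculation diagnostics."""

    analyte: str
    slope: float  # response per nmol/L
    intercept: float  # response
    weighting: str
    r_squared: float
    level_concs: list[float]  # distinct nominal levels, ascending (nmol/L)
    level_bias_percent: dict[float, float]  # back-calculated bias per level
    failed_levels: list[float]
    accepted: bool
    valid_range: tuple[float, float]  # [lloq, uloq] nmol/L

    @property
    def lloq(self) -> float:
        return self.valid_range[0]

    @property
    def uloq(self) -> float:
        return self.valid_range[1]

    def predict(self, conc):
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def back_calculate(self, response: float) -> tuple[float, set[str]]:
        """Invert the curve: concentration (nmol/L) plus range flags."""
        if not self.accepted:
            raise CalibrationError(f"{self.analyte}: calibration curve was rejected")
        if self.slope <= 0:
            raise CalibrationError(f"{self.analyte}: non-positive calibration slope")
        conc = (response - self.intercept) / self.slope
        flags: set[str] = set()
        if conc < self.valid_range[0]:
            flags.add("below_lloq")
        elif conc > self.valid_range[1]:
            flags.add("above_uloq")
        return conc, flags

    def summary(self) -> str:
        lines = [
            f"Calibration curve: {self.analyte or '(unnamed)'}",
            f"  model       response = {self.slope:.6g} * conc + {self.intercept:.6g}",
            f"  weighting   {self.weighting}",
            f"  r-squared   {self.r_squared:.6f}",
            f"  levels      {len(self.level_concs)} "
            f"({self.level_concs[0]:.4g} - {self.level_concs[-1]:.4g} nmol/L)",
            f"  range       [{self.valid_range[0]:.4g}, {self.valid_range[1]:.4g}] nmol/L",
            f"  accepted    {self.accepted}",
        ]
        if self.failed_levels:
            lines.append(
                "  failing back-calculation at: "
                + ", ".join(f"{c:.4g}" for c in self.failed_levels)
            )
        return "\n".join(lines)


class CalibrationModel:
    """Weighted straight-line calibration of response on concentration.

    Parameters
    ----------
    concentrations, responses
        Calibrant nominal concentrations (nmol/L) and IS-normalized responses;
        replicate levels are allowed.
    weighting
        ``"none"``, ``"1/x"`` or ``"1/x^2"`` (default), applied per point.
    """

    def __init__(self, concentrations, responses, weighting: str = "1/x^2", analyte: str = ""):
        self.conc = np.asarray(concentrations, dtype=float)
        self.resp = np.asarray(responses, dtype=float)
        if self.conc.shape != self.resp.shape:
            raise DataError("concentrations and responses differ in length")
        if np.any(self.conc <= 0):
            raise DataError("calibrant concentrations must be > 0")
        if np.any(self.resp < 0):
            raise DataError("responses must be non-negative")
        if np.unique(self.conc).size < 5:
            raise CalibrationError("calibration needs >= 5 distinct levels")
        self.weighting = weighting
        self.analyte = analyte

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, analyte: str, weighting: str = "1/x^2"
    ) -> "CalibrationModel":
        """Build from a tidy calibration table (analyte, level_nmol_per_l, area, is_area)."""
        sub = df[df["analyte"] == analyte]
        if sub.empty:
            raise DataError(f"no calibration rows for analyte {analyte!r}")
        responses = [
            compute_response(a, ia) for a, ia in zip(sub["area"], sub["is_area"])
        ]
        return cls(sub["level_nmol_per_l"].to_numpy(), responses, weighting, analyte)

    def fit(self) -> CalibrationResult:
        import statsmodels.api as sm

        w = _weights(self.conc, self.weighting)
        design = sm.add_constant(self.conc)
        res = sm.WLS(self.resp, design, weights=w).fit()
        intercept, slope = float(res.params[0]), float(res.params[1])
        r_squared = float(res.rsquared)

        levels = sorted(np.unique(self.conc))
        bias: dict[float, float] = {}
        failed: list[float] = []
        for i, level in enumerate(levels):
            tol = BACKCALC_TOLERANCE_LLOQ if i == 0 else BACKCALC_TOLERANCE
            if slope > 0:
                back = (self.resp[self.conc == level].mean() - intercept) / slope
                bias[level] = 100.0 * (back - level) / level
            else:
                bias[level] = float("nan")
            if not abs(bias[level]) <= tol:
                failed.append(level)
        accepted = (
            slope > 0 and len(failed) <= MAX_FAILING_LEVEL_FRACTION * len(levels)
        )
        passing = [lv for lv in levels if lv not in failed]
        valid = (min(passing), max(passing)) if passing else (levels[0], levels[-1])
        return CalibrationResult(
            analyte=self.analyte,
            slope=slope,
            intercept=intercept,
            weighting=self.weighting,
            r_squared=r_squared,
            level_concs=[float(lv) for lv in levels],
            level_bias_percent=bias,
            failed_levels=[float(lv) for lv in failed],
            accepted=bool(accepted),
            valid_range=(float(valid[0]), float(valid[1])),
        )


def fit_calibration(levels, responses, weighting: str = "1/x^2", analyte: str = "") -> CalibrationResult:
    """Fit a weighted calibration line (functional form of :class:`CalibrationModel`)."""
    return CalibrationModel(levels, responses, weighting, analyte).fit()


def back_calculate(curve: CalibrationResult, response: float) -> tuple[float, set[str]]:
    """Concentration (nmol/L) and range flags for a measured response."""
    return curve.back_calculate(response)


@dataclass
class CorrectionFactor:
    """Ionization-efficiency correction factor of an analyte vs its surrogate."""

    analyte: str
    surrogate: str
    value: float  # true conc = value * apparent (surrogate-equivalent) conc
    r_squared: float
    n_levels: int
    per_level: dict[float, float] = field(default_factory=dict)
    constant_within_15pct: bool = True
    verified: bool = True

    def summary(self) -> str:
        spread = (
            100.0 * (max(self.per_level.values()) / min(self.per_level.values()) - 1.0)
            if self.per_level
            else float("nan")
        )
        return "\n".join(
            [
                f"Correction factor: {self.analyte} vs {self.surrogate}",
                f"  value            {self.value:.4g}",
                f"  r-squared        {self.r_squared:.6f}",
                f"  levels           {self.n_levels}",
                f"  per-level spread {spread:.1f}%",
                f"  constant (±15%)  {self.constant_within_15pct}",
            ]
        )


class CorrectionFactorModel:
    """Derive a correction factor from a matched calibration series.

    Each calibrant response of the analyte is back-calculated through the
    surrogate's curve to an apparent concentration; the factor is the
    zero-intercept weighted (1/x^2) regression slope of true concentration on
    apparent concentration, which for that weighting equals the mean of the
    per-level ``true/apparent`` ratios.
    """

    def __init__(
        self,
        concentrations,
        responses,
        surrogate_curve: CalibrationResult,
        analyte: str = "",
    ):
        self.conc = np.asarray(concentrations, dtype=float)
        self.resp = np.asarray(responses, dtype=float)
        if self.conc.shape != self.resp.shape:
            raise DataError("concentrations and responses differ in length")
        if np.unique(self.conc).size < 3:
            raise CalibrationError("correction-factor derivation needs >= 3 levels")
        self.surrogate_curve = surrogate_curve
        self.analyte = analyte

    def fit(self) -> CorrectionFactor:
        curve = self.surrogate_curve
        if curve.slope <= 0:
            raise CalibrationError("surrogate curve has non-positive slope")
        apparent = (self.resp - curve.intercept) / curve.slope
        if np.any(apparent <= 0):
            raise CalibrationError(
                "non-positive apparent concentrations; cannot derive correction factor"
            )
        w = 1.0 / apparent**2
        value = float(np.sum(w * apparent * self.conc) / np.sum(w * apparent**2))
        fitted = value * apparent
        ss_res = float(np.sum(w * (self.conc - fitted) ** 2))
        ss_tot = float(np.sum(w * (self.conc - np.average(self.conc, weights=w)) ** 2))
        r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

        per_level: dict[float, float] = {}
        for level in sorted(np.unique(self.conc)):
            mask = self.conc == level
            per_level[float(level)] = float(np.mean(level / apparent[mask]))
        constant = all(
            abs(v / value - 1.0) <= 0.15 for v in per_level.values()
        )
        return CorrectionFactor(
            analyte=self.analyte,
            surrogate=curve.analyte,
            value=value,
            r_squared=max(0.0, min(1.0, r_squared)),
            n_levels=len(per_level),
            per_level=per_level,
            constant_within_15pct=constant,
        )


def derive_correction_factor(
    analyte_series, surrogate_curve: CalibrationResult, analyte: str = ""
) -> CorrectionFactor:
    """Functional wrapper: ``analyte_series`` is a sequence of (conc, response) pairs."""
    conc, resp = zip(*analyte_series)
    return CorrectionFactorModel(conc, resp, surrogate_curve, analyte).fit()


@dataclass
class QuantResult:
    """Absolute concentration of one analyte in one sample."""

    sample_id: str
    analyte: str
    concentration: float  # nmol/L
    mode: str  # {"targeted", "untargeted"}
    flags: set[str] = field(default_factory=set)


def quantify_targeted(
    response: float,
    curve: CalibrationResult,
    sample_id: str = "",
    dilution_factor: float = 1.0,
) -> QuantResult:
    """Back-calculate a targeted analyte; declared dilutions are multiplied in
    before the range flags are applied."""
    conc, _ = curve.back_calculate(response)
    conc *= dilution_factor
    flags: set[str] = set()
    if dilution_factor != 1.0:
        flags.add("diluted")
    if conc < curve.valid_range[0]:
        flags.add("below_lloq")
    elif conc > curve.valid_range[1]:
        flags.add("above_uloq")
    return QuantResult(sample_id, curve.analyte, conc, "targeted", flags)


def quantify_untargeted(
    response: float,
    surrogate_curve: CalibrationResult,
    cf: CorrectionFactor,
    sample_id: str = "",
) -> QuantResult:
    """Quantify an untargeted analyte through its surrogate's curve.

    concentration = back_calculate(surrogate curve, response) * correction factor.
    """
    if cf.surrogate != surrogate_curve.analyte:
        raise ConfigError(
            f"correction factor for surrogate {cf.surrogate!r} used with curve "
            f"{surrogate_curve.analyte!r}"
        )
    apparent, flags = surrogate_curve.back_calculate(response)
    conc = apparent * cf.value
    if not cf.verified:
        flags = flags | {"unverified_factor"}
    return QuantResult(sample_id, cf.analyte, conc, "untargeted", set(flags))


@dataclass
class AgreementResult:
    """Targeted-vs-untargeted agreement regression for one analyte."""

    slope: float
    offset: float
    r: float
    offset_percent_of_median: float
    n: int


def agreement_analysis(targeted_concs, untargeted_concs) -> AgreementResult:
    """OLS of untargeted on targeted concentrations.

    The slope measures the constant relative bias introduced by surrogate
    calibration; the offset is also reported as a percentage of the median
    targeted concentration.
    """
    from scipy import stats

    x = np.asarray(targeted_concs, dtype=float)
    y = np.asarray(untargeted_concs, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("agreement analysis needs >= 3 paired values")
    if np.ptp(x) == 0:
        raise DataError("targeted concentrations have zero variance")
    res = stats.linregress(x, y)
    median = float(np.median(x))
    return AgreementResult(
        slope=float(res.slope),
        offset=float(res.intercept),
        r=float(res.rvalue),
        offset_percent_of_median=100.0 * float(res.intercept) / median if median else float("nan"),
        n=int(x.size),
    )


def quantify_samples(
    panel: Panel,
    calibration_df: pd.DataFrame,
    areas_df: pd.DataFrame,
    weighting: str | None = None,
) -> pd.DataFrame:
    """Full quantitation of an area table against a calibration table.

    Fits one curve per targeted analyte from ``calibration_df`` (tidy:
    analyte, level_nmol_per_l, area, is_area), then quantifies every row of
    ``areas_df`` (sample_id, analyte, area, is_area) — targeted analytes
    directly, untargeted analytes through their surrogate curve and the
    panel's correction factor. Returns a tidy table with columns
    sample_id, analyte, conc_nmol_per_l, mode, flags (semicolon-joined).
    """
    weighting = weighting or panel.weighting
    curves: dict[str, CalibrationResult] = {}
    for s in panel.targeted:
        if (calibration_df["analyte"] == s.abbreviation).any():
            curves[s.abbreviation] = CalibrationModel.from_dataframe(
                calibration_df, s.abbreviation, weighting
            ).fit()

    rows = []
    for rec in areas_df.itertuples(index=False):
        analyte = panel.steroid(rec.analyte)
        upstream = set()
        if getattr(rec, "flags", "") and isinstance(rec.flags, str):
            upstream = set(rec.flags.split(";")) - {""}
        try:
            response = compute_response(rec.area, rec.is_area)
        except MissingInternalStandardError:
            rows.append((rec.sample_id, rec.analyte, np.nan, analyte.quant_mode,
                         ";".join(sorted(upstream | {"missing_is"}))))
            continue
        if "not_detected" in upstream:
            rows.append((rec.sample_id, rec.analyte, np.nan, analyte.quant_mode,
                         ";".join(sorted(upstream))))
            continue
        if analyte.targeted:
            if analyte.abbreviation not in curves:
                raise CalibrationError(f"no calibration data for {analyte.abbreviation}")
            q = quantify_targeted(response, curves[analyte.abbreviation], rec.sample_id)
        else:
            surrogate = curves.get(analyte.surrogate_ref)
            if surrogate is None:
                raise CalibrationError(
                    f"no calibration data for surrogate {analyte.surrogate_ref!r}"
                )
            cf = CorrectionFactor(
                analyte=analyte.abbreviation,
                surrogate=analyte.surrogate_ref,
                value=analyte.correction_factor,
                r_squared=float("nan"),
                n_levels=0,
                verified=analyte.factor_verified,
            )
            q = quantify_untargeted(response, surrogate, cf, rec.sample_id)
        rows.append(
            (q.sample_id, q.analyte, q.concentration, q.mode, ";".join(sorted(q.flags | upstream)))
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "analyte", "conc_nmol_per_l", "mode", "flags"]
    )
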