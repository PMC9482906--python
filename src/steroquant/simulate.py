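"""Synthetic-data generators with known ground truth.

Every pipeline stage can be exercised without instrument data: the generators
produce calibration series, QC replicate sets, a phase-structured paired
serum/peritoneal-fluid cohort, and centroided full-scan data, each accompanied
by its ground truth. All generators are pure functions of (config, seed).

What is emulated (defaults):

* 12-point calibration over 0.1-2000 nmol/L (> 4 decades), multiplicative
  log-normal measurement noise (CV 5%), constant internal-standard areas.
* Untargeted analyte responses generated through the panel's correction-factor
  table: an analyte with factor ``f`` relative to its surrogate ionizes
  ``1/f`` times as efficiently, so its true response slope is
  ``surrogate slope / f``.
* QC sets: 6 replicates x 4 levels x 3 days.
* Cohort: 11/16/11/9 subjects (menstruation / proliferative / secretory /
  dienogest), paired serum + PF rows per subject, log-normal between-subject
  variation (GSD 1.6). Progestogens are enriched ~2.5x in PF, corticoids and
  androgens ~2x in serum; the secretory phase multiplies P4 and its direct
  metabolites by 10; dienogest suppresses progestogens.
* Scans: Gaussian elution peaks (sigma 0.02 min) at each analyte's (m/z, RT)
  with centroid m/z jitter <= 2 mmu, inside the 5-mmu XIC window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chromatography import ScanSeries
from .errors import ConfigError
from .panel import Panel, SteroidDefinition, assign_internal_standard, default_panel

__all__ = [
    "GeneratorConfig",
    "true_slope",
    "generate_calibration",
    "generate_qc",
    "generate_cohort",
    "generate_scans",
    "DIRECT_P4_METABOLITES",
]

# products one enzymatic step away from progesterone
DIRECT_P4_METABOLITES = (
    "17OHP4", "20aOHP4", "20bOHP4", "5aDHP4", "5bDHP4",
    "6aOHP4", "11aOHP4", "11bOHP4", "16aOHP4",
)

# plausible circulating medians (nmol/L) by steroid class, with per-analyte overrides
_CLASS_MEDIAN = {
    "glucocorticoid": 60.0,
    "mineralocorticoid": 2.0,
    "androgen": 3.0,
    "C11-oxy androgen": 2.0,
    "precursor": 8.0,
    "progestogen": 2.0,
}
_ANALYTE_MEDIAN = {"cortisol": 250.0, "DHEA-S": 2000.0, "aldosterone": 0.35, "P4": 1.5}

_CORTICOID_CLASSES = {"glucocorticoid", "mineralocorticoid"}
_ANDROGEN_CLASSES = {"androgen", "C11-oxy androgen"}


@dataclass
class GeneratorConfig:
    """Study-condition settings shared by all generators."""

    seed: int = 0
    panel: Panel | None = None
    calibration_range: tuple[float, float] = (0.1, 2000.0)  # nmol/L
    n_levels: int = 12
    noise_cv: float = 0.05  # multiplicative measurement noise
    extraction_recovery: float = 0.85
    is_area: float = 5.0e5  # counts*min per internal-standard peak
    base_slope: float = 0.05  # targeted response per nmol/L
    between_subject_gsd: float = 1.6  # geometric SD of biology
    cohort_sizes: dict = field(
        default_factory=lambda: {
            "menstruation": 11, "proliferative": 16, "secretory": 11, "dienogest": 9,
        }
    )
    pf_progestogen_factor: float = 2.5  # progestogens enriched in PF
    serum_corticoid_factor: float = 2.0  # corticoids/androgens enriched in serum
    secretory_p4_factor: float = 10.0  # secretory-phase rise of P4 + direct metabolites
    dienogest_progestogen_factor: float = 0.2  # progestogen suppression under dienogest
    peak_sigma_min: float = 0.02  # chromatographic peak width (minutes)
    scan_interval_min: float = 0.005
    mz_jitter: float = 0.002  # Th, clipped; within the 5-mmu XIC window
    rt_range: tuple[float, float] = (0.0, 17.0)

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = default_panel()
        for name in ("noise_cv", "extraction_recovery"):
            v = getattr(self, name)
            if not (0 <= v <= 2):
                raise ConfigError(f"{name} must be in [0, 2], got {v}")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed, panel=self.panel)


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size=size))


def true_slope(analyte: SteroidDefinition, config: GeneratorConfig) -> float:
    """Ground-truth response slope (response per nmol/L).

    Targeted analytes share the base slope; an untargeted analyte with
    correction factor ``f`` responds ``1/f`` times as strongly as its
    surrogate, which is exactly what makes the derived factor equal ``f``.
    """
    if analyte.targeted:
        return config.base_slope
    return config.base_slope / analyte.correction_factor


def _levels(config: GeneratorConfig) -> np.ndarray:
    lo, hi = config.calibration_range
    return np.geomspace(lo, hi, config.n_levels)


def generate_calibration(
    config: GeneratorConfig, analytes=None
) -> tuple[pd.DataFrame, dict]:
    """Calibration series for the requested analytes (default: whole panel).

    Returns a tidy table (analyte, level_nmol_per_l, area, is_area) and the
    ground truth {"slopes": .., "correction_factors": .., "levels": ..}.
    """
    panel = config.panel
    rng = config.rng(1)
    if analytes is None:
        analytes = [s.abbreviation for s in panel.steroids]
    levels = _levels(config)
    rows = []
    truth_slopes: dict[str, float] = {}
    truth_cf: dict[str, float] = {}
    for ab in analytes:
        s = panel.steroid(ab)
        slope = true_slope(s, config)
        truth_slopes[ab] = slope
        if not s.targeted:
            truth_cf[ab] = s.correction_factor
        is_areas = config.is_area * _lognoise(rng, config.noise_cv, levels.size)
        responses = slope * levels * _lognoise(rng, config.noise_cv, levels.size)
        for level, resp, isa in zip(levels, responses, is_areas):
            rows.append((ab, float(level), float(resp * isa), float(isa)))
    df = pd.DataFrame(rows, columns=["analyte", "level_nmol_per_l", "area", "is_area"])
    truth = {
        "slopes": truth_slopes,
        "correction_factors": truth_cf,
        "levels": levels.tolist(),
    }
    return df, truth


def generate_qc(
    config: GeneratorConfig,
    analytes=None,
    bias: dict | float = 0.0,
    cv: dict | float | None = None,
    n_replicates: int = 6,
    n_days: int = 3,
) -> pd.DataFrame:
    """QC replicate sets: n_replicates x {LLOQ, low, mid, high} x n_days.

    ``bias``/``cv`` may be scalars or {(analyte, level_name): value} mappings.
    Returns a tidy table (analyte, level_name, nominal, day, replicate, measured).
    """
    panel = config.panel
    rng = config.rng(2)
    if analytes is None:
        analytes = [s.abbreviation for s in panel.targeted]

    def setting(table, analyte, level, default):
        if isinstance(table, dict):
            return table.get((analyte, level), table.get(level, default))
        return table if table is not None else default

    rows = []
    for ab in analytes:
        for level_name, nominal in panel.qc_levels(ab).items():
            b = setting(bias, ab, level_name, 0.0)
            c = setting(cv, ab, level_name, config.noise_cv)
            for day in range(1, n_days + 1):
                measured = nominal * (1.0 + b) * _lognoise(rng, c, n_replicates)
                for rep, m in enumerate(measured, start=1):
                    rows.append((ab, level_name, float(nominal), day, rep, float(m)))
    return pd.DataFrame(
        rows, columns=["analyte", "level_name", "nominal", "day", "replicate", "measured"]
    )


def _phase_multiplier(s: SteroidDefinition, phase: str, config: GeneratorConfig) -> float:
    is_p4_family = s.abbreviation == "P4" or s.abbreviation in DIRECT_P4_METABOLITES
    if phase == "secretory" and is_p4_family:
        return config.secretory_p4_factor
    if phase == "dienogest" and s.steroid_class == "progestogen":
        return config.dienogest_progestogen_factor
    return 1.0


def _matrix_multiplier(s: SteroidDefinition, matrix: str, config: GeneratorConfig) -> float:
    if matrix != "PF":
        return 1.0
    if s.steroid_class == "progestogen":
        return config.pf_progestogen_factor
    if s.steroid_class in (_CORTICOID_CLASSES | _ANDROGEN_CLASSES):
        return 1.0 / config.serum_corticoid_factor
    return 1.0


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired serum/PF cohort with phase structure.

    Returns (measured, truth): wide tables with sample_id, subject_id, matrix,
    phase and one concentration column (nmol/L) per panel analyte. ``truth``
    holds the noise-free concentrations.
    """
    panel = config.panel
    rng = config.rng(3)
    sigma_subject = np.log(config.between_subject_gsd)
    meas_rows, truth_rows = [], []
    subject_no = 0
    for phase, n in config.cohort_sizes.items():
        for _ in range(int(n)):
            subject_no += 1
            subject_id = f"S{subject_no:03d}"
            base = {}
            for s in panel.steroids:
                median = _ANALYTE_MEDIAN.get(
                    s.abbreviation, _CLASS_MEDIAN[s.steroid_class]
                )
                base[s.abbreviation] = median * np.exp(rng.normal(0.0, sigma_subject))
            for matrix in ("serum", "PF"):
                meta = {
                    "sample_id": f"{subject_id}-{matrix}",
                    "subject_id": subject_id,
                    "matrix": matrix,
                    "phase": phase,
                }
                truth_row = dict(meta)
                meas_row = dict(meta)
                for s in panel.steroids:
                    conc = (
                        base[s.abbreviation]
                        * _phase_multiplier(s, phase, config)
                        * _matrix_multiplier(s, matrix, config)
                    )
                    truth_row[s.abbreviation] = conc
                    meas_row[s.abbreviation] = conc * float(
                        _lognoise(rng, config.noise_cv)
                    )
                truth_rows.append(truth_row)
                meas_rows.append(meas_row)
    return pd.DataFrame(meas_rows), pd.DataFrame(truth_rows)


def generate_scans(
    config: GeneratorConfig, sample_truth: dict[str, float], stream: int = 4
) -> dict[str, ScanSeries]:
    """Centroided full-scan data for one sample, split by polarity.

    Each analyte with a positive concentration elutes as a Gaussian peak at
    its panel (m/z, RT) whose area is ``slope_true * conc * IS area *
    recovery``; internal standards elute at their spike-equivalent areas (also
    scaled by recovery, so the response ratio is recovery-free, as in isotope
    dilution). Centroid m/z jitter is clipped to ±2 mmu.
    """
    panel = config.panel
    rng = config.rng(stream)
    lo, hi = config.rt_range
    rt_grid = np.arange(lo, hi, config.scan_interval_min)
    sigma = config.peak_sigma_min

    # (species, target area, mz, rt, polarity)
    species = []
    for s in panel.steroids:
        conc = float(sample_truth.get(s.abbreviation, 0.0))
        if conc <= 0:
            continue
        area = (
            true_slope(s, config)
            * conc
            * config.is_area
            * config.extraction_recovery
            * float(_lognoise(rng, config.noise_cv))
        )
        species.append((s.abbreviation, area, s.mz, s.expected_rt, s.polarity))
    for std in panel.internal_standards:
        area = config.is_area * config.extraction_recovery * float(
            _lognoise(rng, config.noise_cv)
        )
        species.append((std.id, area, std.mz, std.expected_rt, std.polarity))

    out: dict[str, ScanSeries] = {}
    for polarity in ("positive", "negative"):
        members = [sp for sp in species if sp[4] == polarity]
        if not members:
            continue
        heights = np.array([a / (sigma * np.sqrt(2 * np.pi)) for _, a, _, _, _ in members])
        mzs = np.array([m for _, _, m, _, _ in members])
        rts = np.array([r for _, _, _, r, _ in members])
        # intensity of every species at every scan (Gaussian, truncated at 5 sigma)
        dt = rt_grid[None, :] - rts[:, None]
        profile = heights[:, None] * np.exp(-0.5 * (dt / sigma) ** 2)
        profile[np.abs(dt) > 5 * sigma] = 0.0
        # centroid mass error: uniform within ±mz_jitter, so the default
        # 2-mmu bound keeps every centroid inside the 5-mmu XIC window
        jitter = rng.uniform(-config.mz_jitter, config.mz_jitter, size=profile.shape)
        scans = []
        for j, t in enumerate(rt_grid):
            active = np.nonzero(profile[:, j] > 0.0)[0]
            scans.append(
                (
                    float(t),
                    mzs[active] + jitter[active, j],
                    profile[active, j],
                )
            )
        out[polarity] = ScanSeries(polarity=polarity, scans=scans)
    return out
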