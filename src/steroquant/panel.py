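"""Steroid panel: analyte registry, internal standards, enzyme-ratio definitions.

A panel defines everything the quantitation pipeline needs to know about its
analytes: the quantifier ion m/z (computed from the molecular formula as the
protonated/deprotonated monoisotopic mass), the expected retention time, and
how each analyte is calibrated — targeted analytes against their own
isotopically labeled internal standard, untargeted analytes through a
surrogate calibrant (A4 or P4) combined with a per-analyte ionization-
efficiency correction factor.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError, PanelReferenceError

__all__ = [
    "SteroidDefinition",
    "InternalStandard",
    "EnzymeRatioDefinition",
    "Panel",
    "load_panel",
    "save_panel",
    "default_panel",
    "assign_internal_standard",
    "formula_monoisotopic_mass",
    "ion_mz",
]

# monoisotopic atomic masses (u)
_ELEMENT_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}
PROTON_MASS = 1.007276466812
# mass added per deuterium label (2H - 1H)
DEUTERIUM_SHIFT = 2.01410177785 - 1.00782503207

STEROID_CLASSES = {
    "progestogen",
    "androgen",
    "C11-oxy androgen",
    "glucocorticoid",
    "mineralocorticoid",
    "precursor",
}
SURROGATE_CHOICES = {"A4", "P4"}
MZ_WINDOW = (200.0, 500.0)  # acquisition mass range (m/z)
RT_WINDOW = (0.0, 17.0)  # elution window of the 17-min method (minutes)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (u) of a molecular formula such as ``C21H30O2``."""
    mass = 0.0
    consumed = 0
    for element, count in _FORMULA_RE.findall(formula):
        if not element:
            continue
        if element not in _ELEMENT_MASS:
            raise ConfigError(f"unknown element {element!r} in formula {formula!r}")
        mass += _ELEMENT_MASS[element] * (int(count) if count else 1)
        consumed += len(element) + len(count)
    if consumed != len(formula) or mass == 0.0:
        raise ConfigError(f"unparseable molecular formula {formula!r}")
    return mass


def ion_mz(formula: str, polarity: str, n_labels: int = 0) -> float:
    """m/z of the [M+H]+ or [M-H]- ion, optionally with deuterium labels."""
    mass = formula_monoisotopic_mass(formula) + n_labels * DEUTERIUM_SHIFT
    if polarity == "positive":
        return mass + PROTON_MASS
    if polarity == "negative":
        return mass - PROTON_MASS
    raise ConfigError(f"polarity must be 'positive' or 'negative', got {polarity!r}")


@dataclass
class SteroidDefinition:
    """One analyte of the panel.

    Targeted analytes carry ``is_ref`` (their internal standard) and the
    validated quantification range ``[lloq, uloq]``; untargeted analytes carry
    ``surrogate_ref`` (A4 or P4) and ``correction_factor`` instead.
    """

    abbreviation: str
    full_name: str
    steroid_class: str
    quant_mode: str  # {"targeted", "untargeted"}
    polarity: str  # {"positive", "negative"}
    formula: str
    expected_rt: float  # minutes
    mz: float | None = None  # computed from formula when omitted
    is_ref: str | None = None
    surrogate_ref: str | None = None
    correction_factor: float | None = None
    factor_verified: bool = True
    lloq: float | None = None  # nmol/L
    uloq: float | None = None  # nmol/L

    def __post_init__(self) -> None:
        if self.steroid_class not in STEROID_CLASSES:
            raise ConfigError(
                f"{self.abbreviation}: unknown steroid_class {self.steroid_class!r}"
            )
        if self.quant_mode not in ("targeted", "untargeted"):
            raise ConfigError(f"{self.abbreviation}: bad quant_mode {self.quant_mode!r}")
        if self.mz is None:
            self.mz = ion_mz(self.formula, self.polarity)
        if not (MZ_WINDOW[0] <= self.mz <= MZ_WINDOW[1]):
            raise ConfigError(
                f"{self.abbreviation}: m/z {self.mz:.4f} outside the "
                f"{MZ_WINDOW[0]:.0f}-{MZ_WINDOW[1]:.0f} acquisition window"
            )
        if not (RT_WINDOW[0] < self.expected_rt < RT_WINDOW[1]):
            raise ConfigError(
                f"{self.abbreviation}: expected_rt {self.expected_rt} outside the "
                "elution window"
            )
        if self.quant_mode == "targeted":
            if not self.is_ref:
                raise ConfigError(f"{self.abbreviation}: targeted analyte needs is_ref")
            if self.surrogate_ref is not None or self.correction_factor is not None:
                raise ConfigError(
                    f"{self.abbreviation}: targeted analyte must not define "
                    "surrogate_ref/correction_factor"
                )
            if self.lloq is not None and self.uloq is not None and not self.lloq < self.uloq:
                raise ConfigError(f"{self.abbreviation}: lloq must be < uloq")
        else:
            if self.is_ref is not None:
                raise ConfigError(
                    f"{self.abbreviation}: untargeted analyte must not define is_ref"
                )
            if self.surrogate_ref not in SURROGATE_CHOICES:
                raise PanelReferenceError(
                    f"{self.abbreviation}: surrogate_ref must be one of "
                    f"{sorted(SURROGATE_CHOICES)}, got {self.surrogate_ref!r}"
                )
            if self.correction_factor is None or not self.correction_factor > 0:
                raise ConfigError(
                    f"{self.abbreviation}: untargeted analyte needs correction_factor > 0"
                )

    @property
    def targeted(self) -> bool:
        return self.quant_mode == "targeted"


@dataclass
class InternalStandard:
    """Isotopically labeled internal standard spiked at a fixed amount."""

    id: str
    labels_analyte: str
    formula: str
    n_labels: int
    polarity: str
    expected_rt: float
    spike_amount_pmol: float
    mz: float | None = None

    def __post_init__(self) -> None:
        if self.mz is None:
            self.mz = ion_mz(self.formula, self.polarity, self.n_labels)
        if self.spike_amount_pmol <= 0:
            raise ConfigError(f"{self.id}: spike_amount_pmol must be > 0")


@dataclass
class EnzymeRatioDefinition:
    """Apparent enzyme activity = sum(product concs) / sum(substrate concs)."""

    name: str
    enzyme: str
    products: list[str]
    substrates: list[str]

    def __post_init__(self) -> None:
        if not self.products or not self.substrates:
            raise ConfigError(f"{self.name}: products and substrates must be non-empty")
        if set(self.products) & set(self.substrates):
            raise ConfigError(f"{self.name}: product/substrate sets must be disjoint")


@dataclass
class Panel:
    steroids: list[SteroidDefinition]
    internal_standards: list[InternalStandard] = field(default_factory=list)
    enzyme_ratios: list[EnzymeRatioDefinition] = field(default_factory=list)
    calibration_range: tuple[float, float] = (0.1, 2000.0)  # nmol/L
    n_calibration_levels: int = 12
    weighting: str = "1/x^2"
    name: str = "panel"
    version: int = 1

    def __post_init__(self) -> None:
        self._by_abbrev = {s.abbreviation: s for s in self.steroids}
        if len(self._by_abbrev) != len(self.steroids):
            raise ConfigError("duplicate analyte abbreviations in panel")
        self._is_by_id = {i.id: i for i in self.internal_standards}
        if len(self._is_by_id) != len(self.internal_standards):
            raise ConfigError("duplicate internal-standard ids in panel")
        lo, hi = self.calibration_range
        if not (0 < lo < hi):
            raise ConfigError("calibration range must satisfy 0 < low < high")
        self._validate_references()

    def _validate_references(self) -> None:
        for s in self.steroids:
            if s.targeted:
                if s.is_ref not in self._is_by_id:
                    raise PanelReferenceError(
                        f"{s.abbreviation}: internal standard {s.is_ref!r} not in panel"
                    )
            else:
                surrogate = self._by_abbrev.get(s.surrogate_ref)
                if surrogate is None or not surrogate.targeted:
                    raise PanelReferenceError(
                        f"{s.abbreviation}: surrogate {s.surrogate_ref!r} is not a "
                        "targeted analyte of the panel"
                    )
        for ratio in self.enzyme_ratios:
            for ab in ratio.products + ratio.substrates:
                if ab not in self._by_abbrev:
                    raise PanelReferenceError(
                        f"enzyme ratio {ratio.name}: analyte {ab!r} not in panel"
                    )

    # -- lookup ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.steroids)

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self._by_abbrev

    def steroid(self, abbreviation: str) -> SteroidDefinition:
        try:
            return self._by_abbrev[abbreviation]
        except KeyError:
            raise PanelReferenceError(f"analyte {abbreviation!r} not in panel") from None

    def internal_standard(self, is_id: str) -> InternalStandard:
        try:
            return self._is_by_id[is_id]
        except KeyError:
            raise PanelReferenceError(f"internal standard {is_id!r} not in panel") from None

    @property
    def targeted(self) -> list[SteroidDefinition]:
        return [s for s in self.steroids if s.targeted]

    @property
    def untargeted(self) -> list[SteroidDefinition]:
        return [s for s in self.steroids if not s.targeted]

    def by_class(self, steroid_class: str) -> list[SteroidDefinition]:
        return [s for s in self.steroids if s.steroid_class == steroid_class]

    # -- calibration design -------------------------------------------------
    def calibration_levels(self, abbreviation: str | None = None) -> list[float]:
        """Geometric 12-point (by default) level series in nmol/L.

        Targeted analytes use their validated [lloq, uloq] range; untargeted
        analytes (and analytes without a validated range) use the panel-wide
        design range, 0.1-2000 nmol/L by default, which spans > 4 decades.
        """
        lo, hi = self.calibration_range
        if abbreviation is not None:
            s = self.steroid(abbreviation)
            if s.lloq is not None and s.uloq is not None:
                lo, hi = s.lloq, s.uloq
        n = self.n_calibration_levels
        ratio = (hi / lo) ** (1.0 / (n - 1))
        return [lo * ratio**i for i in range(n)]

    def qc_levels(self, abbreviation: str) -> dict[str, float]:
        """QC concentrations {LLOQ, low, mid, high} in nmol/L for a targeted analyte."""
        s = self.steroid(abbreviation)
        if s.lloq is None or s.uloq is None:
            lo, hi = self.calibration_range
        else:
            lo, hi = s.lloq, s.uloq
        return {
            "LLOQ": lo,
            "low": 3.0 * lo,
            "mid": math.sqrt(lo * hi),
            "high": 0.75 * hi,
        }

    def decades_spanned(self) -> float:
        lo, hi = self.calibration_range
        return math.log10(hi / lo)

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def strip(d: dict) -> dict:
            return {k: v for k, v in d.items() if v is not None}

        return {
            "name": self.name,
            "version": self.version,
            "calibration": {
                "range_nmol_per_l": list(self.calibration_range),
                "n_levels": self.n_calibration_levels,
                "weighting": self.weighting,
            },
            "steroids": [strip(asdict(s)) for s in self.steroids],
            "internal_standards": [strip(asdict(i)) for i in self.internal_standards],
            "enzyme_ratios": [asdict(r) for r in self.enzyme_ratios],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "Panel":
        try:
            steroids = [SteroidDefinition(**d) for d in raw.get("steroids", [])]
            standards = [InternalStandard(**d) for d in raw.get("internal_standards", [])]
            ratios = [EnzymeRatioDefinition(**d) for d in raw.get("enzyme_ratios", [])]
        except TypeError as exc:
            raise ConfigError(f"panel schema violation: {exc}") from exc
        calib = raw.get("calibration", {})
        rng = calib.get("range_nmol_per_l", [0.1, 2000.0])
        return cls(
            steroids=steroids,
            internal_standards=standards,
            enzyme_ratios=ratios,
            calibration_range=(float(rng[0]), float(rng[1])),
            n_calibration_levels=int(calib.get("n_levels", 12)),
            weighting=calib.get("weighting", "1/x^2"),
            name=raw.get("name", "panel"),
            version=int(raw.get("version", 1)),
        )


def load_panel(path: str | Path) -> Panel:
    """Load and validate a panel from a YAML (or JSON-compatible) config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"panel config not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"panel config {path} is not a mapping")
    return Panel.from_dict(raw)


def save_panel(panel: Panel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(panel.to_dict(), fh, sort_keys=False, allow_unicode=True)


def default_panel() -> Panel:
    """The packaged 51-steroid panel (17 targeted + 34 untargeted)."""
    ref = resources.files("steroquant.data").joinpath("default_panel.yaml")
    raw = yaml.safe_load(ref.read_text())
    return Panel.from_dict(raw)


def assign_internal_standard(analyte: SteroidDefinition, panel: Panel) -> InternalStandard:
    """Internal standard used to normalize an analyte's signal.

    Targeted analytes use their assigned labeled standard. Untargeted analytes
    have no own standard; with labeled standards spread across the whole
    elution range, the standard eluting nearest in retention time is the best
    proxy for matrix effects, so the nearest-RT standard is chosen (ties break
    toward the earlier-eluting standard).
    """
    if not panel.internal_standards:
        raise ConfigError("panel defines no internal standards")
    if analyte.targeted:
        return panel.internal_standard(analyte.is_ref)
    return min(
        panel.internal_standards,
        key=lambda s: (abs(s.expected_rt - analyte.expected_rt), s.expected_rt),
    )
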