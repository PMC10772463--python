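"""Domain types, physical constants, and enrichment-scale conventions.

The whole pipeline works on time series of plasma amino acid concentrations
(μmol·L⁻¹) and tracer enrichments expressed as mole percent excess (MPE).
Internally every kinetic equation consumes *mole-fraction excess* (MPE/100);
a tracer-to-tracee ratio (TTR) helper is provided for interoperability but
is not used by the pipeline itself.

Conventions
-----------
* Time is minutes since ingestion of the protein drink; negative times are
  pre-drink (infusion equilibration) samples and are excluded from
  postprandial integration.
* Rates are μmol · kg body mass⁻¹ · min⁻¹ unless stated otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import DomainError

__all__ = [
    "Tracer",
    "Pool",
    "Constants",
    "CONSTANTS",
    "TrialConfig",
    "EnrichmentSeries",
    "ConcentrationSeries",
    "mpe_to_fraction",
    "fraction_to_mpe",
    "mpe_to_ttr",
    "ttr_to_mpe",
]


class Tracer(str, enum.Enum):
    """Stable-isotope tracers used in the dual tracer feeding-infusion design."""

    D5_PHE = "d5phe"        # L-[ring-2H5]-phenylalanine, IV infusion
    C13_PHE = "13cphe"      # L-[1-13C]-phenylalanine, from the labeled protein
    D2_TYR = "d2tyr"        # L-[ring-3,5-2H2]-tyrosine, IV infusion
    D4_TYR = "d4tyr"        # L-[ring-2H4]-tyrosine, product of D5-phe hydroxylation
    C13_LEU = "13cleu"      # L-[1-13C]-leucine, IV infusion *and* labeled protein


class Pool(str, enum.Enum):
    """Sampling pools for enrichment measurements."""

    PLASMA = "plasma"
    MUSCLE_FREE = "muscle_free"
    BOUND_MIXED = "protein_bound_mixed"
    BOUND_MYOFIBRILLAR = "protein_bound_myofibrillar"
    BOUND_CONNECTIVE = "protein_bound_connective"
    BOUND_PLASMA_PROTEIN = "protein_bound_plasma"


@dataclass(frozen=True)
class Constants:
    """Physiological and chemical constants used in gram-scale conversions.

    ``smm_pro``: protein fraction of skeletal muscle mass (0.20).
    ``bm_blood``: blood fraction of body mass (0.07).
    ``blood_p``: plasma fraction of blood (0.55).
    ``plasma_pro``: protein content of plasma, g·L⁻¹ (70).
    ``mw_phe``/``mw_leu``: molar masses, g·mol⁻¹.
    """

    smm_pro: float = 0.20
    bm_blood: float = 0.07
    blood_p: float = 0.55
    plasma_pro: float = 70.0
    mw_phe: float = 165.19
    mw_leu: float = 131.17


CONSTANTS = Constants()


# ---------------------------------------------------------------------------
# Enrichment-scale conversions


def mpe_to_fraction(e):
    """Convert mole percent excess to mole-fraction excess (MPE/100).

    Accepts scalars or arrays; raises :class:`DomainError` outside [0, 100).
    """
    arr = np.asarray(e, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 100):
        raise DomainError(f"MPE must be in [0, 100), got {e!r}")
    out = arr / 100.0
    return out if arr.ndim else float(out)


def fraction_to_mpe(f):
    """Inverse of :func:`mpe_to_fraction`."""
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise DomainError(f"mole-fraction excess must be in [0, 1), got {f!r}")
    out = arr * 100.0
    return out if arr.ndim else float(out)


def mpe_to_ttr(e):
    """Convert MPE to tracer-to-tracee ratio: TTR = (e/100) / (1 − e/100)."""
    frac = mpe_to_fraction(e)
    arr = np.asarray(frac, dtype=float)
    out = arr / (1.0 - arr)
    return out if np.asarray(e).ndim else float(out)


def ttr_to_mpe(ttr):
    """Inverse of :func:`mpe_to_ttr`."""
    arr = np.asarray(ttr, dtype=float)
    if np.any(arr < 0):
        raise DomainError(f"TTR must be nonnegative, got {ttr!r}")
    out = 100.0 * arr / (1.0 + arr)
    return out if arr.ndim else float(out)


# ---------------------------------------------------------------------------
# Trial configuration


class TrialConfig(BaseModel):
    """Subject- and protocol-level constants for one tracer trial.

    Defaults encode the reference protocol: primed continuous infusion of
    L-[ring-2H5]-phenylalanine (0.060), L-[ring-3,5-2H2]-tyrosine (0.018) and
    L-[1-13C]-leucine (0.12 μmol·kg⁻¹·min⁻¹), with a drink containing 0, 25
    or 100 g of intrinsically L-[1-13C]-phenylalanine/leucine labeled milk
    protein (31.6 / 8.0 MPE).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    body_mass_kg: float = Field(default=75.0, gt=0)
    skeletal_muscle_mass_g: float = Field(default=30_000.0, gt=0)
    protein_dose_g: float = Field(default=25.0, ge=0)  # 0 encodes placebo

    f_phe_iv: float = Field(default=0.060, gt=0, description="μmol·kg⁻¹·min⁻¹")
    f_tyr_iv: float = Field(default=0.018, gt=0)
    f_leu_iv: float = Field(default=0.12, gt=0)

    prime_d5phe: float = Field(default=3.60, gt=0, description="μmol·kg⁻¹")
    prime_d2tyr: float = Field(default=1.10, gt=0)
    prime_13cleu: float = Field(default=7.19, gt=0)

    e_oral_phe_mpe: float = Field(default=31.6, ge=0, lt=100)
    e_oral_leu_mpe: float = Field(default=8.0, ge=0, lt=100)

    pv_phe: float = Field(default=0.125, gt=0, description="L·kg⁻¹")
    pv_tyr: float = Field(default=0.125, gt=0)

    phe_fraction_of_protein: float = Field(default=0.048, gt=0, description="g·g⁻¹")
    leu_fraction_of_protein: float = Field(default=0.098, gt=0)

    @model_validator(mode="after")
    def _check_oral_enrichment(self) -> "TrialConfig":
        if self.protein_dose_g > 0 and self.e_oral_phe_mpe <= 0:
            raise ValueError(
                "protein_dose_g > 0 requires a positive oral phenylalanine enrichment"
            )
        return self

    # -- derived doses ------------------------------------------------------
    @property
    def phe_oral_umol(self) -> float:
        """Total phenylalanine ingested with the drink, μmol."""
        return self.protein_dose_g * self.phe_fraction_of_protein / CONSTANTS.mw_phe * 1e6

    @property
    def leu_oral_umol(self) -> float:
        """Total leucine ingested with the drink, μmol."""
        return self.protein_dose_g * self.leu_fraction_of_protein / CONSTANTS.mw_leu * 1e6


# ---------------------------------------------------------------------------
# Time series containers


def _validate_series(times: np.ndarray, values: np.ndarray, what: str) -> None:
    if times.ndim != 1 or values.ndim != 1:
        raise DomainError(f"{what}: times and values must be 1-D")
    if len(times) != len(values):
        raise DomainError(
            f"{what}: times (n={len(times)}) and values (n={len(values)}) differ in length"
        )
    if len(times) == 0:
        raise DomainError(f"{what}: series is empty")
    if np.any(np.diff(times) <= 0):
        raise DomainError(f"{what}: times must be strictly increasing")
    if np.any(values < 0):
        raise DomainError(f"{what}: values must be nonnegative")


@dataclass(frozen=True)
class EnrichmentSeries:
    """Timestamped enrichments (MPE) for one tracer in one pool."""

    tracer: Tracer
    pool: Pool
    times: np.ndarray
    values_mpe: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values_mpe", np.asarray(self.values_mpe, dtype=float))
        _validate_series(self.times, self.values_mpe, f"EnrichmentSeries[{self.tracer.value}]")
        if np.any(self.values_mpe >= 100):
            raise DomainError("enrichment values must be < 100 MPE")

    @property
    def fractions(self) -> np.ndarray:
        """Values as mole-fraction excess."""
        return self.values_mpe / 100.0

    def restrict(self, t_start: float, t_end: float) -> "EnrichmentSeries":
        """Sub-series with t_start ≤ t ≤ t_end."""
        mask = (self.times >= t_start) & (self.times <= t_end)
        return EnrichmentSeries(self.tracer, self.pool, self.times[mask], self.values_mpe[mask])

    def time_weighted_mean(self, t_start: float, t_end: float) -> float:
        """Trapezoidal time-average of the enrichment over [t_start, t_end], MPE.

        Endpoint values are obtained by linear interpolation; the window must
        lie within the sampled range.
        """
        if t_end <= t_start:
            raise DomainError("window must have t_end > t_start")
        if t_start < self.times[0] or t_end > self.times[-1]:
            raise DomainError(
                f"window [{t_start}, {t_end}] outside sampled range "
                f"[{self.times[0]}, {self.times[-1]}]"
            )
        inner = (self.times > t_start) & (self.times < t_end)
        ts = np.concatenate(([t_start], self.times[inner], [t_end]))
        vs = np.interp(ts, self.times, self.values_mpe)
        return float(np.trapezoid(vs, ts) / (t_end - t_start))


@dataclass(frozen=True)
class ConcentrationSeries:
    """Timestamped plasma concentrations (μmol·L⁻¹) of one amino acid."""

    analyte: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _validate_series(self.times, self.values, f"ConcentrationSeries[{self.analyte}]")

    def restrict(self, t_start: float, t_end: float) -> "ConcentrationSeries":
        mask = (self.times >= t_start) & (self.times <= t_end)
        return ConcentrationSeries(self.analyte, self.times[mask], self.values[mask])
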