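"""Tissue-level tracer incorporation: FSR, de novo synthesis, and partitioning.

The fractional synthesis rate of a protein pool follows the
precursor-product relation

    FSR (%·h⁻¹) = ΔE_bound / (E_precursor · t) × 100

with ΔE_bound the gain in protein-bound enrichment between two biopsies,
E_precursor the time-weighted mean free (plasma or intramuscular) precursor
enrichment over the incorporation window, and t the window length in hours.
The relation is scale-invariant: numerator and denominator may both be MPE
or both mole fractions.

De novo incorporation of dietary amino acids scales the protein-bound oral
tracer gain by the oral protein enrichment and the size of the product pool
(skeletal muscle protein or circulating plasma protein).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, PrecursorError
from .trial import CONSTANTS, Constants, EnrichmentSeries, Pool, Tracer

__all__ = [
    "BiopsyRecord",
    "FsrResult",
    "weighted_precursor_mean",
    "fsr",
    "fsr_table",
    "mps_denovo",
    "pp_denovo",
    "exo_endo_contribution",
]

FRACTIONS = ("mixed", "myofibrillar", "connective")


@dataclass(frozen=True)
class BiopsyRecord:
    """Protein-bound and tissue-free enrichments from one biopsy.

    ``bound_mpe`` maps tracer → protein-bound MPE for this ``fraction``;
    ``free_mpe`` maps tracer → muscle-free-pool MPE (fraction-independent,
    repeated per record for convenience).
    """

    time_min: float
    fraction: str
    bound_mpe: Mapping[Tracer, float]
    free_mpe: Mapping[Tracer, float] = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.bound_mpe, self.free_mpe):
            for tracer, e in d.items():
                if e < 0:
                    raise DomainError(f"negative enrichment for {tracer}: {e}")


def weighted_precursor_mean(series: EnrichmentSeries, t_start: float, t_end: float) -> float:
    """Time-weighted (trapezoidal) mean precursor enrichment over a window, MPE."""
    return series.time_weighted_mean(t_start, t_end)


def fsr(delta_e_bound: float, e_precursor: float, hours: float) -> float:
    """Precursor-product fractional synthesis rate, %·h⁻¹."""
    if e_precursor <= 0:
        raise PrecursorError("precursor enrichment must be positive")
    if hours <= 0:
        raise DomainError("incorporation time must be positive")
    return delta_e_bound / (e_precursor * hours) * 100.0


def _bound_lookup(biopsies, fraction, tracer):
    recs = sorted(
        (b for b in biopsies if b.fraction == fraction and tracer in b.bound_mpe),
        key=lambda b: b.time_min,
    )
    return {b.time_min: b.bound_mpe[tracer] for b in recs}


def _free_lookup(biopsies, tracer):
    vals = {}
    for b in biopsies:
        if tracer in b.free_mpe:
            vals[b.time_min] = b.free_mpe[tracer]
    return vals


@dataclass(frozen=True)
class FsrResult:
    fraction: str
    tracer: Tracer
    precursor_pool: Pool
    window: tuple[float, float]
    fsr_pct_per_h: float
    precursor_mean_mpe: float


def fsr_table(
    biopsies: list[BiopsyRecord],
    plasma_precursors: Mapping[Tracer, EnrichmentSeries],
    windows: list[tuple[float, float]] | None = None,
    tracers: tuple[Tracer, ...] = (Tracer.D5_PHE, Tracer.C13_LEU),
) -> pd.DataFrame:
    """FSR per fraction × tracer × precursor pool × window.

    The plasma precursor mean is the trapezoidal time-average of the plasma
    free enrichment; the muscle-free precursor averages the two bounding
    biopsy free-pool values (the only intramuscular samples available).
    Windows default to every consecutive biopsy pair plus the full span.
    """
    times = sorted({b.time_min for b in biopsies})
    if len(times) < 2:
        raise DomainError("at least two biopsy times are required")
    if windows is None:
        windows = [(times[i], times[i + 1]) for i in range(len(times) - 1)]
        if len(times) > 2:
            windows.append((times[0], times[-1]))

    fractions = sorted({b.fraction for b in biopsies})
    rows = []
    for fraction in fractions:
        for tracer in tracers:
            bound = _bound_lookup(biopsies, fraction, tracer)
            free = _free_lookup(biopsies, tracer)
            for (t0, t1) in windows:
                if t0 not in bound or t1 not in bound:
                    continue
                delta = bound[t1] - bound[t0]
                hours = (t1 - t0) / 60.0
                if tracer in plasma_precursors:
                    prec = weighted_precursor_mean(plasma_precursors[tracer], t0, t1)
                    rows.append(
                        FsrResult(fraction, tracer, Pool.PLASMA, (t0, t1),
                                  fsr(delta, prec, hours), prec)
                    )
                if t0 in free and t1 in free:
                    prec = 0.5 * (free[t0] + free[t1])
                    rows.append(
                        FsrResult(fraction, tracer, Pool.MUSCLE_FREE, (t0, t1),
                                  fsr(delta, prec, hours), prec)
                    )
    return pd.DataFrame(
        {
            "fraction": [r.fraction for r in rows],
            "tracer": [r.tracer.value for r in rows],
            "precursor_pool": [r.precursor_pool.value for r in rows],
            "t_start": [r.window[0] for r in rows],
            "t_end": [r.window[1] for r in rows],
            "fsr_pct_per_h": [r.fsr_pct_per_h for r in rows],
            "precursor_mean_mpe": [r.precursor_mean_mpe for r in rows],
        }
    )


def mps_denovo(
    smm_g: float,
    delta_e_m_bound_exo: float,
    e_oral: float,
    smm_pro: float = CONSTANTS.smm_pro,
) -> float:
    """Dietary amino acids incorporated into mixed-muscle protein, grams.

    SMM · SMM_pro · ΔE_m-bound,exo / E_oral — the muscle protein pool scaled
    by the oral-tracer-normalized bound enrichment gain. Enrichments must
    share a scale.
    """
    if e_oral <= 0:
        raise DomainError("oral protein enrichment must be positive")
    return smm_g * smm_pro * delta_e_m_bound_exo / e_oral


def pp_denovo(
    body_mass_kg: float,
    delta_e_p_bound_exo: float,
    e_oral: float,
    constants: Constants = CONSTANTS,
) -> float:
    """Dietary amino acids incorporated into circulating plasma protein, grams.

    BM · BM_blood · BLOOD_p · PLASMA_pro gives the plasma protein pool in
    grams (body mass × blood fraction × plasma fraction × g protein per L).
    """
    if e_oral <= 0:
        raise DomainError("oral protein enrichment must be positive")
    pool_g = body_mass_kg * constants.bm_blood * constants.blood_p * constants.plasma_pro
    return pool_g * delta_e_p_bound_exo / e_oral


def exo_endo_contribution(
    delta_e_exo: float,
    e_oral: float,
    delta_e_iv: float,
    e_phe_iv_mean: float,
) -> tuple[float, float]:
    """Percent contributions of exogenous vs endogenous amino acids to synthesis.

    Each bound-enrichment gain is normalized by its own free-precursor
    enrichment; their ratio is the exogenous share:

        exo% = (ΔE_exo / E_oral) / (ΔE_iv / E_phe,iv) × 100,  endo% = 100 − exo%.

    Values outside [0, 100] (noise) are capped with a warning.
    """
    if e_oral <= 0 or e_phe_iv_mean <= 0:
        raise DomainError("precursor enrichments must be positive")
    if delta_e_iv == 0:
        raise DomainError("IV-tracer bound enrichment gain is zero; contribution undefined")
    pct = (delta_e_exo / e_oral) / (delta_e_iv / e_phe_iv_mean) * 100.0
    if pct < 0 or pct > 100:
        warnings.warn(f"exogenous contribution {pct:.2f}% outside [0, 100]; capping", stacklevel=2)
        pct = min(max(pct, 0.0), 100.0)
    return pct, 100.0 - pct
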