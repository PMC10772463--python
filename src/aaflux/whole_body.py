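"""Whole-body protein synthesis, oxidation, and net balance.

Phenylalanine is not synthesized de novo and has only one irreversible
disposal route other than protein synthesis: hydroxylation to tyrosine.
With a ring-deuterated phenylalanine infusion, hydroxylation transfers the
ring label to tyrosine; the appearance of that product tracer, scaled by the
tyrosine flux (measured with its own IV tracer), quantifies oxidation:

    oxidation = Tyr_Ra · [E_D4tyr / E_phe,iv] · [Rd / (F_phe,iv + Rd)]

where the last factor is the tracee fraction of phenylalanine disposal
(the infused tracer itself contributes F to the flux). Then

    synthesis   = total_Rd − oxidation
    breakdown   = endo_Ra
    net balance = synthesis − breakdown

all in μmol phenylalanine · kg⁻¹ · min⁻¹. Enrichments are mole fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, PrecursorError
from .trial import CONSTANTS, ConcentrationSeries, EnrichmentSeries, TrialConfig
from .plasma_kinetics import total_ra as _steele_ra

__all__ = [
    "WholeBodyRates",
    "tyr_ra",
    "oxidation",
    "synthesis_breakdown_balance",
    "whole_body_table",
    "aggregate_windows",
    "umol_phe_to_g_protein",
    "g_protein_to_umol_phe",
]


@dataclass(frozen=True)
class WholeBodyRates:
    """Whole-body rates over one window, μmol phe·kg⁻¹·min⁻¹."""

    tyr_ra: float
    oxidation: float
    synthesis: float
    breakdown: float
    net_balance: float
    window: tuple[float, float] | None = None


def tyr_ra(f_tyr_iv, pv_tyr, c_tyr_mean, de_d2tyr_dt, e_d2tyr_mean):
    """Total tyrosine Ra from the D2-tyrosine infusion (Steele form)."""
    return _steele_ra(f_tyr_iv, pv_tyr, c_tyr_mean, de_d2tyr_dt, e_d2tyr_mean)


def oxidation(tyr_ra_val, e_d4tyr_mean, e_phe_iv_mean, total_rd_val, f_phe_iv):
    """Phenylalanine hydroxylation rate (protein oxidation), μmol·kg⁻¹·min⁻¹."""
    e_phe = np.asarray(e_phe_iv_mean, dtype=float)
    if np.any(e_phe <= 0):
        raise PrecursorError("IV phenylalanine enrichment must be positive")
    rd = np.asarray(total_rd_val, dtype=float)
    denom = f_phe_iv + rd
    if np.any(denom <= 0):
        raise DomainError("F_phe,iv + Rd must be positive")
    return np.asarray(tyr_ra_val) * (np.asarray(e_d4tyr_mean) / e_phe) * (rd / denom)


def synthesis_breakdown_balance(
    total_rd_val: float,
    oxidation_val: float,
    endo_ra_val: float,
    tyr_ra_val: float = float("nan"),
    window: tuple[float, float] | None = None,
) -> WholeBodyRates:
    """Assemble synthesis, breakdown and net balance from their components.

    If noise drives oxidation above total Rd, synthesis is floored at 0 with
    a warning rather than reported negative.
    """
    if oxidation_val > total_rd_val:
        warnings.warn(
            f"oxidation ({oxidation_val:.4g}) exceeds total Rd ({total_rd_val:.4g}); "
            "flooring synthesis at 0",
            stacklevel=2,
        )
        synthesis = 0.0
    else:
        synthesis = total_rd_val - oxidation_val
    return WholeBodyRates(
        tyr_ra=tyr_ra_val,
        oxidation=oxidation_val,
        synthesis=synthesis,
        breakdown=endo_ra_val,
        net_balance=synthesis - endo_ra_val,
        window=window,
    )


def whole_body_table(
    kinetics: pd.DataFrame,
    tyr_conc: ConcentrationSeries,
    e_d2tyr: EnrichmentSeries,
    e_d4tyr: EnrichmentSeries,
    config: TrialConfig,
) -> pd.DataFrame:
    """Per-interval whole-body rates joined onto a phenylalanine kinetics table.

    The tyrosine series must cover the kinetics table's sampling times.
    """
    times = np.concatenate((kinetics["t_start"].to_numpy(), [kinetics["t_end"].iloc[-1]]))
    for s in (tyr_conc, e_d2tyr, e_d4tyr):
        missing = sorted(set(times) - set(s.times.tolist()))
        if missing:
            raise DomainError(f"tyrosine series missing sampling times {missing}")

    def at(series_times, series_values):
        idx = np.searchsorted(series_times, times)
        return np.asarray(series_values, dtype=float)[idx]

    ct = at(tyr_conc.times, tyr_conc.values)
    e2 = at(e_d2tyr.times, e_d2tyr.fractions)
    e4 = at(e_d4tyr.times, e_d4tyr.fractions)
    dt = np.diff(times)

    tra = tyr_ra(
        config.f_tyr_iv,
        config.pv_tyr,
        0.5 * (ct[:-1] + ct[1:]),
        np.diff(e2) / dt,
        0.5 * (e2[:-1] + e2[1:]),
    )
    ox = oxidation(
        tra,
        0.5 * (e4[:-1] + e4[1:]),
        kinetics["e_iv_mean"].to_numpy(),
        kinetics["total_rd"].to_numpy(),
        config.f_phe_iv,
    )
    out = kinetics.copy()
    out["tyr_ra"] = tra
    out["oxidation"] = ox
    out["synthesis"] = out["total_rd"] - ox
    out["breakdown"] = out["endo_ra"]
    out["net_balance"] = out["synthesis"] - out["breakdown"]
    return out


def aggregate_windows(
    table: pd.DataFrame,
    windows: list[tuple[float, float]] = ((0, 240), (240, 480), (480, 720), (0, 720)),
    columns: tuple[str, ...] = (
        "total_ra", "exo_ra", "endo_ra", "total_rd", "exo_rd", "endo_rd",
        "tyr_ra", "oxidation", "synthesis", "breakdown", "net_balance",
    ),
) -> pd.DataFrame:
    """Time-weighted means of interval rates over reporting windows."""
    lo_all = table["t_start"].to_numpy()
    hi_all = table["t_end"].to_numpy()
    rows = []
    for (w0, w1) in windows:
        overlap = np.clip(np.minimum(hi_all, w1) - np.maximum(lo_all, w0), 0.0, None)
        total = overlap.sum()
        if total <= 0:
            raise DomainError(f"window {(w0, w1)} does not overlap the kinetics table")
        row = {"t_start": w0, "t_end": w1}
        for col in columns:
            if col in table:
                row[col] = float(np.sum(table[col].to_numpy() * overlap) / total)
        rows.append(row)
    return pd.DataFrame(rows)


def umol_phe_to_g_protein(
    umol_phe: float,
    phe_fraction: float = 0.048,
    mw_phe: float = CONSTANTS.mw_phe,
) -> float:
    """Convert μmol of phenylalanine to grams of (milk-like) protein.

    μmol × MW(g·mol⁻¹) × 1e-6 gives grams of phenylalanine; dividing by the
    phenylalanine mass fraction of the protein scales to protein grams.
    """
    if phe_fraction <= 0:
        raise DomainError("phe_fraction must be positive")
    return umol_phe * mw_phe * 1e-6 / phe_fraction


def g_protein_to_umol_phe(
    g_protein: float,
    phe_fraction: float = 0.048,
    mw_phe: float = CONSTANTS.mw_phe,
) -> float:
    """Inverse of :func:`umol_phe_to_g_protein`."""
    if phe_fraction <= 0:
        raise DomainError("phe_fraction must be positive")
    return g_protein * phe_fraction / (mw_phe * 1e-6)
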