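"""Non-steady-state plasma phenylalanine kinetics (single-pool Steele model).

Between consecutive sampling times the total rate of appearance is estimated
from the intravenous tracer dilution,

    total_Ra = [F_iv − pV · C(t) · dE_iv/dt] / E_iv(t),

the portion derived from the ingested (orally labeled) protein from the oral
tracer,

    exo_Ra = [total_Ra · E_p,oral(t) + pV · C(t) · dE_p,oral/dt] / E_oral,

and endogenous appearance (whole-body protein breakdown) as the residual
endo_Ra = total_Ra − exo_Ra − F_iv. Disappearance rates follow from
total_Rd = total_Ra − pV·dC/dt with the same exogenous split.

All enrichments entering these functions are mole fractions (MPE/100);
:func:`kinetics_table` performs the conversion from MPE series. Interval
statistics follow the convention of arithmetic means of the two bounding
samples and forward differences across the interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, DomainError, PrecursorError
from .trial import ConcentrationSeries, EnrichmentSeries, TrialConfig

__all__ = [
    "total_ra",
    "exo_ra",
    "endo_ra",
    "total_rd",
    "exo_rd",
    "endo_rd",
    "kinetics_table",
    "cumulative_exo_appearance",
    "phe_plasma_percent",
]


def total_ra(f_iv, pv, c_mean, de_iv_dt, e_iv_mean):
    """Total Ra, μmol·kg⁻¹·min⁻¹. Reduces to F/E when dE/dt = 0."""
    e = np.asarray(e_iv_mean, dtype=float)
    if np.any(e <= 0):
        raise PrecursorError("IV tracer enrichment must be positive on every interval")
    return (f_iv - pv * np.asarray(c_mean) * np.asarray(de_iv_dt)) / e


def exo_ra(total_ra_val, e_oral_plasma_mean, de_oral_dt, c_mean, pv, e_oral_protein):
    """Exogenous (dietary) Ra. Identically 0 when no oral tracer circulates."""
    e_p = np.asarray(e_oral_plasma_mean, dtype=float)
    de = np.asarray(de_oral_dt, dtype=float)
    if e_oral_protein <= 0:
        if np.any(e_p != 0) or np.any(de != 0):
            raise ConfigError(
                "plasma oral-tracer enrichment is nonzero but the protein "
                "enrichment (E_oral) is not configured"
            )
        return np.zeros_like(e_p) if e_p.ndim else 0.0
    return (np.asarray(total_ra_val) * e_p + pv * np.asarray(c_mean) * de) / e_oral_protein


def endo_ra(total_ra_val, exo_ra_val, f_iv):
    """Endogenous Ra = whole-body protein breakdown (exact identity)."""
    return np.asarray(total_ra_val) - np.asarray(exo_ra_val) - f_iv


def total_rd(total_ra_val, pv, dc_dt):
    """Total Rd = total_Ra − pV·dC/dt; equals Ra for flat concentration."""
    return np.asarray(total_ra_val) - pv * np.asarray(dc_dt)


def exo_rd(total_rd_val, e_oral_plasma_mean, de_oral_dt, c_mean, pv, e_oral_protein):
    """Exogenous Rd, same oral-tracer split applied to disappearance."""
    return exo_ra(total_rd_val, e_oral_plasma_mean, de_oral_dt, c_mean, pv, e_oral_protein)


def endo_rd(total_rd_val, exo_rd_val):
    """Endogenous Rd = total_Rd − exo_Rd (exact identity)."""
    return np.asarray(total_rd_val) - np.asarray(exo_rd_val)


# ---------------------------------------------------------------------------


def _postprandial_grid(*series) -> np.ndarray:
    """Common postprandial (t ≥ 0) time grid; raises on misalignment."""
    grids = []
    for s in series:
        if s is None:
            continue
        grids.append(s.times[s.times >= 0])
    base = grids[0]
    for g in grids[1:]:
        if len(g) != len(base) or not np.array_equal(g, base):
            offending = sorted(set(base).symmetric_difference(set(g)))
            raise AlignmentError(
                f"series time grids are misaligned at times {offending}", offending
            )
    if len(base) < 2:
        raise DomainError("at least two postprandial sampling times are required")
    return base


def kinetics_table(
    conc: ConcentrationSeries,
    e_iv: EnrichmentSeries,
    e_oral: EnrichmentSeries | None,
    config: TrialConfig,
) -> pd.DataFrame:
    """Interval-wise phenylalanine kinetics over the postprandial period.

    Parameters
    ----------
    conc, e_iv, e_oral
        Plasma phenylalanine concentration, IV-tracer enrichment and
        oral-tracer enrichment series on a shared postprandial grid.
        ``e_oral=None`` (or an all-zero series with a placebo config)
        encodes the placebo arm.
    config
        Supplies F_phe,iv, pV and the protein enrichment E_oral.

    Returns
    -------
    DataFrame with one row per consecutive time pair: interval statistics,
    the six rates, and identity-residual check columns (both ≤ 1e-10 by
    construction).
    """
    times = _postprandial_grid(conc, e_iv, e_oral)

    def at(series_times, series_values):
        idx = np.searchsorted(series_times, times)
        return np.asarray(series_values, dtype=float)[idx]

    c = at(conc.times, conc.values)
    eiv = at(e_iv.times, e_iv.fractions)
    if e_oral is not None:
        eor = at(e_oral.times, e_oral.fractions)
    else:
        eor = np.zeros_like(eiv)

    dt = np.diff(times)
    c_mean = 0.5 * (c[:-1] + c[1:])
    dc_dt = np.diff(c) / dt
    eiv_mean = 0.5 * (eiv[:-1] + eiv[1:])
    deiv_dt = np.diff(eiv) / dt
    eor_mean = 0.5 * (eor[:-1] + eor[1:])
    deor_dt = np.diff(eor) / dt

    e_oral_protein = config.e_oral_phe_mpe / 100.0 if config.protein_dose_g > 0 else 0.0

    ra = total_ra(config.f_phe_iv, config.pv_phe, c_mean, deiv_dt, eiv_mean)
    rexo = exo_ra(ra, eor_mean, deor_dt, c_mean, config.pv_phe, e_oral_protein)
    rexo = np.broadcast_to(np.asarray(rexo, dtype=float), ra.shape).copy()
    rendo = endo_ra(ra, rexo, config.f_phe_iv)
    rd = total_rd(ra, config.pv_phe, dc_dt)
    rdexo = exo_rd(rd, eor_mean, deor_dt, c_mean, config.pv_phe, e_oral_protein)
    rdexo = np.broadcast_to(np.asarray(rdexo, dtype=float), rd.shape).copy()
    rdendo = endo_rd(rd, rdexo)

    return pd.DataFrame(
        {
            "t_start": times[:-1],
            "t_end": times[1:],
            "c_mean": c_mean,
            "dc_dt": dc_dt,
            "e_iv_mean": eiv_mean,
            "de_iv_dt": deiv_dt,
            "e_oral_mean": eor_mean,
            "de_oral_dt": deor_dt,
            "total_ra": ra,
            "exo_ra": rexo,
            "endo_ra": rendo,
            "total_rd": rd,
            "exo_rd": rdexo,
            "endo_rd": rdendo,
            "ra_identity_resid": ra - (rexo + rendo + config.f_phe_iv),
            "rd_identity_resid": rd - (ra - config.pv_phe * dc_dt),
        }
    )


def cumulative_exo_appearance(
    table: pd.DataFrame,
    t_start: float = 0.0,
    t_end: float | None = None,
    clamp_negative: bool = True,
) -> float:
    """Cumulative exogenous appearance over the window, μmol·kg⁻¹.

    Integrates the interval-mean exogenous Ra. Negative interval values
    (measurement noise; instantaneous negative appearance is unphysical) are
    clamped to 0 by default before integration.
    """
    if t_end is None:
        t_end = float(table["t_end"].iloc[-1])
    lo = np.maximum(table["t_start"].to_numpy(), t_start)
    hi = np.minimum(table["t_end"].to_numpy(), t_end)
    overlap = np.clip(hi - lo, 0.0, None)
    rates = table["exo_ra"].to_numpy()
    if clamp_negative:
        rates = np.clip(rates, 0.0, None)
    return float(np.sum(rates * overlap))


def phe_plasma_percent(
    table: pd.DataFrame,
    phe_oral_umol: float,
    body_mass_kg: float,
    t_start: float = 0.0,
    t_end: float | None = None,
    clamp_negative: bool = True,
) -> float:
    """Percentage of ingested phenylalanine that appeared in the circulation.

    100 · AUC(exo_Ra) · BM / Phe_oral. Undefined for placebo (raises).
    """
    if phe_oral_umol <= 0:
        raise DomainError("phe_plasma_percent is undefined for a placebo (Phe_oral = 0)")
    auc = cumulative_exo_appearance(table, t_start, t_end, clamp_negative)
    return 100.0 * auc * body_mass_kg / phe_oral_umol
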