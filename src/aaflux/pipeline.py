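"""End-to-end report generation for one trial bundle.

:func:`run_pipeline` chains the plasma kinetics, whole-body and
incorporation stages and assembles a metabolic-fate summary of the ingested
protein: grams released into the circulation, incorporated into muscle and
plasma protein, oxidized, and the residual (circulating or taken up
elsewhere). All tables are deterministic functions of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AAFluxError, DomainError
from .incorporation import fsr_table, mps_denovo, pp_denovo, exo_endo_contribution
from .io import TrialBundle
from .plasma_kinetics import cumulative_exo_appearance, kinetics_table, phe_plasma_percent
from .trial import Pool, Tracer
from .whole_body import aggregate_windows, umol_phe_to_g_protein, whole_body_table

__all__ = ["PipelineReport", "run_pipeline", "DEFAULT_WINDOWS"]

DEFAULT_WINDOWS = ((0.0, 240.0), (240.0, 480.0), (480.0, 720.0), (0.0, 720.0))


@dataclass(frozen=True)
class PipelineReport:
    kinetics: pd.DataFrame
    whole_body: pd.DataFrame              # per reporting window
    fsr: pd.DataFrame
    fate: pd.DataFrame                    # gram-scale partition of the ingested dose
    summary: dict = field(default_factory=dict)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except AAFluxError as exc:
        raise type(exc)(f"[{name}] {exc}") from exc


def _bound_gain(biopsies, fraction, tracer, t0, t1):
    vals = {
        b.time_min: b.bound_mpe[tracer]
        for b in biopsies
        if b.fraction == fraction and tracer in b.bound_mpe
    }
    if t0 not in vals or t1 not in vals:
        return None
    return vals[t1] - vals[t0]


def run_pipeline(bundle: TrialBundle, windows=DEFAULT_WINDOWS) -> PipelineReport:
    """Compute kinetics, whole-body, FSR and fate tables for one subject."""
    cfg = bundle.config
    placebo = cfg.protein_dose_g == 0

    kin = _stage(
        "plasma_kinetics",
        kinetics_table,
        bundle.concentrations["phe"],
        bundle.enrichments[Tracer.D5_PHE],
        bundle.enrichments.get(Tracer.C13_PHE) if not placebo else None,
        cfg,
    )

    if (
        "tyr" in bundle.concentrations
        and Tracer.D2_TYR in bundle.enrichments
        and Tracer.D4_TYR in bundle.enrichments
    ):
        wb_intervals = _stage(
            "whole_body",
            whole_body_table,
            kin,
            bundle.concentrations["tyr"],
            bundle.enrichments[Tracer.D2_TYR],
            bundle.enrichments[Tracer.D4_TYR],
            cfg,
        )
    else:
        wb_intervals = kin
    wb = _stage("whole_body", aggregate_windows, wb_intervals, list(windows))

    if bundle.biopsies:
        fsr_df = _stage(
            "incorporation",
            fsr_table,
            bundle.biopsies,
            {
                t: bundle.enrichments[t]
                for t in (Tracer.D5_PHE, Tracer.C13_LEU)
                if t in bundle.enrichments
            },
        )
    else:
        fsr_df = pd.DataFrame()

    fate_rows, summary = [], {}
    for (w0, w1) in windows:
        released_umol_kg = cumulative_exo_appearance(kin, w0, w1)
        released_g = umol_phe_to_g_protein(
            released_umol_kg * cfg.body_mass_kg, cfg.phe_fraction_of_protein
        )
        muscle_g = plasma_g = 0.0
        if not placebo and bundle.biopsies:
            gain = _bound_gain(bundle.biopsies, "mixed", Tracer.C13_PHE, w0, w1)
            if gain is not None:
                muscle_g = mps_denovo(cfg.skeletal_muscle_mass_g, gain, cfg.e_oral_phe_mpe)
            gain_p = _bound_gain(bundle.biopsies, "plasma_protein", Tracer.C13_PHE, w0, w1)
            if gain_p is not None:
                plasma_g = pp_denovo(cfg.body_mass_kg, gain_p, cfg.e_oral_phe_mpe)
        # exogenous share of oxidation: oxidation × (exo_Rd / total_Rd) per interval
        oxidized_g = 0.0
        if not placebo and "oxidation" in wb_intervals:
            tab = wb_intervals
            lo = np.maximum(tab["t_start"].to_numpy(), w0)
            hi = np.minimum(tab["t_end"].to_numpy(), w1)
            overlap = np.clip(hi - lo, 0.0, None)
            share = np.divide(
                np.clip(tab["exo_rd"].to_numpy(), 0, None),
                tab["total_rd"].to_numpy(),
                out=np.zeros(len(tab)),
                where=tab["total_rd"].to_numpy() > 0,
            )
            ox_exo_umol_kg = float(np.sum(tab["oxidation"].to_numpy() * share * overlap))
            oxidized_g = umol_phe_to_g_protein(
                ox_exo_umol_kg * cfg.body_mass_kg, cfg.phe_fraction_of_protein
            )
        fate_rows.append({
            "t_start": w0,
            "t_end": w1,
            "released_g": released_g,
            "incorporated_muscle_g": muscle_g,
            "incorporated_plasma_protein_g": plasma_g,
            "oxidized_exo_g": oxidized_g,
            "residual_g": released_g - muscle_g - plasma_g - oxidized_g,
        })
    fate = pd.DataFrame(fate_rows)

    if not placebo:
        summary["release_percent_720"] = phe_plasma_percent(
            kin, cfg.phe_oral_umol, cfg.body_mass_kg
        )
        gain_exo = _bound_gain(bundle.biopsies, "myofibrillar", Tracer.C13_PHE, 0.0, 720.0)
        gain_iv = _bound_gain(bundle.biopsies, "myofibrillar", Tracer.D5_PHE, 0.0, 720.0)
        if gain_exo is not None and gain_iv not in (None, 0.0):
            e_iv_mean = bundle.enrichments[Tracer.D5_PHE].time_weighted_mean(0.0, 720.0)
            exo_pct, endo_pct = exo_endo_contribution(
                gain_exo, cfg.e_oral_phe_mpe, gain_iv, e_iv_mean
            )
            summary["myofibrillar_exo_contribution_pct"] = exo_pct
            summary["myofibrillar_endo_contribution_pct"] = endo_pct
    summary["provenance"] = dict(bundle.provenance)
    return PipelineReport(kin, wb, fsr_df, fate, summary)
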