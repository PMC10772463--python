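"""Intrinsically labeled protein production and planning.

Milk protein biosynthetically enriched with tracer amino acids (by infusing
a lactating cow) lets the ingested protein itself be traced. Producing a
batch at an exact target enrichment is impractical, so higher- and
lower-enriched batches from the same infusion are blended; these helpers
solve the blend and plan the enrichment a steady-state design requires.

Blending is modeled as a mass-weighted linear combination of per-amino-acid
MPE, assuming equal protein content and amino acid profile across batches;
pass ``profile_weights`` to :func:`mix_batches` when the batches' amino acid
contents differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, InfeasibleMixError

__all__ = ["ProteinBatch", "mix_batches", "solve_mix_ratio", "plan_protein_enrichment"]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class ProteinBatch:
    """A protein batch with per-amino-acid tracer enrichments (MPE)."""

    batch_id: str
    enrichments_mpe: Mapping[str, float]
    mass_available_g: float | None = None

    def __post_init__(self):
        if not self.enrichments_mpe:
            raise DomainError("a batch must report at least one labeled amino acid")
        for aa, e in self.enrichments_mpe.items():
            if not (0 <= e < 100):
                raise DomainError(f"enrichment for {aa} must be in [0, 100), got {e}")
        if self.mass_available_g is not None and self.mass_available_g <= 0:
            raise DomainError("mass_available_g must be positive when given")


def mix_batches(
    batches: Sequence[ProteinBatch],
    weights: Sequence[float],
    profile_weights: Mapping[str, Sequence[float]] | None = None,
    batch_id: str = "mix",
) -> ProteinBatch:
    """Blend batches by mass fraction; enrichments combine linearly.

    ``weights`` are mass fractions that must sum to 1. ``profile_weights``
    optionally supplies, per amino acid, relative amino-acid contents of each
    batch (g amino acid per g protein) to weight the blend when profiles
    differ; by default profiles are assumed identical.
    """
    if len(batches) != len(weights):
        raise DomainError("one weight per batch required")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise DomainError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > _WEIGHT_TOL:
        raise DomainError(f"weights must sum to 1 (got {w.sum()!r})")

    keysets = [set(b.enrichments_mpe) for b in batches]
    if any(ks != keysets[0] for ks in keysets[1:]):
        raise DomainError(f"batches report different amino acids: {keysets}")

    mixed: dict[str, float] = {}
    for aa in sorted(keysets[0]):
        e = np.array([b.enrichments_mpe[aa] for b in batches])
        if profile_weights is not None and aa in profile_weights:
            p = np.asarray(profile_weights[aa], dtype=float)
            if len(p) != len(batches) or np.any(p <= 0):
                raise DomainError(f"profile weights for {aa} must be positive, one per batch")
            eff = w * p
            mixed[aa] = float(np.sum(eff * e) / np.sum(eff))
        else:
            mixed[aa] = float(np.sum(w * e))
    return ProteinBatch(batch_id=batch_id, enrichments_mpe=mixed)


def solve_mix_ratio(
    high: ProteinBatch, low: ProteinBatch, target_mpe: float, amino_acid: str
) -> float:
    """Mass fraction of the *high* batch that hits ``target_mpe`` for one amino acid.

    Closed-form inversion of the linear blend: w = (target − E_low) / (E_high − E_low).
    """
    try:
        e_hi = high.enrichments_mpe[amino_acid]
        e_lo = low.enrichments_mpe[amino_acid]
    except KeyError as exc:
        raise DomainError(f"amino acid {amino_acid!r} missing from a batch") from exc
    lo, hi = min(e_lo, e_hi), max(e_lo, e_hi)
    if e_hi == e_lo:
        raise InfeasibleMixError("batches have identical enrichment; ratio is undetermined")
    if not (lo <= target_mpe <= hi):
        raise InfeasibleMixError(
            f"target {target_mpe} MPE outside feasible range [{lo}, {hi}]"
        )
    return (target_mpe - e_lo) / (e_hi - e_lo)


def plan_protein_enrichment(f_iv: float, basal_ra: float) -> float:
    """Protein enrichment (MPE) that keeps plasma enrichment at plateau.

    A primed continuous infusion at rate ``f_iv`` on top of a basal
    appearance rate ``basal_ra`` (both μmol·kg⁻¹·min⁻¹) produces a plasma
    plateau enrichment of F/(Ra+F). If the ingested protein carries exactly
    this enrichment, absorbed amino acids neither dilute nor enrich the
    plasma tracer pool, so the plateau survives feeding.
    """
    if f_iv <= 0 or basal_ra <= 0:
        raise DomainError("infusion rate and basal Ra must both be positive")
    return 100.0 * f_iv / (basal_ra + f_iv)
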