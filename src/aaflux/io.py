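"""Tidy CSV readers/writers, configuration files, and provenance.

Plasma data travel as long-format CSV with columns
``subject_id, time_min, variable, value`` where ``variable`` is one of
``conc_phe, conc_tyr, conc_leu, e_d5phe, e_13cphe, e_d2tyr, e_d4tyr,
e_13cleu`` (concentrations in μmol·L⁻¹, enrichments in MPE). Biopsy data
use ``subject_id, time_min, fraction, tracer, pool, enrichment_mpe`` with
``pool`` in {bound, free}. Trial configuration is a flat TOML or YAML
document mirroring :class:`~aaflux.trial.TrialConfig` fields.
"""

from __future__ import annotations

import hashlib
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import ValidationError

from . import __version__
from .errors import ConfigError, SchemaError
from .incorporation import BiopsyRecord
from .trial import ConcentrationSeries, EnrichmentSeries, Pool, Tracer, TrialConfig

__all__ = [
    "TrialBundle",
    "read_trial_config",
    "read_plasma_csv",
    "write_plasma_csv",
    "read_biopsy_csv",
    "write_biopsy_csv",
    "read_trial",
    "write_trial",
]

CONC_VARIABLES = {"conc_phe": "phe", "conc_tyr": "tyr", "conc_leu": "leu"}
ENRICH_VARIABLES = {
    "e_d5phe": Tracer.D5_PHE,
    "e_13cphe": Tracer.C13_PHE,
    "e_d2tyr": Tracer.D2_TYR,
    "e_d4tyr": Tracer.D4_TYR,
    "e_13cleu": Tracer.C13_LEU,
}
_ENRICH_NAME = {v: k for k, v in ENRICH_VARIABLES.items()}


@dataclass(frozen=True)
class TrialBundle:
    """Validated inputs for one subject plus input provenance."""

    config: TrialConfig
    concentrations: dict[str, ConcentrationSeries]
    enrichments: dict[Tracer, EnrichmentSeries]
    biopsies: list[BiopsyRecord] = field(default_factory=list)
    subject_id: str = "S01"
    provenance: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_trial_config(path: str | Path) -> TrialConfig:
    """Load a flat TOML/YAML config; warn on unknown keys, fail on bad values."""
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    elif path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
    else:
        raise SchemaError(f"unsupported config format: {path.suffix}")
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a flat key-value document")
    known = set(TrialConfig.model_fields)
    unknown = set(data) - known
    if unknown:
        warnings.warn(f"{path}: ignoring unknown config keys {sorted(unknown)}", stacklevel=2)
        data = {k: v for k, v in data.items() if k in known}
    try:
        return TrialConfig(**data)
    except ValidationError as exc:
        raise ConfigError(f"{path}: invalid trial config: {exc}") from exc


def write_trial_config(config: TrialConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


# ---------------------------------------------------------------------------
# Plasma series


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")


def read_plasma_csv(path: str | Path, subject_id: str | None = None):
    """Read a tidy plasma CSV into concentration and enrichment series.

    Rows may arrive in any order; they are sorted by time. Returns
    ``(concentrations, enrichments, subject_id)``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, {"subject_id", "time_min", "variable", "value"}, path)
    subjects = df["subject_id"].unique()
    if subject_id is None:
        if len(subjects) != 1:
            raise SchemaError(f"{path}: multiple subjects {list(subjects)}; pass subject_id")
        subject_id = str(subjects[0])
    df = df[df["subject_id"].astype(str) == str(subject_id)]
    unknown = set(df["variable"]) - set(CONC_VARIABLES) - set(ENRICH_VARIABLES)
    if unknown:
        warnings.warn(f"{path}: ignoring unknown variables {sorted(unknown)}", stacklevel=2)

    conc, enr = {}, {}
    for var, sub in df.groupby("variable"):
        sub = sub.sort_values("time_min")
        times = sub["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise SchemaError(f"{path}: duplicate time points for {var}")
        values = sub["value"].to_numpy(dtype=float)
        if var in CONC_VARIABLES:
            conc[CONC_VARIABLES[var]] = ConcentrationSeries(CONC_VARIABLES[var], times, values)
        elif var in ENRICH_VARIABLES:
            tracer = ENRICH_VARIABLES[var]
            enr[tracer] = EnrichmentSeries(tracer, Pool.PLASMA, times, values)
    return conc, enr, subject_id


def write_plasma_csv(
    concentrations: dict[str, ConcentrationSeries],
    enrichments: dict[Tracer, EnrichmentSeries],
    path: str | Path,
    subject_id: str = "S01",
) -> None:
    frames = []
    for name, series in sorted(concentrations.items()):
        var = {v: k for k, v in CONC_VARIABLES.items()}[name]
        frames.append(pd.DataFrame({
            "subject_id": subject_id, "time_min": series.times,
            "variable": var, "value": series.values,
        }))
    for tracer, series in sorted(enrichments.items(), key=lambda kv: kv[0].value):
        frames.append(pd.DataFrame({
            "subject_id": subject_id, "time_min": series.times,
            "variable": _ENRICH_NAME[tracer], "value": series.values_mpe,
        }))
    # %.17g guarantees binary round-trip of float64 values
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Biopsies


def read_biopsy_csv(path: str | Path, subject_id: str | None = None) -> list[BiopsyRecord]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df, {"subject_id", "time_min", "fraction", "tracer", "pool", "enrichment_mpe"}, path
    )
    if subject_id is not None:
        df = df[df["subject_id"].astype(str) == str(subject_id)]
    bad_pool = set(df["pool"]) - {"bound", "free"}
    if bad_pool:
        raise SchemaError(f"{path}: pool must be 'bound' or 'free', got {sorted(bad_pool)}")
    records = []
    for (t, fraction), sub in sorted(df.groupby(["time_min", "fraction"])):
        bound, free = {}, {}
        for _, row in sub.iterrows():
            tracer = Tracer(row["tracer"])
            (bound if row["pool"] == "bound" else free)[tracer] = float(row["enrichment_mpe"])
        records.append(BiopsyRecord(float(t), str(fraction), bound, free))
    return records


def write_biopsy_csv(
    biopsies: list[BiopsyRecord], path: str | Path, subject_id: str = "S01"
) -> None:
    rows = []
    for b in sorted(biopsies, key=lambda b: (b.time_min, b.fraction)):
        for pool, d in (("bound", b.bound_mpe), ("free", b.free_mpe)):
            for tracer, e in sorted(d.items(), key=lambda kv: kv[0].value):
                rows.append({
                    "subject_id": subject_id, "time_min": b.time_min,
                    "fraction": b.fraction, "tracer": tracer.value,
                    "pool": pool, "enrichment_mpe": e,
                })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Bundles


def read_trial(
    plasma_path: str | Path,
    config_path: str | Path,
    biopsy_path: str | Path | None = None,
    subject_id: str | None = None,
) -> TrialBundle:
    """Load and validate one subject's trial data with provenance digests."""
    config = read_trial_config(config_path)
    conc, enr, subject_id = read_plasma_csv(plasma_path, subject_id)
    biopsies = read_biopsy_csv(biopsy_path, subject_id) if biopsy_path else []
    provenance = {
        "tool": f"aaflux {__version__}",
        "inputs": {
            str(plasma_path): _sha256(Path(plasma_path)),
            str(config_path): _sha256(Path(config_path)),
            **({str(biopsy_path): _sha256(Path(biopsy_path))} if biopsy_path else {}),
        },
        "config": config.model_dump(),
    }
    return TrialBundle(config, conc, enr, biopsies, subject_id, provenance)


def write_trial(
    bundle: TrialBundle,
    plasma_path: str | Path,
    config_path: str | Path,
    biopsy_path: str | Path | None = None,
) -> None:
    """Inverse of :func:`read_trial` (provenance digests are recomputed on read)."""
    write_plasma_csv(bundle.concentrations, bundle.enrichments, plasma_path, bundle.subject_id)
    write_trial_config(bundle.config, config_path)
    if biopsy_path is not None:
        write_biopsy_csv(bundle.biopsies, biopsy_path, bundle.subject_id)
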