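"""Readers, writers and configuration for the partitioning pipeline.

All interchange is plain delimited text (CSV) plus one structured YAML
config format, because the domain's data volumes are tiny and published
tables are the interchange reality.

Documented column schemas
-------------------------
Steady-state isotope table (one row per core, effluent values)::

    core_id, treatment,
    no3_d15N,  no3_d15N_sd,  no3_cap17O, no3_cap17O_sd,
    no2_d15N,  no2_d15N_sd,  no2_cap17O, no2_cap17O_sd,
    trn_d15N,  trn_d15N_sd,
    n2o_d15N,  n2o_d15N_sd,  n2o_cap17O, n2o_cap17O_sd,
    n2o_SP,    n2o_SP_sd
    [optional: no3_uM, no2_uM, nh4_uM, n2o_uM]

All isotope values in permil, concentrations in uM.  Absent measurements are
written as ``ND``, ``^`` or an empty cell and parsed to explicit missing
values (never 0).

Incubation time-series table (long format)::

    core_id, species, time_d, influent_uM, effluent_uM, flow_mL_min

Endmember config (YAML): see the shipped ``data/endmembers_default.yaml``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .exceptions import ConfigurationError, TableParseError
from .flux import FluxRecord, IncubationSeries
from .isotopes import IsotopeComposition, PoolMeasurement, SteadyStateRecord
from .massbalance import (
    Endmember,
    EndmemberSet,
    MonteCarloSummary,
    ProcessFractions,
    ScenarioSpec,
)
from .synthetic import CoreTruth

__all__ = [
    "MISSING_TOKENS",
    "read_steady_table",
    "write_steady_table",
    "read_timeseries_table",
    "write_timeseries_table",
    "load_endmembers",
    "default_endmember_path",
    "load_scenarios",
    "write_flux_table",
    "write_truths_table",
    "config_hash",
]

#: Cell tokens that denote an absent measurement.
MISSING_TOKENS = {"", "ND", "^", "NA", "NaN", "nan", None}

# (column prefix, record species, isotope field) triples of the steady table.
_ISO_COLUMNS: Tuple[Tuple[str, str, str], ...] = (
    ("no3_d15N", "NO3", "d15N_bulk"),
    ("no3_cap17O", "NO3", "cap17O"),
    ("no2_d15N", "NO2", "d15N_bulk"),
    ("no2_cap17O", "NO2", "cap17O"),
    ("trn_d15N", "TRN", "d15N_bulk"),
    ("n2o_d15N", "N2O", "d15N_bulk"),
    ("n2o_cap17O", "N2O", "cap17O"),
    ("n2o_SP", "N2O", "SP"),
)
_CONC_COLUMNS: Tuple[Tuple[str, str], ...] = (
    ("no3_uM", "NO3"), ("no2_uM", "NO2"), ("nh4_uM", "NH4"), ("n2o_uM", "N2O"),
)
_KNOWN_COLUMNS = (
    {"core_id", "treatment"}
    | {c for c, _, _ in _ISO_COLUMNS}
    | {f"{c}_sd" for c, _, _ in _ISO_COLUMNS}
    | {c for c, _ in _CONC_COLUMNS}
)

_TS_COLUMNS = ("core_id", "species", "time_d", "influent_uM",
               "effluent_uM", "flow_mL_min")


def _parse_cell(raw, path, line: int, column: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if s in MISSING_TOKENS:
        return None
    try:
        return float(s)
    except ValueError:
        raise TableParseError(
            f"{path}: line {line}, column {column!r}: "
            f"cannot parse {s!r} as a number") from None


def read_steady_table(path: Union[str, Path]) -> List[SteadyStateRecord]:
    """Parse a steady-state isotope table into typed records.

    ``ND``/``^``/empty cells become explicit absent values.  Unknown
    columns, unparseable cells and duplicate core_ids raise
    :class:`TableParseError` locating the problem.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True,
                     comment="#")
    unknown = set(df.columns) - _KNOWN_COLUMNS
    if unknown:
        raise TableParseError(
            f"{path}: unknown column(s) {sorted(unknown)}; "
            f"expected a subset of {sorted(_KNOWN_COLUMNS)}")
    for required in ("core_id", "treatment"):
        if required not in df.columns:
            raise TableParseError(f"{path}: missing required column {required!r}")

    records: List[SteadyStateRecord] = []
    seen: Dict[str, int] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        core_id = str(row["core_id"]).strip()
        if core_id in seen:
            raise TableParseError(
                f"{path}: line {line}: duplicate core_id {core_id!r} "
                f"(first seen on line {seen[core_id]})")
        seen[core_id] = line
        fields: Dict[str, Dict[str, float]] = {}
        sds: Dict[str, Dict[str, float]] = {}
        for col, species, iso_field in _ISO_COLUMNS:
            if col in df.columns:
                v = _parse_cell(row[col], path, line, col)
                if v is not None:
                    fields.setdefault(species, {})[iso_field] = v
            sd_col = f"{col}_sd"
            if sd_col in df.columns:
                s = _parse_cell(row[sd_col], path, line, sd_col)
                if s is not None:
                    sds.setdefault(species, {})[iso_field] = s
        concs: Dict[str, float] = {}
        for col, species in _CONC_COLUMNS:
            if col in df.columns:
                v = _parse_cell(row[col], path, line, col)
                if v is not None:
                    concs[species] = v
        effluent = {}
        for species in set(fields) | set(concs):
            iso = IsotopeComposition(**fields.get(species, {}),
                                     sd=sds.get(species, {}))
            effluent[species] = PoolMeasurement(
                species=species, concentration=concs.get(species), isotopes=iso)
        records.append(SteadyStateRecord(
            core_id=core_id, treatment=str(row["treatment"]).strip(),
            effluent=effluent))
    return records


def write_steady_table(records: Sequence[SteadyStateRecord],
                       path: Union[str, Path]) -> None:
    """Write records in the steady-state table schema (absent -> ``ND``)."""
    rows = []
    for rec in records:
        row: Dict[str, object] = {"core_id": rec.core_id, "treatment": rec.treatment}
        for col, species, iso_field in _ISO_COLUMNS:
            v = rec.isotope(species, iso_field)
            s = rec.isotope_sd(species, iso_field)
            row[col] = "ND" if v is None else repr(v)
            row[f"{col}_sd"] = "ND" if s is None else repr(s)
        for col, species in _CONC_COLUMNS:
            pm = rec.effluent.get(species)
            c = None if pm is None else pm.concentration
            row[col] = "ND" if c is None else repr(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_timeseries_table(path: Union[str, Path],
                          outer_diameter: float = 10.0,
                          wall_thickness: float = 0.3175) -> List[IncubationSeries]:
    """Parse a long-format incubation time-series table.

    Rows are grouped by (core_id, species) and ordered by time.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True, comment="#")
    missing = set(_TS_COLUMNS) - set(df.columns)
    if missing:
        raise TableParseError(f"{path}: missing column(s) {sorted(missing)}")
    unknown = set(df.columns) - set(_TS_COLUMNS)
    if unknown:
        raise TableParseError(f"{path}: unknown column(s) {sorted(unknown)}")
    parsed = df.copy()
    for col in ("time_d", "influent_uM", "effluent_uM", "flow_mL_min"):
        parsed[col] = [
            _parse_cell(v, path, i + 2, col) for i, v in enumerate(df[col])]
        if any(v is None for v in parsed[col]):
            line = next(i + 2 for i, v in enumerate(parsed[col]) if v is None)
            raise TableParseError(
                f"{path}: line {line}, column {col!r}: value is required")
    out: List[IncubationSeries] = []
    for (core_id, species), g in parsed.groupby(["core_id", "species"], sort=True):
        g = g.sort_values("time_d")
        out.append(IncubationSeries(
            core_id=str(core_id), species=str(species),
            times=tuple(float(v) for v in g["time_d"]),
            influent_conc=tuple(float(v) for v in g["influent_uM"]),
            effluent_conc=tuple(float(v) for v in g["effluent_uM"]),
            flow_rate=tuple(float(v) for v in g["flow_mL_min"]),
            outer_diameter=outer_diameter, wall_thickness=wall_thickness))
    return out


def write_timeseries_table(series: Sequence[IncubationSeries],
                           path: Union[str, Path]) -> None:
    rows = []
    for s in series:
        for t, ci, ce, r in zip(s.times, s.influent_conc, s.effluent_conc,
                                s.flow_rate):
            rows.append({"core_id": s.core_id, "species": s.species,
                         "time_d": repr(t), "influent_uM": repr(ci),
                         "effluent_uM": repr(ce), "flow_mL_min": repr(r)})
    pd.DataFrame(rows, columns=list(_TS_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def default_endmember_path() -> Path:
    """Path of the shipped (non-authoritative) default endmember config."""
    return Path(str(resources.files("n2opart").joinpath(
        "data", "endmembers_default.yaml")))


def _mean_sd(node, name: str) -> Tuple[float, float]:
    if isinstance(node, Mapping):
        return float(node.get("mean")), float(node.get("sd", 0.0))
    raise ConfigurationError(f"{name} must be a mapping with mean/sd")


def load_endmembers(path: Union[str, Path, None] = None,
                    case: Optional[str] = None) -> EndmemberSet:
    """Load an endmember config file (default: the shipped one).

    ``case`` overrides the file's ``case`` entry ("fDNF" for case 1,
    "cDNF" for case 2); the four active endmembers are selected accordingly.
    """
    path = default_endmember_path() if path is None else Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "endmembers" not in doc:
        raise ConfigurationError(f"{path}: not an endmember config file")
    chosen = case or doc.get("case", "fDNF")
    if chosen not in ("fDNF", "cDNF"):
        raise ConfigurationError(f"{path}: case must be fDNF or cDNF, got {chosen!r}")
    table = doc["endmembers"]
    ems = []
    for proc in ("bDNF", chosen, "AMO", "nDNF"):
        if proc not in table:
            raise ConfigurationError(f"{path}: missing endmember {proc!r}")
        row = table[proc]
        dd = row.get("dd15N")
        ems.append(Endmember(
            process=proc,
            dd15N=None if dd is None else float(dd),
            dd15N_sd=float(row.get("dd15N_sd", 0.0)),
            SP=float(row["SP"]),
            SP_sd=float(row.get("SP_sd", 0.0)),
            o_transfer=float(row.get("o_transfer", 0.0))))
    eps_mean, eps_sd = _mean_sd(doc.get("amo_eps", {"mean": 3.7, "sd": 3.0}),
                                "amo_eps")
    return EndmemberSet(
        endmembers=tuple(ems),
        sp_eps_red=float(doc.get("sp_eps_red", -6.0)),
        n15_eps_red=float(doc.get("n15_eps_red", 0.0)),
        amo_eps=eps_mean, amo_eps_sd=eps_sd)


def load_scenarios(path: Union[str, Path]) -> Tuple[List[ScenarioSpec], List[float]]:
    """Load a scenario sweep config: a list of scenarios plus f_red values."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "scenarios" not in doc:
        raise ConfigurationError(f"{path}: not a scenario config file")
    specs = []
    for node in doc["scenarios"]:
        specs.append(ScenarioSpec(
            name=str(node["name"]),
            overrides={str(p): {str(k): float(v) for k, v in f.items()}
                       for p, f in (node.get("overrides") or {}).items()},
            case=node.get("case")))
    f_red = [float(v) for v in doc.get("f_red", [0.1, 0.9])]
    return specs, f_red


def config_hash(ems: EndmemberSet) -> str:
    """Short stable hash of an endmember configuration, for provenance."""
    payload = {
        "endmembers": [
            {"process": e.process, "dd15N": e.dd15N, "dd15N_sd": e.dd15N_sd,
             "SP": e.SP, "SP_sd": e.SP_sd, "o_transfer": e.o_transfer}
            for e in ems.endmembers],
        "sp_eps_red": ems.sp_eps_red, "n15_eps_red": ems.n15_eps_red,
        "amo_eps": ems.amo_eps, "amo_eps_sd": ems.amo_eps_sd,
    }
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode())
    return digest.hexdigest()[:12]


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_flux_table(records: Sequence[FluxRecord], path: Union[str, Path]) -> None:
    """Flux summary, one row per (core, species); negative = sediment uptake."""
    rows = [{
        "core_id": r.core_id, "species": r.species, "flux": r.flux,
        "flux_sd": r.flux_sd, "units": r.units,
        "window_start_d": r.steady_state_window[0],
        "window_end_d": r.steady_state_window[1], "n_points": r.n_points,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truths_table(truths: Sequence[CoreTruth], path: Union[str, Path]) -> None:
    """Sidecar table of synthetic ground truths, for recovery scoring."""
    rows = []
    for t in truths:
        row = {"core_id": t.core_id, "treatment": t.treatment,
               "f_red": t.fractions.f_red}
        for p, f in zip(t.fractions.processes, t.fractions.fractions):
            row[f"true_f_{p}"] = f
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def mc_summary_row(summary: MonteCarloSummary, core_id: str, treatment: str,
                   scenario: str, cfg_hash: str) -> Dict[str, object]:
    """Flatten a MonteCarloSummary into one provenance-stamped table row."""
    row: Dict[str, object] = {
        "core_id": core_id, "treatment": treatment, "scenario": scenario,
        "f_red": summary.f_red, "n_draws": summary.n_draws,
        "seed": summary.seed, "config_hash": cfg_hash,
        "infeasible_fraction": summary.infeasible_fraction,
        "high_infeasibility": summary.high_infeasibility,
    }
    for i, p in enumerate(summary.processes):
        row[f"mean_{p}"] = summary.mean[i]
        row[f"sd_{p}"] = summary.sd[i]
        row[f"q025_{p}"] = summary.q025[i]
        row[f"q500_{p}"] = summary.q500[i]
        row[f"q975_{p}"] = summary.q975[i]
    return row
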