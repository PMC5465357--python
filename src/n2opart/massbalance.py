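"""Four-process isotope mass-balance inversion for N2O source partitioning.

The steady-state N2O efflux from a sediment core is modelled as a mixture of
four production processes — bacterial denitrification (bDNF), fungal
denitrification (fDNF) *or* chemodenitrification (cDNF), ammonia oxidation
via NH2OH decomposition (AMO, bacterial + archaeal pooled), and
nitrifier-denitrification (nDNF) — partially consumed by bacterial N2O
reduction (a prescribed fraction f_red of gross production).

Three measured tracers plus closure give four linear constraints on the
fractional contributions f_i:

    (i)   sum_i f_i                      = 1
    (ii)  sum_i f_i * o_transfer_i       = cap17O(N2O) / cap17O(NO2)
    (iii) sum_i f_i * dd15N_i  - f_red * eps15_red = dd15N_meas
    (iv)  sum_i f_i * SP_i     - f_red * epsSP_red = SP_meas

where dd15N_meas = d15N(NO3) - d15N(N2O) is the steady-state nitrate-to-N2O
offset, SP_meas the measured site preference, and o_transfer_i the fraction
of the process's product oxygen inheriting the steady-state NO2- anomaly
(1 for the NO2--consuming denitrification pathways, 0 for AMO and — in the
base case — for nDNF, whose substrate NO2- derives directly from NH4+
oxidation and carries no anomaly).  N2O reduction is mass dependent, so it
shifts SP (epsSP_red = -6 permil, raising the SP of the residual pool) but
leaves the oxygen anomaly ratio untouched.

With f_red prescribed (it cannot be solved from 4 equations along with 4
unknowns), the system is linear and solved exactly; negative solutions are
diagnostics of endmember misfit and are clipped to the simplex for
presentation.  Uncertainty is propagated by Monte Carlo over independent
Gaussian perturbations of both measured compositions and endmember
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .exceptions import (
    CollinearityError,
    ConfigurationError,
    InfeasibleSolutionError,
    InvalidValueError,
    MissingMeasurementError,
)
from .isotopes import DEFAULT_ANOMALY_FLOOR, SteadyStateRecord, precursor_fraction

__all__ = [
    "PROCESSES_CASE1",
    "PROCESSES_CASE2",
    "Endmember",
    "EndmemberSet",
    "ProcessFractions",
    "MonteCarloSummary",
    "ScenarioSpec",
    "amo_dd15N",
    "default_endmember_set",
    "builtin_scenarios",
    "build_system",
    "solve_fractions",
    "clip_renormalize",
    "forward_model",
    "partition_core",
    "run_monte_carlo",
    "run_scenarios",
]

#: Case 1 considers fungal denitrification; case 2 swaps in chemodenitrification.
PROCESSES_CASE1 = ("bDNF", "fDNF", "AMO", "nDNF")
PROCESSES_CASE2 = ("bDNF", "cDNF", "AMO", "nDNF")
_ALL_PROCESSES = ("bDNF", "fDNF", "cDNF", "AMO", "nDNF")

#: Raw fractions outside [-tol, 1+tol] flag the solution as infeasible.
FEASIBILITY_TOL = 0.02

_COND_LIMIT = 1e10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Endmember:
    """Isotopic endmember of one N2O production process.

    dd15N is on the common nitrate-referenced scale
    (d15N_NO3 - d15N_N2O expected if the process acted alone); SP in permil;
    o_transfer is the coefficient multiplying the steady-state NO2- anomaly
    in the oxygen balance, in [0, 1].  dd15N may be None only for AMO, whose
    value is derived from measured d15N of NO3- and TRN plus the
    NH3-to-N2O fractionation (see :func:`amo_dd15N`).
    """

    process: str
    dd15N: Optional[float]
    SP: float
    o_transfer: float
    dd15N_sd: float = 0.0
    SP_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.process not in _ALL_PROCESSES:
            raise ConfigurationError(
                f"unknown process {self.process!r}; expected one of {_ALL_PROCESSES}")
        if self.dd15N is None and self.process != "AMO":
            raise ConfigurationError(
                f"dd15N may be unresolved only for AMO, not {self.process}")
        if not (0.0 <= self.o_transfer <= 1.0):
            raise ConfigurationError(
                f"o_transfer must be in [0, 1], got {self.o_transfer}")
        for name in ("dd15N_sd", "SP_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class EndmemberSet:
    """Endmembers for the four active processes plus reduction constants.

    Exactly one of fDNF (case 1) / cDNF (case 2) is active.  ``sp_eps_red``
    is the kinetic isotope effect on SP of N2O reduction (-6 permil: the
    residual N2O pool gains SP as it is consumed); ``n15_eps_red`` the
    corresponding bulk-d15N effect on the dd15N scale (0 by default);
    ``amo_eps`` the NH3-to-N2O 15N fractionation of ammonia oxidation
    (3.7 +/- 3 permil, product depleted relative to the NH3 source).
    """

    endmembers: Tuple[Endmember, ...]
    sp_eps_red: float = -6.0
    n15_eps_red: float = 0.0
    amo_eps: float = 3.7
    amo_eps_sd: float = 3.0

    def __post_init__(self) -> None:
        procs = tuple(e.process for e in self.endmembers)
        if len(procs) != 4 or len(set(procs)) != 4:
            raise ConfigurationError(
                f"need exactly 4 distinct processes, got {procs}")
        n_dnf_variants = sum(p in ("fDNF", "cDNF") for p in procs)
        if n_dnf_variants != 1:
            raise ConfigurationError(
                "exactly one of fDNF/cDNF must be active, got "
                f"{n_dnf_variants} of them in {procs}")
        if self.amo_eps_sd < 0:
            raise ConfigurationError("amo_eps_sd must be >= 0")

    @property
    def processes(self) -> Tuple[str, ...]:
        return tuple(e.process for e in self.endmembers)

    @property
    def case(self) -> str:
        return "case2" if "cDNF" in self.processes else "case1"

    def get(self, process: str) -> Endmember:
        for e in self.endmembers:
            if e.process == process:
                return e
        raise KeyError(process)

    def with_amo_dd15N(self, d15N_NO3: float, d15N_NH4: float) -> "EndmemberSet":
        """Resolve the AMO endmember dd15N from measured pool compositions."""
        value = amo_dd15N(d15N_NO3, d15N_NH4, self.amo_eps)
        new = tuple(
            replace(e, dd15N=value, dd15N_sd=self.amo_eps_sd)
            if e.process == "AMO" else e
            for e in self.endmembers)
        return replace(self, endmembers=new)

    def with_overrides(self, overrides: Mapping[str, Mapping[str, float]],
                       case: Optional[str] = None) -> "EndmemberSet":
        """Return a copy with per-process field overrides applied.

        ``case="cDNF"`` (or ``"fDNF"``) first swaps the active
        denitrification variant, taking the replacement endmember from the
        default table unless also overridden.
        """
        ems = self
        if case is not None:
            if case not in ("fDNF", "cDNF"):
                raise ConfigurationError(f"case must be fDNF or cDNF, got {case!r}")
            current = "cDNF" if "cDNF" in ems.processes else "fDNF"
            if case != current:
                replacement = _default_endmember(case)
                new = tuple(replacement if e.process == current else e
                            for e in ems.endmembers)
                ems = replace(ems, endmembers=new)
        active = ems.processes
        for proc, fields in overrides.items():
            if proc not in active:
                raise ConfigurationError(
                    f"override references inactive process {proc!r} "
                    f"(active: {active})")
            em = ems.get(proc)
            em = replace(em, **dict(fields))
            new = tuple(em if e.process == proc else e for e in ems.endmembers)
            ems = replace(ems, endmembers=new)
        return ems


@dataclass(frozen=True)
class ProcessFractions:
    """Fractional contributions of the four processes for one core.

    ``fractions`` follows the order of ``processes``.  ``raw`` keeps the
    unclipped linear solution (possibly outside [0, 1]) when the instance is
    the result of clipping; ``feasible`` is False when any raw fraction lies
    outside [-tol, 1+tol].
    """

    processes: Tuple[str, ...]
    fractions: Tuple[float, ...]
    f_red: float
    residual_norm: float = 0.0
    feasible: bool = True
    raw: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(self.processes) != len(self.fractions):
            raise InvalidValueError("processes/fractions length mismatch")
        if not (0.0 <= self.f_red <= 1.0):
            raise InvalidValueError(f"f_red must be in [0, 1], got {self.f_red}")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.processes, self.fractions))

    def __getitem__(self, process: str) -> float:
        return self.as_dict()[process]


@dataclass(frozen=True)
class MonteCarloSummary:
    """Distributional summary of clipped process fractions over MC draws."""

    processes: Tuple[str, ...]
    mean: Tuple[float, ...]
    sd: Tuple[float, ...]
    q025: Tuple[float, ...]
    q500: Tuple[float, ...]
    q975: Tuple[float, ...]
    infeasible_fraction: float
    n_draws: int
    seed: int
    f_red: float
    high_infeasibility: bool = False

    def interval(self, process: str) -> Tuple[float, float]:
        i = self.processes.index(process)
        return (self.q025[i], self.q975[i])


@dataclass(frozen=True)
class ScenarioSpec:
    """A named endmember-sensitivity scenario.

    ``overrides`` maps an active process name to field overrides
    (e.g. ``{"nDNF": {"dd15N": 28.0}}``); ``case`` optionally swaps the
    fDNF/cDNF variant.
    """

    name: str
    overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    case: Optional[str] = None


# ---------------------------------------------------------------------------
# Default endmember table
# ---------------------------------------------------------------------------

# NON-AUTHORITATIVE defaults: literature-guided placeholder endmembers.
# Denitrification dd15N endmembers are prescribed low because diffusion
# limitation suppresses expression of the intrinsic enzyme-level isotope
# effects in organic-rich sediments; fDNF SP ~37 reflects the fungal P450nor
# pathway; cDNF SP reflects Fe(II)-driven nitrite reduction (>10 permil, up
# to ~26); nDNF dd15N = 56.9 from culture work on nitrifiers under varying
# oxygen.  All values are overridable via the endmember config file.
_DEFAULT_TABLE: Dict[str, Dict[str, float]] = {
    "bDNF": {"dd15N": 0.0, "dd15N_sd": 2.0, "SP": -5.0, "SP_sd": 5.0, "o_transfer": 1.0},
    "fDNF": {"dd15N": 0.0, "dd15N_sd": 2.0, "SP": 37.0, "SP_sd": 3.0, "o_transfer": 1.0},
    "cDNF": {"dd15N": 0.0, "dd15N_sd": 2.0, "SP": 16.0, "SP_sd": 5.0, "o_transfer": 1.0},
    "AMO": {"dd15N": None, "dd15N_sd": 3.0, "SP": 33.0, "SP_sd": 4.0, "o_transfer": 0.0},
    "nDNF": {"dd15N": 56.9, "dd15N_sd": 5.0, "SP": -5.0, "SP_sd": 5.0, "o_transfer": 0.0},
}


def _default_endmember(process: str) -> Endmember:
    row = _DEFAULT_TABLE[process]
    return Endmember(process=process, dd15N=row["dd15N"], SP=row["SP"],
                     o_transfer=row["o_transfer"], dd15N_sd=row["dd15N_sd"],
                     SP_sd=row["SP_sd"])


def default_endmember_set(case: str = "fDNF") -> EndmemberSet:
    """Shipped default endmembers for case 1 (fDNF) or case 2 (cDNF).

    These defaults are placeholders documented in the endmember config file;
    any serious application should supply its own endmember table.
    """
    if case not in ("fDNF", "cDNF"):
        raise ConfigurationError(f"case must be 'fDNF' or 'cDNF', got {case!r}")
    procs = ("bDNF", case, "AMO", "nDNF")
    return EndmemberSet(endmembers=tuple(_default_endmember(p) for p in procs))


def builtin_scenarios() -> List[ScenarioSpec]:
    """The shipped sensitivity scenarios (base plus the classic four knobs).

    Sweeps the nDNF dd15N endmember down from 56.9 to 28 and 14 permil,
    lowers the fungal SP endmember from 37 to 30.3 permil, lets nDNF draw on
    the ambient (anomalous) NO2- pool (o_transfer 0 -> 1), and swaps
    chemodenitrification for fungal denitrification (case 2).
    """
    return [
        ScenarioSpec("base"),
        ScenarioSpec("nDNF_dd15N_28", {"nDNF": {"dd15N": 28.0}}),
        ScenarioSpec("nDNF_dd15N_14", {"nDNF": {"dd15N": 14.0}}),
        ScenarioSpec("fDNF_SP_30.3", {"fDNF": {"SP": 30.3}}),
        ScenarioSpec("nDNF_o_transfer_1", {"nDNF": {"o_transfer": 1.0}}),
        ScenarioSpec("case2_cDNF", case="cDNF"),
    ]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def amo_dd15N(d15N_NO3: float, d15N_NH4: float, eps: float) -> float:
    """AMO endmember on the nitrate-referenced dd15N scale.

    The NH3-to-N2O fractionation eps (product depleted) acts on the ammonium
    substrate, so referencing to nitrate requires adding the steady-state
    d15N offset between the NO3- and NH4+ pools:

        dd15N_AMO = (d15N_NO3 - d15N_NH4) + eps
    """
    for name, v in (("d15N_NO3", d15N_NO3), ("d15N_NH4", d15N_NH4), ("eps", eps)):
        if v is None or not math.isfinite(v):
            raise InvalidValueError(f"{name} must be finite, got {v!r}")
    return (d15N_NO3 - d15N_NH4) + eps


def build_system(meas: Mapping[str, float], ems: EndmemberSet,
                 f_red: float) -> Tuple[np.ndarray, np.ndarray, Tuple[str, ...]]:
    """Assemble the 4x4 linear system A f = b.

    ``meas`` needs ``dd15N_meas``, ``SP_meas`` and ``o_ratio_meas``
    (the measured cap17O(N2O)/cap17O(NO2) ratio).  The prescribed reduction
    terms are moved to the right-hand side:

        b = [1,  o_ratio,  dd15N_meas + f_red*n15_eps_red,
                 SP_meas + f_red*sp_eps_red]

    so that reduction with sp_eps_red < 0 lowers the SP the production
    mixture must explain (the residual pool having been enriched).
    Raises :class:`CollinearityError` on rank deficiency, naming duplicated
    endmembers when the degeneracy is pairwise.
    """
    for key in ("dd15N_meas", "SP_meas", "o_ratio_meas"):
        v = meas.get(key)
        if v is None or not math.isfinite(v):
            raise InvalidValueError(f"meas[{key!r}] must be finite, got {v!r}")
    if not (0.0 <= f_red <= 1.0):
        raise InvalidValueError(f"f_red must be in [0, 1], got {f_red}")
    processes = ems.processes
    cols = []
    for e in ems.endmembers:
        if e.dd15N is None:
            raise ConfigurationError(
                f"endmember {e.process} has unresolved dd15N; call "
                "with_amo_dd15N() or partition_core() first")
        cols.append((1.0, e.o_transfer, e.dd15N, e.SP))
    A = np.array(cols, dtype=float).T  # rows: sum, O, dd15N, SP
    b = np.array([
        1.0,
        meas["o_ratio_meas"],
        meas["dd15N_meas"] + f_red * ems.n15_eps_red,
        meas["SP_meas"] + f_red * ems.sp_eps_red,
    ])
    if np.linalg.cond(A) > _COND_LIMIT:
        for i in range(4):
            for j in range(i + 1, 4):
                if np.allclose(A[:, i], A[:, j], atol=1e-9):
                    raise CollinearityError(
                        f"endmembers {processes[i]} and {processes[j]} are "
                        "identical in (dd15N, SP, o_transfer); system is singular")
        raise CollinearityError(
            f"endmember geometry for {processes} is rank-deficient")
    return A, b, processes


def solve_fractions(system: Tuple[np.ndarray, np.ndarray, Tuple[str, ...]],
                    f_red: float = 0.0,
                    tol: float = FEASIBILITY_TOL) -> ProcessFractions:
    """Exact solution of the mass-balance system (raw, unclipped).

    Fractions may lie outside [0, 1]; ``feasible`` is False when any does so
    by more than ``tol``.  The residual norm of the returned solution is
    reported (it is ~0 for an exactly solvable full-rank system).
    """
    A, b, processes = system
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise CollinearityError(f"singular mass-balance system: {exc}") from exc
    residual = float(np.linalg.norm(A @ x - b))
    feasible = bool(np.all(x >= -tol) and np.all(x <= 1 + tol))
    return ProcessFractions(processes=processes, fractions=tuple(float(v) for v in x),
                            f_red=f_red, residual_norm=residual, feasible=feasible)


def clip_renormalize(raw: ProcessFractions) -> ProcessFractions:
    """Project a raw solution onto the simplex for presentation.

    Small negative contributions are considered equal to zero and the
    remaining values reweighted to sum to 1.  Idempotent.  Raises
    :class:`InfeasibleSolutionError` when no entry is positive.
    """
    x = np.asarray(raw.fractions, dtype=float)
    clipped = np.where(x > 0, x, 0.0)
    total = clipped.sum()
    if total <= 0:
        raise InfeasibleSolutionError(
            f"all fractional contributions non-positive for "
            f"{dict(zip(raw.processes, raw.fractions))}")
    clipped /= total
    return ProcessFractions(
        processes=raw.processes, fractions=tuple(float(v) for v in clipped),
        f_red=raw.f_red, residual_norm=raw.residual_norm,
        feasible=raw.feasible, raw=raw.raw if raw.raw is not None else raw.fractions)


def forward_model(truth: ProcessFractions,
                  ems: EndmemberSet) -> Dict[str, float]:
    """Compose the measured tracers implied by known fractions (no noise).

    Exact inverse of build->solve: partitioning the returned measurement
    dict recovers ``truth``.  Requires a feasible truth on the simplex.
    """
    x = np.asarray(truth.fractions, dtype=float)
    if np.any(x < -1e-12) or abs(x.sum() - 1.0) > 1e-9:
        raise InvalidValueError(
            f"truth fractions must be >= 0 and sum to 1, got {truth.fractions}")
    if truth.processes != ems.processes:
        raise ConfigurationError(
            f"truth processes {truth.processes} do not match endmember set "
            f"{ems.processes}")
    o_t, dd, sp = [], [], []
    for e in ems.endmembers:
        if e.dd15N is None:
            raise ConfigurationError(
                f"endmember {e.process} has unresolved dd15N")
        o_t.append(e.o_transfer)
        dd.append(e.dd15N)
        sp.append(e.SP)
    return {
        "o_ratio_meas": float(np.dot(x, o_t)),
        "dd15N_meas": float(np.dot(x, dd) - truth.f_red * ems.n15_eps_red),
        "SP_meas": float(np.dot(x, sp) - truth.f_red * ems.sp_eps_red),
    }


_REQUIRED_FIELDS = (
    ("NO3", "d15N_bulk"),
    ("N2O", "d15N_bulk"),
    ("N2O", "SP"),
    ("NO2", "cap17O"),
    ("N2O", "cap17O"),
    ("TRN", "d15N_bulk"),
)


def _measurements(record: SteadyStateRecord) -> Dict[Tuple[str, str], float]:
    vals = {}
    for species, fname in _REQUIRED_FIELDS:
        v = record.isotope(species, fname)
        if v is None:
            raise MissingMeasurementError(
                f"record {record.core_id!r} ({record.treatment}) lacks "
                f"effluent {species} {fname}, required for partitioning")
        vals[(species, fname)] = v
    return vals


def partition_core(record: SteadyStateRecord, ems: EndmemberSet,
                   f_red: float,
                   anomaly_floor: float = DEFAULT_ANOMALY_FLOOR) -> ProcessFractions:
    """Partition one core's steady-state N2O efflux among the four processes.

    Computes dd15N_meas = d15N(NO3) - d15N(N2O), the oxygen anomaly ratio
    cap17O(N2O)/cap17O(NO2), resolves the AMO endmember from the record's
    NO3-/TRN d15N (TRN standing proxy for NH4+), then builds, solves and
    clips.  Returns the clipped fractions, with the raw solution and the
    feasibility flag attached.
    """
    v = _measurements(record)
    o_ratio = precursor_fraction(v[("N2O", "cap17O")], v[("NO2", "cap17O")],
                                 floor=anomaly_floor)
    ems_resolved = ems.with_amo_dd15N(v[("NO3", "d15N_bulk")],
                                      v[("TRN", "d15N_bulk")])
    meas = {
        "dd15N_meas": v[("NO3", "d15N_bulk")] - v[("N2O", "d15N_bulk")],
        "SP_meas": v[("N2O", "SP")],
        "o_ratio_meas": o_ratio,
    }
    system = build_system(meas, ems_resolved, f_red)
    raw = solve_fractions(system, f_red=f_red)
    return clip_renormalize(raw)


def run_monte_carlo(record: SteadyStateRecord, ems: EndmemberSet,
                    f_red: float, n_draws: int = 10_000,
                    seed: int = 0,
                    anomaly_floor: float = DEFAULT_ANOMALY_FLOOR) -> MonteCarloSummary:
    """Monte Carlo propagation of measurement and endmember uncertainty.

    Per draw, every measured composition used by the inversion and every
    endmember parameter with a nonzero standard deviation is perturbed by an
    independent Gaussian; the system is solved and the solution clipped to
    the simplex.  Draws in which all fractions are non-positive, the
    perturbed precursor anomaly falls below the informative floor, or the
    solve fails are counted as infeasible and excluded from the summaries.
    Results are reproducible for a fixed seed.
    """
    if n_draws < 100:
        raise ConfigurationError(f"n_draws must be >= 100, got {n_draws}")
    if not (0.0 <= f_red <= 1.0):
        raise InvalidValueError(f"f_red must be in [0, 1], got {f_red}")
    vals = _measurements(record)
    sds = {}
    for species, fname in _REQUIRED_FIELDS:
        s = record.isotope_sd(species, fname)
        if s is None:
            raise MissingMeasurementError(
                f"record {record.core_id!r} lacks an s.d. for effluent "
                f"{species} {fname}, required for Monte Carlo propagation")
        sds[(species, fname)] = s

    rng = np.random.default_rng(seed)
    n = int(n_draws)

    # Measurement draws (fixed order for reproducibility).
    m = {key: rng.normal(vals[key], sds[key], n) for key in _REQUIRED_FIELDS}

    # Endmember draws: dd15N and SP per process; AMO dd15N is recomputed per
    # draw from the perturbed NO3-/TRN d15N and a perturbed NH3->N2O eps.
    processes = ems.processes
    A = np.empty((n, 4, 4))
    A[:, 0, :] = 1.0
    eps_draw = rng.normal(ems.amo_eps, ems.amo_eps_sd, n)
    for j, e in enumerate(ems.endmembers):
        A[:, 1, j] = e.o_transfer
        if e.process == "AMO":
            A[:, 2, j] = (m[("NO3", "d15N_bulk")] - m[("TRN", "d15N_bulk")]
                          + eps_draw)
        else:
            A[:, 2, j] = rng.normal(e.dd15N, e.dd15N_sd, n)
        A[:, 3, j] = rng.normal(e.SP, e.SP_sd, n)

    denom = m[("NO2", "cap17O")]
    informative = np.abs(denom) >= anomaly_floor
    o_ratio = np.where(informative, m[("N2O", "cap17O")] / np.where(informative, denom, 1.0), np.nan)

    b = np.empty((n, 4))
    b[:, 0] = 1.0
    b[:, 1] = o_ratio
    b[:, 2] = (m[("NO3", "d15N_bulk")] - m[("N2O", "d15N_bulk")]
               + f_red * ems.n15_eps_red)
    b[:, 3] = m[("N2O", "SP")] + f_red * ems.sp_eps_red

    x = np.full((n, 4), np.nan)
    solvable = informative & np.isfinite(b).all(axis=1)
    try:
        x[solvable] = np.linalg.solve(A[solvable], b[solvable][..., None])[..., 0]
    except np.linalg.LinAlgError:
        for i in np.nonzero(solvable)[0]:  # rare: per-draw fallback
            try:
                x[i] = np.linalg.solve(A[i], b[i])
            except np.linalg.LinAlgError:
                x[i] = np.nan

    clipped = np.where(x > 0, x, 0.0)
    totals = clipped.sum(axis=1)
    ok = np.isfinite(x).all(axis=1) & (totals > 0)
    clipped[ok] /= totals[ok, None]

    n_ok = int(ok.sum())
    infeasible_fraction = 1.0 - n_ok / n
    if n_ok == 0:
        nan4 = (float("nan"),) * 4
        return MonteCarloSummary(processes, nan4, nan4, nan4, nan4, nan4,
                                 1.0, n, seed, f_red, high_infeasibility=True)
    good = clipped[ok]
    q = np.percentile(good, [2.5, 50.0, 97.5], axis=0)
    return MonteCarloSummary(
        processes=processes,
        mean=tuple(float(v) for v in good.mean(axis=0)),
        sd=tuple(float(v) for v in good.std(axis=0, ddof=1)),
        q025=tuple(float(v) for v in q[0]),
        q500=tuple(float(v) for v in q[1]),
        q975=tuple(float(v) for v in q[2]),
        infeasible_fraction=infeasible_fraction,
        n_draws=n, seed=seed, f_red=f_red,
        high_infeasibility=infeasible_fraction > 0.5)


def run_scenarios(records: Union[SteadyStateRecord, Sequence[SteadyStateRecord]],
                  base_ems: EndmemberSet,
                  scenarios: Optional[Sequence[ScenarioSpec]] = None,
                  f_red_values: Sequence[float] = (0.1, 0.9)):
    """Clipped fractions per (core x scenario x f_red) as a DataFrame.

    ``scenarios`` defaults to :func:`builtin_scenarios`.  Cores whose raw
    solution is entirely non-positive under a scenario are reported with NaN
    fractions and ``feasible = False`` rather than aborting the sweep.
    """
    import pandas as pd

    if isinstance(records, SteadyStateRecord):
        records = [records]
    if scenarios is None:
        scenarios = builtin_scenarios()
    rows = []
    for spec in scenarios:
        ems = base_ems.with_overrides(spec.overrides, case=spec.case)
        for rec in records:
            for f_red in f_red_values:
                row = {"core_id": rec.core_id, "treatment": rec.treatment,
                       "scenario": spec.name, "f_red": f_red}
                try:
                    pf = partition_core(rec, ems, f_red)
                except InfeasibleSolutionError:
                    for p in ems.processes:
                        row[f"f_{p}"] = float("nan")
                        row[f"raw_{p}"] = float("nan")
                    row["feasible"] = False
                    row["residual_norm"] = float("nan")
                else:
                    for p, f, r in zip(pf.processes, pf.fractions, pf.raw):
                        row[f"f_{p}"] = f
                        row[f"raw_{p}"] = r
                    row["feasible"] = pf.feasible
                    row["residual_norm"] = pf.residual_norm
                rows.append(row)
    return pd.DataFrame(rows)
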