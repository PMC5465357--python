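"""Forward generator of synthetic flow-through incubation studies.

Emulates the statistical structure the inference assumes: each core has a
known ("true") set of process fractions, a prescribed N2O-reduction extent,
source-pool isotope compositions and steady-state concentrations; observed
records are the exact forward-model composition plus independent Gaussian
measurement noise, and concentration time series approach steady state
exponentially.  Everything is bit-reproducible under a fixed seed.

Default magnitudes follow the treatment structure of a nitrate-amendment
incubation experiment: high-nitrate (HN/LOHN) treatments carry a positive
nitrate 17O-excess near +15 permil (atmospherically derived amendment), and
only those treatments have measurable cap17O, so the low-nitrate (LN/LOLN)
records are — by construction — rejected by the oxygen-anomaly based
partitioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ConfigurationError, InvalidValueError
from .flux import IncubationSeries
from .isotopes import IsotopeComposition, PoolMeasurement, SteadyStateRecord
from .massbalance import EndmemberSet, ProcessFractions, forward_model

__all__ = [
    "CoreTruth",
    "SyntheticStudy",
    "DEFAULT_NOISE",
    "TREATMENTS",
    "SITES",
    "default_truth",
    "generate_steady_record",
    "generate_timeseries",
    "generate_study",
]

TREATMENTS = ("LN", "LOLN", "HN", "LOHN")
SITES = ("MD", "MX", "SD")
_HIGH_NITRATE = ("HN", "LOHN")

#: Default per-quantity measurement noise (1 s.d.), at the scale of the
#: treatment-mean dispersions of steady-state isotope tables from
#: flow-through incubations: d15N in permil, cap17O in permil, SP in permil.
DEFAULT_NOISE: Dict[str, float] = {
    "d15N_NO3": 0.2,
    "d15N_NO2": 1.8,
    "d15N_TRN": 1.1,
    "d15N_N2O": 0.6,
    "SP": 3.0,
    "cap17O_NO3": 0.7,
    "cap17O_NO2": 1.2,
    "cap17O_N2O": 1.2,
    "conc_frac": 0.03,  # relative concentration noise in time series
}

#: Typical steady-state concentrations (uM): influent and effluent by
#: treatment class.  Effluent values imply nitrate uptake and N2O/NO2-/NH4+
#: efflux of realistic magnitude for organic-rich intertidal sediment.
_DEFAULT_CONC = {
    "low": {
        "influent": {"NO3": 20.0, "NO2": 0.1, "NH4": 0.5, "N2O": 0.01},
        "effluent": {"NO3": 7.5, "NO2": 1.9, "NH4": 19.0, "N2O": 0.057},
    },
    "high": {
        "influent": {"NO3": 140.0, "NO2": 0.1, "NH4": 0.5, "N2O": 0.01},
        "effluent": {"NO3": 112.0, "NO2": 3.5, "NH4": 23.0, "N2O": 0.14},
    },
}

#: Typical source-pool compositions by treatment class (permil).
_DEFAULT_SOURCES = {
    "low": {"d15N_NO3": 14.0, "d15N_NO2": 6.6, "d15N_TRN": 11.9,
            "cap17O_NO3": None, "cap17O_NO2": None},
    "high": {"d15N_NO3": 4.6, "d15N_NO2": -1.2, "d15N_TRN": 11.9,
             "cap17O_NO3": 14.7, "cap17O_NO2": 8.5},
}

#: Default true process fractions (bDNF, fDNF, AMO, nDNF): denitrification-
#: dominated with a large fungal share, the regime the inversion targets.
DEFAULT_TRUE_FRACTIONS = (0.45, 0.36, 0.12, 0.07)


def _treatment_class(treatment: str) -> str:
    return "high" if treatment in _HIGH_NITRATE else "low"


@dataclass(frozen=True)
class CoreTruth:
    """Ground truth for one synthetic core.

    ``fractions`` carries the true process contributions and the true
    reduction extent f_red.  ``cap17O_NO3``/``cap17O_NO2`` must be positive
    for HN/LOHN treatments and absent (None) for LN/LOLN, mirroring the fact
    that the 17O-excess tracer exists only where anomalous nitrate was
    amended.  ``tau_days`` is the e-folding timescale of the approach to
    steady state.
    """

    core_id: str
    treatment: str
    fractions: ProcessFractions
    d15N_NO3: float
    d15N_TRN: float
    cap17O_NO3: Optional[float] = None
    cap17O_NO2: Optional[float] = None
    d15N_NO2: Optional[float] = None
    influent_conc: Mapping[str, float] = field(default_factory=dict)
    effluent_conc: Mapping[str, float] = field(default_factory=dict)
    tau_days: float = 0.5
    noise: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise InvalidValueError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.treatment in _HIGH_NITRATE:
            if self.cap17O_NO3 is None or self.cap17O_NO3 <= 0:
                raise InvalidValueError(
                    f"{self.treatment} truth requires cap17O_NO3 > 0")
            if self.cap17O_NO2 is None:
                raise InvalidValueError(
                    f"{self.treatment} truth requires cap17O_NO2")
        else:
            if self.cap17O_NO3 is not None or self.cap17O_NO2 is not None:
                raise InvalidValueError(
                    f"{self.treatment} truth must have cap17O fields absent "
                    "(the anomaly tracer is only present under nitrate amendment)")
        if self.tau_days <= 0:
            raise InvalidValueError(f"tau_days must be > 0, got {self.tau_days}")


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete generated study: truths, records and time series."""

    truths: Tuple[CoreTruth, ...]
    records: Tuple[SteadyStateRecord, ...]
    timeseries: Tuple[IncubationSeries, ...]
    seed: int


def default_truth(core_id: str, treatment: str,
                  fractions: Sequence[float] = DEFAULT_TRUE_FRACTIONS,
                  f_red: float = 0.1,
                  processes: Tuple[str, ...] = ("bDNF", "fDNF", "AMO", "nDNF"),
                  **overrides) -> CoreTruth:
    """A CoreTruth with study-default compositions and concentrations."""
    cls = _treatment_class(treatment)
    src = _DEFAULT_SOURCES[cls]
    conc = _DEFAULT_CONC[cls]
    pf = ProcessFractions(processes=tuple(processes),
                          fractions=tuple(float(f) for f in fractions),
                          f_red=f_red)
    kwargs = dict(
        core_id=core_id, treatment=treatment, fractions=pf,
        d15N_NO3=src["d15N_NO3"], d15N_TRN=src["d15N_TRN"],
        d15N_NO2=src["d15N_NO2"],
        cap17O_NO3=src["cap17O_NO3"], cap17O_NO2=src["cap17O_NO2"],
        influent_conc=dict(conc["influent"]),
        effluent_conc=dict(conc["effluent"]))
    kwargs.update(overrides)
    return CoreTruth(**kwargs)


def _perturbed_endmembers(ems: EndmemberSet, rng: np.random.Generator) -> EndmemberSet:
    """Draw one 'true world' endmember realisation from the uncertainty model."""
    from dataclasses import replace
    new = []
    for e in ems.endmembers:
        dd = e.dd15N
        if e.process != "AMO" and e.dd15N_sd > 0:
            dd = float(rng.normal(e.dd15N, e.dd15N_sd))
        sp = float(rng.normal(e.SP, e.SP_sd)) if e.SP_sd > 0 else e.SP
        new.append(replace(e, dd15N=dd, SP=sp, dd15N_sd=e.dd15N_sd, SP_sd=e.SP_sd))
    eps = float(rng.normal(ems.amo_eps, ems.amo_eps_sd)) if ems.amo_eps_sd > 0 else ems.amo_eps
    return replace(ems, endmembers=tuple(new), amo_eps=eps)


def generate_steady_record(truth: CoreTruth, ems: EndmemberSet, seed: int = 0,
                           perturb_endmembers: bool = False) -> SteadyStateRecord:
    """Forward-compose one steady-state record with Gaussian noise.

    The noise-free tracers (dd15N, SP, oxygen-anomaly ratio) come from the
    exact forward model; they are converted to absolute pool compositions
    using the truth's source values and perturbed by the truth's noise
    levels, which are also recorded as the per-field standard deviations of
    the output record.  With ``perturb_endmembers=True`` the record is
    generated under a 'true world' endmember realisation drawn from the
    endmember uncertainty model — the design used in coverage studies.
    Identical (truth, ems, seed) always yields an identical record.
    """
    if truth.fractions.processes != ems.processes:
        raise ConfigurationError(
            f"truth processes {truth.fractions.processes} do not match "
            f"endmember set {ems.processes}")
    rng = np.random.default_rng(seed)
    world = _perturbed_endmembers(ems, rng) if perturb_endmembers else ems
    world = world.with_amo_dd15N(truth.d15N_NO3, truth.d15N_TRN)
    obs = forward_model(truth.fractions, world)

    noise = dict(DEFAULT_NOISE)
    noise.update(truth.noise)

    def _noisy(value: Optional[float], key: str) -> Optional[float]:
        if value is None:
            return None
        sd = noise.get(key, 0.0)
        return float(value + rng.normal(0.0, sd)) if sd > 0 else float(value)

    d15N_NO3 = _noisy(truth.d15N_NO3, "d15N_NO3")
    d15N_N2O = _noisy(truth.d15N_NO3 - obs["dd15N_meas"], "d15N_N2O")
    sp = _noisy(obs["SP_meas"], "SP")
    d15N_TRN = _noisy(truth.d15N_TRN, "d15N_TRN")
    d15N_NO2 = _noisy(truth.d15N_NO2, "d15N_NO2")
    if truth.cap17O_NO2 is not None:
        cap_no3 = _noisy(truth.cap17O_NO3, "cap17O_NO3")
        cap_no2 = _noisy(truth.cap17O_NO2, "cap17O_NO2")
        cap_n2o = _noisy(obs["o_ratio_meas"] * truth.cap17O_NO2, "cap17O_N2O")
    else:
        cap_no3 = cap_no2 = cap_n2o = None

    def _sd(*keys: str) -> Dict[str, float]:
        out = {}
        for field_name, key in keys:
            if noise.get(key, 0.0) > 0:
                out[field_name] = noise[key]
        return out

    eff = {
        "NO3": PoolMeasurement(
            "NO3", truth.effluent_conc.get("NO3"),
            isotopes=IsotopeComposition(
                d15N_bulk=d15N_NO3, cap17O=cap_no3,
                sd=_sd(("d15N_bulk", "d15N_NO3"), ("cap17O", "cap17O_NO3")))),
        "NO2": PoolMeasurement(
            "NO2", truth.effluent_conc.get("NO2"),
            isotopes=IsotopeComposition(
                d15N_bulk=d15N_NO2, cap17O=cap_no2,
                sd=_sd(("d15N_bulk", "d15N_NO2"), ("cap17O", "cap17O_NO2")))),
        "TRN": PoolMeasurement(
            "TRN", None,
            isotopes=IsotopeComposition(
                d15N_bulk=d15N_TRN, sd=_sd(("d15N_bulk", "d15N_TRN")))),
        "N2O": PoolMeasurement(
            "N2O", truth.effluent_conc.get("N2O"),
            isotopes=IsotopeComposition(
                d15N_bulk=d15N_N2O, SP=sp, cap17O=cap_n2o,
                sd=_sd(("d15N_bulk", "d15N_N2O"), ("SP", "SP"),
                       ("cap17O", "cap17O_N2O")))),
        "NH4": PoolMeasurement("NH4", truth.effluent_conc.get("NH4")),
    }
    return SteadyStateRecord(core_id=truth.core_id, treatment=truth.treatment,
                             effluent=eff)


def generate_timeseries(truth: CoreTruth, species: str = "N2O",
                        n_points: int = 16, duration_days: float = 8.0,
                        seed: int = 0,
                        flow_mean: float = 1.8,
                        flow_sd: float = 0.06) -> IncubationSeries:
    """Effluent concentration time series approaching steady state.

    c(t) = c_ss + (c_0 - c_ss) * exp(-t / tau), starting from the influent
    composition c_0; flow rate jitters around ``flow_mean`` mL/min with s.d.
    ``flow_sd``; additive Gaussian concentration noise at a relative level
    set by the truth's ``conc_frac`` noise entry.
    """
    if n_points < 6:
        raise ConfigurationError(f"n_points must be >= 6, got {n_points}")
    if duration_days < 8.0:
        raise ConfigurationError(
            f"duration must cover >= 8 days, got {duration_days}")
    if species not in truth.effluent_conc or species not in truth.influent_conc:
        raise ConfigurationError(
            f"truth {truth.core_id} has no concentrations for {species!r}")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.5, duration_days, n_points)
    c0 = float(truth.influent_conc[species])
    c_ss = float(truth.effluent_conc[species])
    clean = c_ss + (c0 - c_ss) * np.exp(-t / truth.tau_days)
    noise = dict(DEFAULT_NOISE)
    noise.update(truth.noise)
    sd = noise.get("conc_frac", 0.0) * max(abs(c_ss), abs(c0))
    eff = clean + rng.normal(0.0, sd, t.size) if sd > 0 else clean
    eff = np.clip(eff, 0.0, None)
    flow = rng.normal(flow_mean, flow_sd, t.size) if flow_sd > 0 else np.full(t.size, flow_mean)
    flow = np.clip(flow, 1e-6, None)
    return IncubationSeries(
        core_id=truth.core_id, species=species,
        times=tuple(float(v) for v in t),
        influent_conc=(c0,) * n_points,
        effluent_conc=tuple(float(v) for v in eff),
        flow_rate=tuple(float(v) for v in flow))


def generate_study(ems: EndmemberSet,
                   sites: Sequence[str] = SITES,
                   treatments: Sequence[str] = TREATMENTS,
                   cores_per_cell: int = 2,
                   seed: int = 0,
                   species: Sequence[str] = ("NO3", "NO2", "NH4", "N2O"),
                   fraction_alpha: float = 25.0,
                   perturb_endmembers: bool = False) -> SyntheticStudy:
    """Generate a full factorial incubation study (default 3 sites x 4
    treatments x 2 cores = 24 cores).

    Per-core true fractions are drawn from a Dirichlet distribution centred
    on the default denitrification-dominated pattern
    (concentration parameter ``fraction_alpha`` controls within-study
    heterogeneity); high-nitrate truths carry a positive nitrate anomaly,
    low-nitrate truths none.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    base = np.asarray(DEFAULT_TRUE_FRACTIONS, dtype=float)
    truths: List[CoreTruth] = []
    records: List[SteadyStateRecord] = []
    series: List[IncubationSeries] = []
    for site in sites:
        for treatment in treatments:
            for k in range(cores_per_cell):
                core_id = f"{site}-{treatment}-{k + 1}"
                frac = rng.dirichlet(base * fraction_alpha)
                truth = default_truth(core_id, treatment,
                                      fractions=tuple(float(f) for f in frac),
                                      processes=ems.processes)
                rec_seed = int(rng.integers(2 ** 31))
                ts_seeds = {sp: int(rng.integers(2 ** 31)) for sp in species}
                truths.append(truth)
                records.append(generate_steady_record(
                    truth, ems, seed=rec_seed,
                    perturb_endmembers=perturb_endmembers))
                for sp in species:
                    series.append(generate_timeseries(truth, species=sp,
                                                      seed=ts_seeds[sp]))
    return SyntheticStudy(truths=tuple(truths), records=tuple(records),
                          timeseries=tuple(series), seed=seed)
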