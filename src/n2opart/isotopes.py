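"""Scalar isotope algebra for N2O source partitioning.

Delta-notation arithmetic shared by every other module: site preference of
N2O, the triple-oxygen anomaly |Delta|17O, conservative concentration-weighted
mixing, precursor-fraction ratios from |Delta|17O, and the total-reduced-
nitrogen (TRN) d15N mass balance.

Units are permil throughout; concentrations are micromolar (uM).

Notation
--------
``d15N`` is the conventional delta value versus atmospheric N2,
``d18O``/``d17O`` versus VSMOW.  ``SP`` (site preference) is
``d15N_alpha - d15N_beta``, the intramolecular 15N difference between the
central (alpha) and outer (beta) nitrogen of the linear N2O molecule.
``cap17O`` is the 17O-excess |Delta|17O: the deviation of d17O from the
mass-dependent relation with d18O, conserved through mass-dependent
fractionation and diluted only by incorporation of O atoms from O2 or H2O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    InvalidValueError,
    UninformativeTracerError,
)

__all__ = [
    "IsotopeComposition",
    "PoolMeasurement",
    "SteadyStateRecord",
    "SPECIES",
    "site_preference",
    "alpha_beta_from_bulk_sp",
    "cap_delta_17O",
    "mix_pools",
    "precursor_fraction",
    "trn_d15N",
]

#: Recognised chemical species tags for pool measurements.
SPECIES = ("NO3", "NO2", "NH4", "TRN", "TDN", "N2O", "O2")

#: Default exponent of the mass-dependent fractionation relation between
#: d17O and d18O.  0.52 is the convention dominant in nitrate triple-oxygen
#: work; the admissible range reflects published mass-dependent slopes.
DEFAULT_LAMBDA = 0.52

#: Smallest precursor |Delta|17O (permil) considered informative for a
#: precursor-fraction ratio.
DEFAULT_ANOMALY_FLOOR = 1.0

_CONSISTENCY_TOL = 1e-9


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if v is None or not math.isfinite(v):
            raise InvalidValueError(f"{name} must be finite, got {v!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeComposition:
    """Isotopic composition of one nitrogen (or oxygen) pool, in permil.

    Every field is optional: absent measurements are represented as ``None``,
    never as 0 (input tables mark them "ND" or "^").  Standard deviations, when
    known, live in ``sd`` keyed by field name.

    When both ``d15N_alpha`` and ``d15N_beta`` are given, ``SP`` and
    ``d15N_bulk`` must agree with them (SP = alpha - beta,
    bulk = (alpha + beta)/2); construction fails loudly otherwise.
    """

    d15N_bulk: Optional[float] = None
    d15N_alpha: Optional[float] = None
    d15N_beta: Optional[float] = None
    SP: Optional[float] = None
    d18O: Optional[float] = None
    d17O: Optional[float] = None
    cap17O: Optional[float] = None
    sd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("d15N_bulk", "d15N_alpha", "d15N_beta", "SP",
                     "d18O", "d17O", "cap17O"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise InvalidValueError(f"{name} must be finite or None, got {v!r}")
        for name, s in self.sd.items():
            if s is None or not math.isfinite(s) or s < 0:
                raise InvalidValueError(f"sd[{name!r}] must be finite and >= 0")
        if self.d15N_alpha is not None and self.d15N_beta is not None:
            sp = self.d15N_alpha - self.d15N_beta
            if self.SP is not None and abs(self.SP - sp) > _CONSISTENCY_TOL:
                raise InvalidValueError(
                    f"SP={self.SP} inconsistent with alpha-beta={sp}")
            bulk = 0.5 * (self.d15N_alpha + self.d15N_beta)
            if self.d15N_bulk is not None and abs(self.d15N_bulk - bulk) > _CONSISTENCY_TOL:
                raise InvalidValueError(
                    f"d15N_bulk={self.d15N_bulk} inconsistent with (alpha+beta)/2={bulk}")

    def check_cap17O(self, lam: float = DEFAULT_LAMBDA, form: str = "linear",
                     atol: float = 1e-6) -> None:
        """Verify cap17O against (d17O, d18O) under the given convention.

        No-op when any of the three fields is absent.
        """
        if None in (self.d17O, self.d18O, self.cap17O):
            return
        expected = cap_delta_17O(self.d17O, self.d18O, lam, form)
        if abs(expected - self.cap17O) > atol:
            raise InvalidValueError(
                f"cap17O={self.cap17O} inconsistent with d17O/d18O "
                f"({form}, lambda={lam}): expected {expected:.6f}")


@dataclass(frozen=True)
class PoolMeasurement:
    """Concentration plus isotopic composition of one dissolved pool."""

    species: str
    concentration: Optional[float] = None
    concentration_sd: Optional[float] = None
    isotopes: IsotopeComposition = field(default_factory=IsotopeComposition)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise InvalidValueError(
                f"unknown species {self.species!r}; expected one of {SPECIES}")
        if self.concentration is not None and (
                not math.isfinite(self.concentration) or self.concentration < 0):
            raise InvalidValueError(
                f"concentration must be >= 0, got {self.concentration!r}")
        if self.concentration_sd is not None and (
                not math.isfinite(self.concentration_sd) or self.concentration_sd < 0):
            raise InvalidValueError("concentration_sd must be >= 0")


@dataclass(frozen=True)
class SteadyStateRecord:
    """One core's steady-state effluent (and optional influent) measurements.

    ``effluent`` and ``influent`` map species tags to
    :class:`PoolMeasurement`.  ``treatment`` is one of LN, LOLN, HN, LOHN
    (low/high nitrate crossed with ambient/low oxygen) but arbitrary labels
    are accepted.
    """

    core_id: str
    treatment: str
    effluent: Mapping[str, PoolMeasurement] = field(default_factory=dict)
    influent: Mapping[str, PoolMeasurement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for side_name, side in (("effluent", self.effluent), ("influent", self.influent)):
            for sp, pm in side.items():
                if pm.species != sp:
                    raise InvalidValueError(
                        f"{side_name}[{sp!r}] holds a {pm.species!r} measurement")

    def isotope(self, species: str, field_name: str) -> Optional[float]:
        pm = self.effluent.get(species)
        return None if pm is None else getattr(pm.isotopes, field_name)

    def isotope_sd(self, species: str, field_name: str) -> Optional[float]:
        pm = self.effluent.get(species)
        return None if pm is None else pm.isotopes.sd.get(field_name)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def site_preference(d15N_alpha: float, d15N_beta: float) -> float:
    """Site preference of N2O: d15N(alpha) - d15N(beta), in permil."""
    _require_finite(d15N_alpha=d15N_alpha, d15N_beta=d15N_beta)
    return d15N_alpha - d15N_beta


def alpha_beta_from_bulk_sp(d15N_bulk: float, SP: float) -> Tuple[float, float]:
    """Invert (bulk, SP) to the (alpha, beta) site-specific deltas.

    bulk = (alpha + beta)/2 and SP = alpha - beta give
    alpha = bulk + SP/2, beta = bulk - SP/2.
    """
    _require_finite(d15N_bulk=d15N_bulk, SP=SP)
    return d15N_bulk + SP / 2.0, d15N_bulk - SP / 2.0


def cap_delta_17O(d17O: float, d18O: float, lam: float = DEFAULT_LAMBDA,
                  form: str = "linear") -> float:
    """17O-excess |Delta|17O of a pool, in permil.

    Parameters
    ----------
    d17O, d18O
        Delta values versus VSMOW, permil.
    lam
        Exponent of the mass-dependent relation; must lie in (0.5, 0.535].
    form
        ``"linear"``: d17O - lam * d18O.
        ``"logarithmic"``: 1000 * (ln(1 + d17O/1000) - lam * ln(1 + d18O/1000)),
        the power-law definition linearised in delta space only for reporting.

    Both forms return exactly 0 for a pool on the mass-dependent line of the
    same form.  The conventions differ by about
    (d17O^2 - lam * d18O^2)/2000 permil (the ln(1+x) curvature): within
    ~0.05 permil for |delta| <= 10 permil but a few tenths of a permil near
    |delta| ~ 50, so comparisons of strongly fractionated pools should use
    one form consistently.
    """
    _require_finite(d17O=d17O, d18O=d18O)
    if not (0.5 < lam <= 0.535):
        raise ConfigurationError(
            f"lambda must be in (0.5, 0.535], got {lam}")
    if form == "linear":
        return d17O - lam * d18O
    if form == "logarithmic":
        return 1000.0 * (math.log1p(d17O / 1000.0) - lam * math.log1p(d18O / 1000.0))
    raise ConfigurationError(f"unknown cap17O form {form!r}")


def mix_pools(pools: Sequence[Tuple[float, float]]) -> float:
    """Concentration-weighted (conservative) mixture of a tracer value.

    ``pools`` is a sequence of (concentration uM, tracer value permil) pairs.
    Exactly conservative: invariant under pool reordering and under splitting
    any pool into sub-pools.
    """
    if not pools:
        raise DegenerateInputError("no pools to mix")
    total = 0.0
    weighted = 0.0
    for conc, value in pools:
        _require_finite(concentration=conc, value=value)
        if conc < 0:
            raise InvalidValueError(f"negative concentration {conc}")
        total += conc
        weighted += conc * value
    if total <= 0.0:
        raise DegenerateInputError("total concentration is zero")
    return weighted / total


def precursor_fraction(cap17O_product: float, cap17O_precursor: float,
                       floor: float = DEFAULT_ANOMALY_FLOOR) -> float:
    """Fraction of product O atoms inherited from an anomalous precursor pool.

    Because |Delta|17O is conserved through mass-dependent fractionation and
    diluted only by O-atom incorporation from O2/H2O (|Delta|17O ~ 0), the
    ratio cap17O(product)/cap17O(precursor) measures the fraction of product
    oxygen deriving from the precursor (e.g. N2O versus the NO2- pool).

    The value is *not* clamped: results outside [0, 1] are physically
    informative (they flag mass-balance violations) and are left to the
    caller.  A precursor anomaly smaller in magnitude than ``floor``
    (default 1 permil) makes the ratio uninformative and raises.
    """
    _require_finite(cap17O_product=cap17O_product, cap17O_precursor=cap17O_precursor)
    if floor <= 0:
        raise ConfigurationError(f"floor must be > 0, got {floor}")
    if abs(cap17O_precursor) < floor:
        raise UninformativeTracerError(
            f"precursor cap17O = {cap17O_precursor} permil is below the "
            f"informative floor of {floor} permil")
    return cap17O_product / cap17O_precursor


def trn_d15N(tdn: PoolMeasurement, no3: PoolMeasurement,
             no2: PoolMeasurement) -> float:
    """d15N of total reduced nitrogen (TRN = TDN - NO3 - NO2) by mass balance.

    Subtracts the molar d15N contribution of the nitrate and nitrite pools
    from the total-dissolved-nitrogen pool:

        d15N_TRN = (dTDN*[TDN] - dNO3*[NO3] - dNO2*[NO2]) / ([TDN]-[NO3]-[NO2])

    TRN is used downstream as a d15N proxy for the ammonium substrate of
    ammonia oxidation.
    """
    for pm, want in ((tdn, "TDN"), (no3, "NO3"), (no2, "NO2")):
        if pm.species != want:
            raise InvalidValueError(f"expected a {want} measurement, got {pm.species}")
        if pm.concentration is None:
            raise InvalidValueError(f"{want} concentration is absent")
        if pm.isotopes.d15N_bulk is None and not (
                want != "TDN" and pm.concentration == 0.0):
            raise InvalidValueError(f"{want} d15N is absent")
    c_tdn, c_no3, c_no2 = (tdn.concentration, no3.concentration, no2.concentration)
    c_trn = c_tdn - c_no3 - c_no2
    if c_trn <= 0:
        raise DegenerateInputError(
            f"TRN concentration {c_trn} uM is not positive "
            f"([TDN]={c_tdn}, [NO3]={c_no3}, [NO2]={c_no2})")
    num = tdn.isotopes.d15N_bulk * c_tdn
    if c_no3 > 0:
        num -= no3.isotopes.d15N_bulk * c_no3
    if c_no2 > 0:
        num -= no2.isotopes.d15N_bulk * c_no2
    return num / c_trn
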