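"""Core 16-state cis-regulatory model of the *eve* stripe 2 minimal stripe element (MSE).

The MSE is modeled with one effective binding site each for the activators
Bicoid (Bcd) and Hunchback (Hb) and the repressors Krüppel (Kr) and Giant
(Gt).  The regulatory state ``E[BHKG]`` is the bound/unbound status of the
four sites, giving 16 states on the 4-cube.  Transcription initiates only
from ``E[1000]`` (Bcd alone, LOW rate ``k_1000``) and ``E[1100]`` (Bcd plus
Hb, HIGH rate ``k_1100``); binding of either repressor blocks initiation.
Termination of a nascent transcript is first order with rate ``k_T``.

Sites bind independently: binding is pseudo-first-order ``k_bind * [TF]``
with the TF concentration an external, non-depleted input, and unbinding is
first order.  The stationary distribution over the 16 states is therefore a
product over per-site equilibria, which :func:`stationary_occupancy`
computes in closed form.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import yaml

__all__ = [
    "TF_NAMES",
    "RegulatoryState",
    "RateSet",
    "TFConcentration",
    "OccupancyVector",
    "ValidationReport",
    "MECHANISMS",
    "ONE_STATE_K_BIND_B",
    "enumerate_states",
    "initiation_rate",
    "transition_rates",
    "stationary_occupancy",
    "validate_rate_set",
    "rates_for_mechanism",
    "state_class",
]

#: Canonical TF ordering, matching the E[BHKG] label (B most significant).
TF_NAMES = ("bcd", "hb", "kr", "gt")

#: Recognized mechanism labels for :func:`validate_rate_set`.
MECHANISMS = ("two_state", "one_state_zero_high", "hb_mutant_zero_low")

#: Bcd binding constant of the one-ON-state (simple ON-OFF) mechanism,
#: 18% of the two-ON-state value, chosen so the single HIGH rate yields
#: full-scale RNA output.
ONE_STATE_K_BIND_B = 4.75e5


@dataclasses.dataclass(frozen=True, order=True)
class RegulatoryState:
    """Bound/unbound status of the four MSE sites, ordered B, H, K, G."""

    bcd_bound: bool
    hb_bound: bool
    kr_bound: bool
    gt_bound: bool

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.bcd_bound, self.hb_bound, self.kr_bound, self.gt_bound)

    @property
    def index(self) -> int:
        """Canonical index 0..15 with the Bcd bit most significant."""
        b, h, k, g = self.flags
        return (b << 3) | (h << 2) | (k << 1) | int(g)

    @property
    def label(self) -> str:
        """The E[BHKG] string, e.g. ``"E1100"``."""
        return "E" + "".join(str(int(f)) for f in self.flags)

    @classmethod
    def from_index(cls, index: int) -> "RegulatoryState":
        if not 0 <= index < 16:
            raise ValueError(f"state index out of range: {index}")
        return cls(bool(index & 8), bool(index & 4), bool(index & 2), bool(index & 1))

    @classmethod
    def from_label(cls, label: str) -> "RegulatoryState":
        if len(label) != 5 or label[0] != "E" or any(c not in "01" for c in label[1:]):
            raise ValueError(f"not an E[BHKG] label: {label!r}")
        return cls(*(c == "1" for c in label[1:]))

    def flip(self, site: int) -> "RegulatoryState":
        """Return the state with one site's flag toggled (0=B, 1=H, 2=K, 3=G)."""
        flags = list(self.flags)
        flags[site] = not flags[site]
        return RegulatoryState(*flags)


#: The two initiating states.
STATE_E1000 = RegulatoryState.from_label("E1000")
STATE_E1100 = RegulatoryState.from_label("E1100")
STATE_E0000 = RegulatoryState.from_label("E0000")


def enumerate_states() -> tuple[RegulatoryState, ...]:
    """All 16 regulatory states in canonical order (E0000 first, E1111 last)."""
    return tuple(RegulatoryState.from_index(i) for i in range(16))


def state_class(state: RegulatoryState) -> str:
    """Classify a state by its initiation activity: ``"high"``, ``"low"`` or ``"off"``."""
    if state == STATE_E1100:
        return "high"
    if state == STATE_E1000:
        return "low"
    return "off"


@dataclasses.dataclass
class RateSet:
    """All kinetic constants of the MSE model.

    Binding constants are second order (M^-1 s^-1); unbinding, initiation and
    termination are first order (s^-1).  Defaults are the calibrated values
    for the two-ON-state mechanism.  ``n_copies`` is the number of
    independent gene copies per nucleus sharing these constants.
    """

    k_bind_b: float = 2.6e6
    k_bind_h: float = 1.8e5
    k_bind_k: float = 9.9e6
    k_bind_g: float = 1.98e7
    k_unbind_b: float = 0.033
    k_unbind_h: float = 0.033
    k_unbind_k: float = 0.033
    k_unbind_g: float = 0.033
    k_1000: float = 0.09
    k_1100: float = 0.56
    k_T: float = 3.97e-3
    n_copies: int = 1

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "n_copies":
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
        if int(self.n_copies) != self.n_copies or self.n_copies < 1:
            raise ValueError(f"n_copies must be a positive integer, got {self.n_copies}")
        self.n_copies = int(self.n_copies)

    # -- convenience views -------------------------------------------------
    @property
    def k_bind(self) -> tuple[float, float, float, float]:
        return (self.k_bind_b, self.k_bind_h, self.k_bind_k, self.k_bind_g)

    @property
    def k_unbind(self) -> tuple[float, float, float, float]:
        return (self.k_unbind_b, self.k_unbind_h, self.k_unbind_k, self.k_unbind_g)

    def replace(self, **changes) -> "RateSet":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RateSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown rate keys: {sorted(unknown)}")
        return cls(**dict(d))

    # -- flat key-value config IO -----------------------------------------
    def to_file(self, path: str | Path) -> None:
        """Write as flat YAML (or JSON if the suffix is .json).

        Units: k_bind_* are M^-1 s^-1 (second order); all other rate
        constants are s^-1 (first order).
        """
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.as_dict(), indent=2))
        else:
            header = (
                "# MSE rate constants.\n"
                "# Units: k_bind_* in M^-1 s^-1; k_unbind_*, k_1000, k_1100, k_T in s^-1.\n"
            )
            path.write_text(header + yaml.safe_dump(self.as_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "RateSet":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclasses.dataclass
class TFConcentration:
    """TF concentrations (M) at one nucleus.

    ``bcd`` and ``hb`` are constants (activators are held fixed through the
    simulated window); ``kr`` and ``gt`` may be floats or callables of time
    (seconds) to represent the ten-fold repressor ramp.
    """

    bcd: float = 0.0
    hb: float = 0.0
    kr: float | Callable[[float], float] = 0.0
    gt: float | Callable[[float], float] = 0.0

    def __post_init__(self) -> None:
        for name in ("bcd", "hb"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} concentration must be finite and >= 0")
        for name in ("kr", "gt"):
            v = getattr(self, name)
            if not callable(v) and not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} concentration must be >= 0 or a callable")

    @property
    def is_constant(self) -> bool:
        return not (callable(self.kr) or callable(self.gt))

    def at(self, t: float) -> tuple[float, float, float, float]:
        """Concentrations (bcd, hb, kr, gt) at time ``t`` seconds."""
        kr = self.kr(t) if callable(self.kr) else self.kr
        gt = self.gt(t) if callable(self.gt) else self.gt
        return (self.bcd, self.hb, kr, gt)


@dataclasses.dataclass
class OccupancyVector:
    """Stationary probability of each of the 16 regulatory states."""

    probabilities: np.ndarray  # shape (16,), canonical state order
    site_occupancy: dict  # tf name -> per-site bound probability

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (16,):
            raise ValueError("probabilities must have shape (16,)")
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be in [0,1] and sum to 1")
        self.probabilities = p

    def prob(self, state: RegulatoryState | str) -> float:
        if isinstance(state, str):
            state = RegulatoryState.from_label(state)
        return float(self.probabilities[state.index])

    @property
    def bcd_bound_fraction(self) -> float:
        return float(self.site_occupancy["bcd"])


def initiation_rate(state: RegulatoryState, rates: RateSet) -> float:
    """Initiation rate (s^-1) of a regulatory state.

    Nonzero only for E[1000] (``k_1000``) and E[1100] (``k_1100``); any state
    with a repressor bound, or without Bcd, does not initiate.
    """
    if state == STATE_E1000:
        return rates.k_1000
    if state == STATE_E1100:
        return rates.k_1100
    return 0.0


def transition_rates(
    state: RegulatoryState,
    nascent_count: int,
    conc: TFConcentration,
    rates: RateSet,
    t: float = 0.0,
) -> dict[str, float]:
    """Propensities (s^-1) of every elementary reaction available from a state.

    One binding propensity ``k_bind_X * [X]`` per unbound site, one unbinding
    propensity ``k_unbind_X`` per bound site, an initiation propensity per
    :func:`initiation_rate`, and a termination propensity ``k_T * nascent``.
    """
    if nascent_count < 0:
        raise ValueError("nascent_count must be >= 0")
    c = conc.at(t)
    out: dict[str, float] = {}
    for i, name in enumerate(TF_NAMES):
        if state.flags[i]:
            out[f"unbind_{name}"] = rates.k_unbind[i]
        else:
            out[f"bind_{name}"] = rates.k_bind[i] * c[i]
    out["initiate"] = initiation_rate(state, rates)
    out["terminate"] = rates.k_T * nascent_count
    return out


def _site_occupancy(k_bind: float, conc: float, k_unbind: float) -> float:
    on = k_bind * conc
    denom = on + k_unbind
    if denom == 0.0:
        return 0.0  # defined limit: a site with no kinetics is never bound
    return on / denom


def stationary_occupancy(conc: TFConcentration, rates: RateSet) -> OccupancyVector:
    """Product-form stationary distribution over the 16 states.

    Sites bind independently, so the per-site occupancy is
    ``p_X = k_bind_X*[X] / (k_bind_X*[X] + k_unbind_X)`` and state
    probabilities are products over sites.  Concentrations must be constant
    in time (evaluated at t=0 otherwise an error is raised).
    """
    if not conc.is_constant:
        raise ValueError("stationary occupancy requires time-constant concentrations")
    c = conc.at(0.0)
    p_site = {
        name: _site_occupancy(rates.k_bind[i], c[i], rates.k_unbind[i])
        for i, name in enumerate(TF_NAMES)
    }
    probs = np.empty(16)
    for state in enumerate_states():
        p = 1.0
        for i, name in enumerate(TF_NAMES):
            p *= p_site[name] if state.flags[i] else (1.0 - p_site[name])
        probs[state.index] = p
    return OccupancyVector(probabilities=probs, site_occupancy=p_site)


@dataclasses.dataclass
class ValidationReport:
    mechanism: str
    valid: bool
    violations: list[str]

    def __bool__(self) -> bool:
        return self.valid


def validate_rate_set(rates: RateSet, mechanism: str = "two_state") -> ValidationReport:
    """Check a rate set against the structural requirements of a mechanism.

    ``two_state`` requires Hb co-activation with the HIGH rate above the LOW
    rate; the one-state mechanisms require the Hb site disabled, with the
    single initiation rate at HIGH (``one_state_zero_high``, k_1000 equal to
    k_1100) or at LOW (``hb_mutant_zero_low``, k_1000 below k_1100).
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; expected one of {MECHANISMS}")
    violations: list[str] = []
    if mechanism == "two_state":
        if not rates.k_1100 > rates.k_1000 > 0:
            violations.append("two_state requires k_1100 > k_1000 > 0")
        if not rates.k_bind_h > 0:
            violations.append("two_state requires k_bind_h > 0 (Hb co-activation)")
    else:
        if rates.k_bind_h != 0:
            violations.append(f"{mechanism} requires k_bind_h = 0 (Hb site disabled)")
        if mechanism == "one_state_zero_high" and rates.k_1000 != rates.k_1100:
            violations.append("one_state_zero_high requires k_1000 at the HIGH rate (= k_1100)")
        if mechanism == "hb_mutant_zero_low" and not rates.k_1000 < rates.k_1100:
            violations.append("hb_mutant_zero_low requires k_1000 at the LOW rate (< k_1100)")
    return ValidationReport(mechanism=mechanism, valid=not violations, violations=violations)


def rates_for_mechanism(mechanism: str, base: RateSet | None = None) -> RateSet:
    """Rate set for a named mechanism, derived from the calibrated two-state set.

    ``hb_mutant_zero_low`` disables Hb binding only (mutagenesis of the Hb
    site; half-scale output at the LOW rate).  ``one_state_zero_high``
    additionally raises the single initiation rate to HIGH and reduces Bcd
    binding to 18% so that full-scale RNA output is retained.
    """
    base = base if base is not None else RateSet()
    if mechanism == "two_state":
        return base
    if mechanism == "hb_mutant_zero_low":
        return base.replace(k_bind_h=0.0)
    if mechanism == "one_state_zero_high":
        return base.replace(k_bind_h=0.0, k_1000=base.k_1100, k_bind_b=ONE_STATE_K_BIND_B)
    raise ValueError(f"unknown mechanism {mechanism!r}; expected one of {MECHANISMS}")
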