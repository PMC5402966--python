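"""Exact stochastic simulation (Gillespie direct method) of the MSE model.

Each nucleus is an independent reaction system: four binding/unbinding site
toggles, initiation from E[1000]/E[1100], and first-order termination of
individual nascent transcripts.  There are no diffusing species coupling
nuclei (TF concentrations are external boundary inputs), so a stripe is an
embarrassingly parallel set of per-nucleus runs.

Time-varying repressor concentrations (the ten-fold Gt/Kr ramp) are handled
by piecewise-constant propensity updates on a configurable grid (default
1 s): within a slice, propensities are constant and the direct method is
exact; at a slice boundary the waiting time is re-drawn, which is valid for
exponential clocks.  Over the linear 45-minute ramp the rates change by
well under 0.1% per 1 s slice.

Seeding: every (position, replicate, copy) stream is derived from the base
seed with ``numpy.random.SeedSequence((base_seed, *keys))``, so ensembles
are bit-reproducible and individual nuclei can be re-simulated in
isolation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    RateSet,
    RegulatoryState,
    TFConcentration,
    state_class,
)
from .profiles import TFProfileSet

__all__ = [
    "NucleusTrajectory",
    "StripeEnsemble",
    "simulate_nucleus",
    "simulate_stripe",
    "extract_minute_series",
    "derive_rng",
]

_EVENT_LABELS = (
    "bind_bcd", "bind_hb", "bind_kr", "bind_gt",
    "unbind_bcd", "unbind_hb", "unbind_kr", "unbind_gt",
    "initiate", "terminate",
)


def derive_rng(seed) -> np.random.Generator:
    """Generator from an int seed or a tuple of (base_seed, *keys).

    String keys are hashed to stable integers so streams like
    ``(seed, position, replicate, "sampling")`` are reproducible.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, (tuple, list)):
        keys = tuple(
            int.from_bytes(k.encode(), "little") % (2**31) if isinstance(k, str) else int(k)
            for k in seed
        )
        return np.random.Generator(np.random.PCG64(np.random.SeedSequence(keys)))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))


@dataclasses.dataclass
class NucleusTrajectory:
    """Event-resolved stochastic trajectory of one nucleus.

    The log starts with a sentinel event at t=0 in E[0000] with zero
    nascent transcripts.  ``state_index`` is the canonical 0..15 index after
    each event (for multi-copy runs, the acting copy's state; per-copy logs
    are kept in ``copies``).  ``nascent`` is the total nascent count over
    all copies after each event.
    """

    duration: float
    position_el: float | None
    seed_keys: tuple
    event_times: np.ndarray
    event_labels: np.ndarray  # dtype=object/str
    state_index: np.ndarray
    nascent: np.ndarray
    cum_init: np.ndarray
    cum_term: np.ndarray
    copies: list["NucleusTrajectory"] | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) < 0):
            raise ValueError("event times must be non-decreasing")
        if np.any(self.nascent < 0):
            raise ValueError("nascent count must stay >= 0")

    @property
    def n_events(self) -> int:
        return len(self.event_times) - 1  # excluding the t=0 sentinel

    @property
    def total_initiations(self) -> int:
        return int(self.cum_init[-1])

    @property
    def total_terminations(self) -> int:
        return int(self.cum_term[-1])

    def nascent_at(self, times) -> np.ndarray:
        """Nascent count (step function from the event log) at given times (s)."""
        times = np.asarray(times, dtype=float)
        if np.any(times < 0) or np.any(times > self.duration + 1e-9):
            raise ValueError("sample time beyond trajectory duration")
        idx = np.searchsorted(self.event_times, times, side="right") - 1
        return self.nascent[idx]

    def state_at(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.event_times, times, side="right") - 1
        return self.state_index[idx]

    def dwell_seconds(self) -> np.ndarray:
        """Total time spent in each of the 16 regulatory states.

        For multi-copy trajectories this sums over copies (total dwell is
        then ``n_copies * duration``).
        """
        if self.copies is not None:
            return np.sum([c.dwell_seconds() for c in self.copies], axis=0)
        out = np.zeros(16)
        times = np.append(self.event_times, self.duration)
        np.add.at(out, self.state_index, np.diff(times))
        return out

    def dwell_fractions_by_class(self) -> dict[str, float]:
        """Fraction of time in OFF / LOW (E1000) / HIGH (E1100) state classes."""
        dwell = self.dwell_seconds()
        total = dwell.sum()
        out = {"off": 0.0, "low": 0.0, "high": 0.0}
        for i, d in enumerate(dwell):
            out[state_class(RegulatoryState.from_index(i))] += d / total
        return out

    def bcd_bound_fraction(self) -> float:
        """Fraction of time with the Bcd site bound (states E[1xxx])."""
        dwell = self.dwell_seconds()
        return float(dwell[8:].sum() / dwell.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = [RegulatoryState.from_index(i).label if i >= 0 else "multi"
                  for i in self.state_index]
        return pd.DataFrame({
            "position_el": self.position_el,
            "time_s": self.event_times,
            "event": self.event_labels,
            "state_label": labels,
            "nascent": self.nascent,
            "mrna_cum": self.cum_term,
        })


def _simulate_copy(
    conc: TFConcentration,
    rates: RateSet,
    duration: float,
    rng: np.random.Generator,
    update_grid: float,
    position_el: float | None,
    seed_keys: tuple,
) -> NucleusTrajectory:
    """Direct-method SSA for a single gene copy, E[0000] start."""
    kb = rates.k_bind
    ku = rates.k_unbind
    k_low, k_high, k_term = rates.k_1000, rates.k_1100, rates.k_T

    bound = [False, False, False, False]
    n = 0
    ci = ct = 0
    t = 0.0

    times = [0.0]
    labels = ["start"]
    states = [0]
    nasc = [0]
    cum_i = [0]
    cum_t = [0]

    constant = conc.is_constant
    cb, ch, ckr, cgt = conc.at(0.0)
    slice_end = duration if constant else min(update_grid, duration)

    exp = rng.exponential
    uni = rng.random

    while True:
        # propensities in fixed order: 4 site toggles, initiate, terminate
        a0c = ku[0] if bound[0] else kb[0] * cb
        a1c = ku[1] if bound[1] else kb[1] * ch
        a2c = ku[2] if bound[2] else kb[2] * ckr
        a3c = ku[3] if bound[3] else kb[3] * cgt
        if bound[0] and not (bound[1] or bound[2] or bound[3]):
            a_init = k_low
        elif bound[0] and bound[1] and not (bound[2] or bound[3]):
            a_init = k_high
        else:
            a_init = 0.0
        a_term = k_term * n
        a_tot = a0c + a1c + a2c + a3c + a_init + a_term

        if a_tot <= 0.0:
            t = slice_end
        else:
            t = t + exp(1.0 / a_tot)
        if t >= slice_end:
            if slice_end >= duration:
                break
            t = slice_end
            slice_end = min(slice_end + update_grid, duration)
            _, _, ckr, cgt = conc.at(t)
            continue

        r = uni() * a_tot
        if r < a0c:
            site, label = 0, ("unbind_bcd" if bound[0] else "bind_bcd")
        elif r < a0c + a1c:
            site, label = 1, ("unbind_hb" if bound[1] else "bind_hb")
        elif r < a0c + a1c + a2c:
            site, label = 2, ("unbind_kr" if bound[2] else "bind_kr")
        elif r < a0c + a1c + a2c + a3c:
            site, label = 3, ("unbind_gt" if bound[3] else "bind_gt")
        elif r < a0c + a1c + a2c + a3c + a_init:
            site, label = -1, "initiate"
        else:
            site, label = -2, "terminate"

        if site >= 0:
            bound[site] = not bound[site]
        elif site == -1:
            n += 1
            ci += 1
        else:
            n -= 1
            ct += 1

        times.append(t)
        labels.append(label)
        states.append((bound[0] << 3) | (bound[1] << 2) | (bound[2] << 1) | bound[3])
        nasc.append(n)
        cum_i.append(ci)
        cum_t.append(ct)

    return NucleusTrajectory(
        duration=duration,
        position_el=position_el,
        seed_keys=seed_keys,
        event_times=np.asarray(times),
        event_labels=np.asarray(labels, dtype=object),
        state_index=np.asarray(states, dtype=np.int64),
        nascent=np.asarray(nasc, dtype=np.int64),
        cum_init=np.asarray(cum_i, dtype=np.int64),
        cum_term=np.asarray(cum_t, dtype=np.int64),
    )


def simulate_nucleus(
    conc: TFConcentration,
    rates: RateSet,
    duration: float = 2700.0,
    seed=0,
    position_el: float | None = None,
    update_grid: float = 1.0,
) -> NucleusTrajectory:
    """Simulate one nucleus with the Gillespie direct method.

    With ``rates.n_copies > 1``, each gene copy is an independent full model
    instance (own regulatory state and nascent pool, own RNG stream derived
    from ``seed``); the returned trajectory merges the event logs and sums
    nascent counts at observation times.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    keys = seed if isinstance(seed, (tuple, list)) else (seed,)

    if rates.n_copies == 1:
        return _simulate_copy(conc, rates, duration, derive_rng(tuple(keys)),
                              update_grid, position_el, tuple(keys))

    copies = [
        _simulate_copy(conc, rates, duration, derive_rng(tuple(keys) + ("copy", i)),
                       update_grid, position_el, tuple(keys) + ("copy", i))
        for i in range(rates.n_copies)
    ]
    # merge: sort all events; totals are step functions summed across copies
    t_all = np.concatenate([c.event_times[1:] for c in copies])
    lab_all = np.concatenate([c.event_labels[1:] for c in copies])
    st_all = np.concatenate([c.state_index[1:] for c in copies])
    order = np.argsort(t_all, kind="stable")
    t_sorted = np.concatenate([[0.0], t_all[order]])
    nascent = np.sum([c.nascent_at(t_sorted) for c in copies], axis=0)
    cum_i = np.sum([c.cum_init[np.searchsorted(c.event_times, t_sorted, side="right") - 1]
                    for c in copies], axis=0)
    cum_t = np.sum([c.cum_term[np.searchsorted(c.event_times, t_sorted, side="right") - 1]
                    for c in copies], axis=0)
    return NucleusTrajectory(
        duration=duration,
        position_el=position_el,
        seed_keys=tuple(keys),
        event_times=t_sorted,
        event_labels=np.concatenate([["start"], lab_all[order]]),
        state_index=np.concatenate([[0], st_all[order]]).astype(np.int64),
        nascent=nascent.astype(np.int64),
        cum_init=cum_i.astype(np.int64),
        cum_term=cum_t.astype(np.int64),
        copies=copies,
    )


@dataclasses.dataclass
class StripeEnsemble:
    """Replicated stochastic stripe: one trajectory per (position, replicate)."""

    trajectories: dict  # (position, replicate) -> NucleusTrajectory
    config: dict

    @property
    def positions(self) -> list[int]:
        return sorted({p for p, _ in self.trajectories})

    @property
    def n_replicates(self) -> int:
        return len({r for _, r in self.trajectories})

    def replicate(self, position: int) -> list[NucleusTrajectory]:
        return [self.trajectories[(position, r)] for r in range(self.n_replicates)]

    def accumulated_profile(self, time_s: float | None = None) -> pd.DataFrame:
        """Cumulative initiations per (position, replicate) at a time (default: end)."""
        rows = []
        for (p, r), traj in sorted(self.trajectories.items()):
            if time_s is None:
                m = traj.total_initiations
            else:
                i = np.searchsorted(traj.event_times, time_s, side="right") - 1
                m = int(traj.cum_init[i])
            rows.append((p, r, m))
        return pd.DataFrame(rows, columns=["position_el", "replicate", "m_prod"])

    def to_frame(self, dt_s: float = 60.0) -> pd.DataFrame:
        """Tidy minute-sampled table across the ensemble."""
        frames = []
        for (p, r), traj in sorted(self.trajectories.items()):
            times, counts = extract_minute_series(traj, dt_s=dt_s)
            idx = np.searchsorted(traj.event_times, times, side="right") - 1
            frames.append(pd.DataFrame({
                "position_el": p, "replicate": r, "time_s": times,
                "nascent": counts, "mrna_cum": traj.cum_term[idx],
            }))
        return pd.concat(frames, ignore_index=True)


def simulate_stripe(
    profiles: TFProfileSet,
    rates: RateSet,
    duration: float = 2700.0,
    n_replicates: int = 1,
    base_seed: int = 0,
    positions: Sequence[int] | None = None,
    update_grid: float = 1.0,
) -> StripeEnsemble:
    """Simulate independent nuclei across the AP lattice with replicates.

    Seeds are derived per (position, replicate) from ``base_seed``, so the
    same base seed reproduces the ensemble bit-identically and any single
    nucleus can be regenerated on its own.
    """
    if n_replicates < 1:
        raise ValueError("replicate count must be >= 1")
    pos = list(positions if positions is not None else profiles.positions)
    trajectories = {}
    for p in pos:
        conc = profiles.conc_at(p)
        for r in range(n_replicates):
            trajectories[(int(p), r)] = simulate_nucleus(
                conc, rates, duration=duration, seed=(base_seed, int(p), r),
                position_el=float(p), update_grid=update_grid,
            )
    config = {
        "rates": rates.as_dict(),
        "base_seed": base_seed,
        "duration_s": duration,
        "positions": [int(p) for p in pos],
        "n_replicates": n_replicates,
        "profile_provenance": profiles.provenance,
    }
    return StripeEnsemble(trajectories=trajectories, config=config)


def extract_minute_series(
    traj: NucleusTrajectory,
    scheme: str = "regular",
    dt_s: float = 60.0,
    mean_gap_s: float = 60.0,
    jitter_sd_s: float = 15.0,
    min_gap_s: float = 20.0,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the nascent count of a trajectory on a ~1-minute grid.

    ``scheme="regular"`` samples every ``dt_s`` seconds from 0 to the
    trajectory end (46 samples for a 45-minute run).  ``scheme="irregular"``
    emulates live-imaging movies: inter-sample gaps are drawn from a normal
    distribution (mean ``mean_gap_s``, sd ``jitter_sd_s``) truncated below
    at ``min_gap_s``.
    """
    if scheme == "regular":
        times = np.arange(0.0, traj.duration + dt_s / 2, dt_s)
        times = times[times <= traj.duration + 1e-9]
    elif scheme == "irregular":
        rng = derive_rng(seed)
        times_list = [0.0]
        while True:
            gap = max(min_gap_s, rng.normal(mean_gap_s, jitter_sd_s))
            t = times_list[-1] + gap
            if t > traj.duration:
                break
            times_list.append(t)
        times = np.asarray(times_list)
    else:
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    return times, traj.nascent_at(times).astype(float)
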