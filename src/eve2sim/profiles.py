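"""Synthetic TF concentration profiles and pseudo-experimental inputs.

Quantitative anterior-posterior (AP) protein profiles for Bcd, Hb, Gt and Kr
are not distributed as numbers, so this module generates them.  The shapes
honor the known geometry of the stripe 2 region: Bcd an anterior-high
exponential gradient; Hb an anterior plateau falling off posterior of
~49 %EL; Gt a domain centered at ~28 %EL; Kr a domain centered at ~53 %EL;
both repressors zero at the stripe center (42 %EL) and increasing ten-fold
over the 45-minute transcription window.

Absolute concentrations are anchored to the calibrated binding constants:
at 42 %EL the Bcd site occupancy is 55% and the Hb site occupancy 13.8%
under the default :class:`~eve2sim.model.RateSet` — the only combination the
model's behavior actually depends on (only ``k_bind * [TF]`` is
identifiable).  All shape parameters are exposed in :class:`ProfileParams`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .model import RateSet, TFConcentration, TF_NAMES, rates_for_mechanism

__all__ = [
    "SUBVOLUME_L",
    "DEFAULT_BCD_OCCUPANCY",
    "DEFAULT_HB_OCCUPANCY",
    "ProfileParams",
    "TFProfileSet",
    "make_tf_profiles",
    "molecules_to_molar",
    "molar_to_molecules",
    "pseudo_experimental_series",
]

#: One nucleus is modeled as a (5 um)^3 subvolume = 1.25e-13 L (so 1 nM is
#: about 75 molecules).  Used only for count<->molar conversions.
SUBVOLUME_L = 1.25e-13

#: Calibrated stripe-center site occupancies the fixtures are anchored to.
DEFAULT_BCD_OCCUPANCY = 0.55
DEFAULT_HB_OCCUPANCY = 115.0 / (0.56 * 0.55 * 2700.0)  # ~= 0.1383


def molecules_to_molar(count: float, volume_l: float = SUBVOLUME_L) -> float:
    """Convert a molecule count in a subvolume to a molar concentration."""
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / (Avogadro * volume_l)


def molar_to_molecules(conc_m: float, volume_l: float = SUBVOLUME_L) -> float:
    """Inverse of :func:`molecules_to_molar`."""
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    return conc_m * Avogadro * volume_l


def _anchor_conc(occupancy: float, k_bind: float, k_unbind: float = 0.033) -> float:
    # concentration at which a site with (k_bind, k_unbind) sits at `occupancy`
    return k_unbind * occupancy / (1.0 - occupancy) / k_bind


@dataclasses.dataclass
class ProfileParams:
    """Shape and anchor parameters of the synthetic TF profiles.

    Positions are %EL (percent embryo length from the anterior pole).
    Concentration anchors are the stripe-center (42 %EL) values in M; the
    defaults reproduce the calibrated activator occupancies under the
    default rate constants.  Repressor amplitudes are peak initial (t=0)
    concentrations, sized so that moderate Gt repression at 38 %EL halves
    output and stronger Kr repression posterior of the stripe shuts it down.
    """

    positions: tuple[int, int] = (30, 55)
    bcd_conc_42: float = _anchor_conc(DEFAULT_BCD_OCCUPANCY, 2.6e6)  # ~1.55e-8 M
    bcd_length_el: float = 20.0  # exponential decay length of the Bcd gradient
    hb_conc_42: float = _anchor_conc(DEFAULT_HB_OCCUPANCY, 1.8e5)  # ~2.94e-8 M
    hb_edge_el: float = 49.0  # posterior edge of the Hb plateau
    hb_edge_width_el: float = 1.5
    gt_center_el: float = 28.0
    gt_halfwidth_el: float = 14.0  # compact support: zero at 42 %EL
    gt_peak_conc_0: float = 8.3e-10  # initial peak concentration, M
    kr_center_el: float = 53.0
    kr_halfwidth_el: float = 11.0  # compact support: zero at 42 %EL
    kr_peak_conc_0: float = 6.8e-9  # initial peak concentration, M
    ramp_fold: float = 10.0  # Gt/Kr fold increase over the window
    ramp_duration_s: float = 2700.0


@dataclasses.dataclass
class TFProfileSet:
    """Concentration of each TF at integer AP positions, with the repressor ramp.

    ``conc0`` holds t=0 concentrations (M); Gt and Kr grow linearly to
    ``ramp_fold`` times their initial value at ``ramp_duration_s`` (a
    first-order translation from fixed mRNA gradients, with no decay).
    """

    positions: np.ndarray  # integer %EL
    conc0: dict  # tf name -> np.ndarray of M, aligned with positions
    ramp_fold: float = 10.0
    ramp_duration_s: float = 2700.0
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        for name in TF_NAMES:
            arr = np.asarray(self.conc0[name], dtype=float)
            if arr.shape != self.positions.shape:
                raise ValueError(f"{name} profile misaligned with positions")
            if np.any(arr < 0):
                raise ValueError(f"{name} concentrations must be >= 0")
            self.conc0[name] = arr

    def _index(self, position: float) -> int:
        idx = np.nonzero(self.positions == int(position))[0]
        if idx.size == 0:
            raise ValueError(f"position {position} %EL not in profile range "
                             f"{self.positions.min()}-{self.positions.max()}")
        return int(idx[0])

    def ramp_factor(self, t: float) -> float:
        """Linear repressor growth factor, 1 at t=0 to ``ramp_fold`` at the horizon."""
        frac = min(max(t, 0.0), self.ramp_duration_s) / self.ramp_duration_s
        return 1.0 + (self.ramp_fold - 1.0) * frac

    def concentration(self, tf: str, position: float, t: float = 0.0) -> float:
        """Concentration (M) of one TF at a position and time."""
        base = float(self.conc0[tf][self._index(position)])
        if tf in ("kr", "gt"):
            return base * self.ramp_factor(t)
        return base

    def conc_at(self, position: float, time_varying: bool = True) -> TFConcentration:
        """The :class:`TFConcentration` input for one nucleus.

        With ``time_varying`` the repressors carry the ten-fold ramp as
        callables of time; otherwise their t=0 values are used.
        """
        i = self._index(position)
        kr0 = float(self.conc0["kr"][i])
        gt0 = float(self.conc0["gt"][i])
        if time_varying:
            kr = (lambda t, c=kr0: c * self.ramp_factor(t)) if kr0 > 0 else 0.0
            gt = (lambda t, c=gt0: c * self.ramp_factor(t)) if gt0 > 0 else 0.0
        else:
            kr, gt = kr0, gt0
        return TFConcentration(
            bcd=float(self.conc0["bcd"][i]), hb=float(self.conc0["hb"][i]), kr=kr, gt=gt
        )

    def to_frame(self, times_s: tuple[float, ...] = (0.0, 2700.0)) -> pd.DataFrame:
        """Tidy table (position_el, tf, time_s, conc_M)."""
        rows = []
        for t in times_s:
            for name in TF_NAMES:
                factor = self.ramp_factor(t) if name in ("kr", "gt") else 1.0
                for pos, c in zip(self.positions, self.conc0[name]):
                    rows.append((int(pos), name, float(t), float(c) * factor))
        return pd.DataFrame(rows, columns=["position_el", "tf", "time_s", "conc_M"])

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        manifest = {
            "provenance": self.provenance,
            "positions": [int(p) for p in self.positions],
            "ramp_fold": self.ramp_fold,
            "ramp_duration_s": self.ramp_duration_s,
        }
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))


def make_tf_profiles(params: ProfileParams | None = None) -> TFProfileSet:
    """Generate the default synthetic TF profile set over 30-55 %EL.

    Bcd is an exponential anterior-high gradient; Hb a logistic anterior
    plateau; Gt and Kr are compact-support parabolic domains that vanish at
    the stripe center, the Gt flank shallower than the Kr flank.
    """
    p = params or ProfileParams()
    x = np.arange(p.positions[0], p.positions[1] + 1, dtype=float)

    bcd = p.bcd_conc_42 * np.exp(-(x - 42.0) / p.bcd_length_el)

    edge = 1.0 / (1.0 + np.exp((x - p.hb_edge_el) / p.hb_edge_width_el))
    edge_42 = 1.0 / (1.0 + np.exp((42.0 - p.hb_edge_el) / p.hb_edge_width_el))
    hb = p.hb_conc_42 * edge / edge_42

    gt = p.gt_peak_conc_0 * np.clip(1.0 - ((x - p.gt_center_el) / p.gt_halfwidth_el) ** 2, 0.0, None)
    kr = p.kr_peak_conc_0 * np.clip(1.0 - ((x - p.kr_center_el) / p.kr_halfwidth_el) ** 2, 0.0, None)

    profiles = TFProfileSet(
        positions=x.astype(int),
        conc0={"bcd": bcd, "hb": hb, "kr": kr, "gt": gt},
        ramp_fold=p.ramp_fold,
        ramp_duration_s=p.ramp_duration_s,
        provenance="synthetic (anchored to calibrated occupancies at 42 %EL)",
    )
    _check_geometry(profiles)
    return profiles


def _check_geometry(profiles: TFProfileSet) -> None:
    x = profiles.positions
    if 42 in x:
        i42 = int(np.nonzero(x == 42)[0][0])
        if profiles.conc0["gt"][i42] != 0.0 or profiles.conc0["kr"][i42] != 0.0:
            raise ValueError("repressor concentration must vanish at 42 %EL")
        gt_peak = x[int(np.argmax(profiles.conc0["gt"]))]
        kr_peak = x[int(np.argmax(profiles.conc0["kr"]))]
        if profiles.conc0["gt"].max() > 0 and not gt_peak < 42:
            raise ValueError("Gt domain must peak anterior of 42 %EL")
        if profiles.conc0["kr"].max() > 0 and not kr_peak > 42:
            raise ValueError("Kr domain must peak posterior of 42 %EL")


def pseudo_experimental_series(
    mechanism: str = "two_state",
    rates: RateSet | None = None,
    position: int = 42,
    *,
    profiles: TFProfileSet | None = None,
    duration: float = 2700.0,
    mean_gap_s: float = 60.0,
    jitter_sd_s: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Irregularly sampled nascent-count series emulating a live-imaging movie.

    Simulates one nucleus under the named mechanism and samples it with
    jittered ~1-minute spacing; the output table (``time_s``, ``nascent``)
    has the same shape as a user-supplied experimental series.
    """
    from .ssa import simulate_nucleus, extract_minute_series  # local: avoid cycle

    rates = rates_for_mechanism(mechanism, rates)
    profiles = profiles or make_tf_profiles()
    conc = profiles.conc_at(position)
    traj = simulate_nucleus(conc, rates, duration=duration, seed=(seed, "traj"),
                            position_el=position)
    times, counts = extract_minute_series(
        traj, scheme="irregular", mean_gap_s=mean_gap_s, jitter_sd_s=jitter_sd_s,
        seed=(seed, "sampling"),
    )
    return pd.DataFrame({"time_s": times, "nascent": counts})
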