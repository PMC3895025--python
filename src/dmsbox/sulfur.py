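"""Three-pool sulfur kinetics: particulate DMSP per functional type,
dissolved DMSP, and DMS, integrated with an explicit Euler scheme.

State equations (all pools in mmolS m-3, fluxes in mmolS m-3 h-1):

* per-FT particulate DMSP follows the carbon fluxes through a fixed S:C
  quota: d(DMSPp_n)/dt = SC_n * (mu_n - lysis_n - grazing_n - sed_n);
* lysed DMSPp is split by the algal lyase yield between direct DMS
  production (f1) and dissolved-DMSP release (f2); grazed DMSPp goes to
  the dissolved pool (f3) except an optional fraction cleaved to DMS
  during digestion (f3b); sedimentation (f4) exports DMSPp;
* bacteria take up dissolved DMSP in proportion to their carbon uptake
  and the DMSPd:substrate ratio; the sulfur they need for growth is
  assimilated (f5), the surplus is demethylated (f6) or cleaved to DMS
  (f7) by the bacterial lyase fraction -- the cleavage shuts off entirely
  whenever the uptake cannot cover the sulfur demand;
* DMS is consumed by bacteria (f8, topping up any unmet sulfur demand),
  vented to the atmosphere (f9) and photooxidized to DMSO (f10) with a
  depth-averaged first-order rate.

Every step emits a :class:`FluxLedger` holding the post-limiting fluxes, so
sulfur mass conservation can be audited exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from dmsbox.forcing import ForcingRecord, ForcingSeries
from dmsbox.gas import k_dms

MGC_PER_MMOLC = 12.0

LEDGER_FIELDS = (
    "f1_phyto_lyase",
    "f2_lysis_release",
    "f3_grazing_release",
    "f3b_grazing_to_dms",
    "f4_sedimentation",
    "f5_s_assimilation",
    "f6_demethylation",
    "f7_bact_lyase",
    "f8_dms_bact_uptake",
    "f9_emission",
    "f10_photooxidation",
    "sneed",
    "uptake_c",
    "s_deficit_unmet",
)


@dataclass
class SulfurParams:
    """Quotas, yields and variant switches of the sulfur module.

    Phytoplankton quotas are stored in mmolS per mgC (divide a molS:molC
    value by 12 to convert); the bacterial quota is molS:molC.
    """

    SC_DA: float = 0.000072
    SC_NF: float = 0.00092
    SC_OP: float = 0.00092
    SC_BC: float = 0.01
    y_DMS_DA: float = 0.1
    y_DMS_NF: float = 0.1
    y_DMS_OP: float = 0.1
    lyase_bact: float = 0.1
    K0: float = 0.09  # h-1, sea-surface photooxidation rate
    ratio_S_DMSPd: float = 1.0
    ratio_S_DMS: float = 1.0
    graz_to_DMS: float = 0.0  # variant: 0.3 routes grazed DMSPp to DMS
    k600_method: str = "yang"
    diel_photoox: bool = False  # optional diel irradiance scaling of K0

    def __post_init__(self) -> None:
        for name in ("y_DMS_DA", "y_DMS_NF", "y_DMS_OP", "lyase_bact",
                     "ratio_S_DMSPd", "ratio_S_DMS", "graz_to_DMS"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("SC_DA", "SC_NF", "SC_OP", "SC_BC", "K0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def sc(self) -> tuple[float, float, float]:
        return (self.SC_DA, self.SC_NF, self.SC_OP)

    @property
    def y_dms(self) -> tuple[float, float, float]:
        return (self.y_DMS_DA, self.y_DMS_NF, self.y_DMS_OP)

    def replace(self, **kwargs) -> "SulfurParams":
        return dataclasses.replace(self, **kwargs)

    @staticmethod
    def quota_from_molar(mols_per_molc: float) -> float:
        """Convert a phytoplankton quota from molS:molC to mmolS:mgC."""
        return mols_per_molc / MGC_PER_MMOLC

    @classmethod
    def from_yaml(cls, path) -> "SulfurParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class SulfurState:
    """The three sulfur pools (DMSPp split per functional type)."""

    DMSPp_DA: float = 0.0
    DMSPp_NF: float = 0.0
    DMSPp_OP: float = 0.0
    DMSPd: float = 0.0
    DMS: float = 0.0

    def __post_init__(self) -> None:
        for name in ("DMSPp_DA", "DMSPp_NF", "DMSPp_OP", "DMSPd", "DMS"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def dmspp(self) -> tuple[float, float, float]:
        return (self.DMSPp_DA, self.DMSPp_NF, self.DMSPp_OP)

    @property
    def total(self) -> float:
        return self.DMSPp_DA + self.DMSPp_NF + self.DMSPp_OP + self.DMSPd + self.DMS

    @classmethod
    def from_forcing(cls, record: ForcingRecord, params: SulfurParams,
                     dmspd: float = 0.0, dms: float = 0.0) -> "SulfurState":
        """Quota-consistent initial state: DMSPp_n = SC_n * B_n."""
        sc = params.sc
        return cls(sc[0] * record.B[0], sc[1] * record.B[1], sc[2] * record.B[2],
                   dmspd, dms)


@dataclass
class FluxLedger:
    """Per-step fluxes (mmolS m-3 h-1), recorded after any limiting."""

    f1_phyto_lyase: float = 0.0
    f2_lysis_release: float = 0.0
    f3_grazing_release: float = 0.0
    f3b_grazing_to_dms: float = 0.0
    f4_sedimentation: float = 0.0
    f5_s_assimilation: float = 0.0
    f6_demethylation: float = 0.0
    f7_bact_lyase: float = 0.0
    f8_dms_bact_uptake: float = 0.0
    f9_emission: float = 0.0
    f10_photooxidation: float = 0.0
    sneed: float = 0.0
    uptake_c: float = 0.0
    s_deficit_unmet: float = 0.0

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, name) for name in LEDGER_FIELDS)


# ---------------------------------------------------------------------------
# process rates
# ---------------------------------------------------------------------------

def dmspp_tendency(record: ForcingRecord, params: SulfurParams):
    """Per-FT DMSPp tendencies and the pool's ledger contributions.

    Returns ``(tendencies, f1, f2, f3, f3b, f4)`` where tendencies is the
    3-tuple SC_n * (mu_n - lysis_n - grazing_n - sed_n).
    """
    f1 = f2 = f3 = f3b = f4 = 0.0
    tendencies = []
    for n in range(3):
        mu, lysis, graz, sed = record.mu[n], record.lysis[n], record.grazing[n], record.sed[n]
        if min(mu, lysis, graz, sed) < 0:
            raise ValueError("negative forcing flux")
        sc = params.sc[n]
        tendencies.append(sc * (mu - lysis - graz - sed))
        lys_s = sc * lysis
        graz_s = sc * graz
        y = params.y_dms[n]
        f1 += y * lys_s
        f2 += (1.0 - y) * lys_s
        f3b += params.graz_to_DMS * graz_s
        f3 += (1.0 - params.graz_to_DMS) * graz_s
        f4 += sc * sed
    return tuple(tendencies), f1, f2, f3, f3b, f4


def bacterial_c_uptake(record: ForcingRecord) -> float:
    """Monod carbon uptake bmx * BC * SBC / (SBC + k_sbc), mgC m-3 h-1."""
    if record.k_sbc <= 0:
        raise ValueError("half-saturation constant must be positive")
    if record.SBC < 0:
        raise ValueError("substrate concentration must be non-negative")
    return record.bmx * record.BC * record.SBC / (record.SBC + record.k_sbc)


def dmspd_uptake(record: ForcingRecord, params: SulfurParams, state: SulfurState,
                 uptake_c: float | None = None, dt: float | None = None) -> float:
    """Bacterial DMSPd uptake scaled by the DMSPd:substrate stoichiometry.

    Capped so the pool cannot be overdrawn within a step when ``dt`` is
    given.
    """
    if state.DMSPd <= 0.0 or record.SBC <= 0.0:
        return 0.0
    if uptake_c is None:
        uptake_c = bacterial_c_uptake(record)
    uptake = params.ratio_S_DMSPd * uptake_c * state.DMSPd / record.SBC
    if dt is not None:
        uptake = min(uptake, state.DMSPd / dt)
    return uptake


def s_need(record: ForcingRecord, params: SulfurParams,
           uptake_c: float | None = None) -> float:
    """Bacterial sulfur demand from growth: y_BC * uptake_C / 12 * SC_BC."""
    if uptake_c is None:
        uptake_c = bacterial_c_uptake(record)
    return record.y_BC * uptake_c / MGC_PER_MMOLC * params.SC_BC


def partition_dmspd(uptake: float, sneed: float, params: SulfurParams):
    """Split DMSPd uptake into assimilation (f5), demethylation (f6) and
    bacterial lyase cleavage (f7).

    The cleavage is a fixed fraction of the non-assimilated surplus, and is
    null whenever the uptake cannot cover the sulfur demand (the deficit is
    then returned for DMS uptake to cover).
    """
    if uptake < 0 or sneed < 0:
        raise ValueError("uptake and sulfur need must be non-negative")
    f5 = min(uptake, sneed)
    residual = uptake - f5
    if residual > 0.0:
        f7 = params.lyase_bact * residual
        f6 = residual - f7
        deficit = 0.0
    else:
        f6 = f7 = 0.0
        deficit = sneed - uptake
    return f5, f6, f7, deficit


def dms_uptake(record: ForcingRecord, params: SulfurParams, state: SulfurState,
               s_deficit: float = 0.0, uptake_c: float | None = None,
               dt: float | None = None) -> float:
    """Bacterial DMS consumption (f8), plus a top-up covering any unmet
    sulfur demand, capped by the available DMS."""
    if state.DMS <= 0.0:
        return 0.0
    if uptake_c is None:
        uptake_c = bacterial_c_uptake(record)
    base = params.ratio_S_DMS * uptake_c * state.DMS / record.SBC if record.SBC > 0 else 0.0
    f8 = base + max(s_deficit, 0.0)
    if dt is not None:
        f8 = min(f8, state.DMS / dt)
    return f8


def photooxidation(record: ForcingRecord, params: SulfurParams,
                   state: SulfurState) -> float:
    """Depth-averaged first-order photooxidation of DMS to DMSO.

    The surface rate K0 attenuates with depth through the light extinction
    coefficient; averaging exp(-kD z) over the box gives the factor
    (1 - exp(-kD H)) / (kD H).
    """
    if record.kD <= 0 or record.H <= 0:
        raise ValueError("light extinction and depth must be positive")
    kd_h = record.kD * record.H
    attenuation = -np.expm1(-kd_h) / kd_h
    rate = params.K0 * attenuation
    if params.diel_photoox:
        # optional: modulate by the local solar half-sine, normalized so the
        # 24 h mean rate is unchanged (daylight 06-18, mean of the clipped
        # half-sine is 1/pi); no effect at night
        hour = record.time_h % 24.0
        rate *= np.pi * max(0.0, np.sin(np.pi * (hour - 6.0) / 12.0))
    return rate * state.DMS


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def step_euler(state: SulfurState, record: ForcingRecord, params: SulfurParams,
               dt: float, _k_dms_m_h: float | None = None):
    """One explicit Euler step; returns ``(new_state, FluxLedger)``.

    All rates are evaluated on the beginning-of-step state.  If the total
    sink of a pool would overdraw it within the step, that pool's sinks
    are rescaled proportionally (flux limiter) and the ledger records the
    rescaled values, so the per-step sulfur balance is exact by
    construction.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for v in (*record.mu, *record.lysis, *record.grazing, *record.sed,
              record.BC, record.SBC, record.u10, record.T_degC):
        if v != v:  # NaN check
            raise ValueError("NaN in forcing record")

    tendencies, f1, f2, f3, f3b, f4 = dmspp_tendency(record, params)

    # limit DMSPp sinks per FT if the Euler update would go negative
    new_dmspp = []
    scale_pp = [1.0, 1.0, 1.0]
    for n in range(3):
        pool = state.dmspp[n]
        sc = params.sc[n]
        src = sc * record.mu[n]
        snk = sc * (record.lysis[n] + record.grazing[n] + record.sed[n])
        if snk > 0 and pool + dt * (src - snk) < 0.0:
            scale_pp[n] = (pool / dt + src) / snk
        new_dmspp.append(pool + dt * (src - snk * scale_pp[n]))
    if scale_pp != [1.0, 1.0, 1.0]:
        # recompute the pool's outgoing ledger entries with scaled losses
        f1 = f2 = f3 = f3b = f4 = 0.0
        for n in range(3):
            sc = params.sc[n]
            s = scale_pp[n]
            lys_s = sc * record.lysis[n] * s
            graz_s = sc * record.grazing[n] * s
            y = params.y_dms[n]
            f1 += y * lys_s
            f2 += (1.0 - y) * lys_s
            f3b += params.graz_to_DMS * graz_s
            f3 += (1.0 - params.graz_to_DMS) * graz_s
            f4 += sc * record.sed[n] * s

    uptake_c = bacterial_c_uptake(record)
    uptake = dmspd_uptake(record, params, state, uptake_c=uptake_c, dt=dt)
    sneed = s_need(record, params, uptake_c=uptake_c)
    f5, f6, f7, deficit = partition_dmspd(uptake, sneed, params)
    new_dmspd = state.DMSPd + dt * (f2 + f3 - uptake)
    if new_dmspd < 0.0:  # guard against rounding; uptake is already capped
        new_dmspd = 0.0

    f8 = dms_uptake(record, params, state, s_deficit=deficit,
                    uptake_c=uptake_c, dt=dt)
    deficit_unmet = max(deficit - max(f8 - params.ratio_S_DMS * uptake_c
                                      * (state.DMS / record.SBC if record.SBC > 0 else 0.0),
                                      0.0), 0.0)
    f10 = photooxidation(record, params, state)
    if _k_dms_m_h is None:
        _k_dms_m_h = k_dms(record.u10, record.T_degC, params.k600_method)
    f9 = _k_dms_m_h * state.DMS / record.H

    sinks = f8 + f9 + f10
    srcs = f1 + f3b + f7
    if sinks > 0 and state.DMS + dt * (srcs - sinks) < 0.0:
        scale = (state.DMS / dt + srcs) / sinks
        f8 *= scale
        f9 *= scale
        f10 *= scale
        sinks = f8 + f9 + f10
    new_dms = state.DMS + dt * (srcs - sinks)
    if new_dms < 0.0:
        new_dms = 0.0

    ledger = FluxLedger(f1, f2, f3, f3b, f4, f5, f6, f7, f8, f9, f10,
                        sneed, uptake_c, deficit_unmet)
    new_state = SulfurState(max(new_dmspp[0], 0.0), max(new_dmspp[1], 0.0),
                            max(new_dmspp[2], 0.0), new_dmspd, new_dms)
    return new_state, ledger


@dataclass
class SimulationResult:
    """Trajectory + ledger series of a box run, both as DataFrames."""

    trajectory: pd.DataFrame  # time_h + the five pools
    ledger: pd.DataFrame      # time_h + LEDGER_FIELDS
    dt_h: float
    depth_m: float

    def to_dataset(self):
        """Export as an :class:`xarray.Dataset` with unit attributes."""
        import xarray as xr

        ds = xr.Dataset(coords={"time": ("time", self.trajectory["time_h"].to_numpy())})
        # plain unit string (not CF "since" syntax) so readers do not try
        # to decode a calendar datetime axis
        ds["time"].attrs["units"] = "h"
        for col in self.trajectory.columns:
            if col == "time_h":
                continue
            ds[col] = ("time", self.trajectory[col].to_numpy())
            ds[col].attrs["units"] = "mmolS m-3"
        for col in LEDGER_FIELDS:
            ds[col] = ("time", self.ledger[col].to_numpy())
            ds[col].attrs["units"] = "mgC m-3 h-1" if col == "uptake_c" else "mmolS m-3 h-1"
        ds.attrs["dt_h"] = self.dt_h
        ds.attrs["depth_m"] = self.depth_m
        return ds


def run_simulation(forcing: ForcingSeries, params: SulfurParams | None = None,
                   init: SulfurState | None = None) -> SimulationResult:
    """Integrate the sulfur module over the whole forcing series.

    The state reported at index i is the beginning-of-step state on which
    the ledger fluxes at index i were evaluated.
    """
    params = params or SulfurParams()
    records = list(forcing.records())
    if init is None:
        init = SulfurState.from_forcing(records[0], params)
    dt = forcing.dt_h

    # transfer velocity is forcing-only; vectorize it out of the loop
    kvals = k_dms(forcing.column("u10_ms"), forcing.column("T_degC"),
                  params.k600_method)
    kvals = np.atleast_1d(kvals)

    n = len(records)
    pools = np.empty((n, 5))
    fluxes = np.empty((n, len(LEDGER_FIELDS)))
    state = init
    for i, rec in enumerate(records):
        pools[i] = (state.DMSPp_DA, state.DMSPp_NF, state.DMSPp_OP,
                    state.DMSPd, state.DMS)
        state, ledger = step_euler(state, rec, params, dt, _k_dms_m_h=float(kvals[i]))
        fluxes[i] = ledger.as_tuple()

    t = forcing.time_h
    trajectory = pd.DataFrame(pools, columns=["DMSPp_DA", "DMSPp_NF", "DMSPp_OP",
                                              "DMSPd", "DMS"])
    trajectory.insert(0, "time_h", t)
    ledger_df = pd.DataFrame(fluxes, columns=list(LEDGER_FIELDS))
    ledger_df.insert(0, "time_h", t)
    # per-FT DMSPp production diagnostics (sources are never flux-limited)
    for ft, sc in zip(("DA", "NF", "OP"), params.sc):
        ledger_df[f"prod_{ft}"] = sc * forcing.column(f"mu_{ft}")
    return SimulationResult(trajectory, ledger_df, dt, float(records[0].H))
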