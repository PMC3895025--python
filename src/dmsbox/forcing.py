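"""Synthetic plankton/environment forcing for the sulfur box model.

The sulfur module is driven by per-functional-type carbon fluxes (growth,
lysis, grazing, sedimentation), bacterial substrate kinetics and physical
forcing (temperature, wind at 10 m, irradiance, light extinction).  This
module generates an internally consistent annual series emulating a shallow,
permanently mixed eutrophied coastal box: a spring diatom bloom, a short and
intense *Phaeocystis*-type colonial bloom, a summer diatom bloom, and
bacterial maxima trailing each bloom.  A CSV reader/writer and a validator
are provided so externally produced forcing can be substituted.

Conventions
-----------
* time is hours since Jan 1 00:00, on a regular grid, one model year;
* biomass in mgC m-3, carbon fluxes in mgC m-3 h-1;
* the discrete carbon balance closes exactly:
  (B[i+1] - B[i]) / dt == mu[i] - lysis[i] - grazing[i] - sed[i];
* structural zeros: colonial phytoplankton (OP) are never grazed,
  nanoflagellates (NF) never sediment.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

FTS = ("DA", "NF", "OP")

#: loss channels a functional type may use (ordering matters: the last
#: allowed channel absorbs the float remainder so the balance is exact)
ALLOWED_CHANNELS = {
    "DA": ("lysis", "grazing", "sedimentation"),
    "NF": ("lysis", "grazing"),
    "OP": ("lysis", "sedimentation"),
}

HOURS_PER_YEAR = 8760.0

CSV_COLUMNS = [
    "time_h",
    "B_DA", "B_NF", "B_OP",
    "mu_DA", "mu_NF", "mu_OP",
    "lysis_DA", "lysis_NF", "lysis_OP",
    "graz_DA", "graz_NF", "graz_OP",
    "sed_DA", "sed_OP",
    "BC", "SBC", "bmx", "k_sbc", "y_BC",
    "T_degC", "u10_ms", "J_Wm2", "kD_m1", "depth_m",
]

#: columns that may be absent from a CSV because they are structurally zero
OPTIONAL_ZERO_COLUMNS = ("graz_OP", "sed_NF")


class ForcingValidationError(ValueError):
    """Raised when a forcing file or series violates the schema."""


@dataclass
class BloomSpec:
    """One Gaussian biomass pulse for a functional type.

    ``loss_partition`` routes the total loss flux to (lysis, grazing,
    sedimentation); entries on channels disallowed for the FT must be zero
    and the triple must sum to 1.
    """

    ft: str
    peak_day: float
    peak_biomass: float
    width_days: float
    loss_partition: tuple[float, float, float]
    baseline: float = 0.0
    loss_rate_scale: float = 0.02  # h-1, specific loss-rate ceiling scale

    def __post_init__(self) -> None:
        if self.ft not in FTS:
            raise ForcingValidationError(f"unknown functional type {self.ft!r}")
        lp = tuple(float(x) for x in self.loss_partition)
        if len(lp) != 3 or any(x < 0 or x > 1 for x in lp):
            raise ForcingValidationError("loss_partition fractions must lie in [0, 1]")
        if abs(sum(lp) - 1.0) > 1e-9:
            raise ForcingValidationError("loss_partition must sum to 1")
        names = ("lysis", "grazing", "sedimentation")
        for name, frac in zip(names, lp):
            if name not in ALLOWED_CHANNELS[self.ft] and frac != 0.0:
                raise ForcingValidationError(
                    f"{name} is structurally zero for {self.ft} but got {frac}"
                )
        if not (self.peak_biomass >= self.baseline >= 0.0):
            raise ForcingValidationError("need peak_biomass >= baseline >= 0")
        self.loss_partition = lp


@dataclass
class EnvironmentSpec:
    """Physical environment of the box and bacterial substrate constants."""

    depth_m: float = 17.0
    # temperature sinusoid: T(d) = mean - amplitude * cos(2 pi (d - phase)/365)
    temp_mean: float = 12.0
    temp_amplitude: float = 7.0
    temp_phase_day: float = 46.0
    kd_m1: float = 0.5
    # daily-mean irradiance sinusoid (W m-2)
    irradiance_mean: float = 100.0
    irradiance_amplitude: float = 80.0
    # wind: seasonal mean sinusoid + AR(1) daily anomalies, held per day
    wind_winter_mean: float = 5.0
    wind_spring_mean: float = 3.3
    wind_sd: float = 1.7
    wind_ar1: float = 0.7
    # bacterial compartment
    # bacteria respond quickly to the lysis wave; the monomeric substrate
    # pool accumulates slowly and persists after the bloom.  The resulting
    # decline of BC/SBC during bloom decay is what lets DMS (whose sinks
    # include photolysis and venting) peak ahead of dissolved DMSP.
    bc_baseline: float = 15.0
    bc_gain: float = 8.0  # mgC of bacteria per (mgC m-3 h-1) of lysis, at steady state
    bc_tau_h: float = 48.0
    sbc_baseline: float = 30.0
    sbc_gain: float = 20.0  # mgC of substrate per (mgC m-3 h-1) of lysis
    sbc_tau_h: float = 300.0
    bmx_h1: float = 0.15
    k_sbc_mgC_m3: float = 25.0
    y_bc: float = 0.3
    # diagnostics only: carbon-to-chlorophyll ratio per FT (mgC : mgChl)
    c_to_chl: dict = field(default_factory=lambda: {"DA": 64.0, "NF": 64.0, "OP": 64.0})
    days_per_year: int = 365

    def __post_init__(self) -> None:
        if self.depth_m <= 0:
            raise ForcingValidationError("depth must be positive")
        if self.kd_m1 <= 0:
            raise ForcingValidationError("light extinction must be positive")
        if not (0.0 < self.y_bc < 1.0):
            raise ForcingValidationError("bacterial growth efficiency must be in (0, 1)")


@dataclass(frozen=True)
class ForcingRecord:
    """One time slice of the forcing, plain floats for a fast inner loop."""

    time_h: float
    B: tuple[float, float, float]
    mu: tuple[float, float, float]
    lysis: tuple[float, float, float]
    grazing: tuple[float, float, float]
    sed: tuple[float, float, float]
    BC: float
    SBC: float
    bmx: float
    k_sbc: float
    y_BC: float
    T_degC: float
    u10: float
    J: float
    kD: float
    H: float


@dataclass
class ValidationReport:
    """Accumulated invariant violations; empty means the series is valid."""

    violations: list[tuple[int, str, str]] = field(default_factory=list)

    def add(self, index: int, name: str, message: str) -> None:
        self.violations.append((index, name, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff clean, mirroring subprocess-style use
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "forcing series valid"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  [t={i}] {name}: {msg}" for i, name, msg in self.violations]
        return "\n".join(lines)


class ForcingSeries:
    """A validated, regular-grid forcing table.

    Thin wrapper around a :class:`pandas.DataFrame` with the canonical
    column set (see :data:`CSV_COLUMNS` plus the structurally zero columns
    ``graz_OP`` and ``sed_NF``).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in OPTIONAL_ZERO_COLUMNS:
            if col not in frame.columns:
                frame[col] = 0.0
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ForcingValidationError(f"missing column(s): {', '.join(missing)}")
        t = frame["time_h"].to_numpy(float)
        if len(t) == 0:
            raise ForcingValidationError("empty forcing series")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ForcingValidationError("time_h must be strictly increasing")
        self.frame = frame.reset_index(drop=True)

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ForcingSeries) and self.frame.equals(other.frame)

    @property
    def time_h(self) -> np.ndarray:
        return self.frame["time_h"].to_numpy(float)

    @property
    def dt_h(self) -> float:
        t = self.time_h
        if len(t) < 2:
            raise ForcingValidationError("need at least two records for a step size")
        return float(t[1] - t[0])

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(float)

    def records(self) -> Iterator[ForcingRecord]:
        """Iterate plain-float records (used by the sulfur integrator)."""
        cols = {c: self.frame[c].to_numpy(float) for c in self.frame.columns}
        graz_op = cols["graz_OP"]
        sed_nf = cols["sed_NF"]
        for i in range(len(self.frame)):
            yield ForcingRecord(
                time_h=cols["time_h"][i],
                B=(cols["B_DA"][i], cols["B_NF"][i], cols["B_OP"][i]),
                mu=(cols["mu_DA"][i], cols["mu_NF"][i], cols["mu_OP"][i]),
                lysis=(cols["lysis_DA"][i], cols["lysis_NF"][i], cols["lysis_OP"][i]),
                grazing=(cols["graz_DA"][i], cols["graz_NF"][i], graz_op[i]),
                sed=(cols["sed_DA"][i], sed_nf[i], cols["sed_OP"][i]),
                BC=cols["BC"][i],
                SBC=cols["SBC"][i],
                bmx=cols["bmx"][i],
                k_sbc=cols["k_sbc"][i],
                y_BC=cols["y_BC"][i],
                T_degC=cols["T_degC"][i],
                u10=cols["u10_ms"][i],
                J=cols["J_Wm2"][i],
                kD=cols["kD_m1"][i],
                H=cols["depth_m"][i],
            )

    # -- diagnostics --------------------------------------------------------------
    def chlorophyll(self, c_to_chl: dict | None = None) -> pd.DataFrame:
        """Per-FT and total chlorophyll (mg m-3) via fixed C:Chl ratios."""
        ratios = c_to_chl or {"DA": 64.0, "NF": 64.0, "OP": 64.0}
        out = pd.DataFrame({"time_h": self.time_h})
        for ft in FTS:
            out[f"chl_{ft}"] = self.column(f"B_{ft}") / ratios[ft]
        out["chl_total"] = out[[f"chl_{ft}" for ft in FTS]].sum(axis=1)
        return out


# ---------------------------------------------------------------------------
# default scenario
# ---------------------------------------------------------------------------

def default_scenario() -> tuple[list[BloomSpec], EnvironmentSpec]:
    """Default coastal-box scenario: spring diatoms, a 1600 mgC m-3 colonial
    bloom (~25 mg Chl m-3 total at C:Chl 64), summer diatoms."""
    blooms = [
        BloomSpec("DA", peak_day=75.0, peak_biomass=400.0, width_days=10.0,
                  loss_partition=(0.50, 0.35, 0.15), baseline=5.0),
        BloomSpec("OP", peak_day=115.0, peak_biomass=1600.0, width_days=9.0,
                  loss_partition=(0.85, 0.0, 0.15), baseline=1.0),
        BloomSpec("NF", peak_day=140.0, peak_biomass=200.0, width_days=15.0,
                  loss_partition=(0.60, 0.40, 0.0), baseline=5.0),
        BloomSpec("DA", peak_day=200.0, peak_biomass=400.0, width_days=20.0,
                  loss_partition=(0.50, 0.35, 0.15), baseline=0.0),
    ]
    return blooms, EnvironmentSpec()


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------

def _gaussian_pulse(day: np.ndarray, spec: BloomSpec) -> np.ndarray:
    return spec.peak_biomass * np.exp(-0.5 * ((day - spec.peak_day) / spec.width_days) ** 2)


def _wind_series(day_of_value: np.ndarray, env: EnvironmentSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Daily AR(1) wind held constant within each day, truncated at zero.

    The seasonal mean is a cosine with its maximum in mid-January; the
    spring (Apr-May) plateau sits near ``wind_spring_mean``.
    """
    ndays = env.days_per_year
    d = np.arange(ndays)
    # solve mean(d=15) = winter mean and mean(spring) ~ spring mean
    # spring (days 90-150) average cosine factor is about -0.22
    b = (env.wind_winter_mean - env.wind_spring_mean) / 1.22
    a = env.wind_winter_mean - b
    seasonal = a + b * np.cos(2.0 * np.pi * (d - 15.0) / ndays)
    phi = env.wind_ar1
    z = np.empty(ndays)
    eps = rng.standard_normal(ndays)
    z[0] = eps[0]
    innov = np.sqrt(1.0 - phi * phi)
    for i in range(1, ndays):
        z[i] = phi * z[i - 1] + innov * eps[i]
    daily = np.maximum(seasonal + env.wind_sd * z, 0.0)
    idx = np.clip(day_of_value.astype(int), 0, ndays - 1)
    return daily[idx]


def _loss_weight(day: np.ndarray, specs: Sequence[BloomSpec]) -> np.ndarray:
    """Descending-limb ramp in [0, 1]: ~0.0 before each bloom peak, ~1.0
    after, so the specific loss rate rises from 10% to 90% of its scale as a
    bloom collapses (this is what delays dissolved-DMSP release)."""
    w = np.zeros_like(day)
    for spec in specs:
        if spec.peak_biomass <= 0:
            continue
        ramp_width = max(spec.width_days / 3.0, 1e-6)
        local = 1.0 / (1.0 + np.exp(-(day - spec.peak_day) / ramp_width))
        # fade the ramp away once the pulse is long gone so the next bloom resets it
        window = np.exp(-0.5 * ((day - spec.peak_day) / (3.0 * spec.width_days)) ** 2)
        w = np.maximum(w, local * window)
    return w


def generate_forcing(bloom_specs: Sequence[BloomSpec], env: EnvironmentSpec,
                     dt: float = 0.25, seed: int = 0) -> ForcingSeries:
    """Generate a one-year forcing series on a regular grid of step ``dt`` h.

    Biomass is baseline plus Gaussian pulses; growth and loss fluxes are
    derived so that the discrete carbon balance closes exactly; losses are
    partitioned per :class:`BloomSpec` respecting the structural zeros;
    bacterial biomass is a lagged first-order response to total lysis.
    """
    if dt <= 0:
        raise ForcingValidationError("dt must be positive")
    if not bloom_specs:
        raise ForcingValidationError("need at least one BloomSpec")
    rng = np.random.default_rng(seed)
    n = int(round(HOURS_PER_YEAR / dt))
    t = np.arange(n) * dt
    day = t / 24.0

    frame = pd.DataFrame({"time_h": t})

    by_ft: dict[str, list[BloomSpec]] = {ft: [] for ft in FTS}
    for spec in bloom_specs:
        by_ft[spec.ft].append(spec)

    for ft in FTS:
        specs = by_ft[ft]
        if specs:
            baseline = sum(s.baseline for s in specs)
            pulses = [_gaussian_pulse(day, s) for s in specs]
            B = baseline + np.sum(pulses, axis=0)
            rate_scale = max(s.loss_rate_scale for s in specs)
            w = _loss_weight(day, specs)
            specific_loss = rate_scale * (0.1 + 0.8 * w)
        else:
            B = np.zeros(n)
            pulses = []
            specific_loss = np.zeros(n)

        dBdt = np.empty(n)
        dBdt[:-1] = np.diff(B) / dt
        dBdt[-1] = dBdt[-2] if n > 1 else 0.0

        # mu - L == dB/dt exactly: relu(x) - relu(-x) == x
        background = specific_loss * B
        L = np.maximum(-dBdt, 0.0) + background
        mu = np.maximum(dBdt, 0.0) + background

        # partition L across channels, weighting specs by pulse dominance;
        # the last allowed channel takes the remainder so the split is exact
        fractions = {"lysis": np.zeros(n), "grazing": np.zeros(n), "sedimentation": np.zeros(n)}
        if specs:
            weights = np.array([p + 1e-30 for p in pulses]) if pulses else None
            wsum = weights.sum(axis=0)
            for spec, pw in zip(specs, weights):
                share = pw / wsum
                for name, frac in zip(("lysis", "grazing", "sedimentation"),
                                      spec.loss_partition):
                    fractions[name] += share * frac
        channels = ALLOWED_CHANNELS[ft]
        split = {"lysis": np.zeros(n), "grazing": np.zeros(n), "sedimentation": np.zeros(n)}
        running = np.zeros(n)
        for name in channels[:-1]:
            split[name] = L * fractions[name]
            running = running + split[name]
        split[channels[-1]] = L - running

        frame[f"B_{ft}"] = B
        frame[f"mu_{ft}"] = mu
        frame[f"lysis_{ft}"] = split["lysis"]
        if ft != "OP":
            frame[f"graz_{ft}"] = split["grazing"]
        if ft != "NF":
            frame[f"sed_{ft}"] = split["sedimentation"]
    frame["graz_OP"] = 0.0
    frame["sed_NF"] = 0.0

    # bacterial biomass and substrate: first-order lags on total lysis flux
    total_lysis = frame[[f"lysis_{ft}" for ft in FTS]].sum(axis=1).to_numpy()

    def lagged(gain: float, tau_h: float) -> np.ndarray:
        s = np.empty(n)
        s[0] = 0.0
        decay = dt / tau_h
        for i in range(1, n):
            s[i] = s[i - 1] + decay * (gain * total_lysis[i - 1] - s[i - 1])
        return s

    frame["BC"] = env.bc_baseline + lagged(env.bc_gain, env.bc_tau_h)
    frame["SBC"] = env.sbc_baseline + lagged(env.sbc_gain, env.sbc_tau_h)
    frame["bmx"] = env.bmx_h1
    frame["k_sbc"] = env.k_sbc_mgC_m3
    frame["y_BC"] = env.y_bc

    ndays = env.days_per_year
    frame["T_degC"] = env.temp_mean - env.temp_amplitude * np.cos(
        2.0 * np.pi * (day - env.temp_phase_day) / ndays)
    daily_mean_J = env.irradiance_mean - env.irradiance_amplitude * np.cos(
        2.0 * np.pi * day / ndays)
    hour = t % 24.0
    diel = np.maximum(0.0, np.sin(np.pi * (hour - 6.0) / 12.0))
    # mean of the clipped half-sine over 24 h is 1/pi; rescale to daily mean
    frame["J_Wm2"] = np.maximum(daily_mean_J, 0.0) * np.pi * diel
    frame["u10_ms"] = _wind_series(day, env, rng)
    frame["kD_m1"] = env.kd_m1
    frame["depth_m"] = env.depth_m

    extra = [c for c in OPTIONAL_ZERO_COLUMNS if c not in CSV_COLUMNS]
    return ForcingSeries(frame[CSV_COLUMNS + extra])


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_forcing(series: ForcingSeries, path) -> None:
    """Write the canonical CSV (full shortest-repr precision round-trips)."""
    cols = CSV_COLUMNS + [c for c in OPTIONAL_ZERO_COLUMNS
                          if c in series.frame.columns and c not in CSV_COLUMNS]
    # %.17g guarantees exact float64 round-trips
    series.frame[cols].to_csv(path, index=False, float_format="%.17g")


def read_forcing(path) -> ForcingSeries:
    """Read and validate a forcing CSV (schema of :data:`CSV_COLUMNS`)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ForcingValidationError(f"missing column(s): {', '.join(missing)}")
    numeric = [c for c in frame.columns
               if c in CSV_COLUMNS or c in OPTIONAL_ZERO_COLUMNS]
    frame[numeric] = frame[numeric].astype(float)
    nan_rows = frame[CSV_COLUMNS].isna().any(axis=1)
    if nan_rows.any():
        idx = int(np.flatnonzero(nan_rows.to_numpy())[0])
        raise ForcingValidationError(f"NaN value at row {idx}")
    for col in ("B_DA", "B_NF", "B_OP", "BC", "SBC"):
        if (frame[col] < 0).any():
            idx = int(np.flatnonzero((frame[col] < 0).to_numpy())[0])
            raise ForcingValidationError(f"negative {col} at row {idx}")
    t = frame["time_h"].to_numpy(float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ForcingValidationError("time_h is not strictly increasing")
    return ForcingSeries(frame)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_FLUX_COLUMNS = [
    "B_DA", "B_NF", "B_OP",
    "mu_DA", "mu_NF", "mu_OP",
    "lysis_DA", "lysis_NF", "lysis_OP",
    "graz_DA", "graz_NF", "graz_OP",
    "sed_DA", "sed_NF", "sed_OP",
    "BC", "SBC",
]


def validate_forcing(series: ForcingSeries, balance_tol: float = 1e-9) -> ValidationReport:
    """Check every record invariant; returns a report rather than raising.

    The carbon-balance residual |dB/dt - (mu - lysis - grazing - sed)| is
    checked at interior points with a forward difference, consistent with
    the generator's construction.
    """
    report = ValidationReport()
    f = series.frame
    n = len(f)

    for col in _FLUX_COLUMNS:
        neg = f[col].to_numpy(float) < 0
        for idx in np.flatnonzero(neg):
            report.add(int(idx), col, f"negative value {f[col].iloc[idx]}")

    for col, label in (("graz_OP", "grazing_OP"), ("sed_NF", "sed_NF")):
        nz = f[col].to_numpy(float) != 0.0
        for idx in np.flatnonzero(nz):
            report.add(int(idx), label, "structural zero violated")

    ybc = f["y_BC"].to_numpy(float)
    bad = ~((ybc > 0) & (ybc < 1))
    for idx in np.flatnonzero(bad):
        report.add(int(idx), "y_BC", f"growth efficiency {ybc[idx]} outside (0, 1)")

    if n > 1:
        dt = np.diff(f["time_h"].to_numpy(float))
        for ft in FTS:
            B = f[f"B_{ft}"].to_numpy(float)
            mu = f[f"mu_{ft}"].to_numpy(float)
            lysis = f[f"lysis_{ft}"].to_numpy(float)
            graz = f[f"graz_{ft}"].to_numpy(float)
            sed = f[f"sed_{ft}"].to_numpy(float)
            resid = np.diff(B) / dt - (mu - lysis - graz - sed)[:-1]
            tol = balance_tol * np.maximum(np.abs(mu[:-1]), 1.0)
            bad = np.abs(resid) > tol
            for idx in np.flatnonzero(bad):
                report.add(int(idx), f"balance_{ft}",
                           f"carbon balance residual {resid[idx]:.3e}")
    return report


# ---------------------------------------------------------------------------
# YAML scenario files
# ---------------------------------------------------------------------------

def scenario_from_yaml(path) -> tuple[list[BloomSpec], EnvironmentSpec]:
    """Load blooms + environment from a YAML file mirroring the dataclasses."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    blooms = [BloomSpec(**b) for b in doc.get("blooms", [])]
    env = EnvironmentSpec(**doc.get("environment", {}))
    return blooms, env


def scenario_to_yaml(blooms: Sequence[BloomSpec], env: EnvironmentSpec, path) -> None:
    doc = {
        "blooms": [dataclasses.asdict(b) for b in blooms],
        "environment": dataclasses.asdict(env),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
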