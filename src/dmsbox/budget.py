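"""Annual areal sulfur budget and percentage shares.

Integrates the per-step flux ledger over a full year and scales by the box
depth, yielding fluxes in mmolS m-2 y-1, then derives the percentage shares
used to characterize the cycle: functional-type shares of DMSPp production,
the fate of bacterial DMSPd uptake (assimilation / demethylation / lyase
cleavage), the sinks of gross DMS production (bacterial uptake /
photooxidation / emission) and emission as a share of DMSPp production.

``compute_shares`` also accepts a plain mapping of annual fluxes, so shares
can be evaluated directly from published numbers without running the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from dmsbox.sulfur import LEDGER_FIELDS, SimulationResult

HOURS_PER_YEAR = 8760.0


class BudgetError(ValueError):
    pass


@dataclass
class BudgetTable:
    """Annually integrated areal fluxes (mmolS m-2 y-1) and derived shares."""

    production_DA: float
    production_NF: float
    production_OP: float
    production_total: float
    phyto_lyase: float
    lysis_release: float
    grazing_release: float
    grazing_to_dms: float
    sedimentation: float
    s_assimilation: float
    demethylation: float
    bact_lyase: float
    dms_bact_uptake: float
    emission: float
    photooxidation: float
    dmspp_storage_change: float
    dmspd_storage_change: float
    dms_storage_change: float
    shares: dict = field(default_factory=dict)
    closure: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k not in ("shares", "closure")}
        out["shares"] = self.shares
        out["closure"] = self.closure
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def integrate_budget(result: SimulationResult, require_full_year: bool = True) -> BudgetTable:
    """Integrate a simulation's ledger into an annual areal budget.

    Each entry is sum(flux * dt) * H in mmolS m-2 y-1.  Closure residuals
    for the DMSPp and DMS pools are reported relative to their gross
    production.
    """
    t = result.ledger["time_h"].to_numpy(float)
    horizon = t[-1] - t[0] + result.dt_h
    if require_full_year and horizon < HOURS_PER_YEAR - 1e-6:
        raise BudgetError(
            f"ledger covers {horizon:.1f} h; a full year ({HOURS_PER_YEAR:.0f} h) is required")

    dt_h = result.dt_h
    H = result.depth_m
    areal = {name: float(result.ledger[name].to_numpy().sum() * dt_h * H)
             for name in LEDGER_FIELDS}

    traj = result.trajectory
    prod = [float(result.ledger[f"prod_{ft}"].to_numpy().sum() * dt_h * H)
            for ft in ("DA", "NF", "OP")]

    def storage(cols) -> float:
        start = sum(float(traj[c].iloc[0]) for c in cols)
        end = sum(float(traj[c].iloc[-1]) for c in cols)
        return (end - start) * H

    dmspp_storage = storage(["DMSPp_DA", "DMSPp_NF", "DMSPp_OP"])
    dmspd_storage = storage(["DMSPd"])
    dms_storage = storage(["DMS"])

    table = BudgetTable(
        production_DA=prod[0],
        production_NF=prod[1],
        production_OP=prod[2],
        production_total=sum(prod),
        phyto_lyase=areal["f1_phyto_lyase"],
        lysis_release=areal["f2_lysis_release"],
        grazing_release=areal["f3_grazing_release"],
        grazing_to_dms=areal["f3b_grazing_to_dms"],
        sedimentation=areal["f4_sedimentation"],
        s_assimilation=areal["f5_s_assimilation"],
        demethylation=areal["f6_demethylation"],
        bact_lyase=areal["f7_bact_lyase"],
        dms_bact_uptake=areal["f8_dms_bact_uptake"],
        emission=areal["f9_emission"],
        photooxidation=areal["f10_photooxidation"],
        dmspp_storage_change=dmspp_storage,
        dmspd_storage_change=dmspd_storage,
        dms_storage_change=dms_storage,
    )

    gross_pp_out = (table.phyto_lyase + table.lysis_release + table.grazing_release
                    + table.grazing_to_dms + table.sedimentation)
    gross_dms_in = table.phyto_lyase + table.grazing_to_dms + table.bact_lyase
    dms_out = table.dms_bact_uptake + table.emission + table.photooxidation
    table.closure = {
        "dmspp_residual": table.production_total - (dmspp_storage + gross_pp_out),
        "dms_residual": gross_dms_in - (dms_storage + dms_out),
        "dmspp_residual_rel": _safe_div(
            table.production_total - (dmspp_storage + gross_pp_out), table.production_total),
        "dms_residual_rel": _safe_div(
            gross_dms_in - (dms_storage + dms_out), gross_dms_in),
    }
    table.shares = compute_shares(table)
    return table


def _safe_div(num: float, den: float) -> float:
    return num / den if den else float("nan")


def compute_shares(table_or_fluxes, round_percent: bool = True) -> dict:
    """Percentage shares of the annual budget.

    Accepts a :class:`BudgetTable` or a mapping with any of the keys
    ``production_DA/NF/OP``, ``phyto_lyase``, ``grazing_to_dms``,
    ``bact_lyase``, ``s_assimilation``, ``demethylation``,
    ``dms_bact_uptake``, ``emission``, ``photooxidation``,
    ``production_total``.  A missing ``photooxidation`` is defined as the
    residual of gross DMS production minus uptake and emission.  Shares are
    rounded to the nearest integer percent unless ``round_percent=False``.
    """
    if isinstance(table_or_fluxes, BudgetTable):
        f = table_or_fluxes.to_dict()
    else:
        f = dict(table_or_fluxes)

    def get(key, default=None):
        return f[key] if key in f and f[key] is not None else default

    shares: dict = {}

    def pct(num, den):
        if den is None or den == 0 or num is None:
            return None
        value = 100.0 * num / den
        return int(round(value)) if round_percent else value

    # FT shares of DMSPp production
    prods = [get("production_DA"), get("production_NF"), get("production_OP")]
    if all(p is not None for p in prods):
        total = get("production_total", sum(prods))
        shares["production_DA_pct"] = pct(prods[0], total)
        shares["production_NF_pct"] = pct(prods[1], total)
        shares["production_OP_pct"] = pct(prods[2], total)

    # DMSPd fate shares over total bacterial DMSPd uptake
    branches = [get("s_assimilation"), get("demethylation"), get("bact_lyase")]
    if all(b is not None for b in branches):
        uptake_total = sum(branches)
        shares["dmspd_assimilation_pct"] = pct(branches[0], uptake_total)
        shares["dmspd_demethylation_pct"] = pct(branches[1], uptake_total)
        shares["dmspd_cleavage_pct"] = pct(branches[2], uptake_total)

    # DMS sink shares over gross DMS production
    phyto = get("phyto_lyase")
    bact = get("bact_lyase")
    if phyto is not None and bact is not None:
        gross = phyto + bact + (get("grazing_to_dms") or 0.0)
        uptake = get("dms_bact_uptake")
        emission = get("emission")
        photoox = get("photooxidation")
        if photoox is None and uptake is not None and emission is not None:
            photoox = gross - uptake - emission
            shares["photooxidation_residual"] = photoox
        shares["dms_bacterial_uptake_pct"] = pct(uptake, gross)
        shares["dms_photooxidation_pct"] = pct(photoox, gross)
        shares["dms_emission_pct"] = pct(emission, gross)

    # emission relative to total DMSPp production
    total_prod = get("production_total")
    if total_prod is None and all(p is not None for p in prods):
        total_prod = sum(prods)
    emission = get("emission")
    if emission is not None and total_prod:
        shares["emission_of_production_pct"] = pct(emission, total_prod)
        shares["emission_of_production_pct_raw"] = 100.0 * emission / total_prod

    return shares


def shares_from_printed(path_or_mapping) -> dict:
    """Evaluate shares from a JSON file (or mapping) of published annual
    fluxes, without running any simulation."""
    if isinstance(path_or_mapping, (str, bytes)) or hasattr(path_or_mapping, "__fspath__"):
        with open(path_or_mapping) as fh:
            fluxes = json.load(fh)
    else:
        fluxes = dict(path_or_mapping)
    return compute_shares(fluxes)


def budget_frame(table: BudgetTable) -> pd.DataFrame:
    """Tidy one-row DataFrame view of the budget (for CSV export)."""
    d = table.to_dict()
    flat = {k: v for k, v in d.items() if not isinstance(v, dict)}
    for k, v in d["shares"].items():
        flat[f"share_{k}"] = v
    for k, v in d["closure"].items():
        flat[f"closure_{k}"] = v
    return pd.DataFrame([flat])
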