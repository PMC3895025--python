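"""Sensitivity-experiment harness: 21 builtin parameter variations plus a
reference run, each a full-year simulation on identical forcing (except for
the wind-forcing tests) reporting annual mean DMS and annual air-sea flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from dmsbox.budget import integrate_budget
from dmsbox.forcing import BloomSpec, EnvironmentSpec, ForcingSeries, default_scenario, generate_forcing
from dmsbox.sulfur import SulfurParams, run_simulation

MOLAR = SulfurParams.quota_from_molar  # molS:molC -> mmolS:mgC


@dataclass
class SensitivityTest:
    """One named perturbation of the reference configuration.

    ``param_changes`` maps :class:`SulfurParams` field names to replacement
    values; ``wind_mode`` is None, ``("constant", value)`` or
    ``("scale", factor)``.
    """

    id: str
    description: str
    param_changes: dict = field(default_factory=dict)
    wind_mode: tuple | None = None

    def apply(self, params: SulfurParams) -> SulfurParams:
        for key in self.param_changes:
            if not hasattr(params, key):
                raise KeyError(f"{self.id}: unknown parameter path {key!r}")
        return params.replace(**self.param_changes)


def builtin_tests() -> list[SensitivityTest]:
    """The 21 builtin sensitivity tests (quotas, lyase yields, bacterial
    community ratios, cleavage fraction, wind and k parameterization)."""
    t = [
        SensitivityTest("test1", "high flagellate/colonial S:C quota (0.018 molS:molC)",
                        {"SC_NF": MOLAR(0.018), "SC_OP": MOLAR(0.018)}),
        SensitivityTest("test2", "low flagellate/colonial S:C quota (0.004 molS:molC)",
                        {"SC_NF": MOLAR(0.004), "SC_OP": MOLAR(0.004)}),
        SensitivityTest("test3", "high diatom S:C quota (0.00212 molS:molC)",
                        {"SC_DA": MOLAR(0.00212)}),
        SensitivityTest("test4", "zero diatom S:C quota", {"SC_DA": 0.0}),
        SensitivityTest("test5", "Skeletonema-type diatom S:C quota (0.0034 molS:molC)",
                        {"SC_DA": MOLAR(0.0034)}),
        SensitivityTest("test6", "no algal lyase activity",
                        {"y_DMS_DA": 0.0, "y_DMS_NF": 0.0, "y_DMS_OP": 0.0}),
        SensitivityTest("test7", "algal lyase yield 0.25 (all groups)",
                        {"y_DMS_DA": 0.25, "y_DMS_NF": 0.25, "y_DMS_OP": 0.25}),
        SensitivityTest("test8", "algal lyase yield 0.5 (all groups)",
                        {"y_DMS_DA": 0.5, "y_DMS_NF": 0.5, "y_DMS_OP": 0.5}),
        SensitivityTest("test9", "algal lyase yield 0.5 (flagellates+colonials)",
                        {"y_DMS_NF": 0.5, "y_DMS_OP": 0.5}),
        SensitivityTest("test10", "algal lyase yield 0.5 (diatoms only)",
                        {"y_DMS_DA": 0.5}),
        SensitivityTest("test11", "high bacterial S:C quota (1:37)",
                        {"SC_BC": 1.0 / 37.0}),
        SensitivityTest("test12", "low bacterial S:C quota (1:196)",
                        {"SC_BC": 1.0 / 196.0}),
        SensitivityTest("test13", "75% of bacteria use DMSPd and DMS",
                        {"ratio_S_DMSPd": 0.75, "ratio_S_DMS": 0.75}),
        SensitivityTest("test14", "50% of bacteria use DMSPd and DMS",
                        {"ratio_S_DMSPd": 0.5, "ratio_S_DMS": 0.5}),
        SensitivityTest("test15", "50% of bacteria use DMSPd",
                        {"ratio_S_DMSPd": 0.5}),
        SensitivityTest("test16", "50% of bacteria use DMS",
                        {"ratio_S_DMS": 0.5}),
        SensitivityTest("test17", "bacterial cleavage fraction 0.25",
                        {"lyase_bact": 0.25}),
        SensitivityTest("test18", "constant annual-mean wind 3.9 m s-1",
                        wind_mode=("constant", 3.9)),
        SensitivityTest("test19", "wind speed -25%", wind_mode=("scale", 0.75)),
        SensitivityTest("test20", "wind speed +25%", wind_mode=("scale", 1.25)),
        SensitivityTest("test21", "dual-tracer (quadratic) k600 parameterization",
                        {"k600_method": "nightingale"}),
    ]
    return t


def _with_wind(forcing: ForcingSeries, wind_mode: tuple | None) -> ForcingSeries:
    if wind_mode is None:
        return forcing
    frame = forcing.frame.copy()
    kind, value = wind_mode
    if kind == "constant":
        frame["u10_ms"] = float(value)
    elif kind == "scale":
        frame["u10_ms"] = frame["u10_ms"] * float(value)
    else:
        raise ValueError(f"unknown wind mode {kind!r}")
    return ForcingSeries(frame)


def run_experiment(tests: Sequence[SensitivityTest] | None = None,
                   blooms: Sequence[BloomSpec] | None = None,
                   env: EnvironmentSpec | None = None,
                   params: SulfurParams | None = None,
                   dt: float = 0.25, seed: int = 0,
                   forcing: ForcingSeries | None = None,
                   keep_budgets: bool = False):
    """Run the reference plus each sensitivity test on identical forcing.

    Returns a DataFrame with one row per run: annual mean DMS
    (umolS m-3), annual F_DMS (mmolS m-2 y-1); budgets optionally attached
    via the second return value (id -> BudgetTable) when
    ``keep_budgets=True``.
    """
    if tests is None:
        tests = builtin_tests()
    if forcing is None:
        if blooms is None or env is None:
            blooms, env = default_scenario()
        forcing = generate_forcing(blooms, env, dt=dt, seed=seed)
    base_params = params or SulfurParams()

    rows = []
    budgets = {}

    def one_run(run_id: str, description: str, run_params: SulfurParams,
                wind_mode: tuple | None) -> None:
        f = _with_wind(forcing, wind_mode)
        result = run_simulation(f, run_params)
        table = integrate_budget(result)
        rows.append({
            "id": run_id,
            "description": description,
            "annual_mean_dms_umolS_m3": float(result.trajectory["DMS"].mean() * 1000.0),
            "annual_fdms_mmolS_m2_y": table.emission,
        })
        if keep_budgets:
            budgets[run_id] = table

    one_run("reference", "reference configuration", base_params, None)
    for test in tests:
        one_run(test.id, test.description, test.apply(base_params), test.wind_mode)

    frame = pd.DataFrame(rows)
    if keep_budgets:
        return frame, budgets
    return frame
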