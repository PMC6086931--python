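"""Scenario decision model: maps a named parameter draw to an
(incremental cost, incremental DALYs averted) pair for one program year.

This is the glue between the parameter tables (see
:mod:`mhealth_cea.synthetic`) and the PSA/tornado machinery: the same
closure serves as the deterministic model (evaluated at point
estimates), the Monte Carlo model, and the one-way sensitivity model.

Parameter names understood by the model:

``users``,
``p_anc4_int`` / ``p_anc4_comp``, ``p_imm_int`` / ``p_imm_comp``,
``p_cc_int`` / ``p_cc_comp`` (carried for reporting; lives saved are an
explicit parameter, so comprehensive-care draws do not re-enter the
effect side — the published lives-saved range already encodes
coverage-effect uncertainty),
``lives_saved``,
``cost_registration``, ``cost_anc_first``, ``cost_anc_later``,
``cost_pnc_first``, ``cost_pnc_later``, ``cost_user_anc``,
``cost_user_pnc``, ``cost_sms_delivery``, ``cost_program_other``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .cea import PerspectiveCosts, UnitCosts, incremental_cost_by_perspective
from .effects import ArmUtilization, DalyConfig, daly_per_death
from .uncertainty import ParameterSpec


def perspective_costs_from_values(values: Mapping[str, float]) -> PerspectiveCosts:
    """Incremental costs by perspective for one parameter assignment."""
    uc = UnitCosts(
        registration_provider=values["cost_registration"],
        anc_visit_first=values["cost_anc_first"],
        anc_visit_subsequent=values["cost_anc_later"],
        pnc_visit_first=values["cost_pnc_first"],
        pnc_visit_subsequent=values["cost_pnc_later"],
        user_anc_visit=values["cost_user_anc"],
        user_pnc_visit=values["cost_user_pnc"],
    )
    # Comprehensive-care coverage cannot exceed either component; random
    # draws of the marginals are clamped into the feasible region.
    p_cc_i = min(values["p_cc_int"], values["p_anc4_int"], values["p_imm_int"])
    p_cc_c = min(values["p_cc_comp"], values["p_anc4_comp"], values["p_imm_comp"])
    intervention = ArmUtilization(
        "intervention", values["p_anc4_int"], values["p_imm_int"], p_cc_i,
        n=max(1, int(round(values["users"]))),
    )
    comparison = ArmUtilization(
        "comparison", values["p_anc4_comp"], values["p_imm_comp"], p_cc_c,
        n=max(1, int(round(values["users"]))),
    )
    program = values["cost_sms_delivery"] + values["cost_program_other"]
    return incremental_cost_by_perspective(
        program, intervention, comparison, values["users"], uc
    )


def scale_up_model(daly_config: DalyConfig = DalyConfig(), perspective: str = "societal"):
    """Build a model closure ``values -> (delta_cost, delta_dalys)``.

    ``perspective`` selects which incremental cost is returned
    (``societal``, ``program``, ``health_system`` or ``user``).
    """
    factor = daly_per_death(daly_config)

    def model(values: Mapping[str, float]) -> tuple[float, float]:
        pc = perspective_costs_from_values(values)
        delta_cost = getattr(pc, perspective)
        delta_dalys = values["lives_saved"] * factor
        return delta_cost, delta_dalys

    return model


def point_values(specs: Sequence[ParameterSpec]) -> dict[str, float]:
    """Point-estimate assignment for a parameter table."""
    return {s.name: s.point for s in specs}
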