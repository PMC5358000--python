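"""Construction of the calibrated default parameter set and baseline state.

The baseline is built analytically as an exact fixed point of the coupled
model: compartment volumes follow from the subject's anthropometry and the
clinical anchors (serum Na 140 mmol/L, osmolality 288 mOsm/kg, hematocrit
0.43, protein 7 g/dL); the glomerular network is solved from the GFR/RPF
anchors; the collecting-duct Hill constant is solved so baseline urine
flow is exactly 0.58 mL/min at baseline AVP (2.5 pg/mL); lymph flow is
scaled so capillary filtration minus lymph equals the insensible loss;
basal oral intake equals urinary plus insensible losses.  Every hormone
multiplier equals 1 at the constructed state, so all time derivatives
vanish there and ``find_baseline`` converges immediately.

``preset="hummod-like"`` raises the minimal urine osmolality to
324 mOsm/kg, reproducing the limited urine dilution the source model
showed after an acute water load; the default preset dilutes correctly
(floor 50 mOsm/kg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .core_state import LN2, FluidState, ModelParams, Subject
from .endocrine import HormoneState
from .errors import DegenerateStateError
from .exchange import oncotic_pressure

PRESETS = ("default", "hummod-like")


@dataclass
class InitialState:
    fluid: FluidState
    hormones: HormoneState
    oro_drive: float = 0.0


def calibrate(subject: Subject | None = None, preset: str = "default",
              overrides: dict | None = None):
    """Return ``(ModelParams, InitialState)`` for a subject.

    ``overrides`` (and ``subject.param_overrides``) are applied by field
    name before the derived quantities are computed, so overriding e.g.
    ``urine_flow0`` re-solves the collecting-duct calibration.
    """
    subject = subject or Subject()
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid: {PRESETS}")
    p = ModelParams()
    if preset == "hummod-like":
        p.u_min = 324.0
    merged = dict(subject.param_overrides)
    if overrides:
        merged.update(overrides)
    for name, value in merged.items():
        if not hasattr(p, name):
            raise KeyError(f"unknown parameter {name!r}")
        setattr(p, name, value)

    # --- compartments -------------------------------------------------------
    tbw = subject.body_mass * subject.tbw_fraction
    v_ic = tbw * subject.icf_fraction
    ecf = tbw - v_ic
    v_pl = ecf * p.plasma_fraction_of_ecf
    v_is = ecf - v_pl
    na_ec = p.serum_na0 * ecf
    p.osm_offset = p.serum_osm0 - 2.0 * p.serum_na0
    osm_ic = p.serum_osm0 * v_ic
    v_rbc = v_pl * p.hct0 / (1.0 - p.hct0)
    prot_pl = p.prot_conc0 * 10.0 * v_pl
    p.ecf0 = ecf
    p.v_is0 = v_is
    p.bv0 = v_pl + v_rbc

    # --- oncotic / Starling / lymph -----------------------------------------
    p.pi_scale = 1.0
    p.pi_scale = p.pi_anchor / oncotic_pressure(7.0, p)
    p.pi_if = oncotic_pressure(p.prot_is, p)
    pi_c0 = oncotic_pressure(p.prot_conc0, p)
    j_cap0 = p.K_f * ((p.p_c0 - p.p_i0) - p.sigma * (pi_c0 - p.pi_if))
    lymph0 = j_cap0 - p.insensible * 1000.0
    if not 0.0 < lymph0 < p.lymph_max:
        raise DegenerateStateError("lymph0", lymph0,
                                   "baseline lymph flow outside (0, lymph_max); "
                                   "check Starling anchors")
    p.lymph_scale = (p.p_i0 - p.p_i_thresh) / math.log(p.lymph_max / (p.lymph_max - lymph0))

    # --- glomerular network -------------------------------------------------
    rbf0 = p.rpf0 / (1.0 - p.hct0)
    r_tot = (p.map0 - p.p_ven) / rbf0
    p.r_aff0 = (p.map0 - p.p_glom0) / rbf0
    p.r_eff0 = r_tot - p.r_aff0
    pi_g0 = p.pi_glom_factor * pi_c0
    nfp0 = p.p_glom0 - p.p_bowman - pi_g0
    if nfp0 <= 0:
        raise DegenerateStateError("net_filtration_pressure", nfp0)
    p.kf_glom = p.gfr0 / nfp0

    # --- tubule calibration (whole-kidney, nephron_multiplier = 1) ----------
    filtered_na0 = p.gfr0 * p.serum_na0 / 1000.0
    p.na_md0 = filtered_na0 * (1.0 - p.f_pt - p.f_lh_na)
    q2 = p.gfr0 * (1.0 - p.f_pt - p.f_lh_w)
    q3 = q2 * (1.0 - p.f_dt_w)
    na_u0 = p.na_md0 * (1.0 - p.f_dt_na0)
    m0 = 2.0 * na_u0 + p.x_osm
    q_eq0 = m0 / (p.u_max / 1000.0)
    perm0 = (q3 - p.urine_flow0) / (q3 - q_eq0)
    if not p.cd_perm_min < perm0 < p.cd_perm_max:
        raise DegenerateStateError("cd_perm0", perm0,
                                   "baseline CD permeability outside its bounds; "
                                   "check segmental fractions vs urine_flow0")
    p.cd_perm_k = p.avp0 * ((p.cd_perm_max - perm0) /
                            (perm0 - p.cd_perm_min)) ** (1.0 / p.cd_perm_n)
    # TGF sigmoid centered so the multiplier is exactly 1 at baseline delivery.
    span = p.tgf_max - p.tgf_min
    p.tgf_center = p.na_md0 + math.log(span / (1.0 - p.tgf_min) - 1.0) / p.tgf_slope

    # --- AVP secretion line and store ---------------------------------------
    p.avp_slope = (p.avp0 - p.avp_floor) / (p.serum_osm0 - p.osm_threshold)
    p.s0_secretion = LN2 / p.avp_half_life * (p.v_d_avp * 1000.0) * p.avp0
    p.synthesis_rate = p.synthesis_mult * p.s0_secretion

    # --- basal intake balancing losses --------------------------------------
    p.basal_water_intake = (p.urine_flow0 / 1000.0) + p.insensible
    p.basal_na_intake = na_u0

    gut_w0 = p.basal_water_intake / p.k_abs_w
    gut_na0 = p.basal_na_intake / p.k_abs_na

    fluid = FluidState(V_ic=v_ic, V_is=v_is, V_pl=v_pl, V_rbc=v_rbc,
                       Na_ec=na_ec, Osm_ic=osm_ic, Prot_pl=prot_pl,
                       Gut_w=gut_w0, Gut_Na=gut_na0, Bladder_v=0.0, CWI=0.0)
    hormones = HormoneState(avp=p.avp0, avp_store=p.store_max,
                            anp=1.0, pra=1.0, angII=1.0, aldo=1.0)
    return p, InitialState(fluid=fluid, hormones=hormones)


def hummod_like(subject: Subject | None = None, overrides: dict | None = None):
    """Parameter preset reproducing the source model's limited urine dilution."""
    return calibrate(subject, preset="hummod-like", overrides=overrides)
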