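"""Single-nephron renal model scaled by the number of filtering nephrons.

The afferent-arteriole / glomerulus / efferent-arteriole complex is an
ohmic (resistance) network with no compliance.  The afferent arteriole
carries two multiplicative controls: tubuloglomerular feedback (TGF) from
macula-densa sodium delivery, and a myogenic response that is affine in
arterial pressure and chosen so that, at baseline multipliers, glomerular
capillary pressure — and hence GFR — is independent of perfusion pressure.
Angiotensin II constricts the efferent arteriole, raising filtration
fraction.

Segmental transport uses constant fractional reabsorption for the proximal
tubule (glomerulotubular balance) and loop of Henle — the loop removes a
larger sodium than water fraction, delivering dilute fluid to the macula
densa — hormone-scaled fractions for the distal tubule (aldosterone up,
ANP down), and an AVP-controlled collecting duct that moves urine toward
osmotic equilibrium with a static medullary gradient capped at ``u_max``.
A constant obligate non-sodium osmolar excretion (urea etc.) keeps
dehydrated urine concentrating rather than shutting off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_state import ModelParams
from .endocrine import avp_effects
from .errors import ConvergenceError, InternalConsistencyError
from .exchange import oncotic_pressure


@dataclass
class GlomState:
    R_aff: float    # afferent resistance, mmHg.min/mL
    R_eff: float    # efferent resistance, mmHg.min/mL
    P_glom: float   # glomerular capillary pressure, mmHg
    GFR: float      # mL/min
    RBF: float      # renal blood flow, mL/min
    FF: float       # filtration fraction


@dataclass
class RenalOutput:
    urine_flow: float   # mL/min
    urine_Na: float     # mmol/min
    urine_osm: float    # mOsm/kg
    Na_MD: float        # mmol/min sodium delivery at the macula densa


def glomerular_hemodynamics(map_mmhg: float, tgf_mult: float, angii_mult: float,
                            prot_conc: float, params: ModelParams,
                            nephron_mult: float = 1.0) -> GlomState:
    """Solve the two-resistor glomerular network for GFR, RBF and P_glom."""
    if map_mmhg <= 0:
        raise ValueError("map_mmhg must be positive")
    myo = max(params.myo_min,
              (map_mmhg - params.p_glom0) / (params.map0 - params.p_glom0))
    r_aff = params.r_aff0 * tgf_mult * myo / nephron_mult
    r_eff = params.r_eff0 * angii_mult / nephron_mult
    rbf = (map_mmhg - params.p_ven) / (r_aff + r_eff)
    p_glom = map_mmhg - rbf * r_aff
    pi_g = params.pi_glom_factor * oncotic_pressure(prot_conc, params)
    nfp = p_glom - params.p_bowman - pi_g
    gfr = params.kf_glom * nephron_mult * max(0.0, nfp)
    rpf = rbf * (1.0 - params.hct0)
    ff = gfr / rpf if rpf > 0 else 0.0
    return GlomState(R_aff=r_aff, R_eff=r_eff, P_glom=p_glom, GFR=gfr, RBF=rbf, FF=ff)


def tgf_multiplier(na_md: float, params: ModelParams) -> float:
    """Afferent-resistance multiplier from macula-densa sodium delivery.

    Monotone increasing sigmoid (high distal delivery constricts the
    afferent arteriole), equal to 1 at baseline delivery and bounded in
    [tgf_min, tgf_max].
    """
    if na_md < 0:
        raise ValueError("na_md must be non-negative")
    span = params.tgf_max - params.tgf_min
    return params.tgf_min + span / (1.0 + math.exp(-params.tgf_slope * (na_md - params.tgf_center)))


def tubule_transport(glom: GlomState, serum_na: float, hormones, params: ModelParams,
                     nephron_mult: float = 1.0) -> RenalOutput:
    """Staged mass balance along the nephron (whole-kidney flows)."""
    gfr = glom.GFR
    if gfr <= 0.0:
        return RenalOutput(urine_flow=0.0, urine_Na=0.0, urine_osm=params.u_min, Na_MD=0.0)

    filtered_w = gfr                              # mL/min
    filtered_na = gfr * serum_na / 1000.0         # mmol/min

    # Proximal tubule: iso-osmotic fractional reabsorption.
    q1 = filtered_w * (1.0 - params.f_pt)
    na1 = filtered_na * (1.0 - params.f_pt)
    # Loop of Henle: reabsorbs a larger Na than water fraction (of filtered load).
    q2 = q1 - params.f_lh_w * filtered_w
    na2 = na1 - params.f_lh_na * filtered_na
    if q2 < 0 or na2 < 0:
        raise InternalConsistencyError(
            f"loop of Henle outflow negative (q2={q2:.4g}, na2={na2:.4g})")
    na_md = na2
    # Distal tubule: aldosterone scales Na reabsorption up, ANP scales it down;
    # fixed water fraction.
    f_dt = params.f_dt_na0 * (1.0 + params.g_aldo_dt * (hormones.aldo - 1.0)) \
        * (1.0 - params.g_anp_dt * (hormones.anp - 1.0))
    f_dt = min(max(f_dt, 0.0), 0.998)
    na3 = na2 * (1.0 - f_dt)
    q3 = q2 * (1.0 - params.f_dt_w)
    if q3 < 0 or na3 < 0:
        raise InternalConsistencyError(
            f"distal outflow negative (q3={q3:.4g}, na3={na3:.4g})")
    # Collecting duct: AVP-dependent permeability moves urine toward osmotic
    # equilibrium with the medullary gradient (osmolality u_max).
    perm = avp_effects(hormones.avp, params).cd_perm
    m = 2.0 * na3 + params.x_osm * nephron_mult    # mOsm/min excreted osmoles
    q_eq = m / (params.u_max / 1000.0)             # mL/min at full equilibration
    flow = q3 - perm * max(0.0, q3 - q_eq)
    if flow <= 0:
        raise InternalConsistencyError(f"collecting-duct outflow non-positive ({flow:.4g})")
    uosm = 1000.0 * m / flow
    uosm = min(max(uosm, params.u_min), params.u_max)
    return RenalOutput(urine_flow=flow, urine_Na=na3, urine_osm=uosm, Na_MD=na_md)


def renal_step(observables, pressures, hormones, params: ModelParams,
               nephron_mult: float = 1.0, tgf_guess: float = 1.0):
    """One algebraic kidney evaluation with the TGF loop closed.

    The TGF fixed point (tgf_multiplier o Na_MD) is found by damped
    fixed-point iteration (the undamped loop gain exceeds 1).  Returns
    ``(RenalOutput, GlomState, tgf_mult)``.
    """
    angii_mult = max(0.5, 1.0 + params.g_ang_reff * (hormones.angII - 1.0))
    x = min(max(tgf_guess, params.tgf_min), params.tgf_max)
    lam = params.tgf_damping
    glom = None
    out = None
    for _ in range(params.tgf_max_iter):
        glom = glomerular_hemodynamics(pressures.map_mmHg, x, angii_mult,
                                       observables.prot_conc, params, nephron_mult)
        out = tubule_transport(glom, observables.serum_Na, hormones, params, nephron_mult)
        x_new = tgf_multiplier(out.Na_MD / nephron_mult, params)
        step = x_new - x
        x = x + lam * step
        if abs(step) < params.tgf_tol:
            return out, glom, x
    raise ConvergenceError(
        "TGF fixed point did not converge",
        diagnostics={"tgf_mult": x, "na_md": out.Na_MD if out else None,
                     "gfr": glom.GFR if glom else None},
    )
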