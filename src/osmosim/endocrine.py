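"""AVP synthesis, secretion, clearance and effects; ANP; the RAAS cascade.

Arginine vasopressin (AVP) is synthesized in the hypothalamus, stored in the
neurohypophysis and secreted in response to serum osmolality above a set
point; baroreceptor *unloading* (hypovolemia/hypotension) multiplies the
osmotic drive.  Note that the classical sign convention is used here —
reduced baroreceptor activity stimulates secretion.  Circulating AVP is
cleared first-order with a half-life of 20 min by default (the physiologic
range is 10-35 min).

Secretion is expressed through a *target concentration*: the steady plasma
AVP the current stimuli would sustain, ``avp_floor + avp_slope * max(0,
osm - threshold)``, converted to a pg/min rate through the clearance
constant and distribution volume.  This makes the osmoregulation line
(0.3 pg/mL per mOsm/kg above 280, passing through 2.5 pg/mL at 288)
directly readable from the parameters.

An optional oropharyngeal reflex transiently suppresses secretion while
water is being drunk, before any osmotic change — the rapid post-drinking
AVP fall seen in rehydration experiments.  The reflex scales with the
hypotonicity of the ingested fluid and is ON by default.

ANP relaxes toward an atrial-pressure-driven target; renin responds to
renal perfusion pressure, macula-densa sodium delivery and the
baroreflexes; angiotensin II tracks renin quickly and aldosterone tracks
angiotensin II over hours.  ANP, renin, AngII and aldosterone are relative
(1 = baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_state import LN2, ModelParams


@dataclass
class HormoneState:
    """Circulating hormone levels.  avp in pg/mL; others relative (1 = baseline)."""

    avp: float
    avp_store: float   # pg, neurohypophyseal pool
    anp: float
    pra: float         # plasma renin activity
    angII: float
    aldo: float


@dataclass
class AvpEffects:
    vascular_mult: float  # >= 1, multiplies peripheral resistance
    cd_perm: float        # collecting-duct water permeability, in [perm_min, perm_max]


def avp_target(serum_osm: float, params: ModelParams) -> float:
    """Steady plasma AVP (pg/mL) sustained by a given serum osmolality."""
    return params.avp_floor + params.avp_slope * max(0.0, serum_osm - params.osm_threshold)


def avp_secretion(serum_osm: float, baro, store: float, params: ModelParams,
                  oro_inhibition: float = 0.0) -> float:
    """Neurohypophyseal AVP secretion rate, pg/min.

    Store-limited; zero when the pool is empty.  ``oro_inhibition`` in [0, 1]
    is the oropharyngeal suppression state (0 = no suppression).
    """
    if store <= 0.0:
        return 0.0
    sat = min(1.0, store / params.store_k)
    combined = 0.5 * (baro.arterial + baro.cardiac)
    baro_mult = max(0.0, 1.0 + params.baro_gain_avp * (1.0 - combined))
    k = LN2 / params.avp_half_life
    return (sat * k * (params.v_d_avp * 1000.0) * avp_target(serum_osm, params)
            * baro_mult * (1.0 - oro_inhibition))


def hormone_kinetics(conc: float, secretion_rate: float, distribution_volume: float,
                     half_life: float) -> float:
    """d(concentration)/dt for first-order clearance.

    ``conc`` in pg/mL, ``secretion_rate`` in pg/min, ``distribution_volume``
    in mL.  With secretion off the concentration halves every ``half_life``
    minutes.
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    return secretion_rate / distribution_volume - (LN2 / half_life) * conc


def anp_secretion(P_ra: float, params: ModelParams) -> float:
    """Relative ANP secretion, monotone in right-atrial pressure, 1 at baseline."""
    return math.exp(params.anp_gain * (P_ra - params.p_ra0))


def raas_cascade(map_mmhg: float, na_md: float, baro, hormones: HormoneState,
                 params: ModelParams):
    """Time derivatives of (pra, angII, aldo).

    Renin secretion falls with renal perfusion pressure and with
    macula-densa sodium delivery; all three relax to 1 at baseline inputs.
    """
    combined = 0.5 * (baro.arterial + baro.cardiac)
    drive = math.exp(
        -params.g_renin_map * (map_mmhg - params.map0) / params.map0
        - params.g_renin_na * (na_md - params.na_md0) / params.na_md0
        + params.g_renin_baro * (1.0 - combined)
    )
    dpra = (drive - hormones.pra) / params.tau_renin
    dang = (hormones.pra - hormones.angII) / params.tau_angii
    daldo = (hormones.angII - hormones.aldo) / params.tau_aldo
    return dpra, dang, daldo


def avp_effects(avp: float, params: ModelParams) -> AvpEffects:
    """Vascular and collecting-duct actions of AVP.

    The pressor effect saturates with a supraphysiologic EC50 so it is only
    mildly above 1 at baseline AVP; collecting-duct water permeability is a
    Hill function saturating at ``cd_perm_max``.
    """
    a = max(avp, 0.0)
    hv = a ** params.n_avp_vas / (a ** params.n_avp_vas + params.ec50_avp_vas ** params.n_avp_vas) if a > 0 else 0.0
    vascular = 1.0 + params.v_avp_vas * hv
    n = params.cd_perm_n
    hp = a ** n / (a ** n + params.cd_perm_k ** n) if a > 0 else 0.0
    cd = params.cd_perm_min + (params.cd_perm_max - params.cd_perm_min) * hp
    return AvpEffects(vascular_mult=vascular, cd_perm=cd)
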