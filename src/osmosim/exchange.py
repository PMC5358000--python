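"""Water movement between compartments and a minimal hemodynamic model.

Transcapillary exchange follows the Starling relation; lymph is a valved,
saturating, strictly non-negative return path driven by interstitial
pressure; intracellular/extracellular water moves down the osmotic gradient.
A single capillary bed at one gravitational level is used: all packaged
protocols are non-orthostatic.

Cardiac output is eliminated as an explicit variable — mean arterial
pressure is a volume-driven pressure function times a total-peripheral-
resistance multiplier assembled from the vascular actions of AVP and
angiotensin II.  Capillary pressure is affine in MAP and blood volume,
interstitial pressure affine in interstitial volume (compliance).
Baseline anchors: MAP 93 mmHg, right-atrial pressure 0 mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_state import ModelParams
from .endocrine import avp_effects
from .errors import DegenerateStateError


@dataclass
class PressureState:
    map_mmHg: float   # mean arterial pressure
    P_c: float        # capillary hydrostatic pressure, mmHg
    P_i: float        # interstitial hydrostatic pressure, mmHg
    P_ra: float       # right-atrial pressure, mmHg
    tpr_mult: float   # total peripheral resistance multiplier


@dataclass
class BaroSignal:
    """Normalized baroreceptor activities; 1 = baseline, bounded in (0, 2)."""

    arterial: float
    cardiac: float


def osmotic_flux(icf_osm: float, ecf_osm: float, k_osm: float) -> float:
    """Water flux into the intracellular space, L/min.

    Antisymmetric in its arguments: water leaves the cells when the
    extracellular fluid is hypertonic.
    """
    if icf_osm <= 0:
        raise DegenerateStateError("icf_osm", icf_osm)
    if ecf_osm <= 0:
        raise DegenerateStateError("ecf_osm", ecf_osm)
    return k_osm * (icf_osm - ecf_osm)


def oncotic_pressure(prot_conc: float, params: ModelParams) -> float:
    """Colloid osmotic pressure, mmHg, from protein concentration in g/dL.

    Landis-Pappenheimer cubic, rescaled so that 7 g/dL maps to the
    calibration anchor (25 mmHg by default).  Monotone increasing and
    convex; zero at zero protein.
    """
    c = max(prot_conc, 0.0)
    return params.pi_scale * (2.1 * c + 0.16 * c * c + 0.009 * c ** 3)


def starling_flux(P_c: float, P_i: float, pi_c: float, pi_i: float,
                  K_f: float, sigma: float) -> float:
    """Capillary-to-interstitium filtration, mL/min (negative = reabsorption)."""
    return K_f * ((P_c - P_i) - sigma * (pi_c - pi_i))


def lymph_flow(P_i: float, params: ModelParams) -> float:
    """Interstitium-to-plasma lymph flow, mL/min.

    Zero at or below the interstitial pressure threshold (lymphatic valves),
    monotone increasing above it, saturating at ``lymph_max``.
    """
    x = P_i - params.p_i_thresh
    if x <= 0.0:
        return 0.0
    return params.lymph_max * (1.0 - math.exp(-x / params.lymph_scale))


def hemodynamics(blood_volume: float, v_is: float, hormones, params: ModelParams) -> PressureState:
    """Pressures and the resistance multiplier from volumes and hormones."""
    if blood_volume <= 0:
        raise DegenerateStateError("blood_volume", blood_volume)
    vas0 = avp_effects(params.avp0, params).vascular_mult
    vas = avp_effects(hormones.avp, params).vascular_mult / vas0
    ang = max(0.5, 1.0 + params.g_ang_tpr * (hormones.angII - 1.0))
    tpr = vas * ang
    dbv = blood_volume - params.bv0
    map_mmhg = params.map0 * (1.0 + params.g_bv * dbv / params.bv0) * tpr
    p_c = params.p_c0 + params.c_pc_map * (map_mmhg - params.map0) + params.c_pc_bv * dbv
    p_i = params.p_i0 + (v_is - params.v_is0) / params.c_is
    p_ra = params.p_ra0 + dbv / params.c_ra
    return PressureState(map_mmHg=map_mmhg, P_c=p_c, P_i=p_i, P_ra=p_ra, tpr_mult=tpr)


def baro_signals(pressures: PressureState, params: ModelParams) -> BaroSignal:
    """Sigmoidal baroreceptor activities, equal to 1 at baseline pressures."""
    art = 2.0 / (1.0 + math.exp(-params.k_baro_art * (pressures.map_mmHg - params.map0)))
    card = 2.0 / (1.0 + math.exp(-params.k_baro_card * (pressures.P_ra - params.p_ra0)))
    return BaroSignal(arterial=art, cardiac=card)
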