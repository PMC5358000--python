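"""Oral/IV input routing, gut absorption, thirst drive and drinking.

Gastric emptying and intestinal absorption are lumped into one first-order
stage with a 12-min water half-time; ingested fluid enters the gut pools
and is absorbed into plasma.  IV infusions bypass the gut.  Thirst is zero
below an osmotic threshold and grows with serum osmolality above it and
with extracellular volume deficit; the drinking rate during an ad-libitum
window saturates with drive and is inhibited by gastric distension, which
front-loads intake at the start of the window.  Insensible water loss is a
fixed 0.625 mL/min (~0.9 L/day, resting indoor subject, no sweating).
"""

from __future__ import annotations

from .core_state import FluidState, ModelParams
from .errors import ScheduleError


def event_rates(event, t: float):
    """Constant rates contributed by an intake event at time ``t``.

    Returns ``(oral_w L/min, oral_na mmol/min, iv_w L/min, iv_na mmol/min)``.
    Loads and infusions deliver their volume at constant rate over
    ``[t_start, t_start + duration)``.
    """
    if event.kind not in ("oral_load", "iv_infusion"):
        return 0.0, 0.0, 0.0, 0.0
    if not (event.t_start <= t < event.t_start + event.duration):
        return 0.0, 0.0, 0.0, 0.0
    w_rate = event.volume / event.duration / 1000.0          # L/min
    na_rate = w_rate * event.na_conc                          # mmol/min
    if event.kind == "oral_load":
        return w_rate, na_rate, 0.0, 0.0
    return 0.0, 0.0, w_rate, na_rate


def apply_intake_event(event, state: FluidState, t0: float, t1: float) -> FluidState:
    """Apply the portion of an intake event falling in ``[t0, t1]``.

    Oral loads add to the gut pools (and to cumulative water intake); IV
    infusions add directly to plasma water and extracellular sodium.
    Discrete-time convenience wrapper; the integrator uses
    :func:`event_rates` inside the derivative instead.
    """
    if event.kind not in ("oral_load", "iv_infusion"):
        return state.copy()
    if event.volume < 0 or event.na_conc < 0:
        raise ScheduleError(f"negative volume/concentration in event {event!r}")
    if event.duration <= 0:
        raise ScheduleError(f"load/infusion event needs duration > 0: {event!r}")
    lo = max(t0, event.t_start)
    hi = min(t1, event.t_start + event.duration)
    overlap = max(0.0, hi - lo)
    if overlap == 0.0 or event.volume == 0.0:
        return state.copy()
    vol_l = event.volume / event.duration * overlap / 1000.0
    na = vol_l * event.na_conc
    new = state.copy()
    if event.kind == "oral_load":
        new.Gut_w += vol_l
        new.Gut_Na += na
        new.CWI += vol_l
    else:
        new.V_pl += vol_l
        new.Na_ec += na
    return new


def gut_absorption(gut_w: float, gut_na: float, params: ModelParams):
    """First-order absorption fluxes to plasma: (L/min water, mmol/min sodium)."""
    return params.k_abs_w * max(gut_w, 0.0), params.k_abs_na * max(gut_na, 0.0)


def thirst_drive(serum_osm: float, volume_deficit: float, params: ModelParams) -> float:
    """Dimensionless thirst drive (>= 0).

    ``volume_deficit`` is the fractional extracellular volume deficit
    (0 = euvolemic).  Zero below the osmotic threshold with no deficit.
    """
    return (params.g_thirst_osm * max(0.0, serum_osm - params.thirst_osm_thresh)
            + params.g_thirst_vol * max(0.0, volume_deficit))


def drinking_rate(drive: float, ad_lib_open: bool, gut_fill: float,
                  params: ModelParams) -> float:
    """Drinking rate in mL/min during an ad-libitum window.

    Zero when the window is closed or drive is zero; otherwise a saturating
    function of drive times a gastric-satiation factor decreasing with gut
    distension.  Bounded by ``drink_rate_max``.
    """
    if not ad_lib_open or drive <= 0.0:
        return 0.0
    satiation = 1.0 / (1.0 + (max(gut_fill, 0.0) / params.gut_half) ** params.satiation_n)
    return params.drink_rate_max * drive / (drive + params.k_drive) * satiation
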