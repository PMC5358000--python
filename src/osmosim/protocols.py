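"""The six published dehydration/rehydration protocols as event schedules.

All protocols act on a 74-kg virtual subject.  Doses scale with body mass:

* A  — 20 mL/kg oral water over 20 min from the basal state.
* B  — 36 h water deprivation, then 15 mL/kg oral water over 3.5 min
  (B1 variant: 1 mL/kg over 3 min).
* C  — 24 h deprivation with an 80 mmol NaCl "pill" (1 mL water) during the
  twelfth hour, then 10 mL/kg tap water over 2 min.
* D  — as C but 10 mL/kg of 180 mmol/L saline.
* E  — 10 h fast, 120 min IV infusion of 5% NaCl at 0.06 mL/kg/min, 15 min
  equilibration, then a 30 min ad-libitum drinking window.
* F  — as E with no water offered.

5% NaCl is mapped to 50 g/L / 58.44 g/mol = 855.6 mmol/L.  Sampling grids
follow the source studies (pre/post for A; +5, 10, 15, 30, 60 min after
the drink for B-D; every 30 min from infusion start for E/F).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from .core_state import Subject
from .errors import ScheduleError

PROTOCOL_IDS = ("A", "B", "B1", "C", "D", "E", "F")

EVENT_KINDS = ("oral_load", "iv_infusion", "ad_lib_open", "ad_lib_close",
               "deprivation", "sample")

#: E/F infusion rate, mL per kg body mass per minute (5% NaCl, 120 min).
INFUSION_RATE_ML_PER_KG_MIN = 0.06
#: Molar concentration of 5% (50 g/L) NaCl, mmol/L.
SALINE_5PCT_MMOL_L = 50.0 / 58.44 * 1000.0


@dataclass
class Event:
    """A timed intervention.  volume in mL, na_conc in mmol/L, times in min.

    ``deprivation`` events are documentation only (deprivation is the
    absence of intake); ``ad_lib_open``/``ad_lib_close`` toggle the
    thirst-driven drinking window.
    """

    t_start: float
    kind: str
    volume: float = 0.0
    na_conc: float = 0.0
    duration: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ScheduleError(f"unknown event kind {self.kind!r}; valid: {EVENT_KINDS}")
        if self.t_start < 0:
            raise ScheduleError(f"event starts before t=0: {self!r}")
        if self.kind in ("oral_load", "iv_infusion") and self.duration <= 0:
            raise ScheduleError(f"load/infusion needs duration > 0: {self!r}")


@dataclass
class Protocol:
    id: str
    subject: Subject
    events: list
    t_end: float
    sample_times: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.t_start, e.kind))
        for kind in ("oral_load", "iv_infusion"):
            active = [e for e in self.events if e.kind == kind]
            for a, b in zip(active, active[1:]):
                if b.t_start < a.t_start + a.duration - 1e-9:
                    raise ScheduleError(
                        f"overlapping {kind} events at t={a.t_start} and t={b.t_start}")
        opens = [e.t_start for e in self.events if e.kind == "ad_lib_open"]
        closes = [e.t_start for e in self.events if e.kind == "ad_lib_close"]
        if len(opens) != len(closes) or any(c <= o for o, c in zip(opens, closes)):
            if opens or closes:
                raise ScheduleError("ad_lib_open/ad_lib_close events must come in ordered pairs")
        for t in self.sample_times:
            if not 0.0 <= t <= self.t_end:
                raise ScheduleError(f"sample time {t} outside [0, {self.t_end}]")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "subject": asdict(self.subject),
            "events": [asdict(e) for e in self.events],
            "t_end": self.t_end,
            "sample_times": list(self.sample_times),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            id=d["id"],
            subject=Subject(**d["subject"]),
            events=[Event(**e) for e in d["events"]],
            t_end=d["t_end"],
            sample_times=list(d.get("sample_times", [])),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "Protocol":
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, s: str) -> "Protocol":
        import yaml

        return cls.from_dict(yaml.safe_load(s))


def default_subject() -> Subject:
    """The packaged virtual subject: 74 kg, normal body-water fractions."""
    return Subject(body_mass=74.0)


def build_protocol(protocol_id: str, subject: Subject | None = None) -> Protocol:
    """Construct one of the packaged protocols (A, B, B1, C, D, E, F)."""
    if protocol_id not in PROTOCOL_IDS:
        raise ScheduleError(
            f"unknown protocol id {protocol_id!r}; valid ids: {', '.join(PROTOCOL_IDS)}")
    subject = subject or default_subject()
    m = subject.body_mass

    if protocol_id == "A":
        events = [Event(0.0, "oral_load", volume=20.0 * m, na_conc=0.0,
                        duration=20.0, label="water load 20 mL/kg")]
        return Protocol("A", subject, events, t_end=180.0, sample_times=[0.0, 80.0])

    if protocol_id in ("B", "B1"):
        t_dep = 2160.0  # 36 h
        if protocol_id == "B":
            vol, dur = 15.0 * m, 3.5
        else:
            vol, dur = 1.0 * m, 3.0
        events = [
            Event(0.0, "deprivation", duration=t_dep, label="36 h water deprivation"),
            Event(t_dep, "oral_load", volume=vol, na_conc=0.0, duration=dur,
                  label="rehydration drink"),
        ]
        samples = [0.0, t_dep] + [t_dep + dt for dt in (5.0, 10.0, 15.0, 30.0, 60.0)]
        return Protocol(protocol_id, subject, events, t_end=t_dep + 70.0,
                        sample_times=samples)

    if protocol_id in ("C", "D"):
        t_dep = 1440.0  # 24 h
        na_conc = 0.0 if protocol_id == "C" else 180.0
        label = "tap water 10 mL/kg" if protocol_id == "C" else "180 mmol/L saline 10 mL/kg"
        events = [
            Event(0.0, "deprivation", duration=t_dep, label="24 h water deprivation"),
            # 80 mmol NaCl in 1 mL water during the twelfth hour.
            Event(720.0, "oral_load", volume=1.0, na_conc=80.0 / 1e-3, duration=1.0,
                  label="NaCl pill (80 mmol)"),
            Event(t_dep, "oral_load", volume=10.0 * m, na_conc=na_conc, duration=2.0,
                  label=label),
        ]
        samples = [0.0, 720.0, t_dep] + [t_dep + dt for dt in (5.0, 10.0, 15.0, 30.0, 60.0)]
        return Protocol(protocol_id, subject, events, t_end=t_dep + 70.0,
                        sample_times=samples)

    # E / F
    t_fast = 600.0  # "overnight fast" = 10 h without intake
    t_inf = 120.0
    events = [
        Event(0.0, "deprivation", duration=t_fast, label="overnight fast (10 h)"),
        Event(t_fast, "iv_infusion",
              volume=INFUSION_RATE_ML_PER_KG_MIN * m * t_inf,
              na_conc=SALINE_5PCT_MMOL_L, duration=t_inf,
              label="5% NaCl at 0.06 mL/kg/min"),
    ]
    if protocol_id == "E":
        events += [
            Event(t_fast + t_inf + 15.0, "ad_lib_open", label="ad-libitum water"),
            Event(t_fast + t_inf + 45.0, "ad_lib_close"),
        ]
    t_end = 810.0
    samples = [0.0] + [t_fast + 30.0 * k for k in range(int((t_end - t_fast) / 30.0) + 1)]
    return Protocol(protocol_id, subject, events, t_end=t_end, sample_times=samples)
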