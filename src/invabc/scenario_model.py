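"""Declarative demographic invasion scenarios: populations, timed events
(splits, admixture, Ne changes), serial sample events, and parameter priors.

Time is measured internally in generations before present (present = 2015 by
default, 10 generations per year); calendar years appear only at the
configuration surface.  A scenario is the unit of ABC model choice: a fixed
topology of introductions whose parameters (event times, effective sizes,
founder-bottleneck sizes and durations, mutation rates) carry priors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

PRESENT_YEAR = 2015
GENERATIONS_PER_YEAR = 10


def years_to_generations(year: float, present: int = PRESENT_YEAR,
                         g_per_year: int = GENERATIONS_PER_YEAR) -> float:
    if year > present:
        raise ValueError(f"year {year} is after present ({present})")
    return (present - year) * g_per_year


def generations_to_year(gens: float, present: int = PRESENT_YEAR,
                        g_per_year: int = GENERATIONS_PER_YEAR) -> float:
    return present - gens / g_per_year


# -- priors -------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """A parameter prior: uniform, loguniform or truncated normal over
    (low, high); ``fixed`` pins the value at ``low``."""

    dist: str
    low: float
    high: float = float("nan")
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform", "normal_trunc", "fixed"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.dist != "fixed":
            if not (np.isfinite(self.low) and np.isfinite(self.high)):
                raise ValueError("prior bounds must be finite")
            if not self.low < self.high:
                raise ValueError(f"prior needs low < high, got [{self.low}, {self.high}]")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError("loguniform needs positive bounds")
        if self.dist == "normal_trunc" and (self.mean is None or self.sd is None):
            raise ValueError("normal_trunc needs mean and sd")

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist == "fixed":
            return self.low
        if self.dist == "uniform":
            return float(rng.uniform(self.low, self.high))
        if self.dist == "loguniform":
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        # truncated normal by rejection (bounds are always a few sd wide here)
        for _ in range(10000):
            x = rng.normal(self.mean, self.sd)
            if self.low <= x <= self.high:
                return float(x)
        raise RuntimeError("truncated-normal rejection failed; widen the bounds")


# -- events -------------------------------------------------------------------


@dataclass(frozen=True)
class SplitEvent:
    """Backward in time, lineages of ``derived`` move into ``parent`` at ``time``."""

    time: str | float
    derived: str
    parent: str
    kind: str = "split"


@dataclass(frozen=True)
class AdmixtureEvent:
    """Backward in time, each lineage of ``derived`` reroutes to ``alt_parent``
    with probability ``ra``, else to ``parent``."""

    time: str | float
    derived: str
    parent: str
    alt_parent: str
    ra: str | float = "ra"
    kind: str = "admixture"


@dataclass(frozen=True)
class NeChangeEvent:
    """For times older than ``time``, ``population`` has size ``ne``."""

    time: str | float
    population: str
    ne: str | float
    kind: str = "ne_change"


@dataclass(frozen=True)
class SampleEvent:
    population: str
    year: int
    n_diploid: int
    kind: str = "sample"

    def label(self) -> str:
        return f"{self.population}_{self.year}"


Event = SplitEvent | AdmixtureEvent | NeChangeEvent


# -- scenario -----------------------------------------------------------------


@dataclass
class Scenario:
    id: str
    populations: list[str]
    root: str
    events: list[Event]
    samples: list[SampleEvent]
    params: dict[str, PriorSpec]
    ne0: dict[str, str | float]  # present-epoch Ne per population (param name)
    conditions: list[str] = field(default_factory=list)  # e.g. "t5 > t4"
    present: int = PRESENT_YEAR
    g_per_year: int = GENERATIONS_PER_YEAR

    # -- parameter machinery --------------------------------------------------

    def _resolve(self, value: str | float, draws: dict[str, float]) -> float:
        if isinstance(value, str):
            if value in draws:
                return draws[value]
            # simple arithmetic over parameter names, e.g. "t5 - db1"
            return float(eval(value, {"__builtins__": {}}, dict(draws)))
        return float(value)

    def _conditions_ok(self, draws: dict[str, float]) -> bool:
        compiled = self.__dict__.get("_compiled_conditions")
        if compiled is None or len(compiled) != len(self.conditions):
            compiled = [compile(c, "<condition>", "eval") for c in self.conditions]
            self.__dict__["_compiled_conditions"] = compiled
        ns = dict(draws)
        return all(bool(eval(c, {"__builtins__": {}}, ns)) for c in compiled)

    def sample_priors(self, seed=None, max_reject: int = 100000) -> dict[str, float]:
        """One draw per parameter honouring distributions and order conditions
        (rejection resampling on violated conditions); deterministic under seed."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        for _ in range(max_reject):
            draws = {name: spec.sample(rng) for name, spec in self.params.items()}
            if self._conditions_ok(draws):
                return draws
        raise RuntimeError(f"scenario {self.id}: could not satisfy conditions {self.conditions}")

    def bound_events(self, draws: dict[str, float]) -> list[tuple]:
        """Events with numeric times, sorted ascending (backward in time)."""
        out = []
        for ev in self.events:
            t = self._resolve(ev.time, draws)
            if isinstance(ev, SplitEvent):
                out.append((t, "split", ev.derived, ev.parent))
            elif isinstance(ev, AdmixtureEvent):
                out.append((t, "admixture", ev.derived, ev.parent, ev.alt_parent,
                            self._resolve(ev.ra, draws)))
            elif isinstance(ev, NeChangeEvent):
                out.append((t, "ne_change", ev.population, self._resolve(ev.ne, draws)))
        return sorted(out, key=lambda e: e[0])

    def bound_samples(self) -> list[tuple[str, float, int, str]]:
        """(population, time in generations, n_diploid, label) per sample event."""
        return [
            (s.population, years_to_generations(s.year, self.present, self.g_per_year),
             s.n_diploid, s.label())
            for s in self.samples
        ]

    def initial_ne(self, draws: dict[str, float]) -> dict[str, float]:
        return {p: self._resolve(v, draws) for p, v in self.ne0.items()}

    # -- validation -----------------------------------------------------------

    def validate(self) -> list[str]:
        """Invariant check; returns a list of violations (empty when clean)."""
        issues: list[str] = []
        for s in self.samples:
            if s.year > self.present:
                issues.append(f"sample event for {s.population} at {s.year} is after present")
            if s.population not in self.populations:
                issues.append(f"sample event references unknown population {s.population}")
        import re

        refs: set[str] = set()
        strings = [v for v in self.ne0.values() if isinstance(v, str)]
        for ev in self.events:
            for attr in ("time", "ne", "ra"):
                v = getattr(ev, attr, None)
                if isinstance(v, str):
                    strings.append(v)
        for v in strings:
            refs.update(re.findall(r"[A-Za-z_]\w*", v))
        missing = refs - set(self.params)
        if missing:
            issues.append(f"unresolved parameter references: {sorted(missing)}")
        if set(self.ne0) != set(self.populations):
            issues.append("ne0 must cover every population exactly")
        # reachability: follow splits backward from each sampled population
        parent = {ev.derived: ev.parent for ev in self.events if isinstance(ev, SplitEvent)}
        for ev in self.events:
            if isinstance(ev, AdmixtureEvent):
                parent.setdefault(ev.derived, ev.parent)
        for s in self.samples:
            p, hops = s.population, 0
            while p != self.root and hops <= len(self.populations):
                if p not in parent:
                    issues.append(f"population {s.population} cannot reach root {self.root}")
                    break
                p, hops = parent[p], hops + 1
        # conditions must evaluate on a draw and not be contradictory
        try:
            self.sample_priors(seed=0, max_reject=5000)
        except Exception as exc:  # noqa: BLE001 - report, never raise
            issues.append(f"condition sampling failed: {exc}")
        return issues

    def timeline_text(self, draws: dict[str, float] | None = None) -> str:
        """Plain-text event timeline (at prior medians unless draws given)."""
        if draws is None:
            draws = self.sample_priors(seed=0)
        lines = [f"scenario {self.id} (generations before present)"]
        for s in sorted(self.bound_samples(), key=lambda x: x[1]):
            lines.append(f"  t={s[1]:>9.1f}  sample   {s[3]} (n={s[2]})")
        for ev in self.bound_events(draws):
            desc = " ".join(str(x) for x in ev[2:])
            lines.append(f"  t={ev[0]:>9.1f}  {ev[1]:<8} {desc}")
        return "\n".join(lines)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "id": self.id,
            "populations": self.populations,
            "root": self.root,
            "events": [asdict(ev) for ev in self.events],
            "samples": [asdict(s) for s in self.samples],
            "params": {k: asdict(v) for k, v in self.params.items()},
            "ne0": self.ne0,
            "conditions": self.conditions,
            "present": self.present,
            "g_per_year": self.g_per_year,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Scenario":
        kinds = {"split": SplitEvent, "admixture": AdmixtureEvent, "ne_change": NeChangeEvent}
        events = []
        for ev in d["events"]:
            ev = dict(ev)
            kind = ev.pop("kind")
            events.append(kinds[kind](**ev))
        samples = [SampleEvent(**{k: v for k, v in s.items() if k != "kind"}) for s in d["samples"]]
        params = {}
        for k, v in d["params"].items():
            v = dict(v)
            params[k] = PriorSpec(**v)
        return cls(
            id=d["id"], populations=list(d["populations"]), root=d["root"],
            events=events, samples=samples, params=params, ne0=dict(d["ne0"]),
            conditions=list(d.get("conditions", [])),
            present=d.get("present", PRESENT_YEAR),
            g_per_year=d.get("g_per_year", GENERATIONS_PER_YEAR),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def validate_scenario(s: Scenario) -> dict[str, Any]:
    """Violations list plus the rendered event timeline (never raises)."""
    issues = s.validate()
    report: dict[str, Any] = {"id": s.id, "violations": issues, "clean": not issues}
    try:
        report["timeline"] = s.timeline_text()
    except Exception as exc:  # noqa: BLE001
        report["timeline"] = f"<timeline unavailable: {exc}>"
    return report


# -- the six-population invasion scenarios ------------------------------------

POPULATIONS = ["ANC", "SEA", "IND", "PAP", "PNG", "SOL", "TSF"]

#: sources of each introduced population per scenario id; every scenario keeps
#: TSF (Torres Strait / southern Fly) seeded from Indonesia.
SCENARIO_SOURCES: dict[str, dict[str, str]] = {
    "1": {"PAP": "SEA", "PNG": "SEA", "SOL": "SEA", "TSF": "IND"},
    "2": {"PAP": "SEA", "PNG": "IND", "SOL": "PNG", "TSF": "IND"},
    "3": {"PAP": "IND", "PNG": "SEA", "SOL": "PNG", "TSF": "IND"},
    "4": {"PAP": "SEA", "PNG": "SEA", "SOL": "PNG", "TSF": "IND"},
    "5": {"PAP": "SEA", "PNG": "PAP", "SOL": "PNG", "TSF": "IND"},
}

_INTRO_TIME = {"PAP": "t5", "PNG": "t4", "SOL": "t3", "TSF": "t2"}
_FOUNDER_DURATION = {"PAP": "db1", "PNG": "db2", "SOL": "db3", "TSF": "db4"}


def default_priors() -> dict[str, PriorSpec]:
    """Shipped prior defaults: wide uniform Ne, loguniform mutation-era ANC
    split, truncated normals around first-detection years (all overridable)."""
    p: dict[str, PriorSpec] = {}
    for pop in ("ANC", "SEA", "IND", "PAP", "PNG", "SOL", "TSF"):
        p[f"N_{pop}"] = PriorSpec("uniform", 10, 1_000_000)
    for pop in ("PAP", "PNG", "SOL", "TSF"):
        p[f"NF_{pop}"] = PriorSpec("uniform", 10, 10_000)
    p["N_TSF_EARLY"] = PriorSpec("uniform", 10, 1_000_000)
    p["t7"] = PriorSpec("loguniform", 17_900, 276_000)
    p["t5"] = PriorSpec("normal_trunc", 480, 960, mean=530, sd=100)   # Papua, detected 1962
    p["t4"] = PriorSpec("normal_trunc", 250, 700, mean=430, sd=60)    # PNG, detected 1972
    p["t3"] = PriorSpec("normal_trunc", 280, 560, mean=360, sd=40)    # Solomons, detected 1979
    p["t2"] = PriorSpec("normal_trunc", 85, 160, mean=100, sd=15)     # TS/Fly, detected 2005
    p["t1"] = PriorSpec("uniform", 5, 75)                             # TSF Ne shift between samples
    for name in ("db1", "db2", "db3", "db4"):
        p[name] = PriorSpec("uniform", 0, 200)
    p["mu_di"] = PriorSpec("loguniform", 1e-6, 1e-3)
    p["mu_tri"] = PriorSpec("loguniform", 1e-6, 1e-3)
    p["mu_seq"] = PriorSpec("uniform", 7e-10, 1e-7)
    p["kappa"] = PriorSpec("uniform", 2, 20)
    return p


DEFAULT_CONDITIONS = [
    "t7 > t5", "t5 > t4", "t4 > t3", "t3 > t2", "t2 > t1",
    "db1 < t5", "db2 < t4 - 230", "db3 < t3", "db4 < t2 - 80",
]

DEFAULT_SAMPLES = [
    SampleEvent("SEA", 2015, 30),
    SampleEvent("IND", 2015, 30),
    SampleEvent("PAP", 2015, 20),
    SampleEvent("PNG", 1992, 30),
    SampleEvent("PNG", 2011, 30),
    SampleEvent("SOL", 2015, 30),
    SampleEvent("TSF", 2007, 30),
    SampleEvent("TSF", 2015, 30),
]


def _study_scenario(sid: str, sources: dict[str, str], priors: dict[str, PriorSpec],
                    samples: list[SampleEvent], admixture: bool = False) -> Scenario:
    events: list[Event] = [
        SplitEvent("t7", "SEA", "ANC"),
        SplitEvent("t7", "IND", "ANC"),
    ]
    for pop, parent in sources.items():
        t = _INTRO_TIME[pop]
        if admixture and pop == "SOL":
            events.append(AdmixtureEvent(t, "SOL", parent, "PNG", "ra"))
        else:
            events.append(SplitEvent(t, pop, parent))
        # founder epoch: reduced Ne for db generations immediately after the
        # introduction (backward: from t - db to t)
        events.append(NeChangeEvent(f"{t} - {_FOUNDER_DURATION[pop]}", pop, f"NF_{pop}"))
    # TS/Fly population-size shift between the temporal samples
    events.append(NeChangeEvent("t1", "TSF", "N_TSF_EARLY"))
    return Scenario(
        id=sid,
        populations=list(POPULATIONS),
        root="ANC",
        events=events,
        samples=list(samples),
        params=dict(priors),
        ne0={p: f"N_{p}" for p in POPULATIONS},
        conditions=list(DEFAULT_CONDITIONS),
    )


def build_study_scenarios(
    priors: dict[str, PriorSpec] | None = None,
    samples: list[SampleEvent] | None = None,
    include_admixture: bool = False,
) -> list[Scenario]:
    """The five shipped invasion scenarios over {ANC, SEA, IND, PAP, PNG, SOL,
    TSF}; scenario 4 and 1 differ only in the Solomons' source (PNG vs SEA).

    ``include_admixture`` appends an optional sixth scenario where the
    Solomons originate as a SEA x PNG admixture with proportion ``ra``.
    """
    priors = dict(default_priors() if priors is None else priors)
    samples = DEFAULT_SAMPLES if samples is None else samples
    out = [_study_scenario(sid, srcs, priors, samples) for sid, srcs in SCENARIO_SOURCES.items()]
    if include_admixture:
        pr = dict(priors)
        pr["ra"] = PriorSpec("uniform", 0.05, 0.95)
        out.append(_study_scenario("6", SCENARIO_SOURCES["1"], pr, samples, admixture=True))
    return out
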