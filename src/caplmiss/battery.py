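"""Battery specification: components, maxima, domain structure.

The CAPL battery aggregates 25 component scores into four domains
(Physical Competence, Daily Behaviour, Knowledge & Understanding,
Motivation & Confidence) and an overall physical-literacy score out of
100.  A domain score is the sum of its component points divided by a
domain divisor; Physical Competence sums to a raw maximum of 160 and is
divided by 5, the other three use divisor 1.  Domain maxima are
32/32/18/18 and sum to 100.

The battery is shipped as an editable JSON file so that alternative
batteries (different components, maxima or divisors) can be scored with
the same engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class DomainSpec:
    """One scoring domain: ordered components with maxima and a divisor."""

    name: str
    label: str
    components: dict[str, float]  # component name -> maximum points
    divisor: float

    @property
    def raw_max(self) -> float:
        """Sum of component maxima before the divisor is applied."""
        return float(sum(self.components.values()))

    @property
    def domain_max(self) -> float:
        """Maximum attainable domain score (raw_max / divisor)."""
        return self.raw_max / self.divisor


@dataclass(frozen=True)
class BatterySpec:
    """A full battery: ordered domains plus derived component lists."""

    name: str
    domains: dict[str, DomainSpec] = field(default_factory=dict)

    @property
    def component_names(self) -> list[str]:
        return [c for d in self.domains.values() for c in d.components]

    @property
    def component_max(self) -> dict[str, float]:
        return {c: m for d in self.domains.values() for c, m in d.components.items()}

    @property
    def overall_max(self) -> float:
        return float(sum(d.domain_max for d in self.domains.values()))

    def domain_of(self, component: str) -> str:
        for name, dom in self.domains.items():
            if component in dom.components:
                return name
        raise KeyError(f"unknown component {component!r}")

    def validate(self) -> None:
        """Check structural invariants of the battery definition."""
        if not self.domains:
            raise ValueError("battery has no domains")
        for dom in self.domains.values():
            if dom.divisor <= 0:
                raise ValueError(f"domain {dom.name!r}: divisor must be > 0")
            for comp, mx in dom.components.items():
                if mx <= 0:
                    raise ValueError(f"component {comp!r}: maximum must be > 0")
        names = self.component_names
        if len(names) != len(set(names)):
            raise ValueError("duplicate component names across domains")


def _from_dict(payload: dict) -> BatterySpec:
    domains = {}
    for name, d in payload["domains"].items():
        domains[name] = DomainSpec(
            name=name,
            label=d.get("label", name),
            components={k: float(v) for k, v in d["components"].items()},
            divisor=float(d.get("divisor", 1)),
        )
    spec = BatterySpec(name=payload.get("name", "battery"), domains=domains)
    spec.validate()
    return spec


def load_battery(path: str | Path | None = None) -> BatterySpec:
    """Load a battery spec from JSON; default is the shipped CAPL battery."""
    if path is None:
        text = resources.files("caplmiss.data").joinpath("battery.json").read_text()
    else:
        text = Path(path).read_text()
    return _from_dict(json.loads(text))


DEFAULT_BATTERY = load_battery()
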