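"""Run manifest: exact accounting of every record kept or dropped.

Every pipeline stage that discards input (water contacts, non-standard
residues, unmappable positions, clash-only records, ...) charges the drop to
a named reason in a manifest section.  Each section reconciles exactly:

    total == used + sum(drops by reason)

so no record can silently disappear.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class Section:
    name: str
    total: int = 0
    used: Counter = field(default_factory=Counter)
    drops: Counter = field(default_factory=Counter)

    def add_total(self, n: int = 1) -> None:
        self.total += n

    def use(self, reason: str = "used", n: int = 1) -> None:
        self.used[reason] += n

    def drop(self, reason: str, n: int = 1) -> None:
        self.drops[reason] += n

    @property
    def n_used(self) -> int:
        return sum(self.used.values())

    @property
    def n_dropped(self) -> int:
        return sum(self.drops.values())

    def reconciles(self) -> bool:
        return self.total == self.n_used + self.n_dropped

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "used": dict(sorted(self.used.items())),
            "dropped": dict(sorted(self.drops.items())),
            "reconciles": self.reconciles(),
        }


@dataclass
class Manifest:
    """Per-run accounting ledger, grouped into named sections."""

    sections: dict[str, Section] = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    def section(self, name: str) -> Section:
        if name not in self.sections:
            self.sections[name] = Section(name)
        return self.sections[name]

    def reconciles(self) -> bool:
        return all(s.reconciles() for s in self.sections.values())

    def as_dict(self) -> dict:
        return {
            "info": self.info,
            "sections": {
                k: s.as_dict() for k, s in sorted(self.sections.items())
            },
            "reconciles": self.reconciles(),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.as_dict(), indent=2, sort_keys=True) + "\n"
        )
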