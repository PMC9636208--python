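"""Ordinal fibrosis staging systems and the per-animal aggregation rule.

Three reader-assigned scoring systems are encoded as ordered numeric scales:

* ``ishak`` — 0 (no fibrosis) to 6 (probable/definite cirrhosis);
* ``ishak_modified`` — same 0-6 ladder re-anchored on centrilobular
  (pericentral) areas, appropriate for CCl4-type injury;
* ``nash_crn`` — 0, 1A, 1B, 1C, 2, 3, 4 (Kleiner steatohepatitis staging).

Scores are supplied per section; the per-animal statistic is the *highest*
section value.  The NASH CRN substages 1A/1B/1C are all substages of stage 1,
so by default they encode to numeric 1 (the letter survives as the label);
an alternative "thirds" coding (1, 4/3, 5/3) is available for sensitivity
analyses since published analyses rarely state which coding they used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

SYSTEM_NAMES = ("ishak", "ishak_modified", "nash_crn")


@dataclass(frozen=True)
class ScoreSystem:
    """An ordered staging scale: labels with matching numeric encodings."""

    name: str
    labels: Tuple[str, ...]
    numeric_values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.numeric_values):
            raise ValueError("labels and numeric_values must match in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if any(b < a for a, b in zip(self.numeric_values, self.numeric_values[1:])):
            raise ValueError("numeric_values must be non-decreasing")

    def encode(self, label: str) -> float:
        label = str(label).strip()
        try:
            return self.numeric_values[self.labels.index(label)]
        except ValueError:
            raise KeyError(
                f"unknown {self.name} stage {label!r}; valid labels: {list(self.labels)}"
            ) from None


_ISHAK_LABELS = ("0", "1", "2", "3", "4", "5", "6")
_ISHAK_VALUES = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
_NASH_LABELS = ("0", "1A", "1B", "1C", "2", "3", "4")

_SYSTEMS: Dict[str, ScoreSystem] = {
    "ishak": ScoreSystem("ishak", _ISHAK_LABELS, _ISHAK_VALUES),
    "ishak_modified": ScoreSystem("ishak_modified", _ISHAK_LABELS, _ISHAK_VALUES),
    "nash_crn": ScoreSystem("nash_crn", _NASH_LABELS, (0.0, 1.0, 1.0, 1.0, 2.0, 3.0, 4.0)),
}

# Alternative NASH CRN substage coding: 1A/1B/1C spread over thirds of a stage.
_SYSTEMS_THIRDS: Dict[str, ScoreSystem] = dict(_SYSTEMS)
_SYSTEMS_THIRDS["nash_crn"] = ScoreSystem(
    "nash_crn", _NASH_LABELS, (0.0, 1.0, 4.0 / 3.0, 5.0 / 3.0, 2.0, 3.0, 4.0)
)


def get_system(name: str, substage_coding: str = "collapse") -> ScoreSystem:
    """Look up a scoring system by name.

    ``substage_coding`` selects the NASH CRN 1A/1B/1C numeric coding:
    ``"collapse"`` (all -> 1, default) or ``"thirds"`` (1, 4/3, 5/3).
    """
    table = {"collapse": _SYSTEMS, "thirds": _SYSTEMS_THIRDS}.get(substage_coding)
    if table is None:
        raise ValueError(f"unknown substage_coding {substage_coding!r}")
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"unknown scoring system {name!r}; valid: {list(_SYSTEMS)}") from None


def encode_score(system: str | ScoreSystem, label: str, substage_coding: str = "collapse") -> float:
    """Numeric value of one stage label under the given system."""
    if isinstance(system, str):
        system = get_system(system, substage_coding)
    return system.encode(label)


def aggregate_scores(section_labels: Sequence[str], system: str | ScoreSystem,
                     substage_coding: str = "collapse") -> float:
    """Per-animal score: the highest encoded value across the sections."""
    if isinstance(system, str):
        system = get_system(system, substage_coding)
    labels = list(section_labels)
    if not labels:
        raise ValueError("need at least one section label to aggregate")
    return max(system.encode(lab) for lab in labels)
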