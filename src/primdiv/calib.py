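"""Rule-based fossil calibration bounds and chronogram auditing.

Minimum node ages come from the oldest unequivocal crown fossil of a
clade.  Maximum ages are the largest of three contributions:

* **stratigraphic bounding** — walk rootward from the chronologic unit
  containing the clade's oldest fossil until two successive units free
  of clade fossils have been passed; the bound is the old boundary of
  the second barren unit;
* **phylogenetic bracketing** — the oldest stem fossil attached within
  two nodes rootward of the divergence;
* **phylogenetic uncertainty** — a user-supplied age (no formula exists
  for it; it only participates through the max).

A fitted chronogram is audited against the bounds: estimates younger
than a minimum or older than a maximum are violations, with magnitude
measured against the bound itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChronoUnit",
    "ChronoUnitTable",
    "PALEOGENE_NEOGENE_UNITS",
    "CalibrationBound",
    "Violation",
    "ViolationReport",
    "stratigraphic_max",
    "bracketing_max",
    "combine_bounds",
    "audit_violations",
]


@dataclass(frozen=True)
class ChronoUnit:
    name: str
    young: float  # Ma
    old: float  # Ma

    def contains(self, age: float) -> bool:
        return self.young <= age <= self.old


class ChronoUnitTable:
    """Contiguous chronologic units, youngest first."""

    def __init__(self, units):
        self.units = tuple(units)
        ages = [u.young for u in self.units] + [self.units[-1].old]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("units must be contiguous and strictly increasing")
        for a, b in zip(self.units, self.units[1:]):
            if abs(a.old - b.young) > 1e-9:
                raise ValueError(f"gap between {a.name!r} and {b.name!r}")

    def unit_index(self, age: float) -> int:
        for i, u in enumerate(self.units):
            if u.young <= age <= u.old:
                return i
        raise ValueError(f"age {age} Ma outside the unit table")

    def __len__(self):
        return len(self.units)

    def __getitem__(self, i):
        return self.units[i]


# Cenozoic units used for primate calibrations; stage boundary ages follow
# the Gradstein & Ogg geologic time scale.  Editable: pass your own table.
PALEOGENE_NEOGENE_UNITS = ChronoUnitTable(
    [
        ChronoUnit("Pleistocene", 0.0, 1.81),
        ChronoUnit("Pliocene", 1.81, 5.33),
        ChronoUnit("late Miocene", 5.33, 11.61),  # Tortonian + Messinian
        ChronoUnit("middle Miocene", 11.61, 15.97),  # Langhian + Serravallian
        ChronoUnit("early Miocene", 15.97, 23.03),  # Aquitanian + Burdigalian
        ChronoUnit("late Oligocene", 23.03, 28.4),  # Chattian
        ChronoUnit("early Oligocene", 28.4, 33.9),  # Rupelian
        ChronoUnit("late Eocene", 33.9, 37.2),  # Priabonian
        ChronoUnit("late middle Eocene", 37.2, 40.4),  # Bartonian
        ChronoUnit("early middle Eocene", 40.4, 48.6),  # Lutetian
        ChronoUnit("early Eocene", 48.6, 55.8),  # Ypresian
        ChronoUnit("late Paleocene", 55.8, 58.7),  # Thanetian
        ChronoUnit("middle Paleocene", 58.7, 61.7),  # Selandian
        ChronoUnit("early Paleocene", 61.7, 65.5),  # Danian
    ]
)


def stratigraphic_max(occurrence_ages, units: ChronoUnitTable = PALEOGENE_NEOGENE_UNITS):
    """Maximum-age bound from two successive barren units.

    Starting from the unit containing the oldest occurrence, walk toward
    older units; the bound is the old boundary of the second consecutive
    unit containing no occurrences.  If fewer than two barren units
    remain, the old boundary of the oldest unit is returned with
    ``truncated=True``.

    Returns ``(age_ma, truncated)``.
    """
    ages = list(occurrence_ages)
    if not ages:
        raise ValueError("need at least one occurrence")
    occupied = {units.unit_index(a) for a in ages}
    start = max(occupied)
    barren = 0
    for i in range(start + 1, len(units)):
        if i in occupied:
            barren = 0
            continue
        barren += 1
        if barren == 2:
            return units[i].old, False
    return units[len(units) - 1].old, True


def bracketing_max(tree, node, stem_fossils: dict):
    """Oldest stem fossil within two nodes rootward of ``node``.

    ``stem_fossils`` maps a node to the fossil ages assigned to the
    branch subtending it.  The bracket covers the branches subtending
    the node itself (one node below the divergence) and its parent (two
    nodes below).  Returns None when the bracket holds no fossils.
    """
    ages = list(stem_fossils.get(node, ()))
    parent = node.parent_node
    if parent is not None:
        ages += list(stem_fossils.get(parent, ()))
    return max(ages) if ages else None


@dataclass(frozen=True)
class CalibrationBound:
    clade: str
    min_ma: float
    max_ma: float
    provenance: dict = field(default_factory=dict, hash=False)

    def __post_init__(self):
        if not self.max_ma > self.min_ma > 0:
            raise ValueError(
                f"clade {self.clade!r}: need max ({self.max_ma}) > "
                f"min ({self.min_ma}) > 0"
            )


def combine_bounds(clade: str, min_fossil: float, maxima, labels=None) -> CalibrationBound:
    """Minimum from the oldest crown fossil; maximum of the contributing maxima."""
    maxima = [m for m in maxima if m is not None]
    if min_fossil <= 0:
        raise ValueError("minimum age must be positive")
    if not maxima:
        raise ValueError(f"clade {clade!r}: no maximum-age contribution present")
    max_ma = max(maxima)
    if max_ma <= min_fossil:
        raise ValueError(
            f"clade {clade!r}: inconsistent bounds, max {max_ma} <= min {min_fossil}"
        )
    prov = {"oldest_crown_fossil": min_fossil}
    if labels is not None:
        prov.update(dict(zip(labels, maxima)))
    else:
        prov["maxima"] = tuple(maxima)
    return CalibrationBound(clade=clade, min_ma=min_fossil, max_ma=max_ma,
                            provenance=prov)


@dataclass(frozen=True)
class Violation:
    clade: str
    bound_type: str  # "min" or "max"
    bound_ma: float
    estimate_ma: float

    @property
    def magnitude(self) -> float:
        if self.bound_type == "min":
            return self.bound_ma - self.estimate_ma
        return self.estimate_ma - self.bound_ma


@dataclass
class ViolationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def mean_magnitude(self):
        """Mean violation in Ma; None when there are no violations."""
        if not self.violations:
            return None
        return float(np.mean([v.magnitude for v in self.violations]))

    def __len__(self):
        return len(self.violations)


def audit_violations(node_ages: dict, bounds) -> ViolationReport:
    """Check estimated node ages against calibration bounds.

    ``node_ages`` maps clade name -> estimated age (Ma); ``bounds`` is an
    iterable of :class:`CalibrationBound`.  An estimate exactly on a
    bound is not a violation.
    """
    report = ViolationReport()
    for b in bounds:
        if b.clade not in node_ages:
            raise KeyError(f"no estimated age for calibrated clade {b.clade!r}")
        age = node_ages[b.clade]
        if age < b.min_ma:
            report.violations.append(Violation(b.clade, "min", b.min_ma, age))
        elif age > b.max_ma:
            report.violations.append(Violation(b.clade, "max", b.max_ma, age))
    return report
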