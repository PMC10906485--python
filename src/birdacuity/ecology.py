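"""Deterministic data-preparation rules for the acuity database.

Unit conversion of literature acuity values to cycles per degree (cpd),
per-species record selection (anatomical RGC-density estimates preferred
over behavioral ones, most recent study preferred within a method), and
five rule-based ecological classifiers:

* habitat spatial complexity — foraging-stratum percentages summed into
  complex / open / horizon-dominated classes; a species is assigned to a
  class only if it spends strictly more than 70% of its time there,
  otherwise it is a habitat generalist;
* habitat light level — fixed keyword tables (low / medium / high), with
  nocturnality overriding to low;
* dominant diet — the aggregated category reaching at least 50%, else
  omnivore;
* prey mobility — mobile (live vertebrates + invertebrates) versus
  immobile (plant matter + scavenged prey);
* foraging mode — far (resolving prey from a distance: aerial chase,
  pursuit diving, scavenging, sallying) versus near (close-up
  maneuvers), decided by the species' primary (first-listed) maneuver.

All classifiers are pure functions; species whose inputs match no rule
fail loudly rather than being silently defaulted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SpeciesRecord",
    "EcologyProfile",
    "ClassificationError",
    "to_cpd",
    "select_record",
    "aggregate_diet",
    "classify_habitat",
    "classify_light",
    "classify_diet",
    "classify_prey_mobility",
    "classify_foraging",
    "build_profile",
    "HABITAT_STRATA",
    "LIGHT_KEYWORDS",
    "DISTANCE_MANEUVERS",
    "CLOSE_MANEUVERS",
    "DIET_AGGREGATION",
]


class ClassificationError(ValueError):
    """A species could not be classified under the stated rules."""


# ---------------------------------------------------------------------------
# constants: strata groupings, keyword tables, maneuver lists, diet mapping
# ---------------------------------------------------------------------------

# foraging-stratum percentages -> broad habitat classes
HABITAT_STRATA: dict[str, tuple[str, ...]] = {
    "complex": ("understory", "mid_high"),
    "open": ("aerial", "open_water"),
    "horizon": ("ground", "water_surface", "canopy"),
}

LIGHT_KEYWORDS: dict[str, frozenset[str]] = {
    "low": frozenset(
        {"forest understory", "mangrove", "dense shrubland", "heathland", "dense habitat"}
    ),
    "high": frozenset(
        {
            "desert",
            "grassland",
            "savannah",
            "farmland",
            "steppe",
            "meadow",
            "pelagic ocean",
            "open antarctic island",
            "flat beach",
            "dune",
            "mudflat",
        }
    ),
    "medium": frozenset({"forest edge", "secondary forest", "scrub forest", "semi-open"}),
}

DISTANCE_MANEUVERS = frozenset({"aerial chase", "pursuit diving", "scavenging", "sallying"})
CLOSE_MANEUVERS = frozenset(
    {"gleaning", "pecking", "dabbling", "kicking/scratching", "probing"}
)

# Mapping of raw diet-score categories (EltonTraits-style names, plus the
# simplified aliases used by this package's CSV schema) into the three
# analysis categories.  Editable: pass a modified copy to aggregate_diet.
DIET_AGGREGATION: dict[str, str] = {
    # plants: plant matter of all kinds
    "fruit": "plants",
    "nect": "plants",
    "seed": "plants",
    "planto": "plants",
    "plants": "plants",
    # invertebrates
    "inv": "invertebrates",
    "invertebrates": "invertebrates",
    # vertebrates including scavenged prey
    "vend": "vertebrates_scavenged",
    "vect": "vertebrates_scavenged",
    "vfish": "vertebrates_scavenged",
    "vunk": "vertebrates_scavenged",
    "scav": "vertebrates_scavenged",
    "vertebrates": "vertebrates_scavenged",
    "scavenged": "vertebrates_scavenged",
}

# raw categories counted as scavenged (immobile) for the mobility rule
_SCAVENGED = frozenset({"scav", "scavenged"})
_PLANT_RAW = frozenset(k for k, v in DIET_AGGREGATION.items() if v == "plants")
_INVERT_RAW = frozenset(k for k, v in DIET_AGGREGATION.items() if v == "invertebrates")
_VERT_RAW = frozenset(
    k for k, v in DIET_AGGREGATION.items() if v == "vertebrates_scavenged"
) - _SCAVENGED


# ---------------------------------------------------------------------------
# records and profiles
# ---------------------------------------------------------------------------


@dataclass
class SpeciesRecord:
    """One species' measured traits (one literature record)."""

    species: str
    acuity_cpd: float
    method: str  # "behavioral" | "RGC"
    source_year: int
    eye_axial_length_mm: float | None = None
    body_mass_g: float | None = None
    habitat_pct: dict[str, float] = field(default_factory=dict)
    diet_raw: dict[str, float] = field(default_factory=dict)
    habitat_keywords: list[str] = field(default_factory=list)
    nocturnal: bool = False
    maneuvers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.acuity_cpd is not None and self.acuity_cpd <= 0:
            raise ValueError(f"{self.species}: acuity must be > 0")
        if self.method not in ("behavioral", "RGC"):
            raise ValueError(f"{self.species}: method must be 'behavioral' or 'RGC'")
        for name, val in (
            ("eye_axial_length_mm", self.eye_axial_length_mm),
            ("body_mass_g", self.body_mass_g),
        ):
            if val is not None and not math.isnan(val) and val <= 0:
                raise ValueError(f"{self.species}: {name} must be > 0")
        for k, v in self.habitat_pct.items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.species}: habitat percentage {k}={v} outside [0, 100]")


@dataclass
class EcologyProfile:
    """Derived categorical classifications for one species."""

    habitat_class: str  # complex | open | horizon | generalist
    light_class: str  # low | medium | high
    diet_class: str  # plants | invertebrates | vertebrates_scavenged | omnivore
    prey_mobility: str  # mobile | immobile
    foraging_mode: str  # far | near


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

_UNIT_CONVERSIONS = ("cpd", "mar_arcmin", "mar_deg", "cycles_per_radian")


def to_cpd(value: float, unit: str) -> float:
    """Convert an acuity value to cycles per degree.

    One grating cycle spans two minimum angles of resolution (MAR), and a
    degree holds 60 arcmin, so MAR in arcmin converts as 30/value and MAR
    in degrees as 0.5/value.  Cycles per radian scale by pi/180.
    """
    if value <= 0:
        raise ValueError(f"acuity value must be > 0, got {value}")
    if unit == "cpd":
        return value
    if unit == "mar_arcmin":
        return 30.0 / value
    if unit == "mar_deg":
        return 0.5 / value
    if unit == "cycles_per_radian":
        return value * math.pi / 180.0
    raise ValueError(f"unknown acuity unit {unit!r}; expected one of {_UNIT_CONVERSIONS}")


def select_record(candidates: list[SpeciesRecord]) -> SpeciesRecord:
    """Pick the single record to analyze for one species.

    RGC-density estimates are preferred over behavioral ones; within the
    preferred method the most recent study wins; remaining ties are
    broken by the highest reported acuity.
    """
    if not candidates:
        raise ValueError("no records to select from")
    species = {r.species for r in candidates}
    if len(species) > 1:
        raise ValueError(f"records span multiple species: {sorted(species)}")
    rgc = [r for r in candidates if r.method == "RGC"]
    pool = rgc if rgc else list(candidates)
    return max(pool, key=lambda r: (r.source_year, r.acuity_cpd))


def classify_habitat(habitat_pct: dict[str, float], threshold: float = 70.0) -> str:
    """Habitat spatial-complexity class from foraging-stratum percentages.

    Strata are summed into complex (understory + mid-high vegetation),
    open (aerial + open water) and horizon-dominated (ground + water
    surface + canopy); the first class whose sum strictly exceeds the
    threshold wins (at most one can, for thresholds >= 50); otherwise the
    species is a habitat generalist.
    """
    for k, v in habitat_pct.items():
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"habitat percentage {k}={v} outside [0, 100]")
    total = sum(habitat_pct.values())
    if total > 100.0 + 1e-6:
        raise ValueError(f"habitat percentages sum to {total} > 100")
    for cls, strata in HABITAT_STRATA.items():
        if sum(habitat_pct.get(s, 0.0) for s in strata) > threshold:
            return cls
    return "generalist"


def classify_light(habitat_keywords: list[str], nocturnal: bool) -> str:
    """Light-level class from habitat keywords, nocturnality overriding.

    Primarily nocturnal species (and deep-foraging equivalents) are 'low'
    regardless of habitat.  Otherwise keywords are matched against the
    fixed low/medium/high tables and decided by majority vote, ties going
    to 'medium'.  Unmatched, non-nocturnal species raise.
    """
    if nocturnal:
        return "low"
    votes = {"low": 0, "medium": 0, "high": 0}
    for kw in habitat_keywords:
        token = kw.strip().lower()
        for cls, table in LIGHT_KEYWORDS.items():
            if token in table:
                votes[cls] += 1
    if sum(votes.values()) == 0:
        raise ClassificationError(
            f"no light-level keyword match for {habitat_keywords!r} (not nocturnal)"
        )
    best = max(votes.values())
    winners = [cls for cls, v in votes.items() if v == best]
    return winners[0] if len(winners) == 1 else "medium"


def aggregate_diet(
    diet_raw: dict[str, float], mapping: dict[str, str] | None = None
) -> dict[str, float]:
    """Sum raw diet-category scores into the three analysis categories."""
    mapping = DIET_AGGREGATION if mapping is None else mapping
    out = {"plants": 0.0, "invertebrates": 0.0, "vertebrates_scavenged": 0.0}
    for k, v in diet_raw.items():
        key = k.strip().lower()
        if key not in mapping:
            raise ValueError(f"unknown raw diet category {k!r}")
        if v < 0:
            raise ValueError(f"negative diet score {k}={v}")
        out[mapping[key]] += float(v)
    return out


def classify_diet(diet_pct: dict[str, float], threshold: float = 50.0) -> str:
    """Dominant-diet class: the category scoring >= threshold, else omnivore.

    Input is the three aggregated categories (raw scores may be passed
    through :func:`aggregate_diet` first).  An exact 50/50 split between
    two categories is an omnivore.
    """
    for k, v in diet_pct.items():
        if v < 0:
            raise ValueError(f"negative diet score {k}={v}")
    eligible = {k: v for k, v in diet_pct.items() if v >= threshold}
    if not eligible:
        return "omnivore"
    if len(eligible) > 1:
        return "omnivore"  # 50/50 tie
    return next(iter(eligible))


def classify_prey_mobility(diet_raw: dict[str, float]) -> str:
    """Mobile vs immobile primary prey from raw diet scores.

    Mobile prey: live vertebrates and invertebrates (scavenged prey
    excluded); immobile prey: plant matter of all kinds plus scavenged
    prey.  An exact tie cannot be resolved by the rule and raises for a
    manual call.
    """
    if not diet_raw or all(v == 0 for v in diet_raw.values()):
        raise ValueError("all-zero diet scores: prey mobility undefined")
    mobile = immobile = 0.0
    for k, v in diet_raw.items():
        key = k.strip().lower()
        if v < 0:
            raise ValueError(f"negative diet score {k}={v}")
        if key in _INVERT_RAW or key in _VERT_RAW:
            mobile += v
        elif key in _PLANT_RAW or key in _SCAVENGED:
            immobile += v
        else:
            raise ValueError(f"unknown raw diet category {k!r}")
    if mobile == immobile:
        raise ClassificationError(
            "mobile and immobile scores exactly tied: flag for manual classification"
        )
    return "mobile" if mobile > immobile else "immobile"


def classify_foraging(maneuvers: list[str]) -> str:
    """Far vs near foraging mode from the species' primary maneuver.

    The primary maneuver is the first listed.  Distance maneuvers
    (aerial chase, pursuit diving, scavenging, sallying) make a species
    far-sighted; the close-up maneuvers (gleaning, pecking, dabbling,
    kicking/scratching, probing) near-sighted.
    """
    if not maneuvers:
        raise ClassificationError("no foraging maneuvers listed")
    tokens = [m.strip().lower() for m in maneuvers]
    unknown = [t for t in tokens if t not in DISTANCE_MANEUVERS | CLOSE_MANEUVERS]
    if unknown:
        raise ClassificationError(f"unknown foraging maneuver(s): {unknown}")
    return "far" if tokens[0] in DISTANCE_MANEUVERS else "near"


def build_profile(
    record: SpeciesRecord,
    habitat_threshold: float = 70.0,
    diet_threshold: float = 50.0,
) -> EcologyProfile:
    """Run all five classifiers on one selected species record."""
    return EcologyProfile(
        habitat_class=classify_habitat(record.habitat_pct, threshold=habitat_threshold),
        light_class=classify_light(record.habitat_keywords, record.nocturnal),
        diet_class=classify_diet(aggregate_diet(record.diet_raw), threshold=diet_threshold),
        prey_mobility=classify_prey_mobility(record.diet_raw),
        foraging_mode=classify_foraging(record.maneuvers),
    )
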