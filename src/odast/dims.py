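"""Study dimensions: countries, age groups, sexes, years and the flow index.

The study system is a set of countries plus an optional "rest of the world"
aggregate.  Migration is a directed flow between two distinct units; the rest
of the world, when present, always occupies unit index 0 and exchanges flows
with every country.  Age is coded ``1..A`` (five-year groups, last open-ended);
sex is the fixed pair ``(F, M)`` with females first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

SEXES: tuple[str, str] = ("F", "M")
FEMALE, MALE = 0, 1

REPORTERS: tuple[str, str] = ("S", "R")
SENDING, RECEIVING = 0, 1


@dataclass(frozen=True)
class StudyDimensions:
    """Index sets of the study: units, ages, sexes and years.

    Parameters
    ----------
    countries
        Ordered country codes, excluding the rest-of-the-world aggregate.
    n_ages
        Number of age groups (coded ``1..n_ages`` externally, ``0..n_ages-1``
        internally).
    years
        Strictly increasing calendar years.
    rest_of_world
        Code of the rest-of-the-world unit (unit index 0).
    has_rest_of_world
        If true (the default), flows to and from the rest of the world are part
        of the system and are observed from one side only.
    """

    countries: tuple[str, ...]
    n_ages: int
    years: tuple[int, ...]
    rest_of_world: str = "RW"
    has_rest_of_world: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "countries", tuple(self.countries))
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        if self.n_ages < 2:
            raise ConfigError("need at least 2 age groups")
        if len(self.countries) < 2:
            raise ConfigError("need at least 2 countries besides rest-of-world")
        if len(set(self.countries)) != len(self.countries):
            raise ConfigError("duplicate country codes")
        if self.has_rest_of_world and self.rest_of_world in self.countries:
            raise ConfigError("rest-of-world code clashes with a country code")
        if not self.years:
            raise ConfigError("years must be non-empty")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ConfigError("years must be strictly increasing")

    # ---- units -----------------------------------------------------------
    @property
    def units(self) -> tuple[str, ...]:
        """All spatial units; rest of world (if any) at index 0."""
        if self.has_rest_of_world:
            return (self.rest_of_world,) + self.countries
        return self.countries

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_sexes(self) -> int:
        return len(SEXES)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def unit_index(self, code: str) -> int:
        try:
            return self.units.index(code)
        except ValueError:
            raise ConfigError(f"unknown country code {code!r}") from None

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise ConfigError(f"year {year} outside the study period") from None

    # ---- flows -----------------------------------------------------------
    @property
    def flows(self) -> tuple[tuple[int, int], ...]:
        """Ordered (origin, destination) unit-index pairs, origin != destination."""
        n = self.n_units
        return tuple((o, d) for o in range(n) for d in range(n) if o != d)

    @property
    def n_flows(self) -> int:
        return self.n_units * (self.n_units - 1)

    def flow_index(self, origin: str, destination: str) -> int:
        o, d = self.unit_index(origin), self.unit_index(destination)
        if o == d:
            raise ConfigError(f"origin equals destination ({origin})")
        # lexicographic enumeration with the diagonal removed
        return o * (self.n_units - 1) + (d if d < o else d - 1)

    def flow_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Origin and destination unit indices, each of shape ``(n_flows,)``."""
        pairs = np.array(self.flows, dtype=np.intp)
        return pairs[:, 0].copy(), pairs[:, 1].copy()

    def flow_labels(self) -> list[tuple[str, str]]:
        return [(self.units[o], self.units[d]) for o, d in self.flows]


def desk_scale_dimensions() -> StudyDimensions:
    """Default desk-scale system: 6 countries plus rest of world, 18 five-year
    age groups, 2 years."""
    return StudyDimensions(
        countries=("DE", "ES", "FR", "IT", "PL", "UK"),
        n_ages=18,
        years=(2007, 2008),
    )
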