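"""Factorial plate designs for salinity × pH × temperature growth assays.

A design enumerates, for each organism, one inoculated well per
(salinity, pH, temperature, replicate) combination, plus optionally one
set of uninoculated control wells per (salinity, pH, temperature)
treatment.  The canonical layout is 2 salinities × 5 pHs ×
4 temperatures × 8 replicates = 320 inoculated wells per organism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence


class DesignError(ValueError):
    """Raised for an invalid plate design specification."""


# Levels used in the motivating hydrothermal-vent isolate study.
DEFAULT_SALINITIES = (0.0, 30.0)          # per mille, sea-salt
DEFAULT_PHS = (1.0, 3.0, 5.0, 7.0, 9.0)
DEFAULT_TEMPERATURES = (15.0, 25.0, 37.0, 45.0)  # degrees C
DEFAULT_REPLICATES = 8
DEFAULT_DAYS = 30


@dataclass(frozen=True)
class Well:
    """Identity and treatment of a single well in the design."""

    well_id: str
    organism: str
    salinity: float
    ph: float
    temperature: float
    replicate: int
    role: str  # "inoculated" | "control"

    @property
    def treatment(self) -> tuple[float, float, float]:
        return (self.salinity, self.ph, self.temperature)


@dataclass(frozen=True)
class PlateDesign:
    """A fully crossed factorial design of microplate wells.

    Parameters
    ----------
    salinities, phs, temperatures
        Factor levels (per mille, pH units, degrees C).
    replicates
        Inoculated wells per treatment combination, >= 1.
    organisms
        Organism labels; each gets its own complete factorial.
    days
        Number of daily OD readings (day 0 included), >= 2.
    include_controls
        If true, one set of uninoculated control wells per treatment
        (replicated like the inoculated wells, shared across organisms).
    """

    salinities: tuple[float, ...]
    phs: tuple[float, ...]
    temperatures: tuple[float, ...]
    replicates: int
    organisms: tuple[str, ...]
    days: int = DEFAULT_DAYS
    include_controls: bool = True
    times: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        for name in ("salinities", "phs", "temperatures", "organisms"):
            if len(getattr(self, name)) == 0:
                raise DesignError(f"{name} must be non-empty")
        if self.replicates < 1:
            raise DesignError("replicates must be >= 1")
        if self.days < 2:
            raise DesignError("days must be >= 2")
        object.__setattr__(self, "times", tuple(range(self.days)))

    @property
    def treatments(self) -> list[tuple[float, float, float]]:
        return [
            (s, p, t)
            for s in self.salinities
            for p in self.phs
            for t in self.temperatures
        ]

    @property
    def wells_per_organism(self) -> int:
        """Inoculated wells per organism: product of level counts × replicates."""
        return (
            len(self.salinities)
            * len(self.phs)
            * len(self.temperatures)
            * self.replicates
        )

    def iter_wells(self) -> Iterator[Well]:
        """Enumerate inoculated wells, then control wells, in a stable order."""
        for org in self.organisms:
            for s, p, t in self.treatments:
                for r in range(1, self.replicates + 1):
                    yield Well(
                        well_id=f"{org}|s{s:g}|pH{p:g}|T{t:g}|r{r}",
                        organism=org,
                        salinity=s,
                        ph=p,
                        temperature=t,
                        replicate=r,
                        role="inoculated",
                    )
        if self.include_controls:
            for s, p, t in self.treatments:
                for r in range(1, self.replicates + 1):
                    yield Well(
                        well_id=f"CTRL|s{s:g}|pH{p:g}|T{t:g}|r{r}",
                        organism="none",
                        salinity=s,
                        ph=p,
                        temperature=t,
                        replicate=r,
                        role="control",
                    )


def generate_design(
    salinities: Sequence[float] = DEFAULT_SALINITIES,
    phs: Sequence[float] = DEFAULT_PHS,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    replicates: int = DEFAULT_REPLICATES,
    organisms: Sequence[str] = ("organism_1",),
    days: int = DEFAULT_DAYS,
    include_controls: bool = True,
) -> PlateDesign:
    """Build a validated factorial :class:`PlateDesign`.

    Raises :class:`DesignError` if any level list is empty or
    ``replicates < 1``.
    """
    return PlateDesign(
        salinities=tuple(float(s) for s in salinities),
        phs=tuple(float(p) for p in phs),
        temperatures=tuple(float(t) for t in temperatures),
        replicates=int(replicates),
        organisms=tuple(str(o) for o in organisms),
        days=int(days),
        include_controls=bool(include_controls),
    )
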