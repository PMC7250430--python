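"""Rule-based classification of environmental growth responses.

Each organism's presence/absence of growth over the tested
(salinity, pH, temperature) grid is summarized into a profile and
assigned to one of three response groups commonly distinguished for
extremotolerant fungi:

``temperature_tolerant``
    grows at 45 °C under any condition (this clause dominates);
``wide_range``
    grows at 37 °C in both salinities, at pH 3 under some condition,
    and in both salinities;
``salinity_dependent_temperature_sensitive``
    everything else — growth restricted to the milder temperatures,
    usually pH > 5, and typically better in seawater.

The rules operationalize descriptive growth-range groupings from
presence/absence alone; growth-rate magnitudes are not weighed.  Each
clause threshold is overridable through :class:`ClassifierRules`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd


class GroupLabel(str, Enum):
    WIDE_RANGE = "wide_range"
    SALINITY_DEPENDENT_TEMPERATURE_SENSITIVE = (
        "salinity_dependent_temperature_sensitive"
    )
    TEMPERATURE_TOLERANT = "temperature_tolerant"


@dataclass(frozen=True)
class ClassifierRules:
    """Tunable thresholds for the three clauses."""

    hot_temperature: float = 45.0    # clause (i): tolerant iff growth here
    warm_temperature: float = 37.0   # clause (ii): wide range needs growth here
    acidic_ph: float = 3.0           # clause (ii): ... and at this pH
    warm_in_both_salinities: bool = True  # clause (ii) scope of the 37 °C test


@dataclass(frozen=True)
class ResponseProfile:
    """Per-organism growth occurrence and mean rate over the tested grid."""

    organism: str
    growth: Mapping[tuple[float, float, float], bool]
    mean_rate: Mapping[tuple[float, float, float], float]

    def grows(self, salinity=None, ph=None, temperature=None) -> bool:
        """True if growth occurs in any cell matching the given levels."""
        for (s, p, t), flag in self.growth.items():
            if not flag:
                continue
            if salinity is not None and s != salinity:
                continue
            if ph is not None and p != ph:
                continue
            if temperature is not None and t != temperature:
                continue
            return True
        return False

    @property
    def salinities(self) -> set[float]:
        return {s for (s, _, _) in self.growth}


class ProfileError(ValueError):
    """Raised when a profile or rate table is incomplete."""


def summarize_profile(rates: pd.DataFrame, organism: str) -> ResponseProfile:
    """Condense a replicate-level rate table into one organism's profile.

    A condition counts as growth iff at least half of its replicates are
    flagged as growing (the boundary uses >=); the mean rate averages
    the growing replicates (0 if none).
    """
    sub = rates[rates["organism"] == organism]
    if sub.empty:
        raise ProfileError(f"organism {organism!r} not in rate table")
    growth: dict[tuple[float, float, float], bool] = {}
    mean_rate: dict[tuple[float, float, float], float] = {}
    for (s, p, t), grp in sub.groupby(["salinity", "pH", "temperature"]):
        key = (float(s), float(p), float(t))
        flags = grp["growth_flag"].to_numpy()
        growth[key] = bool(flags.sum() * 2 >= len(flags))
        growing = grp.loc[grp["growth_flag"], "rate"]
        mean_rate[key] = float(growing.mean()) if len(growing) else 0.0
    return ResponseProfile(organism=organism, growth=growth, mean_rate=mean_rate)


def classify(
    profile: ResponseProfile, rules: ClassifierRules = ClassifierRules()
) -> GroupLabel:
    """Assign a response group by clause precedence (i) > (ii) > (iii)."""
    temps = {t for (_, _, t) in profile.growth}
    if rules.hot_temperature in temps and profile.grows(
        temperature=rules.hot_temperature
    ):
        return GroupLabel.TEMPERATURE_TOLERANT

    salinities = profile.salinities
    if rules.warm_in_both_salinities:
        warm_ok = all(
            profile.grows(salinity=s, temperature=rules.warm_temperature)
            for s in salinities
        )
    else:
        warm_ok = profile.grows(temperature=rules.warm_temperature)
    acid_ok = profile.grows(ph=rules.acidic_ph)
    both_salinities = all(profile.grows(salinity=s) for s in salinities)
    if warm_ok and acid_ok and both_salinities:
        return GroupLabel.WIDE_RANGE
    return GroupLabel.SALINITY_DEPENDENT_TEMPERATURE_SENSITIVE


def group_counts(
    profiles: Iterable[ResponseProfile],
    rules: ClassifierRules = ClassifierRules(),
) -> dict[GroupLabel, int]:
    """Classify every profile and tally the groups (all labels reported)."""
    counts = Counter(classify(p, rules) for p in profiles)
    return {label: counts.get(label, 0) for label in GroupLabel}
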