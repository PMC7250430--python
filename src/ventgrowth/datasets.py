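"""Packaged reference datasets.

``load_vent_isolates`` returns the growth presence/absence profiles of
ten fungal isolates from sediments around a shallow-water hydrothermal
vent system, over the full 2-salinity × 5-pH × 4-temperature grid
(0/30 ‰; pH 1, 3, 5, 7, 9; 15/25/37/45 °C).  No isolate grows at pH 1;
a single isolate (*Aspergillus terreus* NTOU4989) grows at 45 °C.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import ResponseProfile


def load_vent_isolates_table() -> pd.DataFrame:
    """The raw fixture table: organism, salinity, pH, temperature, growth."""
    with resources.files("ventgrowth.data").joinpath("vent_isolates.csv").open() as fh:
        df = pd.read_csv(fh)
    df["growth"] = df["growth"].astype(bool)
    return df


def load_vent_isolates() -> list[ResponseProfile]:
    """The ten isolates' profiles as :class:`ResponseProfile` objects.

    Mean rates are unknown for this presence/absence dataset and are
    reported as 0.
    """
    df = load_vent_isolates_table()
    profiles = []
    for org, grp in df.groupby("organism", sort=False):
        growth = {
            (float(r.salinity), float(r.pH), float(r.temperature)): bool(r.growth)
            for r in grp.itertuples()
        }
        profiles.append(
            ResponseProfile(
                organism=str(org),
                growth=growth,
                mean_rate={k: 0.0 for k in growth},
            )
        )
    return profiles
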