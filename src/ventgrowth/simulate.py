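"""Synthetic plate simulation with known ground truth.

Simulated inoculated wells follow the Richards curve on a baseline:

    OD(day) = baseline + y_richards(day) + noise       (growth cells)
    OD(day) = baseline + noise                         (no-growth cells)

Control wells read baseline + noise.  Noise is additive Gaussian,
truncated at zero because absorbance is non-negative.  A single master
seed drives a deterministic per-well substream keyed by the well id, so
subsetting a design never changes another well's noise.

Defaults emulate the motivating study's conditions: daily readings for
30 days, a 2 × 5 × 4 × 8 factorial per organism, no growth at pH 1 for
any organism, and growth at 45 °C for exactly one organism.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .design import PlateDesign, Well
from .plate_io import WellSeries
from .richards import RichardsParams, evaluate_richards, normalized_growth_rate

# Free parameters of the simulator; the source study reports neither its
# plate-reader noise nor its blank level, so these are fixed here at
# values typical of a 630 nm microplate assay in 1% malt-extract medium.
DEFAULT_NOISE_SD = 0.01   # absorbance units
DEFAULT_BASELINE = 0.08   # uninoculated-well OD630

NO_GROWTH = None  # marker value in the truth mapping


class CoverageError(KeyError):
    """Raised when the ground truth does not cover every design cell."""


@dataclass(frozen=True)
class GroundTruth:
    """Known simulation parameters per (organism, salinity, pH, temperature).

    ``cells`` maps each design cell to a :class:`RichardsParams` (growth)
    or ``None`` (no growth).
    """

    cells: Mapping[tuple[str, float, float, float], RichardsParams | None]
    noise_sd: float = DEFAULT_NOISE_SD
    baseline: float = DEFAULT_BASELINE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")

    def params_for(self, well: Well) -> RichardsParams | None:
        key = (well.organism, well.salinity, well.ph, well.temperature)
        try:
            return self.cells[key]
        except KeyError:
            raise CoverageError(f"ground truth missing cell {key}") from None

    def expected_rate(self, organism, salinity, ph, temperature) -> float:
        p = self.cells[(organism, salinity, ph, temperature)]
        return normalized_growth_rate(p) if p is not None else 0.0


def _well_rng(master_seed: int, well_id: str) -> np.random.Generator:
    # crc32 gives a stable 32-bit key per well id across runs/platforms
    return np.random.default_rng([master_seed, zlib.crc32(well_id.encode())])


def simulate_wells(design: PlateDesign, truth: GroundTruth) -> list[WellSeries]:
    """Simulate OD series for every well of ``design``.

    Identical (design, truth) including seed reproduce byte-identical
    output.  Raises :class:`CoverageError` if the truth omits any
    inoculated design cell.
    """
    t = np.asarray(design.times, dtype=float)
    out: list[WellSeries] = []
    for well in design.iter_wells():
        if well.role == "control":
            signal = np.zeros_like(t)
        else:
            params = truth.params_for(well)
            signal = (
                evaluate_richards(params, t)
                if params is not None
                else np.zeros_like(t)
            )
        od = truth.baseline + signal
        if truth.noise_sd > 0:
            rng = _well_rng(truth.seed, well.well_id)
            od = od + rng.normal(0.0, truth.noise_sd, size=len(t))
        od = np.maximum(od, 0.0)  # absorbance cannot be negative
        out.append(
            WellSeries(
                well_id=well.well_id,
                organism=well.organism,
                salinity=well.salinity,
                ph=well.ph,
                temperature=well.temperature,
                replicate=well.replicate,
                role=well.role,
                times=t.copy(),
                od=od,
            )
        )
    return out


def default_ground_truth(
    design: PlateDesign,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    baseline: float = DEFAULT_BASELINE,
) -> GroundTruth:
    """Qualitatively realistic truth for a vent-isolate style factorial.

    Rules: no organism grows at pH 1; only the first organism in the
    design grows at 45 °C; elsewhere growth occurs in ~75% of cells with
    parameters drawn from ranges typical of 30-day microplate fungal
    growth (plateau within ~2 weeks at the optimum).
    """
    rng = np.random.default_rng([seed, 0xBEEF])
    cells: dict[tuple[str, float, float, float], RichardsParams | None] = {}
    thermotolerant = design.organisms[0]
    for org in design.organisms:
        for s, p, temp in design.treatments:
            if p <= 1.0:
                cells[(org, s, p, temp)] = NO_GROWTH
                continue
            if temp >= 45.0 and org != thermotolerant:
                cells[(org, s, p, temp)] = NO_GROWTH
                continue
            if rng.uniform() > 0.75:
                cells[(org, s, p, temp)] = NO_GROWTH
                continue
            cells[(org, s, p, temp)] = RichardsParams(
                a=float(rng.uniform(0.3, 1.2)),
                k=float(rng.uniform(0.3, 0.8)),
                d=float(rng.uniform(1.5, 4.0)),
                xc=float(rng.uniform(6.0, 14.0)),
            )
    return GroundTruth(cells=cells, noise_sd=noise_sd, baseline=baseline, seed=seed)


@dataclass(frozen=True)
class RateTableTruth:
    """Ground-truth effect decomposition behind a simulated rate table."""

    grand_mean: float
    effects_a: dict
    effects_b: dict
    interaction: dict = field(default_factory=dict)


def simulate_rate_table(
    levels_a,
    levels_b,
    n_per_cell: int,
    effects_a: Mapping | None = None,
    effects_b: Mapping | None = None,
    interaction: Mapping | None = None,
    grand_mean: float = 0.0,
    noise_sd: float = 1.0,
    error_model: str = "normal",
    seed: int = 0,
):
    """Simulate a balanced two-factor response table for statistics tests.

    Response = grand_mean + effect_a + effect_b + interaction + noise.
    ``error_model`` is "normal" or "exponential" (centred, same sd).
    Returns ``(DataFrame[A, B, response], RateTableTruth)``.

    Raises ``ValueError`` unless both factors have >= 2 levels and
    ``n_per_cell >= 2`` (within-cell variance is undefined below that).
    """
    import pandas as pd

    levels_a = list(levels_a)
    levels_b = list(levels_b)
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("both factors need >= 2 levels")
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    effects_a = dict(effects_a or {})
    effects_b = dict(effects_b or {})
    interaction = dict(interaction or {})
    rng = np.random.default_rng(seed)
    rows = []
    for a in levels_a:
        for b in levels_b:
            mu = (
                grand_mean
                + effects_a.get(a, 0.0)
                + effects_b.get(b, 0.0)
                + interaction.get((a, b), 0.0)
            )
            if error_model == "normal":
                noise = rng.normal(0.0, noise_sd, size=n_per_cell)
            elif error_model == "exponential":
                noise = rng.exponential(noise_sd, size=n_per_cell) - noise_sd
            else:
                raise ValueError(f"unknown error model: {error_model}")
            for e in noise:
                rows.append((a, b, mu + e))
    table = pd.DataFrame(rows, columns=["A", "B", "response"])
    truth = RateTableTruth(grand_mean, effects_a, effects_b, interaction)
    return table, truth
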