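"""End-to-end orchestration: simulate → fit → stats → classify → report.

Every stage reads and writes plain text (CSV/TSV/JSON) so that a rerun
with the same configuration and seed is byte-identical.  A run manifest
records the package version, seed, and SHA-256 digests of each stage's
inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .classify import ClassifierRules, classify, summarize_profile
from .design import generate_design
from .plate_io import (
    RATE_COLUMNS,
    blank_subtract,
    read_plate_table,
    read_rate_table,
    write_plate_table,
    write_rate_table,
)
from .richards import (
    DEFAULT_THRESHOLD_OD,
    DEFAULT_THRESHOLD_R2,
    fit_richards,
)
from .simulate import (
    DEFAULT_BASELINE,
    DEFAULT_NOISE_SD,
    default_ground_truth,
    simulate_wells,
)
from .stats import (
    StatsError,
    aligned_rank_transform,
    art_anova,
    dunn_test,
    kruskal_wallis,
    letter_display,
)

log = logging.getLogger("ventgrowth")


class RunConfig(BaseModel):
    """Configuration for a full pipeline run."""

    out_dir: Path
    seed: int = 0
    organisms: list[str] = Field(default_factory=lambda: ["organism_1"])
    salinities: list[float] = [0.0, 30.0]
    phs: list[float] = [1.0, 3.0, 5.0, 7.0, 9.0]
    temperatures: list[float] = [15.0, 25.0, 37.0, 45.0]
    replicates: int = 8
    days: int = 30
    noise_sd: float = DEFAULT_NOISE_SD
    baseline: float = DEFAULT_BASELINE
    threshold_od: float = DEFAULT_THRESHOLD_OD
    threshold_r2: float = DEFAULT_THRESHOLD_R2
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    adjustment: str = "none"
    stages: list[str] = Field(
        default_factory=lambda: ["simulate", "fit", "stats", "classify", "report"]
    )
    plate_csv: Path | None = None  # input for `fit` when simulate is disabled


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# fit stage


def fit_plate(
    wells,
    threshold_od: float = DEFAULT_THRESHOLD_OD,
    threshold_r2: float = DEFAULT_THRESHOLD_R2,
) -> pd.DataFrame:
    """Blank-subtract and fit every inoculated well; return the rate table."""
    controls = [w for w in wells if w.role == "control"]
    rows = []
    n_ok = 0
    for w in wells:
        if w.role != "inoculated":
            continue
        sub = blank_subtract(w, controls) if controls else w
        fit = fit_richards(
            sub.times, sub.od,
            threshold_od=threshold_od, threshold_r2=threshold_r2,
        )
        p = fit.params
        rows.append(
            (
                w.organism, w.salinity, w.ph, w.temperature, w.replicate,
                p.a if p else 0.0, p.k if p else 0.0,
                p.d if p else 0.0, p.xc if p else 0.0,
                fit.rate, fit.growth_flag, fit.converged, fit.rss,
            )
        )
        n_ok += fit.converged
    table = pd.DataFrame(rows, columns=RATE_COLUMNS)
    log.info("fit: %d wells, %d converged", len(table), n_ok)
    return table


# ---------------------------------------------------------------------------
# stats stage


def _growth_cells(stratum: pd.DataFrame) -> pd.DataFrame:
    """Per-(pH, temperature) flag: does the cell contain any growth?"""
    return (
        stratum.groupby(["pH", "temperature"])["growth_flag"]
        .any()
        .unstack("temperature")
        .fillna(False)
    )


def _largest_complete_cross(grid: pd.DataFrame):
    """Trim factor levels until every remaining (pH, temperature) cell grows.

    Cells that are entirely no-growth break the full crossing the
    aligned rank transform needs, so whole levels are dropped greedily
    (the level with the most failing cells first) until the subgrid is
    complete.  Returns (ph_levels, temperature_levels) or None if either
    factor falls below two levels.
    """
    g = grid.copy()
    while not g.to_numpy().all():
        row_bad = (~g).sum(axis=1)
        col_bad = (~g).sum(axis=0)
        if row_bad.max() >= col_bad.max():
            g = g.drop(index=row_bad.idxmax())
        else:
            g = g.drop(columns=col_bad.idxmax())
        if len(g.index) < 2 or len(g.columns) < 2:
            return None
    return list(g.index), list(g.columns)


def analyze_rates(
    rates: pd.DataFrame, alpha: float = 0.05, adjustment: str = "none"
) -> dict[str, pd.DataFrame]:
    """Run the factorial chain per (organism, salinity) stratum.

    Returns three tables: ``effects`` (two-way ANOVA on aligned ranks of
    pH, temperature and their interaction), ``pairwise`` (Dunn tests of
    each factor at each level of the other) and ``letters`` (compact
    letter displays).  Cells with no growing replicate are excluded;
    degenerate strata skip the two-way ANOVA with a logged notice.
    """
    effects_rows, pairwise_rows, letters_rows = [], [], []
    for (org, sal), stratum in rates.groupby(["organism", "salinity"]):
        label = f"{org}@{sal:g}"
        grid = _growth_cells(stratum)
        cross = _largest_complete_cross(grid)
        if cross is None:
            log.info("stats: stratum %s degenerate, two-way ANOVA skipped", label)
        else:
            phs, temps = cross
            sub = stratum[
                stratum["pH"].isin(phs) & stratum["temperature"].isin(temps)
            ]
            try:
                art = aligned_rank_transform(sub, "pH", "temperature", "rate")
                for t in art_anova(art):
                    name = {"A": "pH", "B": "temperature", "A:B": "pH:temperature"}[
                        t.effect
                    ]
                    effects_rows.append(
                        (org, sal, name, t.f_statistic, t.df1, t.df2, t.p_value)
                    )
            except StatsError as exc:
                log.info("stats: stratum %s two-way ANOVA skipped (%s)", label, exc)

        # one-way chain conditioning on the other factor, growth cells only
        for cond_col, test_col in (("pH", "temperature"), ("temperature", "pH")):
            for cond_level, block in stratum.groupby(cond_col):
                groups = {
                    lvl: grp["rate"].to_numpy()
                    for lvl, grp in block.groupby(test_col)
                    if grp["growth_flag"].any()
                }
                if len(groups) < 2:
                    continue
                kw_h, kw_p = kruskal_wallis(*groups.values())
                pw = dunn_test(groups, alpha=alpha, adjustment=adjustment)
                letters = letter_display(pw)
                stratum_id = f"{org}|{sal:g}|{cond_col}={cond_level:g}"
                for r in pw:
                    pairwise_rows.append(
                        (
                            stratum_id, test_col,
                            f"{r.level_i:g}-{r.level_j:g}",
                            r.z, r.p_value, r.p_adjusted, r.significant,
                            kw_h, kw_p,
                        )
                    )
                for lvl in sorted(letters):
                    letters_rows.append(
                        (stratum_id, test_col, lvl, "".join(sorted(letters[lvl])))
                    )

    return {
        "effects": pd.DataFrame(
            effects_rows,
            columns=["organism", "salinity", "effect", "F", "df1", "df2", "p"],
        ),
        "pairwise": pd.DataFrame(
            pairwise_rows,
            columns=[
                "stratum", "factor", "pair", "z", "p", "p_adj",
                "significant", "kw_H", "kw_p",
            ],
        ),
        "letters": pd.DataFrame(
            letters_rows, columns=["stratum", "factor", "level", "letters"]
        ),
    }


# ---------------------------------------------------------------------------
# classify stage


def classify_rates(
    rates: pd.DataFrame, rules: ClassifierRules = ClassifierRules()
) -> pd.DataFrame:
    """Summarize and classify every organism in a rate table."""
    rows = []
    for org in rates["organism"].unique():
        profile = summarize_profile(rates, org)
        rows.append((org, classify(profile, rules).value))
    return pd.DataFrame(rows, columns=["organism", "group"])


# ---------------------------------------------------------------------------
# report


def render_report(
    rates: pd.DataFrame,
    letters: pd.DataFrame,
    classification: pd.DataFrame,
) -> str:
    """Deterministic plain-text summary of a run."""
    lines = ["# Growth phenotyping report", ""]
    if classification.empty:
        return "\n".join(lines + [""])
    counts = classification["group"].value_counts()
    lines.append("Group counts: " + ", ".join(
        f"{g}={counts.get(g, 0)}"
        for g in (
            "wide_range",
            "salinity_dependent_temperature_sensitive",
            "temperature_tolerant",
        )
    ))
    lines.append("")
    for org in sorted(classification["organism"]):
        group = classification.loc[
            classification["organism"] == org, "group"
        ].iloc[0]
        lines.append(f"## {org}  [{group}]")
        sub = rates[(rates["organism"] == org) & rates["growth_flag"]]
        if sub.empty:
            lines.append("no growth under any tested condition")
        else:
            lines.append(
                "grows at: salinity {%s} ‰, pH {%s}, temperature {%s} °C"
                % (
                    ", ".join(f"{v:g}" for v in sorted(sub["salinity"].unique())),
                    ", ".join(f"{v:g}" for v in sorted(sub["pH"].unique())),
                    ", ".join(f"{v:g}" for v in sorted(sub["temperature"].unique())),
                )
            )
        org_letters = letters[letters["stratum"].str.startswith(f"{org}|")]
        for _, r in org_letters.iterrows():
            lines.append(
                f"  {r['stratum']} {r['factor']}={r['level']:g}: {r['letters']}"
            )
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# runner


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "inputs": {},
    }
    plate_path = out / "plate.csv"
    rates_path = out / "rates.csv"

    if "simulate" in config.stages:
        design = generate_design(
            config.salinities, config.phs, config.temperatures,
            config.replicates, config.organisms, config.days,
        )
        truth = default_ground_truth(
            design, seed=config.seed,
            noise_sd=config.noise_sd, baseline=config.baseline,
        )
        wells = simulate_wells(design, truth)
        write_plate_table(wells, plate_path)
        log.info("simulate: %d wells written", len(wells))
    elif config.plate_csv is not None:
        plate_path = Path(config.plate_csv)

    if "fit" in config.stages:
        wells = read_plate_table(plate_path)
        manifest["inputs"]["plate.csv"] = _digest(plate_path)
        table = fit_plate(
            wells, threshold_od=config.threshold_od,
            threshold_r2=config.threshold_r2,
        )
        write_rate_table(table, rates_path)

    stats_out = {}
    if "stats" in config.stages:
        rates = read_rate_table(rates_path)
        manifest["inputs"]["rates.csv"] = _digest(rates_path)
        stats_out = analyze_rates(
            rates, alpha=config.alpha, adjustment=config.adjustment
        )
        for name, df in stats_out.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)

    classification = pd.DataFrame(columns=["organism", "group"])
    if "classify" in config.stages:
        rates = read_rate_table(rates_path)
        classification = classify_rates(rates)
        classification.to_csv(out / "classification.tsv", sep="\t", index=False)

    if "report" in config.stages:
        rates = read_rate_table(rates_path)
        letters = stats_out.get(
            "letters",
            pd.DataFrame(columns=["stratum", "factor", "level", "letters"]),
        )
        (out / "report.txt").write_text(
            render_report(rates, letters, classification)
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
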