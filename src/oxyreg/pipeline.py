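"""End-to-end orchestration of the two study analyses.

``run_hrc_pipeline`` takes a sample sheet plus traces and produces a
per-fragment table (drawdown duration, fits, selected model, regulation
statistics), per-group mean +/- SE summaries, and pairwise group comparisons
per statistic.  ``run_field_pipeline`` summarizes paired interior/exterior
logger series per colony and correlates the colony-level delta in mean (and
range of) DO against the delta in T_pos from the HRC results.

Both entry points are pure functions of their inputs; a YAML
:class:`StudyConfig` front-end resolves files for the CLI.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import hrc_models, regulation_profile, respirometry, stats_compare
from .errors import ConfigError, DataError, FitError, OxyregError, ParameterError
from .field_oxygen import FieldSeries, cumulative_time_histogram, \
    interior_exterior_delta, summarize_series
from .respirometry import DrawdownTrace

logger = logging.getLogger(__name__)

STATS = regulation_profile.STATS  # ("t_pos", "p_cmax", "p_cmin")


@dataclass
class StudyConfig:
    """File-level description of one study run (see README for the schema)."""

    sample_sheet: str
    trace_dir: str
    blanks: dict[str, str] = field(default_factory=dict)
    models: Sequence[str] = ("linear", "mm", "poly:2", "poly:4", "poly:6",
                             "poly:8", "poly:10", "poly:12")
    window: float = 600.0
    step: float = 300.0
    salinity: float = 35.0
    pressure: float = 1013.0
    floor: float = regulation_profile.DEFAULT_FLOOR
    grid_n: int = regulation_profile.DEFAULT_GRID_N
    tpos_mode: str = regulation_profile.TPOS_INTEGRAL
    group_column: str = "group"
    t_method: str = stats_compare.POOLED
    field_series: dict = field(default_factory=dict)  # colony -> {position: path}
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "sample_sheet" not in raw or "trace_dir" not in raw:
            raise ConfigError("config needs 'sample_sheet' and 'trace_dir'")
        return cls(**raw)


def parse_model_labels(labels: Sequence[str]) -> list[hrc_models.ModelSpec]:
    """Parse CLI-style labels: 'linear', 'mm', 'poly:4', 'poly:2..12'."""
    specs: list[hrc_models.ModelSpec] = []
    for lab in labels:
        lab = lab.strip()
        if lab == "linear":
            specs.append(hrc_models.ModelSpec(hrc_models.LINEAR))
        elif lab == "mm":
            specs.append(hrc_models.ModelSpec(hrc_models.MICHAELIS_MENTEN))
        elif lab.startswith("poly:"):
            body = lab.split(":", 1)[1]
            if ".." in body:
                lo, hi = (int(v) for v in body.split(".."))
                degrees = [d for d in range(lo, hi + 1) if d % 2 == 0]
            else:
                degrees = [int(body)]
            specs += [hrc_models.ModelSpec(hrc_models.CONSTRAINED_POLY, d)
                      for d in degrees]
        else:
            raise ConfigError(f"unknown model label {lab!r}")
    return specs


def _analyse_fragment(trace: DrawdownTrace, blank: DrawdownTrace | None,
                      candidates, cfg: StudyConfig) -> dict:
    rates = respirometry.compute_vo2_curve(
        trace, blank, window=cfg.window, step=cfg.step,
        salinity=cfg.salinity, pressure=cfg.pressure)
    curve = respirometry.normalize_curve(rates)
    sel = hrc_models.select_best(curve, candidates)
    best = sel.best
    prof = regulation_profile.profile(
        best, grid_n=cfg.grid_n, floor=cfg.floor,
        tpos_mode=cfg.tpos_mode, source_id=trace.chamber_id)
    dd = respirometry.drawdown_duration(trace)
    row = {
        "duration_h": dd.hours,
        "duration_censored": dd.censored,
        "n_points": curve.n,
        "selected_model": best.spec.label,
        "rss": best.rss,
        "aic": best.aic,
        "t_pos": prof.t_pos,
        "t_neg": prof.t_neg,
        "p_cmax": prof.p_cmax,
        "p_cmin": prof.p_cmin,
        "x_lo": prof.x_window[0],
        "x_hi": prof.x_window[1],
        "n_failed_models": len(sel.failures),
    }
    for f in sel.ranked:
        row[f"aic_{f.spec.label}"] = f.aic
        row[f"rss_{f.spec.label}"] = f.rss
    return row


def run_hrc_pipeline(sheet: pd.DataFrame,
                     traces: Mapping[str, DrawdownTrace],
                     blanks: Mapping[str, DrawdownTrace] | None = None,
                     config: StudyConfig | None = None) -> dict[str, object]:
    """Fragment table, group summaries and pairwise comparisons.

    ``sheet`` needs columns ``chamber_id`` and the configured group column,
    plus optionally ``blank_id`` mapping each fragment to a blank trace.
    Fragments failing every fit are flagged and excluded from summaries.
    """
    cfg = config or StudyConfig(sample_sheet="", trace_dir="")
    if sheet.empty:
        raise ConfigError("empty sample sheet")
    missing = [cid for cid in sheet["chamber_id"] if cid not in traces]
    if missing:
        raise ConfigError(f"sample-sheet chambers without traces: {missing}")
    blanks = blanks or {}
    candidates = parse_model_labels(cfg.models)

    rows = []
    for _, rec in sheet.iterrows():
        cid = rec["chamber_id"]
        blank = blanks.get(rec.get("blank_id")) if "blank_id" in rec else None
        row = {"chamber_id": cid,
               cfg.group_column: rec.get(cfg.group_column, "all"),
               "flag": ""}
        try:
            row.update(_analyse_fragment(traces[cid], blank, candidates, cfg))
        except OxyregError as exc:
            row["flag"] = f"{type(exc).__name__}: {exc}"
            logger.warning("fragment %s excluded: %s", cid, exc)
        rows.append(row)
    fragments = pd.DataFrame(rows)

    ok = fragments[fragments["flag"] == ""]
    group_rows = []
    for grp, sub in ok.groupby(cfg.group_column):
        entry = {cfg.group_column: grp, "n": len(sub)}
        for stat in (*STATS, "duration_h"):
            vals = sub[stat].dropna().to_numpy(dtype=float)
            entry[f"{stat}_mean"] = float(vals.mean()) if vals.size else np.nan
            entry[f"{stat}_se"] = (float(vals.std(ddof=1) / np.sqrt(vals.size))
                                   if vals.size > 1 else np.nan)
        group_rows.append(entry)
    groups = pd.DataFrame(group_rows)

    comparisons = {}
    levels = sorted(ok[cfg.group_column].unique())
    for ga, gb in itertools.combinations(levels, 2):
        for stat in (*STATS, "duration_h"):
            va = ok.loc[ok[cfg.group_column] == ga, stat].dropna().to_numpy(float)
            vb = ok.loc[ok[cfg.group_column] == gb, stat].dropna().to_numpy(float)
            if va.size < 2 or vb.size < 2:
                continue
            cmp_ = stats_compare.two_sample_t(va, vb, method=cfg.t_method)
            comparisons[f"{stat}:{ga}_vs_{gb}"] = {
                "t": cmp_.value, "df": cmp_.df, "p": cmp_.p,
                "mean_a": cmp_.estimate_a[0], "se_a": cmp_.estimate_a[1],
                "mean_b": cmp_.estimate_b[0], "se_b": cmp_.estimate_b[1],
                "n_a": cmp_.n_a, "n_b": cmp_.n_b, "method": cfg.t_method,
                "checks": stats_compare.assumption_checks(va, vb),
            }
    return {"fragments": fragments, "groups": groups, "comparisons": comparisons}


def run_field_pipeline(field_series: Mapping[str, Mapping[str, FieldSeries]],
                       hrc_groups: pd.DataFrame | None = None,
                       thresholds: Sequence[float] = (2.0, 5.0),
                       bin_width: float = 0.5) -> dict[str, object]:
    """Per-colony field summaries, deltas and the cross-colony correlations.

    ``field_series`` maps colony -> {'interior': FieldSeries, 'exterior':
    FieldSeries}.  When ``hrc_groups`` (from :func:`run_hrc_pipeline`, with a
    ``colony`` column and interior/exterior groups) is given, Pearson
    correlations of delta mean-DO vs delta T_pos and delta range-DO vs delta
    T_pos are computed across colonies; fewer than 3 colonies yields an
    ``n_too_small`` flag instead.
    """
    colonies = {}
    delta_rows = []
    for colony, pair in field_series.items():
        if set(pair) != {"interior", "exterior"}:
            raise ConfigError(
                f"colony {colony!r} needs both interior and exterior series")
        summ = {pos: summarize_series(s, thresholds) for pos, s in pair.items()}
        delta = interior_exterior_delta(pair["interior"], pair["exterior"])
        hist = {pos: cumulative_time_histogram(s, bin_width=bin_width)
                for pos, s in pair.items()}
        colonies[colony] = {"summaries": summ, "delta": delta,
                            "histograms": hist}
        delta_rows.append({"colony": colony, **delta})
    deltas = pd.DataFrame(delta_rows)

    correlations: dict[str, object] = {}
    if hrc_groups is not None and "colony" in hrc_groups.columns:
        tpos = hrc_groups.pivot_table(index="colony", columns="group",
                                      values="t_pos_mean")
        merged = deltas.set_index("colony").join(tpos, how="inner")
        if {"interior", "exterior"} <= set(merged.columns):
            merged["delta_t_pos"] = merged["interior"] - merged["exterior"]
            n = len(merged)
            flag = "n_too_small" if n < 3 else ""
            for key, col in (("delta_mean_do_vs_delta_tpos", "delta_mean"),
                             ("delta_range_do_vs_delta_tpos", "delta_range")):
                if n >= 3:
                    try:
                        c = stats_compare.pearson(merged[col].to_numpy(float),
                                                  merged["delta_t_pos"].to_numpy(float))
                        correlations[key] = {"r": c.value, "r2": c.extra["r2"],
                                             "df": c.df, "p": c.p, "n": n,
                                             "flag": flag}
                    except DataError as exc:
                        correlations[key] = {"error": str(exc), "n": n}
                else:
                    correlations[key] = {"flag": "n_too_small", "n": n}
    return {"colonies": colonies, "deltas": deltas, "correlations": correlations}


# ---------------------------------------------------------------------------
# File-level front end
# ---------------------------------------------------------------------------

def load_study(config: StudyConfig):
    """Resolve a :class:`StudyConfig` into in-memory sheet/traces/blanks."""
    sheet_path = Path(config.sample_sheet)
    if sheet_path.suffix in (".yaml", ".yml"):
        with open(sheet_path) as fh:
            sheet = pd.DataFrame(yaml.safe_load(fh))
    else:
        sheet = pd.read_csv(sheet_path)
    if "chamber_id" not in sheet.columns:
        raise ConfigError("sample sheet needs a 'chamber_id' column")

    trace_dir = Path(config.trace_dir)
    traces = {}
    for _, rec in sheet.iterrows():
        path = trace_dir / f"{rec['chamber_id']}.csv"
        if not path.exists():
            raise ConfigError(f"no trace file for chamber {rec['chamber_id']!r}")
        traces[rec["chamber_id"]] = respirometry.read_firesting_csv(
            path, meta=rec.to_dict())
    blanks = {}
    for blank_id, path in config.blanks.items():
        blanks[blank_id] = respirometry.read_firesting_csv(
            path, meta={"chamber_id": blank_id, "is_blank": True,
                        "displacement_volume": 0.0})
    return sheet, traces, blanks
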