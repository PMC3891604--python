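"""Readers and writers for the tabular dialects the pipeline consumes.

Plate-reader OD CSVs (one timestamp column plus one column per well),
plate-map TSVs, censored lag tables, competition count tables, ON-fraction
series and YAML simulation configs.  All parsing is delegated to pandas;
this module only enforces the column contracts and assembles domain
objects.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .growth import GrowthCurve, GrowthSummary
from .simulate import EnvSchedule, LagSpec, SimConfig, SimResult, StrainParams
from .survival import SurvivalCurve, validate_lag_table
from .switching import OnFractionSeries

__all__ = [
    "read_plate_csv",
    "read_platemap",
    "read_lag_tsv",
    "read_lag_xlsx",
    "lag_spec_from_table",
    "read_counts_tsv",
    "read_on_fraction_tsv",
    "load_sim_config",
    "write_summaries_tsv",
    "write_rate_profiles_tsv",
    "write_survival_tsv",
    "write_sim_result_tsv",
]


def _parse_time_column(col: pd.Series) -> np.ndarray:
    """Decimal hours from either numeric hours or HH:MM:SS strings."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    td = pd.to_timedelta(col.astype(str))
    return (td.dt.total_seconds() / 3600.0).to_numpy()


def read_plate_csv(
    path: "str | Path", platemap: pd.DataFrame | None = None
) -> list[GrowthCurve]:
    """Read a plate-reader CSV into one :class:`GrowthCurve` per well.

    The first column is time — decimal hours (named ``time_h``) or
    ``HH:MM:SS`` strings (named ``time``), auto-detected — and every other
    column is a well.  An optional plate map (``well_id``, ``strain``,
    ``condition``[, ``replicate``]) attaches labels; unmapped wells get
    empty labels.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("plate CSV needs a time column and at least one well")
    time_h = _parse_time_column(df.iloc[:, 0])
    labels: dict[str, tuple[str, str]] = {}
    if platemap is not None:
        for _, row in platemap.iterrows():
            labels[str(row["well_id"])] = (str(row["strain"]), str(row["condition"]))
    curves = []
    for well in df.columns[1:]:
        strain, condition = labels.get(str(well), ("", ""))
        curves.append(
            GrowthCurve(
                well_id=str(well),
                strain=strain,
                condition=condition,
                time_h=time_h,
                od600=df[well].to_numpy(dtype=float),
            )
        )
    return curves


def read_platemap(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("well_id", "strain", "condition"):
        if col not in df.columns:
            raise ValueError(f"plate map missing column {col!r}")
    return df


def read_lag_tsv(path: "str | Path") -> pd.DataFrame:
    """Censored lag table: ``cell_id strain lag_h event`` plus covariates."""
    return validate_lag_table(pd.read_csv(path, sep="\t"))


def read_lag_xlsx(
    path: "str | Path",
    sheet: "str | int" = 0,
    column_map: "dict[str, str] | None" = None,
) -> pd.DataFrame:
    """Lag table from a supplementary-spreadsheet-shaped XLSX sheet.

    ``column_map`` renames spreadsheet columns to the canonical
    ``cell_id/strain/lag_h/event`` names before validation.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    if column_map:
        df = df.rename(columns=column_map)
    return validate_lag_table(df)


def lag_spec_from_table(table: pd.DataFrame, horizon_h: float = 20.0) -> LagSpec:
    """Empirical lag distribution for the simulator from a measured table.

    Event lags form the empirical sample; the fraction of cells that never
    resumed within the horizon becomes the non-viable fraction.
    """
    validate_lag_table(table)
    events = table.loc[table["event"] == 1, "lag_h"].to_numpy(dtype=float)
    if len(events) == 0:
        raise ValueError("no events; empirical lag spec undefined")
    frac_resumed = float(
        ((table["event"] == 1) & (table["lag_h"] <= horizon_h)).mean()
    )
    return LagSpec("empirical", events, viable_frac=frac_resumed)


def read_counts_tsv(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("time_h", "count_query", "count_reference"):
        if col not in df.columns:
            raise ValueError(f"count table missing column {col!r}")
    return df


def read_on_fraction_tsv(path: "str | Path") -> list[OnFractionSeries]:
    """ON-fraction series TSV: ``initial_condition generations frac_on``."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for label, grp in df.groupby("initial_condition", sort=False):
        grp = grp.sort_values("generations")
        out.append(
            OnFractionSeries(
                initial_condition=str(label),
                generations=grp["generations"].to_numpy(dtype=float),
                frac_on=grp["frac_on"].to_numpy(dtype=float),
            )
        )
    return out


def _lag_spec_from_dict(d: dict) -> LagSpec:
    return LagSpec(
        kind=d["kind"], params=d["params"], viable_frac=float(d.get("viable_frac", 1.0))
    )


def load_sim_config(
    path: "str | Path",
) -> tuple[list[StrainParams], "EnvSchedule | None", dict, SimConfig]:
    """Parse a YAML/JSON simulation config.

    Layout::

        strains:
          - {name: A, mu_glucose: 0.35, mu_maltose: 0.30,
             lag: {kind: normal, params: [2.5, 1.0], viable_frac: 0.97}}
        schedule: [[maltose, 8], [glucose, 16]]     # optional
        heatmap: {maltose_h: [...], glucose_h: [...]}  # optional
        init_props: [0.5, 0.5]
        dt: 0.1
        n_cells: 50000
        seed: 1

    Returns (strains, schedule or None, extras, SimConfig); ``extras``
    carries ``init_props`` and any ``heatmap`` grids.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    strains = [
        StrainParams(
            name=s["name"],
            mu_glucose=float(s["mu_glucose"]),
            mu_maltose=float(s["mu_maltose"]),
            lag=_lag_spec_from_dict(s["lag"]),
        )
        for s in data["strains"]
    ]
    schedule = None
    if data.get("schedule"):
        schedule = EnvSchedule([(env, float(d)) for env, d in data["schedule"]])
    config = SimConfig(
        dt=float(data.get("dt", 0.1)),
        n_cells=int(data.get("n_cells", 50_000)),
        seed=data.get("seed"),
        horizon_h=float(data.get("horizon_h", 24.0)),
    )
    extras = {
        "init_props": data.get("init_props", [1.0 / len(strains)] * len(strains)),
        "heatmap": data.get("heatmap"),
    }
    return strains, schedule, extras, config


# ---------------------------------------------------------------------------
# writers


def write_summaries_tsv(
    summaries: "dict[str, GrowthSummary]", path: "str | Path"
) -> None:
    rows = []
    for well, s in summaries.items():
        rows.append(
            {
                "well_id": well,
                "max_rate": s.max_rate,
                "gmr": s.gmr,
                "gmr_norm": s.gmr_norm,
                "min_rate": s.min_rate,
                "od_at_min": s.od_at_min,
                "t_lo": s.t_lo,
                "t_hi": s.t_hi,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_rate_profiles_tsv(profiles: dict, path: "str | Path") -> None:
    """Long-format rate profiles (well_id, time_h, od_smooth, mu)."""
    frames = []
    for well, prof in profiles.items():
        frames.append(
            pd.DataFrame(
                {
                    "well_id": well,
                    "time_h": prof.time_h,
                    "od_smooth": prof.od_smooth,
                    "mu": prof.mu,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_survival_tsv(curve: SurvivalCurve, path: "str | Path") -> None:
    pd.DataFrame(
        {"time_h": curve.time_h, "survival": curve.survival, "at_risk": curve.at_risk}
    ).to_csv(path, sep="\t", index=False)


def write_sim_result_tsv(result: SimResult, path: "str | Path") -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)
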