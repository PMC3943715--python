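"""Trigger records to events, activity indices and detection histories.

A camera emits several triggers per animal visit; the analysis unit is the
*event*: presence of a species within one discrete 15-minute interval.
Survey nights run noon-to-noon in local time so that a nocturnal animal's
activity falls within a single night.  Events per night divided by nights
observed gives the site's activity index; whether any event occurred on a
night gives the binary detection history used by the occupancy models.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRIGGER_COLUMNS = ("site_id", "timestamp", "species")
NIGHT_LENGTH = pd.Timedelta(days=1)
BIN_LENGTH = pd.Timedelta(minutes=15)
BINS_PER_NIGHT = 96


def load_trigger_records(
    path, aliases: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a trigger-record CSV (site_id, timestamp, species).

    Rows whose timestamp cannot be parsed are excluded and logged with their
    line numbers; the exclusion count is available as
    ``df.attrs["n_excluded"]``.  A missing required column is a hard error.
    Species labels are lower-cased, stripped, and mapped through ``aliases``
    if given.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "species": str})
    missing = [c for c in TRIGGER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trigger file {path} lacks required columns {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    bad = ts.isna() & df["timestamp"].notna() | df["timestamp"].isna()
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = (df.index[bad] + 2).tolist()
        logger.warning(
            "excluded %d trigger rows with unparseable timestamps (lines %s)",
            bad.sum(), lines,
        )
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    df["species"] = df["species"].str.strip().str.lower()
    if aliases:
        aliases = {k.strip().lower(): v for k, v in aliases.items()}
        df["species"] = df["species"].map(lambda s: aliases.get(s, s))
    if df.empty:
        logger.warning("trigger file %s contains no usable records", path)
    df = df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    df.attrs["n_excluded"] = int(bad.sum())
    return df


def load_deployments(path) -> pd.DataFrame:
    """Read a deployment log CSV (site_id, start, end)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = [c for c in ("site_id", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"deployment file {path} lacks required columns {missing}")
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    if (df["end"] <= df["start"]).any():
        bad = df.loc[df["end"] <= df["start"], "site_id"].tolist()
        raise ValueError(f"deployment end precedes start for sites {bad}")
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate deployment rows for sites {dup}")
    return df


def night_anchor(start: pd.Timestamp) -> pd.Timestamp:
    """Noon at or before the deployment start: survey night 1 begins here."""
    noon = start.normalize() + pd.Timedelta(hours=12)
    return noon if start >= noon else noon - NIGHT_LENGTH


def assign_survey_nights(
    records: pd.DataFrame,
    deployments: pd.DataFrame,
    bin_anchor: str = "clock",
) -> pd.DataFrame:
    """Attach a survey-night index (>= 1) to each trigger record.

    Nights are noon-to-noon windows counted from the noon at or before each
    site's deployment start.  Records outside the deployment window are
    dropped; the count is reported in ``attrs["n_outside"]``.

    ``bin_anchor`` controls the 15-minute interval index: ``"clock"``
    (default) aligns bins to :00/:15/:30/:45 wall-clock marks;
    ``"deployment"`` counts bins from each site's deployment start time.
    """
    if bin_anchor not in ("clock", "deployment"):
        raise ValueError(f"unknown bin_anchor {bin_anchor!r}")
    unknown = sorted(set(records["site_id"]) - set(deployments["site_id"]))
    if unknown:
        raise ValueError(f"trigger records reference unknown sites: {unknown}")
    dep = deployments.set_index("site_id")
    anchors = dep["start"].map(night_anchor)

    out = records.copy()
    start = dep["start"].reindex(out["site_id"]).to_numpy()
    end = dep["end"].reindex(out["site_id"]).to_numpy()
    anchor = anchors.reindex(out["site_id"]).to_numpy()
    ts = out["timestamp"].to_numpy()
    inside = (ts >= start) & (ts <= end)
    n_outside = int((~inside).sum())
    if n_outside:
        logger.warning(
            "dropped %d trigger records outside their deployment window",
            n_outside,
        )
    out = out.loc[inside].copy()
    elapsed = out["timestamp"].to_numpy() - anchor[inside]
    elapsed_ns = elapsed.astype("timedelta64[ns]").astype(np.int64)
    day_ns = NIGHT_LENGTH.value
    bin_ns = BIN_LENGTH.value
    out["night"] = elapsed_ns // day_ns + 1
    if bin_anchor == "clock":
        out["interval"] = (elapsed_ns % day_ns) // bin_ns
    else:
        since_start = (
            (out["timestamp"].to_numpy() - start[inside])
            .astype("timedelta64[ns]")
            .astype(np.int64)
        )
        out["interval"] = (since_start % day_ns) // bin_ns
    out.attrs["n_outside"] = n_outside
    return out.reset_index(drop=True)


def discretize_events(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse triggers to events: one row per distinct
    (site, species, night, 15-min interval), however many triggers fell in
    the interval."""
    for col in ("night", "interval"):
        if col not in records.columns:
            raise ValueError("records need night/interval; run assign_survey_nights")
    events = (
        records[["site_id", "species", "night", "interval"]]
        .drop_duplicates()
        .sort_values(["site_id", "species", "night", "interval"], kind="mergesort")
        .reset_index(drop=True)
    )
    return events


def nights_observed(
    deployments: pd.DataFrame, mode: str = "fractional"
) -> pd.Series:
    """Nights each site was surveyed.

    ``fractional`` (default): deployment duration in days, so partial first
    or last nights count proportionally.  ``integer``: the number of
    noon-to-noon night windows the deployment intersects (camera nights as
    tallied in the field).
    """
    dep = deployments.set_index("site_id")
    dur = (dep["end"] - dep["start"]) / NIGHT_LENGTH
    if (dur <= 0).any():
        bad = dur.index[dur <= 0].tolist()
        raise ValueError(f"zero-length deployment for sites {bad}")
    if mode == "fractional":
        return dur.rename("nights_observed")
    if mode == "integer":
        anchors = dep["start"].map(night_anchor)
        n = ((dep["end"] - anchors) / NIGHT_LENGTH).map(np.ceil).astype(int)
        return n.rename("nights_observed")
    raise ValueError(f"unknown nights mode {mode!r}")


def activity_index(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species: Sequence[str] | None = None,
    nights_mode: str = "fractional",
) -> pd.DataFrame:
    """Per-site, per-species activity index: events per 24 h of survey.

    Every deployed site appears for every species (zero events -> index 0).
    """
    nights = nights_observed(deployments, mode=nights_mode)
    if species is None:
        species = sorted(events["species"].unique())
    counts = (
        events[events["species"].isin(species)]
        .groupby(["site_id", "species"])
        .size()
        .rename("events_total")
    )
    grid = pd.MultiIndex.from_product(
        [deployments["site_id"], list(species)], names=["site_id", "species"]
    )
    out = counts.reindex(grid, fill_value=0).reset_index()
    out["nights_observed"] = nights.reindex(out["site_id"]).to_numpy()
    out["index"] = out["events_total"] / out["nights_observed"]
    return out


def _max_night(deployments: pd.DataFrame) -> int:
    dep = deployments.set_index("site_id")
    anchors = dep["start"].map(night_anchor)
    return int(((dep["end"] - anchors) / NIGHT_LENGTH).map(np.ceil).max())


def detection_histories(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species: str,
) -> pd.DataFrame:
    """Wide site x night binary detection table for one species.

    y_st = 1 if the species produced >= 1 event at site s on night t, 0 if
    the night was surveyed without an event, NaN if night t lies outside
    the site's deployment.  Columns are night indices 1..T_max, T_max taken
    from the longest deployment.
    """
    t_max = _max_night(deployments)
    dep = deployments.set_index("site_id")
    anchors = dep["start"].map(night_anchor)
    sites = dep.index
    y = pd.DataFrame(
        np.nan,
        index=pd.Index(sites, name="site_id"),
        columns=pd.RangeIndex(1, t_max + 1, name="night"),
    )
    for site in sites:
        a = anchors[site]
        for t in range(1, t_max + 1):
            win_start = a + (t - 1) * NIGHT_LENGTH
            win_end = a + t * NIGHT_LENGTH
            if win_start < dep.loc[site, "end"] and win_end > dep.loc[site, "start"]:
                y.loc[site, t] = 0.0
    sp = events[(events["species"] == species)]
    for site, night in sp[["site_id", "night"]].drop_duplicates().itertuples(index=False):
        if night in y.columns and site in y.index:
            y.loc[site, night] = 1.0
    return y
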