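"""Study filters, movement extraction, and residency/movement indices.

The workflow mirrors a passive-telemetry study on juvenile coastal fish:

1. drop the first 24 h of detections after each release (handling stress),
2. collapse consecutive detections at one receiver into residence runs and
   read transitions between different receivers as *movements*,
3. discard movements faster than a minimum transit time (detection-range
   overlap artefacts),
4. summarise each fish by a residency index (days detected / days
   monitored) and a movement index (movements / days detected), and
5. exclude fish that left the array immediately or never moved.

"Day" always means a calendar date in a local timezone (default
Europe/Stockholm), while timestamps are stored in UTC.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime

import numpy as np
import pandas as pd

from .telemetry_io import DAY_TZ

MOVEMENT_COLUMNS = [
    "transmitter_id",
    "from_receiver",
    "to_receiver",
    "departure",
    "arrival",
    "transit_s",
]

#: Default minimum transit time between two different receivers; faster
#: "movements" are treated as detection-range overlap and removed.
DEFAULT_MIN_TRANSIT = pd.Timedelta(minutes=4)

#: Default post-release exclusion window.
DEFAULT_POSTRELEASE = pd.Timedelta(hours=24)


@dataclass(frozen=True)
class SeasonWindow:
    label: str
    start: date
    end: date  # inclusive


#: Reference seasonal windows for the 2015/2016 Gullmar Fjord deployment:
#: a warm summer, a transitional autumn and a cold winter period.
REFERENCE_SEASONS = (
    SeasonWindow("summer", date(2015, 8, 15), date(2015, 10, 5)),
    SeasonWindow("autumn", date(2015, 10, 6), date(2015, 12, 11)),
    SeasonWindow("winter", date(2015, 12, 12), date(2016, 1, 18)),
)


def check_season_windows(windows) -> None:
    """Validate that season windows are ordered, contiguous and non-overlapping."""
    if not windows:
        raise ValueError("no season windows given")
    for a, b in zip(windows, windows[1:]):
        if a.end >= b.start:
            raise ValueError(f"windows {a.label!r} and {b.label!r} overlap")
        if (b.start - a.end).days != 1:
            raise ValueError(f"gap between {a.label!r} and {b.label!r}")
        if a.start > a.end:
            raise ValueError(f"window {a.label!r} is empty")


def assign_season(timestamp, windows=REFERENCE_SEASONS, tz: str = DAY_TZ) -> str:
    """Return the season label containing ``timestamp``.

    Boundaries are calendar dates in the local timezone ``tz``; each window
    runs from its start date through its end date inclusive (equivalently:
    inclusive of the start, exclusive of the next window's start).
    """
    ts = pd.Timestamp(timestamp)
    d = (ts.tz_convert(tz) if ts.tzinfo else ts).date()
    for w in windows:
        if w.start <= d <= w.end:
            return w.label
    raise ValueError(f"{timestamp} falls outside all season windows")


def local_dates(timestamps: pd.Series, tz: str = DAY_TZ) -> pd.Series:
    """Local-timezone calendar date of each UTC timestamp."""
    return timestamps.dt.tz_convert(tz).dt.date


def remove_postrelease_window(
    detections: pd.DataFrame,
    fish: pd.DataFrame,
    window: pd.Timedelta = DEFAULT_POSTRELEASE,
) -> pd.DataFrame:
    """Drop each fish's detections from the first ``window`` after release.

    Raises ``KeyError`` naming any transmitter present in the detections but
    absent from the fish metadata.
    """
    release = fish.set_index("transmitter_id")["release_datetime"]
    unknown = set(detections["transmitter_id"]) - set(release.index)
    if unknown:
        raise KeyError(f"no release metadata for transmitter(s) {sorted(unknown)!r}")
    if detections.empty:
        return detections.copy()
    cutoff = detections["transmitter_id"].map(release) + window
    return detections.loc[detections["timestamp"] >= cutoff].reset_index(drop=True)


def extract_movements(
    detections: pd.DataFrame,
    min_transit: pd.Timedelta = DEFAULT_MIN_TRANSIT,
) -> pd.DataFrame:
    """Extract receiver-to-receiver movements from valid detections.

    Consecutive valid detections of one fish at two *different* receivers
    define a movement; runs of detections at the same receiver are collapsed
    so departure is the last detection at the origin and arrival the first
    at the destination.  Movements with transit shorter than ``min_transit``
    are removed outright — their endpoints are *not* merged into a longer
    synthetic movement, since the filter targets detection-range overlap
    artefacts, not real paths.

    Input must be sorted by (transmitter_id, timestamp); a ``valid`` column,
    if present, restricts the records considered.
    """
    det = detections
    if "valid" in det.columns:
        det = det.loc[det["valid"]]
    det = det.reset_index(drop=True)
    if det.empty:
        return pd.DataFrame(columns=MOVEMENT_COLUMNS)

    by_fish = det.groupby("transmitter_id", sort=True, observed=True)
    if (by_fish["timestamp"].diff().dropna() < pd.Timedelta(0)).any():
        raise ValueError("detections must be sorted by (transmitter_id, timestamp)")

    fish = det["transmitter_id"].to_numpy()
    recv = det["receiver_id"].to_numpy()
    ts = det["timestamp"]
    new_fish = np.r_[True, fish[1:] != fish[:-1]]
    new_run = new_fish | np.r_[True, recv[1:] != recv[:-1]]
    run_id = np.cumsum(new_run) - 1

    runs = pd.DataFrame(
        {
            "transmitter_id": fish[new_run],
            "receiver_id": recv[new_run],
            "first": ts.groupby(run_id).min().to_numpy(),
            "last": ts.groupby(run_id).max().to_numpy(),
        }
    )
    nxt = runs.shift(-1)
    same_fish = runs["transmitter_id"].to_numpy() == nxt["transmitter_id"].to_numpy()
    moves = pd.DataFrame(
        {
            "transmitter_id": runs["transmitter_id"],
            "from_receiver": runs["receiver_id"],
            "to_receiver": nxt["receiver_id"],
            "departure": runs["last"],
            "arrival": nxt["first"],
        }
    ).loc[same_fish]
    moves["transit_s"] = (moves["arrival"] - moves["departure"]).dt.total_seconds()
    moves = moves.loc[moves["transit_s"] >= min_transit.total_seconds()]
    return moves.reset_index(drop=True)[MOVEMENT_COLUMNS]


def compute_residency_index(days_detected: int, days_monitored: int) -> float:
    """Residency index: days with at least one detection over days at liberty.

    Ranges from 0 (never detected after release) to 1 (detected every
    monitored day).  Reporting layers round to 2 decimals.
    """
    if days_monitored <= 0:
        raise ValueError("days_monitored must be positive")
    if days_detected < 0 or days_detected > days_monitored:
        raise ValueError("days_detected must lie in [0, days_monitored]")
    return days_detected / days_monitored


def compute_movement_index(n_movements: int, days_detected: int) -> float:
    """Movement index: movements per day detected (relative mobility)."""
    if days_detected <= 0:
        raise ValueError("days_detected must be positive")
    if n_movements < 0:
        raise ValueError("n_movements must be non-negative")
    return n_movements / days_detected


def days_monitored(release_datetime, study_end, tz: str = DAY_TZ) -> int:
    """Whole days from the release date to the study end date.

    Computed as the difference between the two local calendar dates, the
    convention that reproduces published days-at-liberty tables for this
    study design (e.g. 15 Aug 2015 -> 18 Jan 2016 gives 156).
    """
    rel = pd.Timestamp(release_datetime)
    end = pd.Timestamp(study_end)
    rel_d = (rel.tz_convert(tz) if rel.tzinfo else rel).date()
    end_d = (end.tz_convert(tz) if end.tzinfo else end).date()
    return (end_d - rel_d).days


def fish_summary(
    detections: pd.DataFrame,
    movements: pd.DataFrame,
    fish: pd.DataFrame,
    study_end,
    tz: str = DAY_TZ,
) -> pd.DataFrame:
    """Per-fish summary table: days detected/monitored, RI, movements, MI.

    ``detections`` should already be quality-screened and post-release
    filtered.  Fish with zero days detected get RI 0 and a missing MI.
    """
    det = detections.loc[detections["valid"]] if "valid" in detections.columns else detections
    dd = (
        pd.Series(local_dates(det["timestamp"], tz).values, index=det["transmitter_id"])
        .groupby(level=0)
        .nunique()
        if len(det)
        else pd.Series(dtype=int)
    )
    nm = movements.groupby("transmitter_id").size() if len(movements) else pd.Series(dtype=int)

    out = fish.copy()
    out["days_detected"] = out["transmitter_id"].map(dd).fillna(0).astype(int)
    out["days_monitored"] = [
        days_monitored(r, study_end, tz) for r in out["release_datetime"]
    ]
    out["n_movements"] = out["transmitter_id"].map(nm).fillna(0).astype(int)
    out["residency_index"] = [
        compute_residency_index(d, m) if m > 0 else np.nan
        for d, m in zip(out["days_detected"], out["days_monitored"])
    ]
    out["movement_index"] = [
        compute_movement_index(n, d) if d > 0 else np.nan
        for n, d in zip(out["n_movements"], out["days_detected"])
    ]
    return out


def exclude_fish(
    fish: pd.DataFrame,
    detections: pd.DataFrame,
    movements: pd.DataFrame,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the study's exclusion rules after the post-release filter.

    Excludes (a) fish with no detections remaining after the post-release
    window ("left the array"), then (b) fish with detections but no extracted
    movements ("no movement patterns").  Returns the retained transmitter ids
    and a per-fish report with columns transmitter_id, retained, reason.
    Idempotent: re-applying to the retained subset changes nothing.
    """
    det = detections.loc[detections["valid"]] if "valid" in detections.columns else detections
    with_det = set(det["transmitter_id"].unique())
    with_mov = set(movements["transmitter_id"].unique()) if len(movements) else set()

    rows = []
    for tid in fish["transmitter_id"]:
        if tid not in with_det:
            rows.append((tid, False, "no detections after post-release window"))
        elif tid not in with_mov:
            rows.append((tid, False, "no movements"))
        else:
            rows.append((tid, True, ""))
    report = pd.DataFrame(rows, columns=["transmitter_id", "retained", "reason"])
    retained = report.loc[report["retained"], "transmitter_id"].tolist()
    return retained, report


def relative_movements_per_day(
    movements: pd.DataFrame,
    detections: pd.DataFrame,
    tz: str = DAY_TZ,
) -> pd.DataFrame:
    """Daily movement activity standardised by the number of fish present.

    For each calendar day: total movements (by departure date) divided by
    the number of distinct fish detected that day.  Days with no fish
    detected yield a missing ratio — a day with movements but no detections
    is a data inconsistency, not zero activity.  Returns a frame with
    columns date, n_movements, n_fish_detected, relative_movements.
    """
    det = detections.loc[detections["valid"]] if "valid" in detections.columns else detections
    fish_per_day = (
        pd.DataFrame(
            {"date": local_dates(det["timestamp"], tz), "fish": det["transmitter_id"]}
        )
        .groupby("date")["fish"]
        .nunique()
        if len(det)
        else pd.Series(dtype=int)
    )
    moves_per_day = (
        pd.Series(1, index=local_dates(movements["departure"], tz)).groupby(level=0).sum()
        if len(movements)
        else pd.Series(dtype=int)
    )
    idx = sorted(set(fish_per_day.index) | set(moves_per_day.index))
    out = pd.DataFrame(
        {
            "date": idx,
            "n_movements": [int(moves_per_day.get(d, 0)) for d in idx],
            "n_fish_detected": [int(fish_per_day.get(d, 0)) for d in idx],
        }
    )
    out["relative_movements"] = np.where(
        out["n_fish_detected"] > 0, out["n_movements"] / out["n_fish_detected"].replace(0, 1), np.nan
    )
    out.loc[out["n_fish_detected"] == 0, "relative_movements"] = np.nan
    return out
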