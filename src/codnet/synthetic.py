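"""Synthetic telemetry generator emulating a two-site fjord receiver array.

The generator reproduces the statistical structure the analysis assumes,
so the whole pipeline is testable without any field data:

- a cohort of tagged juvenile fish (lengths 16–47 cm) released in mid/late
  August at two sites monitored by 11 moored receivers,
- a smooth seasonal sea-surface-temperature decline from ~16 °C summer
  water to ~4 °C winter water,
- fish moving between receiver zones as a continuous-time jump process
  whose per-fish departure rate is log-linear in SST
  (``log rate = beta0 + b_i + beta_sst * SST``, ``b_i ~ N(0, sigma_b)``),
  with a constant per-day hazard of permanently leaving the array,
- transmitters pinging at uniform random intervals (30–90 s) while a fish
  occupies a zone, each ping detected with fixed probability (0.6, the
  convention by which the printed detection ranges were defined).

Fish occupy discrete receiver zones rather than continuous space: the
analysis only ever observes receiver-level presence, so continuous-space
simulation would add cost without adding testable structure.  Travel
between zones is an undetectable dead-time drawn uniformly from a
configurable range.  Between-site movement is restricted to two corridor
node pairs, mimicking the geography that keeps most higher-order motifs
out of the repertoire.

Everything is driven by one integer seed; identical config + seed gives
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import local_dates

_UTC = timezone.utc
_DAY = 86400.0


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic deployment."""

    seed: int  # mandatory: every draw flows from this
    n_fish: int = 48
    study_start: datetime = datetime(2015, 8, 15, tzinfo=_UTC)
    study_end: datetime = datetime(2016, 1, 18, tzinfo=_UTC)
    #: transmitter ping interval bounds, seconds
    transmit_interval: tuple[float, float] = (30.0, 90.0)
    #: probability a ping inside a zone is logged (range-definition convention)
    detection_prob: float = 0.6
    #: SST seasonal curve: logistic decline high -> low (deg C)
    sst_high: float = 17.51
    sst_low: float = 2.71
    sst_mid_day: float = 80.15
    sst_scale: float = 20.83
    sst_noise_sd: float = 0.8
    #: movement rate on the log scale, per day: exp(beta0 + b_i + beta_sst*SST)
    movement_beta0: float = -4.8
    movement_beta_sst: float = 0.25
    sigma_b: float = 0.6
    #: per-day hazard of permanent departure from the array
    emigration_hazard: float = 0.01
    #: undetectable inter-zone travel time bounds, seconds
    transit_deadtime: tuple[float, float] = (300.0, 1800.0)
    #: release staggering: offsets (days after study start) cycled over fish
    release_offsets: tuple[int, ...] = (0, 1, 1, 6, 7, 9)
    #: extra between-site corridors (receiver id pairs)
    corridors: tuple[tuple[str, str], ...] = (("F", "G"), ("E", "H"))

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.transmit_interval
        if not (0 < lo <= hi):
            raise ValueError("bad transmit interval bounds")
        if not (0 <= self.detection_prob <= 1):
            raise ValueError("detection_prob must be a probability")
        for r in (self.emigration_hazard, self.sigma_b):
            if r < 0:
                raise ValueError("rates and SDs must be non-negative")


@dataclass
class SimulatedTruth:
    """Ground truth behind one simulated dataset."""

    fish: pd.DataFrame        # + b_i, emigration_time
    occupancy: pd.DataFrame   # transmitter_id, receiver_id, start, end
    movements: pd.DataFrame   # true zone transitions with depart/arrive
    params: dict


def default_receivers(config: SimulationConfig) -> pd.DataFrame:
    """The reference 11-station array: site I (A–F, open coast) and
    site II (G–K, inner fjord); unvegetated stations use the 216 m range,
    seagrass stations 94–114 m."""
    ids = list("ABCDEFGHIJK")
    sites = ["I"] * 6 + ["II"] * 5
    ranges = [216, 216, 114, 94, 216, 104, 216, 114, 216, 94, 216]
    depths = [4, 8, 3, 2, 12, 5, 18, 6, 25, 3, 30]
    offsets = [12, -8, 25, 0, -30, 18, 45, -15, 8, 60, -22]  # retrieval clock error, s
    start = pd.Timestamp(config.study_start) - pd.Timedelta(days=3)
    end = pd.Timestamp(config.study_end) + pd.Timedelta(days=3)
    return pd.DataFrame(
        {
            "receiver_id": ids,
            "site": sites,
            "longitude": np.round(11.40 + 0.02 * np.arange(11), 3),
            "latitude": np.round(58.25 + 0.008 * np.arange(11), 3),
            "depth_m": depths,
            "detection_range_m": ranges,
            "deployment_start": start,
            "deployment_end": end,
            "clock_offset_s": offsets,
        }
    )


def zone_adjacency(receivers: pd.DataFrame, config: SimulationConfig) -> dict[str, list[str]]:
    """Within-site zones are fully linked; sites connect only via corridors."""
    adj: dict[str, list[str]] = {r: [] for r in receivers["receiver_id"]}
    for site, grp in receivers.groupby("site"):
        ids = list(grp["receiver_id"])
        for u in ids:
            adj[u].extend(v for v in ids if v != u)
    for u, v in config.corridors:
        adj[u].append(v)
        adj[v].append(u)
    return {u: sorted(set(vs)) for u, vs in adj.items()}


def simulate_sst(dates, config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Daily SST: logistic seasonal decline plus Gaussian day-to-day noise.

    Defaults are calibrated so the three reference season windows average
    roughly 16.3, 9.4 and 3.7 deg C.  With ``sst_noise_sd = 0``, the curve
    is the deterministic monotone trend.
    """
    rng = np.random.default_rng(config.seed + 11) if rng is None else rng
    dates = pd.DatetimeIndex(dates)
    d = (dates - pd.Timestamp(config.study_start).tz_localize(None).normalize()
         if dates.tz is None
         else dates - pd.Timestamp(config.study_start).normalize()).days.to_numpy()
    trend = config.sst_low + (config.sst_high - config.sst_low) / (
        1.0 + np.exp((d - config.sst_mid_day) / config.sst_scale)
    )
    noise = rng.normal(0.0, config.sst_noise_sd, len(d)) if config.sst_noise_sd else 0.0
    return pd.DataFrame({"date": dates.date, "sst": trend + noise})


def study_dates(config: SimulationConfig) -> pd.DatetimeIndex:
    return pd.date_range(
        pd.Timestamp(config.study_start).normalize(),
        pd.Timestamp(config.study_end).normalize(),
        freq="D",
    ).tz_localize(None)


def simulate_cohort(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Draw the tagged cohort: sizes, sites, releases, and latent traits.

    Lengths come from a normal (mean 29.8, SD 5.2 cm) truncated to the
    16–47 cm tagging window; weight follows a cubic length–weight relation
    with lognormal scatter.  Latent columns ``b`` (movement random
    intercept) and ``emigration_day`` (days after release) belong to the
    simulated truth, not to the observed metadata.
    """
    rng = np.random.default_rng(config.seed + 23) if rng is None else rng
    n = config.n_fish
    from scipy.stats import truncnorm

    lo, hi = (16 - 29.8) / 5.2, (47 - 29.8) / 5.2
    length = truncnorm.rvs(lo, hi, loc=29.8, scale=5.2, size=n, random_state=rng)
    weight = np.clip(8.8e-3 * length**3 * np.exp(rng.normal(0, 0.12, n)), 35, 569)
    offsets = np.array([config.release_offsets[i % len(config.release_offsets)]
                        for i in range(n)])
    release = [pd.Timestamp(config.study_start) + pd.Timedelta(days=int(o), hours=10)
               for o in offsets]
    site = np.where(np.arange(n) % 2 == 0, "I", "II")
    emigration_day = (
        rng.exponential(1.0 / config.emigration_hazard, n)
        if config.emigration_hazard > 0
        else np.full(n, np.inf)
    )
    return pd.DataFrame(
        {
            "transmitter_id": [str(1001 + i) for i in range(n)],
            "release_site": site,
            "weight_g": np.round(weight, 0),
            "total_length_cm": np.round(length, 1),
            "release_datetime": release,
            "b": rng.normal(0.0, config.sigma_b, n),
            "emigration_day": emigration_day,
        }
    )


def simulate_movement(
    cohort: pd.DataFrame,
    sst_daily: pd.DataFrame,
    config: SimulationConfig,
    receivers: pd.DataFrame | None = None,
    rng=None,
) -> SimulatedTruth:
    """Run the continuous-time zone-jump process for every fish.

    Within a day the departure rate is constant at
    ``exp(beta0 + b_i + beta_sst * SST(day))`` per day; waiting times are
    exponential with day-wise piecewise-constant rates.  Destinations are
    uniform over the current zone's graph neighbours, separated by a
    uniform undetectable travel dead-time.  Emigration (drawn in the
    cohort) truncates the process permanently.
    """
    rng = np.random.default_rng(config.seed + 37) if rng is None else rng
    receivers = default_receivers(config) if receivers is None else receivers
    adj = zone_adjacency(receivers, config)
    if any(len(v) == 0 for v in adj.values()):
        raise ValueError("disconnected receiver zone in adjacency")
    by_site = {s: list(g["receiver_id"]) for s, g in receivers.groupby("site")}

    t0 = pd.Timestamp(config.study_start)
    sst = sst_daily.set_index("date")["sst"]
    end_s = (pd.Timestamp(config.study_end) - t0).total_seconds()

    occ_rows, mov_rows = [], []
    for fishrow in cohort.itertuples(index=False):
        t = (pd.Timestamp(fishrow.release_datetime) - t0).total_seconds()
        stop = min(end_s, t + fishrow.emigration_day * _DAY)
        zone = by_site[fishrow.release_site][rng.integers(len(by_site[fishrow.release_site]))]
        seg_start = t
        log_rate_base = config.movement_beta0 + fishrow.b
        while t < stop:
            day = (t0 + pd.Timedelta(seconds=t)).date()
            lam_day = np.exp(log_rate_base + config.movement_beta_sst * float(sst.get(day, sst.iloc[-1])))
            day_end = (np.floor(t / _DAY) + 1.0) * _DAY
            wait = rng.exponential(_DAY / lam_day)
            if t + wait >= min(day_end, stop):
                t = min(day_end, stop)
                continue
            t_jump = t + wait
            dest = adj[zone][rng.integers(len(adj[zone]))]
            dead = rng.uniform(*config.transit_deadtime)
            arrive = t_jump + dead
            occ_rows.append((fishrow.transmitter_id, zone, seg_start, t_jump))
            if arrive >= stop:
                t = stop
                seg_start = None
                break
            mov_rows.append((fishrow.transmitter_id, zone, dest, t_jump, arrive))
            zone, t, seg_start = dest, arrive, arrive
        if seg_start is not None and stop > seg_start:
            occ_rows.append((fishrow.transmitter_id, zone, seg_start, stop))

    def _ts(col):
        return t0 + pd.to_timedelta(col, unit="s")

    occupancy = pd.DataFrame(occ_rows, columns=["transmitter_id", "receiver_id", "start_s", "end_s"])
    occupancy["start"] = _ts(occupancy["start_s"])
    occupancy["end"] = _ts(occupancy["end_s"])
    movements = pd.DataFrame(
        mov_rows, columns=["transmitter_id", "from_receiver", "to_receiver", "depart_s", "arrive_s"]
    )
    movements["departure"] = _ts(movements["depart_s"])
    movements["arrival"] = _ts(movements["arrive_s"])
    return SimulatedTruth(
        fish=cohort,
        occupancy=occupancy,
        movements=movements,
        params={
            "beta0": config.movement_beta0,
            "beta_sst": config.movement_beta_sst,
            "sigma_b": config.sigma_b,
            "emigration_hazard": config.emigration_hazard,
        },
    )


def simulate_detections(truth: SimulatedTruth, config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Emit the detection log implied by the occupancy truth.

    While a fish occupies a zone, pings fire at i.i.d. uniform intervals in
    ``transmit_interval`` and each is logged with ``detection_prob``.
    Detections carry the occupied receiver's id; none are emitted outside
    occupancy intervals.
    """
    rng = np.random.default_rng(config.seed + 51) if rng is None else rng
    lo, hi = config.transmit_interval
    times, fish, recv = [], [], []
    for row in truth.occupancy.itertuples(index=False):
        dur = row.end_s - row.start_s
        if dur <= 0:
            continue
        n_draw = int(dur / lo) + 2
        gaps = rng.uniform(lo, hi, n_draw)
        # transmitter phase resets at zone entry: first ping on arrival
        t = row.start_s + np.cumsum(gaps) - gaps[0]
        t = t[t < row.end_s]
        if len(t) == 0:
            continue
        keep = rng.random(len(t)) < config.detection_prob
        t = t[keep]
        times.append(t)
        fish.append(np.repeat(row.transmitter_id, len(t)))
        recv.append(np.repeat(row.receiver_id, len(t)))
    if not times:
        return pd.DataFrame(columns=["timestamp", "transmitter_id", "receiver_id", "valid"])
    t0 = pd.Timestamp(config.study_start)
    det = pd.DataFrame(
        {
            "timestamp": t0 + pd.to_timedelta(np.concatenate(times).round(), unit="s"),
            "transmitter_id": np.concatenate(fish),
            "receiver_id": np.concatenate(recv),
            "valid": True,
        }
    )
    return det.sort_values(["transmitter_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def simulate_environment(sst_daily: pd.DataFrame, config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Weekly environmental series joined to the SST curve.

    PAR tracks temperature-season tightly (both are slaves of the seasonal
    cycle) and sea level is a composite of season and wind — so the
    collinearity screen downstream has realistic structure to chew on.
    Weeks start on the reference weekly grid (25 Aug).
    """
    rng = np.random.default_rng(config.seed + 67) if rng is None else rng
    daily = sst_daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    grid_start = pd.Timestamp(config.study_start).tz_localize(None).normalize() + pd.Timedelta(days=10)
    n_weeks = int(((pd.Timestamp(config.study_end).tz_localize(None).normalize() - grid_start).days) // 7)
    rows = []
    for w in range(n_weeks):
        w0 = grid_start + pd.Timedelta(days=7 * w)
        mask = (daily["date"] >= w0) & (daily["date"] < w0 + pd.Timedelta(days=7))
        sst_w = float(daily.loc[mask, "sst"].mean())
        wind = float(np.exp(rng.normal(np.log(5.0), 0.35)))
        par = max(1.0, 30.0 * (sst_w - 2.0) + rng.normal(0, 25.0))
        sea = 95.0 - 5.5 * sst_w + 6.0 * np.log(wind) + 0.12 * par + rng.normal(0, 6.0)
        rows.append(
            {
                "week_start": w0,
                "sst": sst_w,
                "par": par,
                "sea_level": sea,
                "wind_speed": wind,
                "wind_direction": float(rng.uniform(0.0, 360.0)),
            }
        )
    return pd.DataFrame(rows)


def daily_activity(truth: SimulatedTruth, tz: str | None = None) -> pd.DataFrame:
    """True daily movement counts and fish presence (for rate diagnostics).

    A fish is "present" on a date when any occupancy interval touches it.
    Returns date, n_movements, n_fish_present, relative_movements.
    """
    from .preprocess import DAY_TZ

    tz = tz or DAY_TZ
    occ = truth.occupancy
    present: dict = {}
    for row in occ.itertuples(index=False):
        d0 = row.start.tz_convert(tz).date()
        d1 = row.end.tz_convert(tz).date()
        for d in pd.date_range(d0, d1, freq="D"):
            present.setdefault(d.date(), set()).add(row.transmitter_id)
    moves = (
        pd.Series(1, index=local_dates(truth.movements["departure"], tz)).groupby(level=0).sum()
        if len(truth.movements)
        else pd.Series(dtype=int)
    )
    idx = sorted(present)
    out = pd.DataFrame(
        {
            "date": idx,
            "n_movements": [int(moves.get(d, 0)) for d in idx],
            "n_fish_present": [len(present[d]) for d in idx],
        }
    )
    out["relative_movements"] = out["n_movements"] / out["n_fish_present"]
    return out


def simulate_bundle(config: SimulationConfig) -> dict:
    """Full in-memory input bundle: detections, metadata, environment, truth."""
    config.validate()
    receivers = default_receivers(config)
    sst = simulate_sst(study_dates(config), config)
    cohort = simulate_cohort(config)
    truth = simulate_movement(cohort, sst, config, receivers)
    detections = simulate_detections(truth, config)
    environment = simulate_environment(sst, config)
    fish_public = cohort.drop(columns=["b", "emigration_day"])
    return {
        "config": config,
        "receivers": receivers,
        "sst_daily": sst,
        "fish": fish_public,
        "detections": detections,
        "environment": environment,
        "truth": truth,
    }


def end_to_end_fixture(config: SimulationConfig, outdir) -> dict:
    """Write the complete input file set (CSV dialects the readers consume)
    plus a JSON truth bundle; returns the in-memory bundle as well."""
    from .telemetry_io import write_detections

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(config)
    write_detections(bundle["detections"], outdir / "detections.csv")
    bundle["receivers"].to_csv(outdir / "receivers.csv", index=False)
    fish = bundle["fish"].copy()
    fish["release_datetime"] = fish["release_datetime"].dt.strftime("%Y-%m-%d %H:%M:%S")
    fish.to_csv(outdir / "fish.csv", index=False)
    bundle["environment"].to_csv(outdir / "environment.csv", index=False)

    truth = bundle["truth"]
    payload = {
        "params": truth.params,
        "config": {k: str(v) for k, v in asdict(config).items()},
        "n_true_movements": int(len(truth.movements)),
        "movements": [
            {
                "transmitter_id": r.transmitter_id,
                "from": r.from_receiver,
                "to": r.to_receiver,
                "departure": str(r.departure),
                "arrival": str(r.arrival),
            }
            for r in truth.movements.itertuples(index=False)
        ],
        "emigration_day": dict(
            zip(truth.fish["transmitter_id"], map(float, truth.fish["emigration_day"]))
        ),
    }
    (outdir / "truth.json").write_text(json.dumps(payload))
    return bundle


# ---------------------------------------------------------------------------
# model-level simulators (for parameter-recovery studies)
# ---------------------------------------------------------------------------


def reference_weekly_sst(n_weeks: int = 21, config: SimulationConfig | None = None) -> np.ndarray:
    """Noise-free weekly mean SST on the reference weekly grid."""
    cfg = config or SimulationConfig(seed=0, sst_noise_sd=0.0)
    d = 10.0 + 7.0 * np.arange(n_weeks) + 3.0  # midpoints of weekly windows
    return cfg.sst_low + (cfg.sst_high - cfg.sst_low) / (1.0 + np.exp((d - cfg.sst_mid_day) / cfg.sst_scale))


def simulate_nb_counts(
    rng,
    sst_weekly: np.ndarray,
    n_subjects: int = 40,
    beta0: float = -1.0,
    beta_sst: float = 0.25,
    theta: float = 1.5,
    sigma_b: float = 0.8,
    zi_prob: float = 0.0,
):
    """Weekly counts drawn directly from the (ZI)NB random-intercept model.

    Returns (counts, covariate DataFrame with column "SST", subject ids).
    """
    n_weeks = len(sst_weekly)
    b = rng.normal(0.0, sigma_b, n_subjects)
    sst = np.tile(sst_weekly, n_subjects)
    subj = np.repeat(np.arange(n_subjects), n_weeks)
    mu = np.exp(beta0 + b[subj] + beta_sst * sst)
    y = rng.negative_binomial(theta, theta / (theta + mu))
    if zi_prob > 0:
        y = np.where(rng.random(len(y)) < zi_prob, 0, y)
    return y, pd.DataFrame({"SST": sst}), subj
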