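"""Synthetic herds of goat accelerometer streams with ground-truth birth times.

The generator emulates a leg-mounted triaxial sensor on pregnant does: a
Markov chain over behavior states at 1 s resolution, an unsigned 8-bit count
encoding of acceleration (0 g at 128 counts, 1 g at 64 counts per g by
default), a motion-triggered dual sampling rate (one record per second while
active, one per 10 s while inactive), and a single contiguous labor episode
of lateral recumbency with vigorous leg movement preceding each birth.

The posture signal is carried by which axis holds the static gravity
component: upright states load the X axis (sensor along the tibia), lateral
recumbency during labor loads the Z axis. Movement appears as Gaussian
jitter whose amplitude is state-specific.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .errors import ConfigError

__all__ = [
    "BehaviorState",
    "SimulationConfig",
    "GroundTruth",
    "DEFAULT_STATES",
    "default_transition_matrix",
    "simulate_goat",
    "simulate_herd",
    "state_intervals",
    "save_herd",
]

#: States a doe can occupy; labor_lateral is entered only through the
#: scheduled labor episode, never through the transition matrix defaults.
DEFAULT_STATES: tuple["BehaviorState", ...]

LYING_STATE_NAMES = frozenset({"inactive_rest", "sitting", "labor_lateral"})


@dataclass(frozen=True)
class BehaviorState:
    """One behavior state and its sensor signature.

    Parameters
    ----------
    name : str
        State identifier.
    gravity_axis : {'x', 'z'}
        Axis carrying the static 1 g component: X while the leg is upright,
        Z in lateral recumbency.
    jitter_sd : float
        Movement noise amplitude, counts (>= 0).
    activity_prob : float
        Probability that a given second is flagged active by the sensor's
        motion trigger, in [0, 1].
    """

    name: str
    gravity_axis: str
    jitter_sd: float
    activity_prob: float

    def __post_init__(self) -> None:
        if self.gravity_axis not in ("x", "z"):
            raise ConfigError(
                f"state {self.name!r}: gravity_axis must be 'x' or 'z'"
            )
        if self.jitter_sd < 0:
            raise ConfigError(f"state {self.name!r}: jitter_sd must be >= 0")
        if not 0.0 <= self.activity_prob <= 1.0:
            raise ConfigError(
                f"state {self.name!r}: activity_prob must lie in [0, 1]"
            )


#: inactive_rest is quiet lateral recumbency (lying on the side, leg
#: horizontal): the same Z-loaded posture as labor but nearly motionless,
#: so the classifier must separate labor from ordinary lying by movement,
#: not posture alone.
DEFAULT_STATES = (
    BehaviorState("inactive_rest", "z", 1.0, 0.02),
    BehaviorState("standing", "x", 3.0, 0.20),
    BehaviorState("walking", "x", 12.0, 0.90),
    BehaviorState("feeding", "x", 8.0, 0.70),
    BehaviorState("sitting", "x", 1.5, 0.05),
    BehaviorState("labor_lateral", "z", 15.0, 0.85),
)


def default_transition_matrix() -> np.ndarray:
    """Row-stochastic per-second transition matrix over ``DEFAULT_STATES``.

    Self-transition probabilities encode mean dwell times of minutes; the
    labor state has zero inbound probability because labor episodes are
    scheduled explicitly relative to the birth time.
    """
    dwell_s = {"inactive_rest": 1200.0, "standing": 300.0, "walking": 120.0,
               "feeding": 480.0, "sitting": 600.0, "labor_lateral": 600.0}
    # exit destination weights (never into labor_lateral)
    exits = {
        "inactive_rest": {"standing": 0.6, "sitting": 0.3, "walking": 0.1},
        "standing": {"walking": 0.3, "feeding": 0.3, "inactive_rest": 0.25,
                     "sitting": 0.15},
        "walking": {"standing": 0.4, "feeding": 0.3, "inactive_rest": 0.2,
                    "sitting": 0.1},
        "feeding": {"standing": 0.4, "inactive_rest": 0.3, "walking": 0.2,
                    "sitting": 0.1},
        "sitting": {"inactive_rest": 0.4, "standing": 0.4, "walking": 0.1,
                    "feeding": 0.1},
        "labor_lateral": {"inactive_rest": 1.0},
    }
    names = [s.name for s in DEFAULT_STATES]
    P = np.zeros((len(names), len(names)))
    for i, name in enumerate(names):
        p_stay = 1.0 - 1.0 / dwell_s[name]
        P[i, i] = p_stay
        for dest, w in exits[name].items():
            P[i, names.index(dest)] = (1.0 - p_stay) * w
    return P


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic herd.

    Defaults mirror the study cohort: 17 pregnant does, labor onset a mean
    of 90 min before the first kid's birth, a 30 min episode of lateral
    recumbency with constant leg movement, and counts encoded on 0-255 with
    0 g at 128 and 64 counts per g.
    """

    n_goats: int = 17
    duration_hours: float = 48.0
    labor_onset_lead_min: float = 90.0
    labor_episode_len_min: float = 30.0
    states: tuple[BehaviorState, ...] = DEFAULT_STATES
    transition_matrix: np.ndarray | None = None
    encoding_offset: float = 128.0
    encoding_scale: float = 64.0
    #: movement tilts the leg, redistributing gravity between the X and Z
    #: axes; per second the tilt angle is |N(0, tilt_deg_per_count *
    #: jitter_sd)| degrees, so vigorous states sweep orientation more.
    tilt_deg_per_count: float = 1.0
    outlier_rate: float = 0.0
    seed: int = 0
    start_time: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("2024-01-01 00:00:00"))
    birth_offset_hours: float | None = None  # default: duration - 6 h
    birth_jitter_min: float = 30.0
    include_labor: bool = True

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            if tuple(s.name for s in self.states) != tuple(
                    s.name for s in DEFAULT_STATES):
                raise ConfigError(
                    "transition_matrix required for non-default states")
            self.transition_matrix = default_transition_matrix()
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        self.start_time = pd.Timestamp(self.start_time)
        self.validate()

    def validate(self) -> None:
        if self.n_goats < 1:
            raise ConfigError("n_goats must be >= 1")
        if self.duration_hours < 0:
            raise ConfigError("duration_hours must be >= 0")
        P = self.transition_matrix
        if P.shape != (len(self.states), len(self.states)):
            raise ConfigError(
                "transition_matrix shape must match the number of states")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigError(
                "transition matrix rows must be non-negative and sum to 1 "
                "within 1e-9")
        if not 0 < self.labor_episode_len_min <= self.labor_onset_lead_min:
            raise ConfigError(
                "labor_episode_len_min must satisfy "
                "0 < labor_episode_len <= labor_onset_lead")
        for g in (self.encoding_offset - self.encoding_scale,
                  self.encoding_offset + self.encoding_scale):
            if not 0 <= g <= 255:
                raise ConfigError(
                    "encoding_offset +/- encoding_scale must lie in [0, 255]")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ConfigError("outlier_rate must lie in [0, 1]")
        if self.tilt_deg_per_count < 0:
            raise ConfigError("tilt_deg_per_count must be >= 0")

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["states"] = [dataclasses.asdict(s) for s in self.states]
        d["transition_matrix"] = self.transition_matrix.tolist()
        d["start_time"] = str(self.start_time)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "states" in d:
            d["states"] = tuple(BehaviorState(**s) for s in d["states"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-goat truth: 1 s state sequence, labor interval and birth time."""

    goat_id: str
    start_time: pd.Timestamp
    state_names: tuple[str, ...]
    state_codes: np.ndarray  # int8 per second
    birth_time: pd.Timestamp
    labor_onset: pd.Timestamp | None
    labor_interval: tuple[pd.Timestamp, pd.Timestamp] | None

    def labor_mask(self) -> np.ndarray:
        """Boolean per-second mask of labor_lateral seconds."""
        code = self.state_names.index("labor_lateral")
        return self.state_codes == code


def _simulate_states(P: np.ndarray, n: int, start_state: int,
                     rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0  # guard float drift
    u = rng.random(n)
    out = np.empty(n, dtype=np.int8)
    cur = start_state
    for i in range(n):
        out[i] = cur
        cur = int(np.searchsorted(cum[cur], u[i], side="right"))
    return out


def _activity_flags(states: Sequence[BehaviorState], codes: np.ndarray,
                    jitter_x: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Motion-trigger emulation: a second is active when the jitter on the
    movement axis exceeds a per-state threshold chosen so that the marginal
    active probability equals the state's activity_prob."""
    active = np.zeros(codes.shape, dtype=bool)
    for code, st in enumerate(states):
        mask = codes == code
        if not mask.any():
            continue
        p = st.activity_prob
        if p <= 0.0:
            continue
        if p >= 1.0 or st.jitter_sd == 0.0:
            active[mask] = rng.random(int(mask.sum())) < p if p < 1.0 else True
            continue
        thr = norm.isf(p / 2.0) * st.jitter_sd
        active[mask] = np.abs(jitter_x[mask]) > thr
    return active


def _goat_rng(config: SimulationConfig, goat_index: int) -> np.random.Generator:
    child = np.random.SeedSequence(config.seed).spawn(config.n_goats)
    return np.random.default_rng(child[goat_index])


def simulate_goat(config: SimulationConfig, goat_index: int
                  ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one doe's record stream and ground truth.

    Active seconds emit one record each; runs of inactive seconds emit one
    record per completed 10 s, stamped at the tenth second of the run (a
    trailing partial run emits nothing). Counts are
    ``clip(round(offset + scale * gravity + jitter), 0, 255)`` unless the
    record is an injected out-of-range outlier.
    """
    config.validate()
    if not 0 <= goat_index < config.n_goats:
        raise ConfigError("goat_index must satisfy 0 <= goat_index < n_goats")
    rng = _goat_rng(config, goat_index)
    goat_id = f"goat{goat_index + 1:02d}"
    names = tuple(s.name for s in config.states)
    n = int(round(config.duration_hours * 3600))
    t0 = config.start_time

    # scheduled birth and labor episode (in seconds from stream start)
    offset_h = (config.birth_offset_hours if config.birth_offset_hours
                is not None else config.duration_hours - 6.0)
    jitter = rng.normal(0.0, config.birth_jitter_min * 60.0)
    lead_s = config.labor_onset_lead_min * 60.0
    birth_s = int(round(offset_h * 3600 + jitter))
    birth_s = int(np.clip(birth_s, lead_s, max(lead_s, n)))
    onset_s = int(round(birth_s - lead_s))
    episode_end_s = onset_s + int(round(config.labor_episode_len_min * 60))

    if n == 0:
        empty = _empty_records()
        gt = GroundTruth(goat_id, t0, names, np.empty(0, np.int8),
                         t0 + pd.Timedelta(seconds=birth_s), None, None)
        return empty, gt

    codes = _simulate_states(config.transition_matrix, n,
                             start_state=0, rng=rng)
    labor_code = names.index("labor_lateral")
    labor_onset = labor_interval = None
    if config.include_labor:
        lo, hi = max(onset_s, 0), min(episode_end_s, n)
        codes[lo:hi] = labor_code
        labor_onset = t0 + pd.Timedelta(seconds=onset_s)
        labor_interval = (labor_onset,
                          t0 + pd.Timedelta(seconds=episode_end_s))

    sd = np.array([s.jitter_sd for s in config.states])[codes]
    jit = rng.normal(0.0, 1.0, size=(n, 3)) * sd[:, None]
    active = _activity_flags(config.states, codes, jit[:, 0], rng)

    # gravity splits between the native posture axis and the other sagittal
    # axis according to a per-second leg tilt (random sign on the off axis)
    grav_z = np.array(
        [1.0 if s.gravity_axis == "z" else 0.0 for s in config.states])[codes]
    tilt_sd_rad = np.deg2rad(config.tilt_deg_per_count) * sd
    theta = np.abs(rng.normal(0.0, 1.0, n)) * tilt_sd_rad
    off_sign = rng.choice((-1.0, 1.0), n)
    g_native = np.cos(theta)
    g_off = np.sin(theta) * off_sign
    base = np.empty((n, 3))
    base[:, 0] = config.encoding_offset + config.encoding_scale * (
        np.where(grav_z == 1.0, g_off, g_native))
    base[:, 1] = config.encoding_offset
    base[:, 2] = config.encoding_offset + config.encoding_scale * (
        np.where(grav_z == 1.0, g_native, g_off))
    counts = np.clip(np.round(base + jit), 0, 255).astype(np.int64)

    # dual-rate emission: every active second; end-stamped 10 s inactive runs
    idx = np.arange(n)
    last_active = np.maximum.accumulate(np.where(active, idx, -1))
    run_pos = idx - last_active  # 1-based position within an inactive run
    emit = active | (~active & (run_pos % 10 == 0))
    eidx = idx[emit]
    m = eidx.size

    x, y, z = counts[eidx, 0], counts[eidx, 1], counts[eidx, 2]
    if config.outlier_rate > 0 and m:
        bad = rng.random(m) < config.outlier_rate
        nbad = int(bad.sum())
        if nbad:
            axis = rng.integers(0, 3, nbad)
            # 65 corrupt values: [-20, -1] then [256, 300]
            pick = rng.integers(0, 65, nbad)
            val = np.where(pick < 20, pick - 20, pick - 20 + 256)
            for a, arr in enumerate((x, y, z)):
                sel = np.flatnonzero(bad)[axis == a]
                arr[sel] = val[axis == a]

    records = pd.DataFrame({
        "data_number": np.arange(1, m + 1, dtype=np.int64),
        "gateway_id": goat_id,
        "timestamp": t0 + pd.to_timedelta(eidx, unit="s"),
        "rssi": rng.integers(-90, -40, m),
        "battery": np.linspace(100, 95, m).round().astype(np.int64)
        if m else np.empty(0, np.int64),
        "activity": active[eidx],
        "x": x, "y": y, "z": z,
    })
    gt = GroundTruth(goat_id, t0, names, codes,
                     t0 + pd.Timedelta(seconds=birth_s),
                     labor_onset, labor_interval)
    return records, gt


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame({
        "data_number": pd.Series(dtype=np.int64),
        "gateway_id": pd.Series(dtype=str),
        "timestamp": pd.Series(dtype="datetime64[ns]"),
        "rssi": pd.Series(dtype=np.int64),
        "battery": pd.Series(dtype=np.int64),
        "activity": pd.Series(dtype=bool),
        "x": pd.Series(dtype=np.int64),
        "y": pd.Series(dtype=np.int64),
        "z": pd.Series(dtype=np.int64),
    })


def simulate_herd(config: SimulationConfig
                  ) -> list[tuple[pd.DataFrame, GroundTruth]]:
    """Simulate ``n_goats`` independent streams; reproducible from the seed."""
    return [simulate_goat(config, i) for i in range(config.n_goats)]


def state_intervals(gt: GroundTruth) -> pd.DataFrame:
    """Compress the per-second state sequence into run intervals.

    Returns a frame with columns goat_id, state, start, end (half-open).
    """
    codes = gt.state_codes
    if codes.size == 0:
        return pd.DataFrame(columns=["goat_id", "state", "start", "end"])
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))
    return pd.DataFrame({
        "goat_id": gt.goat_id,
        "state": [gt.state_names[codes[s]] for s in starts],
        "start": gt.start_time + pd.to_timedelta(starts, unit="s"),
        "end": gt.start_time + pd.to_timedelta(ends, unit="s"),
    })


def save_herd(herd: list[tuple[pd.DataFrame, GroundTruth]], outdir) -> dict:
    """Write a herd to disk: sensor CSV, state-interval sidecar, birth table.

    Returns the paths written, keyed 'records', 'states', 'births'.
    """
    from pathlib import Path

    from . import sensor_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"records": outdir / "records.csv",
             "states": outdir / "state_intervals.csv",
             "births": outdir / "births.csv"}
    sensor_io.write_records(
        pd.concat([r for r, _ in herd], ignore_index=True), paths["records"])
    pd.concat([state_intervals(gt) for _, gt in herd],
              ignore_index=True).to_csv(paths["states"], index=False)
    pd.DataFrame({
        "goat_id": [gt.goat_id for _, gt in herd],
        "birth_time": [gt.birth_time for _, gt in herd],
        "labor_onset": [gt.labor_onset for _, gt in herd],
        "labor_end": [gt.labor_interval[1] if gt.labor_interval else None
                      for _, gt in herd],
    }).to_csv(paths["births"], index=False)
    return paths
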