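"""Monte Carlo particle simulator of a three-level membrane signaling cascade.

Membrane proteins are volumetric 2-D particles diffusing by Brownian motion
on a periodic square patch of membrane.  A ligand field activates free
receptors to first complexes (T1); T1 recruits a scaffold protein on contact
to form a second complex (T2); T2 recruits a functional protein to form the
signal-emitting third complex (T3).  Active inhibitory proteins depolymerize
T3 on collision, releasing all three monomers back into the pool (negative
feedback): inhibitors are activated at a rate proportional to the current T3
count and deactivate first-order.  Each surviving T3 emits output events
stochastically; the smoothed, normalized event rate is the output signal
strength.

Two study arms differ only in particle diffusivity: the *normal* membrane
uses ``d_normal`` and the *superfluid* membrane (higher fluidity, e.g. after
silicate-ion exposure) uses ``d_normal * fluidity_factor``.  The comparison
of interest is the maximum growth rate of the output signal after a step
stimulus and the time at which it occurs; under a resting (basal) stimulus
the feedback loop produces quasi-periodic oscillations of the T3 level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.stats import binomtest

__all__ = [
    "SimConfig",
    "SimState",
    "SimTrace",
    "SignalMetrics",
    "init",
    "step",
    "run",
    "metrics",
    "compare_fluidity",
    "pairs_within",
    "ConfigError",
]

R_FREE, T1, T2, T3 = 0, 1, 2, 3
_SUBUNITS = np.array([1.0, 1.0, 2.0, 3.0])  # per receptor state

#: Autocorrelation peak thresholds for the oscillation detector; calibrated
#: on closed-form positives (sines) and negatives (white noise, flat traces).
OSC_PROMINENCE = 0.1
OSC_HEIGHT = 0.05


class ConfigError(ValueError):
    """Configuration violates simulator invariants; message lists them."""


@dataclass
class SimConfig:
    """Simulator configuration.

    Lengths in µm, times in s, diffusivities in µm²/s; rate parameters are
    per-step probabilities.  Defaults are order-of-magnitude plausible for a
    1 µm² membrane patch (receptor density 200/µm², membrane-protein
    diffusivity 0.05 µm²/s, 10 nm interaction radius) and place the step
    response on a ~100 ms timescale.
    """

    box_size: float = 1.0
    n_receptors: int = 200
    n_scaffolds: int = 200
    n_functionals: int = 200
    n_inhibitors: int = 50
    d_normal: float = 0.05
    fluidity_factor: float = 1.0
    interaction_radius: float = 0.01
    dt: float = 1e-4
    t_end: float = 0.6
    p_ligand_on: float = 0.05
    p_basal: float = 5e-5
    k_feedback: float = 0.2
    p_inhibitor_off: float = 0.01
    k_output: float = 0.5
    complex_mobility_rule: str = "sqrt_subunits"  # or "constant"
    protocol: str = "step"  # or "resting"
    on_windows: tuple = ((0.1, 0.2), (0.4, 0.5))
    seed: int = 0
    record_interval: float = 1e-3
    smooth_window: int = 10  # recording intervals
    inactive_inhibitors_diffuse: bool = True
    neighbor_method: str = "auto"  # "auto" | "bruteforce" | "grid"

    def __post_init__(self) -> None:
        problems = []
        for name in ("n_receptors", "n_scaffolds", "n_functionals", "n_inhibitors"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.dt <= 0:
            problems.append("dt must be > 0")
        if self.box_size <= 0:
            problems.append("box_size must be > 0")
        if self.interaction_radius <= 0:
            problems.append("interaction_radius must be > 0")
        if self.d_normal < 0 or self.fluidity_factor <= 0:
            problems.append("diffusivity must be >= 0 and fluidity_factor > 0")
        d = self.diffusivity
        if d > 0 and self.dt > 0 and np.sqrt(4.0 * d * self.dt) >= self.box_size / 10.0:
            problems.append(
                "Brownian step RMS sqrt(4 D dt) must stay below box_size / 10"
            )
        if self.protocol not in ("step", "resting"):
            problems.append(f"unknown protocol {self.protocol!r}")
        if self.complex_mobility_rule not in ("sqrt_subunits", "constant"):
            problems.append(f"unknown complex_mobility_rule {self.complex_mobility_rule!r}")
        for p_name in ("p_ligand_on", "p_basal", "p_inhibitor_off", "k_output"):
            if not 0.0 <= getattr(self, p_name) <= 1.0:
                problems.append(f"{p_name} must lie in [0, 1]")
        if self.k_feedback < 0:
            problems.append("k_feedback must be >= 0")
        if self.record_interval < self.dt:
            problems.append("record_interval must be >= dt")
        if problems:
            raise ConfigError("; ".join(problems))

    @property
    def diffusivity(self) -> float:
        """Effective free-monomer diffusivity for this arm."""
        return self.d_normal * self.fluidity_factor

    def signal_on(self, t: float) -> bool:
        if self.protocol == "resting":
            return False
        return any(lo <= t < hi for lo, hi in self.on_windows)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def resting(cls, **kwargs) -> "SimConfig":
        """Resting-state preset: basal stimulation only, 5 s horizon."""
        kwargs.setdefault("protocol", "resting")
        kwargs.setdefault("t_end", 5.0)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["on_windows"] = [list(w) for w in self.on_windows]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "on_windows" in d:
            d["on_windows"] = tuple(tuple(w) for w in d["on_windows"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SimState:
    """Mutable per-particle simulator state.

    Receptor entities carry the complex: ``r_state`` is R_FREE/T1/T2/T3 and
    ``r_scaffold`` / ``r_functional`` index the bound partners (-1 = none).
    Bound scaffolds/functionals move with their complex; their own position
    entries are refreshed only on release.
    """

    time: float
    r_pos: np.ndarray
    r_state: np.ndarray
    r_scaffold: np.ndarray
    r_functional: np.ndarray
    s_pos: np.ndarray
    s_free: np.ndarray
    f_pos: np.ndarray
    f_free: np.ndarray
    i_pos: np.ndarray
    i_active: np.ndarray
    rng: np.random.Generator
    cumulative_output: int = 0

    def counts(self) -> dict:
        states = np.bincount(self.r_state, minlength=4)
        return {
            "R_free": int(states[R_FREE]),
            "T1": int(states[T1]),
            "T2": int(states[T2]),
            "T3": int(states[T3]),
            "S_free": int(self.s_free.sum()),
            "F_free": int(self.f_free.sum()),
            "I_active": int(self.i_active.sum()),
            "I_inactive": int((~self.i_active).sum()),
        }

    def check_conservation(self, config: SimConfig) -> None:
        c = self.counts()
        assert c["R_free"] + c["T1"] + c["T2"] + c["T3"] == config.n_receptors
        assert c["S_free"] + c["T2"] + c["T3"] == config.n_scaffolds
        assert c["F_free"] + c["T3"] == config.n_functionals
        assert c["I_active"] + c["I_inactive"] == config.n_inhibitors
        # every bound partner is marked non-free exactly once
        bound_s = self.r_scaffold[self.r_scaffold >= 0]
        assert len(bound_s) == len(set(bound_s.tolist()))
        for pos in (self.r_pos, self.s_pos, self.f_pos, self.i_pos):
            assert np.all((pos >= 0) & (pos < config.box_size))


def init(config: SimConfig) -> SimState:
    """Place all particles uniformly at random; receptors free, inhibitors
    inactive, time 0.  Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    L = config.box_size

    def uniform(n):
        return rng.uniform(0.0, L, size=(n, 2))

    return SimState(
        time=0.0,
        r_pos=uniform(config.n_receptors),
        r_state=np.zeros(config.n_receptors, dtype=np.int8),
        r_scaffold=np.full(config.n_receptors, -1, dtype=np.int64),
        r_functional=np.full(config.n_receptors, -1, dtype=np.int64),
        s_pos=uniform(config.n_scaffolds),
        s_free=np.ones(config.n_scaffolds, dtype=bool),
        f_pos=uniform(config.n_functionals),
        f_free=np.ones(config.n_functionals, dtype=bool),
        i_pos=uniform(config.n_inhibitors),
        i_active=np.zeros(config.n_inhibitors, dtype=bool),
        rng=rng,
    )


def pairs_within(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    radius: float,
    box: float,
    method: str = "auto",
) -> np.ndarray:
    """Index pairs (i, j) with periodic distance <= radius, sorted
    lexicographically.

    ``method="bruteforce"`` evaluates all pairs under the minimum-image
    metric; ``"grid"`` uses a periodic spatial index (cKDTree with boxsize).
    Both return identical pairs; ``"auto"`` picks by problem size.
    """
    na, nb = len(pos_a), len(pos_b)
    if na == 0 or nb == 0:
        return np.empty((0, 2), dtype=np.int64)
    if method == "auto":
        method = "bruteforce" if na * nb <= 250_000 else "grid"
    if method == "bruteforce":
        delta = pos_a[:, None, :] - pos_b[None, :, :]
        delta -= box * np.round(delta / box)
        d2 = np.einsum("ijk,ijk->ij", delta, delta)
        pairs = np.argwhere(d2 <= radius * radius)
    elif method == "grid":
        tree_a = cKDTree(np.mod(pos_a, box), boxsize=box)
        tree_b = cKDTree(np.mod(pos_b, box), boxsize=box)
        neighbors = tree_a.query_ball_tree(tree_b, radius)
        pairs = np.array(
            [(i, j) for i, js in enumerate(neighbors) for j in sorted(js)],
            dtype=np.int64,
        ).reshape(-1, 2)
    else:
        raise ValueError(f"unknown neighbor method {method!r}")
    if pairs.size:
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
    return pairs.astype(np.int64)


def _greedy_match(pairs: np.ndarray, rng: np.random.Generator):
    """Randomized-order greedy matching; each index used at most once per side."""
    if len(pairs) == 0:
        return []
    order = rng.permutation(len(pairs))
    used_a, used_b, out = set(), set(), []
    for k in order:
        a, b = int(pairs[k, 0]), int(pairs[k, 1])
        if a not in used_a and b not in used_b:
            used_a.add(a)
            used_b.add(b)
            out.append((a, b))
    return out


def step(state: SimState, config: SimConfig) -> int:
    """Advance the state by one time step; returns output events emitted.

    Sub-steps, in order: Brownian displacement with periodic wrap; ligand
    activation of free receptors; contact reactions T1+S→T2 and T2+F→T3
    (randomized pair order, at most one pair reaction per particle per
    step); inhibitor feedback activation/deactivation; T3 depolymerization
    by active inhibitors (monomers released at jittered positions); output
    emission by surviving T3.  The state is mutated in place.
    """
    rng = state.rng
    L = config.box_size
    dt = config.dt
    r = config.interaction_radius
    d_free = config.diffusivity

    # (1) Brownian displacement
    if config.complex_mobility_rule == "sqrt_subunits":
        d_by_state = d_free / np.sqrt(_SUBUNITS)
    else:
        d_by_state = np.full(4, d_free)
    scale = np.sqrt(2.0 * d_by_state[state.r_state] * dt)
    state.r_pos = np.mod(
        state.r_pos + rng.normal(size=state.r_pos.shape) * scale[:, None], L
    )
    sd_free = np.sqrt(2.0 * d_free * dt)
    for pos, mask in ((state.s_pos, state.s_free), (state.f_pos, state.f_free)):
        idx = np.flatnonzero(mask)
        if idx.size:
            pos[idx] = np.mod(pos[idx] + rng.normal(0.0, sd_free, (idx.size, 2)), L)
    if config.inactive_inhibitors_diffuse:
        state.i_pos = np.mod(
            state.i_pos + rng.normal(0.0, sd_free, state.i_pos.shape), L
        )
    else:
        idx = np.flatnonzero(state.i_active)
        if idx.size:
            state.i_pos[idx] = np.mod(
                state.i_pos[idx] + rng.normal(0.0, sd_free, (idx.size, 2)), L
            )

    # (2) ligand activation of free receptors
    p_on = config.p_ligand_on if config.signal_on(state.time) else config.p_basal
    free_idx = np.flatnonzero(state.r_state == R_FREE)
    if free_idx.size and p_on > 0:
        hits = free_idx[rng.random(free_idx.size) < p_on]
        state.r_state[hits] = T1

    reacted = np.zeros(len(state.r_state), dtype=bool)

    # (3a) T1 + free scaffold -> T2
    t1_idx = np.flatnonzero(state.r_state == T1)
    s_idx = np.flatnonzero(state.s_free)
    if t1_idx.size and s_idx.size:
        cand = pairs_within(
            state.r_pos[t1_idx], state.s_pos[s_idx], r, L, config.neighbor_method
        )
        for a, b in _greedy_match(cand, rng):
            ri, si = int(t1_idx[a]), int(s_idx[b])
            state.r_state[ri] = T2
            state.r_scaffold[ri] = si
            state.s_free[si] = False
            reacted[ri] = True

    # (3b) T2 + free functional -> T3
    t2_idx = np.flatnonzero((state.r_state == T2) & ~reacted)
    f_idx = np.flatnonzero(state.f_free)
    if t2_idx.size and f_idx.size:
        cand = pairs_within(
            state.r_pos[t2_idx], state.f_pos[f_idx], r, L, config.neighbor_method
        )
        for a, b in _greedy_match(cand, rng):
            ri, fi = int(t2_idx[a]), int(f_idx[b])
            state.r_state[ri] = T3
            state.r_functional[ri] = fi
            state.f_free[fi] = False
            reacted[ri] = True

    # (4) inhibitor feedback (simultaneous update from current flags)
    n_t3 = int(np.sum(state.r_state == T3))
    p_act = min(1.0, config.k_feedback * n_t3 / config.n_receptors)
    inactive = np.flatnonzero(~state.i_active)
    active = np.flatnonzero(state.i_active)
    turn_on = (
        inactive[rng.random(inactive.size) < p_act] if inactive.size else inactive
    )
    turn_off = (
        active[rng.random(active.size) < config.p_inhibitor_off]
        if active.size
        else active
    )
    state.i_active[turn_on] = True
    state.i_active[turn_off] = False

    # (5) depolymerization of T3 by active inhibitors
    i_idx = np.flatnonzero(state.i_active)
    t3_idx = np.flatnonzero((state.r_state == T3) & ~reacted)
    if i_idx.size and t3_idx.size:
        cand = pairs_within(
            state.i_pos[i_idx], state.r_pos[t3_idx], r, L, config.neighbor_method
        )
        for a, b in _greedy_match(cand, rng):
            ri = int(t3_idx[b])
            si = int(state.r_scaffold[ri])
            fi = int(state.r_functional[ri])
            center = state.r_pos[ri]
            # released monomers land uniformly within one radius of the site
            for pos_arr, idx in ((state.s_pos, si), (state.f_pos, fi)):
                rho = r * np.sqrt(rng.random())
                theta = rng.uniform(0.0, 2.0 * np.pi)
                pos_arr[idx] = np.mod(
                    center + rho * np.array([np.cos(theta), np.sin(theta)]), L
                )
            state.s_free[si] = True
            state.f_free[fi] = True
            state.r_state[ri] = R_FREE
            state.r_scaffold[ri] = -1
            state.r_functional[ri] = -1

    # (6) output emission by surviving T3
    m = int(np.sum(state.r_state == T3))
    events = int(rng.binomial(m, config.k_output)) if m else 0
    state.cumulative_output += events
    state.time += dt
    return events


@dataclass
class SimTrace:
    """Recorded cascade time series.

    Fractions are of ``n_receptors``; ``receptor_activation`` counts every
    activated receptor (T1 + T2 + T3).  ``output_signal`` is the per-interval
    output-event rate, moving-average smoothed and normalized by its
    theoretical per-interval maximum ``n_receptors * k_output * interval/dt``.
    """

    times: np.ndarray
    t1_frac: np.ndarray
    t2_frac: np.ndarray
    t3_frac: np.ndarray
    receptor_activation: np.ndarray
    output_counts: np.ndarray
    output_signal: np.ndarray
    config: SimConfig
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "t1_frac": self.t1_frac,
                "t2_frac": self.t2_frac,
                "t3_frac": self.t3_frac,
                "receptor_activation": self.receptor_activation,
                "output_counts": self.output_counts,
                "output_signal": self.output_signal,
            }
        )


def run(config: SimConfig, check_conservation: bool = False) -> SimTrace:
    """Run the cascade and record a trace every ``record_interval``."""
    state = init(config)
    spi = max(1, int(round(config.record_interval / config.dt)))
    n_steps = int(round(config.t_end / config.dt))
    n_rec = n_steps // spi
    t1 = np.empty(n_rec)
    t2 = np.empty(n_rec)
    t3 = np.empty(n_rec)
    act = np.empty(n_rec)
    out = np.empty(n_rec)
    interval_events = 0
    rec = 0
    for i in range(n_steps):
        interval_events += step(state, config)
        if check_conservation:
            state.check_conservation(config)
        if (i + 1) % spi == 0:
            c = state.counts()
            n_r = config.n_receptors
            t1[rec] = c["T1"] / n_r
            t2[rec] = c["T2"] / n_r
            t3[rec] = c["T3"] / n_r
            act[rec] = (c["T1"] + c["T2"] + c["T3"]) / n_r
            out[rec] = interval_events
            interval_events = 0
            rec += 1
    max_per_interval = config.n_receptors * config.k_output * spi
    smoothed = uniform_filter1d(out, size=config.smooth_window, mode="nearest")
    signal = smoothed / max_per_interval if max_per_interval > 0 else smoothed
    times = (np.arange(n_rec) + 1) * spi * config.dt
    return SimTrace(
        times=times,
        t1_frac=t1,
        t2_frac=t2,
        t3_frac=t3,
        receptor_activation=act,
        output_counts=out,
        output_signal=signal,
        config=config,
        seed=config.seed,
    )


@dataclass
class SignalMetrics:
    """Response metrics of one trace."""

    max_growth_rate: float  # of output_signal, per second
    t_max_growth: float  # s, absolute trace time
    response_lag: float  # s after onset to half-maximal output signal
    oscillating: bool
    period: float  # s; NaN when not oscillating


def _growth_rate(trace: SimTrace) -> np.ndarray:
    """Centered finite difference of output_signal over the smoothing window."""
    h = max(1, trace.config.smooth_window // 2)
    y = trace.output_signal
    t = trace.times
    g = np.full_like(y, np.nan)
    g[h:-h] = (y[2 * h :] - y[: -2 * h]) / (t[2 * h :] - t[: -2 * h])
    return g


def detect_oscillation(
    values: np.ndarray,
    dt: float,
    prominence: float = OSC_PROMINENCE,
    height: float = OSC_HEIGHT,
) -> tuple[bool, float]:
    """Oscillation flag + dominant period from the detrended autocorrelation.

    The series is linearly detrended, its autocorrelation normalized to 1 at
    lag 0, and a secondary peak with sufficient prominence and height marks
    periodicity; the dominant period is the lag of the highest such peak.
    Two credibility rules reject slow trends masquerading as cycles: the
    initial transient (first 10% of the series) is discarded, and the period
    must fit at least three times into the analyzed span.
    """
    y = np.asarray(values, dtype=float)
    y = y[len(y) // 10 :]
    n = len(y)
    if n < 4 or np.ptp(y) == 0:
        return False, float("nan")
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    var = float(np.dot(resid, resid))
    if var == 0:
        return False, float("nan")
    acf = np.correlate(resid, resid, mode="full")[n - 1 :] / var
    max_lag = n // 3
    peaks, props = find_peaks(acf[1 : max_lag + 1], prominence=prominence, height=height)
    if peaks.size == 0:
        return False, float("nan")
    best = peaks[np.argmax(props["peak_heights"])]
    return True, float((best + 1) * dt)


def metrics(
    trace: SimTrace, onset: float | None = None, offset: float | None = None
) -> SignalMetrics:
    """Signal metrics of a trace.

    Growth-rate statistics are taken over ``[onset, offset]``; by default
    ``onset`` is the first stimulus window start (0 for the resting
    protocol) and ``offset`` the matching window end (trace end for
    resting).  Oscillation detection runs on the detrended T3-fraction
    autocorrelation.
    """
    cfg = trace.config
    if len(trace.times) < 2 * cfg.smooth_window:
        raise ValueError("trace shorter than two smoothing windows")
    if onset is None:
        onset = cfg.on_windows[0][0] if cfg.protocol == "step" else 0.0
    if onset > trace.times[-1]:
        raise ValueError("trace does not cover the onset time")
    onset = max(onset, float(trace.times[0]))
    if offset is None:
        offset = trace.times[-1]
        if cfg.protocol == "step":
            for lo, hi in cfg.on_windows:
                if lo <= onset < hi:
                    offset = hi
                    break

    g = _growth_rate(trace)
    window = (trace.times >= onset) & (trace.times <= offset) & np.isfinite(g)
    if not np.any(window):
        raise ValueError("no finite growth-rate samples in the analysis window")
    w_idx = np.flatnonzero(window)
    best = w_idx[np.argmax(g[w_idx])]
    max_rate = float(g[best])
    t_max = float(trace.times[best])

    in_win = (trace.times >= onset) & (trace.times <= offset)
    sig = trace.output_signal[in_win]
    t_win = trace.times[in_win]
    lag = float("nan")
    if sig.size and sig.max() > sig[0]:
        # half-rise above the onset baseline
        half = np.flatnonzero(sig >= sig[0] + 0.5 * (sig.max() - sig[0]))
        lag = float(t_win[half[0]] - onset)

    rec_dt = float(trace.times[1] - trace.times[0])
    oscillating, period = detect_oscillation(trace.t3_frac, rec_dt)
    return SignalMetrics(
        max_growth_rate=max_rate,
        t_max_growth=t_max,
        response_lag=lag,
        oscillating=oscillating,
        period=period,
    )


def compare_fluidity(
    config: SimConfig, n_seeds: int = 20, fluidity_factor: float = 2.0
) -> tuple[pd.DataFrame, dict]:
    """Paired normal vs superfluid comparison over seeds.

    Each seed runs the same configuration twice, differing only in the
    fluidity factor (normal = 1, superfluid = ``fluidity_factor``).  Returns
    a per-seed table and a summary with median metrics, the fraction of
    pairs where the superfluid arm has the larger maximum growth rate (and
    the no-later time of maximum growth), and paired sign-test p-values.
    """
    if n_seeds < 2:
        raise ValueError("need n_seeds >= 2")
    rows = []
    for k in range(n_seeds):
        seed = config.seed + k
        normal = run(config.replace(fluidity_factor=1.0, seed=seed))
        superfluid = run(config.replace(fluidity_factor=fluidity_factor, seed=seed))
        m_n = metrics(normal)
        m_s = metrics(superfluid)
        rows.append(
            {
                "seed": seed,
                "normal_max_growth_rate": m_n.max_growth_rate,
                "superfluid_max_growth_rate": m_s.max_growth_rate,
                "normal_t_max_growth": m_n.t_max_growth,
                "superfluid_t_max_growth": m_s.t_max_growth,
            }
        )
    df = pd.DataFrame(rows)
    d_growth = df["superfluid_max_growth_rate"] - df["normal_max_growth_rate"]
    d_t = df["superfluid_t_max_growth"] - df["normal_t_max_growth"]

    def sign_test(diff, alternative):
        nonzero = diff[diff != 0]
        if len(nonzero) == 0:
            return 1.0
        k = int((nonzero > 0).sum())
        return float(binomtest(k, len(nonzero), 0.5, alternative=alternative).pvalue)

    summary = {
        "median_normal_max_growth_rate": float(df["normal_max_growth_rate"].median()),
        "median_superfluid_max_growth_rate": float(
            df["superfluid_max_growth_rate"].median()
        ),
        "median_normal_t_max_growth": float(df["normal_t_max_growth"].median()),
        "median_superfluid_t_max_growth": float(df["superfluid_t_max_growth"].median()),
        "frac_superfluid_faster_growth": float((d_growth > 0).mean()),
        "frac_superfluid_no_later_peak": float((d_t <= 0).mean()),
        "p_growth_sign_test": sign_test(d_growth, "greater"),
        "p_timing_sign_test": sign_test(-d_t, "greater"),
        "n_seeds": n_seeds,
        "fluidity_factor": fluidity_factor,
    }
    return df, summary
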