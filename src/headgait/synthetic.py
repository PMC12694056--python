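"""Synthetic paired-trial generator with analytic ground truth.

Builds reference trajectories from piecewise motion templates that mimic the
signal morphology the detectors assume:

* walking: straight horizontal path at constant speed with raised-cosine
  acceleration/deceleration ramps and a vertical head oscillation at the step
  frequency (inverted-pendulum head bounce); synthetic heel/toe channels put
  qualified minima of the heel-minus-toe signal at the true heel-strike times;
* pivot turns: raised-cosine yaw ramps while the position is stationary;
* squats: raised-cosine vertical dips (plus shallow distractor dips so the
  deep/shallow clustering is well posed);
* transfers: two-level vertical plateaus (sit/stand) joined by raised-cosine
  ramps.

The AR series is the same motion observed through a second system: per-channel
constant offsets (different coordinate origins), an optional per-participant
vertical excursion scale (headset origin/pitch effects), additive Gaussian
noise, a clock lag, and its own sampling rate.  The reference series can
contain missing samples.  Ground truth (segments in seconds + true metric
values) is recorded before any corruption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .timeseries import PoseSeries, TrialPair

PROTOCOLS = ("walk", "walk_turn", "squat", "transfer", "mixed")


@dataclass
class ProtocolSpec:
    """Study-condition parameters of one simulated trial."""

    protocol: str = "walk"
    duration: float = 60.0          # s, trial length
    walk_speed: float = 1.2         # m/s cruise speed
    step_freq: float = 2.0          # Hz (steps per second); cadence = 60*step_freq
    step_osc_amp: float = 0.02      # m, vertical head oscillation amplitude
    accel_dur: float = 0.8          # s, speed ramp at bout start/end
    walk_dist: float = 8.0          # m per straight bout
    turn_angle: float = 180.0       # deg per pivot turn
    turn_duration: float = 2.0      # s
    squat_depth: float = 0.4        # m
    squat_duration: float = 2.0     # s
    shallow_dip_depth: float = 0.06 # m, distractor dips (not squats)
    shallow_dip_duration: float = 1.5
    stand_height: float = 1.55      # m, head height standing
    sit_height: float = 1.20        # m, head height sitting
    transfer_duration: float = 1.2  # s per sit<->stand ramp
    noise_sd: float = 0.0           # m, AR additive position noise
    yaw_noise_sd: float = 0.0       # deg, AR additive yaw noise
    ar_z_scale: float = 1.0         # AR vertical excursion scale (headset origin)
    offsets: dict = field(default_factory=lambda: {
        "x": 0.30, "y": -0.20, "z": 0.04, "yaw": 15.0})
    lag_s: float = 0.4              # AR clock lag behind the reference
    ar_rate: float = 60.0           # Hz
    ref_rate: float = 50.0          # Hz
    missing_frac: float = 0.0       # fraction of reference frames dropped
    seed: int = 0

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise InputError(f"unknown protocol {self.protocol!r}")
        if self.duration <= 0 or self.ar_rate <= 0 or self.ref_rate <= 0:
            raise InputError("durations and rates must be positive")
        if not (0 <= self.missing_frac <= 0.5):
            raise InputError("missing_frac must be within [0, 0.5]")


@dataclass
class GroundTruth:
    """True segments (state, start_s, end_s) and per-trial metric values."""

    segments: list
    metrics: dict

    def segments_of(self, state: str) -> list:
        return [(s, a, b) for (s, a, b) in self.segments if s == state]


class _Motion:
    """Piecewise-analytic trial motion; evaluable on any time grid."""

    def __init__(self, spec: ProtocolSpec):
        self.spec = spec
        self.phases = []     # (t0, dur, fn(tl, entry_state) -> dict of channels)
        self.state = {"x": 0.0, "y": 0.0, "z": spec.stand_height, "yaw": 0.0}
        self.t = 0.0
        self.hs_times: list[float] = []   # true heel-strike times
        self.truth_segments: list = []
        self._step_phase = 0.0

    # -- phase builders -------------------------------------------------
    def _add(self, dur: float, fn):
        if self.t + dur > self.spec.duration + 1e-9:
            raise InputError(
                f"motion template at t={self.t:.1f}s exceeds trial duration "
                f"{self.spec.duration}s")
        self.phases.append((self.t, dur, fn, dict(self.state)))
        self.t += dur

    def stand(self, dur: float):
        def fn(tl, st):
            return {k: np.full_like(tl, st[k]) for k in st}
        self._add(dur, fn)

    def walk_bout(self, dist: float, reverse: bool = False):
        """Accelerate, cruise ``dist`` metres along the current heading,
        decelerate.  Records the true walking segment (frames with speed above
        0.5 m/s) and the heel-strike times of the cruise.  ``reverse`` walks
        against the current yaw (retracing the path without turning)."""
        sp = self.spec
        V, R, f = sp.walk_speed, sp.accel_dur, sp.step_freq
        theta = math.radians(self.state["yaw"])
        sgn = -1.0 if reverse else 1.0
        ux, uy = sgn * math.cos(theta), sgn * math.sin(theta)
        d_ramp = V * R / 2           # distance covered in one ramp
        cruise = (dist - 2 * d_ramp) / V
        if cruise <= 0:
            raise InputError("walk bout shorter than its speed ramps")
        t_start = self.t
        phase0 = self._step_phase

        def z_of(d_local, v_frac, tl):
            # head bounce at step frequency, amplitude scaled with speed
            osc = sp.step_osc_amp * 0.5 * (1 - np.cos(
                2 * np.pi * (f * tl + phase0)))
            return self.spec.stand_height - osc * v_frac

        def accel(tl, st):
            d = V * (tl - (R / np.pi) * np.sin(np.pi * tl / R)) / 2
            vfrac = (1 - np.cos(np.pi * tl / R)) / 2
            return {"x": st["x"] + ux * d, "y": st["y"] + uy * d,
                    "z": z_of(d, vfrac, tl), "yaw": np.full_like(tl, st["yaw"])}
        self._add(R, accel)
        self.state["x"] += ux * d_ramp
        self.state["y"] += uy * d_ramp

        t_c0 = self.t - t_start  # local time at cruise start (= R)

        def cruise_fn(tl, st):
            d = V * tl
            return {"x": st["x"] + ux * d, "y": st["y"] + uy * d,
                    "z": z_of(d, np.ones_like(tl), tl + t_c0),
                    "yaw": np.full_like(tl, st["yaw"])}
        self._add(cruise, cruise_fn)
        self.state["x"] += ux * V * cruise
        self.state["y"] += uy * V * cruise

        t_d0 = self.t - t_start

        def decel(tl, st):
            d = V * (tl + (R / np.pi) * np.sin(np.pi * tl / R)) / 2
            vfrac = (1 + np.cos(np.pi * tl / R)) / 2
            return {"x": st["x"] + ux * d, "y": st["y"] + uy * d,
                    "z": z_of(d, vfrac, tl + t_d0), "yaw": np.full_like(tl, st["yaw"])}
        self._add(R, decel)
        self.state["x"] += ux * d_ramp
        self.state["y"] += uy * d_ramp
        self._step_phase = (phase0 + f * (self.t - t_start)) % 1.0

        # true boundaries: instantaneous speed crossing 0.5 m/s
        tau_up = (R / np.pi) * math.acos(1 - 2 * 0.5 / V)
        tau_dn = (R / np.pi) * math.acos(2 * 0.5 / V - 1)
        self.truth_segments.append(
            ("straight_walking", t_start + tau_up, t_start + t_d0 + tau_dn))
        # heel strikes during the bout (cruise only: ramp steps are partial)
        k = 0
        while True:
            t_hs = t_start + (k - phase0) / f
            k += 1
            if t_hs < t_start + R:
                continue
            if t_hs > t_start + t_d0:
                break
            self.hs_times.append(t_hs)

    def turn(self, angle: float, dur: float):
        t_start = self.t

        def fn(tl, st):
            ramp = angle * (1 - np.cos(np.pi * tl / dur)) / 2
            return {"x": np.full_like(tl, st["x"]), "y": np.full_like(tl, st["y"]),
                    "z": np.full_like(tl, st["z"]), "yaw": st["yaw"] + ramp}
        self._add(dur, fn)
        self.state["yaw"] += angle
        self.truth_segments.append(("turning", t_start, t_start + dur))

    def dip(self, depth: float, dur: float, is_squat: bool):
        t_start = self.t

        def fn(tl, st):
            drop = depth * (1 - np.cos(2 * np.pi * tl / dur)) / 2
            return {"x": np.full_like(tl, st["x"]), "y": np.full_like(tl, st["y"]),
                    "z": st["z"] - drop, "yaw": np.full_like(tl, st["yaw"])}
        self._add(dur, fn)
        if is_squat:
            self.truth_segments.append(("squatting", t_start, t_start + dur))

    def transfer(self, up: bool):
        sp = self.spec
        dur = sp.transfer_duration
        amp = sp.stand_height - sp.sit_height
        t_start = self.t
        sgn = 1.0 if up else -1.0

        def fn(tl, st):
            ramp = sgn * amp * (1 - np.cos(np.pi * tl / dur)) / 2
            return {"x": np.full_like(tl, st["x"]), "y": np.full_like(tl, st["y"]),
                    "z": st["z"] + ramp, "yaw": np.full_like(tl, st["yaw"])}
        self._add(dur, fn)
        self.state["z"] += sgn * amp
        self.truth_segments.append(
            ("sit_to_stand" if up else "stand_to_sit", t_start, t_start + dur))

    # -- evaluation -----------------------------------------------------
    def pad_to_duration(self):
        rest = self.spec.duration - self.t
        if rest > 1e-9:
            self.stand(rest)

    def evaluate(self, t: np.ndarray) -> dict:
        t = np.asarray(t, dtype=float)
        out = {k: np.empty_like(t) for k in ("x", "y", "z", "yaw")}
        tc = np.clip(t, 0.0, self.t - 1e-12)
        for t0, dur, fn, entry in self.phases:
            idx = (tc >= t0) & (tc < t0 + dur)
            if not idx.any():
                continue
            vals = fn(tc[idx] - t0, entry)
            for k in out:
                out[k][idx] = vals[k]
        # anything at/after the final phase end holds the final state
        idx = tc >= self.phases[-1][0] + self.phases[-1][1] - 1e-12
        if idx.any():
            for k in out:
                out[k][idx] = self.state[k]
        return out

    def foot_channels(self, t: np.ndarray) -> dict:
        """Synthetic heel/toe vertical positions for the reference system.

        The heel-minus-toe signal dips to -0.01 m at each true heel strike
        (a qualified local minimum: |min| < 0.05 m) and peaks 0.12 m above it
        0.15 s later, so the MDHT detector's accepted minima fall on the true
        heel-strike times (left foot: even steps)."""
        t = np.asarray(t, dtype=float)
        chans = {k: np.zeros_like(t) for k in
                 ("heel_l_z", "toe_l_z", "heel_r_z", "toe_r_z")}
        for k, t_hs in enumerate(self.hs_times):
            key = "heel_l_z" if k % 2 == 0 else "heel_r_z"
            chans[key] += (0.12 * np.exp(-((t - (t_hs + 0.15)) ** 2) / (2 * 0.05 ** 2))
                           - 0.01 * np.exp(-((t - t_hs) ** 2) / (2 * 0.04 ** 2)))
        return chans


def _build_motion(spec: ProtocolSpec) -> _Motion:
    m = _Motion(spec)
    sp = spec
    if sp.protocol == "walk":
        m.stand(2.0)
        bout = sp.walk_dist / sp.walk_speed + 2 * sp.accel_dur
        back = False
        while m.t + bout + 2.0 < sp.duration:
            # out-and-back bouts retrace the path without turning, so yaw
            # stays constant and only the heading reverses between bouts
            m.walk_bout(sp.walk_dist, reverse=back)
            m.stand(1.5)
            back = not back
    elif sp.protocol == "walk_turn":
        m.stand(2.0)
        bout = sp.walk_dist / sp.walk_speed + 2 * sp.accel_dur
        cycle = bout + 1.0 + sp.turn_duration + 1.0
        n_turns = 0
        while m.t + cycle + 1.0 < sp.duration:
            m.walk_bout(sp.walk_dist)
            m.stand(1.0)
            m.turn(sp.turn_angle if n_turns % 2 == 0 else -sp.turn_angle,
                   sp.turn_duration)
            n_turns += 1
            m.stand(1.0)
    elif sp.protocol == "squat":
        m.stand(3.0)
        cycle = sp.squat_duration + 3.0 + sp.shallow_dip_duration + 3.0
        while m.t + cycle + 1.0 < sp.duration:
            m.dip(sp.squat_depth, sp.squat_duration, is_squat=True)
            m.stand(3.0)
            m.dip(sp.shallow_dip_depth, sp.shallow_dip_duration, is_squat=False)
            m.stand(3.0)
    elif sp.protocol == "transfer":
        m.state["z"] = sp.sit_height
        m.stand(3.0)
        cycle = 2 * sp.transfer_duration + 7.0
        while m.t + cycle + 1.0 < sp.duration:
            m.transfer(up=True)
            m.stand(3.5)
            m.transfer(up=False)
            m.stand(3.5)
    elif sp.protocol == "mixed":
        m.stand(2.0)
        m.walk_bout(sp.walk_dist)
        m.stand(1.0)
        m.turn(sp.turn_angle, sp.turn_duration)
        m.stand(1.0)
        m.walk_bout(sp.walk_dist)
        m.stand(2.0)
        m.dip(sp.squat_depth, sp.squat_duration, is_squat=True)
        m.stand(2.0)
        m.dip(sp.shallow_dip_depth, sp.shallow_dip_duration, is_squat=False)
        m.stand(2.0)
    m.pad_to_duration()
    return m


def _truth_metrics(m: _Motion, spec: ProtocolSpec) -> dict:
    sp = spec
    metrics = {}
    states = {s for (s, _, _) in m.truth_segments}
    if "straight_walking" in states:
        metrics["step_length_m"] = sp.walk_speed / sp.step_freq
        metrics["cadence_spm"] = 60.0 * sp.step_freq
        metrics["max_gait_speed_mps"] = sp.walk_speed
    if "turning" in states:
        metrics["turn_duration_s"] = sp.turn_duration
        metrics["peak_angular_velocity_dps"] = (
            sp.turn_angle * math.pi / (2 * sp.turn_duration))
    if "squatting" in states:
        metrics["squat_duration_s"] = sp.squat_duration
        metrics["squat_depth_m"] = sp.squat_depth
    if "sit_to_stand" in states:
        metrics["sit_to_stand_duration_s"] = sp.transfer_duration
        metrics["stand_to_sit_duration_s"] = sp.transfer_duration
    return metrics


def simulate_trial(spec: ProtocolSpec) -> tuple[TrialPair, GroundTruth]:
    """Simulate one paired AR/reference trial; reproducible from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    motion = _build_motion(spec)

    # reference: clean motion on its own grid (+ foot channels, missing frames)
    n_ref = int(round(spec.duration * spec.ref_rate))
    t_ref = np.arange(n_ref) / spec.ref_rate
    ref_ch = motion.evaluate(t_ref)
    mask = np.zeros(n_ref, dtype=bool)
    n_miss = int(round(spec.missing_frac * n_ref))
    if n_miss:
        interior = np.arange(2, n_ref - 2)
        drop = rng.choice(interior, size=min(n_miss, len(interior)), replace=False)
        mask[drop] = True
        for k in ref_ch:
            ref_ch[k] = ref_ch[k].copy()
            ref_ch[k][drop] = np.nan
    ref = PoseSeries(t=t_ref, rate=spec.ref_rate, source="ref",
                     missing_mask=mask, extras=motion.foot_channels(t_ref),
                     **ref_ch)

    # AR: same motion seen lag_s later, offset, scaled vertically, noisy
    n_ar = int(round(spec.duration * spec.ar_rate))
    t_ar = np.arange(n_ar) / spec.ar_rate
    ar_ch = motion.evaluate(t_ar - spec.lag_s)
    z = spec.stand_height + spec.ar_z_scale * (ar_ch["z"] - spec.stand_height)
    ar = PoseSeries(
        t=t_ar,
        x=ar_ch["x"] + spec.offsets.get("x", 0.0) + rng.normal(0, spec.noise_sd, n_ar),
        y=ar_ch["y"] + spec.offsets.get("y", 0.0) + rng.normal(0, spec.noise_sd, n_ar),
        z=z + spec.offsets.get("z", 0.0) + rng.normal(0, spec.noise_sd, n_ar),
        yaw=ar_ch["yaw"] + spec.offsets.get("yaw", 0.0)
            + rng.normal(0, spec.yaw_noise_sd, n_ar),
        rate=spec.ar_rate, source="ar",
    )
    truth = GroundTruth(segments=list(motion.truth_segments),
                        metrics=_truth_metrics(motion, spec))
    return TrialPair(ar=ar, ref=ref, game=spec.protocol), truth


# ---------------------------------------------------------------------------
# cohorts

#: Between-participant jitter SDs used by default (chosen to match the spread
#: of mobility metrics reported for mild-to-moderate PD cohorts).
DEFAULT_JITTER = {
    "walk_speed": 0.25,
    "step_freq": 0.2,
    "turn_duration": 0.2,
    "squat_depth": 0.17,
    "squat_duration": 0.5,
    "transfer_duration": 0.2,
    "stand_height": 0.06,
    "sit_height": 0.04,
}

#: Clipping bounds keeping jittered parameters within the regime the
#: detectors' fixed thresholds assume (e.g. walking must exceed 0.5 m/s).
_JITTER_BOUNDS = {
    "walk_speed": (0.8, 1.8),
    "step_freq": (1.5, 2.5),
    "turn_duration": (1.2, 3.0),
    "squat_depth": (0.2, 0.8),
    "squat_duration": (1.2, 3.5),
    "transfer_duration": (0.8, 2.0),
    "stand_height": (1.4, 1.8),
    "sit_height": (1.0, 1.35),
    "ar_z_scale": (0.5, 1.5),
}


@dataclass
class CohortTrial:
    participant: int
    spec: ProtocolSpec
    pair: TrialPair
    truth: GroundTruth


def simulate_cohort(base: ProtocolSpec, n_participants: int = 15,
                    jitter: dict | None = None, seed: int = 0,
                    ar_z_scale_sd: float = 0.0) -> list[CohortTrial]:
    """Simulate one trial per participant with between-participant jitter.

    Each participant's motion parameters are drawn around the base spec
    (truncated normal via clipping), which provides the between-row variance
    that makes ICC estimation well posed.  ``ar_z_scale_sd`` additionally
    draws a per-participant AR vertical excursion scale around 1, emulating
    headset origin/pitch differences: with between-participant depth SD
    sigma_b and induced AR depth error SD sigma_e, the population ICC(A,1)
    of squat depth is sigma_b^2 / (sigma_b^2 + sigma_e^2 / 2).
    """
    if n_participants < 2:
        raise InputError("a cohort needs at least 2 participants")
    jitter = DEFAULT_JITTER if jitter is None else jitter
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.generate_state(2 * n_participants) % (2 ** 31)
    rng = np.random.default_rng(ss.spawn(1)[0])
    out = []
    for i in range(n_participants):
        draws = {}
        for name, sd in jitter.items():
            base_val = getattr(base, name)
            val = rng.normal(base_val, sd)
            lo, hi = _JITTER_BOUNDS.get(name, (-np.inf, np.inf))
            draws[name] = float(np.clip(val, lo, hi))
        if ar_z_scale_sd > 0:
            lo, hi = _JITTER_BOUNDS["ar_z_scale"]
            draws["ar_z_scale"] = float(np.clip(rng.normal(1.0, ar_z_scale_sd),
                                                lo, hi))
        if "sit_height" in draws and "stand_height" in draws:
            draws["sit_height"] = min(draws["sit_height"],
                                      draws["stand_height"] - 0.15)
        spec = replace(base, seed=int(trial_seeds[i]), **draws)
        pair, truth = simulate_trial(spec)
        out.append(CohortTrial(participant=i, spec=spec, pair=pair, truth=truth))
    return out


def depth_icc_calibration(target_icc: float = 0.9,
                          depth_sd: float = None,
                          mean_depth: float = 0.4) -> float:
    """AR vertical-scale SD giving a population squat-depth ICC(A,1) target.

    From ICC = sigma_b^2 / (sigma_b^2 + sigma_e^2 / 2) with
    sigma_e = sigma_s * sqrt(mean_depth^2 + sigma_b^2):
    sigma_e = sigma_b * sqrt(2 (1 - ICC) / ICC).
    """
    sigma_b = DEFAULT_JITTER["squat_depth"] if depth_sd is None else depth_sd
    sigma_e = sigma_b * math.sqrt(2 * (1 - target_icc) / target_icc)
    return sigma_e / math.sqrt(mean_depth ** 2 + sigma_b ** 2)
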