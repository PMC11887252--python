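"""Synthetic trainee cohorts: noisy probe searches toward target views.

The study's raw student logs are restricted, so every stage of the pipeline
is exercised on generated data with the same structure: paired Test 1 /
Test 2 sessions for a cohort of students, each session covering the 16-view
protocol with 10 Hz multi-coordinate trajectories.

Each attempt is a mean-reverting diffusion per control coordinate,

    c <- c + gain * (c* - c) * dt + noise * sqrt(dt) * eps,

Euler-Maruyama discretized at dt = 0.1 s, starting from the previous view's
target state plus a random ``seek_detour`` offset (the novice "wandering"
phase).  ``gain`` maps onto the study's time axis (how quickly the search
converges) and ``noise`` onto its RAR axis (how erratically it moves);
``settle_hold`` scales the residual jitter once the pass threshold is first
reached.  The attempt ends as soon as the pass rule is met (precision >=
0.80 held for 3 s, evaluated with the same forward model the analysis
uses), at a drawn perforation event, or at ``timeout``.  Everything is
deterministic given the seed.

Default parameter values live in ``data/profiles.yaml``; they were
coarse-calibrated once so the default cohort reproduces the direction of
the study's findings (examination time down severalfold after training,
precision up, ante/retroflexion RAR down), not its exact numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import lfilter

from .errors import ValidationError
from .kinematics import AnatomyModel, ControlState, load_anatomy, probe_planes
from .precision_metric import (HOLD_SECONDS, PASS_THRESHOLD, TargetView,
                               load_protocol)
from .session_log import CONTROL_COORDS, SessionLog, ViewAttempt

_DT = 0.1
_EPS = 1e-9

_DATA = Path(__file__).parent / "data" / "profiles.yaml"

_DEFAULTS_CACHE: dict = {}


def _load_defaults() -> dict:
    if not _DEFAULTS_CACHE:
        with open(_DATA, "r", encoding="utf-8") as fh:
            _DEFAULTS_CACHE.update(yaml.safe_load(fh))
    return _DEFAULTS_CACHE


@dataclass(frozen=True)
class SkillProfile:
    """Behavioral parameters of one simulated trainee at one test."""

    gain: float             # 1/s, attraction toward the target state
    noise: float            # multiplier on coordinate diffusion scales
    settle_hold: float      # residual jitter fraction near the target
    timeout: float          # s, maximum attempt duration
    perforation_prob: float  # per-attempt event probability
    seek_detour: float      # initial wrong-direction excursion amplitude

    def __post_init__(self) -> None:
        if self.gain < 0 or self.noise < 0 or self.seek_detour < 0:
            raise ValidationError("profile rates must be non-negative")
        if self.timeout <= 0:
            raise ValidationError("timeout must be positive")
        if not 0 <= self.perforation_prob <= 1:
            raise ValidationError("perforation_prob must lie in [0, 1]")
        if not 0 <= self.settle_hold <= 1:
            raise ValidationError("settle_hold must lie in [0, 1]")


def default_profile(name: str) -> SkillProfile:
    """Bundled profile by name: ``novice``, ``trained`` or ``expert``."""
    doc = _load_defaults()["profiles"]
    if name not in doc:
        raise KeyError(f"unknown profile {name!r}")
    return SkillProfile(**doc[name])


@dataclass(frozen=True)
class ProfileDistribution:
    """Per-student draw: log-normal spread around a base profile."""

    base: SkillProfile
    gain_sigma: float = 0.30
    noise_sigma: float = 0.20

    def draw(self, rng: np.random.Generator) -> SkillProfile:
        return replace(self.base,
                       gain=self.base.gain * np.exp(
                           rng.normal(0.0, self.gain_sigma)),
                       noise=self.base.noise * np.exp(
                           rng.normal(0.0, self.noise_sigma)))


@dataclass
class CohortSpec:
    """Shape of a simulated study cohort."""

    n_students: int = 26
    views: list[TargetView] | None = None      # None -> bundled protocol
    profile_test1: ProfileDistribution | None = None
    profile_test2: ProfileDistribution | None = None
    improvement_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_students < 1:
            raise ValidationError("n_students must be >= 1")
        if not 0 <= self.improvement_fraction <= 1:
            raise ValidationError("improvement_fraction must lie in [0, 1]")
        defaults = _load_defaults()["cohort"]
        if self.profile_test1 is None:
            self.profile_test1 = ProfileDistribution(
                default_profile("novice"),
                gain_sigma=defaults["gain_sigma"],
                noise_sigma=defaults["noise_sigma"])
        if self.profile_test2 is None:
            self.profile_test2 = ProfileDistribution(
                default_profile("trained"),
                gain_sigma=defaults["gain_sigma"],
                noise_sigma=defaults["noise_sigma"])


# ---------------------------------------------------------------------------
# single attempt
# ---------------------------------------------------------------------------

def _ou_path(x0: float, target: float, gain: float, sigma: float,
             n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Exact discrete recursion of the Euler-Maruyama update, vectorized."""
    a = 1.0 - gain * _DT
    drive = np.empty(n_steps + 1)
    drive[0] = x0 - target
    drive[1:] = sigma * np.sqrt(_DT) * rng.standard_normal(n_steps)
    dev = lfilter([1.0], [1.0, -a], drive)
    return target + dev


def _simulate_channels(profile: SkillProfile, start: np.ndarray,
                       target: np.ndarray, scales: np.ndarray, n_steps: int,
                       rng: np.random.Generator) -> np.ndarray:
    out = np.empty((n_steps + 1, len(CONTROL_COORDS)))
    for k in range(len(CONTROL_COORDS)):
        out[:, k] = _ou_path(start[k], target[k], profile.gain,
                             profile.noise * scales[k], n_steps, rng)
    return out


def _precision_of_states(states: np.ndarray, target: TargetView,
                         anatomy: AnatomyModel) -> np.ndarray:
    from .precision_metric import _precision_values
    origins, normals, _, in_range = probe_planes(anatomy, states)
    return _precision_values(origins, normals, in_range, target)


def _first_hold_index(ok: np.ndarray, hold_samples: int) -> int | None:
    """First index k whose trailing run of True spans >= hold_samples."""
    idx = np.arange(ok.size)
    last_bad = np.maximum.accumulate(np.where(~ok, idx, -1))
    run = idx - last_bad
    hit = np.flatnonzero(run >= hold_samples)
    return int(hit[0]) if hit.size else None


def simulate_attempt(profile: SkillProfile, target: TargetView,
                     anatomy: AnatomyModel,
                     seed: int | np.random.Generator,
                     start_state: ControlState | None = None,
                     threshold: float = PASS_THRESHOLD,
                     hold: float = HOLD_SECONDS) -> ViewAttempt:
    """Simulate one view attempt; deterministic given the seed.

    The attempt ends at the first moment the pass rule is satisfied, at a
    perforation (drawn with ``perforation_prob`` or emergent when depth
    exceeds the anatomy's perforation limit), or at ``timeout``.  The
    generated log carries the precision channel.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    doc = _load_defaults()
    scales = np.array([doc["coordinate_noise_scales"][c]
                       for c in CONTROL_COORDS])
    detour = np.array([doc["detour_scales"][c] for c in CONTROL_COORDS])

    tgt = target.target_state.as_array()
    base = tgt if start_state is None else start_state.as_array()
    start = base + profile.seek_detour * detour * rng.uniform(-1, 1, 5)
    lo, hi = anatomy.depth_range
    start[0] = np.clip(start[0], lo, hi)
    start[4] = np.clip(start[4], 0.0, 180.0)

    n_steps = int(round(profile.timeout / _DT))
    states = _simulate_channels(profile, start, tgt, scales, n_steps, rng)

    # forced perforation event
    if profile.perforation_prob > 0 and rng.random() < profile.perforation_prob:
        k_evt = int(rng.integers(1, n_steps + 1))
        states[k_evt, 0] = anatomy.max_depth_perforation + 1.0
        states = states[:k_evt + 1]

    states[:, 4] = np.clip(states[:, 4], 0.0, 180.0)
    prec = _precision_of_states(states, target, anatomy)

    # settle phase: reduced jitter after first reaching the threshold
    if profile.settle_hold < 1.0:
        crossed = np.flatnonzero(prec >= threshold)
        if crossed.size and crossed[0] < len(states) - 1:
            j = int(crossed[0])
            calm = replace(profile, noise=profile.noise * profile.settle_hold)
            tail = _simulate_channels(calm, states[j], tgt, scales,
                                      len(states) - 1 - j, rng)
            states = np.vstack([states[:j], tail])
            states[:, 4] = np.clip(states[:, 4], 0.0, 180.0)
            prec = np.concatenate(
                [prec[:j], _precision_of_states(tail, target, anatomy)])

    # emergent or forced perforation truncates the attempt
    perf_idx = np.flatnonzero(states[:, 0] > anatomy.max_depth_perforation)
    perforated = perf_idx.size > 0
    if perforated:
        end = max(int(perf_idx[0]), 1)
        states, prec = states[:end + 1], prec[:end + 1]
    else:
        hold_samples = int(round(hold / _DT)) + 1
        stop = _first_hold_index(prec >= threshold - _EPS, hold_samples)
        if stop is not None:
            states, prec = states[:stop + 1], prec[:stop + 1]

    t = np.arange(len(states)) * _DT
    return ViewAttempt(view_id=target.view_id, view_name=target.view_name,
                       t=t, depth=states[:, 0], rotation=states[:, 1],
                       ante_retro=states[:, 2], left_right=states[:, 3],
                       omniplane=states[:, 4], precision=prec,
                       perforated=perforated)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: neutral probe state at the start of each test (probe just inserted)
_ENTRY_STATE = ControlState(depth=22.0, rotation=0.0, ante_retro=0.0,
                            left_right=0.0, omniplane=0.0)


def _strictly_better(p2: SkillProfile, p1: SkillProfile) -> SkillProfile:
    """Force a drawn Test 2 profile to dominate the Test 1 profile."""
    return replace(p2,
                   gain=max(p2.gain, 1.1 * p1.gain),
                   noise=min(p2.noise, 0.9 * p1.noise),
                   seek_detour=min(p2.seek_detour, p1.seek_detour),
                   perforation_prob=min(p2.perforation_prob,
                                        p1.perforation_prob))


def _simulate_session(profile: SkillProfile, student_id: str, test_id: int,
                      views: list[TargetView], anatomy: AnatomyModel,
                      rng: np.random.Generator, seed: int) -> SessionLog:
    attempts = []
    prev = _ENTRY_STATE
    for tv in views:
        attempts.append(simulate_attempt(profile, tv, anatomy, rng,
                                         start_state=prev))
        prev = tv.target_state
    return SessionLog(student_id, test_id, attempts,
                      metadata={"generator": "teemetrics-synthetic",
                                "seed": int(seed)})


def simulate_cohort(spec: CohortSpec, anatomy: AnatomyModel | None = None
                    ) -> list[tuple[SessionLog, SessionLog]]:
    """Simulate paired Test 1 / Test 2 sessions for a whole cohort.

    Each student draws a Test 1 profile from the Test 1 distribution; with
    probability ``improvement_fraction`` the Test 2 profile is drawn from
    the Test 2 distribution and forced to strictly dominate the Test 1
    draw, otherwise it is a fresh draw from the Test 1 distribution.
    Fully reproducible from ``spec.seed``.
    """
    if anatomy is None:
        anatomy = load_anatomy()
    views = spec.views if spec.views is not None else load_protocol(
        anatomy=anatomy)
    rng = np.random.default_rng(spec.seed)
    pairs = []
    for i in range(spec.n_students):
        sid = f"student_{i + 1:02d}"
        improved = rng.random() < spec.improvement_fraction
        prof1 = spec.profile_test1.draw(rng)
        if improved:
            prof2 = _strictly_better(spec.profile_test2.draw(rng), prof1)
        else:
            prof2 = spec.profile_test1.draw(rng)
        s1 = _simulate_session(prof1, sid, 1, views, anatomy, rng, spec.seed)
        s2 = _simulate_session(prof2, sid, 2, views, anatomy, rng, spec.seed)
        pairs.append((s1, s2))
    return pairs


def expert_reference(targets=None, anatomy: AnatomyModel | None = None,
                     seed: int = 0) -> SessionLog:
    """Near-noiseless high-gain reference run over all views.

    Stands in for the expert's gold-standard test (the green reference
    point in the study's figures).
    """
    if anatomy is None:
        anatomy = load_anatomy()
    if targets is None:
        targets = load_protocol(anatomy=anatomy)
    rng = np.random.default_rng(seed)
    return _simulate_session(default_profile("expert"), "expert", 1,
                             list(targets), anatomy, rng, seed)
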