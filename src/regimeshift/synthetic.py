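"""Synthetic compositional community records with a known regime history.

The generator emulates a long lacustrine diatom record: an irregularly
sampled ~7 kyr series of ~100 compositional species columns with

* a first regime of episodic fluctuation — the community switches among a
  small set of metastable configurations around a fairly even
  rank-abundance profile,
* a prolonged transitional period during which species evenness declines,
  configuration switching becomes more frequent and larger, and the
  system flickers to the other regime's profile with increasing
  probability, and
* a second, calmer regime numerically dominated by a single
  (planktic-like) species.

Community variation is driven by a few shared latent drivers (e.g. lake
depth and mixing) loading onto every species — species covary rather
than fluctuate independently.  Observations reproduce the underlying
configuration exactly (no per-species observation noise): with ~100
variables, the all-variable state-indistinguishability criterion used by
the Fisher Information method requires recurring configurations to yield
recurring observations, a property real percent-count data approximates
through sparsity and count quantization (see docs/methods.md).

Every analysis stage of the package can be exercised against the
generator's truth record without the original lake dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import CommunityTimeSeries

__all__ = ["ScenarioParams", "SyntheticTruth", "default_params", "generate_community"]

N_FACTORS = 3           # latent environmental drivers
N_SUBSTATES = 6         # metastable community configurations per regime
DWELL_BASE = 8          # steps spent in one configuration, regime-1 baseline
                        # (quasi-periodic multidecadal forcing; +0/1 jitter)
ONSET_DELAY = 0.1       # fraction of the transition before disorder builds
RAMP_EXP = 1.0          # shape of the disorder ramp in transition progress
N_PLATEAUS = 6          # metastable intermediate communities the transition
                        # passes through (short-lived quasi-stable stages)
TRANSITION_DEPTH = 0.3  # how far toward the regime-2 profile the transition
                        # drifts before the abrupt dominance onset at the shift
FLICKER_EXP = 12        # flickering is concentrated immediately before the shift
FACTOR_SIGMA = 0.5      # logit s.d. of each species' response to the drivers
PROFILE_DECAY = 0.96    # geometric rank-abundance decay of regime profiles


@dataclass
class ScenarioParams:
    """Parameters of the two-regime dominance-shift scenario.

    Ages are years BP (present = AD 1950), so ``regime1_end > shift_age``:
    the first regime ends earlier in time (larger BP) than the shift.
    ``transition_noise_factor`` is the factor by which the
    configuration-switch rate has risen when the shift age is reached
    (ramping linearly after an onset delay; the excursion amplitude ramps
    at half that factor), and ``flicker_prob`` is the per-step
    probability of a flicker excursion at the shift age (flickering is
    concentrated immediately before the shift).  ``regime2_noise``
    scales the second regime's switch rate and amplitude (< 1: a calmer
    regime).
    """

    n_species: int = 109
    n_steps: int = 800
    span: float = 7000.0
    dt_range: tuple[float, float] = (5.0, 20.0)
    regime1_end: float = 4500.0
    shift_age: float = 2000.0
    transition_noise_factor: float = 2.5
    flicker_prob: float = 0.6
    dominant_species: int = 0
    dominance_level: float = 60.0
    regime2_noise: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2 or self.n_steps < 3:
            raise ValueError("need >=2 species and >=3 steps")
        if not self.regime1_end > self.shift_age:
            raise ValueError("regime1_end must exceed shift_age (years BP)")
        if not 0.0 <= self.flicker_prob <= 1.0:
            raise ValueError("flicker_prob must lie in [0, 1]")
        if not 0.0 < self.dominance_level <= 100.0:
            raise ValueError("dominance_level must lie in (0, 100]")
        if self.transition_noise_factor < 1.0:
            raise ValueError("transition_noise_factor must be >= 1")
        if not 0.0 < self.regime2_noise <= 2.0:
            raise ValueError("regime2_noise must lie in (0, 2]")
        lo, hi = self.dt_range
        if not 0 < lo <= hi:
            raise ValueError("dt_range must satisfy 0 < min <= max")
        implied_dt = self.span / (self.n_steps - 1)
        if not 0.8 * lo <= implied_dt <= 1.2 * hi:
            raise ValueError(
                f"span/(n_steps-1) = {implied_dt:.2f} yr is inconsistent with "
                f"dt_range {self.dt_range} beyond 20%"
            )
        if not (self.span > self.regime1_end and self.shift_age > 0):
            raise ValueError("regime boundaries must lie inside the span")
        if not 0 <= self.dominant_species < self.n_species:
            raise ValueError("dominant_species index out of range")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated record."""

    true_regime_boundaries: tuple[float, float]
    true_shift_age: float
    regime_mean_profiles: dict[str, np.ndarray]
    flicker_steps: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        rec = asdict(self)
        rec["regime_mean_profiles"] = {
            k: np.asarray(v).tolist() for k, v in rec["regime_mean_profiles"].items()
        }
        Path(path).write_text(json.dumps(rec, indent=1))


def default_params(seed: int = 0) -> ScenarioParams:
    """The Foy-scale defaults: 109 species, 800 steps over ~7 kyr."""
    return ScenarioParams(seed=seed)


def _regime_profiles(params: ScenarioParams) -> tuple[np.ndarray, np.ndarray]:
    """Regime mean compositions in percent (each sums to 100)."""
    n = params.n_species
    ranks = np.arange(n, dtype=float)
    w = PROFILE_DECAY**ranks
    r1 = 100.0 * w / w.sum()

    # regime 2: one species takes dominance_level percent; the remainder is
    # spread geometrically over the other species in reversed rank order,
    # i.e. formerly rare taxa gain -- a community reorganization.
    r2 = np.empty(n)
    others = np.array([i for i in range(n) if i != params.dominant_species])
    w2 = PROFILE_DECAY ** ranks[: n - 1][::-1]
    r2[others] = (100.0 - params.dominance_level) * w2 / w2.sum()
    r2[params.dominant_species] = params.dominance_level
    return r1, r2


def _compose(base: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Percent composition from a base profile and a logit offset."""
    logit = np.log(base) + offset
    p = np.exp(logit - logit.max())
    return 100.0 * p / p.sum()


def generate_community(
    params: ScenarioParams | None = None,
    regime_profiles: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[CommunityTimeSeries, SyntheticTruth]:
    """Generate one synthetic record plus its truth.

    Sampling intervals are drawn uniformly from ``dt_range`` and rescaled
    so the record spans exactly ``params.span`` years (ages run from
    ``span`` down to 0 BP).  The community switches among
    ``N_SUBSTATES`` metastable configurations — shared-driver logit
    offsets of the regime profile, softmax-renormalized to percents so
    every row sums to 100.  Between switches the composition holds still,
    so regime windows contain recurring states.  Within the transition
    the base profile steps through ``N_PLATEAUS`` short-lived
    intermediate communities drifting partway toward the regime-2
    profile (species evenness declines), the switch rate intensifies up
    to ``transition_noise_factor`` and the excursion amplitude up to
    half that, and with a per-step probability rising to
    ``flicker_prob`` the step is a one-step excursion toward the other
    regime's profile (flickering, concentrated just before the shift).
    At ``shift_age`` the dominant species abruptly takes
    ``dominance_level`` percent and the calmer second regime begins.

    ``regime_profiles`` overrides the built-in profiles (two identical
    profiles plus ``transition_noise_factor=1``, ``flicker_prob=0`` and
    ``regime2_noise=1`` give a stationary null scenario).  Identical
    ``params`` (same seed) give bitwise-identical output.
    """
    if params is None:
        params = default_params()
    params.validate()

    ss = np.random.SeedSequence(params.seed)
    rng_age, rng_noise, rng_flick = (np.random.default_rng(s) for s in ss.spawn(3))

    lo, hi = params.dt_range
    dts = rng_age.uniform(lo, hi, params.n_steps - 1)
    dts *= params.span / dts.sum()
    ages = params.span - np.concatenate(([0.0], np.cumsum(dts)))
    ages[-1] = 0.0

    if regime_profiles is None:
        r1, r2 = _regime_profiles(params)
    else:
        r1, r2 = (np.asarray(p, dtype=float) for p in regime_profiles)
        if r1.shape != (params.n_species,) or r2.shape != (params.n_species,):
            raise ValueError("regime profiles must have length n_species")

    # transition progress u in [0, 1]: 0 at regime1_end, 1 at shift_age
    u = np.clip(
        (params.regime1_end - ages) / (params.regime1_end - params.shift_age),
        0.0,
        1.0,
    )
    in_transition = (ages < params.regime1_end) & (ages > params.shift_age)
    in_regime2 = ages <= params.shift_age

    # switch rate and amplitude schedule: the ramp multiplies the
    # configuration-switch rate (divides the dwell time) and the offset
    # amplitude.  Intensification starts only after an onset delay
    # (ONSET_DELAY of the transition) -- the compositional drift begins at
    # regime1_end but dynamic disorder builds up later -- and then rises
    # linearly to transition_noise_factor at the shift age.
    ramp = np.ones(params.n_steps)
    prog = np.clip((u - ONSET_DELAY) / (1.0 - ONSET_DELAY), 0.0, 1.0)
    ramp[in_transition] = (
        1.0 + (params.transition_noise_factor - 1.0) * prog[in_transition] ** RAMP_EXP
    )
    ramp[in_regime2] = params.regime2_noise

    # species loadings on the latent drivers and the configuration
    # coordinates shared by all phases
    L = rng_noise.standard_normal((params.n_species, N_FACTORS))
    L *= FACTOR_SIGMA / np.linalg.norm(L, axis=1, keepdims=True)
    g = rng_noise.standard_normal((N_SUBSTATES, N_FACTORS))
    offsets = g @ L.T  # (N_SUBSTATES, n_species) unit-amplitude logit offsets

    dwell_draw = DWELL_BASE + rng_noise.integers(0, 2, size=params.n_steps)
    # a switch always lands in a *different* configuration
    state_step = rng_noise.integers(1, N_SUBSTATES, size=params.n_steps)
    flick_draw = rng_flick.uniform(size=params.n_steps)
    flicker = in_transition & (flick_draw < params.flicker_prob * u**FLICKER_EXP)
    flick_g = rng_flick.standard_normal((params.n_steps, N_FACTORS))

    # during the transition the base profile moves through N_PLATEAUS
    # metastable intermediate communities (quantized interpolation stages),
    # so configurations can recur within a stage; the offset amplitude is
    # held at the stage midpoint for the same reason
    u_eff = u.copy()
    amp_eff = ramp.copy()
    stage = np.minimum((u * N_PLATEAUS).astype(int), N_PLATEAUS - 1)
    u_mid = (stage[in_transition] + 0.5) / N_PLATEAUS
    # the composition drifts only partway toward regime 2; the dominance
    # onset itself is abrupt at the shift age
    u_eff[in_transition] = TRANSITION_DEPTH * u_mid
    # the offset amplitude ramps at half the rate intensification: most of
    # the transition's disorder is carried by faster switching and
    # flickering rather than ever-larger configuration excursions
    amp_eff[in_transition] = 1.0 + 0.5 * (params.transition_noise_factor - 1.0) * np.clip(
        (u_mid - ONSET_DELAY) / (1.0 - ONSET_DELAY), 0.0, 1.0
    ) ** RAMP_EXP

    abundance = np.empty((params.n_steps, params.n_species))
    k = 0
    remaining = 0
    for t in range(params.n_steps):
        if remaining <= 0:  # configuration switch (renewal process)
            k = (k + int(state_step[t])) % N_SUBSTATES
            remaining = max(2, round(dwell_draw[t] / ramp[t]))
        remaining -= 1
        if flicker[t]:
            # one-step excursion to the other regime's profile, in a fresh
            # driver configuration -- each flicker is its own system state
            other = r2 if u_eff[t] < 0.5 else r1
            abundance[t] = _compose(other, amp_eff[t] * (L @ flick_g[t]))
        else:
            base = (1.0 - u_eff[t]) * r1 + u_eff[t] * r2
            abundance[t] = _compose(base, amp_eff[t] * offsets[k])

    cts = CommunityTimeSeries(
        ages=ages,
        species_names=[f"sp{i:03d}" for i in range(params.n_species)],
        abundance=abundance,
        meta={"source": "synthetic", "params": asdict(params), "n_steps": params.n_steps},
    )
    truth = SyntheticTruth(
        true_regime_boundaries=(params.regime1_end, params.shift_age),
        true_shift_age=params.shift_age,
        regime_mean_profiles={"regime1": r1, "regime2": r2},
        flicker_steps=np.flatnonzero(flicker).tolist(),
    )
    return cts, truth
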