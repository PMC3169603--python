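"""Generative synthetic-observer model of a visual performance field.

A synthetic observer answers a two-alternative tilt discrimination about a
target Gabor embedded in a radial array.  Accuracy is shaped by three
separable factors, all expressed in the observer's *anchoring* reference
frame:

* an angular modulation ``m(theta) = 1 - h*|sin(theta)| - v*max(sin(theta), 0)``
  producing the horizontal-vertical anisotropy (amplitude ``h``) and the
  upper-vertical penalty of the vertical-meridian asymmetry (amplitude ``v``);
* an eccentricity gain ``E(e) = (1 + e0/e2) / (1 + e/e2)`` normalized to 1 at
  the reference ring ``e0 = 6`` dva, declining hyperbolically with ``e`` in the
  manner of cortical-magnification scaling;
* a Weibull psychometric function of Michelson contrast,
  ``p = gamma + (1 - gamma - lapse) * (1 - exp(-(c*s/alpha0)**beta))``,
  where the sensitivity ``s = m(theta) * E(e)`` (times an oblique-effect
  decrement when the distractor array is tilted) scales the effective
  contrast.

The anchoring frame decides which coordinates feed ``m`` and ``E``:

* ``retinotopic`` -- relative to the current fixation, with the angular axes
  rolled along with the head;
* ``head_centric`` -- relative to the head/screen center, axes rolled with the
  head;
* ``allocentric`` -- relative to the screen center, axes fixed to gravity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    MAIN_RING_ECC_DEG,
    ORIGIN,
    FieldLocation,
    PlanarPoint,
    to_cartesian,
)

FRAMES = ("retinotopic", "head_centric", "allocentric")

#: Default truncation (dva) of the simulated gaze-deviation noise.
DEFAULT_GAZE_MAX_DEG = 0.3
#: Default scale (dva) of the half-normal gaze-deviation noise.
DEFAULT_GAZE_SCALE_DEG = 0.12


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic observer.

    ``chance`` is the guessing rate (0.5 for the two-alternative tilt task);
    ``lapse`` the asymptotic error rate; ``hva``/``vma`` the fractional
    accuracy losses at the vertical and upper-vertical meridians; ``e2`` the
    eccentricity half-saturation constant (dva); ``alpha0`` the Weibull
    contrast-threshold scale at the best location on the reference ring;
    ``beta`` the Weibull slope; ``oblique_drop`` the sensitivity decrement
    applied when the distractor array is tilted obliquely; ``frame`` the
    anchoring reference frame; ``seed`` the observer's RNG seed.
    """

    chance: float = 0.5
    lapse: float = 0.01
    hva: float = 0.2
    vma: float = 0.07
    e2: float = 8.0
    alpha0: float = 0.1
    beta: float = 3.0
    oblique_drop: float = 0.05
    frame: str = "retinotopic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.chance < 1.0:
            raise ValueError("chance must lie in (0, 1)")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        if self.hva < 0 or self.vma < 0:
            raise ValueError("hva and vma must be non-negative")
        if self.hva + self.vma >= 1.0:
            raise ValueError("hva + vma must be < 1 (sensitivity must stay positive)")
        if self.e2 <= 0:
            raise ValueError("e2 must be positive")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0.0 <= self.oblique_drop < 1.0:
            raise ValueError("oblique_drop must lie in [0, 1)")
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}")


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus presentation.

    ``target_location`` is the target's position in *screen* coordinates;
    ``contrast`` its Michelson contrast in (0, 1]; ``head_roll_deg`` and
    ``fixation_offset`` the posture of the viewing condition;
    ``distractor_tilt_deg`` the reference orientation of the distractor array
    (0 = vertical distractors).
    """

    target_location: FieldLocation
    contrast: float
    head_roll_deg: float = 0.0
    fixation_offset: PlanarPoint = ORIGIN
    distractor_tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must lie in (0, 1]")


def angular_modulation(params: ObserverParams, retinal_angle_deg) -> np.ndarray | float:
    """Angular accuracy modulation ``m(theta)`` in the anchoring frame.

    Equals 1 on the horizontal meridian, ``1 - hva`` at the lower vertical
    meridian, ``1 - hva - vma`` at the upper vertical meridian, with
    intermediate values at intercardinal angles.
    """
    th = np.deg2rad(np.asarray(retinal_angle_deg, dtype=float))
    s = np.sin(th)
    m = 1.0 - params.hva * np.abs(s) - params.vma * np.maximum(s, 0.0)
    return m if m.ndim else float(m)


def eccentricity_gain(
    params: ObserverParams, ecc_deg, reference_ecc_deg: float = MAIN_RING_ECC_DEG
) -> np.ndarray | float:
    """Sensitivity gain ``E(e)``, normalized to 1 at the reference ring."""
    e = np.asarray(ecc_deg, dtype=float)
    g = (1.0 + reference_ecc_deg / params.e2) / (1.0 + e / params.e2)
    return g if g.ndim else float(g)


def distractors_tilted(distractor_tilt_deg) -> np.ndarray | bool:
    """Whether the distractor orientation is oblique (not a cardinal axis)."""
    r = np.abs(np.asarray(distractor_tilt_deg, dtype=float)) % 90.0
    out = np.minimum(r, 90.0 - r) > 1e-9
    return out if out.ndim else bool(out)


def _frame_polar(
    frame: str,
    x,
    y,
    head_roll_deg,
    fix_x,
    fix_y,
) -> tuple[np.ndarray, np.ndarray]:
    """(eccentricity, angle) of screen targets in the anchoring frame."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if frame == "retinotopic":
        dx, dy = x - fix_x, y - fix_y
        roll = head_roll_deg
    elif frame == "head_centric":
        dx, dy = x, y
        roll = head_roll_deg
    elif frame == "allocentric":
        dx, dy = x, y
        roll = 0.0
    else:  # pragma: no cover - guarded by ObserverParams
        raise ValueError(f"unknown frame {frame!r}")
    ecc = np.hypot(dx, dy)
    angle = np.degrees(np.arctan2(dy, dx)) - roll
    return ecc, angle


def p_correct_arrays(
    params: ObserverParams,
    x,
    y,
    contrast,
    head_roll_deg=0.0,
    fix_x=0.0,
    fix_y=0.0,
    distractor_tilt_deg=0.0,
) -> np.ndarray:
    """Vectorized probability correct for screen-coordinate targets."""
    contrast = np.asarray(contrast, dtype=float)
    if np.any(contrast <= 0):
        raise ValueError("contrast must be positive")
    ecc, angle = _frame_polar(params.frame, x, y, head_roll_deg, fix_x, fix_y)
    s = angular_modulation(params, angle) * eccentricity_gain(params, ecc)
    s = s * np.where(distractors_tilted(distractor_tilt_deg), 1.0 - params.oblique_drop, 1.0)
    g, lam = params.chance, params.lapse
    p = g + (1.0 - g - lam) * (1.0 - np.exp(-((contrast * s / params.alpha0) ** params.beta)))
    return np.asarray(p, dtype=float)


def p_correct(params: ObserverParams, stim: StimulusSpec) -> float:
    """Probability of a correct response to one stimulus."""
    pt = to_cartesian(stim.target_location)
    return float(
        p_correct_arrays(
            params,
            pt.x,
            pt.y,
            stim.contrast,
            head_roll_deg=stim.head_roll_deg,
            fix_x=stim.fixation_offset.x,
            fix_y=stim.fixation_offset.y,
            distractor_tilt_deg=stim.distractor_tilt_deg,
        )
    )


def simulate_gaze_deviation(
    rng: np.random.Generator,
    size=None,
    scale_deg: float = DEFAULT_GAZE_SCALE_DEG,
    max_deg: float = DEFAULT_GAZE_MAX_DEG,
):
    """Gaze deviation (dva) from a truncated half-normal noise model."""
    dev = np.abs(rng.normal(0.0, scale_deg, size=size))
    return np.minimum(dev, max_deg)


def simulate_trial(
    params: ObserverParams,
    stim: StimulusSpec,
    rng: np.random.Generator,
    gaze_scale_deg: float = DEFAULT_GAZE_SCALE_DEG,
    gaze_max_deg: float = DEFAULT_GAZE_MAX_DEG,
) -> dict:
    """Simulate one trial; returns a flat record of factors and outcome.

    Correctness is a Bernoulli draw at :func:`p_correct`; the gaze deviation
    comes from a truncated half-normal channel so the downstream fixation
    filter has realistic input.  The generator state advances deterministically.
    """
    p = p_correct(params, stim)
    correct = bool(rng.random() < p)
    gaze = float(simulate_gaze_deviation(rng, scale_deg=gaze_scale_deg, max_deg=gaze_max_deg))
    return {
        "target_location": stim.target_location.label,
        "target_angle_deg": stim.target_location.angle_deg,
        "ring_eccentricity_deg": stim.target_location.eccentricity_deg,
        "contrast": stim.contrast,
        "head_roll_deg": stim.head_roll_deg,
        "fixation_x": stim.fixation_offset.x,
        "fixation_y": stim.fixation_offset.y,
        "distractor_tilt_deg": stim.distractor_tilt_deg,
        "p_correct": p,
        "correct": correct,
        "gaze_dev_deg": gaze,
    }


def make_observers(
    n: int = 4,
    frame: str = "retinotopic",
    seed: int = 0,
    base: ObserverParams | None = None,
    hva_sd: float = 0.03,
    vma_sd: float = 0.02,
    alpha0_log10_sd: float = 0.05,
) -> list[ObserverParams]:
    """A seeded cohort of observers with mild inter-individual variability.

    Field-shape amplitudes and the contrast-threshold scale are jittered
    around the base parameters, emulating the minor but reliable fluctuations
    of performance-field shape across real observers.
    """
    base = base if base is not None else ObserverParams(frame=frame)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(901,)))
    cohort = []
    for i in range(n):
        hva = float(np.clip(rng.normal(base.hva, hva_sd), 0.0, 0.45))
        vma = float(np.clip(rng.normal(base.vma, vma_sd), 0.0, 0.3))
        alpha0 = float(base.alpha0 * 10 ** rng.normal(0.0, alpha0_log10_sd))
        cohort.append(
            replace(base, hva=hva, vma=vma, alpha0=alpha0, frame=frame, seed=seed + 1000 + i)
        )
    return cohort
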