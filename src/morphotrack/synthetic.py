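"""Synthetic single-molecule data with known ground truth.

Every generator emulates one class of input the analysis pipeline consumes:

* :func:`generate_jumps` — jump distances from a K-component Brownian
  mixture at fixed frame time, with localization noise and a tracking-radius
  cut, the forward model of the jump-distance mixture fit.
* :func:`generate_survival` — binding-event durations from a multi-
  exponential residence-time spectrum observed through time-lapse
  illumination with per-frame photobleaching, frame discretization,
  minimum-track-length selection and acquisition-end censoring, the forward
  model of the rate-spectrum inversion.
* :func:`generate_movie` — per-frame detections of agents diffusing and
  binding inside a tissue geometry, with detection dropouts and localization
  noise, plus hidden ground-truth identities for scoring track linking.

All generators are deterministic under a fixed seed and return a ``truth``
record holding the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import SurvivalCondition, SurvivalData

__all__ = [
    "DEFAULT_LOC_NOISE_UM",
    "TIME_LAPSE_CYCLES",
    "ACQUISITION_FRAMES",
    "generate_jumps",
    "generate_survival",
    "generate_movie",
    "state_to_event_fractions",
]

#: Default localization noise per coordinate (µm); typical SMLM precision.
DEFAULT_LOC_NOISE_UM = 0.020

#: Frame cycle times (s) of the four illumination conditions.
TIME_LAPSE_CYCLES = (0.0117, 0.058, 0.199, 1.006)

#: Illuminated frames recorded per condition, keyed by cycle time.
ACQUISITION_FRAMES = {0.0117: 1000, 0.058: 200, 0.199: 59, 1.006: 24}


def state_to_event_fractions(
    state_fractions: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    """Convert state (time-occupancy) fractions to event fractions.

    Exact inverse of the event-to-state conversion: event fractions are
    proportional to ``state_fraction * rate`` (fast states produce more
    events per unit occupancy).
    """
    s = np.asarray(state_fractions, dtype=float)
    k = np.asarray(rates, dtype=float)
    if not np.isclose(s.sum(), 1.0):
        raise ValueError("state fractions must sum to 1")
    w = s * k
    return w / w.sum()


def generate_jumps(
    diffusion_coefficients: np.ndarray,
    fractions: np.ndarray,
    n_jumps: int,
    frame_time: float = 0.0117,
    tracking_radius: float = 1.66,
    loc_noise: float = DEFAULT_LOC_NOISE_UM,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Draw jump distances from a Brownian mixture with localization noise.

    Each jump picks a component with probability ``fractions[i]``, draws a 2D
    Brownian displacement for ``diffusion_coefficients[i]`` over
    ``frame_time``, perturbs both endpoints by isotropic Gaussian noise of
    s.d. ``loc_noise`` per coordinate, and is rejected if it exceeds the
    tracking radius (a linking algorithm could never have produced it).

    Returns ``(distances_um, truth)``; ``truth`` records the generating
    parameters and the per-jump component labels of the accepted jumps.
    """
    d_coeffs = np.asarray(diffusion_coefficients, dtype=float)
    fracs = np.asarray(fractions, dtype=float)
    if d_coeffs.shape != fracs.shape:
        raise ValueError("diffusion_coefficients and fractions must align")
    if not np.isclose(fracs.sum(), 1.0) or (fracs < 0).any():
        raise ValueError("fractions must lie on the simplex")
    rng = np.random.default_rng(seed)

    distances = np.empty(0)
    labels = np.empty(0, dtype=int)
    while distances.size < n_jumps:
        n_draw = int(1.2 * (n_jumps - distances.size)) + 16
        comp = rng.choice(len(fracs), size=n_draw, p=fracs)
        # per-coordinate variance: 2 D t from diffusion + 2 eps^2 from the
        # localization noise of the two endpoints
        sigma = np.sqrt(2.0 * d_coeffs[comp] * frame_time + 2.0 * loc_noise**2)
        dx = rng.normal(0.0, sigma)
        dy = rng.normal(0.0, sigma)
        r = np.hypot(dx, dy)
        keep = r <= tracking_radius
        distances = np.concatenate([distances, r[keep]])
        labels = np.concatenate([labels, comp[keep]])
    distances, labels = distances[:n_jumps], labels[:n_jumps]
    truth = {
        "D": d_coeffs,
        "A": fracs,
        "frame_time": frame_time,
        "tracking_radius": tracking_radius,
        "loc_noise": loc_noise,
        "component_labels": labels,
    }
    return distances, truth


def generate_survival(
    rates: np.ndarray,
    state_fractions: np.ndarray,
    n_events: int,
    bleach_per_frame: float = 0.1,
    cycle_times: tuple[float, ...] = TIME_LAPSE_CYCLES,
    acquisition_frames: dict[float, int] | None = None,
    min_frames: dict[float, int] | int | None = None,
    seed: int | None = None,
) -> tuple[SurvivalData, dict]:
    """Simulate binding-event durations seen through time-lapse illumination.

    ``n_events`` true binding events are split evenly across the
    ``cycle_times`` conditions.  Per event: a rate component is drawn with
    probability proportional to ``state_fraction * rate`` (the event-fraction
    conversion), a true duration is drawn from Exponential(1/rate), the
    duration is discretized to whole frame cycles, photobleaching truncates
    it with probability ``bleach_per_frame`` at each illuminated frame after
    the first, events outliving the acquisition are right-censored, and
    events observed for fewer than ``min_frames`` frames are dropped (they
    would not have been tracked).
    """
    rates = np.asarray(rates, dtype=float)
    if acquisition_frames is None:
        acquisition_frames = dict(ACQUISITION_FRAMES)
    event_fractions = state_to_event_fractions(state_fractions, rates)
    rng = np.random.default_rng(seed)
    per_cond = [n_events // len(cycle_times)] * len(cycle_times)
    per_cond[0] += n_events - sum(per_cond)

    conditions = []
    for cycle, n_cond in zip(cycle_times, per_cond):
        if isinstance(min_frames, dict):
            mf = min_frames.get(cycle, 3)
        elif min_frames is None:
            # continuous illumination uses a longer minimum track than
            # time-lapse to reject freely diffusing molecules
            mf = 5 if cycle <= 0.012 else 3
        else:
            mf = int(min_frames)
        comp = rng.choice(len(rates), size=n_cond, p=event_fractions)
        t_true = rng.exponential(1.0 / rates[comp])
        k_true = np.floor(t_true / cycle).astype(int)  # survived whole cycles
        if bleach_per_frame > 0:
            # first bleached frame index (frame 0 is always detected)
            k_bleach = rng.geometric(bleach_per_frame, size=n_cond)
        else:
            k_bleach = np.full(n_cond, np.iinfo(np.int64).max)
        k_acq = acquisition_frames.get(cycle, max(k_true.max() + 2, 10)) - 1
        k_obs = np.minimum(k_true, k_bleach - 1)
        censored = k_obs >= k_acq
        k_obs = np.minimum(k_obs, k_acq)
        observed = k_obs + 1 >= mf
        durations = k_obs[observed & ~censored] * cycle
        conditions.append(
            SurvivalCondition(
                cycle_time=cycle,
                durations=durations,
                n_censored=int((observed & censored).sum()),
                censor_time=k_acq * cycle,
                min_frames=mf,
            )
        )
    truth = {
        "rates": rates,
        "state_fractions": np.asarray(state_fractions, dtype=float),
        "event_fractions": event_fractions,
        "bleach_per_frame": bleach_per_frame,
        "cycle_times": cycle_times,
        "min_frames": min_frames,
    }
    return SurvivalData(conditions=conditions), truth


def generate_movie(
    geometry,
    config=None,
    n_frames: int = 200,
    detection_efficiency: float = 1.0,
    loc_noise: float = DEFAULT_LOC_NOISE_UM,
    receptors=None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a single-molecule movie as a per-frame detection table.

    Runs the agent-based simulator for ``n_frames`` steps inside
    ``geometry``, samples each agent position per frame with probability
    ``detection_efficiency`` (missed samples become detection gaps) and adds
    isotropic localization noise.  The returned table carries hidden
    ground-truth agent identities (column ``truth_id``) for link-accuracy
    scoring; the analysis pipeline must not use it.
    """
    from .simulator import SimConfig, run_simulation

    if config is None:
        config = SimConfig(n_steps=n_frames, tau=0.0, seed=seed)
    else:
        config = config.replace(n_steps=n_frames)
    if receptors is None:
        from .geometry import place_receptors

        receptors = place_receptors(geometry, sigma=config.sigma)
    result = run_simulation(geometry, receptors, config)
    rng = np.random.default_rng(None if seed is None else seed + 1)

    n_steps, n_agents, _ = result.positions.shape
    rows = []
    for frame in range(n_steps):
        detected = rng.random(n_agents) < detection_efficiency
        xy = result.positions[frame][detected]
        xy = xy + rng.normal(0.0, loc_noise, size=xy.shape)
        ids = np.where(detected)[0]
        for agent_id, (x, y) in zip(ids, xy):
            rows.append((frame, x, y, agent_id))
    detections = pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "truth_id"])
    truth = {
        "config": config,
        "detection_efficiency": detection_efficiency,
        "loc_noise": loc_noise,
        "n_frames": n_frames,
    }
    return detections, truth
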