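"""Synthetic data generators with known ground truth.

Every input consumed by the analysis modules can be generated here: multi-unit
extracellular voltage traces, odorant-panel response tables, dose–response
tables, and fluctuating molecular trajectories.  The generators emulate the
study conditions of the real experiments they stand in for — spontaneous OSN
firing near 6.87 Hz, 0.3-s odor pulses, doses spanning 0.01–500 ng, three
spike amplitudes per sensillum — so that every downstream stage can be tested
against a known truth without any recorded data.

Spiking is modelled as a homogeneous Poisson process per unit with a 2-ms
refractory period (inter-spike statistics of termite OSNs are not
characterized; Poisson is the conventional null assumption and is documented
as such).  Each spike is rendered as a fixed 1-ms biphasic template scaled to
the unit's amplitude, plus additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spikes import DEFAULT_REFRACTORY, SpikeTrain, VoltageTrace
from .tuning import ResponseMatrix
from .dynamicity import Trajectory
from .dose_response import log_logistic

__all__ = [
    "SsrSimConfig",
    "TrajectorySimConfig",
    "simulate_ssr_trace",
    "simulate_panel",
    "simulate_dose_response",
    "simulate_trajectory",
    "reference_tuning_profile",
]

#: Spike template width in seconds (biphasic, one positive + one negative lobe).
TEMPLATE_WIDTH = 0.001


@dataclass(frozen=True)
class SsrSimConfig:
    """Configuration of a simulated single-sensillum recording.

    ``unit_amplitudes`` are the extracellular spike amplitudes (mV) of each
    unit, in descending order; ``spontaneous_rates`` the per-unit Poisson
    rates (Hz); ``stim_gain`` multiplies each unit's rate inside the stimulus
    window (1.0 = no response).
    """

    n_units: int = 1
    unit_amplitudes: tuple[float, ...] = (1.0,)
    spontaneous_rates: tuple[float, ...] = (6.87,)
    stim_onset: float = 2.0
    stim_duration: float = 0.3
    stim_gain: tuple[float, ...] = (1.0,)
    noise_sd: float = 0.05
    sampling_rate: float = 20_000.0
    duration: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for name in ("unit_amplitudes", "spontaneous_rates", "stim_gain"):
            if len(getattr(self, name)) != self.n_units:
                raise ValueError(f"{name} must have n_units={self.n_units} entries")
        amps = self.unit_amplitudes
        if any(a <= 0 for a in amps):
            raise ValueError("amplitudes must be strictly positive")
        if self.n_units > 1 and len(set(amps)) != self.n_units:
            raise ValueError("unit amplitudes must be pairwise distinct")
        if any(r < 0 for r in self.spontaneous_rates):
            raise ValueError("rates must be >= 0")
        if not (0 < self.stim_onset + self.stim_duration <= self.duration):
            raise ValueError("stimulus window must fit inside the recording")
        if self.noise_sd < 0 or self.sampling_rate <= 0:
            raise ValueError("noise_sd >= 0 and sampling_rate > 0 required")


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Configuration of a simulated fluctuation trajectory.

    Atoms vibrate isotropically (Gaussian, per-atom sigma in Angstrom) around
    fixed mean positions; atoms listed in ``loop_atom_indices`` use the larger
    ``loop_sigma``, emulating a mobile loop.  Each frame is additionally
    rotated/translated by a small random rigid motion which the superposition
    stage must remove.
    """

    n_atoms: int = 200
    n_frames: int = 500
    base_sigma: float = 0.5
    loop_atom_indices: tuple[int, ...] = ()
    loop_sigma: float = 1.0
    rigid_rotation_jitter: float = 0.02
    rigid_translation_jitter: float = 0.5
    atoms_per_residue: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1 or self.n_frames < 1:
            raise ValueError("n_atoms and n_frames must be >= 1")
        if not (self.loop_sigma >= self.base_sigma > 0):
            raise ValueError("require loop_sigma >= base_sigma > 0")
        if any(not (0 <= i < self.n_atoms) for i in self.loop_atom_indices):
            raise ValueError("loop indices out of range")
        if self.rigid_rotation_jitter < 0 or self.rigid_translation_jitter < 0:
            raise ValueError("jitter magnitudes must be >= 0")


# --------------------------------------------------------------------------
# SSR trace
# --------------------------------------------------------------------------

def _poisson_spikes(rng: np.random.Generator, rate: float, start: float,
                    stop: float) -> np.ndarray:
    """Homogeneous Poisson event times in [start, stop)."""
    if rate <= 0 or stop <= start:
        return np.array([])
    n = rng.poisson(rate * (stop - start))
    return np.sort(rng.uniform(start, stop, size=n))


def _biphasic_template(sampling_rate: float) -> np.ndarray:
    """1-ms biphasic waveform with unit positive peak and unit trough."""
    n = max(4, int(round(TEMPLATE_WIDTH * sampling_rate)))
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    return np.sin(2 * np.pi * t)


def simulate_ssr_trace(cfg: SsrSimConfig) -> tuple[VoltageTrace, SpikeTrain]:
    """Simulate a multi-unit extracellular trace with ground truth.

    Returns the rendered :class:`VoltageTrace` and the ground-truth
    :class:`SpikeTrain` (times, true unit amplitudes, unit labels ``a,b,c...``
    in the order of ``cfg.unit_amplitudes``).  Identical seeds give identical
    output.  Overlapping templates from different units simply sum (realistic
    collisions); ground truth always records every generated spike.
    """
    rng = np.random.default_rng(cfg.seed)
    stim_start = cfg.stim_onset
    stim_stop = cfg.stim_onset + cfg.stim_duration

    all_times: list[np.ndarray] = []
    all_amps: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for u in range(cfg.n_units):
        rate = cfg.spontaneous_rates[u]
        gain = cfg.stim_gain[u]
        times = np.concatenate([
            _poisson_spikes(rng, rate, 0.0, stim_start),
            _poisson_spikes(rng, rate * gain, stim_start, stim_stop),
            _poisson_spikes(rng, rate, stim_stop, cfg.duration),
        ])
        times.sort()
        # per-unit refractory period
        kept = []
        for t in times:
            if not kept or t - kept[-1] >= DEFAULT_REFRACTORY:
                kept.append(t)
        times = np.asarray(kept)
        all_times.append(times)
        all_amps.append(np.full(len(times), cfg.unit_amplitudes[u]))
        all_labels.append(np.full(len(times), chr(ord("a") + u), dtype=object))

    times = np.concatenate(all_times)
    order = np.argsort(times, kind="stable")
    truth = SpikeTrain(times[order],
                       np.concatenate(all_amps)[order],
                       np.concatenate(all_labels)[order])

    n_samples = int(round(cfg.duration * cfg.sampling_rate))
    samples = np.zeros(n_samples)
    template = _biphasic_template(cfg.sampling_rate)
    for t, a in zip(truth.times, truth.amplitudes):
        i0 = int(round(t * cfg.sampling_rate))
        i1 = min(i0 + len(template), n_samples)
        samples[i0:i1] += a * template[: i1 - i0]
    if cfg.noise_sd > 0:
        samples += rng.normal(0.0, cfg.noise_sd, size=n_samples)

    trace = VoltageTrace(samples, cfg.sampling_rate, cfg.stim_onset,
                         cfg.stim_duration)
    return trace, truth


# --------------------------------------------------------------------------
# Odorant panel
# --------------------------------------------------------------------------

def heteroscedastic_sd(mean: float, floor: float = 1.9,
                       slope: float = 0.15) -> float:
    """Replicate SD as a function of mean response magnitude.

    SSR replicate scatter grows with response size: weak or silent odorants
    vary by only a couple of spikes (about +/-1.9 delta spikes/s), while
    strong agonist responses vary by roughly 15% of their magnitude.
    """
    return max(floor, slope * abs(mean))


def simulate_panel(tuning_profile: dict[str, float],
                   replicate_sd: float | dict[str, float] | None = 5.0,
                   n_replicates: int = 5, solvent: str = "hexane",
                   solvent_mean: float = 0.0, dose_ng: float = 1000.0,
                   seed: int = 0) -> ResponseMatrix:
    """Simulate an odorant x replicate response table (delta spikes/s).

    Gaussian replicate noise around the stated odorant means; ``replicate_sd``
    is a scalar, a per-odorant mapping, or ``None`` for the heteroscedastic
    default :func:`heteroscedastic_sd`.  A solvent column (default hexane,
    mean ``solvent_mean``) is always included so the solvent-correction stage
    can be exercised.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    profile = dict(tuning_profile)
    if solvent not in profile:
        profile[solvent] = solvent_mean
    for odorant, mean in profile.items():
        if replicate_sd is None:
            sd = heteroscedastic_sd(mean)
        elif isinstance(replicate_sd, dict):
            sd = replicate_sd[odorant]
        else:
            sd = float(replicate_sd)
        draws = mean + rng.normal(0.0, sd, size=n_replicates)
        for rep, value in enumerate(draws, start=1):
            rows.append((odorant, rep, float(value)))
    df = pd.DataFrame(rows, columns=["odorant", "replicate",
                                     "delta_spikes_per_s"])
    return ResponseMatrix(df, solvent=solvent, dose_ng=dose_ng)


def reference_tuning_profile(kind: str = "fly") -> dict[str, float]:
    """Synthetic stand-in tuning profile emulating a narrowly tuned receptor.

    This is a *synthetic* reference dataset, not recorded data.  It encodes
    the published summary behavior of the neocembrene receptor: in the fly
    (heterologous expression, 67-compound panel) a ~56 delta spikes/s
    neocembrene response, a ~25 geranylgeraniol response, a −6.8 inhibitory
    linalool response, and all remaining compounds below 7; in the termite
    sensillum (11-compound panel) ~65 and ~29 for the two agonists with the
    rest below 10.  The weak-response background, which is not published per
    compound, is a fixed exponential profile (scale 1.5 or 2.0 delta
    spikes/s) clipped at the published maximum — drawn once from an internal
    constant seed so the profile is part of the package's definition, not a
    per-run random quantity.
    """
    rng = np.random.default_rng(814)  # fixed: the profile is a constant
    if kind == "fly":
        profile = {"neocembrene": 56.0, "geranylgeraniol": 25.0,
                   "linalool": -6.8}
        n_rest, scale, cap = 64, 1.5, 7.0
    elif kind == "termite":
        profile = {"neocembrene": 65.0, "geranylgeraniol": 29.0}
        n_rest, scale, cap = 9, 2.0, 10.0
    else:
        raise ValueError("kind must be 'fly' or 'termite'")
    weak = np.minimum(rng.exponential(scale, size=n_rest), cap)
    for i, value in enumerate(weak, start=1):
        profile[f"compound_{i:02d}"] = round(float(value), 2)
    return profile


# --------------------------------------------------------------------------
# Dose-response
# --------------------------------------------------------------------------

def simulate_dose_response(ed50: float, top: float = 90.0, bottom: float = 0.0,
                           doses: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0,
                                                       100.0, 500.0),
                           noise_sd: float = 5.0, n_replicates: int = 9,
                           seed: int = 0) -> pd.DataFrame:
    """Simulate a tidy dose-response table (dose_ng, replicate, response).

    Responses are drawn from the three-parameter log-logistic curve (Hill
    slope 1) with additive Gaussian noise.  Default doses follow the standard
    0.01–500 ng series used on filter paper.
    """
    if ed50 <= 0:
        raise ValueError("ed50 must be > 0")
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        mean = log_logistic(dose, bottom, top, np.log10(ed50))
        draws = mean + rng.normal(0.0, noise_sd, size=n_replicates)
        for rep, value in enumerate(draws, start=1):
            rows.append((float(dose), rep, float(value)))
    return pd.DataFrame(rows, columns=["dose_ng", "replicate", "response"])


# --------------------------------------------------------------------------
# Trajectory
# --------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator, magnitude: float) -> np.ndarray:
    """Small random rotation matrix with rotation angle ~ |N(0, magnitude)|."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, magnitude)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def simulate_trajectory(cfg: TrajectorySimConfig
                        ) -> tuple[Trajectory, np.ndarray]:
    """Simulate a fluctuation trajectory and return it with the true sigmas.

    Mean atom positions form a loose 3-D random coil (steps of ~3.8 Angstrom,
    the C-alpha virtual bond length) so that frames are non-degenerate.  Each
    frame is the mean structure plus isotropic Gaussian displacement (per-atom
    sigma), then rigidly rotated and translated by small random amounts.
    Residue ids group consecutive atoms in blocks of ``cfg.atoms_per_residue``.
    """
    rng = np.random.default_rng(cfg.seed)
    # self-avoiding-ish random walk for mean positions
    steps = rng.normal(size=(cfg.n_atoms, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    mean_pos = np.cumsum(3.8 * steps, axis=0)
    mean_pos -= mean_pos.mean(axis=0)

    sigma = np.full(cfg.n_atoms, cfg.base_sigma)
    if cfg.loop_atom_indices:
        sigma[list(cfg.loop_atom_indices)] = cfg.loop_sigma

    coords = np.empty((cfg.n_frames, cfg.n_atoms, 3))
    for f in range(cfg.n_frames):
        frame = mean_pos + rng.normal(size=(cfg.n_atoms, 3)) * sigma[:, None]
        if cfg.rigid_rotation_jitter > 0:
            frame = frame @ _random_rotation(rng, cfg.rigid_rotation_jitter).T
        if cfg.rigid_translation_jitter > 0:
            frame = frame + rng.normal(0.0, cfg.rigid_translation_jitter,
                                       size=3)
        coords[f] = frame

    residue_ids = np.arange(cfg.n_atoms) // cfg.atoms_per_residue + 1
    traj = Trajectory(coords, residue_ids=residue_ids)
    return traj, sigma
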