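"""Synthetic dipole-based 12-lead ECG generator.

The heart's net electrical activity is modelled as a 3-D dipole whose
trajectory over each beat is a sum of Gaussian bumps in beat phase (one bump
per wave: P, Q, R, S, T per axis), in the spirit of the classic ECGSYN
morphology model.  Every recorded lead is then a plane projection of that
dipole — limb leads project (X, Y) in the frontal plane, precordial leads
project (X, Z) in the transverse plane — plus per-lead white measurement
noise and a per-record angular perturbation of each electrode direction.

Because the generator is a pure dipole, noise-free jitter-free output is
exactly rank 3 across the 12 leads and satisfies the Einthoven and
Goldberger identities; every statistical property the redundancy metrics
respond to (rank, inter-lead angles, noise floor) is controllable ground
truth.  Records mimic the PTB-XL shape: 10 s, 500 Hz, 12 leads in mV, one of
five class labels.  The five class morphologies exist to exercise label
plumbing and class-weight computation, not as clinically validated
pathology waveforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ContractError
from .records_io import CLASS_LABELS, MultichannelRecord, RecordCollection
from .selection import LIMB_LEADS, PRECORDIAL_LEADS, STANDARD_12_LEADS, STANDARD_GEOMETRY

#: (center phase rad, width rad, amplitude mV) Gaussian bumps per VCG axis.
#: Phase 0 is the R peak; one beat spans 2*pi.  Amplitudes give a dipole
#: dominated by the QRS loop with a normal frontal electrical axis near
#: +60 deg (lead II carries the tallest R wave, ~1.5 mV) and physiologic
#: P/T proportions.
DEFAULT_WAVES: Mapping[str, tuple[tuple[float, float, float], ...]] = {
    "X": (
        (-1.10, 0.22, 0.06),  # P
        (-0.25, 0.08, -0.10),  # Q
        (0.00, 0.10, 0.80),  # R
        (0.25, 0.08, -0.20),  # S
        (1.60, 0.45, 0.30),  # T
    ),
    "Y": (
        (-1.10, 0.22, 0.10),
        (-0.27, 0.08, -0.08),
        (0.00, 0.10, 1.30),
        (0.28, 0.08, -0.25),
        (1.60, 0.45, 0.35),
    ),
    "Z": (
        (-1.05, 0.22, 0.03),
        (0.03, 0.10, 0.35),
        (0.30, 0.09, -0.10),
        (1.65, 0.45, 0.12),
    ),
}

#: Per-class morphology perturbations (frontal rotation deg, amplitude scale,
#: wave-width scale) applied on top of the base parameters.  Caricatures of
#: axis shift / voltage loss (MI), repolarization widening (STTC), QRS
#: widening (CD) and voltage gain (HYP) — enough to make classes separable
#: and labels meaningful, with no claim of clinical fidelity.
CLASS_PERTURBATIONS: Mapping[str, tuple[float, float, float]] = {
    "NORM": (0.0, 1.0, 1.0),
    "MI": (-15.0, 0.80, 1.10),
    "STTC": (5.0, 1.00, 1.40),
    "CD": (10.0, 1.10, 1.60),
    "HYP": (-20.0, 1.50, 1.00),
}


@dataclass(frozen=True)
class DipoleParams:
    """Ground-truth knobs of the synthetic dipole and its measurement."""

    rate_hz: float = 500.0
    duration_s: float = 10.0
    heart_rate_bpm: float = 70.0
    rr_jitter_frac: float = 0.05
    wave_components: Mapping[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: DEFAULT_WAVES
    )
    noise_sd_mv: float = 0.02
    electrode_jitter_deg: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ContractError("rate_hz and duration_s must be positive")
        n = self.rate_hz * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ContractError(
                f"rate_hz * duration_s = {n} must be an integer sample count"
            )
        if self.heart_rate_bpm <= 0:
            raise ContractError("heart_rate_bpm must be positive")
        if self.rr_jitter_frac < 0 or self.noise_sd_mv < 0 or self.electrode_jitter_deg < 0:
            raise ContractError("jitter and noise magnitudes must be >= 0")
        for axis, bumps in self.wave_components.items():
            if axis not in ("X", "Y", "Z"):
                raise ContractError(f"wave axis must be X/Y/Z, got {axis!r}")
            for c, b, a in bumps:
                if not (math.isfinite(c) and math.isfinite(a)):
                    raise ContractError("bump centers and amplitudes must be finite")
                if not b > 0:
                    raise ContractError(f"bump width must be > 0, got {b}")

    @property
    def n_samples(self) -> int:
        return round(self.rate_hz * self.duration_s)


def _scaled_waves(
    waves: Mapping[str, tuple[tuple[float, float, float], ...]],
    amp_scale: float,
    width_scale: float,
) -> dict:
    return {
        axis: tuple((c, b * width_scale, a * amp_scale) for c, b, a in bumps)
        for axis, bumps in waves.items()
    }


def simulate_vcg(params: DipoleParams) -> MultichannelRecord:
    """Simulate the 3-channel dipole trajectory (X, Y, Z), noise-free.

    Beats are placed at RR intervals of 60/heart_rate_bpm seconds, each
    multiplied by ``1 + rr_jitter_frac * eps`` with standard-normal eps.
    Within a beat, each axis is the sum of its Gaussian bumps in phase
    ``phi = 2*pi*(t - t_beat)/rr``, evaluated over phi in [-pi, pi].
    Measurement noise belongs to the leads, not the dipole, and is added in
    :func:`simulate_12lead`.
    """
    rng = np.random.default_rng([params.seed, 0])
    n = params.n_samples
    t = np.arange(n) / params.rate_hz
    rr_mean = 60.0 / params.heart_rate_bpm
    data = np.zeros((n, 3))

    beat_center = 0.5 * rr_mean
    while beat_center - 0.75 * rr_mean < params.duration_s:
        rr = rr_mean * max(0.2, 1.0 + params.rr_jitter_frac * rng.standard_normal())
        lo = np.searchsorted(t, beat_center - 0.5 * rr)
        hi = np.searchsorted(t, beat_center + 0.5 * rr)
        phi = 2.0 * math.pi * (t[lo:hi] - beat_center) / rr
        for k, axis in enumerate(("X", "Y", "Z")):
            for c, b, a in params.wave_components.get(axis, ()):
                data[lo:hi, k] += a * np.exp(-0.5 * ((phi - c) / b) ** 2)
        beat_center += rr
    return MultichannelRecord(("X", "Y", "Z"), data, params.rate_hz)


def project_plane(
    vcg: MultichannelRecord,
    angle_deg: float,
    plane: str = "frontal",
) -> np.ndarray:
    """Project the dipole onto one in-plane direction (1-D signal).

    Frontal plane spans (X, Y); transverse plane spans (X, Z).  The
    projection at angle theta is ``u cos(theta) + v sin(theta)`` for the
    plane's axis pair (u, v).
    """
    theta = math.radians(angle_deg)
    x = vcg.channel("X")
    if plane == "frontal":
        v = vcg.channel("Y")
    elif plane == "transverse":
        v = vcg.channel("Z")
    else:
        raise ContractError(f"plane must be 'frontal' or 'transverse', got {plane!r}")
    return x * math.cos(theta) + v * math.sin(theta)


def frontal_principal_angle(vcg: MultichannelRecord) -> float:
    """Angle (deg, in (-90, 90]) of the dipole's direction of maximum
    variability in the frontal plane — the axis along which a projection
    captures the most signal, and relative to which the NMI-vs-angle decay
    is cleanest."""
    xy = np.column_stack([vcg.channel("X"), vcg.channel("Y")])
    cov = np.cov(xy.T)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]
    ang = math.degrees(math.atan2(v[1], v[0]))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return ang


def simulate_12lead(params: DipoleParams, label: str | None = None) -> MultichannelRecord:
    """Simulate a standard 12-lead record from the dipole.

    Each lead's nominal projection angle (geometry table) is perturbed once
    per record by a seeded N(0, electrode_jitter_deg) draw — electrode
    placement varies between recordings but not within one — and per-lead
    white noise of ``noise_sd_mv`` is added.
    """
    vcg = simulate_vcg(params)
    rng = np.random.default_rng([params.seed, 1])
    jitter = rng.normal(0.0, params.electrode_jitter_deg, size=len(STANDARD_12_LEADS))
    cols = []
    for k, lead in enumerate(STANDARD_12_LEADS):
        geo = STANDARD_GEOMETRY[lead]
        sig = project_plane(vcg, geo.angle_deg + jitter[k], plane=geo.plane)
        cols.append(sig)
    data = np.column_stack(cols)
    if params.noise_sd_mv > 0:
        data = data + rng.normal(0.0, params.noise_sd_mv, size=data.shape)
    return MultichannelRecord(STANDARD_12_LEADS, data, params.rate_hz, label=label)


def simulate_corpus(
    n_records: int,
    class_mix: Mapping[str, float],
    params: DipoleParams | None = None,
) -> RecordCollection:
    """Simulate a labelled corpus with per-class morphology perturbations.

    ``class_mix`` maps labels to fractions summing to 1; labels are drawn
    i.i.d. from it.  Per class, the base dipole is rotated in the frontal
    plane, amplitude-scaled and wave-width-scaled per
    :data:`CLASS_PERTURBATIONS`.  Fully reproducible from ``params.seed``.
    """
    params = params or DipoleParams()
    if n_records <= 0:
        raise ContractError(f"n_records must be >= 1, got {n_records}")
    labels = list(class_mix)
    fracs = np.array([class_mix[c] for c in labels], dtype=float)
    unknown = [c for c in labels if c not in CLASS_LABELS]
    if unknown:
        raise ContractError(f"unknown class label(s) {unknown}; expected {CLASS_LABELS}")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ContractError(f"class_mix fractions sum to {fracs.sum()}, not 1")

    rng = np.random.default_rng([params.seed, 2])
    drawn = rng.choice(len(labels), size=n_records, p=fracs)
    records = []
    for rec_idx, lab_idx in enumerate(drawn):
        label = labels[lab_idx]
        rot_deg, amp, width = CLASS_PERTURBATIONS[label]
        rec_params = replace(
            params,
            wave_components=_scaled_waves(params.wave_components, amp, width),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec = simulate_12lead(rec_params, label=label)
        if rot_deg:
            rec = _rotate_frontal(rec, rec_params, rot_deg, label)
        records.append(rec)
    return RecordCollection(tuple(records))


def _rotate_frontal(
    record: MultichannelRecord, params: DipoleParams, rot_deg: float, label: str | None
) -> MultichannelRecord:
    """Re-project the limb leads after rotating the dipole in the frontal plane."""
    vcg = simulate_vcg(params)
    theta = math.radians(rot_deg)
    x, y = vcg.channel("X"), vcg.channel("Y")
    rot = MultichannelRecord(
        ("X", "Y", "Z"),
        np.column_stack(
            [
                x * math.cos(theta) - y * math.sin(theta),
                x * math.sin(theta) + y * math.cos(theta),
                vcg.channel("Z"),
            ]
        ),
        params.rate_hz,
    )
    rng = np.random.default_rng([params.seed, 1])
    jitter = rng.normal(0.0, params.electrode_jitter_deg, size=len(STANDARD_12_LEADS))
    cols = []
    for k, lead in enumerate(STANDARD_12_LEADS):
        geo = STANDARD_GEOMETRY[lead]
        src = rot if lead in LIMB_LEADS else vcg if lead in PRECORDIAL_LEADS else rot
        cols.append(project_plane(src, geo.angle_deg + jitter[k], plane=geo.plane))
    data = np.column_stack(cols)
    if params.noise_sd_mv > 0:
        data = data + rng.normal(0.0, params.noise_sd_mv, size=data.shape)
    return MultichannelRecord(STANDARD_12_LEADS, data, params.rate_hz, label=label)
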