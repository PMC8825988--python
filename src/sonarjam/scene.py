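"""Scene configuration for synthetic group-flight recordings.

A :class:`SimulationScene` bundles everything needed to generate a
reproducible group-flight recording session: the flight-chamber geometry,
the number of bats and their individual vocal profiles, timing resolutions
(video frame rate, audio sample rate), the speed of sound and the RNG seed.

Chamber presets mirror the experimental spaces used in telemetry studies of
Japanese horseshoe bats: a full chamber of 9 x 4.5 x 2.4 m that can be
partitioned into a "wide" (6 x 4.5 x 2.4 m) or "narrow" (2 x 4.5 x 2.4 m)
flight space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

__all__ = [
    "VocalProfile",
    "SimulationScene",
    "CHAMBER_PRESETS",
    "make_scene",
]

#: Chamber dimensions (x, y, z) in metres for the named flight spaces.
CHAMBER_PRESETS: Dict[str, Tuple[float, float, float]] = {
    "full": (9.0, 4.5, 2.4),
    "wide": (6.0, 4.5, 2.4),
    "narrow": (2.0, 4.5, 2.4),
}

#: Default mean flight speed (m/s) per preset; group-flight telemetry work
#: reports slower flight in the narrow space than in the wide one.
PRESET_SPEED_BANDS: Dict[str, Tuple[float, float]] = {
    "full": (2.3, 3.1),
    "wide": (2.3, 3.1),
    "narrow": (1.8, 2.6),
}


@dataclass
class VocalProfile:
    """Per-bat vocal parameters for CF-FM pulse emission.

    The emitted call is a long constant-frequency (CF) plateau whose second
    harmonic (CF2, ~68-70 kHz in horseshoe bats) dominates, preceded by an
    optional weak initial upward FM sweep (iFM) and terminated by a brief
    downward FM sweep (tFM).  During flight the bat lowers its emitted CF2
    so that wall echoes return at its individual *reference frequency*
    (Doppler shift compensation); ``compensation_gain`` interpolates between
    no compensation (0) and full compensation (1).

    Durations are in milliseconds, frequencies and bandwidths in Hz.
    ``pulses_per_group`` maps group size to probability; intervals are
    (mean, sd) of truncated normal draws.  ``inter_group_interval`` is the
    silent time between sonar sound groups (end of one group's last pulse to
    the start of the next group).
    """

    reference_frequency: float = 68_500.0
    pulse_duration: Tuple[float, float] = (23.0, 2.0)
    tfm_duration: Tuple[float, float] = (1.8, 0.2)
    tfm_bandwidth: Tuple[float, float] = (14_000.0, 1_200.0)
    ifm_bandwidth: Tuple[float, float] = (8_000.0, 1_000.0)
    ifm_duration: Tuple[float, float] = (1.5, 0.2)
    ifm_present: float = 0.5
    pulses_per_group: Dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.3}
    )
    inter_group_interval: Tuple[float, float] = (52.0, 5.0)
    intra_group_interval: Tuple[float, float] = (10.0, 2.0)
    source_level_rolloff: float = -20.0
    compensation_gain: float = 1.0

    def validate(self) -> None:
        for name in ("pulse_duration", "tfm_duration", "tfm_bandwidth",
                     "ifm_bandwidth", "ifm_duration",
                     "inter_group_interval", "intra_group_interval"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} must have mean > 0 and sd >= 0")
        if self.reference_frequency <= 0:
            raise ValueError("reference_frequency must be > 0")
        if not 0.0 <= self.compensation_gain <= 1.0:
            raise ValueError("compensation_gain must lie in [0, 1]")
        if not 0.0 <= self.ifm_present <= 1.0:
            raise ValueError("ifm_present must be a probability")
        total = sum(self.pulses_per_group.values())
        if total <= 0 or any(k < 1 for k in self.pulses_per_group):
            raise ValueError("pulses_per_group must map counts >= 1 to "
                             "positive weights")


@dataclass
class SimulationScene:
    """Full specification of a synthetic group-flight scene.

    ``speed_band`` gives the (min, max) mean flight speed in m/s from which
    per-bat speeds are drawn; a degenerate band pins every bat to the same
    constant speed.  ``wall_loss_db`` is the flat level drop applied at each
    wall reflection (``inf`` disables echoes entirely).
    ``conspecific_gain`` scales the level of other bats' pulses on each
    channel relative to 1/r spherical spreading.
    """

    chamber_dims: Tuple[float, float, float] = CHAMBER_PRESETS["full"]
    n_bats: int = 3
    duration: float = 20.0
    frame_rate: float = 30.0
    sample_rate: float = 500_000.0
    sound_speed: float = 343.5
    seed: int = 0
    speed_band: Tuple[float, float] = PRESET_SPEED_BANDS["full"]
    wall_margin: float = 0.35
    min_turn_radius: float = 0.25
    wall_loss_db: float = -6.0
    conspecific_gain: float = 1.0
    harmonic_levels_db: Tuple[float, ...] = (-20.0, 0.0)
    noise_rms: float = 0.0
    profiles: Tuple[VocalProfile, ...] = ()

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.chamber_dims):
            raise ValueError("chamber_dims must be positive")
        if self.n_bats < 1:
            raise ValueError("n_bats must be >= 1")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be > 0")
        # CF2 ~70 kHz: the highest synthesized harmonic must stay below
        # Nyquist.  With the default two harmonics (CF1, CF2) this demands
        # fs > 2 * CF2.
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.speed_band[0] > self.speed_band[1] or self.speed_band[0] <= 0:
            raise ValueError("speed_band must satisfy 0 < lo <= hi")
        if not self.profiles:
            self.profiles = tuple(
                default_profiles(self.n_bats, self.seed)
            )
        if len(self.profiles) != self.n_bats:
            raise ValueError("need one VocalProfile per bat")
        for p in self.profiles:
            p.validate()
            n_harm = len(self.harmonic_levels_db)
            if self.sample_rate <= 2 * (p.reference_frequency / 2) * n_harm:
                raise ValueError(
                    "sample_rate must exceed twice the highest harmonic")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def to_dict(self) -> dict:
        return asdict(self)


def default_profiles(n_bats: int, seed: int) -> list:
    """Draw per-bat vocal profiles with reference frequencies spread over a
    colony-typical band.

    Individual reference frequencies of horseshoe bats in one colony differ
    by up to ~1.2 kHz; we draw them uniformly over 68.2-69.4 kHz.
    """
    import numpy as np

    rng = np.random.default_rng(_subseed(seed, 0xB0CA))
    rfs = rng.uniform(68_200.0, 69_400.0, size=n_bats)
    return [VocalProfile(reference_frequency=float(rf)) for rf in rfs]


def make_scene(preset: str = "full", **kwargs) -> SimulationScene:
    """Build a scene from a chamber preset name plus overrides."""
    if preset not in CHAMBER_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(CHAMBER_PRESETS)}")
    kwargs.setdefault("chamber_dims", CHAMBER_PRESETS[preset])
    kwargs.setdefault("speed_band", PRESET_SPEED_BANDS[preset])
    return SimulationScene(**kwargs)


def _subseed(seed: int, salt: int) -> int:
    """Derive an independent 31-bit stream seed from the scene seed."""
    return (int(seed) * 0x9E3779B1 + int(salt)) % (2**31 - 1)
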