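"""Stochastic generator of node-centred transport data with ground truth.

The generator emulates the structure of intravital time-lapse tracking
data around a node of Ranvier: organelles move along the axon with
region-dependent speeds (proximal internode / nodal constriction / distal
internode), pause stochastically with region-dependent probability, and
are localised with small isotropic Gaussian noise. Mitochondria are
bidirectional with a configurable anterograde fraction and carry lengths;
stationary organelles cluster distal to the node. Companion generators
produce fluorescence line profiles with a distal accumulation bump and
diameter profiles with a raised-cosine nodal constriction.

Named presets encode the study conditions the analysis modules are
validated against; every dataset carries its ground truth so that the
full pipeline can be checked by parameter recovery. The same seed
reproduces a dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import ndtr, ndtri

from .exceptions import ConfigError
from .intensity_profile import LineProfile
from .morphometry import DiameterProfile
from .track_io import AxonGeometry, Track

REGIONS = ("proximal", "node", "distal")


def _region_of(s: float, node_half_length: float = 2.0) -> str:
    if s < -node_half_length:
        return "proximal"
    if s > node_half_length:
        return "distal"
    return "node"


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic transport model.

    Speeds are μm/s, lengths μm, times seconds. ``speed_means`` and
    ``pause_p`` map direction (``"anterograde"``/``"retrograde"``) to a
    per-region dict over ``proximal``/``node``/``distal``. Endosomes are
    purely retrograde (``anterograde_fraction`` is None); mitochondria
    draw their direction with probability ``anterograde_fraction``.

    The pause model is per-step i.i.d. Bernoulli by default, so the
    programmed probability equals the expected pause-step fraction; a
    geometric run-length variant (``pause_model="run_length"``) preserves
    the same stationary fraction with correlated pause bouts.
    """

    seed: int = 0
    preset: str | None = None
    organelle_class: str = "endosome"
    n_tracks: int = 300
    n_frames: int = 120
    frame_interval_s: float = 0.5
    speed_means: dict = field(default_factory=lambda: {
        "retrograde": {"proximal": 2.40, "node": 1.25, "distal": 2.10}})
    speed_sd: float = 0.25
    speed_floor: float = 0.15
    pause_p: dict = field(default_factory=lambda: {
        "retrograde": {"proximal": 0.042, "node": 0.30, "distal": 0.099}})
    pause_model: str = "iid_bernoulli"
    pause_mean_run_frames: float = 3.0
    anterograde_fraction: float | None = None
    localization_noise_sd: float = 0.01
    initial_s_range: tuple = (-45.0, 45.0)
    fov_half_um: float = 50.0  # tracking stops when an organelle leaves the field of view
    # axon geometry
    axon_length_um: float = 100.0
    internode_diameter_um: float = 3.0
    node_diameter_um: float = 1.4
    node_length_um: float = 4.0
    lateral_funneling: bool = True
    lateral_sd_um: float = 0.2
    # stationary organelles clustered distal to the node
    n_stationary: int = 0
    stationary_center_s: float = 3.75
    stationary_sd_um: float = 2.0
    # mitochondrial length model
    length_stationary_mean_um: float | None = None
    length_motile_mean_um: float | None = None
    length_sd_um: float = 0.2
    # dataset layout
    n_axons: int = 3
    animal_id: str = "sim"
    # fluorescence profile generator
    profile_baseline: float = 1.0
    bump_amplitude: float = 0.5
    bump_center_um: float = 3.75
    bump_sd_um: float = 2.0
    profile_noise_sd: float = 0.1
    profile_background: float = 0.5
    profile_grid_um: float = 0.5
    profile_channel: str = "endosome"
    # diameter profile generator
    diameter_noise_frac: float = 0.05
    diameter_grid_um: float = 0.1
    diameter_span_um: float = 40.0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def node_half_length(self) -> float:
        return self.node_length_um / 2.0

    def directions(self) -> list[str]:
        return sorted(self.speed_means)

    def validate(self) -> None:
        for direction, per_region in self.pause_p.items():
            for region, p in per_region.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"pause probability {direction}/{region} = {p} not in [0, 1]"
                    )
        if set(self.speed_means) != set(self.pause_p):
            raise ConfigError("speed_means and pause_p must cover the same directions")
        # moving speeds must sit safely above the pause threshold plus the
        # apparent speed induced by localisation noise
        apparent = np.sqrt(2.0) * self.localization_noise_sd / self.frame_interval_s
        floor = 0.1 + 5.0 * apparent
        for direction, per_region in self.speed_means.items():
            for region, v in per_region.items():
                if v <= floor:
                    raise ConfigError(
                        f"speed {direction}/{region} = {v} um/s too close to the "
                        f"pause threshold (needs > {floor:.3f})"
                    )
        if self.anterograde_fraction is not None and not (
            0.0 <= self.anterograde_fraction <= 1.0
        ):
            raise ConfigError("anterograde_fraction must be in [0, 1]")
        if self.pause_model not in ("iid_bernoulli", "run_length"):
            raise ConfigError(f"unknown pause model {self.pause_model!r}")
        if self.frame_interval_s <= 0 or self.n_frames < 2 or self.n_tracks < 0:
            raise ConfigError("invalid acquisition parameters")


@dataclass
class GroundTruth:
    """Programmed parameters and per-track/per-step truth of a dataset."""

    speed_means: dict
    pause_p: dict
    directions: dict          # track_id -> anterograde|retrograde|stationary
    pause_flags: dict         # track_id -> bool array over steps
    stationary_ids: set
    noise_pause_violation_rate: float = 0.0


@dataclass
class SimulatedDataset:
    tracks: list
    geometry: AxonGeometry
    truth: GroundTruth
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESETS: dict[str, dict] = {
    # retrograde endosomes, fast-muscle (tibialis anterior) axons
    "endosome_paper": dict(
        organelle_class="endosome",
        n_tracks=300,
        n_frames=120,
        frame_interval_s=0.5,
        speed_means={"retrograde": {"proximal": 2.40, "node": 1.25, "distal": 2.10}},
        speed_sd=0.25,
        pause_p={"retrograde": {"proximal": 0.042, "node": 0.30, "distal": 0.099}},
        n_stationary=30,
    ),
    # retrograde endosomes, slow-muscle (soleus) axons
    "endosome_soleus_paper": dict(
        organelle_class="endosome",
        n_tracks=300,
        n_frames=120,
        frame_interval_s=0.5,
        speed_means={"retrograde": {"proximal": 2.41, "node": 1.30, "distal": 2.00}},
        speed_sd=0.25,
        pause_p={"retrograde": {"proximal": 0.042, "node": 0.30, "distal": 0.099}},
        n_stationary=30,
    ),
    # bidirectional mitochondria
    "mito_paper": dict(
        organelle_class="mitochondrion",
        n_tracks=300,
        n_frames=240,
        frame_interval_s=1.7,
        speed_means={
            "anterograde": {"proximal": 0.500, "node": 0.360, "distal": 0.456},
            "retrograde": {"proximal": 0.500, "node": 0.380, "distal": 0.494},
        },
        speed_sd=0.05,
        pause_p={
            "anterograde": {"proximal": 0.12, "node": 0.20, "distal": 0.12},
            "retrograde": {"proximal": 0.12, "node": 0.12, "distal": 0.12},
        },
        anterograde_fraction=0.76,
        n_stationary=40,
        length_stationary_mean_um=1.8,
        length_motile_mean_um=1.1,
    ),
    # fluorescence accumulation distal to the node
    "accumulation_paper": dict(
        profile_baseline=1.0,
        bump_amplitude=0.5,
        bump_center_um=3.75,
        bump_sd_um=2.0,
        profile_noise_sd=0.1,
        profile_background=0.5,
    ),
    # nodal constriction geometry
    "morphometry_paper": dict(
        internode_diameter_um=3.0,
        node_diameter_um=1.4,
        node_length_um=4.0,
        diameter_noise_frac=0.05,
    ),
    # negative control: identical parameters in all regions
    "null_uniform": dict(
        organelle_class="endosome",
        n_tracks=300,
        n_frames=120,
        frame_interval_s=0.5,
        speed_means={"retrograde": {"proximal": 2.0, "node": 2.0, "distal": 2.0}},
        speed_sd=0.25,
        pause_p={"retrograde": {"proximal": 0.10, "node": 0.10, "distal": 0.10}},
        n_stationary=0,
    ),
}


def make_config(preset: str, **overrides) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a named preset plus overrides."""
    if preset not in PRESETS:
        raise ConfigError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    params = dict(PRESETS[preset])
    params.update(overrides)
    return GeneratorConfig(preset=preset, **params)


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------

def _truncnorm_draws(rng: np.random.Generator, mean: float, sd: float,
                     lower: float, n: int) -> np.ndarray:
    """Truncated-normal speed draws (> lower) via inverse-CDF sampling."""
    if sd <= 0:
        return np.full(n, max(mean, lower))
    a = ndtr((lower - mean) / sd)
    u = rng.random(n)
    return mean + sd * ndtri(a + u * (1.0 - a))


def diameter_at(s: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Raised-cosine diameter model: dip of programmed half-depth width.

    ``d(s) = D - depth * f(s)`` with ``f = 0.5 * (1 + cos(pi s / (2 h)))``
    for ``|s| <= 2 h`` (``h`` = half the node length) and 0 outside, so
    that the full width at half depth equals the configured node length.
    """
    s = np.asarray(s, dtype=float)
    D = cfg.internode_diameter_um
    depth = D - cfg.node_diameter_um
    h = cfg.node_half_length
    f = np.where(
        np.abs(s) <= 2.0 * h,
        0.5 * (1.0 + np.cos(np.pi * s / (2.0 * h))),
        0.0,
    )
    return D - depth * f


def simulate_tracks(cfg: GeneratorConfig) -> SimulatedDataset:
    """Generate a full track dataset with per-step ground truth.

    Each motile track draws a direction (mitochondria) or is retrograde
    (endosomes), starts uniformly within ``initial_s_range`` and at every
    frame either pauses (region-dependent probability, zero displacement)
    or advances by a truncated-normal speed draw for the region of its
    current position. Stationary organelles are placed from the distal
    cluster and never move. Emitted (x, y) positions carry isotropic
    Gaussian localisation noise; the fraction of true-pause steps whose
    apparent speed exceeds the 0.1 μm/s threshold is checked to stay
    below 1%.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval_s
    n_steps = cfg.n_frames - 1
    L = cfg.axon_length_um
    node_arc = L / 2.0
    geometry = AxonGeometry(
        centerline=np.array([[0.0, 0.0], [L, 0.0]]),
        node_center_arclength=node_arc,
        distal_sign=1,
    )
    h = cfg.node_half_length
    is_mito = cfg.organelle_class == "mitochondrion"

    tracks: list[Track] = []
    directions: dict = {}
    pause_flags: dict = {}
    stationary_ids: set = set()
    duration = cfg.n_frames * dt

    def emit(tid, s_path, true_pauses, direction_label, stationary, k):
        # tracking stops once the organelle leaves the field of view
        inside = np.abs(s_path) <= cfg.fov_half_um
        n_keep = int(np.argmin(inside)) if not inside.all() else len(s_path)
        n_keep = max(n_keep, 2)
        s_path = s_path[:n_keep]
        true_pauses = true_pauses[: n_keep - 1]
        # one lateral offset per organelle; funneling bounds it by the
        # local axon radius as the organelle passes the constriction
        offset = rng.normal(0.0, cfg.lateral_sd_um)
        lateral = np.full(n_keep, offset)
        if cfg.lateral_funneling:
            radius = diameter_at(s_path, cfg) / 2.0
            lateral = np.clip(lateral, -radius, radius)
        x = node_arc + s_path + rng.normal(0.0, cfg.localization_noise_sd, n_keep)
        y = lateral + rng.normal(0.0, cfg.localization_noise_sd, n_keep)
        length = None
        if is_mito and cfg.length_motile_mean_um is not None:
            mean = (cfg.length_stationary_mean_um if stationary
                    else cfg.length_motile_mean_um)
            val = _truncnorm_draws(rng, mean, cfg.length_sd_um, 0.2, 1)[0]
            length = np.full(n_keep, val)
        tracks.append(
            Track(
                track_id=tid,
                organelle_class=cfg.organelle_class,
                frames=np.arange(n_keep),
                t=np.arange(n_keep) * dt,
                x=x,
                y=y,
                length_um=length,
                axon_id=f"axon{k % cfg.n_axons}",
                animal_id=cfg.animal_id,
                video_duration_s=duration,
            )
        )
        directions[tid] = direction_label
        pause_flags[tid] = true_pauses

    for k in range(cfg.n_tracks):
        tid = f"t{k:04d}"
        if is_mito and cfg.anterograde_fraction is not None:
            direction = ("anterograde"
                         if rng.random() < cfg.anterograde_fraction
                         else "retrograde")
        else:
            direction = "retrograde"
        dsign = 1.0 if direction == "anterograde" else -1.0
        means = cfg.speed_means[direction]
        p = cfg.pause_p[direction]
        speeds = {
            r: _truncnorm_draws(rng, means[r], cfg.speed_sd, cfg.speed_floor, n_steps)
            for r in REGIONS
        }
        u = rng.random(n_steps)
        s_path = np.empty(cfg.n_frames)
        pauses = np.empty(n_steps, dtype=bool)
        s = rng.uniform(*cfg.initial_s_range)
        s_path[0] = s
        paused_state = False
        for i in range(n_steps):
            region = _region_of(s, h)
            if cfg.pause_model == "iid_bernoulli":
                pause = u[i] < p[region]
            else:  # geometric run lengths preserving the stationary fraction
                Lrun = cfg.pause_mean_run_frames
                if paused_state:
                    pause = u[i] < 1.0 - 1.0 / Lrun
                else:
                    pr = p[region]
                    enter = pr / ((1.0 - pr) * Lrun) if pr < 1.0 else 1.0
                    pause = u[i] < min(enter, 1.0)
                paused_state = pause
            pauses[i] = pause
            if not pause:
                s += dsign * speeds[region][i] * dt
            s_path[i + 1] = s
        emit(tid, s_path, pauses, direction, False, k)

    for k in range(cfg.n_stationary):
        tid = f"st{k:04d}"
        s0 = rng.normal(cfg.stationary_center_s, cfg.stationary_sd_um)
        s_path = np.full(cfg.n_frames, s0)
        pauses = np.ones(n_steps, dtype=bool)
        emit(tid, s_path, pauses, "stationary", True, cfg.n_tracks + k)
        stationary_ids.add(tid)

    # noise calibration: apparent speed of true-pause steps vs threshold
    n_pause = n_violate = 0
    for tr in tracks:
        flags = pause_flags[tr.track_id]
        dx = np.diff(tr.x)
        dy = np.diff(tr.y)
        speed = np.hypot(dx, dy) / dt
        n_pause += int(flags.sum())
        n_violate += int((speed[flags] > 0.1).sum())
    rate = n_violate / n_pause if n_pause else 0.0
    if rate >= 0.01:
        raise ConfigError(
            f"localisation noise confounds pause detection: "
            f"{100 * rate:.2f}% of true pauses appear moving"
        )
    truth = GroundTruth(
        speed_means={d: dict(v) for d, v in cfg.speed_means.items()},
        pause_p={d: dict(v) for d, v in cfg.pause_p.items()},
        directions=directions,
        pause_flags=pause_flags,
        stationary_ids=stationary_ids,
        noise_pause_violation_rate=rate,
    )
    return SimulatedDataset(tracks=tracks, geometry=geometry, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# profile simulation
# ---------------------------------------------------------------------------

def profile_expectation(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Analytic axonal profile (grid, baseline * (1 + Gaussian bump))."""
    n = int(round(80.0 / cfg.profile_grid_um)) + 1
    s = np.linspace(-40.0, 40.0, n)
    bump = cfg.bump_amplitude * np.exp(
        -((s - cfg.bump_center_um) ** 2) / (2.0 * cfg.bump_sd_um ** 2)
    )
    return s, cfg.profile_baseline * (1.0 + bump)


def simulate_profiles(cfg: GeneratorConfig, n_axons: int = 20,
                      ) -> tuple[list[LineProfile], np.ndarray, np.ndarray]:
    """Noisy fluorescence line profiles plus their analytic expectation.

    Each profile is ``background + axon_signal * noise`` where the axonal
    signal is a flat baseline with a Gaussian accumulation bump distal to
    the node and the noise is multiplicative lognormal with unit mean and
    the configured SD. Off-axon background samples (same additive
    background, with noise) are attached for region-based background
    subtraction. Returns ``(profiles, s_grid, expected_axon_signal)``.
    """
    rng = np.random.default_rng(cfg.seed)
    s, expect = profile_expectation(cfg)
    sd = cfg.profile_noise_sd
    sigma2 = np.log1p(sd ** 2)
    mu = -sigma2 / 2.0
    sigma = np.sqrt(sigma2)
    profiles = []
    for a in range(n_axons):
        noise = np.exp(rng.normal(mu, sigma, len(s)))
        F = cfg.profile_background + expect * noise
        bg_noise = np.exp(rng.normal(mu, sigma, 20))
        bg = cfg.profile_background * bg_noise
        profiles.append(
            LineProfile(
                s=s,
                F=F,
                channel=cfg.profile_channel,
                axon_id=f"axon{a}",
                animal_id=cfg.animal_id,
                background_samples=bg,
            )
        )
    return profiles, s, expect


def simulate_diameter_profile(cfg: GeneratorConfig,
                              rng: np.random.Generator | None = None,
                              ) -> DiameterProfile:
    """Diameter profile with a raised-cosine constriction plus noise.

    The noise-free profile is :func:`diameter_at`; multiplicative Gaussian
    noise of fractional SD ``diameter_noise_frac`` is applied per sample.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    half = cfg.diameter_span_um / 2.0
    n = int(round(cfg.diameter_span_um / cfg.diameter_grid_um)) + 1
    s = np.linspace(-half, half, n)
    d = diameter_at(s, cfg)
    if cfg.diameter_noise_frac > 0:
        d = d * (1.0 + cfg.diameter_noise_frac * rng.standard_normal(n))
        d = np.clip(d, 1e-3, None)
    return DiameterProfile(s=s, d=d)


def config_to_dict(cfg: GeneratorConfig) -> dict:
    """Plain-dict snapshot of a config (for manifests and run logs)."""
    d = asdict(cfg)
    d["initial_s_range"] = list(d["initial_s_range"])
    return d
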