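"""Synthetic resting-state fNIRS cohorts with known ground truth.

The generator emulates the statistical structure of a resting-state
connectome-prediction study: a cohort (default 96 participants) of
46-channel, 7-minute, 10 Hz recordings in which

* each channel carries a band-limited (0.01-0.08 Hz) spontaneous signal
  whose cross-channel covariance has community structure — channels within
  the same cortical network are positively coupled;
* a small set of *planted* channel pairs have participant-varying coupling
  strengths, and the participant's state-anxiety score is a sparse linear
  function of those strengths plus noise;
* one shared low-frequency global physiological component (Mayer-wave-like)
  is added to every channel, plus white sensor noise;
* trait anxiety correlates with state (target r = 0.67 by default) through
  one of two mechanisms: ``trait_mode="from_state"`` (default) mixes the
  state core with independent noise, so trait inherits a share of the
  connectivity signal; ``trait_mode="latent_factor"`` makes trait a latent
  factor F independent of connectivity that also feeds state — the setting
  for specificity analyses, where connectivity drives only state-unique
  variance.

Recordings can be emitted directly as hemoglobin series or pushed through
the forward modified Beer-Lambert model as two-wavelength optical
densities, which makes the full intensity -> hemoglobin pipeline round-trip
testable. All randomness flows from one seed through spawned generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .connectome import n_edges, edge_indices
from .errors import ConfigurationError
from .optics import BeerLambertParams, HemoSeries, IntensityRecording, forward_od
from .report import NETWORKS, default_channel_table, network_assignment

#: Default planted edge structure: 15 channel pairs (0-based, i<j) with
#: signed effect weights — 6 negative, 9 positive — mirroring the reported
#: contributing-edge layout of the study the generator emulates.
DEFAULT_PLANTED_EDGES: tuple[tuple[int, int, float], ...] = (
    (0, 25, -0.6519),
    (6, 44, -0.5970),
    (7, 43, -0.5450),
    (16, 37, -0.7883),
    (7, 24, -1.6234),
    (36, 37, -0.7641),
    (1, 5, 0.8241),
    (6, 33, 0.9947),
    (12, 29, 0.8540),
    (12, 36, 0.7145),
    (4, 5, 0.7113),
    (1, 18, 0.9085),
    (1, 41, 0.7256),
    (8, 38, 0.7408),
    (12, 31, 0.8008),
)


@dataclass
class SimulationConfig:
    """Study-shaped generator settings; defaults are the emulated study conditions."""

    n_participants: int = 96
    n_channels: int = 46
    sampling_rate: float = 10.0
    duration: float = 420.0  # seconds (7-minute session)
    n_networks: int = 7
    global_noise_amplitude: float = 1.0  # relative to spontaneous-signal amplitude
    band: tuple[float, float] = (0.01, 0.08)
    planted_edges: tuple[tuple[int, int, float], ...] = DEFAULT_PLANTED_EDGES
    anxiety_noise_sd: float = 0.5  # on the standardized state scale
    score_range: tuple[float, float] = (20.0, 70.0)
    trait_range: tuple[float, float] = (22.0, 66.0)
    state_trait_r: float = 0.67  # target state-trait correlation
    trait_mode: str = "from_state"  # or "latent_factor" (trait independent of edges)
    within_network_rho: float = 0.3
    edge_strength_mean: float = 0.3
    edge_strength_sd: float = 0.5
    sensor_noise_sd: float = 0.15  # relative to spontaneous-signal amplitude
    hbo_amplitude: float = 0.5  # micromolar RMS of the spontaneous signal
    global_band: tuple[float, float] = (0.02, 0.2)  # Hz, physiological component
    output: str = "intensity"  # "intensity" or "hemoglobin"
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def validate(self) -> None:
        if self.n_channels < 2:
            raise ConfigurationError("n_channels must be >= 2")
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        T = self.duration * self.sampling_rate
        if abs(T - round(T)) > 1e-9 or round(T) < 2:
            raise ConfigurationError("duration x sampling_rate must be an integer >= 2")
        nyq = self.sampling_rate / 2.0
        for name, (lo, hi) in (("band", self.band), ("global_band", self.global_band)):
            if not (0 < lo < hi):
                raise ConfigurationError(f"{name} must satisfy 0 < low < high")
            if hi >= nyq:
                raise ConfigurationError(f"{name} high cutoff {hi} >= Nyquist {nyq}")
        for i, j, _w in self.planted_edges:
            if not (0 <= i < j < self.n_channels):
                raise ConfigurationError(
                    f"planted edge ({i}, {j}) must satisfy 0 <= i < j < n_channels"
                )
        for name, (lo, hi) in (
            ("score_range", self.score_range),
            ("trait_range", self.trait_range),
        ):
            if not lo < hi:
                raise ConfigurationError(f"{name} min must be < max")
        if not (1 <= self.n_networks <= len(NETWORKS)):
            raise ConfigurationError(f"n_networks must be in 1..{len(NETWORKS)}")
        if self.global_noise_amplitude < 0:
            raise ConfigurationError("global_noise_amplitude must be >= 0")
        if not -1 < self.state_trait_r < 1:
            raise ConfigurationError("state_trait_r must be in (-1, 1)")
        if self.trait_mode not in ("from_state", "latent_factor"):
            raise ConfigurationError(f"unknown trait_mode {self.trait_mode!r}")
        if self.output not in ("intensity", "hemoglobin"):
            raise ConfigurationError(f"unknown output mode {self.output!r}")


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted structure."""

    true_edge_weights: np.ndarray  # length E, nonzero exactly at planted edges
    planted_edge_ids: np.ndarray  # edge-vector positions of the planted pairs
    network_assignment: np.ndarray  # channel -> network index
    latent_edge_strengths: np.ndarray  # N x n_planted per-participant couplings
    linear_predictor: np.ndarray  # N, the planted-edge combination driving state
    latent_factor: np.ndarray  # N, trait-shaped factor independent of connectivity
    state: np.ndarray
    trait: np.ndarray
    participant_ids: list[str] = field(default_factory=list)
    n_state_clipped: int = 0
    n_trait_clipped: int = 0


def _edge_positions(n_channels: int, pairs) -> np.ndarray:
    iu, ju = edge_indices(n_channels)
    lookup = {(a, b): k for k, (a, b) in enumerate(zip(iu, ju))}
    return np.asarray([lookup[(i, j)] for i, j, _ in pairs], dtype=int)


def _generic_channel_table(n_channels: int, n_networks: int) -> pd.DataFrame:
    nets = [NETWORKS[c % n_networks] for c in range(n_channels)]
    return pd.DataFrame(
        {
            "channel": np.arange(1, n_channels + 1),
            "mni_x": np.zeros(n_channels),
            "mni_y": np.zeros(n_channels),
            "mni_z": np.zeros(n_channels),
            "region": [f"region{c + 1:02d}" for c in range(n_channels)],
            "network": nets,
        }
    )


def channel_table_for(config: SimulationConfig) -> pd.DataFrame:
    """Channel metadata used for network structure: the shipped 46-channel
    table under default geometry, otherwise a round-robin assignment."""
    if config.n_channels == 46 and config.n_networks == 7:
        return default_channel_table()
    return _generic_channel_table(config.n_channels, config.n_networks)


def _band_limited_noise(rng, shape, band, fs) -> np.ndarray:
    """White noise filtered into ``band`` and standardized along time (axis 0)."""
    sos = sps.butter(3, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=0)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return x / sd


def _nearest_correlation(sigma: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Clip eigenvalues and renormalize to unit diagonal (PSD repair)."""
    vals, vecs = np.linalg.eigh(sigma)
    vals = np.maximum(vals, floor)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _participant_sigma(config, net_assign, u_row, planted_pairs) -> np.ndarray:
    n = config.n_channels
    sigma = np.eye(n)
    same = net_assign[:, None] == net_assign[None, :]
    sigma[same] = config.within_network_rho
    np.fill_diagonal(sigma, 1.0)
    for (i, j, _w), u in zip(planted_pairs, u_row):
        sigma[i, j] = sigma[j, i] = u
    return _nearest_correlation(sigma)


def _scores_to_scale(z: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, int]:
    """Affinely map standardized scores so +-2.8 SD spans [lo, hi]; round to
    integer questionnaire scores, clip, and report how many were clipped."""
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    sd = z.std()
    zs = (z - z.mean()) / (sd if sd > 0 else 1.0)
    raw = np.round(mid + half * zs / 2.8)
    clipped = int(np.sum((raw < lo) | (raw > hi)))
    return np.clip(raw, lo, hi), clipped


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list, GroundTruth, pd.DataFrame]:
    """Generate one cohort: recordings, ground truth and channel metadata.

    Returns ``IntensityRecording`` objects (default) or ``HemoSeries`` when
    ``config.output == "hemoglobin"``. Deterministic given ``config.seed``.
    """
    config.validate()
    meta = channel_table_for(config)
    net_assign = network_assignment(meta)[: config.n_channels]
    N, T, n = config.n_participants, config.n_samples, config.n_channels
    planted = list(config.planted_edges)
    P = len(planted)

    ss = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    participant_seeds = ss.spawn(N)

    # per-participant planted-edge couplings (these drive the state score)
    if P:
        u = np.clip(
            cohort_rng.normal(config.edge_strength_mean, config.edge_strength_sd, (N, P)),
            -0.9,
            0.9,
        )
    else:
        u = np.zeros((N, 0))

    amp = config.hbo_amplitude
    ids = [f"sub-{p + 1:03d}" for p in range(N)]
    bl_params = BeerLambertParams(distance_mm=30.0)
    recordings = []
    for p in range(N):
        rng = np.random.default_rng(participant_seeds[p])
        sigma = _participant_sigma(config, net_assign, u[p], planted)
        L = np.linalg.cholesky(sigma)
        neural = _band_limited_noise(rng, (T, n), config.band, config.sampling_rate) @ L.T
        g = _band_limited_noise(rng, (T,), config.global_band, config.sampling_rate)
        gains = 1.0 + 0.2 * rng.standard_normal(n)
        global_part = config.global_noise_amplitude * amp * np.outer(g, gains)
        hbo = (
            amp * neural
            + global_part
            + config.sensor_noise_sd * amp * rng.standard_normal((T, n))
        ).T
        hbr = (
            -0.5 * amp * neural
            + 0.5 * global_part
            + 0.5 * config.sensor_noise_sd * amp * rng.standard_normal((T, n))
        ).T
        series = HemoSeries(
            participant_id=ids[p],
            hbo=hbo,
            hbr=hbr,
            sampling_rate=config.sampling_rate,
        )
        if config.output == "hemoglobin":
            recordings.append(series)
        else:
            od695, od830 = forward_od(hbo, hbr, bl_params)
            recordings.append(
                IntensityRecording(
                    participant_id=ids[p],
                    od_695=od695,
                    od_830=od830,
                    sampling_rate=config.sampling_rate,
                    distance_mm=bl_params.distance_mm,
                )
            )

    # phenotypes: state score driven by the planted-edge combination
    weights = np.asarray([w for _, _, w in planted])
    lin = u @ weights if P else np.zeros(N)
    if P and lin.std() > 0:
        lin_std = (lin - lin.mean()) / lin.std()
        s_L = 1.0
    else:
        lin_std = np.zeros(N)
        s_L = 0.0
    F = cohort_rng.standard_normal(N)
    F = (F - F.mean()) / F.std()
    rho = config.state_trait_r
    eps = cohort_rng.normal(0.0, config.anxiety_noise_sd, N)
    if config.trait_mode == "latent_factor":
        # trait = F, independent of connectivity; F also feeds state scaled
        # so that the population state-trait correlation hits the target
        s_F = abs(rho) / np.sqrt(1 - rho**2) * np.sqrt(
            s_L**2 + config.anxiety_noise_sd**2
        ) * np.sign(rho)
        state_z = s_L * lin_std + s_F * F + eps
        trait_z = F
    else:
        # trait = state core mixed with independent noise at the target corr
        state_z = s_L * lin_std + eps
        sd = state_z.std()
        core = (state_z - state_z.mean()) / (sd if sd > 0 else 1.0)
        trait_z = rho * core + np.sqrt(1 - rho**2) * F
    state, n_state_clip = _scores_to_scale(state_z, *config.score_range)
    trait, n_trait_clip = _scores_to_scale(trait_z, *config.trait_range)

    E = n_edges(n)
    true_w = np.zeros(E)
    if P:
        pos = _edge_positions(n, planted)
        true_w[pos] = weights
    else:
        pos = np.asarray([], dtype=int)

    truth = GroundTruth(
        true_edge_weights=true_w,
        planted_edge_ids=pos,
        network_assignment=net_assign,
        latent_edge_strengths=u,
        linear_predictor=lin,
        latent_factor=F,
        state=state,
        trait=trait,
        participant_ids=ids,
        n_state_clipped=n_state_clip,
        n_trait_clipped=n_trait_clip,
    )
    return recordings, truth, meta


def phenotype_table(truth: GroundTruth) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": truth.participant_ids,
            "state": truth.state,
            "trait": truth.trait,
        }
    )


def inject_spike(
    series: HemoSeries, channel: int, sample: int, magnitude_sd: float = 20.0
) -> HemoSeries:
    """Add a motion-like spike to one sample of one channel (testing aid)."""
    hbo = series.hbo.copy()
    hbo[channel, sample] += magnitude_sd * series.hbo[channel].std()
    return replace(series, hbo=hbo)
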