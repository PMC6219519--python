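"""Synthetic photon-burst generator.

Emulates the statistical structure of diffusion-based multiparameter
fluorescence detection (MFD) data: single molecules transiting the focus
produce millisecond photon bursts on top of a low Poisson background.  Each
burst belongs to one FRET species (with its interdye distance drawn from a
Gaussian distance distribution), to a donor-only molecule, or to a pair of
states in microsecond two-state exchange.  Photons carry a spectral/
polarization channel and a TCSPC nanotime, so every downstream analysis
stage (burst search, burst observables, FRET lines, photon distribution
analysis) can be validated against known ground truth.

Deliberate simplifications: brightness is constant within a burst (no
diffusion-profile modulation), there is no triplet blinking or acceptor
photophysics, and stoichiometry is emulated by tagging bursts donor-only or
dual-labelled rather than by alternating excitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fret import FretPair, efficiency_from_distance

__all__ = [
    "CH_GREEN_PAR",
    "CH_GREEN_PERP",
    "CH_RED_PAR",
    "CH_RED_PERP",
    "SimConfig",
    "FretSpecies",
    "ExchangingPair",
    "StateTrajectory",
    "PhotonStream",
    "simulate_two_state_trajectory",
    "simulate_bursts",
    "write_photon_hdf5",
    "read_photon_hdf5",
]

CH_GREEN_PAR = 0
CH_GREEN_PERP = 1
CH_RED_PAR = 2
CH_RED_PERP = 3

GREEN_CHANNELS = (CH_GREEN_PAR, CH_GREEN_PERP)
RED_CHANNELS = (CH_RED_PAR, CH_RED_PERP)


@dataclass(frozen=True)
class SimConfig:
    """Global parameters of a simulated MFD acquisition.

    Times in seconds unless noted.  ``excitation_period`` is the laser pulse
    spacing (1/64 MHz = 15.625 ns); ``mean_dwell`` the burst duration scale;
    ``brightness`` the in-focus molecular count rate in photons/ms;
    ``bg_green``/``bg_red`` background rates in kHz per spectral channel.
    """

    excitation_period: float = 1.0 / 64e6
    mean_dwell: float = 3e-3
    dwell_bounds: tuple = (0.5e-3, 10e-3)
    brightness: float = 50.0
    bg_green: float = 0.35
    bg_red: float = 0.35
    crosstalk_alpha: float = 0.0
    gamma: float = 1.0
    donor_only_fraction: float = 0.10
    tau_D0: float = 4.0e-9
    acceptor_tau: float = 1.0e-9
    mean_gap: float = 50e-3
    seed: int = 0

    def __post_init__(self):
        if min(self.brightness, self.bg_green, self.bg_red) < 0:
            raise ValueError("rates must be non-negative")
        for frac in (self.crosstalk_alpha, self.donor_only_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if not self.tau_D0 < self.excitation_period:
            raise ValueError("tau_D0 must be shorter than the excitation period")
        if self.mean_dwell <= 0 or self.mean_gap <= 0:
            raise ValueError("time scales must be positive")

    @property
    def tau_D0_ns(self) -> float:
        return self.tau_D0 * 1e9


@dataclass(frozen=True)
class FretSpecies:
    """A named FRET state.

    ``rda_e`` is the FRET-averaged interdye distance <R_DA>_E in A, ``sigma``
    the half-width of its Gaussian distance distribution (A), ``fraction``
    its equilibrium population and ``anisotropy`` the steady-state donor
    anisotropy used to split photons into polarization channels.
    """

    name: str
    rda_e: float
    sigma: float = 2.0
    fraction: float = 1.0
    anisotropy: float = 0.1

    def __post_init__(self):
        if self.rda_e <= 0:
            raise ValueError("rda_e must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class ExchangingPair:
    """Two FRET states in reversible exchange (rates in s^-1)."""

    state_a: FretSpecies
    state_b: FretSpecies
    k_ab: float
    k_ba: float

    def __post_init__(self):
        if self.k_ab < 0 or self.k_ba < 0:
            raise ValueError("rates must be non-negative")
        if self.k_ab == 0 and self.k_ba == 0:
            raise ValueError("at least one rate must be positive")

    @property
    def p_a(self) -> float:
        """Equilibrium occupancy of state_a."""
        return self.k_ba / (self.k_ab + self.k_ba)

    @property
    def p_b(self) -> float:
        return self.k_ab / (self.k_ab + self.k_ba)


@dataclass
class StateTrajectory:
    """Alternating dwell segments of a two-state trajectory.

    ``boundaries`` are segment end times (the last equals the duration);
    ``states`` holds 0 for state_a, 1 for state_b per segment.
    """

    boundaries: np.ndarray
    states: np.ndarray
    duration: float

    def state_at(self, t):
        """State index (0/1) at time(s) t."""
        idx = np.searchsorted(self.boundaries, np.asarray(t, dtype=float), side="right")
        idx = np.minimum(idx, len(self.states) - 1)
        return self.states[idx]

    def occupancy_a(self) -> float:
        """Fraction of the duration spent in state_a."""
        starts = np.concatenate([[0.0], self.boundaries[:-1]])
        dwell = self.boundaries - starts
        return float(dwell[self.states == 0].sum() / self.duration)


def simulate_two_state_trajectory(
    pair: ExchangingPair,
    duration: float,
    rng,
    initial_state: int | None = None,
) -> StateTrajectory:
    """Sample a stationary two-state Markov trajectory over [0, duration].

    The initial state is drawn from the equilibrium probabilities
    (k_ba, k_ab)/(k_ab + k_ba) unless given explicitly; dwell times are
    exponential with the current state's exit rate.  Segments tile the
    interval exactly (the last dwell is truncated at ``duration``).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rates = (pair.k_ab, pair.k_ba)
    if initial_state is None:
        state = 0 if rng.random() < pair.p_a else 1
    else:
        state = int(initial_state)
    boundaries = []
    states = []
    t = 0.0
    while t < duration:
        k = rates[state]
        dwell = rng.exponential(1.0 / k) if k > 0 else np.inf
        t = min(t + dwell, duration)
        boundaries.append(t)
        states.append(state)
        state = 1 - state
    return StateTrajectory(
        boundaries=np.asarray(boundaries), states=np.asarray(states), duration=duration
    )


@dataclass
class PhotonStream:
    """Time-tagged photon records of one acquisition.

    macrotime in seconds (nondecreasing), channel one of the CH_* constants,
    nanotime in ns within the excitation period.  ``bursts`` carries the
    simulation ground truth (one row per molecule transit) when available.
    """

    macrotime: np.ndarray
    channel: np.ndarray
    nanotime: np.ndarray
    config: SimConfig | None = None
    bursts: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if np.any(np.diff(self.macrotime) < 0):
            raise ValueError("macrotimes must be nondecreasing")
        period_ns = (self.config.excitation_period if self.config else 15.625e-9) * 1e9
        if np.any(self.nanotime < 0) or np.any(self.nanotime >= period_ns + 1e-9):
            raise ValueError("nanotimes must lie within the excitation period")

    def __len__(self) -> int:
        return self.macrotime.size

    @property
    def is_green(self) -> np.ndarray:
        return self.channel <= CH_GREEN_PERP

    @property
    def is_red(self) -> np.ndarray:
        return self.channel >= CH_RED_PAR

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "macrotime_ns": np.round(self.macrotime * 1e9).astype(np.int64),
                "channel": self.channel,
                "nanotime_ps": np.round(self.nanotime * 1e3).astype(np.int64),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: SimConfig | None = None) -> "PhotonStream":
        df = pd.read_csv(path)
        return cls(
            macrotime=df["macrotime_ns"].to_numpy(dtype=float) * 1e-9,
            channel=df["channel"].to_numpy(dtype=np.int8),
            nanotime=df["nanotime_ps"].to_numpy(dtype=float) * 1e-3,
            config=config,
        )


def _apparent_p_red(E, cfg: SimConfig) -> np.ndarray:
    """Probability that a fluorescence photon is detected in a red channel."""
    E = np.asarray(E, dtype=float)
    p_fret = cfg.gamma * E / (cfg.gamma * E + 1.0 - E)
    return p_fret + (1.0 - p_fret) * cfg.crosstalk_alpha


def _polarization_split(n: int, anisotropy: float, rng) -> np.ndarray:
    # detected parallel/perpendicular ratio (1+2r):(1-r)
    p_par = (1.0 + 2.0 * anisotropy) / (2.0 + anisotropy)
    return rng.random(n) < p_par


def _truncated_exponential(mean: float, bounds: tuple, rng) -> float:
    lo, hi = bounds
    while True:
        d = rng.exponential(mean)
        if lo <= d <= hi:
            return d


def simulate_bursts(
    mixture,
    cfg: SimConfig,
    n_bursts: int,
    dynamic: ExchangingPair | None = None,
    dyn_fraction: float = 0.0,
    pair: FretPair | None = None,
    rng=None,
) -> PhotonStream:
    """Generate a photon stream of ``n_bursts`` molecule transits.

    Each burst is assigned donor-only with probability
    ``cfg.donor_only_fraction``, to the exchanging pair with probability
    ``dyn_fraction``, and otherwise to one of the static ``mixture`` species
    (fractions renormalized).  The three groups of probabilities together
    with the static fractions must be consistent (donor_only + dyn_fraction
    <= 1).  Burst durations are exponential with mean ``cfg.mean_dwell``
    truncated to ``cfg.dwell_bounds``; photons arrive as a Poisson process at
    ``cfg.brightness`` per ms; background fills the whole acquisition span.

    Interdye distances are redrawn per burst from each species' Gaussian
    distance distribution.  For dynamic bursts a two-state trajectory sets
    the emitting state of every photon.
    """
    if pair is None:
        pair = FretPair(R0=55.6, tau_D0=cfg.tau_D0_ns)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mixture = list(mixture)
    if dynamic is None and dyn_fraction:
        raise ValueError("dyn_fraction given without a dynamic pair")
    if dynamic is not None and dyn_fraction == 0.0:
        dyn_fraction = 1.0 - cfg.donor_only_fraction - sum(s.fraction for s in mixture)
    static_total = sum(s.fraction for s in mixture)
    remaining = 1.0 - cfg.donor_only_fraction - dyn_fraction
    if remaining < -1e-9:
        raise ValueError("donor_only_fraction + dyn_fraction exceeds 1")
    if mixture and static_total > 0:
        static_probs = np.array([s.fraction for s in mixture]) / static_total
    else:
        static_probs = np.array([])

    period_ns = cfg.excitation_period * 1e9
    tau_a_ns = cfg.acceptor_tau * 1e9

    times, channels, nanotimes = [], [], []
    truth = []
    t_cursor = 0.0
    if cfg.brightness == 0:
        import warnings

        warnings.warn("zero brightness: stream contains background only", stacklevel=2)

    for _ in range(n_bursts):
        t_cursor += rng.exponential(cfg.mean_gap)
        duration = _truncated_exponential(cfg.mean_dwell, cfg.dwell_bounds, rng)
        n_ph = rng.poisson(cfg.brightness * duration * 1e3) if cfg.brightness > 0 else 0
        t_ph = np.sort(rng.random(n_ph)) * duration

        u = rng.random()
        if u < cfg.donor_only_fraction:
            kind, label = "donor_only", "D0"
            E_ph = np.zeros(n_ph)
            aniso = 0.2
        elif u < cfg.donor_only_fraction + dyn_fraction:
            kind, label = "dynamic", f"{dynamic.state_a.name}<->{dynamic.state_b.name}"
            # joint Gaussian draw: the pair's distances are offset together
            r_a = rng.normal(dynamic.state_a.rda_e, dynamic.state_a.sigma)
            r_b = rng.normal(dynamic.state_b.rda_e, dynamic.state_b.sigma)
            traj = simulate_two_state_trajectory(dynamic, duration, rng)
            e_a = efficiency_from_distance(max(r_a, 1.0), pair)
            e_b = efficiency_from_distance(max(r_b, 1.0), pair)
            E_ph = np.where(traj.state_at(t_ph) == 0, e_a, e_b)
            aniso = 0.5 * (dynamic.state_a.anisotropy + dynamic.state_b.anisotropy)
        else:
            if not mixture:
                raise ValueError("no static species supplied")
            sp = mixture[rng.choice(len(static_probs), p=static_probs)]
            kind, label = "static", sp.name
            r = max(rng.normal(sp.rda_e, sp.sigma), 1.0)
            E_ph = np.full(n_ph, efficiency_from_distance(r, pair))
            aniso = sp.anisotropy

        red = rng.random(n_ph) < _apparent_p_red(E_ph, cfg)
        par = _polarization_split(n_ph, aniso, rng)
        ch = np.where(red, np.where(par, CH_RED_PAR, CH_RED_PERP),
                      np.where(par, CH_GREEN_PAR, CH_GREEN_PERP))
        tau_d_ns = cfg.tau_D0_ns * np.clip(1.0 - E_ph, 1e-3, None)
        nt = np.where(
            red,
            rng.exponential(tau_a_ns, n_ph),
            rng.exponential(np.where(tau_d_ns > 0, tau_d_ns, 1.0), n_ph),
        ) % period_ns

        times.append(t_cursor + t_ph)
        channels.append(ch)
        nanotimes.append(nt)
        truth.append(
            dict(start=t_cursor, duration=duration, kind=kind, species=label, n_photons=n_ph)
        )
        t_cursor += duration

    t_end = t_cursor + rng.exponential(cfg.mean_gap)
    for rate_khz, chs in ((cfg.bg_green, GREEN_CHANNELS), (cfg.bg_red, RED_CHANNELS)):
        n_bg = rng.poisson(rate_khz * 1e3 * t_end)
        t_bg = rng.random(n_bg) * t_end
        ch_bg = rng.choice(chs, size=n_bg)
        nt_bg = rng.random(n_bg) * period_ns
        times.append(t_bg)
        channels.append(ch_bg)
        nanotimes.append(nt_bg)

    macrotime = np.concatenate(times) if times else np.empty(0)
    channel = np.concatenate(channels).astype(np.int8) if channels else np.empty(0, np.int8)
    nanotime = np.concatenate(nanotimes) if nanotimes else np.empty(0)
    order = np.argsort(macrotime, kind="stable")
    return PhotonStream(
        macrotime=macrotime[order],
        channel=channel[order],
        nanotime=nanotime[order],
        config=cfg,
        bursts=pd.DataFrame(truth),
    )


def write_photon_hdf5(stream: PhotonStream, path) -> None:
    """Write the stream in a photon-HDF5-style layout.

    Groups: ``photon_data/timestamps`` (int64, units of ``timestamps_unit``
    seconds), ``photon_data/detectors`` and ``photon_data/nanotimes`` (ps).
    """
    import h5py

    unit = 1e-9
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=np.round(stream.macrotime / unit).astype(np.int64))
        g.create_dataset("detectors", data=stream.channel.astype(np.int8))
        g.create_dataset("nanotimes", data=np.round(stream.nanotime * 1e3).astype(np.int32))
        spec = g.create_group("timestamps_specs")
        spec.create_dataset("timestamps_unit", data=unit)
        g.create_dataset("nanotimes_unit", data=1e-12)


def read_photon_hdf5(path, config: SimConfig | None = None) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["photon_data"]
        unit = float(g["timestamps_specs/timestamps_unit"][()])
        return PhotonStream(
            macrotime=g["timestamps"][:] * unit,
            channel=g["detectors"][:].astype(np.int8),
            nanotime=g["nanotimes"][:] * 1e-3,
            config=config,
        )


def config_from_mapping(doc: dict) -> SimConfig:
    """Build a SimConfig from a YAML/TOML-style mapping of field names."""
    valid = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    if "dwell_bounds" in doc:
        doc = dict(doc)
        doc["dwell_bounds"] = tuple(doc["dwell_bounds"])
    return SimConfig(**doc)
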