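"""Synthetic data generators for every analysis stage in the package.

The central object is a burst-level generative model of a pulsed-interleaved
excitation (PIE / ALEX) confocal experiment on a freely diffusing, doubly
labeled protein dimer at ~100 pM: single molecules transit the focus one at a
time and emit a compact packet ("burst") of photons which are detected in
three useful photon classes,

* ``f_DD`` — donor excitation, donor emission,
* ``f_DA`` — donor excitation, acceptor emission,
* ``f_AA`` — acceptor excitation, acceptor emission.

Bursts are *state-pure*: a molecule keeps one conformational state (one FRET
efficiency) for the whole transit, which is the regime in which an efficiency
histogram shows static, well-separated peaks.  Within a burst the per-channel
counts are Poisson with means

.. math::

    \\mu_{DD} = B(1-E), \\qquad
    \\mu_{DA} = B\\gamma E + Lk\\,f_{DD} + Di\\,f_{AA}, \\qquad
    \\mu_{AA} = B\\rho,

where ``B`` is the per-burst donor-excitation brightness, ``gamma`` the
acceptor/donor detection-efficiency ratio, ``Lk`` donor leakage, ``Di``
acceptor direct excitation and ``rho`` the relative acceptor-excitation
brightness.  By construction the standard correction formula
``E = (f_DA - Lk f_DD - Di f_AA) / (... + gamma f_DD)`` recovers the true
efficiency in expectation, and with ``gamma=1, Lk=Di=0`` the plain proximity
ratio ``f_DA/(f_DD+f_DA)`` is unbiased.

Ground-truth burst labels are carried in a sidecar table (``PhotonStream.truth``)
that analysis code never reads; it exists for tests only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "SpeciesSpec",
    "SimConfig",
    "PhotonStream",
    "RulerSet",
    "simulate_bursts",
    "simulate_titration",
    "simulate_rulers",
    "simulate_saxs_curve",
    "simulate_fcs_pair",
    "two_state_config",
]

DOUBLY = "doubly-labeled"
DONOR_ONLY = "donor-only"
ACCEPTOR_ONLY = "acceptor-only"
_KINDS = (DOUBLY, DONOR_ONLY, ACCEPTOR_ONLY)


@dataclass(frozen=True)
class SpeciesSpec:
    """One molecular species in the simulated sample.

    ``true_E`` is the FRET efficiency before any instrumental distortion and
    is only meaningful for doubly labeled species.  ``weight`` is the fraction
    of bursts drawn from this species; weights of a mixture must sum to 1.
    """

    label: str
    kind: str = DOUBLY
    true_E: float = 0.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown species kind {self.kind!r}")
        if not 0.0 <= self.true_E <= 1.0:
            raise ConfigurationError(f"true_E must lie in [0, 1], got {self.true_E}")
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigurationError(f"weight must lie in [0, 1], got {self.weight}")


@dataclass
class SimConfig:
    """Acquisition-level parameters of a simulated PIE measurement.

    Defaults emulate the study conditions the analysis is designed for:
    ~100 pM doubly labeled dimer (burst rate ~10 s^-1 in a confocal spot),
    1 ms binning, mean burst size ~60 detected photons, and modest uniform
    background in each detection channel.
    """

    species: list[SpeciesSpec] = field(default_factory=list)
    burst_rate: float = 10.0          # bursts / s
    burst_size_mean: float = 60.0     # mean detected photons per burst
    burst_size_dist: str = "geometric"
    burst_duration: float = 2e-3      # s, transit time through the focus
    background_rates: tuple[float, float, float] = (300.0, 300.0, 300.0)  # DD, DA, AA c/s
    gamma: float = 1.0
    leakage_Lk: float = 0.0
    direct_Di: float = 0.0
    aex_brightness: float = 1.0       # acceptor-excitation brightness relative to B
    bin_width: float = 1e-3           # s
    duration: float = 60.0            # s
    seed: int = 0

    def validate(self) -> None:
        if not self.species:
            raise ConfigurationError("species list is empty")
        total = sum(s.weight for s in self.species)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"species weights sum to {total}, expected 1")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be positive")
        if self.burst_duration <= 0:
            raise ConfigurationError("burst_duration must be positive")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")
        if self.leakage_Lk < 0 or self.direct_Di < 0:
            raise ConfigurationError("leakage_Lk and direct_Di must be >= 0")
        if self.burst_rate < 0 or any(r < 0 for r in self.background_rates):
            raise ConfigurationError("rates must be >= 0")
        if self.burst_size_dist not in ("geometric", "lognormal"):
            raise ConfigurationError(f"unknown burst size distribution {self.burst_size_dist!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = [dataclasses.asdict(s) for s in self.species]
        return d


@dataclass
class PhotonStream:
    """Excitation- and channel-tagged photon timestamps.

    ``excitation`` and ``channel`` hold one-letter tags ('D' or 'A') per
    photon.  ``truth`` is a test-only sidecar table of ground-truth burst
    intervals and species labels; analysis code must never consume it.
    """

    timestamps: np.ndarray
    excitation: np.ndarray
    channel: np.ndarray
    meta: dict = field(default_factory=dict)
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.excitation = np.asarray(self.excitation, dtype="U1")
        self.channel = np.asarray(self.channel, dtype="U1")
        n = self.timestamps.size
        if self.excitation.size != n or self.channel.size != n:
            raise ValueError("tag arrays must match timestamps in length")
        if n and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be nondecreasing")
        bad = ~np.isin(self.excitation, ("D", "A")) | ~np.isin(self.channel, ("D", "A"))
        if np.any(bad):
            raise ValueError("tags must be 'D' or 'A'")

    @property
    def n_photons(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        if "duration" in self.meta:
            return float(self.meta["duration"])
        return float(self.timestamps[-1]) if self.n_photons else 0.0

    def select(self, excitation: str, channel: str) -> np.ndarray:
        """Timestamps of one photon class, e.g. ``select('A', 'A')`` for f_AA."""
        mask = (self.excitation == excitation) & (self.channel == channel)
        return self.timestamps[mask]


@dataclass
class RulerSet:
    """Calibration streams: doubly labeled DNA rulers plus single-label controls."""

    doubly: list[PhotonStream]
    donor_only: PhotonStream
    acceptor_only: PhotonStream
    true_E: list[float]


def _burst_sizes(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    # B is the donor-excitation brightness scale; total detected photons per
    # burst is ~B * ((1-E) + gamma*E + rho) ~ 2B, hence mean B = size/2.
    mean_b = max(cfg.burst_size_mean / 2.0, 1.0)
    if cfg.burst_size_dist == "geometric":
        return rng.geometric(min(1.0, 1.0 / mean_b), size=n).astype(float)
    sigma = 0.5
    return rng.lognormal(np.log(mean_b) - sigma**2 / 2.0, sigma, size=n)


def simulate_bursts(config: SimConfig, rng: np.random.Generator | None = None) -> PhotonStream:
    """Simulate one PIE acquisition and return the tagged photon stream.

    Burst start times are a Poisson process, burst sizes follow the configured
    distribution, one species is drawn per burst (state-pure bursts) and
    per-channel counts follow the Poisson model in the module docstring.
    Background photons are added as homogeneous Poisson noise per channel.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_bursts = rng.poisson(config.burst_rate * config.duration)
    t_max = max(config.duration - config.burst_duration, 0.0)
    starts = np.sort(rng.uniform(0.0, t_max, size=n_bursts))
    weights = np.array([s.weight for s in config.species])
    sp_idx = rng.choice(len(config.species), size=n_bursts, p=weights)

    kinds = np.array([s.kind for s in config.species])
    e_arr = np.array([s.true_E for s in config.species])
    has_d = np.isin(kinds, (DOUBLY, DONOR_ONLY)).astype(float)[sp_idx]
    has_a = np.isin(kinds, (DOUBLY, ACCEPTOR_ONLY)).astype(float)[sp_idx]
    is_doubly = (kinds == DOUBLY).astype(float)[sp_idx]
    E = e_arr[sp_idx] * is_doubly

    B = _burst_sizes(rng, n_bursts, config)
    f_dd = rng.poisson(B * (1.0 - E) * has_d)
    f_aa = rng.poisson(B * config.aex_brightness * has_a)
    f_fret = rng.poisson(B * config.gamma * E * is_doubly)
    f_leak = rng.poisson(config.leakage_Lk * f_dd)
    f_dir = rng.poisson(config.direct_Di * f_aa)
    f_da = f_fret + f_leak + f_dir

    # Assemble photon records class by class, then time-sort.
    times, excs, chans = [], [], []
    for counts, exc, chan in ((f_dd, "D", "D"), (f_da, "D", "A"), (f_aa, "A", "A")):
        tot = int(counts.sum())
        if tot:
            t0 = np.repeat(starts, counts)
            times.append(t0 + rng.uniform(0.0, config.burst_duration, size=tot))
            excs.append(np.full(tot, exc, dtype="U1"))
            chans.append(np.full(tot, chan, dtype="U1"))
    for rate, exc, chan in zip(config.background_rates, ("D", "D", "A"), ("D", "A", "A")):
        nb = rng.poisson(rate * config.duration)
        if nb:
            times.append(rng.uniform(0.0, config.duration, size=nb))
            excs.append(np.full(nb, exc, dtype="U1"))
            chans.append(np.full(nb, chan, dtype="U1"))

    if times:
        t = np.concatenate(times)
        order = np.argsort(t, kind="stable")
        t = t[order]
        exc = np.concatenate(excs)[order]
        chan = np.concatenate(chans)[order]
    else:  # pragma: no cover - zero-rate corner
        t = np.empty(0)
        exc = np.empty(0, dtype="U1")
        chan = np.empty(0, dtype="U1")

    truth = pd.DataFrame(
        {
            "start": starts,
            "stop": starts + config.burst_duration,
            "label": np.array([s.label for s in config.species])[sp_idx],
            "kind": kinds[sp_idx],
            "true_E": E,
            "f_dd": f_dd,
            "f_da": f_da,
            "f_aa": f_aa,
        }
    )
    meta = config.to_dict()
    meta["n_true_bursts"] = int(n_bursts)
    return PhotonStream(t, exc, chan, meta=meta, truth=truth)


def two_state_config(
    e_states: tuple[float, float] = (0.30, 0.62),
    low_fraction: float = 0.58,
    doubly_fraction: float = 0.75,
    donor_only_fraction: float = 0.15,
    **overrides,
) -> SimConfig:
    """Convenience builder for a two-conformation dimer sample.

    ``low_fraction`` is the population of the low-E state *among doubly
    labeled bursts*; ``doubly_fraction`` is the doubly labeled share of all
    bursts, the remainder being donor-only / acceptor-only contaminants that
    the PIE sorting stage is supposed to remove.
    """
    acceptor_only_fraction = 1.0 - doubly_fraction - donor_only_fraction
    if acceptor_only_fraction < -1e-12:
        raise ConfigurationError("doubly + donor-only fractions exceed 1")
    e_lo, e_hi = sorted(e_states)
    species = [
        SpeciesSpec("state1", DOUBLY, e_lo, doubly_fraction * low_fraction),
        SpeciesSpec("state2", DOUBLY, e_hi, doubly_fraction * (1.0 - low_fraction)),
    ]
    if donor_only_fraction > 0:
        species.append(SpeciesSpec("donor-only", DONOR_ONLY, 0.0, donor_only_fraction))
    if acceptor_only_fraction > 1e-12:
        species.append(SpeciesSpec("acceptor-only", ACCEPTOR_ONLY, 0.0, acceptor_only_fraction))
    # renormalize against float rounding
    total = sum(s.weight for s in species)
    species = [dataclasses.replace(s, weight=s.weight / total) for s in species]
    return SimConfig(species=species, **overrides)


def isotherm_fraction(L, kd: float, f0: float, fmax: float):
    """One-site binding isotherm f(L) = f0 + (fmax - f0) * L / (KD + L)."""
    L = np.asarray(L, dtype=float)
    return f0 + (fmax - f0) * L / (kd + L)


def simulate_titration(
    config: SimConfig,
    concentrations,
    kd: float,
    enriched_label: str = "state1",
    w_max: float = 0.95,
) -> list[PhotonStream]:
    """Simulate one photon stream per ligand concentration.

    At total ligand concentration ``L`` the enriched conformational state's
    weight (within the doubly labeled pair) follows the one-site isotherm
    ``w(L) = w0 + (w_max - w0) L / (KD + L)``; free ligand is approximated by
    total ligand because the receptor is ~100 pM.  Streams are split from one
    root seed, so the series is reproducible as a whole.
    """
    if kd <= 0:
        raise ConfigurationError("KD must be positive")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations < 0):
        raise ConfigurationError("concentrations must be >= 0")
    config.validate()

    labels = [s.label for s in config.species]
    if enriched_label not in labels:
        raise ConfigurationError(f"no species labeled {enriched_label!r}")
    doubly = [s for s in config.species if s.kind == DOUBLY]
    if len(doubly) != 2:
        raise ConfigurationError("titration requires exactly two doubly-labeled states")
    enriched = next(s for s in doubly if s.label == enriched_label)
    other = next(s for s in doubly if s.label != enriched_label)
    d_tot = enriched.weight + other.weight
    w0 = enriched.weight / d_tot

    seeds = np.random.SeedSequence(config.seed).spawn(len(concentrations))
    streams = []
    for L, seq in zip(concentrations, seeds):
        w = float(isotherm_fraction(L, kd, w0, w_max))
        species = []
        for s in config.species:
            if s.label == enriched.label:
                species.append(dataclasses.replace(s, weight=d_tot * w))
            elif s.label == other.label:
                species.append(dataclasses.replace(s, weight=d_tot * (1.0 - w)))
            else:
                species.append(s)
        cfg = dataclasses.replace(config, species=species)
        stream = simulate_bursts(cfg, rng=np.random.default_rng(seq))
        stream.meta["concentration"] = float(L)
        stream.meta["true_enriched_weight"] = w
        stream.meta["kd_true"] = float(kd)
        streams.append(stream)
    return streams


def simulate_rulers(
    config: SimConfig,
    true_E_list,
    contaminant_fraction: float = 0.0,
) -> RulerSet:
    """Simulate DNA-ruler calibration streams sharing one (gamma, Lk, Di).

    Returns one stream per ruler efficiency plus dedicated donor-only and
    acceptor-only streams (the real calibration protocol prepares those by
    annealing with excess unlabeled strand).
    """
    true_E_list = list(true_E_list)
    if len(true_E_list) < 2:
        raise ConfigurationError("gamma determination needs >= 2 ruler E values")
    seeds = np.random.SeedSequence(config.seed).spawn(len(true_E_list) + 2)
    doubly_streams = []
    for e, seq in zip(true_E_list, seeds):
        species = [SpeciesSpec(f"ruler-E{e:.2f}", DOUBLY, e, 1.0 - contaminant_fraction)]
        if contaminant_fraction > 0:
            species.append(SpeciesSpec("donor-only", DONOR_ONLY, 0.0, contaminant_fraction))
        cfg = dataclasses.replace(config, species=species)
        doubly_streams.append(simulate_bursts(cfg, rng=np.random.default_rng(seq)))
    d_cfg = dataclasses.replace(config, species=[SpeciesSpec("donor-only", DONOR_ONLY)])
    a_cfg = dataclasses.replace(config, species=[SpeciesSpec("acceptor-only", ACCEPTOR_ONLY)])
    donor_stream = simulate_bursts(d_cfg, rng=np.random.default_rng(seeds[-2]))
    acceptor_stream = simulate_bursts(a_cfg, rng=np.random.default_rng(seeds[-1]))
    return RulerSet(doubly_streams, donor_stream, acceptor_stream, true_E_list)


def simulate_saxs_curve(
    shape: str,
    geometry: dict,
    I0: float = 1.0,
    noise: float = 0.01,
    q=None,
    seed: int | None = 0,
    noise_slope: float = 3.0,
):
    """Simulate a noisy small-angle scattering curve from a geometric body.

    ``shape`` is one of ``sphere`` (analytic form factor), ``prolate-ellipsoid``
    or ``dumbbell`` (exact Debye sum over an auto-generated bead model).
    Relative noise grows linearly from ``noise`` at the first q point to
    ``noise * (1 + noise_slope)`` at the last, mimicking the loss of signal at
    wide angles; the sigma column always holds the noise model actually used.
    With ``noise=0`` no noise is added but sigma is populated at the 1% level
    so downstream chi^2 weighting stays defined.
    """
    from . import saxs  # deferred: saxs does not import simulate

    if q is None:
        q = np.linspace(0.01, 0.35, 300)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(np.diff(q) <= 0):
        raise ConfigurationError("q grid must be positive and ascending")

    if shape == "sphere":
        R = float(geometry["radius"])
        if R <= 0:
            raise ConfigurationError("radius must be positive")
        I = saxs.sphere_intensity(q, R)
        dmax = 2 * R
    elif shape in ("prolate-ellipsoid", "ellipsoid"):
        a, b = float(geometry["a"]), float(geometry["b"])
        if a <= 0 or b <= 0:
            raise ConfigurationError("semi-axes must be positive")
        beads = saxs.ellipsoid_beads(a, b, b, spacing=geometry.get("spacing"))
        I = saxs.debye_intensity(q, beads)
        dmax = 2 * max(a, b)
    elif shape in ("dumbbell", "dumbbell-of-spheres"):
        R = float(geometry["radius"])
        sep = float(geometry["separation"])
        if R <= 0 or sep < 0:
            raise ConfigurationError("radius must be positive and separation >= 0")
        beads = saxs.dumbbell_beads(R, sep, spacing=geometry.get("spacing"))
        I = saxs.debye_intensity(q, beads)
        dmax = sep + 2 * R
    else:
        raise ConfigurationError(f"unknown shape {shape!r}")

    I = I0 * I  # form factors are normalized to 1 at q = 0, so I(0) = I0
    rel0 = noise if noise > 0 else 0.01
    rel = rel0 * (1.0 + noise_slope * (q - q[0]) / (q[-1] - q[0]))
    # additive floor ~ background-subtraction noise: sigma never vanishes at
    # form-factor zero crossings
    sigma = rel * np.abs(I) + rel0 * 1e-3 * I0
    if noise > 0:
        rng = np.random.default_rng(seed)
        I = I + rng.normal(0.0, sigma)
    meta = {"shape": shape, "geometry": dict(geometry), "true_dmax": dmax, "I0": I0}
    return saxs.SaxsCurve(q=q, I=I, sigma=sigma, meta=meta)


def simulate_fcs_pair(
    mean_rates: tuple[float, float] = (1e4, 1e4),
    correlation_time: float = 1e-3,
    contrast: float = 0.5,
    duration: float = 60.0,
    seed: int | None = 0,
) -> PhotonStream:
    """Two photon channels driven by one shared fluctuating intensity.

    Both channels are Poisson with rate ``r_c (1 + a s(t))`` where ``s(t)`` is
    a shared symmetric random telegraph (flip rate ``1/(2 tc)``) and
    ``a = sqrt(contrast)``.  The normalized cross-correlation is then exactly

        G(tau) - 1 = contrast * exp(-tau / correlation_time),

    which gives the correlator and decay-fit stages an analytic ground truth.
    Channel 1 photons are tagged (A, A) and channel 2 photons (D, D), matching
    the acceptor/donor channels a dual-color cross-correlation consumes.
    """
    if correlation_time <= 0:
        raise ConfigurationError("correlation_time must be positive")
    if not 0.0 <= contrast <= 1.0:
        raise ConfigurationError("contrast must lie in [0, 1]")
    if any(r <= 0 for r in mean_rates) or duration <= 0:
        raise ConfigurationError("rates and duration must be positive")
    rng = np.random.default_rng(seed)
    a = np.sqrt(contrast)

    # Telegraph segments covering [0, duration].
    flip_rate = 1.0 / (2.0 * correlation_time)
    n_guess = int(flip_rate * duration * 1.5 + 20)
    gaps = rng.exponential(1.0 / flip_rate, size=n_guess)
    while gaps.sum() < duration:  # pragma: no cover - rare top-up
        gaps = np.concatenate([gaps, rng.exponential(1.0 / flip_rate, size=n_guess)])
    edges = np.concatenate([[0.0], np.cumsum(gaps)])
    edges = edges[edges < duration]
    edges = np.concatenate([edges, [duration]])
    seg_len = np.diff(edges)
    s0 = rng.choice([-1.0, 1.0])
    states = s0 * (-1.0) ** np.arange(seg_len.size)

    times, excs, chans = [], [], []
    for rate, tag in zip(mean_rates, ("A", "D")):
        lam = rate * (1.0 + a * states) * seg_len
        counts = rng.poisson(lam)
        tot = int(counts.sum())
        t = np.repeat(edges[:-1], counts) + rng.uniform(0, 1, tot) * np.repeat(seg_len, counts)
        times.append(t)
        excs.append(np.full(tot, tag, dtype="U1"))
        chans.append(np.full(tot, tag, dtype="U1"))
    t = np.concatenate(times)
    order = np.argsort(t, kind="stable")
    meta = {
        "duration": duration,
        "mean_rates": tuple(float(r) for r in mean_rates),
        "correlation_time": correlation_time,
        "contrast": contrast,
        "seed": seed,
    }
    return PhotonStream(
        t[order], np.concatenate(excs)[order], np.concatenate(chans)[order], meta=meta
    )
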