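"""Synthetic sleep data with known gating ground truth.

The restricted clinical cohort behind the REM-gating analysis cannot be
redistributed, so this module generates the three ingredients every
downstream stage needs, with ground truth the tests can score against:

* hypnograms — continuous-time stage bout sequences with exponential bout
  durations and Markov stage transitions, the substrate for REM continuity
  (mean bout duration);
* EEG-like epochs — a slow oscillation carrying spindle-band bursts whose
  occurrence phase is von Mises distributed (concentration ``kappa`` is the
  coupling ground truth) on top of 1/f-shaped background noise (exponent
  ``chi`` is the aperiodic ground truth);
* two-group cohort feature tables — "epic dreamer" rows shifted below
  matched controls by configurable standardized effect sizes on each of the
  three oriented gating features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats, optimize
from scipy.special import expit

from .exceptions import InvalidConfigError

__all__ = [
    "STAGES",
    "Bout",
    "Hypnogram",
    "EpochSignal",
    "CouplingGroundTruth",
    "CohortConfig",
    "generate_hypnogram",
    "synthesize_coupled_epoch",
    "synthesize_coupled_epoch_with_events",
    "generate_cohort_features",
    "powerlaw_noise",
    "vector_length_for_kappa",
    "kappa_for_vector_length",
]

STAGES = ("W", "N1", "N2", "N3", "REM")

#: Control-like mean bout durations in seconds, one per stage.
DEFAULT_STAGE_MEAN_BOUTS: dict[str, float] = {
    "W": 90.0,
    "N1": 60.0,
    "N2": 600.0,
    "N3": 480.0,
    "REM": 900.0,
}

#: Plausible adult night-time stage transition weights (rows need not sum to 1).
DEFAULT_TRANSITION_WEIGHTS: dict[str, dict[str, float]] = {
    "W": {"N1": 0.8, "N2": 0.15, "REM": 0.05},
    "N1": {"W": 0.2, "N2": 0.7, "REM": 0.1},
    "N2": {"W": 0.1, "N1": 0.15, "N3": 0.45, "REM": 0.3},
    "N3": {"W": 0.1, "N1": 0.1, "N2": 0.8},
    "REM": {"W": 0.2, "N1": 0.3, "N2": 0.5},
}

_CONTIGUITY_TOL = 1e-6


@dataclass(frozen=True)
class Bout:
    """One contiguous run of a single sleep stage."""

    stage: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise InvalidConfigError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.onset < 0:
            raise InvalidConfigError("bout onset must be >= 0")
        if not self.duration > 0:
            raise InvalidConfigError("bout duration must be > 0")


@dataclass
class Hypnogram:
    """Ordered, contiguous, non-overlapping sequence of stage bouts.

    Bouts live in continuous time (seconds); no 30-s epoch grid is imposed.
    """

    bouts: list[Bout]

    def __post_init__(self) -> None:
        if not self.bouts:
            raise InvalidConfigError("hypnogram needs at least one bout")
        for prev, nxt in zip(self.bouts, self.bouts[1:]):
            if abs(nxt.onset - (prev.onset + prev.duration)) > _CONTIGUITY_TOL:
                raise InvalidConfigError(
                    f"bouts must be contiguous: bout at {nxt.onset} does not "
                    f"follow bout ending at {prev.onset + prev.duration}"
                )

    @property
    def total_duration(self) -> float:
        last = self.bouts[-1]
        return last.onset + last.duration - self.bouts[0].onset

    def stage_durations(self, stage: str) -> np.ndarray:
        return np.array([b.duration for b in self.bouts if b.stage == stage])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "stage": [b.stage for b in self.bouts],
                "onset_s": [b.onset for b in self.bouts],
                "duration_s": [b.duration for b in self.bouts],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Hypnogram":
        df = pd.read_csv(path, sep="\t")
        required = {"stage", "onset_s", "duration_s"}
        if not required.issubset(df.columns):
            raise InvalidConfigError(f"hypnogram TSV must have columns {sorted(required)}")
        return cls(
            [Bout(str(r.stage), float(r.onset_s), float(r.duration_s)) for r in df.itertuples()]
        )


@dataclass
class EpochSignal:
    """A sampled single-channel signal with its rate and stage label."""

    samples: np.ndarray
    fs: float
    channel: str = "C3-C4"
    stage: str = "REM"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidConfigError("fs must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 2 * self.fs:
            raise InvalidConfigError("epoch must be 1-D with at least 2*fs samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.txt`` (one sample per line, round-trip exact) and
        ``<prefix>.json`` metadata sidecar."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".txt"), self.samples, fmt="%.17g")
        meta = {"fs": self.fs, "channel": self.channel, "stage": self.stage}
        prefix.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True))

    @classmethod
    def load(cls, prefix: str | Path) -> "EpochSignal":
        prefix = Path(prefix)
        samples = np.loadtxt(prefix.with_suffix(".txt"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(samples=samples, fs=float(meta["fs"]), channel=meta["channel"], stage=meta["stage"])


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_hypnogram(
    stage_mean_bouts: Mapping[str, float] | None = None,
    transition_weights: Mapping[str, Mapping[str, float]] | None = None,
    total_s: float = 8 * 3600.0,
    seed: int | np.random.Generator | None = None,
    start_stage: str = "W",
) -> Hypnogram:
    """Simulate a night as a Markov chain over stages with exponential bouts.

    Consecutive visits to the same stage are merged into one bout, so a
    transition matrix that always returns to the current stage produces a
    single bout covering the whole night. The final bout is truncated so the
    hypnogram covers exactly ``total_s`` seconds.
    """
    means = dict(DEFAULT_STAGE_MEAN_BOUTS if stage_mean_bouts is None else stage_mean_bouts)
    weights = DEFAULT_TRANSITION_WEIGHTS if transition_weights is None else transition_weights
    if total_s <= 0:
        raise InvalidConfigError("total_s must be > 0")
    for stage, m in means.items():
        if not m > 0:
            raise InvalidConfigError(f"mean bout duration for {stage!r} must be > 0, got {m}")
    for stage, row in weights.items():
        if stage not in means:
            raise InvalidConfigError(f"transition row for {stage!r} has no mean bout duration")
        vals = np.array(list(row.values()), dtype=float)
        if (vals < 0).any() or vals.sum() <= 0:
            raise InvalidConfigError(f"transition weights for {stage!r} must be >= 0 and sum > 0")

    rng = _as_rng(seed)
    current = start_stage if start_stage in weights else next(iter(weights))
    t = 0.0
    bouts: list[Bout] = []
    while t < total_s - _CONTIGUITY_TOL:
        dur = float(rng.exponential(means[current]))
        dur = min(dur, total_s - t)
        if bouts and bouts[-1].stage == current:
            prev = bouts.pop()
            bouts.append(Bout(current, prev.onset, prev.duration + dur))
        else:
            bouts.append(Bout(current, t, dur))
        t += dur
        if t >= total_s - _CONTIGUITY_TOL:
            break
        row = weights[current]
        names = list(row)
        p = np.array([row[s] for s in names], dtype=float)
        current = names[rng.choice(len(names), p=p / p.sum())]
    return Hypnogram(bouts)


@dataclass(frozen=True)
class CouplingGroundTruth:
    """Generator parameters for one coupled epoch.

    ``kappa`` is the von Mises concentration of spindle-burst phases around
    ``preferred_phase`` (phase 0 = SO positive peak); ``aperiodic_exponent``
    is the background-noise 1/f exponent chi with PSD proportional to
    f**(-chi).
    """

    kappa: float
    preferred_phase: float = 0.0
    so_freq: float = 0.75
    spindle_band: tuple[float, float] = (11.0, 16.0)
    aperiodic_exponent: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.spindle_band
        if self.kappa < 0:
            raise InvalidConfigError("kappa must be >= 0")
        if not lo < hi:
            raise InvalidConfigError("spindle_band must satisfy lo < hi")
        if not self.so_freq < lo:
            raise InvalidConfigError("so_freq must lie below the spindle band")
        if self.aperiodic_exponent < 0:
            raise InvalidConfigError("aperiodic exponent chi must be >= 0")


def powerlaw_noise(n: int, chi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise whose PSD falls off as f**(-chi) (chi=0: white).

    Realized by shaping the rFFT amplitudes of white Gaussian noise by
    f**(-chi/2); the DC bin is zeroed.
    """
    white = rng.standard_normal(n)
    if chi == 0:
        x = white - white.mean()
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n)
        scale = np.zeros_like(f)
        scale[1:] = f[1:] ** (-chi / 2.0)
        x = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _draw_burst_phases(truth: CouplingGroundTruth, size: int, rng: np.random.Generator) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    if truth.kappa == 0:
        ph = rng.uniform(-np.pi, np.pi, size)
    else:
        ph = stats.vonmises.rvs(truth.kappa, loc=truth.preferred_phase, size=size, random_state=rng)
    # wrap to (-pi, pi]
    return -np.mod(-ph + np.pi, 2 * np.pi) + np.pi


def synthesize_coupled_epoch_with_events(
    truth: CouplingGroundTruth,
    duration_s: float = 300.0,
    fs: float = 256.0,
    snr: float = 5.0,
    seed: int | np.random.Generator | None = None,
    burst_prob: float = 0.5,
    spindle_amplitude: float = 0.75,
    spindle_duration_s: float = 1.0,
    channel: str = "C3-C4",
) -> tuple[EpochSignal, np.ndarray, np.ndarray]:
    """Like :func:`synthesize_coupled_epoch` but also return the ground-truth
    burst centre times and SO phases (for detector recall / coupling oracles).
    """
    lo, hi = truth.spindle_band
    if fs < 4 * hi:
        raise InvalidConfigError(f"fs={fs} below 4x the spindle-band upper edge ({hi} Hz)")
    if duration_s < 30:
        raise InvalidConfigError("duration_s must be >= 30 s")

    rng = _as_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    # cosine carrier: analytic-signal phase is 0 at the SO positive peak
    so = np.cos(2 * np.pi * truth.so_freq * t)

    n_cycles = int(np.floor(duration_s * truth.so_freq))
    has_burst = rng.random(n_cycles) < burst_prob
    phases_all = _draw_burst_phases(truth, n_cycles, rng)

    spindles = np.zeros(n)
    f_c = 0.5 * (lo + hi)
    n_pkt = int(round(spindle_duration_s * fs))
    window = np.hanning(n_pkt)
    times: list[float] = []
    phases: list[float] = []
    for k in range(n_cycles):
        if not has_burst[k]:
            continue
        phi = phases_all[k]
        frac = np.mod(phi, 2 * np.pi) / (2 * np.pi)
        t_c = (k + frac) / truth.so_freq
        i_c = int(round(t_c * fs))
        i0 = i_c - n_pkt // 2
        i1 = i0 + n_pkt
        if i0 < 0 or i1 > n:
            continue
        seg = np.arange(i0, i1) / fs - t_c
        spindles[i0:i1] += spindle_amplitude * window * np.cos(2 * np.pi * f_c * seg)
        times.append(t_c)
        phases.append(phi)

    signal = so + spindles
    if snr is not None and np.isfinite(snr):
        noise = powerlaw_noise(n, truth.aperiodic_exponent, rng)
        noise *= np.sqrt(np.mean(so**2)) / snr
        signal = signal + noise
    epoch = EpochSignal(samples=signal, fs=fs, channel=channel, stage="REM")
    return epoch, np.array(times), np.array(phases)


def synthesize_coupled_epoch(
    truth: CouplingGroundTruth,
    duration_s: float = 300.0,
    fs: float = 256.0,
    snr: float = 5.0,
    seed: int | np.random.Generator | None = None,
    **kwargs,
) -> EpochSignal:
    """Slow oscillation + phase-coupled spindle bursts + 1/f background.

    Spindle bursts are Hann-windowed packets at the spindle-band centre
    frequency, at most one per SO cycle (occurring with ``burst_prob``),
    placed so the SO phase at the packet centre is a von Mises
    (``preferred_phase``, ``kappa``) draw; kappa=0 gives uniform phases.
    ``snr`` is the RMS ratio of the slow oscillation to the background noise.
    """
    epoch, _, _ = synthesize_coupled_epoch_with_events(
        truth, duration_s=duration_s, fs=fs, snr=snr, seed=seed, **kwargs
    )
    return epoch


def vector_length_for_kappa(kappa: float) -> float:
    """Population mean resultant length of a von Mises(kappa): I1(kappa)/I0(kappa)."""
    if kappa < 0:
        raise InvalidConfigError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_for_vector_length(r: float) -> float:
    """Numerical inverse of :func:`vector_length_for_kappa` on r in [0, 1)."""
    if not 0 <= r < 1:
        raise InvalidConfigError("vector length must be in [0, 1)")
    if r == 0:
        return 0.0
    return float(optimize.brentq(lambda k: vector_length_for_kappa(k) - r, 1e-8, 1e4))


FEATURE_NAMES = ("coupling_vl", "rem_mean_bout_min", "one_over_f_steepness")

FEATURE_CSV_COLUMNS = ["subject_id", "group", "channel", *FEATURE_NAMES]


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort generator settings.

    ``feature_means``/``feature_sds`` parameterize the control group; the
    coupling entries are interpreted on the logit scale for the SD (values
    are drawn as Gaussians on the logit scale and back-transformed, so the
    downstream logit transform is exactly variance-stabilizing), while the
    coupling mean is given on the natural [0, 1] scale. ``effect_sizes`` are
    standardized control-minus-epic shifts, applied on the drawing scale of
    each oriented feature (positive = epic dreamers lower = looser gating).
    """

    n_control: int = 4
    n_epic: int = 4
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {f: 1.0 for f in FEATURE_NAMES}
    )
    feature_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "coupling_vl": 0.45,
            "rem_mean_bout_min": 15.0,
            "one_over_f_steepness": 2.5,
        }
    )
    feature_sds: Mapping[str, float] = field(
        default_factory=lambda: {
            "coupling_vl": 0.35,  # logit scale
            "rem_mean_bout_min": 4.0,
            "one_over_f_steepness": 0.5,
        }
    )
    channel: str = "C3-C4"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_epic < 2:
            raise InvalidConfigError("group sizes must be >= 2")
        for name in FEATURE_NAMES:
            if name not in self.feature_means or name not in self.feature_sds:
                raise InvalidConfigError(f"feature_means/feature_sds must include {name!r}")
            if not self.feature_sds[name] > 0:
                raise InvalidConfigError(f"SD for {name!r} must be > 0")
            if name not in self.effect_sizes:
                raise InvalidConfigError(f"effect_sizes must include {name!r}")
        if not 0 < self.feature_means["coupling_vl"] < 1:
            raise InvalidConfigError("control coupling mean must lie in (0, 1)")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p) - np.log1p(-p)


def generate_cohort_features(config: CohortConfig) -> pd.DataFrame:
    """Draw the per-subject gating feature table for a two-group cohort.

    Control rows come from the configured Gaussians (coupling on the logit
    scale, then back-transformed); epic rows are shifted down by
    ``effect_size * SD`` on each feature's drawing scale. Reproducible given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    mu_logit = _logit(config.feature_means["coupling_vl"])
    for group, n_rows, prefix in (
        ("control", config.n_control, "C"),
        ("epic", config.n_epic, "E"),
    ):
        shift = 0.0 if group == "control" else 1.0
        logit_vals = rng.normal(
            mu_logit - shift * config.effect_sizes["coupling_vl"] * config.feature_sds["coupling_vl"],
            config.feature_sds["coupling_vl"],
            n_rows,
        )
        coupling = expit(logit_vals)
        bout = rng.normal(
            config.feature_means["rem_mean_bout_min"]
            - shift * config.effect_sizes["rem_mean_bout_min"] * config.feature_sds["rem_mean_bout_min"],
            config.feature_sds["rem_mean_bout_min"],
            n_rows,
        )
        if (bout < 0).any():
            warnings.warn("negative REM mean bout durations clipped to 0", stacklevel=2)
            bout = np.clip(bout, 0.0, None)
        steep = rng.normal(
            config.feature_means["one_over_f_steepness"]
            - shift
            * config.effect_sizes["one_over_f_steepness"]
            * config.feature_sds["one_over_f_steepness"],
            config.feature_sds["one_over_f_steepness"],
            n_rows,
        )
        for i in range(n_rows):
            rows.append(
                {
                    "subject_id": f"{prefix}{i + 1:02d}",
                    "group": group,
                    "channel": config.channel,
                    "coupling_vl": coupling[i],
                    "rem_mean_bout_min": bout[i],
                    "one_over_f_steepness": steep[i],
                }
            )
    return pd.DataFrame(rows, columns=FEATURE_CSV_COLUMNS)
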