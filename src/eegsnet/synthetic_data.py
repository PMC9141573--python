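"""Synthetic sleep EEG with the statistical structure the classifier exploits.

Each stage has an oscillatory recipe built from the scoring conventions of
clinical sleep staging: Wake is dominated by alpha (8–13 Hz) active for more
than half the epoch; N1 by low-amplitude mixed-frequency activity (4–7 Hz);
N2 carries 12–14 Hz spindle bursts of 0.5–1.5 s on a mixed background; N3 by
high-amplitude slow waves (0.5–2 Hz); REM by low-amplitude mixed 4–8 Hz
activity.  N1 and REM deliberately overlap spectrally — they are the pair
that single-epoch classifiers confuse — so that the transition structure of
the hypnogram carries real information, which is exactly what the sequence
model is supposed to learn.

Hypnograms are sampled from a first-order Markov chain whose default
transition matrix is ordinally constrained by the transition statistics of
real overnight recordings: wakefulness moves to N1 far more often than
straight to REM, and N1 feeds N2 far more often than REM does.

Band-limited components are synthesised as sums of random-phase sinusoids
within the band, gated by a duty-cycle envelope, plus broadband Gaussian
noise; per-subject amplitude scaling emulates inter-subject gain variability.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signal_io import (
    Recording,
    SleepEpoch,
    Stage,
    StageLabel,
    STAGE_ORDER,
    write_edf,
    write_hypnogram_csv,
)

__all__ = [
    "BandComponent",
    "StageRecipe",
    "TransitionModel",
    "SyntheticSubject",
    "DEFAULT_RECIPES",
    "DEFAULT_TRANSITIONS",
    "sample_hypnogram",
    "synth_epoch",
    "generate_dataset",
    "export_dataset",
]

EPOCH_SECONDS = 30.0


@dataclass(frozen=True)
class BandComponent:
    """One band-limited oscillation: frequency band, amplitude, duty cycle."""

    low_hz: float
    high_hz: float
    amplitude: float  # microvolts (relative scale)
    duty: float = 1.0  # fraction of the epoch the band is active

    def __post_init__(self) -> None:
        if not 0.0 < self.low_hz <= self.high_hz <= 32.0:
            raise ValueError(f"band must lie in (0, 32] Hz: {self.low_hz}-{self.high_hz}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if not 0.0 < self.duty <= 1.0:
            raise ValueError("duty must be in (0, 1]")


@dataclass(frozen=True)
class StageRecipe:
    """Spectral recipe for one stage: components plus broadband noise level."""

    stage: Stage
    components: tuple[BandComponent, ...]
    noise_sd: float = 5.0
    spindles: bool = False  # N2: add 2–4 discrete 12–14 Hz bursts


#: Amplitudes and noise levels are package constants chosen so the stages are
#: separable but not trivially; bands and duty cycles follow the scoring
#: conventions quoted in the module docstring.
DEFAULT_RECIPES: dict[Stage, StageRecipe] = {
    Stage.W: StageRecipe(
        Stage.W,
        (BandComponent(8.0, 13.0, amplitude=30.0, duty=0.8),),
        noise_sd=8.0,
    ),
    Stage.N1: StageRecipe(
        Stage.N1,
        (BandComponent(4.0, 7.0, amplitude=14.0, duty=0.95),),
        noise_sd=8.0,
    ),
    Stage.N2: StageRecipe(
        Stage.N2,
        (BandComponent(4.0, 10.0, amplitude=18.0, duty=0.9),),
        noise_sd=6.0,
        spindles=True,
    ),
    Stage.N3: StageRecipe(
        Stage.N3,
        (BandComponent(0.5, 2.0, amplitude=90.0, duty=0.9),),
        noise_sd=10.0,
    ),
    # REM's theta core is deliberately identical to N1's — the pair real
    # scorers separate mainly by context — with only a faint high-theta tail
    # near the broadband noise floor distinguishing it within an epoch.
    Stage.REM: StageRecipe(
        Stage.REM,
        (
            BandComponent(4.0, 7.0, amplitude=14.0, duty=0.95),
            BandComponent(7.0, 8.0, amplitude=1.0, duty=1.0),
        ),
        noise_sd=8.0,
    ),
}


@dataclass
class TransitionModel:
    """First-order Markov model over (W, N1, N2, N3, REM)."""

    matrix: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.initial = np.asarray(self.initial, dtype=np.float64)
        if self.matrix.shape != (5, 5) or self.initial.shape != (5,):
            raise ValueError("transition matrix must be 5×5 with a 5-vector initial")
        if (self.matrix < 0).any() or (self.initial < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")


#: Entries are package defaults, ordinally constrained by overnight transition
#: statistics: P(W→N1) ≫ P(W→REM) and P(N1→N2) ≫ P(REM→N2).
DEFAULT_TRANSITIONS = TransitionModel(
    matrix=np.array(
        [
            # W     N1     N2     N3     REM
            [0.900, 0.085, 0.005, 0.000, 0.010],  # W
            [0.090, 0.600, 0.280, 0.000, 0.030],  # N1
            [0.020, 0.030, 0.850, 0.060, 0.040],  # N2
            [0.010, 0.000, 0.080, 0.900, 0.010],  # N3
            [0.030, 0.050, 0.020, 0.000, 0.900],  # REM
        ]
    ),
    initial=np.array([1.0, 0.0, 0.0, 0.0, 0.0]),
)


@dataclass
class SyntheticSubject:
    """One simulated night: hypnogram plus the matching recording."""

    subject_id: str
    hypnogram: list[Stage]
    recording: Recording

    def epochs(self) -> list[SleepEpoch]:
        n = int(round(EPOCH_SECONDS * self.recording.sample_rate))
        return [
            SleepEpoch(
                subject_id=self.subject_id,
                epoch_index=i,
                samples=self.recording.samples[i * n : (i + 1) * n],
                label=StageLabel(stage, stage.name),
                sample_rate=self.recording.sample_rate,
            )
            for i, stage in enumerate(self.hypnogram)
        ]


def sample_hypnogram(
    n_epochs: int,
    tm: TransitionModel | None = None,
    seed: int | np.random.Generator = 0,
) -> list[Stage]:
    """Sample a Markov hypnogram of ``n_epochs`` stages."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    tm = tm or DEFAULT_TRANSITIONS
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.empty(n_epochs, dtype=np.int64)
    states[0] = rng.choice(5, p=tm.initial)
    for t in range(1, n_epochs):
        states[t] = rng.choice(5, p=tm.matrix[states[t - 1]])
    return [STAGE_ORDER[s] for s in states]


def _band_oscillation(
    comp: BandComponent, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random-phase sinusoid comb across the band, gated by a duty envelope."""
    freqs = np.arange(comp.low_hz, comp.high_hz + 1e-9, 0.5)
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    weights = rng.uniform(0.5, 1.0, size=len(freqs))
    weights /= np.sqrt((weights**2).sum() / 2.0)  # unit-RMS comb
    x = (weights[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None])).sum(
        axis=0
    )
    if comp.duty < 1.0:
        active = comp.duty * (t[-1] - t[0])
        start = rng.uniform(0, (t[-1] - t[0]) - active)
        env = ((t - t[0]) >= start) & ((t - t[0]) < start + active)
        x = x * env
    return comp.amplitude * x


def _spindle_bursts(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """2–4 sleep-spindle bursts: 12–14 Hz, 0.5–1.5 s, Hann envelope."""
    out = np.zeros_like(t)
    for _ in range(rng.integers(2, 5)):
        dur = rng.uniform(0.5, 1.5)
        start = rng.uniform(0, (t[-1] - t[0]) - dur)
        freq = rng.uniform(12.0, 14.0)
        mask = ((t - t[0]) >= start) & ((t - t[0]) < start + dur)
        tt = t[mask]
        env = np.hanning(len(tt)) if len(tt) > 1 else np.ones(len(tt))
        out[mask] += 30.0 * env * np.sin(2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi))
    return out


def synth_epoch(
    stage: Stage,
    rate: float = 100.0,
    seed: int | np.random.Generator = 0,
    recipes: dict[Stage, StageRecipe] | None = None,
    gain: float = 1.0,
) -> np.ndarray:
    """Synthesise one 30-s epoch of the given stage at ``rate`` Hz."""
    recipes = DEFAULT_RECIPES if recipes is None else recipes
    if stage not in recipes:
        raise ValueError(f"no recipe for stage {stage!r}")
    recipe = recipes[stage]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(EPOCH_SECONDS * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    for comp in recipe.components:
        x += _band_oscillation(comp, t, rng)
    if recipe.spindles:
        x += _spindle_bursts(t, rng)
    x += rng.normal(0.0, recipe.noise_sd, size=n)
    return gain * x


def generate_dataset(
    n_subjects: int,
    epochs_per_subject: int,
    rate: float = 100.0,
    seed: int = 0,
    tm: TransitionModel | None = None,
    recipes: dict[Stage, StageRecipe] | None = None,
    gain_range: tuple[float, float] = (0.7, 1.4),
) -> list[SyntheticSubject]:
    """Generate ``n_subjects`` labelled synthetic nights, reproducibly.

    Per-subject amplitude gain is drawn from ``gain_range`` to emulate
    inter-subject variability (the preprocessing is amplitude-invariant, so
    this stresses the pipeline without changing the class structure).
    """
    if n_subjects < 1 or epochs_per_subject < 1:
        raise ValueError("n_subjects and epochs_per_subject must be positive")
    root = np.random.SeedSequence(seed)
    out = []
    for i, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        gain = rng.uniform(*gain_range)
        hypnogram = sample_hypnogram(epochs_per_subject, tm, rng)
        samples = np.concatenate(
            [
                synth_epoch(stage, rate, rng, recipes, gain)
                for stage in hypnogram
            ]
        )
        out.append(
            SyntheticSubject(
                subject_id=f"syn{i:03d}",
                hypnogram=hypnogram,
                recording=Recording(
                    subject_id=f"syn{i:03d}",
                    channel="EEG Fpz-Cz",
                    sample_rate=rate,
                    samples=samples,
                ),
            )
        )
    return out


def export_dataset(subjects: list[SyntheticSubject], out_dir: str | Path) -> list[Path]:
    """Write each subject as an EDF file plus a hypnogram CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for subj in subjects:
        edf = out_dir / f"{subj.subject_id}.edf"
        csv = out_dir / f"{subj.subject_id}-hypnogram.csv"
        phys = float(np.abs(subj.recording.samples).max() * 1.05 + 1.0)
        write_edf(edf, subj.recording, physical_range=(-phys, phys))
        write_hypnogram_csv(
            csv,
            [
                (i * EPOCH_SECONDS, EPOCH_SECONDS, stage.name)
                for i, stage in enumerate(subj.hypnogram)
            ],
        )
        written += [edf, csv]
    return written
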