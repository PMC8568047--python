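"""Seeded synthetic cohorts with known ground truth.

Emulates the statistical structure of source-extracted calcium traces and
1 s-binned swim tracking, so the analysis pipeline can be exercised against
known class labels, habituation decay constants, and escape dynamics.

Trace model
-----------
Each ROI carries a sensitivity class from {dim, checker, both, none}. For
every stimulus event matching the class (looms match every non-none class;
dims match {dim, both}; checkerboards match {checker, both}), a transient of
amplitude ``A * exp(-c * (k - 1))`` is injected, where ``k`` is the 1-based
index of that event among same-kind events and ``c`` is the ROI's
habituation decay constant. Transients are the event's expansion-period
indicator convolved with the causal calcium kernel; i.i.d. Gaussian noise is
added on top. Because transients superpose linearly, a ``both``-class ROI's
noiseless trace equals the sum of the matching dim-class and checker-class
traces — there is no loom-specific component, mirroring the additive
luminance + motion structure the analysis is designed to detect.

Behavior model
--------------
Per-fish, per-second distances. Baseline bins are a drift/scoot mixture
(80% drift ~ |N(0.1, 0.1)| mm/s, 20% scoot ~ U(0.5, 5) mm/s). On an escape
draw (per-stimulus Bernoulli with kind-specific, possibly habituating
probability), one bin inside the response window is given a speed > 30 mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stimulus import (
    DEFAULT_KERNEL_TAU_S,
    DEFAULT_RATE_HZ,
    Regressor,
    StimulusEvent,
    StimulusKind,
    StimulusTrain,
    _exp_kernel,
    build_train,
)

__all__ = [
    "REGIONS",
    "GroundTruthRoi",
    "BehaviorRecord",
    "CohortConfig",
    "SyntheticCohort",
    "generate_trace",
    "generate_cohort",
    "generate_behavior",
    "LoomEscapeModel",
    "ConstantEscapeModel",
]

REGIONS = (
    "pallium",
    "subpallium",
    "thalamus",
    "habenula",
    "pretectum",
    "tectum",
    "tegmentum",
    "cerebellum",
    "hindbrain",
)

CLASSES = ("dim", "checker", "both", "none")

# Which stimulus kinds drive each sensitivity class. Looms drive every
# responsive class: their luminance component recruits dim-sensitive ROIs and
# their moving edges recruit checkerboard-sensitive ROIs.
_CLASS_KINDS: dict[str, frozenset[StimulusKind]] = {
    "dim": frozenset({StimulusKind.DIM, StimulusKind.LOOM}),
    "checker": frozenset({StimulusKind.CHECKERBOARD, StimulusKind.LOOM}),
    "both": frozenset({StimulusKind.DIM, StimulusKind.CHECKERBOARD, StimulusKind.LOOM}),
    "none": frozenset(),
}

# Region priors per class: the dual-sensitivity population concentrates in
# tectum; dim sensitivity sits in habenula/thalamus/tectum; checkerboard and
# non-responsive ROIs are spread broadly.
_REGION_PRIORS: dict[str, dict[str, float]] = {
    "both": {"tectum": 0.55, "pretectum": 0.10, "thalamus": 0.10},
    "dim": {"habenula": 0.25, "thalamus": 0.25, "tectum": 0.25, "pallium": 0.10},
    "checker": {"tectum": 0.20, "hindbrain": 0.15, "cerebellum": 0.10, "thalamus": 0.10},
    "none": {},
}


@dataclass(frozen=True)
class GroundTruthRoi:
    """Ground truth for one simulated ROI."""

    roi_id: int
    fish_id: int
    region: str
    centroid: tuple[float, float, float]
    label: str  # sensitivity class: dim / checker / both / none
    amplitude: float  # response size, z units
    decay_c: float  # per-presentation habituation rate
    noise_sd: float  # trace noise, z units

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.decay_c < 0:
            raise ValueError("decay_c must be >= 0")
        if self.label == "none" and self.amplitude != 0:
            raise ValueError("class 'none' requires amplitude 0")


@dataclass(frozen=True)
class BehaviorRecord:
    """Per-second distance bins for one fish in one stimulus train."""

    fish_id: int
    bins_mm: np.ndarray  # distance moved in each 1 s bin
    train_id: str = "train0"

    def __post_init__(self) -> None:
        arr = np.asarray(self.bins_mm, dtype=float)
        if np.any(arr < 0):
            raise ValueError("distances must be >= 0")
        object.__setattr__(self, "bins_mm", arr)


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults: 11 fish (the imaging cohort size), 500 ROIs per fish, response
    amplitude 3 z, trace noise sd 1 z, habituation constants ~ U(0.2, 1.2).
    The default class mixture makes responsive ROIs a minority (14%) with
    checkerboard-sensitive ROIs ~4x as common as dim-sensitive ones and
    dual-sensitive ROIs in between, mirroring the relative abundances seen
    in whole-brain recordings where most extracted sources are not visually
    driven.
    """

    n_fish: int = 11
    rois_per_fish: int = 500
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"dim": 0.02, "checker": 0.08, "both": 0.04, "none": 0.86}
    )
    amplitude: float = 3.0
    amplitude_jitter: float = 0.0  # multiplicative lognormal sd; 0 = fixed
    noise_sd: float = 1.0
    decay_c_range: tuple[float, float] = (0.2, 1.2)
    class_decay_c: Mapping[str, float] | None = None  # fixed per-class c overrides
    rate_hz: float = DEFAULT_RATE_HZ
    kernel_tau_s: float = DEFAULT_KERNEL_TAU_S
    protocol: str = "imaging3_component"

    def __post_init__(self) -> None:
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture must sum to 1, got {total}")
        unknown = set(self.class_mixture) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in mixture: {unknown}")


@dataclass
class SyntheticCohort:
    """A generated cohort: ground truth, trace matrix, behavior, and train."""

    rois: list[GroundTruthRoi]
    traces: pd.DataFrame  # index roi_id, columns sample indices
    behavior: list[BehaviorRecord]
    train: StimulusTrain
    seed: int
    config: CohortConfig

    @property
    def roi_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": [r.roi_id for r in self.rois],
                "fish_id": [r.fish_id for r in self.rois],
                "region": [r.region for r in self.rois],
                "x": [r.centroid[0] for r in self.rois],
                "y": [r.centroid[1] for r in self.rois],
                "z": [r.centroid[2] for r in self.rois],
                "label": [r.label for r in self.rois],
                "amplitude": [r.amplitude for r in self.rois],
                "decay_c": [r.decay_c for r in self.rois],
                "noise_sd": [r.noise_sd for r in self.rois],
            }
        ).set_index("roi_id")

    def write(self, outdir: str | Path) -> None:
        """Write traces.csv (long), rois.csv, behavior.csv, train.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fish_of = {r.roi_id: r.fish_id for r in self.rois}
        long = self.traces.stack().rename("value").reset_index()
        long.columns = ["roi_id", "sample_index", "value"]
        long.insert(1, "fish_id", long["roi_id"].map(fish_of))
        long.to_csv(outdir / "traces.csv", index=False)
        self.roi_table.to_csv(outdir / "rois.csv")
        rows = []
        for rec in self.behavior:
            for sec, d in enumerate(rec.bins_mm):
                rows.append((rec.fish_id, sec, d))
        pd.DataFrame(rows, columns=["fish_id", "second", "distance_mm"]).to_csv(
            outdir / "behavior.csv", index=False
        )
        self.train.to_json(outdir / "train.json")


def _noiseless_trace(
    roi_label: str,
    amplitude: float,
    decay_c: float,
    train: StimulusTrain,
    rate_hz: float,
    kernel_tau_s: float,
    n_samples: int,
) -> np.ndarray:
    t = np.arange(n_samples) / rate_hz
    kernel = _exp_kernel(kernel_tau_s, rate_hz)
    trace = np.zeros(n_samples)
    kinds = _CLASS_KINDS[roi_label]
    if not kinds or amplitude == 0:
        return trace
    # k counts presentations per kind: habituation decays within each kind
    kind_counter: dict[StimulusKind, int] = {}
    for ev in train.events:
        if ev.kind not in kinds:
            continue
        k = kind_counter.get(ev.kind, 0)
        kind_counter[ev.kind] = k + 1
        amp = amplitude * np.exp(-decay_c * k)
        indicator = np.zeros(n_samples)
        indicator[(t >= ev.onset_s) & (t < ev.onset_s + ev.expand_s)] = amp
        trace += np.convolve(indicator, kernel)[:n_samples]
    return trace


def generate_trace(
    roi: GroundTruthRoi,
    train: StimulusTrain,
    rate_hz: float = DEFAULT_RATE_HZ,
    seed: int = 0,
    kernel_tau_s: float = DEFAULT_KERNEL_TAU_S,
) -> np.ndarray:
    """One ROI's raw trace: habituating kernel transients plus Gaussian noise."""
    n_samples = int(np.ceil(train.total_duration_s * rate_hz))
    trace = _noiseless_trace(
        roi.label, roi.amplitude, roi.decay_c, train, rate_hz, kernel_tau_s, n_samples
    )
    rng = np.random.default_rng(seed)
    return trace + rng.normal(0.0, roi.noise_sd, size=n_samples)


def _sample_region(label: str, rng: np.random.Generator) -> str:
    prior = _REGION_PRIORS[label]
    rest = [r for r in REGIONS if r not in prior]
    probs = [prior.get(r, 0.0) for r in REGIONS]
    leftover = 1.0 - sum(probs)
    for r in rest:
        probs[REGIONS.index(r)] = leftover / len(rest)
    return str(rng.choice(REGIONS, p=probs))


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full multi-fish cohort: ROIs, traces, behavior, train.

    Deterministic for a fixed seed. Class labels are i.i.d. draws from the
    configured mixture; regions are drawn from class-specific priors
    (both-class enriched in tectum, dim-class in habenula/thalamus/tectum).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    train = build_train(config.protocol, seed=int(rng.integers(2**31)))

    labels = list(config.class_mixture.keys())
    probs = np.array([config.class_mixture[c] for c in labels], dtype=float)

    rois: list[GroundTruthRoi] = []
    roi_id = 0
    for fish in range(config.n_fish):
        for _ in range(config.rois_per_fish):
            label = str(rng.choice(labels, p=probs))
            if label == "none":
                amp = 0.0
            elif config.amplitude_jitter > 0:
                amp = float(
                    config.amplitude * rng.lognormal(0.0, config.amplitude_jitter)
                )
            else:
                amp = config.amplitude
            if config.class_decay_c is not None and label in config.class_decay_c:
                c = float(config.class_decay_c[label])
            else:
                c = float(rng.uniform(*config.decay_c_range))
            rois.append(
                GroundTruthRoi(
                    roi_id=roi_id,
                    fish_id=fish,
                    region=_sample_region(label, rng),
                    centroid=tuple(rng.uniform(0, 500, size=3)),
                    label=label,
                    amplitude=amp,
                    decay_c=c,
                    noise_sd=config.noise_sd,
                )
            )
            roi_id += 1

    n_samples = int(np.ceil(train.total_duration_s * config.rate_hz))
    mat = np.empty((len(rois), n_samples))
    for i, roi in enumerate(rois):
        mat[i] = generate_trace(
            roi,
            train,
            rate_hz=config.rate_hz,
            seed=int(rng.integers(2**31)),
            kernel_tau_s=config.kernel_tau_s,
        )
    traces = pd.DataFrame(mat, index=pd.Index([r.roi_id for r in rois], name="roi_id"))

    behavior = generate_behavior(
        config.n_fish, train, LoomEscapeModel(), seed=int(rng.integers(2**31))
    )
    return SyntheticCohort(
        rois=rois, traces=traces, behavior=behavior, train=train, seed=seed, config=config
    )


@dataclass(frozen=True)
class LoomEscapeModel:
    """Habituating escape probability: p_k = p0 * exp(-lam*(k-1)) + floor for
    looms; constant for checkerboards; near-zero for dims."""

    p0: float = 0.8
    lam: float = 0.25
    floor: float = 0.0
    p_checker: float = 0.35
    p_dim: float = 0.02

    def probability(self, kind: StimulusKind, k: int) -> float:
        if kind is StimulusKind.LOOM:
            return min(1.0, self.p0 * float(np.exp(-self.lam * (k - 1))) + self.floor)
        if kind is StimulusKind.CHECKERBOARD:
            return self.p_checker
        return self.p_dim


@dataclass(frozen=True)
class ConstantEscapeModel:
    """Fixed escape probability per stimulus kind (no habituation)."""

    p: Mapping[str, float] | float = 0.35

    def probability(self, kind: StimulusKind, k: int) -> float:
        if isinstance(self.p, Mapping):
            return float(self.p.get(kind.value, 0.0))
        return float(self.p)


def generate_behavior(
    n_fish: int,
    train: StimulusTrain,
    response_model,
    seed: int = 0,
    *,
    window_s: float | None = None,
) -> list[BehaviorRecord]:
    """Per-fish, per-second distances with seeded stochastic escapes.

    ``response_model.probability(kind, k)`` gives the escape probability for
    the k-th presentation (1-based, counted per kind). Must lie in [0, 1].
    Escapes place one >30 mm/s bin inside the response window (default: the
    expansion period). Baseline bins are an 80/20 drift/scoot mixture.
    """
    rng = np.random.default_rng(seed)
    n_seconds = int(np.ceil(train.total_duration_s))
    records: list[BehaviorRecord] = []
    for fish in range(n_fish):
        # baseline drift/scoot mixture
        is_scoot = rng.random(n_seconds) < 0.2
        drift = np.abs(rng.normal(0.1, 0.1, size=n_seconds))
        scoot = rng.uniform(0.5, 5.0, size=n_seconds)
        bins = np.where(is_scoot, scoot, drift)
        kind_counter: dict[StimulusKind, int] = {}
        for ev in train.events:
            k = kind_counter.get(ev.kind, 0) + 1
            kind_counter[ev.kind] = k
            p = response_model.probability(ev.kind, k)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"escape probability {p} outside [0, 1]")
            if rng.random() < p:
                win = ev.expand_s if window_s is None else window_s
                lo = int(ev.onset_s)
                hi = min(int(np.ceil(ev.onset_s + win)), n_seconds)
                pos = int(rng.integers(lo, hi))
                bins[pos] = rng.uniform(35.0, 80.0)
        records.append(BehaviorRecord(fish_id=fish, bins_mm=bins))
    return records
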