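"""Visual stimulus trains and calcium-kernel regressors.

Three stimulus kinds are modeled: a dark expanding disc (``loom``), an
expanding isoluminant checkerboard (``checkerboard``; moving edges with no
net luminance change), and a whole-field dimming (``dim``). Every stimulus
expands hyperbolically to its maximum over ``expand_s`` seconds and then
fades linearly back to the background over ``fade_s`` seconds.

The hyperbolic rise is the standard looming-angle profile of an object of
half-size *r* approaching at speed *v*::

    theta(t) = 2 * atan(r / (v * (t_max - t)))

normalized so the profile runs from ~0 at onset to 1 at ``t_max``
(= onset + expand_s). The ratio r/v is chosen so the angle reaches 99% of
its maximum exactly at ``t_max``, which pins the curve shape without any
free parameter.

Regressors for trace regression are built by marking each event's expansion
period on the imaging clock and convolving with a causal single-exponential
calcium kernel ``exp(-t/tau)``, matching a first-order model of nuclear
GCaMP6s decay (default tau = 3.5 s).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StimulusKind",
    "StimulusEvent",
    "StimulusTrain",
    "Regressor",
    "PROTOCOLS",
    "stimulus_profile",
    "build_train",
    "build_regressor",
]

DEFAULT_RATE_HZ = 2.0
DEFAULT_KERNEL_TAU_S = 3.5
BEHAVIOR_ISI_CHOICES_S = (20.0, 25.0, 30.0, 35.0)
IMAGING_ISI_S = 20.0
IMAGING_BASELINE_S = 30.0


class StimulusKind(str, Enum):
    LOOM = "loom"
    CHECKERBOARD = "checkerboard"
    DIM = "dim"


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation: kind, onset, and expansion/fade geometry."""

    kind: StimulusKind
    onset_s: float
    expand_s: float = 5.0
    fade_s: float = 15.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", StimulusKind(self.kind))
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.expand_s <= 0:
            raise ValueError(f"expand_s must be > 0, got {self.expand_s}")
        if self.fade_s < 0:
            raise ValueError(f"fade_s must be >= 0, got {self.fade_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.expand_s + self.fade_s


@dataclass(frozen=True)
class StimulusTrain:
    """Ordered stimulus events plus the ISI schedule that generated them."""

    events: tuple[StimulusEvent, ...]
    isi_schedule_s: tuple[float, ...]
    total_duration_s: float
    protocol: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "isi_schedule_s", tuple(self.isi_schedule_s))
        onsets = [e.onset_s for e in events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        if events and self.total_duration_s < events[-1].end_s:
            raise ValueError("total_duration_s shorter than the last event")

    def __len__(self) -> int:
        return len(self.events)

    def events_of_kind(self, kinds: Iterable[StimulusKind | str]) -> list[StimulusEvent]:
        wanted = {StimulusKind(k) for k in kinds}
        return [e for e in self.events if e.kind in wanted]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "protocol": self.protocol,
            "seed": self.seed,
            "total_duration_s": self.total_duration_s,
            "isi_schedule_s": list(self.isi_schedule_s),
            "events": [
                {
                    "kind": e.kind.value,
                    "onset_s": e.onset_s,
                    "expand_s": e.expand_s,
                    "fade_s": e.fade_s,
                }
                for e in self.events
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusTrain":
        payload = json.loads(Path(path).read_text())
        events = tuple(
            StimulusEvent(
                kind=StimulusKind(e["kind"]),
                onset_s=e["onset_s"],
                expand_s=e["expand_s"],
                fade_s=e["fade_s"],
            )
            for e in payload["events"]
        )
        return cls(
            events=events,
            isi_schedule_s=tuple(payload.get("isi_schedule_s", ())),
            total_duration_s=payload["total_duration_s"],
            protocol=payload.get("protocol"),
            seed=payload.get("seed"),
        )


@dataclass(frozen=True)
class Regressor:
    """A stimulus time course sampled on the imaging clock.

    ``samples`` are nonnegative; length equals ceil(duration * rate).
    """

    samples: np.ndarray
    rate_hz: float = DEFAULT_RATE_HZ
    kernel_tau_s: float = DEFAULT_KERNEL_TAU_S

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if np.any(arr < -1e-12):
            raise ValueError("regressor samples must be nonnegative")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate_hz


def _hyperbolic_rise(frac: np.ndarray) -> np.ndarray:
    """Normalized looming-angle profile on frac = (t - onset)/expand_s in [0, 1].

    theta(t) = 2 atan(r / (v (t_max - t))), normalized by theta(t_max-) where
    r/v is set so theta reaches 99% of theta_max (= pi, a full half-field) at
    t_max. Clipped at t_max.
    """
    # theta_max is pi (object fills the visual field). Solve for r/v with
    # expand time 1: 2*atan(rv / (1 - f)) -> 0.99*pi at f -> 1 means we instead
    # anchor: theta(1) would diverge, so anchor at f just below 1. Use the
    # conventional closed form: choose rv so that theta(0) / theta_cap = 1%.
    # theta(f) = 2*atan(rv / (1 - f)) for f < 1, capped at theta_cap where
    # theta_cap = 0.99 * pi; profile = min(theta, theta_cap) / theta_cap.
    theta_cap = 0.99 * math.pi
    # cap at 99% of a full half-field; rv fixes the initial angle at 1% of
    # the cap so the rise starts from a near-point object
    rv = math.tan(0.005 * theta_cap)
    frac = np.asarray(frac, dtype=float)
    with np.errstate(divide="ignore"):
        theta = 2.0 * np.arctan(np.where(frac < 1.0, rv / (1.0 - frac), np.inf))
    theta = np.minimum(theta, theta_cap)
    # subtract the (tiny) initial angle so the profile starts exactly at 0
    theta0 = 2.0 * math.atan(rv)
    prof = (theta - theta0) / (theta_cap - theta0)
    return np.clip(prof, 0.0, 1.0)


def stimulus_profile(event: StimulusEvent, t: float | np.ndarray) -> float | np.ndarray:
    """Normalized stimulus intensity/size in [0, 1] at time(s) ``t``.

    Zero before onset; hyperbolic-approach rise from 0 at onset to 1 at
    onset + expand_s; linear fade to 0 over fade_s; zero afterwards.
    Negative times are a domain error.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    rel = t_arr - event.onset_s
    out = np.zeros_like(t_arr, dtype=float)

    rising = (rel >= 0) & (rel < event.expand_s)
    if np.any(rising):
        out[rising] = _hyperbolic_rise(rel[rising] / event.expand_s)
    at_max = np.isclose(rel, event.expand_s) | (rel == event.expand_s)
    out[at_max & (rel >= 0)] = 1.0

    if event.fade_s > 0:
        fading = (rel > event.expand_s) & (rel < event.expand_s + event.fade_s)
        out[fading] = 1.0 - (rel[fading] - event.expand_s) / event.fade_s
    out[rel >= event.expand_s + event.fade_s] = 0.0
    if event.fade_s == 0:
        out[rel > event.expand_s] = 0.0

    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


# Protocol table. Each entry: (event kinds in order, isi mode)
# isi mode: "behavior" = random from {20,25,30,35}; "imaging20" = fixed 20 s;
# "imaging2" = 60 s spacing with a 300 s break between the two triplets.
def _block(kind: str, n: int) -> list[str]:
    return [kind] * n


PROTOCOLS: dict[str, dict] = {
    # 20 of one kind then 10 looms, randomized ISI
    "behavior_loom": {"kinds": _block("loom", 20) + _block("loom", 10), "isi": "behavior"},
    "behavior_checker": {
        "kinds": _block("checkerboard", 20) + _block("loom", 10),
        "isi": "behavior",
    },
    "behavior_dim": {"kinds": _block("dim", 20) + _block("loom", 10), "isi": "behavior"},
    # imaging dataset 1: 10 of one kind then 5 looms, fixed 20 s ISI
    "imaging1_loom": {"kinds": _block("loom", 10) + _block("loom", 5), "isi": "imaging20"},
    "imaging1_checker": {
        "kinds": _block("checkerboard", 10) + _block("loom", 5),
        "isi": "imaging20",
    },
    "imaging1_dim": {"kinds": _block("dim", 10) + _block("loom", 5), "isi": "imaging20"},
    # imaging dataset 2: dim, checker, loom spaced 1 min, 5 min break, repeat
    "imaging2_sequence": {
        "kinds": ["dim", "checkerboard", "loom"] * 2,
        "isi": "imaging2",
    },
    # imaging dataset 3: d,c,d,c flank block, 10 looms, flank block again
    "imaging3_component": {
        "kinds": ["dim", "checkerboard", "dim", "checkerboard"]
        + _block("loom", 10)
        + ["dim", "checkerboard", "dim", "checkerboard"],
        "isi": "imaging20",
    },
}


def build_train(
    protocol: str,
    seed: int = 0,
    *,
    expand_s: float = 5.0,
    fade_s: float = 15.0,
    baseline_s: float | None = None,
) -> StimulusTrain:
    """Construct the stimulus train for a named protocol.

    Behavioral protocols draw each ISI uniformly from {20, 25, 30, 35} s with
    a seeded generator; imaging protocols use a fixed 20 s ISI (the paired
    dim/checker/loom sequence uses 60 s spacing and a 300 s mid-train break).
    Imaging trains start with 30 s of baseline before the first onset;
    behavioral trains with 300 s (5 min of no stimulus).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(
            f"unknown protocol {protocol!r}; choose from {sorted(PROTOCOLS)}"
        )
    spec = PROTOCOLS[protocol]
    kinds = spec["kinds"]
    n = len(kinds)
    rng = np.random.default_rng(seed)

    if spec["isi"] == "behavior":
        isis = [float(rng.choice(BEHAVIOR_ISI_CHOICES_S)) for _ in range(n - 1)]
        first_onset = 300.0 if baseline_s is None else baseline_s
    elif spec["isi"] == "imaging20":
        isis = [IMAGING_ISI_S] * (n - 1)
        first_onset = IMAGING_BASELINE_S if baseline_s is None else baseline_s
    elif spec["isi"] == "imaging2":
        # 60 s onset-to-onset gaps minus the stimulus footprint, 300 s break
        # between the third and fourth stimuli
        footprint = expand_s + fade_s
        isis = [60.0 - footprint] * (n - 1)
        isis[2] = 300.0 - footprint
        first_onset = IMAGING_BASELINE_S if baseline_s is None else baseline_s
    else:  # pragma: no cover
        raise AssertionError(spec["isi"])

    events: list[StimulusEvent] = []
    onset = first_onset
    for i, kind in enumerate(kinds):
        events.append(
            StimulusEvent(kind=StimulusKind(kind), onset_s=onset, expand_s=expand_s, fade_s=fade_s)
        )
        if i < n - 1:
            onset += expand_s + fade_s + isis[i]
    total = events[-1].end_s + 10.0  # short tail after the final fade
    return StimulusTrain(
        events=tuple(events),
        isi_schedule_s=tuple(isis),
        total_duration_s=total,
        protocol=protocol,
        seed=seed,
    )


def _exp_kernel(tau_s: float, rate_hz: float) -> np.ndarray:
    """Causal exponential kernel exp(-t/tau) sampled at rate_hz, truncated at 8 tau."""
    n = max(1, int(math.ceil(8.0 * tau_s * rate_hz)))
    t = np.arange(n) / rate_hz
    return np.exp(-t / tau_s)


def build_regressor(
    train: StimulusTrain,
    kind_filter: Iterable[StimulusKind | str],
    kernel_tau_s: float = DEFAULT_KERNEL_TAU_S,
    rate_hz: float = DEFAULT_RATE_HZ,
    *,
    convolve: bool = True,
) -> Regressor:
    """Stimulus regressor: expansion-period indicator convolved with the kernel.

    The driving signal is 1 during each matching event's expansion period and
    0 otherwise; events superpose linearly. With ``convolve=False`` the raw
    indicator is returned (for regression against the un-smoothed time
    course).
    """
    kinds = {StimulusKind(k) for k in kind_filter}
    if not kinds:
        raise ValueError("kind_filter must not be empty")
    if kernel_tau_s <= 0:
        raise ValueError("kernel_tau_s must be > 0")
    n_samples = int(math.ceil(train.total_duration_s * rate_hz))
    t = np.arange(n_samples) / rate_hz
    indicator = np.zeros(n_samples)
    for ev in train.events_of_kind(kinds):
        indicator[(t >= ev.onset_s) & (t < ev.onset_s + ev.expand_s)] = 1.0
    if convolve:
        kernel = _exp_kernel(kernel_tau_s, rate_hz)
        samples = np.convolve(indicator, kernel)[:n_samples]
    else:
        samples = indicator
    return Regressor(samples=samples, rate_hz=rate_hz, kernel_tau_s=kernel_tau_s)
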