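"""Experimental paradigm, hemodynamic response, and between-shot handlers.

The BOLD effect is modelled as a change of the gray-matter transverse
relaxation rate, delta-R2* (Hz), inside an activation ROI.  At echo time TE
the linearised contrast update is

    mu_BOLD(t) = (1 - TE * dR2s * h(t)) * mu_GM,

with h the paradigm convolved with a canonical double-gamma HRF and
normalised to a unit peak.  Handlers apply such updates to the phantom
state between consecutive shots; they are pure functions of (initial
state, shot index, time), so any shot can be replayed or computed in
parallel without changing the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .phantom import Phantom, RoiMask, gre_contrast

__all__ = [
    "Paradigm",
    "HemodynamicSignal",
    "BoldSpec",
    "PhantomState",
    "BoldHandler",
    "HandlerChain",
    "block_paradigm",
    "hemodynamic_signal",
    "double_gamma_hrf",
    "bold_contrast",
    "apply_handlers",
    "make_phantom_state",
    "paradigm_to_events_tsv",
    "paradigm_from_events_tsv",
]


@dataclass(frozen=True)
class Paradigm:
    """Task events as (onset_s, duration_s, amplitude) within a run."""

    events: tuple[tuple[float, float, float], ...]
    run_length: float

    def __post_init__(self):
        if self.run_length <= 0:
            raise ValueError("run_length must be positive")
        for onset, dur, _ in self.events:
            if onset < 0 or onset + dur > self.run_length + 1e-9:
                raise ValueError("events must lie within [0, run_length]")

    def boxcar(self, times: np.ndarray) -> np.ndarray:
        out = np.zeros_like(times, dtype=np.float64)
        for onset, dur, amp in self.events:
            out[(times >= onset) & (times < onset + dur)] += amp
        return out


@dataclass
class HemodynamicSignal:
    """Normalised hemodynamic response sampled once per shot."""

    times: np.ndarray  # s
    values: np.ndarray  # dimensionless, peak 1 when any event exists

    def at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))


@dataclass(frozen=True)
class BoldSpec:
    """BOLD modulation: delta-R2* in Hz (negative = signal increase at TE)."""

    delta_r2s: float  # Hz
    TE: float  # ms
    roi: RoiMask
    linearize: bool = True

    def __post_init__(self):
        if abs(self.TE * 1e-3 * self.delta_r2s) >= 1:
            raise ValueError("TE * delta-R2* too large for the linearised model")


# Canonical double-gamma HRF parameters (SPM-like): response peak ~6 s,
# undershoot ~16 s, undershoot ratio 1/6.
HRF_PARAMS = {
    "peak_delay": 6.0,
    "undershoot_delay": 16.0,
    "peak_disp": 1.0,
    "undershoot_disp": 1.0,
    "undershoot_ratio": 1.0 / 6.0,
    "duration": 32.0,
}


def double_gamma_hrf(t: np.ndarray, params: dict | None = None) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times t (s), zero for t < 0."""
    p = dict(HRF_PARAMS, **(params or {}))
    t = np.asarray(t, dtype=np.float64)
    h = _gamma_dist.pdf(t, p["peak_delay"] / p["peak_disp"], scale=p["peak_disp"])
    h = h - p["undershoot_ratio"] * _gamma_dist.pdf(
        t, p["undershoot_delay"] / p["undershoot_disp"], scale=p["undershoot_disp"]
    )
    h[t < 0] = 0.0
    return h


def block_paradigm(on_s: float, off_s: float, run_length: float) -> Paradigm:
    """Alternating rest/task blocks, rest first, truncated at run_length."""
    if on_s <= 0 or off_s <= 0:
        raise ValueError("block durations must be positive")
    if run_length <= 0:
        raise ValueError("run_length must be positive")
    events = []
    t = off_s
    while t < run_length:
        dur = min(on_s, run_length - t)
        events.append((t, dur, 1.0))
        t += on_s + off_s
    return Paradigm(events=tuple(events), run_length=run_length)


def hemodynamic_signal(
    paradigm: Paradigm,
    TR_shot: float,
    hrf_kind: str = "double-gamma",
    hrf_params: dict | None = None,
) -> HemodynamicSignal:
    """Boxcar(events) * HRF, sampled every TR_shot (ms), peak rescaled to 1."""
    if TR_shot <= 0:
        raise ValueError("TR_shot must be positive")
    if hrf_kind != "double-gamma":
        raise ValueError(f"unknown hrf_kind: {hrf_kind}")
    dt = TR_shot * 1e-3  # s
    times = np.arange(0.0, paradigm.run_length, dt)
    box = paradigm.boxcar(times)
    kernel_t = np.arange(0.0, HRF_PARAMS["duration"], dt)
    kernel = double_gamma_hrf(kernel_t, hrf_params)
    vals = np.convolve(box, kernel)[: len(times)] * dt
    peak = np.max(np.abs(vals))
    if peak > 0:
        vals = vals / np.max(vals)
    return HemodynamicSignal(times=times, values=vals)


def bold_contrast(mu_gm: float | np.ndarray, bold: BoldSpec, h: float):
    """Gray-matter contrast under the BOLD modulation at response level h."""
    te_s = bold.TE * 1e-3
    if bold.linearize:
        factor = 1.0 - te_s * bold.delta_r2s * h
    else:
        factor = np.exp(-te_s * bold.delta_r2s * h)
    return factor * mu_gm


@dataclass
class PhantomState:
    """Per-tissue contrast-weighted maps m_i(r) = w_i(r) mu_i, plus T2*."""

    maps: np.ndarray  # (n_tissues, *shape)
    t2s: np.ndarray  # (n_tissues,), ms
    tissue_names: tuple[str, ...]
    shape: tuple[int, int, int]

    def total_contrast(self) -> np.ndarray:
        return self.maps.sum(axis=0)

    def tissue_index(self, name: str) -> int:
        return self.tissue_names.index(name)


def make_phantom_state(phantom: Phantom, TR: float, TE: float, FA: float) -> PhantomState:
    maps = np.stack(
        [
            phantom.fractions[i] * gre_contrast(t, TR, TE, FA)
            for i, t in enumerate(phantom.tissues)
        ]
    )
    return PhantomState(
        maps=maps,
        t2s=np.array([t.T2s for t in phantom.tissues], dtype=np.float64),
        tissue_names=tuple(t.name for t in phantom.tissues),
        shape=phantom.shape,
    )


class BoldHandler:
    """Scales the GM contrast inside the ROI by the BOLD factor at shot time.

    By default the response is sampled at each shot's own echo time (the
    full shot-resolution model).  With ``shots_per_frame`` set, the
    response is frozen over each volume at its first shot's value
    ("frame-locked"), which makes every frame consistent with a single
    image — the exact-model regime in which a GLM with the same regressor
    fits noiseless data perfectly.
    """

    def __init__(
        self,
        bold: BoldSpec,
        signal: HemodynamicSignal,
        tissue: str = "GM",
        shots_per_frame: int | None = None,
        TR_shot_ms: float = 50.0,
    ):
        self.bold = bold
        self.signal = signal
        self.tissue = tissue
        self.shots_per_frame = shots_per_frame
        self.TR_shot_ms = TR_shot_ms

    def __call__(self, state: PhantomState, shot_index: int, time_s: float) -> PhantomState:
        if self.shots_per_frame:
            time_s = time_s - (shot_index % self.shots_per_frame) * self.TR_shot_ms * 1e-3
        h = self.signal.at(time_s)
        if h == 0.0:
            return state
        gi = state.tissue_index(self.tissue)
        maps = state.maps.copy()
        gm = maps[gi]
        roi = self.bold.roi.mask
        gm = gm.copy()
        gm[roi] = bold_contrast(gm[roi], self.bold, h)
        maps[gi] = gm
        return PhantomState(maps=maps, t2s=state.t2s, tissue_names=state.tissue_names, shape=state.shape)


@dataclass
class HandlerChain:
    """Ordered, pure state-update rules applied to the baseline per shot."""

    handlers: tuple = ()

    def apply(self, state: PhantomState, shot_index: int, time_s: float) -> PhantomState:
        for i, h in enumerate(self.handlers):
            try:
                state = h(state, shot_index, time_s)
            except Exception as exc:  # annotate which shot broke
                raise RuntimeError(f"handler {i} failed at shot {shot_index}") from exc
        return state


def apply_handlers(
    chain: HandlerChain, state: PhantomState, shot_index: int, time_s: float
) -> PhantomState:
    return chain.apply(state, shot_index, time_s)


def paradigm_to_events_tsv(paradigm: Paradigm, path: str, trial_type: str = "task"):
    """BIDS-style events table: onset, duration, trial_type (+ amplitude)."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {"onset": o, "duration": d, "trial_type": trial_type, "amplitude": a}
            for o, d, a in paradigm.events
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def paradigm_from_events_tsv(path: str, run_length: float) -> Paradigm:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    amp = df["amplitude"] if "amplitude" in df else np.ones(len(df))
    events = tuple(
        (float(o), float(d), float(a))
        for o, d, a in zip(df["onset"], df["duration"], amp)
    )
    return Paradigm(events=events, run_length=run_length)
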