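"""Post-processing of simulation traces into gait observables.

Footfall bars, stance-count gait classification, contralateral phase,
the hind-to-front swing lag ("3L1") against step period, oscillation
period / duty ratio / pairwise phase for deafferented runs, and phase or
force histograms for standing-leg runs.  All phases are cycle fractions
in [0, 1) computed with circular statistics (resultant-vector mean), so
they are invariant under shifts of the time origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .leg_controller import LEG_IDS

GAIT_LABELS = ("tripod", "tetrapod", "pentapod", "intermediate")


@dataclass
class FootfallTrace:
    """Binary swing indicator per leg on a uniform 10 ms grid."""

    time: np.ndarray
    swing: Dict[str, np.ndarray]
    mn: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class GaitMetrics:
    label: str
    min_stance_count: int
    typical_stance_count: float
    period_s: Dict[str, float]
    swing_s: Dict[str, float]
    stance_s: Dict[str, float]
    contralateral_phase: Dict[str, float]


def circular_mean(phases: Sequence[float]) -> float:
    """Resultant-vector mean of cycle fractions, result in [0, 1)."""
    ph = np.asarray(phases, dtype=float)
    if ph.size == 0:
        raise ValueError("no phases")
    ang = 2.0 * math.pi * ph
    m = math.atan2(float(np.mean(np.sin(ang))), float(np.mean(np.cos(ang))))
    return (m / (2.0 * math.pi)) % 1.0


def _onsets(indicator: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Times where a boolean/0-1 series switches from 0 to 1."""
    x = np.asarray(indicator) > 0.5
    idx = np.flatnonzero(~x[:-1] & x[1:]) + 1
    return time[idx]


def _offsets(indicator: np.ndarray, time: np.ndarray) -> np.ndarray:
    x = np.asarray(indicator) > 0.5
    idx = np.flatnonzero(x[:-1] & ~x[1:]) + 1
    return time[idx]


def extract_footfall(trace: pd.DataFrame,
                     window: Optional[Tuple[float, float]] = None,
                     source: str = "mode",
                     channel: str = "dep",
                     threshold: float = 0.0) -> FootfallTrace:
    """Swing bars from the controller state or from MN-threshold crossings.

    ``source="mode"`` uses the swing-motivation state (walking runs);
    ``source="mn"`` marks the times a motor-neuron channel exceeds
    ``threshold`` (deafferented / standing-leg runs, where the "bars" of
    the experimental figures are muscle activations).
    """
    if window is not None:
        lo, hi = window
        sel = (trace["time_s"] >= lo) & (trace["time_s"] < hi)
        trace = trace.loc[sel]
    if len(trace) == 0:
        raise ValueError("empty analysis window")
    time = trace["time_s"].to_numpy()
    swing: Dict[str, np.ndarray] = {}
    mn: Dict[str, np.ndarray] = {}
    for lid in LEG_IDS:
        if source == "mode":
            swing[lid] = trace[f"{lid}_swing"].to_numpy()
        elif source == "mn":
            col = trace[f"{lid}_mn_{channel}"].to_numpy()
            swing[lid] = (col > threshold).astype(float)
            mn[lid] = col
        else:
            raise ValueError(f"unknown source {source!r}")
    return FootfallTrace(time=time, swing=swing, mn=mn)


def stance_count_series(ft: FootfallTrace) -> np.ndarray:
    stack = np.vstack([ft.swing[lid] for lid in LEG_IDS])
    return (stack < 0.5).sum(axis=0)


def leg_cycle_stats(ft: FootfallTrace, lid: str
                    ) -> Tuple[float, float, float]:
    """(period_s, swing_s, stance_s) from mean onset intervals."""
    on = _onsets(ft.swing[lid], ft.time)
    off = _offsets(ft.swing[lid], ft.time)
    if len(on) < 2:
        return math.nan, math.nan, math.nan
    period = float(np.mean(np.diff(on)))
    durs = []
    for t0 in on:
        later = off[off > t0]
        if len(later):
            durs.append(later[0] - t0)
    swing = float(np.mean(durs)) if durs else math.nan
    return period, swing, period - swing


def contralateral_phase(ft: FootfallTrace, leg_a: str, leg_b: str) -> float:
    """Circular mean of leg_b swing onsets within leg_a's step cycle."""
    on_a = _onsets(ft.swing[leg_a], ft.time)
    on_b = _onsets(ft.swing[leg_b], ft.time)
    if len(on_a) < 4:
        raise ValueError("need at least three full reference cycles")
    phases = []
    for k in range(len(on_a) - 1):
        t0, t1 = on_a[k], on_a[k + 1]
        for tb in on_b[(on_b >= t0) & (on_b < t1)]:
            phases.append((tb - t0) / (t1 - t0))
    if not phases:
        raise ValueError("no events of the second leg inside the window")
    return circular_mean(phases)


def classify_gait(ft: FootfallTrace) -> GaitMetrics:
    """Classification by the minimum simultaneous stance count.

    >= 5 legs always grounded -> pentapod; >= 4 -> tetrapod; >= 3 ->
    tripod; anything below three-leg support is flagged "intermediate"
    (the trace does not match a canonical pattern).
    """
    counts = stance_count_series(ft)
    mn = int(counts.min())
    if mn >= 5:
        label = "pentapod"
    elif mn == 4:
        label = "tetrapod"
    elif mn == 3:
        label = "tripod"
    else:
        label = "intermediate"
    period, swing, stance = {}, {}, {}
    for lid in LEG_IDS:
        period[lid], swing[lid], stance[lid] = leg_cycle_stats(ft, lid)
    phases = {}
    for a, b in (("FL", "FR"), ("ML", "MR"), ("HL", "HR")):
        try:
            phases[f"{a}-{b}"] = contralateral_phase(ft, a, b)
        except ValueError:
            phases[f"{a}-{b}"] = math.nan
    return GaitMetrics(
        label=label,
        min_stance_count=mn,
        typical_stance_count=float(np.median(counts)),
        period_s=period, swing_s=swing, stance_s=stance,
        contralateral_phase=phases,
    )


def lag_3L1(ft: FootfallTrace, side: str = "L"
            ) -> List[Tuple[float, float]]:
    """(lag_s, period_s) pairs: hind swing onset to next ipsilateral front
    swing onset, paired with the concurrent hind-leg period."""
    hind = _onsets(ft.swing[f"H{side}"], ft.time)
    front = _onsets(ft.swing[f"F{side}"], ft.time)
    pairs: List[Tuple[float, float]] = []
    for k in range(len(hind) - 1):
        t0, t1 = hind[k], hind[k + 1]
        nxt = front[front >= t0]
        if len(nxt):
            pairs.append((float(nxt[0] - t0), float(t1 - t0)))
    return pairs


@dataclass
class OscillationMetrics:
    period_s: float
    duty_ratio: float  # active-duration ratio of the two antagonists
    pairwise_phase: pd.DataFrame
    coupling: Dict[Tuple[str, str], str]  # in-phase / anti-phase / unlocked


def oscillation_metrics(mn_traces: Dict[str, np.ndarray], time: np.ndarray,
                        threshold: float = 0.0,
                        antagonist_traces: Optional[Dict[str, np.ndarray]]
                        = None,
                        n_cycles: int = 5,
                        phase_tolerance: float = 0.1,
                        half_max: bool = False) -> OscillationMetrics:
    """Period, duty ratio and pairwise phase of rhythmic MN channels.

    The period is the mean onset-to-onset interval of each channel over
    its last ``n_cycles`` cycles.  The duty ratio compares the
    above-threshold duration of the primary channel (e.g. depressor) with
    that of its antagonist (levator) within the same window.  Pairwise
    phase is the circular mean offset of onsets; |phase| < tolerance is
    labelled in-phase, |phase - 0.5| < tolerance anti-phase.

    With ``half_max=True`` the onset detector of each channel uses half
    its peak activation (floored at ``threshold``) instead of the fixed
    threshold: channels that are driven only through weak coupling ride
    on a small tonic background from the opposite body side, and
    half-maximum detection separates their bursts from that background.
    """
    chans = sorted(mn_traces)
    onsets = {}
    for c in chans:
        thr_c = threshold
        if half_max:
            thr_c = max(threshold, 0.5 * float(np.max(mn_traces[c])))
        on = _onsets((mn_traces[c] > thr_c).astype(float), time)
        if len(on) < 2:
            raise ValueError(f"channel {c}: no detected cycles")
        onsets[c] = on[-(n_cycles + 1):]
    period = float(np.mean([np.mean(np.diff(onsets[c])) for c in chans]))

    duty = math.nan
    if antagonist_traces:
        act_a, act_b = 0.0, 0.0
        t0 = min(onsets[c][0] for c in chans)
        sel = time >= t0
        dt = float(time[1] - time[0])
        for c in chans:
            act_a += float((mn_traces[c][sel] > threshold).sum()) * dt
            act_b += float(
                (antagonist_traces[c][sel] > threshold).sum()) * dt
        duty = act_a / act_b if act_b > 0 else math.inf

    n = len(chans)
    mat = np.zeros((n, n))
    coupling: Dict[Tuple[str, str], str] = {}
    for i, a in enumerate(chans):
        for j, b in enumerate(chans):
            if i == j:
                continue
            phases = []
            on_a = onsets[a]
            for k in range(len(on_a) - 1):
                t0, t1 = on_a[k], on_a[k + 1]
                for tb in onsets[b][(onsets[b] >= t0) & (onsets[b] < t1)]:
                    phases.append((tb - t0) / (t1 - t0))
            ph = circular_mean(phases) if phases else math.nan
            mat[i, j] = ph
            if math.isnan(ph):
                label = "unlocked"
            elif min(ph, 1.0 - ph) < phase_tolerance:
                label = "in-phase"
            elif abs(ph - 0.5) < phase_tolerance:
                label = "anti-phase"
            else:
                label = "unlocked"
            coupling[(a, b)] = label
    return OscillationMetrics(
        period_s=period,
        duty_ratio=duty,
        pairwise_phase=pd.DataFrame(mat, index=chans, columns=chans),
        coupling=coupling,
    )


def phase_histogram(event_times: np.ndarray, reference_onsets: np.ndarray,
                    bins: int = 12) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of event phases within the reference leg's cycle."""
    ref = np.asarray(reference_onsets, dtype=float)
    if len(ref) < 2:
        raise ValueError("reference cycle undefined")
    phases = []
    for k in range(len(ref) - 1):
        t0, t1 = ref[k], ref[k + 1]
        for te in np.asarray(event_times)[(event_times >= t0)
                                          & (event_times < t1)]:
            phases.append((te - t0) / (t1 - t0))
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist, _ = np.histogram(phases, bins=edges)
    return hist, edges


def retraction_onsets(trace: pd.DataFrame, lid: str,
                      threshold: float = 7.0,
                      window: Optional[Tuple[float, float]] = None
                      ) -> np.ndarray:
    """Times the retractor MN output of a leg crosses above a threshold."""
    if window is not None:
        lo, hi = window
        trace = trace[(trace["time_s"] >= lo) & (trace["time_s"] < hi)]
    return _onsets((trace[f"{lid}_mn_ret"].to_numpy() > threshold)
                   .astype(float), trace["time_s"].to_numpy())


def fit_circle(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Algebraic (Kasa) circle fit; returns (cx, cy, radius)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx * cx + cy * cy, 0.0))
    return float(cx), float(cy), float(r)
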