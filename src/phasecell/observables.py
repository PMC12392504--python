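"""Summary statistics of simulated migration.

Three observables summarize the behaviors of interest: the friction cut
F(x→0, v) (whose small-|v| slope distinguishes normal from "negative"
friction), dwell ("hopping") times in the basins of the two-state
geometry, and the area-weighted basin occupancy
P_left = (T_left/A_left) / (T_left/A_left + T_right/A_right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import DriftField


@dataclass
class FrictionCut:
    """F(x→0, v): count-weighted average of F over x-bins near x=0."""

    v: np.ndarray
    F: np.ndarray
    counts: np.ndarray
    slope: float          # weighted LSQ slope of F vs v at small |v|
    x_window: float

    @property
    def negative_friction(self) -> bool:
        """Positive small-|v| slope: slow cells tend to accelerate."""
        return self.slope > 0


@dataclass
class HoppingStats:
    """Dwell durations in the basins of a two-state geometry."""

    dwells_per_run: list
    thresholds: tuple[float, float]   # (x_threshold, hysteresis width)
    bin_width: float = 30.0           # min, for pooled histograms

    @property
    def pooled(self) -> np.ndarray:
        if not self.dwells_per_run:
            return np.array([])
        return np.concatenate([np.asarray(d) for d in self.dwells_per_run]) \
            if any(len(d) for d in self.dwells_per_run) else np.array([])

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        pooled = self.pooled
        if len(pooled) == 0:
            return np.array([]), np.array([0.0])
        top = np.ceil(pooled.max() / self.bin_width) * self.bin_width
        edges = np.arange(0.0, top + self.bin_width, self.bin_width)
        hist, _ = np.histogram(pooled, bins=edges)
        return hist, edges

    @property
    def n_hops(self) -> int:
        return int(sum(len(d) for d in self.dwells_per_run))


@dataclass
class OccupancyStats:
    """Area-weighted occupancy of the left basin."""

    time_left: float
    time_right: float
    area_left: float
    area_right: float

    @property
    def P_left(self) -> float:
        wl = self.time_left / self.area_left
        wr = self.time_right / self.area_right
        if wl + wr == 0:
            raise ValueError("no time spent in either basin")
        return wl / (wl + wr)


def friction_cut(field: DriftField, x_window: float = 10.0,
                 v_fit_fraction: float = 0.5) -> FrictionCut:
    """Cut of the drift field near the symmetry axis x=0.

    Averages F over the populated x-bins with |center| ≤ x_window for each
    v-bin (count-weighted), then fits a weighted least-squares line through
    the small-|v| part of the curve (|v| below ``v_fit_fraction`` of the
    largest |v| with data).  A positive slope is the negative-friction
    signature.
    """
    sel = np.abs(field.x_centers) <= x_window
    if not np.any(sel):
        raise ValueError(f"no x-bins within |x| <= {x_window}")
    F = field.F[sel]              # (n_sel, n_v)
    cnt = np.where(np.isfinite(F), field.counts[sel], 0)
    F0 = np.where(np.isfinite(F), F, 0.0)
    tot = cnt.sum(axis=0)
    with np.errstate(invalid="ignore"):
        Fv = np.where(tot > 0, (F0 * cnt).sum(axis=0) / np.maximum(tot, 1),
                      np.nan)
    if not np.any(tot > 0):
        raise ValueError("friction-cut window contains no populated bins")
    v = field.v_centers
    good = tot > 0
    vmax = np.abs(v[good]).max()
    fit = good & (np.abs(v) <= v_fit_fraction * vmax)
    if fit.sum() < 2:
        fit = good
    w = tot[fit].astype(float)
    vv, ff = v[fit], Fv[fit]
    vbar = np.average(vv, weights=w)
    fbar = np.average(ff, weights=w)
    denom = np.average((vv - vbar) ** 2, weights=w)
    slope = float(np.average((vv - vbar) * (ff - fbar), weights=w) / denom)
    return FrictionCut(v=v, F=Fv, counts=tot, slope=slope,
                       x_window=x_window)


def basin_sequence(x: np.ndarray, x_threshold: float,
                   hysteresis: float) -> np.ndarray:
    """Hysteretic basin state per sample: −1 left, +1 right, 0 undecided.

    The state switches to right only when x > x_threshold + h/2 and to
    left only when x < −x_threshold − h/2, where h is the hysteresis
    width; in between it keeps its previous value, so zero-mean chatter of
    amplitude below h cannot toggle it near a threshold.
    """
    hi = x_threshold + hysteresis / 2.0
    state = 0
    out = np.zeros(len(x), dtype=int)
    for i, xi in enumerate(x):
        if state == 0:
            if xi > hi:
                state = 1
            elif xi < -hi:
                state = -1
        elif state == 1 and xi < -hi:
            state = -1
        elif state == -1 and xi > hi:
            state = 1
        out[i] = state
    return out


def hopping_times(times: np.ndarray, x: np.ndarray, x_threshold: float,
                  hysteresis: float = 4.0) -> list:
    """Dwell durations (min) between successive basin entries of one run.

    A hop is a left↔right transition of the hysteretic basin state; the
    dwell is the time between successive entries.  The incomplete first
    and last dwells are discarded.
    """
    state = basin_sequence(np.asarray(x, float), x_threshold, hysteresis)
    hops = []
    prev = 0
    for i, s in enumerate(state):
        if s != 0 and s != prev:
            if prev != 0:          # an observed left↔right transition
                hops.append(times[i])
            prev = s
    if len(hops) < 2:
        return []
    return list(np.diff(hops))


def count_hops(x: np.ndarray, x_threshold: float,
               hysteresis: float = 4.0) -> int:
    """Number of observed left↔right basin transitions in one run."""
    state = basin_sequence(np.asarray(x, float), x_threshold, hysteresis)
    s = state[state != 0]
    if len(s) < 2:
        return 0
    return int(np.sum(np.abs(np.diff(s)) > 0))


def hopping_stats(runs, x_threshold: float | None = None,
                  hysteresis: float = 4.0,
                  pattern=None, R0: float = 18.0) -> HoppingStats:
    """Pool dwell durations over an ensemble on the two-state geometry.

    The default threshold is half the bridge length minus an R0/2 margin,
    so a hop requires the center of mass to clearly enter the new basin.
    """
    if x_threshold is None:
        bridge_half = (pattern.bridge_length / 2.0 if pattern is not None
                       else 17.5)
        x_threshold = max(bridge_half - R0 / 2.0, 1.0)
    dwells = [hopping_times(r.times, r.x, x_threshold, hysteresis)
              for r in runs]
    return HoppingStats(dwells_per_run=dwells,
                        thresholds=(x_threshold, hysteresis))


def occupancy_fractions(runs, area_left: float, area_right: float,
                        x_split: float = 0.0,
                        bridge_halfwidth: float | None = None
                        ) -> OccupancyStats:
    """Area-weighted occupancy over an ensemble.

    Samples with x < −bridge_halfwidth count as left, x > +bridge_halfwidth
    as right; bridge transits (|x| below the half-width) are excluded.
    With the default ``bridge_halfwidth=None`` the split is a simple sign
    test at ``x_split``.
    """
    t_left = 0.0
    t_right = 0.0
    for r in runs:
        dt = np.median(np.diff(r.times)) if len(r.times) > 1 else 0.0
        x = np.asarray(r.x, float)
        if bridge_halfwidth is None:
            t_left += dt * float(np.sum(x < x_split))
            t_right += dt * float(np.sum(x > x_split))
        else:
            t_left += dt * float(np.sum(x < -bridge_halfwidth))
            t_right += dt * float(np.sum(x > bridge_halfwidth))
    if t_left + t_right == 0:
        raise ValueError("no basin time recorded")
    return OccupancyStats(time_left=t_left, time_right=t_right,
                          area_left=area_left, area_right=area_right)
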