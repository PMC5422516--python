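"""Flow-cytometry 2C DNA content estimation and relative ploidy calls.

Nuclei stained with an intercalating dye fluoresce in proportion to their DNA
content, so the ratio of a sample's 2C-peak position to that of a co-chopped
internal standard of known genome size (chicken erythrocyte nuclei, 2.5 pg/2C)
gives the sample's 2C value in picograms.  Ploidy is then called *relative* to
a reference taxon of known ploidy: the nearest integer to
``reference_ploidy * sample_2C / reference_2C``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde


class PloidyError(ValueError):
    pass


@dataclass
class FlowEvents:
    """One sample's fluorescence-area events plus instrument metadata.

    ``standard_window`` is the channel interval declared to contain the
    internal standard's 2C peak; ``cluster`` optionally labels each event 0
    (sample) or 1 (standard) when gating was done upstream.
    """

    values: np.ndarray
    standard_2c: float = 2.5
    standard_window: tuple[float, float] = (225.0, 275.0)
    cluster: np.ndarray | None = None
    min_events_per_peak: int = 200

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise PloidyError("flow events must be a non-empty 1-D array")
        if np.any(self.values <= 0):
            raise PloidyError("fluorescence values must be positive")
        if self.standard_2c <= 0:
            raise PloidyError("standard 2C must be positive")


@dataclass
class PloidyCall:
    sample_id: str
    sample_2c: float
    cv: float
    ploidy: int
    confident: bool

    def __post_init__(self) -> None:
        if self.sample_2c <= 0:
            raise PloidyError("2C estimate must be positive")
        if self.ploidy < 1:
            raise PloidyError("ploidy must be >= 1")


def _trimmed_peak(values: np.ndarray, mode: float, spread: float) -> tuple[float, float, int]:
    """Mean, CV and event count within +/- 2 estimated SDs of a mode."""
    window = values[np.abs(values - mode) <= 2.0 * spread]
    if window.size == 0:
        window = values
    mean = float(np.mean(window))
    cv = float(np.std(window, ddof=1) / mean) if window.size > 1 else 0.0
    return mean, cv, int(window.size)


def find_peaks(events: FlowEvents) -> tuple[tuple[float, float], tuple[float, float]]:
    """Locate the sample and standard 2C peaks.

    Returns ``((sample_mean, sample_cv), (standard_mean, standard_cv))``.
    With cluster labels the peaks are per-cluster trimmed means; otherwise
    modes of a Gaussian KDE on log-fluorescence are refined by trimmed means
    within +/- 2 SD.  The standard is the mode inside the declared channel
    window.  Fewer than two resolvable, well-separated modes is an error.
    """
    v = events.values
    if events.cluster is not None:
        cl = np.asarray(events.cluster)
        out = []
        for label in (0, 1):
            sub = v[cl == label]
            if sub.size < events.min_events_per_peak:
                raise PloidyError(f"cluster {label} has {sub.size} events, "
                                  f"fewer than {events.min_events_per_peak}")
            mode = float(np.median(sub))
            out.append(_trimmed_peak(sub, mode, float(np.std(sub, ddof=1)) or mode * 0.05))
        (s_mean, s_cv, _), (std_mean, std_cv, _) = out
        return (s_mean, s_cv), (std_mean, std_cv)

    logv = np.log(v)
    kde = gaussian_kde(logv)
    grid = np.linspace(logv.min(), logv.max(), 2048)
    dens = kde(grid)
    # local maxima of the density
    rising = np.r_[False, dens[1:] > dens[:-1]]
    falling = np.r_[dens[:-1] > dens[1:], False]
    modes = grid[rising & falling]
    heights = dens[rising & falling]
    if modes.size < 2:
        raise PloidyError("peaks unresolved: fewer than two modes in the "
                          "fluorescence distribution")
    top = np.sort(np.exp(modes[np.argsort(heights)[::-1][:2]]))
    # partition events by the nearer mode (log scale) before refining, so one
    # peak's tail cannot pollute the other's statistics
    assign = np.argmin(np.abs(logv[:, None] - np.log(top)[None, :]), axis=1)
    peaks = []
    for i, mode in enumerate(top):
        sub = v[assign == i]
        if sub.size < events.min_events_per_peak:
            raise PloidyError(f"peak at {mode:.1f} has only {sub.size} events")
        spread = float(np.std(sub, ddof=1)) or mode * 0.05
        mean, cv, n = _trimmed_peak(sub, mode, spread)
        if n < events.min_events_per_peak:
            raise PloidyError(f"peak at {mode:.1f} has only {n} trimmed events")
        peaks.append((mean, cv, cv * mean))
    (m1, cv1, sd1), (m2, cv2, sd2) = peaks
    if abs(m2 - m1) < 2.0 * (sd1 + sd2) / 2.0:
        raise PloidyError("overlapping modes: peak separation below 2x pooled SD")
    lo, hi = events.standard_window
    in_win = [lo <= m <= hi for m, _, _ in peaks]
    if sum(in_win) != 1:
        raise PloidyError(
            f"expected exactly one peak inside the standard window {events.standard_window}, "
            f"found {sum(in_win)} (peaks at {m1:.1f}, {m2:.1f})")
    std_idx = in_win.index(True)
    std_mean, std_cv, _ = peaks[std_idx]
    s_mean, s_cv, _ = peaks[1 - std_idx]
    return (s_mean, s_cv), (std_mean, std_cv)


def estimate_2c(sample_mean: float, standard_mean: float, standard_2c: float) -> float:
    """Sample 2C in pg from peak-position ratio against the internal standard."""
    if sample_mean <= 0 or standard_mean <= 0 or standard_2c <= 0:
        raise PloidyError("peak means and standard 2C must be positive")
    return sample_mean / standard_mean * standard_2c


def infer_ploidy(sample_2c: float, reference_2c: float, reference_ploidy: int,
                 sample_id: str = "", cv: float = 0.0) -> PloidyCall:
    """Integer ploidy relative to a reference taxon of known ploidy.

    Flagged low-confidence when the pre-rounding value sits more than 0.25
    from its nearest integer.
    """
    if sample_2c <= 0 or reference_2c <= 0:
        raise PloidyError("2C values must be positive")
    if reference_ploidy not in (2, 3, 4, 6, 8):
        raise PloidyError(f"unsupported reference ploidy {reference_ploidy}")
    raw = reference_ploidy * sample_2c / reference_2c
    ploidy = max(1, round(raw))
    confident = abs(raw - ploidy) <= 0.25
    return PloidyCall(sample_id, sample_2c, cv, int(ploidy), confident)


def call_sample(events: FlowEvents, reference_2c: float, reference_ploidy: int,
                sample_id: str = "") -> PloidyCall:
    """End-to-end: peaks -> 2C -> relative ploidy for one event stream."""
    (s_mean, s_cv), (std_mean, _) = find_peaks(events)
    c2 = estimate_2c(s_mean, std_mean, events.standard_2c)
    return infer_ploidy(c2, reference_2c, reference_ploidy, sample_id, s_cv)


def read_events_csv(path: str | Path, standard_2c: float = 2.5,
                    standard_window: tuple[float, float] = (225.0, 275.0),
                    ) -> FlowEvents:
    """Events CSV with columns event_id, fl_area[, cluster]."""
    df = pd.read_csv(path)
    if "fl_area" not in df.columns:
        raise PloidyError(f"{path}: expected a 'fl_area' column")
    cluster = df["cluster"].to_numpy() if "cluster" in df.columns else None
    return FlowEvents(df["fl_area"].to_numpy(), standard_2c=standard_2c,
                      standard_window=standard_window, cluster=cluster)


def write_events_csv(events: FlowEvents, path: str | Path) -> None:
    df = pd.DataFrame({"event_id": np.arange(1, events.values.size + 1),
                       "fl_area": events.values})
    if events.cluster is not None:
        df["cluster"] = events.cluster
    df.to_csv(path, index=False)


def calls_to_frame(calls: list[PloidyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample": c.sample_id, "2C_pg": c.sample_2c, "CV": c.cv,
          "ploidy": c.ploidy, "flag": "" if c.confident else "low_confidence"}
         for c in calls],
        columns=["sample", "2C_pg", "CV", "ploidy", "flag"])
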