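"""Trajectory readouts: F/F0 traces, spike events, kymographs, pattern class.

The classifier replaces by-eye scoring with a fixed quantitative rubric:
per frame a cell is active when its F/F0 exceeds an activity threshold;
active (cell, frame) pairs are grouped into spatiotemporally connected
events (cell adjacency within a frame, same cell across consecutive
frames); the class follows from event extent and propagation.  Rubric
thresholds are free parameters, fixed in :class:`ClassifierConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SpikeEvent",
    "Kymograph",
    "ActivityReport",
    "ClassifierConfig",
    "normalize_trace",
    "detect_spikes",
    "oscillation_metrics",
    "make_kymograph",
    "classify_pattern",
    "integrated_activity",
    "spikes_per_area",
    "analyze_trajectory",
]

#: F/F0 ratio above which a cell counts as active, and the default spike
#: detection threshold.
ACTIVITY_THRESHOLD = 1.5
#: Events closer than this (s) merge into one spike.
MIN_SEPARATION = 20.0
#: Percentile of a trace used as its basal fluorescence F0.
BASELINE_PERCENTILE = 10.0


@dataclass(frozen=True)
class SpikeEvent:
    """One Ca2+ spike: onset/peak times (s), normalized peak amplitude
    (F/F0), and width at half maximum (s, measured relative to baseline)."""

    cell_id: int
    t_onset: float
    t_peak: float
    amplitude: float
    whm: float


def normalize_trace(c_series: np.ndarray,
                    percentile: float = BASELINE_PERCENTILE) -> np.ndarray:
    """F/F0 normalisation: divide by the trace's ``percentile`` value.

    A low percentile is robust to long active episodes; a constant trace
    maps to all ones, and the output is invariant to uniform scaling of
    the raw trace.
    """
    c = np.asarray(c_series, dtype=float)
    if c.size == 0:
        raise ValueError("empty trace")
    if np.any(c < 0):
        raise ValueError("trace values must be >= 0")
    f0 = np.percentile(c, percentile)
    if f0 <= 0:
        raise ValueError("degenerate baseline: F0 = 0")
    return c / f0


def _interp_crossing(t0, t1, y0, y1, level):
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def detect_spikes(
    trace: np.ndarray,
    t: np.ndarray,
    threshold: float = ACTIVITY_THRESHOLD,
    min_separation: float = MIN_SEPARATION,
    cell_id: int = 0,
    normalized: bool = False,
) -> list[SpikeEvent]:
    """Detect spikes as maximal excursions of F/F0 above ``threshold``.

    The raw trace is F/F0-normalised first unless ``normalized`` is set.
    Excursions separated by less than ``min_separation`` merge into one
    event.  The width at half maximum is measured at the level
    ``1 + (peak - 1) / 2`` (halfway between baseline and peak) with linear
    interpolation of the crossing times.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed the baseline ratio 1")
    t = np.asarray(t, dtype=float)
    f = np.asarray(trace, dtype=float)
    if not normalized:
        f = normalize_trace(f)
    above = f > threshold
    if not above.any():
        return []
    # contiguous runs above threshold
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = ([0] if above[0] else []) + list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]]) + ([len(f) - 1] if above[-1] else [])
    runs = list(zip(starts, ends))
    # merge runs with short gaps
    merged = [runs[0]]
    for s, e in runs[1:]:
        if t[s] - t[merged[-1][1]] < min_separation:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events = []
    for s, e in merged:
        seg = f[s:e + 1]
        k = s + int(np.argmax(seg))
        peak = f[k]
        half = 1.0 + (peak - 1.0) / 2.0
        # onset: crossing of the detection threshold entering the run
        if s > 0:
            onset = _interp_crossing(t[s - 1], t[s], f[s - 1], f[s], threshold)
        else:
            onset = t[0]
        # WHM crossings around the peak
        i = k
        while i > 0 and f[i - 1] >= half:
            i -= 1
        t_left = (
            _interp_crossing(t[i - 1], t[i], f[i - 1], f[i], half)
            if i > 0 else t[0]
        )
        j = k
        while j < len(f) - 1 and f[j + 1] >= half:
            j += 1
        t_right = (
            _interp_crossing(t[j], t[j + 1], f[j], f[j + 1], half)
            if j < len(f) - 1 else t[-1]
        )
        events.append(
            SpikeEvent(
                cell_id=cell_id,
                t_onset=float(onset),
                t_peak=float(t[k]),
                amplitude=float(peak),
                whm=float(t_right - t_left),
            )
        )
    return events


def oscillation_metrics(
    trace: np.ndarray,
    t: np.ndarray,
    threshold: float = ACTIVITY_THRESHOLD,
    min_separation: float = MIN_SEPARATION,
    normalized: bool = False,
) -> tuple[float | None, float, float]:
    """(frequency in Hz, mean amplitude, mean WHM) of a trace's spikes.

    Frequency is the reciprocal mean peak-to-peak interval and requires at
    least two detected peaks; it is reported as None (absent) otherwise,
    never as zero.
    """
    events = detect_spikes(trace, t, threshold, min_separation,
                           normalized=normalized)
    if not events:
        return None, np.nan, np.nan
    amp = float(np.mean([ev.amplitude for ev in events]))
    whm = float(np.mean([ev.whm for ev in events]))
    if len(events) < 2:
        return None, amp, whm
    peaks = np.array([ev.t_peak for ev in events])
    freq = 1.0 / float(np.mean(np.diff(peaks)))
    return freq, amp, whm


@dataclass
class Kymograph:
    """Position x time intensity matrix along a line through the tissue."""

    line: np.ndarray              # (2, 2) endpoints
    cell_ids: np.ndarray          # ordered along the line
    positions: np.ndarray         # projections onto the line
    t: np.ndarray
    intensity: np.ndarray         # (n_cells_on_line, T)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.intensity, index=self.cell_ids, columns=self.t)
        df.index.name = "cell_id"
        df.to_csv(path)

    def to_png(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(
            self.intensity, aspect="auto", origin="lower", cmap="inferno",
            extent=[self.t[0], self.t[-1],
                    self.positions[0], self.positions[-1]],
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("position along line (cell diameters)")
        fig.savefig(path, dpi=120)
        plt.close(fig)


def make_kymograph(trajectory, line, normalized: bool = True) -> Kymograph:
    """Intensity of cells intersecting ``line`` (2x2 endpoint array),
    ordered by projection of their centroid onto the line."""
    from shapely.geometry import LineString, Polygon

    line = np.asarray(line, dtype=float).reshape(2, 2)
    seg = LineString(line)
    tissue = trajectory.tissue
    hits = [
        i for i in range(tissue.n_cells)
        if Polygon(tissue.polygons[i]).intersects(seg)
    ]
    if not hits:
        raise ValueError("line does not intersect any cell")
    direction = line[1] - line[0]
    direction = direction / np.linalg.norm(direction)
    proj = np.array([
        float(np.dot(tissue.centroids[i] - line[0], direction)) for i in hits
    ])
    order = np.argsort(proj)
    ids = np.array(hits)[order]
    if normalized:
        mat = np.stack(
            [normalize_trace(trajectory.c[:, i]) for i in ids]
        )
    else:
        mat = trajectory.c[:, ids].T.copy()
    return Kymograph(
        line=line, cell_ids=ids, positions=proj[order],
        t=trajectory.t.copy(), intensity=mat,
    )


@dataclass(frozen=True)
class ClassifierConfig:
    """Rubric thresholds for the automated pattern classifier."""

    activity_threshold: float = ACTIVITY_THRESHOLD  # F/F0 "active" cutoff
    spike_max_cells: int = 3          # largest event still a single-cell spike
    # Event span (as a tissue fraction) qualifying as tissue-scale.  A
    # wave's recruitment depth is set by the kinetics, not the cell count,
    # so this gate is kept low enough not to over-demand on small
    # simulated tissues; propagation (centroid displacement) is the
    # primary wave discriminator.
    icw_tissue_fraction: float = 0.05
    flutter_active_fraction: float = 0.5   # of cells active in a frame
    # Fraction of frames that must reach flutter_active_fraction.  A
    # globally synchronized oscillation is only above the activity
    # threshold for its duty cycle (~1/3 of the time), so this is set
    # well below the duty cycle of tissue-wide oscillation yet an order
    # of magnitude above what even dense wave activity produces.
    flutter_time_fraction: float = 0.2
    propagation_diameters: float = 2.0     # centroid travel marking a wave


@dataclass
class EventSummary:
    """One spatiotemporal activity event."""

    cells: np.ndarray
    frames: np.ndarray
    span: int                 # number of distinct cells
    displacement: float       # max travel of the per-frame active centroid


def _activity_events(active: np.ndarray, tissue) -> list[EventSummary]:
    """Connected components of active (cell, frame) pairs under spatial
    adjacency within a frame and same-cell temporal continuity."""
    T, N = active.shape
    idx = -np.ones((T, N), dtype=int)
    ts, ns = np.nonzero(active)
    idx[ts, ns] = np.arange(len(ts))
    n_nodes = len(ts)
    if n_nodes == 0:
        return []
    rows, cols = [], []
    # temporal: same cell, consecutive frames
    both = active[:-1] & active[1:]
    tt, nn = np.nonzero(both)
    rows.append(idx[tt, nn])
    cols.append(idx[tt + 1, nn])
    # spatial: adjacent cells, same frame; and adjacent cells across
    # consecutive frames, so a front advancing about one cell per frame
    # with brief activation still forms a single event
    if len(tissue.edges):
        i, j = tissue.edges.T
        both = active[:, i] & active[:, j]
        tt, ee = np.nonzero(both)
        rows.append(idx[tt, i[ee]])
        cols.append(idx[tt, j[ee]])
        for a, b in ((i, j), (j, i)):
            both = active[:-1, a] & active[1:, b]
            tt, ee = np.nonzero(both)
            rows.append(idx[tt, a[ee]])
            cols.append(idx[tt + 1, b[ee]])
    rows = np.concatenate(rows) if rows else np.array([], dtype=int)
    cols = np.concatenate(cols) if cols else np.array([], dtype=int)
    graph = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    n_comp, labels = connected_components(graph, directed=False)
    events = []
    for comp in range(n_comp):
        members = np.nonzero(labels == comp)[0]
        cells = ns[members]
        frames = ts[members]
        uniq_frames = np.unique(frames)
        centroids = np.array([
            tissue.centroids[cells[frames == fr]].mean(axis=0)
            for fr in uniq_frames
        ])
        if len(centroids) > 1:
            d = centroids[:, None, :] - centroids[None, :, :]
            displacement = float(np.sqrt((d**2).sum(-1)).max())
        else:
            displacement = 0.0
        events.append(
            EventSummary(
                cells=np.unique(cells), frames=uniq_frames,
                span=len(np.unique(cells)), displacement=displacement,
            )
        )
    return events


def classify_pattern(
    trajectory,
    tissue=None,
    config: ClassifierConfig | None = None,
) -> tuple[str, dict]:
    """Label a trajectory as none / spikes / ICT / ICW / fluttering.

    Precedence: fluttering (sustained near-global activity) is checked
    first; then events are sized — all small events give ``spikes``,
    intermediate multicellular events give ``ICT``, and a tissue-scale
    event whose active centroid travels more than the propagation
    threshold gives ``ICW``.
    """
    config = config or ClassifierConfig()
    tissue = tissue or trajectory.tissue
    if trajectory.t[-1] - trajectory.t[0] < 600.0:
        raise ValueError("classification requires at least 10 min of trajectory")
    N = tissue.n_cells
    f = np.stack([normalize_trace(trajectory.c[:, i]) for i in range(N)], axis=1)
    active = f > config.activity_threshold
    frame_fraction = active.mean(axis=1)
    flutter_frames = (frame_fraction >= config.flutter_active_fraction).mean()
    events = _activity_events(active, tissue)
    diagnostics = {
        "n_events": len(events),
        "max_event_span": max((ev.span for ev in events), default=0),
        "max_displacement": max((ev.displacement for ev in events), default=0.0),
        "flutter_frame_fraction": float(flutter_frames),
        "events": events,
    }
    if flutter_frames >= config.flutter_time_fraction:
        return "fluttering", diagnostics
    if not events:
        return "none", diagnostics
    icw_span = max(config.spike_max_cells + 1,
                   int(np.ceil(config.icw_tissue_fraction * N)))
    is_icw = any(
        ev.span >= icw_span
        and ev.displacement > config.propagation_diameters
        for ev in events
    )
    if is_icw:
        return "ICW", diagnostics
    if any(ev.span > config.spike_max_cells for ev in events):
        return "ICT", diagnostics
    return "spikes", diagnostics


def integrated_activity(trajectory) -> float:
    """Time-tissue sum of suprabasal normalized fluorescence,
    ``sum_cells sum_samples max(F/F0 - 1, 0) * dt``."""
    dt = float(np.mean(np.diff(trajectory.t)))
    total = 0.0
    for i in range(trajectory.n_cells):
        f = normalize_trace(trajectory.c[:, i])
        total += np.maximum(f - 1.0, 0.0).sum() * dt
    return float(total)


def spikes_per_area(report: "ActivityReport", tissue) -> float:
    """Tissue spike count per unit pouch area (cell-diameter^2)."""
    return report.tissue_spike_count / tissue.total_area()


@dataclass
class ActivityReport:
    """Aggregate readouts of one trajectory."""

    spikes_by_cell: dict = field(default_factory=dict)
    tissue_spike_count: int = 0
    spikes_per_area: float = 0.0
    mean_frequency: float | None = None   # Hz, over cells with >= 2 spikes
    mean_whm: float = np.nan              # s, over all spike events
    integrated_activity: float = 0.0
    pattern_class: str = "none"
    max_event_span: int = 0
    n_events: int = 0
    diagnostics: dict = field(default_factory=dict)

    def events_to_csv(self, path) -> None:
        """Write all spike events as CSV (cell_id, t_onset, t_peak,
        amplitude, whm_s)."""
        import pandas as pd

        rows = [
            {"cell_id": ev.cell_id, "t_onset": ev.t_onset,
             "t_peak": ev.t_peak, "amplitude": ev.amplitude,
             "whm_s": ev.whm}
            for events in self.spikes_by_cell.values() for ev in events
        ]
        pd.DataFrame(
            rows, columns=["cell_id", "t_onset", "t_peak", "amplitude",
                           "whm_s"],
        ).to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "pattern_class": self.pattern_class,
            "tissue_spike_count": self.tissue_spike_count,
            "spikes_per_area": self.spikes_per_area,
            "mean_frequency_hz": self.mean_frequency,
            "mean_whm_s": None if np.isnan(self.mean_whm) else self.mean_whm,
            "integrated_activity": self.integrated_activity,
            "n_events": self.n_events,
            "max_event_span": self.max_event_span,
        }


def analyze_trajectory(
    trajectory,
    classifier: ClassifierConfig | None = None,
    threshold: float = ACTIVITY_THRESHOLD,
    min_separation: float = MIN_SEPARATION,
) -> ActivityReport:
    """Full per-trajectory quantification: spikes, metrics, class label."""
    spikes_by_cell = {}
    freqs = []
    whms = []
    for i in range(trajectory.n_cells):
        events = detect_spikes(
            trajectory.c[:, i], trajectory.t, threshold, min_separation,
            cell_id=i,
        )
        if events:
            spikes_by_cell[i] = events
            whms.extend(ev.whm for ev in events)
            if len(events) >= 2:
                peaks = np.array([ev.t_peak for ev in events])
                freqs.append(1.0 / float(np.mean(np.diff(peaks))))
    label, diagnostics = classify_pattern(trajectory, config=classifier)
    count = sum(len(v) for v in spikes_by_cell.values())
    report = ActivityReport(
        spikes_by_cell=spikes_by_cell,
        tissue_spike_count=count,
        mean_frequency=float(np.mean(freqs)) if freqs else None,
        mean_whm=float(np.mean(whms)) if whms else np.nan,
        integrated_activity=integrated_activity(trajectory),
        pattern_class=label,
        max_event_span=diagnostics["max_event_span"],
        n_events=diagnostics["n_events"],
        diagnostics=diagnostics,
    )
    report.spikes_per_area = spikes_per_area(report, trajectory.tissue)
    return report
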