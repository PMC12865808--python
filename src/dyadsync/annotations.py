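"""Laughter annotation algebra.

Parses tab-delimited annotation exports (ELAN-style: participant, tier,
onset_s, offset_s), merges and unions laughter intervals across the two dyad
members, assigns laughter to experimental phases (task interval plus a
pre-onset window, so laughter between tasks counts toward the subsequent
phase), and computes the relative laughter durations LBMP (manipulation phase)
and LBFI (free-interaction phase) used as behavioral predictors.

Intervals follow the half-open convention [onset, offset); touching intervals
merge.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Interval",
    "PhaseWindow",
    "DyadBehavior",
    "parse_annotations",
    "merge_intervals",
    "dyad_union",
    "assign_to_phase",
    "relative_duration",
    "compute_dyad_behavior",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class PhaseWindow:
    """A phase's task interval [start_s, end_s) plus its pre-onset extension."""

    phase: str
    start_s: float
    end_s: float
    preonset_s: float = 0.0

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError(f"{self.phase}: end must exceed start")
        if self.preonset_s < 0 or self.start_s - self.preonset_s < 0:
            raise ValueError(f"{self.phase}: pre-onset window reaches below time zero")

    @property
    def extended(self) -> Interval:
        return (self.start_s - self.preonset_s, self.end_s)

    @property
    def length_s(self) -> float:
        """Exact window length including the pre-onset extension."""
        return self.end_s - self.start_s + self.preonset_s


@dataclass
class DyadBehavior:
    dyad_id: object
    lbmp: float
    lbfi: float
    total_laughter_s: dict


def parse_annotations(path_or_buffer, known_participants=None) -> dict:
    """Read a tab-delimited annotation export into per-participant interval lists.

    Required columns: participant, tier, onset_s, offset_s.  Rows are
    validated (offset > onset, nonnegative onset), sorted, and within-track
    overlaps merged.  Errors cite the offending line number (1-based, header
    = line 1).
    """
    df = pd.read_csv(path_or_buffer, sep="\t")
    required = {"participant", "tier", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file lacks columns: {sorted(missing)}")
    tracks: dict = {}
    for i, row in df.iterrows():
        line = i + 2
        on, off = float(row["onset_s"]), float(row["offset_s"])
        if off <= on:
            raise ValueError(f"line {line}: offset ({off}) must exceed onset ({on})")
        if on < 0:
            raise ValueError(f"line {line}: negative onset {on}")
        pid = row["participant"]
        if known_participants is not None and pid not in known_participants:
            raise ValueError(f"line {line}: unknown participant {pid!r}")
        tracks.setdefault(pid, []).append((on, off))
    return {pid: merge_intervals(ivals) for pid, ivals in tracks.items()}


def merge_intervals(intervals) -> list[Interval]:
    """Sorted union of [on, off) intervals; touching intervals merge."""
    out: list[list[float]] = []
    for on, off in sorted(intervals):
        if out and on <= out[-1][1]:
            out[-1][1] = max(out[-1][1], off)
        else:
            out.append([on, off])
    return [(a, b) for a, b in out]


def total_duration(intervals) -> float:
    return sum(b - a for a, b in intervals)


def dyad_union(track_a, track_b) -> tuple[list[Interval], float]:
    """Union across the two participants: time when at least one was laughing."""
    union = merge_intervals(list(track_a) + list(track_b))
    return union, total_duration(union)


def assign_to_phase(intervals, windows) -> dict[str, list[Interval]]:
    """Clip each interval to the extended window(s) it intersects.

    Windows must be chronologically ordered and non-overlapping after the
    pre-onset extension; laughter in the gap before a task falls into that
    phase's pre-onset extension by construction.  Intervals outside all
    extended windows are dropped (returned under key ``None`` for logging).
    """
    windows = list(windows)
    for w1, w2 in zip(windows, windows[1:]):
        if w2.extended[0] < w1.extended[1]:
            raise ValueError(
                f"extended windows {w1.phase} and {w2.phase} overlap or are out of order"
            )
    out: dict = {w.phase: [] for w in windows}
    dropped = []
    for on, off in intervals:
        covered = False
        for w in windows:
            lo, hi = w.extended
            c_on, c_off = max(on, lo), min(off, hi)
            if c_off > c_on:
                out[w.phase].append((c_on, c_off))
                covered = True
        if not covered:
            dropped.append((on, off))
    for phase in out:
        out[phase] = merge_intervals(out[phase])
    if dropped:
        out[None] = dropped
    return out


def relative_duration(phase_intervals, window: PhaseWindow) -> float:
    """Union length divided by the exact extended window length; in [0, 1]."""
    if window.length_s <= 0:
        raise ValueError("zero-length phase window")
    clipped = [
        (max(a, window.extended[0]), min(b, window.extended[1]))
        for a, b in phase_intervals
        if min(b, window.extended[1]) > max(a, window.extended[0])
    ]
    return total_duration(merge_intervals(clipped)) / window.length_s


def compute_dyad_behavior(dyad_id, track_a, track_b, windows) -> DyadBehavior:
    """Per-dyad relative laughter durations from the two members' tracks.

    The dyad union is computed first (time at least one member laughed), then
    assigned to phases and normalised per extended window, yielding LBMP and
    LBFI.
    """
    union, _ = dyad_union(track_a, track_b)
    by_phase = assign_to_phase(union, windows)
    wmap = {w.phase: w for w in windows}
    rel = {ph: relative_duration(by_phase.get(ph, []), w) for ph, w in wmap.items()}
    totals = {ph: total_duration(by_phase.get(ph, [])) for ph in wmap}
    return DyadBehavior(
        dyad_id=dyad_id,
        lbmp=rel.get("manipulation", 0.0),
        lbfi=rel.get("free_interaction", 0.0),
        total_laughter_s=totals,
    )


def behavior_table(annotations: pd.DataFrame, windows) -> pd.DataFrame:
    """DyadBehavior rows for a cohort annotation table (dyad_id, participant,
    onset_s, offset_s)."""
    rows = []
    for dyad_id, grp in annotations.groupby("dyad_id"):
        tracks = {
            p: merge_intervals(list(zip(g["onset_s"], g["offset_s"])))
            for p, g in grp.groupby("participant")
        }
        track_list = list(tracks.values()) + [[], []]
        beh = compute_dyad_behavior(dyad_id, track_list[0], track_list[1], windows)
        rows.append({"dyad_id": dyad_id, "lbmp": beh.lbmp, "lbfi": beh.lbfi,
                     **{f"total_{ph}_s": t for ph, t in beh.total_laughter_s.items()}})
    return pd.DataFrame(rows)
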