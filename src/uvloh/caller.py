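"""Zygosity calling and LOH segmentation from allele-specific ratio tables.

One sector of a sectored colony yields, per SNP, a pair of hybridization
ratios (one per parental allele).  ``call_states`` thresholds the pair into
HET / HOM_P1 / HOM_P2 / NOCALL; ``segment_states`` merges the called SNPs
into maximal single-state runs and records each het/hom transition with its
inner and outer bounds (positions of the nearest confidently-called SNPs on
either side), mirroring the min/max transition convention used for array
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import HET, HOM_P1, HOM_P2, NOCALL, STATE_NAMES


class CallerError(ValueError):
    pass


@dataclass(frozen=True)
class CallThresholds:
    """Ratio cutoffs.  HOM_P1 requires ratio_P1 >= hom_hi and ratio_P2 <=
    hom_lo (HOM_P2 symmetric); HET requires both ratios within
    [het_lo, het_hi]; anything else is NOCALL."""

    hom_hi: float = 1.4
    hom_lo: float = 0.6
    het_lo: float = 0.7
    het_hi: float = 1.3

    def __post_init__(self) -> None:
        if not (0 <= self.hom_lo < self.het_lo <= self.het_hi < self.hom_hi):
            raise CallerError("thresholds must satisfy hom_lo < het_lo <= het_hi < hom_hi")


@dataclass
class Segment:
    state: int
    first_pos: int
    last_pos: int
    first_idx: int
    last_idx: int

    @property
    def state_name(self) -> str:
        return STATE_NAMES[self.state]


@dataclass
class Transition:
    left_state: int
    right_state: int
    inner: int      # position of the last called SNP of the left segment
    outer: int      # position of the first called SNP of the right segment


@dataclass
class SectorCall:
    """Per-SNP zygosity track for one sector, segmented per chromosome."""

    sector_id: str
    calls: pd.DataFrame                       # snp_id, chromosome, position, state
    segments: dict = field(default_factory=dict)     # chrom -> list[Segment]
    transitions: dict = field(default_factory=dict)  # chrom -> list[Transition]

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.calls["chromosome"]))

    def loh_segments(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments.get(chrom, []) if s.state in (HOM_P1, HOM_P2)]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(per-SNP call table, segment table with BED-style 0-based spans)."""
        calls = self.calls.copy()
        calls["state"] = calls["state"].map(STATE_NAMES)
        seg_rows = [
            (chrom, s.first_pos - 1, s.last_pos, s.state_name, self.sector_id)
            for chrom, segs in self.segments.items() for s in segs
        ]
        segs = pd.DataFrame(seg_rows,
                            columns=["chrom", "start", "end", "state", "sector_id"])
        return calls, segs


def call_states(ratios: pd.DataFrame,
                thresholds: CallThresholds = CallThresholds()) -> pd.DataFrame:
    """Threshold (ratio_P1, ratio_P2) pairs into per-SNP zygosity states."""
    for col in ("chromosome", "position", "ratio_P1", "ratio_P2"):
        if col not in ratios.columns:
            raise CallerError(f"ratio table missing column {col!r}")
    r1 = ratios["ratio_P1"].to_numpy(dtype=float)
    r2 = ratios["ratio_P2"].to_numpy(dtype=float)
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise CallerError("negative hybridization ratio")
    t = thresholds
    state = np.full(len(ratios), NOCALL, dtype=np.int8)
    het = (r1 >= t.het_lo) & (r1 <= t.het_hi) & (r2 >= t.het_lo) & (r2 <= t.het_hi)
    hom1 = (r1 >= t.hom_hi) & (r2 <= t.hom_lo)
    hom2 = (r2 >= t.hom_hi) & (r1 <= t.hom_lo)
    state[het] = HET
    state[hom1] = HOM_P1
    state[hom2] = HOM_P2
    out = ratios.loc[:, ["chromosome", "position"]].copy()
    if "snp_id" in ratios.columns:
        out.insert(0, "snp_id", ratios["snp_id"])
    out["state"] = state
    return out


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs over called (non-NOCALL) indices: (state, start, end)
    positions are indices into the called-subset arrays."""
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((int(states[start]), start, i - 1))
            start = i
    return runs


def segment_states(calls: pd.DataFrame, min_run: int = 2,
                   sector_id: str = "sector") -> SectorCall:
    """Segment a per-SNP state table into maximal runs per chromosome.

    Runs supported by fewer than ``min_run`` SNPs are relabeled NOCALL and
    absorbed (flanking same-state runs then merge); NOCALL SNPs never break a
    run.  Transitions carry inner/outer bounds from the flanking confidently-
    called SNPs.
    """
    if min_run < 1:
        raise CallerError("min_run must be >= 1")
    calls = calls.reset_index(drop=True)
    sector = SectorCall(sector_id=sector_id, calls=calls)
    if calls.empty:
        return sector
    for chrom, grp in calls.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise CallerError(f"SNPs not ordered by position on {chrom}")
        states = grp["state"].to_numpy().copy()
        called = states != NOCALL
        sub_states = states[called]
        sub_pos = pos[called]
        sub_idx = np.flatnonzero(called)
        # iteratively absorb short runs
        while True:
            runs = _runs(sub_states)
            short = [r for r in runs if (r[2] - r[1] + 1) < min_run]
            if not short or len(runs) == 1:
                break
            # drop the shortest run first (ties: leftmost)
            short.sort(key=lambda r: (r[2] - r[1], r[1]))
            _s, a, b = short[0]
            keep = np.ones(len(sub_states), dtype=bool)
            keep[a:b + 1] = False
            sub_states = sub_states[keep]
            sub_pos = sub_pos[keep]
            sub_idx = sub_idx[keep]
        segments: list[Segment] = []
        transitions: list[Transition] = []
        if len(sub_states):
            runs = _runs(sub_states)
            if len(runs) == 1 and (runs[0][2] - runs[0][1] + 1) < min_run:
                runs = []
            for s, a, b in runs:
                segments.append(Segment(state=s, first_pos=int(sub_pos[a]),
                                        last_pos=int(sub_pos[b]),
                                        first_idx=int(sub_idx[a]),
                                        last_idx=int(sub_idx[b])))
            for left, right in zip(segments, segments[1:]):
                transitions.append(Transition(left_state=left.state,
                                              right_state=right.state,
                                              inner=left.last_pos,
                                              outer=right.first_pos))
        sector.segments[str(chrom)] = segments
        sector.transitions[str(chrom)] = transitions
    return sector


def call_sector(ratios: pd.DataFrame, thresholds: CallThresholds = CallThresholds(),
                min_run: int = 2, sector_id: str | None = None) -> SectorCall:
    """Convenience: call_states followed by segment_states."""
    sid = sector_id
    if sid is None:
        sid = str(ratios["sector_id"].iloc[0]) if "sector_id" in ratios.columns and len(ratios) else "sector"
    return segment_states(call_states(ratios, thresholds), min_run=min_run, sector_id=sid)
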