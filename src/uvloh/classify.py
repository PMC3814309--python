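"""Classification of recombination events from paired sector calls.

The two sectors of a red/white colony are the two daughters of the irradiated
cell, so their LOH tracks jointly identify the repair event: reciprocal
terminal LOH is a crossover, one-sided terminal LOH is break-induced
replication, interstitial LOH is a gene conversion (3:1 when one sector is
homozygous, 4:0 when both are homozygous for the same parent, hybrid when a
4:0 core carries a 3:1 extension).  Any 4:0 segment implies both sister
chromatids were broken (DSCB, a G1 break); a pure 3:1 tract implies a single
broken chromatid (SCB, an S/G2 break).  LOH regions separated by more than
15 kb of shared heterozygosity are treated as independently initiated
events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import SectorCall, Segment
from .genome import P1, P2, MarkerConfig, SnpMap
from .states import HET, HOM_P1, HOM_P2, NOCALL

KIND_CO = "CO"
KIND_CO_CONV = "CO_with_conversion"
KIND_NCO = "NCO_conversion"
KIND_BIR = "BIR"
KIND_LOSS = "chromosome_loss"
KIND_COMPLEX = "complex"

INDEPENDENCE_GAP_BP = 15_000

_HOMS = (HOM_P1, HOM_P2)


class ClassifierError(ValueError):
    pass


@dataclass
class RecombEvent:
    kind: str
    pattern: str                       # none | 3:1 | 4:0 | hybrid | complex
    mechanism: str                     # SCB | DSCB | NA
    recipient: str                     # P1 | P2 | ambiguous
    chromosome: str
    tract_min: tuple[int, int] | None  # first..last LOH SNP (bp)
    tract_max: tuple[int, int] | None  # flanking called SNPs (bp)
    independent_group: int = 0
    transitions: dict = field(default_factory=dict)  # sector -> [(inner, outer), ...]
    selected: bool = False

    @property
    def midpoint(self) -> float | None:
        if self.tract_max is None:
            return None
        return 0.5 * (self.tract_max[0] + self.tract_max[1])


@dataclass
class TransitionCluster:
    chromosome: str
    group_id: int
    segments: list[tuple[int, Segment]]    # (sector index, LOH segment)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s.first_pos for _i, s in self.segments),
                max(s.last_pos for _i, s in self.segments))


def _check_same_map(a: SectorCall, b: SectorCall) -> None:
    ka = a.calls[["chromosome", "position"]].to_numpy()
    kb = b.calls[["chromosome", "position"]].to_numpy()
    if ka.shape != kb.shape or not (ka == kb).all():
        raise ClassifierError("sector calls use different SNP maps")


def pair_sectors(a: SectorCall, b: SectorCall,
                 gap_bp: int = INDEPENDENCE_GAP_BP) -> list[TransitionCluster]:
    """Group the two sectors' LOH segments into clusters of one initiating
    event each.  LOH regions separated by more than ``gap_bp`` of shared
    heterozygosity get distinct independent-group ids."""
    _check_same_map(a, b)
    clusters: list[TransitionCluster] = []
    gid = 0
    for chrom in a.chromosomes():
        segs = [(0, s) for s in a.loh_segments(chrom)] + \
               [(1, s) for s in b.loh_segments(chrom)]
        if not segs:
            continue
        segs.sort(key=lambda t: (t[1].first_pos, t[1].last_pos))
        current = [segs[0]]
        cur_end = segs[0][1].last_pos
        for item in segs[1:]:
            if item[1].first_pos - cur_end > gap_bp:
                clusters.append(TransitionCluster(chrom, gid, current))
                gid += 1
                current = []
            current.append(item)
            cur_end = max(cur_end, item[1].last_pos)
        clusters.append(TransitionCluster(chrom, gid, current))
        gid += 1
    return clusters


# ---------------------------------------------------------------------------
# Per-cluster classification
# ---------------------------------------------------------------------------

def _segment_state_track(sector: SectorCall, chrom: str, n: int) -> np.ndarray:
    """Per-SNP states smoothed to the segment level (absorbed single-SNP
    discordances take their segment's state; SNPs in no segment are NOCALL)."""
    arr = np.full(n, NOCALL, dtype=np.int8)
    for seg in sector.segments.get(chrom, []):
        arr[seg.first_idx:seg.last_idx + 1] = seg.state
    return arr


def _donor_to_recipient(hom_states: set[int]) -> str:
    if hom_states == {HOM_P1}:
        return P2
    if hom_states == {HOM_P2}:
        return P1
    return "ambiguous"


class EventClassifier:
    """Pairs two sector calls on a shared SNP map and classifies each
    transition cluster into a recombination event."""

    def __init__(self, snp_map: SnpMap, marker: MarkerConfig,
                 gap_bp: int = INDEPENDENCE_GAP_BP, boundary_tol_snps: int = 1):
        self.snp_map = snp_map
        self.marker = marker
        self.gap_bp = gap_bp
        self.boundary_tol_snps = boundary_tol_snps

    def classify(self, a: SectorCall, b: SectorCall) -> list[RecombEvent]:
        clusters = pair_sectors(a, b, gap_bp=self.gap_bp)
        return self.classify_clusters(clusters, a, b)

    def classify_clusters(self, clusters: list[TransitionCluster],
                          a: SectorCall, b: SectorCall) -> list[RecombEvent]:
        events = []
        for cluster in clusters:
            events.append(self._classify_one(cluster, (a, b)))
        return events

    # -- internals ---------------------------------------------------------
    def _classify_one(self, cluster: TransitionCluster,
                      sectors: tuple[SectorCall, SectorCall]) -> RecombEvent:
        chrom = cluster.chromosome
        pos = self.snp_map.positions(chrom)
        n = len(pos)
        tracks = [_segment_state_track(s, chrom, n) for s in sectors]
        cen = self.marker.centromere(chrom)

        seg_lists = [
            [s for _i, s in cluster.segments if _i == si] for si in (0, 1)
        ]
        all_sector_segs = [sectors[si].segments.get(chrom, []) for si in (0, 1)]

        def terminal_side(si: int, seg: Segment) -> str | None:
            segs = all_sector_segs[si]
            if seg.first_idx == 0:
                return "left"
            last_called = max(s.last_idx for s in segs) if segs else -1
            if seg.last_idx == last_called and seg.last_idx == n - 1:
                return "right"
            # tolerate trailing NOCALLs: terminal if nothing called beyond it
            if all(s.last_idx <= seg.last_idx for s in segs) and \
                    not np.any(tracks[si][seg.last_idx + 1:] != NOCALL):
                return "right"
            if all(s.first_idx >= seg.first_idx for s in segs) and \
                    not np.any(tracks[si][:seg.first_idx] != NOCALL):
                return "left"
            return None

        terminals: list[tuple[int, Segment, str]] = []
        for si in (0, 1):
            for seg in seg_lists[si]:
                side = terminal_side(si, seg)
                if side is not None:
                    terminals.append((si, seg, side))

        transitions = {
            si: [(t.inner, t.outer) for t in sectors[si].transitions.get(chrom, [])
                 if cluster.span[0] <= t.outer and t.inner <= cluster.span[1]]
            for si in (0, 1)
        }

        def build(kind, pattern, mechanism, recipient, tmin, tmax) -> RecombEvent:
            return RecombEvent(kind=kind, pattern=pattern, mechanism=mechanism,
                               recipient=recipient, chromosome=chrom,
                               tract_min=tmin, tract_max=tmax,
                               independent_group=cluster.group_id,
                               transitions=transitions)

        lo_idx = int(np.searchsorted(pos, cluster.span[0]))
        hi_idx = int(np.searchsorted(pos, cluster.span[1], side="right")) - 1

        def flank_bounds(first_i: int, last_i: int) -> tuple[int, int]:
            left = pos[first_i - 1] if first_i > 0 else 1
            right = pos[last_i + 1] if last_i < n - 1 else self.snp_map.lengths[chrom]
            return int(left), int(right)

        # -- chromosome loss: one sector homozygous end to end, other all het
        for si in (0, 1):
            segs = all_sector_segs[si]
            other = 1 - si
            if (len(segs) == 1 and segs[0].state in _HOMS
                    and segs[0].first_idx == 0 and segs[0].last_idx == n - 1
                    and not sectors[other].loh_segments(chrom)):
                return build(KIND_LOSS, "none", "NA",
                             _donor_to_recipient({segs[0].state}),
                             (int(pos[0]), int(pos[-1])), (1, self.snp_map.lengths[chrom]))

        term_by_sector: dict[int, tuple[Segment, str]] = {}
        for si, seg, side in terminals:
            term_by_sector.setdefault(si, (seg, side))

        if len(term_by_sector) == 2:
            (sa, side_a), (sb, side_b) = term_by_sector[0], term_by_sector[1]
            if side_a == side_b and sa.state != sb.state:
                return self._classify_crossover(cluster, tracks, pos, side_a,
                                                (sa, sb), build, flank_bounds)
            return build(KIND_COMPLEX, "complex",
                         self._mechanism_from_joint(tracks, lo_idx, hi_idx),
                         "ambiguous", *self._loh_bounds(tracks, pos, lo_idx, hi_idx,
                                                        flank_bounds))

        if len(term_by_sector) == 1:
            si = next(iter(term_by_sector))
            other = 1 - si
            other_has_loh = bool(seg_lists[other])
            seg, _side = term_by_sector[si]
            tmin = (seg.first_pos, seg.last_pos)
            tmax = flank_bounds(seg.first_idx, seg.last_idx)
            if not other_has_loh and len(seg_lists[si]) == 1:
                return build(KIND_BIR, "none", "NA",
                             _donor_to_recipient({seg.state}), tmin, tmax)
            return build(KIND_COMPLEX, "complex",
                         self._mechanism_from_joint(tracks, lo_idx, hi_idx),
                         "ambiguous", *self._loh_bounds(tracks, pos, lo_idx, hi_idx,
                                                        flank_bounds))

        # -- interstitial-only cluster ------------------------------------
        return self._classify_interstitial(cluster, tracks, pos, seg_lists,
                                           build, flank_bounds, lo_idx, hi_idx)

    def _loh_bounds(self, tracks, pos, lo_idx, hi_idx, flank_bounds):
        idx = [i for i in range(lo_idx, hi_idx + 1)
               if tracks[0][i] in _HOMS or tracks[1][i] in _HOMS]
        if not idx:
            return None, None
        return ((int(pos[idx[0]]), int(pos[idx[-1]])),
                flank_bounds(idx[0], idx[-1]))

    def _mechanism_from_joint(self, tracks, lo_idx, hi_idx) -> str:
        """Any 4:0 segment (both sectors homozygous for the same parent at
        >= 2 consecutive informative SNPs) implies a DSCB."""
        a, b = tracks[0][lo_idx:hi_idx + 1], tracks[1][lo_idx:hi_idx + 1]
        shared = (a == b) & np.isin(a, _HOMS)
        run = 0
        for flag in shared:
            run = run + 1 if flag else 0
            if run >= 2:
                return "DSCB"
        return "SCB"

    def _classify_crossover(self, cluster, tracks, pos, side, term_segs,
                            build, flank_bounds) -> RecombEvent:
        sa, sb = term_segs
        n = len(pos)
        # orient so "distal" is increasing index
        orient = np.arange(n) if side == "right" else np.arange(n)[::-1]
        a = tracks[0][orient]
        b = tracks[1][orient]
        # the reciprocal region begins once *both* sectors are inside their
        # terminal segments; LOH proximal of that is conversion evidence
        if side == "right":
            start_a, start_b = sa.first_idx, sb.first_idx
        else:
            start_a, start_b = n - 1 - sa.last_idx, n - 1 - sb.last_idx
        r = max(start_a, start_b)
        loh = np.isin(a, _HOMS) | np.isin(b, _HOMS)
        # conversion SNPs are confined to this cluster's span; unrelated LOH
        # elsewhere on the chromosome belongs to other clusters
        lo_g = int(np.searchsorted(pos, cluster.span[0]))
        hi_g = int(np.searchsorted(pos, cluster.span[1], side="right")) - 1
        in_cluster = np.zeros(n, dtype=bool)
        in_cluster[lo_g:hi_g + 1] = True
        in_cluster = in_cluster[orient]
        conv_idx = [i for i in range(n)
                    if loh[i] and i < r and in_cluster[i]]
        # map back to genomic indices
        conv_gidx = sorted(orient[i] for i in conv_idx)
        hom_dirs: set[int] = set()
        has_40 = has_31 = False
        for i in conv_idx:
            ah, bh = a[i] in _HOMS, b[i] in _HOMS
            if ah and bh and a[i] == b[i]:
                has_40 = True
                hom_dirs.add(int(a[i]))
            elif ah != bh:
                has_31 = True
                hom_dirs.add(int(a[i] if ah else b[i]))
        if not conv_gidx:
            return build(KIND_CO, "none", "NA", "ambiguous", None, None)
        tmin = (int(pos[conv_gidx[0]]), int(pos[conv_gidx[-1]]))
        # distal max bound is the first SNP of the reciprocal region
        first_recip_g = int(orient[r]) if r < n else conv_gidx[-1]
        if side == "right":
            left = pos[conv_gidx[0] - 1] if conv_gidx[0] > 0 else 1
            tmax = (int(left), int(pos[first_recip_g]))
        else:
            right = pos[conv_gidx[-1] + 1] if conv_gidx[-1] < n - 1 \
                else self.snp_map.lengths[cluster.chromosome]
            tmax = (int(pos[first_recip_g]), int(right))
        if has_40 and has_31:
            pattern, mech = "hybrid", "DSCB"
        elif has_40:
            pattern, mech = "4:0", "DSCB"
        else:
            pattern, mech = "3:1", "SCB"
        return build(KIND_CO_CONV, pattern, mech,
                     _donor_to_recipient({h for h in hom_dirs}), tmin, tmax)

    def _classify_interstitial(self, cluster, tracks, pos, seg_lists,
                               build, flank_bounds, lo_idx, hi_idx) -> RecombEvent:
        n_segs = (len(seg_lists[0]), len(seg_lists[1]))
        tmin, tmax = self._loh_bounds(tracks, pos, lo_idx, hi_idx, flank_bounds)

        def hom_states(si):
            return {s.state for s in seg_lists[si]}

        if n_segs[0] and n_segs[1]:
            states = hom_states(0) | hom_states(1)
            if len(states) > 1:
                return build(KIND_COMPLEX, "complex",
                             self._mechanism_from_joint(tracks, lo_idx, hi_idx),
                             "ambiguous", tmin, tmax)
            if n_segs == (1, 1):
                s0, s1 = seg_lists[0][0], seg_lists[1][0]
                overlap = not (s0.last_pos < s1.first_pos or s1.last_pos < s0.first_pos)
                d_first = abs(s0.first_idx - s1.first_idx)
                d_last = abs(s0.last_idx - s1.last_idx)
                if overlap and d_first <= self.boundary_tol_snps \
                        and d_last <= self.boundary_tol_snps:
                    pattern = "4:0"
                elif overlap:
                    pattern = "hybrid"
                else:
                    return build(KIND_COMPLEX, "complex", "DSCB", "ambiguous",
                                 tmin, tmax)
                return build(KIND_NCO, pattern, "DSCB",
                             _donor_to_recipient(states), tmin, tmax)
            return build(KIND_COMPLEX, "complex",
                         self._mechanism_from_joint(tracks, lo_idx, hi_idx),
                         "ambiguous", tmin, tmax)

        si = 0 if n_segs[0] else 1
        if n_segs[si] == 1:
            seg = seg_lists[si][0]
            return build(KIND_NCO, "3:1", "SCB",
                         _donor_to_recipient({seg.state}),
                         (seg.first_pos, seg.last_pos),
                         flank_bounds(seg.first_idx, seg.last_idx))
        return build(KIND_COMPLEX, "complex",
                     self._mechanism_from_joint(tracks, lo_idx, hi_idx),
                     "ambiguous", tmin, tmax)


def classify_events(clusters: list[TransitionCluster], a: SectorCall, b: SectorCall,
                    snp_map: SnpMap, marker: MarkerConfig, **kw) -> list[RecombEvent]:
    return EventClassifier(snp_map, marker, **kw).classify_clusters(clusters, a, b)


def infer_recipient(event: RecombEvent) -> str:
    """Recipient homolog of a conversion: the one whose alleles were
    overwritten (the donor's alleles became homozygous)."""
    return event.recipient


# ---------------------------------------------------------------------------
# Cohort bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    by_kind: pd.Series
    by_pattern: pd.Series
    by_mechanism: pd.Series
    n_events: int
    n_selected: int
    n_unselected: int
    unselected_by_kind: pd.Series


def mark_selected(events: list[RecombEvent], marker: MarkerConfig) -> None:
    """Flag events on the selected chromosome arm (centromere-to-marker side)."""
    chrom, start, end = marker.selected_interval
    lo, hi = min(start, end), max(start, end)
    cen = marker.centromere(chrom)
    for ev in events:
        if ev.chromosome != chrom:
            continue
        span = ev.tract_max or ev.tract_min
        if span is None:
            continue
        # the selected arm runs from the arm telomere through the centromere
        arm_lo, arm_hi = (1, cen) if hi <= cen else (cen, None)
        if arm_hi is None:
            sel = span[1] >= arm_lo
        else:
            sel = span[0] <= arm_hi
        ev.selected = bool(sel)


def summarize_cohort(events: list[RecombEvent],
                     selection_filter=None) -> CohortSummary:
    """Counts by kind/pattern/mechanism with selected-interval events
    separable from the unselected tallies."""
    if selection_filter is not None:
        for ev in events:
            ev.selected = bool(selection_filter(ev))
    df = pd.DataFrame({
        "kind": [e.kind for e in events],
        "pattern": [e.pattern for e in events],
        "mechanism": [e.mechanism for e in events],
        "selected": [e.selected for e in events],
    })
    if df.empty:
        empty = pd.Series(dtype=int)
        return CohortSummary(empty, empty, empty, 0, 0, 0, empty)
    unsel = df[~df["selected"]]
    return CohortSummary(
        by_kind=df["kind"].value_counts(),
        by_pattern=df["pattern"].value_counts(),
        by_mechanism=df["mechanism"].value_counts(),
        n_events=len(df),
        n_selected=int(df["selected"].sum()),
        n_unselected=len(unsel),
        unselected_by_kind=unsel["kind"].value_counts(),
    )


def scb_dscb_matrix(nco_scb: int, nco_dscb: int,
                    co_scb: int, co_dscb: int) -> np.ndarray:
    """2x2 contingency matrix of SCB/DSCB counts for conversions unassociated
    (row 0) and associated (row 1) with crossovers."""
    return np.array([[nco_scb, nco_dscb], [co_scb, co_dscb]], dtype=int)


def scb_dscb_matrix_from_events(events: list[RecombEvent]) -> np.ndarray:
    nco = [e for e in events if e.kind == KIND_NCO]
    co = [e for e in events if e.kind == KIND_CO_CONV]
    return scb_dscb_matrix(
        sum(e.mechanism == "SCB" for e in nco), sum(e.mechanism == "DSCB" for e in nco),
        sum(e.mechanism == "SCB" for e in co), sum(e.mechanism == "DSCB" for e in co),
    )
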