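"""Chromosome XII rDNA crossover assay: marker phase, sector phenotypes and
Table-style tabulation.

One homolog (H1) carries a hygromycin-resistance insertion immediately
centromere-proximal to the rDNA cluster and a TRP1 insertion inside the
cluster; the other homolog (H2) carries URA3 immediately distal to the
cluster.  Replica-plating sectored colonies to hygromycin, -trp, -ura and
5-FOA media distinguishes reciprocal crossovers (RCO), break-induced
replication initiated on either homolog (BIR-U / BIR-H) and intrachromosomal
events (ICR) in three intervals: CEN12-HYG (300 kb), HYG-TRP1 and TRP1-URA3
(together the 1170 kb HYG-URA3 interval containing the cluster).

5-FOA resolves the Ura+ ambiguity: URA3/URA3 homozygotes (crossover
products) produce no 5-FOA-resistant papillae, heterozygotes (BIR products
and the parental configuration) papillate, and ura-/ura- segregants grow
confluently.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

from .stats import normalized_induced

HYG, TRP1, URA3 = "HYG", "TRP1", "URA3"
_MARKER_POS = {HYG: 1.0, TRP1: 2.0, URA3: 3.0}

RCO, BIR_U, BIR_H, ICR = "RCO", "BIR-U", "BIR-H", "ICR"
CEN12_HYG, HYG_TRP1, TRP1_URA3 = "CEN12-HYG", "HYG-TRP1", "TRP1-URA3"
INTERVALS = (CEN12_HYG, HYG_TRP1, TRP1_URA3)
_BREAKPOINT = {CEN12_HYG: 0.5, HYG_TRP1: 1.5, TRP1_URA3: 2.5}

FOA_CONFLUENT = "confluent"   # no URA3 copy
FOA_PAPILLAE = "papillae"     # URA3 heterozygous
FOA_NONE = "none"             # URA3 homozygous


class RdnaError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerPhase:
    """Marker arrangement on chromosome XII.  Interval lengths in kb."""

    cen12_hyg_kb: float = 300.0
    hyg_ura3_kb: float = 1170.0
    h1_markers: frozenset = frozenset({HYG, TRP1})
    h2_markers: frozenset = frozenset({URA3})


@dataclass(frozen=True)
class SectorPhenotype:
    hyg_resistant: bool
    trp_plus: bool
    ura_plus: bool
    foa: str

    def __post_init__(self) -> None:
        if self.foa not in (FOA_CONFLUENT, FOA_PAPILLAE, FOA_NONE):
            raise RdnaError(f"unknown FOA phenotype {self.foa!r}")
        if self.ura_plus and self.foa == FOA_CONFLUENT:
            raise RdnaError("Ura+ cells cannot grow confluently on 5-FOA")
        if not self.ura_plus and self.foa != FOA_CONFLUENT:
            raise RdnaError("Ura- cells grow confluently on 5-FOA")


@dataclass(frozen=True)
class EventCategory:
    kind: str                      # RCO | BIR-U | BIR-H | ICR
    interval: str | None = None    # None for ICR

    def __post_init__(self) -> None:
        if self.kind not in (RCO, BIR_U, BIR_H, ICR):
            raise RdnaError(f"unknown event kind {self.kind!r}")
        if self.kind == ICR:
            if self.interval is not None:
                raise RdnaError("ICR events carry no interval")
        elif self.interval not in INTERVALS:
            raise RdnaError(f"unknown interval {self.interval!r}")


ALL_CATEGORIES = tuple(
    [EventCategory(k, i) for k, i in product((RCO, BIR_U, BIR_H), INTERVALS)]
    + [EventCategory(ICR)]
)


def _phenotype(genotype: tuple[frozenset, ...]) -> SectorPhenotype:
    ura_copies = sum(URA3 in chrom for chrom in genotype)
    return SectorPhenotype(
        hyg_resistant=any(HYG in chrom for chrom in genotype),
        trp_plus=any(TRP1 in chrom for chrom in genotype),
        ura_plus=ura_copies > 0,
        foa={0: FOA_CONFLUENT, 1: FOA_PAPILLAE, 2: FOA_NONE}[ura_copies],
    )


def predict_phenotypes(category: EventCategory,
                       phase: MarkerPhase = MarkerPhase()
                       ) -> tuple[SectorPhenotype, SectorPhenotype]:
    """Propagate marker zygosity through the event geometry and return the
    two daughter-sector phenotypes."""
    h1, h2 = phase.h1_markers, phase.h2_markers
    if category.kind == ICR:
        d1 = (h1 - {TRP1}, h2)
        d2 = (h1, h2)
    else:
        c = _BREAKPOINT[category.interval]
        def split(m):  # (proximal, distal) marker sets around the breakpoint
            return ({x for x in m if _MARKER_POS[x] < c},
                    {x for x in m if _MARKER_POS[x] > c})
        h1p, h1d = split(h1)
        h2p, h2d = split(h2)
        if category.kind == RCO:
            r1 = frozenset(h1p | h2d)
            r2 = frozenset(h2p | h1d)
            d1 = (h1, r2)
            d2 = (h2, r1)
        elif category.kind == BIR_U:   # DSB on the URA3 homolog; copies H1 distal
            d1 = (h1, frozenset(h2p | h1d))
            d2 = (h1, h2)
        else:                          # BIR-H: DSB on the HYG homolog
            d1 = (frozenset(h1p | h2d), h2)
            d2 = (h1, h2)
    return _phenotype(tuple(map(frozenset, d1))), _phenotype(tuple(map(frozenset, d2)))


@dataclass
class ColonyClassification:
    category: EventCategory | None     # unique category, or kind-level call
    candidates: tuple[EventCategory, ...]

    @property
    def unambiguous(self) -> bool:
        return len(self.candidates) == 1


def classify_colony(phenotypes: tuple[SectorPhenotype, SectorPhenotype],
                    phase: MarkerPhase = MarkerPhase()) -> ColonyClassification:
    """Inverse lookup of predict_phenotypes over all categories.

    Sector order is ignored.  The three BIR-U categories produce identical
    phenotype pairs on the four scoring media, so a BIR-U colony is returned
    with all three intervals as candidates (the event kind itself is always
    unambiguous); any pattern produced by no category is unclassified
    (empty candidates).
    """
    observed = frozenset(phenotypes)
    if len(observed) == 1:
        return ColonyClassification(category=None, candidates=())
    matches = [cat for cat in ALL_CATEGORIES
               if frozenset(predict_phenotypes(cat, phase)) == observed]
    if not matches:
        return ColonyClassification(category=None, candidates=())
    if len(matches) == 1:
        return ColonyClassification(category=matches[0], candidates=tuple(matches))
    # interval-degenerate pattern (the three BIR-U classes): kind is still
    # unambiguous, the interval is not
    return ColonyClassification(category=None, candidates=tuple(matches))


# ---------------------------------------------------------------------------
# Table-style tabulation
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    (RCO, CEN12_HYG), (BIR_U, CEN12_HYG), (BIR_H, CEN12_HYG),
    (RCO, HYG_TRP1), (BIR_U, HYG_TRP1), (BIR_H, HYG_TRP1),
    (RCO, TRP1_URA3), (BIR_U, TRP1_URA3), (BIR_H, TRP1_URA3),
    (ICR, None),
]


@dataclass
class RdnaTable:
    table: pd.DataFrame                  # rows: treated/untreated/normalized
    per_kb_co: dict                      # interval -> per-kb crossover frequency
    n_treated: int
    n_untreated: int


def tabulate_rdna(counts: dict, n_treated: int, n_untreated: int,
                  phase: MarkerPhase = MarkerPhase()) -> RdnaTable:
    """Build the normalized event table from observed category counts.

    ``counts`` maps (kind, interval) -> (observed_treated, observed_untreated);
    the phenotypically silent BIR-H TRP1-URA3 class is imputed as equal to
    its BIR-U counterpart in both rows.  Normalization subtracts the
    untreated counts scaled by the ratio of colonies examined; per-kb
    crossover frequencies use detection factor 2 (only half of crossovers
    yield a sectored colony).
    """
    counts = {(k, i): tuple(v) for (k, i), v in counts.items()}
    imputed = counts.get((BIR_U, TRP1_URA3), (0, 0))
    counts[(BIR_H, TRP1_URA3)] = imputed

    treated_row, untreated_row, norm_row, norm_raw = {}, {}, {}, {}
    for key in _TABLE_COLUMNS:
        t, u = counts.get(key, (0, 0))
        ac = normalized_induced(t, u, n_treated, n_untreated,
                                name=f"{key[0]}:{key[1]}")
        label = key[0] if key[1] is None else f"{key[0]} {key[1]}"
        treated_row[label] = t
        untreated_row[label] = u
        norm_raw[label] = ac.normalized
        norm_row[label] = int(round(ac.normalized))

    table = pd.DataFrame(
        [treated_row, untreated_row, norm_row, norm_raw],
        index=["UV-treated", "Untreated", "Normalized UV-treated",
               "Normalized (unrounded)"],
    )

    rco_cen = norm_raw[f"{RCO} {CEN12_HYG}"]
    rco_rdna = norm_raw[f"{RCO} {HYG_TRP1}"] + norm_raw[f"{RCO} {TRP1_URA3}"]
    per_kb = {
        CEN12_HYG: rco_cen / n_treated * 2.0 / phase.cen12_hyg_kb,
        "HYG-URA3": rco_rdna / n_treated * 2.0 / phase.hyg_ura3_kb,
    }
    return RdnaTable(table=table, per_kb_co=per_kb,
                     n_treated=n_treated, n_untreated=n_untreated)
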