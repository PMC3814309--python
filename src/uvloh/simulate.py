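"""Forward simulator of UV-induced mitotic recombination in a diploid.

The model chain is: UV dose -> pyrimidine-dimer lesions (Poisson, uniform
over the diploid genome) -> recombinogenic breaks (isolated lesions become
single-chromatid breaks, SCBs; closely-opposed opposite-strand lesion pairs
become double-sister-chromatid breaks, DSCBs) -> repair off the homolog by
SDSA, double-Holliday-junction repair (crossover or not) or break-induced
replication -> segregation of the four chromatids into two daughter cells ->
colony color from marker copy number and array-like per-SNP hybridization
ratios per sector.

Breaks repaired off the sister chromatid are invisible to loss of
heterozygosity; the simulator prunes them at generation via
``interhomolog_prob`` (applied to SCBs only, since a G1 double-sister break
has no intact sister to copy).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import P1, P2, MarkerConfig, SnpMap
from .states import HET, HOM_P1, HOM_P2

SCB = "SCB"
DSCB = "DSCB"

PATH_SDSA = "SDSA"
PATH_DSBR = "DSBR"
PATH_BIR = "BIR"

COLOR_BY_COPIES = {0: "red", 1: "pink", 2: "white"}
_COLOR_ORDER = {"pink": 0, "red": 1, "white": 2}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All tunable parameters of the lesion/repair/readout model.

    Pathway choice is parameterized as (p_sdsa, p_dsbr, p_bir) summing to 1,
    with ``crossover_prob`` the probability that double-Holliday-junction
    repair resolves as a crossover; the implied per-break outcome
    probabilities are therefore SDSA, DSBR-CO = p_dsbr*crossover_prob,
    DSBR-NCO and BIR.
    """

    dose: float = 15.0                    # J/m^2
    dimers_per_jm2: float = 500.0         # lesions per J/m^2 per diploid genome
    closely_opposed_max_sep: int = 75     # bp; opposite-strand pair window
    scb_rate_per_dimer: float = 0.012     # isolated lesion -> single-chromatid break
    dscb_from_opposed: float = 0.05       # closely-opposed pair -> G1 double-sister break
    clustered_dimer_excess: float = 0.0   # dose-independent fraction placed near a prior lesion
    interhomolog_prob: float = 0.05       # SCB repaired off the homolog (vs silent sister repair)
    p_sdsa: float = 0.40
    p_dsbr: float = 0.545
    p_bir: float = 0.055
    crossover_prob: float = 0.578         # CO | DSBR
    tract_shape: float = 2.0              # gamma shape for conversion tract lengths
    # Per-chromatid heteroduplex tract medians (bp).  Observed tracts merge
    # the two sisters' tracts, so these are calibrated such that the
    # *measured* medians land near 4.9 kb (non-crossover) and 7.6 kb
    # (crossover-associated) conversions.
    tract_median_bp: float = 3850.0
    tract_median_co_bp: float = 6000.0
    dscb_equal_tract_prob: float = 0.5    # both sisters resect/repair to identical bounds (4:0)
    patchy_repair_prob: float = 0.10      # per-SNP mixed-direction mismatch repair
    restoration_prob: float = 0.05        # whole-tract restoration-type repair (no LOH)
    branch_migration_prob: float = 0.0    # extend one tract edge by an extra gamma draw
    noise_sd: float = 0.10                # array ratio noise
    ratio_hom_hi: float = 1.8
    ratio_hom_lo: float = 0.2
    max_breaks_per_cell: int = 25         # Poisson thinning cap
    second_division_prob: float = 0.0     # damage persisting into the second division
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = {
            "scb_rate_per_dimer": self.scb_rate_per_dimer,
            "dscb_from_opposed": self.dscb_from_opposed,
            "clustered_dimer_excess": self.clustered_dimer_excess,
            "interhomolog_prob": self.interhomolog_prob,
            "p_sdsa": self.p_sdsa,
            "p_dsbr": self.p_dsbr,
            "p_bir": self.p_bir,
            "crossover_prob": self.crossover_prob,
            "dscb_equal_tract_prob": self.dscb_equal_tract_prob,
            "patchy_repair_prob": self.patchy_repair_prob,
            "restoration_prob": self.restoration_prob,
            "branch_migration_prob": self.branch_migration_prob,
            "second_division_prob": self.second_division_prob,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1], got {p}")
        if abs(self.p_sdsa + self.p_dsbr + self.p_bir - 1.0) > 1e-9:
            raise SimulationError("pathway probabilities must sum to 1")
        if self.dose < 0:
            raise SimulationError("dose must be >= 0")
        if self.tract_median_bp <= 0 or self.tract_median_co_bp <= 0:
            raise SimulationError("tract medians must be positive")
        if self.tract_shape <= 0:
            raise SimulationError("tract shape must be positive")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.closely_opposed_max_sep <= 0:
            raise SimulationError("closely_opposed_max_sep must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SimulationError(f"unknown simulation parameters: {sorted(unknown)}")
        return cls(**d)

    def tract_scale(self, crossover: bool) -> float:
        median = self.tract_median_co_bp if crossover else self.tract_median_bp
        return median / sps.gamma.ppf(0.5, self.tract_shape)


# ---------------------------------------------------------------------------
# Lesions and breaks
# ---------------------------------------------------------------------------

@dataclass
class LesionSet:
    """Dimer positions per homolog and strand (columns: chromosome, position,
    homolog in {0, 1}, strand in {0, 1})."""

    table: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass
class BreakSet:
    """Breaks (columns: chromosome, position, homolog, kind in {SCB, DSCB})."""

    table: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.table)


def place_dimers(config: SimulationConfig, snp_map: SnpMap,
                 rng: np.random.Generator | None = None) -> LesionSet:
    """Scatter UV lesions Poisson-distributed over the diploid genome.

    Expected count is dose x dimers_per_jm2.  A ``clustered_dimer_excess``
    fraction is placed on the opposite strand within the closely-opposed
    window of an already-placed lesion, emulating the observed dose-
    independent excess of near-opposed dimer pairs.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = rng.poisson(config.dose * config.dimers_per_jm2)
    cols = ["chromosome", "position", "homolog", "strand"]
    if n == 0:
        return LesionSet(pd.DataFrame(columns=cols))
    names = snp_map.chromosome_names
    lengths = np.array([l for _, l in snp_map.chromosomes], dtype=float)
    weights = lengths / lengths.sum()
    n_clustered = rng.binomial(n, config.clustered_dimer_excess)
    n_base = n - n_clustered
    ci = rng.choice(len(names), size=n_base, p=weights)
    pos = (rng.random(n_base) * lengths[ci]).astype(np.int64) + 1
    hom = rng.integers(0, 2, size=n_base)
    strand = rng.integers(0, 2, size=n_base)
    chroms = [names[i] for i in ci]
    if n_clustered > 0 and n_base > 0:
        anchor = rng.integers(0, n_base, size=n_clustered)
        offs = rng.integers(1, config.closely_opposed_max_sep + 1, size=n_clustered)
        sign = rng.choice([-1, 1], size=n_clustered)
        cpos = pos[anchor] + sign * offs
        cpos = np.clip(cpos, 1, lengths[ci[anchor]].astype(np.int64))
        chroms = chroms + [names[i] for i in ci[anchor]]
        pos = np.concatenate([pos, cpos])
        hom = np.concatenate([hom, hom[anchor]])
        strand = np.concatenate([strand, 1 - strand[anchor]])
    df = pd.DataFrame({"chromosome": chroms, "position": pos,
                       "homolog": hom, "strand": strand})
    order = {name: i for i, name in enumerate(names)}
    df["_o"] = df["chromosome"].map(order)
    df = df.sort_values(["_o", "homolog", "position"]).drop(columns="_o")
    return LesionSet(df.reset_index(drop=True))


def derive_breaks(lesions: LesionSet, config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> BreakSet:
    """Convert lesions into SCBs and DSCBs.

    Opposite-strand pairs separated by at most ``closely_opposed_max_sep`` on
    the same (unreplicated G1) homolog become DSCBs with probability
    ``dscb_from_opposed`` (break at the pair midpoint); each remaining lesion
    independently becomes an SCB with probability ``scb_rate_per_dimer``.
    With no clustering, SCB counts scale linearly and DSCB counts roughly
    quadratically with dose.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows: list[tuple[str, int, int, str]] = []
    if lesions.n:
        for (chrom, hom), grp in lesions.table.groupby(["chromosome", "homolog"], sort=False):
            pos = grp["position"].to_numpy()
            strand = grp["strand"].to_numpy()
            n = len(pos)
            used = np.zeros(n, dtype=bool)
            i = 0
            while i < n - 1:
                if (not used[i] and not used[i + 1]
                        and strand[i] != strand[i + 1]
                        and pos[i + 1] - pos[i] <= config.closely_opposed_max_sep):
                    if rng.random() < config.dscb_from_opposed:
                        rows.append((chrom, int((pos[i] + pos[i + 1]) // 2), int(hom), DSCB))
                    # the pair is consumed whether or not it broke
                    used[i] = used[i + 1] = True
                    i += 2
                else:
                    i += 1
            free = ~used
            scb_mask = free & (rng.random(n) < config.scb_rate_per_dimer)
            for p in pos[scb_mask]:
                rows.append((chrom, int(p), int(hom), SCB))
    df = pd.DataFrame(rows, columns=["chromosome", "position", "homolog", "kind"])
    return BreakSet(df)


def expected_closely_opposed(n_dimers: int, genome_len: float, max_sep: float,
                             strand_model: str = "opposite") -> float:
    """Closed-form expected number of closely-opposed dimer pairs.

    Under uniform independent placement of ``n_dimers`` positions on a
    contiguous genome of ``genome_len`` bp, the expected number of unordered
    pairs within ``max_sep`` of each other is C(n,2) * (2dG - d^2)/G^2;
    with the "opposite" strand model each pair additionally requires
    opposite strands (probability 1/2).
    """
    if genome_len <= 0:
        raise SimulationError("genome_len must be positive")
    if n_dimers < 0:
        raise SimulationError("n_dimers must be >= 0")
    if n_dimers < 2:
        return 0.0
    d = min(float(max_sep), float(genome_len))
    g = float(genome_len)
    p_dist = (2.0 * d * g - d * d) / (g * g)
    if strand_model == "opposite":
        p_strand = 0.5
    elif strand_model == "any":
        p_strand = 1.0
    else:
        raise SimulationError(f"unknown strand_model {strand_model!r}")
    return 0.5 * n_dimers * (n_dimers - 1) * p_strand * p_dist


# ---------------------------------------------------------------------------
# Chromatids and repair
# ---------------------------------------------------------------------------

class DiploidChromatids:
    """Four chromatids per chromosome, tracked as parental-origin codes
    (0 = P1, 1 = P2) on the SNP grid plus the color-marker locus.

    Rows 0-1 are the sisters of homolog 0 (P1), rows 2-3 of homolog 1 (P2).
    """

    def __init__(self, snp_map: SnpMap, marker: MarkerConfig):
        self.snp_map = snp_map
        self.marker = marker
        self.positions: dict[str, np.ndarray] = {}
        self.origins: dict[str, np.ndarray] = {}
        self.is_snp: dict[str, np.ndarray] = {}
        self.marker_index: int | None = None
        mchrom, mpos, carrier = marker.color_marker
        self.marker_carrier_code = 0 if carrier == P1 else 1
        for chrom, _length in snp_map.chromosomes:
            pos = snp_map.positions(chrom)
            is_snp = np.ones(len(pos), dtype=bool)
            if chrom == mchrom and mpos not in pos:
                j = int(np.searchsorted(pos, mpos))
                pos = np.insert(pos, j, mpos)
                is_snp = np.insert(is_snp, j, False)
                self.marker_index = j
            elif chrom == mchrom:
                self.marker_index = int(np.searchsorted(pos, mpos))
            self.positions[chrom] = pos
            self.is_snp[chrom] = is_snp
            org = np.zeros((4, len(pos)), dtype=np.int8)
            org[2:, :] = 1
            self.origins[chrom] = org

    def marker_copies(self, rows: tuple[int, ...]) -> int:
        chrom = self.marker.marker_chromosome
        j = self.marker_index
        return int(sum(self.origins[chrom][r, j] == self.marker_carrier_code for r in rows))


@dataclass
class EventTruth:
    """Ground-truth record of one repaired break, annotated after segregation
    with what an ideal (noise-free) array reader of the two sectors would see."""

    chromosome: str
    position: int
    mechanism: str                     # SCB | DSCB (true break geometry)
    pathway: str                       # SDSA | DSBR | BIR
    crossover: bool
    recipient: str                     # P1 | P2 (the broken homolog)
    rows: tuple[int, ...]
    tract_bp: dict = field(default_factory=dict)       # row -> (start, end)
    conv_idx: dict = field(default_factory=dict)       # row -> converted grid indices
    patchy: dict = field(default_factory=dict)         # row -> bool (patchy repair drawn)
    restored: dict = field(default_factory=dict)       # row -> bool
    partner_row: int | None = None
    bir_row: int | None = None
    # observable annotation (filled by annotate_observables)
    observable: bool = False
    obs_kind: str | None = None
    obs_pattern: str | None = None
    obs_mechanism: str | None = None
    obs_span: tuple[int, int] | None = None            # bp bounds of visible LOH SNPs
    obs_simple: bool = False                           # clean textbook pattern


def _sample_tract(position: int, length: float, chrom_len: int,
                  rng: np.random.Generator) -> tuple[int, int]:
    u = rng.random()
    start = position - u * length
    end = start + length
    return max(1, int(start)), min(chrom_len, int(end))


def _tract_snp_idx(chromatids: DiploidChromatids, chrom: str,
                   start: int, end: int) -> np.ndarray:
    pos = chromatids.positions[chrom]
    lo = int(np.searchsorted(pos, start, side="left"))
    hi = int(np.searchsorted(pos, end, side="right"))
    return np.arange(lo, hi)


def _apply_conversion(chromatids: DiploidChromatids, chrom: str, row: int,
                      donor_row: int, idx: np.ndarray, patchy: bool,
                      rng: np.random.Generator) -> np.ndarray:
    """Copy donor origins into ``row`` over ``idx`` (all of it, or a random
    per-SNP subset under patchy repair).  Returns the converted indices."""
    org = chromatids.origins[chrom]
    if len(idx) == 0:
        return idx
    if patchy:
        idx = idx[rng.random(len(idx)) < 0.5]
    org[row, idx] = org[donor_row, idx]
    return idx


def repair_break(brk, config: SimulationConfig, chromatids: DiploidChromatids,
                 marker: MarkerConfig, rng: np.random.Generator) -> EventTruth:
    """Repair one break off the homolog and record ground truth.

    The broken homolog is always the conversion recipient.  SCBs repair one
    sister; DSCBs repair both (the second sister always as a non-crossover
    conversion, with identical tract bounds with probability
    ``dscb_equal_tract_prob``).  Crossovers exchange linkage distal to the
    tract; BIR copies the donor from the break to the telomere.
    """
    chrom = brk.chromosome
    lengths = chromatids.snp_map.lengths
    if chrom not in lengths or not (1 <= brk.position <= lengths[chrom]):
        raise SimulationError(f"break position outside chromosome: {chrom}:{brk.position}")
    chrom_len = lengths[chrom]
    cen = marker.centromere(chrom)
    h = int(brk.homolog)
    donor_rows = (2 * (1 - h), 2 * (1 - h) + 1)
    recip_rows = (2 * h, 2 * h + 1)

    pathway = rng.choice([PATH_SDSA, PATH_DSBR, PATH_BIR],
                         p=[config.p_sdsa, config.p_dsbr, config.p_bir])
    crossover = bool(pathway == PATH_DSBR and rng.random() < config.crossover_prob)
    donor_row = int(rng.choice(donor_rows))

    truth = EventTruth(
        chromosome=chrom, position=int(brk.position), mechanism=brk.kind,
        pathway=pathway, crossover=crossover,
        recipient=P1 if h == 0 else P2, rows=recip_rows if brk.kind == DSCB else (),
    )

    def distal_idx(from_bp: int) -> np.ndarray:
        pos = chromatids.positions[chrom]
        if brk.position >= cen:   # right arm: distal is toward the high end
            return np.arange(int(np.searchsorted(pos, from_bp, side="right")), len(pos))
        return np.arange(0, int(np.searchsorted(pos, from_bp, side="left")))

    def do_conversion(row: int, crossover_tract: bool,
                      bounds: tuple[int, int] | None = None) -> tuple[int, int]:
        if bounds is None:
            length = rng.gamma(config.tract_shape, config.tract_scale(crossover_tract))
            if rng.random() < config.branch_migration_prob:
                length += rng.gamma(config.tract_shape, config.tract_scale(False))
            bounds = _sample_tract(brk.position, length, chrom_len, rng)
        restored = rng.random() < config.restoration_prob
        truth.restored[row] = restored
        truth.tract_bp[row] = bounds
        if not restored:
            patchy = rng.random() < config.patchy_repair_prob
            idx = _tract_snp_idx(chromatids, chrom, *bounds)
            truth.conv_idx[row] = _apply_conversion(chromatids, chrom, row,
                                                    donor_row, idx, patchy, rng)
            truth.patchy[row] = patchy
        else:
            truth.conv_idx[row] = np.array([], dtype=np.int64)
            truth.patchy[row] = False
        return bounds

    def do_crossover(row: int, bounds: tuple[int, int]) -> None:
        outer = bounds[1] if brk.position >= cen else bounds[0]
        idx = distal_idx(outer)
        org = chromatids.origins[chrom]
        tmp = org[row, idx].copy()
        org[row, idx] = org[donor_row, idx]
        org[donor_row, idx] = tmp
        truth.partner_row = donor_row

    def do_bir(row: int) -> None:
        idx = distal_idx(brk.position)
        org = chromatids.origins[chrom]
        org[row, idx] = org[donor_row, idx]
        truth.bir_row = row
        truth.tract_bp[row] = ((brk.position, chrom_len) if brk.position >= cen
                               else (1, brk.position))

    if brk.kind == SCB:
        row = int(rng.choice(recip_rows))
        truth.rows = (row,)
        if pathway == PATH_BIR:
            do_bir(row)
        else:
            bounds = do_conversion(row, crossover)
            if crossover:
                do_crossover(row, bounds)
    else:  # DSCB: sister A follows the sampled pathway, sister B converts
        row_a, row_b = recip_rows
        truth.rows = (row_a, row_b)
        if pathway == PATH_BIR:
            do_bir(row_a)
            do_conversion(row_b, False)
        else:
            bounds_a = do_conversion(row_a, crossover)
            equal = rng.random() < config.dscb_equal_tract_prob
            do_conversion(row_b, False, bounds=bounds_a if equal else None)
            if crossover:
                do_crossover(row_a, bounds_a)
    return truth


# ---------------------------------------------------------------------------
# Segregation, colony truth and observable annotation
# ---------------------------------------------------------------------------

@dataclass
class ColonyTruth:
    """One simulated colony: daughter zygosity tracks over the SNP grid,
    colony color pattern, and the ground-truth event list."""

    snp_map: SnpMap
    marker: MarkerConfig
    daughters: list[dict]            # two dicts: chrom -> zygosity array (SNPs only)
    colors: tuple[str, ...]
    pattern: str
    events: list[EventTruth]
    assignment: dict                 # chrom -> ((d1 rows), (d2 rows))

    @property
    def sectored(self) -> bool:
        return "/" in self.pattern


def _zygosity(org: np.ndarray, rows: tuple[int, ...], is_snp: np.ndarray) -> np.ndarray:
    if len(rows) == 1:   # monosomic after chromosome loss
        single = org[rows[0]][is_snp]
        return np.where(single == 0, HOM_P1, HOM_P2).astype(np.int8)
    a, b = org[rows[0]][is_snp], org[rows[1]][is_snp]
    out = np.full(len(a), HET, dtype=np.int8)
    both = a == b
    out[both & (a == 0)] = HOM_P1
    out[both & (a == 1)] = HOM_P2
    return out


def segregate(chromatids: DiploidChromatids, events: list[EventTruth],
              rng: np.random.Generator,
              lose_chromosome: tuple[str, int] | None = None,
              second_division_prob: float = 0.0) -> ColonyTruth:
    """Segregate the four chromatids of each chromosome into two daughters.

    Each daughter receives one sister of each homolog; the two segregation
    patterns are equiprobable, so a crossover yields distal reciprocal LOH in
    half of the simulations.  ``lose_chromosome=(chrom, homolog)`` drops that
    homolog's chromatid from daughter 1 (chromosome loss at the first
    division).
    """
    snp_map = chromatids.snp_map
    marker = chromatids.marker
    assignment: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {}
    for chrom in snp_map.chromosome_names:
        s1, s2 = int(rng.integers(2)), int(rng.integers(2))
        d1 = (s1, 2 + s2)
        d2 = (1 - s1, 2 + (1 - s2))
        if lose_chromosome is not None and chrom == lose_chromosome[0]:
            lost_hom = lose_chromosome[1]
            d1 = tuple(r for r in d1 if r // 2 != lost_hom)
        assignment[chrom] = (d1, d2)

    daughters = []
    for di in range(2):
        track = {}
        for chrom in snp_map.chromosome_names:
            rows = assignment[chrom][di]
            track[chrom] = _zygosity(chromatids.origins[chrom], rows,
                                     chromatids.is_snp[chrom])
        daughters.append(track)

    mchrom = marker.marker_chromosome
    copies = [chromatids.marker_copies(assignment[mchrom][di]) for di in range(2)]
    colors = tuple(COLOR_BY_COPIES[c] for c in copies)
    color_set = sorted(set(colors), key=_COLOR_ORDER.get)
    if second_division_prob > 0 and rng.random() < second_division_prob:
        color_set = sorted(set(list(colors) + _second_division_colors(colors, rng)),
                           key=_COLOR_ORDER.get)
    pattern = "unsectored" if color_set == ["pink"] else "/".join(color_set)
    if len(color_set) == 1 and color_set != ["pink"]:
        pattern = f"unsectored-{color_set[0]}"

    colony = ColonyTruth(snp_map=snp_map, marker=marker, daughters=daughters,
                         colors=colors, pattern=pattern, events=list(events),
                         assignment=assignment)
    annotate_observables(colony, chromatids)
    return colony


def _second_division_colors(colors: tuple[str, ...],
                            rng: np.random.Generator) -> list[str]:
    """Colors added when damage persists into the second division: a
    marker-interval crossover in a pink daughter splits it white/red."""
    if "pink" in colors and rng.random() < 0.5:
        return ["white", "red"]
    return []


def _daughter_of(assignment, chrom: str, row: int) -> int:
    d1, _d2 = assignment[chrom]
    return 0 if row in d1 else 1


def annotate_observables(colony: ColonyTruth, chromatids: DiploidChromatids,
                         min_snps: int = 2) -> None:
    """Fill each event's observable kind/pattern/mechanism.

    The annotation states what an ideal reader of the two noise-free sector
    tracks would report for the event in isolation, including crossover
    detectability (only one of the two equiprobable segregation patterns
    yields reciprocal distal LOH) and array blindness inside SNP-free
    regions.
    """
    for ev in colony.events:
        _annotate_event(ev, colony, chromatids, min_snps)


def _annotate_event(ev: EventTruth, colony: ColonyTruth,
                    chromatids: DiploidChromatids, min_snps: int = 2) -> None:
    chrom = ev.chromosome
    pos_grid = chromatids.positions[chrom]
    is_snp = chromatids.is_snp[chrom]
    snp_pos = pos_grid[is_snp]
    # map grid index -> called-SNP index (the marker locus is not a SNP)
    grid_to_snp = np.cumsum(is_snp) - 1
    n_snp = len(snp_pos)
    assignment = colony.assignment
    cen = colony.marker.centromere(chrom)
    right_arm = ev.position >= cen

    def visible_segments(row, threshold) -> list[tuple[int, int]]:
        """Min-run-smoothed homozygous segments (called-SNP index bounds)
        produced by this chromatid's converted SNPs."""
        gidx = ev.conv_idx.get(row)
        if gidx is None or len(gidx) == 0:
            return []
        sidx = np.unique(grid_to_snp[gidx[is_snp[gidx]]])
        return _smooth_segments(sidx, n_snp, min_run=threshold)

    # BIR visibility: terminal SNPs copied from the donor
    if ev.bir_row is not None:
        a, b = ev.tract_bp[ev.bir_row]
        bir_pts = snp_pos[(snp_pos >= a) & (snp_pos <= b)]
    else:
        bir_pts = np.array([], dtype=np.int64)

    co_visible = False
    if ev.crossover and ev.partner_row is not None:
        co_row = ev.rows[0]
        same = (_daughter_of(assignment, chrom, co_row)
                == _daughter_of(assignment, chrom, ev.partner_row))
        outer = max(b for _a, b in ev.tract_bp.values()) if right_arm else \
            min(a for a, _b in ev.tract_bp.values())
        n_distal = int((snp_pos > outer).sum()) if right_arm \
            else int((snp_pos < outer).sum())
        co_visible = (not same) and n_distal >= min_snps

    conv_rows = [r for r in ev.rows if r in ev.tract_bp and r != ev.bir_row]
    # the crossover chromatid's tract abuts its own exchanged terminal
    # segment, so a single SNP suffices to register it when the CO is seen
    segs = {r: visible_segments(r, 1 if (co_visible and r == ev.rows[0])
                                else min_snps)
            for r in conv_rows}
    vis_rows = [r for r in conv_rows if segs[r]]
    fragmented = any(len(segs[r]) > 1 for r in vis_rows)

    span_bounds = [(int(snp_pos[a]), int(snp_pos[b]))
                   for r in vis_rows for a, b in segs[r]]
    if len(bir_pts):
        span_bounds.append((int(bir_pts[0]), int(bir_pts[-1])))
    if span_bounds:
        ev.obs_span = (min(a for a, _ in span_bounds),
                       max(b for _, b in span_bounds))

    # --- decide observable labels ----------------------------------------
    if ev.bir_row is not None:
        if len(bir_pts) < min_snps:
            ev.observable = False
            return
        ev.observable = True
        if vis_rows:                       # DSCB: BIR on one sister, tract on the other
            ev.obs_kind, ev.obs_pattern, ev.obs_mechanism = "complex", "complex", DSCB
        else:
            ev.obs_kind, ev.obs_pattern, ev.obs_mechanism = "BIR", "none", "NA"
            ev.obs_simple = True
        return

    if not vis_rows and not co_visible:
        ev.observable = False
        return

    ev.observable = True
    if fragmented:
        ev.obs_kind, ev.obs_pattern = "complex", "complex"
        ev.obs_mechanism = DSCB if len(vis_rows) > 1 else SCB
        return

    def touches_end(row) -> bool:
        (a, b), = segs[row]
        return (b == n_snp - 1) if right_arm else (a == 0)

    # conversion tracts that run into the terminal SNP read as terminal LOH
    if vis_rows and not co_visible:
        if any(touches_end(r) for r in vis_rows):
            if len(vis_rows) == 1:
                ev.obs_kind, ev.obs_pattern, ev.obs_mechanism = "BIR", "none", "NA"
            else:
                ev.obs_kind, ev.obs_pattern, ev.obs_mechanism = "complex", "complex", DSCB
            return

    boundary_tol = 1
    if len(vis_rows) == 2:
        (a1, b1), = segs[vis_rows[0]]
        (a2, b2), = segs[vis_rows[1]]
        overlap = not (b1 < a2 or b2 < a1)
        if overlap and abs(a1 - a2) <= boundary_tol and abs(b1 - b2) <= boundary_tol:
            pattern = "4:0"
        elif overlap:
            pattern = "hybrid"
        else:
            pattern = "complex"
        mech = DSCB
    elif len(vis_rows) == 1:
        pattern, mech = "3:1", SCB
    else:
        pattern, mech = "none", SCB if ev.mechanism == SCB else DSCB

    if co_visible:
        ev.obs_kind = "CO_with_conversion" if vis_rows else "CO"
        ev.obs_pattern = pattern
        ev.obs_mechanism = mech if vis_rows else "NA"
    else:
        ev.obs_kind = "complex" if pattern == "complex" else "NCO_conversion"
        ev.obs_pattern = pattern
        ev.obs_mechanism = mech

    # textbook pattern: non-patchy repair, no fragmentation, and for
    # two-sister tracts either coincident bounds or a clear shared core
    shared_core = True
    if len(vis_rows) == 2:
        (a1, b1), = segs[vis_rows[0]]
        (a2, b2), = segs[vis_rows[1]]
        shared_core = min(b1, b2) - max(a1, a2) >= 1
    ev.obs_simple = (not any(ev.patchy.get(r, False) for r in vis_rows)
                     and ev.obs_pattern in ("3:1", "4:0", "hybrid", "none")
                     and shared_core)


def _smooth_segments(hom_idx: np.ndarray, n_snp: int,
                     min_run: int = 2) -> list[tuple[int, int]]:
    """Visible homozygous segments after min-run absorption.

    ``hom_idx`` are called-SNP indices made homozygous by one chromatid.
    Emulates the caller's segmentation semantics: runs (homozygous or
    heterozygous) supported by fewer than ``min_run`` SNPs are absorbed into
    their neighbors, iteratively, shortest first.
    """
    if len(hom_idx) == 0:
        return []
    lo, hi = int(hom_idx[0]), int(hom_idx[-1])
    width = hi - lo + 1
    flags = np.zeros(width + 2, dtype=bool)   # pad with het on both sides
    flags[hom_idx - lo + 1] = True
    # left/right padding represents the flanking het context; make it "long"
    runs = []      # (value, start, end) over the padded array
    start = 0
    for i in range(1, len(flags) + 1):
        if i == len(flags) or flags[i] != flags[start]:
            runs.append([bool(flags[start]), start, i - 1])
            start = i
    # the padded flanking het runs are never absorbed (only interior runs)
    while True:
        if len(runs) == 1:
            break
        interior = runs[1:-1] if len(runs) > 2 else []
        short = [r for r in interior if (r[2] - r[1] + 1) < min_run]
        if not short:
            break
        short.sort(key=lambda r: (r[2] - r[1], r[1]))
        victim = short[0]
        k = runs.index(victim)
        # merge victim into neighbors (which share a value)
        runs[k - 1][2] = runs[k + 1][2]
        del runs[k + 1]
        del runs[k]
    out = []
    for value, a, b in runs:
        if value and (b - a + 1) >= min_run:
            out.append((a - 1 + lo, b - 1 + lo))
    return out


# ---------------------------------------------------------------------------
# Array readout
# ---------------------------------------------------------------------------

def simulate_array(zygosity: np.ndarray, noise_sd: float,
                   rng: np.random.Generator,
                   r_hi: float = 1.8, r_lo: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP allele-specific hybridization ratios for one zygosity track.

    Heterozygous SNPs hybridize at ~1 on both parental channels; homozygous
    SNPs at (r_hi, r_lo) for the retained parent.  Gaussian noise with
    ``noise_sd`` is added and truncated at zero.
    """
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    n = len(zygosity)
    r1 = np.ones(n)
    r2 = np.ones(n)
    r1[zygosity == HOM_P1] = r_hi
    r2[zygosity == HOM_P1] = r_lo
    r1[zygosity == HOM_P2] = r_lo
    r2[zygosity == HOM_P2] = r_hi
    if noise_sd > 0:
        r1 = r1 + rng.normal(0.0, noise_sd, n)
        r2 = r2 + rng.normal(0.0, noise_sd, n)
    return np.clip(r1, 0.0, None), np.clip(r2, 0.0, None)


def sector_ratio_table(colony: ColonyTruth, daughter: int, noise_sd: float,
                       rng: np.random.Generator,
                       r_hi: float = 1.8, r_lo: float = 0.2,
                       sector_id: str | None = None) -> pd.DataFrame:
    """Ratio TSV (snp_id, chromosome, position, ratio_P1, ratio_P2, sector_id)
    for one daughter sector of a colony."""
    frames = []
    snp_map = colony.snp_map
    sid = sector_id if sector_id is not None else f"sector{daughter + 1}"
    for chrom in snp_map.chromosome_names:
        z = colony.daughters[daughter][chrom]
        r1, r2 = simulate_array(z, noise_sd, rng, r_hi=r_hi, r_lo=r_lo)
        pos = snp_map.positions(chrom)
        frames.append(pd.DataFrame({
            "snp_id": [f"{chrom}_{p}" for p in pos],
            "chromosome": chrom, "position": pos,
            "ratio_P1": r1, "ratio_P2": r2, "sector_id": sid,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Whole-experiment driver
# ---------------------------------------------------------------------------

def simulate_colony(config: SimulationConfig, genome, rng: np.random.Generator) -> ColonyTruth:
    """Run the full lesion -> break -> repair -> segregation chain for one cell."""
    snp_map, marker, _annotations = genome
    lesions = place_dimers(config, snp_map, rng)
    breaks = derive_breaks(lesions, config, rng)
    tbl = breaks.table
    if len(tbl):
        keep = np.ones(len(tbl), dtype=bool)
        scb_mask = (tbl["kind"] == SCB).to_numpy()
        keep[scb_mask] = rng.random(scb_mask.sum()) < config.interhomolog_prob
        tbl = tbl[keep]
        if len(tbl) > config.max_breaks_per_cell:
            sel = rng.choice(len(tbl), size=config.max_breaks_per_cell, replace=False)
            tbl = tbl.iloc[np.sort(sel)]
    chromatids = DiploidChromatids(snp_map, marker)
    events = [repair_break(brk, config, chromatids, marker, rng)
              for brk in tbl.itertuples(index=False)]
    return segregate(chromatids, events, rng,
                     second_division_prob=config.second_division_prob)


def simulate_experiment(config: SimulationConfig, genome, n_cells: int,
                        seed: int | None = None) -> list[ColonyTruth]:
    """Simulate ``n_cells`` independent irradiated cells.

    One root seed; per-colony child generators are derived deterministically,
    so the same seed reproduces the same colonies.
    """
    if n_cells <= 0:
        raise SimulationError("n_cells must be positive")
    root = seed if seed is not None else config.seed
    ss = np.random.SeedSequence(root)
    return [simulate_colony(config, genome, np.random.default_rng(child))
            for child in ss.spawn(n_cells)]


def dscb_fraction_of_breaks(config: SimulationConfig, snp_map: SnpMap,
                            n_cells: int, seed: int) -> float:
    """Aggregate DSCB fraction of breaks over ``n_cells`` simulated cells
    (0.0 when no breaks occur)."""
    ss = np.random.SeedSequence(seed)
    n_scb = n_dscb = 0
    for child in ss.spawn(n_cells):
        rng = np.random.default_rng(child)
        brks = derive_breaks(place_dimers(config, snp_map, rng), config, rng)
        if brks.n:
            kinds = brks.table["kind"]
            n_dscb += int((kinds == DSCB).sum())
            n_scb += int((kinds == SCB).sum())
    total = n_scb + n_dscb
    return n_dscb / total if total else 0.0
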