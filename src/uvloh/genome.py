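"""Diploid genome model: chromosomes, SNP map, marker loci and annotations.

The experimental system is a diploid yeast whose two homologs (roles ``P1``
and ``P2``, conventionally drawn red and black) differ at thousands of
single-nucleotide polymorphisms.  A SNP microarray reads out, for every SNP,
whether a clone is heterozygous or homozygous for either parental allele,
so the SNP map is the shared coordinate system for the simulator, the LOH
caller and the statistics layer.

Coordinates are 1-based inclusive internally; BED exports are 0-based
half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

P1 = "P1"  # "red" homolog role
P2 = "P2"  # "black" homolog role; carries the terminal color marker by default

SNP_COLUMNS = ("chromosome", "position", "snp_id")


class GenomeValidationError(ValueError):
    """Raised when a SNP map, marker config or annotation set is inconsistent."""


@dataclass(frozen=True)
class MarkerConfig:
    """Marker loci of the sectored-colony assay.

    ``color_marker`` is an ochre-suppressor-style insertion near one telomere
    of one homolog; colony color reports its copy number (0 -> red, 1 -> pink,
    2 -> white).  ``selected_interval`` is the centromere-to-marker region in
    which crossovers are selected as red/white sectored colonies.
    """

    color_marker: tuple[str, int, str]          # (chromosome, position, carrier homolog)
    selected_interval: tuple[str, int, int]     # (chromosome, start, end), 1-based inclusive
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        chrom, pos, carrier = self.color_marker
        if carrier not in (P1, P2):
            raise GenomeValidationError(f"marker carrier must be {P1} or {P2}, got {carrier!r}")
        ichrom, start, end = self.selected_interval
        if start >= end:
            raise GenomeValidationError("selected interval start must precede end")
        if chrom == ichrom and not (pos <= start or pos >= end):
            # The color marker delimits the selected interval from outside:
            # it must be centromere-distal to the interval's outer bound.
            raise GenomeValidationError("color marker must lie at or beyond the selected interval")

    @property
    def marker_chromosome(self) -> str:
        return self.color_marker[0]

    def centromere(self, chrom: str) -> int:
        try:
            return self.centromeres[chrom]
        except KeyError:
            raise GenomeValidationError(f"no centromere recorded for chromosome {chrom!r}") from None


@dataclass
class AnnotationSet:
    """Named interval classes (LTR, tRNA, non-coding RNA, rDNA, ...).

    Intervals are (chromosome, start, end), 1-based inclusive.  ``rdna_fraction``
    is the fraction of the genome occupied by the ribosomal RNA gene cluster,
    modeled as a single interval rather than as repeat units.
    """

    classes: dict[str, list[tuple[str, int, int]]]
    rdna_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.rdna_fraction < 1.0):
            raise GenomeValidationError("rdna_fraction must be in (0, 1)")
        for name, ivals in self.classes.items():
            for chrom, start, end in ivals:
                if start > end or start < 1:
                    raise GenomeValidationError(
                        f"bad interval ({chrom}, {start}, {end}) in class {name!r}"
                    )

    def validate_against(self, snp_map: "SnpMap") -> None:
        lengths = dict(snp_map.chromosomes)
        for name, ivals in self.classes.items():
            for chrom, start, end in ivals:
                if chrom not in lengths or end > lengths[chrom]:
                    raise GenomeValidationError(
                        f"interval ({chrom}, {start}, {end}) in class {name!r} outside genome"
                    )

    def to_bed(self, path) -> None:
        rows = [
            (chrom, start - 1, end, name)
            for name, ivals in sorted(self.classes.items())
            for chrom, start, end in ivals
        ]
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bed(cls, path, rdna_fraction: float = 0.10) -> "AnnotationSet":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name"], comment="#")
        classes: dict[str, list[tuple[str, int, int]]] = {}
        for row in df.itertuples(index=False):
            classes.setdefault(str(row.name), []).append(
                (str(row.chrom), int(row.start) + 1, int(row.end))
            )
        return cls(classes=classes, rdna_fraction=rdna_fraction)


@dataclass
class SnpMap:
    """Ordered map of heterozygous SNP positions on a set of chromosomes."""

    chromosomes: list[tuple[str, int]]
    snps: pd.DataFrame  # columns: chromosome, position, snp_id
    parents: tuple[str, str] = (P1, P2)

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def chromosome_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.snps.loc[self.snps["chromosome"] == chrom, "position"]
        return sub.to_numpy(dtype=np.int64)

    def mean_spacing(self) -> float:
        """Mean distance (bp) between consecutive SNPs within chromosomes."""
        gaps: list[np.ndarray] = []
        for chrom in self.chromosome_names:
            pos = self.positions(chrom)
            if len(pos) > 1:
                gaps.append(np.diff(pos))
        if not gaps:
            raise GenomeValidationError("SNP map has no consecutive SNP pairs")
        return float(np.concatenate(gaps).mean())

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise GenomeValidationError(f"SNP table missing columns: {missing}")
        lengths = self.lengths
        if len(lengths) != len(self.chromosomes):
            raise GenomeValidationError("duplicate chromosome names")
        seen: set[str] = set()
        order = {name: i for i, name in enumerate(self.chromosome_names)}
        last_order = -1
        for chrom, group in self.snps.groupby("chromosome", sort=False):
            chrom = str(chrom)
            if chrom not in lengths:
                raise GenomeValidationError(f"SNP on unknown chromosome {chrom!r}")
            if chrom in seen or order[chrom] < last_order:
                raise GenomeValidationError("SNP table not grouped in chromosome order")
            seen.add(chrom)
            last_order = order[chrom]
            pos = group["position"].to_numpy()
            if np.any(np.diff(pos) == 0):
                raise GenomeValidationError(f"duplicate SNP position on {chrom}")
            if np.any(np.diff(pos) < 0):
                raise GenomeValidationError(f"unsorted SNP positions on {chrom}")
            if pos[0] < 1 or pos[-1] > lengths[chrom]:
                raise GenomeValidationError(f"SNP outside chromosome bounds on {chrom}")

    # -- I/O -----------------------------------------------------------------
    def save(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"#chromosome\t{name}\t{length}\n")
            self.snps.to_csv(fh, sep="\t", index=False, columns=list(SNP_COLUMNS))

    @classmethod
    def load(cls, path) -> "SnpMap":
        return load_snp_map(path)


def load_snp_map(path) -> SnpMap:
    """Load a SNP map from TSV (columns chromosome, position, snp_id, 1-based).

    Optional ``#chromosome\tname\tlength`` header lines declare chromosome
    lengths; without them, lengths default to the last SNP position per
    chromosome.  Malformed rows raise a parse error naming the line.
    """
    chromosomes: list[tuple[str, int]] = []
    body_lines: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#chromosome\t"):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise GenomeValidationError(f"line {lineno}: malformed chromosome header")
            try:
                chromosomes.append((parts[1], int(parts[2])))
            except ValueError:
                raise GenomeValidationError(
                    f"line {lineno}: chromosome length {parts[2]!r} is not an integer"
                ) from None
        elif line.strip():
            body_lines.append((lineno, line))
    if not body_lines:
        raise GenomeValidationError("SNP map file has no data rows")
    header_no, header = body_lines[0]
    cols = header.rstrip("\n").split("\t")
    missing = [c for c in SNP_COLUMNS if c not in cols]
    if missing:
        raise GenomeValidationError(f"line {header_no}: missing columns {missing}")
    records = []
    for lineno, line in body_lines[1:]:
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(cols):
            raise GenomeValidationError(f"line {lineno}: expected {len(cols)} fields")
        row = dict(zip(cols, parts))
        try:
            records.append((row["chromosome"], int(row["position"]), row["snp_id"]))
        except ValueError:
            raise GenomeValidationError(
                f"line {lineno}: position {row['position']!r} is not an integer"
            ) from None
    snps = pd.DataFrame(records, columns=list(SNP_COLUMNS))
    if not chromosomes:
        chromosomes = [
            (str(chrom), int(group["position"].max()))
            for chrom, group in snps.groupby("chromosome", sort=False)
        ]
    return SnpMap(chromosomes=chromosomes, snps=snps)


# ---------------------------------------------------------------------------
# Default synthetic genome
# ---------------------------------------------------------------------------

# 16 chromosomes totaling 12.0 Mb.  Chromosome sizes loosely follow the shape
# of the S. cerevisiae karyotype; chr12 is extended to host a 1.2 Mb rDNA-like
# cluster (10% of the genome).  All values in bp.
_DEFAULT_CHROM_KB = {
    "chr01": 230, "chr02": 720, "chr03": 300, "chr04": 1360,
    "chr05": 580, "chr06": 270, "chr07": 970, "chr08": 500,
    "chr09": 400, "chr10": 660, "chr11": 590, "chr12": 2210,
    "chr13": 700, "chr14": 640, "chr15": 970, "chr16": 900,
}
RDNA_INTERVAL = ("chr12", 460_001, 1_660_000)   # 1.2 Mb = 10% of 12 Mb
SELECTED_CHROM = "chr05"
MARKER_POSITION = 33_000                        # near the left telomere
CEN5_POSITION = 152_000                         # selected interval CEN5..marker = 119 kb
TELOMERE_EXCLUSION = 20_000                     # SNP-free (repetitive) chromosome ends, bp
TARGET_N_SNPS = 13_000


def _default_centromeres() -> dict[str, int]:
    cen = {}
    for chrom, kb in _DEFAULT_CHROM_KB.items():
        cen[chrom] = int(kb * 1000 * 0.35)
    cen[SELECTED_CHROM] = CEN5_POSITION
    cen["chr12"] = 150_000  # proximal, placing the rDNA cluster on the right arm
    return cen


def make_default_genome(seed: int) -> tuple[SnpMap, MarkerConfig, AnnotationSet]:
    """Build the default synthetic diploid genome.

    16 chromosomes, ~12 Mb, ~13,000 SNPs at ~1 kb mean spacing, a terminal
    color marker on chr05 defining a ~119 kb centromere-marker selected
    interval, and an rDNA-like cluster covering 10% of the genome on chr12.
    SNPs are excluded from the rDNA cluster and from 20 kb at each chromosome
    end, emulating the repetitive regions absent from the array.
    """
    rng = np.random.default_rng(seed)
    chromosomes = [(name, kb * 1000) for name, kb in _DEFAULT_CHROM_KB.items()]

    # SNP-eligible span per chromosome (excludes telomeric ends and rDNA)
    eligible: dict[str, list[tuple[int, int]]] = {}
    for name, length in chromosomes:
        spans = [(TELOMERE_EXCLUSION + 1, length - TELOMERE_EXCLUSION)]
        if name == RDNA_INTERVAL[0]:
            lo, hi = RDNA_INTERVAL[1], RDNA_INTERVAL[2]
            spans = [(spans[0][0], lo - 1), (hi + 1, spans[0][1])]
        eligible[name] = spans

    total_eligible = sum(b - a + 1 for spans in eligible.values() for a, b in spans)
    frames = []
    for name, length in chromosomes:
        spans = eligible[name]
        chrom_eligible = sum(b - a + 1 for a, b in spans)
        n = int(round(TARGET_N_SNPS * chrom_eligible / total_eligible))
        # sample uniformly over the eligible spans
        weights = np.array([b - a + 1 for a, b in spans], dtype=float)
        weights /= weights.sum()
        counts = rng.multinomial(n, weights)
        pos_parts = [
            rng.integers(a, b + 1, size=k) for (a, b), k in zip(spans, counts)
        ]
        pos = np.unique(np.concatenate(pos_parts)) if pos_parts else np.array([], dtype=int)
        frames.append(pd.DataFrame({
            "chromosome": name,
            "position": pos.astype(np.int64),
            "snp_id": [f"{name}_{p}" for p in pos],
        }))
    snps = pd.concat(frames, ignore_index=True)
    snp_map = SnpMap(chromosomes=chromosomes, snps=snps)

    marker = MarkerConfig(
        color_marker=(SELECTED_CHROM, MARKER_POSITION, P2),
        selected_interval=(SELECTED_CHROM, MARKER_POSITION, CEN5_POSITION),
        centromeres=_default_centromeres(),
    )

    annotations = _default_annotations(rng, chromosomes)
    annotations.validate_against(snp_map)
    return snp_map, marker, annotations


def _default_annotations(rng: np.random.Generator,
                         chromosomes: list[tuple[str, int]]) -> AnnotationSet:
    """Scatter small LTR / tRNA / non-coding RNA elements over the genome."""
    names = [c for c, _ in chromosomes]
    lengths = np.array([l for _, l in chromosomes], dtype=float)
    weights = lengths / lengths.sum()

    def scatter(n: int, size: int) -> list[tuple[str, int, int]]:
        out = []
        chroms = rng.choice(len(names), size=n, p=weights)
        for ci in chroms:
            length = int(lengths[ci])
            start = int(rng.integers(1, max(2, length - size)))
            out.append((names[ci], start, start + size - 1))
        return out

    classes = {
        "LTR": scatter(300, 330),
        "tRNA": scatter(275, 80),
        "ncRNA": scatter(100, 500),
        "rDNA": [RDNA_INTERVAL],
    }
    return AnnotationSet(classes=classes, rdna_fraction=0.10)
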