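"""Quantitative analyses of recombination cohorts.

Covers conversion-tract lengths (minimal/maximal spans and their mean as the
estimate, medians with order-statistic confidence limits), Mann-Whitney
distribution comparisons, detection-corrected crossover counts, control-
normalized induced-event counts and per-kb rates, regional expectation tests
(binomial and chi-square), chromosome-size regression, permutation-based
element enrichment with Benjamini-Hochberg correction, and AA/TT
dinucleotide composition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import RecombEvent
from .genome import AnnotationSet, SnpMap


class StatsError(ValueError):
    pass


@dataclass
class StatResult:
    name: str
    value: float
    p_value: float
    adjusted_p: float | None = None
    meta: dict | None = None


@dataclass
class TractLengthRecord:
    event_id: str
    min_len: float
    max_len: float
    crossover_associated: bool = False

    @property
    def estimate(self) -> float:
        return 0.5 * (self.min_len + self.max_len)


@dataclass
class AssayCount:
    name: str
    length_kb: float
    observed_treated: float
    observed_untreated: float
    n_treated: int
    n_untreated: int
    detection_factor: float = 1.0
    normalized: float = 0.0
    per_kb: float = 0.0


# ---------------------------------------------------------------------------
# Tract lengths
# ---------------------------------------------------------------------------

def tract_length(event: RecombEvent, event_id: str = "") -> TractLengthRecord:
    """Tract length record for one event: the minimal span is first-to-last
    LOH SNP; the maximal span runs between the flanking heterozygous SNPs.
    Hybrid/complex tracts were already merged across 3:1/4:0 segments and
    internal het gaps when the event bounds were computed."""
    if event.tract_min is None or event.tract_max is None:
        raise StatsError("event has no conversion tract (pattern=none)")
    min_len = event.tract_min[1] - event.tract_min[0]
    max_len = event.tract_max[1] - event.tract_max[0]
    return TractLengthRecord(
        event_id=event_id or f"{event.chromosome}:{event.tract_min[0]}",
        min_len=float(min_len), max_len=float(max_len),
        crossover_associated=event.kind == "CO_with_conversion",
    )


def median_with_ci(lengths, level: float = 0.95) -> tuple[float, float, float]:
    """Median with a distribution-free confidence interval from binomial
    order statistics (ranks n/2 +- z*sqrt(n)/2, the construction behind the
    standard printed tables)."""
    x = np.sort(np.asarray(lengths, dtype=float))
    n = len(x)
    if n < 8:
        raise StatsError(f"need n >= 8 observations for a median CI, got {n}")
    z = sps.norm.ppf(0.5 + level / 2.0)
    lo_rank = int(math.ceil(n / 2.0 - z * math.sqrt(n) / 2.0))
    hi_rank = int(math.ceil(1 + n / 2.0 + z * math.sqrt(n) / 2.0))
    lo_rank = max(1, lo_rank)
    hi_rank = min(n, hi_rank)
    return float(np.median(x)), float(x[lo_rank - 1]), float(x[hi_rank - 1])


def compare_distributions(a, b) -> StatResult:
    """Two-sided Mann-Whitney U.  Small tie-free samples use the exact
    distribution; otherwise the normal approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise StatsError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(name="mann_whitney_u", value=float(res.statistic),
                      p_value=float(res.pvalue),
                      meta={"n1": len(a), "n2": len(b), "method": method})


# ---------------------------------------------------------------------------
# Spatial distribution
# ---------------------------------------------------------------------------

def bin_midpoint_distribution(midpoints, interval_bounds,
                              reference=None) -> StatResult:
    """Bin event midpoints into the given intervals and test the counts
    against a reference set (Fisher exact for 2x2, otherwise chi-square on
    the contingency table) or against a uniform expectation."""
    bounds = np.asarray(interval_bounds, dtype=float)
    if bounds.ndim != 1 or len(bounds) < 2 or np.any(np.diff(bounds) <= 0):
        raise StatsError("interval_bounds must be increasing bin edges")
    mids = np.asarray(midpoints, dtype=float)
    inside = (mids >= bounds[0]) & (mids <= bounds[-1])
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} events outside the binned interval "
                      "were excluded", stacklevel=2)
    counts, _ = np.histogram(mids[inside], bins=bounds)
    if reference is not None and len(np.asarray(reference)):
        ref = np.asarray(reference, dtype=float)
        ref_counts, _ = np.histogram(ref[(ref >= bounds[0]) & (ref <= bounds[-1])],
                                     bins=bounds)
        table = np.vstack([counts, ref_counts])
        if table.shape == (2, 2):
            _odds, p = sps.fisher_exact(table)
            stat = float(_odds)
            name = "fisher_exact"
        else:
            chi2, p, _dof, _exp = sps.chi2_contingency(table, correction=False)
            stat, name = float(chi2), "chi_square_contingency"
        return StatResult(name=name, value=stat, p_value=float(p),
                          meta={"counts": counts.tolist(),
                                "reference": ref_counts.tolist()})
    widths = np.diff(bounds)
    expected = counts.sum() * widths / widths.sum()
    chi2, p = sps.chisquare(counts, expected)
    return StatResult(name="chi_square_uniform", value=float(chi2),
                      p_value=float(p),
                      meta={"counts": counts.tolist(), "expected": expected.tolist()})


def detection_corrected_counts(n_co: int, n_bir: int, n_conv: int) -> dict:
    """Correct observed counts for crossover detectability.

    Only one of the two equiprobable segregation patterns reveals a
    crossover, so true crossovers = 2 x observed; the other half of the
    crossover-associated conversions were tallied as plain conversions, so
    truly unassociated conversions = observed conversions - observed
    crossovers."""
    if min(n_co, n_bir, n_conv) < 0:
        raise StatsError("counts must be >= 0")
    if n_conv < n_co:
        raise StatsError("fewer conversions than crossovers is inconsistent "
                         "with half-detection of crossovers")
    co_true = 2 * n_co
    conv_unassoc = n_conv - n_co
    denom = n_conv + n_co
    assoc_fraction = co_true / denom if denom else 0.0
    return {
        "co_corrected": co_true,
        "bir": n_bir,
        "conv_unassociated": conv_unassoc,
        "conv_associated": co_true,
        "association_fraction": assoc_fraction,
        "co_bir_ratio": co_true / n_bir if n_bir else float("inf"),
    }


def normalized_induced(observed_treated: float, observed_untreated: float,
                       n_treated: int, n_untreated: int,
                       length_kb: float | None = None,
                       detection_factor: float = 1.0,
                       name: str = "") -> AssayCount:
    """Subtract the expected number of spontaneous events from a treated
    count: normalized = treated - untreated x (n_treated / n_untreated).
    With an interval length, also computes the per-kb event frequency
    normalized / n_treated x detection_factor / length_kb."""
    if n_untreated <= 0:
        raise StatsError("n_untreated must be positive")
    norm = observed_treated - observed_untreated * (n_treated / n_untreated)
    if norm < 0:
        warnings.warn(f"normalized count for {name or 'interval'} clamped to 0",
                      stacklevel=2)
        norm = 0.0
    per_kb = 0.0
    if length_kb:
        per_kb = norm / n_treated * detection_factor / length_kb
    return AssayCount(name=name, length_kb=length_kb or 0.0,
                      observed_treated=observed_treated,
                      observed_untreated=observed_untreated,
                      n_treated=n_treated, n_untreated=n_untreated,
                      detection_factor=detection_factor,
                      normalized=norm, per_kb=per_kb)


def fold_stimulation(induced_frequency: float, spontaneous_rate: float) -> float:
    if spontaneous_rate <= 0:
        raise StatsError("spontaneous rate must be positive")
    return induced_frequency / spontaneous_rate


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting only, never internal)."""
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1)))


def region_expectation_test(n_in_region: int, n_events: int,
                            region_fraction: float) -> StatResult:
    """Observed vs expected events in a genomic region covering a given
    fraction of the event-visible genome; reports the exact binomial p and a
    chi-square p (without continuity correction)."""
    if not (0.0 < region_fraction < 1.0):
        raise StatsError("region_fraction must be in (0, 1)")
    if n_in_region > n_events:
        raise StatsError("observed events in region exceed total events")
    expected = n_events * region_fraction
    if n_events == 0:
        return StatResult(name="region_expectation", value=0.0, p_value=1.0,
                          meta={"expected": 0.0, "chi2_p": 1.0, "observed": 0})
    binom_p = float(sps.binomtest(n_in_region, n_events, region_fraction).pvalue)
    obs = np.array([n_in_region, n_events - n_in_region], dtype=float)
    exp = np.array([expected, n_events - expected], dtype=float)
    chi2, chi2_p = sps.chisquare(obs, exp)
    return StatResult(name="region_expectation", value=float(expected),
                      p_value=binom_p,
                      meta={"expected": float(expected), "observed": n_in_region,
                            "chi2": float(chi2), "chi2_p": float(chi2_p)})


def chromosome_size_correlation(counts, lengths) -> StatResult:
    """Ordinary least squares of per-chromosome event counts on chromosome
    lengths; reports r^2 with the slope p-value."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if len(counts) != len(lengths) or len(counts) < 3:
        raise StatsError("need matched counts/lengths for >= 3 chromosomes")
    if np.allclose(lengths, lengths[0]):
        raise StatsError("chromosome lengths have zero variance")
    res = sps.linregress(lengths, counts)
    return StatResult(name="chromosome_size_ols", value=float(res.rvalue ** 2),
                      p_value=float(res.pvalue),
                      meta={"slope": float(res.slope), "intercept": float(res.intercept)})


# ---------------------------------------------------------------------------
# Element enrichment
# ---------------------------------------------------------------------------

def _covered_spans(snp_map: SnpMap) -> dict[str, tuple[int, int]]:
    """SNP-covered span per chromosome: observed tracts can only be seen
    where the array has markers, so the permutation null is confined there."""
    spans = {}
    for chrom in snp_map.chromosome_names:
        pos = snp_map.positions(chrom)
        if len(pos) >= 2:
            spans[chrom] = (int(pos[0]), int(pos[-1]))
    return spans


def _overlap_count(tracts, intervals_by_chrom) -> int:
    n = 0
    for chrom, start, end in tracts:
        ivals = intervals_by_chrom.get(chrom)
        if ivals is None or not len(ivals):
            continue
        starts, ends = ivals
        j = np.searchsorted(ends, start, side="left")
        if j < len(starts) and starts[j] <= end:
            n += 1
    return n


def element_enrichment(tracts, annotations: AnnotationSet, snp_map: SnpMap,
                       n_perm: int = 1000, seed: int = 0,
                       classes: list[str] | None = None) -> list[StatResult]:
    """Permutation test of tract overlap with each annotation class.

    Observed statistic: number of tracts overlapping at least one element of
    the class.  Null: tracts of the same lengths placed uniformly at random
    on the SNP-covered genome, ``n_perm`` times; two-sided empirical p with
    the +1 correction, Benjamini-Hochberg adjusted across classes.
    """
    if n_perm < 1000:
        raise StatsError("n_perm must be >= 1000")
    tracts = [(c, int(a), int(b)) for c, a, b in tracts]
    rng = np.random.default_rng(seed)
    spans = _covered_spans(snp_map)
    chrom_names = [c for c in snp_map.chromosome_names if c in spans]
    span_lens = np.array([spans[c][1] - spans[c][0] + 1 for c in chrom_names],
                         dtype=float)
    weights = span_lens / span_lens.sum()

    by_class = {}
    names = classes if classes is not None else sorted(annotations.classes)
    for name in list(names):
        ivals = annotations.classes.get(name, [])
        if not ivals:
            warnings.warn(f"annotation class {name!r} is empty; skipped", stacklevel=2)
            continue
        per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in {c for c, _a, _b in ivals}:
            sub = sorted((a, b) for c, a, b in ivals if c == chrom)
            merged = [list(sub[0])]
            for a, b in sub[1:]:   # merge overlaps so interval ends stay sorted
                if a <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], b)
                else:
                    merged.append([a, b])
            per_chrom[chrom] = (np.array([a for a, _ in merged]),
                                np.array([b for _, b in merged]))
        by_class[name] = per_chrom

    lengths = np.array([b - a for _c, a, b in tracts], dtype=np.int64)
    observed = {name: _overlap_count(tracts, per) for name, per in by_class.items()}
    ge = {name: 0 for name in by_class}
    le = {name: 0 for name in by_class}
    for _ in range(n_perm):
        ci = rng.choice(len(chrom_names), size=len(lengths), p=weights)
        placed = []
        for k, c in enumerate(ci):
            chrom = chrom_names[c]
            lo, hi = spans[chrom]
            max_start = max(lo, hi - lengths[k])
            start = int(rng.integers(lo, max_start + 1))
            placed.append((chrom, start, start + int(lengths[k])))
        for name, per in by_class.items():
            cnt = _overlap_count(placed, per)
            if cnt >= observed[name]:
                ge[name] += 1
            if cnt <= observed[name]:
                le[name] += 1
    results = []
    for name in by_class:
        p_hi = (ge[name] + 1) / (n_perm + 1)
        p_lo = (le[name] + 1) / (n_perm + 1)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
        results.append(StatResult(name=name, value=float(observed[name]), p_value=p,
                                  meta={"n_perm": n_perm, "p_over": p_hi,
                                        "p_under": p_lo, "n_tracts": len(tracts)}))
    if results:
        _rej, adj, _a, _b = multipletests([r.p_value for r in results],
                                          method="fdr_bh")
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
    return results


# ---------------------------------------------------------------------------
# Dinucleotide composition
# ---------------------------------------------------------------------------

def dinucleotide_freq(sequence: str, pair: str = "AA",
                      max_other_fraction: float = 0.05) -> float:
    """Frequency of a dinucleotide and its reverse complement among all
    overlapping dinucleotides of a sequence (AA/TT are counted together)."""
    seq = sequence.upper()
    if len(seq) < 2:
        raise StatsError("sequence shorter than one dinucleotide")
    other = sum(1 for c in seq if c not in "ACGT")
    if other / len(seq) > max_other_fraction:
        raise StatsError("sequence contains too many non-ACGT characters")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    pair = pair.upper()
    rc = comp[pair[1]] + comp[pair[0]]
    targets = {pair, rc}
    total = hits = 0
    for i in range(len(seq) - 1):
        di = seq[i:i + 2]
        if di[0] not in "ACGT" or di[1] not in "ACGT":
            continue
        total += 1
        if di in targets:
            hits += 1
    if total == 0:
        raise StatsError("no valid dinucleotides in sequence")
    return hits / total


def compare_dinucleotide_regions(seq_a: str, seq_b: str,
                                 pair: str = "AA") -> StatResult:
    """Fisher exact comparison of AA/TT dinucleotide counts between two
    regions."""
    def counts(seq):
        f = dinucleotide_freq(seq, pair)
        total = len(seq) - 1
        return int(round(f * total)), total
    ha, ta = counts(seq_a)
    hb, tb = counts(seq_b)
    table = [[ha, ta - ha], [hb, tb - hb]]
    odds, p = sps.fisher_exact(table)
    return StatResult(name="dinucleotide_fisher", value=float(odds),
                      p_value=float(p),
                      meta={"freq_a": ha / ta, "freq_b": hb / tb})
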