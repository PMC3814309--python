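"""Shared fixtures: genomes, configs, and a classified simulated cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import uvloh
from uvloh.genome import P1, P2


@pytest.fixture(scope="session")
def default_genome():
    return uvloh.make_default_genome(seed=1)


@pytest.fixture(scope="session")
def snp_map(default_genome):
    return default_genome[0]


@pytest.fixture(scope="session")
def marker(default_genome):
    return default_genome[1]


@pytest.fixture(scope="session")
def annotations(default_genome):
    return default_genome[2]


@pytest.fixture(scope="session")
def classifier(snp_map, marker):
    return uvloh.EventClassifier(snp_map, marker)


@pytest.fixture()
def small_genome():
    """One-chromosome genome with evenly spaced SNPs, for hand-built cases."""
    n = 200
    positions = np.arange(1, n + 1) * 1000  # 1 kb spacing, 200 kb chromosome
    snps = pd.DataFrame({
        "chromosome": "chrT",
        "position": positions,
        "snp_id": [f"chrT_{p}" for p in positions],
    })
    snp_map = uvloh.SnpMap(chromosomes=[("chrT", 210_000)], snps=snps)
    mk = uvloh.MarkerConfig(
        color_marker=("chrT", 5_000, P2),
        selected_interval=("chrT", 5_000, 70_000),
        centromeres={"chrT": 70_000},
    )
    return snp_map, mk


def make_ratio_table(snp_map, states_by_chrom, r_hi=1.8, r_lo=0.2):
    """Noise-free ratio table from per-chromosome state arrays."""
    from uvloh.states import HET, HOM_P1, HOM_P2
    frames = []
    for chrom, states in states_by_chrom.items():
        pos = snp_map.positions(chrom)
        states = np.asarray(states)
        r1 = np.ones(len(pos))
        r2 = np.ones(len(pos))
        r1[states == HOM_P1] = r_hi
        r2[states == HOM_P1] = r_lo
        r1[states == HOM_P2] = r_lo
        r2[states == HOM_P2] = r_hi
        frames.append(pd.DataFrame({
            "snp_id": [f"{chrom}_{p}" for p in pos],
            "chromosome": chrom, "position": pos,
            "ratio_P1": r1, "ratio_P2": r2,
        }))
    return pd.concat(frames, ignore_index=True)


def match_events(truth_events, called):
    """Pair each observable truth event with the called event of maximal
    span overlap on its chromosome."""
    results = []
    for te in truth_events:
        if not te.observable:
            continue
        cands = []
        for ce in called:
            if ce.chromosome != te.chromosome:
                continue
            span = ce.tract_max or ce.tract_min
            lo, hi = te.obs_span if te.obs_span else (te.position, te.position)
            if span is None:
                cands.append((0, ce))
                continue
            ov = min(hi, span[1]) - max(lo, span[0])
            if ov >= 0:
                cands.append((ov, ce))
        best = max(cands, key=lambda t: t[0])[1] if cands else None
        results.append((te, best))
    return results


def is_isolated(colony, truth_event):
    """True when the event is the only one (visible or not) on its
    chromosome, so its in-isolation ground-truth label is well defined."""
    return not any(e is not truth_event and e.chromosome == truth_event.chromosome
                   for e in colony.events)


def recovery_rates(colonies_with_events):
    """(all-isolated, simple-isolated) recovery fractions and counts."""
    tot = ok = stot = sok = 0
    for colony, called in colonies_with_events:
        for te, ce in match_events(colony.events, called):
            if not is_isolated(colony, te):
                continue
            good = ce is not None and \
                (ce.kind, ce.pattern) == (te.obs_kind, te.obs_pattern)
            tot += 1
            ok += good
            if te.obs_simple:
                stot += 1
                sok += good
    return ok, tot, sok, stot


@pytest.fixture(scope="session")
def simulated_cohort(default_genome):
    """500 default-condition colonies with classified events at the default
    array noise (0.1), shared across the expensive tests."""
    snp_map, marker, _ann = default_genome
    config = uvloh.SimulationConfig()
    colonies = uvloh.simulate_experiment(config, default_genome, 500, seed=2024)
    clf = uvloh.EventClassifier(snp_map, marker)
    rng = np.random.default_rng(99)
    classified = []
    for colony in colonies:
        a = uvloh.call_sector(
            uvloh.sector_ratio_table(colony, 0, config.noise_sd, rng), sector_id="a")
        b = uvloh.call_sector(
            uvloh.sector_ratio_table(colony, 1, config.noise_sd, rng), sector_id="b")
        classified.append((colony, clf.classify(a, b)))
    return classified
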