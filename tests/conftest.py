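"""Shared fixtures: hand-made loci and a cached closed-loop simulation sweep."""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pytest

import hdrquant as hq
from hdrquant.locus import Interval


def exhaustive_align_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Independent alignment oracle: exhaustive max over all global alignments.

    Recursion over alignment columns with the last-move state; a gap of
    length L costs gap_open + L * gap_extend.  Written directly from the
    definition, independent of the production aligner.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        cands = []
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] != "N") else mismatch
            cands.append(s + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "A" else gap_open + gap_extend
            cands.append(-cost + best(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if prev == "B" else gap_open + gap_extend
            cands.append(-cost + best(i, j + 1, "B"))
        return max(cands)

    return best(0, 0, "-")


@pytest.fixture(scope="session")
def sim_locus_edit():
    """Deterministic synthetic locus + edit used across modules."""
    return hq.simulate_locus(1)


@pytest.fixture(scope="session")
def sim_patterns(sim_locus_edit):
    locus, edit = sim_locus_edit
    return hq.derive_patterns(locus, edit, hq.minimal_flank(locus, edit))


@pytest.fixture
def coding_locus():
    """Small locus with a guide inside a 45 nt CDS window, built by hand."""
    locus, _ = hq.simulate_locus(2)
    return locus


def run_closed_loop(seed: int, n_reads: int = 20_000, per_base_error: float = 0.001):
    """Simulate -> merge -> classify one seed; returns (report, truth, expected)."""
    locus, edit = hq.simulate_locus(1)
    patterns = hq.derive_patterns(locus, edit, hq.minimal_flank(locus, edit))
    config = hq.SimulationConfig(
        seed=seed, n_reads=n_reads, per_base_error=per_base_error
    )
    pairs, truth = hq.simulate_reads(locus, edit, config)
    merged = hq.PairedReadMerger().fit().transform(pairs)
    clf = hq.HdrOutcomeClassifier(locus=locus, edit=edit).fit()
    calls = clf.classify(merged)
    report = hq.summarize(calls, f"seed{seed}")
    expected = hq.expected_category_probabilities(
        locus, edit, patterns, config.class_proportions, per_base_error
    )
    return report, truth, expected


@pytest.fixture(scope="session")
def closed_loop_sweep():
    """Recovered vs expected category fractions for seeds 1-20 at n=20,000.

    Computed once per session; the recovery acceptance check uses seeds 1-10
    and the mean-absolute-error check all twenty.
    """
    import time

    out = {}
    for seed in range(1, 21):
        t0 = time.perf_counter()
        report, _, expected = run_closed_loop(seed)
        elapsed = time.perf_counter() - t0
        observed = {c: report.percentages[c] / 100.0 for c in hq.CATEGORIES}
        out[seed] = (observed, expected, report.total_assembled, elapsed)
    return out


def binomial_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n)
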