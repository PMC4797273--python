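"""Shared fixtures and independent oracle implementations.

The oracles here deliberately use brute force (all-pairs scans, O(n^2) rank
counting) so that the package's faster implementations are checked against
arithmetic that shares no code with them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from cobindscan.events import Peak
from cobindscan.synthetic import FeatureTrackSpec, SyntheticConfig, simulate_cell


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_classify(peaks_a, peaks_b, min_frac=0.30):
    """All-pairs reciprocal-overlap classification.

    Returns two lists (for A and B peaks, in input order) of the chosen
    partner Peak or None, using the same deterministic best-partner rule:
    largest min(frac_self, frac_other), ties to leftmost partner start, then
    end, then name.
    """

    def partner(p, others):
        best, best_key = None, None
        for q in others:
            if q.chrom != p.chrom:
                continue
            ov = min(p.end, q.end) - max(p.start, q.start)
            if ov <= 0:
                continue
            fp = ov / (p.end - p.start)
            fq = ov / (q.end - q.start)
            if fp >= min_frac and fq >= min_frac:
                key = (-min(fp, fq), q.start, q.end, q.name)
                if best_key is None or key < best_key:
                    best, best_key = q, key
        return best

    return ([partner(p, peaks_b) for p in peaks_a],
            [partner(p, peaks_a) for p in peaks_b])


def brute_force_auc(scores, labels):
    """Pairwise rank statistic: P(pos > neg) + 0.5 P(tie), by explicit loops."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_peaks(rng, n, genome_bp=100_000, prefix="p", min_w=50, max_w=500):
    peaks = []
    for i in range(n):
        w = int(rng.integers(min_w, max_w))
        start = int(rng.integers(0, genome_bp - w))
        peaks.append(Peak("chrT", start, start + w, start + w // 2,
                          float(rng.random()), f"{prefix}{i}"))
    return peaks


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def small_config(seed=0, **overrides) -> SyntheticConfig:
    """A fast configuration for unit tests: 60 sites per class, 3 channels."""
    defaults = dict(
        chrom_sizes={"chrS1": 300_000, "chrS2": 200_000},
        n_a_only=60,
        n_b_only=60,
        n_co=60,
        features=(
            FeatureTrackSpec("DNaseI", baseline_mu=20, log2_effect=1.5,
                             background_reads=500),
            FeatureTrackSpec("H3K27ac", baseline_mu=20, log2_effect=1.5,
                             background_reads=500),
            FeatureTrackSpec("H3K9me3", baseline_mu=20, log2_effect=0.0,
                             background_reads=500),
        ),
        cpg_per_kb=15.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_cell():
    return simulate_cell(small_config(seed=11))


@pytest.fixture(scope="session")
def default_cell():
    """One full-size cell (500 sites/class, 12 channels) shared across tests."""
    return simulate_cell(SyntheticConfig(seed=7))
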