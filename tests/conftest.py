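"""Shared fixtures and independent brute-force oracles for the suite.

The oracles deliberately re-state the grouping rules with different
algorithms (pairwise cluster merging, exhaustive run enumeration) so the
production implementations are checked against independent code paths.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")


# ---------------------------------------------------------------- oracles

def oracle_bursts(times, max_isi=0.05, min_ibi=0.1, min_spikes=5):
    """Burst grouping by iterated pairwise cluster merging.

    Phase 1: repeatedly merge adjacent clusters whose boundary gap is
    <= max_isi. Phase 2: merge adjacent clusters with gap < min_ibi.
    Keep clusters with >= min_spikes. Returns (start, end, n) tuples.
    """
    clusters = [[float(t)] for t in times]

    def merge_pass(gap_limit, strict):
        changed = True
        while changed:
            changed = False
            for i in range(len(clusters) - 1):
                gap = clusters[i + 1][0] - clusters[i][-1]
                hit = gap < gap_limit if strict else gap <= gap_limit
                if hit:
                    clusters[i].extend(clusters[i + 1])
                    del clusters[i + 1]
                    changed = True
                    break

    if not clusters:
        return []
    merge_pass(max_isi, strict=False)
    merge_pass(min_ibi, strict=True)
    return [(c[0], c[-1], len(c)) for c in clusters if len(c) >= min_spikes]


def oracle_event_bursts(onsets, amplitudes, n_min=3, max_gap=0.05, amp_thr=100.0):
    """Exhaustive enumeration of maximal qualifying runs of synaptic
    events: every contiguous index range is checked for the run property
    (all consecutive gaps <= max_gap), maximality, size and amplitude."""
    n = len(onsets)
    out = []
    for i in range(n):
        for j in range(i, n):
            gaps_ok = all(onsets[k + 1] - onsets[k] <= max_gap for k in range(i, j))
            if not gaps_ok:
                continue
            left_max = i == 0 or onsets[i] - onsets[i - 1] > max_gap
            right_max = j == n - 1 or onsets[j + 1] - onsets[j] > max_gap
            if not (left_max and right_max):
                continue
            if j - i + 1 >= n_min and max(amplitudes[i:j + 1]) > amp_thr:
                out.append((i, j))
    return out


def oracle_sphere_crossings(p0, p1, center, r):
    """Number of points on segment p0->p1 at exact distance r from center
    (excluding endpoints), by dense parametric sampling refinement."""
    p0, p1, center = map(np.asarray, (p0, p1, center))
    s = np.linspace(0.0, 1.0, 20001)
    d = np.linalg.norm(p0[None] + s[:, None] * (p1 - p0)[None] - center[None], axis=1)
    flips = np.sum(np.abs(np.diff(np.sign(d - r))) > 1)
    return int(flips)


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
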