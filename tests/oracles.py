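"""Independent brute-force oracles used only by the test suite.

These reimplement feature matching and the prioritization cascade with
naive explicit loops and set operations, staying deliberately
independent of the package's bookkeeping so that equality is a real
cross-check.
"""

from __future__ import annotations

import numpy as np

from edakit.types import FeatureTable, MatchTolerances


def oracle_match_pairs(a: FeatureTable, b: FeatureTable,
                       tol: MatchTolerances) -> list[tuple[int, int]]:
    """Nearest-pair one-to-one assignment by repeated global minimum."""
    candidates = []
    for i, fa in enumerate(a.features):
        for j, fb in enumerate(b.features):
            dmz = abs(fa.mz - fb.mz)
            drt = abs(fa.rt - fb.rt)
            if dmz <= tol.ms1_tol and drt <= tol.rt_tol:
                candidates.append((dmz, drt, i, j))
    pairs = []
    used_a, used_b = set(), set()
    while True:
        best = None
        for c in candidates:
            if c[2] in used_a or c[3] in used_b:
                continue
            if best is None or c < best:
                best = c
        if best is None:
            break
        used_a.add(best[2])
        used_b.add(best[3])
        pairs.append((best[2], best[3]))
    return sorted(pairs)


def _matches_any(feature, table: FeatureTable, tol: MatchTolerances) -> bool:
    return any(
        abs(feature.mz - g.mz) <= tol.ms1_tol and abs(feature.rt - g.rt) <= tol.rt_tol
        for g in table.features
    )


def oracle_cascade(extract5, extract1, upper, lower, blank, tol,
                   intensity_fraction=0.01):
    """Explicit set-operation version of the prioritization cascade.

    Returns (per-step counts, final surviving indices into extract5).
    """
    counts = [len(extract5.features)]

    pairs = oracle_match_pairs(extract5, extract1, tol)
    step1 = {i for i, _ in pairs}
    partner = {i: extract1.features[j] for i, j in pairs}
    counts.append(len(step1))

    def restrict(idx_set, fraction_table):
        sub_idx = sorted(idx_set)
        sub = FeatureTable("sub", extract5.role, extract5.ref,
                           [extract5.features[i] for i in sub_idx])
        pp = oracle_match_pairs(sub, fraction_table, tol)
        return {sub_idx[i] for i, _ in pp}

    up = restrict(step1, upper)
    lo = restrict(step1, lower)
    counts.append(len(up | lo))

    up = {i for i in up if partner[i].intensity <= extract5.features[i].intensity}
    lo = {i for i in lo if partner[i].intensity <= extract5.features[i].intensity}
    counts.append(len(up | lo))

    up = {i for i in up if not _matches_any(extract5.features[i], blank, tol)}
    lo = {i for i in lo if not _matches_any(extract5.features[i], blank, tol)}
    counts.append(len(up | lo))

    both = up & lo
    counts.append(len(both))

    total = sum(f.intensity for f in extract5.features)
    final = {i for i in both
             if extract5.features[i].intensity > intensity_fraction * total}
    counts.append(len(final))
    return counts, sorted(final)


def oracle_local_maxima(intensities: np.ndarray, min_height: float) -> int:
    """Count strict local maxima at or above a height threshold."""
    y = np.asarray(intensities, dtype=float)
    n = 0
    for i in range(1, len(y) - 1):
        if y[i] > y[i - 1] and y[i] > y[i + 1] and y[i] >= min_height:
            n += 1
    return n
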