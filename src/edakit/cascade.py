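"""Feature-prioritization cascade.

Reduces the thousands of features detected in a nontarget screen of an
enriched extract to a handful of candidate toxicity drivers, using the
fractionation design: features must be present in both enrichment
levels of the extract, in both bioactive fractions, scale with the
enrichment factor, be absent from the process blank, and carry more
than a configurable share of the total intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import Feature, FeatureTable, MatchTolerances, Polarity

__all__ = ["MatchedPair", "CascadeReport", "align_features", "subtract_blank", "run_cascade"]


@dataclass(frozen=True)
class MatchedPair:
    """A one-to-one feature match between two tables (indices + features)."""

    index_a: int
    index_b: int
    feature_a: Feature
    feature_b: Feature


@dataclass
class CascadeReport:
    """Per-step bookkeeping of the prioritization cascade."""

    polarity: Polarity
    steps: list[tuple[str, int]] = field(default_factory=list)
    survivors: list[Feature] = field(default_factory=list)

    def record(self, label: str, count: int) -> None:
        if self.steps and count > self.steps[-1][1]:
            raise AssertionError(
                f"cascade counts must be non-increasing: {label} gave {count} "
                f"after {self.steps[-1]}"
            )
        self.steps.append((label, count))

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.steps]


def _check_same_polarity(a: FeatureTable, b: FeatureTable) -> None:
    pa, pb = a.polarity, b.polarity
    if pa is not None and pb is not None and pa != pb:
        raise ValueError(
            f"polarity mismatch: {a.sample_id} is {pa.value}, {b.sample_id} is {pb.value}"
        )


def align_features(
    a: FeatureTable, b: FeatureTable, tol: MatchTolerances = MatchTolerances()
) -> list[MatchedPair]:
    """One-to-one alignment of two feature tables.

    Candidate pairs satisfy |dm/z| <= ms1_tol and |dRT| <= rt_tol.
    Pairs are assigned greedily by ascending m/z distance, ties broken
    by RT distance, then by lower index, and each feature takes at most
    one partner.  This equals the globally nearest-pair assignment
    because candidates are consumed in distance order.
    """
    _check_same_polarity(a, b)
    candidates: list[tuple[float, float, int, int]] = []
    for i, fa in enumerate(a.features):
        for j, fb in enumerate(b.features):
            dmz = abs(fa.mz - fb.mz)
            drt = abs(fa.rt - fb.rt)
            if dmz <= tol.ms1_tol and drt <= tol.rt_tol:
                candidates.append((dmz, drt, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[MatchedPair] = []
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(MatchedPair(i, j, a.features[i], b.features[j]))
    pairs.sort(key=lambda p: p.index_a)
    return pairs


def subtract_blank(
    sample: FeatureTable,
    blank: FeatureTable,
    tol: MatchTolerances = MatchTolerances(),
) -> FeatureTable:
    """Remove every sample feature that matches any blank feature.

    Removal is on any match within tolerance regardless of the
    intensity ratio (strictest reading of blank subtraction); the
    surviving features keep their original order.
    """
    _check_same_polarity(sample, blank)
    drop: set[int] = set()
    for i, f in enumerate(sample.features):
        for g in blank.features:
            if abs(f.mz - g.mz) <= tol.ms1_tol and abs(f.rt - g.rt) <= tol.rt_tol:
                drop.add(i)
                break
    kept = [f for i, f in enumerate(sample.features) if i not in drop]
    return FeatureTable(sample.sample_id, sample.role, sample.ref, kept)


def _aligned_index_set(
    base: FeatureTable,
    keep_idx: list[int],
    other: FeatureTable,
    tol: MatchTolerances,
) -> tuple[list[int], dict[int, Feature]]:
    """Indices of ``keep_idx`` features (in base) that align to ``other``.

    Returns the surviving base indices and the partner feature per index.
    """
    sub = FeatureTable(base.sample_id, base.role, base.ref,
                       [base.features[i] for i in keep_idx])
    pairs = align_features(sub, other, tol)
    survivors = [keep_idx[p.index_a] for p in pairs]
    partners = {keep_idx[p.index_a]: p.feature_b for p in pairs}
    return survivors, partners


def run_cascade(
    extract5: FeatureTable,
    extract1: FeatureTable,
    upper: FeatureTable,
    lower: FeatureTable,
    process_blank: FeatureTable,
    tol: MatchTolerances = MatchTolerances(),
    intensity_fraction: float = 0.01,
) -> CascadeReport:
    """Run the full prioritization cascade on one polarity.

    Steps, in order:

    1. keep features of the 5x extract that are also detected in the
       1x extract (presence/absence with tolerance matching);
    2. intersect those with the upper and the lower fraction
       separately (reported as the union of the two restricted sets);
    3. drop features whose 1x intensity exceeds their 5x intensity
       (enrichment must not be inverted);
    4. subtract the process blank of the plate separation;
    5. keep features present in BOTH fraction-restricted sets;
    6. keep features whose 5x-extract intensity exceeds
       ``intensity_fraction`` of the summed intensity of the 5x table.

    The report lists the surviving count after every step; counts are
    non-increasing by construction.
    """
    tables = {
        "extract5": extract5,
        "extract1": extract1,
        "upper": upper,
        "lower": lower,
        "process_blank": process_blank,
    }
    for name, tbl in tables.items():
        if name != "process_blank" and len(tbl) == 0:
            raise ValueError(f"required table {name!r} is empty")

    polarity = extract5.polarity or Polarity.POSITIVE
    report = CascadeReport(polarity=polarity)
    report.record("input_extract5", len(extract5))

    # step 1: detected in both enrichment levels
    pairs_51 = align_features(extract5, extract1, tol)
    in_both = [p.index_a for p in pairs_51]
    partner_1x = {p.index_a: p.feature_b for p in pairs_51}
    report.record("in_5x_and_1x", len(in_both))

    # step 2: compared to the upper and lower fraction individually
    upper_idx, _ = _aligned_index_set(extract5, in_both, upper, tol)
    lower_idx, _ = _aligned_index_set(extract5, in_both, lower, tol)
    union = sorted(set(upper_idx) | set(lower_idx))
    report.record("in_any_fraction", len(union))

    # step 3: exclude features with higher intensity at 1x than at 5x
    def keep_monotone(idx: list[int]) -> list[int]:
        return [i for i in idx
                if partner_1x[i].intensity <= extract5.features[i].intensity]

    upper_idx = keep_monotone(upper_idx)
    lower_idx = keep_monotone(lower_idx)
    union = sorted(set(upper_idx) | set(lower_idx))
    report.record("ref_monotone", len(union))

    # step 4: subtract the process blank
    def not_in_blank(idx: list[int]) -> list[int]:
        out = []
        for i in idx:
            f = extract5.features[i]
            hit = any(
                abs(f.mz - g.mz) <= tol.ms1_tol and abs(f.rt - g.rt) <= tol.rt_tol
                for g in process_blank.features
            )
            if not hit:
                out.append(i)
        return out

    upper_idx = not_in_blank(upper_idx)
    lower_idx = not_in_blank(lower_idx)
    union = sorted(set(upper_idx) | set(lower_idx))
    report.record("blank_subtracted", len(union))

    # step 5: present in both fractions
    both = sorted(set(upper_idx) & set(lower_idx))
    report.record("in_both_fractions", len(both))

    # step 6: intensity share above threshold
    total = extract5.total_intensity
    final = [i for i in both
             if extract5.features[i].intensity > intensity_fraction * total]
    report.record("intensity_share", len(final))

    report.survivors = [extract5.features[i] for i in final]
    return report
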