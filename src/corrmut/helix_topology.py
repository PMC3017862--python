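"""Coiled-coil helix calling and periodicity of within-helix correlations.

Helix intervals are maximal runs of residues whose coiled-coil probability
is at least 0.5, kept when at least 4 residues long.  Correlated position
pairs falling inside one helix are binned by their sequence separation
d = |i - j|; on an alpha-helical face one expects enrichment at d = 3, 4, 7
and depletion at d = 2, summarized by the statistic
delta = pct(d=4) - pct(d=2).  Significance comes from a random-stretch
null: intervals with the same count and lengths as the real helices are
re-placed uniformly at random (non-overlapping) within the analyzed
region, and delta is recomputed per replicate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqdata import CoilTrack, ContentError, HelixInterval
from .validation import add_one_pvalue

Pair = tuple[int, int]


def call_helices(
    track: CoilTrack | Sequence[float], pmin: float = 0.5, minlen: int = 4
) -> list[HelixInterval]:
    """Maximal runs of residues with coil probability >= pmin and length >= minlen."""
    probs = track.probabilities if isinstance(track, CoilTrack) else np.asarray(track, float)
    intervals: list[HelixInterval] = []
    start = None
    for i, p in enumerate(probs, start=1):
        if p >= pmin:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= minlen:
                intervals.append(HelixInterval(start, i - 1))
            start = None
    if start is not None and len(probs) - start + 1 >= minlen:
        intervals.append(HelixInterval(start, len(probs)))
    return intervals


@dataclass
class SeparationHistogram:
    """Counts of within-helix correlated pairs by sequence separation."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def percentage(self, separation: int) -> float:
        if self.n == 0:
            raise ContentError("empty histogram")
        return 100.0 * self.counts.get(separation, 0) / self.n

    def percentages(self) -> dict[int, float]:
        return {d: self.percentage(d) for d in sorted(self.counts)}

    @classmethod
    def from_percentages(
        cls, percentages: Mapping[int, float], scale: int = 10
    ) -> "SeparationHistogram":
        """Histogram with the given percentage shares (for arithmetic on
        published summaries; counts are percentages times ``scale``)."""
        total = sum(percentages.values())
        if not np.isclose(total, 100.0):
            raise ContentError("percentages must sum to 100")
        return cls({d: round(p * scale) for d, p in percentages.items()})


def separation_histogram(
    cm_pairs: Iterable[Pair], helices: Sequence[HelixInterval]
) -> SeparationHistogram:
    """Bin intramolecular pairs with both positions inside one helix by |i-j|.

    Pairs straddling two helices (or outside all helices) are excluded.
    Separations are counted in reference residue coordinates.
    """
    counts: Counter[int] = Counter()
    for i, j in cm_pairs:
        if i == j:
            continue
        for h in helices:
            if i in h and j in h:
                counts[abs(i - j)] += 1
                break
    return SeparationHistogram(dict(counts))


def periodicity_statistic(
    hist: SeparationHistogram, d_peak: int = 4, d_trough: int = 2
) -> float:
    """delta = pct(d=4) - pct(d=2): helical-face periodicity contrast."""
    if hist.n == 0:
        raise ContentError("empty histogram: statistic undefined")
    return hist.percentage(d_peak) - hist.percentage(d_trough)


@dataclass
class PeriodicityTest:
    observed: float
    null: np.ndarray
    p_value: float
    reps: int


def _place_stretches(
    lengths: Sequence[int], region: tuple[int, int], rng: np.random.Generator
) -> list[HelixInterval]:
    """Uniformly place non-overlapping stretches of given lengths in a region.

    Uniform over all ordered non-overlapping placements (stars-and-bars on
    the slack), with the length order shuffled per call.
    """
    lo, hi = region
    region_len = hi - lo + 1
    lengths = list(lengths)
    total = sum(lengths)
    slack = region_len - total
    m = len(lengths)
    if slack < 0:
        raise ContentError("stretches cannot be placed without overlap")
    order = rng.permutation(m)
    lens = [lengths[i] for i in order]
    # choose m cut points among slack + m slots -> gap sizes before each stretch
    cuts = np.sort(rng.choice(slack + m, size=m, replace=False))
    gaps = np.diff(np.concatenate(([-1], cuts))) - 1
    intervals = []
    cursor = lo
    for g, L in zip(gaps, lens):
        start = cursor + int(g)
        intervals.append(HelixInterval(start, start + L - 1))
        cursor = start + L
    return intervals


def random_stretch_null(
    region: tuple[int, int],
    helices: Sequence[HelixInterval],
    cm_pairs: Sequence[Pair],
    reps: int = 1000,
    seed: int | None = None,
    d_peak: int = 4,
    d_trough: int = 2,
) -> PeriodicityTest:
    """Significance of the periodicity contrast via re-placed stretches.

    Replicate stretches match the real helices in number and lengths but
    sit at uniformly random non-overlapping positions within ``region``.
    Replicates in which no pair falls inside a stretch contribute a neutral
    delta of 0.  p is the add-one fraction of replicates with delta at or
    above the observed value.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    observed = periodicity_statistic(
        separation_histogram(cm_pairs, helices), d_peak, d_trough
    )
    lengths = [h.length for h in helices]
    null = np.empty(reps)
    for i in range(reps):
        stretches = _place_stretches(lengths, region, rng)
        hist = separation_histogram(cm_pairs, stretches)
        null[i] = (
            periodicity_statistic(hist, d_peak, d_trough) if hist.n else 0.0
        )
    return PeriodicityTest(observed, null, add_one_pvalue(null, observed), reps)


def helix_contact_table(
    cm_pairs: Sequence[tuple[int, int]],
    bins_a: Mapping[str, HelixInterval],
    bins_b: Mapping[str, HelixInterval] | None = None,
    mode: str = "intra",
) -> tuple[dict[tuple[str, str], int], int]:
    """Count correlated pairs linking named intervals (helices or domains).

    Intra mode bins both positions with ``bins_a`` (cell keys are unordered);
    inter mode bins the first position with ``bins_a`` and the second with
    ``bins_b``.  Returns (cell counts, count of pairs with a position
    outside all bins).
    """
    if mode == "inter" and bins_b is None:
        raise ValueError("inter mode requires bins_b")
    bins_second = bins_a if mode == "intra" else bins_b
    table: dict[tuple[str, str], int] = {}
    unbinned = 0

    def locate(pos: int, bins: Mapping[str, HelixInterval]) -> str | None:
        for name, interval in bins.items():
            if pos in interval:
                return name
        return None

    for i, j in cm_pairs:
        name_i = locate(i, bins_a)
        name_j = locate(j, bins_second)
        if name_i is None or name_j is None:
            unbinned += 1
            continue
        key = tuple(sorted((name_i, name_j))) if mode == "intra" else (name_i, name_j)
        table[key] = table.get(key, 0) + 1
    return table, unbinned
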