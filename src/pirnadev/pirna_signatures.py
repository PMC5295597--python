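"""Locus- and TE-level small-RNA statistics.

Weights: every alignment hit contributes ``count * norm_factor /
n_hits_region_set`` so that a read's total contribution across all of
its placements equals its (normalised) occurrence count, however many
times it maps.

Overlap convention: for a sense read with 5' end at genome coordinate
``s`` and an antisense read with 5' end at ``a`` (0-based), the overlap
is ``o = a - s + 1`` (1-based inclusive); the ping-pong signature is the
excess of pairs at ``o = 10``.
"""

from __future__ import annotations

import math
from collections import defaultdict
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .smallrna_io import AlignmentHit, SmallRnaRead

OVERLAP_RANGE = (1, 28)
PINGPONG_OVERLAP = 10


def _weight(hit: AlignmentHit, reads: Mapping[str, SmallRnaRead], factor: float) -> float:
    return reads[hit.read_id].count * factor / hit.n_hits_region_set


def weighted_coverage(
    hits: Sequence[AlignmentHit],
    reads: Mapping[str, SmallRnaRead],
    region_lengths: Mapping[str, int],
    norm_factor: float = 1.0,
) -> dict[str, np.ndarray]:
    """Per-position signed coverage (sense positive, antisense negative)."""
    coverage = {
        name: np.zeros(length, dtype=float) for name, length in region_lengths.items()
    }
    for hit in hits:
        if hit.region not in coverage:
            raise KeyError(f"hit on region {hit.region!r} outside the region set")
        track = coverage[hit.region]
        if hit.start < 0 or hit.end > len(track):
            raise ValueError(
                f"hit {hit.read_id!r} at [{hit.start}, {hit.end}) exceeds "
                f"region {hit.region!r} bounds"
            )
        w = _weight(hit, reads, norm_factor)
        track[hit.start : hit.end] += w if hit.strand == "+" else -w
    return coverage


def size_distribution(
    hits: Sequence[AlignmentHit],
    reads: Mapping[str, SmallRnaRead],
    region: str,
    size_range: tuple[int, int] = (20, 29),
    norm_factor: float = 1.0,
) -> pd.DataFrame:
    """Weighted counts per (length, strand); index covers the full range."""
    lo, hi = size_range
    table = pd.DataFrame(
        0.0, index=pd.RangeIndex(lo, hi + 1, name="length"), columns=["+", "-"]
    )
    for hit in hits:
        if hit.region != region or not lo <= hit.length <= hi:
            continue
        table.loc[hit.length, hit.strand] += _weight(hit, reads, norm_factor)
    return table


def u1_bias(
    hits: Sequence[AlignmentHit],
    reads: Mapping[str, SmallRnaRead],
    region: str,
    size_range: tuple[int, int] = (23, 29),
) -> float | None:
    """Weighted fraction of in-range reads whose 5' insert base is T.

    Measured on the read sequence itself (5' base of the insert),
    regardless of which genome strand it matched.  ``None`` when no
    in-range reads map to the region.
    """
    lo, hi = size_range
    num = den = 0.0
    for hit in hits:
        if hit.region != region or not lo <= hit.length <= hi:
            continue
        w = _weight(hit, reads, 1.0)
        den += w
        if reads[hit.read_id].insert_seq[0] == "T":
            num += w
    return None if den == 0 else num / den


def five_prime_profiles(
    hits: Sequence[AlignmentHit],
    reads: Mapping[str, SmallRnaRead],
    region: str,
    size_range: tuple[int, int] = (23, 28),
    norm_factor: float = 1.0,
) -> tuple[dict[int, float], dict[int, float]]:
    """Weighted 5'-end counts per position, split by strand."""
    lo, hi = size_range
    sense: dict[int, float] = defaultdict(float)
    antisense: dict[int, float] = defaultdict(float)
    for hit in hits:
        if hit.region != region or not lo <= hit.length <= hi:
            continue
        w = _weight(hit, reads, norm_factor)
        (sense if hit.strand == "+" else antisense)[hit.five_prime] += w
    return dict(sense), dict(antisense)


def pingpong_signature(
    hits: Sequence[AlignmentHit],
    reads: Mapping[str, SmallRnaRead],
    region: str,
    size_range: tuple[int, int] = (23, 28),
    norm_factor: float = 1.0,
) -> np.ndarray:
    """Histogram of sense/antisense 5'-overlap pair counts.

    Returns an array of length 28; entry ``i`` holds the weighted pair
    count at overlap ``i + 1``.  Pair count at overlap ``o`` is the sum
    over sense 5' positions ``s`` of ``sense[s] * antisense[s + o - 1]``.
    """
    sense, antisense = five_prime_profiles(hits, reads, region, size_range, norm_factor)
    lo, hi = OVERLAP_RANGE
    hist = np.zeros(hi - lo + 1, dtype=float)
    for s, w_s in sense.items():
        for o in range(lo, hi + 1):
            w_a = antisense.get(s + o - 1)
            if w_a:
                hist[o - lo] += w_s * w_a
    return hist


def pingpong_zscore(overlap_hist: np.ndarray) -> float | None:
    """Standard score of the overlap-10 bin against all other bins.

    A perfectly flat histogram scores 0; when the off-bin standard
    deviation is zero but the overlap-10 bin deviates (e.g. a single
    spike), the score is undefined and ``None`` is returned.
    """
    hist = np.asarray(overlap_hist, dtype=float)
    if hist.shape[0] != OVERLAP_RANGE[1] - OVERLAP_RANGE[0] + 1:
        raise ValueError("overlap histogram must cover overlaps 1..28")
    idx = PINGPONG_OVERLAP - OVERLAP_RANGE[0]
    others = np.delete(hist, idx)
    sd = float(np.std(others, ddof=1))
    delta = float(hist[idx] - others.mean())
    if sd == 0.0:
        return 0.0 if delta == 0.0 else None
    return delta / sd


def te_antisense_rpkm(
    hits: Sequence[AlignmentHit],
    reads: Mapping[str, SmallRnaRead],
    te_lengths: Mapping[str, int],
    norm_factor: float,
    effective_depth: float,
    size_range: tuple[int, int] = (23, 29),
) -> pd.DataFrame:
    """Per-TE normalised antisense counts and RPKM.

    ``rpkm = normalised antisense count / (length/1e3) / (depth/1e6)``
    with the library's effective depth as the per-million denominator.
    """
    if effective_depth <= 0:
        raise ValueError("effective_depth must be positive")
    for name, length in te_lengths.items():
        if length <= 0:
            raise ValueError(f"TE {name!r} has non-positive length")
    lo, hi = size_range
    counts = {name: 0.0 for name in te_lengths}
    for hit in hits:
        if hit.region in counts and hit.strand == "-" and lo <= hit.length <= hi:
            counts[hit.region] += _weight(hit, reads, norm_factor)
    rows = [
        {
            "name": name,
            "length": length,
            "antisense_norm_count": counts[name],
            "rpkm": counts[name] / (length / 1e3) / (effective_depth / 1e6),
        }
        for name, length in te_lengths.items()
    ]
    return pd.DataFrame(rows, columns=["name", "length", "antisense_norm_count", "rpkm"])


def glkd_scatter(
    control: pd.DataFrame, test: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Knockdown comparison: x = log2(control + pc), y = log2 test/control.

    Both tables must cover the same TE set (error lists the symmetric
    difference otherwise).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ctrl = control.set_index("name")["antisense_norm_count"]
    tst = test.set_index("name")["antisense_norm_count"]
    missing = set(ctrl.index) ^ set(tst.index)
    if missing:
        raise ValueError(f"TE sets differ between tables: {sorted(missing)}")
    tst = tst.reindex(ctrl.index)
    x = np.log2(ctrl.to_numpy() + pseudocount)
    y = np.log2((tst.to_numpy() + pseudocount) / (ctrl.to_numpy() + pseudocount))
    return pd.DataFrame(
        {
            "name": ctrl.index,
            "log2_control_count": x,
            "log2_ratio_test_over_control": y,
        }
    )


def coverage_to_bedgraph(coverage: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Run-length encode signed coverage as (region, start, end, weight)."""
    rows = []
    for region, track in coverage.items():
        if len(track) == 0:
            continue
        start = 0
        for pos in range(1, len(track) + 1):
            if pos == len(track) or not math.isclose(
                track[pos], track[start], rel_tol=1e-12, abs_tol=0.0
            ):
                if track[start] != 0.0:
                    rows.append(
                        {
                            "region": region,
                            "start": start,
                            "end": pos,
                            "weight": float(track[start]),
                        }
                    )
                start = pos
    return pd.DataFrame(rows, columns=["region", "start", "end", "weight"])
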