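"""Read categorisation and cross-library normalisation.

Every matched read is assigned exactly one category by a fixed priority
order (miscRNA > tRNA > miRNA > TE > genome_other).  Effective depth is
the matched total minus abundant cellular RNA (miscRNA, tRNA) counts;
the lowest-depth library is the normalisation reference.  A second,
miRNA-count-based factor is flagged unusable when the library's miRNA
fraction is too low to be a stable yardstick.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .smallrna_io import SmallRnaRead, match_reads

CATEGORY_ORDER = ("miscRNA", "tRNA", "miRNA", "TE", "genome_other")

#: below this miRNA fraction of matched reads the miRNA factor is unusable
DEFAULT_MIRNA_THRESHOLD = 0.10


@dataclass
class LibraryStats:
    library_id: str
    total_genome_matched: int
    per_category: dict[str, int]
    unmatched: int = 0
    norm_factor_depth: float | None = None
    norm_factor_mirna: float | None = None
    effective_depth: int = field(init=False)

    def __post_init__(self) -> None:
        for cat in self.per_category:
            if cat not in CATEGORY_ORDER:
                raise ValueError(f"unknown category {cat!r}")
        if sum(self.per_category.values()) > self.total_genome_matched:
            raise ValueError("per-category counts exceed matched total")
        self.effective_depth = self.total_genome_matched - (
            self.per_category.get("miscRNA", 0) + self.per_category.get("tRNA", 0)
        )

    @property
    def mirna_fraction(self) -> float:
        if self.total_genome_matched == 0:
            return 0.0
        return self.per_category.get("miRNA", 0) / self.total_genome_matched


def annotate_library(
    library_id: str,
    reads: Sequence[SmallRnaRead],
    genome: Mapping[str, str],
    annotation_sets: Mapping[str, Mapping[str, str]] | None = None,
    te_references: Mapping[str, str] | None = None,
    max_mismatch: int = 1,
) -> tuple[LibraryStats, dict[str, str]]:
    """Assign one category per read and tally the library.

    A read counts as matched when it places on the toy genome or on any
    annotation reference set; its category is the highest-priority set it
    hits, ``genome_other`` when it only hits the genome.  Counts are
    weighted by the collapsed occurrence count.  Reads hitting nothing go
    to ``unmatched`` and are excluded from the effective depth.
    """
    annotation_sets = dict(annotation_sets or {})
    if te_references:
        annotation_sets.setdefault("TE", te_references)
    for cat in annotation_sets:
        if cat not in CATEGORY_ORDER:
            raise ValueError(f"unknown annotation category {cat!r}")

    hit_ids: dict[str, set[str]] = {}
    for cat, refs in annotation_sets.items():
        hit_ids[cat] = {h.read_id for h in match_reads(reads, refs, max_mismatch)}
    hit_ids["genome_other"] = {
        h.read_id for h in match_reads(reads, genome, max_mismatch)
    }

    per_category = {cat: 0 for cat in CATEGORY_ORDER}
    categories: dict[str, str] = {}
    matched = 0
    unmatched = 0
    for read in reads:
        for cat in CATEGORY_ORDER:
            if read.read_id in hit_ids.get(cat, ()):
                categories[read.read_id] = cat
                per_category[cat] += read.count
                matched += read.count
                break
        else:
            unmatched += read.count

    stats = LibraryStats(
        library_id=library_id,
        total_genome_matched=matched,
        per_category=per_category,
        unmatched=unmatched,
    )
    return stats, categories


def normalization_factors(
    stats: Sequence[LibraryStats],
    mirna_threshold: float = DEFAULT_MIRNA_THRESHOLD,
) -> list[LibraryStats]:
    """Fill in both normalisation factors, in place, and return the list.

    Depth factors scale every library down to the smallest effective
    depth, so the reference library's factor is exactly 1.  The miRNA
    factor is computed analogously from miRNA counts, restricted to
    libraries whose miRNA fraction reaches ``mirna_threshold``; below
    that the factor is left ``None`` (unusable).
    """
    if not stats:
        raise ValueError("need at least one library")
    for s in stats:
        if s.effective_depth <= 0:
            raise ValueError(f"library {s.library_id!r} has zero effective depth")
    ref_depth = min(s.effective_depth for s in stats)
    usable = [
        s
        for s in stats
        if s.mirna_fraction >= mirna_threshold and s.per_category.get("miRNA", 0) > 0
    ]
    ref_mirna = min((s.per_category["miRNA"] for s in usable), default=None)
    for s in stats:
        s.norm_factor_depth = ref_depth / s.effective_depth
        if s in usable and ref_mirna is not None:
            s.norm_factor_mirna = ref_mirna / s.per_category["miRNA"]
        else:
            s.norm_factor_mirna = None
    return list(stats)


def normalized_count(raw: float, factor: float) -> float:
    if raw < 0:
        raise ValueError("raw count must be non-negative")
    if factor <= 0:
        raise ValueError("factor must be positive")
    return raw * factor
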