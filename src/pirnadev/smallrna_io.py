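"""Read processing and placement on toy references.

Coordinates are 0-based, half-open internally; the SAM boundary converts
to/from 1-based.  A hit on the ``-`` strand at ``start`` means the
read's reverse complement matches ``reference[start:start+length]``; its
biological 5' end then sits at genome coordinate ``start + length - 1``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pysam

from .synthetic_data import reverse_complement

MIN_INSERT = 19
MAX_INSERT = 29
MAX_TOTAL_REFERENCE = 1_000_000  # desk-scale contract

_NT = set("ACGTN")


@dataclass(frozen=True)
class TrimResult:
    insert: str | None
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.insert is not None


@dataclass(frozen=True)
class SmallRnaRead:
    """A collapsed (deduplicated) insert sequence with its occurrence count."""

    read_id: str
    insert_seq: str
    count: int = 1
    length: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", len(self.insert_seq))
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if set(self.insert_seq) - _NT:
            raise ValueError("insert_seq must be over {A,C,G,T,N}")


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    region: str
    start: int
    strand: str
    mismatches: int
    n_hits_region_set: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Genome coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.start + self.length - 1


def trim_adapter(
    raw_seq: str,
    adapter: str,
    min_overlap: int = 8,
    min_len: int = MIN_INSERT,
    max_len: int = MAX_INSERT,
) -> TrimResult:
    """Strip the 3' adapter and apply the insert length filter.

    The insert is the prefix of ``raw_seq`` before the leftmost exact
    occurrence of an adapter prefix of at least ``min_overlap`` bases
    (the full adapter when room allows, a shorter adapter prefix when the
    adapter runs off the 3' end).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    raw_seq = raw_seq.upper()
    if set(raw_seq) - _NT:
        return TrimResult(None, "non_nucleotide")
    cut = None
    for i in range(len(raw_seq) - min_overlap + 1):
        k = min(len(adapter), len(raw_seq) - i)
        if raw_seq[i : i + k] == adapter[:k]:
            cut = i
            break
    if cut is None:
        return TrimResult(None, "no_adapter")
    insert = raw_seq[:cut]
    if "N" in insert:
        return TrimResult(None, "ambiguous_base")
    if not min_len <= len(insert) <= max_len:
        return TrimResult(None, "length_out_of_range")
    return TrimResult(insert)


def collapse_reads(
    sequences: Sequence[str], id_prefix: str = "read"
) -> list[SmallRnaRead]:
    """One record per distinct sequence; counts sum to the input size.

    Records are ordered by decreasing count, ties broken lexicographically,
    so output is deterministic regardless of input order.
    """
    for seq in sequences:
        if not MIN_INSERT <= len(seq) <= MAX_INSERT:
            raise ValueError(f"sequence length {len(seq)} outside {MIN_INSERT}..{MAX_INSERT}")
    tally = Counter(sequences)
    ordered = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        SmallRnaRead(f"{id_prefix}_{i}", seq, count)
        for i, (seq, count) in enumerate(ordered)
    ]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def match_reads(
    reads: Sequence[SmallRnaRead],
    references: Mapping[str, str],
    max_mismatch: int = 1,
) -> list[AlignmentHit]:
    """All placements of every read on both strands of every reference.

    Substitution-only matching (no indels).  Best-stratum rule: a read
    with at least one 0-mismatch placement reports only its 0-mismatch
    placements.  ``n_hits_region_set`` counts the retained placements of
    the read across the whole reference collection.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    total = sum(len(s) for s in references.values())
    if total > MAX_TOTAL_REFERENCE:
        raise ValueError("reference collection exceeds the desk-scale limit")
    for name, seq in references.items():
        if set(seq) - set("ACGT"):
            raise ValueError(f"reference {name!r} contains non-ACGT characters")

    ref_arrays = {name: _encode(seq) for name, seq in references.items()}

    by_length: dict[int, list[int]] = defaultdict(list)
    for idx, read in enumerate(reads):
        by_length[read.length].append(idx)

    # raw[i] = list of (mismatches, region, start, strand)
    raw: list[list[tuple[int, str, int, str]]] = [[] for _ in reads]

    chunk = 64
    for length, idxs in by_length.items():
        fwd = np.stack([_encode(reads[i].insert_seq) for i in idxs])
        rev = np.stack(
            [_encode(reverse_complement(reads[i].insert_seq)) for i in idxs]
        )
        for region, arr in ref_arrays.items():
            if len(arr) < length:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, length)
            for lo in range(0, len(idxs), chunk):
                sel = slice(lo, lo + chunk)
                for mat, strand in ((fwd[sel], "+"), (rev[sel], "-")):
                    mm = (windows[None, :, :] != mat[:, None, :]).sum(axis=2)
                    rows, cols = np.nonzero(mm <= max_mismatch)
                    for r, c in zip(rows.tolist(), cols.tolist()):
                        raw[idxs[lo + r]].append(
                            (int(mm[r, c]), region, int(c), strand)
                        )

    hits: list[AlignmentHit] = []
    for read, placements in zip(reads, raw):
        if not placements:
            continue
        best = min(p[0] for p in placements)
        kept = [p for p in placements if p[0] == best]
        n = len(kept)
        for mismatches, region, start, strand in kept:
            hits.append(
                AlignmentHit(read.read_id, region, start, strand, mismatches, n, read.length)
            )
    return hits


# ---------------------------------------------------------------------------
# SAM boundary
# ---------------------------------------------------------------------------


def write_sam(
    hits: Sequence[AlignmentHit],
    reads: Mapping[str, SmallRnaRead],
    references: Mapping[str, str],
    path,
) -> None:
    """Minimal SAM: @SQ header plus the 11 mandatory fields; NM carries
    mismatches, NH the region-set hit count, XC the collapsed count."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in references.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {name: i for i, name in enumerate(references)}
        for hit in hits:
            read = reads[hit.read_id]
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = hit.read_id
            seg.flag = 16 if hit.strand == "-" else 0
            seg.reference_id = tid[hit.region]
            seg.reference_start = hit.start
            seg.mapping_quality = 255
            seg.cigarstring = f"{hit.length}M"
            seq = read.insert_seq if hit.strand == "+" else reverse_complement(read.insert_seq)
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * hit.length)
            seg.set_tag("NM", hit.mismatches, "i")
            seg.set_tag("NH", hit.n_hits_region_set, "i")
            seg.set_tag("XC", read.count, "i")
            out.write(seg)


def import_sam(
    path, regions: Sequence[str] | None = None
) -> tuple[list[AlignmentHit], dict[str, SmallRnaRead]]:
    """Parse a SAM file into hits plus the reads they reference.

    Coordinates come back 0-based (pysam converts from SAM's 1-based
    POS); FLAG bit 16 sets the ``-`` strand, bit 4 skips the record.
    When an NH tag is absent, multimapping is recounted over the records
    that fall within ``regions`` (default: all reference sequences in
    the header).  Read sequences are recovered on the original read
    strand; duplicate placements of a read must agree on the sequence.
    """
    entries: list[tuple[str, str, int, str, int, int]] = []
    nh_tags: dict[str, int] = {}
    counts: dict[str, int] = {}
    seqs: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        known = set(regions) if regions is not None else set(sam.references)
        for lineno, seg in enumerate(sam.fetch(until_eof=True), start=1):
            if seg.is_unmapped:
                continue
            if seg.reference_name is None or seg.query_sequence is None:
                raise ValueError(f"malformed SAM record at alignment line {lineno}")
            if seg.reference_name not in known:
                continue
            strand = "-" if seg.is_reverse else "+"
            insert = (
                reverse_complement(seg.query_sequence)
                if seg.is_reverse
                else seg.query_sequence
            )
            name = seg.query_name
            prior = seqs.setdefault(name, insert)
            if prior != insert:
                raise ValueError(
                    f"read {name!r}: conflicting sequences at alignment line {lineno}"
                )
            nm = int(seg.get_tag("NM")) if seg.has_tag("NM") else 0
            if seg.has_tag("NH"):
                nh_tags[name] = int(seg.get_tag("NH"))
            if seg.has_tag("XC"):
                counts[name] = int(seg.get_tag("XC"))
            entries.append(
                (name, seg.reference_name, seg.reference_start, strand, nm, len(insert))
            )

    per_read = Counter(name for name, *_ in entries)
    reads = {
        name: SmallRnaRead(name, seq, counts.get(name, 1))
        for name, seq in seqs.items()
    }
    hits = [
        AlignmentHit(
            name,
            region,
            start,
            strand,
            nm,
            nh_tags.get(name, per_read[name]),
            length,
        )
        for name, region, start, strand, nm, length in entries
    ]
    return hits, reads


def read_fastq(path) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs from an uncompressed 4-line FASTQ."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
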