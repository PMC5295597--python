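"""Synthetic toy genomes, small-RNA libraries and clonal lineage tables.

Every downstream stage of the package is testable against the truth
tables emitted here: each simulated read records its origin region,
strand, start and intended ping-pong partner, and each simulated germ
cell records its (hidden) clone of origin alongside the two observable
markers.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAG"

REGION_ROLES = frozenset({"dual_strand_cluster", "subtelomere", "transgene", "other"})

#: default insert-size distribution, peaked at 25 nt (package choice;
#: only the 19..29 support is constrained).
DEFAULT_SIZE_DIST: dict[int, float] = {
    23: 0.10,
    24: 0.20,
    25: 0.30,
    26: 0.20,
    27: 0.10,
    28: 0.07,
    29: 0.03,
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# planted exact repeat inside dual-strand cluster regions: the block
# [REPEAT_START, REPEAT_START+REPEAT_LEN) is copied to the interval
# ending REPEAT_END_OFFSET before the region end.  Guarantees that reads
# drawn from either copy map at least twice.
REPEAT_LEN = 60
REPEAT_START = 20
REPEAT_END_OFFSET = 80


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FastqRecord(NamedTuple):
    read_id: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class RegionSpec:
    name: str
    length: int
    role: str = "other"

    def __post_init__(self) -> None:
        if self.role not in REGION_ROLES:
            raise ValueError(f"unknown region role {self.role!r}")
        if self.length < 200:
            raise ValueError(f"region {self.name!r}: length must be >= 200 nt")


@dataclass(frozen=True)
class ToyGenomeSpec:
    regions: tuple[RegionSpec, ...]
    gc_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")


class ToyGenome(Mapping):
    """Per-region nucleotide sequences plus region-role metadata.

    Behaves as a ``Mapping[str, str]`` from region name to sequence so
    that alignment code can treat it as a plain reference collection.
    """

    def __init__(self, sequences: dict[str, str], roles: dict[str, str]):
        self._sequences = dict(sequences)
        self.roles = dict(roles)

    def __getitem__(self, name: str) -> str:
        return self._sequences[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sequences)

    def __len__(self) -> int:
        return len(self._sequences)

    def repeat_blocks(self, name: str) -> tuple[tuple[int, int], tuple[int, int]]:
        """Half-open coordinates of the two planted repeat copies."""
        if self.roles.get(name) != "dual_strand_cluster":
            raise KeyError(f"{name!r} is not a dual_strand_cluster region")
        length = len(self._sequences[name])
        first = (REPEAT_START, REPEAT_START + REPEAT_LEN)
        second = (length - REPEAT_END_OFFSET, length - REPEAT_END_OFFSET + REPEAT_LEN)
        return first, second

    def cluster_regions(self) -> list[str]:
        return [n for n, r in self.roles.items() if r == "dual_strand_cluster"]


def _random_sequence(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    p = np.array(
        [
            (1 - gc_fraction) / 2,  # A
            gc_fraction / 2,  # C
            gc_fraction / 2,  # G
            (1 - gc_fraction) / 2,  # T
        ]
    )
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def make_toy_genome(spec: ToyGenomeSpec) -> ToyGenome:
    """Generate per-region sequences; deterministic for a fixed seed.

    Each region is generated from an independent stream (seeded by the
    global seed and the region's index), so adding a region does not
    perturb the others.  Dual-strand cluster regions receive an exact
    internal repeat of ``REPEAT_LEN`` nt so multimapping reads exist.
    """
    sequences: dict[str, str] = {}
    for idx, region in enumerate(spec.regions):
        rng = np.random.default_rng([spec.seed, idx])
        seq = _random_sequence(rng, region.length, spec.gc_fraction)
        if region.role == "dual_strand_cluster":
            block = seq[REPEAT_START : REPEAT_START + REPEAT_LEN]
            dest = region.length - REPEAT_END_OFFSET
            seq = seq[:dest] + block + seq[dest + REPEAT_LEN :]
        sequences[region.name] = seq
    return ToyGenome(sequences, {r.name: r.role for r in spec.regions})


#: annotation-reference shapes per contaminant category:
#: (number of sequences, length of each)
_ANNOTATION_SHAPES = {"miscRNA": (3, 150), "tRNA": (4, 76), "miRNA": (6, 30)}


def make_annotation_references(
    seed: int, gc_fraction: float = 0.45
) -> dict[str, dict[str, str]]:
    """Generate contaminant reference sets (miscRNA, tRNA, miRNA)."""
    out: dict[str, dict[str, str]] = {}
    for cat_idx, (category, (n, length)) in enumerate(sorted(_ANNOTATION_SHAPES.items())):
        rng = np.random.default_rng([seed, 1000 + cat_idx])
        out[category] = {
            f"{category}_{i}": _random_sequence(rng, length, gc_fraction)
            for i in range(n)
        }
    return out


def make_te_references(
    seed: int, n_te: int = 8, length: int = 1000, gc_fraction: float = 0.45
) -> dict[str, str]:
    """Generate a toy transposon reference set."""
    rng = np.random.default_rng([seed, 2000])
    return {f"TE_{i}": _random_sequence(rng, length, gc_fraction) for i in range(n_te)}


@dataclass(frozen=True)
class PiRnaLibrarySpec:
    """Parameters of one simulated small-RNA library."""

    n_reads: int
    size_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_DIST)
    )
    pingpong_fraction: float = 0.0
    u1_bias: float = 0.25
    antisense_fraction: float = 0.5
    contaminant_fractions: Mapping[str, float] = field(default_factory=dict)
    multimap_rate: float = 0.0
    depletion: Mapping[str, float] = field(default_factory=dict)
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        if any(not 19 <= k <= 29 for k in self.size_dist):
            raise ValueError("size_dist mass outside the 19..29 nt window")
        total = float(sum(self.size_dist.values()))
        if total <= 0:
            raise ValueError("size_dist must have positive mass")
        for name in ("pingpong_fraction", "u1_bias", "antisense_fraction", "multimap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if sum(self.contaminant_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("contaminant fractions must sum to <= 1")
        for region, f in self.depletion.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"depletion factor for {region!r} must be in [0, 1]")
        if len(self.adapter) < 10:
            raise ValueError("adapter must be at least 10 nt")
        if set(self.adapter) - set("ACGT"):
            raise ValueError("adapter must be over {A,C,G,T}")


TRUTH_COLUMNS = [
    "read_id",
    "category",
    "origin",
    "strand",
    "start",
    "length",
    "insert_seq",
    "is_pingpong",
    "pair_id",
    "multimap",
]


def _region_probabilities(
    genome: Mapping[str, str], depletion: Mapping[str, float]
) -> tuple[list[str], np.ndarray]:
    """Region sampling weights: length x depletion, with the depleted mass
    redistributed over non-depleted regions so that a depleted region's
    expected read count is exactly ``factor`` times its undepleted count
    (at equal library size)."""
    names = list(genome)
    lengths = np.array([len(genome[n]) for n in names], dtype=float)
    base = lengths / lengths.sum()
    factors = np.array([depletion.get(n, 1.0) for n in names], dtype=float)
    kept = base * factors
    deficit = base.sum() - kept.sum()
    undepleted = factors >= 1.0
    if deficit > 0 and undepleted.any():
        kept[undepleted] += deficit * base[undepleted] / base[undepleted].sum()
    total = kept.sum()
    if total <= 0:
        raise ValueError("all regions fully depleted; no genomic reads possible")
    return names, kept / total


def _sample_length(rng: np.random.Generator, lengths: np.ndarray, probs: np.ndarray) -> int:
    return int(rng.choice(lengths, p=probs))


def _pick_start(
    rng: np.random.Generator,
    seq: str,
    lo: int,
    hi: int,
    want_u1: bool,
    base_at: "callable",
    attempts: int = 200,
) -> int:
    """Uniform start in [lo, hi] subject to a 5' base constraint.

    ``base_at(start)`` returns the 5' base of the read placed at
    ``start``; the constraint is 'is T' == ``want_u1``.  Falls back to an
    unconstrained draw if rejection sampling fails (composition may make
    the constraint unsatisfiable, e.g. gc_fraction == 1)."""
    for _ in range(attempts):
        s = int(rng.integers(lo, hi + 1))
        if (base_at(s) == "T") == want_u1:
            return s
    return int(rng.integers(lo, hi + 1))


def simulate_library(
    genome: Mapping[str, str],
    spec: PiRnaLibrarySpec,
    annotations: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Emit FASTQ records (insert + adapter, constant quality) and a truth
    table with one row per read.

    Ping-pong pairs are emitted jointly: the sense partner's 5' end at
    ``s`` and the antisense partner's 5' end at ``s + 9`` (10-nt overlap,
    1-based inclusive convention).  When a pair is drawn with only one
    read slot remaining, a single unpaired read is emitted instead so
    that exactly ``n_reads`` records are produced.
    """
    for region in spec.depletion:
        if region not in genome:
            raise KeyError(f"depletion names unknown region {region!r}")
    contaminants = dict(spec.contaminant_fractions)
    if contaminants and not annotations:
        raise ValueError("contaminant fractions given but no annotation references")
    for cat in contaminants:
        if annotations is None or cat not in annotations:
            raise KeyError(f"no annotation references for category {cat!r}")

    rng = np.random.default_rng(spec.seed)
    region_names, region_probs = _region_probabilities(genome, spec.depletion)
    size_lengths = np.array(sorted(spec.size_dist), dtype=int)
    size_probs = np.array([spec.size_dist[k] for k in size_lengths], dtype=float)
    size_probs = size_probs / size_probs.sum()

    cat_names = list(contaminants) + ["genomic"]
    cat_probs = np.array(
        list(contaminants.values()) + [1.0 - sum(contaminants.values())]
    )
    cat_probs = np.clip(cat_probs, 0.0, None)
    cat_probs = cat_probs / cat_probs.sum()

    # multimap reads must come from a planted repeat block
    cluster_blocks: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}
    if isinstance(genome, ToyGenome):
        for name in genome.cluster_regions():
            cluster_blocks[name] = genome.repeat_blocks(name)
    if spec.multimap_rate > 0 and not cluster_blocks:
        raise ValueError(
            "multimap_rate > 0 requires a dual_strand_cluster region (ToyGenome)"
        )

    records: list[FastqRecord] = []
    rows: list[dict] = []

    def emit(
        insert: str,
        category: str,
        origin: str,
        strand: str,
        start: int,
        pair_id: str = "",
        is_pp: bool = False,
        multimap: bool = False,
    ) -> str:
        rid = f"sim_{len(records)}"
        seq = insert + spec.adapter
        records.append(FastqRecord(rid, seq, "I" * len(seq)))
        rows.append(
            {
                "read_id": rid,
                "category": category,
                "origin": origin,
                "strand": strand,
                "start": start,
                "length": len(insert),
                "insert_seq": insert,
                "is_pingpong": is_pp,
                "pair_id": pair_id,
                "multimap": multimap,
            }
        )
        return rid

    def emit_contaminant(category: str) -> None:
        refs = annotations[category]  # type: ignore[index]
        name = list(refs)[int(rng.integers(len(refs)))]
        seq = refs[name]
        length = min(_sample_length(rng, size_lengths, size_probs), len(seq))
        want = bool(rng.random() < spec.u1_bias)
        start = _pick_start(rng, seq, 0, len(seq) - length, want, lambda s: seq[s])
        emit(seq[start : start + length], category, name, "+", start)

    def emit_single_genomic() -> None:
        multimap = bool(rng.random() < spec.multimap_rate) and bool(cluster_blocks)
        if multimap:
            region = list(cluster_blocks)[int(rng.integers(len(cluster_blocks)))]
        else:
            region = region_names[int(rng.choice(len(region_names), p=region_probs))]
        seq = genome[region]
        length = _sample_length(rng, size_lengths, size_probs)
        strand = "-" if rng.random() < spec.antisense_fraction else "+"
        want = bool(rng.random() < spec.u1_bias)
        if multimap:
            blocks = cluster_blocks[region]
            block = blocks[int(rng.integers(2))]
            lo, hi = block[0], block[1] - length
        else:
            lo, hi = 0, len(seq) - length
        if strand == "+":
            start = _pick_start(rng, seq, lo, hi, want, lambda s: seq[s])
            insert = seq[start : start + length]
        else:
            start = _pick_start(
                rng, seq, lo, hi, want,
                lambda s: reverse_complement(seq[s + length - 1]),
            )
            insert = reverse_complement(seq[start : start + length])
        emit(insert, "genomic", region, strand, start, multimap=multimap)

    def emit_pingpong_pair() -> None:
        region = region_names[int(rng.choice(len(region_names), p=region_probs))]
        seq = genome[region]
        l_sense = _sample_length(rng, size_lengths, size_probs)
        l_anti = _sample_length(rng, size_lengths, size_probs)
        lo = max(0, l_anti - 10)
        hi = len(seq) - max(l_sense, 10)
        want_s = bool(rng.random() < spec.u1_bias)
        want_a = bool(rng.random() < spec.u1_bias)
        s = None
        for _ in range(200):
            cand = int(rng.integers(lo, hi + 1))
            ok_s = (seq[cand] == "T") == want_s
            ok_a = (reverse_complement(seq[cand + 9]) == "T") == want_a
            if ok_s and ok_a:
                s = cand
                break
        if s is None:
            s = _pick_start(rng, seq, lo, hi, want_s, lambda x: seq[x])
        sense_insert = seq[s : s + l_sense]
        anti_start = s + 10 - l_anti
        anti_insert = reverse_complement(seq[anti_start : anti_start + l_anti])
        rid_s = emit(sense_insert, "genomic", region, "+", s, is_pp=True)
        rid_a = emit(
            anti_insert, "genomic", region, "-", anti_start, pair_id=rid_s, is_pp=True
        )
        rows[-2]["pair_id"] = rid_a

    while len(records) < spec.n_reads:
        category = cat_names[int(rng.choice(len(cat_names), p=cat_probs))]
        if category != "genomic":
            emit_contaminant(category)
        elif (
            rng.random() < spec.pingpong_fraction
            and spec.n_reads - len(records) >= 2
        ):
            emit_pingpong_pair()
        else:
            emit_single_genomic()

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return records, truth


def write_fastq(records: list[FastqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")


def write_fasta(references: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in references.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# clonal lineage simulation
# ---------------------------------------------------------------------------

CLONE_COLUMNS = ["gonad_id", "clone_id", "cell_id", "gfp", "repressed"]


@dataclass(frozen=True)
class CloneSimSpec:
    """Parameters of a gonad lineage simulation.

    ``model='lock'`` copies each founder cell's repression state through
    every division.  ``model='plastic'`` lets each daughter cell redraw
    its state: with probability ``switch_rate`` per division the state is
    resampled as repressed with probability ``r`` (the stationary law),
    otherwise it is inherited.  ``switch_rate=1`` therefore makes leaf
    states fully independent with marginal repression probability ``r``.
    """

    n_gonads: int
    r: float
    model: str = "lock"
    pgc_init: int = 10
    divisions: int = 3
    switch_rate: float = 0.0
    flipout_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gonads < 1:
            raise ValueError("n_gonads must be positive")
        if self.pgc_init < 1:
            raise ValueError("pgc_init must be positive")
        if self.divisions < 0:
            raise ValueError("divisions must be non-negative")
        if self.model not in ("lock", "plastic"):
            raise ValueError("model must be 'lock' or 'plastic'")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must be in [0, 1]")
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ValueError("switch_rate must be in [0, 1]")
        if not 0.0 <= self.flipout_prob <= 1.0:
            raise ValueError("flipout_prob must be in [0, 1]")
        if self.model == "lock" and self.switch_rate != 0.0:
            raise ValueError("lock model implies switch_rate = 0")


def simulate_clones(spec: CloneSimSpec) -> pd.DataFrame:
    """One row per final-stage germ cell.

    ``clone_id`` identifies the founder cell and is ground truth only:
    classification operations must rely on the observable ``gfp`` and
    repression columns.  Per gonad, the cell count is
    ``pgc_init * 2**divisions``.
    """
    rng = np.random.default_rng(spec.seed)
    n_clones = spec.n_gonads * spec.pgc_init
    clone_size = 2**spec.divisions

    founder_state = rng.random(n_clones) < spec.r
    founder_gfp = rng.random(n_clones) < spec.flipout_prob

    # states[clone, cell-slot]; each division doubles the slots
    states = founder_state[:, None].copy()
    for _ in range(spec.divisions):
        states = np.repeat(states, 2, axis=1)
        if spec.model == "plastic" and spec.switch_rate > 0:
            redraw = rng.random(states.shape) < spec.switch_rate
            resampled = rng.random(states.shape) < spec.r
            states = np.where(redraw, resampled, states)

    rows = {
        "gonad_id": np.repeat(
            [f"gonad_{g}" for g in range(spec.n_gonads)], spec.pgc_init * clone_size
        ),
        "clone_id": np.repeat(np.arange(n_clones), clone_size),
        "cell_id": np.arange(n_clones * clone_size),
        "gfp": np.repeat(founder_gfp, clone_size),
        "repressed": states.reshape(-1),
    }
    return pd.DataFrame(rows, columns=CLONE_COLUMNS)
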