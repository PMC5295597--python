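"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: plain Python
scans, exhaustive enumerations and closed forms only.
"""

from __future__ import annotations

from collections import Counter

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def has_internal_repeat(seq: str, k: int) -> bool:
    """Exhaustive scan: does any k-mer occur at two distinct positions?"""
    seen: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in seen and seen[kmer] != i:
            return True
        seen.setdefault(kmer, i)
    return False


def scan_alignments(
    read_seq: str, references: dict[str, str], max_mismatch: int
) -> set[tuple[str, int, str, int]]:
    """Every placement of a read at every offset and strand, by direct
    character comparison with early exit.  Returns
    {(region, start, strand, mismatches)} after the best-stratum rule."""
    out = []
    for query, strand in ((read_seq, "+"), (revcomp(read_seq), "-")):
        n = len(query)
        for region, ref in references.items():
            for start in range(len(ref) - n + 1):
                mm = 0
                for a, b in zip(query, ref[start : start + n]):
                    if a != b:
                        mm += 1
                        if mm > max_mismatch:
                            break
                else:
                    out.append((region, start, strand, mm))
    if not out:
        return set()
    best = min(p[3] for p in out)
    return {p for p in out if p[3] == best}


def pairwise_overlap_histogram(hits, reads) -> dict[int, float]:
    """O(n^2) double loop over sense/antisense hit pairs.

    Weight of a pair = product of the two hits' per-hit weights
    (count / n_hits).  Overlap o = antisense 5' - sense 5' + 1.
    """
    sense = [h for h in hits if h.strand == "+"]
    anti = [h for h in hits if h.strand == "-"]
    hist: dict[int, float] = {o: 0.0 for o in range(1, 29)}
    for hs in sense:
        s5 = hs.start
        ws = reads[hs.read_id].count / hs.n_hits_region_set
        for ha in anti:
            a5 = ha.start + ha.length - 1
            o = a5 - s5 + 1
            if 1 <= o <= 28:
                wa = reads[ha.read_id].count / ha.n_hits_region_set
                hist[o] += ws * wa
    return hist


def homogeneous_clone_probability(
    r: float, divisions: int, switch_rate: float
) -> float:
    """P(all leaves of one clone share a state) by enumeration of the
    binary division tree under the stationary-preserving switch chain:
    each daughter redraws Bernoulli(r) with probability ``switch_rate``,
    else inherits."""

    def trans(s: int, s_next: int) -> float:
        p_one = (1 - switch_rate) * s + switch_rate * r
        return p_one if s_next == 1 else 1 - p_one

    total = 0.0
    for target in (0, 1):
        g = {0: 1.0 if target == 0 else 0.0, 1: 1.0 if target == 1 else 0.0}
        for _ in range(divisions):
            g = {
                s: (trans(s, 0) * g[0] + trans(s, 1) * g[1]) ** 2 for s in (0, 1)
            }
        total += (1 - r) * g[0] + r * g[1]
    return total


def enumerate_ovariole_phenotypes(
    p_two_gsc: float, r: float, flipout: float, model: str, n_cysts: int
) -> dict[str, float]:
    """Exact phenotype distribution by summing over every GFP/βGAL
    assignment; mirrors the simulator's generative story but via full
    enumeration rather than sampling."""
    from itertools import product

    def classify(states):
        gfp = {s[0] for s in states}
        bgal = {s[1] for s in states}
        if len(gfp) < 2 or len(bgal) < 2:
            return "uninformative"
        distinct = set(states)
        if len(distinct) == 2:
            return "overlap" if (True, True) in distinct else "exclusion"
        return "mixed3" if len(distinct) == 3 else "mixed4"

    probs: Counter[str] = Counter()
    for n_gsc, p_gsc in ((2, p_two_gsc), (3, 1 - p_two_gsc)):
        if p_gsc == 0:
            continue
        for gfp in product((True, False), repeat=n_gsc):
            p_gfp = 1.0
            for g in gfp:
                p_gfp *= flipout if g else 1 - flipout
            n_slots = n_gsc if model == "lock" else n_gsc * n_cysts
            for bgal in product((True, False), repeat=n_slots):
                p_b = 1.0
                for b in bgal:
                    p_b *= (1 - r) if b else r
                if model == "lock":
                    states = [
                        (gfp[i], bgal[i]) for i in range(n_gsc) for _ in range(n_cysts)
                    ]
                else:
                    states = [
                        (gfp[i], bgal[i * n_cysts + j])
                        for i in range(n_gsc)
                        for j in range(n_cysts)
                    ]
                probs[classify(states)] += p_gsc * p_gfp * p_b
    informative = sum(v for k, v in probs.items() if k != "uninformative")
    out = {
        k: (probs.get(k, 0.0) / informative if informative else 0.0)
        for k in ("overlap", "exclusion", "mixed3", "mixed4")
    }
    out["uninformative"] = probs.get("uninformative", 0.0)
    return out
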