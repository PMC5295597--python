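"""Clonal analysis of variegated silencing.

The observable unit is a gonad (or, in adults, an ovariole): per germ
cell we see a lineage label (GFP, heritable and repression-independent)
and the repression reporter (βGAL expression, i.e. βGAL-positive means
the target is NOT repressed).  Under the lock hypothesis the repression
state of a labelled founder cell is inherited by its whole clone; under
the plastic hypothesis it can change between divisions.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

PHENOTYPES = ("overlap", "exclusion", "mixed3", "mixed4", "uninformative")


@dataclass(frozen=True)
class RepressionTally:
    gonads: int
    total_pgc: int
    gfp_positive: int

    def __post_init__(self) -> None:
        if self.gfp_positive > self.total_pgc:
            raise ValueError("gfp_positive cannot exceed total_pgc")

    @property
    def repressed_percent(self) -> float:
        return repression_percent(self.total_pgc, self.gfp_positive)


def repression_percent(total_pgc: int, gfp_positive: int) -> float:
    """Percent of counted cells with the reporter silenced (GFP-negative)."""
    if total_pgc <= 0:
        raise ValueError("total_pgc must be positive")
    if gfp_positive > total_pgc:
        raise ValueError("gfp_positive cannot exceed total_pgc")
    return 100.0 * (total_pgc - gfp_positive) / total_pgc


@dataclass(frozen=True)
class GonadObservation:
    """Staining outcome of the GFP-labelled cells of one gonad."""

    gonad_id: str
    gfp_pos_cells: int
    bgal_pos_among_gfp: int

    def __post_init__(self) -> None:
        if self.bgal_pos_among_gfp > self.gfp_pos_cells:
            raise ValueError("bgal_pos_among_gfp cannot exceed gfp_pos_cells")


def classify_clone_homogeneity(obs: GonadObservation) -> str:
    """'compatible' iff the labelled cells could derive from homogeneous
    clones: all βGAL-positive, all βGAL-negative, or an exact 50:50 split
    (two labelled founders of opposite state)."""
    if obs.gfp_pos_cells < 1:
        raise ValueError("need at least one GFP-positive cell")
    b, g = obs.bgal_pos_among_gfp, obs.gfp_pos_cells
    if b == 0 or b == g:
        return "compatible"
    if g % 2 == 0 and b == g // 2:
        return "compatible"
    return "incompatible"


def gonad_observations_from_clones(
    clone_table: pd.DataFrame, max_labelled_cells: int | None = None
) -> list[GonadObservation]:
    """Collapse a simulated cell table to per-gonad staining observations.

    Uses only the observable columns (``gfp`` and ``repressed``; βGAL
    positive = not repressed), never the ground-truth clone id.  Gonads
    with no labelled cell are dropped (nothing to stain against), as are
    gonads with more than ``max_labelled_cells`` labelled cells — the
    screen applied experimentally to retain gonads whose label plausibly
    derives from at most two founders.
    """
    out = []
    for gonad_id, grp in clone_table.groupby("gonad_id", sort=True):
        gfp = grp["gfp"].to_numpy(dtype=bool)
        if not gfp.any():
            continue
        if max_labelled_cells is not None and gfp.sum() > max_labelled_cells:
            continue
        bgal = ~grp["repressed"].to_numpy(dtype=bool)
        out.append(
            GonadObservation(str(gonad_id), int(gfp.sum()), int((gfp & bgal).sum()))
        )
    return out


@dataclass(frozen=True)
class PlasticNullParams:
    r: float
    clone_size: int
    n_repressed_clones: int
    n_nonrepressed_clones: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must be in [0, 1]")
        if self.clone_size < 1:
            raise ValueError("clone_size must be positive")
        if min(self.n_repressed_clones, self.n_nonrepressed_clones) < 0:
            raise ValueError("clone counts must be non-negative")


@dataclass(frozen=True)
class PlasticNullResult:
    probability: float
    log10_probability: float


def plastic_null_probability(p: PlasticNullParams) -> PlasticNullResult:
    """P that every cell of g+ clones is repressed and every cell of g-
    clones is not, when cells are independently repressed with
    probability r:  P = (r^k)^g+ * ((1-r)^k)^g-.

    Evaluated in log space so 1e-22-scale values survive; returns the
    probability together with its log10.  Boundary r values with
    conflicting clone counts give probability 0.
    """
    k, gp, gm = p.clone_size, p.n_repressed_clones, p.n_nonrepressed_clones
    log10p = 0.0
    if gp:
        log10p += k * gp * (math.log10(p.r) if p.r > 0 else -math.inf)
    if gm:
        log10p += k * gm * (math.log10(1 - p.r) if p.r < 1 else -math.inf)
    prob = 0.0 if log10p == -math.inf else 10.0**log10p
    return PlasticNullResult(prob, log10p)


def homogeneous_clone_fraction(r: float, clone_size: int) -> float:
    """Closed form under fully independent cell states with marginal r."""
    return r**clone_size + (1 - r) ** clone_size


# ---------------------------------------------------------------------------
# adult ovarioles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OvarioleObservation:
    ovariole_id: str
    egg_chamber_states: tuple[tuple[bool, bool], ...]  # (gfp, bgal) per chamber

    @property
    def phenotype(self) -> str:
        return classify_ovariole(self.egg_chamber_states)


def classify_ovariole(states: Sequence[tuple[bool, bool]]) -> str:
    """Phenotype of one ovariole from its per-chamber (GFP, βGAL) states.

    Informative ovarioles are heterogeneous for BOTH markers; those with
    exactly two distinct states are 'overlap' ({++, --}) or 'exclusion'
    ({+-, -+}), three distinct states 'mixed3', four 'mixed4'.
    """
    if len(states) < 2:
        raise ValueError("need at least two egg chambers")
    gfp = {s[0] for s in states}
    bgal = {s[1] for s in states}
    if len(gfp) < 2 or len(bgal) < 2:
        return "uninformative"
    distinct = {tuple(s) for s in states}
    if len(distinct) == 2:
        return "overlap" if (True, True) in distinct else "exclusion"
    return "mixed3" if len(distinct) == 3 else "mixed4"


def expected_ovariole_distribution(
    p_two_gsc: float,
    r: float,
    flipout: float,
    model: str,
    n_sim: int,
    seed: int = 0,
    n_cysts_per_gsc: int = 3,
) -> dict[str, float]:
    """Monte-Carlo phenotype frequencies among informative ovarioles.

    Each germarium holds 2 GSCs (probability ``p_two_gsc``) or 3.  A GSC
    is GFP-labelled with probability ``flipout`` and βGAL-positive (not
    repressed) with probability ``1 - r``.  Each GSC contributes
    ``n_cysts_per_gsc`` observed egg chambers: under 'lock' they copy the
    GSC's state pair; under 'plastic' the βGAL state of every chamber is
    resampled independently.  Frequencies are over informative ovarioles
    and sum to 1; ``uninformative`` reports its share of all ovarioles.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if model not in ("lock", "plastic"):
        raise ValueError("model must be 'lock' or 'plastic'")
    for name, v in (("p_two_gsc", p_two_gsc), ("r", r), ("flipout", flipout)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tally: Counter[str] = Counter()
    for _ in range(n_sim):
        n_gsc = 2 if rng.random() < p_two_gsc else 3
        gsc_gfp = rng.random(n_gsc) < flipout
        gsc_bgal = rng.random(n_gsc) >= r
        states: list[tuple[bool, bool]] = []
        for i in range(n_gsc):
            for _ in range(n_cysts_per_gsc):
                bgal = gsc_bgal[i] if model == "lock" else bool(rng.random() >= r)
                states.append((bool(gsc_gfp[i]), bool(bgal)))
        tally[classify_ovariole(states)] += 1
    informative = sum(v for k, v in tally.items() if k != "uninformative")
    freqs = {
        k: (tally.get(k, 0) / informative if informative else 0.0)
        for k in ("overlap", "exclusion", "mixed3", "mixed4")
    }
    freqs["uninformative"] = tally.get("uninformative", 0) / n_sim
    return freqs
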