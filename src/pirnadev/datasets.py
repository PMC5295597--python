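"""Bundled reference observation tables for the clonal-memory analysis.

These are the printed tallies from the lineage-tracing experiment the
package models; they serve as worked examples and as inputs to the
acceptance tooling.  βGAL-positive means the silencing target is
expressed (clone NOT repressed).
"""

from __future__ import annotations

from .clonal_memory import GonadObservation, OvarioleObservation

#: mean repression fraction across the scored gonads
REFERENCE_REPRESSION_FRACTION = 0.6647


def l3_single_clone_gonads() -> list[GonadObservation]:
    """10 L3 gonads with exactly eight GFP-labelled cells (one founder):
    3 were 100% βGAL-positive, 7 were 100% βGAL-negative."""
    obs = [GonadObservation(f"single_{i}", 8, 8) for i in range(3)]
    obs += [GonadObservation(f"single_{i}", 8, 0) for i in range(3, 10)]
    return obs


def l3_double_clone_gonads() -> list[GonadObservation]:
    """13 L3 gonads with 9-16 GFP-labelled cells (two founders): 2 all
    βGAL-positive, 4 all βGAL-negative, 5 exact 50:50 splits, plus one
    gonad with 5 positive / 9 negative and one with 2 positive / 8
    negative labelled cells.

    The source reports exact labelled-cell totals only for the last two
    gonads; the others are encoded with 16 labelled cells (two full
    8-cell clones), which does not affect the compatibility call.
    """
    obs = [GonadObservation(f"double_{i}", 16, 16) for i in range(2)]
    obs += [GonadObservation(f"double_{i}", 16, 0) for i in range(2, 6)]
    obs += [GonadObservation(f"double_{i}", 16, 8) for i in range(6, 11)]
    obs.append(GonadObservation("double_11", 14, 5))
    obs.append(GonadObservation("double_12", 10, 2))
    return obs


def l3_all_gonads() -> list[GonadObservation]:
    """All 23 scored L3 gonads (single- plus double-founder)."""
    return l3_single_clone_gonads() + l3_double_clone_gonads()


_PHENOTYPE_STATES = {
    "overlap": ((True, True), (False, False)),
    "exclusion": ((True, False), (False, True)),
    # observed mixed ovarioles carried three states; four-state ovarioles
    # were never seen
    "mixed3": ((True, True), (False, False), (True, False)),
}

#: per-phenotype counts among the 61 doubly heterogeneous adult ovarioles
ADULT_OVARIOLE_TALLY = {"overlap": 28, "exclusion": 11, "mixed3": 22}


def adult_ovariole_observations() -> list[OvarioleObservation]:
    """The 61 adult ovarioles heterogeneous for both GFP and βGAL,
    encoded as minimal state lists realising each reported phenotype."""
    obs = []
    for phenotype, count in ADULT_OVARIOLE_TALLY.items():
        states = _PHENOTYPE_STATES[phenotype]
        for i in range(count):
            obs.append(OvarioleObservation(f"{phenotype}_{i}", states))
    return obs
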