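"""End-to-end orchestration: simulate → trim → align → annotate →
signatures → report, and the clonal pipeline, driven by a plain YAML
config.  Every output carries the seed and a hash of the config so
reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clonal_memory as cm
from . import library_annotation as ann
from . import pirna_signatures as sig
from . import smallrna_io as sio
from . import synthetic_data as syn

log = logging.getLogger("pirnadev")

DEFAULT_SIZE_WINDOWS = {
    "global": (19, 29),
    "u1": (23, 29),
    "rpkm": (23, 29),
    "pingpong": (23, 28),
}


@dataclass
class RunConfig:
    """Validated run parameters; see ``RunConfig.from_yaml``."""

    seed: int = 0
    outdir: str = "pirnadev_out"
    genome: dict = field(default_factory=dict)
    libraries: dict = field(default_factory=dict)
    normalization: str = "depth"
    pseudocount: float = 1.0
    control_library: str | None = None
    test_library: str | None = None
    te_set: dict = field(default_factory=lambda: {"n_te": 6, "length": 1000})
    size_windows: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_WINDOWS))
    clonal: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.normalization not in ("depth", "mirna"):
            raise ValueError("normalization must be 'depth' or 'mirna'")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        windows = dict(DEFAULT_SIZE_WINDOWS)
        windows.update({k: tuple(v) for k, v in self.size_windows.items()})
        self.size_windows = windows
        g_lo, g_hi = windows["global"]
        for name, (lo, hi) in windows.items():
            if not (19 <= lo <= hi <= 29 and g_lo <= lo and hi <= g_hi):
                raise ValueError(f"size window {name!r} not nested within 19..29")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known, raw=data)

    @property
    def config_hash(self) -> str:
        payload = self.raw or {
            k: v for k, v in self.__dict__.items() if k != "raw"
        }
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _header_lines(config: RunConfig) -> str:
    return f"# seed={config.seed}\n# config={config.config_hash}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=False)


def _write_json(obj, path: Path, config: RunConfig) -> None:
    wrapped = {"seed": config.seed, "config": config.config_hash, "data": obj}
    path.write_text(json.dumps(wrapped, indent=2, sort_keys=True) + "\n")


def _build_genome(config: RunConfig) -> syn.ToyGenome:
    regions = tuple(
        syn.RegionSpec(r["name"], int(r["length"]), r.get("role", "other"))
        for r in config.genome.get(
            "regions",
            [
                {"name": "cluster", "length": 5000, "role": "dual_strand_cluster"},
                {"name": "subtelomere", "length": 2000, "role": "subtelomere"},
                {"name": "transgene", "length": 1500, "role": "transgene"},
            ],
        )
    )
    spec = syn.ToyGenomeSpec(
        regions, float(config.genome.get("gc_fraction", 0.45)), config.seed
    )
    return syn.make_toy_genome(spec)


def _library_spec(name: str, params: Mapping, config: RunConfig) -> syn.PiRnaLibrarySpec:
    allowed = {
        "n_reads",
        "size_dist",
        "pingpong_fraction",
        "u1_bias",
        "antisense_fraction",
        "contaminant_fractions",
        "multimap_rate",
        "depletion",
        "adapter",
    }
    kwargs = {k: v for k, v in params.items() if k in allowed}
    if "size_dist" in kwargs:
        kwargs["size_dist"] = {int(k): float(v) for k, v in kwargs["size_dist"].items()}
    # per-library seed derived deterministically from the global seed
    offset = int(hashlib.sha256(name.encode()).hexdigest()[:8], 16)
    return syn.PiRnaLibrarySpec(seed=config.seed + offset, **kwargs)


def run_signature_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full small-RNA analysis; returns the result bundle and
    writes TSV/JSON tables plus a Markdown report under ``outdir``."""
    if not config.libraries:
        raise ValueError("config defines no libraries")
    for role, name in (("control", config.control_library), ("test", config.test_library)):
        if name is not None and name not in config.libraries:
            raise ValueError(f"{role} library {name!r} not defined under libraries")

    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    genome = _build_genome(config)
    annotations = syn.make_annotation_references(config.seed)
    te_refs = syn.make_te_references(
        config.seed,
        int(config.te_set.get("n_te", 6)),
        int(config.te_set.get("length", 1000)),
    )
    region_lengths = {name: len(seq) for name, seq in genome.items()}
    g_lo, g_hi = config.size_windows["global"]

    bundle: dict = {"libraries": {}, "genome_regions": region_lengths}
    stats_by_lib: dict[str, ann.LibraryStats] = {}
    intermediates: dict[str, dict] = {}

    for name, params in config.libraries.items():
        if "fastq" in params:
            raw_reads = sio.read_fastq(params["fastq"])
            adapter = params.get("adapter", syn.DEFAULT_ADAPTER)
            log.info("library %s: %d raw reads from %s", name, len(raw_reads), params["fastq"])
        else:
            spec = _library_spec(name, params, config)
            records, truth = syn.simulate_library(genome, spec, annotations)
            syn.write_fastq(records, out / f"{name}.fastq")
            _write_tsv(truth, out / f"{name}.truth.tsv", config)
            raw_reads = [(r.read_id, r.sequence) for r in records]
            adapter = spec.adapter
            log.info("library %s: simulated %d reads", name, len(raw_reads))

        inserts = []
        for _, seq in raw_reads:
            trimmed = sio.trim_adapter(seq, adapter, min_len=g_lo, max_len=g_hi)
            if trimmed:
                inserts.append(trimmed.insert)
        log.info("library %s: %d/%d reads pass trim+filter", name, len(inserts), len(raw_reads))
        reads = sio.collapse_reads(inserts, id_prefix=name)
        read_map = {r.read_id: r for r in reads}

        stats, _categories = ann.annotate_library(
            name, reads, genome, annotations, te_refs
        )
        stats_by_lib[name] = stats
        genome_hits = sio.match_reads(reads, genome)
        te_hits = sio.match_reads(reads, te_refs)
        sio.write_sam(genome_hits, read_map, genome, out / f"{name}.sam")
        intermediates[name] = {
            "reads": read_map,
            "genome_hits": genome_hits,
            "te_hits": te_hits,
        }

    ann.normalization_factors(list(stats_by_lib.values()))

    for name, inter in intermediates.items():
        stats = stats_by_lib[name]
        factor = (
            stats.norm_factor_mirna
            if config.normalization == "mirna"
            else stats.norm_factor_depth
        )
        if factor is None:
            raise ValueError(
                f"library {name!r}: miRNA normalization factor unusable "
                f"(miRNA fraction {stats.mirna_fraction:.3f})"
            )
        reads = inter["reads"]
        genome_hits = inter["genome_hits"]

        coverage = sig.weighted_coverage(genome_hits, reads, region_lengths, factor)
        _write_tsv(sig.coverage_to_bedgraph(coverage), out / f"{name}.coverage.tsv", config)

        signatures = {}
        for region in genome:
            size_df = sig.size_distribution(
                genome_hits, reads, region, config.size_windows["global"], factor
            )
            _write_tsv(
                size_df.reset_index(), out / f"{name}.sizes.{region}.tsv", config
            )
            hist = sig.pingpong_signature(
                genome_hits, reads, region, config.size_windows["pingpong"], factor
            )
            signatures[region] = {
                "u1_fraction": sig.u1_bias(
                    genome_hits, reads, region, config.size_windows["u1"]
                ),
                "overlap_hist": hist.tolist(),
                "pingpong_zscore": sig.pingpong_zscore(hist),
            }
        _write_json(signatures, out / f"{name}.signatures.json", config)

        te_table = sig.te_antisense_rpkm(
            inter["te_hits"],
            reads,
            {n: len(s) for n, s in te_refs.items()},
            factor,
            stats.effective_depth,
            config.size_windows["rpkm"],
        )
        _write_tsv(te_table, out / f"{name}.te_rpkm.tsv", config)

        bundle["libraries"][name] = {
            "stats": {
                "total_genome_matched": stats.total_genome_matched,
                "per_category": stats.per_category,
                "unmatched": stats.unmatched,
                "effective_depth": stats.effective_depth,
                "norm_factor_depth": stats.norm_factor_depth,
                "norm_factor_mirna": stats.norm_factor_mirna,
            },
            "signatures": signatures,
            "te_rpkm": te_table,
        }

    if config.control_library and config.test_library:
        scatter = sig.glkd_scatter(
            bundle["libraries"][config.control_library]["te_rpkm"],
            bundle["libraries"][config.test_library]["te_rpkm"],
            config.pseudocount,
        )
        _write_tsv(scatter, out / "glkd_scatter.tsv", config)
        bundle["glkd_scatter"] = scatter

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash,
        "normalization": config.normalization,
        "pseudocount": config.pseudocount,
        "size_windows": {k: list(v) for k, v in config.size_windows.items()},
        "libraries": list(config.libraries),
    }
    _write_json(manifest, out / "manifest.json", config)
    _write_report(bundle, config, out / "report.md")
    return bundle


def _write_report(bundle: dict, config: RunConfig, path: Path) -> None:
    lines = [
        "# Small-RNA signature report",
        "",
        f"- seed: {config.seed}",
        f"- config: {config.config_hash}",
        f"- normalization: {config.normalization}",
        "",
    ]
    for name, lib in bundle["libraries"].items():
        s = lib["stats"]
        lines += [
            f"## Library {name}",
            "",
            f"- matched reads: {s['total_genome_matched']} "
            f"(effective depth {s['effective_depth']})",
            f"- depth factor: {s['norm_factor_depth']:.4f}",
            "",
            "| region | 1U fraction | ping-pong z |",
            "|---|---|---|",
        ]
        for region, sg in lib["signatures"].items():
            u1 = "n/a" if sg["u1_fraction"] is None else f"{sg['u1_fraction']:.3f}"
            z = "n/a" if sg["pingpong_zscore"] is None else f"{sg['pingpong_zscore']:.2f}"
            lines.append(f"| {region} | {u1} | {z} |")
        lines.append("")
    path.write_text("\n".join(lines) + "\n")


def run_clonal_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Classify gonad observations (given or simulated) and evaluate the
    plastic-repression null for the homogeneous-clone tally."""
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.clonal
    clone_size = int(cfg.get("clone_size", 8))
    r = float(cfg.get("r", 0.6647))

    if "observations" in cfg:
        table = pd.read_csv(cfg["observations"], sep="\t", comment="#")
        if table.empty:
            raise ValueError("empty observation table")
        observations = [
            cm.GonadObservation(
                str(row.gonad_id), int(row.gfp_pos_cells), int(row.bgal_pos_among_gfp)
            )
            for row in table.itertuples()
        ]
    elif "simulate" in cfg:
        allowed = {
            "n_gonads", "r", "model", "pgc_init", "divisions",
            "switch_rate", "flipout_prob",
        }
        params = {k: v for k, v in cfg["simulate"].items() if k in allowed}
        spec = syn.CloneSimSpec(seed=config.seed, **params)
        clone_table = syn.simulate_clones(spec)
        _write_tsv(clone_table, out / "clones.truth.tsv", config)
        clone_size = 2**spec.divisions  # progeny of one labelled founder
        # keep gonads whose label is consistent with <= 2 founders,
        # mirroring the experimental screen
        observations = cm.gonad_observations_from_clones(
            clone_table, max_labelled_cells=2 * clone_size
        )
        r = spec.r
    else:
        raise ValueError("clonal config needs 'observations' or 'simulate'")
    if not observations:
        raise ValueError("no scorable gonads")

    rows = []
    for obs in observations:
        rows.append(
            {
                "gonad_id": obs.gonad_id,
                "gfp_pos_cells": obs.gfp_pos_cells,
                "bgal_pos_among_gfp": obs.bgal_pos_among_gfp,
                "classification": cm.classify_clone_homogeneity(obs),
            }
        )
    table = pd.DataFrame(rows)
    _write_tsv(table, out / "clone_classification.tsv", config)

    compatible = (table["classification"] == "compatible").mean()
    g_plus = sum(
        1
        for o in observations
        if o.gfp_pos_cells == clone_size and o.bgal_pos_among_gfp == 0
    )
    g_minus = sum(
        1
        for o in observations
        if o.gfp_pos_cells == clone_size and o.bgal_pos_among_gfp == o.gfp_pos_cells
    )
    null = cm.plastic_null_probability(
        cm.PlasticNullParams(r, clone_size, g_plus, g_minus)
    )
    summary = {
        "n_gonads": len(observations),
        "compatible_fraction": float(compatible),
        "compatible_percent": float(100 * compatible),
        "clone_size": clone_size,
        "r": r,
        "n_repressed_clones": g_plus,
        "n_nonrepressed_clones": g_minus,
        "plastic_null_probability": null.probability,
        "plastic_null_log10": null.log10_probability,
    }
    _write_json(summary, out / "clonal_summary.json", config)
    return {"classification": table, "summary": summary}
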