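"""Reproducible end-to-end runs: config, stage orchestration, manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .antigen import ANTIGEN_LOCAL, ReferenceAntigen, ResidueSpan, load_reference
from .enrichment import LibraryCounts, call_significant, enrichment_factor, rank_fragments
from .frames import classify_library
from .hotspots import call_hotspots, candidate_required_region
from .io import (iter_reads, write_classification_tsv, write_hotspots_tsv,
                 write_profile_tsv, write_ranked_fragments_tsv)
from .simulate import SimConfig, simulate_library, simulate_selection, synthetic_reference, write_fastq, write_truth_tsv

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Everything a run needs; every stage parameter has a default.

    The ``reference`` block either names files (``cds_fasta`` plus optional
    ``protein_fasta`` / ``annotations_tsv`` / ``numbering_offset``) or asks
    for a synthetic one (``synthetic: true`` with optional ``n_residues``).
    The ``simulate`` block, when present, generates the read sets; otherwise
    ``reads.unselected`` / ``reads.selected`` must point at FASTA/FASTQ
    files.
    """

    outdir: str
    seed: int = 0
    log_level: str = "INFO"
    reference: dict = field(default_factory=dict)
    simulate: dict | None = None
    reads: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)  # max_mismatch, min_match_len, ...
    enrich: dict = field(default_factory=dict)  # pseudocount, top_n, depth_normalize
    hotspot: dict = field(default_factory=dict)  # k_mad, min_separation, mode

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ConfigError("config must set 'outdir'")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        if not self.reference:
            raise ConfigError("config must define a 'reference' block")
        if not self.reference.get("synthetic") and "cds_fasta" not in self.reference:
            raise ConfigError("reference block needs 'cds_fasta' (or synthetic: true)")
        if self.simulate is None:
            for key in ("unselected", "selected"):
                if key not in self.reads:
                    raise ConfigError(
                        f"no 'simulate' block: reads.{key} must name a read file"
                    )


def _build_reference(cfg: RunConfig) -> ReferenceAntigen:
    ref_cfg = dict(cfg.reference)
    if ref_cfg.pop("synthetic", False):
        return synthetic_reference(
            n_residues=ref_cfg.get("n_residues", 438),
            numbering_offset=ref_cfg.get("numbering_offset", 183),
            seed=ref_cfg.get("seed", cfg.seed),
        )
    return load_reference(
        ref_cfg["cds_fasta"],
        protein_file=ref_cfg.get("protein_fasta"),
        annotations=ref_cfg.get("annotations_tsv"),
        numbering_offset=ref_cfg.get("numbering_offset", 0),
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_span(item) -> ResidueSpan:
    start, end = item["start"], item["end"]
    system = item.get("coordinate_system", ANTIGEN_LOCAL)
    return ResidueSpan(start, end, system)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute classify -> enrich -> hotspots (plus optional simulate).

    Writes all stage outputs and a machine-readable ``manifest.json`` into
    ``cfg.outdir``; identical config + seed gives identical outputs.  The
    run directory is write-once: an existing manifest aborts the run.
    Returns the manifest dictionary.
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest_path = os.path.join(cfg.outdir, "manifest.json")
    if os.path.exists(manifest_path):
        raise ConfigError(f"refusing to overwrite completed run in {cfg.outdir}")
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
        "inputs": {},
    }

    def out(name: str) -> str:
        return os.path.join(cfg.outdir, name)

    try:
        ref = _build_reference(cfg)
        if "cds_fasta" in cfg.reference:
            manifest["inputs"]["cds_fasta"] = _sha256(cfg.reference["cds_fasta"])

        # ---- simulate (optional) ------------------------------------------
        if cfg.simulate is not None:
            sim_kwargs = dict(cfg.simulate)
            sets = [_parse_span(s) for s in sim_kwargs.pop("epitope_required_sets", [])]
            if "fragment_length_range" in sim_kwargs:
                sim_kwargs["fragment_length_range"] = tuple(
                    sim_kwargs["fragment_length_range"])
            sim_cfg = SimConfig(ref=ref, seed=cfg.seed,
                                epitope_required_sets=sets, **sim_kwargs)
            lib_reads, truth = simulate_library(sim_cfg)
            sel_reads, round_counts = simulate_selection(truth, sim_cfg)
            write_fastq(lib_reads, out("unselected.fastq"))
            write_fastq(sel_reads, out("selected.fastq"))
            write_truth_tsv(truth, out("truth.tsv"))
            unselected_reads, selected_reads = lib_reads, sel_reads
            manifest["stages"]["simulate"] = {
                "n_clones": sim_cfg.n_clones,
                "n_binders": truth.n_binders,
                "rounds": len(round_counts),
            }
        else:
            unselected_reads = list(iter_reads(cfg.reads["unselected"]))
            selected_reads = list(iter_reads(cfg.reads["selected"]))
            manifest["inputs"]["unselected"] = _sha256(cfg.reads["unselected"])
            manifest["inputs"]["selected"] = _sha256(cfg.reads["selected"])

        # ---- classify ------------------------------------------------------
        flanks = None
        if cfg.simulate is not None:
            flanks = SimConfig(ref=ref).flanks
        elif "flanks" in cfg.reads:
            flanks = tuple(cfg.reads["flanks"])
        libs = {}
        for lib_id, reads in (("unselected", unselected_reads),
                              ("selected", selected_reads)):
            frags, summary = classify_library(
                reads, ref, vector_flanks=flanks,
                source_library=lib_id, **cfg.classify)
            write_classification_tsv(frags, out(f"classified_{lib_id}.tsv"))
            libs[lib_id] = LibraryCounts.from_fragments(frags, lib_id)
            manifest["stages"][f"classify_{lib_id}"] = summary.to_dict()

        # ---- enrich --------------------------------------------------------
        enrich_cfg = dict(cfg.enrich)
        top_n = enrich_cfg.pop("top_n", 30)
        profile = enrichment_factor(libs["selected"], libs["unselected"], ref,
                                    **enrich_cfg)
        write_profile_tsv(profile, out("profile.tsv"))
        ranked = rank_fragments(libs["selected"], top_n=top_n,
                                unsel=libs["unselected"])
        write_ranked_fragments_tsv(ranked, out("ranked_fragments.tsv"), ref)
        significant = [c for c in call_significant(libs["selected"],
                                                   libs["unselected"])
                       if c.significant]
        manifest["stages"]["enrich"] = {
            "pseudocount": profile.pseudocount,
            "top_n": top_n,
            "n_unique_selected": len(libs["selected"].fragment_counts),
            "n_significant": len(significant),
        }

        # ---- hotspots ------------------------------------------------------
        calls = call_hotspots(profile, **cfg.hotspot)
        regions = [candidate_required_region(c, profile) for c in calls]
        write_hotspots_tsv(calls, regions, out("hotspots.tsv"))
        manifest["stages"]["hotspots"] = {
            "params": {"k_mad": cfg.hotspot.get("k_mad", 7.0),
                       "min_separation": cfg.hotspot.get("min_separation", 5),
                       "mode": cfg.hotspot.get("mode", "log_ratio")},
            "boundaries": [c.boundary for c in calls],
        }
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    _write_summary(manifest, out("summary.txt"))
    return manifest


def _write_summary(manifest: dict, path: str) -> None:
    lines = [f"phagemap {manifest['package_version']} run (seed {manifest['seed']})"]
    for stage, info in manifest["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
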