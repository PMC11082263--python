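"""End-to-end orchestration: validated run configuration, the packaged
GUIDE-seq scenarios, and the simulate -> classify -> stats -> off-target
pipeline with versioned, reproducible outputs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__, io, offtarget
from .classify import ClassifyContext, classify_table, indel_frequency
from .simulate import (
    DSODN,
    HDR_INSERT,
    load_guideseq_scenarios,
    load_profiles,
    make_demo_site,
    plant_offtargets,
    simulate_alleles,
    simulate_guideseq_reads,
)
from .site_model import protospacer_seq

__all__ = ["RunConfig", "run_pipeline", "run_guideseq_scenario", "child_seed"]


def child_seed(seed: int, stream: int) -> int:
    """Deterministic per-stage child seed (< 2**31) from a master seed."""
    return int(np.random.SeedSequence([int(seed), int(stream)]).generate_state(1)[0] % (2**31))


_ALLOWED_KEYS = {
    "seed",
    "profile",
    "n_reads",
    "window",
    "hdr_insert",
    "dsodn",
    "guideseq_scenario",
    "genome_len",
    "cluster_window",
    "max_mismatches",
    "search_radius",
    "dsodn_match_length",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (YAML-loadable). Unknown keys are
    rejected; thresholds must be positive."""

    seed: int = 0
    profile: str = "spcas9_like"
    n_reads: int = 5000
    window: int = 10
    hdr_insert: Optional[str] = HDR_INSERT
    dsodn: Optional[str] = DSODN
    guideseq_scenario: Optional[str] = "spcas9_like"
    genome_len: int = 100_000
    cluster_window: int = 25
    max_mismatches: int = 6
    search_radius: int = 25
    dsodn_match_length: int = 20

    def __post_init__(self):
        for key in ("n_reads", "window", "genome_len", "cluster_window", "search_radius", "dsodn_match_length"):
            if getattr(self, key) <= 0:
                raise ValueError(f"config: {key} must be positive")
        if self.max_mismatches < 0:
            raise ValueError("config: max_mismatches must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path}: expected a mapping")
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dict(vars(self))


def run_guideseq_scenario(
    scenario: str | dict,
    spacer: str,
    seed: int = 0,
    genome_len: int = 100_000,
    pam_pattern: str = "NNGRRT",
    max_mismatches: int = 6,
):
    """Plant a scenario's sites, simulate junction reads, and run the full
    off-target stage. Returns (sites, OffIndexResult, n_reads)."""
    sc = load_guideseq_scenarios()[scenario] if isinstance(scenario, str) else scenario
    mm = [0] + list(sc["off_mismatches"])
    weights = [float(sc["on_weight"])] + [float(w) for w in sc["off_weights"]]
    planted = plant_offtargets(
        spacer,
        pam_pattern=pam_pattern,
        mismatch_counts=mm,
        weights=weights,
        genome_len=genome_len,
        seed=child_seed(seed, 11),
    )
    reads = simulate_guideseq_reads(planted, seed=child_seed(seed, 12))
    sites = offtarget.identify_sites(
        {planted.name: planted.genome},
        reads,
        spacer,
        DSODN,
        max_mm=max_mismatches,
        on_target=(planted.name, planted.on_target.cut),
    )
    return sites, offtarget.off_index(sites), len(reads)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute simulate -> classify -> stats -> off-target as configured and
    write versioned outputs, a log, and the resolved configuration.

    Outputs are byte-identical for identical (config, seed).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"casedit {__version__}"]

    profiles = load_profiles()
    if config.profile not in profiles:
        raise ValueError(f"config: unknown profile {config.profile!r}")
    profile = profiles[config.profile]

    site = make_demo_site("SpCas9", seed=child_seed(config.seed, 1))
    io.write_fasta(out / "amplicon.fa", {"amplicon": site.amplicon})
    io.write_site_table([site], out / "sites.tsv")
    log.append(f"site: cut_index={site.cut_index} protospacer={protospacer_seq(site)}")

    alleles = simulate_alleles(
        site,
        profile,
        config.n_reads,
        seed=child_seed(config.seed, 2),
        hdr_insert=config.hdr_insert or HDR_INSERT,
        dsodn=config.dsodn or DSODN,
        window=config.window,
    )
    io.write_allele_table(alleles, out / "alleles.tsv")
    log.append(f"simulated {config.n_reads} reads, {len(alleles)} distinct alleles")

    ctx = ClassifyContext(
        hdr_insert=config.hdr_insert,
        dsodn=config.dsodn,
        window=config.window,
        dsodn_min_match=config.dsodn_match_length,
    )
    table = classify_table(site, alleles, ctx)
    io.write_tsv(table.per_allele, out / "classified.tsv")
    summary = {
        "profile": config.profile,
        "total_reads": table.total_reads,
        "edited_reads": table.edited_reads,
        "indel_frequency": indel_frequency(table),
        "relative_frequencies": {c.value: f for c, f in table.relative_frequencies.items()},
    }
    log.append(f"indel frequency {summary['indel_frequency']:.4f}")

    if config.guideseq_scenario:
        spacer = protospacer_seq(site)
        sites, result, n_reads = run_guideseq_scenario(
            config.guideseq_scenario,
            spacer,
            seed=config.seed,
            genome_len=config.genome_len,
            max_mismatches=config.max_mismatches,
        )
        io.write_tsv(io.offtarget_table(sites), out / "offtarget_sites.tsv")
        (out / "offtarget_report.txt").write_text(
            offtarget.render_report(sites, spacer) + "\n"
        )
        summary["guideseq"] = {
            "scenario": config.guideseq_scenario,
            "n_reads": n_reads,
            "n_sites": len(sites),
            "on_reads": result.on_reads,
            "off_reads_total": result.off_reads_total,
            "off_index": result.off_index,
        }
        log.append(f"off-index {result.off_index:.4f} over {len(sites)} sites")

    io.write_json(summary, out / "summary.json")
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out
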