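"""End-to-end orchestration: simulate -> screen -> design -> diagnose ->
date -> validate, with a single TOML config, seeded reproducibility and a
run manifest of output checksums.

Rerunning a stage with the same config and seed reproduces byte-identical
TSV/FASTA outputs; the manifest records the seed, a hash of the resolved
configuration, and a SHA-256 checksum per output file so reruns can be
verified without diffing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clock import ClockRateRange, DivergenceEstimate
from .diagnostics import design_diagnostic_primers, global_align, in_silico_pcr
from .primers import (
    DesignConstraints,
    PairSearchResult,
    enumerate_candidate_pairs,
    multiplex_compatible,
    pairs_to_frame,
)
from .screen import ScreenConfig, select_candidates
from .simulate import (
    PoolDesign,
    cohort_to_frame,
    replica_cohort,
    simulate_count_matrix,
    simulate_ortholog_pair,
    simulate_transcriptome,
    simulate_validation_cohort,
    transcripts_to_fasta,
    truth_table,
)
from .validate import concordance_report

logger = logging.getLogger("zwscreen")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run."""

    seed: int = 0
    outdir: str = "zwscreen_run"
    log_level: str = "INFO"
    # simulator
    n_transcripts: int = 1000
    class_proportions: dict | None = None
    length_range: tuple[int, int] = (600, 2400)
    design: PoolDesign = field(default_factory=PoolDesign)
    # screen
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    # primer design
    constraints: DesignConstraints = field(default_factory=DesignConstraints)
    n_templates_for_primers: int = 3
    control_product_bp: int = 259
    min_separation_bp: int = 40
    # species diagnostics
    ortholog_length: int = 1000
    ortholog_divergence: float = 0.05
    min_differences: int = 2
    # clock worked inputs: (locus, n_diff, n_sites, fast, slow)
    clock_inputs: list = field(
        default_factory=lambda: [
            ("cytochrome_b", 41, 876, 0.0076, 0.0036),
            ("control_region", 6, 396, 0.044, 0.004),
        ]
    )
    # validation
    cohort: str = "replica"  # 'replica' or 'simulated'
    n_per_group: dict | None = None
    sex_reversal_rate: float = 0.0

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                d = asdict(o)
                d.pop("exclusion_list", None)
                return d
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)

        payload = asdict(self)
        payload.pop("outdir", None)  # where outputs land does not change them
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path, seed: int | None = None, outdir: str | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a TOML file; CLI seed/outdir override it."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = PipelineConfig()
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.outdir = raw.get("outdir", cfg.outdir)
    cfg.log_level = raw.get("log_level", cfg.log_level)
    sim = raw.get("simulate", {})
    cfg.n_transcripts = int(sim.get("n_transcripts", cfg.n_transcripts))
    if "class_proportions" in sim:
        cfg.class_proportions = dict(sim["class_proportions"])
    if "length_range" in sim:
        cfg.length_range = tuple(sim["length_range"])
    design_kw = {
        k: sim[k]
        for k in (
            "n_female_pools", "n_male_pools", "fish_per_pool",
            "target_library_size", "library_size_cv",
            "dispersion_log_mean", "dispersion_log_sd",
        )
        if k in sim
    }
    cfg.design = PoolDesign(seed=cfg.seed, **design_kw)
    scr = raw.get("screen", {})
    cfg.screen = ScreenConfig(
        **{
            k: (frozenset(v) if k == "exclusion_list" else v)
            for k, v in scr.items()
        }
    )
    if "primers" in raw:
        prm = dict(raw["primers"])
        cfg.control_product_bp = prm.pop("control_product_bp", cfg.control_product_bp)
        cfg.min_separation_bp = prm.pop("min_separation_bp", cfg.min_separation_bp)
        cfg.n_templates_for_primers = prm.pop(
            "n_templates", cfg.n_templates_for_primers
        )
        cfg.constraints = DesignConstraints(**prm)
    diag = raw.get("diagnostic", {})
    cfg.ortholog_length = int(diag.get("ortholog_length", cfg.ortholog_length))
    cfg.ortholog_divergence = float(diag.get("divergence", cfg.ortholog_divergence))
    cfg.min_differences = int(diag.get("min_differences", cfg.min_differences))
    if "clock" in raw and "loci" in raw["clock"]:
        cfg.clock_inputs = [
            (d["locus"], d["n_differences"], d["n_sites"], d["rate_fast"], d["rate_slow"])
            for d in raw["clock"]["loci"]
        ]
    val = raw.get("validate", {})
    cfg.cohort = val.get("cohort", cfg.cohort)
    if "n_per_group" in val:
        cfg.n_per_group = {
            (d["population"], d["sex"]): d["n"] for d in val["n_per_group"]
        }
    cfg.sex_reversal_rate = float(val.get("sex_reversal_rate", cfg.sex_reversal_rate))
    if seed is not None:
        cfg.seed = seed
        cfg.design = PoolDesign(**{**asdict(cfg.design), "seed": seed})
    if outdir is not None:
        cfg.outdir = outdir
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run all stages in order; returns the manifest (also written to disk).

    Any stage failure aborts the run with a stage-named error; outputs of
    completed stages are retained and a ``FAILED`` marker file names the
    failing stage.
    """
    cfg = config or PipelineConfig()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outputs: dict[str, list[str]] = {}
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("screen", _stage_screen),
        ("design-primers", _stage_primers),
        ("design-diagnostic", _stage_diagnostic),
        ("insilico-pcr", _stage_insilico),
        ("clock", _stage_clock),
        ("validate", _stage_validate),
    ]
    for name, fn in stages:
        logger.info("stage %s", name)
        try:
            outputs[name] = [str(p.relative_to(outdir)) for p in fn(cfg, outdir, state)]
        except Exception as exc:  # noqa: BLE001 - stage-named abort contract
            (outdir / "FAILED").write_text(f"{name}: {exc}\n")
            raise StageError(name, exc) from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": outputs,
        "checksums": {
            rel: _sha256(outdir / rel) for rels in outputs.values() for rel in rels
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    transcripts = simulate_transcriptome(
        cfg.n_transcripts,
        cfg.class_proportions,
        cfg.length_range,
        seed=cfg.seed,
        design=cfg.design,
    )
    matrix = simulate_count_matrix(transcripts, cfg.design)
    state["transcripts"] = transcripts
    state["matrix"] = matrix
    fasta = outdir / "transcripts.fasta"
    transcripts_to_fasta(transcripts, fasta)
    truth = outdir / "truth_table.tsv"
    truth_table(transcripts).to_csv(truth, sep="\t", index=False)
    counts = outdir / "counts.tsv"
    pools = outdir / "pools.tsv"
    matrix.to_tsv(counts, pools)
    return [fasta, truth, counts, pools]


def _stage_screen(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    results = select_candidates(state["matrix"], cfg.screen)
    state["screen_results"] = results
    out = outdir / "candidates.tsv"
    results.to_tsv(out)
    (outdir / "screen_summary.txt").write_text(results.summary() + "\n")
    return [out, outdir / "screen_summary.txt"]


def _stage_primers(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    by_id = {t.transcript_id: t for t in state["transcripts"]}
    candidates = state["screen_results"].candidates
    frames = []
    chosen_products: list[int] = []
    for cid in candidates["contig_id"].head(cfg.n_templates_for_primers):
        result = enumerate_candidate_pairs(by_id[cid].sequence, cfg.constraints)
        df = pairs_to_frame(result)
        df.insert(0, "contig_id", cid)
        frames.append(df)
        if result.pairs:
            chosen_products.append(result.pairs[0].product_bp)
    pairs_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pairs_to_frame(PairSearchResult()).assign(contig_id=[])
    )
    out = outdir / "primer_pairs.tsv"
    pairs_df.to_csv(out, sep="\t", index=False)
    ok, conflicts = multiplex_compatible(
        chosen_products, cfg.control_product_bp, cfg.min_separation_bp
    )
    (outdir / "multiplex_check.json").write_text(
        json.dumps(
            {
                "control_product_bp": cfg.control_product_bp,
                "candidate_products": chosen_products,
                "compatible": ok,
                "conflicts": conflicts,
            },
            indent=2,
        )
    )
    return [out, outdir / "multiplex_check.json"]


def _stage_diagnostic(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    template = state["transcripts"][0].sequence[: cfg.ortholog_length]
    seq_a, seq_b, positions = simulate_ortholog_pair(
        template, cfg.ortholog_divergence, seed=cfg.seed
    )
    alignment = global_align(seq_a, seq_b)
    design = design_diagnostic_primers(
        alignment, min_differences=cfg.min_differences, constraints=cfg.constraints
    )
    state["ortholog"] = (seq_a, seq_b, positions)
    state["diagnostic"] = design
    rows = []
    for pair in design.pairs[:50]:
        for role, p in (("forward", pair.forward), ("reverse", pair.reverse)):
            rows.append(
                {
                    "rank": design.pairs.index(pair) + 1,
                    "role": role,
                    "sequence": p.sequence,
                    "window_start_1based": p.window_start + 1,
                    "window_end_1based": p.window_end + 1,
                    "n_differences": p.n_differences_covered,
                    "tm_on_target": round(p.tm_on_target, 2),
                    "tm_off_target": round(p.tm_off_target, 2),
                    "delta_tm": round(p.delta_tm, 2),
                }
            )
    out = outdir / "diagnostic_primers.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return [out]


def _stage_insilico(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    seq_a, seq_b, _ = state["ortholog"]
    design = state["diagnostic"]
    rows = []
    if design.pairs:
        top = design.pairs[0]
        for species, template in (("target", seq_a), ("off_target", seq_b)):
            for amp in in_silico_pcr(template, top.forward.sequence, top.reverse.sequence):
                rows.append(
                    {
                        "species": species,
                        "start_1based": amp.start_1based,
                        "end_1based": amp.end_1based,
                        "product_bp": amp.product_bp,
                        "strand": amp.strand,
                    }
                )
    out = outdir / "amplicons.tsv"
    pd.DataFrame(
        rows, columns=["species", "start_1based", "end_1based", "product_bp", "strand"]
    ).to_csv(out, sep="\t", index=False)
    return [out]


def _stage_clock(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    rows = []
    for locus, n_diff, n_sites, fast, slow in cfg.clock_inputs:
        est = DivergenceEstimate.from_counts(
            n_diff, n_sites, ClockRateRange(locus, fast, slow)
        )
        rows.append(
            {
                "locus": locus,
                "n_differences": est.n_differences,
                "n_sites": est.n_sites,
                "p_distance": est.p_distance,
                "percent": est.percent,
                "t_min_myr": est.t_min_myr,
                "t_max_myr": est.t_max_myr,
            }
        )
    out = outdir / "divergence.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return [out]


def _stage_validate(cfg: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    if cfg.cohort == "replica":
        cohort = replica_cohort()
    else:
        groups = cfg.n_per_group or {
            ("popA", "F"): 30, ("popA", "M"): 30,
            ("popB", "F"): 30, ("popB", "M"): 25,
        }
        cohort = simulate_validation_cohort(
            groups, cfg.sex_reversal_rate, seed=cfg.seed
        )
    report = concordance_report(cohort)
    cohort_tsv = outdir / "cohort.tsv"
    cohort_to_frame(cohort).to_csv(cohort_tsv, sep="\t", index=False)
    report_tsv = outdir / "concordance.tsv"
    report.to_tsv(report_tsv)
    report_json = outdir / "concordance.json"
    report_json.write_text(report.to_json())
    return [cohort_tsv, report_tsv, report_json]
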