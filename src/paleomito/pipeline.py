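"""End-to-end orchestration: simulate -> trim -> map -> dedup -> damage ->
consensus -> diagnose -> assign -> network, with a machine-readable report.

A single global seed fans out to per-stage seeds by stable derivation
(``numpy.random.SeedSequence([seed, stage_index])``), so individual stages are
reproducible in isolation and two runs with identical config produce identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import consensus as cns
from . import damage as dmg
from . import diagnostics as diag
from . import mapping as mp
from . import readqc
from . import sim
from .network import collapse_haplotypes, median_joining
from .seqs import write_fasta, write_fastq

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("paleomito")

_STAGES = (
    "simulate",
    "trim",
    "map",
    "damage",
    "consensus",
    "diagnose",
    "assign",
    "network",
)


@dataclasses.dataclass
class PipelineConfig:
    """Flat configuration for the full pipeline (defaults follow the study's
    stated processing settings where one exists)."""

    seed: int = 0
    # stage toggles; later stages require their predecessors' outputs
    run_simulate: bool = True
    run_trim: bool = True
    run_map: bool = True
    run_damage: bool = True
    run_consensus: bool = True
    run_diagnose: bool = True
    run_assign: bool = True
    run_network: bool = True
    # panel simulation
    n_clades: int = 3
    samples_per_clade: int = 5
    genome_length: int = 2000
    planted_fixed_diffs_per_clade: int = 12
    intra_clade_mut_rate: float = 0.001
    query_clade: str = "clade2"
    query_private_mutations: int = 4
    # read simulation
    n_fragments: int = 1500
    frag_len_mean: float = 60.0
    frag_len_sd: float = 15.0
    d5: float = 0.02
    d3: float = 0.02
    lambda_decay: float = 0.5
    seq_error: float = 0.001
    dup_rate: float = 0.1
    # damaged/erroneous bases get qual_low; keep it above the trim thresholds
    # unless you specifically want trimming to eat the damaged termini
    qual_high: int = 37
    qual_low: int = 25
    contamination_fraction: float = 0.0
    contaminant_clade: str = ""
    # trimming
    leading_q: int = 20
    trailing_q: int = 20
    window_len: int = 4
    window_q: float = 20.0
    min_len: int = 30
    min_avg_q: float = 30.0
    # mapping
    seed_k: int = 13
    max_mismatch_frac: float = 0.1
    min_score_gap: int = 1
    # damage / consensus / diagnostics / network
    damage_positions: int = 25
    min_depth: int = 2
    breadth3_min: float = 0.80
    max_missing_frac: float = 0.10
    epsilon: int = 0
    # external inputs (used when run_simulate is off)
    reads_fastq: str = ""
    panel_fasta: str = ""
    labels_tsv: str = ""
    refs_fasta: str = ""

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial_report: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial_report = partial_report


def _stage_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0])


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file (# comments allowed)."""
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    values: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (part.strip() for part in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        ftype = fields[key].type
        if ftype == "bool":
            values[key] = val.lower() in ("1", "true", "yes", "on")
        elif ftype == "int":
            values[key] = int(val)
        elif ftype == "float":
            values[key] = float(val)
        else:
            values[key] = val
    return PipelineConfig(**values)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the enabled stages in order and return (and serialize) the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    for idx, stage in enumerate(_STAGES):
        if not getattr(config, f"run_{stage}"):
            continue
        runner = globals()[f"_stage_{stage}"]
        try:
            summary = runner(config, state, outdir, _stage_seed(config.seed, idx))
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            (outdir / "report.json").write_text(json.dumps(report, indent=2))
            raise PipelineError(stage, exc, report) from exc
        report["stages"][stage] = summary
        log.info("stage %s: %s", stage, summary)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage_simulate(config: PipelineConfig, state: dict, outdir: Path, seed: int) -> dict:
    panel_cfg = sim.PanelConfig(
        n_clades=config.n_clades,
        samples_per_clade=config.samples_per_clade,
        genome_length=config.genome_length,
        planted_fixed_diffs_per_clade=config.planted_fixed_diffs_per_clade,
        intra_clade_mut_rate=config.intra_clade_mut_rate,
        seed=seed,
    )
    panel, refs = sim.simulate_panel(panel_cfg)
    rng = np.random.default_rng(seed + 1)
    if config.query_clade not in refs:
        raise ValueError(f"unknown query clade {config.query_clade!r}")
    query_genome = _mutate(refs[config.query_clade], config.query_private_mutations, rng)
    read_params = sim.ReadSimParams(
        n_fragments=config.n_fragments,
        frag_len_mean=config.frag_len_mean,
        frag_len_sd=config.frag_len_sd,
        d5=config.d5,
        d3=config.d3,
        lambda_decay=config.lambda_decay,
        seq_error=config.seq_error,
        dup_rate=config.dup_rate,
        qual_high=config.qual_high,
        qual_low=config.qual_low,
        seed=seed + 2,
    )
    reads, truth = sim.simulate_reads(query_genome, read_params, source="endogenous")
    if config.contamination_fraction > 0:
        cont_clade = config.contaminant_clade or next(
            c for c in sorted(refs) if c != config.query_clade
        )
        cont_params = dataclasses.replace(
            read_params, seed=seed + 3, dup_rate=0.0
        )
        cont_reads, cont_truth = sim.simulate_reads(
            refs[cont_clade], cont_params, source="contaminant", id_prefix="cont"
        )
        reads, truth = sim.mix_contamination(
            reads, truth, cont_reads, cont_truth,
            config.contamination_fraction, seed=seed + 4,
        )
    panel.to_files(outdir / "panel.fa", outdir / "panel_labels.tsv")
    write_fasta(refs, outdir / "references.fa")
    write_fastq(reads, outdir / "reads.fastq")
    truth.to_tsv(outdir / "truth.tsv")
    state.update(panel=panel, refs=refs, reads=reads, truth=truth,
                 query_genome=query_genome)
    return {
        "n_samples": len(panel.sequences),
        "n_reads": len(reads),
        "query_clade": config.query_clade,
        "contamination_fraction": config.contamination_fraction,
    }


def _mutate(genome: str, n_mutations: int, rng: np.random.Generator) -> str:
    seq = list(genome)
    for pos in rng.choice(len(seq), size=n_mutations, replace=False):
        seq[pos] = sim._other_base(seq[pos], rng)
    return "".join(seq)


def _stage_trim(config: PipelineConfig, state: dict, outdir: Path, seed: int) -> dict:
    if "reads" not in state:
        from .seqs import read_fastq

        state["reads"] = list(read_fastq(config.reads_fastq))
    cfg = readqc.TrimConfig(
        leading_q=config.leading_q,
        trailing_q=config.trailing_q,
        window_len=config.window_len,
        window_q=config.window_q,
        min_len=config.min_len,
        min_avg_q=config.min_avg_q,
    )
    kept, stats = readqc.trim_set(state["reads"], cfg)
    write_fastq(kept, outdir / "reads.trimmed.fastq")
    state["trimmed"] = kept
    return {
        "n_in": stats.n_in,
        "n_kept": stats.n_kept,
        "survival_fraction": stats.survival_fraction,
        "discarded_by_step": stats.discarded_by_step,
    }


def _stage_map(config: PipelineConfig, state: dict, outdir: Path, seed: int) -> dict:
    if "refs" not in state:
        from .seqs import read_fasta

        state["refs"] = read_fasta(config.refs_fasta)
    if "panel" not in state and config.panel_fasta:
        state["panel"] = diag.CladePanel.from_files(
            config.panel_fasta, config.labels_tsv
        )
    reads = state.get("trimmed", state.get("reads"))
    params = mp.MapParams(
        k=config.seed_k,
        max_mismatch_frac=config.max_mismatch_frac,
        min_score_gap=config.min_score_gap,
    )
    result = mp.select_best_reference(reads, state["refs"], params)
    mapped = result.mapped[result.best_ref]
    deduped, dup_stats = mp.deduplicate(mapped)
    pileup = mp.make_pileup(deduped, len(state["refs"][result.best_ref]))
    from .samio import write_sam

    write_sam(deduped, result.best_ref, pileup.length, outdir / "mapped.dedup.sam")
    result.table.to_csv(outdir / "mapping_table.tsv", sep="\t", index=False)
    state.update(best_ref=result.best_ref, mapped=deduped, pileup=pileup)
    return {
        "best_reference": result.best_ref,
        "tie": result.tie,
        "per_reference": result.table.to_dict(orient="records"),
        "n_retained": len(mapped),
        "n_after_dedup": len(deduped),
        "duplication_level": dup_stats.duplication_level,
    }


def _stage_damage(config: PipelineConfig, state: dict, outdir: Path, seed: int) -> dict:
    profile = dmg.damage_profile(
        state["mapped"], state["refs"][state["best_ref"]], config.damage_positions
    )
    profile.to_tsv(outdir / "damage_profile.tsv")
    state["damage"] = profile
    ct5 = profile.frequency("5p", "C", "T")
    ga3 = profile.frequency("3p", "G", "A")
    return {
        "ct_5p_offset0": float(ct5[0]),
        "ga_3p_offset0": float(ga3[0]),
        "n_reads": profile.n_reads,
    }


def _stage_consensus(config: PipelineConfig, state: dict, outdir: Path, seed: int) -> dict:
    result = cns.call_consensus(state["pileup"], min_depth=config.min_depth)
    retained, reasons = cns.qc_retain(result, breadth3_min=config.breadth3_min)
    write_fasta({"consensus": result.sequence}, outdir / "consensus.fa")
    state["consensus"] = result
    summary = {
        "mean_depth": result.stats.mean_depth,
        "breadth": {str(k): v for k, v in result.stats.breadth.items()},
        "undetermined_fraction": result.stats.undetermined_fraction,
        "retained": retained,
        "reasons": reasons,
    }
    try:
        summary["gc_content"] = cns.gc_content(result.sequence)
    except ValueError:
        summary["gc_content"] = None
    (outdir / "coverage.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_diagnose(config: PipelineConfig, state: dict, outdir: Path, seed: int) -> dict:
    panel: diag.CladePanel = state["panel"]
    focal = state["best_ref"]
    sites = diag.find_inter_clade_fixed_sites(
        panel, max_missing_frac=config.max_missing_frac, focal_clade=focal
    )
    # panel has no reference-gap columns in the simulated case, but map anyway
    aligned_ref = panel.clade_consensus(focal)
    mapped_sites, dropped = diag.map_sites_to_reference(sites, aligned_ref)
    stats = diag.site_agreement(state["pileup"], mapped_sites)
    stats.per_site.to_csv(outdir / "site_agreement_inter_clade.tsv", sep="\t", index=False)
    summary = {
        "n_inter_clade_fixed_sites": len(sites),
        "n_sites_in_ref_gaps": len(dropped),
        "median_agreement": stats.median,
        "iqr_agreement": stats.iqr,
        "n_uncovered": stats.n_uncovered,
    }
    if "consensus" in state:
        q_sites = diag.find_clade_fixed_query_divergent_sites(
            panel, focal, state["consensus"].sequence
        )
        summary["n_clade_fixed_query_divergent_sites"] = len(q_sites)
        if q_sites:
            q_mapped, _ = diag.map_sites_to_reference(q_sites, aligned_ref)
            q_stats = diag.site_agreement(state["pileup"], q_mapped)
            q_stats.per_site.to_csv(
                outdir / "site_agreement_query_divergent.tsv", sep="\t", index=False
            )
            summary["median_agreement_query_divergent"] = q_stats.median
            summary["iqr_agreement_query_divergent"] = q_stats.iqr
    state["diagnostic_sites"] = sites
    return summary


def _stage_assign(config: PipelineConfig, state: dict, outdir: Path, seed: int) -> dict:
    query = state["consensus"].sequence
    assignment = diag.assign_clade(
        query, state["panel"], max_missing_frac=config.max_missing_frac
    )
    summary = {
        "assigned_clade": assignment.assigned_clade,
        "votes": assignment.votes,
        "p_distances": assignment.p_distances,
        "n_usable_sites": assignment.n_usable_sites,
        "decision_rule": assignment.decision_rule,
        "tied": assignment.tied,
    }
    (outdir / "assignment.json").write_text(json.dumps(summary, indent=2))
    state["assignment"] = assignment
    return summary


def _stage_network(config: PipelineConfig, state: dict, outdir: Path, seed: int) -> dict:
    panel: diag.CladePanel = state["panel"]
    alignment = dict(panel.sequences)
    if "consensus" in state:
        alignment["query"] = state["consensus"].sequence
    alignment, removed = diag.filter_missing(alignment, config.max_missing_frac)
    haplotypes, masked = collapse_haplotypes(alignment)
    summary = {
        "n_sequences": len(alignment),
        "n_removed_missing": len(removed),
        "n_haplotypes": len(haplotypes),
        "n_masked_columns": len(masked),
    }
    if len(haplotypes) >= 2:
        net = median_joining(haplotypes, epsilon=config.epsilon)
        net.write_edge_tsv(outdir / "network_edges.tsv")
        net.write_node_tsv(outdir / "network_nodes.tsv")
        net.write_gml(outdir / "network.gml")
        summary.update(
            n_median_vectors=len(net.median_nodes),
            total_cost=net.total_cost,
            query_haplotype=next(
                (h.hap_id for h in haplotypes if "query" in h.members), None
            ),
        )
    return summary
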