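"""End-to-end orchestration of the replicator-evolution analysis stages.

Composes the library stages — synthetic read/assay generation, mutation
calling, consensus genotyping, lineage analysis, replication-network
inference, the Bahadur interaction statistic and the serial-transfer
simulator — into a reproducible pipeline with one master seed, per-stage
outputs and a manifest of hashes and record counts. Every output is
traceable to (config, seed); re-running the same config reproduces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bahadur as bahadur_mod
from . import genotyping as gt
from . import lineages as ln
from . import network as net
from . import simulator as sim
from . import synthetic as syn

__all__ = ["PipelineConfig", "validate_config", "run_full_pipeline", "ALL_STAGES"]

ALL_STAGES = ("synth", "callmuts", "genotypes", "lineages", "network", "bahadur", "simulate")


@dataclass(frozen=True)
class PipelineConfig:
    """Stage toggles, thresholds and paths for one pipeline run."""

    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    scenario_path: str | None = None  # YAML; None uses the bundled scenario
    reads_dir: str | None = None  # pre-existing reads (skip synth)
    reference_path: str | None = None
    reads_per_round: int = 1000
    error_rate: float = 0.001
    dominant_threshold: float = 0.10
    strict_threshold: bool = True
    edge_threshold: float = 1.5
    lineage_cutoff: float = 3.0
    presence_threshold: float = 0.001
    fold_noise_sd: float = 0.05
    fold_replicates: int = 3
    bahadur_tolerance: float = 0.05
    sim_compartments: int = 10_000
    sim_rounds: int = 25

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed split from the master seed."""
        idx = ALL_STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31))


def validate_config(config: PipelineConfig) -> list[str]:
    """Report configuration violations without side effects."""
    violations: list[str] = []
    for stage in config.stages:
        if stage not in ALL_STAGES:
            violations.append(f"unknown stage {stage!r}")
    if not 0 < config.dominant_threshold < 1:
        violations.append(
            f"dominant_threshold {config.dominant_threshold} outside (0, 1)"
        )
    if config.edge_threshold < 0:
        violations.append(f"edge_threshold {config.edge_threshold} is negative")
    if config.lineage_cutoff < 0:
        violations.append(f"lineage_cutoff {config.lineage_cutoff} is negative")
    if not 0 <= config.presence_threshold < 1:
        violations.append(
            f"presence_threshold {config.presence_threshold} outside [0, 1)"
        )
    if config.reads_per_round < 1:
        violations.append("reads_per_round must be >= 1")
    if config.sim_compartments < 2:
        violations.append("sim_compartments must be >= 2")
    needs_reads = "callmuts" in config.stages and "synth" not in config.stages
    if needs_reads:
        if config.reads_dir is None:
            violations.append("callmuts without synth requires reads_dir")
        elif not Path(config.reads_dir).is_dir():
            violations.append(f"reads_dir {config.reads_dir!r} does not exist")
        if config.reference_path is None:
            violations.append("callmuts without synth requires reference_path")
        elif not Path(config.reference_path).is_file():
            violations.append(f"reference_path {config.reference_path!r} does not exist")
    if config.scenario_path is not None and not Path(config.scenario_path).is_file():
        violations.append(f"scenario_path {config.scenario_path!r} does not exist")
    return violations


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: dict, stage: str, outdir: Path, paths: list[Path], counts: dict) -> None:
    manifest["stages"][stage] = {
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(paths)},
        "counts": counts,
    }


def _load_scenario(config: PipelineConfig) -> syn.EvolutionScenario:
    if config.scenario_path is not None:
        return syn.EvolutionScenario.from_yaml(config.scenario_path)
    return syn.default_scenario(
        reads_per_round=config.reads_per_round,
        error_rate=config.error_rate,
        seed=config.stage_seed("synth"),
    )


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages in order and write a run manifest.

    A stage failure raises with the failing stage named; outputs of earlier
    stages are retained on disk.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid pipeline config: " + "; ".join(violations))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": asdict(config), "stages": {}}
    ctx: dict = {}

    for stage in [s for s in ALL_STAGES if s in config.stages]:
        try:
            _STAGE_RUNNERS[stage](config, outdir, manifest, ctx)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _stage_synth(config: PipelineConfig, outdir: Path, manifest: dict, ctx: dict) -> None:
    refs = syn.generate_references(seed=config.stage_seed("synth"))
    scenario = _load_scenario(config)
    reads_dir = outdir / "reads"
    truth_dir = outdir / "truth"
    reads_dir.mkdir(exist_ok=True)
    truth_dir.mkdir(exist_ok=True)
    paths = []
    ref_path = outdir / "references.fasta"
    with open(ref_path, "w") as fh:
        fh.write(f">{refs.host_id}\n{refs.host_seq}\n>{refs.parasite_id}\n{refs.parasite_seq}\n")
    paths.append(ref_path)
    scen_path = outdir / "scenario.yaml"
    scenario.to_yaml(scen_path)
    paths.append(scen_path)
    n_reads = 0
    for rnd in scenario.rounds:
        readset = syn.generate_reads(scenario, refs, rnd)
        fasta = reads_dir / f"round_{rnd}.fasta"
        syn.write_fasta(readset, fasta)
        truth = truth_dir / f"truth_round_{rnd}.csv"
        readset.truth_frame().to_csv(truth, index=False)
        paths.extend([fasta, truth])
        n_reads += len(readset.records)
    panel = syn.truth_panel(scenario, refs)
    for cls, calls in panel.items():
        p = truth_dir / f"planted_panel_{cls}.csv"
        pd.DataFrame(
            [
                {"label": c.label, "position": c.position, "kind": c.kind,
                 "ref": c.ref or "", "alt": c.alt or "", "length": c.length}
                for c in calls
            ]
        ).to_csv(p, index=False)
        paths.append(p)
    ctx["refs"] = refs
    ctx["scenario"] = scenario
    ctx["reads_dir"] = reads_dir
    ctx["reference_path"] = ref_path
    _register(manifest, "synth", outdir, paths, {"reads": n_reads, "rounds": len(scenario.rounds)})


def _stage_callmuts(config: PipelineConfig, outdir: Path, manifest: dict, ctx: dict) -> None:
    reads_dir = Path(ctx.get("reads_dir") or config.reads_dir)
    ref_path = Path(ctx.get("reference_path") or config.reference_path)
    records = gt.read_fasta(ref_path)
    host_ref = str(records[0].seq)
    parasite_len = len(records[1].seq) if len(records) > 1 else len(host_ref) // 4
    per_round: dict[str, dict[int, list]] = {"host": {}, "parasite": {}}
    n_reads = n_mut = 0
    for fasta in sorted(reads_dir.glob("round_*.fasta")):
        rnd = int(fasta.stem.split("_")[1])
        reads = gt.read_fasta(fasta)
        n_reads += len(reads)
        host_reads, parasite_reads = gt.classify_reads(reads, len(host_ref), parasite_len)
        for cls, subset in (("host", host_reads), ("parasite", parasite_reads)):
            calls = gt.call_reads(subset, host_ref)
            per_round[cls][rnd] = calls
            n_mut += sum(len(c) for c in calls)
    paths = []
    for cls in ("host", "parasite"):
        if any(per_round[cls].values()):
            frame = gt.mutation_frequencies(per_round[cls])
            p = outdir / f"mutations_{cls}.csv"
            frame.to_csv(p)
            paths.append(p)
    ctx["per_round_calls"] = per_round
    ctx["host_ref"] = host_ref
    _register(manifest, "callmuts", outdir, paths, {"reads": n_reads, "mutation_calls": n_mut})


def _stage_genotypes(config: PipelineConfig, outdir: Path, manifest: dict, ctx: dict) -> None:
    if "per_round_calls" not in ctx:
        raise ValueError("genotypes stage requires callmuts results")
    paths = []
    tables = {}
    counts = {}
    for cls in ("host", "parasite"):
        calls = ctx["per_round_calls"][cls]
        if not any(calls.values()):
            continue
        panel = gt.find_dominant_mutations(
            calls, threshold=config.dominant_threshold, strict=config.strict_threshold
        )
        table = gt.build_consensus_genotypes(calls, panel)
        tables[cls] = table
        p = outdir / f"genotypes_{cls}.csv"
        table.to_frame().to_csv(p, index=False)
        paths.append(p)
        counts[f"{cls}_panel"] = len(panel)
        counts[f"{cls}_genotypes"] = len(table)
    ctx["genotype_tables"] = tables
    _register(manifest, "genotypes", outdir, paths, counts)


def _first_rounds(table: gt.GenotypeTable) -> dict[str, int]:
    return {
        gid: min(r for r, c in g.counts.items() if c > 0)
        for gid, g in zip(table.ids, table.genotypes)
    }


def _stage_lineages(config: PipelineConfig, outdir: Path, manifest: dict, ctx: dict) -> None:
    if "genotype_tables" not in ctx:
        raise ValueError("lineages stage requires genotype tables")
    paths = []
    counts = {}
    assignments = {}
    for cls, prefix in (("host", "HL"), ("parasite", "PL")):
        table = ctx["genotype_tables"].get(cls)
        if table is None or len(table) == 0:
            continue
        dm = ln.hamming_matrix(table)
        dm_path = outdir / f"distances_{cls}.csv"
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(dm_path)
        paths.append(dm_path)
        embedding = ln.pcoa_embed(dm, dims=2)
        emb_path = outdir / f"pcoa_{cls}.csv"
        embedding.coordinates.to_csv(emb_path)
        paths.append(emb_path)
        assignment = ln.cluster_lineages(
            dm, config.lineage_cutoff, first_rounds=_first_rounds(table), prefix=prefix
        )
        assignments[cls] = assignment
        asg_path = outdir / f"lineages_{cls}.csv"
        pd.Series(dict(assignment.mapping), name="lineage").rename_axis("genotype").to_csv(asg_path)
        paths.append(asg_path)
        freq, presence = ln.lineage_frequencies(
            table, assignment, presence_threshold=config.presence_threshold
        )
        freq_path = outdir / f"lineage_frequencies_{cls}.csv"
        freq.rename_axis("lineage").to_csv(freq_path)
        paths.append(freq_path)
        if len(table) >= 3:
            nj = ln.nj_tree(dm)
            tree_path = outdir / f"nj_{cls}.nwk"
            tree_path.write_text(nj.newick + "\n")
            paths.append(tree_path)
        counts[f"{cls}_lineages"] = len(assignment.labels)
    ctx["assignments"] = assignments
    _register(manifest, "lineages", outdir, paths, counts)


def _stage_network(config: PipelineConfig, outdir: Path, manifest: dict, ctx: dict) -> None:
    rates_true = syn.five_species_rates()
    table = syn.generate_fold_table(
        rates_true,
        noise_sd=config.fold_noise_sd,
        seed=config.stage_seed("network"),
        replicates=config.fold_replicates,
    )
    folds_path = outdir / "fold_table.csv"
    table.to_csv(folds_path)
    graph = net.build_graph(table, threshold=config.edge_threshold)
    graphml_path = outdir / "replicator_graph.graphml"
    net.write_graphml(graph, graphml_path)
    dot_path = outdir / "replicator_graph.dot"
    net.write_dot(graph, dot_path)
    hosts = [sp for sp in rates_true.columns if rates_true[sp].to_numpy().any()]
    rates = net.rates_from_folds(table, replicase_sources=hosts)
    rates_path = outdir / "rate_matrix.csv"
    rates.to_csv(rates_path)
    ctx["rate_matrix"] = rates
    _register(
        manifest, "network", outdir,
        [folds_path, graphml_path, dot_path, rates_path],
        {"edges": graph.number_of_edges(), "nodes": graph.number_of_nodes()},
    )


def _stage_bahadur(config: PipelineConfig, outdir: Path, manifest: dict, ctx: dict) -> None:
    rates = syn.five_species_rates()
    rows = []
    # log-additive triplets constructed from the rate matrix: fold of the
    # focal template with a subset S of partners present is exp(sum over
    # present sources of k_focal,source), plus its own source if a host
    triplets = [("PL3", "HL1", "HL2"), ("PL2", "HL1", "HL2"), ("HL3", "HL1", "HL2")]
    for focal, pj, pk in triplets:
        for zj, zk in bahadur_mod.DESIGN_POINTS:
            k_total = rates.loc[focal, focal] if focal in rates.columns else 0.0
            if zj > 0:
                k_total += rates.loc[focal, pj]
            if zk > 0:
                k_total += rates.loc[focal, pk]
            rows.append(
                {"focal": focal, "partner_j": pj, "partner_k": pk,
                 "z_j": zj, "z_k": zk, "fold": float(np.exp(k_total))}
            )
    designs = pd.DataFrame(rows)
    designs_path = outdir / "bahadur_designs.csv"
    designs.to_csv(designs_path, index=False)
    coef = bahadur_mod.fit_table(designs, tolerance=config.bahadur_tolerance)
    coef_path = outdir / "bahadur_coefficients.csv"
    coef.to_csv(coef_path, index=False)
    _register(manifest, "bahadur", outdir, [designs_path, coef_path], {"triplets": len(coef)})


def _stage_simulate(config: PipelineConfig, outdir: Path, manifest: dict, ctx: dict) -> None:
    rates = ctx.get("rate_matrix")
    if rates is not None:
        species = tuple(rates.values.index)
        k = rates.to_array(species)
    else:
        frame = syn.five_species_rates()
        species = tuple(frame.index)
        k = frame.to_numpy()
    sim_config = sim.SimConfig(
        species=species,
        rates=k,
        n_compartments=config.sim_compartments,
        rounds=config.sim_rounds,
        seed=config.stage_seed("simulate"),
    )
    cfg_path = outdir / "sim_config.yaml"
    sim_config.to_yaml(cfg_path)
    summaries = sim.run_experiment(sim_config)
    sum_path = outdir / "simulation_summary.csv"
    sim.summaries_to_frame(summaries).to_csv(sum_path, index=False)
    _register(
        manifest, "simulate", outdir, [cfg_path, sum_path],
        {"rounds_run": summaries[-1].round, "extinct": sorted(summaries[-1].extinct)},
    )


_STAGE_RUNNERS = {
    "synth": _stage_synth,
    "callmuts": _stage_callmuts,
    "genotypes": _stage_genotypes,
    "lineages": _stage_lineages,
    "network": _stage_network,
    "bahadur": _stage_bahadur,
    "simulate": _stage_simulate,
}


def demo_config(outdir: str, seed: int = 0) -> PipelineConfig:
    """Desk-scale configuration of the bundled five-lineage scenario."""
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        reads_per_round=150,
        sim_compartments=1000,
        sim_rounds=8,
    )
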