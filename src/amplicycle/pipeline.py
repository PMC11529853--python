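"""End-to-end orchestration: reconstruct, simulate, evaluate.

``reconstruct`` runs the full chain -- SV filtering, breakpoint merging,
genome fragmentation, graph encoding, pruning, simple-cycle search,
clustering, derived-cycle generation, LASSO quantification, candidate
selection and topology annotation -- and returns the reconstructions
(optionally writing the BED-like threads, summary table, fit report and
FASTA).  All thresholds live in :class:`RunConfig`, whose defaults are the
method's published operating point.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .coverage import CoverageProfile
from .cycles import derive_cycles, find_simple_cycles, partition_cycles
from .evaluate import evaluate_sample
from .fragments import (
    amplified_regions,
    annotate_coverage,
    fragment_genome,
    merge_breakpoints,
)
from .graph import build_graph, prune_graph
from .output import FragmentRecord, Reconstruction, read_bed, write_bed, write_fasta, write_summary
from .quantify import (
    QuantifiedCycle,
    build_design_matrix,
    filter_candidates,
    fit_lasso,
    select_cycles,
)
from .simulate import GroundTruth, NoiseSpec, emit_fixture, simulate_truth
from .sv import filter_svs, parse_sv_vcf
from .topology import classify_topology

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReconstructionResult", "reconstruct", "run_reconstruct",
           "run_simulate", "run_evaluate"]


@dataclass
class RunConfig:
    """All tunable thresholds, at their published defaults."""

    min_sv_cov: float = 5.0  # on-target coverage for SV filtering (x)
    min_vaf: float = 0.01
    merge_window: int = 50  # bp
    prune_cov: float = 5.0  # fragment pruning (strictly <= removed)
    alpha: float = 0.1  # LASSO penalty
    min_ecdna_len: int = 100_000  # bp; ecDNA label threshold
    region_gap: int = 10_000  # bp; Multiregion block separation
    max_simple: int = 8  # simple cycles per cluster entering the merge
    dissim_threshold: float = 0.8  # max multiset-Jaccard similarity to splice
    eval_tol: int = 50  # bp; evaluation boundary tolerance
    max_spatial_gap: int | None = None
    wgs_mean: float | None = None  # None = estimate from the profile
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ReconstructionResult:
    reconstructions: list[Reconstruction]
    candidates: list[QuantifiedCycle]
    wgs_mean: float
    counts: dict[str, int] = field(default_factory=dict)
    fit_report: list[dict] = field(default_factory=list)  # per-cluster fits


def reconstruct(
    vcf_path,
    coverage,
    cfg: RunConfig | None = None,
) -> ReconstructionResult:
    """Reconstruct circular elements from an SV VCF and a coverage profile.

    ``coverage`` may be a path (bedGraph/BigWig) or a
    :class:`CoverageProfile`.
    """
    cfg = cfg or RunConfig()
    profile = (
        coverage
        if isinstance(coverage, CoverageProfile)
        else CoverageProfile.load(coverage)
    )
    svs = parse_sv_vcf(vcf_path)
    kept = filter_svs(svs, cfg.min_sv_cov, cfg.min_vaf, profile=profile)
    counts = {"svs_parsed": len(svs), "svs_filtered": len(kept)}

    breakpoints, bp_map = merge_breakpoints(kept, cfg.merge_window)
    regions = amplified_regions(profile, kept, threshold=cfg.prune_cov)
    frags = annotate_coverage(fragment_genome(breakpoints, regions), profile)
    counts["fragments"] = len(frags)

    graph = build_graph(frags, kept, profile, bp_map, strict=False,
                        max_spatial_gap=cfg.max_spatial_gap)
    graph = prune_graph(graph, profile, cfg.prune_cov, cfg.max_spatial_gap)
    counts["fragments_pruned"] = graph.n_fragments()

    wgs_mean = (
        cfg.wgs_mean
        if cfg.wgs_mean is not None
        else profile.background_median(exclude=regions)
    )

    cycles = find_simple_cycles(graph)
    clusters = partition_cycles(cycles, graph.fragments)
    counts["simple_cycles"] = len(cycles)
    counts["clusters"] = len(clusters)

    all_quantified: list[QuantifiedCycle] = []
    fit_rows: list[dict] = []
    frag_list = list(graph.fragments.values())
    n_derived = 0
    for cluster in clusters:
        derived = derive_cycles(
            cluster, graph.fragments, cfg.max_simple, cfg.dissim_threshold
        )
        n_derived += len(derived)
        dm = build_design_matrix(cluster, frag_list, dedup_columns=True)
        weights = np.array(
            [c.n_parents * (1.01 if c.is_derived else 1.0) for c in dm.cycles]
        )
        fit = fit_lasso(dm, cfg.alpha, background_cov=wgs_mean,
                        penalty_weights=weights)
        quantified = select_cycles(fit, dm, cluster.cid)
        cov = {f.fid: f.mean_cov for f in dm.fragments}
        t = max(min(cov[fid] for fid in c.fragment_ids) for c in dm.cycles) / 4.0
        for q in quantified:
            fit_rows.append(
                {
                    "cluster": cluster.cid,
                    "cycle": f"{'D' if q.cycle.is_derived else 'S'}"
                             f"{len(q.cycle.path)}@{q.cycle.path[0][0]}",
                    "beta": q.proportion,
                    "selected": q.selected,
                    "t": t,
                    "alpha": cfg.alpha,
                    "objective": fit.objective,
                }
            )
        all_quantified.extend(q for q in quantified if q.selected)
    counts["derived_cycles"] = n_derived
    counts["selected_cycles"] = len(all_quantified)

    candidates = filter_candidates(all_quantified, wgs_mean, cfg.min_ecdna_len)
    candidates.sort(key=lambda q: (-q.proportion, q.cycle.canon_key))
    counts["candidates"] = len(candidates)

    recs = []
    for circ_id, q in enumerate(candidates):
        topo = classify_topology(q.cycle, graph.fragments, cfg.region_gap)
        frs = [
            FragmentRecord(
                graph.fragments[fid].chrom,
                graph.fragments[fid].start,
                graph.fragments[fid].end,
                fid,
                orient,
                graph.fragments[fid].mean_cov,
            )
            for fid, orient in q.cycle.path
        ]
        recs.append(Reconstruction(circ_id, frs, q.proportion, topo, q.label))

    for key, val in counts.items():
        log.info("%s: %d", key, val)
    return ReconstructionResult(recs, candidates, float(wgs_mean), counts, fit_rows)


def run_reconstruct(
    vcf_path, coverage_path, outdir, cfg: RunConfig | None = None, reference=None
) -> ReconstructionResult:
    """File-level wrapper: run :func:`reconstruct` and write the outputs."""
    cfg = cfg or RunConfig()
    os.makedirs(outdir, exist_ok=True)
    result = reconstruct(vcf_path, coverage_path, cfg)
    write_bed(result.reconstructions, os.path.join(outdir, "reconstruct.bed"))
    write_summary(result.reconstructions, os.path.join(outdir, "summary.txt"))
    with open(os.path.join(outdir, "fit_report.tsv"), "w") as fh:
        fh.write("cluster\tcycle\tbeta\tselected\tt\talpha\tobjective\n")
        for row in result.fit_report:
            fh.write(
                f"{row['cluster']}\t{row['cycle']}\t{row['beta']:.6g}\t"
                f"{int(row['selected'])}\t{row['t']:.6g}\t{row['alpha']:g}\t"
                f"{row['objective']:.6g}\n"
            )
    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write(f"config: {cfg.to_dict()}\n")
        fh.write(f"wgs_mean: {result.wgs_mean:.6g}\n")
        for key, val in result.counts.items():
            fh.write(f"{key}: {val}\n")
    if reference is not None and result.reconstructions:
        write_fasta(
            result.reconstructions, reference, os.path.join(outdir, "reconstruct.fasta")
        )
    return result


def run_simulate(
    outdir,
    n_templates: int = 1,
    topology: str | None = None,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    cfg: RunConfig | None = None,
):
    """Simulate a sample and emit its fixture triplet plus a manifest."""
    noise = noise or NoiseSpec()
    truth = simulate_truth(n_templates=n_templates, seed=seed, target_topology=topology)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    fixture = emit_fixture(truth, noise, outdir, rng)
    with open(os.path.join(outdir, "manifest.txt"), "w") as fh:
        fh.write(f"seed: {seed}\nn_templates: {n_templates}\ntopology: {topology}\n")
        for t in truth.templates:
            fh.write(
                f"{t.name}\t{t.topology}\t{t.proportion:.3f}\t"
                + ";".join(f"{c}:{s}-{e}{o}" for c, s, e, o in t.ring)
                + "\n"
            )
    return truth, fixture


def run_evaluate(truth_bed, rec_bed, out_path, tol: int = 50):
    """Score a reconstruction BED against a truth BED; write a report TSV."""
    truth_recs = read_bed(truth_bed)
    rec_recs = read_bed(rec_bed)
    truth_rings = [r.ring() for r in truth_recs]
    rec_rings = [r.ring() for r in rec_recs]
    scores, bp = evaluate_sample(rec_rings, truth_rings, tol)
    mean = float(np.mean(scores)) if scores else 0.0
    sd = float(np.std(scores)) if scores else 0.0
    with open(out_path, "w") as fh:
        fh.write("truth_id\tlargest_contig_norm\trecall\tprecision\tn_true\tn_rec\n")
        for r, s in zip(truth_recs, scores):
            fh.write(
                f"{r.circ_id}\t{s:.4f}\t{bp.breakpoint_recall:.4f}\t"
                f"{bp.breakpoint_precision:.4f}\t{bp.n_true}\t{bp.n_rec}\n"
            )
        fh.write(f"#aggregate\tmean={mean:.4f}\tsd={sd:.4f}\n")
    return scores, bp
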