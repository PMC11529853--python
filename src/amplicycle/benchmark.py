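"""Seeded benchmark batteries: simulate, reconstruct, score.

These drive the same code paths a user would run from the CLI, at desk
scale: a few hundred templates per battery, emitted as idealized fixtures
in a temporary directory and reconstructed with default thresholds.
"""

from __future__ import annotations

import tempfile

import numpy as np

from .evaluate import breakpoint_metrics, largest_contig_normalized
from .pipeline import RunConfig, reconstruct
from .simulate import (
    GroundTruth,
    NoiseSpec,
    detectable_templates,
    emit_fixture,
    mix_fixtures,
    simulate_truth,
)

__all__ = [
    "reconstruct_truth",
    "topology_contig_scores",
    "complex_topology_fraction",
    "simple_topology_perfect_rate",
    "mixture_recalls",
]

SIMPLE_CLASSES = (
    "SimpleCircularization",
    "SimpleSVs",
    "MixedSVs",
    "Multiregion",
    "Multichromosomal",
)
COMPLEX_CLASSES = ("Duplications", "Foldbacks")


def reconstruct_truth(truth: GroundTruth, noise: NoiseSpec, seed: int,
                      cfg: RunConfig | None = None):
    """Emit a fixture for ``truth`` and run the reconstruction on it."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    with tempfile.TemporaryDirectory() as d:
        fx = emit_fixture(truth, noise, d, rng)
        return reconstruct(fx.vcf, fx.coverage, cfg)


def topology_contig_scores(
    topology: str, n: int, noise: NoiseSpec, seed: int
) -> list[float]:
    """Per-template best normalized largest contig for ``n`` simulated
    templates of one topology class."""
    import zlib

    scores = []
    topo_key = zlib.crc32(topology.encode()) % 2**31  # stable across runs
    for i in range(n):
        sub_seed = int(np.random.SeedSequence([seed, topo_key, i])
                       .generate_state(1)[0] % (2**31))
        truth = simulate_truth(1, seed=sub_seed, target_topology=topology)
        res = reconstruct_truth(truth, noise, sub_seed)
        best = 0.0
        for rec in res.reconstructions:
            best = max(
                best,
                largest_contig_normalized(rec.ring(), truth.templates[0].ring),
            )
        scores.append(best)
    return scores


def complex_topology_fraction(
    n_per_class: int = 100,
    seed: int = 42,
    threshold: float = 0.6,
    noise: NoiseSpec | None = None,
) -> tuple[float, list[float]]:
    """Fraction (%) of complex-topology simulations whose normalized largest
    contig exceeds ``threshold`` under moderate noise."""
    noise = noise or NoiseSpec(cov_sigma=2.0, bp_jitter=10, fn_rate=0.0)
    scores: list[float] = []
    for topo in COMPLEX_CLASSES:
        scores.extend(topology_contig_scores(topo, n_per_class, noise, seed))
    frac = 100.0 * sum(s > threshold for s in scores) / len(scores)
    return frac, scores


def simple_topology_perfect_rate(
    n_per_class: int = 50, seed: int = 1
) -> tuple[float, list[float]]:
    """Fraction (%) of zero-noise simple-topology simulations reconstructed
    with normalized largest contig of exactly 1."""
    scores: list[float] = []
    for topo in SIMPLE_CLASSES:
        scores.extend(topology_contig_scores(topo, n_per_class, NoiseSpec(), seed))
    rate = 100.0 * sum(s >= 1.0 - 1e-9 for s in scores) / len(scores)
    return rate, scores


def mixture_recalls(
    ratios=(0.10, 0.25, 0.50, 0.75, 0.90, 1.00),
    seed: int = 0,
    noise: NoiseSpec | None = None,
) -> list[dict]:
    """Two-element in silico dilution: element 1 at full strength, element 2
    at each ratio.  Returns one row per (ratio, element) with the element's
    breakpoint recall and whether its scaled support still passes the
    filters (only those elements are expected to be recovered).
    """
    noise = noise or NoiseSpec()
    t1 = simulate_truth(1, seed=seed * 2 + 1, target_topology="MixedSVs",
                        proportion_range=(60.0, 200.0))
    t2 = simulate_truth(1, seed=seed * 2 + 2, target_topology="Duplications",
                        proportion_range=(60.0, 200.0))
    # the two elements must not overlap genomically (co-occurrence design)
    attempt = 100
    while any(
        c1 == c2 and min(e1, e2) > max(s1, s2)
        for c1, s1, e1, _ in t1.templates[0].ring
        for c2, s2, e2, _ in t2.templates[0].ring
    ):
        t2 = simulate_truth(1, seed=attempt, target_topology="Duplications",
                            proportion_range=(60.0, 200.0))
        attempt += 1

    rows = []
    for ratio in ratios:
        mixed = mix_fixtures([t1, t2], [1.0, ratio])
        res = reconstruct_truth(mixed, noise, seed=seed + int(ratio * 1000))
        rec_rings = [r.ring() for r in res.reconstructions]
        detect = detectable_templates(mixed)
        for tpl, ok in zip(mixed.templates, detect):
            m = breakpoint_metrics(rec_rings, [tpl.ring])
            rows.append(
                {
                    "ratio": ratio,
                    "template": tpl.name,
                    "detectable": ok,
                    "recall": m.breakpoint_recall,
                    "n_true": m.n_true,
                }
            )
    return rows
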