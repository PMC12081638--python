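"""Self-validation benchmarks on synthetic data with known ground truth.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage end to end, and reports summary statistics (calibration medians,
recovery errors, recall, false-positive rates). They back the acceptance
script and the acceptance-level tests.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import colonies as col
from . import flow as flw
from . import simulate as sim
from . import synergy as syn
from . import transcriptomics as tx
from .plates import normalize_viability

__all__ = [
    "bliss_null_calibration",
    "planted_interaction_recovery",
    "colony_counting_benchmark",
    "subg1_recovery",
    "bh_oracle_max_abs_diff",
    "null_false_positive_rates",
    "graph_weight_mismatches",
]


def _child_seeds(seed: int, n: int, stream: int) -> list[int]:
    rng = np.random.default_rng([seed, stream])
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _screen_score(interaction: float, noise_cv: float, seed: int) -> float:
    table = sim.simulate_plate(
        sim.PlateSimSpec(interaction_factor=interaction, noise_cv=noise_cv, seed=seed)
    )
    return syn.combination_synergy(normalize_viability(table))[0].score


def bliss_null_calibration(
    n_screens: int = 100, noise_cv: float = 0.05, seed: int = 0
) -> dict:
    """Median combination score over Bliss-null screens (no interaction)."""
    scores = [
        _screen_score(1.0, noise_cv, s) for s in _child_seeds(seed, n_screens, 1)
    ]
    return {"median_score": float(np.median(scores)), "n_screens": n_screens}


def planted_interaction_recovery(
    interactions: tuple[float, ...] = (2.0, 5.0, 20.0, 113.0),
    n_screens: int = 30,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> dict:
    """Median recovered score and median relative error per planted factor."""
    out = {}
    for k, sigma in enumerate(interactions):
        scores = np.array(
            [_screen_score(sigma, noise_cv, s) for s in _child_seeds(seed, n_screens, 10 + k)]
        )
        out[sigma] = {
            "median_score": float(np.median(scores)),
            "median_relative_error": float(np.median(np.abs(scores - sigma) / sigma)),
        }
    return out


def colony_counting_benchmark(
    n_images: int = 50,
    max_colonies: int = 20,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> dict:
    """Detection accuracy over synthetic well images with 0..max_colonies disks.

    ``noise_fraction`` scales Gaussian pixel noise relative to the mean colony
    contrast. Reports the exact-count match rate and the per-colony recall
    (detected kept object whose centroid falls inside the true disk).
    """
    rng = np.random.default_rng([seed, 20])
    detector = col.ColonyDetector(pixel_size_um=5.0)
    exact = 0
    found = total = 0
    intensity_range = (800.0, 1500.0)
    noise_sd = noise_fraction * float(np.mean(intensity_range))
    for k in range(n_images):
        n_col = int(rng.integers(0, max_colonies + 1))
        spec = sim.random_colony_spec(
            n_col,
            seed=int(rng.integers(0, 2**31 - 1)),
            intensity_range=intensity_range,
            noise_sd=noise_sd,
        )
        image, truth = sim.simulate_colony_image(spec)
        detector.fit(image)
        exact += detector.count_ == n_col
        kept = detector.features_[detector.features_["kept"]]
        for _, row in truth.iterrows():
            total += 1
            if len(kept):
                dist = np.hypot(
                    kept["centroid_row"] - row["row_px"],
                    kept["centroid_col"] - row["col_px"],
                )
                found += bool(dist.min() < row["radius_um"] / spec.pixel_size_um)
    return {
        "exact_count_rate": exact / n_images,
        "recall": found / total if total else 1.0,
        "n_images": n_images,
        "n_colonies": total,
    }


def subg1_recovery(
    fractions: tuple[float, ...] = (0.0, 0.05, 0.10, 0.25),
    n_events: int = 10_000,
    n_seeds: int = 3,
    seed: int = 0,
) -> dict:
    """Absolute sub-G1 estimation error and landmark ratios per planted level."""
    out = {}
    for k, planted in enumerate(fractions):
        rest = 1.0 - planted
        errors, ratios = [], []
        for s in _child_seeds(seed, n_seeds, 30 + k):
            events, _ = sim.simulate_dna_content(
                sim.DnaContentSpec(
                    n_events=n_events,
                    fractions=(planted, rest * 0.60, rest * 0.15, rest * 0.25),
                    seed=s,
                )
            )
            model = flw.SubG1Model().fit(events)
            errors.append(abs(model.subg1_fraction_ - planted))
            ratios.append(model.g2m_mode_ / model.g1_mode_)
        out[planted] = {
            "max_abs_error": float(np.max(errors)),
            "landmark_ratios": [float(r) for r in ratios],
        }
    return out


def _bh_reference(pvals: np.ndarray) -> np.ndarray:
    """Literal step-up construction, quadratic-time: independent of bh_adjust."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj = np.empty(m)
    for k in range(m):
        adj[k] = min(min(m * sorted_p[j] / (j + 1) for j in range(k, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bh_oracle_max_abs_diff(n_vectors: int = 1000, seed: int = 0) -> float:
    """Max |bh_adjust - brute-force step-up| over random p-value vectors."""
    rng = np.random.default_rng([seed, 40])
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(size=int(rng.integers(1, 30)))
        worst = max(worst, float(np.max(np.abs(tx.bh_adjust(p) - _bh_reference(p)))))
    return worst


def null_false_positive_rates(n_seeds: int = 50, fdr: float = 0.01, seed: int = 0) -> dict:
    """Gene- and set-level false-positive proportions on null simulations."""
    gene_fps, set_fps = [], []
    for s in _child_seeds(seed, n_seeds, 50):
        counts, samples, gene_sets = sim.simulate_counts(
            sim.CountsSimSpec(n_genes=1000, seed=s)
        )
        groups = samples.set_index("sample")["group"]
        de = tx.differential_expression(counts, groups, fdr=fdr)
        gene_fps.append(de["significant"].mean())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expr = tx.TMMNormalizer().fit_transform(counts)
            scores = tx.enrichment_scores(expr, gene_sets)
        sets_result = tx.differential_gene_sets(scores, groups, fdr=fdr)
        set_fps.append(sets_result["significant"].mean())
    return {
        "gene_level_fp_rate": float(np.mean(gene_fps)),
        "set_level_fp_rate": float(np.mean(set_fps)),
        "n_seeds": n_seeds,
    }


def graph_weight_mismatches(n_collections: int = 100, seed: int = 0) -> dict:
    """Edge-weight disagreements vs brute-force pairwise intersections."""
    import pandas as pd

    from .genesets import build_geneset_graph

    rng = np.random.default_rng([seed, 60])
    universe = np.array([f"g{i}" for i in range(300)])
    mismatches = comparisons = 0
    for _ in range(n_collections):
        n_sets = int(rng.integers(3, 15))
        memberships = {
            f"S{k}": list(rng.choice(universe, size=int(rng.integers(5, 80)), replace=False))
            for k in range(n_sets)
        }
        frame = pd.DataFrame(
            {"significant": True, "direction": "up"}, index=list(memberships)
        )
        graph = build_geneset_graph(frame, memberships)
        ids = list(memberships)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                expected = len(set(memberships[a]) & set(memberships[b]))
                observed = graph.edges[a, b]["weight"] if graph.has_edge(a, b) else 0
                comparisons += 1
                mismatches += observed != expected
    return {"mismatches": mismatches, "comparisons": comparisons}
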