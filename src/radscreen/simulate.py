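"""Synthetic-data generators for every pipeline input.

Each generator emulates one assay read-out with known ground truth so the
downstream stages (plate normalization, Bliss synergy scoring, colony
detection, sub-G1 gating, count-based expression analysis) can be exercised
and validated without external data:

* :func:`simulate_plate` — luminescence viability plates under a
  multiplicative Bliss-null model with an optional planted interaction.
* :func:`simulate_colony_image` — grayscale well images with disk-shaped
  colonies on an uneven background.
* :func:`simulate_dna_content` — propidium-iodide DNA-content event lists as
  a four-component sub-G1 / G1 / S / G2-M mixture.
* :func:`simulate_counts` — negative-binomial RNA-seq count matrices with
  two groups and planted differentially expressed gene sets.

All generators take an explicit integer seed and draw from a single local
``numpy.random.Generator``; no global RNG state is touched, so equal specs
give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlateSimSpec",
    "ColonyImageSpec",
    "DnaContentSpec",
    "CountsSimSpec",
    "simulate_plate",
    "simulate_colony_image",
    "simulate_dna_content",
    "simulate_counts",
    "random_colony_spec",
    "write_colony_image",
    "write_counts_bundle",
]

PLATE_COLUMNS = [
    "plate_id",
    "well",
    "drug_a_conc_uM",
    "drug_b_conc_uM",
    "dose_Gy",
    "solvent",
    "raw_signal",
    "experiment_id",
]


def _require(cond: bool, name: str, message: str) -> None:
    if not cond:
        raise ValueError(f"invalid field '{name}': {message}")


# ---------------------------------------------------------------------------
# viability plates
# ---------------------------------------------------------------------------


@dataclass
class PlateSimSpec:
    """Generative model for one drug/drug (or drug/radiation) viability screen.

    The combination's true viability is ``drug_a_viability * drug_b_viability
    / interaction_factor``, so the synergy score recovered downstream equals
    ``interaction_factor`` by construction (1 = Bliss independence). Raw
    luminescence is ``true viability x control_signal`` times multiplicative
    log-normal noise with coefficient of variation ``noise_cv``.
    """

    drug_a_viability: float = 0.8
    drug_b_viability: float = 0.5
    interaction_factor: float = 1.0
    noise_cv: float = 0.1
    n_replicate_wells: int = 4
    n_experiments: int = 3
    seed: int = 0
    # nominal condition labels written to the plate table
    drug_a_conc_uM: float = 2.0
    drug_b_conc_uM: float = 20.0
    b_is_radiation: bool = False
    b_dose_Gy: float = 2.0
    control_signal: float = 1e5
    solvent: str = "DMSO"

    def validate(self) -> None:
        _require(0.0 <= self.drug_a_viability <= 1.0, "drug_a_viability", "must be in [0, 1]")
        _require(0.0 <= self.drug_b_viability <= 1.0, "drug_b_viability", "must be in [0, 1]")
        _require(self.interaction_factor > 0, "interaction_factor", "must be > 0")
        _require(self.noise_cv >= 0, "noise_cv", "must be >= 0")
        _require(self.n_replicate_wells >= 1, "n_replicate_wells", "must be a positive integer")
        _require(self.n_experiments >= 1, "n_experiments", "must be a positive integer")
        _require(self.control_signal > 0, "control_signal", "must be > 0")


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGH"
    names = [f"{r}{c:02d}" for r in rows for c in range(1, 13)]
    if n > len(names):  # spill onto a second virtual plate area
        names = [f"{r}{c:02d}" for r in rows for c in range(1, 1 + (n // len(rows) + 1))]
    return names[:n]


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with E[factor] = 1 and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_plate(spec: PlateSimSpec) -> pd.DataFrame:
    """Simulate raw-well luminescence tables for a combination screen.

    Emits, per experiment (one plate each): solvent-only control wells,
    monotherapy wells for agents A and B, and combination wells,
    ``n_replicate_wells`` of each. Ground truth (true viabilities and the
    planted interaction factor) is attached as ``DataFrame.attrs['ground_truth']``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    ya, yb = spec.drug_a_viability, spec.drug_b_viability
    y_combo = ya * yb / spec.interaction_factor
    b_conc = 0.0 if spec.b_is_radiation else spec.drug_b_conc_uM
    b_dose = spec.b_dose_Gy if spec.b_is_radiation else 0.0

    # (drug_a_conc, drug_b_conc, dose_Gy, true viability)
    conditions = [
        (0.0, 0.0, 0.0, 1.0),
        (spec.drug_a_conc_uM, 0.0, 0.0, ya),
        (0.0, b_conc, b_dose, yb),
        (spec.drug_a_conc_uM, b_conc, b_dose, y_combo),
    ]

    rows = []
    for exp in range(1, spec.n_experiments + 1):
        wells = iter(_well_names(4 * spec.n_replicate_wells))
        noise = _lognormal_noise(rng, spec.noise_cv, 4 * spec.n_replicate_wells)
        i = 0
        for ca, cb, dose, viab in conditions:
            for _ in range(spec.n_replicate_wells):
                rows.append(
                    {
                        "plate_id": f"plate{exp:02d}",
                        "well": next(wells),
                        "drug_a_conc_uM": ca,
                        "drug_b_conc_uM": cb,
                        "dose_Gy": dose,
                        "solvent": spec.solvent,
                        "raw_signal": viab * spec.control_signal * noise[i],
                        "experiment_id": f"exp{exp:02d}",
                    }
                )
                i += 1

    table = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    table.attrs["ground_truth"] = {
        "viability_a": ya,
        "viability_b": yb,
        "viability_combination": y_combo,
        "interaction_factor": spec.interaction_factor,
        "spec": asdict(spec),
    }
    return table


# ---------------------------------------------------------------------------
# colony images
# ---------------------------------------------------------------------------


@dataclass
class ColonyImageSpec:
    """A synthetic clonogenic-well image: disks on a smooth ramp plus noise.

    ``colonies`` is a list of ``((row_px, col_px), radius_um, intensity)``
    tuples. Intensities and noise are in arbitrary grayscale units on top of
    ``base_level``; ``background_gradient`` is the peak-to-peak amplitude of a
    diagonal linear ramp emulating uneven illumination.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 5.0
    colonies: list = field(default_factory=list)
    background_gradient: float = 200.0
    noise_sd: float = 0.0
    base_level: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        _require(len(self.image_shape) == 2 and min(self.image_shape) > 0, "image_shape", "must be two positive ints")
        _require(self.pixel_size_um > 0, "pixel_size_um", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        nr, nc = self.image_shape
        for k, (center, radius_um, intensity) in enumerate(self.colonies):
            _require(radius_um > 0, f"colonies[{k}].radius_um", "must be > 0")
            r, c = center
            _require(0 <= r < nr and 0 <= c < nc, f"colonies[{k}].center", "must lie inside the image")
            _require(intensity > 0, f"colonies[{k}].intensity", "must be > 0")


def simulate_colony_image(spec: ColonyImageSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a grayscale well image plus its ground-truth colony table.

    Returns ``(image, truth)`` where ``truth`` has one row per colony with its
    rendered area in µm² (pixel count x pixel area), circularity 1.0 (disks),
    and an ``overlaps`` flag set when any two disks intersect.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nr, nc = spec.image_shape
    rr, cc = np.mgrid[0:nr, 0:nc]

    image = spec.base_level + spec.background_gradient * (rr + cc) / (nr + nc - 2)
    image = image.astype(float)

    records = []
    masks = []
    for k, ((r0, c0), radius_um, intensity) in enumerate(spec.colonies):
        radius_px = radius_um / spec.pixel_size_um
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
        image[mask] += intensity
        masks.append(((r0, c0), radius_px, mask))
        records.append(
            {
                "colony_id": k,
                "row_px": r0,
                "col_px": c0,
                "radius_um": radius_um,
                "intensity": intensity,
                "area_um2": int(mask.sum()) * spec.pixel_size_um**2,
                "circularity": 1.0,
                "overlaps": False,
            }
        )

    truth = pd.DataFrame(
        records,
        columns=[
            "colony_id", "row_px", "col_px", "radius_um", "intensity",
            "area_um2", "circularity", "overlaps",
        ],
    )
    # flag any pair of intersecting disks
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            (ri, ci), pi, _ = masks[i]
            (rj, cj), pj, _ = masks[j]
            if np.hypot(ri - rj, ci - cj) < pi + pj:
                truth.loc[i, "overlaps"] = True
                truth.loc[j, "overlaps"] = True

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return image, truth


def random_colony_spec(
    n_colonies: int,
    seed: int,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 5.0,
    radius_um_range: tuple[float, float] = (55.0, 90.0),
    intensity_range: tuple[float, float] = (800.0, 1500.0),
    background_gradient: float = 200.0,
    noise_sd: float = 0.0,
    margin_px: int = 6,
) -> ColonyImageSpec:
    """Place ``n_colonies`` non-overlapping disks at random positions.

    Uses rejection sampling with a separation margin so colonies stay disjoint
    and clear of the image border; raises if placement fails repeatedly
    (image too crowded).
    """
    rng = np.random.default_rng(seed)
    nr, nc = image_shape
    placed: list[tuple[float, float, float]] = []  # (row, col, radius_px)
    colonies = []
    attempts = 0
    while len(colonies) < n_colonies:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place non-overlapping colonies; reduce n_colonies")
        radius_um = rng.uniform(*radius_um_range)
        radius_px = radius_um / pixel_size_um
        r0 = rng.uniform(radius_px + margin_px, nr - radius_px - margin_px)
        c0 = rng.uniform(radius_px + margin_px, nc - radius_px - margin_px)
        if any(np.hypot(r0 - r, c0 - c) < radius_px + rp + margin_px for r, c, rp in placed):
            continue
        placed.append((r0, c0, radius_px))
        colonies.append(((r0, c0), radius_um, rng.uniform(*intensity_range)))
    return ColonyImageSpec(
        image_shape=image_shape,
        pixel_size_um=pixel_size_um,
        colonies=colonies,
        background_gradient=background_gradient,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_colony_image(image: np.ndarray, truth: pd.DataFrame, path: str | Path) -> Path:
    """Write a 16-bit grayscale TIFF plus the ground-truth CSV next to it."""
    import tifffile

    path = Path(path)
    data = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


# ---------------------------------------------------------------------------
# DNA-content event lists
# ---------------------------------------------------------------------------


@dataclass
class DnaContentSpec:
    """Four-component DNA-content mixture (sub-G1, G1, S, G2/M).

    ``g1_mode`` is the 2N peak position in arbitrary fluorescence units; the
    G2/M component is centred at exactly twice that. ``cv`` is the peak width
    as a fraction of the mode. The sub-G1 component is uniform on
    ``[0.25, 0.75] x g1_mode`` — strictly below the 2N peak, as fragmented-DNA
    events are.
    """

    n_events: int = 10_000
    fractions: tuple[float, float, float, float] = (0.05, 0.55, 0.15, 0.25)
    g1_mode: float = 200.0
    cv: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        _require(fr.size == 4 and np.all(fr >= 0), "fractions", "must be four nonnegative values")
        _require(abs(fr.sum() - 1.0) <= 1e-9, "fractions", "must sum to 1 within 1e-9")
        _require(self.g1_mode > 0, "g1_mode", "must be > 0")
        _require(self.cv > 0, "cv", "must be > 0")
        if self.n_events < 100:
            raise ValueError("n_events < 100: landmark detection is undefined at tiny n")


def simulate_dna_content(spec: DnaContentSpec) -> tuple[np.ndarray, dict]:
    """Draw per-event DNA intensities; returns ``(events, ground_truth)``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g1 = spec.g1_mode
    counts = rng.multinomial(spec.n_events, np.asarray(spec.fractions, dtype=float))

    parts = [
        rng.uniform(0.25 * g1, 0.75 * g1, size=counts[0]),            # sub-G1
        rng.normal(g1, spec.cv * g1, size=counts[1]),                 # G1 (2N)
        rng.uniform(g1 * (1 + spec.cv), g1 * (2 - spec.cv), counts[2]),  # S
        rng.normal(2 * g1, spec.cv * 2 * g1, size=counts[3]),         # G2/M (4N)
    ]
    events = np.concatenate(parts)
    rng.shuffle(events)
    events = np.clip(events, 1e-9, None)

    truth = {
        "fractions": tuple(float(f) for f in spec.fractions),
        "component_counts": counts.tolist(),
        "g1_mode": g1,
        "g2m_mode": 2 * g1,
        "empirical_subg1_fraction": counts[0] / spec.n_events,
    }
    return events, truth


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


@dataclass
class CountsSimSpec:
    """Two-group negative-binomial count matrix with planted gene sets.

    Counts for gene *g* in sample *s* are NB with mean
    ``baseline_g x library_size_factor_s x 2**(lfc_g)`` (the log2 effect
    applied in group 2 only) and a gamma-Poisson dispersion ``dispersion``
    (variance = mu + dispersion * mu^2). Gene baselines are log-normal around
    ``baseline_mean`` to mimic the spread of real libraries. ``planted_sets``
    is a list of ``(set_id, member_gene_ids, log2_effect)``; decoy sets of
    unperturbed genes are added for null calibration.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 3
    dispersion: float = 0.1
    baseline_mean: float = 200.0
    planted_sets: list = field(default_factory=list)
    library_size_factors: list | None = None
    n_decoy_sets: int = 20
    decoy_set_size: int = 50
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_genes >= 10, "n_genes", "must be >= 10")
        _require(self.n_samples_per_group >= 2, "n_samples_per_group", "must be >= 2")
        _require(self.dispersion > 0, "dispersion", "must be > 0")
        _require(self.baseline_mean > 0, "baseline_mean", "must be > 0")
        for set_id, genes, lfc in self.planted_sets:
            _require(np.isfinite(lfc), f"planted_sets[{set_id}].log2_effect", "must be finite")
            if len(set(genes)) != len(genes):
                raise ValueError(f"invalid field 'planted_sets[{set_id}]': duplicate gene ids")
        if self.library_size_factors is not None:
            lf = np.asarray(self.library_size_factors, dtype=float)
            _require(lf.size == 2 * self.n_samples_per_group, "library_size_factors", "one per sample required")
            _require(np.all(lf > 0), "library_size_factors", "must be positive")


def simulate_counts(
    spec: CountsSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Simulate a gene x sample count matrix, a sample sheet and gene sets.

    Returns ``(counts, samples, gene_sets)``: integer counts indexed by gene
    id with sample columns, a sample sheet with ``sample/group/replicate``
    columns (groups ``group1``/``group2``; planted effects act in ``group2``),
    and the gene-set collection (planted + decoys). Ground truth is attached
    as ``counts.attrs['ground_truth']``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    width = max(5, len(str(spec.n_genes)))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)])
    gene_index = {g: i for i, g in enumerate(genes)}

    n = spec.n_samples_per_group
    samples = pd.DataFrame(
        {
            "sample": [f"S{i:02d}" for i in range(1, 2 * n + 1)],
            "group": ["group1"] * n + ["group2"] * n,
            "replicate": list(range(1, n + 1)) * 2,
        }
    )
    lib = (
        np.ones(2 * n)
        if spec.library_size_factors is None
        else np.asarray(spec.library_size_factors, dtype=float)
    )

    # per-gene baselines: log-normal spread (sd 1 on the natural-log scale)
    baseline = spec.baseline_mean * rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)

    lfc = np.zeros(spec.n_genes)
    gene_sets: dict[str, list[str]] = {}
    for set_id, members, effect in spec.planted_sets:
        missing = [g for g in members if g not in gene_index]
        if missing:
            raise ValueError(f"planted set '{set_id}' references unknown gene ids: {missing[:5]}")
        idx = [gene_index[g] for g in members]
        lfc[idx] += effect
        gene_sets[set_id] = list(members)

    planted_genes = {g for members in gene_sets.values() for g in members}
    free = np.array([g for g in genes if g not in planted_genes])
    for k in range(spec.n_decoy_sets):
        size = min(spec.decoy_set_size, free.size)
        gene_sets[f"DECOY_{k + 1:03d}"] = list(rng.choice(free, size=size, replace=False))

    mu = baseline[:, None] * lib[None, :]
    group2 = (samples["group"] == "group2").to_numpy()
    mu[:, group2] *= 2.0 ** lfc[:, None]

    # NB via gamma-Poisson: shape r = 1/dispersion, p = r / (r + mu)
    r = 1.0 / spec.dispersion
    p = r / (r + mu)
    values = rng.negative_binomial(r, p)

    counts = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples["sample"])
    counts.attrs["ground_truth"] = {
        "log2_effects": dict(zip(genes[lfc != 0], lfc[lfc != 0])),
        "planted_sets": {sid: e for sid, _, e in spec.planted_sets},
        "library_size_factors": lib.tolist(),
    }
    return counts, samples, gene_sets


def write_counts_bundle(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write counts TSV, sample sheet CSV and GMT file into ``out_dir``."""
    from .genesets import write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.csv",
        "gene_sets": out / "gene_sets.gmt",
    }
    counts.to_csv(paths["counts"], sep="\t")
    samples.to_csv(paths["samples"], index=False)
    write_gmt(gene_sets, paths["gene_sets"])
    return paths
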