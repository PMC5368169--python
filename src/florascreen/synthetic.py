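"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data sources the analysis modules consume —
top-view rosette mask time series, longitudinal phenotype tables,
linear-scale expression matrices, qPCR Ct tables and toy proteomes — and
emit the planted truth beside every dataset so recovery can be scored
exactly.  Every generator is a pure function of its seed and parameters.

The rosette renderer follows the phyllotactic leaf cycle: leaves initiate
in pairs (opposite-decussate for the first two pairs, then a ≈137.5°
spiral), each expanding along a logistic schedule.  Two expanding leaves
make the silhouette elliptical; as older leaves catch up it rounds out
again, reproducing the oscillating circularity and the early eccentricity
peak seen in wild-type rosettes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .morphometrics import BinaryMask

__all__ = [
    "RosetteModel",
    "SimulationTruth",
    "render_rosette",
    "render_rosette_series",
    "simulate_longitudinal",
    "simulate_expression",
    "simulate_ct",
    "plant_ring_proteome",
]


@dataclass
class SimulationTruth:
    """Planted ground truth emitted beside each synthetic dataset."""

    kind: str
    details: dict = field(default_factory=dict)


@dataclass
class RosetteModel:
    """Parameters of the synthetic rosette growth model.

    Lengths in mm; times in days after stratification.  ``genotype_size``
    scales final blade length, ``genotype_interval`` scales the leaf
    initiation interval — the two knobs used to emulate mutant lines.
    """

    first_leaf_day: float = 6.0      # emergence of the first true-leaf pair
    leaf_interval_days: float = 2.5  # days between successive pairs
    divergence_deg: float = 137.5
    blade_max_mm: float = 16.0       # mature blade+petiole length
    expansion_rate: float = 0.9      # logistic rate (1/day)
    expansion_lag_days: float = 1.6  # logistic midpoint after emergence
    petiole_fraction: float = 0.32
    blade_aspect: float = 0.68      # blade width / blade length
    serration_depth: float = 0.0     # fraction of blade radius
    serration_freq: int = 7
    genotype_size: float = 1.0
    genotype_interval: float = 1.0
    jitter: float = 0.04             # relative per-leaf length jitter
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("blade_max_mm", "expansion_rate", "leaf_interval_days",
                     "petiole_fraction", "blade_aspect", "genotype_size",
                     "genotype_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _leaf_schedule(model: RosetteModel, day: float, rng: np.random.Generator):
    """Per-leaf (angle_deg, length_mm) for every leaf emerged by ``day``."""
    interval = model.leaf_interval_days * model.genotype_interval
    leaves = []
    i = 0
    while True:
        t_i = model.first_leaf_day + (i // 2) * interval
        if t_i > day:
            break
        if i < 4:  # two decussate pairs
            angle = (0.0, 180.0, 90.0, 270.0)[i]
        else:
            angle = (4 * 90.0 + (i - 3) * model.divergence_deg) % 360.0
        lmax = model.blade_max_mm * model.genotype_size
        lmax *= 1.0 + model.jitter * rng.standard_normal()
        age = day - t_i
        length = lmax / (1.0 + math.exp(
            -model.expansion_rate * (age - model.expansion_lag_days)))
        leaves.append((angle, max(length, 0.3)))
        i += 1
        if i > 200:
            break
    return leaves


def render_rosette(
    model: RosetteModel,
    day: float,
    image_size: int = 400,
    mm_per_px: float = 0.25,
    plant_id: str = "synthetic",
) -> tuple[BinaryMask, list]:
    """Render one binary rosette mask for a given day.

    Each leaf is a petiole segment plus an elliptical (optionally
    serrated) blade at its phyllotactic angle; a small central disc keeps
    the silhouette connected.  Anti-aliasing is off — pixels are hard
    foreground/background — so descriptor tests are deterministic.
    """
    rng = np.random.default_rng((model.seed, int(day * 8)))
    leaves = _leaf_schedule(model, day, rng)
    # auto-resize if the largest leaf would overflow the frame
    max_len_px = max((l for _, l in leaves), default=1.0) / mm_per_px
    need = int(2 * max_len_px + 10)
    if need > image_size:
        image_size = need
    grid = np.zeros((image_size, image_size), bool)
    c0 = image_size / 2.0
    rr, cc = draw_disk((c0, c0), max(2.0, 1.2 / mm_per_px), shape=grid.shape)
    grid[rr, cc] = True
    for angle, length_mm in leaves:
        L = length_mm / mm_per_px
        theta = math.radians(angle)
        ux, uy = math.cos(theta), math.sin(theta)
        pet = model.petiole_fraction * L
        blade = L - pet
        half_w = max(1.0, 0.06 * L)
        # petiole: thin quadrilateral from centre to blade base
        px, py = -uy, ux
        quad_r = [c0 - half_w * py, c0 + pet * uy - half_w * py,
                  c0 + pet * uy + half_w * py, c0 + half_w * py]
        quad_c = [c0 - half_w * px, c0 + pet * ux - half_w * px,
                  c0 + pet * ux + half_w * px, c0 + half_w * px]
        rr, cc = draw_polygon(quad_r, quad_c, shape=grid.shape)
        grid[rr, cc] = True
        # blade: polygon of an ellipse (+ radial serration) centred mid-blade
        bc_r = c0 + (pet + blade / 2.0) * uy
        bc_c = c0 + (pet + blade / 2.0) * ux
        a = blade / 2.0
        b = max(1.0, model.blade_aspect * blade / 2.0)
        phi = np.linspace(0.0, 2 * math.pi, 120, endpoint=False)
        r_ell = (a * b) / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        if model.serration_depth > 0:
            r_ell = r_ell * (
                1.0 - model.serration_depth / 2.0
                + model.serration_depth / 2.0
                * np.cos(model.serration_freq * phi)
            )
        xs = bc_c + r_ell * np.cos(phi + theta)
        ys = bc_r + r_ell * np.sin(phi + theta)
        rr, cc = draw_polygon(ys, xs, shape=grid.shape)
        grid[rr, cc] = True
    return (
        BinaryMask(grid, mm_per_px=mm_per_px, plant_id=plant_id,
                   day=int(round(day))),
        leaves,
    )


def render_rosette_series(
    model: RosetteModel,
    days: range | list = range(10, 21),
    image_size: int = 400,
    mm_per_px: float = 0.25,
    plant_id: str = "synthetic",
) -> tuple[list[BinaryMask], SimulationTruth]:
    """Daily mask series for one plant plus the planted truth."""
    masks, leaf_counts = [], {}
    for day in days:
        mask, leaves = render_rosette(model, day, image_size, mm_per_px,
                                      plant_id)
        masks.append(mask)
        leaf_counts[int(day)] = len(leaves)
    truth = SimulationTruth(
        kind="rosette_series",
        details={
            "leaf_count_per_day": leaf_counts,
            "genotype_size": model.genotype_size,
            "genotype_interval": model.genotype_interval,
            "seed": model.seed,
        },
    )
    return masks, truth


# ---------------------------------------------------------------------------
# longitudinal phenotype tables

#: Baseline wild-type mean curves per descriptor: value = f(day).
#: Area/perimeter follow the lag + exponential phases of rosette growth;
#: the dimensionless descriptors use smooth interpolations of typical
#: wild-type dynamics over days 10-20.
_BASE_CURVES = {
    "area": lambda t: 4.0 * (t - 8.0) ** 2 + 25.0,          # mm², ~600 at d20
    "perimeter": lambda t: 14.0 * (t - 8.0) + 40.0,          # mm
    "roundness": lambda t: 0.45 - 0.02 * (t - 10.0),
    "roundness2": lambda t: 0.85 + 0.08 * math.sin(math.pi * (t - 10.0) / 2.0),
    "isotropy": lambda t: 0.80 + 0.06 * math.sin(math.pi * (t - 10.0) / 2.0),
    "eccentricity": lambda t: 0.55 + 0.25 * math.exp(-((t - 12.0) ** 2) / 4.0),
    "rms": lambda t: 0.25 + 0.30 * math.exp(-((t - 12.0) ** 2) / 4.0),
    "compactness": lambda t: 0.85 - 0.025 * (t - 10.0),
    "sol": lambda t: 8.0 + 2.0 * (t - 10.0),
}

#: Typical measurement noise per descriptor (SD, same units as the value).
_BASE_NOISE = {
    "area": 30.0, "perimeter": 12.0, "roundness": 0.04, "roundness2": 0.04,
    "isotropy": 0.04, "eccentricity": 0.06, "rms": 0.08,
    "compactness": 0.04, "sol": 2.5,
}


def simulate_longitudinal(
    n_plants: int = 20,
    genotype_effects: dict[str, dict[str, float]] | None = None,
    noise_sd: float | dict[str, float] | None = None,
    days: range | list = range(10, 21),
    parameters: tuple[str, ...] = ("area",),
    control: str = "Col-0",
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Long-format phenotype table with planted genotype effects.

    ``genotype_effects`` maps mutant genotype → {"offset": additive shift,
    "slope": additive per-day trend}; the control carries no effect.
    Values are the wild-type mean curve plus effects plus iid Gaussian
    noise (per-descriptor defaults unless ``noise_sd`` overrides).
    """
    if n_plants < 2:
        raise ValueError("need at least 2 plants per genotype")
    genotype_effects = genotype_effects or {}
    rng = np.random.default_rng(seed)
    genotypes = [control] + list(genotype_effects)
    days = list(days)
    t_mid = (days[0] + days[-1]) / 2.0
    rows = []
    for geno in genotypes:
        eff = genotype_effects.get(geno, {})
        offset = eff.get("offset", 0.0)
        slope = eff.get("slope", 0.0)
        for p in range(n_plants):
            pid = f"{geno}_{p:02d}"
            for param in parameters:
                if isinstance(noise_sd, dict):
                    sd = noise_sd.get(param, _BASE_NOISE[param])
                elif noise_sd is not None:
                    sd = noise_sd
                else:
                    sd = _BASE_NOISE[param]
                base = _BASE_CURVES[param]
                for day in days:
                    value = (base(float(day)) + offset
                             + slope * (day - t_mid)
                             + sd * rng.standard_normal())
                    rows.append((pid, geno, int(day), param, value))
    data = pd.DataFrame(
        rows, columns=["plant_id", "genotype", "day", "parameter", "value"]
    )
    truth = SimulationTruth(
        kind="longitudinal",
        details={"effects": genotype_effects, "n_plants": n_plants,
                 "seed": seed},
    )
    return data, truth


# ---------------------------------------------------------------------------
# expression matrices


def _agi_ids(n: int, rng: np.random.Generator) -> list[str]:
    ids: set[str] = set()
    while len(ids) < n:
        ids.add(f"AT{rng.integers(1, 6)}G{rng.integers(0, 70000):05d}")
    return sorted(ids)


def simulate_expression(
    n_genes: int = 400,
    categories: tuple[str, ...] = ("bolting", "young flower",
                                   "developed flower", "flowers and siliques"),
    n_up: int = 37,
    fold_range: tuple[float, float] = (2.5, 8.0),
    null_fold_range: tuple[float, float] = (0.6, 1.8),
    reference: str = "developed rosette",
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Linear-scale expression matrix with planted up-regulated genes.

    Reference expression is log-normal; per category, ``n_up`` randomly
    chosen genes are multiplied by a fold drawn from ``fold_range``
    (strictly above 2) and all others by a fold from ``null_fold_range``
    (strictly below 2), so the planted up-sets are exactly recoverable
    under the >2-fold rule.
    """
    if n_up > n_genes:
        raise ValueError("n_up cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = _agi_ids(n_genes, rng)
    ref = np.exp(rng.normal(6.0, 1.0, n_genes))
    matrix = pd.DataFrame({reference: ref}, index=pd.Index(genes, name="gene_id"))
    planted: dict[str, list[str]] = {}
    for cat in categories:
        chosen = sorted(rng.choice(n_genes, size=n_up, replace=False))
        folds = rng.uniform(*null_fold_range, n_genes)
        folds[chosen] = rng.uniform(*fold_range, n_up)
        matrix[cat] = ref * folds
        planted[cat] = [genes[i] for i in chosen]
    truth = SimulationTruth(
        kind="expression",
        details={"planted_up": planted, "reference": reference, "seed": seed},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables

DEFAULT_REFERENCE_GENES = ("TIP41-like", "AP2M", "PTB1")


def simulate_ct(
    target_folds: dict[str, float],
    references: tuple[str, ...] = DEFAULT_REFERENCE_GENES,
    replicate_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Ct table with planted mutant/control fold changes.

    The mutant's target Ct is shifted by −log2(fold) relative to the
    control while reference genes stay level, so the ΔΔCt pipeline
    recovers each planted fold exactly at zero replicate noise.
    """
    for gene, fold in target_folds.items():
        if fold <= 0:
            raise ValueError(f"fold for {gene!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []

    def emit(sample, gene, role, base):
        for rep in range(1, n_replicates + 1):
            ct = base + replicate_sd * rng.standard_normal()
            rows.append((sample, gene, role, rep, ct))

    for ref in references:
        base = rng.uniform(18.0, 24.0)
        emit("control", ref, "reference", base)
        emit("mutant", ref, "reference", base)
    for gene, fold in target_folds.items():
        base = rng.uniform(20.0, 27.0)
        emit("control", gene, "target", base)
        emit("mutant", gene, "target", base - math.log2(fold))
    table = pd.DataFrame(
        rows, columns=["sample", "gene", "role", "replicate", "ct"]
    )
    truth = SimulationTruth(
        kind="ct",
        details={"target_folds": dict(target_folds),
                 "replicate_sd": replicate_sd, "seed": seed},
    )
    return table, truth


# ---------------------------------------------------------------------------
# toy proteomes with planted RING motifs

#: Filler alphabet free of potential metal ligands (no C/H/D/S/T), so the
#: planted ligand positions are provably the only consensus match.
_FILLER = "AGILMNPQVWFYEKR"

#: Residue tuples producing each canonical subtype (positions 4, 5 vary).
MOTIF_RESIDUES = {
    "HC": ("C", "C", "C", "H", "C", "C", "C", "C"),
    "H2": ("C", "C", "C", "H", "H", "C", "C", "C"),
    "v": ("C", "C", "C", "C", "H", "C", "C", "C"),
    "C2": ("C", "C", "C", "C", "C", "C", "C", "C"),
    "D": ("C", "C", "C", "D", "C", "C", "C", "C"),
    "S/T": ("C", "C", "C", "S", "C", "C", "C", "C"),
}


def _random_gaps(rng: np.random.Generator) -> list[int]:
    from .ring import DEFAULT_SPACING

    return [int(rng.integers(lo, hi + 1)) for lo, hi in DEFAULT_SPACING.gaps]


def plant_ring_proteome(
    n_proteins: int = 20,
    motif_classes: list[str | None] | None = None,
    length_range: tuple[int, int] = (120, 200),
    seed: int = 0,
) -> tuple[dict[str, str], list, SimulationTruth]:
    """Toy proteome with RING motifs planted at known positions.

    ``motif_classes`` gives one entry per protein: a subtype key from
    :data:`MOTIF_RESIDUES` or ``None`` for a motif-free decoy (default:
    cycle through the subtypes with every fourth protein a decoy).
    Returns (sequences by protein id, InterProScan-style annotations
    covering each planted span, truth with positions and classes).
    """
    from .ring import DomainAnnotation

    rng = np.random.default_rng(seed)
    if motif_classes is None:
        keys = list(MOTIF_RESIDUES)
        motif_classes = [
            None if i % 4 == 3 else keys[i % len(keys)]
            for i in range(n_proteins)
        ]
    if len(motif_classes) != n_proteins:
        raise ValueError("motif_classes length must equal n_proteins")
    proteins: dict[str, str] = {}
    annotations = []
    planted = {}
    for i, cls in enumerate(motif_classes):
        pid = f"AT{(i % 5) + 1}G{10000 + 10 * i:05d}.1"
        length = int(rng.integers(*length_range))
        seq = list(rng.choice(list(_FILLER), size=length))
        if cls is not None:
            gaps = _random_gaps(rng)
            motif_len = 8 + sum(gaps)
            start = int(rng.integers(5, max(6, length - motif_len - 5)))
            residues = MOTIF_RESIDUES[cls]
            pos = start
            positions = []
            for j, res in enumerate(residues):
                seq[pos] = res
                positions.append(pos + 1)  # 1-based
                if j < 7:
                    pos += gaps[j] + 1
            span = (max(1, positions[0] - 3),
                    min(length, positions[-1] + 3))
            annotations.append(DomainAnnotation(
                protein_id=pid, signature_db="Pfam",
                signature_accession="PF13639",
                start=span[0], end=span[1],
            ))
            planted[pid] = {
                "class": cls,
                "positions": positions,
                "residues": list(residues),
            }
        else:
            planted[pid] = None
        proteins[pid] = "".join(seq)
    truth = SimulationTruth(
        kind="ring_proteome", details={"planted": planted, "seed": seed}
    )
    return proteins, annotations, truth
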