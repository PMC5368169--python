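"""End-to-end orchestration of the analysis stages.

Each ``run_*`` function composes one analysis path — masks → descriptors →
genotype statistics, expression matrix → candidate sets, Ct table →
classifications, proteome → RING hits — reading and writing the formats in
:mod:`florascreen.io`.  Runs are deterministic: re-running an unchanged
configuration reproduces every tabular output byte for byte (plots exempt).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expression, growth, io, qpcr, ring
from .morphometrics import DESCRIPTOR_NAMES, EmptyMaskError, describe

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_phenotype", "run_screen", "run_qpcr",
           "run_ring", "run_synth"]

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration shared by the pipeline subcommands."""

    output_dir: str = "."
    metadata: str | None = None
    mm_per_px: float = 0.25
    day_start: int = 10
    day_end: int = 20
    alpha: float = 0.05
    control: str = "Col-0"
    order_overrides: dict = field(default_factory=dict)
    expression_matrix: str | None = None
    reference_column: str = "developed rosette"
    log2fc_threshold: float = 1.0
    ct_table: str | None = None
    proteome: str | None = None
    domain_table: str | None = None
    old_gene_set: str | None = None
    evidence: str | None = None
    block: str | None = None
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.day_start < self.day_end:
            raise ValueError("analysis window start must precede end")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _out(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_phenotype(config: RunConfig) -> dict:
    """Masks → descriptor table → per-parameter genotype comparison.

    Per-plant failures (missing file, empty mask) quarantine the plant and
    are reported in the QC summary; they never abort the batch.
    """
    if config.metadata is None:
        raise ValueError("phenotype run needs a metadata CSV")
    meta = io.load_metadata(config.metadata)
    meta = meta[(meta["day"] >= config.day_start) & (meta["day"] <= config.day_end)]
    if meta.empty:
        raise ValueError("no mask records inside the analysis window")
    rows, quarantined = [], []
    for rec in meta.itertuples():
        try:
            mask = io.load_mask(rec.path, mm_per_px=rec.mm_per_px,
                                plant_id=str(rec.plant_id), day=int(rec.day))
            desc = describe(mask)
        except (FileNotFoundError, EmptyMaskError) as exc:
            logger.warning("phenotype plant=%s day=%s quarantined: %s",
                           rec.plant_id, rec.day, exc)
            quarantined.append({"plant_id": str(rec.plant_id),
                                "day": int(rec.day), "reason": str(exc)})
            continue
        flags = ";".join(desc.qc_flags)
        for name, value in desc.as_dict().items():
            rows.append((str(rec.plant_id), str(rec.genotype), int(rec.day),
                         name, value, flags))
    descriptors = pd.DataFrame(
        rows,
        columns=["plant_id", "genotype", "day", "parameter", "value",
                 "qc_flags"],
    )
    out = _out(config)
    _write_csv(descriptors, out / "descriptors.csv")

    comparisons = []
    genotypes = [g for g in descriptors["genotype"].unique()
                 if g != config.control]
    for geno in genotypes:
        sub = descriptors[descriptors["genotype"].isin([config.control, geno])]
        for param in DESCRIPTOR_NAMES:
            order = config.order_overrides.get(param,
                                               growth.default_order(param))
            try:
                cmp_ = growth.compare_genotypes(sub, param, order,
                                                control=config.control)
            except ValueError as exc:
                logger.warning("comparison %s/%s failed: %s", geno, param, exc)
                continue
            comparisons.append({
                "genotype": geno, "parameter": param,
                "polynomial_order": cmp_.polynomial_order,
                "chisq": cmp_.chisq_stat, "df": cmp_.df,
                "p_value": cmp_.p_value, "n_obs": cmp_.n_obs,
                "stars": cmp_.stars,
            })
    comparison_df = pd.DataFrame(comparisons)
    _write_csv(comparison_df, out / "model_comparisons.csv")
    summary = {
        "n_plants": int(descriptors["plant_id"].nunique()),
        "n_quarantined": len(quarantined),
        "quarantined": quarantined,
        "significant": [
            {"genotype": c["genotype"], "parameter": c["parameter"],
             "p_value": c["p_value"]}
            for c in comparisons if c["p_value"] < config.alpha
        ],
    }
    (out / "phenotype_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    if config.make_plots:
        _plot_daily_means(descriptors, out, config)
    return {"descriptors": descriptors, "comparisons": comparison_df,
            "summary": summary}


def _plot_daily_means(descriptors: pd.DataFrame, out: Path,
                      config: RunConfig) -> None:
    """Daily means ± 95% CI per genotype with fitted polynomial curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    for param in DESCRIPTOR_NAMES:
        sub = descriptors[descriptors["parameter"] == param]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for geno, g in sub.groupby("genotype"):
            agg = g.groupby("day")["value"].agg(["mean", "sem", "count"])
            ci = 1.96 * agg["sem"]
            ax.errorbar(agg.index, agg["mean"], yerr=ci, fmt="o", ms=3,
                        capsize=2, label=geno)
            order = config.order_overrides.get(
                param, growth.default_order(param))
            days = np.linspace(agg.index.min(), agg.index.max(), 100)
            coeffs = np.polyfit(g["day"], g["value"],
                                min(order, g["day"].nunique() - 1))
            ax.plot(days, np.polyval(coeffs, days), lw=1)
        ax.set_xlabel("days after stratification")
        ax.set_ylabel(param)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"daily_{param}.png", dpi=120)
        plt.close(fig)


def run_screen(config: RunConfig) -> dict:
    """Expression matrix → ranked per-category candidates, union, Venn."""
    if config.expression_matrix is None:
        raise ValueError("screen run needs an expression matrix CSV")
    matrix = pd.read_csv(config.expression_matrix, index_col=0)
    categories = [c for c in matrix.columns if c != config.reference_column]
    result = expression.screen_categories(
        matrix, categories, config.reference_column,
        threshold=config.log2fc_threshold,
    )
    out = _out(config)
    for cat, up in result["up"].items():
        safe = cat.replace(" ", "_").replace("/", "-")
        _write_csv(
            pd.DataFrame({"gene_id": up.index, "log2fc": up.to_numpy()}),
            out / f"up_{safe}.csv",
        )
    (out / "union_genes.txt").write_text(
        "".join(f"{g}\n" for g in result["union"]))
    if "venn" in result:
        venn_json = {
            "&".join(k): v for k, v in result["venn"].items()
        }
        (out / "venn.json").write_text(
            json.dumps(venn_json, indent=2, sort_keys=True) + "\n")
    return result


def run_qpcr(config: RunConfig) -> pd.DataFrame:
    """Ct table → fold changes and mutant-expression classes."""
    if config.ct_table is None:
        raise ValueError("qpcr run needs a Ct table CSV")
    table = pd.read_csv(config.ct_table)
    result = qpcr.quantify_all(table)
    _write_csv(result, _out(config) / "classifications.csv")
    return result


def run_ring(config: RunConfig) -> dict:
    """Proteome + domain annotations → RING hits and reconciliation."""
    if config.proteome is None or config.domain_table is None:
        raise ValueError("ring run needs a proteome FASTA and a domain TSV")
    proteins = io.read_fasta(config.proteome)
    annotations = ring.parse_domain_table(config.domain_table)
    hits, signature_only = ring.screen_proteome(proteins, annotations)
    out = _out(config)
    hits_df = pd.DataFrame([
        {"protein_id": h.protein_id,
         "span_start": h.span[0], "span_end": h.span[1],
         "ligand_positions": ";".join(map(str, h.ligand_positions)),
         "ligand_residues": "".join(h.ligand_residues),
         "ring_class": h.ring_class}
        for h in hits
    ])
    _write_csv(hits_df, out / "ring_hits.csv")
    result = {"hits": hits, "signature_only": signature_only}
    if config.old_gene_set is not None:
        old = [line.strip() for line
               in Path(config.old_gene_set).read_text().splitlines()
               if line.strip()]
        evidence = {}
        if config.evidence is not None:
            evidence = json.loads(Path(config.evidence).read_text())
        report = ring.reconcile([h.protein_id for h in hits], old, evidence)
        payload = {
            "matched": sorted(report.matched),
            "newly_identified": sorted(report.newly_identified),
            "dropped": report.dropped,
            "unresolved": sorted(report.unresolved),
            "counts": report.counts,
        }
        (out / "reconciliation.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        result["reconciliation"] = report
    return result


def run_synth(config: RunConfig, what: str = "all") -> dict:
    """Generate synthetic inputs (and their truth files) for each stage."""
    from . import synthetic

    out = _out(config)
    written: dict[str, list[str]] = {}

    def record(kind: str, *paths: Path) -> None:
        written.setdefault(kind, []).extend(str(p) for p in paths)

    def dump_truth(truth, path: Path) -> None:
        path.write_text(
            json.dumps(truth.details, indent=2, sort_keys=True) + "\n")

    if what in ("all", "masks"):
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        meta_rows = []
        truths = {}
        genotypes = {"Col-0": {}, "mutant": {"genotype_size": 0.8}}
        for gi, (geno, overrides) in enumerate(genotypes.items()):
            for p in range(2):
                pid = f"{geno}_{p:02d}"
                model = synthetic.RosetteModel(
                    seed=config.seed * 1009 + gi * 101 + p, **overrides)
                masks, truth = synthetic.render_rosette_series(
                    model, days=range(config.day_start, config.day_end + 1),
                    mm_per_px=config.mm_per_px, plant_id=pid)
                truths[pid] = truth.details
                for mask in masks:
                    path = mask_dir / f"{pid}_{mask.day}.png"
                    io.save_mask(mask, path)
                    meta_rows.append((pid, geno, mask.day, str(path),
                                      mask.mm_per_px))
        meta = pd.DataFrame(
            meta_rows,
            columns=["plant_id", "genotype", "day", "path", "mm_per_px"])
        _write_csv(meta, out / "metadata.csv")
        (out / "masks_truth.json").write_text(
            json.dumps(truths, indent=2, sort_keys=True) + "\n")
        record("masks", out / "metadata.csv")

    if what in ("all", "longitudinal"):
        data, truth = synthetic.simulate_longitudinal(
            genotype_effects={"mutant": {"offset": 90.0}},
            days=range(config.day_start, config.day_end + 1),
            seed=config.seed)
        _write_csv(data, out / "longitudinal.csv")
        dump_truth(truth, out / "longitudinal_truth.json")
        record("longitudinal", out / "longitudinal.csv")

    if what in ("all", "expression"):
        matrix, truth = synthetic.simulate_expression(seed=config.seed)
        matrix.to_csv(out / "expression.csv", float_format=FLOAT_FORMAT)
        dump_truth(truth, out / "expression_truth.json")
        record("expression", out / "expression.csv")

    if what in ("all", "ct"):
        table, truth = synthetic.simulate_ct(
            {"GENE_KO": 0.05, "GENE_KD": 0.3, "GENE_WT": 1.0,
             "GENE_UP": 4.0},
            seed=config.seed)
        _write_csv(table, out / "ct.csv")
        dump_truth(truth, out / "ct_truth.json")
        record("ct", out / "ct.csv")

    if what in ("all", "proteome"):
        proteins, annotations, truth = synthetic.plant_ring_proteome(
            seed=config.seed)
        fasta = out / "proteome.fasta"
        with open(fasta, "w") as fh:
            for pid, seq in proteins.items():
                fh.write(f">{pid}\n{seq}\n")
        tsv = out / "domains.tsv"
        with open(tsv, "w") as fh:
            for ann in annotations:
                fh.write("\t".join([
                    ann.protein_id, "-", str(len(proteins[ann.protein_id])),
                    ann.signature_db, ann.signature_accession, "RING domain",
                    str(ann.start), str(ann.end), "1e-10", "T", "01-01-2020",
                ]) + "\n")
        dump_truth(truth, out / "proteome_truth.json")
        record("proteome", fasta, tsv)

    return written
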