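"""Relative qPCR quantification by the 2^−ΔΔCt method.

For each target gene, ΔCt = mean target Ct − mean reference Ct is computed
per sample (technical replicates averaged first; multiple reference genes
combined by the arithmetic mean of their per-gene mean Cts), ΔΔCt is the
mutant-minus-control difference, and the linear fold change 2^−ΔΔCt is
classified against the screening thresholds: below 0.1 knock-out, 0.1–0.5
knock-down, above 2 up-regulated, otherwise unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FoldChangeResult",
    "delta_delta_ct",
    "classify_expression",
    "quantify_all",
]

KNOCK_OUT_MAX = 0.1
KNOCK_DOWN_MAX = 0.5
UP_REGULATED_MIN = 2.0


@dataclass
class FoldChangeResult:
    target: str
    fold_change: float
    ddct: float
    classification: str
    replicate_sd: dict = field(default_factory=dict)


def _mean_ct(sub: pd.DataFrame, sample: str, gene: str) -> tuple[float, float]:
    rows = sub[(sub["sample"] == sample) & (sub["gene"] == gene)]
    if rows.empty:
        raise ValueError(f"no Ct values for gene {gene!r} in sample {sample!r}")
    vals = rows["ct"].astype(float)
    if (vals <= 0).any():
        raise ValueError(f"non-positive Ct for gene {gene!r} in sample {sample!r}")
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    mutant: str = "mutant",
    control: str = "control",
) -> FoldChangeResult:
    """Fold change of ``target`` in the mutant relative to the control.

    ``table`` is long format with columns sample, gene, role
    (target/reference), replicate, ct.  Technical replicates are averaged
    before ΔCt; reference genes are combined by the arithmetic mean of
    their mean Cts.  Replicate SDs are reported per (sample, gene) as QC.
    """
    refs = sorted(table.loc[table["role"] == "reference", "gene"].unique())
    if not refs:
        raise ValueError("no reference genes in the Ct table")
    sds: dict = {}
    dct = {}
    for sample in (mutant, control):
        t_mean, t_sd = _mean_ct(table, sample, target)
        sds[(sample, target)] = t_sd
        ref_means = []
        for ref in refs:
            r_mean, r_sd = _mean_ct(table, sample, ref)
            sds[(sample, ref)] = r_sd
            ref_means.append(r_mean)
        dct[sample] = t_mean - sum(ref_means) / len(ref_means)
    ddct = dct[mutant] - dct[control]
    fc = 2.0 ** (-ddct)
    return FoldChangeResult(
        target=target,
        fold_change=fc,
        ddct=ddct,
        classification=classify_expression(fc),
        replicate_sd=sds,
    )


def classify_expression(fc: float) -> str:
    """Mutant-expression class from the linear fold change.

    Boundaries: 0.1 and 0.5 belong to knock-down (closed interval);
    exactly 2 is unchanged (strictly above 2 is up-regulated).
    """
    if not fc > 0:
        raise ValueError("fold change must be positive")
    if fc < KNOCK_OUT_MAX:
        return "knock-out"
    if fc <= KNOCK_DOWN_MAX:
        return "knock-down"
    if fc > UP_REGULATED_MIN:
        return "up-regulated"
    return "unchanged"


def quantify_all(
    table: pd.DataFrame,
    mutant: str = "mutant",
    control: str = "control",
) -> pd.DataFrame:
    """Fold change and classification for every target gene in the table."""
    targets = sorted(table.loc[table["role"] == "target", "gene"].unique())
    rows = []
    for t in targets:
        res = delta_delta_ct(table, t, mutant=mutant, control=control)
        rows.append({
            "target": t,
            "fold_change": res.fold_change,
            "ddct": res.ddct,
            "classification": res.classification,
        })
    return pd.DataFrame(rows)
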