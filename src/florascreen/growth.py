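"""Longitudinal genotype comparison and flowering statistics.

Daily descriptor values (plant × day × parameter, long format) are compared
between genotypes by fitting two nested polynomial curves: a pooled model
``value ~ poly(day, order)`` and an extended model adding a genotype main
effect plus genotype × polynomial interactions (a full per-genotype curve).
The models are ordinary least squares with Gaussian errors; the comparison
is a likelihood-ratio test referred to a χ² distribution with as many
degrees of freedom as coefficients added (``order + 1`` per non-reference
genotype).  A plant-level block bootstrap of the statistic is available as a
safeguard against within-plant correlation.

Flowering traits (leaves at bolting, days to bolting) are analysed by
one-way ANOVA with many-to-one Dunnett comparisons against the control
genotype; flower-defect counts by Fisher's exact test on a 2×2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_POLY_ORDERS",
    "GrowthFit",
    "ModelComparison",
    "default_order",
    "fit_growth_model",
    "compare_nested",
    "bootstrap_genotype_p",
    "compare_genotypes",
    "flowering_comparison",
    "defect_proportions",
    "significance_stars",
]

#: Polynomial order per descriptor used for the genotype comparison.
DEFAULT_POLY_ORDERS = {
    "area": 3,
    "perimeter": 3,
    "compactness": 4,
    "roundness": 5,
    "roundness2": 5,
    "isotropy": 6,
    "eccentricity": 6,
    "rms": 6,
    "sol": 3,
}


def default_order(parameter: str) -> int:
    """Polynomial order used for a descriptor (case-insensitive; accepts
    display spellings such as "Roundness 2" and "SOL")."""
    key = parameter.strip().lower().replace(" ", "")
    if key not in DEFAULT_POLY_ORDERS:
        raise KeyError(f"unknown parameter {parameter!r}")
    return DEFAULT_POLY_ORDERS[key]


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GrowthFit:
    """An OLS polynomial fit of one descriptor over days."""

    parameter: str
    order: int
    with_genotype: bool
    genotypes: tuple[str, ...]  # reference first
    coef: np.ndarray
    rss: float
    loglik: float
    n_obs: int
    n_params: int
    response_checksum: float

    @property
    def residual_variance(self) -> float:
        return self.rss / self.n_obs


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of nested growth models."""

    parameter: str
    polynomial_order: int
    chisq_stat: float
    df: int
    p_value: float
    n_obs: int
    genotypes: tuple[str, ...]

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _scaled_day(day: np.ndarray) -> np.ndarray:
    """Centre and scale the day axis to [−1, 1] (stabilises order-6 fits)."""
    lo, hi = day.min(), day.max()
    if hi == lo:
        return np.zeros_like(day, dtype=float)
    return 2.0 * (day - lo) / (hi - lo) - 1.0


def _design(
    day: np.ndarray, genotype: np.ndarray, order: int,
    genotypes: tuple[str, ...], with_genotype: bool,
) -> np.ndarray:
    x = _scaled_day(day.astype(float))
    cols = [x**k for k in range(order + 1)]
    if with_genotype:
        for g in genotypes[1:]:
            ind = (genotype == g).astype(float)
            cols.extend(ind * x**k for k in range(order + 1))
    return np.column_stack(cols)


def fit_growth_model(
    data: pd.DataFrame,
    parameter: str,
    order: int,
    with_genotype: bool = False,
    control: str | None = None,
) -> GrowthFit:
    """Least-squares polynomial fit of one descriptor across days.

    ``data`` is long format with columns plant_id, genotype, day,
    parameter, value.  When ``with_genotype`` is set, each non-reference
    genotype gets its own intercept and polynomial terms (``order + 1``
    extra coefficients).  The Gaussian log-likelihood uses the ML variance
    estimate RSS/n.
    """
    if order < 1:
        raise ValueError("order must be ≥ 1")
    sub = data[data["parameter"] == parameter]
    if sub.empty:
        raise ValueError(f"no records for parameter {parameter!r}")
    day = sub["day"].to_numpy()
    if len(np.unique(day)) < order + 2:
        raise ValueError(
            f"parameter {parameter!r}: need ≥ {order + 2} distinct days "
            f"for order {order}, got {len(np.unique(day))}"
        )
    geno = sub["genotype"].to_numpy()
    levels = list(dict.fromkeys(geno))
    if control is not None:
        if control not in levels:
            raise ValueError(f"control genotype {control!r} absent")
        levels.remove(control)
        levels.insert(0, control)
    genotypes = tuple(levels)
    if with_genotype and len(genotypes) < 2:
        raise ValueError("with_genotype requires ≥ 2 genotypes")
    y = sub["value"].to_numpy(float)
    X = _design(day, geno, order, genotypes, with_genotype)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design for parameter {parameter!r}")
    resid = y - X @ coef
    rss = float(resid @ resid)
    n = len(y)
    sigma2 = max(rss / n, np.finfo(float).tiny)
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    return GrowthFit(
        parameter=parameter,
        order=order,
        with_genotype=with_genotype,
        genotypes=genotypes,
        coef=coef,
        rss=rss,
        loglik=loglik,
        n_obs=n,
        n_params=X.shape[1],
        response_checksum=float(np.sum(y) + np.sum(y * y)),
    )


def compare_nested(model_small: GrowthFit, model_large: GrowthFit) -> ModelComparison:
    """Likelihood-ratio χ² test between nested polynomial fits.

    The statistic is ``2(ℓ_large − ℓ_small)`` on ``df`` equal to the
    coefficient-count difference.  Both fits must come from the same
    records (same n and response values) with the large model extending
    the small one.
    """
    if model_small.parameter != model_large.parameter:
        raise ValueError("models fit different parameters")
    if model_small.n_obs != model_large.n_obs or not math.isclose(
        model_small.response_checksum, model_large.response_checksum,
        rel_tol=1e-9, abs_tol=1e-9,
    ):
        raise ValueError("models were fit to different records")
    df = model_large.n_params - model_small.n_params
    if df <= 0 or model_small.order > model_large.order or (
        model_small.with_genotype and not model_large.with_genotype
    ):
        raise ValueError("model_small is not nested in model_large")
    stat = max(2.0 * (model_large.loglik - model_small.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return ModelComparison(
        parameter=model_large.parameter,
        polynomial_order=model_large.order,
        chisq_stat=stat,
        df=df,
        p_value=p,
        n_obs=model_large.n_obs,
        genotypes=model_large.genotypes,
    )


def compare_genotypes(
    data: pd.DataFrame,
    parameter: str,
    order: int | None = None,
    control: str | None = None,
) -> ModelComparison:
    """Convenience wrapper: pooled vs per-genotype curve for one descriptor."""
    if order is None:
        order = default_order(parameter)
    small = fit_growth_model(data, parameter, order, with_genotype=False,
                             control=control)
    large = fit_growth_model(data, parameter, order, with_genotype=True,
                             control=control)
    return compare_nested(small, large)


def bootstrap_genotype_p(
    data: pd.DataFrame,
    parameter: str,
    order: int | None = None,
    control: str | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Plant-level block bootstrap p-value for the genotype comparison.

    Whole plants are resampled with replacement under the null (genotype
    labels permuted across plants), preserving within-plant correlation
    that the OLS likelihood-ratio test ignores.
    """
    if order is None:
        order = default_order(parameter)
    obs = compare_genotypes(data, parameter, order, control).chisq_stat
    rng = np.random.default_rng(seed)
    sub = data[data["parameter"] == parameter]
    plants = sub["plant_id"].unique()
    labels = (
        sub.drop_duplicates("plant_id").set_index("plant_id")["genotype"]
    )
    count = 0
    for _ in range(n_boot):
        perm = rng.permutation(labels.to_numpy())
        relab = dict(zip(plants, perm))
        shuffled = sub.assign(genotype=sub["plant_id"].map(relab))
        stat = compare_genotypes(shuffled, parameter, order).chisq_stat
        if stat >= obs:
            count += 1
    return (count + 1) / (n_boot + 1)


# ---------------------------------------------------------------------------
# flowering-time statistics


def flowering_comparison(
    table: pd.DataFrame,
    control: str = "Col-0",
    traits: tuple[str, ...] = ("LAB", "DTB"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-genotype flowering summary with Dunnett-adjusted significance.

    ``table`` holds one row per plant with columns genotype and the trait
    columns (leaves at bolting, days to bolting).  Each trait is tested by
    one-way ANOVA and many-to-one Dunnett comparisons against ``control``
    at family-wise level ``alpha``.  Returns one row per genotype × trait
    with mean, SD, n, adjusted p (NaN for the control row) and a
    significance mark.
    """
    if control not in set(table["genotype"]):
        raise ValueError(f"control genotype {control!r} missing")
    groups = {g: sub for g, sub in table.groupby("genotype", sort=False)}
    if len(groups) < 2:
        raise ValueError("need at least two genotypes")
    if len(groups[control]) < 2:
        raise ValueError("control needs ≥ 2 plants")
    others = [g for g in table["genotype"].unique() if g != control]
    rows = []
    for trait in traits:
        ctrl_vals = groups[control][trait].to_numpy(float)
        samples = [groups[g][trait].to_numpy(float) for g in others]
        anova = stats.f_oneway(ctrl_vals, *samples)
        res = stats.dunnett(*samples, control=ctrl_vals, rng=0)
        for g, vals, p in zip(others, samples, np.atleast_1d(res.pvalue)):
            rows.append({
                "genotype": g, "trait": trait, "n": len(vals),
                "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                "p_adjusted": float(p), "significant": bool(p < alpha),
                "anova_p": float(anova.pvalue),
            })
        rows.append({
            "genotype": control, "trait": trait, "n": len(ctrl_vals),
            "mean": float(ctrl_vals.mean()),
            "sd": float(ctrl_vals.std(ddof=1)),
            "p_adjusted": float("nan"), "significant": False,
            "anova_p": float(anova.pvalue),
        })
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def defect_proportions(table: pd.DataFrame, control: str | None = None) -> pd.DataFrame:
    """Flower-defect percentages and Fisher exact tests against the control.

    ``table`` has one row per genotype with columns genotype, n_affected,
    n_total.  The displayed percentage is rounded half-up to the nearest
    integer; the raw fraction is retained.  Each non-control genotype is
    tested against the control with Fisher's exact test on the 2×2 table
    of affected/unaffected counts.
    """
    if (table["n_total"] <= 0).any():
        raise ValueError("n_total must be positive for every genotype")
    if ((table["n_affected"] < 0) | (table["n_affected"] > table["n_total"])).any():
        raise ValueError("n_affected must be within [0, n_total]")
    tab = table.reset_index(drop=True).copy()
    if control is None:
        control = tab.loc[0, "genotype"]
    frac = tab["n_affected"] / tab["n_total"]
    tab["fraction"] = frac
    tab["percent"] = [_round_half_up(100.0 * f) for f in frac]
    ctrl = tab[tab["genotype"] == control].iloc[0]
    pvals, odds = [], []
    for _, row in tab.iterrows():
        if row["genotype"] == control:
            pvals.append(float("nan"))
            odds.append(float("nan"))
            continue
        contingency = [
            [int(row["n_affected"]), int(row["n_total"] - row["n_affected"])],
            [int(ctrl["n_affected"]), int(ctrl["n_total"] - ctrl["n_affected"])],
        ]
        o, p = stats.fisher_exact(contingency)
        pvals.append(float(p))
        odds.append(float(o))
    tab["fisher_p"] = pvals
    tab["odds_ratio"] = odds
    return tab
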