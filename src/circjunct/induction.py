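"""Developmental induction statistics for circular versus linear splicing.

Junction counts across samples of increasing developmental age are
depth-normalized by the per-sample median count of well-covered
junctions and tested for age trend with a z statistic::

    z = <o, y> / sqrt(sum_i o_i^2 x_i / c_i)

where x_i = r_i / c_i are normalized counts, y_i = x_i - mean(x), o is
the age vector centered to zero sum and scaled to unit Euclidean norm,
and the denominator is the plug-in Poisson variance of the numerator.  Under exchangeability (no age trend) z is approximately standard
normal; it is maximized when counts increase linearly with age.  Linear
expression is quantified only from "exterior" splices -- linear
junctions with at least one splice site outside every well-expressed
circle of the gene -- since junctions inside a circle may come from
either isoform.  Two-timepoint designs are tested by non-overlap of
binomial confidence intervals on the circle fraction n_c/(n_c + n_l),
and tissue-specific outliers in the circle fraction are found from
regression residuals referred to a t distribution with an
overdispersion correction.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# exterior splice assignment

def assign_exterior(
    linear_junctions: pd.DataFrame,
    circles: pd.DataFrame,
    k_min: int = 10,
) -> dict[str, list[str]]:
    """Per-gene exterior linear junction sets.

    ``linear_junctions`` needs columns junction_id, gene_id, pos5, pos3
    (genomic splice-site positions); ``circles`` needs gene_id, lo, hi,
    count.  A linear junction is exterior to a circle when at least one
    of its splice sites lies outside the circle's genomic span; with
    multiple circles above ``k_min`` counts in a gene, the exterior set
    is the intersection over those circles.
    """
    strong = circles[circles["count"] > k_min]
    out: dict[str, list[str]] = {}
    for gene, lj in linear_junctions.groupby("gene_id"):
        gene_circles = strong[strong.gene_id == gene]
        keep = np.ones(len(lj), dtype=bool)
        for c in gene_circles.itertuples(index=False):
            inside5 = (lj.pos5 >= c.lo) & (lj.pos5 <= c.hi)
            inside3 = (lj.pos3 >= c.lo) & (lj.pos3 <= c.hi)
            keep &= ~(inside5 & inside3).to_numpy()
        out[gene] = sorted(lj.junction_id[keep])
    return out


# ---------------------------------------------------------------------------
# normalization and z scores

def normalization_constants(counts: pd.DataFrame, min_count: int = 5) -> pd.Series:
    """Per-sample depth constant: median count among junctions above ``min_count``."""
    out = {}
    for sample in counts.columns:
        col = counts[sample]
        qualifying = col[col > min_count]
        if qualifying.empty:
            raise ValueError(f"sample {sample!r} has no junction above {min_count} counts")
        out[sample] = float(qualifying.median())
    return pd.Series(out)


def age_contrast(ages: Sequence[float]) -> np.ndarray:
    """Age vector centered to zero sum then scaled to unit 2-norm."""
    o = np.asarray(ages, dtype=float)
    if o.size < 3:
        raise ValueError("need at least 3 samples")
    o = o - o.mean()
    norm = np.linalg.norm(o)
    if norm == 0:
        raise ValueError("ages are constant; no contrast available")
    return o / norm


def induction_zscore(
    r: Sequence[float], c: Sequence[float], ages: Sequence[float]
) -> float:
    """Age-trend z score for one junction; NaN when all counts are zero.

    The denominator is the plug-in Poisson variance of the contrast,
    var(<o, y>) = sum_i o_i^2 x_i / c_i, which makes z approximately
    standard normal under exchangeability.
    """
    r = np.asarray(r, dtype=float)
    c = np.asarray(c, dtype=float)
    o = age_contrast(ages)
    x = r / c
    y = x - x.mean()
    denom_sq = float(np.sum(o * o * x / c))
    if denom_sq <= 0:
        return float("nan")
    return float(np.dot(o, y) / np.sqrt(denom_sq))


def induction_table(
    counts: pd.DataFrame,
    ages: Mapping[str, float] | pd.Series,
    constants: pd.Series | None = None,
) -> pd.DataFrame:
    """Vectorized z scores for a junctions x samples count table."""
    ages = pd.Series(ages).reindex(counts.columns)
    if ages.isna().any():
        raise ValueError("every sample column needs an age")
    if constants is None:
        constants = normalization_constants(counts)
    c = constants.reindex(counts.columns).to_numpy(dtype=float)
    o = age_contrast(ages.to_numpy(dtype=float))
    x = counts.to_numpy(dtype=float) / c
    y = x - x.mean(axis=1, keepdims=True)
    denom_sq = (o * o * x / c).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (y @ o) / np.sqrt(denom_sq)
    z[denom_sq <= 0] = np.nan
    return pd.DataFrame({"junction_id": counts.index, "z": z}).set_index("junction_id")


def jrpkm(
    count: float,
    total_linear_mapped: float,
    read_len: int = 100,
    min_overlap: int = 10,
) -> float:
    """Junctional reads per kilobase of effective window per million linear reads.

    The effective junction length is 2*(read_len - min_overlap), 180 nt
    for 100-nt reads with a 10-nt minimum boundary overlap.
    """
    if total_linear_mapped <= 0:
        raise ValueError("total_linear_mapped must be positive")
    window = 2 * (read_len - min_overlap)
    return float(count / (total_linear_mapped / ((window / 1000) * 1e6)))


# ---------------------------------------------------------------------------
# two-timepoint circle-fraction test

def circle_fraction_ci(
    n_c: int, n_l: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float, float]:
    """Circle fraction n_c/(n_c+n_l) with a binomial confidence interval."""
    from statsmodels.stats.proportion import proportion_confint

    total = n_c + n_l
    if total <= 0:
        raise ValueError("n_c + n_l must be positive")
    meth = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    lo, hi = proportion_confint(n_c, total, alpha=1 - level, method=meth)
    return n_c / total, float(lo), float(hi)


def two_timepoint_test(
    early: tuple[int, int],
    late: tuple[int, int],
    level: float = 0.95,
    method: str = "wilson",
) -> str:
    """Direction of circle-fraction change between two timepoints.

    Returns ``increase``/``decrease`` when the binomial CIs on the two
    circle fractions do not overlap, else ``none``.  Working on the
    fraction intrinsically normalizes for sequencing depth.
    """
    if sum(early) <= 0 or sum(late) <= 0:
        return "none"
    _, lo_e, hi_e = circle_fraction_ci(*early, level=level, method=method)
    _, lo_l, hi_l = circle_fraction_ci(*late, level=level, method=method)
    if lo_l > hi_e:
        return "increase"
    if hi_l < lo_e:
        return "decrease"
    return "none"


# ---------------------------------------------------------------------------
# tissue outlier analysis

def outlier_analysis(
    table: pd.DataFrame,
    fdr_level: float = 0.001,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Residual-based tissue outliers in the circle fraction.

    ``table`` needs columns gene_id, sample_id, n_c, n_l, linear_norm
    (exterior linear counts normalized to sequencing depth), and
    optionally tissue.  Per gene (>= 4 samples): the circle fraction
    p-hat is centred once by the pooled MLE (z_n) and once by an
    ordinary least squares fit of p-hat on linear_norm (z_o); z_o is
    rescaled by the median per-gene standard deviation to absorb
    Poisson overdispersion, referred to t(n-2), and BH-corrected.
    """
    rows = []
    for gene, g in table.groupby("gene_id"):
        if len(g) < 4:
            continue
        n = (g.n_c + g.n_l).to_numpy(dtype=float)
        if np.any(n <= 0):
            continue
        p_hat = g.n_c.to_numpy(dtype=float) / n
        p_mle = g.n_c.sum() / n.sum()
        denom = np.sqrt(np.clip(p_hat * (1 - p_hat), eps, None))
        z_n = (p_hat - p_mle) * np.sqrt(n) / denom

        import statsmodels.api as sm

        X = sm.add_constant(g.linear_norm.to_numpy(dtype=float))
        fit = sm.OLS(p_hat, X).fit()
        p_ols = np.asarray(fit.fittedvalues)
        if np.any((p_ols <= 0) | (p_ols >= 1)):
            warnings.warn(f"gene {gene}: OLS-fitted fraction clamped to (0,1)", stacklevel=2)
            p_ols = np.clip(p_ols, eps, 1 - eps)
        z_o = (p_hat - p_ols) * np.sqrt(n) / np.sqrt(p_ols * (1 - p_ols))
        sd = float(np.std(z_o, ddof=1))
        for i, (_, row) in enumerate(g.iterrows()):
            rows.append(
                {
                    "gene_id": gene,
                    "sample_id": row.sample_id,
                    "tissue": row.get("tissue", ""),
                    "p_hat": p_hat[i],
                    "z_n": z_n[i],
                    "z_o": z_o[i],
                    "sd_zo": sd,
                    "df": len(g) - 2,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "sample_id", "tissue", "p_hat", "z_n", "z_o",
                     "z_corrected", "p", "fdr", "outlier"]
        )
    df = pd.DataFrame(rows)
    med_sd = float(df.groupby("gene_id")["sd_zo"].first().median())
    if med_sd <= 0:
        med_sd = 1.0
    df["z_corrected"] = df.z_o / med_sd
    df["p"] = 2 * stats.t.sf(np.abs(df.z_corrected), df["df"])
    from circjunct.glm import bh_fdr

    df["fdr"] = bh_fdr(df.p.to_numpy())
    df["outlier"] = df.fdr < fdr_level
    return df.drop(columns=["sd_zo", "df"])


def tissue_consistent_outliers(outliers: pd.DataFrame) -> pd.DataFrame:
    """Genes where every sample of some tissue is an outlier (>= 2 samples)."""
    hits = []
    flagged = outliers[outliers.outlier & (outliers.tissue != "")]
    for (gene, tissue), g in flagged.groupby(["gene_id", "tissue"]):
        total = len(
            outliers[(outliers.gene_id == gene) & (outliers.tissue == tissue)]
        )
        if total >= 2 and len(g) == total:
            hits.append({"gene_id": gene, "tissue": tissue, "n_samples": total})
    return pd.DataFrame(hits, columns=["gene_id", "tissue", "n_samples"])
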