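"""Statistical layer: Poisson GLM over resolution counts with analysis of
deviance and pairwise factor contrasts, plus the cross-study regression of
resolution rate on species-to-genus ratio.

The response is the count of resolved species per (barcode, species-per-
genus class) cell with ``log(total)`` as offset, so unequal class sizes do
not masquerade as rate differences.  A binomial response is available as a
sensitivity check.  Pairwise contrasts use the coefficient covariance of
the fitted GLM with Bonferroni adjustment capped at 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

REQUIRED_CELL_COLUMNS = ("barcode", "sg_class", "resolved", "total")


def _validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"count table missing column(s): {', '.join(missing)}")
    if (cells["resolved"] < 0).any() or (cells["resolved"] > cells["total"]).any():
        raise ValueError("need 0 <= resolved <= total in every cell")
    if (cells["total"] <= 0).any():
        raise ValueError("cells with total == 0 cannot enter the model; drop them first")
    return cells.copy()


@dataclass
class GlmFit:
    """Fitted GLM with the pieces downstream operations need."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    deviance: float
    df_resid: int
    df_model: int
    converged: bool
    formula: str
    family: str
    result: object  # statsmodels results, kept for diagnostics

    def __post_init__(self) -> None:
        if not self.converged:
            raise RuntimeError(
                "GLM did not converge; consider merging sparse species-per-genus "
                "classes or removing empty cells"
            )


def fit_poisson_glm(
    cells: pd.DataFrame,
    formula: str = "resolved ~ C(barcode) * C(sg_class)",
    family: str = "poisson",
) -> GlmFit:
    """Fit resolved counts with a log link and log(total) offset.

    ``family='binomial'`` fits resolved/total proportions instead (no
    offset) as a sensitivity alternative.
    """
    cells = _validate_cells(cells)
    import statsmodels.formula.api as smf

    if family == "poisson":
        model = smf.glm(
            formula, data=cells, family=sm.families.Poisson(),
            offset=np.log(cells["total"].astype(float)),
        )
    elif family == "binomial":
        cells["failed"] = cells["total"] - cells["resolved"]
        lhs = formula.split("~")[1]
        model = smf.glm(
            f"resolved + failed ~ {lhs}", data=cells, family=sm.families.Binomial()
        )
    else:
        raise ValueError(f"unknown family {family!r}")
    res = model.fit(maxiter=100, tol=1e-10)
    return GlmFit(
        params=res.params,
        bse=res.bse,
        cov=res.cov_params(),
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        df_model=int(res.df_model),
        converged=bool(res.converged),
        formula=formula,
        family=family,
        result=res,
    )


@dataclass(frozen=True)
class DevianceTest:
    term: str
    df: int
    chi_sq: float
    p: float


def deviance_test(fit_full: GlmFit, fit_reduced: GlmFit, term: str = "") -> DevianceTest:
    """Likelihood-ratio chi-square between two nested fits on the same data."""
    df = fit_reduced.df_resid - fit_full.df_resid
    if df < 1:
        raise ValueError("models are not nested (reduced model must have fewer parameters)")
    chi_sq = fit_reduced.deviance - fit_full.deviance
    if chi_sq < -1e-8:
        raise ValueError("reduced model fits better than full model; inputs not nested?")
    chi_sq = max(chi_sq, 0.0)
    p = float(sps.chi2.sf(chi_sq, df))
    return DevianceTest(term=term, df=df, chi_sq=chi_sq, p=p)


def analysis_of_deviance(cells: pd.DataFrame, family: str = "poisson") -> list[DevianceTest]:
    """Sequential (type-I) analysis of deviance for barcode, class and
    their interaction over the 8 x 5 resolution count table."""
    chain = [
        ("barcode", "resolved ~ 1", "resolved ~ C(barcode)"),
        ("sg_class", "resolved ~ C(barcode)", "resolved ~ C(barcode) + C(sg_class)"),
        (
            "barcode:sg_class",
            "resolved ~ C(barcode) + C(sg_class)",
            "resolved ~ C(barcode) * C(sg_class)",
        ),
    ]
    out = []
    for term, reduced, full in chain:
        fr = fit_poisson_glm(cells, formula=reduced, family=family)
        ff = fit_poisson_glm(cells, formula=full, family=family)
        out.append(deviance_test(ff, fr, term=term))
    return out


@dataclass(frozen=True)
class ContrastResult:
    comparison: str  # "j-i", larger level first
    estimate: float
    se: float
    z: float
    p: float
    p_adj: float


def pairwise_contrasts(
    fit: GlmFit, factor: str = "sg_class", adjustment: str = "bonferroni"
) -> list[ContrastResult]:
    """All pairwise z contrasts between the levels of a model factor.

    For each ordered pair (i < j) the contrast is the coefficient
    difference of levels j and i on the linear-predictor scale; z uses the
    fitted coefficient covariance.  Bonferroni multiplies p by the number
    of comparisons and caps at exactly 1.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError("adjustment must be 'bonferroni' or 'none'")
    names = list(fit.params.index)
    tag = f"C({factor})[T."
    level_coef: dict[str, str] = {}
    for nm in names:
        if nm.startswith(tag) and ":" not in nm:
            level = nm[len(tag):-1]
            level_coef[level] = nm
    if not level_coef:
        raise ValueError(f"factor {factor!r} not found in fit {fit.formula!r}")
    # reference level = the one absorbed into the intercept; recover it from
    # the model frame (patsy uses the sorted-first level as reference)
    frame = fit.result.model.data.frame
    data_levels = sorted({str(v) for v in frame[factor]})
    ref = next(lv for lv in data_levels if lv not in level_coef)
    all_levels = ["<ref>"] + [lv for lv in data_levels if lv != ref]
    cov = fit.cov.values
    idx = {nm: i for i, nm in enumerate(names)}
    k = len(fit.params)
    results: list[ContrastResult] = []

    def coef_vector(level: str) -> np.ndarray:
        v = np.zeros(k)
        if level != "<ref>":
            v[idx[level_coef[level]]] = 1.0
        return v

    pairs = list(itertools.combinations(all_levels, 2))
    m = len(pairs)
    for lo, hi in pairs:
        c = coef_vector(hi) - coef_vector(lo)
        est = float(c @ fit.params.values)
        var = float(c @ cov @ c)
        if var <= 0:
            raise ValueError("rank-deficient covariance for contrast "
                             f"{hi}-{lo}; model may be overparameterised")
        se = float(np.sqrt(var))
        z = est / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, m * p) if adjustment == "bonferroni" else p
        lo_lbl = ref if lo == "<ref>" else lo
        results.append(ContrastResult(f"{hi}-{lo_lbl}", est, se, z, p, p_adj))
    return results


def contrasts_by_barcode(
    cells: pd.DataFrame, adjustment: str = "bonferroni", family: str = "poisson"
) -> pd.DataFrame:
    """Per-barcode GLMs of resolved counts on species-per-genus class, with
    pairwise class contrasts — one row per (barcode, comparison)."""
    rows = []
    for barcode in cells["barcode"].unique():
        sub = cells[cells["barcode"] == barcode]
        fit = fit_poisson_glm(sub, formula="resolved ~ C(sg_class)", family=family)
        for c in pairwise_contrasts(fit, "sg_class", adjustment):
            rows.append({
                "barcode": barcode, "comparison": c.comparison,
                "z": c.z, "p": c.p, "p_adj": c.p_adj,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-study regression


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


def linear_regression(x, y) -> RegressionFit:
    """Ordinary least squares of resolution rate on species-to-genus ratio."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        n=len(x),
    )


def load_study_comparison() -> pd.DataFrame:
    """Packaged comparison table of floristic barcoding studies: study
    site, spatial scale, climate, growth form, species/genera and
    samples/species ratios, barcode set, and reported resolution rate."""
    with resources.files("barcodetree.data").joinpath("study_comparison.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def cross_study_regression(
    table: pd.DataFrame | None = None,
    required_barcodes: tuple[str, ...] = ("rbcL", "matK", "trnH-psbA"),
) -> RegressionFit:
    """Regress reported resolution on species-to-genus ratio across the
    studies whose barcode set includes the three plastid core regions."""
    if table is None:
        table = load_study_comparison()
    sel = table[
        table["barcodes"].map(
            lambda b: all(req in [s.strip() for s in b.split(",")] for req in required_barcodes)
        )
    ]
    return linear_regression(sel["sg_ratio"].values, sel["resolution_pct"].values)
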