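"""GLM layer against an independent Newton-Raphson oracle, deviance
arithmetic, pairwise contrasts, and the cross-study regression."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from barcodetree.stats import (
    analysis_of_deviance,
    contrasts_by_barcode,
    cross_study_regression,
    deviance_test,
    fit_poisson_glm,
    linear_regression,
    load_study_comparison,
    pairwise_contrasts,
)

BARCODES = ["R", "M", "RM", "RP", "RI", "RMP", "RMI", "RMPI"]


def random_cells(rng: np.random.Generator, full=True) -> pd.DataFrame:
    rows = []
    for b in BARCODES:
        for c in range(1, 6):
            total = int(rng.integers(5, 40))
            resolved = int(rng.binomial(total, rng.uniform(0.2, 0.95)))
            rows.append({"barcode": b, "sg_class": c, "resolved": resolved, "total": total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Independent Poisson ML oracle (design matrix + Newton-Raphson)


def oracle_poisson_deviance(cells: pd.DataFrame, terms: str) -> float:
    """Maximise the Poisson log-likelihood with log(total) offset by plain
    Newton-Raphson on an explicitly constructed design matrix, and return
    the residual deviance.  terms: 'null' | 'barcode' | 'additive' | 'full'."""
    y = cells["resolved"].to_numpy(float)
    offset = np.log(cells["total"].to_numpy(float))
    cols = [np.ones(len(cells))]
    b_levels = sorted(cells["barcode"].unique())
    c_levels = sorted(cells["sg_class"].unique())
    if terms in ("barcode", "additive", "full"):
        for lv in b_levels[1:]:
            cols.append((cells["barcode"] == lv).to_numpy(float))
    if terms in ("additive", "full"):
        for lv in c_levels[1:]:
            cols.append((cells["sg_class"] == lv).to_numpy(float))
    if terms == "full":
        for lb, lc in itertools.product(b_levels[1:], c_levels[1:]):
            cols.append(
                ((cells["barcode"] == lb) & (cells["sg_class"] == lc)).to_numpy(float)
            )
    X = np.column_stack(cols)
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        mu = np.exp(X @ beta + offset)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, grad)
        # damp steps that would push the linear predictor out of range
        while np.max(np.abs(X @ (beta + step) + offset)) > 30:
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = np.exp(X @ beta + offset)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


FORMULAS = {
    "null": "resolved ~ 1",
    "barcode": "resolved ~ C(barcode)",
    "additive": "resolved ~ C(barcode) + C(sg_class)",
    "full": "resolved ~ C(barcode) * C(sg_class)",
}


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("terms", ["null", "barcode", "additive", "full"])
def test_glm_deviance_matches_newton_oracle(seed, terms):
    cells = random_cells(np.random.default_rng(seed))
    fit = fit_poisson_glm(cells, formula=FORMULAS[terms])
    assert fit.deviance == pytest.approx(oracle_poisson_deviance(cells, terms), abs=1e-6)


def test_saturated_model_zero_deviance():
    cells = pd.DataFrame({
        "barcode": ["R", "M", "RM"],
        "sg_class": [1, 1, 1],
        "resolved": [3, 5, 7],
        "total": [10, 10, 10],
    })
    fit = fit_poisson_glm(cells, formula="resolved ~ C(barcode)")  # saturated here
    assert fit.deviance == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(fit.result.fittedvalues, cells["resolved"])


def test_intercept_only_closed_form():
    # equal offsets: MLE rate is the mean count over the common total
    cells = pd.DataFrame({
        "barcode": ["R"] * 3,
        "sg_class": [1, 2, 3],
        "resolved": [3, 5, 7],
        "total": [10, 10, 10],
    })
    fit = fit_poisson_glm(cells, formula="resolved ~ 1")
    assert fit.params.iloc[0] == pytest.approx(math.log(5.0 / 10.0))


def test_cell_validation():
    bad = pd.DataFrame({"barcode": ["R"], "sg_class": [1], "resolved": [5], "total": [3]})
    with pytest.raises(ValueError, match="resolved"):
        fit_poisson_glm(bad)
    empty_total = pd.DataFrame({"barcode": ["R"], "sg_class": [1], "resolved": [0], "total": [0]})
    with pytest.raises(ValueError, match="total"):
        fit_poisson_glm(empty_total)


# ---------------------------------------------------------------------------
# Analysis of deviance


def test_deviance_chain_df_and_additivity():
    cells = random_cells(np.random.default_rng(11))
    tests = analysis_of_deviance(cells)
    by_term = {t.term: t for t in tests}
    assert by_term["barcode"].df == 7
    assert by_term["sg_class"].df == 4
    assert by_term["barcode:sg_class"].df == 28
    # chain chi-squares add up to the full-vs-null comparison
    f_null = fit_poisson_glm(cells, formula="resolved ~ 1")
    f_full = fit_poisson_glm(cells, formula="resolved ~ C(barcode) * C(sg_class)")
    total = deviance_test(f_full, f_null, "all")
    assert sum(t.chi_sq for t in tests) == pytest.approx(total.chi_sq, rel=1e-10)
    assert total.df == 39


def test_identical_models_give_null_test():
    cells = random_cells(np.random.default_rng(2))
    f1 = fit_poisson_glm(cells, formula="resolved ~ C(barcode)")
    f2 = fit_poisson_glm(cells, formula="resolved ~ C(barcode) + C(sg_class)")
    t = deviance_test(f2, f1, "sg_class")
    assert t.chi_sq >= 0 and 0 <= t.p <= 1
    with pytest.raises(ValueError, match="nested"):
        deviance_test(f1, f2)


# ---------------------------------------------------------------------------
# Pairwise contrasts


def test_contrast_count_and_labels():
    cells = random_cells(np.random.default_rng(3))
    fit = fit_poisson_glm(cells, formula="resolved ~ C(sg_class)")
    contrasts = pairwise_contrasts(fit, "sg_class")
    assert len(contrasts) == 10  # C(5, 2)
    labels = [c.comparison for c in contrasts]
    assert labels == ["2-1", "3-1", "4-1", "5-1", "3-2", "4-2", "5-2", "4-3", "5-3", "5-4"]


def test_identical_cells_zero_z():
    cells = pd.DataFrame({
        "barcode": ["R"] * 2,
        "sg_class": [1, 2],
        "resolved": [8, 8],
        "total": [10, 10],
    })
    fit = fit_poisson_glm(cells, formula="resolved ~ C(sg_class)")
    (c,) = pairwise_contrasts(fit, "sg_class")
    assert c.z == pytest.approx(0.0, abs=1e-8)
    assert c.p_adj == 1.0


def test_bonferroni_never_below_raw_and_caps_at_one():
    cells = random_cells(np.random.default_rng(4))
    fit = fit_poisson_glm(cells, formula="resolved ~ C(sg_class)")
    for c in pairwise_contrasts(fit, "sg_class", adjustment="bonferroni"):
        assert c.p_adj >= c.p
        assert c.p_adj <= 1.0
    assert any(c.p_adj == 1.0 for c in pairwise_contrasts(fit, "sg_class"))


def test_depressed_class_dominates_contrasts_and_matches_covariance_oracle():
    """A class with clearly lower resolution shows the largest |z| in its
    contrasts, and one z value is reproduced by explicit matrix algebra
    on the coefficient covariance."""
    rows = []
    for c in range(1, 6):
        total = 40
        resolved = 8 if c == 4 else 36  # class 4 depressed
        rows.append({"barcode": "R", "sg_class": c, "resolved": resolved, "total": total})
    cells = pd.DataFrame(rows)
    fit = fit_poisson_glm(cells, formula="resolved ~ C(sg_class)")
    contrasts = pairwise_contrasts(fit, "sg_class")
    involving4 = [abs(c.z) for c in contrasts if "4" in c.comparison.split("-")]
    others = [abs(c.z) for c in contrasts if "4" not in c.comparison.split("-")]
    assert min(involving4) > max(others)
    # oracle arithmetic for the "4-1" contrast: z = b4 / sqrt(var(b4))
    c41 = next(c for c in contrasts if c.comparison == "4-1")
    b4 = fit.params["C(sg_class)[T.4]"]
    var = fit.cov.loc["C(sg_class)[T.4]", "C(sg_class)[T.4]"]
    assert c41.z == pytest.approx(b4 / math.sqrt(var), rel=1e-10)


def test_contrasts_by_barcode_layout():
    cells = random_cells(np.random.default_rng(6))
    out = contrasts_by_barcode(cells)
    assert len(out) == 8 * 10
    assert set(out.columns) == {"barcode", "comparison", "z", "p", "p_adj"}


# ---------------------------------------------------------------------------
# Linear regression


def test_collinear_points_r2_one():
    fit = linear_regression([1, 2, 3, 4], [10, 8, 6, 4])
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.slope == pytest.approx(-2.0)


def test_r2_equals_squared_correlation():
    rng = np.random.default_rng(0)
    x = rng.uniform(1, 3, 30)
    y = 90 - 20 * x + rng.normal(0, 5, 30)
    fit = linear_regression(x, y)
    assert fit.r_squared == pytest.approx(float(np.corrcoef(x, y)[0, 1] ** 2), abs=1e-12)


def test_r2_invariant_to_affine_rescale_of_x():
    rng = np.random.default_rng(1)
    x = rng.uniform(1, 3, 20)
    y = 90 - 20 * x + rng.normal(0, 5, 20)
    assert linear_regression(x, y).r_squared == pytest.approx(
        linear_regression(10 * x + 3, y).r_squared, abs=1e-12
    )


def test_constant_x_rejected():
    with pytest.raises(ValueError, match="constant"):
        linear_regression([1, 1, 1], [2, 3, 4])


def test_cross_study_regression_negative_and_significant():
    table = load_study_comparison()
    assert len(table) == 19
    fit = cross_study_regression(table)
    assert fit.n == 15  # studies whose barcode set includes the plastid core
    assert fit.slope < 0
    assert fit.p_slope < 0.001
    assert 0 <= fit.r_squared <= 1
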