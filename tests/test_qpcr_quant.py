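"""Standard curves, ΔΔCt ratios, contamination flagging, fold induction."""

import numpy as np
import pytest

from lysotrace.errors import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedRatioError,
    ValidationError,
)
from lysotrace.qpcr_quant import (
    QuantResult,
    absolute_quantify,
    contamination_estimate,
    copy_number_ratio,
    fit_standard_curve,
    flag_above_contamination,
    fold_induction,
    format_fold,
    phage_per_bacterium,
    significance_stars,
)
from lysotrace.synthetic_data import QpcrSimConfig, simulate_qpcr


# --------------------------------------------------------- standard curve


def test_perfect_doubling_efficiency():
    copies = [1e2, 1e3, 1e4, 1e5]
    cq = [40.0 - 3.3219 * np.log10(c) for c in copies]
    curve = fit_standard_curve(copies, cq)
    assert curve.slope == pytest.approx(-3.3219, abs=1e-4)
    assert curve.efficiency == pytest.approx(1.0, abs=1e-3)
    assert curve.efficiency_in_range


def test_curve_matches_regression_oracle():
    copies = [1e2, 1e3, 1e4]
    cq = [30.0, 26.7, 23.4]
    curve = fit_standard_curve(copies, cq)
    # closed-form least squares on (log10 copies, cq)
    x = np.log10(copies)
    y = np.array(cq)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    assert curve.slope == pytest.approx(slope, rel=1e-9)
    assert curve.slope == pytest.approx(-3.30, abs=0.01)
    assert curve.r_squared > 0.999


def test_curve_error_modes():
    with pytest.raises(InsufficientDataError):
        fit_standard_curve([1e2, 1e2, 1e3], [30, 30.1, 27])
    with pytest.raises(ValidationError):
        fit_standard_curve([1e2, 1e3, 1e4], [23.4, 26.7, 30.0])  # rising Cq
    with pytest.raises(InvalidParameterError):
        fit_standard_curve([0, 1e3, 1e4], [30, 26.7, 23.4])


# --------------------------------------------------- absolute quantities


def test_absolute_quantify_identities():
    curve = fit_standard_curve(
        [1e2, 1e3, 1e4], [40 - 3.3219 * 2, 40 - 3.3219 * 3, 40 - 3.3219 * 4]
    )
    # cq at the intercept corresponds to 1 copy
    assert absolute_quantify(curve, curve.intercept, 1, 50.0) == pytest.approx(50.0)
    base = absolute_quantify(curve, 30.0)
    # one cycle earlier at efficiency 1 doubles the estimate
    assert absolute_quantify(curve, 30.0 - abs(curve.slope) * np.log10(2)) == (
        pytest.approx(2 * base, rel=1e-6)
    )


def test_roundtrip_simulation_recovery():
    config = QpcrSimConfig(
        true_copies={"gally": 4.3e8}, cq_noise_sd=0.2, dilutions=(50.0, 100.0)
    )
    curve = fit_standard_curve(
        [50, 5e2, 5e3, 5e4, 5e5],
        [config.intercept + config.slope * np.log10(c) for c in (50, 5e2, 5e3, 5e4, 5e5)],
    )
    errors = []
    for seed in range(100):
        ms = simulate_qpcr(config, seed=seed)
        estimates = [
            absolute_quantify(curve, m.cq, m.dilution_factor) for m in ms
        ]
        errors.append(abs(np.median(estimates) - 4.3e8) / 4.3e8)
    assert np.median(errors) < 0.10


# ------------------------------------------------------------------ ΔΔCt


@pytest.mark.parametrize(
    "dcq,expected", [(0.0, 1.0), (-1.0, 0.5), (1.0, 2.0)]
)
def test_copy_ratio_doubling_identities(dcq, expected):
    assert copy_number_ratio([20.0 - dcq], [20.0]) == pytest.approx(expected)


def test_copy_ratio_shift_invariance(rng):
    t = list(20 + rng.normal(0, 1, size=5))
    r = list(22 + rng.normal(0, 1, size=5))
    base = copy_number_ratio(t, r)
    shifted = copy_number_ratio([x + 3.7 for x in t], [x + 3.7 for x in r])
    assert shifted == pytest.approx(base, rel=1e-12)


def test_copy_ratio_unpaired_rejected():
    with pytest.raises(InvalidParameterError):
        copy_number_ratio([20.0, 21.0], [20.0])


# ---------------------------------------------------------- contamination


def test_contamination_estimates_match_printed_arithmetic():
    assert contamination_estimate(2.3e4, 5.5) == pytest.approx(1.265e5)
    assert contamination_estimate(7.6, 5.5) == pytest.approx(41.8)
    assert contamination_estimate(123.0, 1.0) == 123.0


def test_flag_above_contamination_cases():
    above, fold = flag_above_contamination(4.2e6, 1.3e5)
    assert above and round(fold) == 32
    assert flag_above_contamination(1.3e5, 1.3e5) == (False, 1.0)
    assert flag_above_contamination(0.0, 1.3e5) == (False, 0.0)
    above, fold = flag_above_contamination(10.0, 0.0)
    assert above and fold == float("inf")


def test_flag_monotone_in_measurement(rng):
    values = np.sort(rng.uniform(0, 1e7, size=50))
    folds = [flag_above_contamination(v, 1.3e5)[1] for v in values]
    assert all(a <= b for a, b in zip(folds, folds[1:]))


# ------------------------------------------------------ per-bacterium etc.


def test_phage_per_bacterium_values():
    assert phage_per_bacterium(4.3e8, 6.4e8) == pytest.approx(0.67, abs=0.005)
    assert phage_per_bacterium(5e5, 5e5) == 1.0
    assert phage_per_bacterium(7e4, 2.2e6, instability_factor=20) == (
        pytest.approx(0.64, abs=0.005)
    )
    with pytest.raises(UndefinedRatioError):
        phage_per_bacterium(1e5, 0.0)


# --------------------------------------------------------- fold induction


def test_fold_induction_identical_arms():
    arm = [1e6, 1.1e6, 0.9e6]
    fold, p = fold_induction(arm, arm)
    assert fold == 1.0 and p > 0.05


def test_fold_induction_18x_separation(rng):
    untreated = 1e6 * rng.lognormal(0, 0.1, size=6)
    treated = 18.0 * untreated * rng.lognormal(0, 0.05, size=6)
    fold, p = fold_induction(list(treated), list(untreated))
    assert fold == pytest.approx(18.0, rel=0.10)
    assert p < 0.01
    assert significance_stars(p) in ("**", "***")


def test_fold_induction_filters_contaminated_replicates():
    treated = [
        QuantResult("gally", 4e6, contamination_copies_per_mL=1e5),
        QuantResult("gally", 5e6, contamination_copies_per_mL=1e5),
        QuantResult("gally", 5e4, contamination_copies_per_mL=1e5),  # excluded
    ]
    untreated = [
        QuantResult("gally", 1e6, contamination_copies_per_mL=1e5),
        QuantResult("gally", 1.2e6, contamination_copies_per_mL=1e5),
    ]
    fold, _ = fold_induction(treated, untreated)
    assert fold == pytest.approx(4.5e6 / 1.1e6)
    # dropping the below-contamination replicate is what keeps fold finite
    with pytest.raises(InsufficientDataError):
        fold_induction(treated[2:], untreated)


def test_both_tests_agree_on_separated_arms(rng):
    agree = 0
    for _ in range(100):
        a = 1e6 * rng.lognormal(0, 0.1, size=6)
        b = 20e6 * rng.lognormal(0, 0.1, size=6)
        _, p_t = fold_induction(list(b), list(a), test="t")
        _, p_u = fold_induction(list(b), list(a), test="mann_whitney")
        agree += (p_t < 0.05) == (p_u < 0.05)
    assert agree == 100


def test_quant_result_invariants():
    r = QuantResult("cyrano", 4.2e6, contamination_copies_per_mL=1.3e5,
                    instability_factor=3.0)
    assert r.above_contamination
    assert r.fold_over_contamination == pytest.approx(32.3, abs=0.05)
    assert r.corrected_copies_per_mL == pytest.approx(1.26e7)
    assert format_fold(r.fold_over_contamination) == "32"
    assert format_fold(5.5) == "5.5"
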