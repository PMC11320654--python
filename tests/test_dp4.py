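import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from confshift import dp4
from confshift.records import ValidationError
from conftest import make_conformer, make_table


# --------------------------------------------------------------------------
# site shifts from shieldings
# --------------------------------------------------------------------------

def test_reference_atom_gives_zero_shift(params):
    table = make_table(delta_h=[0.0])
    conf = make_conformer("c", shieldings_h=[params.sigma_ref["H1"]])
    shifts = dp4.candidate_site_shifts(conf, table, params)
    assert shifts["H1"][0] == pytest.approx(0.0)


def test_methyl_site_averages_equivalent_atoms(params):
    table = make_table(delta_h=[1.0], atoms_h=[(1, 2, 3)])
    conf = make_conformer("c", shieldings_h=[30.0, 31.0, 32.0])
    shifts = dp4.candidate_site_shifts(conf, table, params)
    # mean shielding 31.0 against sigma_ref 31.8
    assert shifts["H1"][0] == pytest.approx(0.8)


def test_absent_atom_is_an_error(params):
    table = make_table(delta_h=[1.0], atoms_h=[(99,)])
    conf = make_conformer("c", shieldings_h=[30.0])
    with pytest.raises(ValidationError, match="H1"):
        dp4.candidate_site_shifts(conf, table, params)


# --------------------------------------------------------------------------
# scaling
# --------------------------------------------------------------------------

def test_scaling_identity():
    d = np.array([1.0, 2.0, 3.5, 4.0, 7.0])
    fit = dp4.fit_scaling(d, d)
    assert fit.slope == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(fit.delta_scaled, d)


def test_scaling_removes_exact_affine_distortion():
    dexp = np.array([0.8, 2.1, 3.3, 5.9, 7.2])
    dcalc = 1.05 * dexp + 2.0
    fit = dp4.fit_scaling(dcalc, dexp)
    np.testing.assert_allclose(fit.delta_scaled, dexp, atol=1e-12)


def test_scaling_matches_normal_equations_oracle(rng):
    """OLS slope/intercept agree with the Sigma-based closed form to 1e-10."""
    for _ in range(20):
        x = rng.uniform(0, 200, 5)
        y = rng.uniform(0.9, 1.1) * x + rng.normal(0, 2, 5)
        fit = dp4.fit_scaling(y, x)
        n = x.size
        m_oracle = (n * np.sum(x * y) - x.sum() * y.sum()) / (
            n * np.sum(x * x) - x.sum() ** 2
        )
        b_oracle = (y.sum() - m_oracle * x.sum()) / n
        assert fit.slope == pytest.approx(m_oracle, abs=1e-10)
        assert fit.intercept == pytest.approx(b_oracle, abs=1e-10)


def test_degenerate_scaling_instructs_unscaled_channel():
    with pytest.raises(dp4.DegenerateRegressionError, match="unscaled"):
        dp4.fit_scaling(np.array([1.0]), np.array([2.0]))
    with pytest.raises(dp4.DegenerateRegressionError, match="unscaled"):
        dp4.fit_scaling(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


# --------------------------------------------------------------------------
# error statistics
# --------------------------------------------------------------------------

def test_cmae_cmaxerr_arithmetic():
    ds = np.array([1.0, -3.0]) + np.array([5.0, 6.0])
    de = np.array([5.0, 6.0])
    assert dp4.cmae(ds, de) == pytest.approx(2.0)
    assert dp4.cmaxerr(ds, de) == pytest.approx(3.0)
    assert dp4.cmae(de, de) == 0.0
    with pytest.raises(ValidationError):
        dp4.cmae(np.array([]), np.array([]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=30),
)
def test_cmae_never_exceeds_cmaxerr(errors):
    de = np.zeros(len(errors))
    ds = np.asarray(errors)
    assert dp4.cmae(ds, de) <= dp4.cmaxerr(ds, de) + 1e-15


# --------------------------------------------------------------------------
# t density
# --------------------------------------------------------------------------

def test_t_density_symmetry_and_cauchy_value():
    assert dp4.t_density(0.7, 0.5, 1.2, 3.0) == pytest.approx(
        dp4.t_density(0.3, 0.5, 1.2, 3.0)
    )
    # nu=1 is the Cauchy distribution: f(0) = 1/pi
    assert dp4.t_density(0.0, 0.0, 1.0, 1.0) == pytest.approx(1 / np.pi)


def test_t_density_normal_limit():
    for e in (0.0, 1.0, 2.0):
        gauss = np.exp(-(e**2) / 2) / np.sqrt(2 * np.pi)
        assert dp4.t_density(e, 0.0, 1.0, 1e6) == pytest.approx(gauss, abs=1e-4)


def test_t_density_rejects_bad_parameters():
    with pytest.raises(ValidationError):
        dp4.t_density(0.0, 0.0, -1.0, 3.0)
    with pytest.raises(ValidationError):
        dp4.t_density(0.0, 0.0, 1.0, 0.0)


# --------------------------------------------------------------------------
# DP4+ probabilities
# --------------------------------------------------------------------------

def _two_candidate_setup(params, rng, n=8, jitter=0.5):
    table = make_table(
        delta_c=rng.uniform(20, 180, n), delta_h=rng.uniform(1, 8, n)
    )
    def cand(scale_c, scale_h):
        return {
            "C13": table.delta_exp("C13") + rng.normal(0, jitter * scale_c, n),
            "H1": table.delta_exp("H1") + rng.normal(0, 0.1 * jitter * scale_h, n),
        }
    return table, cand


def test_single_candidate_probability_one(params, rng):
    table, cand = _two_candidate_setup(params, rng)
    res = dp4.dp4_probabilities({"only": cand(1, 1)}, table, params)
    assert res.probabilities.loc["only", "combined"] == pytest.approx(1.0)
    assert any("single candidate" in n for n in res.notices)


def test_identical_candidates_split_evenly(params, rng):
    table, cand = _two_candidate_setup(params, rng)
    shifts = cand(1, 1)
    res = dp4.dp4_probabilities({"a": shifts, "b": shifts}, table, params)
    for channel in res.probabilities.columns:
        np.testing.assert_allclose(res.probabilities[channel], [0.5, 0.5])
    assert res.top() == ["a", "b"]  # tie reported as a set


def test_channel_probabilities_sum_to_one(params, rng):
    table, cand = _two_candidate_setup(params, rng)
    res = dp4.dp4_probabilities(
        {f"c{k}": cand(1 + k, 1 + k) for k in range(4)}, table, params
    )
    sums = res.probabilities.sum(axis=0)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    assert (res.probabilities.to_numpy() >= 0).all()


def test_duplicate_candidate_halves_its_probability(params, rng):
    table, cand = _two_candidate_setup(params, rng)
    c1, c2, c3 = cand(1, 1), cand(2, 2), cand(3, 3)
    base = dp4.dp4_probabilities({"a": c1, "b": c2, "c": c3}, table, params)
    dup = dp4.dp4_probabilities(
        {"a": c1, "a2": c1, "b": c2, "c": c3}, table, params
    )
    p = base.probabilities["combined"]
    q = dup.probabilities["combined"]
    # the duplicated structure's mass is split exactly in half between copies
    assert q["a"] == pytest.approx(q["a2"], rel=1e-12)
    assert q["a"] == pytest.approx((q["a"] + q["a2"]) / 2, rel=1e-12)
    # likelihood ratios among candidates unchanged
    assert q["b"] / q["c"] == pytest.approx(p["b"] / p["c"], rel=1e-9)
    assert q["a"] / q["b"] == pytest.approx(p["a"] / p["b"], rel=1e-9)


def test_combined_likelihood_is_product_of_h_and_c(params, rng):
    table, cand = _two_candidate_setup(params, rng)
    res = dp4.dp4_probabilities(
        {"a": cand(1, 1), "b": cand(2, 2)}, table, params
    )
    np.testing.assert_allclose(
        res.log_likelihoods["combined"],
        res.log_likelihoods["H1"] + res.log_likelihoods["C13"],
        rtol=1e-12,
    )


def test_affine_transform_leaves_scaled_channel_unchanged(params, rng):
    table, cand = _two_candidate_setup(params, rng)
    cands = {"a": cand(1, 1), "b": cand(2, 2), "c": cand(3, 3)}
    warped = {
        cid: {nuc: 1.07 * v - 3.1 for nuc, v in shifts.items()}
        for cid, shifts in cands.items()
    }
    chans = (("H1", "scaled"), ("C13", "scaled"))
    base = dp4.dp4_probabilities(cands, table, params, channels=chans)
    moved = dp4.dp4_probabilities(warped, table, params, channels=chans)
    np.testing.assert_allclose(
        base.probabilities["scaled"], moved.probabilities["scaled"], atol=1e-9
    )


def test_log_space_matches_direct_product_on_small_input(params, rng):
    """Softmax of summed log densities == normalized direct products (<=5 sites)."""
    table = make_table(delta_c=rng.uniform(20, 180, 3), delta_h=rng.uniform(1, 8, 2))
    cands = {
        f"c{k}": {
            "C13": table.delta_exp("C13") + rng.normal(0, 1 + k, 3),
            "H1": table.delta_exp("H1") + rng.normal(0, 0.1 * (1 + k), 2),
        }
        for k in range(3)
    }
    res = dp4.dp4_probabilities(cands, table, params)
    # independent direct-product oracle (unscaled channel avoids the scaling fit)
    direct = []
    for cid in cands:
        prod = 1.0
        for nuc in ("H1", "C13"):
            d = params.dist(nuc, "unscaled")
            for e in cands[cid][nuc] - table.delta_exp(nuc):
                prod *= dp4.t_density(e, d.mu, d.sigma, d.nu)
        direct.append(prod)
    direct = np.array(direct) / np.sum(direct)
    np.testing.assert_allclose(
        res.probabilities["unscaled"], direct, rtol=1e-10
    )


def test_missing_experimental_shift_dropped_symmetrically(params, rng):
    table, cand = _two_candidate_setup(params, rng, n=6)
    cands = {"a": cand(1, 1), "b": cand(2, 2)}
    rows = table.rows.copy()
    rows.loc[rows.index[0], "delta_exp"] = np.nan
    from confshift.records import ShiftAssignmentTable

    table_nan = ShiftAssignmentTable(rows)
    trimmed = table_nan.drop_missing()
    cands_trim = {
        cid: {"C13": s["C13"][1:], "H1": s["H1"]} for cid, s in cands.items()
    }
    res_nan = dp4.dp4_probabilities(cands_trim, table_nan, params)
    res_ref = dp4.dp4_probabilities(cands_trim, trimmed, params)
    np.testing.assert_allclose(
        res_nan.probabilities["combined"], res_ref.probabilities["combined"]
    )


def test_site_coverage_mismatch_is_error(params, rng):
    table, cand = _two_candidate_setup(params, rng, n=5)
    bad = cand(1, 1)
    bad["H1"] = bad["H1"][:-1]
    with pytest.raises(ValidationError, match="sites"):
        dp4.dp4_probabilities({"a": bad}, table, params)


# --------------------------------------------------------------------------
# model interface
# --------------------------------------------------------------------------

def test_dp4_model_summary_names_best_candidate(params, rng):
    table = make_table(delta_c=rng.uniform(20, 180, 6), delta_h=rng.uniform(1, 8, 6))
    good = make_conformer(
        "good",
        shieldings_c=params.sigma_ref["C13"] - table.delta_exp("C13"),
        shieldings_h=params.sigma_ref["H1"] - table.delta_exp("H1"),
    )
    bad = make_conformer(
        "bad",
        shieldings_c=good.shieldings[:6] + rng.normal(0, 8, 6),
        shieldings_h=good.shieldings[6:] + rng.normal(0, 0.8, 6),
    )
    res = dp4.DP4Model([good, bad], table, params).fit()
    assert res.top() == ["good"]
    assert "good" in res.summary()
    err = res.error_table().set_index(["candidate", "nucleus"])
    assert err.loc[("good", "C13"), "cmae"] <= err.loc[("bad", "C13"), "cmae"]
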