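import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from confshift import mixtures as mx
from confshift.dp4 import dp4_probabilities
from confshift.records import R_GAS, Composition, ValidationError
from conftest import make_conformer, make_table


# --------------------------------------------------------------------------
# Boltzmann populations
# --------------------------------------------------------------------------

def test_equal_energies_give_uniform_populations():
    np.testing.assert_allclose(mx.boltzmann_weights([5.0, 5.0, 5.0]), 1 / 3)


def test_rt_ln2_gap_gives_two_to_one():
    t = 298.15
    de = R_GAS * t * math.log(2)
    w = mx.boltzmann_weights([0.0, de], temperature=t)
    np.testing.assert_allclose(w, [2 / 3, 1 / 3], rtol=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(st.floats(0, 50, allow_nan=False), min_size=2, max_size=6),
    st.floats(-100, 100, allow_nan=False),
)
def test_boltzmann_invariant_under_uniform_shift(energies, shift):
    w0 = mx.boltzmann_weights(energies)
    w1 = mx.boltzmann_weights([e + shift for e in energies])
    np.testing.assert_allclose(w0, w1, atol=1e-12)


def test_boltzmann_monotone_in_own_energy():
    w_low = mx.boltzmann_weights([0.0, 5.0])
    w_high = mx.boltzmann_weights([0.0, 8.0])
    assert w_high[1] < w_low[1]
    with pytest.raises(ValidationError):
        mx.boltzmann_weights([0.0, np.inf])


# --------------------------------------------------------------------------
# simplex grid
# --------------------------------------------------------------------------

def test_simplex_grid_k2_half_step():
    grid = [c.fractions for c in mx.simplex_grid(2, 0.5)]
    assert grid == [(0.0, 1.0), (0.5, 0.5), (1.0, 0.0)]


def _stars_and_bars_oracle(k, step):
    """Brute-force enumeration of integer compositions of n into k parts."""
    import itertools

    n = round(1 / step)
    return sum(
        1
        for tup in itertools.product(range(n + 1), repeat=k)
        if sum(tup) == n
    )


@pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
@pytest.mark.parametrize("step", [0.5, 0.25, 0.2, 0.1])
def test_simplex_grid_counts_match_stars_and_bars(k, step):
    grid = mx.simplex_grid(k, step)
    n = round(1 / step)
    assert len(grid) == math.comb(n + k - 1, k - 1)
    assert len(grid) == _stars_and_bars_oracle(k, step)
    fr = [c.fractions for c in grid]
    assert fr == sorted(fr)  # lexicographic
    # vertices present
    for v in range(k):
        vertex = tuple(1.0 if i == v else 0.0 for i in range(k))
        assert vertex in fr


def test_simplex_grid_rejects_bad_step():
    with pytest.raises(ValidationError, match="divide"):
        mx.simplex_grid(3, 0.3)


# --------------------------------------------------------------------------
# mixture averaging
# --------------------------------------------------------------------------

def test_mixture_shifts_vertex_and_midpoint():
    s = np.array([[10.0, 100.0], [20.0, 120.0]])
    np.testing.assert_allclose(mx.mixture_shifts(s, Composition((1.0, 0.0))), s[0])
    np.testing.assert_allclose(
        mx.mixture_shifts(s, Composition((0.5, 0.5))), [15.0, 110.0]
    )
    same = np.vstack([s[0], s[0]])
    np.testing.assert_allclose(mx.mixture_shifts(same, Composition((0.3, 0.7))), s[0])


def test_mixture_shifts_coverage_mismatch():
    with pytest.raises(ValidationError):
        mx.mixture_shifts(np.ones((2, 3)), Composition((0.2, 0.3, 0.5)))
    with pytest.raises(ValidationError, match="cover"):
        mx.mixture_shifts(np.array([[1.0, np.nan]]), Composition((1.0,)))


# --------------------------------------------------------------------------
# grid scans
# --------------------------------------------------------------------------

def _reps(params, rng, k=3, n=6):
    table = make_table(delta_c=rng.uniform(20, 180, n), delta_h=rng.uniform(1, 8, n))
    reps = []
    for j in range(k):
        reps.append(
            make_conformer(
                f"rep-{j + 1}",
                shieldings_c=params.sigma_ref["C13"]
                - table.delta_exp("C13")
                + rng.normal(0, 3, n),
                shieldings_h=params.sigma_ref["H1"]
                - table.delta_exp("H1")
                + rng.normal(0, 0.3, n),
                energy=float(j),
            )
        )
    return reps, table


def test_grid_probabilities_sum_to_one(params, rng):
    reps, table = _reps(params, rng)
    res = mx.mixture_dp4_scan(reps, table, params, step=0.2)
    assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


def test_vertex_only_scan_reduces_to_pure_dp4(params, rng):
    reps, table = _reps(params, rng)
    res = mx.mixture_dp4_scan(reps, table, params, step=1.0)
    assert len(res.compositions) == len(reps)
    from confshift.dp4 import candidate_site_shifts

    pure = dp4_probabilities(
        {r.id: candidate_site_shifts(r, table, params) for r in reps},
        table,
        params,
    )
    # vertex (0,0,1) is rep-3, etc.: match by argmax fraction
    for comp, p in zip(res.compositions, res.probabilities):
        rid = reps[int(np.argmax(comp.fractions))].id
        assert p == pytest.approx(pure.probabilities.loc[rid, "combined"], rel=1e-9)


def test_permuting_representatives_permutes_grid(params, rng):
    reps, table = _reps(params, rng)
    res = mx.mixture_dp4_scan(reps, table, params, step=0.5)
    perm = [reps[2], reps[0], reps[1]]
    res_p = mx.mixture_dp4_scan(perm, table, params, step=0.5)
    lookup = {
        tuple(c.fractions): p for c, p in zip(res_p.compositions, res_p.probabilities)
    }
    for comp, p in zip(res.compositions, res.probabilities):
        f = comp.fractions
        assert lookup[(f[2], f[0], f[1])] == pytest.approx(p, rel=1e-9)


def test_error_scan_vertex_matches_single_conformer(params, rng):
    from confshift.dp4 import candidate_site_shifts, error_summary

    reps, table = _reps(params, rng)
    scan = mx.mixture_error_scan(reps, table, params, step=0.5)
    single = error_summary(candidate_site_shifts(reps[0], table, params), table)
    vertex = scan[(scan["x_rep-1"] == 1.0)].iloc[0]
    assert vertex["cmae_C13"] == pytest.approx(single.per_nucleus["C13"][0])
    assert vertex["cmaxerr_H1"] == pytest.approx(single.per_nucleus["H1"][1])


def test_error_scan_constant_for_identical_representatives(params, rng):
    reps, table = _reps(params, rng, k=1)
    twin = reps[0].with_(id="rep-2")
    scan = mx.mixture_error_scan([reps[0], twin], table, params, step=0.25)
    assert scan["cmae_C13"].std() == pytest.approx(0.0, abs=1e-12)


def test_band_probability_trivial_predicates(params, rng):
    reps, table = _reps(params, rng)
    res = mx.mixture_dp4_scan(reps, table, params, step=0.5)
    assert mx.band_probability(res, lambda c: True) == pytest.approx(1.0)
    assert mx.band_probability(res, lambda c: False) == 0.0
    major = mx.band_probability(res, lambda c: c.fractions[0] >= 0.5)
    assert 0.0 <= major <= 1.0


# --------------------------------------------------------------------------
# ternary aggregation
# --------------------------------------------------------------------------

def test_identity_partition_preserves_grid(params, rng):
    reps, table = _reps(params, rng, k=3)
    res = mx.mixture_dp4_scan(reps, table, params, step=0.2)
    tern = mx.aggregate_ternary(res, [[0], [1], [2]])
    assert len(tern.points) == len(res.compositions)
    assert tern.points["probability"].sum() == pytest.approx(1.0, abs=1e-9)
    sums = tern.points[["a", "b", "c"]].sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_merged_axes_collapse_to_k3_grid(params, rng):
    reps, table = _reps(params, rng, k=4)
    res = mx.mixture_dp4_scan(reps, table, params, step=0.1)
    assert len(res.compositions) == 286
    tern = mx.aggregate_ternary(res, [[0], [1], [2, 3]])
    # aggregated points live on the k=3 grid: stars-and-bars C(12,2) = 66
    assert len(tern.points) == 66
    assert tern.points["probability"].sum() == pytest.approx(1.0, abs=1e-9)
    assert tern.axis_labels[2] == "rep-3+rep-4"


def test_invalid_partition_rejected(params, rng):
    reps, table = _reps(params, rng, k=3)
    res = mx.mixture_dp4_scan(reps, table, params, step=0.5)
    with pytest.raises(ValidationError):
        mx.aggregate_ternary(res, [[0], [1], [1, 2]])


# --------------------------------------------------------------------------
# model interface
# --------------------------------------------------------------------------

def test_mixture_model_summary_and_best_errors(params, rng):
    reps, table = _reps(params, rng)
    res = mx.MixtureDP4Model(reps, table, params, step=0.2).fit()
    text = res.summary()
    assert "grid points: 21" in text
    best = res.best_errors()
    assert set(best) == {"C13", "H1"}
    for comp, val in best.values():
        assert val >= 0
        assert len(comp) == 3
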