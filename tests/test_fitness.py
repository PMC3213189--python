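"""Fitness ratios, sweeps, envelopes and random-environment averages."""

import numpy as np
import pytest

from sporedyn.environment import periodic_profile, random_dichotomic_profile
from sporedyn.fitness import (
    _ratios_over_profiles,
    fitness_ratio,
    model_suite,
    random_environment_average,
    sensitivity_envelope,
    sweep_high_stress_fraction,
)
from sporedyn.models import (
    PHASES,
    RateParameters,
    default_parameters,
    make_topology,
)
from sporedyn.propagation import initial_state

from test_propagation import ode_final_state


def growth_only_params(topology, g):
    """All transitions off: the population just grows at rate g."""
    zero = {p: 0.0 for p in PHASES}
    return RateParameters(
        forward={e.key: dict(zero) for e in topology.edges},
        growth={s: {p: (g if s != "S" else 0.0) for p in PHASES} for s in topology.states},
    )


def test_self_ratio_is_exactly_one():
    topo = make_topology("hybrid")
    params = default_parameters(topo)
    prof = random_dichotomic_profile(0.4, 6.0, 30.0, seed=3)
    assert fitness_ratio(topo, params, topo, params, prof) == 1.0


def test_reciprocal_ratios_multiply_to_one():
    hyb = make_topology("hybrid")
    irr = make_topology("irreversible_only")
    p_h, p_i = default_parameters(hyb), default_parameters(irr)
    prof = random_dichotomic_profile(0.6, 6.0, 30.0, seed=9)
    ab = fitness_ratio(hyb, p_h, irr, p_i, prof)
    ba = fitness_ratio(irr, p_i, hyb, p_h, prof)
    assert ab * ba == pytest.approx(1.0, rel=1e-12)


def test_growth_only_models_have_closed_form_ratio():
    """With all transitions off the ratio is exp((g_a - g_b) * T)."""
    topo = make_topology("irreversible_only")
    g_a, g_b, total = 0.4, 0.1, 30.0
    prof = random_dichotomic_profile(0.5, 6.0, total, seed=2)
    r = fitness_ratio(
        topo, growth_only_params(topo, g_a), topo, growth_only_params(topo, g_b), prof
    )
    assert r == pytest.approx(np.exp((g_a - g_b) * total), rel=1e-9)


def test_ratio_invariant_to_initial_scale():
    topo_a = make_topology("hybrid")
    topo_b = make_topology("reversible_only")
    p_a, p_b = default_parameters(topo_a), default_parameters(topo_b)
    prof = periodic_profile(0.3, 6.0, 30.0)
    r1 = fitness_ratio(topo_a, p_a, topo_b, p_b, prof)
    n0a = initial_state(topo_a, total=37.0)
    r2 = fitness_ratio(topo_a, p_a, topo_b, p_b, prof, n0=n0a)
    assert r2 == pytest.approx(r1, rel=1e-12)


def test_fitness_ratio_matches_ode_oracle():
    hyb = make_topology("hybrid")
    irr = make_topology("irreversible_only")
    p_h, p_i = default_parameters(hyb), default_parameters(irr)
    prof = periodic_profile(0.2, 6.0, 30.0)
    r = fitness_ratio(hyb, p_h, irr, p_i, prof)
    num = ode_final_state(hyb, p_h, prof, initial_state(hyb).counts).sum()
    den = ode_final_state(irr, p_i, prof, initial_state(irr).counts).sum()
    assert r == pytest.approx(num / den, rel=1e-6)


def test_sweep_grid_size_and_metadata():
    curve = sweep_high_stress_fraction(n_f=10, n_realizations=2, seed=0)
    assert curve.fractions.size == 10
    assert np.all((curve.fractions > 0) & (curve.fractions < 1))
    assert curve.meta["n_realizations"] == 2
    with pytest.raises(ValueError):
        sweep_high_stress_fraction(n_f=1)


def test_identical_models_give_unit_curves():
    topo = make_topology("hybrid")
    params = default_parameters(topo)
    suite = {name: (topo, params) for name in ("hybrid", "irreversible_only", "reversible_only")}
    profiles = [
        [random_dichotomic_profile(f, 6.0, 30.0, seed=s)]
        for s, f in enumerate((0.2, 0.5, 0.8))
    ]
    r_irr, r_rev = _ratios_over_profiles(suite, profiles)
    np.testing.assert_array_equal(r_irr, 1.0)
    np.testing.assert_array_equal(r_rev, 1.0)


def test_curves_cross_unity_at_interior_fractions():
    """Both ratio curves change sign around 1 inside (0, 1), giving the
    regime structure of the model comparison."""
    curve = sweep_high_stress_fraction(n_f=40, n_realizations=10, seed=5)
    for r in (curve.ratio_hyb_irr, curve.ratio_hyb_rev):
        assert np.any(r > 1.0) and np.any(r < 1.0)


class TestSensitivityEnvelope:
    def test_zero_perturbation_collapses_onto_baseline(self):
        base = sweep_high_stress_fraction(n_f=6, n_realizations=2, seed=1)
        env = sensitivity_envelope(
            base, perturbation_fraction=0.0, n_draws=3, perturbation_seed=2
        )
        np.testing.assert_allclose(env.env_irr[0], base.ratio_hyb_irr, rtol=1e-12)
        np.testing.assert_allclose(env.env_irr[1], base.ratio_hyb_irr, rtol=1e-12)
        np.testing.assert_allclose(env.env_rev[0], base.ratio_hyb_rev, rtol=1e-12)
        np.testing.assert_allclose(env.env_rev[1], base.ratio_hyb_rev, rtol=1e-12)

    def test_envelopes_bracket_baseline_pointwise(self):
        base = sweep_high_stress_fraction(n_f=8, n_realizations=3, seed=1)
        env = sensitivity_envelope(
            base, perturbation_fraction=0.2, n_draws=10, perturbation_seed=3
        )
        for (lo, hi), mid in (
            (env.env_irr, base.ratio_hyb_irr),
            (env.env_rev, base.ratio_hyb_rev),
        ):
            assert np.all(lo <= mid + 1e-12) and np.all(hi >= mid - 1e-12)
            assert np.any(hi > lo)  # perturbation actually widens something

    def test_envelope_width_monotone_in_draws(self):
        """With a shared perturbation stream, the first draws of a larger
        batch coincide, so the min/max envelope can only widen."""
        base = sweep_high_stress_fraction(n_f=6, n_realizations=2, seed=4)
        small = sensitivity_envelope(base, 0.2, n_draws=5, perturbation_seed=7)
        large = sensitivity_envelope(base, 0.2, n_draws=15, perturbation_seed=7)
        assert np.all(large.env_irr[0] <= small.env_irr[0] + 1e-15)
        assert np.all(large.env_irr[1] >= small.env_irr[1] - 1e-15)


def test_random_environment_average_shapes_and_bars():
    res = random_environment_average(
        n_fractions=20, total_time=30.0, seed=0,
        perturbation_fraction=0.2, n_perturbation_draws=5,
    )
    assert res.n_fractions == 20
    assert res.mean_ratio_hyb_irr > 0 and res.mean_ratio_hyb_rev > 0
    lo, hi = res.var_irr
    assert lo <= res.mean_ratio_hyb_irr <= hi
    lo, hi = res.var_rev
    assert lo <= res.mean_ratio_hyb_rev <= hi


def test_curve_csv_and_json_outputs(tmp_path):
    curve = sweep_high_stress_fraction(n_f=5, n_realizations=2, seed=0)
    env = sensitivity_envelope(curve, 0.2, n_draws=2, perturbation_seed=1)
    csv_path = tmp_path / "curve.csv"
    env.to_csv(csv_path)
    import pandas as pd

    df = pd.read_csv(csv_path)
    assert list(df.columns) == [
        "high_stress_fraction",
        "ratio_hybrid_vs_irreversible",
        "ratio_hybrid_vs_reversible",
        "env_irr_lo", "env_irr_hi", "env_rev_lo", "env_rev_hi",
    ]
    env.write_json(tmp_path / "curve.json")
    import json

    meta = json.loads((tmp_path / "curve.json").read_text())
    assert meta["n_fractions"] == 5
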