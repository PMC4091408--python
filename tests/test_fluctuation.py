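"""Fluctuation counting: alpha estimator, unit recovery, controls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cenquant import fluctuation
from cenquant.synthetic import PartitionSimSpec, make_sister_pairs


def make_pairs(values):
    return [fluctuation.SisterPair(a, b) for a, b in values]


def test_pair_construction_and_rejection():
    pair, reason = fluctuation.pair_from_intensities(6, 4)
    assert (pair.delta, pair.sigma, reason) == (2, 10, None)
    pair, _ = fluctuation.pair_from_intensities(5, 5)
    assert pair.delta == 0
    pair, reason = fluctuation.pair_from_intensities(0, 0)
    assert pair is None and reason == "nonpositive"


def test_alpha_hand_example():
    # delta^2/Sigma for (6,4), (5,5), (7,3) is 0.4, 0, 1.6 -> mean 2/3
    pairs = make_pairs([(6, 4), (5, 5), (7, 3)])
    alpha = fluctuation.estimate_alpha(pairs)
    assert alpha == pytest.approx(2 / 3, rel=1e-12)
    est = fluctuation.units_per_centromere(pairs, alpha)
    assert np.allclose(est.units, 15.0)


def test_alpha_error_paths():
    with pytest.raises(ValueError, match="alpha undefined"):
        fluctuation.estimate_alpha(make_pairs([(5, 5), (3, 3), (4, 4)]))
    with pytest.raises(ValueError):
        fluctuation.estimate_alpha(make_pairs([(6, 4)]))


def test_single_unit_partitioning():
    """One unit per centromere: every pair is (b, 0) or (0, b)."""
    table, truth = make_sister_pairs(PartitionSimSpec(
        units_mean=1, units_dispersion=0, unit_brightness=7.0,
        measurement_noise_sd=0, n_cells=5, seed=0,
    ))
    vals = np.sort(table[["i1", "i2"]].values, axis=1)
    assert np.all(vals[:, 0] == 0) and np.all(vals[:, 1] == 7.0)


def test_alpha_recovers_unit_brightness():
    """E[delta^2 / Sigma] equals the per-unit brightness for Binomial(N, 1/2)."""
    b = 100.0
    table, _ = make_sister_pairs(PartitionSimSpec(
        units_mean=75, units_dispersion=0, unit_brightness=b,
        measurement_noise_sd=0, n_cells=220, seed=1,
    ))
    pairs, _ = fluctuation.pairs_from_table(table)
    alpha = fluctuation.estimate_alpha(pairs)
    n = len(pairs)
    se = b * np.sqrt(2 / n)  # Var(delta^2/Sigma) ~ 2 b^2 for binomial halves
    assert abs(alpha - b) < 4 * se


@pytest.mark.parametrize("n_true", [10, 75, 200])
def test_unit_number_recovery(n_true):
    table, _ = make_sister_pairs(PartitionSimSpec(
        units_mean=n_true, units_dispersion=0, unit_brightness=50.0,
        measurement_noise_sd=0, n_cells=220, seed=n_true,
    ))
    pairs, _ = fluctuation.pairs_from_table(table)
    est = fluctuation.units_per_centromere(pairs, fluctuation.estimate_alpha(pairs))
    se = n_true * np.sqrt(2 / est.n_pairs)
    assert abs(est.units_mean - n_true) < 3 * se


def test_measurement_noise_biases_units_downward():
    """Additive intensity noise inflates delta^2, hence alpha, never the units."""
    clean, _ = make_sister_pairs(PartitionSimSpec(
        units_mean=75, units_dispersion=0, measurement_noise_sd=0,
        n_cells=220, seed=2,
    ))
    noisy, _ = make_sister_pairs(PartitionSimSpec(
        units_mean=75, units_dispersion=0, measurement_noise_sd=30.0,
        n_cells=220, seed=2,
    ))
    def mean_units(t):
        pairs, _ = fluctuation.pairs_from_table(t)
        return fluctuation.units_per_centromere(
            pairs, fluctuation.estimate_alpha(pairs)).units_mean
    assert mean_units(noisy) < mean_units(clean)


def test_molecule_conversion_chain():
    assert fluctuation.molecules_from_units(75.4) == pytest.approx(150.8)
    assert fluctuation.molecules_from_units(
        75.4, relative_level=0.40) == pytest.approx(377.0)
    assert fluctuation.molecules_from_units(0) == 0


@given(scale=st.floats(0.01, 100))
def test_scale_invariance(scale):
    """Rescaling intensities rescales alpha but leaves unit numbers unchanged."""
    base = make_pairs([(6, 4), (5, 5), (7, 3), (8, 2)])
    scaled = make_pairs([(6 * scale, 4 * scale), (5 * scale, 5 * scale),
                         (7 * scale, 3 * scale), (8 * scale, 2 * scale)])
    a0 = fluctuation.estimate_alpha(base)
    a1 = fluctuation.estimate_alpha(scaled)
    assert a1 == pytest.approx(a0 * scale, rel=1e-9)
    u0 = fluctuation.units_per_centromere(base, a0).units
    u1 = fluctuation.units_per_centromere(scaled, a1).units
    assert np.allclose(u0, u1)


def test_minimum_estimate_under_cosegregation():
    """Units grouping k nucleosomes undercount molecules, never overcount."""
    k = 3  # nucleosomes co-segregating per unit
    true_nucleosomes = 75
    table, _ = make_sister_pairs(PartitionSimSpec(
        units_mean=true_nucleosomes // k, units_dispersion=0,
        unit_brightness=50.0 * k, n_cells=220, seed=4,
    ))
    pairs, _ = fluctuation.pairs_from_table(table)
    est = fluctuation.units_per_centromere(pairs, fluctuation.estimate_alpha(pairs))
    recovered_molecules = fluctuation.molecules_from_units(est.units_mean)
    assert recovered_molecules <= true_nucleosomes * 2 * 1.05


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_random_pair_control_differs():
    """Random re-pairing breaks the sister correlation in both regimes.

    With inter-centromere dispersion the mixture inflates delta^2 (units drop);
    with none, independent halves carry half the sister fluctuation (alpha
    halves, units double). Either way the Welch test flags the control.
    """
    for dispersion, expect_ratio in ((0.25, "less"), (0.0, "greater")):
        table, _ = make_sister_pairs(PartitionSimSpec(
            units_mean=75, units_dispersion=dispersion, n_cells=100, seed=5,
        ))
        pairs, _ = fluctuation.pairs_from_table(table)
        sister = fluctuation.units_per_centromere(
            pairs, fluctuation.estimate_alpha(pairs))
        rounds = fluctuation.random_pair_control(table, n_rounds=3, seed=6)
        assert all(r.p_value < 1e-4 for r in rounds)
        if expect_ratio == "less":
            assert all(r.units_mean < sister.units_mean for r in rounds)
        else:
            assert all(r.units_mean > sister.units_mean for r in rounds)


def test_random_pair_control_seed_reproducible():
    table, _ = make_sister_pairs(PartitionSimSpec(n_cells=30, seed=7))
    a = fluctuation.random_pair_control(table, seed=42)
    b = fluctuation.random_pair_control(table, seed=42)
    assert [r.alpha for r in a] == [r.alpha for r in b]


def test_analyze_experiment_scopes():
    t1, _ = make_sister_pairs(PartitionSimSpec(n_cells=10, seed=8,
                                               experiment_id="A"))
    t2, _ = make_sister_pairs(PartitionSimSpec(n_cells=10, seed=9,
                                               experiment_id="B"))
    import pandas as pd
    merged = pd.concat([t1, t2], ignore_index=True)
    res = fluctuation.analyze_experiment(merged)
    assert set(res) == {"A", "B"}
    assert all(est.alpha > 0 for est in res.values())
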