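"""Synthetic fixtures: toy ensembles, quartet ground truth, determinism,
and the bundled riboswitch construct."""

import numpy as np
import pandas as pd
import pytest

from lm2r.constructs import BasePair, Construct, design_double_pair_lock
from lm2r.rescue import rescue_factor
from lm2r.synthetic import (
    ToyEnsemble,
    anticorrelated_ensemble,
    correlated_ensemble,
    dotbracket_pairs,
    ensemble_profile,
    independent_ensemble,
    make_calibration_fixture,
    make_quartet_fixture,
    observe_helix,
    three_state_ensemble,
)


@pytest.fixture
def two_state():
    construct = Construct(name="mini", sequence="GGGGAAAACCCCAAAA")
    return ToyEnsemble(
        construct=construct,
        structures=("((((....))))....", "................"),
        weights=(0.5, 0.5),
        noise_sd=0.0,
    )


class TestToyEnsemble:
    def test_dotbracket_parsing(self):
        pairs = dotbracket_pairs("((..))")
        assert pairs == frozenset({(1, 6), (2, 5)})
        with pytest.raises(ValueError, match="unbalanced"):
            dotbracket_pairs("((.)")

    def test_weights_must_sum_to_one(self):
        construct = Construct(name="x", sequence="GGGGAAAACCCC")
        with pytest.raises(ValueError, match="sum to 1"):
            ToyEnsemble(construct, ("." * 12,), (0.5,))

    def test_structures_must_match_sequence(self, two_state):
        with pytest.raises(ValueError, match="unpairable"):
            ToyEnsemble(
                two_state.construct,
                ("(..............)",),  # G1-A16 cannot pair
                (1.0,),
            )

    def test_frequency_and_conditioning(self, two_state):
        pair = BasePair(1, 12)
        assert two_state.frequency_of(pair) == pytest.approx(0.5)
        locked = two_state.conditioned_on(pair)
        assert locked.frequency_of(pair) == pytest.approx(1.0)
        assert len(locked.structures) == 2  # absent structure kept at weight 0
        with pytest.raises(ValueError, match="absent"):
            two_state.conditioned_on(BasePair(2, 3))


class TestEnsembleProfile:
    def test_single_structure_gives_binary_profile(self, two_state):
        prof = ensemble_profile(two_state, weights=(1.0, 0.0))
        assert set(np.unique(prof.values)) == {0.0, 1.0}
        assert (prof.value_at([5, 6, 7, 8]) == 1.0).all()
        assert (prof.value_at([1, 2, 3, 4]) == 0.0).all()

    def test_half_mixture_reads_half(self, two_state):
        prof = ensemble_profile(two_state)
        assert np.allclose(prof.value_at([1, 2, 3, 4, 9, 10, 11, 12]), 0.5)
        assert np.allclose(prof.value_at([5, 6, 7, 8]), 1.0)

    def test_seeded_noise_is_deterministic(self):
        ensemble, _ = three_state_ensemble(4, 0.5, noise_sd=0.1, seed=11)
        a = ensemble_profile(ensemble)
        b = ensemble_profile(ensemble)
        assert np.array_equal(a.values, b.values)
        assert (a.values >= 0).all()


class TestQuartetFixture:
    def test_always_present_pair_rescues_fully(self):
        ensemble, helix = three_state_ensemble(4, 1.0, noise_sd=0.0, seed=2)
        fixture = make_quartet_fixture(ensemble, helix.pairs[0])
        assert fixture.true_frequency == pytest.approx(1.0)
        assert rescue_factor(fixture.quartet) == pytest.approx(1.0)

    def test_absent_pair_shows_no_rescue(self):
        ensemble, helix = three_state_ensemble(4, 0.0, noise_sd=0.0, seed=2)
        fixture = make_quartet_fixture(ensemble, helix.pairs[0])
        assert fixture.true_frequency == 0.0
        assert rescue_factor(fixture.quartet) == pytest.approx(0.0, abs=1e-9)

    def test_half_frequency_gives_partial_rescue(self):
        ensemble, helix = three_state_ensemble(4, 0.5, noise_sd=0.0, seed=2)
        fixture = make_quartet_fixture(ensemble, helix.pairs[0])
        factor = rescue_factor(fixture.quartet)
        assert 0.05 < factor < 0.95

    def test_factor_increases_with_frequency(self):
        factors = []
        for freq in (0.1, 0.3, 0.5, 0.7, 0.9):
            ensemble, helix = three_state_ensemble(4, freq, noise_sd=0.0, seed=5)
            factors.append(rescue_factor(make_quartet_fixture(ensemble, helix.pairs[0]).quartet))
        assert factors == sorted(factors)

    def test_pair_absent_from_all_structures_rejected(self, two_state):
        with pytest.raises(ValueError, match="absent from every structure"):
            make_quartet_fixture(two_state, BasePair(2, 3))

    def test_uniform_response_model_also_informative(self):
        ensemble, helix = three_state_ensemble(4, 0.5, noise_sd=0.0, seed=2)
        fixture = make_quartet_fixture(ensemble, helix.pairs[0], response_model="uniform")
        assert 0.0 < rescue_factor(fixture.quartet) < 1.0


class TestCorrelationFamilies:
    def test_anticorrelated_helices_are_exclusive(self):
        ensemble, h1, h2 = anticorrelated_ensemble(f1=0.5, f2=0.35, seed=3)
        assert ensemble.frequency_of(h1) == pytest.approx(0.5)
        assert ensemble.frequency_of(h2) == pytest.approx(0.35)
        joint = sum(
            w
            for w, ps in zip(ensemble.weights, ensemble.pair_sets)
            if {(p.i, p.j) for p in h1.pairs} <= ps
            and {(p.i, p.j) for p in h2.pairs} <= ps
        )
        assert joint == 0.0

    @pytest.mark.parametrize("g", [0.5, 1.0])
    def test_correlated_ensemble_hits_requested_g(self, g):
        ensemble, h1, h2 = correlated_ensemble(f1=0.5, f2=0.4, g=g, seed=3)
        f1 = ensemble.frequency_of(h1)
        f2 = ensemble.frequency_of(h2)
        assert f1 == pytest.approx(0.5, abs=1e-9)
        assert f2 == pytest.approx(0.4, abs=1e-9)
        joint = sum(
            w
            for w, ps in zip(ensemble.weights, ensemble.pair_sets)
            if {(p.i, p.j) for p in h1.pairs} <= ps
            and {(p.i, p.j) for p in h2.pairs} <= ps
        )
        assert joint == pytest.approx(g * f1 * f2, abs=1e-9)

    def test_locking_independent_module_preserves_other_frequency(self):
        ensemble, h1, h2 = independent_ensemble(f1=0.6, f2=0.4, seed=4)
        locked = ensemble.conditioned_on(h2)
        assert locked.frequency_of(h1) == pytest.approx(0.6, abs=1e-9)

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            correlated_ensemble(f1=0.9, f2=0.9, g=3.0)


class TestCalibrationFixture:
    def test_deterministic_across_runs(self):
        a = make_calibration_fixture(40, seed=9)
        b = make_calibration_fixture(40, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_spans_frequency_range(self, toy_calibration):
        assert toy_calibration.frequency.min() < 0.1
        assert toy_calibration.frequency.max() > 0.9
        assert set(toy_calibration.n_bp.unique()) == {3, 4, 5, 6}

    def test_factor_tracks_true_frequency(self, toy_calibration):
        from scipy.stats import spearmanr

        rho = spearmanr(
            toy_calibration.rescue_factor, toy_calibration.frequency
        ).statistic
        assert rho > 0.8


class TestObserveHelix:
    def test_mean_factor_over_helix_pairs(self):
        ensemble, helix = three_state_ensemble(4, 0.7, seed=6)
        result = observe_helix(ensemble, helix)
        assert result.n_pairs == 4
        assert 0.0 < result.mean_factor < 1.0


class TestBundledConstruct:
    def test_reference_loops_are_gagua(self, add_bundle):
        construct, _, _ = add_bundle
        for loop in construct.reference_loops:
            assert "".join(construct.base_at(p) for p in loop) == "GAGUA"

    def test_sequence_and_numbering(self, add_bundle):
        construct, helices, _ = add_bundle
        assert len(construct.sequence) == 198
        # published helix registries carry Watson-Crick pairs
        for helix in helices.values():
            for pair in helix.pairs:
                assert pair.is_paired_in(construct)

    def test_lock_designs_reproduce_bundled_labels(self, add_bundle):
        construct, helices, locks = add_bundle
        for name in ("P1", "P4B"):
            assert (
                design_double_pair_lock(construct, helices[name]).label
                == locks[f"lock-{name}"]
            )
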