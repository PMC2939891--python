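"""Ensemble prediction: n-lowest averaging, template/register selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sh3score.ensemble import (
    ConfigurationError,
    PredictionConfig,
    n_lowest_average,
    predict,
    predict_batch,
    template_energy,
)
from sh3score.matrixio import EnergyMatrix, MatrixEnsemble
from sh3score.scoring import map_sequence, offset_preference_order, score_mapping

from conftest import random_ensemble, random_matrix, random_peptide


def brute_force_predict(ensemble, sequence, offsets, n_lowest=None):
    """Independent oracle: enumerate (template, offset, size-n conformation subsets)."""
    best = None
    for t in ensemble.template_ids:
        per_template = None
        for o in offset_preference_order(offsets):
            confs = [
                score_mapping(
                    ensemble.matrices[(t, c)], map_sequence(sequence, o)
                )
                for c in ensemble.conformation_ids
            ]
            n = n_lowest if n_lowest is not None else len(confs)
            # the n-lowest mean equals the minimum over all size-n subsets
            e = min(
                float(np.mean(sub)) for sub in itertools.combinations(confs, n)
            )
            if per_template is None or e < per_template[0] - 1e-12:
                per_template = (e, o)
        e, o = per_template
        if best is None or e < best[0] - 1e-12:
            best = (e, t, o)
    return best


class TestNLowestAverage:
    def test_reference_points(self):
        assert n_lowest_average([3, 1, 2], 1) == 1.0
        assert n_lowest_average([3, 1, 2], 3) == 2.0

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            n_lowest_average([1.0, 2.0], 3)
        with pytest.raises(ValueError):
            n_lowest_average([1.0, 2.0], 0)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=11))
    def test_non_decreasing_in_n_and_matches_sort_oracle(self, values):
        results = [n_lowest_average(values, n) for n in range(1, len(values) + 1)]
        expected = [
            float(np.mean(sorted(values)[:n])) for n in range(1, len(values) + 1)
        ]
        assert results == pytest.approx(expected, abs=1e-9)
        assert all(a <= b + 1e-12 for a, b in zip(results, results[1:]))


class TestTemplateEnergy:
    def test_single_conformation_reduces_to_best_offset(self, rng):
        from sh3score.scoring import best_offset

        m = random_matrix(rng)
        ens = MatrixEnsemble(domain_id="toy", matrices={(1, 1): m})
        seq = random_peptide(rng)
        o, e, per_conf = template_energy(ens, 1, seq)
        exp_o, exp_e = best_offset(m, seq)
        assert (o, e) == (exp_o, pytest.approx(exp_e, abs=1e-12))
        assert per_conf == ((1, pytest.approx(exp_e, abs=1e-12)),)

    def test_identical_conformations_equal_single_matrix_energy(self, rng):
        from sh3score.scoring import best_offset

        m = random_matrix(rng)
        matrices = {
            (1, c): EnergyMatrix("toy", 1, "I", c, m.values) for c in range(1, 12)
        }
        ens = MatrixEnsemble(domain_id="toy", matrices=matrices)
        seq = random_peptide(rng)
        _, exp_e = best_offset(m, seq)
        for n in (1, 5, 11):
            cfg = PredictionConfig(n_lowest=n)
            _, e, _ = template_energy(ens, 1, seq, cfg)
            assert e == pytest.approx(exp_e, abs=1e-12)

    def test_matches_subset_enumeration_oracle(self, rng):
        offsets = range(-2, 3)
        for _ in range(30):
            ens = random_ensemble(rng, n_templates=1, n_conformations=3)
            seq = random_peptide(rng)
            cfg = PredictionConfig(n_lowest=2, offset_min=-2, offset_max=2)
            o, e, _ = template_energy(ens, 1, seq, cfg)
            exp_e, _, exp_o = brute_force_predict(ens, seq, offsets, n_lowest=2)
            assert e == pytest.approx(exp_e, abs=1e-12)
            assert o == exp_o


class TestPredict:
    def test_uniformly_lower_template_is_selected(self, rng):
        base = random_ensemble(rng, n_templates=6, n_conformations=4, n_class_i=2)
        matrices = dict(base.matrices)
        for c in base.conformation_ids:
            shifted = matrices[(5, c)].values - 1.0
            matrices[(5, c)] = EnergyMatrix("toy", 5, "II", c, shifted)
        ens = MatrixEnsemble(domain_id="toy", matrices=matrices)
        # full-coverage register for every offset -> the -1.0 shift dominates
        seq = random_peptide(rng, 20)
        pred = predict(ens, seq, PredictionConfig())
        assert pred.template_id == 5

    def test_fixed_template_is_honored(self, rng):
        ens = random_ensemble(rng, n_templates=4, n_conformations=3)
        pred = predict(ens, random_peptide(rng),
                       PredictionConfig(template_selection="fixed:3"))
        assert pred.template_id == 3

    def test_motif_class_restricts_candidates(self, rng):
        ens = random_ensemble(rng, n_templates=9, n_conformations=3, n_class_i=3)
        cfg = PredictionConfig(template_selection="motif_class")
        class_i_peptide = "ARAAPAAPAA"
        pred = predict(ens, class_i_peptide, cfg)
        assert pred.template_id in (1, 2, 3)
        assert pred.template_class == "I"
        # motif-free peptides fall back to the full template set
        free = predict(ens, "AAAAAAAAAA", cfg)
        unrestricted = predict(ens, "AAAAAAAAAA", PredictionConfig())
        assert free.energy == unrestricted.energy

    def test_motif_class_without_matching_templates_errors(self, rng):
        ens = random_ensemble(rng, n_templates=3, n_conformations=2, n_class_i=0)
        with pytest.raises(ConfigurationError, match="class I"):
            predict(ens, "ARAAPAAPAA",
                    PredictionConfig(template_selection="motif_class"))

    def test_predict_energy_bounds_every_template(self, rng):
        for _ in range(20):
            ens = random_ensemble(rng, n_templates=3, n_conformations=3)
            seq = random_peptide(rng)
            cfg = PredictionConfig(n_lowest=2)
            pred = predict(ens, seq, cfg)
            for t in ens.template_ids:
                _, e, _ = template_energy(ens, t, seq, cfg)
                assert pred.energy <= e

    def test_n1_ensemble_bounds_single_conformations(self, rng):
        ens = random_ensemble(rng, n_templates=2, n_conformations=4)
        for _ in range(10):
            seq = random_peptide(rng)
            e_n1 = predict(ens, seq, PredictionConfig(n_lowest=1)).energy
            for c in ens.conformation_ids:
                single = predict(
                    ens, seq, PredictionConfig(conformation_mode=f"single:{c}")
                ).energy
                assert e_n1 <= single + 1e-12

    def test_energy_non_decreasing_in_n_for_fixed_template_and_offset(self, rng):
        ens = random_ensemble(rng, n_templates=1, n_conformations=6)
        seq = random_peptide(rng)
        energies = []
        for n in range(1, 7):
            cfg = PredictionConfig(n_lowest=n, offset_min=0, offset_max=0,
                                   template_selection="fixed:1")
            energies.append(predict(ens, seq, cfg).energy)
        assert all(a <= b + 1e-12 for a, b in zip(energies, energies[1:]))

    def test_prediction_energy_is_n_lowest_average_of_reported_conformations(
        self, rng
    ):
        ens = random_ensemble(rng, n_templates=3, n_conformations=5)
        cfg = PredictionConfig(n_lowest=3)
        pred = predict(ens, random_peptide(rng), cfg)
        per_conf = [e for _, e in pred.per_conformation_energies]
        assert pred.energy == pytest.approx(n_lowest_average(per_conf, 3), abs=1e-12)


class TestPredictBatch:
    def test_empty_batch(self, rng):
        ens = random_ensemble(rng)
        assert predict_batch(ens, []) == []

    def test_batch_equals_loop_of_single_predictions(self, rng):
        ens = random_ensemble(rng, n_templates=3, n_conformations=4)
        seqs = [random_peptide(rng, int(rng.integers(6, 14))) for _ in range(40)]
        cfg = PredictionConfig(n_lowest=2)
        batch = predict_batch(ens, seqs, cfg)
        for seq, b in zip(seqs, batch):
            single = predict(ens, seq, cfg)
            assert (single.energy, single.template_id, single.offset) == (
                b.energy, b.template_id, b.offset,
            )

    def test_matches_brute_force_enumeration(self, rng):
        # small random instances, exhaustive (template x offset x subset) oracle
        for k in range(40):
            ens = random_ensemble(
                rng,
                n_templates=int(rng.integers(1, 4)),
                n_conformations=int(rng.integers(1, 4)),
            )
            n = int(rng.integers(1, ens.n_conformations + 1))
            seq = random_peptide(rng, int(rng.integers(5, 13)))
            cfg = PredictionConfig(n_lowest=n, offset_min=-2, offset_max=2)
            pred = predict(ens, seq, cfg)
            exp_e, exp_t, exp_o = brute_force_predict(
                ens, seq, range(-2, 3), n_lowest=n
            )
            assert pred.energy == pytest.approx(exp_e, abs=1e-12)
            assert (pred.template_id, pred.offset) == (exp_t, exp_o)

    def test_variable_length_sequences_are_supported(self, rng):
        ens = random_ensemble(rng)
        seqs = ["ACD", "ACDEFGHIKLMNPQ", random_peptide(rng)]
        preds = predict_batch(ens, seqs, PredictionConfig())
        assert [p.peptide for p in preds] == seqs

    def test_per_conformation_offset_mode_lower_or_equal(self, rng):
        ens = random_ensemble(rng, n_templates=2, n_conformations=3)
        seq = random_peptide(rng)
        shared = predict(ens, seq, PredictionConfig())
        free = predict(ens, seq, PredictionConfig(per_conformation_offset=True))
        assert free.energy <= shared.energy + 1e-12
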