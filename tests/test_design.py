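import math
import random

import numpy as np
import pytest

import codonfold as cf
from codonfold.codon_model import ProteinSequence, translate
from codonfold.design import Objective, _LatticeFolder, _fixed_lattice, design, fold_fixed
from codonfold.lattice import build_lattice

from conftest import random_protein, random_rna


class TestObjective:
    def test_linear_design_weights(self):
        o = Objective("linear_design", 2.0)
        assert (o.mu, o.kappa) == (1.0, 2.0)

    def test_derna_weights(self):
        o = Objective("derna", 0.3)
        assert o.mu == pytest.approx(0.3) and o.kappa == pytest.approx(0.7)

    @pytest.mark.parametrize(
        "form, lam", [("derna", -0.1), ("derna", 1.1), ("linear_design", -1.0), ("zuker", 0.5)]
    )
    def test_invalid(self, form, lam):
        with pytest.raises(ValueError):
            Objective(form, lam)


class TestDesign:
    def test_single_path_protein(self, human_w, nn):
        lat = build_lattice(ProteinSequence("MW"), human_w)
        r = design(lat, nn, Objective("derna", 0.5))
        assert r.cds == "AUGUGG"
        assert r.mfe == cf.score_structure(r.cds, r.structure, nn)

    def test_pure_cai_limit_selects_max_w_codons(self, human_w, nn):
        # derna lambda=0: objective reduces to -S; every codon must be a
        # family maximum (unique maxima for F and K in the human table)
        lat = build_lattice(ProteinSequence("MFK"), human_w)
        r = design(lat, nn, Objective("derna", 0.0))
        assert r.cds == "AUG" + "UUC" + "AAG"
        assert r.cai == pytest.approx(1.0)
        assert r.structure == "." * 9

    def test_result_invariants_on_random_proteins(self, human_w, nus, nn):
        rng = random.Random(3)
        for _ in range(6):
            prot = random_protein(rng, 3, 8)
            lat = build_lattice(ProteinSequence(prot), human_w)
            for model in (nus, nn):
                r = design(lat, model, Objective("derna", 0.4))
                assert translate(r.cds) == prot
                assert r.cai == pytest.approx(math.exp(r.S / len(prot)))
                assert r.mfe == pytest.approx(
                    cf.score_structure(r.cds, r.structure, model)
                )
                assert r.objective_value == pytest.approx(0.4 * r.mfe - 0.6 * r.S)
                assert r.exact

    def test_stop_codon_designable(self, human_w, nn):
        lat = build_lattice(ProteinSequence("MK*"), human_w)
        r = design(lat, nn, Objective("derna", 0.0))
        assert translate(r.cds) == "MK*"

    def test_lambda_monotonicity_derna(self, human_w, nus, nn):
        # more weight on MFE => MFE non-increasing and S non-increasing
        lat = build_lattice(ProteinSequence("MFKLSR"), human_w)
        for model in (nus, nn):
            prev = None
            for lam in (0.05, 0.25, 0.5, 0.75, 0.95):
                r = design(lat, model, Objective("derna", lam))
                if prev is not None:
                    assert r.mfe <= prev[0] + 1e-9
                    assert r.S <= prev[1] + 1e-9
                prev = (r.mfe, r.S)

    def test_beam_width_validation(self, human_w, nn):
        lat = build_lattice(ProteinSequence("MF"), human_w)
        with pytest.raises(ValueError, match="beam"):
            design(lat, nn, Objective("derna", 0.5), beam=0)

    def test_deterministic_reruns(self, human_w, nn):
        lat = build_lattice(ProteinSequence("MLKSR"), human_w)
        r1 = design(lat, nn, Objective("derna", 0.5))
        r2 = design(lat, nn, Objective("derna", 0.5))
        assert (r1.cds, r1.structure) == (r2.cds, r2.structure)


class TestFoldFixed:
    def test_no_canonical_pairs(self, nus, nn):
        for model in (nus, nn):
            assert fold_fixed("AAAAAA", model) == (0.0, "......")

    def test_nussinov_hairpin(self, nus):
        assert fold_fixed("GGGAAACCC", nus) == (-3.0, "(((...)))")

    def test_dna_input_accepted(self, nus):
        mfe, db = fold_fixed("GGGAAACCC".replace("G", "G").replace("U", "T"), nus)
        assert mfe == -3.0

    def test_short_sequences_fold_open(self, nus, nn):
        for model in (nus, nn):
            for n in range(1, 5):
                assert fold_fixed("G" * n, model)[0] == 0.0

    @pytest.mark.parametrize("bad", ["", "ACGX", "ACG N"])
    def test_invalid_alphabet(self, bad, nus):
        with pytest.raises(ValueError):
            fold_fixed(bad, nus)

    def test_reported_mfe_rescoring(self, nus, nn, human_w):
        rng = random.Random(9)
        for _ in range(10):
            seq = random_rna(rng, 6, 20)
            for model in (nus, nn):
                mfe, db = fold_fixed(seq, model)
                assert mfe == pytest.approx(cf.score_structure(seq, db, model))

    def test_agrees_with_design_on_degenerate_lattice(self, human_w, nus, nn):
        # folding a fixed CDS == designing over a single-path lattice
        lat = build_lattice(ProteinSequence("MWM"), human_w)
        for model in (nus, nn):
            r = design(lat, model, Objective("derna", 1.0))
            assert fold_fixed("AUGUGGAUG", model)[0] == pytest.approx(r.mfe)


def test_exact_step_count_grows_cubically(nus):
    # split-point evaluations on constant-width (single-state) lattices
    rng = random.Random(5)
    ops = []
    for n in (30, 60):
        seq = "".join(rng.choice("ACGU") for _ in range(n))
        folder = _LatticeFolder(_fixed_lattice(seq), nus, 1.0, 0.0)
        folder.solve(trace=False)
        ops.append(folder.ops)
    exponent = math.log(ops[1] / ops[0]) / math.log(2)
    assert 2.2 < exponent < 3.8
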