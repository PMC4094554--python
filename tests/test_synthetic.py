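"""Synthetic generators: seed determinism and planted-structure recoverability."""

import math

import numpy as np
import pandas as pd
import pytest

from are_regnet.mic import MicParams, compute_mic
from are_regnet.motif import scan_sequence
from are_regnet.synthetic import (
    SyntheticConfig,
    UtrSpec,
    gen_decay_timecourse,
    gen_expression,
    gen_qpcr_table,
    gen_utr_fasta,
    gen_validation_geneset,
)


class TestGenExpression:
    def test_seeded_determinism_byte_identical(self):
        cfg = SyntheticConfig(n_genes=30, n_samples=20, seed=1)
        m1, t1 = gen_expression(cfg)
        m2, t2 = gen_expression(cfg)
        assert m1.to_csv() == m2.to_csv()
        assert t1 == t2

    def test_noiseless_linear_targets_perfectly_anticorrelated(self):
        cfg = SyntheticConfig(
            n_genes=20, n_samples=50, n_linear_targets=3, noise_sd=0.0, linear_slope=-2.0
        )
        m, truth = gen_expression(cfg)
        reg = m.loc[cfg.regulator_id]
        for g in truth["linear"]:
            assert np.corrcoef(reg, m.loc[g])[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_noiseless_parabola_invisible_to_pearson_visible_to_mic(self):
        # symmetric regulator: near-zero linear correlation, saturated MIC
        cfg = SyntheticConfig(
            n_genes=6,
            n_samples=12,
            n_linear_targets=0,
            n_nonlinear_targets=2,
            noise_sd=0.0,
            nonlinear_form="parabola",
            seed=5,
        )
        m, truth = gen_expression(cfg)
        reg = m.loc[cfg.regulator_id].to_numpy()
        oracle = MicParams(alpha=1.0, exhaustive_mode=True)
        for g in truth["nonlinear"]:
            # MIC saturates on the generated noiseless rows themselves
            assert compute_mic(reg, m.loc[g].to_numpy(), oracle) >= 0.9
        # under exact sign symmetry of the regulator the sample covariance
        # with any even function vanishes identically
        sym = np.concatenate([reg[:6], -reg[:6]])
        y = sym**2 - 1.0
        assert abs(np.corrcoef(sym, y)[0, 1]) < 0.1
        assert compute_mic(sym, y, oracle) >= 0.9

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="< n_genes"):
            SyntheticConfig(n_genes=5, n_linear_targets=3, n_nonlinear_targets=2)
        with pytest.raises(ValueError, match="noise_sd"):
            SyntheticConfig(noise_sd=-0.1)
        with pytest.raises(ValueError, match="nonlinear_form"):
            SyntheticConfig(nonlinear_form="spiral")


class TestGenUtrFasta:
    def test_planted_copies_recovered_exactly(self):
        specs = [
            UtrSpec(gene="T1", length=400, planted_copies=2),
            UtrSpec(gene="T2", length=400, planted_copies=3),
        ]
        seqs, truth = gen_utr_fasta(specs, seed=0)
        for spec in specs:
            hits = scan_sequence(seqs[spec.gene], gene=spec.gene)
            expected = truth.loc[truth["gene"] == spec.gene, "start"].tolist()
            assert [h[0] for h in hits.hits] == expected
            assert hits.copy_count == spec.planted_copies

    def test_background_is_motif_free(self):
        seqs, truth = gen_utr_fasta([UtrSpec(gene="BG", length=2000, planted_copies=0)], seed=1)
        assert truth.empty
        assert scan_sequence(seqs["BG"]).copy_count == 0

    def test_dna_and_rna_alphabets_scan_identically(self):
        sd, _ = gen_utr_fasta([UtrSpec(gene="G", length=300, planted_copies=2)], seed=2)
        sr, _ = gen_utr_fasta(
            [UtrSpec(gene="G", length=300, planted_copies=2, alphabet="RNA")], seed=2
        )
        assert scan_sequence(sd["G"]).copy_count == scan_sequence(sr["G"]).copy_count == 2
        assert set(sr["G"]) <= set("ACGU")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            UtrSpec(gene="X", length=20, planted_copies=2)


class TestGenValidationGeneset:
    def test_full_overlap_equals_planted(self):
        planted = [f"T{i}" for i in range(5)]
        universe = planted + [f"B{i}" for i in range(20)]
        gs = gen_validation_geneset(planted, 5, 0, universe, seed=0)
        assert set(gs.genes) == set(planted)

    def test_zero_overlap_disjoint_from_planted(self):
        planted = [f"T{i}" for i in range(5)]
        universe = planted + [f"B{i}" for i in range(20)]
        gs = gen_validation_geneset(planted, 0, 10, universe, seed=0)
        assert not set(gs.genes) & set(planted)

    def test_reproducible_and_sized(self):
        planted = [f"T{i}" for i in range(8)]
        universe = planted + [f"B{i}" for i in range(30)]
        a = gen_validation_geneset(planted, 4, 6, universe, seed=3)
        b = gen_validation_geneset(planted, 4, 6, universe, seed=3)
        assert a == b
        assert len(a) == 10

    def test_universe_too_small(self):
        with pytest.raises(ValueError, match="universe too small"):
            gen_validation_geneset(["T1"], 1, 10, ["T1", "B1"], seed=0)


class TestGenDecay:
    def test_noiseless_closed_form(self):
        tc = gen_decay_timecourse(2.6, timepoints=(0, 2, 4), noise_cv=0.0, n_replicates=1)
        expected = np.exp(-math.log(2) / 2.6 * np.array([0.0, 2.0, 4.0]))
        assert np.allclose(tc["abundance"].to_numpy(), expected, atol=1e-14)

    def test_no_decay_limit_constant_one(self):
        tc = gen_decay_timecourse(math.inf, noise_cv=0.0, no_decay=True)
        assert (tc["abundance"] == 1.0).all()

    def test_seeded_noise_reproducible_and_t0_normalised(self):
        a = gen_decay_timecourse(2.6, noise_cv=0.2, seed=4)
        b = gen_decay_timecourse(2.6, noise_cv=0.2, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert a.loc[a["time_h"] == 0, "abundance"].mean() == pytest.approx(1.0)

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ValueError, match="half_life"):
            gen_decay_timecourse(0.0)


class TestGenQpcr:
    def test_planted_ddct_encoded(self):
        table = gen_qpcr_table({"A": 0.0, "B": -1.0}, seed=0)
        dct = (
            table.assign(d=table["ct_target"] - table["ct_reference"])
            .groupby(["gene", "condition"])["d"]
            .mean()
        )
        assert dct["A", "treated"] - dct["A", "control"] == pytest.approx(0.0)
        assert dct["B", "treated"] - dct["B", "control"] == pytest.approx(-1.0)

    def test_reproducible_under_seed(self):
        a = gen_qpcr_table({"A": 0.5}, noise_sd=0.1, seed=6)
        b = gen_qpcr_table({"A": 0.5}, noise_sd=0.1, seed=6)
        pd.testing.assert_frame_equal(a, b)
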