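"""Generators: templates, traces, sequences, replicate tables, counts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from camseed import synthetic as syn
from camseed import composition as comp
from camseed.protchem import STANDARD_RESIDUES

#: (nominal kDa, condition) pairs the decision scheme tests.
DISCRIMINATING_NOMINALS = [
    (17.0, "reduced"), (14.0, "reduced"), (33.0, "reduced"),
    (12.0, "reduced"), (29.0, "reduced"), (54.0, "nonreduced"),
]


def _has(template, nominal, condition, tol=1.5):
    peaks = (template.peaks_reduced if condition == "reduced"
             else template.peaks_nonreduced)
    return any(abs(k - nominal) <= tol for k, _ in peaks)


class TestSpeciesTemplates:
    def test_unknown_taxon_names_valid_ones(self):
        with pytest.raises(ValueError, match="C. sativa"):
            syn.species_template("C. unknown")

    @pytest.mark.parametrize("taxon", syn.TAXA)
    def test_abundances_normalised(self, taxon):
        t = syn.species_template(taxon)
        assert sum(w for _, w in t.peaks_reduced) == pytest.approx(1.0)
        assert sum(w for _, w in t.peaks_nonreduced) == pytest.approx(1.0)

    def test_sativa_discriminators(self):
        t = syn.species_template("C. sativa")
        assert _has(t, 17, "reduced") and _has(t, 14, "reduced")

    def test_neglecta_discriminators(self):
        t = syn.species_template("C. neglecta")
        assert not _has(t, 17, "reduced")
        assert _has(t, 12, "reduced")

    def test_microcarpa_ploidy_54kda(self):
        assert _has(syn.species_template("C. microcarpa 4X"), 54, "nonreduced")
        assert not _has(syn.species_template("C. microcarpa 6X"), 54, "nonreduced")

    def test_every_pair_differs_on_a_discriminating_peak(self):
        """Templates of distinguishable taxa differ on >=1 scheme peak."""
        group = {"C. rumelica rumelica": "rum", "C. rumelica transcapida": "rum",
                 "C. hispida hispida": "his", "C. hispida grandiflora": "his"}
        for a, b in itertools.combinations(syn.TAXA, 2):
            if group.get(a, a) == group.get(b, b):
                continue
            ta, tb = syn.species_template(a), syn.species_template(b)
            assert any(
                _has(ta, k, c) != _has(tb, k, c)
                for k, c in DISCRIMINATING_NOMINALS
            ), (a, b)


class TestGenTrace:
    def test_noiseless_single_peak_maximum_at_nominal(self):
        template = syn.SpeciesTemplate(
            taxon="C. sativa", peaks_reduced=((30.0, 1.0),),
            peaks_nonreduced=((30.0, 1.0),),
        )
        red, _ = syn.gen_trace(syn.TraceSimSpec(template=template, noise_sd=0.0))
        assert red.grid[np.argmax(red.signal)] == pytest.approx(30.0, abs=0.05)

    def test_same_seed_identical(self):
        spec = syn.TraceSimSpec(
            template=syn.species_template("C. laxa"), seed=11
        )
        r1, n1 = syn.gen_trace(spec)
        r2, n2 = syn.gen_trace(spec)
        np.testing.assert_array_equal(r1.signal, r2.signal)
        np.testing.assert_array_equal(n1.signal, n2.signal)

    def test_different_seeds_differ(self):
        t = syn.species_template("C. laxa")
        r1, _ = syn.gen_trace(syn.TraceSimSpec(template=t, seed=1))
        r2, _ = syn.gen_trace(syn.TraceSimSpec(template=t, seed=2))
        assert not np.array_equal(r1.signal, r2.signal)

    def test_invalid_spec_rejected(self):
        t = syn.species_template("C. laxa")
        with pytest.raises(ValueError):
            syn.TraceSimSpec(template=t, sigma_kda=0.0)
        with pytest.raises(ValueError):
            syn.TraceSimSpec(template=t, noise_sd=-1.0)


class TestGenSequence:
    def test_degenerate_composition(self):
        seq = syn.gen_sequence(5, {"A": 1.0}, seed=0)
        assert seq.residues == "AAAAA"

    def test_uniform_composition_frequencies(self):
        comp_uniform = {aa: 1.0 / 20 for aa in STANDARD_RESIDUES}
        seq = syn.gen_sequence(405, comp_uniform, seed=3)
        for aa in STANDARD_RESIDUES:
            freq = seq.residues.count(aa) / 405
            assert freq == pytest.approx(0.05, abs=0.05)

    def test_deterministic(self):
        comp_uniform = {aa: 1.0 / 20 for aa in STANDARD_RESIDUES}
        assert (syn.gen_sequence(60, comp_uniform, seed=9).residues
                == syn.gen_sequence(60, comp_uniform, seed=9).residues)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError, match="nonstandard"):
            syn.gen_sequence(5, {"X": 1.0}, seed=0)


class TestGenAATable:
    def test_zero_cv_reproduces_means_exactly(self):
        table = syn.gen_aa_table(cv_tech=0.0, seed=0)
        pct = comp.percent_ww(table)
        for group, means in syn.CAMELINA_AA_MEANS.items():
            sub = pct[pct.group == group]
            for analyte, mean in means.items():
                vals = sub[sub.analyte == analyte]["pct_ww"]
                # generating means are %w/w of a near-100 total; renormalise
                total = sum(means.values())
                assert vals.unique() == pytest.approx(100 * mean / total)

    def test_noisy_recovery_within_three_se(self):
        means = {"g1": {"Lysine": 30.0, "Glx": 50.0, "Met": 20.0}}
        table = syn.gen_aa_table(means, cv_tech=5.0, n_bio=3, n_tech=3, seed=4)
        pct = comp.percent_ww(table)
        for analyte, mean in means["g1"].items():
            vals = pct[pct.analyte == analyte]["pct_ww"]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - mean) < 3 * max(se, 1e-9)

    def test_deterministic(self):
        t1 = syn.gen_aa_table(cv_tech=5.0, seed=8)
        t2 = syn.gen_aa_table(cv_tech=5.0, seed=8)
        pd.testing.assert_frame_equal(t1, t2)


class TestCatalog:
    def test_family_counts_match_genome_annotation(self):
        cat = syn.build_catalog()
        fam = cat["family"].value_counts()
        assert fam["cruciferin"] == 12
        assert fam["napin"] == 8
        assert fam["vicilin"] == 8
        assert fam["oleosin"] == 12

    def test_structural_absences(self):
        cat = syn.build_catalog()
        napin_sub = set(cat.loc[cat.family == "napin", "subgenome"])
        assert napin_sub == {"G1", "G3"}
        cru_a = cat[(cat.type == "CruA")]
        assert set(cru_a.subgenome) == {"G1", "G2"}
        assert len(cru_a) == 3


class TestGenCounts:
    def test_invariants_of_spec(self):
        cat = syn.build_catalog()
        with pytest.raises(ValueError):
            syn.CountSimSpec(catalog=cat, type_fractions=(0.5, 0.5, 0.5, -0.5))
        with pytest.raises(ValueError):
            syn.CountSimSpec(catalog=cat, onset_daa=30, offset_daa=20)
        with pytest.raises(ValueError):
            syn.CountSimSpec(catalog=cat, timepoints=(0, 8, 4))

    def test_zero_dispersion_counts_equal_rounded_expectations(self):
        cat = syn.build_catalog(n_other=50)
        spec = syn.CountSimSpec(catalog=cat, dispersion=0.0, seed=1)
        counts, lengths = syn.gen_counts(spec)
        tpm_exp = syn.expected_tpm(spec)
        w = tpm_exp.mul(lengths, axis=0)
        mu = w.div(w.sum(axis=0), axis=1) * spec.libsize
        np.testing.assert_array_equal(
            counts.to_numpy(), np.round(mu.to_numpy()).astype(int)
        )

    def test_deterministic_and_integral(self):
        cat = syn.build_catalog(n_other=50)
        spec = syn.CountSimSpec(catalog=cat, seed=6)
        c1, _ = syn.gen_counts(spec)
        c2, _ = syn.gen_counts(spec)
        pd.testing.assert_frame_equal(c1, c2)
        assert (c1.to_numpy() >= 0).all()
        assert np.issubdtype(c1.to_numpy().dtype, np.integer)

    def test_expected_column_sums_near_libsize_monte_carlo(self):
        """Expected library size (MC mean over 20 seeds) is within 2%."""
        cat = syn.build_catalog(n_other=100)
        sums = []
        for seed in range(20):
            spec = syn.CountSimSpec(
                catalog=cat, libsize=1e6, dispersion=0.1, seed=seed
            )
            counts, _ = syn.gen_counts(spec)
            sums.extend(counts.sum(axis=0).tolist())
        assert abs(np.mean(sums) / 1e6 - 1.0) < 0.02

    def test_pooled_sample_is_single_column(self):
        cat = syn.build_catalog(n_other=20)
        counts, _ = syn.gen_counts(
            syn.CountSimSpec(catalog=cat, dispersion=0.0), pooled=True
        )
        assert list(counts.columns) == ["pooled"]
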