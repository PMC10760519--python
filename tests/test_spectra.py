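"""Spectra, catalog renormalization, exposure refitting, enrichment."""

import numpy as np
import pandas as pd
import pytest

from macdnm.contexts import CHANNELS_96, CONTEXTS_32, CPG_CT_CHANNELS
from macdnm.spectra import (
    build_spectrum,
    context_enrichment_test,
    cpa_covariate_model,
    default_catalog,
    fit_exposures,
    renormalize_catalog,
    spectrum_from_channels,
    substitution_class_totals,
    validate_catalog,
)
from macdnm.synthetic_data import (
    MutationProcessConfig,
    PedigreeConfig,
    make_pedigree,
    simulate_truth_dnms,
)

UNIFORM32 = pd.Series(1 / 32, index=CONTEXTS_32)


class TestBuildSpectrum:
    def test_empty_input_is_zero_spectrum(self):
        dnms = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        spec = build_spectrum(dnms, {"chr1": "ACGT"})
        assert spec.sum() == 0

    def test_single_cpg_mutation(self):
        dnms = pd.DataFrame(
            [{"chrom": "chr1", "pos": 2, "ref": "C", "alt": "T"}]
        )
        spec = build_spectrum(dnms, {"chr1": "ACGT"})
        assert spec.sum() == 1
        assert spec.loc["A[C>T]G"] == 1
        assert spec.loc[CPG_CT_CHANNELS].sum() == 1

    def test_hand_tallied_fixture(self):
        #            123456789
        seq = "TACGATTGCA"
        muts = [
            (3, "C", "T"),  # ACG -> A[C>T]G
            (3, "C", "A"),  # ACG -> A[C>A]G
            (6, "T", "C"),  # TTG? pos6 is T in ATT -> A[T>C]T
            (8, "G", "A"),  # TGC -> revcomp GCA -> G[C>T]A
            (9, "C", "G"),  # GCA -> G[C>G]A
        ]
        dnms = pd.DataFrame(
            [{"chrom": "c", "pos": p, "ref": r, "alt": a} for p, r, a in muts]
        )
        spec = build_spectrum(dnms, {"c": seq})
        assert spec.sum() == 5
        assert spec.loc["A[C>T]G"] == 1
        assert spec.loc["A[C>A]G"] == 1
        assert spec.loc["A[T>C]T"] == 1
        assert spec.loc["G[C>T]A"] == 1
        assert spec.loc["G[C>G]A"] == 1

    def test_reference_mismatch_raises_with_sites(self):
        dnms = pd.DataFrame(
            [{"chrom": "chr1", "pos": 2, "ref": "G", "alt": "T"}]
        )
        with pytest.raises(ValueError, match="chr1:2"):
            build_spectrum(dnms, {"chr1": "ACGT"})

    def test_unknown_channel_label_rejected(self):
        with pytest.raises(ValueError):
            spectrum_from_channels(["A[C>T]G", "bogus"])


class TestRenormalization:
    def test_identity_when_frequencies_match(self):
        cat = default_catalog()
        out = renormalize_catalog(cat, UNIFORM32, UNIFORM32)
        pd.testing.assert_frame_equal(out, cat)

    def test_single_context_signature_is_invariant(self):
        sig = pd.Series(0.0, index=CHANNELS_96)
        sig.loc["A[C>T]G"] = 1.0
        cat = pd.DataFrame({"point": sig})
        target = UNIFORM32.copy()
        target.loc["ACG"] *= 3
        target /= target.sum()
        out = renormalize_catalog(cat, UNIFORM32, target)
        pd.testing.assert_frame_equal(out, cat)

    def test_two_context_toy_renormalization(self):
        sig = pd.Series(0.0, index=CHANNELS_96)
        sig.loc["A[C>T]G"] = 0.5
        sig.loc["T[C>T]A"] = 0.5
        cat = pd.DataFrame({"toy": sig})
        target = UNIFORM32.copy()
        target.loc["ACG"] *= 2  # double one context's frequency
        out = renormalize_catalog(cat, UNIFORM32, target)
        # weights 0.5*2 : 0.5 -> renormalized 2/3 : 1/3
        assert out.loc["A[C>T]G", "toy"] == pytest.approx(2 / 3)
        assert out.loc["T[C>T]A", "toy"] == pytest.approx(1 / 3)

    def test_round_trip_inverts_to_1e9(self, small_ref):
        cat = default_catalog()
        f_ref = small_ref.context_frequencies
        there = renormalize_catalog(cat, UNIFORM32, f_ref)
        back = renormalize_catalog(there, f_ref, UNIFORM32)
        assert np.abs(back.values - cat.values).max() < 1e-9

    def test_zero_source_frequency_with_weight_raises(self):
        zeroed = UNIFORM32.copy()
        zeroed.loc["ACG"] = 0.0
        zeroed /= zeroed.sum()
        with pytest.raises(ValueError, match="ACG"):
            renormalize_catalog(default_catalog(), zeroed, UNIFORM32)

    def test_catalog_validation(self):
        bad = default_catalog() * 2
        with pytest.raises(ValueError):
            validate_catalog(bad)


class TestExposures:
    def test_pure_signature_recovered_exactly(self):
        cat = default_catalog()
        spectrum = cat["SBS1-like"] * 500
        est = fit_exposures(spectrum, cat)
        assert est.fractions["SBS1-like"] == pytest.approx(1.0, abs=1e-9)
        assert est.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_mixture_recovered_from_multinomial_draws(self):
        rng = np.random.default_rng(5)
        cat = default_catalog()
        mix = 0.2 * cat["SBS1-like"] + 0.8 * cat["SBS5-like"]
        counts = rng.multinomial(10_000, mix.to_numpy())
        est = fit_exposures(pd.Series(counts, index=CHANNELS_96), cat)
        assert est.fractions["SBS1-like"] == pytest.approx(0.2, abs=0.03)
        assert est.fractions["SBS5-like"] == pytest.approx(0.8, abs=0.03)

    def test_recovery_within_5pp_averaged_over_seeds(self, small_ref):
        """Construct-then-recover: spectra drawn from a known exposure
        mixture (>=2000 mutations) refit to within 0.05 on average."""
        cat = renormalize_catalog(
            default_catalog(), UNIFORM32, small_ref.context_frequencies
        )
        mix = (0.2 * cat["SBS1-like"] + 0.8 * cat["SBS5-like"]).to_numpy()
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            counts = rng.multinomial(2500, mix)
            est = fit_exposures(pd.Series(counts, index=CHANNELS_96), cat)
            errs.append(abs(est.fractions["SBS1-like"] - 0.2))
        assert np.mean(errs) < 0.05

    def test_exposures_are_nonnegative(self):
        rng = np.random.default_rng(3)
        spectrum = pd.Series(rng.integers(0, 20, 96), index=CHANNELS_96)
        est = fit_exposures(spectrum, default_catalog())
        assert (est.exposures >= -1e-12).all()

    def test_zero_spectrum_raises(self):
        with pytest.raises(ValueError):
            fit_exposures(pd.Series(0, index=CHANNELS_96), default_catalog())

    def test_empty_subset_raises(self):
        spectrum = pd.Series(1, index=CHANNELS_96)
        with pytest.raises(ValueError):
            fit_exposures(spectrum, default_catalog(), signature_subset=[])


class TestEnrichment:
    def test_identical_groups_have_unit_rate_ratio(self):
        counts = pd.DataFrame({"ACA": [3, 4, 5, 4], "TCG": [1, 2, 1, 2]})
        out = context_enrichment_test(counts, counts.copy())
        aca = out[out["context"] == "ACA"].iloc[0]
        assert aca["rate_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert aca["p_value"] > 0.9

    def test_fivefold_enrichment_recovered(self):
        rng = np.random.default_rng(17)
        hyper = pd.DataFrame({"ACA": rng.poisson(10.0, 50)})
        control = pd.DataFrame({"ACA": rng.poisson(2.0, 50)})
        out = context_enrichment_test(hyper, control)
        row = out.iloc[0]
        assert 4.0 <= row["rate_ratio"] <= 6.0
        assert row["p_value"] < 1e-6

    def test_zero_counts_flagged(self):
        hyper = pd.DataFrame({"ACA": [3, 5], "GCC": [0, 0]})
        control = pd.DataFrame({"ACA": [0, 0], "GCC": [0, 0]})
        out = context_enrichment_test(hyper, control).set_index("context")
        assert out.loc["GCC", "flag"] == "no_counts"
        assert out.loc["ACA", "flag"] == "zero_in_one_group"

    def test_bonferroni_adjustment_bounded(self):
        counts = pd.DataFrame({c: [1, 2] for c in ["ACA", "CCA", "GCA", "TCA"]})
        out = context_enrichment_test(counts, counts.copy())
        assert (out["p_adjusted"] <= 1.0).all()
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()


@pytest.fixture(scope="module")
def truth_tables(medium_ref):
    proc = MutationProcessConfig()
    hyper_ped = make_pedigree(
        PedigreeConfig(n_control_trios=0, n_hyper_trios=40), seed=31
    )
    ctrl_ped = make_pedigree(PedigreeConfig(n_control_trios=40), seed=32)
    hyper = simulate_truth_dnms(hyper_ped, proc, medium_ref, seed=33)
    ctrl = simulate_truth_dnms(ctrl_ped, proc, medium_ref, seed=34)
    return hyper_ped, ctrl_ped, hyper, ctrl


class TestHypermutatorSpectrum:

    def test_ct_is_the_only_class_in_excess(self, truth_tables):
        """Per-offspring substitution-class totals: C>T is the single
        class with a significant hypermutator excess."""
        hyper_ped, ctrl_ped, hyper, ctrl = truth_tables

        def class_table(truth, ped):
            rows = []
            for child, grp in truth.table.groupby("child_id"):
                totals = substitution_class_totals(
                    spectrum_from_channels(grp["channel"])
                )
                rows.append(totals.rename(child))
            return (
                pd.DataFrame(rows)
                .reindex(ped["child_id"])
                .fillna(0.0)
            )

        ht = class_table(hyper, hyper_ped)
        ct = class_table(ctrl, ctrl_ped)
        out = context_enrichment_test(ht, ct).set_index("context")
        assert out.loc["C>T", "rate_ratio"] > 3
        assert out.loc["C>T", "p_adjusted"] < 1e-6
        for cls in ["C>A", "C>G", "T>A", "T>C", "T>G"]:
            # the non-C>T classes share the control process: their small
            # per-offspring counts fluctuate near ratio 1 and never
            # approach the C>T excess
            assert out.loc[cls, "rate_ratio"] < 2.0
            assert out.loc[cls, "p_adjusted"] > 1e-3

    def test_cpa_model_attributes_excess_to_mbd4_null(self, truth_tables):
        hyper_ped, ctrl_ped, hyper, ctrl = truth_tables
        rows = []
        for ped, truth in ((hyper_ped, hyper), (ctrl_ped, ctrl)):
            counts = (
                truth.table[
                    truth.table["channel"].str.contains(r"\[C>T\]A")
                ]
                .groupby("child_id").size()
            )
            for t in ped.itertuples(index=False):
                rows.append(
                    {
                        "cpa_ct_count": int(counts.get(t.child_id, 0)),
                        "mbd4_hom": int(t.hypermutator),
                        "mbd4_het": 0,
                        "paternal_age": t.paternal_age,
                        "maternal_age": t.maternal_age,
                    }
                )
        fit = cpa_covariate_model(pd.DataFrame(rows))
        assert fit.params["mbd4_hom"] > 1.0  # >e-fold CpA C>T increase
        assert fit.pvalues["mbd4_hom"] < 1e-6
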