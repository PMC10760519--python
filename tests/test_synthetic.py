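"""The cohort generator: truth statistics, evidence, determinism."""

import numpy as np
import pandas as pd
import pytest

from macdnm.contexts import collapse_context
from macdnm.synthetic_data import (
    ARTIFACT_CLASSES,
    EvidenceConfig,
    MutationProcessConfig,
    PedigreeConfig,
    ReferenceIndex,
    make_pedigree,
    make_reference,
    simulate_cohort,
    simulate_site_evidence,
    simulate_truth_dnms,
)


class TestConfigs:
    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            PedigreeConfig(n_control_trios=-1)
        with pytest.raises(ValueError):
            PedigreeConfig(paternal_age_years=0.0)
        with pytest.raises(ValueError):
            MutationProcessConfig(control_burden_mean=-1)
        with pytest.raises(ValueError):
            MutationProcessConfig(control_signature_mix={"SBS1-like": 0.7})
        with pytest.raises(ValueError):
            EvidenceConfig(reference_length=10_000)
        with pytest.raises(ValueError):
            EvidenceConfig(mean_depth=3.0)
        with pytest.raises(ValueError):
            EvidenceConfig(fragment_length=0)
        with pytest.raises(ValueError):
            EvidenceConfig(artifact_rates={"nonsense_class": 1.0})

    def test_hypermutators_are_exactly_the_null_dams(self):
        ped = make_pedigree(
            PedigreeConfig(n_control_trios=5, n_hyper_trios=3), seed=1
        )
        assert ((ped["mother_mbd4"] == "-/-") == ped["hypermutator"]).all()
        assert ped["hypermutator"].sum() == 3


class TestTruthSimulation:
    def test_burden_mean_matches_configuration(self, medium_ref):
        """Poisson sampling oracle: the cohort mean burden stays within
        3 standard errors of the configured mean (age terms centered)."""
        ped = make_pedigree(PedigreeConfig(n_control_trios=1000), seed=5)
        truth = simulate_truth_dnms(
            ped, MutationProcessConfig(), medium_ref, seed=6
        )
        counts = truth.counts_per_offspring().reindex(ped["child_id"], fill_value=0)
        # count variance = E[lambda] + Var(lambda) from the age spread
        var = 10.5 + 1.5**2 * 36 / 12 + 0.4**2 * 36 / 12
        se = np.sqrt(var / 1000)
        assert abs(counts.mean() - 10.5) < 3 * se

    def test_zero_means_give_empty_truth(self, small_ref):
        proc = MutationProcessConfig(
            control_burden_mean=0.0,
            maternal_cpg_excess_mean=0.0,
            maternal_cpa_excess_mean=0.0,
            paternal_age_slope=0.0,
            maternal_age_slope=0.0,
        )
        ped = make_pedigree(PedigreeConfig(n_control_trios=4, n_hyper_trios=2), seed=2)
        truth = simulate_truth_dnms(ped, proc, small_ref, seed=3)
        assert len(truth.table) == 0

    def test_hypermutator_cpg_counts_in_reported_band(self, medium_ref):
        """CpG C>T excess per hypermutator offspring concentrates in the
        25-39 band around its mean of 30."""
        ped = make_pedigree(
            PedigreeConfig(n_control_trios=0, n_hyper_trios=100), seed=7
        )
        truth = simulate_truth_dnms(ped, MutationProcessConfig(), medium_ref, seed=8)
        cpg = (
            truth.table[truth.table["process"] == "cpg_excess"]
            .groupby("child_id").size()
            .reindex(ped["child_id"], fill_value=0)
        )
        assert abs(cpg.mean() - 30) < 3 * np.sqrt(30 / 100)
        assert ((cpg >= 25) & (cpg <= 39)).mean() > 0.6
        # the excess is always maternal
        excess = truth.table[truth.table["process"] != "baseline"]
        assert (excess["parent_of_origin"] == "maternal").all()

    def test_contexts_agree_with_reference(self, small_ref):
        ped = make_pedigree(PedigreeConfig(n_control_trios=10), seed=9)
        truth = simulate_truth_dnms(ped, MutationProcessConfig(), small_ref, seed=10)
        for row in truth.table.itertuples(index=False):
            assert small_ref.base_at(row.pos - 1) == row.ref
            assert collapse_context(small_ref.context_at(row.pos - 1)) == row.context

    def test_absent_context_raises_with_context_name(self):
        ref = ReferenceIndex("AT" * 75_000)  # no cytosines at all
        ped = make_pedigree(PedigreeConfig(n_control_trios=0, n_hyper_trios=1), seed=1)
        with pytest.raises(ValueError, match="CpG"):
            simulate_truth_dnms(ped, MutationProcessConfig(), ref, seed=2)


class TestEvidenceSimulation:
    def test_clean_sites_have_silent_parents_and_balanced_vaf(self, medium_ref):
        sim = simulate_cohort(
            PedigreeConfig(n_control_trios=40),
            evidence_config=EvidenceConfig(
                reference_length=len(medium_ref), base_error_rate=0.0
            ),
            seed=21,
            reference=medium_ref,
        )
        ev = sim.evidence
        assert (ev["mother_alt_ad"] == 0).all()
        assert (ev["father_alt_ad"] == 0).all()
        # binomial oracle: pooled alt fraction within 3 SE of 1/2
        n = ev["child_dp"].sum()
        assert abs(ev["child_alt_ad"].sum() / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_truth_manifest_counts_match_evidence(self, control_cohort):
        sim = control_cohort
        true_rows = sim.evidence[~sim.evidence["truth_process"].str.startswith("artifact")]
        manifest = sim.truth.counts_per_offspring()
        observed = true_rows.groupby("child_id").size()
        pd.testing.assert_series_equal(
            manifest.sort_index(), observed.sort_index(), check_names=False
        )

    def test_undercalled_parent_artifacts_carry_alt_reads(self, medium_ref):
        sim = simulate_cohort(
            PedigreeConfig(n_control_trios=10),
            evidence_config=EvidenceConfig(
                reference_length=len(medium_ref),
                artifact_rates={"inherited_undercalled_in_parent": 3.0},
            ),
            seed=23,
            reference=medium_ref,
        )
        art = sim.evidence[
            sim.evidence["truth_process"] == "artifact:inherited_undercalled_in_parent"
        ]
        assert len(art) > 0
        assert (art[["mother_alt_ad", "father_alt_ad"]].max(axis=1) >= 2).all()

    def test_male_x_sites_are_hemizygous(self, small_ref):
        ped = make_pedigree(
            PedigreeConfig(n_control_trios=1, offspring_sex="M"), seed=3
        )
        truth = simulate_truth_dnms(ped, MutationProcessConfig(), small_ref, seed=4)
        table = truth.table.assign(chrom="chrX")
        truth.table = table
        ev, *_ = simulate_site_evidence(
            truth, ped, EvidenceConfig(reference_length=len(small_ref)),
            small_ref, seed=5,
        )
        assert (ev["child_alt_ad"] / ev["child_dp"] > 0.9).all()

    def test_depth_tracks_cover_all_samples(self, control_cohort):
        sim = control_cohort
        samples = set(sim.depth_tracks["sample"])
        ped = sim.pedigree
        expected = set(ped["child_id"]) | set(ped["mother_id"]) | set(ped["father_id"])
        assert samples == expected
        one = sim.depth_tracks[sim.depth_tracks["sample"] == ped["child_id"].iloc[0]]
        assert one["end"].max() == len(sim.reference)
        assert ((one["end"] - one["start"]) > 0).all()

    def test_phaseable_fraction_in_calibrated_band(self, control_cohort):
        """Default linkage density yields a phaseable fraction in the
        0.45-0.60 band (calibrated near 0.53)."""
        from macdnm.pipeline import phase_survivors

        _, summary = phase_survivors(control_cohort.truth.table, control_cohort)
        assert 0.45 <= summary.phaseable_fraction <= 0.60


class TestDeterminism:
    def test_identical_seeds_reproduce_the_cohort(self, small_ref):
        kwargs = dict(
            pedigree_config=PedigreeConfig(n_control_trios=6, n_hyper_trios=2),
            evidence_config=EvidenceConfig(
                reference_length=len(small_ref),
                artifact_rates={cls: 1.0 for cls in ARTIFACT_CLASSES},
            ),
            seed=99,
            reference=small_ref,
        )
        a = simulate_cohort(**kwargs)
        b = simulate_cohort(**kwargs)
        for attr in ("pedigree", "evidence", "read_obs", "info_sites",
                     "repeat_bed", "segdup_bed", "af_table", "depth_tracks"):
            pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))
        pd.testing.assert_frame_equal(a.truth.table, b.truth.table)
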