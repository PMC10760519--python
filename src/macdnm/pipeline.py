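"""End-to-end driver: simulate -> call -> phase -> spectra -> burden.

The pipeline mirrors a trio WGS study's analysis order: candidate DNMs
are gated and hard-filtered per cohort (with FDR correction grouped per
offspring), survivors are phased to a parental haplotype via read-backed
informative sites, pooled into 96-channel spectra with signature
exposures refit against a genome-renormalized catalog, and modelled as
Poisson counts with age / genotype / coverage covariates.  A single
seed makes the whole run reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden as _burden
from . import calling as _calling
from . import phasing as _phasing
from . import spectra as _spectra
from .contexts import CPA_CT_CHANNELS, CPG_CT_CHANNELS
from .synthetic_data import (
    CohortSimulation,
    EvidenceConfig,
    MutationProcessConfig,
    PedigreeConfig,
    simulate_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "call_cohort", "phase_survivors"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    pedigree: PedigreeConfig = field(default_factory=PedigreeConfig)
    process: MutationProcessConfig = field(default_factory=MutationProcessConfig)
    evidence: EvidenceConfig = field(default_factory=EvidenceConfig)
    out_dir: str | None = None
    run_phasing: bool = True
    run_spectra: bool = True
    run_burden: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "pedigree" in kwargs:
            kwargs["pedigree"] = PedigreeConfig(**kwargs["pedigree"])
        if "process" in kwargs:
            kwargs["process"] = MutationProcessConfig(**kwargs["process"])
        if "evidence" in kwargs:
            ev = dict(kwargs["evidence"])
            kwargs["evidence"] = EvidenceConfig(**ev)
        return cls(**kwargs)


def call_cohort(
    sim: CohortSimulation,
    thresholds: _calling.FilterThresholds = _calling.FilterThresholds(),
) -> tuple[pd.DataFrame, _calling.FilterTrace]:
    """Run the filter cascade over a simulated cohort's candidates.

    Returns the surviving-call table (evidence columns plus cascade
    annotations) and the aggregate filter trace.
    """
    candidates = _calling.candidates_from_frame(sim.evidence)
    survivors, trace = _calling.run_cascade(
        candidates,
        thresholds=thresholds,
        repeat_bed=sim.repeat_bed,
        segdup_bed=sim.segdup_bed,
        af_table=None,  # per-row population_af already attached
    )
    rows = []
    for cand in survivors:
        ev = cand.evidence
        rows.append(
            {
                "dnm_id": cand.id, "child_id": cand.child_id,
                "chrom": ev.chrom, "pos": ev.pos, "ref": ev.ref, "alt": ev.alt,
                "vaf": cand.vaf, "p_dn": cand.p_dn,
                "binomial_p": cand.binomial_p,
                "fdr_adjusted_p": cand.fdr_adjusted_p,
            }
        )
    calls = pd.DataFrame(
        rows,
        columns=["dnm_id", "child_id", "chrom", "pos", "ref", "alt", "vaf",
                 "p_dn", "binomial_p", "fdr_adjusted_p"],
    )
    return calls, trace


def phase_survivors(
    calls: pd.DataFrame, sim: CohortSimulation
) -> tuple[pd.DataFrame, _phasing.PhasingSummary]:
    """Phase surviving calls against the cohort's read observations."""
    table, phased = _phasing.phase_cohort(
        list(zip(calls["dnm_id"], calls["child_id"])),
        sim.read_obs,
        sim.info_sites,
    )
    summary = _phasing.summarize_phasing(list(phased.values()))
    return table, summary


def _phasing_dict(summary: _phasing.PhasingSummary) -> dict:
    return {
        "n_phased_maternal": summary.n_phased_maternal,
        "n_phased_paternal": summary.n_phased_paternal,
        "n_unphased": summary.n_unphased,
        "phaseable_fraction": summary.phaseable_fraction,
        "alpha": summary.alpha,
    }


def _child_callable(sim: CohortSimulation) -> pd.Series:
    """Genome-scale callable bases per offspring from the depth tracks."""
    out = {}
    nominal = sim.evidence_config.nominal_callable_bases
    for trio in sim.pedigree.itertuples(index=False):
        track = sim.depth_tracks[sim.depth_tracks["sample"] == trio.child_id]
        summary = _burden.quantize_track(track, nominal_scaling=nominal)
        out[trio.child_id] = summary.genome_callable
    return pd.Series(out, name="callable_bases")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return a JSON-serializable summary."""
    stage = "simulate"
    try:
        sim = simulate_cohort(
            config.pedigree, config.process, config.evidence, seed=config.seed
        )
        stage = "call"
        calls, trace = call_cohort(sim)
        counts = (
            calls.groupby("child_id").size()
            .reindex(sim.pedigree["child_id"], fill_value=0)
        )
        summary: dict = {
            "seed": config.seed,
            "n_trios": int(len(sim.pedigree)),
            "per_offspring_dnm_counts": {k: int(v) for k, v in counts.items()},
            "filter_trace": {
                "input": trace.input_count,
                "removed": dict(trace.removed),
                "surviving": trace.surviving_count,
            },
        }

        hyper_children = set(
            sim.pedigree.loc[sim.pedigree["hypermutator"], "child_id"]
        )
        is_hyper = calls["child_id"].isin(hyper_children)

        if config.run_phasing and len(calls):
            stage = "phase"
            control_calls = calls[~is_hyper]
            phase_block = {}
            if len(control_calls):
                _, psum = phase_survivors(control_calls, sim)
                phase_block["control"] = _phasing_dict(psum)
            if is_hyper.any():
                _, psum = phase_survivors(calls[is_hyper], sim)
                phase_block["hypermutator"] = _phasing_dict(psum)
            summary["phasing"] = phase_block

        if config.run_spectra and len(calls):
            stage = "spectra"
            reference = {sim.reference.name: sim.reference.sequence}
            catalog = _spectra.renormalize_catalog(
                _spectra.default_catalog(),
                pd.Series(1 / 32, index=_spectra.CONTEXTS_32),
                sim.reference.context_frequencies,
            )
            spec_block = {}
            for label, subset in (
                ("control", calls[~is_hyper]),
                ("hypermutator", calls[is_hyper]),
            ):
                if len(subset) == 0:
                    continue
                spectrum = _spectra.build_spectrum(subset, reference)
                est = _spectra.fit_exposures(spectrum, catalog)
                spec_block[label] = {
                    "n_mutations": int(spectrum.sum()),
                    "exposure_fractions": {
                        k: float(v) for k, v in est.fractions.items()
                    },
                    "cpg_ct_fraction": float(
                        spectrum.loc[CPG_CT_CHANNELS].sum() / spectrum.sum()
                    ),
                    "cpa_ct_fraction": float(
                        spectrum.loc[CPA_CT_CHANNELS].sum() / spectrum.sum()
                    ),
                }
            summary["spectra"] = spec_block

        if config.run_burden and len(calls):
            stage = "burden"
            callable_bases = _child_callable(sim)
            control_children = sim.pedigree.loc[
                ~sim.pedigree["hypermutator"], "child_id"
            ]
            control_counts = counts.loc[control_children]
            rate = _burden.estimate_rate(
                control_counts, callable_bases.loc[control_children]
            )
            cov = sim.pedigree.set_index("child_id").loc[
                counts.index, ["paternal_age", "maternal_age", "mother_mbd4",
                               "hypermutator"]
            ]
            cov["mbd4_het"] = (cov["mother_mbd4"] == "+/-").astype(int)
            cov["mbd4_hom"] = (cov["mother_mbd4"] == "-/-").astype(int)
            cov["callable_bases"] = callable_bases.loc[counts.index]
            terms = [
                t
                for t in ["paternal_age", "maternal_age", "mbd4_het",
                          "mbd4_hom", "callable_bases"]
                if cov[t].nunique() > 1
            ]
            fit = _burden.fit_burden_model(
                counts.to_numpy(), cov, model_label="total", terms=terms
            )
            summary["burden"] = {
                "rate_per_bp_per_generation": rate.rate,
                "pooled_rate": rate.pooled_rate,
                "coefficients": {k: float(v) for k, v in fit.coefficients.items()},
                "p_values": {k: float(v) for k, v in fit.p_values.items()},
            }
            if cov["hypermutator"].astype(int).nunique() > 1:
                ifit = _burden.fit_interaction_model(counts.to_numpy(), cov)
                summary["burden"]["interaction"] = {
                    "coefficient": float(ifit.coefficients[ifit.interaction_term]),
                    "p_value": float(ifit.p_values[ifit.interaction_term]),
                }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        trace.to_frame().to_csv(out / "filter_trace.tsv", sep="\t", index=False)
        calls.to_csv(out / "filtered_dnms.tsv", sep="\t", index=False)
    return summary
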