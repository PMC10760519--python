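"""Mutation spectra, signature catalogs, exposure refitting, enrichment.

A 96-channel spectrum counts single-base substitutions in their
pyrimidine-centered trinucleotide contexts.  Signature catalogs (one
probability column per signature) defined on one genome's trinucleotide
composition can be renormalized onto another genome's composition:
each channel weight is rescaled by the ratio of target to source context
frequency, and columns are renormalized to sum to one.  Exposures are
estimated by nonnegative least squares against a (renormalized) catalog
— a constrained refit against known signatures rather than de novo
factorization, which is not identifiable with a handful of genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import nnls

from .contexts import (
    CHANNEL_CONTEXTS,
    CHANNELS_96,
    CONTEXTS_32,
    CPA_CT_CHANNELS,
    CPG_CT_CHANNELS,
    channel_of,
    collapse_context,
)

__all__ = [
    "Spectrum96",
    "ExposureEstimate",
    "default_catalog",
    "validate_catalog",
    "build_spectrum",
    "spectrum_from_channels",
    "renormalize_catalog",
    "fit_exposures",
    "context_enrichment_test",
    "cpa_covariate_model",
    "substitution_class_totals",
]

#: a 96-channel spectrum is a pandas Series indexed by CHANNELS_96
Spectrum96 = pd.Series


@dataclass
class ExposureEstimate:
    """Nonnegative signature exposures fitted to a spectrum."""

    exposures: pd.Series  # mutation counts attributed per signature
    residual_norm: float

    @property
    def fractions(self) -> pd.Series:
        total = self.exposures.sum()
        if total <= 0:
            return self.exposures * 0.0
        return self.exposures / total


def validate_catalog(catalog: pd.DataFrame, atol: float = 1e-9) -> None:
    """Check catalog shape, nonnegativity, and unit column sums."""
    if list(catalog.index) != CHANNELS_96:
        raise ValueError("catalog must be indexed by the 96 standard channels")
    if (catalog.values < 0).any():
        raise ValueError("catalog entries must be nonnegative")
    sums = catalog.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=atol):
        raise ValueError(f"catalog columns must sum to 1 (got {sums.to_dict()})")


def default_catalog() -> pd.DataFrame:
    """Built-in two-signature catalog (synthetic stand-in).

    ``SBS1-like`` concentrates 92% of its mass on the four N[C>T]G
    channels (spontaneous deamination of methylated CpG cytosines);
    ``SBS5-like`` is a flat, clock-like background with a mild C>T tilt.
    Both columns are expressed relative to uniform trinucleotide
    frequencies; renormalize to a genome before sampling or fitting.
    A real catalog (e.g. a 96-row TSV) may be supplied instead wherever a
    catalog argument is accepted.
    """
    sbs1 = pd.Series(0.08 / 92, index=CHANNELS_96)
    sbs1.loc[CPG_CT_CHANNELS] = 0.92 / 4
    sbs5 = pd.Series(1.0, index=CHANNELS_96)
    ct = [c for c in CHANNELS_96 if c[2:5] == "C>T"]
    sbs5.loc[ct] = 1.4
    sbs5 /= sbs5.sum()
    catalog = pd.DataFrame({"SBS1-like": sbs1, "SBS5-like": sbs5})
    validate_catalog(catalog)
    return catalog


def spectrum_from_channels(channels: Sequence[str]) -> Spectrum96:
    """Tally a list of channel labels into a 96-channel spectrum."""
    counts = pd.Series(0, index=CHANNELS_96, dtype=int)
    tally = pd.Series(channels).value_counts()
    unknown = set(tally.index) - set(CHANNELS_96)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    counts.loc[tally.index] = tally.astype(int)
    return counts


def build_spectrum(
    dnms: pd.DataFrame, reference: Mapping[str, str]
) -> Spectrum96:
    """96-channel spectrum of a DNM table against a reference.

    ``dnms`` needs columns chrom, pos (1-based), ref, alt.  The reference
    base at each site must match the table's ref column; mismatches are
    collected and reported in one error.
    """
    channels = []
    mismatches = []
    for row in dnms.itertuples(index=False):
        seq = reference[str(row.chrom)]
        pos0 = int(row.pos) - 1
        if not (1 <= pos0 <= len(seq) - 2):
            mismatches.append(f"{row.chrom}:{row.pos} (no flanking context)")
            continue
        tri = seq[pos0 - 1 : pos0 + 2].upper()
        if tri[1] != str(row.ref).upper():
            mismatches.append(
                f"{row.chrom}:{row.pos} (reference {tri[1]} != ref {row.ref})"
            )
            continue
        channels.append(channel_of(tri, str(row.ref), str(row.alt)))
    if mismatches:
        raise ValueError(
            "DNMs disagree with the reference at: " + "; ".join(mismatches)
        )
    return spectrum_from_channels(channels)


def renormalize_catalog(
    catalog: pd.DataFrame,
    f_source: pd.Series,
    f_target: pd.Series,
) -> pd.DataFrame:
    """Renormalize a catalog between genomes of different composition.

    Each channel weight is multiplied by ``f_target(ctx) / f_source(ctx)``
    for the channel's trinucleotide context, then each signature column is
    rescaled to sum to one.  A zero source frequency under a channel with
    nonzero weight is an error (the weight cannot be reinterpreted).
    """
    validate_catalog(catalog)
    f_source = f_source.reindex(CONTEXTS_32)
    f_target = f_target.reindex(CONTEXTS_32)
    if f_source.isna().any() or f_target.isna().any():
        raise ValueError("frequency tables must cover all 32 contexts")
    ratios = np.empty(96)
    for i, ctx in enumerate(CHANNEL_CONTEXTS):
        fs = f_source.loc[ctx]
        ft = f_target.loc[ctx]
        if fs <= 0:
            if (catalog.iloc[i] > 0).any():
                raise ValueError(
                    f"source frequency is zero for context {ctx} with nonzero "
                    "catalog weight"
                )
            ratios[i] = 0.0
        else:
            ratios[i] = ft / fs
    out = catalog.mul(ratios, axis=0)
    colsums = out.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError("renormalization annihilated a signature column")
    return out / colsums


def fit_exposures(
    spectrum: Spectrum96,
    catalog: pd.DataFrame,
    signature_subset: Sequence[str] | None = None,
) -> ExposureEstimate:
    """Nonnegative least-squares refit of a spectrum against catalog columns.

    Returns the per-signature exposures (attributed mutation counts), the
    residual norm, and exposure fractions.
    """
    validate_catalog(catalog)
    if signature_subset is not None:
        if len(signature_subset) == 0:
            raise ValueError("signature subset must be nonempty")
        catalog = catalog[list(signature_subset)]
    y = spectrum.reindex(CHANNELS_96).fillna(0.0).to_numpy(dtype=float)
    if y.sum() <= 0:
        raise ValueError("spectrum is all zero; nothing to attribute")
    coef, resid = nnls(catalog.to_numpy(dtype=float), y)
    return ExposureEstimate(
        exposures=pd.Series(coef, index=catalog.columns, name="exposure"),
        residual_norm=float(resid),
    )


# ---------------------------------------------------------------------------
# enrichment testing
# ---------------------------------------------------------------------------


def _poisson_group_fit(counts: np.ndarray, group: np.ndarray):
    X = sm.add_constant(group.astype(float))
    model = sm.GLM(counts, X, family=sm.families.Poisson())
    return model.fit()


def context_enrichment_test(
    hyper_counts_by_context: pd.DataFrame,
    control_counts_by_context: pd.DataFrame,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Per-context Poisson test of hypermutator vs control C>T counts.

    Inputs are per-offspring count tables (rows = offspring, columns =
    the 16 C>T trinucleotide contexts, or any shared context set).  For
    each context a log-linear Poisson model of count on a group indicator
    is fitted; the group coefficient's exponential is the rate ratio,
    with a Wald p-value.  Contexts with zero counts in both groups are
    flagged as undefined; contexts with zero counts in exactly one group
    get a finite-sample flag (the MLE rate ratio is degenerate).
    Multiple-testing adjustment across contexts defaults to Bonferroni.
    """
    contexts = [c for c in hyper_counts_by_context.columns]
    if list(control_counts_by_context.columns) != contexts:
        raise ValueError("count tables must share the same context columns")
    rows = []
    m = len(contexts)
    for ctx in contexts:
        h = hyper_counts_by_context[ctx].to_numpy(dtype=float)
        c = control_counts_by_context[ctx].to_numpy(dtype=float)
        counts = np.concatenate([h, c])
        group = np.concatenate([np.ones_like(h), np.zeros_like(c)])
        if counts.sum() == 0:
            rows.append(
                {"context": ctx, "rate_ratio": np.nan, "coef": np.nan,
                 "p_value": np.nan, "flag": "no_counts"}
            )
            continue
        flag = ""
        if h.sum() == 0 or c.sum() == 0:
            flag = "zero_in_one_group"
        fit = _poisson_group_fit(counts, group)
        coef = float(fit.params[1])
        rows.append(
            {"context": ctx, "rate_ratio": float(np.exp(coef)), "coef": coef,
             "p_value": float(fit.pvalues[1]), "flag": flag}
        )
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["p_adjusted"] = np.minimum(out["p_value"] * m, 1.0)
    elif adjust == "none":
        out["p_adjusted"] = out["p_value"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def cpa_covariate_model(per_offspring: pd.DataFrame):
    """Poisson model of CpA C>T counts with genotype and age covariates.

    ``per_offspring`` needs columns: cpa_ct_count, mbd4_hom (0/1),
    mbd4_het (0/1), paternal_age, maternal_age.  Returns the fitted
    statsmodels GLM results (coefficients for the dam's MBD4 genotype
    terms and the parental ages).
    """
    required = ["cpa_ct_count", "mbd4_hom", "mbd4_het", "paternal_age", "maternal_age"]
    missing = [c for c in required if c not in per_offspring.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    terms = ["mbd4_hom", "mbd4_het", "paternal_age", "maternal_age"]
    usable = [t for t in terms if per_offspring[t].nunique() > 1]
    X = sm.add_constant(per_offspring[usable].astype(float))
    model = sm.GLM(
        per_offspring["cpa_ct_count"].to_numpy(dtype=float),
        X,
        family=sm.families.Poisson(),
    )
    return model.fit()


def substitution_class_totals(spectrum: Spectrum96) -> pd.Series:
    """Collapse a 96-channel spectrum onto the six substitution classes."""
    labels = [c[2:5] for c in CHANNELS_96]
    return spectrum.groupby(labels).sum()
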