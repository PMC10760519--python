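"""Callable-genome summaries, mutation-rate estimation, burden models.

Sequencing depth per position is quantized into NO_COVERAGE [0,1),
LOW_COVERAGE [1,4), CALLABLE [4,80) and HIGH_COVERAGE [80, inf) — the
interval where trio variant calls are trusted is [4, 80).  The
per-generation mutation rate divides each trio's filtered DNM count by
its callable base count (haploid denominator: with a typical ~10.5 DNMs
against ~1.32 Gb callable this yields ~0.8e-8 per bp per generation).
Burden is modelled by Poisson regression (log link, IRLS) with parental
ages, the dam's MBD4 genotype and callable bases as covariates, plus an
optional hypermutator-by-age interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CATEGORY_BOUNDS",
    "CallableSummary",
    "RateEstimate",
    "BurdenFit",
    "quantize_callable",
    "quantize_track",
    "estimate_rate",
    "fit_burden_model",
    "fit_interaction_model",
]

#: half-open depth bins, mirroring a depth-quantize string "0:1:4:80:"
CATEGORY_BOUNDS = {
    "NO_COVERAGE": (0, 1),
    "LOW_COVERAGE": (1, 4),
    "CALLABLE": (4, 80),
    "HIGH_COVERAGE": (80, np.inf),
}


@dataclass
class CallableSummary:
    """Base counts per depth category for one sample."""

    counts: dict[str, int]
    nominal_scaling: float = 1.0  # multiply callable_fraction by this to
    # project the track onto a genome-scale callable size

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def callable_bases(self) -> int:
        return self.counts["CALLABLE"]

    @property
    def callable_fraction(self) -> float:
        if self.total == 0:
            return float("nan")
        return self.callable_bases / self.total

    @property
    def genome_callable(self) -> float:
        return self.callable_fraction * self.nominal_scaling


@dataclass
class RateEstimate:
    """Callable-adjusted per-generation mutation rate."""

    per_trio: pd.Series  # rate per trio (count / callable)
    rate: float  # cohort rate: mean of per-trio rates
    pooled_rate: float  # alternative: pooled counts / pooled callable
    denominator: str = "haploid_callable"


@dataclass
class BurdenFit:
    """Poisson GLM coefficients for a mutation-burden model."""

    model_label: str
    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    deviance: float
    n_obs: int
    interaction_term: str | None = None


def quantize_callable(depth_track, nominal_scaling: float = 1.0) -> CallableSummary:
    """Quantize per-base depths into the four coverage categories.

    ``depth_track`` is a sequence of nonnegative integer depths; bins are
    half-open, so depth 4 is CALLABLE and depth 80 is HIGH_COVERAGE.
    """
    depths = np.asarray(depth_track)
    if depths.size and depths.min() < 0:
        raise ValueError("negative depth in track")
    edges = [0, 1, 4, 80, np.inf]
    hist, _ = np.histogram(depths, bins=edges)
    counts = {
        name: int(c) for name, c in zip(CATEGORY_BOUNDS, hist)
    }
    return CallableSummary(counts=counts, nominal_scaling=nominal_scaling)


def quantize_track(track: pd.DataFrame, nominal_scaling: float = 1.0) -> CallableSummary:
    """Quantize a BedGraph-style interval track (chrom, start, end, depth),
    weighting each interval's depth by its base span."""
    if (track["depth"] < 0).any():
        raise ValueError("negative depth in track")
    spans = (track["end"] - track["start"]).to_numpy()
    depths = track["depth"].to_numpy()
    counts = {}
    for name, (lo, hi) in CATEGORY_BOUNDS.items():
        sel = (depths >= lo) & (depths < hi)
        counts[name] = int(spans[sel].sum())
    return CallableSummary(counts=counts, nominal_scaling=nominal_scaling)


def estimate_rate(
    dnm_counts_per_trio, callable_per_trio
) -> RateEstimate:
    """Callable-adjusted mutation rate per base pair per generation.

    Each trio's rate is its DNM count divided by its callable base count
    (haploid denominator); the cohort rate is the mean of per-trio rates
    (the pooled counts / pooled callable alternative is also reported).
    """
    counts = pd.Series(dnm_counts_per_trio, dtype=float)
    callable_ = pd.Series(callable_per_trio, dtype=float)
    if len(counts) != len(callable_):
        raise ValueError("counts and callable sizes must pair up per trio")
    if len(counts) == 0:
        raise ValueError("need at least one trio")
    if (callable_ <= 0).any():
        raise ValueError("zero or negative callable size")
    callable_ = callable_.set_axis(counts.index)
    per_trio = counts / callable_
    return RateEstimate(
        per_trio=per_trio,
        rate=float(per_trio.mean()),
        pooled_rate=float(counts.sum() / callable_.sum()),
    )


_DEFAULT_TERMS = ["paternal_age", "maternal_age", "mbd4_het", "mbd4_hom", "callable_bases"]


def _design(covariates: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    missing = [t for t in terms if t not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    for t in terms:
        if covariates[t].nunique() <= 1:
            raise ValueError(
                f"covariate {t!r} is constant; term is not identifiable"
            )
    X = covariates[terms].astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_burden_model(
    per_offspring_counts,
    covariates: pd.DataFrame,
    model_label: str = "total",
    terms: list[str] | None = None,
) -> BurdenFit:
    """Poisson regression of per-offspring mutation counts on covariates.

    ``covariates`` holds one row per offspring with the requested term
    columns (default: paternal_age, maternal_age, mbd4_het, mbd4_hom,
    callable_bases — callable size enters as a covariate, not an
    offset).  ``model_label`` names the count response (total or a
    substitution-class subset).  Fitting is by IRLS with a log link;
    constant covariates raise an identifiability error, non-convergence
    raises as well.
    """
    counts = np.asarray(per_offspring_counts, dtype=float)
    if counts.size != len(covariates):
        raise ValueError("counts and covariates must have equal length")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    terms = terms if terms is not None else list(_DEFAULT_TERMS)
    X = _design(covariates, terms)
    if counts.size <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    model = sm.GLM(counts, X, family=sm.families.Poisson())
    result = model.fit(maxiter=100)
    if not result.converged:
        raise RuntimeError("Poisson IRLS did not converge")
    return BurdenFit(
        model_label=model_label,
        coefficients=pd.Series(result.params, index=X.columns),
        standard_errors=pd.Series(result.bse, index=X.columns),
        p_values=pd.Series(result.pvalues, index=X.columns),
        deviance=float(result.deviance),
        n_obs=int(counts.size),
    )


def fit_interaction_model(
    per_offspring_counts,
    covariates: pd.DataFrame,
    age_term: str = "maternal_age",
    terms: list[str] | None = None,
    model_label: str = "total+interaction",
) -> BurdenFit:
    """Burden model with an added hypermutator-by-age interaction term.

    ``covariates`` must contain a 0/1 ``hypermutator`` column and the
    age column named by ``age_term``; both groups must be present.
    """
    if "hypermutator" not in covariates.columns:
        raise ValueError("covariates need a 'hypermutator' column")
    hyper = covariates["hypermutator"].astype(int)
    if hyper.nunique() < 2:
        raise ValueError(
            "interaction model needs both hypermutator and control offspring"
        )
    cov = covariates.copy()
    interaction = f"hypermutator_x_{age_term}"
    cov[interaction] = hyper * cov[age_term].astype(float)
    base_terms = terms if terms is not None else [age_term, "hypermutator"]
    fit = fit_burden_model(
        per_offspring_counts,
        cov,
        model_label=model_label,
        terms=base_terms + [interaction],
    )
    fit.interaction_term = interaction
    return fit
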