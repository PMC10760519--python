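"""Synthetic trio cohorts with known de novo mutations and read evidence.

The generator emulates the statistical structure of a macaque trio WGS
study: control offspring carry ~10.5 DNMs drawn from a two-signature
(deamination + clock-like) mixture with a paternal-biased parent of
origin, while hypermutator offspring (dams homozygous for an MBD4 loss
of function allele) additionally receive maternal-origin C>T excesses
at CpG and CpA contexts.  Mutations are placed on a small synthetic
reference at positions whose trinucleotide context matches the sampled
substitution channel, so spectra computed downstream agree with the
generating mixture.  Read-level evidence (depths, allele counts, strand
splits, linked informative sites for phasing) and a configurable menu of
artifact classes — each designed to violate exactly one downstream
filter — complete the picture, making every pipeline stage testable
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import spectra as _spectra
from .calling import SampleEvidence, TrioEvidence, denovo_posterior
from .contexts import (
    BASES,
    CHANNELS_96,
    CONTEXTS_32,
    context_code_array,
    encode_sequence,
    parse_channel,
    revcomp,
)

__all__ = [
    "ReferenceIndex",
    "make_reference",
    "PedigreeConfig",
    "MutationProcessConfig",
    "EvidenceConfig",
    "TruthSet",
    "CohortSimulation",
    "ARTIFACT_CLASSES",
    "make_pedigree",
    "generate_masks",
    "simulate_truth_dnms",
    "simulate_site_evidence",
    "simulate_cohort",
]

ARTIFACT_CLASSES = [
    "inherited_undercalled_in_parent",
    "strand_biased_error",
    "low_depth_site",
    "common_population_variant",
    "repeat_region_site",
    "mosaic_parent_signal",
    "allele_biased_site",
]

#: cascade stage expected to remove each artifact class
ARTIFACT_TARGET_STAGE = {
    "inherited_undercalled_in_parent": "parental",
    "strand_biased_error": "strand",
    "low_depth_site": "depth",
    "common_population_variant": "popfreq",
    "repeat_region_site": "repeat_mask",
    "mosaic_parent_signal": "parental",
    "allele_biased_site": "vaf",
}


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


class ReferenceIndex:
    """A reference contig with a position index per trinucleotide context.

    Stores, for each of the 32 pyrimidine-collapsed contexts, the 0-based
    center positions at which it occurs, enabling placement of mutations
    at context-matched sites.
    """

    def __init__(self, sequence: str, name: str = "chr1"):
        if len(sequence) < 3:
            raise ValueError("reference must be at least 3 bases long")
        self.name = name
        self.sequence = sequence.upper()
        codes = encode_sequence(self.sequence)
        ctx = context_code_array(codes)  # index i -> center position i+1
        valid = ctx >= 0
        centers = np.nonzero(valid)[0].astype(np.int64) + 1
        labels = ctx[valid]
        order = np.argsort(labels, kind="stable")
        self._sorted_centers = centers[order]
        sorted_labels = labels[order]
        self._bounds = np.searchsorted(sorted_labels, np.arange(33))
        counts = np.bincount(labels, minlength=32)
        self.context_frequencies = pd.Series(
            counts / counts.sum(), index=CONTEXTS_32, name="frequency"
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def positions_for(self, context: str) -> np.ndarray:
        """0-based center positions matching a collapsed context."""
        i = CONTEXTS_32.index(context)
        return self._sorted_centers[self._bounds[i] : self._bounds[i + 1]]

    def base_at(self, pos0: int) -> str:
        return self.sequence[pos0]

    def context_at(self, pos0: int) -> str:
        return self.sequence[pos0 - 1 : pos0 + 2]


def make_reference(
    length: int, seed: int | np.random.Generator = 0, gc: float = 0.41
) -> ReferenceIndex:
    """Random reference contig with a given GC content."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=int(length), p=p)
    seq = "".join(BASES[c] for c in codes) if length < 10_000 else None
    if seq is None:
        lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
        seq = lut[codes].tobytes().decode("ascii")
    return ReferenceIndex(seq)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PedigreeConfig:
    """Cohort layout: how many control and hypermutator trios to draw.

    Ages may be fixed numbers or (low, high) sampling ranges in years.
    Dams of hypermutator trios are MBD4 -/-; all other parents are +/+
    unless ``het_dam_fraction`` of control dams are made +/- carriers.
    """

    n_control_trios: int = 10
    n_hyper_trios: int = 0
    paternal_age_years: float | tuple[float, float] = (7.0, 13.0)
    maternal_age_years: float | tuple[float, float] = (4.0, 10.0)
    offspring_sex: str | None = None  # None -> random M/F
    het_dam_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_control_trios < 0 or self.n_hyper_trios < 0:
            raise ValueError("trio counts must be nonnegative")
        for ages in (self.paternal_age_years, self.maternal_age_years):
            lo = ages[0] if isinstance(ages, tuple) else ages
            if lo <= 0:
                raise ValueError("ages must be positive")


@dataclass
class MutationProcessConfig:
    """Parameters of the germline mutational processes being emulated.

    ``control_burden_mean`` is the expected DNM count per offspring at
    the reference parental ages; age effects enter additively on the
    count scale as ``slope * (age - age_ref)`` so that cohorts drawn from
    the default age ranges keep the configured mean burden.
    """

    control_burden_mean: float = 10.5
    control_signature_mix: Mapping[str, float] = field(
        default_factory=lambda: {"SBS1-like": 0.2, "SBS5-like": 0.8}
    )
    maternal_cpg_excess_mean: float = 30.0
    maternal_cpa_excess_mean: float = 15.0
    paternal_fraction_of_control: float = 0.742
    paternal_age_slope: float = 1.5
    maternal_age_slope: float = 0.4
    paternal_age_ref: float = 10.0
    maternal_age_ref: float = 7.0
    shared_mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "control_burden_mean",
            "maternal_cpg_excess_mean",
            "maternal_cpa_excess_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        weights = np.array(list(self.control_signature_mix.values()), dtype=float)
        if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
            raise ValueError("signature mix weights must be nonnegative and sum to 1")
        if not (0.0 <= self.paternal_fraction_of_control <= 1.0):
            raise ValueError("paternal fraction must lie in [0, 1]")


def _default_artifact_rates() -> dict[str, float]:
    return {cls: 0.0 for cls in ARTIFACT_CLASSES}


@dataclass
class EvidenceConfig:
    """Read-evidence generation parameters.

    ``informative_site_density`` (informative heterozygous sites per
    base pair) together with ``fragment_length`` controls the fraction
    of DNMs that can be phased; the default density is calibrated so
    that ~53% of DNMs are phaseable at the default depth.
    ``artifact_rates`` gives the expected number of injected artifact
    candidates per trio for each class (defaults: all zero).
    """

    reference_length: int = 20_000_000
    nominal_callable_bases: float = 1.32e9
    mean_depth: float = 23.6
    base_error_rate: float = 0.002
    informative_site_density: float = 1.16e-3
    uninformative_site_fraction: float = 0.3
    fragment_length: int = 500
    screening_mutation_prior: float = 1e-4
    artifact_rates: dict[str, float] = field(default_factory=_default_artifact_rates)
    depth_track_window: int = 100_000
    depth_track_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.reference_length < 1e5:
            raise ValueError("reference_length must be at least 1e5")
        if not (4 < self.mean_depth < 80):
            raise ValueError("mean_depth must lie in (4, 80)")
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be at least 1")
        rates = dict(_default_artifact_rates())
        rates.update(self.artifact_rates)
        unknown = set(rates) - set(ARTIFACT_CLASSES)
        if unknown:
            raise ValueError(f"unknown artifact classes: {sorted(unknown)}")
        if any(v < 0 for v in rates.values()):
            raise ValueError("artifact rates must be nonnegative")
        self.artifact_rates = rates


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def _draw_age(ages, rng) -> float:
    if isinstance(ages, tuple):
        return float(rng.uniform(*ages))
    return float(ages)


def make_pedigree(config: PedigreeConfig, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Sample the cohort table: one row per trio with ages, genotypes, sex."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    total = config.n_control_trios + config.n_hyper_trios
    for i in range(total):
        hyper = i >= config.n_control_trios
        if hyper:
            dam_gt = "-/-"
        elif rng.random() < config.het_dam_fraction:
            dam_gt = "+/-"
        else:
            dam_gt = "+/+"
        sex = config.offspring_sex or ("M" if rng.random() < 0.5 else "F")
        rows.append(
            {
                "trio_id": f"trio{i:03d}",
                "child_id": f"child{i:03d}",
                "mother_id": f"dam{i:03d}",
                "father_id": f"sire{i:03d}",
                "paternal_age": _draw_age(config.paternal_age_years, rng),
                "maternal_age": _draw_age(config.maternal_age_years, rng),
                "mother_mbd4": dam_gt,
                "father_mbd4": "+/+",
                "child_sex": sex,
                "hypermutator": dam_gt == "-/-",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def generate_masks(
    reference: ReferenceIndex,
    seed: int | np.random.Generator = 0,
    repeat_fraction: float = 0.01,
    repeat_interval_len: int = 500,
    segdup_fraction: float = 0.02,
    segdup_interval_len: int = 5000,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Random repeat / segmental-duplication masks over the reference.

    Returns the two BED-style frames (0-based half-open) plus a boolean
    per-base array of masked positions, used to keep true DNMs outside
    the masks.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    length = len(reference)
    masked = np.zeros(length, dtype=bool)

    def _draw(fraction: int, interval_len: int) -> pd.DataFrame:
        n = max(1, int(round(fraction * length / interval_len)))
        starts = np.sort(rng.integers(0, max(1, length - interval_len), size=n))
        rows = []
        for s in starts:
            e = min(length, int(s) + interval_len)
            rows.append({"chrom": reference.name, "start": int(s), "end": e})
            masked[s:e] = True
        return pd.DataFrame(rows)

    repeat_bed = _draw(repeat_fraction, repeat_interval_len)
    segdup_bed = _draw(segdup_fraction, segdup_interval_len)
    return repeat_bed, segdup_bed, masked


# ---------------------------------------------------------------------------
# truth simulation
# ---------------------------------------------------------------------------


@dataclass
class TruthSet:
    """Per-offspring true DNMs with context, origin and process labels."""

    table: pd.DataFrame
    reference_name: str = "chr1"

    TABLE_COLUMNS = [
        "dnm_id", "child_id", "chrom", "pos", "ref", "alt",
        "context", "channel", "parent_of_origin", "process",
    ]

    def counts_per_offspring(self) -> pd.Series:
        if len(self.table) == 0:
            return pd.Series(dtype=int)
        return self.table.groupby("child_id").size()


def _channel_mixture(
    process: MutationProcessConfig, reference: ReferenceIndex
) -> np.ndarray:
    """Channel sampling probabilities for control (baseline) mutations.

    The built-in catalog (defined on uniform trinucleotide composition)
    is renormalized to the reference's context frequencies, then mixed
    with the configured signature weights.
    """
    catalog = _spectra.default_catalog()
    uniform = pd.Series(1 / 32, index=CONTEXTS_32)
    renorm = _spectra.renormalize_catalog(
        catalog, uniform, reference.context_frequencies
    )
    mix = np.zeros(96)
    for name, w in process.control_signature_mix.items():
        mix += w * renorm[name].to_numpy()
    return mix / mix.sum()


def _excess_channel_probs(reference: ReferenceIndex, three_prime: str) -> np.ndarray:
    """Channel probabilities for N[C>T]<three_prime> excess mutations,
    weighted by reference context availability."""
    probs = np.zeros(96)
    for i, ch in enumerate(CHANNELS_96):
        f, r, a, t = parse_channel(ch)
        if r == "C" and a == "T" and t == three_prime:
            probs[i] = reference.context_frequencies.loc[f"{f}C{t}"]
    total = probs.sum()
    if total <= 0:
        raise ValueError(
            f"reference contains no Cp{three_prime} contexts; cannot place "
            "excess mutations"
        )
    return probs / total


def _place_channel(
    channel: str,
    reference: ReferenceIndex,
    rng: np.random.Generator,
    taken: set[int],
    masked: np.ndarray | None,
    max_tries: int = 50,
) -> tuple[int, str, str]:
    """Pick a reference position matching a channel's context.

    Returns (1-based position, ref base on the forward strand, alt base
    on the forward strand)."""
    f, r, a, t = parse_channel(channel)
    ctx = f"{f}{r}{t}"
    positions = reference.positions_for(ctx)
    if len(positions) == 0:
        raise ValueError(f"context {ctx} absent from reference")
    for _ in range(max_tries):
        pos0 = int(positions[rng.integers(len(positions))])
        if pos0 in taken:
            continue
        if masked is not None and masked[pos0]:
            continue
        center = reference.base_at(pos0)
        if center in "CT":
            ref_base, alt_base = r, a
        else:
            ref_base, alt_base = revcomp(r), revcomp(a)
        taken.add(pos0)
        return pos0 + 1, ref_base, alt_base
    raise RuntimeError(f"could not place a mutation in context {ctx}")


def simulate_truth_dnms(
    pedigree: pd.DataFrame | PedigreeConfig,
    process_config: MutationProcessConfig,
    reference: ReferenceIndex,
    seed: int | np.random.Generator = 0,
    masked: np.ndarray | None = None,
) -> TruthSet:
    """Draw the per-offspring true DNMs.

    Baseline counts are Poisson around ``control_burden_mean`` plus
    centered linear age effects; parent of origin is Bernoulli with the
    configured paternal fraction.  Hypermutator offspring additionally
    receive Poisson numbers of maternal-origin CpG and CpA C>T
    mutations.  Mutations are placed independently per offspring at
    context-matched reference positions (outside ``masked`` when given).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(pedigree, PedigreeConfig):
        pedigree = make_pedigree(pedigree, rng)
    proc = process_config
    base_mix = _channel_mixture(proc, reference)
    need_cpg = proc.maternal_cpg_excess_mean > 0 and pedigree["hypermutator"].any()
    need_cpa = proc.maternal_cpa_excess_mean > 0 and pedigree["hypermutator"].any()
    cpg_probs = _excess_channel_probs(reference, "G") if need_cpg else None
    cpa_probs = _excess_channel_probs(reference, "A") if need_cpa else None

    rows: list[dict] = []
    for trio in pedigree.itertuples(index=False):
        taken: set[int] = set()
        lam = (
            proc.control_burden_mean
            + proc.paternal_age_slope * (trio.paternal_age - proc.paternal_age_ref)
            + proc.maternal_age_slope * (trio.maternal_age - proc.maternal_age_ref)
        )
        lam = max(lam, 0.0)
        n_base = rng.poisson(lam) if lam > 0 else 0
        batches = [("baseline", n_base, base_mix, None)]
        if trio.hypermutator:
            if cpg_probs is not None:
                batches.append(
                    ("cpg_excess", rng.poisson(proc.maternal_cpg_excess_mean),
                     cpg_probs, "maternal")
                )
            if cpa_probs is not None:
                batches.append(
                    ("cpa_excess", rng.poisson(proc.maternal_cpa_excess_mean),
                     cpa_probs, "maternal")
                )
        k = 0
        for process_label, n, probs, origin in batches:
            if n == 0:
                continue
            channel_idx = rng.choice(96, size=n, p=probs)
            for ci in channel_idx:
                channel = CHANNELS_96[ci]
                pos, ref_base, alt_base = _place_channel(
                    channel, reference, rng, taken, masked
                )
                if origin is None:
                    is_pat = rng.random() < proc.paternal_fraction_of_control
                    poo = "paternal" if is_pat else "maternal"
                else:
                    poo = origin
                f, r, a, t = parse_channel(channel)
                rows.append(
                    {
                        "dnm_id": f"{trio.child_id}_dnm{k:04d}",
                        "child_id": trio.child_id,
                        "chrom": reference.name,
                        "pos": pos,
                        "ref": ref_base,
                        "alt": alt_base,
                        "context": f"{f}{r}{t}",
                        "channel": channel,
                        "parent_of_origin": poo,
                        "process": process_label,
                    }
                )
                k += 1
    table = pd.DataFrame(rows, columns=TruthSet.TABLE_COLUMNS)

    # optional sharing of mutations between offspring (mosaic-like); off
    # by default because real cohorts show near-zero sharing
    if proc.shared_mutation_rate > 0 and len(table) and len(pedigree) > 1:
        extra = []
        children = list(pedigree["child_id"])
        for row in table.itertuples(index=False):
            if rng.random() < proc.shared_mutation_rate:
                others = [c for c in children if c != row.child_id]
                target = others[rng.integers(len(others))]
                dup = row._asdict()
                dup["child_id"] = target
                dup["dnm_id"] = f"{target}_shared_{row.dnm_id}"
                extra.append(dup)
        if extra:
            table = pd.concat([table, pd.DataFrame(extra)], ignore_index=True)

    return TruthSet(table=table, reference_name=reference.name)


# ---------------------------------------------------------------------------
# evidence simulation
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = [
    "dnm_id", "child_id", "chrom", "pos", "ref", "alt",
    "child_dp", "child_ref_ad", "child_alt_ad", "child_alt_fwd", "child_alt_rev",
    "mother_dp", "mother_ref_ad", "mother_alt_ad",
    "father_dp", "father_ref_ad", "father_alt_ad",
    "child_sex", "p_dn", "population_af", "truth_process",
]

READ_OBS_COLUMNS = ["dnm_id", "read_id", "dnm_allele", "info_pos", "info_allele"]

INFO_SITE_COLUMNS = [
    "child_id", "chrom", "pos", "ref", "alt", "child_gt", "mother_gt", "father_gt",
]


@dataclass
class CohortSimulation:
    """Everything a pipeline run needs, in memory."""

    pedigree: pd.DataFrame
    reference: ReferenceIndex
    truth: TruthSet
    evidence: pd.DataFrame
    read_obs: pd.DataFrame
    info_sites: pd.DataFrame
    repeat_bed: pd.DataFrame
    segdup_bed: pd.DataFrame
    af_table: pd.DataFrame
    depth_tracks: pd.DataFrame
    evidence_config: EvidenceConfig
    process_config: MutationProcessConfig


def _depth(rng: np.random.Generator, mean: float, low: int = 1) -> int:
    return max(low, int(rng.poisson(mean)))


def _is_male_x(chrom: str, sex) -> bool:
    return chrom in {"chrX", "X"} and sex == "M"


def _clean_child_evidence(rng, mean_depth, hemizygous=False, error=0.005):
    dp = _depth(rng, mean_depth)
    p_alt = 1.0 - error if hemizygous else 0.5
    alt = int(rng.binomial(dp, p_alt))
    fwd = int(rng.binomial(alt, 0.5)) if alt else 0
    return dp, dp - alt, alt, fwd, alt - fwd


def _balanced_child_evidence(rng, mean_depth, low_dp=10):
    """Child evidence conditioned to pass depth, VAF and strand filters
    (used for artifact sites that must fail only their targeted stage)."""
    dp = min(79, max(low_dp, int(rng.poisson(mean_depth))))
    lo = int(np.ceil(0.35 * dp))
    hi = int(np.floor(0.70 * dp))
    alt = int(rng.binomial(dp, 0.5))
    for _ in range(100):
        if lo <= alt <= hi:
            break
        alt = int(rng.binomial(dp, 0.5))
    alt = min(max(alt, lo), hi)
    fwd = min(max(1, int(rng.binomial(alt, 0.5))), alt - 1)
    return dp, dp - alt, alt, fwd, alt - fwd


def _clean_parent(rng, mean_depth, error):
    dp = _depth(rng, mean_depth)
    alt = int(rng.binomial(dp, error))
    return dp, dp - alt, alt


def _quiet_parent(rng, mean_depth):
    """Parent evidence with zero alt reads (for artifact sites that must
    not trip the parental filter)."""
    dp = min(79, max(10, int(rng.poisson(mean_depth))))
    return dp, dp, 0


def simulate_site_evidence(
    truth: TruthSet,
    pedigree: pd.DataFrame,
    evidence_config: EvidenceConfig,
    reference: ReferenceIndex,
    seed: int | np.random.Generator = 0,
    masked: np.ndarray | None = None,
    repeat_bed: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate read evidence for the truth set plus injected artifacts.

    Returns (evidence, read_obs, info_sites, af_table, depth_tracks).
    True DNM sites get a posterior computed from their evidence; artifact
    sites emulate upstream-caller false positives and carry an assigned
    posterior in (0.5, 1].  Each artifact class violates exactly the
    cascade stage it targets; all other predicates are satisfied by
    construction.
    """
    cfg = evidence_config
    if cfg.fragment_length < 1:
        raise ValueError("fragment_length must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ped_by_child = {t.child_id: t for t in pedigree.itertuples(index=False)}
    err = cfg.base_error_rate

    ev_rows: list[dict] = []
    obs_rows: list[dict] = []
    info_rows: list[dict] = []
    af_rows: list[dict] = []

    # --- true DNMs -------------------------------------------------------
    for row in truth.table.itertuples(index=False):
        trio = ped_by_child[row.child_id]
        hemi = _is_male_x(row.chrom, trio.child_sex)
        c_dp, c_ref, c_alt, c_fwd, c_rev = _clean_child_evidence(
            rng, cfg.mean_depth, hemizygous=hemi, error=err
        )
        m_dp, m_ref, m_alt = _clean_parent(rng, cfg.mean_depth, err)
        f_dp, f_ref, f_alt = _clean_parent(rng, cfg.mean_depth, err)
        trio_ev = TrioEvidence(
            chrom=row.chrom, pos=row.pos, ref=row.ref, alt=row.alt,
            child=SampleEvidence(c_dp, c_ref, c_alt, c_fwd, c_rev),
            mother=SampleEvidence(m_dp, m_ref, m_alt, m_alt, 0),
            father=SampleEvidence(f_dp, f_ref, f_alt, f_alt, 0),
            child_sex=trio.child_sex,
        )
        # candidate callers are deliberately permissive (their specificity
        # comes from the downstream hard filters), so the posterior written
        # as the upstream p_dn uses a screening-level mutation prior
        p_dn = (
            denovo_posterior(
                trio_ev, error_rate=err,
                mutation_prior=cfg.screening_mutation_prior,
            )
            if c_alt > 0
            else 0.0
        )
        ev_rows.append(
            {
                "dnm_id": row.dnm_id, "child_id": row.child_id,
                "chrom": row.chrom, "pos": row.pos, "ref": row.ref, "alt": row.alt,
                "child_dp": c_dp, "child_ref_ad": c_ref, "child_alt_ad": c_alt,
                "child_alt_fwd": c_fwd, "child_alt_rev": c_rev,
                "mother_dp": m_dp, "mother_ref_ad": m_ref, "mother_alt_ad": m_alt,
                "father_dp": f_dp, "father_ref_ad": f_ref, "father_alt_ad": f_alt,
                "child_sex": trio.child_sex, "p_dn": p_dn,
                "population_af": np.nan, "truth_process": row.process,
            }
        )

        # linked informative sites within the fragment window
        lam_sites = cfg.informative_site_density * 2 * cfg.fragment_length
        n_sites = rng.poisson(lam_sites)
        for s in range(n_sites):
            offset = 0
            while offset == 0:
                offset = int(rng.integers(-cfg.fragment_length, cfg.fragment_length + 1))
            ipos = row.pos + offset
            if not (2 <= ipos <= len(reference) - 1):
                continue
            iref = reference.base_at(ipos - 1)
            if iref not in BASES:
                continue
            alts = [b for b in BASES if b != iref]
            ialt = alts[rng.integers(3)]
            if rng.random() < cfg.uninformative_site_fraction:
                mother_gt, father_gt = "0/1", "0/1"
                allele_m = int(rng.integers(2))
                allele_f = 1 - allele_m
            else:
                het_is_mother = rng.random() < 0.5
                hom_alt_config = rng.random() < 0.3
                het_gt = "1/1" if hom_alt_config else "0/1"
                if het_is_mother:
                    mother_gt, father_gt = het_gt, "0/0"
                    allele_m, allele_f = 1, 0
                else:
                    mother_gt, father_gt = "0/0", het_gt
                    allele_m, allele_f = 0, 1
            info_rows.append(
                {
                    "child_id": row.child_id, "chrom": row.chrom, "pos": ipos,
                    "ref": iref, "alt": ialt, "child_gt": "0/1",
                    "mother_gt": mother_gt, "father_gt": father_gt,
                }
            )
            on_hap = allele_m if row.parent_of_origin == "maternal" else allele_f
            p_cover = max(0.0, 1.0 - abs(offset) / cfg.fragment_length)
            n_link = int(rng.binomial(c_alt, p_cover)) if c_alt else 0
            for j in range(n_link):
                obs_rows.append(
                    {
                        "dnm_id": row.dnm_id,
                        "read_id": f"{row.dnm_id}_s{s}_r{j}",
                        "dnm_allele": "alt",
                        "info_pos": ipos,
                        "info_allele": on_hap,
                    }
                )

    # --- artifact candidates --------------------------------------------
    repeat_intervals = (
        [(int(r.start), int(r.end)) for r in repeat_bed.itertuples(index=False)]
        if repeat_bed is not None and len(repeat_bed)
        else []
    )
    length = len(reference)
    for trio in pedigree.itertuples(index=False):
        a_idx = 0
        for cls in ARTIFACT_CLASSES:
            rate = cfg.artifact_rates.get(cls, 0.0)
            n = rng.poisson(rate) if rate > 0 else 0
            for _ in range(n):
                if cls == "repeat_region_site":
                    if not repeat_intervals:
                        raise ValueError(
                            "repeat_region_site artifacts require a repeat mask"
                        )
                    s, e = repeat_intervals[rng.integers(len(repeat_intervals))]
                    pos0 = int(rng.integers(max(1, s), min(e, length - 1)))
                else:
                    pos0 = int(rng.integers(1, length - 1))
                    if masked is not None:
                        for _try in range(50):
                            if not masked[pos0]:
                                break
                            pos0 = int(rng.integers(1, length - 1))
                ref_base = reference.base_at(pos0)
                if ref_base not in BASES:
                    continue
                alts = [b for b in BASES if b != ref_base]
                alt_base = alts[rng.integers(3)]

                c = _balanced_child_evidence(rng, cfg.mean_depth)
                m_dp, m_ref, m_alt = _quiet_parent(rng, cfg.mean_depth)
                f_dp, f_ref, f_alt = _quiet_parent(rng, cfg.mean_depth)
                pop_af = np.nan

                if cls == "low_depth_site":
                    dp = int(rng.integers(1, 4))
                    alt = max(1, int(rng.binomial(dp, 0.5)))
                    fwd = int(rng.binomial(alt, 0.5))
                    c = (dp, dp - alt, alt, fwd, alt - fwd)
                elif cls == "strand_biased_error":
                    dp, rf, alt, _, _ = c
                    if rng.random() < 0.5:
                        c = (dp, rf, alt, alt, 0)
                    else:
                        c = (dp, rf, alt, 0, alt)
                elif cls == "allele_biased_site":
                    dp = min(79, max(15, int(rng.poisson(cfg.mean_depth))))
                    alt = max(2, int(rng.binomial(dp, 0.2)))
                    if alt / dp >= 0.35:
                        alt = max(2, int(np.floor(0.30 * dp)))
                    fwd = min(max(1, int(rng.binomial(alt, 0.5))), alt - 1)
                    c = (dp, dp - alt, alt, fwd, alt - fwd)
                elif cls == "inherited_undercalled_in_parent":
                    dp = int(rng.integers(35, 61))
                    alt = int(rng.integers(2, 4))
                    if rng.random() < 0.5:
                        m_dp, m_ref, m_alt = dp, dp - alt, alt
                    else:
                        f_dp, f_ref, f_alt = dp, dp - alt, alt
                elif cls == "mosaic_parent_signal":
                    dp = min(79, max(10, int(rng.poisson(cfg.mean_depth))))
                    alt = max(2, int(rng.binomial(dp, 0.15)))
                    if rng.random() < 0.5:
                        m_dp, m_ref, m_alt = dp, dp - alt, alt
                    else:
                        f_dp, f_ref, f_alt = dp, dp - alt, alt
                elif cls == "common_population_variant":
                    pop_af = float(rng.uniform(0.02, 0.5))
                    af_rows.append(
                        {
                            "chrom": reference.name, "pos": pos0 + 1,
                            "ref": ref_base, "alt": alt_base, "af": pop_af,
                        }
                    )

                dnm_id = f"{trio.child_id}_art{a_idx:04d}"
                a_idx += 1
                c_dp, c_ref, c_alt, c_fwd, c_rev = c
                ev_rows.append(
                    {
                        "dnm_id": dnm_id, "child_id": trio.child_id,
                        "chrom": reference.name, "pos": pos0 + 1,
                        "ref": ref_base, "alt": alt_base,
                        "child_dp": c_dp, "child_ref_ad": c_ref,
                        "child_alt_ad": c_alt, "child_alt_fwd": c_fwd,
                        "child_alt_rev": c_rev,
                        "mother_dp": m_dp, "mother_ref_ad": m_ref,
                        "mother_alt_ad": m_alt,
                        "father_dp": f_dp, "father_ref_ad": f_ref,
                        "father_alt_ad": f_alt,
                        "child_sex": trio.child_sex,
                        "p_dn": float(rng.uniform(0.5, 1.0)),
                        "population_af": pop_af,
                        "truth_process": f"artifact:{cls}",
                    }
                )

    evidence = pd.DataFrame(ev_rows, columns=EVIDENCE_COLUMNS)
    read_obs = pd.DataFrame(obs_rows, columns=READ_OBS_COLUMNS)
    info_sites = pd.DataFrame(info_rows, columns=INFO_SITE_COLUMNS)
    af_table = pd.DataFrame(af_rows, columns=["chrom", "pos", "ref", "alt", "af"])

    depth_tracks = _simulate_depth_tracks(pedigree, cfg, reference, rng)
    return evidence, read_obs, info_sites, af_table, depth_tracks


def _simulate_depth_tracks(
    pedigree: pd.DataFrame,
    cfg: EvidenceConfig,
    reference: ReferenceIndex,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Windowed BedGraph-style mean depth per sample."""
    length = len(reference)
    win = cfg.depth_track_window
    starts = np.arange(0, length, win)
    rows = []
    samples: list[str] = []
    for t in pedigree.itertuples(index=False):
        samples.extend([t.child_id, t.mother_id, t.father_id])
    for sample in samples:
        depths = np.clip(
            np.round(rng.normal(cfg.mean_depth, cfg.depth_track_sd, size=len(starts))),
            0,
            None,
        ).astype(int)
        for s, d in zip(starts, depths):
            rows.append(
                {
                    "sample": sample, "chrom": reference.name,
                    "start": int(s), "end": int(min(s + win, length)),
                    "depth": int(d),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate_cohort(
    pedigree_config: PedigreeConfig,
    process_config: MutationProcessConfig | None = None,
    evidence_config: EvidenceConfig | None = None,
    seed: int = 0,
    reference: ReferenceIndex | None = None,
) -> CohortSimulation:
    """Simulate a full cohort: reference, masks, truth DNMs, evidence.

    A fixed ``seed`` makes the whole simulation reproducible; pass a
    prebuilt ``reference`` to share the (expensive) context index across
    cohorts.
    """
    process_config = process_config or MutationProcessConfig()
    evidence_config = evidence_config or EvidenceConfig()
    root = np.random.default_rng(seed)
    r_ref, r_ped, r_mask, r_truth, r_ev = root.spawn(5)
    if reference is None:
        reference = make_reference(evidence_config.reference_length, r_ref)
    pedigree = make_pedigree(pedigree_config, r_ped)
    repeat_bed, segdup_bed, masked = generate_masks(reference, r_mask)
    truth = simulate_truth_dnms(
        pedigree, process_config, reference, r_truth, masked=masked
    )
    evidence, read_obs, info_sites, af_table, depth_tracks = simulate_site_evidence(
        truth, pedigree, evidence_config, reference, r_ev,
        masked=masked, repeat_bed=repeat_bed,
    )
    return CohortSimulation(
        pedigree=pedigree,
        reference=reference,
        truth=truth,
        evidence=evidence,
        read_obs=read_obs,
        info_sites=info_sites,
        repeat_bed=repeat_bed,
        segdup_bed=segdup_bed,
        af_table=af_table,
        depth_tracks=depth_tracks,
        evidence_config=evidence_config,
        process_config=process_config,
    )
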