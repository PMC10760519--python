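"""Candidate de novo mutation calling and the hard-filter cascade.

A candidate DNM is a trio site where the offspring carries an allele that
neither parent's genotype explains.  Candidates are screened by a
posterior probability of de novo origin (>0.5), then passed through an
ordered cascade of hard filters mirroring a trio WGS pipeline: read
depth, variant allele frequency with chromosome-aware rules, strand
support, repeat and segmental-duplication masks, population allele
frequency, parental read evidence, and a per-offspring binomial test
with Benjamini-Hochberg correction.  The cascade records a per-stage
audit trail of removals.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleEvidence",
    "TrioEvidence",
    "DNMCandidate",
    "FilterThresholds",
    "FilterTrace",
    "GenomeMask",
    "denovo_posterior",
    "evaluate_site_filters",
    "region_mask_filter",
    "popfreq_filter",
    "binomial_fdr_filter",
    "run_cascade",
    "candidates_from_frame",
]

CASCADE_STAGES = [
    "p_dn",
    "depth",
    "vaf",
    "strand",
    "repeat_mask",
    "segdup_mask",
    "popfreq",
    "parental",
    "binomial_fdr",
]


@dataclass
class SampleEvidence:
    """Read evidence for one sample at one site."""

    dp: int
    ref_ad: int
    alt_ad: int
    alt_fwd: int = 0
    alt_rev: int = 0

    def __post_init__(self) -> None:
        if self.dp < 0 or self.ref_ad < 0 or self.alt_ad < 0:
            raise ValueError("depths and allele depths must be nonnegative")
        if self.ref_ad + self.alt_ad > self.dp:
            raise ValueError("AD components exceed DP")
        if self.alt_fwd + self.alt_rev != self.alt_ad:
            raise ValueError("strand counts do not sum to alt AD")

    @property
    def vaf(self) -> float:
        if self.dp == 0:
            return float("nan")
        return self.alt_ad / self.dp


@dataclass
class TrioEvidence:
    """Per-site read evidence for child, mother and father."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    child: SampleEvidence
    mother: SampleEvidence
    father: SampleEvidence
    child_sex: str | None = None  # "M" or "F"
    population_af: float | None = None


@dataclass
class DNMCandidate:
    """A candidate DNM with its evidence and cascade annotations."""

    evidence: TrioEvidence
    id: str = ""
    child_id: str = ""
    p_dn: float | None = None
    binomial_p: float | None = None
    fdr_adjusted_p: float | None = None
    verdict: str | None = None

    @property
    def vaf(self) -> float:
        return self.evidence.child.vaf


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds; defaults follow the trio WGS protocol."""

    p_dn_min: float = 0.5
    depth_min: int = 4
    depth_max: int = 80
    vaf_min: float = 0.35
    vaf_max: float = 0.70
    male_x_vaf_min: float = 0.70
    min_alt_reads: int = 2
    popfreq_max: float = 0.01
    parent_max_alt_reads: int = 1
    parent_max_vaf: float = 0.10
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.vaf_min < self.vaf_max <= 1):
            raise ValueError("need 0 <= vaf_min < vaf_max <= 1")
        if self.depth_min >= self.depth_max:
            raise ValueError("need depth_min < depth_max")


@dataclass
class FilterTrace:
    """Ordered per-stage removal counts for one cascade run."""

    stages: list[str]
    input_count: int
    removed: "OrderedDict[str, int]"
    survivors: list[DNMCandidate] = field(default_factory=list)

    @property
    def surviving_count(self) -> int:
        return self.input_count - sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        remaining = self.input_count
        for stage in self.stages:
            removed = self.removed.get(stage, 0)
            remaining -= removed
            rows.append({"stage": stage, "removed": removed, "surviving": remaining})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# de novo posterior
# ---------------------------------------------------------------------------

_GENOTYPES = [(0, 0), (0, 1), (1, 1)]  # ref/ref, ref/alt, alt/alt


def _read_loglik(ev: SampleEvidence, genotype: tuple[int, int], error_rate: float) -> float:
    """Binomial log-likelihood of a sample's alt read count given a genotype."""
    n_alt = sum(genotype)
    if n_alt == 0:
        p_alt = error_rate
    elif n_alt == 1:
        p_alt = 0.5
    else:
        p_alt = 1.0 - error_rate
    n = ev.ref_ad + ev.alt_ad
    return stats.binom.logpmf(ev.alt_ad, n, p_alt)


def _transmission_prob(gc: tuple[int, int], gm: tuple[int, int], gf: tuple[int, int]) -> float:
    """Mendelian probability of the child genotype given parental genotypes."""
    p = 0.0
    for am in gm:
        for af in gf:
            if tuple(sorted((am, af))) == gc:
                p += 0.25
    return p


def denovo_posterior(
    trio: TrioEvidence,
    error_rate: float = 0.005,
    mutation_prior: float = 1e-8,
    het_prior: float = 1e-3,
) -> float:
    """Posterior probability that the child carries a de novo allele.

    Enumerates the 27 diploid genotype configurations of the trio with
    binomial read likelihoods (per-read error ``error_rate``), parental
    genotype priors from Hardy-Weinberg at population alt frequency
    ``het_prior``, Mendelian transmission probabilities for the child, and
    a flat ``mutation_prior`` for Mendelian-impossible configurations.
    The posterior sums the configurations in which the child carries an
    allele absent from both parental genotypes.

    Parameters
    ----------
    trio : site evidence; all three samples must have nonzero depth.
    error_rate : per-read probability of observing the wrong allele.
    mutation_prior : prior probability of a de novo event at the site.
    het_prior : population frequency of the alternate allele, used for
        Hardy-Weinberg parental genotype priors.
    """
    for name, ev in (("child", trio.child), ("mother", trio.mother), ("father", trio.father)):
        if ev.dp == 0 or (ev.ref_ad + ev.alt_ad) == 0:
            raise ValueError(f"zero read depth in {name}: site not callable")

    q = het_prior
    geno_prior = {
        (0, 0): (1 - q) ** 2,
        (0, 1): 2 * q * (1 - q),
        (1, 1): q * q,
    }
    log_child = {g: _read_loglik(trio.child, g, error_rate) for g in _GENOTYPES}
    log_mother = {g: _read_loglik(trio.mother, g, error_rate) for g in _GENOTYPES}
    log_father = {g: _read_loglik(trio.father, g, error_rate) for g in _GENOTYPES}

    log_terms = []
    is_denovo = []
    for gm in _GENOTYPES:
        for gf in _GENOTYPES:
            parental_alleles = set(gm) | set(gf)
            for gc in _GENOTYPES:
                trans = _transmission_prob(gc, gm, gf)
                if trans > 0:
                    log_prior = (
                        math.log(geno_prior[gm])
                        + math.log(geno_prior[gf])
                        + math.log(trans)
                    )
                else:
                    log_prior = (
                        math.log(geno_prior[gm])
                        + math.log(geno_prior[gf])
                        + math.log(mutation_prior)
                    )
                loglik = log_mother[gm] + log_father[gf] + log_child[gc]
                log_terms.append(log_prior + loglik)
                is_denovo.append(any(a not in parental_alleles for a in gc))

    log_terms = np.array(log_terms)
    m = log_terms.max()
    weights = np.exp(log_terms - m)
    total = weights.sum()
    dn = weights[np.array(is_denovo)].sum()
    return float(dn / total)


# ---------------------------------------------------------------------------
# site-level hard filters
# ---------------------------------------------------------------------------

_X_LABELS = {"chrX", "X", "x", "chrx"}
_Y_LABELS = {"chrY", "Y", "y", "chry"}


def _chrom_class(chrom: str) -> str:
    if chrom in _X_LABELS:
        return "X"
    if chrom in _Y_LABELS:
        return "Y"
    stripped = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if stripped.isdigit():
        return "autosome"
    raise ValueError(f"unknown chromosome label {chrom!r}")


def _depth_ok(trio: TrioEvidence, thr: FilterThresholds) -> bool:
    return all(
        thr.depth_min <= ev.dp <= thr.depth_max
        for ev in (trio.child, trio.mother, trio.father)
    )


def _vaf_ok(trio: TrioEvidence, thr: FilterThresholds) -> bool:
    """VAF window with chromosome-aware rules; Y sites always fail."""
    cls = _chrom_class(trio.chrom)
    if cls == "Y":
        return False
    vaf = trio.child.vaf
    if cls == "X":
        if trio.child_sex is None:
            raise ValueError("child sex required for X-chromosome VAF rules")
        if trio.child_sex == "M":
            return vaf > thr.male_x_vaf_min
    return thr.vaf_min <= vaf <= thr.vaf_max


def _strand_ok(trio: TrioEvidence, thr: FilterThresholds) -> bool:
    ch = trio.child
    return ch.alt_ad >= thr.min_alt_reads and ch.alt_fwd >= 1 and ch.alt_rev >= 1


def _parental_ok(trio: TrioEvidence, thr: FilterThresholds) -> bool:
    for parent in (trio.mother, trio.father):
        if parent.alt_ad > thr.parent_max_alt_reads:
            return False
        if parent.dp > 0 and parent.vaf > thr.parent_max_vaf:
            return False
    return True


def evaluate_site_filters(
    candidate: DNMCandidate, thresholds: FilterThresholds = FilterThresholds()
) -> str:
    """Apply the site-level filters in order; return ``"pass"`` or
    ``"fail:<stage>"`` naming the first failing stage (depth, vaf,
    strand, parental)."""
    trio = candidate.evidence
    if not _depth_ok(trio, thresholds):
        return "fail:depth"
    if not _vaf_ok(trio, thresholds):
        return "fail:vaf"
    if not _strand_ok(trio, thresholds):
        return "fail:strand"
    if not _parental_ok(trio, thresholds):
        return "fail:parental"
    return "pass"


# ---------------------------------------------------------------------------
# region masks
# ---------------------------------------------------------------------------


class GenomeMask:
    """Set of genomic intervals (0-based half-open) with containment tests."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):  # noqa: D107
        self._trees: dict[str, IntervalTree] = {}
        n = 0
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty or inverted interval [{start}, {end})")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
            n += 1
        self.n_intervals = n

    @classmethod
    def from_frame(cls, bed: pd.DataFrame | None) -> "GenomeMask":
        if bed is None or len(bed) == 0:
            return cls()
        return cls(
            (str(r.chrom), int(r.start), int(r.end))
            for r in bed.itertuples(index=False)
        )

    def contains(self, chrom: str, pos: int) -> bool:
        """Containment of a 1-based position (tested as 0-based pos-1)."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def __len__(self) -> int:
        return self.n_intervals


def _as_mask(mask) -> GenomeMask:
    if mask is None:
        return GenomeMask()
    if isinstance(mask, GenomeMask):
        return mask
    if isinstance(mask, pd.DataFrame):
        return GenomeMask.from_frame(mask)
    return GenomeMask(mask)


def region_mask_filter(
    candidates: Sequence[DNMCandidate],
    repeat_bed,
    segdup_bed,
) -> tuple[list[DNMCandidate], dict[str, int]]:
    """Remove candidates whose site falls in the repeat or segdup masks.

    Masks are 0-based half-open; the repeat mask is applied before the
    segmental-duplication mask and removal counts are reported per mask.
    """
    repeats = _as_mask(repeat_bed)
    segdups = _as_mask(segdup_bed)
    counts = {"repeat_mask": 0, "segdup_mask": 0}
    survivors: list[DNMCandidate] = []
    after_repeats: list[DNMCandidate] = []
    for cand in candidates:
        if repeats.contains(cand.evidence.chrom, cand.evidence.pos):
            counts["repeat_mask"] += 1
            cand.verdict = "fail:repeat_mask"
        else:
            after_repeats.append(cand)
    for cand in after_repeats:
        if segdups.contains(cand.evidence.chrom, cand.evidence.pos):
            counts["segdup_mask"] += 1
            cand.verdict = "fail:segdup_mask"
        else:
            survivors.append(cand)
    return survivors, counts


# ---------------------------------------------------------------------------
# population allele frequency
# ---------------------------------------------------------------------------


def _lookup_af(cand: DNMCandidate, af_table) -> float | None:
    if cand.evidence.population_af is not None:
        return cand.evidence.population_af
    if af_table is None:
        return None
    key = (cand.evidence.chrom, cand.evidence.pos, cand.evidence.ref, cand.evidence.alt)
    if isinstance(af_table, Mapping):
        return af_table.get(key)
    # DataFrame with chrom/pos/ref/alt/af columns
    hit = af_table[
        (af_table["chrom"] == key[0])
        & (af_table["pos"] == key[1])
        & (af_table["ref"] == key[2])
        & (af_table["alt"] == key[3])
    ]
    if len(hit) == 0:
        return None
    return float(hit["af"].iloc[0])


def popfreq_filter(
    candidates: Sequence[DNMCandidate],
    af_table=None,
    popfreq_max: float = 0.01,
) -> tuple[list[DNMCandidate], int]:
    """Remove candidates whose population allele frequency exceeds
    ``popfreq_max`` (strict inequality); candidates absent from the table
    are treated as novel and kept."""
    survivors: list[DNMCandidate] = []
    removed = 0
    for cand in candidates:
        af = _lookup_af(cand, af_table)
        if af is not None:
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency {af} outside [0, 1]")
            if af > popfreq_max:
                removed += 1
                cand.verdict = "fail:popfreq"
                continue
        survivors.append(cand)
    return survivors, removed


# ---------------------------------------------------------------------------
# binomial / FDR stage
# ---------------------------------------------------------------------------


def binomial_fdr_filter(
    candidates: Sequence[DNMCandidate],
    fdr_alpha: float = 0.05,
) -> tuple[list[DNMCandidate], int]:
    """Two-sided exact binomial test of each candidate's alt count against
    balanced sampling (p = 0.5), Benjamini-Hochberg adjusted within each
    offspring; candidates with adjusted p below ``fdr_alpha`` are removed.
    """
    cands = list(candidates)
    for cand in cands:
        n = cand.evidence.child.ref_ad + cand.evidence.child.alt_ad
        if n == 0 or cand.evidence.child.dp == 0:
            raise ValueError(f"candidate {cand.id}: zero depth")
        cand.binomial_p = stats.binomtest(
            cand.evidence.child.alt_ad, n, 0.5
        ).pvalue

    survivors: list[DNMCandidate] = []
    removed = 0
    by_child: dict[str, list[DNMCandidate]] = {}
    for cand in cands:
        by_child.setdefault(cand.child_id, []).append(cand)
    for group in by_child.values():
        pvals = [c.binomial_p for c in group]
        reject, adjusted, _, _ = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")
        for cand, adj, rej in zip(group, adjusted, reject):
            cand.fdr_adjusted_p = float(adj)
            if rej and adj < fdr_alpha:
                removed += 1
                cand.verdict = "fail:binomial_fdr"
            else:
                survivors.append(cand)
    return survivors, removed


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------


def _candidate_p_dn(cand: DNMCandidate, error_rate: float, mutation_prior: float) -> float:
    if cand.p_dn is None:
        cand.p_dn = denovo_posterior(
            cand.evidence, error_rate=error_rate, mutation_prior=mutation_prior
        )
    return cand.p_dn


def run_cascade(
    raw_candidates: Sequence[DNMCandidate],
    thresholds: FilterThresholds = FilterThresholds(),
    repeat_bed=None,
    segdup_bed=None,
    af_table=None,
    error_rate: float = 0.005,
    mutation_prior: float = 1e-8,
) -> tuple[list[DNMCandidate], FilterTrace]:
    """Run the full ordered filter cascade and record per-stage removals.

    Stage order: de novo posterior gate, depth, VAF/chromosome rules,
    strand support, repeat mask, segmental-duplication mask, population
    allele frequency, parental read evidence, binomial test with
    per-offspring FDR correction.  Candidates carrying an upstream
    posterior (``p_dn``) are gated on it; otherwise the posterior is
    computed from the read evidence.
    """
    removed: "OrderedDict[str, int]" = OrderedDict((s, 0) for s in CASCADE_STAGES)
    current = list(raw_candidates)
    input_count = len(current)

    def _stage(name: str, keep_fn) -> None:
        nonlocal current
        kept = []
        for cand in current:
            if keep_fn(cand):
                kept.append(cand)
            else:
                removed[name] += 1
                cand.verdict = f"fail:{name}"
        current = kept

    _stage(
        "p_dn",
        lambda c: _candidate_p_dn(c, error_rate, mutation_prior) > thresholds.p_dn_min,
    )
    _stage("depth", lambda c: _depth_ok(c.evidence, thresholds))
    _stage("vaf", lambda c: _vaf_ok(c.evidence, thresholds))
    _stage("strand", lambda c: _strand_ok(c.evidence, thresholds))

    current, mask_counts = region_mask_filter(current, repeat_bed, segdup_bed)
    removed["repeat_mask"] = mask_counts["repeat_mask"]
    removed["segdup_mask"] = mask_counts["segdup_mask"]

    current, n_pop = popfreq_filter(current, af_table, thresholds.popfreq_max)
    removed["popfreq"] = n_pop

    _stage("parental", lambda c: _parental_ok(c.evidence, thresholds))

    current, n_fdr = binomial_fdr_filter(current, thresholds.fdr_alpha)
    removed["binomial_fdr"] = n_fdr

    for cand in current:
        cand.verdict = "pass"
    trace = FilterTrace(
        stages=list(CASCADE_STAGES),
        input_count=input_count,
        removed=removed,
        survivors=current,
    )
    return current, trace


# ---------------------------------------------------------------------------
# frame conversion
# ---------------------------------------------------------------------------

_EVIDENCE_COLUMNS = [
    "dnm_id", "child_id", "chrom", "pos", "ref", "alt",
    "child_dp", "child_ref_ad", "child_alt_ad", "child_alt_fwd", "child_alt_rev",
    "mother_dp", "mother_ref_ad", "mother_alt_ad",
    "father_dp", "father_ref_ad", "father_alt_ad",
    "child_sex", "p_dn", "population_af",
]


def candidates_from_frame(frame: pd.DataFrame) -> list[DNMCandidate]:
    """Build candidate objects from a flat evidence table (one row per
    site, columns as emitted by the simulator / VCF reader)."""
    cands = []
    for row in frame.itertuples(index=False):
        trio = TrioEvidence(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            child=SampleEvidence(
                dp=int(row.child_dp),
                ref_ad=int(row.child_ref_ad),
                alt_ad=int(row.child_alt_ad),
                alt_fwd=int(row.child_alt_fwd),
                alt_rev=int(row.child_alt_rev),
            ),
            mother=SampleEvidence(
                dp=int(row.mother_dp),
                ref_ad=int(row.mother_ref_ad),
                alt_ad=int(row.mother_alt_ad),
                alt_fwd=int(row.mother_alt_ad),
                alt_rev=0,
            ),
            father=SampleEvidence(
                dp=int(row.father_dp),
                ref_ad=int(row.father_ref_ad),
                alt_ad=int(row.father_alt_ad),
                alt_fwd=int(row.father_alt_ad),
                alt_rev=0,
            ),
            child_sex=None if pd.isna(row.child_sex) else str(row.child_sex),
            population_af=None if pd.isna(row.population_af) else float(row.population_af),
        )
        p_dn = None if pd.isna(row.p_dn) else float(row.p_dn)
        cands.append(
            DNMCandidate(
                evidence=trio,
                id=str(row.dnm_id),
                child_id=str(row.child_id),
                p_dn=p_dn,
            )
        )
    return cands
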