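"""Candidate-gene screens for a genetic cause of hypermutation.

Two complementary screens over an annotated variant table: (1) rare
coding variants homozygous in a proband and not homozygous in any other
parent of the cohort — the signature of a recessive private genotype —
and (2) genes from a curated instability-gene list carrying biallelic
damaging (high/moderate impact) variants in at least one parent, where
"biallelic" covers both a homozygous damaging variant and two or more
heterozygous damaging variants in the same gene (compound-heterozygous
candidates; phase unknown, flagged as such).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ScreenResult",
    "DAMAGING_IMPACTS",
    "private_homozygote_screen",
    "biallelic_damaging_screen",
]

IMPACT_LEVELS = {"high", "moderate", "low", "modifier"}
DAMAGING_IMPACTS = {"high", "moderate"}

_HOM_ALT = {"1/1", "1|1"}
_HET = {"0/1", "1/0", "0|1", "1|0"}


@dataclass
class ScreenResult:
    """Retained variants/genes plus per-filter removal counts."""

    retained: pd.DataFrame
    removal_counts: dict[str, int] = field(default_factory=dict)
    proband: str | None = None


def _genotype_column(variants: pd.DataFrame, sample: str) -> pd.Series:
    col = f"gt_{sample}"
    if col not in variants.columns:
        raise ValueError(f"missing genotype column {col!r}")
    return variants[col].astype(str)


def private_homozygote_screen(
    variants: pd.DataFrame,
    proband: str,
    other_parents: list[str],
    af_max: float = 0.01,
) -> ScreenResult:
    """Rare variants homozygous in the proband and in no other parent.

    ``variants`` needs columns chrom, pos, ref, alt, gene, impact, af and
    per-sample genotype columns ``gt_<sample>``.  Keeps variants with
    population AF strictly below ``af_max``, homozygous-alternate in the
    proband, and not homozygous-alternate in any listed other parent.
    """
    if (variants["af"] < 0).any() or (variants["af"] > 1).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    proband_gt = _genotype_column(variants, proband)

    counts: dict[str, int] = {}
    current = variants
    keep = _genotype_column(current, proband).isin(_HOM_ALT)
    counts["not_homozygous_in_proband"] = int((~keep).sum())
    current = current[keep]

    keep = current["af"] < af_max
    counts["common_af"] = int((~keep).sum())
    current = current[keep]

    other_hom = pd.Series(False, index=current.index)
    for parent in other_parents:
        other_hom |= _genotype_column(current, parent).isin(_HOM_ALT)
    counts["homozygous_in_other_parent"] = int(other_hom.sum())
    current = current[~other_hom]

    return ScreenResult(
        retained=current.reset_index(drop=True),
        removal_counts=counts,
        proband=proband,
    )


def biallelic_damaging_screen(
    variants: pd.DataFrame,
    candidate_gene_list: list[str],
    parents: list[str],
) -> ScreenResult:
    """Genes with biallelic damaging variants in at least one parent.

    Restricts to high/moderate-impact variants in the listed genes, then
    reports each (gene, parent) where the parent is homozygous-alternate
    for one such variant (mechanism ``homozygous``) or carries two or
    more heterozygous such variants (``compound_het``, phase unknown).
    """
    if len(candidate_gene_list) == 0:
        raise ValueError("candidate gene list must be nonempty")
    bad = set(variants["impact"].astype(str)) - IMPACT_LEVELS
    if bad:
        raise ValueError(f"unknown impact levels: {sorted(bad)}")
    damaging = variants[
        variants["impact"].isin(DAMAGING_IMPACTS)
        & variants["gene"].isin(candidate_gene_list)
    ]
    rows = []
    for gene in sorted(set(damaging["gene"])):
        sub = damaging[damaging["gene"] == gene]
        for parent in parents:
            gts = _genotype_column(sub, parent)
            n_hom = int(gts.isin(_HOM_ALT).sum())
            n_het = int(gts.isin(_HET).sum())
            if n_hom >= 1:
                rows.append(
                    {"gene": gene, "parent": parent, "mechanism": "homozygous",
                     "n_hom": n_hom, "n_het": n_het}
                )
            elif n_het >= 2:
                rows.append(
                    {"gene": gene, "parent": parent, "mechanism": "compound_het",
                     "n_hom": n_hom, "n_het": n_het}
                )
    retained = pd.DataFrame(
        rows, columns=["gene", "parent", "mechanism", "n_hom", "n_het"]
    )
    return ScreenResult(
        retained=retained,
        removal_counts={
            "not_damaging_or_not_listed": int(len(variants) - len(damaging))
        },
    )
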