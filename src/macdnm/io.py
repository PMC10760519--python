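"""File formats: trio VCFs, PED, BED masks, TSV tables, FASTA, tracks.

Coordinate conventions: VCF positions are 1-based; BED and BedGraph
intervals are 0-based half-open.  Trio VCFs carry one file per trio with
samples ordered child, mother, father; candidate sites store the de novo
posterior in INFO/DNP and read evidence in FORMAT GT:DP:AD:ADF:ADR,
while informative-site records (no DNP) carry genotypes only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .synthetic_data import (
    CohortSimulation,
    EVIDENCE_COLUMNS,
    INFO_SITE_COLUMNS,
)

__all__ = [
    "write_trio_vcf",
    "read_trio_vcf",
    "roundtrip_vcf",
    "write_ped",
    "read_ped",
    "write_bed",
    "read_bed",
    "write_fasta",
    "read_fasta",
    "write_cohort",
    "read_af_table",
    "write_catalog",
    "read_catalog",
]

_VCF_HEADER_META = [
    ("INFO", [("ID", "DNP"), ("Number", "1"), ("Type", "Float"),
              ("Description", "De novo posterior probability")]),
    ("FORMAT", [("ID", "GT"), ("Number", "1"), ("Type", "String"),
                ("Description", "Genotype")]),
    ("FORMAT", [("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                ("Description", "Read depth")]),
    ("FORMAT", [("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
                ("Description", "Allele depths (ref, alt)")]),
    ("FORMAT", [("ID", "ADF"), ("Number", "R"), ("Type", "Integer"),
                ("Description", "Forward-strand allele depths")]),
    ("FORMAT", [("ID", "ADR"), ("Number", "R"), ("Type", "Integer"),
                ("Description", "Reverse-strand allele depths")]),
]


def _trio_header(contig: str, contig_len: int, samples: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_len}>")
    for key, items in _VCF_HEADER_META:
        header.add_meta(key, items=items)
    for s in samples:
        header.add_sample(s)
    return header


def _parse_gt_str(gt: str) -> tuple[int, int]:
    sep = "|" if "|" in gt else "/"
    a, b = gt.split(sep)
    return int(a), int(b)


def write_trio_vcf(
    path: str | Path,
    child_id: str,
    mother_id: str,
    father_id: str,
    evidence: pd.DataFrame,
    info_sites: pd.DataFrame | None = None,
    contig: str = "chr1",
    contig_len: int = 0,
) -> None:
    """Write one trio's candidate and informative-site records.

    ``evidence`` rows (this child's subset of the cohort evidence table)
    become candidate records with INFO/DNP; ``info_sites`` rows become
    genotype-only records used downstream for phasing.
    """
    samples = [child_id, mother_id, father_id]
    if contig_len <= 0:
        pool = [evidence["pos"].max() if len(evidence) else 1]
        if info_sites is not None and len(info_sites):
            pool.append(info_sites["pos"].max())
        contig_len = int(max(pool)) + 1
    header = _trio_header(contig, contig_len, samples)

    records = []
    for row in evidence.itertuples(index=False):
        records.append(("ev", int(row.pos), row))
    if info_sites is not None:
        for row in info_sites.itertuples(index=False):
            records.append(("info", int(row.pos), row))
    records.sort(key=lambda t: t[1])

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for kind, pos, row in records:
            rec = vcf.new_record(
                contig=contig, start=pos - 1, alleles=(str(row.ref), str(row.alt))
            )
            if kind == "ev":
                rec.id = str(row.dnm_id)
                rec.info["DNP"] = float(row.p_dn) if not pd.isna(row.p_dn) else 0.0
                child_gt = (0, 1)
                rec.samples[child_id]["GT"] = child_gt
                rec.samples[child_id]["DP"] = int(row.child_dp)
                rec.samples[child_id]["AD"] = (int(row.child_ref_ad), int(row.child_alt_ad))
                ref_fwd = int(row.child_ref_ad) // 2
                rec.samples[child_id]["ADF"] = (ref_fwd, int(row.child_alt_fwd))
                rec.samples[child_id]["ADR"] = (
                    int(row.child_ref_ad) - ref_fwd, int(row.child_alt_rev)
                )
                for sample, dp, ref_ad, alt_ad in (
                    (mother_id, row.mother_dp, row.mother_ref_ad, row.mother_alt_ad),
                    (father_id, row.father_dp, row.father_ref_ad, row.father_alt_ad),
                ):
                    rec.samples[sample]["GT"] = (0, 0)
                    rec.samples[sample]["DP"] = int(dp)
                    rec.samples[sample]["AD"] = (int(ref_ad), int(alt_ad))
                    rf = int(ref_ad) // 2
                    rec.samples[sample]["ADF"] = (rf, int(alt_ad))
                    rec.samples[sample]["ADR"] = (int(ref_ad) - rf, 0)
            else:
                rec.samples[child_id]["GT"] = _parse_gt_str(str(row.child_gt))
                rec.samples[mother_id]["GT"] = _parse_gt_str(str(row.mother_gt))
                rec.samples[father_id]["GT"] = _parse_gt_str(str(row.father_gt))
            vcf.write(rec)


def read_trio_vcf(
    path: str | Path, child_sex: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a trio VCF back into (evidence, info_sites) frames.

    Candidate records must carry the full FORMAT evidence; a candidate
    record with missing DP/AD raises a parse error naming the position.
    """
    ev_rows, info_rows = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 3:
            raise ValueError(f"{path}: expected 3 samples, found {len(samples)}")
        child_id, mother_id, father_id = samples
        for rec in vcf:
            if len(rec.alleles) != 2:
                raise ValueError(
                    f"{path}:{rec.pos}: multi-allelic record; split upstream"
                )
            if "DNP" in rec.info:
                try:
                    child = rec.samples[child_id]
                    mother = rec.samples[mother_id]
                    father = rec.samples[father_id]
                    row = {
                        "dnm_id": rec.id or f"{rec.contig}:{rec.pos}",
                        "child_id": child_id,
                        "chrom": rec.contig,
                        "pos": rec.pos,
                        "ref": rec.alleles[0],
                        "alt": rec.alleles[1],
                        "child_dp": int(child["DP"]),
                        "child_ref_ad": int(child["AD"][0]),
                        "child_alt_ad": int(child["AD"][1]),
                        "child_alt_fwd": int(child["ADF"][1]),
                        "child_alt_rev": int(child["ADR"][1]),
                        "mother_dp": int(mother["DP"]),
                        "mother_ref_ad": int(mother["AD"][0]),
                        "mother_alt_ad": int(mother["AD"][1]),
                        "father_dp": int(father["DP"]),
                        "father_ref_ad": int(father["AD"][0]),
                        "father_alt_ad": int(father["AD"][1]),
                        "child_sex": child_sex,
                        "p_dn": float(rec.info["DNP"]),
                        "population_af": np.nan,
                        "truth_process": "",
                    }
                except (KeyError, TypeError) as exc:
                    raise ValueError(
                        f"{path}:{rec.contig}:{rec.pos}: candidate record "
                        f"missing FORMAT evidence ({exc})"
                    ) from exc
                ev_rows.append(row)
            else:
                def _gt(sample):
                    gt = rec.samples[sample]["GT"]
                    if gt is None or None in gt:
                        raise ValueError(
                            f"{path}:{rec.contig}:{rec.pos}: missing GT"
                        )
                    return f"{gt[0]}/{gt[1]}"

                info_rows.append(
                    {
                        "child_id": child_id,
                        "chrom": rec.contig,
                        "pos": rec.pos,
                        "ref": rec.alleles[0],
                        "alt": rec.alleles[1],
                        "child_gt": _gt(child_id),
                        "mother_gt": _gt(mother_id),
                        "father_gt": _gt(father_id),
                    }
                )
    evidence = pd.DataFrame(ev_rows, columns=EVIDENCE_COLUMNS)
    info_sites = pd.DataFrame(info_rows, columns=INFO_SITE_COLUMNS)
    return evidence, info_sites


def roundtrip_vcf(
    evidence: pd.DataFrame,
    info_sites: pd.DataFrame | None,
    child_id: str,
    mother_id: str,
    father_id: str,
    path: str | Path,
    child_sex: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write then re-read a trio's records; the pipeline-relevant fields
    survive unchanged."""
    write_trio_vcf(path, child_id, mother_id, father_id, evidence, info_sites)
    return read_trio_vcf(path, child_sex=child_sex)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_PED_COLUMNS = [
    "trio_id", "child_id", "father_id", "mother_id", "child_sex",
    "paternal_age", "maternal_age", "mother_mbd4", "father_mbd4",
]


def write_ped(path: str | Path, pedigree: pd.DataFrame) -> None:
    """PED-style table with ages and MBD4 genotypes in extra columns."""
    out = pedigree[
        ["trio_id", "child_id", "father_id", "mother_id", "child_sex",
         "paternal_age", "maternal_age", "mother_mbd4", "father_mbd4"]
    ]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_ped(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", header=None, names=_PED_COLUMNS)
    ped["hypermutator"] = ped["mother_mbd4"] == "-/-"
    return ped


# ---------------------------------------------------------------------------
# BED / BedGraph
# ---------------------------------------------------------------------------


def write_bed(path: str | Path, bed: pd.DataFrame) -> None:
    bed[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3+ column BED file (0-based half-open); malformed lines
    raise with their line number."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: non-integer BED coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{i}: end < start")
            rows.append({"chrom": parts[0], "start": start, "end": end})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_depth_tracks(outdir: str | Path, depth_tracks: pd.DataFrame) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, sub in depth_tracks.groupby("sample"):
        sub[["chrom", "start", "end", "depth"]].to_csv(
            outdir / f"{sample}.depth.bedgraph", sep="\t", index=False, header=False
        )


def read_depth_track(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"]
    )


# ---------------------------------------------------------------------------
# FASTA / tables
# ---------------------------------------------------------------------------


def write_fasta(path: str | Path, name: str, sequence: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True) as fa:
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    # pyfaidx leaves a .fai next to the file; harmless
    return seqs


def read_af_table(path: str | Path) -> pd.DataFrame:
    af = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref", "alt", "af"}
    if not required.issubset(af.columns):
        raise ValueError(f"{path}: AF table needs columns {sorted(required)}")
    return af


def write_catalog(path: str | Path, catalog: pd.DataFrame) -> None:
    catalog.rename_axis("channel").to_csv(path, sep="\t")


def read_catalog(path: str | Path) -> pd.DataFrame:
    catalog = pd.read_csv(path, sep="\t", index_col="channel")
    catalog.index.name = None
    return catalog


# ---------------------------------------------------------------------------
# cohort writer
# ---------------------------------------------------------------------------


def write_cohort(outdir: str | Path, sim: CohortSimulation) -> None:
    """Write a simulated cohort to disk in the study's exchange formats:
    per-trio VCFs, PED, BED masks, AF TSV, depth BedGraphs, read
    observations, truth manifest, and the reference FASTA."""
    outdir = Path(outdir)
    (outdir / "trios").mkdir(parents=True, exist_ok=True)
    contig_len = len(sim.reference)
    for trio in sim.pedigree.itertuples(index=False):
        ev = sim.evidence[sim.evidence["child_id"] == trio.child_id]
        info = sim.info_sites[sim.info_sites["child_id"] == trio.child_id]
        write_trio_vcf(
            outdir / "trios" / f"{trio.child_id}.vcf",
            trio.child_id, trio.mother_id, trio.father_id,
            ev, info, contig=sim.reference.name, contig_len=contig_len,
        )
    write_ped(outdir / "pedigree.ped", sim.pedigree)
    write_bed(outdir / "repeats.bed", sim.repeat_bed)
    write_bed(outdir / "segdups.bed", sim.segdup_bed)
    sim.af_table.to_csv(outdir / "population_af.tsv", sep="\t", index=False)
    sim.read_obs.to_csv(outdir / "read_observations.tsv", sep="\t", index=False)
    sim.truth.table.to_csv(outdir / "truth_manifest.tsv", sep="\t", index=False)
    write_depth_tracks(outdir / "depth", sim.depth_tracks)
    write_fasta(outdir / "reference.fa", sim.reference.name, sim.reference.sequence)
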