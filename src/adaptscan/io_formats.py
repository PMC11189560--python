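"""Readers and writers for the formats the pipeline touches.

VCF reading goes through cyvcf2 with the variant filters applied on the fly:
indels and multiallelic records dropped, site quality strictly above the
threshold, per-genotype (or per-site mean) depth inside an inclusive range,
and a minor-allele-frequency floor computed from called genotypes
(``maf >= min_maf`` — a site exactly at the floor is kept). The 012 dosage
matrix follows the vcftools ``--012`` dialect: one row per individual (first
column the row index), dosages in {0,1,2} with -1 for missing, and ``.indv``
/ ``.pos`` sidecar files. GFF3 is parsed with gffutils; only gene-type
features are returned, 1-based inclusive coordinates. All coordinates in I/O
are 1-based inclusive.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .containers import GenotypeMatrix, make_marker_frame
from .exceptions import ConfigurationError, FormatError

logger = logging.getLogger("adaptscan")


def setup_logging(verbose: bool = False) -> None:
    """Configure stderr logging for the package."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


@dataclass
class VariantFilterSpec:
    """Variant filters: biallelic SNPs, QUAL > 20, DP in [6, 100], maf >= 0.01."""

    biallelic_only: bool = True
    min_quality: float = 20.0
    min_depth: int = 6
    max_depth: int = 100
    min_maf: float = 0.01
    per_genotype_depth: bool = True

    def __post_init__(self):
        if not (0 <= self.min_maf < 0.5):
            raise ConfigurationError("min_maf must lie in [0, 0.5)")
        if self.min_depth > self.max_depth:
            raise ConfigurationError("min_depth must not exceed max_depth")


def read_vcf(path, filt: VariantFilterSpec | None = None):
    """Read a VCF into a GenotypeMatrix + marker map, applying the filters.

    Genotypes become alt-allele dosages {0,1,2} with nan for missing calls;
    with per-genotype depth filtering, calls whose DP falls outside
    [min_depth, max_depth] are set missing, otherwise whole sites whose mean
    DP is out of range are dropped. The maf is computed from non-missing
    calls after depth masking.
    """
    filt = filt or VariantFilterSpec()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples")
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_seen = n_kept = 0
    for var in vcf:
        n_seen += 1
        if filt.biallelic_only and (len(var.ALT) != 1 or var.is_indel):
            continue
        if not var.is_snp:
            continue
        if var.QUAL is None or var.QUAL <= filt.min_quality:
            continue
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            dp = dp.astype(float).reshape(-1)
            dp[dp < 0] = np.nan
            if filt.per_genotype_depth:
                bad = np.isnan(dp) | (dp < filt.min_depth) | (dp > filt.max_depth)
                dosage[bad] = np.nan
            else:
                mean_dp = np.nanmean(dp) if np.any(~np.isnan(dp)) else np.nan
                if not (filt.min_depth <= mean_dp <= filt.max_depth):
                    continue
        called = np.sum(~np.isnan(dosage))
        if called == 0:
            continue
        p = np.nansum(dosage) / (2.0 * called)
        maf = min(p, 1.0 - p)
        if maf < filt.min_maf:
            continue
        n_kept += 1
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dosage)
    logger.debug("read_vcf: kept %d of %d records from %s", n_kept, n_seen, path)
    markers = make_marker_frame(chroms, poss, refs, alts)
    dosages = (
        np.array(rows, dtype=float).T
        if rows
        else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(dosages, markers, samples), markers


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with diploid GT calls."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        for j, row in geno.markers.iterrows():
            calls = [
                code.get(d, "./.") if not np.isnan(d) else "./."
                for d in geno.dosages[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.marker_id}\t{row.ref}\t{row.alt}"
                f"\t100\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_dosage_012(geno: GenotypeMatrix, prefix) -> None:
    """Write the vcftools --012 trio: prefix.012, prefix.012.indv, prefix.012.pos."""
    prefix = str(prefix)
    mat = np.where(np.isnan(geno.dosages), -1, geno.dosages).astype(int)
    with open(prefix + ".012", "w") as fh:
        for i, row in enumerate(mat):
            fh.write("\t".join([str(i)] + [str(v) for v in row]) + "\n")
    with open(prefix + ".012.indv", "w") as fh:
        fh.writelines(s + "\n" for s in geno.sample_ids)
    geno.markers[["chrom", "pos"]].to_csv(
        prefix + ".012.pos", sep="\t", header=False, index=False
    )


def read_dosage_012(prefix):
    """Read a --012 trio back into a GenotypeMatrix (-1 -> missing)."""
    prefix = str(prefix)
    rows = []
    with open(prefix + ".012") as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            try:
                values = [int(v) for v in fields[1:]]
            except ValueError as err:
                raise FormatError(f"{prefix}.012 line {lineno}: {err}") from err
            for v in values:
                if v not in (-1, 0, 1, 2):
                    raise FormatError(
                        f"{prefix}.012 line {lineno}: value {v} outside"
                        " {-1,0,1,2}"
                    )
            rows.append(values)
    with open(prefix + ".012.indv") as fh:
        samples = [l.strip() for l in fh if l.strip()]
    pos = pd.read_csv(
        prefix + ".012.pos", sep="\t", header=None, names=["chrom", "pos"]
    )
    markers = make_marker_frame(pos["chrom"], pos["pos"])
    mat = np.array(rows, dtype=float) if rows else np.empty((0, len(markers)))
    if mat.size:
        mat[mat == -1] = np.nan
    return GenotypeMatrix(mat, markers, samples), markers


def read_gff3(path) -> pd.DataFrame:
    """Gene records (gene_id, chrom, start, end, strand), sorted by start.

    Non-gene features are ignored; 1-based inclusive coordinates per the
    GFF3 convention.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as err:
        raise FormatError(f"{path}: not a parseable GFF3 ({err})") from err
    rows = []
    for feat in db.features_of_type("gene"):
        if feat.end < feat.start:
            raise FormatError(
                f"{path}: gene {feat.id} has end < start ({feat.end} < {feat.start})"
            )
        rows.append(
            {
                "gene_id": feat.id,
                "chrom": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return frame.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene records as GFF3 (source 'adaptscan', feature type 'gene')."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            strand = g.get("strand", "+") or "+"
            fh.write(
                f"{g.chrom}\tadaptscan\tgene\t{g.start}\t{g.end}\t.\t{strand}\t."
                f"\tID={g.gene_id}\n"
            )


def load_config(path):
    """Load an ExperimentConfig from a YAML file (keys = field names)."""
    from .synthetic_experiment import ExperimentConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    try:
        return ExperimentConfig(**raw)
    except TypeError as err:
        raise ConfigurationError(str(err)) from err
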