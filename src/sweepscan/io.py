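"""Readers and writers: VCF, GFF3, sample lists, phenotype/term/window tables.

VCF reading goes through cyvcf2 (htslib); GFF3 through gffutils. VCF writing
is a plain VCFv4.2 text emitter for the simulator's FORMAT/INFO layout.

Coordinates: sites and genes are 1-based inclusive; window tables use
half-open ``[start, end)`` 0-based intervals (see :mod:`sweepscan.containers`).
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import INFO_KEYS, MISSING, GeneRecord, SiteTable, VariantSite

logger = logging.getLogger("sweepscan.io")

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

WINDOW_COLUMNS = ["chrom", "start", "end", "n_snps", "fst", "pi_case", "pi_control", "pi_ratio"]


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str, sample_subset: Sequence[str] | None = None) -> Iterator[VariantSite]:
    """Stream :class:`VariantSite` records from a VCF (plain or gzipped).

    Missing FORMAT keys yield missing-value markers rather than errors.
    Multi-allelic records are skipped with a warning (the pipeline is
    biallelic-SNP only).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path, gts012=True)
    if sample_subset is not None:
        unknown = sorted(set(sample_subset) - set(vcf.samples))
        if unknown:
            raise KeyError(f"samples not present in VCF header: {unknown}")
        vcf.close()
        vcf = VCF(path, gts012=True, samples=list(sample_subset))
    n = len(vcf.samples)
    for idx, variant in enumerate(vcf):
        try:
            if len(variant.ALT) != 1:
                logger.warning(
                    "skipping non-biallelic record %s:%s", variant.CHROM, variant.POS
                )
                continue
            gt = np.asarray(variant.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING  # gts012: 3 == unknown
            gq = _format_vector(variant, "GQ", n)
            dp = _format_vector(variant, "DP", n)
            ad = _format_ad(variant, n)
            info = {}
            for key in INFO_KEYS:
                if key == "QUAL":
                    info["QUAL"] = variant.QUAL
                    continue
                value = variant.INFO.get(key)
                if value is not None:
                    info[key] = float(value)
            yield VariantSite(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=variant.ALT[0],
                genotypes=gt,
                gq=gq,
                dp=dp,
                ad=ad,
                info=info,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed VCF record #{idx + 1} in {path}: {exc}") from exc
    vcf.close()


def _format_vector(variant, key: str, n: int) -> np.ndarray:
    raw = variant.format(key)
    if raw is None:
        return np.full(n, MISSING, dtype=np.int32)
    vec = np.asarray(raw).reshape(n, -1)[:, 0].astype(np.int64)
    vec[vec < 0] = MISSING  # htslib encodes missing as large negatives
    return vec.astype(np.int32)


def _format_ad(variant, n: int) -> np.ndarray | None:
    raw = variant.format("AD")
    if raw is None:
        return None
    ad = np.asarray(raw).reshape(n, -1)[:, :2].astype(np.int64)
    ad[ad < 0] = MISSING
    return ad.astype(np.int32)


def read_site_table(path: str, sample_subset: Sequence[str] | None = None) -> SiteTable:
    """Load a whole VCF into the columnar :class:`SiteTable`."""
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples) if sample_subset is None else list(sample_subset)
    vcf.close()
    return SiteTable.from_sites(read_vcf(path, sample_subset), samples)


def write_vcf(table: SiteTable, path: str, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a :class:`SiteTable` as VCFv4.2 with FORMAT GT:AD:DP:GQ."""
    info_keys = [k for k in INFO_KEYS if k != "QUAL"]
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if chrom_lengths:
                for name, length in chrom_lengths.items():
                    fh.write(f"##contig=<ID={name},length={length}>\n")
            else:
                for name in pd.unique(table.chrom):
                    fh.write(f"##contig=<ID={name}>\n")
            for key in info_keys:
                fh.write(
                    f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
                )
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(table.samples)
                + "\n"
            )
            for site in table.iter_sites():
                qual = site.info.get("QUAL")
                qual_str = "." if qual is None or np.isnan(qual) else f"{qual:.6g}"
                parts = []
                for key in info_keys:
                    value = site.info.get(key)
                    if value is not None and not np.isnan(value):
                        parts.append(f"{key}={value:.6g}")
                info_str = ";".join(parts) if parts else "."
                fields = [
                    site.chrom,
                    str(site.pos),
                    ".",
                    site.ref,
                    site.alt,
                    qual_str,
                    ".",
                    info_str,
                    "GT:AD:DP:GQ",
                ]
                for j in range(site.n_samples):
                    gt_str = _GT_STRINGS[int(site.genotypes[j])]
                    if site.ad is not None and site.ad[j, 0] != MISSING:
                        ad_str = f"{site.ad[j, 0]},{site.ad[j, 1]}"
                    else:
                        ad_str = "."
                    dp_str = "." if site.dp is None or site.dp[j] == MISSING else str(site.dp[j])
                    gq_str = "." if site.gq is None or site.gq[j] == MISSING else str(site.gq[j])
                    fields.append(f"{gt_str}:{ad_str}:{dp_str}:{gq_str}")
                fh.write("\t".join(fields) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing VCF to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# GFF3


def read_gff_genes(path: str) -> list[GeneRecord]:
    """Return ``gene`` features (1-based inclusive) from a GFF3 file.

    Features lacking an ID attribute are skipped with a warning.
    """
    import gffutils

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        has_features = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_features:
        return []
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        id_spec={"gene": "ID"},
    )
    genes = []
    for feature in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_ids = feature.attributes.get("ID")
        if not gene_ids:
            logger.warning(
                "gene feature at %s:%d-%d lacks ID attribute; skipped",
                feature.seqid,
                feature.start,
                feature.end,
            )
            continue
        genes.append(GeneRecord(gene_ids[0], feature.seqid, feature.start, feature.end))
    return genes


def write_gff_genes(genes: Iterable[GeneRecord], path: str) -> None:
    try:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in genes:
                fh.write(
                    f"{gene.chrom}\tsweepscan\tgene\t{gene.start}\t{gene.end}\t.\t+\t.\t"
                    f"ID={gene.gene_id}\n"
                )
    except OSError as exc:
        raise OSError(f"failed writing GFF3 to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Plain tables


def read_sample_list(path: str) -> list[str]:
    """One sample ID per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_sample_list(ids: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        for sample_id in ids:
            fh.write(sample_id + "\n")


def read_phenotype_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_term_map(path: str) -> pd.DataFrame:
    """Two-column gene-to-term TSV (gene_id, term_id)."""
    table = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term_id"}.issubset(table.columns):
        table = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"])
    return table[["gene_id", "term_id"]]


def write_window_table(stats: pd.DataFrame, path: str) -> None:
    """Serialize window statistics; NaN written as NA, floats to 10 sig digits."""
    out = stats.loc[:, WINDOW_COLUMNS].copy()
    try:
        out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    except OSError as exc:
        raise OSError(f"failed writing window table to {path}: {exc}") from exc


def read_window_table(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    if table.empty:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return table
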