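"""Core in-memory containers for variant and annotation data.

Two views of the same data coexist:

* :class:`VariantSite` — one biallelic SNP with per-sample genotype calls and
  quality annotations; the record type streamed by the VCF reader.
* :class:`SiteTable` — a columnar (site x sample) representation used by the
  numerical pipeline (filtering, FST/pi, resampling), in the spirit of
  scikit-allel's genotype arrays.

Coordinate conventions: variant positions and gene intervals are 1-based
inclusive (VCF/GFF3 native); genomic windows are half-open ``[start, end)`` in
0-based bp. Converting between the two happens only at window assignment.

Genotypes are stored as alternate-allele dosage: 0 (hom ref), 1 (het),
2 (hom alt), and -1 for missing. Per-sample DP/GQ use -1 for missing; AD is a
``(ref_depth, alt_depth)`` pair with -1,-1 when absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: Site-level annotations carried through the pipeline. ReadPosRankSum is
#: stored under the INFO key RPRS; QUAL is the VCF QUAL column.
INFO_KEYS = ("QD", "FS", "SOR", "MQ", "MQRankSum", "RPRS", "QUAL")


@dataclass
class VariantSite:
    """One biallelic SNP with per-sample diploid calls and quality fields."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: np.ndarray  # int8 dosage, -1 missing
    gq: np.ndarray | None = None  # int, -1 missing
    dp: np.ndarray | None = None  # int, -1 missing
    ad: np.ndarray | None = None  # (n_samples, 2) int, -1 missing
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.ad is not None:
            ad = np.asarray(self.ad)
            if ad.ndim != 2 or ad.shape[1] != 2:
                raise ValueError("ad must have shape (n_samples, 2)")
            valid = ad >= 0
            if not np.all(ad[valid] >= 0):  # pragma: no cover - defensive
                raise ValueError("ad components must be non-negative")
            self.ad = ad

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    def copy(self) -> "VariantSite":
        return VariantSite(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            genotypes=self.genotypes.copy(),
            gq=None if self.gq is None else np.array(self.gq),
            dp=None if self.dp is None else np.array(self.dp),
            ad=None if self.ad is None else np.array(self.ad),
            info=dict(self.info),
        )


@dataclass(frozen=True)
class GeneRecord:
    """Gene interval from GFF3; coordinates 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


class SiteTable:
    """Columnar container of biallelic SNPs across samples.

    Attributes
    ----------
    samples : list of str
    chrom : (S,) object array
    pos : (S,) int64 array, 1-based
    ref, alt : (S,) object arrays
    gt : (S, N) int8 dosage matrix, -1 missing
    dp, gq : optional (S, N) int32, -1 missing
    ad_ref, ad_alt : optional (S, N) int32 per-allele read depths
    info : optional DataFrame with columns from :data:`INFO_KEYS`
    """

    def __init__(
        self,
        samples: Sequence[str],
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        gt: np.ndarray,
        dp: np.ndarray | None = None,
        gq: np.ndarray | None = None,
        ad_ref: np.ndarray | None = None,
        ad_alt: np.ndarray | None = None,
        info: pd.DataFrame | None = None,
    ) -> None:
        self.samples = list(samples)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.gt = np.asarray(gt, dtype=np.int8)
        if self.gt.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"gt shape {self.gt.shape} does not match "
                f"({len(self.pos)} sites, {len(self.samples)} samples)"
            )
        self.dp = None if dp is None else np.asarray(dp, dtype=np.int32)
        self.gq = None if gq is None else np.asarray(gq, dtype=np.int32)
        self.ad_ref = None if ad_ref is None else np.asarray(ad_ref, dtype=np.int32)
        self.ad_alt = None if ad_alt is None else np.asarray(ad_alt, dtype=np.int32)
        self.info = None if info is None else info.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def take_sites(self, index: np.ndarray) -> "SiteTable":
        """Row-subset (boolean mask or integer index), preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SiteTable(
            samples=self.samples,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            gt=self.gt[index],
            dp=None if self.dp is None else self.dp[index],
            gq=None if self.gq is None else self.gq[index],
            ad_ref=None if self.ad_ref is None else self.ad_ref[index],
            ad_alt=None if self.ad_alt is None else self.ad_alt[index],
            info=None if self.info is None else self.info.iloc[index],
        )

    def iter_sites(self) -> Iterator[VariantSite]:
        """Stream the table as :class:`VariantSite` records."""
        for i in range(self.n_sites):
            ad = None
            if self.ad_alt is not None and self.ad_ref is not None:
                ad = np.stack([self.ad_ref[i], self.ad_alt[i]], axis=1)
            yield VariantSite(
                chrom=str(self.chrom[i]),
                pos=int(self.pos[i]),
                ref=str(self.ref[i]),
                alt=str(self.alt[i]),
                genotypes=self.gt[i],
                gq=None if self.gq is None else self.gq[i],
                dp=None if self.dp is None else self.dp[i],
                ad=ad,
                info={} if self.info is None else self.info.iloc[i].to_dict(),
            )

    def chrom_lengths(self, pad: int = 0) -> dict[str, int]:
        """Max observed position per chromosome (+pad), in first-seen order."""
        out: dict[str, int] = {}
        for c in pd.unique(self.chrom):
            out[str(c)] = int(self.pos[self.chrom == c].max()) + pad
        return out

    @classmethod
    def from_sites(
        cls, sites: Sequence[VariantSite] | Iterator[VariantSite], samples: Sequence[str]
    ) -> "SiteTable":
        sites = list(sites)
        n = len(samples)
        s = len(sites)
        chrom = np.empty(s, dtype=object)
        pos = np.empty(s, dtype=np.int64)
        ref = np.empty(s, dtype=object)
        alt = np.empty(s, dtype=object)
        gt = np.full((s, n), MISSING, dtype=np.int8)
        dp = np.full((s, n), MISSING, dtype=np.int32)
        gq = np.full((s, n), MISSING, dtype=np.int32)
        ad_ref = np.full((s, n), MISSING, dtype=np.int32)
        ad_alt = np.full((s, n), MISSING, dtype=np.int32)
        info_rows = []
        for i, site in enumerate(sites):
            chrom[i], pos[i], ref[i], alt[i] = site.chrom, site.pos, site.ref, site.alt
            gt[i] = site.genotypes
            if site.dp is not None:
                dp[i] = site.dp
            if site.gq is not None:
                gq[i] = site.gq
            if site.ad is not None:
                ad_ref[i] = site.ad[:, 0]
                ad_alt[i] = site.ad[:, 1]
            info_rows.append({k: site.info.get(k, np.nan) for k in INFO_KEYS})
        info = pd.DataFrame(info_rows, columns=list(INFO_KEYS)) if s else None
        return cls(
            samples, chrom, pos, ref, alt, gt,
            dp=dp, gq=gq, ad_ref=ad_ref, ad_alt=ad_alt, info=info,
        )


def check_sorted(chrom: np.ndarray, pos: np.ndarray) -> None:
    """Raise if sites are not sorted by (chromosome block, position)."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    seen: dict = {}
    last_chrom = None
    for c in chrom:
        if c != last_chrom:
            if c in seen:
                raise ValueError(f"chromosome {c} appears in non-contiguous blocks")
            seen[c] = True
            last_chrom = c
    for c in seen:
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"positions not sorted on chromosome {c}")
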