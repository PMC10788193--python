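"""Allele-specific read counting over the SNP panel and eSNP filtering.

Turns aligned reads (SAM) into a samples x SNPs matrix of
(ref_count, alt_count) cells, then applies the filter cascade used to
define "eSNPs": SNPs located in the read data at all, SNPs variable
across samples, and SNPs present in at least 75% of samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .panel import SnpPanel

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleCountMatrix",
    "CountingReport",
    "count_alleles",
    "locate_snps",
    "variable_snps",
    "filter_esnps",
]


@dataclass
class AlleleCountMatrix:
    """samples x SNPs grid of reference/alternate read counts.

    A cell with ref + alt == 0 is "absent": the SNP was not observed in
    that sample.  ``depths_m`` carries the water-sampling depth of each
    eDNA sample.
    """

    ref: np.ndarray           # (n_samples, n_snps) int
    alt: np.ndarray           # (n_samples, n_snps) int
    sample_ids: list
    snp_ids: list
    depths_m: np.ndarray      # (n_samples,) float (NaN if unknown)

    def __post_init__(self):
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.depths_m = np.asarray(self.depths_m, dtype=float)
        n_s, n_v = self.ref.shape
        if self.alt.shape != (n_s, n_v):
            raise ValueError("ref and alt count shapes differ")
        if len(self.sample_ids) != n_s or len(self.snp_ids) != n_v:
            raise ValueError("id lists inconsistent with count shapes")
        if self.depths_m.shape != (n_s,):
            raise ValueError("depths_m must have one entry per sample")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("negative read counts")

    @property
    def n_samples(self) -> int:
        return self.ref.shape[0]

    @property
    def n_snps(self) -> int:
        return self.ref.shape[1]

    def total(self) -> np.ndarray:
        """Per-cell total depth ref + alt."""
        return self.ref + self.alt

    def present(self, min_depth: int = 1) -> np.ndarray:
        """Boolean samples x SNPs presence mask at a depth floor."""
        return self.total() >= min_depth

    def subset_snps(self, snp_ids) -> "AlleleCountMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return AlleleCountMatrix(
            self.ref[:, idx], self.alt[:, idx],
            list(self.sample_ids), list(snp_ids), self.depths_m.copy(),
        )

    # ---------------------------------------------------------------- I/O

    def to_tsv(self, path) -> None:
        """Write long-format counts: sample_id, depth_m, snp_id,
        ref_count, alt_count."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.sample_ids):
            for j, vid in enumerate(self.snp_ids):
                rows.append((sid, self.depths_m[i], vid,
                             int(self.ref[i, j]), int(self.alt[i, j])))
        return pd.DataFrame(
            rows, columns=["sample_id", "depth_m", "snp_id", "ref_count", "alt_count"]
        )

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountMatrix":
        """Read long-format counts (the layout written by :meth:`to_tsv`;
        curated tables with at least sample/SNP/ref/alt columns are
        accepted, a missing depth column yields NaN depths)."""
        df = pd.read_csv(path, sep="\t")
        rename = {"sample": "sample_id", "snp": "snp_id", "SNP": "snp_id"}
        df = df.rename(columns=rename)
        needed = {"sample_id", "snp_id", "ref_count", "alt_count"}
        if not needed.issubset(df.columns):
            raise ValueError(f"count table must contain columns {sorted(needed)}")
        if "depth_m" not in df.columns:
            df["depth_m"] = np.nan
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleCountMatrix":
        samples = list(pd.unique(df.sample_id))
        snps = list(pd.unique(df.snp_id))
        s_idx = {s: i for i, s in enumerate(samples)}
        v_idx = {v: j for j, v in enumerate(snps)}
        ref = np.zeros((len(samples), len(snps)), dtype=np.int64)
        alt = np.zeros_like(ref)
        depths = np.full(len(samples), np.nan)
        for row in df.itertuples(index=False):
            i, j = s_idx[row.sample_id], v_idx[row.snp_id]
            ref[i, j] = row.ref_count
            alt[i, j] = row.alt_count
            depths[i] = row.depth_m
        return cls(ref, alt, samples, snps, depths)


@dataclass
class CountingReport:
    """Per-run accounting of SAM records seen, used and skipped."""

    records_seen: int = 0
    records_used: int = 0
    skipped_flag: int = 0       # unmapped/secondary/supplementary/duplicate
    skipped_mapq: int = 0
    skipped_baseq: int = 0
    skipped_other_allele: int = 0
    skipped_chrom: int = 0
    skipped_malformed: int = 0
    duplicate_fragment: int = 0  # mate-overlap second observations

    def log(self) -> None:
        logger.info(
            "allele counting: %d records seen, %d used; skipped %d flagged, "
            "%d low MAPQ, %d low BQ, %d third-allele, %d off-panel chrom, "
            "%d malformed; %d mate-overlap duplicates collapsed",
            self.records_seen, self.records_used, self.skipped_flag,
            self.skipped_mapq, self.skipped_baseq, self.skipped_other_allele,
            self.skipped_chrom, self.duplicate_fragment,
            self.skipped_malformed,
        )


def _iter_sam(source):
    """Yield pysam AlignedSegment records from a path or an iterable."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
            yield from fh
    else:
        yield from source


def count_alleles(
    sam_source,
    panel: SnpPanel,
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
    sample_depths: dict | None = None,
    report: CountingReport | None = None,
) -> AlleleCountMatrix:
    """Count reference/alternate reads at every panel SNP.

    Each mapped record overlapping a panel SNP contributes at most one
    count there: the aligned base (via the CIGAR) is compared to the
    panel ref/alt alleles; third alleles and deletions spanning the SNP
    are ignored, as are records failing the MAPQ floor or flagged
    unmapped/secondary/supplementary/duplicate.  Overlapping mates of one
    fragment (same query name) are counted once per SNP.  Sample identity
    comes from the record's RG tag ("sample1" when absent);
    ``sample_depths`` maps sample id -> water depth in metres.

    Parameters mirror common allele-specific counting practice; the
    quality floors default to 20 and may be lowered to 0 for lossless
    round-trips of synthetic reads.
    """
    rep = report if report is not None else CountingReport()
    snp_ids = panel.snp_ids
    v_idx = {v: j for j, v in enumerate(snp_ids)}
    # chrom -> {0-based ref pos -> (snp_index, ref_base, alt_base)}
    lookup: dict = {}
    for row in panel.table.itertuples(index=False):
        lookup.setdefault(row.chrom, {})[row.pos - 1] = (
            v_idx[row.snp_id], row.ref_allele, row.alt_allele
        )

    counts: dict = {}          # sample -> (ref_vec, alt_vec)
    seen_fragments: set = set()  # (sample, qname, snp_index)

    def vectors(sample):
        if sample not in counts:
            counts[sample] = (
                np.zeros(len(snp_ids), dtype=np.int64),
                np.zeros(len(snp_ids), dtype=np.int64),
            )
        return counts[sample]

    for rec in _iter_sam(sam_source):
        rep.records_seen += 1
        try:
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or rec.is_duplicate):
                rep.skipped_flag += 1
                continue
            if rec.mapping_quality < min_mapping_quality:
                rep.skipped_mapq += 1
                continue
            chrom = rec.reference_name
            if chrom not in lookup:
                rep.skipped_chrom += 1
                continue
            positions = lookup[chrom]
            sample = rec.get_tag("RG") if rec.has_tag("RG") else "sample1"
            seq = rec.query_sequence
            quals = rec.query_qualities
            used = False
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                hit = positions.get(rpos)
                if hit is None:
                    continue
                j, ref_base, alt_base = hit
                if quals is not None and quals[qpos] < min_base_quality:
                    rep.skipped_baseq += 1
                    continue
                base = seq[qpos].upper()
                if base == ref_base:
                    which = 0
                elif base == alt_base:
                    which = 1
                else:
                    rep.skipped_other_allele += 1
                    continue
                key = (sample, rec.query_name, j)
                if key in seen_fragments:
                    rep.duplicate_fragment += 1
                    continue
                seen_fragments.add(key)
                vectors(sample)[which][j] += 1
                used = True
            if used:
                rep.records_used += 1
        except Exception as exc:  # malformed record: warn and move on
            rep.skipped_malformed += 1
            logger.warning("skipping malformed record: %s", exc)

    rep.log()
    samples = sorted(counts)
    if not samples:
        samples = []
    n_v = len(snp_ids)
    ref = np.zeros((len(samples), n_v), dtype=np.int64)
    alt = np.zeros_like(ref)
    for i, s in enumerate(samples):
        ref[i], alt[i] = counts[s]
    depths = np.array(
        [sample_depths.get(s, np.nan) if sample_depths else np.nan for s in samples]
    )
    return AlleleCountMatrix(ref, alt, samples, list(snp_ids), depths)


def locate_snps(counts: AlleleCountMatrix) -> list:
    """SNPs observed (total depth > 0) in at least one sample."""
    total = counts.total().sum(axis=0)
    return [v for v, t in zip(counts.snp_ids, total) if t > 0]


def variable_snps(counts: AlleleCountMatrix) -> list:
    """SNPs where both alleles are seen at least once across all samples."""
    ref_tot = counts.ref.sum(axis=0)
    alt_tot = counts.alt.sum(axis=0)
    return [
        v for v, r, a in zip(counts.snp_ids, ref_tot, alt_tot) if r > 0 and a > 0
    ]


def filter_esnps(
    counts: AlleleCountMatrix,
    min_fraction_present: float = 0.75,
    min_depth: int = 1,
) -> AlleleCountMatrix:
    """Restrict to SNPs present in >= ceil(fraction x n_samples) samples.

    "Present" means cell total depth >= ``min_depth`` (default one read:
    the filter acts on representation, not coverage).  With 16 samples
    and the default 0.75 the threshold is 12 samples.
    """
    if counts.n_samples == 0:
        raise ValueError("cannot filter an empty sample set")
    if not (0 <= min_fraction_present <= 1):
        raise ValueError("min_fraction_present must be in [0, 1]")
    threshold = math.ceil(min_fraction_present * counts.n_samples)
    n_present = counts.present(min_depth).sum(axis=0)
    keep = [v for v, n in zip(counts.snp_ids, n_present) if n >= threshold]
    logger.info(
        "presence filter: %d of %d SNPs present in >= %d of %d samples",
        len(keep), counts.n_snps, threshold, counts.n_samples,
    )
    return counts.subset_snps(keep)
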