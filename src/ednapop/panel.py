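"""Target SNP panel: amplified loci, SNP positions and ref/alt alleles.

The panel is the set of biallelic SNPs assayed from eDNA by amplicon
sequencing.  SNPs nest within amplified loci (several SNPs may share one
amplicon).  SNP positions are held 1-based (VCF convention); amplicon
intervals are 0-based half-open (BED convention) and converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_BASES = ("A", "C", "G", "T")


@dataclass
class SnpPanel:
    """Table of panel SNPs.

    ``table`` columns: snp_id, chrom, pos (1-based), ref_allele,
    alt_allele, locus_id, amp_start, amp_end (0-based half-open).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {
            "snp_id", "chrom", "pos", "ref_allele", "alt_allele",
            "locus_id", "amp_start", "amp_end",
        }
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        if (t.ref_allele == t.alt_allele).any():
            bad = t.loc[t.ref_allele == t.alt_allele, "snp_id"].iloc[0]
            raise ValueError(f"ref and alt alleles identical at {bad}")
        bad_alleles = ~(t.ref_allele.isin(_BASES) & t.alt_allele.isin(_BASES))
        if bad_alleles.any():
            raise ValueError("alleles must be single bases A/C/G/T")
        inside = (t.pos - 1 >= t.amp_start) & (t.pos - 1 < t.amp_end)
        if not inside.all():
            bad = t.loc[~inside, "snp_id"].iloc[0]
            raise ValueError(f"SNP {bad} lies outside its amplicon interval")
        if t.snp_id.duplicated().any():
            raise ValueError("duplicate snp_id in panel")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list:
        return list(self.table.snp_id)

    @property
    def n_loci(self) -> int:
        return self.table.locus_id.nunique()

    def amplicon_lengths(self) -> pd.Series:
        """Length (bp) of each distinct amplified locus."""
        loci = self.table.drop_duplicates("locus_id")
        return (loci.amp_end - loci.amp_start).set_axis(loci.locus_id)

    def mean_amplicon_length(self) -> float:
        """Mean amplicon length across loci (panel design summary)."""
        return float(self.amplicon_lengths().mean())

    # ---------------------------------------------------------------- I/O

    def to_bed(self, path) -> None:
        """Write amplicon intervals as BED (0-based half-open), one row
        per locus, name = locus_id."""
        loci = self.table.drop_duplicates("locus_id")
        loci[["chrom", "amp_start", "amp_end", "locus_id"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def to_allele_tsv(self, path) -> None:
        """Write the per-SNP allele annotation table (positions 1-based)."""
        cols = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele", "locus_id"]
        self.table[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_bed_and_alleles(cls, bed_path, allele_path) -> "SnpPanel":
        """Assemble a panel from a locus BED file and a SNP allele TSV.

        The BED gives amplicon intervals keyed by locus_id; the TSV gives
        snp_id, chrom, pos (1-based), ref_allele, alt_allele, locus_id.
        """
        bed = pd.read_csv(
            bed_path, sep="\t", header=None,
            names=["chrom", "amp_start", "amp_end", "locus_id"],
            dtype={"chrom": str, "locus_id": str},
        )
        alleles = pd.read_csv(allele_path, sep="\t", dtype={"chrom": str, "locus_id": str})
        merged = alleles.merge(
            bed[["locus_id", "amp_start", "amp_end"]], on="locus_id", how="left",
            validate="many_to_one",
        )
        if merged.amp_start.isna().any():
            orphan = merged.loc[merged.amp_start.isna(), "snp_id"].iloc[0]
            raise ValueError(f"SNP {orphan} references a locus absent from the BED file")
        merged["amp_start"] = merged.amp_start.astype(int)
        merged["amp_end"] = merged.amp_end.astype(int)
        return cls(merged)

    def reference_lengths(self) -> dict:
        """Per-chromosome reference length implied by the panel (for SAM
        headers): the furthest amplicon end plus margin."""
        ends = self.table.groupby("chrom").amp_end.max()
        return {c: int(e) + 100 for c, e in ends.items()}


def synthetic_panel(
    n_snps: int = 120,
    n_loci: int = 98,
    amplicon_length: int = 85,
    locus_spacing: int = 5000,
    chrom: str = "chr1",
    seed: int = 0,
) -> SnpPanel:
    """Build a synthetic amplicon panel with SNPs nested in loci.

    Loci are evenly spaced intervals of ``amplicon_length`` bp; the first
    ``n_snps - n_loci`` loci carry two SNPs, the rest one, mirroring a
    design where some amplicons tag more than one SNP.  SNP offsets
    within the amplicon are drawn away from the read edges.
    """
    if n_loci > n_snps:
        raise ValueError("n_loci cannot exceed n_snps")
    rng = np.random.default_rng(seed)
    extra = n_snps - n_loci
    rows = []
    snp_idx = 0
    for i in range(n_loci):
        start = 1000 + i * locus_spacing
        end = start + amplicon_length
        n_here = 2 if i < extra else 1
        offsets = rng.choice(
            np.arange(5, amplicon_length - 5), size=n_here, replace=False
        )
        for off in sorted(offsets):
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            rows.append(
                dict(
                    snp_id=f"snp{snp_idx:04d}",
                    chrom=chrom,
                    pos=start + int(off) + 1,  # 1-based
                    ref_allele=ref,
                    alt_allele=alt,
                    locus_id=f"locus{i:03d}",
                    amp_start=start,
                    amp_end=end,
                )
            )
            snp_idx += 1
    return SnpPanel(pd.DataFrame(rows))
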