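"""Readers and writers for the pipeline's exchange formats.

Genotypes travel as minimal VCF v4.2 (GT only, dosage = count of
reference alleles, "." meaning missing); frequency tables, counts and
truth as TSV.  SAM is handled in :mod:`ednapop.counting` /
:mod:`ednapop.simulate` via pysam.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .structure import GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_frequency_table",
    "read_frequency_table",
    "write_truth",
]

_GT_BY_DOSAGE = {2: "0/0", 1: "0/1", 0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path, panel=None) -> None:
    """Write dosages as a minimal VCF v4.2 with GT fields.

    Dosage counts reference alleles, so 2 -> 0/0, 1 -> 0/1, 0 -> 1/1 and
    missing -> ./.; chrom/pos/alleles come from the panel when supplied,
    otherwise synthetic coordinates are emitted (one SNP per kb on
    chr1, A/T).
    """
    if panel is not None:
        t = panel.table.set_index("snp_id")
    lines = ['##fileformat=VCFv4.2',
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    records = []
    contig_max: dict = {}
    for j, snp in enumerate(genotypes.snp_ids):
        if panel is not None and snp in t.index:
            row = t.loc[snp]
            chrom, pos, ref, alt = row.chrom, int(row.pos), row.ref_allele, row.alt_allele
        else:
            chrom, pos, ref, alt = "chr1", 1000 * (j + 1), "A", "T"
        contig_max[chrom] = max(contig_max.get(chrom, 0), pos)
        gts = []
        for d in genotypes.dosages[:, j]:
            gts.append("./." if np.isnan(d) else _GT_BY_DOSAGE[int(d)])
        records.append(
            "\t".join([str(chrom), str(pos), snp, ref, alt, ".", "PASS", ".", "GT"] + gts)
        )
    for chrom, mx in contig_max.items():
        lines.append(f"##contig=<ID={chrom},length={mx + 1000}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(i) for i in genotypes.individual_ids)
    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines + records) + "\n")


def read_vcf(path, strata: dict | None = None) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (GT parsed; phased or unphased;
    "." -> missing).  ``strata`` maps individual id -> depth-stratum
    label; unknown individuals get the label "unknown"."""
    strata = strata or {}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        snp_ids, chrom, pos, rows = [], [], [], []
        for rec in vf:
            snp_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            dos = []
            for s in samples:
                alleles = rec.samples[s]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    dos.append(np.nan)
                else:
                    dos.append(sum(1 for a in alleles if a == 0))
            rows.append(dos)
    dosages = np.asarray(rows, dtype=float).T
    labels = [strata.get(s, "unknown") for s in samples]
    order = np.lexsort((np.asarray(pos), np.asarray(chrom)))
    return GenotypeMatrix(
        dosages[:, order], samples, [snp_ids[i] for i in order], labels,
        np.asarray(chrom)[order], np.asarray(pos)[order],
    )


def write_frequency_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="row_id")


def read_frequency_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="row_id")


def write_truth(truth, path_prefix) -> None:
    """Write a TruthBundle as TSVs: population frequencies, per-fish q
    and the pooled expected frequencies."""
    p1, p2 = truth.pop_freqs
    n = len(p1)
    pd.DataFrame(
        {"snp_id": [f"snp{j:04d}" for j in range(n)], "p_shallow": p1, "p_deep": p2}
    ).to_csv(f"{path_prefix}.pop_freqs.tsv", sep="\t", index=False)
    if truth.true_q.size:
        pd.DataFrame({"true_q": truth.true_q}).to_csv(
            f"{path_prefix}.true_q.tsv", sep="\t", index_label="fish_index"
        )
    if truth.pooled_freq.size:
        pd.DataFrame(
            truth.pooled_freq, columns=[f"snp{j:04d}" for j in range(n)]
        ).to_csv(f"{path_prefix}.pooled_freq.tsv", sep="\t", index_label="sample_index")
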