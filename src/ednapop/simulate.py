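"""Synthetic stratified-lake data generator.

Emulates the study conditions the analysis assumes: two source
populations diverged at a chosen Fst (Balding-Nichols model), a fish
ancestry cline that is logistic in depth with its midpoint at the
thermo-oxycline, pooled eDNA read counts per sampling depth with
Poisson coverage, dropout and beta-binomial overdispersion, a
depth-structured microbial order-count matrix, and SAM text reads that
let the allele-counting stage be exercised end to end.

Every generator takes an explicit seed and draws from its own
`numpy.random.Generator`; no global random state is touched, and equal
seeds give byte-identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counting import AlleleCountMatrix
from .panel import SnpPanel
from .scenario import (
    FISH_STRATA,
    STRATUM_MIDPOINTS,
    LakeScenario,
    TruthBundle,
    logistic_cline,
)
from .structure import GenotypeMatrix

__all__ = [
    "simulate_divergent_pops",
    "simulate_fish",
    "simulate_edna_counts",
    "simulate_microbial",
    "write_sam_reads",
    "simulate_scenario",
]


def simulate_divergent_pops(n_snps: int, fst: float, seed: int = 0):
    """Draw per-SNP reference-allele frequencies for two populations
    diverged at the given Fst.

    The ancestral frequency p is uniform on [0.05, 0.95]; each
    population's frequency is Balding-Nichols,
    Beta(p (1 - F) / F, (1 - p)(1 - F) / F), so the between-population
    variance at a SNP is F p (1 - p).
    """
    if not (0 < fst < 1):
        raise ValueError(f"fst must be in (0, 1), got {fst}")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    scale = (1.0 - fst) / fst
    a, b = p_anc * scale, (1.0 - p_anc) * scale
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)
    return p1, p2


def simulate_fish(
    pop_freqs,
    fish_per_stratum,
    cline_midpoint_m: float = 15.0,
    cline_steepness_m: float = 1.5,
    seed: int = 0,
    strata=FISH_STRATA,
):
    """Simulate per-fish genotypes along the depth cline.

    Each fish in a stratum gets the cline ancestry q evaluated at the
    stratum midpoint; its dosage at SNP l is Binomial(2, q p1_l +
    (1 - q) p2_l) (dosage = count of reference alleles).  Returns the
    GenotypeMatrix and the per-fish true q.
    """
    p1, p2 = (np.asarray(p, dtype=float) for p in pop_freqs)
    fish_per_stratum = list(fish_per_stratum)
    if len(fish_per_stratum) != len(strata) or not strata:
        raise ValueError("fish_per_stratum must give a positive count per stratum")
    if any(n <= 0 for n in fish_per_stratum):
        raise ValueError("empty stratum: fish_per_stratum entries must be positive")
    rng = np.random.default_rng(seed)
    n_snps = len(p1)
    ids, labels, qs = [], [], []
    for stratum, n_fish in zip(strata, fish_per_stratum):
        q = logistic_cline(STRATUM_MIDPOINTS[stratum], cline_midpoint_m, cline_steepness_m)
        for i in range(n_fish):
            ids.append(f"fish_{stratum}_{i:03d}")
            labels.append(stratum)
            qs.append(q)
    qs = np.asarray(qs)
    freq = qs[:, None] * p1[None, :] + (1 - qs)[:, None] * p2[None, :]
    dosages = rng.binomial(2, freq).astype(float)
    snp_ids = [f"snp{j:04d}" for j in range(n_snps)]
    gm = GenotypeMatrix(dosages, ids, snp_ids, labels)
    return gm, qs


def _pooled_frequencies(scenario: LakeScenario, p1, p2):
    """Expected reference-allele frequency per eDNA sample x SNP.

    The local pooled frequency at depth d is the cline mixture
    q(d) p1 + (1 - q(d)) p2 evaluated at the midpoint of the fish
    stratum the depth maps to; vertical transport mixes in the
    opposite-side frequency with weight tau.  Because the logistic cline
    is symmetric about its midpoint, the opposite-side frequency is the
    cline at the reflected depth, so mixing reduces to the effective
    ancestry weight q' = (1 - tau) q + tau (1 - q).
    """
    from .scenario import DEFAULT_STRATUM_MAP

    depths = scenario.sample_depths()
    mids = np.array([STRATUM_MIDPOINTS[DEFAULT_STRATUM_MAP[d]] for d in depths])
    q = logistic_cline(mids, scenario.cline_midpoint_m, scenario.cline_steepness_m)
    q_eff = (1 - scenario.mixing_tau) * q + scenario.mixing_tau * (1 - q)
    return q_eff[:, None] * p1[None, :] + (1 - q_eff)[:, None] * p2[None, :]


def simulate_edna_counts(truth: TruthBundle, scenario: LakeScenario | None = None):
    """Simulate the eDNA allele-count matrix for a scenario.

    Per sample x SNP cell: read depth ~ Poisson(mean_depth_per_snp),
    zeroed with probability dropout_rate; given depth n and pooled
    frequency f, ref_count ~ BetaBinomial(n, f, rho) with intra-class
    correlation rho standing in for PCR distortion (rho = 0 reduces to
    binomial).  Records the analytic pooled frequency in the returned
    TruthBundle.
    """
    scenario = scenario or truth.scenario
    p1, p2 = truth.pop_freqs
    rng = np.random.default_rng(scenario.seed + 2)
    pooled = _pooled_frequencies(scenario, np.asarray(p1), np.asarray(p2))
    n_samples, n_snps = pooled.shape
    depth = rng.poisson(scenario.mean_depth_per_snp, size=pooled.shape)
    if scenario.dropout_rate > 0:
        depth[rng.random(pooled.shape) < scenario.dropout_rate] = 0
    rho = scenario.overdispersion_rho
    if rho > 0:
        s = (1.0 - rho) / rho
        a = np.clip(pooled * s, 1e-12, None)
        b = np.clip((1.0 - pooled) * s, 1e-12, None)
        p_cell = rng.beta(a, b)
        # degenerate frequencies stay degenerate
        p_cell = np.where(pooled <= 0, 0.0, np.where(pooled >= 1, 1.0, p_cell))
    else:
        p_cell = pooled
    ref = rng.binomial(depth, p_cell)
    alt = depth - ref

    depths = scenario.sample_depths()
    per_depth_counter: dict = {}
    sample_ids = []
    for d in depths:
        k = per_depth_counter.get(d, 0)
        per_depth_counter[d] = k + 1
        sample_ids.append(f"edna_{int(d):02d}m_{k}")
    snp_ids = [f"snp{j:04d}" for j in range(n_snps)]
    acm = AlleleCountMatrix(ref, alt, sample_ids, snp_ids, depths)
    truth.pooled_freq = pooled
    truth.validate()
    return acm, pooled


def simulate_microbial(
    depths,
    n_orders: int = 30,
    gradient_sharpness: float = 2.0,
    total_reads: int = 20000,
    seed: int = 0,
    midpoint_m: float = 15.0,
    concentration: float = 0.5,
):
    """Simulate an order-level microbial count matrix along depth.

    Two community profiles (shallow, deep) are drawn from a symmetric
    Dirichlet; the expected profile of a sample at depth d mixes them by
    the logistic weight w(d) = 1 / (1 + exp(s (d - 15))), with
    ``gradient_sharpness`` s per metre (s = 0 makes all samples share
    one expected profile).  Counts are multinomial with ``total_reads``
    reads per sample.  Returns a DataFrame (samples x orders) and a
    metadata DataFrame with depth_m.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size < 2:
        raise ValueError("need >= 2 depths")
    if n_orders < 2:
        raise ValueError("n_orders must be >= 2")
    rng = np.random.default_rng(seed)
    shallow = rng.dirichlet(np.full(n_orders, concentration))
    deep = rng.dirichlet(np.full(n_orders, concentration))
    w = 1.0 / (1.0 + np.exp(gradient_sharpness * (depths - midpoint_m)))
    profiles = w[:, None] * shallow[None, :] + (1 - w)[:, None] * deep[None, :]
    counts = np.vstack([rng.multinomial(total_reads, p) for p in profiles])
    sample_ids = [f"ont_{int(d):02d}m_{i}" for i, d in enumerate(depths)]
    orders = [f"order{j:02d}" for j in range(n_orders)]
    community = pd.DataFrame(counts, index=sample_ids, columns=orders)
    meta = pd.DataFrame({"sample_id": sample_ids, "depth_m": depths}).set_index("sample_id")
    return community, meta


# ------------------------------------------------------------- SAM output

_OTHER_BASE = {"A": "C", "C": "A", "G": "T", "T": "G"}


def write_sam_reads(
    counts: AlleleCountMatrix,
    panel: SnpPanel,
    path,
    read_length: int | None = None,
    indel_fraction: float = 0.0,
    seed: int = 0,
) -> None:
    """Materialize an allele-count matrix as mapped single-end SAM reads.

    One record per counted allele observation: the read starts at its
    amplicon start, spans ``read_length`` bases, and carries the sampled
    allele at the SNP offset.  By default every CIGAR is all-match; a
    fraction of reads instead carries a benign leading soft-clip and an
    insertion, exercising CIGAR walking without changing the aligned
    bases.  Sample identity is recorded in per-sample read groups.
    """
    rng = np.random.default_rng(seed)
    t = panel.table.set_index("snp_id")
    # per-chrom SNP registry so sibling SNPs inside a read span can be
    # masked with a third allele (the counter must ignore them)
    by_chrom: dict = {}
    for vid, row in t.iterrows():
        neither = next(b for b in "ACGT" if b not in (row.ref_allele, row.alt_allele))
        by_chrom.setdefault(row.chrom, []).append((int(row.pos - 1), vid, neither))
    max_off = int((t.pos - 1 - t.amp_start).max()) if len(t) else 0
    if read_length is None:
        read_length = max(75, max_off + 6)  # default spans every SNP offset
    if read_length <= max_off:
        raise ValueError(
            f"read_length {read_length} cannot reach SNP offset {max_off} in its amplicon"
        )
    lengths = panel.reference_lengths()
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, ln in lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{ln + read_length}")
    for sid in counts.sample_ids:
        lines.append(f"@RG\tID:{sid}\tSM:{sid}")

    rid = 0
    for i, sid in enumerate(counts.sample_ids):
        for j, vid in enumerate(counts.snp_ids):
            row = t.loc[vid]
            offset = int(row.pos - 1 - row.amp_start)
            start0 = int(row.amp_start)
            fill = _OTHER_BASE[row.ref_allele]
            for allele, n_reads in ((row.ref_allele, counts.ref[i, j]),
                                    (row.alt_allele, counts.alt[i, j])):
                for _ in range(int(n_reads)):
                    seq = [fill] * read_length
                    for pos0, other_id, neither in by_chrom[row.chrom]:
                        if other_id != vid and start0 <= pos0 < start0 + read_length:
                            seq[pos0 - start0] = neither
                    seq[offset] = allele
                    seq = "".join(seq)
                    cigar = f"{read_length}M"
                    pos1 = start0 + 1
                    if indel_fraction > 0 and rng.random() < indel_fraction:
                        # 2S prefix + 1-base insertion after the SNP: the
                        # aligned reference span and SNP base are unchanged
                        seq = "NN" + seq[: offset + 1] + "N" + seq[offset + 1:]
                        cigar = f"2S{offset + 1}M1I{read_length - offset - 1}M"
                    qual = "I" * len(seq)
                    lines.append(
                        "\t".join([
                            f"read{rid:07d}", "0", str(row.chrom), str(pos1),
                            "60", cigar, "*", "0", "0", seq, qual, f"RG:Z:{sid}",
                        ])
                    )
                    rid += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def simulate_scenario(scenario: LakeScenario):
    """Run the full generator chain for one scenario.

    Returns (genotypes, edna_counts, truth): fish genotypes with
    per-stratum labels, the eDNA allele-count matrix, and the truth
    bundle holding population frequencies, per-fish q and the analytic
    pooled frequencies.
    """
    p1, p2 = simulate_divergent_pops(scenario.n_snps, scenario.fst, scenario.seed)
    truth = TruthBundle(scenario=scenario, pop_freqs=(p1, p2))
    genotypes, true_q = simulate_fish(
        (p1, p2), scenario.fish_per_stratum,
        scenario.cline_midpoint_m, scenario.cline_steepness_m,
        seed=scenario.seed + 1,
    )
    truth.true_q = true_q
    counts, _ = simulate_edna_counts(truth, scenario)
    return genotypes, counts, truth
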