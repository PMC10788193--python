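"""End-to-end orchestration of the two analyses.

``run_edna_popgen`` chains the fish-structure correspondence analysis:
allele counting (or a pre-curated count table) -> located / variable /
presence-filtered eSNPs -> per-sample and per-stratum frequencies ->
per-depth correspondence tests -> shallow-to-deep shift correlation ->
PCA of the eDNA frequency matrix, optionally followed by admixture on
tissue genotypes and pooled-ancestry estimates per eDNA sample.
``run_microbial`` chains community aggregation -> CCA -> permutation
ANOVA.  Every stage's output is written under the run directory along
with a JSON summary; reruns with the same config and seed are
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import counting, frequencies, io, simulate, structure
from .cca import permutation_anova
from .counting import AlleleCountMatrix
from .panel import SnpPanel
from .scenario import DEFAULT_STRATUM_MAP, LakeScenario

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_edna_popgen", "run_microbial", "simulate_to_dir"]


@dataclasses.dataclass
class RunConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    outdir: str = "run"
    counts_tsv: str | None = None
    sam: str | None = None
    panel_bed: str | None = None
    panel_alleles: str | None = None
    vcf: str | None = None
    strata_tsv: str | None = None      # individual_id -> depth-stratum label
    community_tsv: str | None = None
    meta_tsv: str | None = None
    min_fraction_present: float = 0.75
    min_presence_depth: int = 1
    min_base_quality: int = 20
    min_mapping_quality: int = 20
    ld_window_kb: float = 50.0
    ld_step: int = 10
    ld_r2_threshold: float = 0.1
    K: int = 2
    n_perm: int = 10000
    seed: int = 0
    run_admixture: bool = False
    stratum_map: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_STRATUM_MAP)
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stratum_map" in raw:
            raw["stratum_map"] = {float(k): v for k, v in raw["stratum_map"].items()}
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("counts_tsv", "sam", "panel_bed", "panel_alleles",
                     "vcf", "strata_tsv", "community_tsv", "meta_tsv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    def fingerprint(self) -> str:
        """Stable digest of the analysis parameters (paths excluded, so
        the same inputs staged anywhere give the same provenance tag)."""
        import hashlib

        d = dataclasses.asdict(self)
        for key in ("outdir", "counts_tsv", "sam", "panel_bed", "panel_alleles",
                    "vcf", "strata_tsv", "community_tsv", "meta_tsv"):
            d.pop(key, None)
        digest = hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        return f"seed={self.seed} config_hash={digest}"


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_edna_popgen(config: RunConfig, genotypes=None, counts=None):
    """Run the eDNA population-genetics analysis; returns the summary dict.

    Inputs may be passed in memory (``genotypes``, ``counts``) or via the
    config's paths.  All intermediates plus ``summary.json`` are written
    under ``config.outdir``.
    """
    config.validate_paths()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"fingerprint": config.fingerprint(), "seed": config.seed}

    # --- counts
    if counts is None:
        if config.counts_tsv:
            _stage("load counts")
            counts = AlleleCountMatrix.from_tsv(config.counts_tsv)
        elif config.sam and config.panel_bed and config.panel_alleles:
            _stage("count alleles from SAM")
            panel = SnpPanel.from_bed_and_alleles(config.panel_bed, config.panel_alleles)
            counts = counting.count_alleles(
                config.sam, panel,
                min_base_quality=config.min_base_quality,
                min_mapping_quality=config.min_mapping_quality,
            )
        else:
            raise ValueError("no counts: provide counts_tsv or sam+panel paths")
    counts.to_tsv(out / "counts.tsv")

    # --- filter cascade
    _stage("filter cascade")
    located = counting.locate_snps(counts)
    located_counts = counts.subset_snps(located)
    variable = counting.variable_snps(located_counts)
    variable_counts = located_counts.subset_snps(variable)
    esnps = counting.filter_esnps(
        variable_counts, config.min_fraction_present, config.min_presence_depth
    )
    summary["n_panel"] = counts.n_snps
    summary["n_located"] = len(located)
    summary["n_variable"] = len(variable)
    summary["n_esnp"] = esnps.n_snps
    logger.info(
        "filter cascade: %d panel -> %d located -> %d variable -> %d eSNPs",
        counts.n_snps, len(located), len(variable), esnps.n_snps,
    )

    # --- frequencies
    _stage("allele frequencies")
    per_sample = frequencies.sample_allele_freq(esnps)
    edna_strata = frequencies.stratum_mean_freq(per_sample, config.stratum_map)
    io.write_frequency_table(per_sample, out / "freq_per_sample.tsv")
    io.write_frequency_table(edna_strata, out / "freq_per_stratum.tsv")

    # --- tissue side
    if genotypes is None and config.vcf:
        _stage("load genotypes")
        strata = None
        if config.strata_tsv:
            st = pd.read_csv(config.strata_tsv, sep="\t", dtype=str)
            strata = dict(zip(st.individual_id, st.stratum))
        genotypes = io.read_vcf(config.vcf, strata=strata)
    if genotypes is not None:
        wgs = frequencies.wgs_stratum_freq(genotypes)
        io.write_frequency_table(wgs, out / "freq_wgs_stratum.tsv")
        _stage("depth correspondence")
        per_depth = frequencies.depth_correspondence(edna_strata, wgs)
        summary["correspondence"] = {
            s: {"r": c.r, "df": c.df, "t": c.t, "p": c.p_two_sided}
            for s, c in per_depth.items()
        }
        if {"0-5", "20-25"} <= set(wgs.index):
            _stage("frequency shift")
            shift = frequencies.shift_correlation(edna_strata, wgs)
            summary["shift"] = {
                "r": shift.r, "n": shift.n_pairs, "t": shift.t, "p": shift.p_two_sided
            }
            pd.DataFrame({
                "delta_edna": frequencies.frequency_shift(edna_strata),
                "delta_wgs": frequencies.frequency_shift(wgs),
            }).to_csv(out / "shift_scatter.tsv", sep="\t", index_label="snp_id")
        else:
            logger.warning(
                "tissue table lacks labelled shallow/deep strata: shift skipped"
            )

    # --- PCA of eDNA samples
    _stage("PCA")
    pca = structure.pca_missing(per_sample.to_numpy(dtype=float), n_components=2)
    scores = pd.DataFrame(
        pca.scores, index=per_sample.index, columns=["PC1", "PC2"],
    )
    scores["depth_m"] = [per_sample.attrs["depth_m"][s] for s in per_sample.index]
    scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
    summary["pca_explained_variance"] = [float(v) for v in pca.explained_variance]

    # --- optional admixture on tissue genotypes
    if genotypes is not None and config.run_admixture:
        _stage("admixture")
        snp_subset = genotypes
        if genotypes.pos is not None:
            kept = structure.ld_prune(
                genotypes, config.ld_window_kb, config.ld_step, config.ld_r2_threshold
            )
            summary["n_after_ld_prune"] = len(kept)
            snp_subset = genotypes.subset_snps(kept)
        est = structure.admixture_em(snp_subset, K=config.K, seed=config.seed)
        qdf = pd.DataFrame(
            est.Q, index=genotypes.individual_ids,
            columns=[f"Q{k + 1}" for k in range(config.K)],
        )
        qdf["stratum"] = genotypes.strata
        qdf.to_csv(out / "admixture_Q.tsv", sep="\t", index_label="individual_id")
        np.savetxt(out / "admixture_loglik_trace.tsv", est.loglik_trace)
        summary["admixture"] = {
            "converged": bool(est.converged), "n_iter": int(est.n_iter),
            "final_loglik": float(est.loglik_trace[-1]),
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def run_microbial(config: RunConfig, community=None, meta=None):
    """Run the microbial-gradient analysis; returns the summary dict."""
    config.validate_paths()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if community is None:
        community = pd.read_csv(config.community_tsv, sep="\t", index_col=0)
    if meta is None:
        meta = pd.read_csv(config.meta_tsv, sep="\t", index_col=0)
    depths = meta.loc[community.index, "depth_m"].to_numpy(dtype=float)
    if np.unique(depths).size < 2:
        raise ValueError(
            "depth constraint is constant across samples (rank deficient): "
            "provide samples from at least two depths"
        )
    _stage("CCA + permutation ANOVA")
    res = permutation_anova(
        community, depths[:, None], n_perm=config.n_perm, seed=config.seed
    )
    axis1 = pd.DataFrame({
        "depth_m": depths,
        "cca1": res.site_scores[:, 0],
        "cca1_wa": res.site_scores_wa[:, 0],
    }, index=community.index)
    axis1.to_csv(out / "cca_axis1_vs_depth.tsv", sep="\t", index_label="sample_id")

    # order proportions by depth zone (surface / mid / deep)
    zone = np.where(depths <= 5, "surface", np.where(depths < 20, "mid", "deep"))
    props = community.div(community.sum(axis=1), axis=0)
    props.groupby(pd.Series(zone, index=community.index)).mean().to_csv(
        out / "order_proportions_by_zone.tsv", sep="\t", index_label="zone"
    )
    summary = {
        "fingerprint": config.fingerprint(),
        "seed": config.seed,
        "pseudo_F": res.pseudo_F,
        "df": list(res.df),
        "permutation_p": res.permutation_p,
        "n_permutations": res.n_permutations,
        "total_inertia": res.total_inertia,
        "constrained_inertia": res.constrained_inertia,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def simulate_to_dir(scenario: LakeScenario, outdir) -> dict:
    """Generate a full synthetic dataset and write every exchange file
    (panel BED + allele TSV, counts TSV, SAM reads, VCF, microbial
    community + metadata TSVs, truth TSVs)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    from .panel import synthetic_panel

    panel = synthetic_panel(scenario.n_snps, scenario.n_loci, seed=scenario.seed)
    genotypes, counts, truth = simulate.simulate_scenario(scenario)
    panel.to_bed(out / "panel.bed")
    panel.to_allele_tsv(out / "panel_alleles.tsv")
    counts.to_tsv(out / "counts.tsv")
    simulate.write_sam_reads(counts, panel, out / "reads.sam", seed=scenario.seed + 3)
    io.write_vcf(genotypes, out / "genotypes.vcf", panel=panel)
    pd.DataFrame(
        {"individual_id": genotypes.individual_ids, "stratum": genotypes.strata}
    ).to_csv(out / "fish_strata.tsv", sep="\t", index=False)
    community, meta = simulate.simulate_microbial(
        depths=[3, 3, 3, 7, 12, 18, 22, 22, 22], seed=scenario.seed + 4
    )
    community.to_csv(out / "community.tsv", sep="\t", index_label="sample_id")
    meta.to_csv(out / "community_meta.tsv", sep="\t")
    io.write_truth(truth, str(out / "truth"))
    return {
        "outdir": str(out),
        "n_samples": counts.n_samples,
        "n_snps": counts.n_snps,
        "n_fish": genotypes.n_individuals,
    }
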