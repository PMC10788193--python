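"""Scenario description for the synthetic stratified-lake datasets.

A :class:`LakeScenario` bundles every knob of the generative model: two
source populations diverged by a given Fst, an ancestry cline that is
logistic in depth with its midpoint at the thermo-oxycline (~15 m), an
eDNA sampling design over five depths, and a pooled read-count model for
the eDNA samples (Poisson depth with dropout, beta-binomial allele
counts).  A :class:`TruthBundle` records the latent quantities the
generators drew so that recovery tests can compare estimates against
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LakeScenario",
    "TruthBundle",
    "FISH_STRATA",
    "STRATUM_MIDPOINTS",
    "DEFAULT_STRATUM_MAP",
    "logistic_cline",
]

#: Fish-collection depth bands (metres), shallow to deep.
FISH_STRATA = ("0-5", "5-10", "10-15", "15-20", "20-25")

#: Midpoint depth (m) of each fish stratum, used to evaluate the cline.
STRATUM_MIDPOINTS = {
    "0-5": 2.5,
    "5-10": 7.5,
    "10-15": 12.5,
    "15-20": 17.5,
    "20-25": 22.5,
}

#: eDNA sampling depth (m) -> fish depth stratum.
DEFAULT_STRATUM_MAP = {3.0: "0-5", 7.0: "5-10", 12.0: "10-15", 18.0: "15-20", 22.0: "20-25"}


def logistic_cline(depth_m, midpoint_m: float, steepness_m: float):
    """Shallow-population ancestry weight q at a depth.

    q = 1 / (1 + exp((depth - midpoint) / steepness)); q -> 1 well above
    the midpoint and -> 0 well below it.  ``steepness_m`` <= 0 gives the
    step-cline limit (q in {0, 1}, with q = 0.5 exactly at the midpoint).
    """
    depth_m = np.asarray(depth_m, dtype=float)
    if steepness_m <= 0:
        q = np.where(depth_m < midpoint_m, 1.0, 0.0)
        q = np.where(depth_m == midpoint_m, 0.5, q)
        return q if q.ndim else float(q)
    z = (depth_m - midpoint_m) / steepness_m
    q = 1.0 / (1.0 + np.exp(z))
    return q if q.ndim else float(q)


@dataclass(frozen=True)
class LakeScenario:
    """Parameters of the synthetic stratified-lake study.

    Defaults reproduce the study design the package targets: 16 eDNA
    samples over depths {3, 7, 12, 18, 22} m (5/2/2/2/5 per depth),
    ~120 biallelic SNPs spread over 98 amplified loci, and a pooled
    read-count model with moderate overdispersion and dropout.
    """

    n_snps: int = 120
    n_loci: int = 98
    fst: float = 0.3
    cline_midpoint_m: float = 15.0
    cline_steepness_m: float = 1.5
    depths_edna: tuple = (3.0, 7.0, 12.0, 18.0, 22.0)
    samples_per_depth: tuple = (5, 2, 2, 2, 5)
    fish_per_stratum: tuple = (20, 20, 20, 20, 20)
    mixing_tau: float = 0.05
    mean_depth_per_snp: float = 40.0
    overdispersion_rho: float = 0.05
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fst < 1):
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        if not (0 <= self.mixing_tau <= 1):
            raise ValueError(f"mixing_tau must be in [0, 1], got {self.mixing_tau}")
        if not (0 <= self.overdispersion_rho < 1):
            raise ValueError(
                f"overdispersion_rho must be in [0, 1), got {self.overdispersion_rho}"
            )
        if not (0 <= self.dropout_rate <= 1):
            raise ValueError(f"dropout_rate must be in [0, 1], got {self.dropout_rate}")
        for name in ("n_snps", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_loci > self.n_snps:
            raise ValueError("n_loci cannot exceed n_snps (SNPs nest within loci)")
        if self.mean_depth_per_snp <= 0:
            raise ValueError("mean_depth_per_snp must be positive")
        if len(self.depths_edna) != len(self.samples_per_depth):
            raise ValueError("depths_edna and samples_per_depth must align")
        if any(n < 0 for n in self.samples_per_depth):
            raise ValueError("samples_per_depth must be non-negative")
        if any(n <= 0 for n in self.fish_per_stratum):
            raise ValueError("fish_per_stratum must be positive")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_depth))

    def with_(self, **kwargs) -> "LakeScenario":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def sample_depths(self) -> np.ndarray:
        """Depth (m) of each eDNA sample, expanded per the design."""
        return np.repeat(
            np.asarray(self.depths_edna, dtype=float),
            np.asarray(self.samples_per_depth, dtype=int),
        )

    def ancestry_at(self, depth_m) -> np.ndarray:
        """Shallow-side ancestry weight q of the cline at a depth."""
        return logistic_cline(depth_m, self.cline_midpoint_m, self.cline_steepness_m)


@dataclass
class TruthBundle:
    """Latent truth recorded alongside a simulated dataset.

    Attributes
    ----------
    pop_freqs:
        Pair (p1, p2) of per-SNP reference-allele frequencies in the
        shallow and deep source populations.
    true_q:
        Per-fish shallow-ancestry proportion (empty until fish are
        simulated).
    pooled_freq:
        Expected reference-allele frequency per eDNA sample x SNP,
        i.e. the analytic mixture (1 - tau) * f_local + tau * f_opposite.
    """

    scenario: LakeScenario
    pop_freqs: tuple = ()
    true_q: np.ndarray = field(default_factory=lambda: np.empty(0))
    pooled_freq: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def validate(self) -> None:
        if self.pooled_freq.size:
            if np.any(self.pooled_freq < 0) or np.any(self.pooled_freq > 1):
                raise ValueError("pooled_freq outside [0, 1]")
            if self.pooled_freq.shape != (self.scenario.n_samples, self.scenario.n_snps):
                raise ValueError("pooled_freq shape inconsistent with scenario")
        if self.true_q.size and (np.any(self.true_q < 0) or np.any(self.true_q > 1)):
            raise ValueError("true_q outside [0, 1]")
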