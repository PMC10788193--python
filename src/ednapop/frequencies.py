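"""Reference-allele frequency estimation and correspondence statistics.

Frequencies are of the reference allele throughout (the allele matching
the reference genome assembly).  eDNA sampling depths map to
fish-collection depth strata (3 m -> 0-5 m, ..., 22 m -> 20-25 m);
per-stratum eDNA frequencies are the unweighted mean of per-sample
frequencies; tissue (WGS) stratum frequencies come from dosages.  The
correspondence between the two sides is summarized with Pearson
correlations over pairwise-complete SNPs, per depth and for the
shallow-to-deep frequency shift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counting import AlleleCountMatrix
from .scenario import DEFAULT_STRATUM_MAP, FISH_STRATA
from .structure import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "sample_allele_freq",
    "stratum_mean_freq",
    "stratum_pooled_freq",
    "wgs_stratum_freq",
    "pearson_test",
    "t_from_r",
    "depth_correspondence",
    "frequency_shift",
    "shift_correlation",
    "DEFAULT_STRATUM_MAP",
]


@dataclass
class CorrelationResult:
    """Pearson correlation with its t test.

    t = r sqrt(df) / sqrt(1 - r^2) with df = n_pairs - 2; the two-sided
    p comes from the t distribution (regularized incomplete beta).
    """

    r: float
    n_pairs: int
    t: float
    p_two_sided: float

    @property
    def df(self) -> int:
        return self.n_pairs - 2


def t_from_r(r: float, df: int) -> float:
    """t statistic implied by a correlation coefficient and its df."""
    return r * np.sqrt(df) / np.sqrt(1.0 - r * r)


def pearson_test(x, y) -> CorrelationResult:
    """Pearson product-moment correlation over pairwise-complete pairs.

    Raises if fewer than 3 complete pairs remain or either margin has
    zero variance (correlation undefined).  r = 1 in magnitude yields
    t = inf and p = 0 (the degenerate perfect-correlation limit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = min(1.0, max(-1.0, r))
    df = n - 2
    if abs(r) >= 1.0:
        return CorrelationResult(r, n, np.inf if r > 0 else -np.inf, 0.0)
    t = t_from_r(r, df)
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(r, n, float(t), float(p))


# ----------------------------------------------------------- frequency tables


def sample_allele_freq(counts: AlleleCountMatrix) -> pd.DataFrame:
    """Per-sample reference-allele frequencies (samples x SNPs).

    Cell = ref / (ref + alt); zero-depth cells are missing (NaN).
    """
    total = counts.total().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, counts.ref / np.where(total > 0, total, 1), np.nan)
    df = pd.DataFrame(freq, index=counts.sample_ids, columns=counts.snp_ids)
    df.attrs["provenance"] = "eDNA"
    df.attrs["depth_m"] = dict(zip(counts.sample_ids, counts.depths_m))
    return df


def _depth_to_stratum(depth: float, stratum_map: dict) -> str:
    for d, s in stratum_map.items():
        if np.isclose(depth, d):
            return s
    raise KeyError(depth)


def stratum_mean_freq(
    freq_table: pd.DataFrame,
    stratum_map: dict | None = None,
) -> pd.DataFrame:
    """Average per-sample frequencies within each depth stratum.

    The stratum cell is the unweighted mean over non-missing samples,
    missing only when every sample in the stratum is missing.  Every
    sample depth must have a stratum in the map.
    """
    stratum_map = stratum_map or DEFAULT_STRATUM_MAP
    depth_of = freq_table.attrs.get("depth_m", {})
    strata = []
    for sid in freq_table.index:
        d = depth_of.get(sid, np.nan)
        try:
            strata.append(_depth_to_stratum(float(d), stratum_map))
        except KeyError:
            raise ValueError(f"sample {sid} has depth {d} m with no mapped stratum")
    out = freq_table.groupby(pd.Series(strata, index=freq_table.index)).mean()
    order = [s for s in FISH_STRATA if s in out.index]
    out = out.loc[order]
    out.attrs["provenance"] = freq_table.attrs.get("provenance", "eDNA")
    return out


def stratum_pooled_freq(
    counts: AlleleCountMatrix,
    stratum_map: dict | None = None,
) -> pd.DataFrame:
    """Depth-pooled-count alternative to :func:`stratum_mean_freq`:
    sums reads over the stratum's samples before dividing, weighting
    well-covered samples more.  Provided for comparison; diverges from
    the mean-of-frequencies estimator when coverage varies per sample.
    """
    stratum_map = stratum_map or DEFAULT_STRATUM_MAP
    strata = [_depth_to_stratum(float(d), stratum_map) for d in counts.depths_m]
    ref = pd.DataFrame(counts.ref, index=strata, columns=counts.snp_ids).groupby(level=0).sum()
    alt = pd.DataFrame(counts.alt, index=strata, columns=counts.snp_ids).groupby(level=0).sum()
    total = ref + alt
    out = (ref / total.where(total > 0)).loc[[s for s in FISH_STRATA if s in ref.index]]
    out.attrs["provenance"] = "eDNA-pooled"
    return out


def wgs_stratum_freq(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-stratum reference-allele frequencies from tissue dosages:
    sum of dosages over 2 x (non-missing individuals), per stratum."""
    strata = pd.Series(genotypes.strata)
    rows = {}
    for s in pd.unique(strata):
        D = genotypes.dosages[(strata == s).to_numpy()]
        obs = ~np.isnan(D)
        n_called = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.nansum(D, axis=0) / (2.0 * n_called)
        rows[s] = np.where(n_called > 0, f, np.nan)
    out = pd.DataFrame(rows).T
    out.columns = genotypes.snp_ids
    out = out.loc[[s for s in FISH_STRATA if s in out.index]]
    out.attrs["provenance"] = "WGS"
    return out


# ----------------------------------------------------------- correspondence


def depth_correspondence(
    edna_strata: pd.DataFrame,
    wgs_strata: pd.DataFrame,
) -> dict:
    """Per-stratum Pearson tests of eDNA vs tissue allele frequencies.

    Pairs the two stratum frequency tables over shared SNPs, drops
    incomplete pairs, and returns {stratum: CorrelationResult}.  Strata
    absent from either side are skipped with a warning.
    """
    shared_snps = [c for c in edna_strata.columns if c in set(wgs_strata.columns)]
    results = {}
    for s in edna_strata.index:
        if s not in wgs_strata.index:
            warnings.warn(f"stratum {s} absent from the tissue table: skipped")
            continue
        results[s] = pearson_test(
            edna_strata.loc[s, shared_snps].to_numpy(dtype=float),
            wgs_strata.loc[s, shared_snps].to_numpy(dtype=float),
        )
    return results


def frequency_shift(
    freq_table: pd.DataFrame,
    stratum_a: str = "0-5",
    stratum_b: str = "20-25",
) -> pd.Series:
    """Per-SNP frequency shift freq(b) - freq(a) between two strata
    (shallow to deep by default); missing where either side is missing."""
    for s in (stratum_a, stratum_b):
        if s not in freq_table.index:
            raise ValueError(f"stratum {s} absent from the frequency table")
    if stratum_a == stratum_b:
        warnings.warn("identical strata requested: shift is identically zero")
    return freq_table.loc[stratum_b] - freq_table.loc[stratum_a]


def shift_correlation(
    edna_strata: pd.DataFrame,
    wgs_strata: pd.DataFrame,
    stratum_a: str = "0-5",
    stratum_b: str = "20-25",
) -> CorrelationResult:
    """Pearson test of eDNA vs tissue shallow-to-deep frequency shifts."""
    d_edna = frequency_shift(edna_strata, stratum_a, stratum_b)
    d_wgs = frequency_shift(wgs_strata, stratum_a, stratum_b)
    shared = [c for c in d_edna.index if c in set(d_wgs.index)]
    return pearson_test(
        d_edna[shared].to_numpy(dtype=float), d_wgs[shared].to_numpy(dtype=float)
    )
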