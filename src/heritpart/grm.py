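"""Genomic relationship matrices and SNP-based population summaries.

The estimator is the allele-frequency standardised identity-by-state GRM of
Yang et al. / GCTA:

    A_ij = (1/N) sum_z (s_iz - 2 p_z)(s_jz - 2 p_z) / (2 p_z (1 - p_z)),  i != j
    A_ii = 1 + (1/N) sum_z (s_iz^2 - (1 + 2 p_z) s_iz + 2 p_z^2) / (2 p_z (1 - p_z))

with s_iz the count of the reference (counted) allele and p_z its sample
frequency.  Standardising by 2p(1-p) up-weights rare alleles, so pairs that
share rare alleles — typically relatives, identical by descent — score
higher than pairs sharing common alleles.

Derived matrices: relatedness-thresholded ("kinship") GRMs in which
off-diagonal relationships <= t are zeroed, MAF-restricted GRMs built from
low-frequency SNPs only, and chromosome/region-restricted GRMs.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import MonomorphicSNPError, RegionTooSparseError
from .io import GenotypeMatrix

__all__ = [
    "GRM",
    "AlleleFrequencies",
    "allele_frequencies",
    "build_grm",
    "threshold_grm",
    "maf_subset",
    "region_subset",
    "fhat3",
    "relatedness_summary",
]


@dataclasses.dataclass
class AlleleFrequencies:
    """Counted-allele frequencies and non-missing sample counts per SNP."""

    p: np.ndarray
    n_obs: np.ndarray
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")


@dataclasses.dataclass
class GRM:
    """Symmetric realised-relatedness matrix with provenance.

    ``provenance`` is a short label such as ``"full"``,
    ``"thresholded(t=0.05)"``, ``"maf(<0.01)"``, ``"chromosome(3)"`` or
    ``"region(3:100-200+1000000)"``.
    """

    values: np.ndarray
    ids: list[str]
    n_snps_used: int
    provenance: str = "full"
    pair_snp_counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(s) for s in self.ids]
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("GRM shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric to 1e-10")
        if self.n_snps_used < 1:
            raise ValueError("n_snps_used must be >= 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        """Square matrix with id index/columns, for text export."""
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def subset(self, ids: Sequence[str]) -> "GRM":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        counts = None
        if self.pair_snp_counts is not None:
            counts = self.pair_snp_counts[np.ix_(idx, idx)]
        return GRM(self.values[np.ix_(idx, idx)], list(ids), self.n_snps_used,
                   self.provenance, counts)


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """Sample frequency of the counted allele at each SNP.

    ``p_z = (sum of non-missing dosages at z) / (2 * n_obs_z)``.
    """
    obs = ~np.isnan(g.dosages)
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        bad = g.snps.loc[n_obs == 0, "snp_id"].tolist()
        raise ValueError(f"SNPs with no non-missing calls: {bad}")
    p = np.nansum(g.dosages, axis=0) / (2.0 * n_obs)
    return AlleleFrequencies(p=p, n_obs=n_obs, snp_ids=g.snps["snp_id"].tolist())


def _resolve_subset(g: GenotypeMatrix, snp_subset: Optional[Iterable[str]]):
    if snp_subset is None:
        return np.arange(g.n_snps)
    subset = list(snp_subset)
    if not subset:
        raise ValueError("snp_subset is empty")
    pos = {s: i for i, s in enumerate(g.snps["snp_id"])}
    missing = [s for s in subset if s not in pos]
    if missing:
        raise KeyError(f"snp_subset ids not in panel: {missing[:5]}")
    return np.array([pos[s] for s in subset])


def build_grm(
    g: GenotypeMatrix,
    snp_subset: Optional[Iterable[str]] = None,
    freqs: Optional[AlleleFrequencies] = None,
    per_pair_n: bool = False,
    provenance: str = "full",
) -> GRM:
    """Compute the standardised IBS GRM over the given SNPs.

    Missing dosages contribute zero to each pair's sum (equivalent to
    substituting the mean dosage ``2 p_z``).  By default the denominator N
    stays at the panel size; ``per_pair_n=True`` instead divides each pair's
    sum by the number of SNPs non-missing in both members (GCTA behaviour),
    and each diagonal by the individual's non-missing count.
    """
    cols = _resolve_subset(g, snp_subset)
    d = g.dosages[:, cols]
    if freqs is None:
        sub = g.subset(snp_ids=g.snps["snp_id"].iloc[cols].tolist())
        freqs = allele_frequencies(sub)
        p = freqs.p
    else:
        p = np.asarray(freqs.p)[cols] if len(freqs.p) == g.n_snps else np.asarray(freqs.p)
        if len(p) != len(cols):
            raise ValueError("freqs length does not match SNP subset")
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = g.snps["snp_id"].iloc[cols[mono]].tolist()
        raise MonomorphicSNPError(
            f"monomorphic SNPs (p=0 or 1) cannot be standardised: {bad[:5]}"
        )

    n_snps = len(cols)
    het = 2.0 * p * (1.0 - p)
    obs = ~np.isnan(d)
    centred = np.where(obs, d - 2.0 * p, 0.0) / np.sqrt(het)
    values = centred @ centred.T

    # diagonal by the printed formula, missing SNPs contributing zero
    s = np.where(obs, d, 0.0)
    diag_terms = np.where(
        obs, (s * s - (1.0 + 2.0 * p) * s + 2.0 * p * p) / het, 0.0
    )
    diag_sum = diag_terms.sum(axis=1)

    pair_counts = None
    if per_pair_n:
        obs_f = obs.astype(float)
        pair_counts = obs_f @ obs_f.T
        with np.errstate(invalid="ignore", divide="ignore"):
            values = values / pair_counts
        values[pair_counts == 0] = 0.0
        n_i = obs.sum(axis=1)
        diag = 1.0 + diag_sum / np.maximum(n_i, 1)
    else:
        values /= n_snps
        diag = 1.0 + diag_sum / n_snps
    np.fill_diagonal(values, diag)
    values = (values + values.T) / 2.0
    return GRM(values=values, ids=list(g.sample_ids), n_snps_used=n_snps,
               provenance=provenance, pair_snp_counts=pair_counts)


def threshold_grm(grm: GRM, t: float) -> GRM:
    """Zero all off-diagonal relationships ``<= t`` (kinship GRM).

    The diagonal is copied unchanged: self-relatedness must be retained for
    the matrix to define a usable covariance structure.
    """
    if t < 0:
        raise ValueError(f"threshold t must be >= 0, got {t}")
    if grm.provenance != "full":
        raise ValueError(
            f"threshold_grm expects a full GRM, got provenance {grm.provenance!r}"
        )
    values = grm.values.copy()
    off = ~np.eye(grm.n, dtype=bool)
    values[off & (values <= t)] = 0.0
    return GRM(values=values, ids=list(grm.ids), n_snps_used=grm.n_snps_used,
               provenance=f"thresholded(t={t:g})",
               pair_snp_counts=grm.pair_snp_counts)


def maf_subset(
    freqs: AlleleFrequencies, snps: pd.DataFrame, maf_threshold: float
) -> list[str]:
    """SNP ids whose minor allele frequency is strictly below the threshold."""
    if not 0.0 < maf_threshold <= 0.5:
        raise ValueError(f"maf_threshold must be in (0, 0.5], got {maf_threshold}")
    maf = np.minimum(freqs.p, 1.0 - freqs.p)
    ids = [s for s, m in zip(freqs.snp_ids, maf) if m < maf_threshold]
    if not ids:
        raise ValueError(f"no SNPs with MAF below threshold {maf_threshold}")
    return ids


def region_subset(
    snps: pd.DataFrame,
    chromosome,
    center_start_bp: Optional[int] = None,
    center_end_bp: Optional[int] = None,
    flank_bp: int = 0,
    min_snps: int = 10,
) -> list[str]:
    """SNP ids on a chromosome within ``[start - flank, end + flank]``.

    Coordinates are 1-based inclusive.  With no start/end the whole
    chromosome is taken.  Fewer than ``min_snps`` matches raises
    :class:`RegionTooSparseError` — mirroring the refusal to build a GRM
    from fewer than 10 SNPs.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    on_chrom = snps["chromosome"].astype(str) == str(chromosome)
    sel = on_chrom.to_numpy()
    if center_start_bp is not None or center_end_bp is not None:
        if center_start_bp is None or center_end_bp is None:
            raise ValueError("give both center_start_bp and center_end_bp, or neither")
        lo = center_start_bp - flank_bp
        hi = center_end_bp + flank_bp
        pos = snps["position_bp"].to_numpy()
        sel = sel & (pos >= lo) & (pos <= hi)
    ids = snps.loc[sel, "snp_id"].tolist()
    if len(ids) < min_snps:
        raise RegionTooSparseError(
            f"{len(ids)} SNPs in region (chromosome {chromosome}); refusing to "
            f"build a GRM from fewer than {min_snps} SNPs"
        )
    return ids


def fhat3(g: GenotypeMatrix, freqs: Optional[AlleleFrequencies] = None) -> np.ndarray:
    """SNP-based inbreeding coefficient: the standardised GRM diagonal minus 1.

    ``Fhat3_i = (1/N) sum_z (s_iz^2 - (1+2p_z) s_iz + 2 p_z^2) / (2 p_z (1-p_z))``;
    zero in expectation under Hardy-Weinberg random mating.
    """
    grm = build_grm(g, freqs=freqs)
    return np.diag(grm.values) - 1.0


def relatedness_summary(grm: GRM, bin_edges: Sequence[float]) -> pd.Series:
    """Proportions of off-diagonal relatedness in half-open bins.

    Bins are ``(-inf, e1], (e1, e2], ..., > e_last`` over the upper-triangle
    off-diagonal entries.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    iu = np.triu_indices(grm.n, k=1)
    vals = grm.values[iu]
    labels = [f"<= {edges[0]:g}"]
    counts = [np.sum(vals <= edges[0])]
    for a, b in zip(edges, edges[1:]):
        labels.append(f"({a:g}, {b:g}]")
        counts.append(np.sum((vals > a) & (vals <= b)))
    labels.append(f"> {edges[-1]:g}")
    counts.append(np.sum(vals > edges[-1]))
    return pd.Series(np.array(counts, dtype=float) / vals.size, index=labels)
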