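"""Genetic file input/output and genotype quality control.

Genotypes are held as reference-allele dosages (0/1/2, NaN for missing) in a
:class:`GenotypeMatrix`.  On-disk interoperability covers the PLINK binary
triplet (.bed/.bim/.fam, SNP-major v1.0) and the GCTA GRM binary triplet
(.grm.bin/.grm.N.bin/.grm.id), plus plain tab-separated pedigree and
phenotype tables.

The counted allele is the .bim A1 allele throughout, matching the PLINK/GCTA
convention; "reference allele" in the estimator formulas means this allele.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import EmptyPanelError, FormatError

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def _ext(prefix, ext: str):
    """Append an extension without clobbering dots already in the prefix."""
    prefix = Path(prefix)
    return prefix.parent / (prefix.name + ext)

SNP_COLUMNS = ["snp_id", "chromosome", "position_bp", "counted_allele", "other_allele"]


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x SNPs reference-allele dosage matrix.

    Attributes
    ----------
    dosages:
        ``(n_individuals, n_snps)`` float array with entries in {0, 1, 2}
        and ``NaN`` for missing calls.
    sample_ids:
        Ordered unique individual identifiers (rows).
    snps:
        SNP map with columns ``snp_id, chromosome, position_bp,
        counted_allele, other_allele`` (columns).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match number of sample_ids")
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps table missing columns {missing_cols}")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError("column count does not match SNP table length")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("snp_ids must be unique")
        if (self.snps["position_bp"] < 0).any():
            raise ValueError("positions must be non-negative")
        if (self.snps["counted_allele"] == self.snps["other_allele"]).any():
            raise ValueError("counted_allele must differ from other_allele")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(
        self,
        individuals: Optional[list[str]] = None,
        snp_ids: Optional[list[str]] = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given individuals and/or SNPs."""
        rows = np.arange(self.n_individuals)
        cols = np.arange(self.n_snps)
        ids = self.sample_ids
        snps = self.snps
        if individuals is not None:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            rows = np.array([pos[s] for s in individuals])
            ids = list(individuals)
        if snp_ids is not None:
            pos = {s: i for i, s in enumerate(self.snps["snp_id"])}
            cols = np.array([pos[s] for s in snp_ids])
        snps = self.snps.iloc[cols].reset_index(drop=True)
        return GenotypeMatrix(self.dosages[np.ix_(rows, cols)], ids, snps)


# ---------------------------------------------------------------------------
# PLINK .bed/.bim/.fam
# ---------------------------------------------------------------------------

# 2-bit codes in a SNP-major .bed record, interpreted as A1 (counted) dosage:
#   00 -> 2 (hom A1),  10 -> 1 (het),  11 -> 0 (hom A2),  01 -> missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK binary fileset ``prefix.bed/.bim/.fam``.

    The .bim A1 allele is counted, so a ``00`` genotype code decodes to
    dosage 2.  The missing code maps to NaN.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not _ext(prefix, ext).exists():
            raise FileNotFoundError(f"missing PLINK file: {_ext(prefix, ext)}")
    fam = pd.read_csv(
        _ext(prefix, ".fam"), sep=r"\s+", header=None, dtype=str
    )
    sample_ids = fam[1].tolist()
    bim = pd.read_csv(
        _ext(prefix, ".bim"), sep=r"\s+", header=None, dtype=str
    )
    snps = pd.DataFrame(
        {
            "snp_id": bim[1],
            "chromosome": bim[0],
            "position_bp": bim[3].astype(int),
            "counted_allele": bim[4],
            "other_allele": bim[5],
        }
    )
    raw = _ext(prefix, ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{_ext(prefix, '.bed')} has bad magic bytes "
            f"{raw[:3].hex()}; expected SNP-major v1.0 ({_BED_MAGIC.hex()})"
        )
    n, m = len(sample_ids), len(snps)
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * m:
        raise FormatError(
            f"{_ext(prefix, '.bed')}: expected {bytes_per_snp * m} data "
            f"bytes for {n} individuals x {m} SNPs, found {body.size}"
        )
    codes = np.zeros((m, n), dtype=np.uint8)
    blocks = body.reshape(m, bytes_per_snp)
    for k in range(4):
        idx = np.arange(k, n, 4)
        codes[:, idx] = (blocks[:, : len(idx)] >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes].T
    return GenotypeMatrix(dosages, sample_ids, snps)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``g`` as a PLINK binary fileset (SNP-major v1.0)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fam = pd.DataFrame(
        {
            0: g.sample_ids,
            1: g.sample_ids,
            2: "0",
            3: "0",
            4: "0",
            5: "-9",
        }
    )
    fam.to_csv(_ext(prefix, ".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            0: g.snps["chromosome"],
            1: g.snps["snp_id"],
            2: "0",
            3: g.snps["position_bp"],
            4: g.snps["counted_allele"],
            5: g.snps["other_allele"],
        }
    )
    bim.to_csv(_ext(prefix, ".bim"), sep="\t", header=False, index=False)

    n, m = g.n_individuals, g.n_snps
    # dosage -> 2-bit code; NaN -> 01
    code = np.full((m, n), 1, dtype=np.uint8)
    d = g.dosages.T
    code[d == 2.0] = 0b00
    code[d == 1.0] = 0b10
    code[d == 0.0] = 0b11
    bytes_per_snp = (n + 3) // 4
    blocks = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        idx = np.arange(k, n, 4)
        blocks[:, : len(idx)] |= code[:, idx] << (2 * k)
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(blocks.tobytes())


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class QCReport:
    """Counts and identities removed by each quality-control rule."""

    n_snps_maf: int
    n_snps_call_rate: int
    n_individuals_call_rate: int
    n_individuals_ibs: int
    removed_snps: list[str]
    removed_individuals: list[str]


def _ibs_proportions(d: np.ndarray) -> np.ndarray:
    """Pairwise proportion of identical non-missing genotype calls."""
    obs = ~np.isnan(d)
    shared = obs.astype(float) @ obs.T.astype(float)
    same = np.zeros_like(shared)
    for v in (0.0, 1.0, 2.0):
        ind = (d == v).astype(float)
        same += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = same / shared
    prop[shared == 0] = 0.0
    return prop


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.001,
    snp_call_min: float = 0.99,
    ind_call_min: float = 0.95,
    ibs_max: float = 0.9,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker and individual quality-control filters.

    Keeps SNPs with MAF strictly above ``maf_min`` and call rate strictly
    above ``snp_call_min``; keeps individuals with call rate strictly above
    ``ind_call_min`` and pairwise IBS strictly below ``ibs_max``.  Of an
    offending IBS pair the later-listed member is removed (deterministic).
    Missing dosages are retained, never imputed.
    """
    for name, v in (
        ("maf_min", maf_min),
        ("snp_call_min", snp_call_min),
        ("ind_call_min", ind_call_min),
        ("ibs_max", ibs_max),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")

    d = g.dosages
    obs = ~np.isnan(d)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * obs.sum(axis=0))
    p = np.where(obs.sum(axis=0) == 0, 0.0, p)
    maf = np.minimum(p, 1.0 - p)
    snp_call = obs.mean(axis=0)

    fail_maf = maf <= maf_min
    fail_call = snp_call <= snp_call_min
    keep_snps = ~(fail_maf | fail_call)
    removed_snps = g.snps.loc[~keep_snps, "snp_id"].tolist()
    if not keep_snps.any():
        raise EmptyPanelError("QC removed every SNP: empty panel")

    d2 = d[:, keep_snps]
    obs2 = obs[:, keep_snps]
    ind_call = obs2.mean(axis=1)
    keep_ind = ind_call > ind_call_min
    n_ind_call = int((~keep_ind).sum())

    # IBS duplicates among individuals surviving the call-rate rule
    surv = np.flatnonzero(keep_ind)
    prop = _ibs_proportions(d2[surv])
    drop_ibs: set[int] = set()
    for a in range(len(surv)):
        if a in drop_ibs:
            continue
        for b in range(a + 1, len(surv)):
            if b in drop_ibs:
                continue
            if prop[a, b] >= ibs_max:
                drop_ibs.add(b)
    for b in drop_ibs:
        keep_ind[surv[b]] = False

    removed_individuals = [
        g.sample_ids[i] for i in range(g.n_individuals) if not keep_ind[i]
    ]
    out = GenotypeMatrix(
        d2[keep_ind],
        [s for s, k in zip(g.sample_ids, keep_ind) if k],
        g.snps.loc[keep_snps].reset_index(drop=True),
    )
    report = QCReport(
        n_snps_maf=int(fail_maf.sum()),
        n_snps_call_rate=int((fail_call & ~fail_maf).sum()),
        n_individuals_call_rate=n_ind_call,
        n_individuals_ibs=len(drop_ibs),
        removed_snps=removed_snps,
        removed_individuals=removed_individuals,
    )
    return out, report


# ---------------------------------------------------------------------------
# GCTA GRM binary triplet
# ---------------------------------------------------------------------------


def write_grm_gcta(grm, prefix: str | Path) -> None:
    """Write a GRM as the GCTA binary triplet.

    ``.grm.bin`` holds the lower triangle (diagonal included) row by row as
    little-endian float32; ``.grm.N.bin`` the per-pair SNP counts in the same
    layout; ``.grm.id`` two tab-separated id columns (family id = individual
    id here).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = len(grm.ids)
    tril = np.tril_indices(n)
    vals = np.asarray(grm.values)[tril].astype("<f4")
    with open(f"{prefix}.grm.bin", "wb") as fh:
        fh.write(vals.tobytes())
    if getattr(grm, "pair_snp_counts", None) is not None:
        counts = np.asarray(grm.pair_snp_counts)[tril].astype("<f4")
    else:
        counts = np.full(vals.shape, float(grm.n_snps_used), dtype="<f4")
    with open(f"{prefix}.grm.N.bin", "wb") as fh:
        fh.write(counts.tobytes())
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in grm.ids:
            fh.write(f"{s}\t{s}\n")


def read_grm_gcta(prefix: str | Path):
    """Read a GCTA binary GRM triplet written by :func:`write_grm_gcta`."""
    from .grm import GRM  # local import to avoid a cycle

    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id") if line.strip()]
    n = len(ids)
    n_pairs = n * (n + 1) // 2
    vals = np.frombuffer(Path(f"{prefix}.grm.bin").read_bytes(), dtype="<f4")
    if vals.size != n_pairs:
        raise FormatError(
            f"{prefix}.grm.bin holds {vals.size} values but {prefix}.grm.id "
            f"lists {n} ids (needs {n_pairs})"
        )
    counts = np.frombuffer(Path(f"{prefix}.grm.N.bin").read_bytes(), dtype="<f4")
    if counts.size != n_pairs:
        raise FormatError(
            f"{prefix}.grm.N.bin holds {counts.size} values; expected {n_pairs}"
        )
    m = np.zeros((n, n))
    c = np.zeros((n, n))
    tril = np.tril_indices(n)
    m[tril] = vals
    c[tril] = counts
    m = m + m.T - np.diag(np.diag(m))
    c = c + c.T - np.diag(np.diag(c))
    n_snps = int(round(float(counts.max()))) if counts.size else 0
    return GRM(values=m, ids=ids, n_snps_used=max(n_snps, 1), provenance="full",
               pair_snp_counts=c)


# ---------------------------------------------------------------------------
# Plain-text tables
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated pedigree (id, sire, dam; '0'/empty = unknown)."""
    ped = pd.read_csv(path, sep="\t", dtype=str)
    ped.columns = [c.lower() for c in ped.columns]
    for col in ("id", "sire", "dam"):
        if col not in ped.columns:
            raise FormatError(f"pedigree file {path} lacks column '{col}'")
    ped = ped[["id", "sire", "dam"]]
    ped = ped.replace({"0": pd.NA, "": pd.NA})
    return ped


def write_pedigree(ped: pd.DataFrame, path: str | Path) -> None:
    out = ped.fillna("0")
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated phenotype/covariate table (one row per record)."""
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def write_phenotypes(phenos: pd.DataFrame, path: str | Path) -> None:
    phenos.to_csv(path, sep="\t", index=False)
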