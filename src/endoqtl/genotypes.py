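"""Genotype container, VCF IO, QC filters, and linkage disequilibrium.

Dosages count copies of the A1 allele (A1 = VCF ALT), so a reported effect
is per extra copy of A1, matching the A1/BETA orientation of the association
output. QC boundary semantics are strict, mirroring the PLINK flags the
filters emulate: a variant is removed when missingness is strictly above the
threshold, or MAF / HWE p is strictly below it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ParseError, UndefinedLdError

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with variant metadata.

    dosage is float64 with values {0, 1, 2, NaN}; NaN encodes a missing call.
    ``variants`` is indexed by variant_id with columns chrom, pos (1-based),
    a1, a2, plus optional simulation metadata (af, block).
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ConfigError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if not self.variants.index.is_unique:
            raise ConfigError("variant ids are not unique")
        if len(self.variants) and (self.variants["pos"] < 1).any():
            raise ConfigError("variant positions must be 1-based (>= 1)")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ConfigError("dosages must be in {0, 1, 2} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants.index)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Frequency of A1 among non-missing calls (NaN if all missing)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def column(self, variant_id: str) -> np.ndarray:
        j = self.variants.index.get_loc(variant_id)
        return self.dosage[:, j]

    def subset_variants(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = np.array([self.variants.index.get_loc(v) for v in keep], dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].copy(),
            dosage=self.dosage[:, idx].copy(),
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids])
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            variants=self.variants.copy(),
            dosage=self.dosage[idx].copy(),
        )

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.variants.index)


@dataclass
class QcReport:
    """Accounting of a QC pass; a variant is attributed to the first filter
    it fails, in the order missingness -> MAF -> HWE."""

    n_input: int
    n_removed_missingness: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_removed_missingness
            - self.n_removed_maf
            - self.n_removed_hwe
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("input", self.n_input),
                ("removed_missingness", self.n_removed_missingness),
                ("removed_maf", self.n_removed_maf),
                ("removed_hwe", self.n_removed_hwe),
                ("retained", self.n_retained),
            ],
            columns=["step", "n"],
        )


# ---------------------------------------------------------------- VCF IO


def read_vcf(path, on_multiallelic: str = "error") -> GenotypeMatrix:
    """Read diploid GT calls from a VCF (v4.x) into A1=ALT dosages.

    Multi-allelic records raise a ParseError by default, or are skipped with
    ``on_multiallelic='skip'``. './.' maps to missing; positions stay 1-based.
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "skip"):
        raise ConfigError("on_multiallelic must be 'error' or 'skip'")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if on_multiallelic == "skip":
                continue
            raise ParseError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} ({rec.ID}); "
                "pass on_multiallelic='skip' to drop such records"
            )
        gts = rec.genotype.array()  # (n, ploidy+1); last col = phasing
        if gts.shape[1] - 1 != 2:
            raise ParseError(f"non-diploid GT at {rec.CHROM}:{rec.POS}")
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan  # -1 encodes '.'
        dos = alleles.sum(axis=1)  # NaN if either allele missing
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        meta.append((vid, rec.CHROM, rec.POS, rec.ALT[0], rec.REF))
        rows.append(dos)
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS).set_index("variant_id")
    dosage = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosage=dosage)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes (A1 as ALT)."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for chrom in pd.unique(g.variants["chrom"]):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(g.sample_ids) + "\n")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, (vid, row) in enumerate(g.variants.iterrows()):
        calls = [
            "./." if np.isnan(d) else gt_map[d] for d in g.dosage[:, j]
        ]
        buf.write(
            f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['a2']}\t{row['a1']}"
            f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    g.dosage_frame().rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------- QC filters


def filter_missingness(g: GenotypeMatrix, max_missing: float = 0.05):
    """Drop variants whose missing fraction is strictly above ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ConfigError("max_missing must be in [0, 1]")
    keep = g.missing_rate() <= max_missing
    report = QcReport(
        n_input=g.n_variants,
        n_removed_missingness=int((~keep).sum()),
        thresholds={"missingness": max_missing},
    )
    return g.subset_variants(keep), report


def filter_maf(g: GenotypeMatrix, min_maf: float):
    """Drop variants with MAF strictly below ``min_maf`` (all-missing variants
    have undefined MAF and are removed)."""
    if not 0.0 <= min_maf <= 0.5:
        raise ConfigError("min_maf must be in [0, 0.5]")
    maf = g.maf()
    keep = maf >= min_maf  # NaN compares False -> removed
    report = QcReport(
        n_input=g.n_variants,
        n_removed_maf=int((~keep).sum()),
        thresholds={"maf": min_maf},
    )
    return g.subset_variants(keep), report


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """One-df chi-square goodness-of-fit p of genotype counts vs p^2, 2pq, q^2.

    Monomorphic variants have chi-square 0 (p = 1); variants with fewer than
    two non-missing calls return NaN (skipped by the filter).
    """
    d = g.dosage
    n0 = np.nansum(d == 0, axis=0).astype(float)
    n1 = np.nansum(d == 1, axis=0).astype(float)
    n2 = np.nansum(d == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    p = np.where(n > 0, (2 * n2 + n1) / np.maximum(2 * n, 1), np.nan)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
        chi2 = np.zeros_like(p)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0)
            chi2 += term
    pv = stats.chi2.sf(chi2, df=1)
    pv = np.where((p <= 0) | (p >= 1), 1.0, pv)  # monomorphic: exact fit
    pv = np.where(n < 2, np.nan, pv)
    return pv


def filter_hwe(g: GenotypeMatrix, min_p: float = 1e-6):
    """Drop variants with HWE p strictly below ``min_p``."""
    if not 0.0 < min_p < 1.0:
        raise ConfigError("min_p must be in (0, 1)")
    pv = hwe_pvalues(g)
    keep = ~(pv < min_p)  # NaN (untestable) retained
    report = QcReport(
        n_input=g.n_variants,
        n_removed_hwe=int((~keep).sum()),
        thresholds={"hwe_p": min_p},
    )
    return g.subset_variants(keep), report


def qc_pipeline(
    g: GenotypeMatrix,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
    hwe_min_p: float = 1e-6,
):
    """Apply missingness -> MAF -> HWE in order with combined accounting."""
    g1, r1 = filter_missingness(g, max_missing)
    g2, r2 = filter_maf(g1, min_maf)
    g3, r3 = filter_hwe(g2, hwe_min_p)
    report = QcReport(
        n_input=g.n_variants,
        n_removed_missingness=r1.n_removed_missingness,
        n_removed_maf=r2.n_removed_maf,
        n_removed_hwe=r3.n_removed_hwe,
        thresholds={"missingness": max_missing, "maf": min_maf, "hwe_p": hwe_min_p},
    )
    return g3, report


# ---------------------------------------------------------------- LD


def _pairwise_r(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise UndefinedLdError("fewer than 2 pairwise-complete samples")
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise UndefinedLdError("zero dosage variance at one of the variants")
    return float(np.corrcoef(x, y)[0, 1])


def ld_r2(g: GenotypeMatrix, v1: str, v2: str) -> tuple[float, float]:
    """Signed Pearson r and r^2 of dosages over pairwise-complete samples."""
    r = _pairwise_r(g.column(v1), g.column(v2))
    return r, r * r


def ld_matrix(g: GenotypeMatrix, variant_ids=None, ridge: float = 0.0) -> pd.DataFrame:
    """Symmetric signed-r LD matrix (pairwise-complete). A positive ``ridge``
    is added to the diagonal (used before inversion in HEIDI)."""
    ids = list(variant_ids) if variant_ids is not None else g.variant_ids
    if not ids:
        raise ConfigError("ld_matrix requires at least one variant")
    sub = g.subset_variants(ids)
    if (np.nanstd(sub.dosage, axis=0) == 0).any():
        raise UndefinedLdError("zero dosage variance in LD matrix request")
    corr = sub.dosage_frame().corr()  # pairwise-complete by construction
    mat = corr.to_numpy()
    np.fill_diagonal(mat, 1.0)
    if ridge:
        mat = mat + ridge * np.eye(len(ids))
    return pd.DataFrame(mat, index=ids, columns=ids)
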