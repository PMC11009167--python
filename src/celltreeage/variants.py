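"""Per-cell somatic SNV call matrices: I/O, germline exclusion and
false-positive filtering.

The entry point of the pipeline is a pair of sparse cells x sites UMI count
matrices (alternative and reference allele) as produced by single-cell SNV
callers, with a barcode list and a variant annotation table. Two consecutive
detection filters are applied to reduce false-positive somatic calls: a site
is detected in a cell only if it is covered by at least ``min_umis``
alternative-allele UMIs in that cell, and a site is retained only if it is
detected in at least ``min_barcodes`` cells. Known germline variants
(population minor allele frequency above a threshold) are removed first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

#: default per-cell alternative-UMI detection threshold
MIN_UMIS = 8
#: default minimum number of detecting cells per retained site
MIN_BARCODES = 4


class VariantSite(NamedTuple):
    """A single-nucleotide variant site (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str


def _normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def site_key(chrom, pos, ref, alt, normalize_chrom: bool = True) -> tuple:
    c = _normalize_chrom(chrom) if normalize_chrom else str(chrom)
    return (c, int(pos), str(ref).upper(), str(alt).upper())


class MatrixFormatError(ValueError):
    """Raised when call-matrix inputs are malformed or inconsistent."""


@dataclass
class VariantCallMatrix:
    """Sparse per-cell alt/ref UMI counts over annotated SNV sites.

    Parameters
    ----------
    alt_umis, ref_umis : scipy.sparse matrix, shape (n_cells, n_sites)
        Non-negative integer UMI counts supporting the alternative and the
        reference allele respectively.
    barcodes : list of str
        Cell identifiers, one per row, duplicate-free.
    sites : pandas.DataFrame
        One row per column with columns ``chrom, pos, ref, alt``
        (``pos`` 1-based).
    """

    alt_umis: sp.csr_matrix
    ref_umis: sp.csr_matrix
    barcodes: list = field(default_factory=list)
    sites: pd.DataFrame = None

    def __post_init__(self):
        self.alt_umis = sp.csr_matrix(self.alt_umis)
        self.ref_umis = sp.csr_matrix(self.ref_umis)
        self.barcodes = list(self.barcodes)
        if self.alt_umis.shape != self.ref_umis.shape:
            raise MatrixFormatError(
                f"alt/ref shape mismatch: {self.alt_umis.shape} vs {self.ref_umis.shape}"
            )
        n_cells, n_sites = self.alt_umis.shape
        if len(self.barcodes) != n_cells:
            raise MatrixFormatError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix rows"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise MatrixFormatError("duplicate barcodes")
        if self.sites is None or len(self.sites) != n_sites:
            n = 0 if self.sites is None else len(self.sites)
            raise MatrixFormatError(f"{n} variant annotations for {n_sites} matrix columns")
        missing = {"chrom", "pos", "ref", "alt"} - set(self.sites.columns)
        if missing:
            raise MatrixFormatError(f"variant table lacks columns {sorted(missing)}")
        if self.alt_umis.nnz and self.alt_umis.data.min() < 0:
            raise MatrixFormatError("negative alt UMI counts")
        if self.ref_umis.nnz and self.ref_umis.data.min() < 0:
            raise MatrixFormatError("negative ref UMI counts")
        keys = list(zip(self.sites["chrom"], self.sites["pos"], self.sites["ref"], self.sites["alt"]))
        if len(set(keys)) != len(keys):
            raise MatrixFormatError("duplicate variant sites")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.alt_umis.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alt_umis.shape[1]

    def site_keys(self, normalize_chrom: bool = True) -> list:
        return [
            site_key(c, p, r, a, normalize_chrom)
            for c, p, r, a in zip(self.sites["chrom"], self.sites["pos"], self.sites["ref"], self.sites["alt"])
        ]

    def site_records(self) -> list:
        return [VariantSite(str(c), int(p), str(r), str(a))
                for c, p, r, a in zip(self.sites["chrom"], self.sites["pos"],
                                      self.sites["ref"], self.sites["alt"])]

    def write(self, out_dir) -> dict:
        """Write MTX + barcodes.tsv + variants.csv into ``out_dir``.

        Returns a dict of the four paths written.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "alt": out / "alt.mtx",
            "ref": out / "ref.mtx",
            "barcodes": out / "barcodes.tsv",
            "variants": out / "variants.csv",
        }
        mmwrite(str(paths["alt"]), sp.coo_matrix(self.alt_umis))
        mmwrite(str(paths["ref"]), sp.coo_matrix(self.ref_umis))
        paths["barcodes"].write_text("".join(f"{b}\n" for b in self.barcodes))
        self.sites.to_csv(paths["variants"], index=False)
        return paths


@dataclass(frozen=True)
class GermlineExclusionSet:
    """Set of (chrom, pos, ref, alt) keys of likely germline variants."""

    keys: frozenset
    normalize_chrom: bool = True

    def __contains__(self, key) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def from_records(cls, records: Iterable, normalize_chrom: bool = True) -> "GermlineExclusionSet":
        keys = frozenset(site_key(*r, normalize_chrom=normalize_chrom) for r in records)
        return cls(keys=keys, normalize_chrom=normalize_chrom)


def _read_barcodes(path) -> list:
    barcodes = [ln.strip().split("\t")[0] for ln in Path(path).read_text().splitlines() if ln.strip()]
    return barcodes


def load_call_matrix(mtx_alt_path, mtx_ref_path, barcodes_path, variants_path) -> VariantCallMatrix:
    """Load a :class:`VariantCallMatrix` from MatrixMarket + TSV/CSV files.

    Matrices are cells x sites; a transposed (sites x cells) orientation is
    not guessed — dimensions must match the barcode and variant tables.
    """
    for p in (mtx_alt_path, mtx_ref_path, barcodes_path, variants_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    try:
        alt = sp.csr_matrix(mmread(str(mtx_alt_path)))
        ref = sp.csr_matrix(mmread(str(mtx_ref_path)))
    except Exception as exc:  # scipy raises bare ValueError on bad MTX
        raise MatrixFormatError(f"malformed MatrixMarket input: {exc}") from exc
    barcodes = _read_barcodes(barcodes_path)
    sites = pd.read_csv(variants_path)
    return VariantCallMatrix(alt_umis=alt, ref_umis=ref, barcodes=barcodes, sites=sites)


def load_germline_vcf(vcf_path, maf_threshold: float = 0.01, af_field: str = "AF",
                      normalize_chrom: bool = True) -> GermlineExclusionSet:
    """Collect germline exclusion keys from a population VCF.

    A record (expanded per alternative allele for multi-allelic sites) is
    excluded when its minor allele frequency ``min(AF, 1 - AF)`` exceeds
    ``maf_threshold``. Records lacking the allele-frequency INFO field are
    skipped with a summary warning.
    """
    from cyvcf2 import VCF

    keys = set()
    n_skipped = 0
    vcf = VCF(str(vcf_path))
    for rec in vcf:
        af = rec.INFO.get(af_field)
        if af is None:
            n_skipped += 1
            continue
        afs = af if isinstance(af, (tuple, list)) else (af,)
        alts = rec.ALT
        for alt, a in zip(alts, afs):
            try:
                a = float(a)
            except (TypeError, ValueError):
                n_skipped += 1
                continue
            maf = min(a, 1.0 - a)
            if maf > maf_threshold:
                keys.add(site_key(rec.CHROM, rec.POS, rec.REF, alt, normalize_chrom))
    vcf.close()
    if n_skipped:
        logger.warning("load_germline_vcf: %d records without usable %s field skipped",
                       n_skipped, af_field)
    return GermlineExclusionSet(keys=frozenset(keys), normalize_chrom=normalize_chrom)


def filter_variants(m: VariantCallMatrix, germ: GermlineExclusionSet | None = None,
                    min_umis: int = MIN_UMIS, min_barcodes: int = MIN_BARCODES) -> VariantCallMatrix:
    """Apply germline exclusion and the two consecutive detection filters.

    1. Sites whose (chrom, pos, ref, alt) key is in ``germ`` are dropped.
    2. A cell *detects* a site iff its alternative-UMI count is at least
       ``min_umis``; sub-threshold alternative counts are zeroed (treated as
       not detected).
    3. Sites detected in fewer than ``min_barcodes`` cells are dropped.

    Returns a new matrix; the input is untouched. An empty result is legal.
    """
    if min_umis < 1 or min_barcodes < 1:
        raise ValueError("min_umis and min_barcodes must be >= 1")
    norm = germ.normalize_chrom if germ is not None else True
    if germ is not None and len(germ):
        keep_mask = np.array([k not in germ for k in m.site_keys(normalize_chrom=norm)], dtype=bool)
    else:
        keep_mask = np.ones(m.n_sites, dtype=bool)

    alt = sp.csr_matrix(m.alt_umis[:, keep_mask], copy=True)
    ref = sp.csr_matrix(m.ref_umis[:, keep_mask], copy=True)
    sites = m.sites.loc[keep_mask].reset_index(drop=True)

    # zero sub-threshold alt counts, then drop under-supported sites
    alt.data[alt.data < min_umis] = 0
    alt.eliminate_zeros()
    support = np.asarray((alt > 0).sum(axis=0)).ravel()
    site_ok = support >= min_barcodes
    return VariantCallMatrix(
        alt_umis=alt[:, site_ok],
        ref_umis=ref[:, site_ok],
        barcodes=list(m.barcodes),
        sites=sites.loc[site_ok].reset_index(drop=True),
    )
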