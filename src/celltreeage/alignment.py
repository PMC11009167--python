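"""Binary cell pseudo-alignments over {R, A, ?} and pseudo-replicate draws.

Filtered call matrices are encoded as character matrices with one row per
cell and one column per retained SNV site: 'A' marks detected carriage of
the alternative allele, 'R' reference-only coverage, '?' no usable signal.
Pseudo-replicates are independent uniform subsets of a sample's cells, used
to capture within-sample tree variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: character codes used internally
_CODE = {"R": 0, "A": 1, "?": 2}
_CHAR = np.array(["R", "A", "?"])

#: nucleotide-compatible output alphabet for tools that reject '?'/'R'
NUCLEOTIDE_ALPHABET = {"A": "a", "R": "t", "?": "N"}


@dataclass
class CellAlignment:
    """Cells x sites character matrix over {R, A, ?}.

    ``codes`` is a uint8 matrix with 0='R', 1='A', 2='?'. ``sites`` is the
    variant annotation table matching the columns (may be ``None`` for
    alignments read back from bare FASTA).
    """

    cells: list
    codes: np.ndarray
    sites: pd.DataFrame | None = None
    sample_id: str | None = None

    def __post_init__(self):
        self.cells = list(self.cells)
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.cells):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with {len(self.cells)} cells"
            )
        if self.codes.size and self.codes.max() > 2:
            raise ValueError("state codes must be in {0,1,2}")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell barcodes in alignment")
        if self.sites is not None and len(self.sites) != self.codes.shape[1]:
            raise ValueError("site table length does not match alignment columns")

    @property
    def n_cells(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def state_codes(self) -> np.ndarray:
        return self.codes

    def sequences(self, alphabet: dict | None = None) -> list:
        """Per-cell state strings, optionally remapped through ``alphabet``."""
        chars = _CHAR
        if alphabet is not None:
            chars = np.array([alphabet["R"], alphabet["A"], alphabet["?"]])
        return ["".join(row) for row in chars[self.codes]]

    def take_cells(self, index: np.ndarray, prune_empty_columns: bool = True) -> "CellAlignment":
        """Row subset (by integer index); optionally drop columns left with no 'A'."""
        index = np.asarray(index, dtype=int)
        codes = self.codes[index]
        if prune_empty_columns and codes.size:
            keep = (codes == _CODE["A"]).any(axis=0)
            codes = codes[:, keep]
            sites = None if self.sites is None else self.sites.loc[np.asarray(keep)].reset_index(drop=True)
        else:
            sites = None if self.sites is None else self.sites.reset_index(drop=True)
        return CellAlignment(
            cells=[self.cells[i] for i in index],
            codes=codes,
            sites=sites,
            sample_id=self.sample_id,
        )


def encode_alignment(m, min_umis: int = 8, sample_id: str | None = None) -> CellAlignment:
    """Encode a (filtered) call matrix as a {R, A, ?} alignment.

    Per cell and site: 'A' iff alt UMIs >= ``min_umis``; 'R' iff alt UMIs
    below threshold and at least one reference UMI; '?' otherwise (no usable
    coverage). On matrices passed through the detection filter, sub-threshold
    alt counts have already been zeroed, so '?' reduces to "no UMIs at all".
    """
    alt = np.asarray(m.alt_umis.todense())
    ref = np.asarray(m.ref_umis.todense())
    codes = np.full(alt.shape, _CODE["?"], dtype=np.uint8)
    codes[(alt < min_umis) & (ref >= 1)] = _CODE["R"]
    codes[alt >= min_umis] = _CODE["A"]
    return CellAlignment(cells=list(m.barcodes), codes=codes, sites=m.sites.copy(),
                         sample_id=sample_id)


def subsample_pseudoreplicates(a: CellAlignment, n_reps: int = 5, cells_per_rep: int = 700,
                               seed=None) -> list:
    """Draw ``n_reps`` pseudo-replicate alignments of ``cells_per_rep`` cells.

    Each replicate is an independent uniform draw without replacement (the
    draws may overlap — hence *pseudo*-replicates), with cells kept in input
    order. Columns that lose every 'A' state in a replicate are dropped from
    that replicate. Deterministic for a given ``seed``.
    """
    if cells_per_rep > a.n_cells:
        name = a.sample_id or "<unnamed sample>"
        raise ValueError(
            f"sample {name}: requested {cells_per_rep} cells per replicate "
            f"but alignment has only {a.n_cells}"
        )
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        idx = np.sort(rng.choice(a.n_cells, size=cells_per_rep, replace=False))
        reps.append(a.take_cells(idx, prune_empty_columns=True))
    return reps


def write_fasta(a: CellAlignment, path, alphabet: dict | None = None, wrap: int = 0) -> None:
    """Write one FASTA record per cell (id = barcode, sequence = states)."""
    with open(path, "w") as fh:
        for barcode, seq in zip(a.cells, a.sequences(alphabet=alphabet)):
            fh.write(f">{barcode}\n")
            if wrap and wrap > 0:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i:i + wrap] + "\n")
            else:
                fh.write(seq + "\n")


def read_fasta(path, alphabet: dict | None = None) -> CellAlignment:
    """Read a pseudo-alignment from FASTA (site annotations are not recoverable)."""
    from Bio import SeqIO

    inverse = {"R": _CODE["R"], "A": _CODE["A"], "?": _CODE["?"]}
    if alphabet is not None:
        inverse = {alphabet["R"]: _CODE["R"], alphabet["A"]: _CODE["A"], alphabet["?"]: _CODE["?"]}
    cells, rows = [], []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"ragged FASTA: record {rec.id} has length {len(seq)}, expected {length}"
            )
        try:
            rows.append([inverse[c] for c in seq])
        except KeyError as exc:
            raise ValueError(f"record {rec.id}: unexpected state character {exc}") from exc
        cells.append(rec.id)
    if length is None:
        length = 0
    codes = np.asarray(rows, dtype=np.uint8).reshape(len(cells), length)
    return CellAlignment(cells=cells, codes=codes, sites=None,
                         sample_id=Path(str(path)).stem)
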