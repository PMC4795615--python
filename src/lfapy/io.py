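"""Genotype matrix I/O and the canonical in-memory data model.

Genotype matrices are oriented SNPs x individuals (m x n), with entries
coded 0/1/2 as the count of the designated (counted) allele and a missing
sentinel of -1.  PLINK 1 binary triplets (BED/BIM/FAM, SNP-major) and plain
delimited text matrices are supported; gzip is handled transparently for
text formats.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING = -1

_PLINK_MAGIC = b"\x6c\x1b"
_PLINK_SNP_MAJOR = b"\x01"

# 2-bit PLINK codes -> count of the A1 (counted) allele.
# 00 = hom A1 (2 copies), 01 = missing, 10 = het, 11 = hom A2 (0 copies).
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _open_text(path, mode="rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class GenotypeMatrix:
    """An m x n matrix of biallelic SNP genotypes.

    Parameters
    ----------
    values : ndarray of shape (m, n)
        Integer genotypes in {0, 1, 2} or :data:`MISSING`.
    snp_ids : sequence of m unique SNP identifiers.
    sample_ids : sequence of n unique sample identifiers.
    """

    values: np.ndarray
    snp_ids: Sequence[str] = None
    sample_ids: Sequence[str] = None

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.round(values)):
                raise ValueError("genotypes must be integers")
            values = values.astype(np.int8)
        m, n = values.shape
        if m < 1 or n < 2:
            raise ValueError(f"need m >= 1 SNPs and n >= 2 samples, got {m} x {n}")
        valid = np.isin(values, (0, 1, 2, MISSING))
        if not valid.all():
            bad = values[~valid].ravel()[0]
            raise ValueError(f"invalid genotype code {bad!r}; expected 0/1/2 or missing")
        self.values = values
        if self.snp_ids is None:
            self.snp_ids = [f"snp_{i}" for i in range(m)]
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{j}" for j in range(n)]
        self.snp_ids = list(map(str, self.snp_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match matrix")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix")
        if len(set(self.snp_ids)) != m or len(set(self.sample_ids)) != n:
            raise ValueError("snp_ids and sample_ids must be unique")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def as_float(self) -> np.ndarray:
        """Genotypes as float64 with missing entries mapped to NaN."""
        out = self.values.astype(np.float64)
        out[self.values == MISSING] = np.nan
        return out

    def minor_allele_freq(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls."""
        X = self.as_float()
        p = np.nanmean(X, axis=1) / 2.0
        return np.minimum(p, 1.0 - p)

    def flipped(self) -> "GenotypeMatrix":
        """Swap the counted allele: x -> 2 - x, missing preserved."""
        vals = np.where(self.values == MISSING, MISSING, 2 - self.values)
        return GenotypeMatrix(vals.astype(self.values.dtype), self.snp_ids, self.sample_ids)


@dataclass
class AlleleFreqMatrix:
    """An m x n matrix of individual-specific allele frequencies pi_ij.

    ``provenance`` records the estimator: 'pca' (truncated into [C, 1-C]),
    'lfa' (strictly inside (0,1) by construction) or 'simulated'.
    """

    values: np.ndarray
    provenance: str = "simulated"
    snp_ids: Sequence[str] = None
    sample_ids: Sequence[str] = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("frequency matrix must be 2-dimensional")
        if self.provenance not in ("pca", "lfa", "simulated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if np.any(values < 0) or np.any(values > 1) or not np.all(np.isfinite(values)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.provenance == "lfa" and (np.any(values <= 0) or np.any(values >= 1)):
            raise ValueError("lfa frequencies must lie strictly in (0, 1)")
        self.values = values

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class LogitFreqMatrix:
    """An m x n matrix of logit(pi_ij) values (the natural-parameter scale)."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(values)):
            raise ValueError("logit frequencies must be finite")
        self.values = values


# ---------------------------------------------------------------------------
# PLINK 1 binary


def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK 1 binary triplet (SNP-major) into a GenotypeMatrix.

    Genotypes count the BIM A1 (first/counted) allele; the PLINK missing
    code becomes :data:`MISSING`.  ``bim_path``/``fam_path`` default to the
    BED path with swapped extensions.
    """
    bed_path = os.fspath(bed_path)
    stem = bed_path[:-4] if bed_path.endswith(".bed") else bed_path
    bim_path = bim_path or stem + ".bim"
    fam_path = fam_path or stem + ".fam"

    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    snp_ids = bim.iloc[:, 1].tolist()
    sample_ids = fam.iloc[:, 1].tolist()
    m, n = len(snp_ids), len(sample_ids)

    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        payload = fh.read()
    if header[:2] != _PLINK_MAGIC:
        raise ValueError(f"{bed_path}: not a PLINK BED file (bad magic bytes)")
    if header[2:3] != _PLINK_SNP_MAJOR:
        raise ValueError(f"{bed_path}: only SNP-major BED files are supported")

    bytes_per_snp = (n + 3) // 4
    if len(payload) != m * bytes_per_snp:
        raise ValueError(
            f"{bed_path}: payload is {len(payload)} bytes but BIM/FAM imply "
            f"{m} SNPs x {bytes_per_snp} bytes"
        )
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(m, bytes_per_snp)
    # Two-bit codes, sample j in bits 2*(j % 4) .. 2*(j % 4)+1 of byte j // 4.
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (raw >> (2 * shift)) & 0b11
    values = _BED_DECODE[codes[:, :n]]
    return GenotypeMatrix(values, snp_ids, sample_ids)


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write a GenotypeMatrix as a PLINK 1 binary triplet ``prefix``.bed/.bim/.fam."""
    prefix = os.fspath(prefix)
    m, n = G.m, G.n
    bytes_per_snp = (n + 3) // 4
    codes = np.full((m, bytes_per_snp * 4), _BED_ENCODE[MISSING], dtype=np.uint8)
    for g, code in _BED_ENCODE.items():
        codes[:, :n][G.values == g] = code
    raw = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        raw |= codes[:, shift::4] << (2 * shift)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC + _PLINK_SNP_MAJOR)
        fh.write(raw.tobytes())
    with open(prefix + ".bim", "w") as fh:
        for i, sid in enumerate(G.snp_ids):
            fh.write(f"1\t{sid}\t0\t{i + 1}\tA\tB\n")
    with open(prefix + ".fam", "w") as fh:
        for sid in G.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------------
# Delimited text


def read_matrix(path, delimiter=None, missing_code=MISSING) -> GenotypeMatrix:
    """Read a plain delimited genotype table (rows = SNPs, no headers)."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(delimiter)
            try:
                row = [int(f) for f in fields]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer entry") from exc
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty genotype matrix")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    values = np.array(rows, dtype=np.int64)
    values[values == missing_code] = MISSING
    bad = ~np.isin(values, (0, 1, 2, MISSING))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: entry {values[i, j]} at row {i + 1}, column {j + 1} is not "
            f"in {{0,1,2}} or the missing code"
        )
    return GenotypeMatrix(values.astype(np.int8))


def write_matrix(G: GenotypeMatrix, path, delimiter="\t") -> None:
    """Write genotypes as a headerless delimited table (missing as -1)."""
    with _open_text(path, "wt") as fh:
        for row in G.values:
            fh.write(delimiter.join(str(int(v)) for v in row) + "\n")


def write_freqs(F: AlleleFreqMatrix, path, digits: int = 6) -> None:
    """Write an allele-frequency matrix as TSV with SNP/sample headers.

    Values are fixed-point with ``digits`` decimals (default 6).
    """
    values = np.asarray(F.values, dtype=np.float64)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    snp_ids = F.snp_ids or [f"snp_{i}" for i in range(values.shape[0])]
    sample_ids = F.sample_ids or [f"sample_{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=snp_ids, columns=sample_ids)
    df.index.name = "snp_id"
    df.to_csv(path, sep="\t", float_format=f"%.{digits}f")


def read_freqs(path, provenance="simulated") -> AlleleFreqMatrix:
    """Read a frequency table written by :func:`write_freqs`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AlleleFreqMatrix(
        df.to_numpy(dtype=np.float64),
        provenance=provenance,
        snp_ids=df.index.tolist(),
        sample_ids=df.columns.tolist(),
    )
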