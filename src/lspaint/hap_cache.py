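"""Bit-packed, variant-major storage for phased biallelic haplotypes.

The panel is an ``L x N`` matrix of 0/1 alleles (``L`` variants, ``N``
haplotypes).  Each variant row is packed 32 haplotypes per unsigned 32-bit
word, little-endian within the word (haplotype ``j`` lives in word ``j // 32``
at bit ``j % 32``), and each row is padded to a 32-byte boundary so that a
row always occupies a multiple of 8 words.  Pad bits are zeroed, which makes
whole-word operations on rows safe.

Variant-major orientation matches the access pattern of the forward/backward
recursions, which sweep variant by variant.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "HaplotypeCache",
    "cache_haplotypes",
    "query_cache",
    "read_hap_gz",
    "write_hap_gz",
    "read_haps_h5",
    "write_haps_h5",
]

_WORD_BITS = 32
_ALIGN_WORDS = 8  # 32-byte row alignment


def _stride_for(num_haps: int) -> int:
    """Smallest multiple of 8 words covering ``num_haps`` bits."""
    words = -(-num_haps // _WORD_BITS)
    return -(-words // _ALIGN_WORDS) * _ALIGN_WORDS


@dataclass(frozen=True)
class HaplotypeCache:
    """Variant-major bit-packed haplotype panel.

    Attributes
    ----------
    packed_words
        ``(num_variants, stride)`` array of uint32 words; pad bits are zero.
    num_haps
        Number of haplotypes ``N`` (columns of the logical matrix).
    num_variants
        Number of variants ``L`` (rows of the logical matrix).
    stride
        Words per variant row, a multiple of 8.
    """

    packed_words: np.ndarray
    num_haps: int
    num_variants: int
    stride: int

    def variant_row(self, variant: int) -> np.ndarray:
        """Unpack one variant row to a length-``N`` 0/1 int8 vector."""
        if not 0 <= variant < self.num_variants:
            raise IndexError(
                f"variant index {variant} out of range [0, {self.num_variants})"
            )
        row_bytes = self.packed_words[variant].view(np.uint8)
        bits = np.unpackbits(row_bytes, bitorder="little")
        return bits[: self.num_haps].astype(np.int8)


def _validate_matrix(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat)
    if mat.ndim != 2:
        raise ValueError(f"haplotype matrix must be 2-D, got shape {mat.shape}")
    bad = (mat != 0) & (mat != 1)
    if bad.any():
        ell, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary haplotype value {mat[ell, j]!r} at variant {ell}, "
            f"haplotype {j} (0-based)"
        )
    L, N = mat.shape
    if N < 2:
        raise ValueError(
            f"need at least 2 haplotypes (got N={N}): with a single haplotype "
            "there are no donors and the copying model is undefined"
        )
    if L < 1:
        raise ValueError("need at least one variant")
    return mat.astype(np.uint8)


def cache_haplotypes(source, orientation: str = "variant-major") -> HaplotypeCache:
    """Load a haplotype panel into the packed variant-major cache.

    Parameters
    ----------
    source
        One of: an ``L x N`` 0/1 matrix; a path to a gzipped IMPUTE-style
        ``.hap.gz`` text file (one variant per line); or a path to an HDF5
        file with dataset ``"haps"``.
    orientation
        ``"variant-major"`` if rows of the source are variants (the native
        layout), ``"hap-major"`` if the source is transposed.

    Returns
    -------
    HaplotypeCache
        Bit-exact packed copy of the source; retrievable via
        :func:`query_cache`.
    """
    if orientation not in ("variant-major", "hap-major"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if isinstance(source, (str, Path)):
        name = str(source)
        if name.endswith((".h5", ".hdf5")):
            mat = read_haps_h5(source)
        else:
            mat = read_hap_gz(source)
    else:
        mat = np.asarray(source)
    if orientation == "hap-major":
        mat = np.asarray(mat).T
    mat = _validate_matrix(mat)
    L, N = mat.shape
    stride = _stride_for(N)
    padded = np.zeros((L, stride * _WORD_BITS), dtype=np.uint8)
    padded[:, :N] = mat
    packed_bytes = np.packbits(padded, axis=1, bitorder="little")
    # assemble little-endian uint32 words explicitly (endianness-independent)
    b = packed_bytes.reshape(L, stride, 4).astype(np.uint32)
    words = b[:, :, 0] | (b[:, :, 1] << 8) | (b[:, :, 2] << 16) | (b[:, :, 3] << 24)
    words = np.ascontiguousarray(words, dtype=np.uint32)
    words.setflags(write=False)
    return HaplotypeCache(
        packed_words=words, num_haps=N, num_variants=L, stride=stride
    )


def _as_range(idx, upper: int, what: str) -> range:
    if idx is None:
        return range(upper)
    if isinstance(idx, slice):
        idx = range(*idx.indices(upper))
    if isinstance(idx, range):
        if len(idx) and (min(idx) < 0 or max(idx) >= upper):
            raise IndexError(
                f"{what} range [{idx.start}, {idx.stop}) out of bounds [0, {upper})"
            )
        return idx
    raise TypeError(f"{what} index must be None, slice or range, got {type(idx)}")


def query_cache(cache: HaplotypeCache, variants=None, haps=None) -> np.ndarray:
    """Extract a 0/1 sub-matrix from the packed cache.

    ``variants`` and ``haps`` are half-open ranges (``range``/``slice``/
    ``None`` for the full extent).  Querying the full extent returns exactly
    the matrix that was cached.
    """
    vr = _as_range(variants, cache.num_variants, "variant")
    hr = _as_range(haps, cache.num_haps, "haplotype")
    out = np.empty((len(vr), len(hr)), dtype=np.int8)
    hsel = np.asarray(hr, dtype=np.intp)
    for k, ell in enumerate(vr):
        row = cache.variant_row(ell)
        out[k] = row[hsel] if len(hsel) else row[:0]
    return out


def read_hap_gz(path) -> np.ndarray:
    """Parse a gzipped IMPUTE-style .hap file: one variant per line, N
    space-separated 0/1 tokens.  Lines are validated; errors name the
    offending 1-based line."""
    rows: list[np.ndarray] = []
    width = None
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if any(t not in ("0", "1") for t in toks):
                bad = next(t for t in toks if t not in ("0", "1"))
                raise ValueError(
                    f"line {lineno}: token {bad!r} is not a 0/1 allele"
                )
            if width is None:
                width = len(toks)
            elif len(toks) != width:
                raise ValueError(
                    f"line {lineno}: expected {width} fields, got {len(toks)}"
                )
            rows.append(np.array(toks, dtype=np.int8))
    if not rows:
        raise ValueError(f"{path}: no variant lines found")
    return np.vstack(rows)


def write_hap_gz(matrix, path) -> None:
    """Write an ``L x N`` 0/1 matrix as gzipped .hap text."""
    mat = _validate_matrix(np.asarray(matrix))
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for row in mat:
            fh.write(" ".join("1" if v else "0" for v in row))
            fh.write("\n")


def read_haps_h5(path) -> np.ndarray:
    """Read dataset ``"haps"`` (L x N) from the package HDF5 container."""
    with h5py.File(path, "r") as f:
        if "haps" not in f:
            raise ValueError(f"{path}: missing dataset 'haps'")
        mat = f["haps"][...]
    return np.asarray(mat)


def write_haps_h5(matrix, path) -> None:
    """Write the panel to HDF5: dataset ``"haps"`` (L x N int8), scalar
    attributes ``N`` and ``L``."""
    mat = _validate_matrix(np.asarray(matrix))
    L, N = mat.shape
    with h5py.File(path, "w") as f:
        d = f.create_dataset("haps", data=mat.astype(np.int8))
        d.attrs["N"] = N
        d.attrs["L"] = L
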