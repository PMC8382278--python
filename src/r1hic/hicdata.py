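"""Contact-map data model, SCN normalization and the symmetric
divide-and-merge submatrix pipeline.

An intra-chromosomal Hi-C contact map is a dense, symmetric, non-negative
matrix ``C`` of shape ``N x N`` whose entry ``C[i, j]`` counts contacts
between genomic bins ``i`` and ``j`` at a fixed bin size.  This module owns:

* :class:`ContactMap` / :class:`BiasVector` / :class:`SubmatrixPair` types;
* SCN (sequential component normalization) — an iterative symmetric
  matrix-balancing scheme that factors out per-bin coverage biases ``b`` so
  that the normalized map is ``C / (b b^T)`` with unit row sums — and its
  exact reversion ``X * (b b^T)``;
* the divide-and-merge tiling that cuts a chromosome-scale matrix into
  symmetric ``n x n`` training submatrices (two diagonal blocks joined with
  their off-diagonal block) restricted to a genomic-distance band, and the
  inverse assembly of predicted submatrices back to chromosome scale;
* readers/writers for dense text, NPZ and single-resolution cooler (HDF5)
  files, plus a BED-like export of the bias vector.

Coordinates are 0-based, half-open bin intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactMap",
    "BiasVector",
    "SubmatrixPair",
    "DegenerateMatrixError",
    "scn_normalize",
    "scn_denormalize",
    "divide_submatrices",
    "enumerate_block_pairs",
    "assemble_prediction",
    "read_matrix",
    "write_matrix",
    "read_cool",
    "write_cool",
    "write_bias_bed",
]


class DegenerateMatrixError(ValueError):
    """Raised when an operation receives a matrix it cannot meaningfully
    process (e.g. normalizing an all-zero map)."""


@dataclass
class ContactMap:
    """Dense symmetric non-negative intra-chromosomal contact matrix."""

    chrom: str
    bin_size: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"counts must be square, got {self.counts.shape}")
        if self.counts.shape[0] < 1:
            raise ValueError("contact map needs at least one bin")
        if int(self.bin_size) <= 0:
            raise ValueError("bin_size must be a positive integer")
        self.bin_size = int(self.bin_size)
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T, rtol=1e-10, atol=1e-10):
            raise ValueError("contact matrix must be symmetric")

    @property
    def N(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def empty_rows(self) -> np.ndarray:
        """Boolean mask of unmappable (all-zero) bins."""
        return self.counts.sum(axis=1) == 0


@dataclass
class BiasVector:
    """Per-bin multiplicative bias estimated by SCN.

    ``b[i] == 1`` for bins excluded from normalization (all-zero rows).
    """

    b: np.ndarray
    converged: bool
    iterations: int

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.b.ndim != 1:
            raise ValueError("bias must be a vector")
        if np.any(self.b <= 0):
            raise ValueError("bias entries must be strictly positive")


@dataclass
class SubmatrixPair:
    """One training/inference sample produced by divide-and-merge.

    ``hr_target`` is the symmetric ``n x n`` merge of fine-binned diagonal
    blocks ``(i, i)``, ``(j, j)`` and their off-diagonal block ``(i, j)``;
    ``lr_input`` is the ``m x m`` (``m = n/4``) coarse-binned matrix over the
    identical genomic span; ``lr_down2``/``lr_down4`` are average-pooled
    views of ``lr_input`` used as ground truth for multi-scale rank-1
    feature estimation.
    """

    block_pair: tuple[int, int]
    hr_target: np.ndarray
    lr_input: np.ndarray
    lr_down2: np.ndarray = field(repr=False, default=None)
    lr_down4: np.ndarray = field(repr=False, default=None)
    genomic_start: int = 0

    def __post_init__(self):
        self.hr_target = np.asarray(self.hr_target, dtype=np.float64)
        self.lr_input = np.asarray(self.lr_input, dtype=np.float64)
        m = self.lr_input.shape[0]
        if m % 4 != 0:
            raise ValueError("lr_input side must be divisible by 4")
        if self.hr_target.shape[0] != 4 * m:
            raise ValueError("hr_target side must be 4x the lr_input side")
        if self.lr_down2 is None:
            self.lr_down2 = _avgpool(self.lr_input, 2)
        if self.lr_down4 is None:
            self.lr_down4 = _avgpool(self.lr_input, 4)

    @property
    def m(self) -> int:
        return self.lr_input.shape[0]


def _avgpool(x: np.ndarray, f: int) -> np.ndarray:
    n = x.shape[0]
    if n % f:
        raise ValueError(f"pool factor {f} does not divide side {n}")
    return x.reshape(n // f, f, n // f, f).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# SCN normalization
# ---------------------------------------------------------------------------

def scn_normalize(
    cmap: ContactMap, tol: float = 1e-6, max_iter: int = 300
) -> tuple[ContactMap, BiasVector]:
    """Balance a contact map so every non-empty row sums to one.

    Uses symmetric alternating L1 scaling: each iteration divides the matrix
    by ``sqrt(s) sqrt(s)^T`` where ``s`` is the current row-sum vector, and
    accumulates ``sqrt(s)`` into the bias ``b``.  At the fixed point the
    normalized matrix equals ``C / (b b^T)`` elementwise with unit row sums,
    so the reversion is the exact elementwise product ``X * (b b^T)``.

    All-zero rows (unmappable bins) are left untouched with bias one.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    X = cmap.counts.astype(np.float64, copy=True)
    N = X.shape[0]
    nonempty = X.sum(axis=1) > 0
    if not nonempty.any():
        raise DegenerateMatrixError("cannot normalize an all-zero matrix")
    b = np.ones(N)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = X.sum(axis=1)
        dev = np.abs(s[nonempty] - 1.0).max()
        if dev < tol:
            converged = True
            break
        scale = np.where(nonempty, np.sqrt(np.where(nonempty, s, 1.0)), 1.0)
        X /= np.outer(scale, scale)
        b *= scale
    out = ContactMap(cmap.chrom, cmap.bin_size, 0.5 * (X + X.T))
    return out, BiasVector(b=b, converged=converged, iterations=it)


def scn_denormalize(X, bias: BiasVector) -> np.ndarray:
    """Reverse SCN: ``out[i, j] = X[i, j] * b[i] * b[j]``."""
    mat = X.counts if isinstance(X, ContactMap) else np.asarray(X, dtype=np.float64)
    b = bias.b
    if mat.shape[0] != b.shape[0] or mat.shape[1] != b.shape[0]:
        raise ValueError(
            f"matrix shape {mat.shape} incompatible with bias length {b.shape[0]}"
        )
    return mat * np.outer(b, b)


# ---------------------------------------------------------------------------
# Divide-and-merge submatrix pipeline
# ---------------------------------------------------------------------------

def enumerate_block_pairs(
    N: int, half: int, bin_size: int, max_distance_bp: int
) -> list[tuple[int, int]]:
    """All block pairs (i, j), i < j, on the half-block tiling whose
    off-diagonal block starts within the genomic distance cutoff.

    Distance of block pair ``(i, j)`` is start-to-start:
    ``(j - i) * half * bin_size``.  Trailing bins not filling a whole block
    are dropped.
    """
    nblocks = N // half
    pairs = []
    for i in range(nblocks):
        for j in range(i + 1, nblocks):
            if (j - i) * half * bin_size > max_distance_bp:
                break
            pairs.append((i, j))
    return pairs


def _merge_blocks(M: np.ndarray, half: int, i: int, j: int) -> np.ndarray:
    out = np.empty((2 * half, 2 * half), dtype=np.float64)
    si, sj = slice(i * half, (i + 1) * half), slice(j * half, (j + 1) * half)
    out[:half, :half] = M[si, si]
    out[half:, half:] = M[sj, sj]
    out[:half, half:] = M[si, sj]
    out[half:, :half] = M[si, sj].T
    return out


def divide_submatrices(
    hr: ContactMap,
    lr: ContactMap,
    n: int = 400,
    max_distance_bp: int = 2_000_000,
) -> list[SubmatrixPair]:
    """Cut matched fine/coarse maps into symmetric training submatrices.

    The fine map is tiled into non-overlapping blocks of side ``n/2``; each
    retained pair of diagonal blocks is merged with its off-diagonal block
    into one symmetric ``n x n`` target.  The coarse map (4x coarser bins
    over the same region) is tiled the same way at side ``n/8`` per block,
    giving ``m = n/4`` inputs covering the identical genomic span.  Pairs
    whose off-diagonal block starts beyond ``max_distance_bp`` are omitted.
    """
    if hr.bin_size * 4 != lr.bin_size:
        raise ValueError(
            f"expected lr bin size 4x the hr bin size, got {hr.bin_size} vs {lr.bin_size}"
        )
    if n % 8:
        raise ValueError("submatrix side n must be divisible by 8")
    if hr.N < n:
        raise ValueError(f"fine map has {hr.N} bins, need at least n={n}")
    half_hr = n // 2
    half_lr = n // 8
    nblocks = min(hr.N // half_hr, lr.N // half_lr)
    pairs = [
        p
        for p in enumerate_block_pairs(hr.N, half_hr, hr.bin_size, max_distance_bp)
        if p[1] < nblocks
    ]
    out = []
    for (i, j) in pairs:
        out.append(
            SubmatrixPair(
                block_pair=(i, j),
                hr_target=_merge_blocks(hr.counts, half_hr, i, j),
                lr_input=_merge_blocks(lr.counts, half_lr, i, j),
                genomic_start=i * half_hr * hr.bin_size,
            )
        )
    return out


def assemble_prediction(
    preds: list[tuple[tuple[int, int], np.ndarray]],
    N: int,
    bin_size: int = 10_000,
    chrom: str = "chrS",
) -> tuple[ContactMap, np.ndarray]:
    """Stitch predicted ``n x n`` submatrices back into an ``N x N`` map.

    Entries covered by several submatrices (diagonal blocks shared by
    consecutive pairs) are averaged; uncovered entries stay zero and are
    reported in the boolean coverage mask.
    """
    if not preds:
        raise ValueError("no predictions to assemble")
    n = preds[0][1].shape[0]
    half = n // 2
    acc = np.zeros((N, N))
    cnt = np.zeros((N, N))
    for (i, j), mat in preds:
        mat = np.asarray(mat, dtype=np.float64)
        if mat.shape != (n, n):
            raise ValueError(f"prediction for pair {(i, j)} has shape {mat.shape}")
        if max(i, j) * half + half > N or i < 0 or j <= i:
            raise ValueError(f"block pair {(i, j)} invalid for N={N}")
        mat = 0.5 * (mat + mat.T)
        si, sj = slice(i * half, (i + 1) * half), slice(j * half, (j + 1) * half)
        for (ra, ca), q in (
            ((si, si), mat[:half, :half]),
            ((sj, sj), mat[half:, half:]),
            ((si, sj), mat[:half, half:]),
            ((sj, si), mat[half:, :half]),
        ):
            acc[ra, ca] += q
            cnt[ra, ca] += 1
    mask = cnt > 0
    acc[mask] /= cnt[mask]
    acc = 0.5 * (acc + acc.T)
    acc[acc < 0] = 0.0
    return ContactMap(chrom, bin_size, acc), mask


# ---------------------------------------------------------------------------
# I/O: dense text, NPZ, single-resolution cooler, bias BED
# ---------------------------------------------------------------------------

def write_matrix(cmap: ContactMap, path: str) -> None:
    """Write a contact map as NPZ (``.npz``) or dense TSV (anything else).

    The TSV form stores metadata in ``#`` header lines.
    """
    path = str(path)
    if path.endswith(".npz"):
        np.savez_compressed(
            path, counts=cmap.counts, bin_size=cmap.bin_size, chrom=cmap.chrom
        )
    else:
        header = f"chrom={cmap.chrom}\nbin_size={cmap.bin_size}"
        np.savetxt(path, cmap.counts, fmt="%.10g", delimiter="\t", header=header)


def read_matrix(path: str, chrom: str | None = None, bin_size: int | None = None) -> ContactMap:
    """Read a contact map written by :func:`write_matrix` or a cooler file."""
    path = str(path)
    if path.endswith(".cool"):
        return read_cool(path, chrom=chrom)
    if path.endswith(".npz"):
        with np.load(path) as z:
            return ContactMap(str(z["chrom"]), int(z["bin_size"]), z["counts"])
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("# ").strip().split("=", 1)
                meta[k] = v
    counts = np.loadtxt(path, delimiter="\t")
    return ContactMap(
        chrom or meta.get("chrom", "chr?"),
        int(bin_size or meta.get("bin_size", 1)),
        np.atleast_2d(counts),
    )


def write_cool(cmap: ContactMap, path: str, assembly: str = "synthetic") -> None:
    """Write a minimal single-resolution cooler (HDF5) file."""
    import h5py

    N = cmap.N
    iu = np.triu_indices(N)
    vals = cmap.counts[iu]
    keep = vals != 0
    b1, b2, vals = iu[0][keep], iu[1][keep], vals[keep]
    order = np.lexsort((b2, b1))
    b1, b2, vals = b1[order], b2[order], vals[order]
    bin1_offset = np.searchsorted(b1, np.arange(N + 1))
    with h5py.File(path, "w") as f:
        f.attrs.update(
            {
                "format": "HDF5::Cooler",
                "format-version": 3,
                "bin-type": "fixed",
                "bin-size": cmap.bin_size,
                "nbins": N,
                "nchroms": 1,
                "nnz": len(vals),
                "genome-assembly": assembly,
            }
        )
        chroms = f.create_group("chroms")
        chroms.create_dataset(
            "name", data=np.array([cmap.chrom.encode()]), dtype="S32"
        )
        chroms.create_dataset("length", data=np.array([N * cmap.bin_size], dtype="i8"))
        bins = f.create_group("bins")
        bins.create_dataset("chrom", data=np.zeros(N, dtype="i4"))
        starts = np.arange(N, dtype="i8") * cmap.bin_size
        bins.create_dataset("start", data=starts)
        bins.create_dataset("end", data=starts + cmap.bin_size)
        pixels = f.create_group("pixels")
        pixels.create_dataset("bin1_id", data=b1.astype("i8"))
        pixels.create_dataset("bin2_id", data=b2.astype("i8"))
        pixels.create_dataset("count", data=vals)
        indexes = f.create_group("indexes")
        indexes.create_dataset("chrom_offset", data=np.array([0, N], dtype="i8"))
        indexes.create_dataset("bin1_offset", data=bin1_offset.astype("i8"))


def read_cool(path: str, chrom: str | None = None) -> ContactMap:
    """Read one chromosome's dense matrix from a single-resolution cooler."""
    import h5py

    with h5py.File(path, "r") as f:
        bin_size = int(f.attrs["bin-size"])
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["chroms/name"][:]]
        if chrom is None:
            if len(names) != 1:
                raise ValueError(f"file has chromosomes {names}; pass chrom=")
            chrom = names[0]
        cid = names.index(chrom)
        chrom_offset = f["indexes/chrom_offset"][:]
        lo, hi = int(chrom_offset[cid]), int(chrom_offset[cid + 1])
        bin1_offset = f["indexes/bin1_offset"][:]
        plo, phi = int(bin1_offset[lo]), int(bin1_offset[hi])
        b1 = f["pixels/bin1_id"][plo:phi] - lo
        b2 = f["pixels/bin2_id"][plo:phi] - lo
        vals = f["pixels/count"][plo:phi]
        intra = b2 < (hi - lo)
        N = hi - lo
        counts = np.zeros((N, N))
        counts[b1[intra], b2[intra]] = vals[intra]
        counts = counts + np.triu(counts, 1).T
    return ContactMap(chrom, bin_size, counts)


def write_bias_bed(bias: BiasVector, cmap: ContactMap, path: str) -> None:
    """Export the bias vector as a BED-like TSV (chrom, start, end, bias)."""
    with open(path, "w") as fh:
        for i, v in enumerate(bias.b):
            s = i * cmap.bin_size
            fh.write(f"{cmap.chrom}\t{s}\t{s + cmap.bin_size}\t{v:.10g}\n")
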