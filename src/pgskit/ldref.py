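"""LD reference: windowed sparse correlation, independent blocks, shrinkage,
LD scores, and the compact on-disk SFBM format.

The correlation matrix is windowed on genetic distance (default 3 cM): pairs
farther apart are assumed uncorrelated and never stored.  Splitting the
matrix into nearly independent contiguous blocks, by a dynamic program that
minimizes ``weight * C2 + C1`` (C1 = squared correlation lost outside blocks,
C2 = sum of squared block sizes), keeps iterative solvers from propagating
small errors across the whole chromosome.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from ._kernels import block_inside_sums, split_dp_counted, split_dp_free

__all__ = [
    "LDMatrix",
    "BlockSplit",
    "build_ld",
    "split_blocks",
    "apply_blocks",
    "shrink_offdiag",
    "ld_scores",
    "sfbm_write",
    "sfbm_read",
    "SfbmFormatError",
]


@dataclass
class LDMatrix:
    """Sparse symmetric correlation matrix with genetic positions.

    ``blocks`` (optional) assigns a block id per variant; ``shrink`` records
    the cumulative off-diagonal shrink factor already applied to ``matrix``.
    """

    matrix: sp.csc_matrix
    pos_cm: np.ndarray
    window_cm: float = 3.0
    blocks: np.ndarray | None = None
    shrink: float = 1.0
    monomorphic: np.ndarray | None = None

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[0]

    def validate(self) -> None:
        R = self.matrix
        if (abs(R - R.T) > 1e-12).nnz:
            raise ValueError("matrix must be symmetric")
        if not np.allclose(R.diagonal(), 1.0):
            raise ValueError("diagonal must be exactly 1")
        if R.data.size and (np.max(np.abs(R.data)) > 1.0 + 1e-12):
            raise ValueError("entries must lie in [-1, 1]")
        coo = R.tocoo()
        d = np.abs(self.pos_cm[coo.row] - self.pos_cm[coo.col])
        if np.any(d > self.window_cm + 1e-12):
            raise ValueError("stored entry beyond the window")
        if self.blocks is not None:
            if np.any(self.blocks[coo.row] != self.blocks[coo.col]):
                raise ValueError("stored entry crosses a block boundary")

    def csc_arrays(self):
        R = self.matrix
        if not sp.issparse(R) or R.format != "csc":
            R = sp.csc_matrix(R)
        R.sort_indices()
        return R.indptr.astype(np.int64), R.indices.astype(np.int64), \
            R.data.astype(np.float64)


def build_ld(panel_or_matrix, genetic_pos: np.ndarray | None = None,
             window_cm: float = 3.0) -> LDMatrix:
    """Windowed Pearson correlation of genotype/dosage columns.

    Pairs farther apart than ``window_cm`` are exact zeros (never stored).
    Monomorphic variants keep only their unit diagonal and are flagged.
    """
    if hasattr(panel_or_matrix, "genotypes"):
        X = panel_or_matrix.genotypes
        if genetic_pos is None:
            genetic_pos = panel_or_matrix.pos_cm
    elif hasattr(panel_or_matrix, "dosages"):
        X = panel_or_matrix.dosages
        if genetic_pos is None:
            genetic_pos = panel_or_matrix.pos_cm
    else:
        X = np.asarray(panel_or_matrix)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")
    pos = np.asarray(genetic_pos, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("genetic positions must be non-decreasing")
    Z = X.astype(np.float64) - X.mean(axis=0, dtype=np.float64)
    sd = Z.std(axis=0)
    mono = sd == 0
    sd_safe = np.where(mono, 1.0, sd)
    Z /= sd_safe * np.sqrt(n)
    Z[:, mono] = 0.0

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    # right-neighbour extent of the window per column
    hi = np.searchsorted(pos, pos + window_cm + 1e-12, side="right")
    chunk = max(1, min(m, int(2e7 / max(n, 1))))
    j = 0
    while j < m:
        j2 = min(m, j + chunk)
        kmax = int(hi[j:j2].max())
        block = Z[:, j:kmax].T @ Z[:, j:j2]  # (kmax-j) x (j2-j)
        for c in range(j, j2):
            k0, k1 = c + 1, hi[c]
            if k1 <= k0:
                continue
            r = block[k0 - j:k1 - j, c - j]
            nz = np.flatnonzero(r != 0.0)
            if nz.size:
                rr = (k0 + nz).astype(np.int64)
                vv = np.clip(r[nz], -1.0, 1.0)
                rows.append(rr)
                cols.append(np.full(nz.size, c, dtype=np.int64))
                vals.append(vv)
        j = j2
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        v = np.concatenate(vals)
        # symmetrize and add the unit diagonal
        ri = np.concatenate([r, c, np.arange(m)])
        ci = np.concatenate([c, r, np.arange(m)])
        vi = np.concatenate([v, v, np.ones(m)])
    else:
        ri = ci = np.arange(m)
        vi = np.ones(m)
    R = sp.csc_matrix((vi, (ri, ci)), shape=(m, m))
    R.sort_indices()
    return LDMatrix(matrix=R, pos_cm=pos, window_cm=window_cm,
                    monomorphic=mono if mono.any() else None)


@dataclass
class BlockSplit:
    """A contiguous partition of variants with its cost components."""

    boundaries: np.ndarray  # k+1 indices, 0 ... M
    sizes: np.ndarray
    C1: float  # sum of squared correlations outside blocks (unordered pairs)
    C2: float  # sum of squared block sizes
    weight: float
    max_r2: float
    feasible: bool
    binding_pair: tuple[int, int] | None = None

    @property
    def cost(self) -> float:
        return self.weight * self.C2 + self.C1

    @property
    def n_blocks(self) -> int:
        return len(self.sizes)

    def block_ids(self) -> np.ndarray:
        m = int(self.boundaries[-1])
        ids = np.empty(m, dtype=np.int64)
        for b in range(self.n_blocks):
            ids[self.boundaries[b]:self.boundaries[b + 1]] = b
        return ids


def _total_offdiag_sq(ld: LDMatrix) -> float:
    coo = ld.matrix.tocoo()
    off = coo.row < coo.col
    return float(np.sum(coo.data[off] ** 2))


def split_blocks(ld: LDMatrix, max_block_size: int,
                 n_blocks_range=None, max_r2: float = 0.3,
                 weight: float = 5.0) -> BlockSplit:
    """Optimal contiguous partition minimizing ``weight * C2 + C1``.

    An exact dynamic program over split points.  ``max_r2`` forbids any
    outside-block squared correlation above the threshold: boundaries spanned
    by such a pair are disallowed.  If no partition satisfies the constraints
    the result carries ``feasible=False`` and the binding pair.
    ``n_blocks_range`` restricts the number of blocks (iterable of ints);
    None allows any number.
    """
    if max_block_size < 1:
        raise ValueError("max_block_size must be >= 1")
    m = ld.n_variants
    indptr, indices, data = ld.csc_arrays()
    total_sq = _total_offdiag_sq(ld)

    # boundary t (1..m-1) is forbidden if a high-r2 pair spans it
    allowed = np.ones(m + 1, dtype=bool)
    binding = None
    coo = ld.matrix.tocoo()
    strong = (coo.row < coo.col) & (coo.data**2 > max_r2)
    for a, b in zip(coo.row[strong], coo.col[strong]):
        allowed[a + 1:b + 1] = False
        if b - a + 1 > max_block_size and binding is None:
            binding = (int(a), int(b))

    S = block_inside_sums(indptr, indices, data, int(max_block_size))

    INF = np.inf
    if n_blocks_range is None:
        f, prev = split_dp_free(S, allowed, int(max_block_size),
                                float(weight), m)
        if f[m] == INF:
            return BlockSplit(boundaries=np.array([0, m]), sizes=np.array([m]),
                              C1=total_sq, C2=float(m) ** 2, weight=weight,
                              max_r2=max_r2, feasible=False,
                              binding_pair=binding)
        bounds = [m]
        while bounds[0] != 0:
            bounds.insert(0, int(prev[bounds[0]]))
        bounds = np.array(bounds, dtype=np.int64)
    else:
        ks = sorted(set(int(k) for k in n_blocks_range))
        if not ks or ks[0] < 1:
            raise ValueError("n_blocks_range must contain positive ints")
        kmax = ks[-1]
        f, prev = split_dp_counted(S, allowed, int(max_block_size),
                                   float(weight), m, int(kmax))
        best_k, best_cost = None, INF
        for k in ks:
            if k <= kmax and f[k, m] < best_cost:
                best_cost = f[k, m]
                best_k = k
        if best_k is None:
            return BlockSplit(np.array([0, m]), np.array([m]), C1=total_sq,
                              C2=float(m) ** 2, weight=weight, max_r2=max_r2,
                              feasible=False, binding_pair=binding)
        bounds = [m]
        k = best_k
        while bounds[0] != 0:
            bounds.insert(0, int(prev[k, bounds[0]]))
            k -= 1
        bounds = np.array(bounds, dtype=np.int64)

    sizes = np.diff(bounds)
    inside = float(sum(S[bounds[b], sizes[b] - 1] for b in range(len(sizes))))
    C1 = total_sq - inside
    C2 = float(np.sum(sizes.astype(float) ** 2))
    return BlockSplit(boundaries=bounds, sizes=sizes, C1=C1, C2=C2,
                      weight=weight, max_r2=max_r2, feasible=True,
                      binding_pair=None)


def apply_blocks(ld: LDMatrix, split: BlockSplit) -> LDMatrix:
    """Zero all entries crossing block boundaries; records the fraction of
    non-zeros kept in ``meta`` via the returned matrix."""
    if int(split.boundaries[-1]) != ld.n_variants:
        raise ValueError("split does not cover the matrix")
    ids = split.block_ids()
    coo = ld.matrix.tocoo()
    keep = ids[coo.row] == ids[coo.col]
    nnz_before = coo.nnz
    R = sp.csc_matrix((coo.data[keep], (coo.row[keep], coo.col[keep])),
                      shape=ld.matrix.shape)
    R.sort_indices()
    out = replace(ld, matrix=R, blocks=ids)
    out.kept_fraction = (R.nnz / nnz_before) if nnz_before else 1.0
    return out


def shrink_offdiag(ld: LDMatrix, c: float) -> LDMatrix:
    """Multiply off-diagonal entries by c (diagonal untouched); the result is
    c*R + (1-c)*I, so c=0 yields the identity matrix."""
    if not (0.0 <= c <= 1.0):
        raise ValueError("shrink factor must lie in [0, 1]")
    if c == 1.0:
        return replace(ld, shrink=ld.shrink)
    R = ld.matrix.copy().tocsc()
    R.data = R.data * c
    R.setdiag(1.0)
    if c == 0.0:
        R.eliminate_zeros()
    R.sort_indices()
    return replace(ld, matrix=R, shrink=ld.shrink * c)


def ld_scores(ld: LDMatrix) -> np.ndarray:
    """l_j = sum_k r_jk^2 over stored entries, including the diagonal."""
    R = ld.matrix
    sq = R.copy()
    sq.data = sq.data**2
    return np.asarray(sq.sum(axis=0)).ravel()


MAGIC = b"SFBM"
VERSION = 1


class SfbmFormatError(ValueError):
    pass


def sfbm_write(ld: LDMatrix, path) -> None:
    """Compact sparse-column serialization.

    Layout (little-endian): magic 'SFBM', u32 version, u64 M; per column a
    record (u64 first-row index i0, u64 run length L, L float64 values
    covering rows i0..i0+L-1, interior zeros stored explicitly); then a
    trailing table of u64 byte offsets (one per column) and a final u64
    pointing at the table.  A sidecar JSON carries M, the window and a
    checksum of the variant grid.
    """
    R = sp.csc_matrix(ld.matrix)
    R.sort_indices()
    m = R.shape[1]
    path = str(path)
    offsets = np.empty(m, dtype="<u8")
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<I", VERSION))
        fh.write(struct.pack("<Q", m))
        for j in range(m):
            offsets[j] = fh.tell()
            lo, hi = R.indptr[j], R.indptr[j + 1]
            if hi == lo:
                fh.write(struct.pack("<QQ", 0, 0))
                continue
            rows = R.indices[lo:hi]
            i0, i1 = int(rows[0]), int(rows[-1])
            run = np.zeros(i1 - i0 + 1, dtype="<f8")
            run[rows - i0] = R.data[lo:hi]
            fh.write(struct.pack("<QQ", i0, run.size))
            fh.write(run.tobytes())
        table_at = fh.tell()
        fh.write(offsets.tobytes())
        fh.write(struct.pack("<Q", table_at))
    checksum = hashlib.sha256(
        np.ascontiguousarray(ld.pos_cm, dtype="<f8").tobytes()).hexdigest()
    sidecar = {
        "n_variants": int(m),
        "window_cm": float(ld.window_cm),
        "shrink": float(ld.shrink),
        "variant_checksum": checksum,
        "pos_cm": [float(x) for x in ld.pos_cm],
        "blocks": None if ld.blocks is None else [int(b) for b in ld.blocks],
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh)


def _sfbm_header(fh):
    head = fh.read(4)
    if head != MAGIC:
        raise SfbmFormatError(f"bad magic at byte 0: {head!r}")
    (version,) = struct.unpack("<I", fh.read(4))
    if version != VERSION:
        raise SfbmFormatError(f"unsupported version {version} at byte 4")
    (m,) = struct.unpack("<Q", fh.read(8))
    return m


def sfbm_read(path) -> LDMatrix:
    """Read a full SFBM file back into an LDMatrix (bit-identical values)."""
    path = str(path)
    with open(path, "rb") as fh:
        m = _sfbm_header(fh)
        rows, cols, vals = [], [], []
        for j in range(m):
            at = fh.tell()
            rec = fh.read(16)
            if len(rec) < 16:
                raise SfbmFormatError(f"truncated column header at byte {at}")
            i0, L = struct.unpack("<QQ", rec)
            if L:
                buf = fh.read(8 * L)
                if len(buf) < 8 * L:
                    raise SfbmFormatError(f"truncated column data at byte {at + 16}")
                run = np.frombuffer(buf, dtype="<f8")
                nz = np.flatnonzero(run != 0.0)
                rows.append(i0 + nz)
                cols.append(np.full(nz.size, j, dtype=np.int64))
                vals.append(run[nz])
    R = sp.csc_matrix(
        (np.concatenate(vals) if vals else np.empty(0),
         (np.concatenate(rows) if rows else np.empty(0, dtype=np.int64),
          np.concatenate(cols) if cols else np.empty(0, dtype=np.int64))),
        shape=(m, m))
    R.sort_indices()
    try:
        with open(path + ".json") as fh:
            side = json.load(fh)
        pos = np.asarray(side["pos_cm"], dtype=float)
        window = float(side["window_cm"])
        shrink = float(side.get("shrink", 1.0))
        blocks = side.get("blocks")
        blocks = None if blocks is None else np.asarray(blocks, dtype=np.int64)
    except FileNotFoundError:
        pos = np.arange(m, dtype=float)
        window = np.inf
        shrink = 1.0
        blocks = None
    return LDMatrix(matrix=R, pos_cm=pos, window_cm=window, blocks=blocks,
                    shrink=shrink)


def sfbm_read_column(path, j: int) -> np.ndarray:
    """Random access to one column via the trailing offset table; other
    columns' bytes are never read."""
    path = str(path)
    with open(path, "rb") as fh:
        m = _sfbm_header(fh)
        if not (0 <= j < m):
            raise IndexError(j)
        fh.seek(-8, 2)
        (table_at,) = struct.unpack("<Q", fh.read(8))
        fh.seek(table_at + 8 * j)
        (col_at,) = struct.unpack("<Q", fh.read(8))
        fh.seek(col_at)
        i0, L = struct.unpack("<QQ", fh.read(16))
        col = np.zeros(m)
        if L:
            run = np.frombuffer(fh.read(8 * L), dtype="<f8")
            col[i0:i0 + L] = run
        return col


def ld_to_mtx(ld: LDMatrix, path) -> None:
    mmwrite(str(path), sp.coo_matrix(ld.matrix))


def ld_from_mtx(path, pos_cm: np.ndarray | None = None,
                window_cm: float = np.inf) -> LDMatrix:
    R = sp.csc_matrix(mmread(str(path)))
    R.sort_indices()
    if pos_cm is None:
        pos_cm = np.arange(R.shape[0], dtype=float)
    return LDMatrix(matrix=R, pos_cm=np.asarray(pos_cm, dtype=float),
                    window_cm=window_cm)
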