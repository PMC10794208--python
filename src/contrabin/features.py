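"""Composition and coverage feature vectors for every view.

Composition: canonical tetranucleotide frequencies. A 4-mer and its reverse
complement are collapsed into one class, giving T = 136 classes for k = 4
(120 complementary pairs + 16 palindromes). Counts get a +1 pseudocount and
are normalized to sum to one, removing the effect of contig length.

Coverage: for each of the M sequencing samples, the per-base depth mean and
population standard deviation over the view's interval, computed directly
from the run-length encoding. The 2M-vector (M means, then M stds) is offset
by +1e-5 to avoid zero vectors, then every column is divided by its maximum
over the N *original* contig views — so augmented fragments are scaled by
the same divisor as their parents and the original-contig embedding does
not depend on which fragments were drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_COVERAGE_OFFSET = 1e-5


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass
class CanonicalKmerIndex:
    """Maps each of the 4^k k-mers to a canonical class id in [0, T)."""

    k: int
    lut: np.ndarray  # code -> class id, length 4^k
    T: int
    n_palindromes: int

    def class_of(self, kmer: str) -> int:
        code = 0
        for b in kmer:
            code = code * 4 + _BASE_CODE[b]
        return int(self.lut[code])


def build_canonical_index(k: int = 4) -> CanonicalKmerIndex:
    """Enumerate all 4^k k-mers and collapse reverse-complement pairs.

    The class count is (4^k - p)/2 + p with p palindromes (p = 16 for k = 4,
    giving T = 136), but classes are assigned by enumeration, not formula.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = 4 ** k
    codes = np.arange(n)
    # reverse complement of a code: reverse base order, complement each base
    rc = np.zeros(n, dtype=np.int64)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    canonical = np.minimum(codes, rc)
    uniq = np.unique(canonical)
    lut = np.zeros(n, dtype=np.int64)
    lut[uniq] = np.arange(uniq.size)
    lut = lut[canonical]
    n_pal = int(np.sum(rc == codes))
    return CanonicalKmerIndex(k=k, lut=lut, T=int(uniq.size), n_palindromes=n_pal)


def compute_tnf(seq: str, index: CanonicalKmerIndex,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Canonical k-mer frequency vector of one sequence.

    Sliding window of length k, stride 1; windows containing non-ACGT
    characters are skipped. Raises if no valid window exists.
    """
    k = index.k
    if len(seq) < k:
        raise ValueError("sequence shorter than k")
    base = np.frompyfunc(lambda c: _BASE_CODE.get(c, -1), 1, 1)
    b = base(np.array(list(seq))).astype(np.int64)
    n_win = len(seq) - k + 1
    codes = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for i in range(k):
        bi = b[i:i + n_win]
        codes = codes * 4 + np.where(bi >= 0, bi, 0)
        valid &= bi >= 0
    codes = codes[valid]
    if codes.size == 0:
        raise ValueError("no valid k-mer window (too many non-ACGT bases)")
    counts = np.bincount(index.lut[codes], minlength=index.T).astype(np.float64)
    counts += pseudocount
    return counts / counts.sum()


def coverage_stats(track, contig_id: str, start: int, end: int) -> tuple:
    """Per-base depth mean and population std over [start, end), computed
    from the run-length encoding without materializing per-base arrays."""
    if end <= start:
        raise ValueError("empty interval")
    starts, ends, depths = track.get_runs(contig_id)
    if start < 0 or end > ends[-1]:
        raise ValueError(f"interval [{start},{end}) outside contig {contig_id}")
    lo = np.searchsorted(ends, start, side="right")
    hi = np.searchsorted(starts, end, side="left")
    s = np.maximum(starts[lo:hi], start)
    e = np.minimum(ends[lo:hi], end)
    w = (e - s).astype(np.float64)
    d = depths[lo:hi]
    n = float(end - start)
    mean = float(np.dot(w, d) / n)
    var = float(np.dot(w, d * d) / n) - mean * mean
    return mean, float(np.sqrt(max(var, 0.0)))


def assemble_coverage(view_set, depth_tracks,
                      offset: float = DEFAULT_COVERAGE_OFFSET) -> np.ndarray:
    """Raw coverage matrix: one row per view (contig-major order), columns
    = M per-sample means then M per-sample stds, every entry offset by
    ``offset`` to avoid zero vectors."""
    if not depth_tracks:
        raise ValueError("at least one depth track required")
    M = len(depth_tracks)
    rows = []
    for view in view_set.flat():
        mean_part = np.empty(M)
        std_part = np.empty(M)
        for m, track in enumerate(depth_tracks):
            if view.parent_id not in track.runs:
                raise ValueError(
                    f"sample {track.sample_id} has no depth for contig {view.parent_id}")
            mu, sd = coverage_stats(track, view.parent_id, view.start, view.end)
            mean_part[m] = mu
            std_part[m] = sd
        rows.append(np.concatenate([mean_part, std_part]))
    return np.asarray(rows) + offset


def normalize_coverage(C: np.ndarray, view_indices: np.ndarray) -> np.ndarray:
    """Divide each column by its maximum over original-contig rows
    (view_index == 0); the same divisors rescale the augmented views, so
    all entries of original views land in (0, 1]."""
    C = np.asarray(C, dtype=np.float64)
    originals = np.asarray(view_indices) == 0
    if not originals.any():
        raise ValueError("no original (view 0) rows to normalize against")
    divisors = C[originals].max(axis=0)
    return C / divisors


@dataclass
class FeatureBlock:
    """Per-view feature matrices aligned with the ViewSet's flat row order."""

    x_com: np.ndarray   # (N*V, T) composition
    x_cov: np.ndarray   # (N*V, 2M) normalized coverage
    parent_ids: list
    view_indices: np.ndarray

    @property
    def n_views_total(self) -> int:
        return self.x_com.shape[0]

    @property
    def M(self) -> int:
        return self.x_cov.shape[1] // 2

    def original_rows(self) -> np.ndarray:
        return np.flatnonzero(self.view_indices == 0)


def build_features(view_set, depth_tracks, index: CanonicalKmerIndex | None = None,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   offset: float = DEFAULT_COVERAGE_OFFSET) -> FeatureBlock:
    """Compute composition + normalized coverage features for every view."""
    if index is None:
        index = build_canonical_index(4)
    flat = list(view_set.flat())
    x_com = np.asarray([compute_tnf(v.seq, index, pseudocount) for v in flat])
    view_indices = np.array([v.view_index for v in flat])
    C = assemble_coverage(view_set, depth_tracks, offset)
    x_cov = normalize_coverage(C, view_indices)
    return FeatureBlock(x_com=x_com, x_cov=x_cov,
                        parent_ids=[v.parent_id for v in flat],
                        view_indices=view_indices)
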