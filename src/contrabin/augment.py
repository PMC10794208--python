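"""Multi-view data augmentation.

Each contig yields V = n_aug + 1 views: the original sequence (view 0) plus
n_aug contiguous fragments sampled uniformly at random. Fragments of the
same contig are the positive pairs of the contrastive objective; fragment
coordinates are also what the feature stage uses to slice depth tracks, so
sequence and coverage views stay coherent.

Fragment law: length ~ Uniform[min_frag_len, contig_length] (inclusive),
then start ~ Uniform[0, contig_length - length]. Each contig gets its own
RNG stream derived from (seed, contig_id), so augmentation is independent
of contig order and parallel-safe.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass

import numpy as np

DEFAULT_N_AUG = 5
DEFAULT_MIN_FRAG_LEN = 1000


@dataclass(frozen=True)
class View:
    parent_id: str
    view_index: int
    start: int
    end: int
    seq: str


@dataclass
class ViewSet:
    """All views, grouped per contig in contig order; ``views[i][v]`` is
    view v of contig i. V is constant across contigs."""

    views: list  # list (per contig) of list[View]

    @property
    def n_contigs(self) -> int:
        return len(self.views)

    @property
    def V(self) -> int:
        return len(self.views[0]) if self.views else 0

    def flat(self):
        """Views in row order (contig-major), matching feature matrices."""
        for per_contig in self.views:
            yield from per_contig


def _contig_rng(seed: int, contig_id: str) -> np.random.Generator:
    h = int.from_bytes(hashlib.blake2b(contig_id.encode(), digest_size=8).digest(), "big")
    return np.random.default_rng([seed, h])


def augment_contigs(contigs, n_aug: int = DEFAULT_N_AUG,
                    min_frag_len: int = DEFAULT_MIN_FRAG_LEN,
                    seed: int = 0) -> ViewSet:
    """Build the view set: one original + ``n_aug`` random fragments per contig.

    Every contig must be at least ``min_frag_len`` bp (guaranteed upstream by
    the contig length filter when both thresholds are at their 1000 bp
    defaults). Fully reproducible under ``seed``.
    """
    all_views = []
    for cid, seq in zip(contigs.ids, contigs.seqs):
        L = len(seq)
        if L < min_frag_len:
            raise ValueError(f"contig {cid} shorter than min_frag_len={min_frag_len}")
        rng = _contig_rng(seed, cid)
        per = [View(cid, 0, 0, L, seq)]
        for v in range(1, n_aug + 1):
            frag_len = int(rng.integers(min_frag_len, L + 1))
            start = int(rng.integers(0, L - frag_len + 1))
            per.append(View(cid, v, start, start + frag_len, seq[start:start + frag_len]))
        all_views.append(per)
    return ViewSet(all_views)


def dump_views_tsv(view_set: ViewSet, path) -> None:
    """Audit dump of fragment coordinates (sequences omitted)."""
    with open(os.fspath(path), "w") as fh:
        fh.write("parent_id\tview_index\tstart\tend\n")
        for v in view_set.flat():
            fh.write(f"{v.parent_id}\t{v.view_index}\t{v.start}\t{v.end}\n")
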