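"""Reading and writing the on-disk artifacts of a binning run.

Handles assembled contigs (FASTA), per-base read depth (4-column BED as
produced by ``bedtools genomecov -bga``, or a coordinate-sorted BAM),
single-copy marker-gene hit tables (TSV) and bin assignments (TSV + one
FASTA per bin).

Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONTIG_LEN = 1000


def compute_n50(lengths) -> int:
    """N50 of an assembly: the length L such that contigs of length >= L
    hold at least half the total assembled bases."""
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("cannot compute N50 of an empty assembly")
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


@dataclass
class ContigSet:
    """The universe of contigs being binned.

    ``ids`` are unique, ``seqs`` are uppercase DNA over {A,C,G,T,N}, and
    every retained contig is at least ``min_contig_len`` bp long.
    """

    ids: list
    seqs: list
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("contig ids must be unique")
        self.lengths = np.array([len(s) for s in self.seqs], dtype=np.int64)
        self._index = {cid: i for i, cid in enumerate(self.ids)}

    def __len__(self):
        return len(self.ids)

    def index_of(self, contig_id: str) -> int:
        return self._index[contig_id]

    def length_of(self, contig_id: str) -> int:
        return int(self.lengths[self._index[contig_id]])

    def seq_of(self, contig_id: str) -> str:
        return self.seqs[self._index[contig_id]]

    @property
    def n50(self) -> int:
        return compute_n50(self.lengths)


def read_fasta(path, min_contig_len: int = DEFAULT_MIN_CONTIG_LEN) -> ContigSet:
    """Read contigs from FASTA, uppercase them and drop those shorter than
    ``min_contig_len`` (assemblies are conventionally filtered at 1000 bp).
    """
    ids, seqs = [], []
    n_dropped = 0
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if not rec.id:
            raise ValueError(f"malformed FASTA record near entry {len(ids) + n_dropped + 1}")
        seq = str(rec.seq).upper()
        if len(seq) < min_contig_len:
            n_dropped += 1
            continue
        ids.append(rec.id)
        seqs.append(seq)
    if not ids and n_dropped == 0:
        raise ValueError(f"no FASTA records found in {path}")
    if not ids:
        raise ValueError(f"all {n_dropped} contigs shorter than {min_contig_len} bp")
    if n_dropped:
        logger.info("dropped %d contigs shorter than %d bp", n_dropped, min_contig_len)
    return ContigSet(ids, seqs, min_contig_len=min_contig_len)


@dataclass
class DepthTrack:
    """Run-length-encoded per-base read depth for one sequencing sample.

    For each contig: parallel arrays ``starts`` (inclusive), ``ends``
    (exclusive) and ``depths`` that tile [0, contig_length) without overlap.
    """

    sample_id: str
    runs: dict = field(default_factory=dict)  # contig_id -> (starts, ends, depths)

    def set_runs(self, contig_id, starts, ends, depths, contig_length):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        depths = np.asarray(depths, dtype=np.float64)
        order = np.argsort(starts, kind="stable")
        starts, ends, depths = starts[order], ends[order], depths[order]
        if starts.size == 0:
            starts = np.array([0], dtype=np.int64)
            ends = np.array([contig_length], dtype=np.int64)
            depths = np.array([0.0])
        if starts[0] != 0 or ends[-1] != contig_length or np.any(starts[1:] < ends[:-1]):
            # fill gaps with explicit zero-depth runs; overlaps are an error
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping depth intervals on contig {contig_id}")
            fs, fe, fd = [], [], []
            prev = 0
            for s, e, d in zip(starts, ends, depths):
                if s > prev:
                    fs.append(prev); fe.append(s); fd.append(0.0)
                fs.append(s); fe.append(e); fd.append(d)
                prev = e
            if prev < contig_length:
                fs.append(prev); fe.append(contig_length); fd.append(0.0)
            starts = np.array(fs, dtype=np.int64)
            ends = np.array(fe, dtype=np.int64)
            depths = np.array(fd)
        if np.any(depths < 0):
            raise ValueError(f"negative depth on contig {contig_id}")
        self.runs[contig_id] = (starts, ends, depths)

    def get_runs(self, contig_id):
        return self.runs[contig_id]

    def per_base(self, contig_id) -> np.ndarray:
        """Materialize the per-base depth array (test/diagnostic use)."""
        starts, ends, depths = self.runs[contig_id]
        return np.repeat(depths, ends - starts)


def _read_depth_bed(path, contigs: ContigSet, sample_id: str) -> DepthTrack:
    df = pd.read_csv(os.fspath(path), sep="\t", header=None, comment="#",
                     names=["contig", "start", "end", "depth"],
                     dtype={"contig": str})
    # tolerate an optional header line
    if len(df) and not str(df.iloc[0]["start"]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["depth"] = df["depth"].astype(np.float64)
    track = DepthTrack(sample_id=sample_id)
    known = set(contigs.ids)
    unknown = set(df["contig"]) - known
    if unknown:
        logger.warning("depth file %s: skipping %d unknown contigs", path, len(unknown))
        df = df[df["contig"].isin(known)]
    for cid, grp in df.groupby("contig", sort=False):
        clen = contigs.length_of(cid)
        if (grp["end"] > clen).any():
            raise ValueError(f"depth interval beyond contig length for {cid}")
        track.set_runs(cid, grp["start"].to_numpy(), grp["end"].to_numpy(),
                       grp["depth"].to_numpy(), clen)
    for cid in contigs.ids:
        if cid not in track.runs:
            track.set_runs(cid, [], [], [], contigs.length_of(cid))
    return track


def _read_depth_bam(path, contigs: ContigSet, sample_id: str) -> DepthTrack:
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    track = DepthTrack(sample_id=sample_id)
    with pysam.AlignmentFile(os.fspath(path), mode) as bam:
        refs = set(bam.references)
        for cid in contigs.ids:
            clen = contigs.length_of(cid)
            if cid not in refs:
                track.set_runs(cid, [], [], [], clen)
                continue
            cov = np.zeros(clen, dtype=np.int64)
            for read in bam.fetch(cid) if bam.has_index() else bam.fetch(until_eof=True):
                if bam.has_index() or read.reference_name == cid:
                    if read.is_unmapped:
                        continue
                    for s, e in read.get_blocks():
                        cov[max(0, s):min(clen, e)] += 1
            change = np.flatnonzero(np.diff(cov)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [clen]))
            track.set_runs(cid, starts, ends, cov[starts], clen)
    return track


def read_depth(path, contigs: ContigSet, sample_id: str | None = None) -> DepthTrack:
    """Read one sample's per-base depth from a BED-style file or a BAM/SAM.

    Contigs absent from the file get a single zero-depth run. Intervals past
    a contig's end are an error; rows for unknown contigs are skipped with a
    warning.
    """
    path = os.fspath(path)
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    if path.endswith((".bam", ".sam")):
        return _read_depth_bam(path, contigs, sample_id)
    return _read_depth_bed(path, contigs, sample_id)


def write_depth_bed(track: DepthTrack, path) -> None:
    with open(os.fspath(path), "w") as fh:
        for cid, (starts, ends, depths) in track.runs.items():
            for s, e, d in zip(starts, ends, depths):
                d = int(d) if float(d).is_integer() else d
                fh.write(f"{cid}\t{s}\t{e}\t{d}\n")


@dataclass
class SCGTable:
    """Single-copy marker-gene hits: a multiset of (contig_id, marker_id).

    ``marker_universe`` is the set of markers with known total count G;
    duplicated hits are retained (a contig can carry a marker twice, which
    is the contamination signal).
    """

    hits: list = field(default_factory=list)  # list of (contig_id, marker_id)
    marker_universe: set = field(default_factory=set)

    def __post_init__(self):
        if not self.marker_universe:
            self.marker_universe = {m for _, m in self.hits}

    @property
    def G(self) -> int:
        return len(self.marker_universe)

    def is_empty(self) -> bool:
        return not self.hits

    def hits_by_contig(self) -> dict:
        out = {}
        for cid, mid in self.hits:
            out.setdefault(cid, []).append(mid)
        return out


def read_scg_table(path, contigs: ContigSet, universe=None) -> SCGTable:
    """Read a TSV of (contig_id, marker_id) hits; duplicates are kept.

    Unless a marker ``universe`` is supplied, the universe is the distinct
    markers present in the table.
    """
    df = pd.read_csv(os.fspath(path), sep="\t", dtype=str)
    cols = list(df.columns)
    if "contig_id" not in cols or "marker_id" not in cols:
        raise ValueError("SCG table must have header columns contig_id, marker_id")
    known = set(contigs.ids)
    hits = []
    n_drop = 0
    for cid, mid in zip(df["contig_id"], df["marker_id"]):
        if cid not in known:
            n_drop += 1
            continue
        hits.append((cid, mid))
    if n_drop:
        logger.warning("SCG table %s: dropped %d rows with unknown contigs", path, n_drop)
    return SCGTable(hits=hits, marker_universe=set(universe) if universe else set())


@dataclass
class BinAssignment:
    """contig_id -> bin_id mapping plus the sweep parameters that made it."""

    labels: dict  # contig_id -> bin_id (int)
    params: tuple | None = None  # (sigma, resolution, edge_ratio)

    def bin_members(self) -> dict:
        out = {}
        for cid, b in self.labels.items():
            out.setdefault(b, []).append(cid)
        return out

    def bin_sizes(self, contigs: ContigSet) -> dict:
        return {b: int(sum(contigs.length_of(c) for c in members))
                for b, members in self.bin_members().items()}

    def n_bins(self) -> int:
        return len(set(self.labels.values()))


def write_bins(assignment: BinAssignment, contigs: ContigSet, outdir) -> dict:
    """Write a contig->bin TSV and one FASTA per bin.

    Bin files are named ``bin_000.fa``... in order of decreasing bin size
    (ties by smallest member contig id) so naming is deterministic. Contigs
    not present in the assignment are listed in ``unbinned.tsv``.
    Returns {bin_id: fasta_path}.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    sizes = assignment.bin_sizes(contigs)
    members = assignment.bin_members()
    order = sorted(members, key=lambda b: (-sizes[b], min(members[b])))
    name_of = {b: f"bin_{i:03d}" for i, b in enumerate(order)}
    paths = {}
    with open(os.path.join(outdir, "bins.tsv"), "w") as fh:
        fh.write("contig_id\tbin_id\n")
        for b in order:
            for cid in sorted(members[b]):
                fh.write(f"{cid}\t{name_of[b]}\n")
    for b in order:
        fp = os.path.join(outdir, name_of[b] + ".fa")
        recs = [SeqRecord(Seq(contigs.seq_of(c)), id=c, description="")
                for c in sorted(members[b])]
        SeqIO.write(recs, fp, "fasta")
        paths[name_of[b]] = fp
    binned = set(assignment.labels)
    with open(os.path.join(outdir, "unbinned.tsv"), "w") as fh:
        fh.write("contig_id\n")
        for cid in contigs.ids:
            if cid not in binned:
                fh.write(f"{cid}\n")
    return paths


def read_bin_tsv(path) -> dict:
    df = pd.read_csv(os.fspath(path), sep="\t", dtype=str)
    return dict(zip(df["contig_id"], df["bin_id"]))
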