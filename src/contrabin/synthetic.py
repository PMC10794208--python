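"""Self-contained synthetic metagenomic communities for testing and demos.

Emulates what the binner consumes downstream of assembly and read mapping:
genomes with genome-distinct tetranucleotide signatures (each genome is an
order-1 base-transition chain, biased away from the shared background by a
divergence knob), fragmented into contigs of at least 1000 bp; per-sample
per-base depth tracks driven by a genome x sample abundance matrix with
multiplicative lognormal noise per contig and a smooth sinusoidal
within-contig modulation (so depth standard deviations are non-trivial);
and single-copy marker genes planted exactly once per genome per marker.

What this does *not* emulate: assembly chimerism/fragmentation errors,
read-level sampling noise, inter-genome repeats, or strain microdiversity —
results on these communities bound what the method can do on clean input,
not on adversarial real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ContigSet, DepthTrack, SCGTable, write_depth_bed

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunitySpec:
    n_genomes: int = 10
    genome_length: int = 300_000
    n_samples: int = 5
    abundance: np.ndarray | None = None   # (n_genomes, n_samples) mean depths
    composition_divergence: float = 0.85  # 0 = shared base law, 1 = fully genome-specific
    contig_len_log_mean: float = np.log(2500.0)
    contig_len_log_sigma: float = 0.5
    min_contig_len: int = 1000
    max_contig_len: int = 15_000
    depth_noise_sigma: float = 0.25       # lognormal sigma of per-contig factors
    depth_wave_amplitude: float = 0.3     # within-contig sinusoidal modulation
    depth_wave_period: float = 700.0      # bp
    n_markers: int = 20
    seed: int = 0

    def resolved_abundance(self, rng) -> np.ndarray:
        """Mean per-base depth of each genome in each sample; the default is
        i.i.d. lognormal around 10x, giving every genome a distinct
        cross-sample profile."""
        if self.abundance is not None:
            ab = np.asarray(self.abundance, dtype=np.float64)
            if ab.shape != (self.n_genomes, self.n_samples):
                raise ValueError("abundance must be (n_genomes, n_samples)")
            if (ab < 0).any():
                raise ValueError("abundances must be >= 0")
            return ab
        return rng.lognormal(mean=np.log(10.0), sigma=0.8,
                             size=(self.n_genomes, self.n_samples))


@dataclass
class Community:
    contigs: ContigSet
    tracks: list                      # one DepthTrack per sample
    scg: SCGTable
    truth: dict                       # contig_id -> genome index
    spec: CommunitySpec
    abundance: np.ndarray = field(default=None)


def _markov_sequence(P: np.ndarray, length: int, rng) -> str:
    """Sample an order-1 base chain of ``length`` from transition matrix P."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(length)
    # per-position next-state for each possible current state; indexing the
    # table with the running state keeps the chain exactly Markov(P)
    table = np.empty((length, 4), dtype=np.int8)
    for s in range(4):
        table[:, s] = np.searchsorted(cum[s], u)
    states = np.empty(length, dtype=np.int8)
    s = int(rng.integers(4))
    for t in range(length):
        s = table[t, s]
        states[t] = s
    return _BASES[states].tobytes().decode()


def simulate_genomes(spec: CommunitySpec):
    """Genome sequences, each from its own base-transition law.

    P_g = (1 - delta) * Uniform + delta * B_g with B_g a genome-specific
    random stochastic matrix; delta = composition_divergence. delta = 0
    collapses all genomes onto one shared law (indistinguishable TNF)."""
    rng = np.random.default_rng([spec.seed, 11])
    delta = spec.composition_divergence
    genomes = []
    for g in range(spec.n_genomes):
        B = rng.dirichlet(np.ones(4), size=4)
        P = (1 - delta) * np.full((4, 4), 0.25) + delta * B
        genomes.append(_markov_sequence(P, spec.genome_length, rng))
    return genomes


def _cut_lengths(total: int, spec: CommunitySpec, rng) -> list:
    lens = []
    remaining = total
    while remaining > 0:
        L = int(np.clip(rng.lognormal(spec.contig_len_log_mean,
                                      spec.contig_len_log_sigma),
                        spec.min_contig_len, spec.max_contig_len))
        if remaining - L < spec.min_contig_len:
            L = remaining  # absorb the tail so no short leftover contig
        lens.append(L)
        remaining -= L
    return lens


def fragment_and_cover(genomes, spec: CommunitySpec):
    """Cut genomes into contigs and synthesize per-sample depth tracks.

    Per contig and sample, depth is abundance x a lognormal per-contig
    factor x (1 + a sin(2 pi (pos + phase) / period)), rounded to integer
    read counts; run-length encoded exactly as a genomecov-style file would
    deliver it."""
    rng = np.random.default_rng([spec.seed, 23])
    abundance = spec.resolved_abundance(np.random.default_rng([spec.seed, 7]))
    ids, seqs, truth = [], [], {}
    meta = []  # (contig_id, genome, length)
    for g, genome in enumerate(genomes):
        pos = 0
        for i, L in enumerate(_cut_lengths(len(genome), spec, rng)):
            cid = f"g{g:02d}_c{i:04d}"
            ids.append(cid)
            seqs.append(genome[pos:pos + L])
            truth[cid] = g
            meta.append((cid, g, L))
            pos += L
    contigs = ContigSet(ids, seqs, min_contig_len=spec.min_contig_len)
    tracks = [DepthTrack(sample_id=f"sample_{m}") for m in range(spec.n_samples)]
    for cid, g, L in meta:
        base_pos = np.arange(L)
        for m in range(spec.n_samples):
            mu = abundance[g, m]
            factor = rng.lognormal(0.0, spec.depth_noise_sigma)
            phase = rng.uniform(0, spec.depth_wave_period)
            wave = 1.0 + spec.depth_wave_amplitude * np.sin(
                2 * np.pi * (base_pos + phase) / spec.depth_wave_period)
            depth = np.maximum(np.rint(mu * factor * wave), 0.0).astype(np.int64)
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [L]))
            tracks[m].set_runs(cid, starts, ends, depth[starts].astype(float), L)
    return contigs, tracks, truth, abundance


def plant_scgs(contigs: ContigSet, truth: dict, n_markers: int,
               seed: int = 0) -> SCGTable:
    """Place each of G markers exactly once per genome on a random contig of
    that genome: single-copy within genomes, multi-copy across the community."""
    rng = np.random.default_rng([seed, 31])
    by_genome = {}
    for cid, g in truth.items():
        by_genome.setdefault(g, []).append(cid)
    markers = [f"m{j:03d}" for j in range(n_markers)]
    hits = []
    for g in sorted(by_genome):
        members = sorted(by_genome[g])
        for mid in markers:
            hits.append((members[int(rng.integers(len(members)))], mid))
    return SCGTable(hits=hits, marker_universe=set(markers))


def make_community(spec: CommunitySpec) -> Community:
    genomes = simulate_genomes(spec)
    contigs, tracks, truth, abundance = fragment_and_cover(genomes, spec)
    scg = plant_scgs(contigs, truth, spec.n_markers, seed=spec.seed)
    return Community(contigs=contigs, tracks=tracks, scg=scg, truth=truth,
                     spec=spec, abundance=abundance)


def easy_spec(seed: int = 0, **overrides) -> CommunitySpec:
    """The canonical well-separated community: 10 genomes, 5 samples, high
    composition divergence, distinct abundance profiles, ~100 contigs per
    genome."""
    return CommunitySpec(seed=seed, **overrides)


def hard_strain_spec(seed: int = 0, **overrides) -> CommunitySpec:
    """Two strain-like genomes sharing one base-composition law and
    differing only in abundance: only coverage can separate them."""
    kw = dict(n_genomes=2, composition_divergence=0.0, n_samples=5,
              abundance=np.array([[30.0, 25.0, 4.0, 32.0, 6.0],
                                  [3.0, 4.0, 28.0, 5.0, 30.0]]),
              seed=seed)
    kw.update(overrides)
    return CommunitySpec(**kw)


def write_community(community: Community, outdir) -> dict:
    """Emit exactly the formats the IO layer reads: contigs FASTA, one BED
    depth file per sample, SCG TSV and a truth TSV. Returns the paths."""
    import os

    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {"contigs": os.path.join(outdir, "contigs.fa"),
             "scg": os.path.join(outdir, "scg.tsv"),
             "truth": os.path.join(outdir, "truth.tsv"),
             "depth": []}
    recs = [SeqRecord(Seq(s), id=c, description="")
            for c, s in zip(community.contigs.ids, community.contigs.seqs)]
    SeqIO.write(recs, paths["contigs"], "fasta")
    for track in community.tracks:
        p = os.path.join(outdir, f"depth_{track.sample_id}.bed")
        write_depth_bed(track, p)
        paths["depth"].append(p)
    with open(paths["scg"], "w") as fh:
        fh.write("contig_id\tmarker_id\n")
        for cid, mid in community.scg.hits:
            fh.write(f"{cid}\t{mid}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("contig_id\tgenome_id\n")
        for cid, g in community.truth.items():
            fh.write(f"{cid}\t{g}\n")
    return paths
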