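import numpy as np
import pytest

import contrabin as cb


@pytest.fixture(scope="session")
def tetramer_index():
    return cb.build_canonical_index(4)


@pytest.fixture(scope="session")
def tiny_community():
    """Downsized community for unit tests: 4 genomes x 80 kbp, 3 samples."""
    spec = cb.easy_spec(seed=7, n_genomes=4, genome_length=80_000, n_samples=3,
                        n_markers=10)
    return cb.make_community(spec)


@pytest.fixture(scope="session")
def tiny_views(tiny_community):
    return cb.augment_contigs(tiny_community.contigs, seed=7)


@pytest.fixture(scope="session")
def tiny_features(tiny_community, tiny_views):
    return cb.build_features(tiny_views, tiny_community.tracks)


def make_track(contig_lengths: dict, rng, max_depth=20, sample_id="s0"):
    """Random run-length depth track covering each contig."""
    track = cb.DepthTrack(sample_id=sample_id)
    for cid, L in contig_lengths.items():
        n_runs = int(rng.integers(1, min(L, 8) + 1))
        cuts = np.sort(rng.choice(np.arange(1, L), size=n_runs - 1, replace=False)) \
            if n_runs > 1 else np.array([], dtype=int)
        starts = np.concatenate(([0], cuts))
        ends = np.concatenate((cuts, [L]))
        depths = rng.integers(0, max_depth, size=n_runs).astype(float)
        track.set_runs(cid, starts, ends, depths, L)
    return track
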