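import warnings

import numpy as np
import pytest

import cmuscan as cs

warnings.filterwarnings("ignore", message="only .* samples")


def make_manifest(positions, chroms=None, build="test"):
    """Small manifest from 1-based positions (single chromosome by default)."""
    positions = list(positions)
    if chroms is None:
        chroms = ["chr1"] * len(positions)
    return cs.ProbeManifest(
        probe_ids=np.array([f"cg{i:05d}" for i in range(len(positions))], dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        build=build,
    )


def probe_jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


def recovery(cmu_set, truth_blocks, min_jaccard=0.8):
    """(n_recovered, n_false) of called contiguous CMUs vs planted blocks."""
    runs = [
        set(range(int(r.first_probe), int(r.last_probe) + 1))
        for _, r in truth_blocks.iterrows()
    ]
    called = [set(c.probe_indices) for c in cmu_set.contiguous]
    n_rec = sum(any(probe_jaccard(r, c) >= min_jaccard for c in called) for r in runs)
    n_false = sum(not any(c & r for r in runs) for c in called)
    return n_rec, n_false


@pytest.fixture(scope="session")
def basic_data():
    """The basic planted-block preset: manifest, transformed beta, truth, scan."""
    spec = cs.simulate.basic_spec(seed=1)
    manifest, beta, truth = cs.simulate.generate_block_beta(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        transformed = cs.inverse_normal_transform(beta)
    cmu_set = cs.scan_dataset(transformed, manifest, cs.ICMParams(), dataset="basic")
    return {
        "spec": spec,
        "manifest": manifest,
        "beta": beta,
        "transformed": transformed,
        "truth": truth,
        "cmu_set": cmu_set,
    }


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
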