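"""Shared fixtures: a session-scoped synthetic universe and pipeline run.

The universe is generated once at the generator's default study conditions
and the full pipeline executed on it; tests read the in-memory ground truth
and the emitted reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

from refconcord.cli import run_pipeline
from refconcord.refio import read_report
from refconcord.synthpop import SynthConfig, generate

PIPELINE_INPUT_KEYS = (
    "genome_new", "genome_old", "chain", "refflat", "ccds", "mrna",
    "cds_sidecar", "proteins", "vcf", "pileup",
)


@dataclass
class Universe:
    truth: object
    config: SynthConfig
    simdir: Path
    rundir: Path
    manifest: object

    def report(self, name: str):
        return read_report(self.rundir / name)


@pytest.fixture(scope="session")
def universe(tmp_path_factory) -> Universe:
    simdir = tmp_path_factory.mktemp("sim")
    rundir = tmp_path_factory.mktemp("run")
    config = SynthConfig()
    truth = generate(config, simdir)
    pipeline_cfg = {
        "inputs": {k: str(truth.files[k]) for k in PIPELINE_INPUT_KEYS},
        "params": {"panel": "synthpanel"},
    }
    manifest = run_pipeline(pipeline_cfg, rundir)
    return Universe(truth=truth, config=config, simdir=simdir,
                    rundir=rundir, manifest=manifest)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# Independent DP spliced-alignment oracle
# ---------------------------------------------------------------------------

def dp_spliced_counts(mrna: str, genome: str, intron_open: float = 1.5):
    """Brute-force spliced alignment of an mRNA CDS against a genome window.

    Three-state affine DP: aligned pair (mismatch costs 1), mRNA base
    missing from the genome (costs 1), genome skip (an intron or flanking
    sequence; opening costs ``intron_open`` interior to the alignment and is
    free at the ends, extension free).  Returns (n_mismatch, n_missing) of
    the minimum-cost alignment that consumes the whole mRNA.

    Independent of the package's seeding/chaining route: plain dynamic
    programming over the full matrix.
    """
    m, n = len(mrna), len(genome)
    inf = 1e18
    q = np.frombuffer(mrna.encode(), dtype=np.uint8)
    t = np.frombuffer(genome.encode(), dtype=np.uint8)
    # state arrays over genome prefix j = 0..n; cost plus mismatch/missing counts
    M = np.full(n + 1, inf)
    Mmm = np.zeros(n + 1)
    Mms = np.zeros(n + 1)
    I = np.full(n + 1, inf)
    Imm = np.zeros(n + 1)
    Ims = np.zeros(n + 1)
    G = np.zeros(n + 1)  # leading genome skip is free
    Gmm = np.zeros(n + 1)
    Gms = np.zeros(n + 1)
    for i in range(1, m + 1):
        mis = (q[i - 1] != t).astype(float)  # length n, genome char j-1
        # M[i][j] = mis + min over states at [i-1][j-1]
        prev = np.stack([M[:-1], I[:-1], G[:-1]])
        prev_mm = np.stack([Mmm[:-1], Imm[:-1], Gmm[:-1]])
        prev_ms = np.stack([Mms[:-1], Ims[:-1], Gms[:-1]])
        k = np.argmin(prev, axis=0)
        cols = np.arange(n)
        newM = np.full(n + 1, inf)
        newMmm = np.zeros(n + 1)
        newMms = np.zeros(n + 1)
        newM[1:] = prev[k, cols] + mis
        newMmm[1:] = prev_mm[k, cols] + (q[i - 1] != t)
        newMms[1:] = prev_ms[k, cols]
        # I[i][j] = 1 + min over states at [i-1][j]
        prev2 = np.stack([M, I, G])
        prev2_mm = np.stack([Mmm, Imm, Gmm])
        prev2_ms = np.stack([Mms, Ims, Gms])
        k2 = np.argmin(prev2, axis=0)
        cols2 = np.arange(n + 1)
        newI = prev2[k2, cols2] + 1.0
        newImm = prev2_mm[k2, cols2]
        newIms = prev2_ms[k2, cols2] + 1
        # G[i][j] = min(G[i][j-1], min(M,I)[i][j-1] + open): a prefix-min scan
        newG = np.full(n + 1, inf)
        newGmm = np.zeros(n + 1)
        newGms = np.zeros(n + 1)
        use_m = newM[:-1] <= newI[:-1]
        opens = np.where(use_m, newM[:-1], newI[:-1]) + intron_open
        pref = np.minimum.accumulate(opens)
        shifted = np.concatenate(([inf], pref[:-1]))
        new_min = opens < shifted
        src = np.maximum.accumulate(np.where(new_min, np.arange(n), -1))
        valid = src >= 0
        newG[1:] = pref
        o_mm = np.where(use_m, newMmm[:-1], newImm[:-1])
        o_ms = np.where(use_m, newMms[:-1], newIms[:-1])
        newGmm[1:][valid] = o_mm[src[valid]]
        newGms[1:][valid] = o_ms[src[valid]]
        M, Mmm, Mms = newM, newMmm, newMms
        I, Imm, Ims = newI, newImm, newIms
        G, Gmm, Gms = newG, newGmm, newGms
    # trailing genome free: best over j of M/I
    best = inf
    counts = (0, 0)
    for j in range(n + 1):
        for c, mm, ms in ((M[j], Mmm[j], Mms[j]), (I[j], Imm[j], Ims[j])):
            if c < best:
                best = c
                counts = (int(mm), int(ms))
    return counts
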