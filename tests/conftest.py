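"""Shared fixtures: tiny hand-built objects and one reusable noisy dataset."""

from __future__ import annotations

import numpy as np
import pytest

from intronslide import (
    AlignmentBlock,
    AxtRecord,
    BlockMap,
    SimParams,
    Transcript,
    derive_genome_b,
    generate_ancestor,
    plan_plantings,
)


def make_transcript(
    exons,
    strand="+",
    tid="tx1",
    gene="g1",
    chrom="chr1",
    cds=None,
):
    cds_start, cds_end = cds if cds is not None else (None, None)
    return Transcript(
        transcript_id=tid,
        gene_id=gene,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
    )


def identity_map(length=1000, a_chrom="chrA1", b_chrom="chrB1"):
    return BlockMap(
        [AlignmentBlock(a_chrom=a_chrom, a_start=0, b_chrom=b_chrom, b_start=0, length=length)]
    )


def random_axt_record(rng, strand_choices=("+",)):
    """A random gapped record plus the b_sizes mapping it may need."""
    n_cols = int(rng.integers(5, 120))
    a_start = int(rng.integers(0, 300))
    b_start = int(rng.integers(0, 300))
    strand = str(rng.choice(strand_choices))
    bases = "ACGT"
    a_parts, b_parts = [], []
    a_len = b_len = 0
    for _ in range(n_cols):
        r = rng.random()
        if r < 0.7:
            a_parts.append(bases[int(rng.integers(4))])
            b_parts.append(bases[int(rng.integers(4))])
            a_len += 1
            b_len += 1
        elif r < 0.85:
            a_parts.append(bases[int(rng.integers(4))])
            b_parts.append("-")
            a_len += 1
        else:
            a_parts.append("-")
            b_parts.append(bases[int(rng.integers(4))])
            b_len += 1
    rec = AxtRecord(
        index=0,
        a_chrom="chrA1",
        a_start=a_start,
        a_end=a_start + a_len,
        b_chrom="chrB1",
        b_start=b_start,
        b_end=b_start + b_len,
        strand=strand,
        score=1000,
        a_seq="".join(a_parts),
        b_seq="".join(b_parts),
    )
    b_sizes = {"chrB1": b_start + b_len + int(rng.integers(0, 50))}
    return rec, b_sizes


def make_planted_params(
    seed,
    n_genes=20,
    n_sliding=10,
    n_nonequal=5,
    substitution_rate=0.02,
    **kwargs,
):
    """Params with randomly chosen feasible planting targets."""
    params = SimParams(
        n_genes=n_genes, substitution_rate=substitution_rate, seed=seed, **kwargs
    )
    ancestor = generate_ancestor(params)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    slidings, nonequal = plan_plantings(ancestor, n_sliding, n_nonequal, rng)
    params.planted_slidings = slidings
    params.planted_nonequal = nonequal
    return ancestor, params


@pytest.fixture(scope="session")
def noisy_dataset():
    """One 20-gene dataset with substitutions, indels, decoys and planted events."""
    ancestor, params = make_planted_params(
        seed=11,
        indel_rate=0.001,
        unaligned_fraction=0.1,
        decoy_tsl_fraction=0.2,
    )
    return derive_genome_b(ancestor, params)
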