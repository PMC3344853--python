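import numpy as np
import pandas as pd
import pytest

from pooldiff.types import (
    GenotypeMatrix,
    MarkerInfo,
    Pedigree,
    PedigreeEntry,
    PoolEvidence,
    SiteEvidence,
)


def make_site(
    ref="A",
    fast_counts=None,
    slow_counts=None,
    meanq=30.0,
    contig="c1",
    pos=100,
    fast_depth=None,
    slow_depth=None,
):
    """Build a SiteEvidence from base->count dicts with a flat mean quality."""

    def pool(counts, depth):
        counts = counts or {}
        depth = depth if depth is not None else sum(counts.values())
        q = {b: meanq for b in counts}
        return PoolEvidence(depth=depth, counts=dict(counts), meanq=q)

    return SiteEvidence(
        contig, pos, ref, pool(fast_counts, fast_depth), pool(slow_counts, slow_depth)
    )


def make_genotypes(calls: dict, markers: dict) -> GenotypeMatrix:
    """calls: {sample: {marker: dosage or None}}; markers: {id: (a1, a2, genome)}."""
    df = pd.DataFrame.from_dict(calls, orient="index", dtype=float)
    meta = {m: MarkerInfo(m, *info) for m, info in markers.items()}
    return GenotypeMatrix(calls=df, markers=meta)


def make_pedigree(families: dict) -> Pedigree:
    """families: {family_id: [offspring ids]}; parents are synthesised."""
    entries = {}
    for fam, kids in families.items():
        sire, dam = f"{fam}_sire", f"{fam}_dam"
        entries[sire] = PedigreeEntry(sire, None, None, "", "F0")
        entries[dam] = PedigreeEntry(dam, None, None, "", "F0")
        for kid in kids:
            entries[kid] = PedigreeEntry(kid, sire, dam, fam, "F1")
    return Pedigree(entries=entries)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_921)


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def genotype_factory():
    return make_genotypes


@pytest.fixture
def pedigree_factory():
    return make_pedigree
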