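"""Shared fixtures: tiny hand-built knowledge objects and generated worlds.

Generated worlds are session-scoped so the expensive ones (the biased and
unbiased calibration worlds) are built once per run.
"""

import pytest

from miropa import (
    FixtureSpec,
    PathwayCollection,
    PathwayEntry,
    Signature,
    TargetMap,
    generate,
)

BIASED_IDS = tuple(f"PW{i:03d}" for i in range(1, 11))


@pytest.fixture
def tiny_tmap() -> TargetMap:
    """3 miRNAs, 5 genes; mir-1 hits g1-g3, mir-2 hits g3-g4, mir-3 hits g5."""
    return TargetMap.from_pairs(
        [
            ("mir-1", "g1"), ("mir-1", "g2"), ("mir-1", "g3"),
            ("mir-2", "g3"), ("mir-2", "g4"),
            ("mir-3", "g5"),
        ],
        source_name="tiny",
    )


@pytest.fixture
def tiny_pathways() -> PathwayCollection:
    return PathwayCollection(
        entries=[
            PathwayEntry("P1", "first", frozenset({"g1", "g2", "g3"})),
            PathwayEntry("P2", "second", frozenset({"g3", "g4"})),
            PathwayEntry("P3", "third", frozenset({"g6", "g7"})),
        ],
        member_kind="genes",
    )


@pytest.fixture
def tiny_signature() -> Signature:
    return Signature(label="tiny-sig", mirnas=("mir-1", "mir-2"))


@pytest.fixture(scope="session")
def biased_world():
    """The stated calibration world: 2000 genes, 300 miRNAs, 100 pathways of
    20-80 genes, 1% base targeting, 10 designated pathways at 5x."""
    return generate(
        FixtureSpec(
            biased_pathway_ids=BIASED_IDS, bias_multiplier=5.0, seed=42
        )
    )


@pytest.fixture(scope="session")
def unbiased_world():
    """Same world with the bias multiplier at 1 (the null database)."""
    return generate(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def sparse_biased_world():
    """A sparser database (50 miRNAs, 0.5% base rate) in which the targeted
    genes are a minority of the universe, so whole-list bias scans have
    room to detect the designated pathways."""
    return generate(
        FixtureSpec(
            n_mirnas=50,
            base_target_prob=0.005,
            biased_pathway_ids=BIASED_IDS,
            bias_multiplier=5.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def sparse_unbiased_world():
    return generate(FixtureSpec(n_mirnas=50, base_target_prob=0.005, seed=7))
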