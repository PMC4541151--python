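"""Shared fixtures: tiny reference databases, homologous sequence pairs and
random trees used as oracle inputs across the suite."""

from __future__ import annotations

import random

import numpy as np
import pytest
from skbio import TreeNode

from copatrace.refdb import Group, ReferenceDB, ReferenceGene


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))


def mutate_dna(
    rng: random.Random,
    seq: str,
    sub_rate: float = 0.1,
    max_indels: int = 0,
    max_indel_len: int = 3,
) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < sub_rate:
            out[i] = rng.choice("ACGT".replace(out[i], ""))
    for _ in range(rng.randint(0, max_indels)):
        p = rng.randrange(len(out))
        if rng.random() < 0.5:
            del out[p : p + rng.randint(1, max_indel_len)]
        else:
            out[p:p] = [rng.choice("ACGT") for _ in range(rng.randint(1, max_indel_len))]
    return "".join(out)


def small_db(rng: random.Random, n_genes: int = 3, length: int = 300) -> ReferenceDB:
    genes = [
        ReferenceGene(
            record_id=f"gi_{1000 + i}_Testus_sp{i}",
            gi=str(1000 + i),
            species=f"Testus_sp{i}",
            sequence=random_dna(rng, length),
            group=Group.UNKNOWN,
        )
        for i in range(n_genes)
    ]
    return ReferenceDB(genes=genes, name="test")


def random_binary_tree(rng: random.Random, leaves: list[str]) -> TreeNode:
    """Random unrooted binary tree with random positive branch lengths."""
    assert len(leaves) >= 3
    nodes = [TreeNode(name=nm, length=round(rng.uniform(0.1, 1.0), 3)) for nm in leaves[:3]]
    root = TreeNode(children=nodes)
    edges = list(nodes)
    for nm in leaves[3:]:
        target = rng.choice(edges)
        parent = target.parent
        half = target.length / 2
        mid = TreeNode(length=half)
        target.length = half
        parent.remove(target)
        parent.append(mid)
        mid.append(target)
        leaf = TreeNode(name=nm, length=round(rng.uniform(0.1, 1.0), 3))
        mid.append(leaf)
        edges.extend([target, leaf, mid])
    return root


@pytest.fixture
def quartet_trees() -> tuple[TreeNode, TreeNode]:
    t1 = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
    t2 = TreeNode.read(["((a:1,c:1):1,(b:1,d:1):1);"])
    return t1, t2
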