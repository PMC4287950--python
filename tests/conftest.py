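"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import io

import pytest

from xseq.fixtures import FixtureSpec, generate


class PerBaseOracle:
    """Brute-force per-base dictionary mirror of a genomic array lane.

    Deliberately naive: one dict entry per touched base. Used to check the
    step containers' query results on small lanes.
    """

    def __init__(self, default=0.0):
        self.default = default
        self.data: dict[int, object] = {}

    def set_value(self, start, end, value):
        for p in range(start, end):
            self.data[p] = value

    def add_value(self, start, end, delta):
        for p in range(start, end):
            self.data[p] = self.data.get(p, self.default) + delta

    def add_item(self, start, end, item):
        for p in range(start, end):
            self.data[p] = self.data.get(p, frozenset()) | {item}

    def value_at(self, p):
        return self.data.get(p, self.default)

    def steps(self, start, end):
        """Maximal runs of constant value partitioning [start, end)."""
        out = []
        for p in range(start, end):
            v = self.value_at(p)
            if out and out[-1][2] == v and out[-1][1] == p:
                out[-1][1] = p + 1
            else:
                out.append([p, p + 1, v])
        return [(s, e, v) for s, e, v in out]

    def union(self, start, end):
        out = frozenset()
        for p in range(start, end):
            out = out | self.value_at(p)
        return out


@pytest.fixture(scope="session")
def small_fixture():
    """A modest paired-end dataset with all read categories present."""
    return generate(FixtureSpec(seed=11, n_genes=12, n_fragments=600))


@pytest.fixture(scope="session")
def small_fixture_parsed(small_fixture):
    from xseq import read_gff, read_sam

    feats = list(read_gff(io.StringIO(small_fixture.gtf)))
    alns = list(read_sam(io.StringIO(small_fixture.sam)))
    return small_fixture, feats, alns
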