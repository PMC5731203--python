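"""Mutations on the genealogy and the resulting sequence alignment.

A uniform finite-sites model: mutation counts per branch are Poisson with the
per-sequence rate times the branch length; each mutation hits a uniformly
chosen site and substitutes a uniformly chosen different base.  Multiple hits
(homoplasy) are possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalescent import GeneGenealogy

__all__ = ["MutationModel", "SequenceAlignment", "drop_mutations", "write_fasta"]

BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class MutationModel:
    """Mutation rate specification.

    mu is per site per generation if ``per_site`` (the sequence-level rate is
    mu * L), otherwise per sequence per generation.
    """

    mu: float
    L: int
    per_site: bool = True

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.L < 1:
            raise ValueError("L must be >= 1")

    @property
    def rate_per_sequence(self) -> float:
        return self.mu * self.L if self.per_site else self.mu


@dataclass
class SequenceAlignment:
    """Haplotypes at the sampled leaves.

    ``codes`` holds bases as integers 0..3 (A, C, G, T), one row per leaf in
    genealogy leaf order.
    """

    codes: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    ages: np.ndarray = field(repr=False)
    demes: np.ndarray = field(repr=False)  # (n, 2) row/col per leaf

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def L(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> list[str]:
        return ["".join(BASES[row]) for row in self.codes]

    def by_label(self, label: str) -> np.ndarray:
        return self.codes[self.labels == label]


def drop_mutations(
    genealogy: GeneGenealogy, model: MutationModel, rng: np.random.Generator
) -> SequenceAlignment:
    """Distribute mutations on the tree and return the leaf alignment.

    The root sequence is uniform random; sequences evolve down each branch
    with Poisson(rate_per_sequence * branch_length) substitutions.
    """
    n_nodes = genealogy.n_nodes
    L = model.L
    rate = model.rate_per_sequence
    seqs = np.empty((n_nodes, L), dtype=np.int8)
    seqs[genealogy.root] = rng.integers(0, 4, size=L, dtype=np.int8)
    # parents have larger ids, so a reversed sweep visits them first
    for v in range(n_nodes - 2, -1, -1):
        p = genealogy.parent[v]
        s = seqs[p].copy()
        bl = genealogy.time[p] - genealogy.time[v]
        nmut = rng.poisson(rate * bl)
        for _ in range(nmut):
            site = rng.integers(0, L)
            s[site] = (s[site] + rng.integers(1, 4)) % 4
        seqs[v] = s
    n = genealogy.n_leaves
    return SequenceAlignment(
        codes=seqs[:n],
        labels=genealogy.leaf_labels.copy(),
        ages=genealogy.leaf_ages.copy(),
        demes=genealogy.positions[genealogy.deme[:n]].copy(),
    )


def write_fasta(alignment: SequenceAlignment, path: str | Path) -> None:
    """Write the alignment as FASTA; ids encode label, age BP and deme."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, seq in enumerate(alignment.sequences()):
        r, c = alignment.demes[i]
        rid = f"seq{i}|{alignment.labels[i]}|age{alignment.ages[i]}|deme{r}_{c}"
        records.append(SeqRecord(Seq(seq), id=rid, description=""))
    seqio_write(records, str(path), "fasta")
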