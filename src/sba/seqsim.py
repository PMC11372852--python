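"""Sequence simulation along gene trees and non-informative test inputs.

Alignments are stored as integer matrices (A,C,G,T = 0..3; gap/missing =
4).  :func:`simulate_alignment` is a Seq-Gen-style simulator: the root
state is drawn from the model's stationary distribution and states evolve
down each branch with an independently resampled discrete-gamma rate
category per site.  The remaining generators produce the deliberately
signal-free inputs used to probe engine fairness: identical sequences,
saturated (i.i.d.) sequences, and alignments with randomly deleted
characters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sba.trees import Tree

__all__ = [
    "GAP",
    "Alignment",
    "simulate_alignment",
    "make_identical_alignment",
    "make_saturated_alignment",
    "apply_missing",
]

GAP = 4
_ALPHABET = "ACGT-"
_CHAR_TO_STATE = {c: i for i, c in enumerate(_ALPHABET)}
_CHAR_TO_STATE.update({"N": GAP, "?": GAP})


@dataclass
class Alignment:
    """Taxon labels plus an (n_taxa, K) int8 state matrix."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.labels):
            raise ValueError("matrix must have one row per label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() > GAP):
            raise ValueError("states must be in 0..4")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def K(self) -> int:
        return self.matrix.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.matrix[self.labels.index(label)]

    def take(self, labels) -> "Alignment":
        idx = [self.labels.index(l) for l in labels]
        return Alignment(list(labels), self.matrix[idx].copy())

    # -- text I/O ------------------------------------------------------
    def sequences(self) -> list[str]:
        lut = np.array(list(_ALPHABET))
        return ["".join(lut[row]) for row in self.matrix]

    def to_fasta(self) -> str:
        return "".join(f">{lab}\n{seq}\n" for lab, seq in zip(self.labels, self.sequences()))

    def to_phylip(self) -> str:
        body = "".join(f"{lab}  {seq}\n" for lab, seq in zip(self.labels, self.sequences()))
        return f"{self.n_taxa} {self.K}\n{body}"

    @classmethod
    def from_sequences(cls, labels, seqs) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError("sequences must have equal length")
        matrix = np.array(
            [[_CHAR_TO_STATE[c.upper()] for c in s] for s in seqs], dtype=np.int8
        ).reshape(len(list(labels)), -1)
        return cls(list(labels), matrix)

    @classmethod
    def from_fasta(cls, text: str) -> "Alignment":
        labels, seqs, current = [], [], []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                labels.append(line[1:].split()[0])
                current = []
                seqs.append(current)
            else:
                current.append(line)
        return cls.from_sequences(labels, ["".join(s) for s in seqs])

    @classmethod
    def from_phylip(cls, text: str) -> "Alignment":
        lines = [l for l in text.splitlines() if l.strip()]
        n, k = (int(x) for x in lines[0].split())
        labels, seqs = [], []
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            seqs.append("".join(parts[1:]))
        aln = cls.from_sequences(labels, seqs)
        if aln.K != k:
            raise ValueError("phylip header length mismatch")
        return aln


def _sample_states(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one state per row of a (n, 4) probability matrix."""
    u = rng.random(prob_rows.shape[0])
    return (prob_rows.cumsum(axis=1) > u[:, None]).argmax(axis=1).astype(np.int8)


def simulate_alignment(tree: Tree, model, K: int, rng: np.random.Generator) -> Alignment:
    """Simulate a K-site alignment along ``tree`` under ``model``.

    Sites are i.i.d.; each site gets an independent discrete-gamma rate
    category (a single unit category under JC).  Branch lengths are
    expected substitutions per site at rate 1.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    rates = np.asarray(model.category_rates, dtype=float)
    ncat = len(rates)
    pi = np.asarray(model.pi, dtype=float)

    categories = rng.integers(0, ncat, size=K)
    states: dict[int, np.ndarray] = {}
    root_states = _sample_states(np.tile(pi, (K, 1)), rng)
    states[id(tree.root)] = root_states
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(K, dtype=np.int8)
        for c in range(ncat):
            sel = categories == c
            if not sel.any():
                continue
            p = model.transition_matrix(node.length, rates[c])
            child[sel] = _sample_states(p[parent_states[sel]], rng)
        states[id(node)] = child
    matrix = np.stack([states[id(leaf)] for leaf in leaves])
    return Alignment([leaf.label for leaf in leaves], matrix)


def make_identical_alignment(K: int, rng: np.random.Generator, labels=("S1", "S2", "S3", "S4")) -> Alignment:
    """One uniform-random sequence replicated across all taxa."""
    if K < 1:
        raise ValueError("K must be >= 1")
    row = rng.integers(0, 4, size=K, dtype=np.int8)
    return Alignment(list(labels), np.tile(row, (len(labels), 1)))


def make_saturated_alignment(
    K: int,
    freqs,
    rng: np.random.Generator,
    labels=("S1", "S2", "S3", "S4"),
) -> Alignment:
    """Every cell drawn i.i.d. from ``freqs``, independently across taxa —
    the limiting distribution of infinitely long branches."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (4,) or np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0):
        raise ValueError("freqs must be 4 non-negative values summing to 1")
    matrix = _sample_states(np.tile(freqs, (len(labels) * K, 1)), rng).reshape(len(labels), K)
    return Alignment(list(labels), matrix)


def apply_missing(
    alignment: Alignment,
    fraction: float,
    taxa,
    rng: np.random.Generator,
) -> Alignment:
    """Replace a fixed fraction of sites by gaps in the listed taxa.

    Exactly ``round(fraction * K)`` positions per listed taxon, chosen
    uniformly without replacement.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    matrix = alignment.matrix.copy()
    n_remove = int(round(fraction * alignment.K))
    for taxon in taxa:
        if taxon not in alignment.labels:
            raise ValueError(f"unknown taxon {taxon!r}")
        row = alignment.labels.index(taxon)
        pos = rng.choice(alignment.K, size=n_remove, replace=False)
        matrix[row, pos] = GAP
    return Alignment(list(alignment.labels), matrix)
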