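"""Exact site-pattern probabilities for 4-taxon trees under Jukes–Cantor.

A column of a 4-taxon alignment falls into one of 15 pattern classes
defined by the equality structure of its bases in leaf order (S1, S2, S3,
S4): xxxx; xxxy, xxyx, xyxx, yxxx, xxyy, xyxy, xyyx; xxyz, xyxz, xyzx,
yxxz, yxzx, yzxx; xyzw.  The three doubleton classes xxyy / xyxy / xyyx are
the parsimony-informative ones and map to the quartet topologies
T1 = S1S2|S3S4, T2 = S1S3|S2S4, T3 = S1S4|S2S3.

Class probabilities are obtained by exhaustive enumeration over root (and
internal-node) states and all 256 leaf tuples; under JC every member of a
class is equiprobable, so the per-class totals are exact.  On top of the
class probabilities the module provides the short-branch-attraction
inequalities (uninformative classes dominate; the informative class pairing
the two shortest branches dominates the other two) and the exact
finite-length distribution of the ML quartet topology, obtained by summing
the multinomial law of the informative counts over all compositions.
"""

from __future__ import annotations

from dataclasses import dataclass
import enum
import math

import numpy as np
from scipy.special import gammaln

from sba.models import JCModel, jc_match_prob
from sba.trees import QuartetTopology

__all__ = [
    "PatternClass",
    "PatternProbs",
    "PatternCounts",
    "classify_column",
    "count_patterns",
    "star_class_probs",
    "quartet_class_probs",
    "favored_topology",
    "prob_resolved",
    "exact_mle_distribution",
    "check_sd1_inequalities",
]


class PatternClass(enum.IntEnum):
    """The 15 equality-structure classes of a 4-taxon column."""

    XXXX = 0
    XXXY = 1
    XXYX = 2
    XYXX = 3
    YXXX = 4
    XXYY = 5
    XYXY = 6
    XYYX = 7
    XXYZ = 8
    XYXZ = 9
    XYZX = 10
    YXXZ = 11
    YXZX = 12
    YZXX = 13
    XYZW = 14


_CLASS_NAMES = [c.name.lower() for c in PatternClass]

INFORMATIVE = (PatternClass.XXYY, PatternClass.XYXY, PatternClass.XYYX)

_TOPOLOGY_OF_CLASS = {
    PatternClass.XXYY: QuartetTopology.T1,
    PatternClass.XYXY: QuartetTopology.T2,
    PatternClass.XYYX: QuartetTopology.T3,
}


def _first_occurrence_code(values) -> tuple[int, ...]:
    seen: dict = {}
    out = []
    for v in values:
        if v not in seen:
            seen[v] = len(seen)
        out.append(seen[v])
    return tuple(out)


_CODE_TO_CLASS = {
    _first_occurrence_code(c.name): c for c in PatternClass
}


def _tuple_class_table() -> np.ndarray:
    """Class index of each of the 256 base 4-tuples, flat C-order."""
    table = np.empty(256, dtype=np.int8)
    for flat in range(256):
        w, x, y, z = flat >> 6 & 3, flat >> 4 & 3, flat >> 2 & 3, flat & 3
        table[flat] = _CODE_TO_CLASS[_first_occurrence_code((w, x, y, z))]
    return table


_TUPLE_CLASS = _tuple_class_table()

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class PatternProbs:
    """Probabilities of the 15 pattern classes (each the total over all
    class members) and the informative mass lambda."""

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (15,) or np.any(p < -1e-15):
            raise ValueError("need 15 non-negative class probabilities")
        if not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
            raise ValueError(f"class probabilities must sum to 1, got {p.sum()}")
        object.__setattr__(self, "p", p)

    @property
    def lam(self) -> float:
        """Total probability of the three informative classes."""
        return float(self.p[list(INFORMATIVE)].sum())

    def __getitem__(self, cls: PatternClass) -> float:
        return float(self.p[cls])

    def to_tsv(self) -> str:
        lines = [f"{name}\t{self.p[i]!r}" for i, name in enumerate(_CLASS_NAMES)]
        lines.append(f"lambda\t{self.lam!r}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class PatternCounts:
    """Observed class frequencies of a 4-taxon alignment."""

    omega: np.ndarray
    K: int

    def __post_init__(self):
        omega = np.asarray(self.omega, dtype=np.int64)
        if omega.shape != (15,) or np.any(omega < 0):
            raise ValueError("need 15 non-negative counts")
        if int(omega.sum()) != self.K:
            raise ValueError("counts must sum to K")
        object.__setattr__(self, "omega", omega)

    def __getitem__(self, cls: PatternClass) -> int:
        return int(self.omega[cls])

    def to_tsv(self) -> str:
        lines = [f"{name}\t{int(self.omega[i])}" for i, name in enumerate(_CLASS_NAMES)]
        return "\n".join(lines) + "\n"


def classify_column(bases) -> PatternClass:
    """Pattern class of one alignment column, given as 4 bases in leaf
    order (characters in ACGT or integer state codes 0..3)."""
    states = []
    for b in bases:
        if isinstance(b, str):
            try:
                states.append(_BASE_INDEX[b.upper()])
            except KeyError:
                raise ValueError(f"unknown base {b!r}") from None
        else:
            b = int(b)
            if not 0 <= b <= 3:
                raise ValueError(f"state code out of range: {b}")
            states.append(b)
    if len(states) != 4:
        raise ValueError("a column has exactly 4 bases")
    return _CODE_TO_CLASS[_first_occurrence_code(states)]


def count_patterns(alignment) -> PatternCounts:
    """Tally the 15 pattern classes over the columns of a 4-taxon
    alignment (an :class:`sba.seqsim.Alignment` or a 4xK integer array).

    Columns containing gaps/missing states are excluded; ``K`` is the
    number of classified columns.
    """
    matrix = getattr(alignment, "matrix", None)
    if matrix is None:
        matrix = np.asarray(alignment)
    if matrix.ndim != 2 or matrix.shape[0] != 4:
        raise ValueError("need a 4-row alignment")
    ok = np.all((matrix >= 0) & (matrix <= 3), axis=0)
    cols = matrix[:, ok].astype(np.int64)
    flat = (cols[0] << 6) | (cols[1] << 4) | (cols[2] << 2) | cols[3]
    classes = _TUPLE_CLASS[flat]
    omega = np.bincount(classes, minlength=15)
    return PatternCounts(omega=omega, K=int(omega.sum()))


# ---------------------------------------------------------------------------
# Exact class probabilities


def _aggregate(joint: np.ndarray) -> PatternProbs:
    probs = np.bincount(_TUPLE_CLASS, weights=joint.reshape(256), minlength=15)
    return PatternProbs(p=probs)


def star_class_probs(t1: float, t2: float, t3: float, t4: float) -> PatternProbs:
    """Exact pattern-class probabilities for a 4-taxon star tree under JC.

    The root state is uniform over ACGT; the joint probability of a leaf
    tuple is the product of the four branch transition probabilities,
    summed over the root state and aggregated by class.
    """
    jc = JCModel()
    mats = [jc.transition_matrix(t) for t in (t1, t2, t3, t4)]
    joint = 0.25 * np.einsum("hw,hx,hy,hz->wxyz", *mats)
    return _aggregate(joint)


def quartet_class_probs(t0: float, t1: float, t2: float, t3: float, t4: float) -> PatternProbs:
    """Exact pattern-class probabilities for the bifurcating quartet
    T2 = (S1,S3 | S2,S4) under JC.

    S1 (t1) and S3 (t3) attach to internal node n1; S2 (t2) and S4 (t4)
    attach to n2; t0 is the internal branch.  The class probabilities are
    the mixture of the matched-internal-state star term (weight
    1/4 + 3/4 e^{-4 t0 / 3}) and the mismatched-state term (complementary
    weight, with the second internal state uniform over the three bases
    different from the first).
    """
    for t in (t0, t1, t2, t3, t4):
        if t < 0:
            raise ValueError("branch lengths must be >= 0")
    jc = JCModel()
    m1, m2, m3, m4 = (jc.transition_matrix(t) for t in (t1, t2, t3, t4))
    w_match = jc_match_prob(t0)
    # matched internal states: both halves see the same state H
    joint_match = 0.25 * np.einsum("hw,hx,hy,hz->wxyz", m1, m2, m3, m4)
    # mismatched: n1 = H uniform, n2 = L uniform over the 3 states != H
    mask = (1.0 - np.eye(4)) / 3.0
    joint_mismatch = 0.25 * np.einsum("hl,hw,lx,hy,lz->wxyz", mask, m1, m2, m3, m4)
    joint = w_match * joint_match + (1.0 - w_match) * joint_mismatch
    return _aggregate(joint)


def favored_topology(probs: PatternProbs, rel_tol: float = 1e-12) -> QuartetTopology:
    """Topology of the largest informative class (xxyy -> T1, xyxy -> T2,
    xyyx -> T3); STAR when the maximum is tied within ``rel_tol``."""
    vals = np.array([probs[c] for c in INFORMATIVE], dtype=float)
    best = vals.max()
    tied = np.flatnonzero(vals >= best - rel_tol * max(best, 1e-300))
    if len(tied) > 1:
        return QuartetTopology.STAR
    return _TOPOLOGY_OF_CLASS[INFORMATIVE[int(tied[0])]]


def prob_resolved(lam: float, K: int) -> float:
    """Probability that an alignment of K i.i.d. sites contains at least
    one parsimony-informative site: 1 - (1 - lambda)^K."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if K < 0:
        raise ValueError("K must be >= 0")
    if lam == 1.0:
        return 1.0 if K > 0 else 0.0
    return -math.expm1(K * math.log1p(-lam))


# ---------------------------------------------------------------------------
# Exact finite-length ML-topology distribution

ENUMERATION_CAP = 200


def exact_mle_distribution(
    probs: PatternProbs,
    K: int,
    tie_rule: str = "star",
) -> dict[QuartetTopology, float]:
    """Exact distribution of the count-argmax quartet topology at length K.

    The informative counts (n_xxyy, n_xyxy, n_xyyx) of a K-site alignment
    follow a 4-category multinomial (fourth category: all uninformative
    classes pooled).  Each composition is assigned to the topology whose
    informative count is strictly largest; tied maxima go to STAR
    (``tie_rule='star'``) or are split equally among the tied topologies
    (``tie_rule='random'``, the expected behaviour of a fair engine forced
    to bifurcate).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > ENUMERATION_CAP:
        raise ValueError(
            f"exact enumeration capped at K={ENUMERATION_CAP}; "
            "use Monte Carlo simulation for longer alignments"
        )
    if tie_rule not in ("star", "random"):
        raise ValueError("tie_rule must be 'star' or 'random'")
    p_inf = np.array([probs[c] for c in INFORMATIVE], dtype=float)
    p0 = max(1.0 - p_inf.sum(), 0.0)

    grid = np.arange(K + 1)
    n1, n2, n3 = np.meshgrid(grid, grid, grid, indexing="ij", sparse=False)
    n1 = n1.ravel()
    n2 = n2.ravel()
    n3 = n3.ravel()
    keep = n1 + n2 + n3 <= K
    n1, n2, n3 = n1[keep], n2[keep], n3[keep]
    n0 = K - n1 - n2 - n3

    def xlogp(n, p):
        out = np.zeros_like(n, dtype=float)
        if p > 0:
            out = n * math.log(p)
        else:
            out = np.where(n == 0, 0.0, -np.inf)
        return out

    logpmf = (
        gammaln(K + 1)
        - gammaln(n1 + 1)
        - gammaln(n2 + 1)
        - gammaln(n3 + 1)
        - gammaln(n0 + 1)
        + xlogp(n1, p_inf[0])
        + xlogp(n2, p_inf[1])
        + xlogp(n3, p_inf[2])
        + xlogp(n0, p0)
    )
    pmf = np.exp(logpmf)

    win1 = (n1 > n2) & (n1 > n3)
    win2 = (n2 > n1) & (n2 > n3)
    win3 = (n3 > n1) & (n3 > n2)
    tie = ~(win1 | win2 | win3)

    out = {
        QuartetTopology.T1: float(pmf[win1].sum()),
        QuartetTopology.T2: float(pmf[win2].sum()),
        QuartetTopology.T3: float(pmf[win3].sum()),
        QuartetTopology.STAR: 0.0,
    }
    if tie_rule == "star":
        out[QuartetTopology.STAR] = float(pmf[tie].sum())
    else:
        mx = np.maximum(np.maximum(n1, n2), n3)
        for topo, n in ((QuartetTopology.T1, n1), (QuartetTopology.T2, n2), (QuartetTopology.T3, n3)):
            at_max = tie & (n == mx)
            n_tied = ((n1 == mx).astype(int) + (n2 == mx) + (n3 == mx))
            out[topo] += float((pmf[at_max] / n_tied[at_max]).sum())
    total = sum(out.values())
    assert abs(total - 1.0) < 1e-9
    return out


# ---------------------------------------------------------------------------
# Short-branch-attraction inequalities


def check_sd1_inequalities(t1: float, t2: float, t3: float, t4: float) -> dict:
    """Numerically evaluate the two star-tree pattern inequalities.

    (i) The four singleton (uninformative) two-base classes together carry
    more probability than the three informative classes.
    (ii) When the premise max(t1, t2) < min(t3, t4) holds, the informative
    class xxyy pairing the two short branches strictly dominates xyxy and
    xyyx.

    Returns a dict with each truth value and its margin.
    """
    probs = star_class_probs(t1, t2, t3, t4)
    singletons = sum(
        probs[c] for c in (PatternClass.XXXY, PatternClass.XXYX, PatternClass.XYXX, PatternClass.YXXX)
    )
    lam = probs.lam
    margin1 = singletons - lam
    xxyy = probs[PatternClass.XXYY]
    m_xyxy = xxyy - probs[PatternClass.XYXY]
    m_xyyx = xxyy - probs[PatternClass.XYYX]
    return {
        "uninformative_exceeds_informative": margin1 > 0,
        "uninformative_margin": margin1,
        "short_pair_premise": max(t1, t2) < min(t3, t4),
        "xxyy_dominates": (m_xyxy > 0) and (m_xyyx > 0),
        "xxyy_minus_xyxy": m_xyxy,
        "xxyy_minus_xyyx": m_xyyx,
    }
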