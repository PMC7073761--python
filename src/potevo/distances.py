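"""Site filtering and model-corrected pairwise distances.

Implements the two classical nucleotide substitution corrections used
throughout the pipeline:

* Jukes–Cantor (JC): one substitution class, distance
  ``d = -(3/4) ln(1 - 4p/3)`` for proportion of differing sites ``p``.
* Kimura two-parameter (K2P): transitions (A<->G, C<->T) and
  transversions counted separately as proportions ``P`` and ``Q``,
  distance ``d = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q))``.

Both come with their standard large-sample (delta-method) variances, so
every distance carries a usable standard error.  A raw p-distance is
included for debugging.

Deletion handling follows the usual "complete deletion" convention:
every column containing a gap or ``N`` in *any* row is removed once,
globally, before any pair is compared.  Pairwise deletion (drop bad
sites per pair) is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .seqio import Alignment, SequenceRecord

__all__ = [
    "SitePatternCounts",
    "DistanceEstimate",
    "DistanceMatrix",
    "SaturationError",
    "complete_deletion",
    "count_patterns",
    "p_distance",
    "jc_distance",
    "k2p_distance",
    "distance_matrix",
]

Model = Literal["JC", "K2P", "p"]
Deletion = Literal["complete", "pairwise"]

# Integer coding of bases; -1 marks gap/N/unknown.  Transition partner of
# code b is b ^ 1 (A<->G, C<->T).
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}


class SaturationError(ValueError):
    """Observed divergence outside the domain of the distance formula."""


@dataclass(frozen=True)
class SitePatternCounts:
    """Counts of compared sites and transition/transversion differences."""

    n: int
    ts: int
    tv: int

    def __post_init__(self) -> None:
        if min(self.n, self.ts, self.tv) < 0:
            raise ValueError("site pattern counts must be non-negative")
        if self.ts + self.tv > self.n:
            raise ValueError("ts + tv exceeds number of compared sites")

    @property
    def p(self) -> float:
        """Proportion of differing sites."""
        return (self.ts + self.tv) / self.n

    @property
    def P(self) -> float:
        """Transition proportion."""
        return self.ts / self.n

    @property
    def Q(self) -> float:
        """Transversion proportion."""
        return self.tv / self.n


@dataclass(frozen=True)
class DistanceEstimate:
    """A model-corrected distance (substitutions/site) with its variance."""

    d: float
    var: float
    model: Model

    @property
    def se(self) -> float:
        return math.sqrt(self.var)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes; gaps and N become -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    for base, code in _CODE.items():
        out[arr == base.encode()] = code
    return out


def complete_deletion(aln: Alignment) -> Alignment:
    """Remove every column containing a gap or N in any sequence.

    Row order is preserved.  Raises :class:`SaturationError`-free
    ``ValueError`` if no column survives.
    """
    mat = np.stack([encode(rec.seq) for rec in aln.records])
    keep = (mat >= 0).all(axis=0)
    if not keep.any():
        raise ValueError("no sites remain after complete deletion")
    bases = np.array(list("AGCT"))
    new_records = tuple(
        SequenceRecord(id=rec.id, seq="".join(bases[row[keep]]))
        for rec, row in zip(aln.records, mat)
    )
    return Alignment(records=new_records)


def count_patterns(a: SequenceRecord, b: SequenceRecord) -> SitePatternCounts:
    """Count compared sites, transitions and transversions between two rows.

    Sites with a gap or N in either sequence are excluded from ``n``.
    """
    if len(a) != len(b):
        raise ValueError(
            f"sequences {a.id!r} and {b.id!r} have unequal lengths "
            f"({len(a)} vs {len(b)})"
        )
    ca, cb = encode(a.seq), encode(b.seq)
    ok = (ca >= 0) & (cb >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(
            f"no comparable sites between {a.id!r} and {b.id!r}"
        )
    diff = ok & (ca != cb)
    ts = int((diff & ((ca ^ 1) == cb)).sum())
    tv = int(diff.sum()) - ts
    return SitePatternCounts(n=n, ts=ts, tv=tv)


def p_distance(c: SitePatternCounts) -> DistanceEstimate:
    """Uncorrected proportion of differing sites, binomial variance."""
    p = c.p
    return DistanceEstimate(d=p, var=p * (1.0 - p) / c.n, model="p")


def jc_distance(c: SitePatternCounts) -> DistanceEstimate:
    """Jukes–Cantor distance with its delta-method variance.

    ``d = -(3/4) ln(1 - 4p/3)``; ``var = p(1-p) / (n (1 - 4p/3)^2)``.
    Raises :class:`SaturationError` when ``p >= 3/4``.
    """
    p = c.p
    w = 1.0 - 4.0 * p / 3.0
    if w <= 0.0:
        raise SaturationError(
            f"JC distance undefined: p = {p:.4f} >= 0.75 (saturated pair)"
        )
    d = -0.75 * math.log(w)
    var = p * (1.0 - p) / (c.n * w * w)
    return DistanceEstimate(d=d, var=var, model="JC")


def k2p_distance(c: SitePatternCounts) -> DistanceEstimate:
    """Kimura two-parameter distance with its delta-method variance.

    With ``P = ts/n`` and ``Q = tv/n``::

        d   = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q))
        var = [c1^2 P + c3^2 Q - (c1 P + c3 Q)^2] / n

    where ``c1 = 1/(1-2P-Q)``, ``c2 = 1/(1-2Q)``, ``c3 = (c1+c2)/2``.
    Raises :class:`SaturationError` on domain violation.
    """
    P, Q = c.P, c.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined: P = {P:.4f}, Q = {Q:.4f} (saturated pair)"
        )
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    c1 = 1.0 / w1
    c2 = 1.0 / w2
    c3 = 0.5 * (c1 + c2)
    var = (c1 * c1 * P + c3 * c3 * Q - (c1 * P + c3 * Q) ** 2) / c.n
    return DistanceEstimate(d=d, var=var, model="K2P")


_MODEL_FN = {"JC": jc_distance, "K2P": k2p_distance, "p": p_distance}


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distance estimates."""

    ids: tuple[str, ...]
    d: np.ndarray        # (n, n) distances, zero diagonal
    var: np.ndarray      # (n, n) variances, zero diagonal
    model: Model

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.var.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")

    def index(self, taxon: str) -> int:
        try:
            return self.ids.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in distance matrix") from None

    def pair(self, a: str, b: str) -> DistanceEstimate:
        i, j = self.index(a), self.index(b)
        return DistanceEstimate(
            d=float(self.d[i, j]), var=float(self.var[i, j]), model=self.model
        )

    def to_phylip(self, path: str | Path) -> None:
        """Write the square PHYLIP distance format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, taxon in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{taxon:<10s} {row}\n")

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV: taxon_a, taxon_b, distance, variance, se."""
        with open(path, "w") as fh:
            fh.write("taxon_a\ttaxon_b\tdistance\tvariance\tse\n")
            for i, a in enumerate(self.ids):
                for j in range(i + 1, len(self.ids)):
                    fh.write(
                        f"{a}\t{self.ids[j]}\t{self.d[i, j]:.8f}\t"
                        f"{self.var[i, j]:.3e}\t{math.sqrt(self.var[i, j]):.3e}\n"
                    )


def distance_matrix(
    aln: Alignment,
    model: Model = "K2P",
    deletion: Deletion = "complete",
) -> DistanceMatrix:
    """Pairwise distance matrix under *model* for all rows of *aln*.

    With ``deletion="complete"`` the gap/N columns are removed once,
    globally, before the pair loop; with ``"pairwise"`` each pair drops
    only its own unusable sites.  Saturated pairs raise
    :class:`SaturationError` listing the offending pairs — a silent NaN
    would corrupt downstream tree building.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    if deletion == "complete":
        aln = complete_deletion(aln)
    fn = _MODEL_FN[model]
    n = len(aln)
    D = np.zeros((n, n))
    V = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                est = fn(count_patterns(aln.records[i], aln.records[j]))
            except SaturationError:
                saturated.append((aln.records[i].id, aln.records[j].id))
                continue
            D[i, j] = D[j, i] = est.d
            V[i, j] = V[j, i] = est.var
    if saturated:
        raise SaturationError(
            f"saturated pairs under {model}: {saturated}"
        )
    return DistanceMatrix(ids=aln.ids, d=D, var=V, model=model)
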