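"""Group classification of POTE paralogs from LINE-content signatures.

Human POTE paralogs fall into four groups (I–IV) whose LINE-1 content is
diagnostic:

* group I is massively invaded by young L1PA elements;
* groups I and II carry an L1M5 element in the first intron, absent
  from groups III and IV;
* group II shows the cluster L1M5–L1PA15–L1M5 in the ninth intron,
  where the other groups carry L1ME3G–L1PA15–L1ME3G;
* groups III and IV differ by the intragenic duplication of the exon
  6–9 block (present in group III only).

``assign_group`` encodes these observations as ordered rules R1–R4 over
a :class:`LineSignature`; a paralog whose signature fires conflicting
rules (or none) is ``ambiguous`` — mirroring genes such as POTEKP that
carry features of more than one group.

The module also detects the long inverted repeat (LIR) of the last
intron — a stem-loop-forming palindrome occurring in "full" and "half"
sized variants — by gapped local alignment of a sequence against its
own reverse complement.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .seqio import GenomicInterval, RepeatTrack, interval_length

__all__ = [
    "GeneModel",
    "LineSignature",
    "GroupAssignment",
    "LirCall",
    "extract_line_signature",
    "assign_group",
    "find_inverted_repeat",
    "build_feature_table",
    "read_gene_models",
    "GROUP_II_INTRON9_CLUSTER",
    "GROUP_IV_INTRON9_CLUSTER",
    "DEFAULT_INVASION_FRACTION",
    "DEFAULT_MIN_ARM",
    "DEFAULT_FULL_ARM",
]

Group = Literal["I", "II", "III", "IV", "ambiguous"]

# Diagnostic ninth-intron LINE clusters.
GROUP_II_INTRON9_CLUSTER = ("L1M5", "L1PA15", "L1M5")
GROUP_IV_INTRON9_CLUSTER = ("L1ME3G", "L1PA15", "L1ME3G")

# "Massive L1PA invasion" operationalized as L1PA* elements covering at
# least this fraction of the locus (configurable).
DEFAULT_INVASION_FRACTION = 0.20

# LIR size thresholds (bp of arm). The half/full distinction is an
# operational choice; see docs.
DEFAULT_MIN_ARM = 200
DEFAULT_FULL_ARM = 500


@dataclass
class GeneModel:
    """Exon/intron structure of one gene locus (locus-relative, 1-based).

    ``exons`` are the canonical exons (numbered 1..11 in this family);
    duplicated or paralog-specific exons (6'–9', 9a–9c) are carried in
    ``extra_exons`` as labeled annotations rather than renumbered, so
    intron numbering stays canonical (intron i follows canonical exon i).
    """

    gene_id: str
    exons: list[GenomicInterval]
    extra_exons: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    locus_length: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"gene {self.gene_id!r}: exons overlap near {cur.start}"
                )
        if self.locus_length is None:
            last = self.exons[-1].end
            for _, iv in self.extra_exons:
                last = max(last, iv.end)
            self.locus_length = last

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in order (intron i follows exon i)."""
        out = []
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start - prev.end > 1:
                out.append(
                    GenomicInterval(
                        chrom=prev.chrom, start=prev.end + 1, end=cur.start - 1
                    )
                )
            else:  # zero-length intron; keep numbering stable
                out.append(
                    GenomicInterval(chrom=prev.chrom, start=prev.end, end=prev.end)
                )
        return out

    def intron(self, number: int) -> GenomicInterval:
        """1-based intron number (intron 1 lies between exons 1 and 2)."""
        introns = self.introns
        if not 1 <= number <= len(introns):
            raise ValueError(
                f"gene {self.gene_id!r} has {len(introns)} introns, "
                f"requested intron {number}"
            )
        return introns[number - 1]

    @property
    def total_exon_count(self) -> int:
        return len(self.exons) + len(self.extra_exons)

    @property
    def has_exon6_9_duplication(self) -> bool:
        """True when the gene carries an annotated duplicate of the exon
        6–9 block (labels 6'–9') on top of the 11 canonical exons."""
        primed = {"6'", "7'", "8'", "9'"}
        labels = {label for label, _ in self.extra_exons}
        return self.total_exon_count > 11 and bool(primed & labels)


@dataclass(frozen=True)
class LineSignature:
    """The four LINE-content characters the classifier consumes."""

    l1pa_invasion: bool
    l1m5_intron1: bool
    intron9_cluster: tuple[str, ...]
    exon6_9_dup_content: bool


@dataclass(frozen=True)
class GroupAssignment:
    gene_id: str
    group: Group
    fired_rules: tuple[str, ...]
    conflicts: tuple[str, ...] = ()


@dataclass(frozen=True)
class LirCall:
    """A detected long inverted repeat (stem-loop) in a sequence."""

    status: Literal["full", "half", "none"]
    arm_length: int
    arm_identity: float
    loop_length: int
    arm1: tuple[int, int] | None  # 0-based [start, end) within the query
    arm2: tuple[int, int] | None


def _line_hits(track: RepeatTrack) -> list:
    return [h for h in track.hits if h.repeat_class.upper().startswith("LINE")]


def extract_line_signature(
    track: RepeatTrack,
    model: GeneModel,
    invasion_fraction: float = DEFAULT_INVASION_FRACTION,
) -> LineSignature:
    """Distil a repeat track + gene model into the classifier's characters.

    * ``l1m5_intron1``: any L1M5 hit overlapping intron 1.
    * ``intron9_cluster``: ordered names of LINE hits overlapping intron
      9.  Non-LINE hits are ignored (RepeatMasker fragments elements),
      and consecutive duplicate names are collapsed so a fragmented
      element still reads as one cluster member.
    * ``l1pa_invasion``: L1PA* hits covering at least
      ``invasion_fraction`` of the locus.
    * ``exon6_9_dup_content``: taken from the gene model annotation.
    """
    if track.gene_id != model.gene_id:
        raise ValueError(
            f"track gene {track.gene_id!r} != model gene {model.gene_id!r}"
        )
    locus_len = model.locus_length
    for h in track.hits:
        if h.interval.end > locus_len:
            raise ValueError(
                f"hit {h.repeat_name} at {h.interval.start}-{h.interval.end} "
                f"extends beyond locus end {locus_len} of {model.gene_id!r}: "
                f"coordinate frame mismatch"
            )
    lines = _line_hits(track)

    intron1 = model.intron(1)
    l1m5_intron1 = any(
        h.repeat_name == "L1M5" and h.interval.overlaps(intron1) for h in lines
    )

    intron9 = model.intron(9)
    cluster_raw = [
        h.repeat_name
        for h in lines
        if h.interval.overlaps(intron9)
    ]
    cluster: list[str] = []
    for name in cluster_raw:
        if not cluster or cluster[-1] != name:
            cluster.append(name)

    l1pa_bp = sum(
        interval_length(h.interval)
        for h in lines
        if fnmatch.fnmatch(h.repeat_name, "L1PA*")
    )
    l1pa_invasion = l1pa_bp >= invasion_fraction * locus_len

    return LineSignature(
        l1pa_invasion=l1pa_invasion,
        l1m5_intron1=l1m5_intron1,
        intron9_cluster=tuple(cluster),
        exon6_9_dup_content=model.has_exon6_9_duplication,
    )


def assign_group(sig: LineSignature, gene_id: str = "") -> GroupAssignment:
    """Apply the group rules R1–R4 to a LINE signature.

    R1: L1PA invasion and L1M5 in intron 1          -> group I
    R2: L1M5 in intron 1 and L1M5–L1PA15–L1M5
        cluster in intron 9                          -> group II
    R3: no intron-1 L1M5 and duplicated exon 6–9    -> group III
    R4: no intron-1 L1M5, no duplication, and
        L1ME3G–L1PA15–L1ME3G cluster in intron 9    -> group IV

    All rules are evaluated; more than one firing (or none) yields
    ``ambiguous`` with the conflicting rules recorded.  Pure function:
    the signature fully determines the assignment.
    """
    fired: list[tuple[str, Group]] = []
    if sig.l1pa_invasion and sig.l1m5_intron1:
        fired.append(("R1", "I"))
    if sig.l1m5_intron1 and sig.intron9_cluster == GROUP_II_INTRON9_CLUSTER:
        fired.append(("R2", "II"))
    if not sig.l1m5_intron1 and sig.exon6_9_dup_content:
        fired.append(("R3", "III"))
    if (
        not sig.l1m5_intron1
        and not sig.exon6_9_dup_content
        and sig.intron9_cluster == GROUP_IV_INTRON9_CLUSTER
    ):
        fired.append(("R4", "IV"))

    rule_ids = tuple(r for r, _ in fired)
    groups = {g for _, g in fired}
    if len(groups) == 1:
        return GroupAssignment(gene_id=gene_id, group=fired[0][1], fired_rules=rule_ids)
    return GroupAssignment(
        gene_id=gene_id,
        group="ambiguous",
        fired_rules=rule_ids,
        conflicts=rule_ids if len(groups) > 1 else (),
    )


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


_MATCH, _MISMATCH, _GAP = 1, -1, -2

# Full-matrix DP is used up to this query length; longer sequences get a
# score-only pass plus a windowed traceback (see find_inverted_repeat).
_MAX_FULL_DP = 6000


def _sw_matrix(s: np.ndarray, r: np.ndarray, constrain: bool) -> np.ndarray:
    """Smith–Waterman matrix of *s* vs *r*, filled along anti-diagonals
    (every cell of a diagonal depends only on the previous two, so each
    diagonal is one vectorized update).  With *constrain*, only cells
    with ``i + j <= len(s)`` are computed — the region where, for r =
    revcomp(s), the two aligned segments do not overlap in s.
    """
    n, m = len(s), len(r)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    d_max = n if constrain else n + m
    for d in range(2, d_max + 1):
        lo = max(1, d - m)
        hi = min(n, d - 1)
        if lo > hi:
            continue
        ii = np.arange(lo, hi + 1)
        jj = d - ii
        sub = np.where(s[ii - 1] == r[jj - 1], _MATCH, _MISMATCH)
        vals = H[ii - 1, jj - 1] + sub
        np.maximum(vals, H[ii - 1, jj] + _GAP, out=vals)
        np.maximum(vals, H[ii, jj - 1] + _GAP, out=vals)
        np.maximum(vals, 0, out=vals)
        H[ii, jj] = vals
    return H


def _sw_best_cell(s: np.ndarray, r: np.ndarray) -> tuple[int, int, int]:
    """Score-only constrained SW pass keeping two diagonals: returns
    (best score, i, j) without materializing the matrix."""
    n = len(s)
    prev2 = np.zeros(0, dtype=np.int32)          # interior of diagonal d-2
    prev1 = np.zeros(0, dtype=np.int32)          # interior of diagonal d-1
    best, bi, bj = 0, 0, 0
    for d in range(2, n + 1):
        # interior cells of diagonal d: i = 1..d-1, j = d-i, index k = i-1
        ii = np.arange(1, d)
        jj = d - ii
        cur = np.where(s[ii - 1] == r[jj - 1], _MATCH, _MISMATCH).astype(np.int32)
        cur[1 : len(prev2) + 1] += prev2         # (i-1, j-1), index k-1 on d-2
        up = np.full(d - 1, _GAP, dtype=np.int32)
        up[1:] += prev1                          # (i-1, j), index k-1 on d-1
        left = np.full(d - 1, _GAP, dtype=np.int32)
        left[: len(prev1)] += prev1              # (i, j-1), index k on d-1
        np.maximum(cur, up, out=cur)
        np.maximum(cur, left, out=cur)
        np.maximum(cur, 0, out=cur)
        k = int(cur.argmax())
        if cur[k] > best:
            best = int(cur[k])
            bi, bj = k + 1, d - (k + 1)
        prev2, prev1 = prev1, cur
    return best, bi, bj


def find_inverted_repeat(
    seq: str,
    min_arm: int = DEFAULT_MIN_ARM,
    min_identity: float = 0.8,
    full_arm: int = DEFAULT_FULL_ARM,
) -> LirCall:
    """Locate the best long inverted repeat (stem-loop) in *seq*.

    Smith–Waterman local alignment (match +1, mismatch -1, gap -2) of
    the sequence against its own reverse complement; a cell (i, j)
    pairs base i of the sequence with base n-1-j (complemented), so an
    alignment path is a candidate (arm1, arm2) stem.  Only cells with
    ``i + j <= n`` are considered, which both excludes the trivial
    self-overlapping diagonal and forces arm1 to end before arm2
    starts.  For sequences longer than ~6 kb the matrix is not stored:
    a score-only pass finds the best cell and the traceback is redone
    in a window behind it (exact for any arm of identity above ~0.6,
    which covers every arm the thresholds can call).

    The call is ``full`` when the shorter arm reaches *full_arm* bp at
    identity >= *min_identity*, ``half`` when it reaches *min_arm*,
    otherwise ``none``.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_arm:
        return LirCall("none", 0, 0.0, 0, None, None)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    r = np.frombuffer(_revcomp(seq).encode(), dtype=np.uint8)

    if n <= _MAX_FULL_DP:
        H = _sw_matrix(s, r, constrain=True)
        best = int(H.max())
        if best == 0:
            return LirCall("none", 0, 0.0, 0, None, None)
        i, j = np.unravel_index(int(H.argmax()), H.shape)
        i, j = int(i), int(j)
        oi = oj = 0
    else:
        best, i, j = _sw_best_cell(s, r)
        if best == 0:
            return LirCall("none", 0, 0.0, 0, None, None)
        w = min(min(i, j), 4 * best + 200)
        oi, oj = i - w, j - w
        H = _sw_matrix(s[oi:i], r[oj:j], constrain=False)
        i, j = w, w

    # traceback from (i, j)
    matches = columns = 0
    ei, ej = i, j
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = _MATCH if s[oi + i - 1] == r[oj + j - 1] else _MISMATCH
        if H[i, j] == H[i - 1, j - 1] + sub:
            matches += int(sub == _MATCH)
            columns += 1
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + _GAP:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    gi, gj, gei, gej = oi + i, oj + j, oi + ei, oj + ej
    arm1 = (gi, gei)                    # 0-based half-open in seq
    arm2 = (n - gej, n - gj)            # map revcomp coords back to seq
    arm_len = min(arm1[1] - arm1[0], arm2[1] - arm2[0])
    identity = matches / columns if columns else 0.0
    loop = max(arm2[0] - arm1[1], 0)

    if identity >= min_identity and arm_len >= full_arm:
        status = "full"
    elif identity >= min_identity and arm_len >= min_arm:
        status = "half"
    else:
        status = "none"
    return LirCall(status, arm_len, identity, loop, arm1, arm2)


def build_feature_table(
    assignments: Sequence[GroupAssignment],
    lir_calls: dict[str, LirCall],
    external_features: pd.DataFrame | str | Path | None = None,
) -> pd.DataFrame:
    """Join computed (group, LIR) and externally provided gene features.

    *external_features* supplies columns the pipeline does not compute
    (cysteine/ankyrin/coiled-coil counts, beta-actin retrogene status,
    exon counts) keyed by ``gene_id``.  Genes present in only one
    source get missing-value markers and a warning.
    """
    computed = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in assignments],
            "group": [a.group for a in assignments],
            "fired_rules": [",".join(a.fired_rules) for a in assignments],
        }
    )
    lir_df = pd.DataFrame(
        {
            "gene_id": list(lir_calls),
            "lir": [c.status for c in lir_calls.values()],
            "lir_arm_bp": [c.arm_length for c in lir_calls.values()],
            "lir_arm_identity": [c.arm_identity for c in lir_calls.values()],
        }
    )
    table = computed.merge(lir_df, on="gene_id", how="outer")
    if external_features is not None:
        if not isinstance(external_features, pd.DataFrame):
            external_features = pd.read_csv(external_features, sep="\t")
        if "gene_id" not in external_features.columns:
            raise ValueError("external feature table must have a gene_id column")
        if external_features["gene_id"].duplicated().any():
            dups = external_features.loc[
                external_features["gene_id"].duplicated(), "gene_id"
            ].tolist()
            raise ValueError(f"duplicate gene_id in external table: {dups}")
        if len(external_features.columns) > 1:
            only_ext = set(external_features["gene_id"]) - set(table["gene_id"])
            only_here = set(table["gene_id"]) - set(external_features["gene_id"])
            for gene in sorted(only_ext | only_here):
                warnings.warn(
                    f"gene {gene!r} present in only one feature source",
                    stacklevel=2,
                )
            table = table.merge(external_features, on="gene_id", how="outer")
    return table.sort_values("gene_id").reset_index(drop=True)


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models from a BED-like TSV (1-based inclusive).

    Columns: gene_id, exon_label, start, end.  Canonical exons are
    labeled 1..11; anything else (6', 9a, ...) is carried as an extra
    exon label on the model.
    """
    df = pd.read_csv(path, sep="\t", dtype={"exon_label": str})
    required = {"gene_id", "exon_label", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene model table missing columns: {sorted(missing)}")
    models: dict[str, GeneModel] = {}
    for gene_id, sub in df.groupby("gene_id", sort=False):
        exons: list[GenomicInterval] = []
        extra: list[tuple[str, GenomicInterval]] = []
        for row in sub.itertuples():
            iv = GenomicInterval(
                chrom=str(gene_id), start=int(row.start), end=int(row.end)
            )
            label = str(row.exon_label)
            if label.isdigit():
                exons.append(iv)
            else:
                extra.append((label, iv))
        models[str(gene_id)] = GeneModel(
            gene_id=str(gene_id), exons=exons, extra_exons=extra
        )
    return models
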