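"""Synthetic gene families with known duplication times and repeat histories.

Every stage of the pipeline (distances, trees, rate tests, dating,
classification) can be validated against ground truth generated here:

* :func:`build_event_tree` turns a :class:`DuplicationScenario` — a list
  of timed speciation splits and duplication events — into an
  ultrametric time-tree (branch lengths in Myr);
* :func:`evolve_sequences` runs a continuous-time Kimura two-parameter
  substitution process down that tree at a per-lineage rate ``R``
  (substitutions/site/Myr) and transition/transversion rate ratio
  ``kappa``, so the expected distance between two lineages separated at
  time ``T`` is exactly ``K = 2 R T``;
* :func:`insert_repeats` stamps branch-specific LINE "insertions" onto
  the leaves as RepeatMasker-style annotation tracks (presence in every
  descendant of the insertion lineage, absence elsewhere), emulating
  the group-diagnostic LINE signatures;
* :func:`duplication_scenario_presets` provides the six human POTE
  duplication scenarios (truth times 1.90, 1.57, 1.07, 1.06, 0.55 and
  0.44 Myr) with human–chimpanzee (6 Myr) and human–orangutan (16 Myr)
  calibration splits.

Sequences are generated gap-free, so complete deletion is a no-op on
them; :func:`inject_gaps` exists solely to exercise the deletion logic.
Repeat insertions are annotation-level only — the classifier consumes
tracks, and sequence-level transposon insertion would require
indel-aware alignment, which this package does not model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .classify import (
    GROUP_II_INTRON9_CLUSTER,
    GROUP_IV_INTRON9_CLUSTER,
    GeneModel,
)
from .clock import CalibrationPoint
from .seqio import (
    Alignment,
    GenomicInterval,
    RepeatHit,
    RepeatTrack,
    SequenceRecord,
    write_fasta_alignment,
    write_repeatmasker_out,
)

__all__ = [
    "DuplicationEvent",
    "DuplicationScenario",
    "SimulatedFamily",
    "build_event_tree",
    "evolve_sequences",
    "insert_repeats",
    "inject_gaps",
    "template_gene_model",
    "group_insertion_plan",
    "duplication_scenario_presets",
    "DEFAULT_RATE",
    "DEFAULT_KAPPA",
]

# Per-lineage substitution rate used by the presets, substitutions/site/
# Myr.  1e-3/Myr (= 1e-9/site/year) is the canonical primate neutral
# rate and yields K ~= 0.012 across the 6-Myr human-chimp calibration.
DEFAULT_RATE = 1.0e-3

# Transition/transversion rate ratio; ~2 is typical for mammalian
# nuclear DNA and keeps K2P visibly different from JC.
DEFAULT_KAPPA = 2.0

DEFAULT_SEQ_LENGTH = 10_000


@dataclass(frozen=True)
class DuplicationEvent:
    """A timed duplication: *lineage* splits into (lineage, new_label)."""

    event_id: str
    time_myr: float
    lineage: str
    new_label: str


@dataclass
class DuplicationScenario:
    """A gene-family history: species splits + duplications + process
    parameters.  ``root_label`` is the lineage present at the root."""

    name: str
    root_label: str
    species_splits: list[tuple[str, str, float]]  # (lineage, new_label, Myr)
    events: list[DuplicationEvent]
    rate: float = DEFAULT_RATE            # substitutions/site/Myr per lineage
    kappa: float = DEFAULT_KAPPA
    seq_length: int = DEFAULT_SEQ_LENGTH
    outgroup: str = ""
    group_label: str | None = None        # classifier truth, if repeats simulated

    @property
    def calibrations(self) -> list[CalibrationPoint]:
        return [
            CalibrationPoint(taxon_a=a, taxon_b=b, split_time=t)
            for a, b, t in self.species_splits
        ]

    @property
    def truth_times(self) -> dict[str, float]:
        return {e.event_id: e.time_myr for e in self.events}


@dataclass
class SimulatedFamily:
    """Ground-truthed output of the generator."""

    scenario: DuplicationScenario
    tree: dendropy.Tree                  # time-tree, branch lengths in Myr
    alignment: Alignment                 # gap-free
    tracks: dict[str, RepeatTrack] = field(default_factory=dict)
    gene_models: dict[str, GeneModel] = field(default_factory=dict)
    group_labels: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> list[Path]:
        """Write the family in the formats the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        fasta = outdir / "alignment.fasta"
        write_fasta_alignment(self.alignment, fasta)
        written.append(fasta)

        cal = outdir / "calibrations.tsv"
        with open(cal, "w") as fh:
            fh.write("taxon_a\ttaxon_b\tsplit_time_myr\n")
            for a, b, t in self.scenario.species_splits:
                fh.write(f"{a}\t{b}\t{t}\n")
        written.append(cal)

        truth = outdir / "truth.json"
        with open(truth, "w") as fh:
            json.dump(
                {
                    "scenario": self.scenario.name,
                    "rate_per_myr": self.scenario.rate,
                    "kappa": self.scenario.kappa,
                    "event_times_myr": self.scenario.truth_times,
                    "group_labels": self.group_labels,
                },
                fh,
                indent=2,
            )
        written.append(truth)

        if self.tracks:
            rm = outdir / "repeats.out"
            write_repeatmasker_out(self.tracks.values(), rm)
            written.append(rm)
        if self.gene_models:
            gm = outdir / "gene_models.tsv"
            with open(gm, "w") as fh:
                fh.write("gene_id\texon_label\tstart\tend\n")
                for model in self.gene_models.values():
                    for k, iv in enumerate(model.exons, start=1):
                        fh.write(f"{model.gene_id}\t{k}\t{iv.start}\t{iv.end}\n")
                    for label, iv in model.extra_exons:
                        fh.write(f"{model.gene_id}\t{label}\t{iv.start}\t{iv.end}\n")
            written.append(gm)
        return written


def build_event_tree(sc: DuplicationScenario) -> dendropy.Tree:
    """Time-tree with every split/duplication node at its stated age.

    Splits and duplications are processed from oldest to youngest; each
    acts on a currently-live lineage label and creates a new one.  The
    result is ultrametric with branch lengths in Myr.  A child event
    older than its parent node is an error.
    """
    items: list[tuple[float, str, str]] = [
        (t, lineage, new) for lineage, new, t in sc.species_splits
    ] + [(e.time_myr, e.lineage, e.new_label) for e in sc.events]
    if not items:
        raise ValueError("scenario has no splits or duplication events")
    if sc.species_splits:
        root_split_age = max(t for _, _, t in sc.species_splits)
        for e in sc.events:
            if e.time_myr >= root_split_age:
                raise ValueError(
                    f"duplication {e.event_id!r} at {e.time_myr} Myr is "
                    f"older than its parent split at {root_split_age} Myr"
                )
    items.sort(key=lambda x: -x[0])

    root_age = items[0][0]
    # live lineage -> (node whose subtree is still a tip, birth age)
    live: dict[str, tuple[dendropy.Node, float]] = {}
    root = dendropy.Node()
    first_t, first_lineage, first_new = items[0]
    if first_lineage != sc.root_label:
        raise ValueError(
            f"oldest split must act on the root lineage {sc.root_label!r}, "
            f"got {first_lineage!r}"
        )
    a, b = dendropy.Node(), dendropy.Node()
    root.add_child(a)
    root.add_child(b)
    live[first_lineage] = (a, first_t)
    live[first_new] = (b, first_t)

    for t, lineage, new in items[1:]:
        if lineage not in live:
            raise ValueError(f"event at {t} Myr acts on unknown lineage {lineage!r}")
        if new in live:
            raise ValueError(f"lineage label {new!r} created twice")
        node, birth = live[lineage]
        if t >= birth:
            raise ValueError(
                f"event at {t} Myr on {lineage!r} is older than its parent "
                f"node at {birth} Myr"
            )
        node.edge.length = birth - t
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        live[lineage] = (a, t)
        live[new] = (b, t)

    tns = dendropy.TaxonNamespace()
    for label, (node, birth) in live.items():
        node.edge.length = birth  # tip branch runs to the present
        node.taxon = tns.new_taxon(label)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    tree.root_age = root_age
    return tree


# base codes 0=A 1=G 2=C 3=T; transition partner = code ^ 1
_BASES = np.array(list("AGCT"))


def _k2p_substitution_probs(d: float, kappa: float) -> tuple[float, float]:
    """Expected transition (P) and per-branch transversion (Q)
    proportions after evolving a branch of length *d* substitutions/site
    under K2P with ts/tv rate ratio *kappa*."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    Q = 0.5 * (1.0 - e1)
    P = 0.25 + 0.25 * e1 - 0.5 * e2
    return float(P), float(Q)


def _evolve_branch(
    codes: np.ndarray, d: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """One K2P step: resample every site of *codes* after distance *d*."""
    if d <= 0.0:
        return codes.copy()
    P, Q = _k2p_substitution_probs(d, kappa)
    u = rng.random(codes.shape[0])
    out = codes.copy()
    ts = u < P
    tv1 = (u >= P) & (u < P + Q / 2.0)
    tv2 = (u >= P + Q / 2.0) & (u < P + Q)
    out[ts] ^= 1                                   # A<->G, C<->T
    out[tv1] = (codes[tv1] + 2) % 4                # one transversion partner
    out[tv2] = ((codes[tv2] ^ 1) + 2) % 4          # the other
    return out


def evolve_sequences(
    tree: dendropy.Tree,
    rate: float = DEFAULT_RATE,
    kappa: float = DEFAULT_KAPPA,
    seq_length: int = DEFAULT_SEQ_LENGTH,
    seed: int | np.random.Generator = 0,
    scenario: DuplicationScenario | None = None,
) -> SimulatedFamily:
    """Evolve sequences down a time-tree under the K2P process.

    Branch lengths of *tree* are in Myr; each branch of length ``t``
    applies ``d = rate * t`` expected substitutions/site.  The root
    sequence is uniform over {A,C,G,T}.  Reproducible for a fixed seed.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    root_codes = rng.integers(0, 4, size=seq_length, dtype=np.int8)
    leaf_seqs: dict[str, str] = {}

    def walk(node: dendropy.Node, codes: np.ndarray) -> None:
        for child in node.child_nodes():
            d = rate * (child.edge.length or 0.0)
            child_codes = _evolve_branch(codes, d, kappa, rng)
            if child.is_leaf():
                leaf_seqs[child.taxon.label] = "".join(_BASES[child_codes])
            else:
                walk(child, child_codes)

    walk(tree.seed_node, root_codes)
    records = tuple(
        SequenceRecord(id=label, seq=leaf_seqs[label])
        for label in sorted(leaf_seqs)
    )
    if scenario is None:
        scenario = DuplicationScenario(
            name="ad-hoc",
            root_label="",
            species_splits=[],
            events=[],
            rate=rate,
            kappa=kappa,
            seq_length=seq_length,
        )
    return SimulatedFamily(
        scenario=scenario, tree=tree, alignment=Alignment(records=records)
    )


def simulate_family(
    sc: DuplicationScenario, seed: int | np.random.Generator = 0
) -> SimulatedFamily:
    """Convenience: build the event tree and evolve sequences."""
    tree = build_event_tree(sc)
    return evolve_sequences(
        tree,
        rate=sc.rate,
        kappa=sc.kappa,
        seq_length=sc.seq_length,
        seed=seed,
        scenario=sc,
    )


def inject_gaps(
    aln: Alignment, n_columns: int, seed: int | np.random.Generator = 0
) -> Alignment:
    """Replace *n_columns* random columns with gaps in one random row
    each — exists only to exercise complete-deletion logic."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cols = rng.choice(aln.length, size=n_columns, replace=False)
    rows = [list(rec.seq) for rec in aln.records]
    for col in cols:
        rows[rng.integers(0, len(rows))][col] = "-"
    return Alignment(
        records=tuple(
            SequenceRecord(id=rec.id, seq="".join(row))
            for rec, row in zip(aln.records, rows)
        )
    )


# ---------------------------------------------------------------------------
# Repeat-history simulation
# ---------------------------------------------------------------------------

def template_gene_model(
    gene_id: str, with_exon6_9_duplication: bool = False
) -> GeneModel:
    """The canonical 11-exon gene layout used by the simulator.

    Exons of 150 bp; introns 1 and 9 are large (6 kb) to host the
    diagnostic LINE content, the rest 1 kb.  The optional exon 6–9
    duplicate block (labels 6'–9') is appended downstream of exon 11,
    mimicking the intragenic duplication of group III genes.
    """
    exon_len = 150
    big_intron = 6000
    small_intron = 1000
    exons: list[GenomicInterval] = []
    pos = 1
    for k in range(1, 12):
        exons.append(GenomicInterval(chrom=gene_id, start=pos, end=pos + exon_len - 1))
        intron = big_intron if k in (1, 9) else small_intron
        pos += exon_len + intron
    extra: list[tuple[str, GenomicInterval]] = []
    if with_exon6_9_duplication:
        pos = exons[-1].end + small_intron + 1
        for label in ("6'", "7'", "8'", "9'"):
            extra.append(
                (label, GenomicInterval(chrom=gene_id, start=pos, end=pos + exon_len - 1))
            )
            pos += exon_len + small_intron
    return GeneModel(gene_id=gene_id, exons=exons, extra_exons=extra)


@dataclass(frozen=True)
class RepeatInsertion:
    """A repeat element inserted on *lineage*: present in all its
    descendants, absent elsewhere.  ``intron`` is the canonical intron
    number receiving the element."""

    lineage: str
    repeat_name: str
    intron: int
    length: int = 500
    repeat_class: str = "LINE/L1"


def _descendant_leaves(tree: dendropy.Tree, lineage: str) -> list[str]:
    """Leaves descending from the *branch* of the named lineage.

    A lineage's branch is the edge above the shallowest node whose
    subtree's leaf set equals the lineage's descendants; operationally,
    the lineage label is a leaf label here, and an insertion "on lineage
    X at any time after X's birth" reaches every leaf that X's branch
    leads to — which for post-duplication labels is the leaf itself.
    Insertions meant for an ancestral lineage use the label that was
    live on that branch (labels persist through splits, so e.g. the
    root label's early insertions reach every leaf via ``"root"``).
    """
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if lineage == "root":
        return sorted(labels)
    if lineage not in labels:
        raise ValueError(f"unknown lineage {lineage!r}")
    return [lineage]


def insert_repeats(
    family: SimulatedFamily,
    insertions: list[RepeatInsertion],
    ancestral: dict[str, list[str]] | None = None,
) -> SimulatedFamily:
    """Stamp repeat annotations onto the family's leaves.

    *insertions* on a leaf label mark that leaf only; *ancestral* maps a
    pseudo-lineage name (usable in *insertions*) to the leaf labels it
    subtends, so shared ancestral insertions can be expressed.  The
    special lineage ``"root"`` always means every leaf.  Sequence
    content is untouched: tracks are annotation-level.

    Within each target intron, elements are laid left to right in
    insertion order with a 10 bp spacer, so cluster order is preserved.
    """
    ancestral = dict(ancestral or {})
    leaves = sorted(leaf.taxon.label for leaf in family.tree.leaf_node_iter())
    ancestral.setdefault("root", leaves)

    for gene in leaves:
        family.gene_models.setdefault(gene, template_gene_model(gene))

    per_gene: dict[str, list[RepeatInsertion]] = {g: [] for g in leaves}
    for ins in insertions:
        targets = (
            ancestral[ins.lineage]
            if ins.lineage in ancestral
            else _descendant_leaves(family.tree, ins.lineage)
        )
        for gene in targets:
            per_gene[gene].append(ins)

    spacer = 10
    for gene, gene_insertions in per_gene.items():
        model = family.gene_models[gene]
        cursor: dict[int, int] = {}
        hits = []
        for ins in gene_insertions:
            intron = model.intron(ins.intron)
            start = cursor.get(ins.intron, intron.start)
            end = start + ins.length - 1
            if end > intron.end:
                raise ValueError(
                    f"intron {ins.intron} of {gene!r} overflows at "
                    f"{ins.repeat_name} ({end} > {intron.end})"
                )
            hits.append(
                RepeatHit(
                    query=gene,
                    interval=GenomicInterval(chrom=gene, start=start, end=end),
                    strand="+",
                    repeat_name=ins.repeat_name,
                    repeat_class=ins.repeat_class,
                    score=1000.0,
                )
            )
            cursor[ins.intron] = end + 1 + spacer
        family.tracks[gene] = RepeatTrack(gene_id=gene, hits=hits)
    return family


def group_insertion_plan(group: str, lineage: str = "root") -> list[RepeatInsertion]:
    """The LINE insertions that give a lineage the signature of one of
    the four groups (plus, for group III, the exon 6–9 duplication flag
    which the caller applies via :func:`template_gene_model`).

    Group I:   intron-1 L1M5 + ninth-intron L1ME3G cluster + massive
               L1PA invasion (L1PA2/L1PA3 copies spread across the
               introns, together covering well over the invasion
               threshold fraction of the locus).
    Group II:  intron-1 L1M5 + L1M5–L1PA15–L1M5 cluster in intron 9.
    Group III: L1ME3G cluster in intron 9, no intron-1 L1M5
               (duplicated exon block set on the gene model).
    Group IV:  L1ME3G cluster in intron 9, no intron-1 L1M5, no
               duplication.
    """
    def cluster(names: tuple[str, str, str]) -> list[RepeatInsertion]:
        return [
            RepeatInsertion(lineage=lineage, repeat_name=n, intron=9, length=400)
            for n in names
        ]

    if group == "I":
        invasion = [
            RepeatInsertion(
                lineage=lineage,
                repeat_name="L1PA2" if k % 2 == 0 else "L1PA3",
                intron=k,
                length=800,
            )
            for k in range(2, 9)
        ] + [
            RepeatInsertion(lineage=lineage, repeat_name="L1PA2", intron=1, length=1600),
            RepeatInsertion(lineage=lineage, repeat_name="L1PA3", intron=1, length=1600),
        ]
        l1m5 = [RepeatInsertion(lineage=lineage, repeat_name="L1M5", intron=1, length=400)]
        return l1m5 + invasion + cluster(GROUP_IV_INTRON9_CLUSTER)
    if group == "II":
        l1m5 = [RepeatInsertion(lineage=lineage, repeat_name="L1M5", intron=1, length=400)]
        return l1m5 + cluster(GROUP_II_INTRON9_CLUSTER)
    if group in ("III", "IV"):
        return cluster(GROUP_IV_INTRON9_CLUSTER)
    raise ValueError(f"unknown group {group!r}")


# ---------------------------------------------------------------------------
# Presets: the six dated human POTE duplications
# ---------------------------------------------------------------------------

def _preset(
    name: str,
    paralog_a: str,
    paralog_b: str,
    time_myr: float,
    group_label: str,
) -> DuplicationScenario:
    return DuplicationScenario(
        name=name,
        root_label=paralog_a,
        species_splits=[
            (paralog_a, "orangutan", 16.0),
            (paralog_a, "chimpanzee", 6.0),
        ],
        events=[
            DuplicationEvent(
                event_id=name,
                time_myr=time_myr,
                lineage=paralog_a,
                new_label=paralog_b,
            )
        ],
        outgroup="chimpanzee",
        group_label=group_label,
    )


def duplication_scenario_presets() -> list[DuplicationScenario]:
    """Six single-duplication scenarios matching the dated human POTE
    expansions: each pairs two human paralogs with chimpanzee and
    orangutan ortholog calibration lineages (6 and 16 Myr splits)."""
    return [
        _preset("groupII_first", "POTEB3", "POTEB", 1.07, "II"),
        _preset("groupII_second", "POTEB", "POTEB2", 0.55, "II"),
        _preset("groupIII_EF", "POTEE", "POTEF", 1.90, "III"),
        _preset("groupIII_IJ", "POTEI", "POTEJ", 1.57, "III"),
        _preset("groupIV_first", "POTEH", "POTEG", 1.06, "IV"),
        _preset("groupIV_second", "POTEG", "POTEM", 0.44, "IV"),
    ]
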