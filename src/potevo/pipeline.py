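"""Configuration-driven orchestration of the full analysis.

``run`` ties the stages together: load alignment -> complete deletion
-> distance matrix -> NJ tree with bootstrap + interior-branch supports
-> Tajima rate tests -> rate calibration -> duplication dating ->
LINE-signature classification -> report.  Every output is deterministic
for a fixed config (all randomness flows from the single config seed
through named substreams), and the report records the seed, a config
hash and a checksum per output file.

The config is a flat TOML file; CLI flags override it.  Example::

    alignment = "alignment.fasta"
    calibrations = "calibrations.tsv"
    repeats = "repeats.out"            # optional
    gene_models = "gene_models.tsv"    # optional
    outgroup = "chimpanzee"
    model = "K2P"
    deletion = "complete"
    n_bootstrap = 500
    seed = 1
    events = [["dup1", "POTEE", "POTEF"]]
    outdir = "out"
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, clock, distances, seqio, trees

__all__ = ["RunConfig", "RunReport", "run", "load_config", "substream"]


@dataclass
class RunConfig:
    alignment: str
    calibrations: str | None = None
    repeats: str | None = None
    gene_models: str | None = None
    external_features: str | None = None
    outgroup: str | None = None
    model: str = "K2P"
    deletion: str = "complete"
    n_bootstrap: int = 500
    seed: int = 0
    events: list[list[str]] = field(default_factory=list)  # [id, taxon_a, taxon_b]
    invasion_fraction: float = classify.DEFAULT_INVASION_FRACTION
    lir_min_arm: int = classify.DEFAULT_MIN_ARM
    lir_full_arm: int = classify.DEFAULT_FULL_ARM
    outdir: str = "potevo_out"

    def validate(self) -> None:
        if self.model not in ("JC", "K2P", "p"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.deletion not in ("complete", "pairwise"):
            raise ValueError(f"unknown deletion mode {self.deletion!r}")
        missing = [
            p
            for p in (
                self.alignment,
                self.calibrations,
                self.repeats,
                self.gene_models,
                self.external_features,
            )
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if self.events and self.calibrations is None:
            raise ValueError("dating requested (events set) but no calibration file")
        if self.events and not self.outgroup:
            raise ValueError("dating requested but no outgroup named")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stages: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_config(path: str | Path, **overrides) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child generator of the run seed."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages; see module docstring for order.

    A stage failure raises with the stage name; outputs from completed
    stages are retained on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)

    def finish(stage: str, t0: float) -> None:
        report.stages[stage] = "ok"
        _log(f"[potevo] {stage}: done in {time.perf_counter() - t0:.2f}s")

    def record(path: Path) -> None:
        report.outputs[str(path)] = _checksum(path)

    stage = "load"
    t0 = time.perf_counter()
    try:
        aln = seqio.parse_fasta_alignment(config.alignment)
        cals = (
            clock.read_calibrations(config.calibrations)
            if config.calibrations
            else []
        )
        finish(stage, t0)

        stage = "distances"
        t0 = time.perf_counter()
        dm = distances.distance_matrix(
            aln, model=config.model, deletion=config.deletion
        )
        dm_path = outdir / "distances.tsv"
        dm.to_tsv(dm_path)
        record(dm_path)
        finish(stage, t0)

        stage = "tree"
        t0 = time.perf_counter()
        if len(aln) >= 3:
            tree, boots = trees.bootstrap_support(
                aln,
                model=config.model,
                n_reps=config.n_bootstrap,
                seed=substream(config.seed, "bootstrap"),
            )
            ibt = trees.interior_branch_test(
                aln,
                tree=tree,
                model=config.model,
                n_reps=config.n_bootstrap,
                seed=substream(config.seed, "interior-branch"),
            )
            tree_path = outdir / "tree.nwk"
            seqio.write_newick(tree, tree_path)
            record(tree_path)
            support_path = outdir / "supports.tsv"
            with open(support_path, "w") as fh:
                fh.write(
                    "bipartition\tlength\tbootstrap_support\tbranch_se\t"
                    "confidence_probability\n"
                )
                for rep in ibt:
                    taxa = "|".join(sorted(rep.bipartition))
                    fh.write(
                        f"{taxa}\t{rep.length:.6f}\t{rep.bootstrap_support:.4f}\t"
                        f"{rep.branch_se:.6f}\t{rep.confidence_probability:.4f}\n"
                    )
            record(support_path)
        else:
            report.warnings.append("fewer than 3 sequences: tree stage skipped")
        finish(stage, t0)

        stage = "dating"
        t0 = time.perf_counter()
        if config.events:
            events = [
                clock.DuplicationEventSpec(event_id=e[0], pairs=((e[1], e[2]),))
                for e in config.events
            ]
            results = clock.date_family(
                aln, events, cals, outgroup=config.outgroup, model=config.model
            )
            rows = []
            for r in results:
                test = r.rate_tests[0] if r.rate_tests else None
                rows.append(
                    {
                        "event_id": r.event_id,
                        "K": round(r.K, 8),
                        "R": round(r.rate_used.R, 8),
                        "T_myr": round(r.T, 6),
                        "se_T_myr": round(r.se_T, 6),
                        "se_T_with_rate_myr": round(r.se_T_with_rate, 6),
                        "tajima_chi2": round(test.chi2, 6) if test else "",
                        "tajima_p": round(test.p_value, 6) if test else "",
                    }
                )
            dating = pd.DataFrame(rows)
            dating_tsv = outdir / "dating.tsv"
            dating.to_csv(dating_tsv, sep="\t", index=False)
            record(dating_tsv)
            dating_json = outdir / "dating.json"
            dating.to_json(dating_json, orient="records", indent=2)
            record(dating_json)
        finish(stage, t0)

        stage = "classify"
        t0 = time.perf_counter()
        if config.repeats and config.gene_models:
            tracks = {
                t.gene_id: t
                for t in seqio.parse_repeatmasker_out(config.repeats)
            }
            models = classify.read_gene_models(config.gene_models)
            assignments = []
            for gene_id, model in sorted(models.items()):
                track = tracks.get(gene_id, seqio.RepeatTrack(gene_id=gene_id))
                sig = classify.extract_line_signature(
                    track, model, invasion_fraction=config.invasion_fraction
                )
                assignments.append(classify.assign_group(sig, gene_id=gene_id))
            lir_calls = {
                rec.id: classify.find_inverted_repeat(
                    rec.seq.replace("-", ""),
                    min_arm=config.lir_min_arm,
                    full_arm=config.lir_full_arm,
                )
                for rec in aln.records
                if rec.id in models
            }
            table = classify.build_feature_table(
                assignments, lir_calls, config.external_features
            )
            group_path = outdir / "groups.tsv"
            table.to_csv(group_path, sep="\t", index=False)
            record(group_path)
        finish(stage, t0)
    except Exception as exc:
        report.stages[stage] = f"failed: {exc}"
        report_path = outdir / "report.json"
        report.to_json(report_path)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    report_path = outdir / "report.json"
    report.to_json(report_path)
    return report
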