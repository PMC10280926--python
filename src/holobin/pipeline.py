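"""End-to-end orchestration: simulate -> bin -> covstats -> genomestats
-> ortho -> survey, with curation bookkeeping and a consolidated report.

The report is a plain JSON-serialisable dict: one block per enabled stage,
a full parameter echo, the seed and the package version, so every number
in it is traceable to settings.  Report content is a pure function of
config + inputs; :func:`report_hash` digests it with the timestamp
excluded so reruns can be compared bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .covpart import split_by_coverage, symbiont_cell_ratio, weighted_mean_coverage
from .genomestats import Gene, Transcript, annotation_summary, read_gff3
from .orthstats import core_pan_partition
from .rbh import survey as rbh_survey
from .synthetic import (
    Holobiont,
    HolobiontSpec,
    SynGene,
    generate_holobiont,
    generate_ortho_families,
    generate_protein_panel,
)
from .taxbin import ASSIGNABLE_TAXA, bin_metagenome

__all__ = [
    "ConfigError",
    "StageError",
    "CurationLedger",
    "RunConfig",
    "apply_curation_ledger",
    "run_pipeline",
    "report_hash",
    "genes_from_synthetic",
]

logger = logging.getLogger("holobin")

STAGES = ("simulate", "bin", "covstats", "genomestats", "ortho", "survey")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name (exit code 3)."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class CurationLedger:
    """Bookkeeping of manual gene-set curation: removals and additions.

    ``final_count``, when recorded, must agree with
    initial - sum(removals) + sum(additions); intermediate counts may
    never go negative.
    """

    initial_count: int
    removals: list[tuple[str, int]] = field(default_factory=list)
    additions: list[tuple[str, int]] = field(default_factory=list)
    final_count: int | None = None


def apply_curation_ledger(ledger: CurationLedger) -> int:
    """Replay a curation ledger and return (and verify) the final count."""
    if ledger.initial_count < 0:
        raise ValueError(f"initial_count must be >= 0, got {ledger.initial_count}")
    count = ledger.initial_count
    for reason, n in ledger.removals:
        if n < 0:
            raise ValueError(f"removal {reason!r}: count must be >= 0, got {n}")
        count -= n
        if count < 0:
            raise ValueError(
                f"removal {reason!r} drives the gene count negative ({count})"
            )
    for reason, n in ledger.additions:
        if n < 0:
            raise ValueError(f"addition {reason!r}: count must be >= 0, got {n}")
        count += n
    if ledger.final_count is not None and ledger.final_count != count:
        raise ValueError(
            f"recorded final_count {ledger.final_count} disagrees with "
            f"ledger arithmetic {count}"
        )
    return count


@dataclass
class RunConfig:
    """All knobs of one pipeline run, with paper-derived defaults."""

    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    seed: int = 0
    outdir: str | None = None
    log_level: str = "INFO"
    # stage parameters
    min_fraction: float = 0.5
    min_len: int = 1000
    k: int = 3
    ploidy: int = 2
    window: int = 10000
    min_score: int = 60
    # synthetic-data parameters
    holobiont: dict = field(default_factory=dict)
    ortho: dict = field(
        default_factory=lambda: {
            "n_species": 10,
            "genus_map": {
                f"G{g}_sp{s}": f"Genus{g}" for g in range(1, 6) for s in (1, 2)
            },
            "n_families": 1000,
            "core_fraction": 0.28,
            "genus_restricted_fraction": 0.47,
            "loss_rate": 0.0,
        }
    )
    panel: dict = field(
        default_factory=lambda: {"n_families": 100, "present_fraction": 0.8}
    )
    # optional file inputs (used instead of simulation when given)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError("unknown config keys: " + ", ".join(sorted(bad)))
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ConfigError("unknown stages: " + ", ".join(sorted(bad)))
        on = {s for s in STAGES if self.stages.get(s, False)}
        have_files = {"coverage", "calls"} <= set(self.inputs)
        if "bin" in on and not (self.stages.get("simulate") or have_files):
            raise ConfigError(
                "stage 'bin' needs either the simulate stage or coverage+calls inputs"
            )
        if "covstats" in on and "bin" not in on:
            raise ConfigError("stage 'covstats' depends on stage 'bin'")
        if "genomestats" in on and not (
            self.stages.get("simulate") or {"assembly", "gff"} <= set(self.inputs)
        ):
            raise ConfigError(
                "stage 'genomestats' needs either the simulate stage or assembly+gff inputs"
            )

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def genes_from_synthetic(syngenes: list[SynGene]) -> list[Gene]:
    """Convert generator gene models to annotation-stat gene records."""
    out = []
    for g in syngenes:
        tr = Transcript(f"{g.gene_id}.t1", exons=list(g.exons), cds=list(g.exons))
        out.append(Gene(g.gene_id, g.scaffold_id, g.start, g.end, g.strand, [tr]))
    return out


def _stage_bin(config, scaffolds, calls):
    assignments, summary = bin_metagenome(
        scaffolds, calls, min_fraction=config.min_fraction, min_len=config.min_len
    )
    block = {
        b: {k: v for k, v in info.items() if k != "scaffold_ids"}
        for b, info in summary.items()
    }
    return assignments, summary, block


def _stage_covstats(config, scaffolds, assignments):
    by_bin: dict[str, list] = {}
    lookup = {s.scaffold_id: s for s in scaffolds}
    for a in assignments:
        by_bin.setdefault(a.bin, []).append(lookup[a.scaffold_id])
    host = by_bin.get("Eukaryota", [])
    symb = by_bin.get("Archaea", [])
    if not host or not symb:
        raise StageError(
            "covstats",
            "need non-empty Eukaryota (host) and Archaea (symbiont) bins for the "
            "cell-ratio estimate",
        )
    host_cov = weighted_mean_coverage(host)
    symb_cov = weighted_mean_coverage(symb)
    est = symbiont_cell_ratio(
        symb_cov, host_cov, config.ploidy,
        symbiont_bin="Archaea", host_bin="Eukaryota",
    )
    retained = [s for s in scaffolds if s.scaffold_id in {a.scaffold_id for a in assignments}]
    k = min(config.k, len(retained))
    covbins = split_by_coverage(retained, k)
    return {
        "host_coverage": host_cov,
        "symbiont_coverage": symb_cov,
        "cell_ratio": est.ratio,
        "cell_ratio_rounded": est.rounded,
        "host_ploidy": config.ploidy,
        "coverage_bins": [
            {
                "name": b.name,
                "n_scaffolds": b.n_scaffolds,
                "total_length": b.total_length,
                "mean_coverage": b.mean_coverage,
            }
            for b in covbins
        ],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the report dict."""
    config.validate()
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="[holobin:%(name)s] %(levelname)s %(message)s",
    )
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    holo: Holobiont | None = None
    scaffolds = calls = None
    assignments = None

    if config.stages.get("simulate"):
        logger.info("simulate: generating synthetic holobiont")
        spec = HolobiontSpec(**{**config.holobiont, "seed": config.seed})
        holo = generate_holobiont(spec)
        if config.outdir:
            holo.write(Path(config.outdir) / "sim")
        report["stages"]["simulate"] = {
            "n_scaffolds": len(holo.scaffolds),
            "n_genes": len(holo.genes),
            "n_calls": len(holo.calls),
            "spec": dataclasses.asdict(spec),
        }
        scaffolds, calls = holo.scaffolds, holo.calls

    if config.stages.get("bin"):
        if scaffolds is None:
            from . import io as hio

            cov = hio.read_coverage_tsv(config.inputs["coverage"])
            calls = hio.read_calls_tsv(config.inputs["calls"])
            gene_map = {c.gene_id: c.scaffold_id for c in calls}
            scaffolds = hio.scaffolds_from_tables(cov, gene_map)
        logger.info("bin: classifying %d scaffolds", len(scaffolds))
        try:
            assignments, _summary, block = _stage_bin(config, scaffolds, calls)
        except ValueError as exc:
            raise StageError("bin", str(exc)) from exc
        report["stages"]["bin"] = block

    if config.stages.get("covstats"):
        logger.info("covstats: coverage partition and cell ratio")
        report["stages"]["covstats"] = _stage_covstats(config, scaffolds, assignments)

    if config.stages.get("genomestats"):
        logger.info("genomestats: compactness panel")
        try:
            if holo is not None:
                host_ids = {
                    s for s, b in holo.truth.scaffold_bins.items() if b == "host_nuclear"
                }
                seqs = {s: holo.sequences[s] for s in host_ids}
                genes = genes_from_synthetic(
                    [g for g in holo.genes if g.scaffold_id in host_ids]
                )
            else:
                from . import io as hio

                seqs = hio.read_fasta(config.inputs["assembly"])
                genes = read_gff3(config.inputs["gff"])
            report["stages"]["genomestats"] = annotation_summary(
                seqs, genes, window=config.window
            )
        except ValueError as exc:
            raise StageError("genomestats", str(exc)) from exc

    if config.stages.get("ortho"):
        logger.info("ortho: core/pan partition")
        params = dict(config.ortho)
        params.setdefault("seed", config.seed)
        matrix, truth = generate_ortho_families(**params)
        report["stages"]["ortho"] = core_pan_partition(matrix).headline()

    if config.stages.get("survey"):
        logger.info("survey: reciprocal-best-hit panel")
        params = dict(config.panel)
        params.setdefault("seed", config.seed)
        pdata = generate_protein_panel(**params)
        calls_ = rbh_survey(
            pdata.panel, pdata.queryome, pdata.targetome, min_score=config.min_score
        )
        agree = sum(
            1
            for c in calls_
            if (c.status == "present") == pdata.truth.family_present[c.family]
        )
        report["stages"]["survey"] = {
            "n_families": len(calls_),
            "present": sum(c.status == "present" for c in calls_),
            "absent": sum(c.status == "absent" for c in calls_),
            "ambiguous": sum(c.status == "ambiguous" for c in calls_),
            "truth_agreement": agree / len(calls_) if calls_ else None,
        }

    if config.outdir:
        from . import io as hio

        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_json(report, out / "report.json")
    return report


def report_hash(report: dict) -> str:
    """SHA256 of the report with volatile fields (timestamp) excluded."""
    stable = {k: v for k, v in report.items() if k != "timestamp"}
    payload = json.dumps(stable, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()
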