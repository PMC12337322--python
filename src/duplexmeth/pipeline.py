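"""Run configuration and the staged pipeline driver.

The pipeline chains the library stages over plain files in a working
directory -- simulate -> extract -> call -> filter -> evaluate-spikeins ->
correct -> summarize -- with every intermediate a TSV (or FASTQ/FASTA), so
any stage can be rerun from its serialized inputs.  The effective
configuration is written next to the outputs and its short hash appears in
the header of every tabular file the run produces.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._tsv import read_table
from .align import call_sites, write_sites
from .correct import (ConfusionMatrix, build_confusion, correct_fractions,
                      observed_fractions, write_fractions)
from .extract import extract_fastq, read_quads
from .genome import (DuplexMethylome, SpikeInPanel, assign_states,
                     build_spikein_panel, generate_reference, read_fasta)
from .model import DEFAULT_STATE_FRACTIONS, StateFractions
from .simulate import (AdapterConfig, ChemistryErrorModel, simulate_reads,
                       simulate_spikein_reads, write_fastq)
from .summarize import filter_sites, site_fractions, write_frame

logger = logging.getLogger("duplexmeth")

STAGES = ("simulate", "extract", "call", "filter", "evaluate-spikeins",
          "correct", "summarize")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a run needs; fully serializable to YAML."""

    seed: int = 0
    n_fragments: int = 15_000
    spikein_pairs_per_duplex: int = 500
    read_len: int = 300
    mean_fragment_len: int = 100
    sd_fragment_len: int = 10
    aligner_k: int = 16
    align_max_mismatch: int = 5
    adapter_max_mismatch: int = 2
    min_depth: int = 5
    max_errors: int = 1
    genome_length: int = 20_000
    genome_contigs: int = 1
    cpg_density: float = 0.02
    state_fractions: dict = field(
        default_factory=lambda: DEFAULT_STATE_FRACTIONS.as_dict())
    adapters: AdapterConfig = field(default_factory=AdapterConfig)
    errors: ChemistryErrorModel = field(default_factory=ChemistryErrorModel)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "adapters" in d:
            if d["adapters"] is None:
                raise ValueError("adapter configuration missing")
            d["adapters"] = AdapterConfig(**d["adapters"])
        if "errors" in d:
            d["errors"] = ChemistryErrorModel(**d["errors"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:10]

    def header(self) -> list[str]:
        return [f"duplexmeth {__version__} config={self.hash()}"]

    def fractions(self) -> StateFractions:
        return StateFractions.from_dict(self.state_fractions)


def make_fixture(seed: int = 0, outdir: str | Path = "fixture",
                 config: RunConfig | None = None) -> RunConfig:
    """Emit a small, fully deterministic test dataset.

    Writes the reference, its duplex-state truth, the spike-in panel and
    the run configuration; the simulate stage then produces the reads.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or RunConfig()
    cfg = dataclasses.replace(cfg, seed=seed)
    reference = generate_reference(cfg.genome_contigs, cfg.genome_length,
                                   cfg.cpg_density, seed)
    methylome = assign_states(reference, cfg.fractions(), seed + 1)
    panel = build_spikein_panel(
        seed + 2,
        adapter_sequences=[cfg.adapters.intact, cfg.adapters.cleavable,
                           cfg.adapters.remnant],
        coverage_target=cfg.spikein_pairs_per_duplex)
    methylome.write_fasta(outdir / "genome.fa")
    methylome.write_states(outdir / "genome_states.tsv", cfg.header())
    panel.write_fasta(outdir / "spikein.fa")
    panel.write_sidecar(outdir / "spikein_states.tsv", cfg.header())
    cfg.to_yaml(outdir / "config.yaml")
    return cfg


def run_pipeline(config: RunConfig, workdir: str | Path,
                 stages=None) -> dict:
    """Execute the requested stages in canonical order over ``workdir``.

    ``workdir`` must contain genome.fa / genome_states.tsv / spikein.fa /
    spikein_states.tsv (see :func:`make_fixture`) plus, optionally, a
    blacklist.bed.  Returns a dict of summary information per stage.
    """
    wd = Path(workdir)
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages.sort(key=STAGES.index)
    config.to_yaml(wd / "config_used.yaml")
    hdr = config.header()
    report: dict = {}

    def _require(path: Path, stage: str):
        if not path.exists():
            raise PipelineError(stage, f"missing input {path.name}")
        return path

    for stage in stages:
        logger.info("stage %s", stage)
        try:
            if stage == "simulate":
                methylome = DuplexMethylome.read(
                    _require(wd / "genome.fa", stage),
                    _require(wd / "genome_states.tsv", stage))
                panel = SpikeInPanel.read(
                    _require(wd / "spikein.fa", stage),
                    _require(wd / "spikein_states.tsv", stage),
                    config.spikein_pairs_per_duplex)
                pairs, tp, tc = simulate_reads(
                    methylome, config.n_fragments, config.errors,
                    config.adapters, config.read_len,
                    config.mean_fragment_len, config.sd_fragment_len,
                    seed=config.seed + 10)
                write_fastq(pairs, wd / "reads_R1.fastq.gz", wd / "reads_R2.fastq.gz")
                from ._tsv import write_table
                write_table(tp, wd / "truth_pairs.tsv", hdr)
                write_table(tc, wd / "truth_calls.tsv", hdr)
                spairs, stp, stc = simulate_spikein_reads(
                    panel, config.spikein_pairs_per_duplex, config.errors,
                    config.adapters, config.read_len, seed=config.seed + 20)
                write_fastq(spairs, wd / "spike_R1.fastq.gz", wd / "spike_R2.fastq.gz")
                write_table(stp, wd / "spike_truth_pairs.tsv", hdr)
                write_table(stc, wd / "spike_truth_calls.tsv", hdr)
                report[stage] = {"pairs": len(pairs), "spike_pairs": len(spairs)}
            elif stage == "extract":
                for prefix in ("reads", "spike"):
                    out = "quads.tsv" if prefix == "reads" else "spike_quads.tsv"
                    _, summary = extract_fastq(
                        _require(wd / f"{prefix}_R1.fastq.gz", stage),
                        _require(wd / f"{prefix}_R2.fastq.gz", stage),
                        wd / out, wd / f"{prefix}_extract_summary.json",
                        config.adapters, config.adapter_max_mismatch,
                        comments=hdr)
                    report.setdefault(stage, {})[prefix] = summary
            elif stage == "call":
                for quads_file, ref_file, out in (
                        ("quads.tsv", "genome.fa", "sites.tsv"),
                        ("spike_quads.tsv", "spikein.fa", "spike_sites.tsv")):
                    quads = read_quads(_require(wd / quads_file, stage))
                    reference = read_fasta(_require(wd / ref_file, stage))
                    sites, stats = call_sites(quads, reference,
                                              config.aligner_k,
                                              config.align_max_mismatch)
                    write_sites(sites, wd / out, hdr)
                    report.setdefault(stage, {})[quads_file] = stats
            elif stage == "filter":
                sites = read_table(_require(wd / "sites.tsv", stage))
                blacklist = wd / "blacklist.bed"
                retained, frep = filter_sites(
                    sites, config.min_depth,
                    blacklist if blacklist.exists() else None,
                    config.max_errors)
                write_sites(retained, wd / "sites_filtered.tsv", hdr)
                (wd / "filter_report.json").write_text(json.dumps(frep, indent=2))
                report[stage] = frep
            elif stage == "evaluate-spikeins":
                sites = read_table(_require(wd / "spike_sites.tsv", stage))
                truth = DuplexMethylome.read(
                    _require(wd / "spikein.fa", stage),
                    _require(wd / "spikein_states.tsv", stage)).states
                confusion = build_confusion(sites, truth)
                confusion.write(wd / "confusion.tsv", hdr)
                report[stage] = {"min_accuracy": confusion.min_accuracy(),
                                 "condition": confusion.condition_number()}
            elif stage == "correct":
                sites = read_table(_require(wd / "sites_filtered.tsv", stage))
                confusion = ConfusionMatrix.read(_require(wd / "confusion.tsv", stage))
                observed = observed_fractions(sites)
                result = correct_fractions(observed, confusion)
                frame = result.as_frame()
                frame.insert(1, "observed", observed.values)
                write_frame(frame, wd / "fractions.tsv",
                            hdr + [f"residual={result.residual:.3e} "
                                   f"condition={result.condition:.6g} "
                                   f"estimate_sum={result.estimate.total:.9f}"])
                report[stage] = {"estimate_sum": result.estimate.total,
                                 "residual": result.residual}
            elif stage == "summarize":
                sites = read_table(_require(wd / "sites_filtered.tsv", stage))
                fracs = site_fractions(sites)
                write_frame(fracs, wd / "site_fractions.tsv", hdr)
                report[stage] = {"sites": int(len(fracs))}
        except PipelineError:
            raise
        except Exception as exc:  # halt with the failing stage's name
            raise PipelineError(stage, str(exc)) from exc
    return report
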