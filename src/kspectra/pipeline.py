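"""End-to-end orchestration: simulate -> count -> histogram -> peak/size ->
spectrum fit -> ploidy -> report, with every artifact written under a run
directory and a manifest recording inputs, seeds and conventions.

All randomness flows from the seeds in the config, so a rerun with the same
config is byte-identical (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cytometry import PG_PER_MBP
from .errors import KspectraError, NoPairsError, PipelineStageError
from .kmercount import count_canonical_kmers, histogram_from_counts, write_histo
from .peaksize import find_error_cutoff, find_peaks, general_formula_size
from .smudge import analyze as smudge_analyze
from .spectrumfit import fit_spectrum
from .stats import make_estimate_table, summarize_estimates
from .synthkit import GenomeSpec, ReadSimConfig, simulate_genome, simulate_reads

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

logger = logging.getLogger("kspectra")

_ALL_STAGES = ("simulate", "count", "estimate", "fit", "smudge", "report")


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration: what to simulate, which k values, which stages."""

    genome: GenomeSpec
    reads: ReadSimConfig = field(default_factory=ReadSimConfig)
    ks: tuple[int, ...] = (21,)
    stages: tuple[str, ...] = _ALL_STAGES
    label: str = "run"
    write_reads: bool = True

    def __post_init__(self):
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise KspectraError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        genome = GenomeSpec(**raw["genome"])
        reads = ReadSimConfig(**raw.get("reads", {}))
        return cls(
            genome=genome,
            reads=reads,
            ks=tuple(raw.get("ks", (21,))),
            stages=tuple(raw.get("stages", _ALL_STAGES)),
            label=str(raw.get("label", "run")),
            write_reads=bool(raw.get("write_reads", True)),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "genome": dataclasses.asdict(self.genome),
            "reads": dataclasses.asdict(self.reads),
            "ks": list(self.ks),
            "stages": list(self.stages),
            "label": self.label,
            "write_reads": self.write_reads,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def demo_config() -> PipelineConfig:
    """The default demonstration run: 1-Mb heterozygous diploid (r = 1%),
    60x pooled coverage, k = 21."""
    return PipelineConfig(
        genome=GenomeSpec(haploid_length=1_000_000, ploidy_structure="AB",
                          het_rate=0.01, seed=11),
        reads=ReadSimConfig(coverage=60.0, seed=12),
        ks=(21,),
        label="demo",
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict.

    A stage failure raises :class:`PipelineStageError` naming the stage;
    artifacts from completed stages are retained in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(fh)
    manifest: dict = {
        "label": config.label,
        "version": __version__,
        "inputs": {
            "genome": dataclasses.asdict(config.genome),
            "reads": dataclasses.asdict(config.reads),
            "ks": list(config.ks),
        },
        "decisions": {
            "peak_convention": "global-mode",
            "canonicalization": "lexicographic min(kmer, revcomp), odd k",
            "haploid_length_divisor": "ploidy * lambda",
        },
        "stages": {},
    }

    state: dict = {}
    try:
        for stage in config.stages:
            logger.info("stage %s", stage)
            try:
                outputs = _STAGE_FUNCS[stage](config, outdir, state)
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001 - annotate with stage name
                raise PipelineStageError(stage, e) from e
            manifest["stages"][stage] = outputs
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    finally:
        logger.removeHandler(fh)
        fh.close()


def _stage_simulate(config, outdir, state):
    haps = simulate_genome(config.genome)
    reads = simulate_reads(haps, config.reads)
    state["haps"], state["reads"] = haps, reads
    outputs = []
    fasta = outdir / "haplotypes.fasta"
    haps.write_fasta(fasta)
    outputs.append(fasta.name)
    if config.write_reads:
        for p in reads.write_fastq(outdir / "reads.fastq"):
            outputs.append(p.name)
    return outputs


def _stage_count(config, outdir, state):
    reads = state["reads"]
    outputs = []
    state["hists"] = {}
    state["tables"] = {}
    for k in config.ks:
        table = count_canonical_kmers(reads, k)
        hist = histogram_from_counts(table)
        state["tables"][k] = table
        state["hists"][k] = hist
        path = outdir / f"k{k}.histo"
        write_histo(hist, path)
        outputs.append(path.name)
    return outputs


def _stage_estimate(config, outdir, state):
    rows = []
    results = []
    L = config.reads.read_length
    for k in config.ks:
        hist = state["hists"][k]
        x_err = find_error_cutoff(hist)
        peaks = find_peaks(hist, x_err)
        res = general_formula_size(hist, x_err, peaks.peak_depth, L, k)
        results.append(res)
        rows.append(("General Formula", k, "processed", res.genome_size / 1e6))
    state["gf_results"] = results
    state["estimate_rows"] = rows
    path = outdir / "general_formula.tsv"
    with open(path, "w") as fh:
        fh.write(results[0].tsv_header() + "\n")
        for res in results:
            fh.write(res.tsv_row() + "\n")
    sidecar = outdir / "general_formula.json"
    sidecar.write_text(
        json.dumps([json.loads(r.to_json()) for r in results], indent=2,
                   sort_keys=True) + "\n"
    )
    return [path.name, sidecar.name]


def _stage_fit(config, outdir, state):
    k = config.ks[0]
    fit = fit_spectrum(state["hists"][k], k=k, ploidy=config.genome.ploidy)
    state["fit"] = fit
    path = outdir / "spectrum_fit.json"
    fit.to_json(path)
    tsv = outdir / "genome_properties.tsv"
    tsv.write_text(fit.property_table() + "\n")
    return [path.name, tsv.name]


def _stage_smudge(config, outdir, state):
    k = config.ks[0]
    if k > 31:
        raise KspectraError("smudge stage requires k <= 31")
    fit = state.get("fit")
    if fit is None:
        fit = fit_spectrum(state["hists"][k], k=k, ploidy=config.genome.ploidy)
    # the diploid-convention fit pegs 2*lam at the homozygous peak, so the
    # per-copy depth anchor for a known ploidy p is 2*lam/p
    lam = 2.0 * fit.params.lam / config.genome.ploidy
    x_err = find_error_cutoff(state["hists"][k])
    path = outdir / "smudge.json"
    try:
        grid = smudge_analyze(state["tables"][k], lam=lam, x_err=x_err)
    except NoPairsError as e:
        path.write_text(json.dumps({"ploidy_call": None, "error": str(e)},
                                   indent=2, sort_keys=True) + "\n")
        return [path.name]
    grid.call_json(path)
    grid_tsv = outdir / "smudge_grid.tsv"
    grid.write_tsv(grid_tsv)
    return [path.name, grid_tsv.name]


def _stage_report(config, outdir, state):
    rows = state.get("estimate_rows", [])
    outputs = []
    table = make_estimate_table(rows)
    est_path = outdir / "estimates.tsv"
    table.to_csv(est_path, sep="\t", index=False)
    outputs.append(est_path.name)
    if len(config.ks) >= 2:
        summary = summarize_estimates(table)
        spath = outdir / "estimate_summary.tsv"
        summary.to_csv(spath, sep="\t", index=False, float_format="%.6g")
        outputs.append(spath.name)
    report = {}
    if state.get("gf_results"):
        g = state["gf_results"][0]
        report["general_formula_mbp"] = g.genome_size / 1e6
        report["implied_1c_pg"] = g.genome_size / 1e6 * PG_PER_MBP
    if "fit" in state:
        report["het_pct"] = state["fit"].het_pct
        report["repeat_pct"] = state["fit"].repeat_pct
        report["haploid_length_bp"] = state["fit"].haploid_length
    rpath = outdir / "report.json"
    rpath.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    outputs.append(rpath.name)
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "count": _stage_count,
    "estimate": _stage_estimate,
    "fit": _stage_fit,
    "smudge": _stage_smudge,
    "report": _stage_report,
}
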