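"""End-to-end orchestration of the analysis stages.

Stage order: hits -> blocks -> ks -> peaks (mixtures) -> dating on one
branch; blocks -> depth -> table -> fractionation -> P-index on the other;
table -> orthogroups -> trees -> counts for the phylogenomic check.  A run
writes every stage's artifact under the configured output directory together
with a manifest (inputs, parameters, seed, package version); a rerun with
the same config and seed is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd

import wgdkit
from wgdkit import collinearity, dating, depth_align, fractionation, kaks
from wgdkit.annotation import GenomeAnnotation, read_cds_fasta
from wgdkit.config import PipelineConfig

STAGES = ["simulate", "hits", "blocks", "ks", "peaks", "date", "depth", "table",
          "fractionate", "pindex"]

_DEPS = {
    "hits": [],
    "blocks": ["hits"],
    "ks": ["blocks"],
    "peaks": ["ks"],
    "date": ["peaks"],
    "depth": ["blocks"],
    "table": ["blocks"],
    "fractionate": ["table"],
    "pindex": ["table"],
}


class DependencyError(RuntimeError):
    pass


@dataclass
class RunReport:
    outdir: str
    stages_run: list[str] = field(default_factory=list)
    artifacts: dict[str, list[str]] = field(default_factory=dict)
    counts: dict[str, float] = field(default_factory=dict)

    def manifest(self, config: PipelineConfig) -> dict:
        return {
            "version": wgdkit.__version__,
            "seed": config.seed,
            "parameters": config.params.__dict__,
            "stages": self.stages_run,
            "artifacts": self.artifacts,
            "counts": self.counts,
        }


class Pipeline:
    """Holds loaded inputs and stage products for one configured run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.annotations: dict[str, GenomeAnnotation] = {}
        self.cds: dict[str, dict[str, str]] = {}
        self.hits: dict[tuple[str, str], pd.DataFrame] = {}
        self.blocks: dict[tuple[str, str], list] = {}
        self.ks_samples: dict[tuple[str, str], list[float]] = {}
        self.mixtures: dict[tuple[str, str], dating.KsMixtureModel] = {}
        self.depths: dict[tuple[str, str], depth_align.DepthProfile] = {}
        self.table: depth_align.AlignmentTable | None = None
        self.pindex: dict[str, fractionation.PIndexResult] = {}
        self.report = RunReport(outdir=config.outdir)

    # -- helpers -------------------------------------------------------

    def _out(self, name: str) -> str:
        os.makedirs(self.config.outdir, exist_ok=True)
        return os.path.join(self.config.outdir, name)

    def _record(self, stage: str, *paths: str, **counts) -> None:
        if stage not in self.report.stages_run:
            self.report.stages_run.append(stage)
        self.report.artifacts.setdefault(stage, []).extend(paths)
        self.report.counts.update(counts)

    def _require(self, stage: str) -> None:
        for dep in _DEPS.get(stage, []):
            if dep not in self.report.stages_run:
                raise DependencyError(
                    f"stage {stage!r} needs {dep!r}: run stage {dep!r} first"
                )

    def load_inputs(self) -> None:
        for entry in self.config.genomes:
            if entry.name in self.annotations or not entry.gff3:
                continue
            self.annotations[entry.name] = GenomeAnnotation.from_gff3(
                entry.gff3, name=entry.name
            )
            if entry.cds:
                self.cds[entry.name] = read_cds_fasta(entry.cds)

    # -- stages --------------------------------------------------------

    def stage_simulate(self) -> None:
        from wgdkit.simulate import (LineageRate, Scenario, WgdEvent,
                                     simulate_scenario)

        sc = dict(self.config.scenario)
        if not sc:
            raise DependencyError("no scenario configured for stage 'simulate'")
        events = [WgdEvent(**e) for e in sc.pop("wgd_events", [])]
        rates = [LineageRate(**r) for r in sc.pop("rates", [])]
        sc.setdefault("seed", self.config.seed)
        scenario = Scenario(wgd_events=events, rates=rates, **sc)
        result = simulate_scenario(scenario)
        paths = []
        for sp, genome in result.genomes.items():
            gff = self._out(f"{sp}.gff3")
            fa = self._out(f"{sp}.cds.fasta")
            genome.annotation.to_gff3(gff)
            from wgdkit.annotation import write_cds_fasta

            write_cds_fasta(genome.cds, fa)
            paths += [gff, fa]
            self.annotations[sp] = genome.annotation
            self.cds[sp] = genome.cds
        truth_path = self._out("truth_ledger.tsv")
        result.truth.write_tsv(truth_path)
        species = sorted(result.genomes)
        for i, a in enumerate(species):
            for b in species[i:]:
                hp = self._out(f"hits_{a}_{b}.tsv")
                result.write_hits(a, b, hp, seed=self.config.seed)
                self.hits[(a, b)] = result.hit_pairs(a, b, seed=self.config.seed)
                paths.append(hp)
        self.simulation = result
        self._record("simulate", truth_path, *paths,
                     n_species=len(species))
        self.report.stages_run.append("hits")  # simulate provides hits too

    def stage_hits(self) -> None:
        p = self.config.params
        for entry in self.config.hits:
            pair = (entry.a, entry.b)
            self.hits[pair] = collinearity.read_hits(
                entry.path, self.annotations[entry.a], self.annotations[entry.b],
                evalue_cutoff=p.evalue, best_n=p.best_n,
            )
        self._record("hits", n_hit_files=len(self.config.hits))

    def stage_blocks(self) -> None:
        self._require("blocks")
        p = self.config.params
        total = 0
        paths = []
        for (a, b), hits in self.hits.items():
            blocks = collinearity.chain_blocks(
                hits, self.annotations[a], self.annotations[b],
                max_gap=p.max_gap, min_anchors=p.min_anchors,
            )
            self.blocks[(a, b)] = blocks
            total += len(blocks)
            path = self._out(f"blocks_{a}_{b}.tsv")
            collinearity.blocks_to_frame(blocks).to_csv(path, sep="\t", index=False)
            paths.append(path)
        self._record("blocks", *paths, n_blocks=total)

    def stage_ks(self) -> None:
        self._require("ks")
        paths = []
        for (a, b), blocks in self.blocks.items():
            sample = []
            for block in blocks:
                kaks.block_ks(block, {**self.cds[a], **self.cds[b]})
                sample.extend(v for v in block.ks_values if v is not kaks.SATURATED)
            self.ks_samples[(a, b)] = sample
            pairs = [(g1, g2) for bl in blocks for _, _, g1, g2 in bl.anchors]
            frame = kaks.pairwise_ks_table(pairs, {**self.cds[a], **self.cds[b]})
            path = self._out(f"ks_{a}_{b}.tsv")
            frame.to_csv(path, sep="\t", index=False)
            paths.append(path)
        self._record("ks", *paths)

    def stage_peaks(self) -> None:
        self._require("peaks")
        rows = []
        for pair, sample in self.ks_samples.items():
            try:
                model = dating.fit_mixture(sample, k="auto", seed=self.config.seed)
            except (dating.InsufficientDataError, dating.ConvergenceError):
                continue
            self.mixtures[pair] = model
            for comp in model.components:
                rows.append((f"{pair[0]}-{pair[1]}", comp.weight, comp.mean, comp.sd,
                             model.n))
        path = self._out("mixtures.tsv")
        pd.DataFrame(rows, columns=["comparison", "weight", "mean", "sd", "n"]).to_csv(
            path, sep="\t", index=False
        )
        self._record("peaks", path, n_mixtures=len(self.mixtures))

    def stage_date(self) -> None:
        self._require("date")
        cal = self.config.calibration
        calibration = dating.EventCalibration(cal.event, cal.ks_peak, cal.age_lo,
                                              cal.age_hi)
        events = {}
        for pair, model in self.mixtures.items():
            for i, peak in enumerate(model.peaks):
                events[f"{pair[0]}-{pair[1]}#{i + 1}"] = peak
        frame = dating.dating_report(events, calibration)
        path = self._out("dating.tsv")
        frame.to_csv(path, sep="\t", index=False)
        self._record("date", path, n_dated=len(frame))

    def stage_depth(self) -> None:
        self._require("depth")
        p = self.config.params
        rows = []
        for (a, b), blocks in self.blocks.items():
            profile = depth_align.depth_ratio(
                blocks, self.annotations[a], self.annotations[b],
                min_anchors=p.min_anchors,
            )
            self.depths[(a, b)] = profile
            ratio = profile.ratio or ("NA", "NA")
            rows.append((a, b, ratio[0], ratio[1]))
        path = self._out("depth_ratios.tsv")
        pd.DataFrame(rows, columns=["ref", "query", "ref_multiplicity",
                                    "query_multiplicity"]).to_csv(
            path, sep="\t", index=False
        )
        self._record("depth", path)

    def stage_table(self) -> None:
        self._require("table")
        cfg = self.config
        p = cfg.params
        ref_name = cfg.reference
        ref = self.annotations[ref_name]
        ref_entry = cfg.genome(ref_name)
        queries = []
        for entry in cfg.genomes:
            if entry.name == ref_name:
                continue
            pair = (ref_name, entry.name)
            blocks = self.blocks.get(pair) or self.blocks.get(pair[::-1]) or []
            queries.append((self.annotations[entry.name], entry.depth, blocks))
        self_blocks = self.blocks.get((ref_name, ref_name), [])
        self.table = depth_align.build_alignment_table(
            ref, queries, ref_self_blocks=self_blocks, ref_depth=ref_entry.depth,
            min_anchors=p.min_anchors,
        )
        path = self._out("alignment_table.csv")
        self.table.to_csv(path)
        self._record("table", path, table_columns=self.table.n_columns)

    def stage_fractionate(self) -> None:
        self._require("fractionate")
        paths = []
        rows = []
        for col in self.table.data.columns:
            if col in ("chrom", f"{self.config.reference}.1"):
                continue
            spectrum = fractionation.loss_runs(self.table, col)
            if spectrum.n_runs >= 10:
                fractionation.fit_geometric(spectrum)
            for length, c in sorted(spectrum.counts.items()):
                rows.append((col, length, c, spectrum.p_hat))
        path = self._out("loss_runs.tsv")
        pd.DataFrame(rows, columns=["column", "run_length", "n_runs", "p_hat"]).to_csv(
            path, sep="\t", index=False
        )
        paths.append(path)
        self._record("fractionate", *paths)

    def stage_pindex(self) -> None:
        self._require("pindex")
        p = self.config.params
        rows = []
        for entry in self.config.genomes:
            cols = self.table.columns_of(entry.name) if self.table else []
            if entry.name == self.config.reference or len(cols) < 2:
                continue
            rw = fractionation.retention_windows(
                self.table, cols[0], cols[1], window=p.window, step=p.step
            )
            if rw.n_windows == 0:
                continue
            result = fractionation.p_index(rw, low=p.delta_low, high=p.delta_high)
            self.pindex[entry.name] = result
            rows.append((entry.name, result.p_index,
                         result.is_allopolyploid(p.p_index_threshold)))
        path = self._out("p_index.tsv")
        pd.DataFrame(rows, columns=["genome", "p_index", "allopolyploid"]).to_csv(
            path, sep="\t", index=False
        )
        self._record("pindex", path)

    # -- driver --------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> RunReport:
        wanted = stages or [s for s in STAGES if s != "simulate" or self.config.scenario]
        unknown = set(wanted) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" in wanted:
            self.stage_simulate()
        if self.config.genomes:
            self.load_inputs()
        for stage in STAGES:
            if stage in ("simulate",) or stage not in wanted:
                continue
            if stage == "hits" and "hits" in self.report.stages_run:
                continue  # provided by the simulator
            getattr(self, f"stage_{stage}")()
        manifest_path = self._out("manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(self.report.manifest(self.config), fh, indent=2, sort_keys=True)
        return self.report


def run(config: PipelineConfig, stages: list[str] | None = None) -> RunReport:
    """Run the configured pipeline stages in dependency order."""
    return Pipeline(config).run(stages)
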