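"""End-to-end campaign orchestration.

Runs the stages in dependency order — library design statistics, the
synthetic selection campaign (library, MACS, gated FACS rounds, reads),
read counting, enrichment tables, assay scoring on simulated raw data,
and descriptor flagging/ranking — writing TSV/JSON outputs and a run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amplicon import PARENTAL_KEY, bococizumab_template
from .assays import acsins_score, melting_temperature, polyreactivity_score
from .config import CampaignConfig
from .datasets import characterization_panel
from .enrichment import (
    SampleCounts,
    count_sample,
    normalized_counts,
    pair_enrichment,
    residue_enrichment,
)
from .io import counts_to_frame, write_fastq, write_table
from .library_design import (
    DegenerateLibraryDesign,
    expected_aa_distribution,
    oversampling_fold,
    poisson_coverage,
    report_fold,
)
from .ranking import (
    compute_cutoffs,
    count_flags,
    flags_vs_ranking,
    overall_ranking,
)
from .synthetic import (
    GateSpec,
    calibrate_parental_bias,
    default_phenotype_model,
    simulate_acsins_spectrum,
    simulate_descriptor_tables,
    simulate_elisa_plate,
    simulate_library,
    simulate_melt_curve,
    simulate_reads,
    simulate_round,
)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "design_report"]


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _spawn_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def design_report(config: CampaignConfig) -> pd.DataFrame:
    """Library design statistics table (diversities, folds, coverage)."""
    lib = config.library
    design = DegenerateLibraryDesign.from_pattern(lib.pattern, lib.n_positions)
    n_integrants = lib.cells * lib.efficiency
    fold_dna = oversampling_fold(lib.cells, lib.efficiency, design.dna_diversity)
    fold_aa = oversampling_fold(lib.cells, lib.efficiency, design.aa_diversity)
    cov_dna = poisson_coverage(n_integrants, design.dna_diversity, "uniform")
    cov_aa = poisson_coverage(
        n_integrants, design.aa_diversity, lib.model, design=design
    )
    rows = [
        ("codon_pattern", design.codon_pattern),
        ("n_positions", design.n_positions),
        ("dna_diversity", design.dna_diversity),
        ("aa_diversity", design.aa_diversity),
        ("cells_transfected", lib.cells),
        ("integration_efficiency", lib.efficiency),
        ("n_integrants", n_integrants),
        ("oversampling_dna", fold_dna),
        ("oversampling_dna_reported", report_fold(fold_dna)),
        ("oversampling_aa", fold_aa),
        ("oversampling_aa_reported", report_fold(fold_aa)),
        ("expected_dna_coverage", cov_dna.expected_coverage),
        ("full_aa_coverage_probability", cov_aa.full_coverage_probability),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value"])


def _simulate_samples(config: CampaignConfig):
    """Library + MACS + gated FACS rounds; returns (populations, template,
    model, gates, bias)."""
    sim = config.simulation
    lib = config.library
    design = DegenerateLibraryDesign.from_pattern(lib.pattern, lib.n_positions)
    bias = calibrate_parental_bias(design, lib.target_parental_frequency)
    seeds = iter(_spawn_seeds(sim.seed, 2 + sum(sim.rounds.values()) + len(sim.rounds)))
    model = default_phenotype_model(cell_noise_sd=sim.cell_noise_sd)
    populations = {}
    pre = simulate_library(
        design,
        parental_bias=bias,
        n_integrants=sim.n_integrants,
        seed=next(seeds),
    )
    populations["pre-selection"] = pre
    macs_gate = GateSpec("MACS", display_threshold=sim.macs_display_threshold)
    macs = simulate_round(pre, model, macs_gate, sim.n_cells_sorted, seed=next(seeds))
    populations["MACS-sorted"] = macs
    gates = {
        name: GateSpec(
            name,
            display_threshold=block.display_threshold,
            binding_threshold=block.binding_threshold,
        )
        for name, block in sim.gates.items()
    }
    for name, n_rounds in sim.rounds.items():
        pop = macs
        for r in range(1, n_rounds + 1):
            pop = simulate_round(
                pop, model, gates[name], sim.n_cells_sorted, seed=next(seeds)
            )
            populations[f"{name}-r{r}"] = pop
    return populations, bococizumab_template(), model, gates, bias


def run_pipeline(
    config: CampaignConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = ("design", "simulate", "count", "enrich", "assays", "flags"),
) -> RunManifest:
    """Execute the requested stages in dependency order; manifest last."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__, config=config.model_dump(), started=time.time()
    )
    outputs: list[Path] = []
    state: dict = {}

    def _stage(name, fn):
        if name not in stages:
            return
        t0 = time.time()
        files = fn()
        outputs.extend(files)
        manifest.stages[name] = {
            "outputs": [str(p.relative_to(outdir)) for p in files],
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("stage %s: %.2fs", name, time.time() - t0)

    def do_design():
        path = outdir / "design_report.tsv"
        write_table(design_report(config), path)
        design = DegenerateLibraryDesign.from_pattern(
            config.library.pattern, config.library.n_positions
        )
        dist = expected_aa_distribution(design)
        dist_path = outdir / "expected_aa_distribution.tsv"
        write_table(
            pd.DataFrame(
                sorted(dist.items()), columns=["amino_acid", "expected_frequency"]
            ),
            dist_path,
        )
        return [path, dist_path]

    def do_simulate():
        populations, template, model, gates, bias = _simulate_samples(config)
        state.update(
            populations=populations, template=template, model=model, gates=gates
        )
        sim = config.simulation
        files = []
        read_seeds = _spawn_seeds(sim.seed + 101, len(populations))
        fastq_dir = outdir / "reads"
        fastq_dir.mkdir(exist_ok=True)
        for (name, pop), seed in zip(populations.items(), read_seeds):
            reads = simulate_reads(
                pop, template, sim.depth, sim.per_base_error, seed=seed
            )
            path = fastq_dir / f"{name}.fastq"
            write_fastq(reads, path)
            files.append(path)
        truth_rows = []
        for name, pop in populations.items():
            for key, freq in pop.frequencies.items():
                truth_rows.append(
                    {
                        "sample_id": name,
                        "vh_pair": key.vh_pair,
                        "vl_pair": key.vl_pair,
                        "dna_key": key.dna_key,
                        "frequency": freq,
                        "display_mu": model.display_mu(key),
                        "binding_mu": model.binding_mu(key),
                        "p_pass_best": model.gate_pass_probability(key, gates["best"])
                        if "best" in gates
                        else float("nan"),
                    }
                )
        truth_path = outdir / "ground_truth.tsv"
        write_table(pd.DataFrame(truth_rows), truth_path)
        files.append(truth_path)
        meta_path = outdir / "simulation_meta.json"
        meta_path.write_text(
            json.dumps({"parental_bias": bias, "parental": str(PARENTAL_KEY)}, indent=2)
        )
        files.append(meta_path)
        return files

    def do_count():
        from .io import read_fastq

        enr = config.enrichment
        template = state.get("template", bococizumab_template())
        samples: dict[str, SampleCounts] = {}
        fastq_dir = outdir / "reads"
        for path in sorted(fastq_dir.glob("*.fastq")):
            name = path.stem
            samples[name] = count_sample(
                (rec.sequence for rec in read_fastq(path)),
                template,
                sample_id=name,
                level=enr.level,
                max_anchor_mismatches=enr.max_anchor_mismatches,
            )
        state["samples"] = samples
        path = outdir / "variant_counts.tsv"
        write_table(counts_to_frame(samples.values()), path)
        return [path]

    def do_enrich():
        samples = state["samples"]
        enr = config.enrichment
        pre = samples["pre-selection"]
        files = []
        final_ids = {
            name: f"{name}-r{n}" for name, n in config.simulation.rounds.items()
        }
        top_rows = []
        for popname, fid in final_ids.items():
            if fid not in samples:
                continue
            for rec in pair_enrichment(pre, samples[fid], "combined", top=enr.top):
                top_rows.append(
                    {
                        "population": popname,
                        "variant": str(rec.variant),
                        "normalized_count_pct": 100 * rec.nc_sample,
                        "enrichment_factor": rec.enrichment_factor,
                        "status": rec.status,
                    }
                )
        path = outdir / "top_variants.tsv"
        write_table(pd.DataFrame(top_rows), path)
        files.append(path)
        res_rows = []
        for popname, fid in final_ids.items():
            if fid not in samples:
                continue
            for position in ("VL94", "VL95", "VH53", "VH54"):
                table = residue_enrichment(pre, samples[fid], position)
                for res, rec in table.enrichment.items():
                    res_rows.append(
                        {
                            "population": popname,
                            "position": position,
                            "residue": res,
                            "freq_pre": rec.nc_pre,
                            "freq_final": rec.nc_sample,
                            "enrichment_factor": rec.enrichment_factor,
                        }
                    )
        res_path = outdir / "residue_enrichment.tsv"
        write_table(pd.DataFrame(res_rows), res_path)
        files.append(res_path)
        return files

    def do_assays():
        panel = characterization_panel()
        ass = config.assays
        seeds = iter(_spawn_seeds(config.simulation.seed + 202, 8 * len(panel)))
        rows = []
        for variant, row in panel.iterrows():
            blank = [
                simulate_acsins_spectrum(
                    527.0, noise_sd=ass.spectrum_noise_sd, seed=next(seeds)
                )
                for _ in range(3)
            ]
            sample = [
                simulate_acsins_spectrum(
                    527.0 + row["acsins_nm"],
                    noise_sd=ass.spectrum_noise_sd,
                    seed=next(seeds),
                )
                for _ in range(3)
            ]
            acsins = acsins_score(sample, blank, ass.fit_halfwidth_nm)
            plate = simulate_elisa_plate(
                {a: row["polyreactivity"] for a in
                 ("dsDNA", "ssDNA", "LPS", "KLH", "cardiolipin", "insulin")},
                noise_sd=ass.elisa_noise_sd,
                seed=next(seeds),
            )
            elisa = polyreactivity_score(plate)
            curve = simulate_melt_curve(
                row["tm_c"], noise_sd=ass.melt_noise_sd, seed=next(seeds)
            )
            tm = melting_temperature(curve, ass.smooth_window_c)
            rows.append(
                {
                    "variant": variant,
                    "acsins_nm": acsins.score_nm,
                    "acsins_nm_true": row["acsins_nm"],
                    "polyreactivity": elisa.score,
                    "polyreactivity_true": row["polyreactivity"],
                    "tm_c": tm,
                    "tm_c_true": row["tm_c"],
                    "pdi": row["pdi"],
                    "hic_rt_min": row["hic_rt_min"],
                }
            )
        scores = pd.DataFrame(rows).set_index("variant")
        state["assay_scores"] = scores
        path = outdir / "assay_scores.tsv"
        write_table(scores.reset_index(), path)
        return [path]

    def do_flags():
        fl = config.flags
        scores = state.get("assay_scores")
        if scores is None:
            scores = characterization_panel().rename(columns={})
        rank_panel = scores[["acsins_nm", "polyreactivity", "pdi", "hic_rt_min", "tm_c"]]
        ranking = overall_ranking(rank_panel)
        # descriptor ground truth: liability shift grows with true rank-sum order
        order = ranking.index.tolist()
        shifts = np.linspace(0.0, 2.0, len(order))
        reference, variants = simulate_descriptor_tables(
            n_reference=fl.n_reference,
            n_variants=len(order),
            n_descriptors=fl.n_descriptors,
            shift_per_variant=shifts,
            seed=config.simulation.seed + 303,
        )
        variants.index = order
        cutoffs = compute_cutoffs(reference, sd_mode=fl.sd_mode)
        flags = count_flags(variants, cutoffs)
        files = []
        flags_path = outdir / "descriptor_flags.tsv"
        flags_frame = flags.rename("n_flags").rename_axis("variant").reset_index()
        write_table(flags_frame, flags_path)
        files.append(flags_path)
        rank_path = outdir / "overall_ranking.tsv"
        write_table(ranking.reset_index(names="variant"), rank_path)
        files.append(rank_path)
        report = flags_vs_ranking(flags, ranking["rank_sum"])
        corr_path = outdir / "correlations.json"
        corr_path.write_text(json.dumps(report, indent=2))
        files.append(corr_path)
        return files

    _stage("design", do_design)
    _stage("simulate", do_simulate)
    _stage("count", do_count)
    _stage("enrich", do_enrich)
    _stage("assays", do_assays)
    _stage("flags", do_flags)

    manifest.finished = time.time()
    manifest.output_digests = {
        str(p.relative_to(outdir)): _digest(p) for p in outputs
    }
    manifest.to_json(outdir / "manifest.json")
    return manifest
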