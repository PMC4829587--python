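"""End-to-end orchestration on a synthetic MA cohort: simulate -> coverage
-> detection -> annotation -> fate classification -> statistics, with
deterministic seeded output and optional report emission.

The stage order mirrors the analysis of a real cohort; swap the simulated
pileups for pileup TSVs read with :func:`mitodrift.pileup.read_pileup_tsv`
to run the same stages on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotate import EffectAnnotation, GeneticCode, INVERTEBRATE_MT, annotate_call
from .coverage import CopyNumberSummary, copy_number_table, fold_change, summarize_line
from .detect import FilterThresholds, HeteroplasmyCall, LineProfile, call_heteroplasmies
from .genome import GeneAnnotation, ReferenceGenome, RegionMask
from .inheritance import FateMatrix, build_fate_matrix
from .pileup import write_pileup_tsv
from .reports import indel_table, snp_table, write_fate_tsv, write_vcf
from .simulate import (
    SimulationConfig,
    simulate_pileups,
    simulate_reference,
    simulate_transmission,
    _rng,
)
from .stats import kruskal_wallis, levene_test, pairwise_posthoc

__all__ = ["PipelineResult", "run_pipeline"]

PROGENITOR = "Progenitor"


@dataclass
class PipelineResult:
    genome: ReferenceGenome
    annotations: list[GeneAnnotation]
    mask: RegionMask
    profiles: dict[str, LineProfile]
    copy_number: pd.DataFrame
    calls: dict[str, list[tuple[HeteroplasmyCall, EffectAnnotation]]]
    snp_report: pd.DataFrame
    indel_report: pd.DataFrame
    fate: FateMatrix
    stats_summary: dict
    log: list[str] = field(default_factory=list)

    def passed_calls(self, line: str) -> list[HeteroplasmyCall]:
        return [c for c, _ in self.calls[line] if c.passed]


def _line_names(n_lines: int) -> list[str]:
    return [PROGENITOR] + [f"MA{i + 1}" for i in range(n_lines)]


def _per_region_copy_numbers(
    profile: LineProfile,
    summary: CopyNumberSummary,
    annotations: list[GeneAnnotation],
    mask: RegionMask,
    n_regions: int = 14,
) -> list[float]:
    """Normalized per-region copy numbers for the statistics stage.

    Regions are the annotated genes when a gene layout exists, otherwise
    equal-width windows (unmasked sites only); each region's mean coverage
    is normalized by the line's single-copy nuclear mean.
    """
    covs: dict[int, int] = {
        p.position: p.coverage() for p in profile.pileups if p.position not in mask
    }
    regions: list[list[int]] = []
    if annotations:
        for ann in annotations:
            regions.append([pos for pos in range(ann.start, ann.end + 1) if pos in covs])
    else:
        positions = sorted(covs)
        for chunk in np.array_split(np.array(positions), n_regions):
            regions.append(list(chunk))
    values = []
    for region in regions:
        if region:
            values.append(
                float(np.mean([covs[p] for p in region])) / summary.single_copy_mean
            )
    return values


def run_pipeline(
    config: SimulationConfig,
    thresholds: FilterThresholds = FilterThresholds(),
    line_frequencies: Mapping[str, Mapping[int, float]] | None = None,
    code: GeneticCode = INVERTEBRATE_MT,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a simulated cohort.

    ``line_frequencies`` optionally fixes each line's planted-variant
    frequencies (line name -> position -> frequency); otherwise every MA
    line receives the endpoint of an independent Wright-Fisher transmission
    trajectory started at each variant's founder frequency, and the
    progenitor carries the founder frequencies themselves.

    All randomness derives from ``config.seed``; reruns are byte-identical.
    """
    log = [f"seed={config.seed}", f"thresholds={thresholds}"]
    genome, annotations, mask = simulate_reference(config)
    names = _line_names(config.n_lines)

    freqs: dict[str, dict[int, float]] = {}
    for idx, name in enumerate(names):
        if line_frequencies is not None:
            freqs[name] = dict(line_frequencies.get(name, {}))
        elif name == PROGENITOR:
            freqs[name] = {
                pv.position: pv.founder_frequency for pv in config.planted_variants
            }
        else:
            freqs[name] = {
                pv.position: float(
                    simulate_transmission(
                        pv.founder_frequency,
                        config.bottleneck_N,
                        config.generations,
                        _rng(config.seed, 10, idx, pv.position),
                    )[-1]
                )
                for pv in config.planted_variants
            }

    profiles: dict[str, LineProfile] = {}
    summaries: list[CopyNumberSummary] = []
    for idx, name in enumerate(names):
        pileups = simulate_pileups(config, freqs[name], line_index=idx, genome=genome)
        profiles[name] = LineProfile(
            line=name,
            pileups=pileups,
            role="progenitor" if name == PROGENITOR else "MA",
            generations=0 if name == PROGENITOR else config.generations,
            mask=mask,
        )
        gene_rng = _rng(config.seed, 11, idx)
        gene_means = {
            g: float(config.nuclear_mean_coverage * gene_rng.lognormal(0.0, 0.15))
            for g in ("nuc-a", "nuc-b", "nuc-c")
        }
        summaries.append(summarize_line(name, pileups, gene_means, mask))
        log.append(f"line {name}: planted {freqs[name]}")

    copy_table = copy_number_table(summaries)

    calls: dict[str, list[tuple[HeteroplasmyCall, EffectAnnotation]]] = {}
    baseline = [profiles[PROGENITOR]]
    for name in names:
        raw = call_heteroplasmies(
            profiles[name],
            thresholds,
            baseline_profiles=[] if name == PROGENITOR else baseline,
        )
        calls[name] = [
            (c, annotate_call(c, genome, annotations, code)) for c in raw
        ]

    all_calls = [pair for pairs in calls.values() for pair in pairs]
    snp_report = snp_table([p for p in all_calls if p[0].passed])
    indel_report = indel_table([p for p in all_calls if p[0].passed])

    fate = build_fate_matrix(
        {name: [c for c, _ in calls[name]] for name in names}, progenitor=PROGENITOR
    )

    ma_values = copy_table[copy_table.line != PROGENITOR]["norm_mtdna"].to_list()
    prog_value = float(
        copy_table.loc[copy_table.line == PROGENITOR, "norm_mtdna"].iloc[0]
    )
    mean_fold, fold_range = fold_change(ma_values, prog_value)
    groups = {
        name: _per_region_copy_numbers(
            profiles[name],
            summaries[names.index(name)],
            annotations,
            mask,
        )
        for name in names
    }
    usable = all(len(v) >= 2 for v in groups.values()) and len(groups) >= 2
    stats_summary = {
        "copy_number_fold_change": mean_fold,
        "copy_number_fold_range": fold_range,
        "levene": levene_test(groups) if usable else None,
        "kruskal_wallis": kruskal_wallis(groups) if usable else None,
        "posthoc": pairwise_posthoc(groups) if usable else None,
    }

    result = PipelineResult(
        genome=genome,
        annotations=annotations,
        mask=mask,
        profiles=profiles,
        copy_number=copy_table,
        calls=calls,
        snp_report=snp_report,
        indel_report=indel_report,
        fate=fate,
        stats_summary=stats_summary,
        log=log,
    )
    if outdir is not None:
        _emit(result, Path(outdir))
    return result


def _emit(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.copy_number.to_csv(outdir / "copy_number.tsv", sep="\t", index=False)
    result.snp_report.to_csv(outdir / "snp_heteroplasmies.tsv", sep="\t", index=False)
    result.indel_report.to_csv(outdir / "indel_heteroplasmies.tsv", sep="\t", index=False)
    write_fate_tsv(result.fate, outdir / "fate_matrix.tsv")
    all_pairs = [pair for pairs in result.calls.values() for pair in pairs]
    fate_sites = set(result.fate.frequencies.index)
    write_vcf(
        [p for p in all_pairs if p[0].passed or p[0].position in fate_sites],
        result.genome,
        outdir / "calls.vcf",
    )
    for name, profile in result.profiles.items():
        write_pileup_tsv(profile.pileups, outdir / f"pileup_{name}.tsv")
    (outdir / "run_log.txt").write_text("\n".join(result.log) + "\n", encoding="utf-8")
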