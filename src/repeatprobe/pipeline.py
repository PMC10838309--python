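"""Orchestration of the three execution modes.

* ``run_discover`` — de novo repeat discovery, then probe design and
  selection for every discovered interval.
* ``run_design`` — probe design and selection for user-supplied target
  intervals (skips discovery).
* ``run_analyze`` — re-profiles an existing probe table under (possibly
  new) hybridization conditions, starting at the specificity step.

All modes share the same downstream code path, write their outputs into a
run directory with fixed filenames, and always emit a run manifest
(config echo + version + seed) for reproducibility.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .align import SeedIndex, align_probe
from .config import PipelineConfig
from .design import deduplicate, gc_percent, mine_candidates
from .discovery import discover_repeats
from .genome import BedInterval, GenomeAssembly
from .kmers import KmerCountTable, count_kmers, position_counts
from .rank import mer_cutoff_filter, normalized_rank, score_candidates
from .report import normalize_track, write_bedgraph
from .select import ProbeSet, SelectionCriteria, select_probes
from .specificity import make_windows, profile
from .thermo import ThermoModel, duplex_probability, melting_temperature

logger = logging.getLogger(__name__)

PROBE_COLUMNS = [
    "scaffold", "start", "end", "sequence", "tm", "gc_percent",
    "r_m", "h_m", "k_b", "nr", "on_t", "off_t", "binding_prop",
    "target_scaffold", "target_start", "target_end",
]


def thermo_model(config: PipelineConfig) -> ThermoModel:
    return ThermoModel(
        temperature_celsius=config.temperature,
        sodium_molar=config.sodium,
        magnesium_molar=config.magnesium,
    )


def criteria_from_config(config: PipelineConfig) -> SelectionCriteria:
    return SelectionCriteria(
        target_sum=config.target_sum,
        min_on_target=config.min_on_target,
        max_probe_return=config.max_probe_return,
        min_binding_prop=config.binding_prop,
        max_pdups_binding=config.max_pdups_binding,
        off_bin_thresh=config.off_bin_thresh,
    )


def design_for_interval(
    assembly: GenomeAssembly,
    table: KmerCountTable,
    interval: BedInterval,
    config: PipelineConfig,
    index: SeedIndex | None = None,
) -> ProbeSet:
    """Mine, rank, and select probes for one target interval."""
    candidates = mine_candidates(
        interval, assembly,
        min_length=config.min_length, max_length=config.max_length,
        min_temp=config.min_temp, max_temp=config.max_temp,
        min_gc=config.min_gc, max_gc=config.max_gc,
        sodium_molar=config.sodium, formamide_percent=config.formamide,
    )
    candidates = deduplicate(candidates)
    scored = score_candidates(candidates, table, interval, assembly)
    ranked = normalized_rank(scored, c1=config.c1_val, c2=config.c2_val)
    ranked = mer_cutoff_filter(ranked, config.mer_cutoff, config.k)
    bins = make_windows(assembly.lengths, config.genome_windows)
    return select_probes(
        ranked, assembly, interval,
        criteria_from_config(config), thermo_model(config), bins,
        seed_length=config.seed_length, max_alignments=config.max_alignments,
        index=index,
    )


def _probe_rows(interval: BedInterval, probe_set: ProbeSet) -> list[dict]:
    rows = []
    for ranked, prof in probe_set.accepted:
        cand = ranked.candidate
        rows.append(
            dict(
                scaffold=cand.scaffold, start=cand.start, end=cand.end,
                sequence=cand.sequence, tm=round(cand.tm, 4),
                gc_percent=round(cand.gc_percent, 4),
                r_m=ranked.r_m, h_m=ranked.h_m,
                k_b=round(ranked.k_b, 4), nr=round(ranked.nr, 4),
                on_t=round(prof.on_t, 4), off_t=round(prof.off_t, 4),
                binding_prop=round(prof.binding_prop, 4),
                target_scaffold=interval.scaffold,
                target_start=interval.start, target_end=interval.end,
            )
        )
    return rows


def _write_outputs(
    outdir: Path,
    assembly: GenomeAssembly,
    config: PipelineConfig,
    intervals: list[BedInterval],
    probe_sets: list[ProbeSet],
    mode: str,
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    probe_rows: list[dict] = []
    summary_rows: list[dict] = []
    log_rows: list[dict] = []
    for interval, probe_set in zip(intervals, probe_sets):
        probe_rows.extend(_probe_rows(interval, probe_set))
        summary_rows.append(
            dict(
                scaffold=interval.scaffold, start=interval.start,
                end=interval.end,
                probe_count=len(probe_set.accepted),
                aggregate_on_t=round(probe_set.aggregate_on_t, 4),
                aggregate_off_t=round(probe_set.aggregate_off_t, 4),
                termination_reason=probe_set.termination_reason,
            )
        )
        log_rows.extend(
            dict(target=f"{interval.scaffold}:{interval.start}-{interval.end}",
                 rank=i + 1, probe=pid, verdict=verdict)
            for i, (pid, verdict) in enumerate(probe_set.decisions)
        )
    probes_df = pd.DataFrame(probe_rows, columns=PROBE_COLUMNS)
    probes_df.to_csv(outdir / "probes.tsv", sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    pd.DataFrame(log_rows).to_csv(outdir / "probe_log.tsv", sep="\t", index=False)
    with open(outdir / "repeat_intervals.bed", "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{name}\n")

    # aggregate binding track over all accepted probes
    bins = make_windows(assembly.lengths, config.thresh_windows)
    raw = {b: 0.0 for b in bins}
    for probe_set in probe_sets:
        for _, prof in probe_set.accepted:
            for b, value in prof.bin_aggregates.items():
                if b in raw:
                    raw[b] += value
                else:  # genome_windows and thresh_windows may differ
                    mid = (b.start + b.end) // 2
                    for tb in bins:
                        if tb.scaffold == b.scaffold and tb.start <= mid < tb.end:
                            raw[tb] += value
                            break
    track = normalize_track(bins, [raw[b] for b in bins])
    write_bedgraph(track.bins, track.raw, outdir / "binding_track_raw.bedgraph")
    write_bedgraph(track.bins, track.normalized,
                   outdir / "binding_track_norm.bedgraph", integer=True)

    manifest = dict(mode=mode, version=__version__, seed=config.seed,
                    config=config.to_dict())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return dict(intervals=intervals, probe_sets=probe_sets,
                probes=probes_df, outdir=outdir)


def run_discover(
    assembly: GenomeAssembly, config: PipelineConfig, outdir: str | Path
) -> dict:
    """Repeat Discovery Mode: find repetitive intervals, then design probes."""
    table = count_kmers(assembly, config.k)
    intervals: list[BedInterval] = []
    for name, seq in assembly.scaffolds.items():
        counts = position_counts(table, seq)
        for rep in discover_repeats(
            counts, name, config.window, config.threshold, config.composition,
            config.k, file_start=config.file_start, scaffold_length=len(seq),
        ):
            intervals.append(rep.as_bed())
    index = SeedIndex(assembly, config.seed_length)
    probe_sets = [
        design_for_interval(assembly, table, iv, config, index=index)
        for iv in intervals
    ]
    return _write_outputs(Path(outdir), assembly, config, intervals, probe_sets,
                          mode="repeat_discovery")


def run_design(
    assembly: GenomeAssembly,
    targets: list[BedInterval],
    config: PipelineConfig,
    outdir: str | Path,
) -> dict:
    """Probe Design Mode: design probes for user-supplied intervals."""
    table = count_kmers(assembly, config.k)
    index = SeedIndex(assembly, config.seed_length)
    probe_sets = [
        design_for_interval(assembly, table, iv, config, index=index)
        for iv in targets
    ]
    return _write_outputs(Path(outdir), assembly, config, targets, probe_sets,
                          mode="probe_design")


def run_analyze(
    assembly: GenomeAssembly,
    probe_table: str | Path | pd.DataFrame,
    config: PipelineConfig,
    outdir: str | Path,
) -> dict:
    """Probe Analysis Mode: re-profile an existing probe table.

    The table must carry at least scaffold/start/end/sequence and the
    target_* columns written by the other modes.
    """
    if not isinstance(probe_table, pd.DataFrame):
        probe_table = pd.read_csv(probe_table, sep="\t")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = thermo_model(config)
    index = SeedIndex(assembly, config.seed_length)
    bins = make_windows(assembly.lengths, config.genome_windows)
    rows = []
    profiles = []
    for _, row in probe_table.iterrows():
        target = BedInterval(row["target_scaffold"], int(row["target_start"]),
                             int(row["target_end"]))
        hits = align_probe(
            row["sequence"], assembly, seed_length=config.seed_length,
            max_alignments=config.max_alignments, index=index,
        )
        scored = [
            (h, duplex_probability(h.probe_row, h.target_row, model))
            for h in hits
        ]
        probe_id = f"{row['scaffold']}:{row['start']}-{row['end']}"
        prof = profile(probe_id, scored, target, bins)
        profiles.append(prof)
        tm = melting_temperature(row["sequence"], sodium_molar=config.sodium,
                                 formamide_percent=config.formamide)
        rows.append(
            dict(
                scaffold=row["scaffold"], start=int(row["start"]),
                end=int(row["end"]), sequence=row["sequence"],
                tm=round(tm, 4), gc_percent=round(gc_percent(row["sequence"]), 4),
                on_t=round(prof.on_t, 4), off_t=round(prof.off_t, 4),
                binding_prop=(round(prof.binding_prop, 4)
                              if prof.valid else float("nan")),
                target_scaffold=target.scaffold, target_start=target.start,
                target_end=target.end,
            )
        )
    out_df = pd.DataFrame(rows)
    out_df.to_csv(outdir / "probe_profiles.tsv", sep="\t", index=False)
    manifest = dict(mode="probe_analysis", version=__version__,
                    seed=config.seed, config=config.to_dict())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return dict(profiles=profiles, table=out_df, outdir=outdir)
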