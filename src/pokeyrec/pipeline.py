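"""End-to-end orchestration: strip -> diversity -> phi -> max-chi2 ->
Rm/Rh -> fragment scan -> fragment trees -> parental assignment -> RFLP.

A run is driven by a single :class:`RunConfig` (real alignment or synthetic
scenario), is deterministic given its seed (per-stage seeds are derived by
stable hashing of the stage name), and writes machine-readable artifacts
(JSON report, TSV tables, newick trees, FASTA) to an output directory.
A stage failure is recorded and its dependents are skipped; only configuration
errors abort the run.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import diversity as div
from . import phylo, recomb_detect, rflp
from .core_io import (
    Alignment,
    InputError,
    PartitionMap,
    read_alignment,
    read_partition_map,
    strip_columns,
    write_alignment,
)
from .synthetic_data import SimConfig, default_mosaic_scenario

__all__ = ["RunConfig", "RunReport", "run_pipeline", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage sub-seed (stable, < 2^31) so stage reruns are reproducible."""
    return (seed ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class RunConfig:
    # inputs: either a real alignment...
    alignment_path: str | None = None
    partition_path: str | None = None
    group_map: Mapping[str, str] | None = None
    # ... or a simulation block
    simulate: SimConfig | None = None
    n_mosaics: int = 10
    # detection parameters
    half_widths: Sequence[int] = (70, 80, 90, 100)
    n_perm: int = 10_000
    alpha: float = 0.05
    phi_window: int = 100
    phi_n_perm: int = 1000
    # rflp
    run_rflp: bool = False
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.alignment_path is None) == (self.simulate is None):
            raise InputError("provide exactly one of alignment_path or simulate")


@dataclass
class RunReport:
    config: dict
    stages: dict[str, Any] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        return json.dumps(
            {
                "config": self.config,
                "stages": self.stages,
                "skipped": self.skipped,
                "warnings": self.warnings,
            },
            indent=2,
            default=default,
            sort_keys=True,
        )


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["half_widths"] = list(cfg.half_widths)
    if cfg.group_map is not None:
        d["group_map"] = dict(cfg.group_map)
    return d


def run_pipeline(cfg: RunConfig) -> RunReport:
    cfg.validate()
    report = RunReport(config=_config_echo(cfg))
    warn = report.warnings.append
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ---- load or simulate -------------------------------------------------
    truth = None
    groups = dict(cfg.group_map) if cfg.group_map else None
    if cfg.simulate is not None:
        aln, truth, groups = default_mosaic_scenario(
            seed=stage_seed(cfg.seed, "simulate"),
            cfg=cfg.simulate,
            n_mosaics=cfg.n_mosaics,
        )
        report.stages["simulate"] = {
            "n_sequences": aln.n,
            "L": aln.length,
            "n_mosaics": cfg.n_mosaics,
        }
        if out_dir:
            write_alignment(aln, out_dir / "simulated.fasta")
            truth.to_tsv(out_dir / "truth.tsv")
    else:
        aln = read_alignment(cfg.alignment_path)
        report.stages["load"] = {"n_sequences": aln.n, "L": aln.length}
    part = read_partition_map(cfg.partition_path) if cfg.partition_path else None

    stripped = strip_columns(aln)
    report.stages["strip"] = {
        "L_source": aln.length,
        "L_stripped": stripped.length,
        "columns_removed": aln.length - stripped.length,
    }

    # ---- diversity --------------------------------------------------------
    try:
        if part is not None:
            summaries = div.partition_diversity(aln, part, warn=warn)
        else:
            summaries = [div.summarize(aln)]
        report.stages["diversity"] = [dataclasses.asdict(s) for s in summaries]
        if out_dir:
            div.summaries_to_frame(summaries).to_csv(out_dir / "diversity.tsv", sep="\t")
    except Exception as e:  # noqa: BLE001 - stage isolation
        report.skipped["diversity"] = str(e)

    # ---- phi test ---------------------------------------------------------
    try:
        phi = recomb_detect.phi_test(
            stripped,
            window_w=cfg.phi_window,
            n_perm=cfg.phi_n_perm,
            seed=stage_seed(cfg.seed, "phi"),
        )
        report.stages["phi"] = dataclasses.asdict(phi)
    except Exception as e:  # noqa: BLE001
        report.skipped["phi"] = str(e)

    # ---- max-chi2 + events ------------------------------------------------
    events = []
    try:
        calls = recomb_detect.maxchi_scan(
            stripped,
            half_widths=cfg.half_widths,
            n_perm=cfg.n_perm,
            alpha=cfg.alpha,
            seed=stage_seed(cfg.seed, "maxchi"),
        )
        events = recomb_detect.merge_calls(calls, groups=groups)
        report.stages["maxchi"] = {
            "n_calls": len(calls),
            "calls": [dataclasses.asdict(c) for c in calls],
        }
        report.stages["events"] = [
            {
                "label": e.label,
                "interval": list(e.interval),
                "n_calls": len(e.member_calls),
                "groups_involved": e.groups_involved,
            }
            for e in events
        ]
        if out_dir:
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "pair": "|".join(c.seq_pair),
                        "left": c.interval[0],
                        "right": c.interval[1],
                        "chi2": c.chi2,
                        "p": c.p_value,
                        "h": c.half_width,
                        "step": c.step_index,
                    }
                    for c in calls
                ]
            ).to_csv(out_dir / "breakpoint_calls.tsv", sep="\t", index=False)
            with open(out_dir / "events.bed", "w") as fh:
                for e in events:
                    fh.write(f"alignment\t{e.interval[0] - 1}\t{e.interval[1]}\t{e.label}\n")
    except Exception as e:  # noqa: BLE001
        report.skipped["maxchi"] = str(e)

    # ---- Rm / Rh ----------------------------------------------------------
    try:
        rm = recomb_detect.hudson_kaplan_rm(stripped)
        rh = recomb_detect.haplotype_bound_rh(stripped)
        report.stages["rm"] = {
            "rm": rm.rm,
            "chosen_disjoint_set": rm.chosen_disjoint_set,
        }
        report.stages["rh"] = {"rh": rh.rh, "dp_trace": rh.dp_trace}
    except Exception as e:  # noqa: BLE001
        report.skipped["rm_rh"] = str(e)

    # ---- fragment scan + trees + parental assignment ----------------------
    try:
        breakpoints = recomb_detect.fragment_scan(stripped)
        report.stages["fragment_scan"] = {"breakpoints": breakpoints}
        trees = phylo.fragment_trees(stripped, breakpoints)
        report.stages["fragment_trees"] = {
            f"{span[0]}-{span[1]}": (phylo.tree_to_newick(t) if t else None)
            for span, t in trees
        }
        if out_dir:
            for span, t in trees:
                if t is not None:
                    (out_dir / f"tree_{span[0]}_{span[1]}.nwk").write_text(
                        phylo.tree_to_newick(t) + "\n"
                    )
        if groups:
            recombinants = [
                sid for sid, g in groups.items()
                if g == "recombinant" and sid in stripped.ids
            ]
            dms = []
            for span, t in trees:
                if t is None:
                    continue
                lo, hi = span
                idx = np.flatnonzero(
                    (stripped.column_map >= lo) & (stripped.column_map <= hi)
                )
                dms.append((span, phylo.pairwise_distances(stripped.take_columns(idx))))
            assignments = {}
            for rid in recombinants:
                try:
                    a = phylo.assign_parents(rid, dms, groups)
                    assignments[rid] = a.assignment
                except InputError as e:
                    warn(f"parental assignment failed for {rid}: {e}")
            report.stages["parental_assignment"] = assignments
    except Exception as e:  # noqa: BLE001
        report.skipped["fragments"] = str(e)

    # ---- RFLP -------------------------------------------------------------
    if cfg.run_rflp:
        try:
            codes = {}
            for r in aln.records:
                template = r.residues.replace("-", "")
                amps = rflp.in_silico_pcr(template)
                if not amps:
                    codes[r.id] = None
                    continue
                profile = rflp.digest(amps[0])
                codes[r.id] = rflp.haplotype_code(profile).code
            report.stages["rflp"] = codes
        except Exception as e:  # noqa: BLE001
            report.skipped["rflp"] = str(e)

    if out_dir:
        (out_dir / "report.json").write_text(report.to_json())
    return report
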