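"""End-to-end orchestration: score -> select -> [rescore] -> qc -> elect.

Each stage reads the previous stage's files and writes its own before the
next begins, so a run can be resumed from any intermediate product.  All
human decisions (CV rescues, expert elections) enter through files and are
echoed into the outputs.  Probe-deficient CDS are reported, never fatal.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import crosshyb, genome_io, qc, scoring
from .config import RunConfig

__all__ = ["run_pipeline", "stage_chi", "stage_score", "stage_select", "stage_qc", "stage_elect"]


def _load_inputs(config: RunConfig):
    genes = genome_io.read_gene_models(config.annotation, config.genome, config.est)
    probes = genome_io.read_probe_table(config.probes)
    missing = sorted({p.cds_id for p in probes} - set(genes))
    if missing:
        raise ValueError(f"probes reference unknown CDS: {missing}")
    return genes, probes


def stage_chi(config: RunConfig, genes, probes, outdir: Path) -> dict[str, float]:
    """Cross-hybridization identities, from external hits or internal search."""
    targets = {p.probe_id: p.cds_id for p in probes}
    if config.hits:
        hits = genome_io.read_alignment_hits(config.hits, targets)
        by_probe: dict[str, list] = {p.probe_id: [] for p in probes}
        for h in hits:
            by_probe.setdefault(h.probe_id, []).append(h)
    else:
        cds_set = {g.cds_id: g.spliced for g in genes.values()}
        by_probe = crosshyb.search_probes(
            probes,
            cds_set,
            word_size=config.word_size,
            match_reward=config.match_reward,
            mismatch_penalty=config.mismatch_penalty,
            min_window=config.min_window,
            min_window_identity=config.min_window_identity,
            xdrop=config.xdrop,
        )
    chi = {
        pid: crosshyb.chi_of_probe(pid, by_probe.get(pid, []))
        for pid in sorted(targets)
    }
    df = pd.DataFrame(
        {
            "probe_id": list(chi),
            "chi_percent": [c.chi_percent for c in chi.values()],
            "best_subject": [c.best_subject or "" for c in chi.values()],
        }
    )
    df.to_csv(outdir / "chi.tsv", sep="\t", index=False, float_format="%.4f")
    return {pid: c.chi_percent for pid, c in chi.items()}


def stage_score(config: RunConfig, genes, probes, chi: Mapping[str, float], outdir: Path):
    cards = scoring.score_probes(
        probes,
        genes,
        chi,
        adjacency_window=config.adjacency_window,
        chi_low=config.chi_band_low,
        chi_high=config.chi_band_high,
        dg_cutoff=config.delta_g_cutoff,
        pos_near=config.pos_near,
        pos_mid=config.pos_mid,
    )
    return cards


def stage_select(config: RunConfig, cards, outdir: Path):
    by_cds: dict[str, list] = {}
    for c in cards.values():
        by_cds.setdefault(c.cds_id, []).append(c)
    outcomes = {}
    for cds in sorted(by_cds):
        group = sorted(by_cds[cds], key=lambda c: c.probe_id)
        out = scoring.select_round1(
            group,
            score_cutoff=config.round1_score_cutoff,
            min_distance=config.round1_min_distance,
            panel_size=config.panel_size,
        )
        if len(out.round1_panel) < config.panel_size:
            out = scoring.select_round2(
                group,
                out,
                score_cutoff=config.round2_score_cutoff,
                chi_cutoff=config.round2_chi_cutoff,
                max_distance=config.round2_max_distance,
                panel_size=config.panel_size,
                min_panel=config.min_panel,
            )
        outcomes[cds] = out
    return outcomes


def write_scorecards(cards, outcomes, path) -> None:
    round_of: dict[str, str] = {}
    reason: dict[str, str] = {}
    for out in outcomes.values():
        for pid in out.round1_panel:
            round_of[pid] = "1"
        for pid in out.round2_additions:
            round_of[pid] = "2"
        for pid, why in out.exclusions.items():
            round_of.setdefault(pid, "")
            reason[pid] = why
    rows = []
    for pid in sorted(cards):
        c = cards[pid]
        rows.append(
            {
                "probe_id": c.probe_id,
                "cds_id": c.cds_id,
                "chi_percent": round(c.chi_percent, 4),
                "chi_score": c.chi_score,
                "delta_g": "inf" if math.isinf(c.delta_g) else round(c.delta_g, 4),
                "fold_score": c.fold_score,
                "distance_3p": c.distance_3p,
                "pos_score": c.pos_score,
                "intron_class": c.intron_class,
                "intron_score": c.intron_score,
                "match_score": c.match_score,
                "final_score": c.final_score,
                "round_admitted": round_of.get(pid, ""),
                "exclusion_reason": reason.get(pid, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def stage_qc(config: RunConfig, probes, outdir: Path):
    spots = qc.read_intensity_table(config.intensities)
    rescue = qc.read_rescue_list(config.rescue_list) if config.rescue_list else {}
    thresholds = qc.QCThresholds(
        ssr=config.ssr,
        sbr=config.sbr,
        cv=config.cv,
        ci_factor=config.ci_factor,
        ci_level=config.ci_level,
        ci_method=config.ci_method,
    )
    targets = {p.probe_id: p.cds_id for p in probes}
    present = set(spots["probe_id"].unique())
    targets = {pid: cds for pid, cds in targets.items() if pid in present}
    probe_stats, cds_stats = qc.evaluate_probes(spots, targets, thresholds, rescue)
    rows = []
    for pid in sorted(probe_stats):
        st = probe_stats[pid]
        rows.append(
            {
                "probe_id": pid,
                "cds_id": st.cds_id,
                "snr_fail_count": st.snr_fail_count,
                "n_samples": st.n_samples,
                "max_cv": round(max(st.cv_per_condition.values()), 4)
                if st.cv_per_condition
                else "",
                "m_probe": "" if math.isnan(st.m_probe) else round(st.m_probe, 4),
                "flags": ",".join(sorted(st.flags)),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "probe_stats.tsv", sep="\t", index=False)
    return probe_stats, cds_stats


def stage_elect(config: RunConfig, probes, cards, outcomes, probe_stats, outdir: Path):
    bypass = {p.probe_id for p in probes if p.bypass_experimental}
    overrides = {}
    if config.expert_overrides:
        odf = pd.read_csv(config.expert_overrides, sep="\t")
        overrides = dict(zip(odf["cds_id"], odf["probe_id"]))
    panel_probes = {pid for out in outcomes.values() for pid in out.panel}
    if config.qc_enabled and probe_stats is not None:
        stats = {pid: st for pid, st in probe_stats.items() if pid in panel_probes}
        # bypass probes may lack hybridization data entirely
        for pid in sorted((panel_probes & bypass) - set(stats)):
            stats[pid] = qc.ProbeStats(probe_id=pid, cds_id=cards[pid].cds_id)
    else:
        # computational screening only: every panel probe is treated as a
        # QC bypass and elected on its in silico standing
        stats = {
            pid: qc.ProbeStats(probe_id=pid, cds_id=cards[pid].cds_id)
            for pid in sorted(panel_probes)
        }
        bypass = set(stats)
    report = qc.finalize_selection(
        stats, cards, bypass=bypass, expert_overrides=overrides, all_cds=sorted(outcomes)
    )
    # CDS whose panel came out empty never reached the test array; mirror the
    # supervised-rescue step by electing their least-bad probe in silico.
    by_cds_all: dict[str, list[str]] = {}
    for p in probes:
        by_cds_all.setdefault(p.cds_id, []).append(p.probe_id)
    for cds in list(report.empty):
        members = sorted(by_cds_all.get(cds, []))
        if not members:
            continue
        pick = min(members, key=lambda pid: (cards[pid].final_score,
                                             cards[pid].distance_3p, pid))
        report.elected[cds] = pick
        report.source[cds] = "rescued"
        report.deficient.append(cds)
        report.empty.remove(cds)
    rows = []
    for cds in sorted(outcomes):
        rows.append(
            {
                "cds_id": cds,
                "elected_probe": report.elected.get(cds, ""),
                "source": report.source.get(cds, ""),
                "n_qualified": len(report.qualified.get(cds, [])),
                "panel": ",".join(outcomes[cds].panel),
                "insilico_deficient": outcomes[cds].deficient,
                "qc_deficient": cds in report.deficient,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "election.tsv", sep="\t", index=False)
    return report


def summarize(report, probe_stats, outdir: Path) -> dict:
    """Per-filter rejected/qualified bookkeeping, one row per metric."""
    total = len(probe_stats)
    counts = {}
    for flag in qc.FAIL_FLAGS:
        rejected = sum(1 for st in probe_stats.values() if flag in st.flags)
        counts[flag] = {"rejected": rejected, "qualified": total - rejected}
    summary = {
        "n_probes": total,
        "per_filter": counts,
        "n_cds": len(report.elected) + len(report.empty),
        "cds_with_qualified_probe": sum(1 for q in report.qualified.values() if q),
        "probe_deficient_cds": len(report.deficient),
        "rescued_cds": sum(1 for s in report.source.values() if s in ("rescued", "expert")),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage in order; returns the run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, probes = _load_inputs(config)
    chi = stage_chi(config, genes, probes, outdir)
    cards = stage_score(config, genes, probes, chi, outdir)
    if config.new_cds:
        new_cds = genome_io.read_fasta(config.new_cds)
        cards, orphan_cds = scoring.rescore_after_reannotation(probes, cards, new_cds)
        (outdir / "reannotation_deficient.txt").write_text(
            "\n".join(orphan_cds) + ("\n" if orphan_cds else "")
        )
    outcomes = stage_select(config, cards, outdir)
    write_scorecards(cards, outcomes, outdir / "scorecards.tsv")
    probe_stats = None
    if config.qc_enabled and config.intensities:
        probe_stats, _ = stage_qc(config, probes, outdir)
    report = stage_elect(config, probes, cards, outcomes, probe_stats, outdir)
    summary = summarize(report, probe_stats or {}, outdir)
    config.write_manifest(outdir / "manifest.json", extra={"summary": summary})
    return summary
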