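"""Deterministic synthetic genomes, probes and hybridization data.

The generator emulates the study design the package is built for: an
annotated draft genome (about half the genes carry predicted introns, most
without EST support), four candidate 60-mer probes per CDS placed toward
the CDS 3' end, and a two-channel test-array experiment with several
conditions, four biological replicates each, hybridized against a common
reference RNA pool, with replicate spots per probe.

Defects are planted *by construction* and recorded in ground-truth tables:

* ``HIGH_CHI``    - a 40-nt window of the probe region is a 90%-identity
                    copy of another CDS (mismatches placed to keep an exact
                    7-mer run, so a word-seeded search can find it);
* ``HAIRPIN``     - an inverted repeat (15-bp GC-rich stem, 4-nt loop) is
                    embedded in the probe region;
* ``FAR_5P``      - the probe is placed > 1000 nt from the CDS 3' end;
* ``INTRON_OVERLAP`` - the probe is taken from the unspliced coding strand
                    and runs 30 nt into an intron (a probe designed on a
                    mispredicted single-exon model);
* ``LOW_SNR``     - the whole gene is unexpressed: every probe sees
                    background-level signal in all hybridizations;
* ``HIGH_CV``     - one biological replicate in two conditions is burst by
                    a constant factor, inflating that probe's CV;
* ``INTENSITY_OUTLIER`` - the probe's binding efficiency is a constant
                    multiple of its CDS siblings' on every array.

Intensities are multiplicative log-normal: biological replicate noise is
shared by all probes of a CDS on an array (it is the same mRNA), probe
efficiency is constant across arrays, and spot-level technical noise is
independent.  With the defaults, clean probes show per-condition CVs
around 0.12 and every planted defect is separable by exactly its intended
filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    ProbeRecord,
    build_gene_model,
    write_est_confirmations,
    write_fasta,
    write_gene_models,
    write_probe_table,
)

__all__ = ["FixtureSpec", "GenomeFixture", "Fixture", "simulate_genome",
           "simulate_probes", "simulate_intensities", "make_fixture"]

DEFECTS = (
    "HIGH_CHI", "HAIRPIN", "FAR_5P", "INTRON_OVERLAP",
    "LOW_SNR", "HIGH_CV", "INTENSITY_OUTLIER",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study; the seed fully determines output."""

    seed: int
    n_genes: int = 200
    genes_per_contig: int = 10
    intron_rate: float = 0.5          # fraction of genes with introns
    est_confirm_rate: float = 0.3     # fraction of introns with EST support
    probes_per_gene: int = 4
    n_conditions: int = 5
    n_bio_replicates: int = 4
    n_tech_replicates: int = 4
    # defect counts (genes per defect type; at most one defect per gene)
    n_per_defect: int = 8
    # intensity model
    latent_median: float = 3000.0
    latent_sigma: float = 0.6
    condition_sigma: float = 0.3
    sigma_bio: float = 0.12           # shared per (CDS, array)
    sigma_probe: float = 0.10         # constant per probe
    sigma_spot: float = 0.05          # independent per spot
    sigma_bg: float = 0.03
    bg_mean: float = 100.0
    bg_sd_mean: float = 10.0
    low_expression: float = 30.0      # latent level of LOW_SNR genes
    cv_burst_factor: float = 8.0
    outlier_factor: float = 20.0

    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:04d}" for i in range(self.n_genes)]


# regular probe slots: distance of the probe 5' base from the CDS 3' end
_SLOT_DISTANCES = (160, 260, 360, 460)
_FAR_DISTANCE = 1100
_MIN_CDS = 1300
_MAX_CDS = 2400


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class GenomeFixture:
    spec: FixtureSpec
    contigs: dict[str, str]
    models: dict[str, GeneModel]
    defect_of_gene: dict[str, str]            # cds_id -> defect type or ""
    defect_slot: dict[str, int]               # cds_id -> planted probe slot
    probe_positions: dict[str, list[int]]     # cds_id -> cds_start per slot
    intron_probe: dict[str, tuple[int, str]]  # cds_id -> (cds_start, sequence)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "genome.fasta")
        write_gene_models(self.models, outdir / "genes.gff3")
        write_est_confirmations(self.models, outdir / "est_confirmations.tsv")
        rows = [
            {
                "cds_id": g.cds_id,
                "contig_id": g.contig_id,
                "strand": g.strand,
                "cds_length": g.cds_length,
                "n_introns": len(g.introns),
                "defect": self.defect_of_gene.get(g.cds_id, ""),
            }
            for g in self.models.values()
        ]
        pd.DataFrame(rows).to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)


def _make_defect_plan(spec: FixtureSpec, rng: np.random.Generator) -> dict[str, list[int]]:
    """Assign defect types to disjoint gene indices."""
    order = rng.permutation(spec.n_genes)
    plan: dict[str, list[int]] = {}
    pos = 0
    for defect in DEFECTS:
        if defect == "INTRON_OVERLAP" and spec.intron_rate == 0:
            plan[defect] = []
            continue
        take = min(spec.n_per_defect, max(0, spec.n_genes - pos))
        plan[defect] = sorted(int(i) for i in order[pos : pos + take])
        pos += take
    return plan


def simulate_genome(spec: FixtureSpec) -> GenomeFixture:
    """Generate contigs, gene models and planted sequence-level defects."""
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(3)[0])
    n = spec.n_genes
    plan = _make_defect_plan(spec, rng)
    defect_of_idx = {i: d for d, idxs in plan.items() for i in idxs}
    gene_ids = spec.gene_ids()

    # pass 1: CDS lengths, intron structure, probe slots
    cds_len = rng.integers(_MIN_CDS, _MAX_CDS + 1, size=n)
    has_intron = rng.random(n) < spec.intron_rate
    for i in plan.get("INTRON_OVERLAP", []):
        has_intron[i] = True
    n_introns = np.where(has_intron, rng.integers(1, 4, size=n), 0)

    spliced = [_rand_seq(rng, int(L)) for L in cds_len]
    positions: dict[str, list[int]] = {}
    defect_slot: dict[str, int] = {}
    for i, gid in enumerate(gene_ids):
        L = int(cds_len[i])
        dists = list(_SLOT_DISTANCES)
        slot = int(rng.integers(0, spec.probes_per_gene))
        defect = defect_of_idx.get(i, "")
        if defect == "FAR_5P":
            dists[slot] = _FAR_DISTANCE
        defect_slot[gid] = slot
        positions[gid] = [L - d + 1 for d in dists[: spec.probes_per_gene]]

    # pass 2: sequence-level plants inside the chosen probe region
    for i in plan.get("HAIRPIN", []):
        gid = gene_ids[i]
        start = positions[gid][defect_slot[gid]] - 1  # 0-based probe start
        stem = "".join(rng.choice(list("GC"), size=12)) + "".join(rng.choice(list("AT"), size=3))
        insert = stem + "AAAA" + _revcomp(stem)
        s = spliced[i]
        off = start + 13  # center the 34-nt insert in the 60-nt probe
        spliced[i] = s[:off] + insert + s[off + len(insert):]
    for i in plan.get("HIGH_CHI", []):
        gid = gene_ids[i]
        donor = (i - 1) % spec.n_genes
        if donor == i or defect_of_idx.get(donor):
            donor = (i + 1) % spec.n_genes
        window = spliced[donor][500:540]
        mutated = list(window)
        for off in (3, 12, 21, 30):  # 90% identity, keeps an exact 8-mer run
            old = mutated[off]
            mutated[off] = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
        start = positions[gid][defect_slot[gid]] - 1
        s = spliced[i]
        off = start + 10
        spliced[i] = s[:off] + "".join(mutated) + s[off + 40:]

    # pass 3: exon/intron structure; junctions kept > 600 nt from the 3' end
    contigs: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    intron_probe: dict[str, tuple[int, str]] = {}
    defect_of_gene = {gene_ids[i]: d for i, d in defect_of_idx.items()}
    contig_parts: list[str] = []
    contig_genes: list[tuple] = []
    contig_idx = 0

    def flush_contig():
        nonlocal contig_parts, contig_genes, contig_idx
        if not contig_genes:
            return
        contig_idx += 1
        cid = f"contig{contig_idx:03d}"
        seq = "".join(contig_parts)
        contigs[cid] = seq
        for gid, strand, offset, exons_local, U, est_idx in contig_genes:
            if strand == "+":
                exons_contig = [(offset + s, offset + e) for s, e in exons_local]
            else:
                exons_contig = [
                    (offset + U - e + 1, offset + U - s + 1) for s, e in reversed(exons_local)
                ]
            models[gid] = build_gene_model(gid, cid, strand, seq, exons_contig, est_idx)
        contig_parts = []
        contig_genes = []

    for i, gid in enumerate(gene_ids):
        L = int(cds_len[i])
        k = int(n_introns[i])
        s = spliced[i]
        # junction positions within [100, L-600], spaced >= 80 nt
        junctions: list[int] = []
        lo = 100
        for _ in range(k):
            hi = L - 600 - 80 * (k - len(junctions) - 1)
            if hi <= lo:
                break
            j = int(rng.integers(lo, hi))
            junctions.append(j)
            lo = j + 80
        k = len(junctions)
        intron_seqs = [_rand_seq(rng, int(rng.integers(60, 201))) for _ in range(k)]
        est_flags = [bool(rng.random() < spec.est_confirm_rate) for _ in range(k)]

        defect = defect_of_gene.get(gid, "")
        if defect == "INTRON_OVERLAP" and k:
            # overlapped intron: alternate EST support so round 2 is exercised
            est_flags[0] = i % 2 == 0
            cx = junctions[0]  # CDS coordinate of the last exon base before intron 1
            seq = s[cx - 30 : cx] + intron_seqs[0][:30]
            intron_probe[gid] = (cx - 29, seq)

        # assemble unspliced gene in coding orientation and local exon coords
        exons_local: list[tuple[int, int]] = []
        parts: list[str] = []
        pos = 0       # local unspliced coordinate
        prev = 0      # CDS coordinate consumed
        for j, iseq in zip(junctions, intron_seqs):
            exons_local.append((pos + 1, pos + (j - prev)))
            parts.append(s[prev:j])
            pos += (j - prev) + len(iseq)
            parts.append(iseq)
            prev = j
        exons_local.append((pos + 1, pos + (L - prev)))
        parts.append(s[prev:])
        unspliced = "".join(parts)
        U = len(unspliced)

        strand = "+" if i % 2 == 0 else "-"
        spacer = _rand_seq(rng, 200)
        offset = sum(len(p) for p in contig_parts) + len(spacer)
        contig_parts.append(spacer)
        contig_parts.append(unspliced if strand == "+" else _revcomp(unspliced))
        est_idx = {j + 1 for j, f in enumerate(est_flags) if f}
        contig_genes.append((gid, strand, offset, exons_local, U, est_idx))
        if len(contig_genes) == spec.genes_per_contig:
            flush_contig()
    flush_contig()

    for gid, model in models.items():  # construction self-check
        i = gene_ids.index(gid)
        assert model.spliced == spliced[i], f"{gid}: spliced sequence mismatch"

    return GenomeFixture(
        spec=spec,
        contigs=contigs,
        models=models,
        defect_of_gene=defect_of_gene,
        defect_slot=defect_slot,
        probe_positions=positions,
        intron_probe=intron_probe,
    )


def simulate_probes(genome: GenomeFixture) -> tuple[list[ProbeRecord], pd.DataFrame]:
    """Extract candidate probes and their ground truth from a genome fixture."""
    spec = genome.spec
    probes: list[ProbeRecord] = []
    rows = []
    for gid, model in genome.models.items():
        defect = genome.defect_of_gene.get(gid, "")
        slot = genome.defect_slot[gid]
        for p_idx, cds_start in enumerate(genome.probe_positions[gid]):
            pid = f"{gid}_p{p_idx + 1}"
            planted = defect if (p_idx == slot and defect not in ("", "LOW_SNR")) else ""
            if defect == "LOW_SNR":
                planted = "LOW_SNR"
            if defect == "INTRON_OVERLAP" and p_idx == slot and gid in genome.intron_probe:
                cds_start, seq = genome.intron_probe[gid]
            else:
                seq = model.spliced[cds_start - 1 : cds_start + 59]
            probes.append(ProbeRecord(probe_id=pid, cds_id=gid, cds_start=cds_start, sequence=seq))
            rows.append(
                {
                    "probe_id": pid,
                    "cds_id": gid,
                    "cds_start": cds_start,
                    "distance_3p": model.cds_length - cds_start + 1,
                    "defect": planted,
                }
            )
    return probes, pd.DataFrame(rows)


def simulate_intensities(
    genome: GenomeFixture, probe_truth: pd.DataFrame
) -> pd.DataFrame:
    """Spot-level two-channel intensities with planted QC defects."""
    spec = genome.spec
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(3)[1])
    conditions = [f"cond{c + 1}" for c in range(spec.n_conditions)]
    arrays = [(c, r) for c in conditions for r in range(spec.n_bio_replicates)]

    gene_ids = list(genome.models)
    latent = {
        gid: float(v)
        for gid, v in zip(
            gene_ids,
            np.exp(np.log(spec.latent_median) + spec.latent_sigma * rng.standard_normal(len(gene_ids))),
        )
    }
    cond_factor = {
        (gid, c): float(np.exp(spec.condition_sigma * rng.standard_normal()))
        for gid in gene_ids
        for c in conditions
    }
    bio = {
        (gid, c, r): float(np.exp(spec.sigma_bio * rng.standard_normal()))
        for gid in gene_ids
        for c, r in arrays
    }
    probe_ids = probe_truth["probe_id"].tolist()
    eff = {
        pid: float(np.exp(spec.sigma_probe * rng.standard_normal()))
        for pid in probe_ids
    }
    defect_by_probe = dict(zip(probe_truth["probe_id"], probe_truth["defect"]))
    cds_by_probe = dict(zip(probe_truth["probe_id"], probe_truth["cds_id"]))
    for pid, d in defect_by_probe.items():
        if d == "INTENSITY_OUTLIER":
            eff[pid] *= spec.outlier_factor
    burst_conditions = conditions[:2]

    rows = []
    for c, r in arrays:
        array_id = f"{c}_r{r + 1}"
        for pid in probe_ids:
            gid = cds_by_probe[pid]
            defect = defect_by_probe[pid]
            if defect == "LOW_SNR":
                lat_s = lat_ref = spec.low_expression
            else:
                lat_s = latent[gid] * cond_factor[(gid, c)] * bio[(gid, c, r)]
                lat_ref = latent[gid]
            if defect == "HIGH_CV" and c in burst_conditions and r == 0:
                lat_s *= spec.cv_burst_factor
            for channel, lat in (("sample", lat_s), ("reference", lat_ref)):
                k = spec.n_tech_replicates
                eps = np.exp(spec.sigma_spot * rng.standard_normal(k))
                bg = spec.bg_mean * np.exp(spec.sigma_bg * rng.standard_normal(k))
                bg_sd = spec.bg_sd_mean * np.exp(spec.sigma_bg * rng.standard_normal(k))
                value = lat * eff[pid] * eps
                for t in range(k):
                    rows.append(
                        (array_id, c, channel, pid, t + 1,
                         value[t] + bg[t], bg[t], bg_sd[t])
                    )
    return pd.DataFrame(
        rows,
        columns=["array_id", "condition", "channel", "probe_id", "spot_index", "fg", "bg", "bg_sd"],
    )


@dataclass
class Fixture:
    genome: GenomeFixture
    probes: list[ProbeRecord]
    probe_truth: pd.DataFrame
    intensities: pd.DataFrame

    def planted(self, defect: str) -> set[str]:
        t = self.probe_truth
        return set(t.loc[t["defect"] == defect, "probe_id"])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.write(outdir)
        write_probe_table(self.probes, outdir / "probes.tsv")
        self.probe_truth.to_csv(outdir / "probe_truth.tsv", sep="\t", index=False)
        self.intensities.to_csv(
            outdir / "intensities.tsv", sep="\t", index=False, float_format="%.4f"
        )


def make_fixture(spec: FixtureSpec) -> Fixture:
    genome = simulate_genome(spec)
    probes, truth = simulate_probes(genome)
    intensities = simulate_intensities(genome, truth)
    return Fixture(genome=genome, probes=probes, probe_truth=truth, intensities=intensities)
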