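"""In silico probe scoring and multi-round selection.

Five criteria are scored per probe and summed into a final score:

* cross-hybridization identity (CHI): 0 (<= 60%), 1 (60-85%), 4 (>= 85%);
* self-folding hairpin stability: 0 (dG > -8 kcal/mol), 1 (dG <= -8);
* position in the CDS, counted from the 3' end: 0 (<= 500 nt),
  1 (501-1000 nt), 4 (> 1000 nt);
* position relative to predicted introns: class 1 (exonic, score 0),
  class 2 (starting just downstream of an intron 3' end, score 1),
  class 3 (overlapping an intron, score 4);
* sequence match after genome re-annotation: 0 (perfect match in the
  updated CDS) or 20 (mismatch; guarantees rejection).

Selection proceeds in two rounds per CDS: round 1 admits probes with a
final score below 4 that do not start within the last 100 nt of the CDS
and keeps the four closest to the 3' end; round 2 tops up short panels
with probes scoring up to 8 (recovering probes that overlap EST-confirmed
introns), excluding CHI > 85% and starts farther than 1500 nt from the
3' end.  A CDS left with fewer than two probes is flagged probe-deficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .genome_io import GeneModel, ProbeRecord, distance_from_3prime, map_probe

__all__ = [
    "ScoreCard",
    "SelectionOutcome",
    "NN_STACK_DG37",
    "HAIRPIN_LOOP_DG37",
    "hairpin_structure_energy",
    "hairpin_delta_g",
    "score_chi",
    "score_fold",
    "score_position",
    "classify_intron_relation",
    "intron_class_score",
    "total_score",
    "score_probe",
    "score_probes",
    "select_round1",
    "select_round2",
    "rescore_after_reannotation",
]

# ---------------------------------------------------------------------------
# DNA nearest-neighbor thermodynamics (unified parameters, 37 C, kcal/mol).
# Keys are the 5'->3' top-strand dinucleotide of a stack of two Watson-Crick
# pairs; the antiparallel bottom strand is implied.

NN_STACK_DG37: dict[str, float] = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}

# Hairpin loop initiation penalties by loop length (nt), 37 C, kcal/mol.
HAIRPIN_LOOP_DG37: dict[int, float] = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.1, 8: 4.1, 9: 4.2, 10: 4.3,
    12: 4.5, 14: 4.6, 16: 4.8, 18: 4.9, 20: 5.0, 25: 5.2, 30: 5.3,
}

_RT37 = 0.0019872 * 310.15  # kcal/mol
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

MIN_STEM = 3
MIN_LOOP = 3


def hairpin_loop_penalty(n: int) -> float:
    """Loop initiation free energy for a hairpin loop of ``n`` nt."""
    if n < MIN_LOOP:
        raise ValueError(f"hairpin loop must be >= {MIN_LOOP} nt, got {n}")
    if n in HAIRPIN_LOOP_DG37:
        return HAIRPIN_LOOP_DG37[n]
    sizes = sorted(HAIRPIN_LOOP_DG37)
    if n > sizes[-1]:
        # Jacobson-Stockmayer extrapolation beyond the table
        return HAIRPIN_LOOP_DG37[sizes[-1]] + 1.75 * _RT37 * math.log(n / sizes[-1])
    lo = max(s for s in sizes if s < n)
    hi = min(s for s in sizes if s > n)
    f = (n - lo) / (hi - lo)
    return HAIRPIN_LOOP_DG37[lo] + f * (HAIRPIN_LOOP_DG37[hi] - HAIRPIN_LOOP_DG37[lo])


def hairpin_structure_energy(seq: str, a: int, b: int, stem: int) -> float:
    """Free energy of the hairpin with outer pair (a, b) and given stem length.

    Pairs are ``(a+t, b-t)`` for ``t = 0..stem-1`` (0-based positions); the
    caller guarantees Watson-Crick complementarity.  Energy is the sum of
    nearest-neighbor stack terms along the stem plus the loop penalty.
    """
    loop_len = (b - stem + 1) - (a + stem - 1) - 1
    dg = hairpin_loop_penalty(loop_len)
    for t in range(stem - 1):
        dg += NN_STACK_DG37[seq[a + t] + seq[a + t + 1]]
    return dg


def hairpin_delta_g(sequence: str) -> float:
    """Minimum free energy over all single hairpins of the sequence.

    Hairpins have a contiguous Watson-Crick stem of at least ``MIN_STEM``
    base pairs and a loop of at least ``MIN_LOOP`` nt; energies are
    nearest-neighbor stack sums plus a loop penalty at 37 C.  Returns
    ``math.inf`` when the sequence admits no hairpin.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    n = len(seq)
    if n < 2 * MIN_STEM + MIN_LOOP:
        if n < 8:
            raise ValueError(f"sequence too short for hairpin analysis ({n} nt)")
        return math.inf
    best = math.inf
    span = 2 * MIN_STEM + MIN_LOOP - 1  # minimal outer-pair separation
    for a in range(n - span):
        ca = _COMPLEMENT[seq[a]]
        for b in range(a + span, n):
            if seq[b] != ca:
                continue
            # grow the stem inward from the outer pair (a, b)
            stacks = 0.0
            t = 1
            while True:
                i, j = a + t, b - t
                if j - i - 1 < MIN_LOOP or seq[j] != _COMPLEMENT[seq[i]]:
                    break
                stacks += NN_STACK_DG37[seq[i - 1] + seq[i]]
                if t + 1 >= MIN_STEM:
                    dg = stacks + hairpin_loop_penalty(j - i - 1)
                    if dg < best:
                        best = dg
                t += 1
    return best


# ---------------------------------------------------------------------------
# Criterion scores

def score_chi(chi_percent: float, low: float = 60.0, high: float = 85.0) -> int:
    if not 0.0 <= chi_percent <= 100.0:
        raise ValueError(f"CHI percent out of range: {chi_percent}")
    if chi_percent <= low:
        return 0
    if chi_percent < high:
        return 1
    return 4


def score_fold(delta_g: float, cutoff: float = -8.0) -> int:
    return 1 if delta_g <= cutoff else 0


def score_position(distance_3p: int, near: int = 500, mid: int = 1000) -> int:
    if distance_3p < 1:
        raise ValueError(f"distance from 3' end must be >= 1, got {distance_3p}")
    if distance_3p <= near:
        return 0
    if distance_3p <= mid:
        return 1
    return 4


def classify_intron_relation(
    probe: ProbeRecord, gene: GeneModel, adjacency_window: int = 10
) -> int:
    """Intron class of a probe: 3 overlaps an intron, 2 starts just after one.

    Class 3: the probe's genomic footprint overlaps the interior
    ``(x, y)`` of some intron (exclusive of x and y).  Class 2: no overlap,
    but the 5'-most base lies within ``adjacency_window`` nt downstream of
    some intron's ``y`` (starting exactly at ``y`` counts).  Class 1
    otherwise.
    """
    _, footprint = map_probe(probe, gene)
    for intron in gene.introns:
        lo, hi = intron.x + 1, intron.y - 1
        for s, e in footprint:
            if s <= hi and e >= lo:
                return 3
    p5 = footprint[0][0]
    for intron in gene.introns:
        if intron.y <= p5 < intron.y + adjacency_window:
            return 2
    return 1


_INTRON_CLASS_SCORE = {1: 0, 2: 1, 3: 4}


def intron_class_score(intron_class: int) -> int:
    return _INTRON_CLASS_SCORE[intron_class]


@dataclass
class ScoreCard:
    """Per-probe criterion scores and their sum."""

    probe_id: str
    cds_id: str
    chi_percent: float = 0.0
    chi_score: int = 0
    delta_g: float = math.inf
    fold_score: int = 0
    distance_3p: int = 0
    pos_score: int = 0
    intron_class: int = 1
    intron_score: int = 0
    match_score: int = 0
    est_ok: bool = True  # class-3 probes: every overlapped intron EST-confirmed
    orphaned: bool = False

    @property
    def final_score(self) -> int:
        return (
            self.chi_score
            + self.fold_score
            + self.pos_score
            + self.intron_score
            + self.match_score
        )


def total_score(card: ScoreCard) -> int:
    return card.final_score


def _overlapped_introns(probe: ProbeRecord, gene: GeneModel):
    _, footprint = map_probe(probe, gene)
    out = []
    for intron in gene.introns:
        lo, hi = intron.x + 1, intron.y - 1
        if any(s <= hi and e >= lo for s, e in footprint):
            out.append(intron)
    return out


def score_probe(
    probe: ProbeRecord,
    gene: GeneModel,
    chi_percent: float,
    adjacency_window: int = 10,
    chi_low: float = 60.0,
    chi_high: float = 85.0,
    dg_cutoff: float = -8.0,
    pos_near: int = 500,
    pos_mid: int = 1000,
) -> ScoreCard:
    """Assemble the full scorecard for one probe."""
    d3 = distance_from_3prime(probe, gene)
    dg = hairpin_delta_g(probe.sequence)
    klass = classify_intron_relation(probe, gene, adjacency_window)
    est_ok = True
    if klass == 3:
        est_ok = all(i.est_confirmed for i in _overlapped_introns(probe, gene))
    return ScoreCard(
        probe_id=probe.probe_id,
        cds_id=probe.cds_id,
        chi_percent=chi_percent,
        chi_score=score_chi(chi_percent, chi_low, chi_high),
        delta_g=dg,
        fold_score=score_fold(dg, dg_cutoff),
        distance_3p=d3,
        pos_score=score_position(d3, pos_near, pos_mid),
        intron_class=klass,
        intron_score=intron_class_score(klass),
        est_ok=est_ok,
    )


def score_probes(
    probes: Sequence[ProbeRecord],
    genes: Mapping[str, GeneModel],
    chi: Mapping[str, float],
    adjacency_window: int = 10,
    **thresholds,
) -> dict[str, ScoreCard]:
    cards: dict[str, ScoreCard] = {}
    for p in probes:
        if p.cds_id not in genes:
            raise ValueError(f"{p.probe_id}: unknown target CDS {p.cds_id}")
        cards[p.probe_id] = score_probe(
            p, genes[p.cds_id], chi.get(p.probe_id, 0.0), adjacency_window, **thresholds
        )
    return cards


# ---------------------------------------------------------------------------
# Selection rounds

@dataclass
class SelectionOutcome:
    cds_id: str
    round1_panel: list[str] = field(default_factory=list)
    round2_additions: list[str] = field(default_factory=list)
    deficient: bool = False
    exclusions: dict[str, str] = field(default_factory=dict)

    @property
    def panel(self) -> list[str]:
        return self.round1_panel + self.round2_additions


def _panel_sort_key(card: ScoreCard):
    return (card.distance_3p, card.probe_id)


def select_round1(
    cards: Sequence[ScoreCard],
    score_cutoff: int = 4,
    min_distance: int = 100,
    panel_size: int = 4,
) -> SelectionOutcome:
    """First-round admission: final score below the cutoff, start more than
    ``min_distance`` nt from the 3' end, keep the ``panel_size`` probes
    closest to the 3' end (ties broken by probe_id)."""
    cds_ids = {c.cds_id for c in cards}
    if len(cds_ids) != 1:
        raise ValueError(f"select_round1 expects probes of one CDS, got {sorted(cds_ids)}")
    outcome = SelectionOutcome(cds_id=cds_ids.pop())
    admitted = []
    for c in cards:
        if c.final_score >= score_cutoff:
            outcome.exclusions[c.probe_id] = f"round1:final_score {c.final_score} >= {score_cutoff}"
        elif c.distance_3p <= min_distance:
            outcome.exclusions[c.probe_id] = (
                f"round1:starts within last {min_distance} nt (distance {c.distance_3p})"
            )
        else:
            admitted.append(c)
    admitted.sort(key=_panel_sort_key)
    for c in admitted[panel_size:]:
        outcome.exclusions[c.probe_id] = "round1:panel full (farther from 3' end)"
    outcome.round1_panel = [c.probe_id for c in admitted[:panel_size]]
    return outcome


def select_round2(
    cards: Sequence[ScoreCard],
    outcome: SelectionOutcome,
    score_cutoff: int = 8,
    chi_cutoff: float = 85.0,
    max_distance: int = 1500,
    panel_size: int = 4,
    min_panel: int = 2,
) -> SelectionOutcome:
    """Second-round top-up for CDS with short round-1 panels.

    Admits probes with final score up to ``score_cutoff``, CHI not above
    ``chi_cutoff`` and start within ``max_distance`` nt of the 3' end;
    intron-overlapping (class 3) probes are admissible only when every
    intron they overlap is EST-confirmed.  The panel is topped up to
    ``panel_size`` by ascending distance from the 3' end; the CDS is
    flagged deficient when fewer than ``min_panel`` probes remain.
    """
    if len(outcome.round1_panel) >= panel_size:
        raise ValueError(f"{outcome.cds_id}: round-1 panel already full")
    in_panel = set(outcome.round1_panel)
    candidates = []
    for c in cards:
        if c.probe_id in in_panel:
            continue
        if c.final_score > score_cutoff:
            outcome.exclusions[c.probe_id] = (
                f"round2:final_score {c.final_score} > {score_cutoff}"
            )
        elif c.chi_percent > chi_cutoff:
            outcome.exclusions[c.probe_id] = f"round2:CHI {c.chi_percent:g} > {chi_cutoff:g}"
        elif c.distance_3p > max_distance:
            outcome.exclusions[c.probe_id] = (
                f"round2:starts upstream of 3'-terminal {max_distance} nt "
                f"(distance {c.distance_3p})"
            )
        elif c.intron_class == 3 and not c.est_ok:
            outcome.exclusions[c.probe_id] = "round2:overlaps intron without EST confirmation"
        else:
            candidates.append(c)
    candidates.sort(key=_panel_sort_key)
    room = panel_size - len(outcome.round1_panel)
    for c in candidates[room:]:
        outcome.exclusions[c.probe_id] = "round2:panel full (farther from 3' end)"
    outcome.round2_additions = [c.probe_id for c in candidates[:room]]
    outcome.deficient = len(outcome.panel) < min_panel
    return outcome


def rescore_after_reannotation(
    probes: Sequence[ProbeRecord],
    cards: Mapping[str, ScoreCard],
    new_cds: Mapping[str, str],
) -> tuple[dict[str, ScoreCard], list[str]]:
    """Re-validate probes against an updated CDS set.

    A probe keeps ``match_score`` 0 only if its sequence occurs exactly in
    its target's updated CDS; otherwise it gets 20 (which guarantees a
    final score above every admission cutoff).  Probes whose target CDS
    vanished are marked orphaned (also scored 20).  Returns the updated
    scorecards and the list of probe-deficient CDS (CDS in the updated set
    with no surviving probe).
    """
    updated: dict[str, ScoreCard] = {}
    survivors: dict[str, int] = {cds: 0 for cds in new_cds}
    for p in probes:
        card = cards[p.probe_id]
        if p.cds_id not in new_cds:
            updated[p.probe_id] = replace(card, match_score=20, orphaned=True)
            continue
        if p.sequence in new_cds[p.cds_id]:
            updated[p.probe_id] = replace(card, match_score=0)
            survivors[p.cds_id] += 1
        else:
            updated[p.probe_id] = replace(card, match_score=20)
    deficient = sorted(cds for cds, n in survivors.items() if n == 0)
    return updated, deficient
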