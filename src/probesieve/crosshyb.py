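"""Cross-hybridization screening of probes against a CDS set.

The screen answers one question per probe: what is the highest percent
identity it shares with any *non-target* CDS (the cross-hybridization
identity, CHI)?  Hits are found with a word-seeded, ungapped seed-and-
extend search tuned to detect at least 70% identity over 20 contiguous
bases: exact ``word_size``-mers seed diagonals, each seeded diagonal is
extended with an X-drop rule under +match/-mismatch scoring, and extended
hits are kept only if they are at least ``min_window`` nt long and contain
a ``min_window``-nt sub-window of at least ``min_window_identity`` percent
identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlignmentHit",
    "ChiResult",
    "SubjectIndex",
    "seed_extend_search",
    "search_probes",
    "chi_of_probe",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_SENTINEL = 4
_PAD = 64  # sentinel run between subjects; longer than any probe


@dataclass(frozen=True)
class AlignmentHit:
    """An ungapped (or externally supplied, possibly gapped) probe-vs-CDS hit."""

    probe_id: str
    subject_cds_id: str
    percent_identity: float
    alignment_length: int
    is_target: bool
    q_start: int = 0  # 1-based on the probe; 0 when unknown (external hits)
    s_start: int = 0  # 1-based on the subject

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity out of range: {self.percent_identity}")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")


@dataclass(frozen=True)
class ChiResult:
    probe_id: str
    chi_percent: float
    best_subject: str | None = None


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        bad = sorted({chr(c) for c in arr[out == 255]})
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return out


class SubjectIndex:
    """Concatenated, word-indexed subject set for repeated probe queries."""

    def __init__(self, subjects: Mapping[str, str], word_size: int = 7):
        if word_size < 4:
            raise ValueError("word_size must be >= 4")
        self.word_size = word_size
        self.subject_ids = list(subjects)
        chunks: list[np.ndarray] = []
        offsets: list[int] = []
        pos = 0
        pad = np.full(_PAD, _SENTINEL, dtype=np.uint8)
        for name in self.subject_ids:
            offsets.append(pos)
            enc = _encode(subjects[name])
            chunks.append(enc)
            chunks.append(pad)
            pos += len(enc) + _PAD
        self.seq = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.uint8)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.lengths = np.array([len(subjects[n]) for n in self.subject_ids], dtype=np.int64)
        self._build_word_index()

    def _build_word_index(self) -> None:
        w = self.word_size
        n = len(self.seq)
        if n < w:
            self._sorted_codes = np.zeros(0, dtype=np.int64)
            self._order = np.zeros(0, dtype=np.int64)
            return
        s = self.seq.astype(np.int64)
        codes = np.zeros(n - w + 1, dtype=np.int64)
        valid = np.ones(n - w + 1, dtype=bool)
        for j in range(w):
            part = s[j : n - w + 1 + j]
            codes = codes * 4 + np.where(part < 4, part, 0)
            valid &= part < 4
        codes[~valid] = -1
        self._order = np.argsort(codes, kind="stable")
        self._sorted_codes = codes[self._order]

    def word_positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted_codes, code, side="left")
        hi = np.searchsorted(self._sorted_codes, code, side="right")
        return self._order[lo:hi]

    def subject_of(self, gpos: int) -> tuple[int, int]:
        """Return (subject index, 0-based position within subject)."""
        idx = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return idx, gpos - int(self.offsets[idx])


def _probe_word_codes(probe: np.ndarray, w: int) -> np.ndarray:
    n = len(probe)
    codes = np.zeros(n - w + 1, dtype=np.int64)
    p = probe.astype(np.int64)
    for j in range(w):
        codes = codes * 4 + p[j : n - w + 1 + j]
    return codes


def _xdrop_extend(score: np.ndarray, a: int, b: int, xdrop: int) -> tuple[int, int]:
    """Extend the seed run [a, b) left and right; return max-score extent."""
    best_l = a
    cur = 0
    best = 0
    for k in range(a - 1, -1, -1):
        cur += score[k]
        if cur > best:
            best, best_l = cur, k
        elif best - cur > xdrop:
            break
    best_r = b
    cur = 0
    best = 0
    for k in range(b, len(score)):
        cur += score[k]
        if cur > best:
            best, best_r = cur, k + 1
        elif best - cur > xdrop:
            break
    return best_l, best_r


def _match_runs(match: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, m in enumerate(match):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(match) - start >= min_len:
        runs.append((start, len(match)))
    return runs


def seed_extend_search(
    probe_seq: str,
    subjects: Mapping[str, str] | "SubjectIndex",
    probe_id: str = "query",
    target_cds: str | None = None,
    word_size: int = 7,
    match_reward: int = 2,
    mismatch_penalty: int = 3,
    min_window: int = 20,
    min_window_identity: float = 70.0,
    xdrop: int = 20,
) -> list[AlignmentHit]:
    """Find ungapped probe-vs-subject hits by word seeding and X-drop extension.

    Defaults implement the 70%-identity-over-20-contiguous-bases
    sensitivity target with 7-nt words and +2/-3 scoring.  Hits against
    ``target_cds`` are flagged ``is_target``.
    """
    index = subjects if isinstance(subjects, SubjectIndex) else SubjectIndex(subjects, word_size)
    if index.word_size != word_size:
        raise ValueError("index word size differs from requested word size")
    probe = _encode(probe_seq)
    n = len(probe)
    if n < word_size:
        raise ValueError(f"probe shorter than word size ({n} < {word_size})")
    if not index.subject_ids:
        return []
    big = index.seq
    N = len(big)

    # Seeded diagonals: diag = (global subject pos) - (probe pos).
    codes = _probe_word_codes(probe, word_size)
    diags: set[int] = set()
    for qpos, code in enumerate(codes):
        for gpos in index.word_positions(int(code)):
            diags.add(int(gpos) - qpos)
    if not diags:
        return []
    diag_arr = np.array(sorted(diags), dtype=np.int64)

    # Match matrix: row per diagonal, column per probe position.
    gidx = diag_arr[:, None] + np.arange(n)[None, :]
    inb = (gidx >= 0) & (gidx < N)
    vals = np.where(inb, big[np.clip(gidx, 0, N - 1)], _SENTINEL)
    match = (vals == probe[None, :]) & (vals < 4)

    # Cheap pre-filter: a qualifying hit needs a min_window-nt window with
    # enough matches somewhere on the diagonal.
    need = int(np.ceil(min_window * min_window_identity / 100.0 - 1e-9))
    csum = np.cumsum(match, axis=1)
    if n >= min_window:
        win = csum[:, min_window - 1 :].copy()
        win[:, 1:] -= csum[:, :-min_window]
        cand = np.flatnonzero(win.max(axis=1) >= need)
    else:
        cand = np.zeros(0, dtype=np.int64)

    hits: dict[tuple, AlignmentHit] = {}

    def add_hit(row: int, lo: int, hi: int, nmatch: int) -> None:
        g0 = int(diag_arr[row]) + lo
        sidx, spos = index.subject_of(g0)
        key = (sidx, int(diag_arr[row]), lo, hi)
        if key in hits:
            return
        subject_id = index.subject_ids[sidx]
        hits[key] = AlignmentHit(
            probe_id=probe_id,
            subject_cds_id=subject_id,
            percent_identity=100.0 * nmatch / (hi - lo),
            alignment_length=hi - lo,
            is_target=(subject_id == target_cds),
            q_start=lo + 1,
            s_start=spos + 1,
        )

    for row in cand:
        m = match[row]
        score = np.where(m, match_reward, -mismatch_penalty).astype(np.int64)
        segments: list[tuple[int, int]] = []
        for a, b in _match_runs(m, word_size):
            lo, hi = _xdrop_extend(score, a, b, xdrop)
            length = hi - lo
            if length < min_window:
                continue
            seg = m[lo:hi]
            nmatch = int(seg.sum())
            # best min_window-nt sub-window identity
            c = np.concatenate([[0], np.cumsum(seg)])
            sub = c[min_window:] - c[: length - min_window + 1]
            if sub.max() < need:
                continue
            segments.append((lo, hi))
            add_hit(row, lo, hi, nmatch)
        # Fallback for clustered-match windows that score-trimming shrinks
        # below min_window: a qualifying window containing an exact word run
        # is a hit in its own right (the stated sensitivity floor).
        row_win = win[row]
        best_q, best_n = -1, 0
        for q0 in np.flatnonzero(row_win >= need):
            q0 = int(q0)
            if any(lo <= q0 and q0 + min_window <= hi for lo, hi in segments):
                continue
            wm = m[q0 : q0 + min_window]
            run = best = 0
            for x in wm:
                run = run + 1 if x else 0
                best = max(best, run)
            if best < word_size:
                continue
            nmatch = int(row_win[q0])
            if nmatch > best_n:
                best_q, best_n = q0, nmatch
        if best_q >= 0:
            add_hit(row, best_q, best_q + min_window, best_n)
    return sorted(
        hits.values(),
        key=lambda h: (-h.percent_identity, h.subject_cds_id, h.s_start, h.q_start),
    )


def search_probes(
    probes: Sequence,
    subjects: Mapping[str, str],
    **kwargs,
) -> dict[str, list[AlignmentHit]]:
    """Run the seed-and-extend search for a batch of ProbeRecords."""
    word_size = kwargs.get("word_size", 7)
    index = SubjectIndex(subjects, word_size)
    out: dict[str, list[AlignmentHit]] = {}
    for p in probes:
        out[p.probe_id] = seed_extend_search(
            p.sequence, index, probe_id=p.probe_id, target_cds=p.cds_id, **kwargs
        )
    return out


def chi_of_probe(probe_id: str, hits: Iterable[AlignmentHit]) -> ChiResult:
    """CHI = maximum percent identity over non-target hits (0 if none)."""
    best = 0.0
    best_subject: str | None = None
    for h in hits:
        if h.probe_id != probe_id:
            raise ValueError(f"hit for {h.probe_id} passed to chi_of_probe({probe_id})")
        if h.is_target:
            continue
        if h.percent_identity > best:
            best = h.percent_identity
            best_subject = h.subject_cds_id
    return ChiResult(probe_id=probe_id, chi_percent=best, best_subject=best_subject)
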