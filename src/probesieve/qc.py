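"""Experimental probe QC from two-channel hybridization intensities.

Spot-level foreground/background intensities are normalized, collapsed
over technical replicate spots, and rolled up into per-probe statistics,
to which three filters are applied:

1. signal-to-noise: a probe fails when SSR = (fg - bg) / bg_sd < 10 *and*
   SBR = fg / bg < 2 in all sample hybridizations, or in all but one;
2. reproducibility: a probe fails when the coefficient of variation of its
   normalized signal across the biological replicates of any condition
   exceeds 0.75, unless an expert rescue list retains it;
3. representative intensity: (i) a probe whose median reference-channel
   intensity (M_probe) falls strictly outside the interquartile range of
   its CDS siblings' medians is rejected; (ii) a probe whose sample-channel
   intensity lies outside the CDS mean +/- 1.5 x 95% CI on *every* array is
   rejected.

Flags are computed independently (no sequential elimination), then one
probe per CDS is elected: the qualified probe closest to the CDS 3' end,
or, for probe-deficient CDS, the least-bad rejected probe (fewest failed
filters, then lowest in silico score, then closest to the 3' end), flagged
as rescued.  Probes marked ``bypass_experimental`` (e.g. mitochondrial)
are elected on their in silico standing alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QCThresholds",
    "ProbeStats",
    "CdsStats",
    "SelectionReport",
    "read_intensity_table",
    "normalize",
    "compute_ssr_sbr",
    "collapse_technical_replicates",
    "compute_cv",
    "snr_filter",
    "cv_filter",
    "mprobe_filter",
    "marray_filter",
    "read_rescue_list",
    "evaluate_probes",
    "finalize_selection",
]

SPOT_COLUMNS = ["array_id", "condition", "channel", "probe_id", "spot_index", "fg", "bg", "bg_sd"]

SNR_FAIL = "SNR_FAIL"
CV_FAIL = "CV_FAIL"
MPROBE_FAIL = "MPROBE_FAIL"
MARRAY_FAIL = "MARRAY_FAIL"
RESCUED = "RESCUED"

FAIL_FLAGS = (SNR_FAIL, CV_FAIL, MPROBE_FAIL, MARRAY_FAIL)


@dataclass(frozen=True)
class QCThresholds:
    ssr: float = 10.0
    sbr: float = 2.0
    cv: float = 0.75
    ci_factor: float = 1.5
    ci_level: float = 0.95
    ci_method: str = "normal"  # or "t"


@dataclass
class ProbeStats:
    probe_id: str
    cds_id: str
    snr_fail_count: int = 0
    n_samples: int = 0
    cv_per_condition: dict[str, float] = field(default_factory=dict)
    m_probe: float = math.nan
    flags: set[str] = field(default_factory=set)


@dataclass
class CdsStats:
    cds_id: str
    m_cds: float = math.nan
    iqr_bounds: tuple[float, float] = (math.nan, math.nan)
    m_array_per_array: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class SelectionReport:
    elected: dict[str, str] = field(default_factory=dict)       # cds -> probe
    source: dict[str, str] = field(default_factory=dict)        # qualified|rescued|bypass|expert
    qualified: dict[str, list[str]] = field(default_factory=dict)
    deficient: list[str] = field(default_factory=list)
    empty: list[str] = field(default_factory=list)              # CDS with no probes at all
    verdicts: dict[str, set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Spot-level processing

def read_intensity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table missing columns {missing}")
    bad = set(df["channel"].unique()) - {"sample", "reference"}
    if bad:
        raise ValueError(f"unknown channel values {sorted(bad)}")
    if (df[["fg", "bg", "bg_sd"]] < 0).any().any():
        raise ValueError("negative intensities in spot table")
    return df


def normalize(spots: pd.DataFrame, min_spots: int = 10) -> pd.DataFrame:
    """Fill the ``norm`` column: background-subtract, log2, median-center.

    The stored value is on the linear scale (2**centered-log2), so that
    downstream CVs are scale-free linear-intensity CVs.
    """
    df = spots.copy()
    counts = df.groupby(["array_id", "channel"], sort=False)["fg"].transform("size")
    if (counts < min_spots).any():
        offender = df.loc[counts < min_spots, ["array_id", "channel"]].iloc[0]
        raise ValueError(
            f"array {offender.array_id!r} channel {offender.channel!r} has fewer than "
            f"{min_spots} spots; normalization would be degenerate"
        )
    sub = np.maximum(df["fg"] - df["bg"], 1.0)
    logv = np.log2(sub)
    center = logv.groupby([df["array_id"], df["channel"]], sort=False).transform("median")
    df["norm"] = 2.0 ** (logv - center)
    return df


def compute_ssr_sbr(fg: float, bg: float, bg_sd: float) -> tuple[float, float]:
    """Signal-to-standard-deviation and signal-to-background ratios of one spot."""
    if bg_sd > 0:
        ssr = (fg - bg) / bg_sd
    else:
        warnings.warn("bg_sd = 0: SSR undefined, reporting +inf", stacklevel=2)
        ssr = math.inf
    if bg > 0:
        sbr = fg / bg
    else:
        warnings.warn("bg = 0: SBR undefined, reporting +inf", stacklevel=2)
        sbr = math.inf
    return ssr, sbr


def _with_ratios(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ssr"] = np.where(df["bg_sd"] > 0, (df["fg"] - df["bg"]) / df["bg_sd"], np.inf)
        out["sbr"] = np.where(df["bg"] > 0, df["fg"] / df["bg"], np.inf)
    return out


def collapse_technical_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Median-collapse replicate spots of one probe on one array/channel."""
    value_cols = [c for c in ("norm", "ssr", "sbr") if c in df.columns]
    grouped = (
        df.groupby(["array_id", "condition", "channel", "probe_id"], sort=False)[value_cols]
        .median()
        .reset_index()
    )
    return grouped


# ---------------------------------------------------------------------------
# Filters

def compute_cv(values: Sequence[float]) -> float:
    """Coefficient of variation (sample sd / mean) of replicate intensities."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least 2 replicates")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("mean of normalized intensities must be positive")
    return float(arr.std(ddof=1) / mean)


def snr_filter(fail_count: int, n_samples: int) -> bool:
    """True (fail) when the probe fails both SNR thresholds in >= n-1 samples."""
    return fail_count >= n_samples - 1


def cv_filter(
    cv_per_condition: Mapping[str, float],
    probe_id: str,
    rescue: Mapping[str, str] | None = None,
    cv_threshold: float = 0.75,
) -> set[str]:
    """Return CV flags for one probe ({}, {CV_FAIL} or {RESCUED})."""
    high = any(cv > cv_threshold for cv in cv_per_condition.values())
    if not high:
        return set()
    if rescue and probe_id in rescue:
        return {RESCUED}
    return {CV_FAIL}


def mprobe_filter(m_probes: Mapping[str, float]) -> tuple[set[str], tuple[float, float]]:
    """Flag member probes whose M_probe is strictly outside the member IQR.

    Quartiles use linear interpolation between order statistics; the bounds
    themselves are inclusive.  Single-probe CDS are exempt.
    """
    if len(m_probes) < 2:
        return set(), (math.nan, math.nan)
    values = np.array(list(m_probes.values()), dtype=float)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    flagged = {pid for pid, v in m_probes.items() if v < q1 or v > q3}
    return flagged, (float(q1), float(q3))


def _ci_halfwidth(sd: float, n: int, level: float, method: str) -> float:
    if method == "normal":
        z = stats.norm.ppf(0.5 + level / 2.0)
    elif method == "t":
        z = stats.t.ppf(0.5 + level / 2.0, df=max(n - 1, 1))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return z * sd / math.sqrt(n)


def marray_filter(
    member_intensity: pd.DataFrame,
    ci_factor: float = 1.5,
    ci_level: float = 0.95,
    ci_method: str = "normal",
) -> tuple[set[str], dict[str, tuple[float, float]]]:
    """Flag members outside mean +/- ci_factor x CI on *every* array.

    ``member_intensity`` has columns (array_id, probe_id, norm) for the
    sample-channel intensities of one CDS's probes.  Being inside the band
    on a single array retains the probe.
    """
    probes = sorted(member_intensity["probe_id"].unique())
    if len(probes) < 2:
        return set(), {}
    per_array: dict[str, tuple[float, float]] = {}
    outside_everywhere = {p: True for p in probes}
    for array_id, grp in member_intensity.groupby("array_id", sort=True):
        vals = grp.set_index("probe_id")["norm"]
        n = len(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        half = _ci_halfwidth(sd, n, ci_level, ci_method)
        per_array[array_id] = (mean, half)
        lo, hi = mean - ci_factor * half, mean + ci_factor * half
        for p in probes:
            if p in vals.index and lo <= vals[p] <= hi:
                outside_everywhere[p] = False
    flagged = {p for p, out in outside_everywhere.items() if out}
    return flagged, per_array


def read_rescue_list(path) -> dict[str, str]:
    """Read an expert rescue list (TSV: probe_id, justification)."""
    rescue: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["probe_id", "justification"]:
            raise ValueError(f"bad rescue list header: {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[1].strip():
                raise ValueError(f"rescue list line {lineno}: justification required")
            rescue[fields[0]] = fields[1].strip()
    return rescue


# ---------------------------------------------------------------------------
# Roll-up

def evaluate_probes(
    spots: pd.DataFrame,
    probe_targets: Mapping[str, str],
    thresholds: QCThresholds = QCThresholds(),
    rescue: Mapping[str, str] | None = None,
) -> tuple[dict[str, ProbeStats], dict[str, CdsStats]]:
    """Run all three filters on a spot table; flags are computed independently."""
    df = normalize(_with_ratios(spots))
    collapsed = collapse_technical_replicates(df)

    sample = collapsed[collapsed["channel"] == "sample"]
    reference = collapsed[collapsed["channel"] == "reference"]

    stats_by_probe: dict[str, ProbeStats] = {
        pid: ProbeStats(probe_id=pid, cds_id=cds) for pid, cds in probe_targets.items()
    }

    # --- criterion 1: SNR over sample hybridizations
    n_samples = sample["array_id"].nunique()
    fail = sample[(sample["ssr"] < thresholds.ssr) & (sample["sbr"] < thresholds.sbr)]
    fail_counts = fail.groupby("probe_id")["array_id"].nunique()
    for pid, st in stats_by_probe.items():
        st.n_samples = n_samples
        st.snr_fail_count = int(fail_counts.get(pid, 0))
        if snr_filter(st.snr_fail_count, n_samples):
            st.flags.add(SNR_FAIL)

    # --- criterion 2: CV across biological replicates per condition
    for (pid, condition), grp in sample.groupby(["probe_id", "condition"], sort=False):
        if pid not in stats_by_probe or len(grp) < 2:
            continue
        stats_by_probe[pid].cv_per_condition[condition] = compute_cv(grp["norm"].to_numpy())
    for pid, st in stats_by_probe.items():
        st.flags |= cv_filter(st.cv_per_condition, pid, rescue, thresholds.cv)

    # --- criterion 3(i): M_probe vs CDS interquartile range (reference channel)
    m_probe = reference.groupby("probe_id")["norm"].median()
    for pid, st in stats_by_probe.items():
        if pid in m_probe.index:
            st.m_probe = float(m_probe[pid])

    cds_members: dict[str, list[str]] = {}
    for pid, cds in probe_targets.items():
        cds_members.setdefault(cds, []).append(pid)

    cds_stats: dict[str, CdsStats] = {}
    for cds, members in cds_members.items():
        cs = CdsStats(cds_id=cds)
        mp = {
            pid: stats_by_probe[pid].m_probe
            for pid in members
            if not math.isnan(stats_by_probe[pid].m_probe)
        }
        if mp:
            cs.m_cds = float(np.median(list(mp.values())))
        flagged, bounds = mprobe_filter(mp)
        cs.iqr_bounds = bounds
        for pid in flagged:
            stats_by_probe[pid].flags.add(MPROBE_FAIL)

        # --- criterion 3(ii): M_array +/- 1.5 CI on every array (sample channel)
        member_rows = sample[sample["probe_id"].isin(members)][
            ["array_id", "probe_id", "norm"]
        ]
        flagged_ma, per_array = marray_filter(
            member_rows, thresholds.ci_factor, thresholds.ci_level, thresholds.ci_method
        )
        cs.m_array_per_array = per_array
        for pid in flagged_ma:
            stats_by_probe[pid].flags.add(MARRAY_FAIL)
        cds_stats[cds] = cs

    return stats_by_probe, cds_stats


# ---------------------------------------------------------------------------
# Final per-CDS election

def finalize_selection(
    probe_stats: Mapping[str, ProbeStats],
    cards: Mapping[str, "ScoreCard"],
    bypass: Iterable[str] = (),
    expert_overrides: Mapping[str, str] | None = None,
    all_cds: Iterable[str] | None = None,
) -> SelectionReport:
    """Elect one probe per CDS from QC verdicts and in silico scorecards.

    Qualified probes carry no fail flag (a rescued high-CV probe counts as
    qualified).  For probe-deficient CDS the least-bad rejected probe is
    rescued: fewest failed filters, then lowest final score, then closest
    to the 3' end, then probe_id.  ``expert_overrides`` (cds_id -> probe_id)
    takes precedence for deficient CDS.  ``bypass`` probes skip QC entirely.
    """
    from .scoring import ScoreCard  # noqa: F401  (typing only)

    bypass = set(bypass)
    overrides = dict(expert_overrides or {})
    report = SelectionReport()

    by_cds: dict[str, list[str]] = {}
    for pid, st in probe_stats.items():
        by_cds.setdefault(st.cds_id, []).append(pid)
    for cds in all_cds or ():
        by_cds.setdefault(cds, [])

    for cds in sorted(by_cds):
        members = sorted(by_cds[cds])
        for pid in members:
            report.verdicts[pid] = set(probe_stats[pid].flags)
        if not members:
            report.empty.append(cds)
            continue

        bypass_members = [p for p in members if p in bypass]
        if bypass_members:
            pick = min(bypass_members, key=lambda p: (cards[p].distance_3p, p))
            report.elected[cds] = pick
            report.source[cds] = "bypass"
            report.qualified[cds] = bypass_members
            continue

        qualified = [
            p for p in members if not (probe_stats[p].flags & set(FAIL_FLAGS))
        ]
        report.qualified[cds] = qualified
        if qualified:
            pick = min(qualified, key=lambda p: (cards[p].distance_3p, p))
            report.elected[cds] = pick
            report.source[cds] = "qualified"
            continue

        report.deficient.append(cds)
        if cds in overrides:
            pick = overrides[cds]
            if pick not in members:
                raise ValueError(f"expert override {pick!r} is not a probe of {cds}")
            report.source[cds] = "expert"
        else:
            pick = min(
                members,
                key=lambda p: (
                    len(probe_stats[p].flags & set(FAIL_FLAGS)),
                    cards[p].final_score,
                    cards[p].distance_3p,
                    p,
                ),
            )
            report.source[cds] = "rescued"
        probe_stats[pick].flags.add(RESCUED)
        report.verdicts[pick].add(RESCUED)
        report.elected[cds] = pick

    return report
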