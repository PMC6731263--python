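"""Detection of chromosomal segments departing from the 1:1 allelic ratio.

Sites are binned by integer-percent allele frequency — balanced (40-60),
skewed (20-39 and 61-80) or extreme (outside both, reported but excluded
from either bin) — then counted in genome-anchored sliding windows
(default 10 kb with a 5 kb step).  Runs of windows dominated by skewed
sites merge into segments, the loss-of-heterozygosity-like signature of
a chromosome arm whose alleles sit at a 1:2 ratio on a diploid
background.

Windows with fewer sites than the minimum are *uninformative*: they
neither flag nor break a run (at realistic site densities of ~0.5/kb a
10-kb window holds Poisson-mean 5 sites, so nearly half of all windows
are below any useful minimum; letting them interrupt runs would shred
every real segment).  Only informative balanced-majority windows count
toward the gap allowance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

BALANCED = "balanced"
SKEWED = "skewed"
EXTREME = "extreme"


def classify_site_balance(f: float) -> str:
    """Bin a frequency by integer percent: balanced 40-60, skewed 20-39 | 61-80.

    The integer percent is round-half-down of 100*f (39.5 -> 39, so
    f=0.395 is skewed while f=0.405 is balanced), computed after rounding
    100*f to 6 decimals to suppress float representation fuzz.
    """
    if not (0.0 <= f <= 1.0):
        raise ParameterError(f"frequency {f} outside [0, 1]")
    p = round(f * 100.0, 6)
    r = math.ceil(p - 0.5)
    if 40 <= r <= 60:
        return BALANCED
    if 20 <= r <= 39 or 61 <= r <= 80:
        return SKEWED
    return EXTREME


@dataclass(frozen=True)
class Segment:
    """A contiguous interval classified as allelically skewed.

    ``start``/``end`` are 0-based half-open genome coordinates spanning
    the first to the last flagged window.
    """

    chrom: str
    start: int
    end: int
    n_windows: int
    n_sites: int
    mean_abs_dev: float

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.end <= self.start:
            raise ParameterError(f"{self.chrom}: segment end <= start")


def window_tracks(
    sites: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = 10_000,
    step: int = 5_000,
    mask: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    gc: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-window site counts by balance category, plus repeat and GC fractions.

    ``sites`` needs columns chrom, pos (1-based), f.  Windows are
    genome-anchored (first window starts at position 1), 0-based
    half-open internally, tiling every ``step``; the last partial window
    is included and its ``sites_per_kb`` is length-normalized.
    ``mask`` holds 0-based half-open repeat intervals; ``gc`` optional
    per-base boolean/0-1 arrays.
    """
    if window < step:
        raise ParameterError("window must be >= step")
    mask = mask or {}
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = sites[sites["chrom"] == chrom] if len(sites) else sites
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1 if len(sub) else np.empty(0, np.int64)
        cats = (
            np.array([classify_site_balance(x) for x in sub["f"]], dtype=object)
            if len(sub) else np.empty(0, object)
        )
        repeat_base = np.zeros(length, dtype=bool)
        for s, e in mask.get(chrom, ()):
            repeat_base[s:e] = True
        gc_base = np.asarray(gc[chrom], dtype=float) if gc and chrom in gc else None
        start = 0
        while start < length:
            end = min(start + window, length)
            inside = (pos0 >= start) & (pos0 < end)
            c = cats[inside]
            n_bal = int((c == BALANCED).sum())
            n_skew = int((c == SKEWED).sum())
            n_ext = int((c == EXTREME).sum())
            n = int(inside.sum())
            rows.append((
                chrom, start, end, n, n_bal, n_skew, n_ext,
                n / ((end - start) / 1000.0),
                float(repeat_base[start:end].mean()),
                float(gc_base[start:end].mean()) if gc_base is not None else math.nan,
            ))
            if end == length:
                break
            start += step
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_sites", "n_balanced", "n_skewed",
                 "n_extreme", "sites_per_kb", "repeat_frac", "gc_frac"],
    )


def _window_states(
    track: pd.DataFrame, min_skew_fraction: float, min_sites: int
) -> np.ndarray:
    """Per-window state: 'F' flagged, 'U' informative unflagged, 'N' uninformative."""
    states = np.empty(len(track), dtype="U1")
    for i, row in enumerate(track.itertuples(index=False)):
        informative = row.n_balanced + row.n_skewed
        if row.n_sites < min_sites or informative == 0:
            states[i] = "N"
        elif row.n_skewed / informative > min_skew_fraction:
            states[i] = "F"
        else:
            states[i] = "U"
    return states


def merge_flag_runs(states: np.ndarray, max_gap: int = 1) -> list[tuple[int, int]]:
    """Group flagged windows into runs allowing up to ``max_gap`` interior
    informative-unflagged windows; uninformative windows never break a run.

    Returns (first_flag_index, last_flag_index) pairs, inclusive.
    """
    runs: list[tuple[int, int]] = []
    current_start = None
    last_flag = None
    gap = 0
    for i, s in enumerate(states):
        if s == "F":
            if current_start is None:
                current_start = i
            last_flag = i
            gap = 0
        elif s == "U" and current_start is not None:
            gap += 1
            if gap > max_gap:
                runs.append((current_start, last_flag))
                current_start, last_flag, gap = None, None, 0
        # 'N' windows are transparent
    if current_start is not None:
        runs.append((current_start, last_flag))
    return runs


def detect_skewed_segments(
    track: pd.DataFrame,
    sites: pd.DataFrame | None = None,
    min_skew_fraction: float = 0.5,
    min_sites: int = 5,
    min_windows: int = 3,
    max_gap: int = 1,
) -> list[Segment]:
    """Merge runs of skew-dominated windows into segments.

    A window flags when its skewed-site fraction (among balanced+skewed)
    exceeds ``min_skew_fraction`` and it holds at least ``min_sites``
    sites.  Runs of >= ``min_windows`` flagged windows — tolerating
    ``max_gap`` interior informative gap windows — become segments
    spanning first-flagged-window start to last-flagged-window end.
    """
    segments: list[Segment] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        states = _window_states(sub, min_skew_fraction, min_sites)
        for i0, i1 in merge_flag_runs(states, max_gap):
            n_flagged = int((states[i0 : i1 + 1] == "F").sum())
            if n_flagged < min_windows:
                continue
            start = int(sub.loc[i0, "start"])
            end = int(sub.loc[i1, "end"])
            if sites is not None and len(sites):
                inseg = sites[
                    (sites["chrom"] == chrom)
                    & (sites["pos"] - 1 >= start)
                    & (sites["pos"] - 1 < end)
                ]
                cats = [classify_site_balance(x) for x in inseg["f"]]
                skew_f = inseg["f"].to_numpy()[np.array(cats, dtype=object) == SKEWED] \
                    if cats else np.empty(0)
                n_sites = len(skew_f)
                mean_dev = float(np.abs(skew_f - 0.5).mean()) if n_sites else math.nan
            else:
                n_sites = int(sub.loc[i0:i1, "n_skewed"].sum())
                mean_dev = math.nan
            segments.append(Segment(chrom, start, end, n_flagged, n_sites, mean_dev))
    return segments


def segments_to_bed(segments: Sequence[Segment], path) -> None:
    """Write segments as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\tskewed\t{seg.n_sites}\t.\n")
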