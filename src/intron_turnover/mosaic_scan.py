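"""Sliding-window donor-identity profiling for mosaic (chimeric) sequences.

Gene conversion pastes donor-derived tracts into a recipient sequence, so a
chimeric intron or HEG is *locally* near-identical to different donors in
different regions. The scanner slides a window along an alignment, computes
the fraction of identical columns between a query sequence and each
candidate donor (over columns where both are non-missing), and merges runs
of windows won by the same donor set into candidate donor segments.

Coordinates are 0-based half-open in alignment columns throughout; ties
between equally close donors are reported, never broken arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_io import Alignment, GAP_CODE, MISSING_CODE


@dataclass
class IdentityProfile:
    query: str
    donors: list[str]
    window: int
    step: int
    starts: np.ndarray                 # (n_windows,)
    identity: np.ndarray               # (n_windows, n_donors), NaN = unscored
    comparable: np.ndarray             # (n_windows, n_donors) column counts

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in range(self.n_windows):
            for d, donor in enumerate(self.donors):
                rows.append({
                    "start": int(self.starts[w]),
                    "end": int(self.starts[w]) + self.window,
                    "donor": donor,
                    "identity": self.identity[w, d],
                    "comparable_columns": int(self.comparable[w, d]),
                })
        return pd.DataFrame(rows)


@dataclass
class DonorSegment:
    start: int
    end: int
    top_donors: frozenset[str]
    mean_identity: float

    def as_row(self, query: str) -> dict:
        return {
            "query": query,
            "start": self.start,
            "end": self.end,
            "top_donors": ",".join(sorted(self.top_donors)),
            "mean_identity": self.mean_identity,
        }


def window_identity(
    aln: Alignment,
    query: str,
    donors: list[str],
    window: int = 50,
    step: int = 10,
    count_indels: bool = False,
) -> IdentityProfile:
    """Per-window identity of a query against each donor.

    Identity is matches / comparable columns within the window; a column is
    comparable when neither sequence is missing there. By default gaps are
    missing data; with ``count_indels`` a gap aligned to a base (or to a
    gap) is scored like any other character, matching analyses that count
    indels as differences.
    """
    if query in donors:
        raise ValueError("query must not be among the donors")
    labels = [query, *donors]
    for lab in labels:
        if lab not in aln.labels:
            raise ValueError(f"unknown sequence label {lab!r}")
    L = aln.n_columns
    if not (1 <= step <= window <= L):
        raise ValueError(
            f"require 1 <= step ({step}) <= window ({window}) <= "
            f"alignment length ({L})")

    codes = aln.codes()
    q = codes[aln.labels.index(query)]
    D = np.stack([codes[aln.labels.index(d)] for d in donors])

    if count_indels:
        q_ok = q != MISSING_CODE
        d_ok = D != MISSING_CODE
    else:
        q_ok = (q != MISSING_CODE) & (q != GAP_CODE)
        d_ok = (D != MISSING_CODE) & (D != GAP_CODE)
    comparable_cols = q_ok[None, :] & d_ok          # (n_donors, L)
    match_cols = comparable_cols & (D == q[None, :])

    starts = np.arange(0, L - window + 1, step)
    n_w, n_d = len(starts), len(donors)
    identity = np.full((n_w, n_d), np.nan)
    comparable = np.zeros((n_w, n_d), dtype=int)
    # cumulative sums make each window an O(1) slice
    ccum = np.concatenate(
        [np.zeros((n_d, 1), dtype=int), np.cumsum(comparable_cols, axis=1)], axis=1)
    mcum = np.concatenate(
        [np.zeros((n_d, 1), dtype=int), np.cumsum(match_cols, axis=1)], axis=1)
    for w, s in enumerate(starts):
        e = s + window
        n_cmp = ccum[:, e] - ccum[:, s]
        n_match = mcum[:, e] - mcum[:, s]
        comparable[w] = n_cmp
        with np.errstate(invalid="ignore"):
            identity[w] = np.where(n_cmp > 0, n_match / np.maximum(n_cmp, 1), np.nan)
    return IdentityProfile(
        query=query, donors=list(donors), window=window, step=step,
        starts=starts, identity=identity, comparable=comparable,
    )


def call_segments(
    profile: IdentityProfile, tie_epsilon: float = 0.0
) -> list[DonorSegment]:
    """Merge consecutive windows with identical top-donor sets into segments.

    The top set of a window is every donor within ``tie_epsilon`` of the
    window's maximum identity. Windows with no comparable columns for any
    donor are skipped (flagged in the profile, not scored). Overlapping
    windows from adjacent segments are resolved by clipping each segment's
    start to the previous segment's end, so segments never overlap.
    """
    segments: list[DonorSegment] = []
    cur_set: frozenset[str] | None = None
    cur_start = cur_end = 0
    cur_vals: list[float] = []

    def flush():
        if cur_set is not None:
            segments.append(DonorSegment(
                start=cur_start, end=cur_end, top_donors=cur_set,
                mean_identity=float(np.mean(cur_vals)),
            ))

    for w in range(profile.n_windows):
        row = profile.identity[w]
        if np.all(np.isnan(row)):
            continue
        best = np.nanmax(row)
        top = frozenset(
            d for d, v in zip(profile.donors, row)
            if not np.isnan(v) and v >= best - tie_epsilon
        )
        s = int(profile.starts[w])
        e = s + profile.window
        if top == cur_set:
            cur_end = e
            cur_vals.append(best)
        else:
            flush()
            cur_set, cur_start, cur_end, cur_vals = top, s, e, [best]
    flush()
    # clip overlaps from sliding windows
    for prev, nxt in zip(segments, segments[1:]):
        if nxt.start < prev.end:
            prev.end = nxt.start
    return segments


def segments_table(query: str, segments: list[DonorSegment]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row(query) for s in segments])


def donor_runs(segments: list[DonorSegment], donor: str) -> list[tuple[int, int]]:
    """Spans over which ``donor`` is (part of) the best match: maximal runs
    of consecutive segments whose top set contains the donor, with edge
    segments where the donor is merely tied trimmed away.

    A window straddling a conversion breakpoint has mixed ancestry and
    often produces an exact tie; such a tie says nothing about which side
    of the breakpoint the window belongs to, so tied segments at the edges
    of a run are excluded from its span. Used to estimate planted-tract
    boundaries from a profile."""
    runs: list[list[DonorSegment]] = []
    for seg in segments:
        if donor in seg.top_donors:
            if runs and runs[-1][-1].end == seg.start:
                runs[-1].append(seg)
            else:
                runs.append([seg])
    spans: list[tuple[int, int]] = []
    sole = frozenset({donor})
    for run in runs:
        while run and run[0].top_donors != sole:
            run.pop(0)
        while run and run[-1].top_donors != sole:
            run.pop()
        if run:
            spans.append((run[0].start, run[-1].end))
    return spans
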