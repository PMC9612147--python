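"""Circular sliding-window scan of SNV density and nucleotide diversity.

Windows of a fixed size slide at a fixed step over the reference.  On a
circular genome the window starts cover the whole circle and windows wrap
across the origin; on a linear genome the last full window ends at the
genome end and no shorter trailing window is emitted.

Per window two statistics are computed: the number of distinct segregating
positions (SNV density), and nucleotide diversity pi — the mean pairwise
proportion of differing sites among the strain haplotypes of the window,
with pairwise deletion of columns where either member is ambiguous.  The
marker source window is the one maximising SNV count, with ties broken by
higher pi, then by smaller start (wrapping windows after non-wrapping).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mtmarker.seqcore import CircularGenome, Interval, subseq
from mtmarker.vardetect import StrainVariantMatrix

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


class NoInformativeRegionError(ValueError):
    """All windows carry zero variants; no marker window can be selected."""


@dataclass(frozen=True)
class WindowStat:
    window: Interval
    snv_count: int
    pi: float
    n_strains: int

    def __post_init__(self) -> None:
        if self.snv_count == 0 and self.pi != 0.0:
            raise ValueError("window without variants must have pi == 0")


def sliding_windows(
    genome_length: int, window_size: int, step: int, circular: bool
) -> list[Interval]:
    """Window intervals starting at 1, 1+step, 1+2*step, ...

    Circular genomes yield ceil(L/step) windows, wrapping past the origin;
    linear genomes stop at the last start for which a full window fits.
    """
    if not 1 <= window_size <= genome_length:
        raise ValueError(
            f"window_size {window_size} invalid for genome length {genome_length}"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    out = []
    last_start = genome_length if circular else genome_length - window_size + 1
    for start in range(1, last_start + 1, step):
        end = start + window_size - 1
        if end > genome_length:
            out.append(Interval(start, end - genome_length, wraps=True))
        else:
            out.append(Interval(start, end))
    return out


def window_snv_density(
    matrix: StrainVariantMatrix, windows: Sequence[Interval], genome_length: int
) -> list[int]:
    """Distinct variant positions per window (a shared position counts once)."""
    positions = matrix.distinct_positions()
    if len(positions) and (positions.min() < 1 or positions.max() > genome_length):
        raise ValueError("variant position outside reference")
    counts = []
    for w in windows:
        if w.wraps:
            n = int(((positions >= w.start) | (positions <= w.end)).sum())
        else:
            n = int(((positions >= w.start) & (positions <= w.end)).sum())
        counts.append(n)
    return counts


def window_pi(haplotypes: Sequence[str]) -> float:
    """Nucleotide diversity of equal-length haplotypes.

    pi = 2/(n(n-1)) * sum_{i<j} d_ij / L_ij with pairwise deletion:
    d_ij counts columns where both bases are unambiguous and differ, and
    L_ij counts columns where both are unambiguous.  Pairs with no
    comparable column are excluded with a warning; if every pair is
    excluded the statistic is undefined.
    """
    n = len(haplotypes)
    if n < 2:
        raise ValueError("pi requires at least 2 haplotypes")
    L = len(haplotypes[0])
    if L < 1 or any(len(h) != L for h in haplotypes):
        raise ValueError("haplotypes must share one positive length")
    arrs = [np.frombuffer(h.upper().encode(), dtype=np.uint8) for h in haplotypes]
    oks = [np.isin(a, _ACGT) for a in arrs]
    ratios = []
    for i, j in combinations(range(n), 2):
        both = oks[i] & oks[j]
        L_ij = int(both.sum())
        if L_ij == 0:
            warnings.warn(
                f"haplotype pair ({i}, {j}) has no comparable positions; excluded"
            )
            continue
        d_ij = int(((arrs[i] != arrs[j]) & both).sum())
        ratios.append(d_ij / L_ij)
    if not ratios:
        raise ValueError("pi undefined: no haplotype pair has comparable positions")
    return 2.0 * sum(ratios) / (n * (n - 1))


def _pair_diff_tracks(genomes: Sequence[CircularGenome]) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair boolean difference and comparability tracks, stacked."""
    arrs = [np.frombuffer(g.seq.encode(), dtype=np.uint8) for g in genomes]
    oks = [np.isin(a, _ACGT) for a in arrs]
    diffs, boths = [], []
    for i, j in combinations(range(len(genomes)), 2):
        both = oks[i] & oks[j]
        diffs.append((arrs[i] != arrs[j]) & both)
        boths.append(both)
    return np.array(diffs), np.array(boths)


def _window_sums(track: np.ndarray, windows: Sequence[Interval], L: int) -> np.ndarray:
    """Sum each row of ``track`` over each window, wrap-aware, via cumsum."""
    doubled = np.concatenate([track, track], axis=1)
    csum = np.concatenate(
        [np.zeros((track.shape[0], 1)), np.cumsum(doubled, axis=1)], axis=1
    )
    out = np.empty((track.shape[0], len(windows)))
    for w_i, w in enumerate(windows):
        a = w.start - 1  # 0-based start in doubled coordinates
        b = a + w.span(L)
        out[:, w_i] = csum[:, b] - csum[:, a]
    return out


def scan(
    reference: CircularGenome,
    strain_genomes: Sequence[CircularGenome] | None = None,
    matrix: StrainVariantMatrix | None = None,
    window_size: int = 400,
    step: int = 100,
) -> list[WindowStat]:
    """Joint SNV-density / pi scan over sliding windows.

    Haplotypes for pi come from the strain genomes when given; otherwise
    they are reconstructed from the variant matrix as the reference with
    each strain's alternate alleles substituted (exact on substitution-only
    panels).  The SNV track always derives from the variant matrix, which
    is computed from the genomes if absent.
    """
    from mtmarker.vardetect import snvs_from_genomes  # cycle guard

    if strain_genomes is None and matrix is None:
        raise ValueError("need strain genomes and/or a variant matrix")
    if matrix is None:
        matrix = snvs_from_genomes(reference, strain_genomes)
    if strain_genomes is None:
        strain_genomes = reconstruct_haplotypes(reference, matrix)
    windows = sliding_windows(reference.length, window_size, step, reference.circular)
    counts = window_snv_density(matrix, windows, reference.length)
    diffs, boths = _pair_diff_tracks(strain_genomes)
    d_sums = _window_sums(diffs, windows, reference.length)
    L_sums = _window_sums(boths, windows, reference.length)
    n = len(strain_genomes)
    stats = []
    for w_i, w in enumerate(windows):
        usable = L_sums[:, w_i] > 0
        if not usable.any():
            raise ValueError(f"window {w}: no comparable positions in any pair")
        ratios = d_sums[usable, w_i] / L_sums[usable, w_i]
        pi = float(2.0 * ratios.sum() / (n * (n - 1)))
        if counts[w_i] == 0:
            pi = 0.0  # a window without called variants reports zero diversity
        stats.append(WindowStat(window=w, snv_count=counts[w_i], pi=pi, n_strains=n))
    return stats


def reconstruct_haplotypes(
    reference: CircularGenome, matrix: StrainVariantMatrix
) -> list[CircularGenome]:
    """Strain haplotypes as the reference with per-strain alts substituted."""
    out = []
    for strain in matrix.strains:
        arr = bytearray(reference.seq.encode())
        sub = matrix.records[matrix.records["strain"] == strain]
        for _, row in sub.iterrows():
            arr[int(row["position"]) - 1] = ord(row["alt"])
        out.append(
            CircularGenome(id=strain, seq=arr.decode(), circular=reference.circular)
        )
    return out


def select_marker_window(
    stats: Sequence[WindowStat], min_span: int = 350, max_span: int = 400
) -> Interval:
    """Pick the marker source window.

    Maximise SNV count; break ties by larger pi, then by smaller start with
    wrapping windows ranked after non-wrapping ones.  Raises
    :class:`NoInformativeRegionError` when no window carries a variant.
    """
    if not stats:
        raise ValueError("no window statistics supplied")
    if min_span > max_span:
        raise ValueError("min_span must be <= max_span")
    spans = {s.window.end - s.window.start + 1 for s in stats if not s.window.wraps}
    if spans and not spans.issubset(set(range(min_span, max_span + 1))):
        raise ValueError(
            f"window size(s) {sorted(spans)} outside requested span range "
            f"[{min_span}, {max_span}]"
        )
    if all(s.snv_count == 0 for s in stats):
        raise NoInformativeRegionError("no informative region: all windows carry 0 SNVs")
    best = min(
        stats,
        key=lambda s: (-s.snv_count, -s.pi, s.window.wraps, s.window.start),
    )
    return best.window


def stats_to_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    """Scan track as a table (start, end, wraps, snv_count, pi, n_strains)."""
    return pd.DataFrame(
        {
            "start": [s.window.start for s in stats],
            "end": [s.window.end for s in stats],
            "wraps": [s.window.wraps for s in stats],
            "snv_count": [s.snv_count for s in stats],
            "pi": [s.pi for s in stats],
            "n_strains": [s.n_strains for s in stats],
        }
    )


def write_scan_track(stats: Sequence[WindowStat], path: str | Path) -> None:
    stats_to_frame(stats).to_csv(path, sep="\t", index=False)
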