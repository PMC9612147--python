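"""Primer design around a marker window and specificity screening.

Primer physical properties use the Wallace rule for melting temperature
(Tm = 2(A+T) + 4(G+C)); design enumerates every primer placement inside a
flank-extended region around the target window, filters on length, GC,
Tm, Tm balance and homopolymer runs, and ranks surviving pairs by a
weighted penalty (Tm imbalance, GC deviation from 0.5, amplicon-span
deviation from the target span, non-G/C 3' terminus).

Specificity is screened two ways: in-silico PCR, which locates oriented
primer binding sites on both strands of each (circular-aware) template
under a mismatch tolerance with an exact 3'-terminal segment; and
coverage-weighted local-alignment identity of the marker itself against
off-target genomes (Smith-Waterman with linear gap penalty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from mtmarker.seqcore import CircularGenome, Interval, revcomp, subseq

UNAMBIG = frozenset("ACGT")


def tm_wallace(seq: str) -> int:
    """Wallace-rule melting temperature, 2(A+T) + 4(G+C), in deg C."""
    s = seq.upper()
    if len(s) < 2:
        raise ValueError("Tm requires length >= 2")
    if set(s) - UNAMBIG:
        raise ValueError(f"ambiguity code in primer {seq!r}")
    gc = s.count("G") + s.count("C")
    return 2 * (len(s) - gc) + 4 * gc


def gc_content(seq: str) -> float:
    """G+C fraction over unambiguous positions."""
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    n = sum(s.count(b) for b in "ACGT")
    if n == 0:
        raise ValueError("all-ambiguous sequence: GC content undefined")
    return (s.count("G") + s.count("C")) / n


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class PrimerConstraints:
    """Default constraints for marker-primer enumeration."""

    min_len: int = 18
    max_len: int = 24
    gc_min: float = 0.30
    gc_max: float = 0.60
    tm_min: int = 50
    tm_max: int = 62
    max_tm_diff: int = 5
    max_homopolymer: int = 5
    min_span: int = 350
    max_span: int = 400
    min_window_coverage: float = 0.90

    @property
    def max_amplicon_span(self) -> int:
        return self.max_span + 2 * self.max_len


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair on a template.

    ``rev_seq`` is given 5'->3' on the reverse strand, i.e. it equals the
    reverse complement of the template slice ending at ``rev_end``.
    """

    fwd_seq: str
    rev_seq: str
    fwd_start: int  # 1-based template position of the fwd primer's 5' base
    rev_end: int  # 1-based template position of the rev primer's 5' base
    tm_fwd: int
    tm_rev: int
    gc_fwd: float
    gc_rev: float
    amplicon: Interval
    score: float = 0.0

    @property
    def amplicon_length(self) -> int:
        return self.amplicon.end - self.amplicon.start + 1


@dataclass
class DesignResult:
    pairs: list[PrimerPair]
    failure_counts: dict[str, int] = field(default_factory=dict)


def primer_ok(seq: str, c: PrimerConstraints) -> str | None:
    """None if the primer passes the single-primer filters, else the reason."""
    if not c.min_len <= len(seq) <= c.max_len:
        return "length"
    if set(seq) - UNAMBIG:
        return "ambiguity"
    gc = gc_content(seq)
    if not c.gc_min <= gc <= c.gc_max:
        return "gc_range"
    tm = tm_wallace(seq)
    if not c.tm_min <= tm <= c.tm_max:
        return "tm_range"
    if max_homopolymer(seq) > c.max_homopolymer:
        return "homopolymer"
    return None


def _pair_score(
    pair_tm_diff: int,
    gc_f: float,
    gc_r: float,
    span: int,
    target_span: int,
    fwd_seq: str,
    rev_seq: str,
) -> float:
    score = 1.0 * pair_tm_diff
    score += 10.0 * (abs(gc_f - 0.5) + abs(gc_r - 0.5))
    score += 0.05 * abs(span - target_span)
    # G/C 3' terminus preferred, not required
    score += 0.5 * (fwd_seq[-1] not in "GC") + 0.5 * (rev_seq[-1] not in "GC")
    return score


def design_primers(
    template: CircularGenome,
    target_window: Interval,
    flank: int = 200,
    constraints: PrimerConstraints | None = None,
) -> DesignResult:
    """Enumerate and rank primer pairs whose amplicon covers the window.

    The search region is the target window extended by ``flank`` on each
    side (clamped at the ends of a linear template, wrapping on a circular
    one).  A pair is kept when both primers pass the single-primer
    filters, their Tm difference is within bounds, the amplicon span lies
    in [min_span, max_span + 2*max primer length] and the amplicon covers
    at least ``min_window_coverage`` of the target window.  Ranking is by
    ascending penalty score with ties broken by leftmost forward start.
    """
    c = constraints or PrimerConstraints()
    template.validate_interval(target_window)
    if flank < 0:
        raise ValueError("flank must be >= 0")
    L = template.length
    win_span = target_window.span(L)

    if template.circular:
        rs = (target_window.start - 1 - flank) % L + 1
        re = (target_window.end - 1 + flank) % L + 1
        region_iv = (
            Interval(rs, re, wraps=re < rs)
            if win_span + 2 * flank < L
            else Interval(1, L)
        )
    else:
        rs = max(1, target_window.start - flank)
        re = min(L, target_window.end + flank)
        region_iv = Interval(rs, re)
    region = subseq(template, region_iv)
    tpos = list(region_iv.positions(L))  # local index -> 1-based template pos
    local_of = {p: i for i, p in enumerate(tpos)}
    ws_local = local_of[target_window.start]
    we_local = local_of[target_window.end]

    failures: dict[str, int] = {}

    def _fail(reason: str) -> None:
        failures[reason] = failures.get(reason, 0) + 1

    fwd_cands: list[tuple[int, str]] = []  # (local start, seq)
    rev_by_end: dict[int, list[str]] = {}  # local end -> rev primer seqs
    for l in range(c.min_len, c.max_len + 1):
        for i in range(len(region) - l + 1):
            s = region[i : i + l]
            why = primer_ok(s, c)
            if why is not None:
                if why != "length":
                    _fail(f"fwd_{why}")
                continue
            fwd_cands.append((i, s))
            rseq = revcomp(s)
            why_r = primer_ok(rseq, c)
            if why_r is None:
                rev_by_end.setdefault(i + l - 1, []).append(rseq)
            else:
                _fail(f"rev_{why_r}")
    if not fwd_cands:
        _fail("no_forward_placement")
    if not rev_by_end:
        _fail("no_reverse_placement")

    pairs: list[PrimerPair] = []
    for i, fseq in fwd_cands:
        lo = i + max(c.min_span, 2 * c.min_len) - 1
        hi = min(i + c.max_amplicon_span - 1, len(region) - 1)
        for j in range(lo, hi + 1):
            for rseq in rev_by_end.get(j, ()):
                span = j - i + 1
                if span < len(fseq) + len(rseq):
                    _fail("primer_overlap")
                    continue
                overlap = min(j, we_local) - max(i, ws_local) + 1
                if overlap < c.min_window_coverage * win_span:
                    _fail("window_coverage")
                    continue
                tm_f, tm_r = tm_wallace(fseq), tm_wallace(rseq)
                if abs(tm_f - tm_r) > c.max_tm_diff:
                    _fail("tm_difference")
                    continue
                gc_f, gc_r = gc_content(fseq), gc_content(rseq)
                amp_start, amp_end = tpos[i], tpos[j]
                amp = Interval(amp_start, amp_end, wraps=amp_end < amp_start)
                pairs.append(
                    PrimerPair(
                        fwd_seq=fseq,
                        rev_seq=rseq,
                        fwd_start=amp_start,
                        rev_end=amp_end,
                        tm_fwd=tm_f,
                        tm_rev=tm_r,
                        gc_fwd=gc_f,
                        gc_rev=gc_r,
                        amplicon=amp,
                        score=_pair_score(
                            abs(tm_f - tm_r), gc_f, gc_r, span, win_span, fseq, rseq
                        ),
                    )
                )
    pairs.sort(key=lambda p: (p.score, p.fwd_start, p.rev_end, p.fwd_seq, p.rev_seq))
    return DesignResult(pairs=pairs, failure_counts=failures)


# ---------------------------------------------------------------------------
# in-silico PCR


@dataclass(frozen=True)
class PredictedAmplicon:
    template_id: str
    start: int  # 1-based, on the plus strand
    end: int  # may exceed template length temporarily before normalisation
    span: int
    strand: str  # '+': fwd primer on plus strand; '-': fwd primer on minus
    mismatches_fwd: int
    mismatches_rev: int

    @property
    def total_mismatches(self) -> int:
        return self.mismatches_fwd + self.mismatches_rev


@dataclass
class PcrResult:
    template_id: str
    classification: str  # positive / weak / negative
    amplicons: list[PredictedAmplicon]


def _site_scan(
    arr: np.ndarray,
    primer: str,
    n_starts: int,
    max_mismatch: int,
    three_prime_exact: int,
    three_prime_left: bool,
) -> dict[int, int]:
    """Binding sites of ``primer`` on ``arr``: {0-based start: mismatches}.

    ``three_prime_left`` selects which end of the occurrence carries the
    primer's 3' terminus (left for a reverse-complemented occurrence).
    """
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    k = len(p)
    if k > n_starts:
        return {}
    sw = sliding_window_view(arr, k)[:n_starts]
    neq = sw != p
    mism = neq.sum(axis=1)
    ok = mism <= max_mismatch
    if three_prime_exact > 0:
        tp = (
            neq[:, : three_prime_exact]
            if three_prime_left
            else neq[:, k - three_prime_exact :]
        )
        ok &= ~tp.any(axis=1)
    return {int(i): int(mism[i]) for i in np.nonzero(ok)[0]}


def in_silico_pcr(
    pair: PrimerPair | tuple[str, str],
    templates: Sequence[CircularGenome],
    max_mismatch: int = 3,
    three_prime_exact: int = 3,
    max_amplicon: int = 5000,
) -> list[PcrResult]:
    """Predict amplification of each template by a primer pair.

    Both strands of each template are scanned for forward- and
    reverse-primer binding sites allowing up to ``max_mismatch``
    substitutions per site with the terminal ``three_prime_exact`` bases
    matched exactly; every properly oriented site pair spanning at most
    ``max_amplicon`` nt is reported.  A template is "positive" when some
    pair binds with zero total mismatches, "weak" when only mismatched
    pairs exist, "negative" otherwise.
    """
    fwd, rev = (pair.fwd_seq, pair.rev_seq) if isinstance(pair, PrimerPair) else pair
    results = []
    for t in templates:
        L = t.length
        if len(fwd) > L or len(rev) > L:
            raise ValueError(f"primer longer than template {t.id!r}")
        seq = t.seq + t.seq[: max_amplicon - 1] if t.circular else t.seq
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        horizon = len(seq)

        def sites(primer: str, left3: bool) -> dict[int, int]:
            # scan the full horizon; left-partner sites are later confined
            # to one period so each circular amplicon is reported once
            return _site_scan(arr, primer, horizon - len(primer) + 1,
                              max_mismatch, three_prime_exact, left3)

        f_plus = sites(fwd, left3=False)  # fwd on plus strand, 3' right
        r_rc = sites(revcomp(rev), left3=True)  # rev on minus strand
        r_plus = sites(rev, left3=False)  # rev on plus strand
        f_rc = sites(revcomp(fwd), left3=True)  # fwd on minus strand

        amps: list[PredictedAmplicon] = []
        seen: set[tuple[int, int, str]] = set()

        def emit(p1: int, p2_end: int, strand: str, mm_f: int, mm_r: int) -> None:
            span = p2_end - p1 + 1
            if span > min(max_amplicon, horizon) or (t.circular and span > L):
                return
            key = (p1 % L, span, strand)
            if p1 >= L or key in seen:  # canonical copy only, on circles
                return
            seen.add(key)
            amps.append(
                PredictedAmplicon(
                    template_id=t.id,
                    start=p1 + 1,
                    end=(p2_end % L) + 1 if t.circular else p2_end + 1,
                    span=span,
                    strand=strand,
                    mismatches_fwd=mm_f,
                    mismatches_rev=mm_r,
                )
            )

        for p1, mm_f in f_plus.items():
            if p1 >= L:
                continue
            for q, mm_r in r_rc.items():
                if q >= p1 + len(fwd):
                    emit(p1, q + len(rev) - 1, "+", mm_f, mm_r)
        for r1, mm_r in r_plus.items():
            if r1 >= L:
                continue
            for s, mm_f in f_rc.items():
                if s >= r1 + len(rev):
                    emit(r1, s + len(fwd) - 1, "-", mm_f, mm_r)

        if any(a.total_mismatches == 0 for a in amps):
            cls = "positive"
        elif amps:
            cls = "weak"
        else:
            cls = "negative"
        results.append(PcrResult(template_id=t.id, classification=cls, amplicons=amps))
    return results


# ---------------------------------------------------------------------------
# local alignment


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    identity: float  # matching columns / aligned columns
    aligned_span: int  # number of alignment columns
    matches: int
    a_start: int  # 1-based, inclusive; 0 when the alignment is empty
    a_end: int
    b_start: int
    b_end: int


def smith_waterman(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> LocalAlignment:
    """Optimal local alignment with linear gap penalty.

    Deterministic traceback prefers diagonal, then up (gap in ``b``), then
    left, starting from the first (row-major) maximal cell.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if not (match > 0 >= mismatch and gap < 0):
        raise ValueError("require match > 0 >= mismatch and gap < 0")
    A = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    B = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    n, m = len(A), len(B)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    jidx = np.arange(1, m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        s_row = np.where(B == A[i - 1], match, mismatch).astype(np.int64)
        prev = H[i - 1].astype(np.int64)
        cand = np.maximum(prev[:-1] + s_row, prev[1:] + gap)
        cand = np.maximum(cand, 0)
        # resolve the in-row (left) dependency as a running max:
        # H[i,j] = max_{k<=j} cand_k + gap*(j-k)
        H[i, 1:] = np.maximum.accumulate(cand - gap * jidx) + gap * jidx
    best = int(H.max())
    if best == 0:
        return LocalAlignment(0, 0.0, 0, 0, 0, 0, 0, 0)
    i, j = np.unravel_index(int(H.argmax()), H.shape)  # first maximal, row-major
    a_end, b_end = int(i), int(j)
    matches = cols = 0
    while H[i, j] > 0:
        s = match if A[i - 1] == B[j - 1] else mismatch
        if i > 0 and j > 0 and H[i - 1, j - 1] + s == H[i, j]:
            matches += A[i - 1] == B[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and H[i - 1, j] + gap == H[i, j]:
            i -= 1
        elif j > 0 and H[i, j - 1] + gap == H[i, j]:
            j -= 1
        else:  # pragma: no cover - recurrence guarantees one branch fires
            break
        cols += 1
    return LocalAlignment(
        score=best,
        identity=matches / cols if cols else 0.0,
        aligned_span=cols,
        matches=int(matches),
        a_start=int(i) + 1,
        a_end=a_end,
        b_start=int(j) + 1,
        b_end=b_end,
    )


def marker_specificity(
    marker_seq: str,
    offtarget_genomes: Sequence[CircularGenome],
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> tuple[float, pd.DataFrame]:
    """Coverage-weighted identity of the marker against an off-target panel.

    Per off-target, both strands are searched (origin-spanning hits
    included on circular genomes) and identity is reported as matching
    columns of the best local alignment divided by the marker length, so a
    short perfect hit scores low.  Returns the panel maximum and a
    per-genome report.
    """
    if len(marker_seq) < 50:
        raise ValueError("marker must be >= 50 nt")
    if not offtarget_genomes:
        raise ValueError("empty off-target panel")
    rows = []
    for g in offtarget_genomes:
        seq = g.seq + g.seq[: len(marker_seq) - 1] if g.circular else g.seq
        best = None
        for strand, target in (("+", seq), ("-", revcomp(seq))):
            aln = smith_waterman(marker_seq, target, match, mismatch, gap)
            if best is None or aln.matches > best[1].matches:
                best = (strand, aln)
        strand, aln = best
        rows.append(
            {
                "template": g.id,
                "identity": aln.matches / len(marker_seq),
                "score": aln.score,
                "aligned_span": aln.aligned_span,
                "strand": strand,
            }
        )
    report = pd.DataFrame(rows, columns=["template", "identity", "score", "aligned_span", "strand"])
    return float(report["identity"].max()), report
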