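"""Per-strain SNV calling against a circular reference.

Three routes produce the same container, a :class:`StrainVariantMatrix`:

* allele counts -> calls under the homozygous-support rule (a site is
  called when the leading non-reference allele exceeds the support
  threshold, strictly, at sufficient coverage);
* direct comparison of equal-length assembled strain genomes;
* a pre-computed VCF-like variant table, validated against the reference.

The bundled read mapper is a naive unique-k-mer anchor placer intended for
synthetic substitution-only panels; real read data should be mapped with a
production aligner and summarised to the allele-count table instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mtmarker.seqcore import CircularGenome, CoordinateError, revcomp

log = logging.getLogger(__name__)

_BASE_ORDER = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASE_ORDER)}

RECORD_COLUMNS = ["position", "ref", "strain", "alt", "support"]


@dataclass
class AlleleCounts:
    """Per-position A/C/G/T counts for one strain against a reference."""

    strain: str
    counts: np.ndarray  # shape (L, 4), columns in A,C,G,T order
    n_placed: int = 0
    n_dropped: int = 0

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (strain, pos, nA, nC, nG, nT), covered rows only."""
        cov = self.coverage
        pos = np.nonzero(cov > 0)[0]
        return pd.DataFrame(
            {
                "strain": self.strain,
                "pos": pos + 1,
                "nA": self.counts[pos, 0],
                "nC": self.counts[pos, 1],
                "nG": self.counts[pos, 2],
                "nT": self.counts[pos, 3],
            }
        )


def read_allele_counts(path: str | Path, reference_length: int) -> list[AlleleCounts]:
    """Read the TSV pileup dialect (strain, pos, nA, nC, nG, nT)."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "pos", "nA", "nC", "nG", "nT"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing pileup columns {sorted(missing)}")
    out = []
    for strain, sub in df.groupby("strain", sort=True):
        counts = np.zeros((reference_length, 4), dtype=np.int64)
        pos = sub["pos"].to_numpy()
        if (pos < 1).any() or (pos > reference_length).any():
            raise CoordinateError(f"{path}: pileup position outside reference")
        if len(np.unique(pos)) != len(pos):
            raise ValueError(f"{path}: duplicate (strain, pos) row for {strain!r}")
        for col, j in (("nA", 0), ("nC", 1), ("nG", 2), ("nT", 3)):
            counts[pos - 1, j] = sub[col].to_numpy()
        out.append(AlleleCounts(strain=str(strain), counts=counts))
    return out


@dataclass
class StrainVariantMatrix:
    """SNV records of a strain panel against one reference."""

    reference_id: str
    strains: list[str]
    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=RECORD_COLUMNS)
    )
    rejections: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.records) and (self.records["alt"] == self.records["ref"]).any():
            raise ValueError("variant record with alt == ref")

    def distinct_positions(self) -> np.ndarray:
        """Sorted distinct variant positions (segregating sites)."""
        if not len(self.records):
            return np.array([], dtype=np.int64)
        return np.unique(self.records["position"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        df = self.records.sort_values(["position", "strain"], kind="mergesort")
        df.to_csv(path, sep="\t", index=False, columns=RECORD_COLUMNS)


def build_anchor_index(reference: CircularGenome, k: int) -> dict[str, int | None]:
    """Map each k-mer of the (doubled, if circular) reference to its unique
    0-based start, or None when the k-mer occurs more than once."""
    seq = reference.seq + reference.seq[: k - 1] if reference.circular else reference.seq
    index: dict[str, int | None] = {}
    L = reference.length
    n_starts = L if reference.circular else L - k + 1
    for p in range(n_starts):
        kmer = seq[p : p + k]
        index[kmer] = None if kmer in index else p
    return index


def _place_read(
    read_seq: str, index: dict[str, int | None], k: int, L: int, circular: bool
) -> int | None:
    """0-based start of the read on the reference, or None if unplaceable."""
    for i in range(len(read_seq) - k + 1):
        hit = index.get(read_seq[i : i + k], "absent")
        if hit == "absent":
            continue
        if hit is None:
            return None  # first anchoring k-mer is multi-hit: drop
        start = hit - i
        if circular:
            return start % L
        if 0 <= start and start + len(read_seq) <= L:
            return start
        return None
    return None


def pileup_from_reads(
    reference: CircularGenome,
    reads: Iterable[CircularGenome],
    anchor_k: int = 21,
    strain: str = "sample",
) -> AlleleCounts:
    """Place reads by unique exact k-mer anchor and count bases ungapped.

    Each read is anchored by its first k-mer with a unique exact hit on the
    reference, trying the forward orientation then the reverse complement;
    reads whose anchoring k-mer is multi-hit or absent are dropped and
    tallied.  Suitable for substitution-only synthetic panels only.
    """
    index = build_anchor_index(reference, anchor_k)
    L = reference.length
    counts = np.zeros((L, 4), dtype=np.int64)
    n_placed = n_dropped = 0
    for read in reads:
        seq = read.seq
        if anchor_k > len(seq):
            raise ValueError(f"anchor_k {anchor_k} exceeds read length {len(seq)}")
        start = _place_read(seq, index, anchor_k, L, reference.circular)
        if start is None:
            rc = revcomp(seq)
            start = _place_read(rc, index, anchor_k, L, reference.circular)
            seq = rc
        if start is None:
            n_dropped += 1
            continue
        n_placed += 1
        for offset, base in enumerate(seq):
            j = _BASE_IDX.get(base)
            if j is None:
                continue
            counts[(start + offset) % L if reference.circular else start + offset, j] += 1
    log.info("pileup %s: placed %d reads, dropped %d", strain, n_placed, n_dropped)
    return AlleleCounts(strain=strain, counts=counts, n_placed=n_placed, n_dropped=n_dropped)


def call_snvs_from_counts(
    counts: AlleleCounts | Sequence[AlleleCounts],
    reference: CircularGenome,
    min_coverage: int = 10,
    support_threshold: float = 0.85,
) -> StrainVariantMatrix:
    """Call SNVs under the homozygous-support rule.

    At each position the leading non-reference allele (ties broken
    alphabetically) is called iff coverage >= ``min_coverage`` and its
    fraction of total coverage strictly exceeds ``support_threshold``; a
    site at exactly the threshold is not called.
    """
    if not 0.5 < support_threshold <= 1.0:
        raise ValueError("support_threshold must be in (0.5, 1]")
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    panel = [counts] if isinstance(counts, AlleleCounts) else list(counts)
    rows = []
    ref_idx = np.array(
        [_BASE_IDX.get(b, -1) for b in reference.seq], dtype=np.int64
    )
    for ac in panel:
        if ac.counts.shape[0] != reference.length:
            raise CoordinateError(
                f"counts for {ac.strain!r} cover {ac.counts.shape[0]} positions, "
                f"reference has {reference.length}"
            )
        cov = ac.coverage
        masked = ac.counts.astype(float).copy()
        valid = ref_idx >= 0
        masked[np.arange(len(ref_idx))[valid], ref_idx[valid]] = -1
        alt_j = masked.argmax(axis=1)  # argmax takes the first = alphabetical tie-break
        alt_count = ac.counts[np.arange(len(cov)), alt_j]
        with np.errstate(invalid="ignore", divide="ignore"):
            support = np.where(cov > 0, alt_count / np.maximum(cov, 1), 0.0)
        called = (cov >= min_coverage) & (support > support_threshold) & valid
        for p in np.nonzero(called)[0]:
            rows.append(
                {
                    "position": int(p) + 1,
                    "ref": reference.seq[p],
                    "strain": ac.strain,
                    "alt": _BASE_ORDER[alt_j[p]],
                    "support": float(support[p]),
                }
            )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return StrainVariantMatrix(
        reference_id=reference.id,
        strains=[ac.strain for ac in panel],
        records=records,
    )


def snvs_from_genomes(
    reference: CircularGenome, strain_genomes: Sequence[CircularGenome]
) -> StrainVariantMatrix:
    """SNVs by direct comparison of equal-length assembled genomes.

    Positions where either base is ambiguous (non-ACGT) are skipped and
    tallied; support is reported as 1.0 for sequence-derived calls.
    """
    ref_arr = np.frombuffer(reference.seq.encode(), dtype=np.uint8)
    unambig = np.isin(ref_arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    rows = []
    n_skipped = 0
    for g in strain_genomes:
        if g.length != reference.length:
            raise ValueError(
                f"strain {g.id!r} length {g.length} != reference length "
                f"{reference.length}; supply an aligned (MSA-derived) panel"
            )
        arr = np.frombuffer(g.seq.encode(), dtype=np.uint8)
        ok = unambig & np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        n_skipped += int((~ok).sum())
        diff = np.nonzero((arr != ref_arr) & ok)[0]
        for p in diff:
            rows.append(
                {
                    "position": int(p) + 1,
                    "ref": reference.seq[p],
                    "strain": g.id,
                    "alt": g.seq[p],
                    "support": 1.0,
                }
            )
    if n_skipped:
        log.info("snvs_from_genomes: skipped %d ambiguous position comparisons", n_skipped)
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return StrainVariantMatrix(
        reference_id=reference.id,
        strains=[g.id for g in strain_genomes],
        records=records,
    )


def read_variant_table(path: str | Path, reference: CircularGenome) -> StrainVariantMatrix:
    """Read a VCF-like TSV (CHROM, POS, REF, ALT, STRAIN[, SUPPORT]).

    Rows whose REF disagrees with the reference base at POS, or that are
    otherwise malformed, are rejected and collected in the returned
    matrix's ``rejections`` table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"CHROM", "POS", "REF", "ALT", "STRAIN"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing variant-table columns {sorted(missing)}")
    if not len(df):
        log.warning("%s: empty variant table", path)
    accepted, rejected = [], []
    for _, row in df.iterrows():
        reason = None
        try:
            pos = int(row["POS"])
        except (TypeError, ValueError):
            pos, reason = -1, "POS not an integer"
        ref = str(row["REF"]).upper()
        alt = str(row["ALT"]).upper()
        if reason is None and not 1 <= pos <= reference.length:
            reason = "POS outside reference"
        if reason is None and (len(ref) != 1 or len(alt) != 1):
            reason = "not a single-nucleotide record"
        if reason is None and reference.seq[pos - 1] != ref:
            reason = f"REF mismatch (reference has {reference.seq[pos - 1]})"
        if reason is None and alt == ref:
            reason = "ALT equals REF"
        if reason:
            rejected.append({**row.to_dict(), "reason": reason})
            continue
        support = float(row["SUPPORT"]) if "SUPPORT" in df.columns else 1.0
        accepted.append(
            {
                "position": pos,
                "ref": ref,
                "strain": row["STRAIN"],
                "alt": alt,
                "support": support,
            }
        )
    if rejected:
        log.warning("%s: rejected %d variant rows", path, len(rejected))
    records = pd.DataFrame(accepted, columns=RECORD_COLUMNS)
    strains = sorted(records["strain"].unique()) if len(records) else []
    return StrainVariantMatrix(
        reference_id=reference.id,
        strains=strains,
        records=records,
        rejections=pd.DataFrame(rejected),
    )
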