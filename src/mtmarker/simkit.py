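"""Synthetic strain panels, reads, off-target species and amplicon surveys.

The generator emulates the data structure the pipeline is built for: a
small AT-rich circular genome, a handful of near-identical strains grouped
into clades, substitutions concentrated in one planted hypervariable
window against a sparse background, divergent off-target species, and a
presence/absence amplicon survey over named regions.  Every simulator is a
pure function of its arguments including the seed, and each panel carries
its ground truth for parameter-recovery tests.

The mutation model is substitution-only, so every strain genome stays the
same length as the reference and the panel needs no alignment step.
Clade-shared substitutions are planted directly per clade rather than
drawn from a coalescent: the clades are study conditions, not a
demographic inference target.  Each clade receives at least one diagnostic
substitution inside the planted window (zero-truncated Poisson count), so
the simulated clades are molecularly distinguishable entities, as the
strain panels this emulates are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mtmarker.seqcore import CircularGenome, Interval

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"

DEFAULT_CLADES = {
    "strain1": "clade1",
    "strain2": "clade1",
    "strain3": "clade2",
    "strain4": "clade2",
    "strain5": "clade3",
    "strain6": "clade3",
}


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a simulated strain panel.

    Defaults mirror the study conditions this generator emulates: a 35-kb
    circular genome at 24.3% GC, six strains in three clades, a planted
    400-nt hypervariable window at 5 substitutions per kilobase per clade
    (about six segregating sites in the window across three clades) over a
    1e-5 background.
    """

    genome_length: int = 35_000
    gc_content: float = 0.243
    n_strains: int = 6
    clade_assignment: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLADES)
    )
    background_rate: float = 1e-5
    planted_window: Interval = Interval(5649, 6048)
    planted_rate: float = 5e-3
    private_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError(f"gc_content must be in (0,1), got {self.gc_content}")
        if self.n_strains < 2:
            raise ValueError("need at least 2 strains")
        if self.planted_rate < self.background_rate:
            raise ValueError("planted_rate must be >= background_rate")
        if len(self.clade_assignment) != self.n_strains:
            raise ValueError("every strain needs exactly one clade label")


@dataclass
class GroundTruth:
    """Planted truth of a simulated panel, for recovery tests."""

    true_snvs: pd.DataFrame  # columns: position, ref, strain, alt
    true_clades: dict[str, str]
    true_window: Interval


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def simulate_reference(genome_length: int, gc_content: float, seed: int) -> CircularGenome:
    """I.i.d. circular reference: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if genome_length < 1000:
        raise ValueError("genome_length must be >= 1000")
    if not 0.0 < gc_content < 1.0:
        raise ValueError(f"gc_content must be in (0,1), got {gc_content}")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    arr = rng.choice(BASES, size=genome_length, p=p)
    return CircularGenome(id="reference", seq=_array_to_seq(arr), circular=True)


def _mutate(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> dict[int, str]:
    """Substitute each position (0-based) to a uniform non-reference base."""
    out = {}
    for p in positions:
        ref = chr(arr[p])
        alt = rng.choice([b for b in _BASE_STR if b != ref])
        arr[p] = ord(alt)
        out[int(p)] = alt
    return out


def _zero_truncated_poisson(lam: float, rng: np.random.Generator) -> int:
    k = rng.poisson(lam)
    while k == 0:
        k = rng.poisson(lam)
    return int(k)


def simulate_strains(
    reference: CircularGenome, spec: PanelSpec
) -> tuple[list[CircularGenome], GroundTruth]:
    """Derive a clade-structured strain panel from a reference.

    Clade-shared substitutions are drawn once per clade: inside the planted
    window a zero-truncated Poisson count at ``planted_rate`` per site,
    elsewhere a Poisson count at ``background_rate`` per site.  Positions
    are uniform without replacement within each region class and alternate
    alleles uniform over the three non-reference bases.  Strain-private
    substitutions (``private_rate``) are added per strain afterwards.
    """
    reference.validate_interval(spec.planted_window)
    L = reference.length
    win = spec.planted_window
    win_span = win.span(L)
    if spec.planted_rate * win_span > win_span:
        raise ValueError("expected planted mutation count exceeds window span")
    rng = np.random.default_rng(spec.seed)
    ref_arr = _seq_to_array(reference.seq)

    win_pos = np.fromiter(win.positions(L), dtype=np.int64) - 1  # 0-based
    bg_mask = np.ones(L, dtype=bool)
    bg_mask[win_pos] = False
    bg_pos = np.nonzero(bg_mask)[0]

    clades = sorted(set(spec.clade_assignment.values()))
    clade_muts: dict[str, dict[int, str]] = {}
    for clade in clades:
        arr = ref_arr.copy()
        n_win = _zero_truncated_poisson(spec.planted_rate * win_span, rng)
        n_win = min(n_win, len(win_pos))
        n_bg = min(int(rng.poisson(spec.background_rate * len(bg_pos))), len(bg_pos))
        chosen = np.concatenate(
            [
                rng.choice(win_pos, size=n_win, replace=False),
                rng.choice(bg_pos, size=n_bg, replace=False),
            ]
        )
        clade_muts[clade] = _mutate(arr, chosen, rng)

    strains: list[CircularGenome] = []
    rows = []
    for strain in spec.clade_assignment:
        clade = spec.clade_assignment[strain]
        arr = ref_arr.copy()
        muts = dict(clade_muts[clade])
        for p, alt in muts.items():
            arr[p] = ord(alt)
        if spec.private_rate > 0:
            free = np.array([p for p in range(L) if p not in muts], dtype=np.int64)
            n_priv = min(int(rng.poisson(spec.private_rate * L)), len(free))
            priv = rng.choice(free, size=n_priv, replace=False)
            muts.update(_mutate(arr, priv, rng))
        for p in sorted(muts):
            rows.append(
                {
                    "position": p + 1,
                    "ref": chr(ref_arr[p]),
                    "strain": strain,
                    "alt": muts[p],
                }
            )
        strains.append(
            CircularGenome(id=strain, seq=_array_to_seq(arr), circular=True)
        )

    truth = GroundTruth(
        true_snvs=pd.DataFrame(rows, columns=["position", "ref", "strain", "alt"]),
        true_clades=dict(spec.clade_assignment),
        true_window=win,
    )
    return strains, truth


def simulate_reads(
    genome: CircularGenome,
    read_length: int,
    coverage: float,
    error_rate: float,
    seed: int,
) -> list[CircularGenome]:
    """Uniform single-end reads with i.i.d. substitution errors.

    Read count is ``round(coverage * genome_length / read_length)``.  On a
    circular genome, start positions are uniform over the whole circle and
    reads wrap across the origin.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_length > genome.length:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    L = genome.length
    n_reads = round(coverage * L / read_length)
    doubled = _seq_to_array(genome.seq + genome.seq)
    if genome.circular:
        starts = rng.integers(0, L, size=n_reads)
    else:
        starts = rng.integers(0, L - read_length + 1, size=n_reads)
    reads = []
    for i, s in enumerate(starts):
        arr = doubled[s : s + read_length].copy()
        if error_rate > 0:
            errs = np.nonzero(rng.random(read_length) < error_rate)[0]
            _mutate(arr, errs, rng)
        reads.append(
            CircularGenome(id=f"read{i:06d}_pos{int(s) + 1}", seq=_array_to_seq(arr))
        )
    return reads


def simulate_offtargets(
    reference: CircularGenome, divergence: float, n: int, seed: int
) -> list[CircularGenome]:
    """Off-target species as heavily substituted copies of the reference.

    Each position mutates independently with probability ``divergence`` to
    a uniform non-reference base; the nominal divergence is recorded in the
    record id.
    """
    if not 0.0 < divergence < 0.75:
        raise ValueError("divergence must be in (0, 0.75)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ref_arr = _seq_to_array(reference.seq)
    out = []
    for i in range(n):
        arr = ref_arr.copy()
        hit = np.nonzero(rng.random(len(arr)) < divergence)[0]
        _mutate(arr, hit, rng)
        out.append(
            CircularGenome(
                id=f"offtarget{i + 1}_div{divergence:.3f}",
                seq=_array_to_seq(arr),
                circular=True,
            )
        )
    return out


def simulate_amplicon_survey(
    clade_haplotypes: Mapping[str, str],
    region_presence: Mapping[str, Sequence[str]],
    n_sites_per_region: int,
    amplicons_per_positive_site: int,
    seq_error_rate: float,
    seed: int,
) -> tuple[list[CircularGenome], pd.DataFrame]:
    """Presence/absence amplicon survey across named regions.

    A site is positive iff its region hosts at least one clade; each
    positive site emits amplicons drawn uniformly from the present clades'
    haplotypes with per-base substitution error.  Returns the amplicons and
    a metadata table (amplicon, site, region, true_clade).
    """
    if not clade_haplotypes:
        raise ValueError("clade_haplotypes must not be empty")
    for region, clades in region_presence.items():
        for c in clades:
            if c not in clade_haplotypes:
                raise ValueError(f"region {region!r} lists unknown clade {c!r}")
    rng = np.random.default_rng(seed)
    amplicons: list[CircularGenome] = []
    rows = []
    for region in region_presence:
        present = sorted(region_presence[region])
        slug = region.replace(" ", "_")
        for s in range(1, n_sites_per_region + 1):
            site = f"{slug}_site{s}"
            if not present:
                continue
            for a in range(1, amplicons_per_positive_site + 1):
                clade = present[rng.integers(0, len(present))]
                arr = _seq_to_array(clade_haplotypes[clade]).copy()
                if seq_error_rate > 0:
                    errs = np.nonzero(rng.random(len(arr)) < seq_error_rate)[0]
                    _mutate(arr, errs, rng)
                amp_id = f"{site}_amp{a}"
                amplicons.append(CircularGenome(id=amp_id, seq=_array_to_seq(arr)))
                rows.append(
                    {
                        "amplicon": amp_id,
                        "site": site,
                        "region": region,
                        "true_clade": clade,
                    }
                )
    meta = pd.DataFrame(rows, columns=["amplicon", "site", "region", "true_clade"])
    return amplicons, meta
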