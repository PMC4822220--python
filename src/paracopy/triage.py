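"""Evidence statistics for triaging candidate variants at conserved positions.

Variant callers run against a single-gene reference raise candidate SNPs
that, for a single-organism sample over a multi-copy gene, are very often
artifacts.  This module computes the per-position evidence behind the
classical false-positive categories so candidates can be flagged and
reviewed:

* strand bias — phred-scaled Fisher exact test (FS) on the 2x2 table of
  (reference, alternate) x (forward, reverse) read counts;
* end of read — fraction of alternate-allele observations lying within a
  few bases of a read end, where base quality degrades;
* homopolymer — length of the maximal single-nucleotide run in the
  reference containing or adjacent to the position;
* non-target region — position inside an interval not targeted by the PCR
  primers (amplicons truncated by a single primer still produce reads
  there);
* end of reference — position within a few bases of the reference ends,
  where improper read trimming piles up mismatches.

Contaminant identification (reads from another organism) requires an
external database search and is not computed here; an externally supplied
annotation can be carried through the report.

The flag thresholds are pragmatic defaults, configurable per run; they are
screening aids, not calibrated significance levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy import stats

from .observations import SiteObservation

__all__ = ["TriageConfig", "TriageReport", "fisher_strand_bias", "triage_position"]


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds and context for triage flags."""

    fs_threshold: float = 60.0  # phred-scaled Fisher strand bias
    end_of_read_fraction_threshold: float = 0.9
    homopolymer_min_run: int = 4
    end_of_reference_bp: int = 2
    target_intervals: tuple[tuple[int, int], ...] = ()  # 1-based inclusive
    # intervals explicitly known to be untargeted; used in addition to the
    # complement of target_intervals when provided
    non_target_intervals: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class TriageReport:
    """Computed evidence for one candidate variant position."""

    position: int
    ref_allele: str
    alt_allele: str
    fs: float
    end_of_read_fraction: float
    homopolymer_run: int
    in_non_target_region: bool
    at_end_of_reference: bool
    flags: frozenset[str] = field(default_factory=frozenset)
    contaminant_annotation: str | None = None


def fisher_strand_bias(table: Sequence[Sequence[int]]) -> float:
    """Phred-scaled two-sided Fisher exact test on a 2x2 strand table.

    ``table`` is ((ref_fwd, ref_rev), (alt_fwd, alt_rev)).  The two-sided
    p-value sums all tables with point probability at most the observed
    table's (the standard convention); FS = -10·log10(p), 0 when p = 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    p = min(max(float(p), 5e-324), 1.0)
    return 0.0 if p >= 1.0 else -10.0 * math.log10(p)


def homopolymer_run(reference: str, position: int) -> int:
    """Longest single-base run containing or adjacent to a 1-based position."""
    if not 1 <= position <= len(reference):
        raise ValueError(f"position {position} outside reference")
    seq = reference.upper()
    best = 0
    # runs through the position itself and through its two neighbours
    for anchor in (position - 2, position - 1, position):
        if not 0 <= anchor < len(seq):
            continue
        base = seq[anchor]
        lo = anchor
        while lo > 0 and seq[lo - 1] == base:
            lo -= 1
        hi = anchor
        while hi + 1 < len(seq) and seq[hi + 1] == base:
            hi += 1
        best = max(best, hi - lo + 1)
    return best


def _in_intervals(position: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(lo <= position <= hi for lo, hi in intervals)


def triage_position(
    obs: SiteObservation,
    reference_sequence: str,
    config: TriageConfig | None = None,
    ref_allele: str | None = None,
    alt_allele: str | None = None,
    contaminant_annotation: str | None = None,
) -> TriageReport:
    """Compute all triage statistics and flags for one candidate position.

    The reference allele defaults to the reference base at the position;
    the alternate defaults to the most abundant non-reference base observed.
    """
    config = config or TriageConfig()
    pos = obs.position
    if not 1 <= pos <= len(reference_sequence):
        raise ValueError(f"position {pos} outside reference")
    if ref_allele is None:
        ref_allele = reference_sequence[pos - 1].upper()
    if alt_allele is None:
        others = [(obs.allele_count(b), b) for b in "ACGT" if b != ref_allele]
        alt_allele = max(others)[1]

    ref_f, ref_r = obs.strand_counts(ref_allele)
    alt_f, alt_r = obs.strand_counts(alt_allele)
    if ref_f + ref_r + alt_f + alt_r > 0:
        fs = fisher_strand_bias(((ref_f, ref_r), (alt_f, alt_r)))
    else:
        fs = 0.0

    alt_total = alt_f + alt_r
    end_fraction = obs.end_counts[alt_allele] / alt_total if alt_total else 0.0

    run = homopolymer_run(reference_sequence, pos)

    if config.non_target_intervals:
        non_target = _in_intervals(pos, config.non_target_intervals)
    elif config.target_intervals:
        non_target = not _in_intervals(pos, config.target_intervals)
    else:
        non_target = False

    ref_len = len(reference_sequence)
    at_end = pos <= config.end_of_reference_bp or pos > ref_len - config.end_of_reference_bp

    flags = set()
    if fs > config.fs_threshold:
        flags.add("strand_bias")
    if alt_total and end_fraction > config.end_of_read_fraction_threshold:
        flags.add("end_of_read")
    if run >= config.homopolymer_min_run:
        flags.add("homopolymer")
    if non_target:
        flags.add("non_target_region")
    if at_end:
        flags.add("end_of_reference")

    return TriageReport(
        position=pos,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        fs=fs,
        end_of_read_fraction=end_fraction,
        homopolymer_run=run,
        in_non_target_region=non_target,
        at_end_of_reference=at_end,
        flags=frozenset(flags),
        contaminant_annotation=contaminant_annotation,
    )
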