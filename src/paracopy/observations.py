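"""Extract per-site allele observations and per-read variant combinations.

Input is an alignment of reads against the single-gene reference (SAM/BAM
via pysam, or already-opened records), or pre-tabulated count tables.  Two
products feed the downstream inference:

* :class:`SiteObservation` — per-position, per-allele, per-strand counts
  (the observed variant proportions are computed from these);
* :class:`CombinationCounts` — tallies of the variant combination each read
  carries across a window of variable sites.  A read contributes a
  combination only if it spans *all* sites in the window with a confident,
  non-deleted base call at each; reads carrying a base matching neither
  site allele at any window site are rejected outright (third alleles at
  variable positions are treated as sequencing error upstream of the
  chimera-aware likelihood).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .model import CANONICAL_BASES, VariableSite

__all__ = [
    "PileupFilters",
    "SiteObservation",
    "CombinationCounts",
    "build_pileup",
    "observed_variant_proportion",
    "extract_combinations",
]


@dataclass(frozen=True)
class PileupFilters:
    """Read/base filters applied during extraction.

    Quality thresholds apply only where the records carry qualities
    (Sanger clone consensus input may not; missing qualities pass).
    ``end_window`` is the distance (bp) from either aligned read end within
    which a base is counted as end-of-read.
    """

    min_mapping_quality: int = 20
    min_base_quality: int = 20
    skip_duplicates: bool = False
    skip_secondary: bool = True
    end_window: int = 5


@dataclass
class SiteObservation:
    """Per-allele, per-strand read counts at one reference position."""

    position: int  # 1-based
    counts: dict[str, list[int]] = field(
        default_factory=lambda: {b: [0, 0] for b in "ACGT"}
    )  # base -> [forward, reverse]
    end_counts: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in "ACGT"}
    )  # base -> observations within end_window of a read end

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.counts.values())

    @property
    def end_of_read_count(self) -> int:
        return sum(self.end_counts.values())

    def allele_count(self, base: str) -> int:
        f, r = self.counts[base]
        return f + r

    def strand_counts(self, base: str) -> tuple[int, int]:
        f, r = self.counts[base]
        return f, r


@dataclass
class CombinationCounts:
    """Observed read variant-combination tallies over a site window."""

    window: tuple[int, ...]  # 0-based indices into the site list
    counts: dict[str, int] = field(default_factory=dict)
    rejected: int = 0  # spanned all sites but carried a non-allele base
    non_spanning: int = 0  # overlapped the window span without covering all sites

    def __post_init__(self) -> None:
        v = len(self.window)
        for combo, n in self.counts.items():
            if len(combo) != v:
                raise ValueError(
                    f"combination {combo!r} length != window size {v}"
                )
            if n < 0:
                raise ValueError("negative count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ----------------------------------------------------------------------
# alignment input handling


def _iter_alignments(
    alignments,
    reference_name: str | None = None,
) -> Iterable[pysam.AlignedSegment]:
    """Yield mapped records from a path, AlignmentFile, or record iterable."""
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as handle:
            _check_single_reference(handle, reference_name)
            yield from (r for r in handle if not r.is_unmapped)
        return
    if isinstance(alignments, pysam.AlignmentFile):
        _check_single_reference(alignments, reference_name)
        yield from (r for r in alignments if not r.is_unmapped)
        return
    for record in alignments:
        if record.is_unmapped:
            continue
        if reference_name is not None and record.reference_name not in (
            None,
            reference_name,
        ):
            raise ValueError(
                f"record mapped to {record.reference_name!r}, "
                f"expected {reference_name!r}"
            )
        yield record


def _check_single_reference(handle: pysam.AlignmentFile, expected: str | None) -> None:
    names = list(handle.references)
    if len(names) != 1:
        raise ValueError(
            f"alignments must target a single-gene reference; header lists "
            f"{len(names)} references {names[:5]}"
        )
    if expected is not None and names[0] != expected:
        raise ValueError(f"reference {names[0]!r} != expected {expected!r}")


def _passes_read_filters(read: pysam.AlignedSegment, filters: PileupFilters) -> bool:
    if filters.skip_secondary and (read.is_secondary or read.is_supplementary):
        return False
    if filters.skip_duplicates and read.is_duplicate:
        return False
    mapq = read.mapping_quality
    # 255 means "unavailable" in the SAM spec
    if mapq != 255 and mapq < filters.min_mapping_quality:
        return False
    return True


def _site_calls(
    read: pysam.AlignedSegment,
    wanted: dict[int, int],
    filters: PileupFilters,
):
    """Base calls of one read at the wanted reference positions.

    ``wanted`` maps 0-based reference position -> site index.  Yields
    ``(site_index, base or None, near_end)``; ``base is None`` marks a
    deletion, an ambiguous call, or a base-quality failure at that site.
    """
    seq = read.query_sequence
    quals = read.query_qualities
    qstart = read.query_alignment_start
    qend = read.query_alignment_end  # exclusive
    for qpos, rpos in read.get_aligned_pairs():
        if rpos is None or rpos not in wanted:
            continue
        idx = wanted[rpos]
        if qpos is None or seq is None:  # deletion spanning the site
            yield idx, None, False
            continue
        base = seq[qpos].upper()
        if base not in CANONICAL_BASES:
            yield idx, None, False
            continue
        if (
            quals is not None
            and len(quals) == len(seq)
            and quals[qpos] < filters.min_base_quality
        ):
            yield idx, None, False
            continue
        near_end = min(qpos - qstart, qend - 1 - qpos) < filters.end_window
        yield idx, base, near_end


def build_pileup(
    alignments,
    sites: Sequence[VariableSite],
    filters: PileupFilters | None = None,
    reference_name: str | None = None,
) -> list[SiteObservation]:
    """Tally per-allele, per-strand counts at each variable site.

    Reads failing mapping-quality filters are skipped entirely; at a given
    site, deletions, ambiguous bases, and base-quality failures drop the
    read from that site's counts (and depth) only.
    """
    filters = filters or PileupFilters()
    wanted = {s.position - 1: i for i, s in enumerate(sites)}
    obs = [SiteObservation(position=s.position) for s in sites]
    for read in _iter_alignments(alignments, reference_name):
        if not _passes_read_filters(read, filters):
            continue
        strand = 1 if read.is_reverse else 0
        for idx, base, near_end in _site_calls(read, wanted, filters):
            if base is None:
                continue
            obs[idx].counts[base][strand] += 1
            if near_end:
                obs[idx].end_counts[base] += 1
    return obs


def observed_variant_proportion(
    obs: SiteObservation, site: VariableSite
) -> tuple[int, int]:
    """(x, n): count of the more abundant site allele and the two-allele total.

    Bases other than the site's two alleles are excluded from ``n`` (treated
    as sequencing error).  Raises ``ValueError`` when no informative reads
    cover the site.
    """
    a = obs.allele_count(site.major_allele)
    b = obs.allele_count(site.minor_allele)
    n = a + b
    if n == 0:
        raise ValueError(
            f"no reads carrying either allele at position {obs.position}"
        )
    return max(a, b), n


def extract_combinations(
    alignments,
    sites: Sequence[VariableSite],
    window: Sequence[int] | None = None,
    filters: PileupFilters | None = None,
    reference_name: str | None = None,
) -> CombinationCounts:
    """Tally the variant combination of every read spanning a site window.

    ``window`` holds 0-based indices into ``sites`` (default: all sites).
    Only reads whose alignment yields a confident, non-deleted, canonical
    base call at *every* window site contribute; each such read contributes
    exactly one combination string.  A confident call matching neither site
    allele rejects the whole read (``rejected``); reads overlapping the
    window span without a confident call at every site are counted as
    ``non_spanning``.
    """
    filters = filters or PileupFilters()
    if window is None:
        window = list(range(len(sites)))
    else:
        window = list(window)
    if not window:
        raise ValueError("window must be nonempty")
    if sorted(set(window)) != window:
        raise ValueError("window indices must be strictly increasing and unique")
    wsites = [sites[i] for i in window]
    wanted = {s.position - 1: j for j, s in enumerate(wsites)}
    span_lo = wsites[0].position - 1  # 0-based inclusive
    span_hi = wsites[-1].position  # 0-based exclusive

    result = CombinationCounts(window=tuple(window))
    for read in _iter_alignments(alignments, reference_name):
        if not _passes_read_filters(read, filters):
            continue
        if read.reference_start >= span_hi or read.reference_end <= span_lo:
            continue  # does not overlap the window span at all
        calls: dict[int, str] = {}
        confident = True
        for j, base, _near_end in _site_calls(read, wanted, filters):
            if base is None:
                confident = False
            else:
                calls[j] = base
        if not confident or len(calls) < len(wsites):
            result.non_spanning += 1
            continue
        if any(calls[j] not in wsites[j].alleles for j in range(len(wsites))):
            result.rejected += 1
            continue
        combo = "".join(calls[j] for j in range(len(wsites)))
        result.counts[combo] = result.counts.get(combo, 0) + 1
    return result


# ----------------------------------------------------------------------
# TSV interchange (tab-separated, header row, '.' for missing)


def site_observations_to_tsv(
    observations: Sequence[SiteObservation], path: str | Path | None = None
) -> str:
    lines = ["position\tallele\tstrand\tcount\tend_count"]
    for obs in observations:
        for base in "ACGT":
            f, r = obs.counts[base]
            end = obs.end_counts[base]
            for strand, n in (("+", f), ("-", r)):
                if n == 0:
                    continue
                # end counts are not stranded; attach to '+' row
                e = end if strand == "+" else 0
                lines.append(f"{obs.position}\t{base}\t{strand}\t{n}\t{e}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def site_observations_from_tsv(source: str | Path) -> list[SiteObservation]:
    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    table: dict[int, SiteObservation] = {}
    handle = io.StringIO(text)
    header = handle.readline().rstrip("\n").split("\t")
    idx = {name: i for i, name in enumerate(header)}
    for name in ("position", "allele", "strand", "count"):
        if name not in idx:
            raise ValueError(f"pileup TSV missing column {name!r}")
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        pos = int(fields[idx["position"]])
        base = fields[idx["allele"]].upper()
        strand = fields[idx["strand"]]
        count = int(fields[idx["count"]])
        end = 0
        if "end_count" in idx and fields[idx["end_count"]] not in (".", ""):
            end = int(fields[idx["end_count"]])
        obs = table.setdefault(pos, SiteObservation(position=pos))
        obs.counts[base][0 if strand == "+" else 1] += count
        obs.end_counts[base] += end
    return [table[p] for p in sorted(table)]


def combination_counts_to_tsv(
    cc: CombinationCounts, path: str | Path | None = None
) -> str:
    lines = [
        f"#window={','.join(str(i) for i in cc.window)}",
        f"#rejected={cc.rejected}",
        f"#non_spanning={cc.non_spanning}",
        "combination\tcount",
    ]
    for combo in sorted(cc.counts):
        lines.append(f"{combo}\t{cc.counts[combo]}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def combination_counts_from_tsv(source: str | Path) -> CombinationCounts:
    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    window: tuple[int, ...] | None = None
    rejected = 0
    non_spanning = 0
    counts: dict[str, int] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key == "window":
                window = tuple(int(i) for i in value.split(",") if i)
            elif key == "rejected":
                rejected = int(value)
            elif key == "non_spanning":
                non_spanning = int(value)
            continue
        if line.startswith("combination\t"):
            continue
        combo, _, n = line.partition("\t")
        counts[combo] = counts.get(combo, 0) + int(n)
    if window is None:
        length = len(next(iter(counts), ""))
        window = tuple(range(length))
    return CombinationCounts(
        window=window, counts=counts, rejected=rejected, non_spanning=non_spanning
    )
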