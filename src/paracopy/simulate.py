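"""Seeded read and count simulator for multi-copy gene inference.

Generates data with exactly the statistical structure the estimators
assume: reads drawn uniformly from k paralogous copies, i.i.d. per-base
substitution error, and PCR chimera events formed from two parent copies
with a single breakpoint between consecutive variable sites.  Alignments
are emitted with true coordinates (perfect mapping), isolating the
inference from mapper behaviour.

Read-length presets approximate common platform profiles for a ~1.5 kb
amplicon target; they are presets, not instrument claims:

* ``shotgun-short`` — ~170 bp reads, tens of thousands of them, no
  chimeras (fragment libraries; reads rarely span several variable sites);
* ``amplicon-454`` — ~535 bp amplicon reads, thousands, chimera-prone;
* ``sanger-clone`` — ~850 bp clone consensus reads, tens of them,
  low error, chimera-prone (chimeras form during the pre-cloning PCR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .model import ParalogueSet, VariableSite, make_paralogue_set
from .observations import CombinationCounts, SiteObservation

__all__ = [
    "SimulationConfig",
    "SimulatedReads",
    "PRESETS",
    "simulate_reads",
    "simulate_counts",
    "demo_paralogue_set",
    "random_paralogue_set",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

PRESETS: dict[str, dict] = {
    "shotgun-short": dict(
        read_length=(170, 40, 330), n_reads=20_000, per_base_error=0.005,
        chimera_rate=0.0,
    ),
    "amplicon-454": dict(
        read_length=(535, 450, 620), n_reads=15_000, per_base_error=0.005,
        chimera_rate=0.03,
    ),
    "sanger-clone": dict(
        read_length=(850, 500, 1100), n_reads=90, per_base_error=0.001,
        chimera_rate=0.03,
    ),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    ``read_length`` is either a fixed integer or a (mean, min, max) triple;
    triples draw truncated-normal lengths with sd = (max - min)/6.
    ``strand_bias`` is the probability a read is forward-strand.
    """

    paralogue_set: ParalogueSet
    n_reads: int
    read_length: int | tuple[int, int, int]
    per_base_error: float = 0.0
    chimera_rate: float = 0.0
    strand_bias: float = 0.5
    seed: int = 0
    reference_name: str = "gene"
    breakpoint_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        for name in ("per_base_error", "chimera_rate", "strand_bias"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.chimera_rate > 0 and self.paralogue_set.n_sites < 2:
            raise ValueError("chimeras need at least 2 variable sites")
        L = self.paralogue_set.gene_length
        lengths = (
            (self.read_length,) if isinstance(self.read_length, int)
            else self.read_length
        )
        if max(lengths) > L:
            raise ValueError(
                f"read length {max(lengths)} exceeds gene length {L}"
            )
        if min(lengths) < 1:
            raise ValueError("read length must be >= 1")

    @classmethod
    def from_preset(
        cls, name: str, paralogue_set: ParalogueSet, seed: int = 0, **overrides
    ) -> "SimulationConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        params = {**PRESETS[name], **overrides}
        # clip preset lengths to the gene
        L = paralogue_set.gene_length
        rl = params["read_length"]
        if not isinstance(rl, int):
            mean, lo, hi = rl
            params["read_length"] = (min(mean, L), min(lo, L), min(hi, L))
        return cls(paralogue_set=paralogue_set, seed=seed, **params)


@dataclass
class SimulatedReads:
    """Reads plus per-read provenance from one simulation."""

    config: SimulationConfig
    names: list[str]
    sequences: list[str]  # reference-orientation (aligned) sequence
    starts: list[int]  # 0-based reference start
    is_reverse: list[bool]
    truth: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.names)

    # ------------------------------------------------------------------
    def _header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [
                    {
                        "SN": self.config.reference_name,
                        "LN": self.config.paralogue_set.gene_length,
                    }
                ],
            }
        )

    def to_alignments(self) -> list[pysam.AlignedSegment]:
        """In-memory SAM records (perfect, full-match alignments)."""
        header = self._header()
        records = []
        for name, seq, start, rev in zip(
            self.names, self.sequences, self.starts, self.is_reverse
        ):
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.query_sequence = seq
            a.flag = 16 if rev else 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = [(0, len(seq))]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            records.append(a)
        return records

    def write_sam(self, path: str | Path) -> None:
        with pysam.AlignmentFile(str(path), "w", header=self._header()) as out:
            for record in self.to_alignments():
                out.write(record)

    def write_fastq(self, path: str | Path) -> None:
        """Reads as sequenced (reverse-strand reads reverse-complemented)."""
        with open(path, "w") as out:
            for name, seq, rev in zip(self.names, self.sequences, self.is_reverse):
                read = seq.translate(_COMPLEMENT)[::-1] if rev else seq
                out.write(f"@{name}\n{read}\n+\n{'I' * len(read)}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _draw_lengths(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.read_length, int):
        return np.full(config.n_reads, config.read_length, dtype=int)
    mean, lo, hi = config.read_length
    sd = max((hi - lo) / 6.0, 1e-9)
    lengths = rng.normal(mean, sd, size=config.n_reads)
    return np.clip(np.rint(lengths), lo, hi).astype(int)


def _draw_sources(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(is_chimera, parent1, parent2, gap) per read; non-chimera parent2 = parent1."""
    ps = config.paralogue_set
    n = config.n_reads
    is_chimera = rng.random(n) < config.chimera_rate
    parent1 = rng.integers(0, ps.k, size=n)
    parent2 = parent1.copy()
    gap = np.full(n, -1)
    idx = np.nonzero(is_chimera)[0]
    if idx.size:
        parent2[idx] = rng.integers(0, ps.k, size=idx.size)
        n_gaps = ps.n_sites - 1
        if config.breakpoint_weights is None:
            gap[idx] = rng.integers(0, n_gaps, size=idx.size)
        else:
            w = np.asarray(config.breakpoint_weights, float)
            w = w / w.sum()
            gap[idx] = rng.choice(n_gaps, size=idx.size, p=w)
    return is_chimera, parent1, parent2, gap


def simulate_reads(config: SimulationConfig) -> SimulatedReads:
    """Draw reads from the paralogue set; fully reproducible from the seed.

    Chimeric reads take a base-level crossover uniformly inside the chosen
    inter-site gap, so the left site keeps parent 1's symbol and the right
    site takes parent 2's.  Substitution errors are i.i.d. per base.
    """
    ps = config.paralogue_set
    if ps.reference_sequence is None:
        raise ValueError("simulation requires a reference_sequence")
    rng = np.random.default_rng(config.seed)
    full = [np.frombuffer(s.encode(), dtype="S1").astype("U1")
            for s in ps.render_full_sequences()]
    site_pos0 = np.array([s.position - 1 for s in ps.sites])

    lengths = _draw_lengths(config, rng)
    is_chimera, parent1, parent2, gap = _draw_sources(config, rng)
    starts = np.array(
        [rng.integers(0, ps.gene_length - ln + 1) for ln in lengths]
    )
    forward = rng.random(config.n_reads) < config.strand_bias

    names, seqs = [], []
    truth_rows = []
    for i in range(config.n_reads):
        ln, start = int(lengths[i]), int(starts[i])
        if is_chimera[i]:
            g = int(gap[i])
            lo, hi = site_pos0[g], site_pos0[g + 1]
            crossover = int(rng.integers(lo + 1, hi + 1))  # p2 takes >= crossover
            template = np.concatenate(
                [full[parent1[i]][:crossover], full[parent2[i]][crossover:]]
            )
        else:
            crossover = -1
            template = full[parent1[i]]
        read = template[start : start + ln].copy()
        err_mask = rng.random(ln) < config.per_base_error
        err_pos = np.nonzero(err_mask)[0]
        for p in err_pos:
            choices = [b for b in "ACGT" if b != read[p]]
            read[p] = choices[rng.integers(0, 3)]
        name = f"read_{i:06d}"
        names.append(name)
        seqs.append("".join(read))
        truth_rows.append(
            {
                "read": name,
                "source": "chimera" if is_chimera[i] else "copy",
                "parent1": int(parent1[i]),
                "parent2": int(parent2[i]) if is_chimera[i] else int(parent1[i]),
                "gap": int(gap[i]),
                "crossover_position": crossover + 1 if crossover >= 0 else 0,
                "start": start + 1,
                "length": ln,
                "strand": "+" if forward[i] else "-",
                "error_positions": ",".join(
                    str(start + int(p) + 1) for p in err_pos
                ),
            }
        )

    return SimulatedReads(
        config=config,
        names=names,
        sequences=seqs,
        starts=[int(s) for s in starts],
        is_reverse=[not f for f in forward],
        truth=pd.DataFrame(truth_rows),
    )


def simulate_counts(
    config: SimulationConfig,
) -> tuple[list[SiteObservation], CombinationCounts]:
    """Fast path: draw per-site observations and combination counts directly.

    Equivalent to simulating full-length reads and extracting, without
    synthesizing sequence: every read covers every variable site.  Errors
    at variable sites replace the base with one of the other three bases
    uniformly; a read with a base matching neither site allele at any site
    is rejected from combination counting (but its calls still enter the
    per-site observations), mirroring the extraction rules.
    """
    ps = config.paralogue_set
    rng = np.random.default_rng(config.seed)
    v = ps.n_sites
    combos = np.array(
        [[c[j] for j in range(v)] for c in ps.copies], dtype="U1"
    )  # k x v
    is_chimera, parent1, parent2, gap = _draw_sources(config, rng)
    n = config.n_reads

    read_bases = combos[parent1].copy()  # n x v
    idx = np.nonzero(is_chimera)[0]
    for i in idx:
        g = gap[i]
        read_bases[i, g + 1 :] = combos[parent2[i], g + 1 :]

    err_mask = rng.random((n, v)) < config.per_base_error
    if err_mask.any():
        base_to_int = {b: t for t, b in enumerate("ACGT")}
        ints = np.vectorize(base_to_int.get)(read_bases)
        shift = rng.integers(1, 4, size=(n, v))
        ints = np.where(err_mask, (ints + shift) % 4, ints)
        read_bases = _BASES[ints]

    forward = rng.random(n) < config.strand_bias

    observations = []
    for j, site in enumerate(ps.sites):
        obs = SiteObservation(position=site.position)
        for base in "ACGT":
            sel = read_bases[:, j] == base
            obs.counts[base][0] = int(np.sum(sel & forward))
            obs.counts[base][1] = int(np.sum(sel & ~forward))
        observations.append(obs)

    allele_ok = np.ones(n, dtype=bool)
    for j, site in enumerate(ps.sites):
        allele_ok &= np.isin(read_bases[:, j], list(site.alleles))
    counts: dict[str, int] = {}
    for row in np.nonzero(allele_ok)[0]:
        s = "".join(read_bases[row])
        counts[s] = counts.get(s, 0) + 1
    cc = CombinationCounts(
        window=tuple(range(v)),
        counts=counts,
        rejected=int(n - allele_ok.sum()),
        non_spanning=0,
    )
    return observations, cc


# ----------------------------------------------------------------------
# convenience builders


def random_paralogue_set(
    k: int,
    n_sites: int,
    gene_length: int,
    seed: int = 0,
    min_gap: int = 20,
) -> ParalogueSet:
    """A random but valid paralogue set with a random reference sequence."""
    rng = np.random.default_rng(seed)
    if n_sites * min_gap + 2 * min_gap > gene_length:
        raise ValueError("gene too short for the requested sites and spacing")
    reference = "".join(rng.choice(list("ACGT"), size=gene_length))
    positions = np.sort(
        rng.choice(
            np.arange(min_gap, gene_length - min_gap),
            size=n_sites,
            replace=False,
        )
    )
    while np.any(np.diff(positions) < min_gap):
        positions = np.sort(
            rng.choice(
                np.arange(min_gap, gene_length - min_gap),
                size=n_sites,
                replace=False,
            )
        )
    sites = []
    columns = np.empty((k, n_sites), dtype="U1")
    for j, pos0 in enumerate(positions):
        major, minor = rng.choice(list("ACGT"), size=2, replace=False)
        # at least one minor copy, at most k-1
        n_minor = int(rng.integers(1, k))
        col = np.array([minor] * n_minor + [major] * (k - n_minor))
        rng.shuffle(col)
        columns[:, j] = col
        sites.append(VariableSite(int(pos0) + 1, str(major), str(minor)))
        reference = reference[: int(pos0)] + str(major) + reference[int(pos0) + 1 :]
    copies = ["".join(columns[i]) for i in range(k)]
    return make_paralogue_set(copies, sites, gene_length, reference)


def demo_paralogue_set(seed: int = 0) -> ParalogueSet:
    """A six-copy, three-site gene model shaped like a small 16S copy set.

    Site ratios are 5:1, 5:1, 5:1 and the combination multiset has a
    triple-multiplicity majority combination — a compact stand-in for a
    small bacterial 16S paralogue family.
    """
    gene_length = 300
    rng = np.random.default_rng(seed)
    ref = list(rng.choice(list("ACGT"), size=gene_length))
    sites = (
        VariableSite(60, "A", "G"),
        VariableSite(150, "A", "G"),
        VariableSite(240, "A", "C"),
    )
    for s in sites:
        ref[s.position - 1] = s.major_allele
    copies = ["AAA", "AAA", "AAA", "GAA", "AGA", "AAC"]
    return make_paralogue_set(copies, sites, gene_length, "".join(ref))
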