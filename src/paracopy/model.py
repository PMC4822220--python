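"""Data model for a multi-copy gene.

A single gene (for instance the ~1.5 kb 16S rRNA gene) is present in *k*
paralogous copies within one genome.  The copies are identical except at a
small number of *biologically variable positions*, each of which carries
exactly two nucleotides across the copy set.  The string of nucleotides a
copy (or a read) carries across the variable positions, in ascending
position order, is its *variant combination*; the multiset of the k
combinations is the *gene copy variant combination set*, the quantity the
downstream inference estimates.

Coordinates are 1-based inclusive throughout the object model; file
interchange (BED) converts explicitly.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CANONICAL_BASES",
    "VariableSite",
    "VariantCopyRatio",
    "ParalogueSet",
    "make_paralogue_set",
    "site_ratio",
]

CANONICAL_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class VariableSite:
    """A biologically variable position with its two observed alleles.

    ``major_allele``/``minor_allele`` name the two nucleotides seen across
    the gene copies; the labels carry no frequency claim at construction
    (the actual split is a property of a :class:`ParalogueSet`).
    """

    position: int  # 1-based coordinate on the gene reference
    major_allele: str
    minor_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for allele in (self.major_allele, self.minor_allele):
            if allele not in CANONICAL_BASES:
                raise ValueError(f"allele must be one of A/C/G/T, got {allele!r}")
        if self.major_allele == self.minor_allele:
            raise ValueError("the two alleles of a variable site must differ")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.major_allele, self.minor_allele)


@dataclass(frozen=True)
class VariantCopyRatio:
    """Unordered split M:m of gene copies between the two alleles (M >= m)."""

    major_count: int
    minor_count: int

    def __post_init__(self) -> None:
        if not (self.major_count >= self.minor_count >= 1):
            raise ValueError(
                f"require M >= m >= 1, got {self.major_count}:{self.minor_count}"
            )

    @property
    def k(self) -> int:
        return self.major_count + self.minor_count

    def proportion(self) -> float:
        """Variant proportion M/(M+m) of the more abundant allele."""
        return self.major_count / self.k

    def __str__(self) -> str:  # "6:1"
        return f"{self.major_count}:{self.minor_count}"

    @classmethod
    def from_counts(cls, a: int, b: int) -> "VariantCopyRatio":
        return cls(max(a, b), min(a, b))

    @classmethod
    def parse(cls, text: str) -> "VariantCopyRatio":
        try:
            a, b = (int(part) for part in text.split(":"))
        except ValueError as exc:
            raise ValueError(f"cannot parse ratio {text!r}; expected 'M:m'") from exc
        return cls.from_counts(a, b)


@dataclass(frozen=True)
class ParalogueSet:
    """The k copies of a gene, described by their variant combinations.

    ``copies`` is a multiset (stored sorted): two copies may carry the same
    combination.  Every listed site must actually be variable across the
    copies, i.e. both of its alleles occur; a position where all copies
    agree is biologically conserved and has no place in the model.
    """

    gene_length: int
    sites: tuple[VariableSite, ...]
    copies: tuple[str, ...]
    reference_sequence: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.gene_length < 1:
            raise ValueError("gene_length must be positive")
        if len(self.copies) < 2:
            raise ValueError(
                "a paralogue set needs k >= 2 copies; single-copy genes have "
                "no variable positions to analyse"
            )
        positions = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("sites must be strictly increasing by position")
        if positions and positions[-1] > self.gene_length:
            raise ValueError("site position beyond gene length")
        v = len(self.sites)
        for combo in self.copies:
            if len(combo) != v:
                raise ValueError(
                    f"combination {combo!r} has length {len(combo)}, "
                    f"expected one symbol per site ({v})"
                )
        for i, site in enumerate(self.sites):
            column = {c[i] for c in self.copies}
            bad = column - set(site.alleles)
            if bad:
                raise ValueError(
                    f"site {site.position}: symbol(s) {sorted(bad)} outside "
                    f"allele pair {site.alleles}"
                )
            if len(column) < 2:
                raise ValueError(
                    f"site {site.position} is not variable: all copies carry "
                    f"{column.pop()!r}"
                )
        if self.reference_sequence is not None:
            if len(self.reference_sequence) != self.gene_length:
                raise ValueError("reference_sequence length != gene_length")
            for site in self.sites:
                ref_base = self.reference_sequence[site.position - 1].upper()
                if ref_base not in site.alleles:
                    raise ValueError(
                        f"reference base {ref_base!r} at position "
                        f"{site.position} is neither site allele"
                    )
        # canonical multiset order
        object.__setattr__(self, "copies", tuple(sorted(self.copies)))

    # ------------------------------------------------------------------
    @property
    def k(self) -> int:
        """Gene copy number."""
        return len(self.copies)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def copy_multiplicities(self) -> Counter:
        return Counter(self.copies)

    def site_ratio(self, site_index: int) -> VariantCopyRatio:
        """Variant copy ratio M:m at one variable site (0-based index)."""
        site = self.sites[site_index]  # IndexError propagates
        column = [c[site_index] for c in self.copies]
        n_major = sum(1 for b in column if b == site.major_allele)
        return VariantCopyRatio.from_counts(n_major, self.k - n_major)

    def restrict(self, window: Sequence[int]) -> "ParalogueSet":
        """Project the copy set onto a subset of site indices (0-based).

        The result keeps only windows' sites and the corresponding symbols;
        sites that become non-variable under the projection cannot occur
        (every site is variable over the full copy multiset and projection
        does not change columns), so validation is preserved.
        """
        window = list(window)
        if not window:
            raise ValueError("window must be nonempty")
        if sorted(window) != window or len(set(window)) != len(window):
            raise ValueError("window indices must be strictly increasing")
        sites = tuple(self.sites[i] for i in window)
        copies = tuple("".join(c[i] for i in window) for c in self.copies)
        return ParalogueSet(
            gene_length=self.gene_length,
            sites=sites,
            copies=copies,
            reference_sequence=self.reference_sequence,
        )

    # ------------------------------------------------------------------
    # serialization
    def to_dict(self) -> dict:
        return {
            "gene_length": self.gene_length,
            "k": self.k,
            "sites": [
                {
                    "position": s.position,
                    "major_allele": s.major_allele,
                    "minor_allele": s.minor_allele,
                }
                for s in self.sites
            ],
            "copies": list(self.copies),
            "reference_sequence": self.reference_sequence,
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, doc: dict) -> "ParalogueSet":
        sites = tuple(
            VariableSite(s["position"], s["major_allele"], s["minor_allele"])
            for s in doc["sites"]
        )
        ps = cls(
            gene_length=int(doc["gene_length"]),
            sites=sites,
            copies=tuple(doc["copies"]),
            reference_sequence=doc.get("reference_sequence"),
        )
        if "k" in doc and int(doc["k"]) != ps.k:
            raise ValueError(f"declared k={doc['k']} but {ps.k} copies listed")
        return ps

    @classmethod
    def from_json(cls, source: str | Path) -> "ParalogueSet":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def sites_to_bed(self, path: str | Path | None = None, name: str = "gene") -> str:
        """Variable sites as BED (0-based half-open); name field = alleles."""
        lines = [
            f"{name}\t{s.position - 1}\t{s.position}\t"
            f"{s.major_allele}/{s.minor_allele}"
            for s in self.sites
        ]
        text = "\n".join(lines) + ("\n" if lines else "")
        if path is not None:
            Path(path).write_text(text)
        return text

    def render_full_sequences(self) -> list[str]:
        """Full-length sequence of every copy (reference with substitutions)."""
        if self.reference_sequence is None:
            raise ValueError("reference_sequence required to render copies")
        out = []
        for combo in self.copies:
            seq = list(self.reference_sequence)
            for site, base in zip(self.sites, combo):
                seq[site.position - 1] = base
            out.append("".join(seq))
        return out

    def write_copies_fasta(self, path: str | Path, prefix: str = "copy") -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=f"{prefix}_{i + 1}", description="")
            for i, seq in enumerate(self.render_full_sequences())
        ]
        SeqIO.write(records, str(path), "fasta")


def sites_from_bed(source: str | Path) -> tuple[VariableSite, ...]:
    """Parse variable sites from BED; 4th column must be 'X/Y' alleles."""
    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    sites = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"BED line needs 4 columns (chrom,start,end,alleles): {line!r}")
        start, end = int(fields[1]), int(fields[2])
        if end != start + 1:
            raise ValueError(f"variable sites are single positions, got {line!r}")
        major, _, minor = fields[3].partition("/")
        sites.append(VariableSite(start + 1, major, minor))
    return tuple(sorted(sites))


def make_paralogue_set(
    copies: Iterable[str],
    sites: Iterable[VariableSite],
    gene_length: int,
    reference_sequence: str | None = None,
) -> ParalogueSet:
    """Validated constructor for a :class:`ParalogueSet`.

    Raises ``ValueError`` on length mismatches, sites at which all copies
    agree, and symbols outside a site's allele pair.
    """
    return ParalogueSet(
        gene_length=gene_length,
        sites=tuple(sites),
        copies=tuple(copies),
        reference_sequence=reference_sequence,
    )


def site_ratio(ps: ParalogueSet, site_index: int) -> VariantCopyRatio:
    """Variant copy ratio M:m among the copies at one site (0-based index)."""
    return ps.site_ratio(site_index)
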