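"""Core record types shared by every pipeline stage.

A *spacer* is the ~30 nt sequence acquired between two direct repeats of a
CRISPR array.  Spacers are the unit of comparison throughout: each one is
identified by the sample it came from, the ordinal of the CRISPR locus within
that sample, and its position within the array counted 5'->3' starting at 1.
Sequences are always stored in array orientation (5'->3' of the array as
predicted upstream), so downstream alignment never has to consider strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class SpacerRecord:
    """One spacer with its identity and oriented sequence.

    ``start``/``end`` are 1-based inclusive genomic coordinates (GFF3
    convention); ``sequence`` is uppercase and already reverse-complemented
    for loci on the minus strand, i.e. it reads 5'->3' along the array.
    """

    sample_id: str
    locus_num: int
    spacer_num: int
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"{self.spacer_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.spacer_id}: bad strand {self.strand!r}")
        bad = set(self.sequence) - IUPAC_NT
        if not self.sequence or bad:
            raise ValueError(
                f"{self.spacer_id}: sequence contains non-IUPAC characters "
                f"{sorted(bad)}" if bad else f"{self.spacer_id}: empty sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def spacer_id(self) -> str:
        """Dataset-wide unique identity: ``sample|locus<k>|spacer<j>``."""
        return f"{self.sample_id}|locus{self.locus_num}|spacer{self.spacer_num}"


@dataclass
class CrisprLocus:
    """One CRISPR array: an ordered (5'->3') run of spacers."""

    sample_id: str
    locus_num: int
    orientation: str
    spacers: list[SpacerRecord] = field(default_factory=list)

    def validate(self) -> None:
        if not self.spacers:
            raise ValueError(f"{self.sample_id} locus {self.locus_num}: no spacers")
        nums = [s.spacer_num for s in self.spacers]
        if nums != list(range(1, len(nums) + 1)):
            raise ValueError(
                f"{self.sample_id} locus {self.locus_num}: spacer numbers "
                f"{nums} are not consecutive from 1"
            )


@dataclass
class Dataset:
    """All loci of all samples, in stable input order.

    Sample order is the order of first appearance in the input files; it is
    preserved because downstream tie-breaking (UPGMA, custom sort fallback)
    is defined relative to it.
    """

    samples: dict[str, list[CrisprLocus]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.keys())

    def loci(self) -> list[CrisprLocus]:
        return [loc for sample in self.samples.values() for loc in sample]

    def spacers(self) -> list[SpacerRecord]:
        return [sp for loc in self.loci() for sp in loc.spacers]

    def sequences_by_id(self) -> dict[str, str]:
        return {sp.spacer_id: sp.sequence for sp in self.spacers()}

    def add_locus(self, locus: CrisprLocus) -> None:
        locus.validate()
        self.samples.setdefault(locus.sample_id, []).append(locus)

    def validate(self) -> None:
        seen: set[str] = set()
        for locus in self.loci():
            locus.validate()
            for sp in locus.spacers:
                if sp.spacer_id in seen:
                    raise ValueError(f"duplicate spacer identity {sp.spacer_id}")
                seen.add(sp.spacer_id)
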