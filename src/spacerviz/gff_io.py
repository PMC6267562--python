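"""Read CRISPRDetect-style GFF3, round-trip the spacer FASTA, sanity checks.

CRISPRDetect emits one ``repeat_region`` feature per CRISPR array, followed by
its ``direct_repeat`` and spacer children (feature type ``binding_site`` or
``Spacer``).  Spacer sequences normally travel in the feature attributes; as a
fallback they can be sliced from a companion genome FASTA by coordinates.

The dataset-wide spacer FASTA uses one header per spacer:

    sample|locus<k>|spacer<j>|start|end|length|strand

(pipe is reserved, so it must not occur in sample names).  The FASTA is the
manual-curation surface: a user can fix mis-split or mis-numbered spacers in
it and restart the pipeline from the FASTA alone.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass
from os import PathLike

from typing import Mapping, Sequence

import gffutils.iterators
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .records import CrisprLocus, Dataset, SpacerRecord

SPACER_TYPES = {"binding_site", "Spacer"}
_SEQ_ATTR_KEYS = ("sequence", "Sequence", "seq", "Note", "note")
_NT_RE = re.compile(r"^[ACGTUNRYSWKMBDHVacgtunryswkmbdhv]+$")

@dataclass(frozen=True)
class LengthWarning:
    """A spacer whose length deviates more than ``factor``-fold from the
    dataset mean — the signature of repeat/spacer mis-splitting upstream."""

    sample_id: str
    locus_num: int
    spacer_num: int
    length: int
    mean_length: float
    factor: float

    def __str__(self) -> str:
        return (
            f"{self.sample_id} locus {self.locus_num} spacer {self.spacer_num}: "
            f"length {self.length} nt deviates more than {self.factor}x from "
            f"the dataset mean ({self.mean_length:.1f} nt)"
        )

def _attr_sequence(attributes: Mapping[str, list[str]]) -> str | None:
    for key in _SEQ_ATTR_KEYS:
        for value in attributes.get(key, []):
            if _NT_RE.match(value):
                return value.upper()
    return None

def _load_genome(path: str | PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}

def parse_crisprdetect_gff(
    paths: Sequence[str | PathLike],
    genomes: Mapping[str, str | PathLike] | str | PathLike | None = None,
    warnings: list[str] | None = None,
) -> Dataset:
    """Parse one or more CRISPRDetect GFF3 files into a :class:`Dataset`.

    Loci are numbered per sample in file order starting at 1.  Spacers are
    numbered 1..n in 5'->3' array orientation: file order for plus-strand
    arrays, reverse file order for minus-strand arrays, with minus-strand
    sequences reverse-complemented so every stored sequence reads along the
    array.  ``genomes`` (one FASTA path, or a map sample_id -> FASTA) is only
    consulted for spacer features that do not carry their sequence in an
    attribute.
    """
    if not paths:
        raise ValueError("no input files")
    warnings = warnings if warnings is not None else []

    genome_cache: dict[str, dict[str, str]] = {}

    def genome_seq(sample_id: str, start: int, end: int, path: str, line: str) -> str:
        if genomes is None:
            raise ValueError(
                f"{path}: spacer feature {line!r} carries no sequence attribute "
                "and no companion genome FASTA was supplied"
            )
        src = genomes if isinstance(genomes, (str, PathLike)) else genomes.get(sample_id)
        if src is None:
            raise ValueError(f"no genome FASTA for sample {sample_id!r}")
        key = str(src)
        if key not in genome_cache:
            genome_cache[key] = _load_genome(src)
        contigs = genome_cache[key]
        if sample_id not in contigs:
            raise ValueError(f"sequence {sample_id!r} not found in genome {key}")
        return contigs[sample_id][start - 1 : end]

    ds = Dataset()
    for path in paths:
        path = str(path)
        locus_counter: dict[str, int] = {}
        # open locus per seqid: (locus_num, orientation, raw spacer tuples)
        open_loci: dict[str, tuple[int, str, list[tuple[int, int, str, str]]]] = {}

        def close(seqid: str) -> None:
            if seqid not in open_loci:
                return
            locus_num, orientation, raw = open_loci.pop(seqid)
            if not raw:
                warnings.append(
                    f"{path}: {seqid} locus {locus_num} has no spacer features"
                )
                return
            if orientation == "-":
                raw = list(reversed(raw))
            locus = CrisprLocus(seqid, locus_num, orientation)
            for num, (start, end, strand, seq) in enumerate(raw, start=1):
                if strand == "-":
                    seq = reverse_complement(seq)
                locus.spacers.append(
                    SpacerRecord(seqid, locus_num, num, start, end, strand, seq)
                )
            ds.add_locus(locus)
            ds.provenance.setdefault(seqid, path)

        n_features = 0
        try:
            feature_iter = list(gffutils.iterators.DataIterator(path))
        except Exception as exc:  # gffutils names the offending line
            raise ValueError(f"{path}: malformed GFF3 ({exc})") from exc
        for feat in feature_iter:
            n_features += 1
            if feat.featuretype == "repeat_region":
                close(feat.seqid)
                locus_counter[feat.seqid] = locus_counter.get(feat.seqid, 0) + 1
                strand = feat.strand if feat.strand in ("+", "-") else "+"
                open_loci[feat.seqid] = (locus_counter[feat.seqid], strand, [])
            elif feat.featuretype in SPACER_TYPES:
                if feat.seqid not in open_loci:
                    raise ValueError(
                        f"{path}: spacer feature at {feat.seqid}:{feat.start} "
                        "appears before any repeat_region"
                    )
                seq = _attr_sequence(feat.attributes)
                if seq is None:
                    seq = genome_seq(
                        feat.seqid, feat.start, feat.end, path, str(feat).strip()
                    )
                expected = feat.end - feat.start + 1
                if len(seq) != expected:
                    warnings.append(
                        f"{path}: {feat.seqid}:{feat.start}-{feat.end} sequence "
                        f"length {len(seq)} != coordinate span {expected}; "
                        "keeping the sequence"
                    )
                if feat.score not in (".", "", None):
                    try:
                        declared = int(float(feat.score))
                    except ValueError:
                        declared = None
                    if declared is not None and declared != len(seq):
                        warnings.append(
                            f"{path}: {feat.seqid}:{feat.start}-{feat.end} declared "
                            f"length {declared} != sequence length {len(seq)}; "
                            "keeping the sequence"
                        )
                strand = feat.strand if feat.strand in ("+", "-") else "+"
                open_loci[feat.seqid][2].append((feat.start, feat.end, strand, seq))
            # direct_repeat and anything else: parsed but unused
        for seqid in list(open_loci):
            close(seqid)
        if n_features == 0:
            raise ValueError(f"{path}: empty GFF3 file (no features)")

    if not ds.samples:
        raise ValueError("no CRISPR loci found in any input file")
    ds.validate()
    check_locus_counts(ds, warnings)
    return ds

def check_locus_counts(ds: Dataset, warnings: list[str]) -> None:
    """Note when samples carry different numbers of loci — the situation in
    which upstream locus numbering is most often inconsistent and should be
    reviewed manually."""
    counts = {sid: len(loci) for sid, loci in ds.samples.items()}
    if len(set(counts.values())) > 1:
        spread = ", ".join(f"{sid}:{n}" for sid, n in counts.items())
        warnings.append(
            "samples carry differing numbers of CRISPR loci "
            f"({spread}); check locus numbering for consistency"
        )

def check_spacer_lengths(ds: Dataset, factor: float = 1.5) -> list[LengthWarning]:
    """Flag spacers more than ``factor`` times longer or shorter than the
    dataset mean length (strict inequality, so a spacer at exactly
    ``factor * mean`` does not warn)."""
    if factor <= 1:
        raise ValueError("factor must be > 1")
    spacers = ds.spacers()
    if not spacers:
        raise ValueError("empty dataset")
    mean = statistics.fmean(sp.length for sp in spacers)
    out = []
    for sp in spacers:
        if sp.length > factor * mean or sp.length < mean / factor:
            out.append(
                LengthWarning(
                    sp.sample_id, sp.locus_num, sp.spacer_num, sp.length, mean, factor
                )
            )
    return out

def write_spacer_fasta(ds: Dataset, path: str | PathLike) -> None:
    """Write every spacer of the dataset to one FASTA file, in sample order,
    then locus, then spacer position."""
    spacers = ds.spacers()
    if not spacers:
        raise ValueError("empty dataset")
    records = [
        SeqRecord(
            Seq(sp.sequence),
            id=f"{sp.sample_id}|locus{sp.locus_num}|spacer{sp.spacer_num}|"
            f"{sp.start}|{sp.end}|{sp.length}|{sp.strand}",
            description="",
        )
        for sp in spacers
    ]
    SeqIO.write(records, str(path), "fasta")

def read_spacer_fasta(
    path: str | PathLike, warnings: list[str] | None = None
) -> Dataset:
    """Rebuild a :class:`Dataset` from a (possibly hand-edited) spacer FASTA.

    Spacers are regrouped by (sample, locus) and sorted by spacer number;
    gaps in the numbering (e.g. after the user deleted a bogus spacer) are
    renumbered consecutively with a note.  Duplicate identities are an error.
    """
    warnings = warnings if warnings is not None else []
    by_locus: dict[tuple[str, int], list[tuple[int, SeqRecord]]] = {}
    seen: set[tuple[str, int, int]] = set()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        parts = rec.id.rsplit("|", 6)
        if len(parts) != 7:
            raise ValueError(f"{path}: header {rec.id!r} does not match the scheme")
        sample, locus_s, spacer_s, start_s, end_s, length_s, strand = parts
        m_loc = re.fullmatch(r"locus(\d+)", locus_s)
        m_sp = re.fullmatch(r"spacer(\d+)", spacer_s)
        if not (m_loc and m_sp and strand in "+-"):
            raise ValueError(f"{path}: header {rec.id!r} does not match the scheme")
        locus_num, spacer_num = int(m_loc.group(1)), int(m_sp.group(1))
        key = (sample, locus_num, spacer_num)
        if key in seen:
            raise ValueError(
                f"{path}: duplicate spacer identity "
                f"{sample}|locus{locus_num}|spacer{spacer_num}"
            )
        seen.add(key)
        seq = str(rec.seq).upper()
        if int(length_s) != len(seq):
            warnings.append(
                f"{path}: {rec.id} declared length {length_s} != sequence "
                f"length {len(seq)}; keeping the sequence"
            )
        by_locus.setdefault((sample, locus_num), []).append(
            (spacer_num, (int(start_s), int(end_s), strand, seq))
        )
    if n == 0:
        raise ValueError(f"{path}: no FASTA records")

    ds = Dataset()
    for (sample, locus_num), entries in by_locus.items():
        entries.sort(key=lambda e: e[0])
        nums = [e[0] for e in entries]
        if nums != list(range(1, len(nums) + 1)):
            warnings.append(
                f"{path}: {sample} locus {locus_num} spacer numbers {nums} "
                "renumbered consecutively"
            )
        locus = CrisprLocus(sample, locus_num, entries[0][1][2])
        for new_num, (_old, (start, end, strand, seq)) in enumerate(entries, start=1):
            locus.spacers.append(
                SpacerRecord(sample, locus_num, new_num, start, end, strand, seq)
            )
        ds.add_locus(locus)
        ds.provenance.setdefault(sample, str(path))
    ds.validate()
    return ds
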