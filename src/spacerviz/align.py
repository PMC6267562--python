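"""Pairwise local alignment of spacers and the adjusted-mismatch score.

Two spacers are compared with an optimal local (Smith-Waterman) alignment and
summarized by the *adjusted number of nucleotide mismatches*:

    adjusted = query_length - (alignment_length - mismatches - gaps)

i.e. the query length minus the number of identical aligned columns, so any
part of the query left out of the local alignment is penalized exactly like a
mismatch.  Two spacers count as "the same" downstream when this score is at or
below a small cutoff (2 by default), which tolerates point mutations and
occasional sequencing errors without linking unrelated sequences.

The aligner is built in (no external alignment binary), uses DNA-style scoring
comparable to fasta36 defaults (match +5, mismatch -4, gap open -12, gap
extend -4 per additional column), and resolves ties among equal-scoring local
alignments deterministically: prefer more aligned columns, then fewer gap
columns, then more identical columns.  `N` and other ambiguity codes never
match anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .records import SpacerRecord

MATCH = 5
MISMATCH = -4
GAP_OPEN = -12   # first gap column
GAP_EXTEND = -4  # each additional gap column

_MAX_LEN = 400  # keeps the packed tie-break key decomposition unambiguous

# Lexicographic objective (score, columns, -gaps, matches) packed into one
# integer so the DP stays a plain max().  Weights leave headroom for sequences
# up to _MAX_LEN nt: columns <= 800, gaps < columns, matches <= 400.
_W_SCORE = 10**12
_W_COLS = 10**6
_W_GAPS = 10**3
_NEG = -(10**18)


@dataclass(frozen=True)
class PairSimilarity:
    """Alignment summary for one (query, subject) spacer pair."""

    query_id: str
    subject_id: str
    query_length: int
    alignment_length: int
    mismatches: int
    gaps: int

    @property
    def adjusted_mismatches(self) -> int:
        return adjusted_mismatches(
            self.query_length, self.alignment_length, self.mismatches, self.gaps
        )


def adjusted_mismatches(
    query_length: int, alignment_length: int, mismatches: int, gaps: int
) -> int:
    """Mismatch count extended over the full query length.

    Equals ``query_length - (alignment_length - mismatches - gaps)``: aligned
    identical columns are the only positions not counted against the query.
    """
    args = (query_length, alignment_length, mismatches, gaps)
    if any(a < 0 for a in args):
        raise ValueError(f"negative argument in {args}")
    if alignment_length < mismatches + gaps:
        raise ValueError(
            f"alignment_length {alignment_length} < mismatches+gaps "
            f"{mismatches + gaps}"
        )
    if alignment_length - gaps > query_length:
        raise ValueError(
            f"alignment consumes {alignment_length - gaps} query residues "
            f"but query is {query_length} nt"
        )
    return query_length - (alignment_length - mismatches - gaps)


def _is_match(x: str, y: str) -> bool:
    # Ambiguity codes (incl. N) are conservatively treated as mismatches.
    return x == y and x in "ACGT"


def _align_stats(a: str, b: str) -> tuple[int, int, int, int, int]:
    """Optimal local alignment of ``a`` vs ``b``.

    Returns ``(score, columns, mismatches, gaps, matches)`` of the alignment
    maximizing (score, columns, -gaps, matches) lexicographically.  Affine-gap
    Gotoh recursion with three states; the empty alignment (all zero) is a
    valid result when no positive-scoring pair exists.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("cannot align an empty sequence")
    if n > _MAX_LEN or m > _MAX_LEN:
        raise ValueError(f"sequence longer than supported maximum {_MAX_LEN} nt")

    sub_match = MATCH * _W_SCORE + _W_COLS + 1
    sub_mis = MISMATCH * _W_SCORE + _W_COLS
    d_open = GAP_OPEN * _W_SCORE + _W_COLS - _W_GAPS
    d_ext = GAP_EXTEND * _W_SCORE + _W_COLS - _W_GAPS

    width = m + 1
    M = [[_NEG] * width for _ in range(n + 1)]
    X = [[_NEG] * width for _ in range(n + 1)]  # gap in subject (consumes a)
    Y = [[_NEG] * width for _ in range(n + 1)]  # gap in query (consumes b)

    best_key, best_i, best_j = 0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            prev = Mp[j - 1]
            if Xp[j - 1] > prev:
                prev = Xp[j - 1]
            if Yp[j - 1] > prev:
                prev = Yp[j - 1]
            if prev < 0:
                prev = 0  # local restart
            mij = prev + (sub_match if _is_match(ai, b[j - 1]) else sub_mis)
            Mi[j] = mij
            if mij > best_key:
                best_key, best_i, best_j = mij, i, j
            xo = Mp[j] + d_open
            xe = Xp[j] + d_ext
            Xi[j] = xo if xo >= xe else xe
            yo = Mi[j - 1] + d_open
            ye = Yi[j - 1] + d_ext
            Yi[j] = yo if yo >= ye else ye

    if best_key == 0:
        return 0, 0, 0, 0, 0

    # Traceback: recount columns along the optimal path.  Any predecessor
    # whose key matches exactly lies on an equally optimal path with the same
    # packed statistics, so the deterministic M > X > Y preference is safe.
    cols = mism = gaps = matches = 0
    state, i, j = "M", best_i, best_j
    while True:
        if state == "M":
            cols += 1
            if _is_match(a[i - 1], b[j - 1]):
                matches += 1
                target = M[i][j] - sub_match
            else:
                mism += 1
                target = M[i][j] - sub_mis
            i, j = i - 1, j - 1
            if target == 0:
                break
            if M[i][j] == target:
                state = "M"
            elif X[i][j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            cols += 1
            gaps += 1
            key = X[i][j]
            i = i - 1
            if M[i][j] + d_open == key:
                state = "M"
            else:
                state = "X"
        else:
            cols += 1
            gaps += 1
            key = Y[i][j]
            j = j - 1
            if M[i][j] + d_open == key:
                state = "M"
            else:
                state = "Y"

    score = (best_key - (cols * _W_COLS - gaps * _W_GAPS + matches)) // _W_SCORE
    return score, cols, mism, gaps, matches


def align_pair(
    a: str, b: str, query_id: str = "query", subject_id: str = "subject"
) -> PairSimilarity:
    """Align ``a`` (query) against ``b`` (subject), forward strand only.

    Spacers are orientation-normalized at parse time, so the reverse strand is
    never searched: a spacer and its reverse complement score as unrelated.
    """
    a, b = a.upper(), b.upper()
    _score, cols, mism, gaps, _matches = _align_stats(a, b)
    return PairSimilarity(
        query_id=query_id,
        subject_id=subject_id,
        query_length=len(a),
        alignment_length=cols,
        mismatches=mism,
        gaps=gaps,
    )


def reduced_adjusted(a: str, b: str) -> int:
    """Symmetric pair score: minimum adjusted mismatches over both query
    directions.

    The alignment statistics are direction-independent, so the minimum is
    realized with the shorter sequence as query.
    """
    if a == b:
        return 0
    *_rest, matches = _align_stats(a.upper(), b.upper())
    return min(len(a), len(b)) - matches


def all_vs_all(
    records: Sequence[SpacerRecord], max_adjusted: int | None = None
) -> list[PairSimilarity]:
    """Reduced symmetric score for every unordered spacer pair.

    Duplicate sequences are aligned once and the result fanned out to every
    record pair, which cannot change any score.  The emitted PairSimilarity
    uses the direction realizing the minimum (shorter sequence as query;
    tie broken by input order).  ``max_adjusted`` drops pairs scoring above
    it, which is all the clustering stage needs.
    """
    if not records:
        raise ValueError("no spacer records given")
    groups: dict[str, list[SpacerRecord]] = {}
    for rec in records:
        groups.setdefault(rec.sequence.upper(), []).append(rec)
    uniq = list(groups)

    out: list[PairSimilarity] = []

    def emit(q: SpacerRecord, s: SpacerRecord, cols: int, mism: int, gaps: int) -> None:
        out.append(
            PairSimilarity(
                query_id=q.spacer_id,
                subject_id=s.spacer_id,
                query_length=q.length,
                alignment_length=cols,
                mismatches=mism,
                gaps=gaps,
            )
        )

    # identical-sequence pairs: perfect full-length alignment, adjusted 0
    for seq, members in groups.items():
        for k in range(len(members)):
            for l in range(k + 1, len(members)):
                emit(members[k], members[l], len(seq), 0, 0)

    for x in range(len(uniq)):
        for y in range(x + 1, len(uniq)):
            sa, sb = uniq[x], uniq[y]
            _score, cols, mism, gaps, matches = _align_stats(sa, sb)
            adj = min(len(sa), len(sb)) - matches
            if max_adjusted is not None and adj > max_adjusted:
                continue
            for ra in groups[sa]:
                for rb in groups[sb]:
                    q, s = (ra, rb) if len(sa) <= len(sb) else (rb, ra)
                    emit(q, s, cols, mism, gaps)
    return out


def parse_fasta36_tabular(
    lines: Iterable[str], query_lengths: Mapping[str, int]
) -> list[PairSimilarity]:
    """Adapter for fasta36/BLAST ``-m 8`` tabular hit lists.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    openings, qstart, qend, sstart, send, evalue, bitscore.  The tabular
    format reports gap *openings*, which stands in for the gap-column count;
    with the recommended low cutoffs gapped hits rarely qualify, so the
    approximation is inconsequential.  ``query_lengths`` maps query ids to
    spacer lengths (the tabular format does not carry them).
    """
    out = []
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 6:
            raise ValueError(f"not a tabular hit line: {ln!r}")
        qid, sid = parts[0], parts[1]
        if qid not in query_lengths:
            raise KeyError(f"no query length for {qid!r}")
        out.append(
            PairSimilarity(
                query_id=qid,
                subject_id=sid,
                query_length=query_lengths[qid],
                alignment_length=int(parts[3]),
                mismatches=int(parts[4]),
                gaps=int(parts[5]),
            )
        )
    return out
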