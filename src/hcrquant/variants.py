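"""Transcript-error classification at the lesion-opposite position.

Transcriptional mutagenesis — erroneous bypass of a DNA adduct by RNA polymerase II
— shows up in amplicon reads of the reporter mRNA as base misincorporations,
deletions or insertions at the transcript position templated by the adducted base
(the lesion-opposite position; a U opposite an adenine adduct). Reads are globally
aligned to the expected transcript with a banded affine-gap aligner (match +1,
mismatch -1, gap open -2, gap extend -1, band +/-5); the aligned column at the
lesion-opposite position determines the event class. Classes are reported as
retained only when their frequency reaches a fold threshold (default 10x) over the
background misincorporation rate (default 0.1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ReferenceTranscript",
    "VariantCall",
    "VariantTally",
    "example_reference",
    "banded_global_alignment",
    "align_and_classify",
    "tally_variants",
    "filter_by_background",
    "MATCH", "MISMATCH", "GAP_OPEN", "GAP_EXTEND", "BAND",
]

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -2.0     # cost of the first gapped base
GAP_EXTEND = -1.0   # each further gapped base
BAND = 5            # |ref_index - read_index| <= BAND
MAX_DIFFERENCES = 3  # mismatches + gapped bases beyond which a read is unclassifiable

_RNA = set("ACGU")

#: The 11-nt transcript context around the lesion-opposite base: the reverse
#: complement (in RNA) of the template-strand oligomer 5'-CTCGTACGCTC-3', whose
#: sole adenine carries the adduct; the complementary transcript base is the U at
#: core position 6.
CORE_CONTEXT = "GAGCGUACGAG"
CORE_LESION_POS = 6


def _to_rna(seq: str) -> str:
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - _RNA
    if bad:
        raise ValueError(f"non-ACGU/T characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class ReferenceTranscript:
    """Expected transcript with the 1-based lesion-opposite position.

    The sequence is stored in RNA alphabet (T converted to U on ingestion) and
    must carry at least 10 nt of flank on each side of the lesion-opposite base.
    """

    sequence: str
    lesion_opposite_pos: int

    def __post_init__(self):
        seq = _to_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 21:
            raise ValueError(f"reference too short ({len(seq)} nt); need >= 21")
        p = self.lesion_opposite_pos
        if not (1 <= p <= len(seq)):
            raise ValueError(f"lesion position {p} outside reference of length {len(seq)}")
        if p - 1 < 10 or len(seq) - p < 10:
            raise ValueError(f"lesion position {p} needs >= 10 nt flank on each side")

    @property
    def lesion_base(self) -> str:
        return self.sequence[self.lesion_opposite_pos - 1]


def example_reference() -> ReferenceTranscript:
    """Reference with the adduct-site transcript context in synthetic flanks.

    The 11-nt core is the genuine transcript context around the lesion-opposite U;
    the 15-nt flanks on either side are synthetic padding (invented here) so the
    aligner has anchor sequence on both sides.
    """
    left = "CCAUAGGCAAGCUUC"   # synthetic flank
    right = "GACUUAGCCGGAUCC"  # synthetic flank
    return ReferenceTranscript(
        sequence=left + CORE_CONTEXT + right,
        lesion_opposite_pos=len(left) + CORE_LESION_POS,
    )


@dataclass(frozen=True)
class VariantCall:
    """Lesion-site classification of one read.

    ``event`` is one of ``match``, ``misincorporation``, ``deletion``,
    ``insertion``, ``unclassifiable``; ``base`` is the read base involved for
    misincorporations/insertions; ``n_differences`` counts mismatches plus gapped
    bases over the whole alignment.
    """

    read_id: str
    event: str
    position: int
    base: str | None = None
    n_differences: int = 0

    @property
    def class_key(self) -> str:
        """Tally key, e.g. ``misincorporation:A`` or ``deletion``."""
        return f"{self.event}:{self.base}" if self.base else self.event


def banded_global_alignment(ref: str, read: str, band: int = BAND):
    """Global affine-gap alignment restricted to a diagonal band.

    Gotoh three-state dynamic programming with cells limited to
    ``|i - j| <= band``. A gap of length L scores ``GAP_OPEN + (L-1)*GAP_EXTEND``.
    Returns ``(score, columns)`` where columns is a list of
    ``(ref_index | None, read_index | None)`` pairs (0-based), None marking a gap.

    Traceback ties are broken deterministically (diagonal, then gap-in-read,
    then gap-in-ref).
    """
    m, n = len(ref), len(read)
    if abs(m - n) > band:
        raise ValueError(f"length difference {abs(m - n)} exceeds band {band}")
    NEG = float("-inf")
    # M: ends in (mis)match, X: gap in read (deletion), Y: gap in ref (insertion)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, min(m, band) + 1):
        X[i][0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, min(n, band) + 1):
        Y[0][j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, m + 1):
        jlo, jhi = max(1, i - band), min(n, i + band)
        for j in range(jlo, jhi + 1):
            s = MATCH if ref[i - 1] == read[j - 1] else MISMATCH
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if diag > NEG:
                M[i][j] = diag + s
            up_m, up_x = M[i - 1][j], X[i - 1][j]
            X[i][j] = max(up_m + GAP_OPEN, up_x + GAP_EXTEND,
                          Y[i - 1][j] + GAP_OPEN)
            left_m, left_y = M[i][j - 1], Y[i][j - 1]
            Y[i][j] = max(left_m + GAP_OPEN, left_y + GAP_EXTEND,
                          X[i][j - 1] + GAP_OPEN)

    finals = {"M": M[m][n], "X": X[m][n], "Y": Y[m][n]}
    state = max(finals, key=lambda k: (finals[k], k == "M", k == "X"))
    score = finals[state]
    if score == NEG:
        raise ValueError("no alignment within the band")

    cols = []
    i, j = m, n
    while i > 0 or j > 0:
        if state == "M":
            s = MATCH if ref[i - 1] == read[j - 1] else MISMATCH
            prev = M[i][j] - s
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            for cand, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i][j] - prev) < 1e-9:
                    state = cand
                    break
        elif state == "X":
            cols.append((i - 1, None))
            val = X[i][j]
            i -= 1
            if abs(M[i][j] + GAP_OPEN - val) < 1e-9:
                state = "M"
            elif abs(X[i][j] + GAP_EXTEND - val) < 1e-9:
                state = "X"
            else:
                state = "Y"
            if i == 0 and j == 0:
                break
            if i > 0 and j == 0:  # leading gap column
                state = "X"
        else:
            cols.append((None, j - 1))
            val = Y[i][j]
            j -= 1
            if abs(M[i][j] + GAP_OPEN - val) < 1e-9:
                state = "M"
            elif abs(Y[i][j] + GAP_EXTEND - val) < 1e-9:
                state = "Y"
            else:
                state = "X"
            if j == 0 and i == 0:
                break
            if j > 0 and i == 0:
                state = "Y"
    cols.reverse()
    return score, cols


def align_and_classify(
    read: str, ref: ReferenceTranscript, read_id: str = "", band: int = BAND
) -> VariantCall:
    """Classify one read at the reference's lesion-opposite position.

    The read is globally aligned within the band; mismatches plus gapped bases
    give the difference count, and reads with more than 3 differences are set
    aside as unclassifiable. Otherwise the aligned column at the lesion-opposite
    position decides: gap in the read -> deletion; a non-reference base ->
    misincorporation; reference base with an inserted read base immediately
    adjacent -> insertion; else match.
    """
    if not read:
        raise ValueError(f"read {read_id!r} is empty")
    rna = _to_rna(read)
    if abs(len(rna) - len(ref.sequence)) > band:
        raise ValueError(
            f"read {read_id!r} length {len(rna)} outside +/-{band} of reference"
        )
    _, cols = banded_global_alignment(ref.sequence, rna, band=band)

    ndiff = 0
    for ri, qi in cols:
        if ri is None or qi is None:
            ndiff += 1
        elif ref.sequence[ri] != rna[qi]:
            ndiff += 1

    pos = ref.lesion_opposite_pos
    if ndiff > MAX_DIFFERENCES:
        return VariantCall(read_id=read_id, event="unclassifiable", position=pos,
                           n_differences=ndiff)

    lesion_col = next(k for k, (ri, _qi) in enumerate(cols) if ri == pos - 1)
    ri, qi = cols[lesion_col]
    if qi is None:
        return VariantCall(read_id=read_id, event="deletion", position=pos,
                           n_differences=ndiff)
    if rna[qi] != ref.lesion_base:
        return VariantCall(read_id=read_id, event="misincorporation", position=pos,
                           base=rna[qi], n_differences=ndiff)
    # inserted read base immediately flanking the lesion column?
    for k in (lesion_col - 1, lesion_col + 1):
        if 0 <= k < len(cols) and cols[k][0] is None:
            return VariantCall(read_id=read_id, event="insertion", position=pos,
                               base=rna[cols[k][1]], n_differences=ndiff)
    return VariantCall(read_id=read_id, event="match", position=pos, n_differences=ndiff)


@dataclass
class VariantTally:
    """Per-class counts/frequencies at the lesion site with the background filter.

    ``frequencies`` are counts over classified (non-unclassifiable) reads;
    ``retained`` flags classes whose frequency reaches
    ``fold_threshold * background_rate`` (boundary inclusive).
    """

    counts: dict[str, int]
    frequencies: dict[str, float]
    n_classified: int
    n_unclassifiable: int
    background_rate: float = 0.001
    fold_threshold: float = 10.0
    retained: dict[str, bool] = field(default_factory=dict)


def tally_variants(
    calls: list[VariantCall],
    background_rate: float = 0.001,
    fold_threshold: float = 10.0,
) -> VariantTally:
    """Tally lesion-site classes over classified reads and apply the filter."""
    classified = [c for c in calls if c.event != "unclassifiable"]
    n_unclass = len(calls) - len(classified)
    if not classified:
        raise ValueError("no classified reads to tally")
    counts: dict[str, int] = {}
    for c in classified:
        counts[c.class_key] = counts.get(c.class_key, 0) + 1
    freqs = {k: v / len(classified) for k, v in counts.items()}
    tally = VariantTally(
        counts=counts, frequencies=freqs, n_classified=len(classified),
        n_unclassifiable=n_unclass, background_rate=background_rate,
        fold_threshold=fold_threshold,
    )
    return filter_by_background(tally)


def filter_by_background(
    tally: VariantTally,
    background_rate: float | None = None,
    fold_threshold: float | None = None,
) -> VariantTally:
    """Set the retained flag: frequency >= fold_threshold * background_rate.

    The boundary is inclusive (a class at exactly 10x the 0.1% background is
    retained). Returns a new tally; the input is not modified.
    """
    bg = tally.background_rate if background_rate is None else background_rate
    fold = tally.fold_threshold if fold_threshold is None else fold_threshold
    if bg <= 0:
        raise ValueError("background rate must be positive")
    cutoff = fold * bg
    retained = {k: f >= cutoff for k, f in tally.frequencies.items()}
    return replace(tally, background_rate=bg, fold_threshold=fold, retained=retained)
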