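"""Protein domain conservation scoring by pairwise global alignment.

Domains annotated on two orthologous proteins are compared by Needleman-
Wunsch global alignment with affine gaps under BLOSUM62 (gap open 10,
gap extend 0.5, end gaps free — the EMBOSS needle defaults).  The alignment
is summarized as

* identity %    — identical residue pairs / alignment length (gap columns
                  count in the denominator),
* similarity %  — residue pairs with a positive substitution score /
                  alignment length,

and a domain is called conserved when identity >= 40%.  Conserved-site
counting over a fixed window of alignment columns supports motif-level
statements such as "similar at 52/58 sites".
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "ProteinSeq",
    "DomainAnnotation",
    "DomainComparison",
    "global_align",
    "domain_conserved",
    "window_conservation",
    "compare_domains",
    "CONSERVATION_IDENTITY_THRESHOLD",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AMINO_ACIDS) | {"X"}
GAP = "-"

#: Minimum identity % for a domain to be called conserved.
CONSERVATION_IDENTITY_THRESHOLD = 40.0


@dataclass(frozen=True)
class ProteinSeq:
    """An identified amino-acid sequence (20 standard residues plus X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinSeq id must be non-empty")
        if not self.residues:
            raise ValueError(f"ProteinSeq {self.id!r} has an empty sequence")
        res = self.residues.upper()
        bad = set(res) - _VALID
        if bad:
            raise ValueError(
                f"ProteinSeq {self.id!r} contains invalid residues {sorted(bad)} "
                "(expected the 20 amino acids or X; gaps are not allowed)"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def region(self, start: int, end: int) -> str:
        """Residues ``start..end`` in 1-based inclusive coordinates."""
        if not (1 <= start <= end <= len(self.residues)):
            raise ValueError(
                f"region {start}..{end} out of bounds for {self.id!r} "
                f"(length {len(self.residues)})"
            )
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class DomainAnnotation:
    """A named interval on a protein, 1-based inclusive coordinates."""

    seq_id: str
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain interval {self.start}..{self.end}")


@dataclass(frozen=True)
class DomainComparison:
    """Summary of one pairwise global alignment of two protein regions."""

    id_a: str
    id_b: str
    score: float
    aligned_a: str
    aligned_b: str
    aligned_length: int
    identical_sites: int
    similar_sites: int
    identity_pct: float
    similarity_pct: float
    conserved: bool


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # affine cost open + (L-1)*extend for an internal gap of length L
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    # end gaps are free, as in EMBOSS needle with default end weighting
    aligner.end_gap_score = 0.0
    return aligner


def global_align(
    a: ProteinSeq | str,
    b: ProteinSeq | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> DomainComparison:
    """Global alignment of two protein (region) sequences with affine gaps.

    Returns a :class:`DomainComparison` whose identity and similarity
    percentages are computed over the full alignment length, gap columns
    included, and whose ``conserved`` flag applies the >= 40% identity rule.
    """
    pa = a if isinstance(a, ProteinSeq) else ProteinSeq("a", a)
    pb = b if isinstance(b, ProteinSeq) else ProteinSeq("b", b)
    aligner = _aligner(matrix, gap_open, gap_extend)
    submat = aligner.substitution_matrix
    alignment = aligner.align(pa.residues, pb.residues)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    length = len(ga)
    identical = similar = 0
    for ra, rb in zip(ga, gb):
        if ra == GAP or rb == GAP:
            continue
        if ra == rb:
            identical += 1
        if submat[ra, rb] > 0:
            similar += 1
    identity_pct = 100.0 * identical / length
    similarity_pct = 100.0 * similar / length
    return DomainComparison(
        id_a=pa.id,
        id_b=pb.id,
        score=float(alignment.score),
        aligned_a=ga,
        aligned_b=gb,
        aligned_length=length,
        identical_sites=identical,
        similar_sites=similar,
        identity_pct=identity_pct,
        similarity_pct=similarity_pct,
        conserved=domain_conserved(identity_pct),
    )


def domain_conserved(identity_pct: float) -> bool:
    """Apply the conservation rule: identity >= 40% (inclusive)."""
    if not (0.0 <= identity_pct <= 100.0):
        raise ValueError(f"identity_pct must be in [0, 100], got {identity_pct}")
    return identity_pct >= CONSERVATION_IDENTITY_THRESHOLD


def window_conservation(
    aligned_a: str, aligned_b: str, start: int = 1, end: int | None = None
) -> tuple[int, int]:
    """Count identical sites in a window of alignment columns.

    ``start``/``end`` are 1-based inclusive column indices into the gapped
    alignment.  Returns ``(identical_sites, window_length)``: a column counts
    toward identity only when both residues are non-gap and equal, but every
    column — gapped or not — counts toward the window length.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned strings differ in length ({len(aligned_a)} vs {len(aligned_b)})"
        )
    if end is None:
        end = len(aligned_a)
    if not (1 <= start <= end <= len(aligned_a)):
        raise ValueError(f"window {start}..{end} out of bounds for alignment length {len(aligned_a)}")
    wa = aligned_a[start - 1 : end]
    wb = aligned_b[start - 1 : end]
    identical = sum(
        1 for ra, rb in zip(wa, wb) if ra != GAP and rb != GAP and ra == rb
    )
    return identical, end - start + 1


def compare_domains(
    seq_a: ProteinSeq,
    seq_b: ProteinSeq,
    annot_a: DomainAnnotation,
    annot_b: DomainAnnotation,
    **align_kwargs,
) -> DomainComparison:
    """Align the annotated region of ``seq_a`` against that of ``seq_b``."""
    for seq, annot in ((seq_a, annot_a), (seq_b, annot_b)):
        if annot.seq_id != seq.id:
            raise ValueError(
                f"annotation {annot.name!r} refers to {annot.seq_id!r}, not {seq.id!r}"
            )
        if annot.end > len(seq):
            raise ValueError(
                f"domain {annot.name!r} ({annot.start}..{annot.end}) exceeds "
                f"sequence {seq.id!r} of length {len(seq)}"
            )
    ra = ProteinSeq(f"{seq_a.id}:{annot_a.name}", seq_a.region(annot_a.start, annot_a.end))
    rb = ProteinSeq(f"{seq_b.id}:{annot_b.name}", seq_b.region(annot_b.start, annot_b.end))
    return global_align(ra, rb, **align_kwargs)
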