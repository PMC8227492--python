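"""Canonical seed-site prediction on 3'-UTRs.

The seed of a mature miRNA is nucleotides 2-8 (5'->3', 1-based). Canonical
target sites on a UTR are, in decreasing strength:

* ``8mer``     — reverse complement of miRNA positions 2-8, followed by an
  ``A`` on the target opposite miRNA position 1;
* ``7mer-m8``  — reverse complement of positions 2-8 alone;
* ``7mer-A1``  — reverse complement of positions 2-7 followed by an ``A``.

The trailing adenosine is a literal ``A`` on the target regardless of the
miRNA's position-1 identity. Matching is done in DNA space on the UTR as
given (single-stranded, 5'->3'); coordinates are 0-based half-open. Where an
8mer occurs, its embedded 7mer-m8 (same start) and 7mer-A1 (start + 1)
sub-matches are suppressed so each site is counted once at its strongest
type; distinct overlapping sites are otherwise all reported.

Only canonical site identification is implemented — no context scoring,
3'-supplementary pairing or conservation weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import SequenceRecord, normalize_sequence, reverse_complement
from .signature import MatureMiRNA

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass(frozen=True)
class SeedSite:
    """One predicted binding site on a UTR (0-based half-open interval)."""

    gene: str
    start: int
    end: int
    site_type: str
    pattern: str

    def __post_init__(self) -> None:
        if self.end - self.start not in (7, 8):
            raise ValueError("seed sites span 7 or 8 bases")
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")


@dataclass
class TargetPrediction:
    """Per-gene site lists for one miRNA; genes with zero sites are absent."""

    mirna: MatureMiRNA
    sites_by_gene: dict[str, list[SeedSite]] = field(default_factory=dict)

    def total_sites(self, gene: str) -> int:
        return len(self.sites_by_gene.get(gene, []))

    @property
    def genes(self) -> set[str]:
        return set(self.sites_by_gene)

    def __len__(self) -> int:
        return len(self.sites_by_gene)


def seed_patterns(mirna_sequence: str) -> dict[str, str]:
    """Derive the three canonical site patterns from a mature sequence.

    Accepts RNA or DNA, any case; patterns are uppercase DNA. Depends only on
    the first 8 nucleotides of the miRNA.
    """
    seq = normalize_sequence(mirna_sequence)
    if len(seq) < 8:
        raise ValueError(f"mature sequence must be >= 8 nt, got {len(seq)}")
    seed_m8 = reverse_complement(seq[1:8])  # positions 2-8
    seed_a1 = reverse_complement(seq[1:7])  # positions 2-7
    return {
        "8mer": seed_m8 + "A",
        "7mer-m8": seed_m8,
        "7mer-A1": seed_a1 + "A",
    }


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) occurrence starts of needle in haystack."""
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_utr(utr: SequenceRecord, patterns: Mapping[str, str]) -> list[SeedSite]:
    """Report every canonical site occurrence in a UTR, strongest type first.

    An 8mer match absorbs the 7mer-m8 at the same start and the 7mer-A1 one
    base downstream (they are its sub-strings by construction); all other
    matches, overlapping or not, are reported. Output is sorted by start,
    then by site-type order 8mer, 7mer-m8, 7mer-A1.
    """
    seq = utr.sequence
    hits_8mer = _find_all(seq, patterns["8mer"]) if "8mer" in patterns else []
    eightmer_starts = set(hits_8mer)
    sites = [SeedSite(utr.id, s, s + 8, "8mer", patterns["8mer"]) for s in hits_8mer]
    if "7mer-m8" in patterns:
        for s in _find_all(seq, patterns["7mer-m8"]):
            if s in eightmer_starts:
                continue  # embedded in an 8mer at the same position
            sites.append(SeedSite(utr.id, s, s + 7, "7mer-m8", patterns["7mer-m8"]))
    if "7mer-A1" in patterns:
        for s in _find_all(seq, patterns["7mer-A1"]):
            if (s - 1) in eightmer_starts:
                continue  # the A1 sub-match of an 8mer one base upstream
            sites.append(SeedSite(utr.id, s, s + 7, "7mer-A1", patterns["7mer-A1"]))
    order = {t: i for i, t in enumerate(SITE_TYPES)}
    sites.sort(key=lambda st: (st.start, order[st.site_type]))
    return sites


def predict_targets(utrs: Sequence[SequenceRecord], mirna: MatureMiRNA) -> TargetPrediction:
    """Scan a UTR set with one miRNA's patterns; aggregate sites per gene."""
    if mirna.sequence is None:
        raise ValueError(f"{mirna.mature_name}: no mature sequence attached")
    ids = [u.id for u in utrs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids in UTR set: {dupes}")
    patterns = seed_patterns(mirna.sequence.sequence)
    prediction = TargetPrediction(mirna)
    for utr in utrs:
        sites = scan_utr(utr, patterns)
        if sites:
            prediction.sites_by_gene[utr.id] = sites
    return prediction
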