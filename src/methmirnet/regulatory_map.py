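"""Promoter assignment, DMR/promoter overlap and miRNA target pairing.

The promoter of a miRNA is the strand-aware upstream window of its
transcription start site (TSS): ``upstream_bp`` bases before the TSS on
the plus strand, after it on the minus strand, always expressed as a
0-based half-open interval on the forward axis.  DMRs are matched to
miRNAs when their intervals intersect by at least one base.

Candidate miRNA -> mRNA pairs come either from seed matching — by
default the canonical 7mer-m8 site, i.e. an exact Watson-Crick
complement of miRNA positions 2-8 in the 3'UTR — or from an external,
MiRanda-style pair table.  Full hybridization/energy scoring is out of
scope; seed matching is an explicit, testable proxy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .errors import CoordinateError, ParseError, SequenceError
from .methylation import DMR

SEED_TYPES = ("7mer-m8", "7mer-A1", "8mer")


@dataclass(frozen=True)
class PromoterInterval:
    """Strand-aware promoter window of one miRNA (0-based half-open)."""

    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class TargetPair:
    """A candidate miRNA -> mRNA regulatory pair."""

    mirna_id: str
    mrna_id: str
    n_sites: int
    source: str  # 'seed_match' | 'external'


def promoter_region(
    mirna_id: str,
    tss: int,
    strand: str,
    chrom: str,
    chrom_len: int,
    upstream_bp: int = 2000,
) -> PromoterInterval:
    """Upstream promoter window of a TSS, clipped to the chromosome.

    Plus strand: [max(0, tss - upstream_bp), tss); minus strand:
    [tss, min(chrom_len, tss + upstream_bp)).  Empty windows (a TSS at
    the chromosome edge on the wrong side) are rejected.
    """
    if not 0 <= tss <= chrom_len:
        raise CoordinateError(
            f"TSS {tss} outside chromosome {chrom} of length {chrom_len}"
        )
    if strand == "+":
        start, end = max(0, tss - upstream_bp), tss
    elif strand == "-":
        start, end = tss, min(chrom_len, tss + upstream_bp)
    else:
        raise CoordinateError(f"strand must be '+' or '-', got {strand!r}")
    if start >= end:
        raise CoordinateError(
            f"empty promoter window for {mirna_id} (tss={tss}, strand={strand})"
        )
    return PromoterInterval(mirna_id, chrom, int(start), int(end), strand)


def promoters_from_annotation(
    annotation, chrom_lengths: Mapping[str, int], upstream_bp: int = 2000
) -> list[PromoterInterval]:
    """Promoter windows for a whole annotation table (mirna_id, chrom, tss, strand)."""
    return [
        promoter_region(
            r.mirna_id, int(r.tss), str(r.strand), str(r.chrom),
            int(chrom_lengths[str(r.chrom)]), upstream_bp,
        )
        for r in annotation.itertuples()
    ]


def overlap_dmr_promoters(
    dmrs: Sequence[DMR], promoters: Sequence[PromoterInterval]
) -> list[tuple[DMR, str]]:
    """All (DMR, miRNA id) pairs whose intervals intersect (>= 1 bp).

    Half-open semantics: touching intervals do not overlap.  Each pair is
    emitted at most once, in sorted DMR order.
    """
    by_chrom: dict[str, list[PromoterInterval]] = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append(p)
    pairs: list[tuple[DMR, str]] = []
    seen: set[tuple[tuple, str]] = set()
    for d in sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end)):
        for p in by_chrom.get(d.chrom, ()):
            if d.start < p.end and p.start < d.end:
                key = ((d.chrom, d.start, d.end), p.mirna_id)
                if key not in seen:
                    seen.add(key)
                    pairs.append((d, p.mirna_id))
    return pairs


def _normalize_seq(seq: str, what: str, name: str) -> str:
    """Uppercase, U->T; reject characters outside the ACGU/ACGT alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise SequenceError(
            f"{what} {name!r} contains non-ACGU/ACGT characters: {sorted(bad)}"
        )
    return s


def seed_site(mirna_seq: str, seed_type: str = "7mer-m8", mirna_id: str = "?") -> str:
    """The DNA site a UTR must contain for the given seed-match class.

    7mer-m8: reverse complement of miRNA positions 2-8 (1-based, 5'->3').
    7mer-A1: reverse complement of positions 2-7 followed by an A.
    8mer: the 7mer-m8 site followed by an A.
    """
    if seed_type not in SEED_TYPES:
        raise SequenceError(f"unknown seed_type {seed_type!r}; use one of {SEED_TYPES}")
    s = _normalize_seq(mirna_seq, "miRNA", mirna_id)
    if len(s) < 8:
        raise SequenceError(f"miRNA {mirna_id!r} shorter than 8 nt")
    if seed_type == "7mer-m8":
        return str(Seq(s[1:8]).reverse_complement())
    if seed_type == "7mer-A1":
        return str(Seq(s[1:7]).reverse_complement()) + "A"
    return str(Seq(s[1:8]).reverse_complement()) + "A"


def count_sites(utr_seq: str, site: str) -> int:
    """Occurrences of ``site`` in the UTR, overlapping matches allowed."""
    n, at = 0, utr_seq.find(site)
    while at != -1:
        n += 1
        at = utr_seq.find(site, at + 1)
    return n


def predict_targets(
    mirna_seqs: Mapping[str, str],
    utr_seqs: Mapping[str, str],
    seed_type: str = "7mer-m8",
) -> list[TargetPair]:
    """Seed-match target prediction for every miRNA x UTR combination.

    A pair is emitted iff the seed-complement site occurs at least once
    in the UTR; ``n_sites`` counts occurrences (overlaps allowed).
    """
    sites = {
        mid: seed_site(seq, seed_type, mid) for mid, seq in mirna_seqs.items()
    }
    utrs = {
        gid: _normalize_seq(seq, "UTR", gid) for gid, seq in utr_seqs.items()
    }
    pairs: list[TargetPair] = []
    for mid, site in sites.items():
        for gid, utr in utrs.items():
            n = count_sites(utr, site)
            if n >= 1:
                pairs.append(TargetPair(mid, gid, n, "seed_match"))
    return pairs


def load_target_map(path: str | Path) -> list[TargetPair]:
    """Load an externally computed miRNA-target pair table (TSV).

    Expects header columns ``mirna_id`` and ``mrna_id``; duplicate rows
    collapse to one pair with source='external'.
    """
    path = Path(path)
    pairs: dict[tuple[str, str], TargetPair] = {}
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (expected a header line)")
        try:
            i_mir = header.index("mirna_id")
            i_gene = header.index("mrna_id")
        except ValueError:
            raise ParseError(
                f"{path}: line 1: header must contain 'mirna_id' and 'mrna_id'"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) <= max(i_mir, i_gene) or not row[i_mir] or not row[i_gene]:
                raise ParseError(f"{path}: line {lineno}: malformed row {row!r}")
            key = (row[i_mir], row[i_gene])
            pairs.setdefault(key, TargetPair(key[0], key[1], 1, "external"))
    return list(pairs.values())


def write_target_pairs(pairs: Iterable[TargetPair], path: str | Path) -> None:
    """Write pairs as TSV (mirna_id, mrna_id, n_sites, source)."""
    with Path(path).open("w") as fh:
        fh.write("mirna_id\tmrna_id\tn_sites\tsource\n")
        for p in pairs:
            fh.write(f"{p.mirna_id}\t{p.mrna_id}\t{p.n_sites}\t{p.source}\n")
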