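"""Read filtering, BLESS barcode matching and diverse-barcode design.

The quality filter keeps reads with a sufficiently long run of
high-quality bases (34 consecutive bases above Q20 by default).  Barcode
matching is exact-prefix by default ("intact" barcode).  The AasI design
replaces the single XhoI-derived 5' barcode with four barcodes that put
all four bases at each early cycle, restoring initial sequence diversity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from collections import Counter

import numpy as np

from longtemplate.base_caller import ReadRecord

#: The two 11 nt BLESS 5' barcodes (the archetypal low-diversity prefixes).
BLESS_BARCODES = ("TCGAGGTAGTA", "TCGAGACGACG")

_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class BarcodeSet:
    barcodes: tuple[str, ...]
    name: str = "barcodes"

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("empty barcode set")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError("barcodes in a set must have equal length")
        for b in self.barcodes:
            if set(b) - _ALPHABET:
                raise ValueError(f"barcode {b!r} not over ACGT")

    @property
    def length(self) -> int:
        return len(self.barcodes[0])

    def min_pairwise_hamming(self) -> int:
        return min(
            hamming_distance(a, b) for a, b in itertools.combinations(self.barcodes, 2)
        )


def quality_filter(read: ReadRecord | list[int], min_run: int = 34, min_q: int = 20) -> bool:
    """Keep reads with >= ``min_run`` consecutive bases above ``min_q``.

    "Above Q20" is read strictly: a base counts iff its Phred score is
    > min_q (i.e. Q21 or better by default).
    """
    quals = read.quals if isinstance(read, ReadRecord) else read
    run = best = 0
    for q in quals:
        run = run + 1 if q > min_q else 0
        best = max(best, run)
    return best >= min_run


def match_barcode(
    read: ReadRecord | str, barcode_set: BarcodeSet, max_mismatch: int = 0
) -> tuple[str | None, str]:
    """Match the read's 5' prefix against a barcode set and trim it.

    Returns (matched barcode or None, read sequence with the barcode
    trimmed off on a match, unchanged otherwise).  N calls never match.
    """
    seq = read.bases if isinstance(read, ReadRecord) else read
    k = barcode_set.length
    if len(seq) < k:
        raise ValueError("read shorter than barcode")
    prefix = seq[:k]
    for bc in barcode_set.barcodes:
        mism = sum(1 for a, b in zip(prefix, bc) if a != b)
        if mism <= max_mismatch and "N" not in prefix:
            return bc, seq[k:]
    return None, seq


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming_distance requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y)


#: AasI recognition pattern for the redesigned primers: GACNNNNNNGTC,
#: where the two variable dinucleotides are reverse complements of each
#: other so the site stays palindromic for the enzyme.
AASI_PRIMERS = ("GACGTGCACGTC", "GACAGGCCTGTC", "GACCAGCTGGTC", "GACTCGCGAGTC")


def design_aasi_barcodes() -> tuple[tuple[str, ...], BarcodeSet]:
    """Return the AasI primer set and the 5-mer barcodes they produce.

    AasI cuts GACNNNN^NNGTC, so each primer leaves a 5 nt 5' barcode: its
    last variable dinucleotide plus GTC.  The four barcodes start with A,
    C, T and G respectively, so the set is perfectly base-balanced at
    cycle 1 — the design goal.
    """
    barcodes = tuple(p[7:12] for p in AASI_PRIMERS)
    return AASI_PRIMERS, BarcodeSet(barcodes=barcodes, name="aasi_bless")


def primer_matches_aasi_site(primer: str) -> bool:
    """Check the GACNNNNNNGTC pattern with reverse-complement-paired N2 blocks."""
    if len(primer) != 12 or primer[:3] != "GAC" or primer[9:] != "GTC":
        return False
    comp = str.maketrans("ACGT", "TGCA")
    first, second = primer[3:5], primer[7:9]
    return second == first.translate(comp)[::-1]


def per_cycle_base_balance(barcode_set: BarcodeSet) -> list[float]:
    """Normalized per-position base diversity of a barcode set.

    For each position, the Shannon entropy of the base frequency
    distribution divided by 2 bits: 1.0 means all four bases equally
    represented, 0.0 means a single base.
    """
    out = []
    for pos in range(barcode_set.length):
        counts = Counter(b[pos] for b in barcode_set.barcodes)
        freqs = np.array(list(counts.values()), dtype=float)
        freqs /= freqs.sum()
        entropy = -np.sum(freqs * np.log2(freqs))
        out.append(float(entropy / 2.0))
    return out


def normalized_barcode_pct(raw_pct: float, lowdiv_sample_fraction: float) -> float:
    """Normalize %-barcoded for the share of the library that carries a barcode.

    E.g. if 10% of the library is the barcoded sample and 10% of reads are
    barcoded, the normalized value is 100%.
    """
    if not 0 < lowdiv_sample_fraction <= 1:
        raise ValueError("lowdiv_sample_fraction must be in (0, 1]")
    return raw_pct / lowdiv_sample_fraction


def write_barcode_fasta(barcode_set: BarcodeSet, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(bc), id=f"{barcode_set.name}_{i+1}", description="")
        for i, bc in enumerate(barcode_set.barcodes)
    ]
    SeqIO.write(records, path, "fasta")


def read_barcode_fasta(path, name: str = "barcodes") -> BarcodeSet:
    from Bio import SeqIO

    return BarcodeSet(
        barcodes=tuple(str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")),
        name=name,
    )
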