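"""In-silico PCR: primer binding, amplicon prediction, specificity, identification.

Binding sites are located by a mismatch-tolerant sliding scan on both
strands; IUPAC ambiguity codes in the template count as matches when
compatible.  By default a perfect-match 3'-terminal trinucleotide is
required (allele-specific PCR logic — the diagnostic SNP sits at the 3'
end), with up to 2 mismatches elsewhere.  An amplicon is any forward(+) /
reverse(−) site combination with the reverse site downstream and a product
no longer than the electrophoretic detectability cutoff (2 kb).

The pair × species specificity matrix is the in-silico analog of running
every species-specific pair against every species on a gel: a specific pair
amplifies its own species and nothing else (single-band diagonal pattern).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align_distance import global_align
from .seq_io import BarcodeLibrary, SequenceRecord, reverse_complement

_MASK = np.zeros(256, dtype=np.uint8)
for _ch, _m in {"A": 1, "C": 2, "G": 4, "T": 8, "M": 3, "R": 5, "W": 9,
                "S": 6, "Y": 10, "K": 12, "V": 7, "H": 11, "D": 13,
                "B": 14, "N": 15}.items():
    _MASK[ord(_ch)] = _m


def _masks(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    m = _MASK[arr]
    if (m == 0).any():
        bad = int(np.argmax(m == 0))
        raise ValueError(f"non-IUPAC character {seq[bad]!r} at position {bad + 1}")
    return m


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    strand: str            # "+" | "-"
    start: int             # 1-based inclusive footprint on the template
    end: int
    mismatches: int
    three_prime_mismatches: int


def find_binding_sites(primer: str, template: SequenceRecord | str,
                       max_mismatch: int = 2,
                       max_3p_mismatch: int = 0) -> list[BindingSite]:
    """All primer footprints on both strands within the mismatch tolerances.

    The 3'-terminal window is the last 3 primer bases; on the minus strand
    it faces the low-coordinate end of the footprint.
    """
    if isinstance(template, str):
        template = SequenceRecord("template", template)
    t = _masks(template.seq)
    n = len(t)
    L = len(primer)
    if n < L:
        return []
    wins = np.lib.stride_tricks.sliding_window_view(t, L)
    sites: list[BindingSite] = []
    for strand in ("+", "-"):
        p = _masks(primer if strand == "+" else reverse_complement(primer))
        compat = (wins & p) != 0
        mism = L - compat.sum(axis=1)
        if strand == "+":
            three_p = (~compat[:, -3:]).sum(axis=1)
        else:
            three_p = (~compat[:, :3]).sum(axis=1)
        hits = np.nonzero((mism <= max_mismatch) & (three_p <= max_3p_mismatch))[0]
        for start in hits:
            sites.append(BindingSite(template.id, strand, int(start) + 1,
                                     int(start) + L, int(mism[start]),
                                     int(three_p[start])))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


@dataclass(frozen=True)
class PCRPair:
    """A primer pair as used by the in-silico PCR layer."""

    species: str
    fwd_seq: str
    rev_seq: str
    expected_len: int | None = None
    name: str = ""

    @classmethod
    def from_design(cls, pair) -> "PCRPair":
        return cls(pair.species, pair.forward.seq, pair.reverse.seq,
                   pair.product_len, getattr(pair, "name", ""))

    @classmethod
    def from_fixture(cls, fwd_row, rev_row) -> "PCRPair":
        return cls(fwd_row.species, fwd_row.seq, rev_row.seq,
                   fwd_row.target_fragment,
                   f"{fwd_row.primer_name}/{rev_row.primer_name}")


def _as_pcrpair(pair) -> PCRPair:
    return pair if isinstance(pair, PCRPair) else PCRPair.from_design(pair)


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    fwd_site: BindingSite
    rev_site: BindingSite
    product_len: int
    product_seq: str


def predict_amplicons(pair, template: SequenceRecord | str,
                      max_product: int = 2000, max_mismatch: int = 2,
                      max_3p_mismatch: int = 0) -> list[AmpliconPrediction]:
    """All products from convergent forward(+)/reverse(−) site combinations."""
    pair = _as_pcrpair(pair)
    if isinstance(template, str):
        template = SequenceRecord("template", template)
    fwd = [s for s in find_binding_sites(pair.fwd_seq, template, max_mismatch,
                                         max_3p_mismatch) if s.strand == "+"]
    rev = [s for s in find_binding_sites(pair.rev_seq, template, max_mismatch,
                                         max_3p_mismatch) if s.strand == "-"]
    out = []
    for f in fwd:
        for r in rev:
            if r.end <= f.start:
                continue
            if r.start <= f.end:          # overlapping footprints: no product
                continue
            pl = r.end - f.start + 1
            if pl > max_product:
                continue
            out.append(AmpliconPrediction(template.id, f, r, pl,
                                          template.seq[f.start - 1:r.end]))
    out.sort(key=lambda a: (a.product_len, a.fwd_site.start))
    return out


@dataclass
class SpecificityMatrix:
    """Pair × species amplification table (the in-silico gel)."""

    pair_species: list[str]
    species: list[str]
    amplified: pd.DataFrame                 # bool, pairs × species
    products: dict[tuple[str, str], list[int]]

    def is_specific(self, pair_sp: str) -> bool:
        row = self.amplified.loc[pair_sp]
        return bool(row.get(pair_sp, False)) and int(row.sum()) == 1

    @property
    def n_specific(self) -> int:
        return sum(self.is_specific(sp) for sp in self.pair_species)

    @property
    def is_diagonal(self) -> bool:
        return self.n_specific == len(self.pair_species)

    def write_tsv(self, path: str | Path) -> None:
        self.amplified.to_csv(path, sep="\t", index_label="pair_species")


def specificity_matrix(pairs, lib: BarcodeLibrary, max_mismatch: int = 2,
                       max_3p_mismatch: int = 0,
                       max_product: int = 2000) -> SpecificityMatrix:
    """Run every pair against every record; a cell is true when at least one
    record of that species yields at least one amplicon."""
    pairs = [_as_pcrpair(p) for p in pairs]
    if not pairs or len(lib) < 1:
        raise ValueError("need at least one pair and one record")
    species = lib.species
    amp = pd.DataFrame(False, index=[p.species for p in pairs], columns=species)
    products: dict[tuple[str, str], list[int]] = {}
    for pair in pairs:
        for sp in species:
            sizes = []
            for rec in lib.records_of(sp):
                sizes += [a.product_len for a in
                          predict_amplicons(pair, rec, max_product,
                                            max_mismatch, max_3p_mismatch)]
            products[(pair.species, sp)] = sorted(sizes)
            if sizes:
                amp.loc[pair.species, sp] = True
    return SpecificityMatrix([p.species for p in pairs], species, amp, products)


@dataclass
class IdentificationCall:
    sample_id: str
    called_species: str            # species label or "no call"
    supporting_pairs: list[str]
    best_match_id: str
    best_match_similarity: float   # percent identity, terminal gaps excluded


def alignment_identity(a: str, b: str) -> float:
    """Percent identity of the global alignment over non-gap columns,
    terminal gap overhangs excluded."""
    aln = global_align(a, b)
    cols = list(zip(aln.seq_a_aligned, aln.seq_b_aligned))
    lo = 0
    hi = len(cols)
    while lo < hi and "-" in cols[lo]:
        lo += 1
    while hi > lo and "-" in cols[hi - 1]:
        hi -= 1
    compared = matched = 0
    for x, y in cols[lo:hi]:
        if x == "-" or y == "-":
            continue
        compared += 1
        if x == y:
            matched += 1
    return 100.0 * matched / compared if compared else 0.0


def identify(sample: SequenceRecord, pairs, lib: BarcodeLibrary,
             size_tolerance: float = 0.10, max_mismatch: int = 2,
             max_3p_mismatch: int = 0) -> IdentificationCall:
    """Call a species when exactly one pair amplifies the sample with a
    product within ±10% of its expected fragment; report the nearest library
    record's percent identity either way."""
    pairs = [_as_pcrpair(p) for p in pairs]
    if not pairs:
        raise ValueError("need at least one primer pair")
    supporting = []
    for pair in pairs:
        amps = predict_amplicons(pair, sample, max_mismatch=max_mismatch,
                                 max_3p_mismatch=max_3p_mismatch)
        expected = pair.expected_len
        for a in amps:
            if expected is None or abs(a.product_len - expected) <= size_tolerance * expected:
                supporting.append(pair.species)
                break
    called = supporting[0] if len(supporting) == 1 else "no call"
    best_id = ""
    best_sim = 0.0
    for rec in lib:
        sim = alignment_identity(sample.seq, rec.seq)
        if sim > best_sim:
            best_sim = sim
            best_id = rec.id
    return IdentificationCall(sample.id, called, supporting, best_id, best_sim)


def write_amplicons_tsv(amps: list[AmpliconPrediction], path: str | Path) -> None:
    """BED-like per-amplicon report (1-based inclusive coordinates)."""
    pd.DataFrame([{"template": a.template_id, "start": a.fwd_site.start,
                   "end": a.rev_site.end, "product_len": a.product_len,
                   "fwd_strand": a.fwd_site.strand,
                   "fwd_mismatches": a.fwd_site.mismatches,
                   "rev_mismatches": a.rev_site.mismatches}
                  for a in amps]).to_csv(path, sep="\t", index=False)
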