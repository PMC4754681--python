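"""Multiple alignment (center-star) and species-diagnostic SNP discovery.

The center-star construction picks the record with the smallest summed
pairwise distance as the center, aligns every other record to it with the
affine-gap global aligner, and merges the pairwise alignments by taking, for
every inter-residue slot of the center, the maximum number of gap columns
required by any pairwise alignment.  It is deterministic and O(k * n^2) —
adequate for libraries of a few hundred sequences of ITS2 length.

A diagnostic site for a species is an alignment column where every row of
that species carries the same unambiguous base and at most a configurable
fraction of the other rows carry it (0 = a strict site).  Columns where any
target row has a gap or ambiguity code are never diagnostic: a primer 3'
terminus cannot sit on an uncertain state.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

from .align_distance import DistanceMatrix, global_align, p_distance
from .seq_io import BarcodeLibrary, write_fasta

#: Alignment scores used for MSA construction.  Gaps are deliberately much
#: stiffer than in the distance scoring: SNP discovery needs positional
#: homology, and cheap gaps let the aligner chase spurious matches between
#: deeply diverged cores, scrambling columns.  Stiff gaps still recover real
#: short indels (a 2-bp gap beats misaligning hundreds of downstream sites).
MSA_SCORES = {"match": 1.0, "mismatch": -1.0, "gap_open": -6.0, "gap_extend": -3.0}


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, record_id: str) -> str:
        return self.rows[self.ids.index(record_id)]

    def column(self, col: int) -> str:
        """1-based column as a string over rows."""
        return "".join(r[col - 1] for r in self.rows)

    def write_fasta(self, path: str | Path) -> None:
        write_fasta([_AlignedRecord(i, r) for i, r in zip(self.ids, self.rows)], path)


class _AlignedRecord:
    """Minimal record-shaped object so gapped rows can reuse write_fasta."""

    def __init__(self, rec_id: str, seq: str) -> None:
        self.id = rec_id
        self.seq = seq


def read_aligned_fasta(path: str | Path) -> MultipleAlignment:
    """Load an externally produced alignment (aligned FASTA)."""
    from .seq_io import _parse_fasta_text  # gapped rows bypass record validation
    text = Path(path).read_text()
    entries = _parse_fasta_text(text, str(path))
    return MultipleAlignment([e[0] for e in entries], [e[2].upper() for e in entries])


def _compose(mid_vs_a: PairwiseAlignmentLike, mid_vs_c: PairwiseAlignmentLike
             ) -> tuple[str, str]:
    """Transitively compose two pairwise alignments sharing a middle sequence.

    `mid_vs_a` aligns the middle sequence (rows seq_a_aligned) to A
    (seq_b_aligned); `mid_vs_c` aligns the same middle sequence to C.
    Returns (c_aligned, a_aligned): an alignment of C and A.  Insertions of A
    relative to the middle are emitted before insertions of C (deterministic).
    """
    cols1 = list(zip(mid_vs_a.seq_a_aligned, mid_vs_a.seq_b_aligned))
    cols2 = list(zip(mid_vs_c.seq_a_aligned, mid_vs_c.seq_b_aligned))
    out_c: list[str] = []
    out_a: list[str] = []
    i = j = 0
    while i < len(cols1) or j < len(cols2):
        if i < len(cols1) and cols1[i][0] == "-":     # A insertion vs middle
            out_c.append("-")
            out_a.append(cols1[i][1])
            i += 1
            continue
        if j < len(cols2) and cols2[j][0] == "-":     # C insertion vs middle
            out_c.append(cols2[j][1])
            out_a.append("-")
            j += 1
            continue
        # both consume the same middle residue
        ca = cols1[i][1] if i < len(cols1) else "-"
        cc = cols2[j][1] if j < len(cols2) else "-"
        if not (ca == "-" and cc == "-"):
            out_c.append(cc)
            out_a.append(ca)
        i += 1
        j += 1
    return "".join(out_c), "".join(out_a)


class PairwiseAlignmentLike:
    """Duck-typed pairwise alignment (aligned strings only)."""

    def __init__(self, seq_a_aligned: str, seq_b_aligned: str) -> None:
        self.seq_a_aligned = seq_a_aligned
        self.seq_b_aligned = seq_b_aligned


def center_star_msa(lib: BarcodeLibrary, dm: DistanceMatrix | None = None,
                    route_within_species: bool = True,
                    **scores: float) -> MultipleAlignment:
    """Deterministic center-star multiple alignment of a library.

    The center is the record minimizing the summed pairwise distance (ties
    broken by input order); a precomputed distance matrix selects it,
    otherwise p-distances from pairwise alignments are computed here.

    With `route_within_species` (default), each record is first aligned to
    its species' leader (the member closest to the rest of its species) and
    that alignment is composed with the leader-to-center alignment.  Aligning
    near-identical conspecifics places their indels unambiguously, so
    conspecific rows stay column-consistent even when the center is deeply
    diverged — without routing, each record's gaps drift independently and
    within-species columns scramble.  With a single species (or labels all
    "unknown") routing reduces to the plain center-star.
    """
    if len(lib) < 2:
        raise ValueError("nothing to align: need at least 2 records")
    kw = {**MSA_SCORES, **scores}
    records = lib.records
    n = len(records)

    if dm is not None:
        order = {rid: i for i, rid in enumerate(dm.ids)}
        dist = lambda i, j: dm.d[order[records[i].id], order[records[j].id]]
    else:
        d = [[0.0] * n for _ in range(n)]
        for i, j in combinations(range(n), 2):
            aln = global_align(records[i].seq, records[j].seq, **kw)
            d[i][j] = d[j][i] = p_distance(aln)
        dist = lambda i, j: d[i][j]
    sums = [sum(dist(i, j) for j in range(n) if j != i) for i in range(n)]
    center = min(range(n), key=lambda i: (sums[i], i))  # ties -> input order

    c_seq = records[center].seq

    # species leaders: member minimizing summed within-species distance
    leaders: dict[str, int] = {}
    if route_within_species:
        by_species: dict[str, list[int]] = {}
        for i, rec in enumerate(records):
            by_species.setdefault(rec.species, []).append(i)
        for sp, members in by_species.items():
            leaders[sp] = min(
                members,
                key=lambda i: (sum(dist(i, j) for j in members if j != i), i))
        leaders[records[center].species] = center
        leader_aln = {
            i: global_align(records[i].seq, c_seq, **kw)   # leader vs center
            for i in set(leaders.values()) if i != center}

    lc = len(c_seq)
    # gaps_before[p]: gap columns inserted before center residue p (slot lc = tail)
    master = [0] * (lc + 1)
    paths = {}
    for i, rec in enumerate(records):
        if i == center:
            continue
        leader = leaders.get(rec.species, center) if route_within_species else center
        if leader == center:
            aln = global_align(c_seq, rec.seq, **kw)
        elif leader == i:
            l_vs_c = leader_aln[leader]
            aln = PairwiseAlignmentLike(l_vs_c.seq_b_aligned, l_vs_c.seq_a_aligned)
        else:
            via = global_align(records[leader].seq, rec.seq, **kw)
            l_vs_c = leader_aln[leader]
            c_row, r_row = _compose(
                PairwiseAlignmentLike(via.seq_a_aligned, via.seq_b_aligned),
                PairwiseAlignmentLike(l_vs_c.seq_a_aligned, l_vs_c.seq_b_aligned))
            aln = PairwiseAlignmentLike(c_row, r_row)
        slot_gaps = [0] * (lc + 1)
        p = 0
        for ch in aln.seq_a_aligned:
            if ch == "-":
                slot_gaps[p] += 1
            else:
                p += 1
        paths[i] = (aln, slot_gaps)
        for p in range(lc + 1):
            if slot_gaps[p] > master[p]:
                master[p] = slot_gaps[p]

    rows = []
    for i, rec in enumerate(records):
        if i == center:
            parts = []
            for p in range(lc + 1):
                parts.append("-" * master[p])
                if p < lc:
                    parts.append(c_seq[p])
            rows.append("".join(parts))
            continue
        aln, slot_gaps = paths[i]
        parts = []
        p = 0
        chunk = []
        for ca, cb in zip(aln.seq_a_aligned, aln.seq_b_aligned):
            if ca == "-":
                chunk.append(cb)
            else:
                parts.append("".join(chunk) + "-" * (master[p] - len(chunk)))
                parts.append(cb)
                chunk = []
                p += 1
        parts.append("".join(chunk) + "-" * (master[lc] - len(chunk)))
        rows.append("".join(parts))
    return MultipleAlignment([r.id for r in records], rows)


@dataclass(frozen=True)
class DiagnosticSite:
    """Alignment column whose base state separates one species from all others."""

    column: int            # 1-based alignment column
    species: str
    target_state: str      # A/C/G/T shared by every target row
    max_offtarget_share: float  # fraction of non-target rows carrying it


def find_diagnostic_sites(msa: MultipleAlignment, lib: BarcodeLibrary,
                          species: str,
                          max_offtarget_share: float = 0.0) -> list[DiagnosticSite]:
    """Columns where the target species is fixed for a base mostly/fully absent
    from the other species' rows."""
    index = lib.species_index
    if species not in index:
        raise ValueError(f"unknown species {species!r}")
    target_rows = [msa.row(rid) for rid in index[species]]
    other_rows = [row for rid, row in zip(msa.ids, msa.rows)
                  if rid not in set(index[species])]
    sites = []
    for col in range(msa.column_count):
        states = {r[col] for r in target_rows}
        if len(states) != 1:
            continue
        state = states.pop()
        if state not in "ACGT":
            continue
        if other_rows:
            share = sum(r[col] == state for r in other_rows) / len(other_rows)
        else:
            share = 0.0
        if share <= max_offtarget_share:
            sites.append(DiagnosticSite(col + 1, species, state, share))
    return sites


def write_diagnostic_sites(sites: list[DiagnosticSite], path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame([{"column": s.column, "species": s.species,
                   "target_state": s.target_state,
                   "max_offtarget_share": s.max_offtarget_share}
                  for s in sites]).to_csv(path, sep="\t", index=False)
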